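"""Nucleotide sequence utilities shared across the evidence channels.

Sequences are plain upper-case ``str`` over {A,C,G,T} at module boundaries;
internally they are encoded as ``uint8`` code arrays (A=0, C=1, G=2, T=3) so
that Hamming scans and k-mer packing vectorise with numpy.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array.

    Raises ``ValueError`` on characters outside {A,C,G,T} (case-insensitive).
    """
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = set(seq) - set(ALPHABET) - set(ALPHABET.lower())
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in arr)


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def random_seq(rng: np.random.Generator, length: int, probs=None) -> str:
    """Uniform (or biased) i.i.d. nucleotide string."""
    return decode(rng.choice(4, size=length, p=probs).astype(np.uint8))


def mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    """Introduce exactly ``n_mut`` substitutions at distinct random positions."""
    if n_mut == 0:
        return seq
    if n_mut > len(seq):
        raise ValueError("more mutations than positions")
    arr = encode(seq).copy()
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    # shift by 1..3 guarantees a different base at every chosen position
    arr[pos] = (arr[pos] + rng.integers(1, 4, size=n_mut)) % 4
    return decode(arr)


def mutate_to_identity(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Point-mutate i.i.d. so each position differs with prob ``1 - identity``."""
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    arr = encode(seq).copy()
    hit = rng.random(len(seq)) < (1.0 - identity)
    n = int(hit.sum())
    if n:
        arr[hit] = (arr[hit] + rng.integers(1, 4, size=n)) % 4
    return decode(arr)


def pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit pack every k-mer of a code array into a uint64 vector.

    Returns an array of length ``len(codes) - k + 1`` (empty if shorter).
    """
    if codes.size < k:
        return np.empty(0, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.uint64)
    weights = (np.uint64(4) ** np.arange(k, dtype=np.uint64))[::-1]
    return win @ weights


def hamming_scan(spacer: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Mismatch count of ``spacer`` against every window of ``target``.

    Full-length ungapped comparison; returns an int array over all start
    positions (empty when the target is shorter than the spacer).
    """
    m = spacer.size
    if target.size < m:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(target, m)
    return (win != spacer).sum(axis=1)
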