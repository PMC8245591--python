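"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct method available
(exhaustive scans, explicit flood enumeration, per-element tallies) and stay
decoupled from the implementation paths they check.
"""

from collections import deque

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def brute_spacer_scan(spacer: str, phage_seq: str, max_mismatch: int):
    """Every (start, strand, mismatches) placement by position-wise scan."""
    out = []
    m = len(spacer)
    for strand, probe in (("+", spacer), ("-", rc(spacer))):
        for i in range(len(phage_seq) - m + 1):
            mm = sum(a != b for a, b in zip(probe, phage_seq[i:i + m]))
            if mm <= max_mismatch:
                out.append((i, strand, mm))
    return out


def brute_orfs(seq: str, min_orf_aa: int):
    """6-frame start-to-stop ORF enumeration; returns {(start, end, strand)}."""
    from Bio.Seq import Seq

    stops = {"TAA", "TAG", "TGA"}
    n = len(seq)
    found = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else rc(seq)
        for frame in range(3):
            pos = frame
            start = None
            while pos + 3 <= n:
                codon = s[pos:pos + 3]
                if codon in stops:
                    if start is not None and (pos - start) // 3 >= min_orf_aa:
                        if strand == "+":
                            found.add((start, pos + 3, strand))
                        else:
                            found.add((n - pos - 3, n - start, strand))
                    start = None
                elif codon == "ATG" and start is None:
                    start = pos
                pos += 3
    return found


def flood_maxima(img: np.ndarray, t: float):
    """Explicit flood oracle for prominence-thresholded maxima.

    For each equal-value plateau P with value v, flood the component of
    {q : I(q) >= v - t} containing P; P is a reported maximum iff that
    component holds no pixel brighter than v, no equal-valued plateau with a
    row-major-smaller representative, and v exceeds the image minimum by
    more than t when nothing else dominates.  Returns the set of plateau
    representative pixels (row-major index of the plateau's minimal pixel).
    """
    h, w = img.shape
    flat = img.ravel()

    def neighbors(i):
        r, c = divmod(i, w)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    yield rr * w + cc

    # plateau labelling by BFS over equal neighbours
    plateau = np.full(h * w, -1)
    reps = {}
    next_id = 0
    for i in range(h * w):
        if plateau[i] >= 0:
            continue
        q = deque([i])
        plateau[i] = next_id
        members = [i]
        while q:
            x = q.popleft()
            for nb in neighbors(x):
                if plateau[nb] < 0 and flat[nb] == flat[i]:
                    plateau[nb] = next_id
                    q.append(nb)
                    members.append(nb)
        reps[next_id] = min(members)
        next_id += 1

    gmin = flat.min()
    reported = set()
    for pid, rep in reps.items():
        v = flat[rep]
        # flood the strictly-dominance basin {I >= v - t}
        seen = {rep}
        q = deque([rep])
        dominated = False
        while q and not dominated:
            x = q.popleft()
            for nb in neighbors(x):
                if nb in seen or flat[nb] < v - t:
                    continue
                if flat[nb] > v:
                    dominated = True
                    break
                if flat[nb] == v and plateau[nb] != pid and \
                        reps[plateau[nb]] < rep:
                    dominated = True
                    break
                seen.add(nb)
                q.append(nb)
        if not dominated and v - gmin > t:
            reported.add(rep)
    return reported


def brute_partition(edges, phage_labels, host_niches):
    """Per-phage, per-niche tally: count each phage once per niche it hits."""
    from collections import defaultdict

    counts = defaultdict(int)
    phages = {p for p, _ in edges}
    for p in phages:
        niches = {host_niches[h] for q, h in edges if q == p}
        for n in niches:
            counts[(phage_labels[p], n)] += 1
    return dict(counts)
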