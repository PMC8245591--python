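"""CRISPR evidence channel: repeat–spacer array detection and spacer matching.

The detector is a deterministic repeat–spacer finder: exact 13-mers recurring
at a consistent period seed a candidate array, the repeat unit is extended
column-wise across copies, and the result is validated against repeat/spacer
length and repeat-identity constraints.  Spacer matching is ungapped,
full-length Hamming comparison on both strands with a mismatch budget
(default 1, the stringency rule used for host assignment from spacers).

A reverse-strand array is detected as its forward-strand mirror image (a
periodic repeat structure is periodic on both strands); spacer matching is
strand-symmetric, so phage–host links are unaffected by array orientation.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import seqs
from .model import EvidenceLink, HostGenome, PhageContig

logger = logging.getLogger(__name__)

SEED_K = 13


@dataclass
class CrisprParams:
    min_repeats: int = 3
    repeat_len: tuple = (21, 48)
    spacer_len: tuple = (17, 60)
    min_repeat_identity: float = 0.9


@dataclass
class CrisprArray:
    host_id: str
    host_contig_id: str
    repeat_consensus: str
    repeats: list  # [(start, end)] sorted
    spacers: list  # [(start, end, sequence)]
    strand: str = "+"

    @property
    def start(self) -> int:
        return self.repeats[0][0]

    @property
    def end(self) -> int:
        return self.repeats[-1][1]


@dataclass
class SpacerHit:
    phage_id: str
    host_id: str
    array_index: int
    spacer_index: int
    phage_start: int
    phage_end: int
    strand: str
    mismatches: int


def _consensus_column(chars: list) -> tuple[str, int]:
    best, cnt = "", 0
    for c in set(chars):
        n = chars.count(c)
        if n > cnt or (n == cnt and c < best):
            best, cnt = c, n
    return best, cnt


def _extend_side(contig: str, anchors: list, direction: int, max_cols: int):
    """Greedy column-wise extension of the repeat unit across copies.

    Extension walks outward while the column consensus keeps at least
    ``n_copies - 2`` copies in agreement (all copies when only 2-3 are
    available) and returns the extent maximising a cumulative score
    (+1 unanimous, -0.6 one dissent, -0.8 two dissents).  This tolerates
    scattered point mutations inside the repeat while random flanking
    sequence quickly drives the score down.
    """
    n = len(contig)
    n_copies = len(anchors)
    floor = n_copies if n_copies <= 3 else n_copies - 2
    best_len, best_score, score = 0, 0.0, 0.0
    for off in range(1, max_cols + 1):
        cols = []
        for a in anchors:
            pos = a - off if direction < 0 else a + off - 1
            if pos < 0 or pos >= n:
                return best_len
            cols.append(contig[pos])
        _, cnt = _consensus_column(cols)
        if cnt < floor:
            return best_len
        if cnt == n_copies:
            score += 1.0
        elif cnt == n_copies - 1:
            score -= 0.6
        else:
            score -= 0.8
        if score > best_score:
            best_score, best_len = score, off
    return best_len


def _candidate_periods(positions: np.ndarray, d_lo: int, d_hi: int):
    """Periods supported by pairwise distances (allowing one skipped copy)."""
    out = set()
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            d = int(positions[j] - positions[i])
            if d_lo <= d <= d_hi:
                out.add(d)
            elif d % 2 == 0 and d_lo <= d // 2 <= d_hi:
                out.add(d // 2)
    return sorted(out)


def detect_arrays(host: HostGenome, params: CrisprParams | None = None) -> list[CrisprArray]:
    """Detect repeat–spacer arrays on every contig of a host genome.

    Greedy and leftmost-first: candidate arrays are considered in order of
    their leftmost coordinate and accepted only if they do not overlap an
    already accepted array on the same contig.
    """
    p = params or CrisprParams()
    rep_lo, rep_hi = p.repeat_len
    spc_lo, spc_hi = p.spacer_len
    d_lo, d_hi = rep_lo + spc_lo, rep_hi + spc_hi
    arrays = []
    for contig_id in sorted(host.contigs):
        contig = host.contigs[contig_id]
        if len(contig) < 3 * rep_lo:
            continue
        codes = seqs.encode(contig)
        kmers = seqs.pack_kmers(codes, SEED_K)
        pos_by_kmer = defaultdict(list)
        for i, km in enumerate(kmers):
            pos_by_kmer[int(km)].append(i)
        candidates = []  # (first_anchor, period, anchors)
        seen = set()
        for km, positions in pos_by_kmer.items():
            if len(positions) < 2:
                continue
            positions = np.asarray(positions)
            for d in _candidate_periods(positions, d_lo, d_hi):
                p0 = int(positions[0])
                phase = {int(q) for q in positions if (q - p0) % d == 0}
                if len(phase) < 2:
                    continue
                anchors = sorted(phase)
                key = (anchors[0] % d, d, anchors[0])
                if key in seen:
                    continue
                seen.add(key)
                candidates.append((anchors[0], d, anchors))
        accepted_spans = []
        # best-supported candidates first (most seed anchors), then leftmost;
        # acceptance itself stays greedy with no overlaps
        candidates.sort(key=lambda c: (-len(c[2]), c[0], c[1]))
        for a0, d, anchors in candidates:
            arr = _build_array(contig, codes, anchors, d, p, host.id, contig_id)
            if arr is None:
                continue
            span = (arr.start, arr.end)
            if any(span[1] > s and span[0] < e for (s, e) in accepted_spans):
                continue
            accepted_spans.append(span)
            arrays.append(arr)
    return arrays


def _window_identity(contig: str, start: int, consensus: str) -> float:
    end = start + len(consensus)
    if start < 0 or end > len(contig):
        return 0.0
    w = contig[start:end]
    return sum(a == b for a, b in zip(w, consensus)) / len(consensus)


def _build_array(contig, codes, anchors, d, p: CrisprParams, host_id, contig_id):
    """Extend a seeded anchor chain to a validated CrisprArray (or None).

    Phase 1 establishes a rough repeat extent from the (possibly few) seed
    anchors, locates the full consecutive copy chain by stepping the period,
    then phase 2 refines the repeat boundaries using all copies.
    """
    rep_lo, rep_hi = p.repeat_len
    spc_lo, spc_hi = p.spacer_len

    def consensus_of(starts_, rep_len_):
        cols = []
        for off in range(rep_len_):
            col = [contig[s + off] for s in starts_
                   if 0 <= s + off < len(contig)]
            cols.append(_consensus_column(col)[0] if col else "N")
        return "".join(cols)

    # phase 1: rough extent
    left = _extend_side(contig, anchors, -1, rep_hi - SEED_K)
    right = _extend_side(contig, [a + SEED_K for a in anchors], +1,
                         rep_hi - SEED_K - left)
    rep_len = SEED_K + left + right
    starts = [a - left for a in anchors]
    consensus = consensus_of(starts, rep_len)
    # rebuild the copy chain by stepping the period from the first anchor;
    # this recovers copies whose seed k-mer was mutated and keeps the chain
    # consecutive (no skipped copies inflating a "spacer")
    run = [starts[0]]
    while True:
        cand = run[0] - d
        if cand >= 0 and _window_identity(contig, cand, consensus) >= p.min_repeat_identity:
            run.insert(0, cand)
        else:
            break
    while True:
        cand = run[-1] + d
        if cand + rep_len <= len(contig) and \
                _window_identity(contig, cand, consensus) >= p.min_repeat_identity:
            run.append(cand)
        else:
            break
    if len(run) < p.min_repeats:
        return None
    # phase 2: refine boundaries with the full copy set
    seed_anchors = [s + left for s in run]
    left2 = _extend_side(contig, seed_anchors, -1, rep_hi - SEED_K)
    right2 = _extend_side(contig, [a + SEED_K for a in seed_anchors], +1,
                          rep_hi - SEED_K - left2)
    rep_len = SEED_K + left2 + right2
    if not rep_lo <= rep_len <= rep_hi:
        return None
    spacer_len = d - rep_len
    if not spc_lo <= spacer_len <= spc_hi:
        return None
    starts = [a - left2 for a in seed_anchors]
    if starts[0] < 0 or starts[-1] + rep_len > len(contig):
        return None
    consensus = consensus_of(starts, rep_len)
    for s in starts:
        if _window_identity(contig, s, consensus) < p.min_repeat_identity:
            return None
    repeats = [(s, s + rep_len) for s in starts]
    spacers = []
    for (a, b), (c, _) in zip(repeats[:-1], repeats[1:]):
        spacers.append((b, c, contig[b:c]))
    return CrisprArray(host_id=host_id, host_contig_id=contig_id,
                       repeat_consensus=consensus, repeats=repeats,
                       spacers=spacers)


def spacer_hits(arrays: list[CrisprArray], phages: list[PhageContig],
                max_mismatch: int = 1) -> list[SpacerHit]:
    """All full-length ungapped spacer placements with <= max_mismatch
    mismatches, on both strands of every phage."""
    hits = []
    phage_codes = [(ph, seqs.encode(ph.seq)) for ph in phages]
    for ai, arr in enumerate(arrays):
        for si, (_, _, spacer) in enumerate(arr.spacers):
            try:
                sp = seqs.encode(spacer)
            except ValueError:
                logger.warning("skipping spacer with ambiguity codes: array %d spacer %d",
                               ai, si)
                continue
            sp_rc = seqs.revcomp_codes(sp)
            for ph, codes in phage_codes:
                for strand, probe in (("+", sp), ("-", sp_rc)):
                    mm = seqs.hamming_scan(probe, codes)
                    for pos in np.flatnonzero(mm <= max_mismatch):
                        hits.append(SpacerHit(
                            phage_id=ph.id, host_id=arr.host_id,
                            array_index=ai, spacer_index=si,
                            phage_start=int(pos), phage_end=int(pos) + sp.size,
                            strand=strand, mismatches=int(mm[pos])))
    return hits


def match_spacers(arrays: list[CrisprArray], phages: list[PhageContig],
                  max_mismatch: int = 1) -> list[EvidenceLink]:
    """One "crispr" EvidenceLink per (phage, host) pair with >= 1 spacer hit.

    The link carries the best hit: fewest mismatches, then leftmost phage
    position, then '+' strand.
    """
    best: dict[tuple, SpacerHit] = {}
    for h in spacer_hits(arrays, phages, max_mismatch):
        key = (h.phage_id, h.host_id)
        cur = best.get(key)
        rank = (h.mismatches, h.phage_start, 0 if h.strand == "+" else 1)
        if cur is None or rank < (cur.mismatches, cur.phage_start,
                                  0 if cur.strand == "+" else 1):
            best[key] = h
    links = []
    for (phage_id, host_id), h in sorted(best.items()):
        links.append(EvidenceLink(
            phage_id=phage_id, host_id=host_id, channel="crispr",
            scores=(("mismatches", h.mismatches),
                    ("phage_start", h.phage_start),
                    ("phage_end", h.phage_end),
                    ("strand", h.strand))))
    return links
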