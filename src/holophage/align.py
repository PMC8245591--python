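"""Nucleotide local alignment: banded affine-gap DP with a seed-and-extend front end.

Scoring follows the BLASTn-style convention match +1 / mismatch -1 with a gap
of length L costing ``gap_open + gap_extend * L`` (defaults 10 and 10, so the
first gap column scores -20 and each further column -10).  At these penalties
gapped paths are rarely optimal, but the DP is exact for them.

The DP is vectorised row-wise over a diagonal band.  Horizontal (subject-gap)
moves within a row are resolved with a running-maximum scan, which is exact
because re-opening a gap in the same row can never beat extending it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import seqs

NEG = -(10**6)


@dataclass
class AlignmentParams:
    match: int = 1
    mismatch: int = -1
    gap_open: int = 10  # charged once per gap, on top of gap_extend
    gap_extend: int = 10  # charged per gap column
    min_score: int = 50
    seed_k: int = 11
    min_seed_hits: int = 5  # even a minimal 1 kb / 80%-identity hit seeds ~86 times
    band_pad: int = 32
    window_margin: int = 100
    full_dp_area: int = 4_000_000  # run exhaustive DP below this q*s area


@dataclass
class RawAlignment:
    """A local alignment in query/subject coordinates (0-based half-open).

    ``strand`` is '+' when the query aligned as given and '-' when its
    reverse complement did; intervals always refer to the forward sequences.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    columns: int
    matches: int
    score: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def subject_span(self) -> int:
        return self.s_end - self.s_start


def _dp_banded(q: np.ndarray, s: np.ndarray, lo: int, hi: int, p: AlignmentParams):
    """Affine local DP restricted to diagonals ``lo <= j - i <= hi``.

    Rows index the query (i = 1..n), columns the subject via the band index
    ``idx`` with j = i + lo + idx.  Returns the score/state matrices needed
    for traceback plus the argmax cell.
    """
    n, m = q.size, s.size
    w = hi - lo + 1
    oe = p.gap_open + p.gap_extend
    H = np.full((n + 1, w), NEG, dtype=np.int32)
    T0 = np.full((n + 1, w), NEG, dtype=np.int32)
    Ix = np.full((n + 1, w), NEG, dtype=np.int32)
    Iy = np.full((n + 1, w), NEG, dtype=np.int32)
    idx = np.arange(w)  # j for row i is i + lo + idx
    H[0, :] = np.where((lo + idx >= 0) & (lo + idx <= m), 0, NEG)
    T0[0, :] = H[0, :]
    ext_ramp = p.gap_extend * idx
    s_pad = np.concatenate((s, np.full(1, 255, dtype=s.dtype)))
    for i in range(1, n + 1):
        j = i + lo + idx
        invalid = (j < 1) | (j > m)
        jj = np.where(invalid, m, j - 1)
        sub = np.where(s_pad[jj] == q[i - 1], p.match, p.mismatch)
        diag = H[i - 1] + sub  # (i-1, j-1) sits at the same band index
        hp = np.empty(w, dtype=np.int32)  # H[i-1, j] -> band index idx+1
        hp[:-1] = H[i - 1, 1:]
        hp[-1] = NEG
        xp = np.empty(w, dtype=np.int32)
        xp[:-1] = Ix[i - 1, 1:]
        xp[-1] = NEG
        ix = np.maximum(hp - oe, xp - p.gap_extend)
        t0 = np.maximum(0, np.maximum(diag, ix))
        t0[invalid] = NEG
        # horizontal scan: Iy[idx] = max_{k<idx} T0[k] - open - ext*(idx-k)
        run = np.maximum.accumulate(t0 + ext_ramp)
        iy = np.empty(w, dtype=np.int32)
        iy[0] = NEG
        iy[1:] = run[:-1] - p.gap_open - ext_ramp[1:]
        iy[invalid] = NEG
        h = np.maximum(t0, iy)
        H[i], T0[i], Ix[i], Iy[i] = h, t0, ix, iy
    # exclude the artificial row 0 from argmax
    best_flat = int(np.argmax(H[1:]))
    bi, bidx = divmod(best_flat, w)
    return H, T0, Ix, Iy, bi + 1, bidx


def _traceback(q, s, H, T0, Ix, Iy, i, idx, lo, p: AlignmentParams):
    """Recover one optimal path from cell (i, idx); returns a RawAlignment
    in '+' orientation (caller fixes strand)."""
    oe = p.gap_open + p.gap_extend
    score = int(H[i, idx])
    q_end = i
    s_end = i + lo + idx
    cols = 0
    matches = 0
    state = "H"
    while True:
        j = i + lo + idx
        if state == "H":
            val = H[i, idx]
            if val == 0:
                break
            dsub = p.match if q[i - 1] == s[j - 1] else p.mismatch
            if i >= 1 and val == H[i - 1, idx] + dsub and H[i - 1, idx] > NEG // 2:
                cols += 1
                matches += int(dsub == p.match)
                i -= 1
                continue
            if val == Ix[i, idx]:
                state = "X"
                continue
            if val == Iy[i, idx]:
                state = "Y"
                continue
            raise AssertionError("inconsistent traceback (H)")
        if state == "X":  # gap in subject, consume query
            cols += 1
            if idx + 1 >= Ix.shape[1]:
                raise AssertionError("inconsistent traceback (X band edge)")
            if Ix[i, idx] == Ix[i - 1, idx + 1] - p.gap_extend:
                i -= 1
                idx += 1
                continue
            # gap opened here
            assert Ix[i, idx] == H[i - 1, idx + 1] - oe
            i -= 1
            idx += 1
            state = "H"
            continue
        # state Y: gap in query, consume subject; find the opening column k
        target = Iy[i, idx]
        k = idx - 1
        while k >= 0:
            if T0[i, k] - p.gap_open - p.gap_extend * (idx - k) == target:
                break
            k -= 1
        assert k >= 0, "inconsistent traceback (Y)"
        cols += idx - k
        idx = k
        # continue from T0 (never another horizontal gap immediately)
        val = T0[i, idx]
        if val == 0:
            break
        j = i + lo + idx
        dsub = p.match if q[i - 1] == s[j - 1] else p.mismatch
        if val == H[i - 1, idx] + dsub and H[i - 1, idx] > NEG // 2:
            cols += 1
            matches += int(dsub == p.match)
            i -= 1
            state = "H"
            continue
        assert val == Ix[i, idx]
        state = "X"
    return RawAlignment(
        q_start=i,
        q_end=q_end,
        s_start=i + lo + idx,
        s_end=s_end,
        strand="+",
        columns=cols,
        matches=matches,
        score=score,
    )


def dp_local(q_codes: np.ndarray, s_codes: np.ndarray, p: AlignmentParams,
             lo: int | None = None, hi: int | None = None) -> RawAlignment | None:
    """Best local alignment by (optionally banded) exact DP; None if best score <= 0."""
    n, m = q_codes.size, s_codes.size
    if n == 0 or m == 0:
        return None
    if lo is None:
        lo = -(n - 1)
    if hi is None:
        hi = m - 1
    H, T0, Ix, Iy, bi, bidx = _dp_banded(q_codes, s_codes, lo, hi, p)
    if H[bi, bidx] <= 0:
        return None
    return _traceback(q_codes, s_codes, H, T0, Ix, Iy, bi, bidx, lo, p)


class SeedIndex:
    """Sorted k-mer index of a code array, reusable across pairings."""

    def __init__(self, codes: np.ndarray, k: int):
        self.codes = codes
        self.k = k
        kmers = seqs.pack_kmers(codes, k)
        self.order = np.argsort(kmers, kind="stable")
        self.sorted = kmers[self.order]


def _seed_clusters(q_codes, s_codes, p: AlignmentParams,
                   q_index: SeedIndex | None = None,
                   s_index: SeedIndex | None = None):
    """Find co-diagonal clusters of exact seed_k-mer matches.

    Returns a list of (q_lo, q_hi, s_lo, s_hi, d_lo, d_hi) candidate regions.
    """
    k = p.seed_k
    qi_idx = q_index if q_index is not None else SeedIndex(q_codes, k)
    si_idx = s_index if s_index is not None else SeedIndex(s_codes, k)
    qs, ss = qi_idx.sorted, si_idx.sorted
    q_order, s_order = qi_idx.order, si_idx.order
    if qs.size == 0 or ss.size == 0:
        return []
    # shared k-mers via merge of the two sorted arrays
    qu = qs[np.concatenate(([True], qs[1:] != qs[:-1]))] if qs.size else qs
    pos = np.searchsorted(ss, qu)
    pos_ok = pos < ss.size
    common = qu[pos_ok][ss[pos[pos_ok]] == qu[pos_ok]]
    if common.size == 0:
        return []
    # expand duplicate k-mers: for each common k-mer, all (qpos, spos) pairs
    q_left = np.searchsorted(qs, common, side="left")
    q_right = np.searchsorted(qs, common, side="right")
    s_left = np.searchsorted(ss, common, side="left")
    s_right = np.searchsorted(ss, common, side="right")
    qp_list, sp_list = [], []
    for a, b, c, d in zip(q_left, q_right, s_left, s_right):
        qpos = q_order[a:b]
        spos = s_order[c:d]
        if len(qpos) * len(spos) > 64:  # ignore hyper-repetitive seeds
            continue
        gq, gs = np.meshgrid(qpos, spos, indexing="ij")
        qp_list.append(gq.ravel())
        sp_list.append(gs.ravel())
    if not qp_list:
        return []
    qp = np.concatenate(qp_list)
    sp = np.concatenate(sp_list)
    diag = sp - qp
    order = np.lexsort((sp, diag))
    qp, sp, diag = qp[order], sp[order], diag[order]
    clusters = []

    def emit(idx):
        if len(idx) >= p.min_seed_hits:
            cq, cs, cd = qp[idx], sp[idx], diag[idx]
            clusters.append((int(cq.min()), int(cq.max()) + p.seed_k,
                             int(cs.min()), int(cs.max()) + p.seed_k,
                             int(cd.min()), int(cd.max())))

    # two-level chaining: split on diagonal gaps, then on subject-position
    # gaps within each diagonal band
    band_start = 0
    for t in range(1, diag.size + 1):
        if t == diag.size or diag[t] - diag[t - 1] > 2 * p.band_pad:
            band = np.arange(band_start, t)
            band = band[np.argsort(sp[band], kind="stable")]
            chain_start = 0
            bsp = sp[band]
            for u in range(1, band.size + 1):
                if u == band.size or bsp[u] - bsp[u - 1] > 2000:
                    emit(band[chain_start:u])
                    chain_start = u
            band_start = t
    return clusters


def _align_one_strand(q_codes, s_codes, strand, p: AlignmentParams,
                      q_index: SeedIndex | None = None,
                      s_index: SeedIndex | None = None):
    n, m = q_codes.size, s_codes.size
    out = []
    if n == 0 or m == 0:
        return out
    if n * m <= p.full_dp_area:
        # exhaustive DP; extract non-overlapping hits by splitting the subject
        def recurse(s_off, s_sub):
            if s_sub.size < p.seed_k:
                return
            aln = dp_local(q_codes, s_sub, p)
            if aln is None or aln.score < p.min_score:
                return
            aln.s_start += s_off
            aln.s_end += s_off
            aln.strand = strand
            out.append(aln)
            left_end = aln.s_start - s_off
            recurse(s_off, s_sub[:left_end])
            recurse(aln.s_end, s_sub[aln.s_end - s_off:])

        recurse(0, s_codes)
        return out
    for (q_lo, q_hi, s_lo, s_hi, d_lo, d_hi) in _seed_clusters(
            q_codes, s_codes, p, q_index, s_index):
        mg = p.window_margin
        qa, qb = max(0, q_lo - mg), min(n, q_hi + mg)
        sa, sb = max(0, s_lo - mg), min(m, s_hi + mg)
        qw, sw = q_codes[qa:qb], s_codes[sa:sb]
        if qw.size * sw.size <= p.full_dp_area:
            aln = dp_local(qw, sw, p)
        else:
            # band expressed in window coordinates (diag = s_idx - q_idx)
            lo = d_lo - (sa - qa) - p.band_pad
            hi = d_hi - (sa - qa) + p.band_pad
            aln = dp_local(qw, sw, p, lo=lo, hi=hi)
        if aln is None or aln.score < p.min_score:
            continue
        aln.q_start += qa
        aln.q_end += qa
        aln.s_start += sa
        aln.s_end += sa
        aln.strand = strand
        out.append(aln)
    return out


def local_align(query: str, subject: str, params: AlignmentParams | None = None,
                indexes=None) -> list[RawAlignment]:
    """High-scoring local alignments of ``query`` against ``subject``, both strands.

    Alignments are greedily selected by descending score with no overlap on
    the subject; only hits with score >= ``params.min_score`` are returned.
    For '-' strand hits the query interval refers to the forward query.
    ``indexes`` may carry precomputed (fwd_query, rc_query, subject)
    SeedIndex objects to amortise k-mer sorting across many pairings.
    """
    p = params or AlignmentParams()
    q = seqs.encode(query)
    s = seqs.encode(subject)
    n = q.size
    q_rc = seqs.revcomp_codes(q)
    qi = ri = si = None
    if indexes is not None:
        qi, ri, si = indexes
    hits = _align_one_strand(q, s, "+", p, qi, si)
    for aln in _align_one_strand(q_rc, s, "-", p, ri, si):
        aln.q_start, aln.q_end = n - aln.q_end, n - aln.q_start
        hits.append(aln)
    hits.sort(key=lambda a: (-a.score, a.s_start, a.strand))
    chosen: list[RawAlignment] = []
    for aln in hits:
        if all(aln.s_end <= c.s_start or aln.s_start >= c.s_end for c in chosen):
            chosen.append(aln)
    return chosen
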