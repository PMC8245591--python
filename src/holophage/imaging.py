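"""Fluorescence spot quantification and group comparison.

``find_maxima`` re-implements prominence-based local-maxima counting (the
"noise tolerance" style of spot calling): a local maximum is reported iff
flooding downward from its value by the prominence threshold never reaches a
higher pixel.  Internally this is computed with a persistence sweep: pixels
are condensed into equal-value plateaus, plateaus are activated from the
brightest down, and a union-find tracks when each peak's basin merges into a
higher peak — the merge level fixes the peak's prominence.  Equal-valued
distinct peaks are ordered deterministically (the plateau containing the
row-major-smallest pixel wins); each plateau reports one representative
pixel, the member nearest its centroid.

Group differences in spot counts are tested with a Kruskal–Wallis omnibus
test followed by Dunn's pairwise z tests under Benjamini–Hochberg FDR
control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class SpotImage:
    image: np.ndarray
    group: str = ""
    probe_id: str = ""
    pixel_size: float | None = None  # micrometres, optional


@dataclass
class SpotCallSet:
    threshold: float
    maxima: list  # [(row, col, intensity, prominence)]

    @property
    def count(self) -> int:
        return len(self.maxima)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
        return ra


_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _plateaus(img: np.ndarray):
    """Condense 8-connected equal-value pixel sets into plateau nodes.

    Returns (label image, per-plateau value, representative pixel index
    (row-major min), report pixel (nearest the plateau centroid), edge flag,
    adjacency sets).
    """
    h, w = img.shape
    n = h * w
    uf = _UnionFind(n)
    flat = img.ravel()
    idx = np.arange(n).reshape(h, w)
    pairs = []
    for (dr, dc) in [(0, 1), (1, 0), (1, 1), (1, -1)]:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = idx[r0:r1, c0:c1]
        b = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        eq = flat[a] == flat[b]
        pairs.append((a[eq].ravel(), b[eq].ravel()))
    for a, b in pairs:
        for x, y in zip(a.tolist(), b.tolist()):
            uf.union(x, y)
    roots = np.fromiter((uf.find(i) for i in range(n)), dtype=np.int64, count=n)
    uniq, labels = np.unique(roots, return_inverse=True)
    k = uniq.size
    value = flat[uniq]
    rep = np.full(k, n, dtype=np.int64)
    np.minimum.at(rep, labels, np.arange(n))
    rows, cols = np.divmod(np.arange(n), w)
    cnt = np.bincount(labels, minlength=k).astype(float)
    cy = np.bincount(labels, weights=rows, minlength=k) / cnt
    cx = np.bincount(labels, weights=cols, minlength=k) / cnt
    d2 = (rows - cy[labels]) ** 2 + (cols - cx[labels]) ** 2
    # per-plateau member nearest the centroid, row-major tie-break
    order = np.lexsort((np.arange(n), d2, labels))
    first = np.searchsorted(labels[order], np.arange(k))
    report = order[first]
    on_edge = np.zeros(k, dtype=bool)
    edge_mask = np.zeros((h, w), dtype=bool)
    edge_mask[0, :] = edge_mask[-1, :] = True
    edge_mask[:, 0] = edge_mask[:, -1] = True
    on_edge[np.unique(labels.reshape(h, w)[edge_mask])] = True
    adj = [set() for _ in range(k)]
    lab2 = labels.reshape(h, w)
    for (dr, dc) in [(0, 1), (1, 0), (1, 1), (1, -1)]:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = lab2[r0:r1, c0:c1].ravel()
        b = lab2[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        ne = a != b
        for x, y in set(zip(a[ne].tolist(), b[ne].tolist())):
            adj[x].add(y)
            adj[y].add(x)
    return labels.reshape(h, w), value, rep, report, on_edge, adj


def find_maxima(image: np.ndarray, prominence: float,
                include_edges: bool = True) -> SpotCallSet:
    """Prominence-thresholded local maxima of a 2-D intensity grid.

    A maximum is reported iff its prominence strictly exceeds the threshold,
    where prominence is the drop from the peak to the level at which its
    basin first touches a higher (or precedence-dominant equal) peak; the
    global maximum's prominence is its height above the image minimum.
    Maxima come back sorted by descending intensity.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.isfinite(img).all():
        raise ValueError("non-finite pixels in image")
    if prominence < 0:
        raise ValueError("prominence threshold must be >= 0")
    _, value, rep, report, on_edge, adj = _plateaus(img)
    k = value.size
    order = sorted(range(k), key=lambda i: (-value[i], rep[i]))
    uf = _UnionFind(k)
    peak = {}  # root -> plateau id of component peak
    active = np.zeros(k, dtype=bool)
    prom = {}  # plateau id -> prominence (set at death)
    for u in order:
        active[u] = True
        peak[u] = u
        for wnb in sorted(adj[u], key=lambda i: (rep[i],)):
            if not active[wnb]:
                continue
            ru, rw = uf.find(u), uf.find(wnb)
            if ru == rw:
                continue
            pu, pw = peak[ru], peak[rw]
            # loser: lower peak; equal peaks lose by larger representative
            if (value[pu], -rep[pu]) < (value[pw], -rep[pw]):
                loser, winner = pu, pw
            else:
                loser, winner = pw, pu
            prom[loser] = float(value[loser] - value[u])
            r = uf.union(ru, rw)
            peak[r] = winner
    gmin = float(value.min())
    survivors = {peak[uf.find(i)] for i in range(k)}
    for s in survivors:
        prom[s] = float(value[s] - gmin)
    maxima = []
    for pid, pr in prom.items():
        if pr > prominence and (include_edges or not on_edge[pid]):
            r, c = divmod(int(report[pid]), img.shape[1])
            maxima.append((r, c, float(value[pid]), pr))
    maxima.sort(key=lambda m: (-m[2], m[0], m[1]))
    return SpotCallSet(threshold=float(prominence), maxima=maxima)


def optimize_threshold(pos_images: list[np.ndarray], neg_images: list[np.ndarray],
                       grid, neg_cap: float = 1.0) -> float:
    """Control-driven prominence selection.

    Chooses the grid value maximising mean count(positive controls) minus
    mean count(negative controls) subject to the negative-control mean not
    exceeding ``neg_cap`` spots per image; ties break toward the larger
    threshold.  If no grid value satisfies the cap the largest grid value is
    returned.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty threshold grid")
    if not pos_images or not neg_images:
        raise ValueError("need >= 1 image per control class")
    best_t, best_obj = None, None
    for t in sorted(grid):
        pos_mean = float(np.mean([find_maxima(im, t).count for im in pos_images]))
        neg_mean = float(np.mean([find_maxima(im, t).count for im in neg_images]))
        if neg_mean > neg_cap:
            continue
        obj = pos_mean - neg_mean
        if best_obj is None or obj >= best_obj:  # >= prefers larger t
            best_t, best_obj = t, obj
    if best_t is None:
        return float(max(grid))
    return float(best_t)


@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adj: float
    significant: bool


@dataclass
class GroupComparison:
    groups: dict
    kw_statistic: float
    kw_p: float
    pairwise: list = field(default_factory=list)


def compare_groups(counts: dict, alpha: float = 0.05) -> GroupComparison:
    """Kruskal–Wallis omnibus + Dunn's pairwise z + Benjamini–Hochberg.

    ``counts`` maps group name -> list of per-image spot counts (each group
    needs n >= 2).  Dunn's z uses pooled mid-ranks with tie correction; BH
    runs across all pairwise tests.
    """
    names = sorted(counts)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    samples = [np.asarray(counts[g], dtype=float) for g in names]
    for g, s in zip(names, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} has n < 2")
    kw_stat, kw_p = stats.kruskal(*samples)
    pooled = np.concatenate(samples)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    split = np.cumsum([s.size for s in samples])[:-1]
    group_ranks = np.split(ranks, split)
    mean_ranks = [gr.mean() for gr in group_ranks]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    raw_p, zs, pairs = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(var_base * (1.0 / samples[i].size + 1.0 / samples[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            pairs.append((names[i], names[j]))
            zs.append(float(z))
            raw_p.append(min(1.0, float(p)))
    if raw_p:
        _, p_adj, _, _ = multipletests(raw_p, method="fdr_bh")
    else:
        p_adj = []
    pairwise = [PairwiseTest(a, b, z, pr, float(pa), bool(pa <= alpha))
                for (a, b), z, pr, pa in zip(pairs, zs, raw_p, p_adj)]
    return GroupComparison(groups={g: list(map(float, s))
                                   for g, s in zip(names, samples)},
                           kw_statistic=float(kw_stat), kw_p=float(kw_p),
                           pairwise=pairwise)
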