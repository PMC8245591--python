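"""Ensemble infection network: assembly, enrichment labelling, environmental
partitioning and the label-randomisation stratification test.

The network is bipartite (phage nodes vs host nodes); an edge carries the
union of evidence channels that support the phage→host assignment.  Only
matched nodes appear (phages and hosts without any link are dropped).

The stratification statistic is ``diffprop``: the difference between the
probability that an edge lands on a sponge-symbiont host given the phage is
sponge-enriched and the same probability given the phage is
seawater-enriched, computed over edges with mixed/unknown phages excluded.
It is bounded in [-1, 1], antisymmetric under swapping the two phage labels,
and pluggable (any callable on the same edge arrays can replace it).
Significance comes from permuting the phage enrichment labels uniformly
among phage nodes (edges fixed) with the add-one permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .model import EvidenceLink

PHAGE_LABELS = ("sponge", "seawater", "mixed", "unknown")
HOST_NICHES = ("sponge_symbiont", "plankton", "other_environment", "other_animal")


class DegenerateLabelsError(ValueError):
    """The statistic is undefined: one of the conditional label classes
    has no edges."""


def assemble_network(links: list[EvidenceLink], phage_meta: dict,
                     host_meta: dict) -> nx.Graph:
    """Combine per-channel links into one bipartite infection network.

    ``phage_meta`` maps phage id -> enrichment label, ``host_meta`` maps
    host id -> niche label.  Duplicate (phage, host) links merge; their
    channels union and per-channel scores are kept side by side.  Ids absent
    from the metadata raise ``KeyError``.
    """
    g = nx.Graph()
    for link in links:
        if link.phage_id not in phage_meta:
            raise KeyError(f"unknown phage id in links: {link.phage_id!r}")
        if link.host_id not in host_meta:
            raise KeyError(f"unknown host id in links: {link.host_id!r}")
        p, h = link.phage_id, link.host_id
        if not g.has_node(p):
            g.add_node(p, bipartite="phage", label=phage_meta[p])
        if not g.has_node(h):
            g.add_node(h, bipartite="host", niche=host_meta[h])
        if g.has_edge(p, h):
            g[p][h]["channels"] = g[p][h]["channels"] | {link.channel}
            g[p][h]["scores"][link.channel] = link.score_dict
        else:
            g.add_edge(p, h, channels={link.channel},
                       scores={link.channel: link.score_dict})
    return g


def label_enrichment(abundance: pd.DataFrame, lengths: dict, sample_env: dict,
                     fold: float = 2.0, min_prevalence: float = 0.5) -> dict:
    """Per-phage environment enrichment from a read-count table.

    Cpk (copy per kilobase) per sample is count / (contig length / 1000).
    A phage is "sponge" when its mean sponge Cpk is >= fold times its mean
    seawater Cpk and it is detected (Cpk > 0) in at least ``min_prevalence``
    of sponge samples; "seawater" symmetrically; otherwise "mixed".  Phages
    with zero counts everywhere are "unknown".
    """
    envs = sorted(set(sample_env.values()))
    if len(envs) != 2 or set(envs) != {"sponge", "seawater"}:
        raise ValueError("label_enrichment expects sponge and seawater samples")
    sponge_cols = [s for s in abundance.columns if sample_env[s] == "sponge"]
    sea_cols = [s for s in abundance.columns if sample_env[s] == "seawater"]
    if not sponge_cols or not sea_cols:
        raise ValueError("need >= 1 sample per environment")
    labels = {}
    for phage_id, row in abundance.iterrows():
        length = lengths[phage_id]
        if length <= 0:
            raise ValueError(f"zero-length contig: {phage_id!r}")
        cpk = row / (length / 1000.0)
        sp, sw = cpk[sponge_cols], cpk[sea_cols]
        if (row == 0).all():
            labels[phage_id] = "unknown"
        elif sp.mean() >= fold * sw.mean() and \
                (sp > 0).mean() >= min_prevalence:
            labels[phage_id] = "sponge"
        elif sw.mean() >= fold * sp.mean() and \
                (sw > 0).mean() >= min_prevalence:
            labels[phage_id] = "seawater"
        else:
            labels[phage_id] = "mixed"
    return labels


def partition_table(network: nx.Graph) -> pd.DataFrame:
    """Environmental partitioning counts (phage source x host niche).

    Each phage contributes once per distinct host-niche category it links
    to, regardless of how many hosts of that niche it hits.
    """
    counts = pd.DataFrame(0, index=list(PHAGE_LABELS), columns=list(HOST_NICHES))
    for node, data in network.nodes(data=True):
        if data.get("bipartite") != "phage":
            continue
        label = data.get("label", "unknown")
        niches = {network.nodes[h].get("niche") for h in network.neighbors(node)}
        for niche in niches:
            if niche in HOST_NICHES:
                counts.loc[label, niche] += 1
    return counts


def _edge_arrays(network: nx.Graph):
    """Flatten the network into (phage ids, per-phage labels, edge phage
    index, edge-is-symbiont mask)."""
    phages = sorted(n for n, d in network.nodes(data=True)
                    if d.get("bipartite") == "phage")
    index = {p: i for i, p in enumerate(phages)}
    labels = np.array([network.nodes[p].get("label", "unknown") for p in phages])
    e_phage, e_symb = [], []
    for u, v in network.edges():
        p, h = (u, v) if network.nodes[u].get("bipartite") == "phage" else (v, u)
        e_phage.append(index[p])
        e_symb.append(network.nodes[h].get("niche") == "sponge_symbiont")
    return phages, labels, np.asarray(e_phage), np.asarray(e_symb, dtype=bool)


def diffprop(labels: np.ndarray, edge_phage: np.ndarray,
             edge_symb: np.ndarray) -> float:
    """P(edge on symbiont | sponge phage) - P(edge on symbiont | seawater phage)."""
    edge_labels = labels[edge_phage]
    sponge = edge_labels == "sponge"
    sea = edge_labels == "seawater"
    if not sponge.any() or not sea.any():
        raise DegenerateLabelsError("degenerate labels: a phage label class has no edges")
    return float(edge_symb[sponge].mean() - edge_symb[sea].mean())


def assortment_statistic(network: nx.Graph, statistic=diffprop) -> float:
    """Evaluate the stratification statistic on a labelled network."""
    _, labels, e_phage, e_symb = _edge_arrays(network)
    if e_phage.size == 0:
        raise DegenerateLabelsError("degenerate labels: network has no edges")
    return statistic(labels, e_phage, e_symb)


@dataclass
class StratificationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    sided: str

    def summary(self) -> dict:
        return {"observed": self.observed, "p_value": self.p_value,
                "n_perm": self.n_perm, "seed": self.seed, "sided": self.sided,
                "null_mean": float(self.null.mean()),
                "null_sd": float(self.null.std(ddof=1)),
                "null_q025": float(np.quantile(self.null, 0.025)),
                "null_q975": float(np.quantile(self.null, 0.975))}


def permutation_test(network: nx.Graph, n_perm: int = 10_000, seed: int = 0,
                     sided: str = "two", statistic=diffprop) -> StratificationResult:
    """Label-randomisation test of network stratification.

    Phage enrichment labels are permuted uniformly among phage nodes while
    the edges stay fixed; the statistic is recomputed per replicate.  The
    p-value uses the add-one rule p = (1 + #extreme) / (1 + n_perm), so its
    floor is 1/(n_perm + 1).  Replicates on which the statistic is undefined
    are redrawn (at most 10 * n_perm attempts in total).
    """
    rng = np.random.default_rng(seed)
    _, labels, e_phage, e_symb = _edge_arrays(network)
    if e_phage.size == 0:
        raise DegenerateLabelsError("degenerate labels: network has no edges")
    observed = statistic(labels, e_phage, e_symb)
    null = np.empty(n_perm)
    attempts = 0
    i = 0
    while i < n_perm:
        if attempts >= 10 * n_perm:
            raise DegenerateLabelsError(
                "too many degenerate permutation replicates")
        attempts += 1
        perm = rng.permutation(labels)
        try:
            null[i] = statistic(perm, e_phage, e_symb)
        except DegenerateLabelsError:
            continue
        i += 1
    if sided == "two":
        extreme = np.abs(null) >= abs(observed)
    elif sided == "greater":
        extreme = null >= observed
    elif sided == "less":
        extreme = null <= observed
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    p = (1 + int(extreme.sum())) / (1 + n_perm)
    return StratificationResult(observed=float(observed), null=null,
                                p_value=p, n_perm=n_perm, seed=seed,
                                sided=sided)
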