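import numpy as np
import pandas as pd
import pytest

from holophage import network
from holophage.model import EvidenceLink

from oracles import brute_partition


def _link(p, h, channel="crispr"):
    return EvidenceLink(phage_id=p, host_id=h, channel=channel)


def _net(edges, phage_labels, host_niches):
    links = [_link(p, h) for p, h in edges]
    return network.assemble_network(links, phage_labels, host_niches)


class TestAssemble:
    def test_channels_union_on_duplicate_pair(self):
        links = [_link("p1", "h1", "crispr"), _link("p1", "h1", "homology")]
        g = network.assemble_network(links, {"p1": "sponge"},
                                     {"h1": "sponge_symbiont"})
        assert g.number_of_edges() == 1
        assert g["p1"]["h1"]["channels"] == {"crispr", "homology"}

    def test_empty_links_empty_network(self):
        g = network.assemble_network([], {}, {})
        assert g.number_of_nodes() == 0

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError, match="pX"):
            network.assemble_network([_link("pX", "h1")], {}, {"h1": "plankton"})

    def test_bipartite_no_isolated_nodes(self):
        g = _net([("p1", "h1"), ("p2", "h1")],
                 {"p1": "sponge", "p2": "seawater", "p3": "mixed"},
                 {"h1": "plankton", "h2": "plankton"})
        assert set(g.nodes) == {"p1", "p2", "h1"}
        for u, v in g.edges():
            kinds = {g.nodes[u]["bipartite"], g.nodes[v]["bipartite"]}
            assert kinds == {"phage", "host"}


class TestEnrichment:
    lengths = {"p": 10_000}
    env = {"s0": "sponge", "s1": "sponge", "w0": "seawater", "w1": "seawater"}

    def _label(self, counts):
        tab = pd.DataFrame({c: [v] for c, v in counts.items()}, index=["p"])
        return network.label_enrichment(tab, self.lengths, self.env)["p"]

    def test_all_sponge_counts(self):
        assert self._label({"s0": 100, "s1": 100, "w0": 0, "w1": 0}) == "sponge"

    def test_all_seawater_counts(self):
        assert self._label({"s0": 0, "s1": 0, "w0": 100, "w1": 100}) == "seawater"

    def test_equal_means_mixed(self):
        assert self._label({"s0": 50, "s1": 50, "w0": 50, "w1": 50}) == "mixed"

    def test_absent_everywhere_unknown(self):
        assert self._label({"s0": 0, "s1": 0, "w0": 0, "w1": 0}) == "unknown"

    def test_prevalence_gate(self):
        # high mean driven by one sample, detected in only half... min_prevalence
        # 0.5 still passes; 1 of 4 sponge samples fails a 0.5 floor
        tab = pd.DataFrame({"s0": [400], "s1": [0], "s2": [0], "s3": [0],
                            "w0": [10], "w1": [10]}, index=["p"])
        env = {"s0": "sponge", "s1": "sponge", "s2": "sponge", "s3": "sponge",
               "w0": "seawater", "w1": "seawater"}
        labels = network.label_enrichment(tab, {"p": 10_000}, env)
        assert labels["p"] == "mixed"

    def test_zero_length_contig_errors(self):
        tab = pd.DataFrame({"s0": [1], "w0": [1]}, index=["p"])
        with pytest.raises(ValueError, match="zero-length"):
            network.label_enrichment(tab, {"p": 0},
                                     {"s0": "sponge", "w0": "seawater"})

    def test_planted_enrichment_recovery(self):
        """fold-8 effects over 6 samples/environment recover >= 95% of
        planted labels across seeds."""
        from holophage import synthetic

        hits = total = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            phages = [type("P", (), {"id": f"p{i}", "seq": "A" * 10_000})()
                      for i in range(8)]
            enrich = {f"p{i}": ["sponge", "seawater", "mixed"][i % 3]
                      for i in range(8)}
            env = {f"s{k}": "sponge" for k in range(6)}
            env.update({f"w{k}": "seawater" for k in range(6)})
            tab = synthetic.simulate_abundance(phages, enrich, env, rng, fold=8.0)
            labels = network.label_enrichment(tab, {p.id: 10_000 for p in phages},
                                              env)
            hits += sum(labels[p] == enrich[p] for p in enrich)
            total += len(enrich)
        assert hits / total >= 0.95


class TestPartition:
    def test_single_phage_two_symbiont_hosts_counts_once(self):
        g = _net([("p1", "h1"), ("p1", "h2")], {"p1": "sponge"},
                 {"h1": "sponge_symbiont", "h2": "sponge_symbiont"})
        tab = network.partition_table(g)
        assert tab.loc["sponge", "sponge_symbiont"] == 1
        assert tab.to_numpy().sum() == 1

    def test_mixed_phage_two_niches_two_cells(self):
        g = _net([("p1", "h1"), ("p1", "h2")], {"p1": "mixed"},
                 {"h1": "sponge_symbiont", "h2": "plankton"})
        tab = network.partition_table(g)
        assert tab.loc["mixed", "sponge_symbiont"] == 1
        assert tab.loc["mixed", "plankton"] == 1

    def test_matches_brute_force_tally(self, rng):
        for _ in range(10):
            n_p, n_h = 8, 6
            labels = {f"p{i}": str(rng.choice(["sponge", "seawater", "mixed"]))
                      for i in range(n_p)}
            niches = {f"h{j}": str(rng.choice(network.HOST_NICHES))
                      for j in range(n_h)}
            edges = {(f"p{int(i)}", f"h{int(j)}")
                     for i, j in zip(rng.integers(0, n_p, 15),
                                     rng.integers(0, n_h, 15))}
            tab = network.partition_table(_net(sorted(edges), labels, niches))
            exp = brute_partition(sorted(edges), labels, niches)
            for lab in tab.index:
                for niche in tab.columns:
                    assert tab.loc[lab, niche] == exp.get((lab, niche), 0)

    def test_zero_cell_without_planted_cross_links(self):
        # seawater-source phages never linked to symbionts: printed cell is 0
        g = _net([("p1", "h1"), ("p2", "h2")],
                 {"p1": "sponge", "p2": "seawater"},
                 {"h1": "sponge_symbiont", "h2": "plankton"})
        assert network.partition_table(g).loc["seawater", "sponge_symbiont"] == 0


class TestStatistic:
    def test_perfect_stratification_is_one(self):
        g = _net([("p1", "h1"), ("p2", "h2")],
                 {"p1": "sponge", "p2": "seawater"},
                 {"h1": "sponge_symbiont", "h2": "plankton"})
        assert network.assortment_statistic(g) == 1.0

    def test_sign_flips_when_labels_swap(self):
        edges = [("p1", "h1"), ("p1", "h2"), ("p2", "h2"), ("p3", "h1")]
        labels = {"p1": "sponge", "p2": "seawater", "p3": "seawater"}
        niches = {"h1": "sponge_symbiont", "h2": "plankton"}
        s1 = network.assortment_statistic(_net(edges, labels, niches))
        swapped = {p: {"sponge": "seawater", "seawater": "sponge"}[v]
                   for p, v in labels.items()}
        s2 = network.assortment_statistic(_net(edges, swapped, niches))
        assert s1 == pytest.approx(-s2)
        assert -1.0 <= s1 <= 1.0

    def test_degenerate_labels_raise(self):
        g = _net([("p1", "h1")], {"p1": "sponge"}, {"h1": "sponge_symbiont"})
        with pytest.raises(network.DegenerateLabelsError):
            network.assortment_statistic(g)

    def test_mean_near_zero_under_independent_labels(self, rng):
        vals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            labels = {f"p{i}": ("sponge" if i < 5 else "seawater")
                      for i in range(10)}
            niches = {f"h{j}": ("sponge_symbiont" if r.random() < 0.5
                                else "plankton") for j in range(8)}
            edges = sorted({(f"p{int(i)}", f"h{int(j)}")
                            for i, j in zip(r.integers(0, 10, 20),
                                            r.integers(0, 8, 20))})
            try:
                vals.append(network.assortment_statistic(
                    _net(edges, labels, niches)))
            except network.DegenerateLabelsError:
                continue
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) <= 2 * se + 1e-12


class TestPermutation:
    def _stratified(self, n_per_side=6):
        edges = [(f"p{i}", f"h{i}") for i in range(2 * n_per_side)]
        labels = {f"p{i}": ("sponge" if i < n_per_side else "seawater")
                  for i in range(2 * n_per_side)}
        niches = {f"h{i}": ("sponge_symbiont" if i < n_per_side else "plankton")
                  for i in range(2 * n_per_side)}
        return _net(edges, labels, niches)

    def test_stratified_network_significant(self):
        res = network.permutation_test(self._stratified(), n_perm=1000, seed=1)
        assert res.observed == 1.0
        assert res.p_value <= 0.05

    def test_add_one_floor(self):
        res = network.permutation_test(self._stratified(), n_perm=200, seed=2)
        assert res.p_value >= 1.0 / 201.0
        assert 0.0 < res.p_value <= 1.0

    def test_symmetric_network_p_near_one(self):
        # every phage hits both niches: statistic 0 regardless of labels
        edges = []
        labels, niches = {}, {}
        for i in range(6):
            labels[f"p{i}"] = "sponge" if i < 3 else "seawater"
            edges += [(f"p{i}", "hs"), (f"p{i}", "hp")]
        niches = {"hs": "sponge_symbiont", "hp": "plankton"}
        res = network.permutation_test(_net(edges, labels, niches),
                                       n_perm=300, seed=3)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_determinism_under_seed(self):
        g = self._stratified()
        a = network.permutation_test(g, n_perm=300, seed=7)
        b = network.permutation_test(g, n_perm=300, seed=7)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null, b.null)
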