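import numpy as np
import pandas as pd
import pytest

from holophage import lifestyle, seqs, synthetic
from holophage.model import PhageContig

from oracles import brute_orfs


@pytest.fixture(scope="module")
def markers():
    return lifestyle.load_marker_db()


def test_marker_db_loads(markers):
    assert len(markers) == 2
    assert markers[0].seq.startswith("M")


@pytest.mark.parametrize("seed", range(5))
def test_find_orfs_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    phage = PhageContig("p", seqs.random_seq(rng, 4000))
    got = {(o.start, o.end, o.strand)
           for o in lifestyle.find_orfs(phage, min_orf_aa=30)}
    assert got == brute_orfs(phage.seq, 30)


def test_orf_interval_length_invariant(rng):
    phage = PhageContig("p", seqs.random_seq(rng, 6000))
    for orf in lifestyle.find_orfs(phage, min_orf_aa=20):
        assert orf.end - orf.start == 3 * (len(orf.protein) + 1)
        assert "*" not in orf.protein


def test_planted_marker_orf_recovered_exactly(rng, markers):
    phage = PhageContig("p", seqs.random_seq(rng, 9000))
    _, feat = synthetic.plant_marker_orf(phage, markers[0].seq, rng)
    orfs = lifestyle.find_orfs(phage)
    match = [o for o in orfs if (o.start, o.end) == (feat.start, feat.end)]
    assert len(match) == 1
    assert match[0].protein == markers[0].seq
    assert match[0].strand == feat.strand


def test_detect_markers_on_planted_orf(rng, markers):
    phage = PhageContig("p", seqs.random_seq(rng, 9000))
    synthetic.plant_marker_orf(phage, markers[0].seq, rng)
    orfs = lifestyle.find_orfs(phage)
    hits = lifestyle.detect_markers(orfs, markers)
    assert hits
    best = max(hits, key=lambda h: h.identity)
    assert best.identity > 0.99
    assert best.coverage > 0.99
    assert best.marker_id == markers[0].id


def test_unmarked_phage_has_no_hits(rng, markers):
    phage = PhageContig("p", seqs.random_seq(rng, 9000))
    hits = lifestyle.detect_markers(lifestyle.find_orfs(phage), markers)
    assert hits == []


def test_shuffled_exemplar_control(rng, markers):
    """Shuffling the exemplar destroys detectability: 20 shuffles, 0 hits."""
    phage = PhageContig("p", seqs.random_seq(rng, 9000))
    synthetic.plant_marker_orf(phage, markers[0].seq, rng)
    orfs = lifestyle.find_orfs(phage)
    n_hits = 0
    base = list(markers[0].seq[1:])
    for _ in range(20):
        rng.shuffle(base)
        shuffled = lifestyle.MarkerProtein("shuffled", "M" + "".join(base))
        n_hits += len(lifestyle.detect_markers(orfs, [shuffled]))
    assert n_hits == 0


class TestClassify:
    def test_marker_precedence(self, markers):
        phage = PhageContig("p", "ACGT" * 100)
        hit = lifestyle.MarkerHit("p", "integrase_exemplar", 1.0, 1.0, 500.0,
                                  orf=None)
        clf = lifestyle.CompositionClassifier().fit(
            ["ACGT" * 300] * 6, ["lytic"] * 6)
        call = lifestyle.classify_lifestyle(phage, [hit], clf)
        assert call.call == "temperate"

    def test_empty_reference_set_unclassified(self):
        phage = PhageContig("p", "ACGT" * 100)
        clf = lifestyle.CompositionClassifier().fit([], [])
        call = lifestyle.classify_lifestyle(phage, [], clf)
        assert call.call == "unclassified"

    def test_low_confidence_unclassified(self, rng):
        seqs_ref = [seqs.random_seq(rng, 3000) for _ in range(10)]
        labels = ["temperate", "lytic"] * 5
        clf = lifestyle.CompositionClassifier(k=2).fit(seqs_ref, labels)
        call = lifestyle.classify_lifestyle(
            PhageContig("p", seqs.random_seq(rng, 3000)), [], clf,
            confidence_threshold=1.1)
        assert call.call == "unclassified"
        assert 0.0 <= call.confidence <= 1.0

    def test_composition_bias_heldout_accuracy(self):
        """Planted GC bias delta=0.05 separates classes at >= 0.9 held-out
        accuracy."""
        rng = np.random.default_rng(42)
        delta = 0.05
        biased = np.array([0.25 - delta / 2, 0.25 + delta / 2,
                           0.25 + delta / 2, 0.25 - delta / 2])
        train_x, train_y = [], []
        test_x, test_y = [], []
        for i in range(60):
            label = "temperate" if i % 2 else "lytic"
            probs = biased if label == "temperate" else None
            s = seqs.random_seq(rng, 8000, probs)
            if i < 40:
                train_x.append(s)
                train_y.append(label)
            else:
                test_x.append(s)
                test_y.append(label)
        clf = lifestyle.CompositionClassifier().fit(train_x, train_y)
        correct = sum(clf.predict(s)[0] == y for s, y in zip(test_x, test_y))
        assert correct / len(test_x) >= 0.9


class TestTlRatio:
    env = {"s0": "sponge", "w0": "seawater"}

    def _calls(self, mapping):
        return [lifestyle.LifestyleCall(phage_id=k, call=v)
                for k, v in mapping.items()]

    def test_equal_cpk_ratio_one(self):
        tab = pd.DataFrame({"s0": [100, 50], "w0": [100, 50]},
                           index=["t1", "l1"])
        lengths = {"t1": 10_000, "l1": 5_000}  # Cpk equal: 10 vs 10
        ratios, _ = lifestyle.tl_ratio(
            self._calls({"t1": "temperate", "l1": "lytic"}), tab, lengths,
            self.env)
        assert ratios["sponge"].ratio == pytest.approx(1.0)

    def test_hand_summation(self):
        tab = pd.DataFrame({"s0": [10, 20, 30], "w0": [1, 2, 3]},
                           index=["a", "b", "c"])
        lengths = {"a": 1000, "b": 2000, "c": 1000}
        calls = self._calls({"a": "temperate", "b": "temperate", "c": "lytic"})
        ratios, _ = lifestyle.tl_ratio(calls, tab, lengths, self.env)
        # sponge: T = 10/1 + 20/2 = 20; L = 30/1 = 30
        assert ratios["sponge"].temperate_cpk == pytest.approx(20.0)
        assert ratios["sponge"].lytic_cpk == pytest.approx(30.0)
        assert ratios["sponge"].ratio == pytest.approx(20.0 / 30.0)

    def test_scale_invariance(self, rng):
        counts = rng.integers(1, 100, size=(4, 2))
        tab = pd.DataFrame(counts, index=list("abcd"), columns=["s0", "w0"])
        lengths = {k: int(v) for k, v in zip("abcd",
                                             rng.integers(2000, 9000, 4))}
        calls = self._calls({"a": "temperate", "b": "lytic",
                             "c": "temperate", "d": "lytic"})
        r1, _ = lifestyle.tl_ratio(calls, tab, lengths, self.env)
        r2, _ = lifestyle.tl_ratio(calls, tab * 17, lengths, self.env)
        assert r1["sponge"].ratio == pytest.approx(r2["sponge"].ratio)

    def test_zero_lytic_is_flagged_infinite(self):
        tab = pd.DataFrame({"s0": [5], "w0": [5]}, index=["t1"])
        ratios, count_ratio = lifestyle.tl_ratio(
            self._calls({"t1": "temperate"}), tab, {"t1": 1000}, self.env)
        assert ratios["sponge"].infinite
        assert ratios["sponge"].ratio == float("inf")
        assert count_ratio == float("inf")

    def test_239_to_138_count_ratio(self):
        mapping = {f"t{i}": "temperate" for i in range(239)}
        mapping.update({f"l{i}": "lytic" for i in range(138)})
        tab = pd.DataFrame({"s0": [1] * 377, "w0": [1] * 377},
                           index=list(mapping))
        _, count_ratio = lifestyle.tl_ratio(self._calls(mapping), tab,
                                            {k: 1000 for k in mapping}, self.env)
        assert count_ratio == pytest.approx(239 / 138)
        assert round(count_ratio, 1) == 1.7


def test_marker_precedence_never_flips_away(rng, markers):
    """Adding a marker hit can only move a call toward temperate."""
    phage = PhageContig("p", seqs.random_seq(rng, 3000))
    clf = lifestyle.CompositionClassifier().fit(
        [seqs.random_seq(rng, 3000) for _ in range(6)], ["lytic"] * 6)
    before = lifestyle.classify_lifestyle(phage, [], clf)
    hit = lifestyle.MarkerHit("p", "m", 0.9, 0.9, 100.0, orf=None)
    after = lifestyle.classify_lifestyle(phage, [hit], clf)
    assert after.call == "temperate"
    assert before.call in ("lytic", "unclassified", "temperate")
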