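import numpy as np
import pandas as pd
import pytest

from holophage import imaging, seqs, synthetic
from holophage.model import HostGenome, PhageContig


def test_identical_seed_gives_identical_community():
    cfg = synthetic.CommunityConfig(n_phages=4, n_hosts=3,
                                    phage_len_range=(5000, 8000),
                                    host_len_range=(12000, 15000),
                                    p_crispr_link=0.3, p_prophage_link=0.3,
                                    p_trna_link=0.3,
                                    prophage_len_range=(1200, 2000), seed=5)
    a = synthetic.generate_community(cfg)
    b = synthetic.generate_community(cfg)
    assert [p.seq for p in a.phages] == [p.seq for p in b.phages]
    assert [h.contigs for h in a.hosts] == [h.contigs for h in b.hosts]
    assert a.truth.links == b.truth.links
    pd.testing.assert_frame_equal(a.abundance, b.abundance)


def test_forced_single_crispr_link():
    cfg = synthetic.CommunityConfig(n_phages=1, n_hosts=1,
                                    phage_len_range=(5000, 5000),
                                    host_len_range=(12000, 12000),
                                    p_crispr_link=1.0, p_prophage_link=0.0,
                                    p_trna_link=0.0, stratified=False, seed=3)
    com = synthetic.generate_community(cfg)
    assert com.truth.links == {("phage0000", "host0000", "crispr")}


def test_link_counts_match_replayed_bernoulli_draws():
    cfg = synthetic.CommunityConfig(n_phages=20, n_hosts=10, seed=7,
                                    stratified=False)
    com = synthetic.generate_community(cfg)
    # replay the generator's dedicated link stream independently
    rng = np.random.default_rng([7, 4])
    u = rng.random((3, 20, 10))
    probs = np.array([cfg.p_crispr_link, cfg.p_prophage_link,
                      cfg.p_trna_link])[:, None, None]
    expected = int((u < probs).sum())
    assert len(com.truth.links) == expected


def test_features_inside_contigs_and_disjoint(small_community):
    com = small_community
    lens = {p.id: len(p.seq) for p in com.phages}
    for h in com.hosts:
        for cid, s in h.contigs.items():
            lens[cid] = len(s)
    by_contig = {}
    for f in com.truth.features:
        assert 0 <= f.start < f.end <= lens[f.contig_id], f
        # source regions on phages may legitimately overlap each other
        if f.kind not in ("protospacer", "prophage_source"):
            by_contig.setdefault(f.contig_id, []).append((f.start, f.end))
    for intervals in by_contig.values():
        intervals.sort()
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            assert a1 <= b0, "planted features overlap"


def test_plant_crispr_spacer_is_phage_substring(rng):
    host = HostGenome("h", {"h_c": seqs.random_seq(rng, 5000)})
    phage = PhageContig("p", seqs.random_seq(rng, 8000))
    _, feats = synthetic.plant_crispr_array(host, phage, 2, 0, rng, occupied={})
    arr_feat = feats[0]
    assert arr_feat.kind == "crispr_array"
    for f in feats[1:]:
        proto = phage.seq[f.start:f.end]
        contig = host.contigs["h_c"]
        region = contig[arr_feat.start:arr_feat.end]
        assert proto in region or seqs.revcomp(proto) in region


def test_plant_crispr_mutations_exact_hamming(rng):
    host = HostGenome("h", {"h_c": seqs.random_seq(rng, 5000)})
    phage = PhageContig("p", seqs.random_seq(rng, 8000))
    _, feats = synthetic.plant_crispr_array(host, phage, 2, 2, rng, occupied={})
    arr_feat = feats[0]
    region = host.contigs["h_c"][arr_feat.start:arr_feat.end]
    if arr_feat.strand == "-":
        region = seqs.revcomp(region)
    # array layout: R S1 R S2 R with 30 bp repeats, 32 bp spacers
    for i, f in enumerate(feats[1:]):
        spacer = region[30 + i * 62:30 + i * 62 + 32]
        proto = phage.seq[f.start:f.end]
        if f.strand == "-":
            proto = seqs.revcomp(proto)
        assert sum(a != b for a, b in zip(spacer, proto)) == 2


def test_plant_prophage_identity_one_is_exact_slice(rng):
    host = HostGenome("h", {"h_c": seqs.random_seq(rng, 20000)})
    phage = PhageContig("p", seqs.random_seq(rng, 8000))
    _, feats = synthetic.plant_prophage(host, phage, 1.0, 2000, rng, occupied={})
    hf = next(f for f in feats if f.kind == "prophage")
    pf = next(f for f in feats if f.kind == "prophage_source")
    segment = host.contigs["h_c"][hf.start:hf.end]
    if hf.strand == "-":
        segment = seqs.revcomp(segment)
    assert segment == phage.seq[pf.start:pf.end]


def test_plant_prophage_mismatches_binomial(rng):
    host = HostGenome("h", {"h_c": seqs.random_seq(rng, 20000)})
    phage = PhageContig("p", seqs.random_seq(rng, 8000))
    _, feats = synthetic.plant_prophage(host, phage, 0.85, 2000, rng, occupied={})
    hf = next(f for f in feats if f.kind == "prophage")
    pf = next(f for f in feats if f.kind == "prophage_source")
    segment = host.contigs["h_c"][hf.start:hf.end]
    if hf.strand == "-":
        segment = seqs.revcomp(segment)
    mism = sum(a != b for a, b in zip(segment, phage.seq[pf.start:pf.end]))
    # Binomial(2000, 0.15): 300 +- 4 sd (sd ~ 16)
    assert 236 <= mism <= 364


def test_plant_prophage_validations(rng):
    host = HostGenome("h", {"h_c": seqs.random_seq(rng, 20000)})
    phage = PhageContig("p", seqs.random_seq(rng, 8000))
    with pytest.raises(ValueError):
        synthetic.plant_prophage(host, phage, 0.9, 500, rng)  # < 1 kb
    with pytest.raises(ValueError):
        synthetic.plant_prophage(host, phage, 1.5, 2000, rng)
    tiny = HostGenome("t", {"t_c": seqs.random_seq(rng, 900)})
    with pytest.raises(synthetic.PlacementError):
        synthetic.plant_prophage(tiny, phage, 0.9, 2000, rng)


def test_plant_trna_identity_one_identical(rng):
    host = HostGenome("h", {"h_c": seqs.random_seq(rng, 5000)})
    phage = PhageContig("p", seqs.random_seq(rng, 8000))
    _, _, feats = synthetic.plant_trna(host, phage, 1.0, rng, occupied={})
    pf = next(f for f in feats if f.kind == "trna_phage")
    hf = next(f for f in feats if f.kind == "trna_host")
    p_seq = phage.seq[pf.start:pf.end]
    if pf.strand == "-":
        p_seq = seqs.revcomp(p_seq)
    h_seq = host.contigs["h_c"][hf.start:hf.end]
    if hf.strand == "-":
        h_seq = seqs.revcomp(h_seq)
    assert p_seq == h_seq


def test_abundance_infinite_fold_zeroes_depleted_environment(rng):
    phages = [PhageContig("p0", "A" * 10000)]
    sample_env = {"s0": "sponge", "s1": "sponge", "w0": "seawater"}
    tab = synthetic.simulate_abundance(phages, {"p0": "sponge"}, sample_env,
                                       rng, fold=np.inf)
    assert tab.loc["p0", "w0"] == 0
    assert (tab.loc["p0", ["s0", "s1"]] > 0).all()


def test_synth_image_trivial_cases():
    img = synthetic.synth_image([], 100, 2.0, 0.0, 7.0, seed=0, shape=(32, 32))
    assert (img == 7).all()
    img2 = synthetic.synth_image([(10, 10), (10, 30)], 100, 1.5, 0.0, 5.0,
                                 seed=0, shape=(20, 40))
    calls = imaging.find_maxima(img2, 50.0)
    assert calls.count == 2


def test_config_validation():
    with pytest.raises(ValueError):
        synthetic.CommunityConfig(p_crispr_link=1.5)
    with pytest.raises(ValueError):
        synthetic.CommunityConfig(phage_len_range=(0, 100))
    with pytest.raises(ValueError):
        synthetic.CommunityConfig(prophage_len_range=(2000, 9000),
                                  phage_len_range=(5000, 30000))


def test_temperate_phages_carry_marker_orf(small_community):
    com = small_community
    marked = {f.phage_id for f in com.truth.features if f.kind == "marker_orf"}
    temperate = {p for p, v in com.truth.lifestyle.items() if v == "temperate"}
    assert marked == temperate
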