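"""Synthetic holobiont community generator with planted ground truth.

Emulates the structure of a sponge/seawater virome host-prediction study:
random phage contigs and microbial host genomes, with three kinds of planted
phage→host evidence (CRISPR protospacer sampling into repeat–spacer arrays,
integrated prophage segments, shared tRNA genes), environment-structured
abundance tables, temperate-phage marker ORFs, and Gaussian-spot fluorescence
images.  Every planted signal is recorded as ground truth so channel
precision/recall is computable downstream.

Background sequence is i.i.d. uniform nucleotides — deliberately free of
compositional structure so the matchers' false-positive behaviour is
analytically predictable.  Planted features overwrite background (contig
lengths never change), are placed by rejection sampling against previously
occupied intervals, and never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seqs
from .model import GroundTruth, HostGenome, PhageContig, PlantedFeature

_MAX_PLACE_TRIES = 100

# child-stream ids: one independent RNG per generation concern, so that e.g.
# the link indicators can be replayed without regenerating sequences
_STREAMS = {"labels": 1, "phage_seq": 2, "host_seq": 3, "links": 4,
            "plant": 5, "abundance": 6, "markers": 7}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class CommunityConfig:
    """Parameters of the synthetic community; defaults define desk-scale
    study conditions (see the methods note for rationale)."""

    n_phages: int = 20
    n_hosts: int = 10
    phage_len_range: tuple = (5_000, 30_000)
    host_len_range: tuple = (20_000, 50_000)
    p_crispr_link: float = 0.05
    p_prophage_link: float = 0.05
    p_trna_link: float = 0.05
    n_spacers: int = 3
    spacer_len: int = 32
    repeat_len: int = 30
    spacer_mutations: int = 0
    repeat_mutations: int = 0
    prophage_identity: float = 0.92
    prophage_len_range: tuple = (2_000, 5_000)
    trna_identity: float = 0.97
    trna_len_range: tuple = (70, 90)
    environments: tuple = ("sponge", "seawater")
    samples_per_env: int = 6
    fold_effect: float = 8.0
    base_cpk: float = 20.0
    nb_dispersion: float = 0.1
    p_sponge: float = 0.4
    p_seawater: float = 0.4
    host_niche_probs: tuple = (("sponge_symbiont", 0.5), ("plankton", 0.5))
    stratified: bool = True
    p_temperate: float = 0.4
    composition_bias: float = 0.0  # GC shift of temperate phages
    seed: int = 0

    def __post_init__(self):
        for name in ("p_crispr_link", "p_prophage_link", "p_trna_link",
                     "p_sponge", "p_seawater", "p_temperate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("phage_len_range", "host_len_range", "prophage_len_range",
                     "trna_len_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name}=({lo}, {hi}) is not a positive interval")
        if self.p_sponge + self.p_seawater > 1.0:
            raise ValueError("p_sponge + p_seawater > 1")
        if not 0.0 < self.prophage_identity <= 1.0:
            raise ValueError("prophage_identity outside (0, 1]")
        if self.prophage_len_range[1] > self.phage_len_range[0]:
            raise ValueError("prophage may exceed the shortest phage")
        if self.prophage_len_range[1] > self.host_len_range[0] // 2:
            raise ValueError("prophage may exceed half the shortest host contig")
        if self.spacer_mutations < 0 or self.repeat_mutations < 0:
            raise ValueError("mutation counts must be >= 0")


class PlacementError(ValueError):
    """A planted feature could not be placed without collision."""


def _place(occupied: list, contig_len: int, feat_len: int,
           rng: np.random.Generator) -> int:
    """Rejection-sample a non-colliding start for a feature; record it."""
    if feat_len > contig_len:
        raise PlacementError(f"feature of {feat_len} bp exceeds contig of {contig_len} bp")
    for _ in range(_MAX_PLACE_TRIES):
        start = int(rng.integers(0, contig_len - feat_len + 1))
        end = start + feat_len
        if all(end <= a or start >= b for (a, b) in occupied):
            occupied.append((start, end))
            return start
    raise PlacementError("no collision-free position found after 100 tries")


def _overwrite(seq: str, start: int, insert: str) -> str:
    return seq[:start] + insert + seq[start + len(insert):]


def plant_crispr_array(host: HostGenome, phage: PhageContig, n_spacers: int,
                       mutations_per_spacer: int, rng: np.random.Generator,
                       *, spacer_len: int = 32, repeat_len: int = 30,
                       repeat_mutations: int = 0, occupied: dict | None = None):
    """Overwrite a repeat–spacer array into a host contig.

    The array is ``R S1 R S2 ... Sn R`` (n_spacers+1 repeat copies, so >= 3
    repeats whenever n_spacers >= 2).  Each spacer samples a random phage
    substring (random strand), mutated at exactly ``mutations_per_spacer``
    positions; protospacer coordinates go into the returned features.
    The whole array is written on a random strand.
    Returns (host, features); the host is modified in place.
    """
    if n_spacers < 2:
        raise ValueError("need n_spacers >= 2 for >= 3 repeat copies")
    contig_id = sorted(host.contigs)[int(rng.integers(len(host.contigs)))]
    contig = host.contigs[contig_id]
    repeat = seqs.random_seq(rng, repeat_len)
    parts, features = [], []
    proto = []
    for _ in range(n_spacers):
        p_start = int(rng.integers(0, len(phage.seq) - spacer_len + 1))
        p_strand = "+" if rng.random() < 0.5 else "-"
        proto_seq = phage.seq[p_start:p_start + spacer_len]
        spacer = proto_seq if p_strand == "+" else seqs.revcomp(proto_seq)
        spacer = seqs.mutate(spacer, mutations_per_spacer, rng)
        proto.append((p_start, p_start + spacer_len, p_strand))
        parts.append(spacer)
    pieces = []
    for i in range(n_spacers + 1):
        pieces.append(seqs.mutate(repeat, repeat_mutations, rng))
        if i < n_spacers:
            pieces.append(parts[i])
    array_seq = "".join(pieces)
    a_strand = "+" if rng.random() < 0.5 else "-"
    written = array_seq if a_strand == "+" else seqs.revcomp(array_seq)
    occ = occupied.setdefault(contig_id, []) if occupied is not None else []
    start = _place(occ, len(contig), len(written), rng)
    host.contigs[contig_id] = _overwrite(contig, start, written)
    features.append(PlantedFeature("crispr_array", contig_id, start,
                                   start + len(written), a_strand,
                                   phage_id=phage.id, host_id=host.id))
    for (ps, pe, pstr) in proto:
        features.append(PlantedFeature("protospacer", phage.id, ps, pe, pstr,
                                       phage_id=phage.id, host_id=host.id))
    return host, features


def plant_prophage(host: HostGenome, phage: PhageContig, identity: float,
                   length: int, rng: np.random.Generator,
                   occupied: dict | None = None):
    """Overwrite a point-mutated phage segment (a lysogen signature) into a
    random host contig at the target nucleotide identity."""
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity outside (0, 1]")
    if not 1000 <= length <= len(phage.seq):
        raise ValueError("prophage length must be in [1 kb, phage length]")
    contig_id = sorted(host.contigs)[int(rng.integers(len(host.contigs)))]
    contig = host.contigs[contig_id]
    p_start = int(rng.integers(0, len(phage.seq) - length + 1))
    segment = seqs.mutate_to_identity(phage.seq[p_start:p_start + length],
                                      identity, rng)
    strand = "+" if rng.random() < 0.5 else "-"
    written = segment if strand == "+" else seqs.revcomp(segment)
    occ = occupied.setdefault(contig_id, []) if occupied is not None else []
    start = _place(occ, len(contig), length, rng)
    host.contigs[contig_id] = _overwrite(contig, start, written)
    feats = [PlantedFeature("prophage", contig_id, start, start + length,
                            strand, phage_id=phage.id, host_id=host.id),
             PlantedFeature("prophage_source", phage.id, p_start,
                            p_start + length, "+", phage_id=phage.id,
                            host_id=host.id)]
    return host, feats


def plant_trna(host: HostGenome, phage: PhageContig, identity: float,
               rng: np.random.Generator, *, length_range=(70, 90),
               occupied: dict | None = None, phage_occupied: list | None = None):
    """Write a shared tRNA gene into both the phage and a host contig.

    The phage carries the exact gene; the host copy is point-mutated at
    exactly ``round((1 - identity) * length)`` positions, so the realised
    identity is deterministic.  Returns (host, phage, features); features
    carry the coordinates needed to emit GFF3 annotations.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity outside (0, 1]")
    t_len = int(rng.integers(length_range[0], length_range[1] + 1))
    gene = seqs.random_seq(rng, t_len)
    # phage copy
    p_strand = "+" if rng.random() < 0.5 else "-"
    p_occ = phage_occupied if phage_occupied is not None else []
    p_start = _place(p_occ, len(phage.seq), t_len, rng)
    p_written = gene if p_strand == "+" else seqs.revcomp(gene)
    phage.seq = _overwrite(phage.seq, p_start, p_written)
    # host copy, mutated
    contig_id = sorted(host.contigs)[int(rng.integers(len(host.contigs)))]
    contig = host.contigs[contig_id]
    h_strand = "+" if rng.random() < 0.5 else "-"
    h_gene = seqs.mutate(gene, int(round((1.0 - identity) * t_len)), rng)
    h_written = h_gene if h_strand == "+" else seqs.revcomp(h_gene)
    occ = occupied.setdefault(contig_id, []) if occupied is not None else []
    h_start = _place(occ, len(contig), t_len, rng)
    host.contigs[contig_id] = _overwrite(contig, h_start, h_written)
    feats = [PlantedFeature("trna_phage", phage.id, p_start, p_start + t_len,
                            p_strand, phage_id=phage.id, host_id=host.id),
             PlantedFeature("trna_host", contig_id, h_start, h_start + t_len,
                            h_strand, phage_id=phage.id, host_id=host.id)]
    return host, phage, feats


# --- marker ORF planting -------------------------------------------------

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOPS = ["TAA", "TAG", "TGA"]


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniformly random synonymous codons (no stop)."""
    return "".join(_CODONS[aa][int(rng.integers(len(_CODONS[aa])))]
                   for aa in protein)


def plant_marker_orf(phage: PhageContig, protein: str,
                     rng: np.random.Generator,
                     phage_occupied: list | None = None):
    """Plant a marker gene as a clean ORF: in-frame stop, ATG...ORF...stop.

    The planted cassette is TAA + back-translated protein + stop so the ORF
    from the first ATG after a stop reproduces the protein exactly.  The
    cassette lands on a random strand.  Returns (phage, feature) where the
    feature interval covers start codon through stop codon on the cassette's
    strand (forward-contig coordinates).
    """
    if not protein.startswith("M"):
        raise ValueError("marker exemplar must start with M")
    cds = back_translate(protein, rng)
    cassette = "TAA" + cds + _STOPS[int(rng.integers(3))]
    strand = "+" if rng.random() < 0.5 else "-"
    written = cassette if strand == "+" else seqs.revcomp(cassette)
    occ = phage_occupied if phage_occupied is not None else []
    start = _place(occ, len(phage.seq), len(written), rng)
    phage.seq = _overwrite(phage.seq, start, written)
    if strand == "+":
        orf_start, orf_end = start + 3, start + len(written)
    else:
        orf_start, orf_end = start, start + len(written) - 3
    return phage, PlantedFeature("marker_orf", phage.id, orf_start, orf_end,
                                 strand, phage_id=phage.id)


# --- abundance ------------------------------------------------------------

def simulate_abundance(phages, enrichment: dict, sample_env: dict,
                       rng: np.random.Generator, *, fold: float = 8.0,
                       base_cpk: float = 20.0, dispersion: float = 0.1) -> pd.DataFrame:
    """Negative-binomial read counts per (phage contig, sample).

    The mean count of phage i in sample s is ``base_cpk * len_kb * factor``
    where factor is ``fold`` in the phage's enriched environment and 1 in the
    other; "mixed" phages get factor 1 everywhere.  ``fold=inf`` zeroes the
    depleted environment.  Variance is mu + dispersion * mu^2 (dispersion 0
    degenerates to Poisson).
    """
    samples = sorted(sample_env)
    rows = {}
    for ph in phages:
        len_kb = len(ph.seq) / 1000.0
        label = enrichment.get(ph.id, "mixed")
        means = []
        for s in samples:
            env = sample_env[s]
            if label in ("sponge", "seawater"):
                if env == label:
                    factor = fold if np.isfinite(fold) else 1.0
                else:
                    factor = 1.0 if np.isfinite(fold) else 0.0
            else:
                factor = 1.0
            means.append(base_cpk * len_kb * factor)
        mu = np.asarray(means)
        counts = np.zeros(len(samples), dtype=np.int64)
        pos = mu > 0
        if dispersion > 0:
            nshape = 1.0 / dispersion
            pgeom = nshape / (nshape + mu[pos])
            counts[pos] = rng.negative_binomial(nshape, pgeom)
        else:
            counts[pos] = rng.poisson(mu[pos])
        rows[ph.id] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


# --- images ---------------------------------------------------------------

def synth_image(spot_centers, amplitude: float, psf_sigma: float,
                noise_sd: float, background: float, seed: int,
                shape=(128, 128)) -> np.ndarray:
    """Isotropic-Gaussian spots + constant background + i.i.d. noise.

    Returns a non-negative integer grid (rounded, clipped at zero).
    ``spot_centers`` are (row, col) coordinates.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, float(background))
    for (cy, cx) in spot_centers:
        img += amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                                  / (2.0 * psf_sigma ** 2))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    return np.clip(np.rint(img), 0, None).astype(np.int64)


# --- the full community ---------------------------------------------------

@dataclass
class Community:
    phages: list
    hosts: list
    truth: GroundTruth
    abundance: pd.DataFrame
    sample_env: dict
    config: CommunityConfig = field(repr=False, default=None)


def draw_link_matrix(config: CommunityConfig, enrichment_order, niche_order):
    """Replayable Bernoulli link indicators, shape (3, n_phages, n_hosts).

    Channel order is (crispr, homology, trna).  Under ``stratified`` the
    per-pair probability is masked to zero for sponge-phage/plankton-host and
    seawater-phage/symbiont-host pairs ("mixed" phages link anywhere).
    """
    rng = child_rng(config.seed, "links")
    u = rng.random((3, config.n_phages, config.n_hosts))
    probs = np.array([config.p_crispr_link, config.p_prophage_link,
                      config.p_trna_link])[:, None, None]
    mask = np.ones((config.n_phages, config.n_hosts))
    if config.stratified:
        for i, e in enumerate(enrichment_order):
            for j, nch in enumerate(niche_order):
                if (e == "sponge" and nch != "sponge_symbiont") or \
                   (e == "seawater" and nch != "plankton"):
                    mask[i, j] = 0.0
    return u < probs * mask[None, :, :]


def generate_community(config: CommunityConfig):
    """Generate phages, hosts and complete ground truth.

    Deterministic under a fixed config (identical seed gives byte-identical
    sequences, tables and truth).  Returns a :class:`Community`.
    """
    lab_rng = child_rng(config.seed, "labels")
    # phage enrichment and lifestyle labels
    enr_u = lab_rng.random(config.n_phages)
    enrichment_order = np.where(
        enr_u < config.p_sponge, "sponge",
        np.where(enr_u < config.p_sponge + config.p_seawater, "seawater",
                 "mixed"))
    lifestyle_order = np.where(lab_rng.random(config.n_phages)
                               < config.p_temperate, "temperate", "lytic")
    niches, niche_p = zip(*config.host_niche_probs)
    niche_order = lab_rng.choice(niches, size=config.n_hosts,
                                 p=np.asarray(niche_p) / sum(niche_p))

    ph_rng = child_rng(config.seed, "phage_seq")
    phages = []
    delta = config.composition_bias
    for i in range(config.n_phages):
        length = int(ph_rng.integers(config.phage_len_range[0],
                                     config.phage_len_range[1] + 1))
        if delta > 0 and lifestyle_order[i] == "temperate":
            probs = np.array([0.25 - delta / 2, 0.25 + delta / 2,
                              0.25 + delta / 2, 0.25 - delta / 2])
        else:
            probs = None
        phages.append(PhageContig(id=f"phage{i:04d}",
                                  seq=seqs.random_seq(ph_rng, length, probs)))

    h_rng = child_rng(config.seed, "host_seq")
    hosts = []
    for j in range(config.n_hosts):
        length = int(h_rng.integers(config.host_len_range[0],
                                    config.host_len_range[1] + 1))
        hid = f"host{j:04d}"
        hosts.append(HostGenome(id=hid,
                                contigs={f"{hid}_c1": seqs.random_seq(h_rng, length)},
                                niche=str(niche_order[j])))

    truth = GroundTruth()
    truth.enrichment = {p.id: str(enrichment_order[i]) for i, p in enumerate(phages)}
    truth.lifestyle = {p.id: str(lifestyle_order[i]) for i, p in enumerate(phages)}

    # marker ORFs for temperate phages
    m_rng = child_rng(config.seed, "markers")
    from .lifestyle import load_marker_db  # deferred: avoids import cycle at module load
    markers = load_marker_db()
    integrase = markers[0].seq
    phage_occ = {p.id: [] for p in phages}
    for i, p in enumerate(phages):
        if lifestyle_order[i] == "temperate":
            _, feat = plant_marker_orf(p, integrase, m_rng,
                                       phage_occupied=phage_occ[p.id])
            truth.features.append(feat)

    links = draw_link_matrix(config, enrichment_order, niche_order)
    plant_rng = child_rng(config.seed, "plant")
    host_occ = {h.id: {} for h in hosts}
    channel_names = ("crispr", "homology", "trna")
    for c, channel in enumerate(channel_names):
        for i, p in enumerate(phages):
            for j, h in enumerate(hosts):
                if not links[c, i, j]:
                    continue
                if channel == "crispr":
                    _, feats = plant_crispr_array(
                        h, p, config.n_spacers, config.spacer_mutations,
                        plant_rng, spacer_len=config.spacer_len,
                        repeat_len=config.repeat_len,
                        repeat_mutations=config.repeat_mutations,
                        occupied=host_occ[h.id])
                elif channel == "homology":
                    length = int(plant_rng.integers(
                        config.prophage_len_range[0],
                        config.prophage_len_range[1] + 1))
                    _, feats = plant_prophage(h, p, config.prophage_identity,
                                              length, plant_rng,
                                              occupied=host_occ[h.id])
                else:
                    _, _, feats = plant_trna(h, p, config.trna_identity,
                                             plant_rng,
                                             length_range=config.trna_len_range,
                                             occupied=host_occ[h.id],
                                             phage_occupied=phage_occ[p.id])
                truth.features.extend(feats)
                truth.links.add((p.id, h.id, channel))
                # protect phage-side source regions from later overwrites
                for f in feats:
                    if f.kind in ("protospacer", "prophage_source"):
                        phage_occ[p.id].append((f.start, f.end))

    ab_rng = child_rng(config.seed, "abundance")
    sample_env = {}
    for env in config.environments:
        for k in range(config.samples_per_env):
            sample_env[f"{env}_s{k}"] = env
    abundance = simulate_abundance(phages, truth.enrichment, sample_env,
                                   ab_rng, fold=config.fold_effect,
                                   base_cpk=config.base_cpk,
                                   dispersion=config.nb_dispersion)
    return Community(phages=phages, hosts=hosts, truth=truth,
                     abundance=abundance, sample_env=sample_env, config=config)


def trna_annotations(truth: GroundTruth):
    """GFF3-style tRNA records for planted genes.

    Returns (phage_records, host_records); each record is a dict with
    1-based inclusive coordinates as GFF3 requires.
    """
    ph, ho = [], []
    for f in truth.features:
        if f.kind not in ("trna_phage", "trna_host"):
            continue
        rec = {"seqid": f.contig_id, "start": f.start + 1, "end": f.end,
               "strand": f.strand, "type": "tRNA",
               "attributes": f"ID=trna_{f.contig_id}_{f.start}"}
        (ph if f.kind == "trna_phage" else ho).append(rec)
    return ph, ho
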