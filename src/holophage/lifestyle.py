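"""Phage replication-mode calling and temperate:lytic abundance ratios.

A phage is called temperate when any of its ORFs hits a lysogeny marker
exemplar (integrase/excisionase-like proteins); marker evidence always takes
precedence.  Phages without marker hits fall back to a transparent
composition classifier — k-nearest-neighbour on tetranucleotide frequency
vectors against a labelled reference set — and stay "unclassified" when the
vote confidence is below threshold.  The bundled marker exemplars are
synthetic stand-ins (see data/synthetic_markers.faa); real exemplar sets can
be supplied as protein FASTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from sklearn.neighbors import KNeighborsClassifier

from . import seqs
from .model import PhageContig

logger = logging.getLogger(__name__)


@dataclass
class MarkerProtein:
    id: str
    seq: str


@dataclass
class OrfRecord:
    phage_id: str
    frame: int  # 0..2 within the oriented strand
    strand: str
    start: int  # forward-contig coordinates, includes the stop codon
    end: int
    protein: str


@dataclass
class MarkerHit:
    phage_id: str
    marker_id: str
    identity: float
    coverage: float
    score: float
    orf: OrfRecord


@dataclass
class LifestyleCall:
    phage_id: str
    call: str  # temperate | lytic | unclassified
    marker_hits: list = field(default_factory=list)
    classifier_vote: str | None = None
    confidence: float = 0.0


def load_marker_db(path=None) -> list[MarkerProtein]:
    """Load marker exemplars from protein FASTA (bundled set by default)."""
    if path is None:
        ref = resources.files("holophage").joinpath("data/synthetic_markers.faa")
        with ref.open() as fh:
            return [MarkerProtein(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta")]
    return [MarkerProtein(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]


def find_orfs(phage: PhageContig, min_orf_aa: int = 60) -> list[OrfRecord]:
    """All maximal start-to-stop ORFs in 6 frames.

    An ORF runs from the first ATG after the previous in-frame stop to the
    next in-frame stop (which must lie inside the contig); the recorded
    interval includes the stop codon, so its length is 3 * (aa + 1).
    Coordinates always refer to the forward contig.
    """
    out = []
    n = len(phage.seq)
    for strand in ("+", "-"):
        oriented = phage.seq if strand == "+" else seqs.revcomp(phage.seq)
        for frame in range(3):
            start_codon = None
            for pos in range(frame, n - 2, 3):
                codon = oriented[pos:pos + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    if start_codon is not None:
                        aa_len = (pos - start_codon) // 3
                        if aa_len >= min_orf_aa:
                            cds = oriented[start_codon:pos]
                            protein = str(Seq(cds).translate())
                            o_start, o_end = start_codon, pos + 3
                            if strand == "+":
                                c_start, c_end = o_start, o_end
                            else:
                                c_start, c_end = n - o_end, n - o_start
                            out.append(OrfRecord(
                                phage_id=phage.id, frame=frame, strand=strand,
                                start=c_start, end=c_end, protein=protein))
                    start_codon = None
                elif codon == "ATG" and start_codon is None:
                    start_codon = pos
    return out


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def detect_markers(orfs: list[OrfRecord], marker_db: list[MarkerProtein],
                   min_identity: float = 0.35,
                   min_coverage: float = 0.5) -> list[MarkerHit]:
    """Protein local alignment of every ORF against every exemplar.

    A hit requires identity >= min_identity over an aligned region covering
    >= min_coverage of the exemplar length.
    """
    aligner = _protein_aligner()
    hits = []
    for orf in orfs:
        for marker in marker_db:
            if len(orf.protein) < min_coverage * len(marker.seq):
                continue
            alns = aligner.align(orf.protein, marker.seq)
            if len(alns) == 0:
                continue
            aln = alns[0]
            blocks_a, blocks_b = aln.aligned
            if len(blocks_a) == 0:
                continue
            matches = 0
            cols = 0
            for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
                matches += sum(x == y for x, y in
                               zip(orf.protein[a0:a1], marker.seq[b0:b1]))
                cols += a1 - a0
            # count internal gap columns once
            gap_cols = (blocks_a[-1][1] - blocks_a[0][0] - cols) + \
                       (blocks_b[-1][1] - blocks_b[0][0] - cols)
            total_cols = cols + gap_cols
            identity = matches / total_cols if total_cols else 0.0
            coverage = (blocks_b[-1][1] - blocks_b[0][0]) / len(marker.seq)
            if identity >= min_identity and coverage >= min_coverage:
                hits.append(MarkerHit(phage_id=orf.phage_id,
                                      marker_id=marker.id,
                                      identity=identity, coverage=coverage,
                                      score=float(aln.score), orf=orf))
    return hits


def tetranucleotide_freqs(seq: str) -> np.ndarray:
    """256-dimensional tetranucleotide frequency vector."""
    codes = seqs.encode(seq)
    kmers = seqs.pack_kmers(codes, 4)
    counts = np.bincount(kmers.astype(np.int64), minlength=256).astype(float)
    total = counts.sum()
    return counts / total if total else counts


class CompositionClassifier:
    """k-NN lifestyle classifier on tetranucleotide frequency vectors."""

    def __init__(self, k: int = 5):
        self.k = k
        self._knn: KNeighborsClassifier | None = None

    def fit(self, sequences: list[str], labels: list[str]) -> "CompositionClassifier":
        if len(sequences) == 0:
            self._knn = None
            return self
        x = np.vstack([tetranucleotide_freqs(s) for s in sequences])
        k = min(self.k, len(sequences))
        self._knn = KNeighborsClassifier(n_neighbors=k).fit(x, labels)
        return self

    def predict(self, seq: str) -> tuple[str | None, float]:
        """Predicted label and vote fraction; (None, 0.0) without references."""
        if self._knn is None:
            return None, 0.0
        x = tetranucleotide_freqs(seq)[None, :]
        proba = self._knn.predict_proba(x)[0]
        i = int(np.argmax(proba))
        return str(self._knn.classes_[i]), float(proba[i])


def classify_lifestyle(phage: PhageContig, marker_hits: list[MarkerHit],
                       classifier: CompositionClassifier | None = None,
                       confidence_threshold: float = 0.6) -> LifestyleCall:
    """Marker-first ensemble call: any marker hit forces "temperate";
    otherwise the composition classifier decides, and the phage stays
    "unclassified" below the confidence threshold."""
    own = [h for h in marker_hits if h.phage_id == phage.id]
    if own:
        return LifestyleCall(phage_id=phage.id, call="temperate",
                             marker_hits=own, confidence=1.0)
    if classifier is not None:
        vote, conf = classifier.predict(phage.seq)
        if vote is not None and conf >= confidence_threshold:
            return LifestyleCall(phage_id=phage.id, call=vote,
                                 classifier_vote=vote, confidence=conf)
        return LifestyleCall(phage_id=phage.id, call="unclassified",
                             classifier_vote=vote, confidence=conf)
    return LifestyleCall(phage_id=phage.id, call="unclassified")


@dataclass
class TLRatio:
    temperate_cpk: float
    lytic_cpk: float
    ratio: float
    infinite: bool


def tl_ratio(calls: list[LifestyleCall], abundance, lengths: dict,
             sample_env: dict):
    """Temperate:lytic abundance ratio per environment, plus the contig
    count ratio.

    Per environment the ratio is sum of temperate Cpk over sum of lytic Cpk
    across that environment's samples; unclassified phages are excluded.
    A zero lytic Cpk yields +inf with the ``infinite`` flag set.  Returns
    (per-environment dict, count_ratio).
    """
    call_of = {c.phage_id: c.call for c in calls}
    envs = sorted(set(sample_env.values()))
    out = {}
    for env in envs:
        cols = [s for s in abundance.columns if sample_env[s] == env]
        t_sum = l_sum = 0.0
        for phage_id, row in abundance.iterrows():
            call = call_of.get(phage_id)
            if call not in ("temperate", "lytic"):
                continue
            cpk = float(row[cols].sum()) / (lengths[phage_id] / 1000.0)
            if call == "temperate":
                t_sum += cpk
            else:
                l_sum += cpk
        if l_sum == 0.0:
            out[env] = TLRatio(t_sum, 0.0, float("inf"), True)
        else:
            out[env] = TLRatio(t_sum, l_sum, t_sum / l_sum, False)
    n_t = sum(1 for c in calls if c.call == "temperate")
    n_l = sum(1 for c in calls if c.call == "lytic")
    count_ratio = float("inf") if n_l == 0 else n_t / n_l
    return out, count_ratio
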