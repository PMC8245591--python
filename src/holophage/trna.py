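"""tRNA evidence channel: link phages to hosts through shared tRNA genes.

tRNA gene *prediction* is an input (GFF3 annotations); this module extracts
the annotated genes strand-aware and matches phage tRNAs to host tRNAs by
end-free (overlap) global alignment, keeping per phage tRNA only the best
host hit with identity >= 95% over >= 90% of the shorter gene.  The coverage
floor is this module's own addition on top of the identity threshold: it
stops short spurious overlaps from becoming "best hits"; both knobs are
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from . import seqs
from .model import EvidenceLink

logger = logging.getLogger(__name__)

MIN_TRNA_LEN, MAX_TRNA_LEN = 50, 120


@dataclass
class TrnaGene:
    owner_id: str  # contig the gene sits on
    start: int  # 0-based half-open, forward-contig coordinates
    end: int
    strand: str
    sequence: str  # oriented 5'->3'


@dataclass
class TrnaMatch:
    phage_trna: TrnaGene
    host_trna: TrnaGene
    identity: float
    coverage: float
    orientation: str  # '+' if host gene matched as annotated, '-' if flipped


def extract_trnas(contigs: dict[str, str], records: list[dict]) -> list[TrnaGene]:
    """Extract annotated tRNA genes from contig sequences.

    ``records`` are GFF3-style dicts with 1-based inclusive ``start``/``end``
    (the GFF3 convention), ``seqid``, ``strand`` and ``type``; non-tRNA
    records are ignored.  Minus-strand genes are reverse-complemented so the
    returned sequence reads 5'->3'.
    """
    out = []
    for ln, rec in enumerate(records, start=1):
        if rec.get("type") != "tRNA":
            continue
        seqid = rec["seqid"]
        if seqid not in contigs:
            raise KeyError(f"record {ln}: unknown contig {seqid!r}")
        start, end = int(rec["start"]) - 1, int(rec["end"])  # to 0-based half-open
        contig = contigs[seqid]
        if not (0 <= start < end <= len(contig)):
            raise ValueError(f"record {ln}: interval [{start + 1}, {end}] outside "
                             f"contig {seqid!r} of length {len(contig)}")
        strand = rec.get("strand", "+")
        seq = contig[start:end]
        if strand == "-":
            seq = seqs.revcomp(seq)
        if not MIN_TRNA_LEN <= len(seq) <= MAX_TRNA_LEN:
            raise ValueError(f"record {ln}: tRNA length {len(seq)} outside "
                             f"[{MIN_TRNA_LEN}, {MAX_TRNA_LEN}]")
        out.append(TrnaGene(owner_id=seqid, start=start, end=end,
                            strand=strand, sequence=seq))
    return out


def _overlap_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # end-free: terminal gaps on either sequence are not penalised
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def _identity_coverage(a: str, b: str, aligner) -> tuple[float, float]:
    """Identity over the aligned (overlap) region and coverage of the
    shorter sequence by that region."""
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0, 0.0
    matches = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        matches += sum(x == y for x, y in zip(a[a0:a1], b[b0:b1]))
    # overlap region: first to last aligned position, internal gaps included
    a_lo, a_hi = blocks_a[0][0], blocks_a[-1][1]
    b_lo, b_hi = blocks_b[0][0], blocks_b[-1][1]
    a_span, b_span = a_hi - a_lo, b_hi - b_lo
    columns = max(a_span, b_span)  # internal gap columns counted once
    identity = matches / columns if columns else 0.0
    shorter = min(len(a), len(b))
    coverage = min(a_span, b_span) / shorter if shorter else 0.0
    return identity, coverage


def match_trnas(phage_trnas: list[TrnaGene], host_trnas: list[TrnaGene],
                min_identity: float = 0.95, min_coverage: float = 0.9,
                contig_to_host: dict | None = None,
                contig_to_phage: dict | None = None):
    """Best-hit matching of phage tRNAs to host tRNAs.

    Every phage tRNA is aligned to every host tRNA in both orientations; a
    candidate needs identity >= min_identity over >= min_coverage of the
    shorter gene.  Per phage tRNA only the single best host hit survives
    (higher identity wins; ties go to the lexicographically smaller host id,
    which is logged).  Returns (links, matches): one "trna" EvidenceLink per
    linked (phage, host) pair plus the per-tRNA matches behind them.
    """
    aligner = _overlap_aligner()
    c2h = contig_to_host or {}
    c2p = contig_to_phage or {}
    matches: list[TrnaMatch] = []
    for pt in phage_trnas:
        best: TrnaMatch | None = None
        for ht in host_trnas:
            for orient, hseq in (("+", ht.sequence), ("-", seqs.revcomp(ht.sequence))):
                ident, cov = _identity_coverage(pt.sequence, hseq, aligner)
                if ident < min_identity or cov < min_coverage:
                    continue
                cand = TrnaMatch(pt, ht, ident, cov, orient)
                if best is None or cand.identity > best.identity:
                    best = cand
                elif cand.identity == best.identity and \
                        ht.owner_id < best.host_trna.owner_id:
                    logger.info("tie at identity %.4f for phage tRNA %s: "
                                "keeping host %s", ident, pt.owner_id, ht.owner_id)
                    best = cand
        if best is not None:
            matches.append(best)
    links = {}
    for m in matches:
        phage_id = c2p.get(m.phage_trna.owner_id, m.phage_trna.owner_id)
        host_id = c2h.get(m.host_trna.owner_id, m.host_trna.owner_id)
        key = (phage_id, host_id)
        if key not in links or m.identity > links[key].identity:
            links[key] = m
    out = []
    for (phage_id, host_id), m in sorted(links.items()):
        out.append(EvidenceLink(
            phage_id=phage_id, host_id=host_id, channel="trna",
            scores=(("identity", round(m.identity, 6)),
                    ("coverage", round(m.coverage, 6)),
                    ("phage_trna_start", m.phage_trna.start),
                    ("host_trna_start", m.host_trna.start))))
    return out, matches
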