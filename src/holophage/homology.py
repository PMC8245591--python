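"""Prophage-homology evidence channel.

Integrated-prophage signatures are found by local alignment of each phage
contig against each host contig (both strands) and accepted through the
identity/length window used for lysogen assignment: identity > 80% over a
host span between 1 kb and half the host contig length.  One link per
(phage, host genome) pair, keeping the highest-scoring accepted alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import AlignmentParams, local_align
from .model import EvidenceLink, HostGenome, PhageContig

logger = logging.getLogger(__name__)


@dataclass
class ProphageFilter:
    min_identity: float = 0.80  # strict: identity must exceed this
    min_span: int = 1000  # bp on the host contig
    max_span_frac: float = 0.5  # of the host contig length


@dataclass
class LocalAlignment:
    """A phage-vs-host-contig local alignment (0-based half-open intervals)."""

    phage_id: str
    host_id: str
    host_contig_id: str
    phage_start: int
    phage_end: int
    host_start: int
    host_end: int
    strand: str
    columns: int
    matches: int
    score: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def host_span(self) -> int:
        return self.host_end - self.host_start


def find_prophages(phages: list[PhageContig], hosts: list[HostGenome],
                   params: AlignmentParams | None = None) -> list[LocalAlignment]:
    """All high-scoring local alignments of phages against host contigs.

    Seed k-mer indexes are precomputed per sequence so the all-vs-all scan
    costs one sort per sequence rather than one per pairing.
    """
    from . import seqs as _seqs
    from .align import SeedIndex

    p = params or AlignmentParams()
    ph_idx = {}
    for phage in phages:
        codes = _seqs.encode(phage.seq)
        ph_idx[phage.id] = (SeedIndex(codes, p.seed_k),
                            SeedIndex(_seqs.revcomp_codes(codes), p.seed_k))
    out = []
    for host in hosts:
        for contig_id in sorted(host.contigs):
            subject = host.contigs[contig_id]
            s_index = SeedIndex(_seqs.encode(subject), p.seed_k)
            for phage in phages:
                qi, ri = ph_idx[phage.id]
                for aln in local_align(phage.seq, subject, p,
                                       indexes=(qi, ri, s_index)):
                    out.append(LocalAlignment(
                        phage_id=phage.id, host_id=host.id,
                        host_contig_id=contig_id,
                        phage_start=aln.q_start, phage_end=aln.q_end,
                        host_start=aln.s_start, host_end=aln.s_end,
                        strand=aln.strand, columns=aln.columns,
                        matches=aln.matches, score=aln.score))
    return out


def filter_prophage_hits(alignments: list[LocalAlignment],
                         hosts: list[HostGenome],
                         flt: ProphageFilter | None = None) -> list[EvidenceLink]:
    """Apply the identity/length acceptance window; best hit per pair.

    Host contigs shorter than ``2 * min_span`` have an empty acceptance
    window (min_span > max_span_frac * len); their alignments are rejected
    with a logged notice.
    """
    f = flt or ProphageFilter()
    contig_len = {}
    for h in hosts:
        for cid, seq in h.contigs.items():
            contig_len[cid] = len(seq)
    best: dict[tuple, LocalAlignment] = {}
    for aln in alignments:
        if aln.host_contig_id not in contig_len:
            raise KeyError(f"unknown host contig id: {aln.host_contig_id!r}")
        clen = contig_len[aln.host_contig_id]
        max_span = f.max_span_frac * clen
        if f.min_span > max_span:
            logger.info("empty acceptance window for contig %s (%d bp); hit rejected",
                        aln.host_contig_id, clen)
            continue
        if aln.identity <= f.min_identity:
            continue
        if not (f.min_span <= aln.host_span <= max_span):
            continue
        key = (aln.phage_id, aln.host_id)
        cur = best.get(key)
        if cur is None or aln.score > cur.score:
            best[key] = aln
    links = []
    for (phage_id, host_id), aln in sorted(best.items()):
        links.append(EvidenceLink(
            phage_id=phage_id, host_id=host_id, channel="homology",
            scores=(("identity", round(aln.identity, 6)),
                    ("span", aln.host_span),
                    ("score", aln.score),
                    ("host_contig", aln.host_contig_id),
                    ("host_start", aln.host_start),
                    ("host_end", aln.host_end),
                    ("strand", aln.strand))))
    return links
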