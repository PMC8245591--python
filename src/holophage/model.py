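"""Core domain containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class PhageContig:
    """A viral genomic sequence (one contig per phage)."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class HostGenome:
    """A microbial genome as a set of named contigs with a niche label.

    ``niche`` is one of {sponge_symbiont, plankton, other_environment,
    other_animal, unknown}.
    """

    id: str
    contigs: dict[str, str]
    niche: str = "unknown"

    def contig_len(self, contig_id: str) -> int:
        return len(self.contigs[contig_id])


@dataclass(frozen=True)
class EvidenceLink:
    """One phage→host assignment from a single evidence channel.

    ``channel`` is "crispr", "homology" or "trna"; ``scores`` carries the
    channel-specific figures of merit (mismatches, identity, span, ...).
    """

    phage_id: str
    host_id: str
    channel: str
    scores: tuple = ()  # tuple of (key, value) pairs; hashable

    @property
    def score_dict(self) -> dict:
        return dict(self.scores)


@dataclass
class PlantedFeature:
    """Ground-truth coordinates of a planted signal.

    Coordinates are 0-based half-open on the named contig; ``kind`` is one of
    crispr_array, protospacer, prophage, trna_host, trna_phage, marker_orf.
    """

    kind: str
    contig_id: str
    start: int
    end: int
    strand: str
    phage_id: str | None = None
    host_id: str | None = None

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GroundTruth:
    """Complete planted truth for a synthetic community."""

    links: set = field(default_factory=set)  # {(phage_id, host_id, channel)}
    lifestyle: dict = field(default_factory=dict)  # phage_id -> temperate|lytic
    enrichment: dict = field(default_factory=dict)  # phage_id -> sponge|seawater|mixed
    features: list = field(default_factory=list)  # [PlantedFeature]

    def links_for_channel(self, channel: str) -> set:
        return {(p, h) for (p, h, c) in self.links if c == channel}
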