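"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython; GFF3, TSV and JSON as plain text.  GFF3 coordinates are
1-based inclusive on disk and converted to/from the 0-based half-open
intervals used in memory.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import EvidenceLink, GroundTruth, HostGenome, PhageContig, PlantedFeature


def write_fasta(path, records: dict):
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def read_phages(path) -> list[PhageContig]:
    return [PhageContig(id=k, seq=v) for k, v in read_fasta(path).items()]


def read_hosts(path, niche_map: dict | None = None) -> list[HostGenome]:
    """One genome per contig unless ids look like ``<genome>_c<N>``, in which
    case contigs group by genome id."""
    groups: dict[str, dict] = {}
    for cid, seq in read_fasta(path).items():
        gid = cid.rsplit("_c", 1)[0] if "_c" in cid else cid
        groups.setdefault(gid, {})[cid] = seq
    niche_map = niche_map or {}
    return [HostGenome(id=g, contigs=c, niche=niche_map.get(g, "unknown"))
            for g, c in sorted(groups.items())]


def write_gff3(path, records: list[dict]):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write("\t".join([
                r["seqid"], r.get("source", "holophage"), r.get("type", "tRNA"),
                str(r["start"]), str(r["end"]), ".", r.get("strand", "+"), ".",
                r.get("attributes", "."),
            ]) + "\n")


def read_gff3(path) -> list[dict]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        out.append({"seqid": f[0], "source": f[1], "type": f[2],
                    "start": int(f[3]), "end": int(f[4]), "strand": f[6],
                    "attributes": f[8]})
    return out


def write_links_tsv(path, links: list[EvidenceLink]):
    rows = []
    for link in links:
        row = {"phage_id": link.phage_id, "host_id": link.host_id,
               "channel": link.channel}
        row.update({f"score_{k}": v for k, v in link.scores})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_links_tsv(path) -> list[EvidenceLink]:
    df = pd.read_csv(path, sep="\t")
    links = []
    score_cols = [c for c in df.columns if c.startswith("score_")]
    for _, row in df.iterrows():
        scores = tuple((c[len("score_"):], row[c]) for c in score_cols
                       if pd.notna(row[c]))
        links.append(EvidenceLink(phage_id=row["phage_id"],
                                  host_id=row["host_id"],
                                  channel=row["channel"], scores=scores))
    return links


def write_truth_json(path, truth: GroundTruth):
    payload = {
        "links": sorted(list(t) for t in truth.links),
        "lifestyle": truth.lifestyle,
        "enrichment": truth.enrichment,
        "features": [asdict(f) for f in truth.features],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        links={tuple(t) for t in payload["links"]},
        lifestyle=payload["lifestyle"],
        enrichment=payload["enrichment"],
        features=[PlantedFeature(**f) for f in payload["features"]],
    )


def write_abundance_tsv(path, abundance: pd.DataFrame):
    abundance.to_csv(path, sep="\t", index_label="contig")


def read_abundance_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="contig")


def write_sample_env_tsv(path, sample_env: dict):
    pd.Series(sample_env, name="environment").rename_axis("sample") \
        .to_csv(path, sep="\t")


def read_sample_env_tsv(path) -> dict:
    return pd.read_csv(path, sep="\t", index_col="sample")["environment"].to_dict()
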