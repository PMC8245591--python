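"""End-to-end pipeline: simulate → predict (3 channels) → network + test →
lifestyle → report.

A single global seed deterministically derives per-stage seeds by hashing
the stage name, so re-running one stage in isolation reproduces its output.
The run report collects per-channel link counts and (when planted truth is
available) precision/recall, the partition table, the stratification test,
lifestyle tallies and temperate:lytic ratios.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import crispr, homology, imaging, lifestyle, network, synthetic, trna
from . import io as hio
from .align import AlignmentParams

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class RunConfig:
    out_dir: str = "holophage_run"
    seed: int = 0
    community: dict = field(default_factory=dict)  # CommunityConfig overrides
    crispr_max_mismatch: int = 1
    min_align_score: int = 50
    trna_min_identity: float = 0.95
    trna_min_coverage: float = 0.9
    enrichment_fold: float = 2.0
    n_perm: int = 10_000
    stages: tuple = ("simulate", "crispr", "homology", "trna", "network",
                     "lifestyle")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def channel_metrics(predicted: set, truth: set) -> dict:
    """Precision/recall of predicted (phage, host) pairs against truth."""
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    return {"n_predicted": len(predicted), "n_truth": len(truth),
            "n_true_positive": tp, "precision": precision, "recall": recall}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report.

    Artifacts (FASTA, TSV, JSON) are written under ``config.out_dir``; the
    report is also returned as a dict and written as ``report.json``.
    Identical config + seed reproduces identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    report = {"seed": config.seed, "stages": list(config.stages), "channels": {}}
    stage = "simulate"
    try:
        cc = synthetic.CommunityConfig(
            **{"seed": stage_seed(config.seed, "simulate"), **config.community})
        community = synthetic.generate_community(cc)
        phages, hosts, truth = community.phages, community.hosts, community.truth
        hio.write_fasta(out / "phages.fasta", {p.id: p.seq for p in phages})
        hio.write_fasta(out / "hosts.fasta",
                        {cid: s for h in hosts for cid, s in h.contigs.items()})
        hio.write_truth_json(out / "truth.json", truth)
        hio.write_abundance_tsv(out / "abundance.tsv", community.abundance)
        hio.write_sample_env_tsv(out / "samples.tsv", community.sample_env)
        ph_gff, ho_gff = synthetic.trna_annotations(truth)
        hio.write_gff3(out / "phage_trnas.gff3", ph_gff)
        hio.write_gff3(out / "host_trnas.gff3", ho_gff)

        all_links = []
        lengths = {p.id: len(p.seq) for p in phages}

        if "crispr" in config.stages:
            stage = "crispr"
            arrays = []
            for h in hosts:
                arrays.extend(crispr.detect_arrays(h))
            links = crispr.match_spacers(arrays, phages,
                                         max_mismatch=config.crispr_max_mismatch)
            hio.write_links_tsv(out / "crispr_links.tsv", links)
            report["channels"]["crispr"] = channel_metrics(
                {(l.phage_id, l.host_id) for l in links},
                truth.links_for_channel("crispr"))
            report["channels"]["crispr"]["n_arrays"] = len(arrays)
            all_links.extend(links)

        if "homology" in config.stages:
            stage = "homology"
            params = AlignmentParams(min_score=config.min_align_score)
            alns = homology.find_prophages(phages, hosts, params)
            links = homology.filter_prophage_hits(alns, hosts)
            hio.write_links_tsv(out / "homology_links.tsv", links)
            report["channels"]["homology"] = channel_metrics(
                {(l.phage_id, l.host_id) for l in links},
                truth.links_for_channel("homology"))
            all_links.extend(links)

        if "trna" in config.stages:
            stage = "trna"
            phage_seqs = {p.id: p.seq for p in phages}
            host_seqs = {cid: s for h in hosts for cid, s in h.contigs.items()}
            contig_to_host = {cid: h.id for h in hosts for cid in h.contigs}
            p_genes = trna.extract_trnas(phage_seqs, ph_gff)
            h_genes = trna.extract_trnas(host_seqs, ho_gff)
            links, _ = trna.match_trnas(p_genes, h_genes,
                                        min_identity=config.trna_min_identity,
                                        min_coverage=config.trna_min_coverage,
                                        contig_to_host=contig_to_host)
            hio.write_links_tsv(out / "trna_links.tsv", links)
            report["channels"]["trna"] = channel_metrics(
                {(l.phage_id, l.host_id) for l in links},
                truth.links_for_channel("trna"))
            all_links.extend(links)

        if "network" in config.stages:
            stage = "network"
            labels = network.label_enrichment(
                community.abundance, lengths, community.sample_env,
                fold=config.enrichment_fold)
            niche_map = {h.id: h.niche for h in hosts}
            g = network.assemble_network(all_links, labels, niche_map)
            table = network.partition_table(g)
            table.to_csv(out / "partition_table.tsv", sep="\t")
            report["n_edges"] = g.number_of_edges()
            report["n_matched_phages"] = sum(
                1 for _, d in g.nodes(data=True) if d.get("bipartite") == "phage")
            report["partition_table"] = {r: table.loc[r].to_dict()
                                         for r in table.index}
            label_recovery = sum(
                1 for p in phages if labels.get(p.id) == truth.enrichment[p.id])
            report["enrichment_label_recovery"] = label_recovery / len(phages)
            try:
                result = network.permutation_test(
                    g, n_perm=config.n_perm,
                    seed=stage_seed(config.seed, "network"))
                report["stratification"] = result.summary()
                (out / "stratification.json").write_text(
                    json.dumps(result.summary(), indent=1))
            except network.DegenerateLabelsError as exc:
                report["stratification"] = {"error": str(exc)}

        if "lifestyle" in config.stages:
            stage = "lifestyle"
            markers = lifestyle.load_marker_db()
            calls = []
            for p in phages:
                orfs = lifestyle.find_orfs(p)
                hits = lifestyle.detect_markers(orfs, markers)
                calls.append(lifestyle.classify_lifestyle(p, hits))
            ratios, count_ratio = lifestyle.tl_ratio(
                calls, community.abundance, lengths, community.sample_env)
            tallies = {}
            for c in calls:
                tallies[c.call] = tallies.get(c.call, 0) + 1
            truth_t = {p for p, v in truth.lifestyle.items() if v == "temperate"}
            called_t = {c.phage_id for c in calls if c.call == "temperate"}
            t_recall = len(called_t & truth_t) / len(truth_t) if truth_t else 1.0
            t_precision = len(called_t & truth_t) / len(called_t) if called_t else 1.0
            report["lifestyle"] = {
                "tallies": tallies,
                "temperate_recall": t_recall,
                "temperate_precision": t_precision,
                "count_ratio": count_ratio,
                "tl_ratios": {env: dataclasses.asdict(r)
                              for env, r in ratios.items()},
            }
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        report["failed_stage"] = stage
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
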