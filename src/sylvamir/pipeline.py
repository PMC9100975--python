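"""End-to-end pipeline: simulate -> QC -> decontaminate -> annotate ->
quantify/DE -> degradome -> enrich, with a consolidated manifest.

The pipeline runs on a synthetic dataset generated from a single
:class:`~sylvamir.simulate.SimulationConfig`; because the generator
records ground truth, the manifest also reports recovery metrics
(planted-locus and planted-target sensitivity/precision) alongside the
per-stage summaries. All artifacts are plain text (FASTA/FASTQ/GFF3/TSV/
JSON); re-running with the same config and seed reproduces identical
file digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .annotate import annotate_loci, build_stacks, collapse_reads, map_reads
from .contaminants import filter_contaminants
from .de import ExpressionMatrix, NBDifferentialExpression
from .degradome import call_targets, map_tags
from .enrich import enrich, enrichment_table
from .qc import FilterReport, filter_reads, infer_adapter3
from .simulate import (
    SimulationConfig,
    simulate_degradome,
    simulate_genome,
    simulate_reads,
    simulate_references,
    simulate_term_map,
    simulate_transcripts,
)

logger = logging.getLogger("sylvamir")


@dataclass
class RunManifest:
    """Provenance and per-stage summaries of one pipeline run."""

    config: dict
    seed: int
    version: str
    digests: dict[str, str] = field(default_factory=dict)
    summaries: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "version": self.version,
                "digests": self.digests,
                "summaries": self.summaries,
            },
            indent=2,
            sort_keys=True,
            default=_jsonable,
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(SimulationConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**data)


def run_pipeline(
    config: SimulationConfig | str | Path,
    outdir: str | Path,
    permutation_rounds: int = 200,
) -> RunManifest:
    """Execute all stages on a synthetic dataset; returns the manifest.

    Artifacts are written under ``outdir``; the manifest (JSON) is written
    last so its presence marks a completed run.
    """
    from . import __version__

    if not isinstance(config, SimulationConfig):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed, version=__version__)

    # -- simulate ----------------------------------------------------------
    logger.info("stage=simulate seed=%d", config.seed)
    genome, truth = simulate_genome(config)
    refs = simulate_references(config, truth)
    transcripts = simulate_transcripts(config, truth)
    reads_by_sample = simulate_reads(
        truth, config, contaminant_refs={k: refs[k] for k in ("rRNA", "tRNA", "organelle")}
    )
    tags = simulate_degradome(truth, transcripts, config)
    term_map = simulate_term_map(config, truth, transcripts)

    sio.write_fasta(genome, outdir / "genome.fa")
    sio.write_fasta(transcripts, outdir / "transcripts.fa")
    sio.write_fasta(refs["known_miRNA"].sequences, outdir / "known_mirnas.fa")
    for kind in ("rRNA", "tRNA", "organelle"):
        sio.write_fasta(refs[kind].sequences, outdir / f"contaminant_{kind}.fa")
    for sample, reads in reads_by_sample.items():
        sio.write_fastq(reads, outdir / f"reads_{sample}.fastq")
    sio.write_fastq(tags, outdir / "degradome_tags.fastq")
    sio.write_term_map(term_map, outdir / "terms.tsv")
    manifest.summaries["simulate"] = {
        "n_planted_loci": len(truth.planted_loci),
        "n_decoys": len(truth.decoys),
        "n_planted_sites": len(truth.planted_sites),
        "reads_per_sample": {s: len(r) for s, r in reads_by_sample.items()},
    }

    # -- qc ----------------------------------------------------------------
    logger.info("stage=qc")
    adapter = infer_adapter3(
        reads_by_sample[truth.sample_ids[0]][: 2000] or [], adapter=None
    ) if reads_by_sample[truth.sample_ids[0]] else config.adapter3
    clean_by_sample: dict[str, list] = {}
    reports: dict[str, FilterReport] = {}
    for sample, reads in reads_by_sample.items():
        clean, report = filter_reads(reads, adapter)
        clean_by_sample[sample] = clean
        reports[sample] = report
    qc_table = pd.DataFrame([{"sample": s, **r.to_dict()} for s, r in reports.items()])
    qc_table.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    manifest.summaries["qc"] = {
        "adapter": adapter,
        "reports": {s: r.to_dict() for s, r in reports.items()},
        "identity_ok": all(r.balanced() for r in reports.values()),
    }

    # -- decontaminate -----------------------------------------------------
    logger.info("stage=decontaminate")
    contaminant_sets = [refs[k] for k in ("rRNA", "tRNA", "organelle")]
    kept_by_sample: dict[str, list] = {}
    removal: dict[str, dict[str, int]] = {}
    for sample, reads in clean_by_sample.items():
        kept, removed, counts = filter_contaminants(reads, contaminant_sets)
        kept_by_sample[sample] = kept
        removal[sample] = counts
    manifest.summaries["decontaminate"] = {"removed": removal}

    # -- annotate ----------------------------------------------------------
    logger.info("stage=annotate")
    unique, sample_ids = collapse_reads(kept_by_sample)
    hits, n_multi = map_reads(unique, genome)
    stacks = build_stacks(hits, counts=unique, n_samples=len(sample_ids))
    loci = annotate_loci(stacks, genome, known_reference=refs["known_miRNA"])
    sio.write_gff3(loci, outdir / "loci.gff3")
    loci_table = pd.DataFrame(
        [
            {
                "name": l.name,
                "status": l.status,
                "family": l.family or "",
                "seq_id": l.coordinates[0],
                "start": l.coordinates[1],
                "end": l.coordinates[2],
                "strand": l.coordinates[3],
                "mature": l.mature,
                "star": l.star,
                **{s: int(c) for s, c in zip(sample_ids, l.counts_per_sample)},
            }
            for l in loci
        ]
    )
    loci_table.to_csv(outdir / "loci.tsv", sep="\t", index=False)

    planted_matures = {p.mature for p in truth.planted_loci}
    found_matures = {l.mature for l in loci}
    sensitivity = (
        len(planted_matures & found_matures) / len(planted_matures)
        if planted_matures
        else 1.0
    )
    # per-locus precision: duplicate annotations of one hairpin count against
    precision = (
        sum(1 for l in loci if l.mature in planted_matures) / len(loci)
        if loci
        else 1.0
    )
    manifest.summaries["annotate"] = {
        "n_loci": len(loci),
        "n_known": sum(l.status == "known" for l in loci),
        "n_novel": sum(l.status == "novel" for l in loci),
        "n_multi_discarded": n_multi,
        "locus_sensitivity": sensitivity,
        "locus_precision": precision,
    }

    # -- quantify / DE -----------------------------------------------------
    logger.info("stage=de")
    mapped_seqs = _mapped_set(hits)
    total_mapped = np.array(
        [
            sum(int(unique[seq][j]) for seq in mapped_seqs)
            for j in range(len(sample_ids))
        ],
        dtype=np.int64,
    )
    counts = np.vstack([l.counts_per_sample for l in loci]) if loci else np.zeros(
        (0, len(sample_ids)), dtype=np.int64
    )
    expr = ExpressionMatrix(
        locus_ids=[l.name for l in loci],
        sample_ids=sample_ids,
        raw_counts=counts,
        total_mapped=np.maximum(total_mapped, 1),
    )
    expr.to_frame().to_csv(outdir / "counts.tsv", sep="\t")
    expr.to_frame(normalized=True).to_csv(outdir / "rptm.tsv", sep="\t")
    groups = ["X"] * config.n_samples_per_group + ["P"] * config.n_samples_per_group
    if len(loci) >= 1:
        de_res = NBDifferentialExpression(counts, groups, expr.locus_ids).fit()
        de_res.summary().to_csv(outdir / "de.tsv", sep="\t", index=False)
        n_up, n_down = de_res.n_up, de_res.n_down
    else:
        de_res = None
        pd.DataFrame(
            columns=["locus", "baseMeanX", "baseMeanP", "log2fc", "p", "padj", "direction"]
        ).to_csv(outdir / "de.tsv", sep="\t", index=False)
        n_up = n_down = 0
    n_loci = len(loci)
    manifest.summaries["de"] = {
        "n_up": n_up,
        "n_down": n_down,
        "n_loci": n_loci,
        "de_percent": round(100.0 * (n_up + n_down) / n_loci, 2) if n_loci else 0.0,
    }

    # -- degradome ---------------------------------------------------------
    logger.info("stage=degradome")
    mirnas = {l.name: l.mature for l in loci}
    profiles, unplaced = map_tags(tags, transcripts) if transcripts else ({}, 0)
    sites = call_targets(
        mirnas,
        transcripts,
        profiles,
        R=permutation_rounds,
        seed=config.seed,
    ) if mirnas and profiles else []
    site_table = pd.DataFrame(
        [
            {
                "miRNA": s.mirna_id,
                "transcript": s.transcript_id,
                "score": s.complementarity_score,
                "cleavage_pos": s.cleavage_pos,
                "site_count": s.site_count,
                "category": s.category,
                "p": s.p_value,
            }
            for s in sites
        ]
    )
    site_table.to_csv(outdir / "targets.tsv", sep="\t", index=False)

    mature_to_name = {l.mature: l.name for l in loci}
    planted_by_name = {p.name: p for p in truth.planted_loci}
    truth_pairs = {
        (mature_to_name[planted_by_name[name].mature], tx, pos)
        for (name, tx, pos, _) in truth.planted_sites
        if planted_by_name[name].mature in mature_to_name
    }
    called_pairs = {(s.mirna_id, s.transcript_id, s.cleavage_pos) for s in sites}
    t_tp = len(truth_pairs & called_pairs)
    n_truth_sites = len(truth.planted_sites)
    manifest.summaries["degradome"] = {
        "n_sites": len(sites),
        "unplaced_tags": unplaced,
        "target_sensitivity": t_tp / n_truth_sites if n_truth_sites else 1.0,
        "target_precision": t_tp / len(called_pairs) if called_pairs else 1.0,
    }

    # -- enrich ------------------------------------------------------------
    logger.info("stage=enrich")
    target_genes = {s.transcript_id for s in sites}
    if term_map and target_genes:
        enr = enrich(target_genes, term_map)
        enrichment_table(enr).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        top = enr[0] if enr else None
        manifest.summaries["enrich"] = {
            "n_terms": len(enr),
            "top_term": top.term_id if top else None,
            "top_padj": top.padj if top else None,
        }
    else:
        manifest.summaries["enrich"] = {"n_terms": 0, "top_term": None, "top_padj": None}

    # -- manifest ----------------------------------------------------------
    for path in sorted(outdir.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.digests[path.name] = _digest(path)
    (outdir / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline complete: %s", outdir)
    return manifest


def _mapped_set(hits) -> set[str]:
    return {h.read_id for h in hits}


def write_report(manifest: RunManifest) -> str:
    """Human-readable run summary mirroring a per-library QC table."""
    lines = ["sylvamir run report", "=" * 60]
    qc = manifest.summaries.get("qc", {})
    reports = qc.get("reports", {})
    if reports:
        lines.append(
            f"{'sample':<8}{'raw':>10}{'clean':>10}{'Q30%':>8}{'GC%':>8}"
        )
        for sample, rep in reports.items():
            lines.append(
                f"{sample:<8}{rep['raw']:>10}{rep['clean']:>10}"
                f"{100 * rep['q30_fraction']:>8.2f}{100 * rep['gc_fraction']:>8.2f}"
            )
        identity = "PASS" if qc.get("identity_ok") else "FAIL"
        lines.append(f"filter ledger identity: {identity}")
    ann = manifest.summaries.get("annotate", {})
    if ann:
        lines.append(
            f"loci: {ann.get('n_loci', 0)} "
            f"(known {ann.get('n_known', 0)}, novel {ann.get('n_novel', 0)}); "
            f"recovery sensitivity {ann.get('locus_sensitivity', float('nan')):.2f} "
            f"precision {ann.get('locus_precision', float('nan')):.2f}"
        )
    de = manifest.summaries.get("de", {})
    if de:
        lines.append(
            f"DE: {de.get('n_up', 0)} up, {de.get('n_down', 0)} down "
            f"({de.get('de_percent', 0.0):.2f}% of {de.get('n_loci', 0)} loci)"
        )
    deg = manifest.summaries.get("degradome", {})
    if deg:
        lines.append(
            f"targets: {deg.get('n_sites', 0)} sites; "
            f"sensitivity {deg.get('target_sensitivity', float('nan')):.2f} "
            f"precision {deg.get('target_precision', float('nan')):.2f}"
        )
    enr = manifest.summaries.get("enrich", {})
    if enr.get("top_term"):
        lines.append(f"top enriched term: {enr['top_term']} (padj {enr['top_padj']:.3g})")
    return "\n".join(lines) + "\n"
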