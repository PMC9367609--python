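"""End-to-end orchestration: merge → filter → spatial → temporal → recurrence → scenarios.

The pipeline reads the cohort inputs (sample sheet, per-caller VCFs, reference
FASTA, tier table), runs the filtering cascade, computes the heterogeneity
statistics and clinical scenario calls, and writes every result as a TSV plus
a manifest. All outputs are deterministically ordered; re-running on identical
inputs yields byte-identical tables (the manifest alone carries a timestamp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import statistics
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import pyfaidx

from . import __version__
from .clinical import (
    ScenarioReport,
    TfTrajectory,
    actionability_summary,
    call_trm,
    driver_persistence,
    tp53bp1_scenario,
)
from .core_io import (
    CallSet,
    SampleRecord,
    TIMEPOINT_ORDER,
    load_tier_table,
    read_sample_sheet,
    read_vcf,
    write_table,
    write_vcf,
)
from .filtering import (
    CascadeResult,
    FilterConfig,
    merge_callsets,
    run_filter_cascade,
    tier_prioritize,
)
from .heterogeneity import (
    TmbSeries,
    compute_tmb,
    concordance_pct,
    classify_spatial,
    correlate_tmb_tf,
    jaccard_matrix,
    nonsynonymous_subset,
)

logger = logging.getLogger("ctdnahet")

__all__ = ["RunConfig", "PipelineResult", "load_cohort", "run_pipeline", "summarize_cohort"]


@dataclass
class RunConfig:
    """Paths and analysis switches for one pipeline run."""

    vcf_dir: Union[str, Path]
    reference: Union[str, Path]
    sample_sheet: Union[str, Path]
    tier_table: Union[str, Path]
    out_dir: Union[str, Path]
    filter: FilterConfig = field(default_factory=FilterConfig)
    pathogenic_only: bool = False  # restrict temporal Jaccard to tier-whitelisted calls
    concordance_denominator: str = "union"
    trm_mode: str = "relative"
    trm_threshold: float = 0.20
    keep_flagged: bool = False  # write removed variants with FILTER tags instead of dropping
    log_level: str = "INFO"

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("vcf_dir", "reference", "sample_sheet", "tier_table", "out_dir"):
            d[k] = str(d[k])
        d["filter"]["tier_whitelist"] = sorted(t.value for t in self.filter.tier_whitelist)
        return d


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    config: RunConfig
    merged: list  # CallSet per sample (post-merge, pre-filter)
    cascade: CascadeResult
    partitions: dict  # patient_id -> ConcordancePartition
    jaccard: dict  # patient_id -> JaccardMatrix
    tmb: pd.DataFrame
    tmb_tf_pearson: tuple
    trm_calls: dict  # patient_id -> timepoint label or None
    persistence: pd.DataFrame
    scenarios: dict  # patient_id -> ScenarioReport
    actionability: pd.DataFrame
    summary: dict

    @property
    def retained(self) -> list:
        return self.cascade.callsets


def _find_vcfs(vcf_dir: Path, sample_id: str) -> list:
    """Locate the caller VCF(s) of a sample: <sid>.caller*.vcf or <sid>.vcf."""
    hits = sorted(vcf_dir.glob(f"{sample_id}.caller*.vcf")) or sorted(vcf_dir.glob(f"{sample_id}.vcf"))
    if not hits:
        raise FileNotFoundError(f"no VCF for sample {sample_id} under {vcf_dir}")
    return hits


def load_cohort(vcf_dir: Union[str, Path], records: list) -> list:
    """Read and ensemble-merge each sample's caller VCFs into one CallSet."""
    vcf_dir = Path(vcf_dir)
    merged = []
    for rec in records:
        paths = _find_vcfs(vcf_dir, rec.sample_id)
        sets = [
            read_vcf(p, rec, caller=(p.suffixes[-2].lstrip(".") if len(p.suffixes) > 1 else "callerA"))
            for p in paths
        ]
        cs = sets[0]
        for other in sets[1:]:
            cs = merge_callsets(cs, other)
        merged.append(cs)
    return merged


def _plasma_timeline(callsets: list) -> list:
    plasma = [cs for cs in callsets if cs.sample.is_plasma]
    return sorted(plasma, key=lambda cs: (cs.sample.collection_order, cs.sample.sample_id))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write the report bundle under ``out_dir``."""
    t0 = time.time()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_sample_sheet(config.sample_sheet)
    reference = pyfaidx.Fasta(str(config.reference))
    tier_table = load_tier_table(config.tier_table)

    merged = load_cohort(config.vcf_dir, records)
    logger.info("merged %d samples, %d variants", len(merged), sum(len(cs) for cs in merged))
    cascade = run_filter_cascade(merged, reference, config.filter)
    logger.info(
        "cascade retained %d variants, removed %d",
        sum(len(cs) for cs in cascade.callsets),
        len(cascade.audits),
    )

    # ---- per-sample derived sets
    retained = cascade.callsets
    nonsyn = {cs.sample.sample_id: nonsynonymous_subset(cs) for cs in retained}
    pathogenic = {
        cs.sample.sample_id: tier_prioritize(nonsyn[cs.sample.sample_id], tier_table,
                                             config.filter.tier_whitelist)
        for cs in retained
    }

    by_patient: dict = {}
    for cs in retained:
        by_patient.setdefault(cs.sample.patient_id, []).append(cs)

    # ---- spatial heterogeneity at T0 (patients with >= 1 biopsy and a T0 plasma)
    partitions = {}
    for pid, sets in sorted(by_patient.items()):
        tissues = [nonsyn[cs.sample.sample_id] for cs in sets if not cs.sample.is_plasma]
        t0_plasma = [
            nonsyn[cs.sample.sample_id]
            for cs in sets
            if cs.sample.is_plasma and cs.sample.timepoint in ("T0", "T1")
        ]
        if tissues and t0_plasma:
            partitions[pid] = classify_spatial(
                t0_plasma[0], tissues, denominator=config.concordance_denominator
            )

    # ---- temporal heterogeneity: Jaccard between plasma timepoints, TMB vs TF
    analysis_sets = pathogenic if config.pathogenic_only else nonsyn
    jaccard = {}
    for pid, sets in sorted(by_patient.items()):
        plasma = _plasma_timeline(sets)
        if len(plasma) >= 2:
            jaccard[pid] = jaccard_matrix([analysis_sets[cs.sample.sample_id] for cs in plasma])
    tmb_rows = []
    for cs in retained:
        tmb_rows.append(
            {
                "patient_id": cs.sample.patient_id,
                "sample_id": cs.sample.sample_id,
                "sample_type": cs.sample.sample_type,
                "timepoint": cs.sample.timepoint,
                "tumor_fraction": cs.sample.tumor_fraction if cs.sample.is_plasma else np.nan,
                "tmb": compute_tmb(nonsyn[cs.sample.sample_id]),
            }
        )
    tmb = pd.DataFrame(tmb_rows)
    plasma_tmb = tmb[tmb["sample_type"] == "plasma"]
    if len(plasma_tmb) >= 3:
        series = TmbSeries(
            sample_ids=list(plasma_tmb["sample_id"]),
            tmb=list(plasma_tmb["tmb"]),
            tumor_fraction=list(plasma_tmb["tumor_fraction"]),
        )
        pearson = correlate_tmb_tf(series)
    else:
        pearson = (float("nan"), float("nan"))

    # ---- molecular recurrence from TF trajectories
    trm_calls = {}
    for pid in sorted(by_patient):
        plasma = _plasma_timeline(by_patient[pid])
        if len(plasma) >= 2:
            traj = TfTrajectory(
                patient_id=pid,
                points=tuple((cs.sample.timepoint, cs.sample.tumor_fraction) for cs in plasma),
            )
            trm_calls[pid] = call_trm(traj, threshold=config.trm_threshold, mode=config.trm_mode)

    # ---- driver persistence, scenarios, actionability on pathogenic plasma sets
    persistence_rows = []
    scenarios = {}
    actionability_rows = []
    for pid in sorted(by_patient):
        plasma = _plasma_timeline(by_patient[pid])
        timeline = [pathogenic[cs.sample.sample_id] for cs in plasma]
        if len(timeline) >= 2:
            for key, info in driver_persistence(timeline).items():
                persistence_rows.append(
                    {
                        "patient_id": pid,
                        "chrom": key.chrom,
                        "pos": key.pos,
                        "ref": key.ref,
                        "alt": key.alt,
                        "consequence": key.consequence,
                        "presence": "".join("1" if x else "0" for x in info["pattern"]),
                        "class": info["class"],
                    }
                )
        if timeline:
            scenarios[pid] = tp53bp1_scenario(timeline)
            actionability_rows.extend(actionability_summary(timeline, tier_table))
    persistence = pd.DataFrame(persistence_rows)
    actionability = pd.DataFrame(actionability_rows)

    result = PipelineResult(
        config=config,
        merged=merged,
        cascade=cascade,
        partitions=partitions,
        jaccard=jaccard,
        tmb=tmb,
        tmb_tf_pearson=pearson,
        trm_calls=trm_calls,
        persistence=persistence,
        scenarios=scenarios,
        actionability=actionability,
        summary={},
    )
    result.summary = summarize_cohort(result)
    _write_bundle(result, out, reference, elapsed=time.time() - t0)
    return result


# ---------------------------------------------------------------------------
# Reporting


def summarize_cohort(result: PipelineResult) -> dict:
    """Cohort-level summary statistics from the per-patient tables."""
    counts = {"private": 0, "shared": 0, "common": 0}
    pair_pcts = []
    patient_medians = []
    for part in result.partitions.values():
        for k, v in part.counts.items():
            counts[k] += v
        pcts = list(part.pair_concordance.values())
        pair_pcts.extend(pcts)
        if pcts:
            patient_medians.append(statistics.median(pcts))
    total = sum(counts.values())
    fractions = {k: (v / total if total else float("nan")) for k, v in counts.items()}
    max_jaccard = {pid: jm.max_offdiagonal() for pid, jm in result.jaccard.items()}
    plasma = result.tmb[result.tmb["sample_type"] == "plasma"]["tmb"]
    tissue = result.tmb[result.tmb["sample_type"] == "tissue"]["tmb"]
    scen_counts: dict = {}
    for rep in result.scenarios.values():
        scen_counts[rep.scenario] = scen_counts.get(rep.scenario, 0) + 1
    summary = {
        "n_patients": len({cs.sample.patient_id for cs in result.retained}),
        "n_samples": len(result.retained),
        "variants_retained": int(sum(len(cs) for cs in result.retained)),
        "variants_removed": len(result.cascade.audits),
        "fraction_private": fractions["private"],
        "fraction_shared": fractions["shared"],
        "fraction_common": fractions["common"],
        "median_pair_concordance_pct": statistics.median(pair_pcts) if pair_pcts else float("nan"),
        "median_patient_concordance_pct": (
            statistics.median(patient_medians) if patient_medians else float("nan")
        ),
        "max_jaccard": max(max_jaccard.values()) if max_jaccard else float("nan"),
        "median_plasma_tmb": float(plasma.median()) if len(plasma) else float("nan"),
        "tmb_range": (
            (int(plasma.min()), int(plasma.max())) if len(plasma) else (float("nan"),) * 2
        ),
        "median_tissue_tmb": float(tissue.median()) if len(tissue) else float("nan"),
        "tmb_tf_pearson_r": result.tmb_tf_pearson[0],
        "tmb_tf_pearson_p": result.tmb_tf_pearson[1],
        "n_trm_called": sum(1 for v in result.trm_calls.values() if v is not None),
        "n_trm_evaluable": len(result.trm_calls),
        "scenario_counts": scen_counts,
        "n_parpi_flagged": sum(1 for r in result.scenarios.values() if r.parpi_resistance_flag),
    }
    return summary


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_bundle(result: PipelineResult, out: Path, reference, elapsed: float) -> None:
    cfg = result.config
    # audit table
    write_table(
        [
            {
                "sample_id": a.sample_id, "chrom": a.chrom, "pos": a.pos, "ref": a.ref,
                "alt": a.alt, "rule_id": a.rule_id.value, "detail": a.detail,
            }
            for a in result.cascade.audits
        ],
        out / "filter_audit.tsv",
        key_columns=("sample_id", "chrom", "pos", "ref", "alt"),
    )
    # retained variants
    write_table(
        [
            {
                "patient_id": v.patient_id, "sample_id": v.sample_id, "chrom": v.chrom,
                "pos": v.pos, "ref": v.ref, "alt": v.alt, "gene": v.gene,
                "consequence": v.consequence, "vaf": v.vaf, "alt_reads": v.alt_reads,
                "total_depth": v.total_depth, "callers": "+".join(sorted(v.callers)),
            }
            for cs in result.retained
            for v in cs.variants
        ],
        out / "retained_variants.tsv",
        key_columns=("patient_id", "sample_id", "chrom", "pos", "ref", "alt"),
    )
    # filtered VCFs (optionally with removed variants flagged instead of dropped)
    vcf_out = out / "filtered_vcf"
    vcf_out.mkdir(exist_ok=True)
    contigs = {name: len(reference[name]) for name in reference.keys()}
    audit_by_sample: dict = {}
    for a in result.cascade.audits:
        audit_by_sample.setdefault(a.sample_id, {})[(a.chrom, a.pos, a.ref, a.alt)] = a.rule_id.value
    merged_by_id = {cs.sample.sample_id: cs for cs in result.merged}
    for cs in result.retained:
        target = merged_by_id[cs.sample.sample_id] if cfg.keep_flagged else cs
        flags = audit_by_sample.get(cs.sample.sample_id, {}) if cfg.keep_flagged else None
        write_vcf(target, vcf_out / f"{cs.sample.sample_id}.filtered.vcf", contigs, flagged=flags)
    # spatial partition + concordance
    part_rows, conc_rows = [], []
    for pid, part in sorted(result.partitions.items()):
        for k, cls in part.assignments.items():
            part_rows.append(
                {
                    "patient_id": pid, "chrom": k.chrom, "pos": k.pos, "ref": k.ref,
                    "alt": k.alt, "consequence": k.consequence, "class": cls,
                }
            )
        for (pl, ti), pct in sorted(part.pair_concordance.items()):
            conc_rows.append(
                {"patient_id": pid, "plasma_sample": pl, "tissue_sample": ti, "concordance_pct": pct}
            )
    write_table(part_rows, out / "spatial_partition.tsv",
                key_columns=("patient_id", "chrom", "pos", "ref", "alt"))
    write_table(conc_rows, out / "spatial_concordance.tsv",
                key_columns=("patient_id", "plasma_sample", "tissue_sample"))
    # temporal Jaccard
    jrows = [row for pid in sorted(result.jaccard) for row in result.jaccard[pid].to_rows()]
    write_table(jrows, out / "jaccard_pairs.tsv", key_columns=("patient_id", "sample_a", "sample_b"))
    write_table(result.tmb, out / "tmb.tsv", key_columns=("patient_id", "sample_id"))
    write_table(
        [{"patient_id": pid, "trm_timepoint": lab or ""} for pid, lab in sorted(result.trm_calls.items())],
        out / "trm_calls.tsv",
        key_columns=("patient_id",),
    )
    write_table(result.persistence, out / "driver_persistence.tsv",
                key_columns=("patient_id", "chrom", "pos", "ref", "alt"))
    write_table(
        [
            {
                "patient_id": pid,
                "scenario": rep.scenario,
                "brca_status": rep.brca_status,
                "parpi_resistance_flag": rep.parpi_resistance_flag,
                "flag_timepoints": "+".join(rep.flag_timepoints),
                "n_tp53bp1_keys": sum(len(s) for s in rep.tp53bp1_timeline.values()),
            }
            for pid, rep in sorted(result.scenarios.items())
        ],
        out / "scenarios.tsv",
        key_columns=("patient_id",),
    )
    write_table(result.actionability, out / "actionability.tsv",
                key_columns=("patient_id", "sample_id", "gene", "hgvs_c"))
    # cohort summary (TSV + plain-text report)
    s = dict(result.summary)
    s["tmb_range"] = f"{s['tmb_range'][0]}-{s['tmb_range'][1]}"
    s["scenario_counts"] = ";".join(f"{k}={v}" for k, v in sorted(s["scenario_counts"].items()))
    write_table([{"metric": k, "value": v} for k, v in s.items()], out / "summary.tsv",
                key_columns=("metric",))
    report = ["cohort summary", "=" * 14]
    report += [f"{k}: {v}" for k, v in s.items()]
    (out / "summary.txt").write_text("\n".join(report) + "\n")
    # manifest
    manifest = {
        "tool": "ctdnahet",
        "version": __version__,
        "elapsed_seconds": round(elapsed, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": cfg.echo(),
        "inputs": {
            name: _sha256(Path(p))
            for name, p in (
                ("sample_sheet", cfg.sample_sheet),
                ("reference", cfg.reference),
                ("tier_table", cfg.tier_table),
            )
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
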