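"""Seeded synthetic cohorts with per-variant ground truth.

The generator emulates the data structure the analysis assumes: a multi-biopsy
cohort (default 12 patients, two synchronous biopsies and three plasma
timepoints T0/TRm/TRc each) sequenced by a two-caller ensemble at deep
targeted coverage (mean 7000x). Each patient carries one truncal TP53-like
variant in every sample; an optional germline BRCA1/2-like variant at ~50%
VAF everywhere (probability 0.28, matching typical germline prevalence in
this tumor type); sample-private subclonal variants whose plasma VAF scales
with the per-timepoint tumor fraction; repeat-context artifacts planted on
reference substrate guaranteed to match each filtering rule; recurrent
cohort-level frameshifts; common-population variants; and caller-private
low-support false positives. Tumor-fraction trajectories contain one designed
>= 20% relative jump at the TRm timepoint.

Every emitted variant has exactly one ground-truth row recording its
generative class, true VAF and intended post-filter fate, enabling exact
recovery checks of the whole pipeline. Identical config (including seed)
yields byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_io import (
    CallSet,
    SampleRecord,
    TierTable,
    VariantCall,
    write_sample_sheet,
    write_table,
    write_vcf,
)
from .clinical import TfTrajectory

__all__ = [
    "SimConfig",
    "ReferenceBundle",
    "SyntheticCohort",
    "generate_reference",
    "generate_cohort",
    "write_cohort",
    "truth_eval",
]

_BASES = np.array(list("ACGT"))

#: Genes assigned to planted loci. The first four are the therapy-relevant
#: genes the scenario logic inspects; the rest are background panel genes.
DEFAULT_GENES = (
    "TP53",
    "BRCA1",
    "BRCA2",
    "TP53BP1",
    "ATM",
    "ATR",
    "POLE",
    "MSH3",
    "PALB2",
    "FANCA",
    "RAD51B",
    "CHEK2",
    "PTEN",
    "NF1",
    "RB1",
    "CCNE1",
    "PIK3CA",
    "KRAS",
    "ARID1A",
    "CDK12",
)

_SPECIAL_GENES = frozenset({"TP53", "BRCA1", "BRCA2", "TP53BP1"})

_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val".split()
)

SCENARIOS = ("never", "mutated_at_baseline_lost", "acquired_at_relapse", "persistent", "mixed")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults are the emulated study conditions."""

    seed: int = 1
    n_patients: int = 12
    biopsies_per_patient: int = 2
    plasma_timepoints: tuple = ("T0", "TRm", "TRc")
    reference_length: int = 100_000
    chrom: str = "chr1"
    homopolymer_enrichment: float = 0.01
    n_tandem_repeats: int = 160
    genes: tuple = DEFAULT_GENES
    n_truncal: int = 1
    p_germline_brca: float = 0.28
    n_private_tissue: tuple = (2, 5)
    n_private_plasma: tuple = (3, 8)
    p_biopsy_to_plasma: float = 0.35
    p_synonymous: float = 0.15
    artifacts_per_rule: tuple = (1, 2)
    n_cohort_frameshift: int = 1
    cohort_frameshift_carrier_fraction: float = 0.70
    n_population_per_sample: tuple = (1, 2)
    population_af_range: tuple = (0.011, 0.40)
    caller_b_sensitivity: float = 0.8
    caller_b_fp_per_sample: int = 5
    depth_mean: float = 7000.0
    base_tf_range: tuple = (0.04, 0.15)
    pre_jump_factor: tuple = (0.75, 1.15)
    trm_jump_factor: tuple = (1.25, 2.0)
    post_jump_factor: tuple = (0.70, 1.60)
    tf_cap: float = 0.33
    scenario_probs: tuple = (
        ("never", 0.28),
        ("mutated_at_baseline_lost", 0.44),
        ("acquired_at_relapse", 0.11),
        ("persistent", 0.11),
        ("mixed", 0.06),
    )
    scenario_keys_range: tuple = (1, 3)
    p_parpi_brca: float = 0.6
    p_tier2_subclone: float = 0.35
    # thresholds mirrored by the fate oracle (must match the cascade defaults)
    fate_vaf_tolerance: float = 0.05
    fate_min_alt_reads: int = 5
    fate_max_population_af: float = 0.01

    def __post_init__(self) -> None:
        if self.reference_length < 1000:
            raise ValueError("reference_length must be >= 1 kb")
        for p in (self.p_germline_brca, self.p_biopsy_to_plasma, self.caller_b_sensitivity):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0,1]")
        if abs(sum(p for _, p in self.scenario_probs) - 1.0) > 1e-9:
            raise ValueError("scenario_probs must sum to 1")
        if "TRm" not in self.plasma_timepoints:
            raise ValueError("plasma_timepoints must include TRm")


# ---------------------------------------------------------------------------
# Reference generation


@dataclass
class ReferenceBundle:
    """Synthetic reference plus the substrate bookkeeping the cohort needs."""

    chrom: str
    sequence: str
    planted_runs: list  # (start 1-based, length, base)
    planted_tandems: list  # (start 1-based, unit, copies)

    def as_mapping(self) -> dict:
        return {self.chrom: self.sequence}

    def __len__(self) -> int:
        return len(self.sequence)


def generate_reference(config: SimConfig, rng: Optional[np.random.Generator] = None) -> ReferenceBundle:
    """Random reference with planted homopolymer runs and tandem repeats.

    Runs (length 3-8) are planted so the artifact rules always have substrate;
    tandem arrays of a 3-base unit (3-4 copies) feed the inframe-repeat rule.
    Planting sites are laid out on a shuffled grid so they never overlap.
    """
    rng = rng or np.random.default_rng([config.seed, 0])
    L = config.reference_length
    seq = rng.integers(0, 4, size=L)
    n_runs = int(config.homopolymer_enrichment * L / 5.5)
    n_tandem = config.n_tandem_repeats
    spacing = max(20, L // (n_runs + n_tandem + 2))
    slots = list(range(spacing, L - spacing, spacing))
    rng.shuffle(slots)
    if len(slots) < n_runs + n_tandem:
        raise ValueError("reference too short for the requested planting density")
    planted_runs = []
    for slot in slots[:n_runs]:
        run_len = int(rng.integers(3, 9))
        base = int(rng.integers(0, 4))
        other = (base + 1 + int(rng.integers(0, 3))) % 4
        seq[slot - 1] = other  # guard bases bound the run exactly
        seq[slot : slot + run_len] = base
        seq[slot + run_len] = (base + 1 + int(rng.integers(0, 3))) % 4
        planted_runs.append((slot + 1, run_len, str(_BASES[base])))
    planted_tandems = []
    for slot in slots[n_runs : n_runs + n_tandem]:
        b = rng.permutation(4)[:3]  # 3 distinct bases: never a homopolymer unit
        unit = "".join(_BASES[b])
        copies = int(rng.integers(3, 5))
        arr = np.tile(b, copies)
        # guard bases: preceding base != unit[-1] (keeps the deletion
        # left-anchored), following base != unit[0] (array ends cleanly)
        seq[slot - 1] = (b[2] + 1 + int(rng.integers(0, 3))) % 4
        seq[slot : slot + 3 * copies] = arr
        seq[slot + 3 * copies] = (b[0] + 1 + int(rng.integers(0, 3))) % 4
        planted_tandems.append((slot + 1, unit, copies))
    return ReferenceBundle(
        chrom=config.chrom,
        sequence="".join(_BASES[seq]),
        planted_runs=planted_runs,
        planted_tandems=planted_tandems,
    )


# ---------------------------------------------------------------------------
# Site pools scanned from the finished reference


_MARGIN = 80  # keep variants away from chromosome ends


class _SitePools:
    """Disjoint pools of reference positions with verified local context."""

    def __init__(self, ref: ReferenceBundle, rng: np.random.Generator, min_run: int = 3) -> None:
        self.seq = ref.sequence
        L = len(self.seq)
        run_start = np.ones(L, dtype=np.int32)  # run length starting at index i (0-based)
        for i in range(L - 2, -1, -1):
            if self.seq[i] == self.seq[i + 1]:
                run_start[i] = run_start[i + 1] + 1
        run_end = np.ones(L, dtype=np.int32)
        for i in range(1, L):
            if self.seq[i] == self.seq[i - 1]:
                run_end[i] = run_end[i - 1] + 1
        self._run_start = run_start
        self._run_end = run_end
        runs = []  # maximal runs >= min_run: (start 1-based, length)
        i = 0
        while i < L:
            n = int(run_start[i])
            if n >= min_run and _MARGIN < i + 1 < L - _MARGIN - n:
                runs.append((i + 1, n))
            i += n
        rng.shuffle(runs)
        self._runs = runs
        clean = [
            p
            for p in range(_MARGIN, L - _MARGIN)  # 0-based index p -> position p+1
            if (run_end[p - 1] < min_run) and (run_start[p + 1] < min_run) and run_start[p] < min_run
        ]
        rng.shuffle(clean)
        self._clean = clean  # 0-based
        tandems = [
            t
            for t in ref.planted_tandems
            if _MARGIN < t[0] < L - _MARGIN - 3 * t[2]
        ]
        rng.shuffle(tandems)
        self._tandems = tandems

    def _base(self, pos: int) -> str:  # 1-based
        return self.seq[pos - 1]

    def pop_run(self) -> tuple:
        if not self._runs:
            raise RuntimeError("exhausted homopolymer-run substrate; raise enrichment")
        return self._runs.pop()

    def pop_clean(self, gene_range: Optional[tuple] = None) -> int:
        """Pop a clean position (1-based), optionally within a gene block."""
        pool = self._clean
        if gene_range is None:
            if not pool:
                raise RuntimeError("exhausted clean sites")
            return pool.pop() + 1
        lo, hi = gene_range
        for i in range(len(pool) - 1, -1, -1):
            pos = pool[i] + 1
            if lo <= pos <= hi:
                pool.pop(i)
                return pos
        raise RuntimeError(f"exhausted clean sites in block {gene_range}")

    def pop_clean_deletion(self, gene_range: Optional[tuple] = None) -> int:
        """Clean 1-bp deletion site: returns the anchor position.

        The deleted base (anchor+1) differs from its neighbours (left-anchored
        representation) and is not followed by a homopolymer run >= 3.
        """
        pool = self._clean
        for i in range(len(pool) - 1, -1, -1):
            d = pool[i] + 1  # candidate deleted base
            if gene_range and not (gene_range[0] <= d <= gene_range[1]):
                continue
            if self._base(d) != self._base(d - 1) and self._base(d) != self._base(d + 1):
                if self._run_start[d] < 3:  # run starting at base after deletion (0-based d == pos d+1)
                    pool.pop(i)
                    return d - 1
        raise RuntimeError("exhausted clean deletion sites")

    def pop_tandem(self) -> tuple:
        if not self._tandems:
            raise RuntimeError("exhausted tandem-repeat substrate; raise n_tandem_repeats")
        return self._tandems.pop()


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class _Event:
    """One generative variant shared by a set of member samples."""

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    gene: str
    hgvs_c: str
    hgvs_p: str
    gen_class: str
    members: dict = field(default_factory=dict)  # sample_id -> true VAF
    population_af: Optional[float] = None
    tier: Optional[str] = None  # tier-table entry to emit
    therapies: str = ""


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort with ground truth."""

    config: SimConfig
    reference: ReferenceBundle
    samples: list  # SampleRecord
    caller_a: dict  # sample_id -> CallSet
    caller_b: dict  # sample_id -> CallSet
    truth: pd.DataFrame
    patients: pd.DataFrame  # per-patient designed truth
    trajectories: dict  # patient_id -> TfTrajectory
    tier_rows: list

    @property
    def contigs(self) -> dict:
        return {self.reference.chrom: len(self.reference)}

    def tier_table(self) -> TierTable:
        return TierTable(self.tier_rows)


def _randint(rng, lohi: tuple) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _uniform(rng, lohi: tuple) -> float:
    return float(rng.uniform(lohi[0], lohi[1]))


def _other_base(rng, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(0, 3))]


class _CohortBuilder:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.ref = generate_reference(config)
        self.rng = np.random.default_rng([config.seed, 1])
        self.pools = _SitePools(self.ref, self.rng)
        self.block = config.reference_length // len(config.genes)
        self.events: list = []

    # -- gene geometry ------------------------------------------------------

    def gene_range(self, gene: str) -> tuple:
        i = self.cfg.genes.index(gene)
        lo = i * self.block + 1
        hi = (i + 1) * self.block if i < len(self.cfg.genes) - 1 else self.cfg.reference_length
        return (max(lo, _MARGIN + 1), min(hi, self.cfg.reference_length - _MARGIN))

    def gene_of(self, pos: int) -> str:
        i = min((pos - 1) // self.block, len(self.cfg.genes) - 1)
        return self.cfg.genes[i]

    def background_gene(self) -> str:
        candidates = [g for g in self.cfg.genes if g not in _SPECIAL_GENES]
        return candidates[int(self.rng.integers(0, len(candidates)))]

    # -- variant fabrication --------------------------------------------------

    def _hgvs(self, gene: str, pos: int, ref: str, alt: str, consequence: str) -> tuple:
        lo, _ = self.gene_range(gene)
        cpos = pos - lo + 1
        hgvs_c = f"c.{cpos}{ref}>{alt}" if len(ref) == len(alt) == 1 else (
            f"c.{cpos}del{ref[1:]}" if len(ref) > len(alt) else f"c.{cpos}ins{alt[1:]}"
        )
        aa_pos = max(1, math.ceil(cpos / 3))
        rng = self.rng
        if consequence == "missense_variant":
            a, b = rng.integers(0, len(_AA3), size=2)
            hgvs_p = f"p.{_AA3[a]}{aa_pos}{_AA3[(b + 1) % len(_AA3)] if _AA3[a] == _AA3[b] else _AA3[b]}"
        elif consequence == "stop_gained":
            hgvs_p = f"p.{_AA3[int(rng.integers(0, len(_AA3)))]}{aa_pos}Ter"
        elif consequence.startswith("frameshift"):
            hgvs_p = f"p.{_AA3[int(rng.integers(0, len(_AA3)))]}{aa_pos}fs"
        else:
            hgvs_p = ""
        return hgvs_c, hgvs_p

    def make_snv(self, gene: str, consequence: str, gen_class: str, pos: Optional[int] = None) -> _Event:
        if pos is None:
            pos = self.pools.pop_clean(self.gene_range(gene))
        ref = self.ref.sequence[pos - 1]
        alt = _other_base(self.rng, ref)
        hgvs_c, hgvs_p = self._hgvs(gene, pos, ref, alt, consequence)
        return _Event(
            chrom=self.cfg.chrom, pos=pos, ref=ref, alt=alt, consequence=consequence,
            gene=gene, hgvs_c=hgvs_c, hgvs_p=hgvs_p, gen_class=gen_class,
        )

    def make_clean_deletion(self, gene: str, n_bases: int, consequence: str, gen_class: str) -> _Event:
        anchor = self.pools.pop_clean_deletion(self.gene_range(gene)) if n_bases == 1 else (
            self.pools.pop_clean(self.gene_range(gene))
        )
        ref = self.ref.sequence[anchor - 1 : anchor + n_bases]
        alt = ref[0]
        hgvs_c, hgvs_p = self._hgvs(gene, anchor, ref, alt, consequence)
        return _Event(
            chrom=self.cfg.chrom, pos=anchor, ref=ref, alt=alt, consequence=consequence,
            gene=gene, hgvs_c=hgvs_c, hgvs_p=hgvs_p, gen_class=gen_class,
        )

    # -- artifact fabrication (context guaranteed to match each rule) --------

    def make_artifact(self, rule: str) -> _Event:
        rng, seq = self.rng, self.ref.sequence
        if rule == "artifact_rule_i":
            # 1-base deletion immediately upstream of a homopolymer run
            while True:
                r, _ = self.pools.pop_run()
                d = r - 1  # deleted base, != run base because the run is maximal
                if d >= 3 and seq[d - 2] != seq[d - 1]:  # left-anchored
                    break
            anchor = d - 1
            ref, alt = seq[anchor - 1] + seq[d - 1], seq[anchor - 1]
            cons = "frameshift_variant"
            pos = anchor
        elif rule == "artifact_rule_ii":
            r, _ = self.pools.pop_run()
            anchor = r - 1
            n_ins = int(rng.integers(1, 3))
            ins = "".join(_other_base(rng, seq[anchor - 1]) for _ in range(n_ins))
            ref, alt = seq[anchor - 1], seq[anchor - 1] + ins
            cons = "frameshift_variant"
            pos = anchor
        elif rule == "artifact_rule_iii":
            r, _ = self.pools.pop_run()
            pos = r - 1  # SNV immediately 5' of the run
            ref = seq[pos - 1]
            alt = _other_base(rng, ref)
            cons = "missense_variant"
        elif rule == "artifact_rule_iv":
            t, unit, copies = self.pools.pop_tandem()
            pos = t - 1  # anchor before the first copy; deletion of one unit
            ref, alt = seq[pos - 1] + unit, seq[pos - 1]
            cons = "inframe_deletion"
        else:
            raise ValueError(f"unknown artifact rule {rule}")
        gene = self.gene_of(pos)
        hgvs_c, hgvs_p = self._hgvs(gene, pos, ref, alt, cons)
        return _Event(
            chrom=self.cfg.chrom, pos=pos, ref=ref, alt=alt, consequence=cons,
            gene=gene, hgvs_c=hgvs_c, hgvs_p=hgvs_p, gen_class=rule,
        )

    # -- depth realisation ----------------------------------------------------

    def draw_depths(
        self,
        true_vaf: float,
        min_alt: Optional[int] = None,
        max_alt: Optional[int] = None,
        vaf_window: Optional[tuple] = None,
    ) -> tuple:
        rng, mean = self.rng, self.cfg.depth_mean
        for _ in range(200):
            depth = max(200, int(rng.poisson(mean)))
            alt = int(rng.binomial(depth, true_vaf)) if true_vaf > 0 else 0
            if max_alt is not None:
                alt = min(alt, max_alt)
            v = alt / depth
            if min_alt is not None and alt < min_alt:
                continue
            if vaf_window is not None and not (vaf_window[0] <= v <= vaf_window[1]):
                continue
            return alt, depth
        raise RuntimeError("could not realise depths under the requested constraints")


def _choose_scenario(rng: np.random.Generator, probs: tuple) -> str:
    names = [n for n, _ in probs]
    p = np.array([x for _, x in probs])
    return names[int(rng.choice(len(names), p=p / p.sum()))]


def generate_cohort(config: SimConfig = SimConfig()) -> SyntheticCohort:
    """Generate the full synthetic cohort with ground truth (in memory)."""
    b = _CohortBuilder(config)
    rng = b.rng
    cfg = config
    tol = cfg.fate_vaf_tolerance

    samples: list = []
    patient_rows = []
    trajectories = {}
    per_sample_events: dict = {}  # sample_id -> list of (event, true_vaf)

    patient_ids = [f"P{i+1:02d}" for i in range(cfg.n_patients)]
    biopsy_labels = [chr(ord("A") + i) for i in range(cfg.biopsies_per_patient)]

    for pid in patient_ids:
        # --- samples and tumor-fraction trajectory
        tissue_samples = []
        purity = {}
        for j, lab in enumerate(biopsy_labels):
            sid = f"{pid}_B{lab}"
            tissue_samples.append(
                SampleRecord(sample_id=sid, patient_id=pid, sample_type="tissue", timepoint=lab,
                             collection_order=0)
            )
            purity[sid] = _uniform(rng, (0.2, 0.5))
        tf_points = []
        trm_pos = cfg.plasma_timepoints.index("TRm")
        tf = _uniform(rng, cfg.base_tf_range)
        for k, tp in enumerate(cfg.plasma_timepoints):
            if k == 0:
                pass
            elif k < trm_pos:
                tf *= _uniform(rng, cfg.pre_jump_factor)
            elif k == trm_pos:
                tf *= _uniform(rng, cfg.trm_jump_factor)
            else:
                tf *= _uniform(rng, cfg.post_jump_factor)
            tf = min(tf, cfg.tf_cap)
            tf_points.append((tp, tf))
        # the designed jump must stay the first >=20% rise even after capping
        if tf_points[trm_pos][1] < tf_points[trm_pos - 1][1] * 1.25:
            tf_points[trm_pos] = (cfg.plasma_timepoints[trm_pos], min(cfg.tf_cap, tf_points[trm_pos - 1][1] * 1.30))
        trajectories[pid] = TfTrajectory(patient_id=pid, points=tuple(tf_points))
        plasma_samples = []
        for k, (tp, tfv) in enumerate(tf_points):
            sid = f"{pid}_{tp}"
            plasma_samples.append(
                SampleRecord(sample_id=sid, patient_id=pid, sample_type="plasma", timepoint=tp,
                             tumor_fraction=tfv, collection_order=k + 1)
            )
        psamples = tissue_samples + plasma_samples
        samples.extend(psamples)
        for s in psamples:
            per_sample_events[s.sample_id] = []
        plasma_tf = {s.sample_id: s.tumor_fraction for s in plasma_samples}
        plasma_by_tp = {s.timepoint: s for s in plasma_samples}

        def clonal_vaf(sid: str) -> float:
            return purity[sid] / 2 if sid in purity else plasma_tf[sid] / 2

        # --- truncal TP53-like drivers
        for _ in range(cfg.n_truncal):
            ev = b.make_snv("TP53", "missense_variant" if rng.random() < 0.6 else "stop_gained", "truncal")
            ev.tier, ev.therapies = "known_driver", ""
            for s in psamples:
                ev.members[s.sample_id] = clonal_vaf(s.sample_id)
            b.events.append(ev)

        # --- optional germline BRCA1/2-like variant (~50% VAF everywhere)
        has_germline = rng.random() < cfg.p_germline_brca
        if has_germline:
            g = "BRCA1" if rng.random() < 0.8 else "BRCA2"
            ev = b.make_clean_deletion(g, 1, "frameshift_variant", "germline")
            ev.tier, ev.therapies = "tier1", "PARPi;platinum"
            for s in psamples:
                ev.members[s.sample_id] = _uniform(rng, (0.46, 0.54))
            b.events.append(ev)

        # --- biopsy-private subclones, a draw of which also reaches T0 plasma
        t0 = plasma_by_tp.get("T0") or plasma_samples[0]
        for s in tissue_samples:
            for _ in range(_randint(rng, cfg.n_private_tissue)):
                cons = "synonymous_variant" if rng.random() < cfg.p_synonymous else "missense_variant"
                ev = b.make_snv(b.background_gene(), cons, "subclonal_private")
                u = _uniform(rng, (0.1, 0.9))
                ev.members[s.sample_id] = clonal_vaf(s.sample_id) * u
                if rng.random() < cfg.p_biopsy_to_plasma:
                    ev.gen_class = "shared_subset"
                    ev.members[t0.sample_id] = clonal_vaf(t0.sample_id) * _uniform(rng, (0.1, 0.9))
                if rng.random() < cfg.p_tier2_subclone:
                    ev.tier = "tier2"
                b.events.append(ev)

        # --- plasma-private subclones per timepoint
        for s in plasma_samples:
            for _ in range(_randint(rng, cfg.n_private_plasma)):
                cons = "synonymous_variant" if rng.random() < cfg.p_synonymous else "missense_variant"
                ev = b.make_snv(b.background_gene(), cons, "subclonal_private")
                ev.members[s.sample_id] = clonal_vaf(s.sample_id) * _uniform(rng, (0.1, 0.9))
                if rng.random() < cfg.p_tier2_subclone:
                    ev.tier = "tier2"
                b.events.append(ev)

        # --- designed TP53BP1 scenario (and PARPi co-occurrence)
        scenario = _choose_scenario(rng, cfg.scenario_probs)
        baseline_tp = "T0" if "T0" in plasma_by_tp else cfg.plasma_timepoints[0]
        relapse_tp = "TRc" if "TRc" in plasma_by_tp else "TRm"
        designed_parpi = False
        somatic_brca = False

        def plant_tp53bp1(timepoints: Sequence[str]) -> None:
            for _ in range(_randint(rng, cfg.scenario_keys_range)):
                ev = b.make_snv("TP53BP1", "missense_variant", "scenario_tp53bp1")
                ev.tier, ev.therapies = "known_driver", ""
                for tp in timepoints:
                    sid = plasma_by_tp[tp].sample_id
                    ev.members[sid] = plasma_tf[sid] / 2 * _uniform(rng, (0.2, 0.9))
                b.events.append(ev)

        if scenario == "mutated_at_baseline_lost":
            plant_tp53bp1([baseline_tp])
        elif scenario == "acquired_at_relapse":
            plant_tp53bp1([relapse_tp])
        elif scenario == "persistent":
            plant_tp53bp1(list(plasma_by_tp))
        elif scenario == "mixed":
            plant_tp53bp1([baseline_tp])
            plant_tp53bp1([relapse_tp])
        if scenario in ("acquired_at_relapse", "mixed") and rng.random() < cfg.p_parpi_brca:
            ev = b.make_snv("BRCA1", "missense_variant", "scenario_brca")
            ev.tier, ev.therapies = "tier1", "PARPi;platinum"
            sid = plasma_by_tp[relapse_tp].sample_id
            ev.members[sid] = plasma_tf[sid] / 2 * _uniform(rng, (0.2, 0.9))
            b.events.append(ev)
            designed_parpi = True
            somatic_brca = True

        # --- per-sample artifacts (rules i-iv) and population variants
        for s in psamples:
            for rule in ("artifact_rule_i", "artifact_rule_ii", "artifact_rule_iii", "artifact_rule_iv"):
                for _ in range(_randint(rng, cfg.artifacts_per_rule)):
                    ev = b.make_artifact(rule)
                    base = clonal_vaf(s.sample_id)
                    ev.members[s.sample_id] = max(0.004, base * _uniform(rng, (0.3, 1.0)))
                    b.events.append(ev)
            for _ in range(_randint(rng, cfg.n_population_per_sample)):
                ev = b.make_snv(b.background_gene(), "missense_variant", "population")
                ev.population_af = _uniform(rng, cfg.population_af_range)
                ev.members[s.sample_id] = max(0.004, clonal_vaf(s.sample_id) * _uniform(rng, (0.3, 1.0)))
                b.events.append(ev)

        brca_status = "germline_mut" if has_germline else ("somatic_mut" if somatic_brca else "wt")
        patient_rows.append(
            {
                "patient_id": pid,
                "brca_status": brca_status,
                "designed_scenario": scenario,
                "designed_parpi_flag": designed_parpi,
                "designed_trm_label": cfg.plasma_timepoints[trm_pos],
                "designed_trm_index": trm_pos,
            }
        )

    # --- cohort-recurrent frameshifts (rule v)
    all_sample_ids = [s.sample_id for s in samples]
    tf_by_sample = {s.sample_id: s.tumor_fraction for s in samples}
    purity_like = {
        s.sample_id: (s.tumor_fraction / 2 if s.is_plasma else 0.15) for s in samples
    }
    n_carriers = math.ceil(cfg.cohort_frameshift_carrier_fraction * len(all_sample_ids))
    for _ in range(cfg.n_cohort_frameshift):
        pos = b.pools.pop_clean()
        ref2 = b.ref.sequence[pos - 1 : pos + 2]
        ev = _Event(
            chrom=cfg.chrom, pos=pos, ref=ref2, alt=ref2[0], consequence="frameshift_variant",
            gene=b.gene_of(pos), hgvs_c=f"c.{pos}del", hgvs_p="", gen_class="cohort_frameshift",
        )
        carriers = list(rng.choice(all_sample_ids, size=n_carriers, replace=False))
        for sid in carriers:
            ev.members[sid] = max(0.004, purity_like[sid] * _uniform(rng, (0.3, 1.0)))
        b.events.append(ev)

    # --- caller-B-private false positives (low support)
    fp_events = []
    for s in samples:
        for _ in range(cfg.caller_b_fp_per_sample):
            ev = b.make_snv(b.background_gene(), "missense_variant", "caller_noise")
            ev.members[s.sample_id] = 2.0 / cfg.depth_mean
            fp_events.append(ev)

    # --- realise depths, intended fates and the two caller call sets
    sample_by_id = {s.sample_id: s for s in samples}
    truth_rows = []
    calls_a: dict = {s.sample_id: [] for s in samples}
    calls_b: dict = {s.sample_id: [] for s in samples}

    def fate_of(gen_class: str, sample: SampleRecord, vaf: float, alt: int, pop: Optional[float]) -> str:
        if sample.is_plasma and vaf > sample.tumor_fraction + tol:
            return "remove:vaf_threshold"
        if alt < cfg.fate_min_alt_reads:
            return "remove:min_alt_reads"
        if gen_class == "germline":
            return "remove:likely_germline"
        if (pop or 0.0) > cfg.fate_max_population_af:
            return "remove:population_af"
        if gen_class == "artifact_rule_i":
            return "remove:del_upstream_homopolymer"
        if gen_class == "artifact_rule_ii":
            return "remove:ins_upstream_homopolymer"
        if gen_class == "artifact_rule_iii":
            return "remove:snv_flanking_repeat"
        if gen_class == "artifact_rule_iv":
            return "remove:inframe_repeat"
        if gen_class == "cohort_frameshift":
            return "remove:cohort_frameshift"
        return "retain"

    for ev in b.events + fp_events:
        for sid, true_vaf in sorted(ev.members.items()):
            s = sample_by_id[sid]
            thr = (s.tumor_fraction + tol) if s.is_plasma else 1.0
            if ev.gen_class == "germline":
                alt, depth = b.draw_depths(true_vaf, min_alt=5, vaf_window=(0.42, 0.58))
            elif ev.gen_class == "caller_noise":
                depth = max(200, int(rng.poisson(cfg.depth_mean)))
                alt = int(rng.integers(1, cfg.fate_min_alt_reads))
            else:
                alt, depth = b.draw_depths(true_vaf, min_alt=5, vaf_window=(0.0, thr))
            make = lambda reads, total, caller: VariantCall(  # noqa: E731
                patient_id=s.patient_id, sample_id=sid, chrom=ev.chrom, pos=ev.pos,
                ref=ev.ref, alt=ev.alt, alt_reads=reads, total_depth=total,
                consequence=ev.consequence, gene=ev.gene, hgvs_c=ev.hgvs_c,
                hgvs_p=ev.hgvs_p or None, population_af=ev.population_af,
                callers=frozenset({caller}),
            )
            if ev.gen_class == "caller_noise":
                calls_b[sid].append(make(alt, depth, "callerB"))
            else:
                calls_a[sid].append(make(alt, depth, "callerA"))
                if rng.random() < cfg.caller_b_sensitivity:
                    depth_b = max(100, int(depth * _uniform(rng, (0.85, 0.99))))
                    alt_b = min(depth_b, int(rng.binomial(depth_b, alt / depth)))
                    calls_b[sid].append(make(alt_b, depth_b, "callerB"))
            truth_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": s.patient_id,
                    "chrom": ev.chrom,
                    "pos": ev.pos,
                    "ref": ev.ref,
                    "alt": ev.alt,
                    "gene": ev.gene,
                    "consequence": ev.consequence,
                    "class": ev.gen_class,
                    "true_vaf": true_vaf,
                    "alt_reads": alt,
                    "total_depth": depth,
                    "population_af": ev.population_af if ev.population_af is not None else "",
                    "fate": fate_of(ev.gen_class, s, alt / depth, alt, ev.population_af),
                }
            )

    caller_a_sets = {
        sid: CallSet(sample=sample_by_id[sid],
                     variants=sorted(vs, key=lambda v: (v.pos, v.ref, v.alt)),
                     provenance="sim:callerA")
        for sid, vs in calls_a.items()
    }
    caller_b_sets = {
        sid: CallSet(sample=sample_by_id[sid],
                     variants=sorted(vs, key=lambda v: (v.pos, v.ref, v.alt)),
                     provenance="sim:callerB")
        for sid, vs in calls_b.items()
    }

    tier_rows = [
        {"gene": ev.gene, "change": ev.hgvs_c, "tier": ev.tier, "evidence": "synthetic",
         "therapies": ev.therapies}
        for ev in b.events
        if ev.tier is not None
    ]
    truth = pd.DataFrame(truth_rows).sort_values(
        ["patient_id", "sample_id", "pos", "ref", "alt"], kind="mergesort"
    ).reset_index(drop=True)
    return SyntheticCohort(
        config=cfg,
        reference=b.ref,
        samples=samples,
        caller_a=caller_a_sets,
        caller_b=caller_b_sets,
        truth=truth,
        patients=pd.DataFrame(patient_rows),
        trajectories=trajectories,
        tier_rows=tier_rows,
    )


# ---------------------------------------------------------------------------
# File emission


def write_cohort(cohort: SyntheticCohort, out_dir: Union[str, Path]) -> dict:
    """Write the cohort to disk (FASTA, VCFs, TSVs, manifest). Returns paths."""
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    fasta = out / "reference.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{cohort.reference.chrom}\n")
        seq = cohort.reference.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    import pyfaidx

    pyfaidx.Faidx(str(fasta))  # writes the .fai index
    write_sample_sheet(cohort.samples, out / "sample_sheet.tsv")
    tf_rows = [
        {"patient_id": pid, "timepoint": lab, "tumor_fraction": tf, "order": i}
        for pid, traj in sorted(cohort.trajectories.items())
        for i, (lab, tf) in enumerate(traj.points)
    ]
    write_table(tf_rows, out / "tf_trajectories.tsv", key_columns=("patient_id", "order"))
    write_table(cohort.truth, out / "ground_truth.tsv",
                key_columns=("patient_id", "sample_id", "pos", "ref", "alt"))
    write_table(cohort.patients, out / "patients_truth.tsv", key_columns=("patient_id",))
    tier_df = pd.DataFrame(cohort.tier_rows).drop_duplicates(subset=["gene", "change"])
    write_table(tier_df, out / "tier_table.tsv", key_columns=("gene", "change"))
    for sid in sorted(cohort.caller_a):
        write_vcf(cohort.caller_a[sid], out / "vcf" / f"{sid}.callerA.vcf", cohort.contigs)
        write_vcf(cohort.caller_b[sid], out / "vcf" / f"{sid}.callerB.vcf", cohort.contigs)
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cohort.config).items()},
        "n_samples": len(cohort.samples),
        "n_truth_rows": int(len(cohort.truth)),
        "planted_homopolymer_runs": len(cohort.reference.planted_runs),
        "planted_tandem_repeats": len(cohort.reference.planted_tandems),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "reference": fasta,
        "sample_sheet": out / "sample_sheet.tsv",
        "vcf_dir": out / "vcf",
        "tier_table": out / "tier_table.tsv",
        "ground_truth": out / "ground_truth.tsv",
        "patients_truth": out / "patients_truth.tsv",
        "tf_trajectories": out / "tf_trajectories.tsv",
        "manifest": out / "manifest.json",
    }


# ---------------------------------------------------------------------------
# Recovery evaluation


#: Expected spatial class at T0 per generative class (non-artifact, retained).
_EXPECTED_SPATIAL = {
    "truncal": "common",
    "shared_subset": "shared",
    "subclonal_private": "private",
    "scenario_tp53bp1": "private",
    "scenario_brca": "private",
}


def truth_eval(
    truth: pd.DataFrame,
    retained: Sequence[CallSet],
    audits: Sequence,
    partitions: Optional[dict] = None,
    trm_calls: Optional[dict] = None,
    scenarios: Optional[dict] = None,
    patients_truth: Optional[pd.DataFrame] = None,
) -> dict:
    """Compare pipeline outputs against the generator's ground truth.

    Returns per-class retention/removal/attribution rates, and (when the
    corresponding outputs are supplied) spatial-classification accuracy, TRm
    recovery and scenario recovery. Raises if a truth variant cannot be found
    in either the retained sets or the audit table (a keying bug).
    """
    retained_loci = {
        cs.sample.sample_id: {(v.chrom, v.pos, v.ref, v.alt) for v in cs.variants} for cs in retained
    }
    audit_rule = {(a.sample_id, a.chrom, a.pos, a.ref, a.alt): a.rule_id.value for a in audits}
    per_class: dict = {}
    records = truth.to_dict("records")
    for row in records:
        key = (row["sample_id"], row["chrom"], row["pos"], row["ref"], row["alt"])
        stats = per_class.setdefault(
            row["class"],
            {"n": 0, "retained": 0, "removed": 0, "attributed": 0, "expected_removed": 0},
        )
        stats["n"] += 1
        observed_retained = key[1:] in retained_loci.get(row["sample_id"], set())
        observed_rule = audit_rule.get(key)
        if not observed_retained and observed_rule is None:
            raise ValueError(f"truth variant {key} missing from both retained sets and audits")
        if observed_retained:
            stats["retained"] += 1
        else:
            stats["removed"] += 1
        if row["fate"].startswith("remove:"):
            stats["expected_removed"] += 1
            if observed_rule == row["fate"].split(":", 1)[1]:
                stats["attributed"] += 1
    metrics = {"per_class": {}}
    for cls, s in sorted(per_class.items()):
        entry = {
            "n": s["n"],
            "retention_rate": s["retained"] / s["n"],
            "removal_rate": s["removed"] / s["n"],
        }
        if s["expected_removed"]:
            entry["rule_attribution_accuracy"] = s["attributed"] / s["expected_removed"]
        metrics["per_class"][cls] = entry

    # aggregate convenience rates used by the acceptance checks
    art = [s for c, s in per_class.items() if c.startswith("artifact_rule") or c == "cohort_frameshift"]
    if art:
        n = sum(s["n"] for s in art)
        metrics["artifact_removal_rate"] = sum(s["removed"] for s in art) / n
        metrics["artifact_attribution_accuracy"] = sum(s["attributed"] for s in art) / n
    retain_rows = [r for r in records if r["fate"] == "retain"]
    if retain_rows:
        kept = sum(
            (r["chrom"], r["pos"], r["ref"], r["alt"]) in retained_loci.get(r["sample_id"], set())
            for r in retain_rows
        )
        metrics["true_retention_rate"] = kept / len(retain_rows)

    if partitions is not None:
        total = correct = 0
        by_key: dict = {}
        for row in retain_rows:
            by_key[
                (row["patient_id"], row["chrom"], row["pos"], row["ref"], row["alt"], row["consequence"])
            ] = row["class"]
        for pid, part in partitions.items():
            for k, assigned in part.assignments.items():
                gen = by_key.get((pid, k.chrom, k.pos, k.ref, k.alt, k.consequence))
                if gen is None or gen not in _EXPECTED_SPATIAL:
                    continue
                total += 1
                correct += assigned == _EXPECTED_SPATIAL[gen]
        metrics["spatial_accuracy"] = correct / total if total else math.nan
        metrics["spatial_n"] = total

    if trm_calls is not None and patients_truth is not None:
        designed = dict(zip(patients_truth["patient_id"], patients_truth["designed_trm_label"]))
        hits = [trm_calls.get(pid) == lab for pid, lab in designed.items()]
        metrics["trm_recovery_rate"] = sum(hits) / len(hits) if hits else math.nan

    if scenarios is not None and patients_truth is not None:
        designed = dict(zip(patients_truth["patient_id"], patients_truth["designed_scenario"]))
        flags = dict(zip(patients_truth["patient_id"], patients_truth["designed_parpi_flag"]))
        sc_hits, fl_hits = [], []
        for pid, sc in designed.items():
            rep = scenarios.get(pid)
            if rep is None:
                continue
            sc_hits.append(rep.scenario == sc)
            fl_hits.append(rep.parpi_resistance_flag == bool(flags[pid]))
        metrics["scenario_recovery_rate"] = sum(sc_hits) / len(sc_hits) if sc_hits else math.nan
        metrics["parpi_flag_recovery_rate"] = sum(fl_hits) / len(fl_hits) if fl_hits else math.nan
    return metrics
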