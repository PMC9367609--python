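"""Ensemble merging and the somatic filtering/prioritization cascade.

Deep-coverage targeted resequencing of cfDNA produces abundant low-level
artifacts, dominated by apparent indels around short reference repeats. The
cascade implemented here removes, in a fixed order and with a per-variant
audit trail:

1. calls whose VAF exceeds what the sample's known tumor fraction supports
   (sample-specific threshold ``TF + tolerance``, plasma only);
2. calls with too few supporting reads;
3. likely germline variants and variants common in the general population;
4. repeat-context artifacts — four deterministic sequence-context rules
   (deletion/insertion upstream of a homopolymer, SNV flanking a homopolymer,
   inframe indel of a tandem-repeated unit);
5. frameshifts recurring across most of the sample cohort.

Variants are then prioritized against a local driver/actionability tier
table. Every removal is attributed to exactly one rule: the first failing
stage in the cascade order above.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .core_io import (
    CallSet,
    FilterAudit,
    FilterRule,
    ReferenceContext,
    Tier,
    TierTable,
    VariantCall,
    VariantClass,
    fetch_context,
)

__all__ = [
    "FilterConfig",
    "InsufficientContextError",
    "merge_callsets",
    "vaf_threshold_filter",
    "min_reads_filter",
    "likely_germline_loci",
    "germline_population_filter",
    "is_del_upstream_homopolymer",
    "is_ins_upstream_homopolymer",
    "is_snv_flanking_repeat",
    "is_inframe_repeat",
    "artifact_rule_filter",
    "cohort_frameshift_filter",
    "tier_prioritize",
    "run_filter_cascade",
]

#: Context window (bases each side) fetched for the repeat-rule predicates.
CONTEXT_FLANK = 60

DEFAULT_TIER_WHITELIST = frozenset({Tier.KNOWN_DRIVER, Tier.TIER1, Tier.TIER2})


class InsufficientContextError(ValueError):
    """The reference window is too small to decide a repeat-context rule."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and semantics of the filtering cascade.

    Boundary semantics are strict for removal throughout: a variant exactly at
    a threshold is retained (VAF == TF + tolerance, alt_reads == min,
    population_af == max, cohort fraction == limit all pass).

    ``vaf_mode`` selects whether ``vaf_tolerance`` is added to the tumor
    fraction (``"additive"``, a percentage-point buffer for sequencing error)
    or applied multiplicatively (``"relative"``). ``vaf_direction`` selects
    whether the threshold is an upper bound (default: VAF above what the
    tumor content supports is implausible for ctDNA) or a lower bound.
    """

    vaf_tolerance: float = 0.05
    vaf_mode: str = "additive"  # "additive" | "relative"
    vaf_direction: str = "upper"  # "upper" | "lower"
    min_alt_reads: int = 5
    max_population_af: float = 0.01
    cohort_frameshift_fraction: float = 0.60
    frameshift_cohort_scope: str = "all"  # "all" | "plasma"
    homopolymer_min_run: int = 3
    inframe_min_copies: int = 2
    germline_vaf_band: tuple = (0.40, 0.60)
    germline_high_vaf: float = 0.90
    snv_flank_mode: str = "either"  # "either" | "both"
    tier_whitelist: frozenset = DEFAULT_TIER_WHITELIST

    def __post_init__(self) -> None:
        for name in ("vaf_tolerance", "max_population_af", "cohort_frameshift_fraction"):
            x = getattr(self, name)
            if not (0 <= x <= 1.01):
                raise ValueError(f"{name} outside [0,1]")
        if self.min_alt_reads < 0:
            raise ValueError("min_alt_reads must be >= 0")
        if self.homopolymer_min_run < 2:
            raise ValueError("homopolymer_min_run must be >= 2")
        if self.vaf_mode not in ("additive", "relative"):
            raise ValueError("vaf_mode must be additive or relative")
        if self.vaf_direction not in ("upper", "lower"):
            raise ValueError("vaf_direction must be upper or lower")
        if self.snv_flank_mode not in ("either", "both"):
            raise ValueError("snv_flank_mode must be either or both")

    def vaf_threshold(self, tf: float) -> float:
        if self.vaf_mode == "additive":
            return tf + self.vaf_tolerance
        return tf * (1.0 + self.vaf_tolerance)


# ---------------------------------------------------------------------------
# Ensemble merge


def merge_callsets(a: CallSet, b: CallSet) -> CallSet:
    """Union of two callers' call sets for the same sample.

    Variants found by both callers carry both caller labels; their depths come
    from the call with the greater total depth (ties favour ``a``).
    """
    if a.sample.sample_id != b.sample.sample_id:
        raise ValueError(
            f"cannot merge call sets of different samples: {a.sample.sample_id} vs {b.sample.sample_id}"
        )
    by_locus = {v.locus: v for v in a.variants}
    merged = dict(by_locus)
    for v in b.variants:
        prev = merged.get(v.locus)
        if prev is None:
            merged[v.locus] = v
        else:
            keep, other = (prev, v) if prev.total_depth >= v.total_depth else (v, prev)
            merged[v.locus] = replace(keep, callers=prev.callers | v.callers, vaf=None)
    variants = sorted(merged.values(), key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return CallSet(
        sample=a.sample,
        variants=variants,
        provenance=f"merged[{a.provenance} + {b.provenance}]",
    )


# ---------------------------------------------------------------------------
# Threshold stages


def _audit(v: VariantCall, rule: FilterRule, detail: str) -> FilterAudit:
    return FilterAudit(
        sample_id=v.sample_id, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, rule_id=rule, detail=detail
    )


def vaf_threshold_filter(
    calls: CallSet, config: FilterConfig = FilterConfig()
) -> tuple:
    """Remove plasma calls whose VAF exceeds the sample-specific threshold.

    The threshold is the sample's known tumor fraction plus the configured
    tolerance. Tissue samples pass through unchanged. A call exactly at the
    threshold is retained.
    """
    if not calls.sample.is_plasma:
        return calls, []
    tf = calls.sample.tumor_fraction
    if tf is None:
        raise ValueError(f"plasma sample {calls.sample.sample_id} has no tumor fraction")
    threshold = config.vaf_threshold(tf)
    retained, audits = [], []
    for v in calls.variants:
        bad = v.vaf > threshold if config.vaf_direction == "upper" else v.vaf < threshold
        if bad:
            audits.append(
                _audit(v, FilterRule.VAF_THRESHOLD, f"vaf={v.vaf:.6g} threshold={threshold:.6g} tf={tf:.6g}")
            )
        else:
            retained.append(v)
    return calls.replace_variants(retained), audits


def min_reads_filter(calls: CallSet, min_alt_reads: int = 5) -> tuple:
    """Remove calls with fewer than ``min_alt_reads`` supporting reads."""
    retained, audits = [], []
    for v in calls.variants:
        if v.alt_reads < min_alt_reads:
            audits.append(_audit(v, FilterRule.MIN_ALT_READS, f"alt_reads={v.alt_reads} min={min_alt_reads}"))
        else:
            retained.append(v)
    return calls.replace_variants(retained), audits


def likely_germline_loci(cohort: Sequence[CallSet], config: FilterConfig = FilterConfig()) -> dict:
    """Identify likely germline loci per patient from cross-sample behaviour.

    A locus is flagged when it is called in *every* sample of the patient and
    its VAF sits in the heterozygous band (default [0.40, 0.60]) or at/above
    the homozygous level (default 0.90) in every sample — i.e. the allele
    fraction does not track tumor content. Returns
    ``{patient_id: set of (chrom,pos,ref,alt)}``.
    """
    lo, hi = config.germline_vaf_band
    patients: dict = {}
    for cs in cohort:
        patients.setdefault(cs.sample.patient_id, []).append(cs)
    flagged = {}
    for pid, callsets in patients.items():
        n = len(callsets)
        presence: Counter = Counter()
        band_ok: dict = {}
        for cs in callsets:
            for v in cs.variants:
                presence[v.locus] += 1
                in_band = (lo <= v.vaf <= hi) or (v.vaf >= config.germline_high_vaf)
                band_ok[v.locus] = band_ok.get(v.locus, True) and in_band
        flagged[pid] = {loc for loc, c in presence.items() if c == n and band_ok[loc]}
    return flagged


def germline_population_filter(
    calls: CallSet,
    config: FilterConfig = FilterConfig(),
    germline_loci: Optional[set] = None,
) -> tuple:
    """Remove likely germline calls and calls common in the population.

    ``germline_loci`` is the patient's flagged locus set from
    :func:`likely_germline_loci` (computed on the cascade's input cohort);
    population frequency above ``max_population_af`` (strict) removes a call,
    with unknown frequency treated as 0.
    """
    germline_loci = germline_loci or set()
    retained, audits = [], []
    for v in calls.variants:
        if v.locus in germline_loci:
            audits.append(_audit(v, FilterRule.LIKELY_GERMLINE, "locus in every patient sample at germline VAF"))
            continue
        pop = v.population_af or 0.0
        if pop > config.max_population_af:
            audits.append(
                _audit(v, FilterRule.POPULATION_AF, f"population_af={pop:.6g} max={config.max_population_af}")
            )
            continue
        retained.append(v)
    return calls.replace_variants(retained), audits


# ---------------------------------------------------------------------------
# Repeat-context artifact rules
#
# Coordinates: variants are left-anchored per VCF. For an indel at anchor
# ``pos``, the inserted sequence sits between pos and pos+1; a deleted segment
# occupies [pos+1, pos+len]. Runs are measured on the reference strand.


def _run_length_forward(ctx: ReferenceContext, start: int, max_needed: int) -> int:
    """Length of the identical-base run starting at ``start`` (capped at max_needed).

    Raises InsufficientContextError if the run reaches the window edge while
    still undecided and the window was not clipped at the chromosome end.
    """
    if start > (ctx.chrom_length or float("inf")):
        return 0
    if not ctx.covers(start):
        raise InsufficientContextError(f"context does not cover {ctx.chrom}:{start}")
    base = ctx.base(start)
    n = 1
    pos = start + 1
    while n < max_needed:
        if pos > ctx.window_end:
            if ctx.chrom_length is not None and ctx.window_end >= ctx.chrom_length:
                return n  # run terminated by the chromosome end
            raise InsufficientContextError(f"run at {ctx.chrom}:{start} extends past the context window")
        if ctx.base(pos) != base:
            return n
        n += 1
        pos += 1
    return n


def _run_length_backward(ctx: ReferenceContext, start: int, max_needed: int) -> int:
    """Length of the identical-base run ending at ``start``, scanning 5'."""
    if start < 1:
        return 0
    if not ctx.covers(start):
        raise InsufficientContextError(f"context does not cover {ctx.chrom}:{start}")
    base = ctx.base(start)
    n = 1
    pos = start - 1
    while n < max_needed:
        if pos < ctx.window_start:
            if ctx.window_start == 1:
                return n
            raise InsufficientContextError(f"run at {ctx.chrom}:{start} extends past the context window")
        if ctx.base(pos) != base:
            return n
        n += 1
        pos -= 1
    return n


def is_del_upstream_homopolymer(v: VariantCall, ctx: ReferenceContext, min_run: int = 3) -> bool:
    """Rule i: one-base deletion immediately upstream of a homopolymer run.

    True iff the base immediately 3' of the deleted base begins a run of at
    least ``min_run`` identical nucleotides.
    """
    if v.variant_class is not VariantClass.DELETION or v.indel_length != 1:
        return False
    run_start = v.pos + 2  # base after the deleted base
    if ctx.chrom_length is not None and run_start > ctx.chrom_length:
        return False
    return _run_length_forward(ctx, run_start, min_run) >= min_run


def is_ins_upstream_homopolymer(v: VariantCall, ctx: ReferenceContext, min_run: int = 3) -> bool:
    """Rule ii: one/two-base insertion immediately upstream of a homopolymer run.

    True iff the reference run starting at the base 3' of the insertion point
    has at least ``min_run`` identical nucleotides.
    """
    if v.variant_class is not VariantClass.INSERTION or v.indel_length not in (1, 2):
        return False
    run_start = v.pos + 1
    if ctx.chrom_length is not None and run_start > ctx.chrom_length:
        return False
    return _run_length_forward(ctx, run_start, min_run) >= min_run


def is_snv_flanking_repeat(
    v: VariantCall, ctx: ReferenceContext, min_run: int = 3, mode: str = "either"
) -> bool:
    """Rule iii: SNV adjacent to a homopolymer run of at least ``min_run``.

    ``mode="either"`` (default) flags a run on the 5' or the 3' flank;
    ``mode="both"`` requires runs on both flanks.
    """
    if v.variant_class is not VariantClass.SNV:
        return False
    up = _run_length_backward(ctx, v.pos - 1, min_run) if v.pos > 1 else 0
    down_start = v.pos + 1
    if ctx.chrom_length is not None and down_start > ctx.chrom_length:
        down = 0
    else:
        down = _run_length_forward(ctx, down_start, min_run)
    if mode == "both":
        return up >= min_run and down >= min_run
    return up >= min_run or down >= min_run


def _count_unit_copies_forward(ctx: ReferenceContext, start: int, unit: str, needed: int) -> int:
    n = 0
    pos = start
    while n < needed:
        end = pos + len(unit) - 1
        if ctx.chrom_length is not None and end > ctx.chrom_length:
            return n
        if pos < ctx.window_start or end > ctx.window_end:
            raise InsufficientContextError(f"repeat scan at {ctx.chrom}:{pos} exceeds the context window")
        if ctx.sequence[pos - ctx.window_start : end - ctx.window_start + 1] != unit:
            return n
        n += 1
        pos += len(unit)
    return n


def _count_unit_copies_backward(ctx: ReferenceContext, end: int, unit: str, needed: int) -> int:
    n = 0
    pos = end
    while n < needed:
        start = pos - len(unit) + 1
        if start < 1:
            return n
        if start < ctx.window_start or pos > ctx.window_end:
            raise InsufficientContextError(f"repeat scan at {ctx.chrom}:{pos} exceeds the context window")
        if ctx.sequence[start - ctx.window_start : pos - ctx.window_start + 1] != unit:
            return n
        n += 1
        pos -= len(unit)
    return n


def is_inframe_repeat(v: VariantCall, ctx: ReferenceContext, min_copies: int = 2) -> bool:
    """Rule iv: inframe indel whose unit is tandem-repeated next to the locus.

    True iff the inserted/deleted unit occurs as at least ``min_copies``
    consecutive copies immediately upstream or immediately downstream of the
    variant in the reference.
    """
    if v.variant_class is VariantClass.INSERTION:
        unit = v.alt[len(v.ref):]
        down_start = v.pos + 1
    elif v.variant_class is VariantClass.DELETION:
        unit = v.ref[len(v.alt):]
        down_start = v.pos + 1 + len(unit)
    else:
        return False
    if len(unit) == 0 or len(unit) % 3 != 0:
        return False  # frameshift, not inframe
    up = _count_unit_copies_backward(ctx, v.pos, unit, min_copies)
    if up >= min_copies:
        return True
    if ctx.chrom_length is not None and down_start > ctx.chrom_length:
        return False
    return _count_unit_copies_forward(ctx, down_start, unit, min_copies) >= min_copies


_ARTIFACT_RULES = (
    (FilterRule.DEL_UPSTREAM_HOMOPOLYMER, "deletion upstream of homopolymer"),
    (FilterRule.INS_UPSTREAM_HOMOPOLYMER, "insertion upstream of homopolymer"),
    (FilterRule.SNV_FLANKING_REPEAT, "SNV flanking homopolymer"),
    (FilterRule.INFRAME_REPEAT, "inframe indel of tandem-repeated unit"),
)


def classify_artifact(v: VariantCall, ctx: ReferenceContext, config: FilterConfig) -> Optional[FilterRule]:
    """First repeat-context rule (i-iv) matched by ``v``, or None."""
    mr = config.homopolymer_min_run
    if is_del_upstream_homopolymer(v, ctx, mr):
        return FilterRule.DEL_UPSTREAM_HOMOPOLYMER
    if is_ins_upstream_homopolymer(v, ctx, mr):
        return FilterRule.INS_UPSTREAM_HOMOPOLYMER
    if is_snv_flanking_repeat(v, ctx, mr, config.snv_flank_mode):
        return FilterRule.SNV_FLANKING_REPEAT
    if is_inframe_repeat(v, ctx, config.inframe_min_copies):
        return FilterRule.INFRAME_REPEAT
    return None


def artifact_rule_filter(calls: CallSet, reference, config: FilterConfig = FilterConfig()) -> tuple:
    """Apply repeat-context rules i-iv to every call, removing matches."""
    retained, audits = [], []
    for v in calls.variants:
        ctx = fetch_context(reference, v.chrom, v.pos, CONTEXT_FLANK)
        rule = classify_artifact(v, ctx, config)
        if rule is None:
            retained.append(v)
        else:
            audits.append(_audit(v, rule, f"min_run={config.homopolymer_min_run}"))
    return calls.replace_variants(retained), audits


# ---------------------------------------------------------------------------
# Cohort-level frameshift rule (v)


def cohort_frameshift_filter(
    cohort: Sequence[CallSet], config: FilterConfig = FilterConfig()
) -> tuple:
    """Rule v: remove frameshifts recurring in more than the cohort fraction.

    A frameshift identity present in strictly more than
    ``cohort_frameshift_fraction`` of the in-scope samples (all samples by
    default, plasma-only via config) is removed from every sample. Returns
    ``(filtered cohort list, audits)``.
    """
    if len(cohort) < 2:
        raise ValueError("cohort frameshift filter requires at least 2 samples")
    if config.frameshift_cohort_scope == "plasma":
        scope = [cs for cs in cohort if cs.sample.is_plasma]
    else:
        scope = list(cohort)
    n_scope = len(scope)
    counts: Counter = Counter()
    for cs in scope:
        for v in cs.variants:
            if v.is_frameshift:
                counts[v.locus] += 1
    recurrent = {
        loc for loc, c in counts.items() if n_scope > 0 and c / n_scope > config.cohort_frameshift_fraction
    }
    out, audits = [], []
    for cs in cohort:
        kept = []
        for v in cs.variants:
            if v.is_frameshift and v.locus in recurrent:
                audits.append(
                    _audit(
                        v,
                        FilterRule.COHORT_FRAMESHIFT,
                        f"in {counts[v.locus]}/{n_scope} samples (> {config.cohort_frameshift_fraction:.2f})",
                    )
                )
            else:
                kept.append(v)
        out.append(cs.replace_variants(kept))
    return out, audits


# ---------------------------------------------------------------------------
# Prioritization


def tier_prioritize(
    calls: CallSet, tier_table: TierTable, whitelist: frozenset = DEFAULT_TIER_WHITELIST
) -> CallSet:
    """Assign tiers from the local lookup and keep only whitelisted tiers.

    Unmatched variants get tier ``none`` and fall outside the pathogenic set.
    """
    kept = []
    for v in calls.variants:
        tier = tier_table.tier_of(v)
        if tier in whitelist:
            kept.append(replace(v, tier=tier))
    return calls.replace_variants(kept, provenance=calls.provenance + "|tiered")


# ---------------------------------------------------------------------------
# Cascade


@dataclass
class CascadeResult:
    """Filtered cohort plus the complete removal audit."""

    callsets: list
    audits: list = field(default_factory=list)

    def audits_for(self, sample_id: str) -> list:
        return [a for a in self.audits if a.sample_id == sample_id]


def run_filter_cascade(
    cohort: Sequence[CallSet],
    reference,
    config: FilterConfig = FilterConfig(),
) -> CascadeResult:
    """Run the full cascade over a merged cohort.

    Stage order is fixed: VAF threshold → supporting reads → germline /
    population → repeat-context rules i-iv → cohort frameshift rule v. The
    likely-germline locus sets are computed on the cascade *input* (so that a
    germline allele suppressed by an earlier stage in one sample still counts
    as present there). Conservation holds per sample:
    ``len(input) == len(retained) + number of audit rows``.
    """
    cohort = list(cohort)
    if not cohort:
        return CascadeResult(callsets=[])
    germline = likely_germline_loci(cohort, config)
    staged, audits = [], []
    for cs in cohort:
        cur, a = vaf_threshold_filter(cs, config)
        audits.extend(a)
        cur, a = min_reads_filter(cur, config.min_alt_reads)
        audits.extend(a)
        cur, a = germline_population_filter(cur, config, germline.get(cs.sample.patient_id))
        audits.extend(a)
        cur, a = artifact_rule_filter(cur, reference, config)
        audits.extend(a)
        staged.append(cur)
    if len(staged) >= 2:
        staged, a = cohort_frameshift_filter(staged, config)
        audits.extend(a)
    for before, after in zip(cohort, staged):
        n_removed = sum(1 for x in audits if x.sample_id == before.sample.sample_id)
        if len(before) != len(after) + n_removed:  # pragma: no cover - internal invariant
            raise AssertionError(f"conservation violated for {before.sample.sample_id}")
    return CascadeResult(callsets=staged, audits=audits)
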