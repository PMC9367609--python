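"""Spatial and temporal heterogeneity statistics on filtered call sets.

Variants are matched across samples by a :class:`VariantKey` — locus, base
change and consequence annotation. Spatial heterogeneity compares the
diagnostic plasma sample against the patient's synchronous tumor biopsies;
temporal heterogeneity compares plasma samples across timepoints via the
Jaccard score. The tumor molecular burden (TMB) is the count of retained
nonsynonymous variant keys per sample.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import CallSet, VariantCall

__all__ = [
    "VariantKey",
    "variant_key",
    "key_set",
    "ConcordancePartition",
    "JaccardMatrix",
    "TmbSeries",
    "NONSYNONYMOUS_TERMS",
    "nonsynonymous_subset",
    "jaccard",
    "jaccard_matrix",
    "concordance_pct",
    "classify_spatial",
    "compute_tmb",
    "correlate_tmb_tf",
]


class VariantKey(NamedTuple):
    """Cross-sample matching key: same locus, base change and annotation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str


def variant_key(v: VariantCall) -> VariantKey:
    return VariantKey(v.chrom, v.pos, v.ref, v.alt, v.consequence)


def key_set(calls: CallSet) -> set:
    keys = {variant_key(v) for v in calls.variants}
    # CallSet uniqueness is on the locus; a locus carrying two consequence
    # strings across callers would silently double here, so flag it.
    if len(keys) != len(calls.variants):
        warnings.warn(f"sample {calls.sample.sample_id}: same locus with differing annotations")
    return keys


#: VEP consequence terms counted as nonsynonymous (matched against
#: ampersand-separated compound consequence strings).
NONSYNONYMOUS_TERMS = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "protein_altering_variant",
    }
)


def nonsynonymous_subset(calls: CallSet, terms: frozenset = NONSYNONYMOUS_TERMS) -> CallSet:
    """Restrict a call set to nonsynonymous consequences.

    Unknown consequences are conservatively excluded (with a warning).
    """
    kept = []
    for v in calls.variants:
        if v.consequence == "unknown":
            warnings.warn(f"excluding variant with unknown consequence at {v.chrom}:{v.pos}")
            continue
        if terms.intersection(v.consequence.split("&")):
            kept.append(v)
    return calls.replace_variants(kept)


# ---------------------------------------------------------------------------
# Jaccard / concordance


def jaccard(a: set, b: set) -> float:
    """Jaccard score |a ∩ b| / |a ∪ b|; defined as 0 when the union is empty."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class JaccardMatrix:
    """Pairwise Jaccard scores between one patient's samples."""

    patient_id: str
    sample_ids: list
    matrix: np.ndarray

    def max_offdiagonal(self) -> float:
        n = len(self.sample_ids)
        if n < 2:
            return 0.0
        mask = ~np.eye(n, dtype=bool)
        return float(self.matrix[mask].max())

    def to_rows(self) -> list:
        rows = []
        for i, a in enumerate(self.sample_ids):
            for j, b in enumerate(self.sample_ids):
                if i < j:
                    rows.append(
                        {
                            "patient_id": self.patient_id,
                            "sample_a": a,
                            "sample_b": b,
                            "jaccard": self.matrix[i, j],
                        }
                    )
        return rows


def jaccard_matrix(samples: Sequence[CallSet]) -> JaccardMatrix:
    """Pairwise Jaccard matrix over the samples' variant-key sets.

    The diagonal is 1 for nonempty call sets (0 for empty ones, where the
    score is undefined and pinned to 0).
    """
    if len(samples) < 2:
        raise ValueError("jaccard_matrix requires at least 2 samples")
    patient = samples[0].sample.patient_id
    sets = [key_set(cs) for cs in samples]
    n = len(sets)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            m[i, j] = m[j, i] = jaccard(sets[i], sets[j])
    return JaccardMatrix(patient_id=patient, sample_ids=[cs.sample.sample_id for cs in samples], matrix=m)


def concordance_pct(set_a, set_b, denominator: str = "union") -> float:
    """Concordance between two call sets as a percentage.

    ``denominator`` chooses the normalisation: ``"union"`` (Jaccard, default),
    ``"a"`` or ``"b"`` (overlap over one set's size). Two empty sets give 0
    with a warning.
    """
    a = key_set(set_a) if isinstance(set_a, CallSet) else set(set_a)
    b = key_set(set_b) if isinstance(set_b, CallSet) else set(set_b)
    if not a and not b:
        warnings.warn("concordance of two empty call sets defined as 0")
        return 0.0
    inter = len(a & b)
    if denominator == "union":
        denom = len(a | b)
    elif denominator == "a":
        denom = len(a)
    elif denominator == "b":
        denom = len(b)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        return 0.0
    return 100.0 * inter / denom


# ---------------------------------------------------------------------------
# Spatial classification


@dataclass
class ConcordancePartition:
    """Per-patient assignment of every variant key to private/shared/common.

    - private: key present in exactly one sample (plasma or tissue);
    - shared: key present in more than one sample, including the plasma sample
      and at most one biopsy;
    - common: key present in the plasma sample and at least two biopsies
      (takes precedence over shared).

    Keys present in several biopsies but absent from plasma are multi-sample
    without plasma support and are assigned to ``shared`` so that the three
    classes partition the key universe.
    """

    patient_id: str
    assignments: dict = field(default_factory=dict)  # VariantKey -> class str
    pair_concordance: dict = field(default_factory=dict)  # (plasma_id, tissue_id) -> pct

    @property
    def counts(self) -> dict:
        c = Counter(self.assignments.values())
        return {k: c.get(k, 0) for k in ("private", "shared", "common")}

    @property
    def fractions(self) -> dict:
        total = len(self.assignments)
        if total == 0:
            return {k: 0.0 for k in ("private", "shared", "common")}
        return {k: v / total for k, v in self.counts.items()}

    @property
    def total_keys(self) -> int:
        return len(self.assignments)


def classify_spatial(
    plasma: CallSet, tissues: Sequence[CallSet], denominator: str = "union"
) -> ConcordancePartition:
    """Partition a patient's variant keys against the matched biopsies.

    Requires exactly one plasma call set (the analysed timepoint, typically
    T0) and at least one tissue biopsy. Also reports the plasma-vs-biopsy
    concordance percentage for every biopsy.
    """
    if not tissues:
        raise ValueError("spatial classification requires at least one tissue biopsy")
    if not plasma.sample.is_plasma:
        raise ValueError(f"{plasma.sample.sample_id} is not a plasma sample")
    plasma_keys = key_set(plasma)
    tissue_keys = [key_set(t) for t in tissues]
    universe = set(plasma_keys).union(*tissue_keys) if tissue_keys else set(plasma_keys)
    assignments = {}
    for k in universe:
        n_biopsies = sum(k in tk for tk in tissue_keys)
        n_samples = n_biopsies + (k in plasma_keys)
        if n_samples == 1:
            assignments[k] = "private"
        elif k in plasma_keys and n_biopsies >= 2:
            assignments[k] = "common"
        else:
            assignments[k] = "shared"
    pair = {
        (plasma.sample.sample_id, t.sample.sample_id): concordance_pct(plasma_keys, tk, denominator)
        for t, tk in zip(tissues, tissue_keys)
    }
    return ConcordancePartition(
        patient_id=plasma.sample.patient_id, assignments=assignments, pair_concordance=pair
    )


# ---------------------------------------------------------------------------
# Tumor molecular burden


@dataclass
class TmbSeries:
    """Per-plasma-sample TMB values paired with tumor fractions."""

    sample_ids: list
    tmb: list
    tumor_fraction: list


def compute_tmb(calls: CallSet) -> int:
    """Tumor molecular burden: number of distinct retained variant keys.

    The call set is expected to be post-cascade and nonsynonymous-restricted.
    """
    return len(key_set(calls))


def correlate_tmb_tf(series: TmbSeries) -> tuple:
    """Pearson correlation between TMB and tumor fraction with two-sided p.

    Returns ``(nan, nan)`` when either series is constant (the coefficient is
    undefined there, not zero). Requires at least 3 paired observations.
    """
    x = np.asarray(series.tmb, dtype=float)
    y = np.asarray(series.tumor_fraction, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired (TMB, TF) observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return (float(r), float(p))
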