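"""Molecular-recurrence calling and therapy-relevant variant dynamics.

Molecular recurrence (TRm) is called from the longitudinal tumor-fraction
trajectory: the first timepoint whose TF rises by at least 20% relative to
the previous point. Driver persistence classifies each pathogenic variant key
by its presence pattern across timepoints. The TP53BP1 scenario logic
formalises the clinically relevant co-occurrence of BRCA1/2 variants with
TP53BP1 variants (a characterised PARP-inhibitor resistance mechanism):
TP53BP1 "loss" is proxied by the presence of pathogenic TP53BP1 variants, as
no copy-number calls are made.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core_io import CallSet, Tier, TierTable
from .heterogeneity import VariantKey, key_set, variant_key

__all__ = [
    "TfTrajectory",
    "ScenarioReport",
    "call_trm",
    "driver_persistence",
    "tp53bp1_scenario",
    "actionability_summary",
    "BASELINE_TIMEPOINTS",
    "RELAPSE_TIMEPOINTS",
]

BASELINE_TIMEPOINTS = frozenset({"T0", "T1"})
RELAPSE_TIMEPOINTS = frozenset({"TRm", "TRc"})

BRCA_GENES = frozenset({"BRCA1", "BRCA2"})


@dataclass(frozen=True)
class TfTrajectory:
    """Chronologically ordered (timepoint label, tumor fraction) series."""

    patient_id: str
    points: tuple  # tuple of (label, tf)

    def __post_init__(self) -> None:
        for label, tf in self.points:
            if not (0 <= tf <= 1):
                raise ValueError(f"tumor fraction {tf} outside [0,1] at {label}")

    @property
    def labels(self) -> tuple:
        return tuple(lab for lab, _ in self.points)

    @property
    def values(self) -> tuple:
        return tuple(tf for _, tf in self.points)


def call_trm(
    traj: TfTrajectory,
    threshold: float = 0.20,
    mode: str = "relative",
    min_absolute_tf: float = 0.0,
) -> Optional[str]:
    """First timepoint with a tumor-fraction increase calling molecular recurrence.

    ``mode="relative"`` (default) calls timepoint *t* when
    ``TF(t) >= TF(t-1) * (1 + threshold)``; an increase from TF = 0 to any
    positive TF is called (the relative increase is undefined, but the
    appearance of ctDNA signal is a fortiori recurrence), optionally gated by
    ``min_absolute_tf``. ``mode="absolute"`` uses a percentage-point increase:
    ``TF(t) >= TF(t-1) + threshold``. Returns the timepoint label, or None.
    """
    if len(traj.points) < 2:
        raise ValueError("TRm calling requires at least 2 trajectory points")
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    for (_, prev), (label, cur) in zip(traj.points, traj.points[1:]):
        if mode == "relative":
            if prev == 0:
                hit = cur > 0 and cur >= min_absolute_tf
            else:
                hit = cur >= prev * (1.0 + threshold)
        else:
            hit = cur >= prev + threshold
        if hit:
            return label
    return None


def trm_index(traj: TfTrajectory, **kwargs) -> Optional[int]:
    """Index (into the trajectory) of the called TRm point, or None."""
    label = call_trm(traj, **kwargs)
    if label is None:
        return None
    return traj.labels.index(label)


# ---------------------------------------------------------------------------
# Driver persistence


def driver_persistence(timeline: Sequence[CallSet]) -> dict:
    """Classify each variant key by its presence pattern across timepoints.

    ``timeline`` is the patient's retained pathogenic call sets in
    chronological order. Classes partition the key universe:

    - truncal: present at every timepoint;
    - lost: present at the first timepoint, absent at the last;
    - acquired: absent at the first timepoint, present at the last;
    - transient: everything else (present only at interior timepoints, or
      present at both ends with an interior gap).

    Returns ``{VariantKey: {"pattern": tuple of bool, "class": str}}``.
    """
    if len(timeline) < 2:
        raise ValueError("driver persistence requires at least 2 timepoints")
    sets = [key_set(cs) for cs in timeline]
    universe = set().union(*sets)
    out = {}
    for k in sorted(universe):
        pattern = tuple(k in s for s in sets)
        if all(pattern):
            cls = "truncal"
        elif pattern[0] and not pattern[-1]:
            cls = "lost"
        elif not pattern[0] and pattern[-1]:
            cls = "acquired"
        else:
            cls = "transient"
        out[k] = {"pattern": pattern, "class": cls}
    return out


# ---------------------------------------------------------------------------
# TP53BP1 / BRCA scenario logic


@dataclass
class ScenarioReport:
    """Per-patient TP53BP1 dynamics and PARPi-resistance co-occurrence flag."""

    patient_id: str
    brca_status: str  # germline_mut | somatic_mut | wt | unknown
    scenario: str  # mutated_at_baseline_lost | acquired_at_relapse | persistent | never | mixed
    tp53bp1_timeline: dict = field(default_factory=dict)  # timepoint -> set of VariantKey
    parpi_resistance_flag: bool = False
    flag_timepoints: tuple = ()


def _gene_keys(calls: CallSet, genes: frozenset) -> set:
    return {variant_key(v) for v in calls.variants if v.gene.upper() in genes}


def tp53bp1_scenario(
    timeline: Sequence[CallSet],
    brca_status: str = "unknown",
    gene: str = "TP53BP1",
    baseline_labels: frozenset = BASELINE_TIMEPOINTS,
    relapse_labels: frozenset = RELAPSE_TIMEPOINTS,
) -> ScenarioReport:
    """Classify the temporal pattern of pathogenic TP53BP1 variants.

    The timeline holds the patient's retained pathogenic plasma call sets.
    With baseline = T0/T1 and relapse = TRm/TRc key sets:

    - never: no TP53BP1 key at any timepoint;
    - mutated_at_baseline_lost: baseline keys, none surviving to or appearing
      at relapse;
    - acquired_at_relapse: novel keys at relapse, none lost from baseline;
    - persistent: keys present with no losses and no gains;
    - mixed: both lost baseline keys and novel relapse keys.

    The PARPi-resistance flag is set only when a BRCA1/2 variant and at least
    one TP53BP1 variant co-occur in the same sample's retained call set.
    """
    genes = frozenset({gene.upper()})
    per_tp: dict = {}
    flag_tps = []
    for cs in timeline:
        tp = cs.sample.timepoint
        keys = _gene_keys(cs, genes)
        per_tp[tp] = per_tp.get(tp, set()) | keys
        if keys and _gene_keys(cs, BRCA_GENES):
            flag_tps.append(tp)
    baseline = set().union(*(per_tp.get(t, set()) for t in baseline_labels)) if per_tp else set()
    relapse = set().union(*(per_tp.get(t, set()) for t in relapse_labels)) if per_tp else set()
    lost = baseline - relapse
    acquired = relapse - baseline
    if not baseline and not relapse:
        scenario = "never"
    elif lost and acquired:
        scenario = "mixed"
    elif acquired:
        scenario = "acquired_at_relapse"
    elif lost:
        scenario = "mutated_at_baseline_lost"
    else:
        scenario = "persistent"
    patient = timeline[0].sample.patient_id if timeline else ""
    return ScenarioReport(
        patient_id=patient,
        brca_status=brca_status,
        scenario=scenario,
        tp53bp1_timeline=per_tp,
        parpi_resistance_flag=bool(flag_tps),
        flag_timepoints=tuple(flag_tps),
    )


# ---------------------------------------------------------------------------
# Actionability


_PROTEIN_POS = re.compile(r"p\.\(?([A-Za-z*]{1,3})(\d+)")


def _protein_position(hgvs_p: Optional[str]) -> Optional[int]:
    if not hgvs_p:
        return None
    m = _PROTEIN_POS.search(hgvs_p)
    return int(m.group(2)) if m else None


def actionability_summary(timeline: Sequence[CallSet], tier_table: TierTable) -> list:
    """Per-timepoint table of tier-assigned variants with associated therapies.

    Emits lolliplot-ready rows (gene, protein position, amino-acid change,
    sample, tier, therapies); variants without a tier-table match are
    excluded, and a variant without protein-position annotation is included
    with a blank position.
    """
    rows = []
    for cs in timeline:
        for v in cs.variants:
            tier = v.tier if v.tier is not Tier.UNASSIGNED else tier_table.tier_of(v)
            if tier in (Tier.NONE, Tier.UNASSIGNED):
                continue
            pos = _protein_position(v.hgvs_p)
            rows.append(
                {
                    "patient_id": v.patient_id,
                    "sample_id": v.sample_id,
                    "timepoint": cs.sample.timepoint,
                    "gene": v.gene,
                    "hgvs_c": v.hgvs_c or "",
                    "aa_change": v.hgvs_p or "",
                    "protein_pos": "" if pos is None else pos,
                    "tier": tier.value,
                    "therapies": tier_table.therapies_of(v),
                }
            )
    return rows
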