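"""Domain types and file I/O for the ctDNA heterogeneity pipeline.

The pipeline consumes somatic variant call sets (VCF 4.x, one per caller per
sample), a cohort sample sheet (TSV), a reference sequence (FASTA) and a local
actionability tier table (TSV). All coordinates are 1-based inclusive and
indels are left-anchored, following the VCF convention; multi-allelic records
are split and no further normalisation is applied.
"""

from __future__ import annotations

import csv
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import pysam

__all__ = [
    "VariantClass",
    "Tier",
    "FilterRule",
    "VariantCall",
    "SampleRecord",
    "CallSet",
    "ReferenceContext",
    "FilterAudit",
    "AnnotationSpec",
    "TierTable",
    "classify_alleles",
    "read_vcf",
    "write_vcf",
    "read_sample_sheet",
    "write_sample_sheet",
    "fetch_context",
    "write_table",
    "load_tier_table",
]

_DNA = frozenset("ACGT")

#: Canonical chronological order of the plasma timepoint labels.
TIMEPOINT_ORDER = ("T0", "T1", "TRm", "TRc")


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    MNV = "MNV"


class Tier(str, Enum):
    """Driver/actionability confidence tier from the local lookup table."""

    KNOWN_DRIVER = "known_driver"
    TIER1 = "tier1"
    TIER2 = "tier2"
    NONE = "none"
    UNASSIGNED = "unassigned"


class FilterRule(str, Enum):
    """Identifier of the cascade rule that removed a variant."""

    VAF_THRESHOLD = "vaf_threshold"
    MIN_ALT_READS = "min_alt_reads"
    LIKELY_GERMLINE = "likely_germline"
    POPULATION_AF = "population_af"
    DEL_UPSTREAM_HOMOPOLYMER = "del_upstream_homopolymer"
    INS_UPSTREAM_HOMOPOLYMER = "ins_upstream_homopolymer"
    SNV_FLANKING_REPEAT = "snv_flanking_repeat"
    INFRAME_REPEAT = "inframe_repeat"
    COHORT_FRAMESHIFT = "cohort_frameshift"


def classify_alleles(ref: str, alt: str) -> VariantClass:
    """Classify a REF/ALT pair as SNV, insertion, deletion or MNV."""
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(alt) > len(ref):
        return VariantClass.INSERTION
    if len(alt) < len(ref):
        return VariantClass.DELETION
    return VariantClass.MNV


@dataclass
class VariantCall:
    """One normalised somatic call from one sample.

    ``pos`` is 1-based; for indels it is the anchor base shared by REF and
    ALT. ``vaf`` is ``alt_reads / total_depth``; ``population_af`` is the
    general-population allele frequency (``None`` when unknown). ``callers``
    records ensemble provenance.
    """

    patient_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    total_depth: int
    consequence: str = "unknown"
    gene: str = ""
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    vaf: Optional[float] = None
    population_af: Optional[float] = None
    callers: frozenset = frozenset({"callerA"})
    tier: Tier = Tier.UNASSIGNED
    variant_class: Optional[VariantClass] = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if not (_DNA.issuperset(self.ref) and _DNA.issuperset(self.alt)):
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError("pos must be 1-based positive")
        if self.total_depth <= 0:
            raise ValueError(f"total_depth must be positive at {self.chrom}:{self.pos}")
        if not (0 <= self.alt_reads <= self.total_depth):
            raise ValueError(f"alt_reads outside [0, total_depth] at {self.chrom}:{self.pos}")
        computed = self.alt_reads / self.total_depth
        if self.vaf is None:
            self.vaf = computed
        elif abs(self.vaf - computed) > 1e-9:
            raise ValueError(f"vaf inconsistent with allele depths at {self.chrom}:{self.pos}")
        if self.population_af is not None and not (0 <= self.population_af <= 1):
            raise ValueError("population_af outside [0,1]")
        if not self.callers:
            raise ValueError("callers must be non-empty")
        self.callers = frozenset(self.callers)
        inferred = classify_alleles(self.ref, self.alt)
        if self.variant_class is None:
            self.variant_class = inferred
        elif self.variant_class is not inferred:
            raise ValueError(
                f"variant_class {self.variant_class} inconsistent with alleles at {self.chrom}:{self.pos}"
            )

    @property
    def locus(self) -> tuple:
        """Identity triple used for merging and deduplication."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_frameshift(self) -> bool:
        """Indel whose length is not a multiple of three (or annotated so)."""
        if "frameshift" in self.consequence:
            return True
        return self.variant_class in (VariantClass.INSERTION, VariantClass.DELETION) and (
            self.indel_length % 3 != 0
        )


@dataclass
class SampleRecord:
    """Identity and context of one sequenced sample.

    Tissue samples carry a biopsy label (A, B, C, ...); plasma samples carry a
    timepoint label (T0/T1/TRm/TRc) and the externally estimated tumor
    fraction of the cfDNA.
    """

    sample_id: str
    patient_id: str
    sample_type: str  # "tissue" | "plasma"
    timepoint: str
    tumor_fraction: Optional[float] = None
    collection_order: int = 0

    def __post_init__(self) -> None:
        if self.sample_type not in ("tissue", "plasma"):
            raise ValueError(f"unknown sample_type {self.sample_type!r} for {self.sample_id}")
        if self.sample_type == "plasma":
            if self.tumor_fraction is None:
                raise ValueError(f"plasma sample {self.sample_id} requires a tumor_fraction")
            if not (0 <= self.tumor_fraction <= 1):
                raise ValueError(f"tumor_fraction outside [0,1] for {self.sample_id}")

    @property
    def is_plasma(self) -> bool:
        return self.sample_type == "plasma"


@dataclass
class CallSet:
    """All variant calls of one sample at one pipeline stage."""

    sample: SampleRecord
    variants: list = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for v in self.variants:
            if v.locus in seen:
                raise ValueError(f"duplicate variant {v.locus} in {self.sample.sample_id}")
            seen.add(v.locus)

    def __len__(self) -> int:
        return len(self.variants)

    def loci(self) -> set:
        return {v.locus for v in self.variants}

    def replace_variants(self, variants: Iterable, provenance: Optional[str] = None) -> "CallSet":
        return CallSet(
            sample=self.sample,
            variants=list(variants),
            provenance=self.provenance if provenance is None else provenance,
        )


@dataclass(frozen=True)
class ReferenceContext:
    """A reference window around a variant, 1-based inclusive coordinates.

    ``chrom_length`` (when known) lets repeat-rule predicates distinguish a
    window clipped at a chromosome end (run genuinely terminates) from a
    window that is simply too small (insufficient context).
    """

    chrom: str
    window_start: int
    sequence: str
    chrom_length: Optional[int] = None

    @property
    def window_end(self) -> int:
        return self.window_start + len(self.sequence) - 1

    def covers(self, pos: int) -> bool:
        return self.window_start <= pos <= self.window_end

    def base(self, pos: int) -> str:
        if not self.covers(pos):
            raise IndexError(f"position {pos} outside context window {self.window_start}-{self.window_end}")
        return self.sequence[pos - self.window_start]


@dataclass(frozen=True)
class FilterAudit:
    """Why one variant was removed: the first failing rule of the cascade."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    rule_id: FilterRule
    detail: str = ""


# ---------------------------------------------------------------------------
# Annotation handling


@dataclass(frozen=True)
class AnnotationSpec:
    """Layout of the consequence annotation INFO field (VEP-style CSQ).

    ``fields`` names the pipe-delimited sub-fields in order; the defaults
    match the VCFs written by this package's simulator. ``population_af_field``
    selects which sub-field carries the general-population allele frequency.
    """

    info_key: str = "CSQ"
    fields: tuple = ("Consequence", "SYMBOL", "HGVSc", "HGVSp", "gnomAD_AF")
    population_af_field: str = "gnomAD_AF"

    def format_description(self) -> str:
        return "Consequence annotations. Format: " + "|".join(self.fields)

    def encode(self, values: Mapping[str, str]) -> str:
        return "|".join(str(values.get(f, "")) for f in self.fields)

    def decode(self, entry: str) -> dict:
        parts = entry.split("|")
        return {f: (parts[i] if i < len(parts) else "") for i, f in enumerate(self.fields)}


DEFAULT_ANNOTATION = AnnotationSpec()


# ---------------------------------------------------------------------------
# VCF I/O


def _vcf_header(contigs: Mapping[str, int], sample_id: str, annotation: AnnotationSpec) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add(annotation.info_key, ".", "String", annotation.format_description())
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.filters.add("removed", None, None, "Removed by the filtering cascade")
    header.add_sample(sample_id)
    return header


def write_vcf(
    callset: CallSet,
    path: Union[str, Path],
    contigs: Mapping[str, int],
    annotation: AnnotationSpec = DEFAULT_ANNOTATION,
    flagged: Optional[Mapping[tuple, str]] = None,
) -> None:
    """Write a call set as single-sample VCF 4.2.

    ``flagged`` optionally maps variant identity tuples to a FILTER label
    (used to keep cascade-removed variants in the output instead of dropping
    them).
    """
    path = Path(path)
    sample_id = callset.sample.sample_id
    header = _vcf_header(contigs, sample_id, annotation)
    if flagged:
        for label in sorted(set(flagged.values())):
            if label not in header.filters:
                header.filters.add(label, None, None, f"Removed by cascade rule {label}")
    ordered = sorted(callset.variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            csq = annotation.encode(
                {
                    "Consequence": v.consequence,
                    "SYMBOL": v.gene,
                    "HGVSc": v.hgvs_c or "",
                    "HGVSp": v.hgvs_p or "",
                    annotation.population_af_field: (
                        "" if v.population_af is None else repr(float(v.population_af))
                    ),
                }
            )
            rec.info[annotation.info_key] = (csq,)
            if flagged and v.locus in flagged:
                rec.filter.add(flagged[v.locus])
            else:
                rec.filter.add("PASS")
            rec.samples[sample_id]["GT"] = (0, 1)
            rec.samples[sample_id]["AD"] = (v.total_depth - v.alt_reads, v.alt_reads)
            rec.samples[sample_id]["DP"] = v.total_depth
            out.write(rec)


def read_vcf(
    path: Union[str, Path],
    sample: SampleRecord,
    annotation: AnnotationSpec = DEFAULT_ANNOTATION,
    caller: str = "callerA",
    vcf_sample: Optional[str] = None,
) -> CallSet:
    """Read a VCF into a :class:`CallSet`, one call per ALT allele.

    Multi-allelic records are split; VAF is computed from the AD/DP genotype
    fields; the population allele frequency is taken from the annotation block
    when present. A record whose annotation cannot be parsed is kept with
    consequence ``"unknown"`` and a warning.
    """
    path = Path(path)
    variants = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        name = vcf_sample or sample.sample_id
        if name not in vcf_samples:
            if len(vcf_samples) == 1 and vcf_sample is None:
                name = vcf_samples[0]
            else:
                raise ValueError(f"sample column {name!r} not found in {path} (has {vcf_samples})")
        for rec in vf:
            fmt = rec.samples[name]
            ad = fmt.get("AD")
            if ad is None or any(x is None for x in ad):
                raise ValueError(f"record {rec.chrom}:{rec.pos} in {path} lacks allele depths (AD)")
            dp = fmt.get("DP")
            total = int(dp) if dp is not None else int(sum(ad))
            csq_entries = rec.info.get(annotation.info_key)
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                ann = {}
                if csq_entries:
                    # one entry per ALT in order; fall back to the first entry
                    entry = csq_entries[i] if i < len(csq_entries) else csq_entries[0]
                    try:
                        ann = annotation.decode(entry)
                    except Exception:  # pragma: no cover - defensive
                        warnings.warn(f"unparsable annotation at {rec.chrom}:{rec.pos}; kept as unknown")
                        ann = {}
                elif annotation.info_key in DEFAULT_ANNOTATION.info_key:
                    warnings.warn(f"no {annotation.info_key} annotation at {rec.chrom}:{rec.pos}")
                pop_raw = ann.get(annotation.population_af_field, "")
                pop_af = float(pop_raw) if pop_raw not in ("", None, ".") else None
                variants.append(
                    VariantCall(
                        patient_id=sample.patient_id,
                        sample_id=sample.sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        alt_reads=int(ad[i + 1]),
                        total_depth=total,
                        consequence=ann.get("Consequence") or "unknown",
                        gene=ann.get("SYMBOL", "") or "",
                        hgvs_c=ann.get("HGVSc") or None,
                        hgvs_p=ann.get("HGVSp") or None,
                        population_af=pop_af,
                        callers=frozenset({caller}),
                    )
                )
    return CallSet(sample=sample, variants=variants, provenance=f"read_vcf:{path.name}:{caller}")


# ---------------------------------------------------------------------------
# Sample sheet


_SHEET_COLUMNS = ("sample_id", "patient_id", "sample_type", "timepoint", "tumor_fraction")


def read_sample_sheet(path: Union[str, Path]) -> list:
    """Read the cohort sample sheet (TSV with header) into SampleRecords.

    When a ``collection_order`` column is absent, tissue samples rank first
    within a patient and plasma samples follow the canonical T0 < T1 < TRm <
    TRc order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample_id in sheet: {sorted(set(dup))}")
    records = []
    for _, row in df.iterrows():
        tf = row["tumor_fraction"]
        tf = None if pd.isna(tf) else float(tf)
        order = int(row["collection_order"]) if "collection_order" in df.columns else _default_order(row)
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
                sample_type=str(row["sample_type"]),
                timepoint=str(row["timepoint"]),
                tumor_fraction=tf,
                collection_order=order,
            )
        )
    return records


def _default_order(row) -> int:
    if row["sample_type"] == "tissue":
        return 0
    tp = str(row["timepoint"])
    return 1 + (TIMEPOINT_ORDER.index(tp) if tp in TIMEPOINT_ORDER else len(TIMEPOINT_ORDER))


def write_sample_sheet(records: Sequence[SampleRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "patient_id": r.patient_id,
            "sample_type": r.sample_type,
            "timepoint": r.timepoint,
            "tumor_fraction": "" if r.tumor_fraction is None else r.tumor_fraction,
            "collection_order": r.collection_order,
        }
        for r in records
    ]
    write_table(rows, path, key_columns=("patient_id", "collection_order", "sample_id"))


# ---------------------------------------------------------------------------
# Reference access


def fetch_context(reference, chrom: str, pos: int, flank: int) -> ReferenceContext:
    """Fetch the reference window ``[pos - flank, pos + flank]``.

    ``reference`` may be a :class:`pyfaidx.Fasta` (or anything whose
    ``__getitem__`` returns a sliceable with ``str()``) or a plain mapping of
    chromosome name to sequence string. The window is clipped at chromosome
    ends; ``window_start`` records the clip.
    """
    if flank < 1:
        raise ValueError("flank must be positive")
    if isinstance(reference, Mapping):
        if chrom not in reference:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = reference[chrom]
        length = len(seq)
        getter = lambda s, e: seq[s - 1 : e]  # noqa: E731
    else:
        if chrom not in reference.keys():
            raise KeyError(f"unknown chromosome {chrom!r}")
        record = reference[chrom]
        length = len(record)
        getter = lambda s, e: str(record[s - 1 : e])  # noqa: E731
    if not (1 <= pos <= length):
        raise ValueError(f"position {pos} outside {chrom} (length {length})")
    start = max(1, pos - flank)
    end = min(length, pos + flank)
    return ReferenceContext(
        chrom=chrom, window_start=start, sequence=getter(start, end).upper(), chrom_length=length
    )


# ---------------------------------------------------------------------------
# Tabular output


def write_table(rows, path: Union[str, Path], key_columns: Sequence[str] = ()) -> None:
    """Write rows as a TSV with header and deterministic order.

    ``rows`` is a DataFrame or an iterable of dicts sharing a schema. Rows are
    sorted by ``key_columns`` (all columns when empty). Free-text cells
    containing tabs or newlines are quoted so the file round-trips.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(list(rows))
    if df.empty and not len(df.columns):
        Path(path).write_text("")
        return
    keys = [c for c in (key_columns or df.columns) if c in df.columns]
    if keys and len(df):
        df = df.sort_values(keys, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_MINIMAL)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Tier table


_VALID_TIERS = {t.value: t for t in (Tier.KNOWN_DRIVER, Tier.TIER1, Tier.TIER2)}


class TierTable:
    """Local driver/actionability lookup keyed by gene plus cDNA change or locus.

    Replaces live database queries: rows carry (gene, change, tier, evidence,
    therapies) where ``change`` is an HGVS.c string or a ``chrom:pos:ref:alt``
    locus key.
    """

    def __init__(self, rows: Iterable[Mapping]) -> None:
        self._by_key: dict = {}
        self.rows = []
        for row in rows:
            tier_token = str(row["tier"]).strip()
            if tier_token not in _VALID_TIERS:
                raise ValueError(f"unknown tier token {tier_token!r} in tier table")
            entry = {
                "gene": str(row["gene"]).strip(),
                "change": str(row["change"]).strip(),
                "tier": _VALID_TIERS[tier_token],
                "evidence": str(row.get("evidence", "") or ""),
                "therapies": str(row.get("therapies", "") or ""),
            }
            self.rows.append(entry)
            self._by_key[(entry["gene"].upper(), entry["change"])] = entry

    def lookup(self, variant: VariantCall) -> Optional[dict]:
        gene = variant.gene.upper()
        if variant.hgvs_c:
            hit = self._by_key.get((gene, variant.hgvs_c))
            if hit:
                return hit
        locus = f"{variant.chrom}:{variant.pos}:{variant.ref}:{variant.alt}"
        return self._by_key.get((gene, locus))

    def tier_of(self, variant: VariantCall) -> Tier:
        hit = self.lookup(variant)
        return hit["tier"] if hit else Tier.NONE

    def therapies_of(self, variant: VariantCall) -> str:
        hit = self.lookup(variant)
        return hit["therapies"] if hit else ""


def load_tier_table(path: Union[str, Path]) -> TierTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene", "change", "tier"}
    if not required.issubset(df.columns):
        raise ValueError(f"tier table {path} must have columns {sorted(required)}")
    return TierTable(df.to_dict("records"))
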