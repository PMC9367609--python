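import numpy as np
import pytest

from ctdnahet.core_io import CallSet, SampleRecord, VariantCall
from ctdnahet.pipeline import RunConfig, run_pipeline
from ctdnahet.simulate import SimConfig, generate_cohort, write_cohort


def make_sample(sample_id="S1", patient_id="P1", sample_type="plasma", timepoint="T0", tf=0.10):
    return SampleRecord(
        sample_id=sample_id,
        patient_id=patient_id,
        sample_type=sample_type,
        timepoint=timepoint,
        tumor_fraction=tf if sample_type == "plasma" else None,
    )


def make_variant(sample=None, chrom="chr1", pos=100, ref="A", alt="T", alt_reads=50,
                 total_depth=1000, consequence="missense_variant", gene="GENE", **kw):
    sample = sample or make_sample()
    return VariantCall(
        patient_id=sample.patient_id, sample_id=sample.sample_id, chrom=chrom, pos=pos,
        ref=ref, alt=alt, alt_reads=alt_reads, total_depth=total_depth,
        consequence=consequence, gene=gene, **kw,
    )


def make_callset(variants, sample=None):
    sample = sample or make_sample()
    return CallSet(sample=sample, variants=list(variants))


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (12 patients, seed 1)."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_paths(default_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    return write_cohort(default_cohort, out)


@pytest.fixture(scope="session")
def pipeline_result(default_cohort, cohort_paths, tmp_path_factory):
    sim = cohort_paths["sample_sheet"].parent
    cfg = RunConfig(
        vcf_dir=sim / "vcf",
        reference=sim / "reference.fa",
        sample_sheet=sim / "sample_sheet.tsv",
        tier_table=sim / "tier_table.tsv",
        out_dir=tmp_path_factory.mktemp("analysis"),
    )
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
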