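import dataclasses

import numpy as np
import pytest

from ctdnahet.core_io import FilterRule, ReferenceContext, Tier, TierTable
from ctdnahet.filtering import (
    FilterConfig,
    artifact_rule_filter,
    cohort_frameshift_filter,
    germline_population_filter,
    is_del_upstream_homopolymer,
    is_ins_upstream_homopolymer,
    is_inframe_repeat,
    is_snv_flanking_repeat,
    likely_germline_loci,
    merge_callsets,
    min_reads_filter,
    run_filter_cascade,
    tier_prioritize,
    vaf_threshold_filter,
)

from conftest import make_callset, make_sample, make_variant
from oracle_rules import (
    oracle_del_upstream_homopolymer,
    oracle_inframe_repeat,
    oracle_ins_upstream_homopolymer,
    oracle_snv_flanking_repeat,
)


def ctx_for(seq, chrom="chr1"):
    return ReferenceContext(chrom=chrom, window_start=1, sequence=seq, chrom_length=len(seq))


class TestMerge:
    def test_union_with_caller_provenance(self):
        s = make_sample()
        v1 = make_variant(s, pos=10)
        v2a = make_variant(s, pos=20, total_depth=1000, alt_reads=50)
        v2b = make_variant(s, pos=20, total_depth=800, alt_reads=60, callers=frozenset({"callerB"}))
        v3 = make_variant(s, pos=30, callers=frozenset({"callerB"}))
        merged = merge_callsets(make_callset([v1, v2a], s), make_callset([v2b, v3], s))
        assert merged.loci() == {v1.locus, v2a.locus, v3.locus}
        shared = next(v for v in merged.variants if v.pos == 20)
        assert shared.callers == {"callerA", "callerB"}
        # depths come from the deeper call
        assert (shared.total_depth, shared.alt_reads) == (1000, 50)

    def test_empty_side_is_identity(self):
        s = make_sample()
        b = make_callset([make_variant(s)], s)
        merged = merge_callsets(make_callset([], s), b)
        assert merged.loci() == b.loci()

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValueError, match="different samples"):
            merge_callsets(
                make_callset([], make_sample(sample_id="S1")),
                make_callset([], make_sample(sample_id="S2")),
            )


class TestThresholdStages:
    def test_vaf_threshold_is_tf_plus_tolerance_upper_bound(self):
        s = make_sample(tf=0.10)
        above = make_variant(s, pos=1, alt_reads=200, total_depth=1000)  # vaf 0.20
        at = make_variant(s, pos=2, alt_reads=150, total_depth=1000)  # vaf 0.15 == threshold
        kept, audits = vaf_threshold_filter(make_callset([above, at], s), FilterConfig())
        assert kept.loci() == {at.locus}
        assert audits[0].rule_id is FilterRule.VAF_THRESHOLD

    def test_full_tumor_fraction_removes_nothing(self):
        s = make_sample(tf=1.0)
        cs = make_callset([make_variant(s, alt_reads=999, total_depth=1000)], s)
        kept, audits = vaf_threshold_filter(cs, FilterConfig())
        assert len(kept) == 1 and not audits

    def test_tissue_passes_through(self):
        s = make_sample(sample_type="tissue", timepoint="A")
        cs = make_callset([make_variant(s, alt_reads=900, total_depth=1000)], s)
        kept, audits = vaf_threshold_filter(cs, FilterConfig())
        assert len(kept) == 1 and not audits

    @pytest.mark.parametrize("alt_reads,kept", [(4, False), (5, True)])
    def test_min_reads_boundary(self, alt_reads, kept):
        cs = make_callset([make_variant(alt_reads=alt_reads)])
        retained, audits = min_reads_filter(cs, 5)
        assert (len(retained) == 1) is kept
        if not kept:
            assert audits[0].rule_id is FilterRule.MIN_ALT_READS

    @pytest.mark.parametrize("pop_af,kept", [(0.011, False), (0.01, True), (None, True)])
    def test_population_af_boundary_is_strict(self, pop_af, kept):
        cs = make_callset([make_variant(population_af=pop_af)])
        retained, audits = germline_population_filter(cs, FilterConfig())
        assert (len(retained) == 1) is kept
        if not kept:
            assert audits[0].rule_id is FilterRule.POPULATION_AF

    def test_germline_heuristic_needs_every_sample_at_germline_vaf(self):
        patient = [
            make_sample("S1", sample_type="tissue", timepoint="A"),
            make_sample("S2", sample_type="tissue", timepoint="B"),
            make_sample("S3", sample_type="plasma", timepoint="T0", tf=0.1),
        ]
        # germline-like: 50% VAF in every sample regardless of tumor fraction
        cohort = [make_callset([make_variant(s, pos=7, alt_reads=500, total_depth=1000)], s) for s in patient]
        # somatic-like in one tissue only, same VAF
        cohort[0] = make_callset(
            [make_variant(patient[0], pos=7, alt_reads=500, total_depth=1000),
             make_variant(patient[0], pos=9, alt_reads=500, total_depth=1000)],
            patient[0],
        )
        flagged = likely_germline_loci(cohort, FilterConfig())["P1"]
        assert {loc[1] for loc in flagged} == {7}
        kept, audits = germline_population_filter(cohort[0], FilterConfig(), flagged)
        assert {v.pos for v in kept.variants} == {9}
        assert audits[0].rule_id is FilterRule.LIKELY_GERMLINE


class TestArtifactRules:
    def test_one_base_deletion_upstream_of_run(self):
        # 5'-C[T]AAAG-3': deletion of T sits upstream of AAA
        seq = "GGCTAAAGCC"
        v = make_variant(pos=3, ref="CT", alt="C")
        assert is_del_upstream_homopolymer(v, ctx_for(seq), 3)

    def test_run_of_two_does_not_trigger(self):
        seq = "GGCTAAGCCC"
        v = make_variant(pos=3, ref="CT", alt="C")
        assert not is_del_upstream_homopolymer(v, ctx_for(seq), 3)

    def test_two_base_deletion_not_applicable(self):
        seq = "GGCTAAAGCC"
        v = make_variant(pos=3, ref="CTA", alt="C")
        assert not is_del_upstream_homopolymer(v, ctx_for(seq), 3)

    def test_insertion_before_run(self):
        seq = "GACTGGGACT"
        v = make_variant(pos=4, ref="T", alt="TA")  # insert A before GGG
        assert is_ins_upstream_homopolymer(v, ctx_for(seq), 3)
        v2 = make_variant(pos=4, ref="T", alt="TACG")  # 3-base insertion: out of scope
        assert not is_ins_upstream_homopolymer(v2, ctx_for(seq), 3)

    def test_insertion_before_short_run(self):
        seq = "GACTGGACTA"
        v = make_variant(pos=4, ref="T", alt="TA")
        assert not is_ins_upstream_homopolymer(v, ctx_for(seq), 3)

    @pytest.mark.parametrize(
        "seq,pos,hit",
        [
            ("TTTACGAGGG", 4, True),  # 5' run TTT
            ("GACACGTGGT", 4, False),
            ("GACAGGGTCA", 4, True),  # 3' run GGG
        ],
    )
    def test_snv_flanking_repeat_either_flank(self, seq, pos, hit):
        ref = seq[pos - 1]
        alt = "C" if ref != "C" else "G"
        v = make_variant(pos=pos, ref=ref, alt=alt)
        assert is_snv_flanking_repeat(v, ctx_for(seq), 3) is hit

    def test_snv_both_flanks_mode(self):
        seq = "TTTAGGGCAT"
        v = make_variant(pos=4, ref="A", alt="C")
        assert is_snv_flanking_repeat(v, ctx_for(seq), 3, mode="both")
        v2 = make_variant(pos=4, ref="A", alt="C")
        assert not is_snv_flanking_repeat(v2, ctx_for("TTTACGGCAT"), 3, mode="both")

    def test_inframe_repeat_unit_deletion(self):
        # delete one CAG out of a CAGCAGCAG array: two copies remain downstream
        seq = "AT" + "CAGCAGCAG" + "TT"
        v = make_variant(pos=2, ref="TCAG", alt="T")
        assert is_inframe_repeat(v, ctx_for(seq))
        # single adjacent copy is not enough
        seq2 = "AT" + "CAGCAG" + "TTTTT"
        v2 = make_variant(pos=2, ref="TCAG", alt="T")
        assert not is_inframe_repeat(v2, ctx_for(seq2))

    def test_frameshift_deletion_not_inframe(self):
        seq = "ATCACACACATT"
        v = make_variant(pos=2, ref="TCA", alt="T")
        assert not is_inframe_repeat(v, ctx_for(seq))

    def test_predicates_match_bruteforce_oracle_on_random_references(self, rng):
        """Property: each rule predicate equals the naive string-scanning oracle."""
        bases = np.array(list("ACGT"))
        for min_run in (2, 3, 4):
            for _ in range(8):
                seq = "".join(rng.choice(bases, size=2000))
                ref_map = {"c": seq}
                for _ in range(150):
                    pos = int(rng.integers(10, 1980))
                    kind = int(rng.integers(0, 4))
                    if kind == 0:  # 1-base deletion
                        ref, alt = seq[pos - 1 : pos + 1], seq[pos - 1]
                        pred, oracle = is_del_upstream_homopolymer, oracle_del_upstream_homopolymer
                    elif kind == 1:  # insertion of 1-2 bases
                        ins = "".join(rng.choice(bases, size=int(rng.integers(1, 3))))
                        ref, alt = seq[pos - 1], seq[pos - 1] + ins
                        pred, oracle = is_ins_upstream_homopolymer, oracle_ins_upstream_homopolymer
                    elif kind == 2:  # SNV
                        ref = seq[pos - 1]
                        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                        pred, oracle = (
                            lambda v, c, m: is_snv_flanking_repeat(v, c, m),
                            oracle_snv_flanking_repeat,
                        )
                    else:  # 3-base (inframe) deletion
                        ref, alt = seq[pos - 1 : pos + 3], seq[pos - 1]
                        pred = lambda v, c, m: is_inframe_repeat(v, c)  # noqa: E731
                        oracle = lambda s, p, r, a, m: oracle_inframe_repeat(s, p, r, a)  # noqa: E731
                    v = make_variant(pos=pos, ref=ref, alt=alt)
                    from ctdnahet.core_io import fetch_context

                    ctx = fetch_context(ref_map, "c", pos, 60)
                    assert pred(v, ctx, min_run) == oracle(seq, pos, ref, alt, min_run), (
                        min_run, pos, ref, alt)


class TestCohortFrameshift:
    def _cohort(self, n_carriers, n_total):
        sets = []
        for i in range(n_total):
            s = make_sample(f"S{i}", sample_type="tissue", timepoint="A")
            variants = [make_variant(s, pos=50, ref="AT", alt="A", consequence="frameshift_variant")] \
                if i < n_carriers else []
            variants.append(make_variant(s, pos=100 + i))
            sets.append(make_callset(variants, s))
        return sets

    def test_recurrent_frameshift_removed_everywhere(self):
        out, audits = cohort_frameshift_filter(self._cohort(7, 10), FilterConfig())
        assert len(audits) == 7
        assert all(a.rule_id is FilterRule.COHORT_FRAMESHIFT for a in audits)
        assert all(all(v.pos != 50 for v in cs.variants) for cs in out)

    def test_exactly_at_fraction_retained(self):
        out, audits = cohort_frameshift_filter(self._cohort(6, 10), FilterConfig())
        assert not audits
        assert sum(any(v.pos == 50 for v in cs.variants) for cs in out) == 6

    def test_single_sample_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cohort_frameshift_filter(self._cohort(1, 1), FilterConfig())


class TestTierPrioritize:
    def test_whitelisted_kept_others_dropped(self):
        table = TierTable(
            [
                {"gene": "BRCA1", "change": "c.1A>T", "tier": "tier1", "therapies": "PARPi"},
                {"gene": "ATM", "change": "c.2G>C", "tier": "tier2"},
            ]
        )
        s = make_sample()
        hits = make_callset(
            [
                make_variant(s, pos=1, gene="BRCA1", hgvs_c="c.1A>T"),
                make_variant(s, pos=2, gene="ATM", hgvs_c="c.2G>C"),
                make_variant(s, pos=3, gene="XRCC1", hgvs_c="c.3T>A"),
            ],
            s,
        )
        out = tier_prioritize(hits, table)
        assert {(v.gene, v.tier) for v in out.variants} == {("BRCA1", Tier.TIER1), ("ATM", Tier.TIER2)}


class TestCascade:
    def test_conservation_and_single_attribution(self, default_cohort, pipeline_result):
        res = pipeline_result
        merged = {cs.sample.sample_id: cs for cs in res.merged}
        audits_per_sample = {}
        seen = set()
        for a in res.cascade.audits:
            key = (a.sample_id, a.chrom, a.pos, a.ref, a.alt)
            assert key not in seen, "variant removed by more than one rule"
            seen.add(key)
            audits_per_sample[a.sample_id] = audits_per_sample.get(a.sample_id, 0) + 1
        for cs in res.retained:
            sid = cs.sample.sample_id
            assert len(merged[sid]) == len(cs) + audits_per_sample.get(sid, 0)

    def test_idempotence_on_own_output(self, default_cohort, pipeline_result):
        res = pipeline_result
        again = run_filter_cascade(res.retained, default_cohort.reference.as_mapping(),
                                   FilterConfig())
        assert not again.audits
        for a, b in zip(res.retained, again.callsets):
            assert a.loci() == b.loci()

    def test_noop_configuration_is_identity(self, default_cohort):
        cfg = FilterConfig(min_alt_reads=0, vaf_tolerance=1.0, cohort_frameshift_fraction=1.01,
                           max_population_af=1.0, germline_vaf_band=(0.0, 0.0), germline_high_vaf=1.01,
                           homopolymer_min_run=10**6, inframe_min_copies=10**6)
        cohort = [default_cohort.caller_a[sid] for sid in sorted(default_cohort.caller_a)][:6]
        res = run_filter_cascade(cohort, default_cohort.reference.as_mapping(), cfg)
        assert not res.audits
        for a, b in zip(cohort, res.callsets):
            assert a.loci() == b.loci()

    def test_empty_cohort(self):
        res = run_filter_cascade([], {"c": "ACGT"})
        assert res.callsets == [] and res.audits == []

    def test_stage_monotonicity(self, default_cohort):
        """Lowering min_alt_reads or raising the VAF tolerance never shrinks retention."""
        sid = sorted(default_cohort.caller_a)[0]
        cs = default_cohort.caller_b[sid]  # contains low-support false positives
        sizes = [len(min_reads_filter(cs, m)[0]) for m in (10, 5, 1, 0)]
        assert sizes == sorted(sizes)
        plasma_sid = next(s.sample_id for s in default_cohort.samples if s.is_plasma)
        ps = default_cohort.caller_a[plasma_sid]
        sizes = [
            len(vaf_threshold_filter(ps, FilterConfig(vaf_tolerance=t))[0])
            for t in (0.0, 0.05, 0.2, 1.0)
        ]
        assert sizes == sorted(sizes)
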