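import numpy as np
import pandas as pd
import pytest

from ctdnahet.core_io import (
    AnnotationSpec,
    CallSet,
    SampleRecord,
    VariantCall,
    VariantClass,
    classify_alleles,
    fetch_context,
    load_tier_table,
    read_sample_sheet,
    read_vcf,
    write_table,
    write_vcf,
)

from conftest import make_callset, make_sample, make_variant


class TestVariantCall:
    def test_vaf_computed_from_depths(self):
        v = make_variant(alt_reads=5, total_depth=100)
        assert v.vaf == pytest.approx(0.05, abs=1e-12)
        assert v.variant_class is VariantClass.SNV

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "T", VariantClass.SNV),
            ("A", "AT", VariantClass.INSERTION),
            ("AT", "A", VariantClass.DELETION),
            ("AT", "GC", VariantClass.MNV),
        ],
    )
    def test_allele_classification(self, ref, alt, expected):
        assert classify_alleles(ref, alt) is expected

    @pytest.mark.parametrize(
        "kw",
        [
            {"alt_reads": 101, "total_depth": 100},
            {"ref": "A", "alt": "A"},
            {"ref": "N", "alt": "T"},
            {"total_depth": 0, "alt_reads": 0},
            {"vaf": 0.5, "alt_reads": 5, "total_depth": 100},
        ],
    )
    def test_invalid_variants_rejected(self, kw):
        with pytest.raises(ValueError):
            make_variant(**kw)

    def test_duplicate_loci_rejected_in_callset(self):
        v = make_variant()
        with pytest.raises(ValueError, match="duplicate"):
            make_callset([v, make_variant()])


class TestSampleSheet:
    def _write(self, tmp_path, rows, cols=("sample_id", "patient_id", "sample_type", "timepoint", "tumor_fraction")):
        path = tmp_path / "sheet.tsv"
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        return path

    def test_valid_rows_round_trip(self, tmp_path):
        path = self._write(
            tmp_path,
            [("S1", "P1", "plasma", "T0", 0.12), ("S2", "P1", "tissue", "A", None)],
        )
        records = read_sample_sheet(path)
        assert len(records) == 2
        assert records[0].tumor_fraction == pytest.approx(0.12)
        assert records[1].sample_type == "tissue" and records[1].tumor_fraction is None

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = self._write(tmp_path, [("S1", "P1", "plasma", "T0", 0.1), ("S1", "P1", "plasma", "TRm", 0.2)])
        with pytest.raises(ValueError, match="duplicate"):
            read_sample_sheet(path)

    def test_plasma_without_tf_rejected(self, tmp_path):
        path = self._write(tmp_path, [("S1", "P1", "plasma", "T0", None)])
        with pytest.raises(ValueError, match="tumor_fraction"):
            read_sample_sheet(path)

    def test_unknown_sample_type_rejected(self, tmp_path):
        path = self._write(tmp_path, [("S1", "P1", "serum", "T0", 0.1)])
        with pytest.raises(ValueError, match="sample_type"):
            read_sample_sheet(path)


class TestFetchContext:
    def test_window_clipped_at_chromosome_start(self):
        ctx = fetch_context({"c": "ACGTACGTAC"}, "c", 2, 5)
        assert ctx.window_start == 1
        assert len(ctx.sequence) == 7

    def test_exact_window(self):
        ctx = fetch_context({"c": "ACGTACGTAC"}, "c", 5, 2)
        assert ctx.sequence == "GTACG"

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            fetch_context({"c": "ACGT"}, "c", 0, 2)
        with pytest.raises(KeyError):
            fetch_context({"c": "ACGT"}, "missing", 1, 2)

    def test_agrees_with_direct_substring_on_random_draws(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        ref = {"chrX": seq}
        for _ in range(1000):
            pos = int(rng.integers(1, 3001))
            flank = int(rng.integers(1, 80))
            ctx = fetch_context(ref, "chrX", pos, flank)
            lo, hi = max(1, pos - flank), min(3000, pos + flank)
            assert ctx.sequence == seq[lo - 1 : hi]
            assert ctx.window_start == lo


class TestVcfIO:
    def test_round_trip_preserves_identity_and_depths(self, tmp_path, rng):
        sample = make_sample()
        variants = []
        used = set()
        for _ in range(50):
            pos = int(rng.integers(1, 900))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            if (pos, ref, alt) in used:
                continue
            used.add((pos, ref, alt))
            depth = int(rng.integers(100, 5000))
            variants.append(
                make_variant(sample, pos=pos, ref=str(ref), alt=str(alt),
                             alt_reads=int(rng.integers(0, depth + 1)), total_depth=depth,
                             population_af=float(rng.uniform(0, 0.05)))
            )
        cs = make_callset(variants, sample)
        path = tmp_path / "t.vcf"
        write_vcf(cs, path, {"chr1": 1000})
        back = read_vcf(path, sample)
        orig = {v.locus: v for v in cs.variants}
        assert {v.locus for v in back.variants} == set(orig)
        for v in back.variants:
            o = orig[v.locus]
            assert (v.alt_reads, v.total_depth) == (o.alt_reads, o.total_depth)
            assert v.vaf == pytest.approx(o.vaf, abs=1e-9)
            assert v.population_af == pytest.approx(o.population_af, abs=1e-9)
            assert (v.consequence, v.gene) == (o.consequence, o.gene)

    def test_multiallelic_record_split(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
            'Format: Consequence|SYMBOL|HGVSc|HGVSp|gnomAD_AF">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tA\tT,G\t.\tPASS\t"
            "CSQ=missense_variant|G1|c.1A>T||,stop_gained|G1|c.1A>G||\t"
            "GT:AD:DP\t0/1:90,5,5:100\n"
        )
        cs = read_vcf(path, make_sample())
        assert len(cs) == 2
        by_alt = {v.alt: v for v in cs.variants}
        assert by_alt["T"].consequence == "missense_variant"
        assert by_alt["G"].consequence == "stop_gained"
        assert by_alt["T"].vaf == pytest.approx(0.05)

    def test_empty_vcf_body(self, tmp_path):
        sample = make_sample()
        path = tmp_path / "e.vcf"
        write_vcf(make_callset([], sample), path, {"chr1": 1000})
        assert len(read_vcf(path, sample)) == 0

    def test_missing_allele_depths_is_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(ValueError, match="AD"):
            read_vcf(path, make_sample())

    def test_unknown_sample_column_is_error(self, tmp_path):
        sample = make_sample()
        path = tmp_path / "t.vcf"
        write_vcf(make_callset([make_variant(sample)], sample), path, {"chr1": 1000})
        with pytest.raises(ValueError, match="sample column"):
            read_vcf(path, make_sample(sample_id="OTHER"), vcf_sample="OTHER")


class TestWriteTable:
    def test_embedded_tab_round_trips(self, tmp_path):
        path = tmp_path / "t.tsv"
        rows = [{"k": "a", "text": "has\ttab"}, {"k": "b", "text": "plain"}]
        write_table(rows, path, key_columns=("k",))
        back = pd.read_csv(path, sep="\t")
        assert list(back["text"]) == ["has\ttab", "plain"]

    def test_empty_rows_give_header_only(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_table(pd.DataFrame(columns=["a", "b"]), path)
        assert path.read_text().strip() == "a\tb"

    def test_rows_sorted_by_key_columns(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_table([{"k": 2, "v": "x"}, {"k": 1, "v": "y"}], path, key_columns=("k",))
        assert list(pd.read_csv(path, sep="\t")["k"]) == [1, 2]


class TestTierTable:
    def test_lookup_and_unknown_token(self, tmp_path):
        path = tmp_path / "tiers.tsv"
        pd.DataFrame(
            [
                {"gene": "BRCA1", "change": "c.10A>T", "tier": "tier1", "therapies": "PARPi"},
                {"gene": "TP53", "change": "chr1:5:A:T", "tier": "known_driver", "therapies": ""},
            ]
        ).to_csv(path, sep="\t", index=False)
        table = load_tier_table(path)
        v = make_variant(gene="BRCA1", hgvs_c="c.10A>T")
        assert table.tier_of(v).value == "tier1"
        assert table.therapies_of(v) == "PARPi"
        v2 = make_variant(gene="TP53", chrom="chr1", pos=5)
        assert table.tier_of(v2).value == "known_driver"
        assert table.tier_of(make_variant(gene="ATM")).value == "none"
        bad = tmp_path / "bad.tsv"
        pd.DataFrame([{"gene": "X", "change": "c.1A>T", "tier": "tier9"}]).to_csv(bad, sep="\t", index=False)
        with pytest.raises(ValueError, match="tier"):
            load_tier_table(bad)
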