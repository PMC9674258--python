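"""DNV ingestion, classification, deduplication, filtering and counting."""

import numpy as np
import pandas as pd
import pytest

from dnvmeta.harmonize import (
    DNV_COLUMNS, ValidationError, classify_variant, count_dnvs,
    deduplicate_samples, filter_dnvs, parse_dnv_input, read_count_table,
    summarize_rates, validate_records, write_count_table,
)


def _rec(sample="S1", pheno="ASD", sex="male", chrom="1", pos=100,
         gene="GENE1", csq="missense_variant", cadd=10.0, platform="exome"):
    return dict(sample_id=sample, cohort="c1", phenotype=pheno, sex=sex,
                chrom=chrom, pos=pos, ref="A", alt="T", gene=gene,
                consequence=csq, cadd=cadd, platform=platform)


def _manifest(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "cohort", "phenotype", "sex", "platform"]
    )


@pytest.mark.parametrize("csq,cadd,expected", [
    ("stop_gained", 45, "LGD"),
    ("frameshift_variant", 0, "LGD"),
    ("splice_donor_variant", 12, "LGD"),
    ("splice_acceptor_variant", 3, "LGD"),
    ("missense_variant", 31, "MIS30"),
    ("missense_variant", 30, "MIS"),       # strictly greater than 30
    ("missense_variant", 30.0001, "MIS30"),
    ("synonymous_variant", 5, "SYN"),
    ("intron_variant", 2, "other"),
    ("missense_variant&synonymous_variant", 3, "MIS"),  # most severe wins
    ("stop_gained&missense_variant", 40, "LGD"),
])
def test_variant_classification(csq, cadd, expected):
    assert classify_variant(csq, cadd) == expected


def test_classify_requires_consequence():
    with pytest.raises(ValidationError):
        classify_variant("", 10)


class TestParse:
    def test_tsv_round_trip(self, tmp_path):
        rows = pd.DataFrame([
            _rec(), _rec(sample="S2", pheno="DD", csq="stop_gained", cadd=40),
            _rec(sample="S3", pheno="sibling", sex="female", chrom="X"),
        ])
        path = tmp_path / "dnvs.tsv"
        rows.to_csv(path, sep="\t", index=False)
        out = parse_dnv_input(path)
        assert len(out) == 3
        assert list(out.columns) == list(DNV_COLUMNS)
        pd.testing.assert_frame_equal(
            out, rows.astype(out.dtypes), check_dtype=False
        )

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("\t".join(DNV_COLUMNS) + "\n")
        assert len(parse_dnv_input(path)) == 0

    def test_unknown_phenotype_rejected(self, tmp_path):
        rows = pd.DataFrame([_rec(pheno="ADHD")])
        path = tmp_path / "bad.tsv"
        rows.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="phenotype"):
            parse_dnv_input(path)

    def test_missing_column_rejected(self):
        frame = pd.DataFrame([_rec()]).drop(columns=["gene"])
        with pytest.raises(ValidationError, match="gene"):
            validate_records(frame)

    def test_vcf_ingestion(self, tmp_path):
        vcf = tmp_path / "s1.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##INFO=<ID=CSQ,Number=1,Type=String,Description="c">\n'
            '##INFO=<ID=CADD,Number=1,Type=Float,Description="d">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tT\t.\t.\tGENE=G1;CSQ=missense_variant;CADD=35.0"
            "\tGT\t0/1\n"
        )
        man = _manifest([("S1", "c1", "ASD", "male", "exome")])
        out = parse_dnv_input(vcf, format="vcf", manifest=man)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["gene"], row["pos"], row["phenotype"]) == ("G1", 100, "ASD")
        assert classify_variant(row["consequence"], row["cadd"]) == "MIS30"


class TestDeduplicate:
    def test_genome_preferred_over_exome(self):
        rec = pd.DataFrame([
            _rec(sample="S1", platform="exome"),
            _rec(sample="S1", platform="genome", pos=200),
            _rec(sample="S2", platform="exome"),
        ])
        man = _manifest([
            ("S1", "c1", "ASD", "male", "exome"),
            ("S1", "c2", "ASD", "male", "genome"),
            ("S2", "c1", "ASD", "male", "exome"),
        ])
        out, man_out, log = deduplicate_samples(rec, man)
        s1 = out[out["sample_id"] == "S1"]
        assert set(s1["platform"]) == {"genome"}
        assert len(out[out["sample_id"] == "S2"]) == 1  # exome-only untouched
        assert man_out["sample_id"].is_unique
        assert len(log) == 1

    def test_disjoint_cohorts_concatenate(self):
        rec = pd.DataFrame([_rec(sample="S1"), _rec(sample="S2")])
        man = _manifest([
            ("S1", "c1", "ASD", "male", "exome"),
            ("S2", "c2", "DD", "female", "exome"),
        ])
        out, _, log = deduplicate_samples(rec, man)
        assert len(out) == 2 and len(log) == 0

    def test_conflicting_phenotype_is_hard_error(self):
        man = _manifest([
            ("S1", "c1", "ASD", "male", "exome"),
            ("S1", "c2", "DD", "male", "genome"),
        ])
        with pytest.raises(ValidationError, match="conflicting"):
            deduplicate_samples(pd.DataFrame([_rec()]), man)


class TestFilter:
    def test_bed_coordinate_convention(self):
        # 1-based position 100 <-> 0-based 99: inside [99, 100), outside
        # [100, 101).
        rec = pd.DataFrame([_rec(pos=100)])
        hit = pd.DataFrame([("1", 99, 100)], columns=["chrom", "start", "end"])
        miss = pd.DataFrame([("1", 100, 101)], columns=["chrom", "start", "end"])
        out, log = filter_dnvs(rec, hit)
        assert len(out) == 0 and log["blacklisted"] == 1
        out, log = filter_dnvs(rec, miss)
        assert len(out) == 1 and log["blacklisted"] == 0

    def test_no_op_without_filters(self):
        rec = pd.DataFrame([_rec(), _rec(pos=5)])
        out, log = filter_dnvs(rec, None, None)
        pd.testing.assert_frame_equal(out, rec.reset_index(drop=True))

    def test_per_sample_cap_drops_whole_sample(self):
        rec = pd.DataFrame([_rec(pos=p) for p in (1, 2, 3)]
                           + [_rec(sample="S2", pos=9)])
        out, log = filter_dnvs(rec, per_sample_cap=2)
        assert set(out["sample_id"]) == {"S2"}
        assert log["capped_samples"] == ["S1"] and log["capped_records"] == 3

    def test_filtering_is_idempotent(self):
        rec = pd.DataFrame([_rec(pos=p, sample=f"S{p%3}") for p in range(1, 40)])
        bl = pd.DataFrame([("1", 0, 10)], columns=["chrom", "start", "end"])
        once, _ = filter_dnvs(rec, bl, per_sample_cap=10)
        twice, _ = filter_dnvs(once, bl, per_sample_cap=10)
        pd.testing.assert_frame_equal(once, twice)

    def test_malformed_bed_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("1\tnotanumber\t100\n")
        with pytest.raises(ValidationError, match="line 1"):
            filter_dnvs(pd.DataFrame([_rec()]), bed)


class TestCount:
    MAN = [
        ("S1", "c1", "ASD", "male", "exome"),
        ("S2", "c1", "ASD", "female", "exome"),
        ("S3", "c1", "DD", "male", "exome"),
        ("S4", "c1", "sibling", "female", "exome"),
    ]

    def test_hand_counted_toy_table(self):
        rec = pd.DataFrame([
            _rec(sample="S1", csq="stop_gained", cadd=40),
            _rec(sample="S2", csq="frameshift_variant", cadd=0),
            _rec(sample="S1", csq="missense_variant", cadd=31),
            _rec(sample="S3", pheno="DD", csq="missense_variant", cadd=10),
            _rec(sample="S2", csq="synonymous_variant", cadd=1),
        ])
        table = count_dnvs(rec, _manifest(self.MAN))
        ndd = table.counts["NDD"].loc["GENE1"]
        assert (ndd["LGD"], ndd["MIS"], ndd["MIS30"], ndd["SYN"]) == (2, 2, 1, 1)
        asd = table.counts["ASD"].loc["GENE1"]
        assert (asd["LGD"], asd["MIS"], asd["MIS30"], asd["SYN"]) == (2, 1, 1, 1)
        assert table.sizes["NDD"].n == 3
        assert table.sizes["ASD"].n == 2
        assert (table.sizes["NDD"].n_male, table.sizes["NDD"].n_female) == (2, 1)

    def test_zero_records_keep_denominators(self):
        rec = pd.DataFrame(columns=list(DNV_COLUMNS))
        table = count_dnvs(rec, _manifest(self.MAN), genes=["G1"])
        assert int(table.counts.to_numpy().sum()) == 0
        assert table.sizes["DD"].n == 1

    def test_ndd_additivity_and_sex_partition(self, small_cohort):
        c = small_cohort["table"].counts
        assert (c["NDD"] == c["ASD"] + c["DD"]).all().all()
        # every simulated proband has known sex, so male+female = NDD
        assert (c["NDD"] == c["male"] + c["female"]).all().all()

    def test_unknown_sample_rejected(self):
        rec = pd.DataFrame([_rec(sample="GHOST")])
        with pytest.raises(ValidationError, match="GHOST"):
            count_dnvs(rec, _manifest(self.MAN))

    def test_round_trip_tsv(self, tmp_path, small_cohort):
        table = small_cohort["table"]
        path = tmp_path / "counts.tsv"
        write_count_table(table, path)
        back = read_count_table(path)
        pd.testing.assert_frame_equal(back.counts, table.counts)
        assert back.sizes["NDD"].n == table.sizes["NDD"].n
        assert back.gene_chrom == table.gene_chrom


class TestRates:
    def test_hand_computed_rate(self):
        rec = pd.DataFrame([
            _rec(sample="S1", csq="missense_variant"),
            _rec(sample="S1", csq="stop_gained", cadd=40),
            _rec(sample="S2", csq="missense_variant"),
        ])
        man = _manifest([(f"S{i}", "c1", "ASD", "male", "exome")
                         for i in (1, 2, 3)])
        assert summarize_rates(rec, man)["ASD"] == 1.00

    def test_synonymous_only_is_zero(self):
        rec = pd.DataFrame([_rec(csq="synonymous_variant")])
        man = _manifest([("S1", "c1", "ASD", "male", "exome")])
        assert summarize_rates(rec, man)["ASD"] == 0.00

    def test_simulated_rate_near_target(self, small_cohort):
        cfg = small_cohort["config"]
        rates = summarize_rates(small_cohort["records"],
                                small_cohort["manifest"])
        target = cfg.target_rates["LGD"] + cfg.target_rates["MIS"]
        # Siblings carry no planted risk, so their rate sits at the target;
        # probands exceed it because of the planted risk genes.
        se = np.sqrt(target / cfg.n_sibling)
        assert abs(rates["sibling"] - target) < 3 * se + 0.005
        assert rates["ASD"] > target
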