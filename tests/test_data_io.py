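"""Metadata parsing, likelihood normalization, and file round-trips."""

import numpy as np
import pandas as pd
import pytest

from chickpop import data_io
from chickpop.data_io import (
    CoordinateParseError,
    DistanceMatrix,
    LocusRecord,
    SampleTable,
    ValidationError,
    parse_coordinate,
    read_genotype_likelihoods,
    read_metadata,
    write_matrix_tsv,
    write_results_tables,
)
from chickpop.differentiation import PairwiseResult

from conftest import make_gl, make_sample_table


class TestCoordinateParsing:
    @pytest.mark.parametrize(
        "text, west, expected",
        [
            ("39° 25′ 7.73″", False, 39.0 + 25 / 60 + 7.73 / 3600),
            ("120° 18′ 24.72″", True, -(120.0 + 18 / 60 + 24.72 / 3600)),
            ("39.0", False, 39.0),
            ("-120.0", True, -120.0),
            ("39° 0′ 0″", False, 39.0),
            ("120° 18′ 24.72″ W", False, -(120.0 + 18 / 60 + 24.72 / 3600)),
        ],
    )
    def test_decimal_and_dms(self, text, west, expected):
        assert parse_coordinate(text, west_negative=west) == pytest.approx(
            expected, abs=1e-9
        )

    def test_sagehen_high_matches_printed_decimal(self):
        # 39°25'7.73" N, 120°18'24.72" W -> 39.41881, -120.30687
        assert parse_coordinate("39° 25′ 7.73″") == pytest.approx(39.41881, abs=1e-5)
        assert parse_coordinate(
            "120° 18′ 24.72″", west_negative=True
        ) == pytest.approx(-120.30687, abs=1e-5)

    def test_garbage_raises(self):
        with pytest.raises(CoordinateParseError):
            parse_coordinate("not a coordinate")


class TestMetadata:
    def test_dms_round_trip_through_file(self, tmp_path):
        path = tmp_path / "meta.tsv"
        rows = make_sample_table(2).frame.astype({"latitude": object, "longitude": object})
        rows.loc[0, "latitude"] = "39° 25′ 7.73″"
        rows.loc[0, "longitude"] = "120° 18′ 24.72″"
        rows.to_csv(path, sep="\t", index=False)
        table = read_metadata(path)
        assert table.frame.loc[0, "latitude"] == pytest.approx(39.41881, abs=1e-5)
        assert table.frame.loc[0, "longitude"] == pytest.approx(-120.30687, abs=1e-5)

    def test_duplicate_individual_rejected(self):
        frame = make_sample_table(2).frame.copy()
        frame.loc[1, "individual_id"] = frame.loc[0, "individual_id"]
        with pytest.raises(ValidationError, match="duplicate"):
            SampleTable(frame)

    def test_site_with_two_elevation_classes_rejected(self):
        frame = make_sample_table(2).frame.copy()
        frame.loc[frame["site_id"] == "SH_H", "elevation_class"] = ["high", "low"]
        with pytest.raises(ValidationError):
            SampleTable(frame)

    def test_transect_missing_low_site_rejected(self):
        frame = make_sample_table(2).frame.copy()
        frame = frame[frame["site_id"] != "SH_L"]
        with pytest.raises(ValidationError, match="transect"):
            SampleTable(frame)


class TestLikelihoodNormalization:
    def test_phred_pl_to_raw(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="pl">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            "##contig=<ID=c1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "c1\t10\t.\tA\tG\t.\t.\t.\tPL:DP\t0,30,300:12\n"
        )
        gl = read_genotype_likelihoods(vcf, "vcf_gl")
        np.testing.assert_allclose(
            gl.likelihoods[0, 0], [1.0, 1e-3, 1e-30], rtol=1e-9
        )
        assert gl.depths[0, 0] == 12

    def test_flat_gl_normalizes_to_ones(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GL,Number=G,Type=Float,Description="gl">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            "##contig=<ID=c1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "c1\t10\t.\tA\tG\t.\t.\t.\tGL:DP\t-1,-1,-1:5\n"
        )
        gl = read_genotype_likelihoods(vcf, "vcf_gl")
        np.testing.assert_allclose(gl.likelihoods[0, 0], [1.0, 1.0, 1.0])

    def test_zero_depth_forces_uninformative_triple(self, tmp_path):
        path = tmp_path / "m.tsv"
        pd.DataFrame(
            {
                "individual": ["i1"], "locus": ["c1:10"], "contig": ["c1"],
                "pos": [10], "ref": ["A"], "alt": ["G"], "depth": [0],
                "L0": [0.2], "L1": [0.5], "L2": [0.3],
            }
        ).to_csv(path, sep="\t", index=False)
        gl = read_genotype_likelihoods(path, "matrix_tsv")
        np.testing.assert_allclose(gl.likelihoods[0, 0], [1.0, 1.0, 1.0])


class TestRoundTrip:
    def test_matrix_tsv_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(7)
        depths = rng.integers(0, 12, size=(5, 8))
        lik = rng.random((5, 8, 3))
        lik /= lik.max(axis=2, keepdims=True)
        lik[depths == 0] = 1.0
        gl = make_gl(lik, depths)
        path = tmp_path / "gl.tsv"
        write_matrix_tsv(gl, path)
        back = read_genotype_likelihoods(path, "matrix_tsv")
        np.testing.assert_allclose(back.likelihoods, gl.likelihoods, atol=1e-12)
        np.testing.assert_array_equal(back.depths, gl.depths)
        assert back.individuals == gl.individuals
        assert [r.locus_id for r in back.loci] == [r.locus_id for r in gl.loci]

    def test_vcf_and_matrix_dialects_agree(self, tmp_path):
        # same data encoded as phred PL in VCF and raw likelihoods in TSV
        pls = [(0, 30, 300), (20, 0, 45), (90, 10, 0)]
        depths = [9, 6, 7]
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="pl">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            "##contig=<ID=c1>\n##contig=<ID=c2>\n##contig=<ID=c3>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        )
        body = "".join(
            f"c{j+1}\t10\t.\tA\tG\t.\t.\t.\tPL:DP\t{a},{b},{c}:{d}\n"
            for j, ((a, b, c), d) in enumerate(zip(pls, depths))
        )
        vcf = tmp_path / "x.vcf"
        vcf.write_text(header + body)
        from_vcf = read_genotype_likelihoods(vcf, "vcf_gl")
        tsv = tmp_path / "x.tsv"
        write_matrix_tsv(from_vcf, tsv)
        from_tsv = read_genotype_likelihoods(tsv, "matrix_tsv")
        np.testing.assert_allclose(
            from_vcf.likelihoods, from_tsv.likelihoods, atol=1e-12
        )
        np.testing.assert_array_equal(from_vcf.depths, from_tsv.depths)

    def test_non_biallelic_vcf_records_skipped(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="pl">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            "##contig=<ID=c1>\n##contig=<ID=c2>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "c1\t10\t.\tA\tG,T\t.\t.\t.\tPL:DP\t0,30,300,5,5,5:9\n"
            "c2\t10\t.\tA\tG\t.\t.\t.\tPL:DP\t0,30,300:9\n"
        )
        gl = read_genotype_likelihoods(vcf, "vcf_gl")
        assert gl.n_loci == 1
        assert gl.loci[0].contig_id == "c2"


class TestResultsTables:
    def test_pairwise_table_has_15_rows_for_6_sites(self, tmp_path):
        results = [
            PairwiseResult(f"s{i}", f"s{j}", 0.01, 0.01, 0.001, 0.008, 0.012,
                           "ns", 0.001)
            for i in range(6) for j in range(i + 1, 6)
        ]
        path = tmp_path / "pairs.tsv"
        write_results_tables(results, path)
        assert len(pd.read_csv(path, sep="\t")) == 15

    def test_empty_results_write_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_results_tables([], path, columns=["site_1", "site_2", "observed_fst"])
        frame = pd.read_csv(path, sep="\t")
        assert list(frame.columns) == ["site_1", "site_2", "observed_fst"]
        assert len(frame) == 0


class TestDomainTypes:
    def test_locus_must_be_biallelic(self):
        with pytest.raises(ValidationError, match="biallelic"):
            LocusRecord("x", "c1", 5, "A", "A")

    def test_duplicate_locus_coordinates_rejected(self):
        lik = np.ones((1, 2, 3))
        depths = np.ones((1, 2), dtype=int)
        with pytest.raises(ValidationError, match="duplicate"):
            make_gl(lik, depths, contigs=["c1", "c1"])

    def test_distance_matrix_requires_symmetry(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_negative_fst_allowed_only_for_fst_kind(self):
        vals = np.array([[0.0, -0.01], [-0.01, 0.0]])
        DistanceMatrix(["a", "b"], vals, kind="fst")
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], vals, kind="generic")
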