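"""I/O round trips, validation and the allele-frequency conventions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from dusgp.data_io import (
    GenotypeTable,
    ParseError,
    RunConfig,
    SchemaError,
    TrialTable,
    ValidationError,
    read_genotypes,
    read_matrix,
    read_trials,
    write_genotypes,
    write_matrix,
    write_trials,
)


class TestGenotypeCSV:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("variety,ploidy,m1,m2\nvarA,2,0.25,0.50\nvarB,4,0.0,1.0\n")
        g = read_genotypes(p, "csv")
        assert g.varieties == ["varA", "varB"]
        assert g.ploidy.tolist() == [2, 4]
        assert g.freq[0].tolist() == [0.25, 0.50]

    def test_missing_cells_kept_as_nan(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("variety,ploidy,m1,m2\nA,2,,0.5\nB,2,0.1,0.2\n")
        g = read_genotypes(p, "csv")
        assert np.isnan(g.freq[0, 0]) and g.freq[0, 1] == 0.5

    @pytest.mark.parametrize("row,err", [
        ("A,2,1.25,0.5", ValidationError),     # frequency outside [0,1]
        ("A,3,0.5,0.5", ValidationError),      # unknown ploidy
        ("A,2,abc,0.5", ValidationError),      # garbage cell
    ])
    def test_invalid_rows_rejected(self, tmp_path, row, err):
        p = tmp_path / "g.csv"
        p.write_text(f"variety,ploidy,m1,m2\n{row}\n")
        with pytest.raises(err):
            read_genotypes(p, "csv")

    def test_marker_map_sidecar(self, tmp_path):
        g = tmp_path / "g.csv"
        g.write_text("variety,ploidy,m1,m2\nA,2,0.1,0.2\nB,2,0.3,0.4\n")
        mm = tmp_path / "map.csv"
        mm.write_text("marker,chrom,pos\nm1,3,100\nm2,1,5\n")
        tbl = read_genotypes(g, "csv", marker_map=mm)
        assert tbl.markers["chrom"].tolist() == ["3", "1"]
        assert tbl.markers["pos"].tolist() == [100, 5]

    def test_round_trip(self, small_panel, tmp_path):
        write_genotypes(small_panel, tmp_path / "g.csv", tmp_path / "m.csv")
        back = read_genotypes(tmp_path / "g.csv", "csv",
                              marker_map=tmp_path / "m.csv")
        assert back.varieties == small_panel.varieties
        np.testing.assert_allclose(back.freq, small_panel.freq, atol=1e-12)
        assert back.markers["chrom"].tolist() == \
            small_panel.markers["chrom"].astype(str).tolist()


class TestGenotypeVCF:
    def _write(self, tmp_path, body, fmt="GT:AD"):
        p = tmp_path / "x.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            + body)
        return p

    def test_ad_frequency(self, tmp_path):
        p = self._write(tmp_path, "1\t10\tv1\tA\tT\t.\t.\t.\tGT:AD\t0/1:3,9\t0/0:10,0\n")
        g = read_genotypes(p, "vcf")
        assert g.freq[0, 0] == pytest.approx(9 / 12)  # alt reads / total reads
        assert g.freq[1, 0] == 0.0

    def test_gt_dosage_fallback(self, tmp_path):
        p = self._write(tmp_path, "1\t10\tv1\tA\tT\t.\t.\t.\tGT\t0/1\t1/1\n")
        g = read_genotypes(p, "vcf")
        assert g.freq[0, 0] == pytest.approx(0.5)  # dosage 1 over ploidy 2
        assert g.freq[1, 0] == pytest.approx(1.0)

    def test_multiallelic_rejected_with_report(self, tmp_path):
        p = self._write(tmp_path,
                        "1\t10\tv1\tA\tT,G\t.\t.\t.\tGT\t0/1\t1/1\n"
                        "1\t20\tv2\tA\tT\t.\t.\t.\tGT\t0/1\t0/0\n")
        g = read_genotypes(p, "vcf")
        assert g.n_markers == 1
        assert g.rejected_markers[0][0] == "v1"


class TestTrials:
    def test_read_counts(self, tmp_path):
        p = tmp_path / "t.csv"
        rows = ["variety,environment,group,characteristic,value"]
        for v in ("a", "b"):
            for y in ("Y1", "Y2", "Y3"):
                rows.append(f"{v},{y},2x,height,{1.0}")
        p.write_text("\n".join(rows) + "\n")
        t = read_trials(p)
        assert len(t.df) == 6

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("variety,environment,group,characteristic,value\n"
                     "a,DE,DE,height,3\na,DE,DE,height,5\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_trials(p, layout="wheat")

    def test_empty_value_names_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("variety,environment,group,characteristic,value\n"
                     "a,Y1,2x,height,\n")
        with pytest.raises(ValidationError, match="line 2"):
            read_trials(p)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("variety,environment,characteristic,value\na,Y1,h,1\n")
        with pytest.raises(SchemaError):
            read_trials(p)

    def test_round_trip(self, small_trials, tmp_path):
        write_trials(small_trials, tmp_path / "t.csv")
        back = read_trials(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(back.df, small_trials.df)

    def test_mask_variety_removes_only_target(self, small_trials):
        v = small_trials.varieties[0]
        masked = small_trials.mask_variety(v, "trait_1")
        sub = masked.df[(masked.df.variety == v)]
        assert set(sub.characteristic) == {"trait_2"}


class TestMatrixIO:
    def test_round_trip_identity(self, tmp_path):
        write_matrix(["a", "b"], np.eye(2), tmp_path / "m.csv")
        labels, vals = read_matrix(tmp_path / "m.csv")
        assert labels == ["a", "b"]
        np.testing.assert_array_equal(vals, np.eye(2))

    def test_labels_with_commas_quoted(self, tmp_path):
        labels = ["x, one", "y"]
        m = np.array([[1.0, 0.25], [0.25, 2.0]])
        write_matrix(labels, m, tmp_path / "m.csv")
        back_labels, back = read_matrix(tmp_path / "m.csv")
        assert back_labels == labels
        np.testing.assert_array_equal(back, m)

    def test_non_square_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_matrix(["a", "b"], np.zeros((2, 3)), tmp_path / "m.csv")

    @settings(max_examples=25, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(n=st.integers(2, 6), seed=st.integers(0, 2 ** 31 - 1))
    def test_round_trip_exact_on_random_matrices(self, tmp_path, n, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(n, n))
        m = m + m.T
        path = tmp_path / f"m{n}_{seed % 1000}.csv"
        write_matrix([f"v{i}" for i in range(n)], m, path)
        _, back = read_matrix(path)
        np.testing.assert_allclose(back, m, atol=1e-12)


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(layout="wheat", alpha=0.05, seed=42)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = RunConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    @pytest.mark.parametrize("kw", [
        {"alpha": 0.0}, {"alpha": 1.5}, {"note_threshold": 0},
        {"lsd_years": 0}, {"n_sim": 0}, {"layout": "barley"},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValidationError):
            RunConfig(**kw)

    def test_unknown_yaml_key_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("alpha: 0.01\nbogus: 1\n")
        with pytest.raises(SchemaError):
            RunConfig.from_yaml(tmp_path / "c.yaml")
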