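import numpy as np
import pandas as pd
import pytest

import gselect as gs
from gselect.data_io import DataFormatError, MISSING


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestPlinkText:
    def test_minor_allele_coding(self, tmp_path):
        ped = _write(tmp_path, "x.ped",
                     "f1 a1 0 0 0 -9 A A\n"
                     "f2 a2 0 0 0 -9 A G\n"
                     "f3 a3 0 0 0 -9 A A\n")
        mp = _write(tmp_path, "x.map", "1 snp1 0 100\n")
        gm = gs.read_plink_text(ped, mp)
        # G is the minor allele: A A -> 0 copies, A G -> 1 copy
        assert gm.map.allele_b[0] == "G" and gm.map.allele_a[0] == "A"
        assert list(gm.calls[:, 0]) == [0, 1, 0]

    def test_missing_pair(self, tmp_path):
        ped = _write(tmp_path, "x.ped",
                     "f a1 0 0 0 -9 A G\nf a2 0 0 0 -9 0 0\nf a3 0 0 0 -9 G G\n")
        mp = _write(tmp_path, "x.map", "1 snp1 0 100\n")
        gm = gs.read_plink_text(ped, mp)
        assert gm.calls[1, 0] == MISSING

    def test_ragged_line_names_line(self, tmp_path):
        ped = _write(tmp_path, "x.ped", "f a1 0 0 0 -9 A G\nf a2 0 0 0 -9 A\n")
        mp = _write(tmp_path, "x.map", "1 snp1 0 100\n")
        with pytest.raises(DataFormatError, match="line 2"):
            gs.read_plink_text(ped, mp)

    def test_non_biallelic_names_snp(self, tmp_path):
        ped = _write(tmp_path, "x.ped",
                     "f a1 0 0 0 -9 A G\nf a2 0 0 0 -9 C C\n")
        mp = _write(tmp_path, "x.map", "1 snpX 0 100\n")
        with pytest.raises(DataFormatError, match="snpX"):
            gs.read_plink_text(ped, mp)

    def test_text_round_trip(self, tmp_path, small_geno):
        gs.write_plink_text(small_geno, tmp_path / "r.ped", tmp_path / "r.map")
        back = gs.read_plink_text(tmp_path / "r.ped", tmp_path / "r.map")
        assert list(back.animal_ids) == list(small_geno.animal_ids)
        assert (back.calls == small_geno.calls).all()
        assert list(back.map.allele_b) == list(small_geno.map.allele_b)


class TestPlinkBinary:
    def test_binary_matches_text(self, tmp_path, small_geno):
        gs.write_plink_text(small_geno, tmp_path / "r.ped", tmp_path / "r.map")
        gs.write_plink_binary(small_geno, tmp_path / "r.bed", tmp_path / "r.bim",
                              tmp_path / "r.fam")
        gt = gs.read_plink_text(tmp_path / "r.ped", tmp_path / "r.map")
        gb = gs.read_plink_binary(tmp_path / "r.bed", tmp_path / "r.bim",
                                  tmp_path / "r.fam")
        assert (gt.calls == gb.calls).all()
        assert list(gt.map.snp_id) == list(gb.map.snp_id)

    def test_bad_magic(self, tmp_path, small_geno):
        gs.write_plink_binary(small_geno, tmp_path / "r.bed", tmp_path / "r.bim",
                              tmp_path / "r.fam")
        raw = (tmp_path / "r.bed").read_bytes()
        (tmp_path / "r.bed").write_bytes(b"\x00\x00" + raw[2:])
        with pytest.raises(DataFormatError, match="magic"):
            gs.read_plink_binary(tmp_path / "r.bed", tmp_path / "r.bim", tmp_path / "r.fam")

    def test_individual_major_rejected(self, tmp_path, small_geno):
        gs.write_plink_binary(small_geno, tmp_path / "r.bed", tmp_path / "r.bim",
                              tmp_path / "r.fam")
        raw = (tmp_path / "r.bed").read_bytes()
        (tmp_path / "r.bed").write_bytes(raw[:2] + b"\x00" + raw[3:])
        with pytest.raises(DataFormatError, match="individual-major"):
            gs.read_plink_binary(tmp_path / "r.bed", tmp_path / "r.bim", tmp_path / "r.fam")

    def test_truncated_reports_byte_counts(self, tmp_path, small_geno):
        gs.write_plink_binary(small_geno, tmp_path / "r.bed", tmp_path / "r.bim",
                              tmp_path / "r.fam")
        raw = (tmp_path / "r.bed").read_bytes()
        (tmp_path / "r.bed").write_bytes(raw[:-3])
        with pytest.raises(DataFormatError, match="expected"):
            gs.read_plink_binary(tmp_path / "r.bed", tmp_path / "r.bim", tmp_path / "r.fam")

    def test_all_missing_column(self, tmp_path):
        gm = gs.GenotypeMatrix(
            np.array(["a1", "a2"], dtype=object),
            np.array([[MISSING, 1], [MISSING, 2]], dtype=np.int8),
            gs.MarkerMap(["s1", "s2"], ["1", "1"], [100, 200], ["A", "A"], ["G", "G"]))
        gs.write_plink_binary(gm, tmp_path / "m.bed", tmp_path / "m.bim", tmp_path / "m.fam")
        back = gs.read_plink_binary(tmp_path / "m.bed", tmp_path / "m.bim", tmp_path / "m.fam")
        assert (back.calls[:, 0] == MISSING).all()
        assert (back.calls == gm.calls).all()


class TestPedigreePhenotypes:
    def test_trio(self, tmp_path, trio_pedigree):
        gs.write_pedigree(trio_pedigree, tmp_path / "p.csv")
        ped = gs.read_pedigree(tmp_path / "p.csv")
        assert len(ped) == 3 and len(ped.founders()) == 2

    def test_cycle_detected(self, tmp_path):
        _write(tmp_path, "c.csv", "animal,sire,dam\nA,B,0\nB,A,0\n")
        with pytest.raises(DataFormatError, match="cyclic"):
            gs.read_pedigree(tmp_path / "c.csv")

    def test_duplicate_animal(self, tmp_path):
        _write(tmp_path, "d.csv", "animal,sire,dam\nA,0,0\nA,0,0\n")
        with pytest.raises(DataFormatError, match="duplicate"):
            gs.read_pedigree(tmp_path / "d.csv")

    def test_naipc_below_one_rejected(self, tmp_path):
        _write(tmp_path, "ph.csv",
               "animal_id,afc,ci,gl,naipc,herd,birth_year,birth_season,"
               "calving_year,calving_season\n"
               "a1,700,,290,0,h1,2018,1,2020,2\n")
        with pytest.raises(DataFormatError, match="naipc"):
            gs.read_phenotypes(tmp_path / "ph.csv")

    def test_phenotype_round_trip(self, tmp_path):
        ds = gs.simulate_trait(None, gs.simulate_pedigree(6, 1, 2, seed=2),
                               gs.TRAIT_PRESETS["gl"], seed=3)
        gs.write_phenotypes(ds.phenotypes, tmp_path / "ph.csv")
        back = gs.read_phenotypes(tmp_path / "ph.csv")
        pd.testing.assert_frame_equal(back.frame, ds.phenotypes.frame)


class TestDescribe:
    def _table(self, gl_values):
        n = len(gl_values)
        return gs.PhenotypeTable(pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(n)],
            "gl": gl_values, "herd": "h1", "birth_year": "y", "birth_season": "s",
            "calving_year": "y", "calving_season": "s"}))

    def test_basic_moments(self):
        d = gs.describe_phenotypes(self._table([1.0, 2.0, 3.0]))
        row = d.loc["gl"]
        assert row["n"] == 3 and row["mean"] == 2.0 and row["sd"] == 1.0
        assert row["min"] == 1.0 and row["max"] == 3.0
        assert d.loc["afc", "n"] == 0 and np.isnan(d.loc["afc", "mean"])

    def test_single_value_sd_blank(self):
        d = gs.describe_phenotypes(self._table([5.0]))
        row = d.loc["gl"]
        assert np.isnan(row["sd"]) and row["min"] == row["max"] == row["mean"] == 5.0

    def test_row_order_invariance(self):
        vals = list(np.random.default_rng(0).normal(280, 5, 30))
        a = gs.describe_phenotypes(self._table(vals))
        b = gs.describe_phenotypes(self._table(vals[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_afc_archetype_matches_target_envelope(self):
        ds = gs.simulate_trait(gs.simulate_genotypes(4000, 400, seed=5)[0], None,
                               gs.TRAIT_PRESETS["afc"], seed=6)
        d = gs.describe_phenotypes(ds.phenotypes)
        assert d.loc["afc", "mean"] == pytest.approx(736.18, rel=0.02)
        assert d.loc["afc", "sd"] == pytest.approx(64.43, rel=0.02)
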