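import numpy as np
import pandas as pd
import pytest

import gselect as gs
from gselect.evaluation import EvaluationError


class TestFolds:
    def test_equal_sizes(self):
        plans = gs.make_folds([f"a{i}" for i in range(10)], k=5, repetitions=1, seed=0)
        sizes = plans[0].assignment.value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]

    def test_near_equal_sizes(self):
        plans = gs.make_folds([f"a{i}" for i in range(11)], k=5, repetitions=1, seed=0)
        assert sorted(plans[0].assignment.value_counts()) == [2, 2, 2, 2, 3]

    def test_partition_and_determinism(self):
        ids = [f"a{i}" for i in range(23)]
        p1 = gs.make_folds(ids, k=5, repetitions=3, seed=7)
        p2 = gs.make_folds(ids, k=5, repetitions=3, seed=7)
        for a, b in zip(p1, p2):
            assert (a.assignment == b.assignment).all()
        covered = set()
        for f in range(1, 6):
            covered |= set(p1[0].validation_ids(f))
        assert covered == set(ids)

    def test_k_exceeds_n(self):
        with pytest.raises(EvaluationError):
            gs.make_folds(["a", "b"], k=5)


class TestAccuracy:
    def test_identity_and_sign(self):
        y = np.array([1.0, 2, 3, 4, 5])
        assert gs.accuracy(y, y, 1.0) == pytest.approx(1.0)
        assert gs.accuracy(y, -y, 1.0) == pytest.approx(-1.0)

    def test_frozen_oracle_example(self):
        # Pearson r computed independently: r = 0.9919760044691721
        y = [1, 2, 3, 4, 5]
        g = [1.1, 1.9, 3.2, 3.7, 5.1]
        assert gs.accuracy(y, g, 0.25) == pytest.approx(1.9839520089383442, rel=1e-9)

    def test_can_exceed_one_not_clipped(self):
        y = np.array([1.0, 2, 3, 4, 5])
        assert gs.accuracy(y, y, 0.25) == pytest.approx(2.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        y, g = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        a = gs.accuracy(y, g, 0.5)
        assert gs.accuracy(y, 3.0 * g + 7.0, 0.5) == pytest.approx(a)

    def test_errors(self):
        with pytest.raises(EvaluationError):
            gs.accuracy([1, 2, 3], [1, 1, 1], 0.5)
        with pytest.raises(EvaluationError):
            gs.accuracy([1, 2, 3], [1, 2, 3], 0.0)


class TestBias:
    def test_slopes(self):
        g = np.array([1.0, 2, 3, 4])
        assert gs.bias_slope(g, g) == pytest.approx(1.0)
        assert gs.bias_slope(2 * g, g) == pytest.approx(2.0)

    def test_not_scale_invariant(self):
        g = np.array([1.0, 2, 3, 4])
        assert gs.bias_slope(g, 2 * g) == pytest.approx(0.5)

    def test_uncorrelated_near_zero(self):
        rng = np.random.default_rng(1)
        y, g = rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)
        assert abs(gs.bias_slope(y, g)) < 0.1

    def test_zero_variance_error(self):
        with pytest.raises(EvaluationError):
            gs.bias_slope([1, 2, 3], [1, 1, 1])


class TestGenomicH2:
    def test_printed_afc_examples(self):
        h2 = gs.pedigree_h2_from_components(284.06, 3756.37)
        hg2_gblup, ratio = gs.genomic_h2(h2, 156.09, 284.06)
        assert round(hg2_gblup, 3) == 0.039 and ratio == pytest.approx(0.55, abs=0.005)
        hg2_bayesr, _ = gs.genomic_h2(h2, 167.33, 284.06)
        assert round(hg2_bayesr, 3) == 0.041

    def test_ratio_one(self):
        hg2, ratio = gs.genomic_h2(0.07, 3.0, 3.0)
        assert hg2 == pytest.approx(0.07) and ratio == 1.0

    def test_zero_sigma_a2(self):
        with pytest.raises(EvaluationError):
            gs.genomic_h2(0.07, 1.0, 0.0)


@pytest.fixture(scope="module")
def cv_fixture():
    gm, _ = gs.simulate_genotypes(150, 300, seed=30)
    G = gs.build_grm(gm)
    ds = gs.simulate_trait(gm, None,
                           gs.TraitSpec("gl", mean=287, sd=5, h2=0.4,
                                        min_value=260, max_value=320),
                           seed=31)
    y = ds.phenotypes.frame.set_index("animal_id")["gl"]
    yc = (y - y.mean()).rename("gl")
    return gm, G, yc


class TestCrossValidate:
    def test_deterministic_and_aggregates(self, cv_fixture):
        gm, G, yc = cv_fixture
        folds = gs.make_folds(list(yc.index), 5, 2, seed=5)
        a = gs.cross_validate(yc, "gblup", folds, 0.4, G=G, gblup_variances=(10, 15))
        b = gs.cross_validate(yc, "gblup", folds, 0.4, G=G, gblup_variances=(10, 15))
        pd.testing.assert_frame_equal(a.records, b.records)
        ok = a.records[a.records["ok"]]
        assert a.mean_accuracy == pytest.approx(ok["accuracy"].mean())
        per_rep = ok.groupby("repetition")["accuracy"].agg(
            lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        assert a.empirical_se == pytest.approx(per_rep.mean())
        assert a.completeness == 1.0

    def test_unknown_method(self, cv_fixture):
        _, G, yc = cv_fixture
        folds = gs.make_folds(list(yc.index), 5, 1, seed=5)
        with pytest.raises(EvaluationError, match="unknown method"):
            gs.cross_validate(yc, "ridge", folds, 0.4, G=G)

    def test_strong_signal_fixture_high_accuracy(self):
        # yc equal to the true breeding values: GBLUP should track them closely
        gm, _ = gs.simulate_genotypes(300, 150, seed=32)
        G = gs.build_grm(gm)
        ds = gs.simulate_trait(gm, None,
                               gs.TraitSpec("gl", mean=287, sd=5, h2=0.9,
                                            min_value=260, max_value=320),
                               seed=33)
        yc = ds.breeding_values.rename("gl")
        folds = gs.make_folds(list(yc.index), 5, 2, seed=6)
        res = gs.cross_validate(yc, "gblup", folds, 1.0, G=G,
                                gblup_variances=(float(yc.var()), 1e-3))
        assert res.mean_accuracy > 0.9


class TestReports:
    def test_tables_and_consistency(self, cv_fixture, tmp_path):
        gm, G, yc = cv_fixture
        folds = gs.make_folds(list(yc.index), 5, 1, seed=5)
        cv = gs.cross_validate(yc, "gblup", folds, 0.4, G=G, gblup_variances=(10, 15))
        est = gs.fit_reml(yc.to_numpy(), np.ones((len(yc), 1)), G, ids=list(yc.index))
        tables = gs.report_tables(variance_estimates={"gl": est},
                                  genomic_variances={("gblup", "gl"): 11.0},
                                  cv_results=[cv])
        assert len(tables["accuracy"]) == 1
        gh = tables["genomic_heritability"].iloc[0]
        assert gh["hg2"] == pytest.approx(est.h2 * gh["ratio"], abs=1e-12)
        assert gh["ratio"] == pytest.approx(gh["sigma_g2"] / est.sigma_a2)
        paths = gs.write_report(tables, tmp_path / "r1")
        first = {p.name: p.read_bytes() for p in paths}
        paths2 = gs.write_report(tables, tmp_path / "r2")
        for p in paths2:
            assert p.read_bytes() == first[p.name]
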