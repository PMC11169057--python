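"""The four network-inference scorers and their oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modnet import datasets
from modnet.inference import (
    InferenceMatrix,
    build_inference_matrix,
    aracne,
    clr,
    lars_stability,
    mi_matrix,
    mutual_information,
    run_all_methods,
    schafer_strimmer_lambda,
    shrinkage_pcor,
    spearman_score,
)
from tests.conftest import log_fpkm


def _imat(n_modules=3, n_tfs=4, n_cols=8, seed=0):
    rng = np.random.default_rng(seed)
    mods = pd.DataFrame(
        rng.normal(size=(n_modules, n_cols)),
        index=range(1, n_modules + 1),
        columns=[f"L{j}" for j in range(n_cols)],
    )
    tfs = pd.DataFrame(
        rng.normal(size=(n_tfs, n_cols)),
        index=[f"TF{i:03d}" for i in range(n_tfs)],
        columns=mods.columns,
    )
    return build_inference_matrix(mods, tfs)


class TestBuildInferenceMatrix:
    def test_paper_scale_row_arithmetic(self):
        # 82 module profiles stacked over 954 DE TF profiles on 6 lines
        cols = [f"L{j}" for j in range(6)]
        mods = pd.DataFrame(np.zeros((82, 6)), index=range(1, 83), columns=cols)
        tfs = pd.DataFrame(
            np.ones((954, 6)),
            index=[f"Glyma.{i:05d}" for i in range(954)],
            columns=cols,
        )
        m = build_inference_matrix(mods, tfs)
        assert m.values.shape == (1036, 6)
        assert m.n_modules == 82
        assert m.n_tfs == 954
        assert (m.row_kind == "module").sum() == 82
        assert (m.row_kind == "tf").sum() == 954

    def test_only_de_tfs_retained(self):
        m = _imat(n_tfs=5)
        mods = m.values.loc[m.module_ids]
        tfs = m.values.loc[m.tf_ids]
        sub = build_inference_matrix(mods, tfs, de_tf_ids={"TF001", "TF003"})
        assert sub.tf_ids == ["TF001", "TF003"]

    def test_empty_tf_set_warns(self):
        m = _imat()
        with pytest.warns(UserWarning, match="no differentially expressed TFs"):
            build_inference_matrix(
                m.values.loc[m.module_ids], m.values.loc[m.tf_ids], de_tf_ids=set()
            )

    def test_column_mismatch_reported(self):
        m = _imat()
        tfs = m.values.loc[m.tf_ids].rename(columns={"L0": "LX"})
        with pytest.raises(ValueError, match="columns differ"):
            build_inference_matrix(m.values.loc[m.module_ids], tfs)


class TestMutualInformation:
    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        mis = [
            mutual_information(rng.normal(size=200), rng.normal(size=200))
            for _ in range(50)
        ]
        assert np.median(mis) < 0.05

    def test_identity_reaches_estimator_maximum(self):
        x = np.random.default_rng(1).normal(size=50)
        mi = mutual_information(x, x)
        assert mi == pytest.approx(-0.5 * np.log1p(-(1 - 1e-12) ** 2))

    def test_binned_2x2_perfect_association_is_ln2(self):
        # balanced two-level variables, perfectly associated
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]) + np.arange(6) * 1e-6
        y = x * 10
        mi = mutual_information(x, y, estimator="binned", bins=2)
        assert mi == pytest.approx(np.log(2), rel=1e-6)

    def test_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        a = mutual_information(x, y)
        assert a == pytest.approx(mutual_information(y, x))
        assert a == pytest.approx(mutual_information(np.exp(x), y))
        assert a == pytest.approx(mutual_information(x, y**3))

    def test_constant_vector_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            mi = mutual_information(np.ones(10), np.arange(10.0))
        assert mi == 0.0

    def test_mi_matrix_symmetric_nonnegative(self):
        m = _imat(seed=3)
        mi = mi_matrix(m.values)
        v = mi.to_numpy()
        assert np.allclose(v, v.T)
        assert (v >= 0).all()
        assert np.allclose(np.diag(v), 0)


def _brute_force_dpi(M, tol):
    n = M.shape[0]
    keep = np.ones((n, n), dtype=bool)
    for i, j, k in itertools.permutations(range(n), 3):
        if i < j and M[i, j] < min(M[i, k], M[j, k]) - tol:
            keep[i, j] = keep[j, i] = False
    return np.where(keep, M, 0.0)


class TestAracne:
    def test_triangle_weakest_edge_removed(self):
        ids = ["A", "B", "C"]
        M = pd.DataFrame(
            [[0, 0.9, 0.3], [0.9, 0, 0.8], [0.3, 0.8, 0]], index=ids, columns=ids
        )
        matrix = InferenceMatrix(
            values=pd.DataFrame(np.zeros((3, 4)), index=ids),
            module_ids=["A"],
            tf_ids=["B", "C"],
        )
        out = aracne(M, matrix).values
        assert out.loc["B", "A"] == pytest.approx(0.9)
        assert out.loc["C", "A"] == 0.0

    def test_large_tolerance_keeps_everything(self):
        rng = np.random.default_rng(4)
        n = 6
        M = rng.uniform(0, 1, (n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        ids = [f"N{i}" for i in range(n)]
        Mdf = pd.DataFrame(M, index=ids, columns=ids)
        matrix = InferenceMatrix(
            values=pd.DataFrame(np.zeros((n, 4)), index=ids),
            module_ids=ids[:2],
            tf_ids=ids[2:],
        )
        out = aracne(Mdf, matrix, dpi_tolerance=2.0).values
        assert np.allclose(out.to_numpy(), Mdf.loc[ids[2:], ids[:2]].to_numpy())

    def test_matches_exhaustive_triangle_oracle(self):
        rng = np.random.default_rng(5)
        for rep in range(20):
            n = 8
            M = rng.uniform(0, 1, (n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0)
            ids = [f"N{i}" for i in range(n)]
            Mdf = pd.DataFrame(M, index=ids, columns=ids)
            matrix = InferenceMatrix(
                values=pd.DataFrame(np.zeros((n, 4)), index=ids),
                module_ids=ids[:3],
                tf_ids=ids[3:],
            )
            got = aracne(Mdf, matrix).values.to_numpy()
            want = _brute_force_dpi(M, 0.0)[3:, :3]
            assert np.allclose(got, want)


class TestClr:
    def test_hand_computed_four_node_scores(self):
        ids = ["m1", "t1", "t2", "t3"]
        M = np.array(
            [
                [0.0, 0.6, 0.2, 0.1],
                [0.6, 0.0, 0.3, 0.2],
                [0.2, 0.3, 0.0, 0.4],
                [0.1, 0.2, 0.4, 0.0],
            ]
        )
        Mdf = pd.DataFrame(M, index=ids, columns=ids)
        matrix = InferenceMatrix(
            values=pd.DataFrame(np.zeros((4, 4)), index=ids),
            module_ids=["m1"],
            tf_ids=["t1", "t2", "t3"],
        )
        got = clr(Mdf, matrix).values
        # independent recomputation with explicit loops
        for i, ti in enumerate(ids):
            for j, tj in enumerate(ids):
                if ti == "m1" or tj != "m1":
                    continue
                bg_i = np.delete(M[i], i)
                bg_j = np.delete(M[j], j)
                zi = max(0.0, (M[i, j] - bg_i.mean()) / bg_i.std())
                zj = max(0.0, (M[i, j] - bg_j.mean()) / bg_j.std())
                assert got.loc[ti, tj] == pytest.approx(np.hypot(zi, zj))

    def test_constant_background_contributes_zero(self):
        ids = ["m1", "t1", "t2"]
        M = pd.DataFrame(
            [[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]],
            index=ids,
            columns=ids,
        )
        matrix = InferenceMatrix(
            values=pd.DataFrame(np.zeros((3, 4)), index=ids),
            module_ids=["m1"],
            tf_ids=["t1", "t2"],
        )
        with pytest.warns(UserWarning, match="constant MI background"):
            out = clr(M, matrix).values
        assert (out.to_numpy() == 0).all()

    def test_scores_nonnegative(self):
        m = _imat(seed=6)
        mi = mi_matrix(m.values)
        assert (clr(mi, m).values.to_numpy() >= 0).all()


class TestLarsStability:
    def test_frequencies_in_unit_interval(self):
        m = _imat(n_modules=2, n_tfs=6, n_cols=12, seed=7)
        f = lars_stability(m, 1, n_resamples=30, seed=0)
        assert ((f >= 0) & (f <= 1)).all()

    def test_planted_strong_regulator_found(self):
        rng = np.random.default_rng(8)
        n_cols, n_tfs = 50, 30
        tfs = rng.normal(size=(n_tfs, n_cols))
        target = 2.0 * tfs[4] + 0.1 * rng.normal(size=n_cols)
        cols = [f"L{j}" for j in range(n_cols)]
        mods = pd.DataFrame([target], index=[1], columns=cols)
        tf_df = pd.DataFrame(
            tfs, index=[f"TF{i:03d}" for i in range(n_tfs)], columns=cols
        )
        m = build_inference_matrix(mods, tf_df)
        f = lars_stability(m, 1, n_resamples=50, seed=1)
        assert f["TF004"] >= 0.9
        assert f.idxmax() == "TF004"

    def test_zero_variance_tf_never_selected(self):
        rng = np.random.default_rng(9)
        cols = [f"L{j}" for j in range(20)]
        mods = pd.DataFrame(rng.normal(size=(1, 20)), index=[1], columns=cols)
        tfs = pd.DataFrame(
            np.vstack([np.zeros(20), rng.normal(size=(3, 20))]),
            index=["TFflat", "TFa", "TFb", "TFc"],
            columns=cols,
        )
        m = build_inference_matrix(mods, tfs)
        f = lars_stability(m, 1, n_resamples=40, seed=2)
        assert f["TFflat"] == 0.0

    def test_steps_capped_with_warning(self):
        m = _imat(n_modules=1, n_tfs=3, n_cols=10, seed=10)
        with pytest.warns(UserWarning, match="capped"):
            lars_stability(m, 1, n_resamples=5, n_steps=10, seed=0)

    def test_deterministic_given_seed(self):
        m = _imat(n_modules=2, n_tfs=5, n_cols=15, seed=11)
        a = lars_stability(m, 2, n_resamples=25, seed=3)
        b = lars_stability(m, 2, n_resamples=25, seed=3)
        pd.testing.assert_series_equal(a, b)


class TestShrinkagePcor:
    def test_two_variables_pcor_equals_cor(self):
        rng = np.random.default_rng(12)
        cols = [f"L{j}" for j in range(30)]
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        mods = pd.DataFrame([x], index=[1], columns=cols)
        tfs = pd.DataFrame([y], index=["TF001"], columns=cols)
        m = build_inference_matrix(mods, tfs)
        # with two variables the standardized inverse gives back |cor|
        # regardless of the shrinkage intensity applied to the off-diagonal
        got = shrinkage_pcor(m, shrinkage=0.0).values.loc["TF001", 1]
        assert got == pytest.approx(abs(np.corrcoef(x, y)[0, 1]))

    def test_lambda_zero_matches_precision_matrix_oracle(self):
        rng = np.random.default_rng(13)
        n, p = 40, 5
        data = rng.normal(size=(p, n))
        cols = [f"L{j}" for j in range(n)]
        mods = pd.DataFrame(data[:2], index=[1, 2], columns=cols)
        tfs = pd.DataFrame(
            data[2:], index=[f"TF{i:03d}" for i in range(3)], columns=cols
        )
        m = build_inference_matrix(mods, tfs)
        got = shrinkage_pcor(m, shrinkage=0.0).values
        omega = np.linalg.inv(np.corrcoef(data))
        d = np.sqrt(np.diag(omega))
        pcor = np.abs(-omega / np.outer(d, d))
        for i in range(3):
            for j in range(2):
                assert got.iloc[i, j] == pytest.approx(pcor[2 + i, j], abs=1e-9)

    def test_analytic_lambda_clipped_to_unit_interval(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            v = rng.normal(size=(10, 6))
            lam = schafer_strimmer_lambda(v)
            assert 0.0 <= lam <= 1.0

    def test_scores_bounded_by_one(self):
        m = _imat(n_modules=4, n_tfs=6, n_cols=6, seed=15)
        out = shrinkage_pcor(m).values.to_numpy()
        assert (out <= 1.0 + 1e-12).all()


class TestRunAllMethods:
    def test_four_methods_identical_shapes(self):
        m = _imat(n_modules=3, n_tfs=5, n_cols=10, seed=16)
        out = run_all_methods(m, lars_resamples=20, seed=0)
        assert [sm.method for sm in out] == ["aracne", "clr", "lars", "pcor"]
        shapes = {sm.values.shape for sm in out}
        assert shapes == {(5, 3)}
        assert all(sm.orientation == "higher=stronger" for sm in out)

    def test_disabling_a_method_drops_it(self):
        m = _imat(seed=17)
        out = run_all_methods(m, methods=("clr", "pcor"), seed=0)
        assert [sm.method for sm in out] == ["clr", "pcor"]

    def test_fifth_spearman_method_available(self):
        m = _imat(seed=18)
        out = run_all_methods(
            m, methods=("aracne", "clr", "lars", "pcor", "spearman"),
            lars_resamples=10, seed=0,
        )
        assert len(out) == 5
        sp = out[-1].values.to_numpy()
        assert ((sp >= 0) & (sp <= 1)).all()

    def test_unknown_method_rejected(self):
        m = _imat(seed=19)
        with pytest.raises(ValueError, match="unknown"):
            run_all_methods(m, methods=("aracne", "genie3"))

    def test_aracne_never_scores_zero_mi_pairs(self):
        m = _imat(seed=20)
        mi = mi_matrix(m.values)
        ar = aracne(mi, m).values
        zero_mi = mi.loc[m.tf_ids, m.module_ids].to_numpy() == 0
        assert (ar.to_numpy()[zero_mi] == 0).all()


def test_methods_separate_true_edges_from_null_pairs(wide_ds):
    """On informative synthetic data every method scores planted edges above
    null pairs (median comparison)."""
    ds = wide_ds
    expr = log_fpkm(ds)
    prof = expr.loc[ds.module_membership.index].groupby(ds.module_membership).mean()
    m = build_inference_matrix(prof, expr.loc[ds.tf_ids])
    out = run_all_methods(m, lars_resamples=50, seed=0)
    truth = ds.truth.weight_matrix() != 0
    for sm in out:
        v = sm.values.to_numpy()
        assert np.median(v[truth]) > np.median(v[~truth]), sm.method
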