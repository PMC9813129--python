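"""Imputation, one-hot encoding and design-matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from trialterm.encoding import (
    AlignmentError,
    EncoderSpec,
    SchemaError,
    UnimputableFeatureError,
    assemble_design_matrix,
    fit_encoder,
    mice_fit_transform,
    mice_transform,
    one_hot,
)


def correlated_table(n=40, missing_at=(3,), seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 10, size=n)
    y = 2.0 * x
    df = pd.DataFrame({"x": x, "y": y})
    for i in missing_at:
        df.loc[i, "y"] = np.nan
    return df


class TestMiceFitTransform:
    def test_complete_table_identity_zero_iterations(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        done, model = mice_fit_transform(df)
        pd.testing.assert_frame_equal(done, df)
        assert model.n_iterations == 0 and model.converged

    def test_correlated_columns_closed_form(self):
        df = correlated_table()
        df.loc[3, "x"] = 3.0
        done, model = mice_fit_transform(df, tol=1e-4)
        assert done.loc[3, "y"] == pytest.approx(6.0, abs=1e-2)
        assert model.converged

    def test_observed_cells_never_modified(self):
        df = correlated_table(missing_at=(0, 7, 11))
        done, _ = mice_fit_transform(df)
        observed = ~df.isna()
        assert np.array_equal(done.to_numpy()[observed.to_numpy()],
                              df.to_numpy()[observed.to_numpy()])
        assert not done.isna().to_numpy().any()

    def test_deterministic(self):
        df = correlated_table(missing_at=(1, 5))
        a, _ = mice_fit_transform(df, seed=4)
        b, _ = mice_fit_transform(df, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_all_missing_column_raises(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(UnimputableFeatureError, match="b"):
            mice_fit_transform(df)

    def test_clamped_to_observed_range(self):
        df = correlated_table()
        done, model = mice_fit_transform(df, clamp=True)
        lo, hi = model.clamp_bounds["y"]
        assert done["y"].between(lo, hi).all()

    def test_agrees_with_sklearn_iterative_imputer(self):
        """Independent chained-equation implementation lands on imputations
        close to sklearn's IterativeImputer with a ridge estimator."""
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer
        from sklearn.linear_model import Ridge

        df = correlated_table(n=200, missing_at=(2, 9, 30, 77), seed=3)
        ours, _ = mice_fit_transform(df, tol=1e-5, max_iter=50, clamp=False)
        ref = IterativeImputer(estimator=Ridge(alpha=1e-3), max_iter=50,
                               tol=1e-5, initial_strategy="mean",
                               sample_posterior=False, random_state=0)
        theirs = ref.fit_transform(df)
        np.testing.assert_allclose(ours.to_numpy(), theirs, atol=1e-2)

    def test_beats_mean_imputation_on_mcar(self):
        rng = np.random.default_rng(42)
        n = 1000
        x = rng.normal(size=n)
        latent = np.column_stack([x, 2 * x + 0.1 * rng.normal(size=n),
                                  -x + 0.1 * rng.normal(size=n)])
        truth = pd.DataFrame(latent, columns=["a", "b", "c"])
        mask = rng.random(truth.shape) < 0.20
        holey = truth.mask(mask)
        done, _ = mice_fit_transform(holey)
        mice_rmse = np.sqrt(np.mean((done.to_numpy() - latent)[mask] ** 2))
        mean_filled = holey.fillna(holey.mean()).to_numpy()
        mean_rmse = np.sqrt(np.mean((mean_filled - latent)[mask] ** 2))
        assert mice_rmse < mean_rmse


class TestMiceTransform:
    def test_complete_rows_unchanged(self):
        df = correlated_table(missing_at=(2,))
        _, model = mice_fit_transform(df)
        test = pd.DataFrame({"x": [4.0], "y": [8.0]})
        pd.testing.assert_frame_equal(mice_transform(test, model), test)

    def test_uses_train_predictors(self):
        df = correlated_table(missing_at=(2,))
        _, model = mice_fit_transform(df, tol=1e-5)
        test = pd.DataFrame({"x": [5.0], "y": [np.nan]})
        assert mice_transform(test, model).loc[0, "y"] == pytest.approx(10.0, abs=0.05)

    def test_schema_mismatch_raises(self):
        df = correlated_table()
        _, model = mice_fit_transform(df)
        bad = pd.DataFrame({"x": [1.0], "y": [2.0], "z": [3.0]})
        with pytest.raises(SchemaError):
            mice_transform(bad, model)


class TestOneHot:
    def test_basic_encoding(self):
        df = pd.DataFrame({"f": ["A", "B", "A"]})
        m, spec = one_hot(df)
        assert spec.column_names == ["f=A", "f=B"]
        assert m.toarray().tolist() == [[1, 0], [0, 1], [1, 0]]

    def test_missing_encodes_as_zeros(self):
        df = pd.DataFrame({"f": ["A", None, "B"]})
        m, _ = one_hot(df)
        assert m.toarray()[1].tolist() == [0, 0]

    def test_unseen_level_encodes_as_zeros(self):
        spec = fit_encoder(pd.DataFrame({"f": ["A", "B"]}))
        m, _ = one_hot(pd.DataFrame({"f": ["C"]}), spec)
        assert m.toarray().tolist() == [[0, 0]]

    def test_per_feature_row_sums_at_most_one(self):
        df = pd.DataFrame({"f": ["A", None, "B"], "g": ["x", "y", None]})
        m, spec = one_hot(df)
        arr = m.toarray()
        assert set(arr[:, :2].sum(axis=1)) <= {0, 1}
        assert set(arr[:, 2:].sum(axis=1)) <= {0, 1}


class TestAssembleDesignMatrix:
    def blocks(self):
        ids = ["A", "B", "C"]
        return {
            "char": (ids, ["e", "s"], np.arange(6).reshape(3, 2)),
            "term": (ids, ["t0", "t1", "t2"], sparse.eye(3, 3, format="csr")),
        }

    def test_column_additivity_and_namespacing(self):
        dm = assemble_design_matrix(self.blocks(), {"A": 1, "B": 0, "C": 1})
        assert dm.shape == (3, 5)
        assert dm.column_names == ["char:e", "char:s", "term:t0", "term:t1", "term:t2"]
        assert dm.y.tolist() == [1, 0, 1]

    def test_permuted_block_realigned_by_id(self):
        blocks = self.blocks()
        perm = (["C", "A", "B"], ["t0", "t1", "t2"],
                sparse.eye(3, 3, format="csr")[[2, 0, 1]])
        blocks["term"] = perm
        a = assemble_design_matrix(self.blocks(), {"A": 1, "B": 0, "C": 1})
        b = assemble_design_matrix(blocks, {"A": 1, "B": 0, "C": 1})
        assert (a.X != b.X).nnz == 0

    def test_missing_id_in_block_raises(self):
        blocks = self.blocks()
        blocks["term"] = (["A", "B"], ["t0"], sparse.eye(2, 1, format="csr"))
        with pytest.raises(AlignmentError, match="term"):
            assemble_design_matrix(blocks, {"A": 1, "B": 0, "C": 1})
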