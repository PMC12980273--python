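"""Tests of correlation-matrix PCA, Gaussian naive Bayes and MPS scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import pharmeeg as pe
from pharmeeg.errors import FitError, InputError, SchemaError
from pharmeeg.model import _pc_columns, loadings_frame


def frame_from(values, groups=None):
    values = np.asarray(values, float)
    df = pd.DataFrame(values, columns=[f"f{j}" for j in range(values.shape[1])])
    df.insert(0, "record_id", [f"r{i}" for i in range(len(df))])
    df.insert(1, "animal_id", [f"A{i}" for i in range(len(df))])
    df.insert(2, "group", groups if groups is not None else "G")
    return df


def scores_from(values, groups):
    values = np.asarray(values, float)
    df = pd.DataFrame(values, columns=[f"PC{j + 1}" for j in range(values.shape[1])])
    df.insert(0, "record_id", [f"r{i}" for i in range(len(df))])
    df.insert(1, "group", groups)
    return df


# ---------------------------------------------------------------------------
# PCA


@pytest.fixture(scope="module")
def random_effects():
    rng = np.random.default_rng(7)
    return frame_from(np.exp(0.2 * rng.standard_normal((20, 8))))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(13)
    df = frame_from(np.exp(0.3 * rng.standard_normal((25, 7))))
    return df, pe.pca_fit(df, k=7)


class TestPcaFit:
    def test_eigenvalue_sum_equals_feature_count(self, random_effects):
        model = pe.pca_fit(random_effects, k=6)
        assert model.eigenvalues.sum() == pytest.approx(8.0, abs=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-10)
        assert model.evr.sum() == pytest.approx(1.0, abs=1e-10)

    def test_loadings_columns_orthonormal(self, random_effects):
        model = pe.pca_fit(random_effects, k=6)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)

    def test_rank_one_data_concentrates_variance(self):
        rng = np.random.default_rng(1)
        latent = rng.standard_normal(30)
        data = np.outer(latent, rng.uniform(0.5, 2.0, size=10))
        data += 1e-4 * rng.standard_normal(data.shape)
        model = pe.pca_fit(frame_from(data), k=3)
        assert model.evr[0] > 0.99

    def test_matches_svd_oracle(self, random_effects):
        """Loadings and eigenvalues agree with an independent SVD of the
        standardised matrix (up to the sign convention)."""
        model = pe.pca_fit(random_effects, k=6)
        X = random_effects[[c for c in random_effects.columns if c.startswith("f")]].to_numpy()
        z = (X - X.mean(0)) / X.std(0, ddof=1)
        _, sv, vt = np.linalg.svd(z / np.sqrt(len(z) - 1), full_matrices=False)
        eig_oracle = sv**2
        np.testing.assert_allclose(model.eigenvalues[: len(eig_oracle)], eig_oracle, atol=1e-8)
        for j in range(6):
            v = vt[j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(model.loadings[:, j], v, atol=1e-8)

    def test_matches_sklearn_cross_check(self, random_effects):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        X = random_effects[[c for c in random_effects.columns if c.startswith("f")]].to_numpy()
        z = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = sklearn_pca(n_components=6).fit(z)
        model = pe.pca_fit(random_effects, k=6)
        np.testing.assert_allclose(
            model.eigenvalues[:6], ref.explained_variance_, atol=1e-8
        )

    def test_near_constant_columns_dropped(self, random_effects):
        df = random_effects.copy()
        df["f0"] = 1.0
        model = pe.pca_fit(df, k=4)
        assert model.dropped_features == ["f0"]
        assert model.eigenvalues.sum() == pytest.approx(7.0, abs=1e-8)

    def test_too_few_records_rejected(self):
        rng = np.random.default_rng(0)
        df = frame_from(rng.standard_normal((4, 8)))
        with pytest.raises(FitError):
            pe.pca_fit(df, k=6)


class TestPcaProject:
    def test_training_mean_projects_to_zero(self, fitted):
        df, model = fitted
        feats = [c for c in df.columns if c.startswith("f")]
        mean_row = frame_from(df[feats].mean().to_numpy()[None, :])
        scores = pe.pca_project(model, mean_row)
        np.testing.assert_allclose(scores[model.pc_names].to_numpy(), 0.0, atol=1e-10)

    def test_full_rank_round_trip(self, fitted):
        df, model = fitted
        scores = pe.pca_project(model, df)[model.pc_names].to_numpy()
        z_back = scores @ model.loadings.T
        feats = [c for c in df.columns if c.startswith("f")]
        X = df[feats].to_numpy()
        z = (X - model.mean) / model.sd
        np.testing.assert_allclose(z_back, z, atol=1e-8)

    def test_training_score_variance_equals_eigenvalue(self, fitted):
        df, model = fitted
        scores = pe.pca_project(model, df)[model.pc_names].to_numpy()
        np.testing.assert_allclose(scores.var(axis=0, ddof=1), model.eigenvalues, atol=1e-8)

    def test_unknown_schema_rejected(self, fitted):
        df, model = fitted
        with pytest.raises(SchemaError):
            pe.pca_project(model, df.rename(columns={"f0": "weird"}))

    def test_loadings_frame_shape(self, fitted):
        _, model = fitted
        lf = loadings_frame(model)
        assert lf.shape == (7, 7)
        assert list(lf.columns) == model.pc_names


# ---------------------------------------------------------------------------
# naive Bayes


def nbc_oracle(model, scores):
    """Brute-force density product: per-class product of scipy.stats normal
    pdfs times the prior, normalised per record."""
    x = scores[model.pc_names].to_numpy(float)
    out = np.zeros((len(x), len(model.classes)))
    for ci, cls in enumerate(model.classes):
        dens = np.ones(len(x)) * model.priors[cls]
        for pj, pc in enumerate(model.pc_names):
            dens *= stats.norm.pdf(
                x[:, pj],
                loc=model.means.loc[cls, pc],
                scale=np.sqrt(model.variances.loc[cls, pc]),
            )
        out[:, ci] = dens
    return out / out.sum(axis=1, keepdims=True)


class TestNbc:
    def test_hand_computed_toy_fit(self):
        """Means/variances equal hand arithmetic on a 4-record table."""
        scores = scores_from([[1.0], [3.0], [10.0], [14.0]], ["A", "A", "B", "B"])
        model = pe.nbc_fit(scores)
        assert model.means.loc["A", "PC1"] == pytest.approx(2.0)
        assert model.variances.loc["A", "PC1"] == pytest.approx(2.0)  # ddof=1
        assert model.means.loc["B", "PC1"] == pytest.approx(12.0)
        assert model.variances.loc["B", "PC1"] == pytest.approx(8.0)
        assert model.priors.sum() == pytest.approx(1.0)

    def test_identical_classes_split_posterior_evenly(self):
        vals = [[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]]
        scores = scores_from(vals, ["A", "A", "B", "B"])
        post = pe.nbc_posterior(pe.nbc_fit(scores), scores)
        np.testing.assert_allclose(post[["A", "B"]].to_numpy(), 0.5, atol=1e-12)

    def test_zero_variance_class_floored(self):
        scores = scores_from([[1.0], [1.0], [2.0], [3.0]], ["A", "A", "B", "B"])
        model = pe.nbc_fit(scores, variance_floor=1e-9)
        assert model.variances.loc["A", "PC1"] == 1e-9
        post = pe.nbc_posterior(model, scores)
        assert np.isfinite(post[["A", "B"]].to_numpy()).all()

    def test_singleton_class_rejected_with_name(self):
        scores = scores_from([[1.0], [2.0], [3.0]], ["A", "A", "Solo"])
        with pytest.raises(FitError, match="Solo"):
            pe.nbc_fit(scores)

    def test_midpoint_symmetry_one_dimension(self):
        """Two unit-variance classes at 0 and 2 with uniform priors give a
        50/50 posterior at their midpoint and 1/(1+e^-2) at x=0."""
        scores = scores_from([[-1.0], [1.0], [1.0], [3.0]], ["C1", "C1", "C2", "C2"])
        model = pe.nbc_fit(scores)  # class means 0 and 2, variances 2 -> rescale
        # construct exact N(0,1), N(2,1) model by hand for the closed form
        model.means.loc["C1", "PC1"] = 0.0
        model.means.loc["C2", "PC1"] = 2.0
        model.variances.loc[:, "PC1"] = 1.0
        mid = scores_from([[1.0]], ["?"])
        post = pe.nbc_posterior(model, mid)
        np.testing.assert_allclose(post[["C1", "C2"]].to_numpy()[0], [0.5, 0.5], atol=1e-12)
        at_zero = pe.nbc_posterior(model, scores_from([[0.0]], ["?"]))
        expected = 1.0 / (1.0 + np.exp(-2.0))
        assert at_zero["C1"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_rows_normalise(self, rng):
        scores = scores_from(rng.standard_normal((30, 6)), ["G%d" % (i % 5) for i in range(30)])
        post = pe.nbc_posterior(pe.nbc_fit(scores), scores)
        sums = post[[f"G{i}" for i in range(5)]].to_numpy().sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        """Log-domain posteriors equal the direct density product to 1e-12."""
        groups = [f"G{i % 5}" for i in range(40)]
        scores = scores_from(2 * rng.standard_normal((40, 4)), groups)
        for priors in ("uniform", "empirical"):
            model = pe.nbc_fit(scores, priors=priors)
            post = pe.nbc_posterior(model, scores)
            oracle = nbc_oracle(model, scores)
            np.testing.assert_allclose(
                post[model.classes].to_numpy(), oracle, atol=1e-12
            )

    def test_non_finite_scores_rejected(self):
        scores = scores_from([[1.0], [2.0], [np.nan], [3.0]], ["A", "A", "B", "B"])
        with pytest.raises(InputError):
            pe.nbc_fit(scores)


# ---------------------------------------------------------------------------
# MPS


class TestMps:
    def test_odd_count_median(self):
        post = scores_from([[0.0]] * 3, ["G"] * 3).drop(columns="PC1")
        post["A"] = [0.2, 0.4, 0.9]
        post["B"] = [0.8, 0.6, 0.1]
        mps = pe.mps_table(post)
        assert mps.table.loc["G", "A"] == pytest.approx(0.4)

    def test_even_count_median_is_mean_of_middle_pair(self):
        post = scores_from([[0.0]] * 4, ["G"] * 4).drop(columns="PC1")
        post["A"] = [0.1, 0.2, 0.6, 0.8]
        post["B"] = [0.9, 0.8, 0.4, 0.2]
        mps = pe.mps_table(post)
        assert mps.table.loc["G", "A"] == pytest.approx(0.4)

    def test_unanimous_group_gets_mps_one(self):
        """A group whose every record is certain of one class scores MPS 1
        there and 0 elsewhere."""
        post = scores_from([[0.0]] * 3, ["MED"] * 3).drop(columns="PC1")
        post["DEX"] = [1.0, 1.0, 1.0]
        post["NaCl"] = [0.0, 0.0, 0.0]
        mps = pe.mps_table(post)
        assert mps.table.loc["MED", "DEX"] == 1.0
        assert mps.table.loc["MED", "NaCl"] == 0.0
        assert mps.ranking.iloc[0]["top_class"] == "DEX"

    def test_record_order_invariance(self, rng):
        post = scores_from([[0.0]] * 6, ["G1", "G2"] * 3).drop(columns="PC1")
        post["A"] = rng.uniform(size=6)
        post["B"] = 1.0 - post["A"]
        shuffled = post.sample(frac=1.0, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(pe.mps_table(post).table, pe.mps_table(shuffled).table)

    def test_tie_broken_by_class_name_and_flagged(self):
        post = scores_from([[0.0]] * 2, ["G"] * 2).drop(columns="PC1")
        post["B"] = [0.5, 0.5]
        post["A"] = [0.5, 0.5]
        mps = pe.mps_table(post)
        row = mps.ranking.iloc[0]
        assert row["top_class"] == "A"
        assert bool(row["tied"])

    def test_missing_group_label_rejected(self):
        post = scores_from([[0.0]], [""]).drop(columns="PC1")
        post["A"] = [1.0]
        with pytest.raises(InputError):
            pe.mps_table(post)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=9))
    def test_mps_bounded_by_unit_interval(self, probs):
        post = pd.DataFrame({"group": "G", "A": probs, "B": [1 - p for p in probs]})
        mps = pe.mps_table(post)
        assert 0.0 <= mps.table.loc["G", "A"] <= 1.0


# ---------------------------------------------------------------------------
# end-to-end classification on a small simulated panel


@pytest.fixture(scope="module")
def small_panel_effects():
    """Six well-separated signatures x 5 records, 30-s phases, low jitter."""
    ids = {"NaCl", "DEX 0.005", "GAL 1.0", "PHE 0.1", "HXZ 5.0", "DIZ 0.25"}
    sigs = [
        pe.DrugSignature(s.class_id, s.multipliers, jitter_sd=0.05)
        for s in pe.default_signatures()
        if s.class_id in ids
    ]
    panel = pe.generate_panel(sigs, 5, seed=202, baseline=pe.BaselineSpec(duration_s=30.0))
    return pe.panel_effect_matrix(panel.pairs)


class TestClassifyGroup:
    def test_training_groups_recover_themselves(self, small_panel_effects):
        result = pe.classify_group(small_panel_effects, small_panel_effects, k=6)
        ranking = result.mps.ranking
        assert (ranking["top_class"] == ranking["group"]).all()

    def test_saline_test_group_lands_on_nacl(self, small_panel_effects):
        test_panel = pe.generate_panel(
            [pe.saline_signature(jitter_sd=0.05)], 5, seed=777,
            baseline=pe.BaselineSpec(duration_s=30.0),
        )
        test_effects = pe.panel_effect_matrix(test_panel.pairs)
        result = pe.classify_group(small_panel_effects, test_effects, k=6)
        assert result.mps.ranking.iloc[0]["top_class"] == "NaCl"

    def test_pca_population_modes_both_run(self, small_panel_effects):
        for mode in ("training", "all"):
            result = pe.classify_group(
                small_panel_effects, small_panel_effects, k=6, pca_population=mode
            )
            assert result.posteriors[result.nbc.classes].to_numpy().sum(axis=1) == pytest.approx(
                np.ones(len(small_panel_effects)), abs=1e-9
            )

    def test_leave_one_out_recovers_groups(self, small_panel_effects):
        frac, mps, posteriors = pe.leave_one_out_mps(small_panel_effects, k=6)
        assert frac >= 0.8
        assert len(posteriors) == len(small_panel_effects)
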