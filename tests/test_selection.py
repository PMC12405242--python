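"""Discriminant selection: LDA effect size, sPLS-DA, PC1 thresholds, Ward HCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from microcog import (
    lefse,
    LefseSelector,
    SparsePLSDA,
    Pc1Selector,
    fit_splsda,
    splsda_wilcoxon_filter,
    pca_pc1_select,
    pathway_screen,
    hca,
)

from oracles import naive_ward_merge_partitions, scipy_linkage_partitions


def planted_block(rng, n_a=3, n_b=15, p=60, planted=6, shift=2.5):
    """Two-class matrix with the first `planted` features shifted in class a."""
    x = rng.normal(size=(n_a + n_b, p))
    x[:n_a, :planted] += shift
    y = np.array(["a"] * n_a + ["b"] * n_b)
    return pd.DataFrame(np.exp(x), columns=[f"f{j}" for j in range(p)]), y


class TestLefse:
    def test_identical_groups_yield_empty_set(self):
        rng = np.random.default_rng(0)
        base = rng.dirichlet(np.ones(20), size=4)
        table = pd.DataFrame(np.vstack([base, base]),
                             columns=[f"s{j}" for j in range(20)])
        y = np.array(["a"] * 4 + ["b"] * 4)
        assert len(lefse(table, y, seed=0)) == 0

    def test_alpha_gate_excludes_nonsignificant_features(self):
        # 2 vs 2: the smallest achievable KW p is ~0.12 > alpha, so even a
        # 100-fold abundance difference cannot pass the screen
        table = pd.DataFrame({
            "big_fold": [1.0, 0.9, 0.01, 0.011],
            "filler": [0.1, 0.2, 0.15, 0.12],
        })
        y = np.array(["a", "a", "b", "b"])
        assert len(lefse(table, y, seed=0)) == 0

    def test_planted_feature_recovered_with_direction(self):
        """1% vs 4% planted species is retained and oriented correctly."""
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(18, 50)) * 0.5
            x[:, 0] += np.log(np.where(np.arange(18) < 3, 0.04, 0.01))
            x[:, 1:] += np.log(0.96 / 49)
            rel = np.exp(x)
            rel /= rel.sum(axis=1, keepdims=True)
            table = pd.DataFrame(rel, columns=[f"s{j}" for j in range(50)])
            y = np.array(["hi_abund"] * 3 + ["lo_abund"] * 15)
            result = lefse(table, y, seed=seed)
            if "s0" in result.features() and (
                    result.frame.loc["s0", "direction"] == "hi_abund"):
                hits += 1
        assert hits >= 27  # >= 90% of seeded runs

    def test_direction_matches_median_difference(self, baseline):
        result = lefse(baseline["species"], baseline["groups"], seed=1)
        vals = baseline["species"].values
        lower = baseline["groups"] == "Lower"
        for feat in result.features():
            med_diff = (np.median(vals.loc[lower.tolist(), feat])
                        - np.median(vals.loc[(~lower).tolist(), feat]))
            expected = "Lower" if med_diff > 0 else "Higher"
            assert result.frame.loc[feat, "direction"] == expected

    def test_single_class_rejected(self):
        table = pd.DataFrame(np.random.default_rng(0).uniform(size=(4, 5)))
        with pytest.raises(ValueError, match="two classes"):
            lefse(table, np.array(["a"] * 4), seed=0)

    def test_deterministic_given_seed(self, baseline):
        a = lefse(baseline["species"], baseline["groups"], seed=9)
        b = lefse(baseline["species"], baseline["groups"], seed=9)
        pd.testing.assert_frame_equal(a.frame, b.frame)


class TestSparsePlsda:
    def test_dense_limit_matches_sklearn_pls(self):
        rng = np.random.default_rng(1)
        x, y = planted_block(rng, p=30, planted=5)
        model = SparsePLSDA(n_components=2, keep_x=30, tol=1e-12,
                            max_iter=2000).fit(x, y)
        ydum = np.column_stack([(y == c).astype(float)
                                for c in np.unique(y)])
        ref = PLSRegression(n_components=2, scale=True, tol=1e-12,
                            max_iter=2000).fit(x.to_numpy(), ydum)
        for k in range(2):
            w_ours = model.x_weights_[:, k]
            w_ref = ref.x_weights_[:, k]
            sign = np.sign(w_ours @ w_ref)
            assert np.allclose(w_ours, sign * w_ref, atol=1e-8)

    def test_exact_cardinality_and_unit_norm(self):
        rng = np.random.default_rng(2)
        x, y = planted_block(rng, p=100, planted=10)
        model = SparsePLSDA(n_components=2, keep_x=15).fit(x, y)
        for k in range(2):
            w = model.x_weights_[:, k]
            assert np.count_nonzero(w) == 15
            assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-9)

    def test_planted_features_dominate_component_one(self):
        kept_counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, y = planted_block(rng, n_a=15, n_b=15, p=500, planted=10,
                                 shift=2.0)
            model = SparsePLSDA(n_components=2, keep_x=10).fit(np.log(x), y)
            kept = set(model.kept_features_[0])
            kept_counts.append(len(kept & {f"f{j}" for j in range(10)}))
        assert np.median(kept_counts) >= 9

    def test_selection_invariant_to_feature_and_sample_order(self):
        rng = np.random.default_rng(3)
        x, y = planted_block(rng, p=40, planted=5)
        model = SparsePLSDA(n_components=2, keep_x=8).fit(x, y)
        perm_feat = rng.permutation(x.columns)
        x2 = x[perm_feat]
        model2 = SparsePLSDA(n_components=2, keep_x=8).fit(x2, y)
        assert set(model.kept_features_[0]) == set(model2.kept_features_[0])
        # permute samples within classes
        idx = np.concatenate([rng.permutation(3), 3 + rng.permutation(15)])
        model3 = SparsePLSDA(n_components=2, keep_x=8).fit(
            x.iloc[idx], y[idx])
        assert set(model.kept_features_[0]) == set(model3.kept_features_[0])

    def test_permuted_labels_give_chance_accuracy(self):
        """Label permutation destroys CV accuracy down to the majority rate."""
        rng = np.random.default_rng(4)
        x, y = planted_block(rng, n_a=9, n_b=9, p=100, planted=10, shift=2.5)
        accs = []
        for _ in range(60):
            yp = rng.permutation(y)
            accs.append(cross_val_score(
                SparsePLSDA(n_components=2, keep_x=20), x.to_numpy(), yp,
                cv=StratifiedKFold(3), scoring="accuracy").mean())
        majority = 0.5
        assert np.mean(accs) == pytest.approx(majority, abs=0.05)

    def test_sklearn_protocol(self):
        model = SparsePLSDA(keep_x=5)
        assert clone(model).get_params()["keep_x"] == 5
        rng = np.random.default_rng(0)
        x, y = planted_block(rng, p=20, planted=3)
        scores = model.fit(x, y).transform(x)
        assert scores.shape == (18, 2)
        assert set(model.predict(x)) <= set(y)


class TestWilcoxonFilter:
    def test_two_stage_gate(self):
        """A variable kept by sPLS-DA but with weak rank separation is dropped."""
        rng = np.random.default_rng(5)
        x, y = planted_block(rng, p=30, planted=4, shift=3.0)
        # an extra feature engineered with a mild, non-significant difference
        x["weak"] = np.concatenate([
            rng.normal(0.35, 1.0, 3), rng.normal(0.0, 1.0, 15)])
        x["weak"] = np.exp(x["weak"])
        model = fit_splsda(x, y, keep_x=31)
        result = splsda_wilcoxon_filter(model, x, y)
        from microcog import exact_rank_sum
        _, p_weak = exact_rank_sum(x["weak"][:3], x["weak"][3:])
        if p_weak >= 0.05:
            assert "weak" not in result.features()
        assert all(result.frame["p_value"] < 0.05)

    def test_planted_recovery(self, baseline):
        model = fit_splsda(baseline["metabolites"], baseline["groups"], seed=0)
        result = splsda_wilcoxon_filter(
            model, baseline["metabolites"], baseline["groups"])
        truth = baseline["truth"]
        planted = set(truth.discriminant_metabolites_up) | set(
            truth.discriminant_metabolites_down)
        recall = len(planted & set(result.features())) / len(planted)
        assert recall >= 0.85
        up = set(truth.discriminant_metabolites_up) & set(result.features())
        assert all(result.frame.loc[f, "direction"] == "Lower" for f in up)


class TestPc1Selector:
    def test_threshold_application(self):
        """Sets are exactly the loadings cut at the two signed thresholds."""
        rng = np.random.default_rng(6)
        x, y = planted_block(rng, p=30, planted=10, shift=2.5)
        sel = Pc1Selector().fit(np.log(x), np.where(y == "a", "Lower", "Higher"))
        pos_expected = set(sel.feature_names_in_[sel.loadings_ > 0.15])
        neg_expected = set(sel.feature_names_in_[sel.loadings_ < -0.10])
        assert set(sel.positive_) == pos_expected
        assert set(sel.negative_) == neg_expected
        assert not set(sel.positive_) & set(sel.negative_)

    def test_orientation_anchors_positive_side_to_lower_group(self):
        """The orientation rule resolves the PCA sign ambiguity: the Lower
        group always scores positive and the positive set is Lower-elevated,
        regardless of the solver's arbitrary component sign."""
        rng = np.random.default_rng(7)
        x, y = planted_block(rng, p=20, planted=6, shift=2.0)
        labels = np.where(y == "a", "Lower", "Higher")
        sel = Pc1Selector().fit(np.log(x), labels)
        assert sel.scores_[labels == "Lower"].mean() > 0
        planted = {f"f{j}" for j in range(6)}
        assert planted <= set(sel.positive_)
        logx = np.log(x)
        lower = labels == "Lower"
        for feat in planted & set(sel.positive_):
            assert (logx.loc[lower, feat].mean()
                    > logx.loc[~lower, feat].mean())
        # negating the data flips every feature's elevation, so the planted
        # Lower-elevated features move to the negative side
        flipped = Pc1Selector().fit(-np.log(x), labels)
        assert np.allclose(sel.scores_, flipped.scores_, atol=1e-8)
        assert planted <= set(flipped.negative_)

    def test_planted_blocks_segregate_by_sign(self, baseline):
        """Up-planted metabolites land positive, down-planted negative."""
        truth = baseline["truth"]
        model = fit_splsda(baseline["metabolites"], baseline["groups"], seed=0)
        kept = splsda_wilcoxon_filter(
            model, baseline["metabolites"], baseline["groups"]).features()
        sel = pca_pc1_select(
            baseline["metabolites"].values[kept], baseline["groups"])
        up = set(truth.discriminant_metabolites_up)
        down = set(truth.discriminant_metabolites_down)
        tab = [
            [len(set(sel.positive_) & up), len(set(sel.positive_) & down)],
            [len(set(sel.negative_) & up), len(set(sel.negative_) & down)],
        ]
        _, p = fisher_exact(tab)
        assert p < 0.01
        assert len(set(sel.positive_) & up) > len(set(sel.positive_) & down)

    def test_needs_two_features(self):
        with pytest.raises(ValueError, match="2 features"):
            Pc1Selector().fit(pd.DataFrame({"only": [1.0, 2.0, 3.0]}),
                              np.array(["Lower", "Higher", "Higher"]))


class TestHca:
    def test_identical_samples_merge_first_at_zero(self):
        x = pd.DataFrame([[1.0, 2.0], [5.0, 1.0], [1.0, 2.0], [9.0, 9.0]],
                         index=list("abcd"))
        z, order = hca(x)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 2}
        assert set(order) == set("abcd")

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_naive_ward_oracle(self, trial):
        rng = np.random.default_rng(trial)
        x = rng.normal(size=(6, 4))
        z, _ = hca(pd.DataFrame(x))
        assert scipy_linkage_partitions(z, 6) == naive_ward_merge_partitions(x)

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(0)
        z, _ = hca(pd.DataFrame(rng.normal(size=(12, 5))))
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    def test_two_planted_clusters_recovered(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.3, size=(6, 4))
        b = rng.normal(6, 0.3, size=(6, 4))
        x = pd.DataFrame(np.vstack([a, b]))
        z, _ = hca(x)
        from scipy.cluster.hierarchy import fcluster
        labels = fcluster(z, t=2, criterion="maxclust")
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[6]


class TestPathwayScreen:
    @staticmethod
    def _pathway_table(rng, planted_shift=0.0):
        x = rng.normal(size=(18, 30)) * 0.4
        x[:, 0] += np.log(0.05)   # abundant, planted candidate
        x[:3, 0] += planted_shift
        x[:, 1] += np.log(0.005)  # below the 1% mean gate
        x[:, 2:] += np.log(0.9 / 28)
        rel = np.exp(x)
        rel /= rel.sum(axis=1, keepdims=True)
        y = np.array(["Lower"] * 3 + ["Higher"] * 15)
        return pd.DataFrame(rel, columns=[f"pw{j}" for j in range(30)]), y

    def test_rare_pathways_not_tested(self):
        rng = np.random.default_rng(0)
        table, y = self._pathway_table(rng, planted_shift=0.0)
        # strongly separated but rare: tripling in Lower keeps the global
        # mean near 0.7%, still under the 1% gate
        table["pw1"] = table["pw1"] * np.where(np.arange(18) < 3, 3, 1)
        assert table["pw1"].mean() < 0.01
        result = pathway_screen(table, y)
        assert "pw1" not in result.features()

    def test_planted_shift_recovered(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            table, y = self._pathway_table(rng, planted_shift=2.0)
            result = pathway_screen(table, y)
            if "pw0" in result.features("Lower"):
                hits += 1
        assert hits >= 27
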