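"""Selector contracts: sparse PCA/IPCA, gene shaving, moderated t,
random forest, elastic-net frequency selection."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import immunosig as im
from immunosig.discovery import _shave, cluster_r2

from conftest import simulate_processed


def frame(a, prefix="p"):
    a = np.asarray(a, dtype=float)
    return pd.DataFrame(a, index=[f"{prefix}{i}" for i in range(a.shape[0])])


class TestSparsePCA:
    def test_rank_one_support_recovery(self):
        """On a rank-1 matrix whose PC1 support is 3 peptides, the first
        sparse component recovers exactly those peptides."""
        u = np.zeros(10)
        u[[2, 5, 7]] = [3.0, -2.0, 1.5]
        v = np.array([1.0, -1.0, 2.0, 0.5])
        X = frame(np.outer(u, v))
        lists = im.sparse_pca_lists(X, k_features=3, n_lists=1)
        assert set(lists[0].peptide_ids) == {"p2", "p5", "p7"}
        # ordered by |loading|
        assert lists[0].peptide_ids[0] == "p2"

    def test_k_exceeding_peptide_count(self):
        rng = np.random.default_rng(1)
        X = frame(rng.normal(size=(50, 8)))
        lists = im.sparse_pca_lists(X, k_features=100, n_lists=3)
        assert all(len(l) == 50 for l in lists)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        X = frame(rng.normal(size=(200, 12)))
        a = im.sparse_pca_lists(X, 20, 5, seed=3)
        b = im.sparse_pca_lists(X, 20, 5, seed=3)
        assert [l.peptide_ids for l in a] == [l.peptide_ids for l in b]

    def test_rank_deficiency_warns_and_truncates(self):
        # rank-1 input with k = p: the first component absorbs everything
        X = frame(np.outer([1.0, 2.0, 3.0], [1.0, -1.0]))
        with pytest.warns(UserWarning, match="rank"):
            lists = im.sparse_pca_lists(X, k_features=3, n_lists=5)
        assert len(lists) == 1

    def test_planted_component_found(self, small_processed):
        """The dominant sparse component captures the planted signature."""
        x = small_processed["discovery"]
        planted = small_processed["planted"]
        lists = im.sparse_pca_lists(x, k_features=100, n_lists=2)
        overlap = len(set(lists[0].peptide_ids) & planted) / 100
        assert overlap >= 0.8


class TestSparseIPCA:
    def test_two_source_recovery(self):
        """Two planted non-Gaussian source patterns are separated into the
        two leading components (>= 80% support recovery over 20 seeds)."""
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            p, n, k = 300, 40, 20
            a1 = rng.choice([0.0, 3.0], size=n, p=[0.75, 0.25])
            a2 = rng.choice([-2.0, 2.0], size=n)
            u1 = np.zeros(p); u1[:k] = rng.uniform(1, 2, k)
            u2 = np.zeros(p); u2[k:2 * k] = rng.uniform(1, 2, k)
            X = frame(np.outer(u1, a1) + np.outer(u2, a2)
                      + 0.2 * rng.normal(size=(p, n)))
            lists = im.sparse_ipca_lists(X, k_features=k, n_lists=2,
                                         seed=seed)
            s1, s2 = (set(l.peptide_ids) for l in lists[:2])
            t1 = {f"p{i}" for i in range(k)}
            t2 = {f"p{i}" for i in range(k, 2 * k)}
            rec = max(len(s1 & t1) + len(s2 & t2),
                      len(s1 & t2) + len(s2 & t1)) / (2 * k)
            hits.append(rec)
        assert np.mean(hits) >= 0.8

    def test_isotropic_noise_no_preferred_peptide(self):
        """On pure Gaussian noise no peptide is systematically selected:
        per-peptide selection frequency stays near k/p across seeds."""
        p, k, n_seeds = 200, 20, 30
        counts = np.zeros(p)
        for seed in range(n_seeds):
            rng = np.random.default_rng(500 + seed)
            X = frame(rng.normal(size=(p, 25)))
            lst = im.sparse_ipca_lists(X, k_features=k, n_lists=1,
                                       seed=seed)[0]
            idx = [int(q[1:]) for q in lst.peptide_ids]
            counts[idx] += 1
        freq = counts / n_seeds
        assert freq.mean() == pytest.approx(k / p)
        assert freq.max() < 0.5

    def test_no_sparsity_returns_everything(self):
        rng = np.random.default_rng(3)
        X = frame(rng.normal(size=(30, 10)))
        lists = im.sparse_ipca_lists(X, k_features=30, n_lists=3, seed=0)
        assert all(set(l.peptide_ids) == set(X.index) for l in lists)


class TestGeneShaving:
    def test_shave_sizes_hand_trace(self):
        assert im.shave_sequence_sizes(4, 0.5) == [4, 2, 1]
        assert im.shave_sequence_sizes(6, 0.1) == [6, 5, 4, 3, 2, 1]
        assert im.shave_sequence_sizes(10, 0.3) == [10, 7, 4, 2, 1]

    def test_nested_sequence_properties(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(40, 8))
        sets = _shave(a, 0.25)
        sizes = [len(s) for s in sets]
        assert sizes == im.shave_sequence_sizes(40, 0.25)
        assert sizes[-1] == 1
        for prev, nxt in zip(sets, sets[1:]):
            assert set(nxt) < set(prev)

    def test_single_peptide_input(self):
        X = frame([[1.0, 2.0, 3.0, 4.0]])
        with pytest.warns(UserWarning):
            lists = im.gene_shaving_lists(X, n_lists=3, seed=0)
        assert len(lists) >= 1
        assert lists[0].peptide_ids == ["p0"]

    def test_planted_block_selected_by_gap(self):
        """A perfectly correlated 3-peptide block among 3 noise peptides is
        isolated by the gap statistic in >= 18/20 seeds."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(600 + seed)
            pattern = np.array([2.0, -1.0, 1.0, -2.0])
            block = np.vstack([pattern * s for s in (1.0, 1.2, 1.1)])
            noise = rng.normal(0, 0.5, size=(3, 4))
            X = frame(np.vstack([block, noise]))
            lst = im.gene_shaving_lists(X, n_lists=1, shave_fraction=0.10,
                                        n_permutations=20, seed=seed)[0]
            if set(lst.peptide_ids) == {"p0", "p1", "p2"}:
                wins += 1
        assert wins >= 18

    def test_signature_block_recovered(self, small_processed):
        """The first shaving cluster is drawn from the planted signature."""
        x = small_processed["discovery"]
        planted = small_processed["planted"]
        lists = im.gene_shaving_lists(x, n_lists=2, n_permutations=8, seed=1)
        ids = set(lists[0].peptide_ids)
        assert len(ids & planted) / len(ids) >= 0.9

    def test_invalid_fraction(self):
        with pytest.raises(ValueError, match="shave_fraction"):
            im.gene_shaving_lists(frame([[1.0, 2.0]]), shave_fraction=1.5)


class TestModeratedT:
    def test_zero_prior_df_equals_ordinary_t(self):
        """With d0 forced to 0, the moderated t reduces to the ordinary
        pooled-variance two-sample t."""
        rng = np.random.default_rng(5)
        X = frame(rng.normal(size=(300, 14)))
        labels = ["case"] * 8 + ["control"] * 6
        res, _ = im.moderated_t_select(X, labels, d0=0)
        oracle = stats.ttest_ind(X.iloc[:, :8], X.iloc[:, 8:], axis=1,
                                 equal_var=True)
        assert np.abs(res.table["t"].to_numpy()
                      - oracle.statistic).max() < 1e-10
        assert np.abs(res.table["p"].to_numpy() - oracle.pvalue).max() < 1e-10

    def test_matches_limma_ebayes(self, tmp_path):
        """The empirical-Bayes prior fit and moderated t agree with the
        reference R implementation (limma eBayes) to numerical precision."""
        rng = np.random.default_rng(7)
        n1, n2, p = 8, 6, 120
        X = frame(rng.normal(0, 1, (p, n1 + n2))
                  * rng.uniform(0.5, 2, (p, 1)), prefix="g")
        X.iloc[:10, :n1] += 1.0
        res, _ = im.moderated_t_select(X, ["case"] * n1 + ["control"] * n2,
                                       winsor=None)
        mat = tmp_path / "mat.csv"
        out = tmp_path / "limma_out.csv"
        X.to_csv(mat)
        script = tmp_path / "check.R"
        script.write_text(f"""
suppressMessages(library(limma))
x <- as.matrix(read.csv("{mat}", row.names=1))
design <- cbind(Intercept=1, case=c(rep(1,{n1}), rep(0,{n2})))
fit <- eBayes(lmFit(x, design))
write.csv(data.frame(t=fit$t[,"case"], p=fit$p.value[,"case"],
                     dfp=fit$df.prior, s2p=fit$s2.prior), "{out}")
""")
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(out, index_col=0)
        assert res.df_prior == pytest.approx(ref["dfp"].iloc[0], rel=1e-5)
        assert res.s2_prior == pytest.approx(ref["s2p"].iloc[0], rel=1e-5)
        assert np.abs(res.table["t"].to_numpy()
                      - ref["t"].to_numpy()).max() < 1e-8

    def test_shrinkage_bounds_and_adjustment(self):
        rng = np.random.default_rng(8)
        X = frame(rng.normal(size=(500, 20))
                  * rng.uniform(0.3, 3.0, (500, 1)))
        labels = ["case"] * 10 + ["control"] * 10
        res, _ = im.moderated_t_select(X, labels)
        t = res.table
        lo = np.minimum(t["s2"], res.s2_prior) - 1e-12
        hi = np.maximum(t["s2"], res.s2_prior) + 1e-12
        assert ((t["s2_post"] >= lo) & (t["s2_post"] <= hi)).all()
        assert (t["adj_p"] >= t["p"] - 1e-15).all()

    def test_monotone_in_mean_difference(self):
        """For equal variances, a larger |mean difference| never yields a
        larger p-value."""
        base = np.array([1.0, -1.0, 0.5, -0.5, 0.0])
        rows, shifts = [], np.linspace(0, 3, 10)
        for c in shifts:
            rows.append(np.concatenate([base + c, base]))
        X = frame(np.array(rows))
        labels = ["case"] * 5 + ["control"] * 5
        res, _ = im.moderated_t_select(X, labels)
        p = res.table["p"].to_numpy()
        assert np.all(np.diff(p) <= 1e-12)

    def test_planted_recovery(self):
        """BH selection at a 1.5-SD planted effect recovers the signature
        with precision and recall >= 0.8 (mean over 20 seeds)."""
        recalls, precisions = [], []
        for seed in range(20):
            d = simulate_processed(2000, seed=700 + 7 * seed)
            _, rl = im.moderated_t_select(d["discovery"],
                                          d["labels_discovery"])
            s, planted = set(rl.peptide_ids), d["planted"]
            recalls.append(len(s & planted) / len(planted))
            precisions.append(len(s & planted) / max(len(s), 1))
        assert np.mean(recalls) >= 0.8
        assert np.mean(precisions) >= 0.8

    def test_empty_group_error(self):
        X = frame(np.ones((3, 4)))
        with pytest.raises(ValueError, match="group"):
            im.moderated_t_select(X, ["case"] * 4)


class TestRandomForest:
    def test_infinite_threshold_empty(self):
        rng = np.random.default_rng(9)
        X = frame(rng.normal(size=(50, 10)))
        lst = im.random_forest_select(X, ["case"] * 5 + ["control"] * 5,
                                      n_trees=50,
                                      gini_threshold=np.inf, seed=0)
        assert lst.peptide_ids == []

    def test_perfect_separator_ranks_first(self):
        """A single perfectly separating peptide among 500 noise peptides
        receives the top importance in >= 19/20 seeds."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(800 + seed)
            X = frame(rng.normal(size=(501, 40)))
            X.iloc[0] = np.concatenate([rng.normal(3, 0.3, 20),
                                        rng.normal(-3, 0.3, 20)])
            labels = ["case"] * 20 + ["control"] * 20
            lst = im.random_forest_select(X, labels, n_trees=300, seed=seed)
            if lst.peptide_ids and lst.peptide_ids[0] == "p0":
                wins += 1
        assert wins >= 19

    def test_determinism_and_single_class_error(self):
        rng = np.random.default_rng(10)
        X = frame(rng.normal(size=(60, 12)))
        labels = ["case"] * 6 + ["control"] * 6
        a = im.random_forest_select(X, labels, n_trees=100, seed=4)
        b = im.random_forest_select(X, labels, n_trees=100, seed=4)
        assert a.peptide_ids == b.peptide_ids
        with pytest.raises(ValueError, match="single class"):
            im.random_forest_select(X, ["case"] * 12, n_trees=10)


class TestElasticNet:
    def _toy(self, seed=0):
        rng = np.random.default_rng(seed)
        n1 = n2 = 12
        X = frame(rng.normal(size=(30, n1 + n2)))
        X.iloc[0] = np.concatenate([np.ones(n1), -np.ones(n2)]) \
            + rng.normal(0, 0.05, n1 + n2)
        return X, ["case"] * n1 + ["control"] * n2

    def test_run_size_and_frequency_bounds(self):
        X, labels = self._toy()
        lst = im.elastic_net_frequency_select(X, labels, n_runs=10, seed=1)
        assert lst.method_params["samples_per_run"] == 20
        assert lst.scores.loc["p0"] == 1.0          # always selected
        assert "p0" in lst.peptide_ids
        assert all(0.0 <= f <= 1.0 for f in lst.scores)

    def test_never_selected_excluded(self):
        X, labels = self._toy(seed=2)
        lst = im.elastic_net_frequency_select(X, labels, n_runs=10, seed=2)
        never = set(X.index) - set(lst.peptide_ids)
        assert never        # pure-noise peptides fall below the threshold

    def test_threshold_monotone_containment(self):
        X, labels = self._toy(seed=3)
        strict = im.elastic_net_frequency_select(X, labels, n_runs=12,
                                                 freq_threshold=0.5, seed=3)
        loose = im.elastic_net_frequency_select(X, labels, n_runs=12,
                                                freq_threshold=0.1, seed=3)
        assert set(strict.peptide_ids) <= set(loose.peptide_ids)

    def test_drop_exceeding_group_error(self):
        X, labels = self._toy()
        with pytest.raises(ValueError, match="exceed"):
            im.elastic_net_frequency_select(X, ["case"] * 2 + ["control"] * 22,
                                            n_case_drop=2)

    def test_paper_design_run_size(self, small_processed):
        """With 22 cases and 21 controls and 2+2 dropped, every elastic-net
        run uses 39 samples."""
        lst = im.elastic_net_frequency_select(
            small_processed["discovery"].iloc[:300],
            small_processed["labels_discovery"], n_runs=3, seed=5)
        assert lst.method_params["samples_per_run"] == 39


def test_supervised_recovery_strong_signal():
    """At a 2-SD planted effect the supervised lists overlap the planted
    set substantially (20 seeds): the moderated-t and random-forest lists
    reach Jaccard >= 0.5; the elastic-net stability list concentrates on a
    smaller stable core, strongly enriched for planted peptides but not
    covering them (bounded Jaccard)."""
    jacc = {"RL": [], "RF": [], "EN": []}
    en_precision = []
    for seed in range(20):
        d = simulate_processed(10_000, seed=900 + 13 * seed,
                               effect_size=2.0, signature_coherence=0.0)
        x, labels, planted = (d["discovery"], d["labels_discovery"],
                              d["planted"])
        _, rl = im.moderated_t_select(x, labels)
        rf = im.random_forest_select(x, labels, n_trees=400, seed=seed)
        en = im.elastic_net_frequency_select(x, labels, n_runs=20, seed=seed)
        for lst in (rl, rf, en):
            s = set(lst.peptide_ids)
            jacc[lst.name].append(len(s & planted) / len(s | planted))
        s = set(en.peptide_ids)
        en_precision.append(len(s & planted) / max(len(s), 1))
    assert np.mean(jacc["RL"]) >= 0.5
    assert np.mean(jacc["RF"]) >= 0.5
    assert np.mean(jacc["EN"]) >= 0.25
    assert np.mean(en_precision) >= 0.5


def test_selectors_subset_of_input(small_processed):
    """Every selector returns ids drawn from the input matrix."""
    x = small_processed["discovery"].iloc[:500]
    labels = small_processed["labels_discovery"]
    universe = set(x.index)
    _, rl = im.moderated_t_select(x, labels)
    outputs = [
        rl,
        im.random_forest_select(x, labels, n_trees=50, seed=0),
        im.elastic_net_frequency_select(x, labels, n_runs=4, seed=0),
        *im.sparse_pca_lists(x, 30, 2),
        *im.sparse_ipca_lists(x, 30, 2, seed=0),
        *im.gene_shaving_lists(x, n_lists=2, n_permutations=4, seed=0),
    ]
    for lst in outputs:
        assert set(lst.peptide_ids) <= universe
        assert len(set(lst.peptide_ids)) == len(lst.peptide_ids)
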