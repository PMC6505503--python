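"""Feature discovery: the three unsupervised and three supervised selectors.

Unsupervised (blind to group labels):

* sparse PCA — soft-thresholded power iteration on the deflated data matrix,
  with the threshold set each iteration so a component keeps exactly
  ``k_features`` nonzero peptide loadings;
* sparse IPCA — an independent-component (kurtosis-maximizing) rotation of
  the leading principal subspace of peptide loadings, then hard selection of
  the ``k_features`` largest-magnitude loadings per component;
* gene shaving — iterative removal of peptides least aligned with the
  current first principal component, cluster size chosen by a row-permutation
  gap statistic, successive clusters found after orthogonalization.

Supervised (labels in the supervising vector):

* moderated t (empirical-Bayes variance shrinkage, BH-adjusted p threshold);
* random forest (Mean Decrease Gini importance threshold);
* elastic-net frequency selection over resampled refits.

All selectors are deterministic given their seed and return
:class:`PeptideList` objects whose ids are a subset of the input matrix rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.decomposition import FastICA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class PeptideList:
    """An ordered peptide selection produced by one method run."""

    name: str
    peptide_ids: list[str]
    method_params: dict = field(default_factory=dict)
    scores: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(set(self.peptide_ids)) != len(self.peptide_ids):
            raise ValueError(f"duplicate peptide ids in list {self.name!r}")

    def __len__(self) -> int:
        return len(self.peptide_ids)


def _row_centered(X: pd.DataFrame) -> np.ndarray:
    a = X.to_numpy(dtype=float)
    return a - a.mean(axis=1, keepdims=True)


def _pc1_sample_vector(a: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading right singular vector of ``a`` (k x n, n small) and its
    singular value, via the exact n x n eigenproblem."""
    c = a.T @ a
    vals, vecs = np.linalg.eigh(c)
    v = vecs[:, -1]
    # deterministic sign: largest-|coefficient| entry positive
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
    return v, float(np.sqrt(max(vals[-1], 0.0)))


# ---------------------------------------------------------------------------
# sparse PCA
# ---------------------------------------------------------------------------

def _soft_topk(z: np.ndarray, k: int) -> np.ndarray:
    """Soft-threshold ``z`` at the (k+1)-th largest magnitude, keeping
    exactly ``k`` nonzeros (all of them if ``k >= len(z)``)."""
    if k >= len(z):
        return z.copy()
    az = np.abs(z)
    lam = np.partition(az, len(z) - k - 1)[len(z) - k - 1]
    return np.sign(z) * np.maximum(az - lam, 0.0)


def sparse_pca_lists(X: pd.DataFrame, k_features: int = 100,
                     n_lists: int = 10, seed: int = 0,
                     max_iter: int = 200, tol: float = 1e-9,
                     ) -> list[PeptideList]:
    """Sparse principal components by penalized power iteration.

    Component ``i`` is extracted from the matrix deflated by components
    ``1..i-1``; its list contains the peptides with nonzero loadings,
    ordered by loading magnitude.
    """
    if k_features < 1:
        raise ValueError("k_features must be >= 1")
    a = _row_centered(X)
    ids = np.asarray(X.index)
    lists: list[PeptideList] = []
    for comp in range(1, n_lists + 1):
        v, sv = _pc1_sample_vector(a)
        if sv <= 1e-12 * max(1.0, np.abs(a).max(initial=0.0)) or sv == 0.0:
            warnings.warn(
                f"matrix rank exhausted after {len(lists)} sparse components")
            break
        u = _soft_topk(a @ v, k_features)
        u /= np.linalg.norm(u)
        for _ in range(max_iter):
            v = a.T @ u
            nv = np.linalg.norm(v)
            if nv == 0:
                break
            v /= nv
            u_new = _soft_topk(a @ v, k_features)
            nu = np.linalg.norm(u_new)
            if nu == 0:
                break
            u_new /= nu
            if np.max(np.abs(u_new - u)) < tol:
                u = u_new
                break
            u = u_new
        support = np.flatnonzero(u)
        order = support[np.argsort(-np.abs(u[support]), kind="stable")]
        lists.append(PeptideList(
            name=f"sPCA{comp}",
            peptide_ids=[str(p) for p in ids[order]],
            method_params={"k_features": k_features, "seed": seed},
            scores=pd.Series(u[order], index=ids[order], name="loading")))
        a = a - np.outer(u, u @ a)
    return lists


# ---------------------------------------------------------------------------
# sparse IPCA
# ---------------------------------------------------------------------------

def sparse_ipca_lists(X: pd.DataFrame, k_features: int = 100,
                      n_lists: int = 10, seed: int = 0) -> list[PeptideList]:
    """Sparse independent principal components.

    The leading ``n_lists``-dimensional principal subspace of peptide
    loadings is rotated towards independence (FastICA with the cubic,
    kurtosis-seeking contrast); each rotated loading vector then yields the
    ``k_features`` peptides of largest absolute loading, ordered by
    magnitude.  Components are ordered by the variance of the data projected
    onto them.
    """
    if k_features < 1:
        raise ValueError("k_features must be >= 1")
    a = _row_centered(X)
    ids = np.asarray(X.index)
    u, s, _ = np.linalg.svd(a, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
    m = min(n_lists, rank)
    if m < n_lists:
        warnings.warn(f"rank {rank} < n_lists={n_lists}; returning {m} lists")
    if m == 0:
        return []
    loadings = u[:, :m]
    if m > 1:
        ica = FastICA(n_components=m, fun="cube", whiten="unit-variance",
                      random_state=seed, max_iter=1000, tol=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sources = ica.fit_transform(loadings)
    else:
        sources = loadings
    # order rotated components by projected variance
    proj_var = []
    cols = []
    for j in range(m):
        w = sources[:, j]
        nw = np.linalg.norm(w)
        w = w / nw if nw > 0 else w
        cols.append(w)
        proj_var.append(float(np.sum((a.T @ w) ** 2)))
    order = np.argsort(-np.asarray(proj_var), kind="stable")
    lists = []
    for rank_i, j in enumerate(order, start=1):
        w = cols[j]
        k = min(k_features, len(w))
        top = np.argsort(-np.abs(w), kind="stable")[:k]
        lists.append(PeptideList(
            name=f"sIPCA{rank_i}",
            peptide_ids=[str(p) for p in ids[top]],
            method_params={"k_features": k_features, "seed": seed},
            scores=pd.Series(w[top], index=ids[top], name="loading")))
    return lists


# ---------------------------------------------------------------------------
# gene shaving
# ---------------------------------------------------------------------------

def shave_sequence_sizes(n_peptides: int, shave_fraction: float) -> list[int]:
    """Strictly decreasing cluster sizes produced by repeated shaving:
    each step removes ``ceil(shave_fraction * k)`` peptides, down to 1."""
    sizes = [n_peptides]
    k = n_peptides
    while k > 1:
        k = k - int(np.ceil(shave_fraction * k))
        k = max(k, 1)
        sizes.append(k)
    return sizes


def _shave(a: np.ndarray, shave_fraction: float) -> list[np.ndarray]:
    """Nested peptide index sets from iterative PC1 shaving of ``a``."""
    current = np.arange(a.shape[0])
    sets = [current]
    while len(current) > 1:
        sub = a[current]
        sub = sub - sub.mean(axis=1, keepdims=True)
        v, _ = _pc1_sample_vector(sub)
        align = np.abs(sub @ v)
        n_drop = int(np.ceil(shave_fraction * len(current)))
        n_keep = max(len(current) - n_drop, 1)
        keep = np.argsort(-align, kind="stable")[:n_keep]
        current = current[np.sort(keep)]
        sets.append(current)
    return sets


def _sign_aligned(block: np.ndarray) -> np.ndarray:
    """Row-centered block with each row flipped to align with the block's
    first principal component, so anti-correlated members reinforce rather
    than cancel the mean profile."""
    block = block - block.mean(axis=1, keepdims=True)
    if block.shape[0] == 1:
        return block
    v, _ = _pc1_sample_vector(block)
    flips = np.where(block @ v < 0, -1.0, 1.0)
    return block * flips[:, None]


def cluster_r2(block: np.ndarray) -> float:
    """Coherence of a peptide cluster: between-sample variance of the
    sign-aligned mean profile divided by the mean per-peptide variance."""
    aligned = _sign_aligned(np.asarray(block, dtype=float))
    mean_profile = aligned.mean(axis=0)
    vb = mean_profile.var()
    vt = aligned.var(axis=1).mean()
    return float(vb / vt) if vt > 0 else 0.0


def gene_shaving_lists(X: pd.DataFrame, n_lists: int = 10,
                       shave_fraction: float = 0.10,
                       n_permutations: int = 20,
                       max_cluster_size: int | None = None,
                       seed: int = 0) -> list[PeptideList]:
    """Gene-shaving clusters with permutation gap-statistic size selection.

    For each cluster: (1) shave the working matrix down a nested sequence of
    peptide sets; (2) compute each set's coherence R-squared; (3) subtract
    the mean R-squared of ``n_permutations`` row-permuted matrices shaved the
    same way (the gap statistic) and keep the set size maximizing the gap
    (ties break towards the larger size); (4) orthogonalize the working
    matrix against the retained cluster's mean profile and repeat.
    """
    if not 0.0 < shave_fraction < 1.0:
        raise ValueError("shave_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    a = _row_centered(X)
    ids = np.asarray(X.index)
    lists: list[PeptideList] = []
    for comp in range(1, n_lists + 1):
        if a.shape[0] == 0:
            break
        sets = _shave(a, shave_fraction)
        obs_r2 = np.array([cluster_r2(a[s]) for s in sets])
        perm_r2 = np.zeros(len(sets))
        for _ in range(n_permutations):
            perm = np.empty_like(a)
            for i in range(a.shape[0]):
                perm[i] = a[i, rng.permutation(a.shape[1])]
            psets = _shave(perm, shave_fraction)
            perm_r2 += np.array([cluster_r2(perm[s]) for s in psets])
        if n_permutations > 0:
            perm_r2 /= n_permutations
        gap = obs_r2 - perm_r2
        allowed = np.arange(len(sets))
        if max_cluster_size is not None:
            allowed = allowed[[len(sets[i]) <= max_cluster_size for i in allowed]]
        best = allowed[int(np.argmax(gap[allowed]))]
        chosen = sets[best]
        # order cluster members by alignment with the cluster's PC1
        sub = a[chosen] - a[chosen].mean(axis=1, keepdims=True)
        v, _ = _pc1_sample_vector(sub)
        align = np.abs(sub @ v)
        order = chosen[np.argsort(-align, kind="stable")]
        lists.append(PeptideList(
            name=f"GS{comp}",
            peptide_ids=[str(p) for p in ids[order]],
            method_params={"shave_fraction": shave_fraction,
                           "n_permutations": n_permutations,
                           "gap": float(gap[best]), "seed": seed},
            scores=pd.Series(align[np.argsort(-align, kind="stable")],
                             index=ids[order], name="pc1_alignment")))
        mean_profile = _sign_aligned(a[chosen]).mean(axis=0)
        mean_profile = mean_profile - mean_profile.mean()
        denom = mean_profile @ mean_profile
        if denom <= 0:
            warnings.warn(
                f"degenerate cluster mean; stopping after {comp} cluster(s)")
            break
        a = a - np.outer((a @ mean_profile) / denom, mean_profile)
    if len(lists) < n_lists:
        warnings.warn(f"returned {len(lists)} gene-shaving lists "
                      f"(requested {n_lists})")
    return lists


# ---------------------------------------------------------------------------
# moderated t (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------

@dataclass
class ModeratedTResult:
    """Per-peptide moderated t-test table with the fitted variance prior."""

    table: pd.DataFrame     # mean_case, mean_control, s2, df_residual,
                            # s2_post, t, p, adj_p
    s2_prior: float
    df_prior: float


def trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for ``x`` by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-10:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df1: float,
               winsor: tuple[float, float] | None = None,
               ) -> tuple[float, float]:
    """Moment-match a scaled-F prior ``(s2_prior, df_prior)`` to observed
    residual variances on the log scale; optionally winsorize the variances
    first to damp outliers."""
    s2 = np.asarray(s2, dtype=float)
    s2 = np.clip(s2, 1e-300, None)
    if winsor is not None:
        lo, hi = np.quantile(s2, winsor)
        s2 = np.clip(s2, lo, hi)
    z = np.log(s2)
    e = z - digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df1 / 2.0))
    if evar > 0:
        df2 = 2.0 * trigamma_inverse(evar)
        s20 = float(np.exp(emean + digamma(df2 / 2.0) - np.log(df2 / 2.0)))
    else:
        df2 = np.inf
        s20 = float(np.exp(emean))
    return s20, df2


def moderated_t_select(X: pd.DataFrame, labels, adj_p_threshold: float = 0.05,
                       case_label: str = "case", d0: float | None = None,
                       winsor: tuple[float, float] | None = (0.05, 0.95),
                       ) -> tuple[ModeratedTResult, PeptideList]:
    """Empirical-Bayes moderated two-sample t-test per peptide.

    The per-peptide pooled residual variance is shrunk toward a prior
    ``s2_prior`` with ``df_prior`` pseudo-degrees of freedom estimated from
    the variance distribution (winsorized at the given quantiles for
    robustness; pass ``winsor=None`` for the plain moment fit).  ``d0``
    overrides the estimated prior df; ``d0=0`` reproduces the ordinary
    pooled-variance t-test.  Returns the full result table and the "RL"
    list of peptides with BH-adjusted p at or below the threshold.
    """
    pos = np.asarray([lab == case_label for lab in labels])
    n1, n2 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    a = X.to_numpy(dtype=float)
    x1, x2 = a[:, pos], a[:, ~pos]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    dg = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dg

    s2_prior, df_prior = fit_f_dist(s2, dg, winsor=winsor)
    if d0 is not None:
        df_prior = float(d0)
    if np.isinf(df_prior):
        s2_post = np.full_like(s2, s2_prior)
        df_total = np.inf
    else:
        s2_post = (df_prior * s2_prior + dg * s2) / (df_prior + dg)
        df_total = df_prior + dg
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(p), 1.0, p)
    adj_p = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {"mean_case": m1, "mean_control": m2, "s2": s2,
         "df_residual": float(dg), "s2_post": s2_post, "t": t,
         "p": p, "adj_p": adj_p}, index=X.index)
    result = ModeratedTResult(table=table, s2_prior=s2_prior,
                              df_prior=df_prior)
    selected = table[table["adj_p"] <= adj_p_threshold].sort_values(
        ["p", "adj_p"], kind="stable")
    rl = PeptideList(
        name="RL", peptide_ids=[str(i) for i in selected.index],
        method_params={"adj_p_threshold": adj_p_threshold,
                       "s2_prior": s2_prior, "df_prior": df_prior},
        scores=selected["adj_p"])
    return result, rl


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

def random_forest_select(X: pd.DataFrame, labels, n_trees: int = 1000,
                         gini_threshold: float | None = None,
                         seed: int = 0,
                         permutation_quantile: float = 0.997,
                         ) -> PeptideList:
    """Random-forest Mean Decrease Gini selection.

    When ``gini_threshold`` is None it is set to the ``permutation_quantile``
    of the importances from a single refit on permuted labels — an empirical
    null for "importance by chance".
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    y = np.asarray(list(labels))
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    a = X.to_numpy(dtype=float).T
    s1, s2 = (int(x) for x in
              np.random.SeedSequence(seed).generate_state(2) % (2 ** 31))
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=s1)
    forest.fit(a, y)
    imp = forest.feature_importances_
    if gini_threshold is None:
        rng = np.random.default_rng(s2)
        y_perm = rng.permutation(y)
        null_forest = RandomForestClassifier(n_estimators=n_trees,
                                             random_state=s2 % (2 ** 31))
        null_forest.fit(a, y_perm)
        gini_threshold = float(np.quantile(null_forest.feature_importances_,
                                           permutation_quantile))
    keep = np.flatnonzero(imp >= gini_threshold) if np.isfinite(
        gini_threshold) else np.array([], dtype=int)
    order = keep[np.argsort(-imp[keep], kind="stable")]
    ids = np.asarray(X.index)
    return PeptideList(
        name="RF", peptide_ids=[str(p) for p in ids[order]],
        method_params={"n_trees": n_trees, "gini_threshold": gini_threshold,
                       "seed": seed},
        scores=pd.Series(imp[order], index=ids[order], name="gini_importance"))


# ---------------------------------------------------------------------------
# elastic-net frequency selection
# ---------------------------------------------------------------------------

def elastic_net_frequency_select(X: pd.DataFrame, labels, n_runs: int = 100,
                                 n_case_drop: int = 2, n_control_drop: int = 2,
                                 freq_threshold: float = 0.10, seed: int = 0,
                                 case_label: str = "case",
                                 l1_ratio: float = 0.5, n_alphas: int = 16,
                                 eps: float = 0.01, cv: int = 3,
                                 tol: float = 1e-3) -> PeptideList:
    """Stability selection with an elastic-net linear classifier.

    Each run drops ``n_case_drop`` cases and ``n_control_drop`` controls at
    random, fits an elastic-net model of the +-1 group indicator with
    internal cross-validation over the penalty strength, and records which
    peptides receive nonzero coefficients.  A peptide's frequency is the
    fraction of runs selecting it; the list keeps peptides at or above
    ``freq_threshold``.
    """
    y_all = np.asarray([1.0 if lab == case_label else -1.0 for lab in labels])
    case_idx = np.flatnonzero(y_all > 0)
    ctrl_idx = np.flatnonzero(y_all < 0)
    if len(case_idx) <= n_case_drop or len(ctrl_idx) <= n_control_drop:
        raise ValueError("group sizes must exceed the per-run drop counts")
    a = X.to_numpy(dtype=float).T
    p = a.shape[1]
    counts = np.zeros(p)
    run_seeds = np.random.SeedSequence(seed).generate_state(2 * n_runs)
    n_samples_per_run = len(y_all) - n_case_drop - n_control_drop
    skipped = 0
    for run in range(n_runs):
        rng = np.random.default_rng(run_seeds[2 * run])
        drop = np.concatenate([
            rng.choice(case_idx, size=n_case_drop, replace=False),
            rng.choice(ctrl_idx, size=n_control_drop, replace=False)])
        keep = np.setdiff1d(np.arange(len(y_all)), drop)
        folds = KFold(n_splits=cv, shuffle=True,
                      random_state=int(run_seeds[2 * run + 1] % (2 ** 31)))
        model = ElasticNetCV(l1_ratio=l1_ratio, alphas=n_alphas, eps=eps,
                             cv=folds, tol=tol, max_iter=2000)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(a[keep], y_all[keep])
        except Exception as exc:  # noqa: BLE001 — a failed refit is skipped
            skipped += 1
            warnings.warn(f"elastic-net run {run} failed and was skipped: {exc}")
            continue
        counts += (model.coef_ != 0)
    freqs = counts / n_runs
    keep_feat = np.flatnonzero(freqs >= freq_threshold)
    order = keep_feat[np.lexsort((np.asarray(X.index)[keep_feat],
                                  -freqs[keep_feat]))]
    ids = np.asarray(X.index)
    return PeptideList(
        name="EN", peptide_ids=[str(q) for q in ids[order]],
        method_params={"n_runs": n_runs, "n_case_drop": n_case_drop,
                       "n_control_drop": n_control_drop,
                       "freq_threshold": freq_threshold,
                       "samples_per_run": n_samples_per_run,
                       "skipped_runs": skipped, "l1_ratio": l1_ratio,
                       "seed": seed},
        scores=pd.Series(freqs[order], index=ids[order],
                         name="selection_frequency"))
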