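"""Signature scoring, ROC/AUC computation, and blinded clustering views.

A signature score for sample ``s`` is the mean, over signature peptides, of
``sign_p * x[p, s]`` where ``x`` is the processed (log2 median-centered)
matrix and ``sign_p`` is the sign of peptide ``p``'s loading on the first
principal component of the peptide-standardized signature submatrix.  A
single global orientation, fixed from known group labels, resolves PC1's
inherent sign indeterminacy so that cases score at least as high as
controls on average (hence AUC >= 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.metrics import rand_score


def standardize_rows(values: pd.DataFrame,
                     drop_constant: bool = True) -> pd.DataFrame:
    """Z-score each peptide row (mean 0, SD 1 across samples).

    Constant rows (SD 0) are dropped with a warning when ``drop_constant``,
    otherwise set to all zeros.
    """
    sd = values.std(axis=1, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        if drop_constant:
            warnings.warn(
                f"dropping {len(constant)} constant peptide row(s) "
                f"(zero SD), e.g. {constant[0]!r}")
            values = values.drop(index=constant)
            sd = sd.drop(index=constant)
        else:
            sd = sd.replace(0, 1).fillna(1)
    return values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)


def auc(scores, labels, case_label: str = "case") -> float:
    """Mann-Whitney AUC of case scores against control scores.

    Equals ``(#{case > control pairs} + 0.5 * #{tied pairs}) / (n1 * n0)``.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray([lab == case_label for lab in labels])
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _auc_se(a: float, n1: int, n0: int) -> float:
    """Hanley-McNeil standard error of a Mann-Whitney AUC."""
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a)
           + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class SignatureScoreResult:
    """Per-sample signature scores with their ROC summary."""

    signs: pd.Series          # +-1 per signature peptide, from PC1 loadings
    orientation: int          # global +-1 fixed by group labels
    scores: pd.Series         # oriented per-sample scores
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]


def _check_signature(X: pd.DataFrame, peptide_ids) -> list:
    ids = list(peptide_ids)
    if not ids:
        raise ValueError("signature is empty")
    missing = [p for p in ids if p not in X.index]
    if missing:
        raise ValueError(
            f"{len(missing)} signature peptide(s) absent from matrix "
            f"(first: {missing[0]!r})")
    return ids


def signature_score(X: pd.DataFrame, signature, labels,
                    case_label: str = "case") -> SignatureScoreResult:
    """Score every sample against a peptide signature.

    ``signature`` may be a CandidateSignature-like object with a
    ``peptide_ids`` attribute or any iterable of peptide ids; ``labels`` is
    the per-sample group vector aligned with the columns of ``X``.
    """
    ids = _check_signature(X, getattr(signature, "peptide_ids", signature))
    sub = X.loc[ids]
    z = standardize_rows(sub, drop_constant=False)
    u, _, _ = np.linalg.svd(z.to_numpy(), full_matrices=False)
    signs = pd.Series(np.where(u[:, 0] < 0, -1.0, 1.0), index=sub.index,
                      name="sign")
    raw_scores = (sub.mul(signs, axis=0)).mean(axis=0)
    pos = np.asarray([lab == case_label for lab in labels])
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("both classes must be present to orient the score")
    orientation = 1 if raw_scores[pos].mean() >= raw_scores[~pos].mean() else -1
    scores = orientation * raw_scores
    a = auc(scores, labels, case_label)
    se = _auc_se(a, int(pos.sum()), int((~pos).sum()))
    ci = (max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se))
    return SignatureScoreResult(signs=signs, orientation=orientation,
                                scores=scores, auc=a, auc_se=se, auc_ci=ci)


def pc1_weight_auc(X_full: pd.DataFrame, signature) -> float:
    """AUC of signature membership against the |PC1 weight| ranking.

    All peptides of the standardized full matrix are ranked by the absolute
    value of their first-principal-component weight; signature members are
    the positives.  1.0 means the signature is exactly the top of the
    ranking, 0.5 means it is indistinguishable from a random draw.
    """
    ids = set(_check_signature(X_full, getattr(signature, "peptide_ids", signature)))
    z = standardize_rows(X_full, drop_constant=False)
    u, _, _ = np.linalg.svd(z.to_numpy(), full_matrices=False)
    weights = np.abs(u[:, 0])
    membership = ["case" if pid in ids else "control" for pid in z.index]
    return auc(weights, membership)


@dataclass
class ClusterView:
    """Blinded PCA + hierarchical-clustering view of samples."""

    coords: pd.DataFrame          # samples x (PC1, PC2)
    linkage: np.ndarray
    clusters: pd.Series           # two-cluster cut assignment per sample
    rand_index: float | None      # agreement with labels, if provided
    dropped_rows: list


def cluster_view(X: pd.DataFrame, signature, labels=None,
                 linkage_method: str = "average",
                 metric: str = "correlation") -> ClusterView:
    """Project and cluster samples on a row-standardized signature submatrix.

    Group labels are never used for the projection or the clustering; when
    provided they are only compared against the two-cluster cut via the
    Rand index.
    """
    ids = _check_signature(X, getattr(signature, "peptide_ids", signature))
    if X.shape[1] < 3:
        raise ValueError("cluster_view requires at least 3 samples")
    z = standardize_rows(X.loc[ids], drop_constant=True)
    dropped = [p for p in ids if p not in z.index]
    if z.empty:
        raise ValueError("all signature rows are constant")
    zm = z.to_numpy()
    u, s, vt = np.linalg.svd(zm - zm.mean(axis=1, keepdims=True),
                             full_matrices=False)
    coords = pd.DataFrame(
        (vt[:2].T * s[:2]), index=z.columns, columns=["PC1", "PC2"])
    dist = pdist(zm.T, metric=metric)
    link = hierarchy.linkage(dist, method=linkage_method)
    cut = hierarchy.fcluster(link, t=2, criterion="maxclust")
    clusters = pd.Series(cut, index=z.columns, name="cluster")
    ri = None
    if labels is not None:
        ri = float(rand_score(list(labels), cut))
    return ClusterView(coords=coords, linkage=link, clusters=clusters,
                       rand_index=ri, dropped_rows=dropped)
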