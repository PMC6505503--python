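"""Signature refinement by per-peptide Welch t-tests across four
case/control comparisons.

The winning candidate signature is filtered to the peptides whose two-sided
Welch p-value is below ``alpha`` in every one of four comparisons spanning
the discovery and validation partitions: discovery cases vs discovery
controls, validation Canadian cases vs Canadian controls, Norwegian cases vs
Canadian controls, and Norwegian cases vs US controls.  The conjunction
across comparisons is itself the stringency mechanism; no multiple-testing
adjustment is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signatures import CandidateSignature

#: Comparison names in their canonical order.
COMPARISON_NAMES = (
    "discovery_case_vs_control",
    "validation_canadian_case_vs_canadian_control",
    "norwegian_case_vs_canadian_control",
    "norwegian_case_vs_us_control",
)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Two-sample t-test assuming unequal variances.

    Returns ``(t, satterthwaite_df, two_sided_p)``; each group needs at
    least two observations.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class RefinementReport:
    """Per-peptide p-values for the four comparisons and the keep decision."""

    table: pd.DataFrame         # p_<comparison> columns plus 'kept'
    alpha: float
    comparisons: dict           # name -> (n_a, n_b)
    adjust: str | None = None


def standard_comparisons(processed_discovery: pd.DataFrame,
                         processed_validation: pd.DataFrame,
                         subjects: pd.DataFrame,
                         ) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Resolve the four stated comparisons from per-subject metadata.

    ``subjects`` is indexed by subject id with columns ``group``, ``cohort``
    and ``partition`` (see :func:`immunosig.preprocess.subject_table`).
    """
    def cols(matrix: pd.DataFrame, partition: str, cohort: str | None,
             group: str, desc: str) -> pd.DataFrame:
        sel = subjects[(subjects["partition"] == partition)
                       & (subjects["group"] == group)]
        if cohort is not None:
            sel = sel[sel["cohort"] == cohort]
        ids = [s for s in sel.index if s in matrix.columns]
        if not ids:
            raise ValueError(f"comparison group empty: {desc}")
        return matrix[ids]

    return {
        COMPARISON_NAMES[0]: (
            cols(processed_discovery, "discovery", None, "case",
                 "discovery cases"),
            cols(processed_discovery, "discovery", None, "control",
                 "discovery controls")),
        COMPARISON_NAMES[1]: (
            cols(processed_validation, "validation", "canadian", "case",
                 "validation Canadian cases"),
            cols(processed_validation, "validation", "canadian", "control",
                 "validation Canadian controls")),
        COMPARISON_NAMES[2]: (
            cols(processed_validation, "validation", "norwegian", "case",
                 "Norwegian cases"),
            cols(processed_validation, "validation", "canadian", "control",
                 "validation Canadian controls")),
        COMPARISON_NAMES[3]: (
            cols(processed_validation, "validation", "norwegian", "case",
                 "Norwegian cases"),
            cols(processed_validation, "validation", "us", "control",
                 "US controls")),
    }


def refine_signature(signature: CandidateSignature,
                     comparisons: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
                     alpha: float = 0.05,
                     adjust: str | None = None,
                     refined_name: str | None = None,
                     ) -> tuple[CandidateSignature, RefinementReport]:
    """Keep the signature peptides significant in every comparison.

    ``comparisons`` maps a name to a pair of matrices (peptides x samples)
    holding the two groups' processed values; all signature peptides must be
    present in each.  ``adjust="bh"`` applies a Benjamini-Hochberg
    correction per comparison before thresholding (off by default).
    """
    ids = list(signature.peptide_ids)
    if not ids:
        raise ValueError(f"signature {signature.name!r} is empty")
    if not comparisons:
        raise ValueError("at least one comparison is required")
    pvals = {}
    sizes = {}
    for name, (ga, gb) in comparisons.items():
        for label, g in (("first", ga), ("second", gb)):
            missing = [p for p in ids if p not in g.index]
            if missing:
                raise ValueError(
                    f"comparison {name!r} ({label} group) lacks peptide "
                    f"{missing[0]!r}")
            if g.shape[1] < 2:
                raise ValueError(
                    f"comparison {name!r} ({label} group) has fewer than "
                    "2 samples")
        res = stats.ttest_ind(ga.loc[ids].to_numpy(), gb.loc[ids].to_numpy(),
                              axis=1, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        if adjust == "bh":
            p = multipletests(p, method="fdr_bh")[1]
        pvals[f"p_{name}"] = p
        sizes[name] = (ga.shape[1], gb.shape[1])
    table = pd.DataFrame(pvals, index=pd.Index(ids, name="peptide_id"))
    table["kept"] = (table < alpha).all(axis=1)
    kept = [pid for pid, keep in table["kept"].items() if keep]
    refined = CandidateSignature(
        name=refined_name or f"{signature.name}A",
        peptide_ids=sorted(kept),
        definition=(f"{signature.name} peptides with p < {alpha} in all "
                    f"{len(comparisons)} comparisons"),
        excluded=(len(kept) == 0))
    report = RefinementReport(table=table, alpha=alpha, comparisons=sizes,
                              adjust=adjust)
    return refined, report
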