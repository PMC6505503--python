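"""Raw-array preprocessing: control-peptide averaging, replicate QC,
replicate merging, and median/log2 normalization.

The output of :func:`normalize` is the "processed matrix" every analysis
stage consumes: analysis peptides only, one column per merged sample,
log2-transformed and median-centered so each sample's median over all
analysis peptides is exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Raw zero intensities are replaced by half the minimum detectable count
#: before log transformation, preserving rank order while avoiding -inf.
ZERO_REPLACEMENT = 0.5


@dataclass
class ReplicateQCReport:
    """Replicate-pair concordance statistics and removal decisions."""

    pair_stats: pd.DataFrame          # subject_id, array_a, array_b, spearman, flagged
    min_concordance: float
    removed_pair_subjects: list[str] = field(default_factory=list)
    removed_singletons: list[str] = field(default_factory=list)


@dataclass
class ProcessedMatrix:
    """Median-centered log2 matrix of analysis peptides by merged samples."""

    values: pd.DataFrame
    removed_pair_subjects: list[str] = field(default_factory=list)
    removed_singletons: list[str] = field(default_factory=list)


def average_control_peptides(raw: pd.DataFrame,
                             library: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Split off control peptides, reporting their per-array mean.

    Returns the matrix restricted to analysis peptides, and the arithmetic
    mean of control-peptide intensities per array (empty if the library has
    no controls).  The control summary is reported for QC only; it is not
    used to rescale samples.
    """
    known = set(library["peptide_id"])
    missing = [pid for pid in raw.index if pid not in known]
    if missing:
        raise ValueError(
            f"{len(missing)} peptide ids in matrix absent from library "
            f"(first: {missing[0]!r})")
    control_ids = library.loc[library["is_control"], "peptide_id"]
    control_rows = raw.index.intersection(control_ids)
    summary = (raw.loc[control_rows].mean(axis=0) if len(control_rows)
               else pd.Series(dtype=float))
    summary.name = "control_mean"
    analysis = raw.drop(index=control_rows)
    return analysis, summary


def _replicate_pairs(manifest: pd.DataFrame) -> pd.DataFrame:
    """One row per subject with its ordered array ids."""
    m = manifest.sort_values(["subject_id", "replicate_index"])
    return m.groupby("subject_id", sort=False)["array_id"].agg(list)


def test_replicate_outliers(analysis: pd.DataFrame, manifest: pd.DataFrame,
                            min_concordance: float = 0.8) -> ReplicateQCReport:
    """Flag replicate pairs whose rank concordance is suspiciously low.

    A pair is flagged when the Spearman correlation between its two arrays,
    over log2 analysis-peptide values, falls below ``min_concordance``; both
    members of a flagged pair are removed downstream.  Non-exempt singletons
    are listed for removal as well.
    """
    if not 0.0 <= min_concordance <= 1.0:
        raise ValueError("min_concordance must lie in [0, 1]")
    missing = set(manifest["array_id"]) - set(analysis.columns)
    if missing:
        raise ValueError(f"manifest arrays missing from matrix: {sorted(missing)[:3]}")
    log2 = np.log2(analysis.clip(lower=ZERO_REPLACEMENT))
    rows = []
    removed_singletons = []
    exempt = manifest.drop_duplicates("subject_id").set_index("subject_id")[
        "singleton_exempt"]
    for subject, arrays in _replicate_pairs(manifest).items():
        if len(arrays) == 1:
            if not exempt[subject]:
                removed_singletons.append(arrays[0])
            continue
        if len(arrays) > 2:
            raise ValueError(
                f"subject {subject!r} has {len(arrays)} replicates; "
                "only duplicates are supported")
        rho = stats.spearmanr(log2[arrays[0]], log2[arrays[1]]).statistic
        rows.append((subject, arrays[0], arrays[1], rho, rho < min_concordance))
    pair_stats = pd.DataFrame(
        rows, columns=["subject_id", "array_a", "array_b", "spearman", "flagged"])
    flagged = pair_stats.loc[pair_stats["flagged"], "subject_id"].tolist()
    if flagged:
        logger.info("replicate QC flagged %d pair(s): %s", len(flagged), flagged)
    return ReplicateQCReport(pair_stats=pair_stats,
                             min_concordance=min_concordance,
                             removed_pair_subjects=flagged,
                             removed_singletons=removed_singletons)


def merge_replicates(analysis: pd.DataFrame, manifest: pd.DataFrame,
                     qc: ReplicateQCReport) -> pd.DataFrame:
    """Collapse arrays to one column per subject.

    Surviving duplicate pairs are averaged element-wise; flagged pairs are
    dropped entirely; singletons are dropped unless marked exempt in the
    manifest.  Columns are named by subject id, in manifest order.
    """
    flagged = set(qc.removed_pair_subjects)
    exempt = manifest.drop_duplicates("subject_id").set_index("subject_id")[
        "singleton_exempt"]
    merged = {}
    for subject, arrays in _replicate_pairs(manifest).items():
        if len(arrays) > 2:
            raise ValueError(
                f"subject {subject!r} has {len(arrays)} replicates; "
                "only duplicates are supported")
        if subject in flagged:
            continue
        if len(arrays) == 1:
            if exempt[subject]:
                merged[subject] = analysis[arrays[0]].astype(float)
            continue
        merged[subject] = analysis[arrays].mean(axis=1)
    out = pd.DataFrame(merged)
    out.index.name = "peptide_id"
    return out


def normalize(merged: pd.DataFrame,
              provenance: ReplicateQCReport | None = None) -> ProcessedMatrix:
    """Median-center each sample on the log2 scale.

    Each sample is divided by its median peptide abundance and
    log2-transformed, putting the median peptide value of every processed
    sample at zero (the centering is performed in log space, which is
    exact for any peptide count).  Zeros are replaced by
    :data:`ZERO_REPLACEMENT` first; a non-positive sample median is an error.
    """
    values = merged.astype(float)
    if (values.to_numpy() < 0).any():
        bad = values.columns[(values < 0).any(axis=0)][0]
        raise ValueError(f"negative abundances in sample {bad!r}")
    medians = values.median(axis=0)
    nonpos = medians.index[medians <= 0]
    if len(nonpos):
        raise ValueError(
            f"sample {nonpos[0]!r} has non-positive median abundance "
            f"({medians[nonpos[0]]})")
    log2 = np.log2(values.clip(lower=ZERO_REPLACEMENT))
    centered = log2 - log2.median(axis=0)
    return ProcessedMatrix(
        values=centered,
        removed_pair_subjects=list(provenance.removed_pair_subjects) if provenance else [],
        removed_singletons=list(provenance.removed_singletons) if provenance else [])


def subject_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-subject view of an array manifest (group, cohort, partition)."""
    cols = ["subject_id", "group", "cohort", "partition", "singleton_exempt"]
    return (manifest.drop_duplicates("subject_id")[cols]
            .set_index("subject_id"))


def preprocess(raw: pd.DataFrame, manifest: pd.DataFrame, library: pd.DataFrame,
               min_concordance: float = 0.8,
               ) -> tuple[ProcessedMatrix, ReplicateQCReport, pd.Series]:
    """Run the full preprocessing chain on a raw abundance matrix.

    Returns the processed matrix, the replicate-QC report and the per-array
    control-peptide means.
    """
    analysis, control_summary = average_control_peptides(raw, library)
    qc = test_replicate_outliers(analysis, manifest, min_concordance)
    merged = merge_replicates(analysis, manifest, qc)
    processed = normalize(merged, provenance=qc)
    return processed, qc, control_summary
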