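"""Synthetic peptide-array immunosignature data.

Generates random-sequence peptide libraries, multi-cohort case/control study
designs, and raw 16-bit fluorescence abundance matrices with a planted
case-vs-control signature, so that every downstream analysis stage can be
exercised and benchmarked against known ground truth.

The generative model, per peptide ``p`` and subject ``s`` on the log2 scale::

    y[p, s] = b_p + delta_p * 1{s is case} + eps[p, s]

where ``b_p ~ N(baseline_mean, baseline_sd)`` is the peptide's baseline
log2 intensity, ``delta_p = sign_p * effect_size * sigma_p`` on planted
signature peptides (zero elsewhere), and ``eps`` is between-subject
biological noise of SD ``sigma_p``.  For signature peptides a fraction
``signature_coherence`` of that noise variance is shared through a common
per-subject factor — the continuously varying antibody titer that makes
signature peptides co-vary as a coherent block::

    eps[p, s] = sigma_p * (sqrt(1 - rho) * noise[p, s]
                           + sign_p * sqrt(rho) * titer[s])

so the per-peptide within-group SD remains exactly ``sigma_p`` and
``effect_size`` keeps its meaning as a standardized mean difference.
Each physical array then adds a per-batch, per-peptide shift
``N(0, batch_shift_sd)`` and technical replicate noise
``N(0, log2(1 + replicate_cv))``.  Values are exponentiated, rounded and
clipped to the 16-bit digitizer range [0, 65535].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: 16-letter amino-acid alphabet used on the array: the 20 proteinogenic
#: residues excluding threonine, methionine, isoleucine and cysteine.
ALPHABET = "ADEFGHKLNPQRSVWY"

#: Library-synthesis peptide length.
PEPTIDE_LENGTH = 12

#: Upper detection limit of the 16-bit fluorescence digitizer.
INTENSITY_CEILING = 65535

#: Full-scale library composition: total synthesized peptides and the number
#: that survive to analysis; the remainder are array-control features.
FULL_SCALE_TOTAL_PEPTIDES = 125_000
FULL_SCALE_ANALYSIS_PEPTIDES = 122_926

MANIFEST_COLUMNS = [
    "array_id",
    "subject_id",
    "group",
    "cohort",
    "partition",
    "replicate_index",
    "batch",
    "singleton_exempt",
]

#: Default study design: Discovery = 22 Canadian cases + 21 Canadian controls;
#: Validation = 22 Norwegian cases + 6 US controls (singletons) + 6 Canadian
#: cases + 7 Canadian controls.  All non-US samples run as technical
#: duplicates; discovery and validation arrays belong to separate assay runs.
PAPER_DEFAULT_DESIGN: tuple[dict, ...] = (
    dict(n=22, group="case", cohort="canadian", partition="discovery"),
    dict(n=21, group="control", cohort="canadian", partition="discovery"),
    dict(n=22, group="case", cohort="norwegian", partition="validation"),
    dict(n=6, group="control", cohort="us", partition="validation",
         replicates=1, singleton_exempt=True),
    dict(n=6, group="case", cohort="canadian", partition="validation"),
    dict(n=7, group="control", cohort="canadian", partition="validation"),
)


def generate_peptide_library(n_analysis: int, n_control: int,
                             length: int = PEPTIDE_LENGTH,
                             seed: int = 0) -> pd.DataFrame:
    """Draw a library of unique random-sequence peptides.

    Parameters
    ----------
    n_analysis, n_control
        Number of analysis features and of control peptides.  Controls carry
        no group effect in the simulator and are stripped out during
        preprocessing.
    length
        Residues per peptide.
    seed
        Seed for the sequence draw; identical seeds give identical libraries.

    Returns
    -------
    DataFrame with columns ``peptide_id``, ``sequence``, ``is_control``.
    """
    total = n_analysis + n_control
    if total < 1:
        raise ValueError("n_analysis + n_control must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    capacity = len(ALPHABET) ** length
    if total > capacity:
        raise ValueError(
            f"requested {total} unique peptides but only {capacity} "
            f"length-{length} sequences exist over a {len(ALPHABET)}-letter "
            "alphabet")
    rng = np.random.default_rng(seed)
    letters = np.array(list(ALPHABET))
    seen: dict[str, None] = {}
    # rejection-sample batches; collisions are vanishingly rare at array scale
    while len(seen) < total:
        need = total - len(seen)
        idx = rng.integers(0, len(ALPHABET), size=(max(need, 32), length))
        for row in letters[idx]:
            seen.setdefault("".join(row))
            if len(seen) == total:
                break
    sequences = list(itertools.islice(seen, total))
    n_digits = max(6, len(str(total)))
    ids = ([f"P{i:0{n_digits}d}" for i in range(n_analysis)]
           + [f"CTRL{i:04d}" for i in range(n_control)])
    flags = [False] * n_analysis + [True] * n_control
    return pd.DataFrame(
        {"peptide_id": ids, "sequence": sequences, "is_control": flags})


def generate_design(template: str = "paper_default",
                    params: Sequence[Mapping] | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Build a per-array sample manifest.

    ``template="paper_default"`` realizes the default multi-cohort design
    (see :data:`PAPER_DEFAULT_DESIGN`); ``template="custom"`` takes
    ``params``, a sequence of dicts with keys ``n``, ``group``, ``cohort``,
    ``partition`` and optional ``replicates`` (default 2), ``batch`` and
    ``singleton_exempt`` (default False).

    Returns a DataFrame with one row per physical array
    (columns :data:`MANIFEST_COLUMNS`).
    """
    if template == "paper_default":
        groups = PAPER_DEFAULT_DESIGN
    elif template == "custom":
        if params is None:
            raise ValueError("custom template requires params")
        groups = tuple(params)
    else:
        raise ValueError(f"unknown design template: {template!r}")

    rows = []
    for spec in groups:
        n = int(spec["n"])
        if n < 0:
            raise ValueError("group counts must be non-negative")
        if n == 0:
            continue
        group, cohort, partition = spec["group"], spec["cohort"], spec["partition"]
        replicates = int(spec.get("replicates", 2))
        exempt = bool(spec.get("singleton_exempt", False))
        batch = spec.get("batch") or f"assay_{partition}"
        for i in range(n):
            subject = f"{cohort[:3]}-{group[:4]}-{partition[:3]}-{i + 1:02d}"
            for r in range(1, replicates + 1):
                rows.append((f"{subject}-r{r}", subject, group, cohort,
                             partition, r, batch, exempt))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest["array_id"].duplicated().any():
        dup = manifest.loc[manifest["array_id"].duplicated(), "array_id"].iloc[0]
        raise ValueError(f"duplicate array_id generated: {dup}")
    return manifest


def choose_outlier_arrays(manifest: pd.DataFrame, n_pairs: int,
                          seed: int = 0,
                          partition: str | None = None) -> list[str]:
    """Pick one array from each of ``n_pairs`` duplicated subjects.

    The returned array ids are meant for ``SignalSpec.outlier_replicate_ids``,
    turning those arrays into across-peptide permutations that replicate-QC
    should flag.
    """
    m = manifest if partition is None else manifest[manifest["partition"] == partition]
    counts = m.groupby("subject_id")["array_id"].count()
    duplicated = sorted(counts.index[counts == 2])
    if n_pairs > len(duplicated):
        raise ValueError(
            f"requested {n_pairs} outlier pairs but only {len(duplicated)} "
            "duplicated subjects available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.array(duplicated, dtype=object), size=n_pairs,
                        replace=False)
    second = m.sort_values(["subject_id", "replicate_index"]).groupby(
        "subject_id")["array_id"].last()
    return [second[s] for s in sorted(chosen)]


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of the planted case-vs-control signal and noise model.

    ``effect_size`` is the case-minus-control shift on the log2 scale in
    units of the peptide's between-subject SD; ``effect_sign_mix`` is the
    fraction of planted peptides shifted downward in cases.
    """

    n_signature_peptides: int = 100
    effect_size: float = 1.5
    effect_sign_mix: float = 0.5
    baseline_mean_sd: tuple[float, float] = (10.0, 1.5)
    subject_sd: float = 0.5          # median between-subject log2 SD
    subject_sd_dispersion: float = 0.25  # lognormal spread of per-peptide SDs
    signature_coherence: float = 0.5  # shared-titer fraction of signal variance
    replicate_cv: float = 0.10
    batch_shift_sd: float = 0.3
    outlier_replicate_ids: tuple[str, ...] = ()
    saturation_limit: int = INTENSITY_CEILING
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_sign_mix <= 1.0:
            raise ValueError("effect_sign_mix must lie in [0, 1]")
        if not 0.0 <= self.signature_coherence <= 1.0:
            raise ValueError("signature_coherence must lie in [0, 1]")
        if self.n_signature_peptides < 0:
            raise ValueError("n_signature_peptides must be >= 0")
        if self.saturation_limit < 1:
            raise ValueError("saturation_limit must be >= 1")


@dataclass
class SimulatedDataset:
    """Raw abundance matrix plus the planted ground truth."""

    abundance: pd.DataFrame            # peptides x arrays, integer counts
    planted_peptides: list[str] = field(default_factory=list)
    effects: pd.Series | None = None   # signed log2 shift per planted peptide
    library: pd.DataFrame | None = None
    manifest: pd.DataFrame | None = None
    spec: SignalSpec | None = None


def simulate_abundances(library: pd.DataFrame, manifest: pd.DataFrame,
                        spec: SignalSpec) -> SimulatedDataset:
    """Simulate a raw peptides-by-arrays abundance matrix.

    Planted effects are applied at the subject level, before replicate noise
    and batch shifts, so both study partitions carry the signal.  Identical
    ``(library, manifest, spec)`` — including ``spec.seed`` — produce a
    bitwise-identical matrix.
    """
    if len(library) == 0:
        raise ValueError("peptide library is empty")
    if len(manifest) == 0:
        raise ValueError("sample manifest is empty")
    analysis_ids = library.loc[~library["is_control"], "peptide_id"].to_numpy()
    if spec.n_signature_peptides > len(analysis_ids):
        raise ValueError(
            f"n_signature_peptides={spec.n_signature_peptides} exceeds the "
            f"{len(analysis_ids)} analysis features in the library")
    unknown = set(spec.outlier_replicate_ids) - set(manifest["array_id"])
    if unknown:
        raise ValueError(f"outlier_replicate_ids not in manifest: {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    p = len(library)
    peptide_ids = library["peptide_id"].to_numpy()
    is_control = library["is_control"].to_numpy()

    mu, sd = spec.baseline_mean_sd
    baseline = rng.normal(mu, sd, size=p)
    sigma = spec.subject_sd * np.exp(
        rng.normal(0.0, spec.subject_sd_dispersion, size=p))

    # plant the signature among analysis peptides only
    delta = np.zeros(p)
    planted_pos = np.array([], dtype=int)
    signs = np.array([])
    planted: list[str] = []
    if spec.n_signature_peptides > 0:
        analysis_pos = np.flatnonzero(~is_control)
        planted_pos = rng.choice(analysis_pos, size=spec.n_signature_peptides,
                                 replace=False)
        n_neg = int(round(spec.effect_sign_mix * spec.n_signature_peptides))
        signs = np.ones(spec.n_signature_peptides)
        signs[:n_neg] = -1.0
        rng.shuffle(signs)
        delta[planted_pos] = signs * spec.effect_size * sigma[planted_pos]
        planted = sorted(peptide_ids[planted_pos])

    subjects = manifest.drop_duplicates("subject_id")
    subj_ids = subjects["subject_id"].to_numpy()
    is_case = (subjects["group"].to_numpy() == "case")
    n_subj = len(subj_ids)
    noise = rng.normal(0.0, 1.0, size=(p, n_subj))
    titer = rng.normal(0.0, 1.0, size=n_subj)
    if len(planted_pos) and spec.signature_coherence > 0:
        # share a fraction of signature-peptide variance through the common
        # per-subject titer factor; per-peptide within-group SD is unchanged
        rho = spec.signature_coherence
        noise[planted_pos] = (np.sqrt(1.0 - rho) * noise[planted_pos]
                              + signs[:, None] * np.sqrt(rho) * titer[None, :])
    latent = (baseline[:, None]
              + np.where(is_case[None, :], delta[:, None], 0.0)
              + noise * sigma[:, None])
    subj_col = {s: j for j, s in enumerate(subj_ids)}

    batches = list(dict.fromkeys(manifest["batch"]))
    batch_shift = {b: rng.normal(0.0, spec.batch_shift_sd, size=p)
                   for b in batches}

    tech_sd = np.log2(1.0 + spec.replicate_cv)
    values = np.empty((p, len(manifest)))
    for a, row in enumerate(manifest.itertuples(index=False)):
        y = latent[:, subj_col[row.subject_id]] + batch_shift[row.batch]
        if tech_sd > 0:
            y = y + rng.normal(0.0, tech_sd, size=p)
        values[:, a] = y

    raw = np.clip(np.rint(np.exp2(values)), 0, spec.saturation_limit)
    raw = raw.astype(np.int64)
    abundance = pd.DataFrame(raw, index=pd.Index(peptide_ids, name="peptide_id"),
                             columns=manifest["array_id"].to_numpy())

    for aid in spec.outlier_replicate_ids:
        perm = rng.permutation(p)
        abundance[aid] = abundance[aid].to_numpy()[perm]

    effects = pd.Series(delta[np.isin(peptide_ids, planted)],
                        index=[pid for pid in peptide_ids if pid in set(planted)],
                        name="log2_effect") if planted else None
    return SimulatedDataset(abundance=abundance, planted_peptides=planted,
                            effects=effects, library=library,
                            manifest=manifest, spec=spec)
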