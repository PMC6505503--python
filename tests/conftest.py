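"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import immunosig as im


def two_group_design(n_case: int, n_control: int, replicates: int = 1,
                     cohort: str = "canadian", partition: str = "discovery",
                     ) -> pd.DataFrame:
    """Convenience single-cohort case/control manifest."""
    return im.generate_design("custom", params=[
        dict(n=n_case, group="case", cohort=cohort, partition=partition,
             replicates=replicates),
        dict(n=n_control, group="control", cohort=cohort,
             partition=partition, replicates=replicates),
    ])


@pytest.fixture(scope="session")
def paper_manifest() -> pd.DataFrame:
    return im.generate_design()


@pytest.fixture(scope="session")
def small_dataset():
    """2000-peptide default-design dataset with the default planted signal."""
    library = im.generate_peptide_library(2000, 40, seed=101)
    manifest = im.generate_design()
    spec = im.SignalSpec(seed=202)
    dataset = im.simulate_abundances(library, manifest, spec)
    return library, manifest, dataset


@pytest.fixture(scope="session")
def small_processed(small_dataset):
    """Processed matrices and labels for both partitions of the small set."""
    library, manifest, dataset = small_dataset
    processed, qc, _ = im.preprocess(dataset.abundance, manifest, library)
    subjects = im.subject_table(manifest)
    disc = [s for s in subjects.index
            if subjects.loc[s, "partition"] == "discovery"
            and s in processed.values.columns]
    val = [s for s in subjects.index
           if subjects.loc[s, "partition"] == "validation"
           and s in processed.values.columns]
    return {
        "discovery": processed.values[disc],
        "validation": processed.values[val],
        "labels_discovery": subjects.loc[disc, "group"].tolist(),
        "labels_validation": subjects.loc[val, "group"].tolist(),
        "subjects": subjects,
        "planted": set(dataset.planted_peptides),
    }


def simulate_processed(n_peptides: int, seed: int, effect_size: float = 1.5,
                       n_signature: int = 100, **spec_kwargs):
    """One-call generator -> preprocess -> discovery/validation split."""
    library = im.generate_peptide_library(n_peptides, 0, seed=seed)
    manifest = im.generate_design()
    spec = im.SignalSpec(n_signature_peptides=n_signature,
                         effect_size=effect_size, seed=seed + 1,
                         **spec_kwargs)
    dataset = im.simulate_abundances(library, manifest, spec)
    processed, _, _ = im.preprocess(dataset.abundance, manifest, library)
    subjects = im.subject_table(manifest)
    out = {"planted": set(dataset.planted_peptides), "subjects": subjects}
    for part in ("discovery", "validation"):
        cols = [s for s in subjects.index
                if subjects.loc[s, "partition"] == part
                and s in processed.values.columns]
        out[part] = processed.values[cols]
        out[f"labels_{part}"] = subjects.loc[cols, "group"].tolist()
    return out
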