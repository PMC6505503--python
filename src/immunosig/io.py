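"""File-format dialects: TSV matrices, CSV manifests, JSON panels/signatures.

Matrix orientation is fixed everywhere as peptides in rows and samples in
columns, with the first column holding peptide ids.  All writers produce
files the package's own readers round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .discovery import PeptideList
from .preprocess import ReplicateQCReport
from .signatures import CandidateSignature, Panel
from .synthetic import MANIFEST_COLUMNS


def write_matrix(matrix: pd.DataFrame, path, float_format: str | None = None,
                 ) -> None:
    """Write a peptides-by-samples matrix as TSV (first column peptide_id)."""
    out = matrix.copy()
    out.index.name = "peptide_id"
    out.to_csv(path, sep="\t", float_format=float_format)


def write_processed_matrix(matrix: pd.DataFrame, path) -> None:
    """Processed matrices are written with 6 significant digits."""
    write_matrix(matrix, path, float_format="%.6g")


def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix, validating header, ids and cell contents."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "peptide_id":
        raise ValueError(
            f"{path}:1: malformed header; first column must be 'peptide_id' "
            f"(got {header[:1]})")
    if len(header) != len(set(header)):
        dup = [h for h in header if header.count(h) > 1][0]
        raise ValueError(f"{path}:1: duplicated column id {dup!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated peptide id {dup!r}")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & ~df.isna()
    if bad.to_numpy().any() or df.isna().to_numpy().any():
        mask = values.isna().to_numpy()
        r, c = np.argwhere(mask)[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at row {df.index[r]!r} "
            f"(line {r + 2}), column {df.columns[c]!r}")
    # integer matrices stay integer through a round trip
    arr = values.to_numpy()
    if np.all(np.mod(arr, 1) == 0):
        values = values.astype(np.int64)
    values.index.name = "peptide_id"
    return values


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    if df["array_id"].duplicated().any():
        dup = df.loc[df["array_id"].duplicated(), "array_id"].iloc[0]
        raise ValueError(f"{path}: duplicate array_id {dup!r}")
    df["singleton_exempt"] = df["singleton_exempt"].astype(bool)
    return df[MANIFEST_COLUMNS + [c for c in df.columns
                                  if c not in MANIFEST_COLUMNS]]


def write_library(library: pd.DataFrame, path) -> None:
    library.to_csv(path, sep="\t", index=False)


def read_library(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["peptide_id", "sequence", "is_control"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: library missing columns {missing}")
    if df["peptide_id"].duplicated().any():
        dup = df.loc[df["peptide_id"].duplicated(), "peptide_id"].iloc[0]
        raise ValueError(f"{path}: duplicate peptide_id {dup!r}")
    df["is_control"] = df["is_control"].astype(bool)
    return df[required]


def write_id_list(ids, path) -> None:
    """Flat one-id-per-line text file."""
    Path(path).write_text("".join(f"{pid}\n" for pid in ids))


def read_id_list(path) -> list[str]:
    return [line for line in Path(path).read_text().splitlines() if line]


def _jsonable(obj):
    if isinstance(obj, pd.Series):
        return {str(k): (None if pd.isna(v) else float(v))
                for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_panel(panel: Panel | PeptideList, path) -> None:
    """Panel or peptide list as JSON (name, params, ids, scores)."""
    payload = {"name": panel.name,
               "peptide_ids": list(panel.peptide_ids)}
    if isinstance(panel, Panel):
        payload["constituent_lists"] = list(panel.constituent_lists)
        payload["selection_rule"] = _scrub(panel.selection_rule)
    else:
        payload["method_params"] = _scrub(panel.method_params)
        if panel.scores is not None:
            payload["scores"] = _jsonable(panel.scores)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _scrub(d: dict) -> dict:
    return json.loads(json.dumps(d, default=_jsonable))


def read_panel(path) -> Panel:
    payload = json.loads(Path(path).read_text())
    return Panel(name=payload["name"], peptide_ids=payload["peptide_ids"],
                 constituent_lists=payload.get("constituent_lists", []),
                 selection_rule=payload.get("selection_rule",
                                            payload.get("method_params", {})))


def write_signature(sig: CandidateSignature, path) -> None:
    payload = {"name": sig.name, "definition": sig.definition,
               "peptide_ids": list(sig.peptide_ids),
               "excluded": sig.excluded, "carried": sig.carried}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_signature(path) -> CandidateSignature:
    payload = json.loads(Path(path).read_text())
    return CandidateSignature(
        name=payload["name"], peptide_ids=payload["peptide_ids"],
        definition=payload.get("definition", ""),
        excluded=payload.get("excluded", len(payload["peptide_ids"]) == 0),
        carried=payload.get("carried", True))


def write_qc_report(qc: ReplicateQCReport, path) -> None:
    payload = {
        "min_concordance": qc.min_concordance,
        "pairs": qc.pair_stats.to_dict(orient="records"),
        "removed_pair_subjects": list(qc.removed_pair_subjects),
        "removed_singletons": list(qc.removed_singletons),
    }
    Path(path).write_text(json.dumps(_scrub(payload), indent=1,
                                     sort_keys=True) + "\n")
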