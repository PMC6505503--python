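"""Panel assembly and candidate-signature set algebra.

Each feature-selection method contributes one panel: the supervised methods
pass their single list through unchanged, while for each unsupervised method
the ten lists are scored by signature-score AUC on the discovery data and
the best-separating lists (within an AUC tolerance of the best, up to
``max_lists``) are unioned.  Candidate signatures CPS001-CPS007 are then
fixed unions/intersections of the six panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .discovery import PeptideList
from .evaluate import signature_score

PANEL_NAMES = ("sPCA_panel", "sIPCA_panel", "GS_panel",
               "RL_panel", "RF_panel", "EN_panel")
UNSUPERVISED_PANELS = ("sPCA_panel", "sIPCA_panel", "GS_panel")
SUPERVISED_PANELS = ("RL_panel", "RF_panel", "EN_panel")


@dataclass
class Panel:
    """Union of the selected peptide lists from one method."""

    name: str
    peptide_ids: list[str]
    constituent_lists: list[str] = field(default_factory=list)
    selection_rule: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peptide_ids)


@dataclass
class CandidateSignature:
    """A named peptide set defined by set algebra over panels."""

    name: str
    peptide_ids: list[str]
    definition: str
    excluded: bool = False      # empty signatures are excluded from evaluation
    carried: bool = True        # rejected alternatives are reported only

    def __len__(self) -> int:
        return len(self.peptide_ids)


def _union_ordered(id_lists: Sequence[Iterable[str]]) -> list[str]:
    seen: dict[str, None] = {}
    for ids in id_lists:
        for pid in ids:
            seen.setdefault(pid)
    return list(seen)


def assemble_panel(lists: Sequence[PeptideList],
                   X: pd.DataFrame | None = None,
                   labels=None,
                   max_lists: int = 2,
                   auc_tolerance: float = 0.02,
                   score_fn: Callable[[PeptideList], float] | None = None,
                   name: str | None = None) -> Panel:
    """Combine a method's lists into one panel.

    A single list passes through unchanged (the supervised case).  With
    several lists, each is scored by the AUC of its signature score on the
    discovery data (``score_fn`` overrides the scorer, e.g. for testing the
    rule in isolation); the best list and every list within ``auc_tolerance``
    of it — at most ``max_lists`` in total, best first — are unioned.
    """
    if not lists:
        raise ValueError("assemble_panel requires at least one list")
    panel_name = name or f"{lists[0].name.rstrip('0123456789')}_panel"
    if len(lists) == 1:
        lst = lists[0]
        return Panel(name=panel_name, peptide_ids=list(lst.peptide_ids),
                     constituent_lists=[lst.name],
                     selection_rule={"rule": "pass_through"})
    if score_fn is None:
        if X is None or labels is None:
            raise ValueError(
                "scoring multiple lists requires X and labels (or score_fn)")

        def score_fn(lst: PeptideList) -> float:
            return signature_score(X, lst.peptide_ids, labels).auc

    aucs = [(score_fn(lst) if len(lst) else float("nan")) for lst in lists]
    scored = [(a, i) for i, a in enumerate(aucs) if a == a]  # drop NaN/empty
    if not scored:
        raise ValueError("no non-empty lists to assemble")
    scored.sort(key=lambda t: (-t[0], t[1]))
    best = scored[0][0]
    chosen = [i for a, i in scored if a >= best - auc_tolerance][:max_lists]
    return Panel(
        name=panel_name,
        peptide_ids=_union_ordered([lists[i].peptide_ids for i in chosen]),
        constituent_lists=[lists[i].name for i in chosen],
        selection_rule={"rule": "best_auc_within_tolerance",
                        "auc_tolerance": auc_tolerance,
                        "max_lists": max_lists,
                        "list_aucs": {lists[i].name: a for a, i in scored}})


def _ids(panel) -> set[str]:
    return set(getattr(panel, "peptide_ids", panel))


def build_candidate_signatures(panels: Mapping[str, object],
                               ) -> dict[str, CandidateSignature]:
    """Construct CPS001-CPS007 (plus the rejected CPS001 alternative).

    ``panels`` maps the six panel names to Panel objects (or plain peptide-id
    collections).  Definitions::

        CPS001 = GS ∩ (RL ∪ RF ∪ EN)
        CPS002 = sPCA ∪ sIPCA ∪ GS          CPS003 = sPCA ∩ sIPCA ∩ GS
        CPS004 = RL ∪ RF ∪ EN               CPS005 = RL ∩ RF ∩ EN
        CPS006 = union of all six           CPS007 = intersection of all six

    Empty signatures are flagged ``excluded``.  The alternative
    ``CPS001_alt = GS ∩ RL ∩ RF ∩ EN`` is computed for reporting but marked
    not carried forward.
    """
    missing = [n for n in PANEL_NAMES if n not in panels]
    if missing:
        raise ValueError(f"missing panels: {missing}")
    spca, sipca, gs = (_ids(panels[n]) for n in UNSUPERVISED_PANELS)
    rl, rf, en = (_ids(panels[n]) for n in SUPERVISED_PANELS)
    defs = {
        "CPS001": (gs & (rl | rf | en), "GS ∩ (RL ∪ RF ∪ EN)"),
        "CPS002": (spca | sipca | gs, "sPCA ∪ sIPCA ∪ GS"),
        "CPS003": (spca & sipca & gs, "sPCA ∩ sIPCA ∩ GS"),
        "CPS004": (rl | rf | en, "RL ∪ RF ∪ EN"),
        "CPS005": (rl & rf & en, "RL ∩ RF ∩ EN"),
        "CPS006": (spca | sipca | gs | rl | rf | en, "union of all six panels"),
        "CPS007": (spca & sipca & gs & rl & rf & en,
                   "intersection of all six panels"),
        "CPS001_alt": (gs & rl & rf & en, "GS ∩ RL ∩ RF ∩ EN (rejected)"),
    }
    out = {}
    for nm, (ids, expr) in defs.items():
        out[nm] = CandidateSignature(
            name=nm, peptide_ids=sorted(ids), definition=expr,
            excluded=(len(ids) == 0), carried=(nm != "CPS001_alt"))
    return out


def summary_table(signatures: Mapping[str, CandidateSignature]) -> pd.DataFrame:
    """Signature name / size / excluded-flag summary."""
    rows = [(s.name, len(s), s.excluded, s.carried, s.definition)
            for s in signatures.values()]
    return pd.DataFrame(rows, columns=["signature", "size", "excluded",
                                       "carried", "definition"])
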