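"""Sensitivity/specificity scoring of screen output against truth labels.

Sensitivity is the percentage of contaminant sequences assigned a
corrective action (EXCLUDE, TRIM, FIX) whose reported division matches the
taxonomic division of the true source genome; sequences assigned as
prokaryote virus count as true positives for prokaryote sources.
Specificity is the percentage of non-contaminant sequences remaining after
subtracting those assigned a corrective or review action (EXCLUDE, TRIM,
FIX, REVIEW).  Sequence-level specificity bounds follow the length-based
formulas: the upper bound treats only same-kingdom calls as false
positives, the lower bound treats every call as one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .report_io import ActionRecord
from .taxonomy import superkingdom

__all__ = ["EvalResult", "evaluate_sn_sp"]

CORRECTIVE = {"EXCLUDE", "TRIM", "FIX"}
PENALIZED = {"EXCLUDE", "TRIM", "FIX", "REVIEW"}


@dataclass
class EvalResult:
    sensitivity: float | None  # percent, None when no contaminant truth rows
    specificity: float | None  # percent, None when no clean truth rows
    n_contaminant_truth: int
    n_clean_truth: int
    true_positives: int
    false_positives: int
    action_counts: dict[str, int] = field(default_factory=dict)
    seq_level_sp_upper: float | None = None
    seq_level_sp_lower: float | None = None


def _division_matches(reported: str, true_division: str, true_kingdom: str) -> bool:
    if reported == true_division:
        return True
    # prokaryote-virus assignments count as true positives for prokaryote sources
    if superkingdom(true_kingdom) == "prokaryote" and reported == "virs:prokaryotic viruses":
        return True
    return False


def evaluate_sn_sp(
    records: list[ActionRecord],
    truth: pd.DataFrame,
    sequence_lengths: dict[str, int],
) -> EvalResult:
    """Score an action report against truth labels.

    ``truth`` has columns ``seq_id, role, taxid, division, kingdom`` where
    role is ``host`` (clean), ``contaminant``, or ``chimera`` (a host
    sequence carrying a contaminant span).  Records referencing unknown
    sequence ids are a hard error.
    """
    known = set(truth["seq_id"])
    for r in records:
        if r.seq_id not in known:
            raise KeyError(f"action report references unknown sequence {r.seq_id!r}")

    by_seq: dict[str, list[ActionRecord]] = {}
    for r in records:
        by_seq.setdefault(r.seq_id, []).append(r)

    action_counts: dict[str, int] = {}
    for r in records:
        action_counts[r.action] = action_counts.get(r.action, 0) + 1

    tp = 0
    n_contaminant = 0
    fp = 0
    n_clean = 0
    for row in truth.itertuples(index=False):
        recs = by_seq.get(row.seq_id, [])
        if row.role in ("contaminant", "chimera"):
            n_contaminant += 1
            if any(
                r.action in CORRECTIVE
                and _division_matches(r.division, row.division, row.kingdom)
                for r in recs
            ):
                tp += 1
        else:
            n_clean += 1
            if any(r.action in PENALIZED for r in recs):
                fp += 1

    sensitivity = 100.0 * tp / n_contaminant if n_contaminant else None
    specificity = 100.0 * (n_clean - fp) / n_clean if n_clean else None

    # sequence-level bounds over clean (host) sequences, length based
    clean_ids = set(truth.loc[truth["role"] == "host", "seq_id"])
    total_len = sum(sequence_lengths[s] for s in clean_ids)
    same_kingdom_call_len = 0
    cross_kingdom_call_len = 0
    host_kingdoms = dict(
        zip(truth["seq_id"], truth["kingdom"])
    )
    for r in records:
        if r.seq_id not in clean_ids or r.action not in PENALIZED:
            continue
        span = r.end_pos - r.start_pos + 1
        # division prefix identifies the call's kingdom group coarsely;
        # compare superkingdoms via the truth table's host kingdom
        if _call_same_kingdom(r.division, host_kingdoms[r.seq_id]):
            same_kingdom_call_len += span
        else:
            cross_kingdom_call_len += span
    sp_upper = sp_lower = None
    if total_len:
        denom = total_len - cross_kingdom_call_len
        sp_upper = 100.0 * (1 - same_kingdom_call_len / denom) if denom else None
        sp_lower = 100.0 * (
            1 - (same_kingdom_call_len + cross_kingdom_call_len) / total_len
        )

    return EvalResult(
        sensitivity=sensitivity,
        specificity=specificity,
        n_contaminant_truth=n_contaminant,
        n_clean_truth=n_clean,
        true_positives=tp,
        false_positives=fp,
        action_counts=action_counts,
        seq_level_sp_upper=sp_upper,
        seq_level_sp_lower=sp_lower,
    )


_PREFIX_KINGDOM = {
    "anml": "Metazoa",
    "plnt": "Viridiplantae",
    "fung": "Fungi",
    "prot": "other-Eukaryota",
    "prok": "Bacteria",
    "arch": "Archaea",
    "virs": "Viruses",
    "synt": "Synthetic",
}


def _call_same_kingdom(call_division: str, host_kingdom: str) -> bool:
    prefix = call_division.split(":", 1)[0]
    call_kingdom = _PREFIX_KINGDOM.get(prefix, "")
    return call_kingdom == host_kingdom
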