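"""Partial-credit scoring of forced-choice emotion judgements.

Single-judgement (nonverbal/verbal) items are scored trichotomously:

* 2 - the target emotion was selected (correct),
* 1 - a plausible distractor was selected (partially correct),
* 0 - anything else (inaccurate).

Concealed-emotion items collect two judgements (displayed and concealed
emotion) and are scored on four ordered categories:

* 3 - both judgements match their targets (correct),
* 2 - both target labels selected but the felt and expressed emotion were
      confused, i.e., fully swapped (mostly correct),
* 1 - exactly one of the two target labels was selected, in either slot
      (somewhat correct),
* 0 - neither target label selected (inaccurate).

Ordered categories reflect degrees of correctness: emotions form a fuzzy
set, so near-miss labels carry real information about perception ability
and a graded (rather than right/wrong) response model is appropriate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import (
    MISSING,
    GradedMatrix,
    ItemBank,
    ItemKey,
    ResponseTable,
    ValidationError,
)
from .labels import normalize_label

M_BY_MODALITY = {"nonverbal": 3, "verbal": 3, "concealed": 4}


def score_choice(choice: str, key: ItemKey) -> int:
    """Trichotomous score of a single-judgement response: 0, 1, or 2."""
    choice = normalize_label(choice)
    if choice not in key.options:
        raise ValidationError(
            f"item {key.item_id}: choice {choice!r} is not one of the item's options"
        )
    if choice == key.correct[0]:
        return 2
    if choice in key.partial:
        return 1
    return 0


def score_concealed(choice_displayed: str, choice_concealed: str, key: ItemKey) -> int:
    """Four-category score of a concealed-emotion response pair: 0..3.

    ``key.correct`` holds the ordered (displayed_target, concealed_target)
    pair.  The full swap is the only placement exception (scores 2); a
    single target label anywhere scores 1.
    """
    if len(key.correct) != 2:
        raise ValidationError(f"item {key.item_id} is not a concealed item")
    cd = normalize_label(choice_displayed)
    cc = normalize_label(choice_concealed)
    for c in (cd, cc):
        if c not in key.options:
            raise ValidationError(
                f"item {key.item_id}: choice {c!r} is not one of the item's options"
            )
    displayed_target, concealed_target = key.correct
    if cd == displayed_target and cc == concealed_target:
        return 3
    if cd == concealed_target and cc == displayed_target:
        return 2
    if {cd, cc} & {displayed_target, concealed_target}:
        return 1
    return 0


def score_dichotomous(choice: str, key: ItemKey) -> int:
    """Right/wrong scoring (the 2-category degenerate rule).

    Used for conventionally scored comparison tests fit with a
    two-parameter logistic model; not used for graded items.
    """
    choice = normalize_label(choice)
    if choice not in key.options:
        raise ValidationError(
            f"item {key.item_id}: choice {choice!r} is not one of the item's options"
        )
    return 1 if choice == key.correct[0] else 0


def build_graded_matrix(table: ResponseTable, bank: ItemBank) -> GradedMatrix:
    """Score every judgement in the table against the bank's keys.

    Returns a participant x item :class:`GradedMatrix` with unadministered
    cells at the MISSING sentinel.  Items with fewer than 2 observed score
    categories are left in the matrix but reported by
    :meth:`GradedMatrix.degenerate_items` -- flagged, never silently
    dropped.
    """
    participants = table.participants()
    item_ids = sorted({r.stimulus_id for r in table.rows})
    for sid in item_ids:
        if sid not in bank.keys:
            raise ValidationError(f"no scoring key for stimulus {sid}")
    p_index = {p: i for i, p in enumerate(participants)}
    j_index = {s: j for j, s in enumerate(item_ids)}
    scores = np.full((len(participants), len(item_ids)), MISSING, dtype=int)
    for row in table.rows:
        key = bank.keys[row.stimulus_id]
        stim = bank.stimuli[row.stimulus_id]
        if stim.modality == "concealed":
            val = score_concealed(row.choice, row.choice_concealed, key)
        else:
            val = score_choice(row.choice, key)
        scores[p_index[row.participant_id], j_index[row.stimulus_id]] = val
    m_per_item = np.array(
        [M_BY_MODALITY[bank.stimuli[s].modality] for s in item_ids], dtype=int
    )
    # per-participant group labels (first row wins; they are constant per id)
    by_pid: dict[str, dict] = {}
    for row in table.rows:
        by_pid.setdefault(row.participant_id, dict(row.group_labels))
    groups = pd.DataFrame([by_pid[p] for p in participants])
    return GradedMatrix(
        participant_ids=participants,
        item_ids=item_ids,
        scores=scores,
        m_per_item=m_per_item,
        group_labels=groups,
    )


def category_frequencies(matrix: GradedMatrix) -> pd.DataFrame:
    """Observed count of each score category per item (MISSING excluded)."""
    m_max = int(matrix.m_per_item.max())
    rows = []
    for j, item in enumerate(matrix.item_ids):
        col = matrix.scores[:, j]
        col = col[col != MISSING]
        counts = {f"cat{c}": int(np.sum(col == c)) for c in range(m_max)}
        counts["item_id"] = item
        counts["m"] = int(matrix.m_per_item[j])
        rows.append(counts)
    return pd.DataFrame(rows).set_index("item_id")
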