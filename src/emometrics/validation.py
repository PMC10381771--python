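"""Stimulus validation analytics for forced-choice emotion judgements.

Covers the first, norming stage of test construction: per-stimulus hit
rates, chance-corrected accuracy via the proportion index, confusion
matrices pooled by intended emotion, intensity/believability rating
summaries, threshold-based stimulus selection, and confusion-driven
distractor keys for the items built from the retained stimuli.

The proportion index pi rescales a k-option hit rate P onto the scale of a
dichotomous judgement::

    pi = P (k - 1) / (1 + P (k - 2))

so that chance responding (P = 1/k) always maps to pi = 0.50 and hit rates
from tasks with different numbers of options become comparable.  No
response-bias correction is applied to hit rates; a plug-in point exists
but ships empty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ItemKey, ResponseTable
from .labels import LabelSet, normalize_label

logger = logging.getLogger(__name__)

#: Optional hook applied to raw hit rates before pi conversion.  The
#: pipeline applies no bias correction (ships as identity = None).
BIAS_CORRECTION: Callable[[float], float] | None = None


# ---------------------------------------------------------------------------
# Proportion index
# ---------------------------------------------------------------------------


def proportion_index(P, k: int):
    """Chance-corrected proportion index of a k-option hit rate.

    Accepts a scalar or array ``P`` in [0, 1]; ``k >= 2`` is the number of
    response options.  Monotone increasing in P; equal to P when k = 2;
    maps P = 1/k to exactly 0.5.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    arr = np.asarray(P, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("hit rate P outside [0, 1]")
    out = arr * (k - 1) / (1.0 + arr * (k - 2))
    return float(out) if np.isscalar(P) or arr.ndim == 0 else out


def concealed_joint_space(k1: int, k2: int) -> int:
    """Size of the joint response space of a two-judgement (concealed) trial.

    With k1 options for the displayed emotion and k2 for the hidden one
    there are k1 x k2 unique answer pairs; that product is the k used when
    pi-converting joint hit rates.
    """
    if k1 < 2 or k2 < 2:
        raise ValueError("both option counts must be >= 2")
    return k1 * k2


# ---------------------------------------------------------------------------
# Hit rates
# ---------------------------------------------------------------------------


def hit_rate(table: ResponseTable, stimulus_id: str) -> float:
    """Fraction of judgements of a stimulus that chose the intended emotion.

    For concealed stimuli a hit requires BOTH judgements correct: the
    perceiver must label the displayed and the concealed emotion.
    """
    rows = table.for_stimulus(stimulus_id)
    if not rows:
        raise ValueError(f"stimulus {stimulus_id!r} has no judgements")
    stim = table.stimulus_index[stimulus_id]
    if stim.modality == "concealed":
        hits = sum(
            1
            for r in rows
            if r.choice == stim.displayed_emotion
            and r.choice_concealed == stim.concealed_emotion
        )
    else:
        hits = sum(1 for r in rows if r.choice == stim.target_emotion)
    return hits / len(rows)


# ---------------------------------------------------------------------------
# Confusion matrices
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Distribution of chosen labels per intended emotion.

    Rows are intended target emotions (pooled over all stimuli of that
    emotion within a modality); columns are response labels.  ``raw`` is
    row-stochastic; ``pi`` is the elementwise proportion-index conversion
    with k = number of response options.
    """

    target_emotions: list[str]
    response_labels: list[str]
    raw: np.ndarray
    pi: np.ndarray
    n_per_row: np.ndarray
    k: int

    def __post_init__(self) -> None:
        sums = self.raw.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("confusion rows must sum to 1")
        if np.any(self.raw < 0) or np.any(self.raw > 1):
            raise ValueError("confusion entries outside [0, 1]")

    def row(self, target: str) -> pd.Series:
        i = self.target_emotions.index(normalize_label(target))
        return pd.Series(self.pi[i], index=self.response_labels, name=target)

    def raw_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.raw, index=self.target_emotions, columns=self.response_labels
        )

    def pi_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pi, index=self.target_emotions, columns=self.response_labels
        )


def confusion_matrix(
    table: ResponseTable, modality: str, judgement: str = "displayed"
) -> ConfusionMatrix:
    """Pooled confusion matrix for one modality.

    ``judgement`` selects which of the two concealed-trial judgements is
    tabulated ("displayed" or "concealed"); it is ignored for single-
    judgement modalities.  The diagonal of ``raw`` is the per-emotion hit
    rate; off-diagonal mass identifies plausible distractors.
    """
    labels = list(table.label_set)
    k = table.label_set.k
    col_of = {lab: j for j, lab in enumerate(labels)}
    counts: dict[str, np.ndarray] = {}
    for row in table.rows:
        stim = table.stimulus_index[row.stimulus_id]
        if stim.modality != modality:
            continue
        if stim.modality == "concealed":
            if judgement == "concealed":
                target, choice = stim.concealed_emotion, row.choice_concealed
            else:
                target, choice = stim.displayed_emotion, row.choice
        else:
            target, choice = stim.target_emotion, row.choice
        counts.setdefault(target, np.zeros(k))[col_of[choice]] += 1
    if not counts:
        raise ValueError(f"no judgements for modality {modality!r}")
    targets = sorted(counts)
    mat = np.vstack([counts[t] for t in targets])
    n_per_row = mat.sum(axis=1)
    raw = mat / n_per_row[:, None]
    return ConfusionMatrix(
        target_emotions=targets,
        response_labels=labels,
        raw=raw,
        pi=proportion_index(raw, k),
        n_per_row=n_per_row.astype(int),
        k=k,
    )


# ---------------------------------------------------------------------------
# Rating summaries
# ---------------------------------------------------------------------------


@dataclass
class RatingSummary:
    per_stimulus: pd.DataFrame  # index stimulus_id; mean/sd per rating kind
    per_modality: pd.DataFrame  # index modality
    unrated_stimuli: list[str]  # stimuli with no ratings at all
    degenerate_stimuli: list[str]  # single-rating stimuli (SD reported as 0)


def summarize_ratings(table: ResponseTable) -> RatingSummary:
    """Per-stimulus and per-modality means/SDs of the 1-5 rating scales.

    Stimuli without ratings are omitted from the tables and listed; a
    stimulus with a single rating reports SD = 0 and is flagged as a
    degenerate sample rather than crashing the pipeline.
    """
    recs = []
    for r in table.rows:
        recs.append(
            {
                "stimulus_id": r.stimulus_id,
                "modality": table.stimulus_index[r.stimulus_id].modality,
                "intensity": r.intensity_rating,
                "believability": r.believability_rating,
            }
        )
    df = pd.DataFrame(recs)
    rated = df.dropna(subset=["intensity", "believability"], how="all")
    unrated = sorted(set(df["stimulus_id"]) - set(rated["stimulus_id"]))

    def _agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        for kind in ("intensity", "believability"):
            vals = g[kind].dropna().astype(float)
            out[f"{kind}_mean"] = vals.mean() if len(vals) else np.nan
            out[f"{kind}_sd"] = (vals.std(ddof=1) if len(vals) > 1 else 0.0) if len(vals) else np.nan
            out[f"{kind}_n"] = len(vals)
        return pd.Series(out)

    per_stim = rated.groupby("stimulus_id").apply(_agg, include_groups=False)
    degenerate = sorted(
        per_stim.index[
            (per_stim["intensity_n"] == 1) | (per_stim["believability_n"] == 1)
        ]
    )
    per_mod = rated.groupby("modality").apply(_agg, include_groups=False)
    return RatingSummary(
        per_stimulus=per_stim,
        per_modality=per_mod,
        unrated_stimuli=unrated,
        degenerate_stimuli=degenerate,
    )


# ---------------------------------------------------------------------------
# Stimulus selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for carrying a stimulus forward into the item pool.

    ``min_pi`` is the above-chance cut (strict inequality, chance = 0.50);
    the intensity band targets moderate-intensity displays and
    ``min_believability`` at-least-moderate believability.  Believability
    is not applied to concealed stimuli, which look unnatural by design.
    """

    min_pi: float = 0.50
    intensity_band: tuple[float, float] = (2.0, 4.0)
    min_believability: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.min_pi < 1.0):
            raise ValueError("min_pi must be in (0, 1)")
        lo, hi = self.intensity_band
        if lo > hi:
            raise ValueError("intensity band inverted")


@dataclass(frozen=True)
class StimulusStats:
    """Per-stimulus inputs to selection."""

    stimulus_id: str
    modality: str
    pi: float
    mean_intensity: float | None
    mean_believability: float | None


@dataclass
class SelectionResult:
    accepted: list[str]
    rejected: list[str]
    reasons: dict[str, list[str]] = field(default_factory=dict)


def select_stimuli(
    stats: Iterable[StimulusStats], criteria: SelectionCriteria | None = None
) -> SelectionResult:
    """Apply the selection thresholds; every rejection carries its reasons.

    A stimulus is accepted iff pi > min_pi, mean intensity inside the band,
    and (non-concealed only) mean believability >= the floor.  Pure and
    order-independent: results are sorted by stimulus id.
    """
    criteria = criteria or SelectionCriteria()
    accepted: list[str] = []
    rejected: list[str] = []
    reasons: dict[str, list[str]] = {}
    lo, hi = criteria.intensity_band
    for s in sorted(stats, key=lambda s: s.stimulus_id):
        fails: list[str] = []
        if not (s.pi > criteria.min_pi):
            fails.append("below-chance recognition")
        if s.mean_intensity is None or not (lo <= s.mean_intensity <= hi):
            fails.append("intensity outside band")
        if s.modality != "concealed":
            if s.mean_believability is None or s.mean_believability < criteria.min_believability:
                fails.append("believability below floor")
        if fails:
            rejected.append(s.stimulus_id)
            reasons[s.stimulus_id] = fails
        else:
            accepted.append(s.stimulus_id)
    return SelectionResult(accepted=accepted, rejected=rejected, reasons=reasons)


# ---------------------------------------------------------------------------
# Distractor keys
# ---------------------------------------------------------------------------


def select_distractors(
    confusion_row: Mapping[str, float] | pd.Series,
    target: str | Sequence[str],
    n_options: int = 6,
    n_partial: int = 1,
    item_id: str | None = None,
) -> ItemKey:
    """Build an item key from a pi-converted confusion row.

    Off-target labels are ranked by descending confusion pi (ties broken
    by ascending alphabetical label); the top ``n_partial`` become
    partial-credit distractors, the next ``n_options - n_correct -
    n_partial`` become incorrect distractors.  Deterministic given the row.
    If too few labels have nonzero confusion, the remaining slots fall back
    to the lowest-confusion labels (which the ranking already yields) and
    the fallback is logged.
    """
    row = pd.Series(dict(confusion_row), dtype=float)
    targets = (
        tuple(normalize_label(t) for t in ((target,) if isinstance(target, str) else target))
    )
    candidates = row.drop(labels=[t for t in targets if t in row.index])
    n_correct = len(set(targets))
    n_distractors = n_options - n_correct
    if n_distractors < n_partial:
        raise ValueError("n_options too small for the requested partial count")
    if len(candidates) < n_distractors:
        raise ValueError(
            f"confusion row offers {len(candidates)} candidate labels, "
            f"{n_distractors} needed"
        )
    ranked = sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0]))
    n_nonzero = int((candidates > 0).sum())
    if n_nonzero < n_distractors:
        logger.info(
            "distractor fallback for %s: only %d nonzero-confusion labels, "
            "padding with lowest-confusion labels",
            item_id or targets[0],
            n_nonzero,
        )
    chosen = [lab for lab, _ in ranked[:n_distractors]]
    partial = frozenset(chosen[:n_partial])
    incorrect = frozenset(chosen[n_partial:])
    # Concealed keys score by label placement, not partial credit sets.
    if n_correct == 2:
        partial, incorrect = frozenset(), frozenset(chosen)
    return ItemKey(
        item_id=item_id or f"item_{'_'.join(targets)}",
        correct=targets,
        partial=partial,
        incorrect=incorrect,
        n_options=n_options,
    )


def stimulus_pi(
    table: ResponseTable,
    stimulus_id: str,
    concealed_k_mode: str = "joint",
    n_options: int | None = None,
) -> float:
    """Pi-converted hit rate of one stimulus.

    ``n_options`` is the size of the menu actually offered per judgement;
    it defaults to the full label set (norming-style judgements).  Pass the
    item key's option count for keyed forced-choice data.  For concealed
    stimuli the default conversion uses the joint response space
    k = k1 x k2 (both judgements over the menu), which is what makes low
    joint hit rates comparable to single-judgement ones; a per-judgement
    mode (k = menu size) is available via ``concealed_k_mode="single"``.
    """
    P = hit_rate(table, stimulus_id)
    stim = table.stimulus_index[stimulus_id]
    k = n_options if n_options is not None else table.label_set.k
    if stim.modality == "concealed" and concealed_k_mode == "joint":
        k = concealed_joint_space(k, k)
    if BIAS_CORRECTION is not None:  # pragma: no cover - ships empty
        P = BIAS_CORRECTION(P)
    return proportion_index(P, k)


def _pi_mean(values: Iterable[float]) -> float:
    vals = list(values)
    return float(np.mean(vals)) if vals else math.nan
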