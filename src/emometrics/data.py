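"""Domain types and file formats for emotion-judgement data.

The raw input of the pipeline is a long-format response table: one row per
judgement, each row naming the perceiver, their demographic group labels,
the stimulus judged, the emotion label chosen (two labels for concealed
stimuli, where the perceiver judges both the displayed and the hidden
emotion), and optional 1-5 intensity / believability ratings.

Alongside it sits an item bank: per stimulus, its modality, target
emotion(s), actor metadata, and -- once distractor keys have been built --
the scoring key (correct label, partial-credit labels, incorrect labels).

File formats are deliberately plain: responses as UTF-8 CSV with a fixed
header, item banks and fitted models as JSON.  Every writer stamps a
``format_version`` field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .labels import LabelSet, default_label_set, normalize_label

FORMAT_VERSION = "1"

#: Out-of-band code for "not administered" in a graded score matrix.
#: Never 0 -- zero is a real (fully incorrect) score.
MISSING: int = -1

RESPONSE_COLUMNS = (
    "participant_id",
    "race",
    "gender",
    "stimulus_id",
    "choice",
    "choice_concealed",
    "intensity",
    "believability",
)

MODALITIES = ("nonverbal", "verbal", "concealed")


class SchemaError(ValueError):
    """A file does not have the required columns/fields."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusRecord:
    """One stimulus in the bank.

    Non-concealed stimuli carry a single ``target_emotion``; concealed
    stimuli carry a (``displayed_emotion``, ``concealed_emotion``) pair with
    displayed != concealed (e.g., felt anger but displayed contentment).
    """

    stimulus_id: str
    modality: str
    target_emotion: str | None = None
    displayed_emotion: str | None = None
    concealed_emotion: str | None = None
    actor_race: str | None = None
    actor_gender: str | None = None
    mean_intensity: float | None = None
    mean_believability: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"stimulus {self.stimulus_id}: unknown modality {self.modality!r}"
            )
        if self.modality == "concealed":
            if self.displayed_emotion is None or self.concealed_emotion is None:
                raise ValidationError(
                    f"concealed stimulus {self.stimulus_id} needs both a displayed "
                    "and a concealed target emotion"
                )
            if self.displayed_emotion == self.concealed_emotion:
                raise ValidationError(
                    f"concealed stimulus {self.stimulus_id}: displayed and "
                    "concealed targets must differ"
                )
            if self.target_emotion is not None:
                raise ValidationError(
                    f"concealed stimulus {self.stimulus_id} must not carry a "
                    "single target_emotion"
                )
        else:
            if self.target_emotion is None:
                raise ValidationError(
                    f"stimulus {self.stimulus_id} needs a target emotion"
                )
            if self.displayed_emotion is not None or self.concealed_emotion is not None:
                raise ValidationError(
                    f"non-concealed stimulus {self.stimulus_id} must not carry "
                    "displayed/concealed targets"
                )
        for attr in ("mean_intensity", "mean_believability"):
            v = getattr(self, attr)
            if v is not None and not (1.0 <= float(v) <= 5.0):
                raise ValidationError(
                    f"stimulus {self.stimulus_id}: {attr} {v} outside [1, 5]"
                )

    @property
    def targets(self) -> tuple[str, ...]:
        if self.modality == "concealed":
            return (self.displayed_emotion, self.concealed_emotion)  # type: ignore[return-value]
        return (self.target_emotion,)  # type: ignore[return-value]


@dataclass(frozen=True)
class RawResponse:
    """One judgement: perceiver x stimulus."""

    participant_id: str
    group_labels: Mapping[str, str]
    stimulus_id: str
    choice: str
    choice_concealed: str | None = None
    intensity_rating: int | None = None
    believability_rating: int | None = None

    def __post_init__(self) -> None:
        for attr in ("intensity_rating", "believability_rating"):
            v = getattr(self, attr)
            if v is not None and not (1 <= int(v) <= 5):
                raise ValidationError(
                    f"response ({self.participant_id}, {self.stimulus_id}): "
                    f"{attr} {v} outside 1-5"
                )


@dataclass(frozen=True)
class ItemKey:
    """Scoring key for one item.

    ``correct`` holds one label (nonverbal/verbal) or the ordered
    (displayed, concealed) target pair for concealed items.  ``partial``
    labels earn partial credit; ``incorrect`` labels earn none.  The full
    option menu has ``n_options`` labels.
    """

    item_id: str
    correct: tuple[str, ...]
    partial: frozenset[str]
    incorrect: frozenset[str]
    n_options: int

    def __post_init__(self) -> None:
        correct = tuple(normalize_label(c) for c in self.correct)
        partial = frozenset(normalize_label(x) for x in self.partial)
        incorrect = frozenset(normalize_label(x) for x in self.incorrect)
        object.__setattr__(self, "correct", correct)
        object.__setattr__(self, "partial", partial)
        object.__setattr__(self, "incorrect", incorrect)
        if len(correct) not in (1, 2):
            raise ValidationError(f"item {self.item_id}: correct must hold 1 or 2 labels")
        cset = set(correct)
        if cset & (partial | incorrect):
            raise ValidationError(
                f"item {self.item_id}: correct label(s) also listed as distractors"
            )
        if partial & incorrect:
            raise ValidationError(
                f"item {self.item_id}: partial and incorrect sets overlap"
            )
        if not partial and len(correct) == 1:
            raise ValidationError(f"item {self.item_id}: partial set is empty")
        n = len(cset | partial | incorrect)
        if n != self.n_options:
            raise ValidationError(
                f"item {self.item_id}: option set has {n} labels, "
                f"n_options says {self.n_options}"
            )

    @property
    def options(self) -> frozenset[str]:
        return frozenset(self.correct) | self.partial | self.incorrect


@dataclass
class ItemBank:
    """item_id -> (StimulusRecord, ItemKey or None until keys are built)."""

    stimuli: dict[str, StimulusRecord]
    keys: dict[str, ItemKey] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item_id in self.keys:
            if item_id not in self.stimuli:
                raise ValidationError(f"key for unknown stimulus {item_id}")

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.stimuli

    def __len__(self) -> int:
        return len(self.stimuli)

    def item_ids(self) -> list[str]:
        return sorted(self.stimuli)

    def by_modality(self, modality: str) -> list[str]:
        return [s for s in self.item_ids() if self.stimuli[s].modality == modality]


# ---------------------------------------------------------------------------
# Response table
# ---------------------------------------------------------------------------


@dataclass
class ResponseTable:
    """Long-format judgement table with its label set and stimulus index."""

    rows: list[RawResponse]
    label_set: LabelSet
    stimulus_index: dict[str, StimulusRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for i, row in enumerate(self.rows):
            if row.stimulus_id not in self.stimulus_index:
                raise ValidationError(
                    f"row {i}: stimulus {row.stimulus_id!r} not in the stimulus index"
                )
            stim = self.stimulus_index[row.stimulus_id]
            if row.choice not in self.label_set:
                raise ValidationError(f"row {i}: unknown emotion label {row.choice!r}")
            if stim.modality == "concealed":
                if row.choice_concealed is None:
                    raise ValidationError(
                        f"row {i}: concealed stimulus {row.stimulus_id} requires a "
                        "second (concealed-emotion) judgement"
                    )
                if row.choice_concealed not in self.label_set:
                    raise ValidationError(
                        f"row {i}: unknown emotion label {row.choice_concealed!r}"
                    )
            elif row.choice_concealed is not None:
                raise ValidationError(
                    f"row {i}: non-concealed stimulus {row.stimulus_id} must not "
                    "carry a concealed-emotion judgement"
                )
            pair = (row.participant_id, row.stimulus_id)
            if pair in seen:
                raise ValidationError(
                    f"row {i}: duplicate (participant, stimulus) pair {pair}"
                )
            seen.add(pair)

    def __len__(self) -> int:
        return len(self.rows)

    def participants(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for row in self.rows:
            if row.participant_id not in seen:
                seen.add(row.participant_id)
                out.append(row.participant_id)
        return out

    def group_factors(self) -> list[str]:
        return sorted({k for row in self.rows for k in row.group_labels})

    def for_stimulus(self, stimulus_id: str) -> list[RawResponse]:
        return [r for r in self.rows if r.stimulus_id == stimulus_id]

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with the canonical column layout."""
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "participant_id": r.participant_id,
                    "race": r.group_labels.get("race", ""),
                    "gender": r.group_labels.get("gender", ""),
                    "stimulus_id": r.stimulus_id,
                    "choice": r.choice,
                    "choice_concealed": r.choice_concealed or "",
                    "intensity": r.intensity_rating,
                    "believability": r.believability_rating,
                }
            )
        return pd.DataFrame(recs, columns=list(RESPONSE_COLUMNS))


# ---------------------------------------------------------------------------
# Graded score matrix
# ---------------------------------------------------------------------------


@dataclass
class GradedMatrix:
    """Participant x item matrix of ordered partial-credit scores.

    Scores live in {0..m-1} per item (m = 3 for nonverbal/verbal, 4 for
    concealed); cells not administered hold :data:`MISSING`.  Group labels
    travel with the participants so per-group calibration can split rows.
    """

    participant_ids: list[str]
    item_ids: list[str]
    scores: np.ndarray  # int array (n_participants, n_items), MISSING for gaps
    m_per_item: np.ndarray  # int array (n_items,)
    group_labels: pd.DataFrame | None = None  # index aligned with participant_ids

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        self.m_per_item = np.asarray(self.m_per_item, dtype=int)
        n, j = self.scores.shape
        if n != len(self.participant_ids) or j != len(self.item_ids):
            raise ValidationError("score matrix shape does not match id lists")
        if len(self.m_per_item) != j:
            raise ValidationError("m_per_item length does not match items")
        observed = self.scores != MISSING
        if np.any(self.scores[observed] < 0):
            raise ValidationError("negative score that is not the MISSING sentinel")
        if np.any(self.scores > (self.m_per_item[None, :] - 1)):
            raise ValidationError("score exceeds m-1 for its item")
        if self.group_labels is not None and len(self.group_labels) != n:
            raise ValidationError("group_labels length does not match participants")

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def observed_mask(self) -> np.ndarray:
        return self.scores != MISSING

    def observed_categories(self, j: int) -> np.ndarray:
        col = self.scores[:, j]
        return np.unique(col[col != MISSING])

    def degenerate_items(self) -> list[str]:
        """Items with fewer than 2 observed categories (unusable for IRT)."""
        return [
            self.item_ids[j]
            for j in range(self.n_items)
            if len(self.observed_categories(j)) < 2
        ]

    def subset_items(self, item_ids: Iterable[str]) -> "GradedMatrix":
        keep = [self.item_ids.index(i) for i in item_ids]
        return GradedMatrix(
            participant_ids=list(self.participant_ids),
            item_ids=[self.item_ids[j] for j in keep],
            scores=self.scores[:, keep].copy(),
            m_per_item=self.m_per_item[keep].copy(),
            group_labels=None if self.group_labels is None else self.group_labels.copy(),
        )

    def subset_participants(self, mask: np.ndarray) -> "GradedMatrix":
        mask = np.asarray(mask, dtype=bool)
        gl = None
        if self.group_labels is not None:
            gl = self.group_labels.loc[mask].reset_index(drop=True)
        return GradedMatrix(
            participant_ids=[p for p, m in zip(self.participant_ids, mask) if m],
            item_ids=list(self.item_ids),
            scores=self.scores[mask].copy(),
            m_per_item=self.m_per_item.copy(),
            group_labels=gl,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores.astype(float), index=self.participant_ids, columns=self.item_ids
        )
        return df.where(self.scores != MISSING)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_responses(
    path: str | Path,
    label_set: LabelSet | None = None,
    stimulus_index: Mapping[str, StimulusRecord] | None = None,
) -> ResponseTable:
    """Read a long-format response CSV into a validated :class:`ResponseTable`.

    When no ``stimulus_index`` is supplied, a minimal index is inferred from
    the file itself: a stimulus is treated as concealed exactly when its rows
    carry a second judgement (its target labels are then unknown and marked
    with placeholder modality metadata only).  Supplying the real bank gives
    full validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label_set = label_set or default_label_set()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"response file missing required column(s): {missing_cols}")

    rows: list[RawResponse] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        choice = normalize_label(rec.choice)
        if choice not in label_set:
            raise ValidationError(f"row {i + 1}: unknown emotion label {rec.choice!r}")
        cc = normalize_label(rec.choice_concealed) if rec.choice_concealed else None
        if cc is not None and cc not in label_set:
            raise ValidationError(
                f"row {i + 1}: unknown emotion label {rec.choice_concealed!r}"
            )
        rows.append(
            RawResponse(
                participant_id=str(rec.participant_id),
                group_labels={"race": rec.race, "gender": rec.gender},
                stimulus_id=str(rec.stimulus_id),
                choice=choice,
                choice_concealed=cc,
                intensity_rating=int(rec.intensity) if rec.intensity else None,
                believability_rating=int(rec.believability) if rec.believability else None,
            )
        )

    if stimulus_index is None:
        stimulus_index = _infer_stimulus_index(rows)
    return ResponseTable(rows=rows, label_set=label_set, stimulus_index=dict(stimulus_index))


def _infer_stimulus_index(rows: list[RawResponse]) -> dict[str, StimulusRecord]:
    concealedness: dict[str, bool] = {}
    for row in rows:
        has_cc = row.choice_concealed is not None
        prev = concealedness.setdefault(row.stimulus_id, has_cc)
        if prev != has_cc:
            raise ValidationError(
                f"stimulus {row.stimulus_id}: inconsistent presence of the "
                "concealed-emotion judgement across rows"
            )
    index: dict[str, StimulusRecord] = {}
    for sid, is_concealed in concealedness.items():
        if is_concealed:
            index[sid] = StimulusRecord(
                stimulus_id=sid,
                modality="concealed",
                displayed_emotion="__unknown_displayed__",
                concealed_emotion="__unknown_concealed__",
            )
        else:
            index[sid] = StimulusRecord(
                stimulus_id=sid, modality="nonverbal", target_emotion="__unknown__"
            )
    return index


def write_responses(table: ResponseTable, path: str | Path) -> None:
    df = table.to_frame()
    df["intensity"] = df["intensity"].astype("Int64")
    df["believability"] = df["believability"].astype("Int64")
    df.to_csv(path, index=False)


def _stimulus_to_json(s: StimulusRecord) -> dict:
    return {
        "stimulus_id": s.stimulus_id,
        "modality": s.modality,
        "target_emotion": s.target_emotion,
        "displayed_emotion": s.displayed_emotion,
        "concealed_emotion": s.concealed_emotion,
        "actor_race": s.actor_race,
        "actor_gender": s.actor_gender,
        "mean_intensity": s.mean_intensity,
        "mean_believability": s.mean_believability,
    }


def _key_to_json(k: ItemKey) -> dict:
    return {
        "item_id": k.item_id,
        "correct": list(k.correct),
        "partial": sorted(k.partial),
        "incorrect": sorted(k.incorrect),
        "n_options": k.n_options,
    }


def write_item_bank(bank: ItemBank, path: str | Path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "stimuli": [_stimulus_to_json(s) for _, s in sorted(bank.stimuli.items())],
        "keys": [_key_to_json(bank.keys[i]) for i in sorted(bank.keys)],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_item_bank(path: str | Path) -> ItemBank:
    """Load an item-bank JSON, enforcing all key invariants."""
    raw = json.loads(Path(path).read_text())
    if "stimuli" not in raw:
        raise SchemaError("item bank JSON missing 'stimuli' field")
    stimuli: dict[str, StimulusRecord] = {}
    for rec in raw["stimuli"]:
        s = StimulusRecord(
            stimulus_id=rec["stimulus_id"],
            modality=rec["modality"],
            target_emotion=rec.get("target_emotion"),
            displayed_emotion=rec.get("displayed_emotion"),
            concealed_emotion=rec.get("concealed_emotion"),
            actor_race=rec.get("actor_race"),
            actor_gender=rec.get("actor_gender"),
            mean_intensity=rec.get("mean_intensity"),
            mean_believability=rec.get("mean_believability"),
        )
        stimuli[s.stimulus_id] = s
    keys: dict[str, ItemKey] = {}
    for rec in raw.get("keys", []):
        k = ItemKey(
            item_id=rec["item_id"],
            correct=tuple(rec["correct"]),
            partial=frozenset(rec["partial"]),
            incorrect=frozenset(rec["incorrect"]),
            n_options=int(rec["n_options"]),
        )
        keys[k.item_id] = k
    return ItemBank(stimuli=stimuli, keys=keys)
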