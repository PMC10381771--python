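"""Emotion label sets for forced-choice judgement tasks.

A :class:`LabelSet` is the closed menu of emotion words a perceiver can
choose from.  The default menu holds seventeen emotion categories plus an
explicit "neutral" option; including neutral avoids forcing perceivers to
pick an emotion when they believe none is expressed, and it counts as a
response option when computing chance-corrected accuracy (k = 18).
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_EMOTIONS: tuple[str, ...] = (
    "amusement",
    "anger",
    "anxiety",
    "awe",
    "boredom",
    "contempt",
    "content",
    "disgust",
    "embarrassment",
    "fear",
    "joy",
    "pride",
    "relief",
    "sadness",
    "shame",
    "surprise",
    "sympathy",
)

NEUTRAL = "neutral"


def normalize_label(label: str) -> str:
    """Case-fold and trim a label; no fuzzy matching."""
    return label.strip().casefold()


@dataclass(frozen=True)
class LabelSet:
    """An ordered, unique, case-normalized set of emotion labels.

    Parameters
    ----------
    labels
        The response options, in canonical order.
    includes_neutral
        Whether "neutral" is one of the options (flagged explicitly so
        chance-level computations can document k).
    """

    labels: tuple[str, ...]
    includes_neutral: bool = field(default=False)

    def __post_init__(self) -> None:
        norm = tuple(normalize_label(x) for x in self.labels)
        if len(norm) == 0:
            raise ValueError("label set must be non-empty")
        if len(set(norm)) != len(norm):
            raise ValueError("label set contains duplicates after normalization")
        object.__setattr__(self, "labels", norm)
        object.__setattr__(self, "includes_neutral", NEUTRAL in norm)

    def __contains__(self, label: str) -> bool:
        return normalize_label(label) in self.labels

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def k(self) -> int:
        """Number of response options (the k of the proportion index)."""
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(normalize_label(label))

    def require(self, label: str) -> str:
        """Return the normalized label, raising if it is not in the set."""
        norm = normalize_label(label)
        if norm not in self.labels:
            raise ValueError(f"unknown emotion label: {label!r}")
        return norm


def default_label_set() -> LabelSet:
    """The 17-emotion menu plus neutral (k = 18)."""
    return LabelSet(DEFAULT_EMOTIONS + (NEUTRAL,))
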