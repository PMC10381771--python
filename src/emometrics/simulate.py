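"""Synthetic respondents, stimuli, and judgements with known ground truth.

The generator emulates the structure of a large emotion-perception norming
study: a demographically crossed respondent pool (4 self-identified race
groups x 2 genders), sparse random stimulus assignment (each perceiver
rates a subset of each modality), latent-trait-driven forced choices with
plausible-distractor confusions, ordered graded responses under the GRM,
and 1-5 intensity/believability rating scales.

Every draw is a pure function of (spec, seed).  Graded categories are
drawn from the engine's own :func:`~emometrics.grm.category_probs`, so the
simulator and the estimator share one probability implementation; raw
choices are then mapped onto labels such that re-scoring the choices
reproduces the drawn categories exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import (
    MISSING,
    GradedMatrix,
    ItemBank,
    ItemKey,
    RawResponse,
    ResponseTable,
    StimulusRecord,
)
from .grm import GRMItemParams, category_probs
from .labels import DEFAULT_EMOTIONS, LabelSet, default_label_set

#: Default seed baked into example configs; all entry points accept a seed.
DEFAULT_SEED = 20230719

#: The four concealment patterns used for concealed displays: the felt
#: emotion is masked with one of opposing valence.
CONCEALED_PAIRS = (
    ("content", "anger"),  # displayed content, felt (concealed) anger
    ("anger", "content"),
    ("joy", "sadness"),
    ("sadness", "joy"),
)

RACES = ("asian", "black", "hispanic", "white")
GENDERS = ("men", "women")

VALENCE_ACTIVATION = {
    "amusement": "positive_high", "joy": "positive_high", "pride": "positive_high",
    "surprise": "positive_high", "awe": "positive_high",
    "content": "positive_low", "relief": "positive_low", "sympathy": "positive_low",
    "anger": "negative_high", "anxiety": "negative_high", "disgust": "negative_high",
    "fear": "negative_high", "contempt": "negative_high", "embarrassment": "negative_high",
    "boredom": "negative_low", "sadness": "negative_low", "shame": "negative_low",
    "neutral": "neutral",
}


@dataclass
class ItemSpec:
    """How many items of a modality to generate and from which ranges."""

    modality: str
    n_items: int
    m: int
    a_range: tuple[float, float] = (0.8, 2.5)
    b_range: tuple[float, float] = (-2.0, 2.0)
    min_gap: float = 0.3


@dataclass
class SimulationSpec:
    """Full description of a synthetic norming study.

    Defaults mirror the structure of the real design at its study scale:
    400 respondents per race x gender cell; 31 nonverbal (m=3), 20 verbal
    (m=3) and 13 concealed (m=4) items; each respondent is administered
    16/12/4 items of the three modalities.  Latent ability is standard
    normal within every demographic cell unless offsets are supplied.
    """

    n_per_cell: int = 400
    races: tuple[str, ...] = RACES
    genders: tuple[str, ...] = GENDERS
    theta_offsets: dict = field(default_factory=dict)  # level -> additive mean shift
    theta_sd: float = 1.0
    items: list[ItemSpec] = field(
        default_factory=lambda: [
            ItemSpec("nonverbal", 31, 3),
            ItemSpec("verbal", 20, 3),
            ItemSpec("concealed", 13, 4),
        ]
    )
    items_per_participant: dict = field(
        default_factory=lambda: {"nonverbal": 16, "verbal": 12, "concealed": 4}
    )
    n_options: int = 6
    rating_sd: float = 0.9
    seed: int = DEFAULT_SEED

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Item parameters and bank
# ---------------------------------------------------------------------------


def simulate_item_params(
    n_items: int,
    m: int,
    a_range: tuple[float, float] = (0.8, 2.5),
    b_range: tuple[float, float] = (-2.0, 2.0),
    min_gap: float = 0.3,
    seed: int | np.random.Generator = DEFAULT_SEED,
    prefix: str = "item",
) -> list[GRMItemParams]:
    """Draw GRM item parameters: a ~ U(a_range), ordered thresholds.

    Thresholds are drawn uniformly in ``b_range``, sorted, and pushed
    apart to a minimum gap so category curves stay distinguishable.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    items = []
    for i in range(n_items):
        a = float(rng.uniform(*a_range))
        b = np.sort(rng.uniform(*b_range, size=m - 1))
        for j in range(1, len(b)):
            if b[j] - b[j - 1] < min_gap:
                b[j] = b[j - 1] + min_gap
        items.append(GRMItemParams(item_id=f"{prefix}{i + 1:03d}", a=a, b=b, m=m))
    return items


def build_synthetic_bank(
    spec: SimulationSpec, rng: np.random.Generator, label_set: LabelSet | None = None
) -> tuple[ItemBank, dict[str, GRMItemParams]]:
    """A stimulus bank with keys plus the generating item parameters.

    Target emotions cycle through the label menu; actor race/gender cycle
    through the demographic levels so balanced selection has material to
    work with.  Distractors are drawn at random from the off-target labels
    (one partial + the rest incorrect for graded single-judgement items).
    """
    label_set = label_set or default_label_set()
    emotions = [e for e in label_set if e != "neutral"]
    prefix = {"nonverbal": "NV", "verbal": "V", "concealed": "C"}
    stimuli: dict[str, StimulusRecord] = {}
    keys: dict[str, ItemKey] = {}
    truth: dict[str, GRMItemParams] = {}
    for ispec in spec.items:
        params = simulate_item_params(
            ispec.n_items, ispec.m, ispec.a_range, ispec.b_range, ispec.min_gap,
            seed=rng, prefix=prefix[ispec.modality],
        )
        for i, p in enumerate(params):
            sid = p.item_id
            race = spec.races[i % len(spec.races)]
            gender = spec.genders[(i // len(spec.races)) % len(spec.genders)]
            if ispec.modality == "concealed":
                displayed, concealed = CONCEALED_PAIRS[i % len(CONCEALED_PAIRS)]
                others = [e for e in emotions if e not in (displayed, concealed)]
                pick = rng.choice(len(others), size=spec.n_options - 2, replace=False)
                stimuli[sid] = StimulusRecord(
                    stimulus_id=sid, modality="concealed",
                    displayed_emotion=displayed, concealed_emotion=concealed,
                    actor_race=race, actor_gender=gender,
                )
                keys[sid] = ItemKey(
                    item_id=sid, correct=(displayed, concealed),
                    partial=frozenset(),
                    incorrect=frozenset(others[j] for j in pick),
                    n_options=spec.n_options,
                )
            else:
                target = emotions[i % len(emotions)]
                others = [e for e in emotions if e != target]
                pick = rng.choice(len(others), size=spec.n_options - 1, replace=False)
                chosen = [others[j] for j in pick]
                stimuli[sid] = StimulusRecord(
                    stimulus_id=sid, modality=ispec.modality, target_emotion=target,
                    actor_race=race, actor_gender=gender,
                )
                keys[sid] = ItemKey(
                    item_id=sid, correct=(target,),
                    partial=frozenset(chosen[:1]),
                    incorrect=frozenset(chosen[1:]),
                    n_options=spec.n_options,
                )
            truth[sid] = p
    return ItemBank(stimuli=stimuli, keys=keys), truth


# ---------------------------------------------------------------------------
# Participants and assignment
# ---------------------------------------------------------------------------


def simulate_participants(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[list[str], pd.DataFrame, np.ndarray]:
    """Participant ids, group labels, and latent abilities."""
    ids, groups, theta = [], [], []
    i = 0
    for race in spec.races:
        for gender in spec.genders:
            shift = spec.theta_offsets.get(race, 0.0) + spec.theta_offsets.get(gender, 0.0)
            for _ in range(spec.n_per_cell):
                ids.append(f"p{i + 1:05d}")
                groups.append({"race": race, "gender": gender})
                theta.append(rng.normal(shift, spec.theta_sd))
                i += 1
    return ids, pd.DataFrame(groups), np.asarray(theta)


def sparse_assignment(
    n_participants: int, bank: ItemBank, per_modality: dict, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (participant x item) administration matrix.

    Each participant receives a without-replacement random subset of each
    modality, emulating sparse random stimulus assignment.
    """
    item_ids = bank.item_ids()
    j_index = {s: j for j, s in enumerate(item_ids)}
    A = np.zeros((n_participants, len(item_ids)), dtype=bool)
    by_mod = {mod: bank.by_modality(mod) for mod in per_modality}
    for i in range(n_participants):
        for mod, n_take in per_modality.items():
            pool = by_mod[mod]
            take = min(n_take, len(pool))
            for j in rng.choice(len(pool), size=take, replace=False):
                A[i, j_index[pool[j]]] = True
    return A


# ---------------------------------------------------------------------------
# Graded responses and raw choices
# ---------------------------------------------------------------------------


def simulate_graded_responses(
    theta: np.ndarray,
    items: list[GRMItemParams],
    assignment: np.ndarray,
    seed: int | np.random.Generator,
    group_labels: pd.DataFrame | None = None,
) -> GradedMatrix:
    """Draw graded scores cell-by-cell from the GRM category probabilities."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    theta = np.asarray(theta, dtype=float)
    n, J = len(theta), len(items)
    if assignment.shape != (n, J):
        raise ValueError("assignment shape mismatch")
    scores = np.full((n, J), MISSING, dtype=int)
    u = rng.random((n, J))
    for j, params in enumerate(items):
        probs = category_probs(theta, params)  # (n, m)
        cum = np.cumsum(probs, axis=1)
        draw = (u[:, [j]] > cum[:, :-1]).sum(axis=1)
        scores[assignment[:, j], j] = draw[assignment[:, j]]
    return GradedMatrix(
        participant_ids=[f"p{i + 1:05d}" for i in range(n)],
        item_ids=[it.item_id for it in items],
        scores=scores,
        m_per_item=np.array([it.m for it in items]),
        group_labels=group_labels,
    )


def _graded_to_choice(
    cat: int, key: ItemKey, modality: str, rng: np.random.Generator,
    label_pool: list[str],
) -> tuple[str, str | None]:
    """Map a drawn graded category onto label choice(s); inverse of scoring."""
    if modality == "concealed":
        displayed_t, concealed_t = key.correct
        wrong = sorted(key.incorrect)
        if cat == 3:
            return displayed_t, concealed_t
        if cat == 2:
            return concealed_t, displayed_t
        if cat == 1:
            slot = rng.integers(2)
            filler = wrong[rng.integers(len(wrong))]
            return (displayed_t, filler) if slot == 0 else (filler, concealed_t)
        w1 = wrong[rng.integers(len(wrong))]
        w2 = wrong[rng.integers(len(wrong))]
        return w1, w2
    if cat == 2:
        return key.correct[0], None
    if cat == 1:
        partial = sorted(key.partial)
        return partial[rng.integers(len(partial))], None
    wrong = sorted(key.incorrect)
    return wrong[rng.integers(len(wrong))], None


def simulate_raw_choices(
    theta: np.ndarray,
    bank: ItemBank,
    truth: dict[str, GRMItemParams],
    assignment: np.ndarray,
    seed: int | np.random.Generator,
    group_labels: pd.DataFrame | None = None,
    label_set: LabelSet | None = None,
    choice_model: str = "graded",
    rating_means: dict | None = None,
    rating_sd: float = 0.9,
) -> tuple[ResponseTable, GradedMatrix]:
    """Generate a raw forced-choice response table plus its true score matrix.

    ``choice_model="graded"`` draws a graded category per administered cell
    and maps it to labels (top category -> correct label, middle ->
    uniform partial distractor, bottom -> uniform incorrect distractor;
    concealed categories map to both-correct / swapped / one-correct /
    neither pairs).  Scoring the table against the bank reproduces the
    drawn categories exactly.  ``choice_model="uniform"`` ignores theta and
    draws labels uniformly from each item's option menu (a chance-level
    population).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    label_set = label_set or default_label_set()
    item_ids = bank.item_ids()
    items = [truth[s] for s in item_ids]
    n = len(theta)
    if choice_model == "graded":
        graded = simulate_graded_responses(theta, items, assignment, rng, group_labels)
    elif choice_model == "uniform":
        graded = None
    else:
        raise ValueError(f"unknown choice model {choice_model!r}")

    pool = list(label_set)
    rows: list[RawResponse] = []
    true_scores = np.full((n, len(item_ids)), MISSING, dtype=int)
    for i in range(n):
        gl = (
            dict(group_labels.iloc[i]) if group_labels is not None else {}
        )
        for j, sid in enumerate(item_ids):
            if not assignment[i, j]:
                continue
            key = bank.keys[sid]
            stim = bank.stimuli[sid]
            if choice_model == "uniform":
                options = sorted(key.options)
                choice = options[rng.integers(len(options))]
                cc = options[rng.integers(len(options))] if stim.modality == "concealed" else None
            else:
                cat = int(graded.scores[i, j])
                choice, cc = _graded_to_choice(cat, key, stim.modality, rng, pool)
                true_scores[i, j] = cat
            intensity = believability = None
            if rating_means is not None and sid in rating_means:
                mu_i, mu_b = rating_means[sid]
                intensity = int(np.clip(round(rng.normal(mu_i, rating_sd)), 1, 5))
                believability = int(np.clip(round(rng.normal(mu_b, rating_sd)), 1, 5))
            rows.append(
                RawResponse(
                    participant_id=f"p{i + 1:05d}",
                    group_labels=gl,
                    stimulus_id=sid,
                    choice=choice,
                    choice_concealed=cc,
                    intensity_rating=intensity,
                    believability_rating=believability,
                )
            )
    table = ResponseTable(rows=rows, label_set=label_set, stimulus_index=dict(bank.stimuli))
    truth_matrix = GradedMatrix(
        participant_ids=[f"p{i + 1:05d}" for i in range(n)],
        item_ids=item_ids,
        scores=true_scores,
        m_per_item=np.array([truth[s].m for s in item_ids]),
        group_labels=group_labels,
    )
    return table, truth_matrix


def simulate_ratings(
    stimulus_means: dict[str, tuple[float, float]],
    n_raters: int,
    seed: int | np.random.Generator,
    sd: float = 0.9,
) -> pd.DataFrame:
    """Discretized 1-5 rating draws around per-stimulus latent means."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    recs = []
    for sid, (mu_i, mu_b) in stimulus_means.items():
        if not (1.0 <= mu_i <= 5.0 and 1.0 <= mu_b <= 5.0):
            raise ValueError(f"latent rating means for {sid} outside [1, 5]")
        ints = np.clip(np.round(rng.normal(mu_i, sd, size=n_raters)), 1, 5).astype(int)
        bels = np.clip(np.round(rng.normal(mu_b, sd, size=n_raters)), 1, 5).astype(int)
        for i, b in zip(ints, bels):
            recs.append({"stimulus_id": sid, "intensity": i, "believability": b})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Planted DIF
# ---------------------------------------------------------------------------


@dataclass
class DIFTruth:
    planted_items: list[str]
    delta: float
    reference_group: str
    focal_group: str


def simulate_dif(
    items: list[GRMItemParams],
    n_per_group: int,
    planted_items: list[str],
    delta: float,
    seed: int,
    factor: str = "group",
    levels: tuple[str, str] = ("reference", "focal"),
) -> tuple[GradedMatrix, DIFTruth]:
    """Two-group graded data with focal-group threshold shifts on planted items.

    Both groups draw theta ~ N(0,1); the focal group's planted items have
    all thresholds shifted by ``delta`` (harder for the focal group at
    equal ability), every other item is identical across groups.
    """
    unknown = [p for p in planted_items if p not in {it.item_id for it in items}]
    if unknown:
        raise ValueError(f"planted items not in the bank: {unknown}")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    theta = rng.normal(0.0, 1.0, size=n)
    groups = pd.DataFrame({factor: [levels[0]] * n_per_group + [levels[1]] * n_per_group})
    focal_items = [
        GRMItemParams(it.item_id, it.a, it.b + delta, it.m)
        if it.item_id in set(planted_items)
        else it
        for it in items
    ]
    assignment = np.ones((n, len(items)), dtype=bool)
    ref = simulate_graded_responses(
        theta[:n_per_group], items, assignment[:n_per_group], rng
    )
    foc = simulate_graded_responses(
        theta[n_per_group:], focal_items, assignment[n_per_group:], rng
    )
    scores = np.vstack([ref.scores, foc.scores])
    matrix = GradedMatrix(
        participant_ids=[f"p{i + 1:05d}" for i in range(n)],
        item_ids=[it.item_id for it in items],
        scores=scores,
        m_per_item=np.array([it.m for it in items]),
        group_labels=groups,
    )
    return matrix, DIFTruth(
        planted_items=list(planted_items),
        delta=delta,
        reference_group=levels[0],
        focal_group=levels[1],
    )


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    spec: SimulationSpec
    bank: ItemBank
    true_params: dict[str, GRMItemParams]
    theta: np.ndarray
    table: ResponseTable
    true_scores: GradedMatrix


def simulate_study(spec: SimulationSpec | None = None) -> SyntheticStudy:
    """End-to-end synthetic norming study under the default conditions.

    Rating latent means are drawn per stimulus around moderate intensity
    (2.7) and moderate believability (3.1), except concealed stimuli whose
    believability is pinned low (1.2): concealment looks unnatural.
    """
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    bank, truth = build_synthetic_bank(spec, rng)
    ids, groups, theta = simulate_participants(spec, rng)
    assignment = sparse_assignment(len(ids), bank, spec.items_per_participant, rng)
    rating_means = {}
    for sid, stim in bank.stimuli.items():
        mu_i = float(np.clip(rng.normal(2.7, 0.25), 1.0, 5.0))
        mu_b = 1.2 if stim.modality == "concealed" else float(np.clip(rng.normal(3.1, 0.25), 1.0, 5.0))
        rating_means[sid] = (mu_i, mu_b)
    table, true_scores = simulate_raw_choices(
        theta, bank, truth, assignment, rng,
        group_labels=groups, rating_means=rating_means, rating_sd=spec.rating_sd,
    )
    return SyntheticStudy(
        spec=spec, bank=bank, true_params=truth, theta=theta,
        table=table, true_scores=true_scores,
    )
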