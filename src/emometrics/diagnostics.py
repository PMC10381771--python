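"""Item and test diagnostics: information, fit, reliability, culling.

Item information is Samejima's Fisher information for a graded item,

    I(theta) = Sum_k (dP_k/dtheta)^2 / P_k ,

which for a 2-category item reduces to the familiar a^2 P (1 - P).  Test
information is the sum over items; its reciprocal square root is the
standard error of measurement along the trait.  The scalar "item
information" reported in tables is the prior-weighted average
integral I(theta) phi(theta) dtheta over the fit's quadrature (information
at theta = 0 is available as an alternative).

Item fit uses a summed-score (Orlando-Thissen S-X2 style) comparison of
observed and model-expected category frequencies within total-score
groups, with cells collapsed to a minimum expected count; the chi-square
to degrees-of-freedom ratio >= 3 is read as poor fit.

Reliability is Cronbach's alpha on the graded scores (pairwise-complete
covariances by default, given sparse designs) and McDonald's omega from
the one-factor model implied by the GRM loadings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import MISSING, GradedMatrix
from .grm import GRMFit, GRMItemParams, QuadratureSpec, category_probs, expected_score

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Information
# ---------------------------------------------------------------------------


def item_information(theta, params: GRMItemParams):
    """Samejima item information Sum_k (P_k')^2 / P_k at theta."""
    th = np.asarray(theta, dtype=float)[..., None]
    from scipy.special import expit

    pstar = expit(params.a * (th - params.b))  # (..., m-1)
    s = params.a * pstar * (1.0 - pstar)
    zeros = np.zeros(s.shape[:-1] + (1,))
    s_ext = np.concatenate([zeros, s, zeros], axis=-1)
    dP = s_ext[..., :-1] - s_ext[..., 1:]  # dP_k/dtheta
    P = category_probs(np.asarray(theta, dtype=float), params)
    info = (dP**2 / np.clip(P, 1e-300, 1.0)).sum(axis=-1)
    return float(info) if np.isscalar(theta) else info


def scalar_item_information(
    params: GRMItemParams, quad: QuadratureSpec, at_theta0: bool = False
) -> float:
    """One-number item information: prior-weighted mean of I(theta).

    With ``at_theta0=True`` returns I(0) instead (the alternative scalar).
    """
    if at_theta0:
        return float(item_information(0.0, params))
    return float(quad.weights @ item_information(quad.nodes, params))


def test_information(theta, fit: GRMFit):
    """Test information function: pointwise sum of item information curves."""
    if not fit.items:
        raise ValueError("fit has no items")
    total = sum(item_information(theta, it) for it in fit.items)
    return float(total) if np.isscalar(theta) else np.asarray(total)


def tif_area(
    fit: GRMFit, theta_range: tuple[float, float] = (-3.0, 3.0), grid_size: int = 601
) -> float:
    """Trapezoidal area under the test information function."""
    lo, hi = theta_range
    if hi <= lo:
        raise ValueError("invalid theta range")
    grid = np.linspace(lo, hi, grid_size)
    return float(np.trapezoid(test_information(grid, fit), grid))


@dataclass
class TIFComparison:
    t: float | None
    df: int
    cohens_d: float | None
    mean_diff: float
    degenerate: bool


def compare_tifs(
    fit_a: GRMFit,
    fit_b: GRMFit,
    grid_size: int = 60,
    theta_range: tuple[float, float] = (-3.0, 3.0),
) -> TIFComparison:
    """Paired comparison of two TIFs over a shared theta grid.

    The two information curves are evaluated on ``grid_size`` equally
    spaced points; the paired t statistic (df = grid_size - 1) and Cohen's
    d = mean(diff)/sd(diff) quantify how much more information one test
    provides.  Identical curves have zero variance and are reported as
    degenerate rather than producing an infinite t.
    """
    if grid_size < 2:
        raise ValueError("need at least 2 grid points")
    grid = np.linspace(theta_range[0], theta_range[1], grid_size)
    diff = test_information(grid, fit_a) - test_information(grid, fit_b)
    sd = float(np.std(diff, ddof=1))
    mean = float(np.mean(diff))
    if sd == 0.0:
        return TIFComparison(t=None, df=grid_size - 1, cohens_d=None, mean_diff=mean, degenerate=True)
    d = mean / sd
    t = mean / (sd / np.sqrt(grid_size))
    return TIFComparison(t=t, df=grid_size - 1, cohens_d=d, mean_diff=mean, degenerate=False)


# ---------------------------------------------------------------------------
# Item fit (summed-score chi-square)
# ---------------------------------------------------------------------------


def _score_distribution(items: list[GRMItemParams], nodes: np.ndarray) -> np.ndarray:
    """Lord-Wingersky recursion: P(total = s | theta_q); shape (Q, S+1)."""
    dist = np.ones((len(nodes), 1))
    for params in items:
        P = category_probs(nodes, params)  # (Q, m)
        S_old = dist.shape[1] - 1
        new = np.zeros((len(nodes), S_old + params.m))
        for k in range(params.m):
            new[:, k : k + S_old + 1] += P[:, [k]] * dist
        dist = new
    return dist


def item_fit_chisq(
    matrix: GradedMatrix,
    fit: GRMFit,
    item_id: str,
    min_expected: float = 1.0,
    min_obs: int = 50,
) -> tuple[float, int, float]:
    """Summed-score item-fit chi-square (Orlando-Thissen style).

    Respondents are grouped by their total score over the fitted items
    (complete cases only); within each group the observed category counts
    for the item are compared with the model-expected counts, obtained by
    combining the item's category curves with the Lord-Wingersky rest-score
    distribution under the N(0,1) prior.  Adjacent score groups are merged
    until every expected cell reaches ``min_expected``; df = (cells after
    collapsing) - (number of item parameters).  Returns (chisq, df, p);
    raises if too little data survives collapsing.
    """
    j = fit.item_ids.index(item_id)
    params = fit.items[j]
    complete = np.all(matrix.scores != MISSING, axis=1)
    if complete.sum() < min_obs:
        raise ValueError(
            f"item fit needs >= {min_obs} complete-case respondents, "
            f"got {int(complete.sum())}"
        )
    scores = matrix.scores[complete]
    totals = scores.sum(axis=1)
    nodes, w = fit.quadrature.nodes, fit.quadrature.weights

    rest_items = [it for i, it in enumerate(fit.items) if i != j]
    S_rest = _score_distribution(rest_items, nodes)  # (Q, S_rest+1)
    P_item = category_probs(nodes, params)  # (Q, m)
    S_max_rest = S_rest.shape[1] - 1
    S_max = S_max_rest + params.m - 1

    # expected joint P(total=s, X=k) marginalized over the prior
    joint = np.zeros((S_max + 1, params.m))
    for k in range(params.m):
        # P(rest = s-k | theta) P(X=k | theta), summed over theta
        contrib = (w[:, None] * P_item[:, [k]] * S_rest).sum(axis=0)  # (S_rest+1,)
        joint[k : k + S_max_rest + 1, k] += contrib
    p_total = joint.sum(axis=1)

    n_by_total = np.bincount(totals, minlength=S_max + 1)
    obs = np.zeros((S_max + 1, params.m))
    for s, x in zip(totals, scores[:, j]):
        obs[s, x] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(p_total[:, None] > 0, joint / p_total[:, None], 0.0)
    exp = n_by_total[:, None] * cond

    # drop empty score groups, then merge adjacent groups until all expected
    # cells reach the minimum count
    keep = n_by_total > 0
    obs, exp = obs[keep], exp[keep]
    merged_obs: list[np.ndarray] = []
    merged_exp: list[np.ndarray] = []
    acc_o = np.zeros(params.m)
    acc_e = np.zeros(params.m)
    for row_o, row_e in zip(obs, exp):
        acc_o += row_o
        acc_e += row_e
        if np.all(acc_e >= min_expected):
            merged_obs.append(acc_o)
            merged_exp.append(acc_e)
            acc_o, acc_e = np.zeros(params.m), np.zeros(params.m)
    if np.any(acc_e > 0):
        if merged_obs:
            merged_obs[-1] = merged_obs[-1] + acc_o
            merged_exp[-1] = merged_exp[-1] + acc_e
        else:
            merged_obs.append(acc_o)
            merged_exp.append(acc_e)
    O = np.vstack(merged_obs)
    E = np.vstack(merged_exp)
    # within-row category collapsing if any cell is still too small
    rows_o, rows_e = [], []
    for ro, re in zip(O, E):
        o, e = list(ro), list(re)
        k = 0
        while k < len(e):
            if e[k] < min_expected and len(e) > 1:
                tgt = k - 1 if k > 0 else k + 1
                e[tgt] += e[k]
                o[tgt] += o[k]
                del e[k], o[k]
            else:
                k += 1
        rows_o.append(o)
        rows_e.append(e)
    n_cells = sum(len(r) for r in rows_e)
    n_params = 1 + (params.m - 1)
    df = n_cells - len(rows_e) - n_params
    if df < 1:
        raise ValueError("insufficient data after collapsing (df < 1)")
    chisq = float(
        sum(
            (oo - ee) ** 2 / ee
            for ro, re in zip(rows_o, rows_e)
            for oo, ee in zip(ro, re)
        )
    )
    p = float(chi2.sf(chisq, df))
    return chisq, df, p


def chisq_df_ratio(chisq: float, df: int) -> tuple[float, str]:
    """Chi-square to degrees-of-freedom ratio and its fit verdict.

    Ratios >= 3 are read as poor fit; ratios < 3 as adequate fit.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    ratio = chisq / df
    return ratio, ("poor" if ratio >= 3.0 else "adequate")


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------


def cronbach_alpha(
    matrix: GradedMatrix, pairwise: bool = True, coverage_warning: float = 0.5
) -> float:
    """Cronbach's alpha: k/(k-1) (1 - Sum var_i / var_total).

    With ``pairwise=True`` (the default, suited to sparse designs) the item
    covariance matrix uses pairwise-complete observations; a warning is
    logged when fewer than half the item pairs have 50%+ joint coverage.
    Returns NaN when the total variance is zero (reported, not raised).
    """
    if matrix.n_items < 2:
        raise ValueError("alpha needs at least 2 items")
    df = matrix.to_frame()
    if not pairwise:
        df = df.dropna()
    cov = df.cov()  # pairwise-complete by construction
    if pairwise:
        n_pair = df.notna().astype(float).T @ df.notna().astype(float)
        frac = (n_pair.to_numpy() >= 0.5 * matrix.n_participants).mean()
        if frac < coverage_warning:
            logger.warning(
                "pairwise coverage is thin (%.0f%% of item pairs have >= 50%% joint "
                "coverage); alpha may be unstable",
                100 * frac,
            )
    total_var = float(cov.to_numpy().sum())
    if total_var <= 0:
        logger.warning("zero total variance; alpha undefined")
        return float("nan")
    k = matrix.n_items
    return k / (k - 1) * (1.0 - float(np.trace(cov.to_numpy())) / total_var)


def mcdonald_omega(loadings: Sequence[float]) -> float:
    """McDonald's omega from standardized one-factor loadings.

    omega = (Sum lambda)^2 / ((Sum lambda)^2 + Sum (1 - lambda^2)).
    """
    lam = np.asarray(loadings, dtype=float)
    if np.any(lam <= 0) or np.any(lam >= 1):
        raise ValueError("loadings must be in (0, 1)")
    num = lam.sum() ** 2
    return float(num / (num + (1.0 - lam**2).sum()))


@dataclass
class ReliabilityReport:
    alpha: float
    omega: float
    n_items: int
    n_respondents: int


def reliability(matrix: GradedMatrix, fit: GRMFit) -> ReliabilityReport:
    """Alpha and omega on the same item set (omega from the GRM loadings)."""
    if matrix.item_ids != fit.item_ids:
        raise ValueError("matrix and fit cover different item sets")
    return ReliabilityReport(
        alpha=cronbach_alpha(matrix),
        omega=mcdonald_omega(fit.loadings),
        n_items=matrix.n_items,
        n_respondents=matrix.n_participants,
    )


# ---------------------------------------------------------------------------
# Diagnostics table and culling
# ---------------------------------------------------------------------------


@dataclass
class ItemDiagnostics:
    item_id: str
    scalar_information: float
    loading: float
    fit_chisq: float | None
    fit_df: int | None
    fit_p: float | None
    chisq_df_ratio: float | None
    flags: list[str] = field(default_factory=list)


def compute_diagnostics(
    matrix: GradedMatrix, fit: GRMFit, alpha_level: float = 0.05
) -> list[ItemDiagnostics]:
    """Per-item scalar information, loading, and summed-score fit statistics."""
    out: list[ItemDiagnostics] = []
    for j, item_id in enumerate(fit.item_ids):
        try:
            chisq, dfree, p = item_fit_chisq(matrix, fit, item_id)
            ratio, _ = chisq_df_ratio(chisq, dfree)
        except ValueError as err:
            logger.warning("item fit unavailable for %s: %s", item_id, err)
            chisq = dfree = p = ratio = None
        out.append(
            ItemDiagnostics(
                item_id=item_id,
                scalar_information=scalar_item_information(fit.items[j], fit.quadrature),
                loading=float(fit.loadings[j]),
                fit_chisq=chisq,
                fit_df=dfree,
                fit_p=p,
                chisq_df_ratio=ratio,
            )
        )
    return out


@dataclass(frozen=True)
class CullThresholds:
    loading_min: float = 0.30
    alpha: float = 0.05
    info_reference: float | None = None  # None -> candidate-pool mean


@dataclass
class CullResult:
    retained: list[str]
    culled: list[str]
    reasons: dict[str, list[str]]
    info_reference: float


def cull_items(
    diagnostics: Sequence[ItemDiagnostics],
    thresholds: CullThresholds | None = None,
    rule: str = "two_of_three",
) -> CullResult:
    """Apply the culling rule over the three flags.

    Flags per item: significant misfit (fit p < alpha), poor loading
    (< loading_min), and below-reference information (reference defaults to
    the candidate-pool mean, frozen into the result so re-runs on the
    retained set are idempotent).  ``rule`` is one of ``"any"`` (cull on
    any flag), ``"two_of_three"`` (default), or ``"all"``.
    """
    if rule not in ("any", "two_of_three", "all"):
        raise ValueError(f"unknown culling rule {rule!r}")
    thresholds = thresholds or CullThresholds()
    info_ref = thresholds.info_reference
    if info_ref is None:
        info_ref = float(np.mean([d.scalar_information for d in diagnostics]))
    need = {"any": 1, "two_of_three": 2, "all": 3}[rule]
    retained, culled, reasons = [], [], {}
    for d in sorted(diagnostics, key=lambda d: d.item_id):
        fl: list[str] = []
        if d.fit_p is not None and d.fit_p < thresholds.alpha:
            fl.append("misfit")
        if d.loading < thresholds.loading_min:
            fl.append("low_loading")
        if d.scalar_information < info_ref:
            fl.append("low_information")
        d.flags = fl
        if len(fl) >= need:
            culled.append(d.item_id)
            reasons[d.item_id] = fl
        else:
            retained.append(d.item_id)
    return CullResult(retained=retained, culled=culled, reasons=reasons, info_reference=info_ref)


# ---------------------------------------------------------------------------
# Balanced final selection
# ---------------------------------------------------------------------------


@dataclass
class BalancedSelection:
    selected: list[str]
    unmet_quotas: dict[tuple, int]


def select_balanced_final(
    candidates: pd.DataFrame,
    quotas: Mapping[tuple, int] | None,
    n_final: int,
    cell_columns: Iterable[str] = ("valence_activation", "actor_gender", "actor_race"),
) -> BalancedSelection:
    """Greedy information-maximizing selection under per-cell minimum counts.

    ``candidates`` must be indexed by item_id with a ``scalar_information``
    column plus the ``cell_columns``.  Quota cells are tuples of the cell
    column values mapped to minimum counts; ``quotas=None`` (or empty)
    degenerates to top-``n_final`` by information.  Selection is greedy and
    deterministic: while quota cells are unmet, pick the most informative
    item from an unmet cell (ties: information descending, item_id
    ascending); then fill remaining slots by information.  Unsatisfiable
    quota cells are reported, never silently ignored.
    """
    cell_columns = list(cell_columns)
    df = candidates.copy()
    df["__cell"] = list(zip(*(df[c] for c in cell_columns)))
    # deterministic order: information desc, item_id asc
    order = df.assign(__item=df.index).sort_values(
        by=["scalar_information", "__item"], ascending=[False, True]
    )
    remaining = dict(quotas or {})
    selected: list[str] = []
    chosen = set()
    while remaining and len(selected) < n_final:
        pick = None
        for item_id, row in order.iterrows():
            if item_id in chosen:
                continue
            cell = row["__cell"]
            if remaining.get(cell, 0) > 0:
                pick = (item_id, cell)
                break
        if pick is None:
            break  # no candidate can satisfy any open quota
        item_id, cell = pick
        selected.append(item_id)
        chosen.add(item_id)
        remaining[cell] -= 1
        if remaining[cell] <= 0:
            del remaining[cell]
    unmet = {cell: need for cell, need in remaining.items() if need > 0}
    if unmet:
        logger.warning("unsatisfiable quota cells: %s", unmet)
    for item_id in order.index:
        if len(selected) >= n_final:
            break
        if item_id not in chosen:
            selected.append(item_id)
            chosen.add(item_id)
    return BalancedSelection(selected=sorted(selected, key=lambda i: list(order.index).index(i)), unmet_quotas=unmet)
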