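"""Samejima graded response model: probabilities, likelihood, EM fitting.

The graded response model (GRM) places each respondent at a latent ability
theta and each m-category item at a discrimination ``a > 0`` with ordered
thresholds ``b_1 < ... < b_{m-1}``.  Boundary curves are logistic,

    P*_j(theta) = 1 / (1 + exp(-a (theta - b_j))),

and category probabilities are adjacent differences of the boundaries.
With m = 2 the model collapses to the two-parameter logistic (2PL) used
for dichotomously scored comparison tests.

Estimation is marginal maximum likelihood via EM: the E-step computes each
respondent's posterior over a fixed quadrature grid under a standard-normal
prior (which also identifies the scale); the M-step updates each item by
Newton steps with step-halving on the expected complete-data log-likelihood.
Parameters are carried in the logistic metric; the 1.702 constant appears
only in the conversion to normal-ogive factor loadings.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .data import FORMAT_VERSION, MISSING, GradedMatrix

logger = logging.getLogger(__name__)

_D = 1.702  # logistic -> normal-ogive scaling, used only for loadings


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class GRMItemParams:
    """Discrimination and ordered thresholds of one graded item."""

    item_id: str
    a: float
    b: np.ndarray  # shape (m-1,), strictly increasing
    m: int

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.a = float(self.a)
        if self.a <= 0:
            raise ValueError(f"item {self.item_id}: discrimination must be > 0")
        if len(self.b) != self.m - 1:
            raise ValueError(f"item {self.item_id}: need m-1 thresholds")
        if np.any(np.diff(self.b) <= 0):
            raise ValueError(f"item {self.item_id}: thresholds must be strictly increasing")


@dataclass
class QuadratureSpec:
    """Fixed theta grid with positive weights summing to one."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("quadrature nodes must be strictly increasing")
        if np.any(self.weights <= 0):
            raise ValueError("quadrature weights must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("quadrature weights must sum to 1")


@dataclass
class FitControls:
    """EM settings; defaults are deliberately conservative."""

    max_cycles: int = 500
    tol: float = 1e-4
    a_max: float = 6.0
    min_n: int = 100
    newton_steps: int = 1

    def to_dict(self) -> dict:
        return {
            "max_cycles": self.max_cycles,
            "tol": self.tol,
            "a_max": self.a_max,
            "min_n": self.min_n,
            "newton_steps": self.newton_steps,
        }


@dataclass
class GRMFit:
    """A calibrated model: item parameters plus convergence record."""

    items: list[GRMItemParams]
    loadings: np.ndarray
    loglik_trace: list[float]
    converged: bool
    quadrature: QuadratureSpec
    n_respondents: int
    flags: dict[str, list[str]] = field(default_factory=dict)
    collapsed_categories: dict[str, dict[int, int]] = field(default_factory=dict)
    controls: dict = field(default_factory=dict)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def item(self, item_id: str) -> GRMItemParams:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


def default_quadrature(n_nodes: int = 61, bound: float = 6.0) -> QuadratureSpec:
    """Equally spaced nodes on [-bound, bound] with renormalized N(0,1) weights."""
    nodes = np.linspace(-bound, bound, n_nodes)
    w = norm.pdf(nodes)
    return QuadratureSpec(nodes=nodes, weights=w / w.sum())


# ---------------------------------------------------------------------------
# Model curves
# ---------------------------------------------------------------------------


def boundary_prob(theta, a: float, b_j: float):
    """Logistic boundary curve P(X >= j | theta) = sigma(a (theta - b_j))."""
    if a <= 0:
        raise ValueError("discrimination a must be > 0")
    return expit(a * (np.asarray(theta, dtype=float) - b_j))


def _boundaries(theta, params: GRMItemParams) -> np.ndarray:
    """P* for each threshold; shape (..., m-1)."""
    th = np.asarray(theta, dtype=float)[..., None]
    return expit(params.a * (th - params.b))


def category_probs(theta, params: GRMItemParams) -> np.ndarray:
    """Category probabilities at theta; shape (..., m), rows on the simplex."""
    pstar = _boundaries(theta, params)
    ones = np.ones(pstar.shape[:-1] + (1,))
    zeros = np.zeros_like(ones)
    ext = np.concatenate([ones, pstar, zeros], axis=-1)
    probs = ext[..., :-1] - ext[..., 1:]
    return np.clip(probs, 0.0, 1.0)


def expected_score(theta, params: GRMItemParams):
    """Expected item score Sum_j j P(X=j | theta) = Sum_j P*_j; the ICC."""
    out = _boundaries(theta, params).sum(axis=-1)
    return float(out) if np.isscalar(theta) else out


def loading_from_a(a: float) -> float:
    """Standardized normal-ogive factor loading implied by a logistic slope."""
    if a <= 0:
        raise ValueError("discrimination a must be > 0")
    a_star = a / _D
    return a_star / np.sqrt(1.0 + a_star**2)


def a_from_loading(lam: float) -> float:
    """Inverse of :func:`loading_from_a` (loadings in (0, 1))."""
    if not (0.0 < lam < 1.0):
        raise ValueError("loading must be in (0, 1)")
    return _D * lam / np.sqrt(1.0 - lam**2)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _log_category_probs(nodes: np.ndarray, params: GRMItemParams) -> np.ndarray:
    """log P(X=k | theta_q); shape (Q, m)."""
    probs = category_probs(nodes, params)
    return np.log(np.clip(probs, 1e-300, 1.0))


def _respondent_log_lik(
    scores: np.ndarray, items: list[GRMItemParams], nodes: np.ndarray
) -> np.ndarray:
    """Sum of item log-probabilities per respondent per node; shape (n, Q)."""
    n, J = scores.shape
    L = np.zeros((n, len(nodes)))
    for j, params in enumerate(items):
        obs = scores[:, j] != MISSING
        if not np.any(obs):
            continue
        logp = _log_category_probs(nodes, params)  # (Q, m)
        L[obs] += logp[:, scores[obs, j]].T
    return L


def marginal_log_likelihood(
    matrix: GradedMatrix, items: list[GRMItemParams], quad: QuadratureSpec
) -> float:
    """Marginal log-likelihood Sum_i log Sum_q w_q Prod_j P(x_ij | theta_q).

    Missing cells are skipped; respondents with zero administered items are
    excluded with a warning (their marginal contribution is log 1 = 0 in
    any case only if excluded -- including them would add log Sum w = 0 too,
    but they carry no information and are reported).
    """
    if len(items) != matrix.n_items:
        raise ValueError("item parameter list does not align with the matrix")
    scores = matrix.scores
    administered = (scores != MISSING).sum(axis=1)
    if np.any(administered == 0):
        warnings.warn(
            f"{int((administered == 0).sum())} respondent(s) with no administered "
            "items excluded from the likelihood"
        )
        scores = scores[administered > 0]
    L = _respondent_log_lik(scores, items, quad.nodes)
    return float(logsumexp(L + np.log(quad.weights), axis=1).sum())


# ---------------------------------------------------------------------------
# M-step internals
# ---------------------------------------------------------------------------


def _expected_loglik(r: np.ndarray, nodes: np.ndarray, a: float, b: np.ndarray) -> float:
    """f(a, b) = Sum_{q,k} r_{qk} log P_k(theta_q)."""
    params = GRMItemParams(item_id="_", a=a, b=b, m=len(b) + 1)
    logp = _log_category_probs(nodes, params)
    return float((r * logp).sum())


def _grad(r: np.ndarray, nodes: np.ndarray, a: float, b: np.ndarray) -> np.ndarray:
    """Analytic gradient of the expected complete-data log-likelihood."""
    m = len(b) + 1
    th = nodes[:, None]
    pstar = expit(a * (th - b))  # (Q, m-1)
    s = pstar * (1.0 - pstar)
    ones = np.ones((len(nodes), 1))
    zeros = np.zeros((len(nodes), 1))
    ext = np.concatenate([ones, pstar, zeros], axis=1)
    P = np.clip(ext[:, :-1] - ext[:, 1:], 1e-12, 1.0)  # (Q, m)
    ratio = r / P  # (Q, m)
    # d f / d a: per category k, (theta - b_k) s_k - (theta - b_{k+1}) s_{k+1}
    ds_dA = np.zeros_like(P)
    term = (th - b) * s  # (Q, m-1), threshold j contribution
    ds_dA[:, :-1] += term  # P_k gains +dP*_k/da for k = j
    ds_dA[:, 1:] -= term  # P_k loses dP*_{k+1}/da for k+1 = j
    g_a = float((ratio * ds_dA).sum())
    # d f / d b_t = a Sum_q s_t [ r_{t-1}/P_{t-1} - r_t/P_t ]
    g_b = a * (s * (ratio[:, :-1] - ratio[:, 1:])).sum(axis=0)
    return np.concatenate([[g_a], g_b])


def _valid(a: float, b: np.ndarray, a_max: float) -> bool:
    return a > 1e-3 and a <= a_max * 4 and np.all(np.diff(b) > 1e-6) and np.all(np.abs(b) < 50)


def _newton_update(
    r: np.ndarray,
    nodes: np.ndarray,
    a: float,
    b: np.ndarray,
    a_max: float,
    n_steps: int,
) -> tuple[float, np.ndarray]:
    """A few Newton steps with step-halving; never decreases f."""
    p = np.concatenate([[a], b])
    f0 = _expected_loglik(r, nodes, p[0], p[1:])
    for _ in range(n_steps):
        g = _grad(r, nodes, p[0], p[1:])
        # Hessian by forward differences of the analytic gradient (cheap;
        # step-halving below guards against the small FD error)
        d = len(p)
        H = np.zeros((d, d))
        for i in range(d):
            h = 1e-6 * max(1.0, abs(p[i]))
            pp = p.copy()
            pp[i] += h
            if not _valid(pp[0], pp[1:], a_max):
                pp[i] -= 2 * h  # step the other way near a boundary
                h = -h
            H[:, i] = (_grad(r, nodes, pp[0], pp[1:]) - g) / h
        H = 0.5 * (H + H.T)
        step = None
        ridge = 0.0
        for _ in range(6):
            try:
                step = np.linalg.solve(-(H - ridge * np.eye(d)), g)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10, 1e-6)
        if step is None:
            step = g  # gradient ascent fallback
        improved = False
        scale = 1.0
        for _ in range(30):  # step-halving
            cand = p + scale * step
            if _valid(cand[0], cand[1:], a_max):
                f1 = _expected_loglik(r, nodes, cand[0], cand[1:])
                if f1 >= f0:
                    p, f0, improved = cand, f1, True
                    break
            scale *= 0.5
        if not improved:
            break
    return float(p[0]), p[1:]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _collapse_item(col: np.ndarray, m: int) -> tuple[np.ndarray, dict[int, int], int]:
    """Remap observed categories to consecutive 0..m'-1, merging empty ones."""
    observed = np.unique(col[col != MISSING])
    mapping = {int(old): new for new, old in enumerate(observed)}
    out = col.copy()
    mask = col != MISSING
    out[mask] = np.array([mapping[int(v)] for v in col[mask]])
    return out, mapping, len(observed)


def _start_values(col: np.ndarray, m: int) -> tuple[float, np.ndarray]:
    """a = 1; thresholds from logit transforms of cumulative category proportions."""
    obs = col[col != MISSING]
    b = []
    for j in range(1, m):
        p_ge = np.clip(np.mean(obs >= j), 0.01, 0.99)
        b.append(-np.log(p_ge / (1 - p_ge)))  # boundary at a=1, theta=0
    b = np.sort(np.asarray(b, dtype=float))
    for j in range(1, len(b)):  # enforce a minimal gap
        if b[j] - b[j - 1] < 0.05:
            b[j] = b[j - 1] + 0.05
    return 1.0, b


def fit_grm(
    matrix: GradedMatrix,
    quad: QuadratureSpec | None = None,
    controls: FitControls | None = None,
) -> GRMFit:
    """Calibrate a unidimensional GRM by EM marginal maximum likelihood.

    The theta scale is identified by the fixed N(0,1) prior encoded in the
    quadrature weights.  Categories never observed in the data are merged
    out before fitting and recorded in ``collapsed_categories``.  The EM
    trace of marginal log-likelihoods is non-decreasing; convergence is
    declared when the largest absolute parameter change falls below
    ``controls.tol``.  A runaway discrimination is capped at
    ``controls.a_max`` and flagged.  Estimation is fully deterministic.
    """
    quad = quad or default_quadrature()
    controls = controls or FitControls()
    if matrix.n_participants < controls.min_n:
        raise ValueError(
            f"need at least {controls.min_n} respondents, got {matrix.n_participants} "
            "(lower FitControls.min_n deliberately for small designs)"
        )
    degenerate = matrix.degenerate_items()
    if degenerate:
        raise ValueError(f"degenerate categories (single observed value): {degenerate}")

    scores = matrix.scores.copy()
    administered = (scores != MISSING).sum(axis=1)
    if np.any(administered == 0):
        logger.warning(
            "%d respondent(s) with no administered items excluded",
            int((administered == 0).sum()),
        )
        scores = scores[administered > 0]
    n = scores.shape[0]

    collapsed: dict[str, dict[int, int]] = {}
    items: list[GRMItemParams] = []
    m_eff = np.zeros(matrix.n_items, dtype=int)
    for j, item_id in enumerate(matrix.item_ids):
        col, mapping, m_obs = _collapse_item(scores[:, j], int(matrix.m_per_item[j]))
        scores[:, j] = col
        m_eff[j] = m_obs
        if any(old != new for old, new in mapping.items()) or m_obs != matrix.m_per_item[j]:
            collapsed[item_id] = mapping
        a0, b0 = _start_values(col, m_obs)
        items.append(GRMItemParams(item_id=item_id, a=a0, b=b0, m=m_obs))

    nodes, logw = quad.nodes, np.log(quad.weights)
    flags: dict[str, list[str]] = {}
    trace: list[float] = []
    converged = False
    obs_masks = [scores[:, j] != MISSING for j in range(matrix.n_items)]

    for _cycle in range(controls.max_cycles):
        # E-step
        L = _respondent_log_lik(scores, items, nodes)
        joint = L + logw
        ll = float(logsumexp(joint, axis=1).sum())
        trace.append(ll)
        post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))  # (n, Q)

        # M-step
        max_delta = 0.0
        for j, params in enumerate(items):
            obs = obs_masks[j]
            x = scores[obs, j]
            onehot = np.zeros((x.size, params.m))
            onehot[np.arange(x.size), x] = 1.0
            r = post[obs].T @ onehot  # (Q, m)
            a_new, b_new = _newton_update(
                r, nodes, params.a, params.b, controls.a_max, controls.newton_steps
            )
            if a_new > controls.a_max:
                a_new = controls.a_max
                flags.setdefault(params.item_id, []).append("a_capped")
            delta = max(abs(a_new - params.a), float(np.max(np.abs(b_new - params.b))))
            max_delta = max(max_delta, delta)
            params.a, params.b = a_new, b_new
        if max_delta < controls.tol:
            converged = True
            break

    # final trace point at the returned parameters
    trace.append(
        float(
            logsumexp(_respondent_log_lik(scores, items, nodes) + logw, axis=1).sum()
        )
    )
    if not converged:
        logger.warning("EM reached the cycle cap (%d) without converging", controls.max_cycles)
    loadings = np.array([loading_from_a(it.a) for it in items])
    return GRMFit(
        items=items,
        loadings=loadings,
        loglik_trace=trace,
        converged=converged,
        quadrature=quad,
        n_respondents=n,
        flags=flags,
        collapsed_categories=collapsed,
        controls=controls.to_dict(),
    )


# ---------------------------------------------------------------------------
# Person scoring
# ---------------------------------------------------------------------------


def eap_theta(scores_row: np.ndarray, fit: GRMFit) -> tuple[float, float]:
    """Expected-a-posteriori ability and posterior SD for one response row.

    The prior is the standard normal encoded in the fit's quadrature.
    Requires at least one administered item.
    """
    row = np.asarray(scores_row, dtype=int).reshape(1, -1)
    if row.shape[1] != len(fit.items):
        raise ValueError("row length does not match the fitted item list")
    if np.all(row == MISSING):
        raise ValueError("respondent has no administered items")
    L = _respondent_log_lik(row, fit.items, fit.quadrature.nodes)[0]
    logpost = L + np.log(fit.quadrature.weights)
    post = np.exp(logpost - logsumexp(logpost))
    mean = float(post @ fit.quadrature.nodes)
    var = float(post @ (fit.quadrature.nodes - mean) ** 2)
    return mean, float(np.sqrt(var))


def eap_scores(matrix: GradedMatrix, fit: GRMFit) -> np.ndarray:
    """EAP ability estimates for every respondent; shape (n, 2) = (mean, sd)."""
    L = _respondent_log_lik(matrix.scores, fit.items, fit.quadrature.nodes)
    logpost = L + np.log(fit.quadrature.weights)
    post = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))
    mean = post @ fit.quadrature.nodes
    var = (post * (fit.quadrature.nodes[None, :] - mean[:, None]) ** 2).sum(axis=1)
    return np.column_stack([mean, np.sqrt(var)])


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def write_grm_fit(fit: GRMFit, path: str | Path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "items": [
            {"item_id": it.item_id, "a": it.a, "b": list(map(float, it.b)), "m": it.m}
            for it in fit.items
        ],
        "loadings": list(map(float, fit.loadings)),
        "loglik_trace": fit.loglik_trace,
        "converged": fit.converged,
        "quadrature": {
            "nodes": list(map(float, fit.quadrature.nodes)),
            "weights": list(map(float, fit.quadrature.weights)),
        },
        "n_respondents": fit.n_respondents,
        "flags": fit.flags,
        "collapsed_categories": {
            k: {str(o): n for o, n in v.items()} for k, v in fit.collapsed_categories.items()
        },
        "controls": fit.controls,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_grm_fit(path: str | Path) -> GRMFit:
    raw = json.loads(Path(path).read_text())
    return GRMFit(
        items=[
            GRMItemParams(item_id=r["item_id"], a=r["a"], b=np.array(r["b"]), m=r["m"])
            for r in raw["items"]
        ],
        loadings=np.array(raw["loadings"]),
        loglik_trace=list(raw["loglik_trace"]),
        converged=bool(raw["converged"]),
        quadrature=QuadratureSpec(
            nodes=np.array(raw["quadrature"]["nodes"]),
            weights=np.array(raw["quadrature"]["weights"]),
        ),
        n_respondents=int(raw["n_respondents"]),
        flags={k: list(v) for k, v in raw.get("flags", {}).items()},
        collapsed_categories={
            k: {int(o): n for o, n in v.items()}
            for k, v in raw.get("collapsed_categories", {}).items()
        },
        controls=raw.get("controls", {}),
    )
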