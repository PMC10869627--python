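"""Closed-form and filtering-based crisis-risk prediction.

The patient's weekly mental state follows a two-state Markov chain over
{stable (S), unstable (U)} with transition probabilities

    P(U | S) = q,        P(U | U) = r,

and a crisis can only be observed while unstable, with probability ``p``
per week.  Given the last observed state (a crisis reveals U) and a run of
crisis-free weeks since then, the predictive crisis risk at week ``t``
satisfies a scalar Riccati difference equation whose closed-form solution
is evaluated here through the quadratic roots ``y+``/``y-``.  An exact
recursive Bayes filter over the latent state provides the same quantity
for arbitrary observation histories and serves as the fallback whenever
the closed form is inapplicable (p = 1, q = r, or a degenerate
denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "S",
    "U",
    "StateLabel",
    "ModelParams",
    "RiccatiCoefficients",
    "RiskCurve",
    "ClosedFormInapplicableError",
    "ImpossibleObservationError",
    "one_step_risk",
    "riccati_coefficients",
    "crisis_risk",
    "risk_limit",
    "risk_curve",
    "forward_filter_risk",
]

#: Stable / unstable state labels.
S: Literal["S"] = "S"
U: Literal["U"] = "U"

StateLabel = Literal["S", "U"]

# Numerical guards for the closed form.  Parameters closer than this to a
# degeneracy are routed to the Bayes filter, which is the semantic ground
# truth; the closed form is an optimisation on top of it.
_EPS_DEGENERATE = 1e-9
#: Week horizon at which the filter is treated as converged when the
#: closed-form limit is unavailable.
_LIMIT_FALLBACK_T = 500


class ClosedFormInapplicableError(ValueError):
    """The Riccati closed form does not apply to these parameters."""


class ImpossibleObservationError(ValueError):
    """An observation has probability zero under the model."""


def _check_state(x: str) -> str:
    if x not in (S, U):
        raise ValueError(f"state label must be {S!r} or {U!r}, got {x!r}")
    return x


@dataclass(frozen=True)
class ModelParams:
    """The (p, q, r) triple defining one patient's hidden Markov model.

    Parameters
    ----------
    p
        Probability of a crisis in a week spent in the unstable state U.
    q
        Transition probability S -> U.
    r
        Self-transition probability U -> U.
    """

    p: float
    q: float
    r: float

    def __post_init__(self) -> None:
        for name in ("p", "q", "r"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic transition matrix over (S, U), S first."""
        return np.array(
            [[1.0 - self.q, self.q], [1.0 - self.r, self.r]], dtype=float
        )

    @property
    def stationary_U(self) -> float:
        """Stationary probability of the unstable state, q / (1 + q - r).

        Falls back to 0.5 for the degenerate absorbing case q = 0, r = 1
        where every distribution is stationary.
        """
        denom = 1.0 + self.q - self.r
        if denom <= 0.0:
            return 0.5
        return float(min(max(self.q / denom, 0.0), 1.0))

    def closed_form_applicable(self) -> bool:
        """Whether the Riccati closed form can be evaluated safely."""
        try:
            riccati_coefficients(self, U)
            riccati_coefficients(self, S)
        except ClosedFormInapplicableError:
            return False
        return True


@dataclass(frozen=True)
class RiccatiCoefficients:
    """Derived quantities evaluating the closed-form risk recursion.

    ``R`` is the dimensionless ratio (r-q)(1-p)/(1-pr+r-q)^2; ``y_plus``
    and ``y_minus`` are the fixed points of the Riccati recursion (roots
    of y^2 - y + R); ``y0`` is its initial value, which depends on the
    anchoring observed state via the weight ``w_S`` or ``w_U``.
    """

    R: float
    w_S: float
    w_U: float
    y_plus: float
    y_minus: float
    y0: float


@dataclass(frozen=True)
class RiskCurve:
    """Predicted weekly crisis risk after the last observed state."""

    weeks: np.ndarray
    risk: np.ndarray
    limit: float


def one_step_risk(params: ModelParams, x_last: StateLabel) -> float:
    """Crisis risk one week after an observed state.

    By the Markov property this is ``p * r`` when the last state was U and
    ``p * q`` when it was S.
    """
    _check_state(x_last)
    return params.p * (params.r if x_last == U else params.q)


def riccati_coefficients(
    params: ModelParams, x0: StateLabel
) -> RiccatiCoefficients:
    """Evaluate the closed-form coefficients anchored at state ``x0``.

    Raises
    ------
    ClosedFormInapplicableError
        If p = 1, q = r, the discriminant 1 - 4R is negative, or a
        denominator is (numerically) zero.  Callers fall back to
        :func:`forward_filter_risk` in that case.
    """
    _check_state(x0)
    p, q, r = params.p, params.q, params.r
    if p >= 1.0 - _EPS_DEGENERATE:
        raise ClosedFormInapplicableError("requires p < 1")
    if abs(q - r) <= _EPS_DEGENERATE:
        raise ClosedFormInapplicableError("requires q != r")
    D = 1.0 - p * r + r - q
    if abs(D) <= _EPS_DEGENERATE:
        raise ClosedFormInapplicableError("denominator 1 - pr + r - q is zero")
    R = (r - q) * (1.0 - p) / D**2
    disc = 1.0 - 4.0 * R
    if disc < 0.0:
        raise ClosedFormInapplicableError("complex Riccati roots (1 - 4R < 0)")
    sq = math.sqrt(disc)
    y_plus = (1.0 + sq) / 2.0
    y_minus = (1.0 - sq) / 2.0
    w_S = (1.0 - p * q) / D
    w_U = (1.0 - p * r) / D
    w = w_U if x0 == U else w_S
    y0_den = 2.0 * R + w - 1.0
    if abs(y0_den) <= _EPS_DEGENERATE:
        raise ClosedFormInapplicableError("y0 denominator 2R + w - 1 is zero")
    y0 = (2.0 * R * w - R) / y0_den
    return RiccatiCoefficients(
        R=R, w_S=w_S, w_U=w_U, y_plus=y_plus, y_minus=y_minus, y0=y0
    )


def _closed_form_risk(
    coeffs: RiccatiCoefficients, params: ModelParams, t: np.ndarray
) -> np.ndarray:
    p, q, r = params.p, params.q, params.r
    D = 1.0 - p * r + r - q
    y0, yp, ym = coeffs.y0, coeffs.y_plus, coeffs.y_minus
    # Divide through by y+^t for numerical stability at large t; y+ >= 1/2
    # always, while y- may be negative (r < q), so keep integer exponents.
    ratio = (ym / yp) ** np.asarray(t, dtype=int)
    a = y0 - ym
    b = yp - y0
    num = a * yp - b * ym * ratio
    den = a - b * ratio
    if np.any(np.abs(den) <= 1e-300):
        raise ClosedFormInapplicableError("vanishing closed-form denominator")
    return 1.0 - D * num / den


def _validate_anchor(x0: StateLabel, y0_obs: int) -> None:
    _check_state(x0)
    if y0_obs not in (0, 1):
        raise ValueError(f"y0_obs must be 0 or 1, got {y0_obs!r}")
    if y0_obs == 1 and x0 == S:
        raise ImpossibleObservationError(
            "a crisis cannot be observed in the stable state"
        )


def crisis_risk(
    params: ModelParams, x0: StateLabel, y0_obs: int, t: int
) -> float:
    """P(crisis at week t | state x0 at week 0, no crisis in weeks 1..t-1).

    Uses the Riccati closed form when applicable and the exact Bayes
    filter otherwise.  Given the anchoring state, the week-0 crisis
    indicator carries no extra information, so ``y0_obs`` only enters as a
    consistency check (a crisis with ``x0 = S`` is contradictory).
    """
    _validate_anchor(x0, y0_obs)
    if t < 1:
        raise ValueError(f"week index t must be >= 1, got {t}")
    try:
        coeffs = riccati_coefficients(params, x0)
        return float(_closed_form_risk(coeffs, params, np.asarray(t)))
    except ClosedFormInapplicableError:
        prior_U = 1.0 if x0 == U else 0.0
        return float(forward_filter_risk(params, prior_U, [0] * t)[t - 1])


def risk_limit(params: ModelParams) -> float:
    """Asymptotic crisis risk after an ever-longer crisis-free run.

    Closed form ``1 - (1 - pr + r - q) * y+``; independent of the anchor
    state.  Falls back to the Bayes filter evaluated at a long horizon for
    degenerate parameters.
    """
    p, q, r = params.p, params.q, params.r
    try:
        coeffs = riccati_coefficients(params, U)
    except ClosedFormInapplicableError:
        prior_U = params.stationary_U
        return float(
            forward_filter_risk(params, prior_U, [0] * _LIMIT_FALLBACK_T)[-1]
        )
    D = 1.0 - p * r + r - q
    return float(np.clip(1.0 - D * coeffs.y_plus, 0.0, 1.0))


def risk_curve(
    params: ModelParams, x0: StateLabel, y0_obs: int, horizon: int
) -> RiskCurve:
    """Weekly risk profile for ``t = 1..horizon`` after the anchor week."""
    _validate_anchor(x0, y0_obs)
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    weeks = np.arange(1, horizon + 1)
    try:
        coeffs = riccati_coefficients(params, x0)
        risks = _closed_form_risk(coeffs, params, weeks)
    except ClosedFormInapplicableError:
        prior_U = 1.0 if x0 == U else 0.0
        risks = forward_filter_risk(params, prior_U, [0] * horizon)
    return RiskCurve(weeks=weeks, risk=np.asarray(risks, dtype=float),
                     limit=risk_limit(params))


def forward_filter_risk(
    params: ModelParams, prior_U: float, observations: Sequence[int]
) -> np.ndarray:
    """Exact recursive Bayes filter for the weekly crisis risk.

    Starting from ``prior_U = P(X_0 = U)`` before anything in
    ``observations`` is seen, alternates transition, prediction and Bayes
    update; element ``i`` of the result is
    ``P(Y_{i+1} = 1 | observations[:i])``.  This is the general-purpose
    predictor for arbitrary histories and the independent oracle for the
    closed form.
    """
    if not (0.0 <= prior_U <= 1.0):
        raise ValueError(f"prior_U={prior_U} outside [0, 1]")
    p, q, r = params.p, params.q, params.r
    obs = np.asarray(observations)
    if obs.ndim != 1:
        raise ValueError("observations must be one-dimensional")
    out = np.empty(len(obs), dtype=float)
    pi = float(prior_U)
    for i, y in enumerate(obs):
        pi = pi * r + (1.0 - pi) * q
        risk = p * pi
        out[i] = risk
        if y == 1:
            if risk == 0.0:
                raise ImpossibleObservationError(
                    f"crisis observed at step {i} has probability zero"
                )
            pi = 1.0  # a crisis reveals the unstable state
        elif y == 0:
            if risk >= 1.0:
                raise ImpossibleObservationError(
                    f"crisis-free week at step {i} has probability zero"
                )
            pi = pi * (1.0 - p) / (1.0 - risk)
        else:
            raise ValueError(f"observations must be 0/1, got {y!r}")
    return out


def _filter_risk_batch(
    p: np.ndarray,
    q: np.ndarray,
    r: np.ndarray,
    prior_U: np.ndarray,
    obs: np.ndarray,
) -> np.ndarray:
    """Vectorised Bayes filter over a cohort.

    ``p, q, r, prior_U`` have shape (B,), ``obs`` shape (B, T); returns
    the (B, T) matrix of predictive risks, element (b, t) being the risk
    for week t of patient b given that patient's observations before t.
    Used by the policy layer; semantics identical to
    :func:`forward_filter_risk` row by row.
    """
    B, T = obs.shape
    out = np.empty((B, T), dtype=float)
    pi = prior_U.astype(float).copy()
    for t in range(T):
        pi = pi * r + (1.0 - pi) * q
        risk = p * pi
        out[:, t] = risk
        y = obs[:, t]
        with np.errstate(invalid="ignore", divide="ignore"):
            upd0 = pi * (1.0 - p) / (1.0 - risk)
        pi = np.where(y == 1, 1.0, np.where(np.isfinite(upd0), upd0, 0.0))
    return out
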