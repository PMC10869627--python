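"""Baum-Welch maximum-likelihood estimation of (p, q, r).

Implements the forward-backward recursions for the two-state crisis HMM
and the expectation-maximisation updates, both per patient and pooled
across a cohort under shared parameters.  The forward/backward values are
kept on a per-step normalised scale (Rabiner scaling) so that sequences
of several hundred weeks do not underflow; the log-likelihood is
recovered from the accumulated scaling factors.

The M-step ratios are expectation counts: q is the expected number of
S->U transitions over the expected weeks spent in S, r the analogue for
U->U (transition sums necessarily exclude the final time point), and p
the expected number of crisis weeks in U over the expected weeks in U,
summed over every week including the last — the exact maximiser of the
EM surrogate, which is what guarantees a non-decreasing log-likelihood.
The initial-state distribution is not a free parameter:
it is tied to the stationary law of the (q, r) chain, keeping the model
three-dimensional.

A vectorised engine (:func:`fit_cohort`) runs the same EM simultaneously
for thousands of sequences with per-sequence parameters and random
restarts; the scalar functions are the readable reference path that the
tests cross-check against it and against brute-force path enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hmm_core import ModelParams

__all__ = [
    "CrisisSeries",
    "PosteriorTables",
    "FitConfig",
    "FitResult",
    "ZeroLikelihoodError",
    "UnidentifiableError",
    "forward_pass",
    "backward_pass",
    "posterior_tables",
    "m_step_single",
    "baum_welch_single",
    "baum_welch_pooled",
    "fit_cohort",
    "assign_parameters",
]

# State indices used throughout the tables: column 0 = S, column 1 = U.
_S, _U = 0, 1

_DENOM_FLOOR = 1e-12


class ZeroLikelihoodError(ValueError):
    """The observation sequence is impossible under the parameters."""


class UnidentifiableError(ValueError):
    """An M-step denominator has zero expected occupancy."""


@dataclass(frozen=True)
class CrisisSeries:
    """One patient's weekly binary crisis record.

    ``obs[t]`` is 1 if at least one crisis occurred during week ``t``
    (weeks are indexed from the patient's own week 0), else 0.
    ``start_week`` optionally anchors week 0 to a calendar date.
    """

    patient_id: str
    obs: np.ndarray
    start_week: object | None = None

    def __post_init__(self) -> None:
        obs = np.asarray(self.obs, dtype=np.int8)
        if obs.ndim != 1 or len(obs) < 1:
            raise ValueError("obs must be a non-empty 1-D sequence")
        if not np.isin(obs, (0, 1)).all():
            raise ValueError("obs values must be 0 or 1")
        object.__setattr__(self, "obs", obs)

    def __len__(self) -> int:
        return len(self.obs)


@dataclass
class PosteriorTables:
    """Forward-backward posteriors for one E-step.

    ``alpha`` holds the per-step normalised forward values (rows sum to
    one) with ``scale`` the normalising constants, so the unscaled
    forward value is ``alpha[t] * prod(scale[:t+1])``.  ``beta`` is
    scaled against the same constants with ``beta[T] = 1`` exactly.
    ``gamma[t]`` is the state posterior, ``xi[t]`` the posterior over the
    transition t -> t+1.
    """

    alpha: np.ndarray
    scale: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    xi: np.ndarray
    loglik: float


@dataclass(frozen=True)
class FitConfig:
    """EM settings.

    ``init_prior_U`` is the initial-state probability of U used in the
    forward recursion's first step.  It is held fixed during the run so
    that each M-step exactly maximises the EM surrogate and the
    log-likelihood is guaranteed non-decreasing; the default 0.5 is
    uninformative (one week of data cannot overrule 200).  ``None``
    instead ties the prior to the stationary law of the current (q, r)
    at every iteration — that keeps the prior self-consistent with the
    chain but makes the update a generalised-EM step whose
    log-likelihood may occasionally dip.
    """

    tol: float = 1e-5
    max_iter: int = 100
    n_restarts: int = 10
    seed: int | None = None
    init_prior_U: float | None = 0.5

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("max_iter and n_restarts must be >= 1")


@dataclass
class FitResult:
    params: ModelParams
    loglik: float
    n_iter: int
    converged: bool
    restart_logliks: np.ndarray
    unidentifiable: bool = False
    loglik_history: np.ndarray | None = None


def _emissions(params: ModelParams, obs: np.ndarray) -> np.ndarray:
    """(T, 2) matrix of P(y_t | x_t); crises are impossible in S."""
    p = params.p
    e = np.empty((len(obs), 2), dtype=float)
    e[:, _S] = 1.0 - obs
    e[:, _U] = np.where(obs == 1, p, 1.0 - p)
    return e


def _prior_vector(params: ModelParams, prior_U: float) -> np.ndarray:
    return np.array([1.0 - prior_U, prior_U], dtype=float)


def forward_pass(
    params: ModelParams, prior_U: float, obs: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward recursion alpha(x_t) = p(y_0..t, x_t).

    Returns ``(alpha, scale, loglik)`` where each row of ``alpha`` is
    normalised to sum to one and ``loglik = sum(log(scale))`` is the
    log-probability of the observations.
    """
    obs = np.asarray(obs, dtype=np.int8)
    if len(obs) == 0:
        raise ValueError("obs must be non-empty")
    e = _emissions(params, obs)
    P = params.transition_matrix
    T = len(obs)
    alpha = np.empty((T, 2), dtype=float)
    scale = np.empty(T, dtype=float)
    a = _prior_vector(params, prior_U) * e[0]
    for t in range(T):
        if t > 0:
            a = (alpha[t - 1] @ P) * e[t]
        c = a.sum()
        if c <= 0.0:
            raise ZeroLikelihoodError(
                f"observation sequence impossible at week {t}"
            )
        alpha[t] = a / c
        scale[t] = c
    return alpha, scale, float(np.log(scale).sum())


def backward_pass(
    params: ModelParams, obs: Sequence[int], scale: np.ndarray | None = None
) -> np.ndarray:
    """Scaled backward recursion with beta(x_T) = 1 exactly.

    When ``scale`` (the forward normalisers) is given, beta is divided by
    ``scale[t+1]`` at each step, which is the scaling that makes
    ``gamma = alpha * beta`` already normalised; without it the raw
    recursion is returned (fine for short sequences).
    """
    obs = np.asarray(obs, dtype=np.int8)
    e = _emissions(params, obs)
    P = params.transition_matrix
    T = len(obs)
    beta = np.empty((T, 2), dtype=float)
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        b = P @ (e[t + 1] * beta[t + 1])
        if scale is not None:
            b = b / scale[t + 1]
        beta[t] = b
    return beta


def posterior_tables(
    params: ModelParams, prior_U: float, obs: Sequence[int]
) -> PosteriorTables:
    """Full E-step: state posteriors gamma and transition posteriors xi."""
    obs = np.asarray(obs, dtype=np.int8)
    alpha, scale, loglik = forward_pass(params, prior_U, obs)
    beta = backward_pass(params, obs, scale=scale)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    e = _emissions(params, obs)
    P = params.transition_matrix
    T = len(obs)
    xi = np.empty((max(T - 1, 0), 2, 2), dtype=float)
    for t in range(T - 1):
        m = (
            alpha[t][:, None]
            * P
            * (e[t + 1] * beta[t + 1])[None, :]
            / scale[t + 1]
        )
        xi[t] = m / m.sum()
    return PosteriorTables(
        alpha=alpha, scale=scale, beta=beta, gamma=gamma, xi=xi,
        loglik=loglik,
    )


def m_step_single(
    tables: PosteriorTables,
    obs: Sequence[int],
    current: ModelParams | None = None,
) -> ModelParams:
    """Maximisation step from one patient's posteriors.

    A denominator with (numerically) zero expected occupancy makes the
    corresponding parameter unidentifiable: it is frozen at its value in
    ``current`` when provided, otherwise :class:`UnidentifiableError` is
    raised.
    """
    obs = np.asarray(obs, dtype=np.int8)
    gamma, xi = tables.gamma, tables.xi
    gS = gamma[:-1, _S].sum()
    gU = gamma[:-1, _U].sum()
    gU_all = gamma[:, _U].sum()
    xi_SU = xi[:, _S, _U].sum()
    xi_UU = xi[:, _U, _U].sum()
    p_num = (obs * gamma[:, _U]).sum()

    def ratio(num: float, den: float, name: str) -> float:
        if den <= _DENOM_FLOOR:
            if current is None:
                raise UnidentifiableError(
                    f"zero expected occupancy in denominator of {name}"
                )
            return getattr(current, name)
        return min(max(num / den, 0.0), 1.0)

    return ModelParams(
        p=ratio(p_num, gU_all, "p"), q=ratio(xi_SU, gS, "q"),
        r=ratio(xi_UU, gU, "r"),
    )


def _draw_inits(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random (p, q, r) initialisations, uniform on (0.02, 0.98), q != r."""
    inits = rng.uniform(0.02, 0.98, size=(n, 3))
    bad = np.abs(inits[:, 1] - inits[:, 2]) < 1e-6
    while bad.any():
        inits[bad] = rng.uniform(0.02, 0.98, size=(int(bad.sum()), 3))
        bad = np.abs(inits[:, 1] - inits[:, 2]) < 1e-6
    return inits


def _stationary_U(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    denom = 1.0 + q - r
    with np.errstate(divide="ignore", invalid="ignore"):
        s = q / denom
    return np.where(denom > 0.0, s, 0.5)


def _em_batch(
    obs: np.ndarray,
    inits: np.ndarray,
    tol: float,
    max_iter: int,
    init_prior_U: float | None,
    track_history: bool = False,
) -> dict:
    """Run EM simultaneously for B sequences with per-sequence parameters.

    ``obs`` is (B, T) of 0/1, ``inits`` (B, 3) of (p, q, r) starting
    points.  Each sequence iterates until its own log-likelihood change
    falls below ``tol`` or ``max_iter`` is reached; converged sequences
    drop out of the active set.  Returns final parameters, log-likelihood
    (of the returned parameters), iteration counts, convergence flags and
    an unidentifiability flag (frozen denominator or all-zero sequence).
    """
    B, T = obs.shape
    y = obs.astype(float)
    p = inits[:, 0].astype(float).copy()
    q = inits[:, 1].astype(float).copy()
    r = inits[:, 2].astype(float).copy()

    final_ll = np.full(B, -np.inf)
    n_iter = np.zeros(B, dtype=int)
    converged = np.zeros(B, dtype=bool)
    unident = obs.sum(axis=1) == 0
    history: list[list[float]] = [[] for _ in range(B)] if track_history else []

    active = np.arange(B)
    prev_ll = np.full(B, np.nan)
    obs_a, y_a = obs, y

    for it in range(1, max_iter + 1):
        pa, qa, ra = p[active], q[active], r[active]
        nA = len(active)
        if init_prior_U is None:
            prior_U = _stationary_U(qa, ra)
        else:
            prior_U = np.full(nA, float(init_prior_U))

        # --- forward (scaled) ---
        alpha = np.empty((nA, T, 2))
        scale = np.empty((nA, T))
        eS = 1.0 - y_a  # emission in S: crisis impossible
        # emission in U for week t: p if crisis else 1-p
        a0 = np.empty((nA, 2))
        a0[:, _S] = (1.0 - prior_U) * eS[:, 0]
        a0[:, _U] = prior_U * np.where(obs_a[:, 0] == 1, pa, 1.0 - pa)
        a = a0
        dead = np.zeros(nA, dtype=bool)
        for t in range(T):
            if t > 0:
                eU = np.where(obs_a[:, t] == 1, pa, 1.0 - pa)
                prevS, prevU = alpha[:, t - 1, _S], alpha[:, t - 1, _U]
                a = np.empty((nA, 2))
                a[:, _S] = (prevS * (1.0 - qa) + prevU * (1.0 - ra)) * eS[:, t]
                a[:, _U] = (prevS * qa + prevU * ra) * eU
            c = a.sum(axis=1)
            zero = c <= 0.0
            if zero.any():
                dead |= zero
                c = np.where(zero, 1.0, c)
            alpha[:, t] = a / c[:, None]
            scale[:, t] = c
        ll = np.log(scale).sum(axis=1)
        ll[dead] = -np.inf

        # --- backward + accumulated posteriors ---
        gS_sum = np.zeros(nA)
        gU_sum = np.zeros(nA)
        # emission update includes the final week (gamma there is alpha,
        # since beta(T) = 1); transition sums cannot
        gU_all = alpha[:, T - 1, _U].copy()
        p_num = y_a[:, T - 1] * alpha[:, T - 1, _U]
        xi_SU = np.zeros(nA)
        xi_UU = np.zeros(nA)
        beta_next = np.ones((nA, 2))
        for t in range(T - 2, -1, -1):
            eU_next = np.where(obs_a[:, t + 1] == 1, pa, 1.0 - pa)
            tmpS = eS[:, t + 1] * beta_next[:, _S]
            tmpU = eU_next * beta_next[:, _U]
            c_next = scale[:, t + 1]
            beta = np.empty((nA, 2))
            beta[:, _S] = ((1.0 - qa) * tmpS + qa * tmpU) / c_next
            beta[:, _U] = ((1.0 - ra) * tmpS + ra * tmpU) / c_next
            # gamma at t (normalised by construction of the scaling)
            gS = alpha[:, t, _S] * beta[:, _S]
            gU = alpha[:, t, _U] * beta[:, _U]
            norm = gS + gU
            norm = np.where(norm > 0.0, norm, 1.0)
            gS, gU = gS / norm, gU / norm
            gS_sum += gS
            gU_sum += gU
            gU_all += gU
            p_num += y_a[:, t] * gU
            xi_SU += alpha[:, t, _S] * qa * tmpU / c_next
            xi_UU += alpha[:, t, _U] * ra * tmpU / c_next
            beta_next = beta

        if track_history:
            for k, b in enumerate(active):
                history[b].append(float(ll[k]))

        n_iter[active] = it
        final_ll[active] = ll
        delta = np.abs(ll - prev_ll[active])
        conv_now = delta < tol
        done = conv_now | dead
        converged[active[conv_now & ~dead]] = True
        unident[active[dead]] = True

        # --- M-step for sequences that continue ---
        cont = ~done
        if it < max_iter and cont.any():
            idx = np.where(cont)[0]
            frozen = np.zeros(len(idx), dtype=bool)
            gU_c, gS_c, gA_c = gU_sum[idx], gS_sum[idx], gU_all[idx]
            okU, okS = gU_c > _DENOM_FLOOR, gS_c > _DENOM_FLOOR
            okA = gA_c > _DENOM_FLOOR
            frozen |= ~okU | ~okS | ~okA
            sel = active[idx]
            p[sel] = np.where(okA, np.clip(
                np.divide(p_num[idx], gA_c, where=okA,
                          out=np.zeros_like(gA_c)), 0, 1), p[sel])
            q[sel] = np.where(okS, np.clip(
                np.divide(xi_SU[idx], gS_c, where=okS,
                          out=np.zeros_like(gS_c)), 0, 1), q[sel])
            r[sel] = np.where(okU, np.clip(
                np.divide(xi_UU[idx], gU_c, where=okU,
                          out=np.zeros_like(gU_c)), 0, 1), r[sel])
            unident[sel] |= frozen
            prev_ll[sel] = ll[idx]
            active = sel
            obs_a, y_a = obs[active], y[active]
        else:
            break

    return {
        "p": p, "q": q, "r": r, "loglik": final_ll, "n_iter": n_iter,
        "converged": converged, "unidentifiable": unident,
        "history": history,
    }


def _best_restart(
    res: dict, offsets: slice, track_history: bool
) -> FitResult:
    ll = res["loglik"][offsets]
    best = int(np.argmax(ll))  # ties -> lowest restart index
    i = offsets.start + best
    return FitResult(
        params=ModelParams(
            p=float(res["p"][i]), q=float(res["q"][i]), r=float(res["r"][i])
        ),
        loglik=float(res["loglik"][i]),
        n_iter=int(res["n_iter"][i]),
        converged=bool(res["converged"][i]),
        restart_logliks=ll.copy(),
        unidentifiable=bool(res["unidentifiable"][i]),
        loglik_history=(
            np.array(res["history"][i]) if track_history else None
        ),
    )


def baum_welch_single(
    series: CrisisSeries, config: FitConfig = FitConfig()
) -> FitResult:
    """Fit (p, q, r) to one patient's sequence by EM with random restarts.

    The best restart (highest final log-likelihood, ties broken by the
    lowest restart index) is returned; per-iteration log-likelihoods of
    every restart are tracked so that EM monotonicity can be audited via
    ``loglik_history``.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 weeks of observations to fit")
    rng = np.random.default_rng(config.seed)
    inits = _draw_inits(rng, config.n_restarts)
    obs = np.tile(series.obs, (config.n_restarts, 1))
    res = _em_batch(
        obs, inits, config.tol, config.max_iter, config.init_prior_U,
        track_history=True,
    )
    return _best_restart(res, slice(0, config.n_restarts), True)


def fit_cohort(
    cohort: Sequence[CrisisSeries], config: FitConfig = FitConfig()
) -> list[FitResult]:
    """Per-patient EM fits for a whole cohort, vectorised across patients.

    Sequences are grouped by length and each group is fitted in one
    batched EM run covering all patients and restarts.  Results are
    deterministic for a given ``config.seed`` and independent of the
    grouping (every series draws its initialisations from its own spawned
    child seed).
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(cohort))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(cohort):
        if len(s) < 2:
            raise ValueError(f"series {s.patient_id!r} shorter than 2 weeks")
        by_len.setdefault(len(s), []).append(i)
    results: list[FitResult | None] = [None] * len(cohort)
    R = config.n_restarts
    for T, idxs in by_len.items():
        obs = np.vstack([
            np.tile(cohort[i].obs, (R, 1)) for i in idxs
        ])
        inits = np.vstack([
            _draw_inits(np.random.default_rng(children[i]), R) for i in idxs
        ])
        res = _em_batch(
            obs, inits, config.tol, config.max_iter, config.init_prior_U
        )
        for k, i in enumerate(idxs):
            results[i] = _best_restart(res, slice(k * R, (k + 1) * R), False)
    return results  # type: ignore[return-value]


def baum_welch_pooled(
    cohort: Sequence[CrisisSeries], config: FitConfig = FitConfig()
) -> FitResult:
    """Fit a single shared (p, q, r) to all patients jointly.

    Patients are independent, so the pooled log-likelihood is the sum of
    the per-patient ones and the M-step ratios pool the expectation
    counts over patients.  With a cohort of one this reduces exactly to
    :func:`baum_welch_single`.
    """
    if len(cohort) < 1:
        raise ValueError("need at least one series")
    rng = np.random.default_rng(config.seed)
    inits = _draw_inits(rng, config.n_restarts)
    obs_list = [s.obs for s in cohort]

    restart_lls = np.full(config.n_restarts, -np.inf)
    best: FitResult | None = None
    for j in range(config.n_restarts):
        params = ModelParams(*inits[j])
        prev_ll = np.nan
        history: list[float] = []
        n_iter = 0
        converged = False
        unident = False
        for it in range(1, config.max_iter + 1):
            n_iter = it
            if config.init_prior_U is None:
                prior = float(_stationary_U(
                    np.asarray(params.q), np.asarray(params.r)
                ))
            else:
                prior = config.init_prior_U
            gS = gU = gU_all = p_num = xi_SU = xi_UU = 0.0
            ll = 0.0
            try:
                tables_all = [
                    posterior_tables(params, prior, o) for o in obs_list
                ]
            except ZeroLikelihoodError:
                ll = -np.inf
                break
            for o, tb in zip(obs_list, tables_all):
                ll += tb.loglik
                gS += tb.gamma[:-1, _S].sum()
                gU += tb.gamma[:-1, _U].sum()
                gU_all += tb.gamma[:, _U].sum()
                p_num += (o * tb.gamma[:, _U]).sum()
                xi_SU += tb.xi[:, _S, _U].sum()
                xi_UU += tb.xi[:, _U, _U].sum()
            history.append(ll)
            if np.isfinite(prev_ll) and abs(ll - prev_ll) < config.tol:
                converged = True
                break
            prev_ll = ll
            if it == config.max_iter:
                break  # keep params matched to the reported log-likelihood
            if gU <= _DENOM_FLOOR or gS <= _DENOM_FLOOR:
                unident = True
            params = ModelParams(
                p=(min(max(p_num / gU_all, 0.0), 1.0)
                   if gU_all > _DENOM_FLOOR else params.p),
                q=(min(max(xi_SU / gS, 0.0), 1.0)
                   if gS > _DENOM_FLOOR else params.q),
                r=(min(max(xi_UU / gU, 0.0), 1.0)
                   if gU > _DENOM_FLOOR else params.r),
            )
        restart_lls[j] = ll
        if best is None or ll > best.loglik:
            best = FitResult(
                params=params, loglik=float(ll), n_iter=n_iter,
                converged=converged, restart_logliks=restart_lls,
                unidentifiable=unident or all(o.sum() == 0 for o in obs_list),
                loglik_history=np.array(history),
            )
    assert best is not None
    best.restart_logliks = restart_lls
    return best


def assign_parameters(
    cohort: Sequence[CrisisSeries],
    pooled: ModelParams,
    fits: dict[str, FitResult],
    min_history_weeks: int = 13,
) -> dict[str, ModelParams]:
    """Choose pooled vs individual parameters per patient.

    Patients with strictly fewer than ``min_history_weeks`` weeks of
    history receive the pooled (average-patient) parameters; everyone
    else keeps their individual fit.  The default of 13 weeks is the
    three-month rule.
    """
    if min_history_weeks < 0:
        raise ValueError("min_history_weeks must be >= 0")
    out: dict[str, ModelParams] = {}
    for s in cohort:
        if len(s) < min_history_weeks:
            out[s.patient_id] = pooled
        else:
            try:
                out[s.patient_id] = fits[s.patient_id].params
            except KeyError:
                warnings.warn(
                    f"no individual fit for {s.patient_id!r}; using pooled "
                    "parameters"
                )
                out[s.patient_id] = pooled
    return out
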