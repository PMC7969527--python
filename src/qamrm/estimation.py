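"""Marginal maximum likelihood estimation of anchored mixture Rasch models.

Fitting follows the classic MMLE/EM recipe for mixture IRT.  The missing data
are each person's latent class g and ability theta; the E-step computes joint
posterior responsibilities over (class, quadrature node), and the M-step has
closed or one-dimensional updates:

* mixing proportions: posterior class mass,
* each shared difficulty slot: the one-dimensional weighted Rasch likelihood
  equation, pooling expected counts over every (item, class) cell anchored to
  that slot, solved by safeguarded Newton,
* the shared ability variance: posterior expected second moment of theta
  (the mean stays fixed at 0).

Multi-start protocol: a number of random starts are each run for a few burn-in
iterations, the best few survivors continue to convergence, and the best
survivor is returned.  Because classes are pinned to attribute profiles by the
anchor map there is no label switching to correct.

Standard errors come from the observed information: the analytic score of the
marginal log-likelihood (difficulty slots, log-ratio mixing, ability sd) is
differenced centrally to form the Hessian, and mixing-proportion errors are
mapped back from the log-ratio scale by the delta method.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .likelihood import (
    QAMRMParams,
    QuadratureRule,
    ResponseMatrix,
    class_difficulty_matrix,
    response_loglik_nodes,
)
from .qstructure import (
    AnchorMap,
    LatentClassSpace,
    ParameterLayout,
    QMatrix,
    build_anchor_map,
    build_layout,
)

logger = logging.getLogger("qamrm")

_MAX_B = 15.0  # difficulty clamp for empty/saturated slots
_MIN_SD = 1e-3


@dataclass(frozen=True)
class FitConfig:
    """Optimization settings.

    Defaults mirror the two-stage multi-start protocol: 20 random starts, 10
    burn-in EM iterations each, the best 4 continued to convergence.
    Convergence is a relative log-likelihood change below ``tol``.
    """

    n_starts: int = 20
    burn_iters: int = 10
    n_survivors: int = 4
    max_iters: int = 2000
    tol: float = 1e-7
    seed: int = 0
    n_quadrature: int = 31
    compute_se: bool = True

    def __post_init__(self) -> None:
        if self.n_starts > 0 and not 1 <= self.n_survivors <= self.n_starts:
            raise ValueError("need 1 <= n_survivors <= n_starts")
        if self.tol < 0:
            raise ValueError("tol must be non-negative")
        if self.n_quadrature < 1:
            raise ValueError("need at least one quadrature node")


@dataclass
class EStepResult:
    loglik: float
    posterior: np.ndarray  # (N, G)
    node_responsibilities: np.ndarray  # (N, G, Q) joint posterior over (g, node)


def e_step(
    y: ResponseMatrix,
    params: QAMRMParams,
    layout: ParameterLayout,
    quad: QuadratureRule,
) -> EStepResult:
    """Posterior responsibilities over (class, node) and the marginal loglik."""
    B = class_difficulty_matrix(params, layout)
    ll = response_loglik_nodes(y, B, quad)  # (N, G, Q)
    logj = (
        ll
        + np.log(quad.weights)[None, None, :]
        + np.log(params.mixing)[None, :, None]
    )
    m = logj.max(axis=(1, 2))
    w = np.exp(logj - m[:, None, None])
    tot = w.sum(axis=(1, 2))
    loglik = float((np.log(tot) + m).sum())
    if not np.isfinite(loglik):
        raise FloatingPointError("non-finite marginal log-likelihood in E-step")
    w /= tot[:, None, None]
    posterior = w.sum(axis=2)
    return EStepResult(loglik=loglik, posterior=posterior, node_responsibilities=w)


def _slot_stats(
    y: ResponseMatrix, W: np.ndarray, layout: ParameterLayout
) -> tuple[np.ndarray, np.ndarray]:
    """Expected correct (R) and exposure (Nexp) per difficulty slot and node.

    Both are (n_slots, Q).  For complete data the exposure of every item equals
    the total node mass, which avoids the expensive masked contraction.
    """
    N, G, Q = W.shape
    J = layout.n_items
    Wf = W.reshape(N, G * Q)
    if y.complete:
        r_jgq = (y.values.T @ Wf).reshape(J, G, Q)
        n_gq = Wf.sum(axis=0).reshape(G, Q)
        n_jgq = np.broadcast_to(n_gq, (J, G, Q))
    else:
        mask = y.mask
        y1 = np.where(mask, y.values, 0.0)
        r_jgq = (y1.T @ Wf).reshape(J, G, Q)
        n_jgq = (mask.T.astype(float) @ Wf).reshape(J, G, Q)
    S = layout.n_difficulty
    R = np.zeros((S, Q))
    Nexp = np.zeros((S, Q))
    idx = layout.slot_of.reshape(J * G)
    np.add.at(R, idx, r_jgq.reshape(J * G, Q))
    np.add.at(Nexp, idx, np.ascontiguousarray(n_jgq).reshape(J * G, Q))
    return R, Nexp


def _solve_slots(
    b0: np.ndarray, R: np.ndarray, Nexp: np.ndarray, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve each slot's weighted Rasch likelihood equation by Newton.

    Finds b with sum_q R_q = sum_q Nexp_q * sigma(theta_q - b); the left side
    is the expected number correct pooled over all anchored cells, the right
    the expected model probability mass.  Returns (solution, held-slot flags).
    """
    exposure = Nexp.sum(axis=1)
    r_tot = R.sum(axis=1)
    held = exposure < 1e-8
    b = b0.copy()
    active = ~held
    for _ in range(60):
        p = expit(theta[None, :] - b[:, None])
        f = r_tot - (Nexp * p).sum(axis=1)
        fp = (Nexp * p * (1.0 - p)).sum(axis=1)
        step = np.zeros_like(b)
        ok = active & (fp > 1e-12)
        # f is increasing in b, so the Newton update is b - f / f'
        step[ok] = np.clip(-f[ok] / fp[ok], -3.0, 3.0)
        if not np.any(np.abs(step) > 1e-11):
            break
        b = np.clip(b + step, -_MAX_B, _MAX_B)
    b[held] = b0[held]
    if held.any():
        logger.warning(
            "difficulty slot(s) %s have ~zero expected exposure; values held",
            np.flatnonzero(held).tolist(),
        )
    return b, held


def m_step(
    y: ResponseMatrix,
    estep: EStepResult,
    params: QAMRMParams,
    layout: ParameterLayout,
    quad: QuadratureRule,
) -> QAMRMParams:
    """Closed-form / Newton M-step under the anchoring equality constraints."""
    W = estep.node_responsibilities
    N = y.n_persons
    mixing = estep.posterior.mean(axis=0)
    mixing = np.clip(mixing, 1e-12, None)
    mixing /= mixing.sum()
    node_mass = W.sum(axis=(0, 1))
    sigma2 = float(node_mass @ (quad.nodes**2)) / N
    sd = max(np.sqrt(sigma2), _MIN_SD)
    R, Nexp = _slot_stats(y, W, layout)
    b, _ = _solve_slots(params.difficulties, R, Nexp, quad.nodes)
    return QAMRMParams(difficulties=b, mixing=mixing, ability_sd=sd)


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

@dataclass
class SEResult:
    """Delta-method standard errors from the observed information."""

    difficulties: np.ndarray
    mixing: np.ndarray
    ability_sd: float
    cov: np.ndarray | None
    ok: bool


@dataclass
class FitResult:
    params: QAMRMParams
    layout: ParameterLayout
    space: LatentClassSpace
    amap: AnchorMap
    anchored: bool
    loglik: float
    loglik_path: np.ndarray
    converged: bool
    iterations: int
    posterior: np.ndarray  # (N, G)
    n_params: int
    n_obs: int
    ic: dict[str, float]
    class_mass: np.ndarray  # posterior-expected proportion per profile
    se: SEResult | None = None
    config: FitConfig | None = None

    @property
    def mode(self) -> str:
        return self.amap.mode


def _random_start(
    rng: np.random.Generator, layout: ParameterLayout
) -> QAMRMParams:
    """Random initial values: slot difficulties ~ U(-1, 1) sorted ascending
    within item (so level order starts out monotone), Dirichlet-jittered
    near-uniform mixing, unit ability sd."""
    b = rng.uniform(-1.0, 1.0, size=layout.n_difficulty)
    items = np.array([s[0] for s in layout.difficulty_slots])
    for j in np.unique(items):
        sel = items == j
        b[sel] = np.sort(b[sel])
    mixing = rng.dirichlet(np.full(layout.n_classes, 5.0))
    mixing = np.clip(mixing, 1e-6, None)
    mixing /= mixing.sum()
    return QAMRMParams(difficulties=b, mixing=mixing, ability_sd=1.0)


def _run_em(
    y: ResponseMatrix,
    params: QAMRMParams,
    layout: ParameterLayout,
    cfg: FitConfig,
    max_iters: int,
    tol: float,
) -> tuple[QAMRMParams, list[float], bool, EStepResult]:
    history: list[float] = []
    prev = -np.inf
    est = None
    for it in range(max_iters + 1):
        quad = QuadratureRule.gauss_hermite(cfg.n_quadrature, params.ability_sd)
        est = e_step(y, params, layout, quad)
        history.append(est.loglik)
        if abs(est.loglik - prev) / max(1.0, abs(est.loglik)) < tol:
            return params, history, True, est
        if it == max_iters:
            break
        prev = est.loglik
        params = m_step(y, est, params, layout, quad)
    return params, history, False, est


def fit_em(
    y: ResponseMatrix,
    q: QMatrix,
    space: LatentClassSpace,
    mode: str,
    cfg: FitConfig = FitConfig(),
    anchored: bool = True,
    init_params: QAMRMParams | None = None,
) -> FitResult:
    """Fit by multi-start EM and return the best converged solution.

    ``init_params`` adds a deterministic start (and is the sole start when
    ``cfg.n_starts == 0``).  Fully reproducible given ``cfg.seed``.
    """
    if y.n_items != q.n_items:
        raise ValueError(
            f"response matrix has {y.n_items} items but the Q-matrix has "
            f"{q.n_items} rows"
        )
    if y.n_persons < space.n_classes:
        raise ValueError("need at least as many persons as latent classes")
    amap = build_anchor_map(q, space, mode)
    layout = build_layout(amap, anchored=anchored)
    rng = np.random.default_rng(cfg.seed)
    starts: list[QAMRMParams] = []
    if init_params is not None:
        starts.append(init_params)
    starts.extend(_random_start(rng, layout) for _ in range(cfg.n_starts))
    if not starts:
        raise ValueError("no starting values: n_starts == 0 requires init_params")

    # stage 1: short burn-in from every start
    burned = []
    for s, start in enumerate(starts):
        p_s, hist, _, _ = _run_em(y, start, layout, cfg, cfg.burn_iters, 0.0)
        burned.append((hist[-1], s, p_s))
        logger.debug("start %d: burn-in loglik %.4f", s, hist[-1])
    burned.sort(key=lambda t: (-t[0], t[1]))
    n_surv = min(max(cfg.n_survivors, 1), len(burned))

    # stage 2: continue the survivors to convergence
    best = None
    for ll0, s, p_s in burned[:n_surv]:
        p_f, hist, conv, est = _run_em(y, p_s, layout, cfg, cfg.max_iters, cfg.tol)
        logger.debug(
            "survivor (start %d): loglik %.4f converged=%s iters=%d",
            s, hist[-1], conv, len(hist),
        )
        if best is None or hist[-1] > best[0]:
            best = (hist[-1], p_f, hist, conv, est)
    loglik, params, hist, converged, est = best
    if not converged:
        logger.warning(
            "no EM run met tol=%.1e within %d iterations; returning best "
            "non-converged solution", cfg.tol, cfg.max_iters,
        )
    n = y.n_persons
    ic = information_criteria(loglik, layout.n_total, n)
    se = None
    if cfg.compute_se and converged:
        se = standard_errors(y, params, layout, cfg.n_quadrature)
    return FitResult(
        params=params,
        layout=layout,
        space=space,
        amap=amap,
        anchored=anchored,
        loglik=loglik,
        loglik_path=np.asarray(hist),
        converged=converged,
        iterations=len(hist) - 1,
        posterior=est.posterior,
        n_params=layout.n_total,
        n_obs=n,
        ic=ic,
        class_mass=est.posterior.mean(axis=0),
        se=se,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Standard errors
# ---------------------------------------------------------------------------

def _pack(params: QAMRMParams) -> np.ndarray:
    eta = np.log(params.mixing[1:] / params.mixing[0])
    return np.concatenate([params.difficulties, eta, [params.ability_sd]])


def _unpack(x: np.ndarray, layout: ParameterLayout) -> QAMRMParams:
    S = layout.n_difficulty
    G = layout.n_classes
    eta = x[S : S + G - 1]
    expo = np.exp(np.concatenate([[0.0], eta]))
    mixing = expo / expo.sum()
    return QAMRMParams(
        difficulties=x[:S], mixing=mixing, ability_sd=max(float(x[-1]), _MIN_SD)
    )


def _score(
    x: np.ndarray, y: ResponseMatrix, layout: ParameterLayout, n_quad: int
) -> np.ndarray:
    """Analytic gradient of the marginal log-likelihood (Fisher's identity).

    The score equals the posterior-expected complete-data score, so one
    E-step pass yields every component: slot residuals for the difficulties,
    class-mass residuals for the log-ratio mixing, and the second-moment
    residual for the ability sd.
    """
    params = _unpack(x, layout)
    quad = QuadratureRule.gauss_hermite(n_quad, params.ability_sd)
    est = e_step(y, params, layout, quad)
    W = est.node_responsibilities
    R, Nexp = _slot_stats(y, W, layout)
    p = expit(quad.nodes[None, :] - params.difficulties[:, None])
    g_b = (Nexp * p).sum(axis=1) - R.sum(axis=1)
    N = y.n_persons
    g_eta = est.posterior.sum(axis=0)[1:] - N * params.mixing[1:]
    sd = params.ability_sd
    second = float(W.sum(axis=(0, 1)) @ (quad.nodes**2))
    g_sd = second / sd**3 - N / sd
    return np.concatenate([g_b, g_eta, [g_sd]])


def observed_information(
    y: ResponseMatrix,
    params: QAMRMParams,
    layout: ParameterLayout,
    n_quadrature: int = 31,
    step: float = 1e-4,
) -> np.ndarray:
    """Observed information by central finite differences of the analytic score."""
    x = _pack(params)
    p = x.size
    H = np.empty((p, p))
    for k in range(p):
        h = step * max(1.0, abs(x[k]))
        xp = x.copy(); xp[k] += h
        xm = x.copy(); xm[k] -= h
        H[:, k] = (_score(xp, y, layout, n_quadrature) -
                   _score(xm, y, layout, n_quadrature)) / (2.0 * h)
    H = 0.5 * (H + H.T)
    return -H


def standard_errors(
    y: ResponseMatrix,
    params: QAMRMParams,
    layout: ParameterLayout,
    n_quadrature: int = 31,
    step: float = 1e-4,
) -> SEResult:
    """SEs as sqrt-diagonal of the inverse observed information at the MLE.

    Mixing proportions are handled on the unconstrained log-ratio scale and
    back-transformed by the delta method.  A non-invertible information matrix
    yields NaN standard errors with a warning rather than fabricated values.
    """
    S = layout.n_difficulty
    G = layout.n_classes
    info = observed_information(y, params, layout, n_quadrature, step)
    nan = np.full(S, np.nan)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        logger.warning("observed information is singular; SEs undefined")
        return SEResult(nan, np.full(G, np.nan), float("nan"), None, False)
    d = np.diag(cov)
    if (d <= 0).any():
        logger.warning(
            "observed information is not positive definite; SEs undefined"
        )
        return SEResult(nan, np.full(G, np.nan), float("nan"), cov, False)
    se_b = np.sqrt(d[:S])
    # delta method: pi = softmax(0, eta), d pi_g / d eta_k = pi_g (1[g==k] - pi_k)
    pi = params.mixing
    Jm = np.zeros((G, G - 1))
    for g in range(G):
        for k in range(1, G):
            Jm[g, k - 1] = pi[g] * ((1.0 if g == k else 0.0) - pi[k])
    cov_eta = cov[S : S + G - 1, S : S + G - 1]
    cov_pi = Jm @ cov_eta @ Jm.T
    se_pi = np.sqrt(np.clip(np.diag(cov_pi), 0.0, None))
    return SEResult(se_b, se_pi, float(np.sqrt(d[-1])), cov, True)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def information_criteria(loglik: float, n_params: int, n: int) -> dict[str, float]:
    """AIC, BIC and the sample-size adjusted BIC.

    AIC = -2LL + 2p; BIC = -2LL + p ln n; ABIC = -2LL + p ln((n + 2) / 24).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    m2ll = -2.0 * loglik
    return {
        "AIC": m2ll + 2.0 * n_params,
        "BIC": m2ll + n_params * np.log(n),
        "ABIC": m2ll + n_params * np.log((n + 2) / 24.0),
    }


@dataclass
class Classification:
    class_index: np.ndarray  # (N,) modal profile index
    labels: tuple[str, ...]  # profile label per person
    posterior: np.ndarray
    n_ties: int


def classify(fit: FitResult, tol: float = 1e-12) -> Classification:
    """Modal attribute profile per person.

    Ties are broken toward the lower-mastery profile (the earlier profile in
    canonical order) and counted; a tie is logged rather than silently hidden.
    """
    post = fit.posterior
    modal = post.argmax(axis=1)  # argmax returns the first (lowest-mastery) max
    is_tie = (np.abs(post - post.max(axis=1, keepdims=True)) < tol).sum(axis=1) > 1
    n_ties = int(is_tie.sum())
    if n_ties:
        logger.info(
            "%d person(s) had tied modal classes; assigned the lower-mastery "
            "profile", n_ties,
        )
    labels = fit.space.labels
    return Classification(
        class_index=modal,
        labels=tuple(labels[g] for g in modal),
        posterior=post,
        n_ties=n_ties,
    )


def ability_estimates(
    fit: FitResult, y: ResponseMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """EAP ability and posterior SD per person, mixing over classes.

    The expectation runs over the joint posterior of (class, theta) on the
    quadrature grid.
    """
    n_quad = fit.config.n_quadrature if fit.config is not None else 31
    quad = QuadratureRule.gauss_hermite(n_quad, fit.params.ability_sd)
    est = e_step(y, fit.params, fit.layout, quad)
    W = est.node_responsibilities.sum(axis=1)  # (N, Q), class marginalized
    eap = W @ quad.nodes
    second = W @ (quad.nodes**2)
    psd = np.sqrt(np.clip(second - eap**2, 0.0, None))
    return eap, psd
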