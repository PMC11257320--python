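"""Maximum likelihood estimation, unconstrained and under odds-ratio homogeneity.

Two fitters are provided:

* :func:`fit_unconstrained` — per stratum, alternates the closed-form update
  of ``(π_1, π_2)`` at fixed ``ρ`` (the cubic profile root) with a scalar
  Fisher-scoring step for ``ρ``. Each stratum is independent, so the fit is
  stratum-by-stratum.
* :func:`fit_constrained` — under H0: θ_1 = … = θ_J = θ, eliminates the
  control probabilities via ``π_2j = π_1j/(π_1j(1−θ)+θ)`` and maximises
  ``Σ_j l_{j|θ}`` by a two-step scheme: an inner Newton–Raphson update of θ
  (on the log scale, for positivity and symmetric curvature) holding the
  nuisance parameters fixed, then a per-stratum 2×2 Fisher-scoring update of
  ``(π_1j, ρ_j)`` holding θ fixed.

Both fitters step-halve any update that would leave the parameter domain or
decrease the objective, and fall back to direct bounded numerical
maximisation if the scoring iterations stall. Estimates attracted to the
edge of the parameter space (e.g. a group with no events) are clamped at
``EPS`` and flagged: Wald-type quantities are unreliable there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .data_model import StratifiedCounts
from .likelihood import (
    EPS,
    Group,
    constrained_stratum_loglik,
    d2l_dpi2,
    dl_dpi,
    dl_drho,
    pi2_from,
    pi_closed_form,
    rho_information,
    stratum_groups,
    stratum_information,
    stratum_loglik,
)

__all__ = ["MleFit", "FitOptions", "fit_unconstrained", "fit_constrained"]

_PLO, _PHI = EPS, 1 - EPS
_RLO, _RHI = 0.0, 1 - EPS


@dataclass(frozen=True)
class FitOptions:
    """Tunable knobs of both fitters."""

    tol: float = 1e-10          # log-likelihood change
    param_tol: float = 1e-8     # max parameter change
    max_iter: int = 500
    rho_init: float = 0.5       # deterministic default; see `restarts`
    restarts: int = 0           # extra random rho starts (unconstrained fit)
    seed: int | None = None


@dataclass
class MleFit:
    """Fitted parameters with per-stratum diagnostics.

    ``theta_common`` is ``None`` for an unconstrained fit; for a constrained
    fit ``pi2`` is computed from ``pi1`` and ``theta_common`` (never
    re-estimated), so the constraint holds exactly.
    """

    pi1: np.ndarray
    pi2: np.ndarray
    rho: np.ndarray
    theta: np.ndarray
    theta_common: float | None
    loglik_by_stratum: np.ndarray
    total_loglik: float
    converged: bool
    iterations: int
    boundary_flags: list[str] = field(default_factory=list)
    fingerprint: str = ""

    @property
    def constrained(self) -> bool:
        return self.theta_common is not None


def _boundary(x: float) -> bool:
    return x <= _PLO * 2 or x >= 1 - 2 * EPS


# ---------------------------------------------------------------------------
# Unconstrained fit (per-stratum alternating scheme)
# ---------------------------------------------------------------------------

def _fit_stratum(groups: tuple[Group, Group], opts: FitOptions,
                 rho0: float) -> tuple[float, float, float, float, bool, int, list[str]]:
    g1, g2 = groups
    m_tot = g1.m_tot + g2.m_tot
    flags: list[str] = []

    if m_tot == 0:
        # purely unilateral stratum: rho unidentified, binomial MLEs
        pi1 = min(max(g1.n1 / g1.n_tot, _PLO), _PHI)
        pi2 = min(max(g2.n1 / g2.n_tot, _PLO), _PHI)
        flags.append("rho unidentified (no bilateral subjects); fixed at 0")
        ll = stratum_loglik(groups, pi1, pi2, 0.0)
        return pi1, pi2, 0.0, ll, True, 0, flags

    rho = min(max(rho0, _RLO), 0.98)
    pi1 = pi_closed_form(g1, rho)
    pi2 = pi_closed_form(g2, rho)
    ll = stratum_loglik(groups, pi1, pi2, rho)
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        pi1_new = _clip_p(pi_closed_form(g1, rho))
        pi2_new = _clip_p(pi_closed_form(g2, rho))
        score = dl_drho(groups, pi1_new, pi2_new, rho)
        info = rho_information(groups, pi1_new, pi2_new, rho)
        step = score / info if info > 0 else 0.0
        rho_new = rho + step
        # step-halve into the domain and uphill
        for _ in range(50):
            if _RLO <= rho_new <= _RHI:
                ll_try = stratum_loglik(groups, pi1_new, pi2_new, rho_new)
                if ll_try >= ll - 1e-10:
                    break
            step *= 0.5
            rho_new = rho + step
        else:
            rho_new = rho
            ll_try = stratum_loglik(groups, pi1_new, pi2_new, rho_new)
        delta = max(abs(pi1_new - pi1), abs(pi2_new - pi2), abs(rho_new - rho))
        dll = abs(ll_try - ll)
        pi1, pi2, rho, ll = pi1_new, pi2_new, rho_new, ll_try
        if delta < opts.param_tol and dll < opts.tol:
            converged = True
            break

    if not converged:
        pi1, pi2, rho, ll, ok = _numeric_stratum(groups, (pi1, pi2, rho))
        converged = ok
    for name, val in (("pi1", pi1), ("pi2", pi2)):
        if _boundary(val):
            flags.append(f"{name} at boundary ({val:.2e})")
    if rho >= _RHI - EPS:
        flags.append("rho at upper boundary")
    return pi1, pi2, rho, ll, converged, it, flags


def _clip_p(x: float) -> float:
    return min(max(x, _PLO), _PHI)


def _numeric_stratum(groups, x0):
    """Bounded quasi-Newton fallback on (pi1, pi2, rho)."""
    def neg(x):
        return -stratum_loglik(groups, x[0], x[1], x[2])

    res = minimize(neg, x0, method="L-BFGS-B",
                   bounds=[(_PLO, _PHI), (_PLO, _PHI), (_RLO, _RHI)])
    x = res.x
    return float(x[0]), float(x[1]), float(x[2]), -float(res.fun), bool(res.success)


def fit_unconstrained(counts: StratifiedCounts,
                      opts: FitOptions | None = None) -> MleFit:
    """Per-stratum MLEs of ``(π_1j, π_2j, ρ_j)`` and odds ratios ``θ̂_j``."""
    opts = opts or FitOptions()
    strata = stratum_groups(counts)
    J = counts.J
    rho_starts = [opts.rho_init]
    if opts.restarts:
        rng = np.random.default_rng(opts.seed)
        rho_starts += list(rng.uniform(0.02, 0.98, opts.restarts))

    pi1 = np.empty(J)
    pi2 = np.empty(J)
    rho = np.empty(J)
    lls = np.empty(J)
    flags: list[str] = []
    converged = True
    iters = 0
    for j, groups in enumerate(strata):
        best = None
        for r0 in rho_starts:
            cand = _fit_stratum(groups, opts, r0)
            if best is None or cand[3] > best[3]:
                best = cand
        p1, p2, r, ll, ok, it, fl = best
        pi1[j], pi2[j], rho[j], lls[j] = p1, p2, r, ll
        converged &= ok
        iters = max(iters, it)
        flags += [f"stratum {j + 1}: {f}" for f in fl]

    theta = pi1 * (1 - pi2) / (pi2 * (1 - pi1))
    return MleFit(pi1, pi2, rho, theta, None, lls, float(lls.sum()),
                  converged, iters, flags, counts.fingerprint())


# ---------------------------------------------------------------------------
# Constrained fit under homogeneity
# ---------------------------------------------------------------------------

def _theta_score_curv(strata, pi1, rho, theta):
    """First and second derivative of Σ_j l_{j|θ} in θ at fixed nuisances."""
    d1 = 0.0
    d2 = 0.0
    for groups, p1, r in zip(strata, pi1, rho):
        D = p1 + theta * (1 - p1)
        p2 = p1 / D
        dp2 = -p1 * (1 - p1) / (D * D)
        d2p2 = 2 * p1 * (1 - p1) ** 2 / D ** 3
        gpi2 = dl_dpi(groups[1], p2, r)
        hpi2 = d2l_dpi2(groups[1], p2, r)
        d1 += gpi2 * dp2
        d2 += hpi2 * dp2 * dp2 + gpi2 * d2p2
    return d1, d2


def _constrained_total(strata, pi1, rho, theta):
    return sum(
        constrained_stratum_loglik(g, p, r, theta)
        for g, p, r in zip(strata, pi1, rho)
    )


def _update_theta(strata, pi1, rho, theta, tol=1e-11, max_iter=100):
    """Inner Newton–Raphson on log θ with step-halving; Brent fallback."""
    phi = math.log(theta)
    ll = _constrained_total(strata, pi1, rho, theta)
    for _ in range(max_iter):
        d1, d2 = _theta_score_curv(strata, pi1, rho, math.exp(phi))
        th = math.exp(phi)
        g = d1 * th                      # d/dphi
        h = d2 * th * th + d1 * th       # d2/dphi2
        if h >= 0 or not math.isfinite(h):
            break
        step = -g / h
        if abs(step) > 5:
            step = math.copysign(5, step)
        ok = False
        for _ in range(50):
            phi_new = phi + step
            ll_new = _constrained_total(strata, pi1, rho, math.exp(phi_new))
            if ll_new >= ll - 1e-12:
                ok = True
                break
            step *= 0.5
        if not ok:
            break
        moved = abs(phi_new - phi)
        phi, ll = phi_new, ll_new
        if moved < tol:
            return math.exp(phi), ll, True
    # bracketed fallback on the log-odds-ratio profile
    res = minimize_scalar(
        lambda f: -_constrained_total(strata, pi1, rho, math.exp(f)),
        bounds=(phi - 8, phi + 8), method="bounded",
        options={"xatol": 1e-12},
    )
    return math.exp(res.x), -res.fun, bool(res.success)


def _constrained_info_2x2(groups, p1, r, theta):
    """Expected information for (π_1, ρ) under the constrained likelihood:
    K^T I_{(π1,π2,ρ)} K with K the Jacobian of (π1, π2(π1,θ), ρ)."""
    D = p1 + theta * (1 - p1)
    p2 = p1 / D
    dpi2_dpi1 = theta / (D * D)
    I3 = stratum_information(groups, p1, p2, r)
    K = np.array([[1.0, 0.0], [dpi2_dpi1, 0.0], [0.0, 1.0]])
    return K.T @ I3 @ K, p2, dpi2_dpi1


def _scoring_step_2d(groups, p1, r, theta, step, llj, I2, g_pi1, g_rho):
    """One (π_1, ρ) update: projected joint scoring step with step-halving,
    then coordinate-wise fallbacks so a ρ pinned at its boundary cannot
    stall the π_1 direction."""
    # joint step, projected into the box
    s = step.copy()
    for _ in range(50):
        p1n = min(max(p1 + s[0], _PLO), _PHI)
        rn = min(max(r + s[1], _RLO), _RHI)
        if constrained_stratum_loglik(groups, p1n, rn, theta) >= llj - 1e-12:
            break
        s *= 0.5
    else:
        p1n, rn = p1, r
    # coordinate polish: helps when one coordinate is boundary-pinned
    llj = constrained_stratum_loglik(groups, p1n, rn, theta)
    if I2[0, 0] > 0:
        # pi1 gradient at the (possibly moved) current point
        Dn = p1n + theta * (1 - p1n)
        p2n = p1n / Dn
        g1 = dl_dpi(groups[0], p1n, rn) + \
            dl_dpi(groups[1], p2n, rn) * theta / (Dn * Dn)
        sp = g1 / I2[0, 0]
        for _ in range(50):
            cand = min(max(p1n + sp, _PLO), _PHI)
            ll_try = constrained_stratum_loglik(groups, cand, rn, theta)
            if ll_try >= llj - 1e-12:
                if ll_try > llj:
                    p1n, llj = cand, ll_try
                break
            sp *= 0.5
    return p1n, rn


def fit_constrained(counts: StratifiedCounts, opts: FitOptions | None = None,
                    fit_u: MleFit | None = None) -> MleFit:
    """MLEs of ``(π_1j, ρ_j)`` and the common odds ratio θ under H0.

    Initialised from the unconstrained fit (computed on the fly when not
    supplied): stratum means of ``π̂_1j`` and ``ρ̂_j``, and a geometric mean
    of the ``θ̂_j`` clipped away from boundary artifacts.
    """
    opts = opts or FitOptions()
    strata = stratum_groups(counts)
    J = counts.J
    if fit_u is None:
        fit_u = fit_unconstrained(counts, opts)

    pi1 = np.full(J, float(np.clip(fit_u.pi1.mean(), 0.01, 0.99)))
    rho = np.full(J, float(np.clip(fit_u.rho.mean(), 0.0, 0.95)))
    theta = float(np.exp(np.mean(np.log(np.clip(fit_u.theta, 1e-2, 1e2)))))

    m_tot = [g1.m_tot + g2.m_tot for g1, g2 in strata]
    ll = _constrained_total(strata, pi1, rho, theta)
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        theta_new, ll, _ = _update_theta(strata, pi1, rho, theta)
        delta = abs(theta_new - theta)
        theta = theta_new
        for j, groups in enumerate(strata):
            p1, r = float(pi1[j]), float(rho[j])
            if m_tot[j] == 0:
                r = 0.0
            I2, p2, dpi2 = _constrained_info_2x2(groups, p1, r, theta)
            g_pi1 = dl_dpi(groups[0], p1, r) + dl_dpi(groups[1], p2, r) * dpi2
            g_rho = dl_drho(groups, p1, p2, r)
            if m_tot[j] == 0:
                step = np.array([g_pi1 / I2[0, 0] if I2[0, 0] > 0 else 0.0, 0.0])
            else:
                try:
                    step = np.linalg.solve(I2, np.array([g_pi1, g_rho]))
                except np.linalg.LinAlgError:
                    step = np.array([0.0, 0.0])
            llj = constrained_stratum_loglik(groups, p1, r, theta)
            p1n, rn = _scoring_step_2d(groups, p1, r, theta, step, llj, I2,
                                       g_pi1, g_rho)
            delta = max(delta, abs(p1n - p1), abs(rn - r))
            pi1[j], rho[j] = p1n, rn
        ll_new = _constrained_total(strata, pi1, rho, theta)
        dll = abs(ll_new - ll)
        ll = ll_new
        if delta < opts.param_tol and dll < opts.tol:
            converged = True
            break

    if not converged:
        pi1, rho, theta, ll, converged = _numeric_constrained(
            strata, pi1, rho, theta
        )

    pi2 = np.array([pi2_from(p, theta) for p in pi1])
    lls = np.array([
        stratum_loglik(g, p1, p2_, r)
        for g, p1, p2_, r in zip(strata, pi1, pi2, rho)
    ])
    flags = []
    for j in range(J):
        if _boundary(pi1[j]) or _boundary(pi2[j]):
            flags.append(f"stratum {j + 1}: constrained pi at boundary")
        if m_tot[j] == 0:
            flags.append(f"stratum {j + 1}: rho unidentified (no bilateral subjects)")
    return MleFit(pi1, pi2, np.asarray(rho, dtype=float),
                  np.full(J, theta), theta, lls, float(lls.sum()),
                  converged, it, flags, counts.fingerprint())


def _numeric_constrained(strata, pi1, rho, theta):
    J = len(strata)

    def neg(x):
        p = x[:J]
        r = x[J:2 * J]
        th = math.exp(x[-1])
        return -sum(
            constrained_stratum_loglik(g, pj, rj, th)
            for g, pj, rj in zip(strata, p, r)
        )

    x0 = np.concatenate([pi1, rho, [math.log(theta)]])
    bounds = ([(_PLO, _PHI)] * J + [(_RLO, _RHI)] * J + [(-12, 12)])
    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
    x = res.x
    return (x[:J].copy(), x[J:2 * J].copy(), float(math.exp(x[-1])),
            -float(res.fun), bool(res.success))
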