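"""Large-sample tests of odds-ratio homogeneity across strata.

Under H0: θ_1 = … = θ_J, each statistic is asymptotically χ² with J − 1
degrees of freedom:

* likelihood ratio — twice the gap between the unconstrained and the
  homogeneity-constrained maximised log-likelihoods;
* score — quadratic form in the per-stratum θ-scores at the constrained MLE,
  scaled by the inverse expected information in the ``(θ_j, π_1j, ρ_j)``
  parameterisation (the nuisance components of the score vanish there);
* Wald — quadratic form in consecutive differences of the fitted log odds
  ratios, with delta-method covariance from the unconstrained expected
  information on the logit/log scale.

Expected (not observed) information is used throughout, assembled
analytically from the model's category probabilities and cross-checked
against numerically averaged Hessians in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import StratifiedCounts
from .likelihood import dl_dpi, stratum_groups, stratum_information
from .mle import FitOptions, MleFit, fit_constrained, fit_unconstrained

__all__ = [
    "TestResult",
    "lr_statistic",
    "score_statistic",
    "wald_statistic",
    "chi2_pvalue",
    "run_all",
]

_ZERO_TOL = 1e-9


@dataclass
class TestResult:
    T_LR: float
    T_SC: float
    T_W: float
    df: int
    p_LR: float
    p_SC: float
    p_W: float
    fit_unconstrained: MleFit
    fit_constrained: MleFit
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "T_LR": self.T_LR, "T_SC": self.T_SC, "T_W": self.T_W,
            "df": self.df,
            "p_LR": self.p_LR, "p_SC": self.p_SC, "p_W": self.p_W,
        }


def _check_fits(fit_u: MleFit, fit_c: MleFit) -> None:
    if fit_u.fingerprint and fit_c.fingerprint and \
            fit_u.fingerprint != fit_c.fingerprint:
        raise ValueError("fits were computed on different datasets")


def _clamp0(x: float, name: str) -> float:
    if x < -_ZERO_TOL:
        raise ValueError(f"{name} is negative ({x}); fits are inconsistent")
    return max(x, 0.0)


def lr_statistic(fit_u: MleFit, fit_c: MleFit) -> float:
    """T_LR = 2 Σ_j [l_j(unconstrained) − l_j(constrained)], clamped at 0."""
    _check_fits(fit_u, fit_c)
    return _clamp0(2.0 * (fit_u.total_loglik - fit_c.total_loglik), "T_LR")


def score_statistic(counts: StratifiedCounts, fit_c: MleFit) -> float:
    """Score statistic at the constrained MLE.

    Per stratum the score in ``α_j = (θ_j, π_1j, ρ_j)`` reduces to
    ``U_j = (∂l_j/∂θ_j, 0, 0)`` because the nuisance scores vanish at the
    constrained optimum; the statistic is
    ``Σ_j (∂l_j/∂θ_j)² [I_j⁻¹]_θθ`` with ``I_j`` the expected information
    obtained from the ``(π_1, π_2, ρ)`` information by the chain rule.
    """
    if not fit_c.constrained:
        raise ValueError("score_statistic needs the constrained fit")
    theta = fit_c.theta_common
    total = 0.0
    for j, groups in enumerate(stratum_groups(counts)):
        p1, r = float(fit_c.pi1[j]), float(fit_c.rho[j])
        D = p1 + theta * (1 - p1)
        p2 = p1 / D
        dpi2_dtheta = -p1 * (1 - p1) / (D * D)
        dpi2_dpi1 = theta / (D * D)
        u_theta = dl_dpi(groups[1], p2, r) * dpi2_dtheta
        I3 = stratum_information(groups, p1, p2, r)
        # Jacobian of beta=(pi1,pi2,rho) wrt alpha=(theta,pi1,rho)
        Jac = np.array([
            [0.0, 1.0, 0.0],
            [dpi2_dtheta, dpi2_dpi1, 0.0],
            [0.0, 0.0, 1.0],
        ])
        I_alpha = Jac.T @ I3 @ Jac
        try:
            inv = np.linalg.inv(I_alpha)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular information in stratum {j + 1}; using pseudo-inverse"
            )
            inv = np.linalg.pinv(I_alpha)
        total += u_theta * u_theta * inv[0, 0]
    return _clamp0(total, "T_SC")


def _contrast_matrix(J: int) -> np.ndarray:
    """(J−1)×3J contrast whose rows encode log θ_j − log θ_{j+1} on the
    (logit π_1, logit π_2, log ρ) scale: pattern (1, −1, 0, −1, 1, 0)."""
    C = np.zeros((J - 1, 3 * J))
    for r in range(J - 1):
        C[r, 3 * r:3 * r + 3] = (1, -1, 0)
        C[r, 3 * r + 3:3 * r + 6] = (-1, 1, 0)
    return C


def wald_statistic(counts: StratifiedCounts, fit_u: MleFit) -> tuple[float, list[str]]:
    """Wald statistic from the unconstrained fit; returns (T_W, warnings).

    The covariance of ``δ̂ = (logit π̂_1j, logit π̂_2j, log ρ̂_j)_j`` is
    ``Δ_g I_β⁻¹ Δ_gᵀ`` with ``I_β`` the block-diagonal expected information
    of the observed design (sample sizes absorbed, so everything is on the
    data scale). Boundary-flagged fits yield a statistic that is reported
    but unstable.
    """
    if fit_u.constrained:
        raise ValueError("wald_statistic needs the unconstrained fit")
    J = counts.J
    if J < 2:
        raise ValueError("Wald test needs at least two strata")
    warn: list[str] = []
    if fit_u.boundary_flags:
        warn.append(
            "unconstrained fit has boundary-attracted estimates; "
            "the Wald statistic is unstable: " + "; ".join(fit_u.boundary_flags)
        )
        warnings.warn(warn[-1])
    strata = stratum_groups(counts)
    delta = np.empty(3 * J)
    cov = np.zeros((3 * J, 3 * J))
    for j in range(J):
        p1, p2, r = float(fit_u.pi1[j]), float(fit_u.pi2[j]), float(fit_u.rho[j])
        delta[3 * j:3 * j + 3] = (
            np.log(p1 / (1 - p1)), np.log(p2 / (1 - p2)),
            np.log(r) if r > 0 else np.log(np.finfo(float).tiny),
        )
        I3 = stratum_information(strata[j], p1, p2, r)
        g = np.diag([1 / (p1 * (1 - p1)), 1 / (p2 * (1 - p2)),
                     1 / r if r > 0 else 0.0])
        try:
            I3_inv = np.linalg.inv(I3)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular information block in stratum {j + 1} "
                f"({counts.labels[j]!r})"
            ) from None
        cov[3 * j:3 * j + 3, 3 * j:3 * j + 3] = g @ I3_inv @ g.T
    C = _contrast_matrix(J)
    cd = C @ delta
    mid = C @ cov @ C.T
    try:
        sol = np.linalg.solve(mid, cd)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular contrast covariance; a stratum's log-odds-ratio "
            "variance is degenerate"
        ) from None
    return _clamp0(float(cd @ sol), "T_W"), warn


def chi2_pvalue(T: float, df: int) -> float:
    """Upper-tail χ²_df probability of the observed statistic."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1 (J >= 2 strata)")
    if T < 0:
        raise ValueError("test statistic must be non-negative")
    return float(stats.chi2.sf(T, df))


def run_all(counts: StratifiedCounts, opts: FitOptions | None = None) -> TestResult:
    """Fit both models and compute all three homogeneity tests."""
    if counts.J < 2:
        raise ValueError(
            "homogeneity testing needs J >= 2 strata "
            f"(got J = {counts.J})"
        )
    fit_u = fit_unconstrained(counts, opts)
    fit_c = fit_constrained(counts, opts, fit_u=fit_u)
    df = counts.J - 1
    t_lr = lr_statistic(fit_u, fit_c)
    t_sc = score_statistic(counts, fit_c)
    t_w, warn = wald_statistic(counts, fit_u)
    return TestResult(
        T_LR=t_lr, T_SC=t_sc, T_W=t_w, df=df,
        p_LR=chi2_pvalue(t_lr, df),
        p_SC=chi2_pvalue(t_sc, df),
        p_W=chi2_pvalue(t_w, df),
        fit_unconstrained=fit_u, fit_constrained=fit_c,
        warnings=list(dict.fromkeys(
            warn + fit_u.boundary_flags + fit_c.boundary_flags
        )),
    )
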