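"""Donner ρ-model likelihood for combined bilateral and unilateral data.

Model
-----
Within stratum ``j``, each organ of a subject in group ``i`` responds with
probability ``π_ij``; the two organs of one bilateral subject are exchangeable
with intraclass correlation ``ρ_j``, shared by both groups of the stratum.
The number of responding organs of a bilateral subject is then trinomial with

    p0 = (1 − π)(ρπ − π + 1)
    p1 = 2π(1 − π)(1 − ρ)
    p2 = π(ρ + π − ρπ)

while unilateral subjects are plain Bernoulli(π). The stratum log-likelihood
(multinomial constants dropped throughout, so only differences of
log-likelihoods are meaningful) is

    l_j = Σ_i [ n0 log(1−π_ij) + n1 log π_ij
                + m0 log p0 + m1 log p1 + m2 log p2 ].

All first and second derivatives used by the fitting algorithms are analytic
and are cross-checked against finite differences in the test suite, and the
profile stationarity equation in ``π`` (at fixed ``ρ``) is a cubic solved in
closed form by the trigonometric method (:func:`pi_closed_form`).

Internally a stratum is handled as ``Group`` tuples of plain ints/floats:
the fitting loops run thousands of times per Monte-Carlo study, and scalar
arithmetic keeps them cheap.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

__all__ = [
    "EPS",
    "Group",
    "CategoryProbs",
    "category_probs",
    "pi2_from",
    "stratum_groups",
    "group_loglik",
    "stratum_loglik",
    "constrained_stratum_loglik",
    "dl_dpi",
    "d2l_dpi2",
    "dl_drho",
    "pi_closed_form",
    "rho_information",
    "stratum_information",
]

#: probabilities are evaluated inside [EPS, 1-EPS]; a clamp that binds at an
#: optimum is reported as a boundary solution by the fitting layer.
EPS = 1e-10


class Group(NamedTuple):
    """Counts of one group within one stratum."""

    n0: int
    n1: int
    m0: int
    m1: int
    m2: int

    @property
    def n_tot(self) -> int:
        return self.n0 + self.n1

    @property
    def m_tot(self) -> int:
        return self.m0 + self.m1 + self.m2


def stratum_groups(counts) -> list[tuple[Group, Group]]:
    """Decompose a :class:`~bilat_or.data_model.StratifiedCounts` into
    per-stratum ``(treatment, control)`` :class:`Group` pairs."""
    n, m = counts.n, counts.m
    return [
        tuple(
            Group(
                int(n[0, i, j]), int(n[1, i, j]),
                int(m[0, i, j]), int(m[1, i, j]), int(m[2, i, j]),
            )
            for i in (0, 1)
        )
        for j in range(counts.J)
    ]


class CategoryProbs(NamedTuple):
    p0: float
    p1: float
    p2: float


def category_probs(pi, rho):
    """Trinomial probabilities of 0/1/2 responding organs for one subject.

    Accepts scalars or numpy arrays; components sum to one and are
    non-negative for ``π ∈ [0, 1]`` and ``ρ ∈ [0, 1]``.
    """
    pi_a, rho_a = np.asarray(pi, dtype=float), np.asarray(rho, dtype=float)
    if np.any((pi_a < 0) | (pi_a > 1)):
        raise ValueError("pi must lie in [0, 1]")
    if np.any((rho_a < 0) | (rho_a > 1)):
        raise ValueError("rho must lie in [0, 1]")
    p0 = (1 - pi_a) * (rho_a * pi_a - pi_a + 1)
    p1 = 2 * pi_a * (1 - pi_a) * (1 - rho_a)
    p2 = pi_a * (rho_a + pi_a - rho_a * pi_a)
    if p0.ndim == 0:
        return CategoryProbs(float(p0), float(p1), float(p2))
    return CategoryProbs(p0, p1, p2)


def pi2_from(pi1: float, theta: float) -> float:
    """Control-group probability implied by the odds-ratio constraint,
    ``π_2 = π_1 / (π_1(1 − θ) + θ)``."""
    return pi1 / (pi1 * (1 - theta) + theta)


def _clip(x: float) -> float:
    return EPS if x < EPS else (1 - EPS if x > 1 - EPS else x)


def group_loglik(g: Group, pi: float, rho: float) -> float:
    """Log-likelihood contribution of one group (constants dropped)."""
    pi = _clip(pi)
    rho = min(max(rho, 0.0), 1 - EPS)
    p0 = (1 - pi) * (rho * pi - pi + 1)
    p1 = 2 * pi * (1 - pi) * (1 - rho)
    p2 = pi * (rho + pi - rho * pi)
    ll = 0.0
    if g.n0:
        ll += g.n0 * math.log(1 - pi)
    if g.n1:
        ll += g.n1 * math.log(pi)
    for cnt, p, name in ((g.m0, p0, "p0"), (g.m1, p1, "p1"), (g.m2, p2, "p2")):
        if cnt:
            if p <= 0:
                raise ValueError(
                    f"zero probability {name} with positive count {cnt} "
                    f"(pi={pi}, rho={rho})"
                )
            ll += cnt * math.log(p)
    return ll


def stratum_loglik(groups: tuple[Group, Group], pi1: float, pi2: float,
                   rho: float) -> float:
    """``l_j`` for one stratum at group probabilities ``(π_1, π_2)`` and
    shared correlation ``ρ``."""
    return group_loglik(groups[0], pi1, rho) + group_loglik(groups[1], pi2, rho)


def constrained_stratum_loglik(groups: tuple[Group, Group], pi1: float,
                               rho: float, theta: float) -> float:
    """``l_{j|θ}``: the stratum log-likelihood with the control probability
    eliminated through the odds-ratio constraint.

    Implemented by substituting ``π_2(π_1, θ)`` into :func:`stratum_loglik`,
    which makes the identity with the unconstrained likelihood exact by
    construction.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    return stratum_loglik(groups, pi1, pi2_from(pi1, theta), rho)


# ---------------------------------------------------------------------------
# Analytic derivatives
# ---------------------------------------------------------------------------

def dl_dpi(g: Group, pi: float, rho: float) -> float:
    """∂l/∂π for one group: score of the event probability."""
    if g.n_tot + g.m_tot == 0:
        return 0.0
    out = 0.0
    if g.n0:
        out += g.n0 / (pi - 1)
    if g.n1:
        out += g.n1 / pi
    if g.m0:
        # d log p0 / dpi with p0 = (1-pi)(rho*pi - pi + 1)
        out += g.m0 * (2 * pi - 2 * rho * pi + rho - 2) / (
            (1 - pi) * (rho * pi - pi + 1)
        )
    if g.m1:
        out += g.m1 * (1 - 2 * pi) / (pi * (1 - pi))
    if g.m2:
        out += g.m2 * (2 * pi - 2 * rho * pi + rho) / (
            pi * (pi - rho * pi + rho)
        )
    return out


def d2l_dpi2(g: Group, pi: float, rho: float) -> float:
    """∂²l/∂π² for one group (observed curvature)."""
    out = 0.0
    if g.n0:
        out -= g.n0 / (1 - pi) ** 2
    if g.n1:
        out -= g.n1 / pi ** 2
    s = 1 - rho
    p0 = (1 - pi) * (rho * pi - pi + 1)
    p1 = 2 * pi * (1 - pi) * s
    p2 = pi * (rho + pi - rho * pi)
    d0, d1, d2 = 2 * pi * s + rho - 2, 2 * s * (1 - 2 * pi), 2 * pi * s + rho
    for cnt, p, d, dd in ((g.m0, p0, d0, 2 * s), (g.m1, p1, d1, -4 * s),
                          (g.m2, p2, d2, 2 * s)):
        if cnt:
            out += cnt * (dd * p - d * d) / (p * p)
    return out


def dl_drho(groups: tuple[Group, Group], pi1: float, pi2: float,
            rho: float) -> float:
    """∂l_j/∂ρ for one stratum (sums the two groups; ρ is shared)."""
    out = 0.0
    for g, pi in zip(groups, (pi1, pi2)):
        if g.m0:
            out += g.m0 * pi / (rho * pi - pi + 1)
        if g.m1:
            out -= g.m1 / (1 - rho)
        if g.m2:
            out += g.m2 * (1 - pi) / (pi - rho * pi + rho)
    return out


# ---------------------------------------------------------------------------
# Closed-form profile root in pi
# ---------------------------------------------------------------------------

def _cubic_coeffs(g: Group, rho: float) -> tuple[float, float, float, float]:
    """Coefficients (a3, a2, a1, a0) of the stationarity cubic in π obtained
    by clearing denominators in ∂l/∂π = 0 at fixed ρ."""
    n0, n1, m0, m1, m2 = g
    m_tot = m0 + m1 + m2
    n_tot = n0 + n1
    s = rho - 1
    a3 = s * s * (2 * m_tot + n_tot)
    a2 = -s * (rho * (3 * m_tot + n_tot + n1)
               - (2 * m0 + 3 * m1 + 4 * m2 + n0 + 2 * n1))
    a1 = (rho * rho * (m_tot + n1)
          - rho * (2 * m0 + 4 * m1 + 4 * m2 + n0 + 3 * n1)
          + (m1 + 2 * m2 + n1))
    a0 = rho * (m1 + m2 + n1)
    return a3, a2, a1, a0


class CubicWorkspace(NamedTuple):
    """Intermediates of the trigonometric three-real-roots solution."""

    b: float   # -a2 / (3 a3): centre of the depressed cubic
    c: float   # sqrt(-P/3) scale of the root spread
    d: float   # one third of the arccosine phase, in [0, pi/3]


def pi_closed_form(g: Group, rho: float, return_workspace: bool = False):
    """Maximiser of one group's log-likelihood over π at fixed ρ.

    Solves the cubic stationarity equation in closed form and returns the
    root in (0, 1) (verified as the likelihood maximiser). When the
    likelihood is monotone on (0, 1) — e.g. a group with no responding
    organ — the clamped boundary argmax is returned.
    """
    if g.n_tot + g.m_tot == 0:
        raise ValueError("cannot estimate pi for a group with no observations")
    if rho >= 1:
        raise ValueError("rho must be below 1 for the closed-form root")
    if g.m_tot == 0:
        return g.n1 / g.n_tot  # binomial MLE; the cubic degenerates
    if rho == 0:
        # independence: organs pool into one binomial with 2m + n trials
        return _clip((g.m1 + 2 * g.m2 + g.n1) / (2 * g.m_tot + g.n_tot))

    a3, a2, a1, a0 = _cubic_coeffs(g, rho)
    # depressed cubic t^3 + P t + Q, pi = t - a2/(3 a3)
    p_ = a2 / a3
    q_ = a1 / a3
    r_ = a0 / a3
    P = q_ - p_ * p_ / 3
    Q = 2 * p_ ** 3 / 27 - p_ * q_ / 3 + r_
    shift = -p_ / 3
    candidates: list[float] = []
    if P < 0:
        scale = 2 * math.sqrt(-P / 3)
        arg = 3 * Q / (P * scale)
        if arg > 1:
            if arg > 1 + 1e-9:
                raise ValueError("arccos argument outside [-1, 1]")
            arg = 1.0
        elif arg < -1:
            if arg < -1 - 1e-9:
                raise ValueError("arccos argument outside [-1, 1]")
            arg = -1.0
        phase = math.acos(arg) / 3
        ws = CubicWorkspace(shift, scale, phase)
        for k in range(3):
            candidates.append(
                shift + scale * math.cos(phase - 2 * math.pi * k / 3)
            )
    else:
        # single real root (does not arise for count data with mixed
        # categories, but handled for completeness)
        ws = CubicWorkspace(shift, 0.0, 0.0)
        roots = np.roots([a3, a2, a1, a0])
        candidates = [float(r.real) for r in roots if abs(r.imag) < 1e-9]

    interior = [x for x in candidates if EPS < x < 1 - EPS]
    pool = interior if interior else [EPS, 1 - EPS]
    best = max(pool, key=lambda x: group_loglik(g, x, rho))
    if not interior:
        # monotone likelihood: also report against clamped candidates
        best = max([EPS, 1 - EPS], key=lambda x: group_loglik(g, x, rho))
    if return_workspace:
        return best, ws
    return best


# ---------------------------------------------------------------------------
# Expected information
# ---------------------------------------------------------------------------

def _dp_dpi(pi: float, rho: float) -> tuple[float, float, float]:
    s = 1 - rho
    return (2 * pi * s + rho - 2, 2 * s * (1 - 2 * pi), 2 * pi * s + rho)


def _dp_drho(pi: float) -> tuple[float, float, float]:
    w = pi * (1 - pi)
    return (w, -2 * w, w)


def rho_information(groups: tuple[Group, Group], pi1: float, pi2: float,
                    rho: float) -> float:
    """Expected information for ρ in one stratum, ``-E[∂²l_j/∂ρ²]``.

    Simplifies to ``Σ_i m_{+i} π_i(1−π_i) [π_i/p0-factor + 2/(1−ρ) +
    (1−π_i)/p2-factor]``; it is linear in the bilateral group sizes and zero
    when the stratum has no bilateral subjects (ρ is then unidentified).
    """
    out = 0.0
    for g, pi in zip(groups, (pi1, pi2)):
        if g.m_tot == 0:
            continue
        u = rho * pi - pi + 1
        v = pi - rho * pi + rho
        out += g.m_tot * pi * (1 - pi) * (pi / u + 2 / (1 - rho) + (1 - pi) / v)
    return out


def group_information(g: Group, pi: float, rho: float) -> np.ndarray:
    """2×2 expected information of one group's data in ``(π, ρ)``.

    Multinomial part ``m_+ Σ_t (∂p_t/∂a)(∂p_t/∂b)/p_t`` plus the binomial
    ``n_+/(π(1−π))`` in the ππ entry.
    """
    I = np.zeros((2, 2))
    if g.n_tot:
        I[0, 0] += g.n_tot / (pi * (1 - pi))
    if g.m_tot:
        p = category_probs(pi, rho)
        dpi = _dp_dpi(pi, rho)
        drho = _dp_drho(pi)
        for pt, da, db in zip(p, dpi, drho):
            if pt <= 0:
                continue
            I[0, 0] += g.m_tot * da * da / pt
            I[0, 1] += g.m_tot * da * db / pt
            I[1, 1] += g.m_tot * db * db / pt
        I[1, 0] = I[0, 1]
    return I


def stratum_information(groups: tuple[Group, Group], pi1: float, pi2: float,
                        rho: float) -> np.ndarray:
    """3×3 expected information of one stratum in ``(π_1, π_2, ρ)``.

    The π₁–π₂ cross term is zero (the groups are independent) and the ρ row
    collects both groups' bilateral contributions.
    """
    I1 = group_information(groups[0], pi1, rho)
    I2 = group_information(groups[1], pi2, rho)
    I = np.zeros((3, 3))
    I[0, 0] = I1[0, 0]
    I[1, 1] = I2[0, 0]
    I[2, 2] = I1[1, 1] + I2[1, 1]
    I[0, 2] = I[2, 0] = I1[0, 1]
    I[1, 2] = I[2, 1] = I2[0, 1]
    return I
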