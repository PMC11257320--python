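"""Monte-Carlo size and power studies for the homogeneity tests.

Data are generated under the model itself: per stratum and group, unilateral
responders are binomial and bilateral category counts are trinomial with the
Donner ρ-model probabilities; the control probability is implied by the
stratum odds ratio, ``π_2j = π_1j/(π_1j(1−θ_j)+θ_j)``.

Each replicate draws its own generator from a child seed spawned off the
master seed, so results are reproducible and independent of any replicate
scheduling. Replicates whose fits fail even after the numerical fallback are
excluded from the denominator and counted; an alarm is raised when exclusions
exceed 0.1 % of the replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import StratifiedCounts
from .homogeneity import run_all
from .likelihood import category_probs, pi2_from
from .mle import FitOptions

__all__ = [
    "SimSpec",
    "SimResult",
    "THETA_PATTERNS",
    "sample_counts",
    "empirical_size",
    "empirical_power",
    "random_settings_study",
]

#: heterogeneous odds-ratio patterns used in the power studies, by strata count
THETA_PATTERNS = {
    2: {
        "Ha1": (1.0, 1.5), "Ha2": (1.0, 2.0),
        "Ha3": (1.0, 3.0), "Ha4": (1.0, 4.0),
    },
    4: {
        "Ha1": (1.0, 1.2, 1.5, 2.0), "Ha2": (1.0, 2.0, 1.0, 2.0),
        "Ha3": (2.0, 4.0, 2.0, 4.0), "Ha4": (1.0, 2.0, 3.0, 4.0),
    },
    8: {
        "Ha1": (1.0, 1.2, 1.5, 2.0, 1.0, 1.2, 1.5, 2.0),
        "Ha2": (1.0, 2.0) * 4,
        "Ha3": (2.0, 4.0) * 4,
        "Ha4": (1.0, 2.0, 3.0, 4.0) * 2,
    },
}


@dataclass(frozen=True)
class SimSpec:
    """One simulation scenario.

    ``m`` and ``n`` are the bilateral and unilateral group sizes
    ``m_{+ij} = n_{+ij}`` (scalars broadcast to every stratum and group;
    per-stratum arrays are accepted). ``theta`` is scalar under H0 or a
    length-J vector under the alternative.
    """

    J: int
    m: int | tuple
    n: int | tuple
    pi1: float | tuple
    rho: float | tuple
    theta: float | tuple
    reps: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.J < 2:
            raise ValueError("J >= 2 strata are required")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        for p1, th in zip(self._vec("pi1"), self._vec("theta")):
            p2 = pi2_from(p1, th)
            if not 0 <= p2 <= 1:
                raise ValueError(f"implied pi2={p2} outside [0, 1]")

    def _vec(self, name: str) -> np.ndarray:
        return np.broadcast_to(np.asarray(getattr(self, name), dtype=float),
                               (self.J,))

    @property
    def theta_vec(self) -> np.ndarray:
        return self._vec("theta")

    @property
    def is_null(self) -> bool:
        th = self.theta_vec
        return bool(np.all(th == th[0]))


@dataclass
class SimResult:
    """Empirical rejection rates (percent) with Monte-Carlo standard errors."""

    rate: dict = field(default_factory=dict)       # test name -> percent
    mc_se: dict = field(default_factory=dict)      # test name -> percent
    reps_used: int = 0
    non_convergence_count: int = 0
    hypothesis: str = "H0"
    spec: SimSpec | None = None

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "rate_percent": self.rate,
            "mc_se_percent": self.mc_se,
            "reps_used": self.reps_used,
            "non_convergence_count": self.non_convergence_count,
        }


def sample_counts(spec: SimSpec, rng: np.random.Generator) -> StratifiedCounts:
    """Draw one replicate dataset under the scenario's parameters."""
    J = spec.J
    pi1 = spec._vec("pi1")
    rho = spec._vec("rho")
    theta = spec.theta_vec
    m = np.broadcast_to(np.asarray(spec.m, dtype=np.int64), (J,))
    nsz = np.broadcast_to(np.asarray(spec.n, dtype=np.int64), (J,))
    n = np.zeros((2, 2, J), dtype=np.int64)
    mm = np.zeros((3, 2, J), dtype=np.int64)
    for j in range(J):
        for i, pi in enumerate((pi1[j], pi2_from(pi1[j], theta[j]))):
            if nsz[j]:
                k = rng.binomial(nsz[j], pi)
                n[1, i, j] = k
                n[0, i, j] = nsz[j] - k
            if m[j]:
                mm[:, i, j] = rng.multinomial(m[j], category_probs(pi, rho[j]))
    labels = tuple(f"stratum {j + 1}" for j in range(J))
    return StratifiedCounts(n, mm, labels)


_TESTS = ("LR", "SC", "W")


def _run_study(spec: SimSpec, opts: FitOptions | None = None) -> SimResult:
    crit = stats.chi2.ppf(1 - spec.alpha, spec.J - 1)
    rej = dict.fromkeys(_TESTS, 0)
    used = 0
    failed = 0
    children = np.random.SeedSequence(spec.seed).spawn(spec.reps)
    opts = opts or FitOptions()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ss in children:
            counts = sample_counts(spec, np.random.default_rng(ss))
            try:
                res = run_all(counts, opts)
            except Exception:
                failed += 1
                continue
            used += 1
            for name, T in (("LR", res.T_LR), ("SC", res.T_SC), ("W", res.T_W)):
                if T > crit:
                    rej[name] += 1
    if used == 0:
        raise RuntimeError("every replicate failed to fit")
    if failed > 0.001 * spec.reps:
        warnings.warn(
            f"{failed} of {spec.reps} replicates failed to converge "
            "(exceeds 0.1%); results may be biased"
        )
    out = SimResult(reps_used=used, non_convergence_count=failed, spec=spec,
                    hypothesis="H0" if spec.is_null else "Ha")
    for name in _TESTS:
        p = rej[name] / used
        out.rate[name] = 100 * p
        out.mc_se[name] = 100 * np.sqrt(p * (1 - p) / used)
    return out


def empirical_size(spec: SimSpec, opts: FitOptions | None = None) -> SimResult:
    """Empirical type-I error (percent rejections under a common θ)."""
    if not spec.is_null:
        raise ValueError("empirical_size requires all theta_j equal; "
                         "use empirical_power for alternatives")
    return _run_study(spec, opts)


def empirical_power(spec: SimSpec, opts: FitOptions | None = None) -> SimResult:
    """Empirical power (percent rejections under a heterogeneous θ pattern)."""
    if spec.is_null:
        warnings.warn(
            "theta is constant across strata: this is a size run, not power"
        )
    return _run_study(spec, opts)


def random_settings_study(
    J: int,
    size: int,
    n_settings: int = 1000,
    reps_per_setting: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[SimResult]:
    """Size study over random null settings, for box-plot summaries.

    Settings are drawn uniformly from ``π_1 ∈ (0, 1)``, ``ρ ∈ (0, 1)`` and a
    common ``θ ∈ [1, 4]`` (the implied ``π_2`` then always lies in (0, 1)),
    with ``m = n = size`` per group, and an H0 study of ``reps_per_setting``
    replicates is run for each.
    """
    if n_settings < 1:
        raise ValueError("n_settings must be >= 1")
    rng = np.random.default_rng(seed)
    results = []
    for k in range(n_settings):
        pi1 = float(rng.uniform(0.01, 0.99))
        rho = float(rng.uniform(0.0, 1.0))
        theta = float(rng.uniform(1.0, 4.0))
        spec = SimSpec(J=J, m=size, n=size, pi1=pi1, rho=rho, theta=theta,
                       reps=reps_per_setting, alpha=alpha,
                       seed=int(rng.integers(0, 2**31 - 1)))
        results.append(empirical_size(spec))
    return results
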