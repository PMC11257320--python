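"""Plain-text and JSON rendering of fits, tests and simulation results."""

from __future__ import annotations

import json

from .homogeneity import TestResult
from .simulation import SimResult


def _fmt_row(cells, widths):
    return "  ".join(str(c).ljust(w) for c, w in zip(cells, widths))


def mle_table(result: TestResult, labels) -> str:
    """Aligned table of constrained and unconstrained MLEs per stratum."""
    fu, fc = result.fit_unconstrained, result.fit_constrained
    header = ["stratum", "pi1~", "pi2~", "rho~", "theta~",
              "pi1^", "pi2^", "rho^", "theta^"]
    rows = [header]
    for j, lab in enumerate(labels):
        rows.append([
            lab,
            f"{fc.pi1[j]:.4f}", f"{fc.pi2[j]:.4f}", f"{fc.rho[j]:.4f}",
            f"{fc.theta_common:.4f}",
            f"{fu.pi1[j]:.4f}", f"{fu.pi2[j]:.4f}", f"{fu.rho[j]:.4f}",
            f"{fu.theta[j]:.4f}",
        ])
    widths = [max(len(r[k]) for r in rows) for k in range(len(header))]
    lines = [_fmt_row(r, widths) for r in rows]
    lines.insert(1, "-" * len(lines[0]))
    return "\n".join(lines)


def test_table(result: TestResult) -> str:
    header = ["", "T_LR", "T_SC", "T_W"]
    rows = [
        header,
        ["statistic", f"{result.T_LR:.4f}", f"{result.T_SC:.4f}",
         f"{result.T_W:.4f}"],
        ["p-value", f"{result.p_LR:.4f}", f"{result.p_SC:.4f}",
         f"{result.p_W:.4f}"],
    ]
    widths = [max(len(r[k]) for r in rows) for k in range(len(header))]
    lines = [_fmt_row(r, widths) for r in rows]
    lines.insert(1, "-" * len(lines[0]))
    lines.append(f"df = {result.df}")
    return "\n".join(lines)


def full_report(result: TestResult, labels) -> str:
    parts = [
        "Maximum likelihood estimates (constrained ~ / unconstrained ^):",
        mle_table(result, labels),
        "",
        "Homogeneity tests of the odds ratio across strata:",
        test_table(result),
    ]
    if result.warnings:
        parts += ["", "WARNINGS:"] + [f"  * {w}" for w in result.warnings]
    return "\n".join(parts)


def result_json(result: TestResult, labels) -> str:
    fu, fc = result.fit_unconstrained, result.fit_constrained
    return json.dumps(
        {
            "tests": result.to_dict(),
            "constrained": {
                "pi1": fc.pi1.tolist(), "pi2": fc.pi2.tolist(),
                "rho": fc.rho.tolist(), "theta_common": fc.theta_common,
                "loglik": fc.total_loglik, "converged": fc.converged,
            },
            "unconstrained": {
                "pi1": fu.pi1.tolist(), "pi2": fu.pi2.tolist(),
                "rho": fu.rho.tolist(), "theta": fu.theta.tolist(),
                "loglik": fu.total_loglik, "converged": fu.converged,
                "boundary_flags": fu.boundary_flags,
            },
            "labels": list(labels),
            "warnings": result.warnings,
        },
        indent=2,
    )


def sim_table(results: list[SimResult], names=None) -> str:
    header = ["scenario", "hyp", "reps", "LR %", "SC %", "W %",
              "LR se", "SC se", "W se", "excluded"]
    rows = [header]
    for k, r in enumerate(results):
        rows.append([
            names[k] if names else str(k + 1), r.hypothesis,
            str(r.reps_used),
            *(f"{r.rate[t]:.2f}" for t in ("LR", "SC", "W")),
            *(f"{r.mc_se[t]:.2f}" for t in ("LR", "SC", "W")),
            str(r.non_convergence_count),
        ])
    widths = [max(len(r[k]) for r in rows) for k in range(len(header))]
    lines = [_fmt_row(r, widths) for r in rows]
    lines.insert(1, "-" * len(lines[0]))
    return "\n".join(lines)
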