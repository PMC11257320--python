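"""Stratified count tables for combined bilateral and unilateral binary data.

A study enrols subjects in ``J`` strata (age bands, sex, ...). Within each
stratum subjects are randomised to a treatment group (``i = 1``) or a control
group (``i = 2``). A subject contributes either a *bilateral* record — a pair
of correlated binary responses, one per paired organ (both eyes, both ears) —
or a *unilateral* record, a single binary response. The data are therefore
fully summarised per stratum and group by

* ``n[t, i-1, j-1]`` — unilateral subjects with ``t`` (0 or 1) responding
  organs, and
* ``m[t, i-1, j-1]`` — bilateral subjects with ``t`` (0, 1 or 2) responding
  organs.

Purely bilateral (all ``n`` zero) and purely unilateral (all ``m`` zero)
designs are special cases and need no sentinel values.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StratifiedCounts",
    "validate",
    "read_counts",
    "write_counts",
    "fixture",
    "FIXTURE_NAMES",
]

GROUP_LABELS = {"treatment": 1, "control": 2}
DESIGN_LABELS = ("unilateral", "bilateral")


class ValidationError(ValueError):
    """A count table violates a structural requirement."""


@dataclass(frozen=True)
class StratifiedCounts:
    """Aggregated counts for a stratified bilateral + unilateral design.

    Attributes
    ----------
    n : ndarray, shape (2, 2, J)
        Unilateral counts ``n[t, i-1, j-1]`` for ``t`` in {0, 1}.
    m : ndarray, shape (3, 2, J)
        Bilateral counts ``m[t, i-1, j-1]`` for ``t`` in {0, 1, 2}.
    labels : tuple of str
        Stratum names, length ``J``.
    """

    n: np.ndarray
    m: np.ndarray
    labels: tuple[str, ...] = field(default=())

    @property
    def J(self) -> int:
        return self.n.shape[2]

    # per-group margins n_{+ij}, m_{+ij}: shape (2, J)
    @property
    def n_group(self) -> np.ndarray:
        return self.n.sum(axis=0)

    @property
    def m_group(self) -> np.ndarray:
        return self.m.sum(axis=0)

    # per-stratum totals N_j, M_j
    @property
    def N(self) -> np.ndarray:
        return self.n.sum(axis=(0, 1))

    @property
    def M(self) -> np.ndarray:
        return self.m.sum(axis=(0, 1))

    def stratum(self, j: int) -> "StratifiedCounts":
        """Single-stratum view (1-based ``j``), preserving the label."""
        sl = slice(j - 1, j)
        return StratifiedCounts(
            self.n[:, :, sl], self.m[:, :, sl], (self.labels[j - 1],)
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns stratum, group, design, responses, count."""
        rows = []
        for j in range(self.J):
            for gname, i in GROUP_LABELS.items():
                for t in range(2):
                    rows.append((self.labels[j], gname, "unilateral", t,
                                 int(self.n[t, i - 1, j])))
                for t in range(3):
                    rows.append((self.labels[j], gname, "bilateral", t,
                                 int(self.m[t, i - 1, j])))
        return pd.DataFrame(
            rows, columns=["stratum", "group", "design", "responses", "count"]
        )

    def to_json(self) -> str:
        margins = {
            "N": self.N.tolist(),
            "M": self.M.tolist(),
            "n_group": self.n_group.tolist(),
            "m_group": self.m_group.tolist(),
        }
        return json.dumps(
            {
                "labels": list(self.labels),
                "n": self.n.tolist(),
                "m": self.m.tolist(),
                "margins": margins,
            },
            indent=2,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StratifiedCounts):
            return NotImplemented
        return (
            np.array_equal(self.n, other.n)
            and np.array_equal(self.m, other.m)
            and self.labels == other.labels
        )

    def fingerprint(self) -> str:
        return f"J={self.J};n={self.n.tolist()};m={self.m.tolist()}"


def _as_count_array(a, shape, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.shape != shape:
        raise ValidationError(f"{name} must have shape {shape}, got {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=0, rtol=0):
            raise ValidationError(f"{name} contains non-integer counts")
        arr = rounded.astype(np.int64)
    else:
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        t, i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"negative count {name}[t={t}, group={i + 1}, stratum={j + 1}]"
        )
    return arr


def validate(counts: StratifiedCounts) -> StratifiedCounts:
    """Check structural invariants and return a canonicalised copy.

    Raises
    ------
    ValidationError
        On negative or non-integer counts, or when a group has no subjects
        at all in some stratum.
    """
    if counts.n.ndim != 3 or counts.m.ndim != 3:
        raise ValidationError("count arrays must be 3-dimensional (t, group, stratum)")
    J = counts.n.shape[2]
    if J < 1:
        raise ValidationError("at least one stratum is required")
    n = _as_count_array(counts.n, (2, 2, J), "n")
    m = _as_count_array(counts.m, (3, 2, J), "m")
    labels = tuple(counts.labels) if counts.labels else tuple(
        f"stratum {j + 1}" for j in range(J)
    )
    if len(labels) != J:
        raise ValidationError(f"expected {J} stratum labels, got {len(labels)}")
    out = StratifiedCounts(n, m, labels)
    group_tot = out.n_group + out.m_group  # (2, J)
    if (group_tot < 1).any():
        i, j = np.argwhere(group_tot < 1)[0]
        raise ValidationError(
            f"empty group: no subjects in group {i + 1} of stratum {labels[j]!r}"
        )
    if J < 2:
        import warnings

        warnings.warn(
            "only one stratum: homogeneity tests require J >= 2", stacklevel=2
        )
    return out


def build_counts(
    strata: Sequence[dict],
    labels: Sequence[str] | None = None,
) -> StratifiedCounts:
    """Assemble a :class:`StratifiedCounts` from per-stratum dictionaries.

    Each element of ``strata`` maps group name (``"treatment"``/``"control"``)
    to a pair ``(bilateral, unilateral)`` of count tuples ``(m0, m1, m2)``
    and ``(n0, n1)``.
    """
    J = len(strata)
    n = np.zeros((2, 2, J), dtype=np.int64)
    m = np.zeros((3, 2, J), dtype=np.int64)
    for j, stratum in enumerate(strata):
        for gname, (bi, uni) in stratum.items():
            i = GROUP_LABELS[gname] - 1
            m[:, i, j] = bi
            n[:, i, j] = uni
    lab = tuple(labels) if labels is not None else ()
    return validate(StratifiedCounts(n, m, lab))


def read_counts(path: str | Path, sep: str | None = None) -> StratifiedCounts:
    """Read a long-format delimited count table.

    The file must have a header row ``stratum,group,design,responses,count``
    (comma- or tab-separated; autodetected unless ``sep`` is given). Cells
    absent from the file default to zero. Stratum order follows first
    appearance in the file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise ValidationError(f"no records in input file ({exc})") from exc
    required = {"stratum", "group", "design", "responses", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    if df.empty:
        raise ValidationError("no records in input file")
    labels = list(dict.fromkeys(df["stratum"].astype(str)))
    jdx = {lab: j for j, lab in enumerate(labels)}
    J = len(labels)
    n = np.zeros((2, 2, J), dtype=np.int64)
    m = np.zeros((3, 2, J), dtype=np.int64)
    seen: set[tuple] = set()
    for row in df.itertuples(index=False):
        g = str(row.group).strip().lower()
        if g not in GROUP_LABELS:
            raise ValidationError(f"unknown group label {row.group!r}")
        d = str(row.design).strip().lower()
        if d not in DESIGN_LABELS:
            raise ValidationError(f"unknown design label {row.design!r}")
        t = int(row.responses)
        key = (str(row.stratum), g, d, t)
        if key in seen:
            raise ValidationError(f"duplicate cell row {key}")
        seen.add(key)
        i = GROUP_LABELS[g] - 1
        j = jdx[str(row.stratum)]
        c = int(row.count)
        if d == "unilateral":
            if t not in (0, 1):
                raise ValidationError(
                    f"responses={t} invalid under unilateral design (stratum {row.stratum!r})"
                )
            n[t, i, j] = c
        else:
            if t not in (0, 1, 2):
                raise ValidationError(
                    f"responses={t} invalid under bilateral design (stratum {row.stratum!r})"
                )
            m[t, i, j] = c
    return validate(StratifiedCounts(n, m, tuple(labels)))


def write_counts(counts: StratifiedCounts, path: str | Path, sep: str = ",") -> None:
    """Write the long-format delimited table (inverse of :func:`read_counts`)."""
    counts.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# In-package datasets
# ---------------------------------------------------------------------------

# Acute otitis media with effusion: double-blinded randomised trial of a
# 14-day course of cefaclor (treatment) vs amoxicillin (control) in children,
# stratified by age at entry. Counts are effusion-free ears at day 14.
_AOM = dict(
    labels=("<2 years", "2-5 years", ">=6 years"),
    strata=[
        {"treatment": ((8, 2, 8), (3, 9)), "control": ((11, 2, 2), (2, 10))},
        {"treatment": ((6, 6, 10), (24, 7)), "control": ((3, 1, 5), (14, 22))},
        {"treatment": ((0, 1, 3), (11, 8)), "control": ((1, 0, 6), (11, 7))},
    ],
)

# Myopia / orthokeratology observational study: VST lenses (treatment) vs
# CRT lenses (control), stratified by sex. Counts are eyes with axial-length
# growth under 0.3 mm ("improved"). The female CRT group has no improved
# eyes at all, which drives its unconstrained event-rate MLE to the boundary.
_MYOPIA = dict(
    labels=("Female", "Male"),
    strata=[
        {"treatment": ((9, 3, 7), (2, 1)), "control": ((7, 0, 0), (0, 0))},
        {"treatment": ((11, 4, 3), (1, 2)), "control": ((6, 2, 2), (0, 0))},
    ],
)

_FIXTURES = {"aom": _AOM, "myopia": _MYOPIA}
FIXTURE_NAMES = tuple(_FIXTURES)


def fixture(name: str) -> StratifiedCounts:
    """Return one of the bundled example datasets (``"aom"`` or ``"myopia"``)."""
    try:
        spec = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return build_counts(spec["strata"], spec["labels"])
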