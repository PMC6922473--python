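"""Repeat-tract mutation spectra from capillary fragment sizes.

Sized PCR fragments of 5-FOA-resistant clones are converted to integer
repeat-unit deltas relative to the reference allele, binned into the
standard display classes (large deletions, -2, -1, 0, +1, +2, large
additions), tabulated as integer percentages, and compared between strains
with a chi-square test on counts.  A delta of 0 in a resistant clone means
the tract is unchanged and the reporter was inactivated by a coding
mutation elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .compare import TestResult, chi_square_contingency
from .simulate import AssayDesign, CloneRecord

__all__ = [
    "CLASS_LABELS",
    "SpectrumTable",
    "AmbiguousSizingError",
    "call_delta_units",
    "classify_delta",
    "spectrum_table",
    "spectrum_from_counts",
    "aggregate_classes",
    "compare_spectra",
]

#: Display classes, ordered by delta.
CLASS_LABELS = ("LARGE_DEL", "-2", "-1", "0", "+1", "+2", "LARGE_ADD")


class AmbiguousSizingError(ValueError):
    """Observed size too far from every integer repeat-unit length."""

    def __init__(self, message: str, residual_bp: float):
        super().__init__(message)
        self.residual_bp = residual_bp


class DeltaCall(NamedTuple):
    delta: int
    residual_bp: float


class ClassAggregate(NamedTuple):
    percentage: int
    count: int


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def call_delta_units(
    size_bp: float, design: AssayDesign, tol_bp: float | None = None
) -> DeltaCall:
    """Call the integer repeat-unit delta of one sized fragment.

    delta is the nearest integer of (size - L_ref)/unit with
    L_ref = flank + unit*ref_units; the residual must stay within
    ``tol_bp`` (default 0.45*unit, i.e. just inside half a repeat unit) or
    the call is refused as ambiguous.  Mononucleotide tracts are refused
    outright: 1 bp steps are beyond capillary sizing resolution.
    """
    if design.unit_bp < 2:
        raise ValueError(
            "mononucleotide tracts cannot be called from capillary sizes "
            "(1 bp steps are below sizing resolution)"
        )
    if size_bp <= 0:
        raise ValueError("size_bp must be > 0")
    if tol_bp is None:
        tol_bp = 0.45 * design.unit_bp
    if tol_bp <= 0:
        raise ValueError("tol_bp must be > 0")
    delta = _round_half_up((size_bp - design.ref_length_bp) / design.unit_bp)
    residual = size_bp - (design.ref_length_bp + delta * design.unit_bp)
    if abs(residual) > tol_bp:
        raise AmbiguousSizingError(
            f"ambiguous sizing: residual {residual:+.3f} bp exceeds "
            f"tolerance {tol_bp:.3f} bp at size {size_bp} bp",
            residual_bp=residual,
        )
    return DeltaCall(delta=delta, residual_bp=residual)


def classify_delta(delta: int) -> str:
    """Map an integer delta to its display class (large = |delta| >= 3)."""
    if delta <= -3:
        return "LARGE_DEL"
    if delta >= 3:
        return "LARGE_ADD"
    return f"{delta:+d}" if delta else "0"


@dataclass(frozen=True)
class SpectrumTable:
    """Per-class counts and integer percentages for one strain x tract.

    Percentages are rounded half-up from 100*count/n, so they sum to 100
    give or take rounding (within +/-2).
    """

    tract_id: str
    strain: str
    class_counts: Mapping[str, int]
    n_clones: int

    def __post_init__(self) -> None:
        counts = dict(self.class_counts)
        unknown = set(counts) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        full = {label: int(counts.get(label, 0)) for label in CLASS_LABELS}
        if any(v < 0 for v in full.values()):
            raise ValueError("class counts must be >= 0")
        if sum(full.values()) != self.n_clones:
            raise ValueError(
                f"class counts sum to {sum(full.values())}, expected n_clones="
                f"{self.n_clones}"
            )
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        object.__setattr__(self, "class_counts", full)

    @property
    def percentages(self) -> dict[str, int]:
        return {
            label: _round_half_up(100 * count / self.n_clones)
            for label, count in self.class_counts.items()
        }


def spectrum_from_counts(
    class_counts: Mapping[str, int], tract_id: str = "", strain: str = ""
) -> SpectrumTable:
    """Build a table directly from per-class counts."""
    return SpectrumTable(
        tract_id=tract_id,
        strain=strain,
        class_counts=dict(class_counts),
        n_clones=sum(int(v) for v in class_counts.values()),
    )


def spectrum_table(
    clones: Sequence[CloneRecord],
    design: AssayDesign,
    strain: str = "",
    tol_bp: float | None = None,
) -> SpectrumTable:
    """Call and bin every clone of one strain into a spectrum table.

    Every clone must be callable; ambiguous sizings are collected and
    raised together, listing the offenders.
    """
    if not clones:
        raise ValueError("spectrum_table requires at least one clone")
    counts = {label: 0 for label in CLASS_LABELS}
    offenders: list[str] = []
    for clone in clones:
        try:
            delta, _ = call_delta_units(clone.size_bp, design, tol_bp=tol_bp)
        except AmbiguousSizingError as err:
            offenders.append(f"{clone.clone_id} ({err})")
            continue
        counts[classify_delta(delta)] += 1
    if offenders:
        raise AmbiguousSizingError(
            "ambiguous sizing for clones: " + "; ".join(offenders), residual_bp=math.nan
        )
    tract_ids = {c.tract_id for c in clones}
    tract_id = tract_ids.pop() if len(tract_ids) == 1 else "/".join(sorted(tract_ids))
    return SpectrumTable(
        tract_id=tract_id, strain=strain, class_counts=counts, n_clones=len(clones)
    )


def aggregate_classes(
    table: SpectrumTable, classes: Sequence[str]
) -> ClassAggregate:
    """Sum of displayed percentages and of raw counts over selected classes."""
    unknown = set(classes) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    pct = table.percentages
    return ClassAggregate(
        percentage=sum(pct[c] for c in classes),
        count=sum(table.class_counts[c] for c in classes),
    )


def compare_spectra(
    a: SpectrumTable, b: SpectrumTable, min_expected: float = 1.0
) -> TestResult:
    """Chi-square comparison of two spectra on their class counts.

    Classes empty in both spectra are dropped; remaining classes whose
    expected count falls below ``min_expected`` in any cell are pooled into
    the adjacent class (toward the centre of the delta ordering) until none
    are sparse.  The pooling applied is recorded in the result detail.
    """
    if a.tract_id != b.tract_id:
        raise ValueError(
            f"cannot compare spectra of different tracts: {a.tract_id!r} vs {b.tract_id!r}"
        )
    labels = [
        lab
        for lab in CLASS_LABELS
        if a.class_counts[lab] + b.class_counts[lab] > 0
    ]
    cols = [[float(a.class_counts[lab]), float(b.class_counts[lab])] for lab in labels]
    groups = [[lab] for lab in labels]

    def sparse_index(cols: list[list[float]]) -> int | None:
        arr = np.asarray(cols).T  # 2 x k
        total = arr.sum()
        expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total
        bad = np.where((expected < min_expected).any(axis=0))[0]
        return int(bad[0]) if len(bad) else None

    while len(cols) > 2:
        idx = sparse_index(cols)
        if idx is None:
            break
        # pool toward the centre of the ordering
        centre = (len(cols) - 1) / 2
        nbr = idx + 1 if idx < centre else idx - 1
        lo, hi = sorted((idx, nbr))
        cols[lo] = [cols[lo][0] + cols[hi][0], cols[lo][1] + cols[hi][1]]
        groups[lo] = groups[lo] + groups[hi]
        del cols[hi], groups[hi]
    if len(cols) < 2:
        raise ValueError("fewer than two classes remain after pooling; no df")
    table = np.asarray(cols).T
    res = chi_square_contingency(table)
    pooled = [g for g in groups if len(g) > 1]
    detail = (
        "pooled: " + "; ".join("+".join(g) for g in pooled) if pooled else "no pooling"
    )
    return TestResult(
        method="chi_square_spectrum",
        statistic=res.statistic,
        p_value=res.p_value,
        group_sizes=(a.n_clones, b.n_clones),
        exact=False,
        df=res.df,
        detail=detail,
    )
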