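"""Bench-assay quantification: ddCq fold change, tumor volume, group statistics.

Covers the small closed-form formulas applied to wet-lab readouts:

* relative qPCR quantification against a reference gene (18S) by the
  2^(-ddCq) method, assuming perfect doubling per cycle;
* caliper tumor volume, V = length * width^2 / 2;
* per-arm growth-curve summaries;
* two-group Student's t-test / multi-group one-way ANOVA with the usual
  significance stars.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "QpcrSample",
    "TumorMeasurement",
    "DeltaDeltaCqResult",
    "GroupComparison",
    "delta_delta_cq",
    "tumor_volume",
    "growth_summary",
    "group_compare",
    "significance_stars",
]


@dataclass(frozen=True)
class QpcrSample:
    """One qPCR well pair: target and reference (18S) threshold cycles."""

    sample: str
    group: str  # "control" or "treated"
    cq_target: float
    cq_reference: float

    def __post_init__(self) -> None:
        for label, cq in (("target", self.cq_target), ("reference", self.cq_reference)):
            if not (0 < cq < 50):
                warnings.warn(
                    f"{self.sample}: implausible {label} Cq {cq} (expected 0 < Cq < 50)",
                    stacklevel=2,
                )

    @property
    def delta_cq(self) -> float:
        return self.cq_target - self.cq_reference


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper measurement; volume computed as length * width^2 / 2.

    If width exceeds length the two are swapped with a warning (calipers
    do not know which axis is which).
    """

    animal: str
    day: int
    length: float
    width: float

    def __post_init__(self) -> None:
        if self.length < 0 or self.width < 0:
            raise ValidationError("length and width must be >= 0")
        if self.width > self.length:
            warnings.warn(
                f"animal {self.animal} day {self.day}: width {self.width} > length "
                f"{self.length}; swapping",
                stacklevel=2,
            )
            longer, shorter = self.width, self.length
            object.__setattr__(self, "length", longer)
            object.__setattr__(self, "width", shorter)

    @property
    def volume(self) -> float:
        return tumor_volume(self.length, self.width)


@dataclass(frozen=True)
class DeltaDeltaCqResult:
    fold_change: float
    delta_delta_cq: float
    mean_dcq_control: float
    mean_dcq_treated: float
    sd_dcq_control: float
    sd_dcq_treated: float
    per_sample: pd.DataFrame  # sample, group, delta_cq


@dataclass(frozen=True)
class GroupComparison:
    test: str  # "t-test" or "anova"
    statistic: float
    pvalue: float
    stars: str
    warnings: tuple[str, ...] = ()


def delta_delta_cq(
    controls: Sequence[QpcrSample], treateds: Sequence[QpcrSample]
) -> DeltaDeltaCqResult:
    """2^(-ddCq) relative quantification, aggregating mean dCq per group.

    dCq = cq_target - cq_reference per sample; ddCq = mean dCq(treated) -
    mean dCq(control); fold change = 2^(-ddCq).  Efficiency is fixed at 2
    (perfect doubling).  Per-group SD of dCq is reported (sample SD,
    0 for a single sample).
    """
    if not controls or not treateds:
        raise ValidationError("both groups need at least one sample")
    dcq_c = np.array([s.delta_cq for s in controls])
    dcq_t = np.array([s.delta_cq for s in treateds])
    ddcq = float(dcq_t.mean() - dcq_c.mean())
    table = pd.DataFrame(
        {
            "sample": [s.sample for s in controls] + [s.sample for s in treateds],
            "group": ["control"] * len(controls) + ["treated"] * len(treateds),
            "delta_cq": np.concatenate([dcq_c, dcq_t]),
        }
    )
    sd = lambda a: float(a.std(ddof=1)) if a.size > 1 else 0.0
    return DeltaDeltaCqResult(
        fold_change=float(2.0 ** (-ddcq)),
        delta_delta_cq=ddcq,
        mean_dcq_control=float(dcq_c.mean()),
        mean_dcq_treated=float(dcq_t.mean()),
        sd_dcq_control=sd(dcq_c),
        sd_dcq_treated=sd(dcq_t),
        per_sample=table,
    )


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume in mm^3: (length * width^2) / 2.

    Inputs are ordered so the longer axis is the length (swap with a
    warning if needed); negative inputs are rejected.
    """
    if length < 0 or width < 0:
        raise ValidationError("length and width must be >= 0")
    if width > length:
        warnings.warn(
            f"width {width} > length {length}; swapping axes", stacklevel=2
        )
        length, width = width, length
    return length * width * width / 2.0


def growth_summary(
    measurements: dict[str, Sequence[TumorMeasurement]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(arm, day) n/mean/SD of tumor volume plus a final-day table.

    ``measurements`` maps treatment arm -> its animals' measurements.  The
    final day is the largest day present in *every* arm; arms with
    disjoint day grids produce an empty final-day table with a warning.
    Animals missing on a day are simply absent from that day's summary.
    """
    rows = []
    for arm, ms in measurements.items():
        for m in ms:
            rows.append({"arm": arm, "day": m.day, "animal": m.animal, "volume": m.volume})
    if not rows:
        raise ValidationError("no measurements supplied")
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["arm", "day"], as_index=False)["volume"]
        .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .sort_values(["arm", "day"])
        .reset_index(drop=True)
    )
    day_sets = [set(df[df["arm"] == arm]["day"]) for arm in measurements]
    common = set.intersection(*day_sets) if day_sets else set()
    if not common:
        warnings.warn("treatment arms share no common day; empty final-day table",
                      stacklevel=2)
        final = summary.iloc[0:0].copy()
    else:
        final_day = max(common)
        final = summary[summary["day"] == final_day].reset_index(drop=True)
    return summary, final


def significance_stars(p: float) -> str:
    """Star annotation: * p<0.05, ** p<0.01, *** p<0.001, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_compare(
    groups: Sequence[Sequence[float]], welch: bool = False
) -> GroupComparison:
    """Two groups: two-sided Student's t-test (pooled variance unless
    ``welch``); more than two: one-way ANOVA F-test.

    Degenerate zero-within-variance inputs are handled explicitly: equal
    means give (statistic 0, p = 1); different means give p -> 0 with a
    degenerate-variance warning, since the test statistic diverges.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least two groups")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValidationError(f"group {i} has n < 2")
    warns: list[str] = []
    zero_var = all(a.std(ddof=1) == 0 for a in arrays)
    if zero_var:
        means = [a.mean() for a in arrays]
        if all(m == means[0] for m in means):
            stat, p = 0.0, 1.0
        else:
            warns.append("degenerate zero within-group variance; p reported as 0")
            stat, p = math.inf, 0.0
        test = "t-test" if len(arrays) == 2 else "anova"
        return GroupComparison(test, stat, p, significance_stars(p), tuple(warns))
    if len(arrays) == 2:
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=not welch)
        test = "t-test"
    else:
        res = stats.f_oneway(*arrays)
        test = "anova"
    stat, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(p):
        warns.append("test returned a non-finite p-value")
        p = 1.0
    return GroupComparison(test, stat, p, significance_stars(p), tuple(warns))
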