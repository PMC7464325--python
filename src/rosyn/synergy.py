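"""Chou-Talalay median-effect analysis of drug combinations.

The median-effect equation relates dose D to fraction affected fa through

    fa / fu = (D / Dm)^m,          fu = 1 - fa,

with median-effect dose Dm (the dose producing 50% effect) and
sigmoidicity m (the shape of the dose-effect curve).  Taking log10 of both
sides linearises it,

    log10(fa / fu) = m * log10(D) - m * log10(Dm),

so (m, Dm) come from an ordinary unweighted least-squares fit of
log10(fa/fu) on log10(D) — the published median-effect method.

Synergy of a two-drug combination at an observed effect fa is quantified
by the two-term (mutually exclusive) combination index

    CI = D1 / Dx1(fa) + D2 / Dx2(fa),

where D1, D2 are the combination doses and Dx1, Dx2 the single-drug doses
that would produce the same fa alone.  CI < 1 is synergistic, CI = 1
additive (Loewe), CI > 1 antagonistic; with noisy data the additive band
is widened to |CI - 1| <= tol (default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "DoseResponsePoint",
    "DoseResponseSeries",
    "MedianEffectFit",
    "CombinationIndexResult",
    "Isobologram",
    "viability_to_fraction_affected",
    "fit_median_effect",
    "dose_for_effect",
    "combination_index",
    "classify_ci",
    "isobologram_points",
    "read_viability_tsv",
    "aggregate_replicates",
    "analyze_combination",
]


@dataclass(frozen=True)
class DoseResponsePoint:
    dose_1: float
    dose_2: float
    viability: float  # fraction of vehicle control, > 0

    def __post_init__(self) -> None:
        if self.dose_1 < 0 or self.dose_2 < 0:
            raise ValidationError("doses must be >= 0")
        if self.viability <= 0:
            raise ValidationError(f"viability must be > 0, got {self.viability}")

    @property
    def total_dose(self) -> float:
        return self.dose_1 + self.dose_2


@dataclass(frozen=True)
class DoseResponseSeries:
    """One drug's (or one combination's) viability series."""

    label: str
    points: tuple[DoseResponsePoint, ...]
    is_combination: bool = False

    def __post_init__(self) -> None:
        if not self.is_combination:
            d1 = all(p.dose_2 == 0 for p in self.points)
            d2 = all(p.dose_1 == 0 for p in self.points)
            if not (d1 or d2):
                raise ValidationError(
                    f"single-drug series {self.label!r} mixes nonzero doses of both drugs"
                )


@dataclass(frozen=True)
class MedianEffectFit:
    """Result of the linearised median-effect regression for one series."""

    label: str
    m: float  # sigmoidicity slope
    Dm: float  # median-effect dose
    r: float  # Pearson correlation of the linearised fit
    n_used: int
    warnings: tuple[str, ...] = ()

    @property
    def usable(self) -> bool:
        return np.isfinite(self.m) and self.m > 0 and self.Dm > 0


@dataclass(frozen=True)
class CombinationIndexResult:
    fa: float
    D1: float
    D2: float
    Dx1: float
    Dx2: float
    ci: float
    classification: str


@dataclass(frozen=True)
class Isobologram:
    effect_level: float
    axis_intercepts: tuple[float, float]  # (Dx1, Dx2) at the effect level
    combo_points: tuple[tuple[float, float], ...]
    normalized: bool


def viability_to_fraction_affected(
    viability: float, epsilon: float = 1e-4
) -> tuple[float, bool]:
    """fa = 1 - viability, clamped into [epsilon, 1 - epsilon].

    Returns ``(fa, clamped)``; points at or beyond the boundaries (e.g.
    apparent growth stimulation, viability >= 1) are clamped and flagged
    so the fit can exclude them.
    """
    if viability <= 0:
        raise ValidationError(f"viability must be > 0, got {viability}")
    fa = 1.0 - viability
    if fa < epsilon:
        return epsilon, True
    if fa > 1.0 - epsilon:
        return 1.0 - epsilon, True
    return fa, False


def fit_median_effect(
    series: DoseResponseSeries, epsilon: float = 1e-4
) -> MedianEffectFit:
    """OLS fit of log10(fa/fu) on log10(total dose).

    For a combination series the dose is ``dose_1 + dose_2`` (constant-ratio
    design).  Clamped (boundary) points are excluded when at least two
    unflagged points remain; otherwise they are kept with a warning.  A
    zero or negative slope is returned with a "non-monotone" warning flag
    rather than raised, so callers can inspect the degenerate fit.
    """
    doses, fas, flags = [], [], []
    for p in series.points:
        if p.total_dose <= 0:
            continue  # the zero-dose control carries no information here
        fa, clamped = viability_to_fraction_affected(p.viability, epsilon)
        doses.append(p.total_dose)
        fas.append(fa)
        flags.append(clamped)
    doses_arr = np.asarray(doses)
    fas_arr = np.asarray(fas)
    flags_arr = np.asarray(flags, dtype=bool)

    warns: list[str] = []
    keep = ~flags_arr
    if keep.sum() < 2:
        if len(doses) >= 2:
            keep = np.ones(len(doses), dtype=bool)
            warns.append("fewer than 2 unclamped points; clamped points included in fit")
        else:
            raise ValidationError(
                f"series {series.label!r}: need >= 2 points with positive dose"
            )
    x = np.log10(doses_arr[keep])
    if np.unique(x).size < 2:
        raise ValidationError(
            f"series {series.label!r}: need >= 2 distinct positive doses"
        )
    y = np.log10(fas_arr[keep] / (1.0 - fas_arr[keep]))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        warns.append("non-monotone")
        Dm = float("nan")
    else:
        Dm = float(10.0 ** (-res.intercept / m))
    r = float(res.rvalue) if np.isfinite(res.rvalue) else 1.0
    return MedianEffectFit(series.label, m, Dm, r, int(keep.sum()), tuple(warns))


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Invert the median-effect equation: Dx = Dm * (fa/(1-fa))^(1/m)."""
    if not (0.0 < fa < 1.0):
        raise ValidationError(f"fa must be in (0, 1), got {fa}")
    if not fit.usable:
        raise ValidationError(f"fit for {fit.label!r} is not usable (m={fit.m}, Dm={fit.Dm})")
    return float(fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def classify_ci(ci: float, tol: float = 0.05) -> str:
    """Three-way synergy call: CI < 1 synergistic, = 1 additive, > 1 antagonistic.

    Strict equality is unusable with noisy data, so "additive" is the band
    ``|ci - 1| <= tol``.
    """
    if ci < 0:
        raise ValidationError(f"combination index must be >= 0, got {ci}")
    # tiny slack keeps the band boundary inclusive despite representation
    # error (|0.95 - 1| > 0.05 in doubles by one ulp)
    if abs(ci - 1.0) <= tol + 1e-12:
        return "additive"
    return "synergistic" if ci < 1.0 else "antagonistic"


def combination_index(
    combo_point: tuple[float, float, float],
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    tol: float = 0.05,
) -> CombinationIndexResult:
    """Two-term (mutually exclusive) CI at one observed combination point.

    ``combo_point`` is ``(D1, D2, fa)``: the doses of the two drugs and the
    fraction affected they produced together.
    """
    D1, D2, fa = combo_point
    if D1 < 0 or D2 < 0:
        raise ValidationError("combination doses must be >= 0")
    Dx1 = dose_for_effect(fit1, fa)
    Dx2 = dose_for_effect(fit2, fa)
    ci = D1 / Dx1 + D2 / Dx2
    return CombinationIndexResult(fa, D1, D2, Dx1, Dx2, ci, classify_ci(ci, tol))


def isobologram_points(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    combo_points: Sequence[tuple[float, float, float]],
    effect_level: float = 0.5,
    normalized: bool = False,
    fa_band: float = 0.05,
) -> Isobologram:
    """Isobologram data at one effect level.

    Raw mode plots the (D1, D2) of combination points whose observed fa
    lies within ``fa_band`` of ``effect_level``, against the additivity
    line joining (Dx1, 0) and (0, Dx2).  Normalized mode plots every
    combination point as (D1/Dx1(fa_obs), D2/Dx2(fa_obs)), where the
    additivity line is x + y = 1 and the coordinates of a point sum to
    its CI.
    """
    Dx1 = dose_for_effect(fit1, effect_level)
    Dx2 = dose_for_effect(fit2, effect_level)
    pts: list[tuple[float, float]] = []
    if normalized:
        for D1, D2, fa in combo_points:
            pts.append((D1 / dose_for_effect(fit1, fa), D2 / dose_for_effect(fit2, fa)))
    else:
        for D1, D2, fa in combo_points:
            if abs(fa - effect_level) <= fa_band:
                pts.append((D1, D2))
        if combo_points and not pts:
            warnings.warn(
                f"no combination point within fa band +/-{fa_band} of {effect_level}; "
                "empty isobologram",
                stacklevel=2,
            )
    return Isobologram(effect_level, (Dx1, Dx2), tuple(pts), normalized)


# ---------------------------------------------------------------------------
# Tabular interface
# ---------------------------------------------------------------------------

def read_viability_tsv(path: str | Path) -> pd.DataFrame:
    """Read a viability table: columns label, dose_1, dose_2, viability.

    Replicates appear as repeated rows for the same (label, dose_1, dose_2).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"label", "dose_1", "dose_2", "viability"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"viability table missing columns: {sorted(missing)}")
    if (df["viability"] <= 0).any():
        raise ValidationError("viability values must be > 0")
    return df


def aggregate_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Mean viability per (label, dose_1, dose_2); replicate SD and n reported."""
    g = df.groupby(["label", "dose_1", "dose_2"], as_index=False)["viability"]
    out = g.agg(viability="mean", viability_sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
                n_replicates="size")
    return out.sort_values(["label", "dose_1", "dose_2"]).reset_index(drop=True)


def series_from_frame(
    df: pd.DataFrame, label: str, is_combination: bool = False
) -> DoseResponseSeries:
    sub = df[df["label"] == label]
    if sub.empty:
        raise ValidationError(f"no rows with label {label!r}")
    points = tuple(
        DoseResponsePoint(float(r.dose_1), float(r.dose_2), float(r.viability))
        for r in sub.itertuples()
    )
    return DoseResponseSeries(label, points, is_combination)


def analyze_combination(
    df: pd.DataFrame,
    drug1: str,
    drug2: str,
    combo: str,
    epsilon: float = 1e-4,
    tol: float = 0.05,
) -> tuple[dict[str, MedianEffectFit], pd.DataFrame]:
    """Point-wise CI analysis of one combination against its two single drugs.

    Replicates are averaged first; each single drug gets a median-effect
    fit, and the CI is computed at every observed combination dose pair
    from its measured fa (the point-wise design, which handles multiple
    independent dose pairs).  Returns the fits and a per-point CI table.
    """
    agg = aggregate_replicates(df)
    fits = {
        drug1: fit_median_effect(series_from_frame(agg, drug1), epsilon),
        drug2: fit_median_effect(series_from_frame(agg, drug2), epsilon),
        combo: fit_median_effect(series_from_frame(agg, combo, is_combination=True), epsilon),
    }
    rows = []
    for r in agg[agg["label"] == combo].itertuples():
        fa, clamped = viability_to_fraction_affected(float(r.viability), epsilon)
        if clamped:
            continue  # boundary effect levels have no defined equivalent dose
        res = combination_index(
            (float(r.dose_1), float(r.dose_2), fa), fits[drug1], fits[drug2], tol
        )
        rows.append(
            {
                "D1": res.D1, "D2": res.D2, "fa": res.fa,
                "Dx1": res.Dx1, "Dx2": res.Dx2,
                "ci": res.ci, "classification": res.classification,
            }
        )
    return fits, pd.DataFrame(rows)


def write_fits_tsv(fits: Sequence[MedianEffectFit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tm\tDm\tr\tn_used\twarnings\n")
        for f in fits:
            fh.write(
                f"{f.label}\t{f.m:.6g}\t{f.Dm:.6g}\t{f.r:.6g}\t{f.n_used}\t"
                f"{';'.join(f.warnings)}\n"
            )
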