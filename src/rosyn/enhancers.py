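"""Super-enhancer calling: stitch, score, rank, hockey-stick cutoff, annotate.

The procedure follows the ROSE/HOMER strategy for H3K27ac landscapes:
peaks within 12.5 kb of each other are stitched into candidate enhancer
regions, each region is scored by the area of ChIP coverage it spans
(optionally minus a scaled control), regions are ranked by signal, and the
cutoff separating typical enhancers from super-enhancers is the point
where the min-max-scaled rank-vs-signal curve reaches tangent slope 1 —
the inflection of the characteristic "hockey stick".

Geometry of the cutoff: with ``x_i = (i-1)/(n-1)`` and
``y_i = (s_i - s_1)/(s_n - s_1)`` the discrete tangent point is
``argmin_i (y_i - x_i)``; for a convex curve this is exactly where the
slope crosses 1, and it is stable to noise because it needs no numeric
differentiation.  Ties resolve toward the largest index (fewest
super-enhancers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .intervals import (
    CoverageTrack,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    check_chromosome_overlap,
    interval_signal,
    sort_and_merge,
)

__all__ = [
    "StitchedRegion",
    "EnhancerRanking",
    "SuperEnhancerCall",
    "stitch_peaks",
    "score_regions",
    "hockey_stick_cutoff",
    "call_super_enhancers",
    "annotate_nearest_gene",
    "write_ranking_tsv",
    "write_super_bed",
    "DEFAULT_STITCH_GAP",
]

#: Stitching distance in bp: peaks closer than this are merged into one
#: candidate enhancer region.
DEFAULT_STITCH_GAP = 12_500


@dataclass(frozen=True)
class StitchedRegion:
    """A stitched enhancer region with its constituent peaks and score."""

    interval: GenomicInterval
    constituents: tuple[str, ...]
    signal: float = 0.0
    rank: int = 0  # 1 = lowest signal; 0 = unranked

    def __post_init__(self) -> None:
        if not self.constituents:
            raise ValidationError("stitched region must have at least one constituent peak")
        if self.signal < 0:
            raise ValidationError(f"region signal must be >= 0, got {self.signal}")


@dataclass(frozen=True)
class EnhancerRanking:
    """The hockey-stick object: ranked regions plus the computed cutoff."""

    regions: tuple[StitchedRegion, ...]  # ascending by signal, ranks 1..n
    cutoff_signal: float
    cutoff_index: int  # 1-based rank of the cutoff region
    n_super: int
    scaled_x: np.ndarray
    scaled_y: np.ndarray

    def is_super(self, region: StitchedRegion) -> bool:
        return region.signal > self.cutoff_signal

    @property
    def super_regions(self) -> tuple[StitchedRegion, ...]:
        return tuple(r for r in self.regions if self.is_super(r))


@dataclass(frozen=True)
class SuperEnhancerCall:
    region: StitchedRegion
    is_super: bool
    nearest_gene: str
    tss_distance: Optional[int]  # region midpoint - TSS; None when no gene


def stitch_peaks(
    peaks: Sequence[Peak],
    max_gap: int = DEFAULT_STITCH_GAP,
    tss_exclusion: Optional[int] = None,
    genes: Optional[Sequence[GeneAnnotation]] = None,
) -> list[StitchedRegion]:
    """Stitch peaks within ``max_gap`` bp into unscored enhancer regions.

    When ``tss_exclusion`` is set to a window half-width w, peaks fully
    contained in ``[tss - w, tss + w)`` of any annotated TSS are removed
    before stitching (the optional promoter-exclusion of the reference
    ROSE strategy; off by default).  An empty peak set yields an empty
    result, not an error.
    """
    if tss_exclusion is not None:
        if genes is None:
            raise ValidationError("tss_exclusion requires a gene annotation set")
        if tss_exclusion < 0:
            raise ValidationError(f"tss_exclusion must be >= 0, got {tss_exclusion}")
        tss_lists: dict[str, list[int]] = {}
        for g in genes:
            tss_lists.setdefault(g.chrom, []).append(g.tss)
        tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_lists.items()}

        def excluded(p: Peak) -> bool:
            tss = tss_by_chrom.get(p.interval.chrom)
            if tss is None or tss.size == 0:
                return False
            # peak contained in [t - w, t + w) for some TSS t
            lo = p.interval.start
            hi = p.interval.end
            j = np.searchsorted(tss, lo)  # candidates around the peak
            for t in tss[max(0, j - 1) : j + 2]:
                if t - tss_exclusion <= lo and hi <= t + tss_exclusion:
                    return True
            return False

        peaks = [p for p in peaks if not excluded(p)]

    return [
        StitchedRegion(iv, tuple(names))
        for iv, names in sort_and_merge(peaks, max_gap)
    ]


def score_regions(
    regions: Sequence[StitchedRegion],
    chip: CoverageTrack,
    control: Optional[CoverageTrack] = None,
    control_scale: float = 1.0,
) -> list[StitchedRegion]:
    """Score regions by ChIP coverage area, optionally control-subtracted.

    ``signal = area(chip) - control_scale * area(control)``, clamped at 0.
    Regions on chromosomes absent from the track score 0.
    """
    if control_scale < 0:
        raise ValidationError(f"control_scale must be >= 0, got {control_scale}")
    check_chromosome_overlap(
        [Peak(r.interval, f"region_{i}") for i, r in enumerate(regions)], chip
    )
    scored = []
    for r in regions:
        sig = interval_signal(chip, r.interval)
        if control is not None:
            sig -= control_scale * interval_signal(control, r.interval)
        scored.append(replace(r, signal=max(sig, 0.0)))
    return scored


def hockey_stick_cutoff(
    signals: Sequence[float] | np.ndarray,
) -> tuple[float, int, np.ndarray, np.ndarray]:
    """Locate the tangent-slope-1 cutoff on an ascending signal vector.

    Returns ``(cutoff_signal, cutoff_index, scaled_x, scaled_y)`` where
    ``cutoff_index`` is the 1-based rank of the cutoff region.  Regions
    with signal strictly above ``cutoff_signal`` are super-enhancers.

    A flat vector (all signals equal) is degenerate: the cutoff is placed
    at the maximum, no region is super, and a warning is emitted.
    """
    s = np.asarray(signals, dtype=float)
    if s.size < 3:
        raise ValidationError(f"hockey-stick cutoff needs >= 3 signals, got {s.size}")
    if np.any(np.diff(s) < 0):
        raise ValidationError("signals must be sorted ascending")
    n = s.size
    x = np.arange(n) / (n - 1)
    if s[-1] == s[0]:
        warnings.warn("flat signal vector: degenerate hockey-stick, zero super-enhancers",
                      stacklevel=2)
        return float(s[-1]), n, x, np.zeros(n)
    y = (s - s[0]) / (s[-1] - s[0])
    d = y - x
    # ties resolve toward the largest index => fewest super-enhancers
    idx0 = int(np.flatnonzero(d == d.min()).max())
    return float(s[idx0]), idx0 + 1, x, y


def call_super_enhancers(regions: Sequence[StitchedRegion]) -> EnhancerRanking:
    """Rank scored regions and flag super-enhancers via the hockey-stick cutoff.

    Regions are sorted ascending by signal with ties broken by genomic
    position (chrom, then start) for determinism; ranks are 1..n with
    1 = lowest signal.  The result is invariant to input order.
    """
    if len(regions) < 3:
        raise ValidationError(f"super-enhancer calling needs >= 3 regions, got {len(regions)}")
    ordered = sorted(regions, key=lambda r: (r.signal, r.interval.chrom, r.interval.start))
    ranked = tuple(replace(r, rank=i + 1) for i, r in enumerate(ordered))
    signals = np.array([r.signal for r in ranked])
    cutoff_signal, cutoff_index, sx, sy = hockey_stick_cutoff(signals)
    n_super = int(np.sum(signals > cutoff_signal))
    return EnhancerRanking(ranked, cutoff_signal, cutoff_index, n_super, sx, sy)


def annotate_nearest_gene(
    ranking: EnhancerRanking, genes: Sequence[GeneAnnotation]
) -> list[SuperEnhancerCall]:
    """Assign each region the gene with the TSS nearest its midpoint.

    Distance is ``region_midpoint - tss`` (signed).  Equidistant TSSs
    resolve to the lexicographically smaller gene symbol; regions on
    chromosomes without any annotated gene get ``nearest_gene="NA"``
    and an unset distance.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    calls = []
    for region in ranking.regions:
        candidates = by_chrom.get(region.interval.chrom)
        if not candidates:
            calls.append(SuperEnhancerCall(region, ranking.is_super(region), "NA", None))
            continue
        mid = region.interval.midpoint
        best = min(candidates, key=lambda g: (abs(mid - g.tss), g.gene))
        calls.append(
            SuperEnhancerCall(region, ranking.is_super(region), best.gene, mid - best.tss)
        )
    return calls


# ---------------------------------------------------------------------------
# Tabular / BED output
# ---------------------------------------------------------------------------

def write_ranking_tsv(
    ranking: EnhancerRanking,
    path: str | Path,
    calls: Optional[Sequence[SuperEnhancerCall]] = None,
) -> None:
    """Write the ranking table (descending by rank, strongest first)."""
    ann = {id(c.region): c for c in calls} if calls else {}
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tn_constituents\tsignal\trank\tis_super"
            "\tnearest_gene\ttss_distance\n"
        )
        for r in sorted(ranking.regions, key=lambda r: -r.rank):
            c = ann.get(id(r))
            gene = c.nearest_gene if c else ""
            dist = "" if c is None or c.tss_distance is None else str(c.tss_distance)
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{len(r.constituents)}\t{r.signal:.6g}\t{r.rank}\t"
                f"{int(ranking.is_super(r))}\t{gene}\t{dist}\n"
            )


def write_super_bed(ranking: EnhancerRanking, path: str | Path) -> None:
    """Write super-enhancers as BED6, score = region signal scaled to 0-1000."""
    max_sig = max((r.signal for r in ranking.regions), default=0.0)
    with open(path, "w") as fh:
        for i, r in enumerate(ranking.super_regions, start=1):
            score = int(round(1000 * r.signal / max_sig)) if max_sig > 0 else 0
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"SE_{i}\t{score}\t.\n"
            )
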