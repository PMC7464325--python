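"""Differential enhancer landscape analysis between two conditions.

Compares H3K27ac enhancer landscapes (e.g. vehicle vs. a CDK7 inhibitor),
builds deeptools-style reference-point signal matrices and mean profiles
around super-enhancer centers, and classifies each region as stable,
attenuated (still super but >= 2-fold down by default) or decommissioned
(super in the control condition, no longer super after treatment).

Region identity across conditions is fixed by re-scoring the *control*
condition's stitched regions in the treated track rather than re-stitching
independently, so "the same" enhancer is compared on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .enhancers import EnhancerRanking
from .intervals import CoverageTrack, GenomicInterval, interval_signal

__all__ = [
    "SignalMatrix",
    "DifferentialRegion",
    "library_size_normalize",
    "reference_point_matrix",
    "profile_summary",
    "compare_conditions",
    "write_matrix_tsv",
    "write_profile_tsv",
    "write_differential_tsv",
]


@dataclass(frozen=True)
class SignalMatrix:
    """Regions x bins table of mean signal density around region centers."""

    region_ids: tuple[str, ...]
    window: int  # half-width in bp
    bin_size: int
    values: np.ndarray  # shape (n_regions, 2 * window // bin_size)

    @property
    def n_bins(self) -> int:
        return 2 * self.window // self.bin_size

    @property
    def bin_offsets(self) -> np.ndarray:
        """Left edge of each bin relative to the region center."""
        return np.arange(-self.window, self.window, self.bin_size)


@dataclass(frozen=True)
class DifferentialRegion:
    region: GenomicInterval
    signal_control: float
    signal_treated: float
    log2fc: float
    status: str  # stable | attenuated | decommissioned


def library_size_normalize(
    track_a: CoverageTrack, track_b: CoverageTrack
) -> tuple[CoverageTrack, CoverageTrack, tuple[float, float]]:
    """Scale two tracks to a common total equal to their geometric-mean total.

    Required for a fair between-condition comparison: signal areas are only
    comparable when library sizes match.  Returns the scaled tracks and the
    per-track factors; tracks that already share a total get factors 1.
    """
    ta, tb = track_a.total_signal(), track_b.total_signal()
    if ta <= 0 or tb <= 0:
        raise ValidationError(f"both tracks need positive total signal, got {ta} and {tb}")
    target = float(np.sqrt(ta * tb))
    fa, fb = target / ta, target / tb
    return track_a.scaled(fa), track_b.scaled(fb), (fa, fb)


def reference_point_matrix(
    track: CoverageTrack,
    centers: Sequence[GenomicInterval],
    window: int = 50_000,
    bin_size: int = 500,
) -> SignalMatrix:
    """Signal-density matrix in bins around each region's midpoint.

    Each cell is the mean coverage density over one bin
    (``interval_signal / bin_size``).  Bins that extend past chromosome
    position 0 are truncated and averaged over covered length only; bins
    entirely below 0 are 0.  Rows are ordered by total row signal,
    descending (heatmap convention).  The default window of +/-50 kb
    matches the usual presentation of super-enhancer heatmaps.
    """
    if window <= 0 or bin_size <= 0 or window % bin_size != 0:
        raise ValidationError(
            f"window ({window}) must be a positive multiple of bin_size ({bin_size})"
        )
    n_bins = 2 * window // bin_size
    offsets = np.arange(-window, window, bin_size)
    rows = np.zeros((len(centers), n_bins))
    ids = []
    for i, region in enumerate(centers):
        mid = region.midpoint
        ids.append(f"{region.chrom}:{region.start}-{region.end}")
        for j, off in enumerate(offsets):
            left = mid + int(off)
            right = left + bin_size
            gstart = max(left, 0)
            if right <= gstart:
                continue  # bin entirely before the chromosome start
            sig = interval_signal(track, GenomicInterval(region.chrom, gstart, right))
            rows[i, j] = sig / (right - gstart)
    order = np.argsort(-rows.sum(axis=1), kind="stable")
    return SignalMatrix(
        region_ids=tuple(ids[k] for k in order),
        window=window,
        bin_size=bin_size,
        values=rows[order],
    )


def profile_summary(matrix: SignalMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise mean and standard deviation of the matrix (per-bin profile)."""
    if matrix.values.shape[0] == 0:
        raise ValidationError("cannot summarise an empty signal matrix")
    return matrix.values.mean(axis=0), matrix.values.std(axis=0)


def compare_conditions(
    control: EnhancerRanking,
    treated: EnhancerRanking,
    pseudocount: float = 1.0,
    attenuation_threshold: float = -1.0,
) -> list[DifferentialRegion]:
    """Per-region log2 fold change and decommissioning status.

    ``log2fc = log2((signal_treated + c) / (signal_control + c))`` with
    pseudocount ``c``.  A region is *decommissioned* when it is super in
    the control ranking but not in the treated one; *attenuated* when it
    stays super but its log2fc is at or below ``attenuation_threshold``
    (default -1, i.e. a 2-fold drop); otherwise *stable*.  Both rankings
    must cover the identical set of region coordinates.
    """
    if pseudocount <= 0:
        raise ValidationError(f"pseudocount must be > 0, got {pseudocount}")
    ctrl_by_iv = {r.interval: r for r in control.regions}
    trt_by_iv = {r.interval: r for r in treated.regions}
    if set(ctrl_by_iv) != set(trt_by_iv):
        raise ValidationError(
            "control and treated rankings cover different region sets; "
            "re-score the control regions in the treated track"
        )
    out = []
    for iv in sorted(ctrl_by_iv, key=lambda v: (v.chrom, v.start)):
        rc, rt = ctrl_by_iv[iv], trt_by_iv[iv]
        # difference of logs (not log of ratio) so condition swap negates exactly
        log2fc = float(np.log2(rt.signal + pseudocount) - np.log2(rc.signal + pseudocount))
        super_c = control.is_super(rc)
        super_t = treated.is_super(rt)
        if super_c and not super_t:
            status = "decommissioned"
        elif super_c and super_t and log2fc <= attenuation_threshold:
            status = "attenuated"
        else:
            status = "stable"
        out.append(DifferentialRegion(iv, rc.signal, rt.signal, log2fc, status))
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: SignalMatrix, path: str | Path) -> None:
    """One row per region, one column per bin; header gives genomic offsets."""
    with open(path, "w") as fh:
        offs = matrix.bin_offsets
        fh.write("region\t" + "\t".join(f"bin_{o}" for o in offs) + "\n")
        for rid, row in zip(matrix.region_ids, matrix.values):
            fh.write(rid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def write_profile_tsv(matrix: SignalMatrix, path: str | Path) -> None:
    mean, sd = profile_summary(matrix)
    with open(path, "w") as fh:
        fh.write("offset\tmean\tsd\n")
        for o, m, s in zip(matrix.bin_offsets, mean, sd):
            fh.write(f"{o}\t{m:.6g}\t{s:.6g}\n")


def write_differential_tsv(
    diffs: Sequence[DifferentialRegion], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsignal_control\tsignal_treated\tlog2fc\tstatus\n")
        for d in diffs:
            fh.write(
                f"{d.region.chrom}\t{d.region.start}\t{d.region.end}\t"
                f"{d.signal_control:.6g}\t{d.signal_treated:.6g}\t"
                f"{d.log2fc:.6g}\t{d.status}\n"
            )
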