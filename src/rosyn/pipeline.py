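"""End-to-end orchestration: simulate -> call-se -> diff-se -> synergy -> report.

A run is described by a :class:`RunConfig` (flat YAML file with per-stage
sections).  Stages execute in dependency order; each writes its tabular
outputs into the run directory, appends to a timestamped log, and
contributes to a flat machine-readable summary plus a human-readable
report.  Reruns with the same config and seed are bit-for-bit identical.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .errors import ConfigurationError, ValidationError
from . import enhancers, differential, synergy, assays, simulate

from .plots import (
    plot_fa_ci,
    plot_heatmap,
    plot_hockey_stick,
    plot_isobologram,
    plot_profile,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed after validation; partial outputs are retained."""


_KNOWN_KEYS = {
    "seed", "out_dir",
    # enhancer calling
    "max_gap", "tss_exclusion", "control_scale",
    # differential
    "window", "bin_size", "pseudocount", "attenuation_threshold", "normalize",
    # synergy
    "effect_levels", "ci_tolerance", "epsilon", "target_ci", "noise_cv", "replicates",
    # simulation scale
    "chrom_length", "n_typical", "n_super", "treatment_attenuation",
    # qpcr / tumor
    "qpcr_fold_change", "qpcr_sd", "qpcr_n",
}


@dataclass
class RunConfig:
    """Validated parameters of a full pipeline run."""

    seed: int = 1
    out_dir: str = "rosyn_run"
    max_gap: int = enhancers.DEFAULT_STITCH_GAP
    tss_exclusion: Optional[int] = None
    control_scale: float = 1.0
    window: int = 50_000
    bin_size: int = 500
    pseudocount: float = 1.0
    attenuation_threshold: float = -1.0
    normalize: bool = True
    effect_levels: tuple[float, ...] = (0.5, 0.75, 0.9)
    ci_tolerance: float = 0.05
    epsilon: float = 1e-4
    target_ci: float = 0.5
    noise_cv: float = 0.05
    replicates: int = 3
    chrom_length: int = 10_000_000
    n_typical: int = 500
    n_super: int = 10
    treatment_attenuation: float = 4.0
    qpcr_fold_change: float = 0.25
    qpcr_sd: float = 0.1
    qpcr_n: int = 4

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ConfigurationError(f"max_gap must be >= 0, got {self.max_gap}")
        if self.window <= 0 or self.bin_size <= 0 or self.window % self.bin_size:
            raise ConfigurationError("window must be a positive multiple of bin_size")
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be > 0")
        if not all(0 < f < 1 for f in self.effect_levels):
            raise ConfigurationError("effect levels must lie in (0, 1)")
        if self.ci_tolerance < 0:
            raise ConfigurationError("ci_tolerance must be >= 0")
        if self.seed < 0:
            raise ConfigurationError("seed must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a flat YAML config; unknown keys are rejected, CLI overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} must be a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "effect_levels" in raw and isinstance(raw["effect_levels"], (list, tuple)):
            raw["effect_levels"] = tuple(float(x) for x in raw["effect_levels"])
        return cls(**raw)


class _RunLog:
    """Append-only text log with ISO timestamps."""

    def __init__(self, path: Path) -> None:
        self.path = path
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def write(self, stage: str, message: str) -> None:
        stamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
        with open(self.path, "a") as fh:
            fh.write(f"{stamp}\t{stage}\t{message}\n")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage on synthetic inputs and write the run report.

    Returns the flat summary dictionary (also written as summary.json).
    Every numeric in the report traces to a stage output file in the run
    directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run.log")
    summary: dict[str, Any] = {"seed": config.seed}
    log.write("config", json.dumps(asdict(config), default=str))

    try:
        # ---- stage 1: simulate the ChIP landscape ------------------------
        chip_cfg = simulate.ChipSimConfig(
            seed=config.seed,
            chrom_length=config.chrom_length,
            n_typical=config.n_typical,
            n_super=config.n_super,
            treatment_attenuation=config.treatment_attenuation,
        )
        landscape = simulate.simulate_chip_landscape(chip_cfg)
        sim_dir = out / "simulated"
        files = simulate.write_chip_landscape(landscape, sim_dir)
        simulate.write_manifest(sim_dir, chip_cfg, config.seed, files)
        log.write("simulate", f"{len(landscape.peaks)} peaks, "
                              f"{int((landscape.truth['element_class'] == 'super').sum())} planted SEs")

        # ---- stage 2: super-enhancer calling on the control ---------------
        regions = enhancers.stitch_peaks(landscape.peaks, max_gap=config.max_gap)
        scored = enhancers.score_regions(regions, landscape.control)
        ranking = enhancers.call_super_enhancers(scored)
        enhancers.write_ranking_tsv(ranking, out / "ranking_control.tsv")
        enhancers.write_super_bed(ranking, out / "super_enhancers.bed")
        plot_hockey_stick(ranking, out / "hockey_stick.png")
        summary["n_regions"] = len(ranking.regions)
        summary["n_super"] = ranking.n_super
        summary["n_super_planted"] = int((landscape.truth["element_class"] == "super").sum())
        log.write("call-se", f"n_regions={summary['n_regions']} n_super={summary['n_super']}")

        # ---- stage 3: differential (re-score control regions, compare) ----
        control_trk, treated_trk = landscape.control, landscape.treated
        if config.normalize:
            control_trk, treated_trk, factors = differential.library_size_normalize(
                control_trk, treated_trk
            )
            summary["norm_factor_control"] = round(factors[0], 6)
            summary["norm_factor_treated"] = round(factors[1], 6)
            log.write("normalize", f"factors={factors}")
            scored = enhancers.score_regions(regions, control_trk)
            ranking = enhancers.call_super_enhancers(scored)
        treated_scored = enhancers.score_regions(regions, treated_trk)
        treated_ranking = enhancers.call_super_enhancers(treated_scored)
        diffs = differential.compare_conditions(
            ranking, treated_ranking,
            pseudocount=config.pseudocount,
            attenuation_threshold=config.attenuation_threshold,
        )
        differential.write_differential_tsv(diffs, out / "differential.tsv")
        summary["n_decommissioned"] = sum(d.status == "decommissioned" for d in diffs)
        summary["n_attenuated"] = sum(d.status == "attenuated" for d in diffs)
        log.write("diff-se", f"decommissioned={summary['n_decommissioned']}")

        centers = [r.interval for r in ranking.super_regions]
        if centers:
            mat_c = differential.reference_point_matrix(
                control_trk, centers, config.window, config.bin_size
            )
            mat_t = differential.reference_point_matrix(
                treated_trk, centers, config.window, config.bin_size
            )
            differential.write_matrix_tsv(mat_c, out / "matrix_control.tsv")
            differential.write_matrix_tsv(mat_t, out / "matrix_treated.tsv")
            differential.write_profile_tsv(mat_c, out / "profile_control.tsv")
            differential.write_profile_tsv(mat_t, out / "profile_treated.tsv")
            plot_heatmap(mat_c, out / "heatmap_control.png", "control")
            plot_heatmap(mat_t, out / "heatmap_treated.png", "treated")
            plot_profile({"control": mat_c, "treated": mat_t}, out / "profile.png")

        # ---- stage 4: synergy ---------------------------------------------
        dose_cfg = simulate.DoseSimConfig(
            seed=config.seed,
            target_ci=config.target_ci,
            noise_cv=config.noise_cv,
            replicates=config.replicates,
        )
        viability, dose_truth = simulate.simulate_dose_response(dose_cfg)
        viability.to_csv(out / "viability.tsv", sep="\t", index=False)
        fits, ci_table = synergy.analyze_combination(
            viability, "drug1", "drug2", "combo",
            epsilon=config.epsilon, tol=config.ci_tolerance,
        )
        synergy.write_fits_tsv(list(fits.values()), out / "median_effect_fits.tsv")
        ci_table.to_csv(out / "combination_index.tsv", sep="\t", index=False)
        plot_fa_ci(ci_table, out / "fa_ci.png")
        combo_pts = [
            (row.D1, row.D2, row.fa) for row in ci_table.itertuples()
        ]
        iso = synergy.isobologram_points(
            fits["drug1"], fits["drug2"], combo_pts,
            effect_level=config.effect_levels[0], normalized=True,
        )
        plot_isobologram(iso, out / "isobologram.png")
        summary["target_ci"] = config.target_ci
        summary["mean_ci"] = round(float(ci_table["ci"].mean()), 6) if len(ci_table) else float("nan")
        summary["ci_classification"] = (
            synergy.classify_ci(summary["mean_ci"], config.ci_tolerance)
            if len(ci_table) else "NA"
        )
        log.write("synergy", f"mean_ci={summary['mean_ci']}")

        # ---- stage 5: qPCR and tumor growth -------------------------------
        ctrl, trt, qpcr_truth = simulate.simulate_qpcr(
            config.seed, n_per_group=config.qpcr_n,
            true_fold_change=config.qpcr_fold_change, cq_sd=config.qpcr_sd,
        )
        dd = assays.delta_delta_cq(ctrl, trt)
        summary["qpcr_fold_change"] = round(dd.fold_change, 6)
        summary["qpcr_true_fold_change"] = config.qpcr_fold_change

        tumors, tumor_truth = simulate.simulate_tumor_growth(
            config.seed,
            growth_rates={"vehicle": 0.12, "drug1": 0.08, "drug2": 0.10, "combo": 0.03},
        )
        growth, final = assays.growth_summary(tumors)
        growth.to_csv(out / "tumor_growth.tsv", sep="\t", index=False)
        final.to_csv(out / "tumor_final_day.tsv", sep="\t", index=False)
        if len(final):
            arms = {row.arm: row.mean for row in final.itertuples()}
            summary["final_day_volume_combo"] = round(arms.get("combo", float("nan")), 2)
            summary["final_day_volume_vehicle"] = round(arms.get("vehicle", float("nan")), 2)
            samples = [
                [m.volume for m in tumors[arm] if m.day == final["day"].iloc[0]]
                for arm in tumors
            ]
            cmp = assays.group_compare(samples)
            summary["final_day_anova_p"] = float(f"{cmp.pvalue:.3e}")
            summary["final_day_stars"] = cmp.stars
        log.write("assays", f"qpcr_fc={summary['qpcr_fold_change']}")

    except (ValidationError, ConfigurationError):
        raise
    except Exception as exc:  # pragma: no cover - defensive
        log.write("error", repr(exc))
        raise PipelineError(str(exc)) from exc

    # ---- report -----------------------------------------------------------
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    report_lines = ["rosyn pipeline report", "=" * 21, ""]
    for k in sorted(summary):
        report_lines.append(f"{k}: {summary[k]}")
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    log.write("report", "written")
    return summary
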