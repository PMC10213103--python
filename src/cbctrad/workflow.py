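"""End-to-end study orchestration on synthetic data.

Five analyses mirror the optimisation studies a preclinical CBCT radiomics
workflow needs before any biology is attempted:

* **repeatability** — scan–rescan ICC(A,1) screening per imaging energy,
  bin width or slice thickness, with per-condition robust sets and their
  all-condition intersection;
* **reproducibility** — average-measures ICC across the settings of one
  variable, on scan/rescan-averaged values;
* **volume effect** — repeatability per segmentation volume plus Pearson
  correlation of every original (unfiltered) feature against mesh volume;
* **texture** — per-material feature tables and scan–rescan ICCs on the
  texture phantom inserts and the mouse soft tissue;
* **cohort pilot** — two synthetic tumour arms, per-arm reliability
  screening, and paired t-tests on the surviving robust features.

Every run is deterministic given the config seed; with an output directory
set, each command writes tidy CSVs plus a JSON manifest of the exact
configuration.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .features import ExtractionConfig, FeatureExtractor
from .imaging import GridSpec, make_spherical_mask
from .phantoms import (
    DEFAULT_PROTOCOLS,
    CohortSpec,
    ScanProtocol,
    generate_mouse_phantom,
    generate_texture_phantom,
    generate_tumour_cohort,
    sample_roi_centres,
    simulate_scan_pair,
    texture_inserts,
)
from .reliability import (
    ReliabilityReport,
    compare_cohorts,
    reproducibility_screen,
    screen_features,
    volume_correlation,
)

REPEATABILITY_VARIABLES = ("energy", "bin_width", "slice_thickness")


@dataclass(frozen=True)
class StudyConfig:
    """Study conditions: the parameter grids swept and the simulation sizes."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.26, 0.26, 0.26)
    energies: tuple[int, ...] = (40, 50, 60)
    bin_widths: tuple[float, ...] = (10.0, 25.0, 50.0, 100.0)
    slice_thicknesses: tuple[float, ...] = (0.2, 0.26, 0.3, 0.5, 1.0)
    volumes: tuple[float, ...] = (27.68, 34.38, 41.71, 92.24, 237.5)
    roi_volume: float = 92.24
    texture_roi_volume: float = 41.71
    n_placements: int = 10
    n_texture_placements: int = 8
    default_energy: int = 60
    default_bin_width: float = 25.0
    default_thickness: float = 0.26
    wavelet: bool = True
    seed: int = 20230516
    protocols: dict[int, ScanProtocol] | None = None
    cohort_a: CohortSpec = field(default_factory=lambda: CohortSpec("A549-like"))
    cohort_b: CohortSpec = field(default_factory=lambda: CohortSpec("H460-like", effect_size=1.5))
    outdir: str | None = None

    def protocol(self, energy: int) -> ScanProtocol:
        table = self.protocols if self.protocols is not None else DEFAULT_PROTOCOLS
        return table[energy]

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_shape, self.spacing)


def _sub_seed(seed: int, *tags: int) -> int:
    """Stable derived seed below 2^31."""
    h = seed % (2**31 - 1)
    for t in tags:
        h = (h * 1000003 + int(t) + 1) % (2**31 - 1)
    return h


def _extraction_config(config: StudyConfig, **overrides) -> ExtractionConfig:
    kw = dict(
        bin_width=config.default_bin_width,
        slice_thickness=config.default_thickness,
        wavelet=config.wavelet,
        shape=True,
    )
    kw.update(overrides)
    return ExtractionConfig(**kw)


def _long_rows(features: dict, roi_id, condition, replicate) -> list[dict]:
    return [
        {
            "roi_id": roi_id,
            "condition": condition,
            "replicate": replicate,
            "feature_name": k,
            "value": v,
        }
        for k, v in features.items()
    ]


def _write(df: pd.DataFrame, outdir: str | None, name: str) -> None:
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        df.to_csv(os.path.join(outdir, name), index=False)


def write_manifest(config: StudyConfig, outdir: str | None, command: str) -> None:
    if outdir is None:
        return
    os.makedirs(outdir, exist_ok=True)
    d = dataclasses.asdict(config)
    d["protocols"] = {
        int(e): dataclasses.asdict(config.protocol(e)) for e in config.energies
    }
    payload = {"command": command, "version": __version__, "config": d}
    with open(os.path.join(outdir, f"manifest_{command}.json"), "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


# --------------------------------------------------------------------------
# repeatability / reproducibility
# --------------------------------------------------------------------------

def _mouse_setup(config: StudyConfig, volume: float | None = None, n: int | None = None):
    grid = config.grid
    phantom, labels, _ = generate_mouse_phantom(grid, seed=_sub_seed(config.seed, 1))
    vol = volume if volume is not None else config.roi_volume
    count = n if n is not None else config.n_placements
    centres = sample_roi_centres(
        labels, grid, vol, count, seed=_sub_seed(config.seed, 2, int(vol * 100))
    )
    masks = [make_spherical_mask(grid, c, vol) for c in centres]
    return phantom, labels, masks


def repeatability_table(config: StudyConfig, variable: str) -> pd.DataFrame:
    """Long-format scan/rescan feature table for one swept variable."""
    if variable not in REPEATABILITY_VARIABLES:
        raise ValueError(f"variable must be one of {REPEATABILITY_VARIABLES}, got {variable!r}")
    phantom, _, masks = _mouse_setup(config)
    rows: list[dict] = []

    if variable == "energy":
        for e in config.energies:
            scan, rescan = simulate_scan_pair(
                phantom, config.protocol(e), (_sub_seed(config.seed, 3, e), _sub_seed(config.seed, 4, e))
            )
            ex = FeatureExtractor(_extraction_config(config))
            for rep, img in (("scan", scan), ("rescan", rescan)):
                for i, fv in enumerate(ex.extract_batch(img, masks)):
                    rows += _long_rows(fv, i, e, rep)
    else:
        e = config.default_energy
        scan, rescan = simulate_scan_pair(
            phantom, config.protocol(e), (_sub_seed(config.seed, 3, e), _sub_seed(config.seed, 4, e))
        )
        conditions = config.bin_widths if variable == "bin_width" else config.slice_thicknesses
        for cond in conditions:
            if variable == "bin_width":
                ex = FeatureExtractor(_extraction_config(config, bin_width=cond))
            else:
                ex = FeatureExtractor(_extraction_config(config, slice_thickness=cond))
            for rep, img in (("scan", scan), ("rescan", rescan)):
                for i, fv in enumerate(ex.extract_batch(img, masks)):
                    rows += _long_rows(fv, i, cond, rep)
    return pd.DataFrame(rows)


@dataclass
class RepeatabilityResult:
    variable: str
    table: pd.DataFrame
    report: ReliabilityReport
    robust_overlap: set[str]


def run_repeatability(config: StudyConfig, variable: str) -> RepeatabilityResult:
    """Scan–rescan reliability screening across one variable's conditions."""
    table = repeatability_table(config, variable)
    report = screen_features(table)
    conds = report.conditions
    if len(conds) < 2:
        warnings.warn("single-condition run: intersection equals that condition's robust set")
    overlap = report.robust_intersection()
    _write(table, config.outdir, f"repeatability_{variable}_features.csv")
    _write(report.to_frame(), config.outdir, f"repeatability_{variable}_icc.csv")
    summary = report.summary()
    _write(summary, config.outdir, f"repeatability_{variable}_summary.csv")
    inter = pd.DataFrame(
        [{"condition_set": "|".join(str(c) for c in conds), "robust_count": len(overlap)}]
    )
    _write(inter, config.outdir, f"repeatability_{variable}_intersection.csv")
    write_manifest(config, config.outdir, f"repeatability_{variable}")
    return RepeatabilityResult(variable, table, report, overlap)


def run_reproducibility(
    config: StudyConfig, variable: str, table: pd.DataFrame | None = None
) -> ReliabilityReport:
    """Average-measures ICC across the conditions of one variable.

    Values are averaged over scan and rescan per condition and ROI, then the
    conditions act as the raters of an ICC(A,k).  ``table`` may reuse an
    existing repeatability table to avoid re-simulating.
    """
    if table is None:
        table = repeatability_table(config, variable)
    means = (
        table.groupby(["roi_id", "condition", "feature_name"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    report = reproducibility_screen(means)
    _write(report.to_frame(), config.outdir, f"reproducibility_{variable}_icc.csv")
    write_manifest(config, config.outdir, f"reproducibility_{variable}")
    return report


# --------------------------------------------------------------------------
# volume effect
# --------------------------------------------------------------------------

@dataclass
class VolumeEffectResult:
    report: ReliabilityReport
    correlation: pd.DataFrame
    mean_features: pd.DataFrame  # per-volume mean of original features


def run_volume_effect(config: StudyConfig) -> VolumeEffectResult:
    """Repeatability per segmentation volume + volume-correlation filtering."""
    grid = config.grid
    phantom, labels, _ = generate_mouse_phantom(grid, seed=_sub_seed(config.seed, 1))
    e = config.default_energy
    scan, rescan = simulate_scan_pair(
        phantom, config.protocol(e), (_sub_seed(config.seed, 3, e), _sub_seed(config.seed, 4, e))
    )
    ex = FeatureExtractor(_extraction_config(config))
    rows: list[dict] = []
    usable_volumes: list[float] = []
    for v in config.volumes:
        try:
            centres = sample_roi_centres(
                labels, grid, v, config.n_placements, seed=_sub_seed(config.seed, 2, int(v * 100))
            )
        except ValueError as err:
            warnings.warn(f"volume {v} mm³ skipped: {err}")
            continue
        masks = [make_spherical_mask(grid, c, v) for c in centres]
        usable_volumes.append(v)
        for rep, img in (("scan", scan), ("rescan", rescan)):
            for i, fv in enumerate(ex.extract_batch(img, masks)):
                rows += _long_rows(fv, i, v, rep)
    table = pd.DataFrame(rows)
    report = screen_features(table)

    # per-volume mean of every original feature, for the correlation analysis
    orig = table[table["feature_name"].str.startswith("original_")]
    mean_features = (
        orig.groupby(["condition", "feature_name"], sort=False)["value"]
        .mean()
        .unstack("feature_name")
        .loc[usable_volumes]
    )
    mesh = mean_features["original_shape_MeshVolume"].to_numpy()
    corr = volume_correlation(mean_features, mesh)
    _write(table, config.outdir, "volume_features.csv")
    _write(report.to_frame(), config.outdir, "volume_icc.csv")
    _write(corr, config.outdir, "volume_correlation.csv")
    write_manifest(config, config.outdir, "volume_effect")
    return VolumeEffectResult(report, corr, mean_features)


# --------------------------------------------------------------------------
# texture study
# --------------------------------------------------------------------------

@dataclass
class TextureStudyResult:
    mean_intensity: dict[str, float]   # original_firstorder_Mean per material
    ngtdm: pd.DataFrame                # NGTDM feature values per material
    report: ReliabilityReport


def run_texture_study(config: StudyConfig) -> TextureStudyResult:
    """Texture discrimination across phantom inserts and mouse soft tissue."""
    rows: list[dict] = []
    e = config.default_energy
    proto = config.protocol(e)
    v = config.texture_roi_volume
    n = config.n_texture_placements

    # texture phantom inserts (0.5 mm grid)
    tex_img, tex_labels, legend = generate_texture_phantom(seed=_sub_seed(config.seed, 11))
    tex_cfg = _extraction_config(config, slice_thickness=None)
    ex_tex = FeatureExtractor(tex_cfg)
    scan_t, rescan_t = simulate_scan_pair(
        tex_img, proto, (_sub_seed(config.seed, 12), _sub_seed(config.seed, 13))
    )
    materials = [m.label for m in texture_inserts()]
    for mat in materials:
        centres = sample_roi_centres(
            tex_labels, tex_img.grid, v, n,
            seed=_sub_seed(config.seed, 14, legend[mat]), target_label=legend[mat],
        )
        masks = [make_spherical_mask(tex_img.grid, c, v) for c in centres]
        for rep, img in (("scan", scan_t), ("rescan", rescan_t)):
            for i, fv in enumerate(ex_tex.extract_batch(img, masks)):
                rows += _long_rows(fv, i, mat, rep)

    # mouse phantom soft tissue (native 0.26 mm grid)
    phantom, labels, _ = generate_mouse_phantom(config.grid, seed=_sub_seed(config.seed, 1))
    scan_m, rescan_m = simulate_scan_pair(
        phantom, proto, (_sub_seed(config.seed, 3, e), _sub_seed(config.seed, 4, e))
    )
    centres = sample_roi_centres(
        labels, config.grid, v, n, seed=_sub_seed(config.seed, 15)
    )
    masks = [make_spherical_mask(config.grid, c, v) for c in centres]
    ex_mouse = FeatureExtractor(_extraction_config(config))
    for rep, img in (("scan", scan_m), ("rescan", rescan_m)):
        for i, fv in enumerate(ex_mouse.extract_batch(img, masks)):
            rows += _long_rows(fv, i, "mouse_soft_tissue", rep)

    table = pd.DataFrame(rows)
    report = screen_features(table)

    mean_intensity = (
        table[table["feature_name"] == "original_firstorder_Mean"]
        .groupby("condition", sort=False)["value"]
        .mean()
        .to_dict()
    )
    ngtdm = (
        table[table["feature_name"].str.startswith("original_ngtdm_")]
        .groupby(["condition", "feature_name"], sort=False)["value"]
        .mean()
        .unstack("feature_name")
    )
    _write(table, config.outdir, "texture_features.csv")
    _write(report.to_frame(), config.outdir, "texture_icc.csv")
    _write(ngtdm.reset_index(), config.outdir, "texture_ngtdm.csv")
    write_manifest(config, config.outdir, "texture")
    return TextureStudyResult(mean_intensity, ngtdm, report)


# --------------------------------------------------------------------------
# cohort pilot
# --------------------------------------------------------------------------

@dataclass
class CohortPilotResult:
    report: ReliabilityReport
    robust_features: set[str]
    comparison: pd.DataFrame | None
    message: str = ""


def run_cohort_pilot(config: StudyConfig) -> CohortPilotResult:
    """Two-arm synthetic tumour pilot: screen, intersect, differentiate."""
    grid = GridSpec((48, 48, 48), config.spacing)
    subjects = generate_tumour_cohort(
        config.cohort_a, config.cohort_b, grid, seed=_sub_seed(config.seed, 21)
    )
    proto = config.protocol(config.default_energy)
    ex = FeatureExtractor(_extraction_config(config))
    rows: list[dict] = []
    subject_means: list[dict] = []
    for idx, (img, mask, arm) in enumerate(subjects):
        scan, rescan = simulate_scan_pair(
            img, proto, (_sub_seed(config.seed, 22, idx), _sub_seed(config.seed, 23, idx))
        )
        fv_scan = ex.extract(scan, mask)
        fv_rescan = ex.extract(rescan, mask)
        rows += _long_rows(fv_scan, idx, arm, "scan")
        rows += _long_rows(fv_rescan, idx, arm, "rescan")
        mean_fv = {k: 0.5 * (fv_scan[k] + fv_rescan[k]) for k in fv_scan}
        subject_means.append({"cohort": arm, "subject": idx, **mean_fv})

    table = pd.DataFrame(rows)
    report = screen_features(table)
    arms = report.conditions
    robust = report.robust_intersection(arms)
    _write(table, config.outdir, "cohort_features.csv")
    _write(report.to_frame(), config.outdir, "cohort_icc.csv")
    if not robust:
        write_manifest(config, config.outdir, "cohort")
        return CohortPilotResult(report, robust, None, "no robust features survive both cohorts")
    cohort_table = pd.DataFrame(subject_means)
    comparison = compare_cohorts(cohort_table, sorted(robust))
    _write(comparison, config.outdir, "cohort_comparison.csv")
    write_manifest(config, config.outdir, "cohort")
    return CohortPilotResult(report, robust, comparison)
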