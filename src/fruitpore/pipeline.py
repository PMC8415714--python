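"""End-to-end orchestration: volume -> segmentation -> morphometry -> network
-> regions, plus the group statistics used for morphometric comparisons.

A run is described by a :class:`RunConfig` (loadable from YAML), executes
the stages in a fixed order, and emits a :class:`dict` report in which
every number is traceable to one upstream operation.  Stage failures
(e.g. "core not separable by grayscale") are recorded as outcomes and do
not abort later independent stages.  Runs that generate phantoms are
deterministic given config + seed.

Percent-valued morphometrics are variance-stabilized with the arcsine
square-root transform before the two-sample (Welch) t comparison.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from fruitpore import morphometry, network, phantom, regions, segmentation
from fruitpore.volume_io import VoxelVolume, read_volume

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run.

    Exactly one input source: a named phantom preset (with mandatory
    seed) or a volume path (with voxel-size override for TIFF input).
    """

    phantom_preset: str | None = None
    phantom_seed: int | None = None
    volume_path: str | None = None
    voxel_size_um: float | None = None
    smoothing_window: int = 9
    manual_threshold: float | None = None
    connectivity: int = 26
    min_voxels: int = 1
    spur_min_um: float | None = None
    fractions: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    class_width_um: float = 100.0
    max_class_um: float = 3000.0
    do_network: bool = True
    do_regions: bool = True
    output_dir: str | None = None
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        has_phantom = self.phantom_preset is not None
        if has_phantom == (self.volume_path is not None):
            raise ValueError("configure exactly one of phantom_preset / volume_path")
        if has_phantom and self.phantom_seed is None:
            raise ValueError("phantom runs require an explicit seed")
        if has_phantom and self.phantom_preset not in phantom.PRESETS:
            raise ValueError(f"unknown preset {self.phantom_preset!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.pop("schema_version", None)
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fractions"] = list(d["fractions"])
        return d


def arcsine_transform(p):
    """Arcsine square-root transform of a proportion: asin(sqrt(p)), radians.

    Accepts scalars or arrays in [0, 1] (divide percent data by 100
    first); 0 maps to 0 and 1 to pi/2.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def compare_groups(a, b, transform: bool = True, percent: bool = True) -> dict:
    """Welch two-sample t-test between two samples of percentages.

    With ``transform`` the test runs on arcsine-square-root-transformed
    proportions (percent inputs are divided by 100 first); the reported
    group means and standard deviations stay on the original scale.
    Degrees of freedom follow Welch-Satterthwaite.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    ta, tb = a, b
    if transform:
        ta = arcsine_transform(a / 100.0 if percent else a)
        tb = arcsine_transform(b / 100.0 if percent else b)
    res = stats.ttest_ind(ta, tb, equal_var=False)
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "transform": "arcsine_sqrt" if transform else "none",
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "dispersion": "sd",
    }


def _load_input(config: RunConfig):
    if config.phantom_preset is not None:
        spec = phantom.preset_spec(config.phantom_preset, seed=config.phantom_seed)
        vol, truth = phantom.generate_phantom(spec)
        return vol, truth
    vol = read_volume(config.volume_path, voxel_size_um=config.voxel_size_um)
    return vol, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by ``config`` and return the report.

    Stage order: load/generate -> fruit mask -> histogram + threshold ->
    phase segmentation -> pore labeling and morphometry -> skeleton
    network -> regions/core -> report.  Failed stages are recorded under
    ``stages`` with their reason; independent later stages still run.
    """
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "stages": {},
    }
    vol, truth = _load_input(config)
    report["input"] = {
        "shape": list(vol.shape),
        "voxel_size_um": vol.voxel_size_um,
        "bit_depth": vol.bit_depth,
        "axis_convention": vol.axis_convention,
        "provenance": vol.provenance,
    }
    report["stages"]["load"] = "ok"

    fruit_mask = segmentation.compute_fruit_mask(vol)
    report["stages"]["fruit_mask"] = "ok"

    hist = segmentation.compute_histogram(vol, fruit_mask)
    if config.manual_threshold is not None:
        params = segmentation.SegmentationParams(
            threshold=config.manual_threshold,
            smoothing_window=config.smoothing_window,
            source="manual",
        )
    else:
        params = segmentation.find_valley_threshold(hist, config.smoothing_window)
    phase = segmentation.segment_phases(vol, params, fruit_mask)
    report["threshold"] = {"value": params.threshold, "source": params.source}
    report["stages"]["segmentation"] = "ok"

    whole_porosity = morphometry.porosity(phase)
    profile = morphometry.porosity_profile(phase)
    labels = morphometry.label_pores(phase, connectivity=config.connectivity)
    table = morphometry.build_pore_table(labels)
    if config.min_voxels > 1:
        table = table[table["voxel_count"] >= config.min_voxels].reset_index(drop=True)
    fruit_mm3 = float(fruit_mask.sum()) * (vol.voxel_size_um * 1e-3) ** 3
    size_hist = morphometry.pore_size_histogram(
        table, class_width_um=config.class_width_um, max_um=config.max_class_um
    )
    report["porosity_percent"] = whole_porosity
    report["profile"] = {
        "slice_index": profile.slice_index.tolist(),
        "porosity_percent": [None if not v else p for p, v in
                             zip(profile.porosity_percent.tolist(), profile.valid.tolist())],
    }
    report["pores"] = {
        "count": int(len(table)),
        "number_density_per_mm3": morphometry.pore_number_density(table, fruit_mm3),
        "mean_d_eq_um": morphometry.mean_equivalent_diameter(table),
        "region_volume_mm3": fruit_mm3,
        "size_histogram": {
            "class_center_um": size_hist["class_center_um"].tolist(),
            "count": size_hist["count"].tolist(),
        },
        "connectivity": config.connectivity,
    }
    report["stages"]["morphometry"] = "ok"

    if config.do_network:
        sg, nstats = network.analyze_pore_network(phase, spur_min_um=config.spur_min_um)
        report["network"] = dataclasses.asdict(nstats)
        report["stages"]["network"] = "ok"
    else:
        report["stages"]["network"] = "disabled"

    if config.do_regions:
        try:
            core = regions.extract_core(vol, fruit_mask)
            core_source = "grayscale"
        except regions.CoreNotSeparableError as exc:
            core = regions.fallback_core(fruit_mask)
            core_source = f"geometric_fallback ({exc})"
        try:
            part = regions.partition_mesocarp(
                fruit_mask, core, vol.voxel_size_um, fractions=config.fractions
            )
            zone_porosity = {
                name: morphometry.porosity(phase, part.mask(code))
                for name, code in (("LRA", regions.LRA), ("MRA", regions.MRA),
                                   ("HRA", regions.HRA))
                if part.mask(code).any()
            }
            shape = regions.core_shape_metrics(core, vol.voxel_size_um)
            report["regions"] = {
                "core_source": core_source,
                "boundary_fractions": list(part.boundary_fractions),
                "zone_porosity_percent": zone_porosity,
                "core_shape": dataclasses.asdict(shape),
            }
            report["stages"]["regions"] = "ok"
        except ValueError as exc:
            report["stages"]["regions"] = f"failed: {exc}"
    else:
        report["stages"]["regions"] = "disabled"

    if truth is not None:
        cmp: dict = {
            "true_porosity_percent": truth.true_porosity_percent,
            "porosity_error_points": whole_porosity - truth.true_porosity_percent,
        }
        if truth.pore_table is not None and len(truth.pore_table):
            cmp["true_pore_count"] = int(len(truth.pore_table))
            cmp["measured_pore_count"] = int(len(table))
            cmp["true_mean_d_eq_um"] = float(truth.pore_table["d_eq_um"].mean())
            cmp["measured_mean_d_eq_um"] = report["pores"]["mean_d_eq_um"]
        report["truth_comparison"] = cmp

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
        table.to_csv(out / "pore_table.csv", index=False)
        profile.as_frame().to_csv(out / "porosity_profile.csv", index=False)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report_without_timestamp(report: dict) -> dict:
    """Copy of a run report with the timestamp removed (for determinism checks)."""
    out = dict(report)
    out.pop("timestamp", None)
    return out
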