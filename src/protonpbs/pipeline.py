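"""End-to-end pipeline: phantom -> transport -> radiobiology -> evaluation.

A run is described by a structured YAML/dict config (quantities carry unit
suffixes in their key names).  The pipeline executes the stages in fixed
order — geometry, HU-density calibration, dose (analytic or MC), LETd/RBE,
plan metrics — writes every intermediate grid, and emits a machine-readable
JSON report plus a text summary.  The report contains the RNG seed, package
versions, model constants and grid checksums, so a run with the same config
and seed reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .beam_model import EnergyRangeModel, extract_range_metrics
from .evaluation import (
    cumulative_histogram,
    dose_at_volume,
    gamma_analysis,
    volume_at_dose,
    write_histogram_csv,
)
from .gridio import read_grid, write_grid
from .phantom import (
    build_hu_density_table,
    densify,
    fixture_hu_density_curve,
    make_slab_phantom,
    make_thorax_phantom,
    make_water_tank,
    write_hu_density_table_csv,
)
from .radiobiology import RBE_MODELS, RadiobiologyParams, rbe_weighted_dose
from .transport import BeamSource, Spot, analytic_dose, depth_dose_from_grid, mc_dose

__all__ = ["RunConfig", "load_config", "run_pipeline"]

_PHANTOM_TYPES = {"water_tank", "slab", "thorax"}
_ENGINES = {"analytic", "mc"}


class RunConfig:
    """Validated pipeline configuration.

    Thin wrapper over the config mapping: validation happens on
    construction, before any compute; ``to_dict``/``from_dict`` round-trip
    exactly.
    """

    def __init__(self, data: dict):
        self.data = data
        self._validate()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(json.loads(json.dumps(data)))

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self.data))

    def _require(self, section: str) -> dict:
        if section not in self.data or not isinstance(self.data[section], dict):
            raise ValueError(f"config is missing the {section!r} section")
        return self.data[section]

    def _validate(self) -> None:
        ph = self._require("phantom")
        if ph.get("type") not in _PHANTOM_TYPES:
            raise ValueError(f"phantom.type must be one of {sorted(_PHANTOM_TYPES)}")
        beam = self._require("beam")
        if not beam.get("spots"):
            raise ValueError("beam.spots must be a nonempty list")
        for s in beam["spots"]:
            if "energy_mev" not in s or "weight" not in s:
                raise ValueError("each spot needs energy_mev and weight")
        eng = self._require("engine")
        if eng.get("type") not in _ENGINES:
            raise ValueError(f"engine.type must be one of {sorted(_ENGINES)}")
        if eng["type"] == "mc" and int(eng.get("n_primaries", 0)) < 1:
            raise ValueError("engine.n_primaries must be >= 1 for the mc engine")
        rb = self.data.get("radiobiology")
        if rb:
            for m in rb.get("models", []):
                if m not in RBE_MODELS:
                    raise ValueError(f"unknown RBE model {m!r}")
            if any(m != "constant" for m in rb.get("models", [])):
                if "n_fractions" not in rb:
                    raise ValueError("radiobiology.n_fractions is required for variable RBE models")
                if eng["type"] != "mc":
                    raise ValueError("variable RBE models need LETd, i.e. engine.type == 'mc'")
        ev = self.data.get("evaluation", {})
        structures = set(ev.get("structures", []))
        if structures and ph["type"] != "thorax":
            raise ValueError("structure-based metrics require the thorax phantom")
        known = {"ctv", "rib", "lung"}
        unknown = structures - known
        if unknown:
            raise ValueError(f"unknown structures {sorted(unknown)}; thorax provides {sorted(known)}")

    def __getitem__(self, key):
        return self.data[key]

    def get(self, key, default=None):
        return self.data.get(key, default)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig(yaml.safe_load(fh))


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _build_phantom(ph: dict, default_seed: int):
    spacing = ph.get("spacing_mm", 2.0)
    kind = ph["type"]
    masks = {}
    if kind == "water_tank":
        hu = make_water_tank(ph.get("side_cm", 30.0), spacing)
    elif kind == "slab":
        hu = make_slab_phantom(
            [(m, t) for m, t in ph["layers"]], ph.get("lateral_cm", 10.0), spacing
        )
    else:
        hu, masks = make_thorax_phantom(spacing, int(ph.get("seed", default_seed)))
    return hu, masks


def _build_source(beam: dict) -> BeamSource:
    spots = [
        Spot(
            energy_mev=float(s["energy_mev"]),
            weight=float(s["weight"]),
            x_mm=float(s.get("x_mm", 0.0)),
            y_mm=float(s.get("y_mm", 0.0)),
            fwhm_x_mm=float(s.get("fwhm_x_mm", 8.0)),
            fwhm_y_mm=float(s.get("fwhm_y_mm", 8.0)),
        )
        for s in beam["spots"]
    ]
    return BeamSource(
        gantry_angle_deg=float(beam.get("gantry_angle_deg", 0.0)),
        isocenter_mm=np.asarray(beam.get("isocenter_mm", [0.0, 0.0, 0.0]), dtype=float),
        spots=spots,
    )


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """Execute all configured stages and write artifacts.

    Returns the report dict (also written as ``report.json`` /
    ``report.txt`` in the output directory).
    """
    out = Path(output_dir or config.get("output_dir", "protonpbs_out"))
    out.mkdir(parents=True, exist_ok=True)
    eng = config["engine"]
    seed = int(eng.get("seed", 0))
    report: dict = {
        "package": "protonpbs",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "model_constants": {"a_cm_per_mev_p": 0.0022, "p": 1.77},
        "artifacts": {},
        "checksums": {},
        "metrics": {},
    }
    erm = EnergyRangeModel()

    # stage 1: geometry + source
    hu, masks = _build_phantom(config["phantom"], seed)
    source = _build_source(config["beam"])

    # stage 2: HU-density calibration
    table = build_hu_density_table(fixture_hu_density_curve())
    density = densify(hu, table)
    write_hu_density_table_csv(out / "hu_density_table.csv", table)
    report["artifacts"]["hu_density_table"] = "hu_density_table.csv"
    report["metrics"]["hu_density_intervals"] = len(table)

    # stage 3: dose (and LETd for the MC engine)
    letd = None
    if eng["type"] == "analytic":
        dose = analytic_dose(density, source, erm)
    else:
        dose, letd = mc_dose(
            density, source, erm, n_primaries=int(eng["n_primaries"]), seed=seed
        )
    grids = {"hu": hu, "density": density, "dose": dose}
    if letd is not None:
        grids["letd"] = letd
    for name, mgrid in masks.items():
        grids[f"mask_{name}"] = mgrid

    # stage 4: range metrics on the integrated depth-dose (unrotated beams)
    if float(config["beam"].get("gantry_angle_deg", 0.0)) == 0.0:
        curve = depth_dose_from_grid(dose, density, mode="idd")
        try:
            rm = extract_range_metrics(curve)
            report["metrics"]["range_cm"] = {
                "r100": rm.r100, "r90": rm.r90, "r80": rm.r80, "r20": rm.r20
            }
        except ValueError:
            report["metrics"]["range_cm"] = None  # curve does not fall off in-grid

    # stage 5: dose scaling + RBE models
    rb = config.get("radiobiology")
    if rb:
        total_gy = float(rb.get("total_course_gy", 0.0))
        if total_gy > 0:
            presc = rb.get("prescription_structure")
            if presc and presc in masks:
                in_struct = dose.values[masks[presc].values > 0]
                ref = float(np.median(in_struct))
                if ref <= 0:  # field covers only part of the structure
                    ref = float(in_struct.max())
            else:
                ref = float(dose.values.max())
            if ref <= 0:
                ref = float(dose.values.max())
            scale = total_gy / ref if ref > 0 else 0.0
        else:
            scale = 1.0
        course = dose.like(dose.values * scale, "dose", {"unit": "Gy"})
        grids["dose_total"] = course
        for model in rb.get("models", []):
            params = RadiobiologyParams(
                model=model,
                n_fractions=int(rb.get("n_fractions", 1)),
                alpha_beta_gy=float(rb.get("alpha_beta_gy", 3.0)),
                q=float(rb.get("q", 0.434)),
            )
            grids[f"rbe_dose_{model}"] = rbe_weighted_dose(course, letd, params)

    # stage 6: plan metrics
    ev = config.get("evaluation", {})
    for struct in ev.get("structures", []):
        m = masks[struct]
        smet: dict = {}
        dose_grid = grids.get("dose_total", dose)
        if ev.get("dvh", True):
            dvh = cumulative_histogram(dose_grid, m, bin_width=0.1)
            write_histogram_csv(out / f"dvh_{struct}.csv", dvh)
            report["artifacts"][f"dvh_{struct}"] = f"dvh_{struct}.csv"
        if letd is not None and ev.get("lvh", True):
            reached = (m.values > 0) & (letd.values >= 0)
            if np.any(reached):
                lvh = cumulative_histogram(letd, m, bin_width=0.1)
                write_histogram_csv(out / f"lvh_{struct}.csv", lvh)
                report["artifacts"][f"lvh_{struct}"] = f"lvh_{struct}.csv"
                smet["mean_letd_kev_um"] = float(np.mean(letd.values[reached]))
            else:
                smet["lvh"] = "skipped: structure receives no dose"
        for v in ev.get("d_v_cm3", []):
            for name, g in grids.items():
                if name.startswith("rbe_dose_") or name == "dose_total":
                    smet[f"d{v}cm3_gy::{name}"] = dose_at_volume(g, m, float(v))
        for x in ev.get("v_x_gy", []):
            for name, g in grids.items():
                if name.startswith("rbe_dose_") or name == "dose_total":
                    smet[f"v{x}gy_pct::{name}"] = volume_at_dose(g, m, float(x))
        report["metrics"][struct] = smet

    for pair in ev.get("gamma_pairs", []):
        ref = grids.get(pair["reference"]) or read_grid(pair["reference"])
        evl = grids.get(pair["evaluated"]) or read_grid(pair["evaluated"])
        res = gamma_analysis(
            ref, evl,
            dose_pct=float(pair.get("dose_pct", 3.0)),
            dta_mm=float(pair.get("dta_mm", 3.0)),
            low_threshold_pct=float(pair.get("low_threshold_pct", 5.0)),
            shift_search=bool(pair.get("shift_search", False)),
        )
        report["metrics"][f"gamma::{pair['reference']}::{pair['evaluated']}"] = {
            "pass_rate_pct": res.pass_rate,
            "criteria": list(res.criteria),
            "points": res.evaluated_points,
        }

    # artifacts + checksums
    for name, g in grids.items():
        fname = f"{name}.nrrd"
        write_grid(out / fname, g)
        report["artifacts"][name] = fname
        report["checksums"][name] = _sha256(g.values)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "report.txt", "w") as fh:
        fh.write(_format_report(report))
    with open(out / "config_used.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return report


def _format_report(report: dict) -> str:
    lines = [
        f"protonpbs {report['version']} run report",
        f"seed: {report['seed']}",
        "",
        "metrics:",
    ]
    def walk(d, indent=2):
        for k, v in d.items():
            if isinstance(v, dict):
                lines.append(" " * indent + f"{k}:")
                walk(v, indent + 2)
            else:
                lines.append(" " * indent + f"{k}: {v}")
    walk(report["metrics"])
    lines.append("")
    lines.append("artifacts: " + ", ".join(sorted(report["artifacts"].values())))
    return "\n".join(lines) + "\n"
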