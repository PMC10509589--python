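"""End-to-end experiment orchestration.

A run takes a configuration (YAML or :class:`RunConfig`) plus per-case data
and produces a fixed set of text artefacts in ``out_dir``:

* ``targets.csv``        — central pressure targets from the brachial cuff pair
* ``wk3_params.csv``     — tuned Windkessel parameters per outlet and case
* ``ivp_summary.csv``    — stroke volume / peak flow per inlet-condition case
* ``wss_by_region.csv``  — mean shear indices per case and wall region
* ``wss_differences.csv``— per-index difference statistics of each case
  against the baseline case
* ``helicity.csv``       — h1/h2/h3 per case, region and cycle window
* ``clinical.csv``       — transmural pressure and false-lumen ejection
  fraction per case (when tear/pressure data are available)
* ``provenance.json``    — configuration echo and input digests; contains no
  timestamps, so repeated runs are byte-identical

Cases are named inlet variants; the canonical four are ``4d`` (baseline),
``flat``, ``tp`` and ``scaled``.  Velocity fields are the caller's CFD
results (or synthetic stand-ins); this package post-processes them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, helicity, wss
from .fields import (
    FieldError,
    FluidProperties,
    SubdomainMask,
    TimeGrid,
    VelocityField,
)
from .io import read_waveform
from .ivp import InletProfile, make_flat_ivp, make_tp_ivp, scale_ivp
from .windkessel import (
    TuningResult,
    derive_pressure_targets,
    retune_scaled,
    tune_wk3,
)

CANONICAL_CASES = ("4d", "flat", "tp", "scaled")
_FLOAT_FMT = "%.10g"


@dataclass
class CaseData:
    """All per-case inputs the pipeline can consume.  Every piece is
    optional; tables that need a missing piece are skipped for that case."""

    name: str
    field: VelocityField | None = None
    inlet: InletProfile | None = None
    mask: SubdomainMask | None = None
    q_inlet_ml_s: np.ndarray | None = None  # inflow waveform at snapshots
    q_tear_ml_s: np.ndarray | None = None  # tear flux, normal TL -> FL
    p_tl_mmhg: np.ndarray | None = None  # (n_t,) at the paired station
    p_fl_mmhg: np.ndarray | None = None
    stroke_volume_ml: float | None = None


@dataclass
class RunConfig:
    """Experiment configuration.

    ``outlets`` maps outlet name to ``{"q_mean": ml/s, "rho": R1/(R1+R2)}``.
    The inflow waveform may be given inline (times/values) or as a CSV path
    relative to the config file.
    """

    out_dir: str
    brachial_ps: float
    brachial_pd: float
    period: float
    outlets: dict = dc_field(default_factory=dict)
    inflow_times: list | None = None
    inflow_values: list | None = None
    inflow_csv: str | None = None
    scale_factor: float = 1.25
    baseline_case: str = "4d"
    fluid: dict = dc_field(default_factory=dict)
    wk3_dt: float = 1e-3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise FieldError(f"config {path} is not a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise FieldError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.inflow_csv is not None:
            t, v = read_waveform(path.parent / cfg.inflow_csv)
            cfg.inflow_times, cfg.inflow_values = list(t), list(v)
        return cfg

    def fluid_properties(self) -> FluidProperties:
        return FluidProperties(**self.fluid)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def derive_cases(reference: InletProfile, scale_factor: float = 1.25) -> dict[str, InletProfile]:
    """The canonical four inlet variants from one reference (4D) profile."""
    return {
        "4d": reference,
        "flat": make_flat_ivp(reference),
        "tp": make_tp_ivp(reference),
        "scaled": scale_ivp(reference, scale_factor),
    }


def _tune_outlets(cfg: RunConfig, times, values) -> dict[str, TuningResult]:
    q_targets = {k: float(v["q_mean"]) for k, v in cfg.outlets.items()}
    rho = {k: float(v["rho"]) for k, v in cfg.outlets.items()}
    targets = derive_pressure_targets(cfg.brachial_ps, cfg.brachial_pd)
    ref = tune_wk3(times, values, cfg.period, targets, q_targets, rho, dt=cfg.wk3_dt)
    scaled = retune_scaled(
        times,
        np.asarray(values) * cfg.scale_factor,
        cfg.period,
        targets,
        q_targets,
        rho,
        factor=cfg.scale_factor,
        dt=cfg.wk3_dt,
    )
    return {"reference": ref, "scaled": scaled}


def run_experiment(
    cfg: RunConfig,
    cases: list[CaseData],
    config_path: str | Path | None = None,
) -> dict:
    """Execute the full post-processing pipeline and write all artefacts.

    Returns a dict of the in-memory tables keyed by artefact name.  Cases
    missing the data needed for a table simply do not contribute rows to it;
    an entirely empty table is still written (header only) so downstream
    consumers see a stable file set.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fluid = cfg.fluid_properties()
    tables: dict[str, pd.DataFrame] = {}

    # -- pressure targets -------------------------------------------------
    targets = derive_pressure_targets(cfg.brachial_ps, cfg.brachial_pd)
    tables["targets"] = pd.DataFrame(
        [
            {
                "brachial_ps_mmhg": cfg.brachial_ps,
                "brachial_pd_mmhg": cfg.brachial_pd,
                "central_ps_mmhg": targets.ps,
                "central_pd_mmhg": targets.pd,
                "pulse_mmhg": targets.pulse,
                "map_mmhg": targets.map,
            }
        ]
    )

    # -- Windkessel tuning -------------------------------------------------
    wk_rows = []
    if cfg.outlets and cfg.inflow_times is not None:
        tuned = _tune_outlets(cfg, np.asarray(cfg.inflow_times), np.asarray(cfg.inflow_values))
        for case_name, result in tuned.items():
            for p in result.params:
                wk_rows.append(
                    {
                        "case": case_name,
                        "outlet": p.name,
                        "r1_mmhg_s_ml": p.r1,
                        "r2_mmhg_s_ml": p.r2,
                        "c_ml_mmhg": p.c,
                        "q_target_ml_s": p.q_target,
                        "achieved_ps_mmhg": result.achieved_ps,
                        "achieved_pd_mmhg": result.achieved_pd,
                    }
                )
    tables["wk3_params"] = pd.DataFrame(
        wk_rows,
        columns=[
            "case",
            "outlet",
            "r1_mmhg_s_ml",
            "r2_mmhg_s_ml",
            "c_ml_mmhg",
            "q_target_ml_s",
            "achieved_ps_mmhg",
            "achieved_pd_mmhg",
        ],
    )

    # -- inlet summaries ---------------------------------------------------
    ivp_rows = []
    for case in cases:
        if case.inlet is not None:
            q = case.inlet.flux_series()
            sv = case.inlet.stroke_volume_ml()
        elif case.q_inlet_ml_s is not None and case.field is not None:
            q = np.asarray(case.q_inlet_ml_s, dtype=np.float64)
            sv = float(q.sum() * case.field.grid.dt)
        else:
            continue
        ivp_rows.append(
            {
                "case": case.name,
                "stroke_volume_ml": sv,
                "peak_flow_ml_s": float(q.max()),
                "mean_flow_ml_s": float(q.mean()),
            }
        )
    tables["ivp_summary"] = pd.DataFrame(
        ivp_rows, columns=["case", "stroke_volume_ml", "peak_flow_ml_s", "mean_flow_ml_s"]
    )

    # -- wall shear indices ------------------------------------------------
    maps_by_case: dict[str, wss.WallIndexMaps] = {}
    wss_rows = []
    for case in cases:
        if case.field is None:
            continue
        tau = wss.wall_shear_from_field(case.field, fluid)
        maps = wss.compute_wss_indices(tau)
        maps_by_case[case.name] = maps
        regions = _wall_regions(case)
        for region, node_mask in regions.items():
            row = {"case": case.name, "region": region, "n_nodes": int(node_mask.sum())}
            for name in wss.WallIndexMaps.INDEX_NAMES:
                vals = getattr(maps, name)[node_mask]
                vals = vals[np.isfinite(vals)]
                row[name] = float(vals.mean()) if len(vals) else np.nan
            wss_rows.append(row)
    tables["wss_by_region"] = pd.DataFrame(
        wss_rows, columns=["case", "region", "n_nodes", *wss.WallIndexMaps.INDEX_NAMES]
    )

    diff_frames = []
    base = maps_by_case.get(cfg.baseline_case)
    if base is not None:
        for name, maps in maps_by_case.items():
            if name == cfg.baseline_case:
                continue
            d = wss.difference_stats(maps, base)
            d.insert(0, "case", name)
            d.insert(1, "baseline", cfg.baseline_case)
            diff_frames.append(d)
    tables["wss_differences"] = (
        pd.concat(diff_frames, ignore_index=True)
        if diff_frames
        else pd.DataFrame(
            columns=[
                "case",
                "baseline",
                "index",
                "min",
                "max",
                "mean",
                "mean_pct",
                "mean_pct_of_means",
                "n_nodes",
            ]
        )
    )

    # -- helicity ------------------------------------------------------------
    hel_frames = []
    for case in cases:
        if case.field is None:
            continue
        windows = helicity.default_windows(case.field.grid, case.q_inlet_ml_s)
        h = helicity.bulk_helicity_indices(case.field, case.mask, windows)
        h.insert(0, "case", case.name)
        hel_frames.append(h)
    tables["helicity"] = (
        pd.concat(hel_frames, ignore_index=True)
        if hel_frames
        else pd.DataFrame(columns=["case", "region", "window", "h1", "h2", "h3"])
    )

    # -- clinical metrics ------------------------------------------------------
    clin_rows = []
    for case in cases:
        row = {"case": case.name}
        have = False
        grid = case.field.grid if case.field is not None else None
        if grid is None and case.inlet is not None:
            grid = case.inlet.grid
        if grid is not None and case.p_tl_mmhg is not None and case.p_fl_mmhg is not None:
            tmp = compare.transmural_pressure(grid, case.p_tl_mmhg, case.p_fl_mmhg)
            row["mean_tmp_mmhg"] = tmp["mean_tmp_mmhg"]
            have = True
        if grid is not None and case.q_tear_ml_s is not None and case.stroke_volume_ml:
            fl = compare.false_lumen_ejection_fraction(
                grid, case.q_tear_ml_s, case.stroke_volume_ml
            )
            row["flef_pct"] = fl["flef_pct"]
            row["retrograde_volume_ml"] = fl["retrograde_volume_ml"]
            have = True
        if have:
            clin_rows.append(row)
    tables["clinical"] = pd.DataFrame(
        clin_rows, columns=["case", "mean_tmp_mmhg", "flef_pct", "retrograde_volume_ml"]
    )

    # -- write artefacts --------------------------------------------------------
    for name, df in tables.items():
        _write_csv(df, out / f"{name}.csv")
    provenance = {
        # out_dir is excluded so reruns into different directories stay
        # byte-identical; inflow arrays are summarized by their length
        "config": {
            k: getattr(cfg, k)
            for k in cfg.__dataclass_fields__
            if k not in ("inflow_times", "inflow_values", "out_dir")
        },
        "n_inflow_samples": len(cfg.inflow_times) if cfg.inflow_times is not None else 0,
        "cases": [c.name for c in cases],
        "artefacts": sorted(f"{n}.csv" for n in tables),
    }
    if config_path is not None:
        provenance["config_file"] = {
            "name": Path(config_path).name,
            "sha256": _sha256(Path(config_path)),
        }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return tables


def _wall_regions(case: CaseData) -> dict[str, np.ndarray]:
    """Wall-node region masks for a case: per subdomain label when a cell
    mask exists (a wall node belongs to a region if any adjacent labelled
    cell does), else a single 'whole' region."""
    mesh = case.field.mesh
    wall_ids = mesh.wall_node_ids
    if case.mask is None:
        return {"whole": np.ones(len(wall_ids), dtype=bool)}
    out = {}
    for label in case.mask.used_labels:
        cells = case.mask.cells(label)
        nodes = np.unique(mesh.tets[cells])
        member = np.zeros(len(mesh.points), dtype=bool)
        member[nodes] = True
        out[label] = member[wall_ids]
    return out


def demo_cases(seed: int = 0) -> tuple[RunConfig, list[CaseData]]:
    """A small, fully synthetic experiment: a two-lumen dissection phantom
    as the baseline case and a flow-scaled variant, with a two-outlet
    Windkessel calibration.  Deterministic for a fixed seed."""
    from .synthetic import PhantomSpec, two_lumen_phantom

    spec = PhantomSpec(n_rings=3, n_theta=12, n_axial=6, n_snapshots=16)
    ph = two_lumen_phantom(spec)
    rng = np.random.default_rng(seed)
    q_in = ph.stroke_volume_ml / spec.period * (
        1.0 + 0.8 * np.sin(2 * np.pi * ph.grid.times / spec.period)
    )
    # the config's inflow waveform gets slight reproducible jitter so the
    # Windkessel tuner faces a non-idealized input
    jitter = 1.0 + 0.01 * rng.standard_normal(len(q_in))
    q_cfg = q_in * jitter
    q_mean = float(q_cfg.mean())
    cfg = RunConfig(
        out_dir="demo_out",
        brachial_ps=138.0,
        brachial_pd=81.0,
        period=spec.period,
        outlets={
            "upper": {"q_mean": 0.3 * q_mean, "rho": 0.1},
            "lower": {"q_mean": 0.7 * q_mean, "rho": 0.1},
        },
        inflow_times=list(ph.grid.times),
        inflow_values=list(q_cfg),
        baseline_case="phantom",
    )
    scaled_field = VelocityField(ph.mesh, ph.grid, ph.field.values * 1.25)
    cases = [
        CaseData(
            name="phantom",
            field=ph.field,
            mask=ph.mask,
            q_inlet_ml_s=q_in,
            q_tear_ml_s=ph.tear_flow,
            p_tl_mmhg=ph.p_tl[:, 0],
            p_fl_mmhg=ph.p_fl[:, 0],
            stroke_volume_ml=ph.stroke_volume_ml,
        ),
        CaseData(
            name="scaled",
            field=scaled_field,
            mask=ph.mask,
            q_inlet_ml_s=q_in * 1.25,
            q_tear_ml_s=ph.tear_flow * 1.25,
            p_tl_mmhg=ph.p_tl[:, 0],
            p_fl_mmhg=ph.p_fl[:, 0],
            stroke_volume_ml=ph.stroke_volume_ml * 1.25,
        ),
    ]
    return cfg, cases
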