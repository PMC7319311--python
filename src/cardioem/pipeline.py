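"""End-to-end pipeline orchestration, configuration, reporting and logging.

A pipeline run takes a configuration (nested dict, typically from YAML),
builds or loads a mesh, then executes the enabled stages in method order —
surfaces → fibres → ventricular coordinates → eikonal activation → free
contraction → anatomical metrics — and emits a :class:`ReportRow` in the
style of the cohort summary tables (counts, quality, LAT, EF/SV, anatomy).

Configuration is strict: unknown keys are rejected, every default is logged
with its provenance (default vs user override), and a run is deterministic
given its configuration.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .eikonal_ep import StimulusProtocol, build_conduction, lat_statistics, solve_eikonal
from .fibres_uvc import (
    FibreRule,
    assign_fibres,
    cavity_volume,
    compute_uvc,
    long_axis_lengths,
    lv_diameter,
    valve_area,
)
from .mechanics import (
    ActiveTensionParams,
    ContractionSchedule,
    GuccioneParams,
    MaterialConfig,
    default_lv_bcs,
    ef_sv,
    run_contraction,
)
from .mesh_core import (
    LabelSchema,
    edge_length_stats,
    extract_surfaces,
    read_mesh,
    scaled_jacobian,
    write_mesh,
)
from .synthetic_anatomy import EllipsoidSpec, SlabSpec, generate_biventricular, generate_lv_ellipsoid, generate_slab, place_electrode

__all__ = ["PipelineConfig", "ReportRow", "run_pipeline", "summarize_cohort", "DEFAULT_CONFIG"]

log = logging.getLogger("cardioem.pipeline")


DEFAULT_CONFIG: dict = {
    "mesh": {
        "source": "synthetic_lv",  # synthetic_lv | synthetic_biv | slab | carp_txt | vtk
        "path": None,  # input prefix/path for carp_txt / vtk sources
        "id": "synthetic_lv",
        "a_endo": 30.0,
        "b_endo": 30.0,
        "c_endo": 75.0,
        "wall_thickness": 9.0,
        "truncation_fraction": 0.25,
        "edge_length": 6.0,
        "min_transmural_layers": 3,
        "slab_extents": [60.0, 20.0, 20.0],
    },
    "stages": {
        "fibres": True,
        "uvc": True,
        "activation": True,
        "mechanics": True,
        "metrics": True,
    },
    "fibres": {
        "alpha_endo": 80.0,
        "alpha_epi": -60.0,
        "beta_endo": -65.0,
        "beta_epi": 25.0,
    },
    "conduction": {
        "v_l": 0.6,  # mm/ms
        "v_t": 0.24,
        "fast_layer_factor": 2.0,
    },
    "stimulus": {
        "mode": "apical",  # apical | label
        "label": "electrode_endo_rv",
        "radius": 5.0,
        "onset": 0.0,
        "duration": 2.0,
    },
    "mechanics": {
        "dt": 5.0,
        "t_end": 700.0,
        "healthy_variant": False,
        "k_spring": 10.0,
        "k_peri": 1.0,
        "T_peak": 125.0,
        "t_emd": 20.0,
        "t_dur": 550.0,
        "tau_r": 130.0,
        "tau_d": 100.0,
    },
    "output": {
        "dir": None,  # artifacts written here when set
        "write_vtk": False,
    },
    "seed": 0,  # reserved for optional jitter; generation is deterministic
}


class PipelineConfig(dict):
    """Validated pipeline configuration (a nested dict with strict keys)."""

    @classmethod
    def with_defaults(cls, overrides: dict | None = None) -> "PipelineConfig":
        cfg = copy.deepcopy(DEFAULT_CONFIG)
        provenance = {}

        def merge(dst, src, path=""):
            for key, val in src.items():
                here = f"{path}{key}"
                if key not in dst:
                    raise KeyError(f"unknown configuration key: {here!r}")
                if isinstance(dst[key], dict) and isinstance(val, dict):
                    merge(dst[key], val, here + ".")
                else:
                    dst[key] = val
                    provenance[here] = "override"

        if overrides:
            merge(cfg, overrides)
        out = cls(cfg)
        out.provenance = provenance
        return out

    def log_parameters(self) -> list[str]:
        """One line per leaf parameter, with provenance tag."""
        lines = []

        def walk(d, path=""):
            for k in sorted(d):
                v = d[k]
                here = f"{path}{k}"
                if isinstance(v, dict):
                    walk(v, here + ".")
                else:
                    tag = getattr(self, "provenance", {}).get(here, "default")
                    lines.append(f"{here} = {v!r}  [{tag}]")

        walk(self)
        return lines


@dataclass
class ReportRow:
    """One mesh's summary in the cohort-table layout (ms / % / mL / mm)."""

    mesh_id: str
    n_nodes: int
    n_elems: int
    sj_mean: float = np.nan
    sj_sd: float = np.nan
    edge_mean_mm: float = np.nan
    edge_sd_mm: float = np.nan
    lv_lat_ms: float = np.nan
    rv_lat_ms: float = np.nan
    lv_ef_pct: float = np.nan
    lv_sv_ml: float = np.nan
    lv_edv_ml: float = np.nan
    lv_diameter_mm: float = np.nan
    lv_long_axis_mm: float = np.nan
    mitral_area_mm2: float = np.nan

    _FLOAT_FMT = "%.4f"

    def to_text(self) -> str:
        parts = [f"mesh_id\t{self.mesh_id}"]
        for name, val in asdict(self).items():
            if name == "mesh_id":
                continue
            if isinstance(val, (int, np.integer)):
                parts.append(f"{name}\t{val}")
            else:
                parts.append(f"{name}\t{self._FLOAT_FMT % val}")
        return "\n".join(parts) + "\n"

    @staticmethod
    def tsv_header() -> str:
        return "\t".join(ReportRow("", 0, 0).__dataclass_fields__.keys())

    def to_tsv(self) -> str:
        vals = []
        for name, val in asdict(self).items():
            if isinstance(val, str):
                vals.append(val)
            elif isinstance(val, (int, np.integer)):
                vals.append(str(val))
            else:
                vals.append(self._FLOAT_FMT % val)
        return "\t".join(vals)


def _build_mesh(cfg: dict):
    m = cfg["mesh"]
    src = m["source"]
    if src == "synthetic_lv":
        spec = EllipsoidSpec(
            a_endo=m["a_endo"],
            b_endo=m["b_endo"],
            c_endo=m["c_endo"],
            wall_thickness=m["wall_thickness"],
            truncation_fraction=m["truncation_fraction"],
            edge_length=m["edge_length"],
            min_transmural_layers=m["min_transmural_layers"],
        )
        mesh, surfaces = generate_lv_ellipsoid(spec)
        schema = LabelSchema.lv_only()
    elif src == "synthetic_biv":
        spec = EllipsoidSpec(
            a_endo=m["a_endo"],
            b_endo=m["b_endo"],
            c_endo=m["c_endo"],
            wall_thickness=m["wall_thickness"],
            truncation_fraction=m["truncation_fraction"],
            edge_length=m["edge_length"],
            min_transmural_layers=m["min_transmural_layers"],
        )
        mesh, surfaces = generate_biventricular(spec)
        schema = LabelSchema.biventricular()
    elif src == "slab":
        mesh = generate_slab(SlabSpec(extents=tuple(m["slab_extents"]), edge_length=m["edge_length"]))
        surfaces = None
        schema = None
    elif src in ("carp_txt", "vtk"):
        if not m["path"]:
            raise ValueError("mesh.path required for carp_txt/vtk sources")
        mesh = read_mesh(m["path"], format=src)
        schema = LabelSchema.four_chamber()
        surfaces = extract_surfaces(mesh, schema)
    else:
        raise ValueError(f"unknown mesh source {src!r}")
    return mesh, surfaces, schema


def run_pipeline(config: dict | PipelineConfig) -> tuple[ReportRow, dict]:
    """Execute the enabled stages; returns the report row and artifacts.

    Artifacts is a dict with the in-memory products of each stage (mesh,
    surfaces, uvc, activation map, motion trace) plus any files written.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.with_defaults(config)
    for line in config.log_parameters():
        log.info("config: %s", line)

    mesh, surfaces, schema = _build_mesh(config)
    stages = config["stages"]
    artifacts: dict = {"mesh": mesh, "surfaces": surfaces}

    sj, sj_summary = scaled_jacobian(mesh)
    edge_mean, edge_sd, _ = edge_length_stats(mesh)
    row = ReportRow(
        mesh_id=config["mesh"]["id"],
        n_nodes=mesh.n_nodes,
        n_elems=mesh.n_elems,
        sj_mean=sj_summary["mean"],
        sj_sd=sj_summary["sd"],
        edge_mean_mm=edge_mean,
        edge_sd_mm=edge_sd,
    )

    if stages["fibres"] and surfaces is not None:
        f = config["fibres"]
        rule = FibreRule(f["alpha_endo"], f["alpha_epi"], f["beta_endo"], f["beta_epi"])
        assign_fibres(mesh, surfaces, rule)
        log.info("fibres assigned (alpha %s/%s, beta %s/%s)",
                 f["alpha_endo"], f["alpha_epi"], f["beta_endo"], f["beta_epi"])

    uvc = None
    if stages["uvc"] and surfaces is not None:
        uvc = compute_uvc(mesh, surfaces)
        uvc.attach(mesh)
        artifacts["uvc"] = uvc

    amap = None
    if stages["activation"]:
        c = config["conduction"]
        cond = build_conduction(
            mesh,
            surfaces,
            v_l=c["v_l"],
            v_t=c["v_t"],
            fast_layer_factor=c["fast_layer_factor"],
        )
        s = config["stimulus"]
        if s["mode"] == "label":
            stim = StimulusProtocol.from_label(
                mesh, s["label"], onset=s["onset"], duration=s["duration"]
            )
        else:  # apical endocardial electrode
            endo = surfaces.nodes_of("rv_endo" if "rv_endo" in surfaces.surfaces else "lv_endo")
            apex_pt = mesh.nodes[surfaces.node_sets["apex"][0]] if "apex" in surfaces.node_sets else mesh.nodes[endo].mean(axis=0)
            d = np.linalg.norm(mesh.nodes[endo] - apex_pt, axis=1)
            place_electrode(mesh, surfaces, mesh.nodes[endo[np.argmin(d)]], s["radius"])
            stim = StimulusProtocol.from_label(mesh, onset=s["onset"], duration=s["duration"])
        amap = solve_eikonal(mesh, cond, stim)
        artifacts["activation"] = amap
        lat = lat_statistics(amap, mesh)
        row.lv_lat_ms = lat.get("lv_lat", np.nan)
        row.rv_lat_ms = lat.get("rv_lat", np.nan)

    if stages["mechanics"] and amap is not None and surfaces is not None:
        mc = config["mechanics"]
        if schema is not None and schema.rv is not None and 2 in np.unique(mesh.elem_tags):
            mats = MaterialConfig.biventricular_defaults()
        elif schema is not None and len(schema.tags) > 4:
            mats = MaterialConfig.four_chamber_defaults()
        else:
            mats = MaterialConfig.lv_defaults()
        ta = ActiveTensionParams(mc["T_peak"], mc["t_emd"], mc["t_dur"], mc["tau_r"], mc["tau_d"])
        mats.active = {t: ta for t in mats.active}
        if mc["healthy_variant"]:
            g = GuccioneParams.healthy()
            mats.passive = {t: (g if isinstance(p, GuccioneParams) else p) for t, p in mats.passive.items()}
        bcs = default_lv_bcs(mesh, surfaces, k_spring=mc["k_spring"], k_peri=mc["k_peri"])
        trace = run_contraction(
            mesh,
            surfaces,
            mats,
            bcs,
            amap,
            ContractionSchedule(dt=mc["dt"], t_end=mc["t_end"]),
        )
        artifacts["trace"] = trace
        res = ef_sv(trace)["lv"]
        row.lv_ef_pct = res["EF_pct"]
        row.lv_sv_ml = res["SV_mL"]
        row.lv_edv_ml = res["EDV_mL"]

    if stages["metrics"] and surfaces is not None:
        row.lv_edv_ml = cavity_volume(surfaces, "lv") if np.isnan(row.lv_edv_ml) else row.lv_edv_ml
        if uvc is not None:
            try:
                row.lv_diameter_mm = lv_diameter(mesh, uvc)
            except ValueError as exc:
                log.warning("lv_diameter unavailable: %s", exc)
        la = long_axis_lengths(mesh, surfaces)
        row.lv_long_axis_mm = la["lv"]
        if "mitral_plane" in surfaces.surfaces:
            row.mitral_area_mm2 = valve_area(surfaces, "mitral")

    out = config["output"]
    if out["dir"]:
        d = Path(out["dir"])
        d.mkdir(parents=True, exist_ok=True)
        write_mesh(mesh, d / config["mesh"]["id"], format="carp_txt")
        if out["write_vtk"]:
            write_mesh(mesh, d / config["mesh"]["id"], format="vtk")
        (d / "report.txt").write_text(row.to_text())
        (d / "report.tsv").write_text(ReportRow.tsv_header() + "\n" + row.to_tsv() + "\n")
        artifacts["report_path"] = d / "report.tsv"
    return row, artifacts


def summarize_cohort(rows: list[ReportRow]) -> dict[str, tuple[float, float]]:
    """Column-wise mean ± sample (n−1) standard deviation over report rows."""
    if not rows:
        raise ValueError("at least one report row required")
    out = {}
    for name in rows[0].__dataclass_fields__:
        if name == "mesh_id":
            continue
        vals = np.array([getattr(r, name) for r in rows], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[name] = (float(vals.mean()), sd)
    return out
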