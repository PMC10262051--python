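"""End-to-end study orchestration: simulate → extract → quantify → stats.

A study is described by a YAML config (see :class:`StudyConfig`); stages run
in order, each writing its outputs under the study's output directory before
the next starts, so a failing stage preserves everything upstream.  A run
log records the seed, package versions and every analysis setting, and a
fixed config + seed reproduces deterministic outputs bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cfio
from . import repstats, synth
from .geometry import extract_slice, project_velocity
from .quantify import ROISet, flow_metrics, flow_waveform, threshold_segment
from .repstats import PairedMeasurements, repeatability_result
from .studies import FLUX_SEGMENTATION, vessel_plane

__all__ = ["StudyConfig", "PipelineError", "run_pipeline", "write_report"]

log = logging.getLogger("cranioflow")

_DEFAULT_STAGES = ("simulate", "extract", "quantify", "repeatability")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class StudyConfig:
    """Declarative study description.

    ``simulate`` describes a phantom study (phantom name, acquisition
    parameters, number of sessions); alternatively ``volumes`` lists
    pre-existing per-session volume directories and ``planes`` a plane
    definition file.  ``quantify`` controls segmentation (or points ``rois``
    at a .npz mask file) and correction order; ``repeatability`` selects the
    paired design.
    """

    seed: int = 0
    output_dir: Path = Path("cranioflow_out")
    stages: tuple[str, ...] = _DEFAULT_STAGES
    simulate: dict = dc_field(default_factory=dict)
    volumes: list = dc_field(default_factory=list)
    planes: str | None = None
    extract: dict = dc_field(default_factory=dict)
    quantify: dict = dc_field(default_factory=dict)
    repeatability: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            seed=int(doc.get("seed", 0)),
            output_dir=Path(doc.get("output_dir", "cranioflow_out")),
            stages=tuple(doc.get("stages", _DEFAULT_STAGES)),
            simulate=doc.get("simulate", {}) or {},
            volumes=list(doc.get("volumes", []) or []),
            planes=doc.get("planes"),
            extract=doc.get("extract", {}) or {},
            quantify=doc.get("quantify", {}) or {},
            repeatability=doc.get("repeatability", {}) or {},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in self.volumes:
            if not Path(p).exists():
                raise FileNotFoundError(f"volume directory {p} does not exist")
        if self.planes is not None and not Path(self.planes).exists():
            raise FileNotFoundError(f"plane file {self.planes} does not exist")
        venc = self.quantify.get("venc")
        if venc is not None and venc <= 0:
            raise ValueError("quantify.venc must be positive")
        acq = self.simulate.get("acquisition", {})
        if acq.get("venc", 100.0) <= 0:
            raise ValueError("simulate.acquisition.venc must be positive")


def _stage_simulate(cfg: StudyConfig, state: dict) -> None:
    sim = cfg.simulate
    phantom = sim.get("phantom", "circle_of_willis")
    if phantom != "circle_of_willis":
        raise ValueError(f"unknown phantom {phantom!r}")
    vessels = synth.make_circle_of_willis_phantom(cfg.seed,
                                                  **sim.get("phantom_args", {}))
    acq = synth.cow_acquisition(**sim.get("acquisition", {}), seed=cfg.seed)
    n_sessions = int(sim.get("sessions", 1))

    clean = synth.rasterize(vessels, acq)
    rng = np.random.default_rng(cfg.seed)
    state["sessions"] = []
    for s in range(1, n_sessions + 1):
        measured = synth.corrupt(clean, acq, seed=int(rng.integers(2**31)))
        outdir = cfg.output_dir / "volumes" / f"session{s}"
        cfio.write_velocity_volume(measured, outdir)
        state["sessions"].append(outdir)

    planes = [vessel_plane(v, fov=sim.get("plane_fov", (12.0, 12.0)),
                           pixel_size=cfg.extract.get("pixel_size", 0.5))
              for v in vessels]
    planes_path = cfg.output_dir / "planes.yaml"
    cfio.write_planes(planes, planes_path)
    state["planes_path"] = planes_path

    truth = [synth.realize_waveform(v.waveform, name=v.name) for v in vessels]
    cfio.waveforms_to_frame([t.waveform for t in truth]).to_csv(
        cfg.output_dir / "ground_truth_waveforms.csv", index=False)
    cfio.metrics_to_frame([t.metrics for t in truth]).to_csv(
        cfg.output_dir / "ground_truth_metrics.csv", index=False)


def _stage_extract(cfg: StudyConfig, state: dict) -> None:
    session_dirs = state.get("sessions") or [Path(p) for p in cfg.volumes]
    if not session_dirs:
        raise ValueError("no volumes: run the simulate stage or list `volumes`")
    planes_path = state.get("planes_path") or cfg.planes
    if planes_path is None:
        raise ValueError("no plane definitions: provide `planes` or simulate")
    planes = cfio.read_planes(planes_path)
    pixel_size = cfg.extract.get("pixel_size")

    state["slices"] = []  # list over sessions of {vessel: ObliqueSlice}
    for s, vdir in enumerate(session_dirs, start=1):
        volume = cfio.read_velocity_volume(vdir)
        per_vessel = {}
        outdir = cfg.output_dir / "slices" / f"session{s}"
        for plane in planes:
            if pixel_size:
                plane = plane.with_pixel_size(pixel_size)
            slc = project_velocity(extract_slice(volume, plane))
            per_vessel[plane.name] = slc
            cfio.write_slice(slc, outdir, plane.name)
        state["slices"].append(per_vessel)


def _load_rois(path: str, vessel: str, shape) -> ROISet:
    data = np.load(path)
    try:
        return ROISet(vessel_mask=data[f"{vessel}_vessel"],
                      background_mask=data[f"{vessel}_background"], name=vessel)
    except KeyError as exc:
        raise ValueError(f"ROI file {path} lacks masks for vessel {vessel!r}") from exc


def _stage_quantify(cfg: StudyConfig, state: dict) -> None:
    if "slices" not in state:
        raise ValueError("no slices: run the extract stage first")
    q = cfg.quantify
    seg = dict(FLUX_SEGMENTATION)
    seg.update(q.get("segmentation", {}))
    rois_path = q.get("rois")
    if rois_path is not None and not Path(rois_path).exists():
        raise FileNotFoundError(f"ROI file {rois_path} does not exist")

    rows = []
    for s, per_vessel in enumerate(state["slices"], start=1):
        waveforms, metrics = [], []
        for vessel, slc in per_vessel.items():
            if rois_path is not None:
                rois = _load_rois(rois_path, vessel, slc.v_parallel.shape[:2])
            else:
                rois = threshold_segment(slc, name=vessel, **seg)
            w = flow_waveform(slc, rois, venc=q.get("venc"),
                              order=q.get("order", "unwrap_first"),
                              unwrap_aliasing=q.get("unwrap", True),
                              correct_background=q.get("correct_background", True))
            waveforms.append(w)
            metrics.append(flow_metrics(w, rois, slc.plane.pixel_size))
        outdir = cfg.output_dir / "metrics"
        outdir.mkdir(parents=True, exist_ok=True)
        cfio.waveforms_to_frame(waveforms).to_csv(
            outdir / f"waveforms_session{s}.csv", index=False)
        mdf = cfio.metrics_to_frame(metrics)
        mdf.insert(0, "session", s)
        mdf.to_csv(outdir / f"metrics_session{s}.csv", index=False)
        rows.append(mdf)
    state["metrics"] = pd.concat(rows, ignore_index=True)
    state["metrics"].to_csv(cfg.output_dir / "metrics" / "metrics_all.csv", index=False)


def _stage_repeatability(cfg: StudyConfig, state: dict) -> None:
    df = state.get("metrics")
    if df is None:
        raise ValueError("no metrics: run the quantify stage first")
    sessions = sorted(df["session"].unique())
    if len(sessions) < 2:
        raise ValueError("repeatability needs at least two sessions")
    a_ses, b_ses = sessions[0], sessions[1]
    quantities = cfg.repeatability.get("quantities", ["mean_flow", "pi"])
    colmap = {"mean_flow": "mean_flow_ml_s", "pi": "pi"}

    # pair session values across vessels (a single-phantom study has one
    # measurement per vessel per session; multi-subject studies pair across
    # subjects through repstats directly)
    rows = []
    for quantity in quantities:
        col = colmap.get(quantity, quantity)
        wide = df.pivot_table(index="vessel", columns="session", values=col)
        wide = wide.dropna()
        if len(wide) < 3:
            continue
        r = repeatability_result(PairedMeasurements(a=wide[a_ses].to_numpy(),
                                                    b=wide[b_ses].to_numpy(),
                                                    quantity=quantity))
        rows.append({"vessel": "all", "quantity": quantity, "icc": r.icc,
                     "icc_grade": r.icc_grade, "mean_diff": r.mean_diff,
                     "sd_diff": r.sd_diff, "loa_low": r.loa_low,
                     "loa_high": r.loa_high, "t_stat": r.t_stat,
                     "p_value": r.p_value,
                     "stars": repstats.significance_stars(r.p_value), "n": r.n})
    table = pd.DataFrame(rows, columns=["vessel", "quantity", "icc", "icc_grade",
                                        "mean_diff", "sd_diff", "loa_low", "loa_high",
                                        "t_stat", "p_value", "stars", "n"])
    write_report(table, cfg.output_dir / "tables", "repeatability")
    state["repeatability_table"] = table


_STAGES = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "quantify": _stage_quantify,
    "repeatability": _stage_repeatability,
}


def run_pipeline(cfg: StudyConfig) -> dict:
    """Execute the configured stages in order.

    Returns the in-memory stage state (paths, metrics table, repeatability
    table).  A stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages remain on disk.
    """
    cfg.validate()
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    timings = {}
    for stage in cfg.stages:
        if stage not in _STAGES:
            raise PipelineError(f"stage '{stage}': unknown stage")
        log.info("stage %s: starting", stage)
        t0 = time.perf_counter()
        try:
            _STAGES[stage](cfg, state)
        except Exception as exc:
            raise PipelineError(f"stage '{stage}': {exc}") from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.2fs", stage, timings[stage])

    from . import __version__

    run_log = {
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "timings_s": timings,
        "versions": {"cranioflow": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "settings": {
            "segmentation": {**FLUX_SEGMENTATION, **cfg.quantify.get("segmentation", {})},
            "order": cfg.quantify.get("order", "unwrap_first"),
            "simulate": cfg.simulate,
            "extract": cfg.extract,
            "repeatability": cfg.repeatability,
        },
    }
    (cfg.output_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return state


def write_report(table: pd.DataFrame, outdir: str | Path, name: str) -> tuple[Path, Path]:
    """Write a statistics table as CSV plus a human-readable markdown view.

    Significance markers live in their own column, never embedded in the
    numbers; ICC grades come straight from :func:`repstats.grade_icc`.  An
    empty table still produces headers.  The markdown footer notes that no
    multiple-testing correction is applied.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{name}.csv"
    md_path = outdir / f"{name}.md"
    table.to_csv(csv_path, index=False)

    lines = [f"# {name}", ""]
    cols = list(table.columns)
    lines.append("| " + " | ".join(cols) + " |")
    lines.append("|" + "---|" * len(cols))
    for _, row in table.iterrows():
        cells = [f"{v:.4g}" if isinstance(v, (int, float, np.floating)) and np.isfinite(v)
                 else str(v) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    lines += ["", "Stars: * p<0.05, ** p<0.01, *** p<0.001 (uncorrected; no "
              "multiple-testing adjustment is applied)."]
    md_path.write_text("\n".join(lines) + "\n")
    return csv_path, md_path
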