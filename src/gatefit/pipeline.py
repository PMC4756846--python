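"""End-to-end orchestration: config parsing and the full analysis pipeline.

A run reads an induction matrix (plus optional time courses, cytometry
events and calibration tables), performs per-axis four-parameter logistic
fits, the global AND-gate fit, truth-table/logic classification, contour
extraction and induction summaries, and writes every result as a CSV with
a provenance header plus a short human-readable report. A stage failure
aborts with the stage name; outputs written before the failure are renamed
with a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cytometry, fitting, io, kinetics, logic, quantitation

log = logging.getLogger("gatefit")

__all__ = ["RunConfig", "PipelineError", "parse_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    matrix: str | None = None
    matrix_dialect: str = "long"
    timecourse: str | None = None
    events: str | None = None
    events_reference: str | None = None
    calibration_standards: str | None = None
    calibration_samples: str | None = None
    outdir: str = "gatefit_out"
    seed: int = 0
    threshold: float = 0.10
    kinetic_window: tuple[float, float] = (0.0, 5.0)
    gating_method: str = "reference-quantile"
    shared_n: bool = True
    inverse_y_weighting: bool = False
    contour_levels: tuple[float, ...] = (0.10, 0.50, 0.90)
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        text = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


_BOOL = {"true": True, "yes": True, "1": True, "false": False, "no": False, "0": False}


def parse_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a flat ``key: value`` config file; keyword overrides win."""
    cfg = RunConfig()
    known = set(cfg.__dataclass_fields__) - {"extra"}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key not in known:
            cfg.extra[key] = value
            continue
        setattr(cfg, key, _coerce(key, value))
    for key, value in overrides.items():
        if value is not None:
            setattr(cfg, key, value)
    return cfg


def _coerce(key: str, value: str):
    if key in ("seed",):
        return int(value)
    if key in ("threshold",):
        return float(value)
    if key in ("shared_n", "inverse_y_weighting"):
        return _BOOL[value.lower()]
    if key in ("kinetic_window", "contour_levels"):
        return tuple(float(v) for v in value.replace(",", " ").split())
    return value


def run_pipeline(config: RunConfig) -> dict:
    """Run every applicable stage; returns the in-memory result bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = io.provenance_header(seed=config.seed, config_hash=config.config_hash())
    written: list[Path] = []
    results: dict = {}

    def emit(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path, header)
        written.append(path)

    def stage(name: str):
        log.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    for p in written:
                        p.rename(p.with_suffix(p.suffix + ".partial"))
                    raise PipelineError(name, exc) from exc

        return _Ctx()

    report_lines = [f"gatefit pipeline report (seed={config.seed})", ""]

    if config.matrix is not None:
        with stage("read_matrix"):
            m = io.read_matrix(config.matrix, dialect=config.matrix_dialect)
            results["matrix"] = m
        with stage("fit_4pl_slices"):
            slices = {}
            for axis, co_levels in (("I", m.p_levels), ("P", m.i_levels)):
                series = fitting.slice_matrix(m, axis, float(co_levels[-1]))
                fit = fitting.fit_four_pl(
                    series, inverse_y_weighting=config.inverse_y_weighting
                )
                slices[axis] = fit
                emit(f"fit4pl_{axis}.csv", io.write_fit_report, fit)
                if fit.converged:
                    report_lines.append(
                        f"4PL {axis}-axis at saturating co-inducer: "
                        f"EC50={fit.params.ec50:.4g} uM, n={fit.params.n:.4g}, "
                        f"DRLR={fit.drlr:.4g}"
                    )
            results["fits_4pl"] = slices
        with stage("global_fit"):
            gfit = fitting.fit_and_gate_global(m, shared_n=config.shared_n)
            results["global_fit"] = gfit
            emit("global_fit.csv", io.write_fit_report, gfit)
            if gfit.converged:
                report_lines.append(
                    f"Global AND-gate fit: K1={gfit.params.k1:.4g} uM, "
                    f"K2={gfit.params.k2:.4g} uM, n={gfit.params.n:.4g}, "
                    f"f1={gfit.params.f1:.4g} (enhancement "
                    f"{gfit.enhancement:.4g}x), rss={gfit.rss:.4g}, "
                    f"{gfit.start_points_tried} starts"
                )
            for w in gfit.warnings:
                report_lines.append(f"  warning: {w}")
        with stage("logic"):
            corners = logic.CornerOutputs.from_matrix(m)
            tt = logic.truth_table(corners, threshold=config.threshold)
            results["truth_table"] = tt
            df = pd.DataFrame(
                {
                    "state": ["(0,0)", "(1,0)", "(0,1)", "(1,1)"],
                    "d_out": [int(b) for b in tt.d_out],
                }
            )
            df["a_out"] = tt.a_out
            df["gate_label"] = tt.gate_label
            emit("truth_table.csv", io._write_with_header, df)
            report_lines.append(
                f"Truth table ({config.threshold:.0%} cut-off): gate={tt.gate_label}, "
                f"A-OUT={tt.a_out:.3g}"
            )
            summ = logic.induction_summary(m)
            results["induction"] = summ
            sdf = pd.DataFrame(
                [
                    {
                        "fold_induction": summ.fold_induction,
                        "basal_pct_of_max": summ.basal_fraction,
                        "unbounded": summ.unbounded,
                    }
                ]
            )
            emit("induction_summary.csv", io._write_with_header, sdf)
            report_lines.append(
                f"Fold induction (max/basal): {summ.fold_induction:.4g}; "
                f"basal = {summ.basal_fraction:.3g}% of max"
            )
        if results.get("global_fit") is not None and results["global_fit"].converged:
            with stage("contours"):
                cs = fitting.extract_contours(
                    results["global_fit"], levels=config.contour_levels
                )
                results["contours"] = cs
                emit("contours.csv", io.write_contours, cs)

    cal = None
    if config.calibration_standards and config.calibration_samples:
        with stage("calibration"):
            std = pd.read_csv(config.calibration_standards, comment="#")
            smp = pd.read_csv(config.calibration_samples, comment="#")
            cal = quantitation.fit_calibration(
                (std["ng"].to_numpy(), std["signal"].to_numpy()),
                (smp["rfu"].to_numpy(), smp["signal"].to_numpy()),
            )
            results["calibration"] = cal
            report_lines.append(
                f"Calibration: stage1 {cal.stage1.slope:.4g} signal/ng, "
                f"stage2 {cal.stage2.slope:.4g} RFU/ng "
                f"(valid {cal.valid_range[0]:.0f}-{cal.valid_range[1]:.0f} ng)"
            )

    if config.timecourse is not None:
        with stage("kinetics"):
            courses = io.read_timecourses(config.timecourse)
            rows = []
            for tc in courses:
                rf = kinetics.specific_rate(tc, window=config.kinetic_window)
                gf = kinetics.doubling_time(tc)
                row = dict(tc.condition)
                row.update(
                    specific_rate=rf.specific_rate,
                    r_squared=rf.r_squared,
                    mu=gf.mu,
                    doubling_time_h=gf.doubling_time,
                )
                if cal is not None:
                    od_mid = float(np.median(tc.od600))
                    row["volumetric_productivity_mg_l_h"] = (
                        kinetics.volumetric_productivity(rf, cal, od_mid)
                    )
                rows.append(row)
            rdf = pd.DataFrame(rows)
            results["rates"] = rdf
            emit("rates.csv", io._write_with_header, rdf)
            report_lines.append(f"Kinetics: {len(rows)} time course(s) fitted")

    if config.events is not None:
        with stage("cytometry"):
            sample = io.read_events(config.events)
            ref = (
                io.read_events(config.events_reference)
                if config.events_reference
                else None
            )
            thr = cytometry.gate_events(sample, reference=ref, method=config.gating_method)
            summaries = cytometry.population_summary(sample, thr)
            results["cytometry"] = summaries
            emit("cytometry.csv", io.write_gate_summaries, summaries)
            fl = next(g for g in summaries if g.gate_name == "fluorescent")
            report_lines.append(
                f"Cytometry: threshold {thr:.4g}, {fl.pct_events:.1f}% fluorescent"
            )

    with stage("report"):
        (outdir / "report.txt").write_text(header + "\n".join(report_lines) + "\n")
    results["report"] = report_lines
    return results
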