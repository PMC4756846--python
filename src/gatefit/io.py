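"""CSV readers and writers for every table the analysis consumes or emits.

Two matrix dialects are supported. Wide: the first row holds the P-inducer
levels (uM), the first column the I-inducer levels, the body the RFU/OD
responses; one file per replicate. Long: columns ``i_uM, p_uM, replicate,
rfu_per_od``; duplicate (i, p, replicate) combinations are rejected,
duplicate (i, p) rows across replicate ids become replicates. Concentration
units are uM throughout; long tables may carry an explicit ``unit`` column
(``uM`` or ``mM``) to declare otherwise.

All writers prepend a provenance comment header (version, seed, config
hash) so identical runs produce byte-identical outputs; readers skip
``#`` comment lines.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cytometry import EventSample, GateSummary
from .fitting import ContourSet, ExpressionMatrix, FourPLFit, GlobalFit
from .kinetics import TimeCourse

__all__ = [
    "MatrixParseError",
    "provenance_header",
    "read_matrix",
    "write_matrix",
    "read_timecourses",
    "write_timecourse",
    "read_events",
    "write_events",
    "write_fit_report",
    "write_contours",
    "write_gate_summaries",
]

_UNIT_FACTORS = {"uM": 1.0, "um": 1.0, "mM": 1000.0, "mm": 1000.0}


class MatrixParseError(ValueError):
    """A matrix CSV failed validation; the message carries line numbers."""


def provenance_header(seed: int | None = None, config_hash: str | None = None) -> str:
    lines = [f"# gatefit v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config_hash is not None:
        lines.append(f"# config_hash={config_hash}")
    return "\n".join(lines) + "\n"


def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", **kw)
    except pd.errors.ParserError as e:
        raise MatrixParseError(f"{path}: {e}") from e


def _check_numeric(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        coerced = pd.to_numeric(out[c], errors="coerce")
        bad = coerced.isna() & out[c].notna()
        if bad.any():
            rows = [int(r) + 2 for r in out.index[bad][:5]]  # 1-based + header
            raise MatrixParseError(
                f"non-numeric values in column {c!r} near line(s) {rows}"
            )
        out[c] = coerced
    return out


# ---------------------------------------------------------------------------
# expression matrices


def _read_matrix_wide(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = _read_csv(path, header=0, index_col=0)
    try:
        p_levels = df.columns.to_numpy(dtype=float)
        i_levels = df.index.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise MatrixParseError(
            f"{path}: wide dialect needs numeric P levels in row 1 and "
            f"numeric I levels in column 1 ({e})"
        ) from e
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        df2 = df.apply(pd.to_numeric, errors="coerce")
        bad = df2.isna() & df.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise MatrixParseError(
                f"{path}: non-numeric cell at data row {r + 2}, column {c + 2}"
            )
        vals = df2.to_numpy()
    return i_levels, p_levels, vals.astype(float)


def read_matrix(
    paths: str | Path | Sequence[str | Path], dialect: str = "wide"
) -> ExpressionMatrix:
    """Read an ExpressionMatrix from one or more CSV files.

    In the wide dialect each file is one replicate sheet and all sheets
    must share the same concentration grids. The long dialect reads a
    single file with a replicate column.
    """
    if dialect == "wide":
        if isinstance(paths, (str, Path)):
            paths = [paths]
        sheets = [_read_matrix_wide(p) for p in paths]
        i0, p0, _ = sheets[0]
        for pth, (i, p, _) in zip(paths, sheets):
            if not (np.array_equal(i, i0) and np.array_equal(p, p0)):
                raise MatrixParseError(
                    f"{pth}: replicate sheet grids differ from the first sheet"
                )
        values = np.stack([v for _, _, v in sheets], axis=2)
        return ExpressionMatrix(i_levels=i0, p_levels=p0, values=values)
    if dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r} (use 'wide' or 'long')")
    if not isinstance(paths, (str, Path)):
        raise ValueError("long dialect reads a single file")
    df = _read_csv(paths)
    required = {"i_uM", "p_uM", "rfu_per_od"}
    missing = required - set(df.columns)
    if missing:
        raise MatrixParseError(f"{paths}: missing column(s) {sorted(missing)}")
    df = _check_numeric(df, ["i_uM", "p_uM", "rfu_per_od"], paths)
    if "unit" in df.columns:
        factors = df["unit"].map(_UNIT_FACTORS)
        if factors.isna().any():
            raise MatrixParseError(f"{paths}: unknown unit values present")
        df["i_uM"] *= factors
        df["p_uM"] *= factors
    if "replicate" not in df.columns:
        df["replicate"] = df.groupby(["i_uM", "p_uM"]).cumcount()
    i_levels = np.unique(df["i_uM"].to_numpy())
    p_levels = np.unique(df["p_uM"].to_numpy())
    nrep = int(df.groupby(["i_uM", "p_uM"]).size().max())
    values = np.full((i_levels.size, p_levels.size, nrep), np.nan)
    for (iv, pv), grp in df.groupby(["i_uM", "p_uM"]):
        ii = int(np.searchsorted(i_levels, iv))
        pp = int(np.searchsorted(p_levels, pv))
        vals = grp["rfu_per_od"].to_numpy()
        values[ii, pp, : vals.size] = vals
    return ExpressionMatrix(i_levels=i_levels, p_levels=p_levels, values=values)


def write_matrix(
    m: ExpressionMatrix,
    path: str | Path,
    dialect: str = "long",
    header: str | None = None,
) -> None:
    """Write a matrix CSV; wide dialect writes one file per replicate
    (suffix ``_rep<k>`` inserted when there are several replicates)."""
    header = header or provenance_header()
    if dialect == "long":
        rows = []
        for ii, iv in enumerate(m.i_levels):
            for pp, pv in enumerate(m.p_levels):
                for rr in range(m.n_replicates):
                    v = m.values[ii, pp, rr]
                    if np.isfinite(v):
                        rows.append((iv, pv, rr, v))
        df = pd.DataFrame(rows, columns=["i_uM", "p_uM", "replicate", "rfu_per_od"])
        _write_with_header(df, path, header)
        return
    if dialect != "wide":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    for rr in range(m.n_replicates):
        df = pd.DataFrame(m.values[:, :, rr], index=m.i_levels, columns=m.p_levels)
        df.index.name = "i_uM"
        target = (
            path
            if m.n_replicates == 1
            else path.with_name(f"{path.stem}_rep{rr}{path.suffix}")
        )
        with open(target, "w") as fh:
            fh.write(header)
            df.to_csv(fh)


def _write_with_header(df: pd.DataFrame, path: str | Path, header: str) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# time courses


def read_timecourses(path: str | Path) -> list[TimeCourse]:
    """Read a long kinetics CSV into one TimeCourse per condition/replicate.

    Columns: ``time_h, rfu, od600`` plus optional ``i_uM, p_uM, temp_C,
    replicate`` condition keys.
    """
    df = _read_csv(path)
    required = {"time_h", "rfu", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise MatrixParseError(f"{path}: missing column(s) {sorted(missing)}")
    df = _check_numeric(df, sorted(required & set(df.columns)), path)
    keys = [c for c in ("i_uM", "p_uM", "temp_C", "replicate") if c in df.columns]
    courses = []
    groups = df.groupby(keys) if keys else [((), df)]
    for key, grp in groups:
        grp = grp.sort_values("time_h")
        cond = dict(zip(keys, np.atleast_1d(key))) if keys else {}
        courses.append(
            TimeCourse(
                t=grp["time_h"].to_numpy(),
                rfu=grp["rfu"].to_numpy(),
                od600=grp["od600"].to_numpy(),
                condition=cond,
            )
        )
    return courses


def write_timecourse(
    tc: TimeCourse, path: str | Path, header: str | None = None
) -> None:
    df = pd.DataFrame({"time_h": tc.t, "rfu": tc.rfu, "od600": tc.od600})
    for k in ("i_uM", "p_uM", "temp_C", "replicate"):
        if k in tc.condition:
            df[k] = tc.condition[k]
    _write_with_header(df, path, header or provenance_header())


# ---------------------------------------------------------------------------
# cytometry events


def read_events(path: str | Path) -> EventSample:
    """Read a single-column event CSV (column ``fl``, one value per event);
    ``# key: value`` comment lines populate the condition labels."""
    condition: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and ":" in line:
                k, _, v = line.lstrip("# ").partition(":")
                condition[k.strip()] = v.strip()
            elif not line.startswith("#"):
                break
    df = _read_csv(path)
    if "fl" not in df.columns:
        raise MatrixParseError(f"{path}: expected a single 'fl' column")
    df = _check_numeric(df, ["fl"], path)
    return EventSample(fl=df["fl"].to_numpy(), condition=condition)


def write_events(s: EventSample, path: str | Path, header: str | None = None) -> None:
    lines = [header or provenance_header()]
    for k, v in s.condition.items():
        lines.append(f"# {k}: {v}\n")
    df = pd.DataFrame({"fl": s.fl})
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.writelines(lines)
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# fit reports


def write_fit_report(
    fit: FourPLFit | GlobalFit, path: str | Path, header: str | None = None
) -> None:
    """One row per parameter: name, estimate, standard error."""
    rows: list[tuple[str, float, float]] = []
    if fit.params is not None:
        from dataclasses import fields as _fields

        for f in _fields(fit.params):
            val = getattr(fit.params, f.name)
            if val is None:
                continue
            se_key = "span" if f.name == "ymax" else f.name
            rows.append((f.name, val, fit.se.get(f.name, fit.se.get(se_key, np.nan))))
        if isinstance(fit, GlobalFit):
            rows.append(("enhancement_1_over_f1", fit.enhancement, np.nan))
        else:
            for name in ("ec10", "ec90", "drlr"):
                v = getattr(fit, name)
                if v is not None:
                    rows.append((name, v, np.nan))
    rows.append(("rss", fit.rss, np.nan))
    rows.append(("n_obs", fit.n_obs, np.nan))
    rows.append(("converged", float(fit.converged), np.nan))
    df = pd.DataFrame(rows, columns=["name", "estimate", "se"])
    _write_with_header(df, path, header or provenance_header())


def write_contours(cs: ContourSet, path: str | Path, header: str | None = None) -> None:
    rows = [
        (level, float(i), float(p))
        for level in cs.levels
        for i, p in cs.curves[level]
    ]
    df = pd.DataFrame(rows, columns=["level", "i_uM", "p_uM"])
    _write_with_header(df, path, header or provenance_header())


def write_gate_summaries(
    summaries: Iterable[GateSummary], path: str | Path, header: str | None = None
) -> None:
    df = pd.DataFrame(
        [
            {
                "gate": g.gate_name,
                "threshold": g.threshold,
                "mean": g.mean,
                "cv_pct": g.cv,
                "pct_events": g.pct_events,
            }
            for g in summaries
        ]
    )
    _write_with_header(df, path, header or provenance_header())
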