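"""Plate-level I/O: raw fluorescence tables, plate maps, quantification reports.

A *plate run* is the unit of analysis: one real-time PCR run's per-cycle
fluorescence readings (arbitrary instrument units) for every well, plus a
plate map assigning each well a role -- ``sample`` (amplified target),
``calibrator`` (known amount of non-amplified DNA used to map fluorescence to
pmol) or ``ntc`` (no-template control).

Two CSV dialects are accepted for fluorescence: *wide* (first column
``cycle``, one column per well) and *long* (columns ``well,cycle,fluorescence``).
Cycle numbering is 1-based and a reading at cycle ``n`` is taken at the end of
cycle ``n``; all window arithmetic elsewhere relies on these integers.
Fluorescence is never rescaled on input.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateReadingError,
    OrphanWellError,
    PlateMapError,
    RaggedPlateError,
)

ROLES = ("sample", "calibrator", "ntc")
DETECTIONS = ("dye", "probe")

PLATE_MAP_COLUMNS = (
    "well", "role", "target", "sample_group", "replicate", "calibrator_ng", "detection",
)

REPORT_COLUMNS = (
    "well", "target", "group", "E", "takeoff", "sdm", "window_start", "window_end",
    "mean_pmz", "sd_pmz", "sem_pmz", "mean_copies", "sd_copies", "sem_copies", "flags",
)


@dataclass(frozen=True)
class WellMeta:
    """Plate-map entry for one well.

    ``calibrator_ng`` is the loaded amount of calibrator DNA in ng and must be
    present exactly when ``role == "calibrator"`` (0 is allowed, and required
    for the background wells that contain master mix only).
    """

    well_id: str
    role: str
    target: str = ""
    sample_group: str = ""
    replicate: int = 1
    calibrator_ng: float | None = None
    detection: str = "dye"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PlateMapError(
                f"well {self.well_id!r}: unknown role {self.role!r}; expected one of {ROLES}"
            )
        if self.detection not in DETECTIONS:
            raise PlateMapError(
                f"well {self.well_id!r}: unknown detection {self.detection!r}"
            )
        if self.role == "calibrator":
            if self.calibrator_ng is None:
                raise PlateMapError(
                    f"well {self.well_id!r}: calibrator well requires calibrator_ng"
                )
            if self.calibrator_ng < 0:
                raise PlateMapError(
                    f"well {self.well_id!r}: calibrator_ng must be non-negative"
                )
        elif self.calibrator_ng is not None:
            raise PlateMapError(
                f"well {self.well_id!r}: calibrator_ng only allowed for calibrator wells"
            )
        if self.replicate < 1:
            raise PlateMapError(
                f"well {self.well_id!r}: replicate must be a positive integer"
            )


@dataclass
class PlateRun:
    """All wells of one run: per-cycle fluorescence plus (optional) metadata.

    ``cycles`` are strictly increasing consecutive integers starting at 1;
    every fluorescence series has one reading per cycle.
    """

    cycles: np.ndarray
    fluorescence: dict[str, np.ndarray]
    meta: dict[str, WellMeta] = field(default_factory=dict)
    run_id: str = ""

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        if len(self.cycles) and not np.all(np.diff(self.cycles) == 1):
            raise RaggedPlateError("cycle numbers must increase strictly by 1")
        for well, series in self.fluorescence.items():
            series = np.asarray(series, dtype=float)
            if series.shape != self.cycles.shape:
                raise RaggedPlateError(
                    f"ragged plate: well {well!r} has {series.size} readings "
                    f"for {self.cycles.size} cycles"
                )
            self.fluorescence[well] = series

    @property
    def wells(self) -> list[str]:
        return list(self.fluorescence)

    @property
    def n_cycles(self) -> int:
        return int(self.cycles.size)

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, m in self.meta.items() if m.role == role and w in self.fluorescence]


def read_fluorescence_table(path, dialect: str = "wide") -> PlateRun:
    """Read a per-cycle fluorescence CSV into a :class:`PlateRun` (no metadata).

    Parameters
    ----------
    path : str or path-like
    dialect : {"wide", "long"}
        Wide: first column ``cycle``, remaining columns one per well.
        Long: columns ``well,cycle,fluorescence``.
    """
    if dialect == "wide":
        df = pd.read_csv(path)
        if df.columns[0].strip().lower() != "cycle":
            raise RaggedPlateError(
                f"wide fluorescence table must start with a 'cycle' column, got {df.columns[0]!r}"
            )
        long = df.melt(id_vars=[df.columns[0]], var_name="well", value_name="fluorescence")
        long = long.rename(columns={df.columns[0]: "cycle"})
    elif dialect == "long":
        long = pd.read_csv(path)
        missing = {"well", "cycle", "fluorescence"} - set(long.columns)
        if missing:
            raise RaggedPlateError(f"long fluorescence table missing columns {sorted(missing)}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")
    return _plate_from_long(long)


def _plate_from_long(long: pd.DataFrame) -> PlateRun:
    long = long.copy()
    long["well"] = long["well"].astype(str).str.strip()
    long["cycle"] = pd.to_numeric(long["cycle"], errors="raise").astype(int)
    fl = pd.to_numeric(long["fluorescence"], errors="coerce")
    if fl.isna().any():
        bad = long.loc[fl.isna()].iloc[0]
        raise RaggedPlateError(
            f"non-numeric fluorescence for well {bad['well']!r} cycle {bad['cycle']}"
        )
    long["fluorescence"] = fl.astype(float)

    if long.duplicated(subset=["well", "cycle"]).any():
        dup = long[long.duplicated(subset=["well", "cycle"])].iloc[0]
        raise DuplicateReadingError(
            f"duplicate reading for well {dup['well']!r} cycle {dup['cycle']}"
        )

    cycles = np.sort(long["cycle"].unique())
    series: dict[str, np.ndarray] = {}
    for well, sub in long.groupby("well", sort=False):
        if sub.shape[0] != cycles.size:
            got = set(sub["cycle"])
            missing = sorted(set(cycles.tolist()) - got)
            raise RaggedPlateError(
                f"ragged plate: well {well!r} missing cycle(s) {missing[:5]}"
            )
        series[str(well)] = sub.sort_values("cycle")["fluorescence"].to_numpy()
    return PlateRun(cycles=cycles, fluorescence=series)


def read_plate_map(path) -> list[WellMeta]:
    """Read a plate-map CSV (``well,role,target,sample_group,replicate,calibrator_ng,detection``)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = set(PLATE_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise PlateMapError(f"plate map missing columns {sorted(missing)}")
    extra = set(df.columns) - set(PLATE_MAP_COLUMNS)
    if extra:
        warnings.warn(f"plate map: ignoring unknown columns {sorted(extra)}", stacklevel=2)

    metas: list[WellMeta] = []
    for _, row in df.iterrows():
        ng_raw = row["calibrator_ng"].strip()
        role = row["role"].strip().lower()
        if role == "calibrator" and ng_raw == "":
            raise PlateMapError(f"well {row['well']!r}: calibrator row with empty calibrator_ng")
        ng = float(ng_raw) if ng_raw != "" else None
        rep_raw = row["replicate"].strip()
        metas.append(
            WellMeta(
                well_id=row["well"].strip(),
                role=role,
                target=row["target"].strip(),
                sample_group=row["sample_group"].strip(),
                replicate=int(rep_raw) if rep_raw else 1,
                calibrator_ng=ng,
                detection=(row["detection"].strip().lower() or "dye"),
            )
        )
    return metas


def attach_metadata(run: PlateRun, metas: Iterable[WellMeta]) -> PlateRun:
    """Attach plate-map metadata to a run.

    Every well in the run must have exactly one matching entry; map entries
    without fluorescence data are reported as warnings, not errors.
    """
    by_id: dict[str, WellMeta] = {}
    for m in metas:
        if m.well_id in by_id:
            raise PlateMapError(f"duplicate plate-map entry for well {m.well_id!r}")
        by_id[m.well_id] = m
    orphans = [w for w in run.wells if w not in by_id]
    if orphans:
        raise OrphanWellError(f"wells with no plate-map entry: {orphans}")
    unused = [w for w in by_id if w not in run.fluorescence]
    if unused:
        warnings.warn(f"plate map entries without fluorescence data: {unused}", stacklevel=2)
    run.meta = {w: by_id[w] for w in run.wells}
    return run


def _fmt(x) -> str:
    """Render a number with 6 significant digits; NaN as empty string."""
    if x is None or isinstance(x, str):
        return x or ""
    if isinstance(x, float) and math.isnan(x):
        return ""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{float(x):.6g}"


def write_quant_report(results: Sequence, path, fmt: str = "csv") -> None:
    """Write the per-well quantification report.

    One row per well: landmarks (take-off, SDM, window), efficiency, and the
    mean/SD/SEM of the back-calculated starting amount in pmol and copies.
    ``fmt="json"`` emits the same fields as a list of objects.
    """
    rows = [_result_row(r) for r in results]
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
            fh.write("\n")
        return
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    numeric = [c for c in REPORT_COLUMNS if c not in ("well", "target", "group", "flags")]
    for c in numeric:
        df[c] = df[c].map(_fmt) if len(df) else df[c]
    df.to_csv(path, index=False)


def _result_row(r) -> dict:
    flags = sorted(r.flags) if getattr(r, "flags", None) else []
    return {
        "well": r.well_id,
        "target": r.target,
        "group": r.sample_group,
        "E": r.E,
        "takeoff": r.window.takeoff if r.window is not None else float("nan"),
        "sdm": r.window.sdm if r.window is not None else float("nan"),
        "window_start": r.window.start if r.window is not None else "",
        "window_end": r.window.end if r.window is not None else "",
        "mean_pmz": r.mean_pmz,
        "sd_pmz": r.sd_pmz,
        "sem_pmz": r.sem_pmz,
        "mean_copies": r.mean_copies,
        "sd_copies": r.sd_copies,
        "sem_copies": r.sem_copies,
        "flags": ";".join(flags),
    }


def write_fluorescence_table(run: PlateRun, path, dialect: str = "wide") -> None:
    """Inverse of :func:`read_fluorescence_table` (used by the simulator)."""
    if dialect == "wide":
        df = pd.DataFrame({"cycle": run.cycles})
        for well in run.wells:
            df[well] = run.fluorescence[well]
        df.to_csv(path, index=False)
    elif dialect == "long":
        recs = [
            {"well": w, "cycle": int(c), "fluorescence": f}
            for w in run.wells
            for c, f in zip(run.cycles, run.fluorescence[w])
        ]
        pd.DataFrame(recs).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_plate_map(metas: Sequence[WellMeta], path) -> None:
    """Write a plate-map CSV (inverse of :func:`read_plate_map`)."""
    rows = []
    for m in metas:
        d = dataclasses.asdict(m)
        rows.append(
            {
                "well": d["well_id"],
                "role": d["role"],
                "target": d["target"],
                "sample_group": d["sample_group"],
                "replicate": d["replicate"],
                "calibrator_ng": "" if d["calibrator_ng"] is None else d["calibrator_ng"],
                "detection": d["detection"],
            }
        )
    pd.DataFrame(rows, columns=list(PLATE_MAP_COLUMNS)).to_csv(path, index=False)
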