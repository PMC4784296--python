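"""Plate-level model and results objects.

:class:`PlateModel` bundles one run's data (fluorescence + plate map) with
the analysis settings; :meth:`PlateModel.fit` executes the three-step
workflow -- calibrate from the non-amplified calibrator wells, analyze every
sample well's curve (baseline, take-off, second-derivative maximum,
efficiency), back-calculate starting amounts -- and returns a
:class:`PlateResults` carrying per-well estimates with uncertainties, group
aggregates, diagnostics and a ``summary()`` table.  Relative-quantification
comparators and the dilution-series regression hang off the results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration as cal_mod
from . import curve_analysis as ca
from . import plate_io
from . import quantification as quant
from . import relative_quant as rq
from .exceptions import (
    CannotEstimateError,
    CannotQuantifyError,
    DegenerateCurveError,
    NoAmplificationError,
    QpcrCalError,
    ShortCurveError,
    ShortWindowError,
)

_PER_WELL_ERRORS = (
    NoAmplificationError, DegenerateCurveError, ShortWindowError,
    ShortCurveError, CannotEstimateError, CannotQuantifyError,
)

_ERROR_FLAGS = {
    NoAmplificationError: "no_amplification",
    DegenerateCurveError: "degenerate_curve",
    ShortWindowError: "short_window",
    ShortCurveError: "short_curve",
    CannotEstimateError: "cannot_estimate",
    CannotQuantifyError: "cannot_quantify",
}


def _failed_result(meta, exc) -> quant.QuantResult:
    flag = next((f for t, f in _ERROR_FLAGS.items() if isinstance(exc, t)), "failed")
    return quant.QuantResult(
        well_id=meta.well_id, target=meta.target, sample_group=meta.sample_group,
        replicate=meta.replicate, E=float("nan"), window=None, per_cycle=[],
        mean_pmz=float("nan"), sd_pmz=float("nan"), sem_pmz=float("nan"),
        flags={flag},
    )


class PlateModel:
    """Absolute-quantification model for one annotated plate run.

    Parameters
    ----------
    run : PlateRun
        Fluorescence series with metadata attached for every well.
    takeoff_fraction : float
        Fraction of the second-derivative maximum defining the take-off.
    calibrator_length_bp : int
        Length of the calibrator molecule for the ng -> pmol conversion.
    polish_baseline : bool
        Refine each sample baseline to maximize window log-linearity.
    refine : {"spline", "parabola"}
        Sub-cycle refinement of the second-derivative maximum.
    """

    def __init__(self, run: plate_io.PlateRun, takeoff_fraction: float = 0.2,
                 half_width: int = 2, calibrator_length_bp: int = cal_mod.CALIBRATOR_LENGTH_BP,
                 polish_baseline: bool = True, refine: str = "spline"):
        missing = [w for w in run.wells if w not in run.meta]
        if missing:
            raise ValueError(f"run has wells without metadata: {missing}; "
                             "use plate_io.attach_metadata first")
        self.run = run
        self.takeoff_fraction = takeoff_fraction
        self.half_width = half_width
        self.calibrator_length_bp = calibrator_length_bp
        self.polish_baseline = polish_baseline
        self.refine = refine

    @classmethod
    def from_csv(cls, fluorescence_path, plate_map_path, dialect: str = "wide",
                 **kwargs) -> "PlateModel":
        run = plate_io.read_fluorescence_table(fluorescence_path, dialect=dialect)
        metas = plate_io.read_plate_map(plate_map_path)
        plate_io.attach_metadata(run, metas)
        return cls(run, **kwargs)

    # -- calibration only (step one of the workflow) ------------------------

    def calibrate(self) -> cal_mod.CalibrationCurve:
        summaries = [
            cal_mod.summarize_calibrator(
                self.run.cycles, self.run.fluorescence[w], self.run.meta[w],
                length_bp=self.calibrator_length_bp,
            )
            for w in self.run.wells_with_role("calibrator")
        ]
        return cal_mod.fit_calibration(summaries)

    # -- full fit ------------------------------------------------------------

    def fit(self, calibration_curve: cal_mod.CalibrationCurve | None = None) -> "PlateResults":
        cal = calibration_curve if calibration_curve is not None else self.calibrate()
        results: list[quant.QuantResult] = []
        curves: dict[str, ca.CorrectedCurve] = {}
        windows: dict[str, ca.ExponentialWindow] = {}
        for well in self.run.wells:
            meta = self.run.meta[well]
            if meta.role == "calibrator":
                continue
            try:
                curve, window, eff = ca.analyze_curve(
                    self.run.cycles, self.run.fluorescence[well],
                    takeoff_fraction=self.takeoff_fraction,
                    half_width=self.half_width, refine=self.refine,
                    polish_baseline=self.polish_baseline,
                )
                res = quant.quantify_well(curve, eff, cal, meta=meta)
                curves[well] = curve
                windows[well] = window
            except _PER_WELL_ERRORS as exc:
                res = _failed_result(meta, exc)
            if meta.role == "ntc":
                res.flags.add("ntc")
                if res.window is not None:
                    res.flags.add("ntc_amplified")
            results.append(res)
        coverage = cal_mod.validate_calibrator_range(cal, curves, windows)
        return PlateResults(model=self, calibration=cal, results=results,
                            coverage=coverage)


@dataclass
class PlateResults:
    """Fitted plate: per-well quantifications plus plate-level diagnostics."""

    model: PlateModel
    calibration: cal_mod.CalibrationCurve
    results: list[quant.QuantResult]
    coverage: dict = field(default_factory=dict)

    # -- views ---------------------------------------------------------------

    @property
    def sample_results(self) -> list[quant.QuantResult]:
        return [r for r in self.results if "ntc" not in r.flags]

    @property
    def ok_results(self) -> list[quant.QuantResult]:
        return [r for r in self.sample_results if r.window is not None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "well": r.well_id, "target": r.target, "group": r.sample_group,
                "replicate": r.replicate, "E": r.E,
                "takeoff": r.window.takeoff if r.window else float("nan"),
                "sdm": r.window.sdm if r.window else float("nan"),
                "window_start": r.window.start if r.window else pd.NA,
                "window_end": r.window.end if r.window else pd.NA,
                "n_cycles_used": r.n_cycles_used,
                "mean_pmz": r.mean_pmz, "sd_pmz": r.sd_pmz, "sem_pmz": r.sem_pmz,
                "mean_copies": r.mean_copies, "sd_copies": r.sd_copies,
                "sem_copies": r.sem_copies,
                "flags": ";".join(sorted(r.flags)),
            })
        return pd.DataFrame(rows)

    def group_stats(self) -> list[dict]:
        return quant.aggregate_replicates(self.ok_results)

    def cq_table(self) -> pd.DataFrame:
        return rq.cq_table_from_results(self.ok_results)

    # -- downstream analyses -------------------------------------------------

    def dilution_fit(self, theoretical: dict[str, float]) -> dict:
        """Regress determined on theoretical copies across groups.

        ``theoretical`` maps sample_group labels to true starting copies.
        """
        pairs = []
        for g in self.group_stats():
            if g["sample_group"] in theoretical:
                pairs.append((theoretical[g["sample_group"]], g["mean_copies"]))
        return quant.dilution_series_fit(pairs)

    def fold_changes(self, target: str, reference_target: str, control_group: str,
                     method: str = "absolute") -> pd.DataFrame:
        """Fold changes by ``ddcq``, ``pfaffl`` or ``absolute``."""
        if method == "ddcq":
            return rq.delta_delta_cq(self.cq_table(), target, reference_target,
                                     control_group)
        if method == "pfaffl":
            return rq.pfaffl_ratio(self.cq_table(), target, reference_target,
                                   control_group)
        if method == "absolute":
            stats = [g for g in self.group_stats() if g["target"] == target]
            return rq.relative_from_absolute(stats, control_group)
        raise ValueError(f"unknown method {method!r}")

    # -- reporting -----------------------------------------------------------

    def write_report(self, path, fmt: str = "csv") -> None:
        plate_io.write_quant_report(self.results, path, fmt=fmt)

    def summary(self) -> str:
        cal = self.calibration
        lines = [
            "Plate quantification summary",
            "=" * 64,
            f"run id:        {self.model.run.run_id or '(unnamed)'}",
            f"wells:         {len(self.model.run.wells)} total, "
            f"{len(self.results)} analyzed (incl. NTC), "
            f"{len(self.ok_results)} quantified",
            f"calibration:   f = {cal.a:.6g} * pmol + {cal.b:.4g}  "
            f"(r2 = {cal.r2:.6f}, background = {cal.background:.6g} a.u.)",
            f"cal range:     {cal.range_pmol[0]:.4g} - {cal.range_pmol[1]:.4g} pmol",
            f"window check:  {self.coverage.get('status', 'n/a')}",
            "",
            f"{'well':>6} {'group':>10} {'E':>7} {'Cq':>7} {'SDM':>7} "
            f"{'mean copies':>12} {'SEM':>10}  flags",
        ]
        for r in self.results:
            cq = f"{r.window.takeoff:7.2f}" if r.window else "      -"
            sdm = f"{r.window.sdm:7.2f}" if r.window else "      -"
            e = f"{r.E:7.4f}" if math.isfinite(r.E) else "      -"
            mc = f"{r.mean_copies:12.5g}" if math.isfinite(r.mean_copies) else "           -"
            sem = f"{r.sem_copies:10.3g}" if math.isfinite(r.sem_copies) else "         -"
            lines.append(
                f"{r.well_id:>6} {r.sample_group:>10} {e} {cq} {sdm} {mc} {sem}  "
                f"{';'.join(sorted(r.flags))}"
            )
        groups = self.group_stats()
        if groups:
            lines += ["", f"{'target':>10} {'group':>10} {'n':>3} "
                          f"{'mean copies':>12} {'SD':>10} {'SEM':>10}"]
            for g in groups:
                lines.append(
                    f"{g['target']:>10} {g['sample_group']:>10} {g['n']:>3} "
                    f"{g['mean_copies']:12.5g} {g['sd_copies']:10.3g} {g['sem_copies']:10.3g}"
                )
        return "\n".join(lines)
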