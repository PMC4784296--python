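"""Calibration: map background-subtracted fluorescence to pmol of DNA.

The calibrator is a known amount of DNA that is present in the well but *not
amplified*; it is cycled alongside the samples and read every cycle, so its
fluorescence is constant in expectation and linear in the loaded amount.  A
dilution series of calibrator wells (at least six levels including a 0 ng
master-mix-only background, preferably in duplicate, on every plate) yields
the linear map

    f_mean - background = a * pmol + b

whose inverse converts any sample well's corrected fluorescence to pmol.
The intercept is left free: background subtraction should drive ``b`` to 0,
and a large residual intercept is a useful pipetting/contamination
diagnostic, so it is warned about rather than forced away.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .exceptions import (
    InsufficientLevelsError,
    MissingBackgroundError,
    NonPositiveSlopeError,
)
from .plate_io import WellMeta

#: average molar mass of one base pair, g/mol (flat approximation)
BP_MASS_G_PER_MOL = 650.0

#: double-stranded calibrator length in bp (90 bp, ~44% GC)
CALIBRATOR_LENGTH_BP = 90

#: cycles discarded at the start of every calibrator series (thermal settling)
CALIBRATOR_SKIP_CYCLES = 3

MIN_NONZERO_LEVELS = 5


def ng_to_pmol(ng: float, length_bp: int = CALIBRATOR_LENGTH_BP,
               gc_frac: float | None = None,
               bp_mass: float = BP_MASS_G_PER_MOL) -> float:
    """Convert ng of double-stranded DNA of known length to pmol.

    ``pmol = ng * 1000 / (length_bp * bp_mass)`` with ``bp_mass`` = 650 g/mol
    per base pair by default.  ``gc_frac`` is accepted for future
    sequence-aware mass models but unused.
    """
    if ng < 0:
        raise ValueError("ng must be non-negative")
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    return ng * 1000.0 / (length_bp * bp_mass)


@dataclass
class CalibratorSummary:
    """Per-well calibrator summary over the retained cycles."""

    well_id: str
    loaded_ng: float
    loaded_pmol: float
    f_mean: float
    f_sd: float
    retained_cycles: tuple[int, int]
    flags: set[str] = field(default_factory=set)

    @property
    def cv(self) -> float:
        return self.f_sd / max(self.f_mean, 1e-12)


@dataclass
class CalibrationCurve:
    """Linear calibration ``f = a * pmol + b`` on background-subtracted means."""

    a: float                 # a.u. per pmol
    b: float                 # a.u.
    r2: float
    background: float        # mean fluorescence of the 0 ng wells, a.u.
    points: list[tuple[float, float]]   # (pmol, background-subtracted f_mean)
    range_pmol: tuple[float, float]     # [min, max] of non-zero levels

    def to_json(self, path=None) -> str:
        payload = {
            "a": self.a, "b": self.b, "r2": self.r2,
            "background": self.background,
            "points": [list(p) for p in self.points],
            "range_pmol": list(self.range_pmol),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationCurve":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            a=payload["a"], b=payload["b"], r2=payload["r2"],
            background=payload["background"],
            points=[tuple(p) for p in payload["points"]],
            range_pmol=tuple(payload["range_pmol"]),
        )


def summarize_calibrator(cycles, fluorescence, meta: WellMeta,
                         length_bp: int = CALIBRATOR_LENGTH_BP,
                         skip_cycles: int = CALIBRATOR_SKIP_CYCLES) -> CalibratorSummary:
    """Mean/SD of a calibrator well over cycles ``skip_cycles + 1 .. last``.

    The first cycles are discarded for thermal equilibration.  A ``drift``
    flag is set when a linear fit of fluorescence on cycle moves by more than
    5% of the mean across the retained series (calibrator fluorescence should
    be constant: it is not amplified).
    """
    if meta.role != "calibrator":
        raise ValueError(f"well {meta.well_id!r} is not a calibrator")
    cycles = np.asarray(cycles, dtype=int)
    f = np.asarray(fluorescence, dtype=float)
    keep = cycles > skip_cycles
    cyc, fv = cycles[keep], f[keep]
    f_mean = float(fv.mean())
    f_sd = float(fv.std(ddof=1)) if fv.size > 1 else 0.0
    flags: set[str] = set()
    if fv.size > 2:
        fit = linregress(cyc.astype(float), fv)
        if abs(fit.slope) * fv.size > 0.05 * abs(f_mean) and f_mean != 0:
            flags.add("drift")
    return CalibratorSummary(
        well_id=meta.well_id,
        loaded_ng=float(meta.calibrator_ng),
        loaded_pmol=ng_to_pmol(float(meta.calibrator_ng), length_bp),
        f_mean=f_mean,
        f_sd=f_sd,
        retained_cycles=(int(cyc[0]), int(cyc[-1])),
        flags=flags,
    )


def fit_calibration(summaries) -> CalibrationCurve:
    """OLS of background-subtracted level means on loaded pmol.

    Requires at least one 0 ng well (the background) and five distinct
    non-zero levels; replicate wells at a level are averaged first so levels
    are equally weighted.
    """
    summaries = list(summaries)
    zero = [s for s in summaries if s.loaded_ng == 0]
    if not zero:
        raise MissingBackgroundError("no 0 ng calibrator well on the plate")
    background = float(np.mean([s.f_mean for s in zero]))

    by_level: dict[float, list[float]] = {}
    for s in summaries:
        if s.loaded_ng > 0:
            by_level.setdefault(s.loaded_pmol, []).append(s.f_mean)
    if len(by_level) < MIN_NONZERO_LEVELS:
        raise InsufficientLevelsError(
            f"need >= {MIN_NONZERO_LEVELS} distinct non-zero calibrator levels, "
            f"got {len(by_level)}"
        )
    pmols = np.array(sorted(by_level))
    f_sub = np.array([np.mean(by_level[p]) for p in pmols]) - background
    fit = linregress(pmols, f_sub)
    a, b = float(fit.slope), float(fit.intercept)
    if a <= 0:
        raise NonPositiveSlopeError(f"calibration slope must be positive, got {a:g}")
    mid_f = a * float(pmols.mean()) + b
    if abs(b) > 0.05 * abs(mid_f):
        warnings.warn(
            f"calibration intercept {b:.4g} a.u. exceeds 5% of the mid-range "
            f"fitted value; check background wells", stacklevel=2,
        )
    return CalibrationCurve(
        a=a, b=b, r2=float(fit.rvalue ** 2), background=background,
        points=[(float(p), float(f)) for p, f in zip(pmols, f_sub)],
        range_pmol=(float(pmols.min()), float(pmols.max())),
    )


def fluorescence_to_pmol(curve: CalibrationCurve, f: float) -> tuple[float, bool]:
    """Invert the calibration at one background-subtracted fluorescence value.

    Returns ``(pmol, extrapolated)``; values outside the calibrated range
    (including negative ones) are returned as-is with the flag set.
    """
    if curve.a <= 0:
        raise NonPositiveSlopeError("calibration curve has non-positive slope")
    pmol = (f - curve.b) / curve.a
    lo, hi = curve.range_pmol
    extrapolated = not (lo <= pmol <= hi)
    return float(pmol), bool(extrapolated)


def validate_calibrator_range(curve: CalibrationCurve, sample_curves: dict,
                              windows: dict) -> dict:
    """Check that each sample's window fluorescence lies inside the calibrated span.

    ``sample_curves`` maps well id to :class:`~qpcrcal.curve_analysis.CorrectedCurve`,
    ``windows`` to :class:`~qpcrcal.curve_analysis.ExponentialWindow`.  Returns a
    report dict with per-well coverage (fraction of window cycles whose corrected
    fluorescence falls within [min, max] of the calibrator background-subtracted
    means) and a plate-level status of ``pass`` (all covered) or ``warn``.
    """
    f_levels = [f for _, f in curve.points]
    lo, hi = (min(f_levels), max(f_levels)) if f_levels else (0.0, 0.0)
    wells = {}
    for well, cc in sample_curves.items():
        if well not in windows:
            continue
        w = windows[well]
        vals = np.array([cc.at(int(n)) for n in w.cycles], dtype=float)
        inside = (vals >= lo) & (vals <= hi)
        wells[well] = {
            "coverage": float(inside.mean()) if vals.size else 0.0,
            "n_cycles": int(vals.size),
        }
    status = "pass" if all(v["coverage"] == 1.0 for v in wells.values()) else "warn"
    if not wells:
        status = "pass"
    return {"status": status, "span_au": (lo, hi), "wells": wells}
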