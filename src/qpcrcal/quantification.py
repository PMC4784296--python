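"""Back-calculation of starting copy numbers and the comparison statistics.

For every integer cycle ``n`` in a well's exponential window, the calibration
curve converts corrected fluorescence to the pmol of product present at that
cycle, ``pm(n)``; dividing out the amplification gives the amount present
before cycling began:

    pmz(n) = pm(n) / E**n

with ``n`` counted from cycle 1, i.e. amplification is assumed to proceed at
efficiency ``E`` from the first cycle -- the only reading under which
``pmz`` is literally "pmol at time zero".  Per-cycle estimates across the
window are averaged to a mean with SD and SEM (SEM over window cycles; the
replicate-level SEM is a separate aggregation and both are reported).
Copies are obtained via Avogadro's number: ``copies = pmol * 6.022e11``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibration import CalibrationCurve, fluorescence_to_pmol
from .curve_analysis import CorrectedCurve, EfficiencyEstimate, ExponentialWindow
from .exceptions import CannotQuantifyError, InvalidEfficiencyError

#: copies per pmol: 6.022e23 molecules/mol x 1e-12 mol/pmol
COPIES_PER_PMOL = 6.022e23 * 1e-12


def pmol_to_copies(pmz: float) -> float:
    """pmol -> molecule count (``pmz * 6.022e23 * 1e-12``)."""
    return pmz * COPIES_PER_PMOL


def copies_to_pmol(copies: float) -> float:
    """Exact inverse of :func:`pmol_to_copies`."""
    return copies / COPIES_PER_PMOL


@dataclass
class QuantResult:
    """Per-well absolute quantification."""

    well_id: str
    target: str
    sample_group: str
    replicate: int
    E: float
    window: ExponentialWindow | None
    per_cycle: list[tuple[int, float, float]]   # (n, pm, pmz)
    mean_pmz: float
    sd_pmz: float
    sem_pmz: float
    flags: set[str] = field(default_factory=set)

    @property
    def mean_copies(self) -> float:
        return pmol_to_copies(self.mean_pmz)

    @property
    def sd_copies(self) -> float:
        return pmol_to_copies(self.sd_pmz)

    @property
    def sem_copies(self) -> float:
        return pmol_to_copies(self.sem_pmz)

    @property
    def n_cycles_used(self) -> int:
        return len(self.per_cycle)


def quantify_well(curve: CorrectedCurve, eff: EfficiencyEstimate,
                  cal: CalibrationCurve, meta=None) -> QuantResult:
    """Back-calculate the starting amount over the exponential window.

    Cycles whose back-calculated ``pm`` is <= 0 are dropped (negative pmol is
    calibration noise, not signal); at least three cycles must survive.
    """
    if eff.E <= 1:
        raise InvalidEfficiencyError(f"efficiency {eff.E:g} <= 1 cannot be inverted")
    window = eff.window
    per_cycle: list[tuple[int, float, float]] = []
    extrapolated = False
    for n in window.cycles:
        pm, extra = fluorescence_to_pmol(cal, curve.at(int(n)))
        if pm <= 0:
            continue
        extrapolated = extrapolated or extra
        per_cycle.append((int(n), pm, pm / eff.E ** int(n)))
    if len(per_cycle) < 3:
        raise CannotQuantifyError(
            f"only {len(per_cycle)} window cycles back-calculate to positive pmol"
        )
    pmz = np.array([p for _, _, p in per_cycle])
    mean = float(pmz.mean())
    sd = float(pmz.std(ddof=1))
    flags = set(eff.flags)
    if extrapolated:
        flags.add("extrapolated")
    return QuantResult(
        well_id=(meta.well_id if meta else ""),
        target=(meta.target if meta else ""),
        sample_group=(meta.sample_group if meta else ""),
        replicate=(meta.replicate if meta else 1),
        E=eff.E,
        window=window,
        per_cycle=per_cycle,
        mean_pmz=mean,
        sd_pmz=sd,
        sem_pmz=sd / math.sqrt(len(per_cycle)),
        flags=flags,
    )


def aggregate_replicates(results) -> list[dict]:
    """Group statistics of ``mean_copies`` over replicate wells per (target, group)."""
    groups: dict[tuple[str, str], list[float]] = {}
    for r in results:
        groups.setdefault((r.target, r.sample_group), []).append(r.mean_copies)
    out = []
    for (target, group), vals in sorted(groups.items()):
        v = np.asarray(vals, dtype=float)
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        out.append({
            "target": target,
            "sample_group": group,
            "n": int(v.size),
            "mean_copies": float(v.mean()),
            "sd_copies": sd,
            "sem_copies": sd / math.sqrt(v.size),
        })
    return out


@dataclass
class RegressionFit:
    """Simple OLS summary used for dilution-series and slope comparisons."""

    slope: float
    intercept: float
    r2: float
    n: int
    x: np.ndarray
    y: np.ndarray

    @property
    def residual_ss(self) -> float:
        return float(np.sum((self.y - self.slope * self.x - self.intercept) ** 2))

    @property
    def sxx(self) -> float:
        return float(np.sum((self.x - self.x.mean()) ** 2))


def _ols(x, y) -> RegressionFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=float(fit.rvalue ** 2), n=int(x.size), x=x, y=y,
    )


def dilution_series_fit(pairs) -> dict:
    """Regress determined on theoretical copies, on raw and log10 scales.

    ``pairs`` is an iterable of ``(theoretical_copies, determined_copies)``;
    at least three levels are required.  Agreement is summarized by both the
    identity-scale fit and the log-log fit (slope 1 means the determined
    amounts track the dilution series proportionally across its full range).
    """
    pairs = [(float(t), float(d)) for t, d in pairs]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 dilution levels, got {len(pairs)}")
    theo = np.array([t for t, _ in pairs])
    det = np.array([d for _, d in pairs])
    raw = _ols(theo, det)
    pos = (theo > 0) & (det > 0)
    if pos.sum() < 3:
        raise ValueError("need >= 3 positive levels for the log-log fit")
    loglog = _ols(np.log10(theo[pos]), np.log10(det[pos]))
    return {"raw": raw, "loglog": loglog}


def compare_groups(a, b, equal_var: bool = True) -> dict:
    """Unpaired two-sample Student's t-test (pooled variance; Welch by flag).

    Degenerate zero-variance inputs with equal means return ``t=0, p=1`` by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2 if equal_var else float("nan")
            return {"t": 0.0, "df": float(df), "p": 1.0}
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def compare_slopes(fit_a: RegressionFit, fit_b: RegressionFit) -> dict:
    """Two-sided test of slope equality between two simple regressions.

    Common-variance (ANCOVA-style) form: the residual variance is pooled over
    both fits with ``df = n_a + n_b - 4`` and the slope-difference standard
    error is ``sqrt(s2 * (1/Sxx_a + 1/Sxx_b))``.
    """
    for f in (fit_a, fit_b):
        if f.n < 3:
            raise ValueError("each fit needs >= 3 points")
        if f.sxx == 0:
            raise ValueError("degenerate regression: zero variance in x")
    df = fit_a.n + fit_b.n - 4
    s2 = (fit_a.residual_ss + fit_b.residual_ss) / df
    se = math.sqrt(s2 * (1.0 / fit_a.sxx + 1.0 / fit_b.sxx))
    if se == 0:
        t = 0.0 if fit_a.slope == fit_b.slope else math.inf
    else:
        t = (fit_a.slope - fit_b.slope) / se
    p = 2.0 * stats.t.sf(abs(t), df) if math.isfinite(t) else 0.0
    if t == 0.0:
        p = 1.0
    return {"t": float(t), "df": float(df), "p": float(p)}
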