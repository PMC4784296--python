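"""Synthetic plate generator with known ground truth.

Every pipeline stage can be exercised against plates whose true starting
copy numbers, per-reaction efficiency and calibration slope are known.  Two
kinetic models are provided:

* ``ideal`` -- exact exponential growth hard-clipped at a plateau,
  ``N(n) = min(N0 * E0**n, K)``.  Gives closed-form oracles: every
  pre-plateau cycle satisfies ``F(n+1)/F(n) = E0`` exactly (above baseline),
  so noiseless recovery of ``E0`` and ``N0`` can be asserted tightly.
* ``logistic`` -- per-cycle efficiency declines as product accumulates,
  ``E(n) = 1 + (E0 - 1) / (1 + N(n-1)/K)``; realistic curvature into the
  plateau.  Estimated efficiency is biased low relative to ``E0`` (the
  regression sees the declining phase), which is a property of the data, not
  a defect of the estimator.

The default layout mirrors a typical single-plate absolute-quantification
design: a ten-fold dilution series of 4.5e6 .. 4.5e1 starting copies in
quadruplicate, six calibrator levels (0, 40, 60, 80, 120, 140 ng of the
90 bp calibrator) in duplicate, and two no-template controls.  Fluorescence
readout is ``F(n) = baseline + a * pmol(N(n))`` plus multiplicative and
additive Gaussian noise; calibrator wells read a constant
``background + a * pmol(loaded)`` because the calibrator is not amplified.

Noise is seeded per-well from ``(seed, well_index)``, so adding wells to a
layout never perturbs previously generated ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import CALIBRATOR_LENGTH_BP, ng_to_pmol
from .plate_io import PlateRun, WellMeta, write_fluorescence_table, write_plate_map
from .quantification import copies_to_pmol

DEFAULT_DILUTION_LEVELS = (4.5e6, 4.5e5, 4.5e4, 4.5e3, 4.5e2, 4.5e1)
DEFAULT_CALIBRATOR_NG = (0.0, 40.0, 60.0, 80.0, 120.0, 140.0)


@dataclass
class SimConfig:
    """Plate-simulation parameters.

    Amount units: copies per reaction for samples, ng for calibrators.
    ``cal_slope`` couples pmol of DNA to arbitrary fluorescence units and is
    shared by samples and calibrators (same dye chemistry on one plate).
    A ``seed`` is mandatory whenever any noise term is non-zero.
    """

    n_cycles: int = 40
    curve_model: str = "ideal"            # {"ideal", "logistic"}
    E0: float = 1.9                       # per-cycle amplification factor
    cal_slope: float = 2000.0             # a.u. per pmol
    cal_background: float = 100.0         # a.u., 0 ng calibrator level
    sample_baseline: float = 100.0        # a.u., sample-well background
    plateau_copies: float = 1.2e12        # K, copies at saturation (~2 pmol)
    noise_sd_frac: float = 0.01           # multiplicative noise fraction
    additive_sd: float = 1.0              # a.u.
    seed: int | None = None
    dilution_levels: tuple = DEFAULT_DILUTION_LEVELS
    sample_replicates: int = 4
    calibrator_ng: tuple = DEFAULT_CALIBRATOR_NG
    calibrator_replicates: int = 2
    n_ntc: int = 2
    target: str = "lambda"
    calibrator_length_bp: int = CALIBRATOR_LENGTH_BP

    def __post_init__(self) -> None:
        if not 1.0 < self.E0 <= 2.0:
            raise ValueError("E0 must lie in (1, 2]")
        if self.curve_model not in ("ideal", "logistic"):
            raise ValueError(f"unknown curve model {self.curve_model!r}")
        if min(self.dilution_levels) < 0 or min(self.calibrator_ng) < 0:
            raise ValueError("amounts must be non-negative")
        if (self.noise_sd_frac > 0 or self.additive_sd > 0) and self.seed is None:
            raise ValueError("seed is mandatory for any stochastic run")

    @property
    def noiseless(self) -> bool:
        return self.noise_sd_frac == 0 and self.additive_sd == 0


def _well_rng(cfg: SimConfig, well_index: int) -> np.random.Generator:
    return np.random.default_rng((0 if cfg.seed is None else cfg.seed, well_index))


def _add_noise(cfg: SimConfig, f: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if cfg.noiseless:
        return f
    mult = rng.normal(0.0, cfg.noise_sd_frac, size=f.size)
    add = rng.normal(0.0, cfg.additive_sd, size=f.size)
    return f * (1.0 + mult) + add


def _copies_trajectory(cfg: SimConfig, n0: float) -> np.ndarray:
    n = np.arange(1, cfg.n_cycles + 1)
    if cfg.curve_model == "ideal":
        return np.minimum(n0 * cfg.E0 ** n, cfg.plateau_copies)
    traj = np.empty(cfg.n_cycles)
    prev = n0
    for i in range(cfg.n_cycles):
        e = 1.0 + (cfg.E0 - 1.0) / (1.0 + prev / cfg.plateau_copies)
        prev *= e
        traj[i] = prev
    return traj


def simulate_curve(cfg: SimConfig, n0: float, well_index: int = 0):
    """One sample well: fluorescence series plus its truth record."""
    copies = _copies_trajectory(cfg, n0)
    signal = cfg.cal_slope * copies_to_pmol(copies)
    f = cfg.sample_baseline + signal
    f = _add_noise(cfg, f, _well_rng(cfg, well_index))
    truth = {
        "N0": float(n0),
        "E0": cfg.E0,
        "model": cfg.curve_model,
        "baseline": cfg.sample_baseline,
        "plateau_copies": cfg.plateau_copies,
    }
    return f, truth


def simulate_calibrator_well(cfg: SimConfig, ng: float, well_index: int = 0):
    """One calibrator well: constant-in-expectation fluorescence series."""
    if ng < 0:
        raise ValueError("ng must be non-negative")
    level = cfg.cal_background + cfg.cal_slope * ng_to_pmol(ng, cfg.calibrator_length_bp)
    f = np.full(cfg.n_cycles, level, dtype=float)
    f = _add_noise(cfg, f, _well_rng(cfg, well_index))
    truth = {"loaded_ng": float(ng), "level_au": float(level)}
    return f, truth


def _well_ids(n: int) -> list[str]:
    rows = "ABCDEFGH"
    ids = [f"{r}{c}" for r in rows for c in range(1, 13)]
    if n > len(ids):
        ids += [f"X{i}" for i in range(1, n - len(ids) + 1)]
    return ids[:n]


@dataclass
class SimulatedPlate:
    """A generated plate: run + metadata + per-well truth."""

    run: PlateRun
    metas: list[WellMeta]
    truth: dict
    config: SimConfig = field(repr=False, default=None)

    def write(self, out_dir) -> dict:
        """Emit fluorescence CSV (wide), plate-map CSV and truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fluorescence": out / "fluorescence.csv",
            "plate_map": out / "plate_map.csv",
            "truth": out / "truth.json",
        }
        write_fluorescence_table(self.run, paths["fluorescence"], dialect="wide")
        write_plate_map(self.metas, paths["plate_map"])
        cfg = dataclasses.asdict(self.config) if self.config else {}
        with open(paths["truth"], "w") as fh:
            json.dump({"config": cfg, "wells": self.truth}, fh, indent=2, default=list)
            fh.write("\n")
        return {k: str(v) for k, v in paths.items()}


def simulate_plate(cfg: SimConfig) -> SimulatedPlate:
    """Generate a full plate: dilution series, calibrator series, NTCs.

    Well IDs are assigned deterministically in layout order (samples by
    dilution level then replicate, calibrators by level then replicate, then
    NTCs), so identical configs produce byte-identical plates.
    """
    specs: list[tuple[str, float]] = []          # (kind, amount)
    for level in cfg.dilution_levels:
        for _ in range(cfg.sample_replicates):
            specs.append(("sample", float(level)))
    for ng in cfg.calibrator_ng:
        for _ in range(cfg.calibrator_replicates):
            specs.append(("calibrator", float(ng)))
    for _ in range(cfg.n_ntc):
        specs.append(("ntc", 0.0))

    ids = _well_ids(len(specs))
    fluorescence: dict[str, np.ndarray] = {}
    metas: list[WellMeta] = []
    truth: dict[str, dict] = {}
    rep_counter: dict[tuple, int] = {}

    for idx, (kind, amount) in enumerate(specs):
        well = ids[idx]
        if kind == "sample":
            f, t = simulate_curve(cfg, amount, well_index=idx)
            key = ("sample", amount)
            rep = rep_counter[key] = rep_counter.get(key, 0) + 1
            metas.append(WellMeta(
                well_id=well, role="sample", target=cfg.target,
                sample_group=f"{amount:.3g}", replicate=rep,
            ))
        elif kind == "calibrator":
            f, t = simulate_calibrator_well(cfg, amount, well_index=idx)
            key = ("calibrator", amount)
            rep = rep_counter[key] = rep_counter.get(key, 0) + 1
            metas.append(WellMeta(
                well_id=well, role="calibrator", sample_group="cal",
                replicate=rep, calibrator_ng=amount,
            ))
        else:
            f, t = simulate_curve(cfg, 0.0, well_index=idx)
            t = {"N0": 0.0, "model": cfg.curve_model}
            key = ("ntc", 0.0)
            rep = rep_counter[key] = rep_counter.get(key, 0) + 1
            metas.append(WellMeta(
                well_id=well, role="ntc", target=cfg.target,
                sample_group="ntc", replicate=rep,
            ))
        fluorescence[well] = f
        truth[well] = t

    run = PlateRun(
        cycles=np.arange(1, cfg.n_cycles + 1),
        fluorescence=fluorescence,
        run_id=f"sim-{cfg.curve_model}-seed{cfg.seed}",
    )
    run.meta = {m.well_id: m for m in metas}
    return SimulatedPlate(run=run, metas=metas, truth=truth, config=cfg)


def simulate_expression_plate(cfg: SimConfig, expression: dict,
                              replicates: int = 4) -> SimulatedPlate:
    """Gene-expression layout: ``expression[group][target] = starting copies``.

    Used for the relative-quantification scenarios (e.g. a reference gene
    that is, or is not, truly stable across groups).  Calibrator wells and
    NTCs follow ``cfg`` exactly as in :func:`simulate_plate`.
    """
    specs: list[tuple] = []
    for group, targets in expression.items():
        for target, n0 in targets.items():
            for _ in range(replicates):
                specs.append(("sample", group, target, float(n0)))
    for ng in cfg.calibrator_ng:
        for _ in range(cfg.calibrator_replicates):
            specs.append(("calibrator", "cal", "", float(ng)))
    for _ in range(cfg.n_ntc):
        specs.append(("ntc", "ntc", "", 0.0))

    ids = _well_ids(len(specs))
    fluorescence: dict[str, np.ndarray] = {}
    metas: list[WellMeta] = []
    truth: dict[str, dict] = {}
    rep_counter: dict[tuple, int] = {}
    for idx, (kind, group, target, amount) in enumerate(specs):
        well = ids[idx]
        key = (kind, group, target)
        rep = rep_counter[key] = rep_counter.get(key, 0) + 1
        if kind == "sample":
            f, t = simulate_curve(cfg, amount, well_index=idx)
            metas.append(WellMeta(well_id=well, role="sample", target=target,
                                  sample_group=group, replicate=rep))
        elif kind == "calibrator":
            f, t = simulate_calibrator_well(cfg, amount, well_index=idx)
            metas.append(WellMeta(well_id=well, role="calibrator",
                                  sample_group="cal", replicate=rep,
                                  calibrator_ng=amount))
        else:
            f, t = simulate_curve(cfg, 0.0, well_index=idx)
            t = {"N0": 0.0, "model": cfg.curve_model}
            metas.append(WellMeta(well_id=well, role="ntc",
                                  sample_group="ntc", replicate=rep))
        fluorescence[well] = f
        truth[well] = t

    run = PlateRun(
        cycles=np.arange(1, cfg.n_cycles + 1),
        fluorescence=fluorescence,
        run_id=f"sim-expr-{cfg.curve_model}-seed{cfg.seed}",
    )
    run.meta = {m.well_id: m for m in metas}
    return SimulatedPlate(run=run, metas=metas, truth=truth, config=cfg)
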