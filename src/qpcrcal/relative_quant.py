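"""Relative-quantification comparators: ddCq, efficiency-corrected (Pfaffl-
style) ratios, and ratios of absolute copy numbers.

All three express each treatment group's expression of a target gene as a
fold change over a control group (which is exactly 1 by construction):

* ``delta_delta_cq`` assumes perfect doubling (E = 2) for target and
  reference gene: ``fold = 2**(-ddCq)``.
* ``pfaffl_ratio`` replaces the assumed 2 with each gene's measured
  efficiency: ``fold = E_t**dCq_t / E_r**dCq_r`` with
  ``dCq = mean Cq(control) - mean Cq(group)`` per gene.
* ``relative_from_absolute`` needs no reference gene at all: it is the ratio
  of absolutely quantified group means.

The first two stand or fall with the stability of the reference gene; when
the reference is truly regulated alongside the target, they report no change
while the absolute ratio reveals it.

Cq tables are plain :class:`pandas.DataFrame` objects with columns
``sample_group, target, replicate, cq`` and optionally ``efficiency``
(per-reaction E).  Within this package the Cq is the take-off point from
:mod:`~qpcrcal.curve_analysis`.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

CQ_COLUMNS = ("sample_group", "target", "replicate", "cq")


def _check_cq_table(cq: pd.DataFrame, need_efficiency: bool = False) -> pd.DataFrame:
    missing = set(CQ_COLUMNS) - set(cq.columns)
    if missing:
        raise ValueError(f"Cq table missing columns {sorted(missing)}")
    if (cq["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    if need_efficiency:
        if "efficiency" not in cq.columns or cq["efficiency"].isna().any():
            raise ValueError(
                "per-reaction efficiencies required: add an 'efficiency' column "
                "(estimate_efficiency provides them)"
            )
        e = cq["efficiency"]
        if ((e <= 1) | (e > 2.2)).any():
            raise ValueError("efficiencies must lie in (1, 2.2]")
    return cq


def _mean_cq(cq: pd.DataFrame, target: str, group: str) -> float:
    sub = cq[(cq["target"] == target) & (cq["sample_group"] == group)]
    if sub.empty:
        raise ValueError(f"no Cq rows for target {target!r} in group {group!r}")
    return float(sub["cq"].mean())


def delta_delta_cq(cq: pd.DataFrame, target: str, reference_target: str,
                   control_group: str) -> pd.DataFrame:
    """Classic ddCq fold change per group, ``2**(-ddCq)``.

    ``dCq(g) = mean Cq_target(g) - mean Cq_ref(g)``;
    ``ddCq(g) = dCq(g) - dCq(control)``.  The control group's fold change is
    exactly 1.
    """
    cq = _check_cq_table(cq)
    groups = list(dict.fromkeys(cq["sample_group"]))
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} absent from Cq table")
    dcq = {g: _mean_cq(cq, target, g) - _mean_cq(cq, reference_target, g) for g in groups}
    rows = []
    for g in groups:
        ddcq = dcq[g] - dcq[control_group]
        fold = 1.0 if g == control_group else 2.0 ** (-ddcq)
        rows.append({"sample_group": g, "method": "ddcq", "fold": fold, "ddcq": ddcq})
    return pd.DataFrame(rows)


def pfaffl_ratio(cq: pd.DataFrame, target: str, reference_target: str,
                 control_group: str) -> pd.DataFrame:
    """Efficiency-corrected fold change per group.

    ``ratio(g) = E_t**dCq_t(g) / E_r**dCq_r(g)`` with
    ``dCq(g) = mean Cq(control) - mean Cq(g)`` per gene.  Each gene's E is
    the arithmetic mean of the per-reaction efficiencies over the two groups
    being compared (group ``g`` and the control).
    """
    cq = _check_cq_table(cq, need_efficiency=True)
    groups = list(dict.fromkeys(cq["sample_group"]))
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} absent from Cq table")

    def gene_e(gene: str, group: str) -> float:
        sub = cq[(cq["target"] == gene)
                 & (cq["sample_group"].isin([group, control_group]))]
        return float(sub["efficiency"].mean())

    rows = []
    for g in groups:
        if g == control_group:
            rows.append({"sample_group": g, "method": "pfaffl", "fold": 1.0})
            continue
        dcq_t = _mean_cq(cq, target, control_group) - _mean_cq(cq, target, g)
        dcq_r = _mean_cq(cq, reference_target, control_group) - _mean_cq(cq, reference_target, g)
        ratio = gene_e(target, g) ** dcq_t / gene_e(reference_target, g) ** dcq_r
        rows.append({"sample_group": g, "method": "pfaffl", "fold": float(ratio)})
    return pd.DataFrame(rows)


def relative_from_absolute(group_stats, control_group: str) -> pd.DataFrame:
    """Fold changes from absolutely quantified group means; no reference gene.

    ``group_stats`` is the output of
    :func:`~qpcrcal.quantification.aggregate_replicates` restricted to one
    target (dicts with ``sample_group, mean_copies, sem_copies``).  The
    standard error of each fold is propagated by the delta method:
    ``se = fold * sqrt((sem_g/mean_g)**2 + (sem_c/mean_c)**2)``.
    """
    stats = list(group_stats)
    by_group = {s["sample_group"]: s for s in stats}
    if control_group not in by_group:
        raise ValueError(f"control group {control_group!r} missing")
    ctrl = by_group[control_group]
    if ctrl["mean_copies"] <= 0:
        raise ValueError("control group mean copies must be positive")
    rows = []
    for s in stats:
        g = s["sample_group"]
        if g == control_group:
            rows.append({"sample_group": g, "method": "absolute", "fold": 1.0, "se": 0.0})
            continue
        fold = s["mean_copies"] / ctrl["mean_copies"]
        rel_var = 0.0
        for part in (s, ctrl):
            if part["mean_copies"] > 0 and part.get("sem_copies") is not None:
                rel_var += (part["sem_copies"] / part["mean_copies"]) ** 2
        rows.append({
            "sample_group": g, "method": "absolute",
            "fold": float(fold), "se": float(fold * math.sqrt(rel_var)),
        })
    return pd.DataFrame(rows)


def cq_table_from_results(results) -> pd.DataFrame:
    """Build a Cq table from per-well quantification results.

    The take-off point doubles as the Cq; per-reaction efficiencies ride
    along for Pfaffl-style analysis.
    """
    rows = []
    for r in results:
        if r.window is None or not np.isfinite(r.E):
            continue
        rows.append({
            "sample_group": r.sample_group,
            "target": r.target,
            "replicate": r.replicate,
            "cq": r.window.takeoff,
            "efficiency": r.E,
        })
    return pd.DataFrame(rows, columns=list(CQ_COLUMNS) + ["efficiency"])
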