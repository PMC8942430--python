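"""Clinical derivations: HOMA-IR, Friedewald LDL, postprandial AUCs, EGD.

All concentrations are in mmol/L (glucose, cholesterol fractions,
triglycerides) and mIU/L (insulin), matching the conventions that fix the
constants: HOMA-IR = glucose × insulin / 22.5, and Friedewald LDL =
TC − HDL − TG/2.2 (the 2.2 divisor is the mmol/L form of TG/5).  The arm
contrast summarises a crossover comparison as the estimated group
difference (EGD): the mean, over subjects, of the multi-fiber pre→post
change minus the control pre→post change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import design as dsg

#: Standard postprandial sampling grid (minutes after the test breakfast)
#: over the first meal window.
POSTPRANDIAL_GRID = (0, 15, 30, 45, 60, 90, 120, 180, 210, 240)

FRIEDEWALD_TG_LIMIT = 4.5  # mmol/L; formula unreliable above this


def homa_ir(glucose_mm, insulin_miu_l):
    """HOMA-IR: fasting glucose (mM) × fasting insulin (mIU/l) / 22.5."""
    glucose = np.asarray(glucose_mm, dtype=float)
    insulin = np.asarray(insulin_miu_l, dtype=float)
    if (glucose <= 0).any():
        raise ValueError("glucose must be strictly positive")
    if (insulin < 0).any():
        raise ValueError("insulin must be non-negative")
    out = glucose * insulin / 22.5
    return float(out) if out.ndim == 0 else out


def friedewald_ldl(tc_mm, hdl_mm, tg_mm, tg_limit: float = FRIEDEWALD_TG_LIMIT):
    """Friedewald LDL-C (mM): TC − HDL − TG/2.2.

    Values with TG above `tg_limit` are still returned but flagged with a
    warning, since the formula underestimates LDL at high triglycerides.
    """
    tc = np.asarray(tc_mm, dtype=float)
    hdl = np.asarray(hdl_mm, dtype=float)
    tg = np.asarray(tg_mm, dtype=float)
    if (tc < 0).any() or (hdl < 0).any() or (tg < 0).any():
        raise ValueError("lipid concentrations must be non-negative")
    if (tg > tg_limit).any():
        warnings.warn(
            f"triglycerides above {tg_limit} mM: Friedewald LDL unreliable",
            stacklevel=2,
        )
    out = tc - hdl - tg / 2.2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PostprandialSummary:
    tauc: float  # total area under the curve (value·min)
    iauc: float  # incremental AUC: tAUC − baseline × span
    peak: float  # maximum concentration


def postprandial_summary(times, values,
                         truncate_negative: bool = False) -> PostprandialSummary:
    """tAUC (trapezoidal), iAUC (net incremental) and peak of one series.

    `times` are minutes from the meal, starting at 0; the value at t=0 is
    the baseline.  The default iAUC is the net incremental area (negative
    excursions allowed); with `truncate_negative` the per-interval
    increments are floored at zero before summing.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.size < 3:
        raise ValueError("need at least 3 aligned time points")
    if t[0] != 0:
        raise ValueError("series must start at t=0 (the meal)")
    if (np.diff(t) <= 0).any():
        raise ValueError("times must be strictly increasing")
    if (v < 0).any():
        raise ValueError("concentrations must be non-negative")
    tauc = float(np.trapezoid(v, t))
    if truncate_negative:
        centered = v - v[0]
        seg = (centered[1:] + centered[:-1]) / 2 * np.diff(t)
        iauc = float(np.clip(seg, 0, None).sum())
    else:
        iauc = tauc - float(v[0]) * float(t[-1] - t[0])
    return PostprandialSummary(tauc=tauc, iauc=iauc, peak=float(v.max()))


@dataclass(frozen=True)
class ArmContrast:
    variable: str
    n_subjects: int
    mean_change_mf: float
    mean_change_ctl: float
    egd: float              # mean(Δ_MF − Δ_CTL) over subjects
    ci_low: float
    ci_high: float
    cell_means: dict        # (bread, phase) → mean, for reporting


def arm_contrast(values: pd.Series, design: pd.DataFrame, variable: str,
                 confidence: float = 0.95) -> ArmContrast:
    """Estimated group difference for one sample-indexed clinical variable.

    Per subject with all four visits: Δ_MF = post − pre under multi-fiber,
    Δ_CTL likewise; EGD = mean(Δ_MF − Δ_CTL) with a t-based confidence
    interval on the paired per-subject differences.
    """
    from .stats import subject_cell_table

    cells = subject_cell_table(values, design)
    n = len(cells)
    if n < 2:
        raise ValueError("need at least 2 subjects with complete visits")
    d_mf = cells["mf_post"] - cells["mf_pre"]
    d_ctl = cells["ctl_post"] - cells["ctl_pre"]
    paired = (d_mf - d_ctl).to_numpy()
    egd = float(paired.mean())
    se = paired.std(ddof=1) / np.sqrt(n)
    t_crit = sps.t.ppf(0.5 + confidence / 2, df=n - 1)
    means = {(b, p): float(cells[f"{t}_{p}"].mean())
             for b, t in ((dsg.MULTI_FIBER, "mf"), (dsg.CONTROL, "ctl"))
             for p in ("pre", "post")}
    return ArmContrast(
        variable=variable, n_subjects=n,
        mean_change_mf=float(d_mf.mean()), mean_change_ctl=float(d_ctl.mean()),
        egd=egd, ci_low=egd - t_crit * se, ci_high=egd + t_crit * se,
        cell_means=means,
    )


# ---------------------------------------------------------------------
# Long-table helpers
# ---------------------------------------------------------------------

FASTING_VARIABLES = ("glucose", "insulin", "tc", "hdl", "tg")
SERIES_VARIABLES = ("glucose_pp", "insulin_pp")


def derive_summary(clinical_long: pd.DataFrame) -> pd.DataFrame:
    """Per subject × visit derived table from a long clinical table.

    The long table has columns ``subject_id, visit, variable, time_min,
    value``; fasting rows have empty ``time_min``.  Output columns: the
    fasting variables plus ``homa``, ``ldl`` and, for each postprandial
    analyte, ``*_tauc``, ``*_iauc`` and ``*_peak``.
    """
    keys = ["subject_id", "visit"]
    fasting = clinical_long[clinical_long["variable"].isin(FASTING_VARIABLES)]
    wide = fasting.pivot_table(index=keys, columns="variable", values="value",
                               aggfunc="first")
    wide["homa"] = homa_ir(wide["glucose"], wide["insulin"])
    wide["ldl"] = friedewald_ldl(wide["tc"], wide["hdl"], wide["tg"])
    series = clinical_long[clinical_long["variable"].isin(SERIES_VARIABLES)]
    for (subject, visit, var), grp in series.groupby(keys + ["variable"]):
        grp = grp.sort_values("time_min")
        summ = postprandial_summary(grp["time_min"].to_numpy(), grp["value"].to_numpy())
        stem = var.removesuffix("_pp")
        wide.loc[(subject, visit), f"{stem}_tauc"] = summ.tauc
        wide.loc[(subject, visit), f"{stem}_iauc"] = summ.iauc
        wide.loc[(subject, visit), f"{stem}_peak"] = summ.peak
    return wide
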