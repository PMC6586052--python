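"""Diffusion-time slope statistics on hierarchical voxel data.

Voxel metrics measured at gradient separations Δ ∈ {29, 52, 76} ms form a
three-level hierarchy (Δ within voxel within subject).  The quantity of
interest is the per-metric slope dm/dΔ, reported with a 95% CI and
converted to a percentage change over the 47 ms span from Δ = 29 to 76 ms
relative to the ROI-wise median baseline at Δ = 29 ms.

Two estimators are provided: a closed-form two-stage procedure (per-voxel
OLS slopes averaged with between-subject inference, the default) and a
mixed-effects model with random intercept and random slope by subject plus
a voxel-level random intercept (maximum likelihood, via statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SlopeEstimate", "fit_slope", "percent_change", "BASELINE_DELTA_MS", "DELTA_SPAN_MS"]

BASELINE_DELTA_MS = 29.0
DELTA_SPAN_MS = 47.0  # 76 − 29 ms


@dataclass
class SlopeEstimate:
    slope: float  # metric units per ms
    ci_low: float
    ci_high: float
    p_value: float
    baseline: float  # ROI median at the baseline Δ
    percent_change: float  # over DELTA_SPAN_MS
    method: str
    n_voxels: int
    n_dropped: int = 0


def percent_change(slope: float, baseline: float, d_delta: float = DELTA_SPAN_MS) -> float:
    """Convert a Δ-slope to a % change over ``d_delta`` ms of baseline."""
    if baseline == 0:
        raise ZeroDivisionError("zero baseline; percent change undefined")
    return 100.0 * slope * d_delta / baseline


def _voxel_slopes(sub: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-(subject, voxel) OLS slope of value on Δ; drops singular voxels."""
    rows = []
    dropped = 0
    for (subj, vox), grp in sub.groupby(["subject", "voxel"]):
        d = grp["Delta"].to_numpy(dtype=float)
        v = grp["value"].to_numpy(dtype=float)
        if len(np.unique(d)) < 2:
            dropped += 1
            continue
        slope = np.polyfit(d, v, 1)[0]
        rows.append({"subject": subj, "voxel": vox, "slope": slope})
    return pd.DataFrame(rows), dropped


def fit_slope(
    table: pd.DataFrame,
    metric: str,
    roi: str,
    method: str = "two_stage",
) -> SlopeEstimate:
    """Estimate dm/dΔ for one metric in one ROI.

    ``table`` is long-format with columns {subject, voxel, roi, Delta,
    metric, value}.  ``two_stage``: per-voxel OLS slopes, pooled by subject
    means with a t interval over subjects (falling back to a
    between-voxel t interval for a single subject).  ``mixed_ml``:
    three-level random-intercept/random-slope model fitted by ML.
    """
    sub = table[(table["metric"] == metric) & (table["roi"] == roi)]
    if sub.empty:
        raise ValueError(f"no rows for metric={metric!r}, roi={roi!r}")
    if sub["Delta"].nunique() < 2:
        raise ValueError("need at least 2 distinct Delta values")
    base = sub[np.isclose(sub["Delta"], BASELINE_DELTA_MS)]
    baseline = float(base["value"].median()) if len(base) else float(sub["value"].median())

    if method == "two_stage":
        vs, dropped = _voxel_slopes(sub)
        if vs.empty:
            raise ValueError("all voxels dropped (singular designs)")
        est = float(vs["slope"].mean())
        subj_means = vs.groupby("subject")["slope"].mean()
        if len(subj_means) >= 2:
            se = float(subj_means.std(ddof=1) / np.sqrt(len(subj_means)))
            df = len(subj_means) - 1
        else:
            se = float(vs["slope"].std(ddof=1) / np.sqrt(len(vs)))
            df = len(vs) - 1
        tcrit = stats.t.ppf(0.975, df)
        tstat = est / se if se > 0 else np.inf
        p = float(2 * stats.t.sf(abs(tstat), df))
        ci = (est - tcrit * se, est + tcrit * se)
        n_vox = vs["voxel"].nunique()
    elif method == "mixed_ml":
        import statsmodels.formula.api as smf

        sub = sub.copy()
        sub["dc"] = sub["Delta"] - BASELINE_DELTA_MS
        sub["voxid"] = sub["subject"].astype(str) + ":" + sub["voxel"].astype(str)
        model = smf.mixedlm(
            "value ~ dc",
            data=sub,
            groups="subject",
            re_formula="~dc",
            vc_formula={"voxid": "0 + C(voxid)"},
        )
        with np.errstate(all="ignore"):
            fit = model.fit(reml=False, method="lbfgs")
        est = float(fit.params["dc"])
        se = float(fit.bse["dc"])
        ci = (est - 1.959964 * se, est + 1.959964 * se)
        p = float(fit.pvalues["dc"])
        n_vox = sub["voxid"].nunique()
        dropped = 0
    else:
        raise ValueError(f"unknown method {method!r}")

    return SlopeEstimate(
        slope=est,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=p,
        baseline=baseline,
        percent_change=percent_change(est, baseline) if baseline != 0 else np.nan,
        method=method,
        n_voxels=int(n_vox),
        n_dropped=int(dropped),
    )
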