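"""Quantification of validation experiments.

Three assay types close the loop on a candidate off-target:

* OD600 growth curves — a three-parameter logistic fit yields the maximal
  specific growth rate r (1/hr) and a tangent-intercept lag time;
* chemiluminescence dose-response of the purified enzyme — the kinase assay
  couples residual ATP to luminescence, so inhibition RAISES the signal;
  signals are rescaled to percent activity against the no-reaction and
  zero-inhibitor references, a four-parameter logistic gives the IC50, and
  the Cheng-Prusoff relation Ki = IC50 / (1 + [S]/Km) converts it to the
  competitive inhibition constant;
* single-cell length distributions from DIC imaging — non-normal, compared
  by the one-sided Mann-Whitney test with a boxplot-style percentile summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .metabstats import mann_whitney_one_sided

__all__ = [
    "GrowthFit",
    "ActivityFit",
    "fit_logistic_growth",
    "percent_activity",
    "fit_ic50",
    "ki_cheng_prusoff",
    "compare_cell_lengths",
]


@dataclass
class GrowthFit:
    """Logistic growth parameters: rate r (1/hr), lag (hr), capacity K (OD)."""

    r: float
    lag: float
    K: float
    t_mid: float
    residual_norm: float
    flat: bool = False


def _logistic(t, K, r, t_mid):
    return K / (1.0 + np.exp(-r * (t - t_mid)))


def fit_logistic_growth(curve: pd.DataFrame, lag_method: str = "tangent") -> GrowthFit:
    """Least-squares logistic fit of an OD600 time course.

    curve: DataFrame with columns time_h, od600 (time strictly increasing).
    Lag is the tangent-intercept time by default — where the tangent at the
    inflection point crosses the initial OD — with a threshold-crossing
    alternative (first time OD exceeds 5% of K) via lag_method="threshold".
    A flat curve returns r = 0 with lag undefined (NaN) and flat=True.
    """
    t = np.asarray(curve["time_h"], dtype=float)
    od = np.asarray(curve["od600"], dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    span = od.max() - od.min()
    if span < 1e-6 * max(od.max(), 1.0):
        return GrowthFit(0.0, math.nan, float(od.mean()), math.nan, 0.0, flat=True)

    K0 = od.max()
    half = np.argmin(np.abs(od - K0 / 2))
    t_mid0 = t[half]
    r0 = 4.0 / max(t[-1] - t[0], 1e-6) * 4  # crude slope scale
    try:
        popt, _ = curve_fit(
            _logistic, t, od, p0=[K0, r0, t_mid0],
            bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"logistic growth fit did not converge: {exc}") from exc
    K, r, t_mid = popt
    resid = float(np.linalg.norm(od - _logistic(t, *popt)))
    if lag_method == "tangent":
        # tangent at inflection: slope rK/4 through (t_mid, K/2); crosses the
        # pre-growth baseline (~0) at t_mid - 2/r
        lag = t_mid - 2.0 / r
    elif lag_method == "threshold":
        above = np.nonzero(od > 0.05 * K)[0]
        lag = float(t[above[0]]) if above.size else math.nan
    else:
        raise ValueError(f"unknown lag_method {lag_method!r}")
    return GrowthFit(float(r), float(lag), float(K), float(t_mid), resid)


def percent_activity(signal, zero_inhibitor_signal: float, no_reaction_signal: float):
    """Residual enzyme activity (%) from chemiluminescence signals.

    activity = (signal - no_reaction) / (zero_inhibitor - no_reaction) x 100.
    The zero-inhibitor reference is the fully active reaction (ATP consumed,
    low luminescence); the no-reaction reference is the enzyme-free maximum.
    Values are not clipped to [0, 100]: clipping noisy points would bias
    downstream IC50 fits.  Invariant to any affine re-gaining of the
    luminometer applied to all three signals.
    """
    if zero_inhibitor_signal == no_reaction_signal:
        raise ZeroDivisionError("reference signals are equal; activity undefined")
    signal = np.asarray(signal, dtype=float)
    out = (signal - no_reaction_signal) / (zero_inhibitor_signal - no_reaction_signal) * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass
class ActivityFit:
    """Four-parameter logistic fit of percent activity vs inhibitor dose."""

    ic50: float  # concentration at 50% activity (uM)
    hill: float
    top: float  # activity asymptote at zero inhibitor (%)
    bottom: float  # activity asymptote at saturating inhibitor (%)
    activity: pd.DataFrame  # conc_um, percent_activity
    ki: float = math.nan
    substrate_conc: float = math.nan
    km: float = math.nan

    def activity_at(self, conc: float) -> float:
        return _four_pl(np.asarray([conc]), self.top, self.bottom,
                        self.ic50_param, self.hill)[0]

    ic50_param: float = math.nan  # 4PL midpoint parameter


def _four_pl(c, top, bottom, mid, hill):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        frac = np.where(c > 0, (c / mid) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + frac)


def fit_ic50(dose_response: pd.DataFrame, no_reaction_signal: float | None = None) -> ActivityFit:
    """Fit the inhibition curve and locate the 50%-activity concentration.

    dose_response: columns conc_um, signal; must include concentration 0
    (the zero-inhibitor reference).  The no-reaction reference is taken, in
    order of preference, from the argument, from the table's
    attrs['no_reaction_signal'] (the enzyme-free control well), or from the
    signal at the highest dose (saturating inhibition).  Signals are
    converted to percent activity, a 4PL with asymptotes bounded to
    [-10, 110]% is fitted, and the IC50 is the concentration where the
    fitted curve crosses 50%.
    """
    conc = np.asarray(dose_response["conc_um"], dtype=float)
    signal = np.asarray(dose_response["signal"], dtype=float)
    if conc.size < 4:
        raise ValueError("need at least 4 concentrations")
    if not np.any(conc == 0):
        raise ValueError("dose-response must include the zero-inhibitor point")
    zero_sig = float(signal[conc == 0].mean())
    if no_reaction_signal is None:
        no_reaction_signal = dose_response.attrs.get("no_reaction_signal")
    if no_reaction_signal is None:
        no_reaction_signal = float(signal[conc == conc.max()].mean())
    act = percent_activity(signal, zero_sig, no_reaction_signal)

    pos = conc > 0
    if act[pos].min() > 55 or act[pos].max() < 45:
        raise ValueError("no 50% transition within the tested concentration range")
    mid0 = float(np.exp(np.interp(50.0, act[pos][::-1], np.log(conc[pos][::-1]))))
    popt, _ = curve_fit(
        _four_pl, conc, act,
        p0=[100.0, 0.0, mid0, 1.0],
        bounds=([-10.0, -10.0, 1e-9, 0.1], [110.0, 110.0, 1e9, 10.0]),
        maxfev=20000,
    )
    top, bottom, mid, hill = (float(v) for v in popt)
    if not (bottom < 50.0 < top):
        raise ValueError("fitted asymptotes do not bracket 50% activity")
    ic50 = float(brentq(lambda c: _four_pl(c, *popt) - 50.0,
                        1e-12, conc[pos].max() * 1e3))
    fit = ActivityFit(ic50=ic50, hill=hill, top=top, bottom=bottom,
                      activity=pd.DataFrame({"conc_um": conc,
                                             "percent_activity": act}),
                      ic50_param=mid)
    return fit


def ki_cheng_prusoff(ic50: float, substrate_conc: float, km: float) -> float:
    """Competitive-inhibitor constant via Cheng-Prusoff: IC50/(1+[S]/Km)."""
    if ic50 <= 0 or substrate_conc <= 0 or km <= 0:
        raise ValueError("ic50, substrate_conc and km must all be positive")
    return ic50 / (1.0 + substrate_conc / km)


def compare_cell_lengths(sample_a, sample_b, alternative: str = "greater") -> dict:
    """Compare two cell-length samples (um), boxplot summary + rank test.

    alternative='greater' tests whether sample_b tends to exceed sample_a
    (treated cells longer than untreated).  Returns medians, means, the
    10/25/75/90 percentiles of each sample, and the one-sided p-value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u, p = mann_whitney_one_sided(b, a, alternative)

    def summary(v):
        q = np.percentile(v, [10, 25, 75, 90])
        return {"median": float(np.median(v)), "mean": float(v.mean()),
                "p10": q[0], "p25": q[1], "p75": q[2], "p90": q[3],
                "min": float(v.min()), "max": float(v.max()), "n": int(v.size)}

    return {"a": summary(a), "b": summary(b), "U": u, "p_value": p}
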