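"""Onset/offset kinetics of band power: sigmoid fits, 90% rise time, 90-10% fall."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ParameterError, UndefinedKineticsError
from .spectral import BandPowerSeries


def sigmoid(t: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    """c / (1 + exp(-a*t + a*b)) + d; a in 1/min, b in min."""
    return c / (1.0 + np.exp(-a * t + a * b)) + d


@dataclass
class SigmoidFit:
    a: float                  # slope, 1/min
    b: float                  # midpoint, min
    c: float                  # amplitude
    d: float                  # baseline
    rss: float
    converged: bool
    fit_window: tuple | None = None

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def default_init(times_min: np.ndarray, values: np.ndarray) -> dict:
    """Heuristic starting parameters: amplitude/baseline from the range,
    midpoint at the half-max crossing, slope from the 10-90% rise span."""
    vmin, vmax = float(np.min(values)), float(np.max(values))
    c = max(vmax - vmin, 1e-12)
    half = vmin + 0.5 * c
    above = np.flatnonzero(values >= half)
    b = float(times_min[above[0]]) if above.size else float(np.median(times_min))
    hi = np.flatnonzero(values >= vmin + 0.9 * c)
    lo = np.flatnonzero(values >= vmin + 0.1 * c)
    span = (times_min[hi[0]] - times_min[lo[0]]) if hi.size and lo.size else 0.0
    a = 4.0 / span if span > 0 else 1.0
    return {"a": a, "b": b, "c": c, "d": vmin}


def fit_sigmoid(times_min: np.ndarray, values: np.ndarray, init: dict | None = None,
                fit_window: tuple | None = None) -> SigmoidFit:
    """Nonlinear least squares of the four-parameter sigmoid.

    Non-convergence or a fitted slope a <= 0 marks the fit unusable
    (``converged = False``); such channels are excluded downstream.
    """
    times_min = np.asarray(times_min, float)
    values = np.asarray(values, float)
    if times_min.size == 0:
        raise ParameterError("empty fit window")
    if times_min.size < 8:
        raise ParameterError(f"need >= 8 samples to fit, got {times_min.size}")
    p0d = default_init(times_min, values)
    if init:
        p0d.update(init)
    p0 = [p0d["a"], p0d["b"], p0d["c"], p0d["d"]]
    try:
        import warnings as _w
        with np.errstate(over="ignore"), _w.catch_warnings():
            _w.simplefilter("ignore")
            popt, _ = curve_fit(sigmoid, times_min, values, p0=p0, maxfev=20000)
        a, b, c, d = (float(v) for v in popt)
        resid = values - sigmoid(times_min, a, b, c, d)
        rss = float(resid @ resid)
        ok = np.isfinite([a, b, c, d]).all() and a > 0 and c > 0
        # a flat series can "converge" to a degenerate sigmoid; require the
        # fitted rise to actually occur and to explain variance
        rng = values.max() - values.min()
        if ok and (rng <= 0 or c < 0.1 * rng):
            ok = False
        return SigmoidFit(a, b, c, d, rss, bool(ok), fit_window)
    except (RuntimeError, TypeError):
        return SigmoidFit(*p0, rss=np.inf, converged=False, fit_window=fit_window)


def gbo90_min(fit: SigmoidFit) -> float:
    """Smallest t with fitted power >= 90% of the asymptote c + d.

    Closed form t = b - (1/a) * ln(c / (0.9 (c+d) - d) - 1).
    """
    if not fit.converged:
        raise UndefinedKineticsError("cannot derive GBO_90 from a failed fit")
    a, b, c, d = fit.params
    thresh = 0.9 * (c + d) - d
    if thresh <= 0:
        raise UndefinedKineticsError("90% threshold at or below baseline; GBO_90 undefined")
    arg = c / thresh - 1.0
    if arg <= 0:
        raise UndefinedKineticsError("sigmoid asymptote below 90% threshold")
    return b - np.log(arg) / a


def fall_interval(times_s: np.ndarray, values: np.ndarray,
                  antagonist_onset_s: float | None = None) -> dict:
    """90->10% fall interval of a power series, via linear interpolation.

    Thresholds are referenced to the window minimum: hi = min + 0.9*(max-min),
    lo = min + 0.1*(max-min).  The last falling pass is used: the final
    downward crossing of lo, and the latest downward crossing of hi before
    it.  ``gbo10_s`` is the lo-crossing time relative to
    ``antagonist_onset_s`` (or to the window start).
    """
    t = np.asarray(times_s, float)
    v = np.asarray(values, float)
    if t.size < 3:
        raise ParameterError("need >= 3 samples")
    imax = int(np.argmax(v))
    if imax == t.size - 1:
        raise UndefinedKineticsError("series maximum at last sample; no falling phase")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise UndefinedKineticsError("constant series; fall interval undefined")
    hi = vmin + 0.9 * (vmax - vmin)
    lo = vmin + 0.1 * (vmax - vmin)

    def down_crossings(level: float) -> np.ndarray:
        idx = np.flatnonzero((v[:-1] >= level) & (v[1:] < level))
        return t[idx] + (level - v[idx]) / (v[idx + 1] - v[idx]) * (t[idx + 1] - t[idx])

    lo_x = down_crossings(lo)
    if lo_x.size == 0:
        raise UndefinedKineticsError("series never falls below the 10% threshold")
    t_lo = float(lo_x[-1])
    hi_x = down_crossings(hi)
    hi_before = hi_x[hi_x <= t_lo]
    if hi_before.size == 0:
        raise UndefinedKineticsError("no 90% downward crossing before the 10% crossing")
    t_hi = float(hi_before[-1])
    ref = antagonist_onset_s if antagonist_onset_s is not None else float(t[0])
    return {"gbo90_10_s": t_lo - t_hi, "gbo10_s": t_lo - ref}


def fractional_power_change(p_drug: float, p_vehicle: float) -> float:
    """(P_drug - P_vehicle) / P_vehicle; e.g. -0.55 for power reduced to 45%."""
    if p_vehicle <= 0:
        raise UndefinedKineticsError("vehicle power must be positive")
    return (p_drug - p_vehicle) / p_vehicle


def channel_kinetics(bps: BandPowerSeries, drug_window: tuple[float, float],
                     fall_window: tuple[float, float] | None = None,
                     antagonist_onset_s: float | None = None,
                     vehicle_window: tuple[float, float] | None = None,
                     drug_plateau_window: tuple[float, float] | None = None,
                     region_of=None, slice_id: str = "") -> pd.DataFrame:
    """Per-electrode kinetics table from a band-power series.

    ``drug_window`` (seconds, record time) bounds the sigmoid fit; times are
    refit in minutes from drug onset.  ``fall_window`` bounds the 90-10 fall
    search.  ``vehicle_window`` / ``drug_plateau_window`` feed the fractional
    power change.  Channels whose sigmoid fit fails get fit_ok = False.
    """
    t = bps.times_s
    rows = []
    for i, eid in enumerate(bps.electrode_ids):
        p = bps.power[i]
        rec: dict = {"electrode_id": int(eid), "slice_id": slice_id,
                     "region": region_of(int(eid)) if region_of else "",
                     "fit_ok": False, "gbo90_min": np.nan, "gbo10_s": np.nan,
                     "gbo90_10_s": np.nan, "frac_change": np.nan,
                     "a_per_min": np.nan, "b_min": np.nan}
        m = (t >= drug_window[0]) & (t < drug_window[1])
        if m.sum() >= 8:
            tm = (t[m] - drug_window[0]) / 60.0
            fit = fit_sigmoid(tm, p[m], fit_window=drug_window)
            if fit.converged:
                rec["fit_ok"] = True
                rec["a_per_min"], rec["b_min"] = fit.a, fit.b
                try:
                    rec["gbo90_min"] = gbo90_min(fit)
                except UndefinedKineticsError:
                    pass
        if fall_window is not None:
            fm = (t >= fall_window[0]) & (t < fall_window[1])
            try:
                fi = fall_interval(t[fm], p[fm], antagonist_onset_s=antagonist_onset_s)
                rec.update(gbo90_10_s=fi["gbo90_10_s"], gbo10_s=fi["gbo10_s"])
            except (UndefinedKineticsError, ParameterError):
                pass
        if vehicle_window is not None and drug_plateau_window is not None:
            vm = (t >= vehicle_window[0]) & (t < vehicle_window[1])
            dm = (t >= drug_plateau_window[0]) & (t < drug_plateau_window[1])
            if vm.any() and dm.any():
                pv, pdg = float(p[vm].mean()), float(p[dm].mean())
                if pv > 0:
                    rec["frac_change"] = fractional_power_change(pdg, pv)
        rows.append(rec)
    return pd.DataFrame.from_records(rows)
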