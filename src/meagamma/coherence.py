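"""Pairwise magnitude coherence, power-envelope correlation, and graph export."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocess import LfpRecording
from .spectral import (BandDefinition, BandPowerSeries, GAMMA_BAND, DEFAULT_K, DEFAULT_NW,
                       DEFAULT_WINDOW_S, _dpss_tapers, _frame)

WITHIN_CA1 = "within_CA1"
WITHIN_CA3 = "within_CA3"
BETWEEN = "between_CA1_CA3"

DEFAULT_GRAPH_THRESHOLD = 0.45


@dataclass
class CoherenceSpectrum:
    freqs_hz: np.ndarray
    coherence: np.ndarray      # in [0, 1]
    pair: tuple[int, int] | None = None
    window: tuple | None = None


def _tapered_frames(x: np.ndarray, fs: float, nw: float, k: int, window_s: float) -> np.ndarray:
    """Tapered FFTs of sliding windows: (n_windows, K, n_freqs) complex."""
    frames, _ = _frame(x, fs, window_s, window_s)  # non-overlapping windows
    tapers = _dpss_tapers(frames.shape[1], nw, k)
    return np.fft.rfft(frames[:, None, :] * tapers[None, :, :], axis=-1)


def multitaper_coherence(x: np.ndarray, y: np.ndarray, fs: float, nw: float = DEFAULT_NW,
                         k: int = DEFAULT_K, window_s: float = DEFAULT_WINDOW_S,
                         zero_lag: bool = False) -> CoherenceSpectrum:
    """Magnitude coherence |S_xy| / sqrt(S_x S_y), averaged over tapers and windows.

    ``zero_lag`` replaces |S_xy| with Re(S_xy) (the zero-phase-lag
    component); the default is the magnitude form.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ParameterError(f"length mismatch: {x.size} vs {y.size}")
    fx = _tapered_frames(x, fs, nw, k, window_s)
    fy = _tapered_frames(y, fs, nw, k, window_s)
    sx = (np.abs(fx) ** 2).mean(axis=(0, 1))
    sy = (np.abs(fy) ** 2).mean(axis=(0, 1))
    # symmetrized cross-spectrum so coherence(x, y) == coherence(y, x) bitwise
    sxy = (0.5 * (fx * np.conj(fy) + np.conj(fy * np.conj(fx)))).mean(axis=(0, 1))
    denom = np.sqrt(sx * sy)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.real(sxy) if zero_lag else np.abs(sxy)
        c = np.where(denom > 0, num / denom, 0.0)
    c = np.clip(c, -1.0 if zero_lag else 0.0, 1.0)
    n = int(round(window_s * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return CoherenceSpectrum(freqs_hz=freqs, coherence=c, pair=None, window=None)


def band_coherence(cs: CoherenceSpectrum, band: BandDefinition = GAMMA_BAND) -> float:
    """Mean coherence over band frequencies (inclusive band edges)."""
    f = cs.freqs_hz
    if band.f_lo < f[0] or band.f_hi > f[-1]:
        raise ParameterError("band outside coherence spectrum range")
    m = (f >= band.f_lo) & (f <= band.f_hi)
    return float(cs.coherence[m].mean())


def region_pair_label(r1: str, r2: str) -> str:
    if r1 == r2 == "CA1":
        return WITHIN_CA1
    if r1 == r2 == "CA3":
        return WITHIN_CA3
    return BETWEEN


def pairwise_table(lfp: LfpRecording, condition_windows: dict[str, tuple[float, float]],
                   band: BandDefinition = GAMMA_BAND, nw: float = DEFAULT_NW,
                   k: int = DEFAULT_K, window_s: float = DEFAULT_WINDOW_S,
                   vehicle_condition: str = "vehicle",
                   drug_condition: str = "kainate") -> pd.DataFrame:
    """Band coherence for every unordered labeled electrode pair and condition.

    ``condition_windows`` maps condition -> (t0_s, t1_s) analysis window.
    Electrodes without a CA1/CA3 label (including the reference) are
    excluded.  fold_change = coherence_drug / coherence_vehicle when both
    conditions are present.
    """
    tbl = lfp.layout.table
    keep = (~tbl["is_reference"]) & tbl["region"].isin(["CA1", "CA3"])
    eids = tbl.loc[keep, "electrode_id"].to_numpy()
    regions = dict(zip(tbl.loc[keep, "electrode_id"], tbl.loc[keep, "region"]))
    if len(eids) < 2:
        raise ParameterError("need >= 2 labeled electrodes")
    for r in ("CA1", "CA3"):
        if sum(1 for e in eids if regions[e] == r) < 1:
            warnings.warn(f"region {r} has no labeled electrodes; its pairs are absent")

    # per-condition band coherence matrix over labeled channels
    band_c: dict[str, np.ndarray] = {}
    for cond, (t0, t1) in condition_windows.items():
        seg = lfp.segment(t0, t1)
        n_win = int(round(window_s * lfp.fs_hz))
        freqs = np.fft.rfftfreq(n_win, 1.0 / lfp.fs_hz)
        fmask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
        ffts = []
        for eid in eids:
            ch = lfp.layout.channel_index(int(eid))
            ffts.append(_tapered_frames(seg[ch], lfp.fs_hz, nw, k, window_s)[:, :, fmask])
        ffts = np.asarray(ffts)  # (n_elec, n_windows, K, n_band_freqs)
        auto = (np.abs(ffts) ** 2).mean(axis=(1, 2))
        ne = len(eids)
        mat = np.eye(ne)
        for i in range(ne):
            cross = (ffts[i][None, :, :, :] * np.conj(ffts[i + 1:])).mean(axis=(1, 2))
            denom = np.sqrt(auto[i][None, :] * auto[i + 1:])
            c = np.clip(np.abs(cross) / denom, 0.0, 1.0).mean(axis=1)
            mat[i, i + 1:] = c
            mat[i + 1:, i] = c
        band_c[cond] = mat

    rows = []
    for ii in range(len(eids)):
        for jj in range(ii + 1, len(eids)):
            e1, e2 = int(eids[ii]), int(eids[jj])
            label = region_pair_label(regions[e1], regions[e2])
            fold = np.nan
            if vehicle_condition in band_c and drug_condition in band_c:
                cv = band_c[vehicle_condition][ii, jj]
                cd = band_c[drug_condition][ii, jj]
                if cv > 0:
                    fold = cd / cv
            for cond in condition_windows:
                rows.append({
                    "slice_id": lfp.slice_id, "elec1": min(e1, e2), "elec2": max(e1, e2),
                    "region_pair": label, "condition": cond,
                    "band_coherence": float(band_c[cond][ii, jj]),
                    "fold_change": float(fold),
                })
    return pd.DataFrame.from_records(rows)


def power_correlation_map(bps: BandPowerSeries,
                          window: tuple[float, float] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of band-power time courses for every electrode pair.

    Returns (electrode_ids, matrix).  Zero-variance channels yield NaN rows
    /columns (flagged via a warning); the diagonal is 1 by convention.
    """
    p = bps.power
    if window is not None:
        m = (bps.times_s >= window[0]) & (bps.times_s < window[1])
        p = p[:, m]
    if p.shape[0] < 2 or p.shape[1] < 3:
        raise ParameterError("need >= 2 electrodes and >= 3 time points")
    sd = p.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        warnings.warn(f"zero-variance channels {bps.electrode_ids[flat].tolist()}; "
                      "their correlations are undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(p)
    np.fill_diagonal(r, 1.0)
    return bps.electrode_ids.copy(), r


def build_graph(records: pd.DataFrame, node_powers: dict[int, float], layout,
                threshold: float = DEFAULT_GRAPH_THRESHOLD,
                condition: str | None = None) -> nx.Graph:
    """Coherence graph: all labeled electrodes as nodes, edges where
    band_coherence >= threshold (inclusive)."""
    df = records
    if condition is not None:
        df = df[df["condition"] == condition]
    g = nx.Graph(threshold=threshold)
    eids = sorted(set(df["elec1"]) | set(df["elec2"]))
    for eid in eids:
        x, y = layout.position(int(eid))
        g.add_node(int(eid), x_um=x, y_um=y, region=layout.region_of(int(eid)),
                   band_power=float(node_powers.get(int(eid), np.nan)))
    for _, row in df.iterrows():
        if row["band_coherence"] >= threshold:
            g.add_edge(int(row["elec1"]), int(row["elec2"]),
                       band_coherence=float(row["band_coherence"]))
    return g
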