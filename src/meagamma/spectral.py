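"""Multitaper spectra, sliding band power, Morlet spectrograms, peak/Q factor."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.signal.windows import dpss

from .errors import ParameterError, UndefinedKineticsError
from .preprocess import LfpRecording

DEFAULT_NW = 3.0
DEFAULT_K = 5
DEFAULT_WINDOW_S = 2.0
DEFAULT_STEP_S = 1.0


@dataclass(frozen=True)
class BandDefinition:
    """Analysis band; defaults to the 25-59 Hz slow-gamma band."""

    f_lo: float = 25.0
    f_hi: float = 59.0

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ParameterError(f"invalid band [{self.f_lo}, {self.f_hi}]")


GAMMA_BAND = BandDefinition(25.0, 59.0)


@dataclass
class PowerSpectrum:
    freqs_hz: np.ndarray
    power: np.ndarray          # one-sided density, uV^2/Hz
    window: tuple | None = None
    channel_id: int | None = None
    nw: float = DEFAULT_NW
    k: int = DEFAULT_K


@dataclass
class Spectrogram:
    times_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray          # (n_freqs, n_times), uV^2
    valid: np.ndarray          # boolean, False near edges (within 3 sigma_t)
    wavelet_width: float = 25.0


@dataclass
class SpectralPeak:
    f0_hz: float
    bandwidth_hz: float        # width at 50% of peak power

    @property
    def q(self) -> float:
        return self.f0_hz / self.bandwidth_hz


@dataclass
class BandPowerSeries:
    times_s: np.ndarray        # window centers
    power: np.ndarray          # (n_channels, n_windows), uV^2
    electrode_ids: np.ndarray
    band: BandDefinition = field(default_factory=BandDefinition)
    window_s: float = DEFAULT_WINDOW_S
    step_s: float = DEFAULT_STEP_S

    def channel(self, electrode_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.electrode_ids == electrode_id)
        if idx.size == 0:
            raise KeyError(f"electrode {electrode_id} not in series")
        return self.power[int(idx[0])]


def _dpss_tapers(n: int, nw: float, k: int) -> np.ndarray:
    if k > int(2 * nw - 1 + 1e-9):
        raise ParameterError(f"taper count K={k} exceeds 2*NW-1={2 * nw - 1:g}")
    return dpss(n, nw, Kmax=k)


def multitaper_psd(x: np.ndarray, fs: float, nw: float = DEFAULT_NW,
                   k: int = DEFAULT_K) -> PowerSpectrum:
    """One-sided multitaper power spectral density.

    Averages K Slepian eigenspectra; the density integrates (over [0,
    Nyquist]) to the signal's mean square, i.e. the Parseval convention.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("signal must be 1-D with >= 2 samples")
    tapers = _dpss_tapers(x.size, nw, k)
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=-1)) ** 2
    psd = spectra.mean(axis=0) / fs
    psd[1:] *= 2.0
    if x.size % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    return PowerSpectrum(freqs_hz=freqs, power=psd, nw=nw, k=k)


def segment_psd(x: np.ndarray, fs: float, nw: float = DEFAULT_NW, k: int = DEFAULT_K,
                window_s: float = DEFAULT_WINDOW_S, step_s: float | None = None) -> PowerSpectrum:
    """Mean multitaper PSD over sliding windows (Welch-style variance reduction)."""
    frames, _ = _frame(x, fs, window_s, step_s if step_s is not None else window_s)
    tapers = _dpss_tapers(frames.shape[1], nw, k)
    spec = np.abs(np.fft.rfft(frames[:, None, :] * tapers[None, :, :], axis=-1)) ** 2
    psd = spec.mean(axis=(0, 1)) / fs
    psd[1:] *= 2.0
    if frames.shape[1] % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(frames.shape[1], 1.0 / fs)
    return PowerSpectrum(freqs_hz=freqs, power=psd, nw=nw, k=k)


def band_power(ps: PowerSpectrum, band: BandDefinition = GAMMA_BAND) -> float:
    """Trapezoidal integral of the density over [f_lo, f_hi]."""
    f, p = ps.freqs_hz, ps.power
    if band.f_lo < f[0] or band.f_hi > f[-1]:
        raise ParameterError(f"band [{band.f_lo}, {band.f_hi}] outside spectrum range")
    inside = (f > band.f_lo) & (f < band.f_hi)
    grid = np.concatenate([[band.f_lo], f[inside], [band.f_hi]])
    vals = np.concatenate([[np.interp(band.f_lo, f, p)], p[inside],
                           [np.interp(band.f_hi, f, p)]])
    return float(np.trapezoid(vals, grid))


def _frame(x: np.ndarray, fs: float, window_s: float, step_s: float):
    """Split a signal into sliding windows; returns (frames, center_times)."""
    x = np.asarray(x, dtype=np.float64)
    win = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))
    if win > x.size:
        raise ParameterError(f"window {window_s}s longer than record {x.size / fs:g}s")
    starts = np.arange(0, x.size - win + 1, step)
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[starts]
    centers = (starts + win / 2.0) / fs
    return frames, centers


def sliding_band_power(lfp: LfpRecording, band: BandDefinition = GAMMA_BAND,
                       window_s: float = DEFAULT_WINDOW_S, step_s: float = DEFAULT_STEP_S,
                       nw: float = DEFAULT_NW, k: int = DEFAULT_K,
                       include_reference: bool = False) -> BandPowerSeries:
    """Per-channel time course of in-band power from windowed multitaper PSDs."""
    tbl = lfp.layout.table
    keep = np.ones(len(tbl), bool) if include_reference else ~tbl["is_reference"].to_numpy()
    eids = tbl["electrode_id"].to_numpy()[keep]
    fs = lfp.fs_hz
    win = int(round(window_s * fs))
    tapers = _dpss_tapers(win, nw, k)
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    out = []
    centers = None
    for ch in np.flatnonzero(keep):
        frames, centers = _frame(lfp.data[ch], fs, window_s, step_s)
        spec = np.abs(np.fft.rfft(frames[:, None, :] * tapers[None, :, :], axis=-1)) ** 2
        psd = spec.mean(axis=1) / fs
        psd[:, 1:] *= 2.0
        if win % 2 == 0:
            psd[:, -1] /= 2.0
        bp = [band_power(PowerSpectrum(freqs, row), band) for row in psd]
        out.append(bp)
    return BandPowerSeries(times_s=np.asarray(centers), power=np.asarray(out),
                           electrode_ids=eids, band=band, window_s=window_s, step_s=step_s)


def morlet_spectrogram(x: np.ndarray, fs: float, freqs_hz: np.ndarray | None = None,
                       m: float = 25.0, t_step_s: float | None = None) -> Spectrogram:
    """Wavelet power via convolution with w(t,f0) = A exp(-t^2/2 s_t^2) exp(2 i pi f0 t).

    Per analyzing frequency f0: s_f = f0/m, s_t = 1/(2 pi s_f), and
    A = (s_t sqrt(pi))^(-1/2).  Samples within 3 s_t of either record edge
    are flagged invalid.  Frequencies whose 3 s_t support exceeds half the
    record are dropped with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    if freqs_hz is None:
        freqs_hz = np.arange(1.0, 100.5, 0.5)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if np.any(freqs_hz <= 0) or np.any(freqs_hz >= fs / 2):
        raise ParameterError("analyzing frequencies must lie in (0, Nyquist)")
    n = x.size
    duration = n / fs
    stride = max(1, int(round((t_step_s or 1.0 / fs) * fs)))
    times = np.arange(n)[::stride] / fs
    kept, rows, valids = [], [], []
    for f0 in freqs_hz:
        sigma_f = f0 / m
        sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
        if 3.0 * sigma_t > duration / 2.0:
            warnings.warn(f"dropping {f0:g} Hz: wavelet support exceeds half the record")
            continue
        half = int(np.ceil(4.0 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        a = (sigma_t * np.sqrt(np.pi)) ** -0.5
        w = a * np.exp(-t ** 2 / (2.0 * sigma_t ** 2)) * np.exp(2j * np.pi * f0 * t)
        conv = signal.fftconvolve(x, w, mode="same") / fs
        p = np.abs(conv) ** 2
        kept.append(f0)
        rows.append(p[::stride])
        edge = 3.0 * sigma_t
        valids.append((times >= edge) & (times <= duration - edge))
    if not kept:
        raise ParameterError("no analyzing frequency fits the record")
    return Spectrogram(times_s=times, freqs_hz=np.asarray(kept),
                       power=np.asarray(rows), valid=np.asarray(valids), wavelet_width=m)


def peak_and_q(ps: PowerSpectrum, search_band: BandDefinition = BandDefinition(5.0, 59.0)) -> SpectralPeak:
    """Peak frequency and half-power bandwidth -> Q = f0 / B.

    f0 is the in-band argmax of the density (ties broken toward lower
    frequency).  B spans the outermost half-max crossings flanking f0,
    located by linear interpolation between bins.  If the density never
    drops below half-max on one side, Q is undefined.
    """
    f, p = ps.freqs_hz, ps.power
    if search_band.f_lo < f[0] or search_band.f_hi > f[-1]:
        raise ParameterError("search band outside spectrum range")
    mask = (f >= search_band.f_lo) & (f <= search_band.f_hi)
    if not mask.any():
        raise ParameterError("no frequency bins inside search band")
    sub_idx = np.flatnonzero(mask)
    peak_pos = sub_idx[int(np.argmax(p[sub_idx]))]
    f0 = float(f[peak_pos])
    half = p[peak_pos] / 2.0

    def crossing(i_lo: int, i_hi: int) -> float:
        # linear interpolation of the half-max crossing between two bins
        f1, f2, p1, p2 = f[i_lo], f[i_hi], p[i_lo], p[i_hi]
        return float(f1 + (half - p1) / (p2 - p1) * (f2 - f1))

    # outermost upward crossing left of the peak (scanning from the low edge)
    up = np.flatnonzero((p[:peak_pos] < half) & (p[1:peak_pos + 1] >= half))
    if up.size == 0:
        raise UndefinedKineticsError("no half-max crossing left of peak; Q undefined")
    left = crossing(up[0], up[0] + 1)

    # outermost downward crossing right of the peak (scanning from the high edge)
    down = np.flatnonzero((p[peak_pos:-1] >= half) & (p[peak_pos + 1:] < half)) + peak_pos
    if down.size == 0:
        raise UndefinedKineticsError("no half-max crossing right of peak; Q undefined")
    right = crossing(down[-1], down[-1] + 1)

    b = right - left
    if b <= 0:
        raise UndefinedKineticsError("degenerate half-power bandwidth; Q undefined")
    return SpectralPeak(f0_hz=f0, bandwidth_hz=float(b))


def spectral_summary(lfp: LfpRecording, window: tuple[float, float],
                     band: BandDefinition = GAMMA_BAND,
                     search_band: BandDefinition = BandDefinition(5.0, 59.0),
                     nw: float = DEFAULT_NW, k: int = DEFAULT_K,
                     window_s: float = DEFAULT_WINDOW_S) -> pd.DataFrame:
    """Per-electrode peak frequency, bandwidth, Q, and band power in a time window."""
    t0, t1 = window
    tbl = lfp.layout.table
    rows = []
    for i in range(len(tbl)):
        if tbl["is_reference"].iloc[i]:
            continue
        seg = lfp.segment(t0, t1)[i]
        ps = segment_psd(seg, lfp.fs_hz, nw=nw, k=k, window_s=window_s)
        rec = {"electrode_id": int(tbl["electrode_id"].iloc[i]),
               "region": tbl["region"].iloc[i],
               "band_power": band_power(ps, band),
               "f0_hz": np.nan, "bandwidth_hz": np.nan, "q": np.nan}
        try:
            pk = peak_and_q(ps, search_band)
            rec.update(f0_hz=pk.f0_hz, bandwidth_hz=pk.bandwidth_hz, q=pk.q)
        except UndefinedKineticsError:
            pass
        rows.append(rec)
    return pd.DataFrame.from_records(rows)
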