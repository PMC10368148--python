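"""Wideband recording -> 1 kHz LFP: zero-phase low-pass, decimation, artifact repair."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ParameterError
from .synth import Recording

DEFAULT_CUTOFF_HZ = 100.0
DEFAULT_ORDER = 4
DEFAULT_LFP_FS = 1000.0


@dataclass
class LfpRecording(Recording):
    """Low-pass filtered, decimated recording with processing provenance."""

    provenance: dict = field(default_factory=dict)


def lowpass_lfp(rec: Recording, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                order: int = DEFAULT_ORDER) -> Recording:
    """Zero-phase (forward-backward) Butterworth low-pass on every channel.

    Filtering is applied to the full record once; epoch boundaries are
    untouched.  The forward-backward pass doubles the effective order and
    leaves phase (hence coherence) intact.
    """
    if cutoff_hz >= rec.fs_hz / 2:
        raise ParameterError(f"cutoff {cutoff_hz} Hz >= Nyquist {rec.fs_hz / 2} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.fs_hz, output="sos")
    data = signal.sosfiltfilt(sos, rec.data.astype(np.float64), axis=-1).astype(np.float32)
    out = dataclasses.replace(rec, data=data)
    out.filter_spec = {"type": "butterworth", "order": order, "cutoff_hz": cutoff_hz,
                       "zero_phase": True}
    return out


def downsample(rec: Recording, target_fs: float = DEFAULT_LFP_FS) -> LfpRecording:
    """Decimate by an integer factor; timestamps stay in seconds.

    The record must already be low-pass filtered below the new Nyquist
    (see :func:`lowpass_lfp`); plain sample-picking is then alias-free.
    """
    factor = rec.fs_hz / target_fs
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ParameterError(f"fs {rec.fs_hz} not an integer multiple of target {target_fs}")
    factor = int(round(factor))
    data = np.ascontiguousarray(rec.data[:, ::factor])
    prov = {
        "filter_spec": getattr(rec, "filter_spec", None),
        "decimation_factor": factor,
        "interpolated_segments": {},
    }
    return LfpRecording(data=data, fs_hz=target_fs, layout=rec.layout, epochs=list(rec.epochs),
                        slice_id=rec.slice_id, ground_truth=rec.ground_truth, provenance=prov)


def to_lfp(rec: Recording, cutoff_hz: float = DEFAULT_CUTOFF_HZ, order: int = DEFAULT_ORDER,
           target_fs: float = DEFAULT_LFP_FS) -> LfpRecording:
    """Convenience: low-pass then decimate."""
    return downsample(lowpass_lfp(rec, cutoff_hz, order), target_fs)


def interpolate_artifacts(lfp: LfpRecording, segments: dict, max_len_s: float = 5.0) -> LfpRecording:
    """Replace artifact windows with straight lines between their neighbors.

    ``segments`` maps electrode_id -> list of half-open (t0_s, t1_s) windows.
    Each window is replaced by the line joining the last sample before it to
    the first sample at/after its end.  Windows touching either record
    boundary have no anchor and raise.
    """
    data = lfp.data.copy()
    fs = lfp.fs_hz
    n = data.shape[1]
    applied: dict = {}
    for eid, segs in segments.items():
        ch = lfp.layout.channel_index(eid)
        for (t0, t1) in segs:
            if t1 <= t0:
                raise ParameterError(f"empty or reversed segment ({t0}, {t1})")
            if t1 - t0 > max_len_s:
                raise ParameterError(f"segment ({t0}, {t1}) longer than max {max_len_s}s")
            i0 = int(round(t0 * fs))
            i1 = int(round(t1 * fs))
            if i0 <= 0 or i1 >= n:
                raise ParameterError(f"segment ({t0}, {t1}) touches record boundary")
            xa, xb = data[ch, i0 - 1], data[ch, i1]
            data[ch, i0:i1] = np.interp(np.arange(i0, i1), [i0 - 1, i1], [xa, xb])
            applied.setdefault(int(eid), []).append([float(t0), float(t1)])
    prov = dict(lfp.provenance)
    merged = dict(prov.get("interpolated_segments", {}))
    for k, v in applied.items():
        merged[k] = merged.get(k, []) + v
    prov["interpolated_segments"] = merged
    return LfpRecording(data=data, fs_hz=lfp.fs_hz, layout=lfp.layout, epochs=list(lfp.epochs),
                        slice_id=lfp.slice_id, ground_truth=lfp.ground_truth, provenance=prov)
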