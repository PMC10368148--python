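"""Synthetic multielectrode-array recordings with known ground truth.

Generates 60-channel grid recordings in which each region (CA1 / CA3) is
driven by a latent narrowband Gaussian source.  Channel signals mix the
within-region source, the other region's source, and independent white
noise, so peak frequency, onset kinetics, and pairwise coherence are all
controllable and analytically predictable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

REGIONS = ("CA1", "CA3")

#: default epoch labels, in temporal order
EPOCH_VEHICLE = "vehicle"
EPOCH_DRUG = "kainate"
EPOCH_ANTAGONIST = "bicuculline"

_LAYOUT_COLUMNS = ["electrode_id", "row", "col", "x_um", "y_um", "region", "is_reference"]


@dataclass(frozen=True)
class Epoch:
    """Half-open [t_start_s, t_end_s) interval with a condition label."""

    label: str
    t_start_s: float
    t_end_s: float

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass
class ArrayLayout:
    """Electrode grid: ids, positions, region labels, and the reference flag.

    ``table`` columns: electrode_id, row, col, x_um, y_um, region
    ("CA1" / "CA3" / "none"), is_reference (bool).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _LAYOUT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"layout table missing columns: {missing}")
        if self.table["electrode_id"].duplicated().any():
            raise ConfigurationError("duplicate electrode ids in layout")
        n_ref = int(self.table["is_reference"].sum())
        if n_ref != 1:
            raise ConfigurationError(f"layout must have exactly 1 reference electrode, got {n_ref}")
        bad = set(self.table["region"]) - {"CA1", "CA3", "none"}
        if bad:
            raise ConfigurationError(f"unknown region labels: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_electrodes(self) -> int:
        return len(self.table)

    @property
    def recording_ids(self) -> np.ndarray:
        """Electrode ids excluding the reference."""
        return self.table.loc[~self.table["is_reference"], "electrode_id"].to_numpy()

    def region_ids(self, region: str) -> np.ndarray:
        """Non-reference electrode ids with the given region label."""
        m = (self.table["region"] == region) & ~self.table["is_reference"]
        return self.table.loc[m, "electrode_id"].to_numpy()

    def region_of(self, electrode_id: int) -> str:
        row = self.table.loc[self.table["electrode_id"] == electrode_id]
        if row.empty:
            raise KeyError(f"electrode {electrode_id} not in layout")
        return str(row["region"].iloc[0])

    def channel_index(self, electrode_id: int) -> int:
        """Row index of the electrode in the data matrix."""
        idx = np.flatnonzero(self.table["electrode_id"].to_numpy() == electrode_id)
        if idx.size == 0:
            raise KeyError(f"electrode {electrode_id} not in layout")
        return int(idx[0])

    def position(self, electrode_id: int) -> tuple[float, float]:
        r = self.table.loc[self.table["electrode_id"] == electrode_id].iloc[0]
        return float(r["x_um"]), float(r["y_um"])


def make_layout(rows: int = 6, cols: int = 10, pitch_um: float = 100.0,
                region_split: int = 5, reference_id: int = 0) -> ArrayLayout:
    """Build a rows x cols grid layout with a column-wise CA3 | CA1 split.

    Columns left of ``region_split`` are labeled CA3, the rest CA1.  The
    electrode ``reference_id`` is flagged as the reference, labeled "none",
    and excluded from all analyses.
    """
    if rows * cols != 60:
        raise ConfigurationError(f"grid must have 60 electrodes, got {rows}x{cols}={rows * cols}")
    recs = []
    eid = 0
    for r in range(rows):
        for c in range(cols):
            region = "CA3" if c < region_split else "CA1"
            is_ref = eid == reference_id
            recs.append(
                dict(electrode_id=eid, row=r, col=c, x_um=c * pitch_um, y_um=r * pitch_um,
                     region="none" if is_ref else region, is_reference=is_ref)
            )
            eid += 1
    return ArrayLayout(pd.DataFrame.from_records(recs))


@dataclass(frozen=True)
class OscSpec:
    """Latent oscillatory source of one region.

    ``shape`` selects the source power spectrum: "gaussian" gives a
    Gaussian bump centered at ``peak_hz`` whose full width at half maximum
    is ``bandwidth_hz`` (tunable Q factor); "flat" gives a brick-wall band
    [peak - bw/2, peak + bw/2] with constant density, which makes in-band
    coherence analytically flat.
    """

    peak_hz: float = 30.0
    bandwidth_hz: float = 10.0
    amplitude_uv: float = 20.0
    shape: str = "gaussian"


def _as_region_map(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {r: float(value[r]) for r in REGIONS if r in value}
    return {r: float(value) for r in REGIONS}


@dataclass
class SimConfig:
    """All knobs of the simulator; fully determines a recording given a seed."""

    seed: int = 0
    fs_hz: float = 20000.0
    duration_vehicle_s: float = 120.0
    duration_drug_s: float = 600.0
    duration_antagonist_s: float = 120.0
    osc: dict = field(default_factory=lambda: {
        "CA1": OscSpec(peak_hz=30.0, bandwidth_hz=10.0, amplitude_uv=20.0),
        "CA3": OscSpec(peak_hz=21.0, bandwidth_hz=10.0, amplitude_uv=25.0),
    })
    onset_a_per_min: float = 0.8    # sigmoid slope of the power envelope
    onset_b_min: float = 5.0        # sigmoid midpoint, minutes from drug onset
    w_within: object = 0.8          # scalar or {region: weight}
    w_between: object = 0.3
    noise_sd_uv: float = 5.0
    antagonist_tau_s: float = 20.0  # e-folding time of power suppression

    def __post_init__(self) -> None:
        self.osc = {r: (s if isinstance(s, OscSpec) else OscSpec(**s)) for r, s in self.osc.items()}

    @property
    def w_within_map(self) -> dict[str, float]:
        return _as_region_map(self.w_within, "w_within")

    @property
    def w_between_map(self) -> dict[str, float]:
        return _as_region_map(self.w_between, "w_between")

    def validate(self) -> None:
        for d in (self.duration_vehicle_s, self.duration_drug_s, self.duration_antagonist_s):
            if d <= 0:
                raise ConfigurationError("epoch durations must be positive")
        if self.fs_hz <= 0:
            raise ConfigurationError("fs_hz must be positive")
        for m in (self.w_within_map, self.w_between_map):
            for r, w in m.items():
                if not 0.0 <= w <= 1.0:
                    raise ConfigurationError(f"mixing weight for {r} out of [0,1]: {w}")
        for r, spec in self.osc.items():
            if not 0.0 < spec.peak_hz < self.fs_hz / 2:
                raise ConfigurationError(f"{r} peak_hz {spec.peak_hz} outside (0, Nyquist)")
            if spec.bandwidth_hz <= 0:
                raise ConfigurationError(f"{r} bandwidth_hz must be positive")
            if spec.shape not in ("gaussian", "flat"):
                raise ConfigurationError(f"unknown source shape {spec.shape!r}")
        if self.antagonist_tau_s <= 0:
            raise ConfigurationError("antagonist_tau_s must be positive")
        if self.onset_a_per_min <= 0:
            raise ConfigurationError("onset_a_per_min must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["osc"] = {r: dataclasses.asdict(s) for r, s in self.osc.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "osc" in d:
            d["osc"] = {r: OscSpec(**s) if not isinstance(s, OscSpec) else s
                        for r, s in d["osc"].items()}
        return cls(**d)


@dataclass
class Recording:
    """Multichannel voltage matrix plus layout, epochs, and provenance."""

    data: np.ndarray          # (n_channels, n_samples) float32, microvolts
    fs_hz: float
    layout: ArrayLayout
    epochs: list[Epoch]
    slice_id: str = "slice0"
    ground_truth: SimConfig | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.layout.n_electrodes:
            raise ConfigurationError(
                f"data has {self.data.shape[0]} channels but layout has "
                f"{self.layout.n_electrodes} electrodes")
        prev_end = -np.inf
        for ep in self.epochs:
            if ep.t_start_s < prev_end:
                raise ConfigurationError("epochs overlap or are unordered")
            prev_end = ep.t_end_s

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def epoch(self, label: str) -> Epoch:
        for ep in self.epochs:
            if ep.label == label:
                return ep
        raise KeyError(f"no epoch labeled {label!r}")

    def segment(self, t0_s: float, t1_s: float) -> np.ndarray:
        """Data view for the half-open time window [t0_s, t1_s)."""
        i0 = max(0, int(round(t0_s * self.fs_hz)))
        i1 = min(self.n_samples, int(round(t1_s * self.fs_hz)))
        return self.data[:, i0:i1]

    def channel(self, electrode_id: int) -> np.ndarray:
        return self.data[self.layout.channel_index(electrode_id)]


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, spec: OscSpec) -> np.ndarray:
    """Unit-variance Gaussian noise with the source's target power spectrum."""
    white = rng.standard_normal(n)
    spec_w = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    if spec.shape == "flat":
        lo = spec.peak_hz - spec.bandwidth_hz / 2.0
        hi = spec.peak_hz + spec.bandwidth_hz / 2.0
        h = ((f >= lo) & (f <= hi)).astype(float)
    else:
        # power FWHM = bandwidth_hz -> power sigma = bw/2.355, amplitude H = sqrt(power)
        sigma_p = spec.bandwidth_hz / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        h = np.exp(-((f - spec.peak_hz) ** 2) / (4.0 * sigma_p ** 2))
    s = np.fft.irfft(spec_w * h, n=n)
    sd = s.std()
    if sd > 0:
        s /= sd
    return s


def onset_envelope(t_min: np.ndarray, a_per_min: float, b_min: float) -> np.ndarray:
    """Sigmoid power envelope 1 / (1 + exp(-a*t + a*b)), t in minutes."""
    return 1.0 / (1.0 + np.exp(-a_per_min * t_min + a_per_min * b_min))


def simulate_recording(cfg: SimConfig, layout: ArrayLayout, slice_id: str = "slice0") -> Recording:
    """Generate a deterministic synthetic recording from ``cfg`` and ``layout``.

    The band-power envelope of the oscillatory component follows the
    configured sigmoid exactly during the drug epoch (the amplitude is
    scaled by its square root), rises from zero at drug onset, and decays
    as exp(-t/tau) in power during the antagonist epoch.  The vehicle
    epoch and the reference electrode contain white noise only.
    """
    cfg.validate()
    fs = cfg.fs_hz
    n_veh = int(round(cfg.duration_vehicle_s * fs))
    n_drug = int(round(cfg.duration_drug_s * fs))
    n_ant = int(round(cfg.duration_antagonist_s * fs))
    n = n_veh + n_drug + n_ant
    t_v, t_d, t_a = (n_veh / fs, (n_veh + n_drug) / fs, n / fs)
    epochs = [
        Epoch(EPOCH_VEHICLE, 0.0, t_v),
        Epoch(EPOCH_DRUG, t_v, t_d),
        Epoch(EPOCH_ANTAGONIST, t_d, t_a),
    ]

    # power-domain envelope over the full record
    t_drug_min = np.arange(n_drug) / fs / 60.0
    sig = onset_envelope(t_drug_min, cfg.onset_a_per_min, cfg.onset_b_min)
    t_ant = np.arange(n_ant) / fs
    tail = (sig[-1] if n_drug else 1.0) * np.exp(-t_ant / cfg.antagonist_tau_s)
    power_env = np.concatenate([np.zeros(n_veh), sig, tail])
    amp_env = np.sqrt(power_env)

    rng = np.random.default_rng(cfg.seed)
    regions_present = [r for r in REGIONS if r in cfg.osc]
    sources = {}
    for r in regions_present:  # fixed order for determinism
        s = _shaped_noise(rng, n, fs, cfg.osc[r])
        sources[r] = (s * amp_env * cfg.osc[r].amplitude_uv).astype(np.float64)

    w_in, w_bt = cfg.w_within_map, cfg.w_between_map
    data = np.empty((layout.n_electrodes, n), dtype=np.float32)
    tbl = layout.table
    for i in range(layout.n_electrodes):
        x = rng.standard_normal(n) * cfg.noise_sd_uv
        region = tbl["region"].iloc[i]
        if not tbl["is_reference"].iloc[i] and region in sources:
            x = x + w_in.get(region, 0.0) * sources[region]
            other = "CA3" if region == "CA1" else "CA1"
            if other in sources:
                x = x + w_bt.get(region, 0.0) * sources[other]
        data[i] = x
    return Recording(data=data, fs_hz=fs, layout=layout, epochs=epochs,
                     slice_id=slice_id, ground_truth=cfg)


# ---------------------------------------------------------------------------
# analytic ground-truth helpers (oracles for downstream modules)

def noise_density_uv2_per_hz(cfg: SimConfig) -> float:
    """One-sided spectral density of the additive white channel noise."""
    return cfg.noise_sd_uv ** 2 / (cfg.fs_hz / 2.0)


def source_density(spec: OscSpec, f: np.ndarray) -> np.ndarray:
    """One-sided power density of the unit-variance latent source at ``f`` (Hz)."""
    f = np.asarray(f, float)
    if spec.shape == "flat":
        lo = spec.peak_hz - spec.bandwidth_hz / 2.0
        hi = spec.peak_hz + spec.bandwidth_hz / 2.0
        return np.where((f >= lo) & (f <= hi), 1.0 / spec.bandwidth_hz, 0.0)
    sigma_p = spec.bandwidth_hz / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-((f - spec.peak_hz) ** 2) / (2.0 * sigma_p ** 2)) \
        / (sigma_p * np.sqrt(2.0 * np.pi))


def source_band_fraction(spec: OscSpec, f_lo: float, f_hi: float) -> float:
    """Fraction of the latent source's variance inside [f_lo, f_hi]."""
    if spec.shape == "flat":
        lo = spec.peak_hz - spec.bandwidth_hz / 2.0
        hi = spec.peak_hz + spec.bandwidth_hz / 2.0
        return max(0.0, (min(hi, f_hi) - max(lo, f_lo))) / spec.bandwidth_hz
    from scipy.stats import norm
    sigma_p = spec.bandwidth_hz / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return float(norm.cdf(f_hi, spec.peak_hz, sigma_p) - norm.cdf(f_lo, spec.peak_hz, sigma_p))


def expected_band_powers(cfg: SimConfig, region: str, f_lo: float = 25.0,
                         f_hi: float = 59.0) -> tuple[float, float]:
    """(oscillatory, noise) in-band power of a channel in ``region`` at full drive."""
    other = "CA3" if region == "CA1" else "CA1"
    w_in = cfg.w_within_map.get(region, 0.0)
    w_bt = cfg.w_between_map.get(region, 0.0)
    p_osc = (w_in * cfg.osc[region].amplitude_uv) ** 2 * \
        source_band_fraction(cfg.osc[region], f_lo, f_hi)
    if other in cfg.osc:
        p_osc += (w_bt * cfg.osc[other].amplitude_uv) ** 2 * \
            source_band_fraction(cfg.osc[other], f_lo, f_hi)
    p_noise = noise_density_uv2_per_hz(cfg) * (f_hi - f_lo)
    return p_osc, p_noise


def expected_band_coherence_within(spec: OscSpec, w: float, noise_sd_uv: float,
                                   fs_hz: float, f_lo: float = 25.0,
                                   f_hi: float = 59.0, n_grid: int = 400) -> float:
    """Band-averaged coherence of a within-region pair (w_between = 0).

    At each frequency coherence is P_shared / (P_shared + P_noise); this
    averages the exact expression over the band, matching how
    ``band_coherence`` averages the estimate.
    """
    f = np.linspace(f_lo, f_hi, n_grid)
    s = (w * spec.amplitude_uv) ** 2 * source_density(spec, f)
    n = noise_sd_uv ** 2 / (fs_hz / 2.0)
    return float(np.mean(s / (s + n)))


def solve_within_weight(rho_target: float, spec: OscSpec, noise_sd_uv: float, fs_hz: float,
                        f_lo: float = 25.0, f_hi: float = 59.0) -> float:
    """Mixing weight giving band-averaged within-region coherence ``rho_target``.

    Bisection on :func:`expected_band_coherence_within`; raises if the
    target is unreachable with w <= 1.
    """
    if not 0.0 < rho_target < 1.0:
        raise ConfigurationError("rho_target must be in (0, 1)")
    if expected_band_coherence_within(spec, 1.0, noise_sd_uv, fs_hz, f_lo, f_hi) < rho_target:
        raise ConfigurationError(
            f"coherence {rho_target} unreachable with w<=1 for source {spec}")
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expected_band_coherence_within(spec, mid, noise_sd_uv, fs_hz, f_lo, f_hi) < rho_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def expected_within_coherence(cfg: SimConfig, region: str) -> float:
    """Predicted in-band coherence of a within-region pair at full drive.

    Valid for a flat source spectrum with ``w_between`` = 0: each channel is
    w*s + noise, so coherence at in-band frequencies is
    P_shared / (P_shared + P_noise) per unit bandwidth.
    """
    spec = cfg.osc[region]
    w = cfg.w_within_map[region]
    s_density = (w * spec.amplitude_uv) ** 2 / spec.bandwidth_hz
    return s_density / (s_density + noise_density_uv2_per_hz(cfg))


def within_weight_for_coherence(rho: float, spec: OscSpec, noise_sd_uv: float,
                                fs_hz: float) -> float:
    """Mixing weight that yields in-band within-region coherence ``rho``.

    Inverse of :func:`expected_within_coherence` for a flat source.
    """
    if not 0.0 < rho < 1.0:
        raise ConfigurationError("rho must be in (0, 1)")
    n_density = noise_sd_uv ** 2 / (fs_hz / 2.0)
    s_density = rho / (1.0 - rho) * n_density
    return float(np.sqrt(s_density * spec.bandwidth_hz) / spec.amplitude_uv)


def ground_truth_gbo90_min(cfg: SimConfig, region: str | None = None,
                           f_lo: float = 25.0, f_hi: float = 59.0) -> float:
    """Time (minutes from drug onset) at which band power reaches 90% of max.

    The simulator's oscillatory power envelope is exactly the configured
    sigmoid, so with zero baseline this is b + ln(9)/a.  When ``region`` is
    given, the in-band noise floor acts as the sigmoid's baseline d and the
    crossing solves d + c*sig(t) = 0.9*(c + d).
    """
    a, b = cfg.onset_a_per_min, cfg.onset_b_min
    if region is None:
        return b + np.log(9.0) / a
    c, d = expected_band_powers(cfg, region, f_lo, f_hi)
    thresh = 0.9 * (c + d) - d
    if thresh <= 0:
        raise ConfigurationError("90% threshold at or below the noise floor")
    return b - np.log(c / thresh - 1.0) / a


# ---------------------------------------------------------------------------
# HDF5 container

def write_recording(rec: Recording, path) -> None:
    """Write a recording to an HDF5 container (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32))
        tbl = rec.layout.table
        layout_dt = np.dtype([
            ("electrode_id", "i4"), ("row", "i4"), ("col", "i4"),
            ("x_um", "f8"), ("y_um", "f8"), ("region", "S8"), ("is_reference", "i1"),
        ])
        layout_arr = np.zeros(len(tbl), dtype=layout_dt)
        for name in ("electrode_id", "row", "col", "x_um", "y_um"):
            layout_arr[name] = tbl[name].to_numpy()
        layout_arr["region"] = [s.encode() for s in tbl["region"]]
        layout_arr["is_reference"] = tbl["is_reference"].to_numpy().astype(np.int8)
        f.create_dataset("layout", data=layout_arr)
        epoch_dt = np.dtype([("label", "S32"), ("t_start_s", "f8"), ("t_end_s", "f8")])
        ep_arr = np.array([(e.label.encode(), e.t_start_s, e.t_end_s) for e in rec.epochs],
                          dtype=epoch_dt)
        f.create_dataset("epochs", data=ep_arr)
        f.attrs["fs_hz"] = rec.fs_hz
        f.attrs["slice_id"] = rec.slice_id
        if rec.ground_truth is not None:
            f.attrs["ground_truth"] = json.dumps(rec.ground_truth.to_dict())
        prov = getattr(rec, "provenance", None)
        if prov is not None:
            f.attrs["provenance"] = json.dumps(prov)


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    with h5py.File(path, "r") as f:
        for key in ("data", "layout", "epochs"):
            if key not in f:
                raise FormatError(f"container missing /{key}")
        if "fs_hz" not in f.attrs:
            raise FormatError("container missing fs_hz attribute")
        data = f["data"][...]
        la = f["layout"][...]
        table = pd.DataFrame({
            "electrode_id": la["electrode_id"].astype(int),
            "row": la["row"].astype(int),
            "col": la["col"].astype(int),
            "x_um": la["x_um"],
            "y_um": la["y_um"],
            "region": [b.decode() for b in la["region"]],
            "is_reference": la["is_reference"].astype(bool),
        })
        eps = [Epoch(b["label"].decode(), float(b["t_start_s"]), float(b["t_end_s"]))
               for b in f["epochs"][...]]
        gt = None
        if "ground_truth" in f.attrs:
            gt = SimConfig.from_dict(json.loads(f.attrs["ground_truth"]))
        rec = Recording(data=data, fs_hz=float(f.attrs["fs_hz"]), layout=ArrayLayout(table),
                        epochs=eps, slice_id=str(f.attrs.get("slice_id", "slice0")),
                        ground_truth=gt)
        if "provenance" in f.attrs:
            rec.provenance = json.loads(f.attrs["provenance"])
        return rec
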