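"""Smart-bed multirate signal simulation and preprocessing.

A night of bed data consists of four streams on a shared clock: a pressure
grid at 10 Hz, frame load cells at 50 Hz, a frame IMU at 25 Hz and bedside
environment sensors at 1 Hz.  Preprocessing mirrors what a ballistocardio-
graphy-style pipeline does: Hampel filtering for spike artifacts, zero-phase
Butterworth band-pass filtering (0.1-0.5 Hz respiration band, 0.8-2.5 Hz
cardiac band), resampling of every stream to a synchronized 1 Hz frame, and
hidden-Markov smoothing of the observed posture sequence.  From the aligned
frame four nightly features are extracted: respiratory rate, posture
transition count, a micro-movement index and the spatial pressure entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import CategoricalHMM
from scipy import signal as sps

__all__ = [
    "MultirateNight",
    "BedFeatures",
    "RATES",
    "POSTURES",
    "simulate_night",
    "hampel",
    "bandpass",
    "resample_1hz",
    "smooth_posture",
    "extract_bed_features",
    "preprocess_night",
]

RATES = {"pressure": 10, "load": 50, "imu": 25, "env": 1}
POSTURES = ("supine", "prone", "left", "right")
RESP_BAND = (0.1, 0.5)
CARDIAC_BAND = (0.8, 2.5)


@dataclass
class MultirateNight:
    """Raw streams of one night; each stream is (n_samples, n_channels)."""

    duration_s: int
    pressure: np.ndarray  # 10 Hz, one column per grid cell
    load: np.ndarray      # 50 Hz, single channel
    imu: np.ndarray       # 25 Hz, 3 axes
    env: np.ndarray       # 1 Hz, temperature/light/noise
    posture_obs: np.ndarray  # 1 Hz observed posture state indices
    artifact_positions: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def validate(self) -> None:
        for name, rate in RATES.items():
            arr = getattr(self, name)
            if arr.shape[0] != self.duration_s * rate:
                raise ValueError(
                    f"stream '{name}' has {arr.shape[0]} samples, expected "
                    f"{self.duration_s * rate} at {rate} Hz for {self.duration_s} s"
                )


@dataclass(frozen=True)
class BedFeatures:
    respiratory_rate: float      # breaths / min
    posture_transitions: int     # state changes / night
    micro_movement_index: float  # mean |diff| of total grid pressure, >= 0
    pressure_entropy: float      # Shannon entropy (bits) of spatial distribution


def simulate_night(
    resp_hz: float,
    duration_s: int = 600,
    posture_schedule: list[tuple[int, int]] | None = None,
    cardiac_hz: float = 1.2,
    noise_sd: float = 0.3,
    n_artifacts: int = 5,
    posture_flip_prob: float = 0.05,
    n_cells: int = 16,
    seed: int = 0,
) -> MultirateNight:
    """Synthesize one night of raw bed streams around planted truth.

    The load channel carries respiration and cardiac sinusoids plus white
    noise and ``n_artifacts`` large spikes at seeded positions (recorded in
    ``artifact_positions``).  The pressure grid concentrates weight on cells
    determined by the scheduled posture; the observed posture sequence is
    the schedule corrupted by symmetric flips at ``posture_flip_prob``.

    ``resp_hz`` must lie inside the respiration band [0.1, 0.5] Hz — a
    planted rate outside the band cannot be recovered and is rejected.
    """
    if not RESP_BAND[0] <= resp_hz <= RESP_BAND[1]:
        raise ValueError(f"planted respiration {resp_hz} Hz outside band {RESP_BAND}")
    rng = np.random.default_rng(seed)
    if posture_schedule is None:
        posture_schedule = [(0, 0), (duration_s // 2, 2)]

    t50 = np.arange(duration_s * RATES["load"]) / RATES["load"]
    load = (
        1.0 * np.sin(2 * np.pi * resp_hz * t50)
        + 0.25 * np.sin(2 * np.pi * cardiac_hz * t50)
        + rng.normal(0.0, noise_sd, size=t50.size)
    )
    artifacts = np.sort(rng.choice(t50.size, size=n_artifacts, replace=False))
    load[artifacts] += 40.0 * rng.choice([-1.0, 1.0], size=n_artifacts)

    # Posture truth at 1 Hz from the schedule of (start_second, state) pairs.
    posture_true = np.zeros(duration_s, dtype=int)
    for start, state in sorted(posture_schedule):
        posture_true[start:] = state
    flips = rng.random(duration_s) < posture_flip_prob
    posture_obs = posture_true.copy()
    other = rng.integers(1, len(POSTURES), size=duration_s)
    posture_obs[flips] = (posture_obs[flips] + other[flips]) % len(POSTURES)

    # Pressure grid: weight concentrated on posture-dependent cells.
    n10 = duration_s * RATES["pressure"]
    pressure = np.abs(rng.normal(0.05, 0.02, size=(n10, n_cells)))
    sec_idx = np.repeat(np.arange(duration_s), RATES["pressure"])
    centers = (posture_true[sec_idx] * (n_cells // len(POSTURES))) % n_cells
    for off, w in ((0, 1.0), (1, 0.6), (2, 0.3)):
        pressure[np.arange(n10), (centers + off) % n_cells] += w

    imu = rng.normal(0.0, 0.05, size=(duration_s * RATES["imu"], 3))
    env = np.column_stack([
        rng.normal(21.0, 0.1, size=duration_s),
        np.abs(rng.normal(5.0, 1.0, size=duration_s)),
        np.abs(rng.normal(30.0, 2.0, size=duration_s)),
    ])
    night = MultirateNight(
        duration_s=duration_s, pressure=pressure, load=load, imu=imu,
        env=env, posture_obs=posture_obs, artifact_positions=artifacts,
    )
    night.validate()
    return night


def hampel(series: np.ndarray, window_half_width: int = 5, n_mad: float = 3.0) -> np.ndarray:
    """Sliding-window median/MAD outlier replacement.

    For each sample the window is ``series[max(0, i-k) : i+k+1]`` (truncated
    at the edges).  Samples deviating from the window median by more than
    ``n_mad`` scaled MADs (scale factor 1.4826, the Gaussian consistency
    constant) are replaced by that median; everything else is untouched.
    """
    x = np.asarray(series, dtype=float)
    k = int(window_half_width)
    if k < 1:
        raise ValueError("window_half_width must be >= 1")
    if 2 * k + 1 > x.size:
        raise ValueError(f"window {2 * k + 1} longer than series of length {x.size}")

    med = np.empty_like(x)
    mad = np.empty_like(x)
    n = x.size
    # Interior: vectorized over full windows.
    if n >= 2 * k + 1:
        win = np.lib.stride_tricks.sliding_window_view(x, 2 * k + 1)
        med[k:n - k] = np.median(win, axis=1)
        mad[k:n - k] = np.median(np.abs(win - med[k:n - k, None]), axis=1)
    for i in list(range(k)) + list(range(n - k, n)):
        w = x[max(0, i - k): i + k + 1]
        med[i] = np.median(w)
        mad[i] = np.median(np.abs(w - med[i]))
    out = x.copy()
    thresh = n_mad * 1.4826 * mad
    outlier = np.abs(x - med) > thresh
    out[outlier] = med[outlier]
    return out


def bandpass(series: np.ndarray, fs: float, f_low: float, f_high: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    if not 0 < f_low < f_high < fs / 2:
        raise ValueError(
            f"band ({f_low}, {f_high}) must satisfy 0 < low < high < Nyquist {fs / 2}"
        )
    sos = sps.butter(order, [f_low, f_high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(series, dtype=float))


def _bin_1hz(arr: np.ndarray, rate: int) -> np.ndarray:
    """Mean within each 1 s bin; arr is (seconds*rate, channels) or 1-d."""
    a = np.asarray(arr, dtype=float)
    if a.shape[0] % rate:
        raise ValueError("stream length not a whole number of seconds")
    if a.ndim == 1:
        return a.reshape(-1, rate).mean(axis=1)
    return a.reshape(-1, rate, a.shape[1]).mean(axis=1)


def resample_1hz(night: MultirateNight, clean_load: bool = True) -> pd.DataFrame:
    """Synchronized 1 Hz frame of cleaned channels plus decoded posture.

    The load channel is Hampel-filtered then band-pass filtered into
    respiration and cardiac proxies *before* decimation (both bands sit
    below the 25 Hz load Nyquist but the cardiac band would fold at 1 Hz),
    and each stream is averaged within 1 s bins.  Because the respiration
    band lies under 0.5 Hz, bin-averaging the band-limited signal does not
    alias it.  Posture comes from HMM smoothing of the observed sequence.
    """
    night.validate()
    dur = night.duration_s

    load = night.load
    if clean_load:
        load = hampel(load, window_half_width=5, n_mad=3.0)
    resp = bandpass(load, RATES["load"], *RESP_BAND)
    cardiac = bandpass(load, RATES["load"], *CARDIAC_BAND)

    frame = pd.DataFrame({
        "second": np.arange(dur),
        "load_mean": _bin_1hz(load, RATES["load"]),
        "load_resp": _bin_1hz(resp, RATES["load"]),
        "cardiac_power": _bin_1hz(cardiac ** 2, RATES["load"]),
        "imu_mag": _bin_1hz(np.linalg.norm(night.imu, axis=1), RATES["imu"]),
        "temperature": night.env[:, 0],
        "light": night.env[:, 1],
        "noise": night.env[:, 2],
    })
    p1 = _bin_1hz(night.pressure, RATES["pressure"])
    for c in range(p1.shape[1]):
        frame[f"pressure_{c}"] = p1[:, c]
    frame["pressure_total"] = p1.sum(axis=1)
    frame["posture"] = smooth_posture(night.posture_obs)
    if frame.isna().any().any():
        raise ValueError("aligned frame contains missing cells")
    return frame


def smooth_posture(
    observed_states: np.ndarray,
    transition_stickiness: float = 0.95,
    emission_error: float = 0.1,
    n_states: int = len(POSTURES),
) -> np.ndarray:
    """Viterbi-decode the posture sequence under a sticky HMM.

    Transition matrix has ``transition_stickiness`` on the diagonal with the
    remainder spread evenly; emissions are the observed state with symmetric
    confusion ``emission_error``.  With high stickiness, isolated one-sample
    glitches inside long blocks are removed, so the decoded sequence never
    has more flips than the observation for stickiness above ~0.9.
    """
    obs = np.asarray(observed_states)
    if obs.dtype.kind in "US":
        lut = {s: i for i, s in enumerate(POSTURES)}
        try:
            obs = np.array([lut[s] for s in obs])
        except KeyError as e:
            raise ValueError(f"unknown posture symbol {e.args[0]!r}") from None
    obs = obs.astype(int)
    if obs.size == 0:
        return obs
    if obs.min() < 0 or obs.max() >= n_states:
        raise ValueError(f"state index outside alphabet of size {n_states}")

    s = float(transition_stickiness)
    eps = float(emission_error)
    model = CategoricalHMM(n_components=n_states, init_params="")
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    model.transmat_ = np.full((n_states, n_states), (1 - s) / (n_states - 1))
    np.fill_diagonal(model.transmat_, s)
    emission = np.full((n_states, n_states), eps / (n_states - 1))
    np.fill_diagonal(emission, 1 - eps)
    model.emissionprob_ = emission
    _, decoded = model.decode(obs.reshape(-1, 1), algorithm="viterbi")
    return decoded


def dominant_frequency(x: np.ndarray, fs: float, band: tuple[float, float],
                       nperseg: int = 60) -> float:
    """Peak frequency of the Welch periodogram restricted to ``band``."""
    x = np.asarray(x, dtype=float)
    nperseg = min(nperseg * int(round(fs)), x.size)
    freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError("no spectral support inside band")
    return float(freqs[in_band][np.argmax(psd[in_band])])


def extract_bed_features(frame: pd.DataFrame) -> BedFeatures:
    """Nightly bed features from a 1 Hz aligned frame.

    respiratory_rate: 60 x dominant Welch frequency (60 s segments, 50%
    overlap) of the respiration-band load channel.  posture_transitions:
    state changes in the smoothed sequence.  micro_movement_index: mean
    absolute first difference of total grid pressure (cohort z-scaling, when
    wanted, is a profiling-stage concern).  pressure_entropy: Shannon
    entropy in bits of the night-averaged normalized spatial distribution.
    """
    if len(frame) < 60:
        raise ValueError("frame shorter than 60 s: spectral estimate undefined")
    resp_hz = dominant_frequency(frame["load_resp"].to_numpy(), fs=1.0, band=RESP_BAND)

    posture = frame["posture"].to_numpy()
    transitions = int(np.count_nonzero(np.diff(posture)))

    total = frame["pressure_total"].to_numpy()
    micro = float(np.mean(np.abs(np.diff(total))))

    cell_cols = [c for c in frame.columns if c.startswith("pressure_") and c != "pressure_total"]
    mean_cells = frame[cell_cols].to_numpy().mean(axis=0)
    p = mean_cells / mean_cells.sum() if mean_cells.sum() > 0 else np.full(len(cell_cols), 1 / len(cell_cols))
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())

    return BedFeatures(
        respiratory_rate=60.0 * resp_hz,
        posture_transitions=transitions,
        micro_movement_index=micro,
        pressure_entropy=entropy,
    )


def preprocess_night(night: MultirateNight) -> tuple[pd.DataFrame, BedFeatures]:
    """Full per-night pipeline: clean, align to 1 Hz, extract features."""
    frame = resample_1hz(night)
    return frame, extract_bed_features(frame)
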