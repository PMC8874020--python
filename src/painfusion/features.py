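"""Per-modality signal preprocessing and 20-s window feature reduction.

Each recorded 20-s window (one relaxed baseline, then one per cold-water
immersion session) is reduced to a labeled feature vector:

* FE  — mean probability of each of the 17 action units;
* EEG — log band power per channel and band (delta..gamma) after a 1-50 Hz
  zero-phase band-pass;
* EM  — pupil diameter mean and SD (mm) after velocity-based artifact
  interpolation;
* SC  — mean (uS) and least-squares slope (uS/s);
* BVP — heart rate (bpm) from peak detection;
* EMG — RMS amplitude (uV) of the mean-removed window;
* RR  — respiration rate (breaths/min) from peak detection;
* ST  — mean (degC) and slope (degC/s);
* BP  — post minus pre cuff deltas (mmHg), broadcast to every window of
  the day (only two cuff readings exist per day).

Windows are labeled B (baseline), LP (VRS 1-5) or HP (VRS 6-10); a session
rating of 0 — "no pain" on the verbal rating scale — is labeled B.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .modalities import (
    AU_NAMES,
    BANDS,
    BAND_NAMES,
    DEFAULT_EEG_CHANNELS,
    MODALITY_ORDER,
    SAMPLING_RATES,
    WINDOW_SECONDS,
)


class DataQualityError(ValueError):
    """Raised when a window is too corrupted to yield a feature."""


class SchemaError(ValueError):
    """Raised when on-disk data does not match the expected layout."""


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")


#: Canonical EEG bands as :class:`BandDefinition` objects.
BAND_DEFINITIONS: dict[str, BandDefinition] = {
    name: BandDefinition(name, lo, hi) for name, (lo, hi) in BANDS.items()
}


# ---------------------------------------------------------------------------
# EEG spectral operations
# ---------------------------------------------------------------------------

def bandpass_eeg(
    series: np.ndarray,
    fs: float,
    lo: float = 1.0,
    hi: float = 50.0,
    order: int = 6,
) -> np.ndarray:
    """Zero-phase band-pass filter for raw EEG.

    A Butterworth filter of the given order is applied forward and backward
    (``sosfiltfilt``), doubling the effective roll-off and cancelling phase
    distortion.  With the default order the attenuation one octave beyond
    either edge exceeds 20 dB.

    Parameters
    ----------
    series : 1-D array of samples.
    fs : sampling rate in Hz; must exceed 100 Hz (scalp EEG rates).
    lo, hi : pass-band edges in Hz.

    Raises
    ------
    ValueError
        If the series is shorter than the filter warm-up (~1 s).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if fs <= 100:
        raise ValueError("bandpass_eeg expects fs > 100 Hz")
    if x.size < fs:
        raise ValueError("series shorter than filter warm-up (need >= 1 s)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def band_power(series: np.ndarray, fs: float, band: BandDefinition) -> float:
    """Integrated spectral power of ``series`` over ``[band.lo, band.hi)``.

    Uses an averaged modified periodogram (Welch: 2-s Hann segments, 50 %
    overlap), which stabilizes the estimate on 20-s windows.  The result is
    in signal-variance units, so the power of a unit-amplitude sinusoid
    inside the band is 0.5.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("band_power needs at least 2 s of samples")
    if not (0 <= band.lo < band.hi <= fs / 2):
        raise ValueError(f"band {band.name} outside [0, fs/2)")
    nperseg = int(2 * fs)
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant", scaling="density",
    )
    df = freqs[1] - freqs[0]
    mask = (freqs >= band.lo) & (freqs < band.hi)
    return float(np.sum(psd[mask]) * df)


def eeg_session_powers(
    window: np.ndarray | pd.DataFrame,
    fs: float = SAMPLING_RATES["eeg"],
    channels: Sequence[str] | None = None,
    bands: Mapping[str, BandDefinition] = BAND_DEFINITIONS,
) -> pd.DataFrame:
    """Channel x band power matrix for one 20-s EEG window.

    Applies :func:`bandpass_eeg` per channel, then :func:`band_power` per
    band.  Returns a DataFrame indexed by channel with one column per band
    (power in variance units, not log).
    """
    if isinstance(window, pd.DataFrame):
        if channels is None:
            channels = list(window.columns)
        missing = [c for c in channels if c not in window.columns]
        if missing:
            raise ValueError(f"missing EEG channels: {missing}")
        data = window[list(channels)].to_numpy(dtype=float)
    else:
        data = np.asarray(window, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
        if channels is None:
            channels = list(DEFAULT_EEG_CHANNELS[: data.shape[1]])
        if len(channels) != data.shape[1]:
            raise ValueError("channel names do not match column count")
    out = np.empty((len(channels), len(bands)))
    for j in range(data.shape[1]):
        filtered = bandpass_eeg(data[:, j], fs)
        for k, bdef in enumerate(bands.values()):
            out[j, k] = band_power(filtered, fs, bdef)
    return pd.DataFrame(out, index=list(channels), columns=list(bands))


# ---------------------------------------------------------------------------
# Pupil, cardio-respiratory and scalar summaries
# ---------------------------------------------------------------------------

def pupil_velocity_filter(
    series: np.ndarray, fs: float, vmax: float = 10.0
) -> np.ndarray:
    """Velocity-based artifact rejection for pupil diameter traces.

    Samples adjoining a first-difference velocity above ``vmax`` (mm/s) are
    flagged, together with one neighbor on each side, and replaced by
    linear interpolation from the nearest unflagged samples.  Blink
    closures produce near-instantaneous diameter collapses with velocities
    far above any physiological dilation, so they are removed while slow
    drifts pass through untouched.

    Raises
    ------
    DataQualityError
        If more than half of the samples are flagged.
    """
    x = np.asarray(series, dtype=float)
    if fs <= 0 or vmax <= 0:
        raise ValueError("fs and vmax must be positive")
    if x.size < 3:
        return x.copy()
    vel = np.abs(np.diff(x)) * fs
    bad = np.zeros(x.size, dtype=bool)
    idx = np.nonzero(vel > vmax)[0]
    for i in idx:  # diff i connects samples i and i+1; pad one each side
        bad[max(i - 1, 0): min(i + 3, x.size)] = True
    if not bad.any():
        return x.copy()
    if bad.mean() > 0.5:
        raise DataQualityError("more than 50% of pupil samples flagged")
    good = np.nonzero(~bad)[0]
    out = x.copy()
    out[bad] = np.interp(np.nonzero(bad)[0], good, x[good])
    return out


def _peak_rate(window: np.ndarray, fs: float, min_distance_s: float) -> float:
    """Events per minute from peak detection with a refractory distance."""
    x = np.asarray(window, dtype=float)
    ptp = float(np.ptp(x))
    if ptp <= 0:
        raise DataQualityError("flat signal: no peaks")
    peaks, _ = sps.find_peaks(
        x, distance=max(int(min_distance_s * fs), 1), prominence=0.3 * ptp
    )
    if peaks.size < 2:
        raise DataQualityError("fewer than 2 peaks in window")
    span_s = (peaks[-1] - peaks[0]) / fs
    return 60.0 * (peaks.size - 1) / span_s


def heart_rate_from_bvp(window: np.ndarray, fs: float) -> float:
    """Heart rate (bpm) from a blood-volume-pulse window (>= 10 s).

    Pulse peaks are detected with a 0.33-s minimum inter-peak distance
    (refractory period; caps detectable rate at ~180 bpm).
    """
    if np.asarray(window).size < 10 * fs:
        raise ValueError("heart_rate_from_bvp needs >= 10 s of signal")
    return _peak_rate(window, fs, 0.33)


def respiration_rate(window: np.ndarray, fs: float) -> float:
    """Respiration rate (breaths/min) from a respiration belt window.

    Same peak logic as heart rate with a 1.5-s minimum distance.
    """
    if np.asarray(window).size < 20 * fs:
        raise ValueError("respiration_rate needs >= 20 s of signal")
    return _peak_rate(window, fs, 1.5)


def emg_rms(window: np.ndarray) -> float:
    """RMS amplitude (uV) of the mean-removed EMG window."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def mean_slope(window: np.ndarray, fs: float) -> tuple[float, float]:
    """Arithmetic mean and least-squares slope (units/s) of a window.

    Time origin is the window start; slope is per second.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise ValueError("mean_slope needs >= 2 samples")
    t = np.arange(x.size) / fs
    slope = float(np.polyfit(t, x, 1)[0])
    return float(x.mean()), slope


def au_session_features(fe_window: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Column-wise mean of the 17 AU probability series in one window."""
    if isinstance(fe_window, pd.DataFrame):
        data = fe_window.to_numpy(dtype=float)
    else:
        data = np.asarray(fe_window, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] != len(AU_NAMES):
        raise SchemaError(
            f"expected {len(AU_NAMES)} AU columns, got {data.shape[1]}"
        )
    return data.mean(axis=0)


def label_from_vrs(window_kind: str, rating: int | None = None) -> str:
    """Map a window to its pain class.

    Baseline windows are B.  Session windows: rating 1-5 is LP, 6-10 is
    HP, and 0 — "no pain" on the rating scale — is B.
    """
    if window_kind == "baseline":
        return "B"
    if window_kind != "session":
        raise ValueError(f"unknown window kind {window_kind!r}")
    if rating is None:
        raise ValueError("session windows require a rating")
    r = int(rating)
    if not 0 <= r <= 10:
        raise ValueError(f"rating {r} outside [0, 10]")
    if r == 0:
        return "B"
    return "LP" if r <= 5 else "HP"


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def feature_columns(
    eeg_channels: Sequence[str] = DEFAULT_EEG_CHANNELS,
    modalities: Iterable[str] = MODALITY_ORDER,
) -> list[str]:
    """Namespaced feature column names, in canonical order."""
    enabled = set(modalities)
    cols: list[str] = []
    if "fe" in enabled:
        cols += [f"fe.{au}" for au in AU_NAMES]
    if "eeg" in enabled:
        cols += [f"eeg.{ch}.{b}" for ch in eeg_channels for b in BAND_NAMES]
    if "em" in enabled:
        cols += ["em.pupil_mean", "em.pupil_sd"]
    if "sc" in enabled:
        cols += ["sc.mean", "sc.slope"]
    if "bvp" in enabled:
        cols += ["bvp.hr"]
    if "emg" in enabled:
        cols += ["emg.rms"]
    if "rr" in enabled:
        cols += ["rr.rate"]
    if "st" in enabled:
        cols += ["st.mean", "st.slope"]
    if "bp" in enabled:
        cols += ["bp.sys_delta", "bp.dia_delta"]
    return cols


def _window_slice(df: pd.DataFrame, k: int) -> pd.DataFrame:
    t0, t1 = k * WINDOW_SECONDS, (k + 1) * WINDOW_SECONDS
    return df[(df["time_s"] >= t0) & (df["time_s"] < t1)]


def _extract_window_features(
    k: int,
    eeg: pd.DataFrame | None,
    em: pd.DataFrame | None,
    fe: pd.DataFrame | None,
    physio: pd.DataFrame | None,
    eeg_channels: Sequence[str],
    enabled: set[str],
) -> dict[str, float]:
    feats: dict[str, float] = {}
    if "fe" in enabled and fe is not None:
        w = _window_slice(fe, k)
        means = au_session_features(w[list(AU_NAMES)])
        feats.update({f"fe.{au}": m for au, m in zip(AU_NAMES, means)})
    if "eeg" in enabled and eeg is not None:
        w = _window_slice(eeg, k)
        powers = eeg_session_powers(
            w[list(eeg_channels)], SAMPLING_RATES["eeg"], eeg_channels
        )
        for ch in eeg_channels:
            for b in BAND_NAMES:
                feats[f"eeg.{ch}.{b}"] = float(
                    np.log(max(powers.loc[ch, b], 1e-12))
                )
    if "em" in enabled and em is not None:
        w = _window_slice(em, k)
        pupil = pupil_velocity_filter(
            w["pupil_mm"].to_numpy(), SAMPLING_RATES["em"]
        )
        feats["em.pupil_mean"] = float(pupil.mean())
        feats["em.pupil_sd"] = float(pupil.std())
    if physio is not None:
        w = _window_slice(physio, k)
        fs = SAMPLING_RATES["sc"]
        if "sc" in enabled:
            m, s = mean_slope(w["sc"].to_numpy(), fs)
            feats["sc.mean"], feats["sc.slope"] = m, s
        if "bvp" in enabled:
            feats["bvp.hr"] = heart_rate_from_bvp(w["bvp"].to_numpy(), fs)
        if "emg" in enabled:
            feats["emg.rms"] = emg_rms(w["emg"].to_numpy())
        if "rr" in enabled:
            feats["rr.rate"] = respiration_rate(w["rr"].to_numpy(), fs)
        if "st" in enabled:
            m, s = mean_slope(w["st"].to_numpy(), fs)
            feats["st.mean"], feats["st.slope"] = m, s
    return feats


def assemble_session_features(root: str | Path) -> pd.DataFrame:
    """Reduce an on-disk dataset to one feature row per 20-s window.

    Reads the manifest and the per-subject-day CSV files written by
    :func:`painfusion.cohort.generate_dataset` and applies the full
    per-modality reduction.  BP day-level deltas are broadcast to every
    window of that day.

    Returns a DataFrame with identification columns (``subject``, ``day``,
    ``window``, ``vrs``, ``label``) followed by the namespaced feature
    columns of :func:`feature_columns`.
    """
    root = Path(root)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"no manifest.json under {root}")
    manifest = json.loads(manifest_path.read_text())
    enabled = set(manifest["config"]["modalities"])
    eeg_channels = list(manifest["config"]["eeg_channels"])

    rows: list[dict] = []
    for entry in manifest["recordings"]:
        day_dir = root / entry["path"]
        required = {
            "eeg": "eeg.csv", "em": "em.csv", "fe": "fe.csv",
            "bp": "bp.csv",
        }
        tables: dict[str, pd.DataFrame | None] = {}
        for mod, fname in required.items():
            p = day_dir / fname
            if mod in enabled:
                if not p.exists():
                    raise SchemaError(f"missing {fname} in {day_dir}")
                tables[mod] = pd.read_csv(p)
            else:
                tables[mod] = None
        physio_mods = {"sc", "bvp", "emg", "rr", "st"}
        if physio_mods & enabled:
            p = day_dir / "physio.csv"
            if not p.exists():
                raise SchemaError(f"missing physio.csv in {day_dir}")
            tables["physio"] = pd.read_csv(p)
        else:
            tables["physio"] = None
        ratings = pd.read_csv(day_dir / "ratings.csv")
        vrs = ratings["vrs"].astype(int).tolist()

        bp_sys = bp_dia = np.nan
        if "bp" in enabled:
            bp = tables["bp"]
            pre = bp[bp["phase"] == "pre"].iloc[0]
            post = bp[bp["phase"] == "post"].iloc[0]
            bp_sys = float(post["systolic"] - pre["systolic"])
            bp_dia = float(post["diastolic"] - pre["diastolic"])

        for k in range(len(vrs) + 1):  # window 0 is baseline
            if k == 0:
                label, rating = label_from_vrs("baseline"), np.nan
            else:
                rating = vrs[k - 1]
                label = label_from_vrs("session", rating)
            feats = _extract_window_features(
                k, tables["eeg"], tables["em"], tables["fe"],
                tables["physio"], eeg_channels, enabled,
            )
            if "bp" in enabled:
                feats["bp.sys_delta"] = bp_sys
                feats["bp.dia_delta"] = bp_dia
            rows.append({
                "subject": entry["subject"],
                "day": entry["day"],
                "window": k,
                "vrs": rating,
                "label": label,
                **feats,
            })
    cols = ["subject", "day", "window", "vrs", "label"] + feature_columns(
        eeg_channels, sorted(enabled)
    )
    return pd.DataFrame(rows)[cols]
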