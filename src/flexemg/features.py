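"""Windowed sEMG features (RMS, iEMG, ARV, MDF, MPF) and ratio normalization.

Signals are cut into 0.5 s windows that advance by
``window_length * (1 - overlap)`` with ``overlap = 1/8`` of the window by
default, taken from a manually chosen stable segment of the record. Each
window yields three time-domain features — root mean square, integrated EMG
(time integral of the rectified signal, mV*s) and average rectified value —
and two spectral ones, the median frequency (MDF) and mean power frequency
(MPF) of a Hann-tapered, zero-padded periodogram restricted to the 20-500 Hz
analysis band.

Because absolute sEMG amplitudes depend on effort and electrode coupling,
feature tables are expressed as **ratios**: each affected-side row is
divided by a per-channel-role summary (mean) of a reference table — the
contralateral healthy limb for patients, or the subject's own pre-injury
baseline for the evoked protocol. Ratio tables are dimensionless, which
removes the subject's overall willingness/ability to contract from the
classifier input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import SignalRecord

__all__ = [
    "WindowingConfig",
    "SilentWindowError",
    "window_starts",
    "segment_windows",
    "time_domain_features",
    "spectral_features",
    "feature_vector",
    "build_feature_table",
    "ratio_normalize",
    "FEATURE_COLUMNS",
    "DEFAULT_CLASSIFIER_FEATURES",
    "PATIENT_PAIRING",
]

FEATURE_COLUMNS = ("rms", "iemg", "arv", "mdf", "mpf")

#: Features consumed by the classifiers by default. ARV is computed and
#: stored but excluded from the default model.
DEFAULT_CLASSIFIER_FEATURES = ("rms", "iemg", "mdf", "mpf")

#: Affected-channel role -> contralateral reference role (same muscle).
PATIENT_PAIRING = {
    "tibialis_affected": "tibialis_unaffected",
    "gastrocnemius_affected": "gastrocnemius_unaffected",
}


class SilentWindowError(ValueError):
    """A window carries no in-band spectral power."""


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window segmentation parameters.

    ``overlap`` is the overlapping *fraction of the window* (default 1/8,
    step 0.4375 s for a 0.5 s window). Set ``step_is_overlap=True`` for the
    alternative reading in which the step itself is ``overlap * window``.
    ``stable_segment`` selects the analysed (start, end) seconds of the
    record; ``None`` uses the whole record.
    """

    window_length: float = 0.5
    overlap: float = 1.0 / 8.0
    stable_segment: tuple[float, float] | None = None
    step_is_overlap: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap fraction must be in [0, 1)")
        if self.window_length <= 0:
            raise ValueError("window length must be positive")
        if self.step <= 0:
            raise ValueError("window step must be positive")

    @property
    def step(self) -> float:
        if self.step_is_overlap:
            return self.window_length * self.overlap
        return self.window_length * (1.0 - self.overlap)


def window_starts(segment_length: float, cfg: WindowingConfig) -> np.ndarray:
    """Start offsets (s) of all complete windows inside a segment.

    Starts are ``k * step`` for ``k = 0 .. floor((L - w) / step)``; the final
    partial window is dropped. A segment shorter than one window raises.
    """
    if segment_length + 1e-9 < cfg.window_length:
        raise ValueError(
            f"segment of {segment_length} s is shorter than one "
            f"{cfg.window_length} s window"
        )
    count = int(np.floor((segment_length - cfg.window_length) / cfg.step + 1e-9)) + 1
    return np.arange(count) * cfg.step


def segment_windows(
    x: np.ndarray, fs: float, cfg: WindowingConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a channel into overlapping windows.

    Returns ``(windows, starts_s)`` where ``windows`` has shape
    ``(n_windows, window_samples)`` and ``starts_s`` gives each window's
    absolute start time within the record.
    """
    cfg = cfg or WindowingConfig()
    x = np.asarray(x, dtype=float)
    if cfg.stable_segment is None:
        seg_start, seg_end = 0.0, len(x) / fs
    else:
        seg_start, seg_end = cfg.stable_segment
        if seg_start < 0 or seg_end * fs > len(x) + 0.5:
            raise ValueError("stable segment lies outside the record")
    starts = window_starts(seg_end - seg_start, cfg) + seg_start
    win_n = int(round(cfg.window_length * fs))
    idx = np.round(starts * fs).astype(int)
    windows = np.stack([x[i : i + win_n] for i in idx])
    return windows, starts


def time_domain_features(window: np.ndarray, fs: float) -> tuple[float, float, float]:
    """(RMS, iEMG, ARV) of one window.

    RMS = sqrt(mean(x^2)); ARV = mean(|x|); iEMG = sum(|x|)/fs (time-integral
    convention, mV*s). RMS >= ARV always (Cauchy-Schwarz).
    """
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    rms = float(np.sqrt(np.mean(w**2)))
    arv = float(np.mean(np.abs(w)))
    iemg = float(np.sum(np.abs(w)) / fs)
    return rms, iemg, arv


def spectral_features(
    window: np.ndarray,
    fs: float,
    *,
    band: tuple[float, float] = (20.0, 500.0),
    nfft: int | None = None,
) -> tuple[float, float]:
    """(MDF, MPF) of one window, restricted to the analysis band.

    The PSD is a Hann-tapered periodogram zero-padded to at least 1024
    points (windows are too short for Welch averaging without destroying
    frequency resolution). MPF is the power-weighted mean frequency; MDF is
    the frequency splitting the in-band power in half, linearly interpolated
    between bins.

    Raises
    ------
    SilentWindowError
        When the window has no in-band power ("silent window").
    """
    w = np.asarray(window, dtype=float)
    if len(w) < 64:
        raise ValueError("spectral features need windows of >= 64 samples")
    if nfft is None:
        nfft = 1024
        while nfft < len(w):
            nfft *= 2
    freqs, psd = sps.periodogram(w, fs=fs, window="hann", nfft=nfft)
    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= min(hi, fs / 2.0))
    f, p = freqs[in_band], psd[in_band]
    total = float(p.sum())
    if total <= 0.0:
        raise SilentWindowError("silent window: no in-band spectral power")
    mpf = float(np.sum(f * p) / total)
    cum = np.cumsum(p)
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        mdf = float(f[0])
    else:
        frac = (half - cum[i - 1]) / p[i] if p[i] > 0 else 0.0
        mdf = float(f[i - 1] + frac * (f[i] - f[i - 1]))
    return mdf, mpf


def feature_vector(window: np.ndarray, fs: float, **spectral_kwargs) -> dict:
    """All five features of one window as a dict."""
    rms, iemg, arv = time_domain_features(window, fs)
    mdf, mpf = spectral_features(window, fs, **spectral_kwargs)
    return dict(rms=rms, iemg=iemg, arv=arv, mdf=mdf, mpf=mpf)


def build_feature_table(
    record: SignalRecord,
    cfg: WindowingConfig | None = None,
    *,
    band: tuple[float, float] = (20.0, 500.0),
) -> pd.DataFrame:
    """Per-window feature rows for every channel of a preprocessed record.

    Row order is deterministic: channels in record order, then window index.
    Columns: subject, channel_role, window_idx, the five features, label,
    normalized ("raw").
    """
    cfg = cfg or WindowingConfig()
    subject = record.meta.get("subject", "")
    label = record.meta.get("label", "")
    rows = []
    for role in record.channel_roles:
        windows, _ = segment_windows(record.channel(role), record.fs, cfg)
        for w_idx, w in enumerate(windows):
            row = dict(subject=subject, channel_role=role, window_idx=w_idx)
            row.update(feature_vector(w, record.fs, band=band))
            row["label"] = label
            row["normalized"] = "raw"
            rows.append(row)
    return pd.DataFrame(rows)


def ratio_normalize(
    affected: pd.DataFrame,
    reference: pd.DataFrame,
    *,
    pairing: dict[str, str] | None = None,
    features: tuple[str, ...] = FEATURE_COLUMNS,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Divide affected-side features by per-channel-role reference means.

    ``pairing`` maps each affected channel role to the reference role whose
    summary it is divided by (identity when omitted). The result is flagged
    ``normalized="ratio"`` and is dimensionless.

    Raises
    ------
    ValueError
        When a reference summary is below ``eps`` for any feature, naming
        the feature and channel role; or when a required reference role is
        absent.
    """
    pairing = pairing or {}
    ref_means = reference.groupby("channel_role")[list(features)].mean()
    out = affected.copy()
    for role in out["channel_role"].unique():
        ref_role = pairing.get(role, role)
        if ref_role not in ref_means.index:
            raise ValueError(
                f"reference table has no rows for channel role {ref_role!r}"
            )
        summary = ref_means.loc[ref_role]
        for feat in features:
            denom = float(summary[feat])
            if not denom > eps:
                raise ValueError(
                    f"reference summary for feature {feat!r} on channel "
                    f"{ref_role!r} is below {eps}"
                )
            sel = out["channel_role"] == role
            out.loc[sel, feat] = out.loc[sel, feat] / denom
    out["normalized"] = "ratio"
    return out
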