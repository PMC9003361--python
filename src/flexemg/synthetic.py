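"""Synthetic sEMG and evoked-response generators with exact ground truth.

Two recording modes are emulated:

* **Voluntary contraction sEMG** — a superposition of motor-unit action
  potential (MUAP) trains: each active motor unit fires as a
  Poisson-with-refractory point process and contributes a Hermite–Rodriguez
  first-order waveform ``w(t) = a * (t/tau) * exp(-(t/tau)^2)``. Baseline
  Gaussian noise and a 50 Hz powerline sinusoid are added. This is the
  standard parsimonious surrogate for interference-pattern surface EMG.

* **Electrically evoked responses** — a train of stimulus artifacts (sharp
  biphasic spikes at exact stimulus times) each followed, after the
  condition's latency, by a compound muscle response. The compound response
  is a canonical biphasic template parameterized *directly* by latency,
  peak-to-peak amplitude and duration, so each epoch's true parameters are
  known exactly before noise is added (AUC has the closed form
  ``amplitude * duration / pi``).

The three condition parameter sets (healthy, nerve injury, limb
immobilization) encode the qualitative physiology the analysis rests on:
nerve injury removes motor units (smaller evoked amplitude and AUC, shorter
duration) and slows neuromuscular transmission (longer latency), while
immobilization-related disuse atrophy mainly shrinks fibre contributions
(reduced amplitude scale) with near-normal latency. Voluntary-mode feature
distributions of the two atrophy conditions overlap substantially — the
premise that motivates classifying on multi-domain feature combinations.

Whole-cohort generators reproduce the two study protocols: a rat cohort
(two groups of subjects, many evoked acquisitions each, plus pre-injury
healthy baselines for ratio normalization) and a patient cohort (4-channel
maximum-voluntary-contraction records, affected vs. unaffected limb).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .records import SignalRecord

__all__ = [
    "MuapShape",
    "ConditionParams",
    "StimulusConfig",
    "CohortConfig",
    "SubjectEffect",
    "RatCohort",
    "PatientCohort",
    "muap_waveform",
    "simulate_voluntary_emg",
    "synthesize_epoch",
    "simulate_evoked_train",
    "generate_rat_cohort",
    "generate_patient_cohort",
    "default_condition",
    "default_rat_config",
    "default_patient_config",
    "PATIENT_ROLES",
]

CONDITION_LABELS = ("nerve_injury", "immobilization", "healthy")

#: Positive class for classification (per the performance-metric convention:
#: positive = immobilization, negative = nerve injury).
LABEL_CODES = {"immobilization": 1, "nerve_injury": 0}

PATIENT_ROLES = (
    "tibialis_affected",
    "gastrocnemius_affected",
    "tibialis_unaffected",
    "gastrocnemius_unaffected",
)

# Surrogate scale constants (mV / s). Chosen once to place voluntary MVC
# surface EMG in the 0.05-0.1 mV RMS range and healthy evoked responses at
# 1 mV peak-to-peak; see docs/methods.md.
MUAP_BASE_AMP_MV = 0.3
MUAP_BASE_TAU_S = 0.003
MU_UNIT_P2P_MV = 0.05
BASE_EVOKED_DURATION_MS = 8.0
ARTIFACT_AMPLITUDE_MV = 10.0  # fixed: 10x the nominal healthy response p2p

# Per-epoch physiological jitter of the evoked response.
EVOKED_LATENCY_SD_MS = 0.3
EVOKED_AMP_LOG_SD = 0.15
EVOKED_DURATION_SD_FRAC = 0.08


class ParameterError(ValueError):
    """Invalid generator parameter."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MuapShape:
    """Hermite–Rodriguez first-order MUAP surrogate.

    ``w(t) = amplitude * (t/tau) * exp(-(t/tau)^2)`` for t >= 0. The single
    positive extremum sits at ``t = tau/sqrt(2)`` with value
    ``amplitude / sqrt(2) * exp(-1/2)``, and the waveform decays below 1 %
    of its peak beyond ``t = 4 * tau``.
    """

    tau: float  # time scale, s
    amplitude: float  # peak scale, mV

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ParameterError("MUAP tau must be positive")


@dataclass(frozen=True)
class ConditionParams:
    """Generative parameters of one physiological condition."""

    label: str
    mu_count: int  # active motor units
    amplitude_scale: float  # multiplicative factor on MUAP amplitude
    tau_scale: float  # multiplicative factor on MUAP time scale
    firing_rate: float  # mean motor-unit firing rate, Hz
    noise_sd: float  # baseline Gaussian noise, mV
    powerline_amp: float  # 50 Hz interference amplitude, mV
    latency_ms: float  # mean evoked-response onset latency, ms

    def __post_init__(self) -> None:
        if self.label not in CONDITION_LABELS:
            raise ParameterError(
                f"unknown condition label {self.label!r}; "
                f"expected one of {CONDITION_LABELS}"
            )
        if self.mu_count < 1:
            raise ParameterError("mu_count must be >= 1")
        for name in ("amplitude_scale", "tau_scale", "firing_rate", "latency_ms"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("noise_sd", "powerline_amp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


_CONDITION_DEFAULTS = {
    "healthy": dict(
        mu_count=20, amplitude_scale=1.0, tau_scale=1.0, firing_rate=15.0,
        noise_sd=0.01, powerline_amp=0.02, latency_ms=5.0,
    ),
    # Denervation: fewer motor units respond (x0.4) and conduction is
    # slower (+40 % latency); shorter MUAP time scale shortens the evoked
    # response and shifts voluntary spectra upward.
    "nerve_injury": dict(
        mu_count=8, amplitude_scale=1.0, tau_scale=0.85, firing_rate=15.0,
        noise_sd=0.01, powerline_amp=0.02, latency_ms=7.0,
    ),
    # Disuse atrophy: fibre shrinkage reduces per-unit amplitude (x0.7),
    # motor-unit pool nearly intact (x0.9), normal timing.
    "immobilization": dict(
        mu_count=18, amplitude_scale=0.7, tau_scale=1.0, firing_rate=15.0,
        noise_sd=0.01, powerline_amp=0.02, latency_ms=5.0,
    ),
}


def default_condition(label: str, **overrides) -> ConditionParams:
    """Default :class:`ConditionParams` for a condition label.

    Any field can be overridden by keyword, e.g.
    ``default_condition("healthy", noise_sd=0.0)``.
    """
    if label not in _CONDITION_DEFAULTS:
        raise ParameterError(
            f"unknown condition label {label!r}; expected one of {CONDITION_LABELS}"
        )
    params = dict(_CONDITION_DEFAULTS[label])
    params.update(overrides)
    return ConditionParams(label=label, **params)


@dataclass(frozen=True)
class StimulusConfig:
    """Electrical stimulation protocol (bipolar square pulse train).

    Defaults follow the in-vivo protocol: 2 mA pulses at 2 Hz, 100 us pulse
    width, 30 s train. ``pulse_amplitude_ma`` and ``pulse_width_s`` are
    metadata; the recorded trace only carries the stimulus *artifact*, a
    narrow biphasic spike of fixed large amplitude.
    """

    pulse_amplitude_ma: float = 2.0
    rate: float = 2.0  # Hz
    pulse_width_s: float = 100e-6
    train_duration: float = 30.0  # s
    artifact_amplitude: float = ARTIFACT_AMPLITUDE_MV  # mV
    artifact_width: float = 1e-3  # s

    def __post_init__(self) -> None:
        if not (self.rate > 0 and self.train_duration > 0):
            raise ParameterError("stimulus rate and train duration must be positive")
        if not self.artifact_width < 1.0 / self.rate:
            raise ParameterError("artifact width must be below the inter-stimulus interval")
        if self.rate * self.train_duration < 1:
            raise ParameterError("stimulus train must contain at least one pulse")

    @property
    def n_stimuli(self) -> int:
        return int(round(self.rate * self.train_duration))


@dataclass(frozen=True)
class SubjectEffect:
    """Per-subject random effect applied on top of the condition params."""

    amp_factor: float = 1.0
    tau_factor: float = 1.0
    latency_offset_ms: float = 0.0

    @staticmethod
    def draw(rng: np.random.Generator) -> "SubjectEffect":
        return SubjectEffect(
            amp_factor=float(rng.lognormal(0.0, 0.12)),
            tau_factor=float(rng.lognormal(0.0, 0.05)),
            latency_offset_ms=float(rng.normal(0.0, 0.3)),
        )


@dataclass(frozen=True)
class CohortConfig:
    """Generative description of a whole study.

    ``groups`` maps condition labels to subject counts; the rat protocol
    additionally simulates ``baseline_epochs`` pre-injury healthy epochs per
    subject (the denominator of the ratio normalization).
    """

    protocol: str  # "rat_evoked" | "patient_mvc"
    groups: tuple[tuple[str, int], ...]
    acquisitions_per_subject: int
    channels: tuple[str, ...]
    record_duration: float  # s
    sampling_rate: float = 2000.0
    seed: int | None = None
    baseline_epochs: int = 10
    stimulus: StimulusConfig | None = None

    def __post_init__(self) -> None:
        if self.protocol not in ("rat_evoked", "patient_mvc"):
            raise ParameterError(f"unknown protocol {self.protocol!r}")
        if self.acquisitions_per_subject < 1:
            raise ParameterError("acquisitions_per_subject must be >= 1")
        for label, n in self.groups:
            if label not in LABEL_CODES:
                raise ParameterError(
                    f"cohort group label {label!r} must be one of "
                    f"{tuple(LABEL_CODES)}"
                )
            if n < 1:
                raise ParameterError("each group needs at least one subject")
        if self.protocol == "patient_mvc" and len(self.channels) != 4:
            raise ParameterError(
                "patient protocol requires exactly 4 channels "
                "(affected/unaffected x tibialis/gastrocnemius)"
            )


def default_rat_config(**overrides) -> CohortConfig:
    """6 + 6 rats, 150 single-stimulus evoked acquisitions each, fs 10 kHz."""
    params = dict(
        protocol="rat_evoked",
        groups=(("immobilization", 6), ("nerve_injury", 6)),
        acquisitions_per_subject=150,
        channels=("emg",),
        record_duration=0.5,
        sampling_rate=10000.0,
        stimulus=StimulusConfig(train_duration=0.5),
        baseline_epochs=10,
    )
    params.update(overrides)
    return CohortConfig(**params)


def default_patient_config(**overrides) -> CohortConfig:
    """7 immobilization + 3 nerve-injury patients, 60 s 4-channel MVC records."""
    params = dict(
        protocol="patient_mvc",
        groups=(("immobilization", 7), ("nerve_injury", 3)),
        acquisitions_per_subject=1,
        channels=PATIENT_ROLES,
        record_duration=60.0,
        sampling_rate=2000.0,
    )
    params.update(overrides)
    return CohortConfig(**params)


# ---------------------------------------------------------------------------
# MUAP waveform and voluntary sEMG
# ---------------------------------------------------------------------------


def muap_waveform(shape: MuapShape, fs: float) -> np.ndarray:
    """Sample the MUAP surrogate on ``[0, 5 * tau]``.

    Raises :class:`ParameterError` for non-positive ``tau`` or ``fs`` below
    1 kHz (the waveform is a few ms wide; coarser sampling aliases it).
    """
    if not fs >= 1000:
        raise ParameterError("fs must be >= 1000 Hz for MUAP synthesis")
    t = np.arange(0.0, 5.0 * shape.tau, 1.0 / fs)
    u = t / shape.tau
    return shape.amplitude * u * np.exp(-(u**2))


def _spike_train(
    rng: np.random.Generator, rate: float, duration: float, refractory: float = 0.020
) -> np.ndarray:
    """Poisson-like firing times with an absolute refractory floor."""
    if rate <= 0:
        return np.empty(0)
    mean_gap = max(1.0 / rate - refractory, 1e-4)
    # Generous draw count, then truncate to the record.
    n_max = int(duration / (refractory + mean_gap) * 3) + 10
    gaps = refractory + rng.exponential(mean_gap, size=n_max)
    times = np.cumsum(gaps) - rng.uniform(0.0, refractory + mean_gap)
    return times[(times >= 0.0) & (times < duration)]


def simulate_voluntary_emg(
    cond: ConditionParams,
    duration: float,
    fs: float = 2000.0,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    role: str = "emg",
    effect: SubjectEffect | None = None,
    meta: dict | None = None,
) -> SignalRecord:
    """Simulate one channel of maximum-voluntary-contraction surface EMG.

    The signal is the sum over ``cond.mu_count`` motor units of spike trains
    (rate ``firing_rate``, 20 ms refractory floor) convolved with per-unit
    MUAP kernels whose ``tau`` is jittered +-20 %, plus Gaussian baseline
    noise and a 50 Hz powerline sinusoid with random phase. Reproducible
    given the seed; noiseless output is exactly linear in
    ``amplitude_scale``.
    """
    if not duration > 1.0:
        raise ParameterError("voluntary records must be longer than 1 s")
    if rng is None:
        rng = np.random.default_rng(seed)
    effect = effect or SubjectEffect()
    n = int(round(duration * fs))
    x = np.zeros(n)
    base_tau = MUAP_BASE_TAU_S * cond.tau_scale * effect.tau_factor
    base_amp = MUAP_BASE_AMP_MV * cond.amplitude_scale * effect.amp_factor
    for _ in range(cond.mu_count):
        tau = base_tau * rng.uniform(0.8, 1.2)
        amp = base_amp * rng.uniform(0.7, 1.3)
        kernel = muap_waveform(MuapShape(tau=tau, amplitude=amp), fs)
        spikes = _spike_train(rng, cond.firing_rate, duration)
        if spikes.size == 0:
            continue
        impulses = np.zeros(n)
        idx = np.round(spikes * fs).astype(int)
        np.add.at(impulses, idx[idx < n], 1.0)
        x += fftconvolve(impulses, kernel)[:n]
    if cond.noise_sd > 0:
        x += cond.noise_sd * rng.standard_normal(n)
    if cond.powerline_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += cond.powerline_amp * np.sin(2.0 * np.pi * 50.0 * np.arange(n) / fs + phase)
    record_meta = {"condition": cond.label, "protocol": "voluntary_mvc"}
    record_meta.update(meta or {})
    return SignalRecord(data=x, fs=fs, channel_roles=(role,), meta=record_meta)


# ---------------------------------------------------------------------------
# evoked responses
# ---------------------------------------------------------------------------

# Biphasic response template b(u) = sin(2*pi*u) on u in [0, 1):
_TEMPLATE_P2P = 2.0
_TEMPLATE_ABS_INTEGRAL = 2.0 / np.pi  # integral of |b| over [0, 1]


def synthesize_epoch(
    n: int,
    fs: float,
    latency_ms: float,
    amplitude_mv: float,
    duration_ms: float,
    *,
    artifact_amplitude: float = ARTIFACT_AMPLITUDE_MV,
    artifact_width: float = 1e-3,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One evoked epoch: stimulus artifact at t=0, response after the latency.

    The response is ``(A/2) * sin(2*pi * (t - t0) / D)`` on
    ``[t0, t0 + D]`` with ``t0 = latency`` and ``D = duration``, so the true
    peak-to-peak amplitude is exactly ``amplitude_mv`` and the true rectified
    area is ``amplitude_mv * duration_ms / pi`` (mV*ms).
    """
    if artifact_width * 1000.0 >= latency_ms:
        raise ParameterError(
            "stimulus artifact would overlap the response onset "
            f"(artifact width {artifact_width * 1e3:.2f} ms >= latency "
            f"{latency_ms:.2f} ms)"
        )
    t = np.arange(n) / fs
    x = np.zeros(n)
    in_art = t < artifact_width
    x[in_art] = artifact_amplitude * np.sin(2.0 * np.pi * t[in_art] / artifact_width)
    t0 = latency_ms / 1000.0
    dur = duration_ms / 1000.0
    in_resp = (t >= t0) & (t < t0 + dur)
    x[in_resp] += (amplitude_mv / _TEMPLATE_P2P) * np.sin(
        2.0 * np.pi * (t[in_resp] - t0) / dur
    )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        x += noise_sd * rng.standard_normal(n)
    return x


def true_auc(amplitude_mv: float, duration_ms: float) -> float:
    """Closed-form rectified area of the response template, mV*ms."""
    return amplitude_mv / _TEMPLATE_P2P * _TEMPLATE_ABS_INTEGRAL * duration_ms


def simulate_evoked_train(
    cond: ConditionParams,
    stim: StimulusConfig | None = None,
    fs: float = 10000.0,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    effect: SubjectEffect | None = None,
    jitter: bool = True,
    meta: dict | None = None,
) -> tuple[SignalRecord, pd.DataFrame]:
    """Simulate a stimulation train and return (record, per-epoch ground truth).

    One artifact is placed at each exact stimulus time ``k / rate``;
    ``rate * train_duration`` epochs in total. Per-epoch latency, amplitude
    and duration are jittered around the condition means (lognormal amplitude,
    Gaussian timing) unless ``jitter=False``. The returned table holds the
    exact pre-noise truth per epoch: ``latency_ms``, ``amplitude_mv``,
    ``duration_ms``, ``auc_mvms``.
    """
    stim = stim or StimulusConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    effect = effect or SubjectEffect()
    n = int(round(stim.train_duration * fs))
    x = np.zeros(n)
    mean_amp = MU_UNIT_P2P_MV * cond.mu_count * cond.amplitude_scale * effect.amp_factor
    mean_dur = BASE_EVOKED_DURATION_MS * cond.tau_scale * effect.tau_factor
    mean_lat = cond.latency_ms + effect.latency_offset_ms
    rows = []
    min_lat = stim.artifact_width * 1000.0 + 0.5
    for k in range(stim.n_stimuli):
        if jitter:
            lat = max(mean_lat + rng.normal(0.0, EVOKED_LATENCY_SD_MS), min_lat)
            amp = mean_amp * rng.lognormal(0.0, EVOKED_AMP_LOG_SD)
            dur = mean_dur * max(1.0 + rng.normal(0.0, EVOKED_DURATION_SD_FRAC), 0.3)
        else:
            lat, amp, dur = mean_lat, mean_amp, mean_dur
        start = int(round(k / stim.rate * fs))
        length = min(n - start, int(round(fs / stim.rate)))
        epoch = synthesize_epoch(
            length,
            fs,
            lat,
            amp,
            dur,
            artifact_amplitude=stim.artifact_amplitude,
            artifact_width=stim.artifact_width,
        )
        x[start : start + length] += epoch
        rows.append(
            dict(
                epoch=k,
                latency_ms=lat,
                amplitude_mv=amp,
                duration_ms=dur,
                auc_mvms=true_auc(amp, dur),
            )
        )
    if cond.noise_sd > 0:
        x += cond.noise_sd * rng.standard_normal(n)
    if cond.powerline_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += cond.powerline_amp * np.sin(2.0 * np.pi * 50.0 * np.arange(n) / fs + phase)
    truth = pd.DataFrame(rows)
    record_meta = {"condition": cond.label, "protocol": "evoked_train"}
    record_meta.update(meta or {})
    record = SignalRecord(data=x, fs=fs, channel_roles=("emg",), meta=record_meta)
    return record, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class RatAcquisition:
    subject_id: str
    acquisition_id: int
    label: int  # 1 = immobilization (positive), 0 = nerve injury
    condition: str
    record: SignalRecord
    truth: pd.DataFrame


@dataclass
class RatCohort:
    """Evoked-protocol cohort: labeled acquisitions + per-subject baselines."""

    config: CohortConfig
    acquisitions: list[RatAcquisition]
    baselines: dict[str, list[tuple[SignalRecord, pd.DataFrame]]]
    labels: pd.DataFrame  # subject_id, acquisition_id, label


@dataclass
class PatientCohort:
    """MVC-protocol cohort: one 4-channel record per patient acquisition."""

    config: CohortConfig
    records: list[SignalRecord]
    labels: pd.DataFrame  # subject_id, acquisition_id, label


def generate_rat_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    *,
    conditions: dict[str, ConditionParams] | None = None,
) -> RatCohort:
    """Generate the evoked-protocol cohort with pre-injury baselines.

    Each subject contributes ``acquisitions_per_subject`` labeled evoked
    records plus ``baseline_epochs`` healthy records acquired "before
    surgery" (same subject random effect), which the pipeline averages into
    the ratio denominator. With the default 6 + 6 x 150 design the label
    table has 1800 rows, 900 positive and 900 negative.
    """
    config = config or default_rat_config()
    if config.protocol != "rat_evoked":
        raise ParameterError("generate_rat_cohort requires the rat_evoked protocol")
    master = np.random.SeedSequence(
        config.seed if seed is None else seed
    )
    conditions = conditions or {}
    stim = config.stimulus or StimulusConfig(train_duration=config.record_duration)
    fs = config.sampling_rate
    acquisitions: list[RatAcquisition] = []
    baselines: dict[str, list[tuple[SignalRecord, pd.DataFrame]]] = {}
    label_rows = []
    subject_idx = 0
    group_seeds = master.spawn(len(config.groups))
    for (cond_label, n_subjects), group_ss in zip(config.groups, group_seeds):
        cond = conditions.get(cond_label, default_condition(cond_label))
        healthy = conditions.get("healthy", default_condition("healthy"))
        for subj_ss in group_ss.spawn(n_subjects):
            subject_idx += 1
            subject_id = f"rat{subject_idx:02d}"
            subj_rng = np.random.default_rng(subj_ss)
            effect = SubjectEffect.draw(subj_rng)
            base_list = []
            for b in range(config.baseline_epochs):
                rec, truth = simulate_evoked_train(
                    healthy, stim, fs, rng=subj_rng, effect=effect,
                    meta={"subject": subject_id, "baseline": str(b)},
                )
                base_list.append((rec, truth))
            baselines[subject_id] = base_list
            for a in range(config.acquisitions_per_subject):
                rec, truth = simulate_evoked_train(
                    cond, stim, fs, rng=subj_rng, effect=effect,
                    meta={"subject": subject_id, "acquisition": str(a)},
                )
                acquisitions.append(
                    RatAcquisition(
                        subject_id=subject_id,
                        acquisition_id=a,
                        label=LABEL_CODES[cond_label],
                        condition=cond_label,
                        record=rec,
                        truth=truth,
                    )
                )
                label_rows.append(
                    dict(subject_id=subject_id, acquisition_id=a,
                         label=LABEL_CODES[cond_label])
                )
    labels = pd.DataFrame(label_rows)
    return RatCohort(config=config, acquisitions=acquisitions,
                     baselines=baselines, labels=labels)


def generate_patient_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    *,
    conditions: dict[str, ConditionParams] | None = None,
) -> PatientCohort:
    """Generate the 4-channel patient MVC cohort.

    Affected-limb channels follow the patient's condition parameters,
    unaffected-limb channels the healthy parameters, both under the same
    per-patient random effect (so affected/unaffected ratios cancel the
    patient's overall effort and electrode gain). Default template: 7
    immobilization + 3 nerve-injury patients.
    """
    config = config or default_patient_config()
    if config.protocol != "patient_mvc":
        raise ParameterError("generate_patient_cohort requires the patient_mvc protocol")
    if len(config.channels) != 4:
        raise ParameterError("patient protocol requires exactly 4 channels")
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    conditions = conditions or {}
    fs = config.sampling_rate
    records: list[SignalRecord] = []
    label_rows = []
    subject_idx = 0
    group_seeds = master.spawn(len(config.groups))
    for (cond_label, n_subjects), group_ss in zip(config.groups, group_seeds):
        cond = conditions.get(cond_label, default_condition(cond_label))
        healthy = conditions.get("healthy", default_condition("healthy"))
        for subj_ss in group_ss.spawn(n_subjects):
            subject_idx += 1
            subject_id = f"pat{subject_idx:02d}"
            subj_rng = np.random.default_rng(subj_ss)
            effect = SubjectEffect.draw(subj_rng)
            for a in range(config.acquisitions_per_subject):
                channels = []
                for role in config.channels:
                    ch_cond = cond if role.endswith("_affected") else healthy
                    gain = float(subj_rng.lognormal(0.0, 0.05))
                    ch_effect = replace(effect, amp_factor=effect.amp_factor * gain)
                    ch = simulate_voluntary_emg(
                        ch_cond, config.record_duration, fs,
                        rng=subj_rng, role=role, effect=ch_effect,
                    )
                    channels.append(ch.data[:, 0])
                rec = SignalRecord(
                    data=np.column_stack(channels),
                    fs=fs,
                    channel_roles=tuple(config.channels),
                    meta={
                        "subject": subject_id,
                        "condition": cond_label,
                        "label": str(LABEL_CODES[cond_label]),
                        "acquisition": str(a),
                        "protocol": "patient_mvc",
                    },
                )
                records.append(rec)
                label_rows.append(
                    dict(subject_id=subject_id, acquisition_id=a,
                         label=LABEL_CODES[cond_label])
                )
    labels = pd.DataFrame(label_rows)
    return PatientCohort(config=config, records=records, labels=labels)
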