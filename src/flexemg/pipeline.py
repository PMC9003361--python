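"""End-to-end pipeline: simulate -> preprocess -> features -> ratio -> classify.

:func:`run_pipeline` executes one of the two study protocols from a single
:class:`PipelineConfig` and returns a JSON-serializable report containing
cohort accounting, the evoked group comparison (rat protocol), per-classifier
cross-validation and hold-out metrics, and a provenance block (config hash,
seed, library versions). Identical config + seed gives a byte-identical
report; all stage randomness derives from the master seed by documented
sub-seeding (cohort, split and CV seeds are spawned from it in a fixed
order).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import features as _features
from .evoked import compare_groups, detect_stimuli, extract_evoked_parameters
from .preprocess import PreprocessConfig, preprocess_record
from .records import write_table
from .synthetic import (
    CohortConfig,
    PatientCohort,
    RatCohort,
    StimulusConfig,
    default_patient_config,
    default_rat_config,
    generate_patient_cohort,
    generate_rat_cohort,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "rat_feature_table",
    "patient_feature_table",
    "config_hash",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one experiment needs, validated before any computation."""

    protocol: str = "rat_evoked"
    cohort: CohortConfig | None = None  # None -> protocol default
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    windowing: _features.WindowingConfig = field(
        default_factory=lambda: _features.WindowingConfig(stable_segment=(15.0, 45.0))
    )
    classifiers: tuple[_classify.ClassifierSpec, ...] = (
        _classify.ClassifierSpec("gbdt"),
        _classify.ClassifierSpec("svm_rbf"),
        _classify.ClassifierSpec("knn"),
    )
    folds: int = 5
    train_frac: float = 0.8
    subject_wise: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.protocol not in ("rat_evoked", "patient_mvc"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.cohort is not None and self.cohort.protocol != self.protocol:
            raise ValueError("cohort protocol does not match pipeline protocol")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def resolved_cohort(self) -> CohortConfig:
        if self.cohort is not None:
            return self.cohort
        if self.protocol == "rat_evoked":
            return default_rat_config()
        return default_patient_config()

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs and kwargs["cohort"] is not None:
            c = dict(kwargs["cohort"])
            if "groups" in c:
                c["groups"] = tuple((str(l), int(n)) for l, n in c["groups"])
            if "channels" in c:
                c["channels"] = tuple(c["channels"])
            if "stimulus" in c and c["stimulus"] is not None:
                c["stimulus"] = StimulusConfig(**c["stimulus"])
            kwargs["cohort"] = CohortConfig(**c)
        if "preprocess" in kwargs and kwargs["preprocess"] is not None:
            p = dict(kwargs["preprocess"])
            if "band" in p:
                p["band"] = tuple(p["band"])
            kwargs["preprocess"] = PreprocessConfig(**p)
        if "windowing" in kwargs and kwargs["windowing"] is not None:
            w = dict(kwargs["windowing"])
            if w.get("stable_segment") is not None:
                w["stable_segment"] = tuple(w["stable_segment"])
            kwargs["windowing"] = _features.WindowingConfig(**w)
        if "classifiers" in kwargs and kwargs["classifiers"] is not None:
            kwargs["classifiers"] = tuple(
                _classify.ClassifierSpec(**dict(c)) for c in kwargs["classifiers"]
            )
        return PipelineConfig(**kwargs)


def config_hash(config: PipelineConfig) -> str:
    """Stable sha256 of the canonicalized configuration."""
    payload = dataclasses.asdict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    from . import __version__

    return {
        "flexemg": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
    }


# ---------------------------------------------------------------------------
# rat (evoked) protocol
# ---------------------------------------------------------------------------


def _evoked_epoch_features(
    record,
    pcfg: PreprocessConfig,
    stim: StimulusConfig,
    *,
    blanking_ms: float = 2.0,
    epoch_ms: float = 100.0,
) -> tuple[dict, "object"]:
    """(mean sEMG features, evoked parameters) of one stimulation record.

    The record is filtered, the stimulus artifact located, and the sEMG
    features computed on the post-blanking response window (artifact
    excluded); evoked parameters are extracted from the same epoch.
    """
    rec = preprocess_record(record, pcfg)
    x = rec.data[:, 0]
    fs = rec.fs
    idx = detect_stimuli(x, fs, stim)
    blank_n = int(round(blanking_ms / 1000.0 * fs))
    epoch_n = int(round(epoch_ms / 1000.0 * fs))
    feats: list[dict] = []
    params = []
    for i in idx:
        start = max(int(i) - int(round(0.0005 * fs)), 0)
        epoch = x[start : start + epoch_n]
        seg = epoch[blank_n:]
        feats.append(_features.feature_vector(seg, fs))
        params.append(extract_evoked_parameters(epoch, fs, blanking_ms=blanking_ms))
    mean_feats = {
        k: float(np.mean([f[k] for f in feats])) for k in _features.FEATURE_COLUMNS
    }
    return mean_feats, params[0] if len(params) == 1 else params


def rat_feature_table(
    cohort: RatCohort,
    pcfg: PreprocessConfig | None = None,
    *,
    with_evoked: bool = True,
) -> tuple[pd.DataFrame, dict[str, list]]:
    """One ratio-normalized feature row per acquisition, plus evoked params.

    Each acquisition's sEMG features are divided by the mean features of the
    subject's pre-injury healthy baseline epochs ("versus the values of the
    healthy subjects before the surgery"). Returns the feature table
    (columns: subject, acquisition_id, rms, iemg, arv, mdf, mpf, label,
    normalized) and, when ``with_evoked``, the per-condition lists of
    extracted :class:`~flexemg.evoked.EvokedParameters`.
    """
    pcfg = pcfg or PreprocessConfig()
    stim = cohort.config.stimulus or StimulusConfig(
        train_duration=cohort.config.record_duration
    )
    baseline_means: dict[str, dict] = {}
    for subject_id, pairs in cohort.baselines.items():
        feats = [
            _evoked_epoch_features(rec, pcfg, stim)[0] for rec, _ in pairs
        ]
        baseline_means[subject_id] = {
            k: float(np.mean([f[k] for f in feats])) for k in _features.FEATURE_COLUMNS
        }
    rows = []
    evoked_by_condition: dict[str, list] = {}
    for acq in cohort.acquisitions:
        feats, params = _evoked_epoch_features(acq.record, pcfg, stim)
        base = baseline_means[acq.subject_id]
        row = dict(subject=acq.subject_id, acquisition_id=acq.acquisition_id)
        for k in _features.FEATURE_COLUMNS:
            row[k] = feats[k] / base[k]
        row["label"] = acq.label
        row["normalized"] = "ratio"
        rows.append(row)
        if with_evoked:
            plist = params if isinstance(params, list) else [params]
            evoked_by_condition.setdefault(acq.condition, []).extend(plist)
    return pd.DataFrame(rows), evoked_by_condition


# ---------------------------------------------------------------------------
# patient (voluntary MVC) protocol
# ---------------------------------------------------------------------------


def patient_feature_table(
    cohort: PatientCohort,
    pcfg: PreprocessConfig | None = None,
    wcfg: _features.WindowingConfig | None = None,
) -> pd.DataFrame:
    """Affected/unaffected ratio feature rows for every patient window."""
    pcfg = pcfg or PreprocessConfig()
    wcfg = wcfg or _features.WindowingConfig(stable_segment=(15.0, 45.0))
    tables = []
    for record in cohort.records:
        rec = preprocess_record(record, pcfg)
        table = _features.build_feature_table(rec, wcfg)
        affected = table[table["channel_role"].isin(_features.PATIENT_PAIRING)]
        reference = table[~table["channel_role"].isin(_features.PATIENT_PAIRING)]
        ratio = _features.ratio_normalize(
            affected, reference, pairing=_features.PATIENT_PAIRING
        )
        ratio = ratio.copy()
        ratio["label"] = int(record.meta["label"])
        tables.append(ratio)
    out = pd.concat(tables, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def _metrics_dict(m: _classify.Metrics) -> dict:
    return {k: v for k, v in m.__dict__.items()}


def _classifier_report(
    table: pd.DataFrame,
    config: PipelineConfig,
    split_seed: int,
    cv_seed: int,
) -> dict:
    groups = table["subject"].to_numpy() if config.subject_wise else None
    out = {}
    for spec in config.classifiers:
        spec = dataclasses.replace(spec, seed=cv_seed)
        cv = _classify.run_cv(
            table, config.folds, spec, seed=cv_seed, groups=groups
        )
        train, test = _classify.split_dataset(
            table, config.train_frac, seed=split_seed
        )
        cm = _classify.fit_predict(spec, train, test)
        out[spec.kind] = {
            "cv_mean": _metrics_dict(cv.mean),
            "cv_sd": _metrics_dict(cv.sd),
            "cv_folds": [_metrics_dict(m) for m in cv.fold_metrics],
            "holdout_confusion": dataclasses.asdict(cm),
            "holdout_metrics": _metrics_dict(_classify.compute_metrics(cm)),
        }
    return out


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute the configured protocol end to end and return the report.

    When ``config.outdir`` is set, the feature table, label table and report
    are written there as text files, each embedding the config hash.
    """
    config = config or PipelineConfig()
    chash = config_hash(config)
    master = np.random.SeedSequence(config.seed)
    cohort_ss, split_ss, cv_ss = master.spawn(3)
    cohort_seed = int(cohort_ss.generate_state(1)[0] % (2**31))
    split_seed = int(split_ss.generate_state(1)[0] % (2**31))
    cv_seed = int(cv_ss.generate_state(1)[0] % (2**31))

    report: dict = {
        "protocol": config.protocol,
        "provenance": {
            "config_hash": chash,
            "seed": config.seed,
            "versions": _versions(),
        },
    }
    cohort_cfg = config.resolved_cohort()
    if config.protocol == "rat_evoked":
        cohort = generate_rat_cohort(cohort_cfg, seed=cohort_seed)
        table, evoked_params = rat_feature_table(cohort, config.preprocess)
        labels = cohort.labels
        comparison = compare_groups(
            evoked_params["nerve_injury"], evoked_params["immobilization"]
        )
        report["evoked_comparison"] = {
            name: dataclasses.asdict(c) for name, c in comparison.parameters.items()
        }
    else:
        cohort = generate_patient_cohort(cohort_cfg, seed=cohort_seed)
        table = patient_feature_table(cohort, config.preprocess, config.windowing)
        labels = cohort.labels

    report["counts"] = {
        "feature_rows": int(len(table)),
        "positive_rows": int((table["label"] == 1).sum()),
        "negative_rows": int((table["label"] == 0).sum()),
        "subjects": int(labels["subject_id"].nunique()),
        "positive_subjects": int(
            labels.drop_duplicates("subject_id")["label"].sum()
        ),
    }
    report["classifiers"] = _classifier_report(table, config, split_seed, cv_seed)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": chash, "seed": config.seed}
        write_table(table, outdir / "feature_table.csv", header_meta=meta)
        write_table(labels, outdir / "labels.csv", header_meta=meta)
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
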