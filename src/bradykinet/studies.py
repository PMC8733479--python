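"""Bundled in-silico experiments on the synthetic cohort.

These are the package's own validation studies: parameter recovery on
noise-free tracks, null calibration with exchangeable groups, and
discrimination of the default separated phenotype. Tests and the
reproduction script both run them, so the numbers they report are always
recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import (
    MODEL_NAMES,
    build_feature_table,
    cross_validate,
    external_validate,
    group_compare,
    train_classifier,
)
from .features import ExtractionConfig, extract_features
from .kinematics import curve_for_task
from .pipeline import cohort_features, side_metadata
from .simulate import CohortSpec, GroupParams, MotionSimParams, simulate_cohort, simulate_track

__all__ = [
    "extract_from_params",
    "parameter_recovery",
    "decrement_recovery",
    "null_calibration",
    "discrimination_study",
]

_FPS = 30.0
_DURATION_S = 12.0
_CALIBRATION_S = 0.5


def extract_from_params(
    params: MotionSimParams,
    task: str = "finger_tapping",
    fps: float = _FPS,
    duration_s: float = _DURATION_S,
    calibration_s: float = _CALIBRATION_S,
    config: Optional[ExtractionConfig] = None,
):
    """Simulate one track and run the full extraction chain on it."""
    frames = simulate_track(params, task, fps=fps, duration_s=duration_s, calibration_s=calibration_s)
    cal = (0, int(round(calibration_s * fps)))
    curve = curve_for_task(frames, task, fps, cal)
    config = config or ExtractionConfig(calibration_frames=cal)
    return extract_features(curve, task, config)


def _n_expected_peaks(cadence_hz: float, motion_s: float) -> int:
    """Raised-cosine pulses peak at (k + 1/2) / f; count those before the end."""
    return int(np.floor(cadence_hz * motion_s - 0.5)) + 1


def parameter_recovery(
    cadences_hz: Sequence[float] = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0),
    amplitudes: Sequence[float] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    task: str = "finger_tapping",
) -> pd.DataFrame:
    """Noise-free recovery of cadence (as speed) and amplitude over a grid."""
    motion_s = _DURATION_S - _CALIBRATION_S
    rows = []
    for f in cadences_hz:
        for a in amplitudes:
            params = MotionSimParams(
                cadence_hz=f, base_amplitude=a, decrement_rate=0.0,
                hesitation_prob=0.0, jitter_px_sd=0.0,
            )
            feats = extract_from_params(params, task=task)
            rows.append(
                {
                    "cadence_hz": f,
                    "amplitude": a,
                    "speed": feats.speed,
                    "amplitude_mean": feats.amplitude_mean,
                    "n_peaks": feats.n_peaks,
                    "speed_error": abs(feats.speed - f),
                    "amplitude_rel_error": abs(feats.amplitude_mean - a) / a,
                    "expected_n_peaks": _n_expected_peaks(f, motion_s),
                }
            )
    return pd.DataFrame(rows)


def decrement_recovery(
    decrements: Sequence[float] = (0.01, 0.02, 0.03, 0.04, 0.05),
    cadence_hz: float = 2.0,
    base_amplitude: float = 1.0,
) -> pd.DataFrame:
    """Noise-free fatigue vs the closed form of the linear amplitude decay.

    Peaks sit at t_k = (k + 1/2)/f, so the envelope spans
    A0*d*(t_last - t_first) = A0 * d * k_max / f exactly.
    """
    motion_s = _DURATION_S - _CALIBRATION_S
    rows = []
    for d in decrements:
        params = MotionSimParams(
            cadence_hz=cadence_hz, base_amplitude=base_amplitude,
            decrement_rate=d, hesitation_prob=0.0, jitter_px_sd=0.0,
        )
        feats = extract_from_params(params)
        k_max = _n_expected_peaks(cadence_hz, motion_s) - 1
        expected = base_amplitude * d * k_max / cadence_hz
        rows.append(
            {
                "decrement_rate": d,
                "fatigue": feats.fatigue,
                "expected_fatigue": expected,
                "rel_error": abs(feats.fatigue - expected) / expected,
            }
        )
    return pd.DataFrame(rows)


def _exchangeable_null_spec(seed: int, n_pd: int, n_hs: int) -> CohortSpec:
    null_params = replace(GroupParams.healthy(), asymmetry_mean=1.0, asymmetry_sd=0.0)
    return CohortSpec(
        n_pd=n_pd,
        n_hs=n_hs,
        seed=seed,
        tasks=("finger_tapping",),
        conditions=("unilateral",),
        pd_params=null_params,
        hs_params=null_params,
    )


def null_calibration(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_pd: int = 22,
    n_hs: int = 20,
    models: Sequence[str] = MODEL_NAMES,
) -> pd.DataFrame:
    """Cross-validated AUC and rank-sum p-values when the two groups share
    one parameter distribution (asymmetry pinned at 1, sides exchangeable).

    Returns one row per seed with the mean-ROC AUC of each classifier on the
    unilateral finger-tapping speed input and the Mann-Whitney p-value of
    the amplitude_mean side contrast.
    """
    rows = []
    for i in range(n_seeds):
        seed = int((base_seed + i) % (2**31))
        spec = _exchangeable_null_spec(seed, n_pd, n_hs)
        cohort = simulate_cohort(spec)
        features = cohort_features(cohort)
        table = build_feature_table(features, "speed", "finger_tapping", "unilateral")
        row: Dict[str, float] = {"seed": seed}
        for model in models:
            row[f"auc_{model}"] = cross_validate(table, model, k=4, seed=seed).auc
        comparisons = group_compare(
            features, side_metadata(cohort), feature_names=("amplitude_mean",)
        )
        row["p_amplitude"] = comparisons[0].p_value
        rows.append(row)
    return pd.DataFrame(rows)


def discrimination_study(
    seed: int = 0,
    feature_name: str = "speed",
    task: str = "finger_tapping",
    condition: str = "unilateral",
    models: Sequence[str] = MODEL_NAMES,
) -> Dict[str, object]:
    """Default separated phenotype: 22 PD + 20 HS training cohort under
    4-fold CV, plus an independent 6+6 validation cohort scored by models
    fitted on the full training cohort."""
    train_spec = CohortSpec(seed=seed, tasks=(task,), conditions=(condition,))
    val_spec = CohortSpec(
        n_pd=6, n_hs=6, seed=seed + 90000, tasks=(task,), conditions=(condition,)
    )
    train_features = cohort_features(simulate_cohort(train_spec))
    val_features = cohort_features(simulate_cohort(val_spec))
    train_rows = build_feature_table(train_features, feature_name, task, condition)
    val_rows = build_feature_table(val_features, feature_name, task, condition)

    out: Dict[str, object] = {
        "n_train": int(len(train_rows)),
        "n_validation": int(len(val_rows)),
    }
    for model in models:
        cv = cross_validate(train_rows, model, k=4, seed=seed)
        fitted = train_classifier(train_rows, model, seed=seed)
        val = external_validate(fitted, val_rows, model)
        out[f"cv_auc_{model}"] = cv.auc
        out[f"validation_auc_{model}"] = val.auc
        out[f"validation_accuracy_{model}"] = val.accuracy
    return out
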