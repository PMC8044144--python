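"""Prediction of future visits and the constant-carry-forward baseline.

The model prediction personalizes the course map on a subject's past
visits only and extrapolates the fitted trajectory to the requested
future ages; hidden future data are never read.  The benchmark baseline
repeats each marker's last observed value.  Errors are reported as MAE on
the normalized scale and rescaled to raw instrument points (MMSE x 30,
ADAS-Cog-13 x 85), with a two-sided Mann-Whitney U comparison between the
model's and the baseline's absolute-error samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .model import CourseMap, IndividualEffects, trajectory_eval
from .personalization import personalize

__all__ = [
    "predict_future",
    "constant_prediction",
    "evaluate_predictions",
    "select_prediction_cohort",
    "RAW_SCALE_SPANS",
]

#: spans used to convert normalized errors to raw instrument points
RAW_SCALE_SPANS = {"mmse": 30.0, "adas_cog13": 85.0, "adas_cog": 70.0}

DIAGNOSIS_ORDER = {"CN": 0, "MCI": 1, "AD": 2}


def _check_future(past_times, future_times):
    past_times = np.atleast_1d(np.asarray(past_times, dtype=float))
    future_times = np.atleast_1d(np.asarray(future_times, dtype=float))
    if past_times.size == 0:
        raise ValueError("past data must be nonempty")
    if np.any(future_times < past_times.max()):
        raise ValueError(
            "future times must not precede the last past visit "
            f"(last past at {past_times.max():g})"
        )
    return past_times, future_times


def predict_future(
    cmap: CourseMap,
    past_times,
    past_values,
    future_times,
    method: str = "powell",
    **personalize_kwargs,
) -> tuple[np.ndarray, IndividualEffects]:
    """Extrapolate a subject's trajectory to future ages.

    Personalizes on the past visits only, then evaluates the fitted
    trajectory ``f(theta, z_hat, t)`` at ``future_times``.  Returns the
    (n_future, K) predictions and the fitted effects.
    """
    past_times, future_times = _check_future(past_times, future_times)
    effects = personalize(cmap, past_times, past_values, method=method, **personalize_kwargs)
    return trajectory_eval(cmap, effects, future_times), effects


def constant_prediction(past_times, past_values, future_times) -> np.ndarray:
    """Carry each marker's last observed past value forward unchanged.

    Markers never observed in the past yield NaN in the output.
    """
    past_times, future_times = _check_future(past_times, future_times)
    past_values = np.asarray(past_values, dtype=float).reshape(len(past_times), -1)
    K = past_values.shape[1]
    last = np.full(K, np.nan)
    for k in range(K):
        obs = np.isfinite(past_values[:, k])
        if obs.any():
            last[k] = past_values[np.nonzero(obs)[0][-1], k]
    return np.tile(last, (len(future_times), 1))


def evaluate_predictions(
    predicted,
    truth,
    scale_spans: dict | None = None,
    marker_names: list[str] | None = None,
    baseline=None,
) -> dict:
    """MAE per marker (normalized and raw points) and baseline comparison.

    ``scale_spans`` maps marker name -> raw span (e.g. 30 for the MMSE, 85
    for ADAS-Cog-13).  If ``baseline`` predictions are given, the model and
    baseline absolute-error samples (pooled over markers and visits) are
    compared with a two-sided Mann-Whitney U rank test.
    """
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"predictions {predicted.shape} and truth {truth.shape} are misaligned"
        )
    predicted = np.atleast_2d(predicted)
    truth = np.atleast_2d(truth)
    K = truth.shape[1]
    if marker_names is None:
        marker_names = [f"marker_{k + 1}" for k in range(K)]
    mask = np.isfinite(truth) & np.isfinite(predicted)
    abs_err = np.where(mask, np.abs(predicted - truth), np.nan)
    mae = np.array([np.nanmean(abs_err[:, k]) if mask[:, k].any() else np.nan for k in range(K)])
    out = {
        "mae": dict(zip(marker_names, mae)),
        "mae_pooled": float(np.nanmean(abs_err[mask])),
        "abs_errors": abs_err[mask],
    }
    if scale_spans:
        out["mae_raw"] = {
            name: float(mae[k] * scale_spans[name])
            for k, name in enumerate(marker_names)
            if name in scale_spans
        }
    if baseline is not None:
        baseline = np.atleast_2d(np.asarray(baseline, dtype=float))
        bmask = mask & np.isfinite(baseline)
        b_err = np.abs(baseline - truth)[bmask]
        m_err = np.abs(predicted - truth)[bmask]
        stat, p = mannwhitneyu(m_err, b_err, alternative="two-sided")
        out["baseline_mae_pooled"] = float(np.mean(b_err))
        out["mannwhitney_u"] = float(stat)
        out["mannwhitney_p"] = float(p)
    return out


def select_prediction_cohort(
    visits: pd.DataFrame,
    horizons=(3.0, 4.0),
    window: float = 0.5,
) -> list[tuple]:
    """Index visits eligible for the hide-and-predict protocol.

    A (subject, visit) pair qualifies when, at that visit, the subject
    (1) is labeled MCI, (2) has MMSE <= 27, (3) is amyloid positive, and
    (4) has a monotonic diagnosis history up to the visit (no reversion
    toward normal, no prior AD label) — and at least one follow-up of the
    same subject exists ``h +/- window`` years later for some horizon h.

    ``visits`` needs columns ID, TIME, DX (CN/MCI/AD), MMSE (raw score)
    and AMYLOID (positive/negative/unknown).
    """
    required = {"ID", "TIME", "DX", "MMSE", "AMYLOID"}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"visit table is missing columns: {sorted(missing)}")
    bad = set(visits["DX"].dropna()) - set(DIAGNOSIS_ORDER)
    if bad:
        raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")

    eligible = []
    for sid, grp in visits.groupby("ID", sort=False):
        grp = grp.sort_values("TIME")
        times = grp["TIME"].to_numpy(dtype=float)
        dx = [DIAGNOSIS_ORDER[d] for d in grp["DX"]]
        for j in range(len(grp)):
            row = grp.iloc[j]
            if row["DX"] != "MCI":
                continue
            if not row["MMSE"] <= 27:
                continue
            if row["AMYLOID"] != "positive":
                continue
            hist = dx[: j + 1]
            if any(b < a for a, b in zip(hist, hist[1:])):
                continue  # reversion toward normal
            if any(d == DIAGNOSIS_ORDER["AD"] for d in hist[:-1]):
                continue  # prior AD label before an MCI visit
            gaps = times[j + 1 :] - times[j]
            if any(abs(g - h) <= window for g in gaps for h in horizons):
                eligible.append((sid, float(times[j])))
    return eligible
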