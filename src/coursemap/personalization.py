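"""Positioning subjects in a calibrated course map (MAP estimation of z).

Personalization maximizes the conditional posterior of the individual
effects given a subject's observations and the fixed effects, using
either a derivative-free direction-set (Powell-style) search with
restarts, or a quasi-Newton method with analytic gradients of the
logistic forward map.  The fitted map is never modified.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import mannwhitneyu

from .model import CourseMap, IndividualEffects, LongitudinalDataset, log_posterior, time_warp

__all__ = [
    "personalize",
    "personalize_dataset",
    "alzheimer_age",
    "reconstruction_error",
    "crossval_generalisation",
]


def _prepare_subject(cmap: CourseMap, times, values):
    """Split one subject's observations into interior and censored masks."""
    from .model import BOUNDARY_EPS

    times = np.atleast_1d(np.asarray(times, dtype=float))
    values = np.asarray(values, dtype=float).reshape(len(times), cmap.n_markers)
    observed = np.isfinite(values)
    if not observed.any():
        raise ValueError("personalization requires at least one observed entry")
    lo = observed & (values <= BOUNDARY_EPS)
    hi = observed & (values >= 1.0 - BOUNDARY_EPS)
    interior = observed & ~lo & ~hi
    clipped = np.where(interior, np.clip(values, 1e-4, 1 - 1e-4), values)
    return times, clipped, (interior, lo, hi)


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _neg_log_post_and_grad(z, cmap: CourseMap, times, values, masks):
    """Negative log-posterior of z and its analytic gradient.

    Interior observations are Gaussian; values at the scale bounds are
    censored and contribute ``-log Phi(+/-(bound - f)/sigma)``.
    """
    from scipy.special import log_ndtr

    mask, lo, hi = masks
    tau, xi = z[0], z[1]
    src = z[2:]
    alpha = np.exp(xi)
    p0, v0 = cmap.p0, cmap.v0
    b = v0 / (p0 * (1.0 - p0))
    delays = (cmap.A @ src) / v0
    psi_rel = alpha * (times - cmap.t0 - tau)  # psi - t0
    h = psi_rel[:, None] + delays[None, :]
    f = expit(logit(p0) + b * h)
    r = np.where(mask, f - values, 0.0)
    inv_s2 = 1.0 / cmap.sigma_noise**2
    obj = (
        0.5 * inv_s2 * float(np.sum(r * r))
        + 0.5 * tau**2 / cmap.sigma_tau**2
        + 0.5 * xi**2 / cmap.sigma_xi**2
        + 0.5 * float(src @ src)
    )
    G = r * f * (1.0 - f) * inv_s2  # dL/dq, (J, K)
    if lo.any() or hi.any():
        sig = cmap.sigma_noise
        fp = f * (1.0 - f)
        if lo.any():
            zz = np.where(lo, -f / sig, 0.0)
            obj -= float(np.where(lo, log_ndtr(zz), 0.0).sum())
            hz = np.exp(-0.5 * zz * zz - _LOG_SQRT_2PI - log_ndtr(zz))
            G = G + np.where(lo, hz * fp / sig, 0.0)
        if hi.any():
            zz = np.where(hi, (f - 1.0) / sig, 0.0)
            obj -= float(np.where(hi, log_ndtr(zz), 0.0).sum())
            hz = np.exp(-0.5 * zz * zz - _LOG_SQRT_2PI - log_ndtr(zz))
            G = G - np.where(hi, hz * fp / sig, 0.0)
    g_tau = float(np.sum(G * (-b) * alpha)) + tau / cmap.sigma_tau**2
    g_xi = float(np.sum(G * b * psi_rel[:, None])) + xi / cmap.sigma_xi**2
    g_src = (b / v0 * G.sum(axis=0)) @ cmap.A + src
    return obj, np.concatenate([[g_tau, g_xi], g_src])


def personalize(
    cmap: CourseMap,
    times,
    values,
    method: str = "powell",
    coarse_grid: bool = True,
    xtol: float = 1e-6,
    maxfev: int = 5000,
) -> IndividualEffects:
    """MAP estimate of the individual effects for one subject.

    Parameters
    ----------
    cmap : calibrated course map (read-only).
    times, values : visit ages and (visits, K) observations; NaN = missing.
    method : ``"powell"`` (derivative-free, default) or ``"gradient"``
        (L-BFGS-B with analytic gradients).
    coarse_grid : also restart from the best point of a coarse
        (tau, xi) grid spanning +/- 2 prior stds (guards against the
        optimizer settling in a shallow basin far from the data fit).
    """
    times, values, masks = _prepare_subject(cmap, times, values)
    Ns = cmap.n_sources
    starts = [np.zeros(2 + Ns)]
    if coarse_grid:
        taus = np.linspace(-2 * cmap.sigma_tau, 2 * cmap.sigma_tau, 7)
        xis = np.linspace(-2 * cmap.sigma_xi, 2 * cmap.sigma_xi, 5)
        best, best_val = None, np.inf
        for t_ in taus:
            for x_ in xis:
                z = np.concatenate([[t_, x_], np.zeros(Ns)])
                val, _ = _neg_log_post_and_grad(z, cmap, times, values, masks)
                if val < best_val:
                    best, best_val = z, val
        if np.any(best):
            starts.append(best)

    best_res = None
    for z0 in starts:
        if method == "powell":
            res = minimize(
                lambda z: _neg_log_post_and_grad(z, cmap, times, values, masks)[0],
                z0,
                method="Powell",
                options={"xtol": xtol, "ftol": xtol, "maxfev": maxfev},
            )
        elif method == "gradient":
            res = minimize(
                _neg_log_post_and_grad,
                z0,
                args=(cmap, times, values, masks),
                jac=True,
                method="L-BFGS-B",
                options={"ftol": 1e-12, "gtol": 1e-10, "maxfun": maxfev},
            )
        else:
            raise ValueError(f"unknown method {method!r}; use 'powell' or 'gradient'")
        if best_res is None or res.fun < best_res.fun:
            best_res = res
    z = best_res.x
    return IndividualEffects(tau=float(z[0]), xi=float(z[1]), sources=z[2:])


def personalize_dataset(
    cmap: CourseMap, data: LongitudinalDataset, method: str = "powell", **kwargs
) -> pd.DataFrame:
    """Personalize every subject of a dataset; returns the effects table."""
    rows = []
    for t, y in zip(data.times, data.values):
        eff = personalize(cmap, t, y, method=method, **kwargs)
        rows.append(np.concatenate([[eff.tau, eff.xi], eff.sources]))
    arr = np.asarray(rows)
    cols = {"tau": arr[:, 0], "xi": arr[:, 1]}
    for d in range(cmap.n_sources):
        cols[f"source_{d + 1}"] = arr[:, 2 + d]
    df = pd.DataFrame(cols, index=pd.Index(data.subject_ids, name="ID"))
    df["alpha"] = np.exp(df["xi"])
    return df


def alzheimer_age(cmap: CourseMap, effects: IndividualEffects, t):
    """Latent disease age psi_i(t): the subject's stage on the normative timeline."""
    return time_warp(cmap, effects, t)


def reconstruction_error(cmap: CourseMap, effects: IndividualEffects, times, values) -> dict:
    """Signed residuals y - f(theta, z, t) on observed entries plus summaries.

    Returns a dict with ``residuals`` (visits x K, NaN where missing),
    per-marker ``mae`` and ``std``, and pooled ``mae``/``std``.
    """
    times, values, masks = _prepare_subject(cmap, times, values)
    from .model import trajectory_eval

    mask = masks[0] if masks[0].any() else (masks[0] | masks[1] | masks[2])
    f = trajectory_eval(cmap, effects, times)
    resid = np.where(mask, values - f, np.nan)
    flat = resid[mask]
    with np.errstate(invalid="ignore"):
        per_mae = np.array(
            [np.nanmean(np.abs(resid[:, k])) if mask[:, k].any() else np.nan for k in range(cmap.n_markers)]
        )
        per_std = np.array(
            [np.nanstd(resid[:, k]) if mask[:, k].any() else np.nan for k in range(cmap.n_markers)]
        )
    return {
        "residuals": resid,
        "mae_per_marker": per_mae,
        "std_per_marker": per_std,
        "mae": float(np.mean(np.abs(flat))),
        "std": float(np.std(flat)),
        "n_observed": int(mask.sum()),
    }


def _pooled_residuals(cmap: CourseMap, data: LongitudinalDataset, effects: pd.DataFrame) -> np.ndarray:
    out = []
    for sid, t, y in zip(data.subject_ids, data.times, data.values):
        row = effects.loc[sid]
        eff = IndividualEffects(
            tau=float(row["tau"]),
            xi=float(row["xi"]),
            sources=row[[c for c in effects.columns if c.startswith("source_")]].to_numpy(dtype=float),
        )
        res = reconstruction_error(cmap, eff, t, y)
        out.append(res["residuals"][np.isfinite(res["residuals"])])
    return np.concatenate(out)


def crossval_generalisation(
    data: LongitudinalDataset,
    config=None,
    n_folds: int = 5,
    seed: int = 0,
    method: str = "powell",
) -> dict:
    """K-fold generalisation protocol: calibrate on ~(k-1)/k of the subjects,
    position the held-out subjects on the fitted map.

    Returns per-fold fixed effects, pooled reconstruction residuals (train
    subjects, from calibration) and generalisation residuals (held-out
    subjects, from personalization), a rank-test comparison of the two
    absolute-residual samples, and the per-subject agreement (r^2) between
    effects estimated as a train member and as a test member.
    """
    from .calibration import SAEMConfig, calibrate

    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if data.n_subjects < n_folds:
        raise ValueError("need at least one subject per fold")
    if config is None:
        config = SAEMConfig()

    rng = np.random.default_rng(seed)
    order = rng.permutation(data.n_subjects)
    folds = [np.sort(order[i::n_folds]) for i in range(n_folds)]

    recon_resid, gen_resid = [], []
    fold_maps, fold_records = [], []
    train_effects: dict = {}
    test_effects: dict = {}
    from dataclasses import replace as dc_replace

    for f, test_idx in enumerate(folds):
        train_idx = np.sort(np.setdiff1d(np.arange(data.n_subjects), test_idx))
        train, test = data.subset(train_idx), data.subset(test_idx)
        fold_config = dc_replace(config, seed=config.seed + f)
        cmap, _, _ = calibrate(train, fold_config)
        fold_maps.append(cmap)
        # reconstruction = MAP personalization of the training subjects, so
        # the comparison with the held-out subjects is like for like
        eff_train = personalize_dataset(cmap, train, method=method)
        recon_resid.append(_pooled_residuals(cmap, train, eff_train))
        eff_test = personalize_dataset(cmap, test, method=method)
        gen_resid.append(_pooled_residuals(cmap, test, eff_test))
        # each fold's map carries its own time gauge (reference-point slide);
        # align fold estimates on their cohort-wide mean before comparing
        # train-time with test-time effects
        gauge = pd.concat([eff_train[["tau", "xi"]], eff_test[["tau", "xi"]]]).mean()
        for sid in train.subject_ids:
            train_effects.setdefault(sid, []).append(
                (eff_train.loc[sid, ["tau", "xi"]] - gauge).to_numpy(dtype=float)
            )
        for sid in test.subject_ids:
            test_effects[sid] = (eff_test.loc[sid, ["tau", "xi"]] - gauge).to_numpy(dtype=float)
        fold_records.append(
            {
                "fold": f,
                "t0": cmap.t0,
                "p0": cmap.p0.copy(),
                "v0": cmap.v0.copy(),
                "sigma_noise": cmap.sigma_noise,
                "sigma_tau": cmap.sigma_tau,
                "sigma_xi": cmap.sigma_xi,
                "test_subjects": [data.subject_ids[i] for i in test_idx],
            }
        )

    recon = np.concatenate(recon_resid)
    gen = np.concatenate(gen_resid)
    stat, pval = mannwhitneyu(np.abs(recon), np.abs(gen), alternative="two-sided")

    # train-vs-test agreement per subject (paper-style r^2 check)
    ids = sorted(test_effects, key=str)
    tr = np.array([np.mean(train_effects[sid], axis=0) for sid in ids])
    te = np.array([test_effects[sid] for sid in ids])
    r2 = {}
    for j, name in enumerate(("tau", "xi")):
        ss_res = np.sum((tr[:, j] - te[:, j]) ** 2)
        ss_tot = np.sum((te[:, j] - te[:, j].mean()) ** 2)
        r2[name] = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else np.nan

    return {
        "folds": fold_records,
        "fold_maps": fold_maps,
        "reconstruction_residuals": recon,
        "generalisation_residuals": gen,
        "rank_test_stat": float(stat),
        "rank_test_p": float(pval),
        "train_test_r2": r2,
    }
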