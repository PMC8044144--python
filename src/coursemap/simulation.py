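"""Simulation of virtual patient cohorts.

The empirical posterior distribution of the individual effects
(tau, xi, sources) is fitted — optionally per stratum, e.g. men and
women separately — by standardizing, projecting onto principal axes
retaining at least 95% of the variance, and placing a Gaussian kernel
density (Scott bandwidth) in the reduced space.  Virtual subjects draw
effects from this density, a visit schedule (matched to a template
cohort or user-specified), and observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .model import CourseMap, LongitudinalDataset, metric_weights, trajectory_eval, IndividualEffects

__all__ = ["EffectsSampler", "VirtualCohort", "fit_effects_density", "simulate_cohort"]

_EFFECT_COLS_EXCLUDE = ("alpha",)


@dataclass
class VirtualCohort:
    """A simulated longitudinal dataset together with its generating truth."""

    data: LongitudinalDataset
    effects: pd.DataFrame
    strata: pd.Series | None = None


class _StratumKDE:
    def __init__(self, X: np.ndarray, var_retained: float, bw_method):
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0, ddof=1)
        self.std_[self.std_ == 0] = 1.0
        Z = (X - self.mean_) / self.std_
        # principal axes retaining >= var_retained of the variance
        cov = np.cov(Z, rowvar=False)
        evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        frac = np.cumsum(evals) / evals.sum()
        d = int(np.searchsorted(frac, var_retained) + 1)
        self.components_ = evecs[:, :d]
        self.explained_variance_ratio_ = evals[:d] / evals.sum()
        proj = Z @ self.components_
        self.kde_ = gaussian_kde(proj.T, bw_method=bw_method)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        draws = self.kde_.resample(n, seed=rng).T
        # smoothed-bootstrap variance correction: kernel smoothing inflates
        # the sample covariance by (1 + h^2), shrink back toward the mean
        center = self.kde_.dataset.mean(axis=1)
        draws = center + (draws - center) / np.sqrt(1.0 + self.kde_.factor**2)
        Z = draws @ self.components_.T
        return Z * self.std_ + self.mean_


class EffectsSampler:
    """Stratified KDE sampler over individual-effect vectors."""

    def __init__(self, strata: dict[object, _StratumKDE], columns: list[str], weights: dict):
        self.strata = strata
        self.columns = columns
        self.weights = weights

    def sample(self, n: int, rng: np.random.Generator, stratum=None) -> pd.DataFrame:
        """Draw n effect vectors; strata are drawn by their empirical weights
        unless a single ``stratum`` is requested."""
        if stratum is not None:
            X = self.strata[stratum].sample(n, rng)
            labels = [stratum] * n
        else:
            keys = list(self.strata)
            w = np.array([self.weights[k] for k in keys], dtype=float)
            counts = rng.multinomial(n, w / w.sum())
            parts, labels = [], []
            for key, c in zip(keys, counts):
                if c:
                    parts.append(self.strata[key].sample(c, rng))
                    labels.extend([key] * c)
            X = np.vstack(parts)
        df = pd.DataFrame(X, columns=self.columns)
        df["stratum"] = labels
        return df


def fit_effects_density(
    effects: pd.DataFrame,
    stratify_by: pd.Series | None = None,
    min_stratum: int = 10,
    var_retained: float = 0.95,
    bw_method="scott",
    cmap: CourseMap | None = None,
) -> EffectsSampler:
    """Fit the empirical distribution of individual effects for resampling.

    Effects are standardized, reduced to principal axes keeping at least
    ``var_retained`` of the variance, and modelled with a Gaussian KDE
    (Scott's rule by default).  With ``stratify_by`` (a subject-indexed
    series, e.g. sex) an independent density is fitted per stratum.
    Sampled sources parameterize the space-shift subspace directly, so
    ``w = A s`` keeps its metric-orthogonality; when ``cmap`` is given this
    is additionally re-enforced by projection at sampling time.
    """
    cols = [c for c in effects.columns if c not in _EFFECT_COLS_EXCLUDE]
    X = effects[cols].to_numpy(dtype=float)
    if stratify_by is None:
        groups = {"all": np.arange(len(effects))}
        weights = {"all": 1.0}
    else:
        stratify_by = stratify_by.reindex(effects.index)
        groups = {
            key: np.flatnonzero((stratify_by == key).to_numpy())
            for key in pd.unique(stratify_by.dropna())
        }
        weights = {key: len(idx) / len(effects) for key, idx in groups.items()}
    strata = {}
    for key, idx in groups.items():
        if len(idx) < min_stratum:
            raise ValueError(
                f"stratum {key!r} has only {len(idx)} subjects; at least "
                f"{min_stratum} are required for density estimation"
            )
        strata[key] = _StratumKDE(X[idx], var_retained, bw_method)
    sampler = EffectsSampler(strata, cols, weights)
    sampler.cmap = cmap
    return sampler


def _project_sources(cmap: CourseMap, src: np.ndarray) -> np.ndarray:
    """Re-enforce metric-orthogonality of w = A s by projecting through A."""
    w = src @ cmap.A.T
    u = metric_weights(cmap.p0) * cmap.v0
    u = u / np.linalg.norm(u)
    # remove any numerical component along the metric-weighted velocity
    w = w - np.outer((w @ u), u)
    return w @ cmap.A


def _template_schedules(template: LongitudinalDataset):
    return [(t[0], np.diff(t)) for t in template.times]


def simulate_cohort(
    cmap: CourseMap,
    sampler: EffectsSampler,
    n_subjects: int,
    schedule,
    seed: int = 0,
    noise_std: float | None = None,
    id_prefix: str = "sim",
) -> VirtualCohort:
    """Simulate a cohort of virtual patients.

    Each virtual subject draws effects from ``sampler``, a visit schedule,
    and i.i.d. Gaussian observation noise (the calibrated ``sigma_noise``
    unless overridden); values are clipped to [0, 1].  The generating
    effects are retained as ground truth.  Deterministic given ``seed``.

    ``schedule`` is either a template :class:`LongitudinalDataset` (visit
    counts, baseline ages and inter-visit gaps are bootstrap-resampled
    from its subjects) or a dict with keys ``n_visits``, ``interval`` and
    ``baseline_age`` (scalar or (low, high) ranges).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    rng = np.random.default_rng(seed)
    if noise_std is None:
        noise_std = cmap.sigma_noise

    if isinstance(schedule, LongitudinalDataset):
        pool = _template_schedules(schedule)
        picks = rng.integers(0, len(pool), size=n_subjects)
        schedules = [pool[i] for i in picks]
    elif isinstance(schedule, dict):
        if not schedule:
            raise ValueError("empty schedule specification")

        def _draw(spec, size=None):
            if np.isscalar(spec):
                return spec if size is None else np.full(size, float(spec))
            lo, hi = spec
            return rng.uniform(lo, hi, size=size)

        schedules = []
        for _ in range(n_subjects):
            nv = schedule.get("n_visits", 5)
            nv = int(nv) if np.isscalar(nv) else int(rng.integers(nv[0], nv[1] + 1))
            base = float(_draw(schedule.get("baseline_age", cmap.t0 - 5.0)))
            gaps = _draw(schedule.get("interval", 1.0), size=max(nv - 1, 0))
            schedules.append((base, np.asarray(gaps, dtype=float)))
    else:
        raise TypeError("schedule must be a LongitudinalDataset template or a dict")

    draws = sampler.sample(n_subjects, rng)
    src_cols = [c for c in draws.columns if c.startswith("source_")]
    src = draws[src_cols].to_numpy(dtype=float)
    if src_cols:
        src = _project_sources(cmap, src)
        draws[src_cols] = src

    ids, times, values = [], [], []
    for i in range(n_subjects):
        base, gaps = schedules[i]
        t = base + np.concatenate([[0.0], np.cumsum(gaps)])
        eff = IndividualEffects(
            tau=float(draws.iloc[i]["tau"]),
            xi=float(draws.iloc[i]["xi"]),
            sources=src[i] if src_cols else np.zeros(cmap.n_sources),
        )
        f = trajectory_eval(cmap, eff, t)
        y = np.clip(f + noise_std * rng.standard_normal(f.shape), 0.0, 1.0)
        ids.append(f"{id_prefix}_{i + 1:05d}")
        times.append(t)
        values.append(y)

    data = LongitudinalDataset(ids, times, values, cmap.marker_names)
    effects = draws.drop(columns=["stratum"]).copy()
    effects.index = pd.Index(ids, name="ID")
    effects["alpha"] = np.exp(effects["xi"])
    strata = pd.Series(draws["stratum"].to_numpy(), index=effects.index, name="stratum")
    return VirtualCohort(data=data, effects=effects, strata=strata)
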