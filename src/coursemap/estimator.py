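"""Scikit-learn style front end for disease course mapping.

:class:`DiseaseCourseMapper` wraps calibration (``fit``), personalization
(``transform``) and trajectory reconstruction behind the estimator API so
the model composes with sklearn pipelines and model selection.  Input is
a long-format DataFrame (``ID``, ``TIME``, one column per marker) or a
:class:`~coursemap.model.LongitudinalDataset`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .calibration import SAEMConfig, calibrate
from .model import IndividualEffects, LongitudinalDataset, trajectory_eval
from .personalization import personalize_dataset

__all__ = ["DiseaseCourseMapper"]


def _as_dataset(X) -> LongitudinalDataset:
    if isinstance(X, LongitudinalDataset):
        return X
    if isinstance(X, pd.DataFrame):
        return LongitudinalDataset.from_dataframe(X)
    raise TypeError(
        "X must be a long-format DataFrame (ID, TIME, markers) or a "
        f"LongitudinalDataset, got {type(X).__name__}"
    )


class DiseaseCourseMapper(BaseEstimator, TransformerMixin):
    """Nonlinear mixed-effects disease course map.

    ``fit`` calibrates the population model (MCMC-SAEM); ``transform``
    positions subjects on the fitted map, returning one row of individual
    effects (tau, xi, sources, alpha) per subject.

    Parameters
    ----------
    n_sources : dimension of the space-shift subspace (default: K - 1).
    n_iter, n_burn_in : SAEM iteration schedule.
    step_exponent : decay power of the stochastic-approximation steps.
    target_acceptance : Metropolis-Hastings adaptation target.
    personalize_method : ``"powell"`` or ``"gradient"``.
    random_state : seed for the whole stochastic fit.

    Attributes
    ----------
    map_ : fitted :class:`~coursemap.model.CourseMap`.
    effects_ : per-subject effects estimated during calibration.
    trace_ : full SAEM iteration trace.
    marker_names_ : marker labels seen during fit.
    """

    def __init__(
        self,
        n_sources: int | None = None,
        n_iter: int = 5000,
        n_burn_in: int = 1000,
        step_exponent: float = 0.65,
        target_acceptance: float = 0.3,
        personalize_method: str = "powell",
        random_state: int = 0,
    ):
        self.n_sources = n_sources
        self.n_iter = n_iter
        self.n_burn_in = n_burn_in
        self.step_exponent = step_exponent
        self.target_acceptance = target_acceptance
        self.personalize_method = personalize_method
        self.random_state = random_state

    def _config(self) -> SAEMConfig:
        return SAEMConfig(
            n_iter=self.n_iter,
            n_burn_in=self.n_burn_in,
            step_exponent=self.step_exponent,
            target_acceptance=self.target_acceptance,
            seed=self.random_state,
            n_sources=self.n_sources,
        )

    def fit(self, X, y=None):
        data = _as_dataset(X)
        self.map_, self.effects_, self.trace_ = calibrate(data, self._config())
        self.marker_names_ = list(self.map_.marker_names)
        self.n_features_in_ = self.map_.n_markers
        return self

    def transform(self, X) -> pd.DataFrame:
        """MAP-personalize each subject of X on the fitted map."""
        check_is_fitted(self, "map_")
        data = _as_dataset(X)
        if data.marker_names != self.marker_names_:
            raise ValueError(
                f"marker mismatch: fitted on {self.marker_names_}, got {data.marker_names}"
            )
        return personalize_dataset(self.map_, data, method=self.personalize_method)

    def reconstruct(self, X, effects: pd.DataFrame | None = None) -> pd.DataFrame:
        """Fitted values f(theta, z_hat, t) for every visit of X."""
        check_is_fitted(self, "map_")
        data = _as_dataset(X)
        if effects is None:
            effects = self.transform(data)
        src_cols = [c for c in effects.columns if c.startswith("source_")]
        rows = []
        for sid, t, _ in zip(data.subject_ids, data.times, data.values):
            r = effects.loc[sid]
            eff = IndividualEffects(
                tau=float(r["tau"]), xi=float(r["xi"]), sources=r[src_cols].to_numpy(dtype=float)
            )
            f = trajectory_eval(self.map_, eff, t)
            for j, tj in enumerate(t):
                rows.append([sid, tj, *f[j]])
        return pd.DataFrame(rows, columns=["ID", "TIME", *self.marker_names_])

    def score(self, X, y=None) -> float:
        """Negative mean squared reconstruction error over observed entries."""
        check_is_fitted(self, "map_")
        data = _as_dataset(X)
        recon = self.reconstruct(data)
        sq, n = 0.0, 0
        for sid, t, yv in zip(data.subject_ids, data.times, data.values):
            f = recon[recon["ID"] == sid].sort_values("TIME")[self.marker_names_].to_numpy()
            mask = np.isfinite(yv)
            sq += float(np.sum((yv[mask] - f[mask]) ** 2))
            n += int(mask.sum())
        return -sq / n
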