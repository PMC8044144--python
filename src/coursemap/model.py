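"""Core domain types and the deterministic forward model.

The normative disease progression is a geodesic of the open unit cube
endowed, per coordinate, with the metric ``g(p) = 1 / (p (1 - p))^2``.
Geodesics of this metric are exactly the logistic curves, so the
population trajectory is a bank of coupled logistics

    gamma0_k(t) = sigmoid( logit(p0_k) + v0_k (t - t0) / (p0_k (1 - p0_k)) )

parameterised by an initial point ``p0``, velocity ``v0`` and reference
time ``t0``.  A subject deviates from the normative scenario through

* a time-shift ``tau`` (years) and log-acceleration ``xi`` entering the
  affine time-warp ``psi(t) = exp(xi) (t - t0 - tau) + t0`` that maps
  chronological age to the latent disease age,
* a space-shift ``w = A s`` orthogonal (in the metric above) to the
  geodesic velocity, realised on this product manifold as per-marker
  time-delays ``w_k / v0_k`` (exp-parallelisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "CourseMap",
    "IndividualEffects",
    "LongitudinalDataset",
    "metric_weights",
    "build_mixing_matrix",
    "geodesic_eval",
    "time_warp",
    "exp_parallel",
    "trajectory_eval",
    "log_posterior",
]

_ORTHO_TOL = 1e-8

#: observed values within this distance of 0 or 1 are treated as censored
#: (bounded scores pile up at the scale ends; their residuals are not
#: Gaussian) and excluded from likelihood computations
BOUNDARY_EPS = 1e-4


def metric_weights(p0: np.ndarray) -> np.ndarray:
    """Metric coefficients ``g(p) = 1/(p(1-p))^2`` at the reference point."""
    p0 = np.asarray(p0, dtype=float)
    return 1.0 / (p0 * (1.0 - p0)) ** 2


def build_mixing_matrix(p0: np.ndarray, v0: np.ndarray, n_sources: int) -> np.ndarray:
    """Orthonormal basis of an ``n_sources``-dim subspace of the space-shift hyperplane.

    Space-shifts must satisfy ``sum_k g_k(p0_k) v0_k w_k = 0`` so that their
    effect does not overlap with the time-shift; with K markers only K-1
    independent inter-marker spacings exist.  The construction is
    deterministic given ``(p0, v0, n_sources)``: a Householder QR of the
    metric-weighted velocity, keeping the orthogonal-complement columns.

    Parameters
    ----------
    p0, v0 : (K,) arrays of baseline positions and velocities.
    n_sources : dimension of the space-shift subspace, ``1 <= Ns <= K-1``.

    Returns
    -------
    (K, n_sources) matrix with Euclidean-orthonormal columns, each
    metric-orthogonal to ``v0`` at ``p0``.
    """
    p0 = np.asarray(p0, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    K = p0.shape[0]
    if not 1 <= n_sources <= K - 1:
        raise ValueError(
            f"n_sources must satisfy 1 <= Ns <= K-1 = {K - 1} "
            f"(only K-1 independent inter-marker spacings); got {n_sources}"
        )
    u = (metric_weights(p0) * v0).reshape(-1, 1)
    q, _ = np.linalg.qr(u, mode="complete")
    basis = q[:, 1:]  # orthogonal complement of u
    # deterministic sign convention: largest-|.| entry of each column positive
    idx = np.argmax(np.abs(basis), axis=0)
    signs = np.sign(basis[idx, np.arange(basis.shape[1])])
    basis = basis * signs
    return np.ascontiguousarray(basis[:, :n_sources])


@dataclass
class CourseMap:
    """Population-level disease course map (the fixed effects ``theta``).

    Attributes
    ----------
    t0 : reference time in years (latent-age origin).
    p0 : (K,) baseline positions, each strictly inside (0, 1).
    v0 : (K,) baseline velocities per year, all nonzero.
    sigma_noise : observation noise std on the normalized score scale.
    sigma_tau : std of the time-shift random effect (years).
    sigma_xi : std of the log-acceleration random effect.
    A : (K, Ns) mixing matrix; columns span the space-shift subspace.
    marker_names : K marker labels.
    """

    t0: float
    p0: np.ndarray
    v0: np.ndarray
    sigma_noise: float
    sigma_tau: float
    sigma_xi: float
    A: np.ndarray | None = None
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.p0 = np.atleast_1d(np.asarray(self.p0, dtype=float))
        self.v0 = np.atleast_1d(np.asarray(self.v0, dtype=float))
        if self.p0.shape != self.v0.shape:
            raise ValueError("p0 and v0 must have the same length")
        if not np.all((self.p0 > 0) & (self.p0 < 1)):
            raise ValueError("all components of p0 must lie strictly in (0, 1)")
        if np.any(self.v0 == 0):
            raise ValueError("all components of v0 must be nonzero")
        for name in ("sigma_noise", "sigma_tau", "sigma_xi"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.A is None:
            self.A = build_mixing_matrix(self.p0, self.v0, self.n_markers - 1)
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if self.A.shape[0] != self.n_markers:
            raise ValueError("A must have one row per marker")
        if self.A.shape[1] > self.n_markers - 1:
            raise ValueError(
                "A has more columns than K-1: only K-1 independent "
                "inter-marker spacings exist"
            )
        u = metric_weights(self.p0) * self.v0
        resid = np.abs(self.A.T @ u) / max(np.linalg.norm(u), 1.0)
        if np.any(resid > _ORTHO_TOL):
            raise ValueError(
                "columns of A must be metric-orthogonal to the geodesic "
                f"velocity (max residual {resid.max():.3e})"
            )
        if not self.marker_names:
            self.marker_names = [f"marker_{k + 1}" for k in range(self.n_markers)]
        if len(self.marker_names) != self.n_markers:
            raise ValueError("marker_names must have one entry per marker")

    @property
    def n_markers(self) -> int:
        return self.p0.shape[0]

    @property
    def n_sources(self) -> int:
        return self.A.shape[1]

    def copy(self) -> "CourseMap":
        return replace(
            self,
            p0=self.p0.copy(),
            v0=self.v0.copy(),
            A=self.A.copy(),
            marker_names=list(self.marker_names),
        )


@dataclass
class IndividualEffects:
    """Subject-level random effects ``z = (tau, xi, sources)``.

    ``alpha = exp(xi)`` is the acceleration factor (always positive) and
    ``w = A @ sources`` the space-shift (per-marker spacing), inheriting
    metric-orthogonality from the columns of A.
    """

    tau: float
    xi: float
    sources: np.ndarray

    def __post_init__(self) -> None:
        self.sources = np.atleast_1d(np.asarray(self.sources, dtype=float))

    @property
    def alpha(self) -> float:
        return float(np.exp(self.xi))

    def space_shift(self, cmap: CourseMap) -> np.ndarray:
        return cmap.A @ self.sources

    def as_vector(self) -> np.ndarray:
        return np.concatenate([[self.tau, self.xi], self.sources])

    @classmethod
    def from_vector(cls, z: np.ndarray) -> "IndividualEffects":
        z = np.asarray(z, dtype=float)
        return cls(tau=float(z[0]), xi=float(z[1]), sources=z[2:])

    @classmethod
    def null(cls, n_sources: int) -> "IndividualEffects":
        return cls(tau=0.0, xi=0.0, sources=np.zeros(n_sources))


class LongitudinalDataset:
    """Subject-indexed longitudinal observations with a missingness mask.

    Stores, per subject, strictly increasing visit ages (years) and a
    (visits, K) matrix of normalized biomarker values in [0, 1]; NaN marks
    a missing entry.  Also exposes dense padded arrays for vectorized use.
    """

    def __init__(
        self,
        subject_ids: list,
        times: list[np.ndarray],
        values: list[np.ndarray],
        marker_names: list[str],
    ):
        if not (len(subject_ids) == len(times) == len(values)):
            raise ValueError("subject_ids, times and values must be aligned")
        self.subject_ids = list(subject_ids)
        self.marker_names = list(marker_names)
        K = len(self.marker_names)
        self.times: list[np.ndarray] = []
        self.values: list[np.ndarray] = []
        for sid, t, y in zip(subject_ids, times, values):
            t = np.asarray(t, dtype=float).ravel()
            y = np.asarray(y, dtype=float).reshape(len(t), K)
            if not np.all(np.isfinite(t)):
                raise ValueError(f"subject {sid!r}: non-finite visit time")
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"subject {sid!r}: visit times must be strictly increasing")
            obs = y[np.isfinite(y)]
            if obs.size and (obs.min() < 0 or obs.max() > 1):
                raise ValueError(f"subject {sid!r}: observed values must lie in [0, 1]")
            self.times.append(t)
            self.values.append(y)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def n_visits(self) -> np.ndarray:
        return np.array([len(t) for t in self.times])

    @property
    def n_observations(self) -> int:
        return int(sum(np.isfinite(y).sum() for y in self.values))

    def subject(self, sid) -> tuple[np.ndarray, np.ndarray]:
        i = self.subject_ids.index(sid)
        return self.times[i], self.values[i]

    def padded(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense (N, Jmax) times, (N, Jmax, K) values, boolean observed mask.

        Padding slots carry the subject's first visit time and a False mask.
        """
        N, K = self.n_subjects, self.n_markers
        Jmax = int(self.n_visits.max())
        T = np.zeros((N, Jmax))
        Y = np.zeros((N, Jmax, K))
        M = np.zeros((N, Jmax, K), dtype=bool)
        for i, (t, y) in enumerate(zip(self.times, self.values)):
            j = len(t)
            T[i, :j] = t
            T[i, j:] = t[0]
            obs = np.isfinite(y)
            Y[i, :j][obs] = y[obs]
            M[i, :j] = obs
        return T, Y, M

    def subset(self, indices) -> "LongitudinalDataset":
        return LongitudinalDataset(
            [self.subject_ids[i] for i in indices],
            [self.times[i] for i in indices],
            [self.values[i] for i in indices],
            self.marker_names,
        )

    def require_calibratable(self) -> None:
        """Calibration needs >= 2 visits per subject and >= 2 markers."""
        if self.n_markers < 2:
            raise ValueError("calibration requires at least 2 markers")
        for sid, t in zip(self.subject_ids, self.times):
            if len(t) < 2:
                raise ValueError(
                    f"subject {sid!r} has fewer than 2 visits; calibration "
                    "requires at least two time-points per subject"
                )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for sid, t, y in zip(self.subject_ids, self.times, self.values):
            for j, tj in enumerate(t):
                rows.append([sid, tj, *y[j]])
        return pd.DataFrame(rows, columns=["ID", "TIME", *self.marker_names])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LongitudinalDataset":
        if "ID" not in df.columns or "TIME" not in df.columns:
            raise ValueError("long-format table must have ID and TIME columns")
        markers = [c for c in df.columns if c not in ("ID", "TIME")]
        dup = df.duplicated(subset=["ID", "TIME"])
        if dup.any():
            r = df[dup].iloc[0]
            raise ValueError(f"duplicate visit for ID={r['ID']!r} at TIME={r['TIME']}")
        ids, times, values = [], [], []
        for sid, grp in df.groupby("ID", sort=False):
            grp = grp.sort_values("TIME")
            ids.append(sid)
            times.append(grp["TIME"].to_numpy(dtype=float))
            values.append(grp[markers].to_numpy(dtype=float))
        return cls(ids, times, values, markers)


# ---------------------------------------------------------------------------
# forward model


def _check_finite_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("evaluation time must be finite")
    return t


def geodesic_eval(cmap: CourseMap, t) -> np.ndarray:
    """Normative trajectory ``gamma0(t)``, one logistic per marker.

    ``gamma0(t0) = p0`` and ``d gamma0/dt (t0) = v0``; each component is
    strictly monotone in t with the sign of ``v0_k``.  ``t`` may be scalar
    or an array; the marker axis is appended last.
    """
    t = _check_finite_time(t)
    slope = cmap.v0 / (cmap.p0 * (1.0 - cmap.p0))
    dt = np.asarray(t)[..., None] - cmap.t0
    return expit(logit(cmap.p0) + slope * dt)


def time_warp(cmap: CourseMap, effects: IndividualEffects, t) -> np.ndarray | float:
    """Latent disease age ``psi(t) = alpha (t - t0 - tau) + t0``."""
    t = np.asarray(t, dtype=float)
    out = effects.alpha * (t - cmap.t0 - effects.tau) + cmap.t0
    return float(out) if out.ndim == 0 else out


def exp_parallel(cmap: CourseMap, w: np.ndarray, t) -> np.ndarray:
    """Exp-parallelisation ``eta^w[gamma0](t)`` of the normative curve.

    On this product of 1D logistic manifolds, parallel-transporting ``w``
    along the geodesic and applying the exponential map reduces exactly to
    a per-marker time-delay: component k is ``gamma0_k(t + w_k / v0_k)``.
    """
    if np.any(cmap.v0 == 0):
        raise ValueError("exp-parallel time-delays are undefined for v0_k = 0")
    t = _check_finite_time(t)
    w = np.asarray(w, dtype=float)
    delays = w / cmap.v0
    slope = cmap.v0 / (cmap.p0 * (1.0 - cmap.p0))
    dt = np.asarray(t)[..., None] + delays - cmap.t0
    return expit(logit(cmap.p0) + slope * dt)


def trajectory_eval(cmap: CourseMap, effects: IndividualEffects, t) -> np.ndarray:
    """Subject trajectory ``f(theta, z, t) = eta^w[gamma0](psi(t))`` (noiseless)."""
    return exp_parallel(cmap, effects.space_shift(cmap), time_warp(cmap, effects, t))


def log_posterior(
    cmap: CourseMap,
    effects: IndividualEffects,
    times,
    values,
) -> float:
    """Unnormalized log-posterior of ``z`` given one subject's observations.

    ``sum_obs -(y - f)^2 / (2 sigma^2) - tau^2/(2 sigma_tau^2)
    - xi^2/(2 sigma_xi^2) - ||s||^2 / 2``; missing (NaN) entries contribute
    nothing.  Normalizing constants are dropped (they do not involve z).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    values = np.asarray(values, dtype=float).reshape(len(times), cmap.n_markers)
    mask = np.isfinite(values)
    if not mask.any():
        raise ValueError("log_posterior requires at least one observed entry")
    f = trajectory_eval(cmap, effects, times)
    resid = np.where(mask, values - f, 0.0)
    data_term = -0.5 * np.sum(resid**2) / cmap.sigma_noise**2
    prior = (
        -0.5 * effects.tau**2 / cmap.sigma_tau**2
        - 0.5 * effects.xi**2 / cmap.sigma_xi**2
        - 0.5 * float(effects.sources @ effects.sources)
    )
    return float(data_term + prior)
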