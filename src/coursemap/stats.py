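"""Downstream cohort statistics.

Covariate associations of the individual parameters (joint multivariate
linear regression per effect, two-tailed t-tests, Benjamini-Hochberg FDR),
a conditional-correlation graph across parameters (Gaussian graphical
model via ridge-regularized partial correlations), amyloid-status
classification from PET/CSF measurements, and test/retest measurement-
noise estimation on the percent scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CovariateTable",
    "amyloid_status",
    "benjamini_hochberg",
    "associate",
    "conditional_correlation_graph",
    "estimate_measurement_noise",
    "noise_percent",
]

# amyloid-positivity thresholds: AV45 SUVR (cerebellum-normalised), PiB SUVR,
# CSF A-beta-42 concentration in pg/mL
AV45_SUVR_THRESHOLD = 1.1
PIB_SUVR_THRESHOLD = 1.47
CSF_ABETA42_THRESHOLD = 1098.0

_CATEGORICALS = {
    "sex": None,
    "apoe4_carrier": None,
    "amyloid_status": {"positive", "negative", "unknown"},
    "marital": {"married", "non-married"},
}


class CovariateTable:
    """Per-subject covariates: sex, APOE-e4 carriership, amyloid status,
    marital status (married vs non-married) and education years."""

    COLUMNS = ["sex", "apoe4_carrier", "amyloid_status", "marital", "education_years"]

    def __init__(self, df: pd.DataFrame):
        if df.index.duplicated().any():
            raise ValueError("one row per subject required")
        for col, allowed in _CATEGORICALS.items():
            if col in df.columns and allowed is not None:
                bad = set(df[col].dropna()) - allowed
                if bad:
                    raise ValueError(f"{col}: unknown categories {sorted(bad)}")
        if "education_years" in df.columns and (df["education_years"].dropna() < 0).any():
            raise ValueError("education_years must be non-negative")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


def _as_array(x):
    if x is None:
        return np.array([])
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    return arr[np.isfinite(arr)]


def amyloid_status(av45_suvr=None, pib_suvr=None, csf_abeta42=None) -> str:
    """Classify amyloid status from any available measurements (any visit).

    Positive if AV45 SUVR > 1.1, or PiB SUVR > 1.47, or CSF A-beta-42
    < 1098 pg/mL at any provided visit; unknown if no measurement of any
    kind is available; negative otherwise.
    """
    av45, pib, csf = _as_array(av45_suvr), _as_array(pib_suvr), _as_array(csf_abeta42)
    for name, arr in (("av45_suvr", av45), ("pib_suvr", pib), ("csf_abeta42", csf)):
        if np.any(arr < 0):
            raise ValueError(f"{name}: negative measurement")
    if av45.size == 0 and pib.size == 0 and csf.size == 0:
        return "unknown"
    if (
        np.any(av45 > AV45_SUVR_THRESHOLD)
        or np.any(pib > PIB_SUVR_THRESHOLD)
        or np.any(csf < CSF_ABETA42_THRESHOLD)
    ):
        return "positive"
    return "negative"


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR-adjusted p-values (Benjamini-Hochberg)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _design_matrix(cov: pd.DataFrame) -> pd.DataFrame:
    """Numeric coding of the covariates; binary contrasts follow the
    reporting conventions female-vs-male, carrier-vs-non-carrier,
    positive-vs-negative, married-vs-non-married."""
    X = pd.DataFrame(index=cov.index)
    for col in cov.columns:
        s = cov[col]
        if s.dtype.kind in "ifb" and col != "apoe4_carrier":
            X[col] = s.astype(float)
        elif col == "sex":
            X[col] = (s == "female").astype(float) if s.dtype == object else s.astype(float)
        elif col == "apoe4_carrier":
            X[col] = s.astype(float) if s.dtype.kind in "ifb" else (s == "carrier").astype(float)
        elif col == "amyloid_status":
            X[col] = (s == "positive").astype(float)
        elif col == "marital":
            X[col] = (s == "married").astype(float)
        else:
            raise ValueError(f"cannot encode covariate {col!r}")
    return X


def associate(
    effects: pd.DataFrame,
    covariates: pd.DataFrame,
    which_effects: list[str] | None = None,
    alpha: float = 0.05,
    discriminating_covariate: str | None = None,
) -> pd.DataFrame:
    """Associations between individual parameters and cofactors.

    For every effect in ``which_effects`` (default: tau, xi, and — when
    sources are present — the space-shift magnitude along the top
    discriminating direction), a multivariate linear regression on all
    covariates jointly is fitted; per-coefficient two-tailed t-tests are
    Benjamini-Hochberg adjusted across the whole family.  Reporting
    conventions: tau coefficients in months (x 12), xi coefficients as
    multiplicative factors on alpha (exponentiated), space-shift
    magnitudes unsigned.

    Subjects with unknown amyloid status are dropped when amyloid status
    is among the covariates.
    """
    cov = covariates.copy()
    if "amyloid_status" in cov.columns:
        cov = cov[cov["amyloid_status"] != "unknown"]
    common = effects.index.intersection(cov.index)
    if len(common) < 20:
        raise ValueError(f"need at least 20 subjects with complete covariates, got {len(common)}")
    eff = effects.loc[common]
    X = _design_matrix(cov.loc[common])
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")

    src_cols = [c for c in eff.columns if c.startswith("source_")]
    if which_effects is None:
        which_effects = ["tau", "xi"] + (["space_shift"] if src_cols else [])

    targets = {}
    for name in which_effects:
        if name == "space_shift":
            S = eff[src_cols].to_numpy(dtype=float)
            if discriminating_covariate is None:
                # pick the binary covariate best separated in source space
                best, direction = -np.inf, None
                for c in X.columns:
                    vals = X[c]
                    if vals.nunique() != 2:
                        continue
                    g = vals.to_numpy() > vals.median()
                    if g.sum() < 2 or (~g).sum() < 2:
                        continue
                    diff = S[g].mean(axis=0) - S[~g].mean(axis=0)
                    sep = np.linalg.norm(diff)
                    if sep > best:
                        best, direction = sep, diff
            else:
                g = X[discriminating_covariate].to_numpy() > X[discriminating_covariate].median()
                direction = S[g].mean(axis=0) - S[~g].mean(axis=0)
            if direction is None or not np.linalg.norm(direction):
                continue
            direction = direction / np.linalg.norm(direction)
            targets[name] = S @ direction
        else:
            targets[name] = eff[name].to_numpy(dtype=float)

    rows = []
    for name, y in targets.items():
        model = sm.OLS(y, sm.add_constant(X)).fit()
        ci = model.conf_int(alpha=alpha)
        for c in X.columns:
            rows.append(
                {
                    "effect": name,
                    "covariate": c,
                    "coef": model.params[c],
                    "ci_low": ci.loc[c, 0],
                    "ci_high": ci.loc[c, 1],
                    "p_raw": model.pvalues[c],
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = benjamini_hochberg(table["p_raw"])
    table["significant"] = table["p_adj"] < alpha

    # reporting scales
    rep, lo, hi = [], [], []
    for _, r in table.iterrows():
        if r["effect"] == "tau":
            rep.append(r["coef"] * 12.0), lo.append(r["ci_low"] * 12.0), hi.append(r["ci_high"] * 12.0)
        elif r["effect"] == "xi":
            rep.append(np.exp(r["coef"])), lo.append(np.exp(r["ci_low"])), hi.append(np.exp(r["ci_high"]))
        elif r["effect"] == "space_shift":
            rep.append(abs(r["coef"])), lo.append(min(abs(r["ci_low"]), abs(r["ci_high"]))), hi.append(
                max(abs(r["ci_low"]), abs(r["ci_high"]))
            )
        else:
            rep.append(r["coef"]), lo.append(r["ci_low"]), hi.append(r["ci_high"])
    table["reported"] = rep
    table["reported_ci_low"] = lo
    table["reported_ci_high"] = hi
    table["unit"] = table["effect"].map(
        {"tau": "months", "xi": "multiplicative factor on alpha", "space_shift": "unsigned magnitude"}
    ).fillna("raw")
    return table


def conditional_correlation_graph(
    params: pd.DataFrame,
    alpha: float = 0.05,
    ridge: float = 0.01,
) -> nx.Graph:
    """Gaussian graphical model over standardized parameters.

    Partial correlations are read off the ridge-regularized inverse
    correlation matrix; an edge is kept between two parameters when the
    Fisher-z test of its partial correlation (conditioning on all other
    parameters) passes Benjamini-Hochberg FDR at ``alpha``.  Edge weights
    are the partial correlations.
    """
    n, d = params.shape
    if n < 30:
        raise ValueError(f"need at least 30 subjects, got {n}")
    X = params.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(X, rowvar=False)
    P = np.linalg.inv(R + ridge * np.eye(d))
    if np.linalg.matrix_rank(P) < d:
        raise ValueError("correlation matrix rank-deficient even after ridge regularization")
    denom = np.sqrt(np.outer(np.diag(P), np.diag(P)))
    partial = -P / denom
    np.fill_diagonal(partial, 1.0)

    iu = np.triu_indices(d, k=1)
    r = np.clip(partial[iu], -1 + 1e-12, 1 - 1e-12)
    df_eff = n - (d - 2) - 3
    if df_eff <= 0:
        raise ValueError("too few subjects for the Fisher z-test at this dimension")
    z = np.arctanh(r) * np.sqrt(df_eff)
    p_raw = 2.0 * norm.sf(np.abs(z))
    p_adj = benjamini_hochberg(p_raw)

    G = nx.Graph()
    G.add_nodes_from(params.columns)
    names = list(params.columns)
    for (i, j), rho, padj in zip(zip(*iu), r, p_adj):
        if padj < alpha:
            G.add_edge(names[i], names[j], weight=float(rho), p_adj=float(padj))
    return G


def noise_percent(std: float, scale_span: float) -> float:
    """Express a raw-score noise std as a percentage of the instrument span."""
    if not scale_span > 0:
        raise ValueError("scale_span must be positive")
    return 100.0 * std / scale_span


def estimate_measurement_noise(first, second, scale_span: float) -> dict:
    """Test/retest noise std on the percent scale.

    Paired measurements give an empirical distribution of differences; the
    noise level is their standard deviation divided by the instrument span,
    as a percentage.  The difference sample is returned for overlay plots.
    """
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if first.shape != second.shape or first.size == 0:
        raise ValueError("paired test/retest samples required")
    if first.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = first - second
    std = float(np.std(diff, ddof=1))
    return {
        "std": std,
        "percent": noise_percent(std, scale_span),
        "differences": diff,
    }
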