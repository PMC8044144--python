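"""Readers/writers, score normalization and model serialization.

Neuropsychological scores are normalized to [0, 1] with 0 = normal and
1 = maximal pathological value: MMSE (span 30, 30 is normal) maps through
``(30 - raw) / 30``; the ADAS family (ADAS-Cog-13 span 85, former
ADAS-Cog span 70, sub-scores by their item-sum spans) through
``raw / span``.  Longitudinal data travel as long-format CSV
(``ID,TIME,<markers...>``, empty cell = missing, TIME in years of age);
models as a schema-versioned JSON document with bit-stable round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CourseMap, LongitudinalDataset

__all__ = [
    "INSTRUMENTS",
    "ADAS_ITEM_MAX",
    "ADAS_SUBSCORE_ITEMS",
    "normalize_score",
    "denormalize_score",
    "adas_subscores",
    "read_long_csv",
    "write_long_csv",
    "save_model",
    "load_model",
]

#: instrument -> (span, normal_anchor); normal_anchor is the raw value mapping to 0
INSTRUMENTS = {
    "mmse": (30.0, 30.0),
    "adas_cog13": (85.0, 0.0),
    "adas_cog": (70.0, 0.0),
}

#: per-item maxima of the 13 ADAS-Cog items (sum = 85)
ADAS_ITEM_MAX = {
    1: 10.0,  # word recall
    2: 5.0,  # commands
    3: 5.0,  # constructional praxis
    4: 10.0,  # delayed word recall
    5: 5.0,  # naming
    6: 5.0,  # ideational praxis
    7: 8.0,  # orientation
    8: 12.0,  # word recognition
    9: 5.0,  # remembering test instructions
    10: 5.0,  # spoken language ability
    11: 5.0,  # word-finding difficulty
    12: 5.0,  # comprehension
    13: 5.0,  # number cancellation
}

#: item groupings of the four ADAS sub-scores
ADAS_SUBSCORE_ITEMS = {
    "memory": (1, 4, 7, 8, 9),
    "language": (2, 5, 10, 11, 12),
    "praxis": (3, 6),
    "concentration": (13,),
}


def normalize_score(raw: float, instrument: str) -> float:
    """Map a raw instrument score to the normalized [0, 1] scale.

    0 corresponds to the normal anchor and 1 to the maximum pathological
    value (e.g. MMSE 23 -> 0.233..., ADAS-Cog-13 28.9 -> 0.34).
    """
    if instrument not in INSTRUMENTS:
        raise ValueError(f"unknown instrument {instrument!r}; known: {sorted(INSTRUMENTS)}")
    span, normal = INSTRUMENTS[instrument]
    lo, hi = sorted((normal, normal - span if normal else span))
    if not lo <= raw <= hi:
        raise ValueError(f"{instrument} score {raw} outside the range [{lo}, {hi}]")
    return abs(raw - normal) / span


def denormalize_score(value: float, instrument: str) -> float:
    """Inverse of :func:`normalize_score` (exact round-trip)."""
    if instrument not in INSTRUMENTS:
        raise ValueError(f"unknown instrument {instrument!r}; known: {sorted(INSTRUMENTS)}")
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"normalized value {value} outside [0, 1]")
    span, normal = INSTRUMENTS[instrument]
    return normal - value * span if normal else value * span


def adas_subscores(items) -> dict[str, float]:
    """Normalized ADAS sub-scores from the 13 item scores.

    ``items`` is a sequence of 13 values in item order (item 1 first);
    ``None``/NaN marks a missing item, which propagates to its sub-score
    (missing, not zero).  Each sub-score is the item-group sum normalized
    by the group's own span.
    """
    items = list(items)
    if len(items) != 13:
        raise ValueError(f"expected 13 ADAS item scores, got {len(items)}")
    vals = {}
    for i, raw in enumerate(items, start=1):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            vals[i] = None
            continue
        raw = float(raw)
        if not 0.0 <= raw <= ADAS_ITEM_MAX[i]:
            raise ValueError(f"ADAS item {i} score {raw} outside [0, {ADAS_ITEM_MAX[i]}]")
        vals[i] = raw
    out = {}
    for name, group in ADAS_SUBSCORE_ITEMS.items():
        if any(vals[i] is None for i in group):
            out[name] = float("nan")
        else:
            span = sum(ADAS_ITEM_MAX[i] for i in group)
            out[name] = sum(vals[i] for i in group) / span
    return out


# ---------------------------------------------------------------------------
# long-format CSV


def read_long_csv(path) -> LongitudinalDataset:
    """Read a long-format longitudinal table (``ID,TIME,<markers...>``)."""
    df = pd.read_csv(path, dtype={"ID": str}, float_precision="round_trip")
    if "ID" not in df.columns or "TIME" not in df.columns:
        raise ValueError(f"{path}: header must start with ID,TIME")
    times = pd.to_numeric(df["TIME"], errors="coerce")
    bad = times.isna() & df["TIME"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: non-numeric TIME in data row {row + 1}")
    if times.isna().any():
        row = int(np.flatnonzero(times.isna())[0])
        raise ValueError(f"{path}: missing TIME in data row {row + 1}")
    df["TIME"] = times
    markers = [c for c in df.columns if c not in ("ID", "TIME")]
    df[markers] = df[markers].apply(pd.to_numeric, errors="raise")
    return LongitudinalDataset.from_dataframe(df)


def write_long_csv(data: LongitudinalDataset, path) -> None:
    """Write a dataset as long-format CSV; missing entries become empty cells.

    Floats use the shortest round-trip representation, so write -> read is
    the identity.
    """
    df = data.to_dataframe()
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model JSON

_SCHEMA_VERSION = 1
_REQUIRED_FIELDS = (
    "t0",
    "p0",
    "v0",
    "sigma_noise",
    "sigma_tau",
    "sigma_xi",
    "A",
    "marker_names",
)


def save_model(cmap: CourseMap, path, seed: int | None = None) -> None:
    """Serialize a course map as a single JSON document (bit-stable floats)."""
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "t0": cmap.t0,
        "p0": [float(x) for x in cmap.p0],
        "v0": [float(x) for x in cmap.v0],
        "sigma_noise": cmap.sigma_noise,
        "sigma_tau": cmap.sigma_tau,
        "sigma_xi": cmap.sigma_xi,
        "A": [[float(x) for x in row] for row in cmap.A],  # row-major
        "marker_names": list(cmap.marker_names),
        "meta": {"version": _SCHEMA_VERSION, "seed": seed},
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_model(path) -> CourseMap:
    """Load a course map from JSON; validates schema and model invariants."""
    doc = json.loads(Path(path).read_text())
    missing = [f for f in _REQUIRED_FIELDS if f not in doc]
    if missing:
        raise ValueError(f"{path}: missing model fields: {missing}")
    A = np.asarray(doc["A"], dtype=float)
    K = len(doc["p0"])
    if A.ndim != 2 or A.shape[0] != K:
        raise ValueError(f"{path}: A must be a K x Ns matrix with K = {K}")
    if A.shape[1] >= K:
        raise ValueError(
            f"{path}: A has {A.shape[1]} columns for {K} markers; only K-1 "
            "independent inter-marker spacings exist (Ns <= K-1)"
        )
    return CourseMap(
        t0=float(doc["t0"]),
        p0=np.asarray(doc["p0"], dtype=float),
        v0=np.asarray(doc["v0"], dtype=float),
        sigma_noise=float(doc["sigma_noise"]),
        sigma_tau=float(doc["sigma_tau"]),
        sigma_xi=float(doc["sigma_xi"]),
        A=A,
        marker_names=list(doc["marker_names"]),
    )
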