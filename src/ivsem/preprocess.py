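"""Construction of the analysis variables.

The investment composite is the mean of four Likert items (Q15 on 1–3;
Q26, Q27, Q38 on 1–4) after reverse-scaling Q26; the adversity index is
the sum of eight binary events; living distance enters as three dummies
with "overseas" as the reference level.  Investment and adversity are
grand-mean centered before their product is formed, so the interaction
coefficient reads as "change in the adversity slope per unit of
investment at the sample mean".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import AELE_COLUMNS, DISTANCE_LEVELS, ITEM_RANGES, SurveyDataset

__all__ = [
    "AnalysisFrame", "build_gi_composite", "build_aele_index",
    "encode_distance", "apply_exclusions", "build_analysis_frame",
    "sdq_total_from_subscales", "grand_means",
]

#: Dummy column order (reference level "overseas" maps to all zeros).
DUMMY_LEVELS = ("same_town", "within_10_miles", "further_in_uk")

INSTRUMENT_COLUMNS = ("d1", "d2", "d3", "d1_x_aele", "d2_x_aele", "d3_x_aele")


def _as_float(x):
    return np.asarray(x, dtype=float)


def _check_item_range(name: str, values: np.ndarray) -> None:
    lo, hi = ITEM_RANGES[name]
    bad = np.isfinite(values) & ((values < lo) | (values > hi))
    if np.any(bad):
        first = values[bad].flat[0]
        raise ValueError(
            f"item {name} outside its {lo}-{hi} Likert range (e.g. {first})")


def reverse_q26(values):
    """Reverse-scale Q26 on its 4-point scale: v -> 5 - v (involution)."""
    return 5 - _as_float(values)


def build_gi_composite(q15, q26, q27, q38):
    """Grandparental-investment composite: mean of the available items after
    reversing Q26.  Returns NaN where all four items are missing.

    Scalar inputs give a scalar; array inputs give an ndarray.
    """
    scalar = np.isscalar(q15) or q15 is None
    cols = {}
    for name, v in (("q15", q15), ("q26", q26), ("q27", q27), ("q38", q38)):
        arr = np.atleast_1d(_as_float(v if v is not None else np.nan))
        _check_item_range(name, arr)
        cols[name] = arr
    stacked = np.column_stack([cols["q15"], reverse_q26(cols["q26"]),
                               cols["q27"], cols["q38"]])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN rows
        out = np.nanmean(stacked, axis=1)
    return float(out[0]) if scalar and out.size == 1 else out


def build_aele_index(events, require_complete: bool = True):
    """Adversity count: sum of eight yes(1)/no(0) indicators, in {0,…,8}.

    With ``require_complete`` (default) any missing indicator makes the
    count missing; set it False to sum over the available items (the
    imputation path is the faithful way to use partially observed records).
    """
    arr = _as_float(events)
    if isinstance(events, pd.DataFrame):
        arr = events.to_numpy(dtype=float)
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != 8:
        raise ValueError(f"expected 8 adversity indicators, got {arr.shape[-1]}")
    finite = np.isfinite(arr)
    bad = finite & ~np.isin(arr, (0.0, 1.0))
    if np.any(bad):
        raise ValueError(
            f"adversity indicators must be binary 0/1, found {arr[bad].flat[0]}")
    if require_complete:
        out = np.where(finite.all(axis=1), np.nansum(arr, axis=1), np.nan)
    else:
        any_obs = finite.any(axis=1)
        out = np.where(any_obs, np.nansum(arr, axis=1), np.nan)
    return float(out[0]) if out.size == 1 and np.ndim(events) <= 1 else out


def encode_distance(distance):
    """Map a distance category to (d1, d2, d3); overseas is (0, 0, 0)."""
    if isinstance(distance, str):
        if distance not in DISTANCE_LEVELS:
            raise ValueError(f"unknown distance category {distance!r}; "
                             f"expected one of {DISTANCE_LEVELS}")
        return tuple(int(distance == lvl) for lvl in DUMMY_LEVELS)
    s = pd.Series(distance)
    unknown = set(s.dropna()) - set(DISTANCE_LEVELS)
    if unknown:
        raise ValueError(f"unknown distance categories {sorted(unknown)}; "
                         f"expected one of {DISTANCE_LEVELS}")
    out = np.column_stack([(s == lvl).to_numpy(int) for lvl in DUMMY_LEVELS])
    return out


@dataclass
class ExclusionLog:
    n_input: int = 0
    n_no_living_grandparent: int = 0
    n_coresident: int = 0
    n_missing_flags: int = 0
    n_retained: int = 0

    def to_json(self) -> str:
        return json.dumps(vars(self), indent=2)

    def to_text(self) -> str:
        return (f"records in: {self.n_input}\n"
                f"excluded, no living grandparent: {self.n_no_living_grandparent}\n"
                f"excluded, co-residing with grandparent: {self.n_coresident}\n"
                f"excluded, missing flags: {self.n_missing_flags}\n"
                f"retained: {self.n_retained}\n")


def apply_exclusions(df: pd.DataFrame, on_missing: str = "exclude"):
    """Drop children with no living grandparent, then those co-residing
    with a grandparent (their investment is near-obligatory and not
    comparable), and log counts per rule.

    Missing flags are excluded with a warning by default
    (``on_missing='exclude'``) or raise with ``on_missing='error'``.
    Idempotent and order-independent on the surviving rows.
    """
    import warnings

    log = ExclusionLog(n_input=len(df))
    if len(df) == 0:
        return df.copy(), log
    for col in ("has_living_grandparent", "coresides_with_grandparent"):
        if col not in df.columns:
            raise ValueError(f"exclusion flags require column {col!r}")
    living = df["has_living_grandparent"]
    cores = df["coresides_with_grandparent"]
    missing = living.isna() | cores.isna()
    if missing.any():
        if on_missing == "error":
            raise ValueError(f"{int(missing.sum())} records have missing "
                             "exclusion flags")
        warnings.warn(f"excluding {int(missing.sum())} records with missing "
                      "exclusion flags", stacklevel=2)
    log.n_missing_flags = int(missing.sum())
    step1 = df[~missing & living.astype("boolean").fillna(False).astype(bool)]
    log.n_no_living_grandparent = log.n_input - log.n_missing_flags - len(step1)
    kept = step1[~step1["coresides_with_grandparent"].astype(bool)]
    log.n_coresident = len(step1) - len(kept)
    log.n_retained = len(kept)
    return kept.copy(), log


def sdq_total_from_subscales(emotional, conduct, hyperactivity, peer):
    """Total difficulties score: sum of the four difficulty subscales
    (prosocial behavior is excluded by construction)."""
    return (_as_float(emotional) + _as_float(conduct)
            + _as_float(hyperactivity) + _as_float(peer))


def grand_means(datasets) -> tuple[float, float]:
    """Grand means of the investment composite and adversity count over a
    stack of (imputed) datasets, so centering — hence the meaning of "one
    unit" — is identical across imputations."""
    gis, aeles = [], []
    for d in datasets:
        df = d.data if isinstance(d, SurveyDataset) else d
        gis.append(build_gi_composite(df["q15"], df["q26"], df["q27"], df["q38"]))
        aeles.append(build_aele_index(df[list(AELE_COLUMNS)]))
    gi = np.concatenate([np.atleast_1d(g) for g in gis])
    ae = np.concatenate([np.atleast_1d(a) for a in aeles])
    return float(np.nanmean(gi)), float(np.nanmean(ae))


@dataclass
class AnalysisFrame:
    """Model-ready table: centered composites, their product, distance
    dummies and dummy×adversity instrument columns, and the outcome."""

    data: pd.DataFrame
    gi_mean: float
    aele_mean: float
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def build_analysis_frame(dataset, means: tuple[float, float] | None = None,
                         min_complete: int = 10) -> AnalysisFrame:
    """Assemble the analysis frame from a survey table.

    ``means`` optionally supplies externally computed grand means (used to
    share one centering across multiply imputed datasets); otherwise the
    frame's own complete cases define them.  Rows with a non-computable
    composite, adversity count, outcome or distance are dropped.
    """
    df = dataset.data if isinstance(dataset, SurveyDataset) else dataset
    gi = np.atleast_1d(build_gi_composite(df["q15"], df["q26"], df["q27"], df["q38"]))
    aele = np.atleast_1d(build_aele_index(df[list(AELE_COLUMNS)]))
    sdq = df["sdq_total"].to_numpy(dtype=float)
    dummies = encode_distance(df["distance"])

    ok = (np.isfinite(gi) & np.isfinite(aele) & np.isfinite(sdq)
          & df["distance"].notna().to_numpy())
    if ok.sum() < min_complete:
        raise ValueError(f"only {int(ok.sum())} complete rows; "
                         f"at least {min_complete} required")
    gi, aele, sdq, dummies = gi[ok], aele[ok], sdq[ok], dummies[ok]

    gi_mean, aele_mean = means if means is not None else (gi.mean(), aele.mean())
    gi_c = gi - gi_mean
    aele_c = aele - aele_mean

    out = pd.DataFrame({
        "gi_c": gi_c,
        "aele_c": aele_c,
        "gi_x_aele": gi_c * aele_c,
        "d1": dummies[:, 0], "d2": dummies[:, 1], "d3": dummies[:, 2],
        "d1_x_aele": dummies[:, 0] * aele_c,
        "d2_x_aele": dummies[:, 1] * aele_c,
        "d3_x_aele": dummies[:, 2] * aele_c,
        "sdq_total": sdq,
    })
    return AnalysisFrame(data=out, gi_mean=float(gi_mean),
                         aele_mean=float(aele_mean),
                         n_dropped=int(len(df) - ok.sum()))
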