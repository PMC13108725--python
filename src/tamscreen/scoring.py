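"""Robust polarization-capacity scoring of tumor cell lines.

Macrophage responses to tumor-conditioned media (TCM) are standardized per
analyte with the modified z-score

    z_i = 0.6745 * (x_i - median(x)) / MAD(x),    MAD = median(|x - median(x)|),

so that +0.6745 marks an observation exactly one MAD above the dataset
median. Scores are averaged over donors per cell line, ranked, and split
into top/bottom quartile "high"/"low" stimulator groups used downstream for
differential expression.

The module also houses the assay-floor (LLoQ) retention rule: an analyte is
dropped when too large a fraction of its observations fall below the lower
limit of quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .io import AnalyteMeasurementTable

CONSISTENCY_CONSTANT = 0.6745
#: Mean-absolute-deviation consistency constant (sqrt(2/pi)) for the MAD=0 fallback.
MEAN_AD_CONSTANT = 0.7979

__all__ = [
    "ScoringParameters",
    "PolarizationScoreMatrix",
    "modified_z",
    "filter_analytes_by_lloq",
    "impute_censored",
    "score_table",
    "aggregate_scores",
    "assign_quartiles",
]


@dataclass(frozen=True)
class ScoringParameters:
    """Knobs of the modified z-score computation.

    consistency_constant : multiplier making MAD consistent for the normal
        scale; fixed at 0.6745 unless explicitly overridden.
    pooling : "pooled" standardizes each analyte over all observations
        (donors, cell lines and controls together); "per_donor" standardizes
        within each donor separately.
    mad_zero_fallback : what to do when MAD == 0 — rescale by the mean
        absolute deviation (constant 0.7979), or raise.
    """

    consistency_constant: float = CONSISTENCY_CONSTANT
    pooling: Literal["pooled", "per_donor"] = "pooled"
    mad_zero_fallback: Literal["mean_abs_dev_07979", "flag_undefined"] = "mean_abs_dev_07979"


@dataclass
class PolarizationScoreMatrix:
    """Modified z-scores at observation level plus donor-averaged summaries.

    per_observation : long frame (donor, unit, analyte, score).
    per_unit : long frame (unit, analyte, mean_score, sem, n_donors);
        mean is the arithmetic mean over donors, SEM = sd/sqrt(n).
    retained_analytes : analytes surviving the LLoQ filter.
    control_units : unit ids treated as unstimulated controls (excluded from
        ranking/quartiles but scored on the same scale).
    """

    per_observation: pd.DataFrame
    per_unit: pd.DataFrame
    retained_analytes: list[str]
    control_units: set[str] = field(default_factory=set)

    def unit_scores(self, analyte: str, include_controls: bool = False) -> pd.Series:
        """Donor-mean score per unit for one analyte, descending."""
        sub = self.per_unit[self.per_unit["analyte"] == analyte]
        if not include_controls:
            sub = sub[~sub["unit"].isin(self.control_units)]
        s = sub.set_index("unit")["mean_score"]
        return s.sort_values(ascending=False)

    def ranks(self, analyte: str) -> pd.Series:
        """1-based rank of each non-control unit, 1 = highest mean score."""
        s = self.unit_scores(analyte)
        return pd.Series(np.arange(1, len(s) + 1), index=s.index)

    def quartile_labels(self, analyte: str) -> pd.Series:
        top, bottom = assign_quartiles(self, analyte)
        s = self.unit_scores(analyte)
        lab = pd.Series("middle", index=s.index)
        lab[list(top)] = "top"
        lab[list(bottom)] = "bottom"
        return lab


def modified_z(values, params: ScoringParameters | None = None) -> np.ndarray:
    """Modified z-scores 0.6745*(x - median)/MAD of a 1-D sample.

    Order-preserving; the median maps to 0 and a point one MAD above the
    median maps to +0.6745 exactly. When MAD == 0 the configured fallback
    applies (rescale by the mean absolute deviation with constant 0.7979,
    or raise ``ZeroDivisionError``).
    """
    params = params or ScoringParameters()
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("modified_z requires a 1-D vector of length >= 2")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad > 0:
        return params.consistency_constant * (x - med) / mad
    if params.mad_zero_fallback == "flag_undefined":
        raise ZeroDivisionError("MAD is zero; modified z-score undefined")
    mean_ad = np.mean(np.abs(x - med))
    if mean_ad == 0:  # constant vector: all points are the median
        return np.zeros_like(x)
    return MEAN_AD_CONSTANT * (x - med) / mean_ad


def filter_analytes_by_lloq(
    table: AnalyteMeasurementTable, max_censored_fraction: float = 0.40
) -> tuple[list[str], list[tuple[str, float]]]:
    """Partition analytes into retained and excluded by censoring fraction.

    An analyte is excluded iff the fraction of its observations below the
    assay LLoQ strictly exceeds ``max_censored_fraction``. Returns
    (retained names, [(excluded name, censored fraction), ...]); the two
    lists are exhaustive and disjoint.
    """
    df = table.records
    retained: list[str] = []
    excluded: list[tuple[str, float]] = []
    for analyte, grp in df.groupby("analyte", sort=True):
        if analyte not in table.lloq_map:
            raise KeyError(f"analyte {analyte!r} missing from lloq_map")
        frac = float(grp["below_lloq"].mean())
        if frac > max_censored_fraction:
            excluded.append((str(analyte), frac))
        else:
            retained.append(str(analyte))
    return retained, excluded


def impute_censored(
    table: AnalyteMeasurementTable,
    method: Literal["half_lloq", "lloq", "drop"] = "half_lloq",
) -> AnalyteMeasurementTable:
    """Replace (or drop) below-LLoQ concentrations in retained analytes.

    half_lloq substitutes LLoQ/2 (standard censored-value convention), lloq
    substitutes the LLoQ itself, drop removes the rows. The below_lloq flags
    are preserved so downstream stages can still see what was censored.
    """
    df = table.records.copy()
    mask = df["below_lloq"].to_numpy(bool)
    if method == "drop":
        df = df[~mask].reset_index(drop=True)
    elif method in ("half_lloq", "lloq"):
        scale = 0.5 if method == "half_lloq" else 1.0
        lloqs = df.loc[mask, "analyte"].map(table.lloq_map).astype(float)
        df.loc[mask, "concentration"] = scale * lloqs
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return AnalyteMeasurementTable(
        records=df, lloq_map=dict(table.lloq_map), metadata=dict(table.metadata),
        validate=False,
    )


def score_table(
    table: AnalyteMeasurementTable,
    retained: list[str] | None = None,
    params: ScoringParameters | None = None,
    control_units: set[str] | None = None,
) -> PolarizationScoreMatrix:
    """Modified z-scores for every observation of the retained analytes.

    With pooled standardization (default) each analyte's "dataset" is all of
    its observations across donors, cell lines and controls; per_donor mode
    standardizes within donor.
    """
    params = params or ScoringParameters()
    df = table.records
    if retained is None:
        retained, _ = filter_analytes_by_lloq(table)
    df = df[df["analyte"].isin(retained)].copy()
    if params.pooling == "pooled":
        keys = ["analyte"]
    else:
        keys = ["analyte", "donor"]
    df["score"] = (
        df.groupby(keys, sort=False)["concentration"]
        .transform(lambda v: modified_z(v.to_numpy(), params))
    )
    per_obs = df[["donor", "unit", "analyte", "score"]].reset_index(drop=True)
    matrix = aggregate_scores(per_obs, retained, control_units or set())
    return matrix


def aggregate_scores(
    per_observation: pd.DataFrame,
    retained: list[str],
    control_units: set[str] | None = None,
) -> PolarizationScoreMatrix:
    """Donor-mean +/- SEM per (unit, analyte).

    Units seen by a single donor get a missing SEM; the mean is the plain
    arithmetic mean of that unit's per-observation scores, so permuting
    donor order never changes it.
    """
    g = per_observation.groupby(["unit", "analyte"], sort=True)["score"]
    per_unit = g.agg(mean_score="mean", sd="std", n_donors="count").reset_index()
    per_unit["sem"] = per_unit["sd"] / np.sqrt(per_unit["n_donors"])
    per_unit.loc[per_unit["n_donors"] < 2, "sem"] = np.nan
    per_unit = per_unit.drop(columns="sd")
    return PolarizationScoreMatrix(
        per_observation=per_observation.reset_index(drop=True),
        per_unit=per_unit,
        retained_analytes=list(retained),
        control_units=set(control_units or set()),
    )


def assign_quartiles(
    score_matrix: PolarizationScoreMatrix, analyte: str
) -> tuple[set[str], set[str]]:
    """Top/bottom quartile stimulator groups for one analyte.

    Group size k = ceil(n/4) over the n non-control units; top = k highest
    donor-mean scores, bottom = k lowest. Ties at the group boundary are
    broken by lexicographically smaller unit id so group membership is
    run-to-run stable.
    """
    s = score_matrix.unit_scores(analyte)
    n = len(s)
    if n < 8:
        raise ValueError(f"need >= 8 scored units to form quartiles, got {n}")
    k = math.ceil(n / 4)
    if 2 * k > n:
        raise ValueError(f"quartiles overlap: 2*ceil({n}/4) = {2 * k} > {n}")
    df = s.reset_index()
    df.columns = ["unit", "score"]
    top_order = df.sort_values(["score", "unit"], ascending=[False, True])
    bottom_order = df.sort_values(["score", "unit"], ascending=[True, True])
    top = set(top_order["unit"].head(k))
    bottom = set(bottom_order["unit"].head(k))
    if top & bottom:
        raise ValueError("quartiles overlap after tie-breaking")
    return top, bottom
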