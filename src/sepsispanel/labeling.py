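"""Hematologic 2-of-4 sepsis score, three-group assignment and exclusions.

An evaluation's sepsis score is positive when at least two of four
CBC-derived laboratory criteria fire: abnormal absolute neutrophil count
(outside a reference band), elevated absolute band count, elevated
immature-to-total neutrophil ratio, and thrombocytopenia.  Evaluations are
then partitioned into three exclusive groups — culture-proven sepsis (1),
clinical sepsis (positive score, negative culture; 2), nonseptic (3) — and
groups 1 and 2 together form the septic label (+1) for all downstream
analysis.

The numeric thresholds are configuration with documented defaults drawn from
the neonatal hematologic-scoring literature; every report produced from them
carries the values used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import BIOMARKERS


@dataclass(frozen=True)
class CriteriaThresholds:
    """Thresholds for the four laboratory criteria.

    Units: ANC/ABC in cells/mm^3, IT-ratio dimensionless, Plt in 10^3/uL.
    """

    anc_low: float = 1750.0
    anc_high: float = 25000.0
    abc_min: float = 1500.0
    it_ratio_min: float = 0.2
    plt_max: float = 150.0

    def __post_init__(self) -> None:
        if not self.anc_low < self.anc_high:
            raise ValueError("anc_low must be < anc_high")
        if min(self.anc_low, self.abc_min, self.plt_max) <= 0:
            raise ValueError("all thresholds must be > 0")
        if not 0.0 < self.it_ratio_min < 1.0:
            raise ValueError("it_ratio_min must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "anc_low": self.anc_low, "anc_high": self.anc_high,
            "abc_min": self.abc_min, "it_ratio_min": self.it_ratio_min,
            "plt_max": self.plt_max,
        }


#: Package defaults (implementer-chosen, see module docstring).
DEFAULT_THRESHOLDS = CriteriaThresholds()


@dataclass
class LabeledDataset:
    """Biomarker matrix with ±1 septic labels and group assignments."""

    X: np.ndarray
    y: np.ndarray
    group: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = np.where(np.isin(self.group, (1, 2)), 1, -1)
        if not np.array_equal(self.y, expected):
            raise ValueError("y must be +1 exactly for groups 1 and 2")
        if np.isnan(self.X).any():
            raise ValueError("X must not contain missing values")

    @property
    def n(self) -> int:
        return self.X.shape[0]


def _score_inputs(record) -> tuple[float, float, float, float]:
    """Extract (anc, abc, it_ratio, plt) from a record, Series or mapping."""
    if hasattr(record, "anc"):
        vals = (record.anc, record.abc, record.it_ratio, record.plt)
    else:
        plt = record["Plt"] if "Plt" in record else record["plt"]
        vals = (record["anc"], record["abc"], record["it_ratio"], plt)
    return tuple(float(v) for v in vals)  # type: ignore[return-value]


def hematologic_score(record, th: CriteriaThresholds = DEFAULT_THRESHOLDS,
                      ) -> tuple[int, bool]:
    """Count the laboratory criteria met and apply the 2-of-4 rule.

    Criteria (inclusive boundaries throughout): ANC outside
    [anc_low, anc_high]; ABC >= abc_min; IT-ratio >= it_ratio_min;
    Plt <= plt_max.  Returns ``(criteria_met, positive)`` with positive
    iff at least two criteria are met.
    """
    anc, abc, it, plt = _score_inputs(record)
    if not all(np.isfinite([anc, abc, it, plt])):
        raise ValueError("score inputs must be present and finite; "
                         "flag the record for exclusion instead of scoring it")
    met = int(anc < th.anc_low or anc > th.anc_high) \
        + int(abc >= th.abc_min) \
        + int(it >= th.it_ratio_min) \
        + int(plt <= th.plt_max)
    return met, met >= 2


def assign_group(record, th: CriteriaThresholds = DEFAULT_THRESHOLDS) -> int:
    """Assign an evaluation to exactly one of the three outcome groups.

    Group 1: positive blood culture (culture dominates the score);
    group 2: culture-negative but score-positive (clinical sepsis);
    group 3: neither.
    """
    culture = record.culture_positive if hasattr(record, "culture_positive") \
        else record["culture_positive"]
    if culture is None or (isinstance(culture, float) and np.isnan(culture)):
        raise ValueError("culture result must be known to assign a group")
    if bool(culture):
        return 1
    _, positive = hematologic_score(record, th)
    return 2 if positive else 3


def _criteria_matrix(df: pd.DataFrame, th: CriteriaThresholds) -> np.ndarray:
    anc = df["anc"].to_numpy(dtype=float)
    abc = df["abc"].to_numpy(dtype=float)
    it = df["it_ratio"].to_numpy(dtype=float)
    plt = df["Plt"].to_numpy(dtype=float)
    return np.stack([
        (anc < th.anc_low) | (anc > th.anc_high),
        abc >= th.abc_min,
        it >= th.it_ratio_min,
        plt <= th.plt_max,
    ], axis=1)


def make_labels(records: pd.DataFrame,
                th: CriteriaThresholds = DEFAULT_THRESHOLDS) -> LabeledDataset:
    """Build the ±1 septic label (groups 1 and 2 vs 3) from complete records."""
    if len(records) == 0:
        raise ValueError("cannot label an empty record table")
    culture = records["culture_positive"].to_numpy(dtype=bool)
    positive_score = _criteria_matrix(records, th).sum(axis=1) >= 2
    group = np.where(culture, 1, np.where(positive_score, 2, 3))
    y = np.where(np.isin(group, (1, 2)), 1, -1)
    if len(np.unique(y)) < 2:
        raise ValueError("labeling produced a single class; downstream "
                         "classifiers are undefined")
    X = records[list(BIOMARKERS)].to_numpy(dtype=float)
    return LabeledDataset(X=X, y=y, group=group, names=BIOMARKERS)


def exclude_incomplete(
    records: pd.DataFrame,
    *,
    cd64_outlier_cutoff: float | None = None,
    score_columns: Sequence[str] = ("anc", "abc", "it_ratio"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records lacking any biomarker, score input or culture result.

    Returns ``(kept, excluded)`` where ``excluded`` has columns ``eval_id``
    and ``reason`` (machine-readable: ``missing:<col>`` / ``outlier:CD64``).
    ``cd64_outlier_cutoff`` (disabled by default) additionally excludes
    evaluations whose CD64 index exceeds the cutoff — the analog of removing
    a single extreme CD64 evaluation that would otherwise skew the fit.
    """
    reasons: list[tuple[str, str]] = []
    keep = np.ones(len(records), dtype=bool)
    check_cols = list(BIOMARKERS) + list(score_columns) + ["culture_positive"]
    for col in check_cols:
        if col not in records.columns:
            bad = np.ones(len(records), dtype=bool)
        else:
            vals = records[col]
            bad = vals.isna().to_numpy()
            if col != "culture_positive":
                numeric = pd.to_numeric(vals, errors="coerce")
                bad = bad | numeric.isna().to_numpy()
        for i in np.nonzero(bad & keep)[0]:
            reasons.append((str(records["eval_id"].iloc[i]), f"missing:{col}"))
        keep &= ~bad
    if cd64_outlier_cutoff is not None:
        cd64 = pd.to_numeric(records["CD64"], errors="coerce").to_numpy()
        out = keep & (cd64 > cd64_outlier_cutoff)
        for i in np.nonzero(out)[0]:
            reasons.append((str(records["eval_id"].iloc[i]), "outlier:CD64"))
        keep &= ~out
    excluded = pd.DataFrame(reasons, columns=["eval_id", "reason"])
    return records.loc[keep].reset_index(drop=True), excluded
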