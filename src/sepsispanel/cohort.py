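"""Seeded synthetic NICU-style sepsis cohorts with planted informative panels.

The generator emulates a two-group (septic / nonseptic) cohort of sepsis
evaluations: ten hematological biomarkers per evaluation (Age, WBC, Hgb, Hct,
Plt, Segs, Bands, Lymph, Mono, CD64), the CBC-derived score-rule inputs
(ANC, ABC, IT-ratio, Plt), and a blood-culture result.  Marginals for the
five panel biomarkers default to published pooled means/SDs; right-skewed
counts (WBC, Plt, Bands, CD64) are drawn lognormally with moment matching,
the rest Gaussian truncated at zero.  A shared latent Gaussian copula imposes
a configurable correlation structure, by default with Bands more correlated
with CD64 than with Plt.

Informative biomarkers (the planted panel) differ in group mean by a
specified number of pooled SDs; everything else is exchangeable between
groups, which is what makes parameter-recovery tests well-posed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical biomarker order used everywhere in the package.
BIOMARKERS: tuple[str, ...] = (
    "Age", "WBC", "Hgb", "Hct", "Plt", "Segs", "Bands", "Lymph", "Mono", "CD64",
)

#: Biomarkers drawn on a log scale (right-skewed counts / indices).
LOG_SCALE: frozenset[str] = frozenset({"WBC", "Plt", "Bands", "CD64"})

# Pooled marginal defaults.  WBC/Plt/Segs/Bands/CD64 use the published pooled
# moments; the remaining five are implementer-chosen plausible NICU values
# (units: Age days, WBC & Plt 10^3/uL, Hgb g/dL, Hct %, differential %, CD64
# index unitless).
DEFAULT_POOLED_MEAN: dict[str, float] = {
    "Age": 14.0, "WBC": 14.04, "Hgb": 14.5, "Hct": 44.0, "Plt": 231.37,
    "Segs": 39.64, "Bands": 7.92, "Lymph": 38.0, "Mono": 7.0, "CD64": 2.96,
}
DEFAULT_POOLED_SD: dict[str, float] = {
    "Age": 12.0, "WBC": 8.70, "Hgb": 2.6, "Hct": 7.5, "Plt": 103.38,
    "Segs": 17.25, "Bands": 9.61, "Lymph": 15.0, "Mono": 3.5, "CD64": 2.42,
}

# Default standardized group-mean differences (septic minus nonseptic, in
# pooled-SD units) for the five-biomarker panel; signs follow the direction of
# each marker's association with sepsis (bandemia, CD64 induction and
# leukocytosis up; thrombocytopenia and relative mature-neutrophil drop down).
DEFAULT_EFFECTS: dict[str, float] = {
    "WBC": 0.5, "Plt": -0.8, "Segs": -0.5, "Bands": 1.2, "CD64": 0.9,
}


def default_correlation() -> np.ndarray:
    """Default latent correlation among the ten biomarkers.

    Encodes a handful of physiological dependencies: Hgb-Hct near-identity,
    the differential trade-off between Segs and Lymph, WBC driving its
    components, and — deliberately — corr(Bands, CD64) > |corr(Bands, Plt)|.
    Positive definite by construction (checked in the spec validator).
    """
    C = np.eye(len(BIOMARKERS))

    def _set(a: str, b: str, v: float) -> None:
        i, j = BIOMARKERS.index(a), BIOMARKERS.index(b)
        C[i, j] = C[j, i] = v

    _set("Hgb", "Hct", 0.85)
    _set("Segs", "Lymph", -0.65)
    _set("WBC", "Segs", 0.30)
    _set("WBC", "Bands", 0.25)
    _set("WBC", "Mono", 0.10)
    _set("Segs", "Bands", -0.10)
    _set("Bands", "CD64", 0.50)
    _set("Bands", "Plt", -0.15)
    _set("Plt", "CD64", -0.10)
    _set("WBC", "CD64", 0.15)
    _set("Lymph", "Bands", -0.15)
    return C


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic two-group cohort.

    ``mean_pos``/``mean_neg`` and ``sd_pos``/``sd_neg`` are raw-scale
    per-biomarker moments for the septic (+) and nonseptic (−) groups;
    ``corr`` is the latent-scale correlation target shared by both groups.
    ``informative_set`` lists the indices whose group means differ — outside
    it the two groups must match exactly.
    """

    n_pos: int
    n_neg: int
    biomarker_names: tuple[str, ...] = BIOMARKERS
    mean_pos: np.ndarray = field(default=None)  # type: ignore[assignment]
    mean_neg: np.ndarray = field(default=None)  # type: ignore[assignment]
    sd_pos: np.ndarray = field(default=None)  # type: ignore[assignment]
    sd_neg: np.ndarray = field(default=None)  # type: ignore[assignment]
    corr: np.ndarray = field(default=None)  # type: ignore[assignment]
    informative_set: tuple[int, ...] = ()
    seed: int = 0
    culture_fraction: float = 0.5
    force_score_consistency: bool = True

    def validate(self) -> None:
        p = len(self.biomarker_names)
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must both be >= 1")
        for nm, arr in (("mean_pos", self.mean_pos), ("mean_neg", self.mean_neg),
                        ("sd_pos", self.sd_pos), ("sd_neg", self.sd_neg)):
            if arr is None or np.asarray(arr).shape != (p,):
                raise ValueError(f"{nm} must be a length-{p} array")
        if np.any(np.asarray(self.sd_pos) <= 0) or np.any(np.asarray(self.sd_neg) <= 0):
            raise ValueError("all sd values must be > 0")
        C = np.asarray(self.corr, dtype=float)
        if C.shape != (p, p):
            raise ValueError(f"corr must be {p}x{p}")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise ValueError("corr must have a unit diagonal")
        lam_min = float(np.linalg.eigvalsh(C)[0])
        if lam_min <= 0:
            raise ValueError(
                f"corr is not positive definite (smallest eigenvalue {lam_min:.3e})"
            )
        outside = [j for j in range(p) if j not in self.informative_set]
        if not np.array_equal(np.asarray(self.mean_pos)[outside],
                              np.asarray(self.mean_neg)[outside]):
            raise ValueError("group means must agree outside informative_set")
        if not 0.0 <= self.culture_fraction <= 1.0:
            raise ValueError("culture_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("mean_pos", "mean_neg", "sd_pos", "sd_neg"):
            d[key] = np.asarray(d[key]).tolist()
        d["corr"] = np.asarray(d["corr"]).tolist()
        d["biomarker_names"] = list(self.biomarker_names)
        d["informative_set"] = list(self.informative_set)
        return d


@dataclass
class EvaluationRecord:
    """One sepsis evaluation: biomarkers, score-rule inputs, culture, group."""

    eval_id: str
    day_of_life: float
    biomarkers: dict[str, float]
    anc: float
    abc: float
    it_ratio: float
    plt: float
    culture_positive: bool
    true_group: int | None = None

    @classmethod
    def from_row(cls, row: Mapping) -> "EvaluationRecord":
        return cls(
            eval_id=str(row["eval_id"]),
            day_of_life=float(row["Age"]),
            biomarkers={name: float(row[name]) for name in BIOMARKERS},
            anc=float(row["anc"]),
            abc=float(row["abc"]),
            it_ratio=float(row["it_ratio"]),
            plt=float(row["Plt"]),
            culture_positive=bool(row["culture_positive"]),
            true_group=int(row["true_group"]) if "true_group" in row and not pd.isna(row["true_group"]) else None,
        )


def default_cohort_spec(
    n_pos: int,
    n_neg: int,
    *,
    effects: Mapping[str, float] | None = None,
    corr: np.ndarray | None = None,
    seed: int = 0,
    culture_fraction: float = 0.5,
    force_score_consistency: bool = True,
) -> CohortSpec:
    """Cohort spec anchored to the default pooled marginals.

    ``effects`` maps biomarker name -> standardized group-mean difference
    (septic minus nonseptic, pooled-SD units); defaults to the five-marker
    panel pattern.  Group means are placed symmetrically about the pooled
    mean so that with equal group sizes the pooled sample mean matches the
    anchor value.
    """
    if effects is None:
        effects = DEFAULT_EFFECTS
    p = len(BIOMARKERS)
    m = np.array([DEFAULT_POOLED_MEAN[b] for b in BIOMARKERS])
    s = np.array([DEFAULT_POOLED_SD[b] for b in BIOMARKERS])
    d = np.array([effects.get(b, 0.0) for b in BIOMARKERS])
    informative = tuple(j for j in range(p) if d[j] != 0.0)
    # The effect is planted on the generative scale so d carries the same
    # discriminative content for every marker family.  Gaussian markers:
    # additive shift of d pooled SDs.  Lognormal markers: multiplicative
    # shift of d latent (log-scale) SDs, placed so the pooled arithmetic
    # mean stays exactly at the anchor, with a constant coefficient of
    # variation (count-like CBC quantities disperse with their level).
    mean_pos, mean_neg = m.copy(), m.copy()
    sd_pos, sd_neg = s.copy(), s.copy()
    for j, b in enumerate(BIOMARKERS):
        if b in LOG_SCALE:
            sd_log = np.sqrt(np.log1p((s[j] / m[j]) ** 2))
            h = 0.5 * d[j] * sd_log
            mean_pos[j] = m[j] * np.exp(h) / np.cosh(h)
            mean_neg[j] = m[j] * np.exp(-h) / np.cosh(h)
            sd_pos[j] = s[j] * mean_pos[j] / m[j]
            sd_neg[j] = s[j] * mean_neg[j] / m[j]
        else:
            mean_pos[j] = m[j] + 0.5 * d[j] * s[j]
            mean_neg[j] = m[j] - 0.5 * d[j] * s[j]
    return CohortSpec(
        n_pos=n_pos,
        n_neg=n_neg,
        mean_pos=mean_pos,
        mean_neg=mean_neg,
        sd_pos=sd_pos,
        sd_neg=sd_neg,
        corr=default_correlation() if corr is None else np.asarray(corr, dtype=float),
        informative_set=informative,
        seed=seed,
        culture_fraction=culture_fraction,
        force_score_consistency=force_score_consistency,
    )


def _truncation_compensated_mu(m: float, s: float) -> float:
    """Location of a zero-truncated Gaussian whose clipped mean equals m.

    Clipping N(mu, s) at zero inflates the mean by
    s*(phi(a) - a*Phi(-a)) with a = mu/s; a short fixed-point iteration
    removes the bias so sample means recover the spec value.
    """
    from scipy.stats import norm

    mu = m
    for _ in range(50):
        a = mu / s
        clipped_mean = mu * norm.cdf(a) + s * norm.pdf(a)
        err = clipped_mean - m
        if abs(err) < 1e-12 * max(1.0, abs(m)):
            break
        mu -= err
    return mu


def _draw_group(rng: np.random.Generator, n: int, mean: np.ndarray,
                sd: np.ndarray, chol: np.ndarray,
                names: Sequence[str]) -> np.ndarray:
    """Draw one group via a latent Gaussian copula with moment matching."""
    Z = rng.standard_normal((n, len(names))) @ chol.T
    X = np.empty_like(Z)
    for j, name in enumerate(names):
        m, s = float(mean[j]), float(sd[j])
        if name in LOG_SCALE:
            if m <= 0:
                raise ValueError(
                    f"{name} is drawn lognormally and needs a positive "
                    f"group mean (got {m:g})")
            # lognormal matched to raw-scale mean/SD
            s2 = np.log1p((s / m) ** 2)
            mu_log = np.log(m) - 0.5 * s2
            X[:, j] = np.exp(mu_log + np.sqrt(s2) * Z[:, j])
        else:
            mu = _truncation_compensated_mu(m, s)
            X[:, j] = np.maximum(mu + s * Z[:, j], 0.0)
    return X


def _derived_inputs(X: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ANC/ABC/IT-ratio from WBC (10^3/uL) and Segs/Bands percentages.

    ANC = WBC * Segs% and ABC = WBC * Bands%, converted to cells/mm^3
    (x10 since WBC is in 10^3/uL and the percentages are of WBC).
    """
    wbc = X[:, list(names).index("WBC")]
    segs = X[:, list(names).index("Segs")]
    bands = X[:, list(names).index("Bands")]
    anc = wbc * segs * 10.0
    abc = wbc * bands * 10.0
    total = anc + abc
    with np.errstate(invalid="ignore", divide="ignore"):
        it = np.where(total > 0, abc / total, 0.0)
    return anc, abc, it


def _force_consistency(df: pd.DataFrame, septic: np.ndarray, th) -> None:
    """Minimally nudge score-rule inputs so the 2-of-4 rule matches groups.

    Touches only the derived ANC/ABC/IT-ratio columns, never the ten
    classifier biomarkers: intended-septic evaluations without a positive
    culture are given ABC and IT-ratio just over threshold; intended
    nonseptic evaluations have their ANC/ABC/IT criteria forced negative so
    at most the platelet criterion can fire (1 < 2).
    """
    anc = df["anc"].to_numpy().copy()
    abc = df["abc"].to_numpy().copy()
    it = df["it_ratio"].to_numpy().copy()
    plt = df["Plt"].to_numpy()
    culture = df["culture_positive"].to_numpy()

    crit = np.stack([
        (anc < th.anc_low) | (anc > th.anc_high),
        abc >= th.abc_min,
        it >= th.it_ratio_min,
        plt <= th.plt_max,
    ], axis=1)
    n_met = crit.sum(axis=1)

    need_pos = septic & ~culture & (n_met < 2)
    abc[need_pos] = th.abc_min * 1.05
    it[need_pos] = min(th.it_ratio_min * 1.05, 1.0)

    need_neg = ~septic & (n_met >= 2)
    anc[need_neg] = 0.5 * (th.anc_low + th.anc_high)
    abc[need_neg] = th.abc_min * 0.9
    it[need_neg] = th.it_ratio_min * 0.9

    df["anc"] = anc
    df["abc"] = abc
    df["it_ratio"] = it


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort table of evaluations from a validated spec.

    Returns a DataFrame with columns ``eval_id``, the ten biomarkers in
    canonical order, ``anc``, ``abc``, ``it_ratio``, ``culture_positive``
    and ``true_group`` (1 = culture-proven septic, 2 = clinical septic,
    3 = nonseptic).  Deterministic under ``spec.seed``.
    """
    spec.validate()
    names = spec.biomarker_names
    p = len(names)
    n = spec.n_pos + spec.n_neg
    if n < 10 * p:
        warnings.warn(
            f"cohort of n={n} is small for p={p} biomarkers; "
            "moment/correlation recovery will be noisy",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(np.asarray(spec.corr, dtype=float))
    X_pos = _draw_group(rng, spec.n_pos, np.asarray(spec.mean_pos, float),
                        np.asarray(spec.sd_pos, float), chol, names)
    X_neg = _draw_group(rng, spec.n_neg, np.asarray(spec.mean_neg, float),
                        np.asarray(spec.sd_neg, float), chol, names)
    X = np.vstack([X_pos, X_neg])
    septic = np.zeros(n, dtype=bool)
    septic[: spec.n_pos] = True

    culture = np.zeros(n, dtype=bool)
    culture[: spec.n_pos] = rng.random(spec.n_pos) < spec.culture_fraction

    anc, abc, it = _derived_inputs(X, names)
    df = pd.DataFrame(X, columns=list(names))
    df.insert(0, "eval_id", [f"ev{i:06d}" for i in range(n)])
    df["anc"] = anc
    df["abc"] = abc
    df["it_ratio"] = it
    df["culture_positive"] = culture

    if spec.force_score_consistency:
        from .labeling import DEFAULT_THRESHOLDS

        _force_consistency(df, septic, DEFAULT_THRESHOLDS)

    df["true_group"] = np.where(culture, 1, np.where(septic, 2, 3))
    return df


def planted_panel_cohort(
    informative: Sequence[int] | Sequence[str],
    effect_size: float | Sequence[float] | Mapping[str, float],
    n_pos: int,
    n_neg: int,
    seed: int,
    *,
    corr: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cohort with a known planted informative panel, for recovery tests.

    ``informative`` may be biomarker indices or names; ``effect_size`` a
    scalar, a per-index sequence, or a name->effect mapping of standardized
    (pooled-SD) signed mean differences.  The noise biomarkers are
    independent by default (``corr=I``) so recovery is attributable to the
    planted means alone.  Returns ``(table, ground_truth)`` where
    ground_truth records the planted names, indices and effects.
    """
    if all(isinstance(b, str) for b in informative):
        idx = [BIOMARKERS.index(b) for b in informative]  # type: ignore[arg-type]
    else:
        idx = [int(b) for b in informative]
    if isinstance(effect_size, Mapping):
        eff = [float(effect_size[BIOMARKERS[j]]) for j in idx]
    elif np.isscalar(effect_size):
        eff = [float(effect_size)] * len(idx)
    else:
        eff = [float(e) for e in effect_size]
    if len(eff) != len(idx):
        raise ValueError("effect_size length must match informative set")
    if not all(np.isfinite(eff)):
        raise ValueError("effect sizes must be finite")
    effects = {BIOMARKERS[j]: e for j, e in zip(idx, eff)}
    spec = default_cohort_spec(
        n_pos, n_neg,
        effects=effects,
        corr=np.eye(len(BIOMARKERS)) if corr is None else corr,
        seed=seed,
    )
    table = generate_cohort(spec)
    truth = {
        "informative_names": [BIOMARKERS[j] for j in sorted(idx)],
        "informative_indices": sorted(idx),
        "effects": {BIOMARKERS[j]: e for j, e in zip(idx, eff)},
        "n_pos": n_pos,
        "n_neg": n_neg,
        "seed": seed,
    }
    return table, truth


def write_cohort_csv(df: pd.DataFrame, path: str | Path,
                     spec: CohortSpec | None = None) -> None:
    """Write a cohort CSV; if ``spec`` is given, a JSON sidecar
    (``<path>.spec.json``) records the full spec and seed for provenance."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    if spec is not None:
        sidecar = path.with_suffix(path.suffix + ".spec.json")
        sidecar.write_text(json.dumps(spec.to_dict(), indent=2))
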