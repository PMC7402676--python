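"""Initial chemical trait divergence within mixtures and moderator regressions.

Divergence of one trait among a mixture's component species is quantified by
Rao's quadratic entropy,

    Rao = sum_{i<j} d_ij p_i p_j,

the abundance-weighted expected difference between two randomly drawn
individuals, where d_ij is the mean character difference (1/n) sum_k
|X_ik - X_jk| over the n traits considered — here one trait at a time, so
d_ij is simply the absolute trait difference, in the trait's own units.

Mixture effects (study-averaged lnRR within the 10-40% null-mass-loss window,
the stage where non-additive effects peak) are then regressed on divergence,
or on site climate (MAT, MAP), by ordinary least squares. A leverage filter
lets each regression be re-run without its high-leverage points as a
sensitivity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effect_size import EffectSize
from .records_io import Dataset, TRAIT_NAMES

__all__ = [
    "TraitDivergence",
    "RegressionResult",
    "mean_character_difference",
    "rao_q",
    "dataset_divergences",
    "window_effect_per_study",
    "moderator_regression",
    "MASS_LOSS_WINDOW",
]

#: Null-mass-loss window (%) used for the trait-divergence regressions —
#: the decomposition stage with the strongest non-additive effects.
MASS_LOSS_WINDOW = (10.0, 40.0)


@dataclass(frozen=True)
class TraitDivergence:
    treatment_id: str
    trait: str
    rao: float  # trait units
    n_traits: int = 1


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided on the slope
    n_points: int


def mean_character_difference(
    traits_i: Sequence[float], traits_j: Sequence[float],
) -> float:
    """(1/n) sum_k |X_ik - X_jk|; with one trait this is the absolute
    difference."""
    if len(traits_i) != len(traits_j):
        raise ValueError("trait lists differ in length")
    if len(traits_i) == 0:
        raise ValueError("trait lists must be non-empty")
    n = len(traits_i)
    return math.fsum(abs(a - b) for a, b in zip(traits_i, traits_j)) / n


def rao_q(trait_values: Sequence[float], proportions: Sequence[float]) -> float:
    """Rao's quadratic entropy for one trait: the upper-triangle sum
    sum_{i<j} |x_i - x_j| p_i p_j (no factor 2)."""
    if len(trait_values) != len(proportions):
        raise ValueError("trait_values and proportions differ in length")
    s = len(trait_values)
    if s < 2:
        raise ValueError("need >= 2 components")
    if abs(math.fsum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    if any(x is None or (isinstance(x, float) and math.isnan(x)) for x in trait_values):
        raise ValueError("divergence undefined: missing trait value")
    total = 0.0
    for i in range(s - 1):
        for j in range(i + 1, s):
            total += mean_character_difference([trait_values[i]], [trait_values[j]]) \
                * proportions[i] * proportions[j]
    return total


def dataset_divergences(
    ds: Dataset,
    traits: Sequence[str] = TRAIT_NAMES,
) -> tuple[dict[str, dict[str, float]], list[dict]]:
    """Rao divergence of every trait for every mixture treatment.

    Traits with a missing value in any component are undefined for that
    treatment (logged; the treatment is excluded from that trait's
    regression only).
    """
    comp_by_tid: dict[str, list[tuple[str, float]]] = {}
    for r in ds.compositions.to_dict("records"):
        comp_by_tid.setdefault(r["treatment_id"], []).append(
            (r["species_id"], float(r["proportion"])))
    trait_by_sid = {r["species_id"]: r for r in ds.species.to_dict("records")}
    out: dict[str, dict[str, float]] = {}
    log: list[dict] = []
    for tid, comps in sorted(comp_by_tid.items()):
        sids = [s for s, _ in comps]
        props = [p for _, p in comps]
        vals_by_trait = {}
        for trait in traits:
            vals = [trait_by_sid[s].get(trait, float("nan")) for s in sids]
            vals = [float(v) if pd.notna(v) else float("nan") for v in vals]
            if any(math.isnan(v) for v in vals):
                log.append({"treatment_id": tid, "trait": trait,
                            "reason": "missing trait value; divergence undefined"})
                continue
            vals_by_trait[trait] = rao_q(vals, props)
        out[tid] = vals_by_trait
    return out, log


def window_effect_per_study(
    effects: Sequence[EffectSize],
    window: tuple[float, float] = MASS_LOSS_WINDOW,
) -> dict[str, float]:
    """One mass-loss effect value per study: the arithmetic mean of the
    study's lnRRs whose additive-null mass loss falls inside *window*
    (closed interval). Studies with no in-window effect are absent from the
    result (excluded from the divergence regressions)."""
    lo, hi = window
    per_study: dict[str, list[float]] = {}
    for e in effects:
        if lo <= e.expected_mass_loss <= hi:
            per_study.setdefault(e.study_id, []).append(e.lnrr)
    return {s: float(np.mean(vals)) for s, vals in sorted(per_study.items())}


def _leverage(x: np.ndarray) -> np.ndarray:
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    return 1.0 / n + (x - x.mean()) ** 2 / sxx


def moderator_regression(
    x: Sequence[float],
    y: Sequence[float],
    weights: Sequence[float] | None = None,
    exclude_leverage_above: float | None = None,
) -> RegressionResult:
    """OLS of effect size on a continuous moderator.

    Parameters
    ----------
    weights
        Optional inverse-variance weights (weighted meta-regression);
        default is plain OLS.
    exclude_leverage_above
        If set, points with hat value above this threshold (e.g. ``4/n``)
        are dropped before fitting — the sensitivity harness for clusters of
        extreme moderator values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression inputs")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate regressor: zero variance in x")
    if np.ptp(y) == 0.0:  # flat response: no fit to speak of
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                                p_value=1.0, n_points=int(x.size))
    if exclude_leverage_above is not None:
        keep = _leverage(x) <= exclude_leverage_above
        if keep.sum() < 3:
            raise ValueError("leverage filter leaves fewer than 3 points")
        x, y = x[keep], y[keep]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)[keep]
    if weights is None:
        res = stats.linregress(x, y)
        return RegressionResult(
            slope=float(res.slope), intercept=float(res.intercept),
            r_squared=float(res.rvalue**2), p_value=float(res.pvalue),
            n_points=int(x.size))
    w = np.asarray(weights, dtype=float)
    sw = w.sum()
    xm, ym = np.sum(w * x) / sw, np.sum(w * y) / sw
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    slope = float(sxy / sxx)
    intercept = float(ym - slope * xm)
    resid = y - intercept - slope * x
    dof = x.size - 2
    s2 = float(np.sum(w * resid**2) / dof)
    se = math.sqrt(s2 / sxx)
    t = slope / se if se > 0 else float("inf")
    p = 2.0 * float(stats.t.sf(abs(t), dof))
    syy = float(np.sum(w * (y - ym) ** 2))
    r2 = 1.0 - float(np.sum(w * resid**2)) / syy if syy > 0 else 0.0
    return RegressionResult(slope=slope, intercept=intercept,
                            r_squared=max(0.0, min(1.0, r2)), p_value=p,
                            n_points=int(x.size))
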