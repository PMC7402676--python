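"""Random-effects meta-analysis with bootstrap confidence intervals.

Pooling follows the classical inverse-variance random-effects model with the
DerSimonian–Laird moment estimator of the between-observation variance tau^2:

    Q       = sum w_i (y_i - theta_FE)^2,      w_i = 1 / v_i
    tau^2   = max(0, (Q - (k - 1)) / (sum w - sum w^2 / sum w))
    theta   = sum w*_i y_i / sum w*_i,         w*_i = 1 / (v_i + tau^2)

Confidence intervals are nonparametric bootstrap intervals: effect sizes are
resampled with replacement at the observation level, tau^2 and the pooled
effect are recomputed for every replicate, and the 95% interval is read off
the replicate distribution either as plain percentiles or with the
bias-corrected adjustment (the default). REML is available as an alternative
tau^2 estimator behind a flag.

Subgroup (categorical moderator) analysis partitions the total heterogeneity
Q_total, computed with fixed-effect weights so the identity
Q_total = Q_between + Q_within is exact, and pools each group with
random-effects weights using a within-group pooled tau^2 (the classical
mixed-model convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .effect_size import EffectSize, percent_effect

__all__ = [
    "Direction",
    "MetaResult",
    "SubgroupResult",
    "dl_tau_squared",
    "reml_tau_squared",
    "pooled_effect",
    "bootstrap_ci",
    "meta_analysis",
    "subgroup_analysis",
]

logger = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP_REPS = 4999


class Direction(str, Enum):
    synergistic = "synergistic"
    antagonistic = "antagonistic"
    additive = "additive"


class CIMethod(str, Enum):
    percentile = "percentile"
    bias_corrected = "bias_corrected"


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect for one set of effect sizes."""

    k: int
    pooled_lnrr: float
    tau_squared: float
    ci_low: float | None
    ci_high: float | None
    significant: bool | None  # None when no CI could be computed
    direction: Direction | None
    percent_effect: float
    low_n: bool = False  # flagged: sample size too low for inference

    def to_dict(self) -> dict:
        return {
            "k": self.k, "pooled_lnrr": self.pooled_lnrr,
            "tau_squared": self.tau_squared,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "significant": self.significant,
            "direction": self.direction.value if self.direction else None,
            "percent_effect": self.percent_effect, "low_n": self.low_n,
        }


@dataclass(frozen=True)
class SubgroupResult:
    groups: Mapping[str, MetaResult]
    q_total: float
    q_between: float
    q_within: float
    df_between: int
    df_within: int
    p_between: float
    tau_squared_pooled: float

    def to_dict(self) -> dict:
        return {
            "groups": {g: r.to_dict() for g, r in self.groups.items()},
            "q_total": self.q_total, "q_between": self.q_between,
            "q_within": self.q_within, "df_between": self.df_between,
            "df_within": self.df_within, "p_between": self.p_between,
            "tau_squared_pooled": self.tau_squared_pooled,
        }


def _to_arrays(effects) -> tuple[np.ndarray, np.ndarray]:
    """Accept a sequence of EffectSize or of (lnRR, variance) pairs."""
    if len(effects) and isinstance(effects[0], EffectSize):
        y = np.array([e.lnrr for e in effects], dtype=float)
        v = np.array([e.variance for e in effects], dtype=float)
    else:
        arr = np.asarray(effects, dtype=float)
        y, v = arr[:, 0], arr[:, 1]
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0")
    return y, v


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _q_statistic(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    w = 1.0 / v
    theta_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - theta_fe) ** 2))
    return q, theta_fe


def dl_tau_squared(effects) -> float:
    """DerSimonian–Laird moment estimate of the between-observation variance."""
    y, v = _to_arrays(effects)
    k = y.size
    if k < 2:
        logger.warning("tau^2 undefined for k < 2; returning 0")
        return 0.0
    w = 1.0 / v
    q, _ = _q_statistic(y, v)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / c)


def reml_tau_squared(effects, tol: float = 1e-10) -> float:
    """Restricted maximum-likelihood tau^2 (alternative estimator)."""
    y, v = _to_arrays(effects)
    k = y.size
    if k < 2:
        return 0.0

    def neg_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        theta = np.sum(wi * y) / np.sum(wi)
        return float(0.5 * (np.sum(np.log(v + tau2))
                            + np.log(np.sum(wi))
                            + np.sum(wi * (y - theta) ** 2)))

    upper = max(10.0 * float(np.var(y)), 1e-3)
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, upper),
                                   method="bounded", options={"xatol": tol})
    return max(0.0, float(res.x))


def pooled_effect(effects, tau_squared: float) -> float:
    """Random-effects weighted mean with weights 1 / (v_i + tau^2)."""
    y, v = _to_arrays(effects)
    if y.size < 1:
        raise ValueError("need at least one effect")
    w = 1.0 / (v + tau_squared)
    return float(np.sum(w * y) / np.sum(w))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _replicate_estimates(y: np.ndarray, v: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pooled RE estimate for each bootstrap replicate (rows of idx),
    re-estimating DL tau^2 per replicate. Fully vectorized."""
    k = idx.shape[1]
    yb, vb = y[idx], v[idx]
    w = 1.0 / vb
    sw = w.sum(axis=1)
    theta_fe = (w * yb).sum(axis=1) / sw
    q = (w * (yb - theta_fe[:, None]) ** 2).sum(axis=1)
    c = sw - (w**2).sum(axis=1) / sw
    with np.errstate(divide="ignore", invalid="ignore"):
        tau2 = np.where(c > 0, (q - (k - 1)) / c, 0.0)
    tau2 = np.maximum(tau2, 0.0)
    ws = 1.0 / (vb + tau2[:, None])
    return (ws * yb).sum(axis=1) / ws.sum(axis=1)


def _interval_from_replicates(
    thetas: np.ndarray, theta_hat: float, method: CIMethod, level: float = 0.95,
) -> tuple[float, float]:
    alpha = 1.0 - level
    if np.ptp(thetas) == 0.0:
        return float(thetas[0]), float(thetas[0])
    if method is CIMethod.percentile:
        lo, hi = np.quantile(thetas, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)
    # bias-corrected percentile (BC; no acceleration term)
    b = thetas.size
    prop = np.clip(np.mean(thetas < theta_hat), 1.0 / (b + 1), b / (b + 1.0))
    z0 = stats.norm.ppf(prop)
    zlo, zhi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    qlo = stats.norm.cdf(2 * z0 + zlo)
    qhi = stats.norm.cdf(2 * z0 + zhi)
    lo, hi = np.quantile(thetas, [qlo, qhi])
    return float(lo), float(hi)


def bootstrap_ci(
    effects,
    reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | np.random.Generator = 0,
    method: CIMethod | str = CIMethod.bias_corrected,
    level: float = 0.95,
) -> tuple[float, float]:
    """95% bootstrap CI for the pooled random-effects estimate.

    Effect sizes are resampled with replacement at the observation level;
    tau^2 and the pooled effect are recomputed per replicate. Deterministic
    given the seed.
    """
    y, v = _to_arrays(effects)
    k = y.size
    if k < 2:
        raise ValueError("cannot bootstrap a single observation")
    if reps < 999:
        raise ValueError("reps must be >= 999 for stable 2.5% tails")
    method = CIMethod(method)
    rng = _rng(seed)
    idx = rng.integers(0, k, size=(reps, k))
    thetas = _replicate_estimates(y, v, idx)
    theta_hat = pooled_effect(effects, dl_tau_squared(effects))
    return _interval_from_replicates(thetas, theta_hat, method, level)


def _classify(pooled: float, ci: tuple[float, float] | None) -> tuple[bool | None, Direction | None]:
    if ci is None:
        return None, None
    significant = not (ci[0] <= 0.0 <= ci[1])
    if not significant:
        return False, Direction.additive
    return True, Direction.synergistic if pooled > 0 else Direction.antagonistic


def meta_analysis(
    effects,
    reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | np.random.Generator = 0,
    method: CIMethod | str = CIMethod.bias_corrected,
    tau_estimator: str = "DL",
    min_k_ci: int = 2,
) -> MetaResult:
    """Full random-effects pooling of one set of effect sizes.

    Groups with fewer than *min_k_ci* effects are reported with a point
    estimate only, flagged ``low_n`` (sample size too low for inference).
    """
    y, v = _to_arrays(effects)
    k = y.size
    if k == 0:
        return MetaResult(k=0, pooled_lnrr=float("nan"), tau_squared=0.0,
                          ci_low=None, ci_high=None, significant=None,
                          direction=None, percent_effect=float("nan"), low_n=True)
    pairs = np.column_stack([y, v])
    tau2 = (reml_tau_squared(pairs) if tau_estimator.upper() == "REML"
            else dl_tau_squared(pairs))
    pooled = pooled_effect(pairs, tau2)
    if k < max(2, min_k_ci):
        return MetaResult(k=k, pooled_lnrr=pooled, tau_squared=tau2,
                          ci_low=None, ci_high=None, significant=None,
                          direction=None, percent_effect=percent_effect(pooled),
                          low_n=True)
    ci = bootstrap_ci(pairs, reps=reps, seed=seed, method=method)
    significant, direction = _classify(pooled, ci)
    return MetaResult(k=k, pooled_lnrr=pooled, tau_squared=tau2,
                      ci_low=ci[0], ci_high=ci[1], significant=significant,
                      direction=direction, percent_effect=percent_effect(pooled))


# ---------------------------------------------------------------------------
# Subgroup analysis
# ---------------------------------------------------------------------------

def _group_arrays(effects: Sequence, labels: Sequence[str]):
    y, v = _to_arrays(effects)
    labels = np.asarray(labels, dtype=object)
    order = sorted(set(labels.tolist()), key=str)
    return y, v, labels, order


def heterogeneity_partition(
    y: np.ndarray, v: np.ndarray, labels: np.ndarray,
) -> tuple[float, float, float, int, int]:
    """Q_total about the grand FE mean, Q_within summed over group FE means,
    Q_between as the difference; all with fixed-effect weights 1/v so the
    partition is exact."""
    q_total, _ = _q_statistic(y, v)
    q_within = 0.0
    groups = sorted(set(labels.tolist()), key=str)
    for g in groups:
        m = labels == g
        if m.sum() >= 2:
            qg, _ = _q_statistic(y[m], v[m])
            q_within += qg
    q_between = q_total - q_within
    df_between = len(groups) - 1
    df_within = int(y.size - len(groups))
    return q_total, q_between, q_within, df_between, df_within


def _pooled_within_tau2(y, v, labels, order) -> float:
    """Within-group pooled DL tau^2 (mixed-model convention)."""
    q_within = 0.0
    df_within = 0
    c_sum = 0.0
    for g in order:
        m = labels == g
        kg = int(m.sum())
        if kg < 2:
            continue
        w = 1.0 / v[m]
        qg, _ = _q_statistic(y[m], v[m])
        q_within += qg
        df_within += kg - 1
        c_sum += float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c_sum <= 0:
        return 0.0
    return max(0.0, (q_within - df_within) / c_sum)


def subgroup_analysis(
    effects,
    labels: Sequence[str],
    reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | np.random.Generator = 0,
    method: CIMethod | str = CIMethod.bias_corrected,
    min_k_ci: int = 2,
) -> SubgroupResult:
    """Categorical-moderator analysis: per-group pooled effects with joint
    bootstrap CIs and the Q_total = Q_between + Q_within partition.

    Per replicate, every group is resampled within itself and the pooled
    within-group tau^2 is re-estimated from the whole resample, so the
    per-group intervals share the mixed-model variance structure.
    """
    method = CIMethod(method)
    y, v, lab, order = _group_arrays(effects, labels)
    if y.size == 0:
        raise ValueError("no effects supplied")
    q_total, q_between, q_within, df_b, df_w = heterogeneity_partition(y, v, lab)
    p_between = float(stats.chi2.sf(q_between, df_b)) if df_b > 0 else float("nan")
    tau2_pooled = _pooled_within_tau2(y, v, lab, order)

    rng = _rng(seed)
    group_masks = {g: lab == g for g in order}
    # joint bootstrap: one resample per group per replicate
    boot_thetas: dict[str, np.ndarray] = {}
    boot_idx = {}
    for g in order:
        kg = int(group_masks[g].sum())
        if kg >= 2:
            boot_idx[g] = rng.integers(0, kg, size=(reps, kg))
    if boot_idx:
        # pooled tau^2 per replicate from all resampled groups
        q_w = np.zeros(reps)
        df_w_b = 0
        c_b = np.zeros(reps)
        for g, idx in boot_idx.items():
            yg, vg = y[group_masks[g]], v[group_masks[g]]
            yb, vb = yg[idx], vg[idx]
            w = 1.0 / vb
            sw = w.sum(axis=1)
            th = (w * yb).sum(axis=1) / sw
            q_w += (w * (yb - th[:, None]) ** 2).sum(axis=1)
            df_w_b += idx.shape[1] - 1
            c_b += sw - (w**2).sum(axis=1) / sw
        with np.errstate(divide="ignore", invalid="ignore"):
            tau2_b = np.where(c_b > 0, (q_w - df_w_b) / c_b, 0.0)
        tau2_b = np.maximum(tau2_b, 0.0)
        for g, idx in boot_idx.items():
            yg, vg = y[group_masks[g]], v[group_masks[g]]
            yb, vb = yg[idx], vg[idx]
            ws = 1.0 / (vb + tau2_b[:, None])
            boot_thetas[g] = (ws * yb).sum(axis=1) / ws.sum(axis=1)

    groups: dict[str, MetaResult] = {}
    for g in order:
        m = group_masks[g]
        kg = int(m.sum())
        pooled = pooled_effect(np.column_stack([y[m], v[m]]), tau2_pooled)
        if kg < max(2, min_k_ci) or g not in boot_thetas:
            groups[str(g)] = MetaResult(
                k=kg, pooled_lnrr=pooled, tau_squared=tau2_pooled,
                ci_low=None, ci_high=None, significant=None, direction=None,
                percent_effect=percent_effect(pooled), low_n=True)
            continue
        ci = _interval_from_replicates(boot_thetas[g], pooled, method)
        significant, direction = _classify(pooled, ci)
        groups[str(g)] = MetaResult(
            k=kg, pooled_lnrr=pooled, tau_squared=tau2_pooled,
            ci_low=ci[0], ci_high=ci[1], significant=significant,
            direction=direction, percent_effect=percent_effect(pooled))
    return SubgroupResult(groups=groups, q_total=q_total, q_between=q_between,
                          q_within=q_within, df_between=df_b, df_within=df_w,
                          p_between=p_between, tau_squared_pooled=tau2_pooled)
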