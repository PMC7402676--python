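"""Decomposition-stage binning and per-interval meta-analysis.

Mixture effects shift as decomposition proceeds. To localise them, paired
observations from *all* harvests are binned by their additive-null mass loss
into 10%-wide intervals up to 70%, with a single terminal 70-100% interval
(late-stage observations are scarce). Each interval is then pooled as its own
random-effects meta-analysis with a bootstrap CI.

Binning always uses the expected (additive-null) mass loss, not the observed
mixture mass loss, so stage assignment is independent of the effect being
estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .effect_size import EffectSize, compute_effects, percent_effect
from .meta_model import DEFAULT_BOOTSTRAP_REPS, CIMethod, MetaResult, meta_analysis
from .mixture_null import PairedObservation, Response

__all__ = ["MassLossInterval", "INTERVALS", "assign_interval", "staged_meta"]


@dataclass(frozen=True)
class MassLossInterval:
    label: str
    lower: float
    upper: float

    def __contains__(self, value: float) -> bool:
        if self.upper == 100.0:  # terminal interval closed at 100
            return self.lower <= value <= 100.0
        return self.lower <= value < self.upper


#: The eight intervals partition [0, 100]: half-open [lower, upper) bins of
#: 10% up to 70%, then one closed terminal bin 70-100%.
INTERVALS: tuple[MassLossInterval, ...] = tuple(
    MassLossInterval(f"{lo}-{hi}", float(lo), float(hi))
    for lo, hi in [(0, 10), (10, 20), (20, 30), (30, 40),
                   (40, 50), (50, 60), (60, 70), (70, 100)]
)


def assign_interval(expected_mass_loss: float) -> MassLossInterval:
    """Bin an additive-null mass loss (%) into its stage interval."""
    if not 0.0 <= expected_mass_loss <= 100.0:
        raise ValueError(
            f"expected_mass_loss must be in [0, 100], got {expected_mass_loss}")
    for interval in INTERVALS:
        if expected_mass_loss in interval:
            return interval
    raise AssertionError("intervals do not partition [0, 100]")  # pragma: no cover


def staged_meta(
    pairs: Sequence[PairedObservation],
    response: Response | str = Response.mass_loss,
    reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | np.random.Generator = 0,
    method: CIMethod | str = CIMethod.bias_corrected,
    collapse_per_study: bool = False,
    min_k_ci: int = 2,
) -> tuple[dict[str, MetaResult], list[dict]]:
    """Per-interval random-effects meta-analysis over all-harvest pairs.

    Parameters
    ----------
    pairs
        All-harvest paired observations (every response; filtered here).
    collapse_per_study
        If True, multiple harvests of one study falling in the same interval
        are first averaged (inverse-variance weights are then the sum of the
        component weights); default keeps them as separate observations.

    Returns the interval -> MetaResult table (intervals with k < min_k_ci are
    reported flagged, empty intervals with k = 0) and the effect-size
    exclusion log.
    """
    response = Response(response)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    effects, exclusions = compute_effects(
        [p for p in pairs if p.response is response])

    by_interval: dict[str, list[EffectSize]] = {iv.label: [] for iv in INTERVALS}
    for e in effects:
        by_interval[assign_interval(e.expected_mass_loss).label].append(e)

    results: dict[str, MetaResult] = {}
    for iv in INTERVALS:
        evs = by_interval[iv.label]
        if collapse_per_study and evs:
            collapsed = []
            frame = pd.DataFrame({"study": [e.study_id for e in evs],
                                  "y": [e.lnrr for e in evs],
                                  "v": [e.variance for e in evs]})
            for _, sub in frame.groupby("study"):
                y = float(sub["y"].mean())
                v = float(sub["v"].sum() / len(sub) ** 2)  # variance of the mean
                collapsed.append((y, v))
            pairs_yv = collapsed
        else:
            pairs_yv = [(e.lnrr, e.variance) for e in evs]
        if not pairs_yv:
            results[iv.label] = MetaResult(
                k=0, pooled_lnrr=float("nan"), tau_squared=0.0, ci_low=None,
                ci_high=None, significant=None, direction=None,
                percent_effect=float("nan"), low_n=True)
            continue
        results[iv.label] = meta_analysis(
            pairs_yv, reps=reps, seed=rng, method=method, min_k_ci=min_k_ci)
    return results, exclusions


def staging_table(results: dict[str, MetaResult]) -> pd.DataFrame:
    """Flatten a staged_meta result into the audit table."""
    rows = []
    for label, r in results.items():
        rows.append({"interval": label, "k": r.k, "pooled_lnrr": r.pooled_lnrr,
                     "percent_effect": r.percent_effect,
                     "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "significant": r.significant,
                     "direction": r.direction.value if r.direction else None,
                     "low_n": r.low_n})
    return pd.DataFrame(rows)
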