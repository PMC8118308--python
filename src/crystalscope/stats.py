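"""Crystal-burden quantification and two-group statistics.

Burden is the reflectance-bright crystal area inside a plaque divided by
the plaque area, as a percent. Group comparisons use the Mann-Whitney U
test (exact enumeration for small samples, tie-corrected normal
approximation with continuity correction otherwise) and Student t tests
(unpaired pooled-variance by default, Welch and paired variants available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .io import IntensityImage
from .morphometry import MorphometryResult, otsu_threshold

__all__ = [
    "BurdenResult",
    "ComparisonMethod",
    "GroupComparison",
    "compute_burden",
    "mann_whitney_u",
    "t_test",
    "compare_study",
]

EXACT_ENUMERATION_MAX_N = 12


@dataclass
class BurdenResult:
    crystal_area_um2: float
    plaque_area_um2: float
    burden_percent: float
    threshold_value: float

    def to_dict(self) -> dict:
        return {
            "crystal_area_um2": self.crystal_area_um2,
            "plaque_area_um2": self.plaque_area_um2,
            "burden_percent": self.burden_percent,
            "threshold_value": self.threshold_value,
        }


class ComparisonMethod(str, Enum):
    MANN_WHITNEY_U = "MANN_WHITNEY_U"
    T_UNPAIRED = "T_UNPAIRED"
    T_WELCH = "T_WELCH"
    T_PAIRED = "T_PAIRED"


@dataclass
class GroupComparison:
    method: ComparisonMethod
    statistic: float
    p_value: float
    n_per_group: tuple[int, int]
    effect_direction: str  # "a_greater" | "b_greater" | "none"

    def to_dict(self) -> dict:
        return {
            "method": self.method.value,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": list(self.n_per_group),
            "effect_direction": self.effect_direction,
        }


def compute_burden(
    reflectance: IntensityImage,
    plaque_mask: np.ndarray,
    threshold_strategy: str | float = "otsu_within_plaque",
    min_contrast: float = 1.5,
) -> BurdenResult:
    """Crystal burden of a reflectance section.

    The crystal mask is the set of plaque pixels above a threshold — Otsu
    restricted to plaque pixels (default; the dark exterior would otherwise
    dominate the histogram) or a fixed value — and the burden is the
    crystal/plaque area ratio in percent. Areas are physical (um^2).

    Otsu always finds a split even in a crystal-free plaque, so with the
    Otsu strategy the above-threshold class only counts as crystal when its
    mean exceeds ``min_contrast`` times the below-threshold mean; otherwise
    the burden is zero.
    """
    mask = np.asarray(plaque_mask, dtype=bool)
    if mask.shape != reflectance.shape:
        raise ValueError("plaque mask shape does not match the image")
    n_plaque = int(mask.sum())
    if n_plaque == 0:
        raise ValueError("plaque mask is empty")
    inside = reflectance.pixels[mask]
    if isinstance(threshold_strategy, (int, float)):
        thr = float(threshold_strategy)
    elif threshold_strategy == "otsu_within_plaque":
        thr, _ = otsu_threshold(inside.reshape(1, -1))
        hi, lo = inside[inside > thr], inside[inside <= thr]
        if hi.size == 0 or lo.size == 0 or hi.mean() < min_contrast * max(lo.mean(), 1e-12):
            px_area = reflectance.pixel_size_um**2
            return BurdenResult(0.0, n_plaque * px_area, 0.0, thr)
    else:
        raise ValueError(f"unknown threshold strategy {threshold_strategy!r}")
    crystal = (reflectance.pixels > thr) & mask
    px_area = reflectance.pixel_size_um**2
    n_crystal = int(crystal.sum())
    return BurdenResult(
        crystal_area_um2=n_crystal * px_area,
        plaque_area_um2=n_plaque * px_area,
        burden_percent=100.0 * n_crystal / n_plaque,
        threshold_value=thr,
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample a from midrank sums."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2.0)


def _exact_u_pvalue(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n1+n2, n1) group labelings.

    Ties are handled through midranks: the null distribution of U is built
    over all ways of assigning the pooled (mid)ranks to group A.
    p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    offset = n1 * (n1 + 1) / 2.0
    us = np.array(
        [sum(c) - offset for c in combinations(ranks, n1)]
    )
    n = len(us)
    eps = 1e-9
    p_le = np.sum(us <= u_obs + eps) / n
    p_ge = np.sum(us >= u_obs - eps) / n
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_u_pvalue(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided normal approximation with tie-corrected variance and
    continuity correction."""
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return 1.0
    diff = u_obs - mu
    # continuity correction toward the mean
    cc = 0.5 if diff != 0 else 0.0
    z = (diff - math.copysign(cc, diff)) / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def mann_whitney_u(sample_a, sample_b) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    The statistic is U of sample A (in [0, n1*n2]). The p-value comes from
    exact enumeration of all group labelings when n1+n2 <= 12, and from the
    tie-corrected normal approximation with continuity correction
    otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    if a.size + b.size <= EXACT_ENUMERATION_MAX_N:
        p = _exact_u_pvalue(a, b, u)
    else:
        p = _normal_u_pvalue(a, b, u)
    mu = a.size * b.size / 2.0
    direction = "a_greater" if u > mu else ("b_greater" if u < mu else "none")
    return GroupComparison(
        method=ComparisonMethod.MANN_WHITNEY_U,
        statistic=u,
        p_value=p,
        n_per_group=(a.size, b.size),
        effect_direction=direction,
    )


def t_test(
    sample_a,
    sample_b,
    paired: bool = False,
    equal_variance: bool = True,
) -> GroupComparison:
    """Two-sided Student t test (pooled variance by default).

    ``paired=True`` requires equal-length samples; ``equal_variance=False``
    selects the Welch variant for the unpaired test.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t test requires n >= 2 per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired t test requires equal sample sizes")
        res = sps.ttest_rel(a, b)
        method = ComparisonMethod.T_PAIRED
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_variance)
        method = ComparisonMethod.T_UNPAIRED if equal_variance else ComparisonMethod.T_WELCH
    stat = float(res.statistic)
    direction = "a_greater" if stat > 0 else ("b_greater" if stat < 0 else "none")
    return GroupComparison(
        method=method,
        statistic=stat,
        p_value=float(res.pvalue),
        n_per_group=(a.size, b.size),
        effect_direction=direction,
    )


_METRIC_GETTERS = {
    "density_per_mm2": lambda r: r.density_per_mm2,
    "mean_length_um": lambda r: r.length_mean_um,
    "median_length_um": lambda r: r.length_median_um,
    "burden_percent": lambda r: r.burden_percent,
}


def _metric_values(results, metric: str) -> np.ndarray:
    getter = _METRIC_GETTERS.get(metric)
    if getter is None:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRIC_GETTERS)}")
    return np.array([getter(r) for r in results], dtype=float)


def compare_study(
    group_results: dict[str, list],
    metric: str,
    method: ComparisonMethod | str = ComparisonMethod.MANN_WHITNEY_U,
    animal_ids: dict[str, list] | None = None,
) -> GroupComparison:
    """Compare a per-image metric between two groups.

    ``group_results`` maps group name to a list of per-image results
    (:class:`~crystalscope.morphometry.MorphometryResult` or
    :class:`BurdenResult`). Values are pooled per group; when
    ``animal_ids`` is given (same structure, one id per image), per-image
    values are first averaged within animal so the test runs on animal
    means.
    """
    if len(group_results) != 2:
        raise ValueError(f"exactly two groups required, got {len(group_results)}")
    method = ComparisonMethod(method)
    (name_a, res_a), (name_b, res_b) = group_results.items()
    vals = {}
    for name, results in ((name_a, res_a), (name_b, res_b)):
        v = _metric_values(results, metric)
        if animal_ids is not None:
            ids = np.asarray(animal_ids[name])
            if len(ids) != len(v):
                raise ValueError(f"animal_ids for group {name!r} do not match its image count")
            v = np.array([v[ids == i].mean() for i in np.unique(ids)])
        vals[name] = v
    a, b = vals[name_a], vals[name_b]
    if method is ComparisonMethod.MANN_WHITNEY_U:
        return mann_whitney_u(a, b)
    if method is ComparisonMethod.T_PAIRED:
        return t_test(a, b, paired=True)
    return t_test(a, b, equal_variance=method is ComparisonMethod.T_UNPAIRED)
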