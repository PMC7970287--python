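"""Cluster-trial design: power, cluster requirements, stratified
randomisation, and the village eligibility screen.

Power for a two-arm comparison of cluster means uses the design-effect
normal approximation: with ``m`` participants per cluster and intracluster
correlation ``rho``, the variance of the mean difference is inflated by
``DE = 1 + (m - 1) rho``, giving

    SE = sd * sqrt(DE * (1/(k_t m) + 1/(k_c m)))
    power = Phi(|delta| / SE - z_{1 - alpha/2})

A cluster-degrees-of-freedom t variant (``use_t=True``) is available and is
slightly more conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil, gcd

import numpy as np
import pandas as pd
import scipy.stats


@dataclass(frozen=True)
class DesignSpec:
    """Inputs of the cluster sample-size calculation."""

    delta: float = 2.0         # target mean difference
    sd: float = 3.3            # outcome SD
    icc: float = 0.20
    m: int = 20                # participants per cluster
    alpha: float = 0.05
    power_target: float = 0.80
    k_treatment: int | None = None
    k_control: int | None = None

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0 <= self.icc < 1:
            raise ValueError("icc must lie in [0, 1)")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power_target < 1:
            raise ValueError("power_target must lie in (0, 1)")


@dataclass(frozen=True)
class AllocationPlan:
    """Cluster counts per arm within each randomisation stratum."""

    strata: dict[str, dict[str, int]]

    def __post_init__(self):
        for stratum, arms in self.strata.items():
            for arm, k in arms.items():
                if k < 0:
                    raise ValueError(
                        f"negative cluster count for {arm!r} in stratum {stratum!r}")

    def total(self, stratum: str) -> int:
        return sum(self.strata[stratum].values())


def design_effect(m: int, icc: float) -> float:
    """Variance inflation ``1 + (m - 1) * icc`` of an m-per-cluster design."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= icc < 1:
        raise ValueError("icc must lie in [0, 1)")
    return 1.0 + (m - 1) * icc


def power(spec: DesignSpec, use_t: bool = False) -> float:
    """Power of the two-sided two-sample comparison under the design."""
    if not spec.k_treatment or not spec.k_control:
        raise ValueError("k_treatment and k_control must be positive")
    de = design_effect(spec.m, spec.icc)
    se = spec.sd * np.sqrt(de * (1.0 / (spec.k_treatment * spec.m)
                                 + 1.0 / (spec.k_control * spec.m)))
    ncp = abs(spec.delta) / se
    if use_t:
        # t with cluster-level degrees of freedom: k_t + k_c - 2
        dof = spec.k_treatment + spec.k_control - 2
        crit = scipy.stats.t.ppf(1 - spec.alpha / 2, dof)
        return float(scipy.stats.nct.sf(crit, dof, ncp))
    crit = scipy.stats.norm.ppf(1 - spec.alpha / 2)
    return float(scipy.stats.norm.cdf(ncp - crit))


def required_clusters(spec: DesignSpec, allocation_ratio: tuple[int, int] = (8, 15),
                      use_t: bool = False, max_multiplier: int = 10_000
                      ) -> tuple[int, int]:
    """Smallest (k_treatment, k_control) on the given ratio reaching the
    target power; raises if the target is unreachable (e.g. delta = 0)."""
    if spec.delta == 0:
        raise ValueError("power target unreachable with delta = 0")
    rt, rc = allocation_ratio
    if rt <= 0 or rc <= 0:
        raise ValueError("allocation ratio parts must be positive")
    g = gcd(rt, rc)
    rt, rc = rt // g, rc // g
    for s in range(1, max_multiplier + 1):
        kt, kc = rt * s, rc * s
        if power(replace(spec, k_treatment=kt, k_control=kc), use_t=use_t) \
                >= spec.power_target:
            return kt, kc
    raise ValueError(
        f"power target {spec.power_target} not reached within "
        f"{max_multiplier}x the allocation ratio")


def randomize(villages: pd.DataFrame, plan: AllocationPlan, seed: int | None = None
              ) -> pd.DataFrame:
    """Stratified random arm assignment honouring the plan's counts.

    ``villages`` needs ``village_id`` and ``stratum`` columns; each
    stratum's village count must match the plan's total for that stratum.
    Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = villages.copy()
    out["arm"] = None
    for stratum, grp in villages.groupby("stratum"):
        if stratum not in plan.strata:
            raise ValueError(f"stratum {stratum!r} not in the allocation plan")
        counts = plan.strata[stratum]
        if len(grp) != sum(counts.values()):
            raise ValueError(
                f"stratum {stratum!r}: {len(grp)} villages but plan allocates "
                f"{sum(counts.values())}")
        labels = np.repeat([a for a in sorted(counts)],
                           [counts[a] for a in sorted(counts)])
        rng.shuffle(labels)
        out.loc[grp.index, "arm"] = labels
    return out


def screen_villages(village_stats: pd.DataFrame, district_means: dict[str, float],
                    district_sds: dict[str, float], threshold: float = 1.5
                    ) -> pd.DataFrame:
    """Eligibility screen on demographic balance.

    Keeps villages whose every screened statistic lies within ``threshold``
    district SDs of the district mean (|z| <= threshold). Statistics are the
    keys of ``district_means``; a zero district SD is an error.
    """
    z_ok = np.ones(len(village_stats), dtype=bool)
    for stat, mean in district_means.items():
        sd = district_sds[stat]
        if sd == 0:
            raise ValueError(f"district SD for {stat!r} is zero")
        z = (village_stats[stat].to_numpy(float) - mean) / sd
        z_ok &= np.abs(z) <= threshold
    return village_stats.loc[z_ok].copy()
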