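"""Internal age-standardisation of development scores.

Raw development scores (milestone-domain raws, their total, vocabulary
counts) are z-scored against age-conditional means and SDs estimated from
the trial's own control arm, rather than external norms: for a child of age
``a`` with raw score ``x``, ``z = (x - mean(a)) / sd(a)``. Scores more than
4 control-arm SDs from the age-conditional mean (|z| > 4) are flagged for
exclusion, which is why analysed n differs across development outcomes.

The default estimator of the age-conditional moments bins age (3-month
bins, sparse bins merged with their neighbour); a quadratic-mean /
linear-SD regression alternative is available via ``method='polynomial'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .synthetic import TrialDataset


class StandardizationError(ValueError):
    pass


@dataclass
class AgeStandardizer:
    """Fitted age-conditional mean/SD model (control arm only)."""

    outcome: str
    method: str                      # 'age_bins' | 'polynomial'
    fit_n: int
    fit_arm: str = "control"
    # age_bins representation
    bin_edges: np.ndarray | None = None     # len k+1
    bin_means: np.ndarray | None = None     # len k
    bin_sds: np.ndarray | None = None       # len k
    # polynomial representation
    mean_coef: np.ndarray | None = None     # [c0, c1, c2] of c0 + c1*a + c2*a^2
    sd_coef: np.ndarray | None = None       # [d0, d1] of d0 + d1*a
    age_min: float = 0.0
    age_max: float = np.inf
    exclusion_threshold: float = 4.0

    def _bin_index(self, age: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.bin_edges, age, side="right") - 1
        return np.clip(idx, 0, len(self.bin_means) - 1)  # edge ages clamp

    def mean_model(self, age):
        age = np.asarray(age, float)
        if self.method == "age_bins":
            out = self.bin_means[self._bin_index(age)]
        else:
            a = np.clip(age, self.age_min, self.age_max)
            out = self.mean_coef[0] + self.mean_coef[1] * a + self.mean_coef[2] * a ** 2
        return out if out.shape else float(out)

    def sd_model(self, age):
        age = np.asarray(age, float)
        if self.method == "age_bins":
            out = self.bin_sds[self._bin_index(age)]
        else:
            a = np.clip(age, self.age_min, self.age_max)
            out = np.maximum(self.sd_coef[0] + self.sd_coef[1] * a, 1e-8)
        return out if out.shape else float(out)

    # --- audit serialisation ----------------------------------------------
    def to_yaml(self) -> str:
        d = {
            "outcome": self.outcome, "method": self.method, "fit_n": self.fit_n,
            "fit_arm": self.fit_arm, "age_min": float(self.age_min),
            "age_max": float(self.age_max),
            "exclusion_threshold": float(self.exclusion_threshold),
        }
        if self.method == "age_bins":
            d["bin_edges"] = [float(x) for x in self.bin_edges]
            d["bin_means"] = [float(x) for x in self.bin_means]
            d["bin_sds"] = [float(x) for x in self.bin_sds]
        else:
            d["mean_coef"] = [float(x) for x in self.mean_coef]
            d["sd_coef"] = [float(x) for x in self.sd_coef]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "AgeStandardizer":
        d = yaml.safe_load(text)
        for key in ("bin_edges", "bin_means", "bin_sds", "mean_coef", "sd_coef"):
            if key in d:
                d[key] = np.asarray(d[key], float)
        return cls(**d)


@dataclass(frozen=True)
class StandardizedScore:
    outcome: str
    z: float
    excluded: bool
    exclusion_reason: str | None = None
    participant_id: str | None = None


def _merge_sparse_bins(edges: np.ndarray, counts: np.ndarray, min_count: int) -> np.ndarray:
    """Merge adjacent bins until every bin holds >= min_count records."""
    edges = list(edges)
    counts = list(counts)
    i = 0
    while i < len(counts):
        if counts[i] >= min_count or len(counts) == 1:
            i += 1
            continue
        # merge into the smaller neighbour (rightwards for the first bin)
        if i == 0:
            j = 1
        elif i == len(counts) - 1:
            j = i - 1
        else:
            j = i - 1 if counts[i - 1] <= counts[i + 1] else i + 1
        lo, hi = min(i, j), max(i, j)
        counts[lo] = counts[lo] + counts[hi]
        del counts[hi]
        del edges[hi]
        i = 0  # restart: merging can change neighbour order
    return np.asarray(edges)


def fit_standardizer(dataset: TrialDataset | pd.DataFrame, outcome: str,
                     method: str = "age_bins", bin_width_months: float = 3.0,
                     min_per_bin: int = 15, min_total: int = 30,
                     age_col: str = "child_age_months_endline",
                     exclusion_threshold: float = 4.0) -> AgeStandardizer:
    """Fit age-conditional control-arm norms for one outcome.

    Only control-arm, followed-up records with both the raw score and age
    present enter the fit. Raises when fewer than ``min_total`` such records
    exist or when a bin has zero variance.
    """
    df = dataset.df if isinstance(dataset, TrialDataset) else dataset
    sub = df[(df["arm"] == "control")]
    if "followed_up" in sub.columns:
        sub = sub[sub["followed_up"].astype(bool)]
    sub = sub[[age_col, outcome]].dropna()
    n = len(sub)
    if n < min_total:
        raise StandardizationError(
            f"only {n} control-arm records with {outcome!r}; need >= {min_total}")
    age = sub[age_col].to_numpy(float)
    x = sub[outcome].to_numpy(float)

    if method == "age_bins":
        lo = np.floor(age.min())
        hi = age.max()
        edges = np.arange(lo, hi + bin_width_months, bin_width_months)
        if edges[-1] <= hi:
            edges = np.append(edges, hi + 1e-9)
        counts, _ = np.histogram(age, bins=edges)
        edges = _merge_sparse_bins(edges, counts, min_per_bin)
        idx = np.clip(np.searchsorted(edges, age, side="right") - 1, 0, len(edges) - 2)
        k = len(edges) - 1
        means = np.empty(k)
        sds = np.empty(k)
        for b in range(k):
            vals = x[idx == b]
            means[b] = vals.mean()
            sds[b] = vals.std(ddof=1)
            if not np.isfinite(sds[b]) or sds[b] <= 0:
                raise StandardizationError(
                    f"zero variance in age bin [{edges[b]:.1f}, {edges[b + 1]:.1f}) "
                    f"for {outcome!r}")
        return AgeStandardizer(outcome=outcome, method="age_bins", fit_n=n,
                               bin_edges=edges, bin_means=means, bin_sds=sds,
                               age_min=float(age.min()), age_max=float(age.max()),
                               exclusion_threshold=exclusion_threshold)

    if method == "polynomial":
        X = np.column_stack([np.ones_like(age), age, age ** 2])
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        resid = x - X @ beta
        # |resid| regression scaled to an SD under normality
        A = np.column_stack([np.ones_like(age), age])
        gamma, *_ = np.linalg.lstsq(A, np.abs(resid) * np.sqrt(np.pi / 2.0), rcond=None)
        sd_check = A @ gamma
        if (sd_check <= 0).any():
            raise StandardizationError(
                f"fitted SD non-positive inside the age range for {outcome!r}")
        return AgeStandardizer(outcome=outcome, method="polynomial", fit_n=n,
                               mean_coef=beta, sd_coef=gamma,
                               age_min=float(age.min()), age_max=float(age.max()),
                               exclusion_threshold=exclusion_threshold)

    raise StandardizationError(f"unknown method {method!r}")


def transform(standardizer: AgeStandardizer, raw: float, age_months: float,
              participant_id: str | None = None) -> StandardizedScore:
    """Standardise one raw score; flags |z| above the exclusion threshold."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or \
            age_months is None or (isinstance(age_months, float) and np.isnan(age_months)):
        return StandardizedScore(standardizer.outcome, float("nan"), False,
                                 "missing input", participant_id)
    z = (float(raw) - standardizer.mean_model(age_months)) / standardizer.sd_model(age_months)
    thr = standardizer.exclusion_threshold
    excluded = abs(z) > thr
    reason = f"|z| > {thr:g} control-arm SD" if excluded else None
    return StandardizedScore(standardizer.outcome, float(z), bool(excluded),
                             reason, participant_id)


def transform_series(standardizer: AgeStandardizer, raw: pd.Series,
                     age: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Vectorised transform: returns (z, excluded) aligned with the input."""
    z = (raw.to_numpy(float) - standardizer.mean_model(age.to_numpy(float))) \
        / standardizer.sd_model(age.to_numpy(float))
    z = pd.Series(z, index=raw.index)
    excluded = z.abs() > standardizer.exclusion_threshold
    excluded &= z.notna()
    return z, excluded


def standardize_dataset(df: pd.DataFrame, outcomes: list[str],
                        method: str = "age_bins", **fit_kwargs
                        ) -> tuple[pd.DataFrame, dict[str, AgeStandardizer], dict[str, int]]:
    """Fit-and-apply convenience over a scored table.

    For each outcome, fits control-arm norms, adds ``{outcome}_z`` (NaN where
    excluded or missing) and ``{outcome}_excluded`` columns, and returns the
    augmented table, the fitted standardizers and per-outcome exclusion
    counts. Exclusion is applied per outcome independently, which is what
    makes analysed n vary across the development outcomes.
    """
    out = df.copy()
    standardizers: dict[str, AgeStandardizer] = {}
    exclusions: dict[str, int] = {}
    for outcome in outcomes:
        st = fit_standardizer(df, outcome, method=method, **fit_kwargs)
        z, excl = transform_series(st, df[outcome], df["child_age_months_endline"])
        out[f"{outcome}_z"] = z.where(~excl)
        out[f"{outcome}_excluded"] = excl
        standardizers[outcome] = st
        exclusions[outcome] = int(excl.sum())
    return out, standardizers, exclusions
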