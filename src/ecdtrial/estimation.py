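"""Intention-to-treat effect estimation.

The estimator is parametric g-computation (marginal standardisation): fit an
outcome regression — linear for continuous outcomes, logistic for binary —
on the two compared arms, predict every analysed record's outcome under
treatment and under control assignment, and difference the two mean
predictions. For a linear model without treatment-covariate interactions
this collapses to the fitted arm coefficient; for a logistic model it does
not collapse to any single coefficient, which is the point of standardising.

Covariates enter only if they pass a likelihood-ratio prescreen (each
candidate added singly to the arm-only model; retained when p < 0.20).
Confidence intervals come from a percentile bootstrap that resamples whole
villages with replacement, stratified by arm, so that within-village
correlation and the arms' cluster counts are preserved in every replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .synthetic import TrialDataset

logger = logging.getLogger(__name__)

#: Covariates eligible for adjustment (plus any ``*_baseline`` column).
COVARIATE_REGISTRY = (
    "maternal_primary_education", "child_age_months_endline", "child_sex",
    "household_income", "wall_material", "asset_count", "electricity",
    "interviewer",
)


class EstimationError(RuntimeError):
    """Model fitting failed (separation / non-convergence); carries diagnostics."""


@dataclass(frozen=True)
class OutcomeSpec:
    """Declares how one outcome is analysed."""

    name: str
    scale: str                                   # 'continuous' | 'binary'
    candidate_covariates: tuple[str, ...] = ()
    comparisons: tuple[tuple[str, str], ...] = (("group", "control"),
                                                ("combined", "control"))
    standardized: bool = False

    def __post_init__(self):
        if self.scale not in ("continuous", "binary"):
            raise ValueError(f"scale must be continuous|binary, got {self.scale!r}")
        for c in self.candidate_covariates:
            if c not in COVARIATE_REGISTRY and not c.endswith("_baseline"):
                raise ValueError(f"covariate {c!r} not in the registered dictionary")

    @property
    def analysis_column(self) -> str:
        return f"{self.name}_z" if self.standardized else self.name


@dataclass
class EffectEstimate:
    """Adjusted mean (or prevalence) difference for one arm-vs-control
    comparison, with a village-bootstrap percentile CI."""

    outcome: str
    comparison: tuple[str, str]
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_analyzed: int = 0
    n_clusters: int = 0
    covariates_used: tuple[str, ...] = ()
    B: int = 0
    seed: int | None = None
    model: object = field(default=None, repr=False, compare=False)


# ---------------------------------------------------------------------------
# design-matrix assembly (plain numpy; the bootstrap re-runs this a lot)

def _encode(df: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    """Covariate block: numeric/boolean columns as floats, object columns
    dummy-coded dropping the first level."""
    blocks, names = [], []
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True)
            blocks.append(dummies.to_numpy(float))
            names.extend(dummies.columns)
        else:
            blocks.append(col.to_numpy(float)[:, None])
            names.append(cov)
    if not blocks:
        return np.empty((len(df), 0)), []
    return np.hstack(blocks), names


def _fit(y: np.ndarray, X: np.ndarray, scale: str):
    if scale == "continuous":
        return sm.OLS(y, X).fit()
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and friends
        raise EstimationError(f"logistic fit failed: {exc!r}") from exc
    if not res.mle_retvals.get("converged", True):
        raise EstimationError(
            f"logistic fit did not converge: {res.mle_retvals}")
    return res


def _predict(res, X: np.ndarray, scale: str) -> np.ndarray:
    eta = X @ res.params
    return eta if scale == "continuous" else 1.0 / (1.0 + np.exp(-eta))


def gcompute(dataset: TrialDataset | pd.DataFrame, spec: OutcomeSpec,
             covariates: list[str] | tuple[str, ...] = (),
             comparison: tuple[str, str] = ("group", "control"),
             return_model: bool = False) -> EffectEstimate:
    """Point estimate of the adjusted mean/prevalence difference.

    Complete-case over the outcome and covariates, restricted to the two
    compared arms and followed-up records. The returned difference is
    treatment minus control, on the outcome scale (probability scale for
    binary outcomes).
    """
    df = dataset.df if isinstance(dataset, TrialDataset) else dataset
    treatment, control = comparison
    col = spec.analysis_column
    covariates = list(covariates)

    mask = df["arm"].isin(comparison).to_numpy()
    if "followed_up" in df.columns:
        mask &= df["followed_up"].to_numpy(bool)
    sub = df.loc[mask, ["arm", "cluster_id", col, *covariates]].dropna()
    if (sub["arm"] == treatment).sum() == 0 or (sub["arm"] == control).sum() == 0:
        raise EstimationError(f"empty arm in comparison {comparison}")

    y = sub[col].to_numpy(float)
    arm_ind = (sub["arm"] == treatment).to_numpy(float)
    Z, _ = _encode(sub, covariates)
    X = np.column_stack([np.ones(len(sub)), arm_ind, Z])
    res = _fit(y, X, spec.scale)

    Xt = X.copy()
    Xt[:, 1] = 1.0
    Xc = X.copy()
    Xc[:, 1] = 0.0
    est = float(_predict(res, Xt, spec.scale).mean()
                - _predict(res, Xc, spec.scale).mean())
    return EffectEstimate(
        outcome=spec.name, comparison=comparison, estimate=est,
        n_analyzed=len(sub), n_clusters=sub["cluster_id"].nunique(),
        covariates_used=tuple(covariates),
        model=res if return_model else None)


def prescreen_covariates(dataset: TrialDataset | pd.DataFrame, spec: OutcomeSpec,
                         alpha_screen: float = 0.20) -> list[str]:
    """Likelihood-ratio prescreen of the candidate covariates.

    Each candidate is added singly to the base model (arm indicators only,
    all arms named in the outcome's comparisons); candidates with LRT p <
    ``alpha_screen`` are retained, in registered order. A candidate whose
    model fails to fit is dropped with a logged warning.
    """
    df = dataset.df if isinstance(dataset, TrialDataset) else dataset
    col = spec.analysis_column
    arms = sorted({a for comp in spec.comparisons for a in comp})
    mask = df["arm"].isin(arms).to_numpy()
    if "followed_up" in df.columns:
        mask &= df["followed_up"].to_numpy(bool)

    retained: list[str] = []
    for cov in spec.candidate_covariates:
        sub = df.loc[mask, ["arm", col, cov]].dropna()
        y = sub[col].to_numpy(float)
        arm_dummies = pd.get_dummies(sub["arm"], drop_first=True).to_numpy(float)
        X0 = np.column_stack([np.ones(len(sub)), arm_dummies])
        Z, _ = _encode(sub, [cov])
        if Z.shape[1] == 0 or np.allclose(Z.std(axis=0), 0):
            logger.warning("prescreen: covariate %r is constant; dropped", cov)
            continue
        X1 = np.hstack([X0, Z])
        try:
            ll0 = _fit(y, X0, spec.scale).llf
            ll1 = _fit(y, X1, spec.scale).llf
        except EstimationError as exc:
            logger.warning("prescreen: covariate %r dropped (%s)", cov, exc)
            continue
        lrt = 2.0 * (ll1 - ll0)
        p = scipy.stats.chi2.sf(max(lrt, 0.0), df=Z.shape[1])
        if p < alpha_screen:
            retained.append(cov)
    return retained


def adjusted_means(dataset: TrialDataset | pd.DataFrame, spec: OutcomeSpec,
                   adjust_for: list[str] = ["child_age_months_endline"],
                   arms: tuple[str, ...] = ("control", "group", "combined"),
                   B: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Per-arm marginal means adjusted to the pooled covariate distribution.

    Fits the outcome on arm indicators plus ``adjust_for`` over all listed
    arms, then averages each arm's counterfactual predictions over the
    pooled analysed distribution of the adjustment covariates. CIs are
    village-bootstrap percentiles. Rows come back in the given arm order.
    """
    df = dataset.df if isinstance(dataset, TrialDataset) else dataset

    def _means(d: pd.DataFrame) -> np.ndarray:
        mask = d["arm"].isin(arms).to_numpy()
        if "followed_up" in d.columns:
            mask &= d["followed_up"].to_numpy(bool)
        sub = d.loc[mask, ["arm", spec.analysis_column, *adjust_for]].dropna()
        y = sub[spec.analysis_column].to_numpy(float)
        arm_block = np.column_stack([(sub["arm"] == a).to_numpy(float) for a in arms[1:]])
        Z, _ = _encode(sub, list(adjust_for))
        X = np.column_stack([np.ones(len(sub)), arm_block, Z])
        res = _fit(y, X, spec.scale)
        out = np.empty(len(arms))
        for i, a in enumerate(arms):
            Xa = X.copy()
            Xa[:, 1:1 + len(arms) - 1] = 0.0
            if i > 0:
                Xa[:, i] = 1.0
            out[i] = _predict(res, Xa, spec.scale).mean()
        return out

    point = _means(df)
    lo = np.full(len(arms), np.nan)
    hi = np.full(len(arms), np.nan)
    if B > 0:
        reps = _bootstrap_replicates(df, _means, B=B, seed=seed, width=len(arms))
        lo = np.percentile(reps, 2.5, axis=0)
        hi = np.percentile(reps, 97.5, axis=0)
    return pd.DataFrame({"arm": arms, "mean": point, "ci_low": lo, "ci_high": hi})


# ---------------------------------------------------------------------------
# village bootstrap

def _cluster_groups(df: pd.DataFrame) -> dict[str, list[np.ndarray]]:
    """Row-index arrays of every cluster, grouped by arm."""
    groups: dict[str, list[np.ndarray]] = {}
    codes, uniques = pd.factorize(df["cluster_id"])
    arm_of = df.groupby("cluster_id")["arm"].first()
    order = np.argsort(codes, kind="stable")
    bounds = np.searchsorted(codes[order], np.arange(len(uniques) + 1))
    for j, cl in enumerate(uniques):
        idx = order[bounds[j]:bounds[j + 1]]
        groups.setdefault(arm_of[cl], []).append(idx)
    return groups


def _bootstrap_replicates(df: pd.DataFrame, estimator, B: int, seed,
                          width: int = 1, max_failure_frac: float = 0.05) -> np.ndarray:
    groups = _cluster_groups(df)
    for a, cl in groups.items():
        if len(cl) < 2:
            raise ValueError(f"arm {a!r} has fewer than 2 clusters; cannot bootstrap")
    rng = np.random.default_rng(seed)
    arms = sorted(groups)
    reps = np.empty((B, width))
    failures = 0
    max_failures = int(np.ceil(max_failure_frac * B))
    b = 0
    while b < B:
        take = []
        for a in arms:
            cl = groups[a]
            take.extend(cl[i] for i in rng.integers(0, len(cl), size=len(cl)))
        idx = np.concatenate(take)
        sample = df.iloc[idx]
        try:
            reps[b] = estimator(sample)
        except Exception as exc:
            failures += 1
            if failures > max_failures:
                raise EstimationError(
                    f"> {max_failure_frac:.0%} of bootstrap replicates failed "
                    f"({failures}/{b + failures}); last error: {exc!r}") from exc
            continue  # redraw
        b += 1
    if failures:
        logger.warning("bootstrap: %d replicate(s) redrawn after failures", failures)
    return reps


def cluster_bootstrap(dataset: TrialDataset | pd.DataFrame, estimator,
                      B: int = 1000, seed: int | None = None) -> tuple[float, float]:
    """95% percentile CI from a village bootstrap, stratified by arm.

    ``estimator`` maps a participant table to a scalar; each replicate
    resamples every arm's villages with replacement (keeping the arm's
    village count) and re-runs the estimator on the stacked records.
    Replicates that raise are redrawn, up to 5% of B.
    """
    df = dataset.df if isinstance(dataset, TrialDataset) else dataset
    reps = _bootstrap_replicates(df, lambda d: estimator(d), B=B, seed=seed)
    return float(np.percentile(reps[:, 0], 2.5)), float(np.percentile(reps[:, 0], 97.5))


# ---------------------------------------------------------------------------
# effect sizes and the orchestrated run

def cohens_d(mean1: float, sd1: float, n1: int, mean2: float, sd2: float,
             n2: int) -> tuple[float, float, float]:
    """Pooled-SD standardised mean difference with a normal-approximation CI.

    ``d = (mean1 - mean2) / s_p`` with ``s_p`` pooled over ``n1-1`` and
    ``n2-1`` degrees of freedom; the CI uses
    ``var(d) = (n1+n2)/(n1*n2) + d^2 / (2*(n1+n2))``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("cohens_d requires n >= 2 per group")
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("pooled SD is zero; d undefined")
    d = (mean1 - mean2) / np.sqrt(sp2)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2 * (n1 + n2)))
    z = scipy.stats.norm.ppf(0.975)
    return float(d), float(d - z * se), float(d + z * se)


def estimate_effects(dataset: TrialDataset | pd.DataFrame,
                     specs: list[OutcomeSpec], B: int = 1000, seed: int = 0,
                     alpha_screen: float = 0.20,
                     ) -> tuple[list[EffectEstimate], dict]:
    """Run the full pipeline for a list of outcomes.

    Prescreens each outcome's candidates once on the original data (the
    retained set is frozen across bootstrap replicates), computes the
    g-computation point estimate and a village-bootstrap CI for each
    comparison, and returns the estimates plus a JSON-ready run manifest.
    A single run-level seed fans out deterministically to per-comparison
    bootstrap streams.
    """
    df = dataset.df if isinstance(dataset, TrialDataset) else dataset
    root = np.random.SeedSequence(seed)
    estimates: list[EffectEstimate] = []
    manifest: dict = {"seed": seed, "B": B, "alpha_screen": alpha_screen,
                      "outcomes": {}}
    for spec in specs:
        covs = prescreen_covariates(df, spec, alpha_screen=alpha_screen)
        manifest["outcomes"][spec.name] = {
            "scale": spec.scale, "covariates_retained": covs, "comparisons": {}}
        for comparison in spec.comparisons:
            sub_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            two_arms = df[df["arm"].isin(comparison)]
            point = gcompute(two_arms, spec, covs, comparison)
            lo, hi = cluster_bootstrap(
                two_arms,
                lambda d: gcompute(d, spec, covs, comparison).estimate,
                B=B, seed=sub_seed)
            est = EffectEstimate(
                outcome=spec.name, comparison=comparison,
                estimate=point.estimate, ci_low=lo, ci_high=hi,
                n_analyzed=point.n_analyzed, n_clusters=point.n_clusters,
                covariates_used=tuple(covs), B=B, seed=sub_seed)
            estimates.append(est)
            manifest["outcomes"][spec.name]["comparisons"]["_vs_".join(comparison)] = {
                "estimate": est.estimate, "ci_low": lo, "ci_high": hi,
                "n_analyzed": est.n_analyzed, "n_clusters": est.n_clusters,
                "bootstrap_seed": sub_seed}
    return estimates, manifest


def effects_to_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy table: one row per outcome x comparison."""
    return pd.DataFrame([{
        "outcome": e.outcome,
        "comparison": f"{e.comparison[0]}_vs_{e.comparison[1]}",
        "estimate": e.estimate, "ci_low": e.ci_low, "ci_high": e.ci_high,
        "n_analyzed": e.n_analyzed, "n_clusters": e.n_clusters,
        "covariates_used": ";".join(e.covariates_used), "B": e.B, "seed": e.seed,
    } for e in estimates])
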