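"""Synthetic cluster-randomised trial generator.

Emulates the data structure of a three-arm, village-randomised early child
development trial in two subdistrict strata: 31 village clusters allocated
5:5:8 and 3:3:7 (group : combined : control), ~20 participants per cluster,
an intracluster correlation around 0.20 on continuous endpoints, bounded
integer instrument scales, age-dependent development scores, binary
household outcomes, and missing-completely-at-random loss to follow-up.

Continuous endpoints follow a random-intercept model

    y_ij = mu + effect[arm] + beta_age * (age_ij - age_mid) + u_j + e_ij

with ``u_j ~ N(0, rho * sigma^2)`` between villages and
``e_ij ~ N(0, (1 - rho) * sigma^2)`` within, so that the marginal SD is
``sigma`` and the intracluster correlation is ``rho``. Binary endpoints use a
logistic model with a normal village intercept whose variance is chosen so
the *latent-scale* ICC equals ``rho``. Development scores receive a small
rate of gross outliers (heavy-tailed measurement error), mirroring the
handful of implausible scores real assessments produce.

Item-level responses (play activities, play materials, home observation,
milestone items, depressive-symptom items, food-group indicators) are
derived from the bounded scores so that re-scoring the items reproduces the
generated totals exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

ARMS = ("control", "group", "combined")

#: Default village allocation: stratum -> arm -> cluster count.
#: 5:5:8 in stratum A and 3:3:7 in stratum B for group : combined : control.
DEFAULT_CLUSTER_TABLE: dict[str, dict[str, int]] = {
    "A": {"group": 5, "combined": 5, "control": 8},
    "B": {"group": 3, "combined": 3, "control": 7},
}


@dataclass(frozen=True)
class ContinuousOutcome:
    """Generating parameters for one bounded continuous endpoint."""

    mean: float            # marginal mean at the reference (mid-range) age
    sd: float              # marginal SD sigma (cluster + residual combined)
    age_slope: float       # change in mean per month of age
    lo: float
    hi: float
    integer: bool = True   # round to integer support after clipping
    step: float = 1.0      # score granularity (5.0 for milestone domain raws)
    outlier_prone: bool = False


#: Marginal means/SDs track the control-arm endline summaries of the trial
#: the generator emulates; slopes are a realistic monthly growth gradient.
CONTINUOUS_OUTCOMES: dict[str, ContinuousOutcome] = {
    "fci_activities": ContinuousOutcome(3.2, 1.5, 0.03, 0, 6),
    "fci_materials": ContinuousOutcome(2.5, 1.4, 0.03, 0, 6),
    "fci_observation": ContinuousOutcome(8.3, 1.5, 0.02, 0, 11),
    "asqi_communication": ContinuousOutcome(45.0, 11.0, 0.9, 0, 60, step=5.0, outlier_prone=True),
    "asqi_gross_motor": ContinuousOutcome(46.0, 11.0, 0.9, 0, 60, step=5.0, outlier_prone=True),
    "asqi_fine_motor": ContinuousOutcome(44.0, 10.0, 0.8, 0, 60, step=5.0, outlier_prone=True),
    "asqi_problem_solving": ContinuousOutcome(44.0, 11.0, 0.9, 0, 60, step=5.0, outlier_prone=True),
    "asqi_personal_social": ContinuousOutcome(45.0, 11.0, 0.9, 0, 60, step=5.0, outlier_prone=True),
    "cdi_receptive": ContinuousOutcome(45.0, 16.0, 2.0, 0, 100, outlier_prone=True),
    "cdi_expressive": ContinuousOutcome(17.0, 12.0, 1.5, 0, 100, outlier_prone=True),
    "cesd": ContinuousOutcome(15.0, 8.5, 0.0, 0, 60),
    "maternal_food_groups": ContinuousOutcome(5.0, 1.3, 0.0, 0, 10),
    "child_food_groups": ContinuousOutcome(3.8, 1.5, 0.08, 0, 8),
}

#: Control-arm endline prevalences for the binary household outcomes.
BINARY_OUTCOMES: dict[str, float] = {
    "hygienic_latrine": 0.34,
    "handwashing_station": 0.21,
    "potty_use": 0.20,
    "lead_knowledge": 0.24,
}

_FCI_ACT_ITEMS = [
    "fci_act_read", "fci_act_told_stories", "fci_act_sang",
    "fci_act_took_outside", "fci_act_played", "fci_act_named_drew",
]
_FCI_MAT_ITEMS = [
    "fci_mat_music", "fci_mat_drawing", "fci_mat_pretending",
    "fci_mat_movement", "fci_mat_shapes", "fci_mat_stacking",
]
_FCI_OBS_ITEMS = [f"fci_obs_{i:02d}" for i in range(1, 12)]
_CESD_ITEMS = [f"cesd_{i:02d}" for i in range(1, 21)]
_CESD_REVERSE = {"cesd_04", "cesd_08", "cesd_12", "cesd_16"}
ASQ_DOMAINS = ("communication", "gross_motor", "fine_motor",
               "problem_solving", "personal_social")
_MATERNAL_GROUPS = [
    "grains_roots_tubers", "legumes", "nuts_seeds", "dairy", "flesh_foods",
    "eggs", "dark_green_leafy", "other_vitamin_a", "other_vegetables",
    "other_fruits",
]
_CHILD_GROUPS = [
    "breastmilk", "grains_roots_tubers", "legumes_nuts", "dairy",
    "flesh_foods", "eggs", "vitamin_a_fruit_veg", "other_fruit_veg",
]


class ConfigError(ValueError):
    """Raised when a SimConfig field fails validation."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic trial.

    ``outcome_effects`` maps outcome name -> {arm: effect}; effects are
    additive on the continuous scale and log-odds shifts for binary
    outcomes. ``residual_sd`` overrides the marginal SD sigma per outcome.
    """

    n_clusters_per_arm_per_stratum: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {s: dict(a) for s, a in DEFAULT_CLUSTER_TABLE.items()})
    participants_per_cluster: int = 20
    icc: float = 0.20
    outcome_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    residual_sd: Mapping[str, float] = field(default_factory=dict)
    age_range_months: tuple[float, float] = (4.0, 26.0)
    attrition_rate: float = 0.076
    outlier_rate: float = 0.02
    asq_items_per_domain: int = 6
    clip_scores: bool = True
    n_interviewers: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.icc < 1:
            raise ConfigError("icc must lie in [0, 1)")
        if not 0 <= self.attrition_rate < 1:
            raise ConfigError("attrition_rate must lie in [0, 1)")
        if not 0 <= self.outlier_rate < 1:
            raise ConfigError("outlier_rate must lie in [0, 1)")
        if self.participants_per_cluster < 1:
            raise ConfigError("participants_per_cluster must be positive")
        if self.asq_items_per_domain < 1:
            raise ConfigError("asq_items_per_domain must be positive")
        for stratum, arms in self.n_clusters_per_arm_per_stratum.items():
            for arm, k in arms.items():
                if arm not in ARMS:
                    raise ConfigError(
                        f"n_clusters_per_arm_per_stratum: unknown arm {arm!r}")
                if k < 0 or (isinstance(k, float) and not float(k).is_integer()):
                    raise ConfigError(
                        f"n_clusters_per_arm_per_stratum[{stratum}][{arm}] "
                        "must be a non-negative integer")
        for name, sd in self.residual_sd.items():
            if sd <= 0:
                raise ConfigError(f"residual_sd[{name}] must be positive")
        lo, hi = self.age_range_months
        if not (0 <= lo < hi):
            raise ConfigError("age_range_months must be an increasing pair of non-negative months")

    def sigma(self, outcome: str) -> float:
        return float(self.residual_sd.get(outcome, CONTINUOUS_OUTCOMES[outcome].sd))

    def effect(self, outcome: str, arm: str) -> float:
        return float(self.outcome_effects.get(outcome, {}).get(arm, 0.0))

    def to_yaml(self) -> str:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["n_clusters_per_arm_per_stratum"] = {
            s: dict(a) for s, a in d["n_clusters_per_arm_per_stratum"].items()}
        d["outcome_effects"] = {o: dict(e) for o, e in d["outcome_effects"].items()}
        d["residual_sd"] = dict(d["residual_sd"])
        d["age_range_months"] = list(d["age_range_months"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text)
        if "age_range_months" in d:
            d["age_range_months"] = tuple(d["age_range_months"])
        return cls(**d)


@dataclass(frozen=True)
class ParticipantRecord:
    """One enrolled caregiver-child dyad (a single dataset row)."""

    participant_id: str
    cluster_id: str
    stratum_id: str
    arm: str
    pregnant_at_baseline: bool
    child_age_months_endline: float
    child_sex: str
    maternal_primary_education: bool
    household_income: float
    wall_material: bool
    electricity: bool
    asset_count: int
    followed_up: bool
    baseline_outcome_values: Mapping[str, float] = field(default_factory=dict)
    endline_item_responses: Mapping[str, Mapping[str, object]] = field(default_factory=dict)


class TrialDataset:
    """A participant table with cluster/arm/stratum integrity invariants.

    Thin wrapper around a :class:`pandas.DataFrame` (one row per participant)
    plus the generating :class:`SimConfig` when the data are synthetic.
    """

    def __init__(self, df: pd.DataFrame, config: SimConfig | None = None,
                 validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.config = config
        if validate:
            self.validate()

    def validate(self) -> None:
        df = self.df
        for col in ("participant_id", "cluster_id", "stratum_id", "arm"):
            if col not in df.columns:
                raise ValueError(f"dataset missing required column {col!r}")
        bad = df.groupby("cluster_id")["arm"].nunique()
        if (bad > 1).any():
            offenders = list(bad.index[bad > 1])
            raise ValueError(f"arm varies within cluster(s): {offenders}")
        unknown = set(df["arm"].unique()) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arm label(s): {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_clusters(self) -> int:
        return self.df["cluster_id"].nunique()

    def arm_sizes(self) -> dict[str, int]:
        return self.df["arm"].value_counts().to_dict()

    def to_csv(self, path, config_path=None) -> None:
        """Write the participant table as CSV; optionally the config as YAML."""
        self.df.to_csv(path, index=False)
        if config_path is not None and self.config is not None:
            with open(config_path, "w") as fh:
                fh.write(self.config.to_yaml())

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.df.to_csv(buf, index=False)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, path, config_path=None) -> "TrialDataset":
        df = pd.read_csv(path)
        config = None
        if config_path is not None:
            with open(config_path) as fh:
                config = SimConfig.from_yaml(fh.read())
        return cls(df, config=config)


# ---------------------------------------------------------------------------
# generation helpers

def _spread_items(rng: np.random.Generator, counts: np.ndarray, n_items: int) -> np.ndarray:
    """Endorse exactly ``counts[i]`` of ``n_items`` binary items per row,
    choosing which items uniformly at random."""
    n = len(counts)
    ranks = rng.random((n, n_items)).argsort(axis=1)
    return (ranks < counts[:, None]).astype(float)


def _latent(rng: np.random.Generator, cfg: SimConfig, outcome: str,
            cluster_idx: np.ndarray, n_clusters: int, arm: np.ndarray,
            age: np.ndarray) -> np.ndarray:
    """Draw the random-intercept latent score for one continuous outcome."""
    spec = CONTINUOUS_OUTCOMES[outcome]
    sigma = cfg.sigma(outcome)
    u = rng.normal(0.0, np.sqrt(cfg.icc) * sigma, size=n_clusters)
    e = rng.normal(0.0, np.sqrt(1.0 - cfg.icc) * sigma, size=len(cluster_idx))
    lo, hi = cfg.age_range_months
    age_mid = 0.5 * (lo + hi)
    effect = np.zeros(len(arm))
    for a in ARMS:
        effect[arm == a] = cfg.effect(outcome, a)
    y = spec.mean + effect + spec.age_slope * (age - age_mid) + u[cluster_idx] + e
    if spec.outlier_prone and cfg.outlier_rate > 0:
        is_out = rng.random(len(y)) < cfg.outlier_rate
        y = y + is_out * rng.normal(0.0, 6.0 * sigma, size=len(y))
    return y


def _bound(y: np.ndarray, spec: ContinuousOutcome, clip: bool) -> np.ndarray:
    if not clip:
        return y
    y = np.clip(y, spec.lo, spec.hi)
    if spec.integer:
        y = np.round(y / spec.step) * spec.step
    return y


def simulate_trial(config: SimConfig | None = None, **overrides) -> TrialDataset:
    """Generate one synthetic trial dataset.

    Keyword overrides are applied on top of ``config`` (or the defaults), so
    ``simulate_trial(seed=7, icc=0.0)`` is a convenient shorthand.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- clusters ---------------------------------------------------------
    clusters: list[tuple[str, str, str]] = []  # (cluster_id, stratum, arm)
    i = 0
    for stratum in sorted(cfg.n_clusters_per_arm_per_stratum):
        arms = cfg.n_clusters_per_arm_per_stratum[stratum]
        for arm in ARMS:
            for _ in range(int(arms.get(arm, 0))):
                i += 1
                clusters.append((f"V{i:03d}", stratum, arm))
    if len(clusters) == 0:
        raise ConfigError("n_clusters_per_arm_per_stratum yields zero clusters")

    m = cfg.participants_per_cluster
    n = len(clusters) * m
    cluster_idx = np.repeat(np.arange(len(clusters)), m)
    cluster_id = np.array([c[0] for c in clusters])[cluster_idx]
    stratum_id = np.array([c[1] for c in clusters])[cluster_idx]
    arm = np.array([c[2] for c in clusters])[cluster_idx]

    # --- covariates -------------------------------------------------------
    lo_age, hi_age = cfg.age_range_months
    age = rng.uniform(lo_age, hi_age, size=n)
    df = pd.DataFrame({
        "participant_id": [f"P{i:04d}" for i in range(1, n + 1)],
        "cluster_id": cluster_id,
        "stratum_id": stratum_id,
        "arm": arm,
        "pregnant_at_baseline": rng.random(n) < 0.20,
        "child_age_months_endline": age,
        "child_sex": np.where(rng.random(n) < 0.56, "female", "male"),
        "maternal_primary_education": rng.random(n) < 0.57,
        "household_income": np.exp(rng.normal(np.log(12000.0), 0.5, size=n)),
        "wall_material": rng.random(n) < 0.20,
        "electricity": rng.random(n) < 0.85,
        "asset_count": rng.poisson(3.0, size=n),
        "interviewer": np.array([f"I{k + 1}" for k in rng.integers(0, cfg.n_interviewers, size=n)]),
    })

    # --- latent continuous endpoints --------------------------------------
    latents: dict[str, np.ndarray] = {}
    for name in CONTINUOUS_OUTCOMES:
        latents[name] = _latent(rng, cfg, name, cluster_idx, len(clusters), arm, age)

    new_cols: dict[str, np.ndarray] = {}

    # baseline values share the village effect with the endline endpoint, so
    # they genuinely predict it (used by the covariate prescreen); the arm
    # effect is removed — baselines predate the intervention
    for name in ("fci_activities", "cesd"):
        spec = CONTINUOUS_OUTCOMES[name]
        sigma = cfg.sigma(name)
        arm_effect = np.zeros(n)
        for a in ARMS:
            arm_effect[arm == a] = cfg.effect(name, a)
        half = latents[name] - arm_effect - spec.mean
        base = spec.mean + 0.5 * half + rng.normal(0.0, 0.7 * sigma, size=n)
        new_cols[f"{name}_baseline"] = _bound(base, spec, cfg.clip_scores)

    followed = rng.random(n) >= cfg.attrition_rate
    new_cols["followed_up"] = followed

    scores: dict[str, np.ndarray] = {}
    for name in CONTINUOUS_OUTCOMES:
        spec = CONTINUOUS_OUTCOMES[name]
        if name.startswith("asqi_"):
            hi = 10.0 * cfg.asq_items_per_domain
            spec = replace(spec, hi=hi)
        scores[name] = _bound(latents[name], spec, cfg.clip_scores)

    # --- item-level responses, derived from the bounded scores ------------
    act = _spread_items(rng, scores["fci_activities"].astype(int)
                        if cfg.clip_scores else np.clip(np.round(scores["fci_activities"]), 0, 6).astype(int), 6)
    mat = _spread_items(rng, np.clip(np.round(scores["fci_materials"]), 0, 6).astype(int), 6)
    obs = _spread_items(rng, np.clip(np.round(scores["fci_observation"]), 0, 11).astype(int), 11)
    for j, col in enumerate(_FCI_ACT_ITEMS):
        new_cols[col] = act[:, j]
    for j, col in enumerate(_FCI_MAT_ITEMS):
        new_cols[col] = mat[:, j]
    for j, col in enumerate(_FCI_OBS_ITEMS):
        new_cols[col] = obs[:, j]

    n_items = cfg.asq_items_per_domain
    for dom in ASQ_DOMAINS:
        s = np.clip(np.round(latents[f"asqi_{dom}"] / 5.0) * 5.0, 0, 10 * n_items)
        k_yes = (s // 10).astype(int)
        has_sometimes = (s - 10 * k_yes) >= 5
        ranks = rng.random((n, n_items)).argsort(axis=1)
        resp = np.full((n, n_items), "not_yet", dtype=object)
        resp[ranks < k_yes[:, None]] = "yes"
        resp[(ranks == k_yes[:, None]) & has_sometimes[:, None]] = "sometimes"
        for j in range(n_items):
            new_cols[f"asq_{dom}_{j + 1:02d}"] = resp[:, j]

    s = np.clip(np.round(scores["cesd"]), 0, 60).astype(int)
    base_c, rem = s // 20, s % 20
    ranks = rng.random((n, 20)).argsort(axis=1)
    contrib = base_c[:, None] + (ranks < rem[:, None])
    for j, col in enumerate(_CESD_ITEMS):
        raw = contrib[:, j]
        new_cols[col] = (3 - raw) if col in _CESD_REVERSE else raw

    new_cols["cdi_receptive"] = scores["cdi_receptive"]
    new_cols["cdi_expressive"] = scores["cdi_expressive"]

    if not cfg.clip_scores:
        # calibration mode: expose the unbounded continuous scores directly,
        # so additive effects are exact estimands (no bound attenuation)
        for name in CONTINUOUS_OUTCOMES:
            if name not in ("cdi_receptive", "cdi_expressive"):
                new_cols[name] = scores[name]

    mk = _spread_items(rng, np.clip(np.round(scores["maternal_food_groups"]), 0, 10).astype(int), 10)
    for j, g in enumerate(_MATERNAL_GROUPS):
        new_cols[f"diet_w_{g}"] = mk[:, j]
    ck = _spread_items(rng, np.clip(np.round(scores["child_food_groups"]), 0, 8).astype(int), 8)
    for j, g in enumerate(_CHILD_GROUPS):
        new_cols[f"diet_c_{g}"] = ck[:, j]

    # --- binary household outcomes (logistic-normal village intercept) ----
    sd_b = np.sqrt(cfg.icc / (1.0 - cfg.icc) * np.pi ** 2 / 3.0) if cfg.icc > 0 else 0.0
    for name, p0 in BINARY_OUTCOMES.items():
        ub = rng.normal(0.0, sd_b, size=len(clusters)) if sd_b > 0 else np.zeros(len(clusters))
        eff = np.zeros(n)
        for a in ARMS:
            eff[arm == a] = cfg.effect(name, a)
        logit = np.log(p0 / (1 - p0)) + eff + ub[cluster_idx]
        new_cols[name] = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(float)

    df = pd.concat([df, pd.DataFrame(new_cols, index=df.index)], axis=1)

    # --- eligibility windows and attrition --------------------------------
    endline_cols = [c for c in df.columns
                    if (c.startswith(("fci_act_", "fci_mat_", "fci_obs_", "asq_",
                                      "cesd_", "cdi_", "diet_"))
                        and not c.endswith("_baseline"))
                    or c in BINARY_OUTCOMES or c in CONTINUOUS_OUTCOMES]
    young = age <= 9.0
    df.loc[young, "cdi_expressive"] = np.nan          # word production: > 9 months only
    under6 = age <= 6.0
    df.loc[under6, [f"diet_c_{g}" for g in _CHILD_GROUPS]] = np.nan
    for col in endline_cols:
        if df[col].dtype == object:
            df.loc[~followed, col] = None
        else:
            df.loc[~followed, col] = np.nan

    return TrialDataset(df, config=cfg)


# ---------------------------------------------------------------------------
# ICC estimation (one-way ANOVA estimator)

def estimate_icc(dataset: TrialDataset | pd.DataFrame, outcome: str) -> float:
    """ANOVA intracluster correlation of a continuous outcome.

    Uses the one-way random-effects decomposition with the unbalanced-design
    average cluster size ``n0 = (N - sum(m_j^2)/N) / (k - 1)``:
    ``ICC = (MSB - MSW) / (MSB + (n0 - 1) MSW)``.
    """
    df = dataset.df if isinstance(dataset, TrialDataset) else dataset
    sub = df[["cluster_id", outcome]].dropna()
    groups = sub.groupby("cluster_id")[outcome]
    k = groups.ngroups
    if k < 2:
        raise ValueError("ICC requires at least two clusters with data")
    N = len(sub)
    if N <= k:
        raise ValueError("ICC requires within-cluster replication")
    y = sub[outcome].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("outcome has zero total variance; ICC undefined")
    means = groups.mean()
    sizes = groups.size().to_numpy(float)
    grand = y.mean()
    ssb = float((sizes * (means.to_numpy(float) - grand) ** 2).sum())
    sst = float(((y - grand) ** 2).sum())
    ssw = sst - ssb
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - (sizes ** 2).sum() / N) / (k - 1)
    return float((msb - msw) / (msb + (n0 - 1) * msw))
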