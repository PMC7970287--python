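"""Instrument scoring: item-level responses -> trial outcome variables.

Covers the caregiving-stimulation scales (play activities 0-6, play
materials 0-6, home-observation 0-11), milestone-inventory domain raw scores
and their pre-standardisation total, the 20-item depressive-symptom score
(0-60, standard reverse-coding key), and the minimum-dietary-diversity
binaries (women: >=5 of 10 food groups; children: >=5 of 8 counting
breastmilk).

Scores are never pro-rated: any missing required item flags the affected
score (and any total built on it) as missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml


class ScoringError(ValueError):
    pass


@lru_cache(maxsize=1)
def instrument_registry() -> dict:
    """Item dictionaries (ids, legal codes, subscale membership) from the
    versioned YAML shipped with the package."""
    text = resources.files("ecdtrial.data").joinpath("instruments.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class InstrumentResponse:
    """One respondent's answers to one instrument."""

    instrument: str
    items: Mapping[str, object]


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def _check_instrument(response: InstrumentResponse, expected: str) -> None:
    if response.instrument != expected:
        raise ScoringError(
            f"expected a {expected!r} response, got {response.instrument!r}")


def _subscale_count(items: Mapping, ids: Iterable[str], codes: set) -> float | None:
    """Sum of binary items; None if any is missing."""
    total = 0
    for item_id in ids:
        if item_id not in items:
            raise ScoringError(f"item {item_id!r} absent from response")
        v = items[item_id]
        if _is_missing(v):
            return None
        if v not in codes and int(v) not in codes:
            raise ScoringError(f"illegal code {v!r} for item {item_id!r}")
        total += int(v)
    return float(total)


def score_fci(response: InstrumentResponse) -> tuple[float | None, float | None, float | None]:
    """Score the three home-stimulation subscales.

    Returns ``(activities, materials, observation)``: the count of
    caregiver-endorsed stimulating activities in the previous 3 days (0-6),
    the count of play-material varieties observed in the home (0-6), and the
    sum of the 11 responsiveness/home-environment observation items (0-11).
    A subscale with any missing item is returned as None (no imputation).
    """
    _check_instrument(response, "fci")
    reg = instrument_registry()["fci"]
    codes = set(reg["codes"])
    out = []
    for sub in ("activities", "materials", "observation"):
        try:
            out.append(_subscale_count(response.items, reg["subscales"][sub], codes))
        except ScoringError:
            raise
    return tuple(out)  # type: ignore[return-value]


def score_asqi(response: InstrumentResponse,
               scheme: Mapping[str, float] | None = None,
               items_per_domain: int | None = None,
               ) -> tuple[dict[str, float | None], float | None]:
    """Milestone-inventory domain raw scores and their total.

    Each item is a 3-level category mapped through ``scheme`` (default:
    yes=10, sometimes=5, not yet=0). The total is the sum of the five domain
    raw scores, computed on the raw scale (standardisation, if any, comes
    after summation). A domain with a missing item is None, and so is the
    total.
    """
    _check_instrument(response, "asqi")
    reg = instrument_registry()["asqi"]
    if scheme is None:
        scheme = reg["scheme"]
    scheme = {str(k): float(v) for k, v in scheme.items()}
    n_items = items_per_domain or reg["items_per_domain"]
    expected = {f"asq_{d}_{j:02d}" for d in reg["domains"]
                for j in range(1, n_items + 1)}
    unknown = set(response.items) - expected
    if unknown:
        raise ScoringError(f"unknown item(s): {sorted(unknown)[:5]}")
    domains: dict[str, float | None] = {}
    for dom in reg["domains"]:
        total: float | None = 0.0
        for j in range(1, n_items + 1):
            item_id = f"asq_{dom}_{j:02d}"
            if item_id not in response.items:
                raise ScoringError(f"item {item_id!r} absent from response")
            v = response.items[item_id]
            if _is_missing(v):
                total = None
                break
            v = str(v)
            if v not in scheme:
                raise ScoringError(f"illegal code {v!r} for item {item_id!r}")
            total += scheme[v]
        domains[dom] = total
    grand = None if any(v is None for v in domains.values()) \
        else float(sum(domains.values()))  # type: ignore[arg-type]
    return domains, grand


def score_mdd(food_groups_consumed: Iterable[str], role: str,
              breastfed: bool | None = None) -> bool:
    """Minimum-dietary-diversity indicator.

    ``role='maternal'``: true iff at least 5 of the 10 registered women's
    food groups were consumed in the previous 24 h. ``role='child'``: true
    iff at least 5 of the 8 registered child groups, where breastmilk counts
    as a group (``breastfed=True`` adds it if not already listed).
    """
    reg = instrument_registry()["diet"]
    if role == "maternal":
        registered, threshold = set(reg["maternal_groups"]), reg["maternal_threshold"]
    elif role == "child":
        registered, threshold = set(reg["child_groups"]), reg["child_threshold"]
    else:
        raise ScoringError(f"unknown role {role!r}")
    groups = set(food_groups_consumed)
    unknown = groups - registered
    if unknown:
        raise ScoringError(f"unregistered food group(s): {sorted(unknown)}")
    if role == "child" and breastfed:
        groups.add("breastmilk")
    return len(groups) >= threshold


def score_cesd(response: InstrumentResponse) -> float | None:
    """Total depressive-symptom score in [0, 60].

    Sums the 20 items (each 0-3) after reverse-coding the four positively
    worded items of the standard key. Returns None if any item is missing;
    raises on a wrong item set or an out-of-range code.
    """
    _check_instrument(response, "cesd")
    reg = instrument_registry()["cesd"]
    expected = set(reg["items"])
    got = set(response.items)
    if got != expected:
        raise ScoringError(
            f"item set mismatch: missing {sorted(expected - got)}, "
            f"unexpected {sorted(got - expected)}")
    reverse = set(reg["reverse_items"])
    codes = set(reg["codes"])
    total = 0
    for item_id in reg["items"]:
        v = response.items[item_id]
        if _is_missing(v):
            return None
        v = int(v)
        if v not in codes:
            raise ScoringError(f"illegal code {v!r} for item {item_id!r}")
        total += (3 - v) if item_id in reverse else v
    return float(total)


# ---------------------------------------------------------------------------
# vectorised dataset scoring

_ID_COLS = ["participant_id", "cluster_id", "stratum_id", "arm",
            "pregnant_at_baseline", "child_age_months_endline", "child_sex",
            "maternal_primary_education", "household_income", "wall_material",
            "electricity", "asset_count", "interviewer", "followed_up"]


def _row_sum(df: pd.DataFrame, cols: list[str]) -> pd.Series:
    """Row-wise sum that is NaN whenever any contributing item is NaN."""
    block = df[cols]
    return block.sum(axis=1).where(~block.isna().any(axis=1))


def score_dataset(df: pd.DataFrame, scheme: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Score every instrument for every row of a participant table.

    Returns a new table with identifier/covariate columns followed by one
    column per scored outcome. Row-level and vectorised scoring agree item
    for item (covered by tests); this path exists because the estimation
    experiments score thousands of simulated datasets.
    """
    reg = instrument_registry()
    out = df[[c for c in _ID_COLS if c in df.columns]].copy()
    for c in df.columns:
        if c.endswith("_baseline"):
            out[c] = df[c]

    fci = reg["fci"]["subscales"]
    out["fci_activities"] = _row_sum(df, fci["activities"])
    out["fci_materials"] = _row_sum(df, fci["materials"])
    out["fci_observation"] = _row_sum(df, fci["observation"])

    if scheme is None:
        scheme = reg["asqi"]["scheme"]
    scheme = {str(k): float(v) for k, v in scheme.items()}
    domain_cols = []
    for dom in reg["asqi"]["domains"]:
        cols = sorted(c for c in df.columns if c.startswith(f"asq_{dom}_"))
        if not cols:
            continue
        numeric = df[cols].apply(lambda s: s.map(scheme))
        col = f"asqi_{dom}"
        out[col] = numeric.sum(axis=1).where(~numeric.isna().any(axis=1))
        domain_cols.append(col)
    if domain_cols:
        out["asqi_total"] = _row_sum(out, domain_cols)

    cesd_items = reg["cesd"]["items"]
    if set(cesd_items) <= set(df.columns):
        vals = df[cesd_items].copy()
        for item in reg["cesd"]["reverse_items"]:
            vals[item] = 3 - vals[item]
        out["cesd"] = vals.sum(axis=1).where(~vals.isna().any(axis=1))

    for col in ("cdi_receptive", "cdi_expressive"):
        if col in df.columns:
            out[col] = df[col]

    w_cols = [f"diet_w_{g}" for g in reg["diet"]["maternal_groups"]]
    if set(w_cols) <= set(df.columns):
        k = _row_sum(df, w_cols)
        out["maternal_mdd"] = (k >= reg["diet"]["maternal_threshold"]).astype(float).where(k.notna())
    c_cols = [f"diet_c_{g}" for g in reg["diet"]["child_groups"]]
    if set(c_cols) <= set(df.columns):
        k = _row_sum(df, c_cols)
        out["child_mdd"] = (k >= reg["diet"]["child_threshold"]).astype(float).where(k.notna())

    for col in ("hygienic_latrine", "handwashing_station", "potty_use", "lead_knowledge"):
        if col in df.columns:
            out[col] = df[col]
    return out
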