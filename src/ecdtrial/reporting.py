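"""CONSORT-style accounting, results-table assembly, run provenance.

Percentages are always re-derived from the stored counts (never stored
independently), rounded half-up to one decimal; effect estimates print to
two decimals, prevalences as proportions to two decimals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .estimation import EffectEstimate
from .synthetic import TrialDataset

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Display rounding: 0.05 -> 0.1 regardless of binary representation."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FlowAccounting:
    """Participant flow: enrolled / lost / analysed, per arm and overall."""

    enrolled: dict[str, int]
    lost: dict[str, int]
    partial: int = 0
    analyzed_per_outcome: dict[str, int] = field(default_factory=dict)

    @property
    def total_enrolled(self) -> int:
        return sum(self.enrolled.values())

    @property
    def total_lost(self) -> int:
        return sum(self.lost.values())

    def pct_lost(self, arm: str | None = None) -> float:
        """100 * lost / enrolled, one decimal, recomputed on demand."""
        if arm is None:
            enrolled, lost = self.total_enrolled, self.total_lost
        else:
            enrolled, lost = self.enrolled[arm], self.lost[arm]
        if enrolled == 0:
            return 0.0
        return round_half_up(100.0 * lost / enrolled, 1)

    def analyzed(self, arm: str | None = None) -> int:
        if arm is None:
            return self.total_enrolled - self.total_lost
        return self.enrolled[arm] - self.lost[arm]

    def to_dict(self) -> dict:
        return {
            "enrolled": dict(self.enrolled), "lost": dict(self.lost),
            "partial": self.partial,
            "analyzed": {a: self.analyzed(a) for a in self.enrolled},
            "pct_lost": {a: self.pct_lost(a) for a in self.enrolled},
            "total": {"enrolled": self.total_enrolled, "lost": self.total_lost,
                      "analyzed": self.analyzed(), "pct_lost": self.pct_lost()},
            "analyzed_per_outcome": dict(self.analyzed_per_outcome),
        }


def consort_flow(dataset: TrialDataset | pd.DataFrame,
                 analyzed_per_outcome: dict[str, int] | None = None,
                 partial: int = 0) -> FlowAccounting:
    """Count enrolment and loss to follow-up per arm from the flags."""
    df = dataset.df if isinstance(dataset, TrialDataset) else dataset
    enrolled = df.groupby("arm").size().to_dict()
    lost = df[~df["followed_up"].astype(bool)].groupby("arm").size() \
        .reindex(enrolled.keys(), fill_value=0).to_dict()
    return FlowAccounting(enrolled=enrolled, lost=lost, partial=partial,
                          analyzed_per_outcome=analyzed_per_outcome or {})


def compute_descriptives(scored: pd.DataFrame, outcomes: dict[str, str],
                         arms: tuple[str, ...] = ("control", "group", "combined")
                         ) -> dict[str, dict[str, str]]:
    """Unadjusted per-arm summaries: 'mean±SD' for continuous outcomes,
    'n (pct%)' for binary ones. ``outcomes`` maps name -> scale."""
    df = scored
    if "followed_up" in df.columns:
        df = df[df["followed_up"].astype(bool)]
    out: dict[str, dict[str, str]] = {}
    for name, scale in outcomes.items():
        row = {}
        for arm in arms:
            vals = df.loc[df["arm"] == arm, name].dropna()
            if len(vals) == 0:
                row[arm] = ""
            elif scale == "binary":
                n = int(vals.sum())
                row[arm] = f"{n} ({round_half_up(100.0 * n / len(vals), 0):.0f}%)"
            else:
                row[arm] = f"{vals.mean():.1f}±{vals.std(ddof=1):.1f}"
        out[name] = row
    return out


def results_table(effects: list[EffectEstimate],
                  descriptives: dict[str, dict[str, str]] | None = None,
                  arms: tuple[str, ...] = ("control", "group", "combined"),
                  comparisons: tuple[tuple[str, str], ...] = (("group", "control"),
                                                              ("combined", "control")),
                  ) -> pd.DataFrame:
    """One row per outcome: unadjusted per-arm summaries alongside the
    adjusted difference (95% CI) for each comparison. A missing comparison
    leaves a blank cell and logs it."""
    descriptives = descriptives or {}
    by_key = {(e.outcome, e.comparison): e for e in effects}
    outcome_order = list(dict.fromkeys(e.outcome for e in effects))
    rows = []
    for outcome in outcome_order:
        row: dict[str, str] = {"outcome": outcome}
        desc = descriptives.get(outcome, {})
        for arm in arms:
            row[arm] = desc.get(arm, "")
        for comp in comparisons:
            label = f"{comp[0]} vs {comp[1]}"
            e = by_key.get((outcome, comp))
            if e is None:
                logger.warning("results_table: no estimate for %s, %s", outcome, label)
                row[label] = ""
            else:
                row[label] = (f"{e.estimate:.2f} "
                              f"({e.ci_low:.2f} to {e.ci_high:.2f})")
        rows.append(row)
    cols = ["outcome", *arms, *(f"{c[0]} vs {c[1]}" for c in comparisons)]
    return pd.DataFrame(rows, columns=cols)


def table_to_markdown(table: pd.DataFrame) -> str:
    header = "| " + " | ".join(table.columns) + " |"
    sep = "|" + "|".join("---" for _ in table.columns) + "|"
    body = ["| " + " | ".join(str(v) for v in row) + " |"
            for row in table.itertuples(index=False)]
    return "\n".join([header, sep, *body]) + "\n"


def write_manifest(path, manifest: dict) -> None:
    """Persist the run manifest (seeds, B, retained covariates, exclusion
    counts); re-running with these inputs reproduces every cell."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
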