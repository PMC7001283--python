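"""Any-positive integration of the three classification analyses.

A concentration tier is DDI overall if at least one of the three analyses
(PA, PCA, 2DC) calls it DDI; a chemical is DDI if any tested tier is DDI
overall.  Indeterminate calls count as non-positive — the vote only ever
escalates on an affirmative DDI call.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Mapping

import pandas as pd

from .containers import DDI, INDETERMINATE, NON_DDI

ANALYSES = ("PA", "PCA", "2DC")
_VALID = {DDI, NON_DDI, INDETERMINATE}


@dataclasses.dataclass
class ClassCall:
    """One analysis' verdict on one condition.

    ``score`` is the posterior probability (PA), the PC1 score (PCA) or the
    branch purity (2DC).
    """

    analysis: str
    condition: str
    call: str
    score: float

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValueError(f"unknown analysis {self.analysis!r}")
        if self.call not in _VALID:
            raise ValueError(f"invalid call {self.call!r}")


@dataclasses.dataclass
class IntegratedCall:
    """Per-tier and chemical-level integrated verdicts for one chemical."""

    chemical: str
    tier_calls: dict[str, dict[str, str]]   # tier -> analysis -> call
    tier_overall: dict[str, str]            # tier -> DDI / non-DDI
    chemical_call: str


def overall_tier_call(calls: Mapping[str, str]) -> str:
    """DDI iff at least one analysis says DDI; indeterminate is non-positive."""
    missing = set(ANALYSES) - set(calls)
    if missing:
        raise ValueError(f"missing analyses for tier: {sorted(missing)}")
    bad = {a: c for a, c in calls.items() if c not in _VALID}
    if bad:
        raise ValueError(f"invalid calls: {bad}")
    return DDI if any(calls[a] == DDI for a in ANALYSES) else NON_DDI


def integrate_calls(tier_calls: Mapping[str, Mapping[str, str]],
                    chemical: str = "") -> IntegratedCall:
    """Roll per-tier, per-analysis calls up to tier and chemical verdicts."""
    if not tier_calls:
        raise ValueError("no tiers supplied")
    tier_overall = {tier: overall_tier_call(calls)
                    for tier, calls in tier_calls.items()}
    chemical_call = DDI if DDI in tier_overall.values() else NON_DDI
    return IntegratedCall(
        chemical=chemical,
        tier_calls={t: dict(c) for t, c in tier_calls.items()},
        tier_overall=tier_overall,
        chemical_call=chemical_call,
    )


def integrate_study(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Integrate a long calls table into per-tier and per-chemical tables.

    ``calls`` needs columns chemical, tier, PA_call, PCA_call, DC_call.
    Returns (per-tier table with an ``overall_call`` column appended,
    chemical-level table with one row per chemical).
    """
    required = {"chemical", "tier", "PA_call", "PCA_call", "DC_call"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"calls table missing columns: {sorted(missing)}")

    out = calls.copy()
    out["overall_call"] = [
        overall_tier_call({"PA": r.PA_call, "PCA": r.PCA_call, "2DC": r.DC_call})
        for r in calls.itertuples()
    ]
    chem = (out.groupby("chemical", sort=False)["overall_call"]
            .apply(lambda c: DDI if (c == DDI).any() else NON_DDI)
            .rename("chemical_call").reset_index())
    return out, chem


def vote_truth_table() -> pd.DataFrame:
    """All 27 combinations of the three analyses and their overall call."""
    rows = []
    for pa, pca, dc in itertools.product(sorted(_VALID), repeat=3):
        rows.append(dict(PA=pa, PCA=pca, DC=dc,
                         overall=overall_tier_call({"PA": pa, "PCA": pca,
                                                    "2DC": dc})))
    return pd.DataFrame(rows)
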