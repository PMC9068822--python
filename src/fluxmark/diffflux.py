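"""Differentially active reactions between two conditions.

A single LP optimum is one point on a (possibly large) optimal face, so
flux differences between two conditions are tested against an ensemble of
near-optimal states: the LP is re-solved ``n`` times per condition with the
objective coefficients multiplied by independent U(1-jitter, 1+jitter)
draws.  Reactions whose activity distributions differ between conditions by
a two-sample rank-sum test, Benjamini-Hochberg corrected across all
reactions, are called increased/decreased.

Bound-saturated reactions are invariant to objective jitter and therefore
have zero ensemble variance; the degenerate rank test is replaced by an
exact mean comparison in that case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import Category, solve_flux_state
from .network import MetabolicNetwork

__all__ = [
    "FluxEnsemble",
    "ReactionTestResult",
    "sample_flux_ensemble",
    "test_differential_reactions",
    "summarize_subsystems",
    "results_to_frame",
]


@dataclass
class FluxEnsemble:
    condition: str
    activities: pd.DataFrame  # n draws (rows) x parent reactions (columns)
    seed: int
    jitter: float

    @property
    def n(self) -> int:
        return len(self.activities)


@dataclass(frozen=True)
class ReactionTestResult:
    reaction_id: str
    subsystem: str
    mean_a: float
    mean_b: float
    difference: float  # mean_b - mean_a
    p_raw: float
    p_adj: float
    direction: str  # increased / decreased / unchanged


def sample_flux_ensemble(
    split_net: MetabolicNetwork,
    categories: dict[str, Category],
    *,
    n: int = 50,
    jitter: float = 0.05,
    seed: int = 0,
    epsilon: float = 1e-4,
    vmax: float | None = None,
    condition: str = "condition",
) -> FluxEnsemble:
    """Seeded ensemble of ``n`` jittered LP optima (activity space)."""
    if n < 2:
        raise ValueError("ensemble needs n >= 2")
    if not (0 <= jitter < 1):
        raise ValueError("jitter must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        w = rng.uniform(1.0 - jitter, 1.0 + jitter, size=len(split_net.reactions))
        fs = solve_flux_state(
            split_net,
            categories,
            epsilon=epsilon,
            vmax=vmax,
            condition=condition,
            objective_weights=w,
        )
        if fs.status != "optimal":
            raise RuntimeError(f"ensemble member {i} is {fs.status}")
        rows.append(fs.activity)
    acts = pd.DataFrame(rows)
    return FluxEnsemble(condition, acts, seed, jitter)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    if np.allclose(pooled, pooled[0], atol=1e-12):
        return 1.0
    if np.ptp(x) < 1e-12 and np.ptp(y) < 1e-12:
        # both degenerate at different values: exact separation
        return 0.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def test_differential_reactions(
    a: FluxEnsemble, b: FluxEnsemble, alpha: float = 0.01
) -> list[ReactionTestResult]:
    """Per-reaction rank-sum tests of *b* (treatment) vs *a* (control), BH-adjusted."""
    cols_a, cols_b = set(a.activities.columns), set(b.activities.columns)
    if cols_a != cols_b:
        raise ValueError(
            f"ensembles disagree on reactions: {sorted(cols_a ^ cols_b)[:10]}"
        )
    reactions = list(a.activities.columns)
    p_raw = np.array(
        [
            _rank_sum_p(a.activities[r].to_numpy(), b.activities[r].to_numpy())
            for r in reactions
        ]
    )
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    results = []
    for r, pr, pa in zip(reactions, p_raw, p_adj):
        ma = float(a.activities[r].mean())
        mb = float(b.activities[r].mean())
        diff = mb - ma
        if pa < alpha and diff > 0:
            direction = "increased"
        elif pa < alpha and diff < 0:
            direction = "decreased"
        else:
            direction = "unchanged"
        results.append(
            ReactionTestResult(r, "unassigned", ma, mb, diff, float(pr), float(pa), direction)
        )
    return results


def annotate_subsystems(
    results: list[ReactionTestResult], net: MetabolicNetwork
) -> list[ReactionTestResult]:
    sub = {r.id: r.subsystem for r in net.reactions}
    return [
        ReactionTestResult(
            t.reaction_id,
            sub.get(t.reaction_id, "unassigned"),
            t.mean_a,
            t.mean_b,
            t.difference,
            t.p_raw,
            t.p_adj,
            t.direction,
        )
        for t in results
    ]


def summarize_subsystems(results: list[ReactionTestResult]) -> pd.DataFrame:
    """Counts of significantly increased/decreased reactions per subsystem."""
    sig = [t for t in results if t.direction != "unchanged"]
    if not sig:
        return pd.DataFrame(columns=["subsystem", "increased", "decreased"]).set_index(
            "subsystem"
        )
    df = pd.DataFrame(
        {"subsystem": [t.subsystem for t in sig], "direction": [t.direction for t in sig]}
    )
    out = (
        df.pivot_table(index="subsystem", columns="direction", aggfunc="size", fill_value=0)
        .reindex(columns=["increased", "decreased"], fill_value=0)
    )
    out.columns.name = None
    return out


def results_to_frame(results: list[ReactionTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reaction_id": t.reaction_id,
                "subsystem": t.subsystem,
                "mean_ctrl": t.mean_a,
                "mean_trt": t.mean_b,
                "diff": t.difference,
                "p_raw": t.p_raw,
                "p_adj": t.p_adj,
                "direction": t.direction,
            }
            for t in results
        ]
    )
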