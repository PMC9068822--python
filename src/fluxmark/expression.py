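"""Expression-constrained flux prediction.

The condition-specific flux state is the solution of a single linear
program in the spirit of iMAT-style integration, but fully linear (no
binary indicators): on the reversibility-split network with fluxes
``v >= 0``, the activity of a parent reaction r is ``w_r = v_{r,f} +
v_{r,b}`` and the program is

    maximize   sum_{r in UP} w_r  -  sum_{r in DOWN} w_r  -  eps * sum_r w_r
    subject to S v = 0,   0 <= v <= u.

UP/DOWN categories come from a differential-expression table thresholded
at (FDR, |log2FC|) cutoffs and propagated to reactions through their GPR
rules.  The small parsimony weight ``eps`` makes the reported optimum the
minimum-total-activity member of the optimal face, so alternate optima do
not inflate neutral reactions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .network import MetabolicNetwork, build_stoichiometric_matrix

__all__ = [
    "Category",
    "DifferentialExpressionTable",
    "ExpressionState",
    "FluxState",
    "read_de_table",
    "categorize_genes",
    "map_genes_to_reactions",
    "solve_flux_state",
    "predicted_histone_flux",
]

MASS_BALANCE_TOL = 1e-6


class Category(enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    NEUTRAL = "NEUTRAL"


@dataclass(frozen=True)
class ExpressionState:
    up: frozenset[str]
    down: frozenset[str]
    fdr_cut: float
    lfc_cut: float

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up/down gene sets overlap")

    def mirrored(self) -> "ExpressionState":
        """Swap up and down — the baseline condition implied by a
        treatment-vs-control table."""
        return ExpressionState(self.down, self.up, self.fdr_cut, self.lfc_cut)


#: rows of {gene_id, log2fc, fdr}
DifferentialExpressionTable = pd.DataFrame


def read_de_table(path) -> DifferentialExpressionTable:
    de = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "fdr"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if de["gene_id"].duplicated().any():
        dups = de.loc[de["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in DE table: {dups[:5]}")
    if ((de["fdr"] < 0) | (de["fdr"] > 1)).any():
        raise ValueError("fdr column outside [0, 1]")
    return de


def categorize_genes(
    de: DifferentialExpressionTable, fdr_cut: float = 0.01, lfc_cut: float = 2.0
) -> ExpressionState:
    """Threshold a DE table into up/down gene sets.

    up:   fdr < fdr_cut and log2fc >= +lfc_cut
    down: fdr < fdr_cut and log2fc <= -lfc_cut
    """
    if fdr_cut <= 0 or lfc_cut <= 0:
        raise ValueError("thresholds must be positive")
    if len(de) == 0:
        return ExpressionState(frozenset(), frozenset(), fdr_cut, lfc_cut)
    sig = de["fdr"] < fdr_cut
    up = frozenset(de.loc[sig & (de["log2fc"] >= lfc_cut), "gene_id"])
    down = frozenset(de.loc[sig & (de["log2fc"] <= -lfc_cut), "gene_id"])
    return ExpressionState(up, down, fdr_cut, lfc_cut)


def map_genes_to_reactions(
    net: MetabolicNetwork,
    state: ExpressionState,
    id_mapping: dict[str, str] | None = None,
) -> dict[str, Category]:
    """Propagate gene categories to reactions through GPR rules.

    A reaction is UP if at least one of its genes is up and none are down,
    DOWN symmetrically, and NEUTRAL otherwise (empty rules, mixed signals).
    ``id_mapping`` translates model gene ids to DE-table gene ids first;
    unmapped genes are neutral.
    """
    cats: dict[str, Category] = {}
    for r in net.reactions:
        genes = {id_mapping.get(g, g) for g in r.gene_rule.genes} if id_mapping else set(
            r.gene_rule.genes
        )
        has_up = bool(genes & state.up)
        has_down = bool(genes & state.down)
        if has_up and not has_down:
            cats[r.id] = Category.UP
        elif has_down and not has_up:
            cats[r.id] = Category.DOWN
        else:
            cats[r.id] = Category.NEUTRAL
    return cats


@dataclass
class FluxState:
    condition: str
    flux: dict[str, float]  # parent reaction id -> net flux v_f - v_b
    activity: dict[str, float]  # parent reaction id -> v_f + v_b
    objective: float
    status: str
    split_flux: np.ndarray = field(repr=False, default=None)

    def as_series(self) -> pd.Series:
        return pd.Series(self.flux, name=self.condition)


def _objective_coefficients(
    split_net: MetabolicNetwork,
    categories: dict[str, Category],
    epsilon: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    sign = {Category.UP: 1.0, Category.DOWN: -1.0, Category.NEUTRAL: 0.0}
    c = np.empty(len(split_net.reactions))
    for j, r in enumerate(split_net.reactions):
        parent = split_net.parent_map.get(r.id, r.id)
        cat = categories.get(parent, Category.NEUTRAL)
        c[j] = sign[cat] - epsilon
    if weights is not None:
        c = c * weights
    return c


def solve_flux_state(
    split_net: MetabolicNetwork,
    categories: dict[str, Category],
    *,
    epsilon: float = 1e-4,
    vmax: float | None = None,
    condition: str = "condition",
    objective_weights: np.ndarray | None = None,
) -> FluxState:
    """Solve the expression-consistency LP on a reversibility-split network.

    Parameters
    ----------
    split_net
        Output of :func:`fluxmark.network.split_reversible` (all lower
        bounds zero).  Categories are keyed by parent reaction id.
    epsilon
        Parsimony weight; must stay well below 1 so it only tie-breaks.
    vmax
        Optional cap overriding larger upper bounds (infinite bounds are
        always capped so the LP cannot be unbounded).
    objective_weights
        Optional per-split-reaction multiplicative jitter on the objective
        (used by the ensemble sampler).
    """
    if any(r.lower_bound < 0 for r in split_net.reactions):
        raise ValueError("network must be reversibility-split (non-negative bounds)")
    unknown = set(categories) - {
        split_net.parent_map.get(r.id, r.id) for r in split_net.reactions
    }
    if unknown:
        raise KeyError(f"categories reference unknown reactions: {sorted(unknown)[:5]}")

    sm = build_stoichiometric_matrix(split_net)
    ub = np.array([r.upper_bound for r in split_net.reactions], dtype=float)
    cap = vmax if vmax is not None else 1000.0
    ub = np.minimum(ub, cap) if vmax is not None else np.where(np.isinf(ub), cap, ub)
    c = _objective_coefficients(split_net, categories, epsilon, objective_weights)

    res = linprog(
        -c,
        A_eq=sm.S,
        b_eq=np.zeros(sm.shape[0]),
        bounds=np.column_stack([np.zeros_like(ub), ub]),
        method="highs",
    )
    if res.status == 2:
        return FluxState(condition, {}, {}, math.nan, "infeasible")
    if not res.success:
        raise RuntimeError(f"LP solver failure ({res.status}): {res.message}")

    v = np.asarray(res.x)
    flux: dict[str, float] = {}
    activity: dict[str, float] = {}
    for j, r in enumerate(split_net.reactions):
        parent = split_net.parent_map.get(r.id, r.id)
        direction = -1.0 if r.id.endswith("_b") and parent != r.id else 1.0
        flux[parent] = flux.get(parent, 0.0) + direction * v[j]
        activity[parent] = activity.get(parent, 0.0) + v[j]

    residual = np.abs(sm.S @ v).max() if v.size else 0.0
    if residual > MASS_BALANCE_TOL:
        raise RuntimeError(f"mass-balance residual {residual:.2e} exceeds tolerance")
    return FluxState(condition, flux, activity, float(-res.fun), "optimal", split_flux=v)


def predicted_histone_flux(fs: FluxState) -> dict[str, float]:
    """Bulk histone-mark predictions: the two demand-sink fluxes.

    Acetylation is read from the nuclear acetyl-CoA demand, methylation
    from the nuclear SAM demand.
    """
    if fs.status != "optimal":
        raise ValueError(f"flux state is {fs.status}, not optimal")
    try:
        return {
            "acetylation": fs.flux["DM_histone_ac"],
            "methylation": fs.flux["DM_histone_me"],
        }
    except KeyError as exc:
        raise KeyError(
            "model not augmented: histone demand reactions absent"
        ) from exc
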