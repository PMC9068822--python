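"""Constraint-based metabolic network model.

A :class:`MetabolicNetwork` is an ordered collection of metabolites and
reactions with flux bounds (mmol/gDW/h) and gene-protein-reaction (GPR)
rules.  It is the substrate for the stoichiometric matrix ``S`` used by
flux balance analysis: feasible steady states satisfy ``S @ v = 0`` with
``lb <= v <= ub``.

SBML import/export is delegated to cobrapy so both the fbc dialect and the
legacy note-embedded dialect (``GENE_ASSOCIATION``/``SUBSYSTEM`` notes) of
Recon-family models are accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Metabolite",
    "GeneRule",
    "Reaction",
    "MetabolicNetwork",
    "StoichiometricMatrix",
    "NetworkValidationError",
    "read_sbml",
    "write_sbml",
    "build_stoichiometric_matrix",
    "split_reversible",
    "validate_network",
    "network_to_tsv",
]

#: community-convention default bounds for Recon-family models
DEFAULT_BOUND = 1000.0


class NetworkValidationError(ValueError):
    """Raised when a network (or SBML file) violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise NetworkValidationError(f"metabolite {self.id!r}: empty compartment")


_GENE_TOKEN = re.compile(r"[A-Za-z0-9_.\-]+")


@dataclass(frozen=True)
class GeneRule:
    """Boolean AND/OR tree over gene ids, stored in cobra rule syntax.

    An empty expression means the reaction has no gene association.
    """

    expression: str = ""

    @property
    def genes(self) -> frozenset[str]:
        toks = _GENE_TOKEN.findall(self.expression)
        return frozenset(t for t in toks if t.lower() not in ("and", "or"))

    def __bool__(self) -> bool:
        return bool(self.expression.strip())


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gene_rule: GeneRule = field(default_factory=GeneRule)
    subsystem: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions import/export a single species."""
        return len(self.stoichiometry) == 1

    def equation(self, arrow: str | None = None) -> str:
        arrow = arrow or ("<=>" if self.reversible else "-->")
        lhs = [
            (f"{-c:g} " if c != -1 else "") + m
            for m, c in sorted(self.stoichiometry.items())
            if c < 0
        ]
        rhs = [
            (f"{c:g} " if c != 1 else "") + m
            for m, c in sorted(self.stoichiometry.items())
            if c > 0
        ]
        return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    name: str = "network"
    #: for split networks: child reaction id -> parent reaction id
    parent_map: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gene_rule.genes
        return frozenset(out)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def exchange_for(self, metabolite_id: str) -> Reaction | None:
        """The exchange reaction of an (extracellular) species, if any."""
        for r in self.reactions:
            if r.is_exchange and metabolite_id in r.stoichiometry:
                return r
        return None

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            name=self.name,
            parent_map=dict(self.parent_map),
        )


@dataclass
class StoichiometricMatrix:
    S: sp.csc_matrix
    row_index: list[str]  # metabolite ids
    col_index: list[str]  # reaction ids

    @property
    def shape(self) -> tuple[int, int]:
        return self.S.shape

    def dense(self) -> np.ndarray:
        return self.S.toarray()


# ---------------------------------------------------------------------------
# operations


def validate_network(net: MetabolicNetwork) -> list[dict[str, str]]:
    """Structural findings; empty list means the network is valid.

    Each finding is ``{"kind": ..., "entity": ..., "detail": ...}`` so callers
    can report every problem at once instead of failing on the first.
    """
    findings: list[dict[str, str]] = []
    seen_m: set[str] = set()
    for m in net.metabolites:
        if m.id in seen_m:
            findings.append(
                {"kind": "duplicate-id", "entity": m.id, "detail": "metabolite id repeated"}
            )
        seen_m.add(m.id)
    seen_r: set[str] = set()
    for r in net.reactions:
        if r.id in seen_r:
            findings.append(
                {"kind": "duplicate-id", "entity": r.id, "detail": "reaction id repeated"}
            )
        seen_r.add(r.id)
        for mid in r.stoichiometry:
            if mid not in seen_m and mid not in {m.id for m in net.metabolites}:
                findings.append(
                    {
                        "kind": "unresolved-metabolite",
                        "entity": r.id,
                        "detail": f"references unknown metabolite {mid!r}",
                    }
                )
        if r.lower_bound > r.upper_bound:  # unreachable via constructor, belt-and-braces
            findings.append(
                {"kind": "bad-bounds", "entity": r.id, "detail": "lb > ub"}
            )
    return findings


def build_stoichiometric_matrix(net: MetabolicNetwork) -> StoichiometricMatrix:
    row = {m: i for i, m in enumerate(net.metabolite_ids)}
    data, ri, ci = [], [], []
    for j, r in enumerate(net.reactions):
        for mid, coef in r.stoichiometry.items():
            ri.append(row[mid])
            ci.append(j)
            data.append(float(coef))
    S = sp.csc_matrix(
        (data, (ri, ci)), shape=(len(net.metabolites), len(net.reactions))
    )
    return StoichiometricMatrix(S=S, row_index=net.metabolite_ids, col_index=net.reaction_ids)


def split_reversible(net: MetabolicNetwork) -> MetabolicNetwork:
    """Replace each reversible reaction by irreversible forward/backward halves.

    The split network has only non-negative fluxes, so the activity of a
    parent reaction is the linear form ``v_f + v_b`` and its net flux is
    ``v_f - v_b`` — both usable directly in an LP objective.
    """
    reactions: list[Reaction] = []
    parent_map: dict[str, str] = {}
    for r in net.reactions:
        if r.reversible:
            fwd = replace(r, id=r.id + "_f", lower_bound=0.0, upper_bound=r.upper_bound)
            bwd = replace(
                r,
                id=r.id + "_b",
                lower_bound=0.0,
                upper_bound=-r.lower_bound,
                stoichiometry={m: -c for m, c in r.stoichiometry.items()},
            )
            reactions += [fwd, bwd]
            parent_map[fwd.id] = r.id
            parent_map[bwd.id] = r.id
        else:
            reactions.append(r)
            parent_map[r.id] = r.id
    return MetabolicNetwork(
        metabolites=list(net.metabolites),
        reactions=reactions,
        name=net.name + "_split",
        parent_map=parent_map,
    )


# ---------------------------------------------------------------------------
# SBML and TSV I/O


def _to_cobra(net: MetabolicNetwork):
    import cobra

    model = cobra.Model(net.name)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        for m in net.metabolites
    }
    rxns = []
    for r in net.reactions:
        cr = cobra.Reaction(
            r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        if r.gene_rule:
            cr.gene_reaction_rule = r.gene_rule.expression
        cr.subsystem = r.subsystem
        cr.notes["SUBSYSTEM"] = r.subsystem
        rxns.append(cr)
    model.add_reactions(rxns)
    return model


def _from_cobra(model) -> MetabolicNetwork:
    metabolites = [
        Metabolite(m.id, name=m.name or "", compartment=(m.compartment or "c").lower())
        for m in model.metabolites
    ]
    reactions = []
    for r in model.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if lb is None or ub is None:
            lb, ub = (-DEFAULT_BOUND, DEFAULT_BOUND) if r.reversibility else (0.0, DEFAULT_BOUND)
        subsystem = r.notes.get("SUBSYSTEM") or r.subsystem or "unassigned"
        if not r.metabolites:
            raise NetworkValidationError(
                f"reaction {r.id!r}: SBML entry carries no stoichiometry"
            )
        reactions.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(lb),
                upper_bound=float(ub),
                gene_rule=GeneRule(r.gene_reaction_rule or ""),
                subsystem=subsystem,
            )
        )
    return MetabolicNetwork(metabolites=metabolites, reactions=reactions, name=model.id or "network")


def read_sbml(path) -> MetabolicNetwork:
    """Read an SBML (L2/L3, fbc or note-embedded dialect) model.

    Bounds absent from the file default to [-1000, 1000] for reversible and
    [0, 1000] for irreversible reactions.
    """
    import logging

    import cobra.io

    # cobra warns about the absent optimization objective; bounds/GPRs are
    # all we consume here
    logging.getLogger("cobra.io.sbml").setLevel(logging.ERROR)
    try:
        model = cobra.io.read_sbml_model(str(path))
    except OSError:
        raise
    except Exception as exc:  # libsbml reports the offending line in its message
        raise NetworkValidationError(f"malformed SBML in {path}: {exc}") from exc
    return _from_cobra(model)


def write_sbml(net: MetabolicNetwork, path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(_to_cobra(net), str(path))


def network_to_tsv(net: MetabolicNetwork, path) -> None:
    """Plain-text dump (one row per reaction) for human inspection."""
    import pandas as pd

    rows = [
        {
            "reaction_id": r.id,
            "equation": r.equation(),
            "lb": r.lower_bound,
            "ub": r.upper_bound,
            "gene_rule": r.gene_rule.expression,
            "subsystem": r.subsystem,
        }
        for r in net.reactions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
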