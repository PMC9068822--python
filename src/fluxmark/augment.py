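"""Histone-modification augmentation and growth-media bounds.

Genome-scale reconstructions stop at the metabolic precursors of chromatin
chemistry.  To let a flux state speak about bulk histone marks, the network
is augmented with a small set of nuclear reactions: transport of the donors
acetyl-CoA and S-adenosyl-L-methionine (SAM) into the nucleus, the
acetyl-transfer and methyl-transfer reactions themselves, export of the
S-adenosyl-L-homocysteine (SAH) by-product, a histone-tail supply, and two
demand sinks whose fluxes are the model's predictions of bulk histone
acetylation and methylation.

Histone tails are a non-conserved pseudo-species with unconstrained supply,
so modification flux is limited only by donor availability — the bulk-mark
reading of the model.

Growth media enter as uptake caps on exchange reactions: 1 mM of a nutrient
maps to 1 mmol/gDW/h of maximum uptake by default (a single configurable
scale), and fatty-acid exchanges are closed unless the condition supplies
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .network import GeneRule, MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "AugmentationSpec",
    "MediaConfig",
    "Nutrient",
    "default_augmentation_spec",
    "augment_with_histone_reactions",
    "apply_media_config",
    "control_media",
    "octanoate_media",
    "linoleate_media",
]


@dataclass
class AugmentationSpec:
    reactions: list[Reaction]
    metabolites: list[Metabolite]
    required_precursors: list[str]
    nucleus_compartment: str = "n"


def default_augmentation_spec(
    accoa: str = "accoa_c",
    coa: str = "coa_c",
    sam: str = "amet_c",
    sah: str = "ahcys_c",
    nucleus: str = "n",
) -> AugmentationSpec:
    """The fixed 8-reaction default augmentation.

    2 donor transports + 2 modification reactions + 2 demand sinks +
    1 histone supply + 1 nuclear SAH export.  Acetyl-CoA transport is an
    antiport against free CoA so the nuclear CoA released by acetylation is
    returned to the cytosol without an extra reaction.
    """
    n = nucleus
    mets = [
        Metabolite(f"accoa_{n}", "acetyl-CoA (nuclear)", n),
        Metabolite(f"coa_{n}", "coenzyme A (nuclear)", n),
        Metabolite(f"amet_{n}", "S-adenosyl-L-methionine (nuclear)", n),
        Metabolite(f"ahcys_{n}", "S-adenosyl-L-homocysteine (nuclear)", n),
        Metabolite(f"hist_{n}", "histone tail (nuclear)", n),
        Metabolite(f"histac_{n}", "acetylated histone tail (nuclear)", n),
        Metabolite(f"histme_{n}", "methylated histone tail (nuclear)", n),
    ]
    sub = "Histone modification"
    rxns = [
        Reaction(
            "ACCOAtn",
            {accoa: -1, f"coa_{n}": -1, f"accoa_{n}": 1, coa: 1},
            name="acetyl-CoA nuclear antiport (vs CoA)",
            subsystem="Transport, nuclear",
        ),
        Reaction(
            "AMETtn",
            {sam: -1, f"amet_{n}": 1},
            name="SAM nuclear transport",
            subsystem="Transport, nuclear",
        ),
        Reaction(
            "HIST_AC",
            {f"accoa_{n}": -1, f"hist_{n}": -1, f"histac_{n}": 1, f"coa_{n}": 1},
            name="histone acetyltransferase (bulk)",
            gene_rule=GeneRule("KAT2A or KAT2B"),
            subsystem=sub,
        ),
        Reaction(
            "HIST_ME",
            {f"amet_{n}": -1, f"hist_{n}": -1, f"histme_{n}": 1, f"ahcys_{n}": 1},
            name="histone methyltransferase (bulk)",
            gene_rule=GeneRule("EHMT2 or KMT2A"),
            subsystem=sub,
        ),
        Reaction(
            "AHCYStn",
            {f"ahcys_{n}": -1, sah: 1},
            name="SAH nuclear export",
            subsystem="Transport, nuclear",
        ),
        Reaction(
            "SK_hist",
            {f"hist_{n}": 1},
            name="histone tail supply (pseudo)",
            subsystem=sub,
        ),
        Reaction(
            "DM_histone_ac",
            {f"histac_{n}": -1},
            name="bulk histone acetylation demand",
            subsystem=sub,
        ),
        Reaction(
            "DM_histone_me",
            {f"histme_{n}": -1},
            name="bulk histone methylation demand",
            subsystem=sub,
        ),
    ]
    return AugmentationSpec(
        reactions=rxns,
        metabolites=mets,
        required_precursors=[accoa, coa, sam, sah],
        nucleus_compartment=n,
    )


def augment_with_histone_reactions(
    net: MetabolicNetwork, spec: AugmentationSpec | None = None
) -> MetabolicNetwork:
    """Return a copy of *net* with the spec's nuclear histone chemistry added.

    The reaction count increases by exactly ``len(spec.reactions)``.
    Augmenting an already-augmented network raises (id collision guard).
    """
    spec = spec or default_augmentation_spec()
    missing = [
        m for m in spec.required_precursors if m not in {x.id for x in net.metabolites}
    ]
    if missing:
        raise KeyError(
            "network lacks required precursor species: " + ", ".join(sorted(missing))
        )
    existing_r = {r.id for r in net.reactions}
    dup = sorted({r.id for r in spec.reactions} & existing_r)
    if dup:
        raise ValueError(f"duplicate-id: reactions already present: {', '.join(dup)}")
    out = net.copy()
    existing_m = {m.id for m in out.metabolites}
    out.metabolites += [m for m in spec.metabolites if m.id not in existing_m]
    out.reactions += list(spec.reactions)
    out.name = net.name + "+histone"
    return out


# ---------------------------------------------------------------------------
# media


@dataclass(frozen=True)
class Nutrient:
    metabolite_id: str
    mM: float
    max_uptake: float = float("inf")

    def __post_init__(self) -> None:
        if self.mM < 0:
            raise ValueError(f"{self.metabolite_id}: negative concentration")


@dataclass
class MediaConfig:
    name: str
    nutrients: list[Nutrient]
    scale: float = 1.0  # mmol/gDW/h of uptake capacity per mM
    closed_fatty_acids: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "MediaConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            name=raw["name"],
            nutrients=[
                Nutrient(
                    metabolite_id=n["id"],
                    mM=float(n["mM"]),
                    max_uptake=float(n.get("max_uptake", float("inf"))),
                )
                for n in raw.get("nutrients", [])
            ],
            scale=float(raw.get("scale", 1.0)),
            closed_fatty_acids=list(raw.get("closed_fatty_acids", [])),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "name": self.name,
            "scale": self.scale,
            "nutrients": [
                {"id": n.metabolite_id, "mM": n.mM}
                | ({} if n.max_uptake == float("inf") else {"max_uptake": n.max_uptake})
                for n in self.nutrients
            ],
            "closed_fatty_acids": list(self.closed_fatty_acids),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def apply_media_config(net: MetabolicNetwork, media: MediaConfig) -> MetabolicNetwork:
    """Set exchange uptake bounds from a media composition.

    Exchange reactions are written export-positive (``met_e <=>`` with
    coefficient -1), so uptake capacity is the negative lower bound.
    Listed nutrients get ``lb = -min(max_uptake, scale * mM)``; fatty-acid
    exchanges named in ``closed_fatty_acids`` but absent from the nutrient
    list are closed to uptake (``lb = 0``).  Secretion bounds are untouched.
    """
    out = net.copy()
    index = {r.id: i for i, r in enumerate(out.reactions)}

    def _set_uptake(metabolite_id: str, cap: float) -> None:
        ex = out.exchange_for(metabolite_id)
        if ex is None:
            raise KeyError(f"no exchange reaction found for nutrient {metabolite_id!r}")
        out.reactions[index[ex.id]] = replace(ex, lower_bound=-cap)

    supplied = set()
    for nut in media.nutrients:
        _set_uptake(nut.metabolite_id, min(nut.max_uptake, media.scale * nut.mM))
        supplied.add(nut.metabolite_id)
    for fa in media.closed_fatty_acids:
        if fa not in supplied:
            _set_uptake(fa, 0.0)
    out.name = f"{net.name}[{media.name}]"
    return out


# Study media. Base medium supplies glucose at 1.441 g/L and glutamine at
# 0.292 g/L, i.e. 8.0 and 2.0 mM after dividing by molar masses 180.16 and
# 146.14 g/mol. Treatments add 5 mM octanoate or 0.5 mM linoleate.
_FATTY_ACIDS = ["octa_e", "lnlc_e"]
_BASE = [Nutrient("glc_e", 8.0), Nutrient("gln_e", 2.0)]


def control_media() -> MediaConfig:
    return MediaConfig("control", list(_BASE), closed_fatty_acids=list(_FATTY_ACIDS))


def octanoate_media() -> MediaConfig:
    return MediaConfig(
        "octanoate", _BASE + [Nutrient("octa_e", 5.0)], closed_fatty_acids=list(_FATTY_ACIDS)
    )


def linoleate_media() -> MediaConfig:
    return MediaConfig(
        "linoleate", _BASE + [Nutrient("lnlc_e", 0.5)], closed_fatty_acids=list(_FATTY_ACIDS)
    )
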