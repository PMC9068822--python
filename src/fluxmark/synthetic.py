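"""Seeded generators for every input the pipeline consumes.

The centerpiece is a fixed ~30-reaction toy metabolic network wiring
glucose -> glycolysis -> acetyl-CoA, octanoate/linoleate beta-oxidation,
serine/glycine -> folate cycle, the methionine cycle (MAT, MS, AHCY, GNMT)
and, through the standard augmentation, nuclear histone acetylation and
methylation sinks.  Every enzymatic reaction carries a recognizable human
gene symbol and a pathway (subsystem) label, so differential-expression
presets map onto it directly.

The toy tracks a reduced element set: carbon skeletons plus the sulfur of
the methionine cycle.  Carrier moieties (CoA, THF, the adenosyl group of
SAM/SAH) are treated as zero-mass carriers, so e.g. acetyl-CoA is C2 and
SAM is C5S.  Internal reactions are exactly balanced in this accounting;
the formula table is packaged alongside the network for verification.

All stochastic generators take a :class:`SyntheticConfig` whose seed fixes
their output exactly (numpy integer-state PCG64), and every generator
returns a "truth sidecar" stating what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import augment_with_histone_reactions, default_augmentation_spec
from .chromatin import FeatureSet, GenomicInterval, PeakSet
from .network import GeneRule, MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "SyntheticConfig",
    "PRESETS",
    "make_toy_network",
    "toy_formula_table",
    "simulate_de_table",
    "simulate_expression_matrix",
    "simulate_peaks_and_features",
    "simulate_ct_table",
]


# ---------------------------------------------------------------------------
# the toy network


#: reduced formulas (carbon skeleton + methionine-cycle sulfur); carriers are C0
TOY_FORMULAS: dict[str, str] = {
    "glc": "C6", "pg3": "C3", "pyr": "C3", "accoa": "C2", "coa": "C0",
    "octa": "C8", "lnlc": "C18", "gln": "C5", "ser": "C3", "gly": "C2",
    "sarcs": "C3", "thf": "C0", "mlthf": "C1", "mthf": "C1", "f10thf": "C1",
    "met": "C5S", "amet": "C5S", "ahcys": "C4S", "hcys": "C4S", "co2": "C1",
    "hist": "C0", "histac": "C2", "histme": "C1",
}

_ONE_CARBON = "One-carbon/Methionine"


def _m(base: str, comp: str, name: str) -> Metabolite:
    return Metabolite(f"{base}_{comp}", name, comp)


def make_toy_network(augmented: bool = True) -> MetabolicNetwork:
    """The fixed toy network (deterministic constant).

    With ``augmented=True`` (default) the standard 8-reaction histone
    augmentation is already applied.
    """
    mets = [
        _m("glc", "e", "D-glucose"), _m("octa", "e", "octanoate"),
        _m("lnlc", "e", "linoleate"), _m("gln", "e", "L-glutamine"),
        _m("ser", "e", "L-serine"), _m("met", "e", "L-methionine"),
        _m("glc", "c", "D-glucose"), _m("pg3", "c", "3-phosphoglycerate"),
        _m("pyr", "c", "pyruvate"), _m("accoa", "c", "acetyl-CoA"),
        _m("coa", "c", "coenzyme A"), _m("octa", "c", "octanoate"),
        _m("lnlc", "c", "linoleate"), _m("gln", "c", "L-glutamine"),
        _m("ser", "c", "L-serine"), _m("gly", "c", "glycine"),
        _m("sarcs", "c", "sarcosine"), _m("thf", "c", "tetrahydrofolate"),
        _m("mlthf", "c", "5,10-methylene-THF"), _m("mthf", "c", "5-methyl-THF"),
        _m("f10thf", "c", "10-formyl-THF"), _m("met", "c", "L-methionine"),
        _m("amet", "c", "S-adenosyl-L-methionine"),
        _m("ahcys", "c", "S-adenosyl-L-homocysteine"),
        _m("hcys", "c", "L-homocysteine"), _m("co2", "c", "CO2"),
    ]

    def ex(met: str) -> Reaction:
        return Reaction(f"EX_{met.rsplit('_', 1)[0]}", {met: -1.0},
                        name=f"{met} exchange", subsystem="Exchange")

    def t(rid, frm, to, gene="", name=""):
        return Reaction(rid, {frm: -1.0, to: 1.0}, name=name,
                        gene_rule=GeneRule(gene), subsystem="Transport")

    exchanges = [ex("glc_e"), ex("octa_e"), ex("lnlc_e"), ex("gln_e"),
                 ex("ser_e"), ex("met_e"),
                 Reaction("EX_co2", {"co2_c": -1.0}, name="CO2 exchange",
                          subsystem="Exchange")]
    transports = [
        t("GLCt", "glc_e", "glc_c", "SLC2A1", "glucose transport"),
        t("OCTAt", "octa_e", "octa_c", "", "octanoate diffusion"),
        t("LNLCt", "lnlc_e", "lnlc_c", "CD36", "linoleate transport"),
        t("GLNt", "gln_e", "gln_c", "SLC1A5", "glutamine transport"),
        t("SERt", "ser_e", "ser_c", "SLC1A4", "serine transport"),
        t("METt", "met_e", "met_c", "SLC7A5", "methionine transport"),
    ]
    core = [
        Reaction("GLYC", {"glc_c": -1, "pg3_c": 2}, name="glycolysis (lumped upper)",
                 gene_rule=GeneRule("HK1 and PFKL"), subsystem="Glycolysis"),
        Reaction("PYK", {"pg3_c": -1, "pyr_c": 1}, name="pyruvate kinase (lumped lower)",
                 gene_rule=GeneRule("PKM"), subsystem="Glycolysis"),
        Reaction("SERSYN", {"pg3_c": -1, "ser_c": 1}, name="serine biosynthesis (lumped)",
                 gene_rule=GeneRule("PHGDH"), subsystem="Serine biosynthesis"),
        Reaction("PDH", {"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "co2_c": 1},
                 name="pyruvate dehydrogenase",
                 gene_rule=GeneRule("PDHA1 and DLAT"), subsystem="Pyruvate metabolism"),
        Reaction("BOX_OCT", {"octa_c": -1, "coa_c": -4, "accoa_c": 4},
                 name="octanoate beta-oxidation (lumped)",
                 gene_rule=GeneRule("ACADM"), subsystem="Fatty acid oxidation"),
        Reaction("BOX_LNLC", {"lnlc_c": -1, "coa_c": -9, "accoa_c": 9},
                 name="linoleate beta-oxidation (lumped)",
                 gene_rule=GeneRule("CPT1B and ACADVL"), subsystem="Fatty acid oxidation"),
        Reaction("GLNLYS", {"gln_c": -1, "pyr_c": 1, "co2_c": 2},
                 name="glutaminolysis (lumped)",
                 gene_rule=GeneRule("GLS"), subsystem="Glutamine metabolism"),
        # enzyme-capacity cap: the toy's citrate-synthase step is the accoa
        # bottleneck that lets fatty-acid influx overflow toward the nucleus
        Reaction("TCA", {"accoa_c": -1, "coa_c": 1, "co2_c": 2}, upper_bound=18.0,
                 name="TCA cycle (lumped oxidation)",
                 gene_rule=GeneRule("CS"), subsystem="TCA cycle"),
        Reaction("SHMT", {"ser_c": -1, "thf_c": -1, "gly_c": 1, "mlthf_c": 1},
                 name="serine hydroxymethyltransferase",
                 gene_rule=GeneRule("SHMT1 or SHMT2"), subsystem=_ONE_CARBON),
        Reaction("MTHFD", {"mlthf_c": -1, "f10thf_c": 1}, lower_bound=-1000.0,
                 name="methylene-THF dehydrogenase (lumped, reversible)",
                 gene_rule=GeneRule("MTHFD1"), subsystem=_ONE_CARBON),
        Reaction("MTHFR", {"mlthf_c": -1, "mthf_c": 1},
                 name="5,10-methylene-THF reductase",
                 gene_rule=GeneRule("MTHFR"), subsystem=_ONE_CARBON),
        Reaction("FTHFD", {"f10thf_c": -1, "thf_c": 1, "co2_c": 1},
                 name="formyl-THF dehydrogenase",
                 gene_rule=GeneRule("ALDH1L1"), subsystem=_ONE_CARBON),
        Reaction("GCS", {"gly_c": -1, "thf_c": -1, "mlthf_c": 1, "co2_c": 1},
                 name="glycine cleavage system",
                 gene_rule=GeneRule("GLDC"), subsystem=_ONE_CARBON),
        Reaction("MAT", {"met_c": -1, "amet_c": 1},
                 name="methionine adenosyltransferase",
                 gene_rule=GeneRule("MAT2A or MAT1A"), subsystem=_ONE_CARBON),
        Reaction("MS", {"hcys_c": -1, "mthf_c": -1, "met_c": 1, "thf_c": 1},
                 name="methionine synthase",
                 gene_rule=GeneRule("MTR"), subsystem=_ONE_CARBON),
        Reaction("AHCY", {"ahcys_c": -1, "hcys_c": 1},
                 name="adenosylhomocysteinase",
                 gene_rule=GeneRule("AHCY"), subsystem=_ONE_CARBON),
        # methyl-cycle short circuit; capacity cap keeps it from absorbing
        # the whole SAM flux
        Reaction("GNMT", {"amet_c": -1, "gly_c": -1, "ahcys_c": 1, "sarcs_c": 1},
                 upper_bound=10.0, name="glycine N-methyltransferase",
                 gene_rule=GeneRule("GNMT"), subsystem=_ONE_CARBON),
        Reaction("SARDH", {"sarcs_c": -1, "thf_c": -1, "gly_c": 1, "mlthf_c": 1},
                 name="sarcosine dehydrogenase",
                 gene_rule=GeneRule("SARDH"), subsystem=_ONE_CARBON),
    ]
    net = MetabolicNetwork(metabolites=mets, reactions=exchanges + transports + core,
                           name="toy")
    if augmented:
        net = augment_with_histone_reactions(net, default_augmentation_spec())
        net.name = "toy"
    return net


def toy_formula_table() -> pd.DataFrame:
    """Reduced formula per toy metabolite base name (the balance fixture)."""
    return pd.DataFrame(
        [{"metabolite": k, "formula": v} for k, v in TOY_FORMULAS.items()]
    )


# ---------------------------------------------------------------------------
# presets and config

PRESETS: dict[str, dict[str, list[str]]] = {
    # treatment signature: beta-oxidation + one-carbon/methionine genes up,
    # proliferation genes (absent from the metabolic toy) down
    "octanoate": {
        "up": ["ACADM", "SHMT1", "MTHFR", "ALDH1L1", "GLDC", "GNMT",
               "MAT2A", "MTR", "AHCY"],
        "down": ["CCNB1", "CDK1", "PLK1", "E2F1", "MKI67"],
    },
    "linoleate": {
        "up": ["CD36", "CPT1B", "ACADVL", "SHMT1", "MTHFR", "MAT2A", "MTR", "AHCY"],
        "down": ["CCNB1", "CDK1", "PLK1"],
    },
}


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_genes: int = 500
    preset: str | None = "octanoate"
    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)
    n_up: int = 0  # used when no preset/explicit lists are given
    n_down: int = 0
    effect_lfc: float = 4.0
    noise_sd: float = 0.25
    # expression matrix
    kappa: float = 0.5  # mean-reversion strength of the treatment response
    n_replicates: int = 3
    # toy genome / intervals
    genome: dict[str, int] = field(default_factory=lambda: {"chr1": 600_000, "chr2": 400_000})
    n_peaks: int = 1000
    peak_len: int = 500
    n_features: int = 10
    feature_len: int = 1500
    p_feature: float = 0.0  # probability a peak is planted on a feature

    def resolved_sets(self) -> tuple[list[str], list[str]]:
        if self.up_genes or self.down_genes:
            up, down = list(self.up_genes), list(self.down_genes)
        elif self.preset:
            up = list(PRESETS[self.preset]["up"])
            down = list(PRESETS[self.preset]["down"])
        else:
            filler = [f"gene{i:04d}" for i in range(1, self.n_up + self.n_down + 1)]
            up, down = filler[: self.n_up], filler[self.n_up:]
        if set(up) & set(down):
            raise ValueError("up and down gene sets overlap")
        return up, down


# ---------------------------------------------------------------------------
# generators


def _gene_universe(cfg: SyntheticConfig, up: list[str], down: list[str]) -> list[str]:
    filler_needed = max(0, cfg.n_genes - len(up) - len(down))
    filler = [f"gene{i:04d}" for i in range(1, 10 * cfg.n_genes)]
    filler = [g for g in filler if g not in set(up) | set(down)][:filler_needed]
    return up + down + filler


def simulate_de_table(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DESeq2-style differential-expression table with planted truth.

    Planted genes get |log2fc| ~ N(effect_lfc, noise_sd) with FDR ~
    U(0, 1e-4); null genes get log2fc ~ N(0, noise_sd) with FDR ~ U(0.2, 1).
    Returns ``(de_table, truth)``.
    """
    up, down = cfg.resolved_sets()
    genes = _gene_universe(cfg, up, down)
    rng = np.random.default_rng(cfg.seed)
    rows, truth = [], []
    for g in genes:
        if g in up:
            lfc = rng.normal(cfg.effect_lfc, cfg.noise_sd)
            fdr = rng.uniform(0, 1e-4)
            label = "up"
        elif g in down:
            lfc = rng.normal(-cfg.effect_lfc, cfg.noise_sd)
            fdr = rng.uniform(0, 1e-4)
            label = "down"
        else:
            lfc = rng.normal(0.0, cfg.noise_sd)
            fdr = rng.uniform(0.2, 1.0)
            label = "null"
        rows.append({"gene_id": g, "log2fc": lfc, "fdr": fdr})
        truth.append({"gene_id": g, "truth": label})
    return pd.DataFrame(rows), pd.DataFrame(truth)


def simulate_expression_matrix(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM matrix (genes x samples) with a planted mean-reverting response.

    Control abundances are log-normal; treatment means are
    ``ctrl * exp(-kappa * baseline + noise)`` so that with ``kappa > 0``
    initially high genes fall and initially low genes rise.  Returns
    ``(matrix_with_labels, truth)``; condition labels are the column-name
    prefixes (ctrl_1..n, trt_1..n).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes = [f"gene{i:04d}" for i in range(1, n + 1)]
    log_mu = rng.normal(2.0, 1.5, size=n)
    ctrl_mean = np.exp(log_mu)
    baseline = np.log(ctrl_mean / ctrl_mean.mean())
    response = -cfg.kappa * baseline + rng.normal(0.0, cfg.noise_sd, size=n)
    trt_mean = ctrl_mean * np.exp(response)
    cols = {}
    for i in range(cfg.n_replicates):
        cols[f"ctrl_{i + 1}"] = ctrl_mean * rng.lognormal(0.0, 0.05, size=n)
        cols[f"trt_{i + 1}"] = trt_mean * rng.lognormal(0.0, 0.05, size=n)
    matrix = pd.DataFrame(cols, index=genes)
    truth = pd.DataFrame(
        {"gene_id": genes, "baseline_true": baseline, "response_true": response}
    )
    return matrix, truth


def simulate_peaks_and_features(
    cfg: SyntheticConfig,
) -> tuple[PeakSet, FeatureSet, dict[str, pd.DataFrame], pd.DataFrame]:
    """Toy peak/feature sets plus per-peak Poisson cut profiles.

    Features are placed uniformly (non-overlapping by rejection); each peak
    is planted to overlap a random feature with probability ``p_feature``
    and placed uniformly otherwise, so the expected enrichment is available
    in closed form in the truth sidecar.  Returns
    ``(peaks, features, cuts_per_sample, truth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms = list(cfg.genome)
    lengths = np.array([cfg.genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    def place(length: int) -> GenomicInterval:
        c = chroms[rng.choice(len(chroms), p=probs)]
        start = int(rng.integers(0, cfg.genome[c] - length))
        return GenomicInterval(c, start, start + length)

    features: list[GenomicInterval] = []
    guard = 0
    while len(features) < cfg.n_features:
        cand = place(cfg.feature_len)
        if all(
            cand.chrom != f.chrom or cand.end <= f.start or cand.start >= f.end
            for f in features
        ):
            features.append(cand)
        guard += 1
        if guard > 100 * cfg.n_features:
            raise RuntimeError("cannot place non-overlapping features; genome too small")

    peaks: list[GenomicInterval] = []
    for _ in range(cfg.n_peaks):
        if rng.uniform() < cfg.p_feature:
            f = features[rng.integers(0, len(features))]
            lo = max(0, f.start - cfg.peak_len + 1)
            hi = min(cfg.genome[f.chrom] - cfg.peak_len, f.end - 1)
            start = int(rng.integers(lo, hi + 1))
            peaks.append(GenomicInterval(f.chrom, start, start + cfg.peak_len))
        else:
            peaks.append(place(cfg.peak_len))

    peak_set = PeakSet("peaks", peaks, cfg.genome)
    feature_set = FeatureSet("features", features, cfg.genome)

    # per-peak Poisson cut intensities for two samples (vectorized)
    lam = rng.uniform(5, 50, size=cfg.n_peaks)
    starts = np.array([iv.start for iv in peak_set.intervals])
    plens = np.array([iv.length for iv in peak_set.intervals])
    pchroms = np.array([iv.chrom for iv in peak_set.intervals])
    cuts: dict[str, pd.DataFrame] = {}
    for sample in ("s1", "s2"):
        ks = rng.poisson(lam)
        start_rep = np.repeat(starts, ks)
        len_rep = np.repeat(plens, ks)
        pos = start_rep + (rng.random(int(ks.sum())) * len_rep).astype(np.int64)
        cuts[sample] = pd.DataFrame({"chrom": np.repeat(pchroms, ks), "pos": pos})

    G = float(sum(cfg.genome.values()))
    background_rate = cfg.n_features * (cfg.peak_len + cfg.feature_len) / G
    expected_overlap = cfg.p_feature + (1 - cfg.p_feature) * background_rate
    d = G / (cfg.peak_len + cfg.feature_len)
    # per-peak planted intensity plus (broadcast) closed-form expectations
    truth = pd.DataFrame(
        {
            "chrom": pchroms,
            "start": starts,
            "end": starts + plens,
            "lam": lam,
            "p_feature": cfg.p_feature,
            "expected_overlap_fraction": expected_overlap,
            "expected_enrichment": expected_overlap / (cfg.n_features / d),
        }
    )
    return peak_set, feature_set, cuts, truth


def simulate_ct_table(
    cfg: SyntheticConfig,
    planted_dct: dict[str, dict[str, float]] | None = None,
    n_samples: int = 4,
    reference_gene: str = "GAPDH",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR Ct table with planted per-gene, per-condition delta-Ct.

    Reference Ct ~ N(20, 0.2) per sample; each target's Ct is the sample
    reference plus the planted delta-Ct plus N(0, noise_sd/2) noise, so the
    recovered log2RE is -delta_ct on average.  Returns ``(ct_table, truth)``.
    """
    if planted_dct is None:
        planted_dct = {
            "NOTCH1": {"ctrl": 8.0, "trt": 6.0},
            "DLL4": {"ctrl": 10.0, "trt": 5.4},
            "HEY1": {"ctrl": 9.0, "trt": 8.0},
        }
    rng = np.random.default_rng(cfg.seed)
    rows, truth = [], []
    for cond in sorted({c for v in planted_dct.values() for c in v}):
        for i in range(n_samples):
            sample = f"{cond}_{i + 1}"
            ref_ct = rng.normal(20.0, 0.2)
            rows.append({"sample": sample, "gene": reference_gene, "Ct": ref_ct})
            for gene, dcts in planted_dct.items():
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "Ct": ref_ct + dcts[cond] + rng.normal(0, cfg.noise_sd / 2),
                    }
                )
    for gene, dcts in planted_dct.items():
        for cond, dct in dcts.items():
            truth.append({"gene": gene, "condition": cond, "dct_true": dct,
                          "log2re_true": -dct})
    return pd.DataFrame(rows), pd.DataFrame(truth)
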