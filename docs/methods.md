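# Methods

## Expression-constrained flux model

The flux model is standard constraint-based analysis: a stoichiometric
matrix `S` (metabolites × reactions), steady state `S v = 0`, and box
bounds `l ≤ v ≤ u` in mmol/gDW/h. Instead of a biomass objective, the
program scores agreement with a transcriptional state. Reactions are
categorized UP/DOWN/NEUTRAL from a differential-expression table through
their gene-protein-reaction (GPR) rules; the solved state maximizes total
activity of UP reactions and minimizes that of DOWN reactions.

The network is first reversibility-split (each reaction with `l < 0`
becomes a forward and a backward child with non-negative bounds), so the
activity of a parent reaction is the linear form `w_r = v_{r,f} + v_{r,b}`
and the whole problem stays a single LP:

    max  Σ_{UP} w_r − Σ_{DOWN} w_r − ε Σ_all w_r
    s.t. S v = 0,  0 ≤ v ≤ u.

Design choices, in order of consequence:

* **Fully linear objective, no binary indicators.** Integer formulations
  of expression integration (iMAT and kin) give each reaction an on/off
  state; here the magnitudes themselves are optimized. This keeps the
  solve in scipy's HiGHS LP and makes the vertex-enumeration oracle
  in the tests exact.
* **Parsimony term.** ε = 1e-4 is small enough never to override a unit
  of UP/DOWN score and exists to select the minimum-total-activity member
  of the optimal face, so neutral reactions do not carry arbitrary flux in
  reported optima. It must stay well below 1/(longest pathway length) to
  remain a tie-break.
* **GPR combination rule.** A reaction is UP if at least one of its genes
  is up and none are down; DOWN symmetrically; everything else (empty
  rules, mixed signals) is NEUTRAL. The rule is isolated in one function
  (`map_genes_to_reactions`) so alternatives (AND-aware evaluation,
  majority voting) can be swapped without touching the solver.
* **Condition pairing.** A DE table is treatment-vs-control; treatment
  categories are its up/down sets and the control condition uses the
  mirrored sets. With the shipped presets — whose down genes are
  proliferation markers absent from the metabolic network — the control
  reduces to an all-neutral (zero-flux) state.
* **DE thresholds.** Defaults are FDR < 0.01 and |log2FC| ≥ 2; both are
  plain parameters, and a (0.01, 1.0) setting is equally supported. The
  threshold on effect size is inclusive (≥).

**Known degeneracy.** Because activity is `v_f + v_b`, a *reversible*
reaction in the UP set can inflate its activity by running both split
children simultaneously (a futile two-cycle that is stoichiometrically
invisible). The packaged networks avoid this by keeping every reaction
reachable by the presets irreversible; if you integrate expression onto a
model with reversible UP reactions, interpret their activities with care
or tighten their bounds first.

## Histone augmentation

Eight reactions connect metabolism to bulk histone marks: nuclear import
of acetyl-CoA (as an antiport against free CoA, so nuclear CoA returns
without a ninth reaction) and of SAM; the acetyl- and methyl-transfer
reactions on a histone-tail pseudo-species; nuclear SAH export; an
unconstrained histone-tail supply; and the two demand sinks whose fluxes
are the model's predictions of bulk acetylation and methylation. The
histone tail is deliberately non-conserved: modification flux is limited
by donor supply only, which is the bulk-mark interpretation. Site
specificity (H3K9 vs H3K27 etc.) is out of scope.

Growth media map to exchange bounds linearly: 1 mM of a nutrient opens
1 mmol/gDW/h of uptake (one configurable scalar, `MediaConfig.scale`).
The shipped conditions are control (glucose 8.0 mM, glutamine 2.0 mM —
the 1.441 g/L and 0.292 g/L of the culture medium divided by molar
masses 180.16 and 146.14 g/mol), octanoate (control + 5 mM octanoate)
and linoleate (control + 0.5 mM linoleate). Fatty-acid exchanges are
closed in any condition that does not supply them; octanoate enters by
diffusion (its transport reaction carries no gene), linoleate through a
transporter with a GPR, so both wirings are represented.

## Differential reactions

A single LP optimum is one point on a possibly large optimal face, so
condition comparison uses an ensemble: the objective coefficients are
multiplied by independent U(1−j, 1+j) draws (default j = 0.05, n = 50,
seeded) and the LP re-solved per draw. Per reaction, activities are
compared across conditions with a two-sided Mann–Whitney rank-sum test
and Benjamini–Hochberg adjusted over all reactions (α = 0.01 on the
adjusted values). Bound-saturated reactions have zero ensemble variance;
when both groups are constant the degenerate rank test is replaced by an
exact rule (p = 1 if the means agree, p = 0 otherwise). The
jitter-ensemble null is a pragmatic, seeded stand-in — published
per-reaction p-values in this setting rarely state their resampling
scheme, so absolute significance counts from other implementations should
not be expected to match reaction-for-reaction; directions and pathway
membership are the robust readouts.

## Feature enrichment

Coordinates are 0-based half-open throughout; BED is native and 1-based
inputs are converted at the boundary. Overlap means ≥ 1 bp. The statistic
`(a/b)/(c/d)` uses `d = G/(mean peak + mean feature length)`, the
estimated number of genome slots where a peak and a feature could
co-occupy; `d` is kept real-valued (not rounded to an integer count of
slots). Under uniform random peak placement the expected overlap
fraction `a/b` equals `c/d` up to edge effects of order (interval
length)/G, which is the calibration property the tests verify. Peak
merge and intersect are delegated to pyranges (bookended intervals
coalesce on merge); Tn5 cut sites are read 5′ ends shifted +4 (forward)
/ −5 (reverse), configurable off.

## Expression profiles

Baseline is `ln(E_ctrl/E_ctrl,avg)` with `E_ctrl` the per-gene arithmetic
mean over control replicates and `E_ctrl,avg` the grand mean over all
genes and control replicates; response is `ln(E_trt/E_ctrl)`. A
pseudocount (default 0.5 TPM) guards zero-expression genes; an optional
minimum-TPM filter exists but defaults off. The trend statistic is
Spearman's rho with average ranks for ties. qPCR relative expression is
`log2RE = −(Ct_X − Ct_ref)` against a per-sample reference gene (GAPDH
by default); group comparisons of log2RE are ordinary rank tests plus BH
and are left to standard routines.

## Synthetic data

The toy network is a fixed constant, not sampled: 31 reactions plus the
8-reaction augmentation, covering glucose → glycolysis → pyruvate →
acetyl-CoA, octanoate (C8) and linoleate (C18) β-oxidation, serine
biosynthesis, the folate cycle (SHMT, MTHFD, MTHFR, FTHFD, glycine
cleavage), and the methionine cycle (MAT, MS, AHCY, GNMT, SARDH), each
enzymatic step carrying a human gene symbol and a subsystem label.
Elemental accounting is reduced: carbon skeletons plus the sulfur of the
methionine cycle, with CoA, THF and the adenosyl moiety treated as
zero-mass carriers; under that accounting every internal reaction is
exactly balanced (the formula table ships with the package).

Two reactions carry finite capacity caps and they are what make the
fixture informative: GNMT (10 mmol/gDW/h) bounds the methyl-cycle short
circuit so surplus SAM must exit through histone methylation, and the
lumped TCA step (18 mmol/gDW/h) bounds acetyl-CoA oxidation so the
β-oxidation influx of the octanoate condition (5 mM × 4 acetyl-CoA = 20)
overflows modestly — by 2 — into histone acetylation. This reproduces
the qualitative treatment phenotype: a strong methylation response with
a modest acetylation response.

Generators (DE tables, TPM matrices, peak/feature sets with per-peak
Poisson cut intensities, Ct tables) are deterministic per seed (PCG64)
and each emits a truth sidecar naming what was planted. Planted DE
effects default to |log2FC| = 4 against a threshold of 2, so recovery is
exact rather than probabilistic; the mean-reverting expression matrix
plants `response = −κ·baseline + noise` with κ = 0.5 by default. Peak
sets default to 1000 peaks of 500 bp on a 1 Mb two-chromosome toy
genome with 10 features of 1500 bp — scaled down by roughly the ratio of
the toy genome to a human genome from the tens of thousands of peaks a
real merged ATAC set contains, which keeps the Monte-Carlo error of the
calibration experiments small at desk scale.

What the generators do **not** emulate: read-level noise (inputs start at
tables and intervals), correlated gene effects, GC or mappability bias in
peak placement, batch structure, and any coupling between the DE tables
and the expression matrices. Passing tests therefore demonstrate the
correctness and calibration of the computations, not robustness to the
full messiness of real sequencing data.

## Numerical notes

* LP solver: scipy `linprog` (HiGHS). Mass-balance residual of every
  reported state is checked against 1e-6; bounds are respected to solver
  tolerance (~1e-9). Infinite upper bounds are capped at 1000 before the
  solve so the program cannot be unbounded.
* Infeasible models return a `FluxState` with status "infeasible" rather
  than raising; ensembles abort with the member index.
* Degenerate inputs: empty DE tables give empty states; empty interval
  sets merge/intersect to empty sets but make enrichment undefined (an
  error); all-zero count columns stay zero under CPM.
* Determinism: all randomness flows through explicitly seeded PCG64
  generators; repeated runs of any seeded command are byte-identical.

## Problem sizes

The packaged analyses run at toy scale by choice: a 39-reaction network
(solved LPs are ~45 variables after splitting), ensembles of 50 draws
(200 for the null-control experiment), 200 calibration replicates of
1000 peaks, and expression matrices of 500–5000 genes. The full test
suite and the acceptance script each complete in well under a minute on
a single CPU. Genome-scale models (Recon-family SBML parses through the
same reader) and real DE tables are supported by the same code paths but
are not exercised by the shipped fixtures.
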