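# fluxmark

Fatty-acid exposure rewires central metabolism in mammary epithelial
cells, and that rewiring reaches the nucleus: the donors of histone
acetylation (acetyl-CoA) and methylation (S-adenosyl-L-methionine, SAM)
are metabolites, so a shift in flux through β-oxidation and one-carbon
metabolism changes the supply of substrate for histone marks. `fluxmark`
is a pipeline for asking, quantitatively, what a transcriptional response
implies for those fluxes — and for the companion chromatin-accessibility
and qPCR readouts that such a study produces.

It is aimed at computational biologists who have differential-expression
tables, ATAC-seq peak sets, and Ct tables in hand and want the bespoke
computations between those inputs and the biology, with every step seeded
and testable.

## What it computes

**Expression-constrained flux states.** Given a constraint-based
metabolic network (SBML; any Recon-family model works) augmented with
nuclear histone acetylation/methylation chemistry, and up/down gene sets
thresholded from a DE table, the condition-specific flux state solves

```
max   Σ_{r∈UP} w_r − Σ_{r∈DOWN} w_r − ε Σ_r w_r
s.t.  S v = 0,  0 ≤ v ≤ u        (reversibility-split network)
```

where `w_r = v_{r,f} + v_{r,b}` is the activity of reaction *r* and the
parsimony weight ε (default 1e-4) picks the minimum-activity member of
the optimal face. Bulk histone acetylation and methylation are predicted
as the fluxes of the nuclear demand reactions `DM_histone_ac` and
`DM_histone_me`, fed by the donors acetyl-CoA and SAM. Reactions that
differ between conditions are found by re-solving the program over an
ensemble of jittered objectives, rank-sum testing each reaction, and
Benjamini–Hochberg correction.

**ATAC-seq feature enrichment.** For a peak set against a genomic
feature set (e.g. ±1 kb TSS windows), the enrichment is

```
(a/b) / (c/d),   d = G / (mean peak length + mean feature length)
```

with *a* peaks overlapping the feature, *b* total peaks, *c* feature
regions, and *G* the genome length. Peak merge/intersect, Tn5 cut-site
count matrices, and CPM normalization are included.

**Expression-response profiles.** Per-gene baseline
`ln(E_ctrl/E_ctrl,avg)` versus response `ln(E_trt/E_ctrl)` with a
Spearman trend statistic, and the qPCR relative expression
`log2RE = −(Ct_X − Ct_ref)`.

A synthetic-data module generates every input — including a fixed,
elementally balanced ~30-reaction toy network wiring glycolysis,
β-oxidation, the folate and methionine cycles, and the nuclear histone
sinks — so the full pipeline runs with no downloads.

## Worked example

```
fluxmark simulate --preset octanoate --seed 7 --out fixtures/
fluxmark flux --model fixtures/toy_model.xml --de fixtures/de_table.tsv \
    --media-ctrl fixtures/media_control.yaml \
    --media-trt fixtures/media_octanoate.yaml \
    --out results/ --seed 7 --n-ensemble 50
```

The second command prints (stderr) a summary like:

```json
{
 "conditions": {"control": "optimal", "treatment": "optimal"},
 "histone_flux": {
  "control":   {"acetylation": 0.0, "methylation": 0.0},
  "treatment": {"acetylation": 2.0, "methylation": 32.0}
 },
 "n_decreased": 0,
 "n_increased": 25
}
```

Reading: under the octanoate media (glucose 8 mM, glutamine 2 mM,
octanoate 5 mM) with β-oxidation and one-carbon genes upregulated, the
model routes 32 mmol/gDW/h of SAM into the histone-methylation sink and
only 2 into acetylation (the β-oxidation-derived acetyl-CoA overflow
after the TCA capacity is filled) — methylation responds strongly,
acetylation modestly. 25 reactions are called significantly increased at
adjusted p < 0.01, 8 of them in the one-carbon/methionine subsystem
(`results/subsystem_summary.tsv`). The same library surface is available
programmatically (`fluxmark.solve_flux_state`, `fluxmark.feature_enrichment`,
…); the CLI subcommands `enrich` and `profile` cover the interval and
expression statistics.

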