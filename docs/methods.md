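# Methods

This note records the models, parameter choices and numerical decisions
behind `pdzscreen`, in the package's own terms.

## Duplicate-spot hit calling

The processing chain assumes single-channel spot tables (one foreground
and one local-background estimate per spot, plus the printed protein
concentration) with every protein printed twice per slide.

* **Background correction.** `net = max(fg − bg, 0)`. The floor protects
  the subsequent log transform from negative values produced by noisy
  background estimates; floored spots are genuinely indistinguishable
  from empty ones.
* **Spatial de-trending.** `norm = log2(net + 1) − fit + median(fit)`,
  where `fit` is a LOWESS regression (statsmodels; `frac = 0.3`, 3
  robustifying iterations) of the log signal on row-major print order.
  Print order is a deliberate proxy for every slow spatial/print
  artefact of a single-channel slide; the vendor software's exact
  geometry is undocumented, and a locally weighted fit on print order is
  fully specifiable and removes the same low-frequency structure. Adding
  back the median keeps `norm` on the original log2 scale.
* **Concentration adjustment.** `adj = norm − g(log10 conc)` with `g` a
  LOWESS fit (`frac = 0.5`) of `norm` on log10 printed concentration
  over all non-blank spots of the slide. Signal grows sublinearly and
  saturates with spotted protein amount, so a monotone nonparametric fit
  is the right shape; when all concentrations are equal the step
  degenerates to centering. Blank spots (`conc = 0`) are excluded from
  every fit and are never callable.
* **Z-scores.** `z = (adj − mean) / sd` over all non-blank spots of the
  slide, with the sample (n−1) standard deviation; a robust variant
  (median, 1.4826 × MAD) is available for slides where strong binders
  inflate the classical sd. The population is the whole slide: per-block
  populations would be needed only if block-level artefacts survived
  de-trending.
* **Decision rule.** Per protein and slide: `mean_z` over the duplicate
  pair and `cv = sd(s1, s2) / mean(s1, s2)` (sample sd, i.e.
  `|s1 − s2|/√2 / mean`) on the adjusted signals back-transformed to
  linear scale (`2**adj`; configurable to raw or net — CV is
  conventionally a linear-scale statistic). A protein is a hit iff
  `mean_z > 3` **and** `cv < 0.5`, both strict, so values exactly at a
  threshold are non-hits. Zero-mean pairs get `cv = ∞`. Reproducible
  hits are the set intersection across ≥ 2 slides.

## Interactor lists and enrichment

Records merge on the gene identifier, never the symbol, and no
cross-species unification is attempted automatically (orthologue
conflation is too easy to commit silently; a mapping table can be
applied upstream). Provenance source tags are unioned; symbol conflicts
keep the first-seen symbol and are logged. The annotation filter
partitions records exactly into `annotated` and the four removal
statuses (`utr3`, `withdrawn`, `suppressed_noncoding`, `nmd_candidate`).

Category proportions are reported as percentages rounded half-even to
one decimal (the convention used when the kinase fractions 11/62 → 17.7%
and 448/8000 → 5.6% are printed). The hypergeometric upper-tail p-value
(population = background size, successes = category size in background,
draws = number of hits) is an added convenience for judging such
proportions; the screen-level observation itself is a proportion
comparison, not a test.

## GO similarity clustering

* **Induced sets** contain a protein's direct annotations plus all
  ancestors along `is_a` and `part_of` up to and including the aspect
  root (the classical union–intersection induced-graph construction;
  `part_of` can be excluded by flag). All GAF evidence codes are
  accepted by default — IEA exclusion is a flag, since electronic
  annotations dominate coverage for most proteomes.
* **simUI** is the Jaccard ratio of two induced sets; it is symmetric,
  lies in [0, 1], equals 1 exactly when the induced sets coincide, and
  never decreases when the same term is annotated to both proteins.
  Dissimilarity is 1 − sim. Proteins with no annotation in an aspect are
  excluded from that aspect's matrix (logged, not an error).
* **PAM** is the canonical deterministic k-medoid algorithm: BUILD
  greedily adds the medoid with the largest cost reduction (first
  medoid: the minimiser of total dissimilarity), then SWAP repeatedly
  applies the single medoid/non-medoid exchange with the largest strict
  cost decrease until none exists. All ties break to the lowest point
  index, so the result is reproducible without any randomness.
  *Known limitation:* single-swap descent is a local search; on a few
  percent of small random matrices it converges to a cost above the
  exhaustive C(n,k) optimum. R's `cluster::pam` exhibits the same
  behaviour on the same instances (we verified identical converged costs
  on a trapped 7-point instance), so this is a property of the
  algorithm, not of this implementation.
* **k selection** maximises the average silhouette width
  `s(i) = (b − a)/max(a, b)` (a: mean within-cluster dissimilarity
  excluding self; b: smallest mean dissimilarity to another cluster;
  singletons score 0) over k = 2 … min(15, n−1); ties prefer smaller k.
* **Network export.** Edges with dissimilarity strictly above the
  aspect threshold (0.4 for BP and MF, 0.3 for CC; overridable) are
  removed — the comparison is strict, so an edge exactly at the
  threshold survives. Edge display width grows as dissimilarity
  approaches 0; medoid nodes are flagged and enlarged. Outputs are
  GraphML and SIF (isolated nodes listed bare so no protein is lost).
* **Cluster labels** default to the medoid's direct term with the
  highest information content, IC(t) = −log of the fraction of
  clustered proteins whose induced set contains t (the aspect root has
  IC 0 and never wins); curated overrides are supported because an
  automatically chosen term is a starting point, not a biological
  judgement.

## C-terminal motif analysis

Positions follow PDZ ligand convention: the C-terminal residue is 0,
counting −1, −2, … leftward. Classes, in precedence order:
`cys_terminal` (C at 0), `class1` (S/T at −2 and hydrophobic at 0),
`hydrophobic_0`, `other`. The hydrophobic set is {A, F, G, I, L, M, V,
W, Y} — glycine is included because small aliphatic termini such as
…VFG behave as hydrophobic-0 ligands in array screens; the set is
configurable, and cysteine is deliberately absent because it forms its
own class. Wild-type comparison distinguishes natural termini (token
`WT` or an identical sequence), artificial cloning tails (a differing
wild-type sequence) and untranslated constructs.

Conservative matching compares the final three residues (−2, −1, 0)
group-wise using standard physicochemical classes {S,T}, {A,V,L,I,M},
{F,Y,W}, {K,R,H}, {D,E}, {N,Q}, {C}, {G}, {P}; since no canonical group
table exists for this purpose, match counts against other published
tallies are indicative rather than exact. Binding-site identity is the
per-position match fraction over the 17 ligand-contacting residues of a
PDZ domain (supplied as a pre-extracted string, since the position map
lives in structural work outside this package); specificity transfer is
predicted strictly above 70% identity.

## Synthetic data: what it emulates, and what it does not

The generators define the package's study conditions; all defaults were
fixed once, before any result was read off, and are recorded here.

* **Arrays** (`ArraySimConfig`): 200 proteins, 2 slides, 10 planted
  binders at 8-fold effect. Per-spot background is
  LogNormal(log 500, 0.3) times a smooth trend
  `1 + 0.3·(sin + cos)/2` over the grid — a low-frequency surface of the
  kind LOWESS must remove. The reported local-background estimate errs
  from the true spot background by a 5% CV, which is what makes `net`
  noisy rather than exact. Printed concentrations are log-uniform on
  5–50 ng/µL and signal scales as √concentration (normalised to unit
  mean), creating the dependence the adjustment step must flatten while
  keeping the planted-signal expectation exactly `effect_size × mean
  background`. Replicate noise is multiplicative with 10% CV and unit
  mean; the binding signal sees the pair-mean trend, so duplicate
  signals are identical (CV 0, up to integer quantisation of the output)
  when replicate noise is switched off. Not emulated: scanner
  saturation, optical bleed, spot-shape artefacts, and any real-slide
  noise statistics — none were published for the original screens, so
  passing recovery tests shows the rule works under a plausible noise
  model, not under the vendor's.
* **GO corpora** (`GoSimConfig`): 3 latent groups × 8 proteins; each
  group owns a depth-3, branching-3 subtree (40 terms) under a single
  aspect root, with occasional second parents inside the subtree so the
  graph is a genuine DAG. Each protein draws 6 distinct direct terms,
  each from its own subtree with probability 0.95. Six terms per protein
  is the smallest annotation load at which the group signal reliably
  survives the 5% noise (with 4, one stray term flips about one protein
  per corpus and the 20-seed median ARI drops to ~0.87); real GOA
  profiles of well-studied proteins carry that many direct terms per
  aspect or more. Not emulated: the real GO's size and shape,
  evidence-code structure, or annotation-depth bias.
* **C-termini** (`TerminiSimConfig`): 12-mers with exact planted counts
  (floors of the requested fractions) of Class I and terminal-Cys
  motifs; background sequences are rejection-sampled away from both
  planted motifs so truth counts are exact, and a separate
  `random_peptides` provides unconstrained uniform draws for frequency
  checks.

## Problem sizes

The test suite runs the planted-recovery studies at 20 seeds each
(2 × 400-spot slides; 24-protein corpora with k searched over 2–8), the
clustering oracle checks at 200 random matrices with n ≤ 8, and the
end-to-end pipeline at 120 proteins — sizes at which every check
completes in seconds while the statistics (sensitivity, false-positive
counts, ARI medians) remain stable across seeds.
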