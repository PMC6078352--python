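# Methods

## The experiment being modelled

A deep mutational scan measures the fitness of every single amino-acid
substitution of a protein in one pooled experiment. A library of
variants — here, all 19 amino-acid replacements plus a stop codon at
each of positions 2–76 of ubiquitin (1500 substitutions; the initiator
methionine carries no data) — is tagged with DNA barcodes and grown in
competition. Sequencing the barcodes at successive timepoints tracks
each variant's frequency; a variant's fitness is inferred from how fast
its frequency changes relative to wild type. Repeating the competition
under different chemical perturbations, each dosed to inhibit wild-type
growth by a fixed fraction, reveals condition-specific sensitization
(fitness drops relative to the vehicle control) or alleviation (fitness
rises).

## Growth model and fitness estimator

The simulator grows each variant exponentially with per-generation
multiplicative factor 2^(1+f): wild type (f = 0) doubles every
generation; a null allele (f = −1) does not grow. Expected frequencies
follow

    p_v(t) ∝ p_v(0) · 2^((1+f_v)·t),

so log2(p_v(t)/p_WT(t)) is linear in elapsed generations t with slope
f_v. The estimator is the ordinary least-squares slope of

    log2((c_v,t + pc) / (c_WT,t + pc))   against t,

with pseudocount pc = 0.5 keeping logarithms finite at zero counts.
Under this pairing the estimator is unbiased in expectation; the
choice of growth model and estimator as a matched pair is the module's
defining design decision, since the upstream study defers its exact
formulas to a companion paper.

Raw slopes are rescaled to the conventional scale

    fitness(v) = (raw(v) − raw(WT)) / |mean raw over stop variants|,

so that wild type sits at exactly 0 and the average nonsense variant at
exactly −1 ("as deleterious as a premature stop"). Variants with fewer
than 10 reads at the first timepoint are masked as unreliable rather
than estimated. Replicates are normalized independently and then
averaged cellwise; a cell missing in any replicate is masked in the
average, and a single-replicate condition passes through with a logged
warning (the experimental design collects duplicates, with historical
exceptions).

Degenerate inputs: a missing WT row, an all-zero WT trajectory, no
surviving stop variants, or a non-negative stop mean (which cannot be
anchored to −1) are all hard errors, not silently patched values.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: 75 mutable
positions × 20 substitutions, two barcodes per variant (length 18,
drawn uniformly without replacement), timepoints 0/2/4 generations,
sequencing depth 10^6 reads per timepoint, two replicates, multinomial
sampling, and a 17-condition panel (a DMSO control plus 16 chemical
treatments) whose additive effect profiles mirror the published
cluster structure: a sensitizing cluster targeting the hydrophobic
patch (residues 8/44/70) and the C-terminal tail, a cluster
sensitizing positions 35/46/63 while alleviating 58, a mild cluster
near the control, and three strong idiosyncratic outliers. Effect
magnitudes sit on the ±0.25 scale used for difference-map rendering.
Base fitness values are drawn from a mixture (70% near-neutral
N(0, 0.03), 30% uniformly deleterious on [−1, 0]), clipped to
[−1, 0.5]; stops are fixed at −1 and wild-type cells at 0.

The simulation omits PCR amplification bias, read-quality structure,
codon-level effects, barcode-abundance skew (available as an optional
log-normal perturbation, off by default), and any chemical mechanism —
conditions are purely named fitness-shift profiles. Passing tests
therefore demonstrate that the estimation and multivariate machinery
recovers known structure under multinomial sampling noise; they do not
validate the biological assumptions of the growth model against real
sequencing data.

## Counting

Reads are assigned to the unique barcode within Hamming distance
`max_mismatch` (default 1) of the read's barcode region, located at a
fixed offset (default 0) — the real read layout of the deposited data
is not described in the source, so the offset is configuration, not
assumption. Ambiguity (two barcodes equidistant from a read) always
discards the read; discards are tallied per timepoint and
assigned + discarded = total holds unconditionally. Barcode-to-variant
collapse sums counts and conserves totals.

## Difference maps and position classification

Difference maps are cellwise treatment − control on normalized
landscapes with mask union; the ±0.25 blue–white–red range is applied
only when rendering, never to stored values. Position sensitivity
averages the non-missing substitution cells at each position
(unweighted), excluding stops and the wild-type cell by default — the
WT cell is identically 0 and would dilute every position equally;
both exclusions are flags because the convention is not fully
determined. The per-position minimum of this average across conditions
is classified with both boundaries closed toward their named bin:
sensitive ≤ −0.35, tolerant ≥ −0.075, intermediate strictly between.

## Clustering and PCA

Conditions are observations and mutants are features. Clustering uses
absolute fitness vectors (the control is itself a vector, giving 17
under the default panel); PCA uses difference vectors with stop
substitutions excluded (16 vectors). Both apply the complete-case
filter first: a mutant missing in any condition is removed everywhere.
Ward linkage over Euclidean distances (scipy) is verified in tests
against an exhaustive objective check — every merge must minimize the
within-cluster variance increase over all cluster pairs, with heights
equal to √(2·ΔSS). Flat clusters cut the dendrogram at 6 distance
units by default. PCA (scikit-learn, column-centered, no whitening or
variance scaling) is verified against a covariance eigendecomposition
oracle to 10⁻⁸ up to sign; component signs are fixed by making each
component's largest-magnitude loading positive, since signs are
otherwise arbitrary. Loading heat-map values are reported as percent of
the component's maximum-magnitude loading (rendered with a ±75% clip);
raw loadings are used rather than singular-value-weighted ones, a
convention exposed for the caller to change by weighting the loadings
matrix itself.

## Interface ddG aggregation

The module consumes per-model score tables (mutation, model index, and
four energies: mutant/wild-type × complex/separated partners); the
conformational-ensemble generation that produces such tables is out of
scope. The per-model score is
(E_mut_complex − E_mut_separated) − (E_wt_complex − E_wt_separated),
and the prediction is the unweighted mean over the ensemble (
conventionally 50 models). The score is linear in the energy scale and
invariant to shifting an allele's complex and separated energies
together — both properties are tested exactly. The "destabilizing"
flag uses a default cutoff of +1.0 energy units, exposed as
configuration because no numeric criterion is standard; association
with PCA loadings uses Spearman rank correlation, since predicted
energies are on an arbitrary scale.

## Problem sizes and numerical choices

The test suite runs most operations on a 6-residue mini-protein
(101 variants) and reserves full 76-residue, depth-10^6 simulations
for the acceptance checks, where estimation recovers the true
landscape with Pearson r ≈ 0.998 and MAE ≈ 0.015. The acceptance
script simulates all 17 panel conditions at full depth in a few
seconds. Ties in Ward clustering break by lowest cluster index
(scipy's convention); anchor checks use a 10⁻⁹ absolute tolerance;
oracle comparisons use 10⁻⁸.

## Known limitations

- The fitness estimator is unweighted least squares; no per-variant
  error bars or count-variance weighting.
- Barcode collision tolerance relies on discarding ambiguous reads,
  not on minimum-distance library design.
- The generator's condition effects are position-uniform; real
  chemical perturbations act on individual substitutions.
- The published experiment's headline observations (which residues
  remain tolerant, the fraction of variance in the leading
  components) depend on the real sequencing data and are not
  reproduced by the synthetic panel.
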