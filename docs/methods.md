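# Methods

This note documents the models, defaults and numerical choices behind
`cernet`, and what the synthetic benchmark does and does not establish.

## The screen

The pipeline operates per tissue on three count matrices (circRNA,
miRNA, mRNA) over a two-condition design, plus a predicted
miRNA→target interaction table. Stages, in order:

**CPM and fold change.** Each sample column is scaled to counts per
million. The reported effect is
`log2((mean CPM_treatment + c) / (mean CPM_control + c))` with
pseudocount `c = 1.0` CPM (configurable); the pseudocount stabilizes
fold changes at zero counts at the cost of shrinking effects for very
low-abundance features.

**Exact conditional NB test.** Counts are rescaled to a common
effective library size — the geometric mean of the observed library
sizes — and rounded to integer pseudo-counts. A single dispersion φ
(Var = μ + φμ²) is estimated by maximizing the conditional likelihood
of the within-group count configurations given their sums (a quantity
free of the group means), summed over all features and both groups,
with a bounded scalar search over log₁₀φ ∈ [−4, 1]. The per-feature
test conditions on the total pseudo-count t across both groups: the
group-A sum then has probabilities proportional to the product of the
two group-sum NB pmfs, in which the NB success probability cancels;
the two-sided p-value is the total probability of all splits whose
probability does not exceed the observed split's (minimum-likelihood
method, well defined for asymmetric conditional laws). At φ = 0 the
conditional law is Binomial(t, n_A/(n_A+n_B)) and the test reduces to
the exact binomial-split test, which is how it is validated against a
rational-arithmetic enumeration oracle. Probability ties are compared
with a 1e−9 relative tolerance in log space so that exact ties are not
split by float rounding. This is a deliberately self-contained classic
exact test — CPM normalization, common dispersion, no trended/tagwise
shrinkage and no GLM — so that every component is oracle-checkable; it
is not a numerical re-implementation of any specific DE package.

**Gates.** Significance requires |log2FC| ≥ 1 (FC ≥ 2) in every class,
combined with raw p < 0.05 for circRNAs and miRNAs but BH FDR < 0.05
for mRNAs. BH adjustment is applied within each (tissue, class)
stratum. Direction is up/down when log2FC clears ±1.

**Correlation filters.** Spearman (mid-ranks for ties) is computed on
CPM across all samples of the tissue, conditions pooled — the
condition contrast is itself part of the co-expression signal, and the
screen does not stratify. A `within_condition` mode (Fisher-z mean of
per-condition coefficients) is exposed for sensitivity analysis.
Pearson for circRNA–mRNA pairs is computed on log2(CPM+1): expression
co-variation is multiplicative, and on the raw scale a single
high-count sample dominates the product-moment statistic. Both
thresholds are strict inequalities (< −0.7, > 0.9); pairs at the
boundary are excluded. Constant-expression features make the
coefficient undefined; such pairs are excluded with a logged warning
rather than assigned 0, which would silently fail thresholds while
misrepresenting undefinedness.

**Sponge test and universe.** Regulator sets are taken from the
*retained* negative pairs, not the raw interaction table, since the
test is chained after the correlation filters. The universe N defaults
to the number of distinct interaction-table miRNAs that are DE
(`interactions_de`), making the test self-contained; `interactions_all`
and `profiled` are available. Raw p < 0.05 (strict) is the default
gate, with an optional BH correction (off by default, recorded in the
output metadata). Note a structural consequence: with singleton
regulator sets (K = n = k = 1) the attainable p is 1/N, so no pair can
pass at α = 0.05 unless N > 20 — small desk-scale fixtures need enough
DE miRNAs in the interaction table for the network to be nonempty.

**Network.** The graph contains exactly the sponge-tested circRNA–mRNA
edges plus, for each, the witnessing miRNA's two negative edges; nodes
are typed (tripartite by construction) and carry DE direction.
Serialization sorts nodes lexicographically and edges by (type,
endpoints), so outputs are byte-stable and hashable. An audit pass
re-verifies tripartiteness, the PCC and sponge-p constraints, and the
presence of a shared-miRNA witness on every circ–mRNA edge of every
serialized network.

## The synthetic generator

The generator emulates the statistical structure the screen assumes —
it is a calibration instrument, not a biophysical model.

* **Counts.** NB with a single class-level dispersion (default 0.1)
  around log-normal baselines (location ln 100, sd 1.0 on the natural
  log scale). Library sizes are jittered uniformly within ±20% per
  sample, exercising normalization without dominating it.
* **Planted DE.** A fraction (default 0.1/class) of features shifts
  between conditions by 2^Δ with Δ = 3 log2 units by default — the
  8-fold scale of strongly heat-responsive transcripts, well clear of
  the FC ≥ 2 gate. The shift is applied symmetrically about the
  baseline (−Δ/2 in control, +Δ/2 in treatment) and planted triad
  polarities alternate, so up- and down-shifted mass balances and
  library composition stays stable across conditions; without this,
  concentrated one-sided effects induce spurious apparent DE in null
  features under CPM (the composition artifact TMM-style normalization
  exists to fix, which this pipeline deliberately does not include).
* **Triads.** Each planted triad shares a per-sample latent factor on
  the log2-mean scale: positive sign for the circRNA and mRNA,
  negative for the miRNA, scaled by `coupling ∈ (0,1]` times a latent
  sd of 2.5. The latent is uniform on ±√3 sd — bounded, because a
  Gaussian latent of this magnitude produces lognormal tails that make
  desk-scale mean-CPM fold changes unstable. Its multiplicative mean
  is analytically removed (sinh(k)/k correction), keeping coupled
  features at their baseline. With NB noise of ≈0.23 log2-variance at
  these abundances, the induced log-scale correlation at full coupling
  is ≈0.96, comfortably inside the |r| > 0.9 regime the screen
  filters on — planting triads whose pairwise correlations satisfy the
  screen's thresholds is the generator's purpose. Triad members draw
  their baselines from a higher-abundance distribution (ln 1000 ±
  0.5): sponge regulation is stoichiometric, so plausible ceRNA
  partners are abundant transcripts, and this also keeps their counts
  clear of the zero-saturation regime across the latent's range, where
  log-scale Pearson would otherwise degrade while rank correlation
  does not.
* **Interactions.** All planted miRNA→target edges plus decoy edges
  sampled independently at `interaction_density` (default 0.05) over
  non-planted combinations; rows unique and deterministically sorted.
* **Determinism.** All randomness flows from one integer seed;
  identical configurations reproduce outputs byte-for-byte.

What passing the benchmark shows: the pipeline's statistics are
calibrated (null p-fractions ≈ 5%, BH controls mRNA false calls,
dispersion is recovered), its filters implement the stated strict
thresholds, and when data genuinely contain the assumed structure the
screen finds it (recall ≥ 0.9 at coupling 0.95 with 20
replicates/condition; ~0 triads emitted on matched nulls). What it
does not show: robustness to the things real RNA-seq adds —
composition shifts, batch effects, trended dispersion,
zero-inflation, mis-predicted interactions — none of which the
generator emulates.

## Problem sizes and defaults

The desk-scale fixture is 300 circRNAs / 100 miRNAs / 500 mRNAs per
tissue, chosen so the full pipeline runs in seconds while leaving room
for decoys. The recovery benchmark uses one tissue at that scale with
30 triads and 20 replicates/condition; calibration checks use 2000
features/class at the 3-vs-3 design scale; the matched-null check uses
200 features/class over 20 seeds. The default study design is 3
tissues × {NHS, HS} × 3 replicates (18 samples), with sample IDs of
the form `NHS_H1` … `HS_M3`.

## Degenerate inputs and edge handling

All-zero sample columns abort normalization with the sample named;
all-zero features are excluded from dispersion estimation; interaction
rows referencing unknown features are skipped, counted, and surfaced
in the run manifest; a zero total count gives p = 1; an empty sponge
table yields an empty (not missing) network. Anchors absent from a
network produce an empty subnetwork with a warning rather than an
error.

## THI

THI = (1.8 T + 32) − (0.55 − 0.55 RH)(1.8 T − 26), with T in °C and RH
as a fraction. RH is treated as a fraction even though it is
conventionally quoted in percent: with RH as a raw percent the formula
produces large negative values incompatible with the livestock
heat-load range (comfort ≈ 58, severe stress ≈ 84), so percent-looking
inputs in (1, 100] are auto-scaled with a logged note. Useful
identities: at RH = 1 the index is the Fahrenheit temperature; at
T = 26/1.8 ≈ 14.44 °C it is 58 regardless of humidity, and the
humidity sensitivity changes sign there.

## Known limitations

The DE test assumes a common dispersion; strongly variable features
(e.g. the latent-coupled triad members themselves) inflate the pooled
estimate and cost some power. CPM cannot correct composition shifts.
Correlation thresholds at n = 6 are weak evidence either way — the
discrete Spearman null at n = 6 puts ≈ 1.7% of mass beyond |0.7| per
tested pair — so desk-scale 3-vs-3 networks should be read as
illustrative, not inferential. The hypergeometric test treats the
interaction table as fixed truth and miRNA sets as exchangeable, and
raw-p gating performs no multiplicity control across candidate pairs
(the BH option exists but is off by default to match the screen's
stated form).
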