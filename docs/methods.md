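# Methods

`paleomt` reimplements, as a tested library, the population-genetic
analysis pipeline used to interrogate ancient mitochondrial HVR-I data from
North East Europe: two Mesolithic burial sites pooled as aUzPo (11
genotypes, ~300 generations old at a 25-year generation time) and the Early
Metal Age site aBOO (23 genotypes, ~140 generations old), compared against
modern North East Europeans (NEE), Saami (saa) and Central Europeans (CE)
through haplogroup spectra, haplotype sharing, summary statistics, and
serial-coalescent simulation with ABC model choice.

## Haplotype model

A haplotype is a set of variant sites on the rCRS window np 16056–16409,
written in motif shorthand (position minus 16000; upper case = transition,
lower case = transversion; parenthesised IUPAC codes = ambiguous calls,
e.g. `(390R)`). Two haplotypes are equal when their *resolved* variant
sets agree over the intersection of their sequenced windows; ambiguous
sites never enter comparisons, mirroring the exclusion of heteroplasmic
positions from population-genetic analyses. A motif is treated as a
complete observation over its window, so absence of a listed variant is
informative: `356C` does not match `093C-356C`.

Haplogroup assignment walks an editable, ordered motif table
(`data/hg_motifs.yaml`): the first (most-derived) haplogroup whose full
diagnostic variant set is contained in the haplotype wins; the root entry
(H, empty motif) is the fallback, so an rCRS-identical HVR-I sequence is
assigned H. The table reproduces the published assignments of all 34
packaged ancient genotypes exactly; it is data, not code, and can be
replaced. A companion mapping rolls HVR-I haplogroups up to the class
resolvable by the 22-SNP coding-region assay (U2e→U, Z1a→M, …) for
HVR-I/coding consistency checks; the SNP panel itself is represented only
at haplogroup level.

### Reference window

The true rCRS segment is not redistributed here; a *synthetic* stand-in
(`data/synthetic_rcrs_hvr1.fasta`, labelled as such) provides the 354-nt
backbone for FASTA reconstruction and per-site statistics. It is generated
so that its base at every position differs from every derived base in the
packaged fixture and the motif table — motif semantics require a variant to
differ from the reference, and a careless stand-in would silently shrink
sequence-space distances. All variant-set analyses are independent of the
literal backbone bases.

## Summary statistics

* **Haplogroup spectra** use the 19 pooled variables
  {C, D, H, HV, I, J, K, N1, T, U2, U4, U5a, U5b, V, W, X, Z, EAS, misc};
  EAS pools the east-Eurasian haplogroups A, B, E, F, G, Y and misc pools
  rare Eurasian classes (L, M\*, N\*, U1, U6–U8). Sub-haplogroups roll up
  by longest-prefix matching (C1→C, U4a1→U4, U5a1→U5a, Z1a→Z). Printed
  percentages use round-half-up to integers. The published "U4 (37%)" for
  aUzPo corresponds to 4/11 = 36.4%, which rounds to 36; the discrepancy is
  reported, not forced.
* **Haplotype diversity** is Nei's corrected form
  h = n/(n−1)·(1 − Σp²) over distinct-haplotype classes. The published
  diversities for the ancient samples (0.74 aUzPo, 0.82 aBOO) are *not*
  reproduced by this formula on the packaged genotypes (0.8727 and 0.8893);
  the grouping behind the published values is unknown. They are therefore
  treated as fixture inputs to the ABC stage, never as recomputation
  targets.
* **F_ST** is the two-level AMOVA variance-component ratio
  σ²_a/(σ²_a+σ²_w) between two samples. Two inter-haplotype distances are
  supported: `pairwise_diff` (count of resolved sequence differences, the
  Arlequin default for sequence data and the package default) and
  `haplotype_freq` (0/1). Because Hamming distance decomposes per site, the
  pairwise-difference AMOVA sums are computed from per-site base-count
  matrices in O(L) rather than O(n²) (`fst_from_site_counts`), which keeps
  sequence-level F_ST affordable inside simulation loops. Estimates are
  reported as computed, including the estimator's small negative values;
  when the total variance is exactly zero (both samples fixed for the same
  haplotype) F_ST is defined as 0. Note that the unbiased estimator gives
  exactly −1/(n−1) for two copies of the same polymorphic sample — a
  duplicated sample is *not* a zero-F_ST case.
* **PCA** of population × haplogroup-frequency matrices is column-centered
  and unscaled (covariance PCA) via eigendecomposition, with a
  correlation-mode option; component signs are fixed so each component's
  largest-magnitude loading is positive.
* **Genetic distance profiles** default to Nei's standard distance
  D = −ln(J_xy/√(J_x·J_y)) on haplogroup frequencies, with Euclidean as an
  alternative. (The original distance-mapping software's metric is not
  documented; Nei's standard distance is the assumed default.)

## Haplotype sharing

Comparative pools hold 500 haplotypes by convention: populations smaller
than the target are pooled by the caller, larger collections are
sub-sampled uniformly without replacement under an explicit, mandatory
seed. Sharing is exact-match only: the percentage of pool members whose
resolved variant set matches at least one *distinct* ancient haplotype,
divided by pool size (duplicated ancient haplotypes — possible kin — do
not inflate the count). Ancient–ancient sharing is directional (divide by
the second sample's size; report both directions). Redundancy filtering
keeps each haplotype once per burial-site group (aUz and aPo form one
pooled group), the kinship-robust treatment used for sensitivity analyses;
it is idempotent.

## Serial coalescent simulator

A haploid (mtDNA gene-copy) coalescent with heterochronous sampling:
lineages sampled at age *a* generations enter the process at *a*; within a
deme of size Ne(t) each lineage pair coalesces at rate 1/Ne(t) per
generation. Deme trajectories are piecewise exponential backwards in time,
normally *anchored*: Ne(t) = Ne_modern·e^(−rt) with
r = ln(Ne_modern/5000)/1500, so every trajectory passes through the
Palaeolithic size of 5,000 at 1,500 generations and stays at 5,000 beyond.
Waiting times are drawn by exact inversion of the cumulative hazard across
segments, so cost is independent of time spans; per-deme candidate times
are cached between events (deme intensities are independent Poisson
processes in absolute time, so a candidate stays valid until that deme's
lineage count changes). Two event types are processed in backward time:
a *migration pulse* (each sink lineage moves to the source independently
with the stated migrant fraction — a mass migration) and a *divergence*
(derived deme merges into its ancestor; the ancestral deme continues the
sink's trajectory).

Mutations follow a finite-sites model on the 354-site window: per-site
rate μ = 7.5×10⁻⁶ substitutions/site/generation, transition:transversion
ratio 0.9841, and discretised gamma rate heterogeneity with shape 0.205 in
10 equal-probability mean-one categories (the shape/category reading of
the published "0.205 (theta) and 10 (kappa)" parameters, a documented
assumption). Sites are assigned categories uniformly at random per
replicate; mutations are a Poisson process along branches, placed by
inverse-CDF sampling proportional to site rates; recurrent and back
mutation are allowed (HVR-I hotspots are the point of the gamma model).
For summary-statistic simulation each tip is reduced to a 63-bit XOR
digest of its (site, base) differences from the root — haplotype identity
only, with vanishing collision probability — plus sparse per-site
deviation counts when sequence-level F_ST is requested.

`simulate_dataset` groups tips by sample label and emits corrected
haplotype diversity per sample and pairwise F_ST per sample pair
(`pairwise_diff` by default, for comparability with observed fixation
indices computed from sequences), deterministically from a single seed.

The simulator is validated against closed forms (E[T₂] = Ne; total branch
length 2·Ne·H₉ for n = 10) and distributionally against msprime (used
strictly as an independent oracle) by Kolmogorov–Smirnov tests for
constant-size and anchored-growth scenarios with serial samples.

## Demographic models and ABC

Presets follow the published model set. Continuity models (k = 1 free
parameter, the modern Ne): H0a NEE+aUzPo, H0b NEE+aBOO (Ne prior
U(10⁵, 3×10⁷)), H0c saa+aUzPo (U(10³, 5×10⁵)), and H0d/H0e, which chain
the European hunter-gatherer series aHG (20 tips spread evenly over
168–614 generations), aPWC (19 @ 116) and aUzPo or aBOO in one growing
deme with no modern sample (the texts do not name one; the NEE prior keeps
the 5,000-anchor). Migration models (k = 4): NEE sink and CE source, both
anchored, Ne priors U(10⁵, 1.5×10⁷), migration-time prior U(2, 139)
generations, divergence-time prior U(620, 2600), and a fixed migrant
fraction per variant (10%, 50%, 75%); the ancient sample sits in the sink,
older than the migration pulse. Observed statistics per model are all
applicable published entries for its sampled populations (six for the
three-population models; "n/a" cells are dropped).

Stage 1 is rejection ABC: statistics are standardised by the simulated
pool's per-statistic standard deviation (diversities and F_ST live on
different scales), Euclidean distance is taken, and the closest 1% of
simulations is retained; the largest retained distance is the recorded
tolerance, and zero-variance statistics are dropped with a warning.
Posterior point estimates are retained-draw medians (a KDE mode is
available). A final batch of simulations at the point estimates yields the
model likelihood, with AIC = −2 ln L̂ + 2k and Akaike weights
ω_i = e^(−Δ_i/2)/Σe^(−Δ_j/2).

Two likelihood estimators are provided. The default, `gaussian`, evaluates
the observed vector's density under a multivariate normal fitted to the
final simulations (full covariance with a light ridge — simulated
diversities and fixation indices are strongly correlated — falling back to
independent normals only if the covariance is numerically unusable);
`fraction` is the fraction of final simulations
whose stage-1-standardised distance falls within the stage-1 tolerance,
floored at 1/(n_final+1). The default was chosen on measured behaviour:
in model-recovery experiments on pseudo-observed data generated under the
migration model, the Gaussian estimator identified the true model in every
pilot replicate while the fraction estimator never did — the fraction of
re-achieved extreme quantiles is systematically lower for models scored on
more statistics, biasing that estimator toward lower-dimensional models
irrespective of fit. The fraction estimator also cannot resolve
likelihoods below its floor, whereas published Akaike weights of order
10⁻⁷ at n_final = 10,000 require exactly such resolution.

### What the model comparison does and does not reproduce

Run at the packaged observed statistics (20,000 prior simulations per
model, 1% rejection, 10,000 final simulations), the comparison of H0a
against the 10%-migration model selects *continuity* (H0a) decisively,
under both likelihood estimators and both F_ST modes. Two structural
features drive this. First, simulated modern haplotype diversities are
0.998–0.9999 with standard deviations of 10⁻⁴–10⁻³ for every prior draw —
with μ = 7.5×10⁻⁶/site/generation and the 5,000-anchor, lineage pairs
accumulate tens of substitutions — so the observed h(NEE) = 0.98 and
h(CE) = 0.97 lie tens of standard deviations below every simulation, and
the migration model, carrying two modern populations, accrues roughly twice
the unfittable modern-diversity misfit of the one-population continuity
model. Second, the observed F_ST(CE, aUzPo) = 0.6564 is an order of
magnitude above its neighbours (a suspected typo in the source table) and
sits several standard deviations above the most favourable corner of the
migration model's prior. The source publication is itself internally
inconsistent on this comparison — its model-structure figure names H0a the
best-fitting model (lowest AIC) while its weight table assigns nearly all
weight to the migration model — and this implementation consistently
reproduces the figure's side of that contradiction. The pipeline,
statistics and presets are exactly as described; only the published weight
table's ranking is not recovered.

## Synthetic data

The comparative database behind the published modern pools is not public,
so generators emulate its statistical structure. `generate_modern_pool`
sizes haplotype classes analytically — one large class plus singletons,
with the large-class size chosen so the realised corrected diversity lands
within 0.01 of the target (an error is raised when no integer choice can) —
then gives each class its haplogroup's defining motif plus 1–3 random
private variants, re-checked so haplogroup assignment still returns the
intended label, and embeds planted matches verbatim. Diversity targeting
is exact by construction rather than by rejection sampling.
`generate_frequency_matrix` draws population rows as Dirichlet
perturbations of cluster mean spectra (zero-noise mode reproduces means
exactly). `generate_pseudo_observed` simulates one statistic vector at
known parameter values inside a model's prior support. All generators are
pure functions of (recipe, seed).

What passing tests on synthetic data do and do not show: the generators
reproduce the *marginal* targets the analyses consume (sample sizes,
diversities, haplogroup compositions, planted match fractions) but not the
phylogeographic covariance structure of real Eurasian HVR-I data — shared
deep clades across pools, isolation by distance, or realistic motif
linkage. Cluster-separation and sharing results on synthetic data
therefore validate the machinery, not any claim about real populations.

## Problem sizes and numerical choices

Replicated experiments are sized to run on a single CPU: the headline
model comparison uses 20,000 prior and 10,000 final simulations per model
(the published analysis used 100,000 prior simulations); recovery
experiments use reduced sampling schedules (30+30 modern, 10 ancient tips)
with 5,000 prior simulations per model over 20 replicates, with true
parameters chosen in the identifiable regime (small effective sizes, deep
divergence, mid-prior migration time). At that scale the measured
detection power for 10% migrants is 15/20 replicates; the losses are
replicates whose pseudo-observed statistics happen to carry little
migration signal, and larger sampling schedules sharpen the
fixation-index resolution and with it the power. Monte-Carlo tolerances in tests are
set at 4–5 standard errors of the replicate means. Tie-breaks and
degenerate inputs: zero-variance statistics are dropped from ABC distances
with a warning; F_ST of two identical fixed samples is 0 by convention;
PCA refuses matrices with fewer than three rows or zero total variance;
empty populations and malformed motif tokens raise errors naming the
offending input.

## Known limitations

* At most two demes per model; no recombination, selection, or continuous
  migration (a pulse approximates the published mass-migration event).
* The likelihood estimators approximate a true likelihood; AIC values are
  comparable within a comparison run, not across different statistic sets
  or observation vectors.
* The motif table covers the haplogroups needed for the packaged data and
  common European/Siberian classes; exotic haplogroups fall through to the
  fallback.
* Coding-region SNPs are modelled only at haplogroup level.
* Published haplotype-sharing percentages against the proprietary
  comparative database are not reproducible; sharing is validated on
  planted-match constructions instead.
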