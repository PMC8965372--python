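# Methods

## The model

Autozygosity depresses local heterozygosity: inside a run of
homozygosity (RoH) the only heterozygous calls are mutations younger
than the common ancestor plus genotyping error, while outside it the
het-site density reflects the population's diversity. `rohscan` models
the per-window heterozygosity ratio

    r_w = (het sites in window w) / (callable bp in window w)

of one sample as emissions of a hidden 3-state Markov chain with
Gaussian emissions N(μ_k, σ_k²). The state with the lowest fitted mean
is declared the RoH state; the other two absorb the background and its
fluctuations (regional diversity differences, mapping artefacts,
coverage-driven wobble). Three states rather than two gives the
background a second component so that intermediate windows — tract
edges, locally elevated diversity — do not get forced into the RoH
state.

Windows are 150 kb every 50 kb (100 kb overlap), anchored at position 1
of each scaffold; tiling stops at the first window reaching the scaffold
end, which is truncated there. Adjacent windows share two-thirds of
their sequence and are therefore strongly dependent; the model treats
them as conditionally independent given the state, which is wrong in
detail but is exactly the trade the windowed design makes for smooth
segmentation, and no correction is applied.

### Fitting

* **Emission priors**: 1-D k-means (k = 3, k-means++ under the caller's
  seed) on the ratios of windows with fewer than 60,000 noncallable bp
  against the nominal width. Cluster means/variances/sizes become the
  prior means, variances and weights, sorted by ascending mean.
  Rationale for the cutoff: windows more than ~40% gap have noisy ratios
  and would inflate the middle cluster.
* **Transitions**: each row initialized Dirichlet(1,1,1) from the seeded
  generator (a flat prior over row-stochastic vectors); start
  probabilities initialized to the k-means weights.
* **Baum–Welch**: expectation–maximization on forward–backward
  statistics until the total log-likelihood improves by < 1e-6 or 1000
  iterations. Scaffolds (split further at zero-callable windows) are
  independent observation sequences sharing one parameter set — pooling
  maximizes the data behind each per-sample fit. The E-step runs in
  scaled linear space (per-step normalization constants c_t plus a
  per-frame shift by the max log emission density), which is
  numerically equivalent to log-space arithmetic but avoids both
  underflow (densities of ratios ~1e-4 under variances ~1e-9) and the
  per-step cost of log-sum-exp. Log-likelihood monotonicity is asserted
  at every iteration.
* **Degeneracies**: emission variances are floored at 1e-12 (ratio²
  units) so a constant stretch cannot collapse a Gaussian; a k-means
  cluster with fewer than 2 members takes the floor variance with a
  warning; all-identical input is rejected. A state that receives no
  posterior mass keeps its previous parameters.

### Decoding and calling

Decoding is Viterbi (log space; ties break toward the lower state
index). Posterior (per-window argmax) decoding is available via
`decode(method="posterior")`; Viterbi is the default because it is
deterministic, respects the fitted persistence, and cannot emit
state flips unsupported by a path. Windows with zero callable bp are
excluded from fitting and decoding and break runs — no RoH is called
across sequence we cannot see.

A maximal run of ≥ 3 consecutive RoH-state windows becomes one segment
from the first window's start to that start + n·step, inclusive, so a
run of n windows has length n·step + 1 and the shortest possible call
is 150,001 bp. This is the unique length convention consistent with
that printed minimum given the window geometry (the union of three
overlapping windows would span 250 kb); only the placement of the
segment within the run's span is free, and we anchor it at the first
window's start. `roh_state` is always re-derived as argmin of the
fitted means, so RoH calls are invariant to any permutation of state
labels in the initialization.

A model-free comparator, `baseline_threshold_caller`, applies the same
run and coordinate conventions to the condition `r_w < cutoff`
(default 1e-4, roughly the midpoint between typical background and
within-tract rates on a log scale). It exists to show the HMM's calls
are not an artefact of the machinery: per-sample RoH fractions from
the two callers correlate above 0.9 on planted-tract simulations.

### Accuracy and the edge-trim bias

Only windows fully inside an autozygous tract can be low-heterozygosity,
so a tract of length L yields at most ⌊(L − width)/step⌋ + 1 RoH
windows and a called length near L − (width − step) = L − 100 kb. The
trim is a property of the window geometry and the length convention,
not of the fit: base-pair F1 against planted tracts exceeds 0.90 (we
observe 0.94–0.98 on 100 Mb genomes with 25% autozygosity), while
F_ROH is biased low by roughly 100 kb × (number of tracts) / genome —
about 0.01–0.03 for tracts averaging 2 Mb. F_ROH comparisons between
samples analysed identically are unaffected by the shared bias;
absolute F_ROH values should be read as slight underestimates, more so
when many short tracts near the 150 kb detection floor are present.

## Inbreeding estimators

* **F_ROH** = Σ merged segment lengths / autosomal bp. Additive over
  scaffolds, order-invariant, in [0, 1].
* **F_HOM** = (O − E)/(N − E) per sample, with O the observed
  homozygous genotype count over the sample's non-missing sites, N that
  site count, and E = Σ_i [1 − 2 p_i (1 − p_i) n_i/(n_i − 1)] the
  expected homozygous count under Hardy–Weinberg using the unbiased
  expected-heterozygosity correction (n_i = non-missing allele count at
  site i, p_i the alt frequency over all non-missing genotypes). Sites
  with n_i < 2 are excluded. This is the established `--het` convention;
  it is negative when a sample is more heterozygous than the panel
  expectation, and exactly 1 when the sample has no het genotypes.
  On Hardy–Weinberg panels its sample mean converges to 0.
* **F_PED** = Θ(sire, dam) from the tabular kinship recursion in one
  topological pass. Founders are assumed unrelated and noninbred (the
  standard studbook assumption); the assumption is relaxable by seeding
  founder kinship cells explicitly (`founder_kinship=`). An unknown
  parent contributes 0 (Malécot convention: unrecorded = unrelated
  founder). Pedigree validation rejects cycles, self-parentage, and
  individuals appearing as both sire and dam.

F_PED is an expectation over meioses; the realized autozygous fraction
varies around it (Mendelian sampling, linkage). `expected_vs_realized`
quantifies this against gene-drop replicates: means match F_PED, and
the replicate variance grows as map length concentrates on fewer
chromosomes.

Cross-estimator agreement uses Spearman's rho on pairwise-complete
observations (samples lacking studbook records simply drop out of
F_PED pairs); group contrasts use pairwise two-sided rank-sum tests
with Benjamini–Hochberg adjustment, or one-way ANOVA followed by Tukey
HSD for the heterozygosity comparison. Groups with fewer than two
members are excluded with a warning.

## Colocalization

The Jaccard coefficient of two samples is |A ∩ B| / (|A| + |B| − |A ∩ B|)
in bp over their merged RoH sets; two empty sets give 0 by convention
(the formula is 0/0). The sharing spectrum counts, for every carrier
count k, the bp covered by exactly k samples' RoH, via an event-point
sweep over interval boundaries (never per-bp loops); per-sample private
bp is the sample's RoH minus the union of everyone else's. All interval
arithmetic lives in `rohscan.intervals` on 1-based inclusive intervals;
BED I/O converts to 0-based half-open at the boundary, a round-trip the
tests prove lossless.

## The synthetic-data generator

The analysis consumes only per-site het/hom status, depth and quality,
so the generator emulates exactly that — a marked Poisson process, not
a coalescent:

| parameter | default | why |
|---|---|---|
| background het rate | 2.4e-4 /bp | matches the study system's observed medians (2.1–2.66e-4) |
| within-tract het rate | 1e-5 /bp | residual young mutations + genotyping error inside RoH |
| genome | 4 scaffolds × 15 Mb | desk-scale stand-in for a multi-scaffold assembly |
| cohort | 13 founders, 8 F1, 4 F2, 5 unmanaged | the captive-breeding cohort structure |
| autozygous fraction | 0.25 per sample | upper range of the study's group RoH fractions |
| tract lengths | ≥ 500 kb, exponential excess, mean 2 Mb | recent captive inbreeding produces multi-Mb RoH; keeps the 100 kb edge trim small relative to tract size |
| depth | Poisson(7) per genotype | the ~7× sequencing design, so the 3–30× filter is exercised |
| mask gaps | 5% of bp, exponential mean 10 kb | assembly/callability holes |
| recombination | 0.01 crossovers/Mb (1 cM/Mb) | mammalian-typical map density (gene-drop mode) |
| site quality | Uniform(40, 90) | passes Q30 except spiked sites |

Planted mode draws non-overlapping tracts until the target fraction is
reached within half a mean tract length (the closing tract is capped so
the total never overshoots by more than that; the cap provably never
drops below the minimum length). Gene-drop mode gives each founder two
globally unique haplotype labels and transmits recombined mosaics down
the pedigree (Poisson crossover counts, uniform positions); an interval
is autozygous when both inherited labels coincide, and realized IBD is
the autozygous genome fraction.

Emission unions all samples' het positions into one VCF; at each site
the alt frequency is Beta(0.5, 0.5) and non-focal samples are
homozygous (alt with that probability), so no sample's het count drifts
from its planted rate. An optional spiked fraction of extra sites is
constructed to fail exactly one filter class each (low quality, global
low depth, high missingness, singleton MAF) with positions recorded for
truth bookkeeping. One consequence of the Beta frequency spectrum:
singleton-het sites can legitimately fail the 2% MAF filter (~10% of
them do at n = 30), so heterozygosity-rate calibrations are done on the
emitted table, before filtering.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: linkage disequilibrium and
a realistic site-frequency spectrum, mapping/reference bias (including
the cross-species-assembly rearrangements that make real calls
"putative"), error rates varying with depth, and relatedness between
samples in planted mode (tracts are independent across samples).

All randomness descends from `SimulationConfig.seed` through distinct
`numpy` generator streams per operation; identical configs produce
byte-identical output files.

## Other numerical choices

* Coordinates are 1-based inclusive everywhere in memory; lengths are
  end − start + 1.
* Scaffold retention is strict (> 45 Mb); the pipeline falls back to
  retaining all scaffolds with a warning when none qualifies (the
  desk-scale synthetic genomes), while the library function treats an
  empty selection as an error.
* MAF uses depth-masked genotypes; the missingness test uses the same
  masked genotypes. Depth masks genotypes, quality/missingness/MAF drop
  sites — the conservative reading of a per-genotype depth filter.
* Multi-allelic records are rejected (counted), never decomposed.
* Spearman entries with fewer than 3 complete pairs are reported
  missing rather than computed.

## Known limitations

* The F_ROH edge-trim bias quantified above.
* Segments cannot cross zero-callable windows even when the underlying
  tract does, splitting long tracts that span large mask holes.
* The HMM's middle state has no biological identity; it is a catch-all
  whose fitted mean typically lands on tract-edge windows. Interpreting
  its parameters is not recommended.
* Per-sample fits mean per-sample state scales: comparing fitted
  emission parameters across samples is only meaningful when coverage
  and callability are comparable.
* `F_HOM` depends on the panel's allele frequencies; with structured
  panels (e.g. two diverged populations) it measures departure from the
  pooled expectation, not within-population inbreeding.
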