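# Methods

## Scope and data model

`actampl` analyses paired DNA/RNA (cDNA) *nifH* amplicon libraries — one
pair per station — given three tab-delimited inputs (OTU×sample counts,
sample metadata, OTU→group taxonomy) and one CSV of qPCR cycle thresholds
with technical replicates per (station, template). Sequence processing
(read QC, OTU clustering, chimera removal) is upstream of this package:
tables are the input boundary. Tables are OTU-rows × sample-columns;
orientation is never auto-detected (an explicit `transpose` flag exists)
to avoid silent transposition. OTUs missing from the taxonomy file are
assigned to an explicit `other` group, so group frequencies always sum to
one. qPCR replicates are stored raw; averaging happens only inside the
ratio computation, keeping provenance auditable.

## Rarefaction

Uneven depths are normalized by repeated rarefaction: each sample is
subsampled **without replacement** (multivariate hypergeometric — the
sample holds observed reads, so a subsample cannot contain a read twice),
to a common depth (default: smallest library total; `iterations`
default 100), and the entrywise mean of the draws is carried downstream
unrounded. Multinomial (with-replacement) resampling is available as an
option but is not the default. Column sums of the mean table equal the
depth exactly. Shannon, Simpson and Pielou operate on proportions and are
scale-invariant, so real-valued means are fine; Chao1 needs integer
singleton/doubleton counts and is therefore computed per iteration on the
integer draws and averaged. Whether a repeated-rarefaction protocol should
retain one draw or the average is a genuinely open choice; averaging is
used because it is deterministic in the limit and reduces subsampling
noise, and the per-draw path remains exposed (`rarefaction_draws`).

## Alpha diversity

* Shannon uses natural log (nats). This choice cancels in Pielou
  *J* = *H*/ln *S*, and only rescales *H* itself.
* Simpson is the Gini–Simpson form 1 − Σp², so "higher = more diverse".
* *J* is undefined (NaN, flagged) for single-taxon samples, never coerced
  to 0.
* Chao1 switches to the bias-corrected form
  S_obs + F₁(F₁−1)/(2(F₂+1)) when F₂ = 0, avoiding division by zero.
* The DNA-vs-RNA contrast reports Welch *t* (default, robust to unequal
  variances), Student *t*, and one-way ANOVA (for two groups F = t² of the
  Student statistic). All are emitted side by side rather than choosing
  one test post hoc.

## Beta diversity

Bray–Curtis d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) is computed on per-sample
proportions of the normalized table (Bray–Curtis on raw counts confounds
depth with composition).

NMDS minimizes Kruskal stress-1 with disparities from isotonic regression
of configuration distances on the dissimilarity ranks, using the
**primary** approach to ties (tied dissimilarities are unconstrained; an
all-equal dissimilarity matrix therefore has zero stress for any
configuration — any simplex is an optimal embedding, and the result is
flagged converged). Descent: non-metric SMACOF from a classical-scaling
(PCoA) start plus 20 random restarts (seeds derived deterministically from
the master seed), max 300 iterations, stress tolerance 1e-6, followed by a
quasi-Newton polish of the exact stress-1 objective from the best
candidate. The best configuration across starts is returned with its
stress and a convergence flag.

Beta-dispersion embeds the dissimilarity matrix by principal coordinates
(eigendecomposition of the doubly-centred squared-distance matrix), keeps
real and imaginary axes separately, and measures each sample's distance to
its **group centroid** (centroid, not spatial median) as
√(Σ₊(x−c)² − Σ₋(x−c)²), floored at zero — the standard correction for
negative eigenvalues of non-Euclidean dissimilarities such as
Bray–Curtis. Group differences in these distances are tested by one-way
ANOVA; because the distances are not exactly normal, a permutation
*p*-value (labels permuted over the fixed distances, 999 permutations by
default, add-one correction) is reported alongside the parametric one.

## Expression ratios

* ΔCt is fixed as mean Ct(DNA) − mean Ct(cDNA). More transcript → lower
  cDNA Ct → ΔCt > 0 → R_bulk = E^ΔCt > 1, i.e. R is the mRNA/DNA ratio.
* Technical replicates are averaged on the Ct (log) scale, standard qPCR
  practice.
* Efficiency defaults to E = 2 (perfect doubling) when no standard curve
  is supplied, and is always recorded in the outputs; a slope input uses
  E = 10^(−1/slope).
* R_group = R_bulk·f_RNA/f_DNA uses each station's own frequencies by
  default; an `average_frequencies` mode uses across-station mean
  frequencies instead. Which of the two a published group-mean refers to
  is ambiguous in general, so both are implemented and neither is
  privileged. R_group is undefined (NaN + flag, rendered "n.d.") when the
  group is absent from the station's DNA library.
* Identity worth knowing: Σ_g f_DNA,g · R_group,g = R_bulk whenever all
  groups are defined, since Σ f_RNA,g = 1.
* Proportionality classes (per-OTU): within a configurable fold threshold
  (default 2×) of the 1:1 DNA:RNA frequency line → proportional, else
  RNA- or DNA-enriched; one-sided zeros classify to the non-zero side;
  the threshold is a package definition, not a literature constant.

## Synthetic data generator

The generator emulates the structure of a transect study of
plankton-associated diazotrophs: 9 stations × 2 libraries at 4746 reads,
731 OTUs in 8 taxonomic groups. Each taxon has a DNA relative abundance
dᵢ (Σd = 1) and an activity multiplier rᵢ ≥ 0 (its per-gene-copy
mRNA/DNA ratio); RNA proportions are dᵢrᵢ renormalized, and the station's
true bulk ratio is R_bulk = Σdᵢrᵢ. Reads are multinomial draws (sequencing
samples with replacement from an effectively infinite template pool;
pipeline rarefaction then subsamples those reads without replacement —
the two sampling schemes play distinct roles). qPCR cycle values are
Ct = anchor − log_E(signal), with the cDNA signal scaled by the true bulk
ratio, an arbitrary fixed anchor of 15 cycles, a lognormal station signal
(which cancels in ΔCt), and Gaussian replicate noise (default SD 0.15
cycles, a typical technical-triplicate spread).

Default community (group: DNA share, mean r, #OTUs): Trichodesmium
0.978 / 0.15 / 200; cluster III 0.011 / 0 / 100; Betaproteobacteria
0.0033 / 0.02 / 60; Gammaproteobacteria 0.003 / 2.0 / 120;
Deltaproteobacteria 0.002 / 2.5 / 80; heterocystous cyanobacteria
0.002 / 3.5 / 40; unicellular cyanobacteria 0.0001 / 7.8 / 30; other
0.0006 / 1.0 / 101. Within groups, OTU abundances decay as rank^−1.5 and
activities jitter lognormally (SD 0.3). The implied bulk ratio Σdr ≈ 0.166
and the dominant genus's RNA share ≈ 0.88 sit in the range reported for
oligotrophic-ocean diazotroph assemblages, which is what the defaults are
meant to mirror. Station structure: per-(station, taxon) lognormal
perturbation of d (SD 0.25, keeping the dominant genus's DNA share in the
~95–99.7% band) and per-(station, group) lognormal jitter of r (SD 1.0,
spanning roughly e^±2 over 2 SD — enough to swing the dominant genus's RNA
share between ~65% and ~99% across stations). The activity jitter is the
knob that produces higher between-station dispersion of active than of
total communities.

What the generator does **not** emulate: sequence-level artefacts (PCR
bias, chimeras, frame shifts), real spatial/environmental covariance
between stations, overdispersion beyond multinomial sampling, and
compositional correlations between groups. Passing tests therefore
demonstrate correct recovery of the generative model's quantities, not
robustness to those real-data features.

## Problem sizes in the test suite

Ground-truth recovery is checked at the study scale (9 stations,
4746-read libraries, 0.15-cycle Ct noise) over 100 replicates, with the
median relative error of group ratios required below 10% for groups at
≥1% DNA frequency. The dispersion test's type-I error is calibrated on
500 exchangeable-null datasets at 199 permutations; the qualitative
active-community signatures (higher RNA Shannon, higher RNA dispersion)
are required in ≥95% of 50 replicate datasets. NMDS is validated against
exactly-embeddable configurations and a brute-force grid-search oracle on
4-sample instances; alpha indices against closed forms and scikit-bio;
dispersion F against scikit-bio's permdisp.

## Known limitations

* R_group is a frequency partition of one bulk qPCR signal; it inherits
  any primer or amplification bias shared by sequencing and qPCR and is
  undefined for groups absent from the DNA library at a station.
* The permutation dispersion test permutes distances to fixed centroids
  (it does not recompute centroids per permutation), the common practice;
  it is approximately, not exactly, exchangeable.
* Rarefaction means are a variance-reduction device, not a variance
  model; no compositional (log-ratio) alternative is provided.
* NMDS stress below ~1e-7 is reported as is; stress-1 has a square-root
  singularity at zero, so the last digits of a near-perfect embedding are
  noise.
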