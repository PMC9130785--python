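# Methods

This note documents the statistical model behind `scentmhc`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Chemical preprocessing

A replicate-level peak table holds, per bird × replicate, the sample mass
(g), the internal-standard peak area (arbitrary area units; the standard
corrects instrument-sensitivity drift) and one peak area per compound.
Processing is fixed as **standardize → average → log**:

1. per replicate, area / (internal-standard area × mass), units g⁻¹;
2. mean over a bird's replicates;
3. log(X + 1) entrywise (keeps exact zeros at 0 and tames the few highly
   abundant compounds).

Averaging on the standardized scale matters: replicates carry different
internal-standard areas, so averaging raw areas first would re-weight
replicates by their instrument response. Nonpositive masses or standard
areas are hard errors naming the offending replicate.

**PCA.** Columns are centered; with `scale=True` (default) they are also
divided by their sample s.d. (correlation PCA), dropping zero-variance
compounds with a warning. Scores and loadings come from the SVD of the
centered (scaled) matrix; eigenvalues use the n−1 denominator. Because the
main text of chemical-ecology studies rarely states covariance vs
correlation PCA, both are supported; unit-variance scaling is the default
(it matches the default of the common PCA implementations and makes the
analysis robust to compound-abundance scale). Each component's sign is
fixed so its largest-magnitude loading is positive, making reports
reproducible across BLAS/LAPACK builds.

**Component retention** offers three standard criteria — Kaiser–Guttman
(eigenvalue above the mean), broken-stick (leading components whose
variance fraction exceeds b_k = (1/p)·Σ_{i=k..p} 1/i), and Horn's parallel
analysis (leading eigenvalues above the seeded 95th percentile of
correlation-matrix spectra from standard-normal data of the same shape;
observed spectra are rescaled to sum to p so covariance-based spectra are
comparable). The recommendation is the median of the three; an `override`
reproduces any fixed published choice (the storm-petrel analysis used two
components, `override=2`, which is the pipeline default).

## Functional MHC distances

Residues live in the five z-scales of Sandberg et al. (1998); the residue
distance is Euclidean in that space, the allele distance is the mean over
aligned positions (an optional 0-based position mask restricts to, e.g.,
peptide-binding-region sites), and:

* **individual diversity** — per locus, the distance between the two
  carried copies (homozygotes score 0); for both loci, the mean (default)
  or max over all six unordered pairs of the four copies. The mean is the
  default because no convention exists for reducing four alleles to one
  number; results record the rule used.
* **dyadic MHC distance** — the maximum functional distance over
  locus-matched cross-individual copy pairs (2×2 per locus, pooled over
  the requested loci). Locus-matched, because comparing a DAB1 copy with a
  DAB2 copy would make even identical genotypes nonzero; the max rule
  reads "how dissimilar can these two immune repertoires look", and a
  `mean` rule is available as a sensitivity option.

The z-table ships as a versioned constant; any user table with the same
shape is accepted and all distances scale linearly with the table
(homogeneity is property-tested). Nucleotide input is translated with the
standard code (reading frame required; premature stops are errors).

MHC heterozygosity for the genome-wide comparison defaults to the 0/1
same-sequence indicator per locus, with a `functional` mode (the copy
distance) as alternative; the correlation utility is a plain Pearson r and
treats genome-wide heterozygosity values as given numbers.

## Dyadic permutation tests

Square within-sex matrices unfold to the strict lower triangle in
row-major order; rectangular male×female matrices unfold row-major. All
matrices entering one test are aligned by labels first; disjoint label
sets are an error, never a silent intersection.

The **partial Mantel** statistic is the partial Pearson correlation of the
unfolded chemical (A) and genetic (B) vectors given covariate vectors
(computed by residualizing on an orthonormal basis of [1, C...]; for one
covariate this equals the textbook recursion formula). The null permutes
rows and columns of A simultaneously (individual-level permutation),
holding B and the covariates fixed, and recomputes the partial statistic
each draw — the convention of the common R implementations. The
**rectangular partial Spearman** applies the same machinery to
average-ranked unfolded vectors; its default null permutes A's dyad
entries (matching the cited permutation-pcor convention), and a
`restricted=True` null permutes A's row labels instead, because dyad-entry
permutation ignores the non-independence of dyads sharing an individual.
Both schemes are kept because the literature does not fix one; they should
be compared when conclusions are marginal.

p-values use the add-one estimator (k+1)/(B+1), so p ≥ 1/(B+1) and is
never zero; comparisons use a 1e-12 slack so exact ties count as extreme.
Tests are two-sided by default (`tail="greater"` for directional positive
covariance hypotheses). Every result records its seed, permutation count
and dyad count. A chemical or genetic vector that is constant after
covariate removal makes the statistic undefined and raises. Bonferroni
corrections are plain α/m (families of 6 models and 9 dyadic tests in the
default pipeline).

Calibration of the whole chain is itself part of the test suite: with no
planted effect the F–F partial Mantel rejects at 4–6% across hundreds of
simulated cohorts (pooled 0.049 over 2000 cohorts during development), and
a known inflation mode — a covariate matrix nearly collinear with the
chemical matrix — is avoided in the generator (below) precisely because
raw-data permutation is anticonservative there (Legendre 2000).

## Interaction models

`MHCDiversityModel` fits, by OLS,

    score ~ diversity + sex + status + diversity:sex + diversity:status

with sum-to-zero sex contrasts so the Type III ANOVA is orthodox; a
treatment-coded fit is reported alongside because published coefficient
tables rarely state their coding. Simple slopes per sex (evaluated at the
mean breeding status) and slopes at mean and ±1 s.d. breeding status
("mid", "early", "late" incubation) are linear combinations of the
coefficients with t-based standard errors — the ±1 s.d. split is
presentation only, never a categorical refit. Confidence intervals are
95% t-intervals. Rank-deficient designs raise with the aliased columns
listed. The companion `two_sample_t` is the pooled-variance t-test
(df = n₁+n₂−2, so two groups of 40 give df = 78).

## BIO-ENV

For every subset of ≤ `k_max` compounds (exhaustive, lexicographic
enumeration over sorted compound labels), the Euclidean inter-individual
distance on the subset columns is correlated (Pearson by default; Spearman
optional) with the unfolded target genetic matrix. Columns enter on the
log-profile scale by default — they are already comparable after the
transform — with `scale=True` for the classic unit-variance normalization.
Ties within 1e-12 resolve to the lexicographically smallest subset, making
results invariant to column order; the overall best prefers the smaller
subset at equal correlation. A partial variant residualizes on a covariate
matrix and flags the result. The maximized correlation is selection-biased
and is deliberately not given a p-value.

Exhaustive search over 80 compounds at k ≤ 6 is ~3×10⁸ subsets; the
pipeline therefore pre-filters to the `bioenv_max_compounds` (default 25)
compounds whose single-compound dyadic correlation with the target is
largest in absolute value (a marginal screen that can lose
combination-only compounds, so outputs are flagged `prefiltered`), and a
greedy forward-selection fallback (`bioenv_greedy`) is available, labelled
`+greedy` and carrying no optimality guarantee.

## Synthetic cohorts

The generator emulates the study design the analysis assumes: 80
incubating adults (40 per sex, `n_per_sex=40`), 80 compounds measured in
triplicate, two MHC class IIB loci with two copies each from a finite
allele pool, breeding status = sampling day − hatch day uniform over a
45-day incubation window (negative during incubation, larger = later).
Recorded peak areas are concentration × internal-standard area × mass
(log-normal standards around e^11.5 area units and 4 mg feather mass), so
downstream standardization recovers concentrations exactly and
`noise_sd=0` yields bit-identical standardized replicates.

Log-scale concentration per compound is baseline (Uniform(2,6)) plus:

* **sex and breeding-status loadings** — per-compound signed coefficients
  s_c ~ N(0, sex_effect²), w_c ~ N(0, breeding_effect²). Different
  volatiles rise or fall with sex and incubation stage; a uniform shift
  would make PC1 collinear with breeding status (observed dyadic
  correlation 0.98 in that regime), which both misrepresents real
  profiles and sits exactly in the permutation test's known inflation
  mode.
* **individual identity** — four latent factors (loadings N(0, 0.5²),
  scores N(0,1)) plus per-bird-per-compound idiosyncrasy N(0, 1²), stable
  across replicates. Storm-petrels carry individually distinctive odour
  profiles; these terms make the leading PCs identity axes (as in real
  data, where two PCs can carry ~2/3 of the variance) and give non-signal
  compounds real between-individual variance.
* **MHC signal** (signal compounds only) — `effect_size` × standardized
  both-loci diversity (slope per s.d. of diversity; `diversity_effect`
  overrides the slope separately from the dyadic channel), plus an
  allele-additive term: each allele carries a fixed contribution vector,
  and a bird adds the mean over its four copies. Contributions are signed
  per-compound weights (±Uniform(0.5, 1.5), shared across the paralogous
  loci) times the allele's coordinate on the dominant principal axis of
  the pool's functional distance matrix (classical MDS, orientation fixed
  along pool order). This makes chemical similarity proportional to
  functional allele similarity — the covariance the dyadic tests target —
  rather than rewarding only exact allele sharing, which a max-rule
  genotype distance cannot see.
* replicate noise N(0, noise_sd²).

**Allele pools.** `generate_allele_pool` draws iid-uniform sequences by
default; cohort simulation uses a nested substitution ladder
(`pool_structure="gradient"`, up to `max_divergence`=40% of positions):
allele k carries allele k−1's substitutions plus fresh ones, so functional
distance grows monotonically with rank separation. Uniform pools are
nearly equidistant in descriptor space (measured distance cv ≈ 0.03 at
realistic sizes) — a regime in which every dyadic genotype distance is the
same and no covariance analysis can work, which real allele series do not
resemble. **Genotype coherence** (`genotype_coherence=0.5` default): a
bird's four copies cluster round a per-individual centre allele, emulating
the repeated multi-locus genotypes of real cohorts (e.g. 55 unique
genotypes among 80 birds) and the tight linkage of the paralogous loci;
0 restores independent copy draws. Allele frequencies are uniform by
default and configurable.

**What the generator does not emulate:** chromatography physics, retention
times, co-elution, detection limits and censoring, compound identification
errors, diet/season/colony structure, sequencing or genotyping error, and
any nucleotide-level evolution. Passing tests therefore show the analysis
chain is correct and calibrated on data with the assumed structure — not
that real feather chemistry behaves this way.

## Calibration studies and problem sizes

`scentmhc.calibration` packages three seeded studies (per-cohort seeds
spawned from one master seed; data and permutation streams separated):

* **type-I error** — 500 null cohorts (`effect_size=0`, 20 birds/sex, 30
  compounds), F–F partial Mantel of PC1 distance vs both-loci MHC distance
  controlling PC2 and breeding-status distance, 199 permutations, α=0.05.
  Nominal is ~0.05 (the add-one estimator at B=199 makes the exact
  attainable level 0.045).
* **power** — 100 cohorts with the strong planted effect (20 birds/sex,
  3 signal compounds of 20, 5 alleles/locus of length 40,
  `effect_size=3.0`, `diversity_effect=0.5`, `noise_sd=0.2`,
  `genotype_coherence=0.85`), F–F partial Mantel of the signal-compound
  Euclidean distance vs DAB2 max-rule distance controlling breeding
  status.
* **BIO-ENV recovery** — the same cohorts; success when ≥2 of the 3
  planted compounds appear in the best subset (k ≤ 6).

The strong-effect configuration is a deliberately detectable regime chosen
to exercise the chain, not an estimate of field effect sizes (published
odour–gene correlations are r ≈ 0.1–0.35 and would need far larger samples
at these permutation counts). Problem sizes (500/100/100 cohorts, 199
permutations, reduced compound counts) keep the full studies at a few
minutes on one CPU; the same functions accept larger sizes.

## Known limitations

* The partial Mantel permutes raw data, not residuals; with covariates
  strongly correlated with the chemical matrix it inflates (the generator
  avoids that regime, real data may not — a Freedman–Lane scheme would be
  the next step).
* The rectangular dyad test's entry-permutation null ignores dyadic
  non-independence; the restricted row-permutation null is provided but
  neither is exact.
* BIO-ENV's pre-filter is marginal and can drop compounds informative only
  jointly; the greedy fallback is a heuristic.
* Type III tests assume the sum-to-zero coding; with strongly unbalanced
  sexes the single-coefficient "sex" effect depends on coding (both
  codings are reported).
* Allele sequences must be pre-aligned (equal length per locus); no
  alignment is performed.
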