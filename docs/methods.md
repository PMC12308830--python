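# Methods

This note documents the models, estimators and numerical choices behind
`telandscape`, and what the synthetic-data generator does and does not
emulate.

## Windowed densities and bootstrap summaries

Chromosomes are tiled into fixed windows (default 100 kb, configurable down
to 10 kb). A trailing partial window is kept only when it spans at least
half the window size: shorter tails produce high-variance density estimates,
but discarding every tail would systematically remove up to one window from
each — especially each small — chromosome. Repeat and CDS densities are
computed on the *interval union* of hits (overlapping RepeatMasker hits and
shared isoform exons count once), never on summed hit lengths, so densities
are bounded by 1 by construction. GC content uses only unambiguous A/C/G/T
bases in the denominator; soft-masked lowercase counts normally; a window of
only Ns is missing. Assembly gaps (N runs) remain in the repeat-density
denominator.

Chromosome-level means carry 95% percentile-bootstrap confidence intervals:
windows are resampled with replacement (default 1,000 replicates, equal
weights for partial windows, seeded generator recorded in the run metadata).
Calibration is verified empirically: over 500 simulated chromosomes of 100
Gaussian windows the interval covers the true mean ~94% of the time.

## TE age strata and the spacing ratio

Divergence of a TE copy from its library consensus (the `.out` "% div"
column, used as printed, without Kimura correction — the column itself is
the age proxy) defines two strata: young [0, 5)% and old [5, 10]%. The
interval conventions are: the paper-standard open upper bound for young, and
a closed old interval; copies above 10% are excluded.

Within a stratum, records are sorted by start and each adjacent pair
contributes a distance `next.start − prev.end` (0-based half-open
coordinates, hence the count of bases strictly between the two copies),
floored at 0 for overlapping or nested copies. "Distance between TE
insertions" is taken as intervening sequence because that is what a
deletion-biased mechanism removes; a `start-to-start` mode is provided for
comparability. Records of the other stratum between a pair do not break the
pair. The per-chromosome statistic is mean(young gaps) / mean(old gaps); it
is reported missing when either stratum has fewer than two copies or the
old mean is zero.

Interpretation: under continual removal of inter-TE sequence, old copies
have had longer to drift together, so chromosomes with faster removal show
a larger young/old ratio; a negative ratio-versus-length correlation across
chromosomes is the signature of size-dependent sequence loss.

## Association tests

Spearman ρ is the Pearson correlation of mid-ranks. For n > 10 the two-sided
p-value uses the t-approximation t = ρ√((n−2)/(1−ρ²)); for n ≤ 10 the exact
permutation distribution over all n! orderings is enumerated (chromosome
counts in practice are 20–31, so the exact branch exists for small-n
honesty, not speed). Constant input is an error rather than ρ = 0.
Benjamini–Hochberg adjustment is applied across the family of tests declared
in a run (the statistics listed in one correlation table); the family is
recorded in the output. Multiple regression of repeat density on chromosome
length, GC and CDS density is ordinary least squares with intercept and
n−p−1-df t-tests; because no standardisation convention is universal, both
raw and z-scored coefficients are reported. Sex chromosomes are included in
density/spacing analyses by default and excluded where configured
(`exclude_chroms`), which is also how the Z chromosome is dropped from
population-genomic runs.

## Degeneracy classification and diversity

Each CDS base is labelled by the number of synonymous changes among its
three possible substitutions under the standard nuclear genetic code:
3 → 4-fold degenerate (4D), 0 → 0-fold (0D), otherwise "other" (2- and
3-fold sites). Reverse-strand transcripts are evaluated on the reverse
complement; the phase of the first coding segment trims incomplete leading
codons; transcripts whose CDS is not a whole number of codons, or with an
internal stop, are skipped with a warning. Sites labelled differently by
overlapping transcripts are "conflicting" and excluded from both the 0D and
4D site sets — the conservative choice for a selection proxy. SNP effects
(synonymous/nonsynonymous) come from substituting the alternate allele into
the reference codon; indels, non-CDS sites and transcript conflicts are
"other".

Nucleotide diversity is the missing-data-aware ratio of sums: per site with
k called alleles, differences are summed over unordered allele pairs and
comparisons are k(k−1)/2; window π = Σ diffs / Σ comparisons over retained
sites. A mean of per-site ratios would be biased when call rates vary;
the ratio of sums is not. Invariant sites enter the denominator, hence the
all-sites VCF requirement. Multiallelic sites contribute all called alleles
to the pairwise counts. Chromosome-level π is the *unweighted mean of window
π* (windows without comparisons are dropped and counted), and the 0D/4D
ratio divides these chromosome means; the whole-chromosome ratio of sums is
also emitted for reference.

## Gamma-DFE inference from folded spectra

Under the Poisson random field, segregating sites at population frequency x
with scaled selection coefficient S (negative = deleterious) have density

    h(x; S) = (1 − e^{−S(1−x)}) / ((1 − e^{−S}) · x(1−x)),   h(x; 0) = 1/x,

normalised so the neutral expected unfolded class i of n sampled alleles is
1/i. Expected sample classes are the binomial mixture
e_i(S) = ∫ C(n,i) x^i (1−x)^{n−i} h(x;S) dx, folded onto minor-allele
classes 1..⌊n/2⌋. Deleterious effects follow a gamma distribution (shape β,
mean |S̄|) with no beneficial mass, and inference is folded-only — no
ancestral polarisation is needed.

The observed spectra are modelled as
synonymous class i ~ Poisson(θ·L_syn·e_i(0)·r_i) and
nonsynonymous class i ~ Poisson(θ·L_nonsyn·E_γ[e_i(S)]·r_i), with
frequency-class nuisance factors r_i (r_1 ≡ 1) shared between the two
spectra standing in for an explicit population-size-change model. The
mutation-rate scaling θ is deliberately *common* to both site classes: with
it, the deficit of segregating nonsynonymous sites relative to the surveyed
length ratio L_nonsyn/L_syn — not just the spectrum shape — identifies the
selection strength. (With a free nonsynonymous θ the folded-spectrum
likelihood is flat in |S̄| over orders of magnitude; the shared rate is what
makes the mean estimable, exactly as the surveyed-site counts do in
established DFE software.)

Numerics: e_i(S) is computed by adaptive quadrature with the integrand in
log form; for |S| > 40 a breakpoint at the boundary layer of width ~20/|S|
is supplied to the integrator; |S| beyond 10⁶ is evaluated at the bound with
a warning (the boundary layer is then below 10⁻⁶ and classes are
singleton-dominated). The gamma mixture integrates over a fixed
log-spaced |S| grid (220 cells, 10⁻⁴–10⁵) with exact gamma cell masses via
regularised incomplete gamma functions; mass below the grid is treated as
neutral, mass above as the last cell. Given (β, |S̄|), the nuisance block
(θ, r) is profiled out by an iterative fixed point solving its Poisson
stationarity equations; the outer 2-parameter optimisation is bounded
L-BFGS-B on (log β, log |S̄|) from 8 deterministic starts
(β ∈ {0.1, 0.3, 1, 3} × |S̄| ∈ {10, 1000}). A fit with |S̄| at the lower
bound is flagged as neutral. Profile-likelihood confidence intervals for
|S̄| are available separately. S̄ is reported on the scaled (4Nₑs) axis with
a negative sign; an unscaled s̄ requires a user-supplied Nₑ, and across-
chromosome comparisons use relative ordering only.

Folded spectra are built at a common haploid size n: sites genotyped in more
alleles are hypergeometrically projected down (expected fractional
contribution of each subsampled count); sites with fewer called alleles are
excluded. Parameter recovery on data simulated from the model
(β = 0.3, S̄ = −500, n = 20, 10⁶ sites per class, θ = 0.008) returns median
β ≈ 0.30 and median |S̄| within a few percent of truth.

## Synthetic-data generator

The landscape generator embodies the mechanism under test. TEs insert in two
discrete epochs (old then young — two epochs rather than continuous activity
keeps the ground truth interpretable and matches the two divergence strata);
insertion rates are power laws λ(L) = a·(L/Mb)^b per Mb, size-independent by
default (a_old = 120, a_young = 80 with ~1.2-kb lognormal fragment lengths,
giving ~30% final TE content, the scale seen in lepidopteran assemblies).
Between the epochs every gap between adjacent old copies loses
Binomial(gap, δ(L)) bases with δ(L) = c·(L/Mb)^d clipped to [0,1]
(defaults c = 0.8, d = −0.5: δ ≈ 0.36 at 5 Mb falling to ≈ 0.15 at 30 Mb).
Deletion acts only on inter-TE unique sequence, never on TE bodies, so copy
counts stay interpretable; coordinates are re-laid and the realised
chromosome length is the initial length minus deleted bases (asserted in
tests). Divergences are drawn uniformly within each stratum and
floor-quantised to the 0.1% printed precision so no copy crosses the 5%
boundary in the written annotation. With d < 0 this produces, by
construction, higher final TE density and a higher young/old spacing ratio
on smaller chromosomes; with δ ≡ 0 and size-independent rates, correlation
signs are symmetric — both verified over hundreds of seeds in the test
suite.

The population generator writes an all-sites VCF over a generated (or
supplied) genome. Sites are independent — no linkage — because every
statistic consumed downstream (π, folded SFS, DFE) is a one-site functional;
this keeps generation linear in genome length but means the data contain no
LD structure, no linked selection and no correlated missingness, so passing
tests say nothing about those features of real data. Neutral sites (4D,
2-/3-fold, noncoding) segregate in sample frequency class i with probability
θ/i, which makes expected pairwise diversity exactly θ; 0-fold sites draw
their class from the DFE-integrated expectation. The drawn class already
describes the *sample*, so alternate alleles are assigned directly to
randomly chosen haplotypes; resampling genotypes binomially from i/n on top
would shrink expected diversity by (n−1)/n and break exact θ recovery.
Genotypes then go missing independently at a fixed rate (default 5%).
Divergence-vs-age is exact by construction (divergence is drawn, not
evolved); TE bodies are stamped from a small seeded motif catalogue with
point mutations at the annotated divergence, which supports parsing and GC
computation but is not a model of TE sequence evolution.

The fixture suite (three chromosomes of 120/80/50 kb, eight diploids, dense
gene content, deletion power law rescaled to sub-Mb lengths) exercises every
reader and writer deterministically: one seed reproduces every file byte for
byte. The seed drives the population sample while the landscape is fixed, so
VCF headers are identical across seeds and only genotype bodies differ;
seeds are recorded in the truth JSON and run metadata rather than in data
headers.

## Determinism and reports

All randomness flows through seeded `numpy` generators; report tables are
TSV with fixed float formatting, and provenance (config hash, seed, package
version) lives in a separate `run_metadata.json` so tables are
byte-reproducible run to run. Reports are plain TSV — figure styling is out
of scope. Pipeline correlation tables degrade gracefully: a statistic that
is constant or defined on fewer than three chromosomes yields a NaN row
(the strict library function still raises, per its contract).

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` run entirely on synthetic data
generated at call time: 20-chromosome genomes of 5–30 Mb for the mechanism
checks (hundreds of seeds), 100-window chromosomes for bootstrap
calibration (500 replicates), ≤2-kb full-call panels for the diversity
oracle, and 10⁶-site spectra for DFE recovery (tens of seeds). These sizes
were chosen so every check is a by-construction property of the method at
scales where Monte-Carlo error is well below the tested margins.

## Known limitations

- The spacing statistic treats the `.out` hits as given; fragmented hits of
  one insertion are separate records (mergeable upstream if desired).
- Divergence is used as printed, without CpG or Kimura correction.
- The DFE model has no beneficial mass and no explicit demography; r_i
  absorb demography only as class-wise distortions shared by the two site
  classes.
- π assumes genotypes are missing at random within a site.
- The generator's uniform placement has no insertion-site preference, no
  nesting structure beyond chance overlap, and its deletion acts between
  old-epoch copies only.
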