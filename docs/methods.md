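# Methods

## Data model

The panel holds 31 biallelic SNPs. Each `SnpDef` stores a canonical strand
with a `major_allele`/`minor_allele` pair taken from the allele-change
notation of the source catalogue tables, plus the catalogued gnomAD minor
allele frequency. Two caveats drive the design:

* **Strand.** The published genotype tables report several SNPs on the
  opposite strand to the catalogue rows (e.g. the A>C promoter variant
  tabulated as T/G genotypes). All input calls are normalized to the
  canonical strand on load: identity mapping is tried first, then the
  complement; calls fitting neither strand become missing and are counted.
  Normalization is idempotent. Report output can re-emit the published
  letters per SNP.
* **Allele orientation.** The "X > Y" notation of the catalogue is not
  consistently major > minor: for some common variants (MAF near 0.5) the
  catalogued minor allele is the first letter, and for others the cohort
  major allele differs from the gnomAD major allele — a normal situation
  across populations. Counting is therefore *category-matched*: frequencies
  and tests are computed per genotype category and compared by label, never
  by position, so orientation cannot corrupt results. One SNP (rs1137115)
  is shipped re-oriented (major=C, minor=T) because both the catalogued MAF
  and the cohort data identify T as the variant allele, and the star-allele
  config keys on the variant.

Missing data are handled by per-SNP complete-case exclusion: a subject
missing one SNP is dropped only from that SNP's statistics. This is the
standard convention for per-marker frequency tables.

## Contingency tests

`pearson_chi2` computes Σ(O−E)²/E on 2×k tables with df = k−1, applying
the Yates continuity correction (|O−E| reduced by 0.5, floored at 0) only
when k = 2 and requested. A zero expected cell raises with advice to use
an exact test. Tail probabilities come from `scipy.stats.chi2`.

`fisher_2x2` and `freeman_halton` are exact tests by full enumeration of
tables with the observed margins, summing the (multivariate)
hypergeometric probabilities of all tables no more probable than the
observed one. Log-gamma arithmetic avoids overflow; a relative tolerance
of 1e-9 on the probability comparison protects ties against float noise.
Freeman–Halton enumeration is limited to 2×2 and 2×3 with n ≤ 500; larger
tables are referred to the asymptotic test. In the test suite these
implementations are checked against independent oracles
(`scipy.stats.fisher_exact` and `scipy.stats.multivariate_hypergeom`),
never used as the implementation.

**Test-selection rule.** At the genotype level: if only one genotype
category occurs overall the SNP is flagged NS and not tested; if exactly
two categories occur (the situation "both groups show at most two
genotypes") the empty column is dropped and Fisher's exact test runs on
the 2×2; if three categories occur, Pearson's χ² (df = 2) is the default
and Freeman–Halton the `exact=True` alternative. At the allele level the
2×2 χ² carries the Yates correction by default; when an allele is absent
from one cohort only (zero expected cell) the code falls back to Fisher.

**Why Yates.** Recomputing the four internally consistent published
allele-level p-values (0.0437, 0.0499, 0.0009, 0.0589) matches the
corrected χ² to within 1e-4 and does not match the uncorrected one; the
uncorrected statistic stays available behind a flag. Genotype-level
published p-values are not all reproducible by any standard test we
tried (Pearson, Yates, exact); the concordance report therefore treats
them as soft diagnostics, printing published vs computed values with
deltas instead of asserting equality. Published "<0.0001" entries are
asserted as upper bounds only. One published bound (rs1800955 allele,
"<0.0001" next to 72.37% vs 65.43%) is arithmetically implausible and is
flagged as a suspected erratum, excluded from assertions. Three published
allele rows contradict their own genotype counts (rs1317286 e-Dec,
rs17408276 e-Dec, rs17486278 on-site — apparent row-copy errors); they
are compared and logged, never asserted. No multiple-testing correction
is applied, matching the original protocol; a Bonferroni column is
available opt-in.

## Exact Hardy-Weinberg test

Given genotype counts, the test conditions on the observed allele counts
and enumerates every compatible heterozygote count (same parity as the
rare-allele count), computing each configuration's probability from the
log-multinomial form; the two-sided p sums configurations no more probable
than the observed one. The test is exact and hence conservative: across
400 simulated SNPs (n = 100, MAF 0.3) it rejects about 2-4% at α = 0.05,
inside the binomial 3-SE band around the nominal rate.

## Metabolizer classification

The **minor-count rule** sums minor-allele dose over the five polymorphic
CYP2A6 SNPs. A subject with missing genotypes is unclassified only when
the missing data could change the class (observed dose and worst-case
dose straddle a boundary); a subject already at dose ≥ 2 stays slow.
Adding a minor allele can never move a subject toward normal (verified
exhaustively over all 3⁵ dose vectors).

The **allele-function rule** first calls unphased star-allele pairs: each
minor-allele copy at a defining SNP contributes one copy of its star
allele (multi-SNP definitions use the minimum dose across their SNPs),
remaining slots fill with \*1. Minor alleles at two different defining
SNPs are placed in trans — the parsimony assumption for unphased data —
configurable to "unclassified on ambiguity". Subjects with more star
allele copies than two haplotype slots are unclassified with a
diagnostic; so are carriers of unknown-function alleles. Function pairs
map to phenotypes exactly as catalogued: normal×normal → normal,
normal×decreased → intermediate, and any pair containing a
loss-of-function allele, or two decreased alleles, → slow.

The shipped SNP→star-allele config is a deliberate approximation: the
full published mapping diagram was never printed, so the config assigns
one defining SNP per allele, anchored where the residue change pins the
allele in the PharmVar catalogue (\*2, \*5, \*7, \*9, \*13, \*15, \*21)
and best-effort elsewhere; it is a YAML file intended to be edited when a
better mapping is available. The published headline group sizes
(19/39/48) require individual-level joint genotypes that were never
released and are not a reproduction target.

## Nonparametric comparisons and matching

Mann-Whitney U uses midranks for ties. Below 8 observations per group the
two-sided p comes from full enumeration of all C(n+m, n) group
assignments — cheap there and free of approximation; from 8 up, the
tie-corrected normal approximation with continuity correction
(`scipy.stats.mannwhitneyu`). Kruskal-Wallis is the tie-corrected H with
a χ² reference (df = k−1). Degenerate all-equal samples return p = 1 with
a warning.

Matching is greedy nearest-age within exact gender strata: reference
(e-Dec) subjects repeatedly pick their nearest-aged unmatched candidate
(ties broken by subject ID) until `round(ratio × n_ref)` candidates are
retained. The procedure is deterministic and never drops reference
subjects. Greedy matching is the simplest reproducible choice; optimal
matching is out of scope. Under a +4-year simulated age shift (SD 8) it
restores balance (post-matching rank-test p > 0.05) whenever the
imbalance was detectable pre-matching; under larger shifts the candidate
pool may simply lack young subjects and residual imbalance is reported,
not hidden — the balance report always carries post-matching age and
gender p-values.

## Synthetic data

`reconstruct_from_counts` rebuilds 132 individual genotype vectors from
the published per-SNP counts, filling each cohort block hom-major, het,
hom-minor in subject order. Re-counting reproduces every input count
exactly (the generator is a right inverse of the counter; fuzzed over
random valid specs in the tests). Because columns are reconstructed
independently, within-subject correlation across SNPs is an artifact of
the fill order: minor alleles pile up on the tail subjects of each
cohort. Marginal statistics (all frequency tables and per-SNP tests) are
exact; cross-SNP statistics (joint metabolizer doses) are *not* the real
cohort's and are reported as diagnostics only. This is the key limit on
what passing tests show about the real data.

`simulate_hwe_cohort` draws minor-allele doses binomial(2, MAF) i.i.d.
across subjects and SNPs — Hardy-Weinberg proportions with no LD, which
real CHRNA3/CHRNA5 data would violate. `simulate_demographics` draws
bounded variables from triangular distributions parameterized by the
published per-cohort medians and ranges (mode at the median; a `spread`
of 0 collapses to the median; onset age is clamped to current age). The
tobacco index is derived as cigarettes/day × years / 20 — a pack-years
convention for simulation only; observed data carry the index as given
because the original calculation was never specified. Note the published
ranges are wide and asymmetric, so the *means* of two triangular cohorts
can nearly coincide even when the target medians differ; power studies
therefore configure an explicit shift rather than relying on the default
cohort difference. The default generator seed is 20210619.

## Numerical conventions

* Percentages are exact fractions internally; the report layer rounds
  half-up to 2 decimals (the published style), with optional
  trailing-zero trimming ("73.4"). Published values that appear truncated
  rather than rounded (5.31 for 5.319) are absorbed by the ±0.01
  comparison tolerance.
* Exact-test tie comparison uses a 1e-9 relative tolerance; HWE
  enumeration 1e-12.
* All simulations take explicit integer seeds (`numpy.random.default_rng`);
  reruns at a fixed seed are bitwise identical.
* Test-suite problem sizes: Fisher oracle equality exhaustively over all
  2×2 tables with n ≤ 20 plus 300 random tables with n ≤ 40;
  Freeman–Halton on random 2×3 tables with n ≤ 60; HWE calibration over
  400 SNPs; Kruskal-Wallis power at group means (0, 1, 2)σ, n = 30, over
  200 replicates.

## Known limitations

* Diplotypes are unphased throughout; no liftover, imputation, LD or
  haplotype estimation.
* Copy-number CYP2A6 alleles (whole-gene deletion/duplication) are outside
  the SNP-only panel.
* The nicotine-metabolite ratio (3HC/COT) underlying the phenotype
  grouping is not modelled; the grouping is taken from the catalogued
  allele functions.
* FTND dependence scores are carried as opaque inputs when present; the
  instrument is not scored.
* Genotype-level published p-values that no standard test reproduces are
  reported as concordance diagnostics, not asserted (the original
  software's exact algorithm is unresolved).
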