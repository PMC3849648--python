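# Methods

## Model and procedure

Each candidate variant (chromosome, position, ref, alt — VCF 1-based
coordinates, used verbatim with no indel left-alignment, since forced
calls at a shared allele list already agree on representation) is
analyzed independently of all others.

For every sample's forced-call record the Phred-scaled genotype
likelihood ratio of "no variant" against "some variant" is

    PLR = -10 * log10( L(AA) / (L(AB) + L(BB)) ),  L(g) = 10^(-PL(g)/10)

computed entirely in the log domain (two-term log-sum-exp over the
denominator), so PL values in the thousands — routine in whole-genome
data, and far below the 1e-308 double underflow threshold on the linear
scale — cannot produce infinite ratios. PLR is invariant under a common
additive offset to the PL triple, so the caller's normalization
convention is irrelevant. Dividing by the raw depth DP gives PLRD, a
per-read evidence score: algebraically,

    PL(AA) - min(PL(AB), PL(BB)) <= PLR <= same + 10*log10(2),

so each reference-matching read at Q30 moves PLR by about -3.01 and each
alt read by about +31.8, which is where the -3 wild-type cluster and the
>10 heterozygote cluster come from.

Per site, background records are split by the GATK best-practice hard
filters, re-applied to the INFO annotations as a pure classification
step (SNV set: QD < 2.0, MQ < 40.0, FS > 60.0, HaplotypeScore > 13.0,
MQRankSum < -12.5, ReadPosRankSum < -8.0; indel set: QD < 2.0,
ReadPosRankSum < -20.0, FS > 200.0). Rules are strict inequalities;
values exactly at a threshold pass; a missing annotation never fails a
rule (the upstream caller only filters on annotations it computed). A
`--trust-filter-field` switch uses the VCF FILTER column verbatim
instead, for inputs whose FILTER column is known-consistent.

The failing (wild-type/non-variant) records — excluding unusable records
(missing PL or DP), depth-zero records, and confidently
homozygous-variant records — contribute their PLRD values to the
site-specific background distribution, summarized by median and
inter-quartile distance (IQD = Q3 - Q1, quartiles by linear
interpolation at positions p·(n-1) on the sorted values). 1.38·IQD
serves as a proxy for one standard deviation. The proband variant is
binned with strict inequalities, Bin 1/2 rules evaluated before Bin 3/4:

* Bin 1: PLRD > 10 and PLRD > median + 6 proxy SD (8.28·IQD)
* Bin 2: exactly one of the two conditions
* Bin 3: neither, but PLRD > median + 3 proxy SD (4.14·IQD)
* Bin 4: otherwise

A proband record whose homozygous-variant PL is strictly the smallest is
excluded before binning (`ExcludedHomozygous`, displayed at PLRD 0 by
convention); ties stay in the analysis. Ordered evaluation resolves the
textual overlap between the Bin-2 and Bin-3 regions in favor of Bin 2:
a variant above the evidence cutoff but inside the separation threshold
is uncertain, not presumed false.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `plrd_cutoff` | 10 | Phred per read | lower edge of the confident-het PLRD cluster |
| `sd_proxy_factor` | 1.38 | IQD per SD | the method's defining proxy constant, used verbatim (the Gaussian relation would give IQR/1.349; the stated constant defines the method) |
| `k_high`, `k_low` | 6, 3 | proxy SDs | Bin-1/2 and Bin-3/4 separation boundaries (8.28·IQD, 4.14·IQD) |
| `min_background` | 5 | samples | below this the IQD of the background is meaningless; the classifier refuses (`Unclassifiable`) rather than guesses. The study design this emulates used 38+ backgrounds |
| `min_depth` (screen) | 3, exclusive | reads | rare-candidate depth screen |
| `max_maf_1kg` / `max_maf_esp` | 0.03 / 0.02 | frequency | rarity screens; an absent frequency passes, since unknown variants are the rare case of interest |
| `max_families_with_variant` | 3 | families | variants in >3 unrelated background families are too common for a rare disorder |
| `low_depth_max` | 4 | reads | below this a family "wild type" may really be a no-call; mirrors the >3 screening depth |
| bias flags | FS>60, MQ<40, MQRankSum<-12.5, ReadPosRankSum<-8 | — | no separate bias limits exist in the method definition, so the flags reuse the hard-filter values; all overridable. BASEQUAL_BIAS is reserved: the consumed INFO set has no base-quality rank annotation |

## Synthetic cohorts

The generator emulates forced-call VCF output, not reads: per sample and
site, depth ~ Poisson(depth_mean), alt-read count ~ Binomial(depth,
alt_fraction), and diploid genotype likelihoods from a minimal
substitution model — P(match) = 1-e, P(specific mismatch) = e/3,
P(read|g) averaged over the two alleles of g — with e = 10^(-Q/10),
defaults 30x and Q30. True-het sites use alt_fraction 0.5 in the proband
only; systematic error-prone sites draw a latent alt fraction once per
site (mean 0.15, SD 0.05) shared by *all* samples with per-sample jitter
(SD 0.03) — the simplest mechanism for platform-consistent
sequence-specific error — and receive elevated FS and ReadPosRankSum
annotations with probability 0.9 per sample, so most error records fail
the hard filters and land in the background distribution, as in real
data. QD is synthesized as max(PLR,0)/DP, which makes clean wild-type
records fail the QD rule exactly as a forced-call emission would.

What the generator does not model: mapping-quality mixtures, alignment
and realignment artifacts, sequence-context error motifs, indel slippage,
GC/coverage bias, or contamination. Passing recovery tests therefore
show that the classifier separates the likelihood geometry it was
designed around; they do not certify performance on real alignments.

Under these study conditions (depth 30, Q30, 20 backgrounds, 200 sites)
the seeded recovery rates are: wild-type proband sites 100% Bin 4,
systematic-error sites ≥80% (measured 100%) in Bins 2-4, and true hets
~90% Bin 1 with the remainder Bin 2. The het rate is a property of the
read model itself, not of the classifier: a balanced het clears the +10
cutoff iff its alt-read fraction exceeds 0.374, and
P(Binomial(D, 0.5) > 0.374·D) over D ~ Poisson(30) is 0.915 exactly.
Higher depth or base quality moves it toward 1 (e.g. ~0.96 at 40x).
The near-cutoff misses are exactly the "uncertain" Bin-2 fringe the
method is designed to hand on for secondary review.

Problem sizes throughout the suite (200-site cohort, 20 backgrounds,
1e5-triple oracle sweeps) were chosen as the smallest sizes at which the
distributional assertions have comfortable statistical margins.

## Numerical choices and degenerate inputs

* Quartiles: numpy `method="linear"`; deterministic and
  permutation-invariant (the method definition names no quartile rule).
* IQD means Q3 - Q1, not the semi-interquartile range.
* Center statistic: median (not the mean).
* Depth 0: PLRD is an explicit undefined marker; the site reports
  `Unclassifiable`, never NaN arithmetic.
* All bin comparisons strict `>`; a PLRD exactly at 10 or at a threshold
  falls to the lower bin. Hard-filter equality passes.
* HOM_VAR requires PL(BB) strictly smallest; ties remain in analysis
  (conservative toward inspecting possible false positives).
* Degenerate background (IQD = 0): both thresholds collapse onto the
  median; any PLRD above max(10, median) is Bin 1, anything at or below
  the median is Bin 4.
* Missing PL/DP: record is unusable — excluded, counted, reported; never
  imputed. A background sample missing a site entirely is "absent",
  distinct from wild type, and surfaced in the missing-site counts.
* Multi-allelic records are decomposed per ALT using the VCF diploid PL
  ordering (genotype (j,k) at index k(k+1)/2 + j); PL triples are taken
  as given, with no re-normalization to a zero minimum.
* Simulated VCFs round PL to integers (the VCF convention); INFO floats
  are written at two decimals and compared at float32 precision on
  round-trip.

## Known limitations

* The hard-filter split is an imperfect proxy for true wild-type status;
  miscalled background variants leak across groups exactly as they do in
  the workflow this reimplements.
* Bins are discrete; no continuous score is produced.
* No gVCF, phased-genotype, structural-variant or multi-proband support;
  family structure is a flat role map.
* The screening step trusts the supplied allele-frequency table; no live
  database queries.
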