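# varbin

Per-site, cross-sample classification of true versus false-positive
variant calls in Illumina-style NGS data.

## The problem

Rare-disease variant discovery screens thousands to millions of candidate
variants down to a handful, and sequencing-chemistry and alignment errors
survive that screening disproportionately: sequence-specific errors (e.g.
after GG homopolymer motifs) recur at the *same position* in every sample
run on the same platform and chemistry, so they look like rare variants.
Genome-wide quality models (VQSR and the like) average over all sites and
miss such site-specific error structure.

`varbin` evaluates every candidate site individually against a panel of
locally sequenced background samples. The inputs are forced-genotyping
VCFs: the caller is made to emit genotype likelihoods (PL) and depth (DP)
at every candidate site in every sample, whether or not a variant would
have been called there (`varbin gatk-args` prints the caller settings
that produce such files).

## The statistic

For one sample at one site, with Phred-scaled genotype likelihoods
PL(AA) (homozygous reference), PL(AB) (heterozygous), PL(BB)
(homozygous variant):

```
PLR  = -10 * log10( L(AA) / (L(AB) + L(BB)) ),   L(g) = 10^(-PL(g)/10)
PLRD = PLR / DP
```

PLR grows linearly with coverage; dividing by raw depth DP gives a
per-read evidence score. Clean wild-type records cluster near **-3
PLRD** (each reference-matching read contributes about -3 Phred to the
ratio) and confident heterozygotes typically sit **above +10 PLRD**.
Error-prone sites drift upward and broaden — in every sample at once.

Per site, the background records that fail the GATK best-practice hard
filters (SNVs: QD < 2, MQ < 40, FS > 60, HaplotypeScore > 13,
MQRankSum < -12.5, ReadPosRankSum < -8; indels: QD < 2,
ReadPosRankSum < -20, FS > 200) form the wild-type/non-variant PLRD
distribution, summarized by its median and inter-quartile distance
(IQD, with 1.38·IQD as a proxy standard deviation). The proband variant
is then binned:

| Bin | rule | reading |
|-----|------|---------|
| 1 | PLRD > 10 **and** PLRD > median + 8.28·IQD | most likely true |
| 2 | exactly one of the two conditions | uncertain |
| 3 | neither, but PLRD > median + 4.14·IQD | likely false positive |
| 4 | PLRD ≤ median + 4.14·IQD | most likely false positive |

Confidently homozygous-variant records are excluded (reported as
`ExcludedHomozygous`, displayed at PLRD 0); sites with fewer than 5
usable background non-variants refuse to classify (`Unclassifiable`).
Cross-sample annotations (background variant counts and zygosity,
low-depth and strand/mapping/position bias flags), rare/de-novo
candidate screening (depth > 3, MAF < 3% in 1000 Genomes and < 2% in ESP
exomes, absent from family and from > 3 unrelated background families),
and false-negative flagging of family records that fail the filters but
bin as 1-2 are included.

## Worked example

Simulate a small forced-call cohort (3 true heterozygous sites, 2 clean
wild-type sites, 3 systematic error-prone sites; 20 background samples at
30x coverage, Q30 reads), then classify the proband:

```
$ varbin simulate --out-dir demo --seed 7 --n-background 20 --n-family 3 \
      --n-true-het 3 --n-wild-type 2 --n-systematic 3
seed 7: wrote 24 VCFs to demo

$ varbin classify --proband demo/proband.vcf \
      --backgrounds 'demo/background*.vcf' --family demo/family01.vcf \
      --out demo/report.tsv
classified 8 sites: Bin1=2, Bin2=1, Bin4=5
```

`demo/report.tsv` (abridged):

```
chrom  pos    ref alt proband_plrd  bg_median  bg_iqd   bg_n_wildtype bin   flags
1      10000  A   G   16.5625       -3         0        20            Bin1  .
1      10100  C   T   8.58333       -3         0        20            Bin2  .
1      10300  T   C   -3            -3         0        20            Bin4  .
1      10500  C   T   1.11905       0.357143   2.91685  20            Bin4  POSITION_BIAS,STRAND_BIAS
```

Reading the rows: the first site's proband PLRD (16.6) clears both the
+10 cutoff and the background separation threshold → Bin 1. The second
is a true het that drew an unlucky alt-read fraction (8.6 < 10) → Bin 2,
the uncertain class. The third is indistinguishable from its clean
background (-3 ≈ background median) → Bin 4. The last sits at an
error-prone site: the background non-variant distribution has drifted up
and broadened (median 0.36, IQD 2.9), the proband's weak positive score
is typical of that local error process, and the bias flags agree → Bin 4.

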