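# Methods

This note records the models, estimators and design choices behind
`tuberscan`, in the order the pipeline runs them.

## Synthetic panel

The generator emulates a structured diploid resequencing panel under
the Balding–Nichols model: each site draws an ancestral alternate
allele frequency p ~ Uniform(0.05, 0.95); each of K clusters (default
K = 3, 36 diploids each, approximating a ~107-diploid panel) draws its
own frequency from Beta(p(1−F)/F, (1−p)(1−F)/F), so the expected
between-cluster Fst tracks the divergence parameter F. Background
sites use F = 0.05; a configurable number of "selected" loci (default
90) use F = 0.4.

**Selected loci are planted as contiguous blocks** (default 3 blocks of
consecutive sites, ~30 sites ≈ 15 kb at the default site density of one
SNP per 500 bp). This is deliberate: a selective sweep elevates
divergence over a linked region, and a 50 kb window statistic averages
~100 sites — isolated divergent sites would be diluted below any
quantile cutoff and the window scan would (correctly) find nothing.
Block structure is what the windowed statistic is designed to detect.

Sequencing artefacts give the QC filters material to act on: per-call
depth ~ NegativeBinomial with mean 37 and dispersion r = 10 (matching a
typical ~37× short-read panel with realistic overdispersion), site
QUAL ~ Gamma(4, 150) with a 5 % low-quality fraction ~ Uniform(10, 30),
and 5 % of genotype calls missing at random. All randomness flows from
one integer seed through `numpy.random.default_rng`; a fixed seed gives
byte-identical VCF output.

Gene models are two-exon templates (5'UTR, CDS exon, intron, CDS exon,
3'UTR; CDS length 702 nt) whose open reading frame (ATG, sense codons,
stop) is written into the toy genome, on either strand. Of the pathway
genes, 100 carry an `ec_number` attribute drawn from a three-pathway EC
catalog and 48 carry none but share an orthogroup with an annotated
gene — so orthogroup expansion is expected to add exactly 48 %. One
annotated gene is *anchored* so that its splice-donor dinucleotide
covers a planted selected site; that site doubles as the default QTN,
giving one gene with both planted divergence and a phenotype effect —
the ground truth for the cross-reference stage. Reference alleles are
re-labelled from the generated genome after ORFs are written (allele
indices in the genotype matrix are positional, so no statistic
changes).

Phenotypes are additive: trait = baseline + Σ effect·dosage +
N(0, σ²e), with σ²e set so genetic/total variance equals the configured
narrow-sense h² **per single observation**; three replicates at each of
three locations are drawn i.i.d. (no location offsets, so the variance
partition is exact). Traits without a QTN are pure noise with a 5 % CV.
Expression tables carry three TPM replicates per sample per pathway
gene (lognormal baseline, 10 % replicate CV); carriers of the minor
allele at the planted expression SNP are shifted by a 4× fold change.

What the generator does **not** emulate — and therefore what passing
tests do not demonstrate about real data: linkage disequilibrium decay
(sites are exchangeable within blocks), polyploids, allele-frequency
ascertainment, depth-genotype error coupling, shared environment or
genotype×location interaction, and any realistic trait architecture
beyond a handful of additive QTNs.

## Variant QC and consequences

Filters follow the conventional resequencing gates: per-call depth
outside [10, 200] masks the call to missing *before* the call rate is
computed; sites with QUAL < 30 or call rate < 0.5 are dropped
(boundary inclusive, the source convention for `--max-missing`).
Population-genetic filtering keeps biallelic SNPs with MAF ≥ 0.01 on
non-missing alleles and thins greedily left-to-right at ≥ 10 bp. An
optional greedy r² pruner (window 50 kept sites, drop at r² > 0.1) is
provided but disabled by default — there is no canonical definition
for the corresponding flags in the source tool.

Consequence classes use a fixed category→impact table (premature
stop/lost stop/lost start/splice = HIGH; missense = MODERATE;
synonymous = LOW; everything else MODIFIER). Splice sites are the two
intronic bases adjacent to each exon boundary, strand-aware (donor at
the transcription-direction intron start, acceptor at its end) and take
precedence over coding annotation. Codon effects are evaluated on the
coding strand with the standard nuclear code; a CDS whose length is not
divisible by 3 triggers a warning and local-codon classification.
Up/downstream flanks are 5 kb (the usual annotation-tool default). The
"high impact" selection defaults to the protein-disrupting tier;
whether missense belongs in it is genuinely ambiguous in practice, so
it is a switch (`select_high_impact(..., impact_set=...)`), default
off.

## Selection scan

Per-site divergence uses the Weir & Cockerham (1984) two-level
estimator: with r = 2 populations of n_i called diploids, allele
frequencies p_i and observed heterozygosities h_i,

    a = (n̄/nc)[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²/2 − (2n̄−1)h̄/(4n̄)]
    c = h̄/2,          θ̂ = a/(a+b+c)

with sites monomorphic across both clusters, or with fewer than two
called genotypes in either cluster, excluded. Windows anchor at
position 1, advance by 10 kb, span 50 kb, and report the weighted
(ratio-of-sums) Fst Σa/Σ(a+b+c); windows with no variants are omitted
and a chromosome shorter than the window yields one truncated, flagged
window.

Window values are fitted per cluster pair by maximum likelihood with
four families — Weibull, normal, lognormal, gamma — each with k = 2
parameters (no location parameter; positive-support families are fitted
with the location pinned at zero). Non-positive window values are
excluded before fitting the positive-support families; the normal fit
uses all values. Normal and lognormal MLEs are closed-form; Weibull and
gamma use numerical MLE. AIC = 2k − 2logL selects the family, and the
outlier cutoff is that family's inverse CDF at q = 0.95 (comparison
inclusive). With fewer than 30 positive values the fit refuses and
advises an empirical quantile instead.

Genes overlapping any outlier window by ≥ 1 bp (1-based closed
intervals) are selection candidates. "Common regions" are the maximal
intervals covered by at least one outlier window from *every* pair:
per-pair window unions are intersected across pairs and touching
results merged. Term enrichment of candidate genes is a one-sided
hypergeometric tail with Benjamini–Hochberg adjustment across terms.

## Pathways

A pathway is a set of EC codes; dash-terminated codes (e.g. `2.4.1.-`)
match by prefix. Expansion adds every focal-species gene sharing an
orthogroup with a seed gene; added genes inherit the union of their
orthogroup's seed ECs and are labelled provenance "orthology"
("keyword" takes precedence for genes found both ways). Expansion is
anchored on focal-species seeds only: orthogroups whose only EC
evidence comes from another species do not recruit genes. Candidate
SNPs are high-impact consequences whose host gene is in the pathway set
and whose location lies in the transcribed unit (CDS, intron, UTRs —
not the flanks).

## Association

The marker test is a fixed-effect one-way GLM: per-location trait
values (replicates averaged per sample) on the genotype-class factor
(2–3 classes, empty classes dropped; a dosage-regression encoding is
available by flag), F-test p-value, retention at P ≤ 0.001, no
structure covariates and no multiple-testing correction beyond the
fixed gate (a BH option exists but is off) — matching common
candidate-gene practice. Tested SNPs must have MAF ≥ 0.05 (inclusive)
and missing rate < 20 % (strict) among phenotyped samples. A constant
response returns F = 0, p = 1.

Allele effects compare major-allele homozygotes against minor-allele
carriers with a two-tailed t-test; effect % = 100·(mean_minor −
mean_major)/|mean_major|, sign preserved. This definition is explicit
because "effect size as a percentage" has no single convention; it is
the package's choice and is configurable in interpretation (the group
means are also reported). Expression-by-allele averages the TPM
replicates per sample, reports log2(mean + 1) — a plain minus-log
transform would rank higher expression more negative, so the
positive-log form is used — and flags genes whose allele-group fold
change (larger mean over smaller) reaches 2×.

QTN labels are auto-assigned as q⟨TraitAbbrev⟩⟨chrom⟩.⟨rank⟩ (e.g.
`qSC10.1`), ranked by p-value within trait and chromosome.

## Colour indices

From CIELAB (L, a, b), with C = √(a²+b²) and h = atan2(b, a):
WI = 100 − √((100−L)² + a² + b²); YI = 142.86·b/L;
CIRG = (180 − h)/(L + C) with h unsigned in [0, 360);
BI = 100·(x − 0.31)/0.172, x = (a + 1.75L)/(5.645L + a − 3.012b);
HI is the hue angle, reported signed in (−180, 180] by default
(purple-fleshed tubers produce negative hue under this convention;
an unsigned [0, 360) option is provided — the two differ by a
deterministic 360° wrap). At L = 0, YI and BI are undefined and
returned as NaN with a warning. sRGB→Lab conversion (D65) is delegated
to scikit-image and cross-checked against the published transform in
the tests.

## Numerical and testing choices

Problem sizes were chosen so the full suite exercises every stage at
statistical power without heroic run times: the default panel is 2,400
sites × 108 samples on two 600 kb chromosomes (≈ 336 windows per
pair), the end-to-end recovery check averages 20 replicate scans, GLM
calibration uses 10,000 null markers, and family-recovery uses 100
datasets of n = 5,000 per family. Estimator equivalence checks run
against independently written scalar oracles (direct 1984 formulas;
whole-CDS re-translation; pairwise-mismatch π; brute-force interval
overlap; 2^k subset enumeration) at tolerances of 1e-12 where the
arithmetic is exact.

Known limitations: single-transcript gene models only (no isoforms),
SNP-only annotation (no indels/frameshifts), no kinship or structure
correction in the GLM (planted cluster-correlated QTNs therefore drag
linked divergent markers above the gate, visible as mild inflation when
scanning all SNPs — the candidate-gene design restricts testing to
pathway SNPs), and the parametric outlier cutoff inherits the usual
caveat that the best of four families may still fit the extreme tail
poorly.
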