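# Methods

This note documents the models, defaults and numerical choices behind
`epimem`: what the synthetic world simulates, how the statistics are
defined, and which design decisions were genuinely open.

## 1. The synthetic world

### Genome and annotation

The default genome is seven 300-kb "autosomes" plus one 30-kb chloroplast
contig (~2.13 Mb, ≈1.06 M cytosines over both strands, ≥10⁵ per context),
drawn i.i.d. uniform over ACGT. Per autosome: 60 genes (0.8–2 kb), 50
repetitive elements (REs, 0.3–1.5 kb) and 15 pseudogenes (0.6–1.2 kb),
placed uniformly with same-type non-overlap (bounded retries; a crowded
chromosome raises an explicit error). Different types may overlap, which is
what produces RE-inside-gene configurations. The chloroplast carries no
features and is exactly unmethylated — its only role is the non-conversion
control. The scale was chosen to keep every genome-wide statistic stable
at desk scale (one CPU, minutes), not to mimic a 240-Mb plant genome.

### Truth methylation

Each cytosine's baseline truth probability is

    p = base[context] · submult[trinucleotide] · shape(position) · renorm[context]

- `base` defaults to 0.55 / 0.32 / 0.06 (CGN/CHG/CHH).
- `submult` defaults to CCG → 0.8 (CCG suppression within CHG), else 1.
- `shape` is a piecewise-smooth multiplicative profile: genes have body
  multiplier 0.6 with half-cosine dips to 0.2 within 300 bp of TSS/TTS;
  REs a flat plateau ×1.6; pseudogenes edge peaks ×1.5 over 150 bp with
  body ×1.1. Overlapping features multiply. These shapes reproduce the
  qualitative metagene curves (TSS/TTS dips, RE-body plateau, pseudogene
  edge peaks) with few parameters — no published generative model exists
  for them.
- `renorm` rescales the shape field to site-weighted mean 1 per context
  class (chloroplast excluded), so configured base levels ARE genome-wide
  weighted levels. Subcontext multipliers are deliberately *not*
  renormalized, keeping the exact arithmetic `p = base × submult` on flat
  landscapes; the CHG base of 0.32 with CCG×0.8 therefore lands the
  genome-wide CHG mean at 0.32·(2+0.8)/3 ≈ 0.299. A consequence of
  renormalization is that truth probabilities are a *global* property of
  the scenario: adding a feature changes all sites of the context by a
  common scalar. We accept this for the closed testing loop it buys.

Final probabilities are clipped to [0,1]; at the defaults nothing clips
(the largest product is ≈0.9), so additive treatment shifts are preserved
exactly in the genome-wide mean.

### Treatment, planted DMRs, peak fixture

The warm (28 °C) condition adds per-context global shifts — defaults
+0.04 / +0.05 / +0.01, the reported magnitudes for the most responsive
ecotype — plus planted DMR intervals (default +0.4 over a few hundred bp,
context CHG) and an optional peak fixture: eight designated 50-kb windows
(two each on four autosomes) that receive 12 planted 400-bp clusters
spaced 3.5 kb apart, in every group. Twelve clusters per window clears the
peak floor of 10 with margin; 3.5-kb spacing keeps clusters from merging
across the 250-bp rule. Groups are exchangeable by default; a per-group
scale on the warm response is available but uncalibrated (the study's
per-ecotype baseline differences are not modelled).

The peak-fixture scenario zeroes the global shifts. This is deliberate: a
genome-wide shift makes *every* cytosine weakly differential, and at
~200 k CHG sites the empirical-FDR threshold then admits thousands of
scattered true-but-weak calls that blanket all windows with DMRs. The
fixture isolates what the peak analysis is about — regional clustering of
strong differential methylation against a quiet background.

### Sequencing and expression counts

Coverage is negative binomial with mean 30 and shape 10 (variance
30 + 90 = 120), reflecting over-dispersed WGBS depth. Methylated counts
are Binomial(cov, p·(1−ε_under) + (1−p)·ε) with ε = 0.005 and
ε_under = 0 by default — the chloroplast control only constrains
false-methylation, so under-conversion is off unless configured.
Chloroplast sites therefore read at ε. The observed genome-wide level sits
(1−p)·ε above truth (e.g. 6.47 % observed for 6 % CHH truth); all
recovery tolerances account for this analytically.

Expression: per-gene NB counts, baseline mean 150, dispersion 0.05. Genes
with an RE within 2 kb (boundary-to-boundary, 0 if overlapping) have their
mean multiplied by the repression factor (default 0.5) in both conditions.
A DE fraction (default 0.2) of genes responds to temperature with signed
log2 fold changes drawn uniform from ±[1,2]; a coupling fraction (default
0.6) of those is drawn preferentially from genes whose promoter/body holds
a planted DMR — the mechanism that produces DEDMG enrichment. Seeds for
every stream derive from SHA-256 of (master seed, stream name, sample id),
so outputs are pure functions of (scenario, seed).

### What the generator does not emulate

Read-level artifacts (mapping bias, duplicates, M-bias), epiallele
structure, per-ecotype baseline methylomes, biological replicate variance
beyond binomial sampling, DMR length/effect distributions of real data,
and any sequence preference of the methylation machinery. Passing tests
demonstrate that the *pipeline recovers planted structure under its own
stated sampling model* — not that it would behave identically on real
WGBS data.

## 2. Statistics

### Contexts and levels

Context classification reads the trinucleotide 5′→3′ on the cytosine's
strand: CGN if the next base is G, else CHG if the base after is G, else
CHH. Sites whose trinucleotide runs off a chromosome end are flagged and
excluded from subcontext summaries only. All levels are weighted
(pooled-read) ratios, never means of per-site fractions, so they are
invariant to splitting/merging of region sets. Zero pooled coverage is
reported as NaN (undefined), never 0. Internally all coordinates are
0-based half-open; on-disk allc/GFF3 are 1-based inclusive and BED is
0-based half-open, converted only in `epimem.io`.

### DMS calling

`filter_sites` keeps sites of the requested context with pooled coverage
Σnᵢ ≥ 30 across the contrast's samples and ≥1 read in every sample —
per-sample ≥30 at ~30× data would discard nearly everything. The RMS
statistic is computed on the two *group-pooled* count units by default:

    d = sqrt( (1/2) Σ_g (m_g/n_g − p̄)² ),  p̄ = Σm/Σn .

An all-sample heterogeneity variant (each replicate its own unit) is
available via `heterogeneity=True`. The contrast form is the default
because, at 3 vs 3 replicates and 30×, per-replicate binomial noise
dominates the per-sample statistic: we measured that no threshold reaches
an empirical FDR of 0.003 with nonzero power under the per-sample form,
while the contrast form achieves FDP ≈ 0.002 with power ≈ 0.6 at a +0.3
methylation difference.

The null is a parametric bootstrap: B = 1000 replicates of
m* ~ Binomial(n, p̄) per unit. Per-site permutation p-values are
(1 + #{d* ≥ d})/(B+1). For genome-wide calling the null statistics are
pooled across sites within a context and the empirical FDR at threshold t
is (mean null exceedances per replicate)/(observed exceedances); the
caller takes the smallest t with eFDR(t) ≤ 0.003, evaluated exactly on a
2048-point grid over the observed range (observed d are floats; the grid
caps the cost of exceedance counting at no practical loss — the grid
resolution is ~1.5·10⁻⁴ in d). Sites tied with the threshold are included.
Per-site BH on permutation p-values is retained behind `pooled_null=False`
but cannot operate at q = 0.003 with B = 1000 over ≥20 k sites, since
min p = 1/(B+1) already exceeds the BH cutoffs.

Direction (hyper/hypo at warm) comes from pooled group levels. Merging is
greedy left-to-right within context and direction with inter-site distance
≤250 bp (inclusive); a DMR spans first to last member cytosine, and every
called DMS belongs to exactly one DMR.

### Integration

DMR midpoints annotate against gene zones with category precedence
promoter > gene body > downstream across genes (|TSS distance| then
lexicographic gene id break ties), guaranteeing the partition property. The
promoter is 2 kb (`--promoter-len`); the flank convention of the metagene
profiles, since no published value exists for this analysis. DMG sets are
per context with an any-context union.

TMM follows the standard recipe: upper-quartile-nearest reference, M/A
over genes positive in both, 30 %/5 % double trimming, inverse-variance
weights, geometric-mean-one factors. The DE engine is deliberately simple:
effective libraries = TMM × depth, MoM NB dispersion per gene floored at
10⁻⁸ and shrunk 50/50 toward a 10 %-trimmed trend across 20
abundance bins, delta-method SE of log2FC, Wald statistic. The statistic
is referred to a t distribution with 3×(n₁+n₂−2) df: the naive normal
reference is anti-conservative (≈0.07 at nominal 0.05 for 3 vs 3) and the
residual-df t over-corrects (≈0.01); the factor 3 — consistent with the
shrinkage borrowing roughly two extra replicates' worth of information per
gene — puts the null rejection rate at 0.049 ± 0.004 in calibration
simulations at the default design. Calibration (type-I error, recovery of
planted fold changes), not agreement with any specific GLM tool, is this
engine's contract.

Overlap statistics use the upper-tail hypergeometric (identical to
one-tailed Fisher on the 2×2 table) with RF = O·N/(n_A·n_B). The
enrichment universe is the genes that passed DE testing, not all annotated
genes, to avoid inflating RF; DMGs outside the universe are dropped before
testing. The DEDMG share is reported as O/n_DMG (fraction of DMGs that
respond in expression).

### Landscape

DMR density assigns each DMR's midpoint to its half-open 50-kb window.
A window is a peak when its count ≥ max(floor = 10, the group's 0.99
quantile of nonzero counts); `quantile=None` gives the floor-only rule
used with the planted fixture, where the quantile is meaningless because
the fixture pins the scale. Shared peaks are peaks in every group, so
adding a group can only shrink the shared set. Feature densities are
union-covered bp per window / window size. The methylation regression is
OLS per context over windows with defined levels; condition numbers >10⁸
flag collinearity. On the default synthetic landscape the fits are much
tighter (R² ≈ 0.95) than on real data, because the truth really is a
feature-driven multiplicative field.

RE proximity uses boundary-to-boundary distances with right-closed edges
(exactly 2000 bp → "within 2 kb"). Games–Howell: Welch t and
Welch–Satterthwaite df per pair, p from the studentized range at
q = |t|·√2 with k groups (scipy's CDF, abs. tolerance ~10⁻⁸); degenerate
zero-variance pairs return p = 1 (equal means) or 0 (unequal). PCA is a
centered SVD of the sample × window matrix with NaN windows dropped.

## 3. Problem sizes and defaults

| quantity | default | note |
|---|---|---|
| genome | 7×300 kb + 30 kb chloroplast | ~1.06 M cytosines |
| coverage | NB(mean 30, shape 10) | ε = 0.005 |
| design | 4 groups × 2 conditions × 3 reps | ≥2 reps enforced |
| DMS test | pooled cov ≥ 30, B = 1000, eFDR 0.003 | contrast units |
| merge gap | 250 bp | inclusive |
| windows | 50 kb | half-open |
| metagene | 20 body bins, ±2 kb flanks in 100-bp bins | pooled reads |
| promoter | 2 kb | annotation + DMG |
| DEG | p ≤ 0.05, \|FC\| ≥ 1.5 | padj / 2.0-fold presets available |
| proximity | ≤2 kb / 2–5 kb / 5–10 kb / none ≤10 kb | right-closed |
| peaks | floor 10, quantile 0.99 (or None) | shared = all groups |

The calibration experiment (20 replicates of 20 000 sites) and the
four-group peak fixture run in minutes on one CPU; these sizes were chosen
so that the binomial/permutation Monte-Carlo error is small relative to
every asserted tolerance.

## 4. Known limitations

- The metagene profiles pool reads across features; whether the original
  analyses pooled or averaged per-feature levels is unknown, and the two
  differ when coverage correlates with feature length.
- The RMS permutation test models binomial sampling only; overdispersion
  between biological replicates within a condition would inflate the
  contrast statistic and is not captured (the heterogeneity variant
  exists partly to probe this).
- DEDMG enrichment in the generator arises solely through the planted
  coupling; no causal methylation→expression model is implied.
- The Games–Howell p-value uses the studentized-range approximation
  standard for this test; at very small n (<5 per group) it is
  approximate, and the test suite checks agreement with an independent
  implementation rather than exactness.
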