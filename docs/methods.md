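# Methods

`isgland` implements the computational skeleton of an interferon-stimulated
gene (ISG) landscape analysis: how the set of genes induced by type I
interferon (IFN) expands when the negative regulator USP18 is removed, which
of those genes are "typical" versus "atypical" ISGs, and how the change is
reflected in regulatory chromatin. Because the analysis is exercised on
synthetic data with planted ground truth, every stage can be scored exactly;
this note records the models, the defaults and the design choices, and what
the synthetic benchmarks do and do not establish about real data.

## 1. Differential expression model

Counts are modelled as negative binomial (NB) with the mean/dispersion
parameterisation

    Var(Y) = mu + alpha * mu^2,

where `alpha` is the per-gene dispersion. The design is the 2x2 factorial
genotype (WT, KO) x treatment (untreated, IFN); analysis proceeds by
pairwise condition contrasts rather than a GLM with interaction terms. The
four canonical contrasts are

    C1 = WT+IFN  vs WT        (IFN response of the wild type)
    C2 = KO+IFN  vs KO        (IFN response of the knockout)
    C3 = KO+IFN  vs WT+IFN    (knockout-specific IFN response)
    C4 = KO      vs WT        (baseline shift of the knockout)

**Normalisation.** Median-of-ratios size factors: for each sample, the
median over reference genes (genes with a nonzero count in every sample) of
`count / geometric mean across samples`, rescaled so the factors have
geometric mean 1. Note that with strongly asymmetric differential
expression (many genes up in one condition, few down) the median ratio
itself shifts, biasing all log fold changes slightly toward zero. This
composition bias is a property of ratio-based normalisation in general; at
the ~20% responsive-gene fraction used by the default scenario it costs
roughly 0.05-0.1 of a log2 unit.

**Dispersion.** Per-gene method of moments: within each condition with at
least two replicates, `alpha_c = (var_c - mean_c) / mean_c^2` on normalised
counts; the per-condition estimates are pooled with `(n_c - 1)` weights and
clipped below at `1e-8`. Moments are taken per condition, not against the
grand mean: a grand-mean formulation inflates `alpha` for exactly the genes
whose condition means truly differ, which penalises the genes one is trying
to detect. No trend fitting and no shrinkage toward a prior is performed —
the estimator is honest but noisy at small replicate numbers (with 3
replicates per condition it has ~8 degrees of freedom per gene).

**Wald test.** For a contrast with group means `m1, m2` (normalised, with a
pseudo-mean `c = 0.5` added to keep zeros finite):

    log2FC = log2((m1 + c) / (m2 + c))
    se^2   = (1/ln 2)^2 * sum_g (mu_g + alpha mu_g^2) / (n_g mu_g^2)
    z      = log2FC / se,  p = two-sided normal tail

Genes with zero counts in all samples of both groups are excluded from the
test and from the multiple-testing family. p-values are adjusted by the
Benjamini-Hochberg step-up, implemented directly (sort, `p_(i) m/i`,
monotonise from the largest rank, cap at 1) and cross-checked against
statsmodels in the tests.

*Calibration caveat.* The Wald z is well calibrated when `alpha` is known:
in the all-null benchmark (20,000 genes, 3 vs 3, `alpha = 0.1`) the raw
p < 0.05 fraction is ~0.049. When the per-gene method-of-moments estimate is
plugged in at n = 3 the test becomes anticonservative (empirically ~0.12 at
nominal 0.05), because a normal test with an 8-df variance estimate behaves
like a t-statistic treated as z. The calibration benchmark therefore
evaluates the statistic at the simulation's dispersion; analyses of real
small-n data should treat raw p-values from the plug-in estimator as
optimistic. This is precisely the problem that dispersion shrinkage in
dedicated DE tools exists to solve, and such shrinkage is deliberately out
of scope here.

**Regulation calls.** `up` requires `log2FC > lfc_min` *and* the p
criterion, both strict; `down` is symmetric. Two threshold styles are
supported: raw `p < 0.005` with `log2FC > 1` (heatmap) or `> 0.5` (volcano),
and the classifier default `padj < 0.05` with `log2FC > 1`.

## 2. ISG taxonomy

Given boolean up-calls for the four contrasts (with all four computed at the
same thresholds, and "not upregulated" read as the set complement of the
up-call, not as a demonstrated non-change):

    typical   <=>  up(C1) and up(C2)
    atypical  <=>  up(C2) and not up(C1)
    cluster A <=>  up(C1) and up(C2) and not up(C4)
    cluster D <=>  up(C3) and up(C2) and not up(C1) and not up(C4)

Clusters B and C are intentionally not assigned (they have no published
definition). Cluster D is a subset of the atypical set by construction.

Atypical ISGs are subdivided using two evidence sources: membership in a
known-ISG reference list (emulating an Interferome-style lookup; the list is
a plain-text user input because the original query parameters are not
recoverable) and ISRE/STAT1 evidence in the gene's regulatory regions,
implemented as an ISRE-or-GAS motif hit in the gene's promoter sequence with
an optional user-supplied binding-evidence flag OR-ed in:

    reported      = atypical and in the reference list
    hidden        = atypical, not reported, motif evidence present
    noncanonical  = atypical, not reported, no motif evidence

An atypical gene with no motif data is left `unassigned` with a warning
rather than silently classified.

## 3. Motif models and scanning

Four motif models ship with the package. The ISRE, GAS and NF-kB matrices
are synthetic position frequency matrices built around the canonical
consensus families (AGTTTCNNTTTC, TTCNNNGAA, GGGRNNYYCC); they are *not*
measured matrices from a curated database, and users can substitute
JASPAR-format files. The interferon-response core element IRE is the exact
4-mer `TTTC`, matched as a string on both strands, because a 4-mer PWM at
any usable threshold degenerates to string matching.

PWM scoring is log-odds in bits against a uniform background
(`sum_j log2(p[base_j, j] / 0.25)`), with a 0.01 pseudocount per cell before
normalisation; `N` bases contribute 0 bits; ambiguity codes other than `N`
are rejected. A window is a hit when its score reaches 0.8 x the maximum
achievable score (configurable). Scanning covers the forward strand and the
reverse complement, with reverse-strand hits reported in forward
coordinates; scanning a sequence and its reverse complement yields
mirror-image hit sets. Planting in the simulator uses each motif's
consensus (the per-column argmax), which scores exactly the maximum, so
planted instances are recovered deterministically at any threshold <= 1.

**Enrichment.** For each motif, foreground regions (>= 1 hit) versus a
background superset are tested with the two-tailed hypergeometric test under
the minimum-likelihood rule: `p = sum of P(X = x)` over the support for
every `x` with `P(X = x) <= P(X = k)`. Point probabilities are compared in
exact integer arithmetic (`C(K,x) C(N-K,n-x)` as Python integers) so ties
resolve exactly; the tests verify agreement with an independent
rational-arithmetic enumeration to 1e-12 across an `N <= 60` grid. A
one-sided upper-tail mode is also exposed. BH adjustment is applied across
the motif set. Fold enrichment is `(k/n)/(K/N)`.

## 4. Regulatory peaks

Peaks are 0-based half-open intervals with a summit (midpoint when absent).
Conventions, each of which the underlying publication-style pipeline leaves
open and which are fixed here deterministically:

- TSS distance is measured summit-to-TSS (not edge-to-TSS), signed in the
  gene's frame: negative always means upstream of the gene.
- Equidistant TSS ties break to the lexicographically smaller gene id.
- Promoter-proximal means `|distance| <= 3000` bp, boundary inclusive
  ("within 3000 bp" read inclusively); proximal peaks are excluded before
  differential testing.
- Histone signal is quantified in the half-open 1000-bp window
  `[summit - 500, summit + 500)`; for motif work the windows are "shifted
  back" to the original peak intervals — the two interval sets are kept as
  explicit separate bookkeeping.
- Peaks on chromosomes absent from the TSS table are flagged and excluded
  downstream with a warning rather than guessed.

Differential regions reuse the NB machinery on the peak x sample tag-count
table; significance requires `|log2FC| > 1` (fold change > 2, strict) and
`padj < 0.05`. The scatter table behind the fold-change plot (normalised
mean per condition, > 2-fold flag) is emitted alongside. Enrichment
foreground is the significant regions in the requested direction; background
is all tested regions.

## 5. Synthetic data generator

The generator emulates the *statistical* structure the pipeline assumes and
nothing more. Per gene class (fractions of `n_genes`; the remainder are
null):

| class                  | fraction | log2 effect | where                      |
|------------------------|----------|-------------|----------------------------|
| typical                | 0.07     | 2.0         | +IFN, both genotypes       |
| atypical_hidden        | 0.055    | 2.0         | +IFN, KO only              |
| atypical_noncanonical  | 0.04     | 2.0         | +IFN, KO only              |
| constitutive           | 0.04     | 1.5         | KO, both treatments        |
| null                   | 0.765    | 0           | —                          |

The typical:atypical ratio (0.07 : 0.095) mirrors the observed landscape
(~448 typical vs ~605 atypical genes), with ~20% of genes responsive
overall — enough planted genes at the default 2,000-gene scale for stable
recovery statistics while keeping the composition bias of ratio
normalisation modest. Baselines are log-uniform on [20, 2000]; library
size factors are log-normal (sigma 0.2, geometric mean 1) unless supplied;
counts are NB with the same `mu + alpha mu^2` law the DE stage assumes
(`alpha = 0.1` by default, Poisson at 0), with n = 3 replicates per
condition. Effect sizes are scenario parameters, not estimates of the real
effect-size distribution, which is unknown.

Promoters are i.i.d. uniform A/C/G/T (no GC skew, no repeats) of length
1000 with consensus motif instances planted at uniform non-overlapping
positions on a random strand: hidden atypical genes always receive an ISRE,
non-canonical atypical genes never receive ISRE or GAS (enforced at config
validation; they may receive NF-kB), typical genes receive an ISRE at rate
0.9, and null promoters receive NF-kB at rate 0.1 so motif presence is not
trivially class-separating. Spontaneous background hits are possible and
intentionally uncorrected.

The known-ISG reference lists every typical gene plus an independent
`reported_fraction` (default 0.43, echoing the observed 262-of-605 reported
split) of atypical genes.

Peaks (default 2,000) sit on one synthetic chromosome with TSSs every
50 kb; each peak's signed TSS distance is uniform on [-20000, 20000]
(~15% proximal), width 200 bp. A `peak_diff_fraction = 0.15` subset gets a
true fold change of 4 in the second condition (duplicates per condition,
`alpha = 0.05`, matching an ATAC-style duplicate design). The genome is
uniform-random background with the ISRE consensus written at the summit of
every true-differential peak, giving enrichment a planted positive.

Determinism: all draws derive from `numpy.random.default_rng([seed,
stream])` with a fixed stream per generator function, so identical configs
produce byte-identical outputs; the tests assert this.

**What passing does not show.** The generator matches the DE model exactly
(no outliers, no GC or length effects, no correlated genes, no unmodelled
batch structure), promoters are compositionally unrealistic, and planted
motifs are exact consensus sites. Recovery at >= 0.9 here therefore
demonstrates internal consistency of the pipeline, not expected performance
on real sequencing data, where dispersion trends, composition shifts and
degenerate motif instances all bite harder.

## 6. Benchmarks and problem sizes

The planted-truth benchmarks (`isgland.evaluation`, driver
`analysis/06_planted_truth_benchmarks.py`, reproduction script
`scripts/acceptance.py`) use: 20,000 genes for null calibration; 2,000
genes for end-to-end class recovery; 300 promoters x 4 motifs (1,200
planted instances) for the scan round trip; 1,000 random peaks against 60
TSSs for the nearest-TSS oracle; 2,000 peaks for differential-region
recovery and enrichment. These sizes give binomial standard errors well
below the margins being tested while keeping a full run in seconds.

## 7. Assay formulas

Two closed-form assay conversions are included for completeness of the
study's quantitative methods: LDH-release cytotoxicity,
`100 x (OD_treated - OD_spontaneous) / (OD_maximum - OD_spontaneous)`
(undefined when maximum <= spontaneous; values outside [0, 100] are
reported as-is), and caliper tumor volume `L x W^2 x 0.5` in mm^3 with
explicit mm/cm unit tagging (2 cm x 2 cm gives 4000 mm^3).

## 8. Known limitations

- No dispersion or LFC shrinkage, no independent filtering, no outlier
  handling: small-n raw p-values are optimistic (see §1).
- Median-of-ratios composition bias under asymmetric DE is not corrected.
- Bundled PFMs are consensus-derived placeholders, not measured matrices.
- The classifier's "STAT1 binding data" evidence channel is a user-supplied
  flag file; no ChIP data retrieval is attempted.
- Cluster B/C of the expression heatmap are undefined and unassigned.
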