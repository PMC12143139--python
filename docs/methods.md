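# Methods

## The analysis model

XCI erosion is the progressive, culture-acquired reactivation of genes on
the inactive X (Xi) after loss of XIST in primed female pluripotent cells.
The pipeline treats erosion as a property observable on three scales:

1. **Chromosome scale** — the X:autosome ratio of raw summed RNA-seq
   counts. Because the active X (Xa) output is shared by all lines, any
   extra output from the eroding Xi raises this ratio; it is computed on
   raw counts (the ratio itself cancels sequencing depth), with Y and MT
   genes excluded from both sums and an optional flag to exclude XIST
   itself (its count falls with erosion while the rest of the X rises).
2. **Allele scale** — per-gene haplotype read counts, summarized by the
   minor allele frequency MAF = min(a, b)/(a + b). A fully silenced gene is
   monoallelic (MAF near 0), a fully reactivated gene balanced (0.5).
   Classes: monoallelic MAF ≤ 0.10, biallelic MAF ≥ 0.40, intermediate in
   between, undetermined below 10 reads. The literature states both
   inclusive and strict boundary conventions; the inclusive one is the
   default and a `inclusive=False` switch gives the strict reading. The
   depth filter is applied to the gene-level (summed) counts, since
   classification operates on the gene MAF.
3. **Gene-population scale** — differential expression of XIST− lines
   against XIST+ controls, condensed into the five-way consistency
   categorization (below), crossed with reference XCI status and with the
   candidate predictors of reactivation.

## Haplotype handling

SNP-level counts are stored in REF/ALT orientation; phase (which allele
sits on which haplotype) comes from the phased VCF and is applied during
aggregation. When phase is absent, `phase_by_concordance` assigns the
larger pooled count of each SNP to haplotype A — a deliberate, simple
stand-in for read-backed phasing that is deterministic (ties go to the
lexicographically smaller allele) and exact whenever one haplotype
dominates within a gene. It will co-phase incorrectly for genes that are
truly balanced, where the MAF is insensitive to phase anyway. Replicates
of a line are pooled by summing haplotype counts before computing the line
MAF, so deep replicates dominate, as pooled reads would.

## Eroded-gene calls and persistence

Within an isogenic pair (same genome, different XIST status), a gene is
called eroded when MAF(test) − MAF(reference) ≥ 0.10. The threshold is the
absolute MAF difference, not a relative change — matching the MAF scale on
which the classes are defined — and is a parameter. No per-gene test is
attached (the cutoff is the definition). The same pairing logic compares
two states of one line (e.g. pluripotent vs differentiated) and flags
class changes.

## The DE stand-in

The DE stage is deliberately minimal and documented as such; it is not a
re-implementation of a full DE tool (no outlier handling, no independent
filtering, no logFC shrinkage), so gene counts on real data will not match
such tools at equality:

* size factors: median over all-positive genes of count/geometric mean;
* per-gene dispersion by method of moments on normalized counts, clipped
  to [1e-8, 10], then shrunk 50/50 toward a trend α(μ) = a₀ + a₁/μ fitted
  across genes by least squares (coefficients clipped non-negative);
* Wald statistic on β = ln(q₁/q₀) of group means of normalized counts,
  delta-method variance Var(β) = Σ_k (q_k⁻¹ c_k + α)/n_k with c_k the mean
  reciprocal size factor, a half-count stabilizer when a group mean is 0;
* two-sided p from a Student-t with 3·(n₀+n₁−2) df. The trend-shrunk
  dispersion carries information beyond the per-gene residual df, so the
  plain normal reference is slightly anti-conservative in the far tail at
  n = 3 + 3, and t(n−2) is far too heavy; the moderated reference (spirit
  of empirical-Bayes moderated t statistics) keeps both the 5% level
  (measured type-I ≈ 0.04) and BH false-discovery control (measured FDR
  ≈ 0.03 at nominal 0.05) calibrated, and converges to the normal as
  replication grows;
* BH step-up adjustment within each contrast; calls require adjusted
  p < 0.05 and |log2FC| > 0.33 (strict inequality).

**Categorization.** For each gene, a test line "counts as up" only when
the gene is called up against *every* control line (same for down). With
U up-lines and D down-lines among the four test lines: U ≥ 3 and D = 0 →
consistently up; U ∈ {1,2} and D = 0 → sporadically up; symmetric for
down; everything else — including cross-line conflicts (U > 0 and D > 0)
and within-line control conflicts — is unchanged (the conservative
reading). The expressed-gene universe defaults to mean TPM ≥ 1 across all
samples, a documented guess since no cutoff is standard; it is applied
before DE and categorization.

## Predictor features

* **Distance to the nearest upregulated escapee** (reference-escape genes
  in the consistently/sporadically-up categories): interval gap on 0-based
  half-open coordinates, 0 for overlap or bookending (a one-off divergence
  from some interval tools; immaterial for the rank tests used on it).
  Strand is ignored for distances.
* **Metagene H3K27me3**: gene bodies linearly rescaled to 5 kb and binned
  at 1 kb together with 5 kb real-coordinate flanks; each bin is the
  coverage-weighted mean of track values, uncovered bases counting as 0;
  minus-strand genes are flipped so profiles read 5′→3′. The flank length
  is configurable (unstated in the source ecosystem's defaults).
* **Promoter methylation**: mean β over [TSS − 1 kb, TSS + 1 kb) with the
  strand-aware TSS; Δβ = β(XIST+) − β(XIST−).
* Category contrasts: Mann-Whitney (midranks; exact enumeration when
  n_x·n_y ≤ 400 and tie-free, else tie-corrected normal) for distances,
  unpaired t for signal and methylation, Cohen's d (pooled SD) for every
  pair; degenerate groups yield NA rows rather than errors.

## UMI amplicon pipeline

Reads carry an 8-nt UMI followed by the template; amplicons are assigned
by exact primer-prefix match (a desk-scale stand-in for alignment — reads
with primer-spanning indels would be unassigned and are counted). Exact
dedup counts distinct (UMI, allele) pairs. Directional dedup clusters UMIs
per amplicon: u merges into a more abundant v when Hamming(u, v) = 1 and
reads(v) ≥ 2·reads(u) − 1, connected components collapse to one molecule
each, and the component's allele is the read majority (tie → the
most-read UMI's majority). Directional mode can also merge genuinely
adjacent real UMI pairs — an inherent ~1–2% undercount at 100 molecules
per amplicon with an 8-nt UMI (expected C(n,2)·24/4⁸ adjacent pairs) —
which is why exact mode is the default and directional is offered for
error tolerance. Reads whose interrogated base matches neither allele are
reported as "other" and excluded from MAF.

## The synthetic-data generator

The generator emulates the statistical structure of a clonal female hiPSC
erosion experiment; defaults are the study conditions.

* **Design**: six lines — two XIST+ references (erosion degree e = 0) and
  four XIST− lines at e = (0.55, 0.70, 0.85, 0.95) — each in triplicate;
  600 X-linked plus 2000 autosomal genes. Under the emitted XIST model
  (level = max·(1 − e)), a line that has lost XIST necessarily carries
  substantial erosion, hence the XIST− degrees; their spread reproduces
  the heterogeneous per-line ordering the analysis must recover.
* **Status composition**: 15% escapees, 10% variable, 75% inactive.
* **Susceptibility**: s = logistic(−2.5 + 1.0·band + 1.0·K27-domain +
  2.0·exp(−d/300 kb)) with d the distance to the nearest escapee; escapees
  have s = 1. The weights were set so that only the band/domain/proximity-
  favored minority reactivates strongly, reproducing the observed
  structure where roughly a quarter of X genes upregulate on erosion and
  only ~5% do so consistently; variable genes follow the inactive-gene
  model (their cell-type-specific escape is not simulated).
* **Xi share** (fraction of Xa-level output from the Xi/Xe allele):
  inactive/variable x = leak + (1 − leak)·e·s with leak = 0.01; escape
  x = base + (1 − base)·e with base ~ U[0.20, 0.35] — biased but nonzero
  escapee expression in XIST+ cells that balances under full erosion. The
  base range is a modeling choice (no quantitative escaped-allele ratio is
  established for XIST+ hiPSCs) and is configurable.
* **Counts**: totals ~ NB(mean = μ_g·(1 + x)/(1 + x_ref), α = 0.01) with
  μ_g log-normal around 1000; the depth and dispersion reflect deep bulk
  RNA-seq of consecutive-passage clonal replicates, which are tight;
  allelic reads at each het SNP ~ Binomial(n = Binomial(total, 0.25),
  p = x/(1 + x)) with the Xi haplotype as hapB and random REF/ALT
  orientation per SNP.
* **Epigenome**: H3K27me3 tracks are piecewise-constant (unit baseline,
  4× inside ~25 random domains; the XIST− track retains 40% of the domain
  excess); promoter β ~ U[0.7, 0.9] on methylated promoters (escapee
  promoters U[0.05, 0.2]) and β_eroded = β·(1 − x).
* **Amplicons**: molecules per allele ~ Poisson(100·allele share); reads
  per molecule ~ Geometric(0.5); per-base errors hit the UMI and the SNP
  base only. The truth table records *identifiable* molecules (distinct
  (UMI, allele) pairs) because co-tagged molecules are indistinguishable
  in principle; the raw Poisson draw is kept in `molecules_drawn`.
* **Randomness**: one seed, split via `SeedSequence.spawn` into four
  stage streams (landscape, expression, epitracks, ampseq), so each stage
  is independently reproducible and byte-identical across runs.

**What the generator does not emulate** — alignment artifacts and mapping
bias, reference bias at SNPs, aneuploidy/CNV, transcript structure and
isoform switching, cell-to-cell heterogeneity within a line, genuine
variable-escape biology, and spatially autocorrelated methylation. Tests
passing on this generator therefore demonstrate that the *statistical
machinery* recovers planted structure at realistic depths and effect
sizes, not that real-data preprocessing is free of bias.

## Validation studies and problem sizes

`xcierosion.validation` (driven by `tests/test_acceptance.py` and
`scripts/acceptance.py`) measures, at sizes chosen to run in seconds to a
few minutes on one CPU:

* classification recovery on ~600 genes at Xi shares {0, 0.25, 1} and
  gene depth ≥ 500 (≥ 99% recovered);
* erosion ranking of five lines at e = (0, 0.1, 0.3, 0.6, 1.0), three
  replicates: the X:A ratio ranks the lines exactly (Spearman ρ = 1). The
  biallelic fraction cannot: MAF ≥ 0.40 requires Xi share ≥ 2/3, which no
  gene reaches below e ≈ 0.45, so the three least-eroded lines tie at
  exactly zero and midranks cap ρ near 0.97 — a structural property of
  the class definition, reported as measured;
* the categorization rule vs brute-force enumeration on 1000 random
  4×2 call tables (100% agreement);
* NB-test calibration on 10,000 genes, 3 vs 3 (type-I in [0.03, 0.07];
  BH FDR ≤ 0.08 with 10% true two-fold genes);
* eroded-call operating point at depth 200, true ΔMAF 0.25 vs 0
  (sensitivity ≥ 0.90, false-positive rate ≤ 0.05);
* predictor ordering end-to-end on a 1500-gene X panel (so the
  consistently-up group exceeds 40 genes), extreme-pair p < 0.01;
* UMI dedup: exact equality on clean reads; directional bias under 1%
  UMI error averaged over eight independent 12-amplicon read sets
  (within 2% of truth);
* closed-form anchors: exact Mann-Whitney p = 0.1 at complete separation
  3 vs 3; BH on (0.01, 0.02, 0.03, 0.04) → all 0.04.

## Known limitations

The DE stand-in's divergences from full DE tools are listed above; real
phased VCFs with partial phase fall back to concordance phasing, which is
unreliable for balanced genes; amplicon assignment is exact-prefix only;
the report's XIST grouping assumes XIST expression separates the line
groups (override by supplying your own line grouping through the library
API when it does not).
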