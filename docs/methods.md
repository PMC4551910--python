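# Methods

## The analysis

σ54 (RpoN) is the bacterial enhancer-dependent sigma factor: its holoenzyme
forms closed promoter complexes at −24/−12 elements and normally requires a
cognate AAA+ ATPase activator, acting on the N-terminal Region I of σ54, to
open the DNA. Deleting Region I (the ΔRI "bypass" allele) permits
activator-independent transcription in vitro. The package implements the
genome-wide computational analysis that characterises this system from
three-strain RNA-seq: wild-type σ54 (`WT`), the bypass allele (`dRI`) and a
σ54 deletion (`none`).

The analysis runs in five stages:

1. **quantify** — per-gene RPKM, MA statistics for the three strain pairs,
   and a per-gene one-way ANOVA across strains;
2. **contrast** — a decision ladder over the M statistics categorises each
   gene as `RI_dependent`, `bypass`, `sigma54_repressed` or `unchanged`;
3. **motif scan** — exhaustive weighted-mismatch detection of σ54 −24/−12
   and σ70 −35/−10 bipartite motifs on both strands;
4. **site classify** — at σ54-repressed genes, positional classification of
   the σ54 site relative to the active σ70 promoter into classes I–IV;
5. **report** — MA-plot data export and run manifests.

Because the analysis is exercised on simulated data with known ground
truth, a first-class synthetic-data generator produces the genomes,
annotations, planted promoters and counts (below).

## Statistics

**RPKM.** `count × 10⁹ / (gene length in bp × library size)`, with the
library size taken as the realised column sum of the count matrix. Note
that dividing by the realised library size makes RPKM compositional: a
strain in which a subset of genes is strongly induced has its remaining
genes' RPKM deflated. This is inherent to the statistic, visible in dense
simulated designs, and negligible when differential genes are a small
minority of the transcriptome.

**MA statistics.** For strains 1 and 2,
`M = log₂(RPKM₁ + ε) − log₂(RPKM₂ + ε)` and
`A = ½[log₂(RPKM₁ + ε) + log₂(RPKM₂ + ε)]`, computed on per-strain mean
RPKM. The pseudocount ε (default 0.5 RPKM) is added inside the logarithms
only — reported RPKM values are unshifted — so M and A stay finite for
silent genes. Using one ε everywhere preserves the exact identity
`M(WT,none) = M(WT,dRI) + M(dRI,none)`. `|M| ≤ 2` delimits genes at most
four-fold differently expressed (the MA-plot shaded region); the boundary
value itself is *inside* the region, so the four-fold flag is `|M| > 2`.

**ANOVA.** Classical equal-variance one-way ANOVA on `log₂(RPKM + ε)` over
replicates, three groups. The normal path uses `scipy.stats.f_oneway`;
degenerate inputs are resolved explicitly rather than propagated as NaN:
all-identical values give F = 0, p = 1; zero within-group variance with
distinct means gives F = ∞, p = 0; one replicate per group returns a
flagged "not computable" result — the q gate is then skipped and only the
M thresholds apply (single-sample mode). Sums of squared deviations below
a relative floor of 1e−12 are treated as zero, since identical replicate
values do not reproduce exactly in float arithmetic. Multiple testing uses
Benjamini–Hochberg FDR (statsmodels), default q ≤ 0.05.

**Decision ladder** (first match wins; with replicates, each non-unchanged
rung also requires q ≤ α):

1. `RI_dependent`: M(WT,dRI) ≥ t_major and M(WT,none) ≥ t_major;
2. `bypass`: M(dRI,none) ≥ t_bypass;
3. `sigma54_repressed`: −M(WT,none) ≥ t_major and −M(dRI,none) ≥ t_major;
4. `unchanged` otherwise.

Defaults: t_major = 2 (four-fold, the shaded-region boundary), t_bypass = 1
(two-fold — bypass transcription is low-level, so a lower threshold than
for canonical activation). The RI > bypass > repressed precedence resolves
the rare genes satisfying several rungs and mirrors the sequential scoring
of the three pairwise comparisons.

## Motif models

No published mismatch matrix accompanies the canonical σ54 consensus, so
the models are declared, configurable operationalisations:

* σ54: −24 element `TGGCACG`, spacer 4–5 nt, −12 element `TTGCW`. The
  invariant GG (−24) and GC (−12) cores carry mismatch weight 2, all other
  positions 1; default threshold ≤ 2 total weighted mismatches. The −12 C
  consensus position is the C of `TTGC`; a non-C base there is the
  signature of bypass-capable promoters, and `minus12_conservation`
  reports the C fraction of any site set (~96% across bacterial σ54
  promoters at large).
* σ70: `TTGACA`, spacer 16–18 nt, `TATAAT`, uniform weights, threshold ≤ 3.

Scanning semantics: degenerate IUPAC letters match their base set at zero
cost; `N` in the subject never matches; at a given element-1 start the
best-scoring spacer is reported (ties to the shorter spacer); minus-strand
sites are reported in forward coordinates. Inferred tss conventions
(declared, since none is standard): σ54 tss = 12 nt downstream of the −12
C position; σ70 tss = 7 nt downstream of the −10 element start. Site→gene
assignment uses a promoter window of 300 bp upstream to 100 bp downstream
of the gene 5′ end in gene orientation, nearest gene on ties, smaller
start coordinate on exact ties.

Consensus building aligns sites by concatenating element sequences
(spacers removed); a column's letter is the majority base at frequency
≥ 0.75, otherwise the IUPAC code covering all bases at frequency ≥ 0.25.

## Positional classes I–IV

The σ70 footprint is the interval from 5 bp upstream of the −35 element to
20 bp past the tss (configurable pads). With the σ54 site's full element
span (−24 start through −12 end):

* **I** — overlaps the footprint, same strand as the σ70 promoter
  (binding competition);
* **II** — overlaps, opposite strand;
* **III** — disjoint but within 100 bp of the footprint;
* **IV** — farther than 100 bp (e.g. convergent, downstream of the tss).

The I/II strand distinction and the III/IV proximity cutoff are declared
operationalisations of the four observed positional groups — the
underlying literature does not print exact class geometry — and every
threshold is configurable and recorded in the output metadata. At genes
with several candidate sites the best-scoring site is used (ties to the
leftmost) and the choice is logged; genes missing either site type are
reported as unclassifiable, never dropped silently.

## Synthetic data

`build_genome` lays out non-overlapping genes (lengths uniform 300–1500 bp,
intergenic gaps 220–400 bp, i.i.d. background at configurable GC, default
0.50, random strands) and writes promoter elements verbatim at fixed
strand-aware offsets from each planted tss, chosen so the scanner's tss
inference recovers the planted tss exactly. Background windows that happen
to contain a perfect σ54 or σ70 consensus core are rejection-resampled, so
the truth table is exhaustive and recovery tests are exact. Four promoter
types are planted, with per-strain activity multipliers (all configurable):

| type | WT | dRI | none | notes |
|---|---|---|---|---|
| activator-dependent σ54 | 8 | 1 | 1 | consensus −12 C |
| bypass σ54 | 8 | 2.5 | 1 | non-C at −12 (default A) |
| constitutive σ70 | 1 | 1 | 1 | |
| σ54-repressed σ70 | 1 | 1 | 8 | σ54 site with consensus C, class I–IV |

The 8× major effects and the 2.5× low-level bypass effect are assumptions
(the literature reports bypass only qualitatively as low-level); repressed
configurations cycle through classes I–IV. Counts are negative binomial
with mean `depth × length_kb × activity / normaliser` and variance
`μ + μ²/k` (shared dispersion, default k = 10, i.e. ~32% biological CV;
large k approaches Poisson). The normaliser is shared across strains (the
strain-averaged `Σ length_kb × activity`), which preserves cross-strain
mean ratios exactly at the cost of per-strain expected totals deviating
from the target depth by the strain's share of differential mass — within
10% whenever differential genes are a small minority, as in a real
transcriptome. Default 3 replicates per strain so the ANOVA stage is
exercised; single-replicate mode is supported (contrasts only).

What the generator does **not** emulate: read-level errors and alignment,
rRNA depletion and library-prep artifacts, operon structure, correlated
gene-gene expression, GC or positional coverage bias. Passing recovery
tests therefore demonstrate correctness of the statistics and decision
rules under the stated count model, not robustness to real-data artifacts.

## Statistical power at the default recovery conditions

The promoter-dense default design (500 genes, 10 planted per type, depth
2×10⁶, 3 replicates, k = 10) is deliberately hard. Per-replicate log₂
noise is ≈ 1.44·√(1/μ + 1/k) ≈ 0.46, so sd(M) ≈ 0.37. Two consequences,
visible in the acceptance suite:

* the bypass margin log₂(2.5) − t_bypass ≈ 0.32 is below one sd of M, so
  per-gene bypass sensitivity is ~70–80%;
* an 8-fold effect yields ANOVA p ≈ 0.003–0.005 at n = 3, and BH over 500
  genes with ~30 true positives leaves the q ≤ 0.05 gate with ~70–85%
  per-gene power.

Recovery at these conditions is therefore reported as measured (typically
70–100% per type depending on seed) rather than guaranteed; the
false-category rate stays ≤ 2% because the ladder's thresholds are
conservative. Larger replicate numbers, lower dispersion or sparser
planting all push sensitivity toward 1, as the low-noise unit tests show.

## Numerical and design notes

* Coordinates are 0-based half-open internally; GFF3 is written 1-based
  inclusive, BED 0-based half-open.
* Determinism: every random step flows from an explicit integer seed
  through `numpy.random.default_rng`; the pipeline derives the count seed
  as `seed + 1` and manifests record configuration hashes, so identical
  configurations give byte-identical outputs.
* Site scores: `score = total weight − weighted mismatches` (perfect match
  scores the model maximum); thresholds are expressed in mismatches, so
  lowering a threshold never adds hits. BED scores are rescaled to 0–1000.
* The fixture round trip stores the full truth table in the YAML manifest;
  the BED6 truth file is an interoperability view (name = promoter type,
  σ54 sites of repressed configurations as separate records).

## Problem sizes

Test and acceptance runs use 16–2000-gene genomes (tens of kb to ~2.4 Mb)
and depths of 2×10⁵–2×10⁶ reads, chosen as the smallest sizes at which the
Monte-Carlo checks have clear margins; the full default pipeline completes
in roughly a second on one core.

## Known limitations

* The motif models are consensus-with-weights, not position weight
  matrices estimated from alignments; scores are not probabilistic.
* Class I/II geometry allows overlapping σ54 and σ70 *footprints* but not
  overlapping written *elements* in the generator (planted elements never
  collide, so recovery stays exact).
* The ANOVA assumes equal variances across strains (no Welch correction)
  and approximate normality of log₂(RPKM + ε).
* RPKM compositionality (above) biases M in promoter-dense simulated
  genomes; no TMM/median-ratio style correction is applied, by design.
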