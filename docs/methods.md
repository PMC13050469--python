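# Methods

`herbscreen` implements a computational screen that ranks candidate herbs
(and their compounds) against cell-cell communication programs that change
across disease conditions in single-cell expression data, then nominates key
targets by network proximity. This note records the models, the parameters
that matter, and the design choices made where the procedure was genuinely
open.

## Study design emulated by the synthetic-data module

The generator emulates a five-group single-cell study of gut tissue: a
healthy reference (`Nor`), a chemically induced disease model sampled at an
early inflammatory and a late adenoma stage (`A1`, `A2`), and the same model
under a dietary co-exposure at the same two stages (`F1`, `F2`). Each group
contributes `n_cells_per_condition` cells (default 300) over a shared panel
of `n_genes` genes (default 200) split across three cell types (epithelial
0.40, stromal 0.35, myeloid 0.25).

**Count model.** Counts are negative binomial, drawn as a gamma–Poisson
mixture: gene-level means are log-normal (median `baseline_mean` = 1.0
counts, `gene_mean_sigma` = 0.6 on the log scale), per-cell library-size
factors are log-normal(0, 0.3), and the NB dispersion is 0.3
(variance = mu + 0.3 mu²). The noise scale was fixed once, by calibration of
the generator itself, so that the sampling error of a per-stratum mean
(~100 cells) sits well below the planted effect — emulating communication
scoring over the reasonably well-detected ligand/receptor genes that survive
quality control in a real study, not the full zero-inflated transcriptome.

**Planted signal.** `n_planted_pairs` (default 6) ligand-receptor pairs are
assigned a contrast pattern that cycles through three templates —
*fructose* (shifted in F1+F2), *disease* (shifted in A1+A2+F1+F2), and
*late_fructose* (shifted in F2 only). The shift is multiplicative,
`2**effect_log2fc` (default log2FC = 2), applied to the ligand's mean in a
designated source cell type and the receptor's mean in a designated target
cell type — exactly the quantity the interaction score multiplies, so the
signal is detectable by construction and invisible to marginal per-gene
tests in other cell types. The pattern determines the differential set each
pair must land in (fructose → A, B, D; disease → B, C; late_fructose →
A, B, D), which is recorded as ground truth.

**Herb panel.** 20 herbs with 30 targets each. One "true hit" receives
`floor(planted_overlap_fraction × 12)` planted genes (default fraction 0.7 →
8 genes), padded with genes drawn from the remaining universe; decoys draw
all 30 targets uniformly. The filler pool excludes only the already-chosen
genes, so at overlap 0 the true hit is exchangeable with the decoys (this
matters for the null calibration of the screen).

**PPI graph.** Barabási–Albert preferential attachment (m = 2) over the gene
universe, with the true-hit herb's targets re-wired to within graph distance
2 of a planted gene where necessary, so network proximity is also
recoverable by construction.

**Compound descriptors.** A mixture of conventionally drug-like compounds
and large, flexible, alert-laden ones (mimicking the polysaccharides and
polyphenol oligomers common in food-derived panels, 40% of draws), so a
druglikeness filter at 0.3 splits a 50-compound panel nontrivially.

**What the generator does not emulate** — doublets, ambient RNA, batch
effects, realistic cell-type hierarchies, dropout beyond what NB sampling
produces, or correlated gene programs. Passing recovery tests therefore
demonstrates that the pipeline's statistics behave as specified under a
clean overdispersed-count world; they say nothing about robustness to
technical artefacts in real data.

## Expression processing

Cells are library-size normalized to `scale` (default 10⁴) total counts and
log1p-transformed before any means are taken; cells with zero totals are
dropped with a warning and double normalization is an error. Whether a
communication score should multiply raw or log-normalized means is not
settled usage; both are supported (the mean tables can be built from either
matrix) and logged-normalized is the default. Per-(cell type, condition)
strata with fewer than `min_cells` cells (default 10) are excluded and
recorded rather than contributing unstable means.

## Interaction scoring

score(L→R, s→t, c) = mean(L | type s, condition c) × mean(R | type t,
condition c), over single-gene ligands and receptors (multi-subunit
complexes are out of scope). Autocrine (s = t) channels are included.
Records are emitted in a fixed (pair, source, target, condition) order so
outputs diff cleanly. An optional label-permutation test shuffles cell-type
labels within the condition and reports p = (1 + #{permuted ≥ observed}) /
(n_perm + 1); it is off by default because the deterministic product is the
primary statistic.

## Differential sets

An entry (pair, source, target) *changes* between conditions x and y when
|log2((score_x + eps)/(score_y + eps))| ≥ tau, with tau = 1 and eps = 0.01
by default; an entry scored in only one condition is compared against eps.
Direction is ignored — gained and lost communication both count. The four
sets combine fixed contrast lists (A: A2|A1, F1|A1, F2|F1, F2|A2; B: F1|Nor,
F2|Nor; C: A1|Nor, A2|Nor; D = B \ C), by union by default. Union was chosen
over intersection because the stage-wise contrasts are noisy individually
and the screen's universe-level statistics tolerate false entries better
than false dropouts; intersection mode is exposed (`mode`) and is asserted
to produce subsets of the union-mode sets. Membership is kept at
(pair, source, target) granularity and projected to the union of ligand and
receptor genes only when an enrichment universe is needed.

## Enrichment and ranking

Closeness of a target profile to an effect set is the upper-tail
hypergeometric probability of their overlap inside a shared universe
(default: the expression matrix's gene space; all of K, n, k are measured
inside it). BH adjustment is applied within each set label across the panel
— matching a per-screen false-discovery criterion — not pooled across
labels (configurable). The screening order formalizes "significance and
mapping count": number of sets with p_adj < alpha (desc), mean p_adj (asc),
total overlap k (desc), then entity id for determinism. "Mapping count"
could also be read as the raw overlap k; both keys are present in the
table. Only over-representation is tested; depletion is not of interest
here.

## Druglikeness

QED = exp(Σ w_i ln d_i / Σ w_i) over the eight canonical descriptor
desirabilities (asymmetric double sigmoids normalized by their maxima, with
published parameters shipped as a versioned JSON). Desirabilities are
clamped below at 10⁻⁶ to keep logarithms finite. The default weights are
the *mean*-weight variant — the default of the widely used structure-based
implementation this score is usually computed with — with the
max-information and unweighted variants selectable. The 0.3 cutoff is
inclusive (≥). Descriptors are table inputs; no chemistry toolkit is
required at run time.

## Network proximity

d_obs is the mean over effect-set genes of the shortest-path distance to the
nearest target; the null re-draws target sets of equal size within
log2-degree bins (minimum bin size 20, short bins merged upward) and
z = (d_obs − null mean)/null sd. Negative z means the targets sit closer to
the program than degree-matched chance. The platform the original analysis
used is proprietary/unspecified, so this standard drug–disease proximity
construction is adopted as this package's own method; conclusions drawn
from it are statements about this statistic, not a reproduction. With
n_random = 100 the z-scores of random target sets are approximately standard
normal (checked in the acceptance suite); a degenerate null (sd numerically
zero) reports z as undefined rather than a number.

## Ontology similarity

Wang-style semantic similarity over a term DAG: S-values propagate from a
term to its ancestry with edge-type factors (is_a 0.8, part_of 0.6, the
method's canonical constants, overridable), and the similarity of two terms
is the shared-ancestry S-value mass over the total. Gene-gene similarity is
the best-match average over the genes' term sets, and set-set similarity the
best-match average over genes, in both directions. Terms in disjoint
components score 0; unannotated gene sets are an error.

## Pipeline and reproducibility

All stages run behind one YAML config (unknown keys rejected) with every
seed declared; the manifest records effective parameters and SHA-256 hashes
of all outputs, and a stage whose config digest and output hashes match the
manifest is skipped. Deterministic stages reproduce bit-identical outputs
under the same seed.

## Problem sizes

Defaults (5 × 300 cells, 200 genes, 60 LR pairs, 20 herbs) were chosen as
the smallest design at which every planted effect is comfortably
recoverable; the acceptance checks run the screen at exactly these sizes
(100 replicate seeds for the recovery and null-rank studies; 200 replicates
of n_random = 100 for proximity calibration; 500 permutation-tested records
at n_perm = 500 for the permutation null).

## Known limitations

* The change criterion (fold-change of the score) is one of several
  defensible readings (score-rank shifts or permutation significance being
  others); tau and eps move set sizes directly.
* BH within set labels assumes the per-label tests are the analysis unit;
  pooling would be more conservative for entities tested in many labels.
* Proximity z treats the PPI graph as complete and unbiased; literature
  PPI graphs are neither, and degree binning corrects only for degree.
* The compound stage's target profiles are external inputs in any real run;
  the analysis driver that demonstrates it constructs labelled synthetic
  profiles instead.
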