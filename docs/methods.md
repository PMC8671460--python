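# Methods

This note records the models behind each stage, the defaults that matter and
why, what the synthetic generators do and do not emulate, and the numerical
choices a maintainer would otherwise have to reverse-engineer.

## Screen model and sensitivity calling

The unit of data is the log fold-change (logFC) of a cell line's barcode
abundance under a compound relative to the DMSO vehicle in a pooled,
single-dose viability screen; more negative means more killing. Values are
consumed as-is — no rescaling — so the log base never affects results as long
as the cutoff is defined on the same scale.

Sensitivity is a strict threshold call: line *l* is sensitive to compound *c*
iff logFC(c, l) < t, with t = −1 by default. The strictness matters only for
values exactly at the cutoff and is fixed by convention ("less than"). A
missing entry is neither sensitive nor evaluable; the activity rule (≥ 3
sensitive lines ⇒ active, `min_lines = 3` as an absolute count) is applied
over evaluable lines only, so sparse secondary-screen matrices do not
penalize compounds for unmeasured lines. Broad toxicity is
`frac_sensitive > 0.9` over evaluable lines.

Threshold calibration maximizes Youden's J over a grid (default: all observed
values plus −1). Ties at the maximum break toward the smallest |t|, then the
smaller t — the most conservative call rate, and deterministic. The
"positive" class is the biomarker-positive lines (e.g. lines carrying the
responder mutation); inverting the labels negates J, which the tests check.

## MOA landscape

Compounds carrying several MOA labels count once under each label (annotation
strings are split on commas/semicolons); unannotated compounds pool under
"unknown". The display floor `min_active_per_moa` applies to the count of
*active* compounds per MOA. Consequently the per-MOA active counts sum to at
least the number of active annotated compounds (multi-label double counting
only) — an invariant under test.

## Clustering, embedding and MOA assignment

Profile distance is 1 − Spearman ρ, pairwise-complete over shared non-missing
entries with average ranks for ties; pairs sharing fewer than 3 observations
get a missing distance (clustering then refuses to run rather than guess).
Agglomeration is scipy complete linkage on the precomputed distances; exact
height ties follow scipy's deterministic input-order handling. Trees export
to Newick via scikit-bio.

Embeddings use scikit-learn t-SNE on the precomputed distance matrix with the
screen-analysis settings (perplexity 30, learning rate 100) and ten runs from
seeds 1..10 by default. The optimizer itself is deliberately not
re-implemented. Runs with fewer than 3× perplexity items warn; small
scenarios should lower perplexity (the bundled scenarios use 10 for ~80
compounds). `max_iter` defaults to 500; the planted-block scenarios use 1000
because under-converged layouts blur cluster boundaries and destabilize
neighbour votes.

A query compound is assigned a putative MOA only when every run supports the
same mechanism. A run supports mechanism *m* when (i) *m* holds a unique
plurality of the query's k = 10 nearest annotated neighbours (Euclidean in
2-D; distance ties break by id), (ii) its vote fraction is ≥ `min_frac` =
0.5, and (iii) the query's median distance to those k neighbours is at most
`max_dist_ratio` = 1.3 times the winning MOA's own median pairwise member
distance. The third condition is this package's addition to plain kNN
voting: rank-nearest is not proximity — a compound far from every cluster
still has *some* nearest cluster, and over a 28-line panel a pure-noise
profile acquires chance rank-correlations (≈ N(0, 1/√27)) with one block
that are fixed in the data and therefore survive the all-runs rule. The gate
factor is deliberately conservative (1.3 rather than the ~1.6 upper range of
true members' ratios): a false mechanism assignment is costlier than a missed
one, matching the asymmetry of the all-runs criterion itself, and under the
all-runs rule a borderline noise compound must clear the gate in *every* run,
which the stricter factor makes vanishingly unlikely while only the most
peripheral true members are sacrificed.

## Differential killing

Per compound, Welch's unequal-variance t-test on in-group vs out-group logFC,
effect size = difference of group means, significance = p < α (default 0.01)
*and* negative effect. Welch is the robust default for strongly unequal
cohort sizes (tens vs hundreds of lines); the two-class engines of screen
portals are not always specified, so exact hit lists may differ at the
margin — validation by intersecting independent screens is the intended
guard, and the intersection operates on deduplicated compound names.
Compounds with fewer than two values in either group are skipped with a
warning, not failed. No multiple-testing correction is applied at this stage
(the raw-p gate plus cross-screen intersection is the procedure); the
moderated-t machinery is available for sensitivity analysis.

Mann–Whitney comparisons are exact by enumeration when n·m ≤ 400 and no ties
are present (delegated to scipy's exact method), tie-corrected normal
approximation otherwise; all values identical across both groups returns
p = 1 since the statistic carries no information.

## Moderated t and the variance prior

Pooled two-sample variances s²_g on d_g = n_A + n_B − 2 df are shrunk toward
a scaled inverse-χ² prior (d₀, s₀²) fitted by moment matching on the log
scale: e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has excess variance ψ′(d₀/2)
beyond the sampling term, so d₀ comes from inverting the trigamma (Newton,
with the usual asymptotic starts) and s₀² from the mean of e_g. Zero excess
spread flags d₀ = ∞ (complete shrinkage, normal reference distribution);
d₀ = 0 recovers the ordinary pooled t exactly (tested to 1e−10 against
scipy). Genes with zero variance everywhere and zero mean difference get
t = 0, p = 1. Zero sample variances are dropped from the prior fit with a
warning. Significance defaults to Benjamini–Hochberg q < 0.05 with no
fold-change floor — the conventional default, exposed as configuration.

Over-representation is the one-sided hypergeometric tail on a user-supplied
gene-set collection (a generic stand-in for web pathway portals), BH-adjusted
across sets. Pearson shortlisting uses the t-transform on n − 2 df with the
conventional p < 0.05 gate. Signature scores are mean-of-Z (each gene
standardized across lines before averaging), which equalizes gene scales and
is invariant to affine rescaling of any input gene — not Z-of-mean, which is
dominated by highly expressed genes.

## GSEA

Ranking metric: signal-to-noise (μ_A − μ_B)/(σ_A + σ_B), each class sd
floored at max(0.2·|class mean|, 0.2); ranking ties break by gene name. The
enrichment score walks the ranked list (hits add |metric|^p with p = 1
normalized over hit weights, misses subtract 1/(N − N_hits)); the signed
maximum deviation is ES ∈ [−1, 1] and the walk ends at 0 (conservation, used
as a numerical check). If every hit metric is zero the hit increments fall
back to equal weights rather than 0/0.

Permutation mode defaults to phenotype relabelling (re-ranking per
permutation) when both classes have ≥ 7 samples and random same-size gene
sets otherwise, following the usual small-sample guidance; the 4v4 and 6v6
designs this targets sit below the boundary and therefore default to
gene-set permutation, with the mode exposed in configuration. NES divides ES
by the mean same-sign permuted |ES| of that set; nominal p is the same-sign
tail fraction; FDR q is the standard pooled ratio of normalized tail
fractions, clipped to [0, 1]. Gene sets are restricted to 15–500 members
after intersection with the matrix (configurable). Cross-dataset comparison
filters each dataset's results at FDR < 0.25 in a chosen direction and
reports the all-datasets intersection plus pairwise overlap counts.

## Synthetic data: what it emulates, and what it does not

`generate_screen` emulates a single-dose pooled screen: logFC = planted mean
shift + Gaussian noise. Gaussian is an assumption (vehicle-relative logFC is
roughly symmetric; the screen literature does not characterize the noise), not
an inference. Active compounds kill through their MOA: each MOA has a latent
per-line susceptibility Bernoulli(0.6) × Uniform(0.5, 1.0) — so some lines
fully resist each mechanism, reproducing selective-vs-broad patterns — and a
compound's planted shift is its potency (Normal(effect_mu, 0.3), clipped
non-positive) times that latent. Defaults are the study conditions: 500
compounds × 28 lines, 20% active, potency mean −2.5, noise sd 0.4, category
labels in 21/2/77 proportions (targeted/chemo/non-oncology). Active
compounds occupy the front of the compound list and MOA blocks are assigned
from the front, so block members are active by construction. The generator
does not simulate barcode deconvolution, paracrine confounding between
pooled lines, dose–response curves, or plate/batch effects — so passing
recovery tests demonstrates the statistical machinery under clean Gaussian
conditions, not robustness to those real-data artefacts.

`generate_expression` plants differential genes (±deg_delta in group A),
response-correlated genes (baseline + slope·response + noise against an
internally drawn per-line response), and enriched sets (the planted up/down
genes as coordinated sets); values are clipped at 0 to respect the
log2(TPM+1) scale. `generate_calibration_set` draws biomarker-positive lines
from Normal(mu_pos, sd²) and negative lines from Normal(mu_neg, sd²)
(defaults −1.8 / −0.2 / 0.5, straddling the −1 cutoff).

Planted-recovery scenario sizes were chosen to keep the full check suite in
tens of seconds: differential-expression recovery uses the 28-line panel
split 14 v 14 (the group split is not part of the generator contract; larger
groups make power a property of the method rather than of a minimal design),
enrichment uses 2,000 genes with 5% planted differential genes, and the
MOA-assignment scenario uses four 15-compound blocks plus pure-noise
compounds over 28 lines with perplexity 10.

## Degenerate inputs and determinism

Single-class calibration labels, overlapping comparison groups, empty
reference sets, missing distances, non-finite embeddings inputs, all-absent
signature genes and empty gene universes raise immediately with actionable
messages. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); t-SNE run seeds default to 1..n_runs so the
all-runs criterion is reproducible; rerunning a pipeline configuration
bit-reproduces every deterministic stage, and the run directory records the
configuration hash.

## Known limitations

- The distance-gated kNN assignment rule has two free constants (k, gate
  factor) whose defaults were fixed on synthetic geometry; real screens with
  diffuse MOA clusters may need looser settings.
- Welch's t is a stand-in for unspecified portal comparison engines; hit
  lists near the significance boundary are engine-dependent.
- Phenotype permutation with ≤ 6 samples per class explores few distinct
  relabellings; gene-set permutation (the small-sample default) tests a
  different null (random sets, fixed ranking).
- The hypergeometric over-representation stand-in ignores gene–gene
  correlation and annotation redundancy, as such tests do.
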