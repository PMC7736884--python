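# Methods

## Model and procedure

`priontx` analyzes a three-strain bulk RNA-seq design — wild type (wt),
a prion-carrying strain, and a deletion strain, three biological
replicates each — through a fixed chain: differential expression →
pattern taxonomy → TF-target overrepresentation → sign-consistency
attribution → combined-effect classification → gene-set statistics.
The unifying assumption is **one-hop signed regulation**: an altered
transcription factor affects exactly its documented direct targets,
with direction given by the product of the TF's effective sign
(up = +1; down = −1; aggregated = −1, i.e. loss of function) and the
edge's role sign (activator = +1, inhibitor = −1; dual edges carry both
signs). No cascades are modeled: two-hop effects would make both the
attribution logic and the simulator's ground truth ill-defined.

## Differential expression

Counts are modeled as negative binomial with variance μ + φμ².
Library-size factors come from the median-of-ratios estimator (per-gene
geometric-mean reference over genes positive in every sample; fallback
to total-count scaling, with a warning, when no such gene exists). The
test is a likelihood-ratio test of a condition effect (1 df): per-gene
NB means are fitted by damped Newton iteration on the log-mean with
size factors as offsets, under a one-mean null and a mean-per-condition
alternative, and the deviance is referred to χ²₁.

Dispersion is moderated rather than fitted per gene at full resolution:
per-gene method-of-moments estimates (pooled within-condition variance
on normalized counts) are shrunk 70% toward their mean and floored at
1e-4. At three replicates per group, raw MoM estimates are extremely
noisy; strong shrinkage toward the global value trades per-gene
adaptivity for calibration, which is what the decision rule needs. The
calibration is verified by simulation, not assumed: under the null
generator the raw-p false-positive rate at nominal 0.05 is ≈ 0.058
(200 simulations × 2000 genes, 3 vs 3; recomputed by
`scripts/acceptance.py` and the test suite).

A gene is a DEG at BH-adjusted p < 0.001 **and** |log₂FC| > 1. Fold
change is computed from normalized group means with pseudocount 0.5,
which keeps it finite at zero counts; the pseudocount and the
normalization target are this package's choices (the decision rule's
provenance does not fix them). "Unchanged" is an explicit third state
— the pattern taxonomy and combined-effect logic depend on it. Genes
with all-zero counts in both groups are excluded from testing and
reported with NaN p-values.

### Replicate-outlier screening

Samples are embedded by classical multidimensional scaling
(double-centered Euclidean distances, top-2 eigenvectors) of
log₂(normalized + 0.5) over the 500 most variable genes. A replicate is
flagged when its distance to its condition centroid exceeds 2× the
median within-condition centroid distance; at most one replicate per
condition may be flagged (if the rule would flag more, only the
farthest stays flagged, with a warning). This replaces a visual-MDS
judgment with a fixed, reproducible rule; the 2× threshold and top-500
window are conventions chosen once, not fitted.

## Attribution

For a set of altered TFs, every DEG targeted by at least one of them is
scored: *interpretable* iff its observed direction equals at least one
altered TF's predicted direction for it. Counts are unique unions over
genes (a gene explained by three TFs counts once) and are reported
separately for up- and down-regulated targets; genes targeted only by
unaltered TFs are excluded from denominators. A gene predicted both up
and down (conflicting TFs, or a dual edge) is counted in the conflict
tally; it is interpretable if either prediction matches — the
permissive reading that matches how union fractions below 100% arise in
practice. A TF that is both transcriptionally upregulated and
aggregated contributes both signs.

TF-target overrepresentation is the upper-tail hypergeometric
P(X ≥ k) with population = gene universe, successes = regulon, draws =
DEG list — identical to a one-sided Fisher exact test. The per-TF table
reports User% (targets-in-DEGs / DEG-list size) and CK%
(targets-in-DEGs / regulon size), sorted by p with lexicographic
tie-break.

Aggregation attribution is the same machinery with every screened TF
set to the aggregated state; aggregation is modeled as complete loss of
regulatory output, not a graded magnitude. The aggregation-prone screen
itself consumes externally computed solubility (CamSol-style intrinsic
variant) and prion-core (pWALTZ) scores — those algorithms are not
reimplemented — and combines them with N+Q sequence content under
strict inequalities: pass ⇔ camsol < 1.5 OR (pwaltz > 73.5 AND
N+Q > 0.20); a missing score fails its branch.

## Combined effects

For targets of the aggregated TFs, the observed prion-strain direction
is checked against two explanation sources: the gene's deletion-strain
direction (a proxy for losing the remodeler) and the aggregated TFs'
predictions. Matching either source makes the gene interpretable;
matching both is recorded as "combination". Genes unchanged in the
prion strain form their own subgroups and are excluded from the
interpretability denominator — an unchanged gene poses no pattern to
explain. When every deletion-strain direction is "unchanged" the
classifier provably reduces to aggregation-only attribution (property-
tested on random networks).

## Gene-set statistics

All enrichment tests are one-sided (overrepresentation); only the
between-direction comparison of TF-gene content is two-sided — the
direction of that comparison is not known a priori. BH-adjusted
p-values are reported everywhere, but significance calls follow raw-p
cutoffs with the ORA's extra conditions (overlap > 3 strictly,
enrichment ratio > 1.5 strictly), mirroring how such thresholds are
conventionally applied. The iESR/rESR analysis requires disjoint sets
and reports per-set activated/repressed percentages against a
configurable background universe (default: the annotated universe; the
choice of genome vs measured transcriptome background is exposed as the
`universe` argument rather than fixed).

## Synthetic data

The generator emulates the target study design: ~6000 genes, a
TF panel, 3 strains × 3 replicates, library sizes ~15 M reads
(giving ~62–75× genome coverage at 50-bp reads, via N×L/G), lognormal
baseline expression (log-mean 4.0, log-sd 1.5), shared NB dispersion
φ = 0.05 — a typical value for well-behaved isogenic bulk replicates —
and planted two- to four-fold effects (effect_log2fc 1–2) on direct
targets. TF out-degrees are Poisson; edges are independently activators
with probability 0.7 (documented regulons skew toward activation).
Planted transcriptional alterations are also applied to the TF's own
counts so DEG calling can rediscover the TF itself; aggregation is not
(a sequestered protein need not change its own transcript). Per-strain
mean vectors are renormalized to the configured library size, as in
real fixed-depth sequencing; downstream median-of-ratios normalization
undoes this common factor. Opposing planted contributions on the same
gene cancel when their signs sum to zero.

What the generator does **not** emulate: GC/length bias, gene-specific
dispersion trends, correlated replicates, cascading (multi-hop)
regulation, and partial loss of function. Tests passing on this
generator therefore demonstrate the pipeline's correctness under its
own model assumptions — decision-rule fidelity, calibration, and
recovery of one-hop planted structure — not robustness to every
artifact of real libraries.

## Problem sizes and numerical choices

The simulation-backed checks run at 2000 genes (type-I calibration,
200 simulations; planted-target recovery) and 1000 genes × 100 seeded
runs (TF-rank recovery), with library sizes of 1–2 M reads — these
sizes give stable Monte-Carlo estimates while keeping the full suite
fast, and results were indistinguishable at full depth in spot checks.
Newton fitting of NB means uses Fisher scoring on the log scale with
step clipping at ±2 and a 1e-10 convergence tolerance; fitted means are
floored at 1e-12 to keep likelihoods finite for all-zero groups.
Display percentages are rounded to one decimal; stored values keep full
precision.

## Known limitations

- The NB test targets the *decision rule* (cutoffs, FDR, direction), not
  numerical identity with any specific published DE package; p-values
  will differ from tools with per-gene dispersion shrinkage curves.
- Attribution is correlational sign-matching; it cannot distinguish a
  direct regulatory cause from a confounded one, and the one-hop
  assumption undercounts genuine indirect effects.
- The permissive either-source rule in the combined classifier is one
  of several defensible readings of "explained by a combination"; it is
  the most inclusive one that still leaves genuinely contradictory
  patterns unexplained.
- With only three replicates the outlier screen cannot distinguish a
  departed replicate from true biological variability; it enforces at
  most one exclusion per condition by construction.
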