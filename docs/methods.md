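# Methods

This note documents the statistical models, the defaults and the design
choices behind each stage, and what the synthetic-data tests do and do not
establish about real data.

## Normalization and process control

Counts r_gi (probe g, sample i) are transformed to
y_gi = log2(((r_gi + 0.5)/(R_i + 1))·10⁶) with R_i the sample's total
count over all probes. The typeset form of this formula is ambiguous about
whether 10⁶ multiplies the ratio or the denominator; the offsets' stated
purpose (0.5 avoids log 0; +1 keeps the ratio strictly below one) fixes
the implemented reading, under which a zero count in a sample with
R = 999,999 maps to exactly −1.

Median normalization rescales each sample by (target/median), where the
per-sample median is taken over miRNA-class probes with nonzero counts —
control probes never drive scaling — and the target is the median of the
per-sample medians. Whether the upstream workflow median-normalized raw
counts or CPM first is not documented; the default here normalizes raw
counts and `median_normalize(..., on_cpm=True)` gives the CPM-first
variant. Differential expression is fit on log2(median-normalized + 0.5)
values so that effects are log2 fold changes; the reported `fold_change`
is 2^effect.

Process QC mirrors control-chart practice for the assay's negative-control
("ANT") probes: per-sample mean ANT value, deviation Δmean from the grand
mean, and acceptance iff |Δmean| ≤ 2·SD where SD is the n−1 sample
standard deviation of the Δmean values. Σ Δmean = 0 by construction. QC is
advisory by default; `qc_strict` drops failing samples before any
analysis. Note that the ±2SD rule flags ≈5% of in-control samples by
construction.

## Moderated differential expression

Each probe gets a two-group linear model; residual variances s_g² on d df
are shrunk toward a prior s0² with prior df d0, estimated by the method of
moments on e_g = log s_g² − ψ(d/2) + log(d/2): the excess of Var(e) over
ψ′(d/2) identifies d0 through the trigamma inverse, and s0² follows from
the mean. When the observed spread of log-variances is at or below the
chi-square sampling noise (no detectable heterogeneity) d0 = ∞ and the
shrinkage target is the geometric mean of the sample variances, making a
matrix of identical per-probe variances an exact fixed point (moderated
t = pooled t). The moderated t uses the posterior variance
(d0·s0² + d·s_g²)/(d0 + d) on d0 + d df. The implementation was
cross-checked against the Bioconductor reference implementation on a fixed
instance (agreement ≈1e−14 in d0, s0², t and p); those values are frozen
in the unit tests.

Stage-course ranking within a tissue computes, per probe, the two-sample
Hotelling T² for each of the three stage pairs — with one response per
probe this is the squared pooled-variance t — and ranks by the maximum
over pairs (ties broken by probe id). The moderated multivariate
alternative is deliberately out of scope. A probe with zero pooled
variance scores 0 when the group means agree and +inf when they differ.
FDR is Benjamini–Hochberg, controlled separately per stage contrast. PCA
is centered (not scaled) sample-space SVD of log2(CPM) values.

## Over-connection

The link population N is the multiset of miRNA–gene links restricted to
the miRNAs actually tested in the contrast. DE miRNAs (raw p < 0.05) are
split by fold-change sign and each direction tested separately, matching
the per-direction "group" labels of the downstream tables. The p-value is
the upper tail P(X ≥ k) of the hypergeometric (the printed point-mass
formula is read through its stated "at least k" definition); binomial
coefficients are evaluated with log-gamma so populations of ~10⁵ links are
exact to double precision (checked against both exhaustive enumeration for
N ≤ 12 and an independent survival-function implementation at scale). BH
adjustment is applied within each (contrast, direction) gene list;
significance at adjusted p < 0.10. The transcription-factor filter is a
case-insensitive substring match on annotated term names.

## Pathway analysis

Annotation transfer inverts pathway→gene membership through the target
links: a pathway's miRNA set is every miRNA with ≥1 target gene in the
pathway. The unit of analysis is the miRNA (the inverse-annotation
paradigm), avoiding gene-level knowledge bias; the gene-level reading is
not implemented. For each transferred set within the size bounds (default
3–500 after intersection with the tested universe), membership is
regressed logistically on the standardized ranking statistic r (default:
moderated t; a signed-rank normal-quantile transform is available). The
slope is the reported LOR — per SD of r, so magnitudes are comparable
across contrasts — with a Wald p-value; BH across pathways. Perfect
separation falls back to a ridge-stabilized IRLS fit (λ = 0.01) and is
flagged; flagged p-values are stabilized, not exact. The fit was verified
against a brute-force likelihood grid search (≤1e−4 in the slope) and the
null false-positive rate is calibrated to 5% ± 2% in simulation.

## Per-sample enrichment scores

Gene activity is transferred from miRNA expression as
activity(g, j) = s · mean over distinct miRNAs targeting g of y(m, j),
with s = −1 by default (miRNAs repress their targets); sign and
aggregation (mean/sum) are options. The per-sample score of a gene set is
a weighted Kolmogorov–Smirnov random walk over the per-sample gene
ranking, in the GSVA family: per gene, an across-sample Gaussian-kernel
CDF estimate (bandwidth = SD/4) expresses where the sample sits in that
gene's distribution; per sample, genes are ranked by the estimate (ties by
gene id); the walk steps up by w^τ (normalized within the set) on set
genes and down by w^τ (normalized outside) otherwise, with w the centered
rank magnitude |rank − (G+1)/2| and τ = 1; the score is the signed maximal
deviation (a max.pos + max.neg variant is available). Weighting both the
in-set and out-of-set steps makes the score of a set's complement the
exact negation of the set's score and keeps |score| ≤ 1.

Two design choices are deliberate. First, the kernel estimate is computed
on the within-gene across-sample fractional ranks (bandwidth = SD of the
ranks / 4), not on raw values: the score is then an exact function of
within-gene orderings, hence invariant under any strictly monotone
per-gene transform — the natural contract for a rank-based statistic. A
kernel on raw values (affine-invariant only) is available via
`kernel_input="values"`. Second, a constant gene row has no spread and
receives the neutral estimate 0.5 everywhere. Sets are intersected with
available genes and need ≥2 members; scoring needs ≥3 samples. Scores are
compared between tissues with the same moderated linear model; terms
significant at raw p < 0.05 feed the semantic reduction.

## Semantic reduction

IC(c) = −ln p(c) (Lin similarity is base-invariant);
sim = 2·IC(MICA)/(IC(t1)+IC(t2)) with ancestors including the terms
themselves, sim(t,t) = 1, and sim = 1 by convention when both ICs vanish.
Reduction is greedy with a pairwise ceiling C (default 0.7): terms sorted
by ascending corpus probability (rarest = most specific first, ties by
id), each retained unless its similarity to an already-retained term
exceeds C, in which case that term becomes its representative. Enrichment
p-values are deliberately not used in the reduction. The retained set is
maximal: re-adding any dropped term would violate the ceiling. Cluster
size and representatives are exported for treemap-style display;
proportionality choices are left to the plotting layer.

## Seed-site prediction

The seed is miRNA nucleotides 2–8. Site classes on the UTR (5'→3' DNA):
7mer-m8 = reverse complement of positions 2–8; 8mer = 7mer-m8 followed by
A; 7mer-A1 = reverse complement of positions 2–7 followed by A; 6mer = the
bare 2–7 complement. Coordinates are 0-based half-open; overlapping
classes at one seed-match locus resolve by specificity
(8mer > 7mer-m8 > 7mer-A1 > 6mer); N never matches. Context scoring,
conservation and accessibility are out of scope — the prediction step
exists so that database-derived link tables can be replaced by sequence
scanning in tests. Pooling across family members is by union (an
intersection flag exists).

## Synthetic data

The generator emulates the study design: 2,255 miRNA probes plus 13
negative-control probes; 27 samples = {CVG, NC, OV} × stages {13, 14, 15}
× 3 technical replicates. Counts are negative binomial
(Var = μ + φμ², default φ = 0.05, as expected of tight technical
replicates of a nuclease-protection assay) around per-probe log-normal
baseline abundances (σ = 1.0, giving a median probe ≈ e^−1/2·L/2255 counts)
scaled by log-normal library sizes (median 5·10⁵ reads, σ = 0.4 —
heterogeneous depths at realistic MiSeq per-sample throughput).
Negative-control probes sit at 2% of the median miRNA baseline and receive
no effects. Planted effects are multiplicative on the mean, matching log2
fold-change semantics; the default plants a miR-183-family-like trio at
+2 log2FC in CVG at stage 13. All generators are pure functions of
(config, seed); one integer seed is split into fixed per-generator streams
via `SeedSequence(seed, spawn_key=(stream,))`.

Companion generators produce: a bipartite target multiset (per-miRNA
Poisson out-degree, optional hub genes with multiplied link probability),
random pathway sets with an optional planted set, a random tree-shaped
ontology with p(child) = p(parent)·U(0.3, 0.9) (monotone by construction),
and random UTRs with planted seed sites whose flanking bases are fixed so
a planted site cannot be upgraded to a higher-priority class by chance
context.

What the generator does not model: FFPE degradation chemistry, plate or
processor batch effects, probe-specific capture efficiencies, biological
(between-individual) variation — the real study has one specimen per
stage, so its stage contrasts confound individual and stage. Passing
recovery tests on this generator therefore demonstrates the statistical
machinery under the design's sample sizes and noise level, not robustness
to those unmodeled artifacts.

## Problem sizes and checks

The test suite and `scripts/acceptance.py` use these sizes, chosen to
exercise each property at meaningful scale: exhaustive hypergeometric
enumeration for all N ≤ 12; BH versus a quadratic-time reference on 1000
random vectors; null DE calibration on 1000 probes (3 vs 3; KS distance
to U(0,1) < 0.05); null logistic GSA on 1000 pathways per replicate (false
positive rate 5% ± 2%); planted-trio recovery on the full 2,255-probe
design over 100 seeds (top-10 membership ≥95%); hub-gene recovery on a
500×500 target table with multiplier 5 over 100 seeds (minimum adjusted
p ≥95%); planted-pathway recovery end to end (200 miRNAs, 300 genes, 40
pathways) over 100 seeds (top-5 ≥90%); walk-score brute-force oracles on
5-gene toys; seed-site agreement with a sliding-window oracle on 100
random (miRNA, UTR) pairs. The acceptance script reports recovery rates
over 25 fresh replicates per quantity.

## Known limitations

- Flagged (separated) GSA fits report stabilized, not exact, p-values.
- The per-sample score walk is quadratic in samples within the kernel
  estimate (n² per gene) — fine for dozens of samples, not thousands.
- The time-course statistic is the univariate max-pairwise T²; it ignores
  correlation between stage pairs and is a ranking device, not a test with
  calibrated p-values.
- Identifier matching is exact and case-sensitive throughout; no alias
  resolution.
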