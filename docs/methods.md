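# Methods

## Scope and data model

The package analyzes circRNA expression at the level of back-splice
junction (BSJ) counts: for each candidate circle and each sample it
expects the number of reads spanning the BSJ and the numbers of linear
reads spanning the same splice donor and splice acceptor sites.
Upstream read alignment and circRNA calling are out of scope; candidate
loci are inputs, carried as 0-based half-open coordinates (BED
convention) with the acceptor at `start` and the exclusive donor at
`end` on the annotated strand. Likewise, single-cell clustering is out
of scope — cluster labels are inputs to the composition analysis — and
migration profiles arrive as 1-D depth-intensity vectors, not images.

## Quantification statistics

**RPM.** `rpm[i,j] = bsj[i,j] / library_size[j] × 10⁶`. The denominator
is the per-sample total read count supplied in the sample metadata; the
package does not decide between raw and mapped totals, which is the
caller's choice of metadata.

**CTL ratio.** `ctl[i,j] = bsj[i,j] / ((donor[i,j] + acceptor[i,j])/2 +
c)` with pseudocount `c = 1` by default. The pseudocount keeps the
ratio finite where no linear reads span either site; `ctl = 0` exactly
where `bsj = 0`.

**High-abundance filter.** A candidate is retained when its mean BSJ
count across all samples is at least `min_mean` (default 5). The rule
is *inclusive* at the boundary: phrased as a total over 15 samples, a
candidate with exactly 75 reads is kept. The equivalent strict total
formulation ("more than 75 in total") disagrees only at exactly the
boundary; inclusivity follows the "at least five on average" reading,
and `min_mean` is exposed for callers who want the other convention.

**Caller harmonization.** Two candidate lists are merged on identical
loci. Dual-caller candidates pass automatically; single-caller
candidates are marked for review. Manual artifact inspection is modeled
as an explicit exclusion list — no automated artifact heuristic is
claimed — and excluded candidates can be dropped.

**Median-of-ratios normalization.** The reference is the row-wise
geometric mean over rows detected (count > 0) in all samples; each
sample's size factor is the median ratio of its counts to the reference
over those rows. Scaling one sample's column by `c` also rescales the
reference by `c^(1/m)`, so equivariance is a statement about
size-factor ratios, which is how the property is tested.

**log2 z-scaling.** For marker heatmaps, rows are transformed to
`z = (log2(x + 1) − mean) / sd` with sample sd (ddof = 1). Rows that
are constant up to floating-point roundoff map to all-zero z-scores;
this is a display convention, not a statistic.

## Differential and coupling statistics

**Expression scale.** The global-shift test runs on per-candidate
`log2(RPM + 1)` averaged over replicates within each state. The source
analysis does not state its scale; the log transform stabilizes the
paired differences that the rank test sees, and the scale is a
parameter of the drivers, not hard-coded.

**Normality gate.** Both paired vectors and their differences pass
through the D'Agostino–Pearson omnibus test (K² = Z²_skew + Z²_kurt
against χ²₂; scipy's `normaltest`). If any of the three fails at
α = 0.05 the Wilcoxon matched-pairs signed-rank test is used, otherwise
a paired t-test. Applying the gate to the differences as well is the
conservative reading of "the data were not normally distributed"; with
n < 8 the gate is undefined and the caller must force a test choice.

**Signed-rank test.** Zero differences are dropped (Wilcoxon's original
convention); ties in |d| receive midranks. For n ≤ 25 the two-sided
p-value is exact: the null distribution of the positive-rank sum is
built by dynamic programming over doubled midranks (doubling makes tied
midranks integral), which reproduces full 2ⁿ sign enumeration — the
test suite checks this identity against literal enumeration up to
n = 12 — and the two-sided p doubles the smaller tail, capped at 1.
Beyond n = 25 a normal approximation with the standard tie-corrected
variance is used (no continuity correction, matching the common
uncorrected implementation). All pairs equal yields the degenerate
result p = 1 with zero pairs used.

**Fold changes.** `fc = (mean_b + c)/(mean_a + c)` with a default
pseudocount of 1 on the RPM scale (whether the original analysis used
one is unstated; the parameter is explicit). Classification is strict:
"up" requires `fc > threshold` (default 2), "down" `fc < 1/threshold`;
a fold change of exactly 2 is "unchanged", matching the "more than
two-fold" wording. The same strictness applies to the differential
record filter (`p < 0.05`, `basemean > 10`, `|log2FC| > 0.5`) and the
single-cell thresholds.

**Coupling regression.** Ordinary least squares of linear-host log2
fold changes on circRNA log2 fold changes; `R²` is the squared Pearson
correlation and the slope test uses `F = r²(n−2)/(1−r²)` on (1, n−2)
df, algebraically identical to the squared slope t-statistic (asserted
in tests).

**Multiple testing.** Benjamini–Hochberg step-up (the source reports
adjusted p-values without naming a procedure; BH is the field default),
delegated to statsmodels and cross-checked against a hand step-up
implementation.

## Construct design

The junction context is assembled from the circle's exon sequences:
back-splicing joins the 3' end of the *last* exon to the 5' start of
the *first*, so `junction_seq` is the final `flank` nt of the last exon
followed by the initial `flank` nt of the first (a single-exon circle
wraps onto itself).

**shRNA pair.** Two 21-nt target windows whose centers sit at −3 and
+3 nt from the junction. "Placed 3 nt upstream/downstream" is read as a
window-center shift — the alternative (window edge 3 nt away) would
leave one window junction-free and hence not circle-specific. Each
hairpin insert is sense + loop + antisense + XhoI site (CTCGAG) +
termination signal. The loop default is the classic pSUPER-type
TTCAAGAGA; vendor loops are configurable since the original loop is not
printed in the main text.

**agoshRNA.** An 18-nt stem centered on the junction (≥ 5 nt on each
side). The first transcribed base is forced to A (U6 +1 preference; the
substitution is recorded when the template base differed). One A-C
mismatch is placed at the stem base: the antisense 3' position that
would pair the +1 A carries C instead of T, recorded as a substitution.
A poly-T signal terminates pol III transcription and BbsI overhangs
(ACCG/AAAC) flank the annealed oligo duplex. The mismatch position and
all sequences are parameters; the defaults are design conventions, not
claims about the original oligos (which live in unpublished
supplementary tables).

**Off-target scan.** Mature guides are screened by an ungapped scan of
both strands of every transcript for the guide's reverse-complement
site with at most `max_mismatch` (default 2) mismatches *and* at least
one exact match run of `min_word` (default 7) bases — the seed
requirement of a word-based aligner. E-values are not computed; the hit
criterion is the mismatch count. Model transcripts (XM/XR/XP prefixes)
are excluded by default. The scanner is vectorized; the test suite
holds it equal to a position-by-position string oracle.

## Synthetic data

The generators produce inputs with the statistical structure the
analyses assume; they are first-class, tested code.

**Landscape counts.** Defaults mirror the study design: 417 candidates,
5 cell states × 3 replicates. Counts are negative binomial
(mean/dispersion parameterization, `var = μ + αμ²`) — the standard
noise model for RNA-seq junction counts; the source states none.
Per-candidate baselines are lognormal (σ = 0.8) around a mean of 8 BSJ
reads, so a realistic minority of candidates falls below the abundance
filter. A fraction `frac_up` (default 0.7, reflecting the large
upregulated majority in the original landscape) gains `effect_log2fc`
(default 1.0) log2 units per state step; host-coupled candidates
(default 30%) have linear-junction means tracking their circ means at a
5:1 ratio, the rest keep state-1 linear means, which makes CTL ratios
rise for upregulated host-independent circles. Expected counts scale
with per-sample library sizes drawn uniformly from 8–12 M reads so that
RPM normalization is exercised. One `numpy.random.Generator` per call,
seeded explicitly; identical parameters and seed give bit-identical
output.

**What the generator does not emulate:** positional read biases,
multi-mapping artifacts, caller-specific false positives, correlated
replicates, batch effects, and any coupling between abundance and
dispersion. Passing recovery tests therefore demonstrates correctness
of the statistics under the assumed NB model, not robustness to the
full messiness of real libraries.

**Cluster tables.** Cells are assigned to conditions by independent
Bernoulli draws: unbiased clusters at p = 0.5, planted clusters at
`bias_level` (default 0.9) toward their assigned condition. The chance
a planted cluster is called by the strict >75% rule is the exact
binomial tail P(X > 0.75 n), which the tests verify by Monte Carlo; at
500 cells/cluster and bias 0.9 the recovery is deterministic for
practical purposes.

**Depth profiles.** Intensity is spread uniformly within each subregion
(VZ = [0, lo), DL = [lo, hi], UL = (hi, 1], identical to the
quantifier's boundary conventions) over grid-cell midpoints, so a
noiseless profile round-trips exactly; Gaussian noise is added and
clipped at zero.

## Migration quantification

Depth is normalized per section to [0, 1] (0 = ventricle, 1 = pia) by
the caller; the original per-image normalization protocol is not
reproducible from the main text, so normalization is explicitly the
caller's responsibility. Bins are equal-depth intervals numbered from
the pia; boundary mass goes to the pia-ward bin (ties are measure-zero
on continuous profiles). Subregion boundaries are the Ctip2-positive
interval, with boundary positions assigned to DL. Bin and subregion
percentages each sum to 100 by construction, and all outputs are
invariant to intensity rescaling.

## Problem sizes and numerical choices

The test suite and acceptance script run the landscape at the study
scale (417 × 15). Null calibration uses 1000 simulated landscapes; the
type-I error of the gated pipeline is required to stay ≤ 0.07 at
nominal 0.05. Mean-recovery tests use 2000 replicates per state so the
5% agreement band measures the generator rather than NB sampling noise
(at dispersion 0.3 and 50 replicates the relative standard error alone
is ≈ 9%). Oracle-equivalence suites use 100 random instances per
operation. Exact signed-rank enumeration is tested to n = 12 (2¹²
assignments); the DP path extends exactness to n = 25.

## Known limitations

* The abundance filter's inclusive boundary and all strict threshold
  readings are conventions taken from wording; real pipelines differ at
  measure-zero boundary cases.
* The off-target scan is ungapped and E-value-free; it approximates a
  word-seeded aligner's sensitivity for short near-perfect matches only.
* Construct defaults (loops, overhangs, stem length, mismatch position)
  are reasonable conventions, configurable but not validated against
  the original oligo designs.
* The NB generator's independence assumptions make the null calibration
  a best-case check; correlated candidates would inflate the global
  shift test's effective significance.
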