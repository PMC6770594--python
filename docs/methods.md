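# Methods

## The model

Benford's law (the first-digit law) states that in many naturally
occurring collections of numbers spanning several orders of magnitude,
the leading significant digit *d* is distributed as

    E_d = log10(1 + 1/d),        d = 1, ..., 9,

so digit 1 leads ~30.1% of values and digit 9 only ~4.6%. Gene expression
matrices — both bulk and single-cell — adhere closely to this law when
all genes are pooled. Individual genes, however, differ: a gene whose
values within a cell type are confined to a narrow range has a
concentrated first-digit distribution and deviates strongly from Benford.
That deviation is quantified by the mean absolute error

    MAE = (1/9) * sum_{d=1..9} |A_d - E_d|,

where `A_d` are observed digit frequencies. MAE ranges from 0 (perfect
adherence) to `2*(1 - log10(10/9))/9 = 0.2120539` (all mass on digit 9,
the rarest Benford digit). The package exposes this maximum as `MAX_MAE`.

Two orientations of the calculation are used:

* **gene-centered** — digits of one gene's values across the cells of one
  group; ranks genes within a group;
* **cell-centered** — digits of one cell's values across a fixed gene
  panel; summarizes a cell by a single number per panel.

The classification idea: per group, select the k (default 200) genes with
the most extreme gene-centered MAE; score every cell against every
group's panel (cell-centered); feed the resulting cells x groups score
matrix to a standard classifier. Two comparator routes replace the MAE
ranking with mean expression, or with a Welch t-test differential-
expression ranking whose panels are scored by the polygenic score
`PS = sum_i s_i * e_i` (sign `s_i` = direction of regulation, `e_i` =
normalized expression).

## Numerical choices

* **Digit extraction** reads the digit off a scientific-notation decimal
  rendering with 12 significant digits, so binary-float artifacts (a
  stored `0.2999999999999998` meaning 0.3) cannot flip the digit. The
  vectorized path rounds the mantissa to 12 significant digits and falls
  back to the string rendering for the rare values whose rounded mantissa
  leaves [1, 10). Both paths are property-tested against an independent
  string-prefix oracle.
* **Zeros carry no digit.** They are excluded from every digit histogram
  and reported in `n_zero_excluded`. The MAE denominator stays 9 even
  when digits are unobserved.
* **All-zero panel fallback.** A cell expressing none of a panel's genes
  receives the theoretical maximum MAE (`MAX_MAE`) with a logged warning:
  it is maximally non-Benford on that panel, and dropping it would break
  the fixed-width feature table the classifiers need.
* **Eligibility floor.** Gene-centered MAE requires at least
  `min_nonzero = 10` digits per group (configurable); an MAE estimated
  from one or two digits would otherwise dominate the panel extremes.
* **Ties** in every ranking are broken by gene id ascending (and for DE
  by |t| descending first), so identical inputs give byte-identical
  panels.
* **Goodness of fit** is Pearson's chi-square against `E_d` on 8 degrees
  of freedom, no continuity correction; the null hypothesis is adherence,
  so p > 0.05 reads "consistent with Benford". Note that with very many
  values the test detects minuscule deviations; the MAE is reported
  alongside so users can weigh magnitude against significance.
* **MRN normalization** uses the geometric-mean-1 convention for size
  factors (only ratios between factors matter downstream) and requires at
  least one gene positive in every sample. TPM input bypasses MRN.
* **Welch vs Student.** The DE route uses Welch's unequal-variance
  t-test; users comparing against pipelines that assume equal variances
  should expect small rank differences. Equal means get sign +1 (fixed,
  logged choice). Raw p <= alpha (default 0.05) with no multiple-testing
  correction is deliberate: the route mimics the plain t-test ranking it
  is compared against, not a calibrated discovery procedure.
* **PS uses normalized (or TPM) values without log transform.**

## Evaluation harness

The 80/20 split is stratified by group (otherwise the smallest group
could vanish from a split) and deterministic given a seed. Panels are
derived from training samples only; because each sample's panel scores
depend only on its own column, test samples cannot leak into panels,
tuning, or fitted models — a property the suite verifies by replacing
test columns with noise and asserting byte-identical panels and models.

Five learners are tuned by stratified 10-fold cross-validation on the
training scores with small standard grids: radial SVM (C in
{0.25, 1, 4, 16}, gamma = scale-heuristic x {0.5, 1, 2}), linear SVM
(C in {0.25, 1, 4}), random forest (500 trees, max_features 1..G),
nearest-shrunken-centroids (10 log-spaced shrinkage thresholds), and LDA
(no grid). SVM probabilities come from Platt calibration
(`CalibratedClassifierCV`, ensemble=False, deterministic folds). Features
are standardized inside the CV pipeline for the SVMs, LDA and the
centroid classifier; the forest sees raw scores. The "pam" learner is the
nearest-shrunken-centroids classifier (the learner ML tuning frameworks
label `pam`); partition-around-medoids proper is a clustering method and
cannot act as a supervised learner in this harness.

Evaluation is the one-vs-one multiclass AUC (Hand-and-Till-style): the
mean over unordered class pairs of the two directed pairwise AUCs,
computed from the corresponding probability columns restricted to the
pair's samples. The whole split-tune-test procedure repeats over
consecutive seeds (default 10) and reports per-algorithm median AUC and
IQR. Group separations of individual score columns are tested with the
two-sided Wilcoxon rank-sum (exact enumeration when both sides have <= 25
untied values, normal approximation with tie correction otherwise).

## The synthetic world

Real expression data are not redistributable inputs here, so the
generator plants the structure the method exploits, with known truth:

* **Background genes** (default 5,000) are `floor(10^U)`,
  `U ~ Uniform[0, 4]`. Flooring never moves a value across a
  leading-digit boundary, so these are *integer counts with exactly
  Benford first digits* — they calibrate the GOF test (>= 95% of cells
  pass at alpha = 0.01) and exercise the MRN path on realistic input.
* **Marker genes** (default 200 per group, disjoint) are, in their own
  group, narrow low-expression rounded lognormals (median 7 counts,
  log-sd 0.1) — the empirical profile of Benford-deviant genes: narrow
  and lowly expressed. In other groups they follow the background law
  scaled by 0.2 (broad, Benford-adherent, moderate mean), which makes a
  group's own markers simultaneously its most Benford-deviant *and* its
  lowest-expressed genes, so the high-MAE and low-mean-expression panels
  largely coincide — the overlap structure observed in real data.
  Bernoulli dropout (rate 0.3) overlays zeros on marker entries.
* **DE genes** (default 200 per group) are broad lognormals (log-sd 0.5)
  with median 5,000 in the focus group and 500 elsewhere: classical
  highly expressed differential markers. They dominate the t-test
  ranking without being Benford-deviant, keeping the DE route's panels
  disjoint from the Benford route's.

Group sizes default to (374, 173, 138, 105, 69, 159) — six groups,
1,018 cells, mirroring a published six-cell-type single-cell dataset —
with a fixed default seed (1004); a single seed drives deterministic
per-block substreams.

What the generator does **not** emulate: negative-binomial mean-variance
trends, ambient RNA, batch effects, doublets, gene-gene correlation, or
library-size gradients. Passing tests therefore demonstrate that the
implementation is correct and that the method recovers planted
Benford-deviant structure under idealized noise — not that the method
attains any particular accuracy on real tissues.

## Problem sizes used in the test suite

The acceptance-style checks run the full 1,018-cell reference scenario:
top-200 panel recovery of planted markers per group, a 10-repeat
radial-SVM evaluation (with 3 permuted-label null repeats), digit-oracle
agreement on 10^6 log-uniform values, GOF calibration over 1,000
replicates of 10,000 Benford draws, and size-factor recovery on a
500-gene, 3-sample Poisson design. Faster unit tests use a 3-group,
100-cell scenario. These sizes were chosen so the whole suite runs
comfortably on a single CPU while keeping every estimate's Monte-Carlo
error far from the asserted margins.

## Known limitations

* The chi-square test's power grows with n; on full matrices it rejects
  adherence even when deviations are visually negligible. Interpret it
  jointly with MAE.
* First-digit distributions are not invariant under normalization in
  general; every matrix records the `value_kind` that fed each score.
* The DE route's panels depend on group sizes through the Welch degrees
  of freedom; with very unbalanced designs, genes differential in *other*
  groups can outrank the focus group's own.
* HDF5/loom/h5ad ingestion is future work; inputs are dense CSV/TSV,
  MatrixMarket triplets, or GCT `#1.2`.
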