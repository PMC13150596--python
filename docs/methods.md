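# Methods

## Synthetic spectra: what is emulated, and what is not

Each replicate spectrum is generated as

    x = (shared bands + class markers) · (1 + ε_scatter) + baseline + noise

where every band is a Gaussian `a·exp(−(λ−c)²/2σ²)`, `ε_scatter ~
N(0, scatter_sd)` is a per-replicate multiplicative factor, the baseline is
a straight line whose endpoint offsets are drawn uniformly in
±`baseline_drift_max`, and the noise is i.i.d. Gaussian per point. A
Gaussian band shape was chosen over Lorentzian/Voigt because the
classification machinery under test is insensitive to the line shape; only
smooth overlap between classes matters.

Default study conditions: 15 class-A ("LU") and 18 class-B ("MI") samples;
UV-vis on 240–400 nm at 1 nm (161 points) in triplicate, FTIR on
1800→600 cm⁻¹ at 2 cm⁻¹ (601 points, stored descending as instruments
export it) in duplicate; `scatter_sd` 0.05, `baseline_drift_max` 0.02 AU,
`noise_sd` 0.01 AU — a mid-grade bench spectrophotometer regime. Class
markers sit at the discriminant positions known for the Lupinus/Mimosa
problem — A: 259 nm, 1658 cm⁻¹; B: 284 and 356 nm, 1561 and 1103 cm⁻¹ —
with amplitudes 0.12–0.15 AU (12–15× the noise sd) and widths of 2–3 nm /
6 cm⁻¹.

Two deliberate structural choices:

- The shared-band envelope places its global maximum (≈248 nm / ≈1030 cm⁻¹)
  away from every marker. Per-spectrum min–max normalization divides by the
  spectrum maximum; if a marker perturbed that maximum, the rescaling would
  smear the class difference over the entire axis and any column would
  classify, making variable selection meaningless as a localization tool.
- Within a class the clean signal is identical across samples; all
  within-class variance comes from scatter, drift and noise. Real extracts
  add per-sample chemistry (concentration differences, co-extracted
  interferents), so a perfect synthetic classification rate does not imply
  the same on real data — it shows the pipeline recovers planted structure
  under instrument-like nuisances.

Determinism: one `numpy.random.default_rng(seed)` drives all draws in a
fixed sample/replicate order, so identical configs are bit-identical.

## Preprocessing

Chain order: Savitzky–Golay smoothing → baseline correction → per-spectrum
min–max to [0, 1] → mean-centering. SG uses a 2nd-order polynomial over 13
points; edges are handled by evaluating the first/last full-window
polynomial at the edge positions (no shortening), so an order-≤2 signal
passes through exactly. The baseline method defaults to
`linear_endpoints` (subtract the chord through the first and last point —
the standard offset/tilt correction for ATR work); a pure `offset` mode
(subtract the minimum) is provided. Since min–max normalization follows,
the residual difference between baseline models is second-order for
classification.

Mean-centering is the only cross-row stage. Exploratory analyses center on
all samples; supervised stages refit the column means on the Kennard–Stone
training partition and apply them to the test partition, so no test
statistic enters the model. Kennard–Stone itself is run on the un-centered
(row-wise preprocessed) matrix — subtracting one common mean vector leaves
every pairwise Euclidean distance unchanged, so the split is identical
either way.

A constant spectrum is rejected by min–max as degenerate (a dead detector
or a blank), rather than silently mapped to zeros.

## Exploration

PCA is the SVD of the centered matrix; explained variance is
`100·σᵢ²/Σσⱼ²` and the sign of each loading column is fixed so its
largest-magnitude element is positive (reproducible plots across BLAS
builds). The input must already be centered; visibly uncentered input is a
contract error, not silently fixed. HCA builds the dendrogram from
Euclidean distances with average linkage by default (complete and Ward
available); the settings of the original study are unrecorded, so these
defaults are a documented substitute, not a reproduction. The two-group
purity statistic cuts the tree at the top merge and scores each leaf
against its cluster's majority class.

## Partitioning

Kennard–Stone: the first two picks are the farthest pair, each later pick
maximizes its minimum distance to the already-picked set; all ties break
toward the lexicographically smallest original index (pair), which makes
the order deterministic and permutation-consistent. The stratified split
runs KS inside each class with quota `floor(f·n_class + 0.5)`; at f = 2/3 on
15 + 18 samples this yields the canonical 10 + 12 = 22 train / 11 test
division. Whether the original study ran KS per class or globally is not
recorded; per-class is the only variant that guarantees those printed
counts, and is the default.

## Variable selection

Both searches minimize the same cost: leave-one-out LDA misclassification
fraction on the training partition. LOO was chosen over k-fold because it
is deterministic and the training set is small (n = 22). "Selection
windows 1–10" is interpreted as candidate subset sizes 1–10, the standard
SPA formulation.

SPA grows, from every start column, a chain that repeatedly appends the
column with the largest residual norm after projection onto the orthogonal
complement of the chain's span (sequential Gram–Schmidt deflation; columns
whose relative residual falls below 1e−10 become ineligible). Every prefix
of every chain is scored; the winner is the minimum-cost subset with ties
broken toward fewer variables, then the smaller start index (parsimony
first).

GA chromosomes are variable-length lists of ≤ 10 distinct column indices
(the cap is native to the encoding, no repair step). Fitness is 1 − LOO
error; selection is tournament-of-2; crossover (probability 0.60) uniformly
exchanges genes then de-duplicates and truncates; mutation replaces each
gene independently with probability 0.05 by an unused index ("5 %
mutation" is read per-gene); one elite survives each generation, so the
best-ever fitness trace is non-decreasing. Deterministic given the seed.
Fitness evaluations are memoised per sorted index set (the cost is a pure
function of the subset on a fixed partition).

Fisher weights `(μ_A − μ_B)²/(s²_A + s²_B)` (unbiased variances) rank the
selected variables; each is attributed to the class with the larger mean.
A zero pooled variance with distinct means is reported as an infinite
weight rather than raised.

### Known limitation: plateau ties in the count-based cost

The 13-point smoothing window spreads each narrow marker band into a
plateau of columns whose LOO error is exactly zero on 22 training samples.
The discrete cost cannot rank within that plateau, and the deterministic
SPA tie rule then returns the plateau's smallest-index (edge) column —
typically 4–6 grid steps off the band center, occasionally a marginal
column that generalizes slightly worse than the center. Selection should
therefore be judged at the resolution of the smoothed band support (about
±6 grid steps), not the exact grid point; the recovery tests use that
tolerance. A continuous (Mahalanobis-risk) cost would break these ties but
would no longer be the misclassification count the models report.

## Discriminant model

Classical two-class LDA: pooled within-class covariance `S_p =
scatter/(n−2)`, weight `w = S_p⁻¹(μ₊ − μ₋)`, bias placing the boundary at
the mean midpoint (equal priors — the 15/18 design is near-balanced; a
proportional-priors flag exists). With equal priors this is exactly the
Mahalanobis-closest-class rule, which the tests use as an independent
oracle. If `cond(S_p) > 1e10`, a ridge `λ·(tr S_p/k)·I` is added with λ
escalated from 1e−8 by decades and recorded on the model (λ = 0 identifies
a classical fit); escalation is capped at 1e−2, beyond which the fit raises.
A score of exactly 0 goes to the negative class, and an unsalvageable LOO
fold counts as a misclassification (with a warning) so the confusion table
always totals n. The positive class defaults to the first label in sorted
order ("LU" before "MI").

Figures of merit are computed in exact rational arithmetic scaled to
percent, so identities such as ACC = (SEN·(TP+FN) + SPE·(TN+FP))/n hold to
the last bit.

## Pipeline and problem sizes

One run seed is expanded by `numpy.random.SeedSequence` into independent
per-stage seeds (data generation, GA), so changing the GA settings never
perturbs the simulated data. With `method=both` the GA is run at the three
standard population/generation combinations (100/100, 200/200, 300/300)
and the best-cost result is flagged; single-method runs use the configured
GA size. The reference workflow and the acceptance script use the default
33-sample datasets and GA 100/100 — at these sizes a full two-modality run
with the 20-search cap check completes in a few minutes on one CPU. The
report joins selected variables to a static band-annotation table within
±3 nm / ±6 cm⁻¹; variables outside every window are listed as unannotated.

Outlier handling is reporting-only by design: exploratory diagnostics are
emitted, but no sample is ever removed automatically.
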