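# Methods

perioscope analyzes transcriptome time courses of synchronized budding-yeast
populations: cultures arrested with alpha-factor, released at t = 0, and
sampled every 5 minutes to 60 minutes and every 10 minutes to 150 minutes
(22 points). After release the population cycles roughly twice within the
sampled window while individual cells progressively desynchronize, so
population-level periodic expression looks like a cosine whose amplitude
decays over time.

## Periodic model and score

Each gene's log2 fold-change trajectory y(t) (fold change to the gene's own
temporal mean) is fit with

    f(t) = m + A · exp(−σ t) · cos(2π (t − φ) / λ)

where λ is the period (the cell-cycle length seen by that gene), φ the first
peak time after release, A the amplitude, m the mean level and σ the
synchrony-decay rate. The fit is an exhaustive scan over a discrete grid —
λ ∈ [40, 130] min in 1-min steps, φ ∈ {0, 1, …, λ−1} min, σ ∈ {0, 0.002,
0.004, 0.008, 0.016}/min — with (m, A) solved per grid point by ordinary
least squares on the regressors {1, exp(−σt)·cos(2π(t−φ)/λ)}. The 1-min φ
grid gives peak-time estimates finer than the sampling interval. Ties break
deterministically toward the smallest λ, then φ, then σ; a negative OLS
amplitude is folded into a half-period phase shift. No shape-warping term is
included: allowing the cosine to deform markedly inflates false positives.
One global period is used per gene across the whole course; cycle-specific
timing is the job of the phase classifier below.

The periodicity score is the Gaussian log-likelihood-ratio statistic against
the constant model,

    score = (n/2) · ln(RSS_flat / RSS_periodic),

zero when the periodic fit offers no improvement and increasing with fit
quality. A BIC with k = 5 parameters, n·ln(RSS/n) + k·ln(n), penalizes good
fits on trajectories with few valid points, and is divided by the fitted
amplitude so that vanishing-amplitude fits can never pass (A = 0 maps to an
infinite normalized BIC). Genes with fewer than 13 valid time points are
excluded outright.

### Cutoff calibration

Score scales are implementation-specific, so no absolute threshold is
hard-coded. Both cutoffs are calibrated on a reference set of known-periodic
genes at a target false-negative rate (default 20%): with n reference genes
and k = ⌊fnr·n⌋, the score cutoff is the (k+1)-th smallest reference score
and the normalized-BIC cutoff the (k+1)-th largest reference value, so
exactly k reference genes fail each criterion when values are distinct. The
two cutoffs are calibrated marginally; because score and normalized BIC are
only partially correlated, the joint reference failure rate is somewhat
above the per-criterion rate (~30% at defaults), which the
`CalibrationResult.realized_fnr` field reports.

## Clustering and peak-time shifts

Complete log2fc trajectories are clustered by k-means (best of 10 restarts,
default k = 12 so that the ~5 periodic waves, the alpha-factor-response
decay class and background each get room). A cluster is flagged oscillatory
when its centroid passes the calibrated score cutoff; flagged clusters are
ordered by centroid peak time. Note that k-means may split one tight wave
into two clusters (both flagged, same peak time) when that reduces
within-cluster variance more than splitting the background does — the set of
distinct flagged peak times, not the cluster count, is the meaningful
output.

Timing differences between two strains are summarized over genes that pass
the oscillation filter in both: mutant peak time is regressed on wild-type
peak time by robust local linear regression (lowess: tricube weights over a
20% span, 5 bisquare reweighting passes). Because φ is circular within a
cycle, mutant peaks are first unwrapped into [φ_wt − λ/2, φ_wt + λ/2). The
curve's mean vertical offset estimates a global onset delay; a local slope
different from 1 marks cell-cycle intervals the mutant traverses at a
different speed (with mutant time on the y-axis, slower mutant progression
appears as slope > 1).

## TF-network phase classification

A generic TF→target edge list is reduced to its oscillating subnetwork: a
TF is kept when at least 3 of its targets are measured and the mean
trajectory of its targets passes the (re-calibrated) periodicity-score
cutoff. Edges between retained TFs are oriented forward when the source's
targets peak before the target TF's targets.

Phase transitions are called from an ordered "classification set" of TF
groups peaking at G1/S, S/G2, G2/M and M/G1. Defaults take the canonical
G1/S factors (Swi4, Swi6, Mbp1) and late factors (Mcm1, Ace2, Swi5); the
S/G2 and G2/M groups are configuration-driven (the synthetic fixture
supplies stand-ins). Per TF, the mean target signal is interpolated with a
natural cubic spline to a 1-minute grid and a grid point is a detected peak
iff it strictly exceeds all 10 preceding and 10 following points (boundary
points with truncated windows are ineligible; ties are not peaks). A peak is
valid only if strictly later than every first-cycle peak assigned to the
previous group; the earliest valid peak per TF is assigned to the first
cycle and assigned peaks are averaged into the group's transition time. Only
the first cycle is classified — alpha-factor and osmotic stress act mainly
on the first cycle, and the fitted model's single global period cannot
represent cycle-specific phase lengths. G2 and M are merged: durations are
G1 = t(G1/S) − 0 (cycle start at release; an onset delay therefore counts as
G1), S = t(S/G2) − t(G1/S), G2M = t(M/G1) − t(S/G2). A strain in which no
group yields a valid peak gets an incomplete annotation rather than made-up
numbers. Replicate spread of the durations, rounded up to the minute, gives
the minimum detectable change in phase length (~5 min with 5 replicates at
default noise).

## Regulon delays and bud index

Delays between the MBF and SBF regulons (or one regulon across strains) use
lagged Pearson correlation: each target is centred to its temporal mean,
linearly interpolated to 1-minute steps (linear here, spline in the peak
detector — the two procedures are deliberately as specified for each task),
and averaged; for integer lags within ±40 min the correlation over the
overlapping support is computed without padding (the signals are short and
non-stationary, so circular correlation would wrap artefacts). The delay is
the arg-max lag, ties resolved toward the smallest |lag| and negative first.
Sign convention, stated because conventions differ silently between tools:
positive delay means the second signal lags the first, b(t) ≈ a(t − delay).
The ±40-min bound stays below one period so the estimator cannot lock onto
the next cycle's peak.

The bud index at each time point is (buds + large/2)/total, where "large"
daughter cells that cannot be distinguished from unseparated mothers are
split equally between the groups; lower/upper bounds count them entirely as
cells or buds.

## Synthetic data generator

The generator is first-class, tested code that defines the study
conditions. Periodic genes follow f(t) = A·exp(−σt)·cos(2π(t − φ −
onset)/λ) on the log2 scale around a mean read level m; expected reads are
m·2^f(t); observed counts are Poisson draws with a multiplicative unit-mean
lognormal factor (CV 0.2 by default) — the simplest over-dispersed count
model that exercises the read-depth and low-expression filters.
Alpha-factor-response genes decay as m·(1 + R·2^(−t/30 min)) with induction
ratio R ∈ [2.5, 7.7]; background genes are flat. The default library scale
(mean ~400 reads/gene, ~5·10^5 reads/column for the ~1000-gene panel) keeps
columns above the 7·10^4 depth filter; tests exercise the filter by
injecting a shallow column.

Strain presets carry the generating parameters: wild-type period 64 min
with schedule G1 = 14, S = 20, G2M = 30 and a 6-min MBF→SBF offset; the
cln1/cln2 double knockout 80 min with G1 12.3, G2M 48 and offset 12; the
cln1/cln3 double knockout 74 min with a 20-min onset delay; cln3 deletion a
5-min onset delay and 3-min offset; osmotic stress adds 11.5 min onset
delay (16.9 in the cln1 deletion); the cln2/cln3 double knockout produces
no periodic genes at all and a non-decaying alpha response. Values not
specific to a strain fall back to the wild type; the synchrony decay
default (0.004/min) keeps both cycles visible across 150 min. The 600
periodic genes form five tight waves (peak-time jitter SD 1 min, amplitude
1.0–1.2) mirroring the coherent expression waves of synchronized cultures;
30 MBF and 30 SBF targets share their group's exact generating peak so the
regulon offset is exact by construction; 16 alpha-response and 400
background genes complete the panel.

The TF fixture gives each classification-set TF 50 targets (large regulons,
matching generic networks with tens of targets per TF) peaking at the
preset's phase boundaries, plus distractor TFs (too few targets, or flat
targets) and 4000 flat ballast genes. The ballast matters: total-count
normalization divides by the column sum, and if periodic transcripts carried
a large fraction of the read mass the column totals would oscillate and
distort every trajectory; at ~10% periodic read mass (realistic for a
transcriptome) the residual common-mode is negligible.

Bud-count tables are multinomial draws over {cell, bud, large daughter} with
a budded-fraction bump peaking at 40 min for the wild type (shifted by any
onset delay) and 60 min for the cln2/cln3 double knockout.

What the generator does **not** emulate: read-level artefacts (mapping,
PCR/UMI effects), gene-length or GC biases, burst-like transcription noise,
cell-size covariates, second-cycle phase-length changes, and regulon target
lists with annotation errors. Passing tests therefore demonstrate that the
estimators recover their generating quantities under idealized but
realistically noisy conditions — not that the pipeline is robust to
annotation noise in real target lists.

## Numerical choices and edge cases

- Grid fits are vectorized over genes sharing a valid-point pattern; the
  arg-min over the grid visits combinations in tie-break order.
- RSS values are clipped at 0 (floating-point) and floored at 1e−12 inside
  logs; a numerically perfect periodic fit returns a capped score (1e6)
  with a flag rather than infinity.
- log2 transforms add a pseudo-fraction of half the smallest positive
  normalized value; centring uses the mean of log2 values (exactly zero-mean
  by construction, unlike log2 of the mean).
- Dropped time points are masked, not deleted, so time grids stay aligned
  across strains; re-running a pipeline stage on its own output is rejected
  by stage checks.
- Replicate merging warns (never fails) when the Pearson correlation of
  per-gene medians falls below 0.9.
- The lowess curve is collapsed to one fitted value per abscissa; slopes are
  finite differences on that curve.

## Problem sizes

Default analyses run a ~1,100-gene panel per strain (plus a ~4,500-gene TF
fixture and a 200-gene calibration reference) on the 22-point experimental
grid; a full strain analysis takes a few seconds on one CPU, and the whole
acceptance computation about ten. These sizes preserve the class structure
(five waves, two regulons, four TF groups, distractors) at desk scale.

## Known limitations

- The period grid's 1-min step bounds period resolution; the spline/linear
  1-min interpolations bound timing resolution. Quantities derived from
  them inherit ±1 min granularity.
- The score scale depends on the score definition, so thresholds quoted for
  other periodicity scores are not transferable; use the FNR calibration.
- The first-cycle peak of a very short G1 (≈12 min) sits close to the
  10-point eligibility edge of the peak detector; with weakly averaged
  (noisy) TF signals the G1/S peak can occasionally fall below 10 min and
  be discarded, leaving the annotation incomplete. Averaging more targets
  per TF (the default fixture uses 50) makes this rare.
- Cross-correlation delays assume the two signals share a waveform up to a
  shift; strong shape changes (for example amplitude collapse in one
  regulon) bias the estimate.
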