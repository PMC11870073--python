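# Methods

This note documents the models, estimators and numerical choices behind
`licklock`, in the order the pipeline runs. Times are seconds throughout;
coordinates are mm, with x positive toward the animal's right (ipsiversive
for right-hemisphere recordings; a flag flips this for left-hemisphere
data) and y positive in the protrusion direction.

## Behavioural segmentation

A licking bout is a maximal run of lick detections whose inter-lick
intervals are strictly below 0.5 s; a gap of exactly 0.5 s splits bouts
(the within-bout rule is "interval < 500 ms"). Single-lick bouts are
permitted and included in bout-transition analyses, since no minimum bout
size is part of the definition; they simply carry no lick-cycle phase.
Maximal tongue protrusion, when not measured by video, is taken 16 ms
after optical detection — the measured mean detection-to-protrusion lag.

Cell inclusion requires that every complex spike is followed by at least
8 ms without simple spikes (the physiological signature that both spike
types come from one Purkinje cell) and at least 20 analysable trials.
Violations are reported, never raised.

## Synthetic sessions

The generator is the package's test bed: it produces sessions whose latent
parameters are known exactly, so each estimator is validated by parameter
recovery rather than against irreproducible in-vivo statistics.

Behaviour: bout sizes are geometric (mean 8 licks); intra-bout intervals
are i.i.d. Gamma with mean 160 ms (6.25 Hz) and CV 0.1, clipped to
[0.02, 0.45] s so the generated partition is exactly recoverable by
segmentation; inter-bout gaps are 0.5 s plus an exponential tail with an
overall 2 s mean. Tongue endpoints are 2-D Gaussian around the current
port position (SD 0.3 mm lateral, 0.5 mm in extension, mean extension
4.2 mm). These values emulate head-fixed licking at a stationary spout;
they are configuration, not estimates.

Spiking: simple spikes are an inhomogeneous Poisson process sampled by
thinning with an exact envelope. Inside lick cycles the rate is
`ss_base_rate · exp(κ·cos(φ(t) − φ*)) / I₀(κ)` — a unit-mean von Mises
modulation, so phase locking does not change the mean rate — optionally
multiplied by an in-bout gain (`ss_bout_gain`) and augmented by an
endpoint coupling (`ss_endpoint_gain_hz_per_mm` · endpoint x) confined to
the 75 ms before each maximal protrusion. Outside bouts the rate is flat:
rhythmicity is confined to licking by construction, matching the finding
that rhythmic simple-spike firing is largely absent between bouts. κ is
capped at 20 as an overflow guard. Complex spikes are Poisson at
~1 Hz with multiplicative bumps of 300 ms duration centred on bout starts
and ends and following lick-port movements, plus optional phase locking.
After each complex spike, all simple spikes within `cs_pause` (≥ 8 ms) are
deleted post hoc, which makes the pause guarantee exact rather than
probabilistic.

Perturbation trials follow the closed-loop protocol: each detected lick
triggers, with probability 0.5 and subject to a 1.5 s hold+refractory
period, a 3 mm rightward port movement starting 40 ms after detection with
50 ms travel; the port returns to centre 750 ms later (the return is the
"centreward" event, analysed with the same machinery). Endpoint means
follow the port with gains (0.5, 1.0, 1.0) for the first three licks after
each movement and fully thereafter; following also saturates in time —
any lick more than 750 ms after the last movement event is fully adapted,
because a pause in licking does not freeze the adaptation state at a
partial value. Optogenetic trials bend the first post-stimulation
protrusion by ±0.5 mm (sign by fibre side; a lateral fibre is distinctly
less effective) and shorten it by 0.3 mm; matched non-stimulated control
triggers are drawn from the same eligible-lick pool (stored in
`opto_trials.csv` with `fibre=control`).

One master seed is split into independent substreams (behaviour, trial
plan, opto plan, one per cell), so adding a cell never changes the
behavioural realisation.

What the generator does *not* emulate: video noise and missed detections,
slow drifts in lick rate or motivation, cell-quality drift, correlated
noise across simultaneously recorded cells, and any biophysics of the
tongue or of channelrhodopsin. Passing recovery tests therefore shows the
estimators are correct and calibrated under the stated statistical
structure, not that real recordings satisfy that structure.

## PSTHs, Z-scores and significance

PSTHs pool events over alignments in 10 ms bins; rate = counts /
(n_align · bin). Alignments whose window crosses the session edge are
dropped whole (no per-bin n adjustment) — simple and unbiased. Z-scores
are (value − baseline mean) / baseline SD with baselines fixed per
analysis: −1000..−500 ms before bout onset (start responses), +500..+1000
ms after bout end (end responses), −1000..−250 ms before the licks of
interest (per-lick normalization), a 500 ms pre-bout baseline for complex-
spike responses to port movements, and a 750 ms pre-lick baseline for
simple-spike adaptation peaks. No SD floor is applied: a zero-SD baseline
leaves Z undefined and excludes the cell from significance counts, rather
than silently inflating scores.

Significance of a modulation is judged at the *peak bin* within the stated
analysis window (300 ms centred on the transition lick), at the 3σ level.
For sparse complex-spike histograms the plain (value − mean)/SD score is
badly right-skewed — with ~2 counts per bin the nominal "3σ" bin tail is
~0.5%, and a 30-bin window then flags a quarter of flat cells. The peak
criterion is therefore evaluated through the exact Poisson mid-P tail of
the bin count at the baseline mean count, mapped to a normal quantile
(z = Φ⁻¹(P(K > k) + P(K = k)/2)). This converges to (value − mean)/SD as
counts grow and keeps the 3σ criterion calibrated at 1 Hz complex-spike
rates (measured on flat synthetic cells: ~2.5% flag rate). The
conventional z-scored trace is still computed and used for modulation
depth (max − min in a 200 ms window).

For port-movement responses the baseline comes from a different alignment
set (bout starts) than the response (movement onsets), so the baseline SD
is scaled by √(n_bouts / n_trials): bin-rate variance is inversely
proportional to the number of alignments, and without the correction the
yardstick under-states the trial PSTH's own sampling noise.

## Phase transform and coherence

Phase anchors per cycle: 0 at protrusion start, π at maximal protrusion,
2π at the end of retraction. With only the max-protrusion anchors
available, cycle boundaries are placed at the temporal midpoints between
neighbouring anchors within a bout; bout-edge cycles use the bout's mean
half-cycle. This is symmetric, parameter-free, and honours the anchors
exactly (φ(mᵢ) = π regardless of jitter). The map is piecewise linear on
[sᵢ, mᵢ] → [0, π] and [mᵢ, eᵢ] → [π, 2π], and cycles are indexed globally
so spike times can be *warped* to a cumulative cycle coordinate.

Coherence between spiking and licking is estimated on the warped axis,
where the phase transform has annihilated timing differences between
individual licks. Each lick contributes one ±2-cycle window; the spike–
lick cross and lick–lick auto transforms are evaluated at 1 cycle⁻¹
directly from the continuous lags with a Hann taper (whose spectrum is
exactly zero at the fundamental for a uniform background), and averaged
over licks:

    msc = |⟨X̄ᵢ·Yᵢ⟩|² / (⟨|Xᵢ|²⟩·⟨|Yᵢ|²⟩),  phase = arg⟨X̄ᵢ·Yᵢ⟩ + π.

Summed over licks these windows are precisely the spike-lick
cross-correlogram and the lick autocorrelogram; keeping them separate
before averaging makes the events themselves provide the spectral
averaging. Under the null (spiking independent of the lick cycle) the
per-lick spectral phases are random and msc collapses toward 0; perfect
locking gives msc → 1 with the phase equal to the locked phase in the
lick-cycle convention. Two estimator variants were rejected during
development: a single-segment spectrum of the summed correlograms (msc is
identically 1 between any two single-segment spectra) and Welch averaging
over the summed correlograms (both correlograms are near-deterministic lag
series sharing the bout-length envelope, so msc approaches 1 regardless of
locking). Direct continuous-lag evaluation also avoids a half-bin phase
bias that lag binning introduces when the lick comb teeth sit exactly on
bin edges. A cell is *coherent* when msc > 0.5 (strictly); estimates from
fewer than 100 in-cycle spikes are flagged low-power and not classified.

Rhythmicity in vs between bouts: simple-spike autocorrelograms (±2 s lags,
10 ms bins, zero-lag self-pairs excluded, mean removed, Hann tapered) are
computed separately from in-bout and between-bout spikes; spectra are
normalized to unit total power so the comparison is about rhythmicity,
not firing rate, and read at the preferred lick frequency (argmax of the
lick autocorrelogram spectrum in 3–12 Hz). Only the in/out ordering is
interpreted; absolute power units are not meaningful across conventions.

The 8×4 electrode grid is reduced to 7×3 by averaging the available
values in each 2×2 neighbourhood (NaN where all four are missing).

## Endpoint rosette

Tertile edges are the empirical 1/3 and 2/3 quantiles of the session's
endpoints per axis, so the partition adapts to each animal's bias and is
invariant under axis-wise shifts. Zone assignment is half-open: a value
equal to an edge goes to the upper tertile (deterministic,
order-independent). Per lick, the SS rate in the −150..−75 ms and
−75..0 ms windows before maximal protrusion is Z-scored against that
lick's own −1000..−250 ms baseline (binned at 10 ms for the baseline
statistics); zone maps average these per-lick Z values — the per-lick-
then-average convention, chosen over pooled-PSTH-then-Z because it weights
licks equally and exports per-lick values for population tests. Baseline
windows overlapping earlier licks are allowed. Group *peaks* for the
ipsiversive/contraversive comparison do use pooled PSTHs (peak of the
group's Z-scored trace in the late window), since a per-lick peak is not
well defined at 10 ms resolution.

## Decoder

Snippets are 200 ms with a 10 ms overlap between consecutive windows
(stride 190 ms), tiled from t = 0; events count in [t_start, t_end). A
CV2 value (2|ISIₙ₊₁ − ISIₙ|/(ISIₙ₊₁ + ISIₙ); 0 for regular, expectation 1
for Poisson trains) belongs to the window containing the middle spike of
its ISI pair. Windows with fewer than 3 simple spikes have no CV2 of
their own and get the cell's median in-class CV2 imputed (flagged);
imputation rather than dropping keeps the class balance intact, and a
drop mode exists for sensitivity analysis. A window is labelled *lick*
iff ≥ 1 detection falls inside it (a bout-overlap labelling is available
behind a flag). Training draws ⌊⅔·min(n_lick, n_nolick)⌋ snippets per
class without replacement; all remaining snippets are tested. The
classifier is XGBoost with 4096 estimators, depth 8, histogram split
finding; no early stopping. One seed governs split and model and is
recorded in the report. Attribution is the per-feature mean of absolute
per-snippet Shapley values, computed with XGBoost's exact TreeSHAP
(`pred_contribs`). Predictivity uses strict inequalities: both accuracies
> 55% → predictive, both > 65% → strongly predictive; exactly 55/65 does
not qualify. Validation runs use 256-tree ensembles — the same model
class and configuration at a size that keeps the suite fast; reported
accuracies are not compared across ensemble sizes.

## Perturbation and optogenetics

Lick k (k = 1..3) after a movement event is the k-th detection after the
onset and before the next movement event; trials with no subsequent lick
are excluded and counted. Baseline licks are ≥ 300 ms clear of any port
displacement. Coordinates are normalized per trial to the mean endpoint
of up to three licks immediately preceding the movement event within the
same lick chain — for rightward onsets these are the centred pre-trigger
licks, for returns the licks tracking the displaced port, which is what
"prior to the movement" means for each event. Normalization is
idempotent. SS adaptation peaks reuse the −75..0 ms protraction window of
the rosette analysis, against the 750 ms pre-lick baseline; CS movement
responses use a 0..300 ms post-onset window. Optogenetic effects are mean
endpoint differences (stimulated − control) per lick index, pulse timing
and fibre. Population tests over lick indices (rank correlations,
Benjamini–Hochberg across indices) are called from standard scipy/
statsmodels routines on the exported per-trial values; the package
assembles the values rather than re-deriving the tests.

## Pipeline

`run_pipeline` applies the enabled stages per cell and writes a summary
(per-cell flags and values, population fractions, collected warnings).
Unknown configuration keys are rejected. Re-running with the same
configuration and seed is byte-identical.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use 600 s sessions (≈ 1400
licks, ≈ 190 bouts) for coherence, detection and decoder calibration,
1200 s with 200 trials for adaptation recovery, and 900 s with 150 trials
per fibre for optogenetic recovery; oracle-equivalence checks run on
thousands of small random instances. These sizes give the recovery
estimates standard errors well inside the asserted tolerances while the
whole suite stays fast.

## Known limitations

* The coherence estimator's msc scale depends on the window span and
  taper; the 0.5 threshold is calibrated for the default ±2-cycle Hann
  configuration and should be revisited if those change.
* Per-lick Z-scores need a non-degenerate baseline; very regular,
  low-rate cells can have zero baseline SD for some licks, which are then
  excluded (reported per lick).
* The CS-conditioned lick analysis attributes pre-lick SS suppression to
  the climbing-fibre pause mechanistically only in the generator; on real
  data it is correlational.
* Sessions are analysed independently; there is no cross-session or
  population-level decoding.
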