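# Methods

This note documents the statistical procedures implemented in
`vtaephys`, the choices made where the procedure left details open, what
the synthetic-data generators do and do not emulate, and the known
limitations — in particular a quantified caveat about the bootstrap
classifier's error rate at short baselines.

## Windowed rates and the response statistic Δf

Firing frequency is estimated in sliding windows of length W = 60 s
advanced in s = 15 s steps.  Windows are half-open, `[c − W/2, c + W/2)`,
with centers on the grid `interval_start + W/2 + k·s`, and only windows
fully contained in the analysis interval are produced; half-open edges
prevent double counting of spikes on window boundaries.

Rates are normalized to the baseline mean as percent change,
`v = 100·(rate − μ)/μ`.  The baseline mean μ is the spike count of the
pre-injection baseline divided by its duration (default 300 s
immediately preceding the injection).  This estimator — rather than the
mean of windowed rates — is used because it is *exactly* conserved by
the ISI shuffle (spike count and span are invariant), so surrogate and
observed traces share one normalizer by construction.

A window belongs to the response period iff its **center** lies in
`(t_inject, t_inject + 180 s]`.  Δf is the signed extremal variation:
whichever of the maximal and minimal normalized values over response
windows has the larger magnitude.  An exact magnitude tie
(|max| = |min| ≠ 0) resolves to the maximum (activation) and sets a tie
flag; ties are measure-zero for real data and the flag keeps them
auditable.

## ISI-shuffle bootstrap classification

The null hypothesis is that Δf reflects nothing beyond spontaneous
baseline variability.  Per neuron:

1. baseline ISIs are permuted uniformly at random, n = 1000 times; each
   surrogate keeps the original first-spike time, spike count, span and
   ISI multiset;
2. each surrogate is windowed identically, normalized to the original μ,
   and its signed extremal variation is taken over the **same number of
   windows** as contribute to the observed response-period extremum
   (the first k windows of the surrogate trace);
3. the mid-rank percentile of the observed Δf in the 1000 surrogate
   extrema (ties counted half) decides the label: responsive iff
   percentile ≥ 0.95 or ≤ 0.05, activated for Δf > 0, inhibited for
   Δf < 0.

Matching the window count (rather than using the whole baseline span)
keeps the null extremum comparable to the observed one: an extremum over
more windows is stochastically larger.  With the default geometry
(300 s baseline, 180 s response, recording ending at injection + 180 s)
the first k windows cover exactly one response-period length of the
surrogate.

When the extreme tail and the sign of Δf disagree (percentile ≥ 0.95
with Δf ≤ 0, or ≤ 0.05 with Δf ≥ 0) the neuron is left nonresponsive
with a conflict flag; such cases are never silently relabeled.

Reproducibility: one root seed; per-neuron generator streams are derived
by stable (SHA-256) hashing of the neuron id and drug, so results are
identical regardless of processing order.

### Known limitation: anti-conservatism at short baselines

The shuffle null conditions on the baseline's ISI multiset.  A
surrogate's response-length stretch can therefore deviate from μ only by
reallocating intervals *within* the fixed baseline span — a
without-replacement fluctuation whose variance carries a factor
(1 − T/B) relative to a free stretch (T response length, B baseline
length).  The observed response period, by contrast, is an independent
stretch of the process whose local mean fluctuates with full variance.
The percentile test is consequently anti-conservative when B is not
much larger than T.  Measured on stationary gamma-renewal neurons
(5 Hz, shape κ = 2, T = 180 s): the responsive fraction at the nominal
10 % two-tail level is ≈ 0.22–0.26 at B = 300 s, ≈ 0.16 at 600 s and
≈ 0.14 at 900 s, approaching nominal as B grows.  Two checks localize
the cause: the *pooled* null matches the marginal distribution of
stationary Δf almost exactly (SD 7.1 vs 7.3 %), and the inflation
persists when the true rate replaces μ̂ — so neither the per-shuffle
computation nor the normalizer is at fault; the deficit is the missing
between-stretch variance, which no construction that shuffles only
baseline intervals can supply.  Practical consequence: with ~5-min
baselines the classifier over-calls weak responses; classifications of
large-|Δf| responses (the regime the polarity analysis rests on) are
unaffected — power at a planted |Δf| = 40 % is ≈ 100 % with perfect
polarity assignment.  `scripts/acceptance.py` reports the measured
false-positive fraction on every run.

## Drug-vs-saline contrast and dose-response rule

Paired per-neuron Δf values (drug vs saline) are compared with a test
selected by a normality screen on the differences: Shapiro-Wilk
p > 0.05 → paired t test, otherwise Wilcoxon signed-rank.  Identical
pairs short-circuit to p = 1 ("degenerate") since neither test is
defined on all-zero differences.  Holm's sequential step-down
(statsmodels) is available across multiple contrasts.  For dose series
the overall polarity is that of the lowest dose whose bootstrap
classification is responsive; doses must be strictly ascending.

## Concordance and the pooled-surrogate permutation test

Neurons responsive to both drugs contribute one polarity pair;
concordance is `100 · n_same_sign / n_pairs`.  "Pooling the two response
groups" is implemented as permutation of the drug-2 polarity labels
across neurons: the within-neuron pairing is destroyed while each drug's
response composition (its margins) is preserved — the exchangeable null
consistent with pooling.  p = (1 + #{surrogate ≥ observed}) /
(n_surrogates + 1), with 10,000 surrogates by default; the add-one rule
avoids p = 0.  An exhaustive enumeration over all n! pairings
(`exhaustive_concordance_test`) serves as the small-n oracle.

Because the statistic is a count with fixed margins, the permutation
p-value is discrete — permuting labels changes the concordant count in
steps of two — and conservative (P(p ≤ t) ≤ t).  At realistic pair
counts (30–100) the p-value atoms are ~0.1, so the null p distribution
is only coarsely uniform; a continuous-uniform KS check over a few
hundred replicates sits at or beyond its rejection boundary for
structural reasons.  The test's *power* is unaffected: with ρ = 0.9 and
30 pairs, p < 0.05 in ≈ 99 % of replicate datasets.

Pearson correlation of paired Δf magnitudes (`response_correlation`,
t = r·√(n−2)/√(1−r²)) is provided as a separate, optional statistic;
concordance itself uses signs only.

## Putative-DA screening and opto-tagging

Screening applies the four in vivo criteria as strict inequalities:
(i) triphasic action potential (supplied flag), (ii) total duration
> 2.0 ms, (iii) start-to-trough width > 1.1 ms, (iv) mean rate strictly
between 1 and 10 Hz.  The function is pure and returns every failed
criterion by name.

The opto-tag statistic is the fraction of light pulses followed by at
least one spike within 10 ms.  The accompanying significance procedure
is this package's construction (the criterion itself does not prescribe
one): pulse onsets are circularly shifted by a common uniform offset
within the recording epoch, n = 1000 times, preserving both the
spike-train autostructure and the pulse-train regularity; p uses the
add-one rule and a unit is tagged iff p < 0.05 *and* the observed
fraction exceeds the null mean.  False-tag rate on pulse-independent
Poisson trains measures ≤ the nominal level.

## Synaptic event detection

The detector follows the classical scaled-template criterion.  At every
offset the template w is fit to the trace segment y by least squares in
scale and offset; the detection statistic is the fitted scale divided by
its standard error, `a / sqrt(SSE/(L−2) / Σ(w−w̄)²)`.  Local maxima of
|statistic| above a criterion threshold (default 4) become candidates;
candidates are kept iff the fitted |amplitude| ≥ 3 × noise SD; overlaps
are resolved greedily by descending score with a refractory span of one
template length.  The threshold and noise estimator are configurable
because the source procedure names only its acquisition software.

Templates average ≥ 15 example currents.  Each snippet spans 5 ms of
pre-onset baseline plus the event (30 ms total by default); the average
is baseline-subtracted using the pre-onset span and normalized by its
signed extremal value so that fitted scales are signed amplitudes in pA.
The normalizing peak is read from a ~1 ms-smoothed copy of the average:
the raw extremum of a noisy average is biased outward, which would
systematically shrink the template and inflate every fitted amplitude
(~10 % at 15 examples of 5σ events; < 2 % with the smoothed estimate).

Noise SD is 1.4826 × MAD of the first-difference residual (÷√2), a
high-pass statistic insensitive to slow drift, computed outside detected
events when a mask is available.  Evoked amplitudes are measured as the
signed extremal deviation of a post-stimulus window from the mean of a
pre-stimulus baseline window.

## Synthetic data: what it emulates, and what it does not

Spike trains are time-rescaled gamma renewal processes: unit-mean
gamma(κ, 1/κ) intervals on operational time mapped through the inverse
integrated intensity Λ⁻¹, with
λ(t) = λ₀·max(0, 1 + (m/100)·g(t − t_inj)).  Defaults: λ₀ = 5 Hz (the
middle of the 1–10 Hz DA range), κ = 2 — dopamine firing is more regular
than Poisson, and the ISI-shuffle null is only non-degenerate for
irregular trains; κ = 1 recovers Poisson.  The default kernel g is a
plateau over the 180-s response period with 10-s linear ramps — a shape
that matches a ~3-min response without claiming particular kinetics; a
difference-of-exponentials kernel (τ_rise = 10 s, τ_decay = 60 s) is
available for transient responses.  Inhibition floors λ at 0 rather
than allowing negative intensity.

Populations default to the observed composition: 57 % activated, 39 %
inhibited, 4 % non-responsive, cross-drug concordance ρ = 0.8, planted
|Δf| = 40 %.  Drug-2 polarity equals drug-1 polarity with probability ρ
and is flipped otherwise; non-responders respond to neither drug.  A
projection-polarity map can instead assign each neuron a projection
target (e.g. NAc mostly activated, Amg mostly inhibited) and draw its
polarity from that target's composition.  Each neuron receives both
injections in one session (baseline 300 s, response 180 s, washout
300 s, epoch 960 s).

Current traces are Gaussian noise plus biexponential events
(τ_rise = 1 ms, τ_decay = 8 ms, peak-normalized) at Poisson times with
lognormal amplitude magnitudes (mean 30 pA, CV 0.3, negative-going), at
10 kHz.

What the generators do **not** emulate: bursting and pause structure of
real DA firing, slow nonstationarities (anesthesia depth, electrode
drift), injection artifacts, biological washout kinetics between
consecutive injections, correlated (non-white) recording noise, and
event-shape heterogeneity within a neuron.  Passing tests therefore
demonstrate that the *procedures* recover planted structure under the
model's assumptions — not that those assumptions hold for any particular
recording.

## Numerical and interface choices

- Times are seconds everywhere internally; spike tables are CSV with
  header `neuron_id,spike_time_s`, parsed with exact float round-trip.
- Metadata is JSON (one canonical dialect for bit-exact round-trips);
  YAML is accepted only behind an explicit flag.
- Epoch bounds default to `[first_spike − 1 s, last_spike + 1 s]` when
  no sidecar provides them, and the inference is logged.
- SEM of a single profile is defined as 0 (with a warning) so population
  aggregation is total.
- Reports are CSV plus a JSON manifest (config, seed, versions) with no
  timestamps: identical inputs give byte-identical outputs.
- Problem sizes in the test and acceptance runs — 500 stationary neurons
  for the error-rate measurement, 200 neurons for recovery, 200
  replicate datasets for calibration, 100-s traces with ~105 events for
  the detector — were chosen to pin Monte-Carlo standard errors well
  below the tolerances being checked while keeping a full run within a
  couple of minutes on one CPU.
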