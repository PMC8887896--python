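# Methods

`wildsleep` scores sleep from collar accelerometry in group-living wild
animals and analyses the collective structure of nocturnal sleep: where
individuals sleep (tree fidelity), how their wakefulness aligns (group
synchronization against resampling nulls), and whether a sleeping animal's
arousal responds to the nighttime activity of its tree-mates. A synthetic
biologger-data generator with known ground truth makes every stage testable
without field data.

## Sleep scoring

**Signal.** VeDBA (vectorial dynamic body acceleration) is the Euclidean norm
of the dynamic acceleration components; the static (gravitational) component
per axis is estimated by a centred running mean over 0.7 s (0.5 s for the
daytime cumulative-activity measure), truncated at burst edges. One 2.5 s,
10 Hz burst per minute yields a burst-mean VeDBA; the per-minute series is
`log_vedba = ln(mean VeDBA + 1e-6)`. The offset guards against all-still
bursts; natural log is fixed and documented because the threshold rule below
is *not* invariant to the log base. Continuous daytime streams (12 Hz) are
linearly interpolated onto the nocturnal burst schedule so one uniform
series covers the full day.

**Scoring unit.** A noon-to-noon local day (1440 epochs), which contains
exactly one nocturnal sleep period. The classification threshold is the 10th
percentile (linear-interpolation definition) of the day's non-missing log
VeDBA multiplied by 1.125, computed per individual-day.

*Operating regime of the threshold.* Multiplying a percentile by 1.125 raises
the threshold only when the percentile is positive; applied to negative log
values it lowers it and nothing is classified as sleep. The rule therefore
presumes an acceleration scale on which resting log VeDBA is positive — e.g.
VeDBA in milli-g, where a resting animal sits near ln(33 mg) ≈ 3.5 — and the
synthetic generator emits on that scale. The formula is nevertheless applied
literally whatever the sign (a regression test pins the negative-percentile
behaviour), and the scale question is flagged here because the choice of
units is consequential when applying the pipeline to new data.

**SPT window.** A 9-minute centred rolling median smooths the series (window
shrinking symmetrically at the edges, missing epochs excluded from the
window). Maximal runs of ≥30 min strictly below the threshold are sleep
blocks; blocks separated by ≤45 min are merged (a single left-to-right pass
over time-sorted blocks, which is the fixed point of the merge relation);
the longest merged period is the sleep period, ties going to the earliest.
Onset and awakening are its ends.

*Missing epochs.* Epoch classification (below) requires observed data and
breaks runs at missing epochs. Block detection, however, bridges missing
epochs by evaluating the rolling median over the available neighbours: the
QC regime (see below) has a dedicated rule for ≥20 *consecutive* missing
bursts precisely because only long gaps corrupt the window determination,
while tolerating up to 119 scattered missing bursts per day. Strict
run-breaking at missing epochs is available via
`ScoringParams.spt_break_at_missing`.

**Epoch labels.** Every epoch of the day (inside and outside the SPT window)
is labelled sleep when it lies in a run of ≥3 consecutive epochs with raw log
VeDBA strictly below the threshold; other observed epochs are wake. Ties at
the threshold count as wake ("less than").

**Night metrics.** Total sleep time (TST) = sleep epochs within the SPT
window; efficiency = TST / window duration; fragmentation = qualifying wake
bouts per hour of sleep, where wake runs separated by fewer than 3 sleep
epochs form one bout and a bout qualifies at ≥2 min total wake; napping =
sleep epochs between 07:30 and 17:30 local. Onset/awakening are also
expressed relative to astronomical twilight (solar elevation −18°, computed
with NOAA solar-position equations, accuracy well under ±2 min).

**QC.** Days missing ≥120 bursts are unusable (no reliable threshold; all
metrics dropped, including napping on the adjacent calendar days). Days with
≥20 consecutive missing bursts lose SPT-derived metrics but keep napping.

## Sleep sites

Nightly sleep location = componentwise median of the first 10 GPS fixes
before 06:15 (fewer than 10 → excluded). Assignment: containment in a
digitized crown polygon wins; otherwise the nearest crown within 10 m
(ties to the smallest tree id); farther → excluded. All metric geometry runs
in a local equidistant projection about the site centre (planar error is
negligible below 5 km extents). Daily travel distance discretizes the track
to 5 m (a fix is kept only ≥5 m from the last kept fix) and is excluded on
days whose GPS coverage starts after 07:30 or ends before 17:00.

## Tree fidelity

Per individual, tree-use entropy H = −Σ p ln p over its assigned nights
(nats; the base cancels in the comparison). The null preserves each night's
occupancy exactly: within each night the multiset of occupied tree slots is
reshuffled among the individuals present. Individuals with <4 assigned
nights are excluded (empirical and permuted alike), and the analysis is
limited to the first 14 study nights by default.

The discrepancy between empirical entropies and the pooled permuted
entropies is the one-tailed two-sample KS statistic (alternative: empirical
stochastically smaller, i.e. fidelity). Its p-value is obtained by
calibrating that statistic against the same statistic computed for each
permutation round — an exact permutation test, since under the null the
empirical round is exchangeable with the permutation rounds. The raw
two-sample KS p against the pool is also reported (`ks_pooled_pvalue`) but is
strongly conservative: the pool is the data's own permutation distribution
rather than an independent sample, and entropies of count data are discrete.
In simulation the calibrated test rejects at ≈5% under the null where the
raw pooled p rejects at ≈0%.

The fidelity index per individual × tree is observed nights minus the
permutation-mean nights; indices sum to zero across trees by construction.

## Group synchronization

Statistics are computed on the 21:00–05:00 window (480 epochs/night),
strictly interior to every individual's sleep period:

- `prop_any_awake` — fraction of epochs with ≥1 observed individual awake;
- `mean_prop_synchronized` — per epoch, the fraction of concordant dyads
  among observed individuals, averaged over epochs.

The pairwise-agreement definition is the default for a structural reason:
the time-shift null conserves each individual-night's wake total, and
whenever no epoch has a wake majority the modal-state fraction averages to
exactly one minus the overall wake fraction — a deterministic function of the
conserved totals, so its null distribution collapses and the test can never
reject. The pairwise statistic is strictly convex in the per-epoch wake
count and responds to wake clustering. The modal variant remains available
(`statistic="modal"`).

Nulls: the *time-shift* null circularly rotates each individual-night vector
by a uniform offset in {1..479} (missing epochs travel with the vector; wake
totals and autocorrelation conserved exactly); the *night-permutation* null
reassigns each individual's nights to night slots, preserving clock
alignment, which controls for a stereotyped schedule shared across nights.
P-values are the proportion of null values at least as extreme as the
empirical value (denominator = iteration count; a zero count is displayed as
"< 1/n"). Field reports sometimes label such permutation proportions a
"Fisher's exact test"; no contingency table is involved, and the proportion
is reported here as what it is.

Wake contagion moves the two statistics in opposite directions: coupled
awakenings overlap in time, so fewer epochs contain any waker (collective
vigilance *below* null) while concordance rises (synchronization *above*
null).

Dyadic synchronization = minutes in the same state / co-observed minutes per
dyad-night (21:00–05:00), with a same-tree flag — a model-ready table for any
mixed-model backend; fitting Bayesian mixed models is out of scope.

## Arousal response

Eligible rows: epochs 21:00–05:00 within the first 14 nights where the focal
was asleep at t−1, t−2 and t−3, has a tree assignment, and at least one
same-tree group-mate has an observed state at t−1. Outcome: focal awake at t.
Predictors: any same-tree group-mate awake at t−1 (state-based, not
onset-based; the onset-based variant is a one-line change at the call site),
previous-night TST and fragmentation centred on the individual's own mean,
and their interactions. The stand-in fit is an ordinary logistic regression
with cluster-robust errors by focal individual; it provides the
sign/significance surface only — a full Bayesian random-effects fit is
intentionally out of scope.

## Synthetic generator

The generator emulates the study conditions: 26 collared individuals, 35
nights, 10 sleep trees at a tropical site (UTC+3; default coordinates near
0.29° N, 36.90° E where evening astronomical twilight ends ≈ 19:50 local).

- **Sleep windows.** Onset ~ N(19:30, 20 min), offset ~ N(05:45, 20 min) —
  onset before the end of evening astronomical twilight and awakening around
  morning twilight, as observed in wild primates.
- **Wake bouts.** A Poisson process (default 1.5 spontaneous bouts/h) inside
  the sleep window with geometric durations (mean 2 min). Observed
  fragmentation then lands near typical field estimates of ~1.8 bouts/h once
  contagion and detection are applied.
- **Contagion.** If any same-tree group-mate transitions to wake at t−1, each
  sleeping tree-mate wakes at t with `coupling_prob` (default 0; studies of
  contagion set it explicitly). Coupling acts only within trees and at lag 1,
  matching the arousal model's predictor.
- **Trees.** Per-individual preference weights are a softmax of standard
  normal logits scaled by `tree_preference_concentration` (0 = uniform
  choice, ∞ = a single favourite tree); one tree per night.
- **Emissions.** log VeDBA per epoch is Gaussian per latent state: sleep
  3.5 ± 0.12, resting wake 3.8 ± 0.12 (deliberately sleep-like), active wake
  6.0 ± 0.5 (mg scale). These place the day's 10th-percentile-×1.125
  threshold ≈ 2.8 sd above the sleep mean and far below the active-wake
  mean — the separation regime in which the adapted human-actigraphy rule is
  valid, and the regime the pipeline's accuracy statements refer to.
- **Resting wake** is a third latent state so the known failure mode — quiet
  wakefulness scored as sleep — can be quantified against truth; the default
  rate inside the night window is 0 and tests raise it to demonstrate that
  accuracy degrades in the documented direction.
- **Sensors.** Bursts are gravity plus a fixed dynamic waveform scaled so
  the ingest pipeline recovers the drawn log VeDBA exactly (VeDBA is
  1-homogeneous in the dynamic amplitude); burst drops are i.i.d. with
  probability 0.01/epoch by default plus optional inserted gaps; GPS fixes
  are jittered (σ = 2 m) around the true tree centroid, with a daily loop
  track of nominal length 3000 m whose fixes sit ~10 m apart (well above the
  5-m discretization).

**What the generator does not emulate:** real VeDBA distributions are
heavier-tailed and autocorrelated within bouts; animals move between fixes
non-circularly; tree choice has social structure; there are no predators,
weather or terrain. Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical structure, not field-data accuracy
(field validations of this class of scoring against direct observation
report accuracies near 80%, driven largely by resting wakefulness).

## Validation experiments (tests and `scripts/acceptance.py`)

- **Oracle equivalence.** Rolling median, run-length classification,
  wake-bout counting, dyad scores and arousal-row eligibility match
  independent brute-force implementations exactly on 1000 random series.
- **Parameter recovery** (26 individuals × 10 nights). "Noise-free" switches
  off every stochastic perturbation — emission noise, missingness *and*
  spontaneous wake bouts — because a ≥5-min wake bout within ~35 min of the
  window edge legitimately truncates the detected window (an inherent
  property of the block/merge rule, not an implementation error); without
  perturbations recovery of onset/awakening is exact. Under default noise,
  pooled epoch accuracy ≥95% and mean per-night relative TST error ≤3% are
  the targets; measured values are ≈99.7% and ≈2%.
- **Calibration** (400 null groups of 15 × 14 nights, 100 iterations each):
  type-I error of the fidelity test and the time-shift synchronization test
  at nominal 5% must land in [0.02, 0.09].
- **Power** (100 coupled groups, coupling 0.3): the sign pattern —
  `prop_any_awake` below null and synchronization above null, both p < 0.05 —
  and a positive, significant group-mate-awake log-odds in ≥90% of groups.
- **Conservation**: exact wake-total conservation under every time shift,
  exact per-night occupancy conservation under every fidelity permutation,
  fidelity indices summing to zero.

Group sizes for the simulation studies (15 individuals × 14 nights) mirror
the first-14-days analysis scale after collar dropout; the recovery study
uses the full 26 individuals over 10 nights.

## Known limitations

- The scoring threshold assumes a log-VeDBA scale with positive resting
  values; data in g-units must be rescaled (e.g. to mg) before scoring.
- Resting wakefulness is structurally misclassified as sleep; TST is an
  overestimate wherever animals rest quietly at night.
- The SPT window cannot distinguish a terminal ≥5-min wake bout followed by a
  short sleep fragment (<30 min) from final awakening.
- The logistic arousal fit ignores random effects for night; with strong
  night-level confounds its standard errors are optimistic despite clustering
  by individual.
- Twilight times assume |latitude| < ~48° so astronomical twilight exists
  year-round.
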