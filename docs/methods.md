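# Methods

This note documents the generative model behind the synthetic data, the
processing conventions, the numerical choices, and what the test battery does
and does not establish about real recordings.

## Trial-sequence generation

Each block presents 6 primary items (1 probe + 5 irrelevants) × `reps`
(default 30) trials in groups of six, every group a permutation of the six
items. Constraints: no primary or secondary item repeats across consecutive
trials, and precedence is balanced **exactly** — each nontarget precedes
every primary item `reps/5` times, each target `reps/10` times (targets half
as frequent, preserving the 1:4 target:nontarget ratio). `reps` must make
these quotas integral.

No closed-form construction is attempted: the primary stream is per-group
shuffling with bounded rejection (group heads must differ from the previous
group's tail), and the secondary stream is a randomized backtracking
assignment over the quota table with a node budget and up to 50 full restarts
(`SequenceConstraintError` beyond that; in practice the first restart
succeeds). Both inter-stimulus intervals are uniform on 1500–1700 ms,
recorded at 1 ms resolution. Recall checks (3 per block, 9 per session) are
placed by a dedicated seed shared across participants, so every plan built
with the same recall seed has identical check positions. `validate_sequence`
re-checks every postcondition and reports offending trial indices rather than
raising.

The candidate-foil selector prefers minimal character-length distance to the
probe and excludes candidates sharing the probe's initial letter; the letter
rule is disabled for the date category (month names would exhaust the pool).
Examinee-flagged candidates (at most 2 per category) are excluded before the
final seeded draw of 5 irrelevants from 8 candidates.

## Synthetic EEG model

Epochs are generated directly (−100…1400 ms at 250 Hz, half-open window,
375 samples); a continuous-recording input path exists for the preprocessing
chain but the generator does not use it, since every downstream computation
operates on epochs.

The evoked template on Pz is a raised-cosine P300 bump (peak 550 ms, width
400 ms — free choices; the scoring window only requires the peak inside
400–800 ms) plus a **common late negative slow wave** (trough 1000 ms, width
500 ms, depth 2 μV). The slow wave is a standard feature of parietal ERPs
and is load-bearing here: it gives the min-segment search a genuine trough
shared by all conditions. Without it the search runs over a flat tail and
reduces to pure noise minimisation, whose selection bias is first-order in
the noise level and does not cancel between averages with unequal trial
counts (30 probes vs. 150 pooled irrelevants) — the probe−irrelevant
difference would then carry a spurious positive offset for innocent
subjects.

**Amplitude convention.** A component's amplitude parameter is the
peak-to-peak score its noiseless waveform produces (the best 100 ms segment
mean of a raised cosine is ≈0.95 of its peak, so kernels are internally
rescaled by the scored value of a unit kernel). "Inject 9.16 μV" therefore
means "a noiseless probe−irrelevant peak-to-peak difference of 9.16 μV",
which is the quantity parameter-recovery tests compare against.

Default per-category probe increments (9.16 / 5.66 / 3.57 μV for forename /
date / animal) and their between-subject SDs (4.43 / 4.14 / 3.17, truncated
normal at 0) mirror the group-level dispersion of published CTP data, as do
the base amplitudes (irrelevant 2.8, nontarget 4.5, target +6.7 μV, which
yield measured peak-to-peak values of ≈4.8 / 6.4 / 13.1 μV once the slow
wave's trough is included). Innocent profiles set all increments and probe
RT slowing to zero — an extrapolation, since the emulated design had no
innocent group, but required to test classifier specificity.

Noise is white (SD 2 μV) + alpha oscillation (10 Hz, Rayleigh amplitude,
mean 1.5 μV) + slow drift (0.1–0.5 Hz, ~1 μV), independent per channel;
mastoids carry 0.7× scaled noise and no P300 (so the linked-mastoid
reference preserves Pz amplitudes). These levels describe a clean laboratory
recording: after 30-epoch averaging the segment-mean noise floor is ~0.2 μV,
the regime in which the peak-to-peak measure is approximately additive and
injected amplitudes are recovered without material bias. Blinks are
raised-cosine deflections on the vertical EOG pair (8/min, ~120 μV) leaking
into scalp channels with fixed coefficients (0.05–0.18); gross artifacts
(rate 0.08, 100–250 μV transients on a monitored channel) exist to exercise
amplitude rejection, calibrated so retained-epoch counts resemble published
bookkeeping (~27–28 of 30). RTs are shifted lognormal (shift 200 ms, mean
420, SD 100) with additive per-category probe slowing (13.9 / 8.4 / −1.5 ms);
error rates per role are 2.7 / 2.3 / 18.5 / 2.5 %.

What the generator does **not** emulate: scalp topography beyond crude
channel gains, autocorrelated ongoing EEG beyond one alpha component, eye
movements beyond stereotyped blinks, latency jitter of the P300 across
trials, habituation across blocks, or any dependence of amplitude on
preceding-trial history. Passing tests therefore show that the *analysis
machinery* is correct and well-calibrated under the stated statistical
structure, not that the pipeline is robust to every physiological
contingency of real recordings.

## Preprocessing conventions

Canonical order: resample → band-pass → epoch → baseline → EOG regression →
amplitude rejection → linked-mastoid re-reference. Filters are
Hamming-windowed sinc FIRs with the half-amplitude (−6 dB) cutoff
convention, applied zero-phase; transition widths default to
`min(max(0.25·cutoff, 2 Hz), cutoff)` per edge (0.3 Hz at the 0.3 Hz edge —
wider defaults would leave ~25% DC gain), with the order set by the narrower
band. On epoched input only the 30 Hz low-pass is applied (the 0.3 Hz
high-pass kernel is ~11 s, longer than a 1.5 s epoch); baseline correction
(−100…0 ms mean) takes over slow-drift removal. Ocular correction is
ordinary least-squares regression of scalp on EOG channels fit across all
epochs jointly — a deliberate, deterministic replacement for adaptive
recursive-least-squares schemes, adequate when leakage is stationary, and
recorded in the provenance log. Rejection (±75 μV on Pz/TP9/TP10) runs after
EOG correction, following the narrative order of the chain; the threshold's
position relative to ocular correction is a convention, not a derivation.

## Peak-to-peak scoring

Scan step is 1 sample; segments must lie entirely inside their windows
(boundaries inclusive); the max-segment midpoint is floored to the sample
grid before bounding the min search; ties break to the earliest segment.
Segment means use the same pairwise reduction as `numpy.mean` on each slice,
so the vectorised scorer agrees bit-for-bit with an exhaustive scan. A
warning fires when the max segment abuts a search-window edge (the automated
analogue of visually verifying the peak falls inside the window). The
alternative reading that bounds segment *starts* rather than whole segments
is available as a config switch. Averages use correct-response trials only.

## Bootstrap diagnostic

Per iteration both pools are resampled with replacement at their original
counts (implemented as multinomial-weighted means, one matrix product per
side). Defaults B = 1000, θ = 0.9, probe vs. all-irrelevants-pooled — the
conventional values of this literature; the exact historical parameters vary
by lab, so all are config-exposed, and a probe-vs-max-irrelevant mode is
provided. Verdict is `p̂ ≥ θ`.

A property worth knowing: for a single subject under the exchangeable null
(equal-size pools from the identical distribution), p̂ is *not* near 0.5 — it
concentrates on that subject's realized epoch-sample gap and spreads widely
(SD ≈ 0.3) across null subjects; only the across-subject mean is 0.5. The
verdict rule is consequently an approximate one-sided 10% test: with
30-epoch pools its exact size is ≈10.4% (the bootstrap jitter of a resampled
mean understates the sampling SD by √(29/30)), which is what the cohort
false-positive rate converges to when the evoked template dominates the
averaged noise. In the opposite, noise-dominated regime, segment
re-selection inflates the bootstrap jitter and the rate drops well below
10% — at the price of biased amplitude recovery. The defaults sit in the
first regime.

## Group statistics

Behavioral validity: RT > 150 ms; accuracy = correct/valid; RT means over
correct valid trials; empty cells flagged, never silently dropped. Cohen's d
defaults to d_z (mean/SD of within-subject differences; d_av available with
explicit condition SDs). The mixed ANOVA delegates to pingouin's split-plot
decomposition; the within-factor GG ε is applied to both the within main
effect and the interaction (they share the within-error term), ε ≡ 1 for
two-level factors, and partial η² = SS_effect/(SS_effect+SS_error). An
independent textbook sums-of-squares oracle in the tests pins the
decomposition. Power for the within–between interaction follows the
repeated-measures convention λ = f²·N·m·ε/(1−ρ), df = (g−1)(m−1)ε and
(N−g)(m−1)ε, with defaults ρ = 0.5, ε = 1; a Monte-Carlo of the same 2×2
design (interaction F ≡ squared two-sample t on difference scores) serves as
an independent cross-check. Exclusion defaults: probe accuracy < .75, target
accuracy < .60, > 4 of 9 recall failures — the two quoted historical cases
(49% probe accuracy; 7/9 recall failures) fall under them; the accuracy
cutoffs themselves are package choices. Significance is uncorrected α = .05
throughout.

## Problem sizes

Monte-Carlo batteries use 200 subjects per cohort for parameter recovery and
null calibration, 1000 random waveforms for scorer equivalence, 5000
replicates for the power cross-check, and 60-seed sweeps for sequence
properties — sizes chosen so each check's own sampling error is several
times smaller than the tolerance it asserts.

## Known limitations

* The bootstrap verdict's null size marginally exceeds the nominal 10% in
  the signal-anchored regime (see above); θ should be raised if a stricter
  specificity target is needed.
* EOG correction assumes stationary leakage coefficients within a session.
* The sequence generator enforces slot-wise adjacency only (a primary item
  may textually match the *next trial's secondary* item under word inducers;
  impossible with number-string secondaries).
* Serialization covers the package's own container (npy + JSON + CSV); no
  EDF/BrainVision interchange.
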