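# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, in the spirit of a methods appendix: what is computed,
why the defaults are what they are, and what the synthetic data can and
cannot show.

## Study structure emulated by the generator

Two arms of a Latin Square Task experiment are simulated: an fMRI arm
(n = 40 participants, 3 rotated presentations per puzzle) and an EEG arm
(n = 45, 4 presentations). Both use the same 36 puzzles — 12 unique designs
at each of three relational-complexity (RC) levels. Rotation replicates are
generated as independent noisy re-draws of the same puzzle representation
and averaged back to one estimate per puzzle downstream, mirroring how
trial-level estimates are averaged in the real analysis.

### Behaviour

Per-participant, per-puzzle accuracy and response time are drawn around
condition-level targets, which default to the observed study means
(accuracy 96.66/87.02/66.25 % fMRI and 95.00/80.69/56.30 % EEG;
RT 0.74/0.81/0.93 s fMRI and 0.61/0.78/0.87 s EEG). Puzzle-level
difficulty offsets (logit scale for accuracy, log scale for RT; defaults
0.35 and 0.06 sd) are drawn once per seed and shared between arms, so the
same puzzles are relatively hard in both — as observed empirically — and so
the data-driven cognitive-effort (CE) model acquires stable within-condition
structure. At these defaults the RC–CE model rank correlation averages
≈ 0.82 over seeds (the study reported r_s = 0.81 on real data).
Participant offsets (0.20 / 0.08 sd) add between-subject variability, and a
0.10-sd log-normal trial term jitters RT. After perturbation, each
condition's mean success probability is re-centred on its target, so the
expected condition means equal the configured values; accuracy is then the
mean of rotation-level Bernoulli outcomes (a proportion, as it enters the
CE model). Setting every dispersion to zero and `sample_trials=False`
reproduces the targets exactly — the noise-free limit used in tests.

### fMRI patterns

Each of 376 regions (allocated over 13 functional networks in proportions
loosely mirroring published cortical network sizes, plus a 16-region
subcortex) receives a puzzle × feature pattern

    rc_effect(network) · E_RC Q₁ + ce_effect(network) · E_CE Q₂ + ε,

where E_RC and E_CE are classical (Torgerson) MDS embeddings of the model
RDMs — so the implanted pattern distances reproduce the model distances
exactly before noise — and Q₁, Q₂ are region-specific orthonormal-row
mixing matrices (distance-preserving) into a 30-feature space.
ε is i.i.d. Gaussian with sd 1.0. Effects default to 1.0 in
frontoparietal, dorsal-attention and cingulo-opercular networks, 0.6 in
visual/default/language/posterior-multimodal, 0.35 in the remaining
networks, and 0 in orbito-affective, which serves as a designed null; CE
effects follow the same profile at ~0.4× strength. The noise sd and effect
profile were fixed once, during generator design, so that group-level
recovery at the study sample size is reliable while per-participant coding
strengths stay in a realistic range (group mean z ≈ 0.03–0.5 across
networks).

### EEG epochs

Epochs span −0.4…4.5 s at 250 Hz on the half-open grid
t = t_start + k/fs, k = 0…N−1 with N = round((t_end − t_start)·fs) = 1225
samples. Background noise has a 1/f^χ power spectrum (χ = 1.0, realized by
spectral shaping of white noise; broadband sd 10 µV). The RC implant maps
the RC embedding into sensor space through a shared orthonormal mixing and
multiplies it by band-limited sinusoidal carriers at the alpha and beta band
centres (random phase per participant), with a Hann (sin²) amplitude
envelope supported exactly on 2.5–4.1 s — zero outside. The amplitude
default (5 µV per unit embedding coordinate) was likewise frozen after
design-time calibration: strong enough that time-resolved group RSA detects
the window reliably at reduced test scale, weak enough that filter leakage
into theta/gamma stays below detection.

Every output is a pure function of the seed; independent substreams (puzzle
difficulty, each modality, each participant) are derived from it with fixed
integer tags, so any participant subset regenerates identically.

## Analysis pipeline

**RDMs.** Patterns are z-scored per feature across the 36 puzzles (constant
features dropped with a logged count) and turned into squared-Euclidean
RDMs. Temporal RDMs are computed at every sample from the puzzle × sensor
pattern and averaged element-wise within consecutive 100 ms bins; the
trailing partial bin is dropped, giving floor(1225/25) = 49 bins. (The
nominal grid is sometimes described as 50 segments of 100 ms, but 1225
samples at 250 Hz only fill 49 full bins; the bin count is configurable but
49 is the computed default.) Band-limited variants first pass the
baseline-corrected epochs through a zero-phase forward–backward Butterworth
band-pass (order 4 per pass; theta 4–8, alpha 8–12, beta 13–30, gamma
30–45 Hz). Baseline correction subtracts each trial × sensor's mean
pre-stimulus (t < 0) signal from the whole epoch. Region RDMs are averaged
element-wise into their networks.

**Coding strengths and group inference.** Empirical-to-model comparison
uses Spearman correlation *without tie correction*: mid-ranks, then
ρ = 1 − 6Σd²/(n(n²−1)) even in the presence of ties. A consequence worth
making explicit: with a heavily tied model RDM this estimator is positively
biased under pure noise — for tie deficit T of the model's rank vector its
null expectation is 6T/(m(m²−1)), ≈ +0.069 for the three-level RC model
over 630 puzzle pairs. Group one-sample t-tests therefore centre the
Fisher-z coding strengths on this closed-form null mean (verified against
brute-force permutation in the tests); without the centring, a t-test
against zero flags pure noise everywhere and no null result could ever be
observed. Tests are one-sided (positive) by default — model correspondence
is directional — with a two-sided option. FDR control uses
Benjamini–Yekutieli by default (Benjamini–Hochberg available) across
regions, networks, or time bins within band × model.

**Fusion.** Ranks are computed once per RDM (mid-ranked upper triangles,
row-major i < j); semi-partial R² is realized as ordinary least-squares
residualization on ranks followed by squared Pearson correlation, and the
commonality coefficient is the difference of the two semi-partial R²
values. Negative commonality (suppression) is possible and never clipped.
The permutation null draws one puzzle relabelling per iteration and applies
it to the rows and columns of every EEG RDM, shared across time bins so the
null preserves the temporal dependence of the statistic (per-bin redraws
are available); p = (1 + #{null ≥ observed})/(n_perm + 1), ties counted as
exceeding. The fusion stage defaults to BH for its FDR step: with
permutation granularity 1/(n_perm+1), the BY penalty c(49) ≈ 4.5 would push
the smallest achievable adjusted p above α = 0.05 unless five or more bins
tie at the minimum, making discoveries nearly impossible at realistic
permutation counts. n_perm defaults to 5000 in the library and 1000 in the
pipeline configuration.

**Spectra.** Welch PSD over 2.1–4.2 s post-stimulus (500-sample Hann
segments, 50 % overlap, restricted to 2–45 Hz), averaged over trials and
channels. The aperiodic component is a fixed-mode (no-knee) robust line in
log–log space: iteratively refit while discarding the largest positive
residuals (peaks only add power), which recovers a peak-free power law
exactly and tolerates narrowband peaks. The periodic component is a single
Gaussian fitted to the flattened spectrum around the in-band residual
maximum (width bounded by half the 0.5–12 Hz peak-width limits); a maximum
sitting on a band edge with the residual still rising beyond it is treated
as a neighbouring band's tail, not an in-band peak. This is deliberately a
single-band, single-pass simplification of full multi-peak spectral
parameterization; participants without a defined peak in every condition
are excluded from group peak comparisons.

## Problem sizes

The default configuration reproduces the study dimensions (376 regions,
64 sensors, n = 40/45). Analysis drivers, recovery tests and the heavier
acceptance checks run at reduced scale — typically 94 regions (same 13
networks), 24 sensors, and 12–20 participants, with 1000 permutations —
chosen as the smallest sizes at which the implanted effects are recovered
reliably; all structural checks (grid sizes, RDM dimensions, network
counts) use the full defaults.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* of the study: graded
behaviour, model-consistent representational geometry, band- and
window-limited temporal structure over 1/f noise, and cross-modal shared
variance. It deliberately omits: realistic vertex-level spatial covariance
and haemodynamics (betas are drawn directly), volume conduction and sensor
covariance in EEG (the mixing is orthonormal, noise is spatially white),
artefacts, and any dependence of single-trial brain data on single-trial
behaviour. Recovery of the implants therefore validates the *pipeline* —
estimators, inference, calibration — not claims about real neural data.
Two further caveats: the broadband temporal RSA is less sensitive than the
band-limited analyses at the default signal-to-noise (the implant occupies
a small fraction of broadband power), and FDR at α = 0.05 across 49 bins
admits occasional false-positive bins outside the implant window by
construction (~5 % of discoveries), so localization checks treat the
*peak* of the significant set, not every stray bin, as the recovered
window in the fusion analysis.

## Degenerate inputs and numerical conventions

Constant vectors raise explicit degenerate-input errors in correlation and
semi-partial computations (rather than returning 0); |ρ| = 1 raises on
Fisher transform unless clipping is requested; RDM constructors symmetrize,
clip tiny negative round-off to zero and zero the diagonal; all oracles in
the test suite are independent implementations (explicit loops, normal
equations, counting-based mid-ranks, step-up FDR) compared at 1e−12
(1e−10 for regression-based quantities).
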