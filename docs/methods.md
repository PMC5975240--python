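# Methods

`speechdcm` implements a complete dynamic-causal-modelling analysis of
two-condition auditory evoked responses over a bilateral fronto-temporal
speech network: a combinatorial model space, a neural-mass generative model,
scalp-level ERP preprocessing, variational model inversion, and
random-effects Bayesian model selection (BMS) with family-level inference.
Because no raw EEG accompanies the design it emulates, every empirical claim
the package makes is validated on synthetic data whose generating process is
known; this note records the model, the defaults, and the reasoning behind
the choices that were genuinely open.

## 1. Model space

Ten sources — primary auditory cortex (A1), Wernicke's area (W), Geschwind's
territory (G), Broca's area (B) and the supplementary motor area (SMA), per
hemisphere — occupy hierarchy levels 1–5. Each hemisphere independently
realises one of five pathway levels:

| level | forward edges (within hemisphere)   | interpretation |
|-------|-------------------------------------|----------------|
| L0    | —                                   | A1 only |
| L1    | A1→W                                | temporal cortex only |
| L2    | A1→W, W→B                           | arcuate, direct segment |
| L3a   | A1→W, W→G, G→B                      | arcuate, indirect segments |
| L3b   | A1→W, W→G, G→B, W→B                 | arcuate, direct + indirect |

Two constraints close the enumeration: the L3a/L3b variants are never mixed
across hemispheres, and a B→SMA (frontal-aslant) extension may only attach
to a hemisphere that realises the deepest pathway present in the model (and
at least L2, so B exists). These rules produce exactly 48 structures. Each
structure appears twice — condition effects on forward gains only, or on
forward and backward gains — for 96 models. Family labels follow the deepest
arcuate pathway anywhere in the model crossed with the presence of any SMA
extension, which reproduces all printed family sizes simultaneously:
8 (Null) / 10 / 28 / 14 / 36, merging to 38 vs 50 (arcuate vs
arcuate-aslant) and 24 vs 64 (direct-only vs Geschwind-routed).

Backward connectivity is treated as structurally present in every model
(reversals of the forward set); the modulation field selects which gains may
*change* between conditions. This is the reading under which "forward-only"
and "forward-and-backward" models remain nested generative models of the
same data and differ in where condition effects can act. Interhemispheric
(lateral) connections are omitted throughout: no model description uses
them. Model identifiers are assigned lexicographically over
(level_left, level_right, sma_left, sma_right, modulation) and are stable.

## 2. Neural-mass generative model

Each source is a Jansen–Rit column: pyramidal cells, excitatory
interneurons and inhibitory interneurons, coupled through second-order
synaptic kinetics `v'' = (H/τ)u − (2/τ)v' − v/τ²` and a zero-centred
sigmoid `S(v) = 2e₀·σ(r(v−v₀)) − 2e₀·σ(−rv₀)` (so the resting state is an
exact equilibrium at 0). Constants are literature-standard: He = 3.25 mV,
Hi = 22 mV, τe = 10 ms, τi = 20 ms, γ = (135, 108, 33.75, 33.75),
e₀ = 2.5 s⁻¹, v₀ = 6 mV, r = 0.56 mV⁻¹. Integration is performed in SI
units internally.

Extrinsic afferents follow the hierarchical convention. Forward afferents
enter the excitatory-interneuron sigmoid argument. Backward afferents drive
the pyramidal population through an amplified excitatory relay
(κ_bwd_pyr = 10) and the inhibitory population weakly (κ_bwd_inh = 0.1).
The κ weights are a deliberate design decision: with a symmetric targeting
the inhibitory route (weighted by γ₄·Hi·τi) dominates and top-down coupling
is net *suppressive*, in which case reducing backward gains would enlarge
the evoked response. The chosen weights put the network in the regime where
recurrent loops amplify the response, so the embedded ground-truth effect —
backward-gain attenuation under temporal cueing shrinks the N1 — has the
direction the design calls for. Both weights are exposed on `JRParams`.

Default coupling gains (forward 24, backward 8, SMA edges 8, stimulus
amplitude 60 on a 16 ms Gaussian bump at t = 60 ms) were calibrated once,
jointly, against four requirements: sources stay out of sigmoid saturation,
dynamics remain stable at 1.8× all extrinsic gains (beyond the ±2σ range of
the inversion priors), the vertex N1 lands near −7 µV, and the backward
attenuation effect (B = −0.4) moves the N1 by roughly 15 % — the kind of
single-condition effect size auditory suppression studies report. The
integrator is fixed-step RK4 at dt = 0.5 ms with a 16 ms extrinsic delay
ring buffer; delayed drives are linearly interpolated across RK4 stages,
which brings the dt = 0.5 → 0.25 ms difference to ~0.01 % of the ERP peak
(fitting therefore runs safely at dt = 1 ms). Intra-columnar interactions
are instantaneous, as in the standard single-column formulation; the
nominal 2 ms intrinsic delay is kept as metadata only.

The lead field is synthetic: each source projects a Gaussian spatial
profile (σ = 0.8 in normalised head coordinates) centred at its scaled MNI
(x, y) position onto a 63-electrode grid with a vertex channel ("Cz"),
signed per region (temporal sources negative) so the summed auditory
response is a fronto-central negativity. Only topographic plausibility is
claimed — there is no head model, and the MNI coordinates serve as layout
metadata, not anatomy.

## 3. Synthetic cohort

`synthetic_data.gen_cohort` emulates the cued/passive listening design: per
subject, log connection gains jitter with sd 0.1 and condition gains with
sd 0.15 around the group truth (backward B = −0.4, intrinsic A1 B = −0.2,
forward B = 0); 75–125 trials per condition (uniform per subject) are tiled
at 1–3 s intervals; band-limited noise (70 % white / 30 % 1/f power) is
added at a single-trial ERP-to-noise RMS ratio of 0.3; stereotyped ~300 ms,
180 µV blinks appear on VEOG at 8/min with quadratic anterior falloff into
frontal channels. Recordings are 63 EEG + VEOG/HEOG channels at 256 Hz
(the windows are specified in milliseconds, so the rate is free).

What the generator does *not* emulate: real N1 morphology beyond a single
evoked transient (no P2/N2 complex), spatially correlated noise, alpha
rhythms, electrode drift or bad channels, volume-conducted EOG beyond the
stereotyped blink, or any acoustic property of the vocalisations. Passing
tests therefore demonstrate that the pipeline's logic is sound and its
estimators calibrated under known ground truth — not that the method would
behave identically on recorded EEG.

## 4. Scalp pipeline

Fixed order: EOG regression (OLS of each EEG channel on [VEOG, HEOG] over
the whole recording, intercept estimated but not subtracted) → zero-phase
band-pass → epoching (−100..+400 ms) → baseline correction (−100..0 ms) →
±50 µV rejection (EEG channels, after baseline correction — the rejection
threshold is deliberately applied post-correction so a DC-offset trial is
not rejected for its offset) → per-condition averaging. The band-pass is a
4th-order Butterworth high-pass/low-pass cascade run forward–backward; the
corner frequencies are pre-warped so the *two-pass* magnitude is −3 dB at
the nominal 0.5 and 30 Hz edges, keeping ripple under 1 dB across 1–25 Hz
(a naive filtfilt at the nominal corners fails that). The N1 is the most
negative value 50–150 ms post-onset at the vertex channel, ties resolved to
the earliest latency; the condition contrast is a paired t-test with
Cohen's d = mean(diff)/sd(diff). Identical inputs return t = 0, d = 0 by
convention; constant non-zero differences are an error. A mastoid-style
re-referencing helper is provided but unused by default (the synthetic
montage has no mastoids and is generated average-reference-like).

## 5. Inversion

Free parameters are log-scalings: one per extrinsic gain, one per modulated
condition gain (B), intrinsic A1 condition gains, a global input amplitude
and a global lead-field scale (5–36 parameters depending on the model).
Priors are zero-mean Gaussians — variance 1/16 for gains, input and
lead-field scale, 1/4 for condition gains — and the passive condition is
always the baseline (multiplier 1). Data are reduced to the top spatial
singular vectors of the concatenated two-condition ERP; six modes are the
default. Four modes capture ~97 % of variance but were found to distort the
intrinsic-gain estimates (the cued-vs-passive difference at A1 loads on the
later modes); six modes recover all parameter classes without bias at
negligible extra cost.

The objective is the variational free energy
`F = −λ/2(e'e + tr(J'JΣq)) + N/2·log(λ/2π) − KL(q‖prior) + log p(log λ)`,
ascended by damped Gauss–Newton steps on the posterior mean (Jacobian by
central finite differences, step 1e−3, batched through the simulator so a
full Jacobian costs one vectorised run), with closed-form coordinate
updates for Σq and scalar Newton ascent for the noise precision under a
weak Gaussian hyperprior on its log (mean 0, variance 16). A step is
accepted only if the fully re-evaluated F does not decrease (tolerance
1e−6); otherwise the Levenberg damping doubles (initial 1, halved on
acceptance). Iteration stops at |ΔF| < 0.01 or 64 iterations, or when no
admissible uphill step exists. Unstable parameter proposals (non-finite
integrations) are treated as rejected steps; a non-finite prediction at an
accepted point aborts the fit loudly. Cohort fitting never imputes missing
entries — a failed fit fails the cohort.

Observation noise is a single iid Gaussian precision across modes and time;
mode-specific precisions were considered and dropped for parsimony (the
residual after fitting the generating model is projection-isotropic in the
synthetic setting).

## 6. Random-effects BMS

Given subjects × models log evidences, the mean-field scheme alternates
assignment weights `u_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα))` with counts
`α = α₀ + Σ_n u_n` until max |Δα| < 1e−6. Reported per comparison:
expected probabilities α/Σα, exceedance probabilities by Monte Carlo
(10⁶ draws, chunked, seeded; argmax ties break to the first index — a
measure-zero event), the exact regularised-incomplete-beta value for
two-way comparisons (used as the test oracle for the Monte Carlo path), and
the Bayesian omnibus risk `BOR = 1/(1 + exp(F₁ − F₀))` comparing the
random-effects bound F₁ against the equal-frequency null F₀. Protected
exceedance probabilities, `(1 − BOR)·xp + BOR/K`, are computed alongside as
a clearly-labelled extension.

Family-level inference gives every family equal prior mass by marginalising
models within each family under a uniform 1/m_j prior —
`L_nj = logsumexp_{k∈j} L_nk − log m_j` — and running the random-effects
scheme over family frequencies with unit prior counts. The superficially
equivalent alternative, feeding per-model counts α₀ = 1/m_j directly into
the mean-field update, was implemented first and rejected: with sub-unity
asymmetric counts the digamma-weighted assignment step is prior-dominated,
and for completely uninformative evidence its fixed point puts ~0.92 of the
expected mass on the smaller family, whereas the exact posterior is the
prior (equal family probabilities). The marginalisation route reproduces
the exact limit, reduces to the model-level scheme for singleton families,
and makes the two-way family comparisons amenable to the exact beta oracle.
The merged partitions (arcuate vs arcuate-aslant; Geschwind vs
no-Geschwind) operate on the 88 non-Null models only.

## 7. Validation studies and problem sizes

All validation runs on synthetic data with fixed seeds and desk-scale
sizes chosen as the package's own defaults:

- **Model/parameter recovery**: 8 subjects generated from the bilateral
  L3b forward+backward model, fitted with a 6-model subset (three
  structures × two modulation schemes). The generating model should carry
  the highest evidence for most subjects, its modulation family should win
  the family comparison decisively, and pooled true-vs-posterior condition
  gains should correlate above 0.7. The pooled correlation is carried by
  the separation of backward (≈ −0.4) from forward (≈ 0) effects plus
  within-class jitter; the two intrinsic gains are only weakly identified
  and dilute it, so the pooled value sits near the 0.7 mark and varies
  across noise realizations.
- **Scalp contrast**: 20 subjects through the full preprocessing chain;
  the cued condition should show the smaller |N1| at p < 0.05.
- **BMS calibration**: 100 null evidence matrices (median BOR > 0.5), a
  dominant-model matrix (BOR ≪ 0.05), exceedance Monte Carlo vs the exact
  beta integral, and Dirichlet mass conservation.

The full 96-model × cohort fit is supported (`--fit-all-models`) but is a
long batch job (~10 s per subject-model fit); the four family comparisons
of the full design are therefore demonstrated on synthetic 96-column
evidence matrices in the default reports.

## 8. Known limitations

- The inversion estimates log-scalings around the true generative
  architecture's default gains; it is a reduced scheme, not a full
  neural-mass parameter estimation (synaptic constants are fixed).
- Free energies are comparable across models for a fixed data reduction;
  changing `n_modes` changes the data and hence the evidence scale.
- The equal-prior-mass family construction resolves prior sensitivity at
  the family level but still inherits the mean-field approximation of the
  random-effects model.
- No parametric empirical Bayes / Bayesian model reduction, no
  conductance-based or canonical-microcircuit variants, no source
  localisation, and no fixed-effects group inference beyond a debug output.
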