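# Methods

## Model overview and assumptions

The package reduces the multicompartmental mushroom body to two
compartments with a single rate unit per cell class: one approach MBON
(M₊), one avoidance MBON (M₋), one appetitive DAN (D₊) and one aversive DAN
(D₋).  Kenyon cells are the only modelled input; upstream olfactory
processing is bypassed.  All neurons are linear–nonlinear units,
y = f(Σⱼ wⱼxⱼ) with f(z) = max(0, z), and every event within a trial is
compressed to a single point in time — there are no within-trial dynamics,
no eligibility traces, and no credit assignment across time.  The only
objective embodied in the plasticity rules is the minimisation of the
squared reinforcement prediction error C = ½ Σᵢ (r̂ⁱ − m̂ⁱ)², where
m̂ = m₊ − m₋ is the circuit's reinforcement prediction and r̂ = r₊ − r₋ the
net reinforcement.

One sign convention is worth flagging: the valence channels of a signed
reinforcement draw r are stored as magnitudes, r₊ = max(0, r) and
r₋ = max(0, −r), so that r̂ = r₊ − r₋ always recovers the signed draw.

## Circuit variants

All variants share the MBON equation m± = f(w±ᵀk), the KC→DAN weight
vector w_K = γ·1 and the MBON→DAN feedback weight w_M = 1, and differ only
in the DAN equations and the plasticity drive (see the README table).  The
VSu-B equations are not uniquely fixed by qualitative circuit descriptions
alone; the implemented form — same-valence reinforcement excitation,
inhibitory same-valence feedback, and potentiation driven by the
same-valence DAN above its KC baseline, P± = η k (d± − γΣk) — is the unique
choice under which the two dual unbounded circuits produce identical RP
trajectories, which the test suite verifies to 1e-9.

The MV model's two plasticity derivations are both provided: the
DAN-difference form P± = (η/2) k (d± − d∓) (the default) and the
KC-reference form P± = η k (γΣk − d∓).  They coincide whenever neither DAN
is clipped by rectification.  The factor ½ in the DAN-difference form
exists because the MV DAN difference doubles the RPE; η is therefore passed
to it unmodified and never halved a second time.  The two forms genuinely
dissociate when DAN activation substitutes for reinforcement: artificial
D₊ input sustains a memory under the DAN-difference form but produces only
a transient one under the KC-reference form, because the latter's
unmodified opponent drive erodes the potentiated weights once the
avoidance weights are pinned at zero.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| η | learning rate | 0.025 (step demos), 0.1 (bandit), 0.05 (conditioning), 0.025 (blocking) | protocol-specific values used by the reference simulations; blocking uses 0.025 because the compound stimulus doubles Σk to 20 and η must respect the averaging bound η < (2Σk)⁻¹ — at η = 0.05 the compound phase overshoots 2× per trial and never converges |
| β | softmax inverse temperature | 3 | chosen so that control appetitive conditioning reaches a near-ceiling CS+ preference (PI ≈ 0.78); at β = 1 the control PI is only ≈ 0.46, inconsistent with training protocols tuned to plateau near maximal performance |
| λ | VSλ potentiation constant | 11.5 (demos), 12 (conditioning) | sets the RP bound \|m̂\|max = max(0, λ − γΣk); 12 leaves conditioning (\|r̂\| ≤ 1) unbounded |
| γ | KC→DAN weight | 1.0 | baseline DAN drive γΣk = 10 keeps both DANs away from rectification for the RPE ranges simulated |
| σ_R | reinforcement noise s.d. | 0.1 | per-trial Gaussian noise on the scheduled mean |
| w_M | MBON→DAN feedback | 1.0 | required for d₊ − d₋ = r̂ − m̂ |
| w(0) | initial weights | 0.1·U(0,1) per synapse | standard initialisation for every run |
| N_fly | Δ_f sample size | 50 | matches the runs per batch |

Weight updates apply only to the chosen cue's synapses (enforced by the
cue's KC vector) and are clipped at zero by projection after each update —
for dedicated coding it is immaterial whether clipping precedes or follows
the chosen-cue restriction, and clipping-after-update is used throughout.
The stability bound η < (2Σⱼkⱼ)⁻¹ is surfaced as a warning, not an error:
the bandit protocol deliberately runs at the deadbeat boundary.

## Sensory coding and schedules

Dedicated coding assigns 10 KCs per cue at 1 Hz (N_K = 10·N_c, disjoint);
random-sparse coding assigns each of 2000 KCs to each cue with probability
0.05 and renormalises each cue's total rate to 10 Hz so that the
rate-dependent learning speed is unchanged.  The blocking paradigm uses two
disjoint 20-cell subsets with 10 active cells each; corruption silences
each active cell with probability p_cor and wakes an equal number of silent
cells of the same subset, preserving the active count.  Corruption is
redrawn on every compound trial (a frozen corruption would merely define a
new stimulus); a `frozen_corruption` switch preserves the alternative
reading.

The step schedule holds μ = 0 for 20 trials and applies cumulative ±1 steps
(+1 at trials 21, 41, 141, 161; −1 at 61, 81, 101, 121).  The filtered-noise
schedule low-pass filters 250 samples of unit white noise with a unit-area
circular Gaussian kernel (s.d. τ = 10 trials) in the frequency domain,
discards 50 burn-in samples, and scales each cue's trace so its retained
peak is exactly 2; the amplitude normalisation is per cue, and the σ_R
noise term is folded directly into μ (the returned schedule carries
σ_R = 0 so the noise is not added twice).

## Protocols

Conditioning: 10 forced CS+ exposures (r ~ N(μ_US, σ_R), μ_US ∈ {+1, 0, −1}),
10 forced CS− exposures (μ = 0), then 2 two-alternative softmax test trials
with μ = 0 for both cues and plasticity continuing.  Interventions rescale
(×0.1) or offset (+5) the target neuron's output during their scheduled
stages — "CS+ only", "training" (both stages), "test only", or "all" — and
the modified output is consumed everywhere it projects: the softmax, the
DAN feedback, and (for DAN targets) the plasticity drive.  Batches of 50
runs pool 100 test choices into one PI; 20 batches yield a PI distribution,
and intervention batch *i* is paired with control batch *i* for Δ_f.

Blocking: 10 forced X trials (r ~ N(1, 0.1)), 10 forced compound XY trials
(same rewards, per-trial corruption), then 2 softmax test choices between
the uncorrupted Y and a null option whose RP is the constant 0 (the null
bypasses the circuit; choosing it updates nothing).

The bandit (MAFC) protocol evaluates RPs for all cues, samples one choice
per trial by inverse-CDF sampling of the softmax, and updates only the
chosen cue.  A perfect-plasticity baseline (chosen cue's RP set to the last
obtained reinforcement) provides an upper reference for the trial-averaged
obtained reinforcement in noiseless environments.

## Statistics

Δ_f uses the two-sample binomial null s.d. exactly as written above; for
f_i = 0.7, f_c = 0.9, N_fly = 50 it evaluates to −2.5.  Degenerate records
(f_i = f_c ∈ {0, 1}) are NaN and dropped from fits with a logged warning.
The robust fit is IRLS with the Tukey bisquare (tuning constant 4.685, MAD
scale, ≤ 50 iterations, 1e-8 coefficient tolerance), delegated to
statsmodels' RLM; perfectly collinear data (zero robust scale) short-circuit
to the least-squares solution with unit weights.  The reported correlation
is the Pearson R of the weight-scaled vectors — computed literally as the
covariance of (w·x, w·y) over the product of their standard deviations,
even though other weighted-correlation conventions exist.  The permutation
test reshuffles the pairing of the weighted vectors with +1 smoothing; the
bootstrap CI case-resamples and refits the weights per resample.

## Synthetic comparison fixture

The experimental performance indices that the comparison pipeline was
designed for live in external publications and are not shipped.
`generate_fixture_table` emits a synthetic stand-in with the same schema:
each row's "experimental" Δ_f equals attenuation × model Δ_f plus Gaussian
noise, realised as a (PI_intervention, PI_control) pair by inverting the
Δ_f formula at a fixed control fraction (0.85).  Attenuation < 1 emulates
the compression of real behavioural effect sizes.  Passing tests on this
fixture demonstrate that the pipeline recovers a known relationship
(R = 1 at zero noise; high R under attenuation and noise); they do not
certify agreement with real fly data, which additionally varies in fly
counts, protocol details and inter-study heterogeneity the fixture does
not model.

## Problem sizes and numerical choices

Simulated protocols are short by construction (22 trials per conditioning
or blocking run; 180–200 trials per bandit run), and the shipped analyses
use 20 batches × 50 runs per condition, matching the reference batching.
Softmax probabilities are computed with max-subtraction; β = ∞ is an exact
argmax with uniform tie-breaking.  Choice sampling uses the standard
inverse-CDF rule (smallest index whose cumulative probability reaches the
uniform draw).  Each run draws its own initial weights; named RNG
substreams derived from the root seed keep protocol stages decoupled so
that toggling an intervention does not perturb unrelated draws.

## Known limitations

No spiking dynamics, within-trial time courses, compartment-resolved
anatomy, memory consolidation, forgetting/weight decay, DAN adaptation, or
temporal-difference-style credit assignment.  The environment is
non-reactive (schedules do not depend on behaviour).  β is a free parameter
of the decision layer: results that depend on choice stochasticity scale
with it, and only effect sizes robust to its neighbourhood should be
interpreted quantitatively.  One genuine divergence is documented in the
test suite: with the intervention contract applied literally, blocking M₊
throughout training leaves the CS− cue with a residual positive RP in the
MV model, producing a moderate negative Δ_f where a near-zero effect would
be expected from the corresponding fly experiments.
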