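# Methods

## The model

`prodiff` simulates the spread of a novel behaviour `b` through a fixed
population of `N` agents that already share an established behaviour `a`.
Two coupled processes run each timestep.

**Acquisition** (who *knows* `b`). Each naive agent `i` acquires knowledge
of `b` with per-timestep probability

    P_i(t) = 1 − exp(−λ_b (T_i(t) + A)),      T_i(t) = s Σ_j a_ij w_bj(t),

where `a_ij` is the binary association network, `A ∈ {0,1}` switches
spontaneous asocial innovation, `s` is the social transmission rate, and
the transmission weight `w_bj(t)` is the proportion of the last `m`
completed timesteps in which neighbour `j` actually produced `b`. This is
the generative form of the hazard that network-based diffusion analysis
(NBDA) fits statistically: transmission flows along edges, and only from
agents who perform the behaviour, not merely from agents who know it.

**Production** (who *does* `b`). Every agent produces exactly one
behaviour per timestep from its repertoire (`{a}` or `{a, b}`), following
an experience-weighted-attraction (EWA) style choice rule. Expected values
update by exponential smoothing, `E_k(t) = ρ r_k(t−1) + (1−ρ) E_k(t−1)`,
with reward 1 for the behaviour produced last step and 0 otherwise, so
values of unproduced behaviours decay — values can never exceed the true
reward. A softmax with risk-appetite `α` maps values to individual choice
probabilities `I_k`; counts of each *known* behaviour produced by
neighbours within the memory window, raised to the frequency-bias exponent
`f` and normalized, give social weights `S_k`; the final probability is
`P_k = (1−σ) I_k + σ S_k`. A newly knowledgeable agent starts at `E_b = 0`
(it has never experienced the reward) but can still produce `b` through the
softmax floor and social weight — this reinforcement-learning bottleneck is
what separates first production from acquisition.

The two sub-models close the loop: production frequencies drive the
transmission weights, and acquisition expands the repertoires available to
the production rule.

## Parameters and defaults

| symbol | meaning | default | tested values |
|---|---|---|---|
| N | population size | 24 | fixed |
| k | network degree (random regular) | 6 | fixed |
| λ_b | baseline learning rate / timestep | 0.05 | fixed |
| s | social transmission rate | 5 | 0 or 5 in inference studies |
| A | asocial innovation switch | 0 | 1 in inference studies |
| σ | social information bias | 0.5 | 0.25, 0.5, 0.75 |
| f | frequency-dependence exponent | 1 | 0.33, 1, 3 |
| m | memory window (timesteps) | 10 | 10, 20, 30 |
| ρ | recent experience bias | 0.1 | 0.01, 0.1, 0.99 |
| α | risk appetite | 1 | 0.5, 1, 2 |
| r_a, r_b | behaviour rewards | 1, 1 | fixed |

The defaults are the reference condition; the full factorial over the five
production parameters (3⁵ = 243 constellations) is `table1_grid()`.
ρ is swept over orders of magnitude because the value recursion responds
nonlinearly to it.

## Timing conventions

Timesteps are 1-based. Within a timestep the order is: value update from
last step's rewards → production by all agents → acquisition draws by
naive agents. Consequences: (i) the acquisition hazard and the social
observation term both read the `m` *completed* timesteps strictly before
`t` — a production at `t` is not observable until `t+1`; (ii) an agent
acquiring at `t` first produces `b` at `t+1` or later. The alternative
ordering, in which acquisition precedes production and a new acquirer may
produce `b` immediately, is available via `run_simulation(order=
"acquire_first")`. We fixed the default by replicating the reference
diffusion statistics: the one-step information lag reproduces the
benchmark tempo/divergence/delay values, while the immediate-production
variant runs systematically faster (mean TTD ≈ 51 vs ≈ 54) with smaller
delays. At early timesteps (`t ≤ m`) windows are truncated to the
available history; transmission weights always divide by `m`, while the
social weights are self-normalizing so the divisor cancels.

The seed agent is assigned acquisition time 0, so it always holds
acquisition rank 1; its first production is stochastic like everyone
else's. Simultaneous events receive distinct ranks by seeded uniform
tie-breaking. Simulations that cannot meet their stopping rule (e.g.
`s = 0, A = 0`) are cut off at 10,000 timesteps and flagged, not raised.

## Diffusion statistics

Per run we record times and ranks of acquisition and first production, and
report time-to-diffusion (TTD, last acquisition), time-to-first-production
(TTFP), the order divergence `d_order = Σ|o_a − o_p| / (N−1)` (the seed
agent's term excluded), the delay `d_time = mean |t_a − t_p|`, the fraction
of agents with divergent ranks, and the pooled agent-level R² of
first-production rank on acquisition rank. Replicate batches are
summarized by mean, standard error and 92% central percentile intervals
(linear-interpolation quantiles). Pooling R² and the divergent fraction at
the agent level across replicates matches how the benchmark density plots
are constructed; per-run and pooled versions agree in expectation.

## TADAc inference

`nbda.fit_tadac` maximizes the continuous time-of-acquisition diffusion
likelihood: between events each naive agent has hazard
`λ0 (s Σ_j a_ij w_j z_j(t) + 1)` with `z_j` the (inferred-as-known)
knowledge indicator; the asocial null fixes `s = 0` and is nested. The
likelihood is the product over inter-event intervals of joint survival
times the event agent's hazard. For fixed `s` the baseline rate has the
closed-form optimum `λ0(s) = n / ∫exposure`, so the social fit reduces to
a one-dimensional profile search over `s` (coarse log-grid plus bounded
refinement); the asocial MLE is fully closed-form. Models are compared by
AICc with `n` = number of events; support for social transmission is
`ΔAICc = AICc_asocial − AICc_social > 0` (ties count as asocial).

Event times come from a discrete-time simulation, so simultaneous events
are common, especially in the fast "ideal" diffusions. We keep tied events
at their recorded timestep, break their order uniformly at random with
negligible (1e-6) offsets, and update knowledge states event-by-event:
tied events contribute no survival mass between one another. Smearing ties
uniformly across the whole step instead systematically weakens the social
model (it randomizes event order *and* donates survival time to the
asocial null) and noticeably understates support for social transmission
on ideal data.

Data regimes: *ideal* data are times of acquisition generated by the
hazard alone with indicator weights (`w_j = 1` once knowledgeable) — the
assumption set under which NBDA is exact; *realistic* data are times of
first production from the full linked model, fitted with static per-agent
weights equal to the observed production rate of `b` (total productions ÷
timesteps knowledgeable). Under social mechanisms the seed agent enters as
a demonstrator (hazard contribution, no event term); under purely asocial
mechanisms there is no seed and every agent is an event.

## Production-parameter inference

`ewa.fit_ewa` estimates `(ρ, σ)` from a production history with `f, α, m`
held at reference, under independent uniform(0,1) priors. The likelihood
deterministically replays the generative equations — given the recorded
productions, the network and the knowledge states, it reconstructs every
agent's choice probability at every timestep and scores the recorded
choices; at the true parameters the reconstructed probabilities equal the
engine's recorded ones to machine precision (tested). The value recursion
is evaluated as a linear filter over the reward stream, so one likelihood
evaluation is a few array operations.

Two analyst conventions are provided. The *realized-repertoire* likelihood
honours true acquisition times (`E_b` pinned to 0 at acquisition). The
*homogeneous-repertoire* likelihood — the default for diffusion scenarios,
and the convention of standard EWA analyses — assumes everyone knew both
behaviours throughout, with the symmetric stationary start
`E_a = E_b = 1` at `t = 1`. Applied to data from a real diffusion, the
homogeneous convention must explain early universal production of `a` by
apparent social influence, which is exactly the σ-overestimation artefact
the recovery study demonstrates.

Sampling uses an affine-invariant ensemble MCMC (walkers serve as chains
for R-hat and effective-sample-size diagnostics via ArviZ); defaults are
32 walkers, 500 burn-in steps and 16,000 retained draws. Any sampler
meeting the draw-count and convergence contract is acceptable; fits with
R-hat > 1.05 are flagged, not discarded. Intervals are 92% highest-density
intervals (narrowest window containing ⌈0.92 n⌉ sorted draws).

The recovery study (`ewa.run_scenarios`) runs three scenarios at each
(ρ, σ) in {0.25, 0.5, 0.75}²: (1) homogeneous repertoires, pure production
dynamics for 300 timesteps; (2) diffusion by social transmission only
(A=0, s=5); (3) asocial innovation only (A=1, s=0). Scenarios 2–3 run for
twice their time-to-diffusion so the record holds equal spans of during-
and post-diffusion data.

## Experiment batteries and reproducibility

Every battery derives its randomness from a master seed through
`numpy.random.SeedSequence` spawn keys indexed by (cell, replicate), so
results are bit-reproducible and cells are independent; each replicate
draws a fresh random regular network. `nbda_battery` optionally
checkpoints per-constellation CSVs and resumes interrupted sweeps.
Problem sizes used by the shipped analyses: 100 replicates per
constellation for the sensitivity rows, 10 per constellation (2,430 runs)
for each TADAc battery, and a reduced recovery battery (2×2 grid, 1–2
replicates) for the Bayesian fits, whose conclusions are qualitative
(coverage and bias direction) rather than count-exact.

## What the synthetic data do and do not show

All data are generated by the model itself; that is the point of the
study design (known ground truth for inference), but it bounds the claims.
The networks are static, unweighted and regular; rewards are equal,
deterministic and constant; agents never die, forget `b`, or attend to
others' rewards; behaviour is binary. Passing tests therefore demonstrate
internal consistency of generation and inference and the qualitative
failure modes of the inferential models under repertoire heterogeneity —
not performance on empirical diffusion data, where association strengths,
reward structure and observability all vary.

## Numerical notes and limitations

- `0^f` is defined as 0; if every in-repertoire neighbour count is zero
  the social weights fall back to uniform over the repertoire (no-signal
  neutrality).
- Probability maps are normalized to 1 within 1e-12 by construction;
  hazards use `expm1` for accuracy at small rates.
- The TADAc profile search is bounded at `s ≤ 1e4`; data with no social
  exposure ever (all-zero weights) make `s` unidentifiable and the fit
  returns `s_hat = 0`.
- AICc requires `n ≥ K + 2` events; smaller datasets raise an error.
- Ensemble-sampler autocorrelation leaves R-hat around 1.05–1.15 at the
  reduced test settings even when posterior summaries are stable; the
  shipped defaults are chosen to clear the diagnostic on the scenario-1
  proof of concept.
- Replicated ΔAICc magnitudes depend on the tie and weight conventions
  above at the 5–20% level; support *patterns* (which mechanism wins, and
  how often) are robust across the conventions we examined.
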