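# Methods

## Model

The agent is a discrete-state active-inference agent: a POMDP generative
model over T = 5 time steps with two binary hidden-state factors — the
auditory factor (*voice present* / *no voice*) and the speech factor
(*speaking* / *not speaking*) — each observed through its own binary
outcome modality (*sound* / *silence*; *speech movement* / *none*).
Observations arrive at steps τ = 1..T; actions u ∈ {listen, speak} occur
on the T−1 transitions between them, so a policy π is a string of T−1
action labels. Actions are oppositional: listening (orienting, attending)
and talking exclude one another.

### Likelihood (A) and precision ζ

The auditory likelihood is the column-normalized elementwise power

    A(ζ) ∝ (I₂ + κ)^ζ ,   κ = e⁻³ by default,

so the diagonal (correct-mapping) probability is
(1+κ)^ζ / [(1+κ)^ζ + κ^ζ]: 0.894 at ζ = 0.7, 0.83 at 0.525, 0.71 at 0.3,
exactly 0.5 at ζ = 0. ζ is the *likelihood precision*: the fidelity of
the mapping from the world's auditory state to the sensed outcome. The
default κ = e⁻³ places the three experimental ζ values on the
scientifically interesting part of this curve (a tiny κ such as e⁻³⁰
would make all three regimes numerically indistinguishable from the
identity; κ remains a config field). While the agent speaks, the auditory
likelihood is replaced by the uniform matrix — *sensory attenuation*,
protecting the intention to speak from contradictory auditory evidence.
Attenuation is triggered by the *executed* action on the transition into
a step, the unambiguous operationalization (the alternative — triggering
on the inferred speaking state — creates a circular dependency between
inference and the model used for inference). Proprioception is a
noiseless identity mapping and is never attenuated.

### Transitions (B)

Speaking drives the speech factor to *speaking* and the auditory factor
to *no voice*, both deterministically (one-hot columns): one cannot
listen to a partner one is talking over. Listening drives the speech
factor to *not speaking* deterministically, and the auditory factor
*softly toward voice*:

    B_aud(listen) = [[2/3, 4/5], [1/3, 1/5]]   (columns: from voice, from silence)

i.e. while listening, a present voice persists with probability 2/3 and a
voice onsets out of silence with probability 4/5. This soft "expectation
of being spoken to" is the load-bearing design choice of the package: it
is how beliefs about policies ("now is my turn to listen") become prior
beliefs about states ("I am hearing a voice"), while remaining
*defeasible*, so that precise sensory evidence can correct it. A
deterministic listen→voice transition would pin the per-policy auditory
belief at the floored-log odds (±16 nats) against at most ζ·ln((1+κ)/κ) ≈
2.1 nats of sensory evidence, making correct inference impossible at any
precision. The two probabilities were calibrated once against the
intended regimes: the post-turn onset prior (logit 1.386) must lose to
the likelihood at ζ ∈ {0.525, 0.7} (silent-step beliefs 0.45 and 0.32 —
ambiguity and correct inference respectively) and win at ζ = 0.3 (0.62 —
a hallucination); the weaker persistence prior keeps an agent that just
listened through a partner's utterance from hallucinating its
continuation. Values outside roughly (0.75, 0.85) for the onset break one
or the other regime; 4/5 and 2/3 are the round numbers in the feasible
windows.

### Preferences (C), initial beliefs (D), precisions

C is flat (log 1/2 per outcome) in both modalities — behaviour is driven
purely by epistemic considerations — and D is uniform per factor. The
policy precision γ = exp(gamma_log) sharpens the policy posterior (see
below); experiment presets use gamma_log ∈ {−4, 0, +4} (near-flat,
baseline, near-winner-take-all). Probabilities are floored at e⁻¹⁶
before any logarithm, which makes one-hot columns behave as delta
distributions at working precision without −∞.

## Inference

Per policy, the two factors are independent chains (nothing in the model
couples them), so state inference is *exact*: cavity (sum-product)
messages — a forward filtering sweep and a backward future-evidence
sweep — give the smoothing marginals Q(s_τ|π) in one pass. Observed steps
contribute attenuation-aware likelihood messages; future steps are pure
rollout. An earlier draft updated each step from its neighbours' full
marginals (fixed-point mean-field); that scheme double-counts evidence on
soft chains (max deviation 4×10⁻² from enumeration) and was replaced —
the enumeration oracle in `avhsim.oracle` now agrees with the engine to
~3×10⁻¹⁶ over the whole T ≤ 3 validation grid.

The free energy of a policy is evaluated on the time-factorized Q:

    F(π) = Σ_f [ E_q ln q − E_q ln D − Σ_τ q_τᵀ (ln B) q_{τ−1} − Σ_τ q_τ · ln A[o_τ,:] ]

which upper-bounds −log evidence (equality when the true posterior
factorizes, e.g. under deterministic chains); the bound is asserted over
the validation grid.

The expected free energy of the remaining steps is risk plus ambiguity
per modality, G(π) = Σ_τ Σ_m [ o·(ln o − C) + s·H ], with o = A·s the
predicted outcome. Predictions are attenuation-aware: a policy that
prescribes speaking predicts flat auditory outcomes, which carry zero
risk under flat C — taking a speaking turn is never penalized. The
ambiguity vector H holds the column entropies of the *unattenuated*
likelihood: H is a property of the world's auditory channel, whereas
attenuation is the agent's own attentional act. (If H were computed from
the attenuated mapping, risk + ambiguity would equal ln 2 per step and
modality for *every* policy — G could not distinguish policies at all and
the agent would never speak.)

The policy posterior is a γ-sharpened softmax of total log-evidence over
the action-consistent set:

    Q(π) ∝ exp{ γ · (−F(π) − G(π)) } ,  masked to policies whose past
    actions match those executed.

γ multiplies the whole exponent rather than G alone: with flat C the
G-differences between policies are small, and a precision that scales
only G would be behaviourally inert; as an inverse temperature on the
full posterior, γ → 0 flattens beliefs about what one is doing and large
γ commits to the single best explanation. Percepts are the Bayesian model
average Q(s_τ) = Σ_π Q(s_τ|π) Q(π).

### Action selection

Planning is treated as model selection: the agent executes the action
prescribed by the MAP policy. Policies whose posterior lies within 0.01
nats of the maximum are *tied* — at this problem size, free-energy
margins below that arise from the factorization of F rather than from
anything the model knows — and ties resolve by catalog order, keeping
every run fully deterministic. A tie-break seed parameter exists for
stochastic selection variants and is recorded in outputs, but the default
pipeline never consumes randomness.

## Environment (generative process)

The partner is a script, default `-x-x-` (silence, sound, silence, sound,
silence): alternating speech with silences at steps 1, 3, 5. Whenever the
agent speaks, that generates sound at the next step (overriding the
baseline) and raises the attenuation flag; the environment consults only
executed actions, never beliefs. This scripted partner emulates the
*structure* of a dialogue — turn alternation and self-generated sound —
and nothing else: no semantics, no adaptivity of the partner to the
agent, no acoustic detail. Results therefore speak to the belief dynamics
of precision imbalance, not to speech perception per se.

## Scoring

A **hallucination** at step τ: marginal voice belief > 0.5 (strict),
true outcome silence, and the agent did not speak into τ. A **false
negative** (speech-detection error): belief in *no voice* > 0.5 while
sound is truly present; self-generated sound steps count by default,
because "no longer hearing one's own voice" is itself a reported failure
mode. The 0.5 threshold is deliberately permissive; in the regimes of
interest the flagged beliefs sit near 0.62 and the non-flagged near 0.45,
so the flags are insensitive to the exact threshold within [0.5, 0.6).

## Experiments

All three experiments run the default script at T = 5 and report
hallucination / false-negative steps per condition; each trial takes
milliseconds.

- **Precision sweep** (`fig4_zeta_sweep`): catalog F4 = [SLSL, LLLL,
  LSLL, LLSL] at ζ ∈ {0.7, 0.525, 0.3}, baseline γ. The turn-taking
  policy SLSL is selected; flags move from none (0.7) through ambiguity
  (0.525, max silent-step belief 0.55) to hallucinations at steps 3 and
  5 (0.3).
- **Policy precision** (`fig5_gamma`): F4 at ζ ∈ {0.7, 0.525} × gamma_log
  ∈ {−4, +4}. At baseline ζ no γ produces a flag. The package does *not*
  reproduce γ-induced hallucinations at ζ = 0.525: in this architecture
  the step-3 belief depends only on the executed path and ζ (γ enters
  state inference nowhere, and all action-consistent policies share their
  past), so any parameterization that lets some γ hallucinate at a given
  ζ makes every γ hallucinate there. This is a known limitation,
  documented rather than papered over.
- **Policy-space lesion** (`fig6_lesion`): the full six-policy repertoire
  F6 = [LLLL, LLSS, SLLS, SSLL, SLSL, LSLS] versus the same space with
  the originally-inferred policy LLSS removed, across the ζ sweep. The
  full agent listens through the partner's turn and then takes its own
  (LLSS), covering the silences — no hallucination at any ζ, but it
  stops hearing its own (attenuated) voice at steps 4–5. The lesioned
  agent falls back on policies that speak at step 2 and listen at step 3,
  committing it to expecting a voice during the step-3 silence:
  a hallucination at ζ = 0.3, dose–response 0 → 0 → 1 over the sweep.

The policy catalogs are reconstructions constrained by the experimental
narratives (a vulnerable space whose preferred policy listens into the
silent steps; a full space containing a better explanation of the
exchange; a lesion that removes exactly that policy, leaving two
plausible policies that speak at step 2 but not step 3). Catalog order
matters only through the tie-break and encodes which equally-scoring
policy the agent enacts.

## Numerical choices

- Probability floor e⁻¹⁶ everywhere a log is taken (engine and oracle use
  the same floored matrices, so oracle comparisons are like-for-like).
- Action-selection tie tolerance 0.01 nats (see above); softmaxes are
  computed with max-subtraction and are shift-invariant by construction.
- The enumeration oracle refuses state spaces above 10⁵ trajectories.
- Degenerate inputs: T = 1 trials perform pure likelihood-weighted
  perception (no actions); an all-masked policy set raises an error
  rather than renormalizing silently.

## Known limitations

- The γ manipulation changes the sharpness of policy beliefs (and is
  verified to do so monotonically) but cannot change percepts at observed
  steps; see above.
- False negatives while speaking arise at every ζ, because attenuation —
  not ζ — flattens the likelihood during speech; a graded
  "stops hearing its own voice only at the lowest precision" effect would
  require partial attenuation.
- Two states per factor, five steps, a scripted partner: the model is a
  minimal mechanism demonstration, not a fitted model of hallucinating
  subjects; no parameter is estimated from data.
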