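# avhsim

Auditory verbal hallucinations can be framed as *false positive
inference*: a confident percept of a voice in the absence of any auditory
input, arising when prior beliefs dominate imprecise sensory evidence.
`avhsim` implements a discrete-state active-inference (POMDP) agent
engaged in a simulated turn-taking conversation and reproduces, in
silico, how such false percepts emerge from three computational
manipulations:

1. lowering the **auditory likelihood precision** ζ (a flattened
   state→outcome mapping, as in a cholinergic deficit or degraded sensory
   pathway),
2. changing the **policy precision** γ (confidence in one's own action
   plans, the putative dopaminergic quantity), and
3. **lesioning the policy space** (removing the action plan that best
   explains the conversational exchange).

The package is aimed at computational-psychiatry researchers and students
who want a small, fully inspectable agent–environment loop where every
belief, free energy, and action is exact and reproducible.

## The model

The agent entertains two binary hidden-state factors — *listening to a
voice* (or not) and *speaking* (or not) — observed through two outcome
modalities (sound/silence, speech-movement/none). Beliefs follow a
variational scheme over policies π (candidate action sequences of
`listen`/`speak` over the trial's T−1 transitions):

- **Likelihood.** The auditory mapping is the column-normalized
  elementwise power `(I + κ)^ζ` (κ = e⁻³ by default): ζ = 0 gives a flat
  mapping, large ζ the identity. While the agent speaks, the mapping is
  replaced by the uniform matrix outright — *sensory attenuation*.
  Proprioception is an identity mapping.
- **Transitions.** Speaking deterministically silences the partner and
  engages the speech state; listening carries a *defeasible expectation
  of being spoken to* (a voice onsets out of silence with probability
  0.8, persists with probability 2/3). This is how beliefs about policies
  become prior beliefs about hearing.
- **State inference.** Per policy, each factor is an exact Markov chain;
  cavity message passing yields the smoothing posterior Q(s_τ|π).
- **Policy inference.** F(π) scores the evidence of observed steps;
  G(π) (expected free energy) scores future risk + ambiguity under flat
  preferences. The posterior Q(π) = σ(γ·(−F−G)) masks policies
  inconsistent with executed actions; the percept is the Bayesian model
  average Q(s_τ) = Σ_π Q(s_τ|π)Q(π).
- **Action.** The agent executes the action prescribed by the MAP policy
  (policies within 0.01 nats count as tied and resolve by catalog order).

A *hallucination* is flagged when the marginal belief in "voice present"
exceeds 0.5 at a step whose true outcome is silence that the agent did
not itself break; the mirror-image *speech-detection error* (believing
"no voice" during true sound) is also scored.

## Worked example

Run the vulnerable four-policy space at low auditory precision against
the alternating partner script (silence at steps 1, 3, 5):

```bash
$ avhsim run --zeta 0.3 --catalog f4 --out scratch/trial
actions: speak listen speak listen | hallucination steps: [3, 5] | false-negative steps: [2, 4]
```

The agent takes speaking turns at transitions 1 and 3. Having spoken, its
turn-taking model expects the partner's voice next — and with ζ = 0.3 the
silence at steps 3 and 5 is too weakly sensed to correct that prior: the
marginal belief in "voice present" reaches 0.62 at both silent steps
(written per-step to `scratch/trial_beliefs.csv`), a false positive
percept. The same command with `--zeta 0.7` yields the same actions but
beliefs of 0.32 at those steps — precise evidence corrects the prior and
no hallucination is flagged. At `--zeta 0.525` the belief sits at 0.45:
perceptual confusion without a frank hallucination.

The preset grids behind the three manipulations:

```bash
avhsim experiment fig4_zeta_sweep   # precision sweep, 3 trials + summary CSV
avhsim experiment fig5_gamma        # gamma x zeta grid
avhsim experiment fig6_lesion       # full vs lesioned policy space
avhsim validate                     # engine vs exact enumeration
```

`avhsim experiment fig6_lesion` shows the context dependence: the full
six-policy repertoire never hallucinates at any ζ (it covers the silences
with its own speech, though at every ζ it stops "hearing" its own voice —
false negatives at steps 4 and 5), while the space lesioned of the
originally inferred policy hallucinates at step 3 once ζ drops to 0.3,
with a dose–response over the sweep (0 → 0 → 1 flags).

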