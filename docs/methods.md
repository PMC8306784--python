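# Methods

`aifcollective` simulates two active-inference agents on a circular 1-D
world and scores the collective behaviour of an ensemble of such dyads with
a system-level free energy. This note records the model, its numerical
conventions, and the design choices made where the design was genuinely
open.

## The world

The environment is a ring of `N` cells (default 60). A single chemical
source sits at the field centre `psi0`; an agent at cell `psi` with
perceptiveness `k` receives a 1-bit chemical sample per epoch,

    P(s = 1 | psi) = k · exp(−omega · d(psi, psi0)),   P(s = 0) = 1 − P(s = 1),

with `d` the ring distance and `omega` the spatial decay rate. The agents'
generative model uses the same expression — sensing is noisy but the model
of the noise is correct. Each agent also observes, noiselessly and every
epoch, the offset `Delta = (psi_own − psi_partner) mod N` and the partner's
last realised action. Printed forms of this sensory model are ambiguous
about normalisation over `s`; we take `k` to be the *maximum* sensory
probability and give `s = 0` the complementary mass, which makes the
channel a proper Bernoulli, and we read the exponent's distance as ring
distance (the world has no boundary).

The field centre defaults to the shared target cell and moves with it when
target layout is randomised; it can be placed on any cell via
`WorldConfig.center`. Whether private targets should also emit signal is an
open modelling question; this package implements a single source only, and
all experiments place it on the shared target.

## Beliefs and desires

Beliefs live in log space: a vector `b` with entries in `B = [−10, 0]`,
decoded to a distribution by a max-stabilised softmax. The inverse codec is
`b_i = ln q_i − ln max(q)` floored at −10, so the largest entry is always
exactly 0 and no cell is ever believed impossible; the floor doubles as an
overconfidence guard. Each agent carries four such vectors: actual and
desired beliefs about its own position, and actual and desired beliefs
about its partner's.

Desires are built from equal-height log-space bumps (discretised Gaussians,
sigma = `peak_width` cells, default 2; width 0 degenerates to point masses)
at the target cells. Goal Alignment `gamma` blends shared and private
desires in log space,

    b* ← clamp(b*_shared + (1 − gamma) · b*_private),

applied identically to the agent's own desires and to the desires it
imputes to its partner: `gamma = 0` weights private and shared goals
equally, `gamma = 1` suppresses private goals entirely. Alignment is a
property of the pair, and shared goals are assigned exogenously.

## Generative densities and the joint free energy

For a candidate own action `a`, the sensory model predicts the next own
position as likelihood times shifted prior,

    p_own[psi'] = P(s | psi' − a) · q_own[psi' − a],

the Kronecker transition expressing that actions always have their intended
effect. The partner model composes three factors in the partner's
next-position coordinate `phi'` (expected partner action `a_p`, observed
offset `Delta`, observed previous partner action `a_pp`):

    p_partner[phi'] = q_own[phi' − a_p + Delta]
                      · P(a_pp | phi' − a_p − a_pp, b*_partner)
                      · q_partner[phi' − a_p].

The middle factor is the partner-action model: the partner is assumed to
act mechanistically on its desires, standing still with probability
`xi · q*[phi] / max(q*)` (exactly the ceiling `xi = 0.9` at a global desire
maximum) and splitting the remaining mass between the two moves in
proportion to the desirability of the destination cells. A printed
subscript suggests the *origin* cell instead; the destination reading is
the one consistent with the accompanying prose and illustration (actions
climb desire gradients), so that is what is implemented.

Both densities are clamped elementwise to `[e^−10, 1]` — a simple maximum
that prevents overconfident (out-of-range) beliefs.

The joint free energy couples the two inference problems through the
alterity gate. With `Delta'` the expected next-epoch offset
(`Delta + a_own − a_partner`):

    F = KL(q'_own ‖ clamp(p_own · G_alpha(p_partner shifted by +Delta')))
      + KL(q'_partner ‖ clamp(p_partner · G_alpha²(p_own shifted by −Delta'))) .

`G_alpha(p) = alpha·N·p + (1 − alpha)` is the re-ranging ("squishing") map
applied to the partner evidence, scaled so that `alpha = 0` multiplies by
exactly 1. The unscaled convention `alpha·p + (1 − alpha)/N` differs by a
constant `ln N` per divergence term, which affects no gradient and no
action comparison; the scaled form makes the `alpha = 0` reduction to the
single-agent model *exact*, bit for bit, which the test suite exploits.
The `alpha²` in the second term is second-order Theory of Mind: the agent
assumes its partner gates evidence about *it* with the same alterity.

## The epoch

Each epoch, in lockstep for both agents:

1. **Select actions.** All nine candidate pairs (own move, expected partner
   move) in `{−1, 0, +1}²` are scored by F with the variational side fixed
   at the *desire* distributions; the first strict minimum in the fixed
   order (own-major 0, +1, −1; partner minor the same) wins, so exact ties
   resolve deterministically.
2. **Update beliefs** by projected gradient descent on F with the chosen
   actions and the *current* observation — the update encodes the expected
   effects of the actions about to be taken. The two divergence terms
   decouple in the candidate beliefs and are descended separately, starting
   from the action-shifted current beliefs.
3. **Move.** `psi ← psi + a_own mod N`.
4. **Sense** at the new position (chemical bit, offset, partner action) —
   the observation the *next* epoch acts on.

Updating before moving is not cosmetic: it makes every index in the
generative densities line up exactly (the chemical bit is attributed to the
cell where it was sampled, and the partner-model offset factor evaluates
the own-position belief at precisely the believed own cell). Updating
*after* moving with the post-move observation would misattribute each
sample by one action.

Gradient descent runs `gd_steps = 30` iterations at step size
`gd_rate = 5.0`, projecting entries into `[−10, 0]` after every step, with
backtracking: a step that would increase F is halved (up to 40 times) and
logged, so F is non-increasing across accepted iterations; descent stops
early at gradient infinity-norm below 1e−12. The rate was calibrated so the
per-epoch descent approximately attains the variational optimum and the
strong agent's self-localisation takes a few tens of epochs, the intended
qualitative regime; behaviour is robust across rates 4–6, whereas rates
below ~1 under-assimilate so severely that no agent ever localises. After
descent, beliefs are re-canonicalised (max 0, floor −10), which changes F
only through the floor.

## The ensemble score

M replicate dyads (2M agents), each in its own world differing only in
food-source placement, are read as a single collective. With `q` the
empirical distribution of the 2M positions and `psi0_i` agent i's food
source,

    F_Sigma = sum_psi q ln q + (k_Sigma / 2M) · sum_i d(psi_i, psi0_i)² .

This is the divergence between the empirical density and a per-agent
generative factor `exp(−k_Sigma · d²)` whose constant log-normaliser is
dropped: the collective's generative density is not fully specified (its
domain and normaliser over the global state are left open), so only
relative and temporal comparisons of `F_Sigma` carry meaning — the
package never treats its absolute value as meaningful, and neither should
downstream analyses. `k_Sigma` defaults to 1. The trace of `F_Sigma` over
an entire run is read as a single system-level inference step; a
per-replicate decomposition (same formula per dyad) is emitted alongside
the joint trace for dispersion estimates.

## The experiment protocol

Four conditions share two agents — A strong (`k = 0.99`), B weak
(`k = 0.05`) — with a shared target at cell 30 and private targets at 15
(A) and 45 (B) on a 60-cell ring, 200 epochs:

| Model | alterity (A, B) | alignment |
|------:|:---------------:|:---------:|
| 1     | 0, 0            | 0         |
| 2     | 0, 0.2          | 0         |
| 3     | 0, 0            | 1         |
| 4     | 0, 0.2          | 1         |

A batch of `n_runs` dyads lays the common start cell of both agents on a
uniform grid *relative to the shared target* (every cell `n_runs/N` times
when `n_runs` is a multiple of N; every `N/n_runs`-th cell for scaled-down
batches), and randomises the absolute target layout per run while
preserving relative target distances, so behaviour is not an artefact of
absolute position. RNG substreams derive as (base seed, run, agent);
sensing is the only stochastic consumer, so runs replay bit-identically.

Metrics per agent: `time_to_target` (first epoch within 1 cell of an own
target; sentinel epochs+1 if never), `final_target_distance` (end-state
ring distance from the closest own target — the individual-performance
measure proper), `target_pursued` (nearest target to the final position;
ties resolve shared, then own-private), end-state belief summaries (mean
decoded distribution and pooled argmax histogram — both, since either
reading of "end-state belief distribution" is defensible), and the
`F_Sigma` trace across the whole batch. First-passage time is reported but
is a blunt instrument: an agent that never localises sweeps around the
ring and crosses a target band early by chance, so convergence claims are
better read from final distance or belief sharpness.

The default batch for the test suite is 30 runs per condition (the full
180-run protocol is available from the CLI); problem sizes were chosen so
a four-condition replication completes in a couple of minutes on one core.

## What the generator does and does not emulate

The synthetic conditions are the study conditions: parameter values,
world size, epoch count, start-grid and target-randomisation scheme as
above. They do not emulate: agent collisions or exclusion (co-occupancy is
allowed), noise on the partner channel, multiple or moving chemical
sources, desire learning, endogenous shared-goal discovery, or any
system-level *active* mechanism (the collective only performs the
inference half of its loop). Passing tests therefore speak to the internal
consistency and the qualitative 2×2 orderings of this idealised system,
not to robustness under sensor noise on the social channel or richer
environments.

## Known limitations

- With `k = 0.05` the weak agent's chemical channel carries very little
  information; its behaviour under Models 1 and 3 is dominated by long
  undirected sweeps, and batch statistics involving it are noisy at 30
  runs per condition. Effects of Theory of Mind on the weak agent's
  position metrics are visible but modest at this scale.
- The absolute scale of `F_Sigma` depends on the dropped normaliser and on
  `k_Sigma`; traces are comparable across conditions run with the same
  settings only.
- Tie-breaking in action selection is deterministic by candidate order;
  under exactly symmetric configurations this injects a fixed, arbitrary
  preference (0, then +1, then −1).
- The partner-observation channel is noiseless and always on; there is no
  occlusion or range limit.
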