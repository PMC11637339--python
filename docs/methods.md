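# Methods

## Model representation

A model is a species set (id, initial concentration, buffered flag,
compartment), a reaction set (integer reactant/product stoichiometries, a
modifier list, an arbitrary arithmetic rate law over species ids and
parameter names, a reversibility flag, local parameters) and global
parameters. Buffered species — boundary/constant species in SBML — have their
dynamics frozen; they act as inputs. Units are taken at face value and never
converted. Reversible reactions are stored as one reaction with a signed net
rate law (e.g. `kf*A - kb*B`); the decomposition treats them as bidirectional
unless explicitly marked forward-irreversible.

Rate-law dependencies are extracted symbolically (sympy parse +
differentiate), with a finite-difference probe at ten random positive states
as a fallback for unparseable expressions; the symbolic route is primary
because the autonomy conditions are stated through partial derivatives.
Tunable scalars are addressed by path: `reaction.param`, `species.concInit`,
or a bare global name.

Two file formats are supported and semantically interchangeable: SBML L2/L3
(kinetic laws required; events, algebraic rules and rule-based semantics out
of scope) via libsbml, and the `hoss-model-1` JSON dialect whose schema
mirrors SBML's species/reactions/modifiers/parameters structure.

## Decomposition

The interaction graph, blocks, quotient graph, longest-path levels and the
nested (I_l, J_l) chain follow the definitions in the README. Design points
that were genuinely open:

* **Buffered inputs at level 0.** Buffered species that appear in rate laws
  of reactions touching dynamic species are reported as singleton source
  blocks at level 0 (dynamic blocks shift up by one). This matches the
  convention of drawing stimulus enzymes as the root tier of a cascade, and
  it is how the reduced MAPK model ends with maximum level index 3. The
  nested I/J sets always range over non-buffered species only, so autonomy
  checks are unaffected. Disable with `include_buffered_inputs=False`, which
  restores I_0 = union of dynamic root blocks.
* **Agony.** The per-edge penalty is max(0, rank(u) − rank(v) + 1), the
  standard choice in the hierarchy-recovery literature; an edge costs nothing
  exactly when it climbs at least one level. Minimization is exact: branch
  and bound over rank vectors for quotient graphs up to 12 nodes (quotient
  graphs are small by construction — that is the point of applying agony to
  the r-quotient rather than to the full interaction graph), an LP with a
  totally unimodular constraint matrix above that. Among minimizers we first
  maximize the number of zero-penalty (strictly upward) edges — otherwise a
  cycle of blocks ties with the all-equal ranking and the hierarchy
  collapses — then prefer designated roots at level 0, then take the
  lexicographically smallest vector. Levels are normalized to be contiguous
  from 0.
* **r-causality.** Default r = 1 (small radii suffice for signalling models;
  configurable). Mutual r-causality is not transitive, so r-blocks are the
  maximal cliques of the mutual-reachability graph; overlapping blocks are
  consolidated by union-find. r = ∞ reproduces exact SCCs. Agony levelling
  of the r-quotient is skipped entirely whenever exact SCCs already give more
  than one block.
* **QSS shadow models.** QSS reduction and forward irreversibility transform
  a shadow copy used only to define the hierarchy; the returned decomposition
  records which transforms informed it, and species eliminated from the
  shadow (enzyme–substrate complexes) are lifted into the block of their
  highest-level non-buffered neighbour so the hierarchy can be applied back
  to the full model. On the full mass-action model those pairs are *not*
  autonomous — enzyme sequestration is exactly why the reduction exists —
  so autonomy is checked against the shadow.

## QSS reduction and irreversibility

Motifs S+E ⇌ ES → P+E are identified structurally (reversible bimolecular
binding, irreversible unimolecular catalysis regenerating the same enzyme);
complexes are recognized by pattern, never by name, and a motif whose complex
participates in any other reaction is left unreduced with a warning, because
the reduced rate formula assumes the pure mechanism. Substrates sharing an
enzyme share the saturation denominator. After reduction, a species that is
only ever a modifier becomes buffered ("exclusively an enzyme").

A reversible reaction is declared forward irreversible when, along a
simulated trajectory, R₋(t) ≤ 0.01·R₊(t) at all samples after the first 5%
of the simulated span. The 0.01 threshold and 5% transient window are this
package's defaults — two orders of magnitude is a conservative reading of
"backward flux negligible"; both are arguments. If R₊ is identically zero
over the window the verdict is flagged inconclusive. The default protocol is
the model's own initial state (settle-then-observe); any experiment protocol
can be passed instead.

## Simulation and scoring

Integration uses LSODA with rtol 1e-6 / atol 1e-9 (signalling models are
routinely stiff); stimulus events restart the integration at their event
times. Clamped species follow linear interpolation of their series, holding
the last value beyond it — the simplest defensible reading of "replace the
input with its data". Negative concentrations within integrator tolerance are
clipped to zero; beyond it the simulation errors out. Steady states are
detected by ‖dx/dt‖∞ < tol·max(1, ‖x‖∞) with an expanding time horizon capped
at 10⁶ s, or by a fixed settle time when the experiment specifies one; an
oscillator returns converged = False rather than hanging.

NRMS normalizes each residual by the readout's maximum observation within its
experiment (predictions never contribute to the maximum; an all-zero readout
is rejected rather than silently skipped), and all points of an experiment
share one N_d. Direct-parameter estimates contribute ((p − y)/y)² per
constraint. Pipeline-config weights override weights stored in experiment
files. The Gaussian negative log-likelihood with per-readout scale s_i and
noise σ_i is available as an alternative objective; the default remains
NRMS/WNRMS.

## Optimization methods

All methods work in log-parameter space by default (linear selectable), with
box bounds defaulting to nominal ×/÷ 1000 when unspecified. COBYLA is the
default algorithm (most reliable at producing small costs on conflicted,
ill-conditioned objectives); SLSQP, BFGS and Nelder–Mead are selectable, BFGS
with bound clipping inside the objective. Budgets are enforced as a hard cap
on objective evaluations (reported counts are actual calls); a wall-clock
timeout per elementary run is optional and off by default, because evaluation
budgets — unlike timeouts — keep reruns bit-reproducible. On budget or
timeout exhaustion the best-so-far point is returned, flagged.

Blocks derive their parameters from reactions first appearing at their level
and their experiments from readouts lying inside the block (direct-parameter
constraints follow the parameter). A block with no parameters or no
applicable experiments passes through with a note. Feedback inputs with
observed time courses can be clamped (dependent inputs); species without data
are reported and left free. An optional repeat-level pass is not implemented;
clamping covers the tested scenarios.

`initScram` seeds its population with the unscrambled nominal model (so the
multistart minimum can never lose to the corresponding single start) plus
log-uniform scrambles; successive rounds re-scramble around the incumbent
best. `hossMC` gives each of the N carried parents ⌈S/N⌉ variants per block,
optimizes blocks independently, rank-pairs results across blocks *within the
same parent* (block costs are additive in the squared weighted mean, so
best-with-best is optimal, and pairing across parents would merge
inconsistent frozen histories), pools the parent's merged candidates, and
carries the best N by level cost; the final ranking uses the full-model
WNRMS. Master seed → per-task seeds derive from a counter-based SeedSequence
scheme, so results are independent of worker count and scheduling.

## Synthetic fixtures

`generate_synthetic_cascade` emulates a kinase cascade: each unit is an
inactive/active pair with first-order (de)activation, activation of tier
t > 1 catalysed mass-action-style by an active species of tier t−1, rate
constants log-uniform in [0.5, 2]. An optional feedback term modulates tier-1
deactivation by the top tier's active species, closing a global loop. The
default experiments are 12-point time series of each active species on
t ∈ [0.25, 8] s from the cold start, which expose both the relaxation rate
and the steady-state level of every unit — making both constants of each unit
identifiable. Noise is multiplicative Gaussian, y = x(1 + sd·ε). What these
fixtures do *not* emulate: conservation-law degeneracies, strongly conflicting
replicate datasets, unidentifiable parameter combinations, and stiff
timescale separation; passing tests therefore demonstrate correctness of the
machinery, not fitting performance on hard real-world data.

`huang_ferrell_mapk` reconstructs the classic three-tier MAPK cascade from
its published mass-action mechanism (22 species: 8 kinase forms, 4 enzymes,
10 complexes; 10 Michaelis–Menten cycles; association 1000 /(µM·s),
dissociation and catalysis 150 /s, totals 3·10⁻³ µM KKK, 1.2 µM KK and K,
3·10⁻⁵…0.12 µM enzymes). It is a synthetic stand-in assembled in code, not a
parsed copy of any repository file; the structural claims tested on it
(22 → 8 dynamic equations, 4 exclusively-enzyme species, maximum hierarchy
level 3) depend only on the mechanism, not on the rate values.

## Problem sizes and numerical choices in the shipped checks

The recovery and method-comparison checks run on the 3-tier, 1-unit-per-tier
cascade (6 species, 6 reactions, 6 parameters, 3 × 12 data points): recovery
uses 800 COBYLA evaluations per block; the flat-vs-hierarchical comparison
uses 600 per block vs 1800 flat (equal totals) over 20 scrambled starts of
range 2; the multistart check uses 20 starts at 100 evaluations per block.
These sizes were chosen so each elementary minimization converges in seconds
while the comparisons remain clearly resolved. The QSS validity check uses
total enzyme = 10⁻³·km, where the reduced and full models agree within 1%
sup-norm. Exhaustive agony comparisons go up to 6-node graphs (6⁶ rank
vectors); SCC oracle comparisons use 200 random digraphs of up to 12 nodes.

## Known limitations

No forward sensitivities or gradient-based fitting of the simulated
objective; no profile-likelihood identifiability analysis; no stochastic or
spatial simulation; SBML events/algebraic rules unsupported; the feedback
decomposition beyond the four-step r-causality/agony procedure is
experimental; parallelism is local processes only.
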