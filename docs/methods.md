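# Methods

`hillswitch` implements two complementary descriptions of the dynamics of a
small gene regulatory network and the machinery to compare them
quantitatively.

## Models

**Shifted-Hill ODE ensemble.** Each node k of a signed network evolves as

    dx_k/dt = P_k * prod_{j->k} H(x_j, th_kj, n_kj, a_kj)/a_kj
                  * prod_{j-|k} H(x_j, th_kj, n_kj, i_kj) - g_k x_k,

with the shifted Hill function `H(x, T, n, lam) = lam + (1-lam) T^n/(T^n + x^n)`,
activation fold a > 1, repression fold i < 1, production P, decay g,
half-saturation threshold th and Hill coefficient n.  Activating factors
enter as H/a, so their range is (1/a, 1); repressing factors range over
(i, 1).  Because nothing pins the kinetic parameters of a real circuit,
dynamics is characterized over an *ensemble*: parameters are sampled
uniformly from broad ranges, each set is integrated from many initial
conditions, and the statistics of the resulting attractors describe the
network.

**Switching system.** Replacing every Hill factor by its infinitely steep
limit gives a piecewise-linear system `dx_i/dt = -g_i x_i + Lam_i(x)`,
where Lam_i is a product over input edges of two-level step functions
(value U above/below the edge threshold depending on sign, L otherwise).
Thresholds partition phase space into boxes; inside each box every
coordinate relaxes exponentially toward a constant target point.  Which
wall of a box the flow can cross depends only on inequalities between
production values `Lam_i` and decay-threshold products `g_i * th`, giving:

* a finite **state transition graph** (STG) on boxes,
* its condensation, the **Morse graph**, whose sinks are the predicted
  attractors — `FP(beta)` for a box containing its own target point,
  `cycle` for a nontrivial recurrent component,
* a finite decomposition of *parameter* space: all parameter sets with the
  same inequality signature share one STG.  For networks in which every
  node has one input and one output, each node contributes a three-way
  choice (`g*th` below L, between L and U, above U) and the parameter graph
  is the 3^n product grid — nine nodes for the two-node motifs, with the
  doubly-intermediate central node (index 4 in row-major order; the only
  index the package relies on) predicting bistability (toggle switch,
  double activation) or a cycle (negative feedback).

**Translation.** The two parameterizations are in exact correspondence up
to the Hill coefficient: the forward map splits each node's production
evenly over its m inputs, `U_kj = P_k^(1/m)`, `L_kj = U_kj/a_kj` or
`U_kj * i_kj`, carrying g and th over unchanged; the product of upper
levels recovers P_k exactly.  The reverse map inverts this where the
implied folds stay admissible and tags its output as a switching-limit
model (n = infinity).  Forward-then-reverse is the identity; the reverse
map is neither surjective nor compatible with the parameter-graph
decomposition and is provided only for completeness.

## Sampling conditions (the synthetic-data generator)

The generator emulates random circuit perturbation: every marginal is an
independent uniform draw.

| parameter | default | note |
|---|---|---|
| production P | U(1, 100) conc/time | median 50 |
| degradation g | U(0.1, 1) 1/time | time scales 1–10 |
| activation fold a | U(1, 100) | |
| repression fold i | 1 / U(1, 100) | reciprocal of a uniform magnitude |
| Hill coefficient n | U(1, 6), continuous | presets 1–10, 10–50, 50–100, 100–1000 |
| threshold th | U(0.02 M_src, 1.98 M_src) | half-functional rule, see below |
| initial conditions | log-uniform on [0.01 min(P/g), 10 max(P/g)] | spans all basins |

The repression fold is the *reciprocal* of a uniformly drawn magnitude, so
strong repression is common; drawing i itself uniformly would make weak
repression dominate and, downstream, would nearly empty the central
(bistable) parameter node.

The threshold scale M_src is the median expression of the edge's
*regulator*, estimated self-consistently by a seeded Monte-Carlo fixed
point (`sampling.regulated_median_levels`): a node's level is P/g times one
fold factor per input, applied when that regulator clears its own
threshold, and the medians are iterated until stable.  For the toggle
switch this gives M of roughly 10 (the mutually repressed nodes sit well
below the unregulated level of about 46, which is available as
`threshold_mode="unregulated"`), and the rule self-validates: each edge
ends up functional for close to half of all draws.  Under these conditions
over half of all sampled sets satisfy the central node's inequalities —
the sampling bias the ensemble statistics must be corrected for.

Every sampled set is screened for *regularity* after translation (no
production value within 1e-9 of any g*th; distinct thresholds per
variable); offenders — a measure-zero event — are resampled and logged.

What the generator does *not* emulate: correlated parameters, non-uniform
(e.g. log-uniform) priors, extrinsic/intrinsic noise, or integer-valued
Hill coefficients (available by flag).  Passing tests therefore certify
the machinery under idealized independent-uniform conditions, not
agreement with any particular experimental circuit.

## Numerical choices

* **Hill integration**: fixed-step Euler, step 0.05 time units, horizon
  200/g_min (at least twenty decay times of the slowest node), vectorized
  over all (parameter set, IC) pairs with early freezing of trajectories
  whose RMS derivative falls below 1e-5.  Euler is the reference scheme for
  this class of ensemble screens and is part of what is being measured (its
  error is visible in the switching-system comparison); an adaptive LSODA
  integrator is available by flag.
* **Steady-state verification**: RMS of the derivative vector below 1e-4.
* **State merging**: final states cluster at 1% relative tolerance
  (log-scale quantization plus greedy merge of representatives).
* **Cycle flag**: a parameter set whose trajectories scatter over at least
  10 distinct final states, none verifying, is classified cyclic — the
  fingerprint a limit cycle leaves on a steady-state detector.
* **Discretization**: verified states are pooled over the ensemble,
  log2-transformed, z-scored per node with basin weights, and binarized at
  zero (z = 0 maps to 1; measure-zero).  The log transform matches how
  multi-decade expression levels are compared in practice; on the raw scale
  a single global cut misclassifies a large fraction of high states.  The
  sorted distinct labels of a set form its canonical repertoire
  (`01-10`, `002-020-200`, `cyclic`).
* **Switching reference**: the same parameter sets' stable fixed points are
  computed exactly from the Morse graph (states = target points, equal
  weights) and pushed through the *identical* discretization, so Hill vs
  switching comparisons measure finite-steepness plus integration error and
  nothing else.  Comparing instead against raw domain-coordinate labels
  would be wrong: a fixed point can sit at high concentration yet below
  large thresholds (coordinates 00), which no concentration-based
  binarization can reproduce.
* **Event-driven switching integration**: exact per-domain crossing times
  in closed form; termination at FP (target inside the current box), at a
  cycle (repeated (domain, exit-wall) pair), or as `ambiguous` on a
  crossing-time tie within 1e-10 relative (measure-zero; no Filippov
  sliding convention is applied — the motifs studied cannot produce
  sliding at regular parameters because a wall's two neighboring boxes
  share the same target coordinate for the crossing variable).
* **Analytic separatrices** (bistable TS and DA): in the two transient
  boxes the basin boundary is where the two wall-crossing times of the
  exponential within-box solution coincide; the package evaluates the
  crossing times directly (algebraically identical to the log-difference
  separatrix equations, and tested against them), classifying any IC
  without integration.
* **Jensen-Shannon divergence**: base 2 (maximum 1); configurable.
* **PCA**: covariance-based on the raw parameter matrix by default —
  standardizing would erase exactly the scale information (production
  rates, thresholds) that carries the monostable/bistable distinction;
  a standardized mode exists.

## Design choices that were genuinely open

* Binarized Hill labels versus switching fixed points are compared through
  the same pooled z-score pipeline (see above); each ensemble uses its own
  pooled statistics.
* The node-count-normalized ensemble distribution is the unweighted mean of
  the per-node distributions over occupied parameter nodes: each region of
  parameter space counts equally, which is the prediction a combinatorial
  decomposition makes when nothing is known about sampling bias.
* Link strength `LS = P n/(g th i)` is defined for repressing edges; on
  activating edges 1/a replaces i (an extension chosen so that stronger
  regulation always increases strength).
* Unregulated nodes keep their production as a plain constant in both
  formalisms; the even-split exponent 1/m is undefined at m = 0.
* Monostable/bistable classes for PCA are assigned by the number of
  distinct *verified* steady states at the default Hill range.

## Problem sizes and limitations

Standard runs use 5000 parameter sets with 100 initial conditions each for
the two-node motifs and 2000 sets for the toggle triad (200 event-driven
ICs when screening for tristability); the analysis drivers default to
2000–3000 sets.  A full two-node ensemble simulates in well under a minute
on one core.

Known limitations: the central-node bistable-recovery fraction at Hill
coefficients just above 5 is about 85–88% here (the remainder is split
between sets that are genuinely monostable at finite steepness — confirmed
by root finding with Jacobian stability — and binarization flips of states
near the pooled z-cut); the worst-node discrepancy between Hill (10–50)
and switching repertoire distributions is 6–9%, concentrated in the
weak-repression node whose fixed points sit within a factor ~1.5 of a
threshold, where even n = 50 saturates poorly.  Analytic basin boundaries
exist only for the two-node bistable motifs; larger networks use numerical
basin estimation, whose step-size dependence the basin driver reports.
The full parameter-graph enumeration covers single-input/single-output
networks; multi-input nodes (toggle triad) are handled per sample via
inequality signatures and Morse graphs.
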