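# Methods

## Model class and inference objective

`rcnbp` implements inference-to-best-explanation in discrete factor
graphs.  A model is a set of discrete random variables `x_i` and factors
`f_a(x_a)` defining the unnormalized joint

    log p(x) = sum_a f_a(x_a) - log Z.

Inference runs loopy belief propagation with a temperature parameter `T`.
The variable-to-factor update is the sum of the variable's other incoming
messages; the factor-to-variable update is the tempered marginalization

    m_{a->i}(x_i) = T log sum_{x_a \ i} exp[(f_a(x_a) + sum_{j!=i} m_{j->a}(x_j)) / T].

`T = 1` is sum-product (beliefs approximate marginals); `T -> 0` is
max-product, which we implement as exact algebra on the (max, +)
semiring (token `MAX_PRODUCT`), never as a small-`T` numeric limit — this
avoids overflow and makes the identity reductions exact.  Fixed points of
these updates are stationary points of the temperature-scaled Bethe free
energy

    F = - sum_a E_{q_a}[f_a] - T [ sum_a H(q_a) + sum_i (1 - n_i) H(q_i) ],

where `q_a` are factor pseudomarginals, `q_i` variable beliefs and `n_i`
the number of factors touching variable `i`.  On trees the minimization
is exact and `F = -log Z` at the fixed point (verified to 1e-8 in the
tests); on loopy graphs BP carries no guarantee, and we document an
empirical bar instead (>= 90% exact-MAP agreement on random 14-variable
binary graphs with damping 0.5).

### Numerical conventions

- Binary messages are stored as the single scalar `m(1) - m(0)`;
  categorical messages are shifted so their maximum is 0.
- `-inf` log-potentials are represented by a sentinel of `-1e9` inside
  arithmetic (no NaN from `-inf - (-inf)`), with true-infinity semantics
  at comparison points.
- `g(x) = log(1 - e^-x)`, which appears in the OR updates, is evaluated
  through a stable `log(e^x - 1)` branch (`expm1` for small arguments,
  linear for large).
- Damped updates mix `damping * old + (1 - damping) * new`.  Free-running
  parallel (Jacobi) schedules default to damping 0.5; sequential and
  staged schedules to 0.  Convergence is declared at max-abs message
  change below 1e-6 (default), capped at 200 iterations.
- MAP decoding takes the per-variable argmax with ties resolved to the
  lowest state index.  An optional seeded perturbation adds Gaussian
  noise to the initial messages and an infinitesimal jitter at decode
  time; it exists to explore bistable solutions and is off by default.

## Specialized factors

Three factor families have closed-form O(M) / O(N) updates, each verified
against literal enumeration of the update at 1e-9 for all temperatures
(this equivalence is the package's primary correctness surface):

- **OR**: output `e` is the logical OR of M binary children; hard
  constraint (0 / -inf potential).  Explaining away between parents that
  share children emerges from these messages.
- **POOL**: a binary pooling variable licenses exactly one of M mutually
  exclusive members, each with probability 1/M; max-product only (a
  tempered pool should be expanded to a TABLE factor).
- **EDGE_APPEARANCE**: two categorical appearance patches and a binary
  contour variable; equal appearances required when the contour is OFF,
  different appearances at penalty `c > 0` when it is ON.

Evidence enters through a binary **CHANNEL** (2x2 conditional table):
`precision = P(pixel ON | source ON)`, `sensitivity = P(pixel ON |
source OFF)`.  Composing a hard OR over parents with a channel per leaf
realizes a noisy-OR leaf while keeping every piece enumerable.

## The RCN architecture

A model is a three-level contour hierarchy over an `R x C` grid (default
24 x 24) plus an optional surface lattice:

- **Leaves**: binary oriented contour units `(row, col, orientation)` with
  orientations {0, 45, 90, 135} degrees; each sees the stimulus through a
  channel (default precision 0.9, sensitivity 0.1).
- **Level 1**: one oriented-segment feature per template outline cell,
  pooling over perpendicular translations of the leaf (pooling radius 1,
  i.e. 3 members; radius 0 gives a rigid matcher).  Consecutive pools
  along a stroke are tied by lateral factors forbidding member pairs
  whose shifts differ by more than 1 (log-weight 0 for allowed pairs,
  sentinel for forbidden ones) — the minimal contour-continuity
  compatibility, realized as pairwise tables over parent-specific clone
  variables.
- **Level 2**: part features, one per contiguous quarter of the outline
  (4 parts; for a square these are its corner arcs), conjunctions of
  their level-1 segments through singleton pools.
- **Level 3**: one object feature per template with prior log-odds
  `-log(n_objects) - 1` (OFF-favoring; lower levels carry prior 0 since
  their state is explained by their parents).
- **OR interfaces**: every lower-level unit referenced by one or more
  pools is driven by a single OR block over its clones; this is where
  top-down context gates bottom-up evidence (explaining away).
- **Surface lattice**: a categorical appearance patch per cell (default
  N = 8 bins) and a binary contour variable per 4-neighbor lattice edge,
  with one edge-appearance factor per edge (penalty c = 1).  Edge
  variables are OR-driven by the oriented leaves crossing them; edges no
  template can reach are pinned OFF, so surfaces can only break along
  contours the hierarchy can explain.

Two deliberate simplifications: pool indicator variables coincide with
the parent feature (conjunctions are hard, so a separate indicator would
only add an inert equality factor), and shifted pool members carry a
weak canonical-transformation prior (`tie_epsilon = 1e-3` per unit of
shift) so that purely top-down generation resolves the member tie at the
anchor position instead of leaving the pool undecided.

A max-product subtlety worth knowing: a translation pool charges
`-log M` in the MAP score for the choice of member even under fully
uncertain evidence, because max-product scores the single best
configuration rather than marginalizing over members.  Top-level beliefs
therefore equal the priors under zero evidence only for rigid pooling;
with pooling they sit `sum_pools log M` below.

## The parsing protocol

Parsing is scheduled, not free-running: evidence injection and one
top-down prior sweep (so parent-side messages start at prior-OFF values,
making the first forward sweep a prior-free evidence broadcast), then a
fast forward pass with short-range lateral iterations (default 2), top-K
hypothesis selection (K = 3; hypotheses with positive belief receive a
top-down attention boost of +2 log-odds, configurable to a hard clamp),
then backward passes with longer-range laterals (default 8 iterations)
and OR-interface explaining-away updates, iterated with fresh forward
sweeps (default 3), and finally surface filling (default 12 iterations,
Gauss-Seidel in raster order, which fills monotonically where a Jacobi
sweep would oscillate transiently).  Stage snapshots carry anatomical
string labels (L4, L2/3, L5, thalamus/TRN, blob) as annotations only.

A contour unit that is ON in the MAP while its bottom-up evidence LLR is
<= 0 is labeled HALLUCINATED, otherwise SUPPORTED — the model correlate
of a subjective contour.  Segmentation masks attribute each ON leaf to
the single best-ranked object whose active pool chain reaches it.

## Synthetic stimuli — what they emulate and what they do not

Stimuli are idealized oriented-edge detector responses: per-cell,
per-orientation log-likelihood ratios written directly onto the leaf
channels (default magnitude e0 = 3, Gaussian channel noise sigma = 0.5),
plus a quantized per-cell appearance observation (or UNOBSERVED, which
contributes zero messages).  This skips the pixel-filtering front end a
real system would need; consequently the tests show that *inference*
behaves as claimed given detector-level evidence, not that the model is
robust to raster-level nuisance (lighting, texture, detector failures).
Scenes are placed at the model's canonical template positions; global
translation invariance is out of scope (pooling gives +/-1 jitter
tolerance only).

- **Kanizsa**: corner inducers cover 4 cells on each side of each corner
  (arm = 4 of an 11-cell side); gap cells carry weakly negative evidence
  (-0.5, a blank region is mild evidence of absence); the control
  rotates each inducer's orientations by 90 degrees in place.
- **Neon spreading**: a lattice of colored lines (spacing 4) whose
  segments inside the illusory disk use the inducer color; appearance is
  observed only on the lines; the disk outline has weak positive
  evidence (1.5) where lines cross it and 0 elsewhere.  The demonstration
  model uses rigid pooling so the mostly-blank boundary is not charged
  the pooling cost, which would otherwise swamp the sparse crossings.
- **Occlusion vs. deletion**: matched stimulus pairs sharing one noise
  field.  Deleted regions are background (-e0 on every channel: absence
  of evidence for expected parts).  Occluded regions carry the occluder
  bar's own positive evidence on its outline and *zero* (uncertain)
  evidence on all covered channels — a covered detector cannot see
  behind the occluder.  The occluder is an ordinary object in the model.
  Recognition is top-1 among object templates by final top-level belief,
  counted correct only if that object is ON in the MAP (the "no object"
  parse must lose).  Battery: 20 scenes per fraction, masking fractions
  {0, .125, .25, .375, .5} calibrated on the square target (achieved
  fractions per scene are recorded; diamond and cross targets yield
  smaller overlaps, reported as measured).

## The worked noisy-OR example

The three-feature network (a, b, c over pixels f, e, g) uses
complexity-scaled priors, `-0.65` log-odds per pixel a feature covers —
a coding-cost prior under which all features are a priori OFF and the
single-cause explanation {b} is the exact MAP, while the two-cause
alternative {a, c} explains the evidence almost as well (it trails by
exactly one `beta`).  Inference is 6 damped parallel sweeps, matching
the fixed-pass character of the staged protocol.

The alternative {a, c} is *not* a stable fixed point of free-running
max-product here: the two shared pixels route roughly `4 beta` of
reignition support to b against its `3 beta` prior, a loopy
double-counting effect, so unbounded iteration always returns to {b}.
Under the sweep-limited protocol with seeded Gaussian perturbation of
the initial messages (scale 2.0), roughly a third of seeds settle the
sweep budget in the alternative basin and decode {a ON, b OFF, c ON};
clamping (top-down attention) can hold either solution indefinitely.
The experiment reports the per-sweep belief dynamics, the perturbed-seed
rate, and the attention effects (clamping b ON zeroes the first-pass
evidence flow to a and c; clamping b OFF raises their beliefs above
their priors).

## Problem sizes and runtime choices

All demonstrations run on 24 x 24 grids with templates of 24-48 outline
cells; the verification batteries use 100 random trees (<= 12 variables,
cardinalities 2-4, enumeration capped at 2^18 joint states), 100 random
loopy binary graphs (<= 14 variables), and 200 random draws per factor
family.  These sizes make every claim checkable against exact
enumeration; nothing in the method is specific to them, but the
enumeration oracle (and hence the strongest form of verification) does
not scale past ~20 binary variables.

## Known limitations

- No learning: features, pools and laterals are hand-built from
  templates (the generative structure, not the learning algorithm, is
  the subject here).
- Max-product only for POOL factors; tempered pooling requires TABLE
  expansion.
- No global translation/scale/rotation invariance; no binocular or
  temporal extensions.
- The hallucination-delay measurement is in units of protocol stages,
  a qualitative analogue of response latency, not a timing model.
- Free-running loopy max-product on the compiled scene graphs can have
  basins that differ from the staged protocol's answer; the protocol's
  fixed pass counts are part of the model's specification of inference,
  not a convergence guarantee.
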