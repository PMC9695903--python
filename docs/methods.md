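# Methods

## The model

`tapraf` implements a discrete-time stochastic model of combinatorial
chemical innovation.  The state at time `t` is a set of molecular
species of size `M_t`, initialized with `M0` food species labeled
`1..M0` that are assumed freely available.  In each time step, for each
reactant arity `i = 1..K`, the number of new species created by
arity-`i` reactions is drawn as

    r_i ~ Poisson(s_i),   s_i = α^i · C(M_prev, i),

where `M_prev` is the species count at the start of the step and `α^i`
is the per-combination reaction propensity (a geometrically decreasing
sequence; the propensity sequence is exposed as a parameter but only the
geometric form is studied).  Each creation event records one reaction:
`i` *distinct* reactants drawn uniformly from the species present at the
start of the step, producing a single new species that continues the
integer labeling.  The binomial coefficient in `s_i` is the number of
unordered distinct `i`-combinations, which is why reactant draws are
distinct and unordered; the same combination may, however, be drawn
again by a later event and then produces a different new species — the
Poisson formulation samples event counts, not distinct combinations.

Catalysis is random and structural (no rates or dynamics): when species
`x` is created, each existing non-food species `y` is trialed twice
independently with probability `p` — once for `x` catalyzing the
reaction that produced `y`, once for `y` catalyzing the reaction that
produced `x`.  `x` trials itself exactly once (as catalyst of its own
reaction), so over a whole run every (non-food species, reaction) pair
direction is trialed exactly once; the run counts its trials and the
test suite recounts them from the creation order.  Food species never
catalyze.  The catalysis loop runs over the *current* species count, so
species created earlier in the same time step participate as trial
partners even though they cannot yet be reactants.

**Stopping rule.**  The run terminates the moment the `M`-th species is
created: that species' catalysis trials are performed, then every loop
exits, leaving the time step unfinished and any in-flight Poisson event
counts abandoned.  An alternative protocol finishes the step (and
generally overshoots `M`); the exact-stop rule is implemented because it
makes the final `(M, R)` deterministic, `R = M − M0`, which is what the
closed-form comparison assumes.  Whether in-flight draws of *other*
arities should be completed is ambiguous in principle; the literal
loop-exit reading is used, which can slightly shift the arity
composition of the last few reactions of a run but nothing else.

Defaults are `M0 = 10`, `α = 0.01`, `K = 4`; `M`, `p` and the seed vary
by experiment.  At the default start the expected first-step increment
is `Σ s_i = 0.1·1 + 0.0045·... = 0.1046221`, used as a calibration
check.  Since `M_t` is nondecreasing and the one-step growth probability
is bounded away from zero, every valid run reaches `M`; a `max_steps`
budget turns mis-configurations (e.g. `α = 0`) into loud failures.

## RAF detection

A reaction subset `R'` is reflexively autocatalytic and food-generated
(RAF) when every reaction in `R'` has at least one catalyst inside the
food-set closure of `R'`, and every reactant of every reaction of `R'`
lies in that closure.  The closure is the smallest food-containing
species set closed under "all distinct reactants present ⇒ product
present", computed by support-counting propagation in time linear in
total reactant arity.  Duplicate reactants (e.g. `1+1 → a`) require only
the distinct species to be present.

The maximal RAF is computed by the classic alternating reduction:
compute the closure of the surviving reactions, delete every reaction
with a missing reactant or no catalyst in the closure, repeat to a fixed
point.  Each pass is linear and at least one reaction is deleted per
iteration, so the worst case is quadratic; in practice a handful of
passes suffice even at 2500 reactions.  Correctness is checked two ways:
a brute-force oracle that enumerates all `2^n − 1` subsets and tests the
two conditions directly (capped at 15 reactions; the suite runs hundreds
of random systems through both paths), and structural property tests
(idempotence under restriction, monotonicity under catalyst addition).

Minimal RAFs are obtained by seeded random reduction: repeatedly drop a
random reaction and keep the drop whenever the remainder still contains
a non-empty maxRAF; the fixed point is an RAF from which no single
reaction can be removed.  Which minimal RAF is found depends on the
seed; the result is verified irreducible by the tests.

Degenerate inputs: a system with no reactions has an empty maxRAF, and
"every reaction catalyzed" is vacuously true for it — consistent with
the `m = M0` convention `P_all = 1` below.  A catalyst of a maxRAF
reaction that is *not* producible inside the maxRAF is excluded from the
reported molecule support: the support is the self-sustaining molecule
set, and an unproducible catalyst is not part of it even when the
reaction also has a producible catalyst.

## Closed-form theory

Because each reaction yields exactly one new product, a TAP network with
`m` species has exactly `R = m − M0` reactions, and it is automatically
food-generated (each species' own creation history reaches back to the
food set).  The whole network is therefore an RAF iff every reaction has
at least one catalyst.  With independent per-pair catalysis,

    P_all(m) = (1 − (1 − p)^R)^R,   R = m − M0,

with `P_all = 1` at `m = M0` by the `0^0 = 1` convention.  The
implementation works in the log domain — `R·log1p(−p)` for the miss
probability, then the `log(1 − e^x)` branch split (expm1 near 0, log1p
otherwise) — so both tails keep full double precision; values that
genuinely underflow double range return 0.0 rather than raising.  Note
`P_all` is *not* monotone in `m` at fixed `p`: it dips while `R` is
small before climbing to 1.

Two asymptotic statements are exposed and verified numerically: along
the critical scaling `p = ln(x·m)/m` the probability converges to
`exp(−1/x)`; and the level of catalysis `f = p·R` required for
`P_all = θ` is `ln(m) + ln(1/ln(1/θ)) + o(1)` — the asymptotic formula
drops a `p·M0` correction.  A separate exact inversion of `P_all` in `p`
(Brent's method to relative tolerance 1e-12, unique root because
`P_all` is strictly increasing in `p`) exists so tests compare the
asymptotic law against finite-`m` truth instead of conflating the two:
at `m = 10^6` the asymptotic and exact `f` agree to better than 0.05.

Throughout the package the level of catalysis is `f = p·(M − M0)`,
the definition used by the asymptotic law; at the sizes studied it differs from the
looser `p·M` by at most `p·M0 ≈ 0.05`, well inside every statistical
band used.

## Monte-Carlo experiments

Sweeps run the simulator over an `(M, p)` grid, `n` replicates per
point, and estimate either the all-network RAF probability (every
reaction catalyzed — the event the closed form describes) or the
any-RAF probability (non-empty maxRAF).  Frequencies carry binomial
standard errors `sqrt(q(1−q)/n)`; no smoothing or curve fitting is
applied anywhere.  Replicates are seeded by hierarchical seed-sequence
spawning from one master seed, so grid points are independent,
individually re-runnable, and sweeps are bit-reproducible.

The transition point of a fixed-`M` sweep is the `f` at which the
empirical curve crosses 0.5: an exact grid hit returns that grid
point's `f`; otherwise the first upward crossing is linearly
interpolated between the bracketing points, with the two binomial
standard errors propagated through the interpolation.  First-crossing
linear interpolation was chosen over averaging multiple crossings or
fitting: noisy curves are handled by raising replicates, not by
smoothing.

The figure-style suites regenerate three standard comparisons: the
probability of RAFs against `M` at `p = 0.005` (all-network empirical
vs. closed form, plus the any-RAF curve, which rises at smaller `M`
since the any-RAF event contains the all-network event and so is at
least as probable); `P_all` against `f` for several `M` (curves
shift slowly right as `M` grows); and the interpolated transition `f`
against `M`, tracking `ln(M) + 0.367`.  Replicate profiles: `full`
(500 replicates, the statistical weight used for the headline checks),
`fast` (tables in about a minute) and `smoke` (plumbing only).  The
acceptance checks use 500 replicates for direct frequency comparisons,
50×9 grid points for the any-RAF transition at `M = 1250`, and 250×7
points per `M` for the logarithmic-law check — sizes chosen so that
3-standard-error bands are a few percentage points wide while a full
regeneration stays in the minutes range.

## What the simulations do and do not show

The generator *is* the model under study — there is no external data —
so passing tests show internal consistency: the simulator realizes the
stated stochastic process (exact trial counts, exact stop, growth law
`R = M − M0`), the RAF algorithms are exact on everything the oracle
can enumerate, and simulation frequencies agree with the closed form
within Monte-Carlo error.  They do not show anything about real
chemistry: any species may react with any other, catalysis is assigned
uniformly at random and independently, reactions have exactly one
product and are irreversible, and there are no concentrations, rates or
thermodynamics.  Relaxing the single-product restriction would lower
the required level of catalysis (more routes to each species); adding
multiple producing reactions per species is the main redundancy absent
from this model.

## Statistical acceptance bands

All simulation-vs-theory checks use 3 binomial standard errors (with
the standard error taken at the theoretical value when the empirical
frequency is degenerate 0 or 1).  Transition-location checks add half
the `f`-grid spacing to the 3-SE band, since linear interpolation
cannot resolve the crossing finer than the grid.  Any-RAF quantities
have no closed form; the any-RAF transition at `M = 1250` is checked
against the five-to-seven reactions-catalyzed-per-molecule range in
which simulations locate it (the observed crossing sits near `f ≈ 5.3`).
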