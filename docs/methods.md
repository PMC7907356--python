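# Model and methods

`evofoodweb` simulates the evolution of trophic metacommunities: local food
webs on a periodic square lattice of habitats, coupled by dispersal and
driven by speciation, with population biomasses set by a donor-controlled
equilibrium rather than explicit population dynamics.  This note documents
the model equations as implemented, the numerical choices behind them, the
analysis conventions, and what the package's tests do and do not
demonstrate.

## Species, feeding kernels, competition

A species is a triple of heritable traits on a natural-log body-mass axis:
log body mass `m`, feeding center `f`, and feeding width `s`.  A consumer
`i` attacks a prey of log mass `m_j` with strength

    a_ij = exp(-(f_i - m_j)^2 / (2 s_i))        if |f_i - m_j| <= c * s_i
    a_ij = 0                                     otherwise.

The hard cutoff `c` (default **1.0**) truncates the Gaussian tails.  With
the default trait-generation rules (`f` drawn 1–3 units below `m`, widths
in [0.5, 1]), `c = 1` implies `f_i + s_i <= m_i`: every realized prey is
strictly lighter than its consumer, so evolved webs are ordered by body
mass and contain no feeding loops.  We found this essential for the model
to develop the layered trophic structure (a distinct basal stratum, a
thinner herbivore stratum, few top species) that all stratified analyses
in the package presuppose; with a looser cutoff (`c = 2`, available in the
configuration) species bands feed within themselves and the basal stratum
disappears.

Consumers sharing a prey compete.  With `a*` the largest strength among
the prey's consumer set, each consumer's handicap is
`F = exp(-((a* - a)/delta)^2)`, and feeding shares `gamma_ij` are the
`F`'s normalized over the prey's consumer set; `delta` (default 0.25)
tunes how strongly the best-adapted consumer dominates.  Every prey's
share column sums to exactly 1.

## Biomass equilibrium: donor-controlled transport

Population biomasses in one habitat satisfy

    B(i) = gamma_i0 * R  +  lambda * sum_j [ gamma_ij B(j) - gamma_ji B(i) ],

with `R` the external resource amount per habitat (default 25) entering
through the resource shares `gamma_i0`, and `lambda` (default 0.65) the
transfer efficiency.  The first term in the sum is species `i`'s intake
from its prey, the second the intake of `i`'s own consumers from `i`.
Both flows are proportional to the *prey's* biomass only — consumer
abundance never feeds back on a resource, which is the donor-control
assumption (no top-down effects).

Because share columns sum to one, predation gains and losses cancel in
the community total, giving an exact conservation law:

    sum_i B(i) = R     whenever the resource has at least one consumer.

Together with the extinction threshold (biomass density 1), this caps the
number of coexisting populations per habitat at `R / threshold = 25` and
is the reason simulated local richness equilibrates around 22.  A preyed
species keeps a fraction `1/(1 + lambda)` of its inflow, so each trophic
transfer passes `lambda/(1 + lambda) ≈ 0.39` of the standing biomass
upward; a large `lambda` is therefore required for more than two trophic
layers to clear the threshold.  Top species keep their full inflow, which
is why the least numerous, highest strata carry the largest per-capita
biomasses.

In matrix form the relation reads `(I + lambda*diag(p) - lambda*G) B = c`
with `G` the species-by-species share matrix, `p` its column sums (1 for
preyed species, 0 for top species) and `c = gamma_col0 * R`.  The matrix
is strictly column diagonally dominant with non-positive off-diagonal
entries — a nonsingular M-matrix — so the equilibrium exists, is unique,
and is componentwise nonnegative; it is computed by a dense linear solve.
An independent damped Picard iteration (`fixed_point_oracle`, damping
0.5, started from zero) verifies the solver in the tests; damping is
needed because the undamped update matrix has spectrum in `(-2*lambda, 0]`.

## Extinction cascades

A population persists only if its equilibrium biomass density is at least
the threshold (survival uses `>=`; an exactly-threshold symmetric layer
survives).  After any insertion the affected habitat is re-equilibrated
and sub-threshold populations are removed **one at a time** — smallest
biomass first, ties to the smaller species id — re-solving after every
removal, because removals renormalize the survivors' shares and can
rescue them.  Removing a whole batch at once would annihilate symmetric
competitor sets (26 equal basal species all sit at 25/26 < 1; sequential
removal instead relaxes the layer to 25 species at exactly 1.0) and
produces the large extinction avalanches the model notably lacks.
Removals in round two or later of a cascade are recorded as secondary
extinctions.

## Events, time, and space

Habitats form a `width x height` torus (4-neighborhoods, wrapped Manhattan
distances).  Each event is a dispersal with probability `d/(1+d)` and a
speciation otherwise, so `d` (default 10) dispersal events occur per
speciation event on average.  The clock advances by `1/H` per speciation
event only, making one time unit equal one speciation event per habitat —
the model's reference time scale.

*Speciation*: a uniformly random habitat, a uniformly random resident
parent; the child's log mass is uniform within `±ln q` of the parent's
(`q = 5`), its feeding center uniform in `[m - 3, m - 1]` (independent of
the parent's), its width uniform in `[0.5, 1]`.  Child body mass is
unconstrained in sign.  *Dispersal*: a source population is drawn with
probability proportional to its local biomass density over all
populations (uniform selection is available behind a switch), and the
species is copied to one of the 4 neighboring habitats chosen uniformly;
copies into habitats that already hold the species change nothing but
still consume the event.  Failed immigrants and failed newborns (below
threshold at their first solve) are flagged `never_established` and are
excluded from lifetime and range statistics; extinction records are
written only for removals of populations that were established before the
triggering event.

The simulation starts from the same founder species on every habitat
(`m = 2, f = 0, s = 0.75`, feeding maximally on the resource at log-mass
0, equilibrium biomass `R`) and runs for `steps * H` speciation events.
All randomness flows from a single seeded NumPy generator; reruns with
the same configuration are byte-identical.

Each extinction record carries the trigger (local speciation vs
immigration) and the trophic relation of the victim to the triggering
species, compared on rounded trophic levels (victim levels from the
pre-event web, the newcomer's from the post-insertion web; rounding is
half-up).  A failed newcomer that removes only itself is labelled
`same_level`, as a no-prey newcomer has no defined level.

## Performance path

The public `trophic_network` and `biomass_equilibrium` modules are plain
NumPy and define the reference semantics.  The event loop calls
numba-compiled kernels (`_kernel.py`) for strength matrices, equilibria,
cascades and trophic levels; the test suite asserts agreement between the
two paths on randomized communities to 1e-9.  Trophic levels in the
kernel use Jacobi iteration of `TL = 1 + mean(prey TL)` (resource at 0,
self-links ignored), which converges because every established species
has an energy path to the resource; the analysis module solves the same
system directly as a linear system.

## Evaluated quantities and analysis conventions

- **Trophic level**: 1 + mean level of the prey set; basal stratum =
  rounded level 1, "higher" = above.  Species-level strata for range and
  lifetime analyses use the level at origination (on the post-insertion
  web of the natal habitat); per-habitat, per-snapshot levels are used
  for similarity strata.
- **Lifetime**: extinction minus origination time; species alive at the
  end of a run are excluded.  Species established and globally extinct at
  the same clock value (possible because dispersal does not advance the
  clock) have zero lifetime and drop out of logarithmic analyses.
- **Lifetime distribution**: log-binned density (8 bins per decade),
  least-squares slope on log-log axes.  The default fitting window is the
  two decades ending at the longest observed lifetime: the short-lifetime
  side is a distinct regime dominated by species that die before ever
  dispersing, and the power law lives in the tail.
- **Range**: occupied habitat count; the time-averaged range is the time
  integral of the occupancy step function over the lifetime (accumulated
  event-by-event, verified in tests against direct trajectory
  integration).
- **Range vs lifetime**: lifetimes binned with width 0.055 in log10;
  slope fitted over bins whose mean range lies in `[2, H/4]` — below 2
  the curve sits on the single-habitat floor, above `H/4` it already
  bends into the system-size plateau (on a torus, a patch of `H/4`
  habitats spans half the lattice diameter).
- **SAR**: nested shells (habitats within toroidal distance `k` of a
  start), averaged over 10 random starts and all snapshots; slope fitted
  over areas in `[5, H/4]`.
- **Similarity**: Jaccard index per habitat pair, averaged within each
  toroidal distance, per stratum, then averaged over snapshots (standard
  deviation across snapshots).  The large-distance plateau is the mean
  over the three largest distances.  The basal plateau equilibrates
  slowly (roughly the first 2000–4000 steps on a 10x10 grid), so plateau
  measurements use the mature second half of the snapshot series and are
  averaged over independent runs: on 100-habitat grids the statistic is
  bimodal, alternating between long high-similarity phases (one basal
  clade dominant everywhere, plateau 0.75–0.85) and occasional global
  basal-turnover episodes during which it temporarily drops to ~0.3.
- **Range-trajectory shape**: trajectories of extinct species whose
  maximum range reached half the grid are resampled to 200 uniform time
  points, smoothed with a moving average of 5% of the lifetime, and local
  maxima with prominence of at least 10% of the maximum range are
  counted; exactly one such maximum (including full-grid plateaus) is a
  "hat", more are "multi-peak".  Both thresholds are configurable; the
  defaults emulate a by-eye grouping that tolerates small wiggles on the
  back of a hat.
- **Ranks**: descending biomass within a habitat, rank 1 most abundant,
  ties to the smaller id; a species' average rank is its mean over
  occupied habitats.

## Scaled-down study conditions

The reference parameter set is fixed throughout (Section above); grids of
6x6 to 10x10 habitats and runs of 3000–5000 speciation events per habitat
are used by the tests and by `scripts/acceptance.py`, chosen so the
community is in its statistically steady state for at least the second
half of each run while a full analysis suite completes on a single CPU.
At these sizes the macroecological quantities are close to, but not
identical with, their large-system values: distributions truncate at the
grid size, the range-growth regime spans barely over a decade, and
trajectory-shape fractions carry sampling noise of several percentage
points.  The trajectory-shape analysis uses the largest (10x10) grid
because the prominence criterion degrades when 10% of a species' range is
only a handful of habitats.

## Known limitations

- One-dimensional niche axis; no multi-trait niches, no adaptive
  foraging, no functional responses, and no abiotic heterogeneity —
  turnover is driven entirely by the trophic network.
- No extrinsic extinction rate; all extinctions are deterministic
  consequences of the equilibrium relation and threshold.
- The donor-controlled equilibrium is an algebraic surrogate for
  population dynamics: transient dynamics, oscillations and
  predator-mediated coexistence are outside the model's scope.
- Dispersal is unconditional copying to a neighbor; dispersal ability
  neither varies among species nor evolves.
- On desk-scale grids the basal similarity plateau and the hat-shaped
  trajectory fractions are noticeably sensitive to run length and grid
  size.  Both trace back to the same finite-size mechanism: with a
  dispersal rate of 10 on ~100 habitats the lattice mixes quickly, so
  competitive replacement of a dominant, widespread basal clade happens
  nearly synchronously across the whole grid.  This produces global
  similarity crashes and crash-and-recover range trajectories
  (classified multi-peaked) that a larger lattice buffers spatially.
  Conclusions about real systems should rest on the large-grid trends,
  not the absolute desk-scale numbers.
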