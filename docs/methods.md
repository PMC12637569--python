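# Methods

## Model

A cluster is a set of RyR2 channels occupying sites `(nx, ny)` of a square
lattice (one channel per ~30 nm footprint).  Each channel is four identical
two-state subunits, `s = -1` (closed) or `s = +1` (open), on a periodic
ring; a channel conducts when at least `open_subunit_min = 3` subunits are
open.  Subunit `i` flips with rates

    k(-1 -> +1) = kfo * [Ca] * gamma_i,      k(+1 -> -1) = kb / gamma_i,
    gamma_i = exp( delta*(s_{i-1} + s_{i+1}) + sigma * sum_b w_b s_b ),

the first sum over the two ring neighbors, the second over the subunit's
inter-channel contacts.  `delta` and `sigma` are both dimensionless
interaction energies in units of kT.  We deliberately treat `sigma` as its
own energy scale rather than a multiplier of `delta`: with
`delta = sigma = 0.5` this choice reproduces the characteristic
sensitivities of coupled-cluster behavior (orders-of-magnitude waiting-time
growth with bond survival and with `sigma` at low Ca) that a
`delta*sigma` exponent, four times weaker per contact at these values,
does not.

The dyadic cleft is treated as well mixed (rapid-diffusion approximation:
Ca diffuses across a sub-400 nm cluster far faster than gating), so every
subunit sees

    [Ca] = c0 + g * n_open,

with `n_open` the conducting-channel count *including* the transitioning
subunit's own channel — Ca is uniform in the dyad, so no self-exclusion is
meaningful.  At `g = 0` the chain satisfies detailed balance with respect to

    E(s) = -delta*sum_ring s s' - sigma*sum_inter w s s' - h*sum_i s_i,
    h = (1/2) ln(kfo*c0/kb),

which is verified algebraically and via the Kolmogorov cycle criterion in
the tests; `g > 0` breaks reversibility (the feedback is a nonequilibrium
drive) but not the master-equation machinery.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `kfo` | 0.005 | (uM ms)^-1 | Ca-binding rate constant; opening rate is first order in Ca (one activation site per subunit) |
| `kb` | 0.3 | ms^-1 | subunit closing rate (~3 ms open dwell) |
| `delta` | 0.5 | kT | intra-tetramer mismatch penalty |
| `sigma` | 0.5 | kT | inter-channel contact energy (per contact; both contacts of the adjoining geometry) |
| `g` | 25 | uM | dyadic Ca rise per conducting channel, so 1-3 open channels span the 25-75 uM CICR range |
| `c0` | 0.1 | uM | bulk/diastolic Ca; study conditions pass 2-120 uM explicitly |
| `open_subunit_min` | 3 | – | majority rule for a conducting pore |
| `nc` | 5 | channels | spark threshold on `n_open`, above baseline fluctuations |

The waiting time `T` runs from the all-closed configuration to the first
moment `n_open >= nc`.  Crossing `nc = 5` is followed by explosive
activation of essentially the whole cluster, so `T` is insensitive to the
exact threshold: in paired-seed runs the `nc = 10` crossing lags `nc = 5`
by well under 1% of `T` on average.  The agreement is statistical, not
pathwise — rarely an excitation recedes after five channels open — so the
corresponding test compares paired means at 3 SE.

## Geometry

Subunits sit at the corners of the channel footprint (0 = NW, 1 = NE,
2 = SE, 3 = SW).  *Adjoining* interfaces pair the two facing corner
subunits of laterally adjacent channels (east: 1-0 and 2-3; south: 3-0 and
2-1), giving interior subunits one horizontal and one vertical contact.
*Oblique* interfaces carry a single diagonal contact assigned so every
subunit serves at most one direction (east: 1-3, south: 2-0), realizing
the staggered 0-2/1-3 checkerboard pattern with inter-degree <= 1.  The
published contact maps do not pin the exact corner indices; any consistent
convention with these per-subunit contact counts yields identical dynamics
because rates depend only on signed neighbor sums.

Fragmentation keeps each inter-channel bond independently with probability
`p`; intra-tetramer rings are covalent structure and never broken.
Heterogeneous morphologies grow by sequential placement with site weight
`1 + ne^alpha` over the occupied von Neumann neighbor count `ne`, with
`0^0 := 1` so `alpha = 0` is exactly uniform (the alternative `1 + ne*alpha`
reading is available as `mode="product"`).  The first site is uniform; ties
need no special handling because selection is a weighted draw.

## Simulation

The engine is the Gillespie direct method over all subunit flips.  The
next-event time is exponential in the total rate `R`; the event is chosen
proportionally to per-subunit rates.  Bookkeeping is incremental: a flip
updates only the coupling factors of its <= 4 neighbors, and because the
total opening propensity factorizes as `kfo*[Ca] * sum_closed gamma_i`, a
change of `n_open` (hence of Ca) is an O(1) prefactor update rather than an
O(N) rate rebuild.  Running sums are refreshed from scratch every 2^16
events to bound floating-point drift, and round-off overshoot in the
selection scan falls back to the last subunit with positive rate.  The
inner loop is a numba kernel consuming flat neighbor/coefficient arrays;
a pure-Python stepper with per-call rate recomputation backs the
fine-grained statistical unit tests.

Runs are censored at `t_max` (default 1e8 ms) and by an event cap (default
1e9), reported distinctly; censored runs are never dropped, and ensemble
means containing them are flagged as lower bounds.  Spark termination
(inactivation, SR depletion, Ca clearance) is outside the model — runs end
at threshold crossing.

Each run owns one PCG64 generator.  Ensemble seeds derive from a master
seed via `SeedSequence` spawning, with *independent recorded streams* for
gating and for graph generation, so a morphology ensemble can be
regenerated without replaying trajectories and vice versa; every result
object and CSV row carries its seeds.

## Ensembles and errors

`mean_waiting_time` averages `n_runs` first-passage times (study protocol:
50) and estimates the standard error by the set-splitting protocol: the
runs are divided into `n_sets = 5` consecutive sets and
`se_T = std(set means, ddof=1)/sqrt(n_sets)`, the usual batch-means
standard error of the grand mean.  Sweeps cover `c0`, `sigma`, `p`
(fresh bond network per run) and `alpha` (fresh morphology per run).
`spark_frequency = 1/mean_T` converts to the spontaneous spark rate.

## Exact oracle

For clusters of up to 4 channels (65,536 subunit configurations) the full
generator is assembled exactly, with off-diagonals the single-flip rates at
the source state's Ca.  The stationary law (solved densely for <= 3
channels; for `g = 0` the Boltzmann closed form covers any size) and the
mean first-passage time (transient-block linear solve; dense up to 4096
states, Jacobi-preconditioned BiCGSTAB with a residual guard beyond —
direct LU fills in catastrophically on the hypercube state graph) provide
ground truth.  The Gillespie engine is required to match `mfpt_exact`
within 3 SE on 1- and 4-channel systems; all larger-cluster results rest on
that validation plus the algebraic propensity identities.

## Scaled-down study conditions

Headline quantities are recomputed in `scripts/acceptance.py` at desk
scale: 50 runs where a quantity is cheap (high-Ca waiting time, the
sigma = 0 baseline), 10 runs for slow conditions (p = 0.5 bonds,
sigma = 0.5 adjoining at c0 = 5 uM, fresh alpha = 0 morphologies), chosen
so the script completes in about a minute on one CPU while keeping
standard errors well inside the order-of-magnitude comparisons being made.

## What the generators do and do not emulate

The synthetic clusters are idealized: pure adjoining or pure oblique
contact rules on a square lattice, independent bond survival, and
preferential-attachment growth as a stand-in for observed morphology
statistics.  Native clusters mix both contact types, fray anisotropically
around scaffold proteins, and live in 3-D membrane geometry; none of that
is represented, so passing tests demonstrate the mechanism (exponential
sensitivity of spark timing to connectivity) rather than quantitative leak
rates of real dyads.  Also outside scope: Mg2+/CaMKII/calmodulin/FKBP12.6
regulation, luminal (SR) Ca dynamics, LCC triggering, spatially resolved
sub-dyad Ca gradients, and spark termination.

## Known limitations

* The rapid-diffusion approximation makes every channel feel every opening
  instantly; clusters wider than the Ca equilibration length would need a
  spatial Ca model.
* Waiting-time means at strong coupling are heavy-tailed; 10-run estimates
  carry ~30-40% standard errors and are intended for order-of-magnitude
  comparisons only.
* The iterative 4-channel hitting-time solve is guarded at 1e-6 relative
  residual; quantities derived from near-singular transient blocks (very
  deep metastability) inherit that accuracy.
* `stationary_distribution` is limited to 3 channels by the dense solve;
  the 4-channel reversible case is covered by the Boltzmann closed form.
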