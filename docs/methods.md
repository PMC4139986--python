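# Methods

## Biological setting

Actinorhizal nodules are nitrogen-fixing root organs induced by the
actinomycete *Frankia*. In *Discaria trinervis* (intercellular infection
pathway) immunolocalization places a PIN1-like auxin **efflux** carrier on
the plasma membranes of the large, hypertrophied infected cortical cells,
while the AUX1 auxin **influx** carrier is expressed in the nodule
meristem. Auxin itself, however, is detected inside the infected cells.
The question the model addresses is whether that carrier arrangement can,
by itself, explain auxin accumulation in infected cells and the meristem.
The contrasting *Casuarina glauca* arrangement — AUX1 on infected cells,
PIN1 on the surrounding uninfected cells — serves as a positive control
known to pump auxin into infected cells.

`nodusim` answers the question in silico: virtual nodule tissues are
digitized (or synthesized) as cell-adjacency graphs, carriers are placed by
cell type, a linear carrier-transport ODE is integrated to steady state,
and the resulting spatial pattern is classified by which cell type holds
the highest area-weighted mean concentration.

## Transport model

Each cell `i` carries a concentration `a_i` (amount per unit area,
nondimensional). For the wall between cells `i` and `j`, each membrane
side has an efflux permeability and an influx permeability

    E = d_wall + p_pin * pin_density(side)
    I = i_base + p_aux * aux_density(side)

`d_wall` is the passive leak out of a cell (anionic auxin escaping the
cytoplasm), `i_base` the passive (protonated) re-uptake from the wall
space. The wall itself is treated as a fast intermediate pool: what both
cells release is instantaneously recaptured in proportion to the influx
permeabilities of the two flanking membranes. Eliminating the wall pool
gives the net flux per unit wall length (positive `i -> j`):

    J(i->j) = ( E_i I_j a_i - E_j I_i a_j ) / (I_i + I_j)

and the cell balance

    da_i/dt = (1/area_i) * sum_j wall_ij * J(j->i)
              + sigma + s_frankia * [has_frankia_i] - delta * a_i

This formulation has two properties that matter scientifically:

* a PIN carrier actively *pushes* auxin out of its cell (`E` grows without
  bound with carrier density), whereas
* an AUX1 carrier only *biases the capture* of auxin already released into
  the shared wall — it cannot extract auxin from a neighbor's cytoplasm
  beyond what the neighbor leaks.

An alternative in which influx carriers pump directly against the
cytoplasmic gradient (a term `p_aux * aux(j) * a_i` in the flux) was
examined and rejected: it makes any AUX1-expressing region an unbounded
trap, so the meristem would always out-accumulate every other tissue, for
every parameter choice — inconsistent with the behavior this model family
is known to produce on nodule sections. The operator form `da/dt = M a + c`
is assembled explicitly, so a different wall treatment (e.g. an explicit
apoplast compartment with wall-to-wall diffusion) can be swapped in without
touching the solvers.

The dynamics are linear with non-saturating carriers (no
Michaelis–Menten): no kinetic constants are available to parameterize
saturation, and linearity gives a unique steady state and an exact direct
solver to test against.

## Parameters, units, defaults

All quantities are nondimensional. Permeabilities are expressed in units
of the passive wall leak, so `d_wall = 1` by convention.

| parameter | meaning | default |
|---|---|---|
| `d_wall` | passive efflux (leak) per unit wall length | 1 |
| `p_pin` | efflux-carrier coefficient (x `pin_density`) | 10 |
| `p_aux` | influx-carrier coefficient (x `aux_density`) | 10 |
| `i_base` | passive influx (capture baseline), must be > 0 | 1 |
| `sigma` | basal production per unit area | 0.1 |
| `delta` | first-order decay rate | 1 |
| `s_frankia` | extra source in Frankia-containing cells | 1 (low) / 10 (high) |
| `a0` | initial uniform level | 1 |

Carrier coefficients of 10 make carrier-mediated transport dominate the
passive leak tenfold, representing strongly membrane-localized
transporters. The decay rate is set so the decay time equals the passive
wall-exchange time. This is a deliberate regime choice: if transport is
much faster than turnover (`delta << 1`), every cell-type interface
settles to its capture-ratio equilibrium and whichever type has the largest
influx/efflux ratio accumulates regardless of geometry or supply; with
turnover comparable to exchange, levels are supply-limited and reflect
actual fluxes — infected cells with PIN drain into their uninfected
neighbors faster than the meristem can scavenge its passive trickle.
Pattern classification is scale-invariant, so the magnitudes of `sigma`,
`s_frankia` and `a0` affect absolute levels only.

## Scenarios

* **production_only** — `a0 = 0`, `sigma > 0`: production everywhere,
  classification at the steady state.
* **initial_pool** — `a0 > 0`, no production: the pool decays to zero, so
  the steady state carries no pattern. The readout is the time-integrated
  exposure profile `∫ a(t) dt = -M⁻¹ a0`, which is dominated by the
  transient while the pool still exists and is computed exactly by direct
  solve (the integrator cross-checks it by trapezoidal accumulation). A
  run-to-quasi-stationarity of the normalized profile was considered and
  rejected: that profile provably converges to the slowest-decaying
  eigenmode, an asymptotic object reached only after the pool is gone
  (< 1e-6 of the initial mass), not the pattern of the observable
  transient. For a uniform initial pool the exposure profile is
  proportional to the uniform-production steady state, so the two
  scenarios legitimately give the same pattern.
* **frankia_source_low/high** — a source only in Frankia-containing
  (infected) cells, at strengths 1 and 10; steady-state readout.

## Solvers

`steady_state_direct` solves `M a = -c` (sparse LU). `simulate` integrates
with explicit Heun (second order) under a stability bound
`dt <= 0.5 / max_i |M_ii|`; an oversized user `dt` is halved until
admissible. Each stage's transport term has zero area-weighted column
sums, so closed-tissue mass is conserved to rounding (measured drift
~1e-14 over 1e4 steps). Convergence is declared when
`max|da/dt| / max(a)` falls below `steady_tol` (1e-8 default).
Nonnegativity comes from the stability bound, never from clipping (the
direct solver clips only sub-1e-9 rounding negatives and raises on
anything larger). Degenerate inputs: `delta = 0` is allowed in time
integration (closed-tissue studies) but rejected by the direct solver and
the exposure integral, where `M` is singular.

## Synthetic tissues

The generator emulates a digitized longitudinal section of one nodule
lobe: an elongated ellipse (3:1) on an integer pixel grid, a contiguous
meristematic cap at the apex (10% of cells), and a cortex in which
rectangular infected tiles (2x2 pixels, area ratio 4, `has_frankia` true)
are interspersed by seeded rejection sampling among single-pixel
uninfected cells (35% of cortex cells infected). Tiles are only accepted
if they keep at least one free cortex pixel adjacent to themselves and to
every neighboring tile, guaranteeing each infected cell an uninfected
neighbor; a logged repair (tile converted back to uninfected) is kept as a
backstop. Default size ~200 cells keeps a full scenario panel under a few
seconds on one CPU.

Integer-grid geometry makes the digitization round-trip
(`render_label_map` then `import_label_map`) exact and the generator
bit-reproducible across platforms. What the generator does **not**
emulate: real cell-shape irregularity, the vascular bundle (the three-type
virtual tissues contain no vascular cells, so AUX1 expression in the
vasculature is out of scope), lobe-to-lobe shape variation beyond the
exposed spec knobs, and any 3-D structure. Passing tests therefore show
that the *carrier logic* produces the reported patterns on tissues with
the right statistical composition — not that geometry is irrelevant.

## Pattern classification

Per cell type the area-weighted mean concentration is computed
(area-weighted because infected cells are hypertrophied and the claim is
about where auxin sits spatially; an unweighted variant is exposed). The
label names the set of types within `epsilon = 0.01` (relative) of the top
mean: a singleton gives `infected`/`uninfected`/`meristem`; the pair
{infected, meristem} gives `infected_and_meristem` (the biologically
observed pattern); anything else is `uniform_ambiguous`. The margin
(relative excess of the top mean over the runner-up) is reported with
every call. "Accumulation" has no quantitative definition in the
underlying imaging; this margin rule is the package's operationalization
and is labeled as such in outputs.

## Parameter sweep

The default exploration is a 4^4 log-spaced grid (256 configurations):
`d_wall` in {0.25, 0.5, 1, 2}, `p_pin` and `p_aux` in {2.5, 8, 25, 80},
source scale in {0.3, 1, 3, 10}, under the *D. trinervis* layout and the
Frankia-source scenario, evaluated by direct solve. The carrier axes start
at 2.5x the unit passive leak by design: a "carrier" weaker than the
passive background does not represent an immunolocalized transporter, and
configurations in that regime reduce to carrier-free tissues. On this
grid, zero configurations classify as `infected_and_meristem` — the
negative result is a property of this flux law on this grid, reported as a
computed count, never asserted as exhaustive.

## Known limitations

* The original model behind the section simulations is not published as
  equations; the flux law here is this package's own (documented above),
  and only pattern-level outcomes are comparable.
* No PIN polarity or canalization feedback, no auxin-dependent carrier
  regulation, no growth or division, no explicit apoplast continuum.
* Classification margins, not significance: the model is deterministic,
  so no statistical machinery is attached to the calls.
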