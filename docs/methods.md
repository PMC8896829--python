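# Methods

## Model

The simulated object is a 2D cross-section of a cellularized fly
embryo at the onset of gastrulation: a ring of 80 congruent wedge cells
between the vitelline membrane (outer circle) and the yolk (inner
disc). Vertices are the apical and basal cell corners (two per cell
boundary, 160 in total); lateral edges are shared between neighbouring
cells and stored once. Topology is fixed — there is no cell
rearrangement, division or growth, matching the few-minute timescale of
furrow formation.

All cell membranes are elastic springs in the energy convention
`K (x − x0)²`; rest lengths and rest areas equal the constructed
initial values, so the unloaded initial state is exactly stress-free.
Cell and yolk areas are soft constraints (quadratic penalties), not
hard ones. The only active inputs are (i) the Gaussian apical
contractility `μᵢ aᵢ²` in the 18-cell mesoderm and (ii) the
zero-rest-length active lateral spring `K_L,active l²` on the 19
lateral edges of the constriction domain (mesoderm-interior plus both
mesoderm–ectoderm boundary edges). The printed lateral force law
`F = K_L,active·l + K_L,passive·(l−l₀)` is exposed as a diagnostic; the
energy terms differ from its integral by the conventional factor 2,
which is absorbed into the constants and does not change which
phenomena occur.

Because the cell count is even, the ventral midline falls on a cell
boundary; the contractility Gaussian is centred there, so cell offsets
are half-integers (±0.5, ±1.5, …) and the profile is exactly
mirror-symmetric.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `n_cells` | 80 | – | cells in the ring |
| `vitelline_radius` | 90 | µm | eggshell radius |
| `cell_length` | 35 | µm | initial apicobasal length |
| `Ka, Kl, Kb` | 30, 20, 2¹⁰→2⁰ | a.u. | apical/lateral/basal stiffness |
| `mu0, sigma` | 5000, 3 | a.u., cells | contractility amplitude and width |
| `Kv, KY` | 5000, 1 | a.u. | cell-area and yolk-area penalty weights |
| `KL_active, KL_passive` | 2, 20 | a.u. | constriction-domain lateral springs |
| `deltaL` | 0.20 | – | ectodermal lateral rest-length reduction |

The embryo's physical dimensions are not part of the standard parameter
table; 90 µm and 35 µm are typical cellularization-stage values and set
the micron scale of all depth readouts. Spring constants are unitless
model parameters (arbitrary units); lengths are µm and areas µm²
throughout.

`deltaL` is applied to every lateral edge whose two adjoining cells are
both ectodermal (61 edges). A config switch
(`shortening_mode="exclude_flanking"`) restricts the target band to the
60 ectodermal cells not adjacent to the mesoderm; the default targets
all of them.

## Equilibration

Each state of the adiabatic schedule is an energy minimum under the
hard confinement `|x_v| ≤ R` (the vitelline shell is rigid and does not
contribute energy). The solver is a projected Newton method:

- dense analytic Hessian (320×320 at default size), assembled in a
  compiled kernel and verified against finite differences of the
  analytic gradient;
- active-set treatment of shell contact: a vertex pressed outward
  against the shell keeps a single tangential degree of freedom, with
  the curvature correction `−g·x/R²` from the circular path;
- Levenberg damping escalated whenever the reduced Hessian fails to
  factor or the step is not a descent direction (the landscape is
  non-convex around the buckling transition);
- monotone Armijo backtracking on radially clamped trial points, so the
  energy never increases along the iterate sequence;
- a per-iteration displacement cap (1 µm base, relaxing to 3 µm during
  long monotone descents). This keeps the descent path local: the
  model's scientific content is hysteresis between coexisting minima,
  and uncapped quasi-Newton steps can hop across the ridge separating
  the relaxed and invaginated basins, which would corrupt exactly the
  bistability being measured. A projected L-BFGS implementation is kept
  as an independent cross-check (`method="lbfgs"`).

Convergence is declared when the infinity-norm of the projected
gradient falls below `1e-6 · max(μ₀, 1000) · a₀` (config-exposed).
Deep relaxations (e.g. removing contractility from a fully invaginated
state) legitimately take several thousand capped iterations; the
default iteration budget (20 000) accommodates them, and unconverged
states are flagged, warned about and never silently classified.

Mirror symmetry: the energy is invariant under reflection about the
midline, but the buckled branch can break symmetry sideways from
round-off noise. By default the solver restricts the search to the
mirror-symmetric subspace (iterates and gradients averaged with their
mirror image), following the symmetric solution branch that the
symmetric loading is meant to probe. The restriction can be switched
off for robustness studies.

## Perturbation protocol

In-silico optogenetic inhibition zeroes `μ₀` and `K_L,active` at a
chosen intermediate equilibrium state `k` and re-equilibrates through
the remaining schedule entries (from `k` inclusive, so the final state
is always re-equilibrated at `K_b = 2⁰`). The response is classified on
the final state against the unperturbed final depth `D_ref`: *relaxed*
below `0.2·D_ref`, *invaginated* above `0.8·D_ref`, *paused* between
(thresholds config-exposed; the acceptance checks verify the
classification is stable over 0.15–0.25 / 0.75–0.85). The transitional
index `k*` is the smallest `k` whose inhibition still invaginates —
an outcome-based operationalization of the transitional configuration,
chosen because the model provides no independent quantitative
morphological criterion. "Late" inhibition means `k = k*`; "early"
means `k < k*`.

Whether the basal-stiffness schedule continues after inhibition is a
genuine protocol ambiguity. We continue it: holding `K_b` at the
inhibition value yields graded final depths rather than the observed
binary dichotomy, whereas the continuation protocol separates the
outcomes cleanly (all-or-none) at every probed condition.

## Readouts

- **Invagination depth `D`**: vitelline radius minus the radial
  coordinate of the apical midline vertex (shared by the two
  midline-adjacent cells). Zero on the initial state by construction.
- **Per-cell shape table**: apical/basal/mean-lateral lengths, shoelace
  area, and tilt (unsigned angle between the apicobasal axis and the
  local radial direction — a single-angle proxy; full curvature
  reconstruction is out of scope).
- **Sector areas**: total cell-layer area in angular windows from the
  ventral midline (ectoderm thickness proxy); a full partition of
  windows recovers the total layer area to 1e-9 relative.
- **Constricting-cell count**: cells whose final apical length is below
  a threshold fraction (default 0.5) of the initial one.

## What the synthetic geometry does and does not emulate

The generator produces an idealized circular cross-section with
congruent cells, exact initial mirror symmetry and a stress-free rest
state. Real embryo cross-sections are mildly elliptical, cells are
heterogeneous in size, cellularization is still completing during early
gastrulation, and embryonic tissue is viscoelastic rather than elastic.
Passing tests therefore demonstrate the mechanical logic of the model
— buckling-like folding under joint apical constriction and in-plane
compression, with history-dependent (bistable) responses — not a
quantitative fit to any particular embryo.

Two consequences of idealization are visible in the numbers. The
partition identity "cell areas + yolk = disc area" holds exactly for
the polygonal disc spanned by the apical ring; against the smooth
circle πR² it carries the 80-gon discretization error (~0.1%), which is
the price of using shoelace areas consistently in the energy. And the
quantitative thresholds of the bistable regime (the minimum `deltaL`,
the depth retained after late inhibition at small `K_L,passive`, the
number of cells ending below half their initial apical length) are
sensitive to the unprinted embryo dimensions and to the minimizer's
path through coexisting minima; the package reports what this
realization computes (e.g. bistability requires `deltaL` between 0.10
and 0.20 here, 18 cells constrict below half, and late-inhibition
depths at `K_L,passive = 20/2/0.2` are 64.8/62.3/54.8 µm with the
strict ordering preserved). The every-other-cell contractility pattern
does not invaginate at all in this realization — its halved drive sits
below this geometry's buckling threshold.

## Numerical choices

- Shoelace (signed) areas on ordered cell quads; positive orientation
  enforced by construction.
- Degenerate edge lengths are floored at 1e-300 to avoid division by
  zero in unit vectors; no physical state approaches this.
- Energy/gradient/Hessian kernels are numba-compiled with a pure-numpy
  reference implementation; a test asserts agreement at machine
  precision.
- The trajectory archive is a flat `.npz` with a format-version field;
  reads of truncated or foreign files fail loudly.
- No randomness anywhere in the default pipeline; the only seeds appear
  in tests and in optional robustness perturbations.

## Known limitations

- Quasi-static only: no time axis, so rate-based readouts (`dD/dt`,
  delay times) have no analogue here.
- Fixed topology: no intercalation, mitosis or delamination.
- The vitelline shell is perfectly rigid and frictionless.
- 2D cross-section: out-of-plane (anteroposterior) coupling, e.g. from
  germband extension, is absent.
- Depth-scale statements inherit the ±20% uncertainty of the assumed
  embryo dimensions.
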