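# furrowsim

A 2D energy-minimization vertex model of ventral furrow formation in the
gastrulating *Drosophila* embryo, built to study the **mechanical
bistability** of the folding mesoderm: once the tissue passes a
stereotyped transitional configuration, invagination completes even if
actomyosin contractility is switched off.

The package is aimed at tissue-mechanics and morphogenesis researchers
who want a tested, scriptable implementation of this model: the energy
function and its analytic derivatives, a robust constrained equilibrium
solver, the in-silico optogenetic perturbation experiments, and the
tissue/cell-shape readouts, all exposed as a Python library plus a
small CLI.

## Model

The embryo cross-section is a ring of `n = 80` quadrilateral cells
between the rigid vitelline membrane (outer circle, radius 90 µm) and
the yolk (inner disc); cells are 35 µm long apicobasally. Each vertex
configuration has the energy

```
E = Σᵢ φᵢ μᵢ aᵢ²                                  apical contractility (mesoderm)
  + Σᵢ [ Kₐ(aᵢ−a₀)² + K_b(bᵢ−b₀)² ]               apical/basal elasticity
  + Σⱼ Kₗ(lⱼ−l₀ⱼ)²                                lateral elasticity (ectoderm)
  + Σⱼ [ K_L,passive(lⱼ−l₀ⱼ)² + K_L,active lⱼ² ]   lateral springs (constriction domain)
  + Σᵢ K_v(Vᵢ−V₀)² + K_Y(V_yolk−V₀,yolk)²          area (2D volume) conservation
```

with `aᵢ, bᵢ, lⱼ` the apical, basal and lateral edge lengths and `Vᵢ`
the shoelace cell areas. The contractility weights
`μᵢ = μ₀ exp(−dᵢ²/2σ²)` follow a Gaussian centred on the ventral
midline and act only on the 18-cell mesoderm (`φᵢ = 1`); the active
lateral spring has zero rest length and models myosin-dependent lateral
tension. In-plane **ectodermal compression** enters by shortening the
lateral rest lengths of the 62 ectodermal cells by a fraction
`ΔL` (default 20 %): area conservation then widens those cells and
compresses the ring. Defaults follow the standard parameter set
(`Kₐ=30, Kₗ=20, μ₀=5000, σ=3, K_v=5000, K_Y=1, K_L,active=2,
K_L,passive=20`).

The model is quasi-static: the basal stiffness `K_b` decreases
adiabatically from 2¹⁰ to 2⁰ (halving per step) and an energy minimum
is computed at each value, subject to the hard vitelline confinement
`|x| ≤ R`. In-silico optogenetic inhibition zeroes `μ₀` and
`K_L,active` at a chosen intermediate state and continues the schedule;
the final state either relaxes or invaginates — the binary response
that diagnoses bistability.

## Worked example

```python
from furrowsim import prepare_model, run_schedule, find_transition, invagination_depth

geom, ann, params = prepare_model()        # 80-cell ring, 20% ectodermal shortening
traj = run_schedule(geom, ann, params)     # equilibria for Kb = 2^10 ... 2^0
print(f"unperturbed final depth D = {invagination_depth(traj.final, geom):.2f} um")

k_star, results = find_transition(traj, method="bisect")
print(f"transitional state k* = {k_star}")
print(f"inhibition at k=0:  {results[0].response}, D = {results[0].D_final:.2f} um")
print(f"inhibition at k*={k_star}: {results[k_star].response}, D = {results[k_star].D_final:.2f} um")
```

prints

```
unperturbed final depth D = 65.38 um
transitional state k* = 3
inhibition at k=0:  relaxed, D = 0.00 um
inhibition at k*=3: invaginated, D = 64.76 um
```

The unperturbed schedule drives a ~65 µm deep ventral furrow.
Removing contractility at the first two intermediate states lets the
tissue relax completely (`D → 0`); from state 3 onward the furrow
completes on its own — the binary, history-dependent response of a
mechanically bistable tissue. Without ectodermal compression
(`deltaL=0`) inhibition at *any* state relaxes the tissue.

The same experiments are available from the shell:

```bash
furrowsim run --out out/                       # unperturbed schedule
furrowsim inhibit --at 3 --out out_inhibit/    # acute inhibition at state 3
furrowsim sweep --param deltaL --values 0,0.05,0.1,0.2
furrowsim grid --kl-active 0,2 --kl-passive 0.2,2,20
```

Each command writes a trajectory archive (`.npz`), tidy metric CSVs,
summary plots and a manifest with the exact configuration.

## Layout

- `src/furrowsim/geometry.py` — synthetic embryo cross-section, mesoderm mask, contractility profile
- `src/furrowsim/mechanics.py` — energy, analytic gradient and Hessian (numba kernels + numpy reference)
- `src/furrowsim/equilibrate.py` — projected Newton solver with shell contact, adiabatic `K_b` schedule
- `src/furrowsim/experiments.py` — inhibition experiments, transition search, parameter sweeps
- `src/furrowsim/metrics.py` — invagination depth, per-cell shape tables, sector areas
- `src/furrowsim/config.py`, `io.py`, `plotting.py`, `cli.py` — configuration, archives, figures, CLI
- `docs/methods.md` — modelling choices, assumptions and limitations
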