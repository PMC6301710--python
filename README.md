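# dfba-pdo

Dynamic flux balance analysis (DFBA) of 1,3-propanediol (PDO) production
from glycerol by *Clostridium butyricum*.

Anaerobic glycerol fermentation splits carbon between a reductive branch
(glycerol → 3-HPA → PDO, consuming NADH) and an oxidative branch (glycerol →
DHAP → pyruvate → acetyl-CoA → acetate/butyrate/…, producing NADH and ATP).
How much PDO a batch or fed-batch culture accumulates therefore depends on
the instantaneous intracellular flux distribution, which this package
predicts by constraint-based optimisation coupled to the extracellular mass
balances:

- **Flux problem** (solved at every instant): maximise the growth-per-flux
  objective

  Z = μ / ( w·Σⱼ vⱼ² + (1−w)·v²_ATPprod )

  subject to S·v = 0 and flux bounds, where μ is the specific growth rate
  and v_ATPprod the summed substrate-level ATP production flux.  The weight
  switches with the glycerol regime: w = 1 under limitation (< 15 g/L),
  w = 0.04 at excess.
- **Kinetic constraints**: the glycerol uptake flux follows a Ghose–Tyagi
  substrate-inhibition law, v = v_max·G/(K_s+G)·(1−G/K_i), and the acetate
  secretion flux is capped by a logistic function of the uptake flux.
- **Dynamics**: dz_i/dt = Σ S_ij·v_j·X and dX/dt = (μ−k_d)·X, integrated by
  three interchangeable strategies — SOA (Euler with per-step optimisation),
  DA (adaptive integration with embedded optimisation) and DOA (orthogonal
  collocation over the whole horizon) — plus fed-batch balances with a
  constant or pH-coupled (proton-secretion-proportional) feed.

On top of the simulator the package provides global sensitivity analysis of
the 60 input parameters (MPSA with Kolmogorov–Smirnov classification, and
partial rank correlation coefficients), a Monte-Carlo population balance
model (PBM) of cell-to-cell variability, design-space scans of batch and
fed-batch conditions, and a synthetic-data module that generates
pseudo-experimental fermentation tables and recovers the kinetic laws from
them.

## Worked example

```python
from dfba_pdo import (build_reduced_network, excess_batch_spec,
                      simulate, trajectory_metrics)
from dfba_pdo.simulate import CultureState

net = build_reduced_network()
spec = excess_batch_spec(net,
                         initial=CultureState(X=0.12, z={"glycerol": 46.0}),
                         tf=40.0, approach="DA")
traj = simulate(spec)
m = trajectory_metrics(traj)
print(f"final PDO        {m['final_pdo']:.1f} g/L")
print(f"culture time     {m['culture_time']:.1f} h")
print(f"productivity     {m['q_pdo']:.2f} g/L/h")
print(f"molar yield      {m['y_pdo_mol']:.2f} mol PDO / mol glycerol")
```

prints

```
final PDO        21.9 g/L
culture time     14.0 h
productivity     1.57 g/L/h
molar yield      0.58 mol PDO / mol glycerol
```

i.e. a 46 g/L batch inoculated with 0.12 gDW/L of cells exhausts its
glycerol in about 14 h and converts 58 % of it (molar basis) to PDO; the
remainder leaves as acetate, butyrate, H₂/CO₂ and biomass.  The same
`Trajectory` object carries the full time courses and the per-step flux
distributions (`traj.states`, `traj.fluxes`).

The command line mirrors the library:

```bash
dfba-pdo simulate --approach da --out results/
dfba-pdo scan --mode batch --out results/
dfba-pdo sensitivity --k 2280 --seed 1 --out results/
dfba-pdo pbm --group acetate3 --rsd 0.30 --cells 1000 --seed 1 --out results/
dfba-pdo synth --regime excess --n 6 --seed 1 --out results/
```

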