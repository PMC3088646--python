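# stemcpm

A cellular Potts model (CPM) of tumor growth driven by a cancer-stem-cell
hierarchy, for computational biologists studying intratumor heterogeneity
and clonal evolution.

Are established tumors maintained by a rare compartment of cancer stem
cells (CSCs)? One testable consequence of that hypothesis concerns
*neutral* epigenetic marks: methylation errors in untranscribed CpG-rich
regions accumulate at µ ≈ 2×10⁻⁵ per site per division and act as a
molecular clock. `stemcpm` grows in-silico tumors from a single founder
cell under both organizations — hierarchical (CSC → transit-amplifying
cells → quiescent differentiated cells) and classical (every cell
clonogenic) — and measures how the organization alone changes clonal
heterogeneity, the exploration of fitness landscapes, and the response
to therapy.

## The model

Cells are connected domains of lattice sites sharing an identifier σ;
the Hamiltonian

&nbsp;&nbsp;&nbsp;&nbsp;H = Σ_σ λ (V_σ − V_tr,σ)² + Σ_⟨ij⟩ J(τ_i, τ_j) · [σ_i ≠ σ_j]

combines volume elasticity (λ = 3) and membrane adhesion (J = 9), and
evolves by Metropolis copy attempts accepted with probability
min(1, e^(−ΔH/T)). On top of the Potts dynamics:

* every non-quiescent cell raises its target volume by δV = V0·Δt/c per
  step (c = 20 h cell cycle, scaled by its fitness f(x)/f(0)), pausing
  while compressed, and divides by a centroid split once its target has
  doubled;
* a CSC self-renews with probability ψ (default 0.1) or spins off a TAC
  that divides at most G = 5 times before quiescence; ψ = 1 is the
  classical model;
* a 64-CpG methylation pattern mutates in mother and daughter at every
  division (neutral clock), and optionally an integer phenotype
  x ∈ [−24, 25] takes ±1 steps (µ_f = 0.1) on a named fitness
  landscape, e.g. f_S(x) = 3 − x·sin(x/2);
* a fraction a of cells (1–2% per 24 h) dies daily; therapy kills
  non-quiescent cells with probability f(x)/f_max.

Heterogeneity is the normalized Shannon index Ξ' = (−Σ p_i ln p_i)/ln S
over clone labels (methylation patterns or phenotypes), 0 for a single
dominant clone and 1 for a maximally even clone mix.

See `docs/methods.md` for the full model description, parameter table
and numerical choices.

## Worked example

Grow a small hierarchical tumor and print its heterogeneity:

```python
import stemcpm as s

cfg = s.SimulationConfig(
    lattice_size=400,   # lattice sites per side
    stop_volume=1000,   # stop at 1,000 cells
    psi=0.1,            # CSC self-renewal probability
    seed=7,
)
res = s.run_simulation(cfg)
ts = res.timeseries
print(res.status, "cells:", res.n_cells,
      "CSC fraction: %.4f" % (ts.n_csc.iloc[-1] / ts.n_cells.iloc[-1]),
      "Shannon': %.3f" % ts.shannon_norm.iloc[-1],
      "clones:", len(res.clone_table))
```

prints

```
reached_volume cells: 1000 CSC fraction: 0.0030 Shannon': 0.011 clones: 2
```

— the tumor reached 1,000 cells, of which 0.3% are CSCs (the fraction
stabilizes near 0.5% in larger runs), and at this early size it carries
two methylation clones with a normalized Shannon index of 0.011. Running
the same config with `psi=1.0` yields a classical tumor whose every
cell is a CSC and whose heterogeneity is lower at matched volume.

The same runs are available from the shell:

```
stemcpm grow --psi 0.1 --stop-volume 1000 --lattice-size 400 --seed 7 --out run1
stemcpm therapy --landscape sinusoidal_S --therapy-at 3000 --out run2
stemcpm constant-population --landscape sinusoidal_S --out run3
stemcpm replicates -n 8 --mode fitness --landscape sinusoidal_S --out run4
stemcpm stats run1/snapshot.txt
```

Each command writes tab-separated time series and clone tables, a JSON
run manifest, and optional plain-text lattice snapshots and PGM images
(`--snapshot`, `--image`).

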