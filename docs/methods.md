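# Methods

## The model

`stemcpm` simulates tumor growth as a 2-D cellular Potts model (CPM).
A cell is a connected set of lattice sites sharing an identifier σ > 0
(0 is the medium); a nominal cell occupies V0 = 16 sites. The system
energy is

    H = Σ_cells λ (V_σ − V_tr,σ)² + Σ_{neighbor pairs} J(τ1, τ2) [σ1 ≠ σ2]

with λ the cell stiffness, V_tr the per-cell target volume, and J the
contact cost per unordered neighboring pair of sites belonging to
different cells (β-exclusion: same-cell pairs cost nothing). Cell–cell
and cell–medium contacts carry separate coefficients (both default 9;
the paper-level literature prints a single J). Dynamics are Metropolis
copy attempts: a random site takes the identifier of a random neighbor,
accepted with probability 1 if ΔH < 0 and exp(−ΔH/T) otherwise. The
temperature T (default 8, the same order as J) controls membrane
fluctuation only; the published description leaves the acceptance
expression and T unspecified, so the standard Boltzmann form is used.
The neighborhood is Moore (8 neighbors) by default, configurable to
von Neumann (4); both the copy attempts and the adhesion sum use the
same neighborhood.

### Growth, division, death

Every non-quiescent cell runs a growth clock: its target volume rises
by δV = V0 · Δt / c per Monte-Carlo step (MCS), where c = 20 h is the
cell-cycle duration, so a cell at the reference fitness accumulates one
full doubling of volume demand in exactly one cycle. Three rules shape
this clock; they are the package's resolution of a printed division
rule ("divide if V_σ > 2 V_tr while V_tr grows by δV") that is not
self-consistent as written:

* **Contact inhibition.** A cell only accumulates target growth while
  its actual volume keeps up with its target (within
  `growth_gate_margin`, default 4 sites — the scale of the
  surface-tension volume deficit, ≈ J_medium/λ + ½ ≈ 3.5 sites, below
  which a cell's equilibrium volume sits under its target). Compressed
  cells pause their cycle; this bounds the pressure any cell can exert,
  which is what lets the quiescent compartment persist. Without the
  gate, cycling cells accumulate unbounded volume deficits and crush
  their quiescent neighbors.
* **Division trigger.** A cell divides once its target has doubled
  (V_tr = 2·V0) and it has at least 2 sites to split. Because of the
  gate, a dividing cell's actual volume is near 2·V0. The cell's
  largest connected component is cut through its pixel centroid
  perpendicular to the principal axis (ties in the projection broken by
  the run's RNG; an isotropic site cloud gets a random cut direction);
  the far half becomes the daughter under a fresh identifier;
  detached fragments, rare at the default J, λ, T, stay with the
  mother. Both offspring reset their target to V0.
* **Apoptosis.** Once per simulated 24 h every live cell, of any type,
  dies independently with probability a (0.01 in neutral runs, 0.02 in
  fitness-driven runs). Death is instantaneous removal: the cell's
  sites revert to medium.

### Time mapping and attempts per step

One MCS maps to `hours_per_mcs` simulated hours (default 0.25, i.e.
4 sweeps per simulated hour). Each MCS performs A elementary attempts,
where A = (number of non-medium sites) + a boundary-shell allowance
(the perimeter of the tumor's padded bounding window). Attempts are
sampled inside that window: outside it every site and all its
neighbors are medium, so a copy is a no-op by construction and skipping
them changes nothing. The published description fixes neither the
MCS↔hours map nor the attempt count; 4 sweeps/hour is the largest
relaxation-per-simulated-hour a desktop-scale run affords. Fewer
sweeps per hour make growth strongly rim-limited: tumors then take so
long (in simulated days) to reach observation size that daily apoptosis
hollows out their interior, which contradicts the compact morphologies
the model is meant to produce.

### The hierarchy

Cells are CSCs (divide indefinitely; self-renew with probability ψ,
default 0.1, else spin off a TAC), TACs (counter g; each division
yields two TACs at g+1; at g = G, default 5, the cell becomes a DC),
and DCs (quiescent: no growth, no division, still occupy space and die
by apoptosis). CSC → (TAC, TAC) never occurs. ψ = 1 recovers the
classical fully clonogenic model. One TAC lineage yields at most
2^G cells.

### Mutations

* **Neutral clock:** a 64-CpG methylation pattern (bit vector, packed
  into a uint64; founder all-zero). At every division, mother and
  daughter patterns are copied with independent per-site flip
  probability µ = 2×10⁻⁵ (one rate for methylation and demethylation);
  this applies to every cell type.
* **Non-neutral walk:** an integer phenotype x ∈ [−24, +25]
  (50 states; founder x₀ = 0). At each division each offspring mutates
  with probability µ_f = 0.1 to x ± 1 (equal probability); steps past
  the solid boundaries are cancelled. A named landscape maps x to a
  division rate f(x) ≥ 1 (floor-clamped; trigonometric arguments in
  radians; tabulated exactly on the 50 integers):
  linear x+8 (1 for all x < 0, as printed), sinusoidal 3 − x·sin(x/2),
  its variant x·sin(x) + 2, and the asymmetric x·cos(x/2) + 2. The
  growth clock scales with f(x)/f(0), so fitness is division rate.

### Heterogeneity statistics

Clone labels are methylation patterns (neutral runs) or phenotypes
(fitness runs). The Shannon index H = −Σ p_i ln p_i is normalized by
ln S over the S labels observed (0 by convention for S = 1; natural
logarithms — normalization cancels the base). S counts observed labels,
not the 2⁶⁴ possible ones, which would degenerate the measure. Group
comparisons use the two-sided Mann–Whitney rank-sum test (exact for
group sizes ≤ 12 without ties), since the published comparisons do not
name their test.

### Protocols

* **Growth:** one founder CSC (unmethylated, x₀ = 0) seeded as a 4×4
  block at the lattice center; run until the live-cell count reaches
  `stop_volume` or no proliferative cell remains (extinction is a
  reported outcome, not an exception). Tumor contact with the lattice
  boundary aborts with an explicit error; `auto_lattice_size` allows
  2.8× the nominal circular diameter because hierarchical tumors grow
  lobed and off-center.
* **Therapy:** at `therapy_trigger_volume` cells, treatment kills every
  non-quiescent cell with probability f(x)/f_max (f_max over live
  cells): an instantaneous, phenotype-targeted kill in which quiescence
  or a slow-cycling phenotype is protective. Two alternative rules are
  selectable: `cycling` (kill every cell whose growth clock is
  currently running) and `window` (for a finite window, cells reaching
  the division trigger die instead of dividing). The survivors regrow
  to the trigger volume; pre/post summaries include the phenotype
  histogram and mean fitness.
* **Constant population:** grow to 25,000 cells (configurable), then
  after every MCS kill uniformly random cells to restore that volume,
  until a division budget (default 1.2×10⁶, scalable) is spent.
* **Replicates:** n runs with distinct seeds; aggregates are mean ± SD
  per phase and statistic, invariant to seed order.

## Randomness and reproducibility

One master seed feeds a `numpy` SeedSequence that spawns (a) a PCG64
generator for all Python-level draws — fate choices, mutations,
apoptosis, split tie-breaks, in that order per event — and (b) a 64-bit
xorshift* state for the compiled Metropolis kernel (site, neighbor and
acceptance draws). Runs are bit-reproducible from (config, seed), and a
checksummed plain-text snapshot stores both generator states so a
resumed run reproduces an uninterrupted one exactly. A daily audit
recomputes every cell's volume and bounding box from the grid and
fails loudly on any registry/grid disagreement.

## Numerical and engineering choices

* Per-cell arrays indexed by σ (never reused) back a numba-compiled
  attempt kernel; the Python-level `metropolis_attempt` shares the
  same ΔH routine and exists for instrumentation and tests.
* Each cell carries a bounding box that is a superset of its sites
  (grown on accepted copies, tightened at division and audits); kills
  and divisions scan only that box.
* Division order within an MCS is ascending σ; apoptosis draws are in
  ascending σ. Both are part of the reproducibility contract.
* Degenerate cases: a cell fragmented below 2 contiguous sites splits
  over all its sites; a copy that would annihilate a cell's last site
  removes the cell from the registry; medium→medium attempts count
  toward A but change nothing.

## Problem sizes

The published experiments use 100,000-cell tumors on a 2000×2000
lattice (with 30,000-cell therapy triggers and 16/8/12 replicates).
This package's default test suite and the acceptance script run the
same code paths at desk scale, a deliberate package choice so that a
full verification completes on a laptop: 10,000–15,000-cell tumors for
the hierarchy and heterogeneity claims (8 replicates), 5,000 cells for
the fitness-landscape comparisons, and therapy at 3,000 cells
(12 replicates). Replicates whose stem-cell lineage dies out before
reaching the observation volume (a real possibility at ψ = 0.1,
a = 0.01) are excluded from replicate statistics, as only grown tumors
are analyzable.

## What the simulations do and do not show

The generator *is* the study system here — there is no external data —
so "synthetic" limitations are model limitations: no microenvironment
(oxygen, growth factors), no active migration, no necrotic layering,
no 3-D effects, no plasticity (DC → CSC). Desk-scale runs reproduce
the fitness-landscape direction (hierarchical tumors occupy more
phenotype bins and reach larger |x| than classical ones at matched
volume), but quantities that mature only in large, long runs remain
scale-sensitive. The heterogeneity excess of the hierarchical model is
one of them: at 10,000 cells only ~1–2 heritable methylation mutations
have ever landed in a CSC lineage (2·N_divisions·64µ with ~500 CSC
divisions), so the drift-amplification channel that separates the
models in 100,000-cell tumors has not engaged — the measured Shannon
indices of the two models overlap at 10,000 cells and separate in
direction but not significance (n = 8) at 20,000. Under the stated ψ = 0.1, G = 5 hierarchy the
branching arithmetic alone bounds the cells-per-CSC ratio near
0.9·2^G/ln(1+ψ) ≈ 300 before apoptosis attrition lowers it further,
so this implementation stabilizes at a CSC fraction of roughly 0.5%
(ratio ≈ 150–200) rather than the published ≈ 0.2% (≈ 500); the
discrepancy is reported as computed, not calibrated away. Likewise, at
a 3,000-cell therapy trigger the relapse regrowth (~2–3 doublings) is
too short to re-climb, let alone overshoot, the fitness peaks the
treatment emptied, so the relapse fitness increase seen at 30,000
cells does not reproduce at this scale.
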