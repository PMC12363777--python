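# Model and methods

`corneasim` simulates a 2D sagittal section of the corneal limbus and
peripheral cornea as a Cellular Potts (Glazier–Graner–Hogeweg) model coupled
to a reaction–diffusion growth-factor field. This note records the model,
its parameters, the numerical choices, what the simulations do and do not
emulate, and the design decisions taken where the design was genuinely open.

## Lattice, agents and time

The domain is a 200×90 square lattice; each voxel covers 4 μm² (2 μm edge),
so the section spans 400×180 μm. One Monte Carlo Step (MCS) — one sweep of
pixel-copy attempts — represents 6 minutes of biological time (240 MCS per
day). Each cell is a set of lattice pixels carrying a type:

* **STEM** — limbal epithelial stem cells, proliferative, anchored to the
  limbal membrane segment;
* **BASAL** — proliferative cells anchored to the basement membrane;
* **WING** — non-proliferative transitional cells;
* **SUPER** — terminally differentiated superficial cells forming the
  tight-junction barrier, shed into the tear film;
* environmental compartments: **TEAR** (the tear film, a mobile
  medium-like compartment that also clamps the EGF field), **LIMB** and
  **MEMB** (limbal and central segments of the merged basement
  membrane/Bowman's layer, one pixel thick), **STROMA** (a passive spatial
  constraint filling the bottom 40 rows), **WALL** (lateral confinement
  columns), **DAMG** (destroyed basement membrane), and medium (air).

LIMB, MEMB, STROMA, WALL, DAMG and medium are frozen: pixel copies into or
out of them are rejected. The tear film participates in copy attempts the
way the medium does in a conventional CPM — cells can expand into it and
shrink against it — and its band geometry is renormalized once per MCS to
fill the space between the epithelial surface and the tear level (local
surface + 4 voxels, or the tissue-median level if higher, so wounds flood
with tear). A strict exclusion of the tear from the dynamics would fix the
total epithelial pixel count and make growth impossible, which is why the
hybrid was chosen.

## Energy and dynamics

A copy attempt replacing the target pixel's owner with a neighboring
owner changes the effective energy

    ΔH = ΔH_contact + ΔH_volume + ΔH_surface + ΔH_chemotaxis + ΔH_links

with contact energies J(τ,τ′) summed over the Moore (8-pixel) neighborhood,
quadratic volume and surface constraints λ_V (V−V_t)², λ_S (S−S_t)² (the
surface constraint is enabled for stem cells only by default; boundary
faces are counted on the von Neumann neighborhood), a chemotaxis work term
−μ_τ (c_target − c_source) for the invading cell on the EGF field, and
optional cell–cell springs k(d−rest)² on center-of-mass distances. The
spring term is implemented and unit-tested but inert by default (no links
are created by the standard scenarios): the recurrent-erosion pathway
already emerges from the differentiation rule and the damaged-membrane
contact energies, so a hemidesmosome spring is left as an opt-in.

Attempts are accepted when ΔH ≤ 0 and with probability exp(−ΔH/T)
otherwise. One MCS performs as many counted attempts as there are
non-frozen pixels; draws landing on frozen pixels are redrawn uncounted,
while degenerate attempts (same owner, frozen source, off-lattice
neighbor) consume an attempt. Cell connectivity is not enforced; a
diagnostic (`metrics.fragmentation_fraction`) monitors it (typically
0.15–0.25 of cells carry a transient satellite pixel at T = 15).

## Growth, division, differentiation, shedding

Stem and basal cells advance their target volume each MCS by

    dV_t = δ · [km_d⁴/(km_d⁴+P⁴)] · [E⁴/(km_E⁴+E⁴)]

where E is the cell's mean EGF, P = max(0, λ_V (V_t − V)) its crowding
pressure, and δ = 25 px / 80 MCS — the value at which a fully activated
25-pixel cell doubles in 8 hours, the model's minimum doubling interval.
Division triggers when the actual volume reaches 50 px (200 μm²): the pixel
set is ranked along the cleavage-plane normal — the x axis for stem cells
(centripetal daughter placement), a uniformly random direction for basal
cells — and split at the median, so daughters differ by at most one pixel;
both inherit the parent type, and their target volumes reset to their
actual volumes. Parents retire their ID; daughters get fresh IDs (the
turnover metrics rely on this).

Differentiation is deterministic and immediate, applied simultaneously
from one snapshot of the neighbor relation per MCS:

* STEM→BASAL when the cell no longer touches the limbal membrane;
* BASAL→WING when its basement-membrane contact area A (cell pixels with at
  least one LIMB/MEMB neighbor, Moore neighborhood) drops to A ≤ ω = 5 px;
* WING→SUPER when the cell touches tear film and another wing cell and
  none of {BASAL, MEMB, STEM}. The source text's condition omits an
  explicit "= ∅" on the second set; it is read as "intersection empty",
  consistent with superficial cells forming the apical layer.

Superficial cells in tear contact slough with probability 1/(3·240) per
MCS — a geometric lifetime of mean 720 MCS (3 days); their pixels become
tear film, mirroring increased tear production. Per-MCS pipeline order
(fixed, logged): field update → scheduled injuries → concentration-triggered
death → growth → differentiation → mitosis → sloughing → Metropolis sweep →
tear renormalization.

## The EGF field

EGF obeys ∂c/∂t = ∇·(D(x,y)∇c) − kd·c + Ω with the tear film as a Dirichlet
clamp at the normalized source value 1.0. D is looked up from the owner's
type: 20 voxel²/MCS in superficial cells and the central membrane, 0 in the
limbal membrane, 186 elsewhere; kd = 0.5 per MCS (deliberately above the
physiological clearance rate, folding receptor uptake and matrix
sequestration into one constant). Top and bottom lattice rows hold zero
concentration; the wall columns carry D = 0, which realizes the lateral
no-flux condition.

Integration is a Peaceman–Rachford ADI scheme (10 substeps per MCS for EGF,
20 for the toxicant) with harmonic-mean face conductances for the
spatially varying D, identity rows for clamped pixels, and symmetric exact
exponential decay halves around each substep. The scheme is unconditionally
stable at D = 186 and reproduces the analytic sinh steady-state profile to
well under 5% RMS (tested). Decay contract: with D = 0 and no sources, one
MCS multiplies the field by exp(−kd) exactly. ADI is not positivity
preserving on pixel-sharp data, so concentrations are clipped at zero after
each substep; for the smooth fields the simulation produces the clip is
inert and total mass is conserved to machine precision in the no-flux test
mode.

The toxicant field reuses the same machinery (D = 80 voxel²/MCS globally
with the same 20/20/0 type map, kd = 0.25 per MCS, no clamp).

## Injury

Ablation removes every epithelial cell whose center of mass lies inside a
disc and hands the pixels to the tear film. Chemical exposure deposits
either a Gaussian droplet (σ → 0 collapses to the printed single-pixel
point deposit at (100, 75)) or a uniform dose on surface tear pixels, after
which the toxicant evolves freely (the deposit is instantaneous, not a
sustained source). Cells whose mean exposure exceeds the kill threshold
(0.067 a.u.) are marked dying — target volume set to zero, no further
growth, division or differentiation — and are removed when shrinkage
empties them; membrane pixels above threshold become DAMG permanently
(there is no membrane-regeneration mechanism, deliberately). Injury depth
classifies as slight (superficial/wing only), mild (reaches basal cells) or
moderate (membrane breach). With the calibrated toxicant transport the
printed amplitudes 750/1500/2500 a.u. produce the three classes on the
reference seeds; because the local surface height varies stochastically by
a few voxels between runs, the 1500 a.u. depth (the narrowest window —
amplitude ratios of 2 and 1.67 must straddle a ~1.3× dose gradient across
the basal layer) occasionally lands one class shallow on other seeds.

Recurrent erosion emerges from two ingredients: cells over destroyed
membrane have A = 0 and differentiate immediately (premature terminal
differentiation), and the damaged surface is poorly adhesive
(J(cell, DAMG) = 14.5 against a tear–DAMG energy of 6), which puts
re-closure at a bistable edge — the wound re-covers, thins by the
differentiation sink, and breaks down again. J(cell, DAMG) = 14 heals
permanently; 16 leaves a chronic ulcer; the default sits at the cycling
boundary.

## Calibrated parameters

All constants not printed in the model description above are calibrated
once against the emergent outcomes and shipped as config defaults (tagged
in `config.py`): contact energies (see table there; the load-bearing
choices are strong stem/basal–membrane adhesion, expensive tear–membrane
contact so the epithelium wets exposed membrane — this is what produces
centripetal sheet spreading and wound coverage — and a cheap
superficial–tear interface so a cap forms), temperature T = 15, λ_V = 2 for
epithelial types, Hill half-saturations km_E = 0.068 (basal) and 0.14
(stem) with km_d = 8, basal chemotaxis μ = 100 toward EGF, tear thickness
4 voxels, one row of 5×5 stem seeds on the limbal segment, stroma 40 rows.
km_E sets the homeostatic thickness (the EGF attenuation depth is the
thickness controller); the stem/basal split balances the limbal column
against the periphery.

## What the simulations show — and what they do not

The default configuration is the study condition, not a dial: a day-0
state of stem cells, tear and membrane develops into a stratified tissue
with all four types correctly ordered within ~1–2 days, reaches a stable
~50 μm epithelium, and maintains it indefinitely with ongoing turnover.
Scales are desk-sized: acceptance-style campaigns use 3 replicates of
45–60 simulated days rather than the six-month, many-replicate campaigns
the model supports through `run_replicates`.

Known quantitative limitations, documented rather than hidden:

* **Throughput ceiling.** At homeostasis divisions must balance sloughing,
  and sloughing is capped at (tear-contacting superficial cells)/3 per day
  ≈ 13–16 cells/day for this geometry. A 50 μm tissue holds ~230–260
  cells, so the intrinsic relaxation time is ~15–20 days: the stability
  detector typically fires between day 15 and day 25, and near-complete
  (95%) ID substitution takes ~18–25 days peripherally and ~16–25 days in
  the limbal zone rather than the 7/14-day figures the same rules are
  reported to produce at full scale. The stability detector evaluates
  daily-mean counts within ±10% of the trailing 5-day mean (with a
  one-cell floor, since the stem population is 5–8 discrete cells) for 5
  consecutive days.
* **Surface texture.** The simulated surface carries mounds of ~10-day
  lifetime; cross-segment SD of temporal-mean thickness is ~2–4 μm over a
  25-day window (the ten segments are the 20-voxel X bins 0–19 … 180–199).
* **Not modeled.** Membrane regeneration, stromal cellular dynamics,
  immune response, endothelium, chemical-specific modes of action, 3D
  geometry, tear-film composition dynamics. The toxicant is a generic
  diffusing/decaying species with a single kill threshold.

Passing tests on synthetic tissue demonstrate internal consistency of the
rule set and solver and reproduction of the emergent outcomes at desk
scale; they do not validate against histology or clinical injury data.

## Reproducibility

Each run owns one master seed; a numpy Generator (rule engine) and the
Metropolis kernel stream are derived from it, and the kernel stream is
re-derived per MCS from (seed, MCS) so branched or interleaved simulations
stay independent. Identical seed and config give bit-identical grids and
byte-identical metrics CSVs (tested). The field solver uses no randomness.
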