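# fluidwalls

Physics and quantification toolkit for **fluid-walled microfluidic
neuronal circuits** — open-microfluidic "dumbbells" in which two
millimetre-scale chambers of culture medium, confined on a Petri dish
only by interfaces with an immiscible fluorocarbon (FC40), are joined by
a shallow conduit that axons (but not somas) grow through.  It is aimed
at people building or analysing such circuits: microfluidics engineers
choosing filling protocols, and neurobiologists quantifying axonal
outgrowth and post-axotomy regeneration from coverage masks.

## What it computes

**Chamber pressures.**  A pinned chamber is a spherical cap of height
*h* on a footprint of effective radius *a*, so

- V = (π h / 6)(3a² + h²),  R = (a² + h²)/(2h),  P_Laplace = 2γ/R,
- P = 2γ/R + ρ_med g h + ρ_FC40 g (h_FC40 − h),
- ΔP = P_R − P_L = 2γ(1/R_R − 1/R_L) + (ρ_med − ρ_FC40) g (h_R − h_L),

with the FC40 free-surface height cancelling exactly in ΔP.  The Bond
number (ρ_FC40 − ρ_med) g a²/γ ≈ 1.8 for a 3 mm chamber.

**Equilibration and the no-backflow seeding rule.**  Unequal filling
drives flow dV_R/dt = −ΔP/R_h through the conduit (lubrication
resistance R_h = 12μL/(w h_c³(1 − 0.63 h_c/w))).  Filling 4 µl into one
chamber before 1 µl of cells into the other guarantees flow away from
the cells until equilibrium, so they stay where deposited.

**Conduit solute gradients.**  With equal volumes, transport is purely
diffusive: a finite-volume conduit coupled to two well-mixed chambers,
driven by the culture media-change schedule, propagated by a matrix
exponential (mass conserved to roundoff).  Used to bound the BDNF
exposure of the cell-body chamber when the distal chamber carries
10× BDNF medium.

**Outgrowth and regrowth metrics.**  From binary coverage masks:
conduit covered area, outgrowth index (A_d20 − A_d0)/A_d0, per-batch
fold differences, the 200 × 300 µm regeneration zone abutting the
proximal damage line, regrowth fractions normalised to pre-axotomy
coverage, and the incomplete-severing exclusion rule.

**Array layout and axotomy toolpath.**  The 7 × 3 dumbbell array in a
6 cm dish, the enlarged rebuilt dumbbells printed around damaged ones,
and the serpentine jet toolpath that severs all 21 conduits in well
under 90 s at 960 mm/min.

**Synthetic data.**  Deterministic generators (side-view drop images
with a 210 µm needle as scale reference, random-walk neurite mask
series, axotomy/regrowth series, protocol schedules) with ground-truth
tables, so the whole pipeline is testable with no experimental data.

## Worked example

```python
import fluidwalls as fw
from fluidwalls import units
from fluidwalls.equilibration import (
    DepositionEvent, simulate_equilibration, assert_no_backflow,
    time_to_equilibration,
)
from fluidwalls.transport import SoluteSpec, simulate_gradient, max_chamber_concentration
from fluidwalls.synthetic.protocols import bdnf_exposure_schedule

fluids = fw.FluidProperties()
dumbbell = fw.default_dumbbell()   # 3 mm chambers, 1 mm x 200 um x 10 um conduit

# seeding protocol: 4 ul medium right, then 1 ul cell suspension left
events = [DepositionEvent(0.0, "right", 4.0, "medium"),
          DepositionEvent(0.0, "left", 1.0, "cells")]
traj = simulate_equilibration(dumbbell, fluids, events, duration_s=24 * 3600)
print(f"initial dP = {traj.deltaP_pa[0]:.2f} Pa")
print(f"no rightward flow: {assert_no_backflow(traj, 'left').ok}")
print(f"90% equilibrated after {time_to_equilibration(traj) / 3600:.1f} h")

# 20-day distal-BDNF culture: how much BDNF reaches the cell bodies?
c_left, c_right, schedule = bdnf_exposure_schedule("CNs-BDNF", 0, 20)
solute = SoluteSpec("BDNF", 1.0e-10, c_left, c_right)
profile = simulate_gradient(dumbbell, solute, schedule, units.days_to_s(20))
print(f"max CN-chamber BDNF: {max_chamber_concentration(profile, 'left'):.2f} ng/ml")
```

prints

```
initial dP = 3.13 Pa
no rightward flow: True
90% equilibrated after 17.0 h
max CN-chamber BDNF: 11.42 ng/ml
```

The 3.13 Pa excess pressure in the fuller chamber drives leftward
conduit flow that never reverses, so cells seeded on the left stay
there; volumes near-equalise on the day timescale.  Over 20 days of
culture with 100 ng/ml BDNF in the distal chamber, diffusion through
the conduit raises the cell-body chamber only ~1.4 ng/ml above its
10 ng/ml baseline — distal BDNF enrichment barely reaches the somas.

A CLI wraps the same functions:

```sh
fluidwalls --out-dir out layout                  # array + toolpath CSVs
fluidwalls --out-dir out simulate-gradient       # BDNF chamber series
fluidwalls --out-dir out synth --what neurites   # synthetic mask series
```

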