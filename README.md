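# chondrosim

Mechanobiochemical simulation of articular-cartilage impact injury and
antioxidant treatment. The package chains three stages:

1. **Impact mechanics** — an axisymmetric poroelastic finite-element solve of
   a drop-tower impact (half-sine force, peak 4000 N over 1 ms) on a
   cartilage disc modeled as a fibril-reinforced poroviscoelastic swelling
   continuum (Neo-Hookean ground matrix, tension-only viscoelastic collagen
   fibrils in a Benninghoff arcade architecture, Darcy flow with
   deformation-dependent permeability, Donnan osmotic swelling from the
   fixed charge density of the proteoglycans).
2. **Cell damage** — the peak maximum shear strain γ_max, taken from the
   Green–Lagrange strain tensor at peak force, is mapped to an initial
   damaged-chondrocyte fraction by a two-threshold damage function
   (initiation ε_init = 40 %, saturation ε_max = 150 %):
   f_dmg(ε) = (ε_max/ε)·(ε − ε_init)/(ε_max − ε_init) between the thresholds.
3. **Biokinetics** — reaction–diffusion evolution of healthy / damaged /
   dead cells, a proteolytic-enzyme stimulus S with
   dS/dt = α_aga(k_aga·C_dmg − S), Michaelis–Menten proteoglycan
   degradation, and diffusion of the antioxidant N-acetylcysteine (NAC)
   from a 2 mM bath applied with a configurable delay. Damaged cells die at
   rate k_death = 6.9·10⁻⁵ s⁻¹ and recover at rate k_rec·C_NAC with
   k_rec = 0.53·10⁻⁴ m³ mol⁻¹ s⁻¹.

It is written for researchers in cartilage mechanobiology and post-traumatic
osteoarthritis who want to explore how treatment timing, dosage, and cell-level
rate constants shape cell viability and proteoglycan loss after an impact.

## Worked example

Evolve the reference injury (56 % of superficial-zone cells damaged) under a
2 mM NAC bath applied after different delays, and report superficial-zone
viability two days after impact:

```python
from chondrosim.fixtures import FixtureSpec, paper_like_strain_field
from chondrosim.scenarios import ScenarioConfig, run_delay_sweep, superficial_damage

field = paper_like_strain_field(FixtureSpec())   # reference synthetic strain field
cfg = ScenarioConfig()
print("superficial damaged fraction:", round(superficial_damage(field, cfg), 3))
print(run_delay_sweep(field, cfg, delays_h=(0, 1, 4, 12)).table.round(3))
```

prints

```
superficial damaged fraction: 0.56
 delay_h  viability
       0      0.779
       1      0.704
       4      0.565
      12      0.457
```

i.e. immediate treatment preserves 78 % of cells at 48 h, while a 12-h delay
leaves only 46 % — the damaged pool has already drained into the dead pool
before the antioxidant arrives. Each viability is the volume-weighted mean of
(healthy + damaged)/total over the top 200 µm of the impacted core.

The same pipeline is available from the shell:

```bash
chondrosim fixture --out field.csv          # synthetic strain field
chondrosim impact  --out field.csv          # ... or run the FE impact stage
chondrosim kinetics --strain field.csv --delay-h 0,1,4,12 --out out/
chondrosim sweep --out out/                 # sensitivity grid
```

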