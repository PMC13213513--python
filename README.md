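# preorg — solution-phase preorganization analysis of crystal growth modifiers

Some additives speed up crystal growth not by acting at the crystal surface
but *in solution*: a planar "imposter" molecule that resembles the
crystallizing solute can template neighboring solute molecules into dimer
conformations that are already compatible with the crystal lattice, so they
incorporate faster.  The canonical example is the urate monoanion (HU⁻, the
building block of ammonium urate kidney stones) around riboflavin-like
modifiers.  `preorg` is a Python library for quantifying this mechanism from
molecular configuration ensembles (e.g. MD trajectories) — and, because such
trajectories are cluster-scale objects, it ships a seeded synthetic-ensemble
generator with the same statistical structure so every stage of the analysis
runs and is testable at desk scale.

## The framework

A pair of planar solute molecules is reduced to three parameters:

* **r** — distance between the two ring centroids (Å);
* **ψ** — planarity angle between the centroid-separation vector and the
  reference molecule's ring-plane normal: ψ ≈ 0 or π for face-to-face
  π-stacks, ψ ≈ π/2 when the two molecules lie in one plane;
* **θ** — angle between the two molecules' intramolecular reference vectors
  (0 = parallel, π = antiparallel).

In solution, dimers are dominated by ~4 Å **antiparallel** stacks; the
crystal instead contains **parallel** stacks plus coplanar hydrogen-bonded
neighbors (contact < 2.5 Å) — so solution stacking is crystallographically
incongruent, and the growth-relevant question is whether a modifier enriches
the *coplanar* population.  The pipeline answers it with:

* **population maps** — (r, θ, ψ) histograms of dimers near the modifier
  (both members within 4 Å) vs the bulk, differential probability maps and
  −ln p free-energy maps;
* **crystal fingerprints** — (r, θ, ψ) target boxes extracted from an
  idealized lattice; the fraction of dimers inside them, near vs bulk, gives
  the *conforming-dimer enrichment* used to rank modifiers;
* **SDF analysis** — frames aligned on the modifier ring system
  (proper-rotation Kabsch fit), solute occupancy grids, and 26-connected
  isosurface components at an occupancy threshold (0.4 by default);
* **contact analysis** — modifier-hydrogen vs solute-acceptor contact
  frequencies (cutoff 2.5 Å), conditional dimer splits by side-chain contact,
  and per-pair hydrogen-bond mode timelines.

## A worked example

```python
import numpy as np
from preorg import (EnsembleSpec, make_templated_ensemble, modifier_template,
                    make_crystal_lattice, extract_fingerprints,
                    select_populations, conforming_probability,
                    histogram3d, psi_marginal, band_mass)

spec = EnsembleSpec(n_frames=150, n_solutes=12, templating_strength=5.0, seed=2)
ens = make_templated_ensemble(spec, modifier_template(3))   # large modifier
near, bulk = select_populations(ens)                        # 4 A near rule

lo, hi = np.pi/2 - np.pi/9, np.pi/2 + np.pi/9
print(band_mass(psi_marginal(histogram3d(near)), lo, hi))   # 0.725
print(band_mass(psi_marginal(histogram3d(bulk)), lo, hi))   # 0.287

fps = extract_fingerprints(make_crystal_lattice((2, 2, 2)))
print(conforming_probability(near, bulk, fps).enrichment)   # 2.49
```

Next to the modifier, 72.5% of dimers sit in the coplanar ψ-band versus
28.7% in the bulk, and a dimer near the modifier is 2.5× more likely to fall
inside a crystal coplanar fingerprint — the quantitative signature of
solution-phase preorganization.  The scripts in `examples/` walk through each
capability (generation and file I/O, dimer geometry, differential maps,
fingerprint ranking, SDF/contacts) and print the numbers they compute.

A thin CLI wraps the same library for config-file driven runs:

```bash
preorg generate run.yaml --out run        # synthetic ensemble -> XYZ + sidecar
preorg analyze run.yaml --out results/    # full pipeline -> tables, grids, report
preorg fingerprint --cells 2 2 2 --out fingerprints.yaml
preorg compare a.yaml b.yaml c.yaml       # enrichment ranking across modifiers
```

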