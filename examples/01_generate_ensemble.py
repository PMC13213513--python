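"""Generate a synthetic solution ensemble and write it to disk.

Builds a small bulk ensemble (no modifier) with the default study conditions
— 30% coplanar hydrogen-bonded dimers, 70% pi-stacked at ~4 Angstrom with an
80% antiparallel preference — and writes a multi-frame XYZ file plus the
topology sidecar that maps atoms back onto molecules and roles.
"""

from pathlib import Path

from preorg import EnsembleSpec, Topology, make_bulk_ensemble, write_ensemble, write_topology

out = Path("scratch")
out.mkdir(exist_ok=True)

spec = EnsembleSpec(n_frames=20, n_solutes=10, seed=1)
ens = make_bulk_ensemble(spec)
write_ensemble(ens, out / "bulk.xyz")
write_topology(Topology.from_ensemble(ens), out / "bulk.topology.yaml")

n_atoms = sum(len(m.atoms) for m in ens.frames[0].molecules)
print(f"frames generated:    {ens.n_frames}")
print(f"molecules per frame: {len(ens.frames[0].molecules)}")
print(f"atoms per frame:     {n_atoms}")
print(f"files: {out / 'bulk.xyz'} + {out / 'bulk.topology.yaml'}")
print()
print("Each frame holds 5 solute pairs; about 30% are coplanar hydrogen-bonded")
print("and the rest are ~4 Angstrom stacks, the statistics the analysis below")
print("is designed to recover.")
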