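"""Modifier-aligned SDF, isosurface components, contacts and H-bond dynamics.

Aligns all frames on the modifier ring system, builds the solute occupancy
grid, reports the templating region at the 0.4 occupancy level, prints the
hydrogen/acceptor contact-frequency table, splits near dimers by side-chain
(H13) contact, and follows one pair's hydrogen-bond mode over time.
"""

from preorg import (
    EnsembleSpec,
    align_frames,
    conditional_dimer_split,
    contact_frequency,
    hbond_mode_timeline,
    isosurface_components,
    make_templated_ensemble,
    modifier_template,
    sdf,
    select_populations,
)

spec = EnsembleSpec(n_frames=150, n_solutes=8, templating_strength=5.0, seed=6)
ens = make_templated_ensemble(spec, modifier_template(3))

aligned, rmsd = align_frames(ens)
print(f"post-alignment modifier ring RMSD, worst frame: {rmsd.max():.2e} A")

grid = sdf(aligned, spacing=1.5, radius=12.0)
for level in (0.4, 0.2):
    comps = isosurface_components(grid, level)
    if comps:
        c = comps[0]
        print(
            f"occupancy >= {level}: largest region {c.voxel_count} voxels, "
            f"extent {tuple(round(e, 1) for e in c.extent)} A, volume {c.volume:.0f} A^3"
        )
    else:
        print(f"occupancy >= {level}: no region")

print("\ncontact frequency (fraction of frames with min distance <= 2.5 A):")
print(contact_frequency(ens, r_cut=2.5).round(2).to_string())

near, _ = select_populations(ens)
touching, rest = conditional_dimer_split(ens, near, "H13")
print(f"\nnear dimers contacting the side-chain H13: {len(touching)} / {len(near)}")

labels, transitions = hbond_mode_timeline(ens, (0, 1))
print(f"hydrogen-bond modes of the tracked near pair: {len(set(labels))} distinct,")
print(f"{transitions} transitions over {len(labels)} frames — templated hydrogen")
print("bonding stays dynamic rather than locking into one arrangement.")
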