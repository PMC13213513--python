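"""Alignment, SDF occupancy, isosurface components and contact analysis."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from preorg import synthetic as syn
from preorg.errors import SelectionError, TopologyError
from preorg.maps import select_populations
from preorg.model import Ensemble, Frame
from preorg.sdf import (
    SDFGrid,
    align_frames,
    conditional_dimer_split,
    contact_frequency,
    hbond_mode_timeline,
    isosurface_components,
    kabsch,
    sdf,
)


def _modifier_frame(make_solute, solute_positions, frame_index=0, rigid=None):
    """A frame with one size-2 modifier at the origin and solutes at given spots."""
    mols = [make_solute(np.eye(3), p, i) for i, p in enumerate(solute_positions)]
    mols.append(syn.modifier_template(2).template.instantiate(np.eye(3), (0.0, 0.0, 0.0), 99))
    if rigid is not None:
        rot, trans = rigid
        mols = [m.transformed(rot, trans) for m in mols]
    return Frame(molecules=mols, frame_index=frame_index)


@pytest.fixture
def rigid_ensemble(make_solute):
    """Frames that are exact rigid motions of frame 0."""
    rng = np.random.default_rng(4)
    frames = [_modifier_frame(make_solute, [(0, 0, 3.4), (6.4, 0, 3.4)])]
    for i in range(1, 10):
        q = rng.standard_normal(4)
        rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        frames.append(
            _modifier_frame(
                make_solute, [(0, 0, 3.4), (6.4, 0, 3.4)], frame_index=i,
                rigid=(rot, rng.uniform(-15, 15, 3)),
            )
        )
    return Ensemble(frames=frames)


class TestAlignment:
    def test_rigid_motions_realign_exactly(self, rigid_ensemble):
        _, rmsd = align_frames(rigid_ensemble)
        assert rmsd.max() < 1e-9

    def test_self_alignment_is_identity(self, make_solute):
        frame = _modifier_frame(make_solute, [(0, 0, 3.4)])
        ens = Ensemble(frames=[frame])
        aligned, rmsd = align_frames(ens)
        assert rmsd[0] < 1e-12
        assert np.allclose(
            aligned.frames[0].molecules[0].positions, frame.molecules[0].positions
        )

    def test_internal_distances_preserved(self, templated_small):
        aligned, _ = align_frames(templated_small)
        for f0, f1 in zip(templated_small.frames[:20], aligned.frames[:20]):
            p0 = np.vstack([m.positions for m in f0.molecules])
            p1 = np.vstack([m.positions for m in f1.molecules])
            d0 = np.linalg.norm(p0[:50, None] - p0[None, :50], axis=-1)
            d1 = np.linalg.norm(p1[:50, None] - p1[None, :50], axis=-1)
            assert np.abs(d0 - d1).max() < 1e-9

    def test_kabsch_returns_proper_rotation(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-3, 3, (8, 3))
        q = rng.standard_normal(4)
        rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        est_rot, est_t = kabsch(pts @ rot.T + 2.0, pts)
        assert np.linalg.det(est_rot) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(est_rot @ (pts @ rot.T + 2.0).T + est_t[:, None], pts.T, atol=1e-9)

    def test_modifier_required(self, bulk_small):
        with pytest.raises(SelectionError):
            align_frames(bulk_small)


class TestSDF:
    def test_fixed_atom_gives_single_full_voxel(self, make_solute):
        frames = [
            _modifier_frame(make_solute, [(20.0, 0.1, 0.1)], frame_index=i)
            for i in range(5)
        ]
        # solute far outside except one atom? keep the whole solute fixed:
        # every voxel it touches has occupancy 1; voxels elsewhere 0
        ens = Ensemble(frames=frames)
        grid = sdf(ens, spacing=0.5, radius=8.0)
        assert set(np.unique(grid.occupancy)) <= {0.0, 1.0}

    def test_point_solute_single_voxel(self, make_solute):
        # a degenerate one-atom "solute" is not constructible from the
        # template; instead check that a fixed template contributes exactly
        # the same voxel set in every frame and that one marked voxel holds 1.0
        frames = [
            _modifier_frame(make_solute, [(3.0, 0.2, 3.4)], frame_index=i)
            for i in range(4)
        ]
        grid = sdf(Ensemble(frames=frames), spacing=0.5, radius=6.0)
        assert grid.occupancy.max() == 1.0
        n_hit = int((grid.occupancy == 1.0).sum())
        assert n_hit > 0
        assert int((grid.occupancy > 0).sum()) == n_hit  # no partial voxels

    def test_empty_region_all_zero(self, make_solute):
        frames = [_modifier_frame(make_solute, [(40.0, 0, 0)], frame_index=i) for i in range(3)]
        grid = sdf(Ensemble(frames=frames), spacing=1.0, radius=5.0)
        assert np.all(grid.occupancy == 0.0)

    def test_brute_force_equivalence(self, templated_small):
        sub = Ensemble(frames=templated_small.frames[:20], metadata={})
        aligned, _ = align_frames(sub)
        grid = sdf(aligned, spacing=1.0, radius=10.0)
        ref = np.zeros(grid.dims)
        for frame in aligned:
            seen = set()
            for m in frame.solutes:
                for p in m.heavy_positions:
                    idx = tuple(np.floor((p - grid.origin) / grid.spacing).astype(int))
                    if all(0 <= k < d for k, d in zip(idx, grid.dims)):
                        seen.add(idx)
            for idx in seen:
                ref[idx] += 1
        assert np.array_equal(grid.occupancy, ref / len(aligned.frames))

    def test_bad_spacing(self, rigid_ensemble):
        with pytest.raises(ValueError):
            sdf(rigid_ensemble, spacing=0.0)


class TestIsosurfaceComponents:
    def _grid(self, occ):
        return SDFGrid(origin=np.zeros(3), spacing=0.5, dims=occ.shape, occupancy=occ)

    def test_single_voxel(self):
        occ = np.zeros((5, 5, 5))
        occ[2, 2, 2] = 0.9
        comps = isosurface_components(self._grid(occ), 0.4)
        assert len(comps) == 1
        assert comps[0].voxel_count == 1
        assert comps[0].volume == pytest.approx(0.5**3)

    def test_corner_sharing_voxels_connect(self):
        occ = np.zeros((5, 5, 5))
        occ[1, 1, 1] = occ[2, 2, 2] = 1.0  # share only a corner
        comps = isosurface_components(self._grid(occ), 0.4)
        assert len(comps) == 1
        assert comps[0].voxel_count == 2

    def test_disjoint_regions_separate(self):
        occ = np.zeros((7, 7, 7))
        occ[0, 0, 0] = occ[5, 5, 5] = 1.0
        comps = isosurface_components(self._grid(occ), 0.4)
        assert len(comps) == 2

    def test_empty_result_allowed(self):
        comps = isosurface_components(self._grid(np.zeros((3, 3, 3))), 0.4)
        assert comps == []


class TestContacts:
    def test_constructed_contact_is_certain(self, make_solute):
        # solute O2 acceptor placed 2.4 Angstrom from the modifier's H13
        mod = syn.modifier_template(2)
        h13 = mod.template.position_of("H13")
        o2_local = syn.solute_template().position_of("O2")
        target = h13 + np.array([0.0, 0.0, 2.4])
        frames = [
            _modifier_frame(make_solute, [tuple(target - o2_local)], frame_index=i)
            for i in range(6)
        ]
        tab = contact_frequency(Ensemble(frames=frames), r_cut=2.5)
        assert tab.loc["H13", "O2"] == 1.0

    def test_distant_solutes_never_contact(self, make_solute):
        frames = [_modifier_frame(make_solute, [(30, 0, 0)], frame_index=i) for i in range(3)]
        tab = contact_frequency(Ensemble(frames=frames), r_cut=2.5)
        assert (tab.values == 0).all()

    def test_brute_force_equivalence(self, templated_small):
        sub = Ensemble(frames=templated_small.frames[:20], metadata={})
        tab = contact_frequency(sub, r_cut=2.5)
        mod_spec = sub.frames[0].modifier.spec
        acc_names = sub.frames[0].solutes[0].spec.acceptor_atoms
        for h in mod_spec.hydrogen_atoms:
            for a in acc_names:
                hits = 0
                for frame in sub:
                    hp = frame.modifier.atom_position(h)
                    dmin = min(
                        np.linalg.norm(s.atom_position(a) - hp) for s in frame.solutes
                    )
                    hits += dmin <= 2.5
                assert tab.loc[h, a] == pytest.approx(hits / len(sub.frames))

    def test_monotone_in_cutoff(self, templated_small):
        sub = Ensemble(frames=templated_small.frames[:15], metadata={})
        t1 = contact_frequency(sub, r_cut=2.5)
        t2 = contact_frequency(sub, r_cut=4.0)
        assert (t2.values >= t1.values).all()


class TestConditionalSplit:
    def test_partition_and_contact_rule(self, templated_small):
        near, _ = select_populations(templated_small)
        contacting, rest = conditional_dimer_split(templated_small, near, "H13", r_cut=2.5)
        assert len(contacting) + len(rest) == len(near)
        # verify the rule on both sides
        by_index = {f.frame_index: f for f in templated_small.frames}
        for subset, expected in ((contacting, True), (rest, False)):
            for g, _ in subset[:20]:
                frame = by_index[g.frame_index]
                h = frame.modifier.atom_position("H13")
                dmin = min(
                    np.linalg.norm(frame.molecule(mid).acceptor_positions - h, axis=-1).min()
                    for mid in g.pair_ids
                )
                assert bool(dmin <= 2.5) is expected

    def test_unknown_label_rejected(self, templated_small):
        near, _ = select_populations(templated_small)
        with pytest.raises(TopologyError):
            conditional_dimer_split(templated_small, near, "H99")


class TestHbondTimeline:
    def _static_pair_frames(self, make_solute, n, flip_every=None):
        _, t = syn.coplanar_pair_transform(syn.COPLANAR_MODES[0])
        frames = []
        for i in range(n):
            if flip_every and (i // flip_every) % 2 == 1:
                _, t_i = syn.coplanar_pair_transform(syn.COPLANAR_MODES[1])
            else:
                t_i = t
            mols = [
                make_solute(np.eye(3), (0, 0, 0), 0),
                make_solute(np.eye(3), t_i, 1),
            ]
            frames.append(Frame(molecules=mols, frame_index=i))
        return Ensemble(frames=frames)

    def test_static_geometry_zero_transitions(self, make_solute):
        ens = self._static_pair_frames(make_solute, 10)
        labels, transitions = hbond_mode_timeline(ens, (0, 1))
        assert transitions == 0
        assert len(set(labels)) == 1 and labels[0] != "none"

    def test_alternating_modes(self, make_solute):
        ens = self._static_pair_frames(make_solute, 10, flip_every=1)
        _, transitions = hbond_mode_timeline(ens, (0, 1))
        assert transitions == 9

    def test_scheduled_switches(self, make_solute):
        k, n = 3, 12
        ens = self._static_pair_frames(make_solute, n, flip_every=k)
        _, transitions = hbond_mode_timeline(ens, (0, 1))
        assert transitions == (n - 1) // k

    def test_missing_pair_rejected(self, make_solute):
        ens = self._static_pair_frames(make_solute, 3)
        with pytest.raises(SelectionError):
            hbond_mode_timeline(ens, (0, 7))
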