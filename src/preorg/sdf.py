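"""Modifier-aligned spatial distribution functions and contact analysis.

All frames are first superposed on the modifier's (rigid) ring system with a
proper-rotation Kabsch fit; the spatial distribution function (SDF) is then a
regular voxel grid around the modifier whose value in each voxel is the
fraction of frames in which *any* solute heavy atom visits the voxel — a
dimensionless occupancy in [0, 1], thresholded (typically at 0.4) to define
the templating region.  Contact analysis reports, per modifier hydrogen and
solute acceptor type, the fraction of frames with a minimum distance under a
cutoff (2.5 Angstrom by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, SelectionError, TopologyError
from .geometry import DimerGeometry, HBOND_CUTOFF
from .model import Ensemble, Frame, PlanarMolecule, minimum_image

__all__ = [
    "SDFGrid",
    "IsosurfaceComponent",
    "kabsch",
    "align_frames",
    "sdf",
    "isosurface_components",
    "contact_frequency",
    "conditional_dimer_split",
    "hbond_mode_timeline",
]


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper-rotation least-squares superposition of ``mobile`` onto
    ``reference`` (both (n, 3)); returns (rotation, translation) such that
    ``rotation @ x + translation`` is optimally superposed."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    if np.linalg.det(rot) < 0:
        raise GeometryError("superposition requires a reflection; fit rejected")
    return rot, rc - rot @ mc


def align_frames(ens: Ensemble) -> tuple[Ensemble, np.ndarray]:
    """Superpose every frame's modifier ring atoms onto frame 0's.

    Returns the rigidly transformed ensemble (boxes dropped: an aligned
    ensemble is no longer periodic) and the per-frame post-alignment modifier
    ring RMSD in Angstrom.
    """
    if not ens.frames:
        raise SelectionError("cannot align an empty ensemble")
    mods = [f.modifier for f in ens.frames]
    if any(m is None for m in mods):
        raise SelectionError("alignment requires one modifier in every frame")
    ref = mods[0].ring_positions
    frames = []
    rmsd = np.empty(len(ens.frames))
    for i, frame in enumerate(ens.frames):
        rot, trans = kabsch(mods[i].ring_positions, ref)
        mols = [m.transformed(rot, trans) for m in frame.molecules]
        moved = mols[[m.molecule_id for m in frame.molecules].index(mods[i].molecule_id)]
        delta = moved.ring_positions - ref
        rmsd[i] = np.sqrt(np.mean(np.sum(delta * delta, axis=1)))
        frames.append(
            Frame(molecules=mols, box=None, frame_index=frame.frame_index, time=frame.time)
        )
    aligned = Ensemble(frames=frames, metadata={**ens.metadata, "aligned": True})
    return aligned, rmsd


@dataclass
class SDFGrid:
    """Regular occupancy grid: ``occupancy[i, j, k]`` covers the voxel
    ``origin + spacing * [i, j, k]`` to ``origin + spacing * [i+1, j+1, k+1]``."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    occupancy: np.ndarray
    reference: np.ndarray | None = None  # aligned modifier coordinates

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != tuple(self.dims):
            raise ValueError("occupancy shape does not match dims")

    def voxel_center(self, index: tuple[int, int, int]) -> np.ndarray:
        return self.origin + self.spacing * (np.asarray(index, dtype=float) + 0.5)


def sdf(aligned: Ensemble, spacing: float = 0.5, radius: float = 12.0) -> SDFGrid:
    """Solute heavy-atom occupancy around the aligned modifier.

    The cubic grid is centered on the frame-0 modifier centroid with
    half-width ``radius``; each voxel's occupancy is the fraction of frames in
    which at least one solute heavy atom falls inside it.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if not aligned.frames:
        raise SelectionError("empty ensemble")
    mod = aligned.frames[0].modifier
    if mod is None:
        raise SelectionError("SDF requires a modifier")
    center = mod.heavy_positions.mean(axis=0)
    n = int(np.ceil(2.0 * radius / spacing))
    origin = center - spacing * n / 2.0
    hits = np.zeros((n, n, n), dtype=np.int64)
    for frame in aligned:
        pts = [m.heavy_positions for m in frame.solutes]
        if not pts:
            continue
        pos = np.vstack(pts)
        idx = np.floor((pos - origin) / spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < n), axis=1)
        if not np.any(ok):
            continue
        uniq = np.unique(idx[ok], axis=0)
        hits[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    return SDFGrid(
        origin=origin,
        spacing=spacing,
        dims=(n, n, n),
        occupancy=hits / len(aligned.frames),
        reference=mod.positions,
    )


@dataclass(frozen=True)
class IsosurfaceComponent:
    """One 26-connected super-threshold region of the SDF."""

    voxel_count: int
    extent: tuple[float, float, float]  # bounding-box edge lengths, Angstrom
    volume: float  # voxel_count * spacing^3, Angstrom^3

    @property
    def max_extent(self) -> float:
        return max(self.extent)


def isosurface_components(grid: SDFGrid, level: float = 0.4) -> list[IsosurfaceComponent]:
    """26-connected components of voxels with occupancy >= ``level``,
    sorted by voxel count (largest first).  An empty list is a valid result."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    mask = grid.occupancy >= level
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    comps = []
    for k in range(1, n + 1):
        where = np.argwhere(labels == k)
        span = where.max(axis=0) - where.min(axis=0) + 1
        comps.append(
            IsosurfaceComponent(
                voxel_count=int(len(where)),
                extent=tuple(float(s * grid.spacing) for s in span),
                volume=float(len(where)) * grid.spacing**3,
            )
        )
    comps.sort(key=lambda c: c.voxel_count, reverse=True)
    return comps


def hosts_two_footprints(grid: SDFGrid, level: float, footprint: float) -> bool:
    """Whether the largest super-threshold component could host two solute
    footprints side by side (its largest bounding extent covers two in-plane
    solute diameters)."""
    comps = isosurface_components(grid, level)
    return bool(comps) and comps[0].max_extent >= 2.0 * footprint


# -- contact analysis ---------------------------------------------------------


def contact_frequency(
    ens: Ensemble, r_cut: float = HBOND_CUTOFF, per_copy: bool = False
) -> pd.DataFrame:
    """Modifier-hydrogen vs solute-acceptor contact frequency table.

    Default convention: a (hydrogen, acceptor-label) cell counts the fraction
    of frames in which the *minimum over all solute copies* of that distance
    is <= ``r_cut``.  With ``per_copy=True`` the cell instead averages, over
    frames, the fraction of solute copies in contact.
    """
    first = ens.frames[0]
    mod = first.modifier
    if mod is None:
        raise SelectionError("contact analysis requires a modifier")
    hydrogens = mod.spec.hydrogen_atoms
    solutes = first.solutes
    if not solutes:
        raise SelectionError("contact analysis requires solutes")
    acceptors = solutes[0].spec.acceptor_atoms
    if not hydrogens or not acceptors:
        raise TopologyError("modifier hydrogens and solute acceptors must be labeled")
    freq = np.zeros((len(hydrogens), len(acceptors)))
    for frame in ens:
        mod = frame.modifier
        h_pos = np.array([mod.atom_position(h) for h in hydrogens])
        # acceptor positions per label, stacked over solute copies
        acc_pos = np.array(
            [[s.atom_position(a) for a in acceptors] for s in frame.solutes]
        )  # (n_solutes, n_acc, 3)
        d = minimum_image(
            h_pos[:, None, None, :] - acc_pos[None, :, :, :], frame.box
        )
        dist = np.linalg.norm(d, axis=-1)  # (n_h, n_solutes, n_acc)
        if per_copy:
            freq += (dist <= r_cut).mean(axis=1)
        else:
            freq += (dist.min(axis=1) <= r_cut).astype(float)
    return pd.DataFrame(freq / len(ens.frames), index=list(hydrogens), columns=list(acceptors))


def conditional_dimer_split(
    ens: Ensemble,
    near_dimers: list[tuple[DimerGeometry, str]] | list[DimerGeometry],
    hydrogen_label: str,
    r_cut: float = HBOND_CUTOFF,
):
    """Partition near-modifier dimers by contact with one modifier hydrogen.

    A dimer is *contacting* when, in its frame, either member has an acceptor
    atom within ``r_cut`` of the named modifier hydrogen.  Returns
    ``(contacting, non_contacting)``; the two lists partition the input.
    """
    mod0 = ens.frames[0].modifier
    if mod0 is None:
        raise SelectionError("conditional split requires a modifier")
    if hydrogen_label not in mod0.spec.hydrogen_atoms:
        raise TopologyError(
            f"modifier has no hydrogen labeled {hydrogen_label!r}"
        )
    by_index = {f.frame_index: f for f in ens.frames}
    contacting, non_contacting = [], []
    for item in near_dimers:
        g = item[0] if isinstance(item, tuple) else item
        frame = by_index[g.frame_index]
        h = frame.modifier.atom_position(hydrogen_label)
        touch = False
        for mid in g.pair_ids:
            acc = frame.molecule(mid).acceptor_positions
            d = np.linalg.norm(minimum_image(acc - h, frame.box), axis=-1)
            if np.min(d) <= r_cut:
                touch = True
                break
        (contacting if touch else non_contacting).append(item)
    return contacting, non_contacting


def hbond_mode_timeline(
    ens: Ensemble, pair_ids: tuple[int, int], r_cut: float = HBOND_CUTOFF
) -> tuple[list[str], int]:
    """Hydrogen-bond mode label per frame for one tracked solute pair.

    The label is the sorted set of (donor-hydrogen, acceptor) name pairs
    within ``r_cut`` between the two molecules (both directions), or ``none``;
    the transition count is the number of consecutive-frame label changes —
    a direct measure of how dynamic the pair's hydrogen bonding is.
    """
    labels: list[str] = []
    for frame in ens:
        try:
            a = frame.molecule(pair_ids[0])
            b = frame.molecule(pair_ids[1])
        except KeyError as exc:
            raise SelectionError(str(exc)) from exc
        bonds = []
        for donor, acceptor, tag in ((a, b, "ab"), (b, a, "ba")):
            for hname in donor.spec.hydrogen_atoms:
                hp = donor.atom_position(hname)
                for aname in acceptor.spec.acceptor_atoms:
                    d = np.linalg.norm(
                        minimum_image(acceptor.atom_position(aname) - hp, frame.box)
                    )
                    if d <= r_cut:
                        bonds.append(f"{tag}:{hname}-{aname}")
        labels.append("+".join(sorted(bonds)) if bonds else "none")
    transitions = sum(1 for x, y in zip(labels, labels[1:]) if x != y)
    return labels, transitions
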