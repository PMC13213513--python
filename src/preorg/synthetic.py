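"""Synthetic configuration ensembles with controlled dimer statistics.

The generator emulates the statistical structure of a solution of planar
aromatic solutes around one planar modifier molecule:

* bulk solute dimers dominated by ~4 Angstrom face-to-face stacking
  (planarity angle psi near 0/pi, mostly antiparallel),
* a minority coplanar population held together by an in-plane hydrogen bond
  (psi near pi/2, hydrogen-acceptor contact below 2.5 Angstrom),
* a near-modifier population whose coplanar fraction grows with a
  *templating strength* parameter and is capped by the modifier's in-plane
  extent (a small aromatic core cannot host two solute footprints side by
  side).

The solute is an idealized planar molecule — a hexagonal ring with four
labeled acceptor sites (N3, O2, O6, O8) and two donor hydrogens — because the
downstream analysis depends only on planarity, a reference vector, and labeled
donor/acceptor sites.  The coplanar hydrogen-bond construction is shared
between the pair generator and the idealized crystal lattice, so generated
coplanar dimers and crystal fingerprints agree by construction rather than by
coincidence.

All randomness flows from one integer seed through per-frame child streams of
a ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import PlacementError
from .geometry import HBOND_CUTOFF
from .model import AtomRecord, Ensemble, Frame, MoleculeSpec, PlanarMolecule, minimum_image

__all__ = [
    "MoleculeTemplate",
    "ModifierTemplate",
    "EnsembleSpec",
    "CoplanarMode",
    "COPLANAR_MODES",
    "HBOND_TARGET",
    "solute_template",
    "modifier_template",
    "coplanar_pair_transform",
    "coplanar_fraction_near",
    "make_bulk_ensemble",
    "make_templated_ensemble",
    "CrystalMotif",
    "make_crystal_lattice",
]

# geometry constants of the idealized molecules (Angstrom)
RING_RADIUS = 1.4
ACCEPTOR_RADIUS = 2.4
HYDROGEN_RADIUS = 2.3
#: generated hydrogen-bond contact distance; must stay below HBOND_CUTOFF
HBOND_TARGET = 1.9
#: hard-sphere heavy-atom overlap cutoff for placement rejection
OVERLAP_CUTOFF = 1.5
#: minimum distance between pair midpoints so that enumerated dimers are
#: exactly the generated pairs (no cross-pair neighbours within 8 Angstrom)
PAIR_EXCLUSION = 16.0
#: minimum pair-midpoint distance from the modifier for "far" (bulk-like) pairs
FAR_FROM_MODIFIER = 23.0
# anchored near-modifier pose parameters
NEAR_LAYER_HEIGHT = 3.4     # first coplanar layer above the modifier plane
NEAR_STACK_HEIGHT = 5.4     # centroid height of edge-on stacked near pairs
NEAR_ANCHOR_FRAC = 0.4      # anchor offset along the modifier axis, x extent
ANCHOR_POS_JITTER = 0.1     # Angstrom, per coordinate
ANCHOR_YAW_JITTER = 0.03    # radians


def _rotz(angle: float) -> np.ndarray:
    return Rotation.from_rotvec([0.0, 0.0, angle]).as_matrix()


def _rot_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12 or angle == 0.0:
        return np.eye(3)
    return Rotation.from_rotvec(axis / n * angle).as_matrix()


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


# -- templates ----------------------------------------------------------------


@dataclass(frozen=True)
class MoleculeTemplate:
    """A rigid planar molecule layout: names, elements, local coordinates.

    Local coordinates put the ring centroid at the origin with the molecular
    plane at z = 0 and the reference vector along +x.
    """

    spec: MoleculeSpec
    names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray

    def instantiate(
        self, rotation: np.ndarray, translation: np.ndarray, molecule_id: int
    ) -> PlanarMolecule:
        pos = self.coords @ rotation.T + np.asarray(translation, dtype=float)
        atoms = [
            AtomRecord(n, e, p) for n, e, p in zip(self.names, self.elements, pos)
        ]
        return PlanarMolecule(self.spec, atoms, molecule_id)

    def position_of(self, name: str) -> np.ndarray:
        return self.coords[self.names.index(name)]

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[[e != "H" for e in self.elements]]

    @property
    def footprint(self) -> float:
        """In-plane diameter: maximum heavy-atom pairwise distance."""
        h = self.heavy_coords
        d = np.linalg.norm(h[:, None] - h[None, :], axis=-1)
        return float(d.max())


def _polar(radius: float, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([radius * np.cos(a), radius * np.sin(a), 0.0])


@lru_cache(maxsize=1)
def solute_template() -> MoleculeTemplate:
    """The idealized planar solute (urate-monoanion stand-in).

    Six ring carbons on a regular hexagon (circumradius 1.4 Angstrom), four
    acceptor sites N3/O2/O6/O8 at 2.4 Angstrom, two donor hydrogens H1/H2 at
    2.3 Angstrom.  The reference vector runs from C4 to C1 (+x).
    """
    names: list[str] = []
    coords: list[np.ndarray] = []
    for i in range(6):
        names.append(f"C{i + 1}")
        coords.append(_polar(RING_RADIUS, 60.0 * i))
    for name, ang in (("N3", 30.0), ("O2", 120.0), ("O6", 210.0), ("O8", 300.0)):
        names.append(name)
        coords.append(_polar(ACCEPTOR_RADIUS, ang))
    for name, ang in (("H1", 0.0), ("H2", 90.0)):
        names.append(name)
        coords.append(_polar(HYDROGEN_RADIUS, ang))
    spec = MoleculeSpec(
        name="solute",
        role="solute",
        ring_atoms=tuple(f"C{i + 1}" for i in range(6)),
        reference_atoms=("C4", "C1"),
        acceptor_atoms=("N3", "O2", "O6", "O8"),
        hydrogen_atoms=("H1", "H2"),
    )
    elements = tuple(n[0] for n in names)
    return MoleculeTemplate(spec, tuple(names), elements, np.array(coords))


@dataclass(frozen=True)
class ModifierTemplate:
    """A planar fused-ring modifier with a tunable in-plane extent.

    ``size`` counts edge-fused hexagon units along the long (x) axis; the
    in-plane extent is strictly increasing in ``size``.  An optional
    side-chain hydrogen labeled H13 sits off the ring plane at the +x end,
    mimicking a flexible side-chain donor.
    """

    size: int
    template: MoleculeTemplate

    @property
    def spec(self) -> MoleculeSpec:
        return self.template.spec

    @property
    def extent(self) -> float:
        """In-plane extent: maximum ring-atom pairwise distance."""
        ring = np.array(
            [self.template.position_of(n) for n in self.spec.ring_atoms]
        )
        d = np.linalg.norm(ring[:, None] - ring[None, :], axis=-1)
        return float(d.max())


def modifier_template(size: int, side_chain: bool = True, name: str | None = None) -> ModifierTemplate:
    """Build a fused-ring modifier of ``size`` hexagon units."""
    if size < 1:
        raise ValueError("modifier size must be >= 1")
    spacing = np.sqrt(3.0) * RING_RADIUS  # center-to-center of edge-fused hexagons
    verts: list[np.ndarray] = []
    for i in range(size):
        cx = (i - (size - 1) / 2.0) * spacing
        for ang in (30.0, 90.0, 150.0, 210.0, 270.0, 330.0):
            verts.append(np.array([cx, 0.0, 0.0]) + _polar(RING_RADIUS, ang))
    uniq: list[np.ndarray] = []
    for v in verts:
        if not any(np.linalg.norm(v - u) < 1e-6 for u in uniq):
            uniq.append(v)
    uniq.sort(key=lambda p: (round(p[0], 6), round(p[1], 6)))
    coords = list(uniq)
    names = [f"C{i + 1}" for i in range(len(coords))]
    ring_names = tuple(names)
    # reference vector along the long axis: leftmost to rightmost ring atom
    ref = (names[0], names[-1])
    hydrogens = []
    # two in-plane perimeter hydrogens on the top edge
    top = max(c[1] for c in coords)
    coords.append(np.array([0.0, top + 1.0, 0.0]))
    names.append("HM1")
    hydrogens.append("HM1")
    coords.append(np.array([0.0, -(top + 1.0), 0.0]))
    names.append("HM2")
    hydrogens.append("HM2")
    if side_chain:
        right = max(c[0] for c in coords[: len(ring_names)])
        # the side-chain donor reaches up toward the first templating layer
        coords.append(np.array([right + 1.6, 0.8, 1.4]))
        names.append("H13")
        hydrogens.append("H13")
    spec = MoleculeSpec(
        name=name or f"modifier{size}",
        role="modifier",
        ring_atoms=ring_names,
        reference_atoms=ref,
        acceptor_atoms=(),
        hydrogen_atoms=tuple(hydrogens),
    )
    elements = tuple("H" if n.startswith("H") else "C" for n in names)
    tpl = MoleculeTemplate(spec, tuple(names), elements, np.array(coords))
    return ModifierTemplate(size=size, template=tpl)


# -- the shared coplanar hydrogen-bond construction ---------------------------


@dataclass(frozen=True)
class CoplanarMode:
    """One in-plane hydrogen-bond geometry: donor H of molecule A meets an
    acceptor of molecule B, with B rotated by ``phi`` about the plane normal.

    ``crystal_like`` marks the modes realized in the idealized lattice
    (parallel, theta = 0); the remaining mode is the antiparallel in-plane
    arrangement solution dimers can adopt but the crystal does not contain.
    """

    phi: float
    donor: str
    acceptor: str
    crystal_like: bool


COPLANAR_MODES: tuple[CoplanarMode, ...] = (
    CoplanarMode(0.0, "H1", "O6", True),
    CoplanarMode(0.0, "H2", "O8", True),
    CoplanarMode(np.pi, "H1", "N3", False),
)


def coplanar_pair_transform(
    mode: CoplanarMode, d: float = HBOND_TARGET
) -> tuple[np.ndarray, np.ndarray]:
    """Rotation and translation placing molecule B hydrogen-bonded in A's plane.

    In A's body frame: B is rotated by ``mode.phi`` about z and translated so
    that B's named acceptor lies at distance ``d`` from A's named donor
    hydrogen, along the outward direction through that hydrogen.  Returns
    ``(R_b, t_b)`` with all geometry in the z = 0 plane, so the resulting pair
    has planarity angle psi = pi/2 exactly.
    """
    tpl = solute_template()
    p_h = tpl.position_of(mode.donor)
    u = p_h / np.linalg.norm(p_h)
    contact = p_h + d * u
    rot = _rotz(mode.phi)
    t = contact - rot @ tpl.position_of(mode.acceptor)
    return rot, t


# -- ensemble specification ---------------------------------------------------


@dataclass
class EnsembleSpec:
    """Study conditions for the synthetic generator.

    Defaults encode the emulated solution: ~4 Angstrom stacking with an 80%
    antiparallel preference, a 30% coplanar hydrogen-bonded minority, 0.1 rad
    of angular disorder, and a hydrogen-bond criterion of 2.5 Angstrom shared
    with the downstream classifier.
    """

    n_frames: int = 100
    n_solutes: int = 40
    box: float = 60.0
    coplanar_fraction_bulk: float = 0.3
    coplanar_fraction_near: float | None = None  # derived from strength if None
    templating_strength: float = 0.0
    stack_distance_mean: float = 4.0
    stack_distance_sd: float = 0.25
    hbond_contact_max: float = HBOND_CUTOFF
    angular_noise_sd: float = 0.10
    antiparallel_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coplanar_fraction_bulk", "antiparallel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coplanar_fraction_near is not None and not (
            0.0 <= self.coplanar_fraction_near <= 1.0
        ):
            raise ValueError("coplanar_fraction_near must be in [0, 1]")
        if self.stack_distance_mean <= 0:
            raise ValueError("stack_distance_mean must be positive")
        if self.templating_strength < 0:
            raise ValueError("templating_strength must be >= 0")
        if self.n_frames < 1 or self.n_solutes < 2:
            raise ValueError("need at least one frame and two solutes")

    @property
    def box_vector(self) -> np.ndarray:
        return np.full(3, float(self.box))

    def as_dict(self) -> dict:
        return {
            k: (None if v is None else float(v) if isinstance(v, (int, float)) else v)
            for k, v in vars(self).items()
        }


def coplanar_fraction_near(spec: EnsembleSpec, modifier: ModifierTemplate) -> float:
    """Map templating strength and modifier extent to the near coplanar fraction.

    ``f_near = f_bulk + (f_max - f_bulk) * s / (1 + s)`` with the ceiling
    ``f_max`` set by how well the modifier's in-plane extent hosts two solute
    footprints side by side: ``f_max = f_bulk + (1 - f_bulk) * x^2 / (1 + x^2)``
    where ``x = extent / footprint``.  Both maps are smooth, bounded and
    strictly increasing, so a larger aromatic core always templates better at
    equal strength.
    """
    if spec.coplanar_fraction_near is not None:
        return spec.coplanar_fraction_near
    f_bulk = spec.coplanar_fraction_bulk
    x = modifier.extent / solute_template().footprint
    cap = x * x / (1.0 + x * x)
    f_max = f_bulk + (1.0 - f_bulk) * cap
    s = spec.templating_strength
    return f_bulk + (f_max - f_bulk) * s / (1.0 + s)


# -- pair construction --------------------------------------------------------


def _sample_pair(
    rng: np.random.Generator,
    spec: EnsembleSpec,
    coplanar: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample B's rotation and centroid offset in A's body frame.

    The same sampler serves bulk and near-modifier pairs, so the two
    populations share one conformational noise model by construction.
    """
    sd = spec.angular_noise_sd
    tpl = solute_template()
    for _ in range(200):
        if coplanar:
            mode = COPLANAR_MODES[rng.integers(len(COPLANAR_MODES))]
            rot_rel, t_rel = coplanar_pair_transform(mode, HBOND_TARGET)
            # out-of-plane tilt (perturbs psi) about a random in-plane axis
            alpha = rng.uniform(0.0, 2.0 * np.pi)
            tilt = _rot_axis(np.array([np.cos(alpha), np.sin(alpha), 0.0]),
                             rng.normal(0.0, sd) if sd > 0 else 0.0)
            # in-plane yaw of B about its own centroid (perturbs theta)
            yaw = _rotz(rng.normal(0.0, sd)) if sd > 0 else np.eye(3)
            rot_b = tilt @ rot_rel @ yaw
            t_b = tilt @ t_rel
        else:
            d = spec.stack_distance_mean
            if spec.stack_distance_sd > 0:
                d = d + spec.stack_distance_sd * rng.standard_normal()
                if d < 2.0:
                    continue
            sign = 1.0 if rng.random() < 0.5 else -1.0
            phi = np.pi if rng.random() < spec.antiparallel_fraction else 0.0
            alpha = rng.uniform(0.0, 2.0 * np.pi)
            tilt = _rot_axis(np.array([np.cos(alpha), np.sin(alpha), 0.0]),
                             rng.normal(0.0, sd) if sd > 0 else 0.0)
            t_b = d * (tilt @ np.array([0.0, 0.0, sign]))
            beta = rng.uniform(0.0, 2.0 * np.pi)
            wobble = _rot_axis(np.array([np.cos(beta), np.sin(beta), 0.0]),
                               rng.normal(0.0, sd) if sd > 0 else 0.0)
            rot_b = wobble @ _rotz(phi + (rng.normal(0.0, sd) if sd > 0 else 0.0))
        # validate: no heavy-atom overlap; coplanar pairs must satisfy the
        # hydrogen-bond criterion they are meant to encode
        heavy_a = tpl.heavy_coords
        heavy_b = tpl.heavy_coords @ rot_b.T + t_b
        dmin = np.min(
            np.linalg.norm(heavy_a[:, None] - heavy_b[None, :], axis=-1)
        )
        if dmin < OVERLAP_CUTOFF:
            continue
        if coplanar:
            h_a = np.array([tpl.position_of(n) for n in tpl.spec.hydrogen_atoms])
            acc_b = (
                np.array([tpl.position_of(n) for n in tpl.spec.acceptor_atoms])
                @ rot_b.T
                + t_b
            )
            if np.min(np.linalg.norm(h_a[:, None] - acc_b[None, :], axis=-1)) > spec.hbond_contact_max:
                continue
        return rot_b, t_b
    raise PlacementError("could not sample a valid pair geometry")


def _place_anchors(
    rng: np.random.Generator,
    n: int,
    box: np.ndarray,
    exclusion: float,
    forbidden_center: np.ndarray | None = None,
    center_clearance: float = 0.0,
    max_tries: int = 4000,
) -> np.ndarray:
    """Rejection-sample ``n`` points with a minimum-image exclusion distance."""
    anchors: list[np.ndarray] = []
    for _ in range(n):
        for attempt in range(max_tries):
            p = rng.uniform(0.0, 1.0, size=3) * box
            if forbidden_center is not None:
                if np.linalg.norm(minimum_image(p - forbidden_center, box)) < center_clearance:
                    continue
            ok = all(
                np.linalg.norm(minimum_image(p - q, box)) >= exclusion
                for q in anchors
            )
            if ok:
                anchors.append(p)
                break
        else:
            raise PlacementError(
                f"box {box[0]:g} Angstrom too small to place {n} non-overlapping "
                f"pairs (exclusion {exclusion:g} Angstrom)"
            )
    return np.array(anchors) if anchors else np.empty((0, 3))


def _build_pair(
    rng: np.random.Generator,
    spec: EnsembleSpec,
    coplanar: bool,
    anchor: np.ndarray,
    rot_a: np.ndarray,
    ids: tuple[int, int],
) -> list[PlanarMolecule]:
    """Materialize a pair with its midpoint at ``anchor``."""
    tpl = solute_template()
    rot_b_rel, t_rel = _sample_pair(rng, spec, coplanar)
    offset_world = rot_a @ t_rel
    pos_a = np.asarray(anchor, dtype=float) - offset_world / 2.0
    pos_b = pos_a + offset_world
    rot_b = rot_a @ rot_b_rel
    return [
        tpl.instantiate(rot_a, pos_a, ids[0]),
        tpl.instantiate(rot_b, pos_b, ids[1]),
    ]


def make_bulk_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Generate a modifier-free ensemble of solute pairs.

    Solutes are placed as well-separated pairs (plus one uniformly placed
    singleton when ``n_solutes`` is odd), so the dimers enumerated downstream
    within 8 Angstrom are exactly the generated pairs.
    """
    tpl = solute_template()
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(spec.n_frames)
    box = spec.box_vector
    n_pairs = spec.n_solutes // 2
    n_single = spec.n_solutes % 2
    frames: list[Frame] = []
    for fi in range(spec.n_frames):
        rng = np.random.default_rng(streams[fi])
        anchors = _place_anchors(rng, n_pairs + n_single, box, PAIR_EXCLUSION)
        mols: list[PlanarMolecule] = []
        for p in range(n_pairs):
            coplanar = rng.random() < spec.coplanar_fraction_bulk
            rot_a = _random_rotation(rng)
            mols.extend(
                _build_pair(rng, spec, coplanar, anchors[p], rot_a, (2 * p, 2 * p + 1))
            )
        if n_single:
            mols.append(
                tpl.instantiate(_random_rotation(rng), anchors[n_pairs], spec.n_solutes - 1)
            )
        frames.append(Frame(molecules=mols, box=box.copy(), frame_index=fi))
    return Ensemble(
        frames=frames,
        metadata={"generator": "make_bulk_ensemble", "spec": spec.as_dict()},
    )


def _near_pair(
    rng: np.random.Generator,
    spec: EnsembleSpec,
    modifier: ModifierTemplate,
    coplanar: bool,
    ids: tuple[int, int],
) -> list[PlanarMolecule]:
    """Build the templated pair in the modifier's body frame (plane z = 0).

    Coplanar pairs lie flat in a first layer at 3.4 Angstrom above the
    modifier plane with the hydrogen-bond axis steered along the modifier's
    long (+x) axis; stacked pairs sit edge-on (plates perpendicular to the
    modifier plane, stacking axis horizontal) so that *both* members remain
    within the 4 Angstrom near-region — the geometry a flat first layer cannot
    achieve for a perpendicular stack.  The anchor site scales with the
    modifier extent (templating across the whole aromatic surface).
    """
    tpl = solute_template()
    anchor_x = -NEAR_ANCHOR_FRAC * modifier.extent
    jitter = rng.normal(0.0, ANCHOR_POS_JITTER, size=3)
    rot_b_rel, t_rel = _sample_pair(rng, spec, coplanar)
    if coplanar:
        # steer the pair so B extends along +x, over the aromatic core
        heading = np.arctan2(t_rel[1], t_rel[0])
        yaw = _rotz(-heading + rng.normal(0.0, ANCHOR_YAW_JITTER))
        rot_a = yaw
        pos_a = np.array([anchor_x, 0.0, NEAR_LAYER_HEIGHT]) + jitter
    else:
        # plate normal along +x: stacked partner displaced horizontally
        plate = Rotation.from_rotvec([0.0, np.pi / 2.0, 0.0]).as_matrix()
        rot_a = plate @ _rotz(rng.normal(0.0, ANCHOR_YAW_JITTER))
        pos_a = np.array(
            [anchor_x + 2.0, 0.0, NEAR_STACK_HEIGHT]
        ) + jitter
    offset = rot_a @ t_rel
    pos_b = pos_a + offset
    rot_b = rot_a @ rot_b_rel
    return [
        tpl.instantiate(rot_a, pos_a, ids[0]),
        tpl.instantiate(rot_b, pos_b, ids[1]),
    ]


def make_templated_ensemble(spec: EnsembleSpec, modifier: ModifierTemplate) -> Ensemble:
    """Generate an ensemble with one modifier and a templated near population.

    Each frame holds one modifier at the box center (random orientation), one
    near pair whose conformer class follows the near coplanar fraction (quota
    sampling over frames for stable statistics), and bulk-like far pairs drawn
    exactly as in :func:`make_bulk_ensemble`.
    """
    tpl = solute_template()
    f_near = coplanar_fraction_near(spec, modifier)
    root = np.random.SeedSequence(spec.seed)
    quota_rng = np.random.default_rng(root.spawn(1)[0])
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_frames + 1)[1:]
    n_cop = int(round(f_near * spec.n_frames))
    near_coplanar = np.zeros(spec.n_frames, dtype=bool)
    near_coplanar[:n_cop] = True
    near_coplanar = quota_rng.permutation(near_coplanar)

    box = spec.box_vector
    center = box / 2.0
    n_far = spec.n_solutes - 2
    n_far_pairs = n_far // 2
    n_single = n_far % 2
    modifier_id = spec.n_solutes
    frames: list[Frame] = []
    for fi in range(spec.n_frames):
        rng = np.random.default_rng(streams[fi])
        # frame 0 is emitted in the modifier body frame (identity orientation)
        # so that modifier-aligned analyses inherit its axes; later frames are
        # randomly oriented and recover frame 0's axes on alignment
        rot_m = np.eye(3) if fi == 0 else _random_rotation(rng)
        mols: list[PlanarMolecule] = []
        local = _near_pair(rng, spec, modifier, bool(near_coplanar[fi]), (0, 1))
        for m in local:
            mols.append(m.transformed(rot_m, center))
        anchors = _place_anchors(
            rng,
            n_far_pairs + n_single,
            box,
            PAIR_EXCLUSION,
            forbidden_center=center,
            center_clearance=FAR_FROM_MODIFIER,
        )
        for p in range(n_far_pairs):
            coplanar = rng.random() < spec.coplanar_fraction_bulk
            rot_a = _random_rotation(rng)
            mols.extend(
                _build_pair(
                    rng, spec, coplanar, anchors[p], rot_a, (2 + 2 * p, 3 + 2 * p)
                )
            )
        if n_single:
            mols.append(
                tpl.instantiate(
                    _random_rotation(rng), anchors[n_far_pairs], spec.n_solutes - 1
                )
            )
        mols.append(modifier.template.instantiate(rot_m, center, modifier_id))
        frames.append(Frame(molecules=mols, box=box.copy(), frame_index=fi))
    return Ensemble(
        frames=frames,
        metadata={
            "generator": "make_templated_ensemble",
            "spec": spec.as_dict(),
            "modifier_size": modifier.size,
            "modifier_extent": modifier.extent,
            "coplanar_fraction_near": f_near,
        },
    )


# -- idealized crystal lattice ------------------------------------------------


@dataclass(frozen=True)
class CrystalMotif:
    """Packing motif of the idealized crystal.

    Molecules stack *parallel* along z at ``stack_spacing`` (the crystal's
    stacking mode, in contrast to the antiparallel preference in solution) and
    tile each plane by the two in-plane hydrogen-bond translations
    ``coplanar_offsets`` with per-axis relative rotations (0 by default:
    all molecules parallel).
    """

    stack_spacing: float = 4.0
    coplanar_offsets: tuple[tuple[float, float], ...] = ()
    relative_rotations: tuple[float, float] = (0.0, 0.0)

    def resolved_offsets(self) -> np.ndarray:
        if self.coplanar_offsets:
            off = np.asarray(self.coplanar_offsets, dtype=float)
            if off.shape != (2, 2):
                raise ValueError("coplanar_offsets must be two in-plane 2-vectors")
            return off
        a1 = coplanar_pair_transform(COPLANAR_MODES[0])[1][:2]
        a2 = coplanar_pair_transform(COPLANAR_MODES[1])[1][:2]
        return np.array([a1, a2])


def make_crystal_lattice(
    n_cells: tuple[int, int, int], motif: CrystalMotif | None = None
) -> Frame:
    """Build an idealized crystal fragment of ``n_cells`` = (nx, ny, nz) cells.

    Every molecule is a solute-template copy; stacking partners along z are
    exactly parallel, and in-plane neighbours are hydrogen bonded by the same
    coplanar construction the solution generator uses.
    """
    nx, ny, nz = (int(c) for c in n_cells)
    if min(nx, ny, nz) < 1:
        raise ValueError("n_cells must be >= (1, 1, 1)")
    motif = motif or CrystalMotif()
    a1, a2 = motif.resolved_offsets()
    tpl = solute_template()
    mols: list[PlanarMolecule] = []
    mol_id = 0
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                pos = np.array(
                    [
                        ix * a1[0] + iy * a2[0],
                        ix * a1[1] + iy * a2[1],
                        iz * motif.stack_spacing,
                    ]
                )
                ang = ix * motif.relative_rotations[0] + iy * motif.relative_rotations[1]
                mols.append(tpl.instantiate(_rotz(ang), pos, mol_id))
                mol_id += 1
    frame = Frame(molecules=mols, box=None, frame_index=0)
    # construction sanity: no heavy-atom overlap between motif copies
    heavy = [m.heavy_positions for m in mols]
    for i in range(len(mols)):
        for j in range(i + 1, len(mols)):
            d = np.min(
                np.linalg.norm(heavy[i][:, None] - heavy[j][None, :], axis=-1)
            )
            if d < OVERLAP_CUTOFF:
                raise PlacementError(
                    f"overlapping motif offsets: molecules {i} and {j} at {d:.2f} Angstrom"
                )
    return frame
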