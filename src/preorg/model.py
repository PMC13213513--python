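"""Core data model: atoms, role-annotated planar molecules, frames, ensembles.

The analysis operates on planar heterocyclic molecules (a solute such as the
urate monoanion, and one optional modifier per frame).  Each molecule carries a
:class:`MoleculeSpec` naming the atoms that define its aromatic plane, its
in-plane reference vector, and its hydrogen-bond donor/acceptor sites; every
geometric operation downstream resolves atoms through these roles only.

Coordinates are in Angstrom throughout.  Frames are 0-indexed internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, TopologyError

__all__ = [
    "AtomRecord",
    "MoleculeSpec",
    "PlanarMolecule",
    "Frame",
    "Ensemble",
    "minimum_image",
]


def minimum_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention (orthorhombic box only).

    ``vec`` may be a single 3-vector or an (..., 3) array of displacement
    vectors; ``box`` holds the three orthorhombic edge lengths in Angstrom or
    is ``None`` for a non-periodic system.
    """
    v = np.asarray(vec, dtype=float)
    if box is None:
        return v
    b = np.asarray(box, dtype=float)
    return v - b * np.round(v / b)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: a label, an element symbol, and a position in Angstrom."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class MoleculeSpec:
    """Role map for one molecule type.

    Parameters
    ----------
    name : str
        Spec name, referenced by the topology sidecar.
    role : {"solute", "modifier"}
    ring_atoms : tuple of str
        Ordered atom names defining the aromatic plane (>= 3, non-collinear).
    reference_atoms : (str, str)
        Two distinct atom names; their difference is the intramolecular
        in-plane reference vector used for the orientation angle theta.
    acceptor_atoms : tuple of str
        Hydrogen-bond acceptor heavy atoms (e.g. N3, O2, O6, O8 for urate).
    hydrogen_atoms : tuple of str
        Labeled hydrogens considered as donors / contact probes.
    """

    name: str
    role: str
    ring_atoms: tuple[str, ...]
    reference_atoms: tuple[str, str]
    acceptor_atoms: tuple[str, ...] = ()
    hydrogen_atoms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ("solute", "modifier"):
            raise ValueError(f"role must be 'solute' or 'modifier', got {self.role!r}")
        if len(self.ring_atoms) < 3:
            raise ValueError("ring_atoms needs at least 3 atom names")
        if len(self.reference_atoms) != 2 or self.reference_atoms[0] == self.reference_atoms[1]:
            raise ValueError("reference_atoms must be two distinct atom names")
        object.__setattr__(self, "ring_atoms", tuple(self.ring_atoms))
        object.__setattr__(self, "reference_atoms", tuple(self.reference_atoms))
        object.__setattr__(self, "acceptor_atoms", tuple(self.acceptor_atoms))
        object.__setattr__(self, "hydrogen_atoms", tuple(self.hydrogen_atoms))


class PlanarMolecule:
    """A molecule instance with resolved atom roles.

    Atom lookup is by name; every role named in the spec must resolve or the
    constructor raises :class:`TopologyError` — role resolution is total by
    construction.
    """

    def __init__(self, spec: MoleculeSpec, atoms: list[AtomRecord], molecule_id: int):
        self.spec = spec
        self.atoms = list(atoms)
        self.molecule_id = int(molecule_id)
        self._index = {}
        for i, a in enumerate(self.atoms):
            if a.name in self._index:
                raise TopologyError(
                    f"molecule {molecule_id} ({spec.name}): duplicate atom name {a.name!r}"
                )
            self._index[a.name] = i
        for role_name in (
            *spec.ring_atoms,
            *spec.reference_atoms,
            *spec.acceptor_atoms,
            *spec.hydrogen_atoms,
        ):
            if role_name not in self._index:
                raise TopologyError(
                    f"molecule {molecule_id} ({spec.name}): atom {role_name!r} "
                    "named in the spec is absent from the instance"
                )

    # -- coordinate accessors -------------------------------------------------

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def atom_position(self, name: str) -> np.ndarray:
        try:
            return self.atoms[self._index[name]].position
        except KeyError:
            raise TopologyError(
                f"molecule {self.molecule_id} ({self.spec.name}): no atom {name!r}"
            ) from None

    def _role_positions(self, names) -> np.ndarray:
        return np.array([self.atom_position(n) for n in names])

    @property
    def ring_positions(self) -> np.ndarray:
        return self._role_positions(self.spec.ring_atoms)

    @property
    def ring_centroid(self) -> np.ndarray:
        return self.ring_positions.mean(axis=0)

    @property
    def reference_vector(self) -> np.ndarray:
        a, b = self.spec.reference_atoms
        v = self.atom_position(b) - self.atom_position(a)
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise GeometryError(
                f"molecule {self.molecule_id}: coincident reference atoms"
            )
        return v / n

    @property
    def acceptor_positions(self) -> np.ndarray:
        return self._role_positions(self.spec.acceptor_atoms)

    @property
    def hydrogen_positions(self) -> np.ndarray:
        return self._role_positions(self.spec.hydrogen_atoms)

    @property
    def heavy_positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms if a.element != "H"])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PlanarMolecule":
        """Return a rigidly moved copy: x -> rotation @ x + translation."""
        atoms = [
            AtomRecord(a.name, a.element, rotation @ a.position + translation)
            for a in self.atoms
        ]
        return PlanarMolecule(self.spec, atoms, self.molecule_id)


@dataclass
class Frame:
    """One configuration: molecules plus an optional orthorhombic box."""

    molecules: list[PlanarMolecule]
    box: np.ndarray | None = None
    frame_index: int = 0
    time: float | None = None

    def __post_init__(self) -> None:
        ids = [m.molecule_id for m in self.molecules]
        if len(ids) != len(set(ids)):
            raise ValueError(f"frame {self.frame_index}: duplicate molecule ids")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive edge lengths")

    @property
    def solutes(self) -> list[PlanarMolecule]:
        return [m for m in self.molecules if m.spec.role == "solute"]

    @property
    def modifier(self) -> PlanarMolecule | None:
        mods = [m for m in self.molecules if m.spec.role == "modifier"]
        if len(mods) > 1:
            raise ValueError(f"frame {self.frame_index}: more than one modifier")
        return mods[0] if mods else None

    def molecule(self, molecule_id: int) -> PlanarMolecule:
        for m in self.molecules:
            if m.molecule_id == molecule_id:
                return m
        raise KeyError(f"frame {self.frame_index}: no molecule id {molecule_id}")


@dataclass
class Ensemble:
    """An ordered list of frames sharing one molecule roster."""

    frames: list[Frame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames:
            roster = self._roster(self.frames[0])
            for f in self.frames[1:]:
                if self._roster(f) != roster:
                    raise ValueError(
                        f"frame {f.frame_index}: molecule roster differs from frame 0"
                    )

    @staticmethod
    def _roster(frame: Frame) -> tuple:
        return tuple(sorted((m.molecule_id, m.spec.name) for m in frame.molecules))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)
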