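"""Reading and writing the pipeline's file formats.

Coordinate I/O (multi-frame XYZ, multi-model PDB) goes through MDAnalysis;
volumetric grids are OpenDX files written/read through GridDataFormats.  The
one format owned by this package is the *topology sidecar*: a small YAML file
that maps the flat atom list of a coordinate file onto molecules and role
specs, because neither XYZ nor PDB carries the role information the analysis
needs.

Sidecar schema (YAML)::

    specs:
      urate:
        role: solute
        ring_atoms: [C1, C2, C3, C4, C5, C6]
        reference_atoms: [C1, C4]
        acceptor_atoms: [N3, O2, O6, O8]
        hydrogen_atoms: [H1, H2]
    molecules:          # file atom order = concatenation of these blocks
      - id: 0
        spec: urate
        atoms: [C1, C2, C3, C4, C5, C6, N3, O2, O6, O8, H1, H2]
    box: [60.0, 60.0, 60.0]   # optional orthorhombic edges, Angstrom
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ContractError, MalformedInputError, TopologyError
from .model import AtomRecord, Ensemble, Frame, MoleculeSpec, PlanarMolecule

__all__ = [
    "Topology",
    "read_topology",
    "write_topology",
    "read_ensemble",
    "write_ensemble",
    "write_grid",
    "read_grid",
]


def _element_of(name: str) -> str:
    """Element symbol from an atom label: leading alphabetic run, e.g. H13 -> H."""
    sym = ""
    for ch in name:
        if ch.isalpha():
            sym += ch
        else:
            break
    if not sym:
        raise TopologyError(f"cannot infer element from atom name {name!r}")
    # Two-letter symbols are not used by the planar heterocycles handled here.
    return sym[0].upper()


@dataclass
class Topology:
    """Sidecar contents: molecule specs plus the file's atom layout."""

    specs: dict[str, MoleculeSpec]
    molecules: list[tuple[int, str, list[str]]]  # (molecule_id, spec_name, atom names)
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        for mol_id, spec_name, names in self.molecules:
            if spec_name not in self.specs:
                raise TopologyError(f"molecule {mol_id}: unknown spec {spec_name!r}")
            if len(names) != len(set(names)):
                raise TopologyError(f"molecule {mol_id}: duplicate atom names")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_atoms(self) -> int:
        return sum(len(names) for _, _, names in self.molecules)

    @property
    def atom_names(self) -> list[str]:
        return [n for _, _, names in self.molecules for n in names]

    @property
    def elements(self) -> list[str]:
        return [_element_of(n) for n in self.atom_names]

    @classmethod
    def from_ensemble(cls, ens: Ensemble) -> "Topology":
        if not ens.frames:
            raise MalformedInputError("cannot derive a topology from an empty ensemble")
        frame = ens.frames[0]
        specs = {m.spec.name: m.spec for m in frame.molecules}
        molecules = [
            (m.molecule_id, m.spec.name, [a.name for a in m.atoms])
            for m in frame.molecules
        ]
        return cls(specs=specs, molecules=molecules, box=frame.box)


def _spec_to_dict(spec: MoleculeSpec) -> dict:
    return {
        "role": spec.role,
        "ring_atoms": list(spec.ring_atoms),
        "reference_atoms": list(spec.reference_atoms),
        "acceptor_atoms": list(spec.acceptor_atoms),
        "hydrogen_atoms": list(spec.hydrogen_atoms),
    }


def write_topology(top: Topology, path: str | Path) -> None:
    doc = {
        "specs": {name: _spec_to_dict(s) for name, s in top.specs.items()},
        "molecules": [
            {"id": mol_id, "spec": spec_name, "atoms": list(names)}
            for mol_id, spec_name, names in top.molecules
        ],
    }
    if top.box is not None:
        doc["box"] = [float(x) for x in top.box]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_topology(path: str | Path) -> Topology:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        specs = {
            name: MoleculeSpec(
                name=name,
                role=d["role"],
                ring_atoms=tuple(d["ring_atoms"]),
                reference_atoms=tuple(d["reference_atoms"]),
                acceptor_atoms=tuple(d.get("acceptor_atoms", ())),
                hydrogen_atoms=tuple(d.get("hydrogen_atoms", ())),
            )
            for name, d in doc["specs"].items()
        }
        molecules = [
            (int(m["id"]), m["spec"], list(m["atoms"])) for m in doc["molecules"]
        ]
    except (KeyError, TypeError) as exc:
        raise TopologyError(f"malformed topology sidecar {path}: {exc}") from exc
    box = np.asarray(doc["box"], dtype=float) if "box" in doc else None
    return Topology(specs=specs, molecules=molecules, box=box)


# -- coordinate files ---------------------------------------------------------


def _mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def read_ensemble(path: str | Path, topology: Topology | str | Path) -> Ensemble:
    """Read a multi-frame XYZ or multi-model PDB file against a topology sidecar.

    Every file atom must map to exactly one molecule/role through the sidecar;
    atom names and roles come from the sidecar (XYZ files only carry element
    symbols).  Frame order is preserved; coordinates are Angstrom.
    """
    if not isinstance(topology, Topology):
        topology = read_topology(topology)
    path = Path(path)
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        uni = mda.Universe(str(path))
        n_file = len(uni.atoms)
        if n_file != topology.n_atoms:
            raise TopologyError(
                f"{path.name}: file has {n_file} atoms but the topology maps "
                f"{topology.n_atoms}; every atom must map to exactly one molecule"
            )
        names = topology.atom_names
        elements = topology.elements
        frames: list[Frame] = []
        for i, ts in enumerate(uni.trajectory):
            pos = uni.atoms.positions.astype(float)
            if not np.all(np.isfinite(pos)):
                raise MalformedInputError(f"{path.name}: non-finite coordinates in frame {i}")
            mols = []
            offset = 0
            for mol_id, spec_name, mol_names in topology.molecules:
                k = len(mol_names)
                atoms = [
                    AtomRecord(names[offset + j], elements[offset + j], pos[offset + j])
                    for j in range(k)
                ]
                try:
                    mols.append(PlanarMolecule(topology.specs[spec_name], atoms, mol_id))
                except TopologyError as exc:
                    raise TopologyError(f"{path.name}, frame {i}: {exc}") from exc
                offset += k
            frames.append(Frame(molecules=mols, box=topology.box, frame_index=i))
    if not frames:
        raise MalformedInputError(f"{path.name}: no frames")
    return Ensemble(frames=frames, metadata={"source": str(path)})


def write_ensemble(ens: Ensemble, path: str | Path) -> None:
    """Write an ensemble as multi-frame XYZ (`.xyz`) or multi-model PDB (`.pdb`).

    The written file re-reads (with the matching sidecar) to coordinates equal
    within format precision (1e-3 Angstrom).
    """
    if not ens.frames:
        raise MalformedInputError("refusing to write an empty ensemble")
    path = Path(path)
    order = [m.molecule_id for m in ens.frames[0].molecules]
    names: list[str] = []
    elements: list[str] = []
    for m in ens.frames[0].molecules:
        names.extend(a.name for a in m.atoms)
        elements.extend(a.element for a in m.atoms)
    coords = np.empty((len(ens.frames), len(names), 3))
    for i, frame in enumerate(ens.frames):
        pos = [frame.molecule(mid).positions for mid in order]
        coords[i] = np.vstack(pos)
    mda = _mda()
    from MDAnalysis.coordinates.memory import MemoryReader

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        uni = mda.Universe.empty(len(names), trajectory=True)
        uni.add_TopologyAttr("names", names)
        uni.add_TopologyAttr("elements", elements)
        uni.load_new(coords, format=MemoryReader)
        multiframe = path.suffix.lower() == ".pdb"
        with mda.Writer(str(path), len(names), multiframe=multiframe) as writer:
            for _ in uni.trajectory:
                writer.write(uni.atoms)


# -- volumetric grids ---------------------------------------------------------


def write_grid(grid, path: str | Path) -> None:
    """Write a regular occupancy grid as an OpenDX file.

    ``grid`` is an :class:`~preorg.sdf.SDFGrid` (or anything exposing
    ``origin``, ``spacing``, ``dims``, ``occupancy``).  Values are stored in
    x-fastest-last scan order (standard OpenDX), voxel values at voxel centers.
    """
    from gridData import Grid as DXGrid

    occupancy = np.asarray(grid.occupancy, dtype=float)
    dims = tuple(int(d) for d in grid.dims)
    if occupancy.shape != dims:
        raise ContractError(
            f"grid dims {dims} do not match value array shape {occupancy.shape}"
        )
    spacing = float(grid.spacing)
    if spacing <= 0:
        raise ContractError("grid spacing must be positive (regular grid only)")
    origin = np.asarray(grid.origin, dtype=float)
    dx = DXGrid(occupancy, origin=origin + spacing / 2.0, delta=spacing)
    dx.export(str(path), file_format="dx")


def read_grid(path: str | Path):
    """Read an OpenDX grid written by :func:`write_grid` back to an SDFGrid."""
    from gridData import Grid as DXGrid

    from .sdf import SDFGrid

    dx = DXGrid(str(path))
    delta = np.atleast_1d(np.asarray(dx.delta, dtype=float))
    if delta.ndim == 2:
        delta = np.diag(delta)
    if not np.allclose(delta, delta[0]):
        raise ContractError("only cubic-voxel regular grids are supported")
    spacing = float(delta[0])
    origin = np.asarray(dx.origin, dtype=float) - spacing / 2.0
    return SDFGrid(
        origin=origin,
        spacing=spacing,
        dims=tuple(int(d) for d in dx.grid.shape),
        occupancy=np.asarray(dx.grid, dtype=float),
    )
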