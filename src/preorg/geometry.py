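"""Dimer conformational parameters (r, theta, psi) and conformer classification.

A solute pair is summarized by three parameters:

* ``r`` — minimum-image distance between the two ring centroids (Angstrom);
* ``psi`` — the planarity angle between the centroid-separation vector and the
  plane normal of the reference molecule: near 0 or pi for face-to-face
  (pi-stacked) pairs, near pi/2 when the second molecule lies in the first
  molecule's plane (the hydrogen-bonded coplanar motif);
* ``theta`` — the angle between the two molecules' intramolecular reference
  vectors, folded to [0, pi] (undirected vectors).

The reference molecule for ``psi`` is the pair member with the lower molecule
id; a symmetrized variant (averaging the two single-normal angles) is exposed
via ``psi_convention="symmetric"``.

Stacked pairs additionally carry a polarity: *parallel* when the reference
vectors point the same way (the crystal's stacking mode) and *antiparallel*
otherwise (the mode aromatic heterocycles prefer in solution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .model import Frame, PlanarMolecule, minimum_image

__all__ = [
    "DimerGeometry",
    "ClassifierThresholds",
    "HBOND_CUTOFF",
    "plane_normal",
    "dimer_params",
    "classify_conformer",
    "stacking_polarity",
    "hbond_contact",
    "enumerate_dimers",
]

logger = logging.getLogger(__name__)

#: Hydrogen–acceptor heavy-atom distance (Angstrom) below which two molecules
#: count as hydrogen bonded.  Shared by the classifier and the synthetic
#: generator so their definitions cannot drift apart.
HBOND_CUTOFF = 2.5


@dataclass(frozen=True)
class DimerGeometry:
    """One solute pair's conformational parameters."""

    r: float
    theta: float
    psi: float
    polarity: str = "undefined"  # {parallel, antiparallel, undefined}
    pair_ids: tuple[int, int] = (-1, -1)
    frame_index: int = -1

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be non-negative")
        for name, val in (("theta", self.theta), ("psi", self.psi)):
            if not (-1e-12 <= val <= np.pi + 1e-12):
                raise ValueError(f"{name} must lie in [0, pi], got {val}")

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.r, self.theta, self.psi)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Band definitions for the stacked/coplanar conformer classifier.

    Defaults: stacking within 30 degrees of the normal and r in [3.0, 5.5]
    Angstrom (around the ~4 Angstrom crystal spacing); coplanar within 20
    degrees of psi = pi/2 with a hydrogen-bond contact under 2.5 Angstrom.
    """

    psi_stack_halfwidth: float = np.pi / 6
    psi_coplanar_halfwidth: float = np.pi / 9
    r_stack_window: tuple[float, float] = (3.0, 5.5)
    hbond_contact_max: float = HBOND_CUTOFF

    def __post_init__(self) -> None:
        if self.psi_stack_halfwidth <= 0 or self.psi_coplanar_halfwidth <= 0:
            raise ValueError("band halfwidths must be positive")
        if self.psi_stack_halfwidth + self.psi_coplanar_halfwidth >= np.pi / 2:
            raise ValueError("stack and coplanar psi bands must not overlap")
        if self.r_stack_window[0] >= self.r_stack_window[1]:
            raise ValueError("r_stack_window must be a nonempty interval")


def plane_normal(mol: PlanarMolecule) -> np.ndarray:
    """Unit normal of the least-squares plane through the ring atoms.

    The normal is the singular direction of smallest singular value of the
    centered ring coordinates.  Its sign is fixed deterministically: positive
    dot product with (reference vector) x (first ring bond), so that rigidly
    rotating a molecule rotates its normal rather than flipping it.
    """
    ring = mol.ring_positions
    centered = ring - ring.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError(
            f"molecule {mol.molecule_id}: ring atoms are collinear, plane undefined"
        )
    normal = vt[2]
    orient = np.cross(mol.reference_vector, ring[1] - ring[0])
    if np.linalg.norm(orient) > 1e-12 and np.dot(normal, orient) < 0:
        normal = -normal
    return normal


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    # atan2 form: well-conditioned near 0 and pi, where arccos loses precision
    return float(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v)))


def dimer_params(
    a: PlanarMolecule,
    b: PlanarMolecule,
    box: np.ndarray | None = None,
    frame_index: int = -1,
    psi_convention: str = "single",
) -> DimerGeometry:
    """Compute (r, theta, psi) for a solute pair.

    psi uses the plane normal of the member with the lower molecule id
    (``psi_convention="single"``, default) or the average of both
    single-normal angles (``"symmetric"``).
    """
    if a.molecule_id > b.molecule_id:
        a, b = b, a
    sep = minimum_image(b.ring_centroid - a.ring_centroid, box)
    r = float(np.linalg.norm(sep))
    if r < 1e-9:
        raise GeometryError(
            f"molecules {a.molecule_id}/{b.molecule_id}: coincident centroids, "
            "psi undefined"
        )
    psi = _angle_between(sep, plane_normal(a))
    if psi_convention == "symmetric":
        psi_b = _angle_between(sep, plane_normal(b))
        psi = 0.5 * (psi + psi_b)
    elif psi_convention != "single":
        raise ValueError(f"unknown psi convention {psi_convention!r}")
    # theta in [0, pi] by arccos; parallel pairs sit near 0, antiparallel near pi
    theta = _angle_between(a.reference_vector, b.reference_vector)
    return DimerGeometry(
        r=r,
        theta=theta,
        psi=psi,
        pair_ids=(a.molecule_id, b.molecule_id),
        frame_index=frame_index,
    )


def classify_conformer(
    g: DimerGeometry, t: ClassifierThresholds | None = None, hbond_ok: bool = False
) -> str:
    """Classify a dimer as ``"stacked"``, ``"coplanar"`` or ``"other"``.

    Stacked: psi within the stack band around 0 or pi *and* r inside the
    stacking window.  Coplanar: psi within the coplanar band around pi/2 *and*
    a hydrogen-bond contact present (``hbond_ok``).
    """
    t = t or ClassifierThresholds()
    lo, hi = t.r_stack_window
    if (g.psi <= t.psi_stack_halfwidth or g.psi >= np.pi - t.psi_stack_halfwidth) and (
        lo <= g.r <= hi
    ):
        return "stacked"
    if abs(g.psi - np.pi / 2) <= t.psi_coplanar_halfwidth and hbond_ok:
        return "coplanar"
    return "other"


def stacking_polarity(a: PlanarMolecule, b: PlanarMolecule) -> str:
    """Polarity of a stacked pair from the reference-vector dot product."""
    d = float(np.dot(a.reference_vector, b.reference_vector))
    if d > 1e-12:
        return "parallel"
    if abs(d) <= 1e-12:
        logger.warning(
            "molecules %d/%d: reference vectors exactly perpendicular; "
            "polarity tie broken to antiparallel",
            a.molecule_id,
            b.molecule_id,
        )
    return "antiparallel"


def hbond_contact(
    a: PlanarMolecule,
    b: PlanarMolecule,
    cutoff: float = HBOND_CUTOFF,
    box: np.ndarray | None = None,
) -> bool:
    """True if any hydrogen of one molecule is within ``cutoff`` of any
    acceptor heavy atom of the other (checked both directions, minimum image)."""
    for donor, acceptor in ((a, b), (b, a)):
        h = donor.hydrogen_positions
        acc = acceptor.acceptor_positions
        if h.size == 0 or acc.size == 0:
            continue
        d = minimum_image(h[:, None, :] - acc[None, :, :], box)
        if np.min(np.linalg.norm(d, axis=-1)) <= cutoff:
            return True
    return False


def enumerate_dimers(
    frame: Frame,
    r_max: float = 8.0,
    thresholds: ClassifierThresholds | None = None,
    psi_convention: str = "single",
) -> list[tuple[DimerGeometry, str]]:
    """All solute pairs with centroid distance <= ``r_max``, with classes.

    Returns ``(geometry, conformer_class)`` tuples; polarity is attached to
    stacked pairs.
    """
    thresholds = thresholds or ClassifierThresholds()
    solutes = sorted(frame.solutes, key=lambda m: m.molecule_id)
    centroids = np.array([m.ring_centroid for m in solutes])
    out: list[tuple[DimerGeometry, str]] = []
    for i in range(len(solutes)):
        sep = minimum_image(centroids[i + 1 :] - centroids[i], frame.box)
        dist = np.linalg.norm(sep, axis=-1)
        for k in np.nonzero(dist <= r_max)[0]:
            j = i + 1 + int(k)
            a, b = solutes[i], solutes[j]
            g = dimer_params(
                a, b, frame.box, frame_index=frame.frame_index,
                psi_convention=psi_convention,
            )
            cls = classify_conformer(
                g, thresholds,
                hbond_ok=hbond_contact(a, b, thresholds.hbond_contact_max, frame.box),
            )
            if cls == "stacked":
                g = DimerGeometry(
                    r=g.r, theta=g.theta, psi=g.psi,
                    polarity=stacking_polarity(a, b),
                    pair_ids=g.pair_ids, frame_index=g.frame_index,
                )
            out.append((g, cls))
    return out
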