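"""Crystal-derived (r, theta, psi) fingerprints and crystal-conforming dimers.

A fingerprint is a small target box in (r, theta, psi) space around one dimer
motif of the crystal lattice.  A solution dimer "conforms" when its parameters
fall inside any selected fingerprint box; comparing the conforming fraction of
the near-modifier population against the bulk (their ratio, the *enrichment*)
quantifies how strongly a modifier preorganizes solutes into crystal-compatible
conformations.  By default only the coplanar fingerprints count: the crystal
stacks parallel while solution dimers stack antiparallel, so solution stacking
is crystallographically incongruent and the promotion mechanism runs through
the coplanar hydrogen-bonded motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ContractError, SelectionError
from .geometry import DimerGeometry, dimer_params, stacking_polarity
from .model import Frame

__all__ = [
    "DEFAULT_TOLERANCE",
    "CrystalFingerprint",
    "ConformingReport",
    "extract_fingerprints",
    "conforms",
    "conforming_probability",
    "rank_modifiers",
    "write_fingerprints",
    "read_fingerprints",
]

#: default tolerance box (delta_r Angstrom, delta_theta rad, delta_psi rad)
DEFAULT_TOLERANCE = (0.5, np.deg2rad(15.0), np.deg2rad(15.0))


@dataclass(frozen=True)
class CrystalFingerprint:
    """One crystal dimer motif: center (r0, theta0, psi0) plus tolerances."""

    r0: float
    theta0: float
    psi0: float
    tolerance: tuple[float, float, float] = DEFAULT_TOLERANCE
    label: str = ""
    multiplicity: int = 1
    polarity: str = "undefined"

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.tolerance):
            raise ValueError("fingerprint tolerances must be positive")

    def contains(self, g: DimerGeometry) -> bool:
        dr, dth, dps = self.tolerance
        return (
            abs(g.r - self.r0) <= dr
            and abs(g.theta - self.theta0) <= dth
            and abs(g.psi - self.psi0) <= dps
        )

    @property
    def is_coplanar(self) -> bool:
        return self.label.startswith("coplanar")


def _motif_label(psi: float, stack_band: float = np.pi / 6) -> str:
    if psi <= stack_band or psi >= np.pi - stack_band:
        return "stacked"
    if abs(psi - np.pi / 2) <= stack_band:
        return "coplanar"
    return "oblique"


def extract_fingerprints(
    lattice: Frame,
    neighbor_cutoff: float = 6.5,
    tolerance: tuple[float, float, float] = DEFAULT_TOLERANCE,
) -> list[CrystalFingerprint]:
    """Enumerate lattice dimers under ``neighbor_cutoff`` and cluster them.

    Clustering is greedy leader agglomeration in the tolerance-scaled metric
    ``max(|dr|/tol_r, |dtheta|/tol_theta, |dpsi|/tol_psi) < 1``: each dimer
    joins the first cluster whose leader is within tolerance, so every lattice
    dimer is guaranteed to conform to the fingerprint list it produced.  One
    fingerprint per cluster, centered on the leader, with the cluster size as
    multiplicity; stacked fingerprints carry the lattice stacking polarity.
    """
    solutes = sorted(lattice.solutes, key=lambda m: m.molecule_id)
    if len(solutes) < 2:
        raise SelectionError("fingerprint extraction needs at least two molecules")
    pairs: list[tuple[DimerGeometry, str]] = []
    for i in range(len(solutes)):
        for j in range(i + 1, len(solutes)):
            a, b = solutes[i], solutes[j]
            r = np.linalg.norm(b.ring_centroid - a.ring_centroid)
            if r <= neighbor_cutoff:
                g = dimer_params(a, b, lattice.box)
                pairs.append((g, stacking_polarity(a, b)))
    if not pairs:
        raise SelectionError(
            f"no dimers under the neighbor cutoff ({neighbor_cutoff:g} Angstrom)"
        )
    dr, dth, dps = tolerance
    leaders: list[DimerGeometry] = []
    counts: list[int] = []
    polarities: list[str] = []
    for g, pol in pairs:
        for k, lead in enumerate(leaders):
            scaled = max(
                abs(g.r - lead.r) / dr,
                abs(g.theta - lead.theta) / dth,
                abs(g.psi - lead.psi) / dps,
            )
            if scaled < 1.0:
                counts[k] += 1
                break
        else:
            leaders.append(g)
            counts.append(1)
            polarities.append(pol)
    out: list[CrystalFingerprint] = []
    mode_counts: dict[str, int] = {}
    for lead, n, pol in zip(leaders, counts, polarities):
        kind = _motif_label(lead.psi)
        mode_counts[kind] = mode_counts.get(kind, 0) + 1
        label = kind if kind == "stacked" else f"{kind}-mode-{mode_counts[kind]}"
        out.append(
            CrystalFingerprint(
                r0=lead.r,
                theta0=lead.theta,
                psi0=lead.psi,
                tolerance=tolerance,
                label=label,
                multiplicity=n,
                polarity=pol if kind == "stacked" else "undefined",
            )
        )
    return out


def conforms(
    g: DimerGeometry, fps: list[CrystalFingerprint], use: str = "coplanar_only"
) -> bool:
    selected = [f for f in fps if use == "all" or f.is_coplanar]
    return any(f.contains(g) for f in selected)


@dataclass(frozen=True)
class ConformingReport:
    """Crystal-conforming fractions of the two populations."""

    name: str
    p_near: float
    p_bulk: float
    n_near: int
    n_bulk: int

    @property
    def enrichment(self) -> float:
        """p_near normalized to the bulk proportion; NaN when p_bulk = 0."""
        if self.p_bulk == 0:
            return float("nan")
        return self.p_near / self.p_bulk


def conforming_probability(
    near,
    bulk,
    fps: list[CrystalFingerprint],
    use: str = "coplanar_only",
    name: str = "",
) -> ConformingReport:
    """Fraction of near and bulk dimers inside any selected fingerprint box.

    ``near``/``bulk`` are lists of :class:`DimerGeometry` or
    ``(DimerGeometry, class)`` tuples as produced by population selection.
    """
    if not fps:
        raise ContractError("fingerprint list is empty")
    if use not in ("coplanar_only", "all"):
        raise ValueError(f"unknown fingerprint selection {use!r}")

    def _geoms(dimers, which):
        if not dimers:
            raise SelectionError(f"the {which} dimer population is empty")
        return [d[0] if isinstance(d, tuple) else d for d in dimers]

    gn = _geoms(near, "near")
    gb = _geoms(bulk, "bulk")
    p_near = float(np.mean([conforms(g, fps, use) for g in gn]))
    p_bulk = float(np.mean([conforms(g, fps, use) for g in gb]))
    return ConformingReport(
        name=name, p_near=p_near, p_bulk=p_bulk, n_near=len(gn), n_bulk=len(gb)
    )


def rank_modifiers(reports: list[ConformingReport]) -> pd.DataFrame:
    """Rank modifiers by enrichment (descending); ties by p_near, then name."""
    df = pd.DataFrame(
        {
            "name": [r.name for r in reports],
            "p_near": [r.p_near for r in reports],
            "p_bulk": [r.p_bulk for r in reports],
            "enrichment": [r.enrichment for r in reports],
            "n_near": [r.n_near for r in reports],
            "n_bulk": [r.n_bulk for r in reports],
        }
    )
    df = df.sort_values(
        by=["enrichment", "p_near", "name"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df.index = pd.RangeIndex(1, len(df) + 1, name="rank")
    return df


# -- serialization ------------------------------------------------------------


def write_fingerprints(fps: list[CrystalFingerprint], path: str | Path) -> None:
    doc = [
        {
            "label": f.label,
            "r0": float(f.r0),
            "theta0": float(f.theta0),
            "psi0": float(f.psi0),
            "tolerance": [float(t) for t in f.tolerance],
            "multiplicity": int(f.multiplicity),
            "polarity": f.polarity,
        }
        for f in fps
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_fingerprints(path: str | Path) -> list[CrystalFingerprint]:
    doc = yaml.safe_load(Path(path).read_text())
    return [
        CrystalFingerprint(
            r0=d["r0"],
            theta0=d["theta0"],
            psi0=d["psi0"],
            tolerance=tuple(d["tolerance"]),
            label=d.get("label", ""),
            multiplicity=int(d.get("multiplicity", 1)),
            polarity=d.get("polarity", "undefined"),
        )
        for d in doc
    ]
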