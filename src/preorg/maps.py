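"""Near/bulk population selection, (r, theta, psi) histograms and derived maps.

The contrast at the heart of the analysis is between solute dimers in the
*vicinity of the modifier* (any member's heavy atoms within a cutoff of the
modifier, 4 Angstrom by default, with a both-members rule) and dimers in the
*bulk* far from it.  Each population is binned into a 3D probability histogram
over (r, theta, psi); subtracting bulk from near gives the differential maps
whose positive mass localizes the templated conformations, and -ln(p) of a 2D
marginal gives a free-energy map in units of kT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, SelectionError
from .geometry import ClassifierThresholds, DimerGeometry, enumerate_dimers
from .model import Ensemble, Frame, minimum_image

__all__ = [
    "AXIS_NAMES",
    "PopulationSelection",
    "ConformerHistogram",
    "DifferentialMap",
    "FreeEnergyMap",
    "default_axes",
    "select_populations",
    "histogram3d",
    "differential_map",
    "psi_marginal",
    "free_energy_map",
    "band_mass",
    "dimer_table",
]

AXIS_NAMES = ("r", "theta", "psi")


def default_axes() -> dict[str, np.ndarray]:
    """Default bin edges: r in [2, 8] Angstrom at 0.2; theta, psi in [0, pi]
    at pi/36 (5 degrees)."""
    return {
        "r": np.linspace(2.0, 8.0, 31),
        "theta": np.linspace(0.0, np.pi, 37),
        "psi": np.linspace(0.0, np.pi, 37),
    }


@dataclass(frozen=True)
class PopulationSelection:
    """Near/bulk selection rule.

    A dimer is *near* when the membership rule holds for the minimum
    heavy-atom distance from each solute to any modifier heavy atom at
    ``r_cut_modifier``; *bulk* when neither member is within the cutoff.
    Dimers straddling the boundary belong to neither population.
    """

    r_cut_modifier: float = 4.0
    membership_rule: str = "both_members"  # or "either_member"
    r_max: float = 8.0  # pair inclusion radius for dimer enumeration

    def __post_init__(self) -> None:
        if self.r_cut_modifier <= 0:
            raise ValueError("r_cut_modifier must be positive")
        if self.membership_rule not in ("both_members", "either_member"):
            raise ValueError(f"unknown membership rule {self.membership_rule!r}")


def _min_dist_to_modifier(frame: Frame) -> dict[int, float]:
    mod = frame.modifier
    if mod is None:
        return {}
    mod_heavy = mod.heavy_positions
    out = {}
    for m in frame.solutes:
        d = minimum_image(m.heavy_positions[:, None] - mod_heavy[None, :], frame.box)
        out[m.molecule_id] = float(np.min(np.linalg.norm(d, axis=-1)))
    return out


def select_populations(
    ens: Ensemble,
    sel: PopulationSelection | None = None,
    thresholds: ClassifierThresholds | None = None,
    require_modifier: bool = True,
) -> tuple[list[tuple[DimerGeometry, str]], list[tuple[DimerGeometry, str]]]:
    """Split all enumerated dimers into (near, bulk) lists of
    ``(geometry, conformer_class)`` tuples.

    A modifier-free ensemble yields an empty near list (allowed only with
    ``require_modifier=False``); counts satisfy
    near + bulk + straddling = all enumerated dimers.
    """
    sel = sel or PopulationSelection()
    near: list[tuple[DimerGeometry, str]] = []
    bulk: list[tuple[DimerGeometry, str]] = []
    saw_modifier = False
    for frame in ens:
        dists = _min_dist_to_modifier(frame)
        saw_modifier = saw_modifier or bool(dists)
        for g, cls in enumerate_dimers(frame, r_max=sel.r_max, thresholds=thresholds):
            if not dists:
                bulk.append((g, cls))
                continue
            w_a = dists[g.pair_ids[0]] <= sel.r_cut_modifier
            w_b = dists[g.pair_ids[1]] <= sel.r_cut_modifier
            if sel.membership_rule == "both_members":
                is_near = w_a and w_b
            else:
                is_near = w_a or w_b
            if is_near:
                near.append((g, cls))
            elif not (w_a or w_b):
                bulk.append((g, cls))
            # else: straddling the boundary -> excluded from both
    if require_modifier and not saw_modifier:
        raise SelectionError(
            "near population requested but the ensemble contains no modifier"
        )
    return near, bulk


@dataclass
class ConformerHistogram:
    """Binned probability over (r, theta, psi)."""

    edges: dict[str, np.ndarray]
    counts: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(len(self.edges[a]) - 1 for a in AXIS_NAMES)
        if self.counts.shape != shape:
            raise ContractError(
                f"counts shape {self.counts.shape} does not match edges {shape}"
            )

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probability(self) -> np.ndarray:
        if self.total == 0:
            raise ContractError("empty histogram has no probability")
        return self.counts / self.total

    def marginal(self, axes: tuple[str, ...]) -> np.ndarray:
        """Probability marginalized onto the named axes (in the given order)."""
        keep = [AXIS_NAMES.index(a) for a in axes]
        drop = tuple(i for i in range(3) if i not in keep)
        m = self.probability.sum(axis=drop)  # remaining axes in sorted order
        order = sorted(keep)
        return m.transpose([order.index(k) for k in keep])


def histogram3d(
    dimers: list[DimerGeometry] | list[tuple[DimerGeometry, str]],
    axes: dict[str, np.ndarray] | None = None,
) -> ConformerHistogram:
    """Exact binning of dimer (r, theta, psi) triples.

    Bins are half-open [lo, hi) with the last bin closed (the numpy
    convention); observations outside the axis ranges are dropped.
    """
    if not dimers:
        raise ContractError("cannot histogram an empty dimer list")
    axes = axes or default_axes()
    pts = np.array(
        [(d[0] if isinstance(d, tuple) else d).params for d in dimers]
    )
    counts, _ = np.histogramdd(pts, bins=[axes[a] for a in AXIS_NAMES])
    return ConformerHistogram(edges={a: np.asarray(axes[a], dtype=float) for a in AXIS_NAMES},
                              counts=counts.astype(np.int64))


@dataclass
class DifferentialMap:
    """Signed probability difference (near - bulk) over a 2D marginal."""

    axes: tuple[str, str]
    edges: tuple[np.ndarray, np.ndarray]
    values: np.ndarray

    def band_sum(self, axis: str, lo: float, hi: float) -> float:
        """Integrated signed mass over bins whose centers fall in [lo, hi]."""
        i = self.axes.index(axis)
        e = self.edges[i]
        centers = 0.5 * (e[:-1] + e[1:])
        mask = (centers >= lo) & (centers <= hi)
        return float(self.values.sum(axis=1 - i)[mask].sum())


def differential_map(
    near: ConformerHistogram, bulk: ConformerHistogram, axes: tuple[str, str]
) -> DifferentialMap:
    """Marginalize both histograms onto ``axes`` and subtract bulk from near."""
    for a in axes:
        if a not in AXIS_NAMES:
            raise ContractError(f"unknown axis {a!r}")
        if not np.array_equal(near.edges[a], bulk.edges[a]):
            raise ContractError(f"axis {a!r}: bin edges differ between histograms")
    values = near.marginal(axes) - bulk.marginal(axes)
    return DifferentialMap(
        axes=tuple(axes),
        edges=tuple(near.edges[a] for a in axes),
        values=values,
    )


def psi_marginal(h: ConformerHistogram) -> pd.Series:
    """1D probability over psi bins, indexed by bin center (radians)."""
    p = h.marginal(("psi",))
    e = h.edges["psi"]
    centers = 0.5 * (e[:-1] + e[1:])
    return pd.Series(p, index=centers, name="probability")


def band_mass(marginal: pd.Series, lo: float, hi: float) -> float:
    """Probability mass of bins with centers in [lo, hi]."""
    idx = np.asarray(marginal.index, dtype=float)
    mask = (idx >= lo) & (idx <= hi)
    return float(marginal.values[mask].sum())


@dataclass
class FreeEnergyMap:
    """-ln(p) in kT over a 2D marginal, shifted so the occupied minimum is 0.

    Empty bins are masked (NaN), never assigned a sentinel value.
    """

    axes: tuple[str, str]
    edges: tuple[np.ndarray, np.ndarray]
    values: np.ndarray  # NaN on empty bins


def free_energy_map(
    h: ConformerHistogram, axes: tuple[str, str] = ("r", "theta")
) -> FreeEnergyMap:
    p = h.marginal(axes)
    if not np.any(p > 0):
        raise ContractError("free-energy map of an all-empty histogram")
    with np.errstate(divide="ignore"):
        f = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)), np.nan)
    f = f - np.nanmin(f)
    return FreeEnergyMap(
        axes=tuple(axes), edges=tuple(h.edges[a] for a in axes), values=f
    )


def dimer_table(dimers: list[tuple[DimerGeometry, str]]) -> pd.DataFrame:
    """Per-dimer export table: frame, pair, r, theta, psi, class, polarity."""
    rows = [
        {
            "frame": g.frame_index,
            "mol_a": g.pair_ids[0],
            "mol_b": g.pair_ids[1],
            "r": g.r,
            "theta": g.theta,
            "psi": g.psi,
            "class": cls,
            "polarity": g.polarity,
        }
        for g, cls in dimers
    ]
    return pd.DataFrame(
        rows, columns=["frame", "mol_a", "mol_b", "r", "theta", "psi", "class", "polarity"]
    )
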