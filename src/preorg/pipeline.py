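"""One-config orchestration: generate/load -> geometry -> maps -> fingerprints
-> SDF/contacts -> report.

A run is fully described by a :class:`RunConfig` (serializable to YAML).  The
effective configuration — all defaults resolved — is written next to the
outputs, so a report is always reproducible from the files it sits beside.
Identical config + seed gives an identical report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fingerprints as fp
from . import io as pio
from . import maps as pmaps
from . import sdf as psdf
from . import synthetic as syn
from .errors import ContractError, PreorgError
from .geometry import ClassifierThresholds
from .model import Ensemble

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_modifiers"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; every field has an explicit default."""

    name: str = "run"
    seed: int = 0
    output_dir: str | None = None

    # input: either coordinate+topology files, or a generator block
    coordinates: str | None = None
    topology: str | None = None
    generator: dict = field(default_factory=dict)  # EnsembleSpec kwargs
    modifier_size: int | None = None  # None -> bulk-only ensemble
    modifier_side_chain: bool = True

    # analysis parameters
    selection: dict = field(default_factory=dict)  # PopulationSelection kwargs
    thresholds: dict = field(default_factory=dict)  # ClassifierThresholds kwargs
    crystal_cells: tuple[int, int, int] = (2, 2, 2)
    fingerprints_file: str | None = None  # overrides lattice-derived fingerprints
    neighbor_cutoff: float = 6.5
    fingerprint_tolerance: tuple[float, float, float] = fp.DEFAULT_TOLERANCE
    fingerprint_use: str = "coplanar_only"
    sdf_spacing: float = 0.5
    sdf_radius: float = 12.0
    sdf_levels: tuple[float, ...] = (0.4, 0.2)
    contact_r_cut: float = 2.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ContractError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        for key in ("crystal_cells", "fingerprint_tolerance", "sdf_levels"):
            doc[key] = [float(x) for x in doc[key]]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    # -- resolved sub-configs --

    def ensemble_spec(self) -> syn.EnsembleSpec:
        kwargs = dict(self.generator)
        kwargs.setdefault("seed", self.seed)
        return syn.EnsembleSpec(**kwargs)

    def population_selection(self) -> pmaps.PopulationSelection:
        return pmaps.PopulationSelection(**self.selection)

    def classifier_thresholds(self) -> ClassifierThresholds:
        return ClassifierThresholds(**self.thresholds)


@dataclass
class RunReport:
    """Numeric summary of one run; every value is an operation output."""

    name: str
    seed: int
    n_frames: int
    n_near: int
    n_bulk: int
    near_coplanar_mass: float | None
    bulk_coplanar_mass: float
    differential_coplanar_band: float | None
    differential_stacked_band: float | None
    conforming: dict | None
    antiparallel_fraction_bulk: float | None
    sdf_components: list | None
    alignment_max_rmsd: float | None
    contact_table: dict | None
    stage_seconds: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _load_or_generate(cfg: RunConfig) -> Ensemble:
    if cfg.coordinates is not None:
        if cfg.topology is None:
            raise ContractError("coordinate input requires a topology sidecar")
        return pio.read_ensemble(cfg.coordinates, cfg.topology)
    spec = cfg.ensemble_spec()
    if cfg.modifier_size is None:
        return syn.make_bulk_ensemble(spec)
    mod = syn.modifier_template(cfg.modifier_size, side_chain=cfg.modifier_side_chain)
    return syn.make_templated_ensemble(spec, mod)


def _coplanar_band(thresholds: ClassifierThresholds) -> tuple[float, float]:
    hw = thresholds.psi_coplanar_halfwidth
    return (np.pi / 2 - hw, np.pi / 2 + hw)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages; write tables/grids/report if ``output_dir`` is set."""
    timings: dict[str, float] = {}
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.effective.yaml")

    t = time.perf_counter()
    ens = _load_or_generate(cfg)
    timings["input"] = time.perf_counter() - t
    logger.info("%s: %d frames", cfg.name, ens.n_frames)

    t = time.perf_counter()
    thresholds = cfg.classifier_thresholds()
    sel = cfg.population_selection()
    has_modifier = any(f.modifier is not None for f in ens.frames[:1])
    near, bulk = pmaps.select_populations(
        ens, sel, thresholds, require_modifier=has_modifier
    )
    timings["select"] = time.perf_counter() - t
    logger.info("%s: %d near, %d bulk dimers", cfg.name, len(near), len(bulk))
    if not bulk:
        raise PreorgError("no bulk dimers enumerated; check r_max and inputs")

    t = time.perf_counter()
    h_bulk = pmaps.histogram3d(bulk)
    lo, hi = _coplanar_band(thresholds)
    bulk_cop = pmaps.band_mass(pmaps.psi_marginal(h_bulk), lo, hi)
    near_cop = diff_cop = diff_stack = None
    h_near = None
    if near:
        h_near = pmaps.histogram3d(near)
        near_cop = pmaps.band_mass(pmaps.psi_marginal(h_near), lo, hi)
        dmap = pmaps.differential_map(h_near, h_bulk, ("r", "psi"))
        diff_cop = dmap.band_sum("psi", lo, hi)
        diff_stack = dmap.band_sum("psi", 0.0, thresholds.psi_stack_halfwidth) + dmap.band_sum(
            "psi", np.pi - thresholds.psi_stack_halfwidth, np.pi
        )
    stacked_bulk = [g for g, cls in bulk if cls == "stacked"]
    anti = (
        float(np.mean([g.polarity == "antiparallel" for g in stacked_bulk]))
        if stacked_bulk
        else None
    )
    timings["maps"] = time.perf_counter() - t

    t = time.perf_counter()
    if cfg.fingerprints_file is not None:
        prints = fp.read_fingerprints(cfg.fingerprints_file)
    else:
        lattice = syn.make_crystal_lattice(cfg.crystal_cells)
        prints = fp.extract_fingerprints(
            lattice, cfg.neighbor_cutoff, tuple(cfg.fingerprint_tolerance)
        )
    conforming = None
    if near:
        report = fp.conforming_probability(
            near, bulk, prints, use=cfg.fingerprint_use, name=cfg.name
        )
        conforming = {
            "p_near": report.p_near,
            "p_bulk": report.p_bulk,
            "enrichment": report.enrichment,
        }
    timings["fingerprints"] = time.perf_counter() - t

    sdf_components = align_rmsd = contact = None
    if has_modifier:
        t = time.perf_counter()
        aligned, rmsd = psdf.align_frames(ens)
        align_rmsd = float(rmsd.max())
        grid = psdf.sdf(aligned, spacing=cfg.sdf_spacing, radius=cfg.sdf_radius)
        sdf_components = [
            {
                "level": float(level),
                "components": [
                    {"voxels": c.voxel_count, "extent": list(c.extent), "volume": c.volume}
                    for c in psdf.isosurface_components(grid, level)[:5]
                ],
            }
            for level in cfg.sdf_levels
        ]
        ctab = psdf.contact_frequency(ens, r_cut=cfg.contact_r_cut)
        contact = {h: {a: float(v) for a, v in row.items()} for h, row in ctab.iterrows()}
        timings["sdf_contacts"] = time.perf_counter() - t
        if out is not None:
            pio.write_grid(grid, out / "sdf.dx")
            ctab.to_csv(out / "contact_frequency.csv")

    report = RunReport(
        name=cfg.name,
        seed=cfg.seed,
        n_frames=ens.n_frames,
        n_near=len(near),
        n_bulk=len(bulk),
        near_coplanar_mass=near_cop,
        bulk_coplanar_mass=bulk_cop,
        differential_coplanar_band=diff_cop,
        differential_stacked_band=diff_stack,
        conforming=conforming,
        antiparallel_fraction_bulk=anti,
        sdf_components=sdf_components,
        alignment_max_rmsd=align_rmsd,
        contact_table=contact,
        stage_seconds={k: round(v, 4) for k, v in timings.items()},
        provenance={
            "config_name": cfg.name,
            "seed": cfg.seed,
            "metadata": {
                k: v for k, v in ens.metadata.items() if isinstance(v, (str, int, float))
            },
        },
    )
    if out is not None:
        pmaps.dimer_table(bulk).to_csv(out / "dimers_bulk.csv", index=False)
        if near:
            pmaps.dimer_table(near).to_csv(out / "dimers_near.csv", index=False)
        fp.write_fingerprints(prints, out / "fingerprints.yaml")
        report.to_json(out / "report.json")
    return report


def compare_modifiers(cfgs: list[RunConfig]):
    """Run several configs and rank their modifiers by conforming enrichment.

    All runs must use consistent fingerprints and dimer selection, otherwise
    the comparison is refused.
    """
    reference = None
    reports = []
    for cfg in cfgs:
        if cfg.modifier_size is None and cfg.coordinates is None:
            raise ContractError(f"config {cfg.name!r} has no modifier to compare")
        rep = run_pipeline(cfg)
        key = (
            tuple(cfg.crystal_cells),
            cfg.fingerprints_file,
            float(cfg.neighbor_cutoff),
            tuple(float(x) for x in cfg.fingerprint_tolerance),
            cfg.fingerprint_use,
            tuple(sorted(cfg.selection.items())),
            tuple(sorted(cfg.thresholds.items())),
        )
        if reference is None:
            reference = key
        elif key != reference:
            raise ContractError(
                f"config {cfg.name!r}: fingerprints/selection differ between runs; "
                "comparison refused"
            )
        if rep.conforming is None:
            raise ContractError(f"config {cfg.name!r} produced no near population")
        reports.append(
            fp.ConformingReport(
                name=cfg.name,
                p_near=rep.conforming["p_near"],
                p_bulk=rep.conforming["p_bulk"],
                n_near=rep.n_near,
                n_bulk=rep.n_bulk,
            )
        )
    return fp.rank_modifiers(reports)
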