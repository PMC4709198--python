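"""Run configuration and the end-to-end analysis pipeline.

A run is declared in YAML (see ``examples/demo.yaml``): either explicit
``structure``/``trajectory`` paths or a ``generate`` block for a synthetic
system, a ligand schema (named ``fatty_acid_22`` or inline), a region map,
the analysis criteria, and an output directory.  The pipeline executes the
chain descriptors, contact analysis, distance/residency analyses and the
density/diffusion analyses in order, writes CSV/DX outputs, and emits a JSON
manifest with SHA-256 checksums and a provenance block.  Outputs are
deterministic for a given config + inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .chain import head_to_tail_distance, order_parameters, radius_of_gyration
from .contacts import ContactCriterion, contact_table, detect_contacts, region_summary
from .core import Trajectory
from .density import iso_surface_export, lateral_diffusion, occupancy_grid
from .distres import backbone_rmsd, residency, segment_min_distances
from .io import read_structure, read_trajectory
from .schema import LigandSchema, default_fatty_acid_schema
from .synthetic import GeneratorConfig, PlantedContact, generate_system

__all__ = ["RunConfig", "StageError", "run_pipeline", "load_config"]

log = logging.getLogger("amphitraj")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    output_dir: str
    structure: str | None = None
    trajectory: str | None = None
    trajectory_format: str | None = None
    generate: dict | None = None
    schema: str | dict = "fatty_acid_22"
    region_map: dict = field(default_factory=dict)
    extracellular: list = field(default_factory=list)
    protein_selection: str = "role:protein"
    ligand_selection: str = "role:ligand"
    contact_cutoff: float = 3.5
    persistence_threshold_ns: float = 300.0
    persistence_mode: str = "cumulative"
    residency_cutoff: float = 2.0
    density_voxel: float = 1.0
    iso_threshold: float = 0.27
    diffusion_fit_window: tuple[float, float] = (0.1, 0.5)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["diffusion_fit_window"] = list(self.diffusion_fit_window)
        return d

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def resolve_schema(self) -> LigandSchema:
        if isinstance(self.schema, str):
            if self.schema == "fatty_acid_22":
                return default_fatty_acid_schema(22)
            if self.schema.startswith("fatty_acid_"):
                return default_fatty_acid_schema(int(self.schema.rsplit("_", 1)[1]))
            raise ValueError(f"unknown schema name {self.schema!r}")
        s = dict(self.schema)
        return LigandSchema(
            head_atoms=frozenset(s["head_atoms"]),
            tail_atoms=tuple(s["tail_atoms"]),
            head_oxygen=s["head_oxygen"],
            segments={k: frozenset(v) for k, v in s.get("segments", {}).items()},
            analysis_tail=frozenset(s.get("analysis_tail", ())),
            ch_pairs={k: tuple(v) for k, v in s.get("ch_pairs", {}).items()},
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "diffusion_fit_window" in data:
        data["diffusion_fit_window"] = tuple(data["diffusion_fit_window"])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ValueError(f"invalid run config {path}: {exc}") from exc


def _expand_residue_spec(spec) -> set[tuple[str, int]]:
    """[chain, resid] or [chain, start, stop] entries → residue key set."""
    out: set[tuple[str, int]] = set()
    for entry in spec:
        if len(entry) == 2:
            out.add((str(entry[0]), int(entry[1])))
        elif len(entry) == 3:
            for r in range(int(entry[1]), int(entry[2]) + 1):
                out.add((str(entry[0]), r))
        else:
            raise ValueError(f"bad residue spec entry {entry!r}")
    return out


def _load_system(config: RunConfig) -> Trajectory:
    if config.generate is not None:
        gen = dict(config.generate)
        gen.setdefault("seed", config.seed)
        if "planted_contacts" in gen:
            gen["planted_contacts"] = [
                PlantedContact(**pc) for pc in gen["planted_contacts"]
            ]
        if "box" in gen:
            gen["box"] = tuple(gen["box"])
        _, traj, _ = generate_system(GeneratorConfig(**gen))
        return traj
    if not config.structure or not config.trajectory:
        raise ValueError("config needs either generate: or structure:+trajectory:")
    topology, _ = read_structure(config.structure)
    if config.region_map:
        topology = topology.with_regions(
            {k: _expand_residue_spec(v) for k, v in config.region_map.items()},
            extracellular=_expand_residue_spec(config.extracellular),
        )
    return read_trajectory(
        config.trajectory, topology, format=config.trajectory_format
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis battery; returns the manifest dict."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = config.resolve_schema()

    def stage(name):
        log.info("stage %s", name)
        return time.monotonic()

    try:
        t0 = stage("load")
        traj = _load_system(config)
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    files: list[Path] = []

    def save(df, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        files.append(path)

    try:
        stage("chain_descriptors")
        profile = order_parameters(traj, schema)
        save(profile.to_frame(), "order_parameters.csv")
        rg = radius_of_gyration(traj, schema)
        save(rg.to_frame(), "radius_of_gyration.csv")
        h2t = head_to_tail_distance(traj, schema)
        save(h2t.to_frame(), "head_to_tail.csv")
    except Exception as exc:
        raise StageError("chain_descriptors", str(exc)) from exc

    try:
        stage("contact_analysis")
        criterion = ContactCriterion(
            distance_cutoff=config.contact_cutoff,
            persistence_threshold=config.persistence_threshold_ns,
            persistence_mode=config.persistence_mode,
        )
        events = detect_contacts(
            traj, criterion, config.protein_selection, schema, config.ligand_selection
        )
        table = contact_table(events, traj)
        save(table.raw, "contacts_raw.csv")
        save(table.filtered, "contacts_filtered.csv")
        summary = region_summary(table, traj.topology)
        save(summary.per_part, "contact_regions.csv")
    except Exception as exc:
        raise StageError("contact_analysis", str(exc)) from exc

    try:
        stage("distance_residency")
        prof = segment_min_distances(
            traj, schema, config.protein_selection, config.ligand_selection
        )
        save(prof.summary(), "segment_min_distances.csv")
        res = residency(
            traj,
            config.protein_selection,
            config.ligand_selection,
            cutoff=config.residency_cutoff,
        )
        save(res.interval_table(), "residency_intervals.csv")
        rmsd = backbone_rmsd(traj, f"({config.protein_selection}) and name:CA")
        save(rmsd.to_frame(), "backbone_rmsd.csv")
    except Exception as exc:
        raise StageError("distance_residency", str(exc)) from exc

    try:
        stage("density_diffusion")
        grid = occupancy_grid(
            traj, config.ligand_selection, voxel=config.density_voxel
        )
        dx = out / "occupancy.dx"
        obj = out / "occupancy_iso.obj"
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            iso_surface_export(grid, config.iso_threshold, dx_path=dx, obj_path=obj)
        files += [dx, obj]
        diff = lateral_diffusion(
            traj,
            config.ligand_selection,
            fit_window=config.diffusion_fit_window,
        )
        save(diff.msd_frame(), "msd.csv")
    except Exception as exc:
        raise StageError("density_diffusion", str(exc)) from exc

    manifest = {
        "outputs": {p.name: _sha256(p) for p in files},
        "provenance": {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "n_frames": traj.n_frames,
            "n_atoms": traj.topology.n_atoms,
            "diffusion_D_cm2_s": diff.D_cm2_per_s,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
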