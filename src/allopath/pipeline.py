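"""End-to-end per-system orchestration with a run manifest.

``run_all`` drives the full analysis of one simulation system from a single
config: backbone metrics, PCA + free-energy landscape, DCCM, contact
matrix, RDCM pathway extraction, and non-covalent interaction occupancy.
Every output is a text table; the manifest records the effective config
(defaults included, so unstated parameters are always visible), the
package version, and a SHA-256 hash of every emitted file — identical
config and inputs therefore reproduce identical hashes.

``compare_systems`` intersects the hotspot sets of several completed runs
into a consensus table (per-system pathway residues plus the common set).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import __version__
from .backbone_metrics import rg_series, rmsd_series, rmsf_profile
from .correlation import DEFAULT_CONTACT_CUTOFF, contact_matrix, covariance_matrix, dccm
from .ensemble import (
    DEFAULT_FEL_BINS,
    DEFAULT_TEMPERATURE_K,
    free_energy_landscape,
    pca,
)
from .interactions import InteractionCriteria, detect_all, events_to_tsv, occupancy_table
from .pathway import (
    DEFAULT_C_MIN,
    DEFAULT_F_MIN,
    DEFAULT_IMPORTANCE_THRESHOLD,
    build_rdcm_graph,
    common_residues,
    extract_spm,
)
from .structure_io import (
    DEFAULT_TIMESTEP_PS,
    ValidationError,
    read_structure,
    read_trajectory,
    write_matrix,
    write_renumber_map,
)

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_all", "compare_systems"]

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    """A pipeline stage failed; the message names the stage and cause."""


def _parse_residue_spec(spec: Any) -> list[int]:
    """Residue selections: list of ints and/or 'a-b' range strings."""
    out: list[int] = []
    if isinstance(spec, (int,)):
        return [spec]
    for item in spec:
        if isinstance(item, int):
            out.append(item)
        elif isinstance(item, str) and "-" in item:
            a, b = item.split("-", 1)
            out.extend(range(int(a), int(b) + 1))
        else:
            out.append(int(item))
    return out


@dataclass
class RunConfig:
    """Everything one system's analysis needs, with explicit defaults."""

    structure: str
    trajectory: str
    output_dir: str
    chain_roles: dict[str, str] = field(default_factory=dict)
    sites: dict[str, list] = field(default_factory=dict)  # name -> residue spec
    timestep_ps: float = DEFAULT_TIMESTEP_PS
    temperature_K: float = DEFAULT_TEMPERATURE_K
    fel_bins: int = DEFAULT_FEL_BINS
    fel_units: str = "kJ/mol"
    contact_cutoff_A: float = DEFAULT_CONTACT_CUTOFF
    contact_mode: str = "min_heavy"
    f_min: float = DEFAULT_F_MIN
    c_min: float = DEFAULT_C_MIN
    importance_threshold: float = DEFAULT_IMPORTANCE_THRESHOLD
    weight_form: str = "neglog"
    hbond_max_dist: float = 3.0
    hbond_min_angle: float = 150.0
    hydrophobic_max_dist: float = 4.0
    hydrophobic_mode: str = "ca"
    cation_pi_max_dist: float = 6.0
    pi_pi_max_centroid_dist: float = 5.0
    rmsf_superpose: bool = True
    emit_nm: bool = False
    seed: int = 0  # reserved for stochastic stages; analysis is deterministic

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for key in ("structure", "trajectory"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise ValidationError(f"{key} path does not exist: {p}")
        if self.fel_bins < 2:
            raise ValidationError("fel_bins must be >= 2")
        if self.contact_cutoff_A <= 0:
            raise ValidationError("contact_cutoff_A must be positive")

    def criteria(self) -> InteractionCriteria:
        return InteractionCriteria(
            hbond_max_dist=self.hbond_max_dist,
            hbond_min_angle=self.hbond_min_angle,
            hydrophobic_max_dist=self.hydrophobic_max_dist,
            cation_pi_max_dist=self.cation_pi_max_dist,
            pi_pi_max_centroid_dist=self.pi_pi_max_centroid_dist,
            hydrophobic_mode=self.hydrophobic_mode,
        )


@dataclass
class RunManifest:
    """Record of one completed (or aborted) run."""

    config: dict
    version: str
    outputs: dict[str, str]  # relative path -> sha256
    warnings: list[str]
    completed: bool
    failed_stage: str | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> RunManifest:
    """Run the full analysis of one system; see module docstring.

    Any stage failure aborts with :class:`PipelineError` naming the stage;
    outputs already written are retained and listed in a manifest flagged
    as incomplete.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    warnings: list[str] = []

    def emit(name: str) -> Path:
        p = outdir / name
        outputs[name] = ""  # filled with hash after the stage completes
        return p

    stage = "load"
    try:
        t0 = time.perf_counter()
        structure = read_structure(config.structure, config.chain_roles or None)
        traj = read_trajectory(config.trajectory, structure, timestep=config.timestep_ps)
        write_renumber_map(structure, emit("renumber_map.json"))
        logger.info("stage load: %d atoms, %d frames (%.2fs)",
                    traj.n_atoms, traj.n_frames, time.perf_counter() - t0)

        stage = "metrics"
        t0 = time.perf_counter()
        ca = structure.ca_indices()
        rmsd_series(traj, 0, ca).to_tsv(emit("rmsd.tsv"), nm=config.emit_nm)
        rg_series(traj).to_tsv(emit("rg.tsv"), nm=config.emit_nm)
        rmsf_profile(traj, ca, superpose_first=config.rmsf_superpose).to_tsv(
            emit("rmsf.tsv"))
        logger.info("stage metrics done (%.2fs)", time.perf_counter() - t0)

        stage = "pca_fel"
        t0 = time.perf_counter()
        pcs = pca(traj, ca)
        pcs.to_tsv(emit("pca_summary.tsv"))
        fel = free_energy_landscape(
            pcs.projections[:, :2], bins=config.fel_bins,
            temperature=config.temperature_K, units=config.fel_units,
        )
        fel.to_tsv(emit("fel.tsv"))
        logger.info("stage pca_fel done (%.2fs)", time.perf_counter() - t0)

        stage = "correlation"
        t0 = time.perf_counter()
        cov = covariance_matrix(traj, ca)
        corr = dccm(cov)
        write_matrix(corr.C, corr.residues, emit("dccm.tsv"))
        contacts = contact_matrix(
            traj, cutoff=config.contact_cutoff_A,
            distance_mode=config.contact_mode, selection=ca,
        )
        write_matrix(contacts.freq, contacts.residues, emit("rcm.tsv"))
        logger.info("stage correlation done (%.2fs)", time.perf_counter() - t0)

        stage = "pathway"
        t0 = time.perf_counter()
        graph = build_rdcm_graph(
            corr, contacts, f_min=config.f_min, c_min=config.c_min,
            weight_form=config.weight_form,
        )
        spm = extract_spm(graph, importance_threshold=config.importance_threshold)
        spm.to_tsv(emit("rdcm_edges.tsv"))
        spm.hotspots_tsv(emit("hotspots.tsv"))
        logger.info("stage pathway: %d edges, %d hotspots (%.2fs)",
                    len(spm.edges), len(spm.hotspots), time.perf_counter() - t0)

        stage = "interactions"
        t0 = time.perf_counter()
        events = detect_all(traj, config.criteria())
        events_to_tsv(events, emit("events.tsv"))
        sites: dict[str, Any] = {"all": None}
        for name, spec in (config.sites or {}).items():
            sites[name] = _parse_residue_spec(spec)
        table = occupancy_table(events, sites, traj.n_frames)
        table.to_csv(emit("occupancy.tsv"), sep="\t", index=False, float_format="%.6g")
        logger.info("stage interactions: %d events (%.2fs)",
                    len(events), time.perf_counter() - t0)
    except Exception as exc:
        manifest = RunManifest(
            config=asdict(config), version=__version__,
            outputs={k: _sha256(outdir / k) for k in outputs if (outdir / k).exists()},
            warnings=warnings + [f"stage {stage} failed: {exc}"],
            completed=False, failed_stage=stage,
        )
        manifest.write(outdir / "manifest.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config=asdict(config), version=__version__,
        outputs={k: _sha256(outdir / k) for k in outputs},
        warnings=warnings, completed=True,
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def _hotspots_from_manifest(manifest_path: Path) -> list[int]:
    outdir = manifest_path.parent
    hotspots = outdir / "hotspots.tsv"
    if not hotspots.exists():
        raise ValidationError(f"{outdir}: no hotspots.tsv (incomplete run?)")
    lines = hotspots.read_text().splitlines()[1:]
    return [int(x) for x in lines if x.strip()]


def compare_systems(
    manifests: Sequence[str | Path],
    window: int = 0,
    out: str | Path | None = None,
    names: Sequence[str] | None = None,
) -> dict[str, list[int]]:
    """Consensus pathway residues across >= 2 completed runs.

    Returns {system name: hotspots, ..., "common": shared residues} and
    optionally writes the consensus table as TSV (one row per system, a
    final row with the common residues).
    """
    if len(manifests) < 2:
        raise ValidationError("need at least two systems to compare")
    names = list(names) if names else [Path(m).parent.name for m in manifests]
    hotspot_sets = [_hotspots_from_manifest(Path(m)) for m in manifests]
    shared = common_residues(hotspot_sets, window=window)
    report = {name: hs for name, hs in zip(names, hotspot_sets)}
    report["common"] = shared
    if out is not None:
        with open(out, "w") as fh:
            fh.write("system\tpathway_residues\n")
            for name, hs in report.items():
                fh.write(name + "\t" + ", ".join(str(r) for r in hs) + "\n")
    return report
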