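"""Config-driven end-to-end orchestration with manifests and derived seeds.

Stages run in the natural processing order — phantom synthesis,
correspondence, statistical surface model, averaged density model, pathway
probes, report — each writing its artifacts under the run directory and
recording them (with content hashes) in a JSON manifest.  One global seed
fans out to per-stage child seeds by stable derivation, so toggling one
stage never shifts another stage's randomness; identical config + seed
yields identical manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from ._mesh import SurfaceDistance
from .correspond import (
    HomologousMeshSet,
    choose_reference,
    establish_homology,
    resample_segments,
    transfer_cartilage_regions,
)
from .density import (
    build_averaged_model,
    build_reference_grid,
    probe_pathway,
    segment_zones,
    zone_stats,
)
from .imaging import LabeledMesh
from .phantom import ZoneProfile, _oriented_axes, generate_population
from .shape import ShapePCA, measure, population_stats, procrustes_align

__all__ = ["PipelineConfig", "run_pipeline", "report", "default_pathways",
           "stage_seed"]

_STAGE_ORDER = ("synth", "correspond", "shape", "density", "probes")


class SynthConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    n: int = 10
    n_subdiv: int = 16
    voxel_size: float = 0.3
    noise_sd: float = 60.0
    make_volumes: bool = True


class CorrespondConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    points_per_segment: int = 11
    points_per_loop: int = 24
    reference: str = "auto"   # "auto" or a specimen id


class ShapeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    n_modes: int = 10
    synth_sd: float = 2.0     # +-k SD meshes written per mode


class DensityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    grid_spacing: float = 0.3
    peripheral_depth: float = 1.0
    centre_start_depth: float = 3.0
    n_controls: int = 800


class ProbesConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    diameter: float = 3.0
    n_stations: int = 100


class PipelineConfig(BaseModel):
    """Typo-safe (unknown keys rejected) round-trippable pipeline settings."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "carposhape_run"
    synth: SynthConfig = Field(default_factory=SynthConfig)
    correspond: CorrespondConfig = Field(default_factory=CorrespondConfig)
    shape: ShapeConfig = Field(default_factory=ShapeConfig)
    density: DensityConfig = Field(default_factory=DensityConfig)
    probes: ProbesConfig = Field(default_factory=ProbesConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2^31) derived from the global seed."""
    idx = _STAGE_ORDER.index(stage)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_pathways(mean_mesh: LabeledMesh) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Central and peripheral candidate screw pathways through a bone mesh.

    The central pathway runs along the long axis through the bone's middle;
    the peripheral pathway is a parallel chord shifted toward the medial
    articular surfaces so it runs just below the cortical shell, bypassing
    the low-density core.
    """
    c, axis, ref = _oriented_axes(mean_mesh.vertices)
    proj = (mean_mesh.vertices - c) @ axis
    lo, hi = proj.min(), proj.max()
    entry_c = c + (lo + 0.05 * (hi - lo)) * axis
    exit_c = c + (hi - 0.05 * (hi - lo)) * axis
    # march medially from the centroid until just below the surface; that
    # offset puts the parallel chord inside the peripheral shell at mid-bone
    sd = SurfaceDistance(mean_mesh.vertices, mean_mesh.triangles)
    offset = 0.0
    while offset < 50.0:
        if sd.query((c + (offset + 0.25) * ref)[None])[0][0] < 1.2:
            break
        offset += 0.25
    return {
        "central": (entry_c, exit_c),
        "peripheral": (entry_c + offset * ref, exit_c + offset * ref),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in order; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.model_dump(), "stages": {},
                      "files": {}, "metrics": {}}

    def add_file(path: Path):
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    specimens = None
    hom = None
    mean_mesh = None
    model = None

    try:
        if config.synth.enabled:
            sc = config.synth
            zones = ZoneProfile(noise_sd=sc.noise_sd) if sc.make_volumes else None
            specimens, latent = generate_population(
                sc.n, seed=stage_seed(config.seed, "synth"),
                n_subdiv=sc.n_subdiv, zones=zones, voxel_size=sc.voxel_size)
            sdir = out / "specimens"
            sdir.mkdir(exist_ok=True)
            latent.to_csv(sdir / "latent_parameters.csv")
            add_file(sdir / "latent_parameters.csv")
            for s in specimens:
                s.mesh.save_ply(sdir / f"{s.specimen_id}.ply")
                s.landmarks.to_json(sdir / f"{s.specimen_id}_landmarks.json")
                add_file(sdir / f"{s.specimen_id}.ply")
                add_file(sdir / f"{s.specimen_id}_landmarks.json")
                if s.volume is not None:
                    s.volume.save(sdir / f"{s.specimen_id}.nii")
                    add_file(sdir / f"{s.specimen_id}.nii")
            manifest["stages"]["synth"] = {
                "n": sc.n, "seed": stage_seed(config.seed, "synth")}

        if config.correspond.enabled:
            if specimens is None:
                raise RuntimeError("correspond stage needs synth outputs")
            cc = config.correspond
            lsets = [resample_segments(s.landmarks, cc.points_per_segment,
                                       points_per_loop=cc.points_per_loop)
                     for s in specimens]
            if cc.reference == "auto":
                ridx = choose_reference(lsets)
            else:
                ids = [s.specimen_id for s in specimens]
                ridx = ids.index(cc.reference)
            hom = establish_homology(
                (specimens[ridx].mesh, lsets[ridx]),
                [(s.mesh, l) for s, l in zip(specimens, lsets)],
                [s.specimen_id for s in specimens],
                reference_id=specimens[ridx].specimen_id)
            hom, areas = transfer_cartilage_regions(
                specimens[ridx].mesh.labels, hom)
            cdir = out / "corresponded"
            hom.save(cdir)
            areas.to_csv(cdir / "region_areas.csv")
            for f in sorted(cdir.iterdir()):
                add_file(f)
            manifest["stages"]["correspond"] = {
                "reference": hom.reference_id,
                "mean_residual_mm": float(hom.residuals.mean()),
                "flagged": hom.flagged}

        if config.shape.enabled:
            if hom is None:
                raise RuntimeError("shape stage needs correspond outputs")
            aligned, mean, gpa = procrustes_align(hom)
            pca = ShapePCA(n_modes=config.shape.n_modes).fit(
                aligned, triangles=hom.triangles, labels=hom.labels)
            mean_mesh = pca.mean_mesh()
            mdir = out / "shape_model"
            mdir.mkdir(exist_ok=True)
            mean_mesh.save_ply(mdir / "mean_mesh.ply")
            np.save(mdir / "modes.npy", pca.components_)
            np.save(mdir / "scores.npy", pca.scores_)
            pd.DataFrame({
                "variance_mm2": np.r_[pca.variances_,
                                      [np.nan] * (len(pca.variance_fractions_)
                                                  - len(pca.variances_))],
                "fraction": pca.variance_fractions_,
            }).to_csv(mdir / "variance_fractions.csv", index_label="mode")
            k = config.shape.synth_sd
            for mode in range(min(2, len(pca.components_))):
                for sgn, tag in ((k, f"plus{k:g}sd"), (-k, f"minus{k:g}sd")):
                    pca.synthesize(mode, sgn).save_ply(
                        mdir / f"pc{mode + 1}_{tag}.ply")
            morpho = pd.DataFrame(
                [measure(hom.mesh(i)).as_dict()
                 for i in range(hom.n_specimens)],
                index=hom.specimen_ids)
            morpho.to_csv(mdir / "morphometrics_specimens.csv")
            mean_row = pd.Series(measure(mean_mesh).as_dict())
            mean_row.to_csv(mdir / "morphometrics_mean_model.csv",
                            header=["value"])
            population_stats(morpho).to_csv(mdir / "morphometrics_stats.csv")
            for f in sorted(mdir.iterdir()):
                add_file(f)
            manifest["stages"]["shape"] = {"n_modes": len(pca.components_)}
            manifest["metrics"]["variance_fractions"] = [
                float(f) for f in pca.variance_fractions_]

        if config.density.enabled:
            if hom is None or mean_mesh is None:
                raise RuntimeError("density stage needs shape outputs")
            if any(s.volume is None for s in specimens):
                raise RuntimeError("density stage needs specimen volumes")
            dc = config.density
            grid = build_reference_grid(mean_mesh, dc.grid_spacing)
            model = build_averaged_model(
                grid, hom, [s.volume for s in specimens],
                mean_mesh.vertices, n_controls=dc.n_controls)
            model = segment_zones(model, mean_mesh, dc.peripheral_depth,
                                  dc.centre_start_depth)
            ddir = out / "density_model"
            ddir.mkdir(exist_ok=True)
            model.as_volume().save(ddir / "mean_vbmd.nii")
            stats = zone_stats(model)
            stats.to_csv(ddir / "zone_stats.csv")
            for f in sorted(ddir.iterdir()):
                add_file(f)
            manifest["stages"]["density"] = {
                "n_inside_nodes": grid.n_inside, "flagged": model.flagged}
            manifest["metrics"]["zone_means"] = {
                z: (None if not np.isfinite(v) else float(v))
                for z, v in stats["mean"].items()}

        if config.probes.enabled:
            if model is None:
                raise RuntimeError("probes stage needs the density model")
            pdir = out / "probes"
            pdir.mkdir(exist_ok=True)
            paths = default_pathways(mean_mesh)
            summaries = {}
            for name, (entry, exit_) in paths.items():
                prof = probe_pathway(model, entry, exit_,
                                     diameter=config.probes.diameter,
                                     n_stations=config.probes.n_stations)
                prof.to_frame().to_csv(pdir / f"{name}_profile.csv",
                                       index=False)
                add_file(pdir / f"{name}_profile.csv")
                summaries[name] = prof.summary
            manifest["stages"]["probes"] = {"paths": sorted(paths)}
            manifest["metrics"]["probe_summaries"] = summaries
    except Exception as err:  # mark partial outputs, re-raise with stage name
        done = list(manifest["stages"])
        raise RuntimeError(
            f"pipeline failed after stages {done}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def report(manifest: dict) -> str:
    """Human-readable summary of a pipeline run."""
    lines = ["carposhape run report", "=" * 21]
    metrics = manifest.get("metrics", {})
    if "variance_fractions" in metrics:
        lines.append("\nPCA variance fractions (% of total form variation):")
        fr = metrics["variance_fractions"]
        for i, f in enumerate(fr[:10]):
            lines.append(f"  PC{i + 1}: {100 * f:.1f}%")
        lines.append(f"  sum of all fractions: {100 * sum(fr):.1f}%")
    else:
        lines.append("\n[shape-model section omitted: stage not run]")
    if "zone_means" in metrics:
        lines.append("\nZone mean vBMD (mg HA/cm^3):")
        for z, v in metrics["zone_means"].items():
            lines.append(f"  {z}: {'empty' if v is None else format(v, '.1f')}")
    else:
        lines.append("[density section omitted: stage not run]")
    if "probe_summaries" in metrics:
        lines.append("\nPathway probes (path-mean vBMD):")
        for name, s in metrics["probe_summaries"].items():
            lines.append(f"  {name}: mean {s['mean']:.1f} "
                         f"(min {s['min']:.1f}, max {s['max']:.1f})")
    else:
        lines.append("[probe section omitted: stage not run]")
    return "\n".join(lines) + "\n"
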