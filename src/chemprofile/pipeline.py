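"""Pipeline orchestration: curate -> profile -> scaffolds -> polyphenols ->
diversity -> chemical space, from one config, into a report bundle.

Every stage writes CSV (plus SDF/SVG where appropriate) into the output
directory, and a JSON manifest records package/toolkit versions, seeds, the
fingerprint dialect and every parameter value, so each number in the bundle
traces back to a recorded setting.  A stage failure aborts the run with the
stage name; the manifest then flags the bundle as partial.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import rdkit
import yaml

from . import __version__
from .curation import CuratedLibrary, curate, library_overlap
from .diversity import (
    DEFAULT_MAX_PAIRS,
    FINGERPRINT_DIALECT,
    cdp_assign,
    consensus_profiles,
    profiles_frame,
)
from .chemspace import (
    distance_preservation,
    fit_projection,
    plot_embedding,
    points_frame,
    project,
    select_satellites,
)
from .io import read_molecules, write_curated_smiles, write_records_sdf
from .polyphenol import polyphenol_fraction
from .profiling import property_table, summarize_library
from .scaffolds import recovery_curve, scaffold_frequencies

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (echoed into the manifest)."""

    libraries: list[tuple[str, str, str]]  # (path, format, tag)
    output_dir: str
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "profile": True, "scaffolds": True, "polyphenols": True,
        "diversity": True, "chemspace": True,
    })
    k_satellites: int = 200
    satellite_method: str = "maxmin"
    projection_dims: int = 2
    max_pairs: int = DEFAULT_MAX_PAIRS
    polyphenol_distinct_rings: bool = False
    include_acyclic: bool = True
    outlier_rule: str = "median_iqr"
    stereo_distinct: bool = True
    top_k_scaffolds: int = 10

    def __post_init__(self):
        tags = [t for _, _, t in self.libraries]
        if len(set(tags)) != len(tags):
            raise ValueError(f"library tags must be unique, got {tags}")
        missing = [p for p, _, _ in self.libraries if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"library files not found: {missing}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["libraries"] = [tuple(entry) for entry in raw["libraries"]]
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "chemprofile_version": __version__,
        "rdkit_version": rdkit.__version__,
        "fingerprint_dialect": FINGERPRINT_DIALECT,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "libraries"},
            "libraries": [list(entry) for entry in config.libraries],
        },
        "stages_completed": [],
        "partial": True,
        "outputs": [],
    }

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)

    try:
        libs: list[CuratedLibrary] = []
        stage = "curate"
        for path, fmt, tag in config.libraries:
            records, malformed = read_molecules(path, fmt)
            lib = curate(records, tag, stereo_distinct=config.stereo_distinct)
            lib.log.n_unparseable += len(malformed)
            lib.log.n_input += len(malformed)
            libs.append(lib)
            emit(f"{tag}_curated.smi", lambda p, lib=lib: write_curated_smiles(lib.records, p))
            emit(f"{tag}_curation_log.csv", lambda p, lib=lib: pd.DataFrame(
                [vars(lib.log)]).to_csv(p, index=False))
        manifest["stages_completed"].append(stage)

        if len(libs) >= 2:
            stage = "overlap"
            rows = []
            for a in libs:
                for b in libs:
                    if a is b:
                        continue
                    count, frac = library_overlap(a, b)
                    rows.append({"a": a.tag, "b": b.tag,
                                 "count": count, "fraction_of_b": frac})
            emit("library_overlap.csv",
                 lambda p: pd.DataFrame(rows).to_csv(p, index=False))
            manifest["stages_completed"].append(stage)

        if config.stages.get("profile", True):
            stage = "profile"
            for lib in libs:
                table = property_table(lib.records)
                emit(f"{lib.tag}_properties.csv", lambda p, t=table: t.to_csv(p))
                summary = summarize_library(table, outlier_rule=config.outlier_rule)
                emit(f"{lib.tag}_property_summary.csv", lambda p, s=summary: s.to_csv(p))
            manifest["stages_completed"].append(stage)

        if config.stages.get("scaffolds", True):
            stage = "scaffolds"
            for lib in libs:
                table = scaffold_frequencies(lib, include_acyclic=config.include_acyclic)
                emit(f"{lib.tag}_scaffolds.csv", lambda p, t=table: t.to_frame().to_csv(p, index=False))
                emit(f"{lib.tag}_scaffolds_top{config.top_k_scaffolds}.csv",
                     lambda p, t=table: t.top_k(config.top_k_scaffolds).to_csv(p, index=False))
                curve = recovery_curve(table)
                emit(f"{lib.tag}_recovery_curve.csv",
                     lambda p, c=curve: pd.DataFrame(
                         {"x": c.x, "y": c.y}).to_csv(p, index=False))
            manifest["stages_completed"].append(stage)

        if config.stages.get("polyphenols", True):
            stage = "polyphenols"
            rows = []
            for lib in libs:
                count, frac, subset = polyphenol_fraction(
                    lib, distinct_rings=config.polyphenol_distinct_rings)
                rows.append({"library": lib.tag, "n_polyphenols": count,
                             "fraction": frac, "size": len(lib)})
                emit(f"{lib.tag}_polyphenols.sdf",
                     lambda p, s=subset: write_records_sdf(s, p))
            emit("polyphenol_counts.csv",
                 lambda p: pd.DataFrame(rows).to_csv(p, index=False))
            manifest["stages_completed"].append(stage)

        if config.stages.get("diversity", True) and len(libs) >= 2:
            stage = "diversity"
            profiles = consensus_profiles(
                libs, max_pairs=config.max_pairs, seed=config.seed,
                include_acyclic=config.include_acyclic)
            assigned = cdp_assign(profiles, plot_path=str(out / "cdp.svg"))
            manifest["outputs"].append("cdp.svg")
            emit("diversity_profiles.csv", lambda p: assigned.to_csv(p))
            manifest["stages_completed"].append(stage)

        if config.stages.get("chemspace", True):
            stage = "chemspace"
            fit_lib = max(libs, key=len)
            k = min(config.k_satellites, len(fit_lib))
            satellites = select_satellites(
                fit_lib, k=k, method=config.satellite_method, seed=config.seed)
            model = fit_projection(fit_lib, satellites, d=config.projection_dims)
            model.to_json(str(out / "projection_model.json"))
            manifest["outputs"].append("projection_model.json")
            points = project(model, libs)
            emit("chemspace_coordinates.csv",
                 lambda p: points_frame(points).to_csv(p, index=False))
            plot_embedding(points, str(out / "chemspace.svg"))
            manifest["outputs"].append("chemspace.svg")
            manifest["chemspace"] = {
                "fit_library": fit_lib.tag,
                "k_satellites": k,
                "explained_variance_fractions":
                    model.explained_variance_fractions.tolist(),
                "distance_preservation_spearman": distance_preservation(
                    model, fit_lib, seed=config.seed)
                if len(fit_lib) >= 10 else None,
            }
            manifest["stages_completed"].append(stage)

        manifest["partial"] = False
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
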