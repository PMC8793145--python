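"""Readers, writers, run configuration and the end-to-end pipeline.

All on-disk formats are plain text: CSV for contours, features and
projections, JSON for models, ellipses, overlaps and the run manifest,
YAML for configuration.  Images are read from TIFF or PNG as grayscale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contours import Contour, ParticleImage, SegmentationConfig, extract_contour, segment_particles
from .overlap import independence_test, overlap_coefficient
from .shape_space import (
    ConfidenceEllipse,
    EnsembleProjection,
    ShapeEnsemble,
    ShapeSpaceModel,
    ensemble_from_contours,
    fit_shape_space,
    project_ensemble,
)
from .synthetic import PRESETS, EnsembleParams, generate_ensemble

__all__ = [
    "read_image",
    "write_contours_csv",
    "load_contours",
    "write_contours_json",
    "write_features_csv",
    "load_features_csv",
    "write_model_json",
    "load_model_json",
    "write_projections_csv",
    "write_ellipse_json",
    "write_overlap_json",
    "RunConfig",
    "run_pipeline",
]


def read_image(path: str | Path, pixel_size_nm: float) -> ParticleImage:
    """Read a TIFF/PNG as a grayscale ParticleImage (RGB is averaged)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        px = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        px = iio.imread(path)
    px = np.asarray(px, dtype=float)
    if px.ndim == 3:
        px = px.mean(axis=2)
    return ParticleImage(pixels=px, pixel_size_nm=pixel_size_nm, id=path.stem)


# ---------------------------------------------------------------- contours

_CONTOUR_COLUMNS = ["particle_id", "vertex_index", "x_nm", "y_nm"]


def write_contours_csv(contours: list[Contour], path: str | Path) -> None:
    rows = []
    for i, c in enumerate(contours):
        pid = c.source_id or str(i)
        for j, (x, y) in enumerate(c.points):
            rows.append((pid, j, repr(float(x)), repr(float(y))))
    df = pd.DataFrame(rows, columns=_CONTOUR_COLUMNS)
    df.to_csv(path, index=False)


def write_contours_json(contours: list[Contour], path: str | Path, **metadata) -> None:
    payload = {
        "metadata": {"package_version": __version__, **metadata},
        "contours": [
            {"particle_id": c.source_id or str(i), "points": c.points.tolist()}
            for i, c in enumerate(contours)
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_contours(path: str | Path) -> list[Contour]:
    """Load contours from the documented CSV or JSON schema.

    Malformed records raise a ValueError naming the offending particle
    (and, for CSV, the first data line involved).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        out = []
        for entry in payload["contours"]:
            pid = entry.get("particle_id", "?")
            pts = np.asarray(entry["points"], dtype=float)
            try:
                out.append(Contour(points=pts, source_id=str(pid)))
            except ValueError as err:
                raise ValueError(f"invalid contour for particle {pid!r}: {err}") from err
        return out

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CONTOUR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contour CSV missing columns: {missing}")
    if df.empty:
        return []
    out = []
    for pid, grp in df.groupby("particle_id", sort=False):
        grp = grp.sort_values("vertex_index")
        first_line = int(grp.index.min()) + 2  # header is line 1
        pts = grp[["x_nm", "y_nm"]].to_numpy(dtype=float)
        try:
            out.append(Contour(points=pts, source_id=str(pid)))
        except ValueError as err:
            raise ValueError(
                f"invalid contour for particle {pid!r} (starting at line {first_line}): {err}"
            ) from err
    return out


# ---------------------------------------------------------------- features

def write_features_csv(ensemble: ShapeEnsemble, path: str | Path) -> None:
    """Particles-by-harmonics matrix with a leading particle_id column."""
    cols = [f"a{k + 1}" for k in range(ensemble.k)]
    df = pd.DataFrame(ensemble.features, columns=cols)
    df.insert(0, "particle_id", ensemble.particle_ids)
    df.insert(0, "label", ensemble.label)
    df.to_csv(path, index=False, float_format="%.17g")


def load_features_csv(path: str | Path) -> ShapeEnsemble:
    df = pd.read_csv(path, float_precision="round_trip")
    if "label" not in df.columns or "particle_id" not in df.columns:
        raise ValueError("feature CSV needs 'label' and 'particle_id' columns")
    labels = df["label"].unique()
    if len(labels) != 1:
        raise ValueError(f"feature CSV mixes labels: {list(labels)}")
    acols = [c for c in df.columns if c.startswith("a")]
    return ShapeEnsemble(
        label=str(labels[0]),
        features=df[acols].to_numpy(dtype=float),
        particle_ids=[str(p) for p in df["particle_id"]],
    )


# ------------------------------------------------------------------- model

def write_model_json(model: ShapeSpaceModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "mean_vector": model.mean_vector.tolist(),
                "components": model.components.tolist(),
                "explained_variance_ratio": model.explained_variance_ratio.tolist(),
            }
        )
    )


def load_model_json(path: str | Path) -> ShapeSpaceModel:
    d = json.loads(Path(path).read_text())
    return ShapeSpaceModel(
        mean_vector=np.array(d["mean_vector"]),
        components=np.array(d["components"]),
        explained_variance_ratio=np.array(d["explained_variance_ratio"]),
    )


def write_projections_csv(projections: list[EnsembleProjection], path: str | Path) -> None:
    rows = []
    for p in projections:
        for pid, coord in zip(p.particle_ids, p.coords):
            rows.append({"label": p.label, "particle_id": pid, **{f"pc{i + 1}": v for i, v in enumerate(coord)}})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_ellipse_json(ellipse: ConfidenceEllipse, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "center": ellipse.center.tolist(),
                "semi_axes": list(ellipse.semi_axes),
                "angle_rad": ellipse.angle_rad,
                "level": ellipse.level,
            }
        )
    )


def write_overlap_json(result, report, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "labels": list(result.labels),
                "ovl": result.ovl,
                "bhattacharyya": result.bhattacharyya,
                "independent": report.independent,
                "threshold": report.threshold,
                "centroid_distance": result.centroid_distance,
                "axis": result.axis.tolist(),
                "grid": result.grid.tolist(),
                "pdf_a": result.pdf_a.tolist(),
                "pdf_b": result.pdf_b.tolist(),
            }
        )
    )


# ---------------------------------------------------------------- pipeline

@dataclass
class RunConfig:
    """Configuration of a full simulate/load -> describe -> space -> overlap run.

    ``ensembles`` lists the inputs, each either
    ``{"label": ..., "preset": "star", "n_particles": 200, "seed": 1}`` or
    ``{"label": ..., "contours": "path.csv"}``.
    """

    out_dir: str
    ensembles: list = field(default_factory=list)
    n: int = 1024
    k: int = 512
    m: int = 3
    level: float = 0.95
    threshold: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if len(self.ensembles) < 1:
            raise ValueError("config lists no ensembles")
        for spec in self.ensembles:
            if "label" not in spec:
                raise ValueError(f"ensemble entry missing 'label': {spec}")
            if "contours" in spec:
                if not Path(spec["contours"]).exists():
                    raise ValueError(f"contour file not found: {spec['contours']}")
            elif "preset" in spec:
                if spec["preset"] not in PRESETS:
                    raise ValueError(
                        f"unknown preset {spec['preset']!r}; available: {sorted(PRESETS)}"
                    )
            else:
                raise ValueError(f"ensemble entry needs 'preset' or 'contours': {spec}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write versioned artifacts.

    Stages: obtain ensembles (synthetic preset or contour files) ->
    feature CSVs -> pooled shape-space model + projections -> pairwise
    overlap JSONs -> manifest (inputs, parameters, seed, package version,
    SHA-256 of every numeric output).  Identical config + seed reproduce
    identical hashes.  Returns the manifest dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ensembles: list[ShapeEnsemble] = []
    stage = "inputs"
    try:
        for i, spec in enumerate(config.ensembles):
            label = spec["label"]
            if "contours" in spec:
                contours = load_contours(spec["contours"])
            else:
                ep = PRESETS[spec["preset"]]
                ep = EnsembleParams(
                    mean=ep.mean,
                    cv=ep.cv,
                    n_particles=int(spec.get("n_particles", ep.n_particles)),
                    seed=int(spec.get("seed", config.seed + i)),
                )
                contours = generate_ensemble(ep)
            ensembles.append(ensemble_from_contours(label, contours, n=config.n, k=config.k))

        stage = "describe"
        feature_files = []
        for e in ensembles:
            fp = out / f"features_{e.label}.csv"
            write_features_csv(e, fp)
            feature_files.append(fp)

        stage = "space"
        model = fit_shape_space(ensembles)
        write_model_json(model, out / "model.json")
        m_eff = min(config.m, model.n_components)
        projections = [project_ensemble(model, e, m=m_eff) for e in ensembles]
        write_projections_csv(projections, out / "projections.csv")

        stage = "overlap"
        overlap_files = []
        for i in range(len(projections)):
            for j in range(i + 1, len(projections)):
                res = overlap_coefficient(projections[i], projections[j])
                rep = independence_test(res, threshold=config.threshold)
                fp = out / f"overlap_{projections[i].label}_{projections[j].label}.json"
                write_overlap_json(res, rep, fp)
                overlap_files.append(fp)
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    numeric = [*feature_files, out / "model.json", out / "projections.csv", *overlap_files]
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            "n": config.n,
            "k": config.k,
            "m": config.m,
            "level": config.level,
            "threshold": config.threshold,
        },
        "inputs": config.ensembles,
        "outputs": {p.name: _sha256(p) for p in numeric},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
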