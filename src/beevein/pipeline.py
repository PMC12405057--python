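"""End-to-end orchestration: images -> masks -> skeletons -> graphs ->
features -> anomaly filtering -> adaptive clustering, with every
intermediate persisted and a run manifest recording seeds and per-stage
counts."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .anomaly import build_report, iforest_flag, sigma_flag, train_cae
from .cae import DESK_CAE
from .clustering import cluster_features, profile_clusters
from .features import extract_feature_vector, feature_table
from .graph import VeinGraph, build_graph
from .io import load_image, save_mask, write_feature_table
from .preprocess import (
    CalibrationProfile,
    match_calibration,
    read_profiles,
    segment_image,
)
from .skeleton import zhang_suen_thin

__all__ = ["PipelineConfig", "run_pipeline", "process_image", "process_images"]

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass
class PipelineConfig:
    """Paths, stage toggles and parameters for a full run."""

    input_dir: Path
    output_dir: Path
    profiles_csv: Path | None = None
    profile: CalibrationProfile | None = None
    dark_veins: bool = True
    align: bool = False
    run_cae: bool = False
    run_anomaly: bool = True
    iforest_contamination: float = 0.007
    cluster_grid: tuple[float, ...] | None = None  # None: derive from the dendrogram
    n_folds: int = 5
    seed: int = 0


def process_image(
    img: np.ndarray,
    profile: CalibrationProfile,
    dark_veins: bool = True,
    align: bool = False,
) -> tuple[np.ndarray, np.ndarray, VeinGraph, np.ndarray]:
    """Single-image chain: returns (mask, skeleton, graph, 45-feature vector)."""
    mask = segment_image(img, profile, dark_veins=dark_veins, align=align)
    skel = zhang_suen_thin(mask)
    graph = build_graph(skel)
    if not mask.any():
        raise ValueError("segmentation produced an empty mask")
    return mask, skel, graph, extract_feature_vector(graph, mask)


def process_images(
    images: Sequence[np.ndarray],
    ids: Sequence[str],
    profile: CalibrationProfile,
    dark_veins: bool = True,
) -> pd.DataFrame:
    """Feature table for an in-memory image stack (no persistence)."""
    vectors = [process_image(im, profile, dark_veins=dark_veins)[3] for im in images]
    return feature_table(list(ids), vectors)


def _timed(label: str, start: float) -> None:
    logger.info("%s finished in %.2f s", label, time.perf_counter() - start)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline on every readable image in the input
    directory.  Persists masks, skeletons, graphs, the feature table, the
    anomaly report and cluster labels under the output directory, and
    returns the run manifest (also written as JSON).

    Unreadable images are skipped with a warning and listed in the
    manifest; if fewer than 2 images survive anomaly filtering, clustering
    is skipped with an explicit status."""
    out = Path(config.output_dir)
    for sub in ("masks", "skeletons", "graphs"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    paths = sorted(
        p for p in Path(config.input_dir).iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if len(paths) < 2:
        raise ValueError("need at least 2 input images")

    profiles = read_profiles(config.profiles_csv) if config.profiles_csv else None
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "skipped": [],
        "stages": {},
    }

    t0 = time.perf_counter()
    ids, images, vectors = [], [], []
    for p in paths:
        try:
            img = load_image(p)
        except Exception as exc:  # unreadable image: skip, record, continue
            logger.warning("skipping unreadable image %s: %s", p.name, exc)
            manifest["skipped"].append(p.name)
            continue
        profile = config.profile
        if profile is None:
            profile = (
                match_calibration(img, profiles) if profiles else CalibrationProfile()
            )
        mask, skel, graph, vec = process_image(
            img, profile, dark_veins=config.dark_veins, align=config.align
        )
        image_id = p.stem
        save_mask(mask, out / "masks" / f"{image_id}.png")
        save_mask(skel, out / "skeletons" / f"{image_id}.png")
        graph.to_json(out / "graphs" / f"{image_id}.json")
        ids.append(image_id)
        images.append(img)
        vectors.append(vec)
    _timed("preprocess+skeleton+graph+features", t0)

    table = feature_table(ids, vectors)
    write_feature_table(table, out / "features.csv")
    manifest["stages"]["input"] = len(paths)
    manifest["stages"]["featurized"] = len(ids)

    keep = np.ones(len(ids), dtype=bool)
    if config.run_anomaly:
        t0 = time.perf_counter()
        recon_errors = cae_flags = None
        if config.run_cae:
            _, recon_errors = train_cae(images, DESK_CAE)
            _, cae_flags = sigma_flag(recon_errors)
        scores, if_flags = iforest_flag(
            table,
            contamination=config.iforest_contamination,
            seed=config.seed,
        )
        report, summary = build_report(ids, recon_errors, cae_flags, scores, if_flags)
        report.to_csv(out / "anomaly.csv", index=False)
        (out / "anomaly_summary.json").write_text(json.dumps(summary, indent=2))
        keep = ~report["final_flag"].to_numpy()
        manifest["stages"]["anomaly_flagged"] = int((~keep).sum())
        _timed("anomaly filtering", t0)
    manifest["stages"]["retained"] = int(keep.sum())

    if keep.sum() < 2:
        manifest["clustering"] = "skipped: fewer than 2 images after filtering"
    else:
        t0 = time.perf_counter()
        x = table.loc[keep, list(table.columns[1:])].to_numpy()
        n_folds = max(2, min(config.n_folds, int(keep.sum()) // 2))
        result = cluster_features(
            x, config.cluster_grid, n_folds=n_folds, seed=config.seed
        )
        labels_df = pd.DataFrame(
            {"image_id": table.loc[keep, "image_id"], "cluster": result.labels}
        )
        labels_df.to_csv(out / "clusters.csv", index=False)
        result.metrics_table.to_csv(out / "cluster_metrics.csv", index=False)
        summary, _ = profile_clusters(table.loc[keep], result.labels)
        summary.to_csv(out / "cluster_profiles.csv", index=False)
        manifest["clustering"] = {
            "k": result.k,
            "threshold": result.threshold,
            "silhouette": result.silhouette,
            "dbi": result.dbi,
            "ch": result.ch,
        }
        _timed("clustering", t0)

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
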