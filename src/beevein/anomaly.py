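"""Two-stage anomaly filtering for wing cohorts.

Stage 1 screens raw images by convolutional-autoencoder reconstruction
error: errors above mu + 3*sigma of the cohort's error distribution flag
gross technical artifacts (tears, occlusions, heavy blur).  Stage 2 runs
an isolation forest on the 45-dimensional venation feature vectors to
catch subtler structural distortions the reconstruction misses.  An image
is removed iff either stage flags it; natural phenotypic variation is
preserved because both stages score deviation from the cohort, not from a
fixed template.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

from .cae import DESK_CAE, CAEConfig, ConvAutoencoder

__all__ = [
    "AnomalyThresholdModel",
    "train_cae",
    "sigma_flag",
    "iforest_flag",
    "build_report",
]


@dataclass(frozen=True)
class AnomalyThresholdModel:
    """The 3-sigma rule on reconstruction errors: threshold = mu + 3*sigma."""

    mu: float
    sigma: float

    @property
    def threshold(self) -> float:
        return self.mu + 3.0 * self.sigma


def train_cae(
    images: "list[np.ndarray]", config: CAEConfig = DESK_CAE
) -> tuple[ConvAutoencoder, np.ndarray]:
    """Train the autoencoder on a cohort and return it with the per-image
    reconstruction errors.  All images must share one shape (they are
    resized to the configured square input)."""
    if len(images) < 10:
        raise ValueError("need at least 10 images")
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"images have mixed shapes {sorted(shapes)}; resize them first")
    model = ConvAutoencoder(config)
    model.fit(images)
    return model, model.reconstruction_errors(images)


def sigma_flag(errors: np.ndarray) -> tuple[AnomalyThresholdModel, np.ndarray]:
    """Flag samples whose reconstruction error strictly exceeds
    mu + 3*sigma (population statistics over the cohort)."""
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size < 2:
        raise ValueError("need at least 2 errors to estimate sigma")
    model = AnomalyThresholdModel(mu=float(errors.mean()), sigma=float(errors.std()))
    return model, errors > model.threshold


def iforest_flag(
    features: "pd.DataFrame | np.ndarray",
    n_trees: int = 100,
    contamination: float = 0.007,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Isolation-forest anomaly scores on 45-dim feature vectors; the top
    ceil(contamination * n) scores are flagged.  Deterministic given the
    seed; higher score = more anomalous."""
    if isinstance(features, pd.DataFrame):
        x = features.drop(columns=["image_id"], errors="ignore").to_numpy(dtype=np.float64)
        ids = features.get("image_id")
    else:
        x = np.asarray(features, dtype=np.float64)
        ids = None
    if x.ndim != 2 or x.shape[1] != 45:
        raise ValueError(f"expected an n x 45 feature matrix, got {x.shape}")
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    bad = ~np.isfinite(x).all(axis=1)
    if bad.any():
        offenders = (
            list(ids[bad]) if ids is not None else np.nonzero(bad)[0].tolist()
        )
        raise ValueError(f"non-finite features for: {offenders}")

    forest = IsolationForest(n_estimators=n_trees, random_state=seed)
    forest.fit(x)
    scores = -forest.score_samples(x)  # higher = more isolated
    n_flag = math.ceil(contamination * len(x))
    # deterministic top-k: sort by (-score, index)
    order = np.lexsort((np.arange(len(x)), -scores))
    flags = np.zeros(len(x), dtype=bool)
    flags[order[:n_flag]] = True
    return scores, flags


def build_report(
    image_ids: "list[str]",
    recon_errors: np.ndarray | None,
    cae_flags: np.ndarray | None,
    iforest_scores: np.ndarray,
    iforest_flags: np.ndarray,
) -> tuple[pd.DataFrame, dict]:
    """Combine stage outputs into the per-image report and the stage-count
    summary.  The final flag is the OR of the stage flags."""
    n = len(image_ids)
    if recon_errors is None:
        recon_errors = np.full(n, np.nan)
        cae_flags = np.zeros(n, dtype=bool)
    final = np.asarray(cae_flags, bool) | np.asarray(iforest_flags, bool)
    report = pd.DataFrame(
        {
            "image_id": image_ids,
            "recon_error": recon_errors,
            "cae_flag": np.asarray(cae_flags, bool),
            "iforest_score": iforest_scores,
            "iforest_flag": np.asarray(iforest_flags, bool),
            "final_flag": final,
        }
    )
    summary = {
        "total": n,
        "cae_flagged": int(report["cae_flag"].sum()),
        "iforest_flagged": int(report["iforest_flag"].sum()),
        "final_flagged": int(final.sum()),
        "remaining": int(n - final.sum()),
    }
    return report, summary


def write_report(
    report: pd.DataFrame, summary: dict, csv_path: str | Path, json_path: str | Path
) -> None:
    report.to_csv(csv_path, index=False)
    Path(json_path).write_text(json.dumps(summary, indent=2))
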