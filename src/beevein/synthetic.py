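"""Synthetic wing-venation images with exact ground truth.

Real forewing photographs show a fan of longitudinal veins radiating from
the wing base, tied together by short cross-veins; the vein network is dark
against a pale, translucent membrane.  This module rasterizes such networks
from analytic curves, so the true vein mask, junction coordinates and
endpoint coordinates are known exactly, and every downstream stage
(segmentation, thinning, graph extraction, anomaly filtering, clustering)
can be validated without photographic data.

Longitudinal veins are quadratic Bezier curves branching off a short
vertical basal stalk at separated attachment points and sharing a common
horizontal span; vertical profiles interpolate between ordered attachment
and distal rows through a shared bow shape with a small per-curve
perturbation bounded so that curves never cross.  Cross-veins are straight
chords between consecutive longitudinal veins with stereotyped counts and
positions (venation is homologous: wings of one regime share a vein plan,
and only geometry jitter distinguishes them).  Junction ground truth is
the set of pairwise analytic curve
intersections (each stalk attachment is one such intersection),
deduplicated by centroid merging at 2 px.  A stalk rather than a single
basal fan point keeps the rasterized network consistent with the analytic
truth: curves meeting at one point fuse into a solid wedge at any finite
stroke width, and thinning then forks them at stroke-dependent positions
no analytic ground truth could predict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk as disk_footprint

from .graph import merge_points

__all__ = [
    "SyntheticWingSpec",
    "GroundTruth",
    "CohortDataset",
    "STUDY_REGIMES",
    "make_wing",
    "degrade",
    "inject_anomaly",
    "generate_cohort",
    "write_cohort",
]

_VEIN_VALUE = 0.12  # intensity of vein centerlines (dark)
_BACKGROUND_VALUE = 0.92  # membrane intensity (pale)
_CURVE_SAMPLES = 700
_JUNCTION_MERGE_RADIUS = 2.0


@dataclass(frozen=True)
class SyntheticWingSpec:
    """Full description of one synthetic wing; spec + seed determine all outputs.

    ``cross_vein_rate`` is the expected number of cross-veins per pair of
    consecutive longitudinal veins (realized as a stereotyped count, see
    module docstring).  Degradation fields
    (``noise_sigma``, ``dust_count``, ``illumination_slope``, ``blur_sigma``)
    apply in :func:`degrade`, not in :func:`make_wing`.
    """

    n_longitudinal: int = 6
    cross_vein_rate: float = 1.2
    stroke_width: int = 3
    image_size: tuple[int, int] = (384, 512)  # (rows, cols)
    noise_sigma: float = 0.03
    dust_count: int = 10
    illumination_slope: float = 0.12
    blur_sigma: float = 0.0
    anomaly: Literal["none", "tear", "occlusion"] = "none"
    regime_label: str = "medium"
    seed: int = 0
    invert_polarity: bool = False

    def validate(self) -> None:
        rows, cols = self.image_size
        if self.n_longitudinal < 1:
            raise ValueError("n_longitudinal must be >= 1")
        if self.cross_vein_rate < 0:
            raise ValueError("cross_vein_rate must be >= 0")
        if self.stroke_width < 1:
            raise ValueError("stroke_width must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.dust_count < 0:
            raise ValueError("dust_count must be >= 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.anomaly not in ("none", "tear", "occlusion"):
            raise ValueError(f"unknown anomaly kind: {self.anomaly!r}")
        if rows < 32 or cols < 32:
            raise ValueError("image_size must be at least 32x32")
        # the fan spans ~80% of the image height; each vein needs clearance
        sep = 0.8 * rows / max(self.n_longitudinal - 1, 1)
        if self.n_longitudinal > 1 and sep < self.stroke_width + 2:
            raise ValueError(
                f"image too small to fit {self.n_longitudinal} longitudinal "
                f"veins of stroke width {self.stroke_width} in {rows} rows"
            )


@dataclass
class GroundTruth:
    """Exact reference data for one synthetic wing."""

    vein_mask: np.ndarray  # bool, same shape as image
    junctions: list[tuple[float, float]]  # (row, col)
    endpoints: list[tuple[float, float]]
    regime_label: str
    is_anomalous: bool


# Canonical study regimes: three venation-density phenotypes mirroring the
# dense-to-sparse contrast seen between honey-bee lineages.
STUDY_REGIMES: dict[str, SyntheticWingSpec] = {
    "sparse": SyntheticWingSpec(n_longitudinal=5, cross_vein_rate=0.5, regime_label="sparse"),
    "medium": SyntheticWingSpec(n_longitudinal=6, cross_vein_rate=1.2, regime_label="medium"),
    "dense": SyntheticWingSpec(n_longitudinal=7, cross_vein_rate=2.0, regime_label="dense"),
}


def _sample_curves(
    spec: SyntheticWingSpec, rng: np.random.Generator
) -> tuple[np.ndarray | None, list[np.ndarray], list[np.ndarray]]:
    """Analytic polylines (N x 2 float arrays of (row, col)): the basal
    stalk (None when n_longitudinal == 1), the longitudinal veins, and the
    cross-veins."""
    rows, cols = spec.image_size
    c0 = 0.06 * cols
    c1 = 0.94 * cols
    n = spec.n_longitudinal

    # stalk attachment rows (near mid-height) and distal row targets,
    # jittered but kept strictly ordered so curves never cross
    if n > 1:
        att = np.linspace(0.38 * rows, 0.62 * rows, n)
        att_sep = float(att[1] - att[0])
        att = np.sort(att + rng.uniform(-0.07 * att_sep, 0.07 * att_sep, size=n))
        base = np.linspace(0.10 * rows, 0.90 * rows, n)
        end_sep = float(base[1] - base[0])
        ends = np.sort(base + rng.uniform(-0.1 * end_sep, 0.1 * end_sep, size=n))
    else:
        att = np.array([0.5 * rows])
        ends = np.array([rng.uniform(0.25, 0.75) * rows])
        att_sep = end_sep = 0.3 * rows

    bow = rng.uniform(0.34, 0.46)  # shared bow of the fan (wing shape is conserved)
    # per-curve bow perturbation, bounded so ordering is preserved
    eps_bound = 0.05 * min(att_sep, end_sep) / max(rows, 1)
    eps = rng.uniform(-eps_bound, eps_bound, size=n)

    t = np.linspace(0.0, 1.0, _CURVE_SAMPLES)
    curves = []
    for i in range(n):
        g = t + (bow + eps[i]) * t * (1.0 - t)
        r = att[i] * (1.0 - g) + ends[i] * g
        c = c0 + (c1 - c0) * t
        curves.append(np.column_stack([r, c]))

    stalk = None
    if n > 1:
        stub = max(6.0, 0.02 * rows)
        stalk = np.array([[att[0] - stub, c0], [att[-1] + stub, c0]])

    # Cross-vein counts and positions are stereotyped, like the homologous
    # cross-veins of real wings: the wing carries round(rate * pairs)
    # cross-veins, spread as evenly as possible over the pairs, each in an
    # evenly spaced span slot with small positional jitter.  Only geometry
    # jitter varies between wings of one regime.
    cross = []
    n_pairs = n - 1
    total = int(round(spec.cross_vein_rate * n_pairs))
    base, extra = divmod(total, max(n_pairs, 1))
    # distribute the remainder over alternating pairs, outermost first
    counts = [base] * n_pairs
    for idx, i in enumerate(list(range(0, n_pairs, 2)) + list(range(1, n_pairs, 2))):
        if idx < extra:
            counts[i] += 1
    for i in range(n_pairs):
        k = counts[i]
        for j in range(k):
            slot = 0.25 + 0.67 * (j + 0.5 + 0.5 * (i % 2)) / max(k + 0.5, 1.0)
            t1 = float(np.clip(slot + rng.normal(0.0, 0.012), 0.22, 0.94))
            t2 = float(np.clip(t1 + rng.normal(0.0, 0.02), 0.2, 0.95))
            i1 = int(round(t1 * (_CURVE_SAMPLES - 1)))
            i2 = int(round(t2 * (_CURVE_SAMPLES - 1)))
            p, q = curves[i][i1], curves[i + 1][i2]
            cross.append(np.array([p, q]))
    return stalk, curves, cross


def _rasterize(curves: Sequence[np.ndarray], spec: SyntheticWingSpec) -> np.ndarray:
    rows, cols = spec.image_size
    mask = np.zeros((rows, cols), dtype=bool)
    for poly in curves:
        pts = np.round(poly).astype(int)
        pts[:, 0] = np.clip(pts[:, 0], 0, rows - 1)
        pts[:, 1] = np.clip(pts[:, 1], 0, cols - 1)
        for (r1, c1), (r2, c2) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(r1, c1, r2, c2)
            mask[rr, cc] = True
    radius = (spec.stroke_width - 1) // 2
    if radius > 0:
        mask = ndimage.binary_dilation(mask, structure=disk_footprint(radius))
    return mask


def _analytic_junctions(
    stalk: np.ndarray | None,
    curves: Sequence[np.ndarray],
    cross: Sequence[np.ndarray],
) -> list[tuple[float, float]]:
    """Pairwise analytic intersections of all vein curves, merged at 2 px.

    Longitudinal veins never cross each other by construction; every stalk
    attachment and every cross-vein endpoint is a touching intersection."""
    polys = ([] if stalk is None else [stalk]) + list(curves) + list(cross)
    n_structural = (0 if stalk is None else 1) + len(curves)
    lines = [LineString(np.column_stack([p[:, 1], p[:, 0]])) for p in polys]  # (x=col, y=row)
    pts: list[tuple[float, float]] = []
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            if stalk is not None and 0 < i < n_structural and j < n_structural:
                continue  # longitudinal pairs are disjoint by construction
            if stalk is None and i < n_structural and j < n_structural:
                continue
            inter = lines[i].intersection(lines[j])
            if inter.is_empty:
                continue
            geoms = getattr(inter, "geoms", [inter])
            for g in geoms:
                if g.geom_type == "Point":
                    cand = [(g.y, g.x)]
                else:  # grazing overlap: take representative vertices
                    cand = [(y, x) for x, y in np.asarray(g.coords)]
                pts.extend((float(r), float(c)) for r, c in cand)
    return merge_points(pts, radius=_JUNCTION_MERGE_RADIUS)


def _snap_to_mask(
    points: Sequence[tuple[float, float]], mask: np.ndarray, max_dist: float = 3.0
) -> list[tuple[float, float]]:
    """Keep points on (or snapped within max_dist of) the rasterized mask."""
    if not len(points):
        return []
    fg = np.argwhere(mask)
    out = []
    for r, c in points:
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1] and mask[ri, ci]:
            out.append((float(r), float(c)))
            continue
        if len(fg):
            d = np.hypot(fg[:, 0] - r, fg[:, 1] - c)
            k = int(np.argmin(d))
            if d[k] <= max_dist:
                out.append((float(fg[k, 0]), float(fg[k, 1])))
    return out


def make_wing(spec: SyntheticWingSpec) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize a clean synthetic wing and its exact ground truth.

    Returns a float image in [0, 1] (dark veins on a pale background, or the
    inverse when ``spec.invert_polarity``) together with the ground-truth
    mask, junction and endpoint coordinates.  If ``spec.anomaly`` is not
    ``"none"``, the corresponding defect is injected and the ground truth is
    updated consistently.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size

    stalk, curves, cross = _sample_curves(spec, rng)
    all_polys = ([] if stalk is None else [stalk]) + curves + cross
    mask = _rasterize(all_polys, spec)

    junctions = _analytic_junctions(stalk, curves, cross)
    # endpoints: distal curve ends, plus stalk tips (or the lone curve's start)
    endpoints = [tuple(c[-1]) for c in curves]
    if stalk is None:
        endpoints.append(tuple(curves[0][0]))
    else:
        endpoints.extend([tuple(stalk[0]), tuple(stalk[1])])

    img = np.full((rows, cols), _BACKGROUND_VALUE, dtype=np.float64)
    soft = ndimage.gaussian_filter(mask.astype(np.float64), 0.6)
    img -= (_BACKGROUND_VALUE - _VEIN_VALUE) * np.clip(soft, 0.0, 1.0)
    img = np.clip(img, 0.0, 1.0)

    if spec.anomaly != "none":
        img, mask = inject_anomaly(img, mask, spec.anomaly, seed=spec.seed + 1)

    junctions = _snap_to_mask(junctions, mask)
    endpoints = _snap_to_mask(endpoints, mask)

    if spec.invert_polarity:
        img = 1.0 - img

    gt = GroundTruth(
        vein_mask=mask,
        junctions=junctions,
        endpoints=endpoints,
        regime_label=spec.regime_label,
        is_anomalous=spec.anomaly != "none",
    )
    return img, gt


def degrade(img: np.ndarray, spec: SyntheticWingSpec) -> np.ndarray:
    """Apply acquisition artifacts: illumination gradient, Gaussian noise,
    dust impulses, and optional blur.  Output clipped to [0, 1]."""
    if spec.noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    img = np.asarray(img, dtype=np.float64)
    rows, cols = img.shape
    rng = np.random.default_rng(spec.seed + 1000)

    out = img.copy()
    if spec.illumination_slope != 0.0:
        ramp = spec.illumination_slope * (np.arange(cols) / max(cols - 1, 1) - 0.5)
        out = out + ramp[None, :]
    if spec.noise_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape)
    for _ in range(spec.dust_count):
        r = rng.integers(2, rows - 2)
        c = rng.integers(2, cols - 2)
        radius = int(rng.integers(1, 3))
        value = 0.05 if rng.random() < 0.5 else 0.98
        rr, cc = draw_disk((r, c), radius, shape=out.shape)
        out[rr, cc] = value
    if spec.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, spec.blur_sigma)
    return np.clip(out, 0.0, 1.0)


def inject_anomaly(
    img: np.ndarray,
    mask: np.ndarray,
    kind: str,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Damage a wing image: a ``tear`` removes a wedge of the wing; an
    ``occlusion`` overlays an opaque blob.  The vein mask is updated so that
    veins no longer visible are no longer foreground."""
    if kind not in ("tear", "occlusion"):
        raise ValueError(f"unknown anomaly kind: {kind!r}")
    img = np.asarray(img, dtype=np.float64).copy()
    mask = np.asarray(mask, dtype=bool).copy()
    rows, cols = img.shape
    rng = np.random.default_rng(seed)
    fg = np.argwhere(mask)
    if len(fg) == 0:
        raise ValueError("cannot inject an anomaly into an empty wing")

    if kind == "tear":
        # wedge from the right border toward the wing interior
        apex = fg[rng.integers(len(fg))]
        base_r = int(rng.uniform(0.2, 0.8) * rows)
        half = int(rng.uniform(0.10, 0.18) * rows)
        rr, cc = draw_polygon(
            [base_r - half, base_r + half, apex[0]],
            [cols - 1, cols - 1, apex[1]],
            shape=img.shape,
        )
        img[rr, cc] = _BACKGROUND_VALUE + 0.03
        mask[rr, cc] = False
    else:
        center = fg[rng.integers(len(fg))]
        radius = int(rng.integers(18, 30))
        rr, cc = draw_disk(tuple(center), radius, shape=img.shape)
        img[rr, cc] = 0.06
        mask[rr, cc] = False
    return np.clip(img, 0.0, 1.0), mask


@dataclass
class CohortDataset:
    """In-memory synthetic cohort: degraded images, ground truths, manifest."""

    images: list[np.ndarray]
    clean_images: list[np.ndarray]
    ground_truths: list[GroundTruth]
    manifest: pd.DataFrame = field(repr=False)


def generate_cohort(
    regimes: Sequence[SyntheticWingSpec],
    n_per_regime: int,
    anomaly_fraction: float = 0.0,
    seed: int = 0,
) -> CohortDataset:
    """Deterministic cohort of degraded wings spanning several regimes.

    Anomalies (alternating tears and occlusions) are spread uniformly across
    regimes; the manifest records id, regime, anomaly status and per-image
    seed for exact reproduction.
    """
    if not regimes:
        raise ValueError("regime list must not be empty")
    if n_per_regime < 1:
        raise ValueError("n_per_regime must be >= 1")
    if not 0.0 <= anomaly_fraction < 1.0:
        raise ValueError("anomaly_fraction must be in [0, 1)")

    total = len(regimes) * n_per_regime
    n_anom = int(round(anomaly_fraction * total))
    # spread anomalies uniformly: round-robin over regimes
    per_regime_anom = [n_anom // len(regimes)] * len(regimes)
    for i in range(n_anom - sum(per_regime_anom)):
        per_regime_anom[i % len(regimes)] += 1

    rng = np.random.default_rng(seed)
    images, clean, gts, rows = [], [], [], []
    anomaly_cycle = ["tear", "occlusion"]
    idx = 0
    for r_i, regime in enumerate(regimes):
        anom_slots = set(rng.choice(n_per_regime, size=per_regime_anom[r_i], replace=False))
        for j in range(n_per_regime):
            child_seed = int((seed * 100003 + idx * 7919 + 13) % (2**31 - 1))
            kind = anomaly_cycle[idx % 2] if j in anom_slots else "none"
            spec = replace(regime, seed=child_seed, anomaly=kind)
            img, gt = make_wing(spec)
            deg = degrade(img, spec)
            images.append(deg)
            clean.append(img)
            gts.append(gt)
            rows.append(
                {
                    "image_id": f"wing_{idx:04d}",
                    "path": f"images/wing_{idx:04d}.png",
                    "regime_label": regime.regime_label,
                    "is_anomalous": kind != "none",
                    "seed": child_seed,
                }
            )
            idx += 1
    manifest = pd.DataFrame(rows)
    return CohortDataset(images=images, clean_images=clean, ground_truths=gts, manifest=manifest)


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Persist a cohort: PNG images, PNG masks, JSON ground-truth sidecars,
    and a CSV manifest.  Returns the output directory."""
    from .io import save_image, save_mask

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    for row, img, gt in zip(
        dataset.manifest.itertuples(index=False), dataset.images, dataset.ground_truths
    ):
        save_image(img, out / "images" / f"{row.image_id}.png")
        save_mask(gt.vein_mask, out / "truth" / f"{row.image_id}_mask.png")
        sidecar = {
            "junctions": [list(p) for p in gt.junctions],
            "endpoints": [list(p) for p in gt.endpoints],
            "regime_label": gt.regime_label,
            "is_anomalous": gt.is_anomalous,
        }
        (out / "truth" / f"{row.image_id}.json").write_text(json.dumps(sidecar))
    dataset.manifest.to_csv(out / "manifest.csv", index=False)
    return out
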