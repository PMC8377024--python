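"""Gaussian heatmap targets and peak decoding.

Each consensus centre point is rendered onto its class channel as an
isotropic 2-D Gaussian ``K(x, y) = exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma^2))``
whose spread is the class radius (rescaled to heatmap resolution).
Overlapping kernels combine by element-wise maximum so every centre keeps a
peak of exactly 1. Decoding thresholds each channel, groups supra-threshold
pixels into connected components and emits one prediction per admissible
cluster at its maximum-valued pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.measure import label as cc_label

from .annotations import AnnotationSet, CentreAnnotation, ClassConfig, class_config_map
from .errors import ConfigError, ValidationError

#: Kernel support truncation, in units of sigma. Beyond this the Gaussian is
#: below 3.4e-4 and is written as exactly 0.
KERNEL_TRUNCATION_SIGMAS = 4.0


@dataclass
class HeatmapTensor:
    """H x W x C array of values in [0, 1]; target ``Y`` or prediction ``Y_hat``.

    ``scale_factor`` is native px per heatmap px (4 for 1024 -> 256).
    """

    values: np.ndarray  # (H, W, C) float
    classes: tuple[str, ...]
    scale_factor: float
    tile_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError("heatmap values must be a (H, W, C) array")
        if self.values.shape[2] != len(self.classes):
            raise ValidationError(
                f"{self.values.shape[2]} channels != {len(self.classes)} classes"
            )
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValidationError("heatmap values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def channel(self, cell_class: str) -> np.ndarray:
        return self.values[:, :, self.classes.index(cell_class)]


@dataclass(frozen=True)
class Prediction:
    """A decoded centre point at native tile scale with a confidence score."""

    x: float
    y: float
    cell_class: str
    score: float
    tile_id: str = ""


def encode_targets(
    consensus: AnnotationSet,
    classes: Sequence[ClassConfig],
    out_size: int = 256,
    scale_factor: float | None = None,
) -> HeatmapTensor:
    """Render centre-point annotations into a per-class Gaussian heatmap.

    Kernels are evaluated at the real-valued rescaled centre (no rounding),
    truncated at 4 sigma, and combined by element-wise max. The pixel onto
    which each centre maps (nearest pixel) is forced to exactly 1 so the
    positive branch of the focal loss can identify centres by equality.
    """
    if scale_factor is None:
        scale_factor = consensus.tile_width / out_size
    if abs(out_size * scale_factor - consensus.tile_width) > 1e-6:
        raise ConfigError(
            f"out_size {out_size} x scale_factor {scale_factor} != tile width "
            f"{consensus.tile_width}"
        )
    sigma_by_class = {c.cell_class: c.sigma_px for c in classes}
    names = tuple(c.cell_class for c in classes)
    values = np.zeros((out_size, out_size, len(classes)), dtype=np.float64)
    for ann in consensus:
        if ann.cell_class not in sigma_by_class:
            raise ValidationError(f"annotation class {ann.cell_class!r} not configured")
        sigma = sigma_by_class[ann.cell_class] / scale_factor
        if sigma <= 0:
            raise ConfigError(f"non-positive sigma for class {ann.cell_class!r}")
        ch = names.index(ann.cell_class)
        x0 = ann.x / scale_factor
        y0 = ann.y / scale_factor
        r = KERNEL_TRUNCATION_SIGMAS * sigma
        xlo, xhi = int(np.floor(x0 - r)), int(np.ceil(x0 + r))
        ylo, yhi = int(np.floor(y0 - r)), int(np.ceil(y0 + r))
        xlo, xhi = max(xlo, 0), min(xhi, out_size - 1)
        ylo, yhi = max(ylo, 0), min(yhi, out_size - 1)
        if xlo > xhi or ylo > yhi:
            continue
        xs = np.arange(xlo, xhi + 1, dtype=np.float64)
        ys = np.arange(ylo, yhi + 1, dtype=np.float64)
        d2 = (xs[None, :] - x0) ** 2 + (ys[:, None] - y0) ** 2
        kernel = np.exp(-d2 / (2.0 * sigma * sigma))
        kernel[d2 > r * r] = 0.0
        window = values[ylo : yhi + 1, xlo : xhi + 1, ch]
        np.maximum(window, kernel, out=window)
        px, py = int(round(x0)), int(round(y0))
        if 0 <= px < out_size and 0 <= py < out_size:
            values[py, px, ch] = 1.0
    return HeatmapTensor(values, names, scale_factor, consensus.tile_id)


def decode_peaks(
    heatmap: HeatmapTensor,
    score_threshold: float = 0.5,
    max_cluster_area: int = 16,
    connectivity: int = 8,
    oversized: str = "split",
    classes: Sequence[ClassConfig] | None = None,
    min_peak_separation: float = 3.0,
) -> list[Prediction]:
    """Extract centre-point predictions from a heatmap.

    Per channel, pixels with value > ``score_threshold`` form connected
    components (8-connectivity by default). Each component of area at most
    ``max_cluster_area`` yields one prediction at its maximum-valued pixel
    (lowest (y, x) on ties), with the maximum as the score, rescaled to
    native coordinates. Oversized components are split into regional maxima
    separated by at least one class radius (``oversized="split"``) or
    discarded (``oversized="strict"``).
    """
    if connectivity not in (4, 8):
        raise ConfigError("connectivity must be 4 or 8")
    if oversized not in ("split", "strict"):
        raise ConfigError("oversized must be 'split' or 'strict'")
    cfg_map = class_config_map(classes) if classes is not None else {}
    skimage_conn = 2 if connectivity == 8 else 1
    preds: list[Prediction] = []
    for ch, name in enumerate(heatmap.classes):
        plane = heatmap.values[:, :, ch]
        mask = plane > score_threshold
        if not mask.any():
            continue
        labels, n_comp = cc_label(mask, connectivity=skimage_conn, return_num=True)
        if name in cfg_map:
            sep = max(1, int(round(cfg_map[name].diameter_px / 2.0 / heatmap.scale_factor)))
        else:
            sep = max(1, int(round(min_peak_separation)))
        for comp in range(1, n_comp + 1):
            comp_mask = labels == comp
            area = int(comp_mask.sum())
            if area <= max_cluster_area:
                peak_pixels = _component_argmax(plane, comp_mask)
            elif oversized == "strict":
                continue
            else:
                peak_pixels = _regional_maxima(plane, comp_mask, sep)
            for (py, px) in peak_pixels:
                preds.append(
                    Prediction(
                        x=px * heatmap.scale_factor,
                        y=py * heatmap.scale_factor,
                        cell_class=name,
                        score=float(plane[py, px]),
                        tile_id=heatmap.tile_id,
                    )
                )
    return preds


def _component_argmax(plane: np.ndarray, comp_mask: np.ndarray) -> list[tuple[int, int]]:
    ys, xs = np.nonzero(comp_mask)
    vals = plane[ys, xs]
    best = vals.max()
    cand = np.flatnonzero(vals == best)
    # lowest (y, x) lexicographic pixel wins; nonzero already scans row-major
    return [(int(ys[cand[0]]), int(xs[cand[0]]))]


def _regional_maxima(
    plane: np.ndarray, comp_mask: np.ndarray, separation: int
) -> list[tuple[int, int]]:
    """Local maxima within a component, at least ``separation`` px apart."""
    size = 2 * separation + 1
    local_max = plane == ndimage.maximum_filter(plane, size=size, mode="constant")
    ys, xs = np.nonzero(local_max & comp_mask)
    order = np.argsort(-plane[ys, xs], kind="stable")
    kept: list[tuple[int, int]] = []
    for i in order:
        p = (int(ys[i]), int(xs[i]))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= separation**2 for q in kept):
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_heatmap(heatmap: HeatmapTensor, path: str | Path) -> None:
    """Write a multi-page TIFF (one page per class) plus a JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(heatmap.values.astype(np.float32), -1, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "classes": list(heatmap.classes),
        "scale_factor": heatmap.scale_factor,
        "tile_id": heatmap.tile_id,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_heatmap(path: str | Path) -> HeatmapTensor:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = np.moveaxis(np.atleast_3d(pages), 0, -1)
    return HeatmapTensor(
        values, tuple(meta["classes"]), float(meta["scale_factor"]), meta.get("tile_id", "")
    )


def predictions_to_frame(preds: Sequence[Prediction]) -> pd.DataFrame:
    rows = [(p.tile_id, p.x, p.y, p.cell_class, "model", p.score) for p in preds]
    return pd.DataFrame(rows, columns=["tile_id", "x", "y", "cell_class", "assessor_id", "score"])


def write_predictions(preds: Sequence[Prediction], path: str | Path) -> None:
    predictions_to_frame(preds).to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[Prediction]:
    df = pd.read_csv(path)
    return [
        Prediction(float(r.x), float(r.y), str(r.cell_class), float(r.score), str(r.tile_id))
        for r in df.itertuples(index=False)
    ]


def predictions_to_set(
    preds: Sequence[Prediction], tile_width: int, tile_height: int, tile_id: str | None = None
) -> AnnotationSet:
    """View predictions as an annotation set (for differential counting)."""
    tid = tile_id if tile_id is not None else (preds[0].tile_id if preds else "")
    s = AnnotationSet(tid, tile_width, tile_height)
    for p in preds:
        x = min(max(p.x, 0.0), np.nextafter(tile_width, 0))
        y = min(max(p.y, 0.0), np.nextafter(tile_height, 0))
        s.add(CentreAnnotation(tid, x, y, p.cell_class, "model"))
    return s
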