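"""Seeded generator of cytospin-like RGB tiles with exact ground truth.

The appearance model is deliberately stylised — flat-shaded cell bodies with
class-specific colour, nuclear lobe count and size distributions, plus
debris specks and mucus smears — because the test surface needs controllable
geometry and class-separable features rather than photorealism. Identical
(config, seed) pairs produce bitwise-identical tiles and annotations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .annotations import (
    CELL_CLASSES,
    AnnotationSet,
    CentreAnnotation,
    annotations_from_frame,
    write_annotations,
)
from .errors import ConfigError, CytopointError, ValidationError

#: Default class mix (fractions of labelled cells). The reference fractions
#: (45.4 / 45.35 / 4.2 / 5.07 %) sum to 100.02%, so they are normalised here
#: to satisfy the sum-to-1 invariant.
_RAW_MIX = {
    "macrophage_lineage": 0.454,
    "neutrophil": 0.4535,
    "eosinophil": 0.042,
    "lymphocyte": 0.0507,
}
DEFAULT_CLASS_MIX: dict[str, float] = {
    c: v / sum(_RAW_MIX.values()) for c, v in _RAW_MIX.items()
}

#: (median, q1, q3) longest-span diameters in px at 1024-px tile scale.
DEFAULT_DIAMETER_QUARTILES: dict[str, tuple[float, float, float]] = {
    "macrophage_lineage": (142.0, 114.0, 183.0),
    "neutrophil": (104.0, 92.0, 114.0),
    "eosinophil": (126.0, 101.0, 142.0),
    "lymphocyte": (61.0, 53.0, 68.5),
}

PALETTES = {
    # pale blue-violet background, strong purple nuclei
    "kwik_diff": {"background": (0.92, 0.90, 0.95), "tint": (1.0, 1.0, 1.0)},
    # May-Gruenwald-Giemsa: warmer, pinker field
    "mgg": {"background": (0.95, 0.89, 0.92), "tint": (1.03, 0.97, 1.0)},
}

_CELL_STYLE = {
    "macrophage_lineage": {
        "cytoplasm": (0.76, 0.72, 0.86),
        "nucleus": (0.40, 0.26, 0.56),
        "lobes": 1,
        "nucleus_frac": 0.38,
    },
    "neutrophil": {
        "cytoplasm": (0.88, 0.79, 0.85),
        "nucleus": (0.36, 0.22, 0.52),
        "lobes": 3,
        "nucleus_frac": 0.24,
    },
    "eosinophil": {
        "cytoplasm": (0.86, 0.45, 0.38),
        "nucleus": (0.40, 0.23, 0.52),
        "lobes": 2,
        "nucleus_frac": 0.28,
    },
    "lymphocyte": {
        "cytoplasm": (0.72, 0.62, 0.82),
        "nucleus": (0.44, 0.28, 0.60),
        "lobes": 1,
        "nucleus_frac": 0.78,
    },
}


@dataclass
class SceneConfig:
    tile_size: int = 1024
    mean_objects: float = 15.0
    min_objects: int = 0
    max_objects: int = 43
    class_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    diameter_quartiles: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DIAMETER_QUARTILES)
    )
    #: None -> pairwise rule: 0.4 x the smaller of the two cells' diameters
    min_separation: float | None = None
    debris_mean: float = 8.0
    mucus_prob: float = 0.3
    palette: str = "kwik_diff"
    #: multiplicative per-cytospin stain jitter (applied to the whole tile)
    style_tint: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.015
    margin_frac: float = 0.05
    fixed_count: int | None = None  # overrides the count distribution

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class mix sums to {total}, not 1")
        if self.min_separation is not None and self.min_separation <= 0:
            raise ConfigError("min_separation must be > 0")
        if self.palette not in PALETTES:
            raise ConfigError(f"unknown palette {self.palette!r}")

    @property
    def scale(self) -> float:
        """Native px per 1024-reference px (diameters scale with tile size)."""
        return self.tile_size / 1024.0


@dataclass
class SyntheticTile:
    image: np.ndarray  # (S, S, 3) uint8
    truth: AnnotationSet
    config: SceneConfig
    seed: int


def _disk_window(shape, cx, cy, rx, ry, soft=1.5):
    """Soft-edged ellipse mask on a local window: ((yslice, xslice), mask)."""
    pad = max(rx, ry) + 0.5 * soft + 2.0
    y0, y1 = max(0, int(cy - pad)), min(shape[0], int(cy + pad) + 1)
    x0, x1 = max(0, int(cx - pad)), min(shape[1], int(cx + pad) + 1)
    if y0 >= y1 or x0 >= x1:
        return (slice(0, 0), slice(0, 0)), np.zeros((0, 0))
    ys = np.arange(y0, y1)[:, None]
    xs = np.arange(x0, x1)[None, :]
    r = np.sqrt(((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2)
    mask = np.clip((1.0 - r) * (max(rx, ry) / soft) + 0.5, 0.0, 1.0)
    return (slice(y0, y1), slice(x0, x1)), mask


def _paint(img, window, mask, color):
    sub = img[window[0], window[1]]
    sub += mask[:, :, None] * (np.asarray(color)[None, None, :] - sub)


def _sample_count(cfg: SceneConfig, rng: np.random.Generator) -> int:
    if cfg.fixed_count is not None:
        return cfg.fixed_count
    for _ in range(1000):
        n = int(rng.poisson(cfg.mean_objects))
        if cfg.min_objects <= n <= cfg.max_objects:
            return n
    return int(np.clip(round(cfg.mean_objects), cfg.min_objects, cfg.max_objects))


def _sample_diameter(cfg: SceneConfig, cell_class: str, rng: np.random.Generator) -> float:
    med, q1, q3 = cfg.diameter_quartiles[cell_class]
    s = math.log(q3 / q1) / (2 * 0.6744897501960817)  # quartiles of a lognormal
    d = math.exp(rng.normal(math.log(med), s))
    return float(np.clip(d, 0.5 * med, 2.0 * med)) * cfg.scale


def _place_centres(
    cfg: SceneConfig,
    diameters: Sequence[float],
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    size = cfg.tile_size
    margin = cfg.margin_frac * size
    placed: list[tuple[float, float]] = []
    retries = 200 * max(1, len(diameters))
    tries = 0
    for i, d in enumerate(diameters):
        while True:
            tries += 1
            if tries > retries:
                raise CytopointError(
                    f"could not place {len(diameters)} cells in a {size}px tile "
                    f"after {retries} attempts (packing infeasible)"
                )
            x = rng.uniform(margin, size - margin)
            y = rng.uniform(margin, size - margin)
            ok = True
            for j, (px, py) in enumerate(placed):
                sep = (
                    cfg.min_separation
                    if cfg.min_separation is not None
                    else 0.4 * min(d, diameters[j])
                )
                if (x - px) ** 2 + (y - py) ** 2 < sep * sep:
                    ok = False
                    break
            if ok:
                placed.append((x, y))
                break
    return placed


def _render_cell(img, cell_class, cx, cy, d, rng, tint):
    style = _CELL_STYLE[cell_class]
    r = d / 2.0
    squash = rng.uniform(0.85, 1.0)
    angle = rng.uniform(0, np.pi)
    rx = r * (squash if angle < np.pi / 2 else 1.0)
    ry = r * (1.0 if angle < np.pi / 2 else squash)
    win, body = _disk_window(img.shape[:2], cx, cy, rx, ry)
    _paint(img, win, body, np.asarray(style["cytoplasm"]) * tint)
    if cell_class == "eosinophil":  # granular cytoplasm
        grain = rng.random(body.shape) < 0.25
        _paint(img, win, body * grain * 0.6, np.asarray((0.75, 0.25, 0.22)) * tint)
    nr = style["nucleus_frac"] * r
    lobes = style["lobes"]
    phase = rng.uniform(0, 2 * np.pi)
    for l in range(lobes):
        if lobes == 1:
            off = rng.uniform(0, 0.2 * r)
            ang = rng.uniform(0, 2 * np.pi)
        else:
            off = 0.4 * r
            ang = phase + 2 * np.pi * l / lobes
        nx, ny = cx + off * np.cos(ang), cy + off * np.sin(ang)
        lwin, lobe = _disk_window(img.shape[:2], nx, ny, nr, nr * rng.uniform(0.85, 1.0))
        _paint(img, lwin, lobe, np.asarray(style["nucleus"]) * tint)


def _render_debris(img, rng, tint, mean_count):
    n = rng.poisson(mean_count)
    size = img.shape[0]
    for _ in range(n):
        x, y = rng.uniform(0, size, 2)
        r = rng.uniform(0.002, 0.008) * size + 1.0
        shade = rng.uniform(0.35, 0.6)
        win, speck = _disk_window(img.shape[:2], x, y, r, r * rng.uniform(0.5, 1.0))
        _paint(img, win, speck * rng.uniform(0.5, 0.9),
               np.asarray((shade, shade * 0.85, shade)) * tint)


def _render_mucus(img, rng, tint):
    size = img.shape[0]
    n_blob = rng.integers(2, 5)
    for _ in range(n_blob):
        x, y = rng.uniform(0, size, 2)
        rx = rng.uniform(0.1, 0.3) * size
        ry = rng.uniform(0.05, 0.2) * size
        win, blob = _disk_window(img.shape[:2], x, y, rx, ry, soft=0.05 * size)
        _paint(img, win, blob * 0.25, np.asarray((0.75, 0.62, 0.78)) * tint)


def generate_tile(cfg: SceneConfig, seed: int) -> SyntheticTile:
    """Render one tile with planted cells; truth annotations at each centre."""
    rng = np.random.default_rng(seed)
    size = cfg.tile_size
    palette = PALETTES[cfg.palette]
    tint = np.asarray(cfg.style_tint) * np.asarray(palette["tint"])
    img = np.ones((size, size, 3), dtype=np.float64) * (
        np.asarray(palette["background"]) * tint
    )[None, None, :]

    if rng.random() < cfg.mucus_prob:
        _render_mucus(img, rng, tint)
    _render_debris(img, rng, tint, cfg.debris_mean)

    n = _sample_count(cfg, rng)
    names = list(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in names])
    chosen = [names[i] for i in rng.choice(len(names), size=n, p=probs)]
    diameters = [_sample_diameter(cfg, c, rng) for c in chosen]
    centres = _place_centres(cfg, diameters, rng)

    truth = AnnotationSet(f"seed{seed}", size, size)
    for cell_class, d, (cx, cy) in zip(chosen, diameters, centres):
        _render_cell(img, cell_class, cx, cy, d, rng, tint)
        truth.add(CentreAnnotation(truth.tile_id, cx, cy, cell_class, "truth"))

    img += rng.normal(0.0, cfg.noise_sd, img.shape)
    image = (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)
    return SyntheticTile(image, truth, cfg, seed)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(
    cfg: SceneConfig,
    n_cytospins: int,
    tiles_per_cytospin: int,
    base_seed: int,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> tuple[list[dict], list[SyntheticTile]]:
    """Generate a multi-cytospin dataset with per-cytospin stain jitter.

    Cytospins are assigned one of the two stain palettes (roughly in the
    7:12 ratio of the two source protocols) plus a seeded tint jitter, so
    tiles from different cytospins differ in style. Returns the manifest
    (cytospin_id, tile_id, seed, style per tile) and the tiles; when
    ``out_dir`` is given, writes PNGs, a truth annotation CSV and
    ``manifest.json`` there.
    """
    if n_cytospins < 1 or tiles_per_cytospin < 1:
        raise ConfigError("need at least 1 cytospin and 1 tile per cytospin")
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise CytopointError(f"output folder {out_dir} is not empty (use overwrite)")
        out_dir.mkdir(parents=True, exist_ok=True)

    manifest: list[dict] = []
    tiles: list[SyntheticTile] = []
    for c in range(n_cytospins):
        style_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=base_seed, spawn_key=(c,))
        )
        palette = "kwik_diff" if (c * 19) // n_cytospins < 7 else "mgg"
        tint = tuple(style_rng.uniform(0.95, 1.05, size=3))
        cyt_cfg = SceneConfig(
            **{
                **cfg.__dict__,
                "palette": palette,
                "style_tint": tint,
            }
        )
        cytospin_id = f"cyt{c:02d}"
        for t in range(tiles_per_cytospin):
            seed = int(
                np.random.SeedSequence(entropy=base_seed, spawn_key=(c, t)).generate_state(1)[0]
            )
            tile = generate_tile(cyt_cfg, seed)
            tile_id = f"{cytospin_id}_tile{t:03d}"
            tile.truth = _retag(tile.truth, tile_id)
            tiles.append(tile)
            manifest.append(
                {
                    "cytospin_id": cytospin_id,
                    "tile_id": tile_id,
                    "seed": seed,
                    "style": {"palette": palette, "tint": list(tint)},
                }
            )
    if out_dir is not None:
        for tile, entry in zip(tiles, manifest):
            Image.fromarray(tile.image).save(out_dir / f"{entry['tile_id']}.png")
        write_annotations([t.truth for t in tiles], out_dir / "annotations.csv")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest, tiles


def _retag(truth: AnnotationSet, tile_id: str) -> AnnotationSet:
    out = AnnotationSet(tile_id, truth.tile_width, truth.tile_height)
    for a in truth:
        out.add(CentreAnnotation(tile_id, a.x, a.y, a.cell_class, a.assessor_id))
    return out


# ---------------------------------------------------------------------------
# Simulated assessors
# ---------------------------------------------------------------------------

def simulate_assessors(
    truth: AnnotationSet,
    n_assessors: int,
    jitter_px: float = 3.0,
    miss_rate: float = 0.0,
    confuse_matrix: np.ndarray | None = None,
    seed: int = 0,
    classes: Sequence[str] = CELL_CLASSES,
) -> list[AnnotationSet]:
    """Degraded copies of the truth: positional jitter, misses, confusions.

    ``confuse_matrix[i, j]`` is the probability an object of class ``i`` is
    labelled as class ``j`` (rows sum to 1; identity when omitted).
    """
    if not 0 <= miss_rate <= 1:
        raise ConfigError("miss_rate must be in [0, 1]")
    if jitter_px < 0:
        raise ConfigError("jitter_px must be >= 0")
    k = len(classes)
    if confuse_matrix is None:
        confuse_matrix = np.eye(k)
    confuse_matrix = np.asarray(confuse_matrix, dtype=float)
    if confuse_matrix.shape != (k, k) or not np.allclose(confuse_matrix.sum(axis=1), 1.0):
        raise ConfigError("confuse_matrix must be class x class with rows summing to 1")
    rng = np.random.default_rng(seed)
    out = []
    for a in range(n_assessors):
        s = AnnotationSet(truth.tile_id, truth.tile_width, truth.tile_height)
        assessor = f"assessor_{a + 1}"
        for ann in truth:
            if rng.random() < miss_rate:
                continue
            x = ann.x + rng.normal(0.0, jitter_px) if jitter_px else ann.x
            y = ann.y + rng.normal(0.0, jitter_px) if jitter_px else ann.y
            x = float(np.clip(x, 0.0, np.nextafter(truth.tile_width, 0)))
            y = float(np.clip(y, 0.0, np.nextafter(truth.tile_height, 0)))
            try:
                i = classes.index(ann.cell_class)
            except ValueError as exc:
                raise ValidationError(f"class {ann.cell_class!r} not in classes") from exc
            j = int(rng.choice(k, p=confuse_matrix[i]))
            s.add(CentreAnnotation(truth.tile_id, x, y, classes[j], assessor))
        out.append(s)
    return out


def benchmark_setup(
    tile_size: int = 64,
    mean_objects: float = 6.0,
    sigma_px: float = 1.8,
) -> tuple[SceneConfig, list]:
    """Scene + class configs for CPU-scale training benchmarks.

    Cells are rendered proportionally larger than the clinical size
    distribution (about a third of them per tile edge) so that a small tile
    still contains resolvable objects; sigma is kept small and uniform so
    that encoded peaks stay within the decoder's default cluster-area limit.
    """
    from .annotations import ClassConfig

    quartiles = {  # reference 1024-px scale; /16 at a 64-px tile
        "macrophage_lineage": (320.0, 272.0, 384.0),
        "neutrophil": (256.0, 224.0, 288.0),
        "eosinophil": (288.0, 232.0, 336.0),
        "lymphocyte": (160.0, 136.0, 176.0),
    }
    cfg = SceneConfig(
        tile_size=tile_size,
        mean_objects=mean_objects,
        max_objects=max(2 * int(mean_objects), 8),
        diameter_quartiles=quartiles,
        debris_mean=3.0,
        mucus_prob=0.2,
    )
    classes = [
        ClassConfig(c, quartiles[c][0] * cfg.scale, sigma_px) for c in CELL_CLASSES
    ]
    return cfg, classes


def load_dataset(folder: str | Path) -> tuple[list[dict], pd.DataFrame]:
    """Read back a generated dataset's manifest and truth annotation table."""
    folder = Path(folder)
    manifest = json.loads((folder / "manifest.json").read_text())
    table = pd.read_csv(folder / "annotations.csv")
    return manifest, table


def truth_sets_from_table(
    table: pd.DataFrame, tile_size: int
) -> dict[str, AnnotationSet]:
    sets = annotations_from_frame(table, tile_size, tile_size)
    return {s.tile_id: s for s in sets}
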