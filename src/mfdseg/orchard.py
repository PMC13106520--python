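"""Seeded synthetic orchard scenes with instance masks.

Real UAV orchard surveys are rarely redistributable, so every part of this
package is exercised against generated scenes: textured elliptical canopies
on a soil/grass background, with four scenario regimes mirroring the
conditions a UAV meets over subtropical orchards —

``a``  high-density planting (many touching canopies),
``b``  greenhouse occlusion (semi-transparent frame/film strips over trees),
``c``  terrain-induced scale variation (canopy size drifts across the frame),
``d``  density variation (a dense block next to a sparse block).

Scenes are deterministic functions of their spec (including the seed).
Labels use the polygon-per-line text dialect of the YOLO segmentation
family, with normalized coordinates at six decimals.

Coordinate convention: x rightward, y downward, origin at the top-left,
normalized to [0, 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

__all__ = [
    "OrchardSceneSpec",
    "InstanceRecord",
    "generate_scene",
    "write_yolo_seg_labels",
    "read_yolo_seg_labels",
    "make_split",
    "write_dataset",
]

POLY_VERTICES = 24  # enough for >=99% area agreement with the true ellipse


@dataclass(frozen=True)
class OrchardSceneSpec:
    """Parameters of one synthetic scene."""

    height: int = 640
    width: int = 640
    count_range: tuple[int, int] | None = None     # None: scenario preset
    radius_range: tuple[float, float] | None = None
    aspect_range: tuple[float, float] = (0.7, 1.0)
    overlap_cap: float = 0.25
    scenario: str = "a"
    texture_noise: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in "abcd":
            raise ValueError("scenario must be one of 'a', 'b', 'c', 'd'")
        if self.count_range is not None and (
            self.count_range[0] > self.count_range[1] or self.count_range[0] < 0
        ):
            raise ValueError("invalid count range")
        if self.radius_range is not None and (
            self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]
        ):
            raise ValueError("invalid radius range")


@dataclass
class InstanceRecord:
    """One canopy instance: polygon (normalized), derived box, binary mask."""

    class_id: int
    polygon: np.ndarray  # (V, 2) normalized x, y
    mask: np.ndarray     # (H, W) bool

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[0] < 3 or self.polygon.shape[1] != 2:
            raise ValueError("polygon needs at least three (x, y) vertices")
        if self.polygon.min() < 0 or self.polygon.max() > 1:
            raise ValueError("polygon coordinates must be normalized to [0, 1]")

    @property
    def box(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2), normalized, from the polygon extremes."""
        x1, y1 = self.polygon.min(axis=0)
        x2, y2 = self.polygon.max(axis=0)
        return float(x1), float(y1), float(x2), float(y2)

    def box_pixels(self) -> tuple[float, float, float, float]:
        h, w = self.mask.shape
        x1, y1, x2, y2 = self.box
        return x1 * w, y1 * h, x2 * w, y2 * h


def _ellipse_polygon(cx, cy, a, b, theta, n=POLY_VERTICES):
    t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ct, st = math.cos(theta), math.sin(theta)
    return np.stack([cx + ct * x - st * y, cy + st * x + ct * y], axis=1)


def _scenario_spec(spec: OrchardSceneSpec) -> OrchardSceneSpec:
    """Fill unset ranges with the scenario's preset regime.

    Presets scale with the frame so that a 160-px scene carries the same
    relative canopy sizes and densities as a 640-px one.
    """
    s = min(spec.height, spec.width) / 640.0
    counts = {"a": (26, 36), "b": (12, 18), "c": (10, 18), "d": (16, 24)}
    radii = {"a": (22.0, 38.0), "b": (30.0, 55.0), "c": (30.0, 60.0), "d": (26.0, 48.0)}
    kw = {}
    if spec.count_range is None:
        kw["count_range"] = counts[spec.scenario]
    if spec.radius_range is None:
        lo, hi = radii[spec.scenario]
        kw["radius_range"] = (lo * s, hi * s)
    if spec.scenario == "a":
        kw["overlap_cap"] = max(spec.overlap_cap, 0.35)
    return replace(spec, **kw) if kw else spec


def generate_scene(spec: OrchardSceneSpec):
    """Render one scene; returns ``(image uint8 HxWx3, [InstanceRecord])``."""
    spec = _scenario_spec(spec)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # --- background: soil/grass gradient plus two scales of noise ----------
    blend = gaussian_filter(rng.normal(0, 1, (h, w)), sigma=min(h, w) / 8)
    blend = (blend - blend.min()) / (np.ptp(blend) + 1e-9)
    soil = np.array([123.0, 92.0, 66.0])
    grass = np.array([96.0, 112.0, 62.0])
    img = soil + (grass - soil) * blend[..., None]
    img += gaussian_filter(rng.normal(0, spec.texture_noise, (h, w)), 1.5)[..., None]
    img += rng.normal(0, 2.0, (h, w, 3))
    # one leaf-speckle field shared by all canopies in the scene
    speckle = gaussian_filter(rng.normal(0, 1, (h, w)), 0.8) * 14.0

    # --- canopy placement ---------------------------------------------------
    n_target = int(rng.integers(spec.count_range[0], spec.count_range[1] + 1))
    r_lo, r_hi = spec.radius_range
    area_cap = 0.85 * h * w
    if n_target * math.pi * ((r_lo + r_hi) / 2) ** 2 > area_cap:
        n_new = max(1, int(area_cap / (math.pi * ((r_lo + r_hi) / 2) ** 2)))
        warnings.warn(
            f"infeasible packing: reducing instance count {n_target} -> {n_new}"
        )
        n_target = n_new

    placed = []  # (cx, cy, r_eff)
    records: list[InstanceRecord] = []
    tries = 0
    while len(placed) < n_target and tries < 80 * n_target:
        tries += 1
        if spec.scenario == "d":
            # dense left block vs sparse right block (3:1 target ratio)
            if rng.random() < 0.8:
                cx = rng.uniform(0.05 * w, 0.48 * w)
            else:
                cx = rng.uniform(0.55 * w, 0.95 * w)
            cy = rng.uniform(0.08 * h, 0.92 * h)
        else:
            cx = rng.uniform(0.06 * w, 0.94 * w)
            cy = rng.uniform(0.08 * h, 0.92 * h)
        a = rng.uniform(r_lo, r_hi)
        if spec.scenario == "c":
            # terrain: canopies shrink smoothly toward the far (right) edge
            a *= 1.35 - 1.0 * (cx / w)
            a = max(a, 0.35 * r_lo)
        b = a * rng.uniform(*spec.aspect_range)
        r_eff = math.sqrt(a * b)
        ok = True
        for px, py, pr in placed:
            d = math.hypot(cx - px, cy - py)
            if d < (1.0 - spec.overlap_cap) * (r_eff + pr):
                ok = False
                break
        if not ok:
            continue
        theta = rng.uniform(0, math.pi)
        poly = _ellipse_polygon(cx, cy, a, b, theta)
        if poly[:, 0].min() < 0 or poly[:, 1].min() < 0 or \
           poly[:, 0].max() >= w or poly[:, 1].max() >= h:
            continue
        placed.append((cx, cy, r_eff))

        mask = np.zeros((h, w), dtype=bool)
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        mask[rr, cc] = True

        # canopy paint: per-tree green with leaf speckle and rim shading,
        # computed only inside the instance's bounding window
        base = np.array([
            rng.uniform(28, 52), rng.uniform(88, 128), rng.uniform(30, 56)
        ])
        y0, y1 = max(int(poly[:, 1].min()), 0), min(int(np.ceil(poly[:, 1].max())) + 1, h)
        x0, x1 = max(int(poly[:, 0].min()), 0), min(int(np.ceil(poly[:, 0].max())) + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        dist = np.hypot((xx - cx) / max(a, 1e-6), (yy - cy) / max(b, 1e-6))
        shade = np.clip(1.15 - 0.45 * dist, 0.45, 1.15)
        paint = base[None, None, :] * shade[..., None] + speckle[y0:y1, x0:x1, None]
        sub = mask[y0:y1, x0:x1]
        img[y0:y1, x0:x1][sub] = paint[sub]

        records.append(
            InstanceRecord(0, poly / np.array([w, h], dtype=float), mask)
        )

    if len(placed) < n_target:
        warnings.warn(
            f"placement saturated: {len(placed)} of {n_target} instances placed"
        )

    # --- scenario b: greenhouse frames / film strips ------------------------
    if spec.scenario == "b":
        opacity = np.zeros((h, w))
        pitch = int(rng.uniform(70, 110))
        width_px = int(rng.uniform(6, 11))
        phase = int(rng.uniform(0, pitch))
        for x0 in range(phase, w, pitch):
            opacity[:, x0 : x0 + width_px] = rng.uniform(0.55, 0.8)
        for y0 in range(int(rng.uniform(0, pitch)), h, pitch):
            opacity[y0 : y0 + width_px, :] = rng.uniform(0.55, 0.8)
        film = np.array([205.0, 210.0, 200.0])
        img = img * (1 - opacity[..., None]) + film * opacity[..., None]
        occluded = opacity > 0.5
        for rec in records:  # polygons stay whole; masks lose covered pixels
            rec.mask &= ~occluded

    return np.clip(img, 0, 255).astype(np.uint8), records


# ---------------------------------------------------------------------------
# label I/O and splits
# ---------------------------------------------------------------------------


def write_yolo_seg_labels(records: list[InstanceRecord], path) -> None:
    """One line per instance: ``class x1 y1 x2 y2 ... xn yn`` (normalized)."""
    lines = []
    for rec in records:
        coords = " ".join(f"{v:.6f}" for v in rec.polygon.reshape(-1))
        lines.append(f"{rec.class_id} {coords}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_seg_labels(path, image_shape: tuple[int, int] | None = None):
    """Parse a label file back into records.

    ``image_shape`` (H, W) is needed to rasterize masks; without it the
    records carry a 1x1 placeholder mask and only polygons/boxes are usable.
    """
    records = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        try:
            cid = int(parts[0])
            vals = [float(v) for v in parts[1:]]
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: malformed label line") from e
        if len(vals) < 6 or len(vals) % 2:
            raise ValueError(f"{path}:{ln}: expected >=3 (x,y) pairs")
        poly = np.array(vals, dtype=float).reshape(-1, 2)
        if poly.min() < 0 or poly.max() > 1:
            raise ValueError(f"{path}:{ln}: coordinates outside [0, 1]")
        if image_shape is not None:
            h, w = image_shape
            mask = np.zeros((h, w), dtype=bool)
            rr, cc = draw_polygon(poly[:, 1] * h, poly[:, 0] * w, shape=(h, w))
            mask[rr, cc] = True
        else:
            mask = np.zeros((1, 1), dtype=bool)
        records.append(InstanceRecord(cid, poly, mask))
    return records


def make_split(items: list, seed: int = 42):
    """Shuffled 7:3 split.

    The split is taken per block of ten shuffled items (seven to train,
    three to validation), which reproduces the 700/298 partition of a
    998-item set and 7/3 for ten items.
    """
    if not items:
        raise ValueError("cannot split an empty list")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(items)))
    n = len(items)
    n_train = (n // 10) * 7 + min(n % 10, 7)
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:]]
    return train, val


def tile_scene(image: np.ndarray, records: list[InstanceRecord], tile: int = 640,
               min_area: int = 64):
    """Cut a large frame into non-overlapping tiles with re-clipped labels.

    Sensor-native frames are far larger than training resolution; this
    produces ``tile x tile`` crops, keeping in each crop the instances whose
    mask intersects it by at least ``min_area`` pixels.  Polygons are
    re-derived from the clipped mask's bounding rectangle corners when the
    original polygon leaves the tile.
    """
    h, w = image.shape[:2]
    out = []
    for y0 in range(0, h - tile + 1, tile):
        for x0 in range(0, w - tile + 1, tile):
            crop = image[y0:y0 + tile, x0:x0 + tile]
            recs = []
            for r in records:
                sub = r.mask[y0:y0 + tile, x0:x0 + tile]
                if sub.sum() < min_area:
                    continue
                poly_px = r.polygon * np.array([w, h]) - np.array([x0, y0])
                poly_px = np.clip(poly_px, 0, tile - 1e-6)
                recs.append(InstanceRecord(r.class_id, poly_px / tile, sub.copy()))
            out.append(((y0, x0), crop, recs))
    return out


def write_dataset(out_dir, n_scenes: int, scenario: str = "a", imgsz: int = 640,
                  seed: int = 42, scenario_mix: bool = False):
    """Generate a dataset directory: images/, labels/, dataset.yaml.

    ``scenario_mix`` cycles a->b->c->d across scenes instead of a single
    regime.  Returns (train list, val list) of image paths.
    """
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    names = []
    for i in range(n_scenes):
        sc = "abcd"[i % 4] if scenario_mix else scenario
        spec = OrchardSceneSpec(height=imgsz, width=imgsz, scenario=sc,
                                seed=seed * 1_000_003 % (2**31) + i)
        img, recs = generate_scene(spec)
        stem = f"scene_{i:05d}"
        Image.fromarray(img).save(out / "images" / f"{stem}.png")
        write_yolo_seg_labels(recs, out / "labels" / f"{stem}.txt")
        names.append(str(out / "images" / f"{stem}.png"))
    train, val = make_split(names, seed=seed)
    yaml_text = (
        f"path: {out}\n"
        "names:\n  0: canopy\n"
        "train:\n" + "".join(f"  - {p}\n" for p in train) +
        "val:\n" + "".join(f"  - {p}\n" for p in val)
    )
    (out / "dataset.yaml").write_text(yaml_text)
    return train, val
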