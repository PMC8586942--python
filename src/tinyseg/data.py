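"""Tiling, augmentation, synthetic scenes and cross-validation splits.

The measurement setup photographs trays of beach sand on a conveyor at
1440x1440 px; networks consume 512x512 crops cut on an overlapping grid.
The real photo set is not distributable, so :func:`synth_scene` emulates
its statistics for tests and experiments: a granular sand-like texture,
a handful of bright or dark compact particles 3-10 px across, and a
foreground fraction kept below 1% of the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Tile", "TileSet", "AugmentConfig", "SceneConfig", "FoldSplit",
    "crop_tiles", "tile_offsets", "augment", "synth_scene", "synth_dataset",
    "kfold_split",
]


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tile:
    row: int  # top offset in the source image
    col: int  # left offset
    image: np.ndarray
    mask: np.ndarray


@dataclass
class TileSet:
    source_shape: tuple[int, int]
    tile: int
    overlap: int
    tiles: list[Tile]

    def __iter__(self):
        return iter(self.tiles)

    def __len__(self):
        return len(self.tiles)

    def reassemble(self) -> tuple[np.ndarray, np.ndarray]:
        """Rebuild the source image/mask, later tiles overwriting earlier."""
        h, w = self.source_shape
        img = np.zeros((h, w) + self.tiles[0].image.shape[2:],
                       dtype=self.tiles[0].image.dtype)
        msk = np.zeros((h, w), dtype=self.tiles[0].mask.dtype)
        for t in self.tiles:
            img[t.row:t.row + self.tile, t.col:t.col + self.tile] = t.image
            msk[t.row:t.row + self.tile, t.col:t.col + self.tile] = t.mask
        return img, msk


def tile_offsets(size: int, tile: int, stride: int) -> list[int]:
    """Grid offsets along one axis, with the last tile snapped to the edge."""
    offs = list(range(0, size - tile + 1, stride))
    if offs[-1] != size - tile:
        offs.append(size - tile)
    return offs


def crop_tiles(image: np.ndarray, mask: np.ndarray, tile: int = 512,
               overlap: int = 100) -> TileSet:
    """Cut a photo and its mask into overlapping ``tile x tile`` crops.

    Adjacent crops share an ``overlap``-pixel border (stride =
    ``tile - overlap``); the final row/column is snapped to the image
    edge so every source pixel is covered.
    """
    h, w = image.shape[:2]
    if h < tile or w < tile:
        raise ValueError(f"image {h}x{w} smaller than tile {tile}")
    if mask.shape[:2] != (h, w):
        raise ValueError("image and mask sizes differ")
    stride = tile - overlap
    tiles = [
        Tile(r, c, image[r:r + tile, c:c + tile], mask[r:r + tile, c:c + tile])
        for r in tile_offsets(h, tile, stride)
        for c in tile_offsets(w, tile, stride)
    ]
    return TileSet((h, w), tile, overlap, tiles)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Training-time geometric augmentation.

    Shifts are uniform in ``[-max_shift_fraction, +max_shift_fraction]``
    of the image size per axis; rotation is uniform in
    ``[-max_rotation, +max_rotation]`` degrees; flips are independent
    coin tosses.  Empty space in the image is filled with ``fill``
    (the dataset mean pixel; defaults to the image's own mean), in the
    mask with background.
    """

    max_shift_fraction: float = 0.20
    max_rotation: float = 45.0
    flip_horizontal: bool = True
    flip_vertical: bool = True
    fill: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.max_shift_fraction <= 1:
            raise ValueError("shift fraction must be in [0, 1]")
        if not 0 <= self.max_rotation < 360:
            raise ValueError("rotation must be in [0, 360)")


def augment(image: np.ndarray, mask: np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random flip/rotate/shift jointly to image and mask.

    The mask is warped with nearest-neighbour interpolation and
    re-binarized, which preserves binarity for 3-px objects; the image
    uses linear interpolation with mean-value fill.
    """
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask sizes differ")
    img = np.asarray(image, dtype=np.float32)
    msk = np.asarray(mask)
    dtype_in, mask_dtype = img.dtype, msk.dtype
    fill = float(cfg.fill) if cfg.fill is not None else float(img.mean())

    if cfg.flip_horizontal and rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if cfg.flip_vertical and rng.random() < 0.5:
        img, msk = img[::-1], msk[::-1]

    angle = rng.uniform(-cfg.max_rotation, cfg.max_rotation)
    if angle:
        img = ndimage.rotate(img, angle, reshape=False, order=1,
                             mode="constant", cval=fill)
        msk = ndimage.rotate(msk.astype(np.float32), angle, reshape=False,
                             order=0, mode="constant", cval=0.0)

    h, w = img.shape[:2]
    dy = rng.uniform(-cfg.max_shift_fraction, cfg.max_shift_fraction) * h
    dx = rng.uniform(-cfg.max_shift_fraction, cfg.max_shift_fraction) * w
    if dy or dx:
        shift = (dy, dx) + (0,) * (img.ndim - 2)
        img = ndimage.shift(img, shift, order=1, mode="constant", cval=fill)
        msk = ndimage.shift(msk.astype(np.float32), (dy, dx), order=0,
                            mode="constant", cval=0.0)

    msk = (msk > 0.5).astype(mask_dtype)
    return np.ascontiguousarray(img, dtype=dtype_in), np.ascontiguousarray(msk)


# ---------------------------------------------------------------------------
# synthetic sand-with-particles scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene generator.

    Defaults emulate the target imagery at test scale: a 128x128
    granular background with 1-3 particles of 3-10 px diameter,
    foreground strictly below 1% of the pixels.
    """

    size: int = 128
    channels: int = 1
    particle_count: tuple[int, int] = (1, 3)  # inclusive range
    particle_diameter: tuple[float, float] = (3.0, 10.0)
    particle_contrast: tuple[float, float] = (0.25, 0.55)
    background_mean: float = 0.45
    background_amplitude: float = 0.13
    granule_scale: float = 1.2  # gaussian smoothing radius of the texture, px
    max_foreground_fraction: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.particle_diameter
        if not (3.0 <= lo <= hi <= 10.0):
            raise ValueError("particle diameters must lie within [3, 10] px")
        if self.particle_count[0] < 0 or self.particle_count[0] > self.particle_count[1]:
            raise ValueError("invalid particle count range")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        # a config whose *minimum* draw cannot respect the foreground
        # budget is rejected outright
        min_area = self.particle_count[0] * np.ceil(np.pi * (lo / 2) ** 2)
        if min_area >= self.max_foreground_fraction * self.size ** 2:
            raise ValueError(
                "particle area exceeds the foreground budget "
                f"({min_area:.0f} px >= "
                f"{self.max_foreground_fraction:.2%} of {self.size}^2)")


def _render_disk(image, mask, cy, cx, diameter, delta):
    """Draw one anti-aliased particle into image and its footprint into mask."""
    r = diameter / 2.0
    h, w = mask.shape
    lo_y = max(int(np.floor(cy - r - 1)), 0)
    hi_y = min(int(np.ceil(cy + r + 1)) + 1, h)
    lo_x = max(int(np.floor(cx - r - 1)), 0)
    hi_x = min(int(np.ceil(cx + r + 1)) + 1, w)
    yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
    dist = np.hypot(yy - cy, xx - cx)
    cover = np.clip(r + 0.5 - dist, 0.0, 1.0)  # soft edge, ~pixel coverage
    image[lo_y:hi_y, lo_x:hi_x] += delta * cover
    mask[lo_y:hi_y, lo_x:hi_x] |= dist <= r


def synth_scene(cfg: SceneConfig, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic sand scene: (image float32 in [0,1], mask uint8).

    The background is smoothed uniform noise (granules of a few px);
    particles are compact disks, randomly bright or dark against the
    sand.  Particle draws that would push the foreground fraction to
    the 1% budget are re-drawn, so the class-imbalance premise holds
    for every emitted scene.  Deterministic given the generator state.
    """
    n_px = cfg.size * cfg.size
    budget = cfg.max_foreground_fraction * n_px
    noise = rng.uniform(-1.0, 1.0, (cfg.size, cfg.size))
    tex = ndimage.gaussian_filter(noise, cfg.granule_scale)
    tex /= max(np.abs(tex).max(), 1e-9)
    image = cfg.background_mean + cfg.background_amplitude * tex
    mask = np.zeros((cfg.size, cfg.size), dtype=bool)

    count = int(rng.integers(cfg.particle_count[0],
                             cfg.particle_count[1] + 1))
    placed = 0
    attempts = 0
    while placed < count and attempts < 50 * max(count, 1):
        attempts += 1
        d = rng.uniform(*cfg.particle_diameter)
        margin = d / 2 + 1.5
        cy = rng.uniform(margin, cfg.size - margin)
        cx = rng.uniform(margin, cfg.size - margin)
        area = np.ceil(np.pi * (d / 2) ** 2)
        if mask.sum() + area >= budget:
            continue  # would break the imbalance premise; redraw smaller
        sign = 1.0 if rng.random() < 0.5 else -1.0
        delta = sign * rng.uniform(*cfg.particle_contrast)
        _render_disk(image, mask, cy, cx, d, delta)
        placed += 1

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    if cfg.channels == 3:
        image = np.stack([image] * 3, axis=-1)
    return image, mask.astype(np.uint8)


def synth_dataset(n: int, cfg: SceneConfig, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Stack of *n* scenes: images (n, H, W[, 3]) and masks (n, H, W)."""
    pairs = [synth_scene(cfg, rng) for _ in range(n)]
    return (np.stack([p[0] for p in pairs]),
            np.stack([p[1] for p in pairs]))


# ---------------------------------------------------------------------------
# cross-validation splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    fold: int
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def kfold_split(n: int, k: int = 5, rng: np.random.Generator | int = 0,
                validation_fraction: float = 0.1) -> list[FoldSplit]:
    """K disjoint test partitions; the remainder split train/validation.

    With the defaults each fold uses 20% of the data for test and
    splits the remaining 80% into 72% train / 8% validation (the
    validation fraction is taken from the non-test remainder).
    """
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(n)
    chunks = np.array_split(perm, k)
    folds = []
    for i, test in enumerate(chunks):
        rest = np.concatenate([c for j, c in enumerate(chunks) if j != i])
        n_val = int(round(validation_fraction * len(rest)))
        folds.append(FoldSplit(fold=i, train=np.sort(rest[n_val:]),
                               validation=np.sort(rest[:n_val]),
                               test=np.sort(test)))
    return folds
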