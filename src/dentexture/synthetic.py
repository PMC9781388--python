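"""Procedural generator of labeled tooth-like textured images.

Each image is a smooth convex crown-like silhouette (a randomly perturbed
superellipse) filled with an oriented sinusoidal ridge texture — a stand-in
for the individual surface texture of natural enamel — over a darker noisy
background scattered with small bright specks. The specks are strictly
smaller than the 10x10 structuring element used downstream, so morphological
opening during segmentation is genuinely exercised.

Classes are laid out on a frequency x orientation grid, which guarantees a
pairwise separation margin between the nine texture signatures.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ParameterError

#: Tooth class names, indexed by integer label 0-8.
CLASS_NAMES = (
    "Lower Anterior",
    "Lower Canine",
    "LowerPremolar",
    "Lower Molar",
    "Upper Centra",
    "Upper Lateral",
    "Upper Canine",
    "UpperPremolar",
    "Upper Molar",
)

#: Per-class image counts of the reference 600-tooth benchmark.
DEFAULT_CLASS_COUNTS = (64, 87, 77, 71, 75, 49, 34, 80, 63)

# 3 frequencies x 3 orientations -> 9 separable texture signatures.
_GRID_FREQUENCIES = (6.0, 12.0, 22.0)  # cycles per image width
_GRID_ORIENTATIONS = (15.0, 75.0, 135.0)  # degrees

_FOREGROUND_MEAN = 0.55
_BACKGROUND_MEAN = 0.15
_SPECK_INTENSITY = 0.92


@dataclass(frozen=True)
class ClassTextureSpec:
    """Surface-texture signature of one tooth class.

    ridge_frequency is in cycles per image width; ridge_orientation in
    degrees within [0, 180); ridge_contrast in [0, 1] scales the sinusoidal
    modulation; noise_sd is the Gaussian pixel-noise standard deviation.
    """

    class_id: int
    ridge_frequency: float
    ridge_orientation: float
    ridge_contrast: float = 0.6
    noise_sd: float = 0.05

    def validate(self) -> None:
        if not 0 <= self.class_id <= 8:
            raise ParameterError(f"class_id must be in 0..8, got {self.class_id}")
        if not self.ridge_frequency > 0:
            raise ParameterError("ridge_frequency must be positive")
        if not 0 <= self.ridge_orientation < 180:
            raise ParameterError("ridge_orientation must lie in [0, 180)")
        if not 0 <= self.ridge_contrast <= 1:
            raise ParameterError("ridge_contrast must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


def default_class_specs() -> list[ClassTextureSpec]:
    """The nine default signatures on the frequency x orientation grid."""
    specs = []
    for cid in range(9):
        specs.append(
            ClassTextureSpec(
                class_id=cid,
                ridge_frequency=_GRID_FREQUENCIES[cid // 3],
                ridge_orientation=_GRID_ORIENTATIONS[cid % 3],
            )
        )
    return specs


@dataclass(frozen=True)
class SyntheticProfile:
    """Full description of a synthetic benchmark to generate."""

    class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    image_size: int = 128
    speck_count: int = 8
    seed: int = 7
    class_specs: tuple[ClassTextureSpec, ...] = field(
        default_factory=lambda: tuple(default_class_specs())
    )

    def validate(self) -> None:
        if len(self.class_counts) != 9:
            raise ParameterError("class_counts must have exactly 9 entries")
        if any(c < 0 for c in self.class_counts):
            raise ParameterError("class counts must be non-negative")
        if self.image_size < 32:
            raise ParameterError("image_size must be >= 32")
        if self.speck_count < 0:
            raise ParameterError("speck_count must be non-negative")
        ids = [s.class_id for s in self.class_specs]
        if sorted(ids) != list(range(9)):
            raise ParameterError("class_specs must cover class ids 0..8 exactly once")
        for s in self.class_specs:
            s.validate()
        # pairwise separation margin on the (frequency, orientation) plane
        for a in self.class_specs:
            for b in self.class_specs:
                if a.class_id >= b.class_id:
                    continue
                df = abs(a.ridge_frequency - b.ridge_frequency)
                dth = abs(a.ridge_orientation - b.ridge_orientation)
                dth = min(dth, 180 - dth)
                if df < 2.0 and dth < 15.0:
                    raise ParameterError(
                        f"classes {a.class_id} and {b.class_id} are not separated: "
                        f"|df|={df:.2f} < 2 and |dtheta|={dth:.2f} < 15"
                    )


def _image_rng(seed: int, class_id: int, index: int) -> np.random.Generator:
    """Counter-based per-image substream: independent of generation order."""
    return np.random.default_rng(np.random.SeedSequence([seed, class_id, index]))


def superellipse_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    """Random crown-like convex silhouette: |x/a|^p + |y/b|^p <= 1, jittered."""
    p = rng.uniform(2.4, 4.0)
    a = rng.uniform(0.30, 0.40) * size  # semi-axis along width
    b = rng.uniform(0.32, 0.44) * size  # semi-axis along height
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    yy, xx = np.mgrid[0:size, 0:size]
    r = (np.abs((xx - cx) / a)) ** p + (np.abs((yy - cy) / b)) ** p
    return r <= 1.0


def generate_tooth_image(
    spec: ClassTextureSpec,
    size: int = 128,
    rng: np.random.Generator | None = None,
    speck_count: int = 8,
    return_mask: bool = False,
):
    """Render one synthetic tooth image in [0, 1].

    Foreground: superellipse mask filled with an oriented sinusoidal ridge
    pattern (class signature) plus Gaussian noise. Background: darker mean
    with the same noise, plus ``speck_count`` isolated bright specks, each
    smaller than 6x6 px and placed strictly outside the mask so that a 10x10
    morphological opening removes them all.
    """
    spec.validate()
    if size < 32:
        raise ParameterError("size must be >= 32")
    if rng is None:
        rng = np.random.default_rng()

    mask = superellipse_mask(size, rng)

    theta = np.deg2rad(spec.ridge_orientation)
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    # coordinate along the ridge normal; frequency in cycles per image width
    u = (xx * np.cos(theta) + yy * np.sin(theta)) / size
    ridge = np.sin(2 * np.pi * spec.ridge_frequency * u + phase)

    img = np.full((size, size), _BACKGROUND_MEAN)
    img[mask] = _FOREGROUND_MEAN + 0.2 * spec.ridge_contrast * ridge[mask]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)

    # bright outlier specks, outside the tooth's bounding box (with margin)
    # so the front-face crop excludes them and the opening removes them
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    box = np.zeros_like(mask)
    box[max(rows[0] - 8, 0) : rows[-1] + 9, max(cols[0] - 8, 0) : cols[-1] + 9] = True
    speck_zone = ~box
    free_rows, free_cols = np.nonzero(speck_zone)
    placed = 0
    attempts = 0
    while (placed < speck_count and len(free_rows) > 0
           and attempts < 50 * max(speck_count, 1)):
        attempts += 1
        j = rng.integers(len(free_rows))
        r, c = int(free_rows[j]), int(free_cols[j])
        h = int(rng.integers(2, 6))
        w = int(rng.integers(2, 6))
        if r + h >= size or c + w >= size:
            continue
        patch = speck_zone[max(r - 2, 0) : r + h + 2, max(c - 2, 0) : c + w + 2]
        if not patch.all():  # keep specks isolated from mask and each other
            continue
        img[r : r + h, c : c + w] = _SPECK_INTENSITY
        speck_zone[max(r - 8, 0) : r + h + 8, max(c - 8, 0) : c + w + 8] = False
        free_rows, free_cols = np.nonzero(speck_zone)
        if len(free_rows) == 0:
            break
        placed += 1

    img = np.clip(img, 0.0, 1.0)
    if return_mask:
        return img, mask
    return img


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    label: int
    class_name: str


def generate_dataset(profile: SyntheticProfile, out_dir: str | Path) -> list[ManifestRecord]:
    """Write the benchmark to ``out_dir`` in folder-per-class layout.

    Produces 8-bit grayscale PNGs plus ``manifest.csv`` with header
    ``path,label,class_name``. Fully deterministic given ``profile.seed``:
    every image is drawn from its own counter-based substream.
    """
    profile.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    specs = {s.class_id: s for s in profile.class_specs}
    records: list[ManifestRecord] = []
    for cid in range(9):
        cls_dir = out_dir / f"{cid}_{CLASS_NAMES[cid].replace(' ', '_')}"
        if profile.class_counts[cid] > 0:
            cls_dir.mkdir(exist_ok=True)
        for idx in range(profile.class_counts[cid]):
            rng = _image_rng(profile.seed, cid, idx)
            img = generate_tooth_image(
                specs[cid], profile.image_size, rng, profile.speck_count
            )
            rel = f"{cls_dir.name}/tooth_{idx:04d}.png"
            save_gray_png(out_dir / rel, img)
            records.append(ManifestRecord(rel, cid, CLASS_NAMES[cid]))

    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "class_name"])
        for rec in records:
            writer.writerow([rec.path, rec.label, rec.class_name])
    return records


def save_gray_png(path: str | Path, img: np.ndarray) -> None:
    """Save a [0,1] float image as an 8-bit grayscale PNG."""
    arr = np.clip(np.round(np.asarray(img) * 255), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_gray_png(path: str | Path) -> np.ndarray:
    """Load PNG/JPG as a [0,1] float grayscale image (RGB via luminance)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
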