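"""Synthetic blastocyst phantoms: concentric tissue masks with microscopy-like
textures.

A phantom emulates the structure of a day-5/6 human blastocyst as seen under
Hoffman modulation contrast: a zona pellucida (ZP) annulus encloses the
trophectoderm (TE) rim, which encloses the fluid-filled blastocoele lumen;
the inner cell mass (ICM) is an elliptical blob inside the lumen, tangent to
the TE's inner boundary, so TE is encased by ZP and blastocoele from two
sides and ICM sits within TE's boundary, closer to the centre.  The class
encoding is 0 = background, 1 = ZP, 2 = TE, 3 = ICM, 4 = blastocoele.

Images are rendered as per-class base intensities plus a directional
illumination gradient, Gaussian blur and additive Gaussian noise.  Base
intensities of adjacent classes are deliberately close (within the noise
scale at the harder settings), so distinct tissues share local textures and
a segmenter must use context — the two structural priors the network is
designed around: rotation consistency (the phantom's semantics are invariant
to rotation about its centre) and local intensity ambiguity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["PhantomSpec", "PhantomDataset", "render_phantom", "random_spec",
           "make_dataset", "rotate_sample", "MASK_PALETTE", "CLASS_NAMES",
           "save_mask_png", "load_mask_png", "save_image_png", "load_image_png"]

CLASS_NAMES = ("background", "ZP", "TE", "ICM", "blastocoele")
MASK_PALETTE = {0: (0, 0, 0), 1: (255, 215, 0), 2: (220, 20, 60),
                3: (65, 105, 225), 4: (60, 179, 113)}

# per-class base intensity (bg, ZP, TE, ICM, blastocoele) and texture scales
DIFFICULTY = {
    "easy":   dict(intensities=(0.25, 0.75, 0.55, 0.90, 0.40),
                   noise_sigma=0.02, blur_sigma=0.6, illum_strength=0.05),
    "medium": dict(intensities=(0.42, 0.62, 0.50, 0.58, 0.40),
                   noise_sigma=0.04, blur_sigma=1.0, illum_strength=0.10),
    "hard":   dict(intensities=(0.46, 0.56, 0.50, 0.54, 0.48),
                   noise_sigma=0.06, blur_sigma=1.5, illum_strength=0.12),
}


@dataclass
class PhantomSpec:
    """Geometric and photometric parameters of one phantom."""

    size: int = 64
    center: tuple = (31.5, 31.5)          # (row, col)
    radius: float = 24.0                  # ZP outer radius
    zp_thickness: float = 5.0
    te_thickness: float = 4.0
    icm_angle: float = 0.0                # angular position of the ICM blob
    icm_radius: float = 6.0               # radial semi-axis of the ICM ellipse
    icm_ecc: float = 0.2                  # 1 − (tangential/radial axis ratio)
    rotation: float = 0.0                 # global rotation about the centre
    intensities: tuple = DIFFICULTY["medium"]["intensities"]
    noise_sigma: float = 0.04
    blur_sigma: float = 1.0
    illum_strength: float = 0.10
    illum_angle: float = 0.0
    seed: int = 0

    # -- derived geometry ------------------------------------------------
    @property
    def r_zp_inner(self) -> float:
        return self.radius - self.zp_thickness

    @property
    def r_lumen(self) -> float:
        return self.r_zp_inner - self.te_thickness

    @property
    def icm_minor(self) -> float:
        return self.icm_radius * (1.0 - self.icm_ecc)

    def validate(self):
        if not (self.radius > self.r_zp_inner > self.r_lumen > 0):
            raise ValueError(
                f"invalid nesting: radius={self.radius}, ZP inner={self.r_zp_inner}, "
                f"lumen={self.r_lumen} must be strictly decreasing and positive")
        if not (0 < self.icm_radius <= self.r_lumen):
            raise ValueError("ICM radius must be positive and fit inside the lumen")
        if not (0 <= self.icm_ecc < 1):
            raise ValueError("ICM eccentricity must lie in [0, 1)")

    def analytic_areas(self) -> np.ndarray:
        """Expected pixel count per class from closed-form disk/annulus areas."""
        a, b = self.icm_radius, self.icm_minor
        icm = np.pi * a * b
        lumen = np.pi * self.r_lumen ** 2
        te = np.pi * (self.r_zp_inner ** 2 - self.r_lumen ** 2)
        zp = np.pi * (self.radius ** 2 - self.r_zp_inner ** 2)
        bg = self.size ** 2 - np.pi * self.radius ** 2
        return np.array([bg, zp, te, icm, lumen - icm])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["center"] = list(self.center)
        d["intensities"] = list(self.intensities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["center"] = tuple(d["center"])
        d["intensities"] = tuple(d["intensities"])
        return cls(**d)


def render_mask(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the class mask from the geometric spec (no randomness)."""
    spec.validate()
    cy, cx = spec.center
    yy, xx = np.mgrid[0:spec.size, 0:spec.size]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    mask = np.zeros((spec.size, spec.size), dtype=np.uint8)
    mask[rho <= spec.radius] = 1                      # ZP
    mask[rho <= spec.r_zp_inner] = 2                  # TE
    mask[rho <= spec.r_lumen] = 4                     # blastocoele
    # ICM: ellipse tangent to the lumen boundary, radial major axis
    phi = spec.icm_angle + spec.rotation
    d = spec.r_lumen - spec.icm_radius
    ey, ex = cy + d * np.sin(phi), cx + d * np.cos(phi)
    u = (xx - ex) * np.cos(phi) + (yy - ey) * np.sin(phi)     # radial
    v = -(xx - ex) * np.sin(phi) + (yy - ey) * np.cos(phi)    # tangential
    inside = (u / spec.icm_radius) ** 2 + (v / spec.icm_minor) ** 2 <= 1.0
    mask[inside & (rho <= spec.r_lumen)] = 3
    return mask


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render (image, mask); the image is float in [0, 1], the mask uint8."""
    mask = render_mask(spec)
    intensities = np.asarray(spec.intensities, dtype=float)
    img = intensities[mask]
    if spec.illum_strength:
        cy, cx = spec.center
        yy, xx = np.mgrid[0:spec.size, 0:spec.size]
        ramp = ((xx - cx) * np.cos(spec.illum_angle) +
                (yy - cy) * np.sin(spec.illum_angle)) / spec.size
        img = img + spec.illum_strength * ramp
    if spec.blur_sigma:
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="nearest")
    if spec.noise_sigma:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0), mask


def random_spec(rng: np.random.Generator, size: int = 64,
                difficulty: str = "medium") -> PhantomSpec:
    """Draw one spec from the documented distributions."""
    if difficulty not in DIFFICULTY:
        raise ValueError(f"unknown difficulty {difficulty!r}; choose from {sorted(DIFFICULTY)}")
    preset = DIFFICULTY[difficulty]
    c = (size - 1) / 2.0
    center = (c + rng.uniform(-0.03, 0.03) * size, c + rng.uniform(-0.03, 0.03) * size)
    radius = rng.uniform(0.33, 0.42) * size
    zp_th = rng.uniform(0.06, 0.10) * size
    te_th = rng.uniform(0.05, 0.09) * size
    r_lumen = radius - zp_th - te_th
    base = np.asarray(preset["intensities"])
    jitter = rng.uniform(-0.02, 0.02, 5)
    return PhantomSpec(
        size=size, center=center, radius=radius,
        zp_thickness=zp_th, te_thickness=te_th,
        icm_angle=rng.uniform(0, 2 * np.pi),
        icm_radius=rng.uniform(0.38, 0.55) * r_lumen,
        icm_ecc=rng.uniform(0.0, 0.4),
        rotation=0.0,
        intensities=tuple(np.clip(base + jitter, 0.0, 1.0)),
        noise_sigma=preset["noise_sigma"] * rng.uniform(0.85, 1.15),
        blur_sigma=preset["blur_sigma"] * rng.uniform(0.85, 1.15),
        illum_strength=preset["illum_strength"] * rng.uniform(0.5, 1.5),
        illum_angle=rng.uniform(0, 2 * np.pi),
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


@dataclass
class PhantomDataset:
    images: list
    masks: list
    specs: list
    seed: int
    size: int
    difficulty: str

    def __len__(self):
        return len(self.images)

    def __getitem__(self, i):
        return self.images[i], self.masks[i]

    def pairs(self):
        return list(zip(self.images, self.masks))

    def manifest(self) -> dict:
        return {"seed": self.seed, "size": self.size, "difficulty": self.difficulty,
                "n": len(self), "specs": [s.to_dict() for s in self.specs]}

    def save(self, out_dir: str | Path):
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for i, (img, msk) in enumerate(zip(self.images, self.masks)):
            save_image_png(img, out / "images" / f"phantom_{i:04d}.png")
            save_mask_png(msk, out / "masks" / f"phantom_{i:04d}.png")
        (out / "manifest.json").write_text(json.dumps(self.manifest(), indent=1))

    @classmethod
    def from_manifest(cls, manifest: dict) -> "PhantomDataset":
        specs = [PhantomSpec.from_dict(d) for d in manifest["specs"]]
        pairs = [render_phantom(s) for s in specs]
        return cls(images=[p[0] for p in pairs], masks=[p[1] for p in pairs],
                   specs=specs, seed=manifest["seed"], size=manifest["size"],
                   difficulty=manifest["difficulty"])

    @classmethod
    def load(cls, in_dir: str | Path) -> "PhantomDataset":
        manifest = json.loads((Path(in_dir) / "manifest.json").read_text())
        return cls.from_manifest(manifest)


def make_dataset(n: int, seed: int = 0, size: int = 64,
                 difficulty: str = "medium", out_dir: str | Path | None = None,
                 min_class_pixels: int = 4) -> PhantomDataset:
    """Generate ``n`` phantoms; every mask is guaranteed to contain all five
    classes (specs whose discretized mask drops a class are redrawn)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    images, masks, specs = [], [], []
    while len(images) < n:
        spec = random_spec(rng, size=size, difficulty=difficulty)
        img, msk = render_phantom(spec)
        census = np.bincount(msk.ravel(), minlength=5)
        if (census >= min_class_pixels).all():
            images.append(img.astype(np.float32))
            masks.append(msk)
            specs.append(spec)
    ds = PhantomDataset(images=images, masks=masks, specs=specs,
                        seed=seed, size=size, difficulty=difficulty)
    if out_dir is not None:
        ds.save(out_dir)
    return ds


def rotate_sample(image: np.ndarray, mask: np.ndarray, angle: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Rotate an (image, mask) pair about the image centre: bilinear for the
    image, nearest-neighbour for the mask (labels stay in {0..4}).  A positive
    angle matches the sign of ``PhantomSpec.rotation`` (y axis points down the
    rows, so this is clockwise in the usual display orientation)."""
    deg = -np.degrees(angle)
    img = ndimage.rotate(image, deg, reshape=False, order=1, mode="constant",
                         cval=float(np.median(image)))
    msk = ndimage.rotate(mask, deg, reshape=False, order=0, mode="constant", cval=0)
    return img, msk.astype(mask.dtype)


def load_image_mask_folder(in_dir: str | Path) -> list:
    """Load (image, mask) pairs from an ``images/`` + ``masks/`` folder layout
    with matching file names — the layout used for externally prepared
    datasets (e.g. real blastocyst images resized to a working resolution).
    No manifest is required; masks must be indexed PNGs with labels 0–4."""
    root = Path(in_dir)
    pairs = []
    for img_path in sorted((root / "images").glob("*.png")):
        mask_path = root / "masks" / img_path.name
        if not mask_path.exists():
            raise FileNotFoundError(f"no mask for image {img_path.name}")
        pairs.append((load_image_png(img_path), load_mask_png(mask_path)))
    if not pairs:
        raise FileNotFoundError(f"no images found under {root / 'images'}")
    return pairs


# ----------------------------------------------------------------------
# PNG IO
# ----------------------------------------------------------------------

def save_image_png(image: np.ndarray, path: str | Path):
    """Save a float image in [0, 1] (or uint8) as an 8-bit PNG; a trailing
    3-channel axis is written as RGB, otherwise grayscale."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def load_image_png(path: str | Path) -> np.ndarray:
    img = Image.open(path).convert("L")
    return np.asarray(img, dtype=np.float32) / 255.0


def save_mask_png(mask: np.ndarray, path: str | Path):
    """Save an integer mask as an indexed (paletted) PNG with the documented
    class palette."""
    mask = np.ascontiguousarray(mask, dtype=np.uint8)
    im = Image.frombytes("P", (mask.shape[1], mask.shape[0]), mask.tobytes())
    palette = np.zeros((256, 3), dtype=np.uint8)
    for k, rgb in MASK_PALETTE.items():
        palette[k] = rgb
    im.putpalette(palette.ravel().tolist())
    im.save(path)


def load_mask_png(path: str | Path) -> np.ndarray:
    im = Image.open(path)
    return np.asarray(im, dtype=np.uint8)
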