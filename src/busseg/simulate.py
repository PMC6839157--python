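"""Synthetic breast-ultrasound (BUS) phantom generator.

Real BUS images show hypoechoic (dark) lesions embedded in a speckled,
low-contrast background.  Benign lesions present a smooth, roughly
elliptical margin; malignant lesions infiltrate surrounding tissue and
show irregular, spiculated, angulated contours.  This module emulates
exactly that morphological contrast so that segmentation networks and
metrics can be exercised end to end with a known gold standard:

* a lesion is a star-convex region described by a radial contour
  ``r(theta)`` — a base radius modulated by low-order harmonics (benign)
  or by high-order harmonics plus narrow radial spikes (malignant);
* the image is a two-level echogenicity map (lesion darker than
  background by a ``contrast`` factor), textured, multiplied by
  gamma-distributed speckle with unit mean, and blurred.

Everything is deterministic given the seeds carried by the parameter
objects; dataset-level seeds are derived per item with a splitmix-style
mix so that item *i* is reproducible independently of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as _sk_polygon

__all__ = [
    "LesionSpec",
    "SpeckleParams",
    "make_lesion_contour",
    "rasterize_mask",
    "render_image",
    "generate_dataset",
    "random_lesion_spec",
    "mask_solidity",
]

#: angles at which radial contours are sampled (periodic, endpoint excluded)
N_THETA = 720

# Benign/malignant morphology bounds
_MAX_BENIGN_HARMONIC_FRAC = 0.08  # harmonic amplitude cap, fraction of base_radius
_MIN_MALIGNANT_SPICULES = 4
_RADIUS_RANGE = (0.05, 0.35)  # base_radius bounds, fraction of image side


@dataclass(frozen=True)
class LesionSpec:
    """Geometry of one simulated lesion.

    Coordinates and radii are fractions of the image side, so the same
    spec rasterizes consistently at any resolution.
    """

    kind: str  # "benign" | "malignant"
    center: tuple[float, float] = (0.5, 0.5)  # (row, col), fractional
    base_radius: float = 0.2
    harmonics: tuple[tuple[int, float, float], ...] = ()  # (order, amplitude, phase)
    n_spicules: int = 0
    spicule_length: float = 0.0  # fraction of base_radius
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("benign", "malignant"):
            raise ValueError(f"kind must be 'benign' or 'malignant', got {self.kind!r}")
        lo, hi = _RADIUS_RANGE
        if not (lo < self.base_radius < hi):
            raise ValueError(
                f"base_radius {self.base_radius} outside ({lo}, {hi})"
            )
        if self.kind == "benign":
            cap = _MAX_BENIGN_HARMONIC_FRAC * self.base_radius
            for order, amp, _ in self.harmonics:
                if abs(amp) > cap:
                    raise ValueError(
                        f"benign harmonic order {order} amplitude {amp} exceeds "
                        f"{_MAX_BENIGN_HARMONIC_FRAC} * base_radius = {cap:.4f}"
                    )
            if self.n_spicules != 0:
                raise ValueError("benign lesions have no spicules")
        else:
            if self.n_spicules < _MIN_MALIGNANT_SPICULES:
                raise ValueError(
                    f"malignant lesions need >= {_MIN_MALIGNANT_SPICULES} spicules, "
                    f"got {self.n_spicules}"
                )
        # lesion must fit inside the unit image, spicules included
        r_max = self.base_radius * (1.0 + abs(self.spicule_length)) + sum(
            abs(a) for _, a, _ in self.harmonics
        )
        cy, cx = self.center
        if min(cy, cx, 1.0 - cy, 1.0 - cx) < r_max:
            raise ValueError(
                f"lesion (max radius {r_max:.3f}) does not fit inside image bounds "
                f"at center {self.center}"
            )


@dataclass(frozen=True)
class SpeckleParams:
    """Echogenicity and noise model for rendering a phantom image.

    contrast
        Lesion-to-background mean intensity ratio; < 1 makes the lesion
        hypoechoic (darker), as in real BUS images.
    speckle_scale
        Dispersion of the multiplicative unit-mean gamma speckle
        (shape = 1/speckle_scale**2).  0 disables noise and texture.
    blur_sigma
        Gaussian blur in pixels applied after speckle, emulating the
        finite point-spread function.
    """

    contrast: float = 0.45
    speckle_scale: float = 0.3
    blur_sigma: float = 1.0
    seed: int = 0
    background_level: float = 0.55
    texture_strength: float = 0.35  # background texture amplitude, x speckle_scale

    def validate(self) -> None:
        if not (0.0 < self.contrast < 1.0):
            raise ValueError(f"contrast must be in (0, 1), got {self.contrast}")
        if self.speckle_scale < 0:
            raise ValueError(f"speckle_scale must be >= 0, got {self.speckle_scale}")
        if self.blur_sigma < 0:
            raise ValueError(f"blur_sigma must be >= 0, got {self.blur_sigma}")
        if not (0.0 < self.background_level <= 1.0):
            raise ValueError("background_level must be in (0, 1]")


def make_lesion_contour(spec: LesionSpec, n_theta: int = N_THETA) -> np.ndarray:
    """Sample the closed radial contour ``r(theta)`` of a lesion.

    Returns an array of shape (n_theta, 2) with columns (theta, r),
    theta on [0, 2*pi) and r > 0 everywhere.  Benign contours are
    smoothly perturbed ellipses; malignant contours add high-order
    harmonics and ``n_spicules`` narrow Gaussian radial spikes at
    seed-determined angles.
    """
    spec.validate()
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    r = np.full(n_theta, spec.base_radius, dtype=float)
    for order, amp, phase in spec.harmonics:
        r += amp * np.cos(order * theta + phase)
    if spec.kind == "malignant" and spec.n_spicules > 0:
        rng = np.random.default_rng(spec.seed)
        # spicule angles jittered around an even spread so spikes never pile up
        base = np.linspace(0.0, 2.0 * math.pi, spec.n_spicules, endpoint=False)
        angles = base + rng.uniform(-0.3, 0.3, size=spec.n_spicules)
        widths = rng.uniform(0.06, 0.14, size=spec.n_spicules)  # radians
        heights = spec.spicule_length * spec.base_radius * rng.uniform(
            0.6, 1.0, size=spec.n_spicules
        )
        for ang, width, height in zip(angles, widths, heights):
            # periodic angular distance
            d = np.angle(np.exp(1j * (theta - ang)))
            r += height * np.exp(-0.5 * (d / width) ** 2)
    if np.any(r <= 0):
        raise ValueError("contour radius became non-positive; reduce perturbations")
    return np.column_stack([theta, r])


def rasterize_mask(
    contour: np.ndarray,
    side: int,
    center: tuple[float, float] = (0.5, 0.5),
) -> np.ndarray:
    """Rasterize a radial contour into a binary lesion mask.

    Pixels inside the polygon obtained by joining the contour samples
    are labeled 1.  Raises if the polygon leaves the image or rasterizes
    to an empty mask.
    """
    if side <= 0:
        raise ValueError(f"side must be positive, got {side}")
    theta, r = contour[:, 0], contour[:, 1]
    if np.any(r <= 0):
        raise ValueError("degenerate contour: non-positive radius")
    rows = (center[0] + r * np.sin(theta)) * side
    cols = (center[1] + r * np.cos(theta)) * side
    if rows.min() < -0.5 or cols.min() < -0.5 or rows.max() > side - 0.5 or cols.max() > side - 0.5:
        raise ValueError("contour extends outside the image bounds")
    rr, cc = _sk_polygon(rows, cols, shape=(side, side))
    mask = np.zeros((side, side), dtype=np.uint8)
    mask[rr, cc] = 1
    if mask.sum() == 0:
        raise ValueError("contour rasterized to an empty mask")
    return mask


def contour_area(contour: np.ndarray) -> float:
    """Analytic area enclosed by a radial contour, in fractional units
    (multiply by side**2 for pixels): A = 1/2 integral r(theta)^2 dtheta."""
    r = contour[:, 1]
    dtheta = 2.0 * math.pi / len(r)
    return 0.5 * float(np.sum(r**2)) * dtheta


def render_image(mask: np.ndarray, sp: SpeckleParams) -> np.ndarray:
    """Render a grayscale phantom image from a binary lesion mask.

    Pipeline: two-level echogenicity map (lesion = contrast x
    background level) + blurred background texture, multiplied by
    unit-mean gamma speckle, Gaussian-blurred, clipped to [0, 1].
    With ``speckle_scale == 0`` and ``blur_sigma == 0`` the output is the
    exact two-level map.
    """
    sp.validate()
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    mask = mask.astype(bool)
    clean = np.where(mask, sp.contrast * sp.background_level, sp.background_level)
    rng = np.random.default_rng(sp.seed)
    if sp.speckle_scale > 0:
        # slowly-varying echotexture, amplitude tied to the noise level
        texture = gaussian_filter(rng.standard_normal(mask.shape), sigma=6.0)
        texture /= max(texture.std(), 1e-12)
        clean = clean * (
            1.0 + sp.texture_strength * sp.speckle_scale * texture
        )
        shape = 1.0 / sp.speckle_scale**2
        noise = rng.gamma(shape, scale=1.0 / shape, size=mask.shape)
        img = clean * noise
    else:
        img = clean
    if sp.blur_sigma > 0:
        img = gaussian_filter(img, sigma=sp.blur_sigma)
    return np.clip(img, 0.0, 1.0)


def _splitmix64(x: int) -> int:
    """SplitMix64 finalizer; decorrelates per-item seeds derived from a
    master seed + index."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) & 0xFFFFFFFFFFFFFFFF


def item_seed(master_seed: int, index: int) -> int:
    """Deterministic per-item seed below 2**31."""
    return _splitmix64(master_seed * 0x10001 + index) % (2**31)


def random_lesion_spec(kind: str, seed: int) -> LesionSpec:
    """Draw a plausible lesion geometry of the given kind.

    Benign: near-elliptical, second/third-order harmonics within the
    smoothness cap.  Malignant: stronger mid-order harmonics plus 4-8
    spicules — the irregular, spiculated margin that distinguishes
    infiltrating lesions.
    """
    rng = np.random.default_rng(seed)
    base_radius = float(rng.uniform(0.13, 0.24))
    if kind == "benign":
        cap = _MAX_BENIGN_HARMONIC_FRAC * base_radius
        harmonics = tuple(
            (order, float(rng.uniform(0.3, 0.95) * cap), float(rng.uniform(0, 2 * math.pi)))
            for order in (2, 3)
        )
        spicule_length = 0.0
        n_spicules = 0
    elif kind == "malignant":
        harmonics = tuple(
            (int(order), float(rng.uniform(0.04, 0.10) * base_radius), float(rng.uniform(0, 2 * math.pi)))
            for order in (3, 5, 7)
        )
        spicule_length = float(rng.uniform(0.35, 0.6))
        n_spicules = int(rng.integers(4, 9))
    else:
        raise ValueError(f"unknown lesion kind {kind!r}")
    # center jitter bounded so the worst-case radius stays inside the frame
    r_max = base_radius * (1.0 + spicule_length) + sum(a for _, a, _ in harmonics)
    jitter = max(0.0, 0.5 - r_max - 0.02)
    center = (
        0.5 + float(rng.uniform(-jitter, jitter)),
        0.5 + float(rng.uniform(-jitter, jitter)),
    )
    return LesionSpec(
        kind=kind,
        center=center,
        base_radius=base_radius,
        harmonics=harmonics,
        n_spicules=n_spicules,
        spicule_length=spicule_length,
        seed=seed,
    )


def generate_dataset(
    n: int,
    malignant_fraction: float = 179 / 387,
    side: int = 160,
    master_seed: int = 0,
    speckle: SpeckleParams | None = None,
) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """Generate ``n`` seeded (image, mask, label) phantoms.

    Exactly ``round(n * malignant_fraction)`` items are malignant; the
    default fraction mirrors the 179:208 malignant:benign balance of a
    typical clinical BUS collection.  Item order is a seeded shuffle and
    every item is reproducible from ``master_seed`` alone.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if not (0.0 <= malignant_fraction <= 1.0):
        raise ValueError("malignant_fraction must be in [0, 1]")
    n_mal = round(n * malignant_fraction)
    labels = ["malignant"] * n_mal + ["benign"] * (n - n_mal)
    order_rng = np.random.default_rng(master_seed)
    order_rng.shuffle(labels)
    base_sp = speckle if speckle is not None else SpeckleParams()
    out = []
    for i, label in enumerate(labels):
        seed_i = item_seed(master_seed, i)
        spec = random_lesion_spec(label, seed_i)
        contour = make_lesion_contour(spec)
        mask = rasterize_mask(contour, side, center=spec.center)
        rng_i = np.random.default_rng(seed_i + 1)
        sp = replace(
            base_sp,
            contrast=float(rng_i.uniform(0.35, 0.60)),
            seed=seed_i,
        )
        image = render_image(mask, sp)
        out.append((image, mask, label))
    return out


def mask_solidity(mask: np.ndarray) -> float:
    """Area / convex-hull-area of a binary mask.

    Spiculated (malignant) shapes are markedly less solid than smooth
    elliptical (benign) ones, which is the separation the generator must
    reproduce.
    """
    from skimage.morphology import convex_hull_image

    area = float(mask.sum())
    if area == 0:
        raise ValueError("empty mask has no solidity")
    hull = convex_hull_image(mask.astype(bool))
    return area / float(hull.sum())
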