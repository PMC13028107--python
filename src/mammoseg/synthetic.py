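"""Mammogram-like phantoms with exact ground truth, plus perturbations.

A phantom emulates the properties that make dense mammograms hard to
segment: a breast-shaped silhouette on a dark background, smooth
fibroglandular-like texture, bright tumors with soft (logistic-profiled)
rims rather than step edges, a smooth low-order polynomial multiplicative
bias field of known analytic form, and additive Gaussian noise. The
semantic mask, per-tumor instance map, and true bias field are returned
before bias and noise are applied, so they are exact by construction.

Touching tumors (controlled by ``overlap_fraction``) produce a single
connected semantic component containing several instances, exercising
the watershed splitting stage.

The perturbation harness applies the robustness battery: additive
Gaussian noise, salt-and-pepper impulses, contrast reduction about the
breast mean, rotation with bilinear interpolation, and Gaussian blur.
All randomness is driven by explicit seeds; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erfc

from .imagio import IntensityImage, as_pixels
from .mico import BiasField, make_polynomial_basis

__all__ = [
    "PhantomSpec",
    "battery_specs",
    "BATTERY_SEEDS",
    "PERTURBATIONS",
    "generate_phantom",
    "perturb",
    "rotate_pair",
]

TISSUE_LEVEL = 90.0
TUMOR_LEVEL = 200.0
RIM_SIGMA = 2.0  # px; Gaussian-profiled edge, half-level exactly at the true boundary

# the standard battery: 20 fixed seeds at the reference configuration
BATTERY_SEEDS = tuple(range(20))

# robustness-battery magnitudes (kind -> magnitude)
PERTURBATIONS = {
    "gaussian_noise": 10.0,
    "salt_pepper": 0.02,
    "low_contrast": 0.5,
    "rotate": 15.0,
    "gaussian_blur": 2.0,
}


@dataclass
class PhantomSpec:
    """Reference configuration: 256x256, 1-3 tumors, order-2 bias of
    relative amplitude 0.3, additive noise sigma 5 on the 0-255 scale."""

    shape: tuple[int, int] = (256, 256)
    n_tumors: int = 2
    tumor_radius_range: tuple[int, int] = (10, 22)
    overlap_fraction: float = 0.25
    bias_order: int = 2
    bias_amplitude: float = 0.3
    noise_sigma: float = 5.0
    texture_sigma: float = 8.0
    seed: int = 0


def battery_specs(seeds=BATTERY_SEEDS) -> list[PhantomSpec]:
    """The standard phantom battery: fixed seeds, 1-3 tumors cycling."""
    return [PhantomSpec(n_tumors=1 + s % 3, seed=s) for s in seeds]


def _breast_mask(shape) -> np.ndarray:
    rows, cols = shape
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    R = 0.88 * rows
    return (c**2 + (r - rows / 2.0) ** 2) < R**2


def _place_tumors(spec: PhantomSpec, breast: np.ndarray, rng) -> list[tuple[float, float, float]]:
    rows, cols = spec.shape
    rmin, rmax = spec.tumor_radius_range
    placed: list[tuple[float, float, float]] = []
    for k in range(spec.n_tumors):
        radius = float(rng.uniform(rmin, rmax))
        margin = int(np.ceil(radius)) + 4
        interior = ndimage.binary_erosion(breast, iterations=margin)
        ok_rows, ok_cols = np.nonzero(interior)
        if len(ok_rows) == 0:
            raise RuntimeError("breast region too small for requested tumor radius")
        touch = placed and rng.random() < spec.overlap_fraction
        for _ in range(1000):
            if touch:
                pr, pc, prad = placed[rng.integers(len(placed))]
                theta = rng.uniform(0, 2 * np.pi)
                d = (prad + radius) * rng.uniform(0.75, 0.95)
                cy, cx = pr + d * np.sin(theta), pc + d * np.cos(theta)
                iy, ix = int(round(cy)), int(round(cx))
                if not (0 <= iy < rows and 0 <= ix < cols and interior[iy, ix]):
                    continue
            else:
                j = rng.integers(len(ok_rows))
                cy, cx = float(ok_rows[j]), float(ok_cols[j])
                if any(
                    np.hypot(cy - pr, cx - pc) < radius + prad + 3
                    for pr, pc, prad in placed
                ):
                    continue
            placed.append((cy, cx, radius))
            break
        else:
            raise RuntimeError(
                f"could not place tumor {k + 1}/{spec.n_tumors} after 1000 attempts"
            )
    return placed


def generate_phantom(spec: PhantomSpec):
    """Build one phantom.

    Returns ``(image, semantic, instances, true_bias)``; the masks and
    bias refer to the pre-noise, pre-bias scene. The bias field is
    positive, has unit mean over the breast, and deviates from 1 by at
    most ``bias_amplitude`` (relative) inside the breast.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    breast = _breast_mask(spec.shape)

    # band-passed texture: fibroglandular structure lives at mid frequencies;
    # removing the image-scale components keeps it spectrally separable from
    # the low-order polynomial bias, so the phantom's true bias stays
    # identifiable (a low-pass texture would alias into the bias subspace).
    noise = rng.standard_normal(spec.shape)
    texture = ndimage.gaussian_filter(noise, spec.texture_sigma) - ndimage.gaussian_filter(
        noise, 4.0 * spec.texture_sigma
    )
    std = texture.std()
    if std > 0:
        texture *= 12.0 / std
    scene = np.where(breast, TISSUE_LEVEL + texture, 0.0)

    tumors = _place_tumors(spec, breast, rng)
    semantic = np.zeros(spec.shape, dtype=np.uint8)
    instances = np.zeros(spec.shape, dtype=np.int32)
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    blend = np.zeros(spec.shape)
    best = np.full(spec.shape, np.inf)
    for k, (cy, cx, radius) in enumerate(tumors, start=1):
        d = np.hypot(rr - cy, cc - cx)
        inside = d <= radius
        semantic[inside] = 1
        rel = d / radius
        claim = inside & (rel < best)
        instances[claim] = k
        best = np.where(claim, rel, best)
        # erf profile = hard disc blurred with a sigma = RIM_SIGMA Gaussian
        blend = np.maximum(blend, 0.5 * erfc((d - radius) / (RIM_SIGMA * np.sqrt(2.0))))
    scene = np.where(breast, scene * (1 - blend) + TUMOR_LEVEL * blend, 0.0)

    basis = make_polynomial_basis(spec.shape, spec.bias_order)
    w = np.concatenate([[0.0], rng.uniform(-1, 1, size=len(basis) - 1)])
    raw = np.tensordot(w, basis, axes=(0, 0))
    dev = raw - raw[breast].mean()
    scale = np.abs(dev[breast]).max()
    bias = np.ones(spec.shape)
    if scale > 0:
        bias += spec.bias_amplitude * dev / scale
    bias /= bias[breast].mean()
    coeffs = np.linalg.lstsq(
        basis.reshape(len(basis), -1).T, bias.ravel(), rcond=None
    )[0]

    image = scene * bias + rng.normal(0.0, spec.noise_sigma, spec.shape)
    image = np.clip(image, 0.0, 255.0)
    return (
        IntensityImage(image),
        semantic,
        instances,
        BiasField(values=bias, coefficients=coeffs, basis_order=spec.bias_order),
    )


def perturb(image, kind: str, magnitude: float, seed: int = 0) -> IntensityImage:
    """Apply one robustness perturbation; magnitude 0 is the identity."""
    pix = as_pixels(image).copy()
    rng = np.random.default_rng(seed)
    if kind == "gaussian_noise":
        if magnitude < 0:
            raise ValueError("noise sigma must be >= 0")
        if magnitude > 0:
            pix = np.clip(pix + rng.normal(0, magnitude, pix.shape), 0.0, 255.0)
    elif kind == "salt_pepper":
        if not 0 <= magnitude <= 1:
            raise ValueError("salt-pepper density must be in [0, 1]")
        hit = rng.random(pix.shape) < magnitude
        salt = rng.random(pix.shape) < 0.5
        pix = np.where(hit, np.where(salt, 255.0, 0.0), pix)
    elif kind == "low_contrast":
        if not 0 < magnitude <= 1:
            raise ValueError("contrast factor must be in (0, 1]")
        if magnitude != 1:
            roi = pix > 5
            mean = pix[roi].mean() if roi.any() else pix.mean()
            pix = mean + magnitude * (pix - mean)
    elif kind == "rotate":
        if magnitude != 0:
            pix = ndimage.rotate(pix, magnitude, reshape=False, order=1, mode="constant", cval=0.0)
            pix = np.clip(pix, 0.0, 255.0)
    elif kind == "gaussian_blur":
        if magnitude < 0:
            raise ValueError("blur sigma must be >= 0")
        if magnitude > 0:
            pix = ndimage.gaussian_filter(pix, magnitude)
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    return IntensityImage(pix)


def rotate_pair(image, mask, angle_degrees: float):
    """Rotate an image (bilinear) and its mask (nearest) consistently."""
    pix = as_pixels(image)
    m = np.asarray(mask)
    if pix.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if angle_degrees == 0:
        return IntensityImage(pix.copy()), m.copy()
    rim = ndimage.rotate(pix, angle_degrees, reshape=False, order=1, mode="constant", cval=0.0)
    rmk = ndimage.rotate(m, angle_degrees, reshape=False, order=0, mode="constant", cval=0)
    return IntensityImage(np.clip(rim, 0.0, 255.0)), rmk.astype(m.dtype)
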