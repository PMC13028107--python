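"""Multiplicative Intrinsic Component Optimization (MICO) in 2-D.

The mammogram is modeled as a true piecewise-constant tissue image
multiplied by a smooth, slowly varying bias field b(x, y):

    I(x, y) ≈ sum_k M_k(x, y) * C_k * b(x, y)

where M_k are fuzzy class memberships (crisp for q = 1), C_k class mean
intensities, and b lies in the span of low-order 2-D polynomials.  The
energy

    E(M, C, b) = sum_k ∫ M_k^q (I - C_k b)^2 dΩ

is minimized by exact alternating coordinate descent over M, C, and the
polynomial coefficients of b, so E is non-increasing across iterations.
The bias-corrected image is I / (b + eps), and the crisp argmax of the
memberships is the initial tissue segmentation.

The bias/mean product is only identifiable up to a scale; after every
bias update b is rescaled to unit mean over the breast ROI (with the
class means absorbing the inverse factor), which leaves E unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .imagio import as_pixels

log = logging.getLogger(__name__)

EPS_DIV = 1e-6  # guard for the bias division in the corrected image

__all__ = [
    "BiasField",
    "MicoState",
    "make_polynomial_basis",
    "update_memberships",
    "update_class_means",
    "update_bias_field",
    "mico_energy",
    "run_mico",
]


@dataclass
class BiasField:
    """Smooth multiplicative bias field b = sum_k w_k * Bas_k.

    ``values`` is the evaluated field; ``coefficients`` the weight vector
    w over the polynomial basis of total degree <= ``basis_order``.
    """

    values: np.ndarray
    coefficients: np.ndarray | None = None
    basis_order: int | None = None


@dataclass
class MicoState:
    memberships: np.ndarray  # (K, rows, cols), sum_k = 1 per pixel
    means: np.ndarray  # (K,)
    bias: BiasField
    q: float = 1.0
    energy_trace: list[float] = field(default_factory=list)


def make_polynomial_basis(shape: tuple[int, int], order: int) -> np.ndarray:
    """Stack of monomials x^i y^j, i + j <= order, on [-1, 1]^2 coordinates.

    The count is (order+1)(order+2)/2 and the first basis is the constant
    1. Ordering: by total degree, then by the power of the row coordinate.
    """
    if order < 0:
        raise ValueError("basis order must be >= 0")
    rows, cols = shape
    y = np.linspace(-1.0, 1.0, rows)[:, None]
    x = np.linspace(-1.0, 1.0, cols)[None, :]
    bases = []
    for d in range(order + 1):
        for i in range(d + 1):  # i = power of row coordinate
            bases.append((y**i) * (x ** (d - i)))
    return np.stack([np.broadcast_to(b, shape).astype(np.float64) for b in bases])


def update_memberships(img, state: MicoState) -> np.ndarray:
    """Closed-form membership update with means and bias held fixed.

    q = 1: crisp one-hot assignment to the class minimizing (I - C_k b)^2,
    ties broken by the lowest class index.  q > 1: the fuzzy-c-means form
    ((I - C_k b)^2)^(-1/(q-1)) normalized over classes; pixels with an
    exact fit to some class become one-hot there.
    """
    if state.q < 1:
        raise ValueError(f"fuzziness q must be >= 1, got {state.q}")
    pix = as_pixels(img)
    b = state.bias.values
    d2 = (pix[None] - state.means[:, None, None] * b[None]) ** 2  # (K, r, c)
    if state.q == 1:
        k = np.argmin(d2, axis=0)
        M = (np.arange(len(state.means))[:, None, None] == k[None]).astype(np.float64)
        return M
    with np.errstate(divide="ignore"):
        u = d2 ** (-1.0 / (state.q - 1.0))
    # exact fits: d2 == 0 -> infinite weight -> one-hot over the zero set
    inf_mask = ~np.isfinite(u)
    any_inf = inf_mask.any(axis=0)
    u = np.where(any_inf[None], inf_mask.astype(np.float64), u)
    return u / u.sum(axis=0)


def update_class_means(img, state: MicoState, weights: np.ndarray) -> np.ndarray:
    """Exact mean update C_k = sum(b I M_k^q W) / sum(b^2 M_k^q W).

    ``weights`` is the ROI indicator (1 inside the breast, 0 outside).
    Empty classes keep their previous mean with a logged warning.
    """
    pix = as_pixels(img)
    b = state.bias.values
    W = np.asarray(weights, dtype=np.float64)
    Mq = state.memberships**state.q
    means = state.means.copy()
    num = (b * pix * Mq * W).sum(axis=(1, 2))
    den = (b * b * Mq * W).sum(axis=(1, 2))
    occupied = den > 0
    if not occupied.all():
        log.warning("MICO: %d empty class(es); means left unchanged", (~occupied).sum())
    means[occupied] = num[occupied] / den[occupied]
    return means


def update_bias_field(img, state: MicoState, basis: np.ndarray, weights: np.ndarray) -> BiasField:
    """Solve the normal equations for the bias coefficients w = A^-1 V.

    With memberships and means fixed, dE/dw = 0 gives

        A[m,n] = sum_x Bas_m Bas_n * (sum_k C_k^2 M_k^q) * W
        V[m]   = sum_x Bas_m * I * (sum_k C_k M_k^q) * W

    An ill-conditioned Gram matrix falls back to least squares with the
    condition number logged.
    """
    pix = as_pixels(img)
    W = np.asarray(weights, dtype=np.float64)
    Mq = state.memberships**state.q
    s1 = np.tensordot(state.means, Mq, axes=(0, 0))  # sum_k C_k M_k^q
    s2 = np.tensordot(state.means**2, Mq, axes=(0, 0))
    nb = basis.shape[0]
    B = basis.reshape(nb, -1)
    wa = (s2 * W).ravel()
    wv = (pix * s1 * W).ravel()
    A = (B * wa) @ B.T
    V = B @ wv
    cond = np.linalg.cond(A)
    if cond > 1e12:
        log.warning("MICO bias Gram matrix ill-conditioned (cond=%.3g); using lstsq", cond)
        w = np.linalg.lstsq(A, V, rcond=None)[0]
    else:
        w = np.linalg.solve(A, V)
    values = np.tensordot(w, basis, axes=(0, 0))
    order = state.bias.basis_order
    return BiasField(values=values, coefficients=w, basis_order=order)


def mico_energy(img, state: MicoState, weights: np.ndarray | None = None) -> float:
    """Clustering energy sum over the ROI of sum_k M_k^q (I - C_k b)^2."""
    pix = as_pixels(img)
    b = state.bias.values
    W = 1.0 if weights is None else np.asarray(weights, dtype=np.float64)
    d2 = (pix[None] - state.means[:, None, None] * b[None]) ** 2
    return float(((state.memberships**state.q) * d2 * W).sum())


def run_mico(
    img,
    n_classes: int = 3,
    q: float = 1.0,
    iters: int = 20,
    basis_order: int = 3,
    roi: np.ndarray | None = None,
    rtol: float = 1e-6,
    edge_exclude: float = 0.1,
):
    """Alternating minimization: memberships -> means -> bias, ``iters`` rounds.

    Returns ``(S0, bias, I_bc, state)`` where S0 is the crisp label map
    (0 outside the ROI, 1..K inside, classes sorted by ascending mean so
    ids are reproducible), ``bias`` the fitted field, and ``I_bc`` the
    bias-corrected image I / (b + 1e-6).

    Class means are initialized evenly spaced between the minimum and
    maximum ROI intensity and the bias at 1. Anchoring the extreme
    classes at the intensity extremes lets a small bright structure
    (a tumor occupying a few percent of the breast) claim its own class;
    quantile-style inits place every mean inside the dominant tissue
    mode, and the alternating descent then converges to a local minimum
    in which the spare classes split that mode and the bias field soaks
    up the misfit. Stops early when the relative energy decrease falls
    below ``rtol``.

    ``edge_exclude`` drops that fraction of the highest-gradient ROI
    pixels from the fitting weights (means and bias only; memberships
    and labels are still computed everywhere). Mixed boundary pixels --
    a blurred tumor rim forms a wide intensity bridge between tissue
    and tumor -- violate the piecewise-constant model and otherwise
    drag the bright class mean down the bridge until it swallows bright
    tissue, corrupting the bias fit with it.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    pix = as_pixels(img)
    if roi is None:
        roi = np.ones(pix.shape, dtype=np.uint8)
    W_roi = np.asarray(roi, dtype=np.float64)
    W = W_roi
    if edge_exclude > 0:
        from scipy import ndimage

        gy, gx = np.gradient(ndimage.gaussian_filter(pix, 1.0))
        gmag = np.hypot(gy, gx)
        thr = np.quantile(gmag[W_roi > 0], 1.0 - edge_exclude)
        W = W_roi * (gmag <= thr)
    roi_vals = pix[W > 0]
    if n_classes == 1:
        means = np.array([roi_vals.mean()])
    else:
        means = np.linspace(roi_vals.min(), roi_vals.max(), n_classes)
    basis = make_polynomial_basis(pix.shape, basis_order)
    state = MicoState(
        memberships=np.full((n_classes,) + pix.shape, 1.0 / n_classes),
        means=np.asarray(means, dtype=np.float64),
        bias=BiasField(values=np.ones(pix.shape), basis_order=basis_order),
        q=q,
    )
    for it in range(iters):
        state.memberships = update_memberships(pix, state)
        state.means = update_class_means(pix, state, W)
        state.bias = update_bias_field(pix, state, basis, W)
        # resolve the C*b scale ambiguity: unit-mean bias over the ROI
        scale = float((state.bias.values * W).sum() / W.sum())
        if scale > 0:
            state.bias.values /= scale
            if state.bias.coefficients is not None:
                state.bias.coefficients /= scale
            state.means *= scale
        e = mico_energy(pix, state, W)
        log.debug("MICO iter %d energy %.6g", it, e)
        state.energy_trace.append(e)
        if it > 0:
            prev = state.energy_trace[-2]
            if prev > 0 and (prev - e) / prev < rtol:
                break
    # reorder classes by ascending mean for reproducible label ids
    order = np.argsort(state.means, kind="stable")
    state.means = state.means[order]
    state.memberships = state.memberships[order]
    S0 = np.zeros(pix.shape, dtype=np.int32)
    inside = W_roi > 0  # labels cover the whole ROI, not just fitting pixels
    S0[inside] = np.argmax(state.memberships, axis=0)[inside] + 1
    # the polynomial extrapolates arbitrarily outside the ROI (it can cross
    # zero there); clamp before dividing so the corrected image's dynamic
    # range stays meaningful everywhere
    b_safe = np.clip(state.bias.values, 0.1, 10.0)
    I_bc = pix / (b_safe + EPS_DIV)
    return S0, state.bias, I_bc, state
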