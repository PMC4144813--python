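"""Laurdan generalized-polarization image analysis.

GP = (I_ord - g * I_dis) / (I_ord + g * I_dis) per pixel, where I_ord is
the 400–460 nm channel, I_dis the 470–530 nm channel and g the
instrument G factor measured on a reference of known GP (Laurdan in pure
DMSO).  The G factor multiplies the disordered channel — the convention
of the widely used ImageJ GP macro; it is configurable because the
corrected formula is rarely written out.  Dim pixels (low summed raw
intensity) are masked before any averaging, and per-field means can be
normalized to a control condition by difference (default) or ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .datatypes import GPImagePair


@dataclass(frozen=True)
class GPResult:
    """Masked GP map and its field statistics."""

    gp_map: np.ndarray  # NaN where masked
    mask: np.ndarray  # True where pixel is valid
    field_mean: float
    n_pixels: int
    g_factor: float


def default_mask_threshold(pair: GPImagePair, fraction: float = 0.05) -> float:
    """Mask cutoff: ``fraction`` of the 99th-percentile summed intensity.

    Excludes background without clipping dim membrane pixels.
    """
    total = pair.I_ordered + pair.I_disordered
    return fraction * float(np.percentile(total, 99.0))


def gp_map(
    pair: GPImagePair,
    mask_threshold: float | None = None,
    g_factor: float | None = None,
) -> GPResult:
    """Per-pixel GP with G-factor correction, masking and field mean.

    Pixels whose raw summed intensity I_ord + I_dis falls below
    ``mask_threshold`` (default: 5% of the 99th-percentile summed
    intensity) are masked; the field mean runs over unmasked pixels only.
    Raises when every pixel is masked.
    """
    g = pair.g_factor if g_factor is None else float(g_factor)
    if g <= 0:
        raise ValueError(f"g_factor must be positive, got {g}")
    if mask_threshold is None:
        mask_threshold = default_mask_threshold(pair)
    raw_sum = pair.I_ordered + pair.I_disordered
    corr_dis = g * pair.I_disordered
    denom = pair.I_ordered + corr_dis
    mask = (raw_sum >= mask_threshold) & (denom > 0)
    if not mask.any():
        raise ValueError("all pixels masked; lower the mask threshold")
    gp = np.full(pair.I_ordered.shape, np.nan)
    gp[mask] = (pair.I_ordered[mask] - corr_dis[mask]) / denom[mask]
    return GPResult(
        gp_map=gp,
        mask=mask,
        field_mean=float(np.mean(gp[mask])),
        n_pixels=int(mask.sum()),
        g_factor=g,
    )


def g_factor_from_reference(
    ref_pair: GPImagePair,
    gp_ref_expected: float,
    mask_threshold: float | None = None,
) -> float:
    """Solve for the G factor from a homogeneous reference field.

    Finds g such that the field-mean GP of the reference equals the known
    value (e.g. Laurdan in pure DMSO).  The mean GP is strictly
    decreasing in g, so the root is unique; gp_ref_expected = ±1 is
    degenerate (it would require g -> 0 or g -> infinity).
    """
    if not -1.0 < gp_ref_expected < 1.0:
        raise ValueError(
            f"gp_ref_expected must lie strictly inside (-1, 1), got {gp_ref_expected}"
        )

    def objective(g):
        return gp_map(ref_pair, mask_threshold=mask_threshold, g_factor=g).field_mean - gp_ref_expected

    lo, hi = 1e-8, 1e8
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        raise ValueError("no G factor in (0, inf) reproduces the reference GP")
    return float(brentq(objective, lo, hi, xtol=1e-12, rtol=1e-12))


def normalize_to_control(field_means, control_mean: float, mode: str = "difference"):
    """Normalize per-field GP means to a control condition.

    ``difference`` subtracts the control mean; ``ratio`` divides by it.
    Elementwise: permuting the input permutes the output identically.
    """
    v = np.asarray(field_means, dtype=float)
    if v.size == 0:
        raise ValueError("no field means to normalize")
    if not np.isfinite(control_mean):
        raise ValueError("control mean must be finite")
    if mode == "difference":
        return v - control_mean
    if mode == "ratio":
        if control_mean == 0:
            raise ValueError("control mean must be nonzero in ratio mode")
        return v / control_mean
    raise ValueError(f"mode must be 'difference' or 'ratio', got {mode!r}")
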