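"""Flip-flop event detection and the two-step rate model.

A flip-flop is complete only when the molecule travels from one
equilibrium position across the midplane to the *opposite* equilibrium
position, so event detection uses a hysteresis two-state automaton with
thresholds at ±z_eq: rattling around the bilayer center never counts.

Rates follow the two-step model: k_f = k_d * exp(-dG_center / RT) is the
rate of moving from the equilibrium position to the bilayer center,
k_d = 1/t_d the rate of returning from the center to an equilibrium
position (t_d an input time range, not estimated from data), and the
overall flip-flop rate is the series combination
k_flip = 0.5 / (1/k_f + 1/k_d), approximately k_f/2 when k_f << k_d.
"""

from __future__ import annotations

import warnings

import numpy as np

from .constants import DEFAULT_TEMPERATURE, NS_TO_S, thermal_energy
from .datatypes import FlipFlopEvents, KineticsResult, ProfileFeatures, ReactionCoordSeries


def detect_flipflops(
    series: ReactionCoordSeries,
    z_low: float,
    z_high: float,
) -> FlipFlopEvents:
    """Count leaflet transitions in a Z(t) trace with hysteresis thresholds.

    The molecule is in leaflet A while z <= z_low, in leaflet B while
    z >= z_high, and keeps its previous state in between.  Each A->B or
    B->A transition is one event, stamped at the first crossing of the
    far threshold.  Directions are +1 (upward, A->B) and -1 (downward).
    """
    if not (z_low < 0.0 < z_high):
        raise ValueError(f"need z_low < 0 < z_high, got ({z_low}, {z_high})")
    z = series.z
    labels = np.zeros(z.size, dtype=np.int8)
    labels[z <= z_low] = -1
    labels[z >= z_high] = +1
    hit = labels != 0
    if not hit.any():
        warnings.warn(
            "series never reaches either threshold; zero flip-flop events",
            stacklevel=2,
        )
        empty = np.empty(0)
        return FlipFlopEvents(empty, empty.astype(int), empty, z_low, z_high)
    idx = np.flatnonzero(hit)
    lab = labels[idx]
    change = np.flatnonzero(lab[1:] != lab[:-1]) + 1
    event_idx = idx[change]
    event_times = series.times[event_idx]
    directions = lab[change].astype(int)
    waiting = np.diff(event_times) if event_times.size > 1 else np.empty(0)
    return FlipFlopEvents(event_times, directions, waiting, z_low, z_high)


def rate_kd(t_d: float) -> float:
    """Center-to-equilibrium return rate k_d = 1/t_d, t_d in ns, result in s^-1."""
    if t_d <= 0:
        raise ValueError(f"t_d must be positive, got {t_d}")
    return 1.0 / (t_d * NS_TO_S)


def rate_kf(dG_center: float, k_d: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Equilibrium-to-center rate k_f = k_d * exp(-dG_center / RT) in s^-1."""
    if k_d <= 0:
        raise ValueError(f"k_d must be positive, got {k_d}")
    rt = thermal_energy(temperature)
    return k_d * np.exp(-dG_center / rt)


def rate_kflip(k_f: float, k_d: float, mode: str = "approx") -> float:
    """Overall flip-flop rate: full series formula or the k_f/2 approximation."""
    if k_f <= 0 or k_d <= 0:
        raise ValueError("both rates must be positive")
    if mode == "approx":
        return k_f / 2.0
    if mode == "full":
        return 0.5 / (1.0 / k_f + 1.0 / k_d)
    raise ValueError(f"mode must be 'approx' or 'full', got {mode!r}")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (for comparison with printed tables)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def kinetics_table(
    features,
    t_d_range: tuple,
    temperature: float = DEFAULT_TEMPERATURE,
    mode: str = "approx",
) -> KineticsResult:
    """Rate-constant ranges for one PMF row from its dG_center and a t_d range.

    ``features`` is a ProfileFeatures or a bare dG_center in kJ/mol.
    The short t_d gives the fast end of every rate range and vice versa;
    ranges are returned ordered (low, high) at full precision (use
    ``round_sig`` for 2-significant-figure table display).
    """
    dg = features.dG_center if isinstance(features, ProfileFeatures) else float(features)
    t_lo, t_hi = t_d_range
    if not 0 < t_lo <= t_hi:
        raise ValueError(f"t_d_range must be ordered positive, got {t_d_range}")
    kd_pair = (rate_kd(t_hi), rate_kd(t_lo))  # long t_d -> slow k_d
    kf_pair = tuple(rate_kf(dg, kd, temperature) for kd in kd_pair)
    kflip_pair = tuple(rate_kflip(kf, kd, mode) for kf, kd in zip(kf_pair, kd_pair))
    return KineticsResult(
        dG_center=dg,
        t_d_range=(t_lo, t_hi),
        k_d_range=kd_pair,
        k_f_range=kf_pair,
        k_flip_range=kflip_pair,
        temperature=temperature,
        mode=mode,
    )
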