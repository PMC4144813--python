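"""Overdamped Langevin dynamics along the bilayer normal.

The steroid position z evolves by the Euler–Maruyama discretization of

    dz = (D / RT) * F(z) dt + sqrt(2 D dt) * xi,        F = -dU/dz,

with U the bilayer potential plus an optional harmonic umbrella bias.
This is the high-friction limit: inertia is dropped because every
equilibrium quantity (densities, free-energy profiles) and the barrier
ranking of flip-flop counts depend only on U and T, not on momentum
details.  The base-potential force is evaluated by linear interpolation
on a dense precomputed grid, which makes the stepping kernel a single
numba-compiled loop independent of the potential's functional form.

Boundaries: walkers are reflected at the edges of the force grid (well
outside the water plateau), so desorbed molecules re-enter rather than
drifting to infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import DEFAULT_TEMPERATURE, thermal_energy
from .datatypes import ReactionCoordSeries
from .potentials import BilayerPotential


@dataclass(frozen=True)
class HarmonicBias:
    """Umbrella restraint 0.5 * k_bias * (z - z0_bias)^2."""

    z0_bias: float
    k_bias: float

    def __post_init__(self):
        if self.k_bias <= 0:
            raise ValueError(f"bias force constant must be positive, got {self.k_bias}")


@dataclass(frozen=True)
class LangevinSpec:
    """Full specification of one overdamped Langevin run.

    Units: nm, ns, K, kJ/mol.  ``seed`` is mandatory — there is no
    implicit randomness anywhere in the generator.
    """

    potential: BilayerPotential
    n_steps: int
    z0: float
    seed: int
    temperature: float = DEFAULT_TEMPERATURE
    diffusion_coeff: float = 1.0
    dt: float = 1e-3
    bias: HarmonicBias | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_steps <= 0:
            raise ValueError(f"n_steps must be positive, got {self.n_steps}")
        if self.diffusion_coeff <= 0:
            raise ValueError(f"diffusion_coeff must be positive, got {self.diffusion_coeff}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        thermal_energy(self.temperature)


@njit(cache=True)
def _em_loop(z0, dt, mobility, sigma, grid, force, k_bias, zb, noise):  # pragma: no cover
    n = noise.shape[0]
    out = np.empty(n + 1)
    out[0] = z0
    z = z0
    zmin = grid[0]
    zmax = grid[-1]
    inv_dz = 1.0 / (grid[1] - grid[0])
    m = grid.shape[0]
    for i in range(n):
        x = (z - zmin) * inv_dz
        j = int(x)
        if j < 0:
            f = force[0]
        elif j >= m - 1:
            f = force[m - 1]
        else:
            w = x - j
            f = force[j] * (1.0 - w) + force[j + 1] * w
        if k_bias > 0.0:
            f -= k_bias * (z - zb)
        z = z + mobility * f * dt + sigma * noise[i]
        if z < zmin:
            z = 2.0 * zmin - z
        elif z > zmax:
            z = 2.0 * zmax - z
        out[i + 1] = z
    return out


def simulate_langevin(spec: LangevinSpec, molecule_id: str = "mol-0") -> ReactionCoordSeries:
    """Run one overdamped Langevin trajectory; pure function of (spec, seed).

    Returns a series of length ``n_steps + 1`` starting at ``z0``.
    Raises if the tabulated force contains non-finite values (naming the
    offending z).
    """
    pot = spec.potential
    span_candidates = [pot.z_water + 1.5, abs(spec.z0) + 1.0, 4.5]
    if spec.bias is not None:
        span_candidates.append(abs(spec.bias.z0_bias) + 1.0)
    z_max = max(span_candidates)
    grid, _, force = pot.tabulate(z_max=z_max)
    if not np.all(np.isfinite(force)):
        bad = grid[~np.isfinite(force)][0]
        raise ValueError(f"non-finite force at z={bad:.4f} nm (tabulated potential gap)")
    rt = thermal_energy(spec.temperature)
    mobility = spec.diffusion_coeff / rt
    sigma = np.sqrt(2.0 * spec.diffusion_coeff * spec.dt)
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.n_steps)
    if spec.bias is not None:
        k_bias, zb = spec.bias.k_bias, spec.bias.z0_bias
    else:
        k_bias, zb = 0.0, 0.0
    z = _em_loop(
        float(spec.z0), float(spec.dt), mobility, sigma,
        np.ascontiguousarray(grid), np.ascontiguousarray(force),
        float(k_bias), float(zb), noise,
    )
    times = np.arange(spec.n_steps + 1) * spec.dt
    return ReactionCoordSeries(times=times, z=z, molecule_id=molecule_id)
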