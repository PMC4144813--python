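"""Model free-energy surfaces for a steroid along the bilayer normal.

The bilayer potential is even in z (symmetric leaflets), has its global
minima at the two equilibrium head-group positions z = ±z_eq (value 0),
a barrier of height ``dG_center`` at the bilayer midplane z = 0, and a
desorption plateau of height ``dG_desorb`` in bulk water beyond the
head-group region.  Three functional forms are provided:

``cosine-blend`` (default)
    C1-continuous raised-cosine blend between minimum, center barrier and
    water plateau; closed-form parameterization by (z_eq, dG_center,
    dG_desorb, wall_halfwidth).
``piecewise-harmonic``
    Harmonic wells of curvature ``well_curvature`` at ±z_eq, clipped at
    ``dG_center`` toward the midplane and at ``dG_desorb`` toward water.
    Useful when the barrier-top shape must not scale with barrier height.
``tabulated``
    Linear interpolation of a user-supplied (z, U) table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_FORMS = ("cosine-blend", "piecewise-harmonic", "tabulated")


@dataclass(frozen=True)
class BilayerPotential:
    """Symmetric double-well-plus-walls potential U(z) in kJ/mol, z in nm.

    Parameters
    ----------
    z_eq:
        Equilibrium |z| of the steroid head group (nm, > 0).
    dG_center:
        Barrier at z = 0 relative to the minima (kJ/mol, >= 0).
    dG_desorb:
        Water-plateau height relative to the minima (kJ/mol, >= 0).
    wall_halfwidth:
        Half-width of the climb from the minimum to the water plateau;
        the plateau starts at z_water = z_eq + 2 * wall_halfwidth.
    well_curvature:
        Curvature (kJ mol^-1 nm^-2) of the harmonic wells; used only by
        the piecewise-harmonic form.
    form:
        One of ``cosine-blend``, ``piecewise-harmonic``, ``tabulated``.
    table:
        (z, U) arrays for the tabulated form; z strictly increasing.
    """

    z_eq: float
    dG_center: float
    dG_desorb: float
    wall_halfwidth: float = 0.5
    well_curvature: float = 60.0
    form: str = "cosine-blend"
    table: tuple | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"unknown potential form {self.form!r}; choose from {_FORMS}")
        if self.form == "tabulated":
            if self.table is None:
                raise ValueError("tabulated form requires a (z, U) table")
            zt, ut = (np.asarray(a, dtype=float) for a in self.table)
            if zt.ndim != 1 or zt.shape != ut.shape or zt.size < 2:
                raise ValueError("table must be two equal-length 1-D arrays")
            if not np.all(np.diff(zt) > 0):
                raise ValueError("table z values must be strictly increasing")
            if not np.all(np.isfinite(ut)):
                bad = zt[~np.isfinite(ut)][0]
                raise ValueError(f"non-finite tabulated energy at z={bad}")
            object.__setattr__(self, "table", (zt, ut))
            return
        if self.z_eq <= 0:
            raise ValueError(f"z_eq must be positive, got {self.z_eq}")
        if self.dG_center < 0 or self.dG_desorb < 0:
            raise ValueError("barrier heights must be non-negative")
        if self.wall_halfwidth <= 0:
            raise ValueError("wall_halfwidth must be positive")
        if self.form == "piecewise-harmonic" and self.well_curvature <= 0:
            raise ValueError("well_curvature must be positive")

    @property
    def z_water(self) -> float:
        """|z| beyond which the potential sits on the desorption plateau."""
        if self.form == "tabulated":
            return float(self.table[0][-1])
        return self.z_eq + 2.0 * self.wall_halfwidth

    def energy(self, z) -> np.ndarray:
        """U(z) in kJ/mol; accepts scalars or arrays."""
        z = np.asarray(z, dtype=float)
        if self.form == "tabulated":
            zt, ut = self.table
            return np.interp(z, zt, ut)
        a = np.abs(z)
        if self.form == "cosine-blend":
            # inner blend: dG_center at 0 -> 0 at z_eq, zero slope at both ends
            inner = 0.5 * self.dG_center * (1.0 + np.cos(np.pi * a / self.z_eq))
            # outer blend: 0 at z_eq -> dG_desorb at z_water, then flat
            s = np.clip((a - self.z_eq) / (self.z_water - self.z_eq), 0.0, 1.0)
            outer = 0.5 * self.dG_desorb * (1.0 - np.cos(np.pi * s))
            return np.where(a <= self.z_eq, inner, outer)
        # piecewise-harmonic: clipped parabolas
        c_in, c_out = self._effective_curvatures()
        u_in = 0.5 * c_in * (a - self.z_eq) ** 2
        u_out = 0.5 * c_out * (a - self.z_eq) ** 2
        return np.where(
            a <= self.z_eq,
            np.minimum(u_in, self.dG_center),
            np.minimum(u_out, self.dG_desorb),
        )

    def _effective_curvatures(self):
        """Well curvatures floored so the parabolas reach both caps.

        The inner branch must hit dG_center before the midplane and the
        outer branch dG_desorb before the plateau starts, otherwise the
        prescribed cap values could not be realized.
        """
        c_in = max(self.well_curvature, 2.0 * self.dG_center / self.z_eq**2)
        wall = self.z_water - self.z_eq
        c_out = max(self.well_curvature, 2.0 * self.dG_desorb / wall**2)
        return c_in, c_out

    def force(self, z) -> np.ndarray:
        """-dU/dz in kJ mol^-1 nm^-1."""
        z = np.asarray(z, dtype=float)
        if self.form == "tabulated":
            zt, ut = self.table
            # central-difference derivative of the interpolant on the table grid
            du = np.gradient(ut, zt)
            return -np.interp(z, zt, du)
        a = np.abs(z)
        sgn = np.sign(z)
        if self.form == "cosine-blend":
            f_in = 0.5 * self.dG_center * np.pi / self.z_eq * np.sin(np.pi * a / self.z_eq)
            w = self.z_water - self.z_eq
            s = (a - self.z_eq) / w
            f_out = np.where(
                (s > 0.0) & (s < 1.0),
                -0.5 * self.dG_desorb * np.pi / w * np.sin(np.pi * np.clip(s, 0.0, 1.0)),
                0.0,
            )
            dUda = np.where(a <= self.z_eq, -f_in, -f_out)
        else:
            c_in, c_out = self._effective_curvatures()
            c = np.where(a <= self.z_eq, c_in, c_out)
            dUda = c * (a - self.z_eq)
            u = 0.5 * c * (a - self.z_eq) ** 2
            cap = np.where(a <= self.z_eq, self.dG_center, self.dG_desorb)
            dUda = np.where(u >= cap, 0.0, dUda)
        return -sgn * dUda

    def tabulate(self, z_max: float | None = None, n: int = 4096):
        """Dense (z, U, F) grid for fast interpolation in the integrator."""
        if z_max is None:
            z_max = self.z_water + 1.5
        grid = np.linspace(-z_max, z_max, n)
        return grid, self.energy(grid), self.force(grid)


def flat_potential() -> BilayerPotential:
    """Zero potential everywhere (free diffusion / pure-bias reference)."""
    return BilayerPotential(z_eq=1.0, dG_center=0.0, dG_desorb=0.0)
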