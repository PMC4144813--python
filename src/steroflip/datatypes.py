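"""Core in-memory containers shared across the analysis stages.

All containers validate their invariants on construction and fail loudly,
naming the offending value, rather than silently coercing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as1d(x, name):
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class ReactionCoordSeries:
    """Time series of the reaction coordinate Z (nm) along the bilayer normal.

    The bilayer center sits at Z = 0, the leaflets at ±Z.  Times are in ns,
    strictly increasing, with uniform spacing.
    """

    times: np.ndarray
    z: np.ndarray
    molecule_id: str = "mol-0"

    def __post_init__(self):
        t = _as1d(self.times, "times")
        z = _as1d(self.z, "z")
        if t.size != z.size:
            raise ValueError(f"times ({t.size}) and z ({z.size}) length mismatch")
        if t.size < 2:
            raise ValueError("series needs at least two samples")
        if not np.all(np.isfinite(z)):
            row = int(np.flatnonzero(~np.isfinite(z))[0])
            raise ValueError(f"non-finite z at row {row}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise ValueError(f"times not strictly increasing at row {row}")
        # uniformity to 1e-9 relative, with a floor for the float rounding
        # of n*dt at large n (differences of adjacent times carry ~ulp(t))
        tol = max(1e-9 * abs(dt[0]), 8.0 * np.finfo(float).eps * float(np.max(np.abs(t))))
        if np.max(np.abs(dt - dt[0])) > tol:
            row = int(np.argmax(np.abs(dt - dt[0]))) + 1
            raise ValueError(f"non-uniform time step at row {row}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "z", z)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self):
        return self.times.size


@dataclass(frozen=True)
class LateralTracks:
    """A bundle of 2-D lateral trajectories sharing one time base.

    xy has shape (n_tracks, n_frames, 2) in nm; ``leaflet`` assigns each
    track to a monolayer (0/1) for per-leaflet center-of-mass removal.
    """

    times: np.ndarray
    xy: np.ndarray
    leaflet: np.ndarray | None = None

    def __post_init__(self):
        t = _as1d(self.times, "times")
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 3 or xy.shape[2] != 2:
            raise ValueError(f"xy must have shape (n_tracks, n_frames, 2), got {xy.shape}")
        if xy.shape[1] != t.size:
            raise ValueError("xy frame count does not match times")
        if t.size < 2:
            raise ValueError("tracks need at least two frames")
        if not np.all(np.isfinite(xy)):
            raise ValueError("non-finite coordinates in tracks")
        if self.leaflet is None:
            leaf = np.zeros(xy.shape[0], dtype=int)
        else:
            leaf = np.asarray(self.leaflet, dtype=int)
            if leaf.shape != (xy.shape[0],):
                raise ValueError("leaflet must have one entry per track")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "leaflet", leaf)

    @property
    def n_tracks(self) -> int:
        return self.xy.shape[0]

    @property
    def n_frames(self) -> int:
        return self.xy.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class OrientationSample:
    """C–H bond direction vectors for order-parameter analysis.

    Carbon numbering starts at 2 (the carbon adjacent to the glycerol
    group); each record carries the lipid and frame it came from.
    """

    carbon_index: np.ndarray
    vectors: np.ndarray
    lipid_id: np.ndarray
    frame_id: np.ndarray

    def __post_init__(self):
        ci = np.asarray(self.carbon_index, dtype=int)
        v = np.asarray(self.vectors, dtype=float)
        li = np.asarray(self.lipid_id, dtype=int)
        fi = np.asarray(self.frame_id, dtype=int)
        n = ci.size
        if v.shape != (n, 3) or li.size != n or fi.size != n:
            raise ValueError("orientation sample fields have inconsistent lengths")
        norms = np.linalg.norm(v, axis=1)
        bad = np.abs(norms - 1.0) > 1e-9
        if np.any(bad):
            raise ValueError(
                f"vector at record {int(np.flatnonzero(bad)[0])} is not unit-norm"
            )
        if n and ci.min() < 2:
            raise ValueError("carbon indices start at 2")
        object.__setattr__(self, "carbon_index", ci)
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "lipid_id", li)
        object.__setattr__(self, "frame_id", fi)

    def __len__(self):
        return self.carbon_index.size


_ROLES = frozenset(
    {"donor", "hydrogen", "acceptor", "charged-positive", "charged-negative", "other"}
)


@dataclass(frozen=True)
class MolecularScene:
    """Minimal 3-D coordinate scene for geometric H-bond / charge-pair counting.

    atoms: list of (id, element, role, xyz) where role is one of
    donor | hydrogen | acceptor | charged-positive | charged-negative | other.
    bonds: (donor_id, hydrogen_id) covalent pairs; every hydrogen must be
    bonded to exactly one donor.  An optional ``groups`` mapping assigns
    atom ids to molecule classes for per-class averaging.
    """

    ids: np.ndarray
    elements: tuple
    roles: tuple
    xyz: np.ndarray
    bonds: tuple
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = np.asarray(self.ids, dtype=int)
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (ids.size, 3):
            raise ValueError("xyz must be (n_atoms, 3)")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates in scene")
        if len(set(ids.tolist())) != ids.size:
            raise ValueError("duplicate atom ids")
        roles = tuple(self.roles)
        bad = [r for r in roles if r not in _ROLES]
        if bad:
            raise ValueError(f"unknown atom role {bad[0]!r}")
        bonds = tuple((int(d), int(h)) for d, h in self.bonds)
        role_of = dict(zip(ids.tolist(), roles))
        h_ids = [i for i, r in zip(ids.tolist(), roles) if r == "hydrogen"]
        bonded_h = [h for _, h in bonds]
        for h in h_ids:
            if bonded_h.count(h) != 1:
                raise ValueError(f"hydrogen {h} must be bonded to exactly one donor")
        for d, h in bonds:
            if role_of.get(d) != "donor" or role_of.get(h) != "hydrogen":
                raise ValueError(f"bond ({d}, {h}) must link a donor to a hydrogen")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "roles", roles)
        object.__setattr__(self, "xyz", xyz)
        object.__setattr__(self, "bonds", bonds)

    def position(self, atom_id: int) -> np.ndarray:
        idx = int(np.flatnonzero(self.ids == atom_id)[0])
        return self.xyz[idx]


@dataclass(frozen=True)
class GPImagePair:
    """Two-channel Laurdan intensity images.

    I_ordered is the 400–460 nm (gel/ordered) channel, I_disordered the
    470–530 nm (fluid/disordered) channel; g_factor is the instrument
    correction applied to the disordered channel in the GP formula.
    """

    I_ordered: np.ndarray
    I_disordered: np.ndarray
    g_factor: float = 1.0

    def __post_init__(self):
        a = np.asarray(self.I_ordered, dtype=float)
        b = np.asarray(self.I_disordered, dtype=float)
        if a.ndim != 2 or a.shape != b.shape:
            raise ValueError(f"channel shapes differ or not 2-D: {a.shape} vs {b.shape}")
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("negative intensities in GP image pair")
        if not self.g_factor > 0:
            raise ValueError(f"g_factor must be positive, got {self.g_factor}")
        object.__setattr__(self, "I_ordered", a)
        object.__setattr__(self, "I_disordered", b)


@dataclass(frozen=True)
class UmbrellaWindow:
    """Biased samples of Z from one umbrella-sampling window.

    ``samples`` are post-equilibration; ``n_discarded`` records how many
    leading samples were dropped as equilibration.  k_bias = 0 denotes an
    unbiased window (used when WHAM is cross-checked against direct
    Boltzmann inversion).
    """

    z0: float
    k_bias: float
    samples: np.ndarray
    n_discarded: int = 0
    label: str = ""

    def __post_init__(self):
        if self.k_bias < 0:
            raise ValueError(f"k_bias must be >= 0, got {self.k_bias}")
        s = _as1d(self.samples, "samples")
        if s.size == 0:
            raise ValueError(f"window z0={self.z0} has no samples after discard")
        if not np.all(np.isfinite(s)):
            raise ValueError(f"non-finite sample in window z0={self.z0}")
        object.__setattr__(self, "samples", s)

    def bias_energy(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return 0.5 * self.k_bias * (z - self.z0) ** 2


@dataclass(frozen=True)
class PMFProfile:
    """Gridded free-energy profile G(z) in kJ/mol with optional bootstrap errors.

    Bins never visited are NaN (masked); finite values are referenced so
    that min G = 0.
    """

    z_grid: np.ndarray
    G: np.ndarray
    err: np.ndarray | None = None
    temperature: float = 310.0

    def __post_init__(self):
        zg = _as1d(self.z_grid, "z_grid")
        g = _as1d(self.G, "G")
        if zg.size != g.size:
            raise ValueError("z_grid and G length mismatch")
        if zg.size >= 2:
            dz = np.diff(zg)
            if np.max(np.abs(dz - dz[0])) > 1e-9 * abs(dz[0]):
                raise ValueError("z_grid must be uniform")
        if self.err is not None:
            e = _as1d(self.err, "err")
            if e.size != g.size:
                raise ValueError("err and G length mismatch")
            if np.any(e[np.isfinite(e)] < 0):
                raise ValueError("negative bootstrap errors")
            object.__setattr__(self, "err", e)
        finite = np.isfinite(g)
        if finite.any():
            g = g - np.nanmin(g[finite])
        object.__setattr__(self, "z_grid", zg)
        object.__setattr__(self, "G", g)

    @property
    def bin_width(self) -> float:
        return float(self.z_grid[1] - self.z_grid[0])


@dataclass(frozen=True)
class ProfileFeatures:
    """The three free-energy differences read off a translocation PMF.

    z_eq: equilibrium head-group position; dG_center: midplane minus
    minimum; dG_barrier: highest point on the path from the minimum to the
    midplane, minus the minimum (may exceed dG_center when the barrier top
    sits off-center); dG_desorb: water plateau minus minimum.
    """

    z_eq: float
    dG_center: float
    dG_barrier: float
    dG_desorb: float


@dataclass(frozen=True)
class FlipFlopEvents:
    """Leaflet-transition events detected in one Z(t) trace."""

    event_times: np.ndarray
    directions: np.ndarray
    waiting_times: np.ndarray
    z_low: float
    z_high: float

    def __post_init__(self):
        t = _as1d(self.event_times, "event_times")
        d = np.asarray(self.directions, dtype=int)
        if d.size != t.size:
            raise ValueError("event_times and directions length mismatch")
        if t.size > 1:
            if np.any(np.diff(t) <= 0):
                raise ValueError("event times must be strictly increasing")
            if np.any(d[1:] == d[:-1]):
                raise ValueError("directions must alternate")
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "waiting_times", _as1d(self.waiting_times, "waiting_times"))

    @property
    def n_events(self) -> int:
        return self.event_times.size


@dataclass(frozen=True)
class KineticsResult:
    """Flip-flop/desorption rate constants derived from one PMF row.

    All rate ranges in s^-1, ordered (low, high); t_d_range in ns.
    ``mode`` records whether k_flip used the full series formula
    0.5/(1/k_f + 1/k_d) or the approximation k_f/2.
    """

    dG_center: float
    t_d_range: tuple
    k_d_range: tuple
    k_f_range: tuple
    k_flip_range: tuple
    temperature: float
    mode: str

    def __post_init__(self):
        for name in ("t_d_range", "k_d_range", "k_f_range", "k_flip_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered (low, high), got ({lo}, {hi})")
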