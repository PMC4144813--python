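"""Optional adapters for standard MD coordinate/trajectory formats.

These extract the Z coordinate of a named atom from PDB/GRO structures
and XTC/DCD trajectories via MDAnalysis.  They live in their own module
with a lazy import so the core package never depends on MDAnalysis.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ReactionCoordSeries


def zseries_from_trajectory(
    topology,
    trajectory=None,
    selection: str = "name O3",
    center_selection: str = "all",
    dt_ns: float | None = None,
    molecule_id: str = "md-mol",
) -> ReactionCoordSeries:
    """Z(t) of the first atom matching ``selection``, relative to the
    geometric center of ``center_selection`` (the bilayer), in nm.

    The geometric center (centroid) is used rather than the mass-weighted
    center so the adapter also works on topologies without mass
    information.  ``dt_ns`` overrides the trajectory's frame spacing
    (MDAnalysis reports ps; the override is useful for formats without
    times).
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "the MD-format adapters require MDAnalysis (install extra 'adapters')"
        ) from exc

    u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    atoms = u.select_atoms(selection)
    if len(atoms) == 0:
        raise ValueError(f"selection {selection!r} matched no atoms")
    ref = u.select_atoms(center_selection)
    zs, ts = [], []
    for ts_frame in u.trajectory:
        z_atom = atoms.positions[0][2]
        z_ref = ref.centroid()[2]
        zs.append((z_atom - z_ref) / 10.0)  # Å -> nm
        ts.append(ts_frame.time / 1000.0)  # ps -> ns
    times = np.asarray(ts)
    if dt_ns is not None or np.allclose(np.diff(times), 0.0):
        dt = dt_ns if dt_ns is not None else 1e-3
        times = np.arange(len(zs)) * dt
    return ReactionCoordSeries(times=times, z=np.asarray(zs), molecule_id=molecule_id)
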