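"""Membrane observables: chain order, H-bonds, charge pairs, MSD, area per lipid.

Conventions implemented here, stated explicitly because packages differ:

* The acyl-chain order parameter is S_CD = 0.5 * <3 cos^2(theta) - 1>,
  theta the angle between the C–H bond vector and the membrane normal,
  averaged over time and lipids; profiles report |S_CD| (signed values
  are retained alongside).  Both chain hydrogens of a carbon are pooled
  before averaging.
* A hydrogen bond exists iff the donor–acceptor distance is <= 0.325 nm
  AND the angle between the donor->acceptor vector and the donor->hydrogen
  covalent-bond vector is <= 35 degrees.  Note this is the D->A vs D->H
  angle — not the H–D–A or D–H...A convention some tools use.  Both
  cutoffs are inclusive.
* A charge pair is a pair of oppositely charged atoms within 0.4 nm
  (inclusive).
* MSD(t) = <|r_i(tau+t) - r_i(tau)|^2> over molecules i and all
  overlapping time origins tau, optionally after removing each leaflet's
  per-frame center-of-mass displacement (monolayers can drift); the
  lateral diffusion coefficient is the fitted MSD slope divided by 4.
* Area per lipid = time-averaged box area / lipids per leaflet,
  reported in Å^2 (1 nm^2 = 100 Å^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import LateralTracks, MolecularScene, OrientationSample


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond and charge-pair cutoffs (inclusive)."""

    d_max: float = 0.325  # nm, donor-acceptor distance
    angle_max: float = 35.0  # degrees, angle(D->A, D->H)
    charge_pair_cutoff: float = 0.4  # nm

    def __post_init__(self):
        if min(self.d_max, self.angle_max, self.charge_pair_cutoff) <= 0:
            raise ValueError("all cutoffs must be positive")


@dataclass(frozen=True)
class OrderProfile:
    """Per-carbon order parameters with standard errors over lipids."""

    carbons: np.ndarray
    s_cd: np.ndarray  # signed
    s_abs: np.ndarray
    se: np.ndarray
    n_lipids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "carbon": self.carbons,
                "S_CD": self.s_cd,
                "abs_S_CD": self.s_abs,
                "se": self.se,
                "n_lipids": self.n_lipids,
            }
        )


@dataclass(frozen=True)
class MSDCurve:
    """Mean-squared displacement vs lag, with pair counts per lag."""

    lag: np.ndarray  # ns, starts at 0
    msd: np.ndarray  # nm^2
    n_pairs: np.ndarray

    def __post_init__(self):
        if self.msd[0] != 0.0:
            raise ValueError("MSD at zero lag must be 0")
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lags must be increasing")


def scd_profile(sample: OrientationSample, normal=(0.0, 0.0, 1.0)) -> OrderProfile:
    """Order parameter |S_CD| per carbon from C–H bond vectors.

    S = 0.5 * (3 <cos^2 theta> - 1), pooled over all records of a carbon;
    the standard error is over per-lipid means.
    """
    if len(sample) == 0:
        raise ValueError("empty orientation sample")
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    cos2 = (sample.vectors @ n) ** 2
    df = pd.DataFrame(
        {"carbon": sample.carbon_index, "lipid": sample.lipid_id, "cos2": cos2}
    )
    per_lipid = (
        df.groupby(["carbon", "lipid"])["cos2"].mean().reset_index()
    )
    per_lipid["s"] = 0.5 * (3.0 * per_lipid["cos2"] - 1.0)
    agg = per_lipid.groupby("carbon")["s"].agg(["mean", "std", "count"])
    carbons = agg.index.to_numpy()
    s = agg["mean"].to_numpy()
    n_lip = agg["count"].to_numpy()
    with np.errstate(invalid="ignore"):
        se = np.where(n_lip > 1, agg["std"].to_numpy() / np.sqrt(n_lip), 0.0)
    se = np.nan_to_num(se)
    return OrderProfile(carbons=carbons, s_cd=s, s_abs=np.abs(s), se=se, n_lipids=n_lip)


def count_hbonds(scene: MolecularScene, criteria: HBondCriteria = HBondCriteria()):
    """Geometric hydrogen-bond census of a scene.

    Returns (n_bonds, detail DataFrame with one row per bond: donor,
    hydrogen, acceptor ids, distance and angle, plus donor/acceptor group
    labels when the scene defines groups).
    """
    ids = scene.ids
    pos = {int(i): scene.xyz[k] for k, i in enumerate(ids)}
    acceptors = [int(i) for i, r in zip(ids, scene.roles) if r == "acceptor"]
    rows = []
    for d_id, h_id in scene.bonds:
        d = pos[d_id]
        h = pos[h_id]
        dh = h - d
        for a_id in acceptors:
            if a_id == d_id:
                continue
            da = pos[a_id] - d
            dist = float(np.linalg.norm(da))
            if dist > criteria.d_max + 1e-12:
                continue
            cosang = float(np.dot(da, dh) / (dist * np.linalg.norm(dh)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle <= criteria.angle_max + 1e-9:
                rows.append(
                    {
                        "donor": d_id,
                        "hydrogen": h_id,
                        "acceptor": a_id,
                        "distance_nm": dist,
                        "angle_deg": angle,
                        "donor_group": scene.groups.get(d_id, ""),
                        "acceptor_group": scene.groups.get(a_id, ""),
                    }
                )
    detail = pd.DataFrame(
        rows,
        columns=[
            "donor", "hydrogen", "acceptor",
            "distance_nm", "angle_deg", "donor_group", "acceptor_group",
        ],
    )
    return len(rows), detail


def count_charge_pairs(scene: MolecularScene, cutoff: float = 0.4) -> int:
    """Count oppositely charged atom pairs within the (inclusive) cutoff."""
    plus = scene.xyz[[r == "charged-positive" for r in scene.roles]]
    minus = scene.xyz[[r == "charged-negative" for r in scene.roles]]
    if plus.size == 0 or minus.size == 0:
        return 0
    d = np.linalg.norm(plus[:, None, :] - minus[None, :, :], axis=2)
    return int(np.count_nonzero(d <= cutoff + 1e-12))


def msd(
    tracks: LateralTracks,
    remove_leaflet_com: bool = False,
    max_lag: int | None = None,
) -> MSDCurve:
    """All-time-origin MSD of a track bundle.

    MSD(m*dt) = mean over tracks i and origins tau of
    |r_i(tau + m*dt) - r_i(tau)|^2.  With ``remove_leaflet_com`` each
    leaflet's per-frame mean position is subtracted first, cancelling
    common drift (at the cost of a (1 - 1/n_tracks) bias, negligible for
    the track counts used here).
    """
    if tracks.n_frames < 2:
        raise ValueError("tracks must have at least two frames")
    xy = tracks.xy
    if remove_leaflet_com:
        xy = xy.copy()
        for leaf in np.unique(tracks.leaflet):
            sel = tracks.leaflet == leaf
            com = xy[sel].mean(axis=0, keepdims=True)
            xy[sel] = xy[sel] - com
    n_frames = tracks.n_frames
    if max_lag is None:
        max_lag = n_frames - 1
    max_lag = min(max_lag, n_frames - 1)
    lags = np.arange(max_lag + 1)
    out = np.zeros(max_lag + 1)
    n_pairs = np.zeros(max_lag + 1, dtype=int)
    n_pairs[0] = tracks.n_tracks * n_frames
    for m in lags[1:]:
        d = xy[:, m:, :] - xy[:, :-m, :]
        out[m] = float(np.mean(np.sum(d * d, axis=2)))
        n_pairs[m] = d.shape[0] * d.shape[1]
    return MSDCurve(lag=lags * tracks.dt, msd=out, n_pairs=n_pairs)


def fit_diffusion(curve: MSDCurve, fit_window: tuple) -> float:
    """Lateral diffusion coefficient D_L = slope(MSD vs lag) / 4 over a lag window.

    A least-squares line is fitted, so a constant MSD offset (localization
    noise, short-time caging) does not bias D.
    """
    lo, hi = fit_window
    sel = (curve.lag >= lo) & (curve.lag <= hi)
    if np.count_nonzero(sel) < 2:
        raise ValueError("fit window must contain at least two lag points")
    slope = np.polyfit(curve.lag[sel], curve.msd[sel], 1)[0]
    return float(slope) / 4.0


def area_per_lipid(box_areas, n_per_leaflet: int):
    """Time-averaged area per lipid in Å^2 (inputs in nm^2).

    Returns (mean, standard deviation), both in Å^2.
    """
    a = np.asarray(box_areas, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty box-area series")
    if n_per_leaflet <= 0:
        raise ValueError(f"n_per_leaflet must be positive, got {n_per_leaflet}")
    per_lipid_nm2 = a / n_per_leaflet
    return float(per_lipid_nm2.mean() * 100.0), float(per_lipid_nm2.std(ddof=0) * 100.0)
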