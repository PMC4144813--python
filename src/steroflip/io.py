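"""Readers and writers for the package's plain-text and image formats.

All tabular files are TSV with a ``#steroflip/1 <kind>`` header line, a
``#units:`` line, and optional ``#key: value`` metadata.  Canonical units
are nm and ns; headers may declare Å (``angstrom``/``A``) or ``ps`` and
values are converted on read.  Readers validate and reject rather than
silently coerce, naming the first offending row.

Profiles are written with 17 significant digits so that write -> read is
a float64-lossless round trip.  GP image pairs are 2-page float32 TIFFs
(page 1 = 400–460 nm channel, page 2 = 470–530 nm) with the G factor in
the image description.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .datatypes import (
    GPImagePair,
    LateralTracks,
    MolecularScene,
    OrientationSample,
    PMFProfile,
    ReactionCoordSeries,
    UmbrellaWindow,
)

MAGIC = "#steroflip/1"

_LENGTH_FACTORS = {"nm": 1.0, "angstrom": 0.1, "a": 0.1, "å": 0.1}
_TIME_FACTORS = {"ns": 1.0, "ps": 1e-3}


def _parse_header(lines):
    meta = {}
    kind = None
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        body = line[1:].strip()
        if line.startswith(MAGIC):
            parts = line.split()
            kind = parts[1] if len(parts) > 1 else None
        elif ":" in body:
            key, val = body.split(":", 1)
            meta[key.strip()] = val.strip()
    return kind, meta, n_header


def _unit_factors(meta):
    units = {}
    for token in meta.get("units", "").replace(",", " ").split():
        if "=" in token:
            k, v = token.split("=", 1)
            units[k.strip()] = v.strip().lower()
    tf = _TIME_FACTORS.get(units.get("time", "ns"))
    lf = _LENGTH_FACTORS.get(units.get("length", units.get("z", "nm")))
    if tf is None or lf is None:
        raise ValueError(f"unsupported units declaration: {units}")
    return tf, lf


def _load_table(path):
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(MAGIC):
        raise ValueError(f"{path}: missing '{MAGIC}' header")
    kind, meta, n_header = _parse_header(lines)
    body = [ln for ln in lines[n_header:] if ln.strip()]
    if body and not body[0][0].isdigit() and not body[0][0] in "-+.":
        body = body[1:]  # column-name line
    try:
        data = np.array([[float(x) for x in ln.split()] for ln in body])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric value in data rows: {exc}") from exc
    return kind, meta, data


def write_series(series: ReactionCoordSeries, path, extra_meta: dict | None = None):
    lines = [f"{MAGIC} series", "#units: time=ns length=nm",
             f"#molecule_id: {series.molecule_id}"]
    for k, v in (extra_meta or {}).items():
        lines.append(f"#{k}: {v}")
    lines.append("time_ns\tz_nm")
    for t, z in zip(series.times, series.z):
        lines.append(f"{t:.17g}\t{z:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_tracks(tracks: LateralTracks, path):
    lines = [f"{MAGIC} tracks", "#units: time=ns length=nm",
             f"#n_tracks: {tracks.n_tracks}",
             f"#leaflet: {' '.join(map(str, tracks.leaflet.tolist()))}"]
    cols = ["time_ns"]
    for i in range(tracks.n_tracks):
        cols += [f"x{i}", f"y{i}"]
    lines.append("\t".join(cols))
    flat = tracks.xy.transpose(1, 0, 2).reshape(tracks.n_frames, -1)
    for t, row in zip(tracks.times, flat):
        lines.append("\t".join([f"{t:.17g}"] + [f"{v:.17g}" for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_orientations(sample: OrientationSample, path):
    lines = [f"{MAGIC} orientations", "#units: length=nm",
             "carbon\tlipid\tframe\tvx\tvy\tvz"]
    for c, l, f, v in zip(
        sample.carbon_index, sample.lipid_id, sample.frame_id, sample.vectors
    ):
        lines.append(f"{c}\t{l}\t{f}\t{v[0]:.17g}\t{v[1]:.17g}\t{v[2]:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_series(path):
    """Read a steroflip TSV; returns the object the header's kind declares.

    Kinds: ``series`` -> ReactionCoordSeries, ``tracks`` -> LateralTracks,
    ``orientations`` -> OrientationSample.  Unit conversion from Å/ps is
    applied; non-monotone times and NaN values are rejected with the
    offending row named.
    """
    kind, meta, data = _load_table(path)
    if kind == "series":
        tf, lf = _unit_factors(meta)
        if data.ndim != 2 or data.shape[1] != 2:
            raise ValueError(f"{path}: series needs two columns (time, z)")
        t = data[:, 0] * tf
        z = data[:, 1] * lf
        if np.any(~np.isfinite(z)):
            row = int(np.flatnonzero(~np.isfinite(z))[0]) + 1
            raise ValueError(f"{path}: NaN/inf z at data row {row}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.flatnonzero(dt <= 0)[0]) + 2
            raise ValueError(f"{path}: time not strictly increasing at data row {row}")
        return ReactionCoordSeries(times=t, z=z, molecule_id=meta.get("molecule_id", "mol-0"))
    if kind == "tracks":
        tf, lf = _unit_factors(meta)
        t = data[:, 0] * tf
        n_tracks = (data.shape[1] - 1) // 2
        xy = data[:, 1:1 + 2 * n_tracks].reshape(t.size, n_tracks, 2).transpose(1, 0, 2) * lf
        leaflet = None
        if "leaflet" in meta:
            leaflet = np.array([int(x) for x in meta["leaflet"].split()])
        return LateralTracks(times=t, xy=xy, leaflet=leaflet)
    if kind == "orientations":
        ci = data[:, 0].astype(int)
        v = data[:, 3:6]
        return OrientationSample(
            carbon_index=ci,
            vectors=v,
            lipid_id=data[:, 1].astype(int),
            frame_id=data[:, 2].astype(int),
        )
    raise ValueError(f"{path}: unknown or missing dialect kind {kind!r}")


def write_umbrella_set(windows, directory, manifest_name="windows.yaml"):
    """Write one sample file per window plus a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, w in enumerate(windows):
        fname = f"window_{i:02d}.tsv"
        times = np.arange(w.samples.size, dtype=float)
        lines = [f"{MAGIC} series", "#units: time=ns length=nm",
                 f"#molecule_id: {w.label or fname}", "time_ns\tz_nm"]
        lines += [f"{t:.17g}\t{z:.17g}" for t, z in zip(times, w.samples)]
        (directory / fname).write_text("\n".join(lines) + "\n")
        entries.append({"z0": float(w.z0), "k_bias": float(w.k_bias), "file": fname})
    manifest = {"windows": entries, "equilibration_discard": 0}
    (directory / manifest_name).write_text(yaml.safe_dump(manifest, sort_keys=False))
    return directory / manifest_name


def read_umbrella_set(manifest_path) -> list[UmbrellaWindow]:
    """Read an umbrella-window set from a YAML manifest (or a directory holding one).

    The manifest lists per-window bias center z0, force constant and
    sample file; windows are returned sorted ascending by z0 with the
    per-window equilibration discard applied.  Duplicate z0 values and
    missing sample files are errors; an empty manifest is an error.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "windows.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"umbrella manifest not found: {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    entries = manifest.get("windows") or []
    if not entries:
        raise ValueError(f"{manifest_path}: empty umbrella manifest")
    discard = int(manifest.get("equilibration_discard", 0))
    z0s = [float(e["z0"]) for e in entries]
    if len(set(z0s)) != len(z0s):
        dup = next(z for z in z0s if z0s.count(z) > 1)
        raise ValueError(f"{manifest_path}: duplicate window center z0={dup}")
    windows = []
    for e in entries:
        fpath = manifest_path.parent / e["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"window sample file missing: {fpath}")
        series = read_series(fpath)
        samples = series.z[discard:]
        windows.append(
            UmbrellaWindow(
                z0=float(e["z0"]),
                k_bias=float(e["k_bias"]),
                samples=samples,
                n_discarded=discard,
                label=e.get("label", Path(e["file"]).stem),
            )
        )
    windows.sort(key=lambda w: w.z0)
    return windows


def write_profile(profile: PMFProfile, path):
    """Write a PMF profile TSV (columns z_nm, G_kJmol, err_kJmol)."""
    lines = [f"{MAGIC} profile", "#units: length=nm energy=kJ/mol",
             f"#temperature_K: {profile.temperature:.17g}",
             f"#has_err: {int(profile.err is not None)}",
             "z_nm\tG_kJmol\terr_kJmol"]
    err = profile.err if profile.err is not None else np.full(profile.G.size, np.nan)
    for z, g, e in zip(profile.z_grid, profile.G, err):
        e_str = "" if profile.err is None else f"{e:.17g}"
        lines.append(f"{z:.17g}\t{g:.17g}\t{e_str}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path) -> PMFProfile:
    """Read a PMF profile; float64-lossless round trip of write_profile."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(MAGIC):
        raise ValueError(f"{path}: missing '{MAGIC}' header")
    kind, meta, n_header = _parse_header(lines)
    if kind != "profile":
        raise ValueError(f"{path}: not a profile file (kind={kind!r})")
    body = [ln for ln in lines[n_header:] if ln.strip()]
    if body and body[0].startswith("z_nm"):
        body = body[1:]
    has_err = meta.get("has_err", "0") == "1"
    z, g, e = [], [], []
    for ln in body:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed profile row: {ln!r}")
        z.append(float(parts[0]))
        g.append(float(parts[1]))
        if has_err:
            if len(parts) < 3 or parts[2] == "":
                raise ValueError(f"{path}: has_err declared but error missing in row {ln!r}")
            e.append(float(parts[2]))
    z = np.array(z)
    g = np.array(g)
    if z.size != g.size:
        raise ValueError(f"{path}: grid/values length mismatch")
    return PMFProfile(
        z_grid=z,
        G=g,
        err=np.array(e) if has_err else None,
        temperature=float(meta.get("temperature_K", 310.0)),
    )


def write_scene(scene: MolecularScene, path):
    """JSON scene: atoms as [id, element, role, x, y, z], bonds as [donor, hydrogen]."""
    payload = {
        "steroflip": 1,
        "atoms": [
            [int(i), e, r, *map(float, p)]
            for i, e, r, p in zip(scene.ids, scene.elements, scene.roles, scene.xyz)
        ],
        "bonds": [list(b) for b in scene.bonds],
        "groups": {str(k): v for k, v in scene.groups.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_scene(path) -> MolecularScene:
    payload = json.loads(Path(path).read_text())
    atoms = payload["atoms"]
    return MolecularScene(
        ids=np.array([a[0] for a in atoms], dtype=int),
        elements=tuple(a[1] for a in atoms),
        roles=tuple(a[2] for a in atoms),
        xyz=np.array([a[3:6] for a in atoms], dtype=float),
        bonds=tuple((int(d), int(h)) for d, h in payload.get("bonds", [])),
        groups={int(k): v for k, v in payload.get("groups", {}).items()},
    )


def write_gp_tiff(pair: GPImagePair, path):
    """2-page float32 TIFF: page 1 ordered channel, page 2 disordered."""
    desc = json.dumps({"steroflip": 1, "g_factor": pair.g_factor})
    tifffile.imwrite(
        path,
        np.stack([pair.I_ordered, pair.I_disordered]).astype(np.float32),
        description=desc,
    )


def read_gp_tiff(path, g_factor: float | None = None) -> GPImagePair:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description or ""
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-page image stack, got shape {stack.shape}")
    g = g_factor
    if g is None:
        try:
            g = float(json.loads(desc).get("g_factor", 1.0))
        except (ValueError, AttributeError):
            g = 1.0
    return GPImagePair(
        I_ordered=stack[0].astype(float),
        I_disordered=stack[1].astype(float),
        g_factor=g,
    )
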