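"""Columnar text readers and writers for every data product.

Formats (all whitespace-delimited plain text with ``#`` comments):

* QENS spectra: repeated Q blocks, each opened by ``# Q = <value>`` and a
  ``# T = <K>`` header at the top, followed by rows ``E  I  sigma``.
* Elastic scans: long format ``T  Q  I  sigma``.
* SANS profiles: ``Q  I  sigma`` (the de-facto reduced-SANS exchange layout).
* XRD patterns: ``2theta  counts [sigma]``.
* Trajectories: rows ``frame  molecule  x  y  z`` with a ``# dt = <ps>``
  header.
* Ground-truth sidecars: YAML next to the data file (suffix ``.truth.yaml``)
  so test harnesses can recover generating parameters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mdwater import TrajectorySet
from .qens import ElasticScan, QENSSpectrum
from .sans import SANSProfile
from .xrd import XRDPattern

__all__ = [
    "write_qens", "read_qens",
    "write_elastic_scan", "read_elastic_scan",
    "write_sans", "read_sans",
    "write_xrd", "read_xrd",
    "write_trajectories", "read_trajectories",
    "write_ground_truth", "read_ground_truth",
    "read_resolution_curve",
]


def _clean(obj):
    """Make ground-truth dicts YAML-safe (numpy -> plain python)."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_ground_truth(path: str | Path, truth: dict) -> Path:
    """Write the sidecar ``<path>.truth.yaml`` and return its path."""
    side = Path(str(path) + ".truth.yaml")
    side.write_text(yaml.safe_dump(_clean(truth), sort_keys=False))
    return side


def read_ground_truth(path: str | Path) -> dict | None:
    side = Path(str(path) + ".truth.yaml")
    if not side.exists():
        return None
    return yaml.safe_load(side.read_text())


# -- QENS -------------------------------------------------------------------


def write_qens(path: str | Path, spectrum: QENSSpectrum) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# T = {spectrum.temperature}\n")
        for i, q in enumerate(spectrum.q):
            fh.write(f"# Q = {q}\n")
            for e, y, s in zip(spectrum.e, spectrum.intensity[i], spectrum.sigma[i]):
                fh.write(f"{e:.6g} {y:.8g} {s:.8g}\n")
    if spectrum.ground_truth is not None:
        write_ground_truth(path, spectrum.ground_truth)


def read_qens(path: str | Path) -> QENSSpectrum:
    temperature, qs, blocks, cur = np.nan, [], [], None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("T"):
                temperature = float(body.split("=")[1])
            elif body.startswith("Q"):
                qs.append(float(body.split("=")[1]))
                cur = []
                blocks.append(cur)
            continue
        cur.append([float(v) for v in line.split()])
    arr = [np.asarray(b, float) for b in blocks]
    e = arr[0][:, 0]
    intensity = np.stack([a[:, 1] for a in arr])
    sigma = np.stack([a[:, 2] for a in arr])
    return QENSSpectrum(
        q=np.asarray(qs), e=e, intensity=intensity, sigma=sigma,
        temperature=temperature, ground_truth=read_ground_truth(path),
    )


# -- elastic scans ----------------------------------------------------------


def write_elastic_scan(path: str | Path, scan: ElasticScan) -> None:
    sigma = scan.sigma if scan.sigma is not None else np.zeros_like(scan.intensity)
    rows = []
    for i, q in enumerate(scan.q):
        for j, t in enumerate(scan.t):
            rows.append((t, q, scan.intensity[i, j], sigma[i, j]))
    df = pd.DataFrame(rows, columns=["T", "Q", "I", "sigma"])
    with Path(path).open("w") as fh:
        fh.write("# elastic scan: T  Q  I  sigma\n")
        df.to_csv(fh, sep=" ", index=False, header=False, float_format="%.8g")
    if scan.ground_truth is not None:
        write_ground_truth(path, scan.ground_truth)


def read_elastic_scan(path: str | Path) -> ElasticScan:
    df = pd.read_csv(path, sep=r"\s+", comment="#",
                     names=["T", "Q", "I", "sigma"])
    t = np.sort(df["T"].unique())
    q = np.sort(df["Q"].unique())
    pivot_i = df.pivot_table(index="Q", columns="T", values="I").loc[q, t]
    pivot_s = df.pivot_table(index="Q", columns="T", values="sigma").loc[q, t]
    return ElasticScan(
        t=t, q=q, intensity=pivot_i.to_numpy(), sigma=pivot_s.to_numpy(),
        ground_truth=read_ground_truth(path),
    )


# -- SANS / XRD / resolution ------------------------------------------------


def write_sans(path: str | Path, profile: SANSProfile) -> None:
    data = np.column_stack([profile.q, profile.i, profile.sigma])
    np.savetxt(path, data, header=f"label: {profile.label}\nQ I sigma")
    if profile.ground_truth is not None:
        write_ground_truth(path, profile.ground_truth)


def read_sans(path: str | Path, label: str = "synthetic") -> SANSProfile:
    data = np.loadtxt(path)
    return SANSProfile(q=data[:, 0], i=data[:, 1], sigma=data[:, 2], label=label,
                       ground_truth=read_ground_truth(path))


def write_xrd(path: str | Path, pattern: XRDPattern) -> None:
    cols = [pattern.two_theta, pattern.counts]
    if pattern.sigma is not None:
        cols.append(pattern.sigma)
    np.savetxt(path, np.column_stack(cols),
               header=f"wavelength_A: {pattern.wavelength}\n2theta counts [sigma]")
    if pattern.ground_truth is not None:
        write_ground_truth(path, pattern.ground_truth)


def read_xrd(path: str | Path, wavelength: float | None = None) -> XRDPattern:
    lam = wavelength
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") and "wavelength_A" in line and lam is None:
            lam = float(line.split(":")[1])
        if not line.startswith("#"):
            break
    data = np.loadtxt(path)
    sigma = data[:, 2] if data.shape[1] > 2 else None
    from .xrd import CU_KALPHA

    return XRDPattern(two_theta=data[:, 0], counts=data[:, 1], sigma=sigma,
                      wavelength=lam if lam is not None else CU_KALPHA,
                      ground_truth=read_ground_truth(path))


def read_resolution_curve(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column (E, R) tabulated resolution curve."""
    data = np.loadtxt(path)
    return data[:, 0], data[:, 1]


# -- trajectories -----------------------------------------------------------


def write_trajectories(path: str | Path, traj: TrajectorySet) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# dt = {traj.frame_interval}\n")
        if traj.temperature is not None:
            fh.write(f"# T = {traj.temperature}\n")
        fh.write("# frame molecule x y z\n")
        for m in range(traj.n_molecules):
            for f in range(traj.n_frames):
                x, y, z = traj.positions[m, f]
                fh.write(f"{f} {m} {x:.6f} {y:.6f} {z:.6f}\n")
    if traj.ground_truth is not None:
        write_ground_truth(path, traj.ground_truth)


def read_trajectories(path: str | Path) -> TrajectorySet:
    dt, temperature = None, None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("dt"):
                dt = float(body.split("=")[1])
            elif body.startswith("T "):
                temperature = float(body.split("=")[1])
        else:
            break
    if dt is None:
        raise ValueError("trajectory file lacks the '# dt = <ps>' header")
    df = pd.read_csv(path, sep=r"\s+", comment="#",
                     names=["frame", "molecule", "x", "y", "z"])
    mols = np.sort(df["molecule"].unique())
    frames = np.sort(df["frame"].unique())
    pos = np.empty((len(mols), len(frames), 3))
    df = df.sort_values(["molecule", "frame"])
    pos[:] = df[["x", "y", "z"]].to_numpy().reshape(len(mols), len(frames), 3)
    return TrajectorySet(positions=pos, frame_interval=dt, temperature=temperature,
                         ground_truth=read_ground_truth(path))
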