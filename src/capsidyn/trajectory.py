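"""Time-ordered coordinate frames in reduced time units, with run metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Trajectory", "write_trajectory", "read_trajectory"]


@dataclass
class Trajectory:
    """Frames of positions (nm) at reduced times, plus run metadata.

    ``positions`` has shape (n_frames, n_atoms, 3); ``velocities`` is
    optional with the same shape.  ``metadata`` records at least the
    seed and reduced temperature of the run that produced it.
    """

    positions: np.ndarray
    times: np.ndarray
    velocities: np.ndarray | None = None
    elements: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, atoms, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("times/positions frame count mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory.

    ``.xyz`` (mandatory plain-text dialect): one XYZ block per frame,
    comment line ``time=<reduced time>``, coordinates in nm with six
    decimals.  ``.npz``: compact binary (numpy archive) round-tripping
    at full precision.
    """
    if traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    path = Path(path)
    if path.suffix == ".npz":
        payload = {"positions": traj.positions, "times": traj.times}
        if traj.velocities is not None:
            payload["velocities"] = traj.velocities
        if traj.elements is not None:
            payload["elements"] = traj.elements.astype(str)
        np.savez_compressed(path, **payload)
        return
    elements = (traj.elements.astype(str) if traj.elements is not None
                else np.full(traj.n_atoms, "C"))
    with open(path, "w") as fh:
        for t, frame in zip(traj.times, traj.positions):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"time={t:.6f}\n")
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            return Trajectory(
                positions=data["positions"],
                times=data["times"],
                velocities=data["velocities"] if "velocities" in data else None,
                elements=data["elements"] if "elements" in data else None,
            )
    frames, times = [], []
    elements: list[str] | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1]
        t = float(comment.split("time=")[1].split()[0])
        block = lines[i + 2:i + 2 + n]
        parts = [ln.split() for ln in block]
        if elements is None:
            elements = [p[0] for p in parts]
        frames.append([[float(p[1]), float(p[2]), float(p[3])] for p in parts])
        times.append(t)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames")
    return Trajectory(positions=np.array(frames), times=np.array(times),
                      elements=np.array(elements))
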