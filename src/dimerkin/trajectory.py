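"""Core data model: bead trajectories, periodic geometry, TM annotation, units.

Internal units are Å for length and ns for time throughout the package;
conversions to cm²/s or μm²/s happen only at reporting boundaries
(1 Å²/ns = 1e-7 cm²/s).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BeadTrajectory",
    "ProtomerTopology",
    "TMAssignment",
    "SimulationMetadata",
    "load_trajectory",
    "write_columnar",
    "read_columnar",
    "minimum_image_displacement",
    "align_to_reference",
    "assign_tm_regions",
    "bw_label",
    "effective_time",
]

# 1 Å²/ns expressed in cm²/s
A2_PER_NS_TO_CM2_PER_S = 1e-7


@dataclass(frozen=True)
class TMAssignment:
    """Helix name → inclusive residue ranges, with Ballesteros–Weinstein anchors.

    ``ranges`` maps a helix name (``TM1``..``TM7``, ``H8``) to a list of
    ``(first, last)`` inclusive residue-index ranges.  ``anchors`` maps each
    TM helix to the residue numbered x.50 in the Ballesteros–Weinstein
    scheme (the most conserved residue of the helix).
    """

    ranges: Mapping[str, tuple[tuple[int, int], ...]]
    anchors: Mapping[str, int]

    def __post_init__(self) -> None:
        seen: list[tuple[int, int]] = []
        for helix, rngs in self.ranges.items():
            for lo, hi in rngs:
                if lo > hi:
                    raise ValueError(f"empty range for {helix}: ({lo}, {hi})")
                for plo, phi in seen:
                    if lo <= phi and plo <= hi:
                        raise ValueError(f"overlapping residue ranges at {helix}")
                seen.append((lo, hi))
        for helix, anchor in self.anchors.items():
            if helix not in self.ranges:
                raise ValueError(f"anchor for undeclared helix {helix}")
            if not any(lo <= anchor <= hi for lo, hi in self.ranges[helix]):
                raise ValueError(f"anchor {anchor} outside ranges of {helix}")

    def helix_of(self, residue: int) -> str:
        for helix, rngs in self.ranges.items():
            if any(lo <= residue <= hi for lo, hi in rngs):
                return helix
        return "loop"


@dataclass(frozen=True)
class ProtomerTopology:
    """Per-protomer layout: subtype tag, residues, backbone beads, TM map."""

    subtype: str
    residue_range: tuple[int, int]  # inclusive
    backbone_beads: Mapping[int, int]  # residue index -> bead index
    tm: TMAssignment

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        residues = set(range(lo, hi + 1))
        if set(self.backbone_beads) != residues:
            raise ValueError("every residue must map to exactly one backbone bead")
        if len(set(self.backbone_beads.values())) != len(self.backbone_beads):
            raise ValueError("backbone bead indices must be unique")

    @property
    def residues(self) -> range:
        lo, hi = self.residue_range
        return range(lo, hi + 1)

    @property
    def bead_indices(self) -> np.ndarray:
        return np.array([self.backbone_beads[r] for r in self.residues], dtype=int)


@dataclass(frozen=True)
class SimulationMetadata:
    """Provenance of one trajectory: id, membrane area, composition, time basis."""

    trajectory_id: str
    area_um2: float
    monomer_counts: Mapping[str, int]
    simulated_time_us: float
    time_scaling: float = 4.0  # CG effective-time factor

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("membrane area must be positive")
        if self.time_scaling < 1:
            raise ValueError("effective-time scaling factor must be >= 1")

    @property
    def effective_time_us(self) -> float:
        return effective_time(self.simulated_time_us, self.time_scaling)


class BeadTrajectory:
    """Time-ordered bead positions with per-frame orthorhombic box lengths.

    Parameters
    ----------
    positions : (n_frames, n_beads, 3) array, Å.  Stored unwrapped per
        molecule so that displacement computations never jump across
        periodic images; wrap on demand via :meth:`wrapped`.
    times : (n_frames,) array, ns, strictly increasing.
    box : (n_frames, 3) or (3,) array, Å.
    topologies : optional sequence of :class:`ProtomerTopology`.
    """

    def __init__(
        self,
        positions: np.ndarray,
        times: np.ndarray,
        box: np.ndarray,
        topologies: Sequence[ProtomerTopology] = (),
    ) -> None:
        positions = np.asarray(positions, dtype=float)
        times = np.asarray(times, dtype=float)
        box = np.asarray(box, dtype=float)
        if positions.ndim != 3 or positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_beads, 3)")
        if positions.shape[0] == 0:
            raise ValueError("no frames")
        if times.shape != (positions.shape[0],):
            raise ValueError("times must match the number of frames")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if box.ndim == 1:
            box = np.broadcast_to(box, (positions.shape[0], 3)).copy()
        if box.shape != (positions.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3) or (3,)")
        if np.any(box <= 0):
            raise ValueError("box lengths must be positive")
        self.positions = positions
        self.times = times
        self.box = box
        self.topologies = tuple(topologies)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def wrapped(self) -> np.ndarray:
        """Positions wrapped into the primary box (for density bookkeeping)."""
        return np.mod(self.positions, self.box[:, None, :])

    def protomer_positions(self, i: int, frame: int | None = None) -> np.ndarray:
        """Backbone-bead positions of protomer ``i`` (one frame or all)."""
        idx = self.topologies[i].bead_indices
        if frame is None:
            return self.positions[:, idx, :]
        return self.positions[frame, idx, :]


def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) ``b - a`` under an orthorhombic box.

    Each returned component has magnitude ≤ half the corresponding box length.
    Broadcasts over leading axes.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)


def align_to_reference(
    snapshot: np.ndarray,
    reference: np.ndarray,
    in_plane: bool = False,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``snapshot`` onto ``reference``.

    Returns ``(R, t, rmsd)`` such that ``snapshot @ R.T + t`` best matches
    ``reference``.  With ``in_plane=True`` the rotation is restricted to the
    membrane plane (about z) and the translation to x–y, as used when
    building receptor-frame maps; otherwise the full 3D Kabsch solution is
    used (crystal-RMSD protocol).
    """
    X = np.asarray(snapshot, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("snapshot and reference must be matching (n, 3) arrays")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 beads")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    if in_plane:
        # optimal rotation about z from the 2D cross-covariance
        C = X0[:, :2].T @ Y0[:, :2]
        theta = np.arctan2(C[0, 1] - C[1, 0], C[0, 0] + C[1, 1])
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        t = yc - R @ xc
        t[2] = 0.0
    else:
        C = X0.T @ Y0
        U, S, Vt = np.linalg.svd(C)
        if S[1] < 1e-12 * max(S[0], 1.0):
            raise ValueError("degenerate (collinear) geometry")
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        D = np.diag([1.0, 1.0, d])
        R = Vt.T @ D @ U.T
        t = yc - R @ xc
    moved = X @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Y) ** 2, axis=1))))
    return R, t, rmsd


def assign_tm_regions(topology: ProtomerTopology) -> dict[int, str]:
    """Label every residue of a protomer with its helix name or ``"loop"``."""
    return {r: topology.tm.helix_of(r) for r in topology.residues}


def bw_label(residue: int, tm: TMAssignment) -> str:
    """Ballesteros–Weinstein label ``helix.position`` for a residue.

    The anchor residue of each helix is numbered 50; other helix residues
    are numbered by their offset from the anchor.  Loop residues are
    labelled ``loop.<residue>``.
    """
    helix = tm.helix_of(residue)
    if helix == "loop" or helix not in tm.anchors:
        return f"loop.{residue}"
    num = helix.removeprefix("TM")
    return f"{num}.{50 + residue - tm.anchors[helix]}"


def bw_residue(label: str, tm: TMAssignment) -> int:
    """Inverse of :func:`bw_label` for helix residues."""
    head, pos = label.split(".")
    if head == "loop":
        return int(pos)
    helix = f"TM{head}"
    return tm.anchors[helix] + int(pos) - 50


def effective_time(simulated: float, factor: float = 4.0) -> float:
    """Effective duration after the CG time rescaling (unit-preserving)."""
    if simulated < 0:
        raise ValueError("duration must be non-negative")
    if factor < 1:
        raise ValueError("scaling factor must be >= 1")
    return simulated * factor


# ---------------------------------------------------------------------------
# I/O: columnar text fallback + standard MD formats via MDAnalysis
# ---------------------------------------------------------------------------

def write_columnar(traj: BeadTrajectory, path: str | Path) -> None:
    """Write a trajectory in the plain-text columnar format.

    Layout: one header line ``n_beads``; then per frame a line
    ``t <time> <bx> <by> <bz>`` followed by ``n_beads`` lines of
    ``bead_id x y z``.  A ``.gz`` suffix enables gzip compression.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(f"{traj.n_beads}\n")
        for f in range(traj.n_frames):
            bx, by, bz = traj.box[f]
            fh.write(f"t {traj.times[f]:.9g} {bx:.9g} {by:.9g} {bz:.9g}\n")
            for b in range(traj.n_beads):
                x, y, z = traj.positions[f, b]
                fh.write(f"{b} {x:.9g} {y:.9g} {z:.9g}\n")


def read_columnar(path: str | Path, topologies: Sequence[ProtomerTopology] = ()) -> BeadTrajectory:
    """Read a trajectory written by :func:`write_columnar`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().split()
        if not header:
            raise ValueError("no frames")
        n_beads = int(header[0])
        times, boxes, frames = [], [], []
        line = fh.readline()
        while line:
            parts = line.split()
            if parts[0] != "t":
                raise ValueError(f"expected time line, got: {line!r}")
            times.append(float(parts[1]))
            boxes.append([float(v) for v in parts[2:5]])
            pos = np.empty((n_beads, 3))
            for _ in range(n_beads):
                bid, x, y, z = fh.readline().split()
                pos[int(bid)] = (float(x), float(y), float(z))
            frames.append(pos)
            line = fh.readline()
    if not frames:
        raise ValueError("no frames")
    return BeadTrajectory(np.stack(frames), np.array(times), np.array(boxes), topologies)


def load_trajectory(
    paths: str | Path | Sequence[str | Path],
    topologies: Sequence[ProtomerTopology] = (),
    selection: str = "all",
) -> BeadTrajectory:
    """Load a trajectory from the columnar format or standard MD formats.

    A single ``.txt``/``.dat``/``.gz`` path is read with
    :func:`read_columnar`.  Otherwise ``paths`` is handed to MDAnalysis
    (e.g. ``("system.gro", "run.xtc")``); positions are converted from nm
    to Å and frame times from ps to ns.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
    if len(paths) == 1 and paths[0].suffix in {".txt", ".dat", ".gz"}:
        return read_columnar(paths[0], topologies)

    import MDAnalysis as mda  # deferred: heavy import

    u = mda.Universe(*map(str, paths))
    atoms = u.select_atoms(selection)
    pos, times, boxes = [], [], []
    for ts in u.trajectory:
        pos.append(atoms.positions.copy())  # MDAnalysis positions are Å
        times.append(ts.time / 1000.0)  # ps -> ns
        boxes.append(ts.dimensions[:3].copy())
    return BeadTrajectory(np.stack(pos), np.array(times), np.array(boxes), topologies)
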