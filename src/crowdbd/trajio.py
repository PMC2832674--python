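"""Trajectory container, text trajectory format, and PDB snapshot export.

The on-disk format is a self-describing plain-text container: a header
with the box edge and the per-molecule template names, then one ``FRAME
<time_ps>`` line per recorded frame followed by one line per molecule
holding 12 floats — the unwrapped centre (Å) and the row-major 3x3
rotation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "TruncatedTrajectoryError",
           "write_trajectory", "read_trajectory", "export_pdb_snapshot"]


class TruncatedTrajectoryError(ValueError):
    """Raised on a truncated trajectory file; carries the valid prefix."""

    def __init__(self, message, n_valid, trajectory):
        super().__init__(message)
        self.n_valid = n_valid
        self.trajectory = trajectory


@dataclass
class Trajectory:
    """Recorded poses: times (T,), unwrapped positions (T, M, 3),
    rotations (T, M, 3, 3), one type label per molecule."""

    times: np.ndarray
    positions: np.ndarray
    rotations: np.ndarray
    type_labels: list[str]
    box_edge: float
    templates: dict | None = None  # name -> RigidBodyTemplate, optional

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[1]

    @property
    def frame_spacing(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames for a frame spacing")
        return float(self.times[1] - self.times[0])

    def molecules_of_type(self, type_name: str) -> np.ndarray:
        idx = np.array([i for i, t in enumerate(self.type_labels)
                        if t == type_name], dtype=int)
        if len(idx) == 0:
            raise ValueError(f"no molecules of type {type_name!r}")
        return idx

    def template_for(self, label: str):
        if self.templates is None or label not in self.templates:
            raise ValueError(f"no template attached for type {label!r}")
        return self.templates[label]


def write_trajectory(traj: Trajectory, path):
    with open(path, "w") as fh:
        fh.write("# crowdbd trajectory v1\n")
        fh.write(f"# box_edge {traj.box_edge!r}\n")
        fh.write(f"# molecules {traj.n_molecules}\n")
        fh.write("# types " + " ".join(traj.type_labels) + "\n")
        for k in range(traj.n_frames):
            fh.write(f"FRAME {float(traj.times[k])!r}\n")
            for m in range(traj.n_molecules):
                row = np.concatenate([traj.positions[k, m],
                                      traj.rotations[k, m].ravel()])
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_trajectory(path, templates: dict | None = None) -> Trajectory:
    """Read the text trajectory format.

    A file cut off mid-frame raises :class:`TruncatedTrajectoryError`
    whose ``trajectory`` attribute holds the valid prefix and ``n_valid``
    the number of complete frames.
    """
    box_edge = None
    n_mol = None
    labels: list[str] = []
    times, frames_p, frames_r = [], [], []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        parts = lines[i].split()
        if parts[1:2] == ["box_edge"]:
            box_edge = float(parts[2])
        elif parts[1:2] == ["molecules"]:
            n_mol = int(parts[2])
        elif parts[1:2] == ["types"]:
            labels = parts[2:]
        i += 1
    if box_edge is None or n_mol is None or len(labels) != n_mol:
        raise ValueError(f"{path}: malformed trajectory header")

    def _partial(msg):
        traj = Trajectory(np.array(times),
                          np.array(frames_p).reshape(len(times), n_mol, 3),
                          np.array(frames_r).reshape(len(times), n_mol, 3, 3),
                          labels, box_edge, templates)
        raise TruncatedTrajectoryError(
            f"{path}: {msg} (last valid frame index {len(times) - 1})",
            len(times), traj)

    while i < len(lines):
        if not lines[i].startswith("FRAME"):
            _partial(f"expected FRAME at line {i + 1}")
        t = float(lines[i].split()[1])
        i += 1
        if i + n_mol > len(lines):
            _partial("file truncated mid-frame")
        pos = np.empty((n_mol, 3))
        rot = np.empty((n_mol, 3, 3))
        for m in range(n_mol):
            vals = lines[i + m].split()
            if len(vals) != 12:
                _partial(f"bad molecule record at line {i + m + 1}")
            row = np.array([float(v) for v in vals])
            pos[m] = row[:3]
            rot[m] = row[3:].reshape(3, 3)
        times.append(t)
        frames_p.append(pos)
        frames_r.append(rot)
        i += n_mol
    return Trajectory(np.array(times),
                      np.array(frames_p), np.array(frames_r),
                      labels, box_edge, templates)


def export_pdb_snapshot(state, path):
    """Write one configuration as a PDB file for visualization."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb
    coords = []
    names = []
    res_ids = []
    for m in range(state.n_molecules):
        tmpl = state.template_of(m)
        lab = state.centres[m] + tmpl.positions @ state.rotations[m].T
        coords.append(lab)
        names.extend(a.name[:4] for a in tmpl.atoms)
        res_ids.extend([m + 1] * tmpl.n_atoms)
    coords = np.concatenate(coords)
    arr = struc.AtomArray(len(coords))
    arr.coord = coords.astype(np.float32)
    arr.atom_name = np.array(names)
    arr.res_id = np.array(res_ids)
    arr.res_name = np.array(["MOL"] * len(coords))
    arr.chain_id = np.array(["A"] * len(coords))
    arr.element = np.array([n[:1] for n in names])
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))
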