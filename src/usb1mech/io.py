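"""Text formats: hills logs, FES grid tables, XYZ trajectories.

The hills dialect mirrors the de-facto standard header
``#! FIELDS time <cv...> sigma_<cv...> height biasf`` so logs from common
metadynamics engines can be ingested; a trailing ``# walker=<id>`` comment
records the depositing walker.  CV names containing spaces are written
with underscores.  All writers round-trip losslessly at %.17g precision;
rewriting a file just read reproduces it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fes import FESGrid
from .metad import Hill, HillsLog

__all__ = ["Trajectory", "read_hills", "write_hills", "read_fes", "write_fes",
           "read_xyz", "write_xyz", "file_sha256", "write_provenance"]

_F = "%.17g"


def _san(name: str) -> str:
    return name.replace(" ", "_")


def write_hills(log: HillsLog, path: str | Path) -> None:
    names = [_san(n) for n in log.cv_names]
    lines = ["#! FIELDS time " + " ".join(names) + " "
             + " ".join(f"sigma_{n}" for n in names) + " height biasf"]
    for hill, wid in zip(log.hills(), log.walker_ids):
        bf = 0.0 if hill.bias_factor is None else hill.bias_factor
        row = [_F % hill.time]
        row += [_F % c for c in hill.center]
        row += [_F % w for w in hill.widths]
        row += [_F % hill.height, _F % bf, f"# walker={wid}"]
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_hills(path: str | Path) -> HillsLog:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    fields = lines[0].split()[2:]
    if fields[0] != "time" or fields[-2:] != ["height", "biasf"]:
        raise ValueError(f"{path}: unexpected FIELDS layout {fields}")
    mid = fields[1:-2]
    d = len(mid) // 2
    if len(mid) != 2 * d or any(not s.startswith("sigma_") for s in mid[d:]):
        raise ValueError(f"{path}: cannot split CV / sigma columns in {mid}")
    log = HillsLog(mid[:d])
    for ln, line in enumerate(lines[1:], start=2):
        body, _, comment = line.partition("#")
        if not body.strip():
            continue
        toks = body.split()
        if len(toks) != 2 * d + 3:
            raise ValueError(f"{path}:{ln}: expected {2*d+3} columns, "
                             f"got {len(toks)}")
        try:
            vals = [float(t) for t in toks]
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: non-numeric value") from e
        wid = 0
        if "walker=" in comment:
            wid = int(comment.split("walker=")[1].split()[0])
        bf = vals[-1] if vals[-1] != 0.0 else None
        log.append(Hill(vals[0], np.array(vals[1:1 + d]),
                        np.array(vals[1 + d:1 + 2 * d]), vals[-2], bf), wid)
    return log


def write_fes(fes: FESGrid, path: str | Path) -> None:
    if fes.dimension > 3:
        raise ValueError("only 1-3 dimensional grids are supported")
    lines = [f"# axis {_san(name)} {_F % lo} {_F % hi} {n}"
             for name, lo, hi, n in fes.axes]
    grids = np.meshgrid(*[fes.axis_points(k) for k in range(fes.dimension)],
                        indexing="ij")
    flat = [g.ravel() for g in grids] + [fes.values.ravel()]
    for row in zip(*flat):
        lines.append(" ".join(_F % x for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fes(path: str | Path) -> FESGrid:
    axes = []
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("# axis "):
            toks = line.split()
            if len(toks) < 6:
                raise ValueError(f"{path}:{ln}: malformed axis header")
            name = " ".join(toks[2:-3])
            axes.append((name, float(toks[-3]), float(toks[-2]), int(toks[-1])))
        elif line.strip() and not line.startswith("#"):
            rows.append([float(t) for t in line.split()])
    if not axes:
        raise ValueError(f"{path}: no axis headers")
    if len(axes) > 3:
        raise ValueError("only 1-3 dimensional grids are supported")
    shape = tuple(n for _, _, _, n in axes)
    expected = int(np.prod(shape))
    if len(rows) != expected or any(len(r) != len(axes) + 1 for r in rows):
        raise ValueError(f"{path}: non-rectangular data "
                         f"({len(rows)} rows for shape {shape})")
    values = np.array([r[-1] for r in rows]).reshape(shape)
    return FESGrid(axes, values - values.min() if values.min() < 0 else values)


@dataclass
class Trajectory:
    """Labelled multi-frame XYZ coordinates."""

    labels: list[str]
    coords: np.ndarray            # (n_frames, n_atoms, 3)
    comments: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.coords)


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    n = len(traj.labels)
    lines = []
    for f in range(len(traj)):
        comment = traj.comments[f] if f < len(traj.comments) else f"frame {f}"
        lines.append(str(n))
        lines.append(comment)
        for lab, (x, y, z) in zip(traj.labels, traj.coords[f]):
            lines.append(f"{lab} {_F % x} {_F % y} {_F % z}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    i, frame_no = 0, 0
    labels: list[str] | None = None
    frames, comments = [], []
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i])
        except ValueError as e:
            raise ValueError(f"{path}: expected atom count at line {i+1}") from e
        if i + 2 + n > len(lines):
            raise ValueError(f"{path}: truncated frame {frame_no}")
        comments.append(lines[i + 1])
        labs, xyz = [], []
        for row in lines[i + 2:i + 2 + n]:
            toks = row.split()
            if len(toks) != 4:
                raise ValueError(f"{path}: bad atom row in frame {frame_no}")
            labs.append(toks[0])
            xyz.append([float(t) for t in toks[1:]])
        if labels is None:
            labels = labs
        elif len(labs) != len(labels):
            raise ValueError(f"{path}: atom count changed at frame {frame_no}")
        frames.append(xyz)
        i += 2 + n
        frame_no += 1
    if labels is None:
        raise ValueError(f"{path}: empty XYZ file")
    return Trajectory(labels, np.array(frames), comments)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(out_path: str | Path, config: dict,
                     inputs: list[str | Path] = ()) -> Path:
    """Write ``<out>.prov.json`` recording config, seeds and input hashes."""
    prov = {
        "output": str(out_path),
        "config": config,
        "inputs": {str(p): file_sha256(p) for p in inputs},
    }
    p = Path(str(out_path) + ".prov.json")
    p.write_text(json.dumps(prov, indent=1, sort_keys=True, default=str) + "\n")
    return p
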