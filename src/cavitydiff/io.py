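"""Readers and writers for the text formats the pipeline exchanges.

Formats
-------
* XYZ trajectory: one block per frame; the comment line carries metadata
  as key=value tokens, exactly ``time_ps=<t> box_nm=<lx>,<ly>,<lz>``.
* GRO series: concatenated fixed-width GRO frames (nm); box from the
  final line of each frame; time parsed from a ``t=`` token in the title
  when present.
* Trajectory CSV: columns ``t_ps,x_nm,y_nm,z_nm[,state]``.
* Response-function CSV (``t_seconds,normalized_size``) + JSON metadata
  sidecar; packings as ``x,y,z,radius`` CSV + JSON box sidecar;
  parameterizations and Markov models as JSON.

Every writer emits a ``#`` header naming the package version and the
resolved parameters; readers skip ``#`` lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .droplet_fickian import DiffusivityParameterization, ResponseFunction
from .synthetic_data import PackedConfiguration
from .trajectory import Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_response",
    "write_response",
    "read_packing",
    "write_packing",
    "read_diffusivity",
    "write_diffusivity",
]

_HEADER = f"# cavitydiff {__version__}"


def _check_uniform_dt(times: np.ndarray) -> None:
    if len(times) > 2:
        dts = np.diff(times)
        bad = np.nonzero(np.abs(dts - dts[0]) > 1e-6 * max(abs(dts[0]), 1e-30))[0]
        if len(bad):
            raise ValueError(f"non-uniform time step at frame {bad[0] + 1}")


def _unwrap(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Reconstruct continuous positions from wrapped ones (minimum image)."""
    jumps = np.diff(positions, axis=0)
    jumps -= box * np.round(jumps / box)
    return positions[0] + np.concatenate(
        [np.zeros((1, 3)), np.cumsum(jumps, axis=0)]
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, path, fmt: str = "xyz") -> None:
    path = Path(path)
    if fmt == "xyz":
        _write_xyz(traj, path)
    elif fmt == "csv":
        _write_traj_csv(traj, path)
    elif fmt == "gro":
        _write_gro(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectory(path, fmt: str | None = None) -> Trajectory:
    """Read a trajectory; format inferred from the suffix when omitted.

    Enforces uniform frame spacing and reconstructs both wrapped and
    unwrapped position arrays.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".xyz": "xyz", ".csv": "csv", ".gro": "gro"}.get(path.suffix)
        if fmt is None:
            raise ValueError(f"cannot infer trajectory format from {path.name}")
    if fmt == "xyz":
        times, pos, box = _read_xyz(path)
    elif fmt == "csv":
        times, pos, box = _read_traj_csv(path)
    elif fmt == "gro":
        times, pos, box = _read_gro(path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    _check_uniform_dt(times)
    if box is None:
        raise ValueError(f"{path.name}: no box found; periodic data needs one")
    wrapped = np.mod(pos, box)
    return Trajectory(
        times=times,
        positions=wrapped,
        unwrapped=_unwrap(wrapped, box),
        box=box,
        periodic=True,
    )


def _write_xyz(traj: Trajectory, path: Path) -> None:
    box = traj.box if traj.box is not None else np.zeros(3)
    with open(path, "w") as fh:
        for t, p in zip(traj.times, traj.positions):
            fh.write("1\n")
            fh.write(
                f"time_ps={t:.6f} box_nm={box[0]:.6f},{box[1]:.6f},{box[2]:.6f}"
                f" generator=cavitydiff-{__version__}\n"
            )
            fh.write(f"W {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def _read_xyz(path: Path):
    times, pos = [], []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i].strip())
        comment = lines[i + 1]
        tokens = dict(
            tok.split("=", 1) for tok in comment.split() if "=" in tok
        )
        if "time_ps" not in tokens or "box_nm" not in tokens:
            raise ValueError(
                f"{path.name}: XYZ comment must carry time_ps= and box_nm= tokens"
            )
        times.append(float(tokens["time_ps"]))
        box = np.array([float(v) for v in tokens["box_nm"].split(",")])
        frame = []
        for k in range(natoms):
            parts = lines[i + 2 + k].split()
            frame.append([float(parts[1]), float(parts[2]), float(parts[3])])
        pos.append(frame[0])  # single-tracer convention
        i += 2 + natoms
    return np.array(times), np.array(pos), box


def _write_gro(traj: Trajectory, path: Path) -> None:
    box = traj.box if traj.box is not None else np.zeros(3)
    with open(path, "w") as fh:
        for t, p in zip(traj.times, traj.positions):
            fh.write(f"cavitydiff tracer t= {t:.6f}\n")
            fh.write("    1\n")
            fh.write(
                f"{1:5d}{'SOL':<5s}{'OW':>5s}{1:5d}"
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}\n"
            )
            fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def _read_gro(path: Path):
    times, pos = [], []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        natoms = int(lines[i + 1].strip())
        t = None
        if "t=" in title:
            t = float(title.split("t=")[1].split()[0])
        times.append(t if t is not None else float(frame_idx))
        atoms = []
        for k in range(natoms):
            line = lines[i + 2 + k]
            atoms.append(
                [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            )
        box_line = lines[i + 2 + natoms].split()
        box = np.array([float(v) for v in box_line[:3]])
        pos.append(atoms[0])
        i += 3 + natoms
        frame_idx += 1
    return np.array(times), np.array(pos), box


def _write_traj_csv(traj: Trajectory, path: Path) -> None:
    box = traj.box if traj.box is not None else np.zeros(3)
    state = traj.meta.get("states")
    with open(path, "w") as fh:
        fh.write(f"{_HEADER} trajectory box_nm={box[0]},{box[1]},{box[2]}\n")
        fh.write("t_ps,x_nm,y_nm,z_nm" + (",state\n" if state is not None else "\n"))
        for k, (t, p) in enumerate(zip(traj.times, traj.positions)):
            row = f"{t:.6f},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}"
            if state is not None:
                row += f",{int(state[k])}"
            fh.write(row + "\n")


def _read_traj_csv(path: Path):
    box = None
    times, pos = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.split():
                    if tok.startswith("box_nm="):
                        box = np.array(
                            [float(v) for v in tok.split("=", 1)[1].split(",")]
                        )
                continue
            if line[0].isalpha() or line.startswith("t_ps"):
                continue
            parts = line.split(",")
            times.append(float(parts[0]))
            pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
    return np.array(times), np.array(pos), box


# ---------------------------------------------------------------------------
# response functions
# ---------------------------------------------------------------------------


def write_response(rf: ResponseFunction, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_HEADER} response_function\n")
        fh.write("t_seconds,normalized_size\n")
        for t, y in zip(rf.times, rf.normalized_size):
            fh.write(f"{t:.8e},{y:.10f}\n")
    sidecar = {
        "version": __version__,
        "rh_initial": rf.rh_initial,
        "rh_final": rf.rh_final,
        "temperature": rf.temperature,
        "droplet_radius_initial": rf.droplet_radius_initial,
        "solute_label": rf.solute_label,
        "meta": {k: v for k, v in rf.meta.items() if _json_safe(v)},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_response(path) -> ResponseFunction:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", comments="#", skiprows=2)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    times = data[:, 0]
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        bad = int(np.argmax(np.diff(times) <= 0))
        raise ValueError(f"{path.name}: time column not increasing at row {bad + 1}")
    return ResponseFunction(
        times=times,
        normalized_size=data[:, 1],
        rh_initial=meta.get("rh_initial", np.nan),
        rh_final=meta.get("rh_final", np.nan),
        temperature=meta.get("temperature", 298.0),
        droplet_radius_initial=meta.get("droplet_radius_initial", 4e-6),
        solute_label=meta.get("solute_label", ""),
        meta=meta.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# packings
# ---------------------------------------------------------------------------


def write_packing(config: PackedConfiguration, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_HEADER} packing\n")
        fh.write("x_nm,y_nm,z_nm,radius_nm\n")
        for c, r in zip(config.centers, config.radii):
            fh.write(f"{c[0]:.6f},{c[1]:.6f},{c[2]:.6f},{r:.6f}\n")
    sidecar = {
        "version": __version__,
        "box_nm": config.box.tolist(),
        "label": config.label,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_packing(path) -> PackedConfiguration:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", comments="#", skiprows=2, ndmin=2)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if data.size == 0:
        data = np.empty((0, 4))
    return PackedConfiguration(
        centers=data[:, :3],
        radii=data[:, 3],
        box=np.asarray(sidecar["box_nm"], dtype=float),
        label=sidecar.get("label", ""),
    )


# ---------------------------------------------------------------------------
# parameterizations
# ---------------------------------------------------------------------------


def write_diffusivity(param: DiffusivityParameterization, path) -> None:
    payload = {"version": __version__, **param.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_diffusivity(path) -> DiffusivityParameterization:
    return DiffusivityParameterization.from_dict(json.loads(Path(path).read_text()))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except (TypeError, ValueError):
        return False
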