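"""Trajectory file I/O.

Trajectories are written as tab-separated text: '#'-prefixed ``key=value``
metadata lines, then a header row naming every column, then one row per
sampled frame.  All floats are written at full double precision so a
write→read round trip is lossless.
"""

from __future__ import annotations

import ast
import io as _io
import os
from typing import List

import numpy as np

from .engine import Trajectory

__all__ = ["write_trajectory", "read_trajectory"]

_REQUIRED_META = ("pH", "seed", "mode", "dt", "sample_stride")


def _format_meta_value(v) -> str:
    return repr(v)


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write a Trajectory to a TSV file (lossless, full float precision)."""
    cols: List[str] = ["step", "time_ps"]
    cols += traj.lambda_names
    cols += [f"env_{k}" for k in range(traj.env.shape[1])]
    cols += [f"gate_{k}" for k in range(traj.gate.shape[1])]
    cols += [f"s_{k}" for k in range(traj.s.shape[1])]
    cols += list(Trajectory.TEMP_COLUMNS)
    cols += list(Trajectory.ENERGY_COLUMNS)

    stride = int(traj.metadata["sample_stride"])
    steps = stride * np.arange(1, traj.lam.shape[0] + 1)
    data = np.column_stack([
        steps, traj.times, traj.lam, traj.env, traj.gate, traj.s,
        traj.temps, traj.energies,
    ])
    buf = _io.StringIO()
    for key in sorted(traj.metadata):
        buf.write(f"# {key}={_format_meta_value(traj.metadata[key])}\n")
    buf.write(f"# lambda_names={traj.lambda_names!r}\n")
    buf.write(f"# n_env={traj.env.shape[1]} n_gate={traj.gate.shape[1]}\n")
    buf.write(f"# max_constraint_residual={traj.max_constraint_residual!r}\n")
    buf.write("\t".join(cols) + "\n")
    np.savetxt(buf, data, delimiter="\t", fmt="%.17g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_trajectory(path: str) -> Trajectory:
    """Read a Trajectory written by :func:`write_trajectory`.

    Malformed headers, truncated rows and missing required metadata (e.g.
    the pH) are rejected with explicit errors naming the offending line.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    meta = {}
    header = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    # allow multiple key=value pairs per comment line
                    for part in _split_meta(body):
                        key, val = part.split("=", 1)
                        try:
                            meta[key.strip()] = ast.literal_eval(val.strip())
                        except (ValueError, SyntaxError):
                            meta[key.strip()] = val.strip()
                continue
            if header is None:
                header = line.split("\t")
                continue
            vals = line.split("\t")
            if len(vals) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(vals)} (truncated file?)"
                )
            rows.append([float(v) for v in vals])
    if header is None:
        raise ValueError(f"{path}: no header row found")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"{path}: missing required metadata key {key!r}")
    lambda_names = meta.pop("lambda_names")
    n_env = int(meta.pop("n_env", 0))
    n_gate = int(meta.pop("n_gate", 0))
    max_res = float(meta.pop("max_constraint_residual", 0.0))
    data = np.array(rows)
    n_l = len(lambda_names)
    i = 2
    lam = data[:, i:i + n_l]; i += n_l
    env = data[:, i:i + n_env]; i += n_env
    gate = data[:, i:i + n_gate]; i += n_gate
    s = data[:, i:i + n_gate]; i += n_gate
    n_t = len(Trajectory.TEMP_COLUMNS)
    temps = data[:, i:i + n_t]; i += n_t
    energies = data[:, i:]
    if energies.shape[1] != len(Trajectory.ENERGY_COLUMNS):
        raise ValueError(f"{path}: energy column-count mismatch")
    return Trajectory(
        times=data[:, 1], lam=lam, lambda_names=list(lambda_names),
        env=env, gate=gate, s=s, temps=temps, energies=energies,
        metadata=meta, max_constraint_residual=max_res,
    )


def _split_meta(body: str):
    """Split '# a=1 b=2' style lines while keeping list/str literals intact."""
    parts = []
    depth = 0
    current = ""
    for ch in body:
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth -= 1
        if ch == " " and depth == 0 and "=" in current:
            parts.append(current)
            current = ""
        else:
            current += ch
    if current:
        parts.append(current)
    return [p for p in parts if "=" in p]
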