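"""Trajectory I/O: CSV state files with JSON metadata sidecars.

Trajectories are small (at most 120001 x 4 doubles) so they are written as
human-inspectable CSV with header ``t,y1,y2,y3`` at full double precision
(``repr`` round-trip).  Run metadata (scheme, orders, gains, termination
reason, config hash) goes to a ``.json`` sidecar next to the CSV, so every
run is reproducible from its sidecar alone.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .errors import DomainError
from .fixed_order import Trajectory

__all__ = ["sidecar_path", "write_trajectory", "read_trajectory"]

_HEADER = ["t", "y1", "y2", "y3"]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory CSV plus its JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for t, row in zip(traj.times, traj.states):
            writer.writerow([repr(float(t)), repr(float(row[0])),
                             repr(float(row[1])), repr(float(row[2]))])
    sidecar_path(path).write_text(
        json.dumps(traj.metadata, indent=2, sort_keys=True, default=str))
    return path


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV (and its sidecar, if present).

    Inverts :func:`write_trajectory` bit-exactly.  Malformed rows raise
    :class:`DomainError` naming the line number.
    """
    path = Path(path)
    if not path.exists():
        raise DomainError(f"trajectory file not found: {path}")
    times, states = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DomainError(f"{path}: empty file") from None
        if [h.strip() for h in header] != _HEADER:
            raise DomainError(
                f"{path}: line 1: expected header {','.join(_HEADER)!r}, "
                f"got {','.join(header)!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise DomainError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(row)}")
            try:
                values = [float(v) for v in row]
            except ValueError as exc:
                raise DomainError(f"{path}: line {lineno}: {exc}") from None
            times.append(values[0])
            states.append(values[1:])
    metadata = {}
    sc = sidecar_path(path)
    if sc.exists():
        metadata = json.loads(sc.read_text())
    return Trajectory(times=np.array(times), states=np.array(states),
                      metadata=metadata)
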