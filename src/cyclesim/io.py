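"""Reader/writer for the OpenSim storage dialect (.sto / .mot).

Plain-text, tab-delimited time series: header lines ``name``, ``nRows=``,
``nColumns=``, ``inDegrees=yes|no`` terminated by ``endheader``; the first
column is ``time``.  Angle columns of degree files are normalized to
radians on read.
"""

from __future__ import annotations

import math

import numpy as np


class StorageParseError(ValueError):
    """Malformed .sto/.mot content; the message names the offending line."""


def write_sto(path, name: str, time, columns: dict, in_degrees: bool = False) -> None:
    """Write a storage file with full float precision (lossless round trip)."""
    time = np.asarray(time, dtype=float)
    cols = {k: np.asarray(v, dtype=float) for k, v in columns.items()}
    for k, v in cols.items():
        if v.shape != time.shape:
            raise ValueError(f"column {k!r} length {v.shape} != time length {time.shape}")
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        fh.write(f"nRows={len(time)}\n")
        fh.write(f"nColumns={1 + len(cols)}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("time\t" + "\t".join(cols.keys()) + "\n")
        for i in range(len(time)):
            row = [time[i]] + [v[i] for v in cols.values()]
            fh.write("\t".join(f"{x:.17e}" for x in row) + "\n")


def read_sto(path, angles_to_radians: bool = True):
    """Read a storage file.

    Returns (name, time, columns, in_degrees_flag_of_file).  If the file is
    in degrees and ``angles_to_radians`` is set, every non-time column is
    converted to radians (the dialect stores kinematic quantities).
    """
    with open(path) as fh:
        lines = fh.readlines()

    name = None
    n_rows = n_cols = None
    in_degrees = False
    header_end = None
    for i, line in enumerate(lines):
        s = line.strip()
        if i == 0:
            name = s
            continue
        if s.lower() == "endheader":
            header_end = i
            break
        if "=" in s:
            key, _, val = s.partition("=")
            key, val = key.strip(), val.strip()
            if key == "nRows":
                try:
                    n_rows = int(val)
                except ValueError:
                    raise StorageParseError(f"{path}: line {i + 1}: bad nRows value {val!r}")
            elif key == "nColumns":
                try:
                    n_cols = int(val)
                except ValueError:
                    raise StorageParseError(f"{path}: line {i + 1}: bad nColumns value {val!r}")
            elif key == "inDegrees":
                in_degrees = val.lower() == "yes"
    if header_end is None:
        raise StorageParseError(f"{path}: missing 'endheader' terminator")

    labels_line = header_end + 1
    if labels_line >= len(lines):
        raise StorageParseError(f"{path}: line {labels_line + 1}: missing column labels")
    labels = lines[labels_line].rstrip("\n").split("\t")
    if not labels or labels[0] != "time":
        raise StorageParseError(f"{path}: line {labels_line + 1}: first column must be 'time'")
    if n_cols is not None and len(labels) != n_cols:
        raise StorageParseError(
            f"{path}: line {labels_line + 1}: {len(labels)} labels but nColumns={n_cols}"
        )

    data = []
    for j, line in enumerate(lines[labels_line + 1 :], start=labels_line + 2):
        s = line.strip()
        if not s:
            continue
        parts = s.split()
        if len(parts) != len(labels):
            raise StorageParseError(f"{path}: line {j}: expected {len(labels)} values, got {len(parts)}")
        try:
            data.append([float(p) for p in parts])
        except ValueError:
            raise StorageParseError(f"{path}: line {j}: non-numeric value")
    if n_rows is not None and len(data) != n_rows:
        raise StorageParseError(f"{path}: {len(data)} data rows but nRows={n_rows}")

    arr = np.asarray(data, dtype=float)
    time = arr[:, 0]
    columns = {}
    scale = math.pi / 180.0 if (in_degrees and angles_to_radians) else 1.0
    for k, label in enumerate(labels[1:], start=1):
        columns[label] = arr[:, k] * scale
    return name, time, columns, in_degrees
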