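"""Minimal reader for plain-text JCAMP-DX spectra.

Supports the subset an FT-NIR export actually produces: AFFN (plain decimal)
encoded ``##XYDATA=(X++(Y..Y))`` blocks on an evenly spaced abscissa, and
``##XYPOINTS=(XY..XY)`` pair lists.  Compressed ordinate forms (SQZ/DIF/DUP)
are not supported and are rejected with a clear message.
"""

from __future__ import annotations

import re

import numpy as np

__all__ = ["parse_jcampdx"]

_NUM = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


def parse_jcampdx(path) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(x, y)`` arrays from a JCAMP-DX file.

    ``x`` is in the file's abscissa units scaled by XFACTOR; for 1/CM data
    that is wavenumber in cm^-1.  Raises ``ValueError`` on compressed or
    tabular forms outside the supported subset.
    """
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()

    headers: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None  # None | "xydata" | "xypoints"
    for raw in lines:
        line = raw.split("$$")[0].rstrip()  # strip comments
        if not line.strip():
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                if "X++" not in value.replace(" ", ""):
                    raise ValueError(
                        f"{path}: unsupported XYDATA form {value!r}"
                    )
                mode = "xydata"
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "END":
                mode = None
            else:
                headers[key] = value
                if mode in ("xydata", "xypoints"):
                    mode = None
        elif mode is not None:
            data_lines.append(line)

    if not data_lines:
        raise ValueError(f"{path}: no XYDATA or XYPOINTS block found")

    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))

    if mode == "xypoints" or ("," in data_lines[0] and mode != "xydata"):
        xs, ys = [], []
        for line in data_lines:
            for pair in line.replace(";", " ").split():
                if "," not in pair:
                    continue
                a, b = pair.split(",", 1)
                xs.append(float(a))
                ys.append(float(b))
        x = np.array(xs) * xfactor
        y = np.array(ys) * yfactor
        return x, y

    # (X++(Y..Y)): each line starts with an X value followed by Y ordinates.
    first_x: list[float] = []
    y_rows: list[list[float]] = []
    for line in data_lines:
        residue = _NUM.sub("", line)
        if residue.strip(" \t+-,;"):
            raise ValueError(
                f"{path}: unsupported (compressed?) XYDATA content in "
                f"line {line!r}"
            )
        nums = [float(m) for m in _NUM.findall(line)]
        if len(nums) < 2:
            raise ValueError(f"{path}: malformed XYDATA line {line!r}")
        first_x.append(nums[0])
        y_rows.append(nums[1:])

    ys = [v for row in y_rows for v in row]
    npts_header = headers.get("NPOINTS")
    if npts_header is not None and int(float(npts_header)) != len(ys):
        raise ValueError(
            f"{path}: NPOINTS={npts_header} but {len(ys)} ordinates found"
        )

    # Reconstruct the abscissa from FIRSTX/LASTX when present (the line-start
    # X values are often rounded), otherwise from consecutive line starts.
    if "FIRSTX" in headers and "LASTX" in headers and len(ys) > 1:
        fx = float(headers["FIRSTX"]) * xfactor
        lx = float(headers["LASTX"]) * xfactor
        x = np.linspace(fx, lx, len(ys))
    else:
        fx = first_x[0] * xfactor
        if len(first_x) > 1:
            dx = (first_x[1] - first_x[0]) * xfactor / len(y_rows[0])
        else:
            dx = 1.0
        x = fx + dx * np.arange(len(ys))
    return x, np.array(ys) * yfactor
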