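"""Minimal ENVI-style hypercube I/O (text header + raw binary).

Supports the subset of the format the pipeline needs: BSQ/BIL
interleaves, little-endian floating point, a wavelength list, and the
camera/pixel-pitch fields stashed in the header description.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .hypercube import Hypercube

_DTYPES = {4: np.float32, 5: np.float64}
_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(path, cube: Hypercube, interleave: str = "bsq", dtype=np.float32) -> None:
    """Write ``<path>.hdr`` + ``<path>.raw``."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil"):
        raise ValueError("interleave must be 'bsq' or 'bil'")
    path = Path(path)
    data = cube.data.astype(dtype)
    if interleave == "bsq":  # (bands, rows, cols)
        ordered = np.moveaxis(data, 2, 0)
    else:  # bil: (rows, bands, cols)
        ordered = np.moveaxis(data, 2, 1)
    raw_path = path.with_suffix(".raw")
    ordered.tofile(raw_path)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{camera={cube.camera}, pixel_pitch_mm={cube.pixel_pitch}}}\n"
        f"samples = {cube.cols}\n"
        f"lines = {cube.rows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    path.with_suffix(".hdr").write_text(header)


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for line in text.splitlines():
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip().lower(), value.strip()
        if value.startswith("{") and "}" not in value:
            buf = [value]
            in_braces = True
        else:
            fields[key] = value
    return fields


def read_envi(header_path) -> Hypercube:
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    dtype = _DTYPES[int(fields["data type"])]
    raw = np.fromfile(header_path.with_suffix(".raw"), dtype=dtype)
    if interleave == "bsq":
        data = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2)
    elif interleave == "bil":
        data = np.moveaxis(raw.reshape(rows, bands, cols), 1, 2)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    wl_text = fields["wavelength"].strip("{} ")
    wavelengths = np.array([float(x) for x in wl_text.split(",")])
    camera, pitch = "STITCHED", 0.5
    desc = fields.get("description", "")
    for token in desc.strip("{} ").split(","):
        k, _, v = token.strip().partition("=")
        if k == "camera":
            camera = v
        elif k == "pixel_pitch_mm":
            pitch = float(v)
    return Hypercube(np.ascontiguousarray(data, dtype=float), wavelengths, camera, pitch)
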