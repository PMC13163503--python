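"""Minimal ENVI-convention cube I/O (BSQ float32 + text header)."""

from __future__ import annotations

import os

import numpy as np

from .geometry import HyperCube

_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(cube: HyperCube, path_stem: str) -> None:
    """Write cube as <stem>.raw (BSQ float32) plus <stem>.hdr."""
    data = cube.values.astype(np.float32)
    lines, samples, bands = data.shape
    bsq = np.transpose(data, (2, 0, 1))  # band, line, sample
    raw_path = path_stem + ".raw"
    bsq.tofile(raw_path)
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{sscmap cube, kind={cube.kind}, "
        f"correction={cube.correction}}}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    with open(path_stem + ".hdr", "w") as fh:
        fh.write(header)


def _parse_header(path: str) -> dict:
    with open(path) as fh:
        text = fh.read()
    fields: dict = {}
    i = 0
    lines = text.splitlines()
    while i < len(lines):
        line = lines[i]
        if "=" in line:
            key, _, val = line.partition("=")
            key = key.strip().lower()
            val = val.strip()
            if val.startswith("{") and not val.endswith("}"):
                while not val.endswith("}") and i + 1 < len(lines):
                    i += 1
                    val += " " + lines[i].strip()
            fields[key] = val.strip("{} ")
        i += 1
    return fields


def read_envi(path_stem: str) -> HyperCube:
    hdr = path_stem + ".hdr"
    if not os.path.exists(hdr):
        raise FileNotFoundError(hdr)
    fields = _parse_header(hdr)
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    dtype = _DTYPES[int(fields.get("data type", 4))]
    interleave = fields.get("interleave", "bsq").lower()
    raw = np.fromfile(path_stem + ".raw", dtype=dtype)
    if raw.size != samples * lines * bands:
        raise ValueError("raw file size does not match header dimensions")
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    wl_field = fields.get("wavelength", "")
    if wl_field:
        wavelengths = np.array([float(w) for w in wl_field.split(",")])
    else:
        wavelengths = np.arange(bands, dtype=float)
    desc = fields.get("description", "")
    kind = "reflectance" if "kind=reflectance" in desc else "intensity"
    return HyperCube(values=data.astype(float), wavelengths=wavelengths,
                     kind=kind)
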