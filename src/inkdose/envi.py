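"""Minimal ENVI cube I/O (text header + raw binary) and CSV spectra I/O.

Supports the three classic interleaves (BSQ, BIL, BIP), float64 samples,
little-endian byte order, and carries the acquisition metadata this package
needs (frame rate, stage speed, across-track pitch, cube mode) as extra
header keys.  Reference spectra travel as 2-column CSV
(wavelength_nm, counts).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .errors import ParseError
from .spectra_core import HyperspectralCube, ReferencePair

_INTERLEAVES = ("bsq", "bil", "bip")

# ENVI data type codes we read/write
_DTYPES = {4: np.float32, 5: np.float64}


def _header_path(path: str | Path) -> Path:
    path = Path(path)
    return path if path.suffix == ".hdr" else path.with_suffix(".hdr")


def _data_path(path: str | Path) -> Path:
    return _header_path(path).with_suffix(".img")


def write_envi_cube(
    path: str | Path, cube: HyperspectralCube, interleave: str = "bil"
) -> Path:
    """Write ``<path>.hdr`` + ``<path>.img``; returns the header path."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ParseError(f"unknown interleave {interleave!r}")
    hdr, img = _header_path(path), _data_path(path)
    lines, samples, bands = cube.data.shape
    # axis order on disk per interleave; memory order is (frame, spatial, band)
    if interleave == "bip":
        ondisk = cube.data
    elif interleave == "bil":
        ondisk = cube.data.transpose(0, 2, 1)  # (lines, bands, samples)
    else:  # bsq
        ondisk = cube.data.transpose(2, 0, 1)  # (bands, lines, samples)
    ondisk.astype("<f8").tofile(img)

    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    hdr.write_text(
        "ENVI\n"
        "description = {inkdose hyperspectral cube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 5\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
        f"frame rate = {cube.frame_rate}\n"
        f"stage speed = {cube.stage_speed}\n"
        f"pixel pitch across = {cube.pixel_pitch_across}\n"
        f"cube mode = {cube.mode}\n"
    )
    return hdr


def _parse_header(text: str, hdr: Path) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise ParseError(f"{hdr}: missing ENVI magic line")
    # join brace-delimited multi-line values
    fields: dict[str, str] = {}
    buf = ""
    for raw_line in text.splitlines()[1:]:
        line = buf + raw_line.strip()
        if not line:
            continue
        if "{" in line and "}" not in line:
            buf = line + " "
            continue
        buf = ""
        m = re.match(r"([^=]+?)\s*=\s*(.*)$", line)
        if not m:
            raise ParseError(f"{hdr}: malformed header line: {raw_line!r}")
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def read_envi_cube(path: str | Path) -> HyperspectralCube:
    """Read an ENVI header+raw pair back into a cube."""
    hdr = _header_path(path)
    if not hdr.exists():
        raise ParseError(f"header not found: {hdr}")
    fields = _parse_header(hdr.read_text(), hdr)

    def need(key: str) -> str:
        if key not in fields:
            raise ParseError(f"{hdr}: header missing required key {key!r}")
        return fields[key]

    samples = int(need("samples"))
    lines = int(need("lines"))
    bands = int(need("bands"))
    dtype_code = int(need("data type"))
    if dtype_code not in _DTYPES:
        raise ParseError(f"{hdr}: unsupported data type {dtype_code}")
    interleave = need("interleave").lower()
    if interleave not in _INTERLEAVES:
        raise ParseError(f"{hdr}: unknown interleave {interleave!r}")
    wl_raw = need("wavelength")
    if not (wl_raw.startswith("{") and wl_raw.endswith("}")):
        raise ParseError(f"{hdr}: malformed wavelength block: {wl_raw[:40]!r}")
    wavelengths = np.array(
        [float(tok) for tok in wl_raw[1:-1].replace(",", " ").split()]
    )
    if wavelengths.size != bands:
        raise ParseError(
            f"{hdr}: {wavelengths.size} wavelengths for {bands} bands"
        )

    img = _data_path(path)
    data = np.fromfile(img, dtype=np.dtype(_DTYPES[dtype_code]).newbyteorder("<"))
    expected = samples * lines * bands
    if data.size != expected:
        raise ParseError(
            f"{img}: expected {expected} samples, found {data.size}"
        )
    if interleave == "bip":
        cube_data = data.reshape(lines, samples, bands)
    elif interleave == "bil":
        cube_data = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:
        cube_data = data.reshape(bands, lines, samples).transpose(1, 2, 0)

    return HyperspectralCube(
        data=np.ascontiguousarray(cube_data.astype(np.float64)),
        wavelengths=wavelengths,
        frame_rate=float(fields.get("frame rate", 111.0)),
        stage_speed=float(fields.get("stage speed", 200.0)),
        pixel_pitch_across=float(fields.get("pixel pitch across", 114.0)),
        mode=fields.get("cube mode", "raw_reflectance"),
    )


def write_reference_csv(path: str | Path, wavelengths: np.ndarray,
                        counts: np.ndarray) -> None:
    """2-column CSV (wavelength_nm, counts) for one mean reference spectrum."""
    arr = np.column_stack([np.asarray(wavelengths), np.asarray(counts)])
    np.savetxt(path, arr, delimiter=",", header="wavelength_nm,counts",
               comments="")


def read_reference_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
    except ValueError as exc:
        raise ParseError(f"{path}: not a 2-column numeric CSV") from exc
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParseError(f"{path}: expected exactly 2 columns")
    return arr[:, 0], arr[:, 1]


def read_reference_pair(white_csv: str | Path,
                        black_csv: str | Path) -> ReferencePair:
    """Mean white/black spectra from CSV, broadcast over the sensor line."""
    _, white = read_reference_csv(white_csv)
    _, black = read_reference_csv(black_csv)
    return ReferencePair(white=white, black=black)
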