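"""Minimal ENVI cube reader/writer (.hdr text header + raw binary data).

Supports the subset of the format hyperspectral snapshot cameras emit: BSQ /
BIL / BIP interleaves, little/big endian, integer and float sample types, and
the in-header wavelength list.  Writing defaults to band-interleaved-by-line
32-bit little-endian floats with the wavelength list in the header.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

_DTYPES = {
    1: np.dtype(np.uint8),
    2: np.dtype(np.int16),
    3: np.dtype(np.int32),
    4: np.dtype(np.float32),
    5: np.dtype(np.float64),
    12: np.dtype(np.uint16),
    13: np.dtype(np.uint32),
}
_DTYPE_CODES = {v: k for k, v in _DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


class EnviParseError(ValueError):
    """Malformed ENVI header; the message names the offending field."""


def _parse_header(text: str, path: Path) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviParseError(f"{path}: missing ENVI magic line")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # key = value, where a value starting with '{' runs to the matching '}'
    pos = 0
    pattern = re.compile(r"\s*([^={}\n]+?)\s*=\s*", re.S)
    while pos < len(body):
        m = pattern.match(body, pos)
        if m is None:
            if body[pos:].strip():
                raise EnviParseError(
                    f"{path}: unparseable header text near {body[pos:pos+40]!r}"
                )
            break
        key = m.group(1).strip().lower()
        pos = m.end()
        if pos < len(body) and body[pos] == "{":
            end = body.find("}", pos)
            if end < 0:
                raise EnviParseError(f"{path}: unterminated '{{' in field {key!r}")
            fields[key] = body[pos + 1 : end].strip()
            pos = end + 1
        else:
            end = body.find("\n", pos)
            end = len(body) if end < 0 else end
            fields[key] = body[pos:end].strip()
            pos = end + 1
    return fields


def _require_int(fields: dict, key: str, path: Path) -> int:
    if key not in fields:
        raise EnviParseError(f"{path}: missing required field {key!r}")
    try:
        return int(fields[key])
    except ValueError:
        raise EnviParseError(
            f"{path}: field {key!r} is not an integer: {fields[key]!r}"
        ) from None


def read_envi(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ENVI cube.

    ``path`` may point at either the ``.hdr`` or the data file.  Returns the
    cube as (lines, samples, bands) plus the wavelength array (``None`` when
    the header carries no wavelength list).
    """
    path = Path(path)
    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    if not hdr.exists():
        raise FileNotFoundError(hdr)
    fields = _parse_header(hdr.read_text(), hdr)

    samples = _require_int(fields, "samples", hdr)
    lines = _require_int(fields, "lines", hdr)
    bands = _require_int(fields, "bands", hdr)
    dtype_code = _require_int(fields, "data type", hdr)
    if dtype_code not in _DTYPES:
        raise EnviParseError(f"{hdr}: unsupported 'data type' {dtype_code}")
    dtype = _DTYPES[dtype_code]
    byte_order = int(fields.get("byte order", "0"))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in _INTERLEAVES:
        raise EnviParseError(f"{hdr}: unsupported 'interleave' {interleave!r}")
    offset = int(fields.get("header offset", "0"))

    wavelengths = None
    if "wavelength" in fields:
        try:
            wavelengths = np.array(
                [float(tok) for tok in fields["wavelength"].split(",") if tok.strip()]
            )
        except ValueError:
            raise EnviParseError(f"{hdr}: field 'wavelength' has non-numeric entries")
        if wavelengths.size != bands:
            raise EnviParseError(
                f"{hdr}: field 'wavelength' lists {wavelengths.size} values "
                f"but 'bands' = {bands}"
            )

    data_path = _find_data_file(path, hdr)
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise EnviParseError(
            f"{hdr}: data size {raw.size} does not match "
            f"samples*lines*bands = {expected}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        cube = raw.reshape(lines, samples, bands)
    return np.ascontiguousarray(cube), wavelengths


def _find_data_file(path: Path, hdr: Path) -> Path:
    if path.suffix != ".hdr" and path.exists():
        return path
    for ext in (".dat", ".raw", ".img", ""):
        cand = hdr.with_suffix(ext)
        if cand.exists() and cand != hdr:
            return cand
    raise FileNotFoundError(f"no data file next to {hdr}")


def write_envi(
    cube: np.ndarray,
    wavelengths: np.ndarray | None,
    path: str | Path,
    interleave: str = "bil",
    dtype: np.dtype | type | None = None,
) -> Path:
    """Write a cube to an ENVI ``.hdr``/``.dat`` pair; returns the .hdr path.

    The cube must be (lines, samples, bands).  Values are written verbatim in
    the cube's own dtype unless ``dtype`` overrides it, so a float32 cube
    round-trips bit-exactly.
    """
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("cube must be 3-dimensional (lines, samples, bands)")
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"interleave must be one of {_INTERLEAVES}")
    lines, samples, bands = cube.shape
    if wavelengths is not None and len(wavelengths) != bands:
        raise ValueError(
            f"wavelength list length {len(wavelengths)} != band count {bands}"
        )
    out_dtype = np.dtype(dtype) if dtype is not None else cube.dtype
    out_dtype = out_dtype.newbyteorder("<")
    if out_dtype.newbyteorder("=") not in _DTYPE_CODES:
        out_dtype = np.dtype(np.float32)
    code = _DTYPE_CODES[out_dtype.newbyteorder("=")]

    path = Path(path)
    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    dat = hdr.with_suffix(".dat")

    if interleave == "bsq":
        flat = cube.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = cube.transpose(0, 2, 1)
    else:
        flat = cube
    np.ascontiguousarray(flat, dtype=out_dtype).tofile(dat)

    header_lines = [
        "ENVI",
        "description = {jamspec simulated hyperspectral cube}",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{float(v):.6f}" for v in wavelengths)
        header_lines.append("wavelength units = Nanometers")
        header_lines.append(f"wavelength = {{{wl}}}")
    hdr.write_text("\n".join(header_lines) + "\n")
    return hdr
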