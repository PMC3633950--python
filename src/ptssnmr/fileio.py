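"""Exchange formats: CSV/JSON spectra and FIDs, JCAMP-DX import.

The CSV exchange format is a plain two-column table preceded by ``# key: value``
metadata lines; every writer stamps a ``format_version`` so readers can refuse
incompatible files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .processing import FID, Spectrum

__all__ = [
    "FORMAT_VERSION",
    "DataFormatError",
    "write_spectrum_csv", "read_spectrum_csv",
    "write_fid_csv", "read_fid_csv",
    "write_spectrum_json", "read_spectrum_json",
    "read_jcamp",
]

FORMAT_VERSION = "1.0"


class DataFormatError(ValueError):
    """Raised when an exchange file cannot be parsed or is incompatible."""


def _meta_header(meta: dict) -> str:
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    return "\n".join(lines) + "\n"


def _parse_meta(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            k, v = body.split(":", 1)
            meta[k.strip()] = v.strip()
    return meta


def _check_version(meta: dict, path) -> None:
    version = meta.get("format_version")
    if version is None:
        raise DataFormatError(f"{path}: missing format_version")
    if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise DataFormatError(f"{path}: unsupported format_version {version}")


# -- spectrum CSV -------------------------------------------------------------


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    meta = {
        "format_version": FORMAT_VERSION,
        "kind": "spectrum",
        "scheme": spectrum.scheme,
        "reference_ppm": spectrum.reference_ppm if spectrum.reference_ppm is not None else "none",
    }
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        fh.write("ppm,intensity\n")
        for p, y in zip(spectrum.ppm_axis, spectrum.intensity):
            fh.write(f"{p:.6f},{y:.8e}\n")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    header, rows = [], []
    try:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    header.append(line)
                elif line[0].isalpha():
                    continue  # column header
                else:
                    rows.append(line.split(","))
        meta = _parse_meta(header)
        _check_version(meta, path)
        data = np.array(rows, dtype=float)
        if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
            raise DataFormatError(f"{path}: expected two numeric columns")
        ref = meta.get("reference_ppm", "none")
        return Spectrum(ppm_axis=data[:, 0], intensity=data[:, 1],
                        scheme=meta.get("scheme", "DP"),
                        reference_ppm=None if ref == "none" else float(ref))
    except (ValueError, OSError) as exc:
        if isinstance(exc, DataFormatError):
            raise
        raise DataFormatError(f"{path}: {exc}") from exc


# -- FID CSV ------------------------------------------------------------------


def write_fid_csv(fid: FID, path: str | Path) -> None:
    meta = {
        "format_version": FORMAT_VERSION,
        "kind": "fid",
        "scheme": fid.scheme,
        "dwell_time_s": repr(fid.dwell_time),
        "larmor_c_hz": repr(fid.larmor_c),
        "carrier_ppm": repr(fid.carrier_ppm),
    }
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        fh.write("real,imag\n")
        for z in fid.points:
            fh.write(f"{z.real:.10e},{z.imag:.10e}\n")


def read_fid_csv(path: str | Path) -> FID:
    header, rows = [], []
    try:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    header.append(line)
                elif line[0].isalpha() or line[0] == "r":
                    continue
                else:
                    rows.append(line.split(","))
        meta = _parse_meta(header)
        _check_version(meta, path)
        data = np.array(rows, dtype=float)
        return FID(points=data[:, 0] + 1j * data[:, 1],
                   dwell_time=float(meta["dwell_time_s"]),
                   scheme=meta.get("scheme", "DP"),
                   larmor_c=float(meta.get("larmor_c_hz", 125e6)),
                   carrier_ppm=float(meta.get("carrier_ppm", 125.0)))
    except (KeyError, ValueError, OSError) as exc:
        if isinstance(exc, DataFormatError):
            raise
        raise DataFormatError(f"{path}: {exc}") from exc


# -- spectrum JSON ------------------------------------------------------------


def write_spectrum_json(spectrum: Spectrum, path: str | Path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "spectrum",
        "scheme": spectrum.scheme,
        "reference_ppm": spectrum.reference_ppm,
        "ppm": [float(x) for x in spectrum.ppm_axis],
        "intensity": [float(x) for x in spectrum.intensity],
    }
    Path(path).write_text(json.dumps(payload))


def read_spectrum_json(path: str | Path) -> Spectrum:
    try:
        payload = json.loads(Path(path).read_text())
        _check_version(payload, path)
        return Spectrum(ppm_axis=np.asarray(payload["ppm"], dtype=float),
                        intensity=np.asarray(payload["intensity"], dtype=float),
                        scheme=payload.get("scheme", "DP"),
                        reference_ppm=payload.get("reference_ppm"))
    except (KeyError, ValueError, OSError) as exc:
        if isinstance(exc, DataFormatError):
            raise
        raise DataFormatError(f"{path}: {exc}") from exc


# -- JCAMP-DX -----------------------------------------------------------------


def read_jcamp(path: str | Path) -> Spectrum:
    """Minimal JCAMP-DX spectrum reader (AFFN ``XYDATA=(X++(Y..Y))`` only).

    Supports the subset needed to import 1D processed 13C spectra: FIRSTX,
    LASTX, NPOINTS, YFACTOR and an AFFN-encoded XYDATA table.  Compressed
    (SQZ/DIF/DUP) encodings are not supported.
    """
    fields: dict[str, str] = {}
    y_values: list[float] = []
    in_data = False
    try:
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XYDATA":
                    in_data = True
                    continue
                if key == "END":
                    in_data = False
                fields[key] = value
                continue
            if in_data:
                nums = line.replace(",", " ").split()
                # first number of each data line is the X start; rest are Y
                y_values.extend(float(v) for v in nums[1:])
        firstx = float(fields["FIRSTX"])
        lastx = float(fields["LASTX"])
        npoints = int(float(fields["NPOINTS"]))
        yfactor = float(fields.get("YFACTOR", "1"))
        if len(y_values) != npoints:
            raise DataFormatError(f"{path}: NPOINTS={npoints} but {len(y_values)} Y values")
        x = np.linspace(firstx, lastx, npoints)
        y = np.asarray(y_values) * yfactor
        if x[0] < x[-1]:  # store descending
            x, y = x[::-1], y[::-1]
        return Spectrum(ppm_axis=x, intensity=y, scheme=fields.get("DATATYPE", "DP"))
    except (KeyError, ValueError, OSError) as exc:
        if isinstance(exc, DataFormatError):
            raise
        raise DataFormatError(f"{path}: {exc}") from exc
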