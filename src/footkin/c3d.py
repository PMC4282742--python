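"""Minimal C3D reader/writer for labelled 3D point data.

Supports the Intel (PC) byte order with either 16-bit integer or 32-bit
float point storage on read, and writes float Intel files. Only the 3D
point section is handled: analog channels, events and vendor-specific
parameter groups are ignored. Invalid samples (negative residual) are
returned as NaN; NaN points are written with a negative residual.
"""
from __future__ import annotations

import struct

import numpy as np

from .errors import EmptyTrialError, FormatError

_PROC_INTEL = 84


def _read_exact(fh, n: int) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise FormatError(f"truncated C3D file: wanted {n} bytes, got {len(buf)}")
    return buf


def _parse_parameters(raw: bytes) -> dict[str, dict[str, tuple]]:
    """Parse the parameter section into {GROUP: {PARAM: (type, dims, bytes)}}."""
    if len(raw) < 4:
        raise FormatError("C3D parameter section too short")
    proc = raw[3]
    if proc != _PROC_INTEL:
        raise FormatError(f"unsupported C3D processor type {proc} (only Intel/PC supported)")
    groups: dict[int, str] = {}
    params: dict[int, list[tuple[str, int, list[int], bytes]]] = {}
    pos = 4
    while pos + 2 <= len(raw):
        nchar = struct.unpack_from("b", raw, pos)[0]
        gid = struct.unpack_from("b", raw, pos + 1)[0]
        if nchar == 0 or gid == 0:
            break
        name = raw[pos + 2 : pos + 2 + abs(nchar)].decode("ascii", "replace").upper()
        pos += 2 + abs(nchar)
        offset = struct.unpack_from("<h", raw, pos)[0]
        next_pos = pos + offset if offset > 0 else len(raw)
        if gid < 0:  # group record
            groups[-gid] = name
        else:  # parameter record
            ptype = struct.unpack_from("b", raw, pos + 2)[0]
            ndims = raw[pos + 3]
            dims = list(raw[pos + 4 : pos + 4 + ndims])
            nelem = 1
            for d in dims:
                nelem *= d
            itemsize = abs(ptype)
            dstart = pos + 4 + ndims
            data = raw[dstart : dstart + nelem * itemsize]
            params.setdefault(gid, []).append((name, ptype, dims, data))
        if offset <= 0:
            break
        pos = next_pos
    out: dict[str, dict[str, tuple]] = {}
    for gid, plist in params.items():
        gname = groups.get(gid, f"GROUP{gid}")
        out.setdefault(gname, {})
        for name, ptype, dims, data in plist:
            out[gname][name] = (ptype, dims, data)
    return out


def read_c3d(path) -> tuple[list[str], np.ndarray, float]:
    """Read a C3D file.

    Returns ``(labels, points, rate)`` where ``points`` has shape
    ``(n_frames, n_points, 3)`` in the file's distance units with NaN for
    invalid samples.
    """
    try:
        with open(path, "rb") as fh:
            header = _read_exact(fh, 512)
            param_ptr, magic = struct.unpack_from("<BB", header, 0)
            if magic != 0x50:
                raise FormatError(f"not a C3D file (magic byte {magic:#x} != 0x50)")
            n_points = struct.unpack_from("<H", header, 2)[0]
            first_frame = struct.unpack_from("<H", header, 6)[0]
            last_frame = struct.unpack_from("<H", header, 8)[0]
            scale = struct.unpack_from("<f", header, 12)[0]
            data_block = struct.unpack_from("<H", header, 16)[0]
            rate = struct.unpack_from("<f", header, 20)[0]

            fh.seek((param_ptr - 1) * 512)
            n_param_blocks_probe = _read_exact(fh, 4)
            n_param_blocks = n_param_blocks_probe[2]
            fh.seek((param_ptr - 1) * 512)
            praw = _read_exact(fh, max(n_param_blocks, 1) * 512)
            groups = _parse_parameters(praw)

            n_frames = last_frame - first_frame + 1
            if n_points == 0 or n_frames <= 0:
                raise EmptyTrialError("C3D file contains no 3D point frames")

            labels = _labels_from_params(groups, n_points)

            fh.seek((data_block - 1) * 512)
            if scale < 0:  # float storage
                raw = _read_exact(fh, n_frames * n_points * 16)
                arr = np.frombuffer(raw, dtype="<f4").reshape(n_frames, n_points, 4)
                pts = arr[:, :, :3].astype(float).copy()
                invalid = arr[:, :, 3] < 0
            else:  # signed 16-bit integer storage
                raw = _read_exact(fh, n_frames * n_points * 8)
                arr = np.frombuffer(raw, dtype="<i2").reshape(n_frames, n_points, 4)
                pts = arr[:, :, :3].astype(float) * scale
                invalid = arr[:, :, 3] < 0
            pts[invalid] = np.nan
            return labels, pts, float(rate)
    except (FormatError, EmptyTrialError):
        raise
    except OSError as exc:
        raise FormatError(f"cannot read C3D file {path}: {exc}") from exc
    except (struct.error, ValueError) as exc:
        raise FormatError(f"malformed C3D file {path}: {exc}") from exc


def _labels_from_params(groups, n_points: int) -> list[str]:
    point = groups.get("POINT", {})
    if "LABELS" in point:
        ptype, dims, data = point["LABELS"]
        if ptype == -1 and len(dims) == 2:
            width, n = dims
            labels = []
            for i in range(min(n, n_points)):
                labels.append(data[i * width : (i + 1) * width].decode("ascii", "replace").strip())
            while len(labels) < n_points:
                labels.append(f"PT{len(labels) + 1}")
            return labels
    return [f"PT{i + 1}" for i in range(n_points)]


def write_c3d(path, labels: list[str], points: np.ndarray, rate: float) -> None:
    """Write labelled 3D points to a float-format Intel C3D file.

    ``points`` must have shape ``(n_frames, n_labels, 3)``; NaN samples are
    stored with a negative residual.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 3 or points.shape[2] != 3:
        raise FormatError("points must have shape (n_frames, n_labels, 3)")
    n_frames, n_points, _ = points.shape
    if n_frames == 0 or n_points == 0:
        raise EmptyTrialError("refusing to write an empty C3D trial")
    if len(labels) != n_points:
        raise FormatError("label count does not match point count")

    width = max(4, max(len(s) for s in labels))
    # the parameter section length does not depend on the DATA_START value,
    # so build once to size it, then rebuild with the real block number
    n_param_blocks = (len(_build_point_group(labels, width, n_frames, n_points, rate, 0)) + 511) // 512
    data_block = 2 + n_param_blocks
    params = _build_point_group(labels, width, n_frames, n_points, rate, data_block)
    params = params.ljust(n_param_blocks * 512, b"\x00")
    # patch number-of-blocks byte
    params = params[:2] + bytes([n_param_blocks]) + params[3:]

    header = bytearray(512)
    struct.pack_into("<BB", header, 0, 2, 0x50)
    struct.pack_into("<H", header, 2, n_points)
    struct.pack_into("<H", header, 4, 0)  # analog samples per frame
    struct.pack_into("<H", header, 6, 1)  # first frame
    struct.pack_into("<H", header, 8, n_frames)  # last frame
    struct.pack_into("<H", header, 10, 10)  # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)  # negative scale -> float data
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<H", header, 18, 0)  # analog samples per channel
    struct.pack_into("<f", header, 20, float(rate))

    frame_data = np.zeros((n_frames, n_points, 4), dtype="<f4")
    frame_data[:, :, :3] = np.nan_to_num(points, nan=0.0)
    invalid = np.isnan(points).any(axis=2)
    frame_data[:, :, 3] = np.where(invalid, -1.0, 0.0)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(params)
        fh.write(frame_data.tobytes())


def _param_record(gid: int, name: str, ptype: int, dims: list[int], data: bytes) -> bytes:
    name_b = name.encode("ascii")
    body = struct.pack("bb", ptype, len(dims)) + bytes(dims) + data + b"\x00"
    offset = 2 + len(body)
    return struct.pack("bb", len(name_b), gid) + name_b + struct.pack("<h", offset) + body


def _build_point_group(labels, width, n_frames, n_points, rate, data_block) -> bytes:
    out = bytearray()
    out += bytes([1, 0x50, 1, _PROC_INTEL])
    # group record: POINT (id -1)
    name = b"POINT"
    out += struct.pack("bb", len(name), -1) + name + struct.pack("<h", 3) + b"\x00"
    out += _param_record(1, "USED", 2, [], struct.pack("<h", n_points))
    out += _param_record(1, "FRAMES", 2, [], struct.pack("<h", min(n_frames, 32767)))
    out += _param_record(1, "SCALE", 4, [], struct.pack("<f", -1.0))
    out += _param_record(1, "RATE", 4, [], struct.pack("<f", float(rate)))
    out += _param_record(1, "UNITS", -1, [2], b"mm")
    out += _param_record(1, "DATA_START", 2, [], struct.pack("<h", data_block))
    label_data = b"".join(s.ljust(width).encode("ascii") for s in labels)
    out += _param_record(1, "LABELS", -1, [width, n_points], label_data)
    out += struct.pack("bb", 0, 0)  # terminator
    return bytes(out)
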