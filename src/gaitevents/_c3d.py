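"""Minimal C3D motion-capture file codec.

Implements the subset of the public C3D standard (www.c3d.org) needed
for marker-only trials: the 512-byte header, the POINT parameter group
(USED, FRAMES, RATE, SCALE, DATA_START, LABELS) and the 3D point data
section.  Intel (little-endian) byte order only; the writer always emits
floating-point point data (negative header scale), the reader also
accepts scaled-integer data.  Analog channels are ignored.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_BLOCK = 512
_PROC_INTEL = 84


@dataclass
class C3DContents:
    labels: list[str]
    points: np.ndarray      # (frames, points, 3) mm
    residuals: np.ndarray   # (frames, points); < 0 means invalid point
    rate: float


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_c3d(path: Path) -> C3DContents:
    raw = Path(path).read_bytes()
    if len(raw) < 2 * _BLOCK:
        raise ValueError(f"{path}: too short to be a C3D file")
    param_block, magic = raw[0], raw[1]
    if magic != 0x50:
        raise ValueError(f"{path}: not a C3D file (magic byte {magic})")

    hdr = struct.unpack_from("<4H", raw, 2)
    n_points_hdr, _analog, first_frame, last_frame = hdr
    hdr_scale, = struct.unpack_from("<f", raw, 12)
    data_block_hdr, = struct.unpack_from("<H", raw, 16)
    hdr_rate, = struct.unpack_from("<f", raw, 20)

    params = _read_params(raw, (param_block - 1) * _BLOCK, path)
    point = params.get("POINT", {})
    n_points = int(_scalar(point.get("USED", n_points_hdr)))
    rate = float(_scalar(point.get("RATE", hdr_rate)))
    scale = float(_scalar(point.get("SCALE", hdr_scale)))
    data_block = int(_scalar(point.get("DATA_START", data_block_hdr)))
    n_frames = last_frame - first_frame + 1
    if "FRAMES" in point:
        n_frames = int(_scalar(point["FRAMES"]))

    labels = point.get("LABELS")
    if labels is None:
        labels = [f"P{i + 1}" for i in range(n_points)]
    labels = [str(s).strip() for s in labels][:n_points]
    while len(labels) < n_points:
        labels.append(f"P{len(labels) + 1}")

    off = (data_block - 1) * _BLOCK
    if scale < 0:  # floating-point data
        frame_words = n_points * 4
        data = np.frombuffer(raw, dtype="<f4", count=n_frames * frame_words,
                             offset=off).reshape(n_frames, n_points, 4)
        points = data[:, :, :3].astype(float)
        residuals = data[:, :, 3].astype(float)
    else:  # scaled-integer data
        frame_words = n_points * 4
        data = np.frombuffer(raw, dtype="<i2", count=n_frames * frame_words,
                             offset=off).reshape(n_frames, n_points, 4)
        points = data[:, :, :3].astype(float) * scale
        residuals = data[:, :, 3].astype(float)
    if rate <= 0:
        raise ValueError(f"{path}: invalid point rate {rate}")
    return C3DContents(labels, points, residuals, rate)


def _scalar(v):
    if isinstance(v, (list, np.ndarray)):
        return np.asarray(v).ravel()[0]
    return v


def _read_params(raw: bytes, off: int, path: Path) -> dict:
    proc = raw[off + 3]
    if proc != _PROC_INTEL:
        raise ValueError(f"{path}: unsupported processor type {proc} "
                         "(only Intel/little-endian C3D is handled)")
    pos = off + 4
    group_names: dict[int, str] = {}
    values: dict[int, dict] = {}
    while pos < len(raw) - 1:
        n_chars = struct.unpack_from("<b", raw, pos)[0]
        group_id = struct.unpack_from("<b", raw, pos + 1)[0]
        if n_chars == 0 or group_id == 0:
            break
        name = raw[pos + 2: pos + 2 + abs(n_chars)].decode(
            "ascii", "replace").strip()
        p = pos + 2 + abs(n_chars)
        next_off = struct.unpack_from("<h", raw, p)[0]
        next_pos = p + next_off if next_off > 0 else len(raw)
        p += 2
        if group_id < 0:  # group record
            group_names[-group_id] = name.upper()
        else:  # parameter record
            dtype = struct.unpack_from("<b", raw, p)[0]
            n_dims = raw[p + 1]
            dims = list(raw[p + 2: p + 2 + n_dims])
            p += 2 + n_dims
            count = int(np.prod(dims)) if dims else 1
            if dtype == -1:  # characters
                flat = raw[p: p + count].decode("ascii", "replace")
                if len(dims) >= 2:
                    w = dims[0]
                    val = [flat[i * w:(i + 1) * w].strip()
                           for i in range(int(np.prod(dims[1:])))]
                else:
                    val = flat.strip()
            elif dtype == 1:
                val = np.frombuffer(raw, "<i1", count, p)
            elif dtype == 2:
                val = np.frombuffer(raw, "<i2", count, p)
            elif dtype == 4:
                val = np.frombuffer(raw, "<f4", count, p)
            else:
                raise ValueError(f"{path}: bad parameter type {dtype}")
            values.setdefault(group_id, {})[name.upper()] = (
                val if isinstance(val, (str, list)) else
                (val[0] if count == 1 and not dims else np.asarray(val)))
        if next_off == 0:
            break
        pos = next_pos
    return {group_names.get(gid, str(gid)): pv for gid, pv in values.items()}


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _param_record(name: bytes, group_id: int, dtype: int,
                  dims: list[int], data: bytes) -> bytes:
    body = struct.pack("<bB", dtype, len(dims)) + bytes(dims) + data + b"\x00"
    rec = struct.pack("<bb", len(name), group_id) + name
    rec += struct.pack("<h", 2 + len(body)) + body
    return rec


def write_c3d(path: Path, labels: list[str], points: np.ndarray,
              residuals: np.ndarray, rate: float) -> None:
    """Write marker trajectories as a float-format Intel C3D file."""
    points = np.asarray(points, float)
    n_frames, n_points, _ = points.shape
    if residuals.shape != (n_frames, n_points):
        raise ValueError("residuals shape mismatch")
    if n_frames > 65535:
        raise ValueError("C3D writer limited to 65535 frames")

    label_w = max(4, max((len(s) for s in labels), default=4))
    label_blob = b"".join(s.ljust(label_w).encode("ascii") for s in labels)

    recs = b""
    recs += struct.pack("<bb", 5, -1) + b"POINT" + struct.pack("<h", 3) + b"\x00"
    recs += _param_record(b"USED", 1, 2, [], struct.pack("<h", n_points))
    recs += _param_record(b"FRAMES", 1, 2, [], struct.pack("<H", n_frames))
    recs += _param_record(b"RATE", 1, 4, [], struct.pack("<f", rate))
    recs += _param_record(b"SCALE", 1, 4, [], struct.pack("<f", -1.0))
    recs += _param_record(b"LABELS", 1, -1, [label_w, n_points], label_blob)

    # DATA_START depends on the parameter section length; reserve its record.
    ds_rec_len = len(_param_record(b"DATA_START", 1, 2, [],
                                   struct.pack("<h", 0)))
    n_param_blocks = -(-(4 + len(recs) + ds_rec_len + 2) // _BLOCK)
    data_block = 2 + n_param_blocks  # header is block 1
    recs += _param_record(b"DATA_START", 1, 2, [],
                          struct.pack("<h", data_block))
    recs += struct.pack("<bb", 0, 0)  # terminator

    params = struct.pack("<BBBB", 1, 0x50, n_param_blocks, _PROC_INTEL) + recs
    params = params.ljust(n_param_blocks * _BLOCK, b"\x00")

    header = bytearray(_BLOCK)
    header[0] = 2          # first parameter block
    header[1] = 0x50
    struct.pack_into("<4H", header, 2, n_points, 0, 1, n_frames)
    struct.pack_into("<H", header, 10, 10)           # max gap
    struct.pack_into("<f", header, 12, -1.0)         # float data
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<H", header, 18, 1)            # analog samples/frame
    struct.pack_into("<f", header, 20, rate)

    frame_data = np.zeros((n_frames, n_points, 4), dtype="<f4")
    frame_data[:, :, :3] = points
    frame_data[:, :, 3] = residuals
    blob = frame_data.tobytes()
    pad = (-len(blob)) % _BLOCK
    Path(path).write_bytes(bytes(header) + params + blob + b"\x00" * pad)
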