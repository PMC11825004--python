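"""Minimal uncompressed RIFF/AVI container support.

Only the plain-DIB flavour of AVI is handled: 8-bit palettized
grayscale or 24-bit BGR frames stored bottom-up with rows padded to
4-byte boundaries (``biCompression == BI_RGB``).  That is the flavour a
lab camera or ImageJ exports when asked for an uncompressed AVI, and it
is all the analysis pipeline needs; compressed codecs are rejected with
a clear error rather than mis-decoded.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import MediaError

__all__ = ["read_avi", "write_avi"]

_AVIF_HASINDEX = 0x00000010


def _pad4(n: int) -> int:
    return (n + 3) & ~3


def write_avi(path, frames: np.ndarray, fps: float) -> None:
    """Write ``frames`` (T, H, W) uint8 as an uncompressed grayscale AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise MediaError(f"write_avi expects (T, H, W) frames, got {frames.shape}")
    if frames.dtype != np.uint8:
        raise MediaError("write_avi only writes 8-bit frames")
    n, h, w = frames.shape
    stride = _pad4(w)
    frame_bytes = stride * h

    # bottom-up rows, padded to 4-byte multiples
    padded = np.zeros((n, h, stride), dtype=np.uint8)
    padded[:, :, :w] = frames[:, ::-1, :]

    usec_per_frame = int(round(1_000_000 / fps))
    rate, scale = int(round(fps * 1000)), 1000

    avih = struct.pack(
        "<14I", usec_per_frame, frame_bytes * int(round(fps)), 0,
        _AVIF_HASINDEX, n, 0, 1, frame_bytes, w, h, 0, 0, 0, 0)
    strh = struct.pack(
        "<4s4sI2H8I4h", b"vids", b"DIB ", 0, 0, 0, 0, scale, rate, 0, n,
        frame_bytes, 0xFFFFFFFF & -1, 0, 0, 0, w, h)
    bih = struct.pack("<I2i2H2I2i2I", 40, w, h, 1, 8, 0, frame_bytes,
                      0, 0, 256, 0)
    palette = bytes(b for v in range(256) for b in (v, v, v, 0))
    strf = bih + palette

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def list_chunk(kind: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", kind + payload)

    strl = list_chunk(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = list_chunk(b"hdrl", chunk(b"avih", avih) + strl)

    movi_payload = b"".join(chunk(b"00db", padded[i].tobytes())
                            for i in range(n))
    movi = list_chunk(b"movi", movi_payload)

    # idx1 offsets are relative to the start of the 'movi' fourcc data
    idx_entries = []
    offset = 4
    for _ in range(n):
        idx_entries.append(struct.pack("<4s3I", b"00db", 0x10, offset,
                                       frame_bytes))
        offset += 8 + frame_bytes + (frame_bytes % 2)
    idx1 = chunk(b"idx1", b"".join(idx_entries))

    body = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos:pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path) -> tuple[np.ndarray, float]:
    """Read an uncompressed AVI; returns (frames (T,H,W[,3]) uint8, fps)."""
    path = Path(path)
    try:
        buf = path.read_bytes()
    except OSError as exc:
        raise MediaError(f"cannot read AVI file {path}: {exc}") from exc
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise MediaError(f"{path} is not an AVI (RIFF) file")

    fps = 0.0
    width = height = bitcount = None
    compression = 0
    frames_raw: list[bytes] = []

    def walk(start: int, end: int) -> None:
        nonlocal fps, width, height, bitcount, compression
        for fourcc, data_start, size in _iter_chunks(buf, start, end):
            data_end = data_start + size
            if fourcc == b"LIST":
                walk(data_start + 4, data_end)
            elif fourcc == b"avih" and size >= 40:
                vals = struct.unpack_from("<10I", buf, data_start)
                if vals[0] > 0:
                    fps = 1_000_000 / vals[0]
            elif fourcc == b"strh" and size >= 48:
                if buf[data_start:data_start + 4] == b"vids":
                    scale, rate = struct.unpack_from("<2I", buf, data_start + 20)
                    if scale > 0 and rate > 0:
                        fps = rate / scale
            elif fourcc == b"strf" and size >= 40:
                (_, w, h, _, bc, comp) = struct.unpack_from(
                    "<I2i2HI", buf, data_start)
                width, height, bitcount, compression = w, abs(h), bc, comp
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frames_raw.append(buf[data_start:data_end])

    walk(12, len(buf))

    if width is None or not frames_raw:
        raise MediaError(f"{path}: no decodable video stream found")
    if compression != 0:
        raise MediaError(
            f"{path}: compressed AVI (fourcc {compression:#x}) is not "
            "supported; re-export as uncompressed or TIFF")
    if bitcount not in (8, 24):
        raise MediaError(f"{path}: unsupported bit depth {bitcount}")

    bypp = bitcount // 8
    stride = _pad4(width * bypp)
    out = []
    for raw in frames_raw:
        if len(raw) < stride * height:
            raise MediaError(f"{path}: truncated frame data")
        arr = np.frombuffer(raw[:stride * height], dtype=np.uint8)
        arr = arr.reshape(height, stride)[::-1, :width * bypp]
        if bypp == 3:
            arr = arr.reshape(height, width, 3)[:, :, ::-1]  # BGR -> RGB
        out.append(arr)
    return np.stack(out), float(fps)
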