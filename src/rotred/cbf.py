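"""Byte-offset CBF images.

Rotation frames and per-pixel lookup tables are exchanged on disk as the
byte-offset variant of the CBF format: a short ASCII header followed by a
binary section in which each pixel stores the difference to the previous
pixel, using 1 byte when the delta fits a signed byte, escaping to 2 bytes
(marker ``0x80``) and to 4 bytes (marker ``0x8000``) otherwise.  Values may
be negative; the ``-3`` untrusted-pixel sentinel must survive a round trip
bit-exactly.

Only the binary section plus a minimal key/value header are implemented;
the full imgCIF grammar is out of scope.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CbfImage", "CbfFormatError", "read_cbf", "write_cbf"]

_MAGIC = b"###CBF: rotred byte-offset image\r\n"
_BINARY_MARKER = b"\x0c\x1a\x04\xd5"
_SECTION = b"--CIF-BINARY-FORMAT-SECTION--"


class CbfFormatError(ValueError):
    """Raised when a CBF stream is truncated or malformed."""


@dataclass
class CbfImage:
    """A 2D integer image: ``counts[slow, fast]`` plus free-form header text."""

    counts: np.ndarray
    header: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("CbfImage requires a 2D array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("CbfImage stores integer counts")
        self.counts = self.counts.astype(np.int32, copy=False)

    @property
    def dims(self) -> tuple[int, int]:
        """(slow, fast) pixel counts."""
        return self.counts.shape  # type: ignore[return-value]


def encode_byte_offset(values: np.ndarray) -> bytes:
    """Delta-encode a flat int32 array with the 1/2/4-byte escape scheme.

    The all-small-delta path (flat background regions, lookup tables) is
    fully vectorized; only escape tokens are emitted one by one.
    """
    values = np.asarray(values, dtype=np.int64).ravel()
    deltas = np.diff(values, prepend=np.int64(0))
    small = (deltas >= -127) & (deltas <= 127)
    if small.all():
        return deltas.astype(np.int8).tobytes()
    medium = ~small & (deltas >= -32767) & (deltas <= 32767)
    sizes = np.where(small, 1, np.where(medium, 3, 7))
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    out = np.zeros(offsets[-1], dtype=np.uint8)
    out[offsets[:-1][small]] = deltas[small].astype(np.int8).view(np.uint8)
    for idx in np.nonzero(~small)[0]:
        d = int(deltas[idx])
        pos = int(offsets[idx])
        if medium[idx]:
            out[pos] = 0x80
            out[pos + 1 : pos + 3] = np.frombuffer(struct.pack("<h", d), np.uint8)
        else:
            out[pos : pos + 3] = (0x80, 0x00, 0x80)
            out[pos + 3 : pos + 7] = np.frombuffer(struct.pack("<i", d), np.uint8)
    return out.tobytes()


def decode_byte_offset(data: bytes, n_values: int) -> np.ndarray:
    """Decode ``n_values`` int32 pixels from a byte-offset stream.

    Runs of 1-byte deltas between escape markers are copied in bulk; the
    Python loop advances one escape token at a time.
    """
    raw = np.frombuffer(data, dtype=np.uint8)
    deltas = np.empty(n_values, dtype=np.int64)
    marker_pos = np.nonzero(raw == 0x80)[0]
    pos = 0  # byte offset in raw
    i = 0  # next delta index
    n = len(raw)
    while i < n_values:
        j = np.searchsorted(marker_pos, pos)
        nxt = int(marker_pos[j]) if j < len(marker_pos) else n
        run = min(nxt - pos, n_values - i)
        if run > 0:
            deltas[i : i + run] = raw[pos : pos + run].view(np.int8)
            pos += run
            i += run
            if i >= n_values:
                break
        if pos >= n:
            raise CbfFormatError(f"truncated byte-offset stream at byte {pos}")
        # an escape token starts here
        if pos + 3 > n:
            raise CbfFormatError(f"truncated escape at byte {pos}")
        short = struct.unpack_from("<h", data, pos + 1)[0]
        if short != -32768:
            deltas[i] = short
            pos += 3
        else:
            if pos + 7 > n:
                raise CbfFormatError(f"truncated 4-byte escape at byte {pos}")
            deltas[i] = struct.unpack_from("<i", data, pos + 3)[0]
            pos += 7
        i += 1
    values = np.cumsum(deltas)
    out = values.astype(np.int32)
    if not (out == values).all():
        raise CbfFormatError("decoded values overflow 32-bit signed range")
    return out


def write_cbf(image: CbfImage | np.ndarray, path) -> None:
    """Write an image as a minimal byte-offset CBF file."""
    if not isinstance(image, CbfImage):
        image = CbfImage(np.asarray(image))
    slow, fast = image.dims
    payload = encode_byte_offset(image.counts)
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        for key, value in image.header.items():
            fh.write(f"# {key}: {value}\r\n".encode())
        fh.write(b"\r\n" + _SECTION + b"\r\n")
        fh.write(b"Content-Type: application/octet-stream;\r\n")
        fh.write(b'     conversions="x-CBF_BYTE_OFFSET"\r\n')
        fh.write(b"Content-Transfer-Encoding: BINARY\r\n")
        fh.write(f"X-Binary-Size: {len(payload)}\r\n".encode())
        fh.write(b"X-Binary-Element-Type: \"signed 32-bit integer\"\r\n")
        fh.write(f"X-Binary-Size-Fastest-Dimension: {fast}\r\n".encode())
        fh.write(f"X-Binary-Size-Second-Dimension: {slow}\r\n".encode())
        fh.write(b"\r\n")
        fh.write(_BINARY_MARKER)
        fh.write(payload)
        fh.write(b"\r\n" + _SECTION + b"---\r\n")


def read_cbf(path) -> CbfImage:
    """Read a byte-offset CBF file written by :func:`write_cbf`."""
    with open(path, "rb") as fh:
        raw = fh.read()
    marker_pos = raw.find(_BINARY_MARKER)
    if marker_pos < 0:
        raise CbfFormatError("no binary marker found")
    text = raw[:marker_pos].decode("latin-1")
    header: dict[str, str] = {}
    fast = slow = size = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("# ") and ": " in line:
            key, value = line[2:].split(": ", 1)
            header[key] = value
        elif line.startswith("X-Binary-Size-Fastest-Dimension:"):
            fast = int(line.split(":")[1])
        elif line.startswith("X-Binary-Size-Second-Dimension:"):
            slow = int(line.split(":")[1])
        elif line.startswith("X-Binary-Size:"):
            size = int(line.split(":")[1])
    if fast is None or slow is None or size is None:
        raise CbfFormatError("missing X-Binary-Size / dimension fields")
    start = marker_pos + len(_BINARY_MARKER)
    payload = raw[start : start + size]
    if len(payload) < size:
        raise CbfFormatError(
            f"binary section truncated: expected {size} bytes, found {len(payload)}"
        )
    counts = decode_byte_offset(payload, slow * fast).reshape(slow, fast)
    return CbfImage(counts, header)
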