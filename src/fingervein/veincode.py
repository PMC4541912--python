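"""LBP vein-code extraction and normalized Hamming-distance matching.

Each interior pixel of the 50x20 working image yields an 8-bit local binary
pattern: bit k is 1 when the k-th 8-connected neighbor is at least as bright
as the center (ties count as 1). Neighbors are enumerated clockwise from the
top-left. The 18 x 48 interior centers concatenated in row-major order give
a 6912-bit binary code; two codes are compared by the normalized Hamming
distance, popcount(a XOR b) / 6912, which is 0 for identical codes and 0.5
for unrelated ones in expectation.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ContractError, ValidationError

CODE_ROWS = 18
CODE_COLS = 48
BITS_PER_CENTER = 8
CODE_LENGTH = CODE_ROWS * CODE_COLS * BITS_PER_CENTER  # 6912

#: 8-connected neighbor offsets (dy, dx), clockwise from top-left.
NEIGHBOR_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))

_MAGIC = b"FVC1"
_HEADER = struct.Struct("<4sHHHH4x")  # magic, version, rows, cols, bits; 16 bytes


@dataclass(frozen=True)
class MatchScore:
    """Normalized Hamming distance between two codes, in [0, 1]."""

    hd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.hd <= 1.0:
            raise ValidationError(f"hd must lie in [0, 1], got {self.hd}")


class VeinCode:
    """A 6912-bit finger-vein code (18 rows x 48 cols x 8 neighbor bits)."""

    __slots__ = ("bits",)

    def __init__(self, bits: np.ndarray):
        arr = np.asarray(bits, dtype=bool).ravel()
        if arr.size != CODE_LENGTH:
            raise ContractError(f"code must have {CODE_LENGTH} bits, got {arr.size}")
        self.bits = arr

    def __eq__(self, other: object) -> bool:
        return isinstance(other, VeinCode) and bool(np.array_equal(self.bits, other.bits))

    def __len__(self) -> int:
        return CODE_LENGTH

    def patterns(self) -> np.ndarray:
        """Per-center 8-bit pattern values as an 18x48 uint8 grid."""
        b = self.bits.reshape(CODE_ROWS, CODE_COLS, BITS_PER_CENTER)
        weights = (1 << np.arange(BITS_PER_CENTER)).astype(np.uint16)
        return (b * weights).sum(axis=2).astype(np.uint8)

    def packed(self) -> bytes:
        """Bits packed MSB-first within each 8-bit pattern (bit k=7 first)."""
        per_center = self.bits.reshape(-1, BITS_PER_CENTER)[:, ::-1]
        return np.packbits(per_center.ravel()).tobytes()

    def to_bytes(self) -> bytes:
        header = _HEADER.pack(_MAGIC, 1, CODE_ROWS, CODE_COLS, BITS_PER_CENTER)
        return header + self.packed()

    @classmethod
    def from_bytes(cls, blob: bytes) -> "VeinCode":
        if len(blob) < _HEADER.size:
            raise ValidationError("vein-code blob shorter than its 16-byte header")
        magic, version, rows, cols, bits = _HEADER.unpack(blob[: _HEADER.size])
        if magic != _MAGIC:
            raise ValidationError(f"bad vein-code magic {magic!r}")
        if (version, rows, cols, bits) != (1, CODE_ROWS, CODE_COLS, BITS_PER_CENTER):
            raise ValidationError(f"unsupported vein-code layout {(version, rows, cols, bits)}")
        payload = np.frombuffer(blob, dtype=np.uint8, offset=_HEADER.size)
        if payload.size != CODE_LENGTH // 8:
            raise ValidationError("vein-code payload has the wrong length")
        unpacked = np.unpackbits(payload).reshape(-1, BITS_PER_CENTER)[:, ::-1]
        return cls(unpacked.ravel())

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(self.to_bytes())

    @classmethod
    def load(cls, path: str | Path) -> "VeinCode":
        return cls.from_bytes(Path(path).read_bytes())

    def to_hex(self) -> str:
        """Hex-string export of the packed code, for debugging."""
        return self.packed().hex()

    @classmethod
    def from_hex(cls, text: str) -> "VeinCode":
        payload = bytes.fromhex(text.strip())
        return cls.from_bytes(_HEADER.pack(_MAGIC, 1, CODE_ROWS, CODE_COLS, BITS_PER_CENTER) + payload)


def _check_subsampled(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.shape != (20, 50):
        raise ContractError(f"expected a 20x50 image, got {img.shape}")
    return img


def lbp_bits_at(image: np.ndarray, center: tuple[int, int]) -> int:
    """8-bit LBP pattern at an interior center (row in [1,19), col in [1,49)).

    Bit k is 1 when neighbor k (clockwise from top-left) minus the center is
    >= 0; the value returned is sum_k bit_k * 2^k.
    """
    img = _check_subsampled(image)
    row, col = center
    if not (1 <= row < img.shape[0] - 1 and 1 <= col < img.shape[1] - 1):
        raise ContractError(f"center {center} is not interior to the 20x50 grid")
    c = img[row, col]
    value = 0
    for k, (dy, dx) in enumerate(NEIGHBOR_OFFSETS):
        if img[row + dy, col + dx] - c >= 0:
            value |= 1 << k
    return value


def extract_code(image: np.ndarray) -> VeinCode:
    """Extract the 6912-bit code from a 20x50 (enhanced) working image.

    Concatenates the 8-bit patterns of all 18x48 interior centers in
    row-major order, bit k ascending within each center.
    """
    img = _check_subsampled(image)
    center = img[1:-1, 1:-1]
    bits = np.empty((CODE_ROWS, CODE_COLS, BITS_PER_CENTER), dtype=bool)
    for k, (dy, dx) in enumerate(NEIGHBOR_OFFSETS):
        neighbor = img[1 + dy : 19 + dy, 1 + dx : 49 + dx]
        bits[:, :, k] = (neighbor - center) >= 0
    return VeinCode(bits.ravel())


def hamming(code_a: VeinCode, code_b: VeinCode) -> MatchScore:
    """Normalized Hamming distance: popcount(a XOR b) / 6912."""
    if len(code_a.bits) != len(code_b.bits):
        raise ContractError("codes must have equal length")
    differing = int(np.count_nonzero(code_a.bits != code_b.bits))
    return MatchScore(differing / CODE_LENGTH)


def stack_codes(codes: list[VeinCode]) -> np.ndarray:
    """Stack codes into an (n, 6912) boolean matrix for bulk matching."""
    return np.stack([c.bits for c in codes])


def pairwise_hamming(bits: np.ndarray) -> np.ndarray:
    """All-pairs normalized Hamming distances of an (n, 6912) bit matrix."""
    b = np.asarray(bits, dtype=bool)
    if b.ndim != 2:
        raise ContractError("bits must be a 2-D (n, code_length) matrix")
    packed = np.packbits(b, axis=1)
    # popcount of XOR in row blocks keeps memory bounded for large n
    n = packed.shape[0]
    out = np.zeros((n, n), dtype=np.float64)
    block = max(1, 16_000_000 // max(1, n * packed.shape[1]))
    for start in range(0, n, block):
        stop = min(n, start + block)
        xor = packed[start:stop, None, :] ^ packed[None, :, :]
        out[start:stop] = np.bitwise_count(xor).sum(axis=2)
    return out / b.shape[1]


def hamming_to_set(code_bits: np.ndarray, bits: np.ndarray) -> np.ndarray:
    """Normalized Hamming distances from one code to each row of ``bits``."""
    a = np.packbits(np.asarray(code_bits, dtype=bool))
    b = np.packbits(np.asarray(bits, dtype=bool), axis=1)
    return np.bitwise_count(a[None, :] ^ b).sum(axis=1) / np.asarray(code_bits).size
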