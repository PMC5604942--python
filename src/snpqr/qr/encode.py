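"""QR model-2 encoder: byte mode, automatic version, all masks, PNG output."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

from .galois import rs_encode
from .tables import (
    EC_BLOCKS,
    EC_LEVEL_BITS,
    build_function_mask,
    data_capacity,
    matrix_size,
    remainder_bits,
)

__all__ = ["QRCapacityError", "make_qr_matrix", "write_qr_png", "encode_to_png"]

_PAD_BYTES = (0xEC, 0x11)

_MASK_FUNCS = (
    lambda r, c: (r + c) % 2 == 0,
    lambda r, c: r % 2 == 0,
    lambda r, c: c % 3 == 0,
    lambda r, c: (r + c) % 3 == 0,
    lambda r, c: (r // 2 + c // 3) % 2 == 0,
    lambda r, c: (r * c) % 2 + (r * c) % 3 == 0,
    lambda r, c: ((r * c) % 2 + (r * c) % 3) % 2 == 0,
    lambda r, c: ((r + c) % 2 + (r * c) % 3) % 2 == 0,
)


class QRCapacityError(ValueError):
    """Payload too large for any version at the requested EC level."""


def _bch_format_bits(ec_level: str, mask_id: int) -> int:
    """15-bit format information: 5 data bits + 10 BCH bits, masked."""
    data = (EC_LEVEL_BITS[ec_level] << 3) | mask_id
    rem = data << 10
    gen = 0b10100110111
    for shift in range(14, 9, -1):
        if rem & (1 << shift):
            rem ^= gen << (shift - 10)
    return ((data << 10) | rem) ^ 0b101010000010010


def _bch_version_bits(version: int) -> int:
    """18-bit version information for versions >= 7."""
    rem = version << 12
    gen = 0b1111100100101
    for shift in range(17, 11, -1):
        if rem & (1 << shift):
            rem ^= gen << (shift - 12)
    return (version << 12) | rem


def _byte_mode_bitstream(payload: bytes, version: int, ec_level: str) -> List[int]:
    capacity_bits = data_capacity(version, ec_level) * 8
    count_bits = 8 if version <= 9 else 16
    bits: List[int] = []

    def push(value: int, n: int):
        for i in range(n - 1, -1, -1):
            bits.append((value >> i) & 1)

    push(0b0100, 4)  # byte mode
    push(len(payload), count_bits)
    for b in payload:
        push(b, 8)
    if len(bits) > capacity_bits:
        raise QRCapacityError("payload exceeds capacity")
    push(0, min(4, capacity_bits - len(bits)))  # terminator
    while len(bits) % 8:
        bits.append(0)
    codewords = [
        int("".join(map(str, bits[i : i + 8])), 2) for i in range(0, len(bits), 8)
    ]
    i = 0
    while len(codewords) < capacity_bits // 8:
        codewords.append(_PAD_BYTES[i % 2])
        i += 1
    return codewords


def _select_version(payload: bytes, ec_level: str) -> int:
    for version in range(1, 41):
        count_bits = 8 if version <= 9 else 16
        needed_bits = 4 + count_bits + 8 * len(payload)
        if needed_bits <= data_capacity(version, ec_level) * 8:
            return version
    raise QRCapacityError(
        f"payload of {len(payload)} bytes exceeds QR capacity at level {ec_level}"
    )


def _interleave(codewords: Sequence[int], version: int, ec_level: str) -> List[int]:
    ec_per_block, groups = EC_BLOCKS[version][ec_level]
    blocks: List[List[int]] = []
    offset = 0
    for n_blocks, k in groups:
        for _ in range(n_blocks):
            blocks.append(list(codewords[offset : offset + k]))
            offset += k
    ec_blocks = [rs_encode(block, ec_per_block) for block in blocks]

    out: List[int] = []
    for i in range(max(len(b) for b in blocks)):
        for block in blocks:
            if i < len(block):
                out.append(block[i])
    for i in range(ec_per_block):
        for block in ec_blocks:
            out.append(block[i])
    return out


def _place_fixed_patterns(matrix: List[List[int]], version: int) -> None:
    size = matrix_size(version)

    def finder(r0: int, c0: int):
        for r in range(-1, 8):
            for c in range(-1, 8):
                rr, cc = r0 + r, c0 + c
                if not (0 <= rr < size and 0 <= cc < size):
                    continue
                inside = 0 <= r <= 6 and 0 <= c <= 6
                dark = inside and (
                    r in (0, 6) or c in (0, 6) or (2 <= r <= 4 and 2 <= c <= 4)
                )
                matrix[rr][cc] = 1 if dark else 0

    finder(0, 0)
    finder(0, size - 7)
    finder(size - 7, 0)
    for i in range(8, size - 8):
        matrix[6][i] = matrix[i][6] = 1 if i % 2 == 0 else 0
    from .tables import ALIGNMENT_POSITIONS

    centres = ALIGNMENT_POSITIONS[version]
    for r0 in centres:
        for c0 in centres:
            if (r0 < 9 and c0 < 9) or (r0 < 9 and c0 > size - 10) or (r0 > size - 10 and c0 < 9):
                continue
            for r in range(-2, 3):
                for c in range(-2, 3):
                    dark = max(abs(r), abs(c)) != 1
                    matrix[r0 + r][c0 + c] = 1 if dark else 0
    matrix[size - 8][8] = 1  # dark module


def _place_format_bits(matrix: List[List[int]], version: int, fmt: int) -> None:
    size = matrix_size(version)
    bits = [(fmt >> i) & 1 for i in range(14, -1, -1)]  # MSB first
    # Copy 1, around the top-left finder.
    coords1 = (
        [(8, c) for c in range(6)] + [(8, 7), (8, 8), (7, 8)] + [(r, 8) for r in range(5, -1, -1)]
    )
    # Copy 2, split between the other two finders.
    coords2 = [(size - 1 - i, 8) for i in range(7)] + [
        (8, size - 8 + i) for i in range(8)
    ]
    for (r, c), b in zip(coords1, bits):
        matrix[r][c] = b
    for (r, c), b in zip(coords2, bits):
        matrix[r][c] = b


def _place_version_bits(matrix: List[List[int]], version: int) -> None:
    if version < 7:
        return
    size = matrix_size(version)
    vbits = _bch_version_bits(version)
    for i in range(18):
        b = (vbits >> i) & 1
        matrix[i // 3][size - 11 + i % 3] = b
        matrix[size - 11 + i % 3][i // 3] = b


def _data_module_order(version: int) -> List[Tuple[int, int]]:
    """Zigzag placement order of data modules (bottom-right, column pairs)."""
    size = matrix_size(version)
    func = build_function_mask(version)
    order: List[Tuple[int, int]] = []
    col = size - 1
    upward = True
    while col > 0:
        if col == 6:  # skip the vertical timing column entirely
            col -= 1
        rows = range(size - 1, -1, -1) if upward else range(size)
        for r in rows:
            for c in (col, col - 1):
                if not func[r][c]:
                    order.append((r, c))
        upward = not upward
        col -= 2
    return order


def _penalty(matrix: List[List[int]]) -> int:
    size = len(matrix)
    score = 0
    # Rule 1: runs of length >= 5 in rows and columns.
    for axis in range(2):
        for i in range(size):
            run_val, run_len = -1, 0
            for j in range(size):
                v = matrix[i][j] if axis == 0 else matrix[j][i]
                if v == run_val:
                    run_len += 1
                else:
                    if run_len >= 5:
                        score += 3 + (run_len - 5)
                    run_val, run_len = v, 1
            if run_len >= 5:
                score += 3 + (run_len - 5)
    # Rule 2: 2x2 blocks of one colour.
    for r in range(size - 1):
        for c in range(size - 1):
            if matrix[r][c] == matrix[r][c + 1] == matrix[r + 1][c] == matrix[r + 1][c + 1]:
                score += 3
    # Rule 3: finder-like 1:1:3:1:1 pattern with a 4-module light flank.
    pat1 = [1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0]
    pat2 = pat1[::-1]
    for axis in range(2):
        for i in range(size):
            line = [matrix[i][j] if axis == 0 else matrix[j][i] for j in range(size)]
            for j in range(size - 10):
                window = line[j : j + 11]
                if window == pat1 or window == pat2:
                    score += 40
    # Rule 4: dark-module proportion.
    dark = sum(sum(row) for row in matrix)
    pct = dark * 100 // (size * size)
    score += 10 * (abs(pct - 50) // 5)
    return score


def make_qr_matrix(
    payload: bytes,
    ec_level: str = "M",
    version: Optional[int] = None,
    mask_id: Optional[int] = None,
) -> List[List[int]]:
    """Build the module matrix (1=dark) for a byte-mode QR symbol."""
    if version is None:
        version = _select_version(payload, ec_level)
    size = matrix_size(version)
    codewords = _interleave(_byte_mode_bitstream(payload, version, ec_level), version, ec_level)
    bits: List[int] = []
    for cw in codewords:
        bits.extend((cw >> i) & 1 for i in range(7, -1, -1))
    bits.extend([0] * remainder_bits(version))

    order = _data_module_order(version)
    if len(bits) != len(order):
        raise AssertionError("bitstream does not fill the data region")

    candidates = range(8) if mask_id is None else (mask_id,)
    best: Optional[List[List[int]]] = None
    best_score = None
    for m in candidates:
        matrix = [[0] * size for _ in range(size)]
        _place_fixed_patterns(matrix, version)
        _place_version_bits(matrix, version)
        _place_format_bits(matrix, version, _bch_format_bits(ec_level, m))
        mf = _MASK_FUNCS[m]
        for (r, c), bit in zip(order, bits):
            matrix[r][c] = bit ^ (1 if mf(r, c) else 0)
        score = _penalty(matrix)
        if best_score is None or score < best_score:
            best, best_score = matrix, score
    assert best is not None
    return best


def write_qr_png(matrix: Sequence[Sequence[int]], path, scale: int = 8, border: int = 4) -> None:
    """Render a module matrix as a black/white PNG with a quiet zone."""
    from PIL import Image

    size = len(matrix)
    dim = (size + 2 * border) * scale
    img = Image.new("L", (dim, dim), 255)
    px = img.load()
    for r in range(size):
        for c in range(size):
            if matrix[r][c]:
                for dr in range(scale):
                    for dc in range(scale):
                        px[(c + border) * scale + dc, (r + border) * scale + dr] = 0
    img.save(path, format="PNG")


def encode_to_png(text: str, path, ec_level: str = "M", scale: int = 8) -> None:
    """Encode ``text`` (ISO-8859-1) as a QR symbol and write a PNG."""
    payload = text.encode("latin-1")
    matrix = make_qr_matrix(payload, ec_level=ec_level)
    write_qr_png(matrix, path, scale=scale)
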