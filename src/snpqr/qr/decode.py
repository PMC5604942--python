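"""QR decoder for clean, axis-aligned symbol images.

Locates the symbol by its dark bounding box, infers the module pitch from
the top-left finder pattern, samples module centres, reads the format
information (error-tolerant match over all 32 valid format words), unmasks,
de-interleaves and Reed-Solomon-corrects the codewords, and parses the
byte-mode bitstream.  This is an independent read path — none of the
encoder's intermediate state is reused — so encoder/decoder agreement is a
genuine round-trip check.
"""

from __future__ import annotations

from typing import List, Tuple

from .encode import _MASK_FUNCS, _bch_format_bits, _data_module_order
from .galois import RSDecodeError, rs_decode
from .tables import EC_BLOCKS, EC_LEVELS, build_function_mask

__all__ = ["QRDecodeError", "decode_matrix", "decode_png"]


class QRDecodeError(ValueError):
    """No single decodable QR symbol was found in the image."""


def _binarize(image) -> List[List[int]]:
    gray = image.convert("L")
    w, h = gray.size
    px = gray.load()
    return [[1 if px[x, y] < 128 else 0 for x in range(w)] for y in range(h)]


def _locate_symbol(bits: List[List[int]]) -> Tuple[int, int, float, int]:
    """Return (top, left, module_px, n_modules) of the symbol grid."""
    h, w = len(bits), len(bits[0]) if bits else 0
    rows = [y for y in range(h) if any(bits[y])]
    if not rows:
        raise QRDecodeError("no dark pixels: image contains no QR symbol")
    top, bottom = rows[0], rows[-1]
    cols = [x for x in range(w) if any(bits[y][x] for y in range(top, bottom + 1))]
    left, right = cols[0], cols[-1]
    bw, bh = right - left + 1, bottom - top + 1
    if abs(bw - bh) > max(3, 0.05 * max(bw, bh)):
        raise QRDecodeError("dark region is not square: not a single QR symbol")
    # The first row of the top-left finder is 7 dark modules wide.
    run = 0
    x = left
    while x <= right and bits[top][x]:
        run += 1
        x += 1
    module = run / 7.0
    if module < 1:
        raise QRDecodeError("cannot establish module pitch")
    n_modules = round(bw / module)
    if n_modules < 21 or n_modules > 177 or (n_modules - 17) % 4:
        raise QRDecodeError(f"implausible symbol size of {n_modules} modules")
    return top, left, module, n_modules


def _sample_matrix(bits: List[List[int]], top: int, left: int, module: float, n: int) -> List[List[int]]:
    out = []
    for r in range(n):
        row = []
        y = int(top + (r + 0.5) * module)
        for c in range(n):
            x = int(left + (c + 0.5) * module)
            row.append(bits[y][x])
        out.append(row)
    return out


_FINDER = [
    [1, 1, 1, 1, 1, 1, 1],
    [1, 0, 0, 0, 0, 0, 1],
    [1, 0, 1, 1, 1, 0, 1],
    [1, 0, 1, 1, 1, 0, 1],
    [1, 0, 1, 1, 1, 0, 1],
    [1, 0, 0, 0, 0, 0, 1],
    [1, 1, 1, 1, 1, 1, 1],
]


def _check_finders(m: List[List[int]]) -> None:
    n = len(m)
    for r0, c0 in ((0, 0), (0, n - 7), (n - 7, 0)):
        bad = sum(
            1
            for r in range(7)
            for c in range(7)
            if m[r0 + r][c0 + c] != _FINDER[r][c]
        )
        if bad > 5:  # tolerate a few sampling errors
            raise QRDecodeError("finder pattern missing: not a QR symbol")


def _read_format(m: List[List[int]]) -> Tuple[str, int]:
    n = len(m)
    coords1 = (
        [(8, c) for c in range(6)] + [(8, 7), (8, 8), (7, 8)] + [(r, 8) for r in range(5, -1, -1)]
    )
    coords2 = [(n - 1 - i, 8) for i in range(7)] + [(8, n - 8 + i) for i in range(8)]
    best = None
    for coords in (coords1, coords2):
        observed = 0
        for r, c in coords:
            observed = (observed << 1) | m[r][c]
        for level in EC_LEVELS:
            for mask_id in range(8):
                expected = _bch_format_bits(level, mask_id)
                dist = bin(observed ^ expected).count("1")
                if best is None or dist < best[0]:
                    best = (dist, level, mask_id)
    assert best is not None
    if best[0] > 3:  # BCH(15,5) corrects up to 3 bit errors
        raise QRDecodeError("format information unreadable")
    return best[1], best[2]


def decode_matrix(m: List[List[int]]) -> str:
    n = len(m)
    version = (n - 17) // 4
    if n != 17 + 4 * version or not 1 <= version <= 40:
        raise QRDecodeError(f"invalid matrix size {n}")
    _check_finders(m)
    level, mask_id = _read_format(m)
    mf = _MASK_FUNCS[mask_id]

    order = _data_module_order(version)
    bits = [m[r][c] ^ (1 if mf(r, c) else 0) for r, c in order]
    n_codewords = len(bits) // 8
    codewords = [
        int("".join(map(str, bits[i * 8 : i * 8 + 8])), 2) for i in range(n_codewords)
    ]

    # De-interleave into blocks.
    ec_per_block, groups = EC_BLOCKS[version][level]
    block_sizes = [k for n_blocks, k in groups for _ in range(n_blocks)]
    blocks: List[List[int]] = [[] for _ in block_sizes]
    it = iter(codewords)
    for i in range(max(block_sizes)):
        for b, k in enumerate(block_sizes):
            if i < k:
                blocks[b].append(next(it))
    ec_blocks: List[List[int]] = [[] for _ in block_sizes]
    for i in range(ec_per_block):
        for b in range(len(block_sizes)):
            ec_blocks[b].append(next(it))

    data: List[int] = []
    for block, ec in zip(blocks, ec_blocks):
        try:
            data.extend(rs_decode(block + ec, ec_per_block))
        except RSDecodeError as exc:
            raise QRDecodeError(f"error correction failed: {exc}") from exc

    # Parse byte-mode segments.
    stream = 0
    for byte in data:
        stream = (stream << 8) | byte
    total_bits = len(data) * 8
    pos = 0

    def take(k: int) -> int:
        nonlocal pos
        value = (stream >> (total_bits - pos - k)) & ((1 << k) - 1)
        pos += k
        return value

    out = bytearray()
    while pos + 4 <= total_bits:
        mode = take(4)
        if mode == 0b0000:  # terminator
            break
        if mode != 0b0100:
            raise QRDecodeError(f"unsupported mode indicator {mode:04b}")
        count_bits = 8 if version <= 9 else 16
        count = take(count_bits)
        if pos + 8 * count > total_bits:
            raise QRDecodeError("truncated byte segment")
        for _ in range(count):
            out.append(take(8))
    return out.decode("latin-1")


def decode_png(path) -> str:
    """Decode the single QR symbol in a PNG image to its text payload."""
    from PIL import Image

    with Image.open(path) as image:
        bits = _binarize(image)
    top, left, module, n = _locate_symbol(bits)
    matrix = _sample_matrix(bits, top, left, module, n)
    return decode_matrix(matrix)
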