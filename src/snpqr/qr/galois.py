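"""GF(256) arithmetic and Reed-Solomon coding for QR symbols.

The field is GF(2^8) with the QR generator polynomial x^8+x^4+x^3+x^2+1
(0x11D) and primitive element 2.  Encoding appends ``nsym`` parity bytes;
decoding corrects up to ``nsym // 2`` byte errors (errors-only
Berlekamp-Massey, Chien search and Forney's formula).
"""

from __future__ import annotations

from typing import List, Sequence

_PRIM = 0x11D

EXP = [0] * 512  # alpha^i, doubled to avoid modulo in mul
LOG = [0] * 256

_x = 1
for _i in range(255):
    EXP[_i] = _x
    LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM
for _i in range(255, 512):
    EXP[_i] = EXP[_i - 255]


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return EXP[LOG[a] + LOG[b]]


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("division by zero in GF(256)")
    if a == 0:
        return 0
    return EXP[LOG[a] - LOG[b] + 255]


def gf_pow(a: int, n: int) -> int:
    return EXP[(LOG[a] * n) % 255]


def gf_inv(a: int) -> int:
    return EXP[255 - LOG[a]]


# -- polynomials: coefficient lists, highest degree first ----------------

def poly_mul(p: Sequence[int], q: Sequence[int]) -> List[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, pc in enumerate(p):
        if pc == 0:
            continue
        for j, qc in enumerate(q):
            out[i + j] ^= gf_mul(pc, qc)
    return out


def poly_eval(p: Sequence[int], x: int) -> int:
    y = 0
    for c in p:
        y = gf_mul(y, x) ^ c
    return y


def rs_generator_poly(nsym: int) -> List[int]:
    g = [1]
    for i in range(nsym):
        g = poly_mul(g, [1, gf_pow(2, i)])
    return g


def rs_encode(data: Sequence[int], nsym: int) -> List[int]:
    """Return the ``nsym`` Reed-Solomon parity bytes for ``data``."""
    gen = rs_generator_poly(nsym)
    rem = list(data) + [0] * nsym
    for i in range(len(data)):
        coef = rem[i]
        if coef == 0:
            continue
        for j in range(1, len(gen)):
            rem[i + j] ^= gf_mul(gen[j], coef)
    return rem[len(data):]


class RSDecodeError(ValueError):
    """The codeword contains more errors than the code can correct."""


def rs_decode(codeword: Sequence[int], nsym: int) -> List[int]:
    """Correct up to nsym//2 byte errors; return the data part.

    ``codeword`` is data followed by parity.  Raises :class:`RSDecodeError`
    when the error count exceeds the correction capacity.
    """
    msg = list(codeword)
    synd = [poly_eval(msg, gf_pow(2, i)) for i in range(nsym)]
    if max(synd) == 0:
        return msg[:-nsym]

    # Berlekamp-Massey: find the error locator polynomial (lowest first here).
    err_loc = [1]
    old_loc = [1]
    for i in range(nsym):
        delta = synd[i]
        for j in range(1, len(err_loc)):
            delta ^= gf_mul(err_loc[-(j + 1)], synd[i - j])
        old_loc.append(0)
        if delta != 0:
            if len(old_loc) > len(err_loc):
                new_loc = [gf_mul(c, delta) for c in old_loc]
                old_loc = [gf_div(c, delta) for c in err_loc]
                err_loc = new_loc
            for j in range(len(old_loc)):
                err_loc[-(j + 1)] ^= gf_mul(delta, old_loc[-(j + 1)])
    while err_loc and err_loc[0] == 0:
        err_loc.pop(0)
    n_errors = len(err_loc) - 1
    if n_errors * 2 > nsym:
        raise RSDecodeError("too many errors to correct")

    # Chien search for error positions: roots of the locator are X_k^{-1}
    # where X_k = alpha^(n-1-pos).
    positions = []
    for pos in range(len(msg)):
        x_inv = gf_pow(2, (255 - (len(msg) - 1 - pos)) % 255)
        if poly_eval(err_loc, x_inv) == 0:
            positions.append(pos)
    if len(positions) != n_errors:
        raise RSDecodeError("error locator does not factor; uncorrectable")

    # Magnitudes from the syndrome equations S_i = sum_k e_k X_k^i, solved
    # directly by Gaussian elimination over GF(256) (n_errors <= nsym/2 is
    # tiny, so this is both simple and exact).
    xs = [gf_pow(2, len(msg) - 1 - pos) for pos in positions]
    aug = [
        [gf_pow(x, i) for x in xs] + [synd[i]]
        for i in range(n_errors)
    ]
    for col in range(n_errors):
        pivot = next((r for r in range(col, n_errors) if aug[r][col] != 0), None)
        if pivot is None:
            raise RSDecodeError("singular syndrome system; uncorrectable")
        aug[col], aug[pivot] = aug[pivot], aug[col]
        inv = gf_inv(aug[col][col])
        aug[col] = [gf_mul(c, inv) for c in aug[col]]
        for r in range(n_errors):
            if r != col and aug[r][col] != 0:
                factor = aug[r][col]
                aug[r] = [rc ^ gf_mul(factor, cc) for rc, cc in zip(aug[r], aug[col])]
    for k, pos in enumerate(positions):
        msg[pos] ^= aug[k][n_errors]

    if any(poly_eval(msg, gf_pow(2, i)) for i in range(nsym)):
        raise RSDecodeError("residual syndromes after correction")
    return msg[:-nsym]
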