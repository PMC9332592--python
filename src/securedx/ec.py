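"""Prime-field elliptic-curve arithmetic and message embedding.

Short Weierstrass curves y^2 = x^3 + a x + b over F_p, with the affine group
law, double-and-add scalar multiplication, key-pair generation and a Koblitz
try-and-increment embedding of byte strings as curve points.

Two curves ship with the package:

* ``secp256r1`` — the NIST P-256 domain parameters, the default transport
  curve for the hybrid encryption layer.
* ``toy17`` — y^2 = x^3 + 2x + 2 over F_17 with base point (5, 1) of order
  19.  Small enough that the whole group table can be enumerated, it serves
  as the brute-force oracle in the test suite.

.. warning::
   The arithmetic here is *not* constant-time and makes no attempt at
   side-channel resistance.  This module is a method re-implementation for
   studying an encrypted-analytics pipeline, not production cryptography.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterator, Sequence

from .errors import DecodingError, EncodingError, ValidationError

__all__ = [
    "ECPoint",
    "CurveParams",
    "KeyPair",
    "IDENTITY",
    "CURVES",
    "TOY_CURVE",
    "SECP256R1",
    "point_add",
    "point_neg",
    "point_sub",
    "scalar_mult",
    "generate_keypair",
    "encode_message",
    "decode_points",
    "sqrt_mod",
]


@dataclass(frozen=True)
class ECPoint:
    """Affine point; ``x is None`` encodes the point at infinity."""

    x: int | None
    y: int | None

    @property
    def is_identity(self) -> bool:
        return self.x is None

    def __repr__(self) -> str:  # pragma: no cover - debugging nicety
        if self.is_identity:
            return "ECPoint(identity)"
        return f"ECPoint({self.x:#x}, {self.y:#x})"


IDENTITY = ECPoint(None, None)


@dataclass(frozen=True)
class CurveParams:
    """Domain parameters of a short Weierstrass curve over F_p.

    ``n`` is the order of the base point ``G``; nonces and private scalars
    live in (1, n-1).
    """

    name: str
    p: int
    a: int
    b: int
    gx: int
    gy: int
    n: int

    def __post_init__(self) -> None:
        if (4 * self.a**3 + 27 * self.b**2) % self.p == 0:
            raise ValidationError(f"curve {self.name!r} is singular")

    @property
    def G(self) -> ECPoint:
        return ECPoint(self.gx, self.gy)

    def contains(self, P: ECPoint) -> bool:
        if P.is_identity:
            return True
        assert P.x is not None and P.y is not None
        return (P.y * P.y - (P.x**3 + self.a * P.x + self.b)) % self.p == 0


TOY_CURVE = CurveParams("toy17", p=17, a=2, b=2, gx=5, gy=1, n=19)

SECP256R1 = CurveParams(
    "secp256r1",
    p=0xFFFFFFFF00000001000000000000000000000000FFFFFFFFFFFFFFFFFFFFFFFF,
    a=0xFFFFFFFF00000001000000000000000000000000FFFFFFFFFFFFFFFFFFFFFFFC,
    b=0x5AC635D8AA3A93E7B3EBBD55769886BC651D06B0CC53B0F63BCE3C3E27D2604B,
    gx=0x6B17D1F2E12C4247F8BCE6E563A440F277037D812DEB33A0F4A13945D898C296,
    gy=0x4FE342E2FE1A7F9B8EE7EB4A7C0F9E162BCE33576B315ECECBB6406837BF51F5,
    n=0xFFFFFFFF00000000FFFFFFFFFFFFFFFFBCE6FAADA7179E84F3B9CAC2FC632551,
)

CURVES: dict[str, CurveParams] = {c.name: c for c in (TOY_CURVE, SECP256R1)}


@dataclass(frozen=True)
class KeyPair:
    """Private scalar in (1, n-1) with its public point private*G."""

    private_scalar: int
    public_point: ECPoint
    curve_id: str


def _require_on_curve(P: ECPoint, curve: CurveParams) -> None:
    if not curve.contains(P):
        raise ValidationError(f"point {P!r} is not on curve {curve.name!r}")


def point_neg(P: ECPoint, curve: CurveParams) -> ECPoint:
    _require_on_curve(P, curve)
    if P.is_identity:
        return IDENTITY
    assert P.x is not None and P.y is not None
    return ECPoint(P.x, (-P.y) % curve.p)


def point_add(P: ECPoint, Q: ECPoint, curve: CurveParams) -> ECPoint:
    """Chord-tangent group law on the curve; identity is neutral."""
    _require_on_curve(P, curve)
    _require_on_curve(Q, curve)
    if P.is_identity:
        return Q
    if Q.is_identity:
        return P
    assert P.x is not None and Q.x is not None
    p = curve.p
    if P.x == Q.x and (P.y + Q.y) % p == 0:
        return IDENTITY
    if P == Q:
        lam = (3 * P.x * P.x + curve.a) * pow(2 * P.y, -1, p) % p
    else:
        lam = (Q.y - P.y) * pow(Q.x - P.x, -1, p) % p
    x3 = (lam * lam - P.x - Q.x) % p
    y3 = (lam * (P.x - x3) - P.y) % p
    return ECPoint(x3, y3)


def point_sub(P: ECPoint, Q: ECPoint, curve: CurveParams) -> ECPoint:
    return point_add(P, point_neg(Q, curve), curve)


def scalar_mult(k: int, P: ECPoint, curve: CurveParams) -> ECPoint:
    """k-fold group sum by double-and-add; ``scalar_mult(0, P)`` is identity."""
    if k < 0:
        raise ValidationError("scalar must be nonnegative")
    _require_on_curve(P, curve)
    result = IDENTITY
    addend = P
    while k:
        if k & 1:
            result = point_add(result, addend, curve)
        addend = point_add(addend, addend, curve)
        k >>= 1
    return result


def generate_keypair(curve: CurveParams, rng: random.Random) -> KeyPair:
    """Draw a private scalar uniformly from the open interval (1, n-1)."""
    private = rng.randrange(2, curve.n - 1)
    return KeyPair(private, scalar_mult(private, curve.G, curve), curve.name)


def sqrt_mod(a: int, p: int) -> int | None:
    """Modular square root of ``a`` mod prime ``p`` (Tonelli–Shanks).

    Returns the even-ordered root, or None when ``a`` is a non-residue.
    """
    a %= p
    if a == 0:
        return 0
    if pow(a, (p - 1) // 2, p) != 1:
        return None
    if p % 4 == 3:
        return pow(a, (p + 1) // 4, p)
    # Tonelli–Shanks for p = 1 mod 4
    q, s = p - 1, 0
    while q % 2 == 0:
        q //= 2
        s += 1
    z = 2
    while pow(z, (p - 1) // 2, p) != p - 1:
        z += 1
    m, c, t, r = s, pow(z, q, p), pow(a, q, p), pow(a, (q + 1) // 2, p)
    while t != 1:
        i, t2 = 0, t
        while t2 != 1:
            t2 = t2 * t2 % p
            i += 1
        b = pow(c, 1 << (m - i - 1), p)
        m, c, t, r = i, b * b % p, t * b * b % p, r * b % p
    return r


def _block_size(curve: CurveParams) -> int:
    # 8 bits reserved for the try-and-increment counter, 8 more as headroom so
    # m*256 + 255 can never reach p.
    return (curve.p.bit_length() - 16) // 8


_LEN_PREFIX = 4  # bytes of big-endian length prepended before blocking


def _chunks(data: bytes, size: int) -> Iterator[bytes]:
    for i in range(0, len(data), size):
        yield data[i : i + size]


def encode_message(data: bytes, curve: CurveParams) -> list[ECPoint]:
    """Embed a byte string as curve points (Koblitz try-and-increment).

    The payload is length-prefixed, split into fixed blocks of
    ``(bitlen(p) - 16) // 8`` bytes, and each block integer ``m`` is mapped to
    the first x = m*256 + j (j = 0, 1, ...) whose cubic is a quadratic
    residue.  Each increment fails with probability ~1/2, so 256 tries fail
    with probability ~2^-256.  :func:`decode_points` inverts exactly.
    """
    B = _block_size(curve)
    if B < 1:
        raise EncodingError(
            f"curve {curve.name!r} is too small to embed messages"
        )
    if not data:
        return []
    payload = len(data).to_bytes(_LEN_PREFIX, "big") + data
    points: list[ECPoint] = []
    for chunk in _chunks(payload, B):
        m = int.from_bytes(chunk.ljust(B, b"\x00"), "big")
        for j in range(256):
            x = (m << 8) + j
            rhs = (x * x * x + curve.a * x + curve.b) % curve.p
            y = sqrt_mod(rhs, curve.p)
            if y is not None:
                points.append(ECPoint(x, min(y, (curve.p - y) % curve.p)))
                break
        else:  # pragma: no cover - probability ~2^-256
            raise EncodingError("no embeddable x within 256 increments")
    return points


def decode_points(points: Sequence[ECPoint], curve: CurveParams) -> bytes:
    """Exact inverse of :func:`encode_message`."""
    B = _block_size(curve)
    if not points:
        return b""
    raw = bytearray()
    for P in points:
        if P.is_identity:
            raise DecodingError("identity point in message stream")
        assert P.x is not None
        m = P.x >> 8
        if m >= 1 << (8 * B):
            raise DecodingError("block integer exceeds the embedding range")
        raw += m.to_bytes(B, "big")
    if len(raw) < _LEN_PREFIX:
        raise DecodingError("message stream shorter than its length prefix")
    length = int.from_bytes(raw[:_LEN_PREFIX], "big")
    body = bytes(raw[_LEN_PREFIX:])
    if not 0 < length <= len(body) or len(body) - length >= B:
        raise DecodingError("malformed length prefix or padding")
    if any(body[length:]):
        raise DecodingError("nonzero padding after message body")
    return body[:length]


# -- point / key serialization (hex text) -----------------------------------


def point_to_hex(P: ECPoint, curve: CurveParams) -> str:
    """SEC1-style compressed encoding: 02/03 prefix + fixed-width x."""
    if P.is_identity:
        return "00"
    assert P.x is not None and P.y is not None
    width = (curve.p.bit_length() + 7) // 8 * 2
    prefix = "03" if P.y % 2 else "02"
    return prefix + format(P.x, f"0{width}x")


def point_from_hex(text: str, curve: CurveParams) -> ECPoint:
    text = text.strip().lower()
    if text == "00":
        return IDENTITY
    prefix, xhex = text[:2], text[2:]
    if prefix not in ("02", "03"):
        raise ValidationError(f"bad point prefix {prefix!r}")
    x = int(xhex, 16)
    rhs = (x * x * x + curve.a * x + curve.b) % curve.p
    y = sqrt_mod(rhs, curve.p)
    if y is None:
        raise ValidationError("x coordinate is not on the curve")
    if y % 2 != (prefix == "03"):
        y = (curve.p - y) % curve.p
    P = ECPoint(x, y)
    _require_on_curve(P, curve)
    return P


def keypair_to_text(kp: KeyPair) -> str:
    curve = CURVES[kp.curve_id]
    return "\n".join(
        [
            f"curve\t{kp.curve_id}",
            f"private\t{kp.private_scalar:x}",
            f"public\t{point_to_hex(kp.public_point, curve)}",
            "",
        ]
    )


def keypair_from_text(text: str) -> KeyPair:
    fields = dict(
        line.split("\t", 1) for line in text.splitlines() if line.strip()
    )
    curve = CURVES[fields["curve"]]
    private = int(fields["private"], 16)
    public = point_from_hex(fields["public"], curve)
    kp = KeyPair(private, public, curve.name)
    if scalar_mult(private, curve.G, curve) != public:
        raise ValidationError("public point does not match private scalar")
    return kp
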