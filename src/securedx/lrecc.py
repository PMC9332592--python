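"""Log-of-round-value elliptic-curve hybrid encryption (LR-ECC).

The scheme masks Koblitz-embedded message points with a multiple of the ECDH
shared point.  Sender and receiver each hold a key pair on the same curve;
the shared point S = k_priv_sender * P_pub_receiver = k_priv_receiver *
P_pub_sender is never transmitted.  An integer *secret scalar* is derived
from S by rounding the natural log of its x-coordinate, and the mask applied
to every message point is

    M = (Rn * K_se mod n) * S

with Rn a fresh nonce drawn uniformly from (1, n-1) for each encryption.
Encryption adds M to each embedded point; decryption recomputes S, K_se and
M from its own private key and subtracts.  The nonce travels in the clear
inside the payload; recovering M from Rn still requires a private key.

Note on the secret scalar: deriving it as ``round(ln(x_S + 2))`` (floored at
1) is the only reading of a "round log value" secret under which both
parties can compute the same scalar without transmitting it, and the +2
offset keeps the logarithm positive for every affine x >= 0.  Decryption
subtracts the full mask because multiplying by K_se after subtraction would
not invert the encryption.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .ec import (
    CURVES,
    CurveParams,
    ECPoint,
    KeyPair,
    decode_points,
    encode_message,
    point_add,
    point_from_hex,
    point_sub,
    point_to_hex,
    scalar_mult,
)
from .errors import DecodingError, IntegrityError, KeyDerivationError, ValidationError

__all__ = [
    "SecretScalar",
    "EncryptedPayload",
    "derive_secret_key",
    "encrypt",
    "decrypt",
    "payload_to_text",
    "payload_from_text",
]


@dataclass(frozen=True)
class SecretScalar:
    """The log-derived integer secret K_se, recomputable by both parties."""

    value: int

    def __post_init__(self) -> None:
        if self.value < 1:
            raise ValidationError("secret scalar must be >= 1")


@dataclass(frozen=True)
class EncryptedPayload:
    """Masked message points plus the nonce needed to rebuild the mask."""

    masked_points: tuple[ECPoint, ...]
    nonce: int
    curve_id: str

    def __post_init__(self) -> None:
        curve = CURVES[self.curve_id]
        if not 1 < self.nonce < curve.n - 1:
            raise ValidationError("nonce outside (1, n-1)")
        for P in self.masked_points:
            if not curve.contains(P):
                raise ValidationError("masked point off curve")


def derive_secret_key(shared_point: ECPoint) -> SecretScalar:
    """K_se = max(1, round(ln(x + 2))) of the shared point's affine x."""
    if shared_point.is_identity:
        raise KeyDerivationError("shared point is the identity")
    assert shared_point.x is not None
    return SecretScalar(max(1, round(math.log(shared_point.x + 2))))


def _mask(
    nonce: int, own_private: int, other_public: ECPoint, curve: CurveParams
) -> ECPoint:
    shared = scalar_mult(own_private, other_public, curve)
    kse = derive_secret_key(shared)
    return scalar_mult(nonce * kse.value % curve.n, shared, curve)


def encrypt(
    plaintext: bytes,
    sender_private: int,
    receiver_public: ECPoint,
    curve: CurveParams,
    rng: random.Random,
) -> EncryptedPayload:
    """Embed ``plaintext`` as points and add the nonce-scaled shared mask."""
    if not curve.contains(receiver_public) or receiver_public.is_identity:
        raise ValidationError("receiver public key is not a valid curve point")
    nonce = rng.randrange(2, curve.n - 1)
    M = _mask(nonce, sender_private, receiver_public, curve)
    masked = tuple(
        point_add(C, M, curve) for C in encode_message(plaintext, curve)
    )
    return EncryptedPayload(masked, nonce, curve.name)


def decrypt(
    payload: EncryptedPayload,
    receiver_private: int,
    sender_public: ECPoint,
    curve: CurveParams,
) -> bytes:
    """Recompute the mask from the receiver's side and strip it."""
    if payload.curve_id != curve.name:
        raise ValidationError(
            f"payload curve {payload.curve_id!r} != {curve.name!r}"
        )
    M = _mask(payload.nonce, receiver_private, sender_public, curve)
    unmasked = [point_sub(C, M, curve) for C in payload.masked_points]
    try:
        return decode_points(unmasked, curve)
    except DecodingError as exc:
        raise IntegrityError(f"decryption failed: {exc}") from exc


# -- payload serialization (line-oriented text) -----------------------------


def payload_to_text(payload: EncryptedPayload) -> str:
    curve = CURVES[payload.curve_id]
    lines = [
        f"curve\t{payload.curve_id}",
        f"nonce\t{payload.nonce:x}",
        f"blocks\t{len(payload.masked_points)}",
    ]
    lines += [
        f"point\t{point_to_hex(P, curve)}" for P in payload.masked_points
    ]
    return "\n".join(lines) + "\n"


def payload_from_text(text: str) -> EncryptedPayload:
    curve_id: str | None = None
    nonce: int | None = None
    blocks: int | None = None
    points: list[ECPoint] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("\t")
        if key == "curve":
            curve_id = value
        elif key == "nonce":
            nonce = int(value, 16)
        elif key == "blocks":
            blocks = int(value)
        elif key == "point":
            if curve_id is None:
                raise ValidationError("point listed before curve id")
            points.append(point_from_hex(value, CURVES[curve_id]))
        else:
            raise ValidationError(f"unknown payload field {key!r}")
    if curve_id is None or nonce is None or blocks is None:
        raise ValidationError("payload missing curve/nonce/blocks header")
    if blocks != len(points):
        raise ValidationError("payload block count mismatch")
    return EncryptedPayload(tuple(points), nonce, curve_id)
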