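"""Shared fixtures: toy-curve point enumeration and small synthetic tables."""

from __future__ import annotations

import numpy as np
import pytest

from securedx import synth
from securedx.ec import TOY_CURVE, ECPoint, IDENTITY


def toy_points() -> list[ECPoint]:
    """All rational points of y^2 = x^3 + 2x + 2 over F_17, by exhaustion."""
    pts = [IDENTITY]
    c = TOY_CURVE
    for x in range(c.p):
        for y in range(c.p):
            if (y * y - (x**3 + c.a * x + c.b)) % c.p == 0:
                pts.append(ECPoint(x, y))
    return pts


def oracle_add(P: ECPoint, Q: ECPoint) -> ECPoint:
    """Independent chord-tangent law on the toy curve.

    Uses brute-force modular inversion so it shares no code path with the
    implementation under test.
    """
    p, a = TOY_CURVE.p, TOY_CURVE.a

    def inv(v: int) -> int:
        v %= p
        for w in range(1, p):
            if v * w % p == 1:
                return w
        raise ZeroDivisionError(v)

    if P.is_identity:
        return Q
    if Q.is_identity:
        return P
    if P.x == Q.x and (P.y + Q.y) % p == 0:
        return IDENTITY
    if P == Q:
        lam = (3 * P.x * P.x + a) * inv(2 * P.y) % p
    else:
        lam = (Q.y - P.y) * inv(Q.x - P.x) % p
    x3 = (lam * lam - P.x - Q.x) % p
    y3 = (lam * (P.x - x3) - P.y) % p
    return ECPoint(x3, y3)


@pytest.fixture(scope="session")
def toy_group() -> list[ECPoint]:
    return toy_points()


@pytest.fixture()
def small_table() -> synth.RawTable:
    """Clean 80-row, 6-attribute, 2-class table with learnable structure."""
    return synth.generate_dataset(
        synth.SyntheticConfig(
            n_records=80,
            n_attributes=6,
            n_classes=2,
            class_mean_separation=3.0,
            noise_sd=1.0,
            missing_rate=0.0,
            duplicate_rate=0.0,
            seed=42,
        )
    )


@pytest.fixture()
def messy_table() -> synth.RawTable:
    """Table with duplicates and missing markers for preprocessing tests."""
    return synth.generate_dataset(
        synth.SyntheticConfig(
            n_records=60,
            n_attributes=5,
            n_classes=3,
            class_mean_separation=2.0,
            noise_sd=1.0,
            missing_rate=0.1,
            duplicate_rate=0.15,
            seed=7,
        )
    )


@pytest.fixture()
def gaussian_5class() -> tuple[np.ndarray, np.ndarray]:
    """Random 5-class Gaussian data for eigen-residual checks."""
    rng = np.random.default_rng(123)
    X_parts, y_parts = [], []
    for k in range(5):
        mu = rng.normal(0, 3, size=8)
        X_parts.append(mu + rng.normal(0, 1, size=(30, 8)))
        y_parts.append(np.full(30, k))
    return np.vstack(X_parts), np.concatenate(y_parts)
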