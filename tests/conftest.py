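"""Shared fixtures: small synthetic phantoms and an exhaustive NCC oracle."""

from __future__ import annotations

import numpy as np
import pytest

from tempsub import Ellipse, PhantomSpec


def small_spec(**kwargs) -> PhantomSpec:
    """A 128 px phantom small enough for fast tests."""
    defaults = dict(
        image_size=128,
        background=Ellipse((63.5, 63.5), (50.0, 40.0), 0.0, 100.0),
        tumour_t1=Ellipse((80.0, 52.0), (7.0, 5.0), 20.0, 180.0),
        tumour_t2=Ellipse((80.0, 52.0), (7.0, 5.0), 20.0, 180.0),
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


@pytest.fixture
def spec_identity() -> PhantomSpec:
    return small_spec()


@pytest.fixture
def spec_growth() -> PhantomSpec:
    return small_spec(tumour_t2=Ellipse((80.0, 52.0), (11.0, 8.0), 20.0, 180.0))


def exhaustive_ncc_shift(original, current, roi, radius):
    """Independent oracle: plain-loop NCC over every integer offset.

    Returns ((dtx, dty), ncc_map); ties resolve to smallest |dtx|+|dty|,
    then lexicographic (dtx, dty) — the documented production tie rule.
    """
    x, y, w, h = roi
    t = original[y : y + h, x : x + w].astype(float)
    t = t - t.mean()
    tnorm = np.sqrt((t * t).sum())
    best, best_off = -np.inf, None
    ncc_map = np.full((2 * radius + 1, 2 * radius + 1), np.nan)
    offsets = sorted(
        ((dx, dy) for dy in range(-radius, radius + 1)
         for dx in range(-radius, radius + 1)),
        key=lambda c: (abs(c[0]) + abs(c[1]), c[0], c[1]),
    )
    for dx, dy in offsets:
        p = current[y + dy : y + dy + h, x + dx : x + dx + w].astype(float)
        p = p - p.mean()
        pnorm = np.sqrt((p * p).sum())
        ncc = 0.0 if tnorm == 0 or pnorm == 0 else float((t * p).sum() / (tnorm * pnorm))
        ncc_map[dy + radius, dx + radius] = ncc
        if ncc > best + 1e-12:
            best, best_off = ncc, (dx, dy)
    return best_off, ncc_map
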