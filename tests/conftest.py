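"""Shared fixtures and independent oracles for the ctrval test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ctrval.geometry import MaskPair


# ---------------------------------------------------------------------------
# Brute-force geometric oracle: pure-Python per-pixel scans, deliberately
# independent of the vectorized implementation under test.
# ---------------------------------------------------------------------------

def brute_force_measure(lung: np.ndarray, heart: np.ndarray) -> dict:
    h, w = lung.shape
    lung_cols = sorted({c for r in range(h) for c in range(w) if lung[r, c]})
    midline = (lung_cols[0] + lung_cols[-1]) // 2
    gt = lung_cols[-1] - lung_cols[0] + 1
    mld = mrd = 0
    for r in range(h):
        row_cols = [c for c in range(w) if heart[r, c]]
        if not row_cols:
            continue
        mrd = max(mrd, midline - min(row_cols))
        mld = max(mld, max(row_cols) - midline)
    mld, mrd = max(mld, 0), max(mrd, 0)
    return {
        "mld": mld,
        "mrd": mrd,
        "gt": gt,
        "ctr": (mld + mrd) / gt,
        "midline_col": midline,
    }


def brute_force_max_extent(mask: np.ndarray) -> tuple[int, int]:
    best_w, best_r = 0, 0
    h, w = mask.shape
    for r in range(h):
        cols = [c for c in range(w) if mask[r, c]]
        if cols and max(cols) - min(cols) + 1 > best_w:
            best_w, best_r = max(cols) - min(cols) + 1, r
    return best_w, best_r


def _blob(shape, rng):
    h, w = shape
    out = np.zeros(shape, bool)
    for _ in range(int(rng.integers(1, 4))):
        r0 = rng.integers(0, h)
        c0 = rng.integers(0, w)
        rb = rng.integers(1, max(2, h // 3))
        cb = rng.integers(1, max(2, w // 3))
        rr, cc = np.ogrid[:h, :w]
        out |= ((cc - c0) / cb) ** 2 + ((rr - r0) / rb) ** 2 <= 1.0
    out |= rng.random(shape) < 0.02  # speckle
    if not out.any():
        out[rng.integers(0, h), rng.integers(0, w)] = True
    return out


def random_mask_pair(rng: np.random.Generator) -> MaskPair:
    """A random, irregular (possibly multi-component) lung/heart pair."""
    shape = (int(rng.integers(20, 80)), int(rng.integers(30, 120)))
    return MaskPair(lung=_blob(shape, rng), heart=_blob(shape, rng))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_thorax():
    """Lungs spanning columns 10..89, rectangular heart 40..59 (all rows)."""
    lung = np.zeros((50, 100), bool)
    lung[:, 10:90] = True
    heart = np.zeros((50, 100), bool)
    heart[:, 40:60] = True
    return MaskPair(lung=lung, heart=heart)
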