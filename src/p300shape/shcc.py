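"""Slope Horizontal Chain Code (SHCC) for 1-D biosignal curves.

The SHCC turns an ERP trace into a short symbolic sequence: the curve is
rediscretized to S straight-line segments whose endpoints are existing
samples (no interpolation), min-max normalized to the unit square, and each
segment is coded by its inclination relative to the horizontal, quantized
to two decimals. Unlike the slope chain code for closed contours, symbols
are independent of each other (each depends only on its own segment's two
endpoints), there is no rotation or scale invariance, and the code is
translation-invariant in both axes.

Two codec conventions are provided:

``"slope"`` (default)
    symbol = round(atan2(dy, dx) / 90 deg, 2) on unit-square coordinates,
    i.e. the segment's inclination angle as a fraction of a right angle,
    giving the continuous range (-1, 1) in steps of 0.01.
``"dy"``
    symbol = round(dy, 2): the signed normalized rise of the segment,
    treating each segment as having unit width. Also valued in (-1, 1).

Both conventions agree on the all-zero code for flat curves and on odd
symmetry under y-mirroring; chain distance and tortuosity are
convention-independent arithmetic on the symbols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .preprocess import Curve

__all__ = [
    "Chain",
    "NormalizedCurve",
    "resample_curve",
    "normalize_curve",
    "encode_chain",
    "chain_distance",
    "tortuosity",
    "default_segment_count",
    "parse_chains",
    "format_chain",
]

#: Quantization step of the symbol alphabet (two-decimal precision).
SYMBOL_STEP = 0.01
#: Largest representable |symbol|; the open interval (-1, 1) at two decimals.
SYMBOL_MAX = 0.99


def _round_half_away(values: np.ndarray, decimals: int = 2) -> np.ndarray:
    """Round half away from zero — symmetric for positive/negative slopes."""
    scale = 10.0**decimals
    return np.copysign(np.floor(np.abs(values) * scale + 0.5) / scale, values)


@dataclass(frozen=True)
class Chain:
    """SHCC code sequence (b_1 ... b_S) of quantized slope symbols."""

    symbols: np.ndarray

    def __post_init__(self) -> None:
        sym = np.asarray(self.symbols, dtype=float)
        object.__setattr__(self, "symbols", sym)
        if sym.ndim != 1 or sym.size < 1:
            raise ValueError("a chain needs at least one symbol")
        if np.any(np.abs(sym) >= 1):
            raise ValueError("chain symbols must lie strictly inside (-1, 1)")
        if not np.allclose(sym, _round_half_away(sym), atol=1e-12):
            raise ValueError("chain symbols must be quantized to two decimals")

    @property
    def segment_count(self) -> int:
        return self.symbols.size

    def __len__(self) -> int:
        return self.symbols.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chain):
            return NotImplemented
        return self.symbols.size == other.symbols.size and bool(
            np.all(self.symbols == other.symbols)
        )


@dataclass(frozen=True)
class NormalizedCurve:
    """Curve min-max scaled to the unit square; S+1 points, S segments."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise ValueError("normalized curve needs >= 2 (x, y) pairs")
        for v in (x, y):
            if v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise ValueError("normalized coordinates must lie in [0, 1]")

    @property
    def segment_count(self) -> int:
        return self.x.size - 1


def default_segment_count(epoch_ms: float = 800.0, resample_hz: float = 20.0) -> int:
    """Segments needed to carry the ERP envelope at *resample_hz*.

    The ERP band extends to roughly 10 Hz, so a 20 Hz effective resampling
    rate satisfies Nyquist; over an 800 ms epoch that yields
    floor(800 * 20 / 1000) = 16 segments.
    """
    return int(math.floor(epoch_ms * resample_hz / 1000.0))


def resample_curve(curve: Curve, segments: int) -> Curve:
    """Select S+1 existing samples at nominal spacing T/(S+1).

    Endpoint m (m = 0..S) is the sample nearest 1 + m * Delta with
    Delta = T / (S + 1), clipped to [1, T]; no interpolation is performed,
    so segment endpoints are always acquired samples. S = T - 1 keeps every
    sample (Delta = 1).
    """
    T = len(curve)
    if not 1 <= segments < T:
        raise ValueError(f"segments must satisfy 1 <= S < T = {T}; got {segments}")
    delta = T / (segments + 1)
    m = np.arange(segments + 1)
    idx = np.floor(1 + m * delta + 0.5).astype(int)  # round half up; positions 1-based
    idx = np.clip(idx, 1, T)
    return Curve(curve.x[idx - 1], curve.y[idx - 1])


def normalize_curve(curve: Curve) -> NormalizedCurve:
    """Min-max scale x and y independently onto [0, 1].

    A flat axis (max == min) maps to all zeros, so a zero-amplitude epoch
    encodes to the all-zero chain rather than dividing by zero.
    """

    def scale(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        if span == 0:
            return np.zeros_like(v)
        return (v - v.min()) / span

    return NormalizedCurve(scale(curve.x), scale(curve.y))


def _symbols_from_normalized(nc: NormalizedCurve, mode: str) -> np.ndarray:
    dx = np.diff(nc.x)
    dy = np.diff(nc.y)
    if mode == "slope":
        raw = np.degrees(np.arctan2(dy, dx)) / 90.0
    elif mode == "dy":
        raw = dy
    else:
        raise ValueError(f"unknown codec mode {mode!r}; use 'slope' or 'dy'")
    sym = _round_half_away(raw)
    return np.clip(sym, -SYMBOL_MAX, SYMBOL_MAX)


def encode_chain(curve: Curve, segments: int, mode: str = "slope") -> Chain:
    """Resample, normalize, and code each segment's inclination symbol."""
    nc = normalize_curve(resample_curve(curve, segments))
    return Chain(_symbols_from_normalized(nc, mode))


def chain_distance(a: Chain, b: Chain) -> float:
    """l1 distance between equal-length chains: sum_s |a_s - b_s|.

    The l1 norm is used as the dissimilarity between curve descriptors; it
    is the cheapest of the usual curve distances and performs on par with
    l2 for this task.
    """
    if len(a) != len(b):
        raise ValueError(f"chain lengths differ: {len(a)} vs {len(b)}")
    # symbols are exact multiples of 0.01; re-quantize to kill float dust
    return float(round(np.abs(a.symbols - b.symbols).sum(), 10))


def tortuosity(chain: Chain) -> float:
    """Sum of absolute symbol values over all S symbols.

    Zero for a purely horizontal (flat) curve; grows with curvature. The sum
    runs over every symbol of the chain.
    """
    return float(round(np.abs(chain.symbols).sum(), 10))


# -- chain text dialect ---------------------------------------------------
# One chain per line, space-separated two-decimal tokens; '#' comments.


def format_chain(chain: Chain) -> str:
    def tok(v: float) -> str:
        s = f"{v:.2f}"
        return "0" if s in ("0.00", "-0.00") else s

    return " ".join(tok(v) for v in chain.symbols)


def parse_chains(text_or_path: str | Path, *, from_path: bool = False) -> list[Chain]:
    """Parse chains from text (or a file when *from_path*), one per line."""
    if from_path:
        text = Path(text_or_path).read_text(encoding="utf-8")
    else:
        text = str(text_or_path)
    chains = []
    for line in text.splitlines():
        body = line.split("#", 1)[0].strip().strip("()")
        if not body:
            continue
        chains.append(Chain(np.array([float(t) for t in body.split()])))
    return chains
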