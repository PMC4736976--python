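"""Trapezoid segment areas and the (2S+2)-dimensional shape-feature vector.

The chain code describes waveform shape but discards voltage information,
and two differently shaped curves can share a tortuosity value; area
differences between a template curve and a candidate curve restore that
discriminative information. Each curve is min-max normalized on its own,
then the trapezoidal rule is applied over its consecutive point pairs,
yielding one area per segment (S areas from S+1 points); the segment-wise
differences between two curves use the first S-1 of them. The feature
vector stacks, in order: the signed template-minus-candidate area
differences a_1..a_{S-1},
their absolute sum, the chain distance d, the candidate's tortuosity, and
the candidate's S chain symbols — 2S+2 components, with d always at
position S+1 (1-based), a layout the calibration stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shcc import Chain, NormalizedCurve

__all__ = [
    "ShapeFeatureVector",
    "segment_areas",
    "area_difference_features",
    "assemble_vector",
    "feature_names",
]


@dataclass(frozen=True)
class ShapeFeatureVector:
    """v = [a_1..a_{S-1}, T_sum, d, tortuosity, b_1..b_S], length 2S+2."""

    area_diffs: np.ndarray
    area_diff_sum: float
    distance: float
    tortuosity: float
    chain_symbols: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.area_diffs, dtype=float)
        b = np.asarray(self.chain_symbols, dtype=float)
        object.__setattr__(self, "area_diffs", a)
        object.__setattr__(self, "chain_symbols", b)
        if a.ndim != 1 or b.ndim != 1:
            raise ValueError("area_diffs and chain_symbols must be 1-D")
        if b.size != a.size + 1:
            raise ValueError(
                f"inconsistent sizes: {a.size} area differences need "
                f"{a.size + 1} chain symbols, got {b.size}"
            )

    @property
    def segment_count(self) -> int:
        return self.chain_symbols.size

    def __len__(self) -> int:
        return 2 * self.segment_count + 2

    def to_array(self) -> np.ndarray:
        """Flat layout; element S+1 (1-based) is the chain distance d."""
        return np.concatenate(
            [
                self.area_diffs,
                [self.area_diff_sum, self.distance, self.tortuosity],
                self.chain_symbols,
            ]
        )

    @classmethod
    def from_array(cls, v: np.ndarray, segments: int) -> "ShapeFeatureVector":
        v = np.asarray(v, dtype=float)
        if v.size != 2 * segments + 2:
            raise ValueError(
                f"vector of length {v.size} is not 2S+2 = {2 * segments + 2}"
            )
        S = segments
        return cls(v[: S - 1], float(v[S - 1]), float(v[S]), float(v[S + 1]), v[S + 2 :])


def feature_names(segments: int) -> list[str]:
    """Column names for serialized feature matrices (a1..a{S-1}, Tsum, d, tort, b1..bS)."""
    S = segments
    return (
        [f"a{i}" for i in range(1, S)]
        + ["Tsum", "d", "tort"]
        + [f"b{i}" for i in range(1, S + 1)]
    )


def segment_areas(curve: NormalizedCurve) -> np.ndarray:
    """Trapezoidal-rule area of every segment of the curve.

    An S-segment curve has S+1 points and yields the S trapezoids
    area_i = (y_i + y_{i+1})/2 * (x_{i+1} - x_i); their sum is the exact
    integral of the piecewise-linear interpolant.
    """
    if curve.x.size < 3:
        raise ValueError("need at least 3 points (two trapezoid areas)")
    x, y = curve.x, curve.y
    return 0.5 * (y[:-1] + y[1:]) * np.diff(x)


def area_difference_features(
    template: NormalizedCurve, candidate: NormalizedCurve
) -> tuple[np.ndarray, float]:
    """Signed segment-wise area differences a_1..a_{S-1} and their absolute sum.

    The two S-dimensional area vectors are differenced over the first S-1
    segments: a_i = template_area_i - candidate_area_i keeps direction
    information for the classifier, while T_sum = sum_i |a_i| is a
    dissimilarity (zero iff those segment areas coincide). Each curve is
    assumed normalized on its own min-max range.
    """
    if template.segment_count != candidate.segment_count:
        raise ValueError(
            f"segment counts differ: {template.segment_count} vs "
            f"{candidate.segment_count}"
        )
    diffs = (segment_areas(template) - segment_areas(candidate))[:-1]
    return diffs, float(np.abs(diffs).sum())


def assemble_vector(
    area_diffs: np.ndarray,
    area_diff_sum: float,
    distance: float,
    tortuosity: float,
    chain: Chain,
) -> ShapeFeatureVector:
    """Stack components into the canonical (2S+2)-dimensional layout."""
    return ShapeFeatureVector(
        np.asarray(area_diffs, dtype=float),
        float(area_diff_sum),
        float(distance),
        float(tortuosity),
        chain.symbols,
    )
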