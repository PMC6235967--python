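"""Cross-modality validation of detected cell mosaics.

Two graders (or two imaging modalities — e.g. fluorescence vs. darkfield
views of the same RPE mosaic) each produce a set of cell-centroid
coordinates.  Agreement is quantified by optimally pairing the two sets under
a distance cap and counting true positives (matched pairs), false positives
(unmatched test points) and false negatives (unmatched reference points).
The conventional cap is half the measured cell-to-cell spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .morphometry import SpacingResult

__all__ = ["MatchResult", "match_centroids", "half_spacing_threshold"]


@dataclass
class MatchResult:
    """Point-correspondence counts and rates under a distance threshold.

    ``pairs`` holds (test_index, reference_index) for every matched pair;
    every pair's distance is ≤ ``threshold`` and each point appears in at
    most one pair.  ``recall``/``precision`` are NaN when undefined (empty
    reference/test set), flagged by ``defined``.
    """

    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    threshold: float
    pairs: list[tuple[int, int]]

    @property
    def defined(self) -> bool:
        return not (np.isnan(self.recall) or np.isnan(self.precision))


def match_centroids(
    test: np.ndarray, reference: np.ndarray, threshold: float
) -> MatchResult:
    """One-to-one optimal matching of two centroid sets with a distance cap.

    The assignment maximizes the number of pairs within ``threshold`` and,
    among those, minimizes the total matched distance (solved as a linear
    assignment with over-threshold pairs priced prohibitively).  Convention:
    ``test`` = detections under scrutiny (false positives), ``reference`` =
    the trusted modality (false negatives).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    test = np.asarray(test, dtype=float).reshape(-1, 2)
    reference = np.asarray(reference, dtype=float).reshape(-1, 2)
    nt, nr = len(test), len(reference)
    pairs: list[tuple[int, int]] = []
    if nt and nr:
        d = cdist(test, reference)
        # any feasible match is cheaper than one unit of the penalty, so the
        # solver maximizes match count first, then total distance
        penalty = threshold * (min(nt, nr) + 1) * 10.0
        cost = np.where(d <= threshold, d, penalty)
        ri, ci = linear_sum_assignment(cost)
        pairs = [(int(i), int(j)) for i, j in zip(ri, ci) if d[i, j] <= threshold]
    tp = len(pairs)
    fp = nt - tp
    fn = nr - tp
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return MatchResult(
        tp=tp, fp=fp, fn=fn, recall=recall, precision=precision,
        threshold=threshold, pairs=pairs,
    )


def half_spacing_threshold(spacing: SpacingResult | float) -> float:
    """Correspondence cap: half the measured cell-to-cell spacing (µm)."""
    s = spacing.spacing if isinstance(spacing, SpacingResult) else float(spacing)
    if s <= 0:
        raise ValueError("spacing must be positive")
    return s / 2.0
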