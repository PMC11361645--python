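"""Intensity- and object-based colocalization statistics for image pairs.

Implements the two families of measures commonly applied to two-channel
fluorescence micrographs of punctate structures:

* intensity-based — Pearson product-moment correlation of pixel
  intensities, and the Manders-type overlap coefficient
  ``sum(a*b) / sqrt(sum(a^2) * sum(b^2))``;
* object-based — segment puncta in each channel, then match their
  geometric (intensity-weighted) centers across channels within a
  distance tolerance, reporting the matched percentage in both
  directions (A-in-B and B-in-A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage import measure

from .errors import InvalidInputError, UndefinedStatisticError


@dataclass(frozen=True)
class ObjectSet:
    """Segmented puncta of one channel: centroids (row, col) and pixel areas."""

    centroids: np.ndarray
    areas: np.ndarray
    source_channel: str = ""
    threshold_used: float = float("nan")

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        a = np.asarray(self.areas, dtype=int).reshape(-1)
        object.__setattr__(self, "centroids", c)
        object.__setattr__(self, "areas", a)
        if c.shape[0] != a.shape[0]:
            raise InvalidInputError("centroids and areas must have equal length")

    def __len__(self) -> int:
        return int(self.centroids.shape[0])


@dataclass(frozen=True)
class ColocResult:
    """Colocalization summary for one image pair.

    ``pct_a_in_b`` is 100 * (matched objects) / n_a, and symmetrically for
    ``pct_b_in_a``; intensity coefficients are None when only the
    object-based analysis was run.
    """

    pct_a_in_b: float
    pct_b_in_a: float
    n_matched: int
    n_a: int
    n_b: int
    pearson: float | None = None
    overlap: float | None = None
    matches: tuple[tuple[int, int], ...] = field(default=(), compare=False)


def _check_pair(img_a: np.ndarray, img_b: np.ndarray, mask=None):
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("images must have equal shape")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise InvalidInputError("mask must match image shape")
        return a[mask].ravel(), b[mask].ravel()
    return a.ravel(), b.ravel()


def pearson_coefficient(img_a, img_b, mask=None) -> float:
    """Pearson correlation of pixel intensities over the (masked) pair."""
    a, b = _check_pair(img_a, img_b, mask)
    if a.size < 2:
        raise InvalidInputError("need at least 2 pixels")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedStatisticError("Pearson undefined for a zero-variance channel")
    return float(np.corrcoef(a, b)[0, 1])


def overlap_coefficient(img_a, img_b, mask=None) -> float:
    """Manders-type overlap coefficient, sum(ab)/sqrt(sum(a^2) sum(b^2))."""
    a, b = _check_pair(img_a, img_b, mask)
    ssa, ssb = float(np.sum(a * a)), float(np.sum(b * b))
    if ssa == 0 or ssb == 0:
        raise UndefinedStatisticError("overlap undefined for an all-zero channel")
    return float(np.sum(a * b) / np.sqrt(ssa * ssb))


def segment_objects(
    img,
    rel_threshold: float = 2.0,
    min_area: int = 4,
    source_channel: str = "",
) -> ObjectSet:
    """Segment punctate objects by global thresholding.

    Pixels above ``mean + rel_threshold*sd`` are grouped by 8-connectivity;
    components smaller than ``min_area`` pixels are discarded. Centroids
    are intensity-weighted. An image with no objects yields an empty set.
    """
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise InvalidInputError("expected a 2-D image")
    thr = float(a.mean() + rel_threshold * a.std())
    labels = measure.label(a > thr, connectivity=2)
    cents, areas = [], []
    for region in measure.regionprops(labels, intensity_image=a):
        if region.area < min_area:
            continue
        cents.append(region.centroid_weighted)
        areas.append(region.area)
    return ObjectSet(
        centroids=np.array(cents, dtype=float).reshape(-1, 2),
        areas=np.array(areas, dtype=int),
        source_channel=source_channel,
        threshold_used=thr,
    )


def object_based_colocalization(
    a: ObjectSet, b: ObjectSet, max_dist: float = 3.0
) -> ColocResult:
    """Match centroids across channels and report bidirectional percentages.

    Matching is greedy one-to-one by increasing center-to-center distance,
    accepting pairs with distance <= ``max_dist`` px. Greedy matching is
    deterministic and mirrors common plugin behavior; because a match
    consumes one object from each channel, n_matched <= min(n_a, n_b) and
    swapping the channels swaps the two percentages.
    """
    if max_dist < 0:
        raise InvalidInputError("max_dist must be nonnegative")
    n_a, n_b = len(a), len(b)
    matches: list[tuple[int, int]] = []
    if n_a and n_b:
        d = cdist(a.centroids, b.centroids)
        order = np.argsort(d, axis=None, kind="stable")
        used_a: set[int] = set()
        used_b: set[int] = set()
        for flat in order:
            i, j = divmod(int(flat), n_b)
            if d[i, j] > max_dist:
                break
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            matches.append((i, j))
    n_matched = len(matches)
    return ColocResult(
        pct_a_in_b=100.0 * n_matched / n_a if n_a else 0.0,
        pct_b_in_a=100.0 * n_matched / n_b if n_b else 0.0,
        n_matched=n_matched, n_a=n_a, n_b=n_b,
        matches=tuple(matches),
    )


def colocalize_pair(
    img_a,
    img_b,
    rel_threshold: float = 2.0,
    min_area: int = 4,
    max_dist: float = 3.0,
) -> ColocResult:
    """Full pipeline: intensity coefficients plus object-based matching."""
    obj = object_based_colocalization(
        segment_objects(img_a, rel_threshold, min_area, "a"),
        segment_objects(img_b, rel_threshold, min_area, "b"),
        max_dist=max_dist,
    )
    return ColocResult(
        pct_a_in_b=obj.pct_a_in_b, pct_b_in_a=obj.pct_b_in_a,
        n_matched=obj.n_matched, n_a=obj.n_a, n_b=obj.n_b,
        pearson=pearson_coefficient(img_a, img_b),
        overlap=overlap_coefficient(img_a, img_b),
        matches=obj.matches,
    )
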