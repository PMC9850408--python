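"""Pixel-intensity correlation analysis (PICA).

Correlates a bait ion's per-pixel intensities against every mass feature
(Pearson correlation over pixels), ranks the features, partitions them
into colocalization bands, and provides the three computation-reduction
strategies: feature-range truncation, every-nth-pixel subsampling, and
region-of-interest filtering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msi import MSIDataset, extract_ion_image

__all__ = [
    "BaitQuery",
    "ColocalizationResult",
    "ThresholdBands",
    "pcc",
    "colocalize",
    "classify_bands",
    "reduce_features",
    "bait_cutoff",
    "subsample_pixels",
    "roi_filter",
    "parse_roi",
]

#: Mass headroom above the bait kept by the default feature-reduction
#: cutoff, wide enough to retain K+ adducts (+37.956 Da over [M+H]+).
DEFAULT_CUTOFF_MARGIN = 40.0


@dataclass(frozen=True)
class BaitQuery:
    """The precursor ("bait") ion whose colocalization partners are sought."""

    mz: float
    tol: float = 0.003
    label: str = ""
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.tol <= 0:
            raise ValueError("bait m/z and tolerance must be positive")


@dataclass(frozen=True)
class ThresholdBands:
    """PCC band edges: high ≥ ``high``; moderate in [``moderate_low``, high)."""

    high: float = 0.9
    moderate_low: float = 0.6

    def __post_init__(self) -> None:
        if not (-1 <= self.moderate_low < self.high <= 1):
            raise ValueError("require -1 <= moderate_low < high <= 1")


@dataclass
class ColocalizationResult:
    """Ranked (feature m/z, PCC) list for one bait.

    ``entries`` is a DataFrame with columns ``feature_mz`` and ``pcc``,
    sorted by PCC descending (ties broken by ascending m/z), truncated to
    ``top_n``. Features with undefined PCC (zero variance) are excluded
    from the ranking; their count is in ``n_undefined``.
    """

    bait: BaitQuery
    entries: pd.DataFrame
    top_n: int
    n_undefined: int = 0
    n_pixels: int = 0
    dataset_id: int | None = None
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path, bands: ThresholdBands | None = None) -> None:
        df = self.entries.copy()
        bands = bands or ThresholdBands()
        df["band"] = np.where(
            df["pcc"] >= bands.high, "high",
            np.where(df["pcc"] >= bands.moderate_low, "moderate", "other"),
        )
        df.to_csv(path, index=False)


def pcc(x, y) -> float:
    """Pearson correlation of two equal-length intensity vectors.

    Returns NaN (the "undefined" flag) instead of raising when either
    vector has zero variance — the denominator of the correlation formula
    vanishes and no coefficient exists.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pixels")
    if x.max() == x.min() or y.max() == y.min():  # constant: no coefficient exists
        return float("nan")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if denom == 0:
        return float("nan")
    return float(dx @ dy) / denom


def colocalize(dataset: MSIDataset, bait: BaitQuery, top_n: int = 100) -> ColocalizationResult:
    """PCC of the bait's ion image against every feature column, ranked.

    The bait image is the ±``bait.tol`` binned window around ``bait.mz``
    (matching how single-ion images are rendered), so the bait's own
    feature scores 1 by construction. Correlation uses *all* retained
    pixels, zeros included — absence is information. Zero-variance columns
    are flagged undefined and excluded from the ranking but counted.
    Deterministic: ties at the cutoff break by ascending feature m/z.
    """
    in_window = np.abs(dataset.mz_axis - bait.mz) <= bait.tol
    if not in_window.any():
        nearest = float(dataset.mz_axis[np.argmin(np.abs(dataset.mz_axis - bait.mz))])
        raise ValueError(
            f"bait m/z {bait.mz} not found within ±{bait.tol} Da; nearest feature is {nearest}"
        )
    if not dataset.metadata.get("tic_normalized"):
        warnings.warn("dataset is not TIC-normalized; PCC values reflect raw intensities",
                      stacklevel=2)

    bait_img = extract_ion_image(dataset, bait.mz, bait.tol).values
    X = dataset.intensities
    bx = bait_img - bait_img.mean()
    bnorm = math.sqrt(float(bx @ bx))

    constant = X.max(axis=0) == X.min(axis=0)  # zero variance: PCC undefined
    Xc = X - X.mean(axis=0, keepdims=True)
    col_norms = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    with np.errstate(invalid="ignore", divide="ignore"):
        pccs = (bx @ Xc) / (bnorm * col_norms)
    pccs[constant] = np.nan
    if bnorm == 0 or bait_img.max() == bait_img.min():
        pccs = np.full(dataset.n_features, np.nan)
    defined = np.isfinite(pccs)

    df = pd.DataFrame({"feature_mz": dataset.mz_axis[defined], "pcc": pccs[defined]})
    df = df.sort_values(["pcc", "feature_mz"], ascending=[False, True], kind="mergesort")
    df = df.head(top_n).reset_index(drop=True)
    return ColocalizationResult(
        bait=bait,
        entries=df,
        top_n=top_n,
        n_undefined=int((~defined).sum()),
        n_pixels=dataset.n_pixels,
        dataset_id=id(dataset),
        metadata={"n_features": dataset.n_features},
    )


def classify_bands(result: ColocalizationResult, bands: ThresholdBands | None = None) -> dict:
    """Partition ranked entries into ``high`` / ``moderate`` / ``other``.

    Band edges are inclusive on the lower side: pcc == ``bands.high``
    lands in ``high``. The partition is exhaustive and disjoint over the
    defined entries.
    """
    bands = bands or ThresholdBands()
    df = result.entries
    high = df[df["pcc"] >= bands.high]
    moderate = df[(df["pcc"] >= bands.moderate_low) & (df["pcc"] < bands.high)]
    other = df[df["pcc"] < bands.moderate_low]
    return {"high": high, "moderate": moderate, "other": other}


def bait_cutoff(bait: BaitQuery, margin: float = DEFAULT_CUTOFF_MARGIN) -> float:
    """Default feature-reduction cutoff: bait m/z plus an adduct margin.

    Singly charged fragments cannot exceed the precursor m/z, but alkali
    adducts sit above it; +40 Da keeps K+ adducts (+37.956) in range.
    """
    return bait.mz + margin


def reduce_features(dataset: MSIDataset, max_mz: float) -> MSIDataset:
    """Keep features with m/z ≤ ``max_mz`` (inclusive); pixels unchanged."""
    keep = dataset.mz_axis <= max_mz
    if not keep.any():
        raise ValueError(f"no features at or below m/z {max_mz}")
    meta = dict(dataset.metadata)
    meta.setdefault("reductions", []).append(
        {"op": "reduce_features", "max_mz": max_mz,
         "n_before": dataset.n_features, "n_after": int(keep.sum())}
    )
    return MSIDataset(dataset.coords, dataset.intensities[:, keep],
                      dataset.mz_axis[keep], dataset.pixel_order, meta)


def subsample_pixels(dataset: MSIDataset, n: int) -> MSIDataset:
    """Keep every nth pixel in acquisition order, starting from the first.

    The retained pixel count is ceil(n_pixels / n); the feature axis is
    unchanged. n = 1 is the identity.
    """
    if n < 1:
        raise ValueError("subsampling step must be >= 1")
    order = np.argsort(dataset.pixel_order)
    idx = order[::n]
    return dataset.select_pixels(
        np.sort(idx), note={"op": "subsample_pixels", "n": n, "n_pixels": int(len(idx))}
    )


def parse_roi(text: str):
    """Parse an ROI string ``"x1:x2,y1:y2"`` into a rectangle tuple."""
    try:
        xs, ys = text.split(",")
        x1, x2 = (int(v) for v in xs.split(":"))
        y1, y2 = (int(v) for v in ys.split(":"))
    except ValueError as exc:
        raise ValueError(f"cannot parse ROI {text!r}; expected 'x1:x2,y1:y2'") from exc
    return (x1, x2, y1, y2)


def roi_filter(dataset: MSIDataset, roi) -> MSIDataset:
    """Restrict the dataset to a region of interest.

    ``roi`` may be a rectangle *tuple* ``(x1, x2, y1, y2)``
    (boundary-inclusive), a polygon as a sequence of ≥3 (x, y) vertex
    pairs (boundary-inclusive, even-odd interior rule for simple
    polygons), or an explicit list/array of pixel row indices.
    """
    coords = dataset.coords
    is_pairs = (
        not isinstance(roi, tuple)
        and len(roi) > 0
        and isinstance(roi[0], (tuple, list, np.ndarray))
    )
    if isinstance(roi, tuple) and len(roi) == 4 and np.isscalar(roi[0]):
        x1, x2, y1, y2 = roi
        mask = (
            (coords[:, 0] >= min(x1, x2)) & (coords[:, 0] <= max(x1, x2))
            & (coords[:, 1] >= min(y1, y2)) & (coords[:, 1] <= max(y1, y2))
        )
        idx = np.nonzero(mask)[0]
        note = {"op": "roi", "kind": "rectangle", "roi": list(roi)}
    elif is_pairs:
        from shapely.geometry import Point, Polygon

        poly = Polygon([(float(x), float(y)) for x, y in roi])
        mask = np.array([poly.covers(Point(float(x), float(y))) for x, y in coords])
        idx = np.nonzero(mask)[0]
        note = {"op": "roi", "kind": "polygon", "n_vertices": len(roi)}
    else:
        idx = np.asarray(sorted(int(i) for i in roi))
        if len(idx) and (idx.min() < 0 or idx.max() >= dataset.n_pixels):
            raise ValueError("pixel indices out of range")
        note = {"op": "roi", "kind": "pixel_set", "n": int(len(idx))}
    if len(idx) == 0:
        raise ValueError("ROI does not intersect the pixel grid")
    note["n_pixels"] = int(len(idx))
    return dataset.select_pixels(idx, note=note)
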