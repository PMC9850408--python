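"""MSI data model, imzML I/O, and minimal preprocessing.

The central object is :class:`MSIDataset`: a pixels × features intensity
matrix with 1-based grid coordinates and an ascending feature m/z axis.
Preprocessing covers TIC normalization, mean-spectrum peak picking,
single-linkage peak alignment, linear mass recalibration, and ion-image
extraction/rendering. It is deliberately minimal: no baseline correction,
resampling, or vendor-format support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .chem import monoisotopic_mass

__all__ = [
    "MSIDataset",
    "IonImage",
    "PreprocessConfig",
    "read_imzml",
    "write_imzml",
    "tic_normalize",
    "pick_peaks",
    "align_features",
    "recalibrate",
    "extract_ion_image",
    "render_ion_image",
]

#: Scale factor turning a median absolute deviation into a Gaussian sigma.
MAD_TO_SIGMA = 1.4826


@dataclass
class MSIDataset:
    """Pixels × features intensity matrix with coordinates and m/z axis.

    ``coords`` are 1-based (x, y) grid indices in acquisition order;
    ``intensities[i, j]`` is the intensity of feature ``j`` at pixel ``i``;
    ``mz_axis`` is strictly ascending. ``pixel_order`` records acquisition
    order (defaults to 0..n−1) so that pixel subsetting stays traceable.
    """

    coords: np.ndarray  # (n_pixels, 2) int
    intensities: np.ndarray  # (n_pixels, n_features) float
    mz_axis: np.ndarray  # (n_features,) float, ascending
    pixel_order: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n_pixels, 2) array")
        n_pix, n_feat = self.intensities.shape
        if len(self.coords) != n_pix:
            raise ValueError("coords and intensity rows disagree")
        if len(self.mz_axis) != n_feat:
            raise ValueError("mz_axis and intensity columns disagree")
        if n_feat and (np.any(self.mz_axis <= 0) or np.any(np.diff(self.mz_axis) <= 0)):
            raise ValueError("mz_axis must be strictly ascending and positive")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")
        if len(np.unique(self.coords, axis=0)) != n_pix:
            raise ValueError("pixel coordinates must be unique")
        if self.pixel_order is None:
            self.pixel_order = np.arange(n_pix)
        else:
            self.pixel_order = np.asarray(self.pixel_order, dtype=int)
            if len(self.pixel_order) != n_pix:
                raise ValueError("pixel_order length must equal n_pixels")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def select_pixels(self, idx: np.ndarray, note: str | None = None) -> "MSIDataset":
        """Dataset restricted to pixel rows ``idx`` (features unchanged)."""
        meta = dict(self.metadata)
        if note:
            meta.setdefault("reductions", []).append(note)
        return MSIDataset(
            self.coords[idx], self.intensities[idx], self.mz_axis,
            self.pixel_order[idx], meta,
        )


@dataclass
class IonImage:
    """One binned ion's intensity over the pixels of a dataset."""

    mz: float
    tol: float
    values: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.coords):
            raise ValueError("values must align with coords")
        if np.any(self.values < 0):
            raise ValueError("ion-image intensities must be non-negative")


@dataclass
class PreprocessConfig:
    """Preprocessing knobs: S/N threshold, alignment bin width, TIC target."""

    snr_min: float = 6.0
    bin_tol: float = 0.003
    tic_target: float | str = "mean"
    recal_refs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.snr_min <= 0 or self.bin_tol <= 0:
            raise ValueError("snr_min and bin_tol must be positive")


def read_imzml(path, bin_tol: float = 0.003) -> MSIDataset:
    """Read an imzML file (continuous or processed mode) into an MSIDataset.

    Continuous-mode files use the shared m/z axis directly. Processed-mode
    files (per-pixel centroid lists) are passed through
    :func:`align_features` with gap threshold ``bin_tol`` to form a common
    axis. Pixel order follows spectrum order in the file.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise ValueError(f"cannot parse imzML file {path}: {exc}") from exc

    n = len(parser.coordinates)
    if n == 0:
        raise ValueError(f"imzML file {path} contains no spectra")

    spectra = []
    for i in range(n):
        try:
            mzs, ints = parser.getspectrum(i)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"ill-formed spectrum at index {i} in {path}: {exc}") from exc
        spectra.append((np.asarray(mzs, float), np.asarray(ints, float)))
    coords = np.array([(c[0], c[1]) for c in parser.coordinates], dtype=int)

    first_mz = spectra[0][0]
    continuous = all(len(mz) == len(first_mz) and np.array_equal(mz, first_mz) for mz, _ in spectra)
    meta = {"source": str(path), "mode": "continuous" if continuous else "processed"}
    if continuous:
        order = np.argsort(first_mz)
        intensities = np.stack([ints[order] for _, ints in spectra])
        return MSIDataset(coords, np.clip(intensities, 0, None), first_mz[order], metadata=meta)
    mz_axis, intensities = align_features(spectra, bin_tol)
    return MSIDataset(coords, intensities, mz_axis, metadata=meta)


def align_features(spectra, bin_tol: float = 0.003):
    """Align per-pixel centroid lists onto a common feature axis.

    Single-linkage clustering with a gap threshold: pooled centroid m/z are
    sorted and split wherever two consecutive values differ by more than
    ``bin_tol``. Each cluster becomes one feature whose representative m/z
    is the intensity-weighted mean of its members. Returns
    ``(mz_axis, intensities)``.
    """
    all_mz, all_int, all_pix = [], [], []
    for i, (mzs, ints) in enumerate(spectra):
        all_mz.append(np.asarray(mzs, float))
        all_int.append(np.asarray(ints, float))
        all_pix.append(np.full(len(mzs), i))
    mz = np.concatenate(all_mz)
    inten = np.concatenate(all_int)
    pix = np.concatenate(all_pix)
    if mz.size == 0:
        raise ValueError("no centroids to align")

    order = np.argsort(mz)
    mz, inten, pix = mz[order], inten[order], pix[order]
    # new cluster wherever the sorted gap exceeds the threshold
    labels = np.concatenate([[0], np.cumsum(np.diff(mz) > bin_tol)])
    n_clusters = labels[-1] + 1

    weights = np.where(inten > 0, inten, 1e-12)  # weight zeros negligibly, not invalidly
    wsum = np.bincount(labels, weights=weights, minlength=n_clusters)
    mz_axis = np.bincount(labels, weights=weights * mz, minlength=n_clusters) / wsum

    intensities = np.zeros((len(spectra), n_clusters))
    np.add.at(intensities, (pix, labels), inten)
    return mz_axis, intensities


def write_imzml(dataset: MSIDataset, path) -> None:
    """Write a continuous-mode imzML file (plus its .ibd binary sidecar).

    Coordinates and the m/z axis round-trip losslessly (float64);
    intensities are stored as float32 (≤1e-4 relative round-trip error).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if dataset.n_features == 0:
        raise ValueError("refusing to write a dataset with no features")
    with ImzMLWriter(str(path), mode="continuous") as writer:
        for i in range(dataset.n_pixels):
            x, y = dataset.coords[i]
            writer.addSpectrum(dataset.mz_axis, dataset.intensities[i], (int(x), int(y), 1))


def tic_normalize(dataset: MSIDataset, target: float | str = "mean") -> MSIDataset:
    """Scale each pixel so its total ion current equals ``target``.

    ``target="mean"`` uses the mean TIC over pixels with positive TIC.
    Zero-TIC pixels are kept as zeros (so pixel indexing is stable for
    subsampling) and their count recorded in metadata. Idempotent.
    """
    tic = dataset.intensities.sum(axis=1)
    positive = tic > 0
    if not positive.any():
        raise ValueError("cannot TIC-normalize an all-zero dataset")
    target_value = float(tic[positive].mean()) if target == "mean" else float(target)
    if target_value <= 0:
        raise ValueError("TIC target must be positive")
    scale = np.ones_like(tic)
    scale[positive] = target_value / tic[positive]
    meta = dict(dataset.metadata)
    meta.update(
        tic_normalized=True,
        tic_target=target_value,
        zero_tic_pixels=int((~positive).sum()),
    )
    return replace(
        dataset,
        intensities=dataset.intensities * scale[:, None],
        metadata=meta,
        coords=dataset.coords.copy(),
        pixel_order=dataset.pixel_order.copy(),
    )


def pick_peaks(mz_axis, mean_spectrum=None, config: PreprocessConfig | None = None, dataset: MSIDataset | None = None):
    """Detect features on the mean spectrum at a signal-to-noise threshold.

    Local maxima of the mean spectrum are retained when
    height / (1.4826 × MAD of the mean spectrum) ≥ ``config.snr_min``.
    Accepts either ``(mz_axis, mean_spectrum)`` or ``dataset=``. Returns a
    list of ``(mz, height, snr)`` tuples; a flat spectrum yields an empty
    list with a warning.
    """
    from scipy.signal import find_peaks

    config = config or PreprocessConfig()
    if dataset is not None:
        mz_axis = dataset.mz_axis
        mean_spectrum = dataset.intensities.mean(axis=0)
    mz_axis = np.asarray(mz_axis, float)
    spec = np.asarray(mean_spectrum, float)

    mad = np.median(np.abs(spec - np.median(spec)))
    noise = MAD_TO_SIGMA * mad
    if noise == 0 and spec.max() == spec.min():
        warnings.warn("flat mean spectrum: no peaks detected", stacklevel=2)
        return []
    if noise == 0:  # sparse centroid data: fall back to nonzero MAD
        nz = spec[spec > 0]
        noise = MAD_TO_SIGMA * np.median(np.abs(nz - np.median(nz))) or float(nz.min())

    peaks, props = find_peaks(spec, height=0)
    out = []
    for idx, height in zip(peaks, props["peak_heights"]):
        snr = height / noise
        if snr >= config.snr_min:
            out.append((float(mz_axis[idx]), float(height), float(snr)))
    return out


def recalibrate(dataset: MSIDataset, refs, window: float = 0.01) -> MSIDataset:
    """Correct the m/z axis against known reference masses.

    ``refs`` is a list of true m/z values (floats or formula strings whose
    neutral monoisotopic mass is used), or ``(search_mz, true_mz)`` pairs
    when the observed position differs from the truth by more than
    ``window``. Each reference is matched to the nearest axis feature
    within ``window`` Da. One matched reference fits an offset; two or
    more fit a linear map (slope + offset) by least squares. Residuals at
    the references are recorded in metadata.
    """
    matches = []  # (observed, true)
    searched = []
    for ref in refs:
        if isinstance(ref, tuple):
            search, true = float(ref[0]), float(ref[1])
        else:
            true = monoisotopic_mass(ref) if isinstance(ref, str) else float(ref)
            search = true
        searched.append((search - window, search + window))
        j = int(np.argmin(np.abs(dataset.mz_axis - search)))
        if abs(dataset.mz_axis[j] - search) <= window:
            matches.append((float(dataset.mz_axis[j]), true))
    if not matches:
        raise ValueError(f"no recalibration reference matched; windows searched: {searched}")

    obs = np.array([m[0] for m in matches])
    true = np.array([m[1] for m in matches])
    if len(matches) == 1:
        slope, offset = 1.0, float(true[0] - obs[0])
    else:
        slope, offset = np.polyfit(obs, true, 1)
    new_axis = slope * dataset.mz_axis + offset
    residuals = slope * obs + offset - true
    meta = dict(dataset.metadata)
    meta["recalibration"] = {
        "slope": float(slope),
        "offset": float(offset),
        "n_refs": len(matches),
        "residuals_da": residuals.tolist(),
    }
    return replace(
        dataset,
        mz_axis=new_axis,
        metadata=meta,
        coords=dataset.coords.copy(),
        intensities=dataset.intensities.copy(),
        pixel_order=dataset.pixel_order.copy(),
    )


def extract_ion_image(dataset: MSIDataset, mz: float, tol: float = 0.003) -> IonImage:
    """Sum feature intensities within ``mz ± tol`` per pixel.

    The ±tol bin mirrors how single-ion images are rendered from
    high-resolution MSI data. An empty window yields an all-zero image
    with a warning.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lo = np.searchsorted(dataset.mz_axis, mz - tol, side="left")
    hi = np.searchsorted(dataset.mz_axis, mz + tol, side="right")
    if hi <= lo:
        warnings.warn(f"no features within {mz} ± {tol} Da; returning zero image", stacklevel=2)
        values = np.zeros(dataset.n_pixels)
    else:
        values = dataset.intensities[:, lo:hi].sum(axis=1)
    return IonImage(mz=mz, tol=tol, values=values, coords=dataset.coords)


def _to_grid(image: IonImage) -> np.ndarray:
    coords = image.coords
    if np.any(coords < 1):
        raise ValueError("coordinates must be 1-based positive grid indices")
    w, h = coords[:, 0].max(), coords[:, 1].max()
    grid = np.zeros((h, w))
    grid[coords[:, 1] - 1, coords[:, 0] - 1] = image.values
    return grid


def render_ion_image(image: IonImage, path=None, smoothing: bool = True, contrast: bool = True):
    """Rasterize an ion image onto its pixel grid; optionally save a PNG.

    Smoothing applies a Gaussian kernel of σ = 1 pixel (mass-preserving up
    to edge effects); contrast enhancement clips at the 2nd and 98th
    intensity percentiles. Returns the rendered 2-D array.
    """
    from scipy.ndimage import gaussian_filter

    grid = _to_grid(image)
    if smoothing:
        grid = gaussian_filter(grid, sigma=1.0, mode="constant")
    if contrast:
        lo, hi = np.percentile(grid, [2, 98])
        if hi > lo:
            grid = np.clip(grid, lo, hi)
    if path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        plt.imsave(str(path), grid, cmap="viridis", origin="lower")
    return grid
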