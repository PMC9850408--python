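"""Pseudo-MS/MS spectrum construction and spectral export.

A pseudo-MS/MS spectrum collects the mass features highly colocalized
with a bait ion (PCC at or above a threshold) and assigns each the
arithmetic mean of its intensity over the pixels used in the correlation.
The result mimics a low-collision-energy tandem spectrum of the bait and
can be exported as MSP, MGF, or CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coloc import BaitQuery, ColocalizationResult
from .msi import MSIDataset

__all__ = ["PseudoSpectrum", "build_pseudo_spectrum", "export_spectrum", "read_spectrum_csv"]


@dataclass
class PseudoSpectrum:
    """(m/z, mean intensity, PCC) peak list attributed to one bait ion."""

    bait: BaitQuery
    peaks: pd.DataFrame  # columns: mz, intensity, pcc; sorted by mz
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.peaks["mz"].is_monotonic_increasing):
            self.peaks = self.peaks.sort_values("mz").reset_index(drop=True)
        if (self.peaks["intensity"] < 0).any():
            raise ValueError("peak intensities must be non-negative")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def build_pseudo_spectrum(
    dataset: MSIDataset,
    result: ColocalizationResult,
    threshold: float = 0.9,
) -> PseudoSpectrum:
    """Assemble the pseudo-MS/MS spectrum of ``result``'s bait.

    Every ranked entry with PCC ≥ ``threshold`` becomes a peak whose
    intensity is the mean of that feature's intensity over all pixels of
    ``dataset`` — the same pixel set the correlation used (checked via
    provenance), so reduction strategies propagate consistently. The
    bait's own feature carries PCC 1 and is always included.
    """
    if result.dataset_id is not None and result.dataset_id != id(dataset):
        raise ValueError("result was not computed on this dataset")
    if result.n_pixels != dataset.n_pixels:
        raise ValueError("pixel set differs from the one used for correlation")

    selected = result.entries[result.entries["pcc"] >= threshold]
    if selected.empty:
        raise ValueError(
            f"no colocalized features at PCC >= {threshold}; consider lowering the threshold"
        )
    cols = np.searchsorted(dataset.mz_axis, selected["feature_mz"].to_numpy())
    intensities = dataset.intensities[:, cols].mean(axis=0)
    peaks = pd.DataFrame(
        {"mz": selected["feature_mz"].to_numpy(), "intensity": intensities,
         "pcc": selected["pcc"].to_numpy()}
    )
    prov = {
        "threshold": threshold,
        "n_pixels": dataset.n_pixels,
        "tic_normalized": bool(dataset.metadata.get("tic_normalized", False)),
        "reductions": dataset.metadata.get("reductions", []),
    }
    return PseudoSpectrum(bait=result.bait, peaks=peaks, provenance=prov)


def export_spectrum(spec: PseudoSpectrum, fmt: str, path) -> None:
    """Write a pseudo-spectrum as ``"msp"``, ``"mgf"``, or ``"csv"``.

    The precursor m/z (MGF PEPMASS, MSP PrecursorMZ) is the bait m/z;
    intensities are written at full precision so a CSV round-trip
    reproduces the peak list exactly.
    """
    if spec.n_peaks == 0:
        raise ValueError("cannot export an empty spectrum")
    fmt = fmt.lower()
    if fmt == "csv":
        spec.peaks.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "mgf":
        from pyteomics import mgf

        spectrum = {
            "m/z array": spec.peaks["mz"].to_numpy(),
            "intensity array": spec.peaks["intensity"].to_numpy(),
            "params": {
                "title": spec.bait.label or f"pseudo-MS/MS of m/z {spec.bait.mz}",
                "pepmass": spec.bait.mz,
                "charge": "1+",
            },
        }
        mgf.write([spectrum], str(path), file_mode="w")
    elif fmt == "msp":
        with open(path, "w") as fh:
            name = spec.bait.label or f"pseudo-MS/MS m/z {spec.bait.mz}"
            fh.write(f"Name: {name}\n")
            fh.write(f"PrecursorMZ: {spec.bait.mz:.17g}\n")
            if spec.bait.formula:
                fh.write(f"Formula: {spec.bait.formula}\n")
            fh.write(f"Num Peaks: {spec.n_peaks}\n")
            for row in spec.peaks.itertuples(index=False):
                fh.write(f"{row.mz:.17g} {row.intensity:.17g}\n")
            fh.write("\n")
    else:
        raise ValueError(f"unknown spectral format {fmt!r}; use msp, mgf, or csv")


def read_spectrum_csv(path) -> pd.DataFrame:
    """Read back a CSV peak list written by :func:`export_spectrum`."""
    return pd.read_csv(path, float_precision="round_trip")
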