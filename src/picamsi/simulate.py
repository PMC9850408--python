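"""Synthetic MALDI-MSI data with known ground truth.

Generates a pixels × features dataset in which every feature has a known
origin: a metabolite precursor ion, its in-source fragments at fixed
yields, alkali adducts, multimers, 13C isotope satellites, matrix-cluster
ions enriched off-tissue, or a constant-intensity artifact. All ions of
one metabolite are pixel-wise proportional by construction (intensity
fractions of a shared abundance field), so their mutual Pearson
correlation is exactly 1 before noise — the property the colocalization
analysis exploits. Multiplicative log-normal noise and an additive floor
then degrade that proportionality realistically.

The default configuration sketches a fruit section on a glass slide: a
"skin" band hosting a rutin-like glycoside (precursor + two neutral-loss
fragments + Na adduct + isotopes), a "flesh" interior with a second
metabolite, matrix clusters concentrated on the exposed slide (tissue
absorbs matrix, so matrix ions anticorrelate with tissue ions), and one
constant-on-tissue artifact feature demonstrating that co-occurrence
alone does not imply correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import chem
from .msi import MSIDataset

__all__ = [
    "MetaboliteSpec",
    "SimConfig",
    "simulate_msi",
    "make_artifact_feature",
    "default_config",
    "derived_features",
]


@dataclass
class MetaboliteSpec:
    """One simulated metabolite and the ion species it emits.

    ``fragments`` are (neutral-loss mass in Da, yield fraction) pairs:
    the fragment ion appears at precursor m/z − loss with intensity
    yield × abundance. ``adducts`` maps "H"/"Na"/"K" to the fraction of
    abundance each cationized species carries; ``multimers`` maps k to the
    [kM+H]+ fraction. ``isotope_depth`` heavy-isotope satellites are added
    per species using the shared isotope-pattern model.
    """

    name: str
    formula: str
    region: str
    base: float = 100.0
    fragments: list[tuple[float, float]] = field(default_factory=list)
    adducts: dict[str, float] = field(default_factory=lambda: {"H": 1.0})
    multimers: dict[int, float] = field(default_factory=dict)
    isotope_depth: int = 1

    def __post_init__(self) -> None:
        for _, y in self.fragments:
            if not 0 <= y <= 1:
                raise ValueError(f"fragment yield out of [0,1] for {self.name}")
        for f in list(self.adducts.values()) + list(self.multimers.values()):
            if not 0 <= f <= 1:
                raise ValueError(f"ion fraction out of [0,1] for {self.name}")


@dataclass
class SimConfig:
    """Scene description for the synthetic MSI generator.

    The grid is split into three nested regions by distance from the
    border: "slide" (outer ``slide_margin`` pixels, bare glass), "skin"
    (next ``skin_thickness`` pixels of tissue), and "flesh" (interior).
    ``field_amplitude`` is the log-scale standard deviation of the smooth
    per-metabolite abundance field (≈ one decade of dynamic range at 2σ);
    ``noise_sigma`` the per-pixel multiplicative log-normal σ; ``floor``
    the scale of the additive half-normal noise floor in intensity units.
    """

    grid: tuple[int, int] = (40, 40)
    slide_margin: int = 4
    skin_thickness: int = 4
    metabolites: list[MetaboliteSpec] = field(default_factory=list)
    matrix_species: list[tuple[float, float]] = field(default_factory=list)  # (mz, fraction)
    matrix_base: float = 150.0
    # tissue absorbs matrix, it does not eliminate it: relative matrix
    # signal remaining over tissue compared to bare slide
    matrix_tissue_fraction: float = 0.25
    artifact_features: list[tuple[float, float, str]] = field(default_factory=list)  # (mz, value, region)
    field_amplitude: float = 1.0
    field_smoothing: float = 3.0
    noise_sigma: float = 0.2
    # default 0: the dataset represents peak-picked, S/N-thresholded
    # intensities, where sub-noise signal is already zeroed; raise to
    # emulate raw-like data with a detector floor
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.grid
        if w < 2 or h < 2:
            raise ValueError("grid must be at least 2x2")
        if self.noise_sigma < 0 or self.floor < 0:
            raise ValueError("noise parameters must be non-negative")


def default_config(seed: int = 0, noise_sigma: float = 0.2) -> SimConfig:
    """The stock fruit-section scene used throughout the test suite."""
    dhb = chem.monoisotopic_mass("C7H6O4")
    h2o = chem.monoisotopic_mass("H2O")
    # matrix cluster series: [kDHB + H - kH2O]+
    matrix = [
        (chem.ion_mz(k * dhb - k * h2o, "[M+H]+"), frac)
        for k, frac in ((1, 1.0), (2, 0.6), (3, 0.4))
    ]
    rutin = MetaboliteSpec(
        name="rutin",
        formula="C27H30O16",
        region="skin",
        base=100.0,
        # deoxyhexose loss -> m/z 465.103; full rutinose loss -> aglycone 303.050
        fragments=[(146.057909, 0.4), (308.110732, 0.25)],
        adducts={"H": 1.0, "Na": 0.15},
        isotope_depth=1,
    )
    flesh_met = MetaboliteSpec(
        name="citrate-like",
        formula="C6H8O7",
        region="flesh",
        base=60.0,
        fragments=[(18.010565, 0.3)],
        adducts={"H": 1.0},
        isotope_depth=1,
    )
    # unstructured chemical background over the whole tissue: real MALDI
    # spectra are dense, so no single metabolite dominates the pixel TIC
    background = [
        MetaboliteSpec(
            name=f"background-{i}",
            formula=f"C{9 + 2 * i}H{14 + 2 * i}O{4 + (i % 4)}",
            region="tissue",
            base=35.0,
            adducts={"H": 1.0},
            isotope_depth=0,
        )
        for i in range(8)
    ]
    return SimConfig(
        metabolites=[rutin, flesh_met, *background],
        matrix_species=matrix,
        artifact_features=[(888.888, 500.0, "skin")],
        noise_sigma=noise_sigma,
        seed=seed,
    )


def region_masks(config: SimConfig) -> dict[str, np.ndarray]:
    """Boolean pixel masks for "slide", "skin", and "flesh" (row-major)."""
    w, h = config.grid
    xs = np.arange(1, w + 1)
    ys = np.arange(1, h + 1)
    X, Y = np.meshgrid(xs, ys)  # shape (h, w)
    edge_dist = np.minimum.reduce([X - 1, w - X, Y - 1, h - Y])
    slide = edge_dist < config.slide_margin
    skin = (edge_dist >= config.slide_margin) & (
        edge_dist < config.slide_margin + config.skin_thickness
    )
    flesh = edge_dist >= config.slide_margin + config.skin_thickness
    return {
        "slide": slide.ravel(),
        "skin": skin.ravel(),
        "flesh": flesh.ravel(),
        "tissue": (skin | flesh).ravel(),
    }


def _smooth_field(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Seeded log-Gaussian random field with spatial autocorrelation."""
    w, h = config.grid
    z = gaussian_filter(rng.standard_normal((h, w)), sigma=config.field_smoothing)
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return np.exp(config.field_amplitude * z).ravel()


def _fragment_isotope_formula(parent: chem.Formula, frag_mass: float, parent_mass: float) -> chem.Formula:
    """Carbon-count proxy formula for a fragment's isotope envelope.

    Fragment compositions are not tracked (only the neutral-loss mass is),
    so the 13C envelope is approximated by scaling the parent's carbon
    count by the fragment/parent mass ratio — adequate because A+1 is
    carbon-dominated for CHO metabolites.
    """
    n_c = max(1, round(parent.counts.get("C", 1) * frag_mass / parent_mass))
    return chem.Formula({"C": n_c, "H": 1})


def simulate_msi(config: SimConfig):
    """Generate an (MSIDataset, ground-truth table) pair.

    Per pixel p and metabolite m the latent abundance is
    A(m, p) = base × smooth log-Gaussian field × region mask, and every
    derived ion's noise-free intensity is A(m, p) × its fraction — hence
    pixel-wise proportional to the precursor. Observed intensity adds
    multiplicative LogNormal(0, σ²) noise and a half-normal additive
    floor. Bit-reproducible for a fixed seed.

    The ground truth is a DataFrame with one row per generated feature:
    ``feature_mz``, ``parent``, ``relation`` (precursor | fragment |
    adduct | multimer | isotope | matrix | artifact), ``region``, and
    ``detail``.
    """
    rng = np.random.default_rng(config.seed)
    masks = region_masks(config)
    w, h = config.grid
    n_pixels = w * h
    X, Y = np.meshgrid(np.arange(1, w + 1), np.arange(1, h + 1))
    coords = np.column_stack([X.ravel(), Y.ravel()])

    columns: list[np.ndarray] = []
    records: list[dict] = []

    def emit(mz: float, values: np.ndarray, parent: str, relation: str, region: str, detail: str = "") -> None:
        columns.append(values)
        records.append(
            {"feature_mz": mz, "parent": parent, "relation": relation,
             "region": region, "detail": detail}
        )

    proton = chem.ADDUCTS["[M+H]+"]
    cation_mass = {"H": chem.ELEMENT_MASS["H"], "Na": chem.ELEMENT_MASS["Na"], "K": chem.ELEMENT_MASS["K"]}

    for met in config.metabolites:
        if met.region not in masks:
            raise ValueError(f"unknown region {met.region!r} for metabolite {met.name}")
        mask = masks[met.region]
        abundance = met.base * _smooth_field(rng, config) * mask
        formula = chem.Formula.parse(met.formula)
        neutral_mass = chem.monoisotopic_mass(formula)

        species: list[tuple[float, float, str, str, chem.Formula]] = []
        for cat, frac in met.adducts.items():
            if frac <= 0:
                continue
            mz = chem.ion_mz(formula, chem.ADDUCTS[f"[M+{cat}]+"])
            relation = "precursor" if cat == "H" else "adduct"
            species.append((mz, frac, relation, f"[M+{cat}]+", formula))
        for k, frac in met.multimers.items():
            if frac <= 0:
                continue
            mz = (k * neutral_mass + cation_mass["H"] - chem.ELECTRON_MASS)
            species.append((mz, frac, "multimer", f"[{k}M+H]+", formula * k))
        precursor_mz = chem.ion_mz(formula, proton)
        for loss, yield_frac in met.fragments:
            if yield_frac <= 0:
                continue
            mz = precursor_mz - loss
            frag_formula = _fragment_isotope_formula(formula, mz, precursor_mz)
            species.append((mz, yield_frac, "fragment", f"-{loss:.4f} Da", frag_formula))

        for mz, frac, relation, detail, iso_formula in species:
            emit(mz, frac * abundance, met.name, relation, met.region, detail)
            if met.isotope_depth > 0:
                pattern = chem.isotope_pattern(iso_formula, n_peaks=met.isotope_depth + 1)
                for k in range(1, met.isotope_depth + 1):
                    emit(
                        mz + k * chem.C13_DELTA,
                        frac * pattern[k] * abundance,
                        met.name, "isotope", met.region, f"+{k} 13C of {detail}",
                    )

    if config.matrix_species:
        # one shared field: matrix clusters are mutually proportional,
        # concentrated on the bare slide and depleted (not absent) over
        # tissue, which absorbs part of the matrix coat
        matrix_weight = np.where(masks["slide"], 1.0, config.matrix_tissue_fraction)
        matrix_abundance = config.matrix_base * _smooth_field(rng, config) * matrix_weight
        for mz, frac in config.matrix_species:
            emit(mz, frac * matrix_abundance, "matrix", "matrix", "slide", "matrix cluster")

    noisefree = np.column_stack(columns) if columns else np.zeros((n_pixels, 0))
    if config.noise_sigma > 0:
        noisefree = noisefree * rng.lognormal(0.0, config.noise_sigma, size=noisefree.shape)
    if config.floor > 0:
        noisefree = noisefree + config.floor * np.abs(rng.standard_normal(noisefree.shape))

    # constant-on-mask artifacts carry no noise: their point is exact
    # co-occurrence with zero intensity correlation
    for mz, value, region in config.artifact_features:
        mask = masks[region]
        columns_art = np.where(mask, float(value), 0.0)
        noisefree = np.column_stack([noisefree, columns_art])
        records.append(
            {"feature_mz": mz, "parent": "artifact", "relation": "artifact",
             "region": region, "detail": f"constant {value}"}
        )

    truth = pd.DataFrame.from_records(records)
    order = np.argsort(truth["feature_mz"].to_numpy(), kind="mergesort")
    truth = truth.iloc[order].reset_index(drop=True)
    intensities = noisefree[:, order]
    mz_axis = truth["feature_mz"].to_numpy()

    gaps = np.diff(mz_axis)
    if np.any(gaps < 1e-3):
        warnings.warn("generated features closer than 1 mDa; intentional collision assumed",
                      stacklevel=2)
        # merge exact collisions so the m/z axis stays strictly ascending
        keep = np.concatenate([[True], gaps > 0])
        for j in np.nonzero(~keep)[0]:
            intensities[:, j - 1] += intensities[:, j]
        intensities = intensities[:, keep]
        truth = truth.iloc[np.nonzero(keep)[0]].reset_index(drop=True)
        mz_axis = truth["feature_mz"].to_numpy()

    dataset = MSIDataset(
        coords=coords,
        intensities=intensities,
        mz_axis=mz_axis,
        metadata={"source": "simulate_msi", "seed": config.seed,
                  "grid": list(config.grid), "noise_sigma": config.noise_sigma},
    )
    return dataset, truth


def derived_features(truth: pd.DataFrame, parent: str, include_precursor: bool = False) -> pd.DataFrame:
    """Ground-truth rows for ions derived from one metabolite.

    Derived = fragments, adducts, multimers, and isotopes; the precursor
    ion itself is included only when ``include_precursor`` is set.
    """
    relations = {"fragment", "adduct", "multimer", "isotope"}
    if include_precursor:
        relations.add("precursor")
    return truth[(truth["parent"] == parent) & truth["relation"].isin(relations)]


def make_artifact_feature(dataset: MSIDataset, mask, value: float, mz: float = 888.888):
    """Append one constant-on-mask feature to a dataset.

    The new feature equals ``value`` on masked pixels and 0 elsewhere —
    perfect spatial co-occurrence with anything nonzero on the mask, but
    no intensity relationship. A universal mask is refused because the
    resulting column would be constant over all pixels (undefined PCC).
    Returns ``(dataset, mz)``.
    """
    mask = np.asarray(mask, bool)
    if len(mask) != dataset.n_pixels:
        raise ValueError("mask length must equal the pixel count")
    if not mask.any():
        raise ValueError("mask is empty")
    if mask.all():
        raise ValueError("universal mask would create a zero-variance feature")
    column = np.where(mask, float(value), 0.0)
    j = int(np.searchsorted(dataset.mz_axis, mz))
    if j < dataset.n_features and abs(dataset.mz_axis[j] - mz) < 1e-9:
        raise ValueError(f"feature at m/z {mz} already exists")
    new_axis = np.insert(dataset.mz_axis, j, mz)
    new_int = np.insert(dataset.intensities, j, column, axis=1)
    meta = dict(dataset.metadata)
    meta.setdefault("artifacts", []).append({"mz": mz, "value": float(value)})
    return MSIDataset(dataset.coords, new_int, new_axis, dataset.pixel_order, meta), mz
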