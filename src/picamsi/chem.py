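"""Exact-mass chemistry for ion annotation.

Monoisotopic masses, adduct/multimer ion m/z, greedy relation assignment
(isotopes, alkali adducts, multimers, neutral losses), bounded molecular
formula enumeration, and coarse (nominal-mass) isotope pattern simulation.

All masses are in daltons (Da); mass tolerances are in parts per million
(ppm) relative to the observed m/z unless stated otherwise.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Formula",
    "AdductSpec",
    "AnnotationHit",
    "ADDUCTS",
    "NEUTRAL_LOSSES",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "C13_DELTA",
    "monoisotopic_mass",
    "ion_mz",
    "annotate_relations",
    "formula_candidates",
    "isotope_pattern",
]

# Monoisotopic masses of the light isotope of each supported element (Da).
ELEMENT_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

ELECTRON_MASS = 0.00054857990
PROTON_MASS = ELEMENT_MASS["H"] - ELECTRON_MASS

#: m/z spacing of one 13C isotope substitution.
C13_DELTA = 1.0033548

# Heavy-isotope abundances relative to the whole element, keyed by element
# and nominal mass shift. Aggregated nominal-mass treatment: fine structure
# (e.g. 13C vs 15N splitting) is not resolved.
HEAVY_ISOTOPES: dict[str, dict[int, float]] = {
    "C": {1: 0.0107},
    "H": {1: 0.000115},
    "N": {1: 0.00364},
    "O": {1: 0.00038, 2: 0.00205},
    "S": {1: 0.0075, 2: 0.0429},
    # Na, K, P are monoisotopic.
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Elemental composition with an optional net charge.

    ``counts`` maps element symbols to non-negative atom counts; ``charge``
    is the signed integer charge of the species (0 for neutrals).
    """

    counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if el not in ELEMENT_MASS:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}")
        if not any(self.counts.values()):
            raise ValueError("empty formula: at least one atom required")

    @classmethod
    def parse(cls, text: str, charge: int = 0) -> "Formula":
        """Parse a Hill-style formula string such as ``"C27H30O16"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {pos}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts, charge)

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts, self.charge + other.charge)

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self.counts.items()}, self.charge * k)

    def __str__(self) -> str:
        parts = []
        for el in ("C", "H"):
            if self.counts.get(el):
                parts.append(f"{el}{self.counts[el] if self.counts[el] > 1 else ''}")
        for el in sorted(self.counts):
            if el in ("C", "H") or not self.counts[el]:
                continue
            parts.append(f"{el}{self.counts[el] if self.counts[el] > 1 else ''}")
        return "".join(parts)


@dataclass(frozen=True)
class AdductSpec:
    """Ionization rule: ``k·M + delta`` with a charge change.

    ``delta_mass`` is the mass added to ``k`` copies of the neutral
    (negative for losses); ``charge`` is the resulting ion charge;
    ``k`` the multimer factor. A radical cation is ``delta_mass=0,
    charge=+1`` (electron removal only).
    """

    name: str
    delta_mass: float
    charge: int
    k: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("ionic species must carry a nonzero charge")


_H2O = 2 * ELEMENT_MASS["H"] + ELEMENT_MASS["O"]

ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", ELEMENT_MASS["H"], +1),
    "[M+Na]+": AdductSpec("[M+Na]+", ELEMENT_MASS["Na"], +1),
    "[M+K]+": AdductSpec("[M+K]+", ELEMENT_MASS["K"], +1),
    "[M]+": AdductSpec("[M]+", 0.0, +1),
    "[2M+H]+": AdductSpec("[2M+H]+", ELEMENT_MASS["H"], +1, k=2),
    "[2M+Na]+": AdductSpec("[2M+Na]+", ELEMENT_MASS["Na"], +1, k=2),
    "[3M+H]+": AdductSpec("[3M+H]+", ELEMENT_MASS["H"], +1, k=3),
    "[M+H-H2O]+": AdductSpec("[M+H-H2O]+", ELEMENT_MASS["H"] - _H2O, +1),
}

# Common neutral losses (Da). Editable/extensible via annotate_relations.
NEUTRAL_LOSSES: dict[str, float] = {
    "H2O": 18.010565,
    "deoxyhexose": 146.057909,
    "hexose": 162.052824,
    "rutinose": 308.110733,  # deoxyhexose + hexose, the full glycoside loss
    "pentose": 132.042259,
    "trimethylamine": 59.073499,
    "PE head (C2H8NO4P)": 141.019094,
    "CO": 27.994915,
    "CO2": 43.989829,
}

# Mass shifts from a protonated species to its alkali-metal congeners.
NA_MINUS_H = ELEMENT_MASS["Na"] - ELEMENT_MASS["H"]  # +21.981944
K_MINUS_H = ELEMENT_MASS["K"] - ELEMENT_MASS["H"]  # +37.955881


def monoisotopic_mass(formula: Formula | str) -> float:
    """Neutral monoisotopic mass of a formula in Da (charge ignored)."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    return sum(ELEMENT_MASS[el] * n for el, n in formula.counts.items())


def ion_mz(neutral: Formula | str | float, adduct: AdductSpec | str) -> float:
    """m/z of an ion formed from a neutral under an adduct rule.

    ``neutral`` may be a :class:`Formula`, a formula string, or a neutral
    monoisotopic mass in Da. m/z = (k·M + Δm − z·m_e) / |z| for cations
    (electrons are subtracted per positive charge, added per negative).
    """
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if isinstance(neutral, (Formula, str)):
        mass = monoisotopic_mass(neutral)
    else:
        mass = float(neutral)
    z = adduct.charge
    return (adduct.k * mass + adduct.delta_mass - z * ELECTRON_MASS) / abs(z)


def _ppm(observed: float, expected: float) -> float:
    return (observed - expected) / expected * 1e6


@dataclass
class AnnotationHit:
    """One peak's assigned relation to the bait or another peak."""

    peak_mz: float
    relation: str  # precursor|isotope|adduct|multimer|neutral_loss|unassigned
    reference_mz: float | None
    ppm_error: float | None
    detail: str


def annotate_relations(
    peaks,
    bait_mz: float,
    bait_formula: Formula | str | None = None,
    tol_ppm: float = 5.0,
    loss_library: dict[str, float] | None = None,
    max_isotope: int = 3,
) -> list[AnnotationHit]:
    """Assign a relation type to every peak of a pseudo-MS/MS spectrum.

    Greedy, deterministic assignment in priority order: 13C isotope of an
    already-assigned peak (Δ = k·1.0033548, k ≤ ``max_isotope``) → alkali
    adduct of the bait (Na−H, K−H shifts) → multimer of the bait (k·M,
    k ≤ 3, H/Na/K cationization) → neutral loss from the bait against the
    loss library. Peaks are visited in ascending m/z so isotope parents are
    assigned before their satellites. Every peak receives exactly one hit;
    unmatched peaks are "unassigned", never an error.

    ``peaks`` is an iterable of m/z values (or objects with an ``mz``
    attribute). The bait peak itself, when present within tolerance, is
    labelled "precursor".
    """
    losses = NEUTRAL_LOSSES if loss_library is None else loss_library
    mzs = sorted(float(getattr(p, "mz", p)) for p in peaks)
    if not mzs:
        raise ValueError("spectrum has no peaks")

    if bait_formula is not None and isinstance(bait_formula, str):
        bait_formula = Formula.parse(bait_formula)
    # Neutral mass of the bait, assuming a protonated even-electron ion;
    # used only for multimer matching.
    if bait_formula is not None:
        neutral_mass = monoisotopic_mass(bait_formula)
    else:
        neutral_mass = bait_mz - PROTON_MASS

    hits: list[AnnotationHit] = []
    assigned: list[tuple[float, str]] = []  # (mz, relation) of non-unassigned peaks

    def within(observed: float, expected: float) -> bool:
        return abs(_ppm(observed, expected)) <= tol_ppm

    for mz in mzs:
        hit: AnnotationHit | None = None

        if within(mz, bait_mz):
            hit = AnnotationHit(mz, "precursor", bait_mz, _ppm(mz, bait_mz), "bait")

        if hit is None:  # isotope of any already-assigned peak
            for ref_mz, ref_rel in assigned:
                if ref_rel == "unassigned":
                    continue
                for k in range(1, max_isotope + 1):
                    exp = ref_mz + k * C13_DELTA
                    if within(mz, exp):
                        hit = AnnotationHit(mz, "isotope", ref_mz, _ppm(mz, exp), f"+{k} 13C")
                        break
                if hit:
                    break

        if hit is None:  # alkali adduct relative to the protonated bait
            for name, shift in (("Na adduct (Na-H)", NA_MINUS_H), ("K adduct (K-H)", K_MINUS_H)):
                exp = bait_mz + shift
                if within(mz, exp):
                    hit = AnnotationHit(mz, "adduct", bait_mz, _ppm(mz, exp), name)
                    break

        if hit is None:  # multimer of the bait neutral
            for k in (2, 3):
                for cat, dm in (("H", ELEMENT_MASS["H"]), ("Na", ELEMENT_MASS["Na"]), ("K", ELEMENT_MASS["K"])):
                    exp = k * neutral_mass + dm - ELECTRON_MASS
                    if within(mz, exp):
                        hit = AnnotationHit(mz, "multimer", bait_mz, _ppm(mz, exp), f"[{k}M+{cat}]+")
                        break
                if hit:
                    break

        if hit is None:  # neutral loss from the bait
            for name, loss in losses.items():
                exp = bait_mz - loss
                if exp > 0 and within(mz, exp):
                    hit = AnnotationHit(mz, "neutral_loss", bait_mz, _ppm(mz, exp), name)
                    break

        if hit is None:
            hit = AnnotationHit(mz, "unassigned", None, None, "")
        hits.append(hit)
        assigned.append((mz, hit.relation))

    return hits


def formula_candidates(
    mz: float,
    tol_ppm: float = 2.0,
    element_bounds: dict[str, tuple[int, int]] | None = None,
    charge: int = 1,
    rdbe_filter: bool = True,
    hc_filter: bool = True,
    max_space: int = 50_000_000,
) -> list[Formula]:
    """Enumerate ion formulas whose m/z falls within ``tol_ppm`` of ``mz``.

    The search space is the Cartesian product of per-element count ranges
    (``element_bounds``, default CHNOPS-free CHO bounds scaled to the target
    mass). Candidates are the *ion* formulas: their m/z is computed as
    monoisotopic mass minus ``charge`` electron masses, divided by |charge|.

    Heuristic filters (toggleable): ring-plus-double-bond equivalents
    RDBE = C − H/2 + N/2 + 1 ≥ 0, and elemental ratio 0.2 ≤ H/C ≤ 3.1.
    Results are sorted by absolute ppm error.
    """
    if charge == 0:
        raise ValueError("charge must be nonzero")
    if element_bounds is None:
        # generous CHO default scaled to the target mass
        cmax = int(mz / 12) + 1
        element_bounds = {"C": (0, cmax), "H": (0, 2 * cmax), "O": (0, int(mz / 16) + 1)}

    elements = list(element_bounds)
    ranges = [range(lo, hi + 1) for lo, hi in element_bounds.values()]
    space = 1
    for r in ranges:
        space *= len(r)
    if space > max_space:
        raise ValueError(
            f"search space of {space} formulas exceeds cap {max_space}; tighten element bounds"
        )

    target = mz * abs(charge) + charge * ELECTRON_MASS  # required sum of atomic masses
    tol_da = tol_ppm * 1e-6 * mz * abs(charge)
    masses = np.array([ELEMENT_MASS[el] for el in elements])

    # Vectorized enumeration in blocks over the last element (largest axis last
    # keeps blocks big); plain product is fine at the caps used in practice.
    out: list[tuple[float, Formula]] = []
    *head, last = ranges
    last_counts = np.arange(last.start, last.stop)
    last_mass = masses[-1] * last_counts
    for combo in itertools.product(*head) if head else [()]:
        base = float(np.dot(masses[:-1], combo)) if combo else 0.0
        total = base + last_mass
        ok = np.abs(total - target) <= tol_da
        for n_last in last_counts[ok]:
            counts = {el: int(c) for el, c in zip(elements, (*combo, n_last)) if c > 0}
            if not counts:
                continue
            f = Formula(counts, charge)
            c, h, n = counts.get("C", 0), counts.get("H", 0), counts.get("N", 0)
            if rdbe_filter and (c - h / 2 + n / 2 + 1) < 0:
                continue
            if hc_filter and c > 0 and not (0.2 <= h / c <= 3.1):
                continue
            ion = (monoisotopic_mass(f) - charge * ELECTRON_MASS) / abs(charge)
            out.append((abs(_ppm(mz, ion)), f))
    out.sort(key=lambda t: t[0])
    return [f for _, f in out]


def isotope_pattern(formula: Formula | str, n_peaks: int = 4) -> np.ndarray:
    """Relative A+k abundances (A ≡ 1) by nominal-mass convolution.

    Per element, the distribution of total nominal mass shift contributed
    by its atoms is the n-fold convolution of the single-atom distribution
    over heavy-isotope substitutions; element distributions are then
    convolved together. Aggregates by nominal mass (no fine structure).
    """
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    pattern = np.zeros(n_peaks)
    pattern[0] = 1.0
    for el, n in formula.counts.items():
        heavies = HEAVY_ISOTOPES.get(el)
        if not heavies or n == 0:
            continue
        single = np.zeros(n_peaks)
        single[0] = 1.0 - sum(heavies.values())
        for shift, p in heavies.items():
            if shift < n_peaks:
                single[shift] = p
        # single-atom distribution raised to the n-th convolution power
        el_dist = np.zeros(n_peaks)
        el_dist[0] = 1.0
        base = single.copy()
        k = n
        while k:
            if k & 1:
                el_dist = np.convolve(el_dist, base)[:n_peaks]
            base = np.convolve(base, base)[:n_peaks]
            k >>= 1
        pattern = np.convolve(pattern, el_dist)[:n_peaks]
    return pattern / pattern[0]
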