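"""Peptide chemistry: composition, mass, 15N labeling, isotope envelopes.

The labeling arithmetic is the heart of the differential-labeling design:
female proteins are metabolically enriched in 15N, so a female-derived
peptide's mass is shifted upward by roughly one Dalton per nitrogen atom,
and its isotope envelope moves away from the natural-abundance pattern.
Both effects are modeled here, on top of a pinned residue-formula and
isotope table (:mod:`plugprot.constants`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    ELEMENTS,
    ISOTOPES,
    MONO_MASS,
    N15_N14_MASS_DIFF,
    N15_NATURAL_ABUNDANCE,
    PROTON_MASS,
    RESIDUE_FORMULAS,
    STANDARD_RESIDUES,
    WATER_FORMULA,
)

__all__ = [
    "ElementalComposition",
    "IsotopeEnvelope",
    "EnvelopeClassification",
    "elemental_composition",
    "monoisotopic_mass",
    "peptide_mass",
    "nitrogen_count",
    "n15_mass_adjustment",
    "isotope_distribution",
    "isotope_pattern",
    "mean_mass",
    "theoretical_envelope",
    "envelope_mean_mass",
    "classify_envelope",
    "tryptic_digest",
    "mz_from_mass",
    "mass_from_mz",
]


@dataclass(frozen=True)
class ElementalComposition:
    """Element counts (C, H, N, O, S) of a peptide or fragment."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for element, count in self.as_dict().items():
            if count < 0:
                raise ValueError(f"negative count for element {element}")

    def as_dict(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s}

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.c, self.h, self.n, self.o, self.s)

    @property
    def n_atoms(self) -> int:
        return sum(self.as_tuple())

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            *(a + b for a, b in zip(self.as_tuple(), other.as_tuple()))
        )


def _validate_peptide(peptide: str) -> None:
    if not peptide:
        raise ValueError("empty peptide sequence")
    for i, residue in enumerate(peptide):
        if residue not in STANDARD_RESIDUES:
            raise ValueError(
                f"non-standard residue {residue!r} at position {i + 1}"
            )


def elemental_composition(peptide: str) -> ElementalComposition:
    """Elemental composition of an intact peptide (residues + one water)."""
    _validate_peptide(peptide)
    totals = list(WATER_FORMULA)
    for residue in peptide:
        formula = RESIDUE_FORMULAS[residue]
        for i in range(5):
            totals[i] += formula[i]
    return ElementalComposition(*totals)


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic (all-lightest-isotope) mass in Da."""
    return sum(
        count * MONO_MASS[element]
        for element, count in comp.as_dict().items()
    )


def peptide_mass(peptide: str) -> float:
    return monoisotopic_mass(elemental_composition(peptide))


def nitrogen_count(peptide: str) -> int:
    return elemental_composition(peptide).n


def n15_mass_adjustment(
    peptide: str, incorporation: float, exact: bool = False
) -> float:
    """Expected mass shift of a 15N-labeled peptide, in Da.

    The default reproduces the search-engine approximation used for the
    labeled-mode database search: ``incorporation`` Daltons per nitrogen
    atom (2.85 Da for a 3-nitrogen peptide at 95% incorporation). With
    ``exact=True`` the physical 15N-14N mass difference (0.9970349 Da) is
    applied instead, i.e. ``N * incorporation * 0.9970349``.
    """
    if not 0.0 <= incorporation <= 1.0:
        raise ValueError(f"incorporation must be in [0, 1], got {incorporation}")
    n = nitrogen_count(peptide)
    per_nitrogen = incorporation * (N15_N14_MASS_DIFF if exact else 1.0)
    return n * per_nitrogen


def mz_from_mass(mass: float, charge: int) -> float:
    return (mass + charge * PROTON_MASS) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    return mz * charge - charge * PROTON_MASS


# ---------------------------------------------------------------------------
# isotope patterns
# ---------------------------------------------------------------------------

def _single_atom_pattern(
    element: str, n15_fraction: float, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """(probability, probability-weighted mass offset) per neutron-shift bin
    for one atom of ``element``. Nitrogen's heavy-isotope probability is
    replaced by ``n15_fraction``."""
    probs = np.zeros(n_bins)
    moments = np.zeros(n_bins)
    for shift, offset, abundance in ISOTOPES[element]:
        if element == "N":
            abundance = n15_fraction if shift == 1 else 1.0 - n15_fraction
        if shift < n_bins:
            probs[shift] += abundance
            moments[shift] += abundance * offset
    return probs, moments


def _convolve_pm(
    a: tuple[np.ndarray, np.ndarray],
    b: tuple[np.ndarray, np.ndarray],
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray]:
    pa, ma = a
    pb, mb = b
    probs = np.convolve(pa, pb)[:n_bins]
    moments = (np.convolve(pa, mb) + np.convolve(ma, pb))[:n_bins]
    return probs, moments


def _element_pattern(
    element: str, count: int, n15_fraction: float, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pattern of ``count`` atoms via binary-exponentiation convolution."""
    result = (
        np.array([1.0] + [0.0] * (n_bins - 1)),
        np.zeros(n_bins),
    )
    base = _single_atom_pattern(element, n15_fraction, n_bins)
    k = count
    while k > 0:
        if k & 1:
            result = _convolve_pm(result, base, n_bins)
        k >>= 1
        if k:
            base = _convolve_pm(base, base, n_bins)
    return result


def isotope_pattern(
    comp: ElementalComposition,
    n15_fraction: float = N15_NATURAL_ABUNDANCE,
    n_bins: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full isotopologue pattern aggregated by neutron-shift bin.

    Returns ``(probs, offsets)`` where ``probs[k]`` is the probability of
    the k-neutron bin (probabilities over all bins sum to 1 when ``n_bins``
    covers the support) and ``offsets[k]`` is the intensity-weighted mean
    mass offset of that bin from the monoisotopic mass.

    Truncated convolution is exact for the retained bins: bin ``k`` only
    receives contributions from lighter bins.
    """
    if not 0.0 <= n15_fraction <= 1.0:
        raise ValueError("n15_fraction must be in [0, 1]")
    max_support = comp.c + comp.h + comp.n + 2 * comp.o + 4 * comp.s + 1
    if n_bins is None:
        n_bins = max_support
    n_bins = max(1, min(n_bins, max_support))
    pattern = (np.array([1.0] + [0.0] * (n_bins - 1)), np.zeros(n_bins))
    for element in ELEMENTS:
        count = comp.as_dict()[element]
        if count:
            pattern = _convolve_pm(
                pattern, _element_pattern(element, count, n15_fraction, n_bins),
                n_bins,
            )
    probs, moments = pattern
    with np.errstate(invalid="ignore", divide="ignore"):
        offsets = np.where(probs > 0, moments / np.where(probs > 0, probs, 1.0), 0.0)
    return probs, offsets


def isotope_distribution(
    comp: ElementalComposition,
    n15_fraction: float = N15_NATURAL_ABUNDANCE,
    n_peaks: int = 6,
) -> np.ndarray:
    """First ``n_peaks`` isotopologue intensities, renormalized to sum 1.

    The nitrogen heavy-isotope probability is ``n15_fraction``; at the
    natural abundance (0.003663) this is the natural isotope pattern.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    probs, _ = isotope_pattern(comp, n15_fraction, n_bins=n_peaks)
    total = probs.sum()
    if total <= 0:
        raise ValueError("degenerate isotope pattern")
    return probs / total


def mean_mass(
    comp: ElementalComposition, n15_fraction: float = N15_NATURAL_ABUNDANCE
) -> float:
    """Intensity-weighted mean mass of the full isotope envelope, Da."""
    probs, offsets = isotope_pattern(comp, n15_fraction)
    return monoisotopic_mass(comp) + float(np.dot(probs, offsets) / probs.sum())


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopeEnvelope:
    """An observed or theoretical isotopologue peak series at one charge."""

    charge: int
    mz_values: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if len(self.mz_values) != len(self.intensities):
            raise ValueError("mz_values and intensities length mismatch")
        if not self.mz_values:
            raise ValueError("empty envelope")
        if any(b <= a for a, b in zip(self.mz_values, self.mz_values[1:])):
            raise ValueError("mz_values must be strictly increasing")
        total = sum(self.intensities)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"intensities must sum to 1, got {total}")


@dataclass(frozen=True)
class EnvelopeClassification:
    label: str  # "natural" or "enriched"
    score_natural: float
    score_enriched: float


def theoretical_envelope(
    comp: ElementalComposition,
    charge: int,
    n15_fraction: float = N15_NATURAL_ABUNDANCE,
    n_peaks: int = 6,
    window: str = "top",
) -> IsotopeEnvelope:
    """Theoretical envelope of ``n_peaks`` consecutive isotopologue bins.

    ``window="mono"`` starts at the monoisotopic bin; ``window="top"``
    chooses the ``n_peaks``-bin window with the largest total intensity
    (for heavily labeled peptides the envelope sits many neutrons above
    the monoisotopic bin). Intensities renormalized to the window.
    """
    probs, offsets = isotope_pattern(comp, n15_fraction)
    mono = monoisotopic_mass(comp)
    n_peaks = min(n_peaks, len(probs))
    if window == "mono":
        start = 0
    elif window == "top":
        sums = np.convolve(probs, np.ones(n_peaks), mode="valid")
        start = int(np.argmax(sums))
    else:
        raise ValueError(f"unknown window rule {window!r}")
    sel = slice(start, start + n_peaks)
    intensities = probs[sel]
    masses = mono + np.where(
        probs[sel] > 0, offsets[sel], np.arange(start, start + n_peaks) * 1.0029
    )
    mz = [mz_from_mass(m, charge) for m in masses]
    norm = intensities.sum()
    return IsotopeEnvelope(
        charge=charge,
        mz_values=tuple(mz),
        intensities=tuple(intensities / norm),
    )


def envelope_mean_mass(envelope: IsotopeEnvelope) -> float:
    masses = [mass_from_mz(mz, envelope.charge) for mz in envelope.mz_values]
    return float(np.dot(masses, envelope.intensities))


def classify_envelope(
    observed: IsotopeEnvelope,
    comp: ElementalComposition,
    n15_fraction_labeled: float = 0.95,
    mass_tol: float = 0.35,
) -> EnvelopeClassification:
    """Classify an observed envelope as natural-abundance or 15N-enriched.

    Each theoretical template (natural; labeled at
    ``n15_fraction_labeled``) is projected onto the observed peaks' neutral
    masses (nearest template isotopologue within ``mass_tol`` Da, else
    zero) and compared to the observed intensities by cosine similarity.
    Ties go to natural, the conservative call for inclusion-list building:
    a missed male peptide only costs sensitivity, while fragmenting a
    labeled peak wastes instrument time.
    """
    observed_masses = np.array(
        [mass_from_mz(mz, observed.charge) for mz in observed.mz_values]
    )
    obs = np.asarray(observed.intensities)
    mono = monoisotopic_mass(comp)
    span = observed_masses.max() - observed_masses.min()
    if span > comp.n_atoms * 4.1:
        raise ValueError("observed envelope span inconsistent with composition")

    def template_score(fraction: float) -> float:
        probs, offsets = isotope_pattern(comp, fraction)
        template_masses = mono + offsets
        projected = np.zeros_like(obs)
        for i, m in enumerate(observed_masses):
            j = int(np.argmin(np.abs(template_masses - m)))
            if abs(template_masses[j] - m) <= mass_tol:
                projected[i] = probs[j]
        denom = np.linalg.norm(obs) * np.linalg.norm(projected)
        if denom == 0:
            return 0.0
        return float(np.dot(obs, projected) / denom)

    score_natural = template_score(N15_NATURAL_ABUNDANCE)
    score_enriched = template_score(n15_fraction_labeled)
    label = "natural" if score_natural >= score_enriched else "enriched"
    return EnvelopeClassification(label, score_natural, score_enriched)


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def tryptic_digest(sequence: str, max_missed: int = 0) -> list[str]:
    """In-silico tryptic digestion.

    Cleaves C-terminal to K or R except when the next residue is P.
    Returns all peptides with 0..``max_missed`` missed cleavages, ordered
    by missed-cleavage count and then N-to-C position.
    """
    _validate_peptide(sequence)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    fragments: list[str] = []
    start = 0
    for i, residue in enumerate(sequence):
        if residue in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        fragments.append(sequence[start:])
    peptides: list[tuple[int, int, str]] = []
    for missed in range(max_missed + 1):
        for i in range(len(fragments) - missed):
            peptides.append((missed, i, "".join(fragments[i : i + missed + 1])))
    peptides.sort(key=lambda t: (t[0], t[1]))
    return [p for _, _, p in peptides]
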