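"""Peptide elemental compositions, aggregated isotope envelopes and
light/heavy pair geometry for 16O/18O methionine-sulfoxide quantification.

The heavy (18O) species of a peptide has the same elemental composition as
the light (16O) species -- only the sulfoxide oxygen isotope differs -- so a
single natural-abundance envelope describes both, with the heavy envelope
offset by the 18O-16O mass difference (~2 Da, i.e. two unit-mass
isotopologue positions). Because two extra neutrons of 13C spacing
(2 x 1.00335 Da) and the label offset (2.004246 Da) differ by only 2.5 mDa,
the overlap of the light M+2, M+3, ... isotopologues with the heavy envelope
is treated as unresolved at typical Orbitrap MS1 resolution; the
:func:`mixing_coefficients` / overlap-correction machinery accounts for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "LABEL_OFFSET",
    "ISOTOPOLOGUE_SPACING",
    "ElementalComposition",
    "IsotopeEnvelope",
    "PairGeometry",
    "MixingCoefficients",
    "composition_from_sequence",
    "isotope_envelope",
    "pair_positions",
    "mixing_coefficients",
]

PROTON_MASS = 1.007276466622
#: mass difference between the 18O and 16O sulfoxide labels (Da)
LABEL_OFFSET = 2.004246
#: unit isotopologue spacing, dominated by 13C-12C (Da)
ISOTOPOLOGUE_SPACING = 1.00335

LIGHT = "light16O"
HEAVY = "heavy18O"

_ELEMENTS = ("C", "H", "N", "O", "S")

# recognized variable/fixed modifications and their elemental deltas
_MOD_DELTAS = {
    "met_sulfoxide_16O": {"O": 1},
    "met_sulfoxide_18O": {"O": 1},
    "acetyl_nterm": {"C": 2, "H": 2, "O": 1},
    "carbamidomethyl_C": {"C": 2, "H": 3, "N": 1, "O": 1},
}


def _load_abundance_table() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Load the pinned elemental isotope table (neutron offset, mass, abundance)."""
    table: dict[str, list[tuple[int, float, float]]] = {}
    text = (
        resources.files("mosquant").joinpath("data/isotope_abundances.tsv").read_text()
    )
    for line in text.strip().splitlines()[1:]:
        el, off, m, ab = line.split("\t")
        table.setdefault(el, []).append((int(off), float(m), float(ab)))
    out = {}
    for el, rows in table.items():
        rows.sort()
        kmax = rows[-1][0]
        dist = np.zeros(kmax + 1)
        masses = np.zeros(kmax + 1)
        for off, m, ab in rows:
            dist[off] = ab
            masses[off] = m
        out[el] = (dist, masses)
    return out


_ISOTOPES = _load_abundance_table()


@dataclass(frozen=True)
class ElementalComposition:
    """Element counts (C,H,N,O,S) of one peptide species plus its label."""

    counts: dict[str, int]
    label: str = LIGHT

    def __post_init__(self):
        for el, n in self.counts.items():
            if el not in _ELEMENTS:
                raise ValueError(f"unsupported element: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el}")
        if self.label not in (LIGHT, HEAVY):
            raise ValueError(f"unknown label: {self.label!r}")

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass (Da), lightest isotope of every element.

        The label does not enter: the +2 Da offset of the heavy species is
        applied downstream through :data:`LABEL_OFFSET`.
        """
        return sum(_ISOTOPES[el][1][0] * n for el, n in self.counts.items())

    def total_atoms(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Aggregated (unit-mass binned) relative isotopologue abundances."""

    abundances: np.ndarray
    monoisotopic_mass: float
    charge: int = 0
    spacing: float = ISOTOPOLOGUE_SPACING

    def __post_init__(self):
        a = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "abundances", a)
        if np.any(a < 0):
            raise ValueError("negative isotopologue abundance")
        if a.sum() > 1 + 1e-9:
            raise ValueError("envelope mass exceeds 1")


@dataclass(frozen=True)
class PairGeometry:
    """m/z positions of light and heavy isotopologues for one charge state."""

    light_mz: np.ndarray
    heavy_mz: np.ndarray
    charge: int
    label_offset: float = LABEL_OFFSET


@dataclass(frozen=True)
class MixingCoefficients:
    """Expected contribution of true light (L) and heavy (H) species signal
    to the summed light and heavy channels, given the shared envelope and the
    +2-position shift of the heavy species."""

    light_channel_weight_L: float
    light_channel_weight_H: float
    heavy_channel_weight_L: float
    heavy_channel_weight_H: float

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.light_channel_weight_L, self.light_channel_weight_H],
                [self.heavy_channel_weight_L, self.heavy_channel_weight_H],
            ]
        )


def composition_from_sequence(
    sequence: str, modifications: set[str] | frozenset[str] = frozenset()
) -> ElementalComposition:
    """Elemental composition of a peptide with the recognized modifications.

    Residue compositions (plus one water for the termini) come from the
    standard amino-acid table; each modification adds its elemental delta.
    A methionine sulfoxide adds one oxygen and sets the species label.
    """
    if not sequence:
        raise ValueError("empty sequence")
    for res in sequence:
        if res not in _pmass.std_aa_comp or len(res) != 1 or not res.isupper():
            raise ValueError(f"unknown residue: {res!r}")
    comp = _pmass.Composition(sequence=sequence)
    label = LIGHT
    mods = set(modifications)
    if "met_sulfoxide_16O" in mods and "met_sulfoxide_18O" in mods:
        raise ValueError("a species carries either the 16O or the 18O sulfoxide")
    for mod in mods:
        if mod not in _MOD_DELTAS:
            raise ValueError(f"unknown modification: {mod!r}")
        if mod.startswith("met_sulfoxide") and "M" not in sequence:
            raise ValueError("sulfoxide modification on a methionine-free sequence")
        if mod == "carbamidomethyl_C" and "C" not in sequence:
            raise ValueError("carbamidomethyl modification on a cysteine-free sequence")
        for el, d in _MOD_DELTAS[mod].items():
            comp[el] = comp.get(el, 0) + d
    if "met_sulfoxide_18O" in mods:
        label = HEAVY
    counts = {el: int(comp.get(el, 0)) for el in _ELEMENTS if comp.get(el, 0)}
    return ElementalComposition(counts=counts, label=label)


def _element_power(dist: np.ndarray, n: int, K: int) -> np.ndarray:
    """dist convolved with itself n times, truncated at index K.

    Exponentiation by squaring; truncating intermediates is lossless for
    bins <= K because neutron offsets are nonnegative.
    """
    result = np.zeros(K + 1)
    result[0] = 1.0
    base = dist[: K + 1].copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[: K + 1]
        base = np.convolve(base, base)[: K + 1]
        n >>= 1
    return result


def isotope_envelope(comp: ElementalComposition, K: int = 6) -> IsotopeEnvelope:
    """Theoretical aggregated isotope envelope of a composition, truncated at
    isotopologue index ``K``.

    Abundances are the unit-mass-binned convolution of the per-element
    natural isotope distributions; the tail beyond K is dropped, so the sum
    is <= 1 (and -> 1 as K grows).
    """
    if K < 3:
        raise ValueError("K must be >= 3")
    if not comp.counts or comp.total_atoms() == 0:
        raise ValueError("empty composition")
    env = np.zeros(K + 1)
    env[0] = 1.0
    for el, n in comp.counts.items():
        if n:
            env = np.convolve(env, _element_power(_ISOTOPES[el][0], n, K))[: K + 1]
    return IsotopeEnvelope(abundances=env, monoisotopic_mass=comp.monoisotopic_mass)


def pair_positions(envelope: IsotopeEnvelope, charge: int) -> PairGeometry:
    """m/z grids of the light and heavy species isotopologues at ``charge``."""
    if charge <= 0:
        raise ValueError("charge must be positive")
    k = np.arange(len(envelope.abundances))
    light = (envelope.monoisotopic_mass + k * envelope.spacing + charge * PROTON_MASS) / charge
    heavy = light + LABEL_OFFSET / charge
    return PairGeometry(light_mz=light, heavy_mz=heavy, charge=charge)


def mixing_coefficients(
    envelope: IsotopeEnvelope,
    light_channel: set[int] | frozenset[int],
    heavy_channel: set[int] | frozenset[int],
) -> MixingCoefficients:
    """Channel mixing weights under the +2-position heavy-envelope shift.

    Channels are disjoint index sets over a common peak-position grid where
    the light species contributes abundance ``a[k]`` at position ``k`` and
    the heavy species contributes ``a[k-2]`` at position ``k``.
    """
    light_channel, heavy_channel = set(light_channel), set(heavy_channel)
    if light_channel & heavy_channel:
        raise ValueError("light and heavy channels overlap")
    a = envelope.abundances

    def at(k: int) -> float:
        return float(a[k]) if 0 <= k < len(a) else 0.0

    return MixingCoefficients(
        light_channel_weight_L=sum(at(k) for k in light_channel),
        light_channel_weight_H=sum(at(k - 2) for k in light_channel),
        heavy_channel_weight_L=sum(at(k) for k in heavy_channel),
        heavy_channel_weight_H=sum(at(k - 2) for k in heavy_channel),
    )
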