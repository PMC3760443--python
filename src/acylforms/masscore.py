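"""Peptide and modification mass calculus.

Masses are built on the element and residue tables shipped with
:mod:`pyteomics.mass`. Two mass modes are supported:

``monoisotopic``
    Sum of most-abundant-isotope masses. This is the default and the mode
    in which MALDI-TOF [M+H]+ values of ~2 kDa peptides are interpreted:
    measured values sit within a fraction of a Dalton of monoisotopic
    theory, whereas average masses diverge by more than 1 Da.
``average``
    Abundance-weighted atomic weights; provided for completeness.

A fatty acylation with *n* carbons and *m* double bonds (written Cn:m,
e.g. C8:0 for octanoylation) adds the mass of the fatty acid minus water,
i.e. the acyl group CnH(2n-2-2m)O. C-terminal amidation replaces the
carboxylic OH by NH2, a delta of N + H - O = -0.984016 Da (monoisotopic).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional

from pyteomics import mass as _pmass

MONOISOTOPIC = "monoisotopic"
AVERAGE = "average"
_MODES = (MONOISOTOPIC, AVERAGE)

#: Charge carrier for [M+H]+. The proton mass is the same regardless of
#: whether the neutral is expressed in monoisotopic or average terms.
PROTON = 1.007276

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

WATER = {
    MONOISOTOPIC: _pmass.calculate_mass(formula="H2O"),
    AVERAGE: _pmass.calculate_mass(formula="H2O", average=True),
}

#: C-terminal amide minus free acid: swap OH for NH2 (net N + H - O).
AMIDE_DELTA = {
    MONOISOTOPIC: _pmass.calculate_mass(formula="NH2") - _pmass.calculate_mass(formula="OH"),
    AVERAGE: _pmass.calculate_mass(formula="NH2", average=True)
    - _pmass.calculate_mass(formula="OH", average=True),
}

FREE_ACID = "free_acid"
AMIDE = "amide"
_CTERM_STATES = (FREE_ACID, AMIDE)

_RESIDUE_MASS = {
    MONOISOTOPIC: {aa: _pmass.std_aa_mass[aa] for aa in STANDARD_AA},
    AVERAGE: {
        aa: _pmass.calculate_mass(composition=_pmass.std_aa_comp[aa], average=True)
        for aa in STANDARD_AA
    },
}


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"unknown mass mode {mode!r}; expected one of {_MODES}")


def _check_cterm(cterm: str) -> None:
    if cterm not in _CTERM_STATES:
        raise ValueError(f"unknown C-terminal state {cterm!r}; expected one of {_CTERM_STATES}")


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty-acyl modification Cn:m (n carbons, m double bonds)."""

    n: int
    m: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"acyl chain length must be >= 2, got {self.n}")
        if self.m < 0:
            raise ValueError(f"unsaturation count must be >= 0, got {self.m}")
        if 2 * self.n - 2 - 2 * self.m < 0:
            raise ValueError(
                f"C{self.n}:{self.m} has a negative hydrogen count in CnH(2n-2-2m)O"
            )

    @property
    def formula(self) -> str:
        """Elemental formula of the acyl group (fatty acid minus water)."""
        return f"C{self.n}H{2 * self.n - 2 - 2 * self.m}O"

    @property
    def label(self) -> str:
        return f"C{self.n}:{self.m}"


@dataclass(frozen=True)
class AdductSpec:
    """A named mass shift applied on top of a molecular form (e.g. Na-H)."""

    label: str
    delta: float

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("adduct label must be non-empty")
        if not (self.delta == self.delta and abs(self.delta) != float("inf")):
            raise ValueError("adduct delta must be finite")


#: Built-in adducts. The literature's "+24 sodium-like" species is chemically
#: ambiguous (a true Na-H replacement is +21.98 Da); both are registered and
#: user-overridable.
ADDUCT_REGISTRY = {
    "Na-H": AdductSpec("Na-H", _pmass.calculate_mass(formula="Na") - _pmass.calculate_mass(formula="H")),
    "sodium-like+24": AdductSpec("sodium-like+24", 23.98),
    "satellite+1": AdductSpec("satellite+1", -AMIDE_DELTA[MONOISOTOPIC]),
}


def residue_mass(aa: str, mode: str = MONOISOTOPIC) -> float:
    """Mass of one amino-acid residue (water-loss form), in Da."""
    _check_mode(mode)
    try:
        return _RESIDUE_MASS[mode][aa]
    except KeyError:
        raise ValueError(f"unknown amino-acid residue {aa!r}") from None


def peptide_mass(seq: str, cterm: str = FREE_ACID, mode: str = MONOISOTOPIC) -> float:
    """Neutral mass of a linear peptide with the given C-terminal state."""
    _check_mode(mode)
    _check_cterm(cterm)
    if not seq:
        raise ValueError("peptide sequence must be non-empty")
    total = WATER[mode]
    table = _RESIDUE_MASS[mode]
    for i, aa in enumerate(seq):
        try:
            total += table[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}") from None
    if cterm == AMIDE:
        total += AMIDE_DELTA[mode]
    return total


def acyl_delta(acyl: FattyAcyl, mode: str = MONOISOTOPIC) -> float:
    """Mass added by esterifying the fatty acid Cn:m onto the peptide."""
    _check_mode(mode)
    return _pmass.calculate_mass(formula=acyl.formula, average=(mode == AVERAGE))


def form_mh(
    seq: str,
    cterm: str = FREE_ACID,
    acyl: Optional[FattyAcyl] = None,
    adduct: Optional[AdductSpec] = None,
    mode: str = MONOISOTOPIC,
) -> float:
    """Theoretical [M+H]+ of a (possibly acylated, adducted) peptide form."""
    total = peptide_mass(seq, cterm=cterm, mode=mode)
    if acyl is not None:
        total += acyl_delta(acyl, mode=mode)
    if adduct is not None:
        total += adduct.delta
    return total + PROTON


def elemental_mh(
    seq: str,
    cterm: str = FREE_ACID,
    acyl: Optional[FattyAcyl] = None,
    adduct: Optional[AdductSpec] = None,
    mode: str = MONOISOTOPIC,
) -> float:
    """[M+H]+ computed from the assembled elemental composition.

    Independent route from :func:`form_mh` (which sums per-residue masses):
    the full peptide composition is assembled atom by atom and weighed once.
    Adduct deltas that carry no formula (e.g. the empirical "+24") are added
    as-is.
    """
    _check_mode(mode)
    _check_cterm(cterm)
    comp = _pmass.Composition(sequence=seq)
    if cterm == AMIDE:
        comp += _pmass.Composition(formula="NH2")
        comp -= _pmass.Composition(formula="OH")
    if acyl is not None:
        comp += _pmass.Composition(formula=acyl.formula)
    total = _pmass.calculate_mass(composition=comp, average=(mode == AVERAGE))
    if adduct is not None:
        total += adduct.delta
    return total + PROTON


def export_constants(path) -> None:
    """Write the residue-mass and fixed-delta constants to a TSV for audit."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "monoisotopic_da", "average_da"])
        for aa in STANDARD_AA:
            w.writerow([
                f"residue_{aa}",
                f"{_RESIDUE_MASS[MONOISOTOPIC][aa]:.6f}",
                f"{_RESIDUE_MASS[AVERAGE][aa]:.6f}",
            ])
        w.writerow(["water", f"{WATER[MONOISOTOPIC]:.6f}", f"{WATER[AVERAGE]:.6f}"])
        w.writerow(["amide_delta", f"{AMIDE_DELTA[MONOISOTOPIC]:.6f}", f"{AMIDE_DELTA[AVERAGE]:.6f}"])
        w.writerow(["proton", f"{PROTON:.6f}", f"{PROTON:.6f}"])
        for name, spec in ADDUCT_REGISTRY.items():
            w.writerow([f"adduct_{name}", f"{spec.delta:.6f}", f"{spec.delta:.6f}"])
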