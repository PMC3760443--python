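"""Enumerate the candidate molecular-form space from a processing context.

A molecular form is one candidate processed species: a backbone length (how
many residues of core+extension survive C-terminal processing), a C-terminal
state (free acid or amide), an optional fatty acyl Cn:m at the context's acyl
site, and an optional adduct. The key biochemical constraint is the
glycine-donor rule: a length-L amide can exist only when residue L+1 of the
precursor context is a glycine, because amidation consumes a C-terminal
glycine of the one-residue-longer free acid.

The default chain range is deliberately restricted to medium-chain fatty
acids C7-C10. Backbone lengths and chains interact near-isobarically: on
this context a length-20 amide with chain Cn sits 0.025 Da above the
length-19 free acid with chain Cn+5 (an Ala plus the amide delta nearly
equals five CH2 units), and a 21-residue free acid with Cn:m sits 0.073 Da
below the 20-residue amide with C(n+4):(m-1). Any chain range of width >= 4
therefore contains near-degenerate candidate pairs and makes nearest-mass
assignment ill-posed. C7-C10 covers every acyl state reported in flatfish
stomach extracts (C8-C10, zero to two double bonds) plus the C7 chain
needed to interrogate heptanoate feeding, while keeping the smallest
pairwise candidate gap at 0.98 Da -- comfortably above the 0.25 Da matching
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Set, Tuple

import numpy as np


from .masscore import AMIDE, FREE_ACID, MONOISOTOPIC, AdductSpec, FattyAcyl, form_mh
from .seqprep import ProcessingContext


@dataclass(frozen=True, order=True)
class MolecularForm:
    """One candidate species: (backbone length, C-terminus, acyl, adduct)."""

    length: int
    cterm: str = FREE_ACID
    acyl: Optional[FattyAcyl] = None
    adduct: Optional[AdductSpec] = None

    @property
    def label(self) -> str:
        """Form label in the conventional notation, e.g. ``19-(C10:0)`` or
        ``20-(C8:0)-amide``; unacylated forms read ``19-desacyl``."""
        mod = f"({self.acyl.label})" if self.acyl is not None else "desacyl"
        lab = f"{self.length}-{mod}"
        if self.cterm == AMIDE:
            lab += "-amide"
        if self.adduct is not None:
            lab += f"+{self.adduct.label}"
        return lab


@dataclass(frozen=True)
class EnumConfig:
    """Enumeration settings.

    Defaults span the molecular diversity seen in flatfish stomach extracts:
    backbones of 18-21 residues, acyl chains C7-C10 with up to two double
    bonds, plus the unmodified (des-acyl) backbone. See the module docstring
    for why the chain range must stay narrower than four CH2 units.
    """

    lengths: Tuple[int, ...] = (18, 19, 20, 21)
    chain_range: Tuple[int, int] = (7, 10)
    max_unsat: int = 2
    include_desacyl: bool = True
    adducts: Tuple[AdductSpec, ...] = ()
    mode: str = MONOISOTOPIC

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("lengths must be non-empty")
        lo, hi = self.chain_range
        if lo > hi:
            raise ValueError(f"empty chain range {self.chain_range}")
        if self.max_unsat < 0:
            raise ValueError("max_unsat must be >= 0")
        object.__setattr__(self, "lengths", tuple(sorted(set(self.lengths))))

    def acyl_states(self) -> List[Optional[FattyAcyl]]:
        lo, hi = self.chain_range
        states: List[Optional[FattyAcyl]] = [
            FattyAcyl(n, m) for n in range(lo, hi + 1) for m in range(self.max_unsat + 1)
        ]
        if self.include_desacyl:
            states.append(None)
        return states


@dataclass
class CandidateSet:
    """Enumerated forms with theoretical [M+H]+, sorted ascending by mass."""

    entries: List[Tuple[MolecularForm, float]]

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: (e[1], e[0].label))
        seen = set()
        for form, mh in self.entries:
            if mh <= 0:
                raise ValueError(f"non-positive mass for {form.label}")
            if form in seen:
                raise ValueError(f"duplicate form {form.label}")
            seen.add(form)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def masses(self) -> np.ndarray:
        return np.array([mh for _, mh in self.entries])

    @property
    def labels(self) -> List[str]:
        return [form.label for form, _ in self.entries]

    def min_gap(self) -> float:
        """Smallest pairwise [M+H]+ spacing; justifies the match tolerance."""
        if len(self.entries) < 2:
            return float("inf")
        return float(np.diff(self.masses).min())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("form\ttheoretical_mz\n")
            for form, mh in self.entries:
                fh.write(f"{form.label}\t{mh:.4f}\n")


def glycine_donor_positions(context: ProcessingContext, lengths: Iterable[int]) -> Set[int]:
    """Lengths L at which an amide is permitted: residue L+1 must be glycine."""
    full = context.full
    return {L for L in lengths if L + 1 <= len(full) and full[L] == "G"}


def enumerate_forms(context: ProcessingContext, config: EnumConfig = EnumConfig()) -> CandidateSet:
    """Build the candidate set for a context under an enumeration config.

    The Cartesian product of backbone lengths, permitted C-terminal states,
    acyl states and adduct states is generated, each with its theoretical
    [M+H]+ recomputed from the sequence (no cached masses).
    """
    full = context.full
    max_len = max(config.lengths)
    if max_len > len(full):
        raise ValueError(
            f"length {max_len} not realizable: core+extension has only {len(full)} residues"
        )
    if context.acyl_site > min(config.lengths):
        raise ValueError(
            f"acyl site {context.acyl_site} would be lost at length {min(config.lengths)}"
        )
    amide_ok = glycine_donor_positions(context, config.lengths)
    adduct_states: List[Optional[AdductSpec]] = [None, *config.adducts]
    entries: List[Tuple[MolecularForm, float]] = []
    for L in config.lengths:
        seq = full[:L]
        cterms = [FREE_ACID] + ([AMIDE] if L in amide_ok else [])
        for cterm in cterms:
            for acyl in config.acyl_states():
                for adduct in adduct_states:
                    form = MolecularForm(length=L, cterm=cterm, acyl=acyl, adduct=adduct)
                    entries.append((form, form_mh(seq, cterm=cterm, acyl=acyl, adduct=adduct, mode=config.mode)))
    if not entries:
        raise ValueError("enumeration produced an empty candidate set")
    return CandidateSet(entries)
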