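"""Sequence utilities: degenerate primers, CDS translation, processing context.

The processing context is the object the rest of the pipeline works from: the
cDNA-deduced mature peptide (the *core*) plus the precursor residues
immediately downstream of it (the *extension*). C-terminally shortened,
extended and amidated variants are all read off this one string, and the
acyl site (residue 3 in ghrelin, normally a serine or threonine) must fall
inside every enumerated variant.

All indices exposed here are 1-based, following biochemistry convention;
internally plain 0-based Python slicing is used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import prod
from typing import List, Set, Tuple

from Bio import SeqIO
from Bio.Seq import Seq

from .masscore import STANDARD_AA

#: IUPAC nucleotide degeneracy codes (U accepted, normalized to T).
IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class DegeneratePrimer:
    """A primer over the IUPAC nucleotide alphabet (whitespace ignored)."""

    seq: str

    def __post_init__(self) -> None:
        cleaned = "".join(self.seq.split()).upper().replace("U", "T")
        if not cleaned:
            raise ValueError("primer sequence must be non-empty")
        for i, ch in enumerate(cleaned):
            if ch not in IUPAC_NT:
                raise ValueError(f"invalid IUPAC nucleotide {ch!r} at position {i + 1}")
        object.__setattr__(self, "seq", cleaned)


def degeneracy_count(primer: DegeneratePrimer) -> int:
    """Number of concrete sequences the primer encodes (product of code sizes)."""
    return prod(len(IUPAC_NT[ch]) for ch in primer.seq)


def expand_degenerate(primer: DegeneratePrimer, cap: int = 10**6) -> Set[str]:
    """Materialize every concrete sequence consistent with the IUPAC codes."""
    n = degeneracy_count(primer)
    if n > cap:
        raise ValueError(f"expansion size {n} exceeds cap {cap}")
    return {"".join(p) for p in itertools.product(*(IUPAC_NT[ch] for ch in primer.seq))}


def translate_cds(nt_seq: str, frame: int = 0) -> Tuple[str, bool]:
    """Translate a plain-nucleotide CDS in the given frame (standard code).

    Returns ``(peptide, stop_found)`` where the peptide runs up to, but not
    including, the first stop codon. Degenerate codes are rejected.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    cleaned = "".join(nt_seq.split()).upper().replace("U", "T")
    for i, ch in enumerate(cleaned):
        if ch not in "ACGT":
            raise ValueError(f"non-ACGT character {ch!r} at position {i + 1}; degenerate sequences cannot be translated")
    coding = cleaned[frame:]
    coding = coding[: len(coding) - len(coding) % 3]
    if not coding:
        raise ValueError("sequence too short to contain a codon in this frame")
    full = str(Seq(coding).translate())
    stop_found = "*" in full
    peptide = full.split("*", 1)[0]
    return peptide, stop_found


def _check_protein(seq: str, what: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in STANDARD_AA:
            raise ValueError(f"invalid residue {ch!r} at position {i + 1} of {what}")


@dataclass(frozen=True)
class ProcessingContext:
    """Mature-peptide core plus downstream precursor residues.

    ``acyl_site`` is the 1-based residue index carrying the fatty acylation
    (default 3). It must be a hydroxyl-bearing residue (S or T) unless
    ``allow_any_acyl_residue`` is set.
    """

    core: str
    extension: str
    acyl_site: int = 3
    allow_any_acyl_residue: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.core:
            raise ValueError("core sequence must be non-empty")
        _check_protein(self.core, "core")
        if not self.extension:
            raise ValueError("extension must contain at least one residue (amidation/extension logic needs the downstream context)")
        _check_protein(self.extension, "extension")
        if not 1 <= self.acyl_site <= len(self.core):
            raise ValueError(f"acyl_site {self.acyl_site} outside core (length {len(self.core)})")
        res = self.core[self.acyl_site - 1]
        if res not in "ST" and not self.allow_any_acyl_residue:
            raise ValueError(
                f"acyl-site residue {res!r} at position {self.acyl_site} is not S/T; set allow_any_acyl_residue to override"
            )

    @property
    def full(self) -> str:
        """Core followed by the downstream extension."""
        return self.core + self.extension

    def residue(self, pos: int) -> str:
        """1-based residue lookup within core+extension."""
        if not 1 <= pos <= len(self.full):
            raise IndexError(f"position {pos} outside core+extension (length {len(self.full)})")
        return self.full[pos - 1]


def locate_mature(
    precursor: str,
    core_start: int,
    core_length: int,
    extension_length: int,
    acyl_site: int = 3,
) -> ProcessingContext:
    """Cut a processing context out of a precursor (1-based core_start)."""
    _check_protein(precursor, "precursor")
    if core_start < 1 or core_length < 1:
        raise ValueError("core_start and core_length must be positive")
    if extension_length < 1:
        raise ValueError("extension_length must be >= 1")
    end = core_start - 1 + core_length
    ext_end = end + extension_length
    if ext_end > len(precursor):
        raise ValueError(
            f"core window [{core_start}, {end}] + extension {extension_length} exceeds precursor length {len(precursor)}"
        )
    return ProcessingContext(
        core=precursor[core_start - 1 : end],
        extension=precursor[end:ext_end],
        acyl_site=acyl_site,
    )


def read_fasta(path) -> List[Tuple[str, str, str]]:
    """Read a FASTA file into ``(id, description, sequence)`` tuples."""
    return [(rec.id, rec.description, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
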