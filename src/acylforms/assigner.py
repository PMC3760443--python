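"""Match observed [M+H]+ masses to candidate molecular forms.

Matching is nearest-neighbour in mass with an absolute tolerance (default
0.25 Da, matched to MALDI-TOF external-calibration accuracy at ~2 kDa).
MALDI runs commonly carry a constant calibration offset shared by every
peak; when offset correction is enabled, assignment is two-pass: provisional
matching, robust (median) estimation of the shared offset over confident
matches, then re-matching of offset-corrected masses.

Edman-degradation reads provide an orthogonal consistency check: an
O-acylated residue yields no PTH signal at its cycle, so in strict mode an
'X' cycle must coincide with the form's modified site and the modified site
must read 'X'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence

import numpy as np

from .formspace import CandidateSet, MolecularForm
from .masscore import STANDARD_AA
from .seqprep import ProcessingContext

DEFAULT_TOLERANCE = 0.25  # Da
DEFAULT_TIE_WINDOW = 0.05  # Da


@dataclass(frozen=True)
class ObservedMass:
    """One observed [M+H]+ value with its sample and fraction-group labels."""

    sample_id: str
    group_label: str
    mz: float

    def __post_init__(self) -> None:
        if not (self.mz > 0 and np.isfinite(self.mz)):
            raise ValueError(f"mz must be positive and finite, got {self.mz}")


@dataclass
class Assignment:
    observed: ObservedMass
    best: Optional[MolecularForm]
    theoretical: Optional[float]
    delta: Optional[float]  # (possibly offset-corrected) observed - theoretical
    ties: List[MolecularForm] = field(default_factory=list)

    @property
    def assigned(self) -> bool:
        return self.best is not None


@dataclass(frozen=True)
class CalibrationEstimate:
    """Robust global mass-offset estimate over confident assignments."""

    offset: float
    n_used: int
    dispersion: float  # median absolute deviation of the deltas


class AssignmentResult(NamedTuple):
    assignments: List[Assignment]
    calibration: Optional[CalibrationEstimate]


def match_one(
    observed: ObservedMass,
    candidates: CandidateSet,
    tolerance: float = DEFAULT_TOLERANCE,
    tie_window: float = DEFAULT_TIE_WINDOW,
    mz_override: Optional[float] = None,
) -> Assignment:
    """Assign one mass to the candidate minimizing |observed - theoretical|.

    Returns a no-match assignment (best=None) when the nearest candidate is
    farther than ``tolerance``. All candidates within ``tie_window`` of the
    best |delta| are reported as ties, ordered by |delta| then label.
    """
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    mz = observed.mz if mz_override is None else mz_override
    masses = candidates.masses  # sorted ascending
    # nearest neighbour via bisection on the sorted mass axis
    i = int(np.searchsorted(masses, mz))
    best_idx = min(
        (j for j in (i - 1, i) if 0 <= j < len(masses)),
        key=lambda j: abs(mz - masses[j]),
    )
    best_delta = mz - masses[best_idx]
    if abs(best_delta) > tolerance:
        return Assignment(observed=observed, best=None, theoretical=None, delta=None)
    within = np.abs(mz - masses) <= abs(best_delta) + tie_window
    ties = sorted(
        (candidates.entries[j][0] for j in np.nonzero(within)[0]),
        key=lambda f: (abs(mz - _mass_of(candidates, f)), f.label),
    )
    form, theo = candidates.entries[best_idx]
    return Assignment(observed=observed, best=form, theoretical=float(theo), delta=float(best_delta), ties=ties)


def _mass_of(candidates: CandidateSet, form: MolecularForm) -> float:
    for f, mh in candidates.entries:
        if f == form:
            return mh
    raise KeyError(form.label)


def estimate_offset(assignments: Sequence[Assignment]) -> CalibrationEstimate:
    """Median observed-minus-theoretical offset over assigned masses."""
    deltas = np.array([a.delta for a in assignments if a.assigned])
    if deltas.size == 0:
        raise ValueError("no confident assignments to estimate an offset from")
    med = float(np.median(deltas))
    mad = float(np.median(np.abs(deltas - med)))
    return CalibrationEstimate(offset=med, n_used=int(deltas.size), dispersion=mad)


def assign_all(
    masses: Sequence[ObservedMass],
    candidates: CandidateSet,
    tolerance: float = DEFAULT_TOLERANCE,
    tie_window: float = DEFAULT_TIE_WINDOW,
    offset_correction: bool = False,
) -> AssignmentResult:
    """Assign every observed mass; optionally two-pass with offset correction.

    Output order follows input order. With correction enabled, the returned
    deltas are relative to the offset-corrected masses and the calibration
    estimate from the provisional pass is returned alongside.
    """
    first = [match_one(m, candidates, tolerance, tie_window) for m in masses]
    if not offset_correction:
        return AssignmentResult(first, None)
    est = estimate_offset(first)
    corrected = [
        match_one(m, candidates, tolerance, tie_window, mz_override=m.mz - est.offset)
        for m in masses
    ]
    return AssignmentResult(corrected, est)


@dataclass(frozen=True)
class EdmanRead:
    """Edman cycles; 'X' marks a cycle with no PTH-amino-acid signal."""

    cycles: str

    def __post_init__(self) -> None:
        if not self.cycles:
            raise ValueError("Edman read must be non-empty")
        for i, ch in enumerate(self.cycles):
            if ch not in STANDARD_AA + "X":
                raise ValueError(f"invalid Edman cycle character {ch!r} at cycle {i + 1}")


def edman_consistent(
    read: EdmanRead,
    form: MolecularForm,
    context: ProcessingContext,
    strict: bool = True,
) -> bool:
    """Is an Edman read consistent with a candidate form on this context?

    Detected cycles must equal the context residue at that position. In
    strict mode every 'X' cycle must be explained by a modified site of the
    form (the acyl site of an acylated form), and the acyl site, when inside
    the read span, must have come up empty. Lenient mode lets 'X' match
    anything.
    """
    if len(read.cycles) > form.length:
        raise ValueError(
            f"read spans {len(read.cycles)} cycles but the form has only {form.length} residues"
        )
    modified = {context.acyl_site} if form.acyl is not None else set()
    for pos, ch in enumerate(read.cycles, start=1):
        if ch == "X":
            if strict and pos not in modified:
                return False
        else:
            if ch != context.residue(pos):
                return False
            if strict and pos in modified:
                return False
    return True
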