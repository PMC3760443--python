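"""File I/O for mass lists, assignments and run summaries.

Formats are deliberately plain: tab-separated values with a header line,
``#`` comment lines and blank lines ignored, and JSON run summaries with
sorted keys. Output is byte-stable for a fixed input and configuration
(fixed float formatting: 4 decimals for Da columns, 1 for mDa).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from typing import List, Optional, Sequence

import pandas as pd

from .assigner import Assignment, CalibrationEstimate, ObservedMass

MASSLIST_COLUMNS = ("sample_id", "group_label", "mz")
ASSIGNMENT_COLUMNS = ("mz", "assigned_form", "theoretical_mz", "delta_mda", "rank", "n_ties")


def read_masslist(path) -> List[ObservedMass]:
    """Read a mass-list TSV (columns sample_id, group_label, mz; extras ignored)."""
    out: List[ObservedMass] = []
    header = None
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not raw or not "".join(raw).strip() or raw[0].lstrip().startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in raw]
                missing = [c for c in MASSLIST_COLUMNS if c not in header]
                if missing:
                    raise ValueError(f"{path}: line {lineno}: missing column(s) {missing}")
                idx = {c: header.index(c) for c in MASSLIST_COLUMNS}
                continue
            row = {c: (raw[i].strip() if i < len(raw) else "") for c, i in idx.items()}
            try:
                mz = float(row["mz"])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric mz {row['mz']!r}") from None
            out.append(ObservedMass(sample_id=row["sample_id"], group_label=row["group_label"], mz=mz))
    if header is None:
        raise ValueError(f"{path}: no header line found")
    return out


def write_masslist(masses: Sequence[ObservedMass], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MASSLIST_COLUMNS)
        for m in masses:
            w.writerow([m.sample_id, m.group_label, f"{m.mz:.4f}"])


def write_assignments(assignments: Sequence[Assignment], path) -> None:
    """Write assignments as TSV; unassigned rows carry empty form and rank 0."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ASSIGNMENT_COLUMNS)
        for a in assignments:
            if a.assigned:
                w.writerow([
                    f"{a.observed.mz:.4f}", a.best.label, f"{a.theoretical:.4f}",
                    f"{a.delta * 1000:.1f}", 1, len(a.ties),
                ])
            else:
                w.writerow([f"{a.observed.mz:.4f}", "", "", "", 0, 0])


def read_assignments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_summary(path, payload: dict) -> None:
    """JSON run summary with sorted keys (byte-stable)."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def calibration_dict(est: Optional[CalibrationEstimate]) -> Optional[dict]:
    return None if est is None else asdict(est)
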