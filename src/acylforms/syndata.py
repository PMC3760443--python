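"""Synthetic mass-list generator emulating the feeding-experiment structure.

The measurement model is deliberately simple and matches what MALDI-TOF
peak lists of purified peptides look like: each observation is the exact
[M+H]+ of one true molecular form, shifted by a constant calibration offset
shared across the run, plus i.i.d. Gaussian noise in Da; optionally a form
is replaced by its adduct variant with a fixed probability.

Scenario presets mimic the stomach-extract composition shifts seen when
fish ingest medium-chain fatty acids: control fish are dominated by the
19-residue C10:0 form; C8- or C9-fed fish shift the mode to 19-(C8:0) or
19-(C9:0) respectively; C7-fed fish show the control support (no C7-acylated
form appears) at lower overall abundance. The published evidence is a yield
ranking, not proportions, so the preset weights are qualitative stand-ins:
0.50 on the top-ranked form, 0.15-0.20 on the runner-up, and the remainder
spread over the other forms reported for that group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assigner import Assignment, ObservedMass
from .formspace import CandidateSet, EnumConfig, MolecularForm, enumerate_forms
from .masscore import ADDUCT_REGISTRY, AdductSpec
from .seqprep import ProcessingContext

SCENARIOS = ("control", "C7", "C8", "C9", "custom")

_CONTROL_SUPPORT = [
    "19-(C8:0)", "21-(C8:0)", "19-(C9:0)", "19-(C10:1)", "21-(C9:0)",
    "21-(C10:1)", "20-(C8:0)-amide", "20-(C10:2)-amide", "20-(C9:0)-amide",
    "20-(C10:1)-amide",
]

_PRESETS: Dict[str, Dict[str, float]] = {
    "control": {"19-(C10:0)": 0.50, "20-(C10:0)-amide": 0.20,
                **{lab: 0.03 for lab in _CONTROL_SUPPORT}},
    "C8": {"19-(C8:0)": 0.50, "20-(C8:0)-amide": 0.15, "19-(C10:0)": 0.15,
           "20-(C10:0)-amide": 0.08, "21-(C8:0)": 0.04, "19-(C9:0)": 0.04,
           "19-(C10:1)": 0.04},
    "C9": {"19-(C9:0)": 0.50, "19-(C10:0)": 0.15, "20-(C9:0)-amide": 0.15,
           "21-(C9:0)": 0.08, "18-(C9:0)": 0.04, "19-(C8:0)": 0.04,
           "19-(C10:2)": 0.04},
}
# C7 feeding does not create any C7-acylated species; composition mirrors the
# control group at reduced total abundance.
_PRESETS["C7"] = dict(_PRESETS["control"])

#: Scenarios whose total peptide yield is depressed relative to control.
LOW_ABUNDANCE_SCENARIOS = frozenset({"C7"})


@dataclass(frozen=True)
class SimConfig:
    scenario: str = "control"
    n_masses: int = 100
    sigma: float = 0.05  # Gaussian mass-noise SD, Da
    offset: float = 0.0  # global calibration shift, Da
    adduct_prob: float = 0.0
    seed: int = 0
    weights: Optional[Dict[str, float]] = None  # label -> weight, for scenario="custom"
    adduct: AdductSpec = ADDUCT_REGISTRY["sodium-like+24"]

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.n_masses < 1:
            raise ValueError("n_masses must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.adduct_prob <= 1.0:
            raise ValueError("adduct_prob must lie in [0, 1]")
        if self.scenario == "custom":
            if not self.weights:
                raise ValueError("custom scenario requires explicit weights")
            vals = np.array(list(self.weights.values()), dtype=float)
            if (vals < 0).any() or not np.isclose(vals.sum(), 1.0):
                raise ValueError("weights must be non-negative and sum to 1")


def scenario_weights(scenario: str, candidates: CandidateSet) -> np.ndarray:
    """Mixture weights over the candidate set for a named scenario preset."""
    if scenario not in _PRESETS:
        raise ValueError(f"unknown scenario {scenario!r}; presets exist for {tuple(_PRESETS)}")
    return _weights_from_labels(_PRESETS[scenario], candidates)


def _weights_from_labels(by_label: Dict[str, float], candidates: CandidateSet) -> np.ndarray:
    labels = candidates.labels
    missing = set(by_label) - set(labels)
    if missing:
        raise ValueError(f"weighted forms absent from the candidate set: {sorted(missing)}")
    w = np.array([by_label.get(lab, 0.0) for lab in labels], dtype=float)
    return w / w.sum()


def simulate_dataset(
    config: SimConfig,
    context: ProcessingContext,
    enum: EnumConfig = EnumConfig(),
) -> Tuple[pd.DataFrame, List[ObservedMass]]:
    """Draw a synthetic mass list; returns (truth table, observed masses).

    The truth table has columns ``id, form_label, theoretical_mz,
    observed_mz`` with ``observed = theoretical + offset + N(0, sigma^2)``,
    fully reproducible from ``config.seed``.
    """
    candidates = enumerate_forms(context, enum)
    if config.scenario == "custom":
        weights = _weights_from_labels(dict(config.weights), candidates)
    else:
        weights = scenario_weights(config.scenario, candidates)
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(len(candidates), size=config.n_masses, p=weights)
    noise = rng.normal(0.0, config.sigma, size=config.n_masses)
    adducted = rng.random(config.n_masses) < config.adduct_prob

    rows = []
    observed: List[ObservedMass] = []
    for k, (i, eps, add) in enumerate(zip(idx, noise, adducted)):
        form, theo = candidates.entries[int(i)]
        if add:
            form = MolecularForm(form.length, form.cterm, form.acyl, config.adduct)
            theo = theo + config.adduct.delta
        mz = theo + config.offset + eps
        sid = f"sim-{k:04d}"
        rows.append({"id": sid, "form_label": form.label,
                     "theoretical_mz": theo, "observed_mz": mz})
        observed.append(ObservedMass(sample_id=sid, group_label=config.scenario, mz=mz))
    return pd.DataFrame(rows), observed


def recovery(truth: pd.DataFrame, assignments: Sequence[Assignment]) -> float:
    """Fraction of observations whose top-1 form equals the generating form.

    Inputs must be id-aligned; a no-match assignment counts as a failure.
    """
    if len(truth) != len(assignments):
        raise ValueError(f"truth has {len(truth)} rows but there are {len(assignments)} assignments")
    hits = 0
    for (_, row), a in zip(truth.iterrows(), assignments):
        if row["id"] != a.observed.sample_id:
            raise ValueError(f"misaligned ids: truth {row['id']!r} vs assignment {a.observed.sample_id!r}")
        if a.assigned and a.best.label == row["form_label"]:
            hits += 1
    return hits / len(assignments)
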