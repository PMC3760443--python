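"""Mass-to-form assignment, offset estimation and Edman consistency."""

import numpy as np
import pytest

from acylforms.assigner import (
    Assignment,
    EdmanRead,
    ObservedMass,
    assign_all,
    edman_consistent,
    estimate_offset,
    match_one,
)
from acylforms.formspace import MolecularForm
from acylforms.masscore import FREE_ACID, FattyAcyl
from acylforms.reference import EDMAN_READ_P1, load_group_masses


def _obs(mz, sid="x"):
    return ObservedMass(sample_id=sid, group_label="g", mz=mz)


def test_match_one_major_stomach_form(candidates):
    a = match_one(_obs(2172.06), candidates, tolerance=0.25)
    assert a.best.label == "19-(C10:0)"
    assert a.delta == pytest.approx(-0.169, abs=2e-3)
    assert a.ties[0] == a.best


def test_match_one_no_match_under_tight_tolerance(candidates):
    a = match_one(_obs(2172.06), candidates, tolerance=0.05)
    assert a.best is None and a.delta is None and a.ties == []


def test_match_one_exact_mass_gives_zero_delta(candidates):
    form, theo = candidates.entries[17]
    a = match_one(_obs(theo), candidates, tolerance=0.25)
    assert a.best == form
    assert a.delta == 0.0


def test_far_off_mass_is_unassigned(candidates):
    a = match_one(_obs(10.0), candidates)
    assert a.best is None


def test_control_group_has_unique_decanoylated_19mer(candidates):
    masses = load_group_masses("cont")
    result = assign_all(masses, candidates, tolerance=0.25)
    hits = [a for a in result.assignments if a.assigned and a.best.label == "19-(C10:0)"]
    assert len(hits) == 1
    assert hits[0].observed.mz == 2172.06
    assert result.calibration is None


def test_output_order_follows_input_order(candidates):
    masses = load_group_masses("cont")
    result = assign_all(masses, candidates)
    assert [a.observed.sample_id for a in result.assignments] == [m.sample_id for m in masses]


def test_empty_mass_list_gives_empty_result(candidates):
    assert assign_all([], candidates).assignments == []


def test_offset_invariance_of_assignments(candidates):
    masses = load_group_masses("cont")
    base = assign_all(masses, candidates)
    shifted = [_obs(m.mz + 0.10, m.sample_id) for m in masses]
    corrected = assign_all(shifted, candidates, offset_correction=True)
    assert corrected.calibration is not None
    for a, b in zip(base.assignments, corrected.assignments):
        assert (a.best is None) == (b.best is None)
        if a.best is not None:
            assert a.best == b.best


def test_estimate_offset_median_and_mad():
    def fake(delta):
        form = MolecularForm(19, FREE_ACID, FattyAcyl(8, 0))
        return Assignment(_obs(2000.0), form, 2000.0 - delta, delta)

    est = estimate_offset([fake(-0.17), fake(-0.16), fake(-0.06)])
    assert est.offset == pytest.approx(-0.16)
    assert est.n_used == 3
    est0 = estimate_offset([fake(0.0), fake(0.0)])
    assert est0.offset == 0.0 and est0.dispersion == 0.0


def test_estimate_offset_requires_confident_assignment():
    with pytest.raises(ValueError, match="no confident"):
        estimate_offset([Assignment(_obs(10.0), None, None, None)])


def test_zero_noise_idempotence(candidates):
    """Assigning every candidate's own theoretical mass returns it at rank 1."""
    for form, theo in candidates:
        a = match_one(_obs(theo), candidates)
        assert a.best == form
        assert a.delta == 0.0


def test_growing_tolerance_never_changes_a_best_form(candidates):
    rng = np.random.default_rng(7)
    masses = [_obs(float(m)) for m in rng.uniform(1850.0, 2350.0, size=200)]
    prev = assign_all(masses, candidates, tolerance=0.05).assignments
    for tol in (0.1, 0.25, 0.45):
        cur = assign_all(masses, candidates, tolerance=tol).assignments
        for a, b in zip(prev, cur):
            if a.assigned:
                assert b.assigned and b.best == a.best
        prev = cur


def test_match_one_agrees_with_exhaustive_scan(candidates):
    rng = np.random.default_rng(11)
    labels = candidates.labels
    masses_arr = candidates.masses
    for mz in rng.uniform(1800.0, 2400.0, size=1000):
        a = match_one(_obs(float(mz)), candidates, tolerance=0.25)
        deltas = np.abs(mz - masses_arr)
        j = int(np.argmin(deltas))
        if deltas[j] <= 0.25:
            assert a.best is not None and a.best.label == labels[j]
        else:
            assert a.best is None


def test_ties_reported_when_candidates_nearly_coincide(context):
    # the wide chain range contains the 21-acid/20-amide near-isobars 0.073 Da apart
    from acylforms.formspace import EnumConfig, enumerate_forms

    wide = enumerate_forms(context, EnumConfig(chain_range=(6, 12)))
    a = match_one(_obs(2240.23), wide, tolerance=0.25, tie_window=0.08)
    assert len(a.ties) >= 2
    tie_deltas = [abs(2240.23 - dict((f.label, m) for f, m in wide)[t.label]) for t in a.ties]
    assert tie_deltas == sorted(tie_deltas)


ACYLATED_19 = MolecularForm(19, FREE_ACID, FattyAcyl(10, 0))
DESACYL_19 = MolecularForm(19, FREE_ACID, None)


def test_edman_read_consistent_with_acylated_form(context):
    # acylated Ser3 yields no PTH signal, so cycle 3 reads X
    assert edman_consistent(EdmanRead(EDMAN_READ_P1), ACYLATED_19, context, strict=True)


def test_edman_x_cycle_unexplained_by_desacyl_form(context):
    read = EdmanRead(EDMAN_READ_P1)
    assert not edman_consistent(read, DESACYL_19, context, strict=True)
    assert edman_consistent(read, DESACYL_19, context, strict=False)


def test_edman_detected_residue_at_modified_site_is_inconsistent(context):
    assert not edman_consistent(EdmanRead("GSS"), ACYLATED_19, context, strict=True)


def test_edman_mismatched_residue_fails_any_mode(context):
    assert not edman_consistent(EdmanRead("GAX"), ACYLATED_19, context, strict=False)


def test_edman_read_longer_than_form_errors(context):
    with pytest.raises(ValueError, match="cycles"):
        edman_consistent(EdmanRead("G" * 20), ACYLATED_19, context)


def test_edman_read_validation():
    with pytest.raises(ValueError):
        EdmanRead("")
    with pytest.raises(ValueError, match="cycle 2"):
        EdmanRead("GZS")
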