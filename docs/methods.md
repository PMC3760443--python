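# Methods

## The inference problem

A stomach extract contains several co-occurring molecular forms of one
peptide hormone. MALDI-TOF gives a list of singly protonated masses
([M+H]+) accurate to a fraction of a Dalton at ~2 kDa; cDNA gives the
mature-peptide sequence and its precursor context. The task is to map each
measured mass to the processed/modified species that produced it. This is
a nearest-neighbour assignment in mass space over a *finite, structured*
candidate set, and its validity rests entirely on that set being
well-separated relative to measurement error. The package therefore treats
candidate-space design, not mass arithmetic, as the core modelling problem.

## Candidate space

From a processing context (core `GSSFLSPSHKPPNKGKPPRA`, downstream
glycine, acyl site 3) the enumerator forms the product of:

- **backbone length** L ∈ {18, 19, 20, 21}: only C-terminal variation is
  enumerated, because the N-terminal `GSSF` motif carries the acyl site
  and is required for receptor activity; an N-terminally truncated species
  would not have been captured by the activity-guided purification.
- **C-terminal state**: free acid always; amide only where the
  glycine-donor rule permits (residue L+1 of core+extension is G —
  amidation consumes a C-terminal glycine, so a 20-residue amide and a
  21-residue glycine-extended free acid are two fates of one precursor).
- **acyl state**: Cn:m with n ∈ chain_range, m ≤ max_unsat, as a pure
  mass delta CnH(2n−2−2m)O at the acyl site, plus the des-acyl backbone
  (biologically real, even though none of the purified peaks is one —
  des-acyl ghrelin is invisible to the activity assay used to pool
  fractions, but a user's input masses may contain it).
- **adduct state**: none by default; a registry supplies Na−H (+21.98 Da),
  an empirical "sodium-like +24" (+23.98 Da, chemically unresolved, kept
  configurable) and a "+1" amide/acid satellite.

### Why the default chain range is C7–C10

Backbone and chain deltas nearly cancel in two families on this context:

| collision | spacing |
|---|---|
| (L+1)-amide Cn:m vs L-acid C(n+5):m | +0.025 Da (Ala + amide ≈ 5×CH2) |
| 21-acid Cn:m vs 20-amide C(n+4):(m−1) | −0.073 Da (Gly + amide ≈ 4×CH2 − H2) |

Any chain range spanning ≥ 4 CH2 units therefore contains candidate pairs
separated by far less than the measurement tolerance, and nearest-mass
assignment becomes ill-posed: with chains C6–C12 the smallest pairwise gap
in the 110-candidate space is 0.025 Da, and the measured masses near
2240–2242 Da fall closer to spurious 21-residue C6-acyl forms than to the
amidated C10 forms they belong to. The default `chain_range=(7, 10)` is
the widest contiguous range that (a) contains every acyl state reported in
flatfish stomach extracts (C8–C10, up to two unsaturations), (b) includes
C7 so that heptanoate-feeding data can be interrogated for C7-acylated
forms, and (c) contains no collision family. It yields 65 candidates with
a minimum pairwise gap of 0.984 Da — 4× the matching tolerance. Users who
widen the range get the honest consequence: ties and near-degenerate
assignments, which the assigner reports rather than breaks.

## Mass model

Monoisotopic by default: at ~2.2 kDa the measured values lie 0.06–0.23 Da
below monoisotopic theory (a consistent one-sided calibration offset),
whereas average masses deviate by > 1.3 Da. Residue and element masses
come from pyteomics; [M+H]+ adds the proton mass 1.007276 Da (not the
hydrogen-atom mass — the electron stays behind). Amidation is the exact
element delta N + H − O = −0.984016 Da. An `average` mode exists for
completeness and uses standard atomic weights for the neutral. A dual
computation route (per-residue sum vs assembled elemental composition) is
kept in the package and cross-checked in the tests to 5×10⁻⁴ Da, alongside
an external check against Biopython's `molecular_weight`.

## Assignment

- **Tolerance** 0.25 Da absolute (not ppm): MALDI-TOF error at this mass
  scale is dominated by calibration, which is additive in Da; the largest
  deviation among the unambiguous published peaks is 0.233 Da. A ppm
  interpretation would make the window mass-dependent for no gain over a
  300 Da-wide candidate span.
- **Ties**: every candidate within 0.05 Da of the best |delta| is
  reported, ordered by |delta| then label; ties are never silently broken.
- **Calibration**: the offset estimator is the median of
  observed − theoretical over assigned masses, with the median absolute
  deviation as dispersion; the median resists the occasional gross outlier
  row (one published mass deviates +1.8 Da from its own label's theory).
  Offset-corrected assignment is two-pass (provisional match → estimate →
  re-match on corrected masses) and is invariant to any constant shift
  smaller than half the minimum candidate gap.
- **Duplicates** in the input are assigned independently; de-duplication
  is an opt-in CLI flag.
- **Edman consistency**: strict mode (default) requires every undetected
  cycle (`X`) to coincide with the form's modified site and vice versa
  within the read span; lenient mode lets `X` match anything, for noisy
  sequencer runs. The published read `GSXFLSPSHKPPNKGKP` is consistent, in
  strict mode, only with acylated forms — the des-acyl 19-mer cannot
  explain the silent third cycle.

### Known anomalies in the bundled tables

The bundled fixtures transcribe the published mass lists verbatim, with a
`note` column flagging rows excluded from the reproduction checks rather
than corrected: printed adduct species (`+24`, `+17`, `+1`), the C8-group
2146.02 entry (1.8 Da from its own label's theory; under the default
config it falls 0.13 Da from the 21-residue des-acyl backbone and is
assigned that label), and one `21-(C10:0)-amide` label that contradicts
the glycine-donor rule (the identical mass is labelled
`20-(C10:0)-amide` elsewhere; the engine reports the 20-residue amide).
Rows the source table prints twice verbatim are carried once and flagged.
One genuine cross-group disagreement is preserved as documented output:
the ~2168 Da peak is a `19-(C8:0)+24` adduct in one group and `19-(C10:2)`
in another; with the default adduct-free space the engine reports
`19-(C10:2)`.

## Synthetic data

`simulate_dataset` draws forms i.i.d. from a scenario mixture over the
candidate set, computes exact [M+H]+, and observes
`theoretical + offset + N(0, sigma²)`, optionally swapping a draw for its
adduct variant with probability `adduct_prob`. Defaults: σ = 0.05 Da
(MALDI-TOF scale, ~¼ of the largest published deviation), offset 0,
adducts off; all randomness flows from one `numpy` Generator seeded per
run and recorded in the run summary.

Scenario presets encode the feeding experiment's qualitative outcome —
the published evidence is a *yield ranking*, not proportions — as fixed
weights: 0.50 on the top-ranked form (`19-(C10:0)` for control,
`19-(C8:0)` for C8 feeding, `19-(C9:0)` for C9), 0.15–0.20 on the
runner(s)-up, and the remainder spread over the other forms isolated from
that group. The C7 preset reuses the control support with zero weight on
any C7-acylated form (no heptanoylated ghrelin was isolable) and is
flagged low-abundance. These weights are configuration, not biological
claims; `scenario="custom"` takes explicit label→weight maps.

What the simulator emulates: mixture composition, calibration shift,
Gaussian peak-position noise, occasional adducts. What it does not:
peak intensities and detection limits, isotope envelopes, chemical noise
and matrix clusters, chromatographic behaviour, or digestion/absorption
kinetics of the fed fatty acids. Passing recovery tests therefore
demonstrate the *assignment logic* under a faithful mass-error model, not
instrument-level realism.

Recovery (fraction of draws whose top-1 assignment equals the generating
form, no-match counting as failure) is 1.0 at zero noise by construction,
and ≥ 0.90 at σ = 0.05 with the default space — the minimum candidate gap
(0.98 Da) is ~20σ, so errors come only from the 0.25 Da acceptance window
(a 5σ event), not from confusions. The median offset estimator recovers a
−0.16 Da shift to within ±0.05 Da from 30 observations on ≥ 95% of seeds
(the SE of a median at σ = 0.05, n = 30 is ≈ 0.011 Da).

## Numerical and interface choices

- Candidate sets are sorted by mass (ties by label), making enumeration
  deterministic and letting the matcher bisect; a linear-scan oracle in
  the tests guards the equivalence.
- All user-facing indices are 1-based (biochemistry convention);
  internals are 0-based Python slices.
- Output files are byte-stable for fixed input: fixed float formats
  (4 decimals for Da, 1 for mDa), sorted JSON keys.
- Degenerate-primer expansion is capped (default 10⁶) with the count
  available in closed form without materialization.
- Translation uses the standard genetic code only, rejects ambiguity
  codes, and reports whether a stop codon was seen.
- Problem sizes in the test suite (simulations of 30–1000 masses, 20–100
  seeds) were chosen so the statistical assertions have comfortable
  margins (binomial/median SEs an order of magnitude below the asserted
  bounds) while the whole suite stays interactive-fast.

## Limitations

- One acyl site, one modification at a time; no N-terminal truncation
  series, no charge states beyond +1, no isotope-envelope or MS/MS
  modelling.
- The "+24" adduct identity is left unresolved; its registry delta is an
  empirical constant, so adduct-enabled assignments inherit its ±0.1 Da
  uncertainty.
- Mixture weights for the feeding scenarios cannot be validated against
  published proportions (none are printed); only the rank structure is
  testable.
- Absolute quantification, bioassay activity and mRNA expression are out
  of scope; fraction-group strings are carried as labels only.
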