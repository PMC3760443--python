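"""Barfin flounder ghrelin reference inputs bundled with the package.

The cDNA-deduced mature ghrelin of the barfin flounder (*Verasper moseri*)
is the 20-residue peptide GSSFLSPSHKPPNKGKPPRA, acylated at Ser3 and
followed in the precursor by the glycine that donates the C-terminal amide
of the 20-residue mature form. Bundled TSV fixtures transcribe the
published MALDI-TOF mass lists of the peptides purified from stomach
extracts of fish on normal (control), C7-, C8- and C9-enriched feeds.
"""

from __future__ import annotations

from importlib import resources
from typing import List

import pandas as pd

from .assigner import ObservedMass
from .seqprep import ProcessingContext

#: cDNA-deduced 20-residue mature ghrelin.
MATURE_CORE = "GSSFLSPSHKPPNKGKPPRA"
#: Precursor residue immediately downstream (the amide-donor glycine).
EXTENSION = "G"
#: Octanoylation/decanoylation site.
ACYL_SITE = 3

#: Published Edman read of the highest-yield purified peptide; the acylated
#: Ser3 gives no signal and reads 'X'.
EDMAN_READ_P1 = "GSXFLSPSHKPPNKGKP"

FEED_GROUPS = ("cont", "c7", "c8", "c9")


def flounder_context() -> ProcessingContext:
    """Processing context for barfin flounder ghrelin."""
    return ProcessingContext(core=MATURE_CORE, extension=EXTENSION, acyl_site=ACYL_SITE)


def fixture_path(group: str):
    """Filesystem path of the bundled mass-list TSV for a feed group."""
    if group not in FEED_GROUPS:
        raise ValueError(f"unknown feed group {group!r}; expected one of {FEED_GROUPS}")
    return resources.files("acylforms.data").joinpath(f"table1_{group}.tsv")


def load_group_table(group: str) -> pd.DataFrame:
    """Bundled mass list as a DataFrame (mz, published label, anomaly note)."""
    with resources.as_file(fixture_path(group)) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype={"sample_id": str})
    df["note"] = df.get("note", pd.Series(dtype=str)).fillna("")
    return df


def load_group_masses(group: str) -> List[ObservedMass]:
    """Bundled mass list as ObservedMass records, in published order."""
    df = load_group_table(group)
    return [
        ObservedMass(sample_id=r.sample_id, group_label=r.group_label, mz=float(r.mz))
        for r in df.itertuples()
    ]
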