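"""Bundled reference tables.

``basal_brca_epitope_hervs`` is the published differential-expression
table for the 18 epitope-containing proviruses overexpressed in the
basal breast cancer subtype (shrunken log2 fold changes versus matched
peritumoral tissue, BH-adjusted p-values, and membership of each of the
six selected HLA-A2 epitopes P1-P6).  It serves as a worked example and
as an input for fold-change and pi-value consistency checks; columns
P1..P6 are 0/1 peptide-containment flags.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

PEPTIDE_COLUMNS = ("P1", "P2", "P3", "P4", "P5", "P6")


def basal_brca_epitope_hervs() -> pd.DataFrame:
    """The 18-provirus basal breast cancer epitope table."""
    ref = resources.files("hervitope.data").joinpath("basal_brca_epitope_hervs.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
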