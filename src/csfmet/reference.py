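"""Bundled reference altered-metabolite tables.

Two published altered-metabolite tables from a CSF metabolomics study of
multiple sclerosis phenotypes (SPMS vs RRMS, SPMS vs controls) ship with
the package as plain TSV. They serve as desk-scale inputs for checking the
FDR and set-overlap machinery against independently printed values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("csfmet.data").joinpath(name).open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    df["kegg_id"] = df["kegg_id"].fillna("")
    return df


def altered_spms_rrms() -> pd.DataFrame:
    """37-row altered-metabolite table for the SPMS vs RRMS contrast."""
    return _load("altered_spms_rrms.tsv")


def altered_spms_controls() -> pd.DataFrame:
    """32-row altered-metabolite table for the SPMS vs controls contrast."""
    return _load("altered_spms_controls.tsv")
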