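"""Central intensity-matrix container shared by all pipeline stages.

Intensities are stored on the linear scale with ``NaN`` for missing values
(a zero in the MaxQuant-style input dialect means "not quantified" and is
converted on read). Sample design metadata travels with the matrix so every
downstream stage can resolve replicate structure without re-reading files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DESIGN_COLUMNS = [
    "cell_line",
    "treatment",
    "timepoint",
    "bio_rep",
    "rep_kind",
    "parent_sample",
]

FLAG_COLUMNS = ["reverse", "contaminant", "only_by_site"]

REP_KINDS = ("BR", "SR", "TR")


@dataclass
class IntensityMatrix:
    """Protein x sample LFQ intensity matrix plus per-sample design metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by protein accession, one column per sample,
        linear-scale intensities, ``NaN`` for missing.
    design
        DataFrame indexed by sample identifier with columns
        ``cell_line, treatment, timepoint, bio_rep, rep_kind, parent_sample``.
    peptides
        Per-protein peptide counts (Series indexed like ``intensities``).
    flags
        Per-protein boolean columns ``reverse, contaminant, only_by_site``.
    log2
        True once values have been log2-transformed (bookkeeping only).
    """

    intensities: pd.DataFrame
    design: pd.DataFrame
    peptides: pd.Series | None = None
    flags: pd.DataFrame | None = None
    log2: bool = False
    presence: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            dupes = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate protein accessions: {sorted(set(dupes))}")
        missing_meta = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing_meta:
            raise ValueError(f"design table lacks columns: {missing_meta}")
        unmatched = [s for s in self.intensities.columns if s not in self.design.index]
        if unmatched:
            raise ValueError(f"samples absent from design table: {unmatched}")
        bad_kind = set(self.design["rep_kind"]) - set(REP_KINDS)
        if bad_kind:
            raise ValueError(f"unknown rep_kind values: {sorted(bad_kind)}")
        if not self.log2:
            vals = self.intensities.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError("linear intensities must be >= 0")

    @property
    def proteins(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> pd.Index:
        return self.intensities.columns

    def samples_of_kind(self, rep_kind: str) -> list[str]:
        """Sample identifiers whose design ``rep_kind`` equals *rep_kind*."""
        sel = self.design.loc[list(self.samples)]
        return list(sel.index[sel["rep_kind"] == rep_kind])

    def with_intensities(self, values: pd.DataFrame, **kwargs) -> "IntensityMatrix":
        """Copy of this matrix with *values* substituted for the intensities."""
        return replace(self, intensities=values, **kwargs)
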