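"""Input parsing, identification filtering and replicate quality control.

The reader speaks the MaxQuant proteinGroups dialect (zero intensity means
missing, "+" marks flag columns). QC covers pairwise Pearson correlation of
log2 intensities, identification overlap across biological replicates, and
per-protein coefficients of variation from SR / TR injection groups.
"""

from __future__ import annotations

import itertools
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import DESIGN_COLUMNS, IntensityMatrix

log = logging.getLogger(__name__)

_FLAG_MAP = {
    "Reverse": "reverse",
    "Potential contaminant": "contaminant",
    "Only identified by site": "only_by_site",
}
_LFQ_PREFIX = "LFQ intensity "


def read_design(path: str) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"parent_sample": str}, keep_default_na=False)
    if "sample" not in design.columns:
        raise ValueError("design table must have a 'sample' column")
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table lacks columns: {missing}")
    design["bio_rep"] = design["bio_rep"].astype(int)
    return design.set_index("sample")


def read_protein_groups(path: str, design_path: str) -> IntensityMatrix:
    """Parse a proteinGroups-style TSV together with its design table.

    Zeros become missing values (MaxQuant convention); every LFQ column
    must be described by a design row and vice versa.
    """
    design = read_design(design_path)
    table = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    if "Protein IDs" not in table.columns:
        raise ValueError("missing 'Protein IDs' column")
    table = table.set_index("Protein IDs")
    table.index.name = "protein"
    if table.index.has_duplicates:
        dupes = sorted(set(table.index[table.index.duplicated()]))
        raise ValueError(f"duplicate protein accessions: {dupes}")

    lfq_cols = [c for c in table.columns if c.startswith(_LFQ_PREFIX)]
    samples = [c[len(_LFQ_PREFIX) :] for c in lfq_cols]
    unmatched = [s for s in samples if s not in design.index]
    if unmatched:
        raise ValueError(f"LFQ columns with no design row: {unmatched}")
    missing_cols = [s for s in design.index if s not in samples]
    if missing_cols:
        raise ValueError(f"design samples with no LFQ column: {missing_cols}")

    intensities = table[lfq_cols].astype(float)
    intensities.columns = samples
    intensities = intensities.mask(intensities == 0.0)

    peptides = None
    if "Peptides" in table.columns:
        peptides = table["Peptides"].astype(int)
    flags = pd.DataFrame(index=table.index)
    for col, name in _FLAG_MAP.items():
        flags[name] = table[col].astype(str).str.strip() == "+" if col in table.columns else False

    return IntensityMatrix(
        intensities=intensities,
        design=design.loc[samples],
        peptides=peptides,
        flags=flags,
    )


def filter_identifications(m: IntensityMatrix, min_peptides: int = 2) -> IntensityMatrix:
    """Drop reverse / contaminant / only-by-site rows and low-peptide rows.

    Removal counts per reason are logged. Idempotent.
    """
    if m.flags is None:
        raise ValueError("matrix has no flag columns")
    if m.peptides is None:
        raise ValueError("matrix has no peptide-count column")
    drop = pd.Series(False, index=m.proteins)
    for reason in ("reverse", "contaminant", "only_by_site"):
        hits = m.flags[reason]
        log.info("filter_identifications: %d rows flagged %s", int(hits.sum()), reason)
        drop |= hits
    low = m.peptides < min_peptides
    log.info("filter_identifications: %d rows with < %d peptides", int(low.sum()), min_peptides)
    drop |= low
    keep = m.proteins[~drop]
    return IntensityMatrix(
        intensities=m.intensities.loc[keep],
        design=m.design,
        peptides=m.peptides.loc[keep],
        flags=m.flags.loc[keep],
        log2=m.log2,
    )


def pearson_pairs(
    m: IntensityMatrix, scope: str | list[str] | None = None, min_shared: int = 3
) -> pd.DataFrame:
    """Pairwise Pearson r on log2 intensities over pairwise-complete proteins.

    *scope* selects samples by rep_kind ("BR", "SR", "TR"), by explicit
    list, or all samples when None. Pairs sharing fewer than *min_shared*
    proteins get ``NaN``. Returns long-format columns
    ``sample_a, sample_b, r, n_shared``.
    """
    if scope is None:
        samples = list(m.samples)
    elif isinstance(scope, str):
        samples = m.samples_of_kind(scope)
    else:
        samples = list(scope)
    if len(samples) < 2:
        raise ValueError(f"scope selects {len(samples)} samples; need >= 2")

    vals = m.intensities[samples]
    logged = vals if m.log2 else np.log2(vals)
    rows = []
    for a, b in itertools.combinations(samples, 2):
        pair = logged[[a, b]].dropna()
        n = len(pair)
        if n < min_shared:
            r = np.nan
        else:
            r = float(np.corrcoef(pair[a], pair[b])[0, 1])
        rows.append({"sample_a": a, "sample_b": b, "r": r, "n_shared": n})
    return pd.DataFrame(rows)


def replicate_overlap(m: IntensityMatrix, group: list[str]) -> dict:
    """Identification overlap for a biological-replicate group.

    Returns the group Jaccard as a percentage (100 * |intersection| /
    |union| of identified-protein sets) plus every pairwise Jaccard.
    A protein counts as identified in a sample when its intensity is
    present. An empty union yields ``overlap_pct = None``.
    """
    if len(group) < 2:
        raise ValueError("replicate group needs >= 2 samples")
    sets = {s: set(m.proteins[m.intensities[s].notna()]) for s in group}
    union = set().union(*sets.values())
    inter = set.intersection(*sets.values())
    pairwise = []
    for a, b in itertools.combinations(group, 2):
        u = sets[a] | sets[b]
        pairwise.append(
            {
                "sample_a": a,
                "sample_b": b,
                "jaccard": (len(sets[a] & sets[b]) / len(u)) if u else np.nan,
            }
        )
    overlap = 100.0 * len(inter) / len(union) if union else None
    return {"overlap_pct": overlap, "pairwise": pd.DataFrame(pairwise)}


@dataclass
class CvTable:
    """Per-protein SR / TR coefficients of variation (percent)."""

    table: pd.DataFrame  # columns: cv_sr, cv_tr, n_sr, n_tr

    def passing(self, cv_max: float = 20.0) -> pd.Index:
        t = self.table
        ok = (t["cv_sr"] < cv_max) & (t["cv_tr"] < cv_max)
        return t.index[ok.fillna(False)]


def _group_cv(values: pd.DataFrame, on_log2: bool) -> pd.Series:
    """CV% per protein over the columns of *values* (linear intensities)."""
    data = np.log2(values) if on_log2 else values
    n = data.notna().sum(axis=1)
    mean = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean
    cv[n < 2] = np.nan
    cv[mean == 0] = np.nan
    return cv


def compute_cv(m: IntensityMatrix, on_log2: bool = False, combine: str = "mean") -> CvTable:
    """Per-protein CV% from SR and TR injection groups.

    Each group is a parent biological-replicate sample plus its SR (resp.
    TR) injections; the per-group CVs are combined across groups with
    *combine* (mean / median / max). CVs use the n-1 standard deviation on
    linear intensities by default.
    """
    if combine not in ("mean", "median", "max"):
        raise ValueError(f"unknown combine rule: {combine}")
    results = {}
    for kind in ("SR", "TR"):
        reps = m.samples_of_kind(kind)
        if not reps:
            raise ValueError(
                f"no {kind} samples in the design; add rows with rep_kind={kind} "
                "and parent_sample set to the corresponding BR sample"
            )
        groups: dict[str, list[str]] = {}
        for s in reps:
            parent = m.design.loc[s, "parent_sample"]
            if parent not in m.samples:
                raise ValueError(f"{kind} sample {s} references unknown parent {parent!r}")
            groups.setdefault(parent, []).append(s)
        cvs = []
        n_used = pd.Series(0, index=m.proteins)
        for parent, children in groups.items():
            cols = [parent, *children]
            vals = m.intensities[cols]
            cvs.append(_group_cv(vals, on_log2))
            n_used += vals.notna().sum(axis=1)
        stacked = pd.concat(cvs, axis=1)
        combined = getattr(stacked, combine)(axis=1)
        combined[stacked.notna().sum(axis=1) == 0] = np.nan
        results[f"cv_{kind.lower()}"] = combined
        results[f"n_{kind.lower()}"] = n_used
    table = pd.DataFrame(results, index=m.proteins)
    return CvTable(table=table)


def write_qc_report(m: IntensityMatrix, out_dir: str) -> dict[str, str]:
    """Run the standard QC battery and write TSV reports."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    pearson = pearson_pairs(m)
    paths["pearson"] = os.path.join(out_dir, "qc_pearson.tsv")
    pearson.to_csv(paths["pearson"], sep="\t", index=False)

    design = m.design.loc[list(m.samples)]
    br = design[design["rep_kind"] == "BR"]
    rows = []
    for (line, treat, tp), sub in br.groupby(["cell_line", "treatment", "timepoint"], sort=False):
        if len(sub) < 2:
            continue
        res = replicate_overlap(m, list(sub.index))
        rows.append(
            {
                "cell_line": line,
                "treatment": treat,
                "timepoint": tp,
                "n_replicates": len(sub),
                "overlap_pct": res["overlap_pct"],
            }
        )
    paths["overlap"] = os.path.join(out_dir, "qc_overlap.tsv")
    pd.DataFrame(rows).to_csv(paths["overlap"], sep="\t", index=False)

    cv = compute_cv(m)
    paths["cv"] = os.path.join(out_dir, "qc_cv.tsv")
    cv.table.rename_axis("protein").to_csv(paths["cv"], sep="\t")
    return paths
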