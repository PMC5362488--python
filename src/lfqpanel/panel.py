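"""Candidate-panel assembly and additive evidence scoring.

Hx candidates are proteins significant in any per-cell-line
treated-vs-control t-test; AS candidates are proteins significant in the
all-sample ANOVA separating androgen-sensitive from androgen-independent
lines. Both are gated on SR and TR coefficients of variation, then scored
by five +1 evidence criteria and selected at a score threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import pandas as pd

from .qc import CvTable

log = logging.getLogger(__name__)

PANEL_KINDS = ("AS", "Hx")

# literature hypoxia markers used as the Hx prior-evidence source
HX_LITERATURE_MARKERS = frozenset({"P14174", "P04075", "Q14573", "Q92597"})


@dataclass
class AnnotationRecord:
    """Per-protein boolean evidence flags; each true flag scores +1."""

    protein: str
    prior_evidence: bool = False
    biomarker_or_drug_target: bool = False
    secreted: bool = False
    exosome: bool = False
    database_match: bool = False

    FLAGS = (
        "prior_evidence",
        "biomarker_or_drug_target",
        "secreted",
        "exosome",
        "database_match",
    )

    def __post_init__(self) -> None:
        for name in self.FLAGS:
            value = getattr(self, name)
            if not isinstance(value, (bool,)):
                raise TypeError(f"{name} must be bool, got {type(value).__name__}")


def score_candidate(rec: AnnotationRecord) -> int:
    """Additive score: one point per true evidence flag (0–5)."""
    return sum(int(getattr(rec, name)) for name in AnnotationRecord.FLAGS)


def read_annotations(path: str, prior_list: set[str] | None = None) -> dict[str, AnnotationRecord]:
    """Read the annotation TSV (protein + five 0/1 columns).

    *prior_list* accessions get ``prior_evidence`` forced true (e.g. the
    literature hypoxia-marker list); proteins absent from the table default
    every flag to false.
    """
    table = pd.read_csv(path, sep="\t", dtype={"protein": str}).set_index("protein")
    records = {}
    for protein, row in table.iterrows():
        kwargs = {name: bool(row[name]) for name in AnnotationRecord.FLAGS if name in row}
        records[protein] = AnnotationRecord(protein=protein, **kwargs)
    if prior_list:
        for acc in prior_list:
            rec = records.setdefault(acc, AnnotationRecord(protein=acc))
            rec.prior_evidence = True
    return records


def read_marker_list(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


@dataclass
class PanelCandidate:
    protein: str
    panel_kind: str
    cv_sr: float
    cv_tr: float
    contrasts: list[str] = field(default_factory=list)
    estimate: float = float("nan")
    score: int = 0
    selected: bool = False


def assemble_candidates(
    diff: pd.DataFrame,
    cv: CvTable,
    panel_kind: str,
    cv_max: float = 20.0,
    annotations: dict[str, AnnotationRecord] | None = None,
) -> list[PanelCandidate]:
    """CV-gate the significant proteins of *diff* into panel candidates.

    *diff* is a long-format differential table (protein, contrast,
    estimate, p_value, significant) holding the contrasts relevant to the
    panel kind. A protein qualifies when significant in at least one
    contrast and both its SR and TR CV are below *cv_max*; proteins
    lacking a defined CV are excluded with a logged reason. Scores are
    filled from *annotations* when given.
    """
    if panel_kind not in PANEL_KINDS:
        raise ValueError(f"unknown panel_kind {panel_kind!r}; expected one of {PANEL_KINDS}")
    sig = diff[diff["significant"]]
    candidates: list[PanelCandidate] = []
    for protein, rows in sig.groupby("protein", sort=False):
        if protein not in cv.table.index:
            log.info("panel %s: %s excluded — no CV available", panel_kind, protein)
            continue
        cv_row = cv.table.loc[protein]
        if pd.isna(cv_row["cv_sr"]) or pd.isna(cv_row["cv_tr"]):
            log.info("panel %s: %s excluded — CV undefined", panel_kind, protein)
            continue
        if not (cv_row["cv_sr"] < cv_max and cv_row["cv_tr"] < cv_max):
            log.info(
                "panel %s: %s excluded — CV gate (SR %.1f%%, TR %.1f%%)",
                panel_kind,
                protein,
                cv_row["cv_sr"],
                cv_row["cv_tr"],
            )
            continue
        best = rows.loc[rows["p_value"].idxmin()]
        cand = PanelCandidate(
            protein=protein,
            panel_kind=panel_kind,
            cv_sr=float(cv_row["cv_sr"]),
            cv_tr=float(cv_row["cv_tr"]),
            contrasts=list(rows["contrast"]),
            estimate=float(best["estimate"]),
        )
        if annotations is not None:
            rec = annotations.get(protein, AnnotationRecord(protein=protein))
            cand.score = score_candidate(rec)
        candidates.append(cand)
    return candidates


def select_panel(candidates: list[PanelCandidate], threshold: int = 2) -> list[PanelCandidate]:
    """Retain candidates with score >= threshold, deterministically ordered.

    Order: score descending, TR CV ascending, accession ascending. Marks
    ``selected`` on the retained candidates.
    """
    chosen = [c for c in candidates if c.score >= threshold]
    chosen.sort(key=lambda c: (-c.score, c.cv_tr, c.protein))
    for c in chosen:
        c.selected = True
    return chosen


def panel_to_frame(candidates: list[PanelCandidate]) -> pd.DataFrame:
    cols = [f.name for f in fields(PanelCandidate)]
    rows = []
    for c in candidates:
        row = {name: getattr(c, name) for name in cols}
        row["contrasts"] = ";".join(row["contrasts"])
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)
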