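"""Synthetic study generator.

Emulates a replicate-structured label-free discovery experiment: a protein
catalog with known effects, annotation flags, housekeeping members and
tryptic-friendly sequences; an intensity matrix with nested biological /
preparation / injection noise; and the on-disk fixture files every other
pipeline stage consumes (proteinGroups-style TSV, design TSV, annotation
TSV, housekeeping list, FASTA, spectral-library table).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

ANNOTATION_FLAGS = [
    "prior_evidence",
    "biomarker_or_drug_target",
    "secreted",
    "exosome",
    "database_match",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror a 3 cell-line x 2 treatment x 2 timepoint design with
    three biological replicates and one SR / one TR injection per condition
    cell. Noise standard deviations are on the log2 scale and nested:
    ``sigma_bio > sigma_tech >= sigma_inj``.
    """

    n_proteins: int = 500
    cell_lines: list[str] = field(default_factory=lambda: ["LNCaP", "Abl", "Hof"])
    treatments: list[str] = field(default_factory=lambda: ["DMOG", "control"])
    timepoints: list[str] = field(default_factory=lambda: ["8h", "24h"])
    n_bio_reps: int = 3
    n_sr: int = 1
    n_tr: int = 1
    frac_de_hx: float = 0.1
    frac_de_as: float = 0.1
    effect_log2: float = 2.0
    sigma_bio: float = 0.5
    sigma_tech: float = 0.2
    sigma_inj: float = 0.1
    detection_limit: float = -np.inf
    frac_mar: float = 0.0
    frac_secreted: float = 0.15
    frac_biomarker: float = 0.1
    frac_exosome: float = 0.5
    frac_dbmatch: float = 0.1
    frac_prior: float = 0.05
    frac_housekeeping: float = 0.05
    frac_flagged: float = 0.02
    baseline_mean: float = 25.0
    baseline_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_de_hx": self.frac_de_hx,
            "frac_de_as": self.frac_de_as,
            "frac_mar": self.frac_mar,
            "frac_secreted": self.frac_secreted,
            "frac_biomarker": self.frac_biomarker,
            "frac_exosome": self.frac_exosome,
            "frac_dbmatch": self.frac_dbmatch,
            "frac_prior": self.frac_prior,
            "frac_housekeeping": self.frac_housekeeping,
            "frac_flagged": self.frac_flagged,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("sigma_bio", "sigma_tech", "sigma_inj"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_proteins < 1:
            raise ValueError(f"n_proteins must be >= 1, got {self.n_proteins}")
        if self.n_bio_reps < 2:
            raise ValueError(f"n_bio_reps must be >= 2, got {self.n_bio_reps}")
        if not np.isfinite(self.effect_log2):
            raise ValueError(f"effect_log2 must be finite, got {self.effect_log2}")
        if len(self.cell_lines) < 1 or len(self.treatments) < 2:
            raise ValueError("need >= 1 cell line and >= 2 treatments")


@dataclass
class GroundTruth:
    """Per-protein simulation truth: accession-indexed table plus sequences.

    ``table`` columns: baseline (log2), one ``cl_effect:<line>`` per cell
    line, one ``tr_effect:<line>`` per cell line (applied only to treated
    samples), the five annotation flags, ``housekeeping``, the QC flags
    (``reverse``, ``contaminant``, ``only_by_site``) and ``peptides``.
    """

    table: pd.DataFrame
    sequences: dict[str, str]
    config: SimulationConfig

    @property
    def accessions(self) -> pd.Index:
        return self.table.index


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    # K+R combined frequency boosted to 12% so tryptic peptides of usable
    # length are common; other residues uniform over the remaining mass.
    probs = np.full(20, 0.88 / 18.0)
    probs[AMINO_ACIDS.index("K")] = 0.06
    probs[AMINO_ACIDS.index("R")] = 0.06
    idx = rng.choice(20, size=length, p=probs)
    return "".join(AMINO_ACIDS[i] for i in idx)


def simulate_catalog(config: SimulationConfig) -> GroundTruth:
    """Draw the protein catalog: effects, annotations, sequences, QC flags."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    acc = [f"SIM{i:05d}" for i in range(n)]

    table = pd.DataFrame(index=pd.Index(acc, name="protein"))
    table["baseline"] = rng.normal(config.baseline_mean, config.baseline_sd, n)

    housekeeping = rng.random(n) < config.frac_housekeeping
    # Housekeeping proteins carry no treatment or cell-line effect by
    # construction, so they remain valid normalizers.
    de_hx = (rng.random(n) < config.frac_de_hx) & ~housekeeping
    de_as = (rng.random(n) < config.frac_de_as) & ~housekeeping
    hx_sign = rng.choice([-1.0, 1.0], n)
    as_sign = rng.choice([-1.0, 1.0], n)

    for line in config.cell_lines:
        table[f"cl_effect:{line}"] = 0.0
        table[f"tr_effect:{line}"] = np.where(de_hx, hx_sign * config.effect_log2, 0.0)
    # The first cell line plays the androgen-sensitive role: AS-effect
    # proteins differ between it and the remaining lines.
    as_line = config.cell_lines[0]
    table[f"cl_effect:{as_line}"] = np.where(de_as, as_sign * config.effect_log2, 0.0)

    table["housekeeping"] = housekeeping
    table["de_hx"] = de_hx
    table["de_as"] = de_as

    table["prior_evidence"] = rng.random(n) < config.frac_prior
    table["biomarker_or_drug_target"] = rng.random(n) < config.frac_biomarker
    table["secreted"] = rng.random(n) < config.frac_secreted
    table["exosome"] = rng.random(n) < config.frac_exosome
    table["database_match"] = rng.random(n) < config.frac_dbmatch

    flagged = rng.random(n) < config.frac_flagged
    which = rng.integers(0, 3, n)
    table["reverse"] = flagged & (which == 0)
    table["contaminant"] = flagged & (which == 1)
    table["only_by_site"] = flagged & (which == 2)

    table["peptides"] = rng.integers(1, 31, n)

    lengths = rng.integers(100, 601, n)
    sequences = {a: _random_sequence(rng, int(ln)) for a, ln in zip(acc, lengths)}

    return GroundTruth(table=table, sequences=sequences, config=config)


def build_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet for the configured study.

    Every condition cell gets ``n_bio_reps`` BR injections; the first
    biological replicate of each cell additionally gets ``n_sr`` SR and
    ``n_tr`` TR injections referencing it as ``parent_sample``.
    """
    rows = []
    for line in config.cell_lines:
        for treat in config.treatments:
            for tp in config.timepoints:
                stem = f"{line}_{treat}_{tp}"
                for rep in range(1, config.n_bio_reps + 1):
                    rows.append(
                        {
                            "sample": f"{stem}_BR{rep}",
                            "cell_line": line,
                            "treatment": treat,
                            "timepoint": tp,
                            "bio_rep": rep,
                            "rep_kind": "BR",
                            "parent_sample": "",
                        }
                    )
                parent = f"{stem}_BR1"
                for k in range(1, config.n_sr + 1):
                    rows.append(
                        {
                            "sample": f"{stem}_SR{k}",
                            "cell_line": line,
                            "treatment": treat,
                            "timepoint": tp,
                            "bio_rep": 1,
                            "rep_kind": "SR",
                            "parent_sample": parent,
                        }
                    )
                for k in range(1, config.n_tr + 1):
                    rows.append(
                        {
                            "sample": f"{stem}_TR{k}",
                            "cell_line": line,
                            "treatment": treat,
                            "timepoint": tp,
                            "bio_rep": 1,
                            "rep_kind": "TR",
                            "parent_sample": parent,
                        }
                    )
    return pd.DataFrame(rows).set_index("sample")


def simulate_matrix(truth: GroundTruth, config: SimulationConfig | None = None) -> IntensityMatrix:
    """Generate the linear-scale intensity matrix from the catalog.

    log2 signal per sample = baseline + cell-line effect + treatment effect
    (treated samples only) + biological deviate (shared by a replicate's
    SR/TR injections) + preparation deviate (shared by BR and its TR) +
    injection deviate. Values below ``detection_limit`` become missing.
    """
    config = config or truth.config
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    design = build_design(config)
    n = len(truth.accessions)
    t = truth.table

    control = config.treatments[-1]
    mu = {}
    for line in config.cell_lines:
        for treat in config.treatments:
            base = t["baseline"].to_numpy() + t[f"cl_effect:{line}"].to_numpy()
            if treat != control:
                base = base + t[f"tr_effect:{line}"].to_numpy()
            mu[(line, treat)] = base

    # Nested deviates: bio per (cell, rep); prep per BR injection (shared by
    # its TR); injection per column.
    bio_dev: dict[tuple, np.ndarray] = {}
    prep_dev: dict[str, np.ndarray] = {}
    cols = {}
    for sample, row in design.iterrows():
        cell_key = (row.cell_line, row.treatment, row.timepoint, row.bio_rep)
        if cell_key not in bio_dev:
            bio_dev[cell_key] = rng.normal(0.0, config.sigma_bio, n)
        parent = row.parent_sample or sample
        if row.rep_kind in ("BR", "TR"):
            if parent not in prep_dev:
                prep_dev[parent] = rng.normal(0.0, config.sigma_tech, n)
            prep = prep_dev[parent]
        else:  # SR: split pre-digestion, fresh preparation noise
            prep = rng.normal(0.0, config.sigma_tech, n)
        inj = rng.normal(0.0, config.sigma_inj, n)
        log2_vals = mu[(row.cell_line, row.treatment)] + bio_dev[cell_key] + prep + inj
        log2_vals = np.where(log2_vals < config.detection_limit, np.nan, log2_vals)
        if config.frac_mar > 0:
            log2_vals = np.where(rng.random(n) < config.frac_mar, np.nan, log2_vals)
        cols[sample] = np.exp2(log2_vals)

    intensities = pd.DataFrame(cols, index=truth.accessions)
    return IntensityMatrix(
        intensities=intensities,
        design=design,
        peptides=t["peptides"].copy(),
        flags=t[["reverse", "contaminant", "only_by_site"]].copy(),
    )


def digest_for_library(sequence: str) -> list[str]:
    # local tryptic split (K/R, not before P) to seed the library table
    peps, start = [], 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 >= len(sequence) or sequence[i + 1] != "P"):
            peps.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peps.append(sequence[start:])
    return peps


def write_fixtures(
    truth: GroundTruth,
    matrix: IntensityMatrix,
    out_dir: str,
    library_frac: float = 0.5,
) -> dict[str, str]:
    """Write all six pipeline input files; returns name -> path mapping.

    The proteinGroups-style TSV uses the MaxQuant dialect: missing
    intensities as 0, "+" in the three flag columns, empty cell otherwise.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "protein_groups": os.path.join(out_dir, "proteinGroups.tsv"),
        "design": os.path.join(out_dir, "design.tsv"),
        "annotations": os.path.join(out_dir, "annotations.tsv"),
        "housekeeping": os.path.join(out_dir, "housekeeping.txt"),
        "fasta": os.path.join(out_dir, "proteins.fasta"),
        "library": os.path.join(out_dir, "library.tsv"),
    }
    t = truth.table

    pg = pd.DataFrame(index=truth.accessions.copy().rename("Protein IDs"))
    pg["Peptides"] = t["peptides"]
    pg["Reverse"] = np.where(t["reverse"], "+", "")
    pg["Potential contaminant"] = np.where(t["contaminant"], "+", "")
    pg["Only identified by site"] = np.where(t["only_by_site"], "+", "")
    for sample in matrix.samples:
        pg[f"LFQ intensity {sample}"] = matrix.intensities[sample].fillna(0.0)
    pg.to_csv(paths["protein_groups"], sep="\t")

    matrix.design.to_csv(paths["design"], sep="\t")

    t[ANNOTATION_FLAGS].astype(int).rename_axis("protein").to_csv(paths["annotations"], sep="\t")

    hk = list(t.index[t["housekeeping"]])
    with open(paths["housekeeping"], "w") as fh:
        fh.write("\n".join(hk) + ("\n" if hk else ""))

    with open(paths["fasta"], "w") as fh:
        for acc in truth.accessions:
            seq = truth.sequences[acc]
            fh.write(f">{acc} simulated protein\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    rng = np.random.default_rng(np.random.SeedSequence([truth.config.seed, 2]))
    lib_rows = []
    for acc in truth.accessions:
        usable = [p for p in digest_for_library(truth.sequences[acc]) if 7 <= len(p) <= 25]
        observed = [p for p in usable if rng.random() < library_frac]
        order = rng.permutation(len(observed))
        for rank, idx in enumerate(order, start=1):
            lib_rows.append({"peptide": observed[idx], "protein": acc, "intensity_rank": rank})
    pd.DataFrame(lib_rows, columns=["peptide", "protein", "intensity_rank"]).to_csv(
        paths["library"], sep="\t", index=False
    )
    return paths
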