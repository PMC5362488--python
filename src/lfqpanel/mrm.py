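"""In-silico MRM assay design.

Tryptic digestion (cleave C-terminal to K/R, suppressed before P), peptide
eligibility filtering (length, reactive residues, ragged ends,
proteotypicity), monoisotopic precursor (2+) and singly charged y-ion m/z
computation, transition filtering and ranking, and transition-list export.
All arithmetic is deterministic; identical inputs give identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

PROTON_MASS = 1.007276466
WATER_MASS = 18.0105646863

# Standard residue monoisotopic masses (Da).
RESIDUE_MASS = {
    "G": 57.02146372057,
    "A": 71.03711378471,
    "S": 87.03202840427,
    "P": 97.05276384885,
    "V": 99.06841391299,
    "T": 101.04767846841,
    "C": 103.00918478471,
    "L": 113.08406397713,
    "I": 113.08406397713,
    "N": 114.04292744114,
    "D": 115.02694302383,
    "Q": 128.05857750528,
    "K": 128.09496301399,
    "E": 129.04259308797,
    "M": 131.04048491299,
    "H": 137.05891185845,
    "F": 147.06841391299,
    "R": 156.10111102359,
    "Y": 163.06332853255,
    "W": 186.07931294985,
}


@dataclass
class DesignRules:
    """Eligibility and transition rules for assay design."""

    min_len: int = 7
    max_len: int = 25
    missed_cleavages: int = 0
    forbidden_residues: frozenset = frozenset({"C", "M"})
    exclude_ragged_ends: bool = True
    require_proteotypic: bool = True
    precursor_charge: int = 2
    product_charge: int = 1
    product_mz_max: float = 1000.0
    precursor_exclusion_window: float = 5.0
    min_fragment_index: int = 2
    min_peptides_per_protein: int = 2
    max_peptides_per_protein: int = 3
    min_transitions_per_peptide: int = 4
    max_transitions_per_peptide: int = 5
    il_equivalent: bool = False

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.product_mz_max <= 0 or self.precursor_exclusion_window < 0:
            raise ValueError("m/z bounds must be positive")
        if self.min_fragment_index < 1:
            raise ValueError("min_fragment_index must be >= 1")


@dataclass
class Peptide:
    """A digestion product with positional context."""

    sequence: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    previous: str  # residue before the peptide, "" at N-terminus
    following: str  # residue after the peptide, "" at C-terminus


@dataclass
class PeptideCandidate:
    protein: str
    sequence: str
    start: int
    end: int
    previous: str
    following: str
    mass: float
    precursor_mz: float
    observed_in_discovery: bool = False
    proteotypic: bool = True
    intensity_rank: int | None = None


@dataclass
class TransitionRow:
    protein: str
    peptide: str
    precursor_mz: float
    fragment: str  # e.g. "y5"
    product_mz: float
    rank: int


def _check_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence):
        if aa not in RESIDUE_MASS:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")


def digest(sequence: str, missed_cleavages: int = 0) -> list[Peptide]:
    """Tryptic digest: cleave after K/R except before P.

    With 0 missed cleavages the peptides partition the sequence; higher
    values additionally emit every join of up to that many adjacent
    fragments.
    """
    _check_sequence(sequence)
    if not sequence:
        return []
    cuts = [0]
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 >= len(sequence) or sequence[i + 1] != "P"):
            if i + 1 < len(sequence):
                cuts.append(i + 1)
    cuts.append(len(sequence))

    peptides = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            start, end = cuts[i], cuts[j]
            peptides.append(
                Peptide(
                    sequence=sequence[start:end],
                    start=start + 1,
                    end=end,
                    previous=sequence[start - 1] if start > 0 else "",
                    following=sequence[end] if end < len(sequence) else "",
                )
            )
    return peptides


def peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic mass: residue masses plus one water."""
    _check_sequence(sequence)
    return sum(RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS


def precursor_mz(sequence: str, charge: int = 2) -> float:
    return (peptide_mass(sequence) + charge * PROTON_MASS) / charge


def y_ion_mz(sequence: str, k: int) -> float:
    """m/z of the singly protonated y_k ion (C-terminal k residues)."""
    if not 1 <= k <= len(sequence) - 1:
        raise ValueError(f"y-ion index {k} out of range for length {len(sequence)}")
    tail = sequence[-k:]
    return sum(RESIDUE_MASS[aa] for aa in tail) + WATER_MASS + PROTON_MASS


def build_background_index(
    sequences: dict[str, str], rules: DesignRules | None = None
) -> dict[str, set[str]]:
    """Peptide -> protein set over the fully digested background FASTA."""
    rules = rules or DesignRules()
    index: dict[str, set[str]] = {}
    for acc, seq in sequences.items():
        for pep in digest(seq, rules.missed_cleavages):
            key = pep.sequence.replace("I", "L") if rules.il_equivalent else pep.sequence
            index.setdefault(key, set()).add(acc)
    return index


def _is_ragged(pep: Peptide, protein_sequence: str) -> bool:
    """Ragged end: peptide bordered by a K/R + K/R junction.

    Either the residue immediately preceding the peptide is K/R with the
    residue before it also K/R, or the peptide's own C-terminal K/R is
    immediately followed by K/R.
    """
    if pep.previous in ("K", "R") and pep.start >= 3:
        before_prev = protein_sequence[pep.start - 3]
        if before_prev in ("K", "R"):
            return True
    if pep.sequence and pep.sequence[-1] in "KR" and pep.following in ("K", "R"):
        return True
    return False


def filter_peptides(
    protein: str,
    peptides: list[Peptide],
    background: dict[str, set[str]],
    library: pd.DataFrame | None = None,
    rules: DesignRules | None = None,
    protein_sequence: str | None = None,
) -> list[PeptideCandidate]:
    """Apply length / residue / ragged-end / proteotypicity rules."""
    rules = rules or DesignRules()
    lib_index: dict[str, int] = {}
    if library is not None and len(library):
        for _, row in library.iterrows():
            lib_index[str(row["peptide"])] = int(row.get("intensity_rank", 0) or 0)

    out = []
    for pep in peptides:
        seq = pep.sequence
        if not rules.min_len <= len(seq) <= rules.max_len:
            continue
        if any(aa in rules.forbidden_residues for aa in seq):
            continue
        if rules.exclude_ragged_ends and protein_sequence is not None:
            if _is_ragged(pep, protein_sequence):
                continue
        key = seq.replace("I", "L") if rules.il_equivalent else seq
        owners = background.get(key, {protein})
        proteotypic = owners == {protein}
        if rules.require_proteotypic and not proteotypic:
            continue
        out.append(
            PeptideCandidate(
                protein=protein,
                sequence=seq,
                start=pep.start,
                end=pep.end,
                previous=pep.previous,
                following=pep.following,
                mass=peptide_mass(seq),
                precursor_mz=precursor_mz(seq, rules.precursor_charge),
                observed_in_discovery=seq in lib_index,
                proteotypic=proteotypic,
                intensity_rank=lib_index.get(seq),
            )
        )
    return out


def build_transitions(
    candidate: PeptideCandidate, rules: DesignRules | None = None
) -> list[TransitionRow]:
    """Enumerate, filter and rank the y-ion transitions of one peptide.

    Products above ``product_mz_max`` or within the precursor exclusion
    window are dropped. Ranking prefers longer fragments (a proxy for
    specificity); up to ``max_transitions_per_peptide`` are kept and the
    peptide yields nothing if fewer than ``min_transitions_per_peptide``
    survive.
    """
    rules = rules or DesignRules()
    seq = candidate.sequence
    kept = []
    for k in range(rules.min_fragment_index, len(seq)):
        mz = y_ion_mz(seq, k)
        if mz > rules.product_mz_max:
            continue
        if abs(mz - candidate.precursor_mz) < rules.precursor_exclusion_window:
            continue
        kept.append((k, mz))
    kept.sort(key=lambda km: -km[0])  # longer fragments first
    kept = kept[: rules.max_transitions_per_peptide]
    if len(kept) < rules.min_transitions_per_peptide:
        log.info(
            "peptide %s dropped: only %d valid transitions (need %d)",
            seq,
            len(kept),
            rules.min_transitions_per_peptide,
        )
        return []
    return [
        TransitionRow(
            protein=candidate.protein,
            peptide=seq,
            precursor_mz=candidate.precursor_mz,
            fragment=f"y{k}",
            product_mz=mz,
            rank=rank,
        )
        for rank, (k, mz) in enumerate(kept, start=1)
    ]


@dataclass
class AssayDesign:
    transitions: pd.DataFrame
    failures: pd.DataFrame  # protein, reason

    EXPORT_COLUMNS = [
        "Protein",
        "Peptide",
        "Precursor_mz",
        "Precursor_charge",
        "Product_mz",
        "Product_charge",
        "Fragment_ion",
        "Rank",
    ]

    def to_csv(self, path: str) -> None:
        self.transitions.to_csv(path, index=False, float_format="%.4f")


def design_assay(
    panel_proteins: list[str],
    sequences: dict[str, str],
    library: pd.DataFrame | None = None,
    rules: DesignRules | None = None,
) -> AssayDesign:
    """Design transitions for every panel protein found in the FASTA.

    Peptides are ranked observed-in-discovery first, then by surviving
    transition count, then alphabetically; the top 2–3 are kept. Proteins
    with no eligible peptide end up in the failure table.
    """
    rules = rules or DesignRules()
    if not panel_proteins:
        raise ValueError("empty panel")
    background = build_background_index(sequences, rules)

    rows = []
    failures = []
    for protein in panel_proteins:
        if protein not in sequences:
            failures.append({"protein": protein, "reason": "absent from FASTA"})
            continue
        seq = sequences[protein]
        lib = None
        if library is not None and len(library):
            lib = library[library["protein"] == protein]
        candidates = filter_peptides(
            protein,
            digest(seq, rules.missed_cleavages),
            background,
            library=lib,
            rules=rules,
            protein_sequence=seq,
        )
        scored = []
        for cand in candidates:
            transitions = build_transitions(cand, rules)
            if transitions:
                scored.append((cand, transitions))
        if not scored:
            reason = "no eligible peptides" if not candidates else "no valid transitions"
            failures.append({"protein": protein, "reason": reason})
            continue
        scored.sort(key=lambda ct: (not ct[0].observed_in_discovery, -len(ct[1]), ct[0].sequence))
        if len(scored) < rules.min_peptides_per_protein:
            log.info(
                "protein %s: only %d eligible peptide(s) (wanted >= %d)",
                protein,
                len(scored),
                rules.min_peptides_per_protein,
            )
        for cand, transitions in scored[: rules.max_peptides_per_protein]:
            for t in transitions:
                rows.append(
                    {
                        "Protein": t.protein,
                        "Peptide": t.peptide,
                        "Precursor_mz": t.precursor_mz,
                        "Precursor_charge": rules.precursor_charge,
                        "Product_mz": t.product_mz,
                        "Product_charge": rules.product_charge,
                        "Fragment_ion": t.fragment,
                        "Rank": t.rank,
                    }
                )
    transitions = pd.DataFrame(rows, columns=AssayDesign.EXPORT_COLUMNS)
    return AssayDesign(
        transitions=transitions,
        failures=pd.DataFrame(failures, columns=["protein", "reason"]),
    )


def read_fasta(path: str) -> dict[str, str]:
    """Accession (first whitespace-delimited header token) -> sequence."""
    sequences: dict[str, str] = {}
    acc = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if acc is not None:
                    sequences[acc] = "".join(chunks)
                acc = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if acc is not None:
        sequences[acc] = "".join(chunks)
    return sequences


def read_library(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"peptide": str, "protein": str})
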