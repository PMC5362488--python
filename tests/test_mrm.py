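import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lfqpanel.mrm import (
    PROTON_MASS,
    RESIDUE_MASS,
    WATER_MASS,
    DesignRules,
    PeptideCandidate,
    build_background_index,
    build_transitions,
    design_assay,
    digest,
    filter_peptides,
    peptide_mass,
    precursor_mz,
    read_fasta,
    y_ion_mz,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences_st = st.text(alphabet=AA, min_size=1, max_size=80)


def brute_force_digest(sequence):
    """Independent oracle: scan cleavage sites, then slice."""
    sites = [
        i + 1
        for i in range(len(sequence))
        if sequence[i] in "KR" and not (i + 1 < len(sequence) and sequence[i + 1] == "P")
    ]
    bounds = [0] + [s for s in sites if s < len(sequence)] + [len(sequence)]
    return [sequence[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]


class TestDigest:
    def test_manual_example(self):
        peps = [p.sequence for p in digest("AKRPTESTKGL")]
        assert peps == ["AK", "RPTESTK", "GL"]

    def test_no_cleavage_sites_single_peptide(self):
        assert [p.sequence for p in digest("ANGELSING")] == ["ANGELSING"]

    def test_kkk_boundary(self):
        assert [p.sequence for p in digest("KKK")] == ["K", "K", "K"]

    def test_positions_and_flanks(self):
        peps = digest("AKRPTESTKGL")
        assert (peps[0].start, peps[0].end) == (1, 2)
        assert (peps[1].start, peps[1].end) == (3, 9)
        assert peps[1].previous == "K" and peps[1].following == "G"
        assert peps[0].previous == "" and peps[-1].following == ""

    def test_non_standard_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            digest("AKXPR")

    @given(sequences_st)
    @settings(max_examples=200, deadline=None)
    def test_concatenation_identity(self, seq):
        assert "".join(p.sequence for p in digest(seq)) == seq

    @given(sequences_st)
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force(self, seq):
        assert [p.sequence for p in digest(seq)] == brute_force_digest(seq)

    def test_missed_cleavages_include_joins(self):
        peps = {p.sequence for p in digest("AKRPTESTKGL", missed_cleavages=1)}
        assert {"AK", "RPTESTK", "GL", "AKRPTESTK", "RPTESTKGL"} == peps


class TestMass:
    def test_empty_sequence_is_water(self):
        assert peptide_mass("") == pytest.approx(WATER_MASS)

    def test_glycine(self):
        assert peptide_mass("G") == pytest.approx(57.02146 + WATER_MASS, abs=1e-4)

    def test_reference_peptide(self):
        assert peptide_mass("PEPTIDE") == pytest.approx(799.35996, abs=1e-3)

    def test_against_biopython_oracle(self):
        from Bio.SeqUtils import molecular_weight

        for seq in ["PEPTIDE", "ACDEFGHIK", "WWWW", "LVNELTEFAK"]:
            expected = molecular_weight(seq, seq_type="protein", monoisotopic=True)
            assert peptide_mass(seq) == pytest.approx(expected, abs=1e-3)

    @given(sequences_st, sequences_st)
    @settings(max_examples=200, deadline=None)
    def test_additivity(self, a, b):
        assert peptide_mass(a + b) == pytest.approx(
            peptide_mass(a) + peptide_mass(b) - WATER_MASS, abs=1e-9
        )

    @given(sequences_st.filter(lambda s: len(s) >= 2))
    @settings(max_examples=100, deadline=None)
    def test_precursor_mz_identity(self, seq):
        assert precursor_mz(seq, 2) == pytest.approx(
            (peptide_mass(seq) + 2 * PROTON_MASS) / 2, rel=1e-6
        )


class TestYIon:
    def test_y1_lysine(self):
        assert y_ion_mz("AVGTK", 1) == pytest.approx(147.113, abs=1e-3)

    def test_highest_y_below_mh(self):
        seq = "SAMPLER"
        mh = peptide_mass(seq) + PROTON_MASS
        assert y_ion_mz(seq, len(seq) - 1) < mh

    def test_strictly_increasing_in_k(self):
        seq = "ELVISLIVES"
        mzs = [y_ion_mz(seq, k) for k in range(1, len(seq))]
        assert all(a < b for a, b in zip(mzs, mzs[1:]))

    def test_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            y_ion_mz("PEPTIDE", 7)


class TestFilterPeptides:
    def _filter(self, protein_seq, background=None, rules=None):
        peps = digest(protein_seq)
        background = background or build_background_index({"PROT": protein_seq})
        return filter_peptides(
            "PROT", peps, background, rules=rules, protein_sequence=protein_seq
        )

    def test_short_peptide_excluded(self):
        out = self._filter("AAAGGGK" + "LLLK")  # LLLK is 4 residues
        assert "LLLK" not in [c.sequence for c in out]

    def test_methionine_and_cysteine_excluded(self):
        seq = "AAAMGGGTTTK" + "AAACGGGTTTK" + "AAADGGGTTTK"
        out = self._filter(seq)
        assert [c.sequence for c in out] == ["AAADGGGTTTK"]

    def test_ragged_end_excluded(self):
        # peptide preceded by a KK junction is ragged
        seq = "AAAGGGKKTTTEEEGGGK" + "SSSSSSS"
        out = self._filter(seq)
        assert "TTTEEEGGGK" not in [c.sequence for c in out]

    def test_shared_peptide_not_proteotypic(self):
        shared = "AAAGGGTTTEEEK"
        seqs = {"P1": shared + "LLLLLLLR", "P2": shared + "VVVVVVVR"}
        background = build_background_index(seqs)
        out = filter_peptides(
            "P1", digest(seqs["P1"]), background, protein_sequence=seqs["P1"]
        )
        assert shared not in [c.sequence for c in out]
        relaxed = filter_peptides(
            "P1",
            digest(seqs["P1"]),
            background,
            rules=DesignRules(require_proteotypic=False),
            protein_sequence=seqs["P1"],
        )
        rec = {c.sequence: c for c in relaxed}
        assert shared in rec and rec[shared].proteotypic is False

    def test_library_marks_observed(self):
        seq = "AAAGGGTTTEEEKLLLDDDFFFR"
        lib = pd.DataFrame({"peptide": ["AAAGGGTTTEEEK"], "protein": ["PROT"], "intensity_rank": [1]})
        out = filter_peptides(
            "PROT", digest(seq), build_background_index({"PROT": seq}),
            library=lib, protein_sequence=seq,
        )
        flags = {c.sequence: c.observed_in_discovery for c in out}
        assert flags["AAAGGGTTTEEEK"] is True
        assert flags["LLLDDDFFFR"] is False


class TestTransitions:
    def _candidate(self, seq):
        return PeptideCandidate(
            protein="PROT", sequence=seq, start=1, end=len(seq),
            previous="", following="", mass=peptide_mass(seq),
            precursor_mz=precursor_mz(seq, 2),
        )

    def test_seven_residue_full_enumeration(self):
        out = build_transitions(self._candidate("LVNELTK"))
        assert [t.fragment for t in out] == ["y6", "y5", "y4", "y3", "y2"]
        assert [t.rank for t in out] == [1, 2, 3, 4, 5]

    def test_precursor_window_exclusion(self):
        # AAAGGGK: y3 sits 4.99 Th from the 2+ precursor, inside the default window
        cand = self._candidate("AAAGGGK")
        out = build_transitions(cand, DesignRules(min_transitions_per_peptide=1))
        assert "y3" not in [t.fragment for t in out]
        assert all(abs(t.product_mz - cand.precursor_mz) >= 5.0 for t in out)

    def test_all_products_above_limit_drops_peptide(self):
        cand = self._candidate("WWWWWWWWWWWW")  # every y2+ fragment > 380; set limit low
        rules = DesignRules(product_mz_max=300.0)
        assert build_transitions(cand, rules) == []

    def test_fewer_than_minimum_drops_peptide(self):
        cand = self._candidate("AAAGGGK")
        rules = DesignRules(product_mz_max=350.0)  # leaves fewer than 4 fragments
        assert build_transitions(cand, rules) == []


class TestDesignAssay:
    def _sequences(self):
        return {
            "PROT1": "AAADDDGGGKTTTEEEFFFRVVVLLLGGGKDDDSSSAAAK",
            "PROT2": "GGGEEEDDDKLLLVVVTTTR",
            "METPROT": "MMMAAAGGGKMMMTTTEEEK",
        }

    def test_observed_peptides_rank_first(self):
        seqs = self._sequences()
        lib = pd.DataFrame(
            {"peptide": ["TTTEEEFFFR"], "protein": ["PROT1"], "intensity_rank": [1]}
        )
        assay = design_assay(["PROT1"], seqs, library=lib)
        first_pep = assay.transitions["Peptide"].iloc[0]
        assert first_pep == "TTTEEEFFFR"

    def test_all_methionine_protein_in_failure_table(self):
        assay = design_assay(["METPROT"], self._sequences())
        assert list(assay.failures["protein"]) == ["METPROT"]
        assert (assay.transitions["Protein"] != "METPROT").all()

    def test_absent_protein_logged(self):
        assay = design_assay(["GHOST"], self._sequences())
        assert list(assay.failures["reason"]) == ["absent from FASTA"]

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError, match="empty"):
            design_assay([], self._sequences())

    def test_peptide_count_matches_exhaustive_oracle(self, rng):
        # brute-force enumeration of eligible peptides per protein
        seqs = {}
        for i in range(20):
            n = rng.integers(100, 300)
            seqs[f"SP{i}"] = "".join(rng.choice(list(AA), size=n))
        rules = DesignRules()
        assay = design_assay(list(seqs), seqs, rules=rules)
        background = build_background_index(seqs, rules)
        for acc, seq in seqs.items():
            eligible = []
            for pep in digest(seq):
                s = pep.sequence
                if not 7 <= len(s) <= 25:
                    continue
                if "C" in s or "M" in s:
                    continue
                prev2 = seq[pep.start - 3] if pep.start >= 3 else ""
                ragged = (pep.previous in ("K", "R") and prev2 in ("K", "R")) or (
                    s[-1] in ("K", "R") and pep.following in ("K", "R")
                )
                if ragged:
                    continue
                if background[s] != {acc}:
                    continue
                cand = PeptideCandidate(
                    protein=acc, sequence=s, start=pep.start, end=pep.end,
                    previous=pep.previous, following=pep.following,
                    mass=peptide_mass(s), precursor_mz=precursor_mz(s, 2),
                )
                transitions = build_transitions(cand, rules)
                if transitions:
                    eligible.append((s, len(transitions)))
            eligible.sort(key=lambda sc: (-sc[1], sc[0]))
            expected = [s for s, _ in eligible[: rules.max_peptides_per_protein]]
            got = list(
                dict.fromkeys(
                    assay.transitions.loc[assay.transitions["Protein"] == acc, "Peptide"]
                )
            )
            assert sorted(got) == sorted(expected)

    def test_output_deterministic(self):
        seqs = self._sequences()
        a = design_assay(["PROT1", "PROT2"], seqs)
        b = design_assay(["PROT1", "PROT2"], seqs)
        pd.testing.assert_frame_equal(a.transitions, b.transitions)

    def test_transition_constraints_hold(self, rng):
        rules = DesignRules()
        seqs = {f"RP{i}": "".join(rng.choice(list(AA), size=int(rng.integers(80, 400))))
                for i in range(50)}
        assay = design_assay(list(seqs), seqs, rules=rules)
        t = assay.transitions
        if len(t):
            assert (t["Product_mz"] <= rules.product_mz_max).all()
            assert (
                (t["Product_mz"] - t["Precursor_mz"]).abs() >= rules.precursor_exclusion_window
            ).all()
            assert (t["Precursor_charge"] == 2).all()
            assert (t["Product_charge"] == 1).all()
            per_pep = t.groupby("Peptide").size()
            assert per_pep.between(
                rules.min_transitions_per_peptide, rules.max_transitions_per_peptide
            ).all()
            per_prot = t.groupby("Protein")["Peptide"].nunique()
            assert (per_prot <= rules.max_peptides_per_protein).all()


class TestFastaIo:
    def test_read_fasta_first_token(self, tmp_path):
        path = tmp_path / "t.fasta"
        path.write_text(">ACC1 some description\nAAAK\nGGGR\n>ACC2\nTTTK\n")
        assert read_fasta(str(path)) == {"ACC1": "AAAKGGGR", "ACC2": "TTTK"}
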