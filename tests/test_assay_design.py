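"""Panel construction: candidate/transition selection and serialization."""

import itertools

import numpy as np
import pytest

from srmquant.assay_design import (
    AssayConfig,
    SpectralLibraryEntry,
    build_panel,
    read_transition_list,
    select_peptide_candidates,
    select_transitions,
    write_transition_list,
)
from srmquant.errors import AssayDesignWarning, InvalidInputError
from srmquant.peptide_chem import (
    HEAVY_ARG,
    HEAVY_LYS,
    ProteinRecord,
    digest_trypsin,
    proteome_uniqueness,
)
from srmquant.synthetic_data import make_library, make_proteome


def entry_for(pep: str, intensities: dict[str, float]) -> SpectralLibraryEntry:
    return SpectralLibraryEntry(
        peptide_sequence=pep,
        precursor_charge=2,
        fragments=tuple((label, 1, inten) for label, inten in intensities.items()),
    )


class TestSelectTransitions:
    def test_top_five_of_seven_distinct_intensities(self):
        pep = "AVAENQPFLIEAMTYR"  # length 16: y3..y9 all valid
        intensities = {f"y{i}": float(10 * i) for i in range(3, 10)}
        chosen = select_transitions(entry_for(pep, intensities))
        assert len(chosen) == 5
        assert [t.fragment_label for t in chosen] == ["y9", "y8", "y7", "y6", "y5"]
        assert [t.library_rank for t in chosen] == [1, 2, 3, 4, 5]

    def test_shortfall_returns_all_with_warning(self):
        pep = "LSDIGEGIR"
        intensities = {"y3": 5.0, "y4": 9.0, "y5": 7.0}
        with pytest.warns(AssayDesignWarning):
            chosen = select_transitions(entry_for(pep, intensities), n=5)
        assert len(chosen) == 3

    def test_y1_y2_and_non_y_ions_excluded(self):
        pep = "LSDIGEGIR"
        intensities = {"y1": 100.0, "y2": 90.0, "b5": 80.0, "y4": 1.0}
        chosen = select_transitions(entry_for(pep, intensities), n=5)
        assert [t.fragment_label for t in chosen] == ["y4"]

    def test_tied_intensities_resolved_by_enumeration_oracle(self):
        pep = "AVAENQPFLIEAMTYR"
        intensities = {"y3": 50.0, "y4": 50.0, "y5": 50.0, "y6": 80.0, "y7": 50.0,
                      "y8": 50.0}
        chosen = select_transitions(entry_for(pep, intensities), n=3)
        # oracle: enumerate all 3-subsets, pick the documented best
        # (max summed intensity, ties to higher product m/z, then label)
        from srmquant.peptide_chem import y_ion_mz

        def key(labels):
            total = sum(intensities[lab] for lab in labels)
            mzs = sorted((y_ion_mz(pep, int(lab[1:])) for lab in labels),
                         reverse=True)
            return (total, mzs)

        best = max(itertools.combinations(sorted(intensities), 3), key=key)
        assert sorted(t.fragment_label for t in chosen) == sorted(best)

    def test_no_eligible_fragments_warns_and_returns_empty(self):
        pep = "LSDIGEGIR"
        with pytest.warns(AssayDesignWarning):
            assert select_transitions(entry_for(pep, {"b3": 10.0})) == []


@pytest.fixture()
def small_world():
    proteome = make_proteome(n_decoys=10, seed=3)
    library = make_library(proteome, seed=3)
    return proteome, library


class TestCandidateSelection:
    def test_pool_of_ten_yields_exactly_four(self):
        # one protein embedding 10 unique library-supported peptides
        peptides = ["ACDEFGHILM"[i] * 2 + "SSSGGGVVVK" for i in range(10)]
        protein = ProteinRecord("BIG", "", "".join(peptides))
        digest = digest_trypsin(protein)
        assert len(digest) == 10
        library = [
            entry_for(p.sequence, {f"y{i}": float(30 + i) for i in range(3, 9)})
            for p in digest
        ]
        chosen = select_peptide_candidates(protein, digest, library, [protein])
        assert len(chosen) == 4

    def test_single_eligible_peptide_returned_with_warning(self, small_world):
        proteome, library = small_world
        protein = next(p for p in proteome if p.id == "E2")
        digest = digest_trypsin(protein)
        # restrict library support to one peptide
        lib = [e for e in library if e.peptide_sequence == "LSDIGEGIR"]
        with pytest.warns(AssayDesignWarning):
            chosen = select_peptide_candidates(protein, digest, lib, proteome)
        assert [p.sequence for p in chosen] == ["LSDIGEGIR"]

    def test_ranking_matches_summed_intensity_sort(self, small_world):
        proteome, _ = small_world
        protein = next(p for p in proteome if p.id == "MCAD")
        digest = digest_trypsin(protein)
        totals = {"EEIIPVAAEYDK": 400.0, "TGEYPVPLIR": 100.0,
                  "AFTGFIVEADTPGIQIGR": 300.0, "IYQIYEGTSQIQR": 200.0}
        library = [
            entry_for(seq, {f"y{i}": total / 5 for i in range(3, 8)})
            for seq, total in totals.items()
        ]
        chosen = select_peptide_candidates(protein, digest, library, proteome)
        got = [p.sequence for p in chosen]
        assert got == sorted(totals, key=totals.get, reverse=True)

    def test_selected_peptides_are_proteome_unique(self, small_world):
        proteome, library = small_world
        for pid in ("E1A", "MCAD"):
            protein = next(p for p in proteome if p.id == pid)
            chosen = select_peptide_candidates(
                protein, digest_trypsin(protein), library, proteome
            )
            for pep in chosen:
                assert proteome_uniqueness(pep.sequence, proteome) == 1

    def test_empty_digest_is_an_error(self, small_world):
        proteome, library = small_world
        with pytest.raises(InvalidInputError):
            select_peptide_candidates(proteome[0], [], library, proteome)


class TestBuildPanel:
    def test_structure_of_six_protein_panel(self, small_world):
        proteome, library = small_world
        targets = [p for p in proteome if not p.id.startswith("DECOY")]
        digests = {p.id: digest_trypsin(p) for p in targets}
        panel = build_panel(targets, digests, library, proteome)
        assert set(panel.proteins) == {p.id for p in targets}
        for assays in panel.proteins.values():
            assert 2 <= len(assays) <= 4
            for assay in assays:
                assert 1 <= len(assay.light) <= 5
                assert len(assay.light) == len(assay.heavy)
                light_labels = [t.fragment_label for t in assay.light]
                heavy_labels = [t.fragment_label for t in assay.heavy]
                assert light_labels == heavy_labels

    def test_heavy_light_mz_differ_by_label_mass_only(self, small_world):
        proteome, library = small_world
        targets = [p for p in proteome if not p.id.startswith("DECOY")]
        digests = {p.id: digest_trypsin(p) for p in targets}
        panel = build_panel(targets, digests, library, proteome)
        for assays in panel.proteins.values():
            for assay in assays:
                delta = HEAVY_LYS if assay.peptide_sequence.endswith("K") else HEAVY_ARG
                for lt, ht in zip(assay.light, assay.heavy):
                    assert ht.precursor_mz - lt.precursor_mz == pytest.approx(
                        delta / lt.precursor_charge, abs=1e-9
                    )
                    # y ions always contain the labelled C-terminal residue
                    assert ht.product_mz - lt.product_mz == pytest.approx(
                        delta / lt.fragment_charge, abs=1e-9
                    )

    def test_quantifier_is_top_ranked_candidate(self, small_world):
        proteome, library = small_world
        targets = [p for p in proteome if not p.id.startswith("DECOY")]
        digests = {p.id: digest_trypsin(p) for p in targets}
        panel = build_panel(targets, digests, library, proteome)
        for pid in panel.proteins:
            assert panel.quantifier_peptide(pid).candidate_rank == 1

    def test_empty_library_is_an_error(self, small_world):
        proteome, _ = small_world
        targets = [p for p in proteome if not p.id.startswith("DECOY")]
        digests = {p.id: digest_trypsin(p) for p in targets}
        with pytest.raises(InvalidInputError):
            build_panel(targets, digests, [], proteome)

    def test_missing_reference_protein_is_an_error(self, small_world):
        proteome, library = small_world
        targets = [p for p in proteome if p.id in ("E1A", "E2")]
        digests = {p.id: digest_trypsin(p) for p in targets}
        with pytest.raises(InvalidInputError, match="HSP60"):
            build_panel(targets, digests, library, proteome)


class TestTransitionListIO:
    def test_round_trip_identity(self, small_world, tmp_path):
        proteome, library = small_world
        targets = [p for p in proteome if not p.id.startswith("DECOY")]
        digests = {p.id: digest_trypsin(p) for p in targets}
        panel = build_panel(targets, digests, library, proteome)
        path = tmp_path / "transitions.csv"
        write_transition_list(panel, path)
        loaded = read_transition_list(path)
        assert loaded.reference_protein_id == panel.reference_protein_id
        assert set(loaded.proteins) == set(panel.proteins)
        for pid in panel.proteins:
            got = loaded.proteins[pid]
            want = panel.proteins[pid]
            assert [a.peptide_sequence for a in got] == [
                a.peptide_sequence for a in want
            ]
            for ga, wa in zip(got, want):
                assert [t.fragment_label for t in ga.light] == [
                    t.fragment_label for t in wa.light
                ]
                for gt, wt in zip(ga.light + ga.heavy, wa.light + wa.heavy):
                    assert gt.product_mz == pytest.approx(wt.product_mz, abs=1e-6)

    def test_missing_column_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("protein_id,peptide_sequence\nE1A,LSDIGEGIR\n")
        with pytest.raises(InvalidInputError, match="product_mz"):
            read_transition_list(path)

    def test_hand_written_light_heavy_pair(self, tmp_path):
        path = tmp_path / "pair.csv"
        path.write_text(
            "# reference_protein_id=HSP60\n"
            "protein_id,peptide_sequence,is_heavy,precursor_charge,precursor_mz,"
            "fragment_label,fragment_charge,product_mz,library_rank\n"
            "E2,LSDIGEGIR,0,2,473.25,y5,1,516.29,1\n"
            "E2,LSDIGEGIR,1,2,478.25,y5,1,526.30,1\n"
        )
        panel = read_transition_list(path)
        assert list(panel.proteins) == ["E2"]
        assay = panel.proteins["E2"][0]
        assert len(assay.light) == 1 and len(assay.heavy) == 1
        assert assay.heavy[0].product_mz == pytest.approx(526.30)
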