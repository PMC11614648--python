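"""Split-site enumeration, impact-matrix scoring, ranking, filtering, reporting."""

import numpy as np
import pandas as pd
import pytest

from inteinkit.scanner import (
    ALPHA_HELIX,
    BETA_SHEET,
    POSITIONS,
    UNSTRUCTURED,
    ImpactMatrix,
    ScanError,
    SplitSite,
    StructureTrack,
    annotate_structure,
    apply_c1_filter,
    enumerate_sites,
    load_impact_matrix,
    report_table,
    save_impact_matrix,
    scan,
    score_window,
    select_candidates,
    window,
)
from inteinkit.seqcore import AMINO_ACIDS, ProteinRecord
from inteinkit.synth import gen_impact_matrix, gen_random_protein


def flat_matrix(value=0.0):
    df = pd.DataFrame(value, index=list(AMINO_ACIDS), columns=list(POSITIONS), dtype=float)
    return ImpactMatrix(df)


def brute_force_scan(protein, matrix):
    """Independent oracle: score every complete window, sort by (-score, k)."""
    scored = []
    for k in range(3, len(protein) - 2):
        win = protein.seq[k - 3 : k + 3]
        s = sum(matrix.scores.at[res, pos] for pos, res in zip(POSITIONS, win))
        scored.append((k, win, s))
    scored.sort(key=lambda t: (-t[2], t[0]))
    return scored


class TestImpactMatrixIO:
    def test_all_zero_matrix_scores_every_window_zero(self, tmp_path, gfp):
        path = tmp_path / "zero.tsv"
        save_impact_matrix(flat_matrix(0.0), path)
        mat = load_impact_matrix(path)
        assert all(s.score == 0.0 for s in scan(gfp, mat))

    def test_missing_residue_row_imputed_with_warning(self, tmp_path):
        mat = flat_matrix(1.0)
        df = mat.scores.drop(index="W")
        df.insert(0, "residue", df.index)
        path = tmp_path / "partial.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.warns(UserWarning, match="W"):
            loaded = load_impact_matrix(path)
        assert loaded.score("N-1", "W") == 0.0
        assert loaded.score("N-1", "A") == 1.0

    def test_round_trip_preserves_all_120_values(self, tmp_path):
        mat = gen_impact_matrix(seed=7, effect_sd=3.0)
        path = tmp_path / "mat.tsv"
        save_impact_matrix(mat, path)
        loaded = load_impact_matrix(path)
        assert loaded.scores.shape == (20, 6)
        np.testing.assert_allclose(loaded.scores.values, mat.scores.values)

    def test_duplicate_residue_rows_rejected(self, tmp_path):
        mat = flat_matrix(1.0)
        df = mat.scores.copy()
        df.insert(0, "residue", df.index)
        df = pd.concat([df, df.iloc[[0]]])
        path = tmp_path / "dup.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ScanError, match="duplicate"):
            load_impact_matrix(path)

    def test_wrong_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("residue\tN-3\tN-2\nA\t1\t2\n")
        with pytest.raises(ScanError):
            load_impact_matrix(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "nan.tsv"
        header = "residue\t" + "\t".join(POSITIONS)
        rows = [f"{aa}\t1\t1\t1\t1\t1\t{'oops' if aa == 'A' else 1}" for aa in AMINO_ACIDS]
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(ScanError):
            load_impact_matrix(path)


class TestEnumerationAndWindows:
    def test_length_six_has_single_site(self):
        assert enumerate_sites(ProteinRecord("p", "MKVWYH")) == [3]

    def test_length_five_has_no_sites(self):
        with pytest.warns(UserWarning):
            assert enumerate_sites(ProteinRecord("p", "MKVWY")) == []

    @pytest.mark.parametrize("n", [6, 7, 20, 50, 238])
    def test_site_count_is_n_minus_5(self, n):
        assert len(enumerate_sites(gen_random_protein(n, seed=n))) == n - 5

    @pytest.mark.parametrize("k,expected", [(69, "GVQCFS"), (47, "KFICTT"),
                                            (55, "LPVPWP"), (17, "LVELDG")])
    def test_gfp_windows_match_report(self, gfp, k, expected):
        assert window(gfp, k) == expected

    def test_window_is_first_six_at_k3(self):
        assert window(ProteinRecord("p", "ACDEFGH"), 3) == "ACDEFG"

    def test_window_out_of_range(self, gfp):
        for k in (2, 236):
            with pytest.raises(ScanError):
                window(gfp, k)

    def test_c1_is_fourth_window_character(self, gfp):
        for s in scan(gfp, flat_matrix()):
            assert s.c1 == s.window[3] == gfp.residue(s.k + 1)


class TestScoring:
    def test_zero_matrix_scores_zero(self):
        assert score_window("GVQCFS", flat_matrix(0.0)) == 0.0

    def test_unit_matrix_scores_six(self):
        assert score_window("GVQCFS", flat_matrix(1.0)) == 6.0

    def test_non_canonical_residue_strict_vs_lenient(self):
        mat = flat_matrix(1.0)
        with pytest.raises(ScanError):
            score_window("GVQXFS", mat)
        assert score_window("GVQXFS", mat, strict=False) == 5.0

    def test_wrong_window_length(self):
        with pytest.raises(ScanError):
            score_window("GVQ", flat_matrix())

    def test_constant_shift_moves_every_score_by_6c_and_keeps_ranking(self):
        protein = gen_random_protein(40, seed=3)
        mat = gen_impact_matrix(seed=3, effect_sd=2.0)
        shifted = ImpactMatrix(mat.scores + 1.5, dict(mat.meta))
        base, moved = scan(protein, mat), scan(protein, shifted)
        assert [s.k for s in base] == [s.k for s in moved]
        for s0, s1 in zip(base, moved):
            assert s1.score == pytest.approx(s0.score + 9.0)


class TestScan:
    def test_planted_window_ranks_first(self, gfp):
        mat = gen_impact_matrix(seed=11, effect_sd=4.0, planted_window="GVQCFS")
        sites = scan(gfp, mat)
        assert sites[0].rank == 1 and sites[0].window == "GVQCFS" and sites[0].k == 69

    def test_uniform_matrix_orders_by_ascending_position(self, gfp):
        sites = scan(gfp, flat_matrix(2.0))
        assert [s.k for s in sites] == list(range(3, 236))

    def test_ranks_are_a_permutation(self, gfp):
        sites = scan(gfp, gen_impact_matrix(seed=1, effect_sd=3.0))
        assert sorted(s.rank for s in sites) == list(range(1, 234))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        protein = gen_random_protein(int(rng.integers(6, 51)), seed=seed + 1000)
        mat = gen_impact_matrix(seed=seed + 2000, effect_sd=float(rng.uniform(0.5, 10)))
        oracle = brute_force_scan(protein, mat)
        sites = scan(protein, mat)
        assert [(s.k, s.window) for s in sites] == [(k, w) for k, w, _ in oracle]
        for s, (_, _, score) in zip(sites, oracle):
            assert s.score == pytest.approx(score)

    def test_permuting_matrix_rows_never_changes_scores(self):
        protein = gen_random_protein(30, seed=5)
        mat = gen_impact_matrix(seed=5, effect_sd=3.0)
        shuffled = ImpactMatrix(mat.scores.sample(frac=1, random_state=0), dict(mat.meta))
        for s0, s1 in zip(scan(protein, mat), scan(protein, shuffled)):
            assert s0.score == pytest.approx(s1.score)


class TestC1Filter:
    def make_sites(self):
        return [
            SplitSite(k=69, window="GVQCFS", score=55.64, rank=1),
            SplitSite(k=47, window="KFICTT", score=52.32, rank=2),
            SplitSite(k=128, window="KGIDFK", score=5.93, rank=87),
        ]

    def test_cysteine_filter_keeps_candidates_drops_control(self):
        kept = apply_c1_filter(self.make_sites(), {"C"})
        assert [s.k for s in kept] == [69, 47]
        assert all(s.c1 == "C" for s in kept)

    def test_all_residues_is_identity(self):
        sites = self.make_sites()
        assert apply_c1_filter(sites, set(AMINO_ACIDS)) == sites

    def test_absent_residue_empties(self):
        assert apply_c1_filter(self.make_sites(), {"W"}) == []

    def test_filter_preserves_order_and_ranks(self, gfp):
        sites = scan(gfp, gen_impact_matrix(seed=2, effect_sd=3.0))
        kept = apply_c1_filter(sites, {"C", "S", "T", "M"})
        assert [s.rank for s in kept] == sorted(s.rank for s in kept)

    def test_empty_allowed_set_rejected(self):
        with pytest.raises(ScanError):
            apply_c1_filter(self.make_sites(), set())


class TestStructure:
    def test_all_helix_track(self, gfp):
        track = StructureTrack("H" * len(gfp))
        sites = scan(gfp, flat_matrix(), structure_track=track)
        assert all(s.structure == ALPHA_HELIX for s in sites)

    def test_majority_rule(self):
        site = SplitSite(k=3, window="AAAAAA", score=0.0)
        assert annotate_structure(site, StructureTrack("HHHEEC")) == ALPHA_HELIX
        assert annotate_structure(site, StructureTrack("EEEHHC")) == BETA_SHEET

    def test_tie_resolves_to_unstructured(self):
        site = SplitSite(k=3, window="AAAAAA", score=0.0)
        assert annotate_structure(site, StructureTrack("HHHEEE")) == UNSTRUCTURED

    def test_track_length_mismatch_rejected(self, gfp):
        with pytest.raises(ScanError):
            scan(gfp, flat_matrix(), structure_track=StructureTrack("HEC"))

    def test_from_file_single_line_and_dssp(self, tmp_path):
        p = tmp_path / "track.txt"
        p.write_text("HHECCH\n")
        assert StructureTrack.from_file(p).labels == "HHECCH"
        p.write_text("GHIEBTSC\n")
        assert StructureTrack.from_file(p, dssp=True).labels == "HHHEECCC"

    def test_from_file_tsv(self, tmp_path):
        p = tmp_path / "track.tsv"
        p.write_text("1\tH\n2\tE\n3\tC\n")
        assert StructureTrack.from_file(p).labels == "HEC"


class TestSelection:
    def test_top_candidates_and_default_negative_control(self, gfp):
        mat = gen_impact_matrix(seed=13, effect_sd=4.0, planted_window="GVQCFS")
        sites = scan(gfp, mat)
        candidates, control = select_candidates(sites, n=2, c1_residues={"C"})
        assert candidates[0].window == "GVQCFS"
        assert all(s.c1 == "C" for s in candidates)
        assert control is not None and control.c1 != "C"
        failing_ranks = [s.rank for s in sites if s.c1 != "C"]
        assert control.rank == max(failing_ranks)

    def test_negative_control_override(self, gfp):
        sites = scan(gfp, gen_impact_matrix(seed=13, effect_sd=4.0))
        kgidfk = next(s for s in sites if s.window == "KGIDFK")
        _, control = select_candidates(sites, n=2, negative_control_k=kgidfk.k)
        assert control.window == "KGIDFK" and not control.passes_c1

    def test_requesting_more_than_passing_warns(self):
        sites = [SplitSite(k=69, window="GVQCFS", score=1.0, rank=1),
                 SplitSite(k=10, window="AAADAA", score=0.5, rank=2)]
        with pytest.warns(UserWarning):
            candidates, _ = select_candidates(sites, n=5, c1_residues={"C"})
        assert [s.k for s in candidates] == [69]


class TestReport:
    def test_three_sites_three_rows(self, tmp_path):
        sites = [SplitSite(k=k, window="GVQCFS", score=float(k), rank=r)
                 for r, k in enumerate((10, 9, 8), start=1)]
        path = tmp_path / "report.tsv"
        df = report_table(sites, path)
        assert len(df) == 3
        assert len(path.read_text().strip().splitlines()) == 4

    def test_round_trip_scores_to_two_decimals(self, tmp_path, gfp):
        sites = scan(gfp, gen_impact_matrix(seed=21, effect_sd=3.0))[:20]
        path = tmp_path / "report.tsv"
        report_table(sites, path)
        back = pd.read_csv(path, sep="\t")
        for site, score in zip(sorted(sites, key=lambda s: s.rank), back["Site score"]):
            assert score == pytest.approx(round(site.score, 2), abs=0.005)

    def test_rank_one_gfp_row_layout(self, gfp):
        mat = gen_impact_matrix(seed=11, effect_sd=4.0, planted_window="GVQCFS")
        df = report_table(scan(gfp, mat))
        top = df.iloc[0]
        assert top["Rating position"] == 1
        assert top["Sequence"] == "GVQCFS"
        assert top["Site position"] == "69/70"
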