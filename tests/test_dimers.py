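"""Dimeric pattern construction, configuration scans, naming, divergence,
cooperativity and shape profiles."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from selexdimer._seq import revcomp
from selexdimer.dimers import (
    DimerAnnotation,
    DimerConfig,
    InfeasibleOverlapError,
    ShapeTable,
    align_profiles_with_gaps,
    build_dimer_pattern,
    configuration_scan,
    cooperativity_index,
    half_site_divergence,
    infer_dimer_config,
    name_dimer_motifs,
    shape_profile,
)
from selexdimer.motifs import Motif, iupac_to_ppm, reverse_complement
from selexdimer.selex import pattern_enrichment
from tests.conftest import random_reads

DATA = Path(__file__).parent / "data"


class TestBuildDimerPattern:
    def test_direct_repeat_concatenation(self):
        cfg = DimerConfig("DR", 0, 3)
        assert build_dimer_pattern("ACC", cfg) == "ACCACC"

    def test_inverted_repeat_with_spacer(self):
        assert build_dimer_pattern("ACG", DimerConfig("IR", 1, 3)) == "ACGNCGT"

    def test_everted_repeat(self):
        assert build_dimer_pattern("ACG", DimerConfig("ER", 2, 3)) == "CGTNNACG"

    def test_incompatible_overlap_reports_position(self):
        with pytest.raises(InfeasibleOverlapError) as exc:
            build_dimer_pattern("ACGT", DimerConfig("IR", -1, 4))
        assert exc.value.position == 3

    def test_compatible_overlap_intersects(self):
        # DR(-1) of ACGTA: trailing A overlaps leading A -> single A
        assert build_dimer_pattern("ACGTA", DimerConfig("DR", -1, 5)) == \
            "ACGTACGTA"

    @pytest.mark.parametrize("orientation", ["DR", "IR", "ER"])
    @pytest.mark.parametrize("spacing", [-1, 0, 1, 5, 16])
    def test_length_identity(self, orientation, spacing):
        half = "ACGTA"  # overlap-compatible for spacing -1 in all orientations?
        cfg = DimerConfig(orientation, spacing, 5)
        try:
            pattern = build_dimer_pattern(half, cfg)
        except InfeasibleOverlapError:
            return
        assert len(pattern) == 2 * 5 + spacing

    def test_heterotypic_halves(self):
        cfg = DimerConfig("ER", 1, 7)
        assert build_dimer_pattern("ACCTAAY", cfg, half2="CACGTGG") == \
            "RTTAGGT" + "N" + "CACGTGG"


class TestConfigurationScan:
    def test_signal_equals_background_is_flat(self):
        reads = random_reads(300, 60, 21)
        scan = configuration_scan("ACCTAAT", reads, reads,
                                  spacings=range(0, 4))
        vals = scan.folds.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert np.allclose(finite, 1.0, atol=0.5)

    def test_planted_configuration_is_argmax(self):
        bg = random_reads(1500, 60, 22)
        pattern = build_dimer_pattern("ACCTAAT", DimerConfig("DR", 3, 7))
        sig = [
            s[:10] + pattern.replace("NNN", s[30:33]) + s[10 + len(pattern):]
            for s in bg[:450]
        ] + bg[450:]
        scan = configuration_scan("ACCTAAT", sig, bg, spacings=range(-2, 9))
        assert scan.argmax() == ("DR", 3)

        # oracle: direct slicing count for the argmax cell (N spacer = any)
        def has_dr3(s):
            for seq in (s, revcomp(s)):
                for i in range(len(seq) - 17 + 1):
                    if seq[i:i + 7] == "ACCTAAT" and seq[i + 10:i + 17] == "ACCTAAT":
                        return True
            return False

        f = sum(map(has_dr3, sig)) / len(sig)
        assert scan.f_signal.loc["DR", 3] == pytest.approx(f)

    def test_grid_covers_three_orientations(self):
        reads = random_reads(100, 40, 23)
        scan = configuration_scan("ACGTA", reads, reads, spacings=[0, 1])
        assert list(scan.folds.index) == ["DR", "IR", "ER"]

    def test_infeasible_cells_are_missing_not_zero(self):
        reads = random_reads(100, 40, 24)
        scan = configuration_scan("ACGT", reads, reads, spacings=[-1])
        assert np.isnan(scan.folds.loc["IR", -1])
        assert not scan.to_frame().query("orientation=='IR' and spacing==-1").feasible.item()


class TestInferDimerConfig:
    @pytest.mark.parametrize("orientation", ["DR", "IR", "ER"])
    @pytest.mark.parametrize("spacing", range(-2, 17, 3))
    def test_round_trip(self, orientation, spacing):
        half = "ACCTAAT"
        cfg = DimerConfig(orientation, spacing, 7)
        try:
            pattern = build_dimer_pattern(half, cfg)
        except InfeasibleOverlapError:
            return
        ann = infer_dimer_config(iupac_to_ppm(pattern), iupac_to_ppm(half))
        assert (ann.orientation, ann.spacing) == (orientation, spacing)

    def test_negative_spacing_overlap(self):
        half = "AACGTA"
        cfg = DimerConfig("DR", -1, 6)
        pattern = build_dimer_pattern(half, cfg)
        ann = infer_dimer_config(iupac_to_ppm(pattern), iupac_to_ppm(half))
        assert (ann.orientation, ann.spacing) == ("DR", -1)

    def test_no_half_site_found(self):
        with pytest.raises(ValueError, match="no half-site"):
            infer_dimer_config(iupac_to_ppm("N" * 16), iupac_to_ppm("ACCTAAT"))


class TestNameDimerMotifs:
    def _motif(self, name, o, s, enrichment, halfsite=4):
        cfg = DimerConfig(o, s, halfsite)
        ann = DimerAnnotation(cfg, (0, halfsite), (halfsite + s, 2 * halfsite + s))
        pattern = build_dimer_pattern("ACGT"[:halfsite], cfg)
        from dataclasses import replace

        return replace(iupac_to_ppm(pattern, name=name), dimer=ann,
                       enrichment=enrichment)

    def test_single_motif_keeps_letter_a(self):
        named = name_dimer_motifs([self._motif("x", "ER", 1, 5.0)])
        assert named[0].name == "ER1a"

    def test_letters_by_descending_enrichment(self):
        a = self._motif("strong", "ER", 0, 5.0)
        b = self._motif("weak", "ER", 0, 3.0)
        named = name_dimer_motifs([b, a])
        by_name = {m.enrichment: m.name for m in named}
        assert by_name[5.0] == "ER0a" and by_name[3.0] == "ER0b"

    def test_negative_spacing_renders_with_minus(self):
        cfg = DimerConfig("DR", -1, 5)
        ann = DimerAnnotation(cfg, (0, 5), (4, 9))
        from dataclasses import replace

        m = replace(
            iupac_to_ppm(build_dimer_pattern("ACGTA", cfg), name="x"),
            dimer=ann, enrichment=2.0,
        )
        named = name_dimer_motifs([m])
        assert named[0].name == "DR-1a"


class TestHalfSiteDivergence:
    def _annotated(self, matrix, o, s, h):
        cfg = DimerConfig(o, s, h)
        ann = DimerAnnotation(cfg, (0, h), (h + s, 2 * h + s))
        return Motif(name="dimer", matrix=matrix, dimer=ann)

    def test_exact_copies_have_zero_divergence(self):
        mono = iupac_to_ppm("ACCTAAT")
        dimer = iupac_to_ppm(build_dimer_pattern("ACCTAAT", DimerConfig("ER", 2, 7)))
        d = half_site_divergence(self._annotated(dimer.matrix, "ER", 2, 7), mono)
        assert d["left_d"] == pytest.approx(0, abs=1e-9)
        assert d["right_d"] == pytest.approx(0, abs=1e-9)

    def test_unrelated_right_half_is_flagged(self, rng):
        mono = iupac_to_ppm("ACCTAAT")
        left = reverse_complement(mono).matrix  # ER left element
        right = rng.dirichlet(np.ones(4) * 0.2, size=7)
        spacer = np.full((1, 4), 0.25)
        dimer = self._annotated(np.vstack([left, spacer, right]), "ER", 1, 7)
        d = half_site_divergence(dimer, mono)
        assert d["left_d"] < 0.1 and not d["left_divergent"]
        assert d["right_d"] > 0.4 and d["right_divergent"]

    def test_reverse_complement_swaps_sides(self):
        mono = iupac_to_ppm("ACCTAAT")
        rng = np.random.default_rng(0)
        right = rng.dirichlet(np.ones(4) * 0.2, size=7)
        mat = np.vstack([reverse_complement(mono).matrix,
                         np.full((1, 4), 0.25), right])
        fwd = self._annotated(mat, "ER", 1, 7)
        rc_mat = mat[::-1, [3, 2, 1, 0]]
        rc = self._annotated(rc_mat, "ER", 1, 7)
        d1 = half_site_divergence(fwd, mono)
        d2 = half_site_divergence(rc, mono)
        assert d1["left_d"] == pytest.approx(d2["right_d"], abs=1e-9)
        assert d1["right_d"] == pytest.approx(d2["left_d"], abs=1e-9)


class TestCooperativity:
    def test_arithmetic(self):
        assert cooperativity_index(8.0, 2.0, 2.0) == pytest.approx(2.0)

    def test_independent_half_planting_near_one(self):
        """Halves planted independently show no configuration synergy."""
        g = np.random.default_rng(31)
        left, right = "TTAGGTC", "GACCTAA"
        pattern = left + "N" + right

        def make(n, p_l, p_r):
            out = []
            for s in random_reads(n, 60, int(g.integers(1 << 30))):
                if g.random() < p_l:
                    s = s[:10] + left + s[17:]
                if g.random() < p_r:
                    s = s[:18] + right + s[25:]
                out.append(s)
            return out

        bg = make(4000, 0.02, 0.02)
        sig = make(4000, 0.4, 0.4)  # independent: no joint preference
        fold_d = pattern_enrichment(pattern, sig, bg)["fold"]
        fold_l = pattern_enrichment(left, sig, bg)["fold"]
        fold_r = pattern_enrichment(right, sig, bg)["fold"]
        idx = cooperativity_index(fold_d, fold_l, fold_r)
        assert 0.2 < idx < 3.0

    def test_cooperative_simulation_exceeds_one(self):
        """A dimeric mode with omega > 1 joint preference scores index > 1."""
        from selexdimer.synthetic import BindingMode, BindingModel, simulate_selex

        left, right = "TAGGC", "GCCTA"
        pattern = left + "N" + right
        dimer = iupac_to_ppm(pattern, name="dimer")
        mono_l = iupac_to_ppm(left, name="left")
        mono_r = iupac_to_ppm(right, name="right")
        # weak monomeric binding, strongly cooperative dimeric binding
        cs = 3.1e-4
        lam_m = float(np.log(2)) * 0.6
        lam_d = float(np.log(3200 / 5.0)) / dimer.max_score()
        modes = [
            BindingMode(mono_l, activity=lam_m),
            BindingMode(mono_r, activity=lam_m),
            BindingMode(dimer, activity=lam_d, cooperativity=5.0),
        ]
        model = BindingModel(modes=modes, capture_scale=cs)
        lib, _ = simulate_selex(model, n_ligands=20_000, length=60, cycles=2,
                                seed=33)
        sig, bg = lib.reads(2), lib.reads(0)
        fold_d = pattern_enrichment(pattern, sig, bg)["fold"]
        fold_l = pattern_enrichment(left, sig, bg)["fold"]
        fold_r = pattern_enrichment(right, sig, bg)["fold"]
        assert cooperativity_index(fold_d, fold_l, fold_r) > 1.0


class TestShapeProfile:
    def test_constant_table_gives_flat_profile(self):
        table = ShapeTable({}, default=5.0)
        reads = random_reads(5, 30, 41)
        hits = [(i, 10, "+") for i in range(5)]
        prof = shape_profile(reads, hits, 6, table, "MGW")
        assert np.allclose(prof["mean"], 5.0)

    def test_hand_computed_toy_lookup(self):
        table = ShapeTable({"ACGTA": {"MGW": 4.0}, "CGTAC": {"MGW": 6.0},
                            "GTACG": {"MGW": 5.0}})
        reads = ["TTACGTACGTT"]
        # hit of length 3 at position 4 ("GTA"), pentamer contexts at
        # positions 4,5,6 are CGTAC? -> centred pentamers
        prof = shape_profile(reads, [(0, 4, "+")], 3, table, "MGW")
        # position 0 centre=4: reads[0][2:7] = ACGTA -> 4.0
        assert prof.loc[prof.position == 0, "mean"].item() == pytest.approx(4.0)
        assert prof.loc[prof.position == 1, "mean"].item() == pytest.approx(6.0)
        assert prof.loc[prof.position == 2, "mean"].item() == pytest.approx(5.0)

    def test_minus_strand_hits_flipped(self):
        table = ShapeTable({"ACGTA": {"MGW": 4.0}})
        reads = ["TT" + revcomp("ACGTAC") + "TTT"]
        # '-' strand hit: coordinates are on the + axis of the read
        start = reads[0].index(revcomp("ACGTAC"))
        prof = shape_profile(reads, [(0, start, "-")], 6, table, "MGW")
        assert prof.loc[prof.position == 2, "mean"].item() == pytest.approx(4.0)

    def test_no_hits_rejected(self):
        with pytest.raises(ValueError):
            shape_profile(["ACGT"], [], 2, ShapeTable({}), "MGW")

    def test_table_from_tsv_fixture(self):
        table = ShapeTable.from_tsv(DATA / "toy_shape.tsv")
        assert table.lookup("AACGT", "MGW") == 4.0
        assert np.isnan(table.lookup("AAAAA", "MGW"))

    def test_gap_alignment_matches_half_site_columns(self):
        prof1 = pd.DataFrame({"position": range(10), "mean": range(10)})
        prof2 = pd.DataFrame({"position": range(12), "mean": range(12)})
        a1 = align_profiles_with_gaps(prof1, halfsite_len=4, spacing=2,
                                      max_spacing=4)
        a2 = align_profiles_with_gaps(prof2, halfsite_len=4, spacing=4,
                                      max_spacing=4)
        # left halves align column-to-column, right halves too
        assert list(a1.aligned_position[:4]) == list(a2.aligned_position[:4])
        assert list(a1.aligned_position[-4:]) == list(a2.aligned_position[-4:])
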