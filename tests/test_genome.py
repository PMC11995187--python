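"""Fragment scoring, PR curves, shuffles, peak fractions, TSS/conservation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from selexdimer.genome import (
    GenomicAnnotation,
    ablation_auprc,
    compare_pr,
    conservation_profile,
    fragment_scores,
    peak_site_fraction,
    pr_curve,
    shuffle_sequences,
    tss_density_profile,
)
from selexdimer.motifs import Motif, iupac_to_ppm
from tests.conftest import random_reads


def toy_genome(seed=50, n=4000):
    return {"chr1": random_reads(1, n, seed)[0]}


class TestFragmentScores:
    def test_all_n_fragment_scores_zero(self):
        genome = {"chr1": "N" * 200 + random_reads(1, 200, 51)[0]}
        df = fragment_scores(genome, [iupac_to_ppm("ACGTACG")])
        assert df.iloc[0].score == 0.0

    def test_consensus_fragment_beats_random_fragments(self):
        seq = random_reads(1, 2000, 52)[0]
        seq = seq[:450] + "ACGTACGTAC" + seq[460:]
        df = fragment_scores({"chr1": seq}, [iupac_to_ppm("ACGTACGTAC")])
        scores = df.score.to_numpy()
        assert np.argmax(scores) == 2  # fragment [400, 600)
        assert scores[2] > max(np.delete(scores, 2))

    def test_singleton_set_equals_single_motif(self):
        genome = toy_genome()
        m = iupac_to_ppm("ACCTAAT")
        a = fragment_scores(genome, [m]).score
        b = fragment_scores(genome, [m, m]).score
        np.testing.assert_allclose(a, b)

    def test_empty_motif_set_rejected(self):
        with pytest.raises(ValueError):
            fragment_scores(toy_genome(), [])


def brute_force_average_precision(scores, labels):
    """Independent oracle: enumerate thresholds, accumulate AP step-wise."""
    order = sorted(set(scores), reverse=True)
    P = sum(labels)
    ap, prev_recall = 0.0, 0.0
    for t in order:
        pred = [s >= t for s in scores]
        tp = sum(p and l for p, l in zip(pred, labels))
        precision = tp / sum(pred)
        recall = tp / P
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestPrCurve:
    def test_perfect_separation(self):
        r = pr_curve(np.array([3.0, 2.0, 1.0, 0.5]), np.array([1, 1, 0, 0], bool))
        assert r.auprc == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        r = pr_curve(np.full(10, 2.0), np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], bool))
        assert r.auprc == pytest.approx(0.3)

    def test_worked_example(self):
        r = pr_curve(np.array([0.9, 0.8, 0.7, 0.6]), np.array([1, 0, 1, 0], bool))
        assert r.auprc == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_matches_enumeration_oracle_on_all_small_inputs(self):
        scores = [0.9, 0.8, 0.8, 0.6, 0.5, 0.4]
        for labels in itertools.product([0, 1], repeat=6):
            if 0 < sum(labels) < 6:
                got = pr_curve(np.array(scores), np.array(labels, bool)).auprc
                assert got == pytest.approx(
                    brute_force_average_precision(scores, list(labels)))

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(10):
            scores = rng.normal(size=30)
            labels = rng.random(30) < 0.3
            if labels.all() or not labels.any():
                continue
            assert pr_curve(scores, labels).auprc == pytest.approx(
                average_precision_score(labels, scores))

    def test_recall_monotone(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        r = pr_curve(scores, labels)
        assert (np.diff(r.recall) >= 0).all()

    def test_random_scores_auprc_near_prevalence(self):
        """Over seeded repeats the mean AUPRC approaches the prevalence."""
        vals = []
        for i in range(100):
            g = np.random.default_rng(1000 + i)
            scores = g.normal(size=200)
            labels = np.zeros(200, bool)
            labels[:40] = True
            vals.append(pr_curve(scores, labels).auprc)
        assert abs(np.mean(vals) - 0.2) < 3 * np.std(vals)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pr_curve(np.array([1.0, 2.0]), np.array([1, 1], bool))


class TestShuffles:
    def test_mononucleotide_preserves_composition(self):
        seqs = random_reads(5, 80, 53)
        out = shuffle_sequences(seqs, seed=1)
        for a, b in zip(seqs, out):
            assert sorted(a) == sorted(b)
            assert a != b

    def test_dinucleotide_preserves_dinucleotide_counts(self):
        from collections import Counter

        seqs = random_reads(5, 120, 54)
        out = shuffle_sequences(seqs, mode="dinucleotide", seed=2)
        for a, b in zip(seqs, out):
            assert Counter(zip(a, a[1:])) == Counter(zip(b, b[1:]))

    def test_seeded_determinism(self):
        seqs = random_reads(3, 60, 55)
        assert shuffle_sequences(seqs, seed=9) == shuffle_sequences(seqs, seed=9)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            shuffle_sequences(["ACGT"], mode="trinucleotide")


def planted_peak_annotation(seed=56, n_peaks=200, planted=80):
    """Peaks in a random genome; the first `planted` carry ACGTACGTAC."""
    g = np.random.default_rng(seed)
    genome = random_reads(1, 120_000, seed)[0]
    starts = np.arange(n_peaks) * 600 + 50
    rows = []
    for i, s in enumerate(starts):
        if i < planted:
            off = int(g.integers(20, 160))
            genome = genome[:s + off] + "ACGTACGTAC" + genome[s + off + 10:]
        rows.append({"chrom": "chr1", "start": int(s), "end": int(s) + 200})
    peaks = pd.DataFrame(rows)
    peaks["name"] = [f"p{i}" for i in range(n_peaks)]
    # planted peaks rank on top
    peaks["score"] = np.arange(n_peaks, 0, -1)
    return GenomicAnnotation(genome={"chr1": genome}, peaks=peaks)


class TestPeakSiteFraction:
    def test_motif_longer_than_peaks_gives_zero(self):
        ann = planted_peak_annotation()
        long_motif = iupac_to_ppm("ACGT" * 60)
        assert peak_site_fraction(ann, long_motif, top_n=10) == 0.0

    def test_planted_fraction_matches_brute_force(self):
        ann = planted_peak_annotation(n_peaks=200, planted=40)
        m = iupac_to_ppm("ACGTACGTAC")
        frac = peak_site_fraction(ann, m, p_value=1e-5, top_n=200)
        # brute-force matcher over the same top peaks
        from selexdimer._seq import revcomp

        seqs = ann.peak_sequences(ann.top_peaks(200))
        oracle = sum("ACGTACGTAC" in s or revcomp("ACGTACGTAC") in s
                     for s in seqs) / 200
        assert frac == pytest.approx(oracle, abs=0.02)
        assert frac == pytest.approx(0.2, abs=0.03)

    def test_shuffled_control_is_much_smaller(self):
        ann = planted_peak_annotation()
        m = iupac_to_ppm("ACGTACGTAC")
        intact = peak_site_fraction(ann, m, top_n=200)
        shuffled = peak_site_fraction(ann, m, top_n=200, control="shuffled")
        assert intact >= 0.35
        assert shuffled < 0.5 * intact

    def test_mutated_motif_control_strictly_smaller(self):
        from selexdimer.motifs import mutate_consensus

        ann = planted_peak_annotation()
        m = iupac_to_ppm("ACGTACGTAC")
        mut = mutate_consensus(m, [(7, "T"), (8, "T"), (9, "T")])
        intact = peak_site_fraction(ann, m, top_n=200)
        mutated = peak_site_fraction(ann, m, top_n=200,
                                     control="mutated_motif", control_motif=mut)
        assert mutated < intact

    def test_no_peaks_rejected(self):
        ann = GenomicAnnotation(genome={"chr1": "ACGT" * 100})
        with pytest.raises(ValueError):
            peak_site_fraction(ann, iupac_to_ppm("ACGT"), top_n=5)


def tss_annotation(seed=57, n_tss=25, plant=True):
    genome = random_reads(1, 120_000, seed)[0]
    g = np.random.default_rng(seed)
    rows = []
    for i in range(n_tss):
        pos = 2500 + i * 4500  # genes far apart: windows never overlap
        strand = "+" if i % 2 == 0 else "-"
        if plant:
            site = "ACGTACGTAC"
            if strand == "+":
                start = pos - 50 - 10
            else:
                start = pos + 50
                site = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[c]
                               for c in reversed(site))
            genome = genome[:start] + site + genome[start + 10:]
        rows.append({"chrom": "chr1", "pos": pos, "strand": strand,
                     "gene": f"g{i}"})
    return GenomicAnnotation(genome={"chr1": genome}, tss=pd.DataFrame(rows))


class TestTssDensity:
    def test_reversal_symmetric_motif_nets_zero(self):
        ann = tss_annotation(plant=False)
        # palindromic-in-columns motif: reversal leaves the matrix unchanged
        m = iupac_to_ppm("ACGTTGCA")
        sym = Motif(name="sym", matrix=(m.matrix + m.matrix[::-1]) / 2)
        prof = tss_density_profile(ann, sym, p_value=1e-3, smooth=1)
        np.testing.assert_allclose(prof.net, 0, atol=1e-12)

    def test_planted_offset_peak(self):
        ann = tss_annotation()
        m = iupac_to_ppm("ACGTACGTAC")
        prof = tss_density_profile(ann, m, p_value=1e-5, smooth=50)
        peak_offset = prof.loc[prof.net_smoothed.idxmax(), "offset"]
        assert -110 <= peak_offset <= 0

    def test_profile_integrates_to_net_hit_count(self):
        ann = tss_annotation()
        m = iupac_to_ppm("ACGTACGTAC")
        raw = tss_density_profile(ann, m, p_value=1e-5, smooth=1)
        total_net = raw.net.sum()
        sm = tss_density_profile(ann, m, p_value=1e-5, smooth=41)
        # smoothing conserves mass away from the window edges
        assert sm.net_smoothed.sum() == pytest.approx(total_net, rel=0.05)

    def test_no_tss_rejected(self):
        ann = GenomicAnnotation(genome={"chr1": "ACGT" * 1000})
        with pytest.raises(ValueError):
            tss_density_profile(ann, iupac_to_ppm("ACGTAC"))


class TestConservationProfile:
    def test_constant_track_gives_flat_profile(self):
        ann = tss_annotation()
        ann.conservation = {"chr1": np.full(120_000, 0.37)}
        prof = conservation_profile(ann, iupac_to_ppm("ACGTACGTAC"),
                                    p_value=1e-5)
        covered = prof[prof.n > 0]
        np.testing.assert_allclose(covered["mean"], 0.37)

    def test_elevation_width_equals_motif_width(self):
        ann = tss_annotation()
        track = np.full(120_000, 0.1)
        m = iupac_to_ppm("ACGTACGTAC")
        # elevate exactly over every planted footprint
        from selexdimer.genome import promoter_hits

        for chrom, start, end, strand in promoter_hits(ann, m, p_value=1e-5):
            track[start:end] += 0.8
        ann.conservation = {"chr1": track}
        prof = conservation_profile(ann, m, p_value=1e-5)
        elevated = prof[(prof["mean"] > 0.5) & (prof.n > 0)]
        assert len(elevated) == 10
        assert elevated.position.min() == 0 and elevated.position.max() == 9

    def test_zero_hits_rejected(self):
        ann = tss_annotation(plant=False)
        ann.conservation = {"chr1": np.full(120_000, 0.1)}
        with pytest.raises(ValueError):
            conservation_profile(ann, iupac_to_ppm("ACGTACGTACGTACG"),
                                 p_value=1e-9)


class TestAblation:
    def test_duplicate_motif_leaves_auprc_unchanged(self):
        ann = planted_peak_annotation()
        m = iupac_to_ppm("ACGTACGTAC", name="m")
        res = ablation_auprc(ann, {"one": [m], "two": [m, m.with_name("m2")]},
                             top_n=100)
        assert res["auprc"]["one"] == pytest.approx(res["auprc"]["two"])

    def test_informative_motif_beats_unrelated(self):
        ann = planted_peak_annotation()
        good = iupac_to_ppm("ACGTACGTAC", name="good")
        bad = iupac_to_ppm("TTGACCGGAA", name="bad")
        res = ablation_auprc(ann, {"bad": [bad], "good": [good]}, top_n=100,
                             baseline="bad")
        assert res["auprc"]["good"] > res["auprc"]["bad"]
        assert res["wilcoxon"]["good"]["pvalue"] < 0.05

    def test_empty_set_rejected(self):
        ann = planted_peak_annotation()
        with pytest.raises(ValueError):
            ablation_auprc(ann, {"none": []}, top_n=10)
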