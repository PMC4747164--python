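"""PSSM scoring, exact match p-values, scanning, enrichment and spacing."""

import dataclasses
import itertools
import math

import numpy as np
import pytest

from foxochip.genomic_io import GenomeSequence, Peak
from foxochip.motif_scan import (
    GRID_BITS,
    BackgroundModel,
    Pssm,
    enrichment_curve,
    intermotif_distances,
    match_pvalue,
    sample_random_promoters,
    scan_peaks,
    scan_sequences,
    score_threshold,
    score_window,
    train_background,
)
from foxochip.synthetic_data import _revcomp, simulate_genome


@pytest.fixture(scope="module")
def toy_pssm():
    """Length-4 matrix with a sharp consensus GTAA."""
    counts = np.zeros((4, 4))
    for i, b in enumerate("GTAA"):
        counts[i, "ACGT".index(b)] = 9.0
    return Pssm.from_counts("toy", counts)


@pytest.fixture(scope="module")
def uniform_bg():
    return BackgroundModel.uniform(order=0)


class TestBackground:
    def test_order0_frequencies_match_composition(self):
        seq = "ACGT" * 300 + "A" * 400
        bg = train_background(seq, order=0)
        counts = {b: seq.count(b) for b in "ACGT"}
        expected = np.array([counts[b] + 1 for b in "ACGT"], dtype=float)
        expected /= expected.sum()
        assert np.allclose(bg.conditionals[0][0], expected)

    def test_degenerate_composition_approaches_one(self):
        bg = train_background("A" * 5000, order=0)
        assert bg.conditionals[0][0, 0] > 0.99

    def test_conditionals_sum_to_one_per_context(self, default_sim):
        genome, _, _ = default_sim
        bg = train_background(list(genome.sequences.values()), order=2)
        for table in bg.conditionals:
            assert np.allclose(table.sum(axis=1), 1.0)

    def test_too_small_training_set_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            train_background("ACGT" * 10, order=2)


class TestScoreWindow:
    def test_consensus_maximizes_score(self, toy_pssm, uniform_bg):
        s_cons = score_window("GTAA", toy_pssm, uniform_bg)
        for word in map("".join, itertools.product("ACGT", repeat=4)):
            assert score_window(word, toy_pssm, uniform_bg) <= s_cons

    def test_uniform_pssm_uniform_background_scores_zero(self, uniform_bg):
        flat = Pssm("flat", np.full((4, 4), 0.25))
        assert score_window("ACGT", flat, uniform_bg) == 0.0

    def test_n_in_window_is_undefined(self, toy_pssm, uniform_bg):
        with pytest.raises(ValueError, match="N"):
            score_window("GTNA", toy_pssm, uniform_bg)

    def test_reverse_complement_symmetry(self, toy_pssm, uniform_bg, rng):
        for _ in range(20):
            w = "".join(rng.choice(list("ACGT"), 4))
            assert score_window(w, toy_pssm, uniform_bg) == pytest.approx(
                score_window(_revcomp(_revcomp(w)), toy_pssm, uniform_bg))

    def test_best_window_matches_exhaustive_enumeration(self, toy_pssm, uniform_bg, rng):
        seq = "".join(rng.choice(list("ACGT"), 20))
        scans = scan_sequences({"s": seq}, toy_pssm, uniform_bg, p_threshold=1.0)
        best = scans[0]
        brute = []
        for start in range(len(seq) - 3):
            w = seq[start : start + 4]
            brute.append((score_window(w, toy_pssm, uniform_bg), start, "+"))
            brute.append((score_window(_revcomp(w), toy_pssm, uniform_bg), start, "-"))
        brute_best = max(brute, key=lambda t: (t[0], -t[1], t[2] == "+"))
        assert best.best_score == pytest.approx(brute_best[0])


class TestMatchPvalue:
    def test_floor_and_ceiling(self, toy_pssm, uniform_bg):
        assert match_pvalue(-1e6, toy_pssm, uniform_bg) == 1.0
        assert match_pvalue(1e6, toy_pssm, uniform_bg) == 0.0

    def test_dp_matches_256_case_enumeration(self, toy_pssm):
        bg_probs = np.array([0.3, 0.2, 0.2, 0.3])
        bg = BackgroundModel([bg_probs[None, :]])
        words = ["".join(w) for w in itertools.product("ACGT", repeat=4)]
        scores = {w: score_window(w, toy_pssm, bg) for w in words}
        probs = {w: np.prod([bg_probs["ACGT".index(b)] for b in w]) for w in words}
        for w in words:
            enum_p = sum(probs[v] for v in words
                         if round(scores[v] / GRID_BITS) >= round(scores[w] / GRID_BITS))
            assert match_pvalue(scores[w], toy_pssm, bg) == pytest.approx(
                enum_p, abs=1e-9)

    def test_monotone_decreasing_in_score(self, toy_pssm, uniform_bg):
        grid = np.linspace(-10, 10, 101)
        pvals = [match_pvalue(s, toy_pssm, uniform_bg) for s in grid]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_order2_dp_matches_enumeration(self, toy_pssm):
        """The context-aware DP is exact for Markov backgrounds too."""
        rng = np.random.default_rng(3)
        tables = []
        for k in range(3):
            t = rng.random((4**k, 4)) + 0.5
            tables.append(t / t.sum(axis=1, keepdims=True))
        bg = BackgroundModel(tables)
        words = ["".join(w) for w in itertools.product("ACGT", repeat=4)]

        def word_prob(w):
            idx = ["ACGT".index(b) for b in w]
            p = tables[0][0, idx[0]] * tables[1][idx[0], idx[1]]
            p *= tables[2][idx[0] * 4 + idx[1], idx[2]]
            p *= tables[2][idx[1] * 4 + idx[2], idx[3]]
            return p

        scores = {w: score_window(w, toy_pssm, bg) for w in words}
        for w in words[::17]:
            enum_p = sum(word_prob(v) for v in words
                         if round(scores[v] / GRID_BITS) >= round(scores[w] / GRID_BITS))
            assert match_pvalue(scores[w], toy_pssm, bg) == pytest.approx(
                enum_p, abs=1e-9)


class TestScanning:
    def test_planted_consensus_recovered_at_position(self, uniform_bg, rng):
        pssm = Pssm.from_consensus("dbe", "SYGGTAAACAASR")
        word = "CCGGTAAACAAGA"  # one realization of the degenerate consensus
        background = "".join(rng.choice(list("ACGT"), 501))
        offset = 250 - 30
        seq = background[:offset] + word + background[offset + len(word) :]
        scans = scan_sequences({"s": seq}, pssm, uniform_bg, p_threshold=1e-5)
        assert scans[0].has_match
        assert abs(scans[0].matches[0].center - (offset + 6)) <= 1

    def test_false_positive_rate_bounded_on_random_sequence(self, rng):
        pssm = Pssm.from_consensus("dbe", "SYGGTAAACAASR")
        bg = BackgroundModel.uniform(order=0)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 501)) for i in range(100)}
        scans = scan_sequences(seqs, pssm, bg, p_threshold=1e-5)
        n_matches = sum(1 for s in scans if s.has_match)
        # ~10^5 windows at p<=1e-5 -> expect about 1
        assert n_matches <= 5

    def test_best_only_false_returns_superset(self, toy_pssm, uniform_bg, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        best = scan_sequences({"s": seq}, toy_pssm, uniform_bg,
                              p_threshold=0.05, best_only=True)[0]
        full = scan_sequences({"s": seq}, toy_pssm, uniform_bg,
                              p_threshold=0.05, best_only=False)[0]
        best_set = {(m.center, m.strand) for m in best.matches}
        full_set = {(m.center, m.strand) for m in full.matches}
        assert best_set <= full_set

    def test_peak_windows_use_genome_coordinates(self, uniform_bg, rng):
        pssm = Pssm.from_consensus("dbe", "SYGGTAAACAASR")
        word = "GTGGTAAACAACG"
        chrom = "".join(rng.choice(list("ACGT"), 2000))
        pos = 1000 - 37
        chrom = chrom[:pos] + word + chrom[pos + len(word) :]
        genome = GenomeSequence({"chr1": chrom})
        peaks = [Peak("p", "chr1", 900, 1100, 1000, 5.0)]
        scans = scan_peaks(peaks, genome, pssm, uniform_bg,
                           half_width=250, p_threshold=1e-5)
        assert scans[0].has_match
        assert abs(scans[0].matches[0].center - (pos + 6)) <= 1


class TestPlantedRecovery:
    def test_planted_motifs_recovered_in_default_simulation(self, default_config,
                                                            default_sim):
        genome, genes, truth = default_sim
        bg = train_background(list(genome.sequences.values()), order=2)
        pssm = Pssm.from_consensus("dbe", default_config.motif_consensus)
        peaks = [
            Peak(f"pk_{g}", truth.genes[g].chrom,
                 truth.genes[g].summit - 200, truth.genes[g].summit + 201,
                 truth.genes[g].summit, default_config.chip_enrichment)
            for g in truth.bound_genes
        ]
        scans = scan_peaks(peaks, genome, pssm, bg)
        planted = {f"pk_{g}": dict(
            (name, center) for name, center, _ in truth.genes[g].motifs
        ).get("primary") for g in truth.bound_genes}
        hits = sum(
            1 for s in scans
            if s.has_match and planted[s.sequence_id] is not None
            and abs(s.matches[0].center - planted[s.sequence_id]) <= 1
        )
        assert hits / len(scans) >= 0.9


class TestEnrichment:
    def test_null_ratio_near_one(self, toy_pssm, uniform_bg, rng):
        seqs_a = {f"a{i}": "".join(rng.choice(list("ACGT"), 200)) for i in range(200)}
        seqs_b = {f"b{i}": "".join(rng.choice(list("ACGT"), 200)) for i in range(200)}
        sa = scan_sequences(seqs_a, toy_pssm, uniform_bg, p_threshold=0.02)
        sb = scan_sequences(seqs_b, toy_pssm, uniform_bg, p_threshold=0.02)
        enr = enrichment_curve(sa, sb)
        assert 0.5 <= enr.r <= 2.0

    def test_frequency_profiles_monotone_in_threshold(self, toy_pssm, uniform_bg, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 200)) for i in range(50)}
        scans = scan_sequences(seqs, toy_pssm, uniform_bg)
        enr = enrichment_curve(scans, scans)
        assert np.all(np.diff(enr.freq_peaks) <= 1e-12)
        assert np.all(np.diff(enr.freq_random) <= 1e-12)

    def test_height_correlation_tracks_motif_strength(self, uniform_bg, rng):
        """Peaks whose planted word is closer to consensus score higher; with
        heights set by planted strength the correlation must be strong."""
        pssm = Pssm.from_consensus("dbe", "GTAAACAAGGTCA")
        consensus = "GTAAACAAGGTCA"
        scans_seqs, heights = {}, {}
        for i in range(60):
            n_mut = i % 4
            word = list(consensus)
            for j in range(n_mut):
                pos = 2 * j
                word[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[word[pos]]
            seq = "".join(rng.choice(list("ACGT"), 301))
            seq = seq[:120] + "".join(word) + seq[120 + len(word) :]
            scans_seqs[f"s{i}"] = seq
            heights[f"s{i}"] = 20.0 - 4.0 * n_mut + rng.normal(0, 0.5)
        scans = scan_sequences(scans_seqs, pssm, uniform_bg, p_threshold=1.0)
        enr = enrichment_curve(scans, scans, heights)
        assert enr.pearson_r_vs_height is not None
        assert enr.pearson_r_vs_height > 0.5


class TestIntermotifDistances:
    @staticmethod
    def _match(seq_id, center, strand="+"):
        from foxochip.motif_scan import MotifMatch

        return MotifMatch(seq_id, center, strand, 10.0, 1e-6)

    def test_coincident_centres_give_zero(self):
        ref = [self._match("s1", 100)]
        other = [self._match("s1", 100)]
        d, _, _ = intermotif_distances(ref, other, {"s1": "+"})
        assert list(d) == [0]

    def test_minus_strand_promoter_sign_corrected(self):
        ref = [self._match("s1", 100), self._match("s2", 300)]
        other = [self._match("s1", 100 - 35), self._match("s2", 300 - 35)]
        d, _, mode = intermotif_distances(ref, other, {"s1": "-", "s2": "-"})
        assert list(d) == [35, 35]
        assert mode == pytest.approx(35, abs=5)

    def test_histogram_mode_recovers_planted_offset(self, default_config, default_sim):
        genome, genes, truth = default_sim
        bg = train_background(list(genome.sequences.values()), order=2)
        pssm = Pssm.from_consensus("dbe", default_config.motif_consensus)
        co = Pssm.from_consensus("co", default_config.comotif_consensus)
        seqs, strands = {}, {}
        for g in truth.bound_genes:
            t = truth.genes[g]
            seqs[g] = genome.fetch(t.chrom, t.summit - 250, t.summit + 251)
            strands[g] = t.strand
        origins = {g: truth.genes[g].summit - 250 for g in seqs}
        ref = [m for s in scan_sequences(seqs, pssm, bg, origins=origins)
               for m in s.matches]
        other = [m for s in scan_sequences(seqs, co, bg, origins=origins)
                 for m in s.matches]
        d, hist, mode = intermotif_distances(ref, other, strands)
        assert len(d) >= 20
        assert abs(mode - default_config.comotif_offset) <= 10

    def test_summit_reference_mode(self, default_sim, default_config):
        genome, _, truth = default_sim
        bg = train_background(list(genome.sequences.values()), order=2)
        pssm = Pssm.from_consensus("dbe", default_config.motif_consensus)
        seqs, strands, summits = {}, {}, {}
        for g in truth.bound_genes:
            t = truth.genes[g]
            seqs[g] = genome.fetch(t.chrom, t.summit - 250, t.summit + 251)
            strands[g] = t.strand
            summits[g] = t.summit
        origins = {g: summits[g] - 250 for g in seqs}
        matches = [m for s in scan_sequences(seqs, pssm, bg, origins=origins)
                   for m in s.matches]
        _, _, mode = intermotif_distances(summits, matches, strands)
        assert abs(mode) <= 10  # motifs planted centred on the summit


def test_random_promoters_have_requested_shape(default_sim, rng):
    genome, genes, truth = default_sim
    seqs = sample_random_promoters(genes, genome, 50, 501, rng,
                                   exclude_gene_ids=set(truth.bound_genes))
    assert len(seqs) == 50
    assert all(len(s) == 501 for s in seqs.values())


def test_score_threshold_matches_pvalue_definition(toy_pssm, uniform_bg):
    thr = score_threshold(0.05, toy_pssm, uniform_bg)
    assert match_pvalue(thr, toy_pssm, uniform_bg) <= 0.05
    assert match_pvalue(thr - GRID_BITS, toy_pssm, uniform_bg) > 0.05
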