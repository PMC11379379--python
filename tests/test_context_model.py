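"""5-mer counting, P0 estimation and the flanking chi-square test."""

import numpy as np
import pytest

import emsmap as em
from emsmap.context_model import code_to_pattern, pattern_to_code


def brute_force_c0(genome):
    """Independent window scan: every N-free 5-window counted by string ops."""
    counts = {}
    for seq in genome.chromosomes.values():
        for i in range(len(seq) - 4):
            w = seq[i : i + 5]
            if "N" not in w:
                counts[w] = counts.get(w, 0) + 1
    return counts


def brute_force_c_prime(genome, dataset):
    counts = {}
    skipped = 0
    for rec in dataset:
        if rec.variant_class != "SNV":
            skipped += 1
            continue
        seq = genome[rec.chrom]
        if rec.pos < 2 or rec.pos > len(seq) - 3:
            skipped += 1
            continue
        w = seq[rec.pos - 2 : rec.pos + 3]
        if "N" in w:
            skipped += 1
            continue
        counts[w] = counts.get(w, 0) + 1
    return counts, skipped


class TestGenomePatterns:
    def test_enumeration(self):
        g = em.ReferenceGenome({"chrI": "AACGTT"})
        assert em.count_genome_patterns(g) == {"AACGT": 1, "ACGTT": 1}

    def test_overlapping_windows(self):
        g = em.ReferenceGenome({"chrI": "AAAAAA"})
        assert em.count_genome_patterns(g) == {"AAAAA": 2}

    def test_n_window_masked(self):
        g = em.ReferenceGenome({"chrI": "AANGTTT"})
        # every 5-window containing the N is dropped; only "GTTT" tail too short
        assert em.count_genome_patterns(g) == {}

    def test_short_chromosome(self):
        g = em.ReferenceGenome({"chrI": "ACGT"})
        assert em.count_genome_patterns(g) == {}


class TestComputeP0:
    def test_single_event_hand_value(self):
        # "AAAAA" occurs twice in AAAAAA; one event at the centre of one window
        g = em.ReferenceGenome({"chrI": "AAAAAA"})
        ds = em.MutationDataset.from_records(
            [em.MutationRecord("s1", "chrI", 2, "A", "T")]
        )
        table = em.compute_p0(g, ds)
        assert table.p0_of("AAAAA") == 0.5

    def test_no_mutations_gives_zero(self, toy_genome):
        import pandas as pd

        empty = em.MutationDataset(pd.DataFrame(columns=["strain"]), n_strains=1)
        table = em.compute_p0(toy_genome, empty)
        p0 = table.p0
        assert np.nansum(p0) == 0.0

    def test_event_count_conservation(self, toy_genome, toy_cohort, toy_pipeline):
        table, _, _ = toy_pipeline
        _, skipped = brute_force_c_prime(toy_genome, toy_cohort)
        assert table.c_prime.sum() + table.skipped_events == len(toy_cohort)
        assert table.skipped_events == skipped

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_genomes(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2_000, 10_000))
        bases = rng.choice(list("ACGTN"), size=L, p=[0.3, 0.18, 0.18, 0.3, 0.04])
        g = em.ReferenceGenome({"chrI": "".join(bases)})
        pos = rng.choice(L, size=200, replace=False)
        recs = [
            em.MutationRecord(f"s{rng.integers(20)}", "chrI", int(p), g["chrI"][p], "A" if g["chrI"][p] != "A" else "T")
            for p in pos
            if g["chrI"][p] != "N"
        ]
        ds = em.MutationDataset.from_records(recs)
        table = em.compute_p0(g, ds)
        assert em.count_genome_patterns(g) == brute_force_c0(g)
        expect_cp, _ = brute_force_c_prime(g, ds)
        got_cp = {
            code_to_pattern(i): int(c)
            for i, c in enumerate(table.c_prime)
            if c > 0
        }
        assert got_cp == expect_cp

    def test_recurrent_events_count_per_event(self):
        g = em.ReferenceGenome({"chrI": "CCGCC"})
        recs = [em.MutationRecord(f"s{i}", "chrI", 2, "G", "A") for i in range(3)]
        table = em.compute_p0(g, em.MutationDataset.from_records(recs))
        assert table.c_prime[pattern_to_code("CCGCC")] == 3

    def test_deterministic(self, toy_genome, toy_cohort):
        t1 = em.compute_p0(toy_genome, toy_cohort)
        t2 = em.compute_p0(toy_genome, toy_cohort)
        assert np.array_equal(t1.c0, t2.c0) and np.array_equal(t1.c_prime, t2.c_prime)


class TestP0Track:
    def test_constant_on_homopolymer(self):
        g = em.ReferenceGenome({"chrI": "A" * 20})
        ds = em.MutationDataset.from_records(
            [em.MutationRecord("s1", "chrI", 10, "A", "T")]
        )
        table = em.compute_p0(g, ds)
        track = em.p0_track(g, table)
        v = track.values["chrI"]
        assert np.allclose(v[2:-2], table.p0_of("AAAAA"))

    def test_edges_flagged_with_marginal(self, toy_genome, toy_pipeline):
        table, track, _ = toy_pipeline
        for chrom in toy_genome.chromosomes:
            flags = track.flags[chrom]
            assert flags[:2].all() and flags[-2:].all()
            marg = table.central_base_marginal()
            enc0 = "ACGT".index(toy_genome[chrom][0])
            assert track.values[chrom][0] == pytest.approx(marg[enc0])

    def test_track_sum_conserves_events(self, toy_genome, toy_pipeline):
        # sum over non-flagged bases of P0 = sum_w C0(w) * C'(w)/C0(w) = total C'
        table, track, _ = toy_pipeline
        s = sum(
            track.values[c][~track.flags[c]].sum() for c in toy_genome.chromosomes
        )
        assert s == pytest.approx(table.c_prime.sum(), rel=1e-9)


class TestFlankingChisq:
    def test_hand_computed_statistic(self):
        # genome TGATTGCTTGGT: the four G centres have +1 neighbours A,C,G,T
        # (one each), so the expected composition is uniform.  Ten recurrent
        # events at the G followed by A give observed (10,0,0,0) against
        # expected (2.5,2.5,2.5,2.5): chi2 = 22.5 + 3*2.5 = 30.
        g = em.ReferenceGenome({"chrI": "TGATTGCTTGGT"})
        recs = [em.MutationRecord(f"s{i}", "chrI", 1, "G", "A") for i in range(10)]
        res = em.flanking_chisq(g, em.MutationDataset.from_records(recs), "G", +1)
        assert res.chi2 == pytest.approx(30.0)
        assert res.observed.tolist() == [10, 0, 0, 0]
        assert res.observed.sum() == pytest.approx(res.expected.sum())

    def test_proportional_composition_gives_zero(self):
        # mutating EVERY central-base site makes observed == expected exactly
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        g = em.ReferenceGenome({"chrI": seq})
        recs = [
            em.MutationRecord(f"s{i}", "chrI", int(p), "G", "A")
            for i, p in enumerate(
                np.flatnonzero(np.frombuffer(seq.encode(), np.uint8) == ord("G"))
            )
        ]
        res = em.flanking_chisq(g, em.MutationDataset.from_records(recs), "G", +1)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_expected_zero_cell_is_error(self):
        g = em.ReferenceGenome({"chrI": "AGAGAGAGAG"})  # G never followed by C/G/T... only A
        recs = [em.MutationRecord("s", "chrI", 1, "G", "A")]
        with pytest.raises(ValueError, match="zero"):
            em.flanking_chisq(g, em.MutationDataset.from_records(recs), "G", +1)

    def test_detects_neighbour_dependent_mutability(self, toy_genome):
        # G sites followed by A mutate 4x more often than other G sites: the
        # +1 composition around mutated sites must depart from the genome's
        rng = np.random.default_rng(21)
        recs = []
        i = 0
        for chrom, seq in toy_genome.chromosomes.items():
            enc = np.frombuffer(seq.encode(), np.uint8)
            g_pos = np.flatnonzero(enc[:-1] == ord("G"))
            followed_by_a = enc[g_pos + 1] == ord("A")
            rate = np.where(followed_by_a, 0.02, 0.005)
            hit = g_pos[rng.random(len(g_pos)) < rate]
            for p in hit:
                recs.append(em.MutationRecord(f"s{i % 50}", chrom, int(p), "G", "A"))
                i += 1
        res = em.flanking_chisq(toy_genome, em.MutationDataset.from_records(recs), "G", +1)
        assert res.p_value < 1e-6
        # and at an offset with no engineered effect the test stays calm
        res2 = em.flanking_chisq(toy_genome, em.MutationDataset.from_records(recs), "G", -3)
        assert res2.p_value > 0.001
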