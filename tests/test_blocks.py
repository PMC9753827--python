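"""LD statistics and both block-partition rules, against counting oracles."""

import numpy as np
import pytest

from haplogp.blocks import (
    MonomorphicMarkerError,
    block_summary,
    fixed_partition,
    ld_partition,
    pairwise_r2,
)
from haplogp.simdata import SimConfig, simulate_panel

from conftest import panel_from_haplotypes


def brute_force_r2(hap, i, j):
    """Independent oracle: tally the four haplotype classes explicitly."""
    counts = {"11": 0, "12": 0, "21": 0, "22": 0}
    for row in hap:
        key = ("1" if row[i] == 0 else "2") + ("1" if row[j] == 0 else "2")
        counts[key] += 1
    n = len(hap)
    p11, p12, p21, p22 = (counts[k] / n for k in ("11", "12", "21", "22"))
    pA1, pB1 = p11 + p12, p11 + p21
    D = p11 * p22 - p12 * p21
    return D, D**2 / (pA1 * (1 - pA1) * pB1 * (1 - pB1))


def haps_from_counts(c11, c12, c21, c22):
    rows = (
        [[0, 0]] * c11 + [[0, 1]] * c12 + [[1, 0]] * c21 + [[1, 1]] * c22
    )
    return np.array(rows, dtype=np.int8)


class TestPairwiseR2:
    def test_perfect_ld(self):
        panel = panel_from_haplotypes(haps_from_counts(4, 0, 0, 4))
        s = pairwise_r2(panel, 0, 1)
        assert s.D == pytest.approx(0.25)
        assert s.r2 == pytest.approx(1.0)

    def test_independence(self):
        panel = panel_from_haplotypes(haps_from_counts(2, 2, 2, 2))
        s = pairwise_r2(panel, 0, 1)
        assert s.D == pytest.approx(0.0)
        assert s.r2 == pytest.approx(0.0)

    def test_intermediate_ld_matches_hand_count(self):
        panel = panel_from_haplotypes(haps_from_counts(3, 1, 1, 3))
        s = pairwise_r2(panel, 0, 1)
        assert s.D == pytest.approx(1 / 8)
        assert s.r2 == pytest.approx(0.25)

    def test_hap_freqs_consistency(self):
        panel = panel_from_haplotypes(haps_from_counts(3, 1, 1, 3))
        s = pairwise_r2(panel, 0, 1)
        assert sum(s.hap_freqs) == pytest.approx(1.0)
        # pA1 = pA1B1 + pA1B2
        assert s.allele_freqs[0] == pytest.approx(s.hap_freqs[0] + s.hap_freqs[1])

    def test_symmetry_and_self_r2(self, sim_panel):
        for i, j in [(0, 1), (5, 40), (10, 100)]:
            assert pairwise_r2(sim_panel, i, j).r2 == pairwise_r2(sim_panel, j, i).r2
        assert pairwise_r2(sim_panel, 3, 3).r2 == pytest.approx(1.0)

    def test_monomorphic_marker_raises(self):
        hap = np.array([[0, 0], [0, 1], [0, 0], [0, 1]], dtype=np.int8)
        panel = panel_from_haplotypes(hap)
        with pytest.raises(MonomorphicMarkerError):
            pairwise_r2(panel, 0, 1)

    def test_matches_brute_force_on_random_panels(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 20))
            hap = rng.integers(0, 2, size=(2 * n, 2)).astype(np.int8)
            if hap[:, 0].std() == 0 or hap[:, 1].std() == 0:
                continue
            panel = panel_from_haplotypes(hap)
            s = pairwise_r2(panel, 0, 1)
            D, r2 = brute_force_r2(hap, 0, 1)
            assert s.D == pytest.approx(D, abs=1e-14)
            assert s.r2 == pytest.approx(r2, abs=1e-12)


def check_partition_against_rule(panel, part, threshold):
    """Oracle: each within-block adjacent pair >= threshold, each boundary
    pair (last of block vs next marker, same chromosome) < threshold."""
    chrom = panel.marker_map["chrom"].to_numpy()
    p = panel.haplotypes.mean(axis=0)
    for start, stop in part.blocks:
        for j in range(start, stop - 1):
            assert pairwise_r2(panel, j, j + 1).r2 >= threshold
        nxt = stop
        if nxt < panel.n_markers and chrom[nxt] == chrom[stop - 1] and 0 < p[nxt] < 1:
            assert pairwise_r2(panel, stop - 1, nxt).r2 < threshold


class TestLDPartition:
    def test_forced_two_block(self):
        # markers 0,1 identical (r2=1); marker 2 independent of marker 1
        hap = np.array(
            [[0, 0, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1],
             [0, 0, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=np.int8
        )
        panel = panel_from_haplotypes(hap)
        part = ld_partition(panel, 0.3)
        assert part.blocks == [(0, 2)]
        assert list(part.nonblocked) == [2]

    def test_all_linked_single_block(self):
        col = np.array([0, 1] * 5, dtype=np.int8)
        hap = np.tile(col[:, None], (1, 10))
        panel = panel_from_haplotypes(hap)
        part = ld_partition(panel, 0.99)
        assert part.blocks == [(0, 10)]
        assert part.nonblocked.size == 0

    def test_blocks_do_not_span_chromosomes(self):
        col = np.array([0, 1] * 5, dtype=np.int8)
        hap = np.tile(col[:, None], (1, 6))
        panel = panel_from_haplotypes(hap, chrom=["1"] * 3 + ["2"] * 3,
                                      positions=[100, 200, 300, 100, 200, 300])
        part = ld_partition(panel, 0.5)
        assert part.blocks == [(0, 3), (3, 6)]

    def test_monomorphic_markers_go_nonblocked(self):
        col = np.array([0, 1] * 5, dtype=np.int8)
        hap = np.column_stack([col, np.zeros(10, np.int8), col])
        panel = panel_from_haplotypes(hap)
        part = ld_partition(panel, 0.3)
        assert 1 in part.nonblocked

    def test_threshold_validation(self, sim_panel):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                ld_partition(sim_panel, bad)

    @pytest.mark.parametrize("seed", range(20))
    def test_partition_rule_oracle_random_panels(self, seed):
        cfg = SimConfig(
            n_individuals=60, n_chromosomes=1, markers_per_chrom=50,
            n_founders=30, n_generations=1, ld_decay_bp=200_000,
            chrom_length_bp=2_000_000, seed=900 + seed,
        )
        panel = simulate_panel(cfg)
        part = ld_partition(panel, 0.3)
        check_partition_against_rule(panel, part, 0.3)

    def test_raising_threshold_never_adds_blocked_snps(self, sim_panel):
        previous = None
        for thr in (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8):
            s = block_summary(ld_partition(sim_panel, thr))
            if previous is not None:
                assert s.n_snps_in_blocks <= previous
            previous = s.n_snps_in_blocks


class TestFixedPartition:
    def test_exact_chunking(self, sim_panel):
        part = fixed_partition(sim_panel.marker_map, 5)
        assert part.n_blocks == sim_panel.n_markers // 5
        assert part.nonblocked.size == 0
        assert set(part.block_sizes()) == {5}

    def test_ten_markers_k5(self):
        panel = panel_from_haplotypes(np.zeros((4, 10), np.int8))
        part = fixed_partition(panel.marker_map, 5)
        assert part.blocks == [(0, 5), (5, 10)]

    def test_remainder_per_chromosome(self):
        panel = panel_from_haplotypes(np.zeros((4, 7), np.int8))
        part = fixed_partition(panel.marker_map, 5, chunking_mode="per_chromosome")
        assert sorted(part.block_sizes().tolist()) == [2, 5]

    def test_genome_wide_crosses_chromosomes_per_chrom_does_not(self):
        chrom = ["1"] * 7 + ["2"] * 5
        pos = [100 * (i + 1) for i in range(7)] + [100 * (i + 1) for i in range(5)]
        panel = panel_from_haplotypes(np.zeros((4, 12), np.int8), chrom=chrom, positions=pos)
        gw = fixed_partition(panel.marker_map, 5, "genome_wide")
        pc = fixed_partition(panel.marker_map, 5, "per_chromosome")
        assert [s - e for e, s in [(a, b) for a, b in gw.blocks]] == [5, 5, 2]
        assert sorted(pc.block_sizes().tolist()) == [2, 5, 5]

    def test_k_validation(self, sim_panel):
        with pytest.raises(ValueError):
            fixed_partition(sim_panel.marker_map, 0)


class TestBlockSummary:
    def test_hand_tally(self):
        panel = panel_from_haplotypes(np.zeros((4, 10), np.int8))
        part = fixed_partition(panel.marker_map, 5)
        part.blocks = [(0, 5), (5, 8)]
        part.nonblocked = np.array([8, 9])
        s = block_summary(part)
        assert (s.n_blocks, s.n_snps_in_blocks, s.n_snps_out_of_blocks) == (2, 8, 2)
        assert s.mean_snps_per_block == pytest.approx(4.0)
        assert s.max_snps_per_block == 5

    def test_empty_partition(self, sim_panel):
        part = ld_partition(sim_panel, 1.0)
        s = block_summary(part)
        assert s.n_snps_in_blocks + s.n_snps_out_of_blocks == sim_panel.n_markers

    def test_summary_matches_independent_recount(self, sim_panel):
        part = ld_partition(sim_panel, 0.3)
        s = block_summary(part)
        # recount directly from the partition object
        sizes = [stop - start for start, stop in part.blocks]
        assert s.n_blocks == len(sizes)
        assert s.n_snps_in_blocks == sum(sizes)
        assert s.n_snps_out_of_blocks == len(part.nonblocked)
        assert s.max_snps_per_block == max(sizes)
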