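"""Lattice model: hand-enumerated assortment fixtures, fill invariants,
initial-configuration targets and the per-round r bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from pcdhedge.lattice import (
    A_MINUS,
    A_PLUS,
    B_MINUS,
    B_PLUS,
    EMPTY,
    LatticeParams,
    delta_r_statistics,
    init_lattice,
    lattice_round,
    measure_assortment,
    repopulate_lattice,
    run_lattice_competition,
)


class TestMeasureAssortment:
    def test_lone_pcd_plus_cell_among_competitors(self):
        grid = np.full((3, 3), A_MINUS, dtype=np.int8)
        grid[1, 1] = A_PLUS
        summary = measure_assortment(grid)
        assert summary.mean_r == 0.0
        assert summary.n_cells_counted == 1

    def test_pure_pcd_plus_lattice(self):
        grid = np.full((4, 4), B_PLUS, dtype=np.int8)
        assert measure_assortment(grid).mean_r == 1.0

    def test_hand_enumerated_three_by_three(self):
        # column 0 and centre PCD+, columns 1 (except centre) and 2 PCD-:
        # per-cell r enumerated over each cell's clipped neighborhood
        grid = np.array(
            [
                [A_PLUS, A_MINUS, A_MINUS],
                [A_PLUS, A_PLUS, A_MINUS],
                [A_PLUS, A_MINUS, A_MINUS],
            ],
            dtype=np.int8,
        )
        summary = measure_assortment(grid)
        # corners (0,0) and (2,0): neighbors {A+, A+, A-} -> 2/3
        # edge (1,0): neighbors {A+, A+, A+, A-, A-} -> 3/5
        # centre (1,1): all 8 neighbors, 3 PCD+ -> 3/8
        expected = np.array([2 / 3, 3 / 5, 2 / 3, 3 / 8])
        assert summary.n_cells_counted == 4
        assert sorted(summary.r_values) == pytest.approx(sorted(expected))
        assert summary.mean_r == pytest.approx(expected.mean())

    def test_no_pcd_plus_cells_flagged_undefined(self):
        grid = np.full((3, 3), A_MINUS, dtype=np.int8)
        summary = measure_assortment(grid)
        assert not summary.defined
        assert np.isnan(summary.mean_r)

    def test_dead_neighborhoods_excluded(self):
        grid = np.zeros((3, 3), dtype=np.int8)
        grid[0, 0] = A_PLUS  # isolated: no living neighbor
        grid[2, 2] = A_PLUS
        grid[2, 1] = B_PLUS
        summary = measure_assortment(grid)
        assert summary.n_cells_counted == 2  # the adjacent pair only
        assert summary.mean_r == 1.0


class TestInitLattice:
    @pytest.mark.parametrize("target", [0.5, 0.75, 0.95])
    def test_hits_target_with_equal_genotypes(self, target):
        grid = init_lattice(target, 100, 100, rng=np.random.default_rng(0))
        assert (grid != EMPTY).all()
        n_plus = ((grid == A_PLUS) | (grid == B_PLUS)).sum()
        assert abs(n_plus - 5000) <= 1
        assert abs(measure_assortment(grid).mean_r - target) <= 0.02

    def test_anti_assorted_target_fails_fast(self):
        with pytest.raises(ValueError, match="achieved"):
            init_lattice(0.2, 50, 50, rng=np.random.default_rng(0), max_batches=40)

    def test_phenotypes_roughly_balanced(self):
        grid = init_lattice(0.5, 100, 100, rng=np.random.default_rng(1))
        n_a = ((grid == A_PLUS) | (grid == A_MINUS)).sum()
        assert abs(n_a - 5000) < 300  # binomial(10^4, .5) within ~6 sd


class TestRepopulate:
    def test_full_lattice_unchanged(self):
        grid = np.full((5, 5), A_PLUS, dtype=np.int8)
        out = repopulate_lattice(grid, 0.5, 0.5, np.random.default_rng(0))
        assert (out == grid).all()

    def test_single_gap_copies_sole_neighbor(self):
        grid = np.zeros((3, 3), dtype=np.int8)
        grid[0, 0] = B_MINUS
        grid[0, 1] = EMPTY
        out = repopulate_lattice(grid, 0.0, 0.0, np.random.default_rng(0))
        assert (out != EMPTY).all()
        assert (out == B_MINUS).all()

    def test_no_phenotype_invented_without_switching(self):
        rng = np.random.default_rng(2)
        grid = np.zeros((20, 20), dtype=np.int8)
        grid[0, 0] = A_PLUS
        grid[19, 19] = A_MINUS
        out = repopulate_lattice(grid, 0.0, 0.0, rng)
        assert set(np.unique(out)) <= {A_PLUS, A_MINUS}

    def test_two_seed_fill_front_is_symmetric(self):
        rng = np.random.default_rng(3)
        totals = []
        for _ in range(40):
            grid = np.zeros((15, 15), dtype=np.int8)
            grid[0, 0] = A_PLUS
            grid[14, 14] = A_MINUS
            out = repopulate_lattice(grid, 0.0, 0.0, rng)
            totals.append(((out == A_PLUS).sum(), (out == A_MINUS).sum()))
        totals = np.array(totals, dtype=float)
        diff = totals[:, 0] - totals[:, 1]
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) <= 3 * se

    def test_all_dead_rejected(self):
        with pytest.raises(ValueError):
            repopulate_lattice(np.zeros((3, 3), dtype=np.int8), 0.1, 0.1,
                               np.random.default_rng(0))


class TestLatticeRound:
    def test_quiet_round_is_identity(self):
        params = LatticeParams(pcd_prob=0.0, disaster_prob=0.0)
        grid = init_lattice(0.5, 20, 20, rng=np.random.default_rng(4))
        out, log = lattice_round(grid, params, None, np.random.default_rng(5))
        assert (out == grid).all()
        assert not log["disaster"]

    def test_disaster_refills_lattice_without_target_phenotype_gain(self):
        params = LatticeParams(pcd_prob=0.0, disaster_prob=1.0,
                               switch_prob_plus=0.0, switch_prob_minus=0.0)
        grid = init_lattice(0.5, 20, 20, rng=np.random.default_rng(6))
        out, log = lattice_round(grid, params, None, np.random.default_rng(7))
        assert log["disaster"]
        assert (out != EMPTY).all()  # conservation: full again
        # with p = 0 the annihilated phenotype cannot reappear
        dead = {"A": (A_PLUS, A_MINUS), "B": (B_PLUS, B_MINUS)}[log["target"]]
        assert not np.isin(out, dead).any()

    def test_lattice_full_after_every_round(self):
        params = LatticeParams(rows=30, cols=30)
        grid = init_lattice(0.5, 30, 30, rng=np.random.default_rng(8))
        rng = np.random.default_rng(9)
        prev = None
        for _ in range(30):
            grid, log = lattice_round(grid, params, prev, rng)
            if log["disaster"]:
                prev = log["target"]
            if log["extinct"]:
                break
            assert (grid != EMPTY).all()

    def test_disaster_regrowth_raises_assortment(self):
        """Bottleneck + clonal regrowth is the structure-generating mechanism."""
        params = LatticeParams(pcd_prob=0.0, disaster_prob=1.0)
        deltas = []
        for s in range(30):
            grid = init_lattice(0.5, 20, 20, rng=np.random.default_rng(100 + s))
            before = measure_assortment(grid).mean_r
            out, log = lattice_round(grid, params, None, np.random.default_rng(200 + s))
            if log["extinct"]:
                continue
            after = measure_assortment(out).mean_r
            if np.isfinite(after):
                deltas.append(after - before)
        assert np.mean(deltas) > 0


class TestCompetitionAndStats:
    def test_neutral_lattice_competition_symmetric(self):
        params = LatticeParams(pcd_prob=0.0, disaster_prob=0.1, rows=20, cols=20)
        wins = {"plus": 0, "minus": 0}
        for s in range(30):
            result, _ = run_lattice_competition(0.5, params, max_rounds=400, seed=s)
            if result.plus_won:
                wins["plus"] += 1
            elif result.minus_won:
                wins["minus"] += 1
        decided = wins["plus"] + wins["minus"]
        assert decided > 0
        assert abs(wins["plus"] - decided / 2) <= 2.58 * np.sqrt(decided) / 2 + 1

    def test_trajectory_bookkeeping(self):
        params = LatticeParams(rows=20, cols=20)
        result, traj = run_lattice_competition(0.5, params, max_rounds=50, seed=11)
        assert len(traj) == result.rounds_elapsed or result.winner == "both_extinct"
        total = traj[["n_a_plus", "n_b_plus", "n_a_minus", "n_b_minus"]].sum(axis=1)
        assert (total == 400).all()
        assert np.allclose(traj["mean_r"].diff().dropna(),
                           traj["delta_r"].iloc[1:], equal_nan=True)

    def test_delta_r_statistics_exact_arithmetic(self):
        logs = pd.DataFrame(
            {
                "delta_r": [0.1, 0.3, -0.02, -0.04, 0.5, 0.2],
                "disaster": [True, True, False, False, True, True],
                "switched_target": [True, True, None, None, False, None],
            }
        )
        stats = delta_r_statistics(logs)
        assert stats["no_disaster"]["mean"] == pytest.approx(-0.03)
        assert stats["switching_disaster"]["mean"] == pytest.approx(0.2)
        assert stats["switching_disaster"]["n"] == 2
        assert stats["repeat_disaster"]["mean"] == pytest.approx(0.5)

    def test_empty_class_flagged(self):
        logs = pd.DataFrame(
            {"delta_r": [0.0], "disaster": [False], "switched_target": [None]}
        )
        stats = delta_r_statistics(logs)
        assert np.isnan(stats["switching_disaster"]["mean"])
        assert stats["switching_disaster"]["n"] == 0
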