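import numpy as np
import pandas as pd
import pytest

from occuedge.model import detection_logit, inv_logit
from occuedge.pipeline import assemble
from occuedge.simulate import (
    SimulationConfig,
    TrueParams,
    generate_landscape,
    generate_ranges,
    recovery_score,
    simulate_dataset,
    simulate_surveys,
    simulate_truth,
)


@pytest.fixture(scope="module")
def cfg():
    return SimulationConfig(n_rows=12, n_cols=12, n_species=10, range_size_max=100)


class TestLandscape:
    def test_deterministic_given_seed(self, cfg):
        a = generate_landscape(cfg, seed=3)
        b = generate_landscape(cfg, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_realm_split_is_half_half(self, cfg):
        land = generate_landscape(cfg, seed=3)
        assert (land["R"] == 0).sum() == len(land) // 2

    def test_conversion_classes_both_represented(self, cfg):
        land = generate_landscape(cfg, seed=4)
        prop = (land["C"] == 1).mean()
        assert 0.1 < prop < 0.9

    def test_fraction_in_unit_interval(self, cfg):
        land = generate_landscape(cfg, seed=5)
        assert land["converted_fraction"].between(0, 1).all()


class TestRanges:
    def test_requested_single_cell_range_present(self, cfg):
        ranges = generate_ranges(cfg, seed=1)
        sizes = sorted(r.size for r in ranges.values())
        assert sizes[0] == 1
        assert all(s <= cfg.range_size_max for s in sizes)

    def test_all_cells_on_block(self, cfg):
        from occuedge.simulate import block_cells

        block = set(block_cells(cfg).tolist())
        for rng in generate_ranges(cfg, seed=2).values():
            assert set(rng.cells.tolist()) <= block

    def test_rook_contiguity(self, cfg):
        g = cfg.grid
        for rng in generate_ranges(cfg, seed=3).values():
            rows, cols = g.rowcol(rng.cells)
            cells = set(zip(rows.tolist(), cols.tolist()))
            start = next(iter(cells))
            seen = {start}
            stack = [start]
            while stack:
                r, c = stack.pop()
                for nb in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
                    if nb in cells and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            assert seen == cells, f"range of {rng.species_id} not rook-connected"


class TestTruth:
    def test_degenerate_certain_occupancy(self, cfg):
        params = TrueParams(alpha=(50.0, 50.0, 0.0, 0.0), beta=(0.0, 0.0, 0.0, 0.0),
                            mu_lpsi=50.0, sigma_lpsi=1e-9, sigma_u=1e-9, sigma_v=1e-9)
        land = generate_landscape(cfg, seed=1)
        ranges = generate_ranges(cfg, seed=1)
        truth = simulate_truth(ranges, land, params, seed=1, config=cfg)
        assert truth.z1.all() and truth.z2.all()

    def test_degenerate_all_empty(self, cfg):
        params = TrueParams(mu_lpsi=-50.0, sigma_lpsi=1e-9, mu_lgamma=-50.0, sigma_lgamma=1e-9)
        land = generate_landscape(cfg, seed=1)
        ranges = generate_ranges(cfg, seed=1)
        truth = simulate_truth(ranges, land, params, seed=1, config=cfg)
        assert not truth.z1.any() and not truth.z2.any()

    def test_edge_extinctions_more_frequent_with_negative_slope(self):
        # strong negative slope in realm 0: extinction frequency among edge
        # cells (D' > 0.8) exceeds core cells (D' < 0.4)
        big = SimulationConfig(n_rows=20, n_cols=20, n_species=30,
                               params=TrueParams(alpha=(2.0, 2.0, 0.0, 0.0),
                                                 beta=(-6.0, -6.0, 0.0, 0.0),
                                                 sigma_u=0.1, sigma_v=0.1))
        land = generate_landscape(big, seed=2)
        ranges = generate_ranges(big, seed=2)
        truth = simulate_truth(ranges, land, big.params, seed=2, config=big)
        occupied = truth.z1 == 1
        extinct = occupied & (truth.z2 == 0)
        edge = truth.pair_dprime > 0.8
        core = truth.pair_dprime < 0.4
        rate_edge = extinct[occupied & edge].size and extinct[edge & occupied].mean()
        rate_core = extinct[core & occupied].mean() if (core & occupied).any() else 0.0
        assert (edge & occupied).sum() > 100
        assert rate_edge > rate_core

    def test_records_never_contradict_truth(self, cfg):
        records, _, _, truth = simulate_dataset(cfg, seed=6)
        g = cfg.grid
        zl = truth.z_lookup()
        cells = g.point_to_cell(records["lon"], records["lat"])
        for sp, cell, year in zip(records["species_id"], cells, records["year"]):
            period = 1 if year < 1980 else 2
            assert zl[(sp, int(cell), period)] == 1


class TestSurveysGeneration:
    def test_no_occupancy_no_records(self, cfg):
        params = TrueParams(mu_lpsi=-50.0, sigma_lpsi=1e-9, mu_lgamma=-50.0, sigma_lgamma=1e-9)
        land = generate_landscape(cfg, seed=1)
        ranges = generate_ranges(cfg, seed=1)
        truth = simulate_truth(ranges, land, params, seed=1, config=cfg)
        records, surveys = simulate_surveys(truth, cfg, seed=1)
        assert records.empty and surveys.empty

    def test_certain_detection_records_every_present_species(self, cfg):
        params = TrueParams(alpha=(50.0, 50.0, 0.0, 0.0), mu_lpsi=50.0, sigma_lpsi=1e-9,
                            mu_delta1=50.0, sigma_delta1=1e-9, sigma_delta2=1e-9,
                            sigma_delta3=1e-9, sigma_u=1e-9, sigma_v=1e-9)
        land = generate_landscape(cfg, seed=1)
        ranges = generate_ranges(cfg, seed=1)
        truth = simulate_truth(ranges, land, params, seed=1, config=cfg)
        _, surveys = simulate_surveys(truth, cfg, seed=1)
        # every survey's realized list equals the number of species present
        present_per_cell = {}
        for idx in range(truth.pair_species.size):
            for per, z in ((1, truth.z1[idx]), (2, truth.z2[idx])):
                key = (int(truth.pair_cell[idx]), per)
                present_per_cell[key] = present_per_cell.get(key, 0) + int(z)
        for _, row in surveys.iterrows():
            assert row["list_length"] == present_per_cell[(row["cell_id"], row["period"])]

    def test_detection_frequency_matches_closed_form(self):
        # long-list surveys in period 2: empirical detection rate of present
        # species ~ inverse-logit(mu_delta1 + mu_delta3 + delta_t)
        cfg = SimulationConfig(
            n_rows=14, n_cols=14, n_species=20, range_size_max=120,
            effort_probs=(0.0, 0.0, 1.0),  # all surveys long-effort
            mean_surveys=4.0,
            params=TrueParams(sigma_delta1=1e-9, sigma_delta2=1e-9, sigma_delta3=1e-9),
        )
        land = generate_landscape(cfg, seed=8)
        ranges = generate_ranges(cfg, seed=8)
        truth = simulate_truth(ranges, land, cfg.params, seed=8, config=cfg)
        records, surveys = simulate_surveys(truth, cfg, seed=8)
        p = cfg.params
        expected = inv_logit(detection_logit(0, 1, 2, p.delta_t, p.mu_delta1, p.mu_delta2, p.mu_delta3))
        # trials: present species x period-2 surveys at their cells
        n_svy2 = surveys[surveys["period"] == 2].groupby("cell_id").size()
        # count detections among period-2 records
        g = cfg.grid
        cells = g.point_to_cell(records["lon"], records["lat"])
        det2 = int(((records["year"] >= 1980)).sum())
        trials = 0
        for idx in range(truth.pair_species.size):
            if truth.z2[idx]:
                trials += int(n_svy2.get(int(truth.pair_cell[idx]), 0))
        assert trials > 2000
        rate = det2 / trials
        se = np.sqrt(expected * (1 - expected) / trials)
        # surveys with zero detections vanish from the bookkeeping, which
        # inflates the naive rate slightly; allow generous binomial slack
        assert rate == pytest.approx(expected, abs=max(5 * se, 0.02))

    def test_roundtrip_through_assembly(self, cfg):
        """Assembling the generated records reproduces the generator's
        survey bookkeeping (counts, list lengths, categories) exactly."""
        records, species_cells, cell_attrs, truth = simulate_dataset(cfg, seed=9)
        _, gen_surveys = simulate_surveys(truth, cfg, seed=9)
        from occuedge.surveys import build_surveys

        rec = records.copy()
        rec["cell_id"] = cfg.grid.point_to_cell(rec["lon"], rec["lat"])
        asm = build_surveys(rec)
        asm_key = asm[["cell_id", "year", "period", "list_length", "category"]].sort_values(
            ["cell_id", "year"]).reset_index(drop=True)
        gen_key = gen_surveys.sort_values(["cell_id", "year"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(asm_key, gen_key, check_dtype=False)


class TestRecoveryScore:
    def make_summary(self):
        return pd.DataFrame(
            {"mean": [1.0, -2.0], "q2.5": [0.5, -3.0], "q97.5": [1.5, -1.0]},
            index=["alpha0", "beta0"],
        )

    def test_zero_bias_when_mean_equals_truth(self):
        sc = recovery_score(self.make_summary(), {"alpha0": 1.0})
        assert sc.loc["alpha0", "bias"] == 0.0
        assert bool(sc.loc["alpha0", "covered"])

    def test_boundary_truth_counts_as_covered(self):
        sc = recovery_score(self.make_summary(), {"beta0": -3.0})
        assert bool(sc.loc["beta0", "covered"])

    def test_missing_parameter_raises(self):
        with pytest.raises(KeyError):
            recovery_score(self.make_summary(), {"nope": 0.0})
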