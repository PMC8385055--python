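"""Synthetic time-lapse generator: geometry, dye behaviour, fates, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from droptox import (
    EncapsulationParams,
    GeneratorConfig,
    GroundTruth,
    default_death_time_dist,
    generate_experiment,
    sample_fates,
)


def _cells_table(n_droplets, k_e, k_t):
    rows = []
    cid = 0
    for d in range(n_droplets):
        for _ in range(k_e):
            rows.append((cid, d, 0, "effector", 0.0, 0.0)); cid += 1
        for _ in range(k_t):
            rows.append((cid, d, 0, "target", 0.0, 0.0)); cid += 1
    return pd.DataFrame(
        rows, columns=["cell_id", "droplet_id", "tile_id", "cell_type", "offset_x", "offset_y"]
    )


class TestSampleFates:
    def test_no_killing_no_events(self):
        cells = _cells_table(100, 1, 1)
        ev = sample_fates(cells, 0.0, default_death_time_dist(11), seed=0)
        assert len(ev) == 0

    def test_certain_killing_point_mass(self):
        cells = _cells_table(50, 1, 1)
        dist = np.zeros(11)
        dist[2] = 1.0
        ev = sample_fates(cells, 1.0, dist, seed=0)
        assert len(ev) == 50
        assert (ev.death_time == 2).all()
        assert (ev.cell_type == "target").all()

    def test_event_count_binomial(self):
        cells = _cells_table(2000, 1, 1)
        ev = sample_fates(cells, 0.2, default_death_time_dist(11), seed=3)
        se = math.sqrt(2000 * 0.2 * 0.8)
        assert abs(len(ev) - 400) < 3 * se

    def test_spontaneous_death_only_without_effectors(self):
        cells = _cells_table(1000, 0, 1)
        ev = sample_fates(
            cells, 0.9, default_death_time_dist(11), seed=4, spontaneous_target_rate=0.05
        )
        se = math.sqrt(1000 * 0.05 * 0.95)
        assert abs(len(ev) - 50) < 3 * se
        # paired targets never die spontaneously
        paired = _cells_table(1000, 1, 1)
        ev2 = sample_fates(
            paired, 0.0, default_death_time_dist(11), seed=4, spontaneous_target_rate=0.05
        )
        assert len(ev2) == 0

    def test_death_time_dist_normalised(self):
        for n_t in (5, 11):
            p = default_death_time_dist(n_t)
            assert len(p) == n_t
            assert p[0] == 0.0
            assert p.sum() == pytest.approx(1.0)


class TestGenerateExperiment:
    def test_deterministic_under_fixed_seed(self):
        cfg = GeneratorConfig(n_tiles=1, n_timepoints=2, seed=9)
        s1, t1 = generate_experiment(cfg)
        s2, t2 = generate_experiment(GeneratorConfig(n_tiles=1, n_timepoints=2, seed=9))
        for tid in s1.tile_ids:
            assert np.array_equal(s1.tiles[tid], s2.tiles[tid])
        pd.testing.assert_frame_equal(t1.droplets, t2.droplets)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)

    def test_zero_loading_gives_droplets_without_cells(self):
        cfg = GeneratorConfig(
            n_tiles=1,
            n_timepoints=2,
            seed=1,
            encapsulation=EncapsulationParams(conc_effector=1e-6, conc_target=1e-6),
        )
        stack, truth = generate_experiment(cfg)
        assert truth.n_droplets > 0
        assert len(truth.cells) == 0
        # the brightfield still shows rims (dark pixels well below background)
        bf = stack.get(0, 0, "brightfield").astype(float)
        assert bf.min() < cfg.brightfield_level - 0.5 * cfg.ring_depth

    def test_droplet_interiors_never_overlap(self, small_experiment):
        _, truth = small_experiment
        for (tile, t), grp in truth.droplets.groupby(["tile_id", "timepoint"]):
            pts = grp[["x", "y"]].to_numpy()
            r = grp["radius"].to_numpy()
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            need = r[:, None] + r[None, :]
            np.fill_diagonal(d, np.inf)
            assert (d >= need - 1e-9).all()

    def test_cells_stay_inside_their_droplet(self, small_experiment):
        _, truth = small_experiment
        r_by_droplet = truth.droplets.groupby("droplet_id")["radius"].first()
        off = np.hypot(truth.cells.offset_x, truth.cells.offset_y)
        assert (off <= r_by_droplet.loc[truth.cells.droplet_id].to_numpy()).all()

    def test_mover_and_jitter_contract(self, small_config, small_experiment):
        _, truth = small_experiment
        gate = 0.5 * small_config.droplet_radius_px
        for did, grp in truth.droplets.groupby("droplet_id"):
            grp = grp.sort_values("timepoint")
            steps = np.hypot(grp.x.diff().dropna(), grp.y.diff().dropna())
            if grp.is_mover.iloc[0]:
                assert steps.max() > gate
            else:
                assert steps.max() < gate

    def test_viability_switches_on_at_death_and_stays(self):
        cfg = GeneratorConfig(
            n_tiles=1,
            n_timepoints=5,
            seed=21,
            killer_prob=1.0,
            dead_at_t0_prob=0.0,
            spontaneous_target_rate=0.0,
            noise_sd=0.0,
        )
        stack, truth = generate_experiment(cfg)
        dead = truth.cells.dropna(subset=["death_time"])
        assert len(dead) > 0
        for cell in dead.itertuples():
            death = int(cell.death_time)
            for t in range(cfg.n_timepoints):
                pos = truth.droplets[
                    (truth.droplets.droplet_id == cell.droplet_id)
                    & (truth.droplets.timepoint == t)
                ].iloc[0]
                tile = int(pos.tile_id)
                x = int(round(pos.x + cell.offset_x))
                y = int(round(pos.y + cell.offset_y))
                val = float(stack.get(tile, t, "viability")[y, x])
                if t >= death:
                    assert val > cfg.fluor_background + 0.5 * cfg.viability_amplitude
                else:
                    assert val < cfg.fluor_background + 0.1 * cfg.viability_amplitude

    def test_effector_tracker_decays_target_stays(self):
        cfg = GeneratorConfig(n_tiles=1, n_timepoints=11, seed=30, noise_sd=0.0,
                              mover_fraction=0.0, killer_prob=0.0, dead_at_t0_prob=0.0,
                              spontaneous_target_rate=0.0)
        stack, truth = generate_experiment(cfg)
        pos0 = truth.cell_positions(0)
        pos10 = truth.cell_positions(10)
        for ctype, channel, decays in (
            ("effector", "effector_tracker", True),
            ("target", "target_tracker", False),
        ):
            sub0 = pos0[pos0.cell_type == ctype]
            if len(sub0) == 0:
                continue
            c0 = sub0.iloc[0]
            c10 = pos10[pos10.cell_id == c0.cell_id].iloc[0]
            v0 = float(stack.get(0, 0, channel)[int(round(c0.y)), int(round(c0.x))])
            v10 = float(stack.get(0, 10, channel)[int(round(c10.y)), int(round(c10.x))])
            if decays:
                # one half-life elapsed
                assert v10 - cfg.fluor_background == pytest.approx(
                    0.5 * (v0 - cfg.fluor_background), rel=0.15
                )
            else:
                assert v10 == pytest.approx(v0, rel=0.1)

    def test_occupancy_marginals_follow_poisson(self, small_experiment):
        _, truth = small_experiment
        occ = truth.occupancy()
        lam = truth.config.encapsulation.lambda_effector
        n = len(occ)
        se = math.sqrt(lam / n)
        assert abs(occ.k_effector.mean() - lam) < 4 * se

    def test_infeasible_layout_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_experiment(GeneratorConfig(tile_shape=(48, 48), n_tiles=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_timepoints=1)
        with pytest.raises(ValueError):
            GeneratorConfig(killer_prob=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(cell_diameter_um=60.0)

    def test_ground_truth_round_trip(self, small_experiment, tmp_path):
        _, truth = small_experiment
        truth.save(tmp_path)
        back = GroundTruth.load(tmp_path)
        pd.testing.assert_frame_equal(truth.droplets, back.droplets)
        pd.testing.assert_frame_equal(truth.cells, back.cells)
        assert back.config.seed == truth.config.seed
        assert back.config.encapsulation == truth.config.encapsulation
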