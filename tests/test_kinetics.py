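"""Death-time calling, eligibility, killer fraction and kinetics summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droptox import (
    call_death_time,
    control_viability,
    detect_serial_killers,
    killer_fraction,
    kinetics_histogram,
    select_eligible,
)


class TestCallDeathTime:
    @pytest.mark.parametrize(
        "trace, theta, persistence, expected",
        [
            ([0, 0, 0, 8, 9, 9], 1, 1, 3),
            ([0, 0, 0, 0], 1, 1, None),
            ([5, 5, 5], 1, 1, 0),
            ([0, 5, 0, 5, 5], 1, 2, 3),
            ([0, 0, 5], 1, 2, 2),       # persistence truncated at series end
            ([0, 3, 0, 3, 0], 2, 2, None),
        ],
    )
    def test_examples(self, trace, theta, persistence, expected):
        assert call_death_time(np.array(trace, float), theta, persistence) == expected

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            call_death_time(np.zeros(3), -1.0)
        with pytest.raises(ValueError):
            call_death_time(np.zeros(3), 1.0, persistence=0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=20),
           st.floats(0, 50))
    def test_death_time_is_first_crossing_or_none(self, trace, theta):
        t = call_death_time(np.array(trace), theta, persistence=1)
        above = [v > theta for v in trace]
        assert t == (above.index(True) if any(above) else None)


class TestSelectEligible:
    def _census(self, rows):
        df = pd.DataFrame(rows, columns=["track_id", "k_effector", "k_target", "dead_at_t0"])
        return df

    def test_exclusion_reasons(self):
        census = self._census(
            [(0, 1, 1, 0), (1, 1, 1, 1), (2, 2, 1, 0), (3, 0, 1, 0)]
        )
        eligible, excluded = select_eligible(census)
        assert list(eligible.track_id) == [0]
        reasons = dict(zip(excluded.track_id, excluded.reason))
        assert reasons == {1: "dead_at_t0", 2: "not_1_1", 3: "not_1_1"}

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 5000))
    def test_bookkeeping_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        census = self._census(
            [(i, rng.integers(0, 3), rng.integers(0, 3), rng.integers(0, 2)) for i in range(n)]
        )
        eligible, excluded = select_eligible(census)
        assert len(eligible) + len(excluded) == n
        assert set(eligible.track_id) | set(excluded.track_id) == set(census.track_id)
        assert set(eligible.track_id).isdisjoint(excluded.track_id)


class TestKillerFraction:
    def _events(self, pairs):
        return pd.DataFrame(pairs, columns=["track_id", "cell_type", "death_time"])

    def test_simple_fraction(self):
        eligible = pd.DataFrame({"track_id": range(10), "k_effector": 1, "k_target": 1,
                                 "dead_at_t0": 0})
        events = self._events([(0, "target", 2), (5, "target", 7)])
        frac, kills, n = killer_fraction(eligible, events)
        assert (frac, kills, n) == (0.2, 2, 10)

    def test_effector_deaths_not_counted(self):
        eligible = pd.DataFrame({"track_id": range(4), "k_effector": 1, "k_target": 1,
                                 "dead_at_t0": 0})
        events = self._events([(0, "effector", 2)])
        assert killer_fraction(eligible, events)[0] == 0.0

    def test_empty_eligible_raises(self):
        with pytest.raises(ValueError):
            killer_fraction(pd.DataFrame(columns=["track_id"]), self._events([]))

    def test_invariant_to_droplet_ordering(self, rng):
        ids = rng.permutation(50)
        eligible = pd.DataFrame({"track_id": ids})
        events = self._events([(int(i), "target", 1) for i in ids[:13]])
        f1 = killer_fraction(eligible, events)[0]
        f2 = killer_fraction(eligible.iloc[::-1].reset_index(drop=True), events)[0]
        assert f1 == f2 == 13 / 50


class TestKineticsHistogram:
    def _events(self, times):
        return pd.DataFrame(
            [(i, "target", t) for i, t in enumerate(times)],
            columns=["track_id", "cell_type", "death_time"],
        )

    def test_fast_fraction_example(self):
        hist, fast, slow = kinetics_histogram(self._events([1, 1, 2, 5]), 11, t_fast=4)
        assert fast == 0.75 and slow == 0.25
        assert hist.tolist() == [0, 2, 1, 0, 0, 1, 0, 0, 0, 0, 0]
        assert hist.sum() == 4

    def test_all_fast(self):
        _, fast, _ = kinetics_histogram(self._events([1, 2, 3]), 11, t_fast=4)
        assert fast == 1.0

    def test_zero_events_undefined_not_zero(self):
        hist, fast, slow = kinetics_histogram(self._events([]), 11)
        assert hist.sum() == 0 and fast is None and slow is None

    def test_fast_fraction_monotone_in_t_fast(self, rng):
        times = rng.integers(0, 11, 200)
        fracs = [kinetics_histogram(self._events(times), 11, t_fast=t)[1] for t in range(11)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == 1.0


class TestSerialKillers:
    def _census(self, rows):
        return pd.DataFrame(rows, columns=["track_id", "k_effector", "k_target"])

    def _events(self, rows):
        return pd.DataFrame(rows, columns=["track_id", "cell_type", "death_time"])

    def test_one_effector_two_kills_flagged(self):
        census = self._census([(0, 1, 2)])
        events = self._events([(0, "target", 2), (0, "target", 5)])
        out = detect_serial_killers(census, events)
        assert len(out) == 1
        assert out.iloc[0].n_kills == 2 and out.iloc[0].kill_times == [2, 5]

    def test_single_kill_not_serial(self):
        out = detect_serial_killers(
            self._census([(0, 1, 2)]), self._events([(0, "target", 2)])
        )
        assert len(out) == 0

    def test_two_effectors_never_qualify(self):
        out = detect_serial_killers(
            self._census([(0, 2, 2)]),
            self._events([(0, "target", 1), (0, "target", 2)]),
        )
        assert len(out) == 0

    def test_generator_certain_killing_flags_all_1_to_2(self):
        from droptox import generate_experiment, GeneratorConfig, sample_fates

        cfg = GeneratorConfig(n_tiles=2, n_timepoints=6, seed=55, killer_prob=1.0,
                              dead_at_t0_prob=0.0)
        _, truth = generate_experiment(cfg)
        occ = truth.occupancy()
        census = occ.rename(columns={"droplet_id": "track_id"})[
            ["track_id", "k_effector", "k_target"]
        ]
        events = truth.cells.dropna(subset=["death_time"]).rename(
            columns={"droplet_id": "track_id"}
        )[["track_id", "cell_type", "death_time"]]
        expected = census[(census.k_effector == 1) & (census.k_target >= 2)]
        out = detect_serial_killers(census, events)
        assert set(out.track_id) == set(expected.track_id)


class TestControlViability:
    def _stratum(self, rows):
        return pd.DataFrame(rows, columns=["track_id", "k_target"])

    def test_no_deaths_flat_zero(self):
        curve = control_viability(
            self._stratum([(0, 1), (1, 2)]),
            pd.DataFrame(columns=["track_id", "cell_type", "death_time"]),
            11,
        )
        assert np.allclose(curve, 0.0)

    def test_single_death_steps_at_hour_nine(self):
        events = pd.DataFrame(
            [(0, "target", 9)], columns=["track_id", "cell_type", "death_time"]
        )
        curve = control_viability(self._stratum([(0, 1)]), events, 11)
        assert curve.tolist() == [0.0] * 9 + [1.0, 1.0]

    def test_empty_stratum_is_missing(self):
        assert control_viability(self._stratum([]), pd.DataFrame(), 11) is None

    def test_recovers_spontaneous_rate(self):
        """Fates sampled at rate r in effector-free droplets give a final
        control fraction within 3 binomial SE of r."""
        from droptox import default_death_time_dist, sample_fates

        n, r = 3000, 0.05
        cells = pd.DataFrame(
            {
                "cell_id": range(n),
                "droplet_id": range(n),
                "cell_type": "target",
            }
        )
        events = sample_fates(
            cells, 0.0, default_death_time_dist(11), seed=8, spontaneous_target_rate=r
        ).rename(columns={"droplet_id": "track_id"})
        stratum = self._stratum([(i, 1) for i in range(n)])
        curve = control_viability(stratum, events, 11)
        se = math.sqrt(r * (1 - r) / n)
        assert abs(curve[-1] - r) < 3 * se
        assert all(a <= b for a, b in zip(curve, curve[1:]))  # cumulative
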