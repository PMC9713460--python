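"""Demographic calibration and the daily population model."""

import numpy as np
import pytest

from gdsim import (
    GENOTYPES,
    CalibrationError,
    DriveParams,
    LifecycleParams,
    PopulationState,
    ReleaseSchedule,
    Trajectory,
    build_cube,
    calibrate_equilibrium,
    effector_coverage,
    mendelian_cube,
    scenario_substitute,
    simulate,
    summary_metrics,
)

NG = len(GENOTYPES)


def hardy_weinberg_state(calibration, freqs):
    """Spread the wild-type equilibrium across genotypes at HW proportions."""
    q = np.asarray(freqs, dtype=float)
    p = np.zeros(NG)
    for i, g in enumerate(GENOTYPES):
        a, b = g[0], g[1]
        ia, ib = "WHR".index(a), "WHR".index(b)
        p[i] = q[ia] * q[ib] * (1 if a == b else 2)
    s = calibration.state0
    return PopulationState(
        eggs=np.outer(s.eggs.sum(axis=1), p),
        larvae=np.outer(s.larvae.sum(axis=1), p),
        pupae=s.pupae.sum(axis=2)[..., None] * p,
        males=s.males.sum() * p,
        mated=s.mated.sum() * np.outer(p, p),
        unmated=np.zeros(NG),
    )


class TestCalibration:
    def test_default_equilibrium_holds_for_a_year(self, lifecycle, calibration):
        traj = simulate(
            mendelian_cube(), lifecycle, ReleaseSchedule(), DriveParams(),
            days=365, mode="deterministic", calibration=calibration,
        )[0]
        adults = traj.females.sum(axis=1) + traj.males.sum(axis=1)
        assert np.all(adults >= 0.98 * lifecycle.N_eq)
        assert np.all(adults <= 1.02 * lifecycle.N_eq)

    def test_lethal_adult_mortality_uncalibratable(self):
        with pytest.raises(CalibrationError):
            calibrate_equilibrium(LifecycleParams(muAD=1.0))

    def test_no_surplus_growth_uncalibratable(self):
        with pytest.raises(CalibrationError):
            calibrate_equilibrium(LifecycleParams(popGrowth=0.9))

    def test_gamma_absorbs_fecundity(self):
        lc1 = LifecycleParams()
        lc2 = LifecycleParams(betaK=2 * lc1.betaK)
        for lc in (lc1, lc2):
            cal = calibrate_equilibrium(lc)
            traj = simulate(
                mendelian_cube(), lc, ReleaseSchedule(), DriveParams(),
                days=200, mode="deterministic", calibration=cal,
            )[0]
            adults = traj.females.sum(axis=1) + traj.males.sum(axis=1)
            assert adults[-1] == pytest.approx(lc.N_eq, rel=1e-6)

    def test_random_parameter_sets_hold_equilibrium(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            lc = LifecycleParams(
                tEgg=int(rng.integers(2, 7)),
                tLarva=int(rng.integers(4, 10)),
                tPupa=int(rng.integers(1, 4)),
                betaK=float(rng.uniform(15, 40)),
                muAD=float(rng.uniform(0.06, 0.25)),
                popGrowth=float(rng.uniform(1.05, 1.6)),
                N_eq=float(rng.uniform(5_000, 20_000)),
            )
            cal = calibrate_equilibrium(lc)
            traj = simulate(
                mendelian_cube(), lc, ReleaseSchedule(), DriveParams(),
                days=365, mode="deterministic", calibration=cal,
            )[0]
            adults = traj.females.sum(axis=1) + traj.males.sum(axis=1)
            assert np.all(np.abs(adults / lc.N_eq - 1) <= 0.02)


class TestSimulate:
    def test_neutral_mendelian_allele_frequencies_constant(self, lifecycle, calibration):
        init = hardy_weinberg_state(calibration, (0.6, 0.3, 0.1))
        traj = simulate(
            mendelian_cube(), lifecycle, ReleaseSchedule(), DriveParams(),
            days=200, mode="deterministic", calibration=calibration,
            initial_state=init,
        )[0]
        adults = traj.females + traj.males
        totals = 2 * adults.sum(axis=1)
        h_copies = np.array([g.count("H") for g in GENOTYPES])
        r_copies = np.array([g.count("R") for g in GENOTYPES])
        h_freq = adults @ h_copies / totals
        r_freq = adults @ r_copies / totals
        assert np.all(np.abs(h_freq - 0.3) < 1e-9)
        assert np.all(np.abs(r_freq - 0.1) < 1e-9)

    def test_perfect_drive_fixes_monotonically(self, lifecycle, calibration):
        params = DriveParams(cF=1.0, chF=1.0, cM=1.0, chM=1.0)
        cube = build_cube(params)
        rel = ReleaseSchedule.single_male_release(day=25, count=2000)
        traj = simulate(
            cube, lifecycle, rel, params, days=900,
            mode="deterministic", calibration=calibration,
        )[0]
        adults = traj.females + traj.males
        h_copies = np.array([g.count("H") for g in GENOTYPES])
        h_freq = (adults @ h_copies) / (2 * adults.sum(axis=1))
        # the release pulse itself decays while its offspring are still
        # aquatic, so monotone growth starts once the first drive cohort
        # has emerged (release day + egg/larva/pupa durations + slack)
        post = slice(60, None)
        assert np.all(np.diff(h_freq[post]) >= -1e-9)
        assert h_freq[-1] > 0.99
        ww = adults[:, GENOTYPES.index("WW")]
        assert ww[-1] < 1.0

    def test_equal_seeds_reproduce_trajectories(self, lifecycle, zpg_params, calibration):
        cube = build_cube(zpg_params)
        rel = ReleaseSchedule.single_male_release()
        kw = dict(days=60, reps=2, seed=77, calibration=calibration)
        a = simulate(cube, lifecycle, rel, zpg_params, **kw)
        b = simulate(cube, lifecycle, rel, zpg_params, **kw)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.females, tb.females)
            assert np.array_equal(ta.males, tb.males)
        assert not np.array_equal(a[0].females, a[1].females)  # reps independent

    def test_stochastic_counts_are_nonnegative_integers(self, lifecycle, nos_params,
                                                        calibration):
        cube = build_cube(nos_params)
        rel = ReleaseSchedule.single_male_release()
        traj = simulate(cube, lifecycle, rel, nos_params, days=90, reps=1,
                        seed=3, calibration=calibration)[0]
        for arr in (traj.females, traj.males):
            assert np.all(arr >= 0)
            assert np.all(arr == np.rint(arr))

    def test_trajectory_long_format(self, lifecycle, calibration):
        traj = simulate(
            mendelian_cube(), lifecycle, ReleaseSchedule(), DriveParams(),
            days=3, mode="deterministic", calibration=calibration,
        )[0]
        df = traj.to_dataframe()
        assert list(df.columns) == ["rep", "sex", "day", "genotype", "count"]
        assert len(df) == 3 * 2 * NG
        assert sorted(df["day"].unique()) == [1, 2, 3]


class TestMetrics:
    @staticmethod
    def toy_trajectory(females, males=None, release_day=None):
        females = np.asarray(females, dtype=float)
        days = np.arange(1, len(females) + 1)
        if males is None:
            males = np.zeros_like(females)
        h_copies = np.array([g.count("H") for g in GENOTYPES])
        h = (females + males) @ h_copies
        return Trajectory(rep_id=0, seed=None, release_day=release_day, days=days,
                          females=females, males=np.asarray(males, dtype=float),
                          h_total=h, aquatic_total=np.zeros(len(days)))

    def test_effector_coverage_fraction(self):
        row = np.zeros(NG)
        row[GENOTYPES.index("WW")] = 50
        row[GENOTYPES.index("WH")] = 30
        row[GENOTYPES.index("HR")] = 20
        traj = self.toy_trajectory([row])
        assert effector_coverage(traj)[0] == pytest.approx(0.5)

    def test_coverage_edge_cases(self):
        all_ww = np.zeros(NG); all_ww[GENOTYPES.index("WW")] = 10
        all_hh = np.zeros(NG); all_hh[GENOTYPES.index("HH")] = 10
        none = np.zeros(NG)
        traj = self.toy_trajectory([all_ww, all_hh, none])
        assert list(effector_coverage(traj)) == [0.0, 1.0, 0.0]

    def test_absent_events_reported_as_none(self):
        row = np.zeros(NG)
        row[GENOTYPES.index("WW")] = 10
        m = summary_metrics([self.toy_trajectory([row, row])])
        rep = m["per_rep"][0]
        assert rep["day_WW_eliminated"] is None
        assert rep["day_H_eliminated"] is None  # drive never present
        assert rep["day_coverage_below_half"] is None  # coverage never positive

    def test_days_post_release_and_elimination(self):
        ww = np.zeros(NG); ww[GENOTYPES.index("WW")] = 10
        hh = np.zeros(NG); hh[GENOTYPES.index("HH")] = 10
        rr = np.zeros(NG); rr[GENOTYPES.index("RR")] = 10
        traj = self.toy_trajectory([ww, ww, hh, hh, rr], release_day=2)
        m = summary_metrics([traj])["per_rep"][0]
        assert m["day_WW_eliminated"] == 1   # day 3, one day post-release
        assert m["peak_coverage"] == 1.0
        assert m["day_H_eliminated"] == 3    # day 5
        assert m["final_allele_freq"]["R"] == pytest.approx(1.0)

    def test_stored_sperm_counts_toward_drive_presence(self, lifecycle, calibration):
        # a female mated to an HH male keeps the drive "present" even with
        # no living H-carrying individual
        state = calibration.state0.copy()
        state.mated = np.zeros((NG, NG))
        state.mated[GENOTYPES.index("WW"), GENOTYPES.index("HH")] = 100.0
        assert state.h_allele_total() > 0


class TestScenarioSubstitute:
    def test_single_override_leaves_rest_identical(self, nos_params, lifecycle):
        base = {"drive": nos_params, "lifecycle": lifecycle}
        out = scenario_substitute(base, {"dF": 0.14})
        assert out["drive"].dF == 0.14
        assert out["drive"].evolve(dF=nos_params.dF) == nos_params
        assert out["lifecycle"] == lifecycle

    def test_empty_overrides_copy_equal(self, nos_params, lifecycle):
        base = {"drive": nos_params, "lifecycle": lifecycle}
        out = scenario_substitute(base, {})
        assert out["drive"] == nos_params and out["lifecycle"] == lifecycle
        assert out is not base

    def test_unknown_key_rejected(self, nos_params, lifecycle):
        with pytest.raises(KeyError):
            scenario_substitute({"drive": nos_params, "lifecycle": lifecycle},
                                {"nonsense": 1.0})

    def test_hybrid_config_matches_hand_built(self, nos_params, zpg_params, lifecycle):
        overrides = {
            "crF": zpg_params.crF, "chF": zpg_params.chF,
            "crM": zpg_params.crM, "chM": zpg_params.chM,
            "dF": zpg_params.dF, "xiF": zpg_params.xiF, "xiM": zpg_params.xiM,
        }
        hybrid = scenario_substitute(
            {"drive": nos_params, "lifecycle": lifecycle}, overrides
        )["drive"]
        hand_built = nos_params.evolve(**overrides)
        assert hybrid == hand_built
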