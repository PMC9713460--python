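"""Estimation of cutting/homing/resistance, deposition, and lifecycle params."""

import numpy as np
import pandas as pd
import pytest

from gdsim import (
    DriveParams,
    EstimationError,
    PoolObservation,
    PooledCrossCounts,
    TransHetAssay,
    TransHetReplicate,
    derive_lifecycle,
    estimate_cut_params,
    estimate_deposition,
    pooled_counts_from_table,
)
from gdsim.datasets import load_fitness_defaults


def make_counts(pools, line="L", sex="M"):
    return PooledCrossCounts(line=line, parent_sex=sex, pools=tuple(pools))


class TestCutParamsTableMethod:
    def test_nos_male_pools(self, pool_table):
        """Low/high pool arithmetic: 55.3% of 228 and 86.4% of 214 marker-positive,
        9/54 and 7/27 of the marker-negatives carrying indels."""
        counts = pooled_counts_from_table(pool_table, "AeaNosC109", "M")
        est = estimate_cut_params(counts)
        # oracle: P = 126+185 = 311; G = 102*(9/54) + 29*(7/27) = 24.5185; N = 442
        assert est.n_marker_positive == 311
        assert est.gdbi_estimate == pytest.approx(24.5185185, abs=1e-6)
        assert est.c == pytest.approx(335.5185185 / 442, abs=1e-9)
        assert est.ch == pytest.approx(311 / 335.5185185, abs=1e-9)
        assert round(est.c, 3) == 0.759
        assert round(est.ch, 3) == 0.927
        assert round(est.cr, 3) == 0.073

    def test_zpg_male_pools_zero_indel_branch(self, pool_table):
        counts = pooled_counts_from_table(pool_table, "AeaZpgC109", "M")
        est = estimate_cut_params(counts)
        assert est.n_marker_positive == 131 + 135
        assert est.gdbi_estimate == 0.0
        assert est.c == pytest.approx(266 / 460, abs=1e-12)
        assert est.ch == 1.0 and est.cr == 0.0

    def test_single_mendelian_looking_pool(self):
        counts = make_counts([PoolObservation("low", 100, marker_rate=0.5)])
        est = estimate_cut_params(counts)
        assert est.c == pytest.approx(0.5)
        assert est.ch == 1.0

    def test_invariant_to_splitting_a_pool(self):
        whole = make_counts(
            [PoolObservation("low", 200, marker_positive=120, gdbi_tested=40, gdbi_positive=8)]
        )
        split = make_counts(
            [
                PoolObservation("a", 100, marker_positive=60, gdbi_tested=20, gdbi_positive=4),
                PoolObservation("b", 100, marker_positive=60, gdbi_tested=20, gdbi_positive=4),
            ]
        )
        e1, e2 = estimate_cut_params(whole), estimate_cut_params(split)
        assert e1.c == pytest.approx(e2.c, abs=1e-12)
        assert e1.ch == pytest.approx(e2.ch, abs=1e-12)

    def test_untested_pool_falls_back_to_pooled_fraction(self):
        counts = make_counts(
            [
                PoolObservation("low", 100, marker_positive=60, gdbi_tested=20, gdbi_positive=5),
                PoolObservation("high", 100, marker_positive=80, gdbi_tested=0),
            ]
        )
        est = estimate_cut_params(counts)
        # pool 1: 40 * 5/20 = 10; pool 2 falls back to 5/20 on its 20 negatives
        assert est.gdbi_estimate == pytest.approx(10 + 20 * 0.25)

    def test_all_zero_counts_rejected(self):
        counts = make_counts([PoolObservation("low", 50, marker_positive=0)])
        with pytest.raises(EstimationError):
            estimate_cut_params(counts)

    def test_no_assessed_offspring_rejected(self):
        with pytest.raises(EstimationError):
            estimate_cut_params(make_counts([PoolObservation("low", 0, marker_positive=0)]))


class TestCutParamsCubeMethod:
    def test_inverts_cube_expectations_exactly(self):
        # under the cube, WH transmits the marker at (1+c*ch)/2 and R at c*cr/2
        c_true, ch_true = 0.76, 0.93
        n = 200_000
        pos = int(round(n * 0.5 * (1 + c_true * ch_true)))
        r_carriers = int(round(n * 0.5 * c_true * (1 - ch_true)))
        counts = make_counts(
            [
                PoolObservation(
                    "all", n, marker_positive=pos,
                    gdbi_tested=n - pos, gdbi_positive=r_carriers,
                )
            ]
        )
        est = estimate_cut_params(counts, method="cube")
        assert est.c == pytest.approx(c_true, abs=1e-4)
        assert est.ch == pytest.approx(ch_true, abs=1e-4)

    def test_table_method_overstates_cutting_relative_to_cube(self):
        counts = make_counts([PoolObservation("all", 1000, marker_positive=850,
                                              gdbi_tested=150, gdbi_positive=27)])
        table = estimate_cut_params(counts, method="table")
        cube = estimate_cut_params(counts, method="cube")
        assert table.c > cube.c


class TestDeposition:
    def test_uniform_replicates(self):
        assay = TransHetAssay(
            "L",
            tuple(
                TransHetReplicate("eCFP", 100, n_active_carb109=19) for _ in range(3)
            ),
        )
        assert estimate_deposition(assay).dF == pytest.approx(0.19)

    def test_mean_of_per_replicate_fractions(self):
        assay = TransHetAssay(
            "L",
            (
                TransHetReplicate("eCFP", 10, n_active_carb109=2),
                TransHetReplicate("eCFP", 10, n_active_carb109=4),
                TransHetReplicate("eCFP", 10, n_active_carb109=3),
                TransHetReplicate("mCherry", 10, n_active_carb109=9),
            ),
        )
        est = estimate_deposition(assay)
        assert est.dF == pytest.approx(0.30)
        assert est.dhF == 0.0 and est.drF == 1.0
        assert est.n_replicates == 3  # mCherry class excluded

    def test_zero_activity(self):
        assay = TransHetAssay("L", (TransHetReplicate("eCFP", 50),))
        assert estimate_deposition(assay).dF == 0.0

    def test_requires_ecfp_replicates(self):
        assay = TransHetAssay("L", (TransHetReplicate("mCherry", 50),))
        with pytest.raises(EstimationError):
            estimate_deposition(assay)


class TestLifecycleDerivation:
    def test_betak_from_fecundity(self):
        fitness = pd.DataFrame(
            {
                "line": ["WT", "GD"],
                "fecundity_mean": [75.0, 70.0],
                "larval_viability": [0.80, 0.80],
                "larva_to_pupa_days": [6.4, 6.6],
            }
        )
        out = derive_lifecycle(fitness, "GD", "WT")
        assert out["betaK"] == pytest.approx(75 * 4 / 11)
        assert out["betaK"] == pytest.approx(27.27, abs=5e-3)
        assert out["tLarva"] == 6
        assert out["xiF"] == 1.0  # no viability cost
        assert out["fertility_mult"] == 0.9

    def test_significant_viability_deficit_sets_xi(self):
        fitness = pd.DataFrame(
            {
                "line": ["WT", "GD"],
                "fecundity_mean": [75.0, 70.0],
                "larval_viability": [0.80, 0.70],
                "larva_to_pupa_days": [6.0, 6.0],
            }
        )
        out = derive_lifecycle(fitness, "GD", "WT", viability_significant=True)
        assert out["xiF"] == pytest.approx(0.90)
        assert out["xiM"] == pytest.approx(0.90)
        # the same deficit without significance keeps the modifier off
        out = derive_lifecycle(fitness, "GD", "WT", viability_significant=False)
        assert out["xiF"] == 1.0

    def test_bundled_defaults(self):
        fitness = load_fitness_defaults()
        nos = derive_lifecycle(fitness, "AeaNosC109")
        zpg = derive_lifecycle(fitness, "AeaZpgC109")
        assert nos["xiF"] == pytest.approx(0.90)
        assert zpg["xiF"] == 1.0
        assert nos["betaK"] == pytest.approx(27.2727, abs=1e-3)

    def test_missing_reference_rejected(self):
        fitness = pd.DataFrame(
            {"line": ["GD"], "fecundity_mean": [70.0],
             "larval_viability": [0.7], "larva_to_pupa_days": [6.0]}
        )
        with pytest.raises(EstimationError):
            derive_lifecycle(fitness, "GD", "HWE")


class TestValidation:
    def test_gdbi_positive_bounded_by_tested(self):
        with pytest.raises(EstimationError):
            PoolObservation("low", 10, marker_rate=0.5, gdbi_tested=2, gdbi_positive=3)

    def test_missing_line_in_table(self, pool_table):
        with pytest.raises(EstimationError):
            pooled_counts_from_table(pool_table, "NoSuchLine", "M")
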