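"""Run-matrix orchestration, comparison tables and ordering checks."""

import numpy as np
import pandas as pd
import pytest

import cochlearbox as cb
from cochlearbox.experiments import (
    ordering_checks,
    pathology_decrement,
    pathway_advantage,
    records_to_frame,
    run_matrix,
    write_matrix_outputs,
)
from cochlearbox.metrics import (
    IMPEDANCE_PLAUSIBILITY_BAND,
    METF_PLAUSIBILITY_BAND_DB,
    greenwood_reference,
)


class TestMatrixStructure:
    def test_sixty_cells(self, matrix_records):
        assert len(matrix_records) == 60
        keys = {(r.scenario.name, r.pathway, r.frequency) for r in matrix_records}
        assert len(keys) == 60

    def test_normal_forward_is_zero_reference(self, matrix_frame):
        ref = matrix_frame.query("scenario == 'normal' and pathway == 'forward'")
        assert np.allclose(ref.rel_amp_db, 0.0, atol=1e-9)

    def test_rerun_is_bitwise_identical(self, geometry, materials, matrix_frame):
        again = records_to_frame(run_matrix(geometry, materials))
        pd.testing.assert_frame_equal(matrix_frame, again, check_exact=True)

    def test_incomplete_matrix_rejected(self, geometry, materials):
        partial = run_matrix(geometry, materials, pathways=("forward",))
        with pytest.raises(ValueError, match="incomplete|pathways"):
            pathway_advantage(partial)


class TestPathwayAdvantage:
    def test_normal_reverse_exceeds_forward_by_5_db(self, matrix_records):
        adv = pathway_advantage(matrix_records)
        normal = adv.query("scenario == 'normal'")
        assert (normal.advantage_db > 5.0).all()

    def test_antisymmetry(self, matrix_frame, matrix_records):
        adv = pathway_advantage(matrix_records).set_index(["scenario", "frequency_hz"])
        piv = matrix_frame.pivot_table(
            index=["scenario", "frequency_hz"], columns="pathway",
            values="max_disp_db_re_1m",
        )
        fwd_minus_rev = piv["forward"] - piv["reverse"]
        assert np.allclose(adv.advantage_db, -fwd_minus_rev, atol=1e-12)

    def test_exception_scenario_is_flagged_or_clean(self, matrix_records):
        adv = pathway_advantage(matrix_records)
        flagged = set(adv.loc[adv.violates, "scenario"])
        assert flagged <= {"rwm_ossified"}


class TestPathologyDecrement:
    def test_normal_forward_zero(self, matrix_records):
        dec = pathology_decrement(matrix_records)
        base = dec.query("scenario == 'normal' and pathway == 'forward'")
        assert np.allclose(base.decrement_db, 0.0, atol=1e-9)

    def test_stage_monotone_for_sal(self, matrix_records):
        dec = pathology_decrement(matrix_records).set_index(
            ["scenario", "pathway", "frequency_hz"]
        )["decrement_db"]
        for f in (125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0):
            assert dec[("sal_ossified", "forward", f)] >= dec[("sal_x100", "forward", f)]

    def test_low_frequency_emphasis_for_sal_x100(self, matrix_records):
        dec = pathology_decrement(matrix_records).set_index(
            ["scenario", "pathway", "frequency_hz"]
        )["decrement_db"]
        assert dec[("sal_x100", "forward", 125.0)] >= dec[("sal_x100", "forward", 4000.0)]

    def test_sal_ossified_forward_loss_everywhere_and_worst_at_low_freq(self, matrix_frame):
        sub = matrix_frame.query("scenario == 'sal_ossified' and pathway == 'forward'")
        assert (sub.rel_amp_db < 0).all()
        worst = sub.loc[sub.rel_amp_db.idxmin(), "frequency_hz"]
        assert worst in (125.0, 250.0, 500.0)

    def test_all_ordering_checks_pass(self, matrix_records):
        assert all(ordering_checks(matrix_records).values())


class TestCfStability:
    def test_cf_shift_under_0_02_across_all_cells(self, matrix_frame):
        ref = matrix_frame.query(
            "scenario == 'normal' and pathway == 'forward'"
        ).set_index("frequency_hz").cf_location
        joined = matrix_frame.join(ref, on="frequency_hz", rsuffix="_ref")
        assert (joined.cf_location - joined.cf_location_ref).abs().max() < 0.02

    def test_cf_map_within_factor_2_of_greenwood(self, matrix_frame):
        normal = matrix_frame.query("scenario == 'normal'")
        for _, row in normal.iterrows():
            f_gw = greenwood_reference(row.cf_location)
            assert 0.5 <= row.frequency_hz / f_gw <= 2.0


class TestPlausibilityBands:
    def test_metf_in_band(self, matrix_frame):
        vals = matrix_frame.query("scenario == 'normal' and pathway == 'forward'").metf_db
        lo, hi = METF_PLAUSIBILITY_BAND_DB
        assert vals.between(lo, hi).all()

    def test_impedance_magnitudes_in_band(self, matrix_frame):
        lo, hi = IMPEDANCE_PLAUSIBILITY_BAND
        normal = matrix_frame.query("scenario == 'normal'")
        zc = normal.z_c_abs.dropna()
        zr = normal.z_me_r_abs.dropna()
        assert zc.between(lo, hi).all() and zr.between(lo, hi).all()

    def test_volume_ratio_near_unity(self, matrix_frame):
        fwd = matrix_frame.query("scenario == 'normal' and pathway == 'forward'")
        assert ((fwd.vol_ratio - 1).abs() < 0.25).all()


class TestOutputs:
    def test_write_matrix_outputs(self, matrix_records, tmp_path):
        write_matrix_outputs(matrix_records, tmp_path)
        records = pd.read_csv(tmp_path / "records.csv")
        assert len(records) == 60
        assert {"scenario", "pathway", "frequency_hz", "rel_amp_db"} <= set(records.columns)
        assert (tmp_path / "pathway_advantage.csv").exists()
        assert (tmp_path / "pathology_decrement.csv").exists()


class TestCli:
    def test_calibrate_prints_stimulus_table(self):
        from click.testing import CliRunner

        from cochlearbox.cli import main

        result = CliRunner().invoke(main, ["calibrate"])
        assert result.exit_code == 0
        assert "86.00 dB SPL" in result.output
        assert "92.92 dB SPL" in result.output

    def test_run_matrix_single_cell(self, tmp_path):
        from click.testing import CliRunner

        from cochlearbox.cli import main

        result = CliRunner().invoke(
            main,
            ["run-matrix", "--out", str(tmp_path), "--scenario", "normal",
             "--pathway", "forward", "--freq", "1000"],
        )
        assert result.exit_code == 0, result.output
        df = pd.read_csv(tmp_path / "records.csv")
        assert len(df) == 1
        assert (tmp_path / "resolved_config.yaml").exists()
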