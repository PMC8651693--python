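"""Filtering, loess normalization and two-regime imputation."""

import numpy as np
import pandas as pd
import pytest

from subcellflow.core import QuantTable, SampleDesign
from subcellflow.preprocess import (cyclic_loess_normalize, filter_min_valid,
                                    impute_absent, impute_partial, preprocess)
from subcellflow.simulate import generate_truth, simulate_intensities

from conftest import make_table


@pytest.fixture
def one_fraction_design():
    return SampleDesign.from_layout(1, ("control", "stimulated"), 4)


def _group_cols(design, condition):
    return list(design.samples_for(fraction=1, condition=condition))


class TestFilterMinValid:
    def test_three_of_four_in_one_group_retained(self, one_fraction_design):
        ctl = _group_cols(one_fraction_design, "control")
        table = make_table(
            {"A": {ctl[0]: 20.0, ctl[1]: 20.1, ctl[2]: 19.9}}, one_fraction_design
        )
        out = filter_min_valid(table, min_valid=3)
        assert list(out.features) == ["A"]
        assert bool(out.retained.loc["A", 1])

    def test_two_everywhere_removed(self, one_fraction_design):
        ctl = _group_cols(one_fraction_design, "control")
        stim = _group_cols(one_fraction_design, "stimulated")
        table = make_table(
            {"A": {ctl[0]: 20.0, ctl[1]: 20.1, stim[0]: 20.0, stim[1]: 20.2}},
            one_fraction_design,
        )
        out = filter_min_valid(table, min_valid=3)
        assert len(out.features) == 0

    def test_min_valid_one_keeps_any_observation(self, one_fraction_design):
        ctl = _group_cols(one_fraction_design, "control")
        table = make_table({"A": {ctl[0]: 20.0}}, one_fraction_design)
        out = filter_min_valid(table, min_valid=1)
        assert list(out.features) == ["A"]

    def test_threshold_above_group_size_rejected(self, one_fraction_design):
        ctl = _group_cols(one_fraction_design, "control")
        table = make_table({"A": {ctl[0]: 20.0}}, one_fraction_design)
        with pytest.raises(ValueError, match="group size"):
            filter_min_valid(table, min_valid=5)

    def test_retention_is_per_fraction(self):
        """A feature valid only in FR1 keeps its FR1 block and loses FR2."""
        design = SampleDesign.from_layout(2, ("control",), 4)
        fr1 = list(design.samples_for(fraction=1))
        fr2 = list(design.samples_for(fraction=2))
        values = {s: 20.0 for s in fr1[:3]}
        values[fr2[0]] = 18.0  # a single stray observation in FR2
        table = make_table({"A": values}, design)
        out = filter_min_valid(table, min_valid=3)
        assert bool(out.retained.loc["A", 1]) and not bool(out.retained.loc["A", 2])
        assert out.values.loc["A", fr2].isna().all()


def _big_single_fraction(n=200, seed=0, conditions=("control",), reps=4):
    design = SampleDesign.from_layout(1, conditions, reps)
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.uniform(18, 30, size=(n, len(design.samples))),
        index=[f"P{i}" for i in range(n)],
        columns=design.samples,
    )
    return QuantTable(values, design), design


class TestLoess:
    def test_identical_samples_unchanged(self):
        table, design = _big_single_fraction(reps=2, conditions=("control",))
        table.values.iloc[:, 1] = table.values.iloc[:, 0]
        out = cyclic_loess_normalize(table)
        np.testing.assert_allclose(out.values, table.values, atol=1e-9)

    def test_constant_offset_removed(self):
        table, design = _big_single_fraction(reps=2)
        s0, s1 = table.values.columns[:2]
        table.values[s1] = table.values[s0] + 0.8
        out = cyclic_loess_normalize(table)
        diff = out.values[s1] - out.values[s0]
        assert abs(diff.mean()) < 1e-3

    def test_intensity_trend_flattened(self):
        table, design = _big_single_fraction(reps=2)
        s0, s1 = table.values.columns[:2]
        mean0 = table.values[s0]
        table.values[s1] = mean0 + 0.05 * (mean0 - mean0.mean())
        out = cyclic_loess_normalize(table)
        diff = (out.values[s1] - out.values[s0]).to_numpy()
        avg = ((out.values[s1] + out.values[s0]) / 2).to_numpy()
        slope = np.polyfit(avg, diff, 1)[0]
        assert abs(slope) < 0.01

    def test_missing_cells_stay_missing(self):
        table, _ = _big_single_fraction()
        table.values.iloc[0, 0] = np.nan
        out = cyclic_loess_normalize(table)
        assert np.isnan(out.values.iloc[0, 0])

    def test_few_complete_rows_falls_back_to_median(self):
        design = SampleDesign.from_layout(1, ("control",), 2)
        cols = list(design.samples)
        values = {f"P{i}": {cols[0]: 20.0 + i, cols[1]: 21.0 + i} for i in range(5)}
        table = make_table(values, design)
        with pytest.warns(UserWarning, match="median centering"):
            cyclic_loess_normalize(table)


class TestImputePartial:
    def test_no_missing_is_identity(self):
        table, _ = _big_single_fraction()
        out = impute_partial(table)
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_clone_neighbor_recovers_deleted_cell(self, one_fraction_design):
        ctl = _group_cols(one_fraction_design, "control")
        stim = _group_cols(one_fraction_design, "stimulated")
        base = {s: 20.0 + i * 0.1 for i, s in enumerate(ctl + stim)}
        hole = dict(base)
        hole[ctl[3]] = np.nan
        decoys = {
            f"D{i}": {s: 25.0 + i + j * 0.05 for j, s in enumerate(ctl + stim)}
            for i in range(5)
        }
        table = make_table({"orig": base, "copy": hole, **decoys},
                           one_fraction_design)
        out = impute_partial(table, k_neighbors=1)
        assert out.values.loc["copy", ctl[3]] == pytest.approx(base[ctl[3]])

    def test_mcar_rmse_below_twice_noise(self, design_two_conditions):
        """Simulated 5% MCAR at noise sd 0.3: imputation error < 0.6."""
        truth = generate_truth(800, frac_translocating=0.0, seed=21,
                               mcar_rate=0.05, mnar_slope=0.0,
                               mnar_midpoint=-1e3)
        table = simulate_intensities(truth, design_two_conditions, 0.3, seed=21)
        rng = np.random.default_rng(21)
        mask = table.values.notna() & (
            rng.uniform(size=table.values.shape) < 0.05
        )
        holed = table.values.where(~mask)
        holey = QuantTable(holed, design_two_conditions)
        holey = filter_min_valid(holey, min_valid=3)
        out = impute_partial(holey, k_neighbors=10)
        mask = mask.loc[out.features]
        imputed = out.values[mask].stack()
        truth_vals = table.values.loc[out.features][mask].stack()
        filled = imputed.dropna()
        err = (filled - truth_vals[filled.index]).to_numpy()
        assert len(err) > 500
        rmse = np.sqrt((err ** 2).mean())
        assert rmse < 0.6

    def test_mnar_groups_left_for_quantile_step(self, one_fraction_design):
        ctl = _group_cols(one_fraction_design, "control")
        stim = _group_cols(one_fraction_design, "stimulated")
        values = {f"P{i}": {s: 20.0 + i for s in ctl + stim} for i in range(12)}
        values["A"] = {s: 22.0 for s in ctl}  # absent in the stimulated group
        table = filter_min_valid(make_table(values, one_fraction_design))
        out = impute_partial(table, k_neighbors=3)
        assert out.values.loc["A", stim].isna().all()


class TestImputeAbsent:
    def _table_with_absent_group(self, design):
        ctl = _group_cols(design, "control")
        stim = _group_cols(design, "stimulated")
        values = {f"P{i}": {s: float(i + 1) for s in ctl + stim} for i in range(100)}
        values["A"] = {s: 50.0 for s in ctl}
        return filter_min_valid(make_table(values, design))

    def test_quantile_interpolates_order_statistics(self, one_fraction_design):
        """Observed 1..100 at q=0.025 imputes 3.475."""
        table = self._table_with_absent_group(one_fraction_design)
        out = impute_absent(table, quantile=0.025)
        stim = _group_cols(one_fraction_design, "stimulated")
        for s in stim:
            assert out.values.loc["A", s] == pytest.approx(3.475)

    def test_complete_table_untouched(self):
        table, _ = _big_single_fraction()
        out = impute_absent(table)
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_quantile_zero_is_sample_minimum(self, one_fraction_design):
        table = self._table_with_absent_group(one_fraction_design)
        out = impute_absent(table, quantile=0.0)
        stim = _group_cols(one_fraction_design, "stimulated")
        assert out.values.loc["A", stim[0]] == pytest.approx(1.0)

    def test_sparse_sample_rejected(self, one_fraction_design):
        ctl = _group_cols(one_fraction_design, "control")
        stim = _group_cols(one_fraction_design, "stimulated")
        values = {f"P{i}": {s: float(i + 1) for s in ctl} for i in range(20)}
        values["P0"].update({s: 1.0 for s in stim})
        values["P1"].update({s: 2.0 for s in stim})
        values["P2"].update({s: 3.0 for s in stim})
        values["A"] = {s: 5.0 for s in ctl}
        table = filter_min_valid(make_table(values, one_fraction_design))
        with pytest.raises(ValueError, match="observed values"):
            impute_absent(table)


class TestPipelineInvariants:
    def test_observed_values_never_altered(self, default_simulation):
        table, _, cfg = default_simulation
        out = preprocess(table, normalize=False)
        obs = out.observed & out.values.notna()
        before = table.values.loc[out.features]
        after = out.values
        mask = obs & before.notna()
        np.testing.assert_allclose(after[mask], before[mask], atol=1e-12)

    def test_complete_after_both_steps_and_idempotent(self, default_simulation):
        table, _, _ = default_simulation
        out = preprocess(table)
        assert out.is_complete()
        again = impute_absent(impute_partial(out))
        pd.testing.assert_frame_equal(again.values, out.values)

    def test_censored_imputations_below_sample_median(self, default_simulation):
        table, _, _ = default_simulation
        filtered = filter_min_valid(table)
        out = impute_absent(impute_partial(filtered), quantile=0.025)
        filled = out.values.isna().eq(False) & filtered.values.isna() \
            & out.retained_mask_cells()
        # only cells introduced by the quantile step (whole-group missing)
        partial = impute_partial(filtered)
        filled &= partial.values.isna()
        for s in out.values.columns:
            if filled[s].any():
                median = filtered.values[s].median()
                assert (out.values.loc[filled[s], s] <= median).all()
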