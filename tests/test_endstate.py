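import numpy as np
import pandas as pd
import pytest

from gridqsar.endstate import (
    aggregate_series,
    average_components,
    compare_breakdowns,
    lie_binding,
    mmpbsa_total,
    per_residue_filter,
)
from gridqsar.synthdata import gen_energy_frames
from gridqsar.types import EnergyFrameSeries


def series_from_arrays(n, **cols):
    data = {"frame": np.arange(1, n + 1)}
    for key in ("vdwaals", "e_el", "e_pbgb", "e_surf"):
        data[key] = np.asarray(cols.get(key, np.zeros(n)), dtype=float)
    return EnergyFrameSeries(frames=pd.DataFrame(data), label="test")


class TestAverageComponents:
    def test_constant_series(self):
        s = series_from_arrays(250, vdwaals=np.full(250, -70.0))
        means = average_components(s, last_n=200)
        assert means["vdwaals"] == pytest.approx(-70.0)
        assert means["n_frames"] == 200

    def test_linear_ramp_mean(self):
        ramp = np.concatenate([np.zeros(50), np.linspace(-80, -60, 200)])
        s = series_from_arrays(250, vdwaals=ramp)
        assert average_components(s, last_n=200)["vdwaals"] == pytest.approx(-70.0)

    def test_last_frame_only(self):
        s = series_from_arrays(5, e_el=np.array([1.0, 2.0, 3.0, 4.0, -9.0]))
        assert average_components(s, last_n=1)["e_el"] == pytest.approx(-9.0)

    def test_too_few_frames_reports_available(self):
        s = series_from_arrays(50)
        with pytest.raises(ValueError, match="50"):
            average_components(s, last_n=200)


class TestMmpbsaTotal:
    def test_identities_on_component_means(self):
        b = mmpbsa_total({"vdwaals": -53.77, "e_el": -21.27, "e_pbgb": 34.20, "e_surf": -6.48})
        assert b.dg_gas == pytest.approx(-75.04, abs=1e-9)
        assert b.dg_solv == pytest.approx(27.72, abs=1e-9)
        assert b.dtotal == pytest.approx(-47.32, abs=1e-9)

    def test_gas_phase_sum(self):
        b = mmpbsa_total({"vdwaals": -71.17, "e_el": -51.49, "e_pbgb": 68.69, "e_surf": -8.82})
        assert b.dg_gas == pytest.approx(-122.66, abs=1e-9)

    def test_all_zero_components(self):
        b = mmpbsa_total({c: 0.0 for c in ("vdwaals", "e_el", "e_pbgb", "e_surf")})
        assert b.dg_gas == b.dg_solv == b.dtotal == 0.0

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError, match="e_surf"):
            mmpbsa_total({"vdwaals": 0.0, "e_el": 0.0, "e_pbgb": 0.0})

    def test_aggregation_is_linear_in_frames(self):
        rng = np.random.default_rng(5)
        cols = {k: rng.normal(size=300) for k in ("vdwaals", "e_el", "e_pbgb", "e_surf")}
        s = series_from_arrays(300, **cols)
        b = aggregate_series(s, last_n=200)
        per_frame_total = sum(cols[k][-200:] for k in cols)
        assert b.dtotal == pytest.approx(per_frame_total.mean(), abs=1e-9)

    def test_rounded_view_keeps_full_precision_fields(self):
        b = mmpbsa_total({"vdwaals": -53.7749, "e_el": -21.2661, "e_pbgb": 34.2049, "e_surf": -6.4849})
        view = b.rounded()
        assert view["VDWAALS"] == -53.77
        assert b.vdwaals == -53.7749

    def test_entropy_adjustment_only_on_request(self):
        b = mmpbsa_total({"vdwaals": -10.0, "e_el": -5.0, "e_pbgb": 7.0, "e_surf": -1.0})
        assert not hasattr(b, "minus_t_delta_s")
        assert b.with_entropy(4.0) == pytest.approx(b.dtotal + 4.0)


class TestLie:
    @staticmethod
    def _ens(vdw, ele, n=100):
        return pd.DataFrame({"vdw": np.full(n, vdw), "ele": np.full(n, ele)})

    def test_identical_ensembles_give_zero(self):
        res = lie_binding(self._ens(-50, -30), self._ens(-50, -30))
        assert res.dg_bind == pytest.approx(0.0)

    def test_default_scaling_factors(self):
        res = lie_binding(self._ens(-50, -30), self._ens(-40, -20))
        assert res.alpha == 0.181 and res.beta == 0.43
        assert res.dg_bind == pytest.approx(0.181 * -10 + 0.43 * -10, abs=1e-12)
        assert res.dg_bind == pytest.approx(-6.11, abs=1e-9)

    def test_zero_scaling_factors(self):
        res = lie_binding(self._ens(-50, -30), self._ens(-10, -5), alpha=0.0, beta=0.0)
        assert res.dg_bind == 0.0

    def test_swapping_states_negates(self):
        a = lie_binding(self._ens(-52, -31), self._ens(-41, -19))
        b = lie_binding(self._ens(-41, -19), self._ens(-52, -31))
        assert a.dg_bind == pytest.approx(-b.dg_bind, abs=1e-12)

    def test_affine_in_alpha_beta(self):
        bound, unbound = self._ens(-52, -31), self._ens(-41, -19)
        d_vdw, d_ele = -11.0, -12.0
        for alpha, beta in ((0.1, 0.2), (0.5, 0.0), (0.0, 1.0)):
            res = lie_binding(bound, unbound, alpha=alpha, beta=beta)
            assert res.dg_bind == pytest.approx(alpha * d_vdw + beta * d_ele, abs=1e-12)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lie_binding(pd.DataFrame({"vdw": [], "ele": []}), self._ens(-40, -20))


class TestResidueDecomposition:
    @staticmethod
    def _table():
        return pd.DataFrame(
            {
                "residue_id": ["F691", "C694", "K644", "L616"],
                "contribution": [-2.44, -2.82, -0.02, -2.53],
                "min_distance": [3.2, 3.0, 3.5, 4.5],
            }
        )

    def test_distance_rule_sets_na(self):
        out = per_residue_filter(self._table())
        assert np.isnan(out.loc[out["residue_id"] == "L616", "contribution"]).all()

    def test_close_contributions_retained(self):
        out = per_residue_filter(self._table())
        assert out.loc[out["residue_id"] == "C694", "contribution"].iloc[0] == pytest.approx(-2.82)

    def test_negligible_rule(self):
        out = per_residue_filter(self._table(), negligible=0.05)
        assert np.isnan(out.loc[out["residue_id"] == "K644", "contribution"]).all()

    def test_empty_table_passthrough(self):
        empty = pd.DataFrame({"residue_id": [], "contribution": []})
        assert len(per_residue_filter(empty)) == 0

    def test_sorted_by_residue_number(self):
        out = per_residue_filter(self._table())
        assert list(out["residue_id"]) == ["L616", "K644", "F691", "C694"]


class TestCompareBreakdowns:
    def test_identical_breakdowns_zero(self):
        b = mmpbsa_total({"vdwaals": -70.0, "e_el": -50.0, "e_pbgb": 68.0, "e_surf": -8.8})
        diff = compare_breakdowns(b, b)
        assert all(v == 0 for v in diff.values())

    def test_total_difference(self):
        a = mmpbsa_total({"vdwaals": -71.17, "e_el": -51.49, "e_pbgb": 68.69, "e_surf": -8.82})
        b = mmpbsa_total({"vdwaals": -69.99, "e_el": -53.10, "e_pbgb": 69.92, "e_surf": -8.86})
        # printed totals differ by -0.77; component sums carry 0.01 rounding drift
        diff = compare_breakdowns(a, b)
        assert diff["dtotal"] == pytest.approx(-0.77, abs=0.011)

    def test_na_propagates_in_tables(self):
        a = pd.DataFrame({"residue_id": ["R1", "R2"], "contribution": [np.nan, -2.0]})
        b = pd.DataFrame({"residue_id": ["R1", "R2"], "contribution": [-1.0, -1.5]})
        diff = compare_breakdowns(a, b)
        assert np.isnan(diff.loc[diff["residue_id"] == "R1", "contribution"]).all()
        assert diff.loc[diff["residue_id"] == "R2", "contribution"].iloc[0] == pytest.approx(-0.5)

    def test_schema_mismatch_rejected(self):
        a = pd.DataFrame({"residue_id": ["R1"], "contribution": [1.0]})
        b = pd.DataFrame({"residue_id": ["R1"], "other": [1.0]})
        with pytest.raises(ValueError):
            compare_breakdowns(a, b)


class TestGenEnergyFramesDownstream:
    def test_zero_sd_reproduces_means_exactly(self):
        means = {"vdwaals": -53.77, "e_el": -21.27, "e_pbgb": 34.20, "e_surf": -6.48}
        s = gen_energy_frames(means, {}, n_frames=200, seed=1)
        b = aggregate_series(s, last_n=200)
        assert b.dtotal == pytest.approx(-47.32, abs=1e-9)

    def test_noisy_frames_concentrate_around_target_total(self):
        means = {"vdwaals": -53.77, "e_el": -21.27, "e_pbgb": 34.20, "e_surf": -6.48}
        sds = {k: 1.5 for k in means}
        close = 0
        for seed in range(50):
            s = gen_energy_frames(means, sds, n_frames=200, seed=seed)
            b = aggregate_series(s, last_n=200)
            close += abs(b.dtotal - (-47.32)) < 0.5
        # SD of the 4-component mean total is 1.5*2/sqrt(200) ~ 0.21
        assert close >= 45
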