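"""Structure of the component registry, processes and Gujer matrix."""

import numpy as np
import pytest

import saladm as sa
from saladm.model_core import (BIOMASS_CODES, RateKind, build_model,
                               build_processes, build_registry)


class TestComponentRegistry:
    def test_phase_and_unit_census(self):
        reg = build_registry()
        assert len(reg) == 34
        sol = [c for c in reg if c.phase == "soluble"]
        par = [c for c in reg if c.phase == "particulate"]
        assert (len(sol), len(par)) == (13, 21)
        assert sorted(c.index for c in reg) == list(range(1, 35))
        molar = {c.code for c in reg if c.unit == "kmol/m3"}
        assert molar == {"S_h2s", "S_SO4"}

    def test_sixteen_active_guilds_and_twelve_substrates(self):
        # the food web: 16 microbial guilds and 12 non-inert soluble
        # substrates (S_I and the two gases are not substrates)
        reg = build_registry()
        assert sum(c.is_biomass for c in reg) == 16
        substrates = [c for c in reg if c.phase == "soluble"
                      and c.code != "S_I"]
        assert len(substrates) == 12

    def test_cod_equivalents(self):
        reg = build_registry()
        eq = reg.cod_equivalents()
        assert eq[reg.idx("S_h2s")] == 64.0
        assert eq[reg.idx("S_SO4")] == 0.0
        assert np.sum(eq == 1.0) == 32


class TestBuildModel:
    def test_preset_dimensions(self):
        reg, procs, params = build_model("NaCl")
        assert (len(reg), len(procs)) == (34, 37)

    def test_propionate_uptake_rate_by_preset(self):
        _, _, nacl = build_model("NaCl")
        _, _, so4 = build_model("Na2SO4_NaHCO3")
        assert nacl.km["pro"] == pytest.approx(0.039)
        assert so4.km["pro"] == pytest.approx(2.0)

    def test_nacl_srb_dormant(self):
        model = build_model("NaCl")
        _, _, params = model
        assert all(params.km[g] == 0.0 for g in params.km if "SRB" in g)
        # dormant guilds produce no flux on any trajectory
        rng = np.random.default_rng(0)
        for _ in range(5):
            state = rng.uniform(0, 2.0, 34)
            rho = sa.process_rates(state, model)
            assert np.all(rho[13:21] == 0.0)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            build_model("brine")

    def test_rate_kinds_follow_network_layout(self, nacl_model):
        kinds = {p.j: p.rate_kind for p in nacl_model.processes}
        for j in range(1, 5):
            assert kinds[j] == RateKind.FIRST_ORDER
        for j in list(range(5, 11)) + list(range(14, 22)):
            assert kinds[j] == RateKind.MONOD
        for j in (11, 12, 13):
            assert kinds[j] == RateKind.MONOD_INHIBITED
        for j in range(22, 38):
            assert kinds[j] == RateKind.DECAY

    def test_uptakes_bind_substrate_and_biomass(self, nacl_model):
        for p in nacl_model.processes:
            if p.rate_kind in (RateKind.MONOD, RateKind.MONOD_INHIBITED):
                assert p.substrate is not None and p.biomass is not None


class TestStoichiometry:
    def test_cod_conserved_in_every_process(self, nacl_model, sulfate_model):
        for cm in (nacl_model, sulfate_model):
            res = sa.validate_cod_balance(cm.stoich)
            assert np.abs(res).max() < 1e-8

    def test_butyrate_row_splits(self, nacl_model):
        reg, params = nacl_model.registry, nacl_model.params
        row = nacl_model.stoich.row(10)
        y = params.Y["c4"]
        assert row[reg.idx("S_ac")] == pytest.approx((1 - y) * 0.8)
        assert row[reg.idx("S_h2")] == pytest.approx((1 - y) * 0.2)
        assert row[reg.idx("S_bu")] == -1.0

    def test_valerate_row_splits(self, nacl_model):
        reg, params = nacl_model.registry, nacl_model.params
        row = nacl_model.stoich.row(9)
        y = params.Y["c4"]
        for code, f in (("S_pro", 0.54), ("S_ac", 0.31), ("S_h2", 0.15)):
            assert row[reg.idx(code)] == pytest.approx((1 - y) * f)

    def test_srb_rows_conserve_sulfur(self, sulfate_model):
        reg = sulfate_model.registry
        for j in range(14, 22):
            row = sulfate_model.stoich.row(j)
            assert row[reg.idx("S_h2s")] == -row[reg.idx("S_SO4")]
            assert row[reg.idx("S_h2s")] > 0

    def test_srb_acetate_row_hand_balance(self, sulfate_model):
        # -1 acetate + Y biomass + (1-Y)/64 kmol sulfide x 64 kgCOD/kmol = 0
        reg, params = sulfate_model.registry, sulfate_model.params
        row = sulfate_model.stoich.row(20)
        y = params.Y["aSRB"]
        assert row[reg.idx("S_h2s")] == pytest.approx((1 - y) / 64.0)
        hand = -1.0 + y + (1 - y) / 64.0 * 64.0
        assert abs(hand) < 1e-12
        assert float(row @ reg.cod_equivalents()) == pytest.approx(0, abs=1e-12)

    def test_decay_rows_recycle_to_composite(self, nacl_model):
        reg = nacl_model.registry
        for p in nacl_model.processes:
            if p.rate_kind == RateKind.DECAY:
                row = nacl_model.stoich.row(p.j)
                assert row[reg.idx(p.biomass)] == -1.0
                assert row[reg.idx("X_C")] == 1.0

    def test_disintegration_row_includes_oxalate(self, nacl_model):
        reg, params = nacl_model.registry, nacl_model.params
        row = nacl_model.stoich.row(1)
        assert row[reg.idx("S_ox")] == pytest.approx(params.f_ox_xc)
        assert row[reg.idx("X_C")] == -1.0

    def test_single_row_perturbation_flagged(self):
        reg, procs, params = build_model("NaCl")
        m = sa.assemble_matrix(procs, params, reg)
        m.matrix[6, reg.idx("S_ac")] += 0.01  # amino acid uptake row
        res = sa.validate_cod_balance(m)
        flagged = np.nonzero(np.abs(res) > 1e-8)[0]
        assert list(flagged) == [6]

    def test_nonclosing_fractions_name_offender(self):
        reg, procs, params = build_model("NaCl")
        params.f_pro_va += 0.01  # breaks the valerate product set
        with pytest.raises(ValueError, match="valerate"):
            params.validate()
        with pytest.raises(ValueError):
            sa.assemble_matrix(build_processes(params), params, reg)

    def test_derived_fraction_cannot_go_negative(self):
        _, _, params = build_model("NaCl")
        params.f_va_aa = 0.95  # pushes the derived hydrogen share below 0
        with pytest.raises(ValueError, match="negative"):
            params.validate()

    def test_assembly_deterministic(self):
        reg, procs, params = build_model("Na2SO4_NaHCO3")
        m1 = sa.assemble_matrix(procs, params, reg)
        m2 = sa.assemble_matrix(build_processes(params), params, reg)
        assert np.array_equal(m1.matrix, m2.matrix)

    def test_matrix_csv_roundtrip(self, nacl_model, tmp_path):
        path = tmp_path / "gujer.csv"
        nacl_model.stoich.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path, index_col=0)
        assert df.shape == (37, 34)
        assert list(df.columns) == nacl_model.registry.codes
        np.testing.assert_allclose(df.to_numpy(), nacl_model.stoich.matrix)


class TestParameterSet:
    def test_disintegration_fractions_close(self):
        _, _, params = build_model("NaCl")
        total = (params.f_ch_xc + params.f_pr_xc + params.f_li_xc
                 + params.f_ox_xc + params.f_xI_xc + params.f_sI_xc)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_derived_product_fractions(self):
        _, _, params = build_model("NaCl")
        assert params.f_ac_su == pytest.approx(0.67)
        assert params.f_h2_aa == pytest.approx(0.07)

    def test_flat_access_with_aliases(self):
        _, _, params = build_model("NaCl")
        assert params.get_flat("km_pro") == pytest.approx(0.039)
        assert params.get_flat("KI_pp") == pytest.approx(0.8)
        params.set_flat("KS_su", 0.02)
        assert params.ks["su"] == 0.02
        with pytest.raises(KeyError):
            params.get_flat("km_nonsense")

    def test_invariant_violations_rejected(self):
        _, _, params = build_model("NaCl")
        params.Y["su"] = 1.2
        with pytest.raises(ValueError, match="yield"):
            params.validate()
        _, _, params = build_model("NaCl")
        params.n = 0.5
        with pytest.raises(ValueError, match="n must be"):
            params.validate()
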