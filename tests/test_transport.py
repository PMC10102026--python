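import numpy as np
import pytest

from nct.config import PoreClass, PoreConfig, default_config
from nct.network import CYTOPLASM, NUCLEUS
from nct import transport as tr


class TestBuildNetwork:
    def test_every_base_species_reacts(self, base_model):
        net = base_model.network
        reacting = {sp for rxn in net.reactions
                    for sp, _ in rxn.reactants + rxn.products}
        for sp in ("RanGTP", "RanGDP", "NTF2", "RCC1", "RanGAP", "RanBP1",
                   "RanBP3", "ImpA", "ImpB", "CAS", "CRM1"):
            assert sp in reacting, sp

    def test_zero_cas_builds_with_zero_complexes(self, base_config):
        cfg = base_config.with_species({"CAS": 0.0})
        model = tr.build_network(cfg)
        x0 = model.network.x0
        for i, (sp, _) in enumerate(model.network.states):
            if "CAS" in sp.split(":"):
                assert x0[i] == 0.0

    def test_reaction_count_matches_hand_enumeration(self, base_model):
        # independent tally of the construction recipe:
        #   reversible binding pairs placed in both reactive compartments
        #   or one, catalytic steps, and 4 reactions per shuttling species
        reversible_both = 6    # impab, impb_rangtp, cas_rangtp, cas_impa,
                               # ntf2_rangdp, crm1_rangtp
        reversible_nuc = 4     # casrangtp_impa, crm1_ranbp3,
                               # crm1ranbp3_rangtp, rcc1_rangdp
        reversible_cyt = 1     # ranbp1_rangtp
        irreversible = (2      # rangtp-driven ImpA:ImpB disassembly (both comps)
                        + 1    # rangtp_casimpa (nucleus)
                        + 1    # rcc1 exchange
                        + 2    # rangap catalyzed + basal
                        + 5)   # RanBP1 stripping of carrier complexes
        shuttling = 13         # 12 carrier/cargo species at k_trans + RanBP3 + ImpA
        expected = (reversible_both * 4 + reversible_nuc * 2 + reversible_cyt * 2
                    + irreversible + shuttling * 4)
        assert len(base_model.network.reactions) == expected

    def test_missing_rate_is_an_error(self, base_config):
        cfg = default_config()
        del cfg.rates["kcat_rcc1"]
        with pytest.raises(KeyError, match="kcat_rcc1"):
            tr.build_network(cfg)


class TestAddCargo:
    def test_classical_cargo_gains_trimer_and_translocation(self, base_model):
        m = tr.add_cargo(base_model, tr.NLS_SV40)
        net = m.network
        assert net.has_state("NLS:ImpA:ImpB", CYTOPLASM)
        assert net.has_state("NLS:ImpA:ImpB", "pore")
        assert any(r.name.startswith("t_NLS:ImpA:ImpB") for r in net.reactions)

    def test_ibb_cargo_binds_impb_directly(self, base_model):
        m = tr.add_cargo(base_model, tr.IBB_KPNA2)
        assert m.network.has_state("IBB:ImpB", CYTOPLASM)
        assert not m.network.has_species("IBB:ImpA:ImpB")

    def test_duplicate_cargo_rejected(self, nls_model):
        with pytest.raises(ValueError, match="already present"):
            tr.add_cargo(nls_model, tr.NLS_SV40)

    def test_nes_requires_kd_export(self):
        with pytest.raises(ValueError, match="kd_export"):
            tr.CargoSpec("X", "classical", 32.0, has_nes=True)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            tr.CargoSpec("X", "classical", 0.0)

    def test_affinity_orders_nc_ratio(self, base_model):
        strong = tr.steady_state(tr.add_cargo(base_model, tr.NLS2_CBP80), "2xNLS")
        weak = tr.steady_state(tr.add_cargo(base_model, tr.NLS_SV40), "NLS")
        assert strong.nc_ratio > weak.nc_ratio

    def test_inert_cargo_stays_cytoplasmic(self, base_config):
        cfg = default_config()
        cfg.rates["k_passive_cargo"] = 0.0
        m = tr.add_cargo(tr.build_network(cfg), tr.CargoSpec("X", "inert"))
        res = tr.steady_state(m, "X")
        assert res.nc_ratio == 0.0


class TestIntegrate:
    def test_t_end_zero_returns_initial_state(self, nls_model):
        t, X = tr.integrate(nls_model, 0.0)
        np.testing.assert_array_equal(X[:, 0], nls_model.network.x0)

    def test_concentrations_stay_nonnegative(self, nls_model):
        _, X = tr.integrate(nls_model, 5000.0, n_out=20)
        assert X.min() > -1e-8

    def test_conservation_along_trajectory(self, nls_model):
        _, X = tr.integrate(nls_model, 5000.0, n_out=20)
        _, W = nls_model.network.moiety_matrix()
        totals = W @ X
        rel = np.abs(totals - totals[:, [0]]) / np.abs(totals[:, [0]])
        assert rel.max() < 1e-6

    def test_ran_gradient_direction(self, nls_model, nls_steady_state):
        net = nls_model.network
        x = nls_steady_state.x
        assert x[net.state_index("RanGTP", NUCLEUS)] > \
            10.0 * x[net.state_index("RanGTP", CYTOPLASM)]


class TestSteadyState:
    def test_residual_below_tolerance(self, nls_steady_state):
        assert nls_steady_state.converged
        assert nls_steady_state.residual_norm < 1e-9

    def test_matches_long_time_integration(self, nls_model, nls_steady_state):
        _, X = tr.integrate(nls_model, 1e5, n_out=2)
        ref = X[:, -1]
        denom = np.maximum(np.abs(ref), 1e-8)
        assert np.max(np.abs(nls_steady_state.x - ref) / denom) < 1e-3

    def test_no_karyopherins_means_no_import(self, base_config):
        cfg = default_config()
        cfg.rates["k_passive_cargo"] = 0.0
        cfg = cfg.with_species({"ImpA": 0.0, "ImpB": 0.0, "CAS": 0.0, "CRM1": 0.0})
        m = tr.add_cargo(tr.build_network(cfg), tr.NLS_SV40)
        res = tr.steady_state(m, "NLS")
        assert res.converged
        assert res.nc_ratio == 0.0

    def test_unique_steady_state_from_redistributed_guess(self, nls_model, nls_steady_state):
        net = nls_model.network
        x0 = net.x0.copy()
        # move all Ran to the nucleus, preserving the volume-weighted total
        i_c = net.state_index("RanGDP", CYTOPLASM)
        i_n = net.state_index("RanGDP", NUCLEUS)
        vc = net.compartments[CYTOPLASM].volume
        vn = net.compartments[NUCLEUS].volume
        x0[i_n] += x0[i_c] * vc / vn
        x0[i_c] = 0.0
        res2 = tr.steady_state(nls_model, "NLS", x0=x0)
        assert res2.converged
        assert res2.nc_ratio == pytest.approx(nls_steady_state.nc_ratio, rel=1e-3)

    def test_jittered_configs_match_integration(self, base_config):
        rng = np.random.default_rng(7)
        for _ in range(3):
            jit = {sp: (c * rng.uniform(0.5, 2.0), h)
                   for sp, (c, h) in base_config.species.items()}
            cfg = default_config()
            cfg.species.update(jit)
            m = tr.add_cargo(tr.build_network(cfg), tr.NLS_SV40)
            ss = tr.steady_state(m, "NLS")
            _, X = tr.integrate(m, 1e5, n_out=2)
            ref = X[:, -1]
            denom = np.maximum(np.abs(ref), 1e-8)
            assert np.max(np.abs(ss.x - ref) / denom) < 1e-3


class TestScaleInitialConditions:
    def test_identity_profile(self, base_config):
        out = tr.scale_initial_conditions({g: 1.0 for g in tr.TRANSCRIPT_MAP},
                                          base_config)
        for sp in out.species:
            assert out.species[sp][0] == pytest.approx(base_config.species[sp][0])

    def test_kpna_isoforms_aggregate_to_impa(self, base_config):
        profile = {f"KPNA{i}": 2.0 for i in range(1, 8)}
        out = tr.scale_initial_conditions(profile, base_config)
        assert out.species["ImpA"][0] == pytest.approx(
            2.0 * base_config.species["ImpA"][0])
        assert out.species["ImpB"][0] == base_config.species["ImpB"][0]

    def test_missing_gene_falls_back_with_note(self, base_config):
        notes = []
        out = tr.scale_initial_conditions({"CSE1L": 2.0}, base_config, notes)
        assert out.species["RanBP3"][0] == base_config.species["RanBP3"][0]
        assert any("RanBP3" in n for n in notes)

    def test_nonpositive_level_rejected(self, base_config):
        with pytest.raises(ValueError):
            tr.scale_initial_conditions({"CSE1L": 0.0}, base_config)


class TestSensitivityDirections:
    FOLDS = np.logspace(np.log10(0.25), np.log10(4.0), 5)

    @pytest.mark.parametrize("species,cargo,direction", [
        ("ImpA", tr.NLS_SV40, +1),
        ("CAS", tr.NLS_SV40, -1),
        ("ImpB", tr.IBB_KPNA2, +1),
        ("CRM1", tr.IBB_KPNA2, -1),
    ])
    def test_printed_directions(self, base_config, species, cargo, direction):
        out = tr.sensitivity_scan(base_config, species, self.FOLDS, [cargo])
        vals = np.array([v for _, v, ok in out[cargo.name]])
        assert all(ok for _, _, ok in out[cargo.name])
        diffs = np.diff(vals) * direction
        assert np.all(diffs >= -1e-9), vals

    def test_nls_and_2xnls_scans_rank_identical(self, base_config):
        out = tr.sensitivity_scan(base_config, "CAS", self.FOLDS,
                                  [tr.NLS_SV40, tr.NLS2_CBP80])
        a = [v for _, v, _ in out["NLS"]]
        b = [v for _, v, _ in out["2xNLS"]]
        assert list(np.argsort(a)) == list(np.argsort(b))
        assert all(x < y for x, y in zip(a, b))


class TestNesAndPores:
    def test_nes_negligible_at_base_and_grows_with_ranbp3(self, base_config):
        nes = tr.CargoSpec("NLS", "classical", 32.0, has_nes=True, kd_export=50.0)
        gaps = []
        for fold in (1.0, 50.0):
            cfg = base_config.with_species(
                {"RanBP3": base_config.species["RanBP3"][0] * fold})
            plain = tr.steady_state(tr.add_cargo(tr.build_network(cfg), tr.NLS_SV40), "NLS")
            with_nes = tr.steady_state(tr.add_cargo(tr.build_network(cfg), nes), "NLS")
            gaps.append((plain.nc_ratio - with_nes.nc_ratio) / plain.nc_ratio)
        assert gaps[0] < 0.02
        assert gaps[1] > 5 * gaps[0]

    def test_two_pore_classes_neutral_at_realistic_counts(self, base_config, nls_steady_state):
        cfg = default_config()
        cfg.pores = PoreConfig([PoreClass(2493, "all"), PoreClass(277, "nls")], 2770)
        for cargo, name, ref in [
            (tr.NLS_SV40, "NLS", nls_steady_state.nc_ratio),
            (tr.IBB_KPNA2, "IBB", None),
        ]:
            two = tr.steady_state(tr.add_cargo(tr.build_network(cfg), cargo), name)
            if ref is None:
                ref = tr.steady_state(
                    tr.add_cargo(tr.build_network(default_config()), cargo), name).nc_ratio
            assert abs(two.nc_ratio - ref) / ref < 0.01

    def test_single_selective_class_rejected(self):
        with pytest.raises(ValueError, match="admit all"):
            PoreConfig([PoreClass(2770, "classical")])


class TestStratifiedPredictionTest:
    def test_ceiling_group_sizing(self):
        rng = np.random.default_rng(0)
        out = tr.stratified_prediction_test(rng.normal(size=20), np.arange(20.0))
        assert out["n_high"] == 7
        assert out["n_low"] == 13

    def test_monotone_values_give_separated_medians(self):
        values = np.arange(20.0)
        out = tr.stratified_prediction_test(values, values)
        assert out["median_high"] > out["median_low"]
        assert out["p_one_sided"] < 0.01

    def test_degenerate_stratifier_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            tr.stratified_prediction_test(np.arange(10.0), np.ones(10))

    def test_null_p_values_are_calibrated(self):
        rng = np.random.default_rng(42)
        pvals = [
            tr.stratified_prediction_test(
                rng.normal(size=20), rng.permutation(20).astype(float))["p_one_sided"]
            for _ in range(400)
        ]
        assert abs(np.median(pvals) - 0.5) < 0.08
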