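"""Tests for ITC forward simulation, fitting and the chelator correction."""

import math

import numpy as np
import pytest

from _oracles import wiseman_cumulative_bound

from zurlink.equilibria import LinkageParams
from zurlink.itc import (
    CompetitiveSystem,
    DnaOligomerSystem,
    FitError,
    Isotherm,
    SingleClassSystem,
    ThreeSiteSystem,
    TitrationProtocol,
    apparent_from_intrinsic,
    chelator_correction,
    conditional_chelator_constant,
    fit_isotherm,
    monophasicity_bound,
    simulate_isotherm,
)


class TestSimulateIsotherm:
    def test_zero_enthalpy_gives_zero_heats(self):
        proto = TitrationProtocol(syringe_conc=2e-3, cell_macromolecule=24e-6)
        iso = simulate_isotherm(SingleClassSystem(n=6, K=1e6, dH=0.0), proto)
        assert np.all(iso.ndh == 0.0)

    def test_high_c_step_isotherm_matches_closed_form(self):
        """At c >= 1e3 the curve is a step at ratio n and matches the
        independent closed-form bound-ligand expression point by point."""
        n, K, dH = 3.0, 1e9, -5.0
        M0 = 10e-6
        proto = TitrationProtocol(syringe_conc=500e-6, cell_macromolecule=M0)
        assert n * K * M0 >= 1e3
        iso = simulate_isotherm(SingleClassSystem(n=n, K=K, dH=dH), proto)
        # independent reconstruction with the same dilution bookkeeping
        dv = np.asarray(proto.injection_volumes)
        dcum = np.cumsum(dv)
        V0 = proto.V0
        q_prev = 0.0
        for j, (dvj, dc) in enumerate(zip(dv, dcum)):
            f_cell = (1 - dc / (2 * V0)) / (1 + dc / (2 * V0))
            X = proto.syringe_conc * (dc / V0) / (1 + dc / (2 * V0))
            bound = wiseman_cumulative_bound(X, n * M0 * f_cell, K)
            q = V0 * dH * bound
            dq = q - q_prev + (dvj / V0) * 0.5 * (q + q_prev)
            expected = dq / (dvj * proto.syringe_conc)
            assert iso.ndh[j] == pytest.approx(expected, abs=1e-9)
            q_prev = q
        # step shape: ~dH before the equivalence point, ~0 after
        pre = iso.ndh[iso.molar_ratio < 0.9 * n]
        post = iso.ndh[iso.molar_ratio > 1.1 * n]
        assert np.all(np.abs(pre - dH) < 0.05 * abs(dH))
        assert np.all(np.abs(post) < 0.02 * abs(dH))

    def test_cumulative_heat_converges_to_site_capacity(self):
        """Total heat approaches n * M_cell * V0 * dH in large titrant excess."""
        n, K, dH = 2.0, 1e8, -8.0
        M0 = 5e-6
        proto = TitrationProtocol(
            syringe_conc=2e-3, cell_macromolecule=M0, injection_volumes=(2e-6,) * 40
        )
        iso = simulate_isotherm(SingleClassSystem(n=n, K=K, dH=dH), proto)
        total = float(np.sum(iso.ndh * iso.injection_volumes * proto.syringe_conc))
        assert total == pytest.approx(n * M0 * proto.V0 * dH, rel=0.01)

    def test_uniform_heat_sign_until_saturation(self):
        proto = TitrationProtocol(syringe_conc=2e-3, cell_macromolecule=24e-6)
        iso = simulate_isotherm(SingleClassSystem(n=6, K=8.6e5, dH=-6.0), proto)
        assert np.all(iso.ndh < 0)

    def test_competitive_inflection_near_six_per_dimer(self, zn_egta_protocol):
        """Zn->Zur under EGTA competition: inflection at ~6 zinc per dimer."""
        system = CompetitiveSystem(n=6, K_int=2.3e13, dH_int=-10.0, K_chel=9.3e9, dH_chel=-4.0)
        iso = simulate_isotherm(system, zn_egta_protocol)
        half = 0.5 * (iso.ndh[0] + iso.ndh[-1])
        inflection = float(np.interp(half, iso.ndh, iso.molar_ratio))
        assert 5.5 <= inflection <= 6.5

    def test_zero_injection_protocol_rejected(self):
        with pytest.raises(ValueError):
            TitrationProtocol(syringe_conc=1e-3, cell_macromolecule=1e-5, injection_volumes=())


class TestFitIsotherm:
    def test_round_trip_single_class(self):
        truth = SingleClassSystem(n=3.0, K=1.8e6, dH=-5.0)
        proto = TitrationProtocol(syringe_conc=150e-6, cell_macromolecule=3e-6)
        iso = simulate_isotherm(truth, proto)
        fit = fit_isotherm(iso, proto, SingleClassSystem(n=2.0, K=5e5, dH=-3.0))
        assert fit.params["n"] == pytest.approx(truth.n, rel=1e-4)
        assert fit.params["K"] == pytest.approx(truth.K, rel=1e-4)
        assert fit.params["dH"] == pytest.approx(truth.dH, rel=1e-4)

    def test_round_trip_three_site(self, zn_egta_protocol):
        truth = ThreeSiteSystem(K_sites=(3e5, 8.6e5, 3e6), dH_sites=(-5.0, -6.0, -7.0))
        iso = simulate_isotherm(truth, zn_egta_protocol)
        guess = ThreeSiteSystem(K_sites=(2e5, 1e6, 4e6), dH_sites=(-4.0, -7.0, -6.0))
        fit = fit_isotherm(iso, zn_egta_protocol, guess)
        for got, want in zip(
            [fit.params[f"K{i}"] for i in (1, 2, 3)] + [fit.params[f"dH{i}"] for i in (1, 2, 3)],
            list(truth.K_sites) + list(truth.dH_sites),
        ):
            assert got == pytest.approx(want, rel=1e-4)

    def test_round_trip_competitive(self, zn_egta_protocol):
        truth = CompetitiveSystem(n=6.0, K_int=2.3e13, dH_int=-10.0, K_chel=9.3e9, dH_chel=-4.0)
        iso = simulate_isotherm(truth, zn_egta_protocol)
        guess = CompetitiveSystem(n=5.0, K_int=5e12, dH_int=-8.0, K_chel=9.3e9, dH_chel=-4.0)
        fit = fit_isotherm(iso, zn_egta_protocol, guess)
        assert fit.params["n"] == pytest.approx(6.0, rel=1e-4)
        assert fit.params["K"] == pytest.approx(2.3e13, rel=1e-4)
        assert fit.params["dH"] == pytest.approx(-10.0, rel=1e-4)

    def test_round_trip_dna_oligomer(self, dna_protocol):
        lad = LinkageParams.from_anchors(K_4=1.8e6, K_6=4000 * 1.8e6, n_dna_sites=3)
        truth = DnaOligomerSystem(linkage=lad, zinc_eq_per_dimer=4.0, dH_site=-8.0)
        iso = simulate_isotherm(truth, dna_protocol)
        guess_lad = LinkageParams.from_anchors(K_4=5e5, K_6=4000 * 5e5, n_dna_sites=3)
        guess = DnaOligomerSystem(linkage=guess_lad, zinc_eq_per_dimer=4.0, dH_site=-6.0)
        fit = fit_isotherm(iso, dna_protocol, guess)
        assert fit.params["K4"] == pytest.approx(1.8e6, rel=1e-4)
        assert fit.params["dH"] == pytest.approx(-8.0, rel=1e-4)

    def test_all_zero_heats_unidentifiable(self):
        proto = TitrationProtocol(syringe_conc=2e-3, cell_macromolecule=24e-6)
        iso = simulate_isotherm(SingleClassSystem(n=6, K=1e6, dH=0.0), proto)
        with pytest.raises(FitError):
            fit_isotherm(iso, proto, SingleClassSystem(n=6, K=1e6, dH=-5.0))

    def test_too_few_points_rejected(self):
        proto = TitrationProtocol(
            syringe_conc=2e-3, cell_macromolecule=24e-6, injection_volumes=(2e-6,) * 3
        )
        iso = simulate_isotherm(SingleClassSystem(n=6, K=1e6, dH=-5.0), proto)
        with pytest.raises(FitError):
            fit_isotherm(iso, proto, SingleClassSystem(n=6, K=1e6, dH=-5.0))

    def test_noisy_recovery_within_factor_two(self):
        """2% heat noise: K recovered within 2x in >=95% of replicates
        across the identifiable c-value window."""
        rng = np.random.default_rng(11)
        M0 = 20e-6
        proto = TitrationProtocol(syringe_conc=1.2e-3, cell_macromolecule=M0)
        n, dH = 3.0, -8.0
        ok = 0
        reps = 200
        for _ in range(reps):
            c = 10 ** rng.uniform(0, 3)  # c in [1, 1000]
            K = c / (n * M0)
            clean = simulate_isotherm(SingleClassSystem(n=n, K=K, dH=dH), proto)
            noisy = Isotherm(
                molar_ratio=clean.molar_ratio,
                ndh=clean.ndh + rng.normal(0, 0.02 * abs(dH), len(clean)),
                injection_volumes=clean.injection_volumes,
            )
            try:
                fit = fit_isotherm(noisy, proto, SingleClassSystem(n=n, K=K * 2, dH=dH * 0.8))
            except FitError:
                continue
            if 0.5 <= fit.params["K"] / K <= 2.0:
                ok += 1
        assert ok / reps >= 0.95

    def test_dna_oligomer_stoichiometry_saturating_zinc(self, dna_protocol):
        """Zinc-saturated Zur titrated into DNA: the single-class fit
        reports the site count of the probe (3 for zitB, 2 for znuA)."""
        for K4, ratio, ns in [(1.8e6, 4000.0, 3), (8.7e5, 700.0, 2)]:
            lad = LinkageParams.from_anchors(K_4=K4, K_6=ratio * K4, n_dna_sites=ns)
            sysd = DnaOligomerSystem(linkage=lad, zinc_eq_per_dimer=8.0, dH_site=-8.0)
            iso = simulate_isotherm(sysd, dna_protocol)
            fit = fit_isotherm(iso, dna_protocol, SingleClassSystem(n=2.5, K=1e8, dH=-7.0))
            assert fit.params["n"] == pytest.approx(ns, rel=0.02)

    def test_dna_oligomer_stoichiometry_partial_zinc(self, dna_protocol):
        """With 4 zinc eq per dimer and binding dominated by the measured
        PL_4 affinity, the fitted stoichiometry is near the site count."""
        for K4, ns in [(1.8e6, 3), (8.7e5, 2)]:
            lad = LinkageParams.from_anchors(K_4=K4, K_6=K4, n_dna_sites=ns)
            sysd = DnaOligomerSystem(linkage=lad, zinc_eq_per_dimer=4.0, dH_site=-8.0)
            iso = simulate_isotherm(sysd, dna_protocol)
            fit = fit_isotherm(iso, dna_protocol, SingleClassSystem(n=2.5, K=1e6, dH=-7.0))
            assert fit.params["n"] == pytest.approx(ns, rel=0.15)


class TestChelatorCorrection:
    def test_closed_form_matches_printed_intrinsic_affinity(self):
        K_int = chelator_correction(8.6e5, 3.0e-3, 9.3e9)
        assert K_int == pytest.approx(2.4e13, rel=0.01)
        assert abs(K_int - 2.3e13) <= 0.5e13  # within the reported uncertainty

    def test_no_chelator_identity(self):
        assert chelator_correction(8.6e5, 0.0, 9.3e9) == 8.6e5

    def test_enthalpy_correction_and_inverse(self):
        K_int, dH_int = chelator_correction(8.6e5, 3e-3, 9.3e9, dH_app=-6.0, dH_chel=-4.0)
        assert dH_int == -10.0
        K_app, dH_app = apparent_from_intrinsic(K_int, 3e-3, 9.3e9, dH_int=dH_int, dH_chel=-4.0)
        assert K_app == pytest.approx(8.6e5, rel=1e-12)
        assert dH_app == pytest.approx(-6.0)

    def test_conditional_constant_from_pka(self):
        """log K' = 9.97 at pH 7.8 from absolute log K 12.6, pKa 9.40/8.79."""
        K = conditional_chelator_constant()
        assert math.log10(K) == pytest.approx(9.97, abs=0.01)

    def test_formula_matches_exact_simulation_at_excess_chelator(self, zn_egta_protocol):
        """The closed-form correction inverts the apparent-affinity reduction
        of the exact competitive forward model within 5% when the chelator is
        >= 20x the protein site pool."""
        sites = 6 * zn_egta_protocol.cell_macromolecule
        assert zn_egta_protocol.cell_chelator >= 20 * sites
        truth = CompetitiveSystem(n=6, K_int=2.3e13, dH_int=-10.0, K_chel=9.3e9, dH_chel=-4.0)
        iso = simulate_isotherm(truth, zn_egta_protocol)
        fit = fit_isotherm(iso, zn_egta_protocol, SingleClassSystem(n=5.0, K=5e5, dH=-5.0))
        K_back = chelator_correction(
            fit.params["K"], zn_egta_protocol.cell_chelator, truth.K_chel
        )
        assert K_back == pytest.approx(truth.K_int, rel=0.05)


class TestMonophasicityBound:
    def test_spread_classification(self, zn_egta_protocol):
        """Unit spread is by definition indistinguishable; a 1000-fold
        spread produces systematic residuals far above 2% heat noise."""
        res = monophasicity_bound(
            zn_egta_protocol, base_K=8.6e5, dH=-6.0, noise_sigma=0.12,
            fold_spreads=[1.0, 20.0, 1000.0],
        )
        cls = res["classification"]
        assert cls[1.0] == "indistinguishable"
        assert cls[20.0] == "indistinguishable"
        assert cls[1000.0] == "detectable"
        assert res["max_tolerated"] >= 20.0

    def test_bad_noise_rejected(self, zn_egta_protocol):
        with pytest.raises(ValueError):
            monophasicity_bound(zn_egta_protocol, 8.6e5, -6.0, 0.0, [1.0])
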