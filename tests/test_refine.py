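"""Stability-constant refinement: recovery, uncertainties, model selection."""

import numpy as np
import pytest

import spequil as sq
from spequil.core import EquilibriumModel, ModelError, SpeciesLine
from spequil.refine import IdentifiabilityError


def _noisy_dataset(model, protocol, seed):
    return sq.simulate_potentiometric(model, protocol,
                                      sq.ElectrodeParams(E0=400.0), seed=seed)


def _clean_dataset(model, protocol):
    return sq.simulate_potentiometric(
        model, protocol, sq.ElectrodeParams(E0=400.0, sigma_E=0.0, sigma_v=0.0),
        seed=None)


@pytest.fixture(scope="module")
def clean_ds(asdmsa_mod, protocol_mod):
    return _clean_dataset(asdmsa_mod, protocol_mod)


@pytest.fixture(scope="module")
def asdmsa_mod():
    return sq.load_packaged_model("as3-dmsa")


@pytest.fixture(scope="module")
def protocol_mod():
    comp = sq.SolutionComposition(C_M=0.001, C_L=0.001, C_HCl=0.008)
    return sq.TitrationProtocol(initial=comp, titrant_concentration=0.1,
                                volumes=np.linspace(0.0, 4.0, 41), T=298.15)


FREE_BETAS = ["logB:MLH", "logB:MLH2", "logB:MLH3"]


class TestPotentiometric:
    def test_zero_noise_recovery_from_offset_guesses(self, asdmsa_mod, clean_ds):
        offset = {k: asdmsa_mod.log_beta(k, 298.15) + 0.5
                  for k in ("MLH", "MLH2", "MLH3")}
        spec = sq.RefinementSpec(model=asdmsa_mod.with_log_beta(offset, 298.15),
                                 free=FREE_BETAS)
        res = sq.refine_potentiometric(clean_ds, spec)
        assert res.converged
        for k in ("MLH", "MLH2", "MLH3"):
            assert res.estimates["logB:" + k] == pytest.approx(
                asdmsa_mod.log_beta(k, 298.15), abs=1e-6)

    def test_objective_trace_monotone_non_increasing(self, asdmsa_mod, clean_ds):
        offset = {k: asdmsa_mod.log_beta(k, 298.15) + 0.3 for k in ("MLH", "MLH2", "MLH3")}
        spec = sq.RefinementSpec(model=asdmsa_mod.with_log_beta(offset, 298.15),
                                 free=FREE_BETAS)
        res = sq.refine_potentiometric(clean_ds, spec)
        trace = np.array(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-14 * np.maximum(trace[:-1], 1.0))

    def test_noisy_estimates_within_three_sd(self, asdmsa_mod, protocol_mod):
        hits = 0
        n_rep = 5
        for rep in range(n_rep):
            ds = _noisy_dataset(asdmsa_mod, protocol_mod, seed=300 + rep)
            res = sq.refine_potentiometric(
                ds, sq.RefinementSpec(model=asdmsa_mod, free=FREE_BETAS))
            hits += all(
                abs(res.estimates["logB:" + k] - asdmsa_mod.log_beta(k, 298.15))
                <= 3 * res.sd["logB:" + k]
                for k in ("MLH", "MLH2", "MLH3"))
        assert hits >= n_rep - 1

    def test_calibration_recovers_E0_and_pkw(self, water):
        comp = sq.SolutionComposition(C_HCl=0.008)
        protocol = sq.TitrationProtocol(initial=comp, titrant_concentration=0.1,
                                        volumes=np.linspace(0.0, 3.0, 41), T=298.15)
        el = sq.ElectrodeParams(E0=402.3)
        ds = sq.simulate_potentiometric(water, protocol, el, seed=7)
        res = sq.refine_potentiometric(ds, sq.RefinementSpec(model=water,
                                                             free=["E0", "pKw"]))
        assert res.converged
        assert abs(res.estimates["E0"] - 402.3) <= 3 * res.sd["E0"]
        assert abs(res.estimates["pKw"] - 13.75) <= 3 * res.sd["pKw"]

    def test_point_order_does_not_change_estimates(self, asdmsa_mod, protocol_mod):
        ds = _noisy_dataset(asdmsa_mod, protocol_mod, seed=17)
        res_a = sq.refine_potentiometric(
            ds, sq.RefinementSpec(model=asdmsa_mod, free=FREE_BETAS))
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.volumes.size)
        # shuffled copy: volumes are no longer monotone, so rebuild via the
        # dataset container directly
        shuffled = sq.TitrationDataset(
            protocol=ds.protocol, volumes=ds.volumes[perm], emf=ds.emf[perm],
            electrode=ds.electrode, truth=ds.truth)
        res_b = sq.refine_potentiometric(
            shuffled, sq.RefinementSpec(model=asdmsa_mod, free=FREE_BETAS))
        for k in FREE_BETAS:
            assert res_b.estimates[k] == pytest.approx(res_a.estimates[k], abs=1e-6)

    def test_sd_shrinks_with_replicate_titrations(self, asdmsa_mod, protocol_mod):
        """Merging four replicates shrinks SDs roughly as 1/sqrt(4)."""
        single = _noisy_dataset(asdmsa_mod, protocol_mod, seed=900)
        res1 = sq.refine_potentiometric(
            single, sq.RefinementSpec(model=asdmsa_mod, free=FREE_BETAS))
        merged = [_noisy_dataset(asdmsa_mod, protocol_mod, seed=900 + i) for i in range(4)]
        res4 = sq.refine_potentiometric(
            merged, sq.RefinementSpec(model=asdmsa_mod, free=FREE_BETAS))
        for k in FREE_BETAS:
            ratio = res4.sd[k] / res1.sd[k]
            assert ratio == pytest.approx(0.5, rel=0.2)

    def test_unidentifiable_parameter_reported_by_name(self, water):
        comp = sq.SolutionComposition(C_HCl=0.008)
        protocol = sq.TitrationProtocol(initial=comp, titrant_concentration=0.1,
                                        volumes=np.linspace(0.0, 1.0, 11), T=298.15)
        ds = sq.simulate_potentiometric(water, protocol,
                                        sq.ElectrodeParams(E0=400.0), seed=1)
        # C_M has no effect in a metal-free system
        with pytest.raises(IdentifiabilityError) as err:
            sq.refine_potentiometric(ds, sq.RefinementSpec(model=water,
                                                           free=["E0", "C_M"]))
        assert err.value.parameter == "C_M"

    def test_frozen_parameters_keep_input_values(self, asdmsa_mod, clean_ds):
        spec = sq.RefinementSpec(model=asdmsa_mod, free=["logB:MLH2"])
        res = sq.refine_potentiometric(clean_ds, spec)
        assert set(res.estimates) == {"logB:MLH2"}

    def test_free_list_must_be_known(self, asdmsa_mod):
        with pytest.raises(ModelError):
            sq.RefinementSpec(model=asdmsa_mod, free=["logB:XYZ"])
        with pytest.raises(ModelError):
            sq.RefinementSpec(model=asdmsa_mod, free=[])


@pytest.fixture(scope="module")
def uv_dataset(asdmsa_mod, uv_bands_mod):
    lam, eps = uv_bands_mod
    spectral = sq.SpectralModel(wavelengths=lam, epsilon=eps, sigma_A=0.0)
    comp = sq.SolutionComposition(C_M=5e-5, C_L=1e-4, C_HCl=2e-3)
    protocol = sq.TitrationProtocol(initial=comp, titrant_concentration=0.02,
                                    volumes=np.linspace(0.0, 4.0, 25), T=298.15)
    return sq.simulate_spectrophotometric(asdmsa_mod, protocol, spectral, seed=None)


@pytest.fixture(scope="module")
def uv_bands_mod():
    lam = np.arange(200.0, 351.0, 5.0)
    eps = {
        "L":    sq.gaussian_bands(lam, [(236, 18, 9000)]),
        "HL":   sq.gaussian_bands(lam, [(232, 17, 8200)]),
        "H2L":  sq.gaussian_bands(lam, [(226, 16, 7000)]),
        "H3L":  sq.gaussian_bands(lam, [(220, 15, 5600)]),
        "H4L":  sq.gaussian_bands(lam, [(214, 14, 4500)]),
        "MLH":  sq.gaussian_bands(lam, [(260, 20, 11000)]),
        "MLH2": sq.gaussian_bands(lam, [(252, 19, 9500)]),
        "MLH3": sq.gaussian_bands(lam, [(246, 18, 8000)]),
    }
    return lam, eps


class TestSpectrophotometric:
    def test_zero_noise_recovery_of_constants_and_epsilon(
            self, asdmsa_mod, uv_dataset, uv_bands_mod):
        lam, eps = uv_bands_mod
        guesses = {"MLH": 17.1, "MLH2": 26.4, "MLH3": 30.5}
        spec = sq.RefinementSpec(model=asdmsa_mod.with_log_beta(guesses, 298.15),
                                 free=FREE_BETAS)
        res, eps_fit = sq.refine_spectrophotometric(uv_dataset, spec)
        assert res.converged
        for k in ("MLH", "MLH2", "MLH3"):
            assert res.estimates["logB:" + k] == pytest.approx(
                asdmsa_mod.log_beta(k, 298.15), abs=1e-6)
        for lab, profile in eps.items():
            np.testing.assert_allclose(eps_fit.loc[lab].to_numpy(), profile,
                                       atol=1e-6 * profile.max() + 1e-9)

    def test_noisy_spectra_within_three_sd(self, asdmsa_mod, uv_bands_mod):
        """Two-stage workflow: ligand absorptivities known, complexes refined."""
        lam, eps = uv_bands_mod
        known = {k: eps[k] for k in ("L", "HL", "H2L", "H3L", "H4L")}
        spectral = sq.SpectralModel(wavelengths=lam, epsilon=eps, sigma_A=0.002)
        comp = sq.SolutionComposition(C_M=5e-5, C_L=1e-4, C_HCl=2e-3)
        protocol = sq.TitrationProtocol(initial=comp, titrant_concentration=0.02,
                                        volumes=np.linspace(0.0, 4.0, 25), T=298.15)
        hits = 0
        n_rep = 5
        for rep in range(n_rep):
            ds = sq.simulate_spectrophotometric(asdmsa_mod, protocol, spectral,
                                                seed=40 + rep)
            res, _ = sq.refine_spectrophotometric(
                ds, sq.RefinementSpec(model=asdmsa_mod, free=FREE_BETAS),
                known_epsilon=known)
            hits += all(
                abs(res.estimates["logB:" + k] - asdmsa_mod.log_beta(k, 298.15))
                <= 3 * res.sd["logB:" + k] for k in ("MLH", "MLH2", "MLH3"))
        assert hits >= n_rep - 1

    def test_overproposed_species_is_flagged(self, uv_bands_mod):
        """Data generated with 2 ligand species, model proposing a third."""
        lam, _ = uv_bands_mod
        truth = sq.build_model({
            "components": {"ligand": "L", "proton": "H"},
            "pKw": {"298.15": 13.75},
            "species": [
                {"stoich": [0, 1, 1], "logbeta": {"298.15": 9.0}},
                {"stoich": [0, 1, 2], "logbeta": {"298.15": 13.0}},
            ],
        })
        eps = {
            "L":   sq.gaussian_bands(lam, [(240, 18, 9000)]),
            "HL":  sq.gaussian_bands(lam, [(228, 16, 7000)]),
            "H2L": sq.gaussian_bands(lam, [(216, 14, 5200)]),
        }
        spectral = sq.SpectralModel(wavelengths=lam, epsilon=eps)
        comp = sq.SolutionComposition(C_L=1e-4, C_HCl=1e-3,
                                      full_protonation=2)
        protocol = sq.TitrationProtocol(initial=comp, titrant_concentration=0.02,
                                        volumes=np.linspace(0.0, 2.0, 21), T=298.15)
        ds = sq.simulate_spectrophotometric(truth, protocol, spectral, seed=None)
        proposed = sq.build_model({
            "components": {"ligand": "L", "proton": "H"},
            "pKw": {"298.15": 13.75},
            "species": [
                {"stoich": [0, 1, 1], "logbeta": {"298.15": 9.0}},
                {"stoich": [0, 1, 2], "logbeta": {"298.15": 13.0}},
                {"stoich": [0, 1, 3], "logbeta": {"298.15": 14.0}},  # spurious
            ],
        })
        res, _ = sq.refine_spectrophotometric(
            ds, sq.RefinementSpec(model=proposed, free=["logB:H3L"]))
        flagged = "H3L" in res.negligible or res.sd["logB:H3L"] > 1.0
        assert flagged


class TestModelSelection:
    @staticmethod
    def _variant(model, add=None, drop=()):
        species = [SpeciesLine(s.stoich, dict(s.log_beta_by_T), dict(s.sd_by_T), s.label)
                   for s in model.species if s.label not in drop]
        if add is not None:
            species.append(SpeciesLine(*add))
        return EquilibriumModel(list(model.components), species,
                                dict(model.pKw_by_T), model.medium)

    def test_generating_model_outranks_alternatives(self, asdmsa_mod, protocol_mod):
        ds = _noisy_dataset(asdmsa_mod, protocol_mod, seed=11)
        truth = sq.RefinementSpec(model=asdmsa_mod, free=FREE_BETAS, name="truth")
        over = sq.RefinementSpec(
            model=self._variant(asdmsa_mod, add=((1, 2, 0), {298.15: 20.0})),
            free=FREE_BETAS + ["logB:ML2"], name="over")
        under = sq.RefinementSpec(
            model=self._variant(asdmsa_mod, drop=("MLH", "MLH3")),
            free=["logB:MLH2"], name="under")
        report = sq.select_model([truth, over, under], ds)
        assert report.loc[0, "name"] == "truth"
        under_row = report[report["name"] == "under"].iloc[0]
        truth_row = report[report["name"] == "truth"].iloc[0]
        assert under_row["sigma_fit"] > truth_row["sigma_fit"]
        over_row = report[report["name"] == "over"].iloc[0]
        assert "ML2" in over_row["negligible"]

    def test_identical_candidates_tie_harmlessly(self, asdmsa_mod, protocol_mod):
        ds = _noisy_dataset(asdmsa_mod, protocol_mod, seed=23)
        a = sq.RefinementSpec(model=asdmsa_mod, free=FREE_BETAS, name="a")
        b = sq.RefinementSpec(model=asdmsa_mod, free=FREE_BETAS, name="b")
        report = sq.select_model([a, b], ds)
        sig = report["sigma_fit"]
        assert sig.iloc[0] == pytest.approx(sig.iloc[1], rel=1e-9)

    def test_single_candidate_rejected(self, asdmsa_mod, protocol_mod):
        ds = _noisy_dataset(asdmsa_mod, protocol_mod, seed=23)
        with pytest.raises(ModelError):
            sq.select_model([sq.RefinementSpec(model=asdmsa_mod, free=FREE_BETAS)], ds)
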