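"""CSP weighting, the multi-ligand binding model, and the global fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from synucalc.errors import FitError, InputError
from synucalc import simulate
from synucalc.nmr_csp import (
    ShiftRecord,
    binding_model_chiB,
    chi_B,
    compute_csp,
    detect_broadening,
    fit_binding,
    rank_perturbed_residues,
)
from synucalc.regions import CALCIUM_SHIFT_SITES


def _rec(residue, dH, dN, intensity=1.0):
    return ShiftRecord(residue=residue, delta_H=dH, delta_N=dN, intensity=intensity)


class TestComputeCsp:
    @pytest.mark.parametrize(
        "dH,dN,expected",
        [
            (0.0, 0.0, 0.0),
            # sqrt(0.5*(0.1^2 + 0.15*1.0^2)) = 0.2828427
            (0.10, 1.00, 0.2828427),
        ],
    )
    def test_weighted_csp_values(self, dH, dN, expected):
        free = _rec(10, 8.0, 118.0)
        bound = _rec(10, 8.0 + dH, 118.0 + dN)
        assert compute_csp(free, bound).delta_delta == pytest.approx(expected, abs=1e-6)

    def test_residue_mismatch_rejected(self):
        with pytest.raises(InputError):
            compute_csp(_rec(1, 8.0, 118.0), _rec(2, 8.0, 118.0))

    @settings(max_examples=50, derandomize=True)
    @given(
        dH=st.floats(-1.0, 1.0, allow_nan=False),
        dN=st.floats(-5.0, 5.0, allow_nan=False),
    )
    def test_sign_invariance(self, dH, dN):
        free = _rec(5, 8.0, 118.0)
        plus = compute_csp(free, _rec(5, 8.0 + dH, 118.0 + dN)).delta_delta
        minus = compute_csp(free, _rec(5, 8.0 - dH, 118.0 - dN)).delta_delta
        assert plus == pytest.approx(minus, rel=1e-12, abs=1e-15)


class TestChiB:
    @pytest.mark.parametrize(
        "obs,sat,expected", [(0.2, 0.2, 1.0), (0.0, 0.2, 0.0), (0.05, 0.20, 0.25)]
    )
    def test_ratio(self, obs, sat, expected):
        assert chi_B(obs, sat) == pytest.approx(expected)

    def test_clipped_above_one(self):
        assert chi_B(0.3, 0.2) == 1.0

    def test_zero_saturation_rejected(self):
        with pytest.raises(InputError):
            chi_B(0.1, 0.0)


def _chi_mass_action(P, C, KD, L):
    """Independent oracle: root-finding on the mass-action equilibrium.

    With bound complex concentration B, free protein P-B and free ligand
    clusters C/L - B, K_D = (P-B)(C/L-B)/B; chi_B = B/P.
    """
    CL = C / L
    hi = min(P, CL)
    if hi <= 0:
        return 0.0
    f = lambda B: B * KD - (P - B) * (CL - B)
    return brentq(f, 0.0, hi, xtol=1e-14, maxiter=200) / P


class TestBindingModel:
    def test_zero_ligand_gives_zero(self):
        assert binding_model_chiB(200.0, 0.0, 21.0, 7.8) == 0.0

    def test_reference_value(self):
        # verified against the mass-action oracle before implementation
        assert binding_model_chiB(200.0, 1600.0, 21.0, 7.8) == pytest.approx(
            0.7348, abs=5e-4
        )

    def test_stoichiometric_limit(self):
        # K_D = 0 and exactly L ligands per protein saturates binding
        assert binding_model_chiB(200.0, 7.8 * 200.0, 0.0, 7.8) == pytest.approx(1.0)

    def test_matches_mass_action_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            P = rng.uniform(10, 500)
            C = rng.uniform(0, 5000)
            KD = rng.uniform(1, 500)
            L = rng.uniform(0.5, 20)
            assert binding_model_chiB(P, C, KD, L) == pytest.approx(
                _chi_mass_action(P, C, KD, L), abs=1e-6
            )

    def test_monotone_in_ligand(self):
        rng = np.random.default_rng(7)
        grid = np.linspace(0, 5000, 200)
        for _ in range(20):
            P = rng.uniform(10, 500)
            KD = rng.uniform(0.1, 500)
            L = rng.uniform(0.5, 20)
            chi = binding_model_chiB(P, grid, KD, L)
            assert np.all(np.diff(chi) >= -1e-12)
            assert np.all((chi >= 0) & (chi <= 1))

    def test_saturates_at_high_ligand(self):
        assert binding_model_chiB(200.0, 1e9, 21.0, 7.8) == pytest.approx(1.0, abs=1e-3)


class TestFitBinding:
    @pytest.mark.parametrize("kd,lig", [(50.0, 4.0), (5.0, 1.0), (200.0, 12.0)])
    def test_noiseless_round_trip(self, kd, lig):
        series, _ = simulate.generate_titration(
            seed=21, kd=kd, ligand_number=lig, noise=0.0
        )
        fit = fit_binding(series)
        assert fit.K_D == pytest.approx(kd, rel=0.01)
        assert fit.L == pytest.approx(lig, rel=0.01)

    def test_noisy_recovery_near_truth(self, ):
        kds = []
        for seed in range(1, 6):
            series, _ = simulate.generate_titration(seed=seed, preset="calcium_binding")
            kds.append(fit_binding(series).K_D)
        assert np.median(kds) == pytest.approx(21.0, rel=0.15)

    def test_saturation_shifts_recovered(self, titration_noiseless):
        series, truth = titration_noiseless
        fit = fit_binding(series)
        for r in fit.residues_used:
            assert fit.delta_sat_per_residue[r] == pytest.approx(
                truth["delta_sat"][str(r)], rel=0.02
            )

    def test_no_signal_raises(self):
        series, _ = simulate.generate_titration(seed=5, sites=(120,), noise=0.0)
        # explicit selection of an unperturbed residue -> nothing to fit
        with pytest.raises(FitError):
            fit_binding(series, residues=[10])

    def test_too_few_points_rejected(self):
        series, _ = simulate.generate_titration(
            seed=5, ligand_concs=(0.0, 100.0, 3600.0)
        )
        with pytest.raises(InputError):
            fit_binding(series)


class TestRanking:
    def test_no_perturbation_gives_empty(self):
        series, _ = simulate.generate_titration(seed=8, sites=(), noise=0.0)
        assert rank_perturbed_residues(series) == []

    def test_single_site(self):
        series, _ = simulate.generate_titration(seed=8, sites=(120,), noise=0.0)
        assert rank_perturbed_residues(series, top_k=1) == [120]

    def test_published_site_list_recovered(self):
        series, _ = simulate.generate_titration(seed=9, preset="calcium_binding")
        top = rank_perturbed_residues(series, top_k=len(CALCIUM_SHIFT_SITES))
        assert sorted(top) == sorted(CALCIUM_SHIFT_SITES)

    def test_c_terminal_localization(self):
        series, _ = simulate.generate_titration(seed=10, preset="calcium_binding")
        assert all(r >= 96 for r in rank_perturbed_residues(series))


class TestBroadening:
    def test_flat_intensities_empty(self):
        series, _ = simulate.generate_titration(seed=12, noise=0.0)
        assert detect_broadening(series, ratio_threshold=0.7) == []

    def test_attenuated_sites_detected(self):
        series, _ = simulate.generate_titration(
            seed=13,
            noise=0.0,
            broadening_sites=tuple(range(70, 76)),
            broadening_attenuation=0.5,
        )
        assert detect_broadening(series, ratio_threshold=0.7) == list(range(70, 76))

    def test_nac_region_containment(self):
        nac = tuple(range(61, 96, 3))
        series, _ = simulate.generate_titration(
            seed=14, preset="calcium_binding", broadening_sites=nac, broadening_attenuation=0.6
        )
        found = detect_broadening(series, ratio_threshold=0.7)
        assert found and all(61 <= r <= 95 for r in found)
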