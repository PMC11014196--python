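"""Field-solver verification against closed-form electrostatics."""

import numpy as np
import pytest

from glandeis.geometry import ElectrodeLayout, MacroDomain, MesoUnit, MicroUnit
from glandeis.solver import (
    _edge_conductances,
    analytic_halfspace_impedance,
    effective_admittivity,
    homogenise_cells,
    tetrapolar_impedance,
)


def collinear_unit_spacing():
    return ElectrodeLayout(
        positions={"I1": (-1.5, 0), "V1": (-0.5, 0), "V2": (0.5, 0), "V0": (1.5, 0)},
        radius=0.25,
    )


class TestAnalyticOracle:
    def test_unit_spacing_closed_form(self):
        z = analytic_halfspace_impedance(collinear_unit_spacing(), 1.0)
        assert z == pytest.approx(1000.0 / (2 * np.pi), rel=1e-12)

    def test_doubling_distances_halves_impedance(self):
        lay1 = collinear_unit_spacing()
        lay2 = ElectrodeLayout(
            positions={k: (2 * p[0], 2 * p[1]) for k, p in lay1.positions.items()},
            radius=0.25,
        )
        assert analytic_halfspace_impedance(lay2, 1.0) == pytest.approx(
            analytic_halfspace_impedance(lay1, 1.0) / 2, rel=1e-12
        )

    def test_swapping_sense_electrodes_flips_sign(self):
        lay = collinear_unit_spacing()
        swapped = ElectrodeLayout(
            positions={
                "I1": lay.positions["I1"],
                "V0": lay.positions["V0"],
                "V1": lay.positions["V2"],
                "V2": lay.positions["V1"],
            },
            radius=0.25,
        )
        assert analytic_halfspace_impedance(swapped, 1.0) == pytest.approx(
            -analytic_halfspace_impedance(lay, 1.0), rel=1e-12
        )


class TestHomogenisation:
    def test_homogeneous_composite_returns_material(self):
        x = y = z = np.linspace(0, 1e-5, 7)
        gamma = np.full((6, 6, 6), 0.7 + 0.2j)
        eff = homogenise_cells(x, y, z, gamma)
        assert eff == pytest.approx(0.7 + 0.2j, rel=1e-10)

    def test_series_slabs_harmonic_mean(self):
        """Two equal slabs stacked along the field axis: 2γ1γ2/(γ1+γ2)."""
        x = y = np.linspace(0, 1.0, 5)
        z = np.linspace(0, 1.0, 9)
        g1, g2 = 1.0 + 0.3j, 3.0 - 0.5j
        gamma = np.empty((4, 4, 8), dtype=complex)
        gamma[:, :, :4] = g1
        gamma[:, :, 4:] = g2
        eff = homogenise_cells(x, y, z, gamma)
        expected = 2 * g1 * g2 / (g1 + g2)
        assert abs(eff - expected) / abs(expected) < 1e-3

    def test_wiener_bounds_on_random_mixture(self, rng):
        """Any two-phase mixture lies between series and parallel bounds."""
        x = y = z = np.linspace(0, 1.0, 9)
        mask = rng.random((8, 8, 8)) < 0.4
        s1, s2 = 0.1, 2.0
        gamma = np.where(mask, s1, s2).astype(complex)
        phi = mask.mean()
        eff = homogenise_cells(x, y, z, gamma).real
        harmonic = 1.0 / (phi / s1 + (1 - phi) / s2)
        arithmetic = phi * s1 + (1 - phi) * s2
        assert harmonic - 1e-9 <= eff <= arithmetic + 1e-9

    def test_current_conservation_between_end_faces(self):
        """Net current in at one Dirichlet face leaves through the other."""
        x = y = np.linspace(0, 1.0, 6)
        z = np.linspace(0, 1.0, 6)
        rng = np.random.default_rng(0)
        gamma = (0.5 + rng.random((5, 5, 5))).astype(complex)
        # reproduce the solve, then compare face currents
        from glandeis.solver import _assemble, _solve

        L, idx = _assemble(x, y, z, gamma)
        lo, hi = idx[:, :, 0].ravel(), idx[:, :, -1].ravel()
        v = _solve(
            L,
            np.zeros(L.shape[0], dtype=complex),
            np.concatenate([lo, hi]),
            np.concatenate([np.ones(lo.size), np.zeros(hi.size)]),
        ).reshape(6, 6, 6)
        _, _, gz = _edge_conductances(x, y, z, gamma)
        i_in = np.sum(gz[:, :, 0] * (v[:, :, 0] - v[:, :, 1]))
        i_out = np.sum(gz[:, :, -1] * (v[:, :, -2] - v[:, :, -1]))
        assert abs(i_in - i_out) / abs(i_in) < 1e-9


class TestMicroEffective:
    def test_homogeneous_limit(self, materials):
        """Membrane off and cytoplasm == extracellular fluid: effective
        admittivity equals that single material's at any frequency."""
        from glandeis.materials import CompartmentMaterial, MaterialTable

        mats = MaterialTable(materials)
        mats["cytoplasm"] = CompartmentMaterial("cytoplasm", 1.2, 80.0)
        unit = MicroUnit(xcell=8.0, ycell=8.0, zcell=8.0, dECS=0.4, materials=mats)
        for f in (76.0, 10_000.0, 625_000.0):
            eff = effective_admittivity(unit, f, include_membrane=False)
            ref = mats.gamma("cytoplasm", f)
            assert abs(eff - ref) / abs(ref) < 1e-8

    def test_high_frequency_limit_approaches_membrane_free(self, materials):
        """As f → ∞ the membrane shorts out and the composite converges to
        the same geometry without a membrane."""
        unit = MicroUnit(xcell=8.53, ycell=8.53, zcell=8.53, dECS=0.3, materials=materials)
        f = 1e9
        with_m = effective_admittivity(unit, f)
        without = effective_admittivity(unit, f, include_membrane=False)
        assert abs(with_m.real - without.real) / without.real < 0.05

    def test_membrane_blocks_low_frequency_current(self, materials):
        unit = MicroUnit(xcell=8.53, ycell=8.53, zcell=8.53, dECS=0.3, materials=materials)
        low = effective_admittivity(unit, 76.0).real
        high = effective_admittivity(unit, 625_000.0).real
        assert low < high  # the beta-dispersion mechanism

    def test_mesh_convergence_monotone(self, materials):
        unit = MicroUnit(xcell=8.53, ycell=8.53, zcell=8.53, dECS=0.3, materials=materials)
        f = 10_000.0
        effs = {
            res: effective_admittivity(unit, f, resolution=res)
            for res in ("coarse", "default", "fine")
        }
        err_coarse = abs(effs["coarse"] - effs["fine"])
        err_default = abs(effs["default"] - effs["fine"])
        assert err_default < err_coarse

    def test_meso_requires_shell_gamma(self, materials):
        unit = MesoUnit(dfollicle=100.0, shell_thickness=8.0, dCT=2.0, materials=materials)
        with pytest.raises(ValueError, match="shell_gamma"):
            effective_admittivity(unit, 1000.0)


class TestTetrapolar:
    def homogeneous_domain(self, materials, sigma=1.0):
        return MacroDomain(
            gland="thyroid",
            include_fascia=False,
            dfascia=None,
            dpara=None,
            layout=ElectrodeLayout.collinear(),
            bulk_gamma=lambda f, s=sigma: complex(s),
            materials=materials,
        )

    def test_halfspace_matches_analytic_within_5pct(self, materials):
        dom = self.homogeneous_domain(materials)
        z = tetrapolar_impedance(dom, 1000.0, resolution="default", electrode_model="point")
        ref = analytic_halfspace_impedance(ElectrodeLayout.collinear(), 1.0)
        assert abs(z.Z.real - ref) / ref < 0.05

    def test_linearity_in_admittivity(self, materials):
        z1 = tetrapolar_impedance(
            self.homogeneous_domain(materials, 1.0), 1000.0, "coarse", "point"
        ).Z
        z2 = tetrapolar_impedance(
            self.homogeneous_domain(materials, 2.0), 1000.0, "coarse", "point"
        ).Z
        assert z2 == pytest.approx(z1 / 2, rel=1e-9)

    def test_reciprocity_drive_sense_swap(self, materials):
        lay = ElectrodeLayout.collinear()
        swapped = ElectrodeLayout(
            positions={
                "I1": lay.positions["V1"],
                "V0": lay.positions["V2"],
                "V1": lay.positions["I1"],
                "V2": lay.positions["V0"],
            },
            radius=lay.radius,
        )
        mk = lambda l: MacroDomain(
            "thyroid", False, None, None, l, lambda f: 0.4 + 0.05j, materials
        )
        za = tetrapolar_impedance(mk(lay), 5000.0, "coarse", "point").Z
        zb = tetrapolar_impedance(mk(swapped), 5000.0, "coarse", "point").Z
        assert za == pytest.approx(zb, rel=1e-9)

    def test_conductive_fascia_cap_lowers_high_frequency_impedance(self, materials):
        """A superficial layer more conductive than the bulk shunts current
        and pulls down Re Z at the top of the band."""
        from glandeis.materials import CompartmentMaterial, MaterialTable

        mats = MaterialTable(materials)
        mats["fascia"] = CompartmentMaterial("fascia", 2.0, 2000.0)
        lay = ElectrodeLayout.collinear()
        bulk = lambda f: 0.3 + 0.01j
        plain = MacroDomain("thyroid", False, None, None, lay, bulk, materials)
        capped = MacroDomain("thyroid", True, 0.3, None, lay, bulk, mats)
        z_plain = tetrapolar_impedance(plain, 625_000.0, "coarse").Z.real
        z_capped = tetrapolar_impedance(capped, 625_000.0, "coarse").Z.real
        assert z_capped < z_plain

    def test_fascia_thickness_to_zero_converges_to_no_fascia(self, materials):
        lay = ElectrodeLayout.collinear()
        bulk = lambda f: 0.3 + 0.01j
        plain = MacroDomain("thyroid", False, None, None, lay, bulk, materials)
        thin = MacroDomain("thyroid", True, 5e-4, None, lay, bulk, materials)
        z0 = tetrapolar_impedance(plain, 1000.0, "coarse").Z
        z1 = tetrapolar_impedance(thin, 1000.0, "coarse").Z
        assert abs(z1 - z0) / abs(z0) < 1e-3
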