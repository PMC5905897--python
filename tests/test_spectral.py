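"""Beer's law, Mie scattering, and the adjoint spectral Jacobian."""

import numpy as np
import pytest

import scdot as sd
from scdot.errors import DimensionError, NumericalError, ParameterError
from scdot.fem import DiffusionSolver
from scdot.phantom import TISSUE_BACKGROUNDS

from .oracles import spectral_block_oracle

# printed head-tissue optical table: per tissue, musp and mua at 750/850 nm
TISSUE_TABLE = {
    "scalp": {"musp": (0.74, 0.64), "mua": (0.017, 0.019)},
    "skull": {"musp": (0.94, 0.84), "mua": (0.012, 0.014)},
    "csf": {"musp": (0.3, 0.3), "mua": (0.004, 0.004)},
    "gray_matter": {"musp": (0.84, 0.6726), "mua": (0.018, 0.019)},
    "white_matter": {"musp": (1.19, 1.0107), "mua": (0.017, 0.021)},
}


def _printed_tol(value: float) -> float:
    """Half a unit in the last printed decimal place."""
    s = f"{value}"
    decimals = len(s.split(".")[1]) if "." in s else 0
    return 0.5 * 10.0**-decimals


class TestMieScattering:
    @pytest.mark.parametrize("tissue", sorted(TISSUE_TABLE))
    @pytest.mark.parametrize("iwl,wl", [(0, 750.0), (1, 850.0)])
    def test_reproduces_tissue_musp_values(self, tissue, iwl, wl):
        bg = TISSUE_BACKGROUNDS[tissue]
        expected = TISSUE_TABLE[tissue]["musp"][iwl]
        got = sd.mie_musp(bg["amplitude"], bg["power"], wl)
        assert abs(got - expected) <= _printed_tol(expected)

    def test_zero_power_returns_amplitude(self):
        assert sd.mie_musp(0.7, 0.0, 623.0) == pytest.approx(0.7)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ParameterError):
            sd.mie_musp(-1.0, 1.0, 750.0)
        with pytest.raises(ParameterError):
            sd.mie_musp(1.0, 1.0, 0.0)


class TestBeerLaw:
    def test_matrix_vector_example(self):
        table = sd.ExtinctionTable((750.0, 850.0), ("HbO2", "Hb"), [[1.0, 3.0], [2.0, 4.0]])
        field = sd.ChromophoreField({"HbO2": np.array([1.0]), "Hb": np.array([1.0])})
        assert sd.beer_law_mua(table, field, 750.0)[0] == pytest.approx(3.0)
        assert sd.beer_law_mua(table, field, 850.0)[0] == pytest.approx(7.0)

    def test_identity_extinction(self):
        table = sd.ExtinctionTable((750.0, 850.0), ("HbO2", "Hb"), np.eye(2))
        field = sd.ChromophoreField({"HbO2": np.array([0.01]), "Hb": np.array([0.02])})
        assert sd.beer_law_mua(table, field, 750.0)[0] == pytest.approx(0.01)
        assert sd.beer_law_mua(table, field, 850.0)[0] == pytest.approx(0.02)

    def test_zero_concentration_zero_absorption(self, extinction_table):
        field = sd.ChromophoreField({"HbO2": np.zeros(3), "Hb": np.zeros(3)})
        assert np.all(sd.beer_law_mua(extinction_table, field, 750.0) == 0)

    def test_unknown_wavelength_raises(self, extinction_table):
        field = sd.ChromophoreField({"HbO2": np.ones(2), "Hb": np.ones(2)})
        with pytest.raises(KeyError):
            sd.beer_law_mua(extinction_table, field, 633.0)

    @pytest.mark.parametrize("tissue", sorted(TISSUE_TABLE))
    def test_default_table_reproduces_tissue_mua(self, extinction_table, tissue):
        """The shipped hemoglobin extinction values reproduce the printed
        per-tissue absorption coefficients from the printed concentrations."""
        bg = TISSUE_BACKGROUNDS[tissue]
        field = sd.ChromophoreField(
            {"HbO2": np.array([bg["c1"]]), "Hb": np.array([bg["c2"]])}
        )
        for wl, expected in zip((750.0, 850.0), TISSUE_TABLE[tissue]["mua"]):
            got = sd.beer_law_mua(extinction_table, field, wl)[0]
            assert abs(got - expected) <= _printed_tol(expected)


class TestInvertBeerLaw:
    def test_round_trip(self, extinction_table):
        rng = np.random.default_rng(2)
        c = {"HbO2": rng.uniform(0.01, 0.1, 5), "Hb": rng.uniform(0.01, 0.1, 5)}
        field = sd.ChromophoreField(dict(c))
        mua = {
            wl: sd.beer_law_mua(extinction_table, field, wl) for wl in (750.0, 850.0)
        }
        back = sd.invert_beer_law(extinction_table, mua)
        for name in c:
            assert np.allclose(back[name], c[name], rtol=1e-10)

    def test_identity_extinction_returns_mua(self):
        table = sd.ExtinctionTable((750.0, 850.0), ("HbO2", "Hb"), np.eye(2))
        out = sd.invert_beer_law(table, {750.0: np.array([0.3]), 850.0: np.array([0.7])})
        assert out["HbO2"][0] == pytest.approx(0.3)
        assert out["Hb"][0] == pytest.approx(0.7)

    def test_singular_extinction_raises(self):
        table = sd.ExtinctionTable((750.0, 850.0), ("HbO2", "Hb"), [[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(NumericalError):
            sd.invert_beer_law(table, {750.0: np.array([0.1]), 850.0: np.array([0.1])})


class TestSpectralJacobianAssembly:
    def test_identity_extinction_preserves_blocks(self):
        rng = np.random.default_rng(3)
        J1, J2 = rng.standard_normal((4, 6)), rng.standard_normal((4, 6))
        table = sd.ExtinctionTable((750.0, 850.0), ("HbO2", "Hb"), np.eye(2))
        J = sd.spectral_jacobian([J1, J2], table, (750.0, 850.0))
        assert np.allclose(J.block(0, 0), J1)
        assert np.allclose(J.block(1, 1), J2)

    def test_zero_extinction_zeroes_block(self):
        rng = np.random.default_rng(4)
        J1, J2 = rng.standard_normal((4, 6)), rng.standard_normal((4, 6))
        table = sd.ExtinctionTable((750.0, 850.0), ("HbO2", "Hb"), [[1.0, 1.0], [0.0, 1.0]])
        J = sd.spectral_jacobian([J1, J2], table, (750.0, 850.0))
        assert np.all(J.block(0, 1) == 0)  # chromophore 2 at wavelength 1

    def test_matches_naive_loop_oracle(self, extinction_table):
        rng = np.random.default_rng(5)
        J1, J2 = rng.standard_normal((4, 6)), rng.standard_normal((4, 6))
        J = sd.spectral_jacobian([J1, J2], extinction_table, (750.0, 850.0))
        eps = [
            [extinction_table.value(c, wl) for c in ("HbO2", "Hb")]
            for wl in (750.0, 850.0)
        ]
        assert np.allclose(J.matrix, spectral_block_oracle([J1, J2], eps))
        assert J.shape == (8, 12)

    def test_mismatched_shapes_raise(self, extinction_table):
        with pytest.raises(DimensionError):
            sd.spectral_jacobian(
                [np.ones((4, 6)), np.ones((5, 6))], extinction_table, (750.0, 850.0)
            )


@pytest.fixture(scope="module")
def jac_setup(coarse_disk):
    n = coarse_disk.n_nodes
    field = sd.OpticalField(np.full(n, 0.018), np.full(n, 0.84))
    opt = sd.position_optodes(coarse_disk, 4, 4, "ring", musp_background=0.84)
    J = sd.wavelength_jacobian(coarse_disk, field, opt)
    return coarse_disk, field, opt, J


class TestAdjointJacobian:
    def test_entries_nonpositive_for_raw_amplitudes(self, jac_setup):
        _, _, _, J = jac_setup
        assert J.max() <= 1e-12 * np.abs(J).max()

    def test_columns_match_finite_differences(self, jac_setup):
        mesh, field, opt, J = jac_setup

        def measure(f):
            solver = DiffusionSolver(mesh, f)
            phi = solver.solve_sources(opt.interior_source_points)
            return sd.boundary_measurements(phi, mesh, opt)

        base = measure(field)
        h = 1e-6
        rng = np.random.default_rng(6)
        for node in rng.choice(mesh.n_nodes, size=4, replace=False):
            mua = field.mua.copy()
            mua[node] += h
            fd = (measure(sd.OpticalField(mua, field.musp)) - base) / h
            col = J[:, node]
            assert np.abs(fd - col).max() <= 1e-3 * np.abs(col).max()

    def test_sensitivity_concentrates_between_optodes(self, jac_setup):
        mesh, _, opt, J = jac_setup
        s = opt.source_positions[opt.link_table[0, 0]]
        d = opt.detector_positions[opt.link_table[0, 1]]
        midpoint = 0.5 * (s + d)
        near = np.argmin(np.linalg.norm(mesh.nodes - midpoint, axis=1))
        # the node farthest from both optodes of the link
        far = np.argmax(
            np.minimum(
                np.linalg.norm(mesh.nodes - s, axis=1),
                np.linalg.norm(mesh.nodes - d, axis=1),
            )
        )
        assert abs(J[0, far]) < abs(J[0, near])

    def test_spectral_chain_rule_finite_difference(self, coarse_disk, extinction_table):
        """Perturbing one chromophore changes the data by J @ dc."""
        n = coarse_disk.n_nodes
        conc = {"HbO2": np.full(n, 0.0548), "Hb": np.full(n, 0.0354)}
        field = sd.ChromophoreField(dict(conc), 0.5040, 1.7757)
        opt = sd.position_optodes(coarse_disk, 4, 4, "ring", musp_background=0.84)
        wavelengths = (750.0, 850.0)

        from scdot.recon import forward_measurements

        base = forward_measurements(
            coarse_disk, field, opt, extinction_table, wavelengths
        )
        subs = []
        for wl in wavelengths:
            mua = sd.beer_law_mua(extinction_table, field, wl)
            musp = np.broadcast_to(field.musp(wl), (n,))
            subs.append(
                sd.wavelength_jacobian(
                    coarse_disk, sd.OpticalField(mua, musp, wl), opt
                )
            )
        J = sd.spectral_jacobian(subs, extinction_table, wavelengths)

        node, h = 11, 1e-6
        pert = dict(conc)
        pert["HbO2"] = pert["HbO2"].copy()
        pert["HbO2"][node] += h
        moved = forward_measurements(
            coarse_disk,
            sd.ChromophoreField(pert, 0.5040, 1.7757),
            opt,
            extinction_table,
            wavelengths,
        )
        fd = (moved.vector() - base.vector()) / h
        dc = np.zeros(2 * n)
        dc[node] = 1.0
        predicted = J.matrix @ dc
        assert np.abs(fd - predicted).max() <= 1e-3 * np.abs(predicted).max()


class TestExtinctionTable:
    def test_two_wavelength_submatrix_well_conditioned(self, extinction_table):
        assert extinction_table.condition_number() < 100

    def test_csv_round_trip(self, tmp_path, extinction_table):
        path = tmp_path / "eps.csv"
        extinction_table.to_csv(path)
        back = sd.ExtinctionTable.from_csv(path)
        assert back.wavelengths == extinction_table.wavelengths
        assert back.chromophores == extinction_table.chromophores
        assert np.allclose(back.epsilon, extinction_table.epsilon)

    def test_generic_dye_single_chromophore(self):
        table = sd.generic_dye_table({650.0: 0.02, 710.0: 0.015})
        assert table.chromophores == ("dye",)
        assert table.value("dye", 650.0) == pytest.approx(0.02)

    def test_negative_entries_rejected(self):
        with pytest.raises(ParameterError):
            sd.ExtinctionTable((750.0,), ("HbO2",), [[-0.1]])
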