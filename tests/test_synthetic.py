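import json

import numpy as np
import pytest

from cphmdkit import (
    DataError,
    PanelSpec,
    TitrationModel,
    fraction_threshold,
    generate_dataset,
    read_lambda_xvg,
    simulate_lambda,
    stationary_se,
    theta_true,
)


class TestThetaTrue:
    def test_midpoint_is_half(self, single_site_model):
        assert theta_true(4.0, single_site_model) == pytest.approx(0.5)

    def test_closed_form_one_unit_above(self, single_site_model):
        assert theta_true(5.0, single_site_model) == pytest.approx(1 / 11)

    def test_symmetric_mixture_midpoint(self):
        m = TitrationModel(conformers=((0.5, 2.0), (0.5, 5.0)))
        assert theta_true(3.5, m) == pytest.approx(0.5)

    def test_equal_pka_mixture_degenerates(self, single_site_model):
        m2 = TitrationModel(conformers=((0.5, 4.0), (0.5, 4.0)))
        pH = np.linspace(1, 8, 15)
        np.testing.assert_allclose(theta_true(pH, m2), theta_true(pH, single_site_model))


class TestSimulateLambda:
    def test_determinism(self, single_site_model):
        a = simulate_lambda(single_site_model, 4.0, 5.0, seed=42)
        b = simulate_lambda(single_site_model, 4.0, 5.0, seed=42)
        assert np.array_equal(a.lam, b.lam) and np.array_equal(a.time, b.time)

    def test_seed_changes_trajectory(self, single_site_model):
        a = simulate_lambda(single_site_model, 4.0, 5.0, seed=1)
        b = simulate_lambda(single_site_model, 4.0, 5.0, seed=2)
        assert not np.array_equal(a.lam, b.lam)

    def test_equal_pka_mixture_reproduces_single_conformer(self, single_site_model):
        m2 = TitrationModel(conformers=((0.5, 4.0), (0.5, 4.0)))
        a = simulate_lambda(single_site_model, 4.0, 5.0, seed=9)
        b = simulate_lambda(m2, 4.0, 5.0, seed=9)
        np.testing.assert_array_equal(a.lam, b.lam)

    def test_fraction_matches_oracle_at_midpoint(self, single_site_model):
        traj = simulate_lambda(single_site_model, 4.0, 200.0, seed=5)
        est = fraction_threshold(traj).fraction
        se = stationary_se(4.0, 200.0, single_site_model)
        assert abs(est - 0.5) < 3 * se

    @pytest.mark.parametrize("pH", [1.0, 2.0, 3.5, 5.0, 6.5, 8.0])
    def test_mixture_fraction_matches_oracle(self, pH):
        # fast exchange relative to the run length so conformer occupancy converges
        m = TitrationModel(conformers=((0.5, 2.5), (0.5, 4.5)), exchange_time=5.0)
        traj = simulate_lambda(m, pH, 300.0, seed=7000 + int(pH * 10))
        est = fraction_threshold(traj).fraction
        se = stationary_se(pH, 300.0, m)
        assert abs(est - theta_true(pH, m)) < 3 * max(se, 1e-4)

    def test_emission_band_nearly_empty(self, single_site_model):
        traj = simulate_lambda(single_site_model, 4.0, 100.0, seed=3)
        in_band = np.mean((traj.lam > 0.2) & (traj.lam < 0.8))
        assert in_band < 0.10

    def test_lambda_within_truncation_bounds(self, single_site_model):
        traj = simulate_lambda(single_site_model, 4.0, 50.0, seed=8)
        assert traj.lam.min() >= -0.1 and traj.lam.max() <= 1.1

    def test_duration_too_short_rejected(self, single_site_model):
        with pytest.raises(DataError):
            simulate_lambda(single_site_model, 4.0, 0.05, seed=0)

    def test_invalid_models_rejected(self):
        with pytest.raises(DataError):
            TitrationModel(conformers=((0.7, 4.0), (0.7, 5.0)))  # weights sum > 1
        with pytest.raises(DataError):
            TitrationModel(conformers=((1.0, 4.0),), emission_sd=0.3)
        with pytest.raises(DataError):
            TitrationModel(conformers=())


class TestGenerateDataset:
    def _spec(self, seed=1):
        model = TitrationModel(conformers=((1.0, 3.5),))
        return PanelSpec(
            residues=[("A1", model), ("A2", model)],
            pH_grid=(3.0, 4.0),
            n_monomers=1,
            n_replicas=1,
            duration=1.0,
            seed=seed,
        )

    def test_file_count_and_manifest(self, tmp_path):
        manifest = generate_dataset(self._spec(), tmp_path / "d")
        assert len(manifest["files"]) == 4
        files = {e["file"] for e in manifest["files"]}
        assert len(files) == 4
        for entry in manifest["files"]:
            assert (tmp_path / "d" / entry["file"]).exists()
        on_disk = json.loads((tmp_path / "d" / "manifest.json").read_text())
        assert on_disk["models"]["A1"]["conformers"] == [[1.0, 3.5]]

    def test_same_seed_identical_tree(self, tmp_path):
        m1 = generate_dataset(self._spec(), tmp_path / "a")
        m2 = generate_dataset(self._spec(), tmp_path / "b")
        assert m1["files"] == m2["files"]
        for entry in m1["files"]:
            assert (tmp_path / "a" / entry["file"]).read_text() == (
                tmp_path / "b" / entry["file"]
            ).read_text()

    def test_replica_index_changes_subseed_and_data(self, tmp_path):
        spec = self._spec()
        spec.n_replicas = 2
        manifest = generate_dataset(spec, tmp_path / "d")
        by_key = {(e["replica"], e["pH"]): e for e in manifest["files"] if e["residue"] == "A1"}
        assert by_key[(0, 3.0)]["sub_seed"] != by_key[(1, 3.0)]["sub_seed"]
        a = read_lambda_xvg(tmp_path / "d" / by_key[(0, 3.0)]["file"])
        b = read_lambda_xvg(tmp_path / "d" / by_key[(1, 3.0)]["file"])
        assert not np.array_equal(a.lam, b.lam)

    def test_refuses_nonempty_dir(self, tmp_path):
        out = tmp_path / "d"
        out.mkdir()
        (out / "junk").write_text("x")
        with pytest.raises(DataError, match="not empty"):
            generate_dataset(self._spec(), out)
        generate_dataset(self._spec(), out, overwrite=True)  # and the flag unblocks
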