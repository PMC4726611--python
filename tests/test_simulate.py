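import numpy as np
import pandas as pd
import pytest

from oldowan import (
    BEHAVIORS,
    CoreSpec,
    ParameterError,
    SimParams,
    TaphonomyParams,
    apply_taphonomy,
    generate_cores,
    generate_experimental_assemblage,
    simulate_reduction,
)


class TestSpecValidation:
    def test_core_dimension_ordering_enforced(self):
        with pytest.raises(ParameterError):
            CoreSpec("c1", "basalt", length=50, width=80, thickness=30, weight=500)
        with pytest.raises(ParameterError):
            CoreSpec("c1", "basalt", length=80, width=50, thickness=30, weight=0)
        with pytest.raises(ParameterError):
            CoreSpec("c1", "granite", length=80, width=50, thickness=30, weight=500)

    def test_sim_params_validation(self):
        with pytest.raises(ParameterError):
            SimParams(n_cores=-1, material="basalt")
        with pytest.raises(ParameterError):
            SimParams(n_cores=1, material="basalt",
                      per_behavior_yield={"OBZ": 1.0})
        with pytest.raises(ParameterError):
            SimParams(n_cores=1, material="basalt",
                      measure_means={"SL": -1.0}, measure_sds={"SL": 0.1})

    def test_taphonomy_validation(self):
        with pytest.raises(ParameterError):
            TaphonomyParams(retention_fraction=1.5)
        with pytest.raises(ParameterError):
            TaphonomyParams(import_counts={"OBZ": 5})
        t = TaphonomyParams(retention_fraction={"OBA": 0.2, "OBB": 0.6})
        assert t.retention_for("OBA") == 0.2
        assert t.retention_for("") == pytest.approx(0.4)  # mean fallback


class TestReduction:
    def test_deterministic_for_fixed_seed(self):
        a = generate_experimental_assemblage(
            SimParams(n_cores=10, material="basalt", seed=42))
        b = generate_experimental_assemblage(
            SimParams(n_cores=10, material="basalt", seed=42))
        pd.testing.assert_frame_equal(a.flakes, b.flakes)
        pd.testing.assert_frame_equal(a.cores, b.cores)

    def test_first_removal_is_always_oba(self):
        params = SimParams(n_cores=0, material="basalt", seed=5)
        rng = np.random.default_rng(5)
        for core in generate_cores(
                SimParams(n_cores=20, material="basalt", seed=5), rng):
            flakes = simulate_reduction(core, params, rng)
            whole = flakes[flakes["whole"]]
            assert flakes.iloc[0]["behavior"] == "OBA"
            assert whole.iloc[0]["behavior"] == "OBA"

    def test_behavior_definitions_hold(self):
        a = generate_experimental_assemblage(
            SimParams(n_cores=60, material="quartzite", seed=9))
        whole = a.flakes[a.flakes["whole"]]
        oba = whole[whole["behavior"] == "OBA"]
        obc = whole[whole["behavior"] == "OBC"]
        obd = whole[whole["behavior"] == "OBD"]
        # OBA strikes an unmodified cortical edge; OBC a prior flake scar
        assert (oba["platform_cortex"] == 100.0).all()
        assert (obc["platform_cortex"] == 0.0).all()
        # OBD flakes are side-struck: wider than long
        assert (obd["width"] > obd["length"]).all()
        # dorsal cortex declines with reduction stage
        assert oba["dorsal_cortex"].mean() > obc["dorsal_cortex"].mean()

    def test_measurement_invariants(self):
        a = generate_experimental_assemblage(
            SimParams(n_cores=40, material="basalt", seed=13))
        f = a.flakes
        for c in ("length", "width", "thickness", "platform_area"):
            assert (f[c] > 0).all()
        assert (f["maximum_dimension"] >=
                np.maximum(f["length"], f["width"]) * (1 - 1e-9)).all()
        assert f["platform_cortex"].between(0, 100).all()
        assert f["dorsal_cortex"].between(0, 100).all()
        # platform halves partition the platform width
        assert np.allclose(
            f["left_platform_width"] + f["right_platform_width"],
            f["platform_width"])

    def test_yield_calibration(self):
        """Large-sample means land at the configured per-core yields."""
        a = generate_experimental_assemblage(
            SimParams(n_cores=400, material="basalt", seed=21))
        n = a.n_cores
        assert a.n_flakes / n == pytest.approx(8.67, abs=0.5)
        assert (a.flakes["behavior"] == "OBC").sum() / n == pytest.approx(
            2.02, abs=0.3)

    def test_nondiagnostic_pieces_unlabelled_and_broken(self):
        a = generate_experimental_assemblage(
            SimParams(n_cores=50, material="basalt", seed=3))
        broken = a.flakes[~a.flakes["whole"]]
        assert len(broken) > 0
        assert (broken["behavior"] == "").all()
        whole = a.flakes[a.flakes["whole"]]
        assert set(whole["behavior"]) <= set(BEHAVIORS)


class TestTaphonomy:
    def test_retention_fraction_binomial(self):
        a = generate_experimental_assemblage(
            SimParams(n_cores=200, material="basalt", seed=31))
        out = apply_taphonomy(a, TaphonomyParams(retention_fraction=0.6, seed=1))
        frac = out.n_flakes / a.n_flakes
        # 3-sigma binomial band around 0.6
        sigma = np.sqrt(0.6 * 0.4 / a.n_flakes)
        assert abs(frac - 0.6) < 3 * sigma + 1e-12
        assert out.labels_hidden

    def test_zero_retention_with_imports(self):
        a = generate_experimental_assemblage(
            SimParams(n_cores=9, material="quartzite", seed=32))
        taph = TaphonomyParams(retention_fraction=0.0,
                               import_counts={"OBC": 233}, seed=2)
        out = apply_taphonomy(a, taph)
        assert out.n_flakes == 233
        assert (out.flakes["behavior"] == "OBC").all()
        assert (out.flakes["material"] == "quartzite").all()
        # core inventory survives taphonomy untouched
        assert out.n_cores == 9

    def test_full_retention_is_identity_on_flakes(self):
        a = generate_experimental_assemblage(
            SimParams(n_cores=15, material="basalt", seed=33))
        out = apply_taphonomy(a, TaphonomyParams(retention_fraction=1.0, seed=3))
        pd.testing.assert_frame_equal(
            out.flakes.reset_index(drop=True), a.flakes.reset_index(drop=True))
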