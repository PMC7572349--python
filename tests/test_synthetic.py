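import dataclasses

import numpy as np
import pytest

from cmnet.effects import cohens_d
from cmnet.synthetic import (
    InjectedEffect,
    SyntheticConfig,
    SyntheticConfigError,
    config_from_dict,
    expected_connection_effect,
    folded_normal_moments,
    read_config,
    shift_for_effect,
    simulate_cohort,
)

MEAS = "cortical_thickness"


def make_config(**overrides):
    defaults = dict(
        n_group_a=20, n_group_b=20, n_rois=6,
        measurements=(MEAS,), hemispheres=("lh",), seed=3,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


# -- validation --------------------------------------------------------------

@pytest.mark.parametrize(
    "overrides, fieldname",
    [
        ({"n_group_a": 1}, "n_group_a"),
        ({"n_group_b": 0}, "n_group_b"),
        ({"baseline_sd": 0.0}, "baseline_sd"),
        ({"baseline_sd": -1.0}, "baseline_sd"),
        ({"vertices_per_roi": 0}, "vertices_per_roi"),
        ({"injected_effects": ((MEAS, 99, "female", 1.0),)}, "roi_index"),
        ({"injected_effects": (("bogus", 0, "female", 1.0),)}, "measurement"),
        ({"injected_effects": ((MEAS, 0, "bogus", 1.0),)}, "group"),
    ],
)
def test_invalid_config_names_field(overrides, fieldname):
    with pytest.raises(SyntheticConfigError, match=fieldname):
        make_config(**overrides)


def test_cohort_shape_and_labels(small_cohort):
    assert len(small_cohort.subjects) == 40
    assert set(small_cohort.labels) == {"male", "female"}
    table = small_cohort.tables[("cortical_thickness", "lh")]
    assert table.values.shape == (40, 6)


# -- determinism -------------------------------------------------------------

def test_seed_determinism_byte_identical(tmp_path):
    config = make_config(seed=17)
    paths = []
    for name in ("a.csv", "b.csv"):
        cohort = simulate_cohort(config)
        path = tmp_path / name
        cohort.write_csv(path)
        paths.append(path)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_different_seeds_differ():
    a = simulate_cohort(make_config(seed=1)).tables[(MEAS, "lh")].values
    b = simulate_cohort(make_config(seed=2)).tables[(MEAS, "lh")].values
    assert not np.allclose(a, b)


def test_zero_shift_identical_to_no_effect():
    null = simulate_cohort(make_config(seed=9))
    zero = simulate_cohort(
        make_config(seed=9, injected_effects=((MEAS, 2, "female", 0.0),))
    )
    assert np.array_equal(
        null.tables[(MEAS, "lh")].values, zero.tables[(MEAS, "lh")].values
    )


# -- effect structure --------------------------------------------------------

def test_effect_locality():
    config = make_config(injected_effects=((MEAS, 2, "female", 1.5),))
    for i in range(config.n_rois):
        for j in range(i + 1, config.n_rois):
            d = expected_connection_effect(config, MEAS, i, j)
            if 2 in (i, j):
                assert d > 0.3
            else:
                assert d == pytest.approx(0.0, abs=1e-12)


def test_expected_effect_zero_without_shift():
    assert expected_connection_effect(make_config(), MEAS, 0, 1) == 0.0


def test_expected_effect_group_swap_invariant():
    kwargs = dict(measurement=MEAS, roi_index=3, mean_shift=2.0)
    d_female = expected_connection_effect(
        make_config(injected_effects=(InjectedEffect(group="female", **kwargs),)),
        MEAS, 0, 3,
    )
    d_male = expected_connection_effect(
        make_config(injected_effects=(InjectedEffect(group="male", **kwargs),)),
        MEAS, 0, 3,
    )
    assert d_female == pytest.approx(d_male, rel=1e-12)


def test_expected_effect_domain_errors():
    config = make_config()
    with pytest.raises(SyntheticConfigError, match="distinct"):
        expected_connection_effect(config, MEAS, 1, 1)
    with pytest.raises(SyntheticConfigError, match="out of range"):
        expected_connection_effect(config, MEAS, 0, 77)


def test_folded_moments_against_scipy_closed_form():
    # hand-computed: mu=0 -> mean = sigma*sqrt(2/pi), var = sigma^2*(1 - 2/pi)
    mean, sd = folded_normal_moments(0.0, 2.0)
    assert mean == pytest.approx(2.0 * np.sqrt(2 / np.pi), rel=1e-12)
    assert sd == pytest.approx(2.0 * np.sqrt(1 - 2 / np.pi), rel=1e-12)
    assert folded_normal_moments(3.0, 0.0) == (3.0, 0.0)


def test_oracle_matches_large_monte_carlo(rng):
    """1e6-sample Monte-Carlo d vs the folded-normal closed form, within 0.01."""
    delta, sigma = 2.0, 1.0
    config = make_config(injected_effects=((MEAS, 1, "female", delta),))
    oracle = expected_connection_effect(config, MEAS, 0, 1)
    n = 1_000_000
    scale = sigma * np.sqrt(2.0)  # var of x_i - x_j
    a = np.abs(rng.normal(0.0, scale, size=n))
    b = np.abs(rng.normal(delta, scale, size=n))
    mc = abs(a.mean() - b.mean()) / ((a.std(ddof=1) + b.std(ddof=1)) / 2)
    assert oracle == pytest.approx(mc, abs=0.01)


def test_empirical_d_matches_oracle_at_n5000():
    config = make_config(
        n_group_a=5000, n_group_b=5000, n_rois=3,
        injected_effects=((MEAS, 1, "female", 1.0),), seed=21,
    )
    oracle = expected_connection_effect(config, MEAS, 0, 1)
    table = simulate_cohort(config).tables[(MEAS, "lh")]
    edge_values = np.abs(table.values[:, 0] - table.values[:, 1])
    eff = cohens_d(
        edge_values[table.labels == "male"], edge_values[table.labels == "female"]
    )
    assert eff.d == pytest.approx(oracle, abs=0.05)


def test_null_max_d_below_bruteforce_null_quantile(rng):
    """Mean over seeds of max |d| stays below the brute-force null 99th pctile."""
    n, n_rois = 200, 8
    iu = np.triu_indices(n_rois, k=1)

    def max_d(values):
        edges = np.abs(values[:, iu[0]] - values[:, iu[1]])
        a, b = edges[:n], edges[n:]
        num = np.abs(a.mean(axis=0) - b.mean(axis=0))
        den = (a.std(axis=0, ddof=1) + b.std(axis=0, ddof=1)) / 2
        return float((num / den).max())

    null = [max_d(rng.normal(size=(2 * n, n_rois))) for _ in range(300)]
    q99 = np.quantile(null, 0.99)
    observed = []
    for seed in range(20):
        cohort = simulate_cohort(
            make_config(n_group_a=n, n_group_b=n, n_rois=n_rois, seed=seed)
        )
        observed.append(max_d(cohort.tables[(MEAS, "lh")].values))
    assert np.mean(observed) < q99


def test_vertex_averaging_shrinks_sd_by_sqrt_v():
    v = 4
    base = make_config(n_group_a=2000, n_group_b=2000, n_rois=2, seed=8)
    averaged = dataclasses.replace(base, vertices_per_roi=v)
    sd_roi = simulate_cohort(base).tables[(MEAS, "lh")].values.std(axis=0, ddof=1)
    sd_vertex = simulate_cohort(averaged).tables[(MEAS, "lh")].values.std(axis=0, ddof=1)
    assert np.allclose(sd_vertex, sd_roi / np.sqrt(v), rtol=0.05)
    assert np.allclose(averaged.effective_sd(), 0.5)


def test_shift_for_effect_inverts_oracle():
    config = make_config()
    delta = shift_for_effect(config, MEAS, 0, 1, target_d=0.99)
    probed = dataclasses.replace(
        config, injected_effects=((MEAS, 1, "female", delta),)
    )
    assert expected_connection_effect(probed, MEAS, 0, 1) == pytest.approx(0.99, abs=1e-8)


# -- config file I/O ---------------------------------------------------------

def test_config_from_yaml(tmp_path):
    path = tmp_path / "config.yaml"
    path.write_text(
        "n_group_a: 4\n"
        "n_group_b: 5\n"
        "n_rois: 3\n"
        "measurements: [sulcal_depth]\n"
        "hemispheres: [lh]\n"
        "seed: 2\n"
        "injected_effects:\n"
        "  - {measurement: sulcal_depth, roi_index: 1, group: female, mean_shift: 0.7}\n"
    )
    config = read_config(path)
    assert config.n_group_b == 5
    assert config.injected_effects[0].mean_shift == 0.7


def test_config_unknown_key_rejected():
    with pytest.raises(SyntheticConfigError, match="unknown config keys"):
        config_from_dict({"n_group_a": 4, "n_group_b": 4, "bogus": 1})


def test_truth_csv(tmp_path):
    cohort = simulate_cohort(
        make_config(injected_effects=((MEAS, 1, "female", 0.7),))
    )
    path = tmp_path / "truth.csv"
    cohort.write_truth_csv(path)
    text = path.read_text()
    assert "measurement,roi_index,group,mean_shift" in text
    assert f"{MEAS},1,female,0.7" in text
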