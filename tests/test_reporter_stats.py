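"""Reporter extraction, channel normalization, coverage, group statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from midtail.proteoform_quant import SpectrumQuant
from midtail.reporter_stats import (
    channel_normalize,
    coverage_filter,
    extract_reporters,
    group_and_test,
)
from midtail.spectra_io import RunConfig, default_reporter_table
from conftest import make_spectrum


# ---------------------------------------------------------------------------
# extraction


def test_all_six_reporters_extracted(config):
    table = default_reporter_table()
    s = make_spectrum("s", [(mz, 100.0 + i) for i, mz in enumerate(table.values())])
    out = extract_reporters(s, table, config.reporter_tol_ppm)
    assert sorted(out) == sorted(table)
    assert not any(math.isnan(v) for v in out.values())


def test_no_reporter_peaks_all_missing(config):
    s = make_spectrum("s", [(500.0, 1.0)])
    out = extract_reporters(s, default_reporter_table(), config.reporter_tol_ppm)
    assert all(math.isnan(v) for v in out.values())


def test_peak_beyond_tolerance_of_both_channels_missing():
    table = {"126": 126.127726, "127": 127.124761}
    midpoint = (table["126"] + table["127"]) / 2  # ~0.5 away from each, >> 15 ppm
    s = make_spectrum("s", [(midpoint, 999.0)])
    out = extract_reporters(s, table, 15.0)
    assert all(math.isnan(v) for v in out.values())


def test_closest_in_tolerance_peak_wins():
    table = {"126": 126.127726}
    near = 126.127726 * (1 + 5e-6)
    far = 126.127726 * (1 - 12e-6)
    s = make_spectrum("s", [(far, 1.0), (near, 2.0)])
    out = extract_reporters(s, table, 15.0)
    assert out["126"] == 2.0


# ---------------------------------------------------------------------------
# normalization


def test_channel_normalize_two_channel_toy():
    m = pd.DataFrame({"a": [300.0, 100.0], "b": [150.0, 50.0]})
    out = channel_normalize(m)  # means (200, 100) -> factors (1, 2)
    assert out["a"].tolist() == [300.0, 100.0]
    assert out["b"].tolist() == [300.0, 100.0]
    assert out.mean().tolist() == [200.0, 200.0]


def test_channel_normalize_identity_when_means_equal():
    m = pd.DataFrame({"a": [100.0, 300.0], "b": [300.0, 100.0]})
    pd.testing.assert_frame_equal(channel_normalize(m), m)


def test_channel_normalize_idempotent():
    rng = np.random.default_rng(5)
    m = pd.DataFrame(rng.lognormal(8, 1, size=(40, 6)), columns=list("abcdef"))
    m.iloc[3, 2] = np.nan
    once = channel_normalize(m)
    twice = channel_normalize(once)
    pd.testing.assert_frame_equal(once, twice)


def test_channel_normalize_single_cell():
    m = pd.DataFrame({"a": [42.0]})
    assert channel_normalize(m)["a"].tolist() == [42.0]


def test_channel_with_no_signal_raises():
    m = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
    with pytest.raises(ValueError, match="b"):
        channel_normalize(m)


# ---------------------------------------------------------------------------
# coverage


def _reporters(present):
    nan = float("nan")
    chans = ["126", "127", "128", "129", "130", "131"]
    return {ch: (1.0 if ch in present else nan) for ch in chans}


def test_coverage_all_present_passes(config):
    assert coverage_filter(
        _reporters({"126", "127", "128", "129", "130", "131"}),
        config.channel_conditions,
    )


def test_coverage_exactly_two_per_condition_passes(config):
    assert coverage_filter(
        _reporters({"126", "127", "129", "130"}), config.channel_conditions, 2
    )


def test_coverage_one_reporter_in_a_condition_fails(config):
    assert not coverage_filter(
        _reporters({"126", "127", "128", "129"}), config.channel_conditions, 2
    )


# ---------------------------------------------------------------------------
# grouping and testing


def _log2_matrix(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


def _quants(scan_to_key):
    return [SpectrumQuant(sid, {key: 1.0}, 1.0, 1) for sid, key in scan_to_key.items()]


def two_condition_config(**kw):
    return RunConfig(
        channel_conditions={
            "126": ("control", 1),
            "127": ("control", 2),
            "128": ("control", 3),
            "129": ("treated", 1),
            "130": ("treated", 2),
            "131": ("treated", 3),
        },
        contrasts=[("treated", "control")],
        **kw,
    )


def test_identical_pooled_values_give_zero_log2fc():
    cfg = two_condition_config()
    rows = {
        "s1": {"126": 1.0, "127": 2.0, "128": 3.0, "129": 1.0, "130": 2.0, "131": 3.0},
        "s2": {"126": 3.0, "127": 2.0, "128": 1.0, "129": 3.0, "130": 2.0, "131": 1.0},
    }
    (res,) = group_and_test(_quants({"s1": "H3unmod", "s2": "H3unmod"}),
                            _log2_matrix(rows), cfg)
    assert res.log2fc[("treated", "control")] == pytest.approx(0.0, abs=1e-12)


def test_welch_t_matches_hand_formula():
    """Pooled A={1,2,3}, B={2,3,4}: log2FC = -1, Welch t = -1.2247, df = 4."""
    cfg = two_condition_config()
    rows = {"s1": {"126": 2.0, "127": 3.0, "128": 4.0, "129": 1.0, "130": 2.0, "131": 3.0}}
    (res,) = group_and_test(_quants({"s1": "H3unmod"}), _log2_matrix(rows), cfg)
    assert res.log2fc[("treated", "control")] == pytest.approx(-1.0)
    # textbook Welch: t = (m_a - m_b)/sqrt(s_a^2/n_a + s_b^2/n_b), Welch df
    va = vb = 1.0  # sample variances of {1,2,3} and {2,3,4}
    t = -1.0 / math.sqrt(va / 3 + vb / 3)
    df = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
    expected_p = 2 * stats.t.sf(abs(t), df)
    assert res.p_value[("treated", "control")] == pytest.approx(expected_p, rel=1e-9)


def test_log2fc_antisymmetric_and_p_preserved():
    cfg_fwd = two_condition_config()
    cfg_rev = two_condition_config()
    cfg_rev.contrasts = [("control", "treated")]
    rng = np.random.default_rng(11)
    rows = {
        f"s{i}": {ch: float(v) for ch, v in zip(
            ["126", "127", "128", "129", "130", "131"], rng.normal(10, 1, 6))}
        for i in range(6)
    }
    quants = _quants({sid: "H3unmod" for sid in rows})
    (fwd,) = group_and_test(quants, _log2_matrix(rows), cfg_fwd)
    (rev,) = group_and_test(quants, _log2_matrix(rows), cfg_rev)
    assert fwd.log2fc[("treated", "control")] == pytest.approx(
        -rev.log2fc[("control", "treated")], abs=1e-12
    )
    assert fwd.p_value[("treated", "control")] == pytest.approx(
        rev.p_value[("control", "treated")], rel=1e-12
    )


def test_noise_free_fold_change_two_recovered_exactly():
    cfg = two_condition_config()
    base = 10.0
    rows = {
        f"s{i}": {
            "126": base + 0.1 * i, "127": base + 0.1 * i, "128": base + 0.1 * i,
            "129": base + 0.1 * i + 1.0, "130": base + 0.1 * i + 1.0,
            "131": base + 0.1 * i + 1.0,
        }
        for i in range(5)
    }
    (res,) = group_and_test(_quants({sid: "H3unmod" for sid in rows}),
                            _log2_matrix(rows), cfg)
    assert res.log2fc[("treated", "control")] == pytest.approx(1.0, abs=1e-12)


def test_condition_with_single_value_flagged_untestable():
    cfg = two_condition_config()
    nan = float("nan")
    rows = {"s1": {"126": 1.0, "127": 2.0, "128": nan, "129": 3.0, "130": nan, "131": nan}}
    (res,) = group_and_test(_quants({"s1": "H3unmod"}), _log2_matrix(rows), cfg)
    contrast = ("treated", "control")
    assert res.untestable[contrast]
    assert math.isnan(res.p_value[contrast])
    assert res.log2fc[contrast] == pytest.approx(3.0 - 1.5)


def test_chimeric_scan_contributes_to_every_group_by_default():
    cfg = two_condition_config()
    rows = {"s1": {"126": 1.0, "127": 1.0, "128": 1.0, "129": 2.0, "130": 2.0, "131": 2.0}}
    quants = [SpectrumQuant("s1", {"H3K9me1": 0.7, "H3K14me1": 0.3}, 100.0, 2)]
    results = group_and_test(quants, _log2_matrix(rows), cfg)
    assert {r.proteoform_key for r in results} == {"H3K9me1", "H3K14me1"}
    for r in results:
        assert r.log2fc[("treated", "control")] == pytest.approx(1.0)


def test_weight_by_fraction_shifts_means_not_fold_change():
    cfg = two_condition_config(weight_by_fraction=True)
    rows = {"s1": {"126": 1.0, "127": 1.0, "128": 1.0, "129": 2.0, "130": 2.0, "131": 2.0}}
    quants = [SpectrumQuant("s1", {"H3K9me1": 0.5}, 100.0, 2)]
    (res,) = group_and_test(quants, _log2_matrix(rows), cfg)
    assert res.condition_means["control"] == pytest.approx(1.0 + math.log2(0.5))
    assert res.log2fc[("treated", "control")] == pytest.approx(1.0)


def test_bh_correction_populates_q_values():
    cfg = two_condition_config(bh_correction=True)
    rng = np.random.default_rng(3)
    rows = {}
    scan_to_key = {}
    for g in range(8):
        for i in range(4):
            sid = f"g{g}s{i}"
            rows[sid] = {ch: float(v) for ch, v in zip(
                ["126", "127", "128", "129", "130", "131"], rng.normal(10, 0.5, 6))}
            scan_to_key[sid] = f"H3group{g}"
    results = group_and_test(_quants(scan_to_key), _log2_matrix(rows), cfg)
    contrast = ("treated", "control")
    for r in results:
        assert contrast in r.q_value
        assert r.q_value[contrast] >= r.p_value[contrast] - 1e-12
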