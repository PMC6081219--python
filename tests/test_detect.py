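import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import ampliconcnv as ac
from ampliconcnv.detect import (
    batch_qc,
    call_segments,
    copy_state,
    flag_sd_candidates,
    smooth,
    window_t_test,
)

from conftest import make_dataset, uniform_rows
from _oracles import welch_t_p


def profile_frame(values, rows=None):
    values = np.asarray(values, dtype=float)
    if rows is None:
        rows = uniform_rows(len(values))
    ds = make_dataset(rows, values[:, None])
    norm = pd.DataFrame({"S001": values}, index=ds.design.index)
    retained = pd.Series(True, index=ds.design.index)
    return ds.design, norm, retained


def test_smooth_constant_profile_stays_constant():
    design, norm, retained = profile_frame([2.0] * 9)
    sm = smooth(norm, design, retained)
    assert np.allclose(sm["S001"], 2.0)


def test_smooth_hand_computed_moving_mean():
    design, norm, retained = profile_frame([2, 2, 1, 1, 1, 1, 1, 2, 2])
    sm = smooth(norm, design, retained)["S001"].to_numpy()
    assert sm[4] == pytest.approx(1.0)                  # mean(1,1,1,1,1)
    assert sm[2] == pytest.approx((2 + 2 + 1 + 1 + 1) / 5)
    assert sm[0] == pytest.approx((2 + 2 + 1) / 3)      # truncated edge window


def test_smooth_three_amplicon_gene_uses_all_in_gene_values():
    design, norm, retained = profile_frame([1.0, 2.0, 3.0], uniform_rows(3))
    sm = smooth(norm, design, retained)
    assert np.allclose(sm["S001"], 2.0)  # every window truncates to the 3 values


def test_smooth_does_not_cross_gene_boundaries():
    rows = uniform_rows(3, gene="G1") + [
        ("B%03d" % i, "chr1", 10_000 + i * 300, 10_250 + i * 300, "G2", (i % 2) + 1)
        for i in range(3)
    ]
    values = [1.0, 1.0, 1.0, 3.0, 3.0, 3.0]
    design, norm, retained = profile_frame(values, rows)
    sm = smooth(norm, design, retained)["S001"].to_numpy()
    assert np.allclose(sm[:3], 1.0)
    assert np.allclose(sm[3:], 3.0)


@pytest.mark.parametrize("window", [0, 2, 4])
def test_smooth_rejects_even_or_nonpositive_window(window):
    design, norm, retained = profile_frame([2.0] * 5)
    with pytest.raises(ValueError, match="odd"):
        smooth(norm, design, retained, window=window)


@given(
    values=st.lists(
        st.floats(min_value=0.0, max_value=4.0, allow_nan=False),
        min_size=1, max_size=20,
    )
)
def test_smooth_never_widens_value_range(values):
    design, norm, retained = profile_frame(values, uniform_rows(len(values)))
    sm = smooth(norm, design, retained)["S001"]
    assert sm.min() >= min(values) - 1e-12
    assert sm.max() <= max(values) + 1e-12


def test_sd_flags_zero_sigma_yields_none():
    design, norm, retained = profile_frame([2.0] * 6)
    flags = flag_sd_candidates(norm, retained)
    assert not flags.to_numpy().any()


def test_sd_flags_population_sigma_example():
    # values {2,2,2,2,0}: mu=1.6, population sigma=0.8 -> only the 0 deviates
    design, norm, retained = profile_frame([2, 2, 2, 2, 0])
    flags = flag_sd_candidates(norm, retained)["S001"].to_numpy()
    assert flags.tolist() == [False, False, False, False, True]


def test_sd_flags_single_outlier_in_long_profile():
    rng = np.random.default_rng(0)
    values = 2.0 + rng.normal(0, 1e-3, 2000)
    values[777] = 0.5
    design, norm, retained = profile_frame(values, uniform_rows(2000))
    flags = flag_sd_candidates(norm, retained)["S001"]
    assert flags.sum() == 1 and bool(flags.iloc[777])


def test_sd_flag_count_invariant_under_row_permutation():
    rng = np.random.default_rng(1)
    values = rng.uniform(0, 4, 40)
    design, norm, retained = profile_frame(values, uniform_rows(40))
    flags = flag_sd_candidates(norm, retained)
    perm = rng.permutation(norm.index)
    flags_p = flag_sd_candidates(norm.loc[perm], retained.loc[perm])
    assert flags.to_numpy().sum() == flags_p.to_numpy().sum()


def test_sd_flags_thin_sample_warns_and_flags_nothing(caplog):
    design, norm, retained = profile_frame([2.0, 0.0])
    retained[:] = [True, False]
    with caplog.at_level("WARNING"):
        flags = flag_sd_candidates(norm, retained)
    assert not flags.to_numpy().any()
    assert any("<2 retained" in r.message for r in caplog.records)


def test_window_t_test_matches_textbook_welch():
    rng = np.random.default_rng(7)
    n = 30
    values = rng.uniform(1.0, 3.0, n)
    design, norm, retained = profile_frame(values, uniform_rows(n))
    pvals = window_t_test(norm, design, retained, window=5)["S001"]
    for start in range(n - 4):
        win = values[start : start + 5]
        rest = np.concatenate([values[:start], values[start + 5 :]])
        expected = welch_t_p(list(win), list(rest))
        scipy_expected = stats.ttest_ind(win, rest, equal_var=False).pvalue
        center = norm.index[start + 2]
        assert pvals[center] == pytest.approx(expected, abs=1e-10)
        assert pvals[center] == pytest.approx(scipy_expected, abs=1e-10)


def test_window_t_test_one_sample_mode_matches_scipy():
    rng = np.random.default_rng(8)
    values = rng.uniform(1.0, 3.0, 20)
    design, norm, retained = profile_frame(values, uniform_rows(20))
    pvals = window_t_test(norm, design, retained, window=5, mode="one_sample",
                          exclude_window=False)["S001"]
    global_mean = values.mean()
    for start in range(16):
        win = values[start : start + 5]
        expected = stats.ttest_1samp(win, popmean=global_mean).pvalue
        assert pvals[norm.index[start + 2]] == pytest.approx(expected, abs=1e-10)


def test_window_t_test_degenerate_and_null_conventions():
    # constant profile: zero variance in both groups, equal means -> p = 1
    design, norm, retained = profile_frame([2.0] * 12)
    pvals = window_t_test(norm, design, retained)["S001"]
    assert np.allclose(pvals.dropna(), 1.0)
    # clear loss window vs tight background -> p < 0.01
    rng = np.random.default_rng(3)
    values = np.concatenate([2.0 + rng.normal(0, 0.05, 20), np.ones(5)])
    design, norm, retained = profile_frame(values, uniform_rows(25))
    pvals = window_t_test(norm, design, retained)["S001"]
    assert pvals[norm.index[22]] < 0.01


def test_window_t_test_window_larger_than_sample_warns(caplog):
    design, norm, retained = profile_frame([2.0, 2.0, 2.0])
    with caplog.at_level("WARNING"):
        pvals = window_t_test(norm, design, retained, window=5)
    assert pvals["S001"].isna().all()
    assert any("no t-test windows" in r.message for r in caplog.records)


@pytest.mark.parametrize(
    "value, state",
    [(0.0, 0), (0.49, 0), (0.5, 1), (1.49, 1), (1.5, 2), (2.0, 2), (2.5, 2),
     (2.51, 3), (3.5, 3), (3.51, 4), (5.0, 4), (np.nan, -1)],
)
def test_copy_state_band_boundaries(value, state):
    assert copy_state(value) == state


def _detect_events(events, seed, noise="none", samples=None):
    cfg = ac.SimulationConfig(noise=noise, sexes="all_female", events=events,
                              seed=seed)
    ds, truth = ac.simulate_dataset(cfg)
    nb = ac.normalize_batch(ds)
    res = ac.detect_cnvs(nb, samples=samples)
    return ds, nb, res, truth


def test_call_segments_recovers_noiseless_events_exactly():
    events = [
        ac.CnvEvent(sample_id="S001", gene="GENE001", copy_number=1, first=3, last=12),
        ac.CnvEvent(sample_id="S002", gene="GENE002", copy_number=0, first=3, last=12),
        ac.CnvEvent(sample_id="S004", gene="GENE004", copy_number=3, first=3, last=12),
        ac.CnvEvent(sample_id="S006", chrom="chr21", copy_number=3),
    ]
    ds, nb, res, truth = _detect_events(
        events, seed=3, samples=["S001", "S002", "S004", "S006"]
    )
    calls = res.calls.set_index("sample_id")
    for _, ev in truth.events.iterrows():
        call = calls.loc[ev.sample_id]
        assert call["copy_state"] == ev.copy_number
        assert call["first_amplicon"] == ev.first_amplicon
        assert call["last_amplicon"] == ev.last_amplicon
        assert call["t_p_value"] < 1e-6
    # reported coordinates are 1-based inclusive
    first = ds.design.loc[calls.loc["S001", "first_amplicon"]]
    assert calls.loc["S001", "start"] == first["start"] + 1


def test_call_segments_all_diploid_sample_yields_no_calls():
    ds, nb, res, _ = _detect_events([], seed=4, samples=["S001"])
    assert len(res.calls) == 0


def test_call_segments_attaches_sd_flag_to_strong_events():
    events = [ac.CnvEvent(sample_id="S001", gene="GENE002", copy_number=0)]
    _, _, res, _ = _detect_events(events, seed=5, samples=["S001"])
    loss = res.calls[res.calls.copy_state == 0]
    assert len(loss) == 1 and bool(loss.iloc[0]["sd_flag"])


def test_batch_qc_noiseless_diploid_is_analyzable_with_zero_mad():
    cfg = ac.SimulationConfig(n_samples=6, noise="none", sexes="all_female", seed=1)
    ds, _ = ac.simulate_dataset(cfg)
    nb = ac.normalize_batch(ds)
    qc = batch_qc(nb)
    assert np.allclose(qc["mad"], 0.0, atol=1e-12)
    assert qc["analyzable"].all()


def test_batch_qc_pool_ratio_is_pool1_over_pool2_mean():
    rows = uniform_rows(4, pools=2)
    ds = make_dataset(rows, [[100, 10], [50, 10], [300, 10], [150, 10]])
    nb = ac.normalize_batch(ds)
    qc = batch_qc(nb)
    assert qc.loc["S001", "pool_ratio"] == pytest.approx(200 / 100)
    assert qc.loc["S002", "pool_ratio"] == pytest.approx(1.0)


def test_batch_qc_flags_overdispersed_batch():
    cfg = ac.fixture_configs(seed=11)["unanalyzable"]
    ds, _ = ac.simulate_dataset(cfg)
    qc = batch_qc(ac.normalize_batch(ds))
    assert not qc["analyzable"].any()


def test_bh_correction_is_monotone_and_bounded():
    rng = np.random.default_rng(9)
    values = rng.uniform(1.5, 2.5, 40)
    design, norm, retained = profile_frame(values, uniform_rows(40))
    from ampliconcnv.detect import apply_bh

    raw = window_t_test(norm, design, retained)
    adj = apply_bh(raw)
    mask = raw["S001"].notna()
    assert (adj.loc[mask, "S001"] >= raw.loc[mask, "S001"] - 1e-12).all()
    assert (adj.loc[mask, "S001"] <= 1.0 + 1e-12).all()
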