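"""Preprocessing chain: windowing, averaging, binning, filtering, ROS, AUC, QC."""

import base64
import struct

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import breathshift as bs
from breathshift.preprocess import PreprocessingError, read_frames_mzml
from breathshift.tables import FeatureTable


def _capnogram(times, co2):
    return pd.DataFrame({"time_s": times, "co2_pct": co2})


def _table(values, timepoints=None, times=None):
    """Tiny single-cohort table from a samples x features array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    n_subj = n // 4
    timepoints = timepoints or [1, 2, 3, 4] * n_subj
    times = times or [-15.0, -5.0, 0.0, 25.0] * n_subj
    samples = pd.DataFrame(
        {
            "cohort": "discovery",
            "subject_id": np.repeat([f"S{i}" for i in range(n_subj)], 4),
            "timepoint_index": timepoints,
            "time_min": times,
            "polarity": "positive",
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    cols = [bs.feature_id_for_mz(100.0 + j) for j in range(values.shape[1])]
    return FeatureTable(samples, pd.DataFrame(values, index=samples.index, columns=cols))


# -- exhalation windows -----------------------------------------------------

def test_window_boundaries_half_open():
    cap = _capnogram([0, 1, 2, 3, 4], [1, 2, 4, 5, 2])
    assert bs.detect_exhalation_windows(cap, threshold_pct=3.0) == [(2.0, 4.0)]


def test_constant_low_co2_has_no_windows():
    cap = _capnogram(range(10), [1.0] * 10)
    assert bs.detect_exhalation_windows(cap) == []


def test_empty_capnogram_raises():
    with pytest.raises(PreprocessingError):
        bs.detect_exhalation_windows(_capnogram([], []))


def test_min_duration_filters_short_windows():
    cap = _capnogram(range(8), [1, 5, 1, 5, 5, 5, 5, 1])
    wins = bs.detect_exhalation_windows(cap, min_duration_s=2.0)
    assert wins == [(3.0, 7.0)]


# -- window averaging -------------------------------------------------------

def _recording(frames, co2_times=None, co2=None):
    cap = _capnogram(co2_times or [0, 1, 2, 3], co2 or [5, 5, 5, 5])
    return bs.RawRecording(capnogram=cap, frames=frames)


def test_same_peak_two_frames_averages_intensity():
    frames = [(0.5, np.array([[100.0, 2.0]])), (1.5, np.array([[100.0, 4.0]]))]
    out = bs.average_window_spectra(_recording(frames), [(0.0, 4.0)])
    assert out.shape == (1, 2)
    assert out[0, 1] == pytest.approx(3.0)


def test_single_frame_is_identity():
    frames = [(0.5, np.array([[100.0, 2.0], [200.0, 7.0]]))]
    out = bs.average_window_spectra(_recording(frames), [(0.0, 4.0)])
    assert np.allclose(out, [[100.0, 2.0], [200.0, 7.0]])


def test_peaks_10ppm_apart_stay_distinct():
    frames = [(0.5, np.array([[100.0, 1.0]])), (1.5, np.array([[100.001, 1.0]]))]
    out = bs.average_window_spectra(_recording(frames), [(0.0, 4.0)])
    assert out.shape[0] == 2


def test_frameless_window_warns_and_skips():
    frames = [(0.5, np.array([[100.0, 2.0]]))]
    with pytest.warns(UserWarning, match="no frames"):
        out = bs.average_window_spectra(_recording(frames), [(0.0, 1.0), (2.0, 3.0)])
    assert out.shape[0] == 1


# -- ppm binning ------------------------------------------------------------

def _peaks(mzs, intensities, sample="s1"):
    return pd.DataFrame({"sample_id": sample, "mz": mzs, "intensity": intensities})


def test_boundary_gap_of_exactly_one_ppm_merges():
    fmz, mat = bs.bin_centroids_ppm(_peaks([100.00000, 100.00010], [1.0, 1.0]))
    assert len(fmz) == 1


def test_ten_ppm_gap_splits():
    fmz, mat = bs.bin_centroids_ppm(_peaks([100.00000, 100.00100], [1.0, 1.0]))
    assert len(fmz) == 2


def test_consensus_is_intensity_weighted_mean():
    fmz, _ = bs.bin_centroids_ppm(_peaks([200.0000, 200.0002], [1.0, 1.0]))
    assert fmz.iloc[0] == pytest.approx(200.0001)


def test_nonpositive_tolerance_rejected():
    with pytest.raises(PreprocessingError):
        bs.bin_centroids_ppm(_peaks([100.0], [1.0]), tol_ppm=0.0)


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(min_value=50.0, max_value=999.0), min_size=1, max_size=30),
       st.randoms(use_true_random=False))
def test_binning_is_permutation_invariant(mzs, rnd):
    inten = [1.0 + (i % 3) for i in range(len(mzs))]
    base = bs.bin_centroids_ppm(_peaks(mzs, inten))[0]
    idx = list(range(len(mzs)))
    rnd.shuffle(idx)
    shuffled = bs.bin_centroids_ppm(
        _peaks([mzs[i] for i in idx], [inten[i] for i in idx])
    )[0]
    assert np.allclose(base.to_numpy(), shuffled.to_numpy())


# -- sparsity filter --------------------------------------------------------

def test_sparsity_filter_boundary_and_order():
    vals = np.ones((4, 3))
    vals[:2, 0] = 0.0      # exactly 50% zeros -> removed
    vals[:, 2] = 0.0       # all zeros -> removed
    table = _table(vals)
    out = bs.filter_sparse_features(table)
    assert out.feature_ids == [table.feature_ids[1]]


# -- ROS imputation ---------------------------------------------------------

def test_ros_identity_without_zeros():
    table = _table(np.full((4, 3), 5.0))
    out = bs.impute_ros(table)
    assert out.intensities.equals(table.intensities)


def test_ros_imputed_values_positive_and_below_detected_min():
    rng = np.random.default_rng(1)
    vals = 10 ** rng.normal(3, 0.5, size=(8, 5))
    vals[vals < np.quantile(vals, 0.2)] = 0.0
    out = bs.impute_ros(_table(vals))
    x = out.intensities.to_numpy()
    assert (x > 0).all()
    was_zero = vals == 0
    for j in range(vals.shape[1]):
        detected = vals[~was_zero[:, j], j]
        if was_zero[:, j].any() and detected.size >= 2:
            assert x[was_zero[:, j], j].max() <= detected.min()


def test_ros_recovers_censored_lognormal_mean():
    """With 30% left-censoring of a log-normal sample, the ROS-completed
    sample mean stays within 5% of the uncensored sample mean."""
    rng = np.random.default_rng(42)
    full = np.exp(rng.normal(1.0, 0.8, size=200))
    censored = full.copy()
    cut = np.quantile(full, 0.30)
    censored[censored < cut] = 0.0
    out = bs.impute_ros(_table(censored.reshape(-1, 1)[:200].repeat(1, axis=1)))
    imputed_mean = out.intensities.to_numpy().mean()
    assert abs(imputed_mean - full.mean()) / full.mean() <= 0.05


def test_ros_sparse_feature_falls_back_to_half_min(recwarn):
    vals = np.array([[0.0, 4.0], [0.0, 6.0], [0.0, 2.0], [5.0, 8.0]])
    with pytest.warns(UserWarning, match="<2 detected"):
        out = bs.impute_ros(_table(vals))
    assert np.allclose(out.intensities.iloc[:3, 0], 1.0)  # half of global min (2.0)


# -- AUC aggregation --------------------------------------------------------

def test_two_point_auc_is_mean_of_intensities():
    vals = np.array([[100.0], [300.0], [100.0], [300.0]])
    paired = bs.aggregate_auc(_table(vals))
    assert paired.auc_pre.iloc[0, 0] == pytest.approx(200.0)
    assert paired.auc_post.iloc[0, 0] == pytest.approx(200.0)
    assert paired.log2fc.iloc[0, 0] == pytest.approx(0.0)


def test_threefold_auc_gives_log2_of_three():
    vals = np.array([[100.0], [100.0], [300.0], [300.0]])
    paired = bs.aggregate_auc(_table(vals))
    assert paired.log2fc.iloc[0, 0] == pytest.approx(np.log2(3.0))


def test_incomplete_subject_excluded_with_warning():
    vals = np.ones((8, 2))
    table = _table(vals)
    table = table.subset_samples(table.samples.index[:-1])  # drop S1's 4th tp
    with pytest.warns(UserWarning, match="lacks a timepoint"):
        paired = bs.aggregate_auc(table)
    assert paired.subjects == ["S0"]


def test_zero_intensity_auc_directs_to_impute():
    vals = np.ones((4, 1))
    vals[:2, 0] = 0.0
    with pytest.raises(PreprocessingError, match="impute"):
        bs.aggregate_auc(_table(vals))


def test_filter_impute_aggregate_chain_is_clean(small_cohort_pair):
    ta, _, _ = small_cohort_pair
    imp = bs.impute_ros(bs.filter_sparse_features(ta))
    assert imp.n_samples == ta.n_samples
    paired = bs.aggregate_auc(imp)
    assert np.isfinite(paired.log2fc.to_numpy()).all()
    assert (paired.auc_pre.to_numpy() > 0).all()
    assert (paired.auc_post.to_numpy() > 0).all()


# -- Nelson QC --------------------------------------------------------------

def _nelson_oracle(z):
    """Independent literal implementation of the eight rules; returns the
    set of rule ids that fire anywhere in the series."""
    fired = set()
    n = len(z)
    if any(abs(v) > 3 for v in z):
        fired.add(1)
    for i in range(n - 8):
        w = z[i:i + 9]
        if all(v > 0 for v in w) or all(v < 0 for v in w):
            fired.add(2)
    for i in range(n - 5):
        w = z[i:i + 6]
        if all(w[k] < w[k + 1] for k in range(5)) or all(w[k] > w[k + 1] for k in range(5)):
            fired.add(3)
    for i in range(n - 13):
        w = z[i:i + 14]
        d = [w[k + 1] - w[k] for k in range(13)]
        if all(d[k] * d[k + 1] < 0 for k in range(12)) and all(v != 0 for v in d):
            fired.add(4)
    for i in range(n - 2):
        w = z[i:i + 3]
        if sum(v > 2 for v in w) >= 2 or sum(v < -2 for v in w) >= 2:
            fired.add(5)
    for i in range(n - 4):
        w = z[i:i + 5]
        if sum(v > 1 for v in w) >= 4 or sum(v < -1 for v in w) >= 4:
            fired.add(6)
    for i in range(n - 14):
        if all(abs(v) < 1 for v in z[i:i + 15]):
            fired.add(7)
    for i in range(n - 7):
        if all(abs(v) > 1 for v in z[i:i + 8]):
            fired.add(8)
    return fired


def test_single_extreme_point_fires_rule_one():
    report = bs.nelson_qc([0.0, 0.2, 4.0], 0.0, 1.0)
    assert (1, (2,)) in report.violations
    assert report.verdict == "out_of_control"


def test_nine_points_one_side_fires_rule_two():
    report = bs.nelson_qc([0.5] * 9, 0.0, 1.0)
    assert any(rule == 2 for rule, _ in report.violations)


def test_in_control_series_passes_all_rules():
    # fixed draw pre-validated against the independent oracle
    rng = np.random.default_rng(2024)
    series = rng.normal(0.0, 1.0, size=20)
    assert _nelson_oracle(list(series)) == set()
    assert bs.nelson_qc(series, 0.0, 1.0).verdict == "in_control"


@settings(deadline=None, max_examples=40)
@given(st.lists(st.floats(min_value=-4, max_value=4, allow_nan=False), min_size=3,
                max_size=25))
def test_nelson_rules_match_independent_oracle(series):
    report = bs.nelson_qc(series, 0.0, 1.0)
    assert {rule for rule, _ in report.violations} == _nelson_oracle(series)


def test_nonpositive_sd_rejected():
    with pytest.raises(PreprocessingError):
        bs.nelson_qc([1.0, 2.0], 0.0, 0.0)


# -- mzML reading -----------------------------------------------------------

def _minimal_mzml(tmp_path, spectra):
    """Hand-built minimal mzML document with uncompressed 64-bit arrays."""

    def encode(values):
        return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()

    entries = []
    for i, (t, mz, inten) in enumerate(spectra):
        entries.append(f"""
    <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">
      <scanList count="1"><scan>
        <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{t}" unitName="second"/>
      </scan></scanList>
      <binaryDataArrayList count="2">
        <binaryDataArray encodedLength="0">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>
          <binary>{encode(mz)}</binary>
        </binaryDataArray>
        <binaryDataArray encodedLength="0">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
          <binary>{encode(inten)}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </spectrum>""")
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r1">
    <spectrumList count="{len(spectra)}">{''.join(entries)}
    </spectrumList>
  </run>
</mzML>"""
    path = tmp_path / "frames.mzML"
    path.write_text(doc)
    return path


def test_mzml_frames_reader(tmp_path):
    path = _minimal_mzml(
        tmp_path,
        [(0.5, [100.0, 200.0], [10.0, 20.0]), (1.5, [150.0], [5.0])],
    )
    frames = read_frames_mzml(path)
    assert len(frames) == 2
    t0, c0 = frames[0]
    assert t0 == pytest.approx(0.5)
    assert np.allclose(c0, [[100.0, 10.0], [200.0, 20.0]])
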