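"""Spectral pre- and post-processing for real-time breath metabolomics.

Turns per-session raw recordings (capnogram + centroid frames) into a clean
:class:`~breathshift.tables.FeatureTable` and aggregates the four timepoints
into paired pre/post values:

1. exhalation windows = maximal capnogram intervals with CO2 above the
   end-tidal threshold (3 %),
2. per-window averaging of centroid spectra (centroids matched at +-1 ppm),
3. ppm binning of pooled centroids into consensus features,
4. sparsity filtering (features with >= 50 % zeros dropped),
5. left-censored imputation by regression on order statistics (ROS),
6. time-normalized AUC aggregation of the two pre and two post measurements,
7. Nelson control-chart QC of the daily instrument-standard response.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .tables import FeatureTable, PairedAUC, feature_id_for_mz


class PreprocessingError(ValueError):
    pass


@dataclass
class RawRecording:
    """One measurement session: CO2 trace plus centroid spectral frames.

    ``capnogram`` has columns ``time_s`` (strictly increasing) and
    ``co2_pct`` in [0, 100].  ``frames`` is an ordered list of
    ``(time_s, centroids)`` with ``centroids`` an (n, 2) array of
    (m/z, intensity), m/z > 0 and intensity >= 0.
    """

    capnogram: pd.DataFrame
    frames: list
    polarity: str = "positive"

    def __post_init__(self) -> None:
        t = self.capnogram["time_s"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("capnogram times must be strictly increasing")
        co2 = self.capnogram["co2_pct"].to_numpy()
        if len(co2) and (co2.min() < 0 or co2.max() > 100):
            raise ValueError("CO2 must lie in [0, 100] %")
        for _, cent in self.frames:
            cent = np.asarray(cent)
            if cent.size and (np.any(cent[:, 0] <= 0) or np.any(cent[:, 1] < 0)):
                raise ValueError("centroids need m/z > 0 and intensity >= 0")


# ---------------------------------------------------------------------------
# Exhalation windows
# ---------------------------------------------------------------------------

def detect_exhalation_windows(
    capnogram: pd.DataFrame,
    threshold_pct: float = 3.0,
    min_duration_s: float = 0.0,
) -> list[tuple[float, float]]:
    """Maximal half-open [start, end) intervals with CO2 strictly above
    ``threshold_pct`` and duration >= ``min_duration_s``.

    The end of a window is the time of the first sample back at or below the
    threshold (or the extrapolated next sample time at the trace end).
    """
    if capnogram is None or len(capnogram) == 0:
        raise PreprocessingError("capnogram is empty")
    t = capnogram["time_s"].to_numpy(dtype=float)
    co2 = capnogram["co2_pct"].to_numpy(dtype=float)
    above = co2 > threshold_pct
    windows: list[tuple[float, float]] = []
    i = 0
    n = len(t)
    dt = np.median(np.diff(t)) if n > 1 else 1.0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            start = t[i]
            end = t[j + 1] if j + 1 < n else t[j] + dt
            if end - start >= min_duration_s:
                windows.append((float(start), float(end)))
            i = j + 1
        else:
            i += 1
    return windows


# ---------------------------------------------------------------------------
# Centroid averaging and ppm binning
# ---------------------------------------------------------------------------

def _cluster_sorted_ppm(mz: np.ndarray, intensity: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Greedy single-linkage 1-D clustering of sorted m/z values.

    A new bin starts when the gap from the previous peak exceeds ``tol_ppm``
    of the running intensity-weighted consensus (boundary inclusive: a gap of
    exactly tol_ppm stays in the bin).  Returns per-peak bin labels.
    """
    labels = np.empty(mz.size, dtype=int)
    if mz.size == 0:
        return labels
    bin_id = 0
    wsum = intensity[0]
    mzsum = mz[0] * max(intensity[0], 0.0)
    consensus = mz[0] if wsum <= 0 else mzsum / wsum
    labels[0] = 0
    prev = mz[0]
    for k in range(1, mz.size):
        gap = mz[k] - prev
        # inclusive boundary: a gap of exactly tol_ppm stays in the bin, with
        # a small relative epsilon so float representation cannot flip it
        if gap > consensus * tol_ppm * 1e-6 * (1.0 + 1e-8):
            bin_id += 1
            wsum = 0.0
            mzsum = 0.0
        labels[k] = bin_id
        w = max(intensity[k], 0.0)
        wsum += w
        mzsum += mz[k] * w
        consensus = mzsum / wsum if wsum > 0 else mz[k]
        prev = mz[k]
    return labels


def average_window_spectra(
    recording: RawRecording,
    windows: list[tuple[float, float]],
    tol_ppm: float = 1.0,
) -> np.ndarray:
    """Average centroid spectra over exhalation windows, then pool.

    Within each window, centroids of all frames are matched at +-``tol_ppm``
    and each matched centroid gets intensity = sum over frames / n frames
    (a peak absent from a frame contributes zero).  Window averages are then
    pooled across windows the same way.  Returns an (n, 2) array of
    (consensus m/z, mean intensity) sorted by m/z.

    A window containing no frames is skipped with a warning.
    """
    window_spectra = []
    for start, end in windows:
        peaks = [np.asarray(c) for t, c in recording.frames if start <= t < end]
        peaks = [p for p in peaks if p.size]
        n_frames = sum(1 for t, _ in recording.frames if start <= t < end)
        if n_frames == 0:
            warnings.warn(f"window [{start}, {end}) contains no frames; skipped")
            continue
        if not peaks:
            continue
        allp = np.vstack(peaks)
        order = np.argsort(allp[:, 0])
        mz, inten = allp[order, 0], allp[order, 1]
        labels = _cluster_sorted_ppm(mz, inten, tol_ppm)
        out = []
        for b in range(labels.max() + 1):
            sel = labels == b
            w = inten[sel]
            cmz = np.average(mz[sel], weights=w) if w.sum() > 0 else mz[sel].mean()
            out.append((cmz, inten[sel].sum() / n_frames))
        window_spectra.append(np.asarray(out))
    if not window_spectra:
        return np.empty((0, 2))
    pooled = np.vstack(window_spectra)
    order = np.argsort(pooled[:, 0])
    mz, inten = pooled[order, 0], pooled[order, 1]
    labels = _cluster_sorted_ppm(mz, inten, tol_ppm)
    n_windows = len(window_spectra)
    out = []
    for b in range(labels.max() + 1):
        sel = labels == b
        w = inten[sel]
        cmz = np.average(mz[sel], weights=w) if w.sum() > 0 else mz[sel].mean()
        out.append((cmz, inten[sel].sum() / n_windows))
    return np.asarray(out)


def bin_centroids_ppm(
    peaks: pd.DataFrame, tol_ppm: float = 1.0
) -> tuple[pd.Series, pd.DataFrame]:
    """Bin pooled centroids across samples into consensus features.

    Parameters
    ----------
    peaks :
        DataFrame with columns ``sample_id``, ``mz``, ``intensity`` — every
        centroid of every sample, in any order.
    tol_ppm :
        Gap tolerance; a new bin starts when the m/z gap to the previous
        (sorted) peak exceeds this many ppm of the running consensus.

    Returns
    -------
    (feature_mz, matrix) :
        ``feature_mz``: consensus m/z per feature id (intensity-weighted mean
        of bin members); ``matrix``: samples x features intensity matrix
        (intensities of a sample's peaks falling in one bin are summed;
        absent peaks are 0).
    """
    if tol_ppm <= 0:
        raise PreprocessingError("tol_ppm must be positive")
    df = peaks.sort_values("mz", kind="mergesort").reset_index(drop=True)
    mz = df["mz"].to_numpy(dtype=float)
    inten = df["intensity"].to_numpy(dtype=float)
    labels = _cluster_sorted_ppm(mz, inten, tol_ppm)
    df = df.assign(_bin=labels)
    consensus = df.groupby("_bin").apply(
        lambda g: np.average(g["mz"], weights=g["intensity"])
        if g["intensity"].sum() > 0
        else g["mz"].mean(),
        include_groups=False,
    )
    feature_ids = {b: feature_id_for_mz(m) for b, m in consensus.items()}
    df["_feature"] = df["_bin"].map(feature_ids)
    matrix = (
        df.pivot_table(index="sample_id", columns="_feature", values="intensity",
                       aggfunc="sum", fill_value=0.0)
        .rename_axis(index=None, columns=None)
    )
    # order feature columns by m/z
    ordered = [feature_ids[b] for b in sorted(feature_ids)]
    matrix = matrix[ordered]
    feature_mz = pd.Series({feature_ids[b]: float(m) for b, m in consensus.items()},
                           name="mz")[ordered]
    return feature_mz, matrix


# ---------------------------------------------------------------------------
# Sparsity filter and ROS imputation
# ---------------------------------------------------------------------------

def filter_sparse_features(table: FeatureTable, max_zero_frac: float = 0.5) -> FeatureTable:
    """Drop features whose zero fraction across all samples is >=
    ``max_zero_frac`` (a feature with exactly 50 % zeros is removed under the
    default); survivor order is preserved."""
    zero_frac = (table.intensities == 0).mean(axis=0)
    keep = [f for f in table.feature_ids if zero_frac[f] < max_zero_frac]
    return table.subset_features(keep)


def _ros_impute_column(values: np.ndarray, global_half_min: float) -> np.ndarray:
    """Regression-on-order-statistics imputation of the zeros in one feature.

    All n values are ranked with censored (zero) values lowest; Hazen
    plotting positions (k - 0.5)/n give standard-normal quantiles; ordinary
    least squares of log(detected) on the quantiles of the detected ranks is
    back-transformed at the censored ranks.  Imputed values are clamped to
    the feature's minimum detected value (censoring semantics) and are
    strictly positive.
    """
    out = values.astype(float).copy()
    censored = out == 0
    n_cens = int(censored.sum())
    if n_cens == 0:
        return out
    detected = out[~censored]
    if detected.size < 2:
        warnings.warn(
            "feature has <2 detected values; imputing half the global "
            "minimum positive intensity"
        )
        out[censored] = global_half_min
        return out
    n = out.size
    pp = (np.arange(1, n + 1) - 0.5) / n  # Hazen plotting positions
    q = sstats.norm.ppf(pp)
    det_sorted = np.sort(detected)
    slope, intercept = np.polyfit(q[n_cens:], np.log(det_sorted), 1)
    fitted = np.exp(intercept + slope * q[:n_cens])
    fitted = np.minimum(fitted, det_sorted[0])
    # assign imputed values to censored positions, smallest first (order
    # within ties is immaterial: all censored values were 0)
    out[np.flatnonzero(censored)] = fitted
    return out


def impute_ros(table: FeatureTable) -> FeatureTable:
    """Impute left-censored zeros feature-by-feature via regression on order
    statistics; detected values are unchanged.  Features with fewer than two
    detected values fall back to half the table's global minimum positive
    intensity (with a warning)."""
    x = table.intensities.to_numpy(dtype=float)
    positives = x[x > 0]
    if positives.size == 0:
        raise PreprocessingError("table contains no positive intensities")
    global_half_min = positives.min() / 2.0
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = _ros_impute_column(x[:, j], global_half_min)
    return FeatureTable(
        table.samples.copy(),
        pd.DataFrame(out, index=table.intensities.index, columns=table.intensities.columns),
    )


# ---------------------------------------------------------------------------
# AUC aggregation
# ---------------------------------------------------------------------------

def aggregate_auc(table: FeatureTable) -> PairedAUC:
    """Aggregate the four timepoints into per-subject pre/post values.

    The pre value is the trapezoidal area under timepoints 1-2 divided by
    their time interval (= the mean of the two intensities); the post value
    likewise for timepoints 3-4.  Subjects missing a timepoint are excluded
    with a warning.  Zero intensities make an AUC non-positive and raise —
    impute first.
    """
    rows_pre, rows_post, subjects = [], [], []
    for subject, grp in table.samples.groupby("subject_id", sort=False):
        tps = set(grp["timepoint_index"])
        if not {1, 2, 3, 4} <= tps:
            warnings.warn(f"subject {subject} lacks a timepoint; excluded")
            continue
        idx = {tp: grp.index[grp["timepoint_index"] == tp][0] for tp in (1, 2, 3, 4)}
        inten = table.intensities
        pre = (inten.loc[idx[1]].to_numpy() + inten.loc[idx[2]].to_numpy()) / 2.0
        post = (inten.loc[idx[3]].to_numpy() + inten.loc[idx[4]].to_numpy()) / 2.0
        if np.any(pre <= 0) or np.any(post <= 0):
            raise PreprocessingError(
                f"subject {subject} has a non-positive AUC; impute zeros before "
                "aggregation (impute_ros)"
            )
        rows_pre.append(pre)
        rows_post.append(post)
        subjects.append(subject)
    if not subjects:
        raise PreprocessingError("no subject has all four timepoints")
    cols = table.feature_ids
    return PairedAUC(
        auc_pre=pd.DataFrame(rows_pre, index=subjects, columns=cols),
        auc_post=pd.DataFrame(rows_post, index=subjects, columns=cols),
    )


# ---------------------------------------------------------------------------
# Nelson control-chart QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Instrument-suitability verdict from Nelson control-chart rules."""

    series: np.ndarray
    violations: list  # (rule_id, tuple of 0-based indices)
    verdict: str      # "in_control" | "out_of_control"


def _runs(mask: np.ndarray, length: int):
    """Yield index windows where ``mask`` holds for ``length`` consecutive points."""
    for i in range(mask.size - length + 1):
        if mask[i : i + length].all():
            yield tuple(range(i, i + length))


def nelson_qc(series, historical_mean: float, historical_sd: float) -> QCReport:
    """Evaluate all eight Nelson control-chart rules against historical
    control limits.  Violations carry the rule id (1-8) and the 0-based
    indices of the offending window; the verdict is ``in_control`` iff no
    rule fires."""
    if historical_sd <= 0:
        raise PreprocessingError("historical_sd must be positive")
    x = np.asarray(series, dtype=float)
    z = (x - historical_mean) / historical_sd
    v: list[tuple[int, tuple[int, ...]]] = []

    # 1: one point beyond 3 sigma
    for i in np.flatnonzero(np.abs(z) > 3):
        v.append((1, (int(i),)))
    # 2: nine in a row on the same side of the mean
    for side in (z > 0, z < 0):
        v.extend((2, w) for w in _runs(side, 9))
    # 3: six in a row steadily increasing or decreasing
    d = np.diff(z)
    for trend in (d > 0, d < 0):
        v.extend((3, tuple(range(w[0], w[0] + 6))) for w in _runs(trend, 5))
    # 4: fourteen in a row alternating up and down
    if d.size >= 13:
        alt = np.sign(d[1:]) * np.sign(d[:-1]) < 0
        nonzero = (d[1:] != 0) & (d[:-1] != 0)
        for w in _runs(alt & nonzero, 12):
            v.append((4, tuple(range(w[0], w[0] + 14))))
    # 5: two of three in a row beyond 2 sigma, same side
    for i in range(z.size - 2):
        for side in (1, -1):
            if np.sum(side * z[i : i + 3] > 2) >= 2:
                v.append((5, tuple(range(i, i + 3))))
    # 6: four of five in a row beyond 1 sigma, same side
    for i in range(z.size - 4):
        for side in (1, -1):
            if np.sum(side * z[i : i + 5] > 1) >= 4:
                v.append((6, tuple(range(i, i + 5))))
    # 7: fifteen in a row within 1 sigma
    v.extend((7, w) for w in _runs(np.abs(z) < 1, 15))
    # 8: eight in a row beyond 1 sigma from the mean (either side)
    v.extend((8, w) for w in _runs(np.abs(z) > 1, 8))

    seen = set()
    unique = []
    for rule, idx in v:
        if (rule, idx) not in seen:
            seen.add((rule, idx))
            unique.append((rule, idx))
    return QCReport(series=x, violations=unique,
                    verdict="in_control" if not unique else "out_of_control")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_capnogram_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"time_s", "co2_pct"} <= set(df.columns):
        raise PreprocessingError("capnogram TSV needs columns time_s, co2_pct")
    return df


def write_capnogram_tsv(capnogram: pd.DataFrame, path) -> None:
    capnogram[["time_s", "co2_pct"]].to_csv(path, sep="\t", index=False)


def read_frames_json(path) -> list:
    """Read spectral frames from the documented JSON layout:
    ``[{"time_s": t, "mz": [...], "intensity": [...]}, ...]``."""
    with open(path) as fh:
        payload = json.load(fh)
    frames = []
    for entry in payload:
        cent = np.column_stack([
            np.asarray(entry["mz"], dtype=float),
            np.asarray(entry["intensity"], dtype=float),
        ]) if entry["mz"] else np.empty((0, 2))
        frames.append((float(entry["time_s"]), cent))
    return frames


def write_frames_json(frames: list, path) -> None:
    payload = [
        {
            "time_s": float(t),
            "mz": np.asarray(c)[:, 0].tolist() if np.asarray(c).size else [],
            "intensity": np.asarray(c)[:, 1].tolist() if np.asarray(c).size else [],
        }
        for t, c in frames
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _decode_binary_array(elem, ns: str) -> np.ndarray:
    """Decode one mzML <binaryDataArray>: base64, optionally zlib-compressed,
    32- or 64-bit little-endian floats."""
    import base64
    import zlib

    accessions = {c.get("accession") for c in elem.findall(f"{ns}cvParam")}
    binary = elem.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"  # 32- vs 64-bit float
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_frames_mzml(path) -> list:
    """Read centroid frames from an mzML file.

    Supports the standard binary encodings (base64, optional zlib, 32/64-bit
    floats) and converts scan start times to seconds.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = "{%s}" % root.nsmap[None] if None in root.nsmap else ""
    frames = []
    for spec in root.iter(f"{ns}spectrum"):
        t_s = 0.0
        for cv in spec.findall(f"{ns}scanList/{ns}scan/{ns}cvParam"):
            if cv.get("accession") == "MS:1000016":  # scan start time
                t_s = float(cv.get("value"))
                if cv.get("unitName", "").startswith("minute"):
                    t_s *= 60.0
        mz = inten = np.empty(0)
        for arr in spec.findall(f"{ns}binaryDataArrayList/{ns}binaryDataArray"):
            accessions = {c.get("accession") for c in arr.findall(f"{ns}cvParam")}
            if "MS:1000514" in accessions:  # m/z array
                mz = _decode_binary_array(arr, ns)
            elif "MS:1000515" in accessions:  # intensity array
                inten = _decode_binary_array(arr, ns)
        cent = np.column_stack([mz, inten]) if mz.size else np.empty((0, 2))
        frames.append((t_s, cent))
    frames.sort(key=lambda f: f[0])
    return frames


def preprocess_recording(
    recording: RawRecording,
    threshold_pct: float = 3.0,
    min_duration_s: float = 0.0,
    tol_ppm: float = 1.0,
) -> np.ndarray:
    """Convenience chain: detect windows, average spectra, return the pooled
    (m/z, intensity) consensus spectrum of one session."""
    windows = detect_exhalation_windows(recording.capnogram, threshold_pct, min_duration_s)
    return average_window_spectra(recording, windows, tol_ppm)
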