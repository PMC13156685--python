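"""Central data containers for the breath-metabolomics pipeline.

The pipeline's exchange object is the :class:`FeatureTable`: a samples x
features intensity matrix together with per-sample metadata (cohort, subject,
timepoint 1-4, nominal time in minutes, ionization polarity) and per-feature
consensus m/z values.  Tables round-trip losslessly through a wide TSV layout
in which metadata columns come first and every feature column is named
``mz_<value>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_META_COLUMNS = [
    "sample_id",
    "cohort",
    "subject_id",
    "timepoint_index",
    "time_min",
    "polarity",
]

_FEATURE_RE = re.compile(r"^mz_(\d+(?:\.\d+)?)$")


def feature_id_for_mz(mz: float) -> str:
    """Canonical feature column name for a consensus m/z (6 decimals)."""
    return f"mz_{mz:.6f}"


def mz_of_feature_id(feature_id: str) -> float:
    m = _FEATURE_RE.match(feature_id)
    if m is None:
        raise ValueError(f"not a feature id: {feature_id!r}")
    return float(m.group(1))


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with sample metadata.

    Parameters
    ----------
    samples :
        One row per sample, indexed by ``sample_id``; columns ``cohort``,
        ``subject_id``, ``timepoint_index`` (1-4), ``time_min``, ``polarity``.
    intensities :
        Non-negative intensity matrix, same index as ``samples``; columns are
        feature ids of the form ``mz_<value>``.
    """

    samples: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.samples.index.equals(self.intensities.index):
            raise ValueError("samples and intensities must share a sample index")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    # -- basic queries -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def feature_mz(self) -> pd.Series:
        return pd.Series(
            [mz_of_feature_id(f) for f in self.intensities.columns],
            index=self.intensities.columns,
            name="mz",
        )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.samples.copy(), self.intensities.copy())

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.samples.copy(), self.intensities[list(feature_ids)].copy())

    def subset_samples(self, sample_ids) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(self.samples.loc[ids].copy(), self.intensities.loc[ids].copy())

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        meta = self.samples.reset_index().rename(columns={"index": "sample_id"})
        if "sample_id" not in meta.columns:
            meta.insert(0, "sample_id", self.samples.index)
        return pd.concat(
            [meta[SAMPLE_META_COLUMNS].reset_index(drop=True),
             self.intensities.reset_index(drop=True)],
            axis=1,
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        missing = [c for c in SAMPLE_META_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        feature_cols = [c for c in frame.columns if _FEATURE_RE.match(c)]
        samples = frame[SAMPLE_META_COLUMNS].set_index("sample_id")
        samples["timepoint_index"] = samples["timepoint_index"].astype(int)
        intensities = frame[feature_cols].copy()
        intensities.index = samples.index
        return cls(samples, intensities.astype(float))

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def concat_features(self, other: "FeatureTable") -> "FeatureTable":
        """Concatenate feature columns of two tables over the same samples
        (e.g. positive- and negative-polarity feature sets)."""
        if not self.samples.index.equals(other.samples.index):
            raise ValueError("tables must share samples to concatenate features")
        return FeatureTable(
            self.samples.copy(),
            pd.concat([self.intensities, other.intensities], axis=1),
        )


@dataclass
class PairedAUC:
    """Per subject x feature time-normalized AUCs for the pre and post pair.

    ``auc_pre``/``auc_post``/``log2fc`` are subjects x features DataFrames.
    The time-normalized AUC of a two-point pair is the trapezoidal area
    divided by the elapsed time, i.e. the arithmetic mean of the two
    intensities, so pre (10 min) and post (25 min) spans stay comparable.
    """

    auc_pre: pd.DataFrame
    auc_post: pd.DataFrame
    log2fc: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.log2fc is None:
            self.log2fc = np.log2(self.auc_post / self.auc_pre)

    @property
    def subjects(self) -> list:
        return list(self.auc_pre.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.auc_pre.columns)
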