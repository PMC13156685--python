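"""Synthetic two-cohort breath-study generator with known ground truth.

Emulates the study design the pipeline targets: two independent cohorts
(defaults 19 and 21 subjects, matching a discovery/validation pair), four
exhalation measurements per subject at nominal times -15, -5, 0 and +25
minutes around an acute cold-pressor intervention, and thousands of mass
spectral features.  Log10 baseline intensities are log-normal across
features; a chosen fraction of features is shifted multiplicatively after
the intervention by a known Log2 fold change; features are organized into
blocks that share a latent per-sample factor (inducing within-block
correlation, the substrate for the network-concordance stage); and
intensities below a per-dataset detection quantile are left-censored to
zero (the regime the regression-on-order-statistics imputation assumes).

Every draw is reproducible from the config seed, and the generator returns
the ground truth (affected features, true effects, block and pathway
assignments) so downstream stages can be tested for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    formula_to_string,
    golden_rules_filter,
    monoisotopic_mass,
    parse_formula,
)
from .tables import FeatureTable, feature_id_for_mz

LOG10_2 = np.log10(2.0)

#: Real metabolites reported as intervention-responsive in breath; anchors
#: for annotation tests (formula -> name).
ANCHOR_COMPOUNDS: dict[str, str] = {
    "C6H14N4O2": "arginine",
    "C4H9N3O2": "creatine",
    "C4H9NO3": "threonine",
    "C4H8N2O3": "asparagine",
}


class ConfigurationError(ValueError):
    """Invalid study-design configuration."""


@dataclass
class StudyDesignConfig:
    """Parameters of the simulated two-cohort, four-timepoint study.

    Defaults mirror the emulated study: cohorts of 19 and 21 subjects, four
    measurements per subject at -15/-5/0/+25 min, thousands of features with
    log-normal baselines, ~10% of features responding with |Log2FC| in
    [1.5, 2.5], block-correlated feature groups, and mild left-censoring.
    """

    n_subjects_per_cohort: tuple[int, int] = (19, 21)
    n_features: int = 2000
    frac_affected: float = 0.1
    effect_log2fc_range: tuple[float, float] = (1.5, 2.5)
    frac_down: float = 0.0
    noise_sd_log10: float = 0.15
    n_blocks: int = 20
    block_rho: float = 0.6
    censor_quantile: float = 0.05
    timepoints_min: tuple[float, float, float, float] = (-15.0, -5.0, 0.0, 25.0)
    n_pathways: int = 20
    seed: int = 0

    def validate(self) -> None:
        if any(n < 1 for n in self.n_subjects_per_cohort):
            raise ConfigurationError("each cohort needs at least one subject")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if not 0.0 <= self.frac_affected <= 1.0:
            raise ConfigurationError("frac_affected must lie in [0, 1]")
        if self.frac_affected > 0 and self.frac_affected * self.n_features < 1:
            raise ConfigurationError(
                "frac_affected * n_features must be >= 1 when an effect is requested"
            )
        if not 0.0 <= self.frac_down <= 1.0:
            raise ConfigurationError("frac_down must lie in [0, 1]")
        lo, hi = self.effect_log2fc_range
        if lo > hi or lo < 0:
            raise ConfigurationError("effect_log2fc_range must be 0 <= lo <= hi")
        if self.noise_sd_log10 < 0:
            raise ConfigurationError("noise_sd_log10 must be >= 0")
        if self.n_blocks < 1 or self.n_blocks > self.n_features:
            raise ConfigurationError("n_blocks must be in [1, n_features]")
        if not 0.0 <= self.block_rho < 1.0:
            raise ConfigurationError("block_rho must lie in [0, 1)")
        if not 0.0 <= self.censor_quantile < 0.5:
            raise ConfigurationError(
                "censor_quantile must lie in [0, 0.5) so the sparsity filter "
                "cannot remove every feature"
            )
        if len(self.timepoints_min) != 4 or np.any(np.diff(self.timepoints_min) <= 0):
            raise ConfigurationError("timepoints_min must be four strictly increasing times")
        if self.n_pathways < 1:
            raise ConfigurationError("n_pathways must be >= 1")


@dataclass
class GroundTruth:
    """Generator truth labels for recovery tests."""

    affected_feature_ids: set[str]
    true_log2fc: dict[str, float]
    block_assignment: dict[str, int]
    pathway_assignment: dict[str, list[str]]

    def to_json(self, path) -> None:
        payload = {
            "affected_feature_ids": sorted(self.affected_feature_ids),
            "true_log2fc": self.true_log2fc,
            "block_assignment": self.block_assignment,
            "pathway_assignment": self.pathway_assignment,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            affected_feature_ids=set(payload["affected_feature_ids"]),
            true_log2fc=payload["true_log2fc"],
            block_assignment={k: int(v) for k, v in payload["block_assignment"].items()},
            pathway_assignment=payload["pathway_assignment"],
        )


@dataclass
class CompoundRecord:
    compound_id: str
    formula: dict[str, int]
    monoisotopic_mass: float
    pathway_ids: list[str]
    name: str


@dataclass
class CompoundLibrary:
    """Toy compound library: formulas, exact masses, pathway memberships.

    Stands in for a reference metabolite database (e.g. a serum-metabolite
    set) in annotation and enrichment tests.
    """

    records: list[CompoundRecord]
    pathway_registry: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rec in self.records:
            expected = monoisotopic_mass(rec.formula)
            if abs(expected - rec.monoisotopic_mass) > 1e-4:
                raise ValueError(
                    f"{rec.compound_id}: stored mass {rec.monoisotopic_mass} "
                    f"inconsistent with formula ({expected:.6f})"
                )
            for pw in rec.pathway_ids:
                if pw not in self.pathway_registry:
                    raise ValueError(f"{rec.compound_id}: unknown pathway {pw}")

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self, compound_id: str) -> CompoundRecord:
        for rec in self.records:
            if rec.compound_id == compound_id:
                return rec
        raise KeyError(compound_id)

    def to_json(self, path) -> None:
        payload = {
            "pathway_registry": self.pathway_registry,
            "records": [
                {
                    "compound_id": r.compound_id,
                    "formula": formula_to_string(r.formula),
                    "monoisotopic_mass": r.monoisotopic_mass,
                    "pathway_ids": r.pathway_ids,
                    "name": r.name,
                }
                for r in self.records
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CompoundLibrary":
        with open(path) as fh:
            payload = json.load(fh)
        records = [
            CompoundRecord(
                compound_id=r["compound_id"],
                formula=parse_formula(r["formula"]),
                monoisotopic_mass=float(r["monoisotopic_mass"]),
                pathway_ids=list(r["pathway_ids"]),
                name=r["name"],
            )
            for r in payload["records"]
        ]
        return cls(records=records, pathway_registry=payload["pathway_registry"])


# ---------------------------------------------------------------------------
# Cohort-pair generation
# ---------------------------------------------------------------------------

def _draw_feature_mzs(
    rng: np.random.Generator,
    n_features: int,
    mz_pool: np.ndarray | None = None,
    frac_from_pool: float = 0.5,
) -> np.ndarray:
    """Feature m/z values in the instrument's 70-1000 scan range, spaced so
    that no two features collide within the 1 ppm binning tolerance.

    When ``mz_pool`` is given (e.g. adduct masses of a compound library), up
    to ``frac_from_pool`` of the features take a pool mass with <= 0.2 ppm
    jitter, so downstream annotation has matchable features.
    """
    chosen: list[np.ndarray] = []
    n_uniform = n_features
    if mz_pool is not None and len(mz_pool):
        pool = np.unique(np.asarray(mz_pool, dtype=float))
        pool = pool[(pool >= 70.0) & (pool <= 1000.0)]
        n_pool = min(int(round(frac_from_pool * n_features)), pool.size)
        if n_pool:
            picks = rng.choice(pool, size=n_pool, replace=False)
            jitter = rng.uniform(-0.2e-6, 0.2e-6, size=n_pool)
            chosen.append(picks * (1.0 + jitter))
            n_uniform = n_features - n_pool
    uniforms = rng.uniform(70.0, 1000.0, size=n_uniform)
    if chosen:
        # keep uniform draws away from pool masses so annotation is unambiguous
        pool_sorted = np.sort(chosen[0])
        idx = np.searchsorted(pool_sorted, uniforms)
        near = np.zeros(uniforms.size, dtype=bool)
        for off in (-1, 0):
            k = np.clip(idx + off, 0, pool_sorted.size - 1)
            near |= np.abs(uniforms - pool_sorted[k]) <= pool_sorted[k] * 5e-6
        uniforms = uniforms[~near]
    mzs = np.sort(np.concatenate(chosen + [uniforms])) if chosen else np.sort(uniforms)
    # enforce > 3 ppm spacing by nudging collisions upward
    for i in range(1, mzs.size):
        min_next = mzs[i - 1] * (1 + 3e-6)
        if mzs[i] < min_next:
            mzs[i] = min_next
    while mzs.size < n_features:
        extra = rng.uniform(70.0, 1000.0)
        if np.min(np.abs(mzs - extra)) > extra * 5e-6:
            mzs = np.sort(np.append(mzs, extra))
    return mzs[:n_features] if mzs.size > n_features else mzs


def generate_cohort_pair(
    config: StudyDesignConfig,
    mz_pool=None,
    frac_from_pool: float = 0.5,
) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Simulate the two cohorts over a shared feature space.

    Both cohorts share the feature ids, the set of affected features and the
    true Log2 fold changes (the conserved-response scenario); subject-level
    intensities are independent draws per cohort.

    Log10 intensity of sample s, feature f:

        x_sf = b_f + lam * z_{s, block(f)} + sigma * e_sf + beta_f * log10(2) * post(s)

    with b_f ~ N(4, 0.5) the feature baseline, sigma = ``noise_sd_log10``,
    lam = sigma * sqrt(rho / (1 - rho)) so that within-block Pearson
    correlation equals ``block_rho``, and beta_f the true Log2FC (0 for
    unaffected features).  Left-censoring then zeroes intensities below the
    per-dataset ``censor_quantile`` quantile.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_feat = config.n_features
    mzs = _draw_feature_mzs(rng, n_feat, mz_pool=mz_pool, frac_from_pool=frac_from_pool)
    feature_ids = [feature_id_for_mz(m) for m in mzs]

    baseline = rng.normal(4.0, 0.5, size=n_feat)
    block_of = np.arange(n_feat) % config.n_blocks
    rng.shuffle(block_of)

    n_affected = int(round(config.frac_affected * n_feat))
    affected_idx = rng.choice(n_feat, size=n_affected, replace=False)
    lo, hi = config.effect_log2fc_range
    magnitudes = rng.uniform(lo, hi, size=n_affected)
    signs = np.where(rng.random(n_affected) < config.frac_down, -1.0, 1.0)
    true_fc = np.zeros(n_feat)
    true_fc[affected_idx] = magnitudes * signs

    pathway_ids = [f"PW{i + 1:03d}" for i in range(config.n_pathways)]
    pathway_assignment = {
        fid: [pathway_ids[int(i)] for i in
              rng.choice(config.n_pathways, size=int(rng.integers(1, 3)), replace=False)]
        for fid in feature_ids
    }

    sigma = config.noise_sd_log10
    lam = sigma * np.sqrt(config.block_rho / (1.0 - config.block_rho))

    tables = []
    for cohort_name, n_subj in zip(("discovery", "validation"), config.n_subjects_per_cohort):
        n_samples = n_subj * 4
        post = np.tile(np.array([0.0, 0.0, 1.0, 1.0]), n_subj)  # timepoints 3,4
        z = rng.normal(size=(n_samples, config.n_blocks))
        eps = rng.normal(size=(n_samples, n_feat))
        log10_x = (
            baseline[None, :]
            + lam * z[:, block_of]
            + sigma * eps
            + LOG10_2 * true_fc[None, :] * post[:, None]
        )
        x = 10.0 ** log10_x
        if config.censor_quantile > 0:
            threshold = np.quantile(x, config.censor_quantile)
            x = np.where(x < threshold, 0.0, x)

        subjects = [f"{cohort_name[0].upper()}{i + 1:03d}" for i in range(n_subj)]
        meta = pd.DataFrame(
            {
                "cohort": cohort_name,
                "subject_id": np.repeat(subjects, 4),
                "timepoint_index": np.tile([1, 2, 3, 4], n_subj),
                "time_min": np.tile(np.asarray(config.timepoints_min, dtype=float), n_subj),
                "polarity": "positive",
            },
            index=pd.Index(
                [f"{s}_t{t}" for s in subjects for t in (1, 2, 3, 4)], name="sample_id"
            ),
        )
        intensities = pd.DataFrame(x, index=meta.index, columns=feature_ids)
        tables.append(FeatureTable(meta, intensities))

    truth = GroundTruth(
        affected_feature_ids={feature_ids[i] for i in affected_idx},
        true_log2fc={feature_ids[i]: float(true_fc[i]) for i in range(n_feat)},
        block_assignment={feature_ids[i]: int(block_of[i]) for i in range(n_feat)},
        pathway_assignment=pathway_assignment,
    )
    return tables[0], tables[1], truth


# ---------------------------------------------------------------------------
# Raw-recording generation
# ---------------------------------------------------------------------------

def generate_raw_recording(
    n_exhalations: int,
    co2_peak: float,
    feature_mzs,
    intensities,
    seed: int = 0,
    exhale_duration_s: float = 4.0,
    gap_duration_s: float = 3.0,
    sample_rate_hz: float = 10.0,
    frame_interval_s: float = 0.5,
    mz_jitter_ppm: float = 0.5,
):
    """Simulate one measurement session: capnogram plus spectral frames.

    The capnogram is a square-wave-like CO2 trace with ``n_exhalations``
    plateaus at ``co2_peak`` % separated by near-zero baselines (a typical
    guided-exhalation set has six).  Centroid frames are emitted every
    ``frame_interval_s``; frames inside exhalation plateaus carry the
    requested peaks with m/z jitter <= ``mz_jitter_ppm`` and mild intensity
    noise, frames outside carry nothing.
    """
    from .preprocess import RawRecording  # local import to avoid a cycle

    if co2_peak <= 0:
        raise ValueError("co2_peak must be positive")
    if n_exhalations < 1:
        raise ValueError("n_exhalations must be >= 1")
    feature_mzs = np.asarray(feature_mzs, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if feature_mzs.shape != intensities.shape:
        raise ValueError("feature_mzs and intensities must align")

    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate_hz
    total_s = n_exhalations * (exhale_duration_s + gap_duration_s) + gap_duration_s
    times = np.arange(0.0, total_s, dt)
    co2 = np.full_like(times, 0.5)
    windows = []
    for k in range(n_exhalations):
        start = gap_duration_s + k * (exhale_duration_s + gap_duration_s)
        end = start + exhale_duration_s
        windows.append((start, end))
        mask = (times >= start) & (times < end)
        co2[mask] = co2_peak
    capnogram = pd.DataFrame({"time_s": times, "co2_pct": co2})

    frames = []
    t = frame_interval_s / 2.0
    while t < total_s:
        in_window = any(s <= t < e for s, e in windows)
        if in_window and len(feature_mzs):
            jitter = rng.uniform(-mz_jitter_ppm, mz_jitter_ppm, size=feature_mzs.size) * 1e-6
            mz = feature_mzs * (1.0 + jitter)
            inten = intensities * rng.uniform(0.9, 1.1, size=intensities.size)
            order = np.argsort(mz)
            frames.append((t, np.column_stack([mz[order], inten[order]])))
        else:
            frames.append((t, np.empty((0, 2))))
        t += frame_interval_s

    return RawRecording(capnogram=capnogram, frames=frames, polarity="positive")


# ---------------------------------------------------------------------------
# Compound-library generation
# ---------------------------------------------------------------------------

def generate_compound_library(
    n_compounds: int, n_pathways: int, seed: int = 0
) -> CompoundLibrary:
    """Toy metabolite library with a fixed panel of real anchor compounds.

    The anchors (arginine, creatine, threonine, asparagine) carry their
    correct monoisotopic masses; the remaining compounds are random CHNOS
    formulas constrained to pass the heuristic formula filter.
    """
    if n_compounds < 1 or n_pathways < 1:
        raise ValueError("n_compounds and n_pathways must be >= 1")
    rng = np.random.default_rng(seed)
    pathway_ids = [f"PW{i + 1:03d}" for i in range(n_pathways)]
    registry = {pw: f"toy pathway {i + 1}" for i, pw in enumerate(pathway_ids)}

    records: list[CompoundRecord] = []

    def assign_pathways() -> list[str]:
        k = int(rng.integers(1, min(3, n_pathways) + 1))
        return [pathway_ids[int(i)] for i in rng.choice(n_pathways, size=k, replace=False)]

    for formula_str, name in ANCHOR_COMPOUNDS.items():
        formula = parse_formula(formula_str)
        records.append(
            CompoundRecord(
                compound_id=f"CPD{len(records) + 1:04d}",
                formula=formula,
                monoisotopic_mass=monoisotopic_mass(formula),
                pathway_ids=assign_pathways(),
                name=name,
            )
        )

    seen = {formula_to_string(r.formula) for r in records}
    while len(records) < n_compounds:
        c = int(rng.integers(2, 21))
        h = int(np.clip(round(c * rng.uniform(0.8, 2.5)), 1, 72))
        # even-electron neutral molecules: keep RDBE a whole number
        n = int(rng.integers(0, min(4, int(1.3 * c) + 1)))
        if (h + n) % 2 == 1:
            h += 1
        o = int(rng.integers(0, min(7, int(1.2 * c) + 1)))
        s = int(rng.integers(0, 2))
        formula = {e: v for e, v in (("C", c), ("H", h), ("N", n), ("O", o), ("S", s)) if v}
        key = formula_to_string(formula)
        if key in seen:
            continue
        ok, _ = golden_rules_filter(formula)
        if not ok:
            continue
        seen.add(key)
        records.append(
            CompoundRecord(
                compound_id=f"CPD{len(records) + 1:04d}",
                formula=formula,
                monoisotopic_mass=monoisotopic_mass(formula),
                pathway_ids=assign_pathways(),
                name=f"synthetic compound {len(records) + 1}",
            )
        )

    return CompoundLibrary(records=records[:max(n_compounds, len(ANCHOR_COMPOUNDS))],
                           pathway_registry=registry)
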