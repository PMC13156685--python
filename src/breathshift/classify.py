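"""Participant-grouped PCA + MLP classification of pre/post breath samples.

Every repeat draws a fresh subject-level split (all four measurements of a
participant travel together, avoiding leakage), standardizes and fits PCA
on the training partition only, trains a two-hidden-layer rectified-linear
MLP with early stopping on the held-out validation partition, and records
the post-intervention probabilities of the test samples.  Across repeats
the pooled predictions yield the ROC AUC, overall accuracy at the 0.5
decision boundary, per-measurement (timepoint 1-4) accuracies, and a
subjects x 4 matrix of mean post probabilities whose Ward-linkage
clustering summarizes individual response profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .tables import FeatureTable

PCA_GRID = (48, 64, 96, 128, 144)
HIDDEN_GRID = ((32, 32), (48, 48), (64, 64), (96, 96))


@dataclass
class ClassifierConfig:
    """Training grid cell and evaluation protocol.

    ``pca_components`` and ``hidden_sizes`` correspond to the evaluated
    grid {48, 64, 96, 128, 144} x {[32,32], [48,48], [64,64], [96,96]};
    splits are 90/5/5 at the participant level, repeated ``n_repeats``
    times.  Optimizer details (rectified-linear activations, adaptive-moment
    updates, early-stopping patience on validation loss) are exposed here
    because they are otherwise unconstrained.
    """

    pca_components: int = 48
    hidden_sizes: tuple[int, int] = (96, 96)
    n_repeats: int = 50
    split_fractions: tuple[float, float, float] = (0.90, 0.05, 0.05)
    seed: int = 0
    max_epochs: int = 500
    patience: int = 10
    learning_rate: float = 1e-3

    def validate(self, n_subjects: int | None = None) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if len(self.hidden_sizes) != 2:
            raise ValueError("hidden_sizes must name two hidden layers")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if n_subjects is not None:
            n_train = round(self.split_fractions[0] * n_subjects) * 4
            if self.pca_components > n_train:
                raise ValueError(
                    f"pca_components={self.pca_components} exceeds the "
                    f"~{n_train} training samples"
                )


@dataclass
class ClassifierReport:
    roc_auc: float
    roc_auc_mean_over_repeats: float
    accuracy: float
    per_measurement_accuracy: dict[int, float]
    probability_matrix: pd.DataFrame  # subjects x timepoints 1-4, mean post-prob
    cluster_labels: pd.Series = field(default=None)
    pooled: pd.DataFrame = field(default=None, repr=False)  # one row per test prediction


# ---------------------------------------------------------------------------
# Grouped splitting
# ---------------------------------------------------------------------------

def grouped_split(subject_ids, fractions=(0.90, 0.05, 0.05), seed: int = 0):
    """Partition subjects into disjoint train/validation/test sets.

    Sizes are the fractions rounded by largest remainder so they sum to the
    subject count; every non-zero fraction receives at least one subject.
    All four samples of a subject stay in its partition by construction.
    """
    subjects = list(subject_ids)
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects to form three partitions")
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    raw = fractions * n
    sizes = np.floor(raw).astype(int)
    # largest-remainder rounding, then guarantee one subject per non-zero part
    remainder_order = np.argsort(-(raw - sizes))
    for k in remainder_order[: n - sizes.sum()]:
        sizes[k] += 1
    for k in range(3):
        if fractions[k] > 0 and sizes[k] == 0:
            donor = int(np.argmax(sizes))
            sizes[donor] -= 1
            sizes[k] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [subjects[i] for i in order]
    train = set(shuffled[: sizes[0]])
    val = set(shuffled[sizes[0] : sizes[0] + sizes[1]])
    test = set(shuffled[sizes[0] + sizes[1] :])
    return train, val, test


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------

def _design_matrix(table: FeatureTable) -> np.ndarray:
    """log10 intensities; zeros are replaced by half the global minimum
    positive intensity first (the classifier accepts unimputed tables)."""
    x = table.intensities.to_numpy(dtype=float)
    positives = x[x > 0]
    if positives.size == 0:
        raise ValueError("table has no positive intensities")
    x = np.where(x > 0, x, positives.min() / 2.0)
    return np.log10(x)


def labels_from_timepoints(table: FeatureTable) -> np.ndarray:
    """Timepoints 1-2 are pre-intervention (0), 3-4 post-intervention (1)."""
    return (table.samples["timepoint_index"].to_numpy() >= 3).astype(int)


def _fit_mlp_early_stopping(
    x_train, y_train, x_val, y_val, config: ClassifierConfig, seed: int
) -> MLPClassifier:
    """Adam-trained rectified-linear MLP with early stopping monitored on
    the held-out validation partition (sklearn's built-in early stopping
    splits internally, which would break the grouped protocol)."""
    clf = MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_sizes),
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=1,
        warm_start=False,
        random_state=seed,
    )
    best_loss = np.inf
    best_params = None
    stall = 0
    classes = np.array([0, 1])
    for _ in range(config.max_epochs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-epoch convergence warnings
            clf.partial_fit(x_train, y_train, classes=classes)
        val_loss = log_loss(y_val, clf.predict_proba(x_val), labels=classes)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_params = ([w.copy() for w in clf.coefs_],
                           [b.copy() for b in clf.intercepts_])
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    if best_params is not None:
        clf.coefs_, clf.intercepts_ = best_params
    return clf


def train_evaluate(
    table: FeatureTable, labels=None, config: ClassifierConfig | None = None
) -> ClassifierReport:
    """Run the repeated grouped-split protocol for one grid cell.

    Per repeat: subject-grouped 90/5/5 split; standardization and PCA fit on
    the training partition only, test samples projected onto the same
    space; MLP trained with early stopping on the validation partition;
    test-sample post probabilities recorded.  Pooled over repeats: ROC AUC
    (both pooled over all test predictions and as the mean of per-repeat
    AUCs), accuracy at the 0.5 boundary, per-timepoint accuracies, and the
    per-subject x timepoint mean probability matrix.
    """
    config = config or ClassifierConfig()
    subjects_of = table.samples["subject_id"]
    complete = [
        s for s, grp in table.samples.groupby("subject_id", sort=False)
        if set(grp["timepoint_index"]) == {1, 2, 3, 4}
    ]
    keep = subjects_of.isin(complete)
    table = table.subset_samples(table.samples.index[keep])
    config.validate(n_subjects=len(complete))

    y = labels_from_timepoints(table) if labels is None else np.asarray(labels, dtype=int)
    x = _design_matrix(table)
    subj = table.samples["subject_id"].to_numpy()
    tp = table.samples["timepoint_index"].to_numpy()

    records = []
    rng = np.random.default_rng(config.seed)
    for rep in range(config.n_repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        train_s, val_s, test_s = grouped_split(complete, config.split_fractions, rep_seed)
        assert not (train_s & val_s or train_s & test_s or val_s & test_s)
        tr = np.isin(subj, list(train_s))
        va = np.isin(subj, list(val_s))
        te = np.isin(subj, list(test_s))

        scaler = StandardScaler().fit(x[tr])
        pca = PCA(n_components=config.pca_components, random_state=rep_seed)
        z_tr = pca.fit_transform(scaler.transform(x[tr]))
        z_va = pca.transform(scaler.transform(x[va]))
        z_te = pca.transform(scaler.transform(x[te]))

        clf = _fit_mlp_early_stopping(z_tr, y[tr], z_va, y[va], config, rep_seed)
        prob = clf.predict_proba(z_te)[:, 1]
        for i, p in zip(np.flatnonzero(te), prob):
            records.append(
                {"repeat": rep, "subject_id": subj[i], "timepoint_index": int(tp[i]),
                 "label": int(y[i]), "probability": float(p)}
            )

    pooled = pd.DataFrame(records)
    roc_auc = float(roc_auc_score(pooled["label"], pooled["probability"]))
    per_rep = []
    for _, grp in pooled.groupby("repeat"):
        if grp["label"].nunique() == 2:
            per_rep.append(roc_auc_score(grp["label"], grp["probability"]))
    accuracy = float(np.mean((pooled["probability"] >= 0.5) == (pooled["label"] == 1)))
    per_tp = {
        int(t): float(np.mean((grp["probability"] >= 0.5) == (grp["label"] == 1)))
        for t, grp in pooled.groupby("timepoint_index")
    }

    prob_matrix = pooled.pivot_table(
        index="subject_id", columns="timepoint_index", values="probability",
        aggfunc="mean",
    ).reindex(index=complete, columns=[1, 2, 3, 4])
    never_tested = prob_matrix.index[prob_matrix.isna().all(axis=1)]
    if len(never_tested):
        warnings.warn(
            f"{len(never_tested)} subject(s) never drawn into the test "
            "partition; probability rows are missing"
        )

    return ClassifierReport(
        roc_auc=roc_auc,
        roc_auc_mean_over_repeats=float(np.mean(per_rep)) if per_rep else float("nan"),
        accuracy=accuracy,
        per_measurement_accuracy=per_tp,
        probability_matrix=prob_matrix,
        pooled=pooled,
    )


# ---------------------------------------------------------------------------
# Probability-profile clustering
# ---------------------------------------------------------------------------

def cluster_probability_profiles(
    probability_matrix: pd.DataFrame, k: int = 3
) -> tuple[pd.Series, list]:
    """Ward-linkage clustering of per-subject probability profiles.

    Missing cells (subjects untested at a timepoint) are imputed with the
    subject's row mean (warned); the Euclidean Ward tree over the 4-dim
    profiles is cut into ``k`` clusters.  Returns (labels, leaf order).
    """
    pm = probability_matrix.copy()
    if pm.shape[0] < k:
        raise ValueError("k cannot exceed the number of subjects")
    if pm.isna().any().any():
        warnings.warn("missing probability cells imputed with row means")
        pm = pm.apply(lambda row: row.fillna(row.mean()), axis=1)
        if pm.isna().any().any():
            raise ValueError("subjects with entirely missing profiles cannot be clustered")
    link = hierarchy.linkage(pm.to_numpy(), method="ward", metric="euclidean")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    order = [pm.index[i] for i in hierarchy.leaves_list(link)]
    return pd.Series(labels, index=pm.index, name="cluster"), order


def run_grid(
    table: FeatureTable,
    pca_grid=PCA_GRID,
    hidden_grid=HIDDEN_GRID,
    n_repeats: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate every (PCA components, hidden sizes) grid cell; returns one
    row per cell with pooled AUC and accuracy."""
    rows = []
    for n_pc in pca_grid:
        for hidden in hidden_grid:
            cfg = ClassifierConfig(
                pca_components=n_pc, hidden_sizes=tuple(hidden),
                n_repeats=n_repeats, seed=seed,
            )
            report = train_evaluate(table, config=cfg)
            rows.append(
                {"pca_components": n_pc, "hidden_sizes": str(list(hidden)),
                 "roc_auc": report.roc_auc, "accuracy": report.accuracy}
            )
    return pd.DataFrame(rows)
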