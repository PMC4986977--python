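"""Leave-one-subject-out evaluation, distance statistic, and significance.

The 4-class feature table has one row per (subject, cued location).  Each
LOSO fold holds one subject out; the dendrogram, the node SVMs and the
feature scaler are all refitted on the remaining subjects (leakage-safe;
a pre-built tree can be frozen via the config).  Sixty predictions (15
subjects × 4 locations) feed the confusion matrix whose diagonal mean is
the decoding accuracy; a per-subject majority-correct tally is reported
alongside as an alternative 15-way accounting.

The spatial error statistic is

    D = (1/4) · Σ_ij p_ij · |i − j|        (letter positions)

over the row-normalized confusion matrix, converted to visual angle with
the 0.88° horizontal letter spacing.  Chance-level inference uses the
exact binomial tail (P(X ≥ k) under Binomial(n, 1/n_classes)) and a
permutation test that shuffles location labels within subject and reruns
the full LOSO pipeline, with the add-one p-value estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from attnloc.dsvm import DSVMConfig, build_dendrogram, train, predict, \
    train_binary_attended
from attnloc.synthdata import TaskDesign

N_LOCATIONS = 4


@dataclass(frozen=True)
class EvalConfig:
    """Cross-validation settings."""

    dsvm: DSVMConfig = field(default_factory=DSVMConfig)
    #: rebuild the dendrogram inside every training fold (leakage-safe);
    #: if False, ``fixed_tree`` must be provided
    rebuild_tree_per_fold: bool = True
    fixed_tree: object = None
    n_permutations: int = 1000
    alpha: float = 0.05


@dataclass
class DistanceResult:
    """Mean letter-position distance and its visual-angle equivalent."""

    D: float
    degrees: float


@dataclass
class DecodingReport:
    """Everything the 4-class evaluation produces."""

    folds: pd.DataFrame                  # subject, location, predicted
    accuracy_pct: float
    per_location_accuracy_pct: dict
    confusion: np.ndarray
    distance: DistanceResult
    binomial_threshold_pct: dict         # alpha -> minimum significant DA %
    subject_majority_correct: int        # per-subject accounting (of n_subjects)
    n_subjects: int
    permutation_p: float | None = None
    single_feature_da_pct: pd.Series | None = None

    def summary(self) -> str:
        lines = [
            f"4-class decoding accuracy: {display_percent(self.accuracy_pct)}% "
            f"({self.accuracy_pct:.2f}%) over {len(self.folds)} predictions, "
            f"{self.n_subjects} LOSO folds",
            f"per-location accuracy: "
            + ", ".join(f"loc {k}: {v:.1f}%" for k, v in
                        self.per_location_accuracy_pct.items()),
            f"mean distance D = {self.distance.D:.2f} letter positions "
            f"= {self.distance.degrees:.2f} degrees",
            f"subjects with majority-correct folds: "
            f"{self.subject_majority_correct}/{self.n_subjects}",
        ]
        for a, thr in self.binomial_threshold_pct.items():
            lines.append(f"binomial significance threshold (alpha={a}): "
                         f"{thr:.1f}%")
        if self.permutation_p is not None:
            lines.append(f"permutation p-value: {self.permutation_p:.4g}")
        return "\n".join(lines)


def display_percent(value_pct: float) -> int:
    """Truncate a percentage toward zero for display (10/15 → 66)."""
    return math.trunc(value_pct)


def _feature_columns(features: pd.DataFrame) -> list[str]:
    meta = {"subject", "location", "cued_location", "letter_location",
            "attended"}
    return [c for c in features.columns if c not in meta]


def _fit_fold(X: np.ndarray, y: np.ndarray, config: EvalConfig):
    if config.rebuild_tree_per_fold:
        tree = build_dendrogram(X, y, config.dsvm)
    else:
        if config.fixed_tree is None:
            raise ValueError("rebuild_tree_per_fold=False needs fixed_tree")
        tree = config.fixed_tree
    return train(tree, X, y, config.dsvm)


def loso_cv(
    features: pd.DataFrame,
    config: EvalConfig | None = None,
    label_col: str = "location",
) -> pd.DataFrame:
    """One fold per subject; returns subject, true label, predicted label.

    Subjects missing any location row are excluded up front with a warning
    row in the log; at least 3 complete subjects are required.
    """
    config = config or EvalConfig()
    cols = _feature_columns(features)
    expected = set(range(1, N_LOCATIONS + 1))
    complete = [
        s for s, g in features.groupby("subject", sort=True)
        if set(g[label_col]) >= expected
    ]
    if len(complete) < len(features["subject"].unique()):
        import logging
        logging.getLogger(__name__).warning(
            "excluding %d subject(s) with missing location rows",
            len(features["subject"].unique()) - len(complete))
    if len(complete) < 3:
        raise ValueError("need at least 3 complete subjects for LOSO")
    df = features[features["subject"].isin(complete)]

    X = df[cols].to_numpy(dtype=float)
    y = df[label_col].to_numpy(dtype=int)
    subj = df["subject"].to_numpy()
    records = []
    for held_out in complete:
        test_mask = subj == held_out
        model = _fit_fold(X[~test_mask], y[~test_mask], config)
        preds = predict(model, X[test_mask])
        for t, p in zip(y[test_mask], preds):
            records.append((held_out, int(t), int(p)))
    return pd.DataFrame(records, columns=["subject", "location", "predicted"])


def decoding_accuracy(predictions, truth) -> float:
    """Percent correct, full precision (use display_percent to print)."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth differ in length")
    if len(predictions) == 0:
        raise ValueError("empty predictions")
    return 100.0 * float(np.mean(predictions == truth))


def confusion_matrix(predictions, truth, n_classes: int = N_LOCATIONS
                     ) -> np.ndarray:
    """Row-normalized confusion matrix; rows with zero support are NaN."""
    predictions = np.asarray(predictions, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if np.any((truth < 1) | (truth > n_classes)) or np.any(
            (predictions < 1) | (predictions > n_classes)):
        raise ValueError(f"labels must lie in 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes))
    for t, p in zip(truth, predictions):
        counts[t - 1, p - 1] += 1
    support = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        cm = counts / support
    cm[support.ravel() == 0] = np.nan
    return cm


def mean_distance(
    cm: np.ndarray, horizontal_gap_deg: float = TaskDesign.horizontal_gap_deg
) -> DistanceResult:
    """D = (1/n) Σ_ij p_ij |i−j| over a row-stochastic confusion matrix."""
    cm = np.asarray(cm, dtype=float)
    n = cm.shape[0]
    if cm.shape != (n, n) or not np.all(np.isfinite(cm)):
        raise ValueError("confusion matrix must be square with defined rows")
    if not np.allclose(cm.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("confusion matrix rows must sum to 1")
    i, j = np.indices((n, n)) + 1
    D = float((cm * np.abs(i - j)).sum() / n)
    return DistanceResult(D=D, degrees=D * horizontal_gap_deg)


def binomial_threshold(
    n_samples: int, n_classes: int = N_LOCATIONS, alpha: float = 0.05
) -> float:
    """Smallest accuracy (%) significant at ``alpha`` under chance guessing.

    Exact binomial tail: the minimum k with P(X ≥ k) < alpha for
    X ~ Binomial(n_samples, 1/n_classes), returned as 100·k/n.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    p = 1.0 / n_classes
    # sf(k-1) = P(X >= k)
    for k in range(n_samples + 1):
        if binom.sf(k - 1, n_samples, p) < alpha:
            return 100.0 * k / n_samples
    return 100.0  # alpha so small even n/n is not significant


def permutation_test(
    features: pd.DataFrame,
    config: EvalConfig | None = None,
    n_permutations: int | None = None,
    seed: int = 0,
    observed_da: float | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for the observed LOSO decoding accuracy.

    Location labels are permuted *within subject* (preserving the subject
    structure), the full LOSO pipeline is rerun per permutation, and
    p = (1 + #{perm DA ≥ observed DA}) / (n_permutations + 1).
    Returns (p, null DA distribution).
    """
    config = config or EvalConfig()
    n_perm = n_permutations if n_permutations is not None \
        else config.n_permutations
    if n_perm < 1:
        raise ValueError("n_permutations must be >= 1")
    if observed_da is None:
        folds = loso_cv(features, config)
        observed_da = decoding_accuracy(folds["predicted"], folds["location"])

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    groups = [np.asarray(idx) for _, idx in
              features.groupby("subject", sort=True).indices.items()]
    labels = features["location"].to_numpy().copy()
    permuted = features.copy()
    null_da = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = labels.copy()
        for idx in groups:
            shuffled[idx] = rng.permutation(shuffled[idx])
        permuted["location"] = shuffled
        folds = loso_cv(permuted, config)
        null_da[b] = decoding_accuracy(folds["predicted"], folds["location"])
    p = (1.0 + float(np.sum(null_da >= observed_da))) / (n_perm + 1.0)
    return p, null_da


def single_feature_da(
    features: pd.DataFrame, config: EvalConfig | None = None
) -> pd.Series:
    """LOSO decoding accuracy of each feature column on its own (12 values)."""
    config = config or EvalConfig()
    out = {}
    for col in _feature_columns(features):
        sub = features[["subject", "location", col]]
        folds = loso_cv(sub, config)
        out[col] = decoding_accuracy(folds["predicted"], folds["location"])
    return pd.Series(out)


def binary_attended_eval(
    binary_features: pd.DataFrame, config: EvalConfig | None = None
) -> tuple[float, dict[int, float], pd.DataFrame]:
    """LOSO attended-vs-unattended accuracy, overall and per letter location.

    Rows are (subject, cued location, letter location) target-locked feature
    vectors labeled attended iff cue = letter.  Returns (overall DA %,
    {letter location: DA %}, fold table).  A location whose held-out rows
    ever contain a single class is still scored (accuracy over what exists);
    a location with no rows at all maps to NaN.
    """
    config = config or EvalConfig()
    cols = _feature_columns(binary_features)
    subjects = sorted(binary_features["subject"].unique())
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for LOSO")
    records = []
    for held_out in subjects:
        train_df = binary_features[binary_features["subject"] != held_out]
        test_df = binary_features[binary_features["subject"] == held_out]
        model = train_binary_attended(
            train_df[cols].to_numpy(),
            train_df["attended"].to_numpy(), config.dsvm)
        preds = model.predict(test_df[cols].to_numpy())
        for (_, row), p in zip(test_df.iterrows(), preds):
            records.append((held_out, int(row["letter_location"]),
                            bool(row["attended"]), bool(p)))
    folds = pd.DataFrame(
        records, columns=["subject", "letter_location", "attended",
                          "predicted"])
    overall = decoding_accuracy(folds["predicted"], folds["attended"])
    per_loc = {}
    for loc in range(1, N_LOCATIONS + 1):
        sub = folds[folds["letter_location"] == loc]
        per_loc[loc] = (decoding_accuracy(sub["predicted"], sub["attended"])
                        if len(sub) else float("nan"))
    return overall, per_loc, folds


def heog_confound_split(
    heog_amplitude_uv: dict[str, float],
    features: pd.DataFrame,
    config: EvalConfig | None = None,
) -> dict:
    """Rerun decoding on the low-eye-movement subgroup.

    Subjects are ranked by |lateralized HEOG amplitude at 500 ms|; group 1
    is the ceil(n/3) largest movers (5 of 15), group 2 the rest (10 of 15).
    Ties at the boundary resolve by subject-id order.  Decoding is rerun on
    group 2 alone.
    """
    config = config or EvalConfig()
    subjects = sorted(heog_amplitude_uv)
    n = len(subjects)
    n_group1 = math.ceil(n / 3)
    if n != 15:
        import logging
        logging.getLogger(__name__).warning(
            "HEOG split on n=%d subjects: group sizes %d / %d",
            n, n_group1, n - n_group1)
    ranked = sorted(subjects,
                    key=lambda s: (-abs(heog_amplitude_uv[s]), s))
    group1 = sorted(ranked[:n_group1])
    group2 = sorted(ranked[n_group1:])
    sub_features = features[features["subject"].isin(group2)]
    folds = loso_cv(sub_features, config)
    da = decoding_accuracy(folds["predicted"], folds["location"])
    return {"group1": group1, "group2": group2,
            "group2_accuracy_pct": da, "folds": folds}


def compute_heog_summary(epoch_sets, at_ms: float = 500.0) -> dict[str, float]:
    """Per-subject |HEOG| (μV) at ``at_ms`` after cue onset, mean over kept
    cue-locked epochs — the eye-movement summary behind the confound split."""
    out = {}
    for es in epoch_sets:
        mask = (es.metadata["kind"] == "cue").to_numpy() & es.kept
        if not mask.any():
            out[es.subject] = float("nan")
            continue
        t_idx = int(np.argmin(np.abs(es.times - at_ms / 1000.0)))
        heog = es.data[mask, es.channel_index("HEOG"), t_idx]
        out[es.subject] = float(np.abs(heog).mean())
    return out


def evaluate_decoding(
    features: pd.DataFrame,
    config: EvalConfig | None = None,
    run_permutation: bool = False,
    run_single_feature: bool = False,
    seed: int = 0,
) -> DecodingReport:
    """Full 4-class report: LOSO folds, accuracy, confusion, D, significance."""
    config = config or EvalConfig()
    folds = loso_cv(features, config)
    acc = decoding_accuracy(folds["predicted"], folds["location"])
    cm = confusion_matrix(folds["predicted"], folds["location"])
    per_loc = {loc: 100.0 * cm[loc - 1, loc - 1]
               for loc in range(1, N_LOCATIONS + 1)}
    distance = mean_distance(cm)

    subjects = folds["subject"].unique()
    majority = sum(
        (folds[folds["subject"] == s]["predicted"]
         == folds[folds["subject"] == s]["location"]).mean() > 0.5
        for s in subjects
    )
    thresholds = {a: binomial_threshold(len(subjects), N_LOCATIONS, a)
                  for a in (0.05, 0.01)}
    report = DecodingReport(
        folds=folds, accuracy_pct=acc, per_location_accuracy_pct=per_loc,
        confusion=cm, distance=distance, binomial_threshold_pct=thresholds,
        subject_majority_correct=int(majority), n_subjects=len(subjects),
    )
    if run_permutation:
        report.permutation_p, _ = permutation_test(
            features, config, seed=seed, observed_da=acc)
    if run_single_feature:
        report.single_feature_da_pct = single_feature_da(features, config)
    return report
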