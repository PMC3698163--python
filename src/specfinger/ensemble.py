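"""Repeated-split neural-network ensemble with a soft-decision reject rule.

A small feed-forward network (one hidden layer, 3 logistic units,
logistic output read as a confidence in [0, 1]) is trained in many
independent sessions.  Each session draws a fresh 70/15/15
train/validation/test partition; the validation part drives early
stopping, and only the held-out test part contributes soft outputs.
With 67 sessions at a 15% test fraction every sample lands in about
0.15 x 67 = 10.05 test sets, giving roughly ten independent soft
outputs per sample.

Aggregation takes, per sample, the mean and standard deviation of its
test-set soft outputs.  A call is *reliable* when the distance between
the mean and the 0.5 decision level strictly exceeds the standard
deviation; everything else is *undefined* (rejected).  Metrics
(sensitivity, specificity) are reported over reliable calls, alongside
the full 2x3 classification table with an assigned-undefined column.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier

from .exceptions import (
    CohortError,
    ConfigError,
    EvaluationError,
    TrainingError,
)

CALLS = ("negative", "positive", "undefined")


@dataclass
class EnsembleConfig:
    """Ensemble hyperparameters.

    n_sessions
        Independent train/validation/test repetitions (default 67).
    train_frac / val_frac / test_frac
        Partition fractions; must sum to 1 (default 0.70/0.15/0.15).
        Train size is round(train_frac * n); the remainder is halved,
        validation taking the extra sample when odd.
    hidden_neurons
        Hidden-layer width (default 3).
    max_epochs, patience
        Early-stopping budget: training stops when validation log-loss
        has not improved for ``patience`` epochs (default 10) or at
        ``max_epochs`` (default 500); the best-validation weights are
        restored.
    learning_rate, batch_size
        Adam step size (default 0.003) and minibatch size (default 32;
        capped at the training-set size).  The small step keeps the
        validation-loss trace smooth enough for a 10-epoch patience.
    stratified
        Draw the partition per class (default) so small test sets keep
        both classes; the unstratified mode draws from the pooled
        cohort.
    decision_level
        Soft-output threshold, default 0.5.
    master_seed
        Single seed from which every session's split and weight
        initialisation is derived.
    """

    n_sessions: int = 67
    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    hidden_neurons: int = 3
    max_epochs: int = 500
    patience: int = 10
    learning_rate: float = 0.003
    batch_size: int = 32
    master_seed: int = 0
    stratified: bool = True
    decision_level: float = 0.5

    def __post_init__(self):
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ConfigError("train/val/test fractions must sum to 1")
        if self.n_sessions < 1 or self.hidden_neurons < 1:
            raise ConfigError("n_sessions and hidden_neurons must be >= 1")
        if not 0 < self.decision_level < 1:
            raise ConfigError("decision_level must lie in (0, 1)")


@dataclass
class SessionSplit:
    """Positional index partition of one session."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


@dataclass
class SessionRecord:
    """Held-out soft outputs of one training session."""

    session_id: int
    split: SessionSplit
    test_soft_outputs: np.ndarray  # aligned with split.test
    test_accuracy: float
    n_epochs: int


@dataclass
class ObservationSummary:
    """Aggregated soft-output statistics and the reliability call."""

    sample_id: str
    true_label: str
    n_test_appearances: int
    mean: float
    std: float
    call: str
    low_coverage: bool = False


def expected_test_inclusions(n_sessions: int, test_frac: float) -> float:
    """Expected number of test-set appearances per sample."""
    if n_sessions <= 0 or test_frac <= 0:
        raise ConfigError("n_sessions and test_frac must be positive")
    return n_sessions * test_frac


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _partition_sizes(n: int, config: EnsembleConfig) -> tuple[int, int, int]:
    n_train = _round_half_up(config.train_frac * n)
    rest = n - n_train
    n_val = (rest + 1) // 2  # odd remainder: validation gets the extra
    n_test = rest - n_val
    return n_train, n_val, n_test


def make_session_split(
    sample_ids: Sequence[str],
    labels: Sequence[str],
    config: EnsembleConfig,
    session_index: int,
) -> SessionSplit:
    """Deterministic 70/15/15 partition for one session.

    A pure function of ``(master_seed, session_index)``.  In stratified
    mode the rounding rule is applied within each class.
    """
    n = len(sample_ids)
    lab = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.master_seed) % (2**31), session_index])
    )
    groups = (
        [np.where(lab == c)[0] for c in ("negative", "positive")]
        if config.stratified
        else [np.arange(n)]
    )
    tr, va, te = [], [], []
    for idx in groups:
        if config.stratified and idx.size < 10:
            raise CohortError(
                f"stratified split needs >= 10 samples per class, got {idx.size}"
            )
        perm = idx[rng.permutation(idx.size)]
        n_train, n_val, n_test = _partition_sizes(idx.size, config)
        tr.append(perm[:n_train])
        va.append(perm[n_train : n_train + n_val])
        te.append(perm[n_train + n_val :])
    return SessionSplit(
        np.sort(np.concatenate(tr)),
        np.sort(np.concatenate(va)),
        np.sort(np.concatenate(te)),
    )


def _labels_to_binary(labels) -> np.ndarray:
    lab = np.asarray(labels, dtype=object)
    bad = ~np.isin(lab, ["positive", "negative"])
    if bad.any():
        raise CohortError("ensemble training requires positive/negative labels only")
    return (lab == "positive").astype(int)


def train_session(
    X: np.ndarray,
    labels,
    split: SessionSplit,
    config: EnsembleConfig,
    session_seed: int,
    session_id: int = 0,
) -> SessionRecord:
    """Train one session's network and record held-out soft outputs.

    One hidden layer of ``hidden_neurons`` logistic units with a
    logistic output trained on log-loss (target 1 = positive) by Adam;
    an explicit epoch loop monitors log-loss on the supplied validation
    split, stops after ``patience`` epochs without improvement, and
    restores the best-validation weights before the test split is
    scored.
    """
    y = _labels_to_binary(labels)
    Xtr, ytr = X[split.train], y[split.train]
    Xval, yval = X[split.val], y[split.val]
    clf = MLPClassifier(
        hidden_layer_sizes=(config.hidden_neurons,),
        activation="logistic",
        solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(ytr)),
        random_state=int(session_seed) % (2**31),
        max_iter=1,
        warm_start=False,
    )
    best_loss = np.inf
    best_weights = None
    best_epoch = 0
    stale = 0
    n_epochs = 0
    for epoch in range(config.max_epochs):
        clf.partial_fit(Xtr, ytr, classes=[0, 1])
        n_epochs = epoch + 1
        p_val = clf.predict_proba(Xval)[:, 1]
        if not np.all(np.isfinite(p_val)):
            raise TrainingError(
                f"session {session_id}: non-finite validation outputs at "
                f"epoch {n_epochs}"
            )
        loss = log_loss(yval, p_val, labels=[0, 1])
        if loss < best_loss - 1e-12:
            best_loss = loss
            best_weights = (
                copy.deepcopy(clf.coefs_),
                copy.deepcopy(clf.intercepts_),
            )
            best_epoch = n_epochs
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_weights is None:
        raise TrainingError(f"session {session_id}: validation loss never finite")
    clf.coefs_, clf.intercepts_ = best_weights
    soft = clf.predict_proba(X[split.test])[:, 1]
    acc = float(np.mean((soft > config.decision_level) == (y[split.test] == 1)))
    return SessionRecord(session_id, split, soft, acc, best_epoch)


@dataclass
class EnsembleRun:
    """All session records plus per-session accuracy statistics."""

    records: list[SessionRecord]
    config: EnsembleConfig

    @property
    def session_accuracies(self) -> np.ndarray:
        return np.array([r.test_accuracy for r in self.records])

    @property
    def accuracy_mean(self) -> float:
        return float(self.session_accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        a = self.session_accuracies
        return float(a.std(ddof=1)) if a.size > 1 else 0.0


def run_ensemble(X: np.ndarray, labels, config: EnsembleConfig | None = None) -> EnsembleRun:
    """Run ``n_sessions`` independent sessions from one master seed.

    Each session's split and network initialisation derive from
    ``(master_seed, session_index)``, so the full run is reproducible
    and individual sessions are re-runnable in isolation.
    """
    config = config or EnsembleConfig()
    X = np.asarray(X, dtype=float)
    ids = [str(i) for i in range(X.shape[0])]
    records = []
    for s in range(config.n_sessions):
        split = make_session_split(ids, labels, config, s)
        seed = int(
            np.random.SeedSequence(
                [int(config.master_seed) % (2**31), s, 1]
            ).generate_state(1)[0]
            % (2**31)
        )
        records.append(train_session(X, labels, split, config, seed, session_id=s))
    return EnsembleRun(records, config)


# ---------------------------------------------------------------------------
# aggregation and the reliability rule


def reliability_call(mean: float, std: float, decision_level: float = 0.5) -> str:
    """Reject rule: undefined iff |mean - level| <= std, else sign of mean."""
    if abs(mean - decision_level) <= std:
        return "undefined"
    return "positive" if mean > decision_level else "negative"


def summarize_observations(
    records: Sequence[SessionRecord],
    labels,
    config: EnsembleConfig,
    sample_ids: Sequence[str] | None = None,
) -> list[ObservationSummary]:
    """Per-sample mean/std of test soft outputs and the reliability call.

    Standard deviation uses the sample (n-1) convention; a sample tested
    fewer than twice gets std 0 and a low-coverage flag.  Samples never
    tested are excluded (they would carry no information).
    """
    n = len(labels)
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)]
    outputs: list[list[float]] = [[] for _ in range(n)]
    for rec in records:
        for pos, soft in zip(rec.split.test, rec.test_soft_outputs):
            outputs[pos].append(float(soft))
    summaries = []
    for i in range(n):
        vals = outputs[i]
        if not vals:
            continue
        arr = np.asarray(vals)
        mean = float(arr.mean())
        std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        summaries.append(
            ObservationSummary(
                sample_id=ids[i],
                true_label=str(labels[i]),
                n_test_appearances=arr.size,
                mean=mean,
                std=std,
                call=reliability_call(mean, std, config.decision_level),
                low_coverage=arr.size < 2,
            )
        )
    return summaries


def summaries_frame(summaries: Sequence[ObservationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in summaries],
            "true_label": [s.true_label for s in summaries],
            "n_appearances": [s.n_test_appearances for s in summaries],
            "mean": [s.mean for s in summaries],
            "std": [s.std for s in summaries],
            "call": [s.call for s in summaries],
        }
    )


# ---------------------------------------------------------------------------
# classification tables and metrics


@dataclass
class ClassificationTable:
    """2x3 counts: true class x assigned {negative, positive, undefined}."""

    counts: pd.DataFrame  # index: true negative/positive; columns: CALLS
    n_excluded_unknown: int = 0

    @property
    def row_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def percentages(self) -> pd.DataFrame:
        return 100.0 * self.counts.div(self.row_sums.replace(0, np.nan), axis=0)

    def __str__(self) -> str:
        pct = self.percentages
        rows = []
        header = f"{'':>10}" + "".join(f"{c:>22}" for c in self.counts.columns)
        rows.append(header)
        for t in self.counts.index:
            cells = "".join(
                f"{int(self.counts.loc[t, c]):>12} ({pct.loc[t, c]:5.1f}%)"
                for c in self.counts.columns
            )
            rows.append(f"{t:>10}" + cells)
        return "\n".join(rows)


def classification_table(summaries: Sequence[ObservationSummary]) -> ClassificationTable:
    """Cross-tabulate true labels against ensemble calls.

    Samples with unknown true label are excluded (count reported).
    Row sums equal the per-class cohort sizes among summarised samples.
    """
    counts = pd.DataFrame(
        0, index=["negative", "positive"], columns=list(CALLS), dtype=int
    )
    excluded = 0
    for s in summaries:
        if s.true_label not in ("negative", "positive"):
            excluded += 1
            continue
        counts.loc[s.true_label, s.call] += 1
    return ClassificationTable(counts, excluded)


def sensitivity(correct_positive: int, false_negative: int) -> float:
    """100 * CP / (CP + FN)."""
    denom = correct_positive + false_negative
    if denom <= 0:
        raise EvaluationError("sensitivity undefined: no positive calls to assess")
    return 100.0 * correct_positive / denom


def specificity(correct_negative: int, false_positive: int) -> float:
    """100 * CN / (CN + FP)."""
    denom = correct_negative + false_positive
    if denom <= 0:
        raise EvaluationError("specificity undefined: no negative calls to assess")
    return 100.0 * correct_negative / denom


@dataclass
class MetricsReport:
    """Reliable-call metrics plus rejection statistics."""

    sensitivity: float
    specificity: float
    sensitivity_sd: float | None
    specificity_sd: float | None
    undefined_fraction: float  # of summarised samples, in [0, 1]
    table: ClassificationTable
    n_reliable: int
    n_summarised: int
    session_accuracy_mean: float | None = None
    session_accuracy_sd: float | None = None

    def to_dict(self) -> dict:
        c = self.table.counts
        return {
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "sensitivity_sd_pct": self.sensitivity_sd,
            "specificity_sd_pct": self.specificity_sd,
            "undefined_fraction_pct": 100.0 * self.undefined_fraction,
            "n_reliable": self.n_reliable,
            "n_summarised": self.n_summarised,
            "table_counts": {
                t: {a: int(c.loc[t, a]) for a in c.columns} for t in c.index
            },
            "session_accuracy_mean_pct": None
            if self.session_accuracy_mean is None
            else 100.0 * self.session_accuracy_mean,
            "session_accuracy_sd_pct": None
            if self.session_accuracy_sd is None
            else 100.0 * self.session_accuracy_sd,
        }


def _reliable_metrics(summaries) -> tuple[float, float]:
    tab = classification_table(summaries).counts
    sens = sensitivity(
        int(tab.loc["positive", "positive"]), int(tab.loc["positive", "negative"])
    )
    spec = specificity(
        int(tab.loc["negative", "negative"]), int(tab.loc["negative", "positive"])
    )
    return sens, spec


def evaluate_excluding_undefined(
    summaries: Sequence[ObservationSummary],
    records: Sequence[SessionRecord] | None = None,
    labels=None,
    config: EnsembleConfig | None = None,
    sample_ids: Sequence[str] | None = None,
    n_bootstrap: int = 50,
    bootstrap_seed: int = 12345,
) -> MetricsReport:
    """Sensitivity/specificity over reliable calls, with uncertainty.

    Point metrics come from the 2x3 table with the undefined column
    dropped.  When the session records are supplied, the ± uncertainty
    is a bootstrap over sessions: sessions are resampled with
    replacement, the aggregation and reject rule re-applied, and the
    metric standard deviations taken across replicates.
    """
    known = [s for s in summaries if s.true_label in ("negative", "positive")]
    for cls in ("negative", "positive"):
        if not any(s.true_label == cls and s.call != "undefined" for s in known):
            raise EvaluationError(f"no reliable calls among true-{cls} samples")
    table = classification_table(summaries)
    sens, spec = _reliable_metrics(summaries)
    n_undef = sum(1 for s in known if s.call == "undefined")
    n_reliable = len(known) - n_undef

    sens_sd = spec_sd = None
    if records is not None and labels is not None and config is not None:
        rng = np.random.default_rng(bootstrap_seed)
        records = list(records)
        sens_b, spec_b = [], []
        for _ in range(n_bootstrap):
            pick = rng.integers(0, len(records), size=len(records))
            resampled = [records[i] for i in pick]
            summ_b = summarize_observations(resampled, labels, config, sample_ids)
            try:
                s_b, p_b = _reliable_metrics(summ_b)
            except EvaluationError:
                continue
            sens_b.append(s_b)
            spec_b.append(p_b)
        if len(sens_b) > 1:
            sens_sd = float(np.std(sens_b, ddof=1))
            spec_sd = float(np.std(spec_b, ddof=1))

    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        sensitivity_sd=sens_sd,
        specificity_sd=spec_sd,
        undefined_fraction=n_undef / len(known) if known else 0.0,
        table=table,
        n_reliable=n_reliable,
        n_summarised=len(known),
    )
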