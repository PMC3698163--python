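"""Per-wavenumber class-separation scoring and threshold selection.

The primary score is the Bhattacharyya distance between the two class
distributions at each wavenumber under a univariate Gaussian model,

    D = (mu1 - mu2)^2 / (4 (s1^2 + s2^2)) + 1/2 ln[(s1^2 + s2^2) / (2 s1 s2)]

with overlap coefficient exp(-D).  Although the field often says
"Bhattacharyya coefficient", the quantity ranked here is the distance:
the coefficient is largest for identical classes, and only the distance
orientation makes a largest-5%-of-maximum rule pick separable
wavenumbers.  Alternative rankers (Welch t, Wilcoxon rank-sum, ROC AUC,
single-threshold information gain) are provided for comparison, all
oriented so larger = more separable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CohortError, DegenerateInputError, SelectionError

METHODS = ("bhattacharyya", "t_test", "wilcoxon", "roc_auc", "entropy")


def gaussian_bhattacharyya(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Bhattacharyya distance between N(mu1, sd1^2) and N(mu2, sd2^2).

    Non-negative; zero iff the distributions are identical.  Symmetric in
    its two arguments.  The overlap coefficient is exp(-D).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise DegenerateInputError("standard deviations must be positive")
    v1, v2 = sd1 * sd1, sd2 * sd2
    return 0.25 * (mu1 - mu2) ** 2 / (v1 + v2) + 0.5 * math.log(
        (v1 + v2) / (2.0 * sd1 * sd2)
    )


@dataclass
class FeatureScores:
    """Per-column separation scores with per-class summary statistics."""

    scores: np.ndarray
    method: str
    class_stats: dict[str, dict[str, np.ndarray]]

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)

    def to_frame(self, feature_map: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"score": self.scores})
        df.index.name = "column"
        if feature_map is not None:
            df = feature_map.join(df)
        return df


@dataclass
class FeatureSelection:
    """Indices whose score strictly exceeds ``fraction_of_max * max``."""

    selected: np.ndarray
    threshold: float
    fraction_of_max: float = 0.05

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=int)

    def __len__(self) -> int:
        return self.selected.size

    def mask(self, n_features: int) -> np.ndarray:
        m = np.zeros(n_features, dtype=bool)
        m[self.selected] = True
        return m


def _split_classes(X: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    lab = np.asarray(labels, dtype=object)
    pos = X[lab == "positive"]
    neg = X[lab == "negative"]
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise CohortError(
            f"need >= 2 samples per class, got {pos.shape[0]} positive / "
            f"{neg.shape[0]} negative"
        )
    return pos, neg


def _entropy_gain(x: np.ndarray, y: np.ndarray) -> float:
    """Information gain of the best single-threshold split of one column."""
    order = np.argsort(x, kind="mergesort")
    ys = y[order]
    n = ys.size
    npos = ys.sum()
    p = npos / n

    def h(q):
        q = np.clip(q, 1e-12, 1 - 1e-12)
        return -(q * np.log2(q) + (1 - q) * np.log2(1 - q))

    h_total = h(p)
    cum_pos = np.cumsum(ys)[:-1]
    nl = np.arange(1, n)
    nr = n - nl
    pl = cum_pos / nl
    pr = (npos - cum_pos) / nr
    cond = (nl / n) * h(pl) + (nr / n) * h(pr)
    xs = x[order]
    valid = xs[1:] > xs[:-1]  # no split between tied values
    if not valid.any():
        return 0.0
    return float(h_total - cond[valid].min())


def score_wavenumbers(X: np.ndarray, labels, method: str = "bhattacharyya") -> FeatureScores:
    """Score every feature column for positive/negative separation.

    Methods: ``bhattacharyya`` (Gaussian class model), ``t_test``
    (|Welch t|), ``wilcoxon`` (|standardised Mann-Whitney rank-sum z|),
    ``roc_auc`` (|AUC - 0.5|), ``entropy`` (best single-threshold
    information gain).  All scores are >= 0, larger = more separable,
    and invariant to swapping the class labels.
    """
    if method not in METHODS:
        raise SelectionError(f"unknown method {method!r}; choose from {METHODS}")
    X = np.asarray(X, dtype=float)
    pos, neg = _split_classes(X, labels)
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    sd_p = pos.std(axis=0, ddof=1)
    sd_n = neg.std(axis=0, ddof=1)
    class_stats = {
        "positive": {"mean": mu_p, "std": sd_p, "n": pos.shape[0]},
        "negative": {"mean": mu_n, "std": sd_n, "n": neg.shape[0]},
    }

    if method == "bhattacharyya":
        # floor sds so perfectly separated zero-variance columns rank at
        # the top instead of producing infinities
        floor = 1e-9 * max(1.0, float(np.max(np.abs(X))) if X.size else 1.0)
        s1 = np.maximum(sd_p, floor)
        s2 = np.maximum(sd_n, floor)
        v = s1 * s1 + s2 * s2
        scores = 0.25 * (mu_p - mu_n) ** 2 / v + 0.5 * np.log(v / (2 * s1 * s2))
    elif method == "t_test":
        t, _ = stats.ttest_ind(pos, neg, axis=0, equal_var=False)
        scores = np.abs(np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0))
    elif method in ("wilcoxon", "roc_auc"):
        res = stats.mannwhitneyu(pos, neg, axis=0, alternative="two-sided")
        u = np.asarray(res.statistic, dtype=float)
        n1, n2 = pos.shape[0], neg.shape[0]
        if method == "roc_auc":
            scores = np.abs(u / (n1 * n2) - 0.5)
        else:
            z = (u - n1 * n2 / 2.0) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
            scores = np.abs(z)
    else:  # entropy
        y = (np.asarray(labels, dtype=object) == "positive").astype(float)
        keep = np.isin(np.asarray(labels, dtype=object), ["positive", "negative"])
        Xk, yk = X[keep], y[keep]
        scores = np.array([_entropy_gain(Xk[:, j], yk) for j in range(X.shape[1])])

    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        scores = np.nan_to_num(scores, nan=0.0, posinf=0.0, neginf=0.0)
    return FeatureScores(scores, method, class_stats)


def select_wavenumbers(scores: FeatureScores, fraction_of_max: float = 0.05) -> FeatureSelection:
    """Keep columns whose score strictly exceeds ``fraction_of_max * max``.

    The arg-max column is always selected.  Order of indices is
    preserved (ascending column index).
    """
    s = scores.scores
    if s.size == 0 or np.max(s) <= 0:
        raise SelectionError("all scores are zero; nothing to select")
    top = float(np.max(s))
    threshold = fraction_of_max * top
    mask = s > threshold
    mask[int(np.argmax(s))] = True
    return FeatureSelection(np.where(mask)[0], threshold, fraction_of_max)


def compare_rankers(
    X: np.ndarray,
    labels,
    methods=METHODS,
    ensemble_config=None,
    fraction_of_max: float = 0.05,
) -> pd.DataFrame:
    """Train a reduced ensemble per ranking method; tabulate error rates.

    For each method: score, select at ``fraction_of_max``, run the
    ensemble on the selected columns, and report the mean per-session
    test misclassification rate.  Sorted ascending by misclassification.
    """
    from .ensemble import EnsembleConfig, run_ensemble

    if ensemble_config is None:
        ensemble_config = EnsembleConfig(n_sessions=11, master_seed=0)
    rows = []
    for method in methods:
        sc = score_wavenumbers(X, labels, method)
        sel = select_wavenumbers(sc, fraction_of_max)
        run = run_ensemble(X[:, sel.selected], labels, ensemble_config)
        rows.append(
            {
                "method": method,
                "n_selected": len(sel),
                "misclassification": 1.0 - run.accuracy_mean,
                "accuracy_sd": run.accuracy_sd,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("misclassification", kind="mergesort")
        .reset_index(drop=True)
    )
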