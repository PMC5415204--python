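"""Predictor comparison and group statistics for labeled variant sets.

ROC/AUC over pathogenic vs non-pathogenic variants (ties half-credited, so
the AUC equals the normalized Mann-Whitney U), leave-one-out threshold
accuracy, seeded bootstrap and permutation group tests, Pearson
correlation, and allele-frequency binning of ΔΔG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "RocResult",
    "GroupTestResult",
    "roc",
    "loo_accuracy",
    "bootstrap_group_diff",
    "permutation_group_diff",
    "correlation",
    "frequency_vs_ddg",
]

PATHOGENIC = "pathogenic"
NON_PATHOGENIC = "non_pathogenic"


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    predictor: str
    n_pathogenic: int
    n_benign: int
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})


@dataclass
class GroupTestResult:
    statistic: float
    statistic_type: str
    p_value: float
    group_stats: dict
    n_resamples: int
    seed: int | None
    sidedness: str
    exact: bool = False
    meta: dict = field(default_factory=dict)


def _binary_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "bif":
        y = lab.astype(int)
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("numeric labels must be 0/1")
        return y
    mapping = {PATHOGENIC: 1, NON_PATHOGENIC: 0}
    try:
        return np.array([mapping[str(v)] for v in lab])
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from None


def roc(scores, labels, predictor: str = "score", higher_is_damaging: bool = True) -> RocResult:
    """ROC curve and AUC for one predictor over a labeled variant set.

    Missing scores (NaN) are excluded and counted. AUC is the probability
    that a random pathogenic variant outscores a random benign one, ties
    credited 0.5 — the Mann-Whitney U statistic divided by n₁·n₂.
    """
    s = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    keep = np.isfinite(s)
    n_excluded = int((~keep).sum())
    s, y = s[keep], y[keep]
    if len(set(y)) < 2:
        raise ValueError("single-class input: need both pathogenic and non-pathogenic variants")
    if not higher_is_damaging:
        s = -s
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return RocResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, predictor=predictor,
        n_pathogenic=int(y.sum()), n_benign=int((1 - y).sum()), n_excluded=n_excluded,
    )


def _balanced_accuracy(y: np.ndarray, pred: np.ndarray) -> float:
    pos, neg = y == 1, y == 0
    tpr = pred[pos].mean() if pos.any() else 0.0
    tnr = (1 - pred[neg]).mean() if neg.any() else 0.0
    return 0.5 * (tpr + tnr)


def _best_threshold(s: np.ndarray, y: np.ndarray) -> float:
    """Threshold t maximizing balanced accuracy of `score >= t ⇒ pathogenic`.

    Candidates are the midpoints between consecutive unique training scores
    plus −inf/+inf (classify all/none pathogenic), so the chosen cut sits
    between the classes rather than on a training point. Among equally good
    thresholds the smallest wins, pushing borderline variants to the
    pathogenic side — the conservative choice for a screening setting.
    """
    uniq = np.unique(s)
    candidates = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    best_t, best_acc = math.inf, -1.0
    for t in candidates:
        acc = _balanced_accuracy(y, (s >= t).astype(int))
        if acc > best_acc + 1e-12 or (abs(acc - best_acc) <= 1e-12 and t < best_t):
            best_t, best_acc = t, acc
    return best_t


def loo_accuracy(scores, labels, higher_is_damaging: bool = True) -> dict:
    """Leave-one-out accuracy of single-threshold classification.

    For each held-out variant, the threshold maximizing balanced accuracy
    on the remaining variants classifies it (``score >= threshold`` ⇒
    pathogenic; ties to the pathogenic side). Returns the fraction correct
    and the per-variant prediction record.
    """
    s = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    if s.size < 3:
        raise ValueError("need at least 3 labeled, scored variants")
    if len(set(y)) < 2:
        raise ValueError("single-class input")
    if not higher_is_damaging:
        s = -s
    records = []
    correct = 0
    for i in range(s.size):
        mask = np.ones(s.size, dtype=bool)
        mask[i] = False
        t = _best_threshold(s[mask], y[mask])
        pred = int(s[i] >= t)
        correct += int(pred == y[i])
        records.append({"score": float(s[i]), "label": int(y[i]), "threshold": float(t), "predicted": pred})
    return {"accuracy": correct / s.size, "n": int(s.size), "records": records}


def bootstrap_group_diff(
    values_a,
    values_b,
    n_resamples: int = 10_000,
    seed: int | None = None,
    alternative: str = "greater",
) -> GroupTestResult:
    """One-sided bootstrap test comparing two group means.

    Each group is resampled with replacement at its own size; with
    ``alternative="greater"`` the p-value is the fraction of resamples in
    which mean(a) ≤ mean(b) (evidence against mean(a) > mean(b)).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    rng = np.random.default_rng(seed)
    mean_a = a[rng.integers(0, a.size, size=(n_resamples, a.size))].mean(axis=1)
    mean_b = b[rng.integers(0, b.size, size=(n_resamples, b.size))].mean(axis=1)
    if alternative == "greater":
        p = float(np.mean(mean_a <= mean_b))
    else:
        p = float(np.mean(mean_a >= mean_b))
    return GroupTestResult(
        statistic=float(a.mean() - b.mean()),
        statistic_type="mean_diff",
        p_value=p,
        group_stats={"mean_a": float(a.mean()), "mean_b": float(b.mean()),
                     "n_a": int(a.size), "n_b": int(b.size)},
        n_resamples=n_resamples,
        seed=seed,
        sidedness=alternative,
    )


def permutation_group_diff(
    values_a,
    values_b,
    statistic: str = "mean_diff",
    n_permutations: int = 10_000,
    seed: int | None = None,
    alternative: str = "two-sided",
    exact_limit: int = 100_000,
) -> GroupTestResult:
    """Permutation test on the difference of group means or medians.

    Exhaustive enumeration of label assignments when the number of
    arrangements C(n_a+n_b, n_a) is at most ``exact_limit``, Monte-Carlo
    otherwise; two-sided by default.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    stat_funcs = {"mean_diff": np.mean, "median_diff": np.median}
    if statistic not in stat_funcs:
        raise ValueError(f"unknown statistic {statistic!r}")
    f = stat_funcs[statistic]
    observed = float(f(a) - f(b))
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    eps = 1e-12

    def extreme(value: float) -> bool:
        if alternative == "two-sided":
            return abs(value) >= abs(observed) - eps
        if alternative == "greater":
            return value >= observed - eps
        if alternative == "less":
            return value <= observed + eps
        raise ValueError(f"unknown alternative {alternative!r}")

    n_total = math.comb(n, na)
    if n_total <= exact_limit:
        hits = 0
        idx_all = np.arange(n)
        for combo in combinations(range(n), na):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            hits += extreme(float(f(pooled[sel]) - f(pooled[~sel])))
        p = hits / n_total
        return GroupTestResult(
            statistic=observed, statistic_type=statistic, p_value=p,
            group_stats={"n_a": int(na), "n_b": int(b.size)},
            n_resamples=n_total, seed=seed, sidedness=alternative, exact=True,
        )

    rng = np.random.default_rng(seed)
    hits = 1  # include the observed arrangement, the standard MC correction
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        hits += extreme(float(f(pooled[perm[:na]]) - f(pooled[perm[na:]])))
    p = hits / (n_permutations + 1)
    return GroupTestResult(
        statistic=observed, statistic_type=statistic, p_value=p,
        group_stats={"n_a": int(na), "n_b": int(b.size)},
        n_resamples=n_permutations, seed=seed, sidedness=alternative, exact=False,
    )


def correlation(x, y) -> tuple[float, float]:
    """Squared Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matching vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)


def frequency_vs_ddg(freqs: pd.DataFrame, ddg: pd.Series, bins) -> pd.DataFrame:
    """Per-frequency-bin ΔΔG quartiles.

    ``freqs`` has columns variant, allele_frequency; ``ddg`` is indexed by
    variant string. Bins are frequency edges; each row reports n and the
    25/50/75% ΔΔG quartiles (NaN for empty bins).
    """
    joined = freqs.set_index("variant").join(ddg.rename("ddg"), how="inner")
    if joined.empty:
        raise ValueError("no overlap between the frequency and ΔΔG tables")
    joined["bin"] = pd.cut(joined["allele_frequency"], bins=bins, include_lowest=True)
    rows = []
    for interval, grp in joined.groupby("bin", observed=False):
        if len(grp):
            q25, q50, q75 = np.percentile(grp["ddg"], [25, 50, 75])
        else:
            q25 = q50 = q75 = np.nan
        rows.append({"bin_left": interval.left, "bin_right": interval.right,
                     "n": int(len(grp)), "ddg_q25": q25, "ddg_q50": q50, "ddg_q75": q75})
    return pd.DataFrame(rows)
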