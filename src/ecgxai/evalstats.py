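"""Diagnostic-performance metrics and the clustered paired-proportions test.

Metrics (accuracy, sensitivity, specificity, AUROC) are reported as percents
or unit-interval values with percentile-bootstrap confidence intervals.  The
reader study -- several readers each rating the same ECG set before and after
an intervention -- is analysed with a clustered extension of the McNemar test:
discordant-pair counts are formed per reader (cluster) and the variance of
their sum is estimated across clusters, so within-reader correlation does not
invalidate the test.  A within-reader sign-flip permutation test ships
alongside as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# reader-study container
# ---------------------------------------------------------------------------

@dataclass
class ReaderStudy:
    """Long-format table: one row per (reader, ecg) with truth and both calls."""

    df: pd.DataFrame

    REQUIRED = ["reader_id", "ecg_id", "truth", "call_before", "call_after"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"reader study lacks columns {missing}")
        counts = self.df.groupby("reader_id")["ecg_id"].apply(frozenset)
        if len(set(counts)) != 1:
            raise ValueError("all readers must rate the identical ECG set")
        for c in ["truth", "call_before", "call_after"]:
            self.df[c] = self.df[c].astype(bool)

    @property
    def readers(self) -> list[str]:
        return list(pd.unique(self.df["reader_id"]))

    def reader_frame(self, reader_id: str) -> pd.DataFrame:
        return self.df[self.df["reader_id"] == reader_id]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReaderStudy":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# point metrics
# ---------------------------------------------------------------------------

def confusion_metrics(calls: np.ndarray, truth: np.ndarray
                      ) -> tuple[float, Optional[float], Optional[float]]:
    """(accuracy, sensitivity, specificity) as percents.

    Sensitivity/specificity are ``None`` when the truth vector lacks the
    relevant class.
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    acc = 100.0 * float(np.mean(calls == truth))
    sens = 100.0 * float(np.mean(calls[truth])) if truth.any() else None
    spec = 100.0 * float(np.mean(~calls[~truth])) if (~truth).any() else None
    return acc, sens, spec


def auroc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve via the tie-corrected Mann-Whitney statistic."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)          # midranks handle ties
    r_pos = ranks[truth].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(metric: Callable[..., Optional[float]],
                 data: Sequence[np.ndarray],
                 B: int = 10_000,
                 level: float = 0.95,
                 seed: int = 0,
                 max_redraws: int = 100) -> tuple[float, float]:
    """Percentile bootstrap interval for ``metric(*resampled data)``.

    ``data`` is a sequence of equal-length arrays resampled jointly by rows
    with replacement.  A resample on which the metric is undefined (returns
    ``None`` or raises ``ValueError``, e.g. a single-class draw) is redrawn;
    the redraw count is capped.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("data arrays must share length")
    rng = np.random.default_rng(seed)
    out = np.empty(B)
    redraws = 0
    for b in range(B):
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            try:
                val = metric(*(a[idx] for a in arrays))
            except ValueError:
                val = None
            if val is not None:
                out[b] = val
                break
            redraws += 1
        else:
            raise RuntimeError("too many degenerate bootstrap resamples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(out, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class MetricReport:
    """Point metrics with bootstrap CIs for one (scores, calls, truth) triple."""

    accuracy: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    auroc: Optional[float]
    ci: dict
    B: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "auroc": self.auroc,
            "ci": self.ci, "B": self.B, "seed": self.seed,
        }


def evaluate_predictions(scores: np.ndarray, calls: np.ndarray, truth: np.ndarray,
                         B: int = 10_000, level: float = 0.95, seed: int = 0
                         ) -> MetricReport:
    """Full metric report with percentile-bootstrap CIs."""
    acc, sens, spec = confusion_metrics(calls, truth)
    auc = auroc(scores, truth) if (truth.any() and (~truth).any()) else None
    ci = {}
    pairs = {
        "accuracy": lambda c, t: confusion_metrics(c, t)[0],
        "sensitivity": lambda c, t: confusion_metrics(c, t)[1],
        "specificity": lambda c, t: confusion_metrics(c, t)[2],
    }
    for i, (name, fn) in enumerate(pairs.items()):
        ci[name] = bootstrap_ci(fn, (calls, truth), B=B, level=level, seed=seed + i)
    if auc is not None:
        ci["auroc"] = bootstrap_ci(
            lambda s, t: auroc(s, t) if (t.any() and (~t).any()) else None,
            (scores, truth), B=B, level=level, seed=seed + 3)
    return MetricReport(acc, sens, spec, auc, ci, B, seed)


# ---------------------------------------------------------------------------
# clustered paired-proportions (reader-clustered McNemar) test
# ---------------------------------------------------------------------------

@dataclass
class ClusteredTestResult:
    statistic: float
    df: int
    p_value: float
    discordance: pd.DataFrame      # per cluster: b_k, c_k
    no_discordance: bool = False


def _discordance_counts(rs: ReaderStudy) -> pd.DataFrame:
    rows = []
    for r in rs.readers:
        sub = rs.reader_frame(r)
        correct_b = sub["call_before"].to_numpy() == sub["truth"].to_numpy()
        correct_a = sub["call_after"].to_numpy() == sub["truth"].to_numpy()
        rows.append({
            "reader_id": r,
            "b_k": int(np.sum(correct_b & ~correct_a)),   # lost correctness
            "c_k": int(np.sum(~correct_b & correct_a)),   # gained correctness
            "n_k": len(sub),
        })
    return pd.DataFrame(rows)


def obuchowski_test(rs: ReaderStudy) -> ClusteredTestResult:
    """Clustered paired-proportions test of before-vs-after correctness.

    Per reader k the discordant counts b_k (correct before, wrong after) and
    c_k (wrong before, correct after) are formed; with d_k = b_k - c_k the
    statistic is T = (sum d_k)^2 / sum d_k^2, referred to chi-square with 1
    degree of freedom.  The denominator estimates Var(sum d_k) from the
    clusters themselves (uncentred second moment, which keeps the reference
    distribution near-nominal for small numbers of clusters), so arbitrary
    within-reader correlation is accommodated.  Requires >= 2 readers.
    """
    counts = _discordance_counts(rs)
    if len(counts) < 2:
        raise ValueError("clustered test needs >= 2 readers")
    d = (counts["b_k"] - counts["c_k"]).to_numpy(dtype=float)
    denom = float(np.sum(d ** 2))
    if denom == 0.0:
        return ClusteredTestResult(0.0, 1, 1.0, counts, no_discordance=True)
    T = float(np.sum(d)) ** 2 / denom
    p = float(stats.chi2.sf(T, df=1))
    return ClusteredTestResult(T, 1, p, counts)


def permutation_test(rs: ReaderStudy, n_perm: int = 10_000, seed: int = 0
                     ) -> ClusteredTestResult:
    """Within-reader sign-flip permutation test (independent oracle).

    Under the null the before/after phase labels are exchangeable within each
    reader, so flipping them negates that reader's d_k.  With K readers all
    2^K flips are enumerated when K <= 16; otherwise ``n_perm`` random flips
    are drawn.  The statistic is |sum d_k|.
    """
    counts = _discordance_counts(rs)
    d = (counts["b_k"] - counts["c_k"]).to_numpy(dtype=float)
    K = len(d)
    observed = abs(d.sum())
    if K <= 16:
        signs = np.array(np.meshgrid(*([[-1.0, 1.0]] * K))).T.reshape(-1, K)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, K))
    sums = np.abs(signs @ d)
    p = float(np.mean(sums >= observed - 1e-12))
    return ClusteredTestResult(observed, K, p, counts,
                               no_discordance=bool(np.all(d == 0)))


# ---------------------------------------------------------------------------
# reader summaries
# ---------------------------------------------------------------------------

def population_sd(values: Sequence[float]) -> float:
    """SD with divisor n (population convention), to match summary tables."""
    return float(np.std(np.asarray(values, dtype=float), ddof=0))


def reader_summary(rs: ReaderStudy, phase: str) -> tuple[pd.DataFrame, dict, dict]:
    """Per-reader accuracy/sensitivity/specificity plus mean and population SD.

    ``phase`` is 'before' or 'after'.
    """
    if phase not in ("before", "after"):
        raise ValueError("phase must be 'before' or 'after'")
    col = f"call_{phase}"
    rows = []
    for r in rs.readers:
        sub = rs.reader_frame(r)
        acc, sens, spec = confusion_metrics(sub[col].to_numpy(), sub["truth"].to_numpy())
        rows.append({"reader_id": r, "accuracy": acc,
                     "sensitivity": sens, "specificity": spec})
    table = pd.DataFrame(rows)
    mean = {m: round(float(table[m].mean()), 1)
            for m in ["accuracy", "sensitivity", "specificity"]}
    sd = {m: round(population_sd(table[m]), 1)
          for m in ["accuracy", "sensitivity", "specificity"]}
    return table, mean, sd
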