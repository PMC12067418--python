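"""SOZ discrimination scoring and statistical comparisons.

Covers ROC/AUC of normalized flow scores against the clinician SOZ
annotation, rank-based two-sample tests (exact by enumeration for small
samples), Kolmogorov-Smirnov normality screening, Cohen's d effect sizes,
Bonferroni correction, the inflow-/outflow-dominant regime classification
of a recording, and cohort-level AUC summaries with optional metadata
stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .flows import FlowSeries
from .recording import ValidationError

INFLOW_DOMINANT = "inflow_dominant"
OUTFLOW_DOMINANT = "outflow_dominant"
UNCLASSIFIED = "unclassified"


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve of ``scores`` for boolean ``labels``.

    Equals the Mann-Whitney U statistic (with half-credit for ties)
    divided by n_pos * n_neg.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValidationError("labels must contain both classes")
    return float(roc_auc_score(labels, scores))


def seizure_auc(flow: FlowSeries, pooling: str = "median") -> float:
    """AUC of one seizure's flow measure against its SOZ annotation.

    Each channel's score is the median (default) of its per-segment
    normalized values; the AUC then compares SOZ vs non-SOZ channels.
    """
    if flow.soz_mask is None:
        raise ValidationError("FlowSeries carries no SOZ annotation")
    return roc_auc(flow.channel_scores(pooling), flow.soz_mask)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    Uses midranks, so ties are handled; feasible for n_x + n_y <= 12
    (at most C(12, 6) = 924 assignments).
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx, n = len(x), len(pooled)
    obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(n), nx):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= abs(obs - mu) - 1e-12:
            count += 1
        total += 1
    u = obs - nx * (nx + 1) / 2.0
    return float(u), count / total


def wilcoxon_ranksum(x: np.ndarray, y: np.ndarray,
                     exact_limit: int = 12) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is at most
    ``exact_limit``; otherwise the tie-corrected normal approximation.
    Returns (U statistic of ``x``, p value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    if x.size + y.size <= exact_limit:
        return _exact_ranksum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def ks_normality(x: np.ndarray) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean and sd."""
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValidationError("need at least 5 observations for the KS test")
    res = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(res.statistic), float(res.pvalue)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("need at least 2 observations per sample")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) \
        / (nx + ny - 2)
    if pooled_var == 0:
        raise FloatingPointError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p values: min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else int(m)
    return np.minimum(1.0, p * m)


@dataclass
class RecordingClassification:
    """Outcome of the regime classification of one recording."""

    group_label: str
    tests: pd.DataFrame  # one row per (method, measure) comparison

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.group_label


def classify_recording(flows: dict[tuple[str, str], FlowSeries],
                       alpha: float = 0.05) -> RecordingClassification:
    """Assign a preictal recording to a connectivity regime.

    ``flows`` maps (method, measure) - with method in {pdc, dtf} and
    measure in {inflow, outflow} - to that measure's preictal FlowSeries.
    Per-segment normalized values are pooled across segments; SOZ vs
    non-SOZ channels are compared by Wilcoxon rank-sum at level ``alpha``
    per test (Bonferroni-adjusted p values over the recording's four tests
    are reported alongside).  The recording is inflow-dominant iff SOZ
    inflow is significantly higher for both PDC and DTF while outflow is
    not (symmetrically for outflow-dominant); anything else is
    unclassified.  Requiring agreement of both estimators keeps the rule
    conservative on exchangeable null data.
    """
    methods = sorted({m for m, _ in flows})
    rows = []
    sig_higher: dict[str, dict[str, bool]] = {"inflow": {}, "outflow": {}}
    p_raw = []
    for (method, measure), flow in sorted(flows.items()):
        if flow.soz_mask is None:
            raise ValidationError("FlowSeries carries no SOZ annotation")
        soz = flow.soz_values()
        non = flow.non_soz_values()
        u, p = wilcoxon_ranksum(soz, non)
        d = cohens_d(soz, non) if min(soz.size, non.size) >= 2 else np.nan
        higher = np.median(soz) > np.median(non)
        rows.append({"method": method, "measure": measure,
                     "statistic": u, "p_raw": p, "effect_size_d": d,
                     "soz_higher": higher})
        p_raw.append(p)
    tests = pd.DataFrame(rows)
    tests["p_adjusted"] = bonferroni(tests["p_raw"].to_numpy())
    for _, r in tests.iterrows():
        sig_higher[r["measure"]][r["method"]] = bool(
            r["soz_higher"] and r["p_raw"] < alpha)
    inflow_sig = all(sig_higher["inflow"].get(m, False) for m in methods)
    outflow_sig = all(sig_higher["outflow"].get(m, False) for m in methods)
    if inflow_sig and not outflow_sig:
        label = INFLOW_DOMINANT
    elif outflow_sig and not inflow_sig:
        label = OUTFLOW_DOMINANT
    else:
        label = UNCLASSIFIED
    return RecordingClassification(group_label=label, tests=tests)


@dataclass
class EvaluationResult:
    """Per-recording evaluation bundle used by cohort summaries."""

    auc_table: pd.DataFrame  # patient, seizure, method, measure, period, auc
    group_label: str
    tests: pd.DataFrame
    meta: dict = field(default_factory=dict)


@dataclass
class CohortSummary:
    table: pd.DataFrame
    strata_tests: pd.DataFrame | None = None


def summarize_cohort(results: list[EvaluationResult],
                     stratify_by: str | None = None) -> CohortSummary:
    """Median and IQR of AUC per (method, measure, period, group) cell,
    optionally split by a metadata key, with pairwise Bonferroni-corrected
    rank-sum tests between strata."""
    if not results:
        raise ValidationError("no evaluation results to summarize")
    frames = []
    for res in results:
        t = res.auc_table.copy()
        t["group"] = res.group_label
        if stratify_by is not None:
            if stratify_by not in res.meta:
                raise ValidationError(
                    f"unknown metadata key {stratify_by!r}")
            t["stratum"] = res.meta[stratify_by]
        frames.append(t)
    table = pd.concat(frames, ignore_index=True)
    keys = ["method", "measure", "period", "group"]
    if stratify_by is not None:
        keys.append("stratum")
    summary = table.groupby(keys)["auc"].agg(
        median="median",
        iqr_low=lambda a: float(np.percentile(a, 25)),
        iqr_high=lambda a: float(np.percentile(a, 75)),
        n="count").reset_index()

    strata_tests = None
    if stratify_by is not None:
        rows = []
        cell_keys = ["method", "measure", "period"]
        for cell, sub in table.groupby(cell_keys):
            strata = sorted(sub["stratum"].unique())
            for a, b in combinations(strata, 2):
                xa = sub.loc[sub["stratum"] == a, "auc"].to_numpy()
                xb = sub.loc[sub["stratum"] == b, "auc"].to_numpy()
                if len(xa) == 0 or len(xb) == 0:
                    continue
                u, p = wilcoxon_ranksum(xa, xb)
                rows.append(dict(zip(cell_keys, cell)) | {
                    "stratum_a": a, "stratum_b": b,
                    "statistic": u, "p_raw": p})
        strata_tests = pd.DataFrame(rows)
        if len(strata_tests):
            strata_tests["p_adjusted"] = bonferroni(
                strata_tests["p_raw"].to_numpy())
    return CohortSummary(table=summary, strata_tests=strata_tests)
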