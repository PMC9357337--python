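"""Benchmarking predictions against external dependency scores, plus enrichment.

The external reference is an Achilles-like table of continuous per-(gene,
sample) dependency scores where lower means more essential; the
conventional ground-truth rule labels a gene essential in a sample when
its score falls below -0.5. Predictions are compared to that label on the
pooled (gene, sample) pairs through delta-score (mean score difference
between predicted-essential and predicted-not-essential groups), a
two-sample location test, Matthews correlation and precision. Sweeping the
ECS threshold trades coverage for precision. The case-control enrichment
operation asks, per gene, whether essential calls concentrate in the case
group (one-sided hypergeometric test, BH-adjusted across genes).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import matthews_corrcoef
from statsmodels.stats.multitest import multipletests

from .essentiality import threshold_ecs, classify_global

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkResult",
    "read_scores",
    "benchmark",
    "ecs_sweep",
    "enrichment",
]

#: conventional ground-truth cutoff: score < -0.5 means truly essential
DEFAULT_SCORE_THRESHOLD = -0.5


@dataclass(frozen=True)
class BenchmarkResult:
    """Agreement between binary predictions and continuous scores.

    ``delta_score`` and ``p_value`` are NaN when either prediction group is
    empty; ``precision`` is NaN when nothing was predicted essential.
    """

    n: int
    delta_score: float
    mcc: float
    precision: float
    p_value: float


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a tidy (gene, sample, score) table, comma- or tab-separated."""
    frame = pd.read_csv(path, sep=None, engine="python")
    required = {"gene", "sample", "score"}
    if not required.issubset(frame.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    if frame.duplicated(["gene", "sample"]).any():
        raise ValueError("score table has duplicate (gene, sample) pairs")
    return frame[["gene", "sample", "score"]]


def benchmark(
    calls: pd.DataFrame,
    scores: pd.DataFrame,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    test: str = "welch",
) -> BenchmarkResult:
    """Compare binary calls with continuous scores on (gene, sample) pairs.

    ``calls`` needs columns (gene, sample, c); ``scores`` (gene, sample,
    score). Pairs present in both tables are pooled. Ground truth is
    ``score < threshold``. The location test on the two score groups is
    Welch's t by default, or a two-sided Wilcoxon rank-sum with
    ``test="ranksum"``.
    """
    merged = calls.merge(scores, on=["gene", "sample"], how="inner")
    if merged.empty:
        raise ValueError("calls and scores share no (gene, sample) pair")
    predicted = merged["c"].astype(int).to_numpy()
    score = merged["score"].to_numpy(dtype=float)
    truth = (score < threshold).astype(int)

    ess = score[predicted == 1]
    non = score[predicted == 0]
    if len(ess) and len(non):
        delta = float(ess.mean() - non.mean())
        if test == "welch":
            p_value = float(stats.ttest_ind(ess, non, equal_var=False).pvalue)
        elif test == "ranksum":
            p_value = float(stats.mannwhitneyu(ess, non, alternative="two-sided").pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
    else:
        delta = math.nan
        p_value = math.nan

    with warnings.catch_warnings():
        # single-class inputs: sklearn warns and returns 0, its documented
        # convention for a degenerate confusion matrix
        warnings.simplefilter("ignore")
        mcc = float(matthews_corrcoef(truth, predicted))
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    precision = tp / (tp + fp) if (tp + fp) else math.nan

    return BenchmarkResult(
        n=len(merged),
        delta_score=delta,
        mcc=mcc,
        precision=precision,
        p_value=p_value,
    )


def ecs_sweep(
    ecs_tables: Mapping[str, pd.DataFrame],
    scores: pd.DataFrame,
    grid: Sequence[float],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    test: str = "welch",
) -> pd.DataFrame:
    """Benchmark at each ECS threshold of ``grid``.

    ``ecs_tables`` maps sample id to that sample's ECS table. At every
    threshold, per-sample binary calls are recomputed (``ecs > th``), genes
    that become globally essential or globally not essential across the
    samples are excluded, and the remaining context-dependent pairs are
    benchmarked. Returns one row per threshold with columns (th, n,
    delta_score, mcc, precision, p_value); metrics are NaN when no
    context-dependent pair remains.
    """
    rows = []
    for th in grid:
        per_sample = []
        for sample, table in ecs_tables.items():
            calls = threshold_ecs(table, th).reset_index()
            calls["sample"] = sample
            per_sample.append(calls)
        tidy = pd.concat(per_sample, ignore_index=True)
        labels = classify_global(tidy)
        keep = set(labels.loc[labels["label"] == "context_dependent", "gene"])
        subset = tidy[tidy["gene"].isin(keep)]
        if subset.empty or subset.merge(scores, on=["gene", "sample"]).empty:
            rows.append((th, 0, math.nan, math.nan, math.nan, math.nan))
            continue
        result = benchmark(subset, scores, threshold=threshold, test=test)
        rows.append(
            (th, result.n, result.delta_score, result.mcc, result.precision, result.p_value)
        )
    return pd.DataFrame(
        rows, columns=["th", "n", "delta_score", "mcc", "precision", "p_value"]
    )


def enrichment(
    calls: pd.DataFrame,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Per-gene over-representation of essential calls in the case group.

    ``calls`` is a tidy (gene, sample, c) table of binary essentiality;
    ``groups`` maps every sample to ``"case"`` or ``"control"``. For each
    gene, with N total samples of which K are cases and k_total carry an
    essential call (k_case of them cases), the one-sided hypergeometric
    tail P[X >= k_case] under random allocation of the k_total essential
    samples is reported, Benjamini-Hochberg adjusted across genes. Output
    columns: gene, k_case, k_total, p_hyper, p_adj, sorted by p_hyper.
    """
    samples = sorted(groups)
    labels = {s: groups[s] for s in samples}
    bad = {g for g in labels.values() if g not in ("case", "control")}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    n_total = len(samples)
    n_case = sum(1 for s in samples if labels[s] == "case")
    if n_case == 0 or n_case == n_total:
        raise ValueError("need at least one case and one control sample")

    subset = calls[calls["sample"].isin(labels)]
    rows = []
    for gene, block in subset.groupby("gene", sort=True):
        essential = set(block.loc[block["c"].astype(int) == 1, "sample"])
        k_total = len(essential)
        k_case = sum(1 for s in essential if labels[s] == "case")
        p_hyper = float(stats.hypergeom.sf(k_case - 1, n_total, n_case, k_total))
        rows.append((gene, k_case, k_total, p_hyper))
    frame = pd.DataFrame(rows, columns=["gene", "k_case", "k_total", "p_hyper"])
    if len(frame):
        frame["p_adj"] = multipletests(frame["p_hyper"], method="fdr_bh")[1]
    else:
        frame["p_adj"] = pd.Series(dtype=float)
    return frame.sort_values(["p_hyper", "gene"], ignore_index=True)
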