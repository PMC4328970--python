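"""Tag-count expression data: TPM normalization and differential expression.

Digital gene expression (DGE) tag profiling measures each gene's expression
as the number of sequenced 3' tags falling in that gene.  Counts are
normalized to tags per million (TPM) within each library, and differential
expression between two libraries is assessed with an exact test on the pair
of tag counts, with Benjamini-Hochberg control of the false discovery rate
across genes.

A gene is called temporally differentially expressed (a DEG) between two
developmental stages when it passes three gates simultaneously:
``|log2 ratio| > 0.5``, ``p < 0.009`` and ``q < 0.02``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionDataset",
    "normalize_tpm",
    "tag_count_test",
    "tag_count_density",
    "bh_fdr",
    "detect_temporal_degs",
    "DEG_LOG2_RATIO",
    "DEG_P",
    "DEG_FDR",
]

# Default DEG thresholds applied jointly.
DEG_LOG2_RATIO = 0.5
DEG_P = 0.009
DEG_FDR = 0.02

REQUIRED_SAMPLE_COLUMNS = ("condition", "stage", "period")
PERIODS = ("prenatal", "postnatal")


@dataclass
class ExpressionDataset:
    """A gene-by-sample tag-count matrix with sample metadata.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integer tag counts, genes as rows and
        samples as columns.
    samples
        DataFrame indexed by sample id with columns ``condition``,
        ``stage`` and ``period`` (one of ``prenatal``/``postnatal``).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    _tpm: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("gene identifiers must be unique")
        if not self.counts.columns.is_unique:
            raise ValueError("sample identifiers must be unique")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")
        bad_period = set(self.samples["period"]) - set(PERIODS)
        if bad_period:
            raise ValueError(f"unknown period values: {sorted(bad_period)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        # align metadata to count columns
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def tpm(self) -> pd.DataFrame:
        if self._tpm is None:
            self._tpm = normalize_tpm(self.counts)
        return self._tpm

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, mask: pd.Series) -> "ExpressionDataset":
        keep = list(self.samples.index[mask])
        return ExpressionDataset(self.counts[keep], self.samples.loc[keep])

    def for_period(self, period: str) -> "ExpressionDataset":
        if period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}, got {period!r}")
        return self.subset_samples(self.samples["period"] == period)

    def for_condition(self, condition: str) -> "ExpressionDataset":
        return self.subset_samples(self.samples["condition"] == condition)

    # -- round-trip text I/O ------------------------------------------------
    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "ExpressionDataset":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype={"stage": str})
        samples.index = samples.index.astype(str)
        counts.columns = counts.columns.astype(str)
        return cls(counts, samples)


def normalize_tpm(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Normalize tag counts to tags per million within each sample column.

    ``tpm[g, s] = counts[g, s] / total(s) * 1e6``.  A sample with zero total
    tags has no defined normalization and raises, naming the sample.
    """
    values = np.asarray(counts, dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        if isinstance(counts, pd.DataFrame):
            names = [str(counts.columns[i]) for i in zero]
        else:
            names = [f"column {i}" for i in zero]
        raise ValueError(f"all-zero sample(s): {', '.join(names)}")
    tpm = values / totals * 1e6
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)
    return tpm


# ---------------------------------------------------------------------------
# Exact two-library tag-count test
# ---------------------------------------------------------------------------

def tag_count_density(x: int, y: int, n1: float, n2: float) -> float:
    """Probability of observing ``y`` tags in library 2 given ``x`` in library 1.

    ``p(y|x) = ((x+y)! / (x! y!)) (N2/N1)^y / (1 + N2/N1)^(x+y+1)``, which is
    the negative-binomial pmf ``NB(y; x+1, N1/(N1+N2))``.
    """
    if x < 0 or y < 0:
        raise ValueError("tag counts must be nonnegative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    return float(stats.nbinom.pmf(y, x + 1, n1 / (n1 + n2)))


def _min_likelihood_tail(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided tail: sum of density terms p(y'|x) <= p(y|x).

    The density is unimodal in y', so the retained terms are the complement
    of a contiguous interval around the mode; its edges are located by
    bisection on the log-pmf, making the tail O(log support).
    """
    q = n1 / (n1 + n2)
    r = x + 1
    logpmf = lambda k: stats.nbinom.logpmf(k, r, q)
    ref = logpmf(y)
    if not np.isfinite(ref):
        return 0.0
    thr = ref + abs(ref) * 1e-12 + 1e-12  # tie tolerance
    mode = max(int(np.floor(x * (1 - q) / q)), 0)
    if logpmf(mode) <= thr:
        return 1.0
    # left edge: smallest y' inside the excluded interval
    if logpmf(0) > thr:
        left = 0
    else:
        lo, hi = 0, mode
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if logpmf(mid) > thr:
                hi = mid
            else:
                lo = mid
        left = hi
    # right edge: largest y' inside the excluded interval
    lo = mode
    hi = max(int(stats.nbinom.ppf(1 - 1e-15, r, q)) + 10, mode + 1)
    while logpmf(hi) > thr:
        hi *= 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if logpmf(mid) > thr:
            lo = mid
        else:
            hi = mid
    right = lo
    inside = stats.nbinom.cdf(right, r, q)
    if left > 0:
        inside -= stats.nbinom.cdf(left - 1, r, q)
    return float(min(max(1.0 - inside, 0.0), 1.0))


def tag_count_test(x: int, y: int, n1: float, n2: float) -> float:
    """Exact two-sided p-value for differential expression of one gene
    between two tag libraries of total sizes ``n1`` and ``n2``.

    The minimum-likelihood tail of the exact tag-count density is evaluated
    conditioning on each library in turn and the two tails averaged, making
    the p-value symmetric under swapping ``(x, n1)`` with ``(y, n2)``.
    """
    if x < 0 or y < 0:
        raise ValueError("tag counts must be nonnegative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    p = 0.5 * (_min_likelihood_tail(x, y, n1, n2) + _min_likelihood_tail(y, x, n2, n1))
    return float(min(p, 1.0))


def _nb_logpmf(k, r, q):
    """Negative-binomial log-pmf, vectorized over ``k``; -inf for k < 0."""
    from scipy.special import gammaln

    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        out = (
            gammaln(k + r)
            - gammaln(r)
            - gammaln(k + 1.0)
            + r * np.log(q)
            + k * np.log1p(-q)
        )
    return np.where(k < 0, -np.inf, out)


def _nb_cdf(k, r, q):
    """P(X <= k) for X ~ NB(r, q), vectorized; 0 for k < 0."""
    from scipy.special import betainc

    k = np.asarray(k, dtype=float)
    return np.where(k < 0, 0.0, betainc(r, np.floor(k) + 1.0, q))


def _min_likelihood_tail_many(x: np.ndarray, y: np.ndarray, n1: float, n2: float) -> np.ndarray:
    """Vectorized min-likelihood two-sided tail over gene vectors.

    Same statistic as :func:`_min_likelihood_tail`, computed for all genes
    at once by bisecting the (unimodal) log-pmf around its mode.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    q = n1 / (n1 + n2)
    r = x + 1.0
    ref = _nb_logpmf(y, r, q)
    thr = ref + np.abs(ref) * 1e-12 + 1e-12
    mode = np.maximum(np.floor(x * (1 - q) / q), 0.0)
    everything = _nb_logpmf(mode, r, q) <= thr  # whole support in the tail

    # left edge of the excluded interval: smallest k with logpmf > thr
    lo = np.full_like(x, -1.0)  # logpmf(-1) = -inf <= thr always
    hi = mode.copy()
    while True:
        gap = hi - lo
        if not (gap > 1).any():
            break
        mid = np.floor((lo + hi) / 2.0)
        above = _nb_logpmf(mid, r, q) > thr
        hi = np.where((gap > 1) & above, mid, hi)
        lo = np.where((gap > 1) & ~above, mid, lo)
    left = hi

    # right edge: largest k with logpmf > thr
    sd = np.sqrt(r * (1 - q)) / q
    hi = np.ceil(mode + 20.0 * sd + 20.0)  # keep bounds integral for bisection
    while True:
        open_ = _nb_logpmf(hi, r, q) > thr
        if not open_.any():
            break
        hi = np.where(open_, hi * 2 + 10, hi)
    lo = mode.copy()
    while True:
        gap = hi - lo
        if not (gap > 1).any():
            break
        mid = np.floor((lo + hi) / 2.0)
        above = _nb_logpmf(mid, r, q) > thr
        lo = np.where((gap > 1) & above, mid, lo)
        hi = np.where((gap > 1) & ~above, mid, hi)
    right = lo

    inside = _nb_cdf(right, r, q) - _nb_cdf(left - 1.0, r, q)
    tail = np.clip(1.0 - inside, 0.0, 1.0)
    return np.where(everything, 1.0, tail)


def tag_count_test_many(x, y, n1: float, n2: float) -> np.ndarray:
    """Vectorized :func:`tag_count_test` over per-gene count vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("tag counts must be nonnegative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    p = 0.5 * (
        _min_likelihood_tail_many(x, y, n1, n2)
        + _min_likelihood_tail_many(y, x, n2, n1)
    )
    return np.minimum(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: ``q_i = min_{j>=rank(i)} p_(j) m/j``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Temporal DEG detection
# ---------------------------------------------------------------------------

def _log2_ratio(tpm_a: np.ndarray, tpm_b: np.ndarray, pseudocount: float) -> np.ndarray:
    return np.log2((tpm_a + pseudocount) / (tpm_b + pseudocount))


def detect_temporal_degs(
    dataset: ExpressionDataset,
    period: str,
    *,
    log2_ratio_threshold: float = DEG_LOG2_RATIO,
    p_threshold: float = DEG_P,
    fdr_threshold: float = DEG_FDR,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Identify genes differentially expressed between developmental stages.

    All pairwise stage comparisons within ``period`` are tested; replicate
    libraries of a stage are pooled into one library.  FDR is controlled per
    comparison family (one BH correction per stage pair, across genes).  A
    gene is a DEG if any comparison passes all three gates; its row reports
    the best-supported (smallest-p) comparison.

    Returns a DataFrame with one row per (gene, stage pair) tested, columns
    ``gene, stage_a, stage_b, log2_ratio, p_value, q_value, is_deg, best``.
    """
    sub = dataset.for_period(period)
    stages = list(dict.fromkeys(sub.samples["stage"]))
    if len(stages) < 2:
        raise ValueError(f"need >=2 stages in period {period!r}, found {len(stages)}")

    # pool replicates per stage into one library
    pooled = {}
    for stage in stages:
        cols = sub.samples.index[sub.samples["stage"] == stage]
        pooled[stage] = sub.counts[list(cols)].sum(axis=1)
    pooled = pd.DataFrame(pooled)
    totals = pooled.sum(axis=0)
    tpm = normalize_tpm(pooled)

    records = []
    for i in range(len(stages)):
        for j in range(i + 1, len(stages)):
            a, b = stages[i], stages[j]
            xa = pooled[a].to_numpy()
            xb = pooled[b].to_numpy()
            lr = _log2_ratio(tpm[b].to_numpy(), tpm[a].to_numpy(), pseudocount)
            pvals = tag_count_test_many(xa, xb, totals[a], totals[b])
            qvals = bh_fdr(pvals)
            is_deg = (
                (np.abs(lr) > log2_ratio_threshold)
                & (pvals < p_threshold)
                & (qvals < fdr_threshold)
            )
            records.append(
                pd.DataFrame(
                    {
                        "gene": pooled.index,
                        "stage_a": a,
                        "stage_b": b,
                        "log2_ratio": lr,
                        "p_value": pvals,
                        "q_value": qvals,
                        "is_deg": is_deg,
                    }
                )
            )
    table = pd.concat(records, ignore_index=True)
    # best-supported comparison per gene
    best_idx = table.loc[table.groupby("gene")["p_value"].idxmin().to_numpy()].index
    table["best"] = False
    table.loc[best_idx, "best"] = True
    return table


def deg_gene_set(deg_table: pd.DataFrame) -> list[str]:
    """Genes passing the DEG gates in at least one stage comparison."""
    return sorted(deg_table.loc[deg_table["is_deg"], "gene"].unique())
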