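"""Exploratory data analysis: per-class moments, rank tests and PCA.

Distribution summaries use population moments: Fisher-Pearson skewness
g1 = m3 / m2^(3/2) and excess kurtosis g2 = m4 / m2^2 - 3 (normal -> 0).
Between-class comparisons use the two-sided Mann-Whitney U test, exact for
small tie-free samples and otherwise via the tie-corrected normal
approximation with continuity correction.  Chemical-space PCA standardizes
each descriptor to zero mean / unit variance (equivalently, eigenanalysis
of the correlation matrix) before projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ConfigurationError

#: product of sample sizes below which the exact U distribution is enumerated
EXACT_LIMIT = 400


@dataclass
class ClassSummary:
    """Distribution summary of one descriptor within one potency class."""

    descriptor_name: str
    class_label: str
    n: int
    max: float
    min: float
    median: float
    mean: float
    skewness: float | None
    kurtosis: float | None


def summarize_class(values, class_label: str, descriptor_name: str) -> ClassSummary:
    """Summarize one descriptor/class sample.

    Skewness and kurtosis need at least three points and non-degenerate
    spread; otherwise they are reported as None rather than fabricated.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("summarize_class requires at least one value")
    skew = kurt = None
    if x.size >= 3 and np.ptp(x) > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return ClassSummary(
        descriptor_name=descriptor_name,
        class_label=class_label,
        n=int(x.size),
        max=float(x.max()),
        min=float(x.min()),
        median=float(np.median(x)),
        mean=float(x.mean()),
        skewness=skew,
        kurtosis=kurt,
    )


def class_summary_table(
    descriptor_frame: pd.DataFrame, classes: pd.Series
) -> pd.DataFrame:
    """Long-format table of per-descriptor, per-class summaries."""
    rows = []
    for name in descriptor_frame.columns:
        for label in pd.unique(classes):
            vals = descriptor_frame.loc[np.asarray(classes) == label, name]
            s = summarize_class(vals, str(label), str(name))
            rows.append(s.__dict__)
    return pd.DataFrame(rows)


@dataclass
class RankTestResult:
    descriptor_name: str
    class_pair: tuple[str, str]
    u_statistic: float
    p_value: float
    significant: bool
    method: str = "asymptotic"
    degenerate: bool = False


def mann_whitney(
    x,
    y,
    *,
    alpha: float = 0.05,
    descriptor_name: str = "",
    class_pair: tuple[str, str] = ("x", "y"),
) -> RankTestResult:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    Exact enumeration of the U null distribution is used when
    n1*n2 <= EXACT_LIMIT and the pooled sample is tie-free; otherwise the
    normal approximation with midrank tie correction and continuity
    correction.  When every value in both samples is identical the test is
    degenerate: U = n1*n2/2 and p = 1 are reported with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return RankTestResult(
            descriptor_name, class_pair,
            u_statistic=x.size * y.size / 2.0, p_value=1.0,
            significant=False, method="degenerate", degenerate=True,
        )
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and x.size * y.size <= EXACT_LIMIT:
        method = "exact"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    p = float(min(res.pvalue, 1.0))
    return RankTestResult(
        descriptor_name, class_pair,
        u_statistic=float(res.statistic), p_value=p,
        significant=bool(p < alpha), method=method,
    )


def rank_test_table(
    descriptor_frame: pd.DataFrame,
    classes: pd.Series,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise class comparisons for every descriptor column."""
    labels = list(pd.unique(classes))
    cls = np.asarray(classes)
    rows = []
    for name in descriptor_frame.columns:
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                r = mann_whitney(
                    descriptor_frame.loc[cls == a, name],
                    descriptor_frame.loc[cls == b, name],
                    alpha=alpha,
                    descriptor_name=str(name),
                    class_pair=(str(a), str(b)),
                )
                d = r.__dict__.copy()
                d["class_pair"] = f"{a}|{b}"
                rows.append(d)
    return pd.DataFrame(rows)


@dataclass
class PCAResult:
    feature_names: list[str]
    loadings: np.ndarray            # feature x component
    explained_variance_pct: np.ndarray
    cumulative_variance_pct: np.ndarray
    scores: np.ndarray              # sample x component
    dropped_columns: list[str] = field(default_factory=list)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.feature_names, columns=cols)

    def scores_frame(self, index=None) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=index, columns=cols)


def run_pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of the column-standardized matrix.

    Columns are scaled to zero mean / unit (population) variance; zero
    variance columns are dropped with a warning.  Components are ordered by
    decreasing eigenvalue, with the deterministic sign convention that the
    largest-magnitude loading of each component is positive.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ConfigurationError("PCA requires at least 2 rows and 2 columns")
    if matrix.isna().any().any():
        raise ConfigurationError("PCA input contains missing values")

    sd = matrix.std(axis=0, ddof=0)
    dropped = [str(c) for c in matrix.columns[sd == 0]]
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
        matrix = matrix.loc[:, sd > 0]
        sd = sd[sd > 0]
    z = (matrix - matrix.mean(axis=0)) / sd

    rank = min(z.shape[0] - 1, z.shape[1])
    k = rank if n_components is None else min(n_components, rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_.T.copy()  # feature x component

    # sign convention: dominant loading positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    # explained variance as a share of the full standardized variance
    total_var = float(np.var(z.to_numpy(), axis=0, ddof=1).sum())
    evr = pca.explained_variance_ / total_var * 100.0
    return PCAResult(
        feature_names=[str(c) for c in matrix.columns],
        loadings=loadings,
        explained_variance_pct=evr,
        cumulative_variance_pct=np.cumsum(evr),
        scores=scores,
        dropped_columns=dropped,
    )


def plot_pca_scores(result: PCAResult, classes, path) -> None:
    """PC1-vs-PC2 scatter coloured by potency class, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = np.asarray(classes)
    fig, ax = plt.subplots(figsize=(6, 5))
    for label in pd.unique(classes):
        m = classes == label
        ax.scatter(result.scores[m, 0], result.scores[m, 1], s=18,
                   alpha=0.7, label=str(label))
    ax.set_xlabel(f"PC1 ({result.explained_variance_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({result.explained_variance_pct[1]:.1f}%)")
    ax.legend(title="class")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
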