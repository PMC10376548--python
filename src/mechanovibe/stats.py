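"""Group statistics and feature/mechanics correlations.

Compares filament-feature distributions across experimental conditions and
correlates condition-level summaries (median filament length/thickness,
mean angle) against the mechanical parameters of each condition (RMS
acceleration, shear stress).

Skewed features (lengths, thicknesses) use the Kruskal–Wallis omnibus test
with pairwise Wilcoxon rank-sum post hoc tests; approximately normal
features (angles) use pairwise Welch t tests with a one-way ANOVA omnibus.
No multiple-testing correction is applied by default (a Holm option is
available).  The statistical unit may be the pooled filaments or per-image
summaries (``pooling="filaments"`` / ``"images"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "CorrelationResult", "compare_groups", "correlate"]


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    groups: tuple[str, ...]
    omnibus_p: float
    pairwise: tuple[tuple[str, str, float, float], ...]  # (a, b, statistic, p)
    effect_summary: pd.DataFrame  # per-group n, mean, median

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairwise, columns=["group_a", "group_b", "statistic", "p"]
        )


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    p: float
    n: int


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def compare_groups(
    table: pd.DataFrame,
    feature: str,
    group_col: str = "condition",
    distribution_mode: str = "skewed",
    pooling: str = "filaments",
    holm: bool = False,
) -> GroupComparison:
    """Omnibus + pairwise comparison of one feature across groups.

    ``distribution_mode="skewed"`` (lengths/thicknesses): Kruskal–Wallis
    omnibus, pairwise Wilcoxon rank-sum.  ``"normal"`` (angles): one-way
    ANOVA omnibus, pairwise Welch t tests.  Normality routing is
    caller-declared, not auto-tested.  ``pooling="images"`` first reduces
    each (replicate, field) image to its median feature value.
    """
    if distribution_mode not in ("skewed", "normal"):
        raise ValueError("distribution_mode must be 'skewed' or 'normal'")
    df = table
    if pooling == "images":
        df = (
            table.groupby([group_col, "replicate", "field"], as_index=False)[feature]
            .median()
        )
    elif pooling != "filaments":
        raise ValueError("pooling must be 'filaments' or 'images'")
    labels = [str(g) for g in df[group_col].unique()]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = {g: df.loc[df[group_col] == g, feature].to_numpy(float) for g in labels}
    for g, x in samples.items():
        if x.size < 2:
            raise ValueError(f"group {g!r} has n < 2")

    if distribution_mode == "skewed":
        omnibus = float(sps.kruskal(*samples.values()).pvalue)
        pair_fn = lambda a, b: sps.ranksums(a, b)  # noqa: E731
    else:
        omnibus = float(sps.f_oneway(*samples.values()).pvalue)
        pair_fn = lambda a, b: sps.ttest_ind(a, b, equal_var=False)  # noqa: E731

    pairs = list(combinations(labels, 2))
    stats_p = [pair_fn(samples[a], samples[b]) for a, b in pairs]
    pvals = [float(r.pvalue) for r in stats_p]
    if holm:
        pvals = _holm(pvals)
    pairwise = tuple(
        (a, b, float(r.statistic), p)
        for (a, b), r, p in zip(pairs, stats_p, pvals)
    )
    effect = pd.DataFrame(
        {
            "group": labels,
            "n": [samples[g].size for g in labels],
            "mean": [float(samples[g].mean()) for g in labels],
            "median": [float(np.median(samples[g])) for g in labels],
        }
    ).set_index("group")
    return GroupComparison(feature, tuple(labels), omnibus, pairwise, effect)


def correlate(
    condition_features: np.ndarray | pd.Series,
    mechanical_params: np.ndarray | pd.Series,
    x_name: str = "feature",
    y_name: str = "mechanical",
) -> CorrelationResult:
    """Pearson correlation between condition-level features and mechanics."""
    x = np.asarray(condition_features, dtype=float)
    y = np.asarray(mechanical_params, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    res = sps.pearsonr(x, y)
    return CorrelationResult(x_name, y_name, float(res.statistic), float(res.pvalue), x.size)
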