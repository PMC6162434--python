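"""Group comparison and correlation statistics.

The comparison protocol is one-way ANOVA followed by all pairwise
pooled-variance t tests, with the family of pairwise p-values controlled
for false discovery rate by the Benjamini–Krieger–Yekutieli (BKY)
two-stage step-up procedure at q = 0.05; associations are assessed by
Pearson correlation.  Group summaries are reported as mean ± SEM.

The BKY procedure is implemented from its published two-stage definition
(stage 1: Benjamini–Hochberg step-up at q′ = q/(1+q) to estimate the number
of true nulls; stage 2: BH step-up at level q·m/m̂₀) so that its edge cases
are explicit and unit-testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupData:
    """Per-group observations of one metric."""

    labels: tuple[str, ...]
    values: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values must align")
        if len(self.labels) < 2:
            raise ValueError("need at least 2 groups")
        object.__setattr__(
            self, "values", tuple(np.asarray(v, dtype=float).ravel() for v in self.values)
        )

    @classmethod
    def from_frame(cls, df, group_col: str, value_col: str) -> "GroupData":
        labels = tuple(df[group_col].unique())
        values = tuple(
            df.loc[df[group_col] == lab, value_col].to_numpy(dtype=float)
            for lab in labels
        )
        return cls(labels=labels, values=values)


@dataclass(frozen=True)
class FdrConfig:
    """Target FDR level for the two-stage step-up procedure."""

    q: float = 0.05
    method: str = "two_stage_step_up"

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must lie in (0, 1)")


def _check_anova_groups(data: GroupData) -> None:
    for lab, v in zip(data.labels, data.values):
        if v.size < 2:
            raise ValueError(f"group {lab!r} has n < 2")


def one_way_anova(data: GroupData) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    Returns (F, p) with (k−1, N−k) degrees of freedom.  Raises when the
    pooled within-group variance is zero (F undefined).
    """
    _check_anova_groups(data)
    ns = np.array([v.size for v in data.values])
    means = np.array([v.mean() for v in data.values])
    grand = np.concatenate(data.values).mean()
    k, n_total = len(ns), int(ns.sum())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((v - m) ** 2) for v, m in zip(data.values, means)))
    if ss_within == 0:
        raise ValueError("zero within-group variance: F statistic undefined")
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    f = ms_between / ms_within
    p = float(sps.f.sf(f, k - 1, n_total - k))
    return float(f), p


def pooled_within_ms(data: GroupData) -> tuple[float, int]:
    """Pooled within-group mean square and its df (N−k)."""
    ns = np.array([v.size for v in data.values])
    ss_within = float(
        sum(np.sum((v - v.mean()) ** 2) for v in data.values)
    )
    df = int(ns.sum()) - len(ns)
    return ss_within / df, df


def posthoc_pairwise(data: GroupData, welch: bool = False) -> dict[tuple[str, str], float]:
    """All pairwise two-sided t tests after ANOVA.

    Default uses the pooled within-group mean square with N−k df,
    consistent with ANOVA's homoscedasticity assumption; ``welch=True``
    switches to Welch's unequal-variance t test per pair.
    """
    _check_anova_groups(data)
    out: dict[tuple[str, str], float] = {}
    if not welch:
        ms_w, df = pooled_within_ms(data)
        if ms_w == 0:
            raise ValueError("zero within-group variance")
    for i in range(len(data.labels)):
        for j in range(i + 1, len(data.labels)):
            vi, vj = data.values[i], data.values[j]
            if welch:
                p = float(sps.ttest_ind(vi, vj, equal_var=False).pvalue)
            else:
                se = np.sqrt(ms_w * (1.0 / vi.size + 1.0 / vj.size))
                t = (vi.mean() - vj.mean()) / se
                p = float(2.0 * sps.t.sf(abs(t), df))
            out[(data.labels[i], data.labels[j])] = p
    return out


def _bh_stepup(pvals: np.ndarray, level: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at the given level."""
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    thresh = level * np.arange(1, m + 1) / m
    below = np.nonzero(ranked <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject


def bky_fdr(pvals, config: FdrConfig | None = None) -> tuple[np.ndarray, dict]:
    """Benjamini–Krieger–Yekutieli two-stage step-up FDR control.

    Stage 1 runs BH at q′ = q/(1+q); its rejection count r₁ estimates the
    number of false nulls.  If r₁ = 0 nothing is rejected; if r₁ = m
    everything is.  Otherwise stage 2 reruns BH at the inflated level
    q·m/m̂₀ with m̂₀ = m − r₁.  Flags are returned in input order along
    with stage diagnostics.
    """
    config = config or FdrConfig()
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = config.q
    q1 = q / (1.0 + q)
    stage1 = _bh_stepup(p, q1)
    r1 = int(stage1.sum())
    m = p.size
    diag = {"q_stage1": q1, "r1": r1, "m": m}
    if r1 == 0:
        diag.update(m0_hat=m, q_stage2=None)
        return np.zeros(m, dtype=bool), diag
    if r1 == m:
        diag.update(m0_hat=0, q_stage2=None)
        return np.ones(m, dtype=bool), diag
    m0_hat = m - r1
    q2 = q * m / m0_hat
    diag.update(m0_hat=m0_hat, q_stage2=q2)
    return _bh_stepup(p, q2), diag


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-based p (n−2 df)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def summarize_groups(data: GroupData):
    """Mean ± SEM (SD/√n) table, one row per group."""
    import pandas as pd

    rows = []
    for lab, v in zip(data.labels, data.values):
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        rows.append({"group": lab, "n": int(v.size), "mean": float(v.mean()), "sem": sem})
    return pd.DataFrame(rows)
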