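"""Tissue-specificity statistics: the highest/second-highest fold change,
a group differential-expression test, FDR adjustment, and the rescue rule.

The bias statistic FC is the ratio of the highest to the second-highest
per-tissue expression of a transcript (tissue mean TPM by default), with a
small pseudocount so tissue-exclusive transcripts get a large finite value
instead of a division by zero. Transcripts are called upregulated in their
top tissue when FC >= 2 (inclusive) and the FDR-adjusted q-value of a group
test is < 0.05 (strict); transcripts the group test cannot assess — those
expressed only in tissues lacking replication — are *rescued* when FC >= 2.

The group test is a one-way ANOVA F-test on log2(TPM + 0.5) across tissues
with at least two replicate libraries. It is a transparent stand-in for the
bootstrap-based likelihood-ratio machinery used in pseudoalignment-native
differential-expression tools, not a numerical replica of it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

__all__ = ["tissue_fc", "de_test", "bh_adjust", "call_upregulated", "TissueBiasTester"]

_ZERO_TOL = 1e-10


def tissue_fc(per_tissue_expression: dict, pseudocount: float = 0.01) -> tuple[str, float]:
    """Top tissue and fold change (max + pc) / (second max + pc).

    Exact ties for the top break to the lexicographically smallest tissue
    name (and give FC = 1 before the pseudocount adjustment).
    """
    if len(per_tissue_expression) < 2:
        raise ValueError("tissue fold change needs at least 2 tissues")
    items = sorted(per_tissue_expression.items())
    values = np.array([v for _, v in items], dtype=float)
    if (values < 0).any():
        raise ValueError("negative expression value")
    top_i = int(np.argmax(values))
    second = np.partition(values, -2)[-2]
    fc = (values[top_i] + pseudocount) / (second + pseudocount)
    return items[top_i][0], float(fc)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_f(values: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA over rows of ``values``.

    ``groups`` holds column-index arrays, one per tissue. Returns (F, p) with
    NaN p marking untestable rows (resolved by the caller)."""
    n_total = sum(len(g) for g in groups)
    n_groups = len(groups)
    grand = values[:, np.concatenate(groups)].mean(axis=1)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for g in groups:
        sub = values[:, g]
        mean_g = sub.mean(axis=1)
        ssb += len(g) * (mean_g - grand) ** 2
        ssw += ((sub - mean_g[:, None]) ** 2).sum(axis=1)
    dfb = n_groups - 1
    dfw = n_total - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(f, dfb, dfw)
    # degenerate rows
    flat = (ssw < _ZERO_TOL) & (ssb < _ZERO_TOL)
    p = np.where(flat, 1.0, p)
    f = np.where(flat, 0.0, f)
    separated = (ssw < _ZERO_TOL) & (ssb >= _ZERO_TOL)
    p = np.where(separated, 0.0, p)
    f = np.where(separated, np.inf, f)
    return f, p


def de_test(m: ExpressionMatrix, transcript_id: str, min_replicates: int = 2):
    """One-way ANOVA across tissues for one transcript.

    Returns ``(F, p)``; ``p`` is None when the transcript is untestable:
    fewer than two tissues carry >= ``min_replicates`` libraries, or the
    transcript has zero expression in every tested library (tissue-exclusive
    to an untested tissue — the rescue path).
    """
    if transcript_id not in m.counts.index:
        raise KeyError(f"unknown transcript {transcript_id!r}")
    # TPM is a whole-matrix quantity; test after normalising over all rows
    tester = TissueBiasTester(min_replicates=min_replicates).fit(m)
    row = tester.results_.loc[transcript_id]
    p = None if pd.isna(row["p_value"]) else float(row["p_value"])
    f = None if pd.isna(row["statistic"]) else float(row["statistic"])
    return f, p


def call_upregulated(
    results: pd.DataFrame, fc_min: float = 2.0, q_max: float = 0.05
) -> pd.DataFrame:
    """Retention rule: FC >= ``fc_min`` (inclusive) and q < ``q_max``
    (strict), or the rescue path (untestable and FC >= ``fc_min``)."""
    passed_de = (results["fc"] >= fc_min) & (results["q_value"] < q_max)
    rescued = results["p_value"].isna() & (results["fc"] >= fc_min)
    out = results.copy()
    out["passed_de"] = passed_de.fillna(False)
    out["rescued"] = rescued
    up = out["passed_de"] | out["rescued"]
    out["upregulated_in"] = out["top_tissue"].where(up)
    return out[up]


class TissueBiasTester(BaseEstimator):
    """Per-transcript tissue-bias statistics over an expression matrix.

    Parameters
    ----------
    fc_min : float, default=2.0
        Inclusive fold-change retention threshold.
    q_max : float, default=0.05
        Strict q-value retention threshold.
    pseudocount : float, default=0.01
        TPM added to numerator and denominator of the fold change.
    fc_mode : {"mean", "max"}, default="mean"
        Per-tissue expression summary feeding the fold change: mean TPM over
        the tissue's libraries, or the single-library maximum.
    min_replicates : int, default=2
        Tissues with fewer libraries are excluded from the group test (they
        still contribute to the fold change and may be the top tissue).

    Attributes
    ----------
    results_ : pandas.DataFrame
        Indexed by transcript: top_tissue, fc, statistic, p_value, q_value,
        passed_de, rescued, upregulated_in. p/q are NaN for untestable rows.
    tested_tissues_ : list[str]
        Tissues entering the group test.
    """

    def __init__(
        self,
        fc_min: float = 2.0,
        q_max: float = 0.05,
        pseudocount: float = 0.01,
        fc_mode: str = "mean",
        min_replicates: int = 2,
    ):
        self.fc_min = fc_min
        self.q_max = q_max
        self.pseudocount = pseudocount
        self.fc_mode = fc_mode
        self.min_replicates = min_replicates

    def fit(self, X: ExpressionMatrix, y=None) -> "TissueBiasTester":
        if self.fc_mode not in ("mean", "max"):
            raise ValueError(f"unknown fc_mode {self.fc_mode!r}")
        if len(X.tissues) < 2:
            raise ValueError("tissue bias needs at least 2 tissues")
        tpm = X.tpm()
        if self.fc_mode == "mean":
            per_tissue = X.tissue_means(tpm)
        else:
            per_tissue = tpm.T.groupby(X.design).max().T
        per_tissue = per_tissue.reindex(sorted(per_tissue.columns), axis=1)

        vals = per_tissue.values
        order = np.sort(vals, axis=1)
        top_idx = np.argmax(vals, axis=1)  # first max -> lexicographic tie-break
        fc = (order[:, -1] + self.pseudocount) / (order[:, -2] + self.pseudocount)
        top_tissue = per_tissue.columns.values[top_idx]

        reps = X.replicate_counts()
        tested = [t for t in per_tissue.columns if reps.get(t, 0) >= self.min_replicates]
        self.tested_tissues_ = tested

        n = tpm.shape[0]
        stat = np.full(n, np.nan)
        p = np.full(n, np.nan)
        if len(tested) >= 2:
            libs = X.design.index
            groups = [
                np.flatnonzero(np.asarray(X.design.loc[libs] == t)) for t in tested
            ]
            tested_cols = np.concatenate(groups)
            logv = np.log2(tpm.values + 0.5)
            stat, p = _group_f(logv, groups)
            # zero expression in every tested library: the group test cannot
            # see the transcript at all -> untestable (rescue-eligible)
            unseen = tpm.values[:, tested_cols].max(axis=1) == 0
            stat = np.where(unseen, np.nan, stat)
            p = np.where(unseen, np.nan, p)

        q = np.full(n, np.nan)
        testable = ~np.isnan(p)
        if testable.any():
            q[testable] = bh_adjust(p[testable])

        results = pd.DataFrame(
            {
                "top_tissue": top_tissue,
                "fc": fc,
                "statistic": stat,
                "p_value": p,
                "q_value": q,
            },
            index=tpm.index,
        )
        results["passed_de"] = (results["fc"] >= self.fc_min) & (
            results["q_value"] < self.q_max
        )
        results["rescued"] = results["p_value"].isna() & (results["fc"] >= self.fc_min)
        up = results["passed_de"] | results["rescued"]
        results["upregulated_in"] = results["top_tissue"].where(up)
        self.results_ = results
        self.per_tissue_ = per_tissue
        return self

    @property
    def upregulated_(self) -> pd.DataFrame:
        return self.results_[self.results_["passed_de"] | self.results_["rescued"]]
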