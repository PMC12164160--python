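"""TPM quantification, the TPM >= 1 expression filter, and PCA-based QC.

Counts and effective lengths arrive from an upstream pseudoaligner; here they
are converted to transcripts-per-million (TPM), lowly expressed transcripts
(TPM < 1 in every library) are dropped, and a principal component analysis of
the most variable transcripts summarises whether libraries group by tissue.

TPM for transcript i in a library: (c_i / l_i) / sum_j (c_j / l_j) * 1e6,
with c the estimated count and l the effective length in nucleotides; each
library's TPM column sums to one million.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

__all__ = ["ExpressionMatrix", "QcSummary", "tpm", "expression_filter", "pca_qc", "ExpressionFilter"]


@dataclass
class ExpressionMatrix:
    """Transcripts x libraries counts with effective lengths and a design map.

    ``counts`` is indexed by transcript id with one column per library;
    ``eff_length`` maps transcript id -> effective length (nt, >= 1);
    ``design`` maps library id -> tissue name.
    """

    counts: pd.DataFrame
    eff_length: pd.Series
    design: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.design, pd.Series):
            self.design = pd.Series(self.design)
        if not isinstance(self.eff_length, pd.Series):
            self.eff_length = pd.Series(self.eff_length)
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"libraries missing from design: {sorted(missing)}")
        if not self.counts.index.is_unique:
            raise ValueError("duplicate transcript ids in counts")
        if set(self.counts.index) - set(self.eff_length.index):
            raise ValueError("effective length missing for some transcripts")
        self.eff_length = self.eff_length.reindex(self.counts.index)
        if (self.eff_length < 1).any():
            bad = self.eff_length[self.eff_length < 1].index[0]
            raise ValueError(f"effective length < 1 nt for transcript {bad!r}")
        self.design = self.design.loc[self.counts.columns]

    @property
    def transcripts(self) -> list[str]:
        return list(self.counts.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.design))

    def tpm(self) -> pd.DataFrame:
        """Per-library TPM; columns sum to 1e6 (all-zero libraries stay zero)."""
        rate = self.counts.div(self.eff_length, axis=0)
        totals = rate.sum(axis=0)
        zero = totals == 0
        if zero.any():
            warnings.warn(
                f"all-zero library (TPM left at zero): {list(totals.index[zero])}",
                stacklevel=2,
            )
            totals = totals.mask(zero, 1.0)
        return rate.div(totals, axis=1) * 1e6

    def tissue_means(self, values: pd.DataFrame | None = None) -> pd.DataFrame:
        """Mean of ``values`` (default TPM) over each tissue's libraries."""
        if values is None:
            values = self.tpm()
        return values.T.groupby(self.design).mean().T

    def subset(self, transcript_ids) -> "ExpressionMatrix":
        ids = [t for t in self.transcripts if t in set(transcript_ids)]
        return ExpressionMatrix(
            counts=self.counts.loc[ids],
            eff_length=self.eff_length.loc[ids],
            design=self.design.copy(),
        )

    def replicate_counts(self) -> pd.Series:
        return self.design.value_counts()


@dataclass
class QcSummary:
    """Variance structure of the library-level PCA QC."""

    variance_explained: list[float]
    n_top_transcripts: int
    coordinates: pd.DataFrame = field(repr=False, default=None)


def tpm(counts, eff_length) -> np.ndarray:
    """TPM for a single library's count vector."""
    c = np.asarray(counts, dtype=float)
    l = np.asarray(eff_length, dtype=float)
    if (l <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (c < 0).any():
        raise ValueError("negative counts")
    rate = c / l
    total = rate.sum()
    if total == 0:
        warnings.warn("all-zero library: TPM is all zero", stacklevel=2)
        return np.zeros_like(rate)
    return rate / total * 1e6


def expression_filter(m: ExpressionMatrix, min_tpm: float = 1.0) -> list[str]:
    """Ids of transcripts with TPM >= ``min_tpm`` in at least one library."""
    return ExpressionFilter(min_tpm=min_tpm).fit(m).kept_ids_


class ExpressionFilter(BaseEstimator):
    """Keeps transcripts reaching ``min_tpm`` (inclusive) in >= 1 library.

    Attributes
    ----------
    tpm_ : pandas.DataFrame
        The TPM matrix computed during ``fit``.
    kept_ids_ : list[str]
    """

    def __init__(self, min_tpm: float = 1.0):
        self.min_tpm = min_tpm

    def fit(self, X: ExpressionMatrix, y=None) -> "ExpressionFilter":
        self.tpm_ = X.tpm()
        keep = (self.tpm_ >= self.min_tpm).any(axis=1)
        self.kept_ids_ = list(self.tpm_.index[keep])
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        return X.subset(self.kept_ids_)


def pca_qc(m: ExpressionMatrix, n_top: int = 1000) -> QcSummary:
    """PCA of libraries on the ``n_top`` most variable transcripts.

    Transcript variance is computed on log2(TPM + 1); the selected rows are
    centred per transcript and libraries are projected. Returns the fraction
    of variance explained per component (non-increasing, sums to <= 1).
    """
    if len(m.libraries) < 2:
        raise ValueError("PCA QC needs at least 2 libraries")
    logv = np.log2(m.tpm() + 1.0)
    variances = logv.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="mergesort").index[:n_top]
    X = logv.loc[top]
    X = X.sub(X.mean(axis=1), axis=0)
    pca = PCA(n_components=min(len(m.libraries) - 1, X.shape[0]))
    coords = pca.fit_transform(X.T.values)
    coordinates = pd.DataFrame(
        coords,
        index=m.libraries,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return QcSummary(
        variance_explained=[float(v) for v in pca.explained_variance_ratio_],
        n_top_transcripts=int(len(top)),
        coordinates=coordinates,
    )
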