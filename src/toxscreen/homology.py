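"""Homology-evidence filtering and the toxin best-hit rule.

Transcripts are annotated against several protein databases (a curated animal
toxin set such as ToxProt among them). Retention requires at least one hit
with e-value strictly below the cutoff in *any* database; a retained
transcript is *toxin-like* when its best hit — the highest bit score among
passing hits pooled over all databases — comes from the database flagged as
the toxin database. Bit-score ties break by lower e-value, then lexicographic
subject id, so the decision is independent of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "HomologyHit",
    "AnnotationDecision",
    "filter_by_evalue",
    "annotate",
    "HomologyAnnotator",
]

HIT_COLUMNS = ["query_id", "subject_id", "database", "evalue", "bitscore", "pct_identity"]


@dataclass(frozen=True)
class HomologyHit:
    """One query -> subject scored match from a tabular protein search."""

    query_id: str
    subject_id: str
    database: str
    evalue: float
    bitscore: float
    pct_identity: float = float("nan")


@dataclass(frozen=True)
class AnnotationDecision:
    query_id: str
    retained: bool
    best_hit: HomologyHit | None
    is_toxin_like: bool


def _as_frame(hits) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        df = hits.loc[:, HIT_COLUMNS].copy()
    else:
        df = pd.DataFrame([h.__dict__ for h in hits], columns=HIT_COLUMNS)
    if len(df) and (df["evalue"] < 0).any():
        bad = df.loc[df["evalue"] < 0].iloc[0]
        raise ValueError(f"negative e-value {bad['evalue']} for query {bad['query_id']!r}")
    return df


def filter_by_evalue(hits, max_evalue: float = 1e-5):
    """Keep hits with e-value strictly below ``max_evalue``."""
    if isinstance(hits, pd.DataFrame):
        df = _as_frame(hits)
        return hits.loc[df.index[df["evalue"] < max_evalue]]
    _as_frame(hits)
    return [h for h in hits if h.evalue < max_evalue]


def annotate(
    queries: list[str],
    hits,
    max_evalue: float = 1e-5,
    toxin_db: str = "toxprot",
    databases: set[str] | None = None,
) -> list[AnnotationDecision]:
    """One decision per query: retained iff any passing hit; toxin-like iff
    the pooled best hit is in the toxin database."""
    ann = HomologyAnnotator(
        max_evalue=max_evalue, toxin_db=toxin_db, databases=databases
    ).fit(hits, queries=queries)
    out = []
    for qid, row in ann.decisions_.iterrows():
        best = None
        if row["retained"]:
            best = HomologyHit(
                query_id=qid,
                subject_id=row["best_subject"],
                database=row["best_database"],
                evalue=row["best_evalue"],
                bitscore=row["best_bitscore"],
                pct_identity=row["best_pct_identity"],
            )
        out.append(
            AnnotationDecision(
                query_id=qid,
                retained=bool(row["retained"]),
                best_hit=best,
                is_toxin_like=bool(row["is_toxin_like"]),
            )
        )
    return out


class HomologyAnnotator(BaseEstimator):
    """Best-hit annotator over a table of homology hits.

    Parameters
    ----------
    max_evalue : float, default=1e-5
        Strict upper bound on e-value for a hit to count.
    toxin_db : str, default="toxprot"
        Database tag flagged as the toxin database.
    databases : set of str, optional
        Declared database tags; hits carrying an undeclared tag raise. When
        omitted, the tags observed in the hit table (plus ``toxin_db``) are
        taken as declared.
    best_hit_scope : {"pooled", "per_database"}, default="pooled"
        "pooled" assigns toxin-like when the single best hit across all
        databases is in the toxin database; "per_database" assigns it when
        any passing hit in the toxin database exists, regardless of scores
        elsewhere.

    Attributes
    ----------
    decisions_ : pandas.DataFrame
        Indexed by query id: retained, best_subject, best_database,
        best_evalue, best_bitscore, best_pct_identity, is_toxin_like.
    retained_ids_, toxin_like_ids_ : list[str]
    """

    def __init__(
        self,
        max_evalue: float = 1e-5,
        toxin_db: str = "toxprot",
        databases: set[str] | None = None,
        best_hit_scope: str = "pooled",
    ):
        self.max_evalue = max_evalue
        self.toxin_db = toxin_db
        self.databases = databases
        self.best_hit_scope = best_hit_scope

    def fit(self, X, y=None, queries: list[str] | None = None) -> "HomologyAnnotator":
        if self.best_hit_scope not in ("pooled", "per_database"):
            raise ValueError(f"unknown best_hit_scope {self.best_hit_scope!r}")
        df = _as_frame(X)
        declared = (
            set(self.databases) if self.databases is not None else set(df["database"])
        ) | {self.toxin_db}
        unknown = set(df["database"]) - declared
        if unknown:
            raise ValueError(f"unknown database tag(s): {sorted(unknown)}")
        if queries is None:
            queries = list(dict.fromkeys(df["query_id"]))
        else:
            stray = set(df["query_id"]) - set(queries)
            if stray:
                raise ValueError(f"hits for unknown queries: {sorted(stray)[:5]}")

        passing = df[df["evalue"] < self.max_evalue]
        # canonical tie-break: highest bitscore, then lowest e-value, then
        # lexicographic subject id
        ranked = passing.sort_values(
            ["query_id", "bitscore", "evalue", "subject_id"],
            ascending=[True, False, True, True],
            kind="mergesort",
        )
        best = ranked.drop_duplicates("query_id").set_index("query_id")

        dec = pd.DataFrame(index=pd.Index(queries, name="query_id"))
        dec["retained"] = dec.index.isin(best.index)
        for col, src in [
            ("best_subject", "subject_id"),
            ("best_database", "database"),
            ("best_evalue", "evalue"),
            ("best_bitscore", "bitscore"),
            ("best_pct_identity", "pct_identity"),
        ]:
            dec[col] = best[src].reindex(dec.index)
        if self.best_hit_scope == "pooled":
            dec["is_toxin_like"] = (dec["best_database"] == self.toxin_db).fillna(False)
        else:
            toxin_queries = set(passing.loc[passing["database"] == self.toxin_db, "query_id"])
            dec["is_toxin_like"] = dec.index.isin(toxin_queries) & dec["retained"]
        dec["is_toxin_like"] = dec["is_toxin_like"].astype(bool)

        self.decisions_ = dec
        self.retained_ids_ = list(dec.index[dec["retained"]])
        self.toxin_like_ids_ = list(dec.index[dec["is_toxin_like"]])
        return self
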