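"""End-to-end toxin-candidate discovery.

Chains the cascade on a bundled study: complete-ORF screen, homology
retention and toxin best-hit assignment, >99% identity redundancy
clustering, TPM >= 1 expression filter, tissue-bias testing with the rescue
rule, and candidate integration with family classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator

from . import report
from .bias import TissueBiasTester
from .candidates import integrate
from .cluster import IdentityClusterer
from .expression import ExpressionFilter, ExpressionMatrix
from .homology import HomologyAnnotator
from .orfs import OrfScreen, TranscriptRecord

__all__ = ["StudyData", "ToxinDiscoveryPipeline", "run_pipeline"]


@dataclass
class StudyData:
    """Inputs of one discovery run.

    transcripts: assembled nucleotide sequences; expression: counts /
    effective lengths / design; hits: homology hit table (query_id,
    subject_id, database, evalue, bitscore, pct_identity); annotations:
    optional per-transcript table with domain / signal_peptide / neurotoxic
    columns (external predictions, pass-through only).
    """

    transcripts: list[TranscriptRecord]
    expression: ExpressionMatrix
    hits: pd.DataFrame
    annotations: pd.DataFrame | None = None
    toxin_db: str = "toxprot"
    databases: set[str] | None = None


class ToxinDiscoveryPipeline(BaseEstimator):
    """The full discovery cascade as a single fit-style estimator.

    Attributes (after ``fit``)
    --------------------------
    orf_screen_, annotator_, clusterer_, expression_filter_, bias_ :
        The fitted stage estimators.
    decisions_ : pandas.DataFrame
        Homology decisions for ORF-passing transcripts.
    bias_results_ : pandas.DataFrame
        Tissue-bias statistics for expressed representatives.
    candidates_ : pandas.DataFrame
        Final candidate table (toxin-like and upregulated).
    stage_counts_ : list[tuple[str, int]]
        Survivor count after each cascade stage.
    summary_ : dict
        The machine-readable run summary.
    """

    def __init__(
        self,
        min_aa: int = 20,
        identity_threshold: float = 0.99,
        max_evalue: float = 1e-5,
        min_tpm: float = 1.0,
        fc_min: float = 2.0,
        q_max: float = 0.05,
        pseudocount: float = 0.01,
        fc_mode: str = "mean",
        min_replicates: int = 2,
    ):
        self.min_aa = min_aa
        self.identity_threshold = identity_threshold
        self.max_evalue = max_evalue
        self.min_tpm = min_tpm
        self.fc_min = fc_min
        self.q_max = q_max
        self.pseudocount = pseudocount
        self.fc_mode = fc_mode
        self.min_replicates = min_replicates

    def fit(self, X: StudyData, y=None, seed: int | None = None) -> "ToxinDiscoveryPipeline":
        stage_counts = [("input", len(X.transcripts))]

        # 1. complete-ORF screen
        self.orf_screen_ = OrfScreen(min_aa=self.min_aa).fit(X.transcripts)
        kept = [t for t in X.transcripts if t.id in self.orf_screen_.chosen_orfs_]
        stage_counts.append(("complete_orf", len(kept)))

        # 2. homology retention (any passing hit) + toxin best-hit rule
        kept_ids = {t.id for t in kept}
        hits = X.hits[X.hits["query_id"].isin(kept_ids)]
        self.annotator_ = HomologyAnnotator(
            max_evalue=self.max_evalue,
            toxin_db=X.toxin_db,
            databases=X.databases,
        ).fit(hits, queries=[t.id for t in kept])
        self.decisions_ = self.annotator_.decisions_
        retained = [t for t in kept if t.id in set(self.annotator_.retained_ids_)]
        stage_counts.append(("homology_retained", len(retained)))

        # 3. redundancy clustering; only representatives proceed
        self.clusterer_ = IdentityClusterer(threshold=self.identity_threshold).fit(retained)
        reps = self.clusterer_.transform(retained)
        stage_counts.append(("cluster_representatives", len(reps)))

        # 4. expression filter (TPM >= min_tpm in >= 1 library)
        em = X.expression.subset([t.id for t in reps])
        self.expression_filter_ = ExpressionFilter(min_tpm=self.min_tpm).fit(em)
        expressed = self.expression_filter_.kept_ids_
        stage_counts.append(("expressed", len(expressed)))

        toxin_like = [
            t for t in expressed if t in set(self.annotator_.toxin_like_ids_)
        ]
        stage_counts.append(("toxin_like", len(toxin_like)))

        # 5. tissue bias over the expressed representatives
        self.bias_ = TissueBiasTester(
            fc_min=self.fc_min,
            q_max=self.q_max,
            pseudocount=self.pseudocount,
            fc_mode=self.fc_mode,
            min_replicates=self.min_replicates,
        ).fit(em.subset(expressed))
        self.bias_results_ = self.bias_.results_

        # 6. integration: toxin-like AND upregulated, plus pass-through labels
        ann = X.annotations
        domains = neuro = sigp = None
        if ann is not None:
            domains = ann["domain"] if "domain" in ann.columns else None
            neuro = ann["neurotoxic"] if "neurotoxic" in ann.columns else None
            sigp = ann["signal_peptide"] if "signal_peptide" in ann.columns else None
        proteins = {
            tid: call.protein for tid, call in self.orf_screen_.chosen_orfs_.items()
        }
        self.candidates_ = integrate(
            self.decisions_.loc[expressed],
            self.bias_results_,
            domains=domains,
            neurotoxicity=neuro,
            signal_peptides=sigp,
            proteins=proteins,
        )
        stage_counts.append(("candidates", len(self.candidates_)))

        self.stage_counts_ = stage_counts
        self.summary_ = report.summarize(self, seed=seed)
        return self


def run_pipeline(study: StudyData, seed: int | None = None, **params) -> ToxinDiscoveryPipeline:
    """Convenience wrapper: fit a ToxinDiscoveryPipeline on ``study``."""
    return ToxinDiscoveryPipeline(**params).fit(study, seed=seed)
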