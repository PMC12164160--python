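"""Greedy redundancy clustering of nucleotide sequences at >99% identity.

Near-identical assembly redundancy (allelic variants, partial duplicates) is
collapsed by greedy, longest-first clustering: each sequence joins the first
existing cluster whose *representative* it matches at strictly more than the
identity threshold, otherwise it founds a new cluster. Only representatives
proceed downstream.

Identity between two sequences is the number of identically aligned positions
of a global alignment divided by the length of the shorter sequence, so an
exact prefix of a longer sequence scores 1.0. The strict ``>`` is honoured:
a pair at exactly the threshold does not cluster.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
from Bio import Align
from sklearn.base import BaseEstimator

from .orfs import TranscriptRecord

__all__ = ["Cluster", "pairwise_identity", "cluster_sequences", "IdentityClusterer"]


@dataclass
class Cluster:
    """One redundancy cluster; the representative is the longest member."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)


def _make_aligner() -> Align.PairwiseAligner:
    # unit match score; mismatches preferred over gap pairs so substitutions
    # align as substitutions, terminal overhangs as gaps
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of the shorter sequence aligned identically under a global
    alignment; in [0, 1]."""
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    if a == b:
        return 1.0
    alignment = _ALIGNER.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def cluster_sequences(
    ts: list[TranscriptRecord], threshold: float = 0.99
) -> list[Cluster]:
    """Greedy longest-first clustering at identity strictly above ``threshold``."""
    return IdentityClusterer(threshold=threshold).fit(ts).clusters_


class IdentityClusterer(BaseEstimator):
    """Greedy longest-first sequence clusterer (CD-HIT-like semantics).

    Sequences are processed by decreasing length (ties by id); each joins the
    first cluster, in founding order, whose representative it matches at
    identity strictly greater than ``threshold``, else founds a new cluster.

    A conservative shared-k-mer inverted index plus banded edit-distance
    bounds screen candidate representatives before the exact alignment is
    consulted; the screen is exact for substitution- and truncation-type
    divergence and can be disabled with ``prefilter=False``.

    Attributes
    ----------
    clusters_ : list[Cluster]
        Clusters in founding order; every input appears in exactly one.
    labels_ : list[int]
        Cluster index per input record, in input order.
    representative_ids_ : list[str]
        Representative id per cluster, founding order.
    """

    def __init__(self, threshold: float = 0.99, kmer_size: int = 11, prefilter: bool = True):
        self.threshold = threshold
        self.kmer_size = kmer_size
        self.prefilter = prefilter

    def fit(self, X: list[TranscriptRecord], y=None) -> "IdentityClusterer":
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        ids = [t.id for t in X]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript ids in clustering input")

        order = sorted(X, key=lambda t: (-len(t.seq), t.id))
        k = self.kmer_size
        reps: list[TranscriptRecord] = []
        clusters: list[Cluster] = []
        assignment: dict[str, int] = {}
        index: dict[str, list[int]] = defaultdict(list)

        for rec in order:
            if self.prefilter:
                candidates = self._candidates(rec, reps, index)
            else:
                candidates = range(len(reps))
            target = None
            for ci in candidates:
                if self._joins(rec.seq, reps[ci].seq):
                    target = ci
                    break
            if target is None:
                target = len(clusters)
                reps.append(rec)
                clusters.append(Cluster(representative_id=rec.id))
                if self.prefilter:
                    for km in self._kmers(rec.seq):
                        index[km].append(target)
            clusters[target].member_ids.append(rec.id)
            assignment[rec.id] = target

        self.clusters_ = clusters
        self.representative_ids_ = [c.representative_id for c in clusters]
        self.labels_ = [assignment[t.id] for t in X]
        return self

    def transform(self, X: list[TranscriptRecord]) -> list[TranscriptRecord]:
        """Reduce fitted input to cluster representatives (input order)."""
        keep = set(self.representative_ids_)
        return [t for t in X if t.id in keep]

    # -- internals ---------------------------------------------------------

    def _kmers(self, seq: str) -> set[str]:
        k = self.kmer_size
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    def _min_matches(self, shorter_len: int) -> int:
        # identity strictly > threshold over the shorter sequence
        m = int(self.threshold * shorter_len + 1e-9) + 1
        return min(m, shorter_len)

    def _candidates(
        self,
        rec: TranscriptRecord,
        reps: list[TranscriptRecord],
        index: dict[str, list[int]],
    ) -> list[int]:
        k = self.kmer_size
        ls = len(rec.seq)
        if ls <= k:
            return list(range(len(reps)))
        counts: Counter[int] = Counter()
        for km in self._kmers(rec.seq):
            for ci in index.get(km, ()):
                counts[ci] += 1
        # at most e substituted positions on the shorter sequence, each able
        # to destroy up to k k-mers; factor 2 leaves headroom for indels
        e_max = ls - self._min_matches(ls)
        needed = (ls - k + 1) - 2 * k * max(e_max, 1)
        if needed <= 0:
            return sorted(counts)
        return sorted(ci for ci, n in counts.items() if n >= needed)

    def _joins(self, query: str, rep: str) -> bool:
        if query == rep:
            return True
        ls = min(len(query), len(rep))
        m_min = self._min_matches(ls)
        d = edlib.align(query, rep, mode="NW", task="distance")["editDistance"]
        # each edit operation spoils at most one matched position of the shorter
        if ls - d >= m_min:
            return True
        # any alignment with m matches has edit cost >= la + lb - 2m
        if (len(query) + len(rep) - d) / 2 < m_min:
            return False
        return pairwise_identity(query, rep) > self.threshold
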