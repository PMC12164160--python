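"""Complete-ORF screening and translation of assembled transcripts.

The first stage of the annotation cascade: a transcript survives only if it
carries at least one *complete* open reading frame — an ATG start codon with
an in-frame stop (TAA/TAG/TGA) on either strand — whose translation is at
least ``min_aa`` residues long (20 by default). The longest such ORF is kept
as the transcript's representative protein for all downstream homology and
family classification steps.

Coordinates are 0-based half-open on the *reported* strand's sequence, i.e.
for a minus-strand call they index into the reverse complement. The ORF end
includes the stop codon; the reported protein excludes it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TranscriptRecord",
    "OrfCall",
    "find_orfs",
    "screen_transcripts",
    "reverse_complement",
    "OrfScreen",
]

_INVALID_NT = re.compile(r"[^ACGTN]")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class TranscriptRecord:
    """An assembled nucleotide sequence; the unit flowing through the cascade."""

    id: str
    seq: str


@dataclass(frozen=True)
class OrfCall:
    """A complete open reading frame on a transcript.

    ``start``/``end`` are 0-based half-open positions on the sequence in the
    reported orientation (the reverse complement for ``strand == '-'``);
    ``end`` includes the stop codon. ``protein`` excludes the stop.
    """

    transcript_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str
    complete: bool = True

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a whole number of codons")
        if len(self.protein) != (self.end - self.start) // 3 - 1:
            raise ValueError("protein length inconsistent with ORF span")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_nucleotides(seq: str, transcript_id: str) -> None:
    if not seq:
        raise ValueError(f"empty sequence for transcript {transcript_id!r}")
    m = _INVALID_NT.search(seq)
    if m:
        raise ValueError(
            f"invalid nucleotide {m.group()!r} at position {m.start()} "
            f"in transcript {transcript_id!r}"
        )


def _scan_strand(seq: str, transcript_id: str, strand: str, min_aa: int) -> list[OrfCall]:
    """All complete ORFs on one strand: every ATG paired with its first
    in-frame stop. Any N inside the candidate span disqualifies it."""
    calls: list[OrfCall] = []
    has_n = "N" in seq
    for frame in range(3):
        trimmed = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
        prot = str(Seq(trimmed).translate())
        seg_start = 0
        while True:
            stop = prot.find("*", seg_start)
            if stop == -1:
                break
            # ambiguous codons translate to 'X'; an ORF crossing one would
            # span an N, so only starts after the last X can be emitted
            last_x = prot.rfind("X", seg_start, stop)
            lo = seg_start if last_x == -1 else last_x + 1
            i = prot.find("M", lo, stop)
            while i != -1 and i <= stop - min_aa:
                nt_start = frame + 3 * i
                nt_end = frame + 3 * (stop + 1)
                if not (has_n and "N" in seq[nt_start:nt_end]):
                    calls.append(
                        OrfCall(transcript_id, nt_start, nt_end, strand, frame, prot[i:stop])
                    )
                i = prot.find("M", i + 1, stop)
            seg_start = stop + 1
    return calls


def find_orfs(t: TranscriptRecord, min_aa: int = 20, both_strands: bool = True) -> list[OrfCall]:
    """Return all complete ORFs with protein length >= ``min_aa``.

    Scans the three reading frames of the forward strand and, by default, of
    the reverse complement as well. Results are sorted by protein length
    (descending), then start, then strand ('+' before '-').
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    _validate_nucleotides(t.seq, t.id)
    calls = _scan_strand(t.seq, t.id, "+", min_aa)
    if both_strands:
        calls.extend(_scan_strand(reverse_complement(t.seq), t.id, "-", min_aa))
    calls.sort(key=lambda c: (-len(c.protein), c.start, c.strand))
    return calls


def screen_transcripts(
    ts: list[TranscriptRecord], min_aa: int = 20, both_strands: bool = True
) -> tuple[list[TranscriptRecord], dict[str, OrfCall]]:
    """Keep transcripts with >=1 complete ORF of >= ``min_aa`` residues.

    Returns the kept transcripts (input order) and the chosen ORF per kept
    transcript: the longest, ties broken by smallest start then '+' strand.
    """
    screen = OrfScreen(min_aa=min_aa, both_strands=both_strands).fit(ts)
    kept = [t for t in ts if t.id in screen.chosen_orfs_]
    return kept, dict(screen.chosen_orfs_)


class OrfScreen(TransformerMixin, BaseEstimator):
    """Complete-ORF filter in scikit-learn transformer form.

    Parameters
    ----------
    min_aa : int, default=20
        Minimum protein length (residues, excluding the stop) for an ORF to
        qualify.
    both_strands : bool, default=True
        Whether the reverse complement is scanned as well.

    Attributes
    ----------
    orfs_ : dict[str, list[OrfCall]]
        All qualifying ORFs per transcript seen in ``fit``.
    chosen_orfs_ : dict[str, OrfCall]
        The selected ORF for each kept transcript.
    kept_ids_ : list[str]
        Ids of kept transcripts, in input order.
    """

    def __init__(self, min_aa: int = 20, both_strands: bool = True):
        self.min_aa = min_aa
        self.both_strands = both_strands

    def fit(self, X: list[TranscriptRecord], y=None) -> "OrfScreen":
        ids = [t.id for t in X]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate transcript id {dup!r}")
        self.orfs_ = {}
        self.chosen_orfs_ = {}
        self.kept_ids_ = []
        for t in X:
            calls = find_orfs(t, min_aa=self.min_aa, both_strands=self.both_strands)
            if calls:
                self.orfs_[t.id] = calls
                # find_orfs sort order already encodes the chosen-ORF tie-break
                self.chosen_orfs_[t.id] = calls[0]
                self.kept_ids_.append(t.id)
        return self

    def transform(self, X: list[TranscriptRecord]) -> list[TranscriptRecord]:
        """Filter ``X`` down to transcripts with a qualifying complete ORF."""
        return [
            t
            for t in X
            if find_orfs(t, min_aa=self.min_aa, both_strands=self.both_strands)
        ]
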