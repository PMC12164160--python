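"""Candidate integration, protein-family classification, and the cysteine
framework analysis of knottin-like peptides.

A toxin candidate is a transcript that is both toxin-like (best homology hit
in the toxin database) and upregulated in some tissue (significant fold
change or rescued as tissue-exclusive). Domain labels, signal-peptide flags
and neurotoxicity predictions from external annotators are carried through
descriptively — they never filter. Candidates without a domain label are
reported under the family "No prediction".

The knottin (inhibitor cystine knot) check renders a peptide's cysteine
arrangement as a pattern string — C for each cysteine, X for a single
intervening residue, "-" for a longer variable gap — and compares it with
the canonical 10-cysteine framework C-CXC-CC-CXC-CXC-C.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CandidateRecord",
    "CysSignature",
    "NO_PREDICTION",
    "integrate",
    "classify_family",
    "cys_signature",
    "matches_knottin",
]

NO_PREDICTION = "No prediction"

# gaps between consecutive cysteines of the canonical knottin framework
# C-CXC-CC-CXC-CXC-C: fixed single-residue gaps after C2, C6 and C8, the CC
# adjacency after C4; the remaining gaps are variable but non-empty
KNOTTIN_N_CYS = 10
KNOTTIN_FIXED_GAPS = {2: 1, 4: 0, 6: 1, 8: 1}

_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")  # X = ambiguous translation


@dataclass(frozen=True)
class CandidateRecord:
    """A transcript that passed every filter of the discovery cascade."""

    transcript_id: str
    best_subject: str
    best_database: str
    family: str
    top_tissue: str
    fc: float
    q_value: float | None
    rescued: bool
    neurotoxic: bool | None
    signal_peptide: bool | None
    protein: str | None


@dataclass(frozen=True)
class CysSignature:
    """Cysteine count and inter-cysteine spacing of a peptide."""

    n_cys: int
    gaps: tuple[int, ...]
    pattern: str


def classify_family(domain_label: str | None, has_hit: bool = True) -> str:
    """Family = the predicted domain label, else "No prediction" for
    sequences with a positive homology hit but no domain annotation."""
    if not has_hit:
        raise ValueError("family classification applies to hit-positive sequences")
    if domain_label is None or (isinstance(domain_label, float) and pd.isna(domain_label)):
        return NO_PREDICTION
    label = str(domain_label).strip()
    return label if label else NO_PREDICTION


def cys_signature(protein: str) -> CysSignature:
    """Cysteine spacing signature of ``protein``.

    The pattern writes X for a gap of exactly one residue, nothing for
    adjacent cysteines, and "-" for any longer gap.
    """
    for i, aa in enumerate(protein):
        if aa not in _AA:
            raise ValueError(f"invalid amino acid {aa!r} at position {i}")
    positions = [i for i, aa in enumerate(protein) if aa == "C"]
    gaps = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
    parts = []
    for g in gaps:
        parts.append("" if g == 0 else "X" if g == 1 else "-")
    pattern = "C" + "".join(p + "C" for p in parts) if positions else ""
    return CysSignature(n_cys=len(positions), gaps=gaps, pattern=pattern)


def matches_knottin(sig: CysSignature) -> tuple[bool, list[str]]:
    """Whether a signature satisfies the canonical knottin framework.

    Requires 10 cysteines, the fixed gaps of the printed framework, and at
    least one residue in every variable gap. Returns the verdict and the
    list of violated constraints.
    """
    violations: list[str] = []
    if sig.n_cys != KNOTTIN_N_CYS:
        violations.append(f"n_cys={sig.n_cys}, expected {KNOTTIN_N_CYS}")
        return False, violations
    for i, gap in enumerate(sig.gaps, start=1):
        fixed = KNOTTIN_FIXED_GAPS.get(i)
        if fixed is not None:
            if gap != fixed:
                violations.append(f"gap_{i}={gap}, expected {fixed}")
        elif gap < 1:
            violations.append(f"gap_{i}={gap}, expected >= 1")
    return not violations, violations


def _lookup_table(table, column: str, name: str) -> pd.Series | None:
    """Normalise an optional per-transcript annotation table to a Series."""
    if table is None:
        return None
    if isinstance(table, pd.DataFrame):
        if not table.index.is_unique:
            raise ValueError(f"duplicate transcript ids in {name} table")
        if column in table.columns:
            return table[column]
        if "score" in table.columns and column not in table.columns:
            raise KeyError(f"{name} table lacks a {column!r} column")
        return table.iloc[:, 0]
    s = pd.Series(table)
    if not s.index.is_unique:
        raise ValueError(f"duplicate transcript ids in {name} table")
    return s


def _pick_domains(domains) -> pd.Series | None:
    """One domain label per transcript; with a score column, the highest-
    scoring row wins (deterministic tie-break on the label)."""
    if domains is None:
        return None
    if isinstance(domains, pd.DataFrame) and "score" in domains.columns:
        df = domains.reset_index(names="transcript_id")
        df = df.sort_values(
            ["transcript_id", "score", "domain"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        return df.drop_duplicates("transcript_id").set_index("transcript_id")["domain"]
    return _lookup_table(domains, "domain", "domain")


def integrate(
    decisions: pd.DataFrame,
    bias_results: pd.DataFrame,
    domains=None,
    neurotoxicity=None,
    signal_peptides=None,
    proteins: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Final candidate table: toxin-like AND upregulated.

    ``decisions`` is a HomologyAnnotator decisions frame; ``bias_results`` a
    TissueBiasTester results frame. The optional per-transcript tables add
    the family label, neurotoxicity and signal-peptide flags; transcripts
    missing from them get None-valued fields, never exclusion.
    """
    for name, df in (("decisions", decisions), ("bias results", bias_results)):
        if not df.index.is_unique:
            raise ValueError(f"duplicate transcript ids in {name}")
    domain_s = _pick_domains(domains)
    neuro_s = _lookup_table(neurotoxicity, "neurotoxic", "neurotoxicity")
    sigp_s = _lookup_table(signal_peptides, "signal_peptide", "signal peptide")

    toxin_like = decisions.index[decisions["is_toxin_like"]]
    up = bias_results[bias_results["passed_de"] | bias_results["rescued"]]
    ids = [t for t in toxin_like if t in up.index]

    rows = []
    for tid in ids:
        b = up.loc[tid]
        d = decisions.loc[tid]
        domain = domain_s.get(tid) if domain_s is not None else None
        neuro = neuro_s.get(tid) if neuro_s is not None else None
        sigp = sigp_s.get(tid) if sigp_s is not None else None
        rows.append(
            {
                "transcript_id": tid,
                "best_subject": d["best_subject"],
                "best_database": d["best_database"],
                "family": classify_family(domain, has_hit=True),
                "top_tissue": b["top_tissue"],
                "fc": float(b["fc"]),
                "q_value": None if pd.isna(b["q_value"]) else float(b["q_value"]),
                "rescued": bool(b["rescued"]),
                "neurotoxic": None if neuro is None or pd.isna(neuro) else bool(neuro),
                "signal_peptide": None if sigp is None or pd.isna(sigp) else bool(sigp),
                "protein": proteins.get(tid) if proteins else None,
            }
        )
    columns = [
        "transcript_id",
        "best_subject",
        "best_database",
        "family",
        "top_tissue",
        "fc",
        "q_value",
        "rescued",
        "neurotoxic",
        "signal_peptide",
        "protein",
    ]
    return pd.DataFrame(rows, columns=columns).set_index("transcript_id")
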