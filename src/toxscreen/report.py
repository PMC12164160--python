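"""Run summaries: cascade survival counts, family composition and the
family x tissue distribution of the final candidates.

Percentages are half-up rounded (one decimal for cascade survival, whole
numbers for composition shares by convention); the unrounded value is stored
next to every rounded field so the arithmetic stays recomputable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from . import __version__

__all__ = ["CascadeSummary", "pct", "summarize", "family_by_tissue", "write_summary"]


@dataclass
class CascadeSummary:
    """Per-stage survival of the filtering cascade."""

    stages: list[dict]

    def counts(self) -> dict[str, int]:
        return {s["name"]: s["n_out"] for s in self.stages}


def pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, half-up rounded to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def family_by_tissue(candidates: pd.DataFrame) -> pd.DataFrame:
    """Candidate counts per family (rows) and upregulation tissue (columns);
    row sums equal per-family candidate counts."""
    if candidates.empty:
        return pd.DataFrame()
    table = (
        candidates.groupby(["family", "top_tissue"]).size().unstack(fill_value=0)
    )
    return table.sort_index()


def summarize(pipeline, seed: int | None = None) -> dict:
    """Machine-readable summary of a fitted ToxinDiscoveryPipeline run.

    Contains every stage count with its survival percentage, the candidate
    family composition, the family x tissue matrix, the thresholds used and
    the package version. Deterministic for identical inputs.
    """
    required = ("stage_counts_", "candidates_")
    for attr in required:
        if not hasattr(pipeline, attr):
            raise ValueError(f"missing stage output: {attr} (pipeline not fitted?)")

    stage_counts = pipeline.stage_counts_
    n_input = stage_counts[0][1]
    stages = []
    prev = n_input
    for name, n in stage_counts[1:]:
        stages.append(
            {
                "name": name,
                "n_in": prev,
                "n_out": n,
                "pct_of_input": pct(n, n_input, 1) if n_input else None,
                "fraction_of_input": (n / n_input) if n_input else None,
            }
        )
        prev = n

    candidates = pipeline.candidates_
    families = (
        candidates["family"].value_counts().sort_index().to_dict()
        if not candidates.empty
        else {}
    )
    n_cand = int(len(candidates))
    family_pct = {
        fam: {"n": int(n), "pct_of_candidates": pct(int(n), n_cand, 0)}
        for fam, n in families.items()
    }
    matrix = family_by_tissue(candidates)

    return {
        "n_input_transcripts": n_input,
        "stages": stages,
        "n_candidates": n_cand,
        "n_rescued": int(candidates["rescued"].sum()) if not candidates.empty else 0,
        "n_neurotoxic": int((candidates["neurotoxic"] == True).sum())  # noqa: E712
        if not candidates.empty
        else 0,
        "families": family_pct,
        "family_by_tissue": {
            fam: {t: int(v) for t, v in row.items()}
            for fam, row in matrix.iterrows()
        }
        if not matrix.empty
        else {},
        "params": pipeline.get_params(),
        "seed": seed,
        "version": __version__,
    }


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
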