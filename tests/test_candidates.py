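"""Candidate integration, family classification and the cysteine framework."""

import numpy as np
import pandas as pd
import pytest

import toxscreen as tx
from toxscreen.candidates import NO_PREDICTION

CANONICAL_GAPS = (5, 1, 4, 0, 6, 1, 7, 1, 3)


def peptide_from_gaps(gaps, flank="GA"):
    return flank + "C" + "".join("A" * g + "C" for g in gaps) + flank


def decisions_frame(rows):
    return pd.DataFrame(rows).set_index("transcript_id")


def bias_frame(rows):
    df = pd.DataFrame(rows).set_index("transcript_id")
    df["upregulated_in"] = df["top_tissue"].where(df["passed_de"] | df["rescued"])
    return df


def make_tables():
    decisions = decisions_frame(
        [
            {"transcript_id": "tox_up", "is_toxin_like": True, "retained": True,
             "best_subject": "TOX_1", "best_database": "toxprot"},
            {"transcript_id": "tox_flat", "is_toxin_like": True, "retained": True,
             "best_subject": "TOX_2", "best_database": "toxprot"},
            {"transcript_id": "tox_weak_q", "is_toxin_like": True, "retained": True,
             "best_subject": "TOX_3", "best_database": "toxprot"},
            {"transcript_id": "tox_rescued", "is_toxin_like": True, "retained": True,
             "best_subject": "TOX_4", "best_database": "toxprot"},
            {"transcript_id": "nontox_up", "is_toxin_like": False, "retained": True,
             "best_subject": "GEN_1", "best_database": "swissprot"},
        ]
    )
    bias = bias_frame(
        [
            {"transcript_id": "tox_up", "top_tissue": "midgut", "fc": 10.0,
             "p_value": 1e-6, "q_value": 0.001, "passed_de": True, "rescued": False},
            {"transcript_id": "tox_flat", "top_tissue": "silk", "fc": 1.2,
             "p_value": 0.6, "q_value": 0.8, "passed_de": False, "rescued": False},
            {"transcript_id": "tox_weak_q", "top_tissue": "midgut", "fc": 10.0,
             "p_value": 0.09, "q_value": 0.2, "passed_de": False, "rescued": False},
            {"transcript_id": "tox_rescued", "top_tissue": "gonads", "fc": 801.0,
             "p_value": np.nan, "q_value": np.nan, "passed_de": False, "rescued": True},
            {"transcript_id": "nontox_up", "top_tissue": "midgut", "fc": 9.0,
             "p_value": 1e-5, "q_value": 0.002, "passed_de": True, "rescued": False},
        ]
    )
    return decisions, bias


class TestIntegrate:
    def test_both_gates_required(self):
        decisions, bias = make_tables()
        out = tx.integrate(decisions, bias)
        assert sorted(out.index) == ["tox_rescued", "tox_up"]
        assert not bool(out.loc["tox_up", "rescued"])
        assert bool(out.loc["tox_rescued", "rescued"])
        assert out.loc["tox_rescued", "top_tissue"] == "gonads"

    def test_missing_annotations_yield_none_not_exclusion(self):
        decisions, bias = make_tables()
        out = tx.integrate(
            decisions,
            bias,
            domains=pd.Series({"tox_up": "prokineticin"}),
            neurotoxicity=pd.Series({"tox_up": True}),
            signal_peptides=pd.Series({"tox_up": False}),
        )
        assert out.loc["tox_up", "family"] == "prokineticin"
        assert out.loc["tox_rescued", "family"] == NO_PREDICTION
        assert out.loc["tox_rescued", "neurotoxic"] is None
        assert out.loc["tox_rescued", "signal_peptide"] is None

    def test_duplicate_ids_rejected(self):
        decisions, bias = make_tables()
        dup = pd.concat([decisions, decisions.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            tx.integrate(dup, bias)

    def test_intersection_bounds_and_family_partition(self, small_pipeline):
        cand = small_pipeline.candidates_
        n_toxin_like = small_pipeline.decisions_["is_toxin_like"].sum()
        up = small_pipeline.bias_results_
        n_up = int((up["passed_de"] | up["rescued"]).sum())
        assert len(cand) <= n_toxin_like and len(cand) <= n_up
        assert cand["family"].value_counts().sum() == len(cand)

    def test_highest_scoring_domain_wins(self):
        decisions, bias = make_tables()
        domains = pd.DataFrame(
            {"domain": ["knottin", "defensin"], "score": [40.0, 90.0]},
            index=pd.Index(["tox_up", "tox_up"], name="transcript_id"),
        )
        out = tx.integrate(decisions, bias, domains=domains)
        assert out.loc["tox_up", "family"] == "defensin"


class TestFamilyClassification:
    def test_domain_label_passes_through(self):
        assert tx.classify_family("astacin-like metallopeptidase") == (
            "astacin-like metallopeptidase"
        )

    def test_no_domain_means_no_prediction(self):
        assert tx.classify_family(None) == NO_PREDICTION
        assert tx.classify_family(float("nan")) == NO_PREDICTION

    def test_family_tabulation_matches_simulated_labels(self, small_pipeline, small_study):
        cand = small_pipeline.candidates_
        ann = small_study.annotations["domain"]
        for tid, row in cand.iterrows():
            label = ann.get(tid)
            expected = NO_PREDICTION if label is None or pd.isna(label) else label
            assert row["family"] == expected


class TestCysSignature:
    def test_no_cysteines(self):
        sig = tx.cys_signature("ALWAYS")  # no C anywhere
        assert sig.n_cys == 0 and sig.gaps == () and sig.pattern == ""

    def test_canonical_knottin_pattern(self):
        sig = tx.cys_signature(peptide_from_gaps(CANONICAL_GAPS))
        assert sig.n_cys == 10
        assert sig.gaps == CANONICAL_GAPS
        assert sig.pattern == "C-CXC-CC-CXC-CXC-C"
        ok, violations = tx.matches_knottin(sig)
        assert ok and violations == []

    def test_disrupted_framework_loses_two_cysteines(self):
        pep = peptide_from_gaps(CANONICAL_GAPS)
        positions = [i for i, aa in enumerate(pep) if aa == "C"]
        broken = list(pep)
        broken[positions[1]] = "S"  # second cysteine
        broken[positions[9]] = "S"  # tenth cysteine
        sig = tx.cys_signature("".join(broken))
        assert sig.n_cys == 8
        ok, violations = tx.matches_knottin(sig)
        assert not ok
        assert violations == ["n_cys=8, expected 10"]

    def test_fixed_gap_violation_is_named(self):
        gaps = list(CANONICAL_GAPS)
        gaps[3] = 2  # the CC adjacency (gap 4) stretched
        ok, violations = tx.matches_knottin(tx.cys_signature(peptide_from_gaps(gaps)))
        assert not ok
        assert violations == ["gap_4=2, expected 0"]

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid amino acid"):
            tx.cys_signature("ACB1")

    def test_reversal_symmetry(self):
        pep = peptide_from_gaps(CANONICAL_GAPS, flank="GW")
        fwd = tx.cys_signature(pep)
        rev = tx.cys_signature(pep[::-1])
        assert rev.gaps == fwd.gaps[::-1]
        assert rev.n_cys == fwd.n_cys
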