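"""Synthetic study generator with known ground truth.

Emulates the design of a 13-library, 5-tissue spider RNA-seq study — three
replicates each for midgut, silk glands, chelicerae and prosoma, a single
gonads library — so every downstream stage can be tested without external
data. Transcripts are uniform random nucleotide sequences with a planted
ATG..stop ORF; a configurable minority lack any complete ORF, another
minority are near-identical copies of other transcripts (for the clustering
stage). Counts are negative binomial with variance mu + alpha * mu^2; a set
of spiked toxin-like transcripts has its mean multiplied by ``spike_fold``
in the spike tissue and receives a top-bitscore hit in the toxin database,
while decoy transcripts get their best hits elsewhere.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .orfs import TranscriptRecord, find_orfs
from .pipeline import StudyData

__all__ = [
    "StudyDesign",
    "SimulationConfig",
    "SimulatedStudy",
    "DEFAULT_DESIGN",
    "generate_study",
    "mutate_copy",
]

_NT = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

TOXIN_DB = "toxprot"
GENERAL_DBS = ("swissprot", "refseq", "spider_genomes")

TOXIN_FAMILIES = (
    "astacin-like metallopeptidase",
    "serine protease",
    "prokineticin",
    "kunitz-type serine protease inhibitor",
    "atracotoxin",
    "thyroglobulin type 1",
    "knottin",
    "defensin",
    "phospholipase D",
)
_TOXIN_FAMILY_WEIGHTS = (0.25, 0.15, 0.10, 0.10, 0.10, 0.10, 0.10, 0.05, 0.05)
DECOY_DOMAINS = (
    "ankyrin repeat",
    "protein kinase domain",
    "wd40 repeat",
    "zinc finger",
    "c-type lectin",
)


@dataclass(frozen=True)
class StudyDesign:
    """Tissues, replication and the derived library ids of a study."""

    tissues: tuple[str, ...]
    replicates_per_tissue: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.tissues) < 2:
            raise ValueError("a study design needs at least 2 tissues")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("duplicate tissue names")
        for t in self.tissues:
            reps = self.replicates_per_tissue.get(t, 0)
            if reps < 1:
                raise ValueError(f"tissue {t!r} needs a positive replicate count")

    @property
    def library_ids(self) -> list[str]:
        return [lib for lib, _ in self.libraries()]

    def libraries(self) -> list[tuple[str, str]]:
        out = []
        for t in self.tissues:
            for i in range(1, self.replicates_per_tissue[t] + 1):
                out.append((f"{t}_{i}", t))
        return out

    @property
    def n_libraries(self) -> int:
        return sum(self.replicates_per_tissue[t] for t in self.tissues)

    def design_series(self) -> pd.Series:
        libs = self.libraries()
        return pd.Series({lib: t for lib, t in libs}, name="tissue").loc[
            [lib for lib, _ in libs]
        ]


DEFAULT_DESIGN = StudyDesign(
    tissues=("midgut", "silk", "chelicerae", "prosoma", "gonads"),
    replicates_per_tissue={
        "midgut": 3,
        "silk": 3,
        "chelicerae": 3,
        "prosoma": 3,
        "gonads": 1,
    },
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions.

    ``baseline_mean`` is the expected count of an average transcript at the
    1000 nt reference effective length; per-transcript baselines spread
    around it lognormally (``expression_sigma``). ``nb_dispersion`` is the
    alpha of variance = mu + alpha * mu^2. ``low_depth_library`` optionally
    down-scales one library's depth (mimicking a shallow midgut library).
    """

    n_transcripts: int = 2000
    n_spiked_toxins: int = 50
    spike_tissue: str = "midgut"
    spike_fold: float = 16.0
    nb_dispersion: float = 0.1
    baseline_mean: float = 200.0
    length_range: tuple[int, int] = (300, 1500)
    frac_incomplete_orf: float = 0.25
    frac_duplicated: float = 0.05
    expression_sigma: float = 1.0
    low_depth_library: str | None = None
    low_depth_factor: float = 0.5
    seed: int = 0

    def validate(self, design: StudyDesign) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")
        if not 0 <= self.n_spiked_toxins <= self.n_transcripts:
            raise ValueError("n_spiked_toxins must lie in [0, n_transcripts]")
        if self.spike_tissue not in design.tissues:
            raise ValueError(
                f"spike_tissue {self.spike_tissue!r} not in design tissues"
            )
        if self.spike_fold <= 1:
            raise ValueError("spike_fold must be > 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        lo, hi = self.length_range
        if lo < 100 or hi < lo:
            raise ValueError("length_range must satisfy 100 <= lo <= hi")
        for name in ("frac_incomplete_orf", "frac_duplicated"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_incomplete_orf + self.frac_duplicated > 1:
            raise ValueError("frac_incomplete_orf + frac_duplicated must be <= 1")
        if self.low_depth_library is not None and (
            self.low_depth_library not in design.library_ids
        ):
            raise ValueError(f"unknown low_depth_library {self.low_depth_library!r}")


@dataclass
class SimulatedStudy:
    """A generated study plus its ground truth."""

    transcripts: list[TranscriptRecord]
    expression: ExpressionMatrix
    hits: pd.DataFrame
    annotations: pd.DataFrame
    truth: pd.DataFrame
    design: StudyDesign
    config: SimulationConfig
    toxin_db: str = TOXIN_DB
    databases: set[str] = field(default_factory=lambda: {TOXIN_DB, *GENERAL_DBS})

    def to_study_data(self) -> StudyData:
        return StudyData(
            transcripts=self.transcripts,
            expression=self.expression,
            hits=self.hits,
            annotations=self.annotations,
            toxin_db=self.toxin_db,
            databases=self.databases,
        )

    def spiked_ids(self) -> list[str]:
        return list(self.truth.index[self.truth["is_spiked_toxin"]])

    def write(self, outdir) -> None:
        from . import io

        io.write_study(self, outdir)


def mutate_copy(seq: str, n_subs: int, seed: int) -> str:
    """A copy of ``seq`` with exactly ``n_subs`` substituted positions."""
    if n_subs > len(seq):
        raise ValueError("n_subs exceeds sequence length")
    if n_subs < 0:
        raise ValueError("n_subs must be non-negative")
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def _seq_with_orf(rng: np.random.Generator, length: int) -> str:
    """Random sequence with a planted complete ORF of >= 20 residues."""
    max_aa = (length - 3) // 3 - 1
    target = int(rng.integers(20, min(400, max_aa) + 1))
    orf_nt = 3 * (target + 1)
    utr_total = length - orf_nt
    utr5 = int(rng.integers(0, utr_total + 1))
    codon_idx = rng.integers(0, len(_SENSE_CODONS), size=target - 1)
    orf = "ATG" + "".join(_SENSE_CODONS[i] for i in codon_idx)
    orf += _STOPS[rng.integers(0, 3)]
    return _random_seq(rng, utr5) + orf + _random_seq(rng, utr_total - utr5)


def _seq_without_orf(rng: np.random.Generator, length: int, min_aa: int = 20) -> str:
    """Random sequence guaranteed free of complete ORFs >= ``min_aa``.

    Starts from a uniform random sequence and disrupts the start codon of
    every qualifying ORF (both strands) until a scan comes back empty.
    """
    seq = list(_random_seq(rng, length))
    for _ in range(100):
        calls = find_orfs(TranscriptRecord("probe", "".join(seq)), min_aa=min_aa)
        if not calls:
            return "".join(seq)
        for call in calls:
            if call.strand == "+":
                seq[call.start + 1] = "A"  # ATG -> AAG
            else:
                # position of the start codon's middle base in forward coords
                seq[length - 2 - call.start] = "T"  # revcomp codon ATG -> AAG
    raise RuntimeError("failed to generate an ORF-free sequence")


def _sample_nb(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_study(
    design: StudyDesign | None = None, config: SimulationConfig | None = None
) -> SimulatedStudy:
    """Generate sequences, counts, homology hits, annotations and truth."""
    design = design or DEFAULT_DESIGN
    config = config or SimulationConfig()
    config.validate(design)
    rng = np.random.default_rng(config.seed)

    n = config.n_transcripts
    n_spiked = config.n_spiked_toxins
    n_rest = n - n_spiked
    n_noorf = int(round(config.frac_incomplete_orf * n_rest))
    n_dup = int(round(config.frac_duplicated * n_rest))
    if n_dup > 0 and n_rest - n_noorf - n_dup < 1:
        raise ValueError("no transcripts left to serve as duplication parents")

    ids = [f"TX{i + 1:06d}" for i in range(n)]
    roles = np.array(
        ["spiked"] * n_spiked
        + ["base"] * (n_rest - n_noorf - n_dup)
        + ["noorf"] * n_noorf
        + ["dup"] * n_dup
    )
    roles = roles[rng.permutation(n)]

    lo, hi = config.length_range
    sequences: dict[str, str] = {}
    base_ids = [tid for tid, role in zip(ids, roles) if role == "base"]
    # parents first, duplicates second, each pass in id order (deterministic)
    for tid, role in zip(ids, roles):
        if role == "dup":
            continue
        length = int(rng.integers(lo, hi + 1))
        if role == "noorf":
            sequences[tid] = _seq_without_orf(rng, length)
        else:
            sequences[tid] = _seq_with_orf(rng, length)
    duplicate_of: dict[str, str] = {}
    for tid, role in zip(ids, roles):
        if role != "dup":
            continue
        parent = base_ids[rng.integers(len(base_ids))]
        parent_seq = sequences[parent]
        # strictly fewer substitutions than 1% of the length => identity > 0.99
        max_subs = max(int(np.ceil(0.01 * len(parent_seq))) - 1, 0)
        n_subs = int(rng.integers(0, max_subs + 1))
        sequences[tid] = mutate_copy(parent_seq, n_subs, int(rng.integers(2**31)))
        duplicate_of[tid] = parent

    transcripts = [TranscriptRecord(tid, sequences[tid]) for tid in ids]
    lengths = np.array([len(sequences[tid]) for tid in ids])
    eff_length = np.maximum(lengths - 199, 25)

    # ground truth (ORF status by scan; planted/absent by construction)
    has_orf = {
        tid: bool(find_orfs(TranscriptRecord(tid, sequences[tid]), min_aa=20))
        for tid in ids
    }
    truth = pd.DataFrame(
        {
            "is_spiked_toxin": roles == "spiked",
            "spike_tissue": np.where(roles == "spiked", config.spike_tissue, None),
            "has_complete_orf": [has_orf[tid] for tid in ids],
            "duplicate_of": [duplicate_of.get(tid) for tid in ids],
        },
        index=pd.Index(ids, name="transcript_id"),
    )

    # counts: NB around per-transcript lognormal baselines
    sigma = config.expression_sigma
    theta = config.baseline_mean * np.exp(
        rng.normal(-0.5 * sigma**2, sigma, size=n)
    )
    libs = design.libraries()
    depth = {lib: 1.0 for lib, _ in libs}
    if config.low_depth_library is not None:
        depth[config.low_depth_library] = config.low_depth_factor
    spiked_mask = roles == "spiked"
    counts = {}
    for lib, tissue in libs:
        mu = theta * (eff_length / 1000.0) * depth[lib]
        if tissue == config.spike_tissue:
            mu = np.where(spiked_mask, mu * config.spike_fold, mu)
        counts[lib] = _sample_nb(rng, mu, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="transcript_id"))
    expression = ExpressionMatrix(
        counts=counts_df,
        eff_length=pd.Series(eff_length, index=counts_df.index, name="effective_length"),
        design=design.design_series(),
    )

    # homology hits: spiked get their top bit score in the toxin database;
    # decoys get higher non-toxin hits (or none, or only near-threshold ones)
    rows = []
    for i, (tid, role) in enumerate(zip(ids, roles)):
        if role == "spiked":
            bits = float(rng.uniform(150, 280))
            rows.append(
                (
                    tid,
                    f"TOXPROT_{i + 1:05d}",
                    TOXIN_DB,
                    10.0 ** -float(rng.uniform(20, 80)),
                    round(bits, 1),
                    round(float(rng.uniform(55, 98)), 1),
                )
            )
            rows.append(
                (
                    tid,
                    f"SP_{i + 1:05d}",
                    "swissprot",
                    10.0 ** -float(rng.uniform(10, 40)),
                    round(bits * float(rng.uniform(0.4, 0.8)), 1),
                    round(float(rng.uniform(30, 80)), 1),
                )
            )
        elif role in ("base", "dup"):
            u = float(rng.random())
            if u < 0.7:
                db = GENERAL_DBS[rng.integers(len(GENERAL_DBS))]
                bits = float(rng.uniform(80, 300))
                rows.append(
                    (
                        tid,
                        f"GEN_{i + 1:05d}",
                        db,
                        10.0 ** -float(rng.uniform(10, 60)),
                        round(bits, 1),
                        round(float(rng.uniform(30, 95)), 1),
                    )
                )
                if rng.random() < 0.3:
                    # decoy toxin hit, strictly below the general best hit
                    rows.append(
                        (
                            tid,
                            f"TOXPROT_D{i + 1:05d}",
                            TOXIN_DB,
                            10.0 ** -float(rng.uniform(6, 20)),
                            round(bits * float(rng.uniform(0.3, 0.6)), 1),
                            round(float(rng.uniform(25, 60)), 1),
                        )
                    )
            elif u < 0.8:
                # only a weak hit at / above the e-value cutoff: dropped
                rows.append(
                    (
                        tid,
                        f"WEAK_{i + 1:05d}",
                        "swissprot",
                        float(rng.uniform(1e-5, 1e-3)),
                        round(float(rng.uniform(40, 60)), 1),
                        round(float(rng.uniform(20, 40)), 1),
                    )
                )
        # noorf transcripts receive no hits
    hits = pd.DataFrame(
        rows,
        columns=["query_id", "subject_id", "database", "evalue", "bitscore", "pct_identity"],
    )

    # pass-through annotations (external predictor outputs)
    family_p = np.array(_TOXIN_FAMILY_WEIGHTS) / sum(_TOXIN_FAMILY_WEIGHTS)
    ann_rows = []
    for tid, role in zip(ids, roles):
        if role == "spiked":
            domain = (
                TOXIN_FAMILIES[rng.choice(len(TOXIN_FAMILIES), p=family_p)]
                if rng.random() < 0.8
                else None
            )
            ann_rows.append(
                (tid, domain, bool(rng.random() < 0.8), bool(rng.random() < 0.22))
            )
        elif role in ("base", "dup"):
            domain = (
                DECOY_DOMAINS[rng.integers(len(DECOY_DOMAINS))]
                if rng.random() < 0.6
                else None
            )
            ann_rows.append(
                (tid, domain, bool(rng.random() < 0.1), False)
            )
    annotations = pd.DataFrame(
        ann_rows, columns=["transcript_id", "domain", "signal_peptide", "neurotoxic"]
    ).set_index("transcript_id")

    return SimulatedStudy(
        transcripts=transcripts,
        expression=expression,
        hits=hits,
        annotations=annotations,
        truth=truth,
        design=design,
        config=config,
    )
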