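"""Plain-text readers and writers for the pipeline's inputs and outputs.

Formats: FASTA for sequences (via Biopython), headered TSV for counts,
effective lengths, the library -> tissue design, homology hits and
annotations, JSON for ground truth and run summaries. The 12-column tabular
output of protein search tools is also readable (qseqid, sseqid, evalue,
bitscore and pident are consumed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionMatrix
from .homology import HIT_COLUMNS
from .orfs import OrfCall, TranscriptRecord
from .pipeline import StudyData

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_protein_fasta",
    "read_counts",
    "read_lengths",
    "read_design",
    "read_hits",
    "read_blast_tabular",
    "read_annotations",
    "write_study",
    "load_study",
    "write_clusters",
    "write_orfs",
]

_FLOAT_FMT = "%.10g"

STUDY_FILES = {
    "fasta": "transcripts.fasta",
    "counts": "counts.tsv",
    "lengths": "effective_lengths.tsv",
    "design": "design.tsv",
    "hits": "hits.tsv",
    "annotations": "annotations.tsv",
    "truth": "ground_truth.json",
    "config": "config.json",
}


def read_fasta(path) -> list[TranscriptRecord]:
    return [
        TranscriptRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[TranscriptRecord], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def write_protein_fasta(orfs: dict[str, OrfCall], path) -> None:
    SeqIO.write(
        (
            SeqRecord(
                Seq(call.protein),
                id=tid,
                description=f"strand={call.strand} start={call.start} end={call.end}",
            )
            for tid, call in sorted(orfs.items())
        ),
        str(path),
        "fasta",
    )


def _write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, lineterminator="\n")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_design(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    if "pct_identity" not in df.columns:
        df["pct_identity"] = float("nan")
    return df[HIT_COLUMNS]


def read_blast_tabular(path, database: str) -> pd.DataFrame:
    """Read standard 12-column tabular search output for one database."""
    cols = [
        "qseqid",
        "sseqid",
        "pident",
        "length",
        "mismatch",
        "gapopen",
        "qstart",
        "qend",
        "sstart",
        "send",
        "evalue",
        "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    return pd.DataFrame(
        {
            "query_id": df["qseqid"],
            "subject_id": df["sseqid"],
            "database": database,
            "evalue": df["evalue"],
            "bitscore": df["bitscore"],
            "pct_identity": df["pident"],
        }
    )


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clusters(clusters, path) -> None:
    """Two-column membership TSV: member, representative."""
    rows = [
        {"member": m, "representative": c.representative_id}
        for c in clusters
        for m in c.member_ids
    ]
    _write_tsv(pd.DataFrame(rows, columns=["member", "representative"]), path, index=False)


def write_orfs(orfs: dict[str, OrfCall], path) -> None:
    rows = [
        {
            "transcript_id": tid,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "frame": c.frame,
            "protein_length": len(c.protein),
            "protein": c.protein,
        }
        for tid, c in sorted(orfs.items())
    ]
    _write_tsv(pd.DataFrame(rows), path, index=False)


def write_study(study, outdir) -> None:
    """Write a SimulatedStudy to ``outdir`` (deterministic bytes)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(study.transcripts, out / STUDY_FILES["fasta"])
    em = study.expression
    _write_tsv(em.counts, out / STUDY_FILES["counts"])
    _write_tsv(em.eff_length.to_frame("effective_length"), out / STUDY_FILES["lengths"])
    _write_tsv(em.design.to_frame("tissue").rename_axis("library"), out / STUDY_FILES["design"])
    _write_tsv(study.hits, out / STUDY_FILES["hits"], index=False)
    _write_tsv(study.annotations, out / STUDY_FILES["annotations"])
    truth = study.truth.to_dict(orient="index")
    with open(out / STUDY_FILES["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    cfg = dataclasses.asdict(study.config)
    cfg["design"] = {
        "tissues": list(study.design.tissues),
        "replicates_per_tissue": study.design.replicates_per_tissue,
    }
    cfg["toxin_db"] = study.toxin_db
    cfg["databases"] = sorted(study.databases)
    with open(out / STUDY_FILES["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def load_study(indir, toxin_db: str | None = None) -> StudyData:
    """Load a written study directory back into pipeline inputs."""
    ind = Path(indir)
    databases = None
    cfg_path = ind / STUDY_FILES["config"]
    if cfg_path.exists():
        with open(cfg_path) as fh:
            cfg = json.load(fh)
        toxin_db = toxin_db or cfg.get("toxin_db")
        if "databases" in cfg:
            databases = set(cfg["databases"])
    transcripts = read_fasta(ind / STUDY_FILES["fasta"])
    em = ExpressionMatrix(
        counts=read_counts(ind / STUDY_FILES["counts"]),
        eff_length=read_lengths(ind / STUDY_FILES["lengths"]),
        design=read_design(ind / STUDY_FILES["design"]),
    )
    ann_path = ind / STUDY_FILES["annotations"]
    annotations = read_annotations(ann_path) if ann_path.exists() else None
    return StudyData(
        transcripts=transcripts,
        expression=em,
        hits=read_hits(ind / STUDY_FILES["hits"]),
        annotations=annotations,
        toxin_db=toxin_db or "toxprot",
        databases=databases,
    )
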