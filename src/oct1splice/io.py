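"""File formats: FASTQ/FASTA (gzip-aware), truth/count TSVs, metadata JSON."""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .merge import MERGED, MergedRead
from .simulate import SimulatedSample


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(path: str | Path, ids: list[str], seqs: list[str],
                quals: list[str]) -> None:
    with _open_text(path, "w") as fh:
        for rid, seq, q in zip(ids, seqs, quals):
            fh.write(f"@{rid}\n{seq}\n+\n{q}\n")


def read_fastq(path: str | Path) -> tuple[list[str], list[str], list[str]]:
    ids, seqs, quals = [], [], []
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
            quals.append("".join(chr(q + 33)
                                 for q in rec.letter_annotations[
                                     "phred_quality"]))
    return ids, seqs, quals


def write_fasta(path: str | Path, records: list[SeqRecord]) -> None:
    with _open_text(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_sample_fastqs(sample: SimulatedSample, out_dir: str | Path,
                        gz: bool = False) -> tuple[Path, Path, Path]:
    """Write R1/R2 FASTQ plus the truth TSV for a simulated sample."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gz else ".fastq"
    sid = sample.spec.sample_id
    p1 = out / f"{sid}_R1{ext}"
    p2 = out / f"{sid}_R2{ext}"
    pt = out / f"{sid}_truth.tsv"
    write_fastq(p1, sample.read_ids, sample.r1, sample.quals1)
    write_fastq(p2, sample.read_ids, sample.r2, sample.quals2)
    sample.truth.to_csv(pt, sep="\t", index=False)
    return p1, p2, pt


def write_run_metadata(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True)
                          + "\n")


def write_merged(path: str | Path, ids: list[str],
                 merged: list[MergedRead],
                 unmerged_path: str | Path | None = None,
                 r1: list[str] | None = None, r2: list[str] | None = None,
                 q1: list[str] | None = None,
                 q2: list[str] | None = None) -> None:
    """Write merged reads to FASTQ; optionally route unmerged pairs aside."""
    with _open_text(path, "w") as fh:
        for rid, m in zip(ids, merged):
            if m.status == MERGED:
                fh.write(f"@{rid}\n{m.seq}\n+\n{m.quals}\n")
    if unmerged_path is not None and r1 is not None:
        with _open_text(unmerged_path, "w") as fh:
            for i, m in enumerate(merged):
                if m.status != MERGED:
                    qa = q1[i] if q1 else "I" * len(r1[i])
                    qb = q2[i] if q2 else "I" * len(r2[i])
                    fh.write(f"@{ids[i]}/1\n{r1[i]}\n+\n{qa}\n")
                    fh.write(f"@{ids[i]}/2\n{r2[i]}\n+\n{qb}\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
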