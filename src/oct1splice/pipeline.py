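"""End-to-end seeded pipeline: simulate → merge → classify → quantify.

A run is described by a YAML config (see :class:`RunConfig`). Every random
stage derives its seed deterministically from the global seed and the sample
index, so rerunning a config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import refmodel as rm
from .classify import CountTable, build_anchors, classify_reads
from .defaults import (DEFAULT_ANCHOR_K, DEFAULT_MAX_MISMATCH,
                       DEFAULT_MAX_MISMATCH_FRAC, DEFAULT_MIN_OVERLAP)
from .merge import MERGED, merge_pairs
from .quantify import (aei_test, allele_fraction, nmd_invert,
                       splice_fraction)
from .simulate import SampleSpec, simulate_sample

CONFIG_SCHEMA_VERSION = 1

_SAMPLE_KEYS = {f.name for f in SampleSpec.__dataclass_fields__.values()}  # type: ignore[attr-defined]


@dataclass
class RunConfig:
    samples: list[dict]
    seed: int = 0
    locus_fasta: str | None = None      # default synthetic locus when absent
    locus_json: str | None = None
    k: int = DEFAULT_ANCHOR_K
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    min_overlap: int = DEFAULT_MIN_OVERLAP
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC
    aei_pairs: list[dict] = field(default_factory=list)  # {dna:, rna:}
    out_dir: str = "results/run"
    write_reads: bool = False
    schema_version: int = CONFIG_SCHEMA_VERSION

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        ver = raw.get("schema_version", CONFIG_SCHEMA_VERSION)
        if ver != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"{path}: unsupported schema_version {ver}")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "samples" not in raw or not raw["samples"]:
            raise ValueError(f"{path}: config needs a non-empty samples list")
        for i, s in enumerate(raw["samples"]):
            bad = set(s) - _SAMPLE_KEYS
            if bad:
                raise ValueError(
                    f"{path}: samples[{i}] has unknown keys {sorted(bad)}")
            for req in ("sample_id", "genotype", "context", "depth"):
                if req not in s:
                    raise ValueError(
                        f"{path}: samples[{i}] is missing {req!r}")
        return cls(**raw)


def derive_seed(global_seed: int, index: int) -> int:
    """Deterministic per-sample seed below 2^31."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _load_locus(cfg: RunConfig) -> rm.LocusModel:
    if cfg.locus_fasta is None:
        return rm.make_default_locus()
    if cfg.locus_json is None:
        raise ValueError("locus_fasta given without locus_json sidecar")
    for p in (cfg.locus_fasta, cfg.locus_json):
        if not Path(p).exists():
            raise FileNotFoundError(f"locus file not found: {p}")
    return rm.load_locus(cfg.locus_fasta, cfg.locus_json)


def run_sample(locus: rm.LocusModel, spec: SampleSpec, anchors,
               min_overlap: int = DEFAULT_MIN_OVERLAP,
               max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
               ) -> tuple[CountTable, dict]:
    """simulate → merge → classify one sample; returns counts and QC facts."""
    sim = simulate_sample(locus, spec)
    merged = merge_pairs(sim.r1, sim.r2, sim.quals1, sim.quals2,
                         min_overlap, max_mismatch_frac)
    seqs = [m.seq for m in merged if m.status == MERGED]
    _, counts = classify_reads(seqs, anchors, spec.sample_id)
    qc = {
        "sample_id": spec.sample_id,
        "depth": spec.depth,
        "merge_rate": len(seqs) / spec.depth,
        "splice_unclassified_frac":
            counts.n(splice="unclassified") / max(counts.total, 1),
        "allele_unclassified_frac":
            counts.n(allele="unclassified") / max(counts.total, 1),
        "seed": spec.seed,
    }
    return counts, qc


def run_all(cfg: RunConfig) -> dict:
    """Run the full pipeline for a config; writes TSV/JSON under out_dir."""
    locus = _load_locus(cfg)
    anchors = build_anchors(locus, cfg.k, cfg.max_mismatch)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    count_frames = []
    quant_rows = []
    qc: dict = {"schema_version": cfg.schema_version, "global_seed": cfg.seed,
                "samples": []}
    tables: dict[str, CountTable] = {}
    for i, sdict in enumerate(cfg.samples):
        sdict = dict(sdict)
        sdict.setdefault("seed", derive_seed(cfg.seed, i))
        spec = SampleSpec(**sdict)
        if cfg.write_reads:
            from .io import write_sample_fastqs
            sim = simulate_sample(locus, spec)
            write_sample_fastqs(sim, out / "reads")
        counts, sample_qc = run_sample(locus, spec, anchors,
                                       cfg.min_overlap,
                                       cfg.max_mismatch_frac)
        tables[spec.sample_id] = counts
        count_frames.append(counts.to_frame())
        qc["samples"].append(sample_qc)
        row = {"sample_id": spec.sample_id, "genotype": spec.genotype,
               "context": spec.context}
        if counts.n(splice="correct") + counts.n(splice="alternative") > 0:
            sq = splice_fraction(counts)
            row.update(f_correct=sq.f_correct, f_correct_lo=sq.ci95[0],
                       f_correct_hi=sq.ci95[1], n_classified=sq.n_classified)
        if counts.n(allele="A") + counts.n(allele="G") > 0:
            af = allele_fraction(counts)
            row.update(f_A=af.f_A, f_A_lo=af.ci95[0], f_A_hi=af.ci95[1])
        quant_rows.append(row)

    pd.concat(count_frames, ignore_index=True).to_csv(
        out / "counts.tsv", sep="\t", index=False)
    quant = pd.DataFrame(quant_rows)
    quant.to_csv(out / "quant.tsv", sep="\t", index=False,
                 float_format="%.8g")

    aei_block = None
    if cfg.aei_pairs:
        pairs = []
        per_pair = []
        for p in cfg.aei_pairs:
            dna = allele_fraction(tables[p["dna"]])
            rna = allele_fraction(tables[p["rna"]])
            pairs.append((dna.f_A, rna.f_A))
            per_pair.append({"dna": p["dna"], "rna": p["rna"],
                             "f_A_DNA": dna.f_A, "f_A_RNA": rna.f_A})
        if len(pairs) >= 2:
            res = aei_test(pairs)
            t_stat, p_value = res.t_stat, res.p_value
            f_dna, f_rna = res.f_A_DNA, res.f_A_RNA
            n_pairs = res.n_samples
        else:
            # a single pair cannot support a paired test; report fractions
            t_stat = p_value = None
            f_dna, f_rna = pairs[0]
            n_pairs = 1
        # invert the decay model at the mean RNA allele fraction, using the
        # pooled alternative fraction of the RNA samples
        n_alt = sum(tables[p["rna"]].n(splice="alternative")
                    for p in cfg.aei_pairs)
        n_spl = sum(tables[p["rna"]].n(splice="correct")
                    + tables[p["rna"]].n(splice="alternative")
                    for p in cfg.aei_pairs)
        est = nmd_invert(f_rna, n_alt / n_spl if n_spl else 0.0)
        aei_block = {"pairs": per_pair, "t_stat": t_stat,
                     "p_value": p_value, "f_A_DNA": f_dna,
                     "f_A_RNA": f_rna, "n_samples": n_pairs,
                     "nmd": {"md": est.md, "m": est.m, "d": est.d,
                             "flags": list(est.flags)}}
        Path(out / "aei.json").write_text(
            json.dumps(aei_block, indent=2, sort_keys=True) + "\n")

    Path(out / "qc.json").write_text(
        json.dumps(qc, indent=2, sort_keys=True) + "\n")
    return {"counts": tables, "quant": quant, "aei": aei_block, "qc": qc,
            "out_dir": str(out)}


def hash_outputs(out_dir: str | Path) -> str:
    """SHA-256 over the run's output files, for determinism checks."""
    h = hashlib.sha256()
    for p in sorted(Path(out_dir).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
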