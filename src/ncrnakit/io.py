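"""Shared file formats: FASTA, GFF3, tabular reports and YAML run configs.

Internally every interval is 0-based, half-open, on an explicit strand;
conversion to the 1-based inclusive convention of GFF3 happens only here.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclasses.dataclass(frozen=True)
class Feature:
    """A genomic feature in internal coordinates (0-based, half-open)."""

    seqid: str
    start: int
    end: int
    strand: str
    type: str
    score: float | None = None
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinates: {self.start}..{self.end}")
        if self.start >= self.end:
            raise ValueError(f"empty interval: {self.start}..{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    del width  # Biopython's writer wraps lines itself


def to_gff3_coords(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


def from_gff3_coords(start1: int, end1: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    return start1 - 1, end1


def write_gff3(features: Iterable[Feature], path: str | Path, source: str = "ncrnakit") -> None:
    feats = sorted(features, key=lambda f: (f.seqid, f.start))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            s1, e1 = to_gff3_coords(f.start, f.end)
            score = "." if f.score is None else f"{f.score:g}"
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes) or "."
            fh.write(
                f"{f.seqid}\t{source}\t{f.type}\t{s1}\t{e1}\t{score}\t{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _src, ftype, s1, e1, score, strand, _phase, attrs = cols
            start, end = from_gff3_coords(int(s1), int(e1))
            attributes = tuple(
                tuple(kv.split("=", 1)) for kv in attrs.split(";") if kv and kv != "."
            )
            feats.append(
                Feature(
                    seqid=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    type=ftype,
                    score=None if score == "." else float(score),
                    attributes=attributes,  # type: ignore[arg-type]
                )
            )
    return feats


#: keys accepted at the top level of a run-config YAML
RUN_CONFIG_KEYS = frozenset(
    {"seed", "outdir", "log_level", "sim", "consensus", "profile", "mirna", "snorna", "trna", "phylo"}
)


def load_run_config(path: str | Path) -> dict:
    """Load and validate a pipeline YAML config; unknown top-level keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a YAML mapping")
    unknown = set(cfg) - RUN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    cfg.setdefault("outdir", "ncrna_out")
    return cfg
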