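"""Readers/writers for the plain-text formats the pipeline touches.

FASTA/FASTQ go through Biopython's SeqIO; tables are TSV via pandas.
Collapsed small-RNA tag libraries use ``>id_count`` headers, i.e. the read
count is the integer after the last underscore of the record id.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s: %(message)s"


def get_logger(name: str, level: int = logging.INFO) -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(level)
        logger.propagate = False
    return logger


log = get_logger(__name__)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w") as handle:
        SeqIO.write(recs, handle, "fasta-2line")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTQ as (id, sequence) pairs; qualities are validated by SeqIO."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper()))
    return out


def parse_tag_header(header: str) -> tuple[str, int]:
    """Split a collapsed-tag id ``name_count`` into (name, count).

    The count is the integer after the LAST underscore; everything before it
    is the tag id (ids may themselves contain underscores).
    """
    stem, sep, count = header.rpartition("_")
    if not sep or not count.isdigit():
        raise ValueError(f"collapsed-tag header without _count suffix: {header!r}")
    return stem, int(count)


def read_tag_fasta(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a collapsed-tag FASTA into (id, sequence, count) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, count = parse_tag_header(rec.id)
        out.append((name, str(rec.seq).upper(), count))
    return out


def write_tag_fasta(path: str | Path, tags: Iterable[tuple[str, str, int]]) -> None:
    write_fasta(path, ((f"{name}_{count}", seq) for name, seq, count in tags))


# ---------------------------------------------------------------------------
# Tables / JSON
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    outdir: str = "mirweave_out"
    seed: int = 0
    log_level: str = "INFO"
    # input paths (populated by the simulate stage when it runs)
    transcripts: str = "transcripts.fa"
    srna_prefix: str = "srna_"           # srna_S1.fa .. srna_Sk.fa in outdir
    degradome: str = "degradome.fa"
    counts: str = "counts.tsv"
    reference_mirnas: str = "reference_mirnas.fa"
    contaminants: str = "contaminants.fa"
    gene2term: str = "gene2term.tsv"
    # stage toggles
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "srna", "hairpin", "degradome", "de", "integrate", "network"])
    # srna
    min_len: int = 17
    max_len: int = 25
    max_sub: int = 2
    max_shift: int = 2
    # hairpin
    windows: list[int] = field(default_factory=lambda: [80, 150, 250])
    min_mfei: float | None = None
    # degradome
    max_score: float = 4.0
    max_gap: int = 1
    cleave_window: int = 0
    median_mode: str = "nonzero"
    # differential expression
    control: str = "S1"
    gene_p: float = 0.005
    gene_fdr: float = 0.001
    gene_lfc: float = 1.0
    mirna_p: float = 0.05
    mirna_abundance: int = 10
    # integration
    corr_negative: float = -0.5
    # network
    network_power: int = 6
    max_zeros: int = 4
    min_module: int = 30
    cut_height: float = 0.95
    edge_threshold: float = 0.1
    signed: bool = False
    hubs: list[str] = field(default_factory=list)
    # synthetic study design overrides (passed to StudyDesign)
    simulate_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def path(self, name: str) -> Path:
        """Resolve a configured file name inside the output directory."""
        p = Path(name)
        return p if p.is_absolute() else Path(self.outdir) / p
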