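"""Shared file I/O: FASTA/FASTQ (gzip-transparent), TSV tables, YAML config.

All intermediate files in the pipeline are plain-text standards so that any
stage can be replaced by an external tool (an aligner, Cufflinks output, ...).
FASTQ parsing is delegated to Biopython's fast four-line iterator; this module
only adds gzip transparency, framing errors with line numbers, and header
validation for TSV tables.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def open_text(path, mode: str = "rt"):
    """Open ``path`` for text I/O, decompressing transparently if it ends in .gz."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


class FastqFormatError(ValueError):
    """Malformed FASTQ; carries the 1-based line number of the offending record."""

    def __init__(self, message: str, line: int):
        super().__init__(f"{message} (near line {line})")
        self.line = line


def read_fastq(source) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, sequence, quality)`` from a FASTQ file or open handle.

    Accepts a path (optionally .gz) or any text handle. Framing problems
    (missing '@', '+' line, length mismatch) abort with the line number of the
    record at fault.
    """
    if isinstance(source, (str, Path)):
        handle = open_text(source)
        close = True
    else:
        handle, close = source, False
    n_records = 0
    try:
        for title, seq, qual in FastqGeneralIterator(handle):
            n_records += 1
            yield title.split()[0], seq, qual
    except ValueError as exc:  # Biopython's framing/length errors
        raise FastqFormatError(str(exc), line=n_records * 4 + 1) from exc
    finally:
        if close:
            handle.close()


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> int:
    """Write ``(read_id, sequence, quality)`` triples as 4-line FASTQ; return count."""
    n = 0
    with open_text(path, "wt") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(source) -> list[tuple[str, str]]:
    """Read FASTA into a list of ``(record_id, uppercase sequence)``."""
    if isinstance(source, (str, Path)):
        with open_text(source) as fh:
            return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fasta")]
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(source, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> int:
    n = 0
    with open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n


def read_tsv(path, required_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV (LF or CRLF line endings) and validate required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_config(path, known_sections: dict[str, Sequence[str]] | None = None) -> dict:
    """Load a YAML config of flat per-stage sections.

    ``known_sections`` maps section name -> allowed keys; unknown sections or
    keys are rejected outright so typos fail fast instead of being ignored.
    """
    import yaml

    with open_text(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping of sections")
    if known_sections is not None:
        for section, content in cfg.items():
            if section not in known_sections:
                raise ValueError(f"{path}: unknown section {section!r}")
            if content is None:
                continue
            if not isinstance(content, dict):
                raise ValueError(f"{path}: section {section!r} must be a mapping")
            allowed = set(known_sections[section])
            unknown = sorted(set(content) - allowed)
            if unknown:
                raise ValueError(f"{path}: unknown key(s) {unknown} in section {section!r}")
    return cfg


def sha256_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
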