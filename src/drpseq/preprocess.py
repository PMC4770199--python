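"""Read preprocessing for DRP libraries.

Pipeline order, applied per read:

1. remove any Illumina adapter at the 3' end (full occurrence, or a partial
   suffix overlap of at least 5 nt);
2. require the minimal forward MALBAC adapter near the 5' end — reads without
   it are discarded;
3. dual-mode trimming of the core (the bases after the forward adapter):
   if the reverse MALBAC adapter occurs in the core the read is cut at its
   start (BOTH_ADAPTERS); otherwise only the first 120 nt of the core are kept
   (FORWARD_ONLY);
4. collapse identical reads — grouping on (mode, core including octamers), so
   the random octamers act as molecular counters for PCR duplicates;
5. remove the 5' (and, in BOTH_ADAPTERS mode, the 3') octamer and keep inserts
   of at least 30 nt.

All decisions are sequence-based; quality strings are carried through
unvalidated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from . import io as dio
from .simulate import DEFAULT_ILLUMINA_ADAPTER, FORWARD_MALBAC, REVERSE_MALBAC, revcomp

OCTAMER_LEN = 8


@dataclass(frozen=True)
class AdapterScheme:
    """Adapter sequences and search parameters for trimming.

    The forward search is anchored: the motif must start within
    ``max_forward_offset`` bases of the 5' end (the variable-length PCR
    primers leave 0-3 offset bases). ``max_mismatches`` applies to both the
    forward and the reverse motif search; the default is an exact match.
    """

    forward_malbac: str = FORWARD_MALBAC
    reverse_malbac: str = REVERSE_MALBAC
    octamer_len: int = OCTAMER_LEN
    illumina_adapter: str = DEFAULT_ILLUMINA_ADAPTER
    max_forward_offset: int = 6
    max_mismatches: int = 0
    min_illumina_overlap: int = 5

    def __post_init__(self):
        if self.reverse_malbac != revcomp(self.forward_malbac):
            raise ValueError("reverse_malbac must be the reverse complement of forward_malbac")
        if self.max_mismatches < 0 or self.max_forward_offset < 0:
            raise ValueError("search parameters must be non-negative")


@dataclass
class TrimmedRead:
    read_id: str
    mode: str  # "BOTH_ADAPTERS" | "FORWARD_ONLY"
    core_with_octamers: str
    insert: str
    octamer5: str
    octamer3: str | None


@dataclass
class CollapsedMolecule:
    """One unique molecule after identical-read collapsing."""

    molecule_id: str
    read_count: int
    mode: str
    octamer5: str
    octamer3: str | None
    insert: str
    core_with_octamers: str


@dataclass
class PreprocessStats:
    reads_in: int = 0
    reads_with_forward_adapter: int = 0
    reads_discarded_no_adapter: int = 0
    reads_discarded_short_core: int = 0
    reads_mode_both: int = 0
    reads_mode_forward_only: int = 0
    #: unique molecules after collapsing (before the 30-nt length filter)
    molecules_out: int = 0
    #: molecules whose insert fails the minimum-length filter
    reads_failing_length: int = 0
    #: molecules actually emitted (= molecules_out - reads_failing_length)
    molecules_written: int = 0
    duplicate_fraction: float = 0.0

    @property
    def reads_surviving_trim(self) -> int:
        return self.reads_mode_both + self.reads_mode_forward_only

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["reads_surviving_trim"] = self.reads_surviving_trim
        return d


def _hamming_at(text: str, pattern: str, pos: int, max_mm: int) -> bool:
    """True if pattern matches text at pos with <= max_mm substitutions."""
    if pos + len(pattern) > len(text):
        return False
    mm = 0
    for a, b in zip(text[pos : pos + len(pattern)], pattern):
        if a != b:
            mm += 1
            if mm > max_mm:
                return False
    return True


def strip_illumina_adapter(read_sequence: str, scheme: AdapterScheme) -> str:
    """Remove a 3' Illumina adapter occurrence, including partial read-through.

    The leftmost full occurrence is cut; failing that, the longest adapter
    prefix (>= ``min_illumina_overlap`` nt) that is a suffix of the read is
    cut. The sequence is returned unchanged if neither is found.
    """
    if not read_sequence:
        raise ValueError("empty read sequence")
    ad = scheme.illumina_adapter
    # cheap pre-check: any qualifying hit must contain the adapter's first
    # min_overlap bases somewhere in the read
    if ad[: scheme.min_illumina_overlap] not in read_sequence:
        return read_sequence
    i = read_sequence.find(ad)
    if i >= 0:
        return read_sequence[:i]
    max_k = min(len(ad) - 1, len(read_sequence))
    for k in range(max_k, scheme.min_illumina_overlap - 1, -1):
        if read_sequence.endswith(ad[:k]):
            return read_sequence[:-k]
    return read_sequence


def locate_forward_adapter(read_sequence: str, scheme: AdapterScheme) -> int | None:
    """Start of the leftmost anchored forward-adapter match, or None.

    The match may start at positions 0..max_forward_offset and tolerates up to
    ``max_mismatches`` substitutions.
    """
    fwd = scheme.forward_malbac
    if scheme.max_mismatches == 0:
        for p in range(scheme.max_forward_offset + 1):
            if read_sequence.startswith(fwd, p):
                return p
        return None
    for p in range(scheme.max_forward_offset + 1):
        if _hamming_at(read_sequence, fwd, p, scheme.max_mismatches):
            return p
    return None


def _find_reverse(core: str, scheme: AdapterScheme) -> int:
    """Leftmost occurrence of the reverse adapter in the core, or -1."""
    rev = scheme.reverse_malbac
    if scheme.max_mismatches == 0:
        return core.find(rev)
    for p in range(len(core) - len(rev) + 1):
        if _hamming_at(core, rev, p, scheme.max_mismatches):
            return p
    return -1


def trim_read(
    read_sequence: str,
    scheme: AdapterScheme,
    max_core_nt: int = 120,
    read_id: str = "",
    forward_pos: int | None = None,
) -> tuple[TrimmedRead | None, str]:
    """Dual-mode trimming of one Illumina-stripped read.

    Returns ``(trimmed, reason)``; ``trimmed`` is None when the read is
    discarded and ``reason`` says why ("no_forward_adapter" or "short_core").
    The 120-nt window of the FORWARD_ONLY branch applies to the core after the
    forward adapter, so insert lengths do not depend on the 5' offset.
    """
    k = scheme.octamer_len
    if forward_pos is None:
        forward_pos = locate_forward_adapter(read_sequence, scheme)
    if forward_pos is None:
        return None, "no_forward_adapter"
    core = read_sequence[forward_pos + len(scheme.forward_malbac) :]
    q = _find_reverse(core, scheme)
    if q >= 0:
        if q < 2 * k:  # no room for both octamers
            return None, "short_core"
        core = core[:q]
        return (
            TrimmedRead(
                read_id=read_id,
                mode="BOTH_ADAPTERS",
                core_with_octamers=core,
                insert=core[k:-k],
                octamer5=core[:k],
                octamer3=core[-k:],
            ),
            "",
        )
    core = core[:max_core_nt]
    if len(core) < k:
        return None, "short_core"
    return (
        TrimmedRead(
            read_id=read_id,
            mode="FORWARD_ONLY",
            core_with_octamers=core,
            insert=core[k:],
            octamer5=core[:k],
            octamer3=None,
        ),
        "",
    )


def length_filter(insert: str, min_nt: int = 30) -> bool:
    """Keep inserts of at least ``min_nt`` bases (mapping-length threshold)."""
    return len(insert) >= min_nt


def collapse_molecules(
    trimmed: Iterable[TrimmedRead],
) -> tuple[list[CollapsedMolecule], PreprocessStats]:
    """Group identical reads into unique molecules.

    Reads collapse only when mode and the full core (octamers included) agree:
    collapsing happens *before* octamer removal so that the octamer acts as
    the molecular counter separating independent priming events from PCR
    duplicates. Output order is first occurrence, which makes the operation
    deterministic and input-order independent in content.
    """
    groups: dict[tuple[str, str], CollapsedMolecule] = {}
    stats = PreprocessStats()
    for tr in trimmed:
        if tr.mode == "BOTH_ADAPTERS":
            stats.reads_mode_both += 1
        else:
            stats.reads_mode_forward_only += 1
        key = (tr.mode, tr.core_with_octamers)
        mol = groups.get(key)
        if mol is None:
            groups[key] = CollapsedMolecule(
                molecule_id=f"DRP{len(groups) + 1:07d}",
                read_count=1,
                mode=tr.mode,
                octamer5=tr.octamer5,
                octamer3=tr.octamer3,
                insert=tr.insert,
                core_with_octamers=tr.core_with_octamers,
            )
        else:
            mol.read_count += 1
    molecules = list(groups.values())
    stats.molecules_out = len(molecules)
    surviving = stats.reads_surviving_trim
    stats.duplicate_fraction = 1.0 - len(molecules) / surviving if surviving else 0.0
    return molecules, stats


def preprocess_reads(
    reads: Iterable[tuple[str, str, str]] | Iterable[tuple[str, str]],
    scheme: AdapterScheme | None = None,
    min_nt: int = 30,
    max_core_nt: int = 120,
) -> tuple[list[CollapsedMolecule], PreprocessStats]:
    """Run the full per-read pipeline on an in-memory read stream.

    ``reads`` yields ``(read_id, sequence[, quality])``; qualities are ignored.
    """
    scheme = scheme or AdapterScheme()

    def trimmed_stream() -> Iterator[TrimmedRead]:
        for rec in reads:
            read_id, seq = rec[0], rec[1]
            stats.reads_in += 1
            seq = strip_illumina_adapter(seq, scheme) if seq else seq
            if not seq:
                stats.reads_discarded_no_adapter += 1
                continue
            pos = locate_forward_adapter(seq, scheme)
            if pos is None:
                stats.reads_discarded_no_adapter += 1
                continue
            stats.reads_with_forward_adapter += 1
            tr, _reason = trim_read(seq, scheme, max_core_nt, read_id=read_id, forward_pos=pos)
            if tr is None:
                stats.reads_discarded_short_core += 1
                continue
            yield tr

    stats = PreprocessStats()
    molecules, collapse_stats = collapse_molecules(trimmed_stream())
    # merge collapse counters into the outer stats object
    stats.reads_mode_both = collapse_stats.reads_mode_both
    stats.reads_mode_forward_only = collapse_stats.reads_mode_forward_only
    stats.molecules_out = collapse_stats.molecules_out
    stats.duplicate_fraction = collapse_stats.duplicate_fraction
    kept = [m for m in molecules if length_filter(m.insert, min_nt)]
    stats.reads_failing_length = len(molecules) - len(kept)
    stats.molecules_written = len(kept)
    return kept, stats


def molecules_table(molecules: list[CollapsedMolecule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "molecule_id": m.molecule_id,
                "read_count": m.read_count,
                "mode": m.mode,
                "octamer5": m.octamer5,
                "octamer3": m.octamer3 if m.octamer3 is not None else ".",
                "insert_length": len(m.insert),
            }
            for m in molecules
        ],
        columns=["molecule_id", "read_count", "mode", "octamer5", "octamer3", "insert_length"],
    )


def preprocess_fastq(
    in_fastq,
    out_dir=None,
    scheme: AdapterScheme | None = None,
    min_nt: int = 30,
    max_core_nt: int = 120,
) -> tuple[list[CollapsedMolecule], PreprocessStats, dict[str, str]]:
    """File-level entry point: FASTQ in, insert FASTQ + molecule TSV + stats out.

    Emits one FASTQ record per unique molecule (the insert only, constant
    quality), a TSV describing each molecule, and a flat key-value stats
    report. Malformed FASTQ fails fast with the offending line number.
    """
    molecules, stats = preprocess_reads(dio.read_fastq(in_fastq), scheme, min_nt, max_core_nt)
    paths: dict[str, str] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "inserts": str(out / "inserts.fastq"),
            "molecules": str(out / "molecules.tsv"),
            "stats": str(out / "preprocess_stats.tsv"),
        }
        dio.write_fastq(
            ((m.molecule_id, m.insert, "I" * len(m.insert)) for m in molecules),
            paths["inserts"],
        )
        dio.write_tsv(molecules_table(molecules), paths["molecules"])
        stats_df = pd.DataFrame(sorted(stats.as_dict().items()), columns=["key", "value"])
        dio.write_tsv(stats_df, paths["stats"])
    return molecules, stats, paths
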