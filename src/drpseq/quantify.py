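"""Toy transcript-level quantification of preprocessed inserts.

A stand-in for genome alignment at desk scale: inserts are contiguous
transcript fragments, so exact (or near-exact) substring search against the
transcriptome is a faithful mapper for simulated data. An insert matching a
single gene contributes one fragment to it; an insert matching k genes
contributes 1/k to each ("multi-loci reads distributed uniformly"); matching
one gene at several positions counts once. FPKM is computed without effective
-length correction and normalised by assigned fragments only
(compatible-hits-norm): fpkm = assigned * 1e9 / (length_bp * total_assigned).

Real-data users bring external per-gene tables instead; see
:func:`read_cufflinks_fpkm`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io as dio
from .simulate import ERCC_PREFIX, Transcriptome, revcomp

_POS_SHIFT = 32  # packed candidate = (gene_index << 32) | position


class TranscriptIndex:
    """Exact/near-exact substring lookup over a small transcriptome.

    Seeds of length ``k`` are indexed at every position of every transcript
    (forward strand). A query is verified at each seed hit; reverse-strand
    hits are found by querying the reverse complement. With
    ``max_mismatches = m`` the query is split into m+1 seed chunks so that at
    least one chunk is error-free in any qualifying match (pigeonhole), which
    makes the search exact for queries of length >= (m+1) * k.
    """

    def __init__(self, transcriptome: Transcriptome, k: int = 24):
        if not transcriptome.records:
            raise ValueError("empty transcriptome")
        self.k = k
        self.gene_ids = transcriptome.gene_ids
        self.seqs = [s for _, _, s in transcriptome.records]
        index: dict[str, list[int]] = {}
        for gi, seq in enumerate(self.seqs):
            base = gi << _POS_SHIFT
            for p in range(len(seq) - k + 1):
                index.setdefault(seq[p : p + k], []).append(base | p)
        self._index = index

    def _candidates(self, query: str, max_mm: int) -> set[tuple[int, int]]:
        """Candidate (gene_index, query_start_position) diagonals."""
        k = self.k
        n_chunks = max_mm + 1
        cands: set[tuple[int, int]] = set()
        L = len(query)
        if L < k:
            return cands
        # chunk starts spread over the query; always include the final k-mer
        starts = sorted({min(i * k, L - k) for i in range(n_chunks)})
        for s in starts:
            for packed in self._index.get(query[s : s + k], ()):
                gi, p = packed >> _POS_SHIFT, packed & ((1 << _POS_SHIFT) - 1)
                if p - s >= 0:
                    cands.add((gi, p - s))
        return cands

    def _verify(self, query: str, gi: int, pos: int, max_mm: int) -> bool:
        seq = self.seqs[gi]
        if pos + len(query) > len(seq):
            return False
        window = seq[pos : pos + len(query)]
        if max_mm == 0:
            return window == query
        mm = 0
        for a, b in zip(window, query):
            if a != b:
                mm += 1
                if mm > max_mm:
                    return False
        return True

    def lookup(self, insert: str, max_mismatches: int = 0) -> list[tuple[str, int, int, str]]:
        """All genes containing ``insert`` (either strand).

        Returns one entry per matching gene: ``(gene_id, start, end, strand)``
        using the leftmost forward-strand hit, or the leftmost reverse hit for
        genes matched only on the reverse strand. Coordinates are 0-based
        half-open on the transcript.
        """
        hits: dict[int, tuple[int, str]] = {}
        for strand, query in (("+", insert), ("-", revcomp(insert))):
            for gi, pos in sorted(self._candidates(query, max_mismatches)):
                if gi in hits:
                    continue
                if self._verify(query, gi, pos, max_mismatches):
                    hits[gi] = (pos, strand)
        return [
            (self.gene_ids[gi], pos, pos + len(insert), strand)
            for gi, (pos, strand) in sorted(hits.items())
        ]


def toy_map(
    inserts: Iterable[tuple[str, str]],
    transcriptome: Transcriptome | TranscriptIndex,
    max_mismatches: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Map ``(read_id, insert)`` pairs to genes by substring search.

    Returns ``(assignments, n_unassigned)``. Assignments carry one row per
    (read, gene) with the uniform multi-match weight 1/k, the transcript
    coordinates of the hit and the insert length — everything the analytics
    stage needs (subsampling, base tallies, gene-body coverage).
    """
    index = (
        transcriptome
        if isinstance(transcriptome, TranscriptIndex)
        else TranscriptIndex(transcriptome)
    )
    rows = []
    unassigned = 0
    for read_id, insert in inserts:
        hits = index.lookup(insert, max_mismatches)
        if not hits:
            unassigned += 1
            continue
        w = 1.0 / len(hits)
        for gene_id, start, end, strand in hits:
            rows.append((read_id, gene_id, w, start, end, strand, len(insert)))
    assignments = pd.DataFrame(
        rows,
        columns=["read_id", "gene_id", "weight", "start", "end", "strand", "insert_length"],
    )
    return assignments, unassigned


def counts_from_assignments(
    assignments: pd.DataFrame, gene_ids: Sequence[str] | None = None
) -> pd.Series:
    """Per-gene fractional fragment counts (sum equals assigned reads exactly)."""
    if len(assignments):
        counts = assignments.groupby("gene_id").weight.sum()
    else:
        counts = pd.Series(dtype=float)
    if gene_ids is not None:
        counts = counts.reindex(gene_ids, fill_value=0.0)
    counts.name = "assigned_fragments"
    return counts


def compute_fpkm(counts: pd.Series | pd.DataFrame, lengths: pd.Series) -> pd.Series | pd.DataFrame:
    """FPKM without effective-length correction.

    ``counts`` is a per-gene Series (one sample) or DataFrame (genes x
    samples); ``lengths`` the annotated transcript length in bp. The
    normalising total is the sum of assigned fragments of the same sample
    (compatible-hits-norm), so unassigned reads never enter the denominator.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:3]
        raise ValueError(f"missing gene length for e.g. {missing}")
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])[:3]
        raise ValueError(f"non-positive gene length for e.g. {bad}")
    total = counts.sum(axis=0)
    if np.any(np.asarray(total) <= 0):
        raise ValueError("total assigned fragments must be positive")
    if isinstance(counts, pd.DataFrame):
        return counts.mul(1e9).div(lengths, axis=0).div(total, axis=1)
    return counts * 1e9 / (lengths * total)


def expressed_genes(
    fpkm: pd.Series,
    threshold: float = 1.0,
    exclude_ercc: bool = True,
    ercc_prefix: str = ERCC_PREFIX,
) -> set[str]:
    """Genes considered expressed: FPKM >= threshold, spike-ins removed first."""
    s = fpkm
    if exclude_ercc:
        s = s[~s.index.str.startswith(ercc_prefix)]
    return set(s.index[s >= threshold])


def fpkm_table(
    fpkm_by_sample: dict[str, pd.Series], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Wide per-gene FPKM table with length and biotype columns."""
    ann = annotation.set_index("gene_id")
    df = pd.DataFrame(fpkm_by_sample)
    df.insert(0, "length_bp", ann.length_bp.reindex(df.index))
    df.insert(1, "biotype", ann.biotype.reindex(df.index))
    df.index.name = "gene_id"
    return df


def read_cufflinks_fpkm(
    path,
    gene_id_column: str = "tracking_id",
    fpkm_column: str = "FPKM",
    sample_id: str | None = None,
) -> pd.Series:
    """Ingest an externally produced (Cufflinks-style) FPKM TSV as one sample."""
    df = dio.read_tsv(path, required_columns=(gene_id_column, fpkm_column))
    s = df.set_index(gene_id_column)[fpkm_column].astype(float)
    s.index.name = "gene_id"
    s.name = sample_id
    return s
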