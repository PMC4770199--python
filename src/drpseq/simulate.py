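"""Simulator for double-random-priming (DRP) whole-transcriptome libraries.

The library chemistry being emulated: total RNA is reverse-transcribed with an
oligonucleotide carrying a fixed 25-nt MALBAC adapter and a random 3' octamer;
one round of second-strand synthesis with the same primer yields amplicons
flanked by reverse-complementary adapters. PCR with a mix of variable-length
adapter primers amplifies these amplicons; self-annealing of the complementary
ends ("panhandle" formation) suppresses amplification of short fragments, so
no insert below ``fragment_min_bp`` is ever emitted. Each sequenced read is

    [0-3 random 5' offset bases] + forward adapter + octamer5 + insert
        (+ octamer3 + reverse adapter + Illumina adapter, if they fit)

truncated to ``read_length_nt``. The random octamers act as molecular
counters: PCR duplicates of one priming event share both octamers and insert.

Every simulation emits a truth table mapping each read to its source molecule,
which downstream modules use as the deduplication / quantification oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as dio

FORWARD_MALBAC = "GAGTGATGGTTGAGGTAGTGTGGAG"
REVERSE_MALBAC = "CTCCACACTACCTCAACCATCACTC"

#: molecules per attomole (Avogadro's number x 1e-18)
MOLECULES_PER_ATTOMOLE = 6.02214e5

#: gene classes quantified in composition summaries
BIOTYPES = (
    "protein_coding",
    "rRNA",
    "Mt_rRNA",
    "lincRNA",
    "misc_RNA",
    "snRNA",
    "intergenic",
)

#: biotypes whose abundance mass is controlled by ``rrna_mass_fraction``
RRNA_BIOTYPES = frozenset({"rRNA", "Mt_rRNA"})

#: realistic relative gene-count mix for a small synthetic annotation
DEFAULT_BIOTYPE_WEIGHTS = {
    "protein_coding": 0.70,
    "rRNA": 0.04,
    "Mt_rRNA": 0.02,
    "lincRNA": 0.10,
    "misc_RNA": 0.06,
    "snRNA": 0.04,
    "intergenic": 0.04,
}

ERCC_PREFIX = "ERCC-"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated DRP library.

    Defaults mirror the protocol's 5-ng arm: amplicons sized 150-600 bp,
    150-cycle single-end MiSeq reads, 12 PCR cycles, and four variable-length
    adapter primers modelled as 0-3 random 5' offset bases.
    """

    n_genes: int = 500
    expression_dispersion: float = 1.0  # sigma of log-normal per-gene abundance
    rrna_mass_fraction: float = 0.4
    input_picograms: float = 5000.0
    capture_molecules_per_pg: float = 2.0
    fragment_min_bp: int = 150
    fragment_max_bp: int = 600
    pcr_cycles: int = 12
    per_cycle_efficiency: float = 0.45
    read_length_nt: int = 150
    error_rate: float = 0.0
    adapter_offsets: tuple[int, ...] = (0, 1, 2, 3)
    seed: int = 0
    # -- shape of the synthetic annotation --
    gene_length_range: tuple[int, int] = (800, 3000)
    biotype_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_WEIGHTS)
    )
    #: probability that a molecule is drawn from the antisense strand
    flip_strand_prob: float = 0.0
    #: capture probability per spike-in molecule copy
    ercc_capture_rate: float = 2e-3

    def __post_init__(self):
        if self.fragment_min_bp >= self.fragment_max_bp:
            raise ValueError("fragment_min_bp must be < fragment_max_bp")
        if not (0 < self.per_cycle_efficiency <= 1):
            raise ValueError("per_cycle_efficiency must be in (0, 1]")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0 <= self.rrna_mass_fraction <= 1):
            raise ValueError("rrna_mass_fraction must be in [0, 1]")
        if min(self.adapter_offsets, default=0) < 0:
            raise ValueError("adapter_offsets must be non-negative")
        if self.input_picograms <= 0 or self.capture_molecules_per_pg <= 0:
            raise ValueError("input_picograms and capture_molecules_per_pg must be positive")
        min_usable = max(self.adapter_offsets) + len(FORWARD_MALBAC) + 8 + 30
        if self.read_length_nt <= min_usable - 30:
            raise ValueError(
                f"read_length_nt={self.read_length_nt} leaves no room for adapter+octamer"
            )


@dataclass
class Transcriptome:
    """A toy transcriptome: one transcript per gene, with a biotype each."""

    records: list[tuple[str, str, str]]  # (gene_id, biotype, sequence)

    def __post_init__(self):
        ids = [g for g, _, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        for g, _, seq in self.records:
            if len(seq) < 200:
                raise ValueError(f"{g}: transcript shorter than 200 nt")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _, _ in self.records]

    @property
    def sequences(self) -> dict[str, str]:
        return {g: s for g, _, s in self.records}

    @property
    def lengths(self) -> dict[str, int]:
        return {g: len(s) for g, _, s in self.records}

    @property
    def biotypes(self) -> dict[str, str]:
        return {g: b for g, b, _ in self.records}

    def annotation(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "length_bp": len(s),
                "biotype": b,
                "is_rrna": int(b in RRNA_BIOTYPES),
            }
            for g, b, s in self.records
        ]
        return pd.DataFrame(rows)

    def extended(self, extra: Sequence[tuple[str, str, str]]) -> "Transcriptome":
        return Transcriptome(self.records + list(extra))

    def to_fasta(self, path) -> None:
        dio.write_fasta(((g, s) for g, _, s in self.records), path)

    @classmethod
    def from_fasta(cls, fasta_path, annotation_path) -> "Transcriptome":
        seqs = dict(dio.read_fasta(fasta_path))
        ann = dio.read_tsv(annotation_path, required_columns=("gene_id", "biotype"))
        records = []
        for _, row in ann.iterrows():
            if row.gene_id not in seqs:
                raise ValueError(f"{row.gene_id} in annotation but not in FASTA")
            records.append((row.gene_id, row.biotype, seqs[row.gene_id]))
        return cls(records)


@dataclass
class Molecule:
    """A ground-truth amplifiable fragment: the unit the deduplicator recovers."""

    molecule_id: str
    gene_id: str
    start_0based: int
    insert_length_bp: int
    octamer5: str
    octamer3: str
    copy_count: int
    strand: str = "+"


def _allocate_biotype_counts(n_genes: int, weights: dict[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder allocation with >=1 gene per biotype."""
    names = list(weights)
    if n_genes < len(names):
        raise ValueError(
            f"n_genes={n_genes} is smaller than the {len(names)} requested biotypes"
        )
    total = sum(weights.values())
    spare = n_genes - len(names)  # one gene per biotype is reserved
    raw = {b: spare * weights[b] / total for b in names}
    counts = {b: 1 + int(raw[b]) for b in names}
    # distribute the remainder by largest fractional part, then name order
    leftovers = sorted(names, key=lambda b: (raw[b] - int(raw[b]), b), reverse=True)
    for b in leftovers[: n_genes - sum(counts.values())]:
        counts[b] += 1
    return counts


def make_transcriptome(config: SimConfig) -> Transcriptome:
    """Generate a random transcriptome with the configured biotype mix.

    Deterministic for a fixed ``config.seed``. Gene lengths are drawn uniformly
    from ``gene_length_range`` independently of biotype, so length-normalised
    class shares track the configured abundance-mass shares.
    """
    if config.n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    rng = np.random.default_rng(config.seed)
    counts = _allocate_biotype_counts(config.n_genes, config.biotype_weights)
    lo, hi = config.gene_length_range
    records = []
    i = 0
    for biotype in BIOTYPES:
        for _ in range(counts.get(biotype, 0)):
            i += 1
            length = int(rng.integers(lo, hi + 1))
            records.append((f"G{i:05d}", biotype, random_sequence(rng, length)))
    return Transcriptome(records)


def draw_abundances(
    transcriptome: Transcriptome, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.Series:
    """Per-gene expected fragment mass, normalised to sum 1.

    Abundances are log-normal with sigma ``expression_dispersion``; the rRNA
    classes (rRNA + Mt_rRNA) are then rescaled so their summed mass equals
    ``rrna_mass_fraction`` exactly.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    ann = transcriptome.annotation()
    x = rng.lognormal(mean=0.0, sigma=config.expression_dispersion, size=len(ann))
    abund = pd.Series(x, index=ann.gene_id.values)
    is_r = ann.set_index("gene_id").is_rrna.astype(bool)
    f = config.rrna_mass_fraction
    s_r, s_o = abund[is_r].sum(), abund[~is_r].sum()
    if is_r.any():
        if f == 1.0:
            abund[~is_r] = 0.0
        elif s_r > 0:
            abund[is_r] *= f / (1.0 - f) * s_o / s_r if f < 1 else 0.0
    return abund / abund.sum()


def _draw_copy_counts(rng: np.random.Generator, n: int, cycles: int, efficiency: float) -> np.ndarray:
    """Per-molecule PCR duplicate counts: per-cycle Bernoulli doubling.

    Each existing copy duplicates independently with probability ``efficiency``
    in each cycle, so the mean count is (1 + efficiency) ** cycles.
    """
    counts = np.ones(n, dtype=np.int64)
    for _ in range(cycles):
        counts = counts + rng.binomial(counts, efficiency)
    return counts


def _draw_fragments(
    rng: np.random.Generator,
    gene_ids: np.ndarray,
    lengths: np.ndarray,
    config: SimConfig,
    id_offset: int = 0,
) -> list[Molecule]:
    """Draw insert coordinates, octamers and copy counts for chosen genes."""
    n = len(gene_ids)
    fmin = config.fragment_min_bp
    hi = np.minimum(config.fragment_max_bp, lengths)
    if np.any(hi < fmin):
        bad = gene_ids[hi < fmin][0]
        raise ValueError(
            f"gene {bad} is shorter than fragment_min_bp={fmin}; no fragment can form"
        )
    ins_len = fmin + (rng.random(n) * (hi - fmin + 1)).astype(np.int64)
    starts = (rng.random(n) * (lengths - ins_len + 1)).astype(np.int64)
    octs = _BASES[rng.integers(0, 4, (n, 16))]
    copies = _draw_copy_counts(rng, n, config.pcr_cycles, config.per_cycle_efficiency)
    if config.flip_strand_prob > 0:
        strands = np.where(rng.random(n) < config.flip_strand_prob, "-", "+")
    else:
        strands = np.full(n, "+")
    return [
        Molecule(
            molecule_id=f"M{id_offset + i + 1:07d}",
            gene_id=str(gene_ids[i]),
            start_0based=int(starts[i]),
            insert_length_bp=int(ins_len[i]),
            octamer5=octs[i, :8].tobytes().decode(),
            octamer3=octs[i, 8:].tobytes().decode(),
            copy_count=int(copies[i]),
            strand=str(strands[i]),
        )
        for i in range(n)
    ]


def simulate_molecules(
    transcriptome: Transcriptome,
    abundances: pd.Series,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[Molecule]:
    """Sample amplifiable fragments from the transcriptome.

    The number of captured molecules is Poisson with mean
    ``input_picograms * capture_molecules_per_pg``; genes are chosen in
    proportion to ``abundances``; insert lengths are uniform on
    [fragment_min_bp, min(fragment_max_bp, transcript length)] — shorter
    fragments are suppressed by panhandle formation and never emitted.
    """
    if not transcriptome.records:
        raise ValueError("empty transcriptome")
    missing = set(transcriptome.gene_ids) - set(abundances.index)
    if missing:
        raise ValueError(f"abundances missing for {len(missing)} genes, e.g. {sorted(missing)[:3]}")
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    n_mol = int(rng.poisson(config.input_picograms * config.capture_molecules_per_pg))
    order = transcriptome.gene_ids
    p = abundances.reindex(order).to_numpy(dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(order), size=n_mol, p=p)
    gene_arr = np.array(order, dtype=object)[idx]
    len_map = transcriptome.lengths
    lengths = np.array([len_map[g] for g in gene_arr], dtype=np.int64)
    return _draw_fragments(rng, gene_arr, lengths, config)


# ---------------------------------------------------------------------------
# ERCC spike-ins
# ---------------------------------------------------------------------------

def ercc_copies(stock_attomol_per_ul, dilution_factor, sample_volume_ul):
    """Molecule copies from stock concentration: attomoles x Avogadro x 1e-18."""
    stock = np.asarray(stock_attomol_per_ul, dtype=float)
    if np.any(stock < 0) or np.any(np.asarray(dilution_factor, dtype=float) < 0):
        raise ValueError("concentrations and dilution factors must be non-negative")
    return stock * dilution_factor * sample_volume_ul * MOLECULES_PER_ATTOMOLE


def make_ercc_table(
    n: int = 24,
    stock_range: tuple[float, float] = (0.1, 1000.0),
    dilution_factor: float = 1e-3,
    sample_volume_ul: float = 5.0,
) -> pd.DataFrame:
    """A synthetic spike-in mix with stock concentrations spanning ~4 logs."""
    stocks = np.geomspace(stock_range[0], stock_range[1], n)
    table = pd.DataFrame(
        {
            "ercc_id": [f"{ERCC_PREFIX}{i + 1:05d}" for i in range(n)],
            "stock_attomol_per_ul": stocks,
            "dilution_factor": dilution_factor,
            "sample_volume_ul": sample_volume_ul,
        }
    )
    table["copies"] = ercc_copies(
        table.stock_attomol_per_ul, table.dilution_factor, table.sample_volume_ul
    )
    return table


def make_ercc_records(
    ercc_table: pd.DataFrame,
    seed: int = 1729,
    length_range: tuple[int, int] = (400, 1200),
) -> list[tuple[str, str, str]]:
    """Random spike-in sequences (biotype ``spike_in``) for the table's ids."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    return [
        (eid, "spike_in", random_sequence(rng, int(rng.integers(lo, hi + 1))))
        for eid in ercc_table.ercc_id
    ]


def simulate_ercc(
    ercc_table: pd.DataFrame,
    ercc_records: Sequence[tuple[str, str, str]],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    id_offset: int = 0,
) -> list[Molecule]:
    """Sample spike-in molecules: Poisson(copies x ercc_capture_rate) per id."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    copies = ercc_copies(
        ercc_table.stock_attomol_per_ul, ercc_table.dilution_factor, ercc_table.sample_volume_ul
    )
    seq_map = {g: s for g, _, s in ercc_records}
    counts = rng.poisson(np.asarray(copies) * config.ercc_capture_rate)
    gene_list: list[str] = []
    for eid, c in zip(ercc_table.ercc_id, counts):
        gene_list.extend([eid] * int(c))
    if not gene_list:
        return []
    gene_arr = np.array(gene_list, dtype=object)
    lengths = np.array([len(seq_map[g]) for g in gene_arr], dtype=np.int64)
    return _draw_fragments(rng, gene_arr, lengths, config, id_offset=id_offset)


# ---------------------------------------------------------------------------
# Read rendering
# ---------------------------------------------------------------------------

#: TruSeq read-1 adapter, appended after the reverse MALBAC adapter on read-through
DEFAULT_ILLUMINA_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


def render_reads(
    molecules: Sequence[Molecule],
    transcriptome: Transcriptome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    illumina_adapter: str = DEFAULT_ILLUMINA_ADAPTER,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Render every PCR copy of every molecule as a sequencing read.

    Returns ``(reads, truth)`` where reads are ``(read_id, sequence)`` pairs
    (quality is a constant placeholder at write time) and truth maps each read
    to its molecule, coordinates, octamers and the trim mode the read geometry
    implies (BOTH_ADAPTERS when the full reverse adapter fits in the read,
    FORWARD_ONLY otherwise). One read per copy: nothing is dropped, so the
    read count equals the sum of copy counts.
    """
    min_needed = len(FORWARD_MALBAC) + 8 + 30
    if config.read_length_nt <= min_needed:
        raise ValueError(
            f"read_length_nt must exceed {min_needed} for any read to survive preprocessing"
        )
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    seqs = transcriptome.sequences
    offsets_choices = np.asarray(config.adapter_offsets)
    read_len = config.read_length_nt
    total_reads = sum(m.copy_count for m in molecules)
    # bulk randomness: one offset choice per read, one pool of offset bases
    all_offsets = offsets_choices[rng.integers(0, len(offsets_choices), total_reads)]
    pad_pool = random_sequence(rng, int(all_offsets.sum())) if all_offsets.sum() else ""

    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple] = []
    pad_pos = 0
    r = 0
    fwd_len = len(FORWARD_MALBAC)
    for mol in molecules:
        tx = seqs[mol.gene_id]
        insert = tx[mol.start_0based : mol.start_0based + mol.insert_length_bp]
        if mol.strand == "-":
            insert = revcomp(insert)
        base = (
            FORWARD_MALBAC
            + mol.octamer5
            + insert
            + mol.octamer3
            + REVERSE_MALBAC
            + illumina_adapter
        )
        if len(base) < read_len:
            base = base + "A" * (read_len - len(base))
        for _ in range(mol.copy_count):
            off = int(all_offsets[r])
            prefix = pad_pool[pad_pos : pad_pos + off]
            pad_pos += off
            seq = (prefix + base)[:read_len]
            r += 1
            read_id = f"R{r:08d}"
            # does the full reverse adapter fit in this copy's read?
            rev_end = off + fwd_len + 8 + mol.insert_length_bp + 8 + len(REVERSE_MALBAC)
            mode = "BOTH_ADAPTERS" if rev_end <= read_len else "FORWARD_ONLY"
            reads.append((read_id, seq))
            truth_rows.append(
                (
                    read_id,
                    mol.molecule_id,
                    mol.gene_id,
                    mol.start_0based,
                    mol.insert_length_bp,
                    mol.octamer5,
                    mol.octamer3,
                    mode,
                )
            )
    if config.error_rate > 0 and reads:
        reads = _inject_errors(reads, config.error_rate, rng)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "molecule_id",
            "gene_id",
            "start_0based",
            "insert_length_bp",
            "octamer5",
            "octamer3",
            "mode",
        ],
    )
    return reads, truth


def _inject_errors(
    reads: list[tuple[str, str]], rate: float, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Substitution-only errors: each base flips to one of the 3 others at ``rate``."""
    out = []
    for read_id, seq in reads:
        n_err = rng.binomial(len(seq), rate)
        if n_err == 0:
            out.append((read_id, seq))
            continue
        pos = rng.choice(len(seq), size=n_err, replace=False)
        chars = list(seq)
        for p in pos:
            alternatives = [b for b in "ACGT" if b != chars[p]]
            chars[p] = alternatives[rng.integers(0, 3)]
        out.append((read_id, "".join(chars)))
    return out


def molecules_frame(molecules: Sequence[Molecule]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in molecules])


def write_library(
    out_dir,
    transcriptome: Transcriptome,
    reads: Sequence[tuple[str, str]],
    truth: pd.DataFrame,
    ercc_table: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write a simulated library to ``out_dir``; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcriptome": str(out / "transcriptome.fasta"),
        "annotation": str(out / "annotation.tsv"),
        "reads": str(out / "reads.fastq"),
        "truth": str(out / "truth.tsv"),
    }
    transcriptome.to_fasta(paths["transcriptome"])
    dio.write_tsv(transcriptome.annotation(), paths["annotation"])
    dio.write_fastq(((rid, s, "I" * len(s)) for rid, s in reads), paths["reads"])
    dio.write_tsv(truth, paths["truth"])
    if ercc_table is not None:
        paths["ercc"] = str(out / "ercc.tsv")
        dio.write_tsv(ercc_table, paths["ercc"])
    return paths
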