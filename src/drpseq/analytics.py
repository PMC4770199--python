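"""Downstream analytics for DRP transcriptome profiling.

Implements the study's summary computations on per-gene tables and per-read
assignments: saturation by read subsampling, gene-class (biotype)
composition, rRNA base fraction, gene-body coverage, ERCC copy-number
linearity, replicate concordance, detection overlap between replicates,
dilution-control subtraction of differential-expression lists, complete
-linkage clustering of log2(FPKM), and microarray probeset collapsing.

Differential testing itself is out of scope: q-values are consumed from
external tables, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import compute_fpkm, counts_from_assignments, expressed_genes
from .simulate import ERCC_PREFIX

#: the study reassigns this abundant ribosomal transcript from lincRNA to rRNA
DEFAULT_BIOTYPE_OVERRIDES = {"Gm26924": "rRNA"}


# ---------------------------------------------------------------------------
# saturation
# ---------------------------------------------------------------------------

def saturation(
    assignments: pd.DataFrame,
    lengths: pd.Series,
    fractions: list[float],
    seed: int,
    threshold: float = 1.0,
    exclude_ercc: bool = True,
) -> pd.DataFrame:
    """Expressed-gene counts at subsampled read fractions.

    For each fraction, reads (distinct read ids) are subsampled without
    replacement with a seeded generator, FPKM is recomputed on the subsample,
    and genes with FPKM >= threshold are counted after spike-in removal.
    Fraction 1.0 uses all reads, so it equals the full-sample count exactly.
    """
    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError(f"fraction {f} outside (0, 1]")
    read_ids = assignments.read_id.unique()
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        if f == 1.0:
            sub = assignments
        else:
            take = rng.choice(read_ids, size=int(round(f * len(read_ids))), replace=False)
            sub = assignments[assignments.read_id.isin(set(take))]
        counts = counts_from_assignments(sub)
        fpkm = compute_fpkm(counts, lengths)
        rows.append(
            {
                "fraction": f,
                "genes_detected": len(
                    expressed_genes(fpkm, threshold, exclude_ercc=exclude_ercc)
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# composition and coverage
# ---------------------------------------------------------------------------

def class_composition(
    fpkm: pd.DataFrame | pd.Series,
    biotypes: pd.Series,
    biotype_overrides: dict[str, str] | None = None,
    threshold: float = 1.0,
    exclude_prefix: str = ERCC_PREFIX,
) -> pd.DataFrame:
    """Percent of total FPKM per gene class, over expressed genes only.

    FPKM of genes at or above ``threshold`` is summed within each biotype
    (after applying per-gene overrides such as the lincRNA->rRNA reassignment
    of Gm26924) and expressed as a percentage of the per-sample total, which
    therefore sums to 100.
    """
    df = fpkm.to_frame() if isinstance(fpkm, pd.Series) else fpkm
    df = df[~df.index.str.startswith(exclude_prefix)]
    bt = biotypes.reindex(df.index)
    if biotype_overrides:
        bt = bt.copy()
        for gene, cls in biotype_overrides.items():
            if gene in bt.index:
                bt[gene] = cls
    if bt.isna().any():
        offenders = list(bt.index[bt.isna()])
        raise ValueError(f"genes missing a biotype: {offenders[:10]}")
    out = {}
    for sample in df.columns:
        col = df[sample]
        expressed = col[col >= threshold]
        total = expressed.sum()
        if total <= 0:
            raise ValueError(f"sample {sample}: no expressed genes at threshold {threshold}")
        out[sample] = expressed.groupby(bt.reindex(expressed.index)).sum() / total * 100.0
    comp = pd.DataFrame(out).fillna(0.0)
    comp.index.name = "biotype"
    return comp


def rrna_base_fraction(assignments: pd.DataFrame, rrna_genes: set[str]) -> float:
    """Fraction of aligned bases falling in rRNA genes.

    Bases are insert lengths weighted by the uniform multi-match weight, so
    a read split across k genes contributes length/k to each.
    """
    if not len(assignments):
        raise ValueError("no assigned bases")
    bases = assignments.weight * assignments.insert_length
    total = bases.sum()
    if total <= 0:
        raise ValueError("no assigned bases")
    in_rrna = bases[assignments.gene_id.isin(rrna_genes)].sum()
    return float(in_rrna / total)


def gene_body_coverage(
    assignments: pd.DataFrame,
    lengths: pd.Series,
    genes: set[str] | None = None,
    n_bins: int = 100,
) -> np.ndarray:
    """Mean read coverage along the normalised transcript length.

    Each covered transcript's base-level coverage is rescaled to ``n_bins``
    bins (fractional bin overlap), normalised to mean 1 per gene so abundant
    genes do not dominate, averaged over genes, and renormalised to mean 1.
    """
    if genes is not None:
        assignments = assignments[assignments.gene_id.isin(genes)]
    profiles = []
    for gene_id, grp in assignments.groupby("gene_id"):
        L = float(lengths[gene_id])
        prof = np.zeros(n_bins)
        b0 = grp.start.to_numpy() / L * n_bins
        b1 = grp.end.to_numpy() / L * n_bins
        w = grp.weight.to_numpy()
        for lo, hi, wt in zip(b0, b1, w):
            i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
            for b in range(i0, min(i1, n_bins)):
                overlap = min(hi, b + 1) - max(lo, b)
                if overlap > 0:
                    prof[b] += wt * overlap
        if prof.sum() > 0:
            profiles.append(prof / prof.mean())
    if not profiles:
        return np.zeros(n_bins)
    mean_prof = np.mean(profiles, axis=0)
    return mean_prof / mean_prof.mean()


# ---------------------------------------------------------------------------
# ERCC linearity
# ---------------------------------------------------------------------------

def floor_fpkm(fpkm: pd.Series, floor: float = 0.1) -> pd.Series:
    """Idempotent floor transform: values below ``floor`` report ``floor``."""
    return fpkm.clip(lower=floor)


def ercc_analysis(
    fpkm: pd.Series, ercc_table: pd.DataFrame, floor: float = 0.1
) -> tuple[pd.DataFrame, float]:
    """Spike-in FPKM against calculated copy number.

    FPKM below ``floor`` is set to the floor; the Pearson correlation is
    computed on log10 scale over spike-ins with copies > 0. Requires at least
    three such spike-ins.
    """
    table = ercc_table.set_index("ercc_id")
    merged = pd.DataFrame(
        {
            "copies": table.copies,
            "fpkm": fpkm.reindex(table.index).fillna(0.0),
        }
    )
    merged["fpkm_floored"] = floor_fpkm(merged.fpkm, floor)
    pos = merged[merged.copies > 0]
    if len(pos) < 3:
        raise ValueError("need at least 3 spike-ins with copies > 0")
    r, _ = sps.pearsonr(np.log10(pos.copies), np.log10(pos.fpkm_floored))
    return merged.reset_index(), float(r)


# ---------------------------------------------------------------------------
# replicate concordance and overlap
# ---------------------------------------------------------------------------

def replicate_concordance(
    fpkm_a: pd.Series,
    fpkm_b: pd.Series,
    min_fpkm: float = 0.001,
    log: bool = False,
) -> tuple[float | None, float | None]:
    """(Pearson, Spearman) between two samples' FPKM vectors.

    Genes passing ``min_fpkm`` in *either* sample are retained (union rule),
    so both coefficients see the identical gene set. Coefficients are
    computed on absolute FPKM by default; ``log=True`` applies log10 after a
    half-minimum pseudo-count first. Degenerate (constant) vectors yield
    None for the affected coefficient.
    """
    genes = fpkm_a.index.intersection(fpkm_b.index)
    a, b = fpkm_a[genes], fpkm_b[genes]
    keep = (a >= min_fpkm) | (b >= min_fpkm)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError(f"only {len(a)} genes pass the FPKM >= {min_fpkm} filter")
    if log:
        pseudo = min(x[x > 0].min() for x in (a, b) if (x > 0).any()) * 0.5
        a, b = np.log10(a + pseudo), np.log10(b + pseudo)
    pearson = spearman = None
    if a.nunique() > 1 and b.nunique() > 1:
        pearson = float(sps.pearsonr(a, b)[0])
        spearman = float(sps.spearmanr(a, b)[0])
    return pearson, spearman


def detection_overlap(
    expressed_sets: dict[str, set[str]],
) -> tuple[set[str], dict[str, float | None]]:
    """Intersection across replicates and per-replicate percent in common."""
    if len(expressed_sets) < 2:
        raise ValueError("need at least 2 replicates")
    common = set.intersection(*expressed_sets.values())
    percents = {
        rep: (100.0 * len(common) / len(s) if s else None) for rep, s in expressed_sets.items()
    }
    return common, percents


# ---------------------------------------------------------------------------
# dilution-control subtraction
# ---------------------------------------------------------------------------

def control_subtract(
    de_main: pd.DataFrame,
    de_control: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Remove cycle-number artefacts from a differential-expression list.

    ``de_main`` and ``de_control`` are tables with columns (gene_id,
    log2_fold_change, q_value, direction). The control compares undiluted
    with diluted input amplified at the two cycle numbers of the main
    comparison, with directions labelled by the paired arm (side_A:
    undiluted/somatodendritic; side_B: diluted/axonal). Genes significant in
    the main list are dropped when the control finds them significant in the
    matching arm. Returns the retained rows of the significant main list.
    """
    for df, name in ((de_main, "de_main"), (de_control, "de_control")):
        missing = {"gene_id", "q_value", "direction"} - set(df.columns)
        if missing:
            raise ValueError(f"{name}: missing column(s) {sorted(missing)}")
    main_sig = de_main[de_main.q_value < alpha]
    ctrl_sig = de_control[de_control.q_value < alpha]
    keep = []
    for side, grp in main_sig.groupby("direction"):
        artefacts = set(ctrl_sig.loc[ctrl_sig.direction == side, "gene_id"])
        keep.append(grp[~grp.gene_id.isin(artefacts)])
    if not keep:
        return main_sig.iloc[0:0]
    return pd.concat(keep).sort_index()


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Linkage matrix (scipy layout) plus a deterministic leaf order."""

    linkage: np.ndarray  # rows: (id_a, id_b, height, size), ids scipy-style
    leaf_order: list[int]


def complete_linkage(points: np.ndarray) -> Dendrogram:
    """Agglomerative complete-linkage clustering with Euclidean distances.

    Deterministic tie-breaking: among merges of equal (minimum) height the
    pair with the lexicographically smallest active-cluster indices is merged
    first. Leaf order is a recursive traversal that visits the smaller
    subtree first (ties: the subtree containing the smallest original leaf).
    """
    X = np.asarray(points, dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in clustering input")
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(D, np.inf)
    # active clusters: position -> (scipy id, member leaves, creation order)
    ids = list(range(n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    Z = np.zeros((n - 1, 4))
    children: dict[int, tuple[int, int]] = {}
    for step in range(n - 1):
        flat = np.argmin(D)  # row-major: first minimum = smallest (i, j)
        i, j = divmod(int(flat), D.shape[0])
        if i > j:
            i, j = j, i
        h = D[i, j]
        new_id = n + step
        a, b = ids[i], ids[j]
        Z[step] = (min(a, b), max(a, b), h, len(members[a]) + len(members[b]))
        children[new_id] = (min(a, b), max(a, b))
        members[new_id] = members[a] + members[b]
        # complete linkage: distance to the merged cluster is the max
        d_new = np.maximum(D[i], D[j])
        D[i, :] = d_new
        D[:, i] = d_new
        D[i, i] = np.inf
        ids[i] = new_id
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        del ids[j]

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        la, lb = leaves(a), leaves(b)
        if (len(la), min(la)) <= (len(lb), min(lb)):
            return la + lb
        return lb + la

    return Dendrogram(linkage=Z, leaf_order=leaves(2 * n - 2))


def log2_fpkm(matrix: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """log2 transform with a pseudo-count for zeros.

    The default pseudo-count is half the smallest positive value in the
    matrix, applied additively to every cell.
    """
    values = matrix.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("FPKM values must be non-negative")
    if pseudocount is None:
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("matrix has no positive entries")
        pseudocount = positive.min() * 0.5
    return np.log2(matrix + pseudocount)


def cluster_de_genes(
    fpkm_matrix: pd.DataFrame, pseudocount: float | None = None
) -> dict[str, object]:
    """Cluster significant genes (rows) and samples (columns) on log2(FPKM).

    Returns row/column dendrograms and the matrix reordered by their
    deterministic leaf orders.
    """
    if fpkm_matrix.shape[0] < 2 or fpkm_matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    log_mat = log2_fpkm(fpkm_matrix, pseudocount)
    rows = complete_linkage(log_mat.to_numpy())
    cols = complete_linkage(log_mat.to_numpy().T)
    ordered = log_mat.iloc[rows.leaf_order, cols.leaf_order]
    return {"rows": rows, "columns": cols, "log2_matrix": log_mat, "ordered": ordered}


# ---------------------------------------------------------------------------
# probeset collapsing
# ---------------------------------------------------------------------------

def collapse_probesets(expression: pd.DataFrame, rule: str = "highest") -> pd.DataFrame:
    """One probeset per gene: the highest- or lowest-intensity one.

    Ties are broken by lexicographically smallest probeset_id, making the
    result deterministic.
    """
    if rule not in ("highest", "lowest"):
        raise ValueError("rule must be 'highest' or 'lowest'")
    missing = {"gene_id", "probeset_id", "intensity"} - set(expression.columns)
    if missing:
        raise ValueError(f"missing column(s) {sorted(missing)}")
    if (expression.intensity < 0).any():
        raise ValueError("intensities must be non-negative")
    ordered = expression.sort_values(
        ["intensity", "probeset_id"], ascending=[rule == "lowest", True]
    )
    out = ordered.groupby("gene_id", as_index=False).first()
    return out.sort_values("gene_id").reset_index(drop=True)
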