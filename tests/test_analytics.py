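"""Analytics tests: each operation is checked against an independent oracle
(brute-force agglomeration, set arithmetic, base tallies) or a closed form."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
import scipy.stats as sps

from drpseq.analytics import (
    class_composition,
    cluster_de_genes,
    collapse_probesets,
    complete_linkage,
    control_subtract,
    detection_overlap,
    ercc_analysis,
    floor_fpkm,
    gene_body_coverage,
    log2_fpkm,
    replicate_concordance,
    rrna_base_fraction,
    saturation,
)
from drpseq.preprocess import preprocess_reads
from drpseq.quantify import TranscriptIndex, compute_fpkm, counts_from_assignments, expressed_genes, toy_map
from drpseq.simulate import make_ercc_table


@pytest.fixture(scope="module")
def mapped_library(small_library):
    _, tx, abund, _, reads, _ = small_library
    collapsed, _ = preprocess_reads(reads)
    assign, _ = toy_map(((m.molecule_id, m.insert) for m in collapsed), tx)
    ann = tx.annotation()
    lengths = ann.set_index("gene_id").length_bp
    return tx, abund, assign, ann, lengths


class TestSaturation:
    def test_fraction_one_equals_full_expressed_count(self, mapped_library):
        tx, _, assign, ann, lengths = mapped_library
        fpkm = compute_fpkm(counts_from_assignments(assign, tx.gene_ids), lengths)
        sat = saturation(assign, lengths, [0.5, 1.0], seed=1)
        full = sat.loc[sat.fraction == 1.0, "genes_detected"].iloc[0]
        assert full == len(expressed_genes(fpkm))

    def test_same_seed_identical_curves(self, mapped_library):
        _, _, assign, _, lengths = mapped_library
        a = saturation(assign, lengths, [0.25, 0.5, 0.75], seed=9)
        b = saturation(assign, lengths, [0.25, 0.5, 0.75], seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_detected_genes_monotone_in_expectation(self, mapped_library):
        """Averaged over seeds, detection grows with the subsampled fraction."""
        _, _, assign, _, lengths = mapped_library
        curves = [
            saturation(assign, lengths, [0.1, 0.4, 0.7, 1.0], seed=s).genes_detected.to_numpy()
            for s in range(5)
        ]
        mean_curve = np.mean(curves, axis=0)
        assert np.all(np.diff(mean_curve) >= 0)

    def test_fraction_outside_unit_interval_rejected(self, mapped_library):
        _, _, assign, _, lengths = mapped_library
        with pytest.raises(ValueError, match="fraction"):
            saturation(assign, lengths, [1.5], seed=0)


class TestClassComposition:
    def test_single_biotype_is_hundred_percent(self):
        fpkm = pd.DataFrame({"s": [5.0, 2.0]}, index=["A", "B"])
        bt = pd.Series({"A": "rRNA", "B": "rRNA"})
        comp = class_composition(fpkm, bt)
        assert comp.loc["rRNA", "s"] == pytest.approx(100.0)

    def test_percentages_sum_to_hundred(self, mapped_library):
        tx, _, assign, ann, lengths = mapped_library
        fpkm = compute_fpkm(counts_from_assignments(assign, tx.gene_ids), lengths)
        comp = class_composition(fpkm.to_frame("s"), ann.set_index("gene_id").biotype)
        assert comp["s"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_override_moves_mass_conserving_total(self):
        fpkm = pd.DataFrame({"s": [5.0, 3.0]}, index=["X", "B"])
        bt = pd.Series({"X": "lincRNA", "B": "protein_coding"})
        plain = class_composition(fpkm, bt)
        moved = class_composition(fpkm, bt, biotype_overrides={"X": "rRNA"})
        assert "rRNA" not in plain.index
        assert moved.loc["rRNA", "s"] == pytest.approx(plain.loc["lincRNA", "s"])
        assert moved["s"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_missing_biotype_rejected_with_offenders(self):
        fpkm = pd.DataFrame({"s": [5.0, 3.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="B"):
            class_composition(fpkm, pd.Series({"A": "rRNA"}))

    def test_rrna_share_tracks_configured_mass_fraction(self, mapped_library):
        """Simulation oracle: the FPKM share of the rRNA classes approximates
        the truth-derived expectation (sum of mass/length over rRNA genes),
        which itself tracks the configured fraction of 0.4."""
        tx, abund, assign, ann, lengths = mapped_library
        fpkm = compute_fpkm(counts_from_assignments(assign, tx.gene_ids), lengths)
        comp = class_composition(fpkm.to_frame("s"), ann.set_index("gene_id").biotype,
                                 threshold=0.0)
        got = comp.reindex(["rRNA", "Mt_rRNA"]).fillna(0.0)["s"].sum()
        dens = abund / lengths.reindex(abund.index)
        is_r = ann.set_index("gene_id").is_rrna.astype(bool).reindex(dens.index)
        expected = 100.0 * dens[is_r].sum() / dens.sum()
        assert got == pytest.approx(expected, abs=5.0)
        assert abs(expected - 40.0) < 15.0  # gene-level sampling spread around 0.4


class TestRrnaBaseFraction:
    def test_all_reads_rrna_gives_one(self):
        assign = pd.DataFrame(
            {"gene_id": ["R1", "R2"], "weight": [1.0, 1.0], "insert_length": [100, 50]}
        )
        assert rrna_base_fraction(assign, {"R1", "R2"}) == 1.0

    def test_no_rrna_genes_gives_zero(self):
        assign = pd.DataFrame({"gene_id": ["A"], "weight": [1.0], "insert_length": [100]})
        assert rrna_base_fraction(assign, set()) == 0.0

    def test_matches_brute_force_base_tally(self, mapped_library):
        tx, _, assign, ann, _ = mapped_library
        rrna = set(ann.loc[ann.is_rrna == 1, "gene_id"])
        got = rrna_base_fraction(assign, rrna)
        num = den = 0.0
        for _, row in assign.iterrows():
            b = row.weight * row.insert_length
            den += b
            if row.gene_id in rrna:
                num += b
        assert got == pytest.approx(num / den, rel=1e-12)

    def test_zero_assigned_bases_rejected(self):
        with pytest.raises(ValueError):
            rrna_base_fraction(pd.DataFrame(columns=["gene_id", "weight", "insert_length"]), set())


class TestGeneBodyCoverage:
    def test_uniform_tiling_gives_flat_profile(self):
        lengths = pd.Series({"A": 1000})
        rows = [("r%d" % i, "A", 1.0, s, s + 100) for i, s in enumerate(range(0, 901, 10))]
        assign = pd.DataFrame(rows, columns=["read_id", "gene_id", "weight", "start", "end"])
        cov = gene_body_coverage(assign, lengths, n_bins=20)
        interior = cov[2:-2]
        assert np.all(np.abs(interior - 1.0) < 0.25)

    def test_five_prime_half_only_leaves_three_prime_empty(self):
        lengths = pd.Series({"A": 1000})
        assign = pd.DataFrame(
            [("r1", "A", 1.0, 0, 400), ("r2", "A", 1.0, 50, 450)],
            columns=["read_id", "gene_id", "weight", "start", "end"],
        )
        cov = gene_body_coverage(assign, lengths, n_bins=10)
        assert np.all(cov[5:] == 0)
        assert cov[:5].sum() > 0

    def test_terminal_bins_underrepresented_with_uniform_fragments(self, mapped_library):
        """Geometric edge effect: a fragment's start is uniform on
        [0, L-insert], so transcript ends accumulate less coverage than the
        interior."""
        tx, _, assign, ann, lengths = mapped_library
        fpkm_genes = set(tx.gene_ids)
        cov = gene_body_coverage(assign, lengths, genes=fpkm_genes, n_bins=100)
        interior = cov[20:80].mean()
        assert cov[0] < interior and cov[-1] < interior


class TestErccAnalysis:
    def test_floor_applied_below_threshold(self):
        table = make_ercc_table(n=4)
        fpkm = pd.Series(0.05, index=table.ercc_id)
        rows, _ = ercc_analysis(fpkm, table)
        assert np.all(rows.fpkm_floored == 0.1)

    def test_boundary_value_unchanged_and_idempotent(self):
        s = pd.Series([0.1, 0.05, 3.0])
        floored = floor_fpkm(s)
        assert list(floored) == [0.1, 0.1, 3.0]
        pd.testing.assert_series_equal(floor_fpkm(floored), floored)

    def test_too_few_positive_spikeins_rejected(self):
        table = make_ercc_table(n=2)
        with pytest.raises(ValueError, match="3"):
            ercc_analysis(pd.Series(1.0, index=table.ercc_id), table)

    def test_log_linear_relation_recovered(self):
        # noiseless fpkm proportional to copies -> perfect log-log correlation
        table = make_ercc_table(n=12)
        fpkm = pd.Series(table.copies.to_numpy() * 1e-2, index=table.ercc_id.to_numpy())
        _, r = ercc_analysis(fpkm, table)
        assert r == pytest.approx(1.0, abs=1e-12)


class TestReplicateConcordance:
    def test_identical_tables_give_unity(self, rng):
        fpkm = pd.Series(rng.lognormal(0, 1, 50), index=[f"G{i}" for i in range(50)])
        pearson, spearman = replicate_concordance(fpkm, fpkm.copy())
        assert pearson == pytest.approx(1.0)
        assert spearman == pytest.approx(1.0)

    def test_monotone_transform_preserves_spearman_only(self, rng):
        a = pd.Series(rng.lognormal(0, 1, 100), index=[f"G{i}" for i in range(100)])
        b = a**3  # monotone, non-linear
        pearson, spearman = replicate_concordance(a, b)
        assert spearman == pytest.approx(1.0)
        assert pearson < 1.0

    def test_union_filter_keeps_gene_passing_in_either_sample(self):
        a = pd.Series({"G1": 5.0, "G2": 0.0, "G3": 0.0, "G4": 2.0})
        b = pd.Series({"G1": 4.0, "G2": 0.01, "G3": 0.0, "G4": 1.0})
        # G2 passes in b only -> kept by the union rule; G3 fails in both
        pearson, _ = replicate_concordance(a, b, min_fpkm=0.001)
        a2, b2 = a.drop("G3"), b.drop("G3")
        assert pearson == pytest.approx(sps.pearsonr(a2, b2)[0])

    def test_constant_vector_reports_absent(self):
        a = pd.Series({"G1": 1.0, "G2": 1.0, "G3": 1.0})
        b = pd.Series({"G1": 1.0, "G2": 2.0, "G3": 3.0})
        assert replicate_concordance(a, b) == (None, None)

    def test_too_few_genes_rejected(self):
        a = pd.Series({"G1": 1.0, "G2": 0.0})
        with pytest.raises(ValueError):
            replicate_concordance(a, a)


class TestDetectionOverlap:
    def test_identical_sets_hundred_percent(self):
        s = {"a", "b", "c"}
        common, pct = detection_overlap({"r1": set(s), "r2": set(s)})
        assert common == s and all(v == 100.0 for v in pct.values())

    def test_disjoint_sets_zero_percent(self):
        common, pct = detection_overlap({"r1": {"a"}, "r2": {"b"}})
        assert common == set() and all(v == 0.0 for v in pct.values())

    def test_empty_replicate_percent_undefined(self):
        _, pct = detection_overlap({"r1": {"a"}, "r2": set()})
        assert pct["r2"] is None

    def test_matches_brute_force_set_arithmetic(self, rng):
        pool = [f"G{i}" for i in range(100)]
        sets = {
            f"r{j}": {g for g in pool if rng.random() < 0.6} for j in range(3)
        }
        common, pct = detection_overlap(sets)
        brute = sets["r0"] & sets["r1"] & sets["r2"]
        assert common == brute
        for rep, s in sets.items():
            assert pct[rep] == pytest.approx(100.0 * len(brute) / len(s))


class TestControlSubtract:
    @staticmethod
    def _table(side_a, side_b, q=0.01):
        rows = [(g, 1.0, q, "side_A") for g in side_a]
        rows += [(g, -1.0, q, "side_B") for g in side_b]
        return pd.DataFrame(rows, columns=["gene_id", "log2_fold_change", "q_value", "direction"])

    def test_empty_control_leaves_main_unchanged(self):
        main = self._table(["g1", "g2"], ["g3"])
        control = self._table([], [])
        out = control_subtract(main, control)
        assert sorted(out.gene_id) == ["g1", "g2", "g3"]

    def test_planted_545_468_arithmetic(self):
        """The compartment comparison retains 543 and 465 transcripts after
        subtracting 2 and 3 dilution-control artefacts from 545 and 468."""
        side_a = [f"a{i}" for i in range(545)]
        side_b = [f"b{i}" for i in range(468)]
        main = self._table(side_a, side_b)
        control = self._table(
            ["a1", "a2", "x9"], ["b1", "b2", "b3", "y7"]
        )  # extra control genes absent from main change nothing
        out = control_subtract(main, control)
        kept = out.groupby("direction").size()
        assert kept["side_A"] == 543
        assert kept["side_B"] == 465

    def test_direction_mismatch_not_subtracted(self):
        main = self._table(["g1"], [])
        control = self._table([], ["g1"])  # g1 significant in the other arm
        out = control_subtract(main, control)
        assert list(out.gene_id) == ["g1"]

    def test_alpha_zero_empties_output(self):
        main = self._table(["g1"], ["g2"])
        assert control_subtract(main, main, alpha=0.0).empty

    def test_output_subset_of_main_and_alpha_monotone(self, rng):
        genes = [f"g{i}" for i in range(200)]
        main = pd.DataFrame(
            {
                "gene_id": genes,
                "log2_fold_change": rng.normal(size=200),
                "q_value": rng.random(200),
                "direction": rng.choice(["side_A", "side_B"], 200),
            }
        )
        control = main.sample(frac=0.3, random_state=1).assign(q_value=lambda d: d.q_value / 2)
        prev: set = set()
        for alpha in (0.01, 0.05, 0.2, 0.5):
            out = control_subtract(main, control, alpha=alpha)
            sig_main = set(main.loc[main.q_value < alpha, "gene_id"])
            assert set(out.gene_id) <= sig_main
            assert prev <= set(out.gene_id)  # smaller alpha never enlarges
            prev = set(out.gene_id)


def brute_force_complete_linkage(X):
    """Exhaustive O(n^3) agglomeration oracle: recompute the complete-linkage
    distance between clusters from scratch at every step."""
    X = np.asarray(X, dtype=float)
    clusters = {i: [i] for i in range(len(X))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(
                np.linalg.norm(X[i] - X[j]) for i in clusters[a] for j in clusters[b]
            )
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return np.array(heights)


class TestClustering:
    def test_identical_rows_merge_first_at_height_zero(self, rng):
        X = rng.normal(size=(5, 4))
        X[3] = X[1]
        dg = complete_linkage(X)
        assert dg.linkage[0, 2] == pytest.approx(0.0)
        assert sorted(dg.linkage[0, :2]) == [1, 3]

    @pytest.mark.parametrize("n,m,seed", [(4, 3, 0), (6, 2, 1), (8, 5, 2), (8, 3, 3), (5, 4, 4)])
    def test_heights_match_exhaustive_oracle(self, n, m, seed):
        X = np.random.default_rng(seed).normal(size=(n, m))
        dg = complete_linkage(X)
        np.testing.assert_allclose(dg.linkage[:, 2], brute_force_complete_linkage(X), rtol=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_heights_match_scipy_linkage(self, seed):
        X = np.random.default_rng(100 + seed).normal(size=(12, 6))
        dg = complete_linkage(X)
        Z = sch.linkage(X, method="complete", metric="euclidean")
        np.testing.assert_allclose(np.sort(dg.linkage[:, 2]), np.sort(Z[:, 2]), rtol=1e-9)

    def test_planted_partition_splits_columns_at_top(self, rng):
        """Samples from two simulated compartments separate at the root of
        the column dendrogram."""
        n_genes = 40
        base = rng.lognormal(2, 1, n_genes)
        cols = {}
        for i in range(3):
            cols[f"somato_{i}"] = base * rng.lognormal(0, 0.1, n_genes)
        shifted = base.copy()
        shifted[:20] *= 50  # compartment-enriched genes
        for i in range(3):
            cols[f"axon_{i}"] = shifted * rng.lognormal(0, 0.1, n_genes)
        mat = pd.DataFrame(cols)
        result = cluster_de_genes(mat)
        order = [mat.columns[i] for i in result["columns"].leaf_order]
        groups = ["".join(sorted(c.split("_")[0][0] for c in order[:3])),
                  "".join(sorted(c.split("_")[0][0] for c in order[3:]))]
        assert sorted(groups) == ["aaa", "sss"]

    def test_leaf_order_deterministic_under_ties(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        a = complete_linkage(X)
        b = complete_linkage(X.copy())
        assert a.leaf_order == b.leaf_order
        assert a.leaf_order[:2] == [0, 1]  # smallest-leaf subtree first

    def test_non_finite_input_rejected(self):
        mat = pd.DataFrame({"s1": [1.0, np.nan], "s2": [2.0, 3.0]})
        with pytest.raises(ValueError, match="finite|negative"):
            cluster_de_genes(mat)

    def test_log_transform_uses_half_minimum_pseudocount(self):
        mat = pd.DataFrame({"s1": [0.0, 4.0], "s2": [2.0, 8.0]})
        logm = log2_fpkm(mat)
        assert logm.iloc[0, 0] == pytest.approx(np.log2(0.0 + 1.0))  # min positive 2.0 -> 1.0
        assert logm.iloc[1, 1] == pytest.approx(np.log2(9.0))


class TestCollapseProbesets:
    def test_single_probeset_identity_under_both_rules(self):
        df = pd.DataFrame(
            {"gene_id": ["g1"], "probeset_id": ["p1"], "intensity": [4.0]}
        )
        for rule in ("highest", "lowest"):
            out = collapse_probesets(df, rule)
            assert out.iloc[0].probeset_id == "p1"

    def test_highest_and_lowest_rules(self):
        df = pd.DataFrame(
            {
                "gene_id": ["g1", "g1"],
                "probeset_id": ["p1", "p2"],
                "intensity": [3.0, 7.0],
            }
        )
        assert collapse_probesets(df, "highest").iloc[0].intensity == 7.0
        assert collapse_probesets(df, "lowest").iloc[0].intensity == 3.0

    def test_tie_broken_by_probeset_id(self):
        df = pd.DataFrame(
            {
                "gene_id": ["g1", "g1"],
                "probeset_id": ["pB", "pA"],
                "intensity": [5.0, 5.0],
            }
        )
        assert collapse_probesets(df, "highest").iloc[0].probeset_id == "pA"

    def test_matches_groupby_brute_force(self, rng):
        df = pd.DataFrame(
            {
                "gene_id": rng.choice([f"g{i}" for i in range(30)], 200),
                "probeset_id": [f"p{i}" for i in range(200)],
                "intensity": np.round(rng.random(200) * 10, 1),
            }
        )
        out = collapse_probesets(df, "highest")
        for gene, grp in df.groupby("gene_id"):
            best = grp.intensity.max()
            expect = grp[grp.intensity == best].probeset_id.min()
            assert out.loc[out.gene_id == gene, "probeset_id"].iloc[0] == expect

    def test_negative_intensity_rejected(self):
        df = pd.DataFrame({"gene_id": ["g"], "probeset_id": ["p"], "intensity": [-1.0]})
        with pytest.raises(ValueError):
            collapse_probesets(df)
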