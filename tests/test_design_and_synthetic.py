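"""Study design and synthetic-data generators: planted structure is real."""

import numpy as np
import pandas as pd
import pytest

from shellnet.containers import PlantedTruth
from shellnet.design import make_design
from shellnet.synthetic import (TABLE2_ROWS, make_cerna_truth, revcomp,
                                simulate_cerna_expression, simulate_counts,
                                simulate_genome_and_reads, table2_fixture,
                                table2_truth)
from shellnet.stats import spearman


class TestMakeDesign:
    def test_default_design_names(self):
        d = make_design((3, 3, 4, 3))
        assert d.n_samples == 13
        assert d.samples_by_group["DB"] == ("DB1", "DB2", "DB3")
        assert d.samples_by_group["DP"] == ("DP1", "DP2", "DP3", "DP4")
        assert d.samples[-1] == "PK3"
        assert len(set(d.samples)) == 13

    def test_two_replicates_everywhere(self):
        assert make_design((2, 2, 2, 2)).n_samples == 8

    @pytest.mark.parametrize("reps", [(0, 3, 3, 3), (3, 1, 3, 3), (3, 3, 3)])
    def test_invalid_designs_rejected(self, reps):
        with pytest.raises(ValueError):
            make_design(reps)


class TestSimulateCounts:
    def test_planted_fold_change_recovered_in_group_means(self, design):
        """Group-mean ratio over 1000 planted features ~ 2^3 = 8."""
        truth = PlantedTruth(de_features={
            f"f{i:04d}": ("DB_vs_PK", 3.0) for i in range(1000)})
        cm = simulate_counts(design, truth, n_null=0, baseline_mean=100.0,
                             dispersion=0.1, seed=5)
        db = cm.group_columns("DB").to_numpy().mean()
        pk = cm.group_columns("PK").to_numpy().mean()
        assert db / pk == pytest.approx(8.0, rel=0.1)

    def test_near_poisson_limit_variance_matches_mean(self, design):
        truth = PlantedTruth()
        cm = simulate_counts(design, truth, n_null=2000, baseline_mean=100.0,
                             dispersion=1e-9, seed=6)
        arr = cm.counts.to_numpy(dtype=float)
        # pooled across features: Var ~ mean under Poisson
        assert arr.var(axis=1).mean() == pytest.approx(arr.mean(), rel=0.1)

    def test_same_seed_identical(self, design):
        truth = PlantedTruth(de_features={"a": ("DB_vs_PK", 2.0)})
        one = simulate_counts(design, truth, seed=3).counts
        two = simulate_counts(design, truth, seed=3).counts
        pd.testing.assert_frame_equal(one, two)

    def test_unknown_feature_in_truth_rejected(self, design):
        truth = PlantedTruth(de_features={"ghost": ("DB_vs_PK", 2.0)})
        with pytest.raises(ValueError, match="unknown features"):
            simulate_counts(design, truth, features=["real1", "real2"])

    def test_null_log2fc_centred_on_zero(self, design):
        """Empirical mean null log2FC within 3 SE of 0 over 1000 features."""
        cm = simulate_counts(design, PlantedTruth(), n_null=1000,
                             baseline_mean=200.0, dispersion=0.1, seed=9)
        db = cm.group_columns("DB").to_numpy().mean(axis=1)
        pk = cm.group_columns("PK").to_numpy().mean(axis=1)
        lfc = np.log2((db + 1) / (pk + 1))
        se = lfc.std(ddof=1) / np.sqrt(len(lfc))
        assert abs(lfc.mean()) < 3 * se + 1e-3


class TestCernaExpression:
    def test_perfect_coupling_gives_exact_correlations(self, design):
        truth = make_cerna_truth(n_triples=5, n_decoys=0, seed=0)
        expr = simulate_cerna_expression(design, truth, coupling=1.0,
                                         noise_sd=0.0, seed=2)
        for circ, mir, mrna in truth.cerna_triples:
            x = expr["mirna"].counts.loc[mir].to_numpy(float)
            yc = expr["circ"].counts.loc[circ].to_numpy(float)
            ym = expr["mrna"].counts.loc[mrna].to_numpy(float)
            assert spearman(x, ym) == pytest.approx(-1.0)
            assert spearman(x, yc) == pytest.approx(-1.0)
            assert spearman(yc, ym) == pytest.approx(1.0)

    def test_decoy_pairs_uncorrelated_on_average(self, design):
        truth = make_cerna_truth(n_triples=1, n_decoys=300, seed=1)
        expr = simulate_cerna_expression(design, truth, seed=4)
        circ = expr["circ"].counts
        mrna = expr["mrna"].counts
        rhos = []
        decoy_c = [f for f in circ.index if "_D" in f]
        decoy_m = [f for f in mrna.index if "_D" in f]
        for i, c in enumerate(decoy_c):
            m = decoy_m[i % len(decoy_m)]
            rhos.append(spearman(circ.loc[c].to_numpy(float),
                                 mrna.loc[m].to_numpy(float)))
        assert abs(np.mean(rhos)) < 0.1

    @pytest.mark.parametrize("coupling", [0.0, 1.5, -0.2])
    def test_coupling_out_of_range(self, design, coupling):
        truth = make_cerna_truth(n_triples=2, n_decoys=0)
        with pytest.raises(ValueError):
            simulate_cerna_expression(design, truth, coupling=coupling)

    def test_triple_mirna_must_target_both_partners(self):
        with pytest.raises(ValueError, match="target both"):
            PlantedTruth(target_edges={"miR-1": {"circ_1"}},
                         cerna_triples=[("circ_1", "miR-1", "gene_1")])


class TestGenomeAndReads:
    def test_each_junction_has_planted_depth_distinct_reads(self, small_genome_run):
        genome, reads, truth = small_genome_run
        per_junction = {}
        for r in reads.reads:
            if r.read_id.startswith("bsj_"):
                per_junction.setdefault(r.read_id.rsplit("_", 1)[0], set()).add(
                    r.sequence)
        assert len(per_junction) == len(truth.junctions)
        assert all(len(seqs) >= 3 for seqs in per_junction.values())

    def test_planted_flanks_by_direct_string_lookup(self, small_genome_run):
        genome, _, truth = small_genome_run
        for chrom, start, end, strand in truth.junctions:
            seq = genome.sequences[chrom]
            if strand == "+":
                assert seq[start - 2:start] == "AG"
                assert seq[end:end + 2] == "GT"
            else:
                assert seq[start - 2:start] == "AC"
                assert seq[end:end + 2] == "CT"

    def test_no_circles_means_only_linear_reads(self):
        _, reads, truth = simulate_genome_and_reads(
            n_genes=5, n_circ=0, n_linear=50, seed=3)
        assert truth.junctions == []
        assert all(r.read_id.startswith("lin_") for r in reads.reads)

    def test_short_reads_rejected(self):
        with pytest.raises(ValueError, match="read_length"):
            simulate_genome_and_reads(read_length=39)

    def test_deterministic_under_seed(self):
        g1, r1, t1 = simulate_genome_and_reads(n_genes=5, n_circ=3,
                                               n_linear=20, seed=8)
        g2, r2, t2 = simulate_genome_and_reads(n_genes=5, n_circ=3,
                                               n_linear=20, seed=8)
        assert g1.sequences == g2.sequences
        assert t1.junctions == t2.junctions
        assert [r.sequence for r in r1.reads] == [r.sequence for r in r2.reads]


class TestTable2Fixture:
    def test_planted_rows_match_printed_values(self):
        _, expected = table2_fixture(seed=0)
        row = expected[(expected.feature == "miR-423-y")
                       & (expected.comparison == "DB_vs_PK")]
        assert row.iloc[0]["log2fc"] == -6.51
        assert row.iloc[0]["expected"] == "down"
        row = expected[(expected.feature == "miR-224-x")
                       & (expected.comparison == "LB_vs_PK")]
        assert row.iloc[0]["log2fc"] == 8.72
        assert row.iloc[0]["expected"] == "up"

    def test_recurring_mirnas_satisfy_every_printed_row(self, design):
        """Empirical group-mean log2 ratios track every printed contrast.

        Several miRNAs are printed in more than one comparison, so their
        group means must honour all their rows at once. Single rows
        fluctuate (the log2 ratio of two 3-replicate NB means at phi=0.1
        has sd ~0.6), so the check is aggregate: observed fold changes are
        unbiased and tightly correlated with the planted ones.
        """
        cm, _ = table2_fixture(seed=1)
        g = {grp: cm.group_columns(grp).to_numpy(float).mean(axis=1)
             for grp in design.groups}
        feats = list(cm.features)
        planted, observed = [], []
        for comparison, mirna, lfc, _d in TABLE2_ROWS:
            a, b = comparison.split("_vs_")
            i = feats.index(mirna)
            if g[a][i] > 20 and g[b][i] > 20:  # above the counting floor
                planted.append(lfc)
                observed.append(np.log2(g[a][i] / g[b][i]))
        assert len(planted) >= 10
        resid = np.array(observed) - np.array(planted)
        assert abs(resid.mean()) < 0.5
        assert np.corrcoef(planted, observed)[0, 1] > 0.95

    def test_offset_solver_consistency(self):
        """All 24 printed rows are simultaneously representable: solving the
        chain of contrasts row by row reproduces each printed difference."""
        offsets: dict[str, dict[str, float]] = {}
        for comparison, mirna, lfc, _d in TABLE2_ROWS:
            a, b = comparison.split("_vs_")
            offs = offsets.setdefault(mirna, {"PK": 0.0})
            if a in offs and b in offs:
                assert offs[a] - offs[b] == pytest.approx(lfc)
            elif a in offs:
                offs[b] = offs[a] - lfc
            else:
                offs[a] = offs.get(b, 0.0) + lfc
        for comparison, mirna, lfc, _d in TABLE2_ROWS:
            a, b = comparison.split("_vs_")
            offs = offsets[mirna]
            # a group never pinned by any row sits at the baseline (offset 0)
            assert offs.get(a, 0.0) - offs.get(b, 0.0) == pytest.approx(lfc)

    def test_nulls_expected_ns(self):
        _, expected = table2_fixture(seed=0)
        nulls = expected[expected.feature.str.startswith("null_")]
        assert (nulls["expected"] == "ns").all()
        assert expected.feature.str.startswith("null_").sum() >= 200 * 4

    def test_truth_is_consistent(self):
        # the offset solver accepts the full printed table without conflict
        truth = table2_truth()
        assert len(truth.de_features) == 18


def test_revcomp_involution(rng):
    for _ in range(20):
        s = "".join(rng.choice(list("ACGT"), size=30))
        assert revcomp(revcomp(s)) == s
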