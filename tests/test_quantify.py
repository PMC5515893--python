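"""Detection filter, RPKM arithmetic, Eff definition and sample clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tests.conftest import make_expression
from translatome.errors import PairingError, WrongUnitError
from translatome.quantify import (
    filter_detected,
    hierarchical_cluster,
    rpkm,
    sample_correlation,
    translational_efficiency,
)
from translatome.simulate import (
    SimConfig,
    generate_annotation,
    generate_truth,
    simulate_counts,
)


def two_sample_counts(rpf, rna, genes=None):
    genes = genes or [f"g{i}" for i in range(len(rpf))]
    return make_expression(
        pd.DataFrame({"RPF_A_rep1": rpf, "RNA_A_rep1": rna}, index=genes)
    )


class TestFilterDetected:
    def test_toy_enumeration(self):
        es = two_sample_counts([12, 9, 50, 0, 10], [15, 50, 9, 0, 10])
        assert filter_detected(es) == ["g0", "g4"]

    def test_failing_one_assay_excludes(self):
        es = two_sample_counts([9], [100])
        assert filter_detected(es) == []

    def test_boundary_inclusive(self):
        es = two_sample_counts([10], [10])
        assert filter_detected(es) == ["g0"]

    def test_rpkm_input_rejected(self, small_rpkm):
        with pytest.raises(WrongUnitError):
            filter_detected(small_rpkm)

    def test_pooled_over_replicates_within_condition(self):
        frame = pd.DataFrame(
            {"RPF_A_rep1": [6], "RPF_A_rep2": [6], "RNA_A_rep1": [5], "RNA_A_rep2": [5]},
            index=["g0"],
        )
        assert filter_detected(make_expression(frame)) == ["g0"]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 40), st.integers(0, 40)), min_size=1, max_size=12
        ),
        lo=st.integers(0, 20),
        hi=st.integers(0, 20),
    )
    def test_monotone_in_threshold(self, counts, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        es = two_sample_counts([c[0] for c in counts], [c[1] for c in counts])
        assert set(filter_detected(es, min_reads=hi)) <= set(filter_detected(es, min_reads=lo))


class TestRpkm:
    def test_closed_form(self):
        # one gene carries the remainder so the column total is exactly 1e6
        es = two_sample_counts([10, 999_990, 0], [10, 999_990, 0])
        out = rpkm(es, {"g0": 500, "g1": 1000, "g2": 300})
        assert out.data.loc["g0", "RPF_A_rep1"] == pytest.approx(20.0)
        assert out.data.loc["g2", "RPF_A_rep1"] == 0.0
        assert out.unit == "RPKM"

    def test_column_scale_invariance(self, small_dataset):
        _, genes, _, counts = small_dataset
        doubled = counts.data.copy()
        doubled["RPF_BAT_rep1"] *= 2
        a = rpkm(counts, genes).data["RPF_BAT_rep1"]
        b = rpkm(make_expression(doubled), genes).data["RPF_BAT_rep1"]
        pd.testing.assert_series_equal(a, b)

    def test_zero_column_total_rejected(self):
        from translatome.errors import DegenerateSampleError

        es = two_sample_counts([0, 0], [5, 5])
        with pytest.raises(DegenerateSampleError):
            rpkm(es, {"g0": 300, "g1": 300})


class TestTranslationalEfficiency:
    def test_closed_forms(self, small_rpkm):
        rpf = small_rpkm.for_assay("RPF")
        rna = small_rpkm.for_assay("RNA")
        eff = translational_efficiency(rpf, rna)
        # spot-check one entry against the elementwise definition
        gid = rpf.data.index[0]
        got = eff.data.loc[gid, "BAT_D0_rep1"]
        expected = rpf.data.loc[gid, "RPF_BAT_D0_rep1"] / rna.data.loc[gid, "RNA_BAT_D0_rep1"]
        assert got == pytest.approx(expected)

    def test_equal_inputs_give_unity(self):
        frame = pd.DataFrame({"RPF_A_rep1": [7.3], "RNA_A_rep1": [7.3]}, index=["g0"])
        es = make_expression(frame, unit="RPKM")
        eff = translational_efficiency(es.for_assay("RPF"), es.for_assay("RNA"))
        assert eff.data.loc["g0", "A_rep1"] == pytest.approx(1.0)

    def test_zero_rna_is_nan_not_inf(self):
        frame = pd.DataFrame({"RPF_A_rep1": [20.0, 4.0], "RNA_A_rep1": [5.0, 0.0]},
                             index=["g0", "g1"])
        es = make_expression(frame, unit="RPKM")
        eff = translational_efficiency(es.for_assay("RPF"), es.for_assay("RNA"))
        assert eff.data.loc["g0", "A_rep1"] == pytest.approx(4.0)
        assert np.isnan(eff.data.loc["g1", "A_rep1"])

    def test_mismatched_pairing_rejected(self):
        rpf = make_expression(pd.DataFrame({"RPF_A_rep1": [1.0]}, index=["g0"]), unit="RPKM")
        rna = make_expression(pd.DataFrame({"RNA_B_rep1": [1.0]}, index=["g0"]), unit="RPKM")
        with pytest.raises(PairingError):
            translational_efficiency(rpf, rna)

    def test_recovers_relative_baseline_eff(self):
        # depth normalization makes Eff identifiable only up to a per-sample
        # constant, so the recoverable quantity is the *ratio* of planted
        # baseline efficiencies between gene groups (here 4x)
        cfg = SimConfig(
            n_genes=500,
            conditions=("A", "B"),
            contrasts={"c": ("A", "B")},
            class_fractions={"c": {}},
            n_families=0, targets_per_family=0,
            baseline_eff_sigma=0.0,
            nb_dispersion=0.05, seed=11,
        )
        genes = generate_annotation(cfg)
        truth = generate_truth(genes, cfg)
        truth.baseline_eff[:250] = 1.0
        truth.baseline_eff[250:] = 4.0
        counts = simulate_counts(truth, genes, cfg)
        rp = rpkm(counts, genes)
        eff = translational_efficiency(rp.for_assay("RPF"), rp.for_assay("RNA"))
        col = eff.data["A_rep1"]
        ratio = float(np.nanmedian(col.iloc[250:]) / np.nanmedian(col.iloc[:250]))
        assert 3.6 < ratio < 4.4

    def test_log2_identity_where_defined(self, small_rpkm):
        rpf, rna = small_rpkm.for_assay("RPF"), small_rpkm.for_assay("RNA")
        eff = translational_efficiency(rpf, rna)
        col = "BAT_D5_rep2"
        mask = (rna.data[f"RNA_{col.rsplit('_rep')[0]}_rep2"] > 0) & (rpf.data[f"RPF_BAT_D5_rep2"] > 0)
        lhs = np.log2(eff.data.loc[mask, col])
        rhs = np.log2(rpf.data.loc[mask, "RPF_BAT_D5_rep2"]) - np.log2(
            rna.data.loc[mask, "RNA_BAT_D5_rep2"]
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestSampleCorrelation:
    def test_duplicate_columns_correlate_perfectly(self):
        frame = pd.DataFrame({"RPF_A_rep1": [1, 5, 9], "RPF_A_rep2": [1, 5, 9],
                              "RNA_A_rep1": [2, 3, 4], "RNA_A_rep2": [2, 3, 4]})
        corr = sample_correlation(make_expression(frame))
        assert corr.loc["RPF_A_rep1", "RPF_A_rep2"] == pytest.approx(1.0)

    def test_hand_computed_anticorrelation(self):
        # log2(x+1) gives (1,2,3) vs (3,2,1): exactly -1
        frame = pd.DataFrame({"RNA_A_rep1": [1, 3, 7], "RNA_A_rep2": [7, 3, 1],
                              "RPF_A_rep1": [1, 3, 7], "RPF_A_rep2": [7, 3, 1]})
        corr = sample_correlation(make_expression(frame))
        assert corr.loc["RNA_A_rep1", "RNA_A_rep2"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal(self, small_dataset):
        *_, counts = small_dataset
        corr = sample_correlation(counts)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_constant_column_flagged_nan(self):
        frame = pd.DataFrame({"RNA_A_rep1": [5, 5, 5], "RNA_A_rep2": [1, 2, 3],
                              "RPF_A_rep1": [5, 5, 5], "RPF_A_rep2": [1, 2, 3]})
        corr = sample_correlation(make_expression(frame))
        assert np.isnan(corr.loc["RNA_A_rep1", "RNA_A_rep2"])


class TestHierarchicalCluster:
    def brown_corr(self, seed=13):
        cfg = SimConfig(
            n_genes=600,
            conditions=("BAT_D0", "BAT_D5"),
            contrasts={"brown": ("BAT_D0", "BAT_D5")},
            n_families=0, targets_per_family=0, seed=seed,
        )
        genes = generate_annotation(cfg)
        counts = simulate_counts(generate_truth(genes, cfg), genes, cfg)
        return sample_correlation(counts)

    def test_two_samples_single_merge(self):
        corr = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]],
                            index=["a", "b"], columns=["a", "b"])
        tree = hierarchical_cluster(corr)
        assert len(tree.merges) == 1
        assert tree.merges[0][2] == pytest.approx(0.6)

    def test_first_bipartition_separates_conditions(self):
        corr = self.brown_corr()
        clusters = hierarchical_cluster(corr).cut(2)
        groups = {}
        for label, cid in clusters.items():
            cond = label.split("_rep")[0].split("_", 1)[1]
            groups.setdefault(cid, set()).add(cond)
        assert {frozenset(s) for s in groups.values()} == {
            frozenset({"BAT_D0"}), frozenset({"BAT_D5"})
        }

    def test_invariant_to_column_permutation(self):
        corr = self.brown_corr()
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(corr.columns))
        a = hierarchical_cluster(corr)
        b = hierarchical_cluster(corr.loc[perm, perm])
        assert a.labels == b.labels
        np.testing.assert_allclose(a.linkage, b.linkage)

    def test_single_sample_trivial_tree(self):
        corr = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        assert hierarchical_cluster(corr).merges == []
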