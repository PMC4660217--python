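import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mmra import downstream as ds
from mmra.types import ExpressionMatrix


def _mirna_matrix(rng, n_mirnas=30, n_samples=24):
    vals = rng.normal(5, 1, size=(n_mirnas, n_samples))
    return ExpressionMatrix(pd.DataFrame(
        vals, index=[f"M{i}" for i in range(n_mirnas)],
        columns=[f"S{i}" for i in range(n_samples)]))


def _labels(n_samples, n_subtypes):
    return {f"S{i}": f"T{i % n_subtypes}" for i in range(n_samples)}


class TestNullModelFcThreshold:
    def test_full_set_equals_percentile_of_all_fcs(self, rng):
        mirna = _mirna_matrix(rng)
        labels = _labels(24, 3)
        thr = ds.nullmodel_fc_threshold(mirna, labels, "T0",
                                        set_size=30, n_random=50,
                                        percentile=90, seed=0)
        in_s = np.array([labels[s] == "T0" for s in mirna.sample_ids])
        vals = mirna.values.to_numpy()
        diffs = np.abs(vals[:, in_s].mean(axis=1) - vals[:, ~in_s].mean(axis=1))
        assert thr == pytest.approx(np.percentile(2.0 ** diffs, 90))

    def test_reproducible_across_equal_seeds(self, rng):
        mirna = _mirna_matrix(rng)
        labels = _labels(24, 3)
        a = ds.nullmodel_fc_threshold(mirna, labels, "T1", 5, 200, 90, seed=7)
        b = ds.nullmodel_fc_threshold(mirna, labels, "T1", 5, 200, 90, seed=7)
        c = ds.nullmodel_fc_threshold(mirna, labels, "T1", 5, 200, 90, seed=8)
        assert a == b
        assert c == pytest.approx(a, rel=0.1)    # Monte-Carlo jitter only

    def test_degenerate_subtype_rejected(self, rng):
        mirna = _mirna_matrix(rng)
        with pytest.raises(ValueError):
            ds.nullmodel_fc_threshold(mirna, _labels(24, 3), "NOPE", 5)


class TestCorrelationFraction:
    def test_perfect_anticorrelation_counted(self, rng):
        labels = _labels(30, 5)
        mir = np.array([float(labels[f"S{i}"][1]) for i in range(30)]) + \
            rng.normal(0, 0.01, 30)
        sig = pd.DataFrame(-mir[None, :].repeat(3, axis=0),
                           index=["G0", "G1", "G2"],
                           columns=[f"S{i}" for i in range(30)])
        frac = ds.correlation_fraction(sig, mir, labels, r_threshold=0.9)
        assert frac == 1.0

    def test_constant_gene_excluded(self, rng):
        labels = _labels(30, 5)
        mir = rng.normal(5, 1, size=30)
        sig = pd.DataFrame(np.vstack([np.full(30, 3.0), -mir]),
                           index=["GCONST", "GANTI"],
                           columns=[f"S{i}" for i in range(30)])
        frac = ds.correlation_fraction(sig, mir, labels, r_threshold=0.9)
        assert frac == 1.0                       # denominator excludes GCONST

    def test_three_subtypes_rejected(self, rng):
        labels = _labels(30, 3)
        sig = pd.DataFrame(rng.normal(size=(2, 30)), index=["G0", "G1"],
                           columns=[f"S{i}" for i in range(30)])
        with pytest.raises(ValueError, match=">= 4 subtypes"):
            ds.correlation_fraction(sig, rng.normal(size=30), labels, 0.9)

    def test_matches_hand_computation(self, rng):
        # 10 genes, 6 subtypes: count genes with |spearman r| > thr directly
        labels = _labels(36, 6)
        mir = rng.normal(5, 1, size=36)
        sig_vals = rng.normal(5, 1, size=(10, 36))
        sig = pd.DataFrame(sig_vals, index=[f"G{i}" for i in range(10)],
                           columns=[f"S{i}" for i in range(36)])
        frac = ds.correlation_fraction(sig, mir, labels, r_threshold=0.6)
        groups = [[i for i in range(36) if labels[f"S{i}"] == f"T{t}"]
                  for t in range(6)]
        mir_means = [mir[g].mean() for g in groups]
        n_hit = 0
        for row in sig_vals:
            gene_means = [row[g].mean() for g in groups]
            r, _ = stats.spearmanr(gene_means, mir_means)
            n_hit += abs(r) > 0.6
        assert frac == pytest.approx(n_hit / 10)


def _silencing_frames(rng, n_genes=50):
    genes = [f"G{i}" for i in range(n_genes)]
    scr = pd.DataFrame(rng.normal(5, 0.1, size=(n_genes, 2)), index=genes)
    trans = pd.DataFrame(rng.normal(5, 0.1, size=(n_genes, 2)), index=genes)
    wt = pd.DataFrame(rng.normal(5, 0.1, size=(n_genes, 2)), index=genes)
    trans.loc["G0"] += 1.0    # clean 2x up on silencing
    trans.loc["G1"] -= 1.0    # clean down
    trans.loc["G2"] += 1.0    # shifted in transduced AND wild-type: artifact
    wt.loc["G2"] += 1.0
    return trans, scr, wt


class TestSilencingDe:
    def test_planted_genes_and_artifact_filter(self, rng):
        trans, scr, wt = _silencing_frames(rng)
        up, down = ds.silencing_de(trans, scr, wt)
        assert "G0" in up and "G1" in down
        assert "G2" not in up and "G2" not in down

    def test_replicate_order_irrelevant(self, rng):
        trans, scr, wt = _silencing_frames(rng)
        up, down = ds.silencing_de(trans, scr, wt)
        up2, down2 = ds.silencing_de(trans.iloc[:, ::-1], scr.iloc[:, ::-1],
                                     wt.iloc[:, ::-1])
        assert up == up2 and down == down2

    def test_single_replicate_rejected(self, rng):
        trans, scr, wt = _silencing_frames(rng)
        with pytest.raises(ValueError, match="replicates"):
            ds.silencing_de(trans.iloc[:, :1], scr, wt)


class TestSignatureShiftTest:
    def test_up_genes_from_signature_strongly_enriched(self):
        universe = [f"G{i}" for i in range(1000)]
        ssm_up = set(universe[:100])
        ssm_down = set(universe[100:180])
        report = ds.signature_shift_test(universe[:30], universe[500:520],
                                         ssm_up, ssm_down, universe)
        assert report["up_in_ssm_up"]["fold"] > 5
        assert report["up_in_ssm_up"]["p"] < 1e-10
        assert not report["down_in_ssm_down"]["significant"]

    def test_matches_exact_enumeration(self):
        from tests.test_enrich import brute_force_hypergeom_tail
        universe = [f"G{i}" for i in range(40)]
        up = universe[:8]
        ssm_up = set(universe[4:14])
        report = ds.signature_shift_test(up, [], ssm_up, set(), universe)
        k = report["up_in_ssm_up"]["k"]
        assert report["up_in_ssm_up"]["p"] == pytest.approx(
            brute_force_hypergeom_tail(40, 10, 8, k), rel=1e-9)


class TestCoreTargets:
    def test_anticorrelated_gene_gets_degree_three(self, rng):
        n = 300
        mir_ids = ["M1", "M2", "M3", "M4"]
        mirs = rng.normal(5, 1, size=(4, n))
        gene = 10 - 0.6 * mirs[0] - 0.5 * mirs[1] - 0.7 * mirs[2] \
            + rng.normal(0, 0.3, size=n)
        pos_gene = 2 + 0.9 * mirs[0] + rng.normal(0, 0.3, size=n)
        samples = [f"S{i}" for i in range(n)]
        mrna = ExpressionMatrix(pd.DataFrame(
            np.vstack([gene, pos_gene]), index=["GCORE", "GPOS"], columns=samples))
        mirna = ExpressionMatrix(pd.DataFrame(mirs, index=mir_ids, columns=samples))
        up_lists = {"M1": {"GCORE", "GPOS"}, "M2": set(), "M3": {"GCORE"},
                    "M4": set()}
        out = ds.identify_core_targets(up_lists, mrna, mirna, mir_ids)
        by_gene = {t.gene: t for t in out}
        assert set(by_gene["GCORE"].micrornas) == {"M1", "M2", "M3"}
        assert "GPOS" not in by_gene            # positive coefficient only

    def test_network_edge_styles(self, rng):
        ct = ds.CoreTarget("G1", ["M1", "M2"], in_vitro_upregulated_by=["M1"])
        g = ds.core_target_network([ct])
        assert g.edges["M1", "G1"]["style"] == "solid"
        assert g.edges["M2", "G1"]["style"] == "dashed"

    def test_no_validated_mirna_rejected(self, rng):
        mirna = _mirna_matrix(rng)
        mrna = _mirna_matrix(rng)
        with pytest.raises(ValueError):
            ds.identify_core_targets({}, mrna, mirna, ["NOPE"])
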