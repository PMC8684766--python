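"""M-value transform, probe differential methylation, gene summaries, profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from integratome.diffmeth import (
    beta_to_m,
    context_profile,
    m_to_beta,
    probe_differential,
    summarize_gene_methylation,
)
from integratome.io import BetaMatrix, IntervalSet, ProbeAnnotation

from conftest import make_sheet


class TestBetaToM:
    @pytest.mark.parametrize(
        "beta,expected", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)]
    )
    def test_reference_points(self, beta, expected):
        assert beta_to_m(beta) == pytest.approx(expected)

    def test_clipping_at_zero(self):
        eps = 1e-6
        assert beta_to_m(0.0, eps) == pytest.approx(np.log2(eps / (1 - eps)))

    def test_epsilon_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_to_m(0.5, epsilon=0.7)

    @given(
        st.floats(min_value=1e-6, max_value=1 - 1e-6),
        st.floats(min_value=1e-6, max_value=1 - 1e-6),
    )
    def test_strictly_monotone(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert beta_to_m(lo) < beta_to_m(hi)

    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    def test_logistic_inverse_round_trip(self, beta):
        assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, rel=1e-9)


def _beta_matrix(vals, sheet):
    return BetaMatrix(
        pd.DataFrame(
            vals,
            index=[f"cg{i}" for i in range(len(vals))],
            columns=sheet.sample_ids,
        )
    )


class TestProbeDifferential:
    def test_identical_groups_null(self):
        sheet = make_sheet(3, 3)
        vals = np.tile([0.2, 0.5, 0.8], (4, 2))
        res = probe_differential(_beta_matrix(vals, sheet), sheet, "SAT")
        np.testing.assert_allclose(res["delta_beta"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_constant_probe_degenerate(self):
        sheet = make_sheet(3, 3)
        rng = np.random.default_rng(0)
        vals = rng.random((5, 6))
        vals[0] = 0.0  # fully unmethylated everywhere
        res = probe_differential(_beta_matrix(vals, sheet), sheet, "SAT")
        assert res.iloc[0]["statistic"] == 0.0 and res.iloc[0]["p"] == 1.0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(42)
        sheet = make_sheet(12, 12)
        n_probes = 500
        base = rng.uniform(0.3, 0.5, n_probes)
        noise = rng.normal(0, 0.25, (n_probes, 24))
        logit = np.log2(base / (1 - base))[:, None] + noise
        beta = 2**logit / (1 + 2**logit)
        shift_target = np.clip(base[:50] + 0.2, 0, 0.98)
        logit_s = np.log2(shift_target / (1 - shift_target))[:, None]
        beta[:50, :12] = 2 ** (logit_s + noise[:50, :12]) / (
            1 + 2 ** (logit_s + noise[:50, :12])
        )
        res = probe_differential(_beta_matrix(beta, sheet), sheet, "SAT")
        planted = res.iloc[:50]
        assert 0.15 <= planted["delta_beta"].median() <= 0.25
        assert (planted["q"] < 0.1).mean() >= 0.8
        assert (np.sign(planted["statistic"]) == np.sign(planted["delta_beta"])).all()

    def test_null_pvalues_uniform_under_label_permutation(self):
        # global null: both groups drawn from one distribution, several seeds
        pvals_ks = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            sheet = make_sheet(12, 13)
            base = rng.uniform(0.2, 0.8, 300)
            logit = np.log2(base / (1 - base))[:, None] + rng.normal(
                0, 0.3, (300, 25)
            )
            beta = 2**logit / (1 + 2**logit)
            res = probe_differential(_beta_matrix(beta, sheet), sheet, "SAT")
            pvals_ks.append(sps.kstest(res["p"], "uniform").pvalue)
        assert all(p > 0.01 for p in pvals_ks)


def _annotation(rows):
    return ProbeAnnotation(
        pd.DataFrame(
            rows,
            columns=["probe_id", "chrom", "pos", "gene", "region_class", "cgi_relation"],
        ).set_index("probe_id")
    )


class TestSummarizeGeneMethylation:
    def _stats(self, entries):
        return pd.DataFrame(
            entries,
            columns=["probe_id", "delta_beta", "statistic", "p", "q"],
        ).set_index("probe_id")

    def test_single_probe_gene_passthrough(self):
        stats = self._stats([("cg0", 0.1, 2.0, 0.02, 0.02)])
        ann = _annotation([("cg0", "chr1", 100, "G1", "TSS200", "island")])
        out = summarize_gene_methylation(stats, ann)
        assert out.loc["G1", "statistic"] == 2.0
        assert out.loc["G1", "effect"] == 0.1

    def test_min_p_with_tie_breaks_matches_bruteforce(self, rng):
        probes, anns = [], []
        for i in range(30):
            gene = f"G{i % 6}"
            p = rng.choice([0.01, 0.05, 0.5])
            probes.append((f"cg{i}", rng.normal(0, 0.2), rng.normal(), p, p))
            anns.append((f"cg{i}", "chr1", 100 + i, gene, "TSS1500", "island"))
        stats, ann = self._stats(probes), _annotation(anns)
        out = summarize_gene_methylation(stats, ann)
        merged = stats.join(ann.frame[["gene"]])
        for gene, sub in merged.groupby("gene"):
            best = min(
                sub.itertuples(),
                key=lambda r: (r.p, -abs(r.delta_beta), r.Index),
            )
            assert out.loc[gene, "probe_id"] == best.Index
            assert out.loc[gene, "statistic"] == best.statistic

    def test_body_only_gene_absent(self):
        stats = self._stats([("cg0", 0.1, 2.0, 0.02, 0.02)])
        ann = _annotation([("cg0", "chr1", 100, "G1", "body", "open_sea")])
        assert "G1" not in summarize_gene_methylation(stats, ann).index

    def test_invariant_to_probe_order(self, rng):
        probes = [(f"cg{i}", rng.normal(), rng.normal(), rng.random(), 0.5) for i in range(12)]
        anns = [(f"cg{i}", "chr1", 50 + i, f"G{i % 3}", "5UTR", "island") for i in range(12)]
        stats, ann = self._stats(probes), _annotation(anns)
        fwd = summarize_gene_methylation(stats, ann)
        rev = summarize_gene_methylation(stats.iloc[::-1], ann)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_empty_region_classes_rejected(self):
        stats = self._stats([("cg0", 0.1, 2.0, 0.02, 0.02)])
        ann = _annotation([("cg0", "chr1", 100, "G1", "TSS200", "island")])
        with pytest.raises(ValueError):
            summarize_gene_methylation(stats, ann, region_classes=set())


class TestContextProfile:
    def test_flat_beta_gives_flat_profile(self):
        sheet = make_sheet(2, 2)
        ann = _annotation(
            [(f"cg{i}", "chr1", 1000 + 100 * i, "", "intergenic", "open_sea") for i in range(5)]
        )
        beta = BetaMatrix(
            pd.DataFrame(0.5, index=ann.probe_ids, columns=sheet.sample_ids)
        )
        feats = IntervalSet(
            "f", pd.DataFrame({"chrom": ["chr1"], "start": [999], "end": [1100], "label": [""]})
        )
        prof = context_profile(beta, sheet, "SAT", ann, feats, bins=[-500, 0, 1, 500])
        filled = prof[prof["n_probes"] > 0]
        assert (filled["mean_beta"] == 0.5).all()

    def test_two_probe_hand_computed_bins(self):
        sheet = make_sheet(2, 2)
        ann = _annotation(
            [
                ("cgA", "chr1", 150, "", "intergenic", "open_sea"),  # inside
                ("cgB", "chr1", 700, "", "intergenic", "open_sea"),  # 500 bp right
            ]
        )
        vals = pd.DataFrame(
            [[0.2, 0.2, 0.4, 0.4], [0.6, 0.6, 0.8, 0.8]],
            index=["cgA", "cgB"],
            columns=sheet.sample_ids,
        )
        feats = IntervalSet(
            "f", pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200], "label": [""]})
        )
        prof = context_profile(
            BetaMatrix(vals), sheet, "SAT", ann, feats, bins=[0, 1, 1000]
        )
        case_inside = prof[(prof["group"] == "case") & (prof["bin_lo"] == 0)]
        case_far = prof[(prof["group"] == "case") & (prof["bin_lo"] == 1)]
        assert case_inside["mean_beta"].iloc[0] == pytest.approx(0.2)
        assert case_far["mean_beta"].iloc[0] == pytest.approx(0.6)
        ctrl_far = prof[(prof["group"] == "control") & (prof["bin_lo"] == 1)]
        assert ctrl_far["mean_beta"].iloc[0] == pytest.approx(0.8)

    def test_empty_bin_reported_with_zero_probes(self):
        sheet = make_sheet(2, 2)
        ann = _annotation([("cgA", "chr1", 150, "", "intergenic", "open_sea")])
        beta = BetaMatrix(
            pd.DataFrame(0.3, index=["cgA"], columns=sheet.sample_ids)
        )
        feats = IntervalSet(
            "f", pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200], "label": [""]})
        )
        prof = context_profile(beta, sheet, "SAT", ann, feats, bins=[0, 1, 1000])
        empty = prof[(prof["bin_lo"] == 1) & (prof["group"] == "case")]
        assert empty["n_probes"].iloc[0] == 0 and np.isnan(empty["mean_beta"].iloc[0])

    def test_no_probe_in_any_bin_rejected(self):
        sheet = make_sheet(2, 2)
        ann = _annotation([("cgA", "chr2", 150, "", "intergenic", "open_sea")])
        beta = BetaMatrix(pd.DataFrame(0.3, index=["cgA"], columns=sheet.sample_ids))
        feats = IntervalSet(
            "f", pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200], "label": [""]})
        )
        with pytest.raises(ValueError, match="no probe"):
            context_profile(beta, sheet, "SAT", ann, feats, bins=[0, 1, 1000])
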