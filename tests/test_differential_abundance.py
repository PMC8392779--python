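import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, strategies as st

from matrisomics import (
    EBayesPrior,
    bh_adjust,
    classify_volcano,
    estimate_prior,
    fit_two_group,
    moderate,
    select_testable,
)
from matrisomics.differential_abundance import DifferentialRecord

from conftest import make_table


class TestFitTwoGroup:
    def test_constant_groups(self):
        r = fit_two_group([3, 3, 3], [1, 1, 1])
        assert (r.log2fc, r.s2, r.df) == (2.0, 0.0, 4)

    def test_hand_computed_pooled_variance(self):
        # ((3-2)^2+(3-4)^2+(2-1)^2+(2-3)^2)/2 = 2
        r = fit_two_group([2, 4], [1, 3])
        assert r.log2fc == pytest.approx(1.0)
        assert r.s2 == pytest.approx(2.0)
        assert r.df == 2

    def test_equal_groups_zero_fc(self):
        assert fit_two_group([5, 6, 7], [5, 6, 7]).log2fc == 0.0

    def test_single_value_group_untestable(self):
        assert not fit_two_group([5], [1, 2]).testable


class TestSelectTestable:
    def test_two_of_three_in_both_fractions_is_testable(self):
        table = make_table([("P1", 3, (256, 512, 0), (128, 128, 128))])
        assert len(select_testable(table, table)) == 1

    def test_one_cellular_replicate_not_testable(self):
        table = make_table([("P1", 3, (256, 512, 1024), (128, 0, 0))])
        assert select_testable(table, table) == []

    def test_peptide_rule_applies(self):
        table = make_table([("P1", 1, (256, 512, 256), (128, 128, 128))])
        assert select_testable(table, table) == []


class TestEstimatePrior:
    def test_recovers_planted_hyperparameters(self):
        # parameter-recovery oracle: scaled inverse-chi-square draws
        rng = np.random.default_rng(42)
        d0, s0_sq, df, n = 4.0, 1.0, 4, 5000
        sigma2 = d0 * s0_sq / rng.chisquare(d0, size=n)
        s2 = sigma2 * rng.chisquare(df, size=n) / df
        prior = estimate_prior(s2, np.full(n, df))
        assert abs(prior.d0 - d0) / d0 < 0.15
        assert abs(prior.s0_sq - s0_sq) / s0_sq < 0.10

    def test_equal_variances_shrink_fully(self):
        prior = estimate_prior([0.5] * 20, [4] * 20)
        assert math.isinf(prior.d0)
        # s0^2 equals the common s2 up to the log-scale bias correction at df=4
        assert prior.s0_sq == pytest.approx(0.5, rel=0.35)

    def test_spread_variances_give_finite_positive_d0(self):
        prior = estimate_prior([1e-3, 10.0, 0.1, 5.0], [4, 4, 4, 4])
        assert 0 < prior.d0 < math.inf

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_prior([0.0, 0.0], [4, 4])

    def test_zero_variances_offset_not_dropped(self):
        prior = estimate_prior([0.0, 0.2, 0.3], [4, 4, 4])
        assert prior.s0_sq > 0


class TestModerate:
    def test_worked_example(self):
        from matrisomics.differential_abundance import GroupFitRecord

        rec = GroupFitRecord("g", 2, 0, 2.0, 0.25, 4, 3, 3)
        out = moderate([rec], EBayesPrior(d0=4, s0_sq=0.25))[0]
        assert out.t_moderated == pytest.approx(2 / math.sqrt(0.25 * (2 / 3)), rel=1e-12)
        # p against an independent t-tail oracle at df 8
        from scipy.integrate import quad
        from scipy.stats import t as tdist

        tail, _ = quad(lambda x: tdist.pdf(x, 8), abs(out.t_moderated), np.inf)
        assert out.p_value == pytest.approx(2 * tail, rel=1e-8)

    def test_zero_fc_gives_p_one(self):
        from matrisomics.differential_abundance import GroupFitRecord

        rec = GroupFitRecord("g", 1, 1, 0.0, 0.3, 4, 3, 3)
        out = moderate([rec], EBayesPrior(d0=4, s0_sq=0.3))[0]
        assert out.t_moderated == 0.0 and out.p_value == 1.0

    def test_d0_limits_match_pooled_t_and_z(self):
        from matrisomics.differential_abundance import GroupFitRecord
        from scipy import stats

        rec = GroupFitRecord("g", 3, 1, 2.0, 0.5, 4, 3, 3)
        # d0 -> 0: ordinary pooled two-sample t
        lo = moderate([rec], EBayesPrior(d0=1e-6, s0_sq=1.0))[0]
        t_ref = 2.0 / math.sqrt(0.5 * (2 / 3))
        assert abs(lo.t_moderated - t_ref) / t_ref < 1e-6
        # d0 -> inf: z-statistic with the prior scale
        hi = moderate([rec], EBayesPrior(d0=1e9, s0_sq=0.5))[0]
        z = 2.0 / math.sqrt(0.5 * (2 / 3))
        assert abs(hi.t_moderated - z) / z < 1e-6
        exact_inf = moderate([rec], EBayesPrior(d0=math.inf, s0_sq=0.5))[0]
        assert exact_inf.p_value == pytest.approx(2 * stats.norm.sf(z), rel=1e-12)


class TestBHAdjust:
    def test_small_example_matches_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_identities(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_direct_formula(self, p):
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        scaled = p[order] * m / np.arange(1, m + 1)
        expected = np.minimum.accumulate(scaled[::-1])[::-1].clip(max=1.0)
        out = np.empty(m)
        out[order] = expected
        assert bh_adjust(p) == pytest.approx(out, abs=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40))
    def test_permutation_invariant(self, p):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        direct = bh_adjust(p)
        permuted = bh_adjust(np.asarray(p)[perm])
        assert np.asarray(direct)[perm] == pytest.approx(permuted, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestClassifyVolcano:
    def rec(self, sym, log2fc, p):
        return DifferentialRecord(symbol=sym, log2fc=log2fc, t_moderated=1.0, p_value=p)

    def test_threshold_classification(self):
        records = [
            self.rec("up", 1.2, 0.001),
            self.rec("down", -1.2, 0.001),
            self.rec("flat", 3.0, 0.9),
            self.rec("small", 0.5, 0.001),
        ]
        out = {r.symbol: r.status for r in classify_volcano(records, set())}
        assert out == {
            "up": "ECM_enriched", "down": "cellular_enriched",
            "flat": "not_significant", "small": "not_significant",
        }

    def test_exclusive_records_appended_without_p(self):
        out = classify_volcano([self.rec("a", 2, 0.01)], {"x"})
        exclusive = [r for r in out if r.status == "ECM_exclusive"]
        assert len(exclusive) == 1
        assert exclusive[0].p_value is None and exclusive[0].fdr is None

    def test_overlap_between_tested_and_exclusive_rejected(self):
        with pytest.raises(ValueError, match="exclusive"):
            classify_volcano([self.rec("a", 2, 0.01)], {"a"})


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_moderated_t_matches_limma(tmp_path):
    """Independent cross-check of the whole eBayes chain against limma."""
    rng = np.random.default_rng(7)
    n = 40
    sigma = np.sqrt(0.5 * 4 / rng.chisquare(4, size=n))
    ecm = rng.normal(20, 2, n)[:, None] + rng.normal(0, sigma[:, None], (n, 3))
    cell = ecm.mean(axis=1)[:, None] + rng.normal(0, sigma[:, None], (n, 3))
    mat_path = tmp_path / "mat.tsv"
    np.savetxt(mat_path, np.hstack([ecm, cell]), delimiter="\t",
               header="E1\tE2\tE3\tC1\tC2\tC3", comments="")
    fits = [fit_two_group(ecm[i], cell[i], symbol=str(i)) for i in range(n)]
    prior = estimate_prior([f.s2 for f in fits], [f.df for f in fits])
    ours = moderate(fits, prior)
    script = tmp_path / "limma.R"
    script.write_text(
        'suppressMessages(library(limma))\n'
        f'mat <- as.matrix(read.delim("{mat_path}"))\n'
        'design <- cbind(Intercept=1, ECM=c(1,1,1,0,0,0))\n'
        'fit <- eBayes(lmFit(mat, design))\n'
        'cat(fit$df.prior, fit$s2.prior, "\\n")\n'
        'write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]),'
        f' "{tmp_path / "r.tsv"}", sep="\\t", row.names=FALSE)\n'
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    r_out = np.loadtxt(tmp_path / "r.tsv", skiprows=1)
    t_ours = np.array([r.t_moderated for r in ours])
    p_ours = np.array([r.p_value for r in ours])
    assert np.allclose(t_ours, r_out[:, 0], rtol=1e-8)
    assert np.allclose(p_ours, r_out[:, 1], rtol=1e-8)
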