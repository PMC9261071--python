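import math
import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

from cpmct._errors import ContractError, DegenerateContrastError, DomainError
from cpmct.contrasts import build_mcdermott, build_sequen
from cpmct.simci import (
    contrast_moments,
    equicoordinate_quantile,
    simultaneous_ci,
)

from conftest import make_fit

#: reduced QMC budget for test speed; coverage error stays ~1e-3
BUDGET = 2**13


class TestContrastMoments:
    def test_two_group_variance_adds(self):
        """Independent equal-variance means: var(mu2 - mu1) = 2v."""
        v = 0.37
        fit = make_fit(np.zeros(2), v * np.eye(2))
        C = build_sequen(2)
        _, cov, corr = contrast_moments(fit, C)
        assert cov[0, 0] == pytest.approx(2 * v, rel=1e-12)
        assert corr[0, 0] == 1.0

    def test_sequen_adjacent_correlation_minus_half(self):
        """Adjacent differences sharing one mean have correlation -1/2
        when all mean variances are equal and independent."""
        fit = make_fit(np.zeros(6), 1.3 * np.eye(6))
        _, _, corr = contrast_moments(fit, build_sequen(6))
        off = np.diag(corr, k=1)
        np.testing.assert_allclose(off, -0.5, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr, k=2), 0.0, atol=1e-12)

    def test_matches_direct_matrix_computation(self, stepwise_fit):
        C = build_mcdermott(stepwise_fit.n_per_timepoint)
        est, cov, corr = contrast_moments(stepwise_fit, C)
        W = C.weights
        np.testing.assert_allclose(est, W @ stepwise_fit.beta, atol=1e-10)
        np.testing.assert_allclose(cov, W @ stepwise_fit.vcov_beta @ W.T, atol=1e-10)
        sd = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(corr, cov / np.outer(sd, sd), atol=1e-10)

    def test_dimension_mismatch_rejected(self, stepwise_fit):
        with pytest.raises(ContractError):
            contrast_moments(stepwise_fit, build_sequen(5))

    def test_zero_variance_row_rejected(self):
        fit = make_fit(np.zeros(3), np.zeros((3, 3)))
        with pytest.raises(DegenerateContrastError):
            contrast_moments(fit, build_sequen(3))


class TestEquicoordinateQuantile:
    def test_dimension_one_is_univariate_quantile(self):
        q = equicoordinate_quantile(np.eye(1), df=math.inf, alpha=0.05)
        assert q.crit == pytest.approx(1.959964, abs=1e-6)
        assert q.mc_error == 0.0
        qt = equicoordinate_quantile(np.eye(1), df=7, alpha=0.05)
        assert qt.crit == pytest.approx(stats.t.ppf(0.975, 7), abs=1e-9)

    def test_two_independent_coordinates_closed_form(self):
        """Solve (2 Phi(c) - 1)^2 = 0.95 -> c = 2.2365."""
        q = equicoordinate_quantile(np.eye(2), df=math.inf, alpha=0.05, seed=5, maxpts=BUDGET)
        c_exact = stats.norm.ppf((1 + math.sqrt(0.95)) / 2)
        assert q.crit == pytest.approx(c_exact, abs=max(1e-3, 5 * q.mc_error))
        assert q.crit == pytest.approx(2.2365, abs=2e-3)

    def test_perfect_dependence_reduces_to_univariate(self):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        q = equicoordinate_quantile(corr, df=math.inf, alpha=0.05)
        assert q.crit == pytest.approx(1.959964, abs=1e-6)

    def test_t_quantile_exceeds_normal(self):
        corr = np.eye(3) * 0.7 + 0.3
        qn = equicoordinate_quantile(corr, df=math.inf, seed=2, maxpts=BUDGET)
        qt = equicoordinate_quantile(corr, df=5, seed=2, maxpts=BUDGET)
        assert qt.crit > qn.crit

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_bracket_invariant_random_2x2(self, seed):
        """Univariate quantile <= c <= Bonferroni quantile, any correlation."""
        rng = np.random.default_rng(seed)
        r = rng.uniform(-0.99, 0.99)
        corr = np.array([[1.0, r], [r, 1.0]])
        df = float(rng.integers(3, 200))
        q = equicoordinate_quantile(corr, df=df, alpha=0.05, seed=seed, maxpts=BUDGET)
        lo = stats.t.ppf(0.975, df)
        hi = stats.t.ppf(1 - 0.05 / 4, df)
        assert lo - 1e-6 <= q.crit <= hi + 1e-6

    def test_monotone_in_absolute_correlation(self):
        """Stronger dependence needs a smaller critical value."""
        crits = []
        for r in (0.0, 0.5, 0.9, 0.99):
            corr = np.array([[1.0, r], [r, 1.0]])
            crits.append(
                equicoordinate_quantile(corr, df=math.inf, seed=6, maxpts=BUDGET).crit
            )
        assert all(a >= b - 2e-3 for a, b in zip(crits, crits[1:]))
        assert crits[0] > crits[-1]

    def test_same_seed_reproduces_exactly(self):
        corr = np.eye(4) * 0.6 + 0.4
        q1 = equicoordinate_quantile(corr, df=30, seed=9, maxpts=BUDGET)
        q2 = equicoordinate_quantile(corr, df=30, seed=9, maxpts=BUDGET)
        assert q1.crit == q2.crit

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            equicoordinate_quantile(np.eye(2), alpha=1.5)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # |r| > 1, not PSD
        with pytest.raises(DomainError):
            equicoordinate_quantile(bad)
        with pytest.raises(DomainError):
            equicoordinate_quantile(np.eye(2), df=-1)


class TestSimultaneousCI:
    def test_interval_construction(self, stepwise_fit):
        sci = simultaneous_ci(
            stepwise_fit, build_sequen(12), seed=3, maxpts=BUDGET
        )
        r = sci.rows
        np.testing.assert_allclose(r["lower"], r["estimate"] - sci.crit * r["se"], atol=1e-12)
        np.testing.assert_allclose(r["upper"], r["estimate"] + sci.crit * r["se"], atol=1e-12)
        assert sci.crit >= stats.t.ppf(0.975, sci.df)
        assert sci.df == stepwise_fit.df_residual

    def test_alpha_monotonicity(self, stepwise_fit):
        C = build_sequen(12)
        wide = simultaneous_ci(stepwise_fit, C, alpha=0.05, seed=3, maxpts=BUDGET)
        narrow = simultaneous_ci(stepwise_fit, C, alpha=0.5, seed=3, maxpts=BUDGET)
        assert ((narrow.rows["upper"] - narrow.rows["lower"])
                < (wide.rows["upper"] - wide.rows["lower"])).all()

    def test_adjusted_p_consistent_with_intervals(self, stepwise_fit):
        sci = simultaneous_ci(stepwise_fit, build_sequen(12), seed=3, maxpts=BUDGET)
        r = sci.rows
        excludes_zero = (r["lower"] > 0) | (r["upper"] < 0)
        assert ((r["adjusted_p"] < sci.alpha) == excludes_zero).all()

    def test_adjusted_p_rank_matches_statistic_rank(self, stepwise_fit):
        sci = simultaneous_ci(stepwise_fit, build_sequen(12), seed=3, maxpts=BUDGET)
        r = sci.rows
        # single-step max-t adjustment is rank-preserving: a larger |t| never
        # gets a larger adjusted p (ties at p ~ 0 are allowed)
        t_abs = np.abs(r["t_statistic"].to_numpy())
        p = r["adjusted_p"].to_numpy()
        for i in range(len(p)):
            for j in range(len(p)):
                if t_abs[i] > t_abs[j]:
                    assert p[i] <= p[j] + 1e-12

    def test_df_methods(self, stepwise_fit):
        C = build_sequen(12)
        res = simultaneous_ci(stepwise_fit, C, df_method="residual", seed=1, maxpts=BUDGET)
        con = simultaneous_ci(stepwise_fit, C, df_method="containment", seed=1, maxpts=BUDGET)
        nor = simultaneous_ci(stepwise_fit, C, df_method="normal", seed=1, maxpts=BUDGET)
        assert con.df == stepwise_fit.df_containment and math.isinf(nor.df)
        # heavier-tailed reference -> wider intervals
        assert con.crit > res.crit > nor.crit

    def test_serialization_roundtrip(self, tmp_path, stepwise_fit):
        sci = simultaneous_ci(stepwise_fit, build_sequen(12), seed=3, maxpts=BUDGET)
        path = tmp_path / "sci.tsv"
        sci.to_tsv(path)
        text = path.read_text()
        assert "# critical_value" in text and "adjusted_p" in text


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_matches_multcomp_glht(tmp_path, partly_dropped_ds, partly_dropped_fit):
    """Full pipeline against lme4 + multcomp::glht (normal reference):
    estimates to 1e-6, simultaneous bounds to Monte-Carlo precision."""
    path = tmp_path / "fix.tsv"
    partly_dropped_ds.to_tsv(path)
    rcode = f"""
    suppressMessages({{library(lme4); library(multcomp)}})
    set.seed(1)
    d <- read.delim("{path}")
    d$timepoint <- factor(d$timepoint, levels=paste0("t", 1:12))
    m <- lmer(value ~ 0 + timepoint + (1 | cluster), data = d, REML = TRUE)
    ci <- confint(glht(m, linfct = mcp(timepoint = "Sequen")))$confint
    cat(attr(ci, "calpha"), "\\n")
    write.table(ci, stdout(), col.names = FALSE, row.names = FALSE)
    """
    out = subprocess.run(
        ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    lines = [l for l in out.stdout.strip().splitlines() if l.strip()]
    calpha = float(lines[0])
    tab = np.array([l.split() for l in lines[1:]], dtype=float)
    sci = simultaneous_ci(partly_dropped_fit, build_sequen(12), df_method="normal", seed=5)
    assert sci.crit == pytest.approx(calpha, abs=5e-3)
    np.testing.assert_allclose(sci.rows["estimate"], tab[:, 0], atol=1e-6)
    np.testing.assert_allclose(sci.rows["lower"], tab[:, 1], atol=5e-2)
    np.testing.assert_allclose(sci.rows["upper"], tab[:, 2], atol=5e-2)
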