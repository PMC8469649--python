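import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirswitch.diffexpr import (DEResult, bh_adjust, call_de, de_table,
                                estimate_prior, moderated_t)
from mirswitch.errors import UndefinedStatisticError, ValidationError

from conftest import build_study


class TestModeratedT:
    def test_zero_prior_df_reduces_to_pooled_t(self):
        t, df, p = moderated_t([1, 2, 3], [4, 5, 6], prior_df=0)
        assert t == pytest.approx(-3.6742346141747673, abs=1e-12)
        assert df == 4
        assert p == pytest.approx(0.021311641128756713, abs=1e-9)

    def test_matches_pooled_t_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = rng.normal(size=rng.integers(2, 6))
            b = rng.normal(size=rng.integers(2, 6))
            t, df, _ = moderated_t(a, b, prior_df=0)
            # independently coded pooled-t (sum formulas)
            na, nb = len(a), len(b)
            sp2 = (np.sum(a * a) - na * a.mean() ** 2
                   + np.sum(b * b) - nb * b.mean() ** 2) / (na + nb - 2)
            t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            assert t == pytest.approx(t_ref, abs=1e-12)

    def test_infinite_prior_df_uses_prior_variance_only(self):
        t, df, _ = moderated_t([1, 2, 3], [4, 5, 6], prior_df=np.inf,
                               prior_var=4.0)
        assert t == pytest.approx(-3 / (2 * np.sqrt(2 / 3)))
        assert np.isinf(df)

    def test_zero_variance_without_prior_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            moderated_t([1, 1], [2, 2], prior_df=0)

    def test_too_few_replicates(self):
        with pytest.raises(ValidationError):
            moderated_t([1], [2, 3])


class TestEstimatePrior:
    def test_equal_variances_give_infinite_prior_df(self):
        d0, s0 = estimate_prior([0.25] * 20, residual_df=4)
        assert np.isinf(d0)
        assert s0 == pytest.approx(0.25)

    def test_recovers_planted_hyperparameters(self):
        # variances drawn from the scaled inverse-chi-square model itself
        rng = np.random.default_rng(123)
        d0_true, s0_true, d = 4.0, 1.0, 4
        prior_var = d0_true * s0_true / rng.chisquare(d0_true, size=5000)
        s2 = prior_var * rng.chisquare(d, size=5000) / d
        d0, s0 = estimate_prior(s2, residual_df=d)
        assert d0 == pytest.approx(d0_true, abs=1.0)
        assert s0 == pytest.approx(s0_true, rel=0.10)

    def test_invariant_to_feature_order(self):
        rng = np.random.default_rng(5)
        s2 = rng.chisquare(4, size=200) / 4
        a = estimate_prior(s2, 4)
        b = estimate_prior(s2[::-1], 4)
        assert a == pytest.approx(b)

    def test_too_few_features(self):
        with pytest.raises(ValidationError):
            estimate_prior([0.5] * 5, 4)


class TestBHAdjust:
    @pytest.mark.parametrize("p_in,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2], [0.2]),
        ([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]),
    ])
    def test_hand_computed_step_up(self, p_in, expected):
        np.testing.assert_allclose(bh_adjust(p_in), expected, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.integers(0, 29), st.floats(0, 1))
    def test_monotone_and_permutation_invariant(self, ps, idx, bump):
        adj = bh_adjust(ps)
        # adjusted values are monotone non-decreasing in raw-p rank order
        order = np.argsort(ps, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        # permutation invariance
        perm = np.random.default_rng(0).permutation(len(ps))
        np.testing.assert_allclose(bh_adjust(np.asarray(ps)[perm]), adj[perm],
                                   atol=1e-12)
        # raising one raw p never lowers any adjusted p
        idx = idx % len(ps)
        raised = list(ps)
        raised[idx] = min(1.0, raised[idx] + bump)
        assert (bh_adjust(raised) >= adj - 1e-12).all()


class TestCallDE:
    @pytest.mark.parametrize("p_adj,lfc,expected", [
        (1e-6, 2.5, True),
        (1e-6, 2.0, False),   # fold-change boundary is strict
        (1e-4, 5.0, False),
    ])
    def test_joint_strict_thresholds(self, p_adj, lfc, expected):
        res = DEResult("f", 4, lfc, 0.0, p_adj, p_adj)
        assert call_de([res], alpha=1e-5, lfc_min=2.0)[0].is_de is expected

    def test_non_strict_option_includes_boundaries(self):
        res = DEResult("f", 4, 2.0, 0.0, 1e-5, 1e-5)
        assert call_de([res], alpha=1e-5, lfc_min=2.0, strict=False)[0].is_de


def test_de_table_flags_a_planted_effect():
    rng = np.random.default_rng(11)
    day_values = {}
    for i in range(60):
        base = 8.0
        shift = 4.0 if i < 6 else 0.0
        day_values[f"g{i}"] = {
            0: list(base + rng.normal(0, 0.1, 3)),
            4: list(base + shift + rng.normal(0, 0.1, 3)),
        }
    table = de_table(build_study(day_values), alpha=1e-3, lfc_min=2.0)
    flagged = set(table.loc[table["is_de"], "feature_id"])
    assert flagged == {f"g{i}" for i in range(6)}


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_moderated_t_matches_limma_given_its_prior(tmp_path):
    """Feed limma's estimated prior into our closed form; t must agree."""
    rng = np.random.default_rng(21)
    A = rng.normal(8, 0.5, size=(40, 3))
    B = rng.normal(8, 0.5, size=(40, 3))
    B[:5] += 3
    mat = np.hstack([A, B])
    np.savetxt(tmp_path / "mat.tsv", mat, delimiter="\t")
    script = textwrap.dedent("""
        suppressMessages(library(limma))
        m <- as.matrix(read.table(commandArgs(TRUE)[1], sep="\t"))
        design <- cbind(Intercept=1, Group=c(0,0,0,1,1,1))
        fit <- eBayes(lmFit(m, design))
        out <- cbind(fit$t[, "Group"], fit$df.prior, fit$s2.prior)
        write.table(out, commandArgs(TRUE)[2], sep="\t",
                    row.names=FALSE, col.names=FALSE)
    """)
    (tmp_path / "limma.R").write_text(script)
    subprocess.run(["Rscript", str(tmp_path / "limma.R"),
                    str(tmp_path / "mat.tsv"), str(tmp_path / "out.tsv")],
                   check=True, capture_output=True)
    ref = np.loadtxt(tmp_path / "out.tsv")
    t_limma, d0, s0 = ref[:, 0], ref[0, 1], ref[0, 2]
    ours = np.array([moderated_t(B[i], A[i], prior_df=d0, prior_var=s0)[0]
                     for i in range(40)])
    np.testing.assert_allclose(ours, t_limma, atol=1e-8)
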