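import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from erpmem.lmm import LmmSpec, bf10_bic, fit_random_intercept_lmm


def balanced_within(rng, n_subjects, factors, subject_sd=0.5, resid_sd=0.3,
                    effects=None):
    """Balanced fully-within dataset: one observation per subject per cell."""
    effects = effects or {}
    levels = {f: [f"{f}1", f"{f}2"] for f in factors}
    rows = []
    for s in range(n_subjects):
        b = rng.normal(0, subject_sd)
        cells = [[]]
        for f in factors:
            cells = [c + [(f, l)] for c in cells for l in levels[f]]
        for cell in cells:
            y = b + rng.normal(0, resid_sd)
            for f, l in cell:
                y += effects.get(f, 0.0) * (1 if l.endswith("1") else -1)
            rows.append({"subject": f"s{s}", **dict(cell), "y": y})
    return pd.DataFrame(rows)


class TestSatterthwaiteDf:
    def test_two_by_two_within_30_subjects_gives_df_87(self, rng):
        data = balanced_within(rng, 30, ["A", "B"], effects={"A": 0.2})
        fit = fit_random_intercept_lmm(data, LmmSpec("y", ["A", "B"]))
        for term in ("A", "B", "A:B"):
            assert fit.term(term)["df"] == pytest.approx(87.0, abs=1e-6)

    def test_two_by_two_by_two_within_30_subjects_gives_df_203(self, rng):
        data = balanced_within(rng, 30, ["A", "B", "C"])
        fit = fit_random_intercept_lmm(data, LmmSpec("y", ["A", "B", "C"]))
        assert fit.term("A:B:C")["df"] == pytest.approx(203.0, abs=1e-6)
        # balanced identity: N_obs - N_subjects - (fixed rank - 1)
        assert 240 - 30 - 7 == 203

    def test_balanced_within_df_equals_residual_df_by_construction(self, rng):
        # subject variance cancels in within contrasts; df = N - n - (p - 1)
        n_subj = 17
        data = balanced_within(rng, n_subj, ["A", "B"], subject_sd=1.5)
        fit = fit_random_intercept_lmm(data, LmmSpec("y", ["A", "B"]))
        expected = 4 * n_subj - n_subj - 3
        assert fit.term("A")["df"] == pytest.approx(expected, abs=1e-6)


class TestEstimation:
    def test_matches_statsmodels_reml_on_balanced_data(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        data = balanced_within(rng, 24, ["A", "B"], effects={"A": 0.3, "B": -0.1})
        fit = fit_random_intercept_lmm(data, LmmSpec("y", ["A", "B"]))
        ref = smf.mixedlm(
            "y ~ C(A, Sum) * C(B, Sum)", data, groups=data["subject"]
        ).fit(reml=True)
        assert np.allclose(fit.coef["estimate"], ref.params[:4], atol=1e-6)
        assert fit.sigma2_resid == pytest.approx(float(ref.scale), rel=1e-4)
        assert fit.sigma2_subject == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6
        )

    def test_zero_subject_variance_reduces_to_ols(self):
        # data with no subject effect whose REML fit lands on the boundary:
        # estimates match plain least squares and df collapses to N - rank(X)
        rng = np.random.default_rng(1)
        data = balanced_within(rng, 100, ["A", "B"], subject_sd=0.0, resid_sd=1.0,
                               effects={"A": 0.3})
        fit = fit_random_intercept_lmm(data, LmmSpec("y", ["A", "B"]))
        X = np.column_stack([
            np.ones(len(data)),
            np.where(data["A"] == "A1", 1.0, -1.0),
            np.where(data["B"] == "B1", 1.0, -1.0),
            np.where(data["A"] == "A1", 1.0, -1.0) * np.where(data["B"] == "B1", 1.0, -1.0),
        ])
        beta = np.linalg.lstsq(X, data["y"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.coef["estimate"], beta, atol=1e-8)
        assert fit.sigma2_subject == 0.0
        assert np.allclose(fit.coef["df"], 400 - 4)

    def test_translation_invariance_of_variance_components(self, rng):
        data = balanced_within(rng, 15, ["A", "B"])
        f1 = fit_random_intercept_lmm(data, LmmSpec("y", ["A", "B"]))
        shifted = data.assign(y=data["y"] + 1000.0)
        f2 = fit_random_intercept_lmm(shifted, LmmSpec("y", ["A", "B"]))
        assert f1.sigma2_subject == pytest.approx(f2.sigma2_subject, rel=1e-4)
        assert f1.sigma2_resid == pytest.approx(f2.sigma2_resid, rel=1e-4)
        assert np.allclose(
            f1.coef["estimate"][1:], f2.coef["estimate"][1:], atol=1e-8
        )

    def test_singular_design_rejected(self, rng):
        data = balanced_within(rng, 6, ["A"])
        data["B"] = data["A"]  # perfectly aliased factor
        with pytest.raises(ValueError, match="singular"):
            fit_random_intercept_lmm(data, LmmSpec("y", ["A", "B"]))

    def test_requires_replicated_subjects(self, rng):
        data = pd.DataFrame({"subject": ["s1", "s2"], "A": ["A1", "A2"], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_random_intercept_lmm(data, LmmSpec("y", ["A"]))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestLmerTestOracle:
    def test_df_and_t_match_lmerTest_on_balanced_data(self, rng, tmp_path):
        data = balanced_within(rng, 30, ["A", "B"], effects={"A": 0.25})
        csv = tmp_path / "d.csv"
        out = tmp_path / "out.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "options(contrasts = c('contr.sum', 'contr.poly'))\n"
            "suppressMessages(library(lmerTest))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- lmer(y ~ A * B + (1 | subject), data = d)\n"
            "s <- coef(summary(m))\n"
            "write.csv(data.frame(est = s[, 'Estimate'], df = s[, 'df'],"
            f" t = s[, 't value']), '{out}', row.names = FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out)
        fit = fit_random_intercept_lmm(data, LmmSpec("y", ["A", "B"]))
        assert np.allclose(fit.coef["estimate"], ref["est"], atol=1e-6)
        assert np.allclose(fit.coef["df"], ref["df"], atol=1e-3)
        assert np.allclose(fit.coef["t"], ref["t"], atol=1e-4)


class TestBayesFactors:
    def test_identical_models_give_bf_one(self, rng):
        data = balanced_within(rng, 10, ["A"])
        spec = LmmSpec("y", ["A"])
        f1 = fit_random_intercept_lmm(data, spec, reml=False)
        f2 = fit_random_intercept_lmm(data, spec, reml=False)
        assert bf10_bic(f1, f2).bf10 == pytest.approx(1.0)

    def test_reml_fits_rejected(self, rng):
        data = balanced_within(rng, 10, ["A"])
        f = fit_random_intercept_lmm(data, LmmSpec("y", ["A"]))
        with pytest.raises(ValueError, match="ML"):
            bf10_bic(f, f)

    def test_different_data_rejected(self, rng):
        d1 = balanced_within(rng, 10, ["A"])
        d2 = balanced_within(rng, 10, ["A"])
        f1 = fit_random_intercept_lmm(d1, LmmSpec("y", ["A"]), reml=False)
        f2 = fit_random_intercept_lmm(d2, LmmSpec("y", ["A"]), reml=False)
        with pytest.raises(ValueError, match="different data"):
            bf10_bic(f1, f2)

    def test_non_nested_models_rejected(self, rng):
        data = balanced_within(rng, 10, ["A", "B"])
        fa = fit_random_intercept_lmm(
            data, LmmSpec("y", ["A", "B"], terms=["A"]), reml=False
        )
        fb = fit_random_intercept_lmm(
            data, LmmSpec("y", ["A", "B"], terms=["B"]), reml=False
        )
        with pytest.raises(ValueError, match="nested"):
            bf10_bic(fa, fb)

    def test_strong_effect_yields_bf_above_three_in_most_replicates(self):
        # standardized effect ~0.8 at 30 subjects
        wins = 0
        for rep in range(15):
            rng = np.random.default_rng(500 + rep)
            data = balanced_within(
                rng, 30, ["A"], subject_sd=0.4, resid_sd=0.5, effects={"A": 0.4}
            )
            alt = fit_random_intercept_lmm(data, LmmSpec("y", ["A"]), reml=False)
            null = fit_random_intercept_lmm(
                data, LmmSpec("y", ["A"], terms=[]), reml=False
            )
            wins += bf10_bic(alt, null).bf10 > 3.0
        assert wins >= 14  # >= 90% of replicates

    def test_absent_effect_yields_bf_below_one_in_majority(self):
        small = 0
        for rep in range(15):
            rng = np.random.default_rng(900 + rep)
            data = balanced_within(rng, 40, ["A"], subject_sd=0.4, resid_sd=0.5)
            alt = fit_random_intercept_lmm(data, LmmSpec("y", ["A"]), reml=False)
            null = fit_random_intercept_lmm(
                data, LmmSpec("y", ["A"], terms=[]), reml=False
            )
            small += bf10_bic(alt, null).bf10 < 1.0
        assert small >= 10

    def test_evidence_labels_follow_bands(self, rng):
        data = balanced_within(rng, 10, ["A"])
        spec = LmmSpec("y", ["A"])
        f = fit_random_intercept_lmm(data, spec, reml=False)
        cmp_ = bf10_bic(f, f)
        assert cmp_.label == "no evidence"
        assert cmp_.method == "BIC-approximation"
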