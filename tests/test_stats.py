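"""Condition means, within-subject ANOVA (vs independent oracles), post-hocs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fibsrt.cohort import LearnerSpec, RTParams, simulate_cohort
from fibsrt.stats import (
    EmptyCellError,
    IncompleteDesignError,
    bonferroni_pairwise,
    condition_means,
    rm_anova_two_way,
    run_analysis,
)


# ---------------------------------------------------------------------------
# independent brute-force oracle: plain nested loops over mean deviations,
# no shared code with the implementation
# ---------------------------------------------------------------------------

def brute_force_rm_anova(y):
    """y[s, a, b] -> dict of SS per source, computed from first principles."""
    s, a, b = y.shape
    gm = sum(y[i, j, k] for i in range(s) for j in range(a) for k in range(b)) / (
        s * a * b
    )
    mean_s = [sum(y[i, j, k] for j in range(a) for k in range(b)) / (a * b) for i in range(s)]
    mean_a = [sum(y[i, j, k] for i in range(s) for k in range(b)) / (s * b) for j in range(a)]
    mean_b = [sum(y[i, j, k] for i in range(s) for j in range(a)) / (s * a) for k in range(b)]
    mean_sa = [[sum(y[i, j, k] for k in range(b)) / b for j in range(a)] for i in range(s)]
    mean_sb = [[sum(y[i, j, k] for j in range(a)) / a for k in range(b)] for i in range(s)]
    mean_ab = [[sum(y[i, j, k] for i in range(s)) / s for k in range(b)] for j in range(a)]

    ss = {}
    ss["subjects"] = a * b * sum((m - gm) ** 2 for m in mean_s)
    ss["A"] = s * b * sum((m - gm) ** 2 for m in mean_a)
    ss["B"] = s * a * sum((m - gm) ** 2 for m in mean_b)
    ss["AB"] = s * sum(
        (mean_ab[j][k] - mean_a[j] - mean_b[k] + gm) ** 2
        for j in range(a)
        for k in range(b)
    )
    ss["AS"] = b * sum(
        (mean_sa[i][j] - mean_s[i] - mean_a[j] + gm) ** 2
        for i in range(s)
        for j in range(a)
    )
    ss["BS"] = a * sum(
        (mean_sb[i][k] - mean_s[i] - mean_b[k] + gm) ** 2
        for i in range(s)
        for k in range(b)
    )
    ss["total"] = sum(
        (y[i, j, k] - gm) ** 2 for i in range(s) for j in range(a) for k in range(b)
    )
    ss["ABS"] = ss["total"] - sum(
        ss[key] for key in ("subjects", "A", "B", "AB", "AS", "BS")
    )
    return ss


def cells_frame(y, factor_b="block"):
    s, a, b = y.shape
    rows = []
    for i, j, k in itertools.product(range(s), range(a), range(b)):
        rows.append(
            {
                "subject": i + 1,
                "congruency": ["congruent", "incongruent", "neutral"][j],
                factor_b: k + 1,
                "mean_rt": y[i, j, k],
                "accuracy": 1.0,
                "n_trials": 10,
            }
        )
    return pd.DataFrame(rows)


class TestConditionMeans:
    def _tiny_cohort(self):
        # 2 subjects x 8 trials, hand-computable
        rows = []
        rts = {
            (1, "congruent", "fib"): [400, 420],
            (1, "incongruent", "fib"): [600, 640],
            (1, "congruent", "skip"): [500, 540],
            (1, "incongruent", "skip"): [700, 680],
            (2, "congruent", "fib"): [410, 430],
            (2, "incongruent", "fib"): [610, 650],
            (2, "congruent", "skip"): [510, 530],
            (2, "incongruent", "skip"): [710, 690],
        }
        trial = 0
        for (subj, cong, gram), values in rts.items():
            for v in values:
                trial += 1
                rows.append(
                    {
                        "subject": subj, "trial": trial, "block": 1,
                        "grammar": gram, "congruency": cong,
                        "a1": False, "a2": False, "a3": True, "is_k": False,
                        "rt_ms": v, "timeout": False, "correct": True,
                    }
                )
        return pd.DataFrame(rows)

    def test_constant_rt_gives_constant_means(self):
        cohort = self._tiny_cohort()
        cohort["rt_ms"] = 500.0
        cells = condition_means(cohort, "a3", "grammar")
        assert (cells.mean_rt == 500.0).all()

    def test_hand_computed_golden_values(self):
        cells = condition_means(self._tiny_cohort(), "a3", "grammar")
        lookup = cells.set_index(["subject", "congruency", "grammar"]).mean_rt
        assert lookup[(1, "congruent", "fib")] == 410.0
        assert lookup[(1, "incongruent", "skip")] == 690.0
        assert lookup[(2, "congruent", "skip")] == 520.0
        assert (cells.n_trials == 2).all()

    def test_incorrect_and_timeout_trials_excluded_from_rt(self):
        cohort = self._tiny_cohort()
        # subject 1 congruent fib: mark the 420 trial wrong -> mean 400
        cohort.loc[(cohort.rt_ms == 420) & (cohort.subject == 1), "correct"] = False
        cells = condition_means(cohort, "a3", "grammar")
        lookup = cells.set_index(["subject", "congruency", "grammar"])
        assert lookup.mean_rt[(1, "congruent", "fib")] == 400.0
        assert lookup.accuracy[(1, "congruent", "fib")] == 0.5
        assert lookup.n_trials[(1, "congruent", "fib")] == 1

    def test_empty_cell_raises_with_location(self):
        cohort = self._tiny_cohort()
        cohort.loc[
            (cohort.subject == 2) & (cohort.grammar == "skip")
            & (cohort.congruency == "incongruent"),
            "correct",
        ] = False
        with pytest.raises(EmptyCellError, match="subject=2"):
            condition_means(cohort, "a3", "grammar")

    def test_shape_contract_on_default_cohort(self, default_trials):
        cohort = simulate_cohort(22, master_seed=0, trials=default_trials)
        cells = condition_means(cohort, "a1", "block")
        assert len(cells) == 22 * 2 * 4


class TestRmAnova:
    def test_flat_data_gives_zero_f(self):
        y = np.full((4, 2, 3), 100.0)
        res = rm_anova_two_way(cells_frame(y), factor_b="block")
        for name in ("congruency", "block", "congruency*block"):
            assert res.effect(name).f == 0.0
            assert res.effect(name).partial_eta_sq == 0.0

    def test_three_subject_2x2_fixture_matches_oracle(self):
        rng = np.random.default_rng(42)
        y = rng.normal(500, 50, size=(3, 2, 2))
        res = rm_anova_two_way(cells_frame(y), factor_b="block")
        oracle = brute_force_rm_anova(y)
        assert res.effect("congruency").ss == pytest.approx(oracle["A"], rel=1e-9)
        assert res.effect("block").ss == pytest.approx(oracle["B"], rel=1e-9)
        assert res.effect("congruency*block").ss == pytest.approx(
            oracle["AB"], rel=1e-9
        )
        f_a = (oracle["A"] / 1) / (oracle["AS"] / 2)
        assert res.effect("congruency").f == pytest.approx(f_a, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_designs(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.integers(3, 9)
        a = rng.integers(2, 4)
        b = rng.integers(2, 5)
        y = rng.normal(500, 60, size=(s, a, b))
        res = rm_anova_two_way(cells_frame(y), factor_b="block")
        oracle = brute_force_rm_anova(y)
        pairs = [
            ("subjects", "subjects"), ("congruency", "A"), ("block", "B"),
            ("congruency*block", "AB"), ("congruency*subjects", "AS"),
            ("block*subjects", "BS"), ("congruency*block*subjects", "ABS"),
        ]
        for name, key in pairs:
            assert res.effect(name).ss == pytest.approx(oracle[key], rel=1e-9)
        # SS conservation
        total = sum(res.effect(n).ss for n, _ in pairs)
        assert total == pytest.approx(res.ss_total, rel=1e-9)

    def test_partial_eta_squared_definition(self):
        rng = np.random.default_rng(3)
        y = rng.normal(500, 50, size=(5, 2, 4))
        res = rm_anova_two_way(cells_frame(y), factor_b="block")
        eff, err = res.effect("block"), res.effect("block*subjects")
        assert eff.partial_eta_sq == pytest.approx(eff.ss / (eff.ss + err.ss))
        assert 0 <= eff.partial_eta_sq <= 1

    def test_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        y = rng.normal(500, 50, size=(6, 2, 4))
        res = rm_anova_two_way(cells_frame(y), factor_b="block")
        long = cells_frame(y)
        pg = pingouin.rm_anova(
            data=long, dv="mean_rt", within=["congruency", "block"],
            subject="subject", detailed=True,
        )
        pg = pg.set_index("Source")
        assert res.effect("congruency").f == pytest.approx(
            float(pg.loc["congruency", "F"]), rel=1e-6
        )
        assert res.effect("block").f == pytest.approx(
            float(pg.loc["block", "F"]), rel=1e-6
        )
        assert res.effect("congruency*block").f == pytest.approx(
            float(pg.loc["congruency * block", "F"]), rel=1e-6
        )

    def test_incomplete_design_rejected(self):
        y = np.random.default_rng(0).normal(500, 50, size=(4, 2, 3))
        cells = cells_frame(y).drop(index=[0])
        with pytest.raises(IncompleteDesignError, match="missing cells"):
            rm_anova_two_way(cells, factor_b="block")

    def test_too_few_subjects_rejected(self):
        y = np.random.default_rng(0).normal(500, 50, size=(1, 2, 3))
        with pytest.raises(IncompleteDesignError):
            rm_anova_two_way(cells_frame(y), factor_b="block")


class TestBonferroni:
    def test_identical_levels_give_t_zero_p_one(self):
        y = np.tile(np.array([500.0, 510, 520, 530])[:, None, None], (1, 2, 2))
        res = bonferroni_pairwise(cells_frame(y, "block"), factor="block")
        assert len(res) == 1
        assert res[0].t == 0.0 and res[0].p_bonferroni == 1.0

    def test_four_levels_give_six_comparisons(self):
        y = np.random.default_rng(1).normal(500, 50, size=(5, 2, 4))
        res = bonferroni_pairwise(cells_frame(y, "block"), factor="block")
        assert len(res) == 6
        for r in res:
            assert r.p_bonferroni >= r.p_raw
            assert r.p_bonferroni == pytest.approx(min(1.0, 6 * r.p_raw))

    def test_three_subject_fixture_matches_closed_form_paired_t(self):
        y = np.zeros((3, 2, 2))
        y[:, :, 0] = np.array([[500, 600], [520, 640], [480, 590]])
        y[:, :, 1] = np.array([[490, 585], [515, 620], [470, 580]])
        res = bonferroni_pairwise(cells_frame(y, "block"), factor="block")
        # subject-level marginal means over congruency
        m1, m2 = y[:, :, 0].mean(axis=1), y[:, :, 1].mean(axis=1)
        d = m1 - m2
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_exp = 2 * sps.t.sf(abs(t_exp), len(d) - 1)
        assert res[0].t == pytest.approx(t_exp, rel=1e-9)
        assert res[0].p_raw == pytest.approx(p_exp, rel=1e-9)
        assert res[0].df == 2


@pytest.fixture(scope="module")
def structural_cohort(default_trials):
    return simulate_cohort(22, master_seed=12345, trials=default_trials)


class TestRunAnalysis:
    def test_analysis1_report_shape(self, structural_cohort):
        report = run_analysis(structural_cohort, 1)
        assert report.group_table["mean"].shape == (2, 4)  # congruency x block
        assert report.anova.effect("congruency").p < 0.001
        assert report.posthoc is not None and len(report.posthoc) == 6

    def test_analysis3_report_shape(self, structural_cohort):
        report = run_analysis(structural_cohort, 3)
        assert report.group_table["mean"].shape[1] == 2  # fib vs skip
        assert report.posthoc is None
        assert report.factor_b == "grammar"

    def test_unknown_analysis_rejected(self, structural_cohort):
        with pytest.raises(ValueError):
            run_analysis(structural_cohort, 4)

    def test_static_cohort_shows_no_block_effect(self, default_trials):
        # no learning signal by construction: Block must be null in most runs
        nonsig = 0
        n_rep = 200
        for s in range(n_rep):
            cohort = simulate_cohort(
                22, LearnerSpec(kind="static"), RTParams(),
                master_seed=20_000 + s, trials=default_trials,
            )
            report = run_analysis(cohort, 1)
            if report.anova.effect("block").p >= 0.05:
                nonsig += 1
        assert nonsig >= int(0.9 * n_rep)

    def test_permutation_destroys_grammar_effect(self, structural_cohort):
        # relabelling grammars within subject should null the effect
        report = run_analysis(structural_cohort, 3)
        assert report.anova.effect("grammar").p < 0.05
        cells = report.cell_means
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(100):
            shuffled = cells.copy()
            for subj in shuffled.subject.unique():
                if rng.random() < 0.5:
                    mask = shuffled.subject == subj
                    shuffled.loc[mask, "grammar"] = shuffled.loc[mask, "grammar"].map(
                        {"fib": "skip", "skip": "fib"}
                    )
            res = rm_anova_two_way(shuffled, factor_b="grammar")
            pvals.append(res.effect("grammar").p)
        assert np.median(pvals) > 0.2
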