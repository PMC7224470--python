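"""Repeated-measures analyses of simulated Simon-task cohorts.

Three analyses, mirroring the experimental logic:

1. **First Law** — blue trials following a red; Congruency × Block (4).
2. **Second Law** — red trials following two blues; Congruency × Block (4).
3. **Hierarchy** — blue trials following a red–blue pair (k-points in Fib);
   Congruency × Grammar (Fib blocks pooled vs Skip).

Each analysis computes per-subject condition means over correct,
non-timeout target trials, a classical two-factor within-subject ANOVA
(complete balanced design; F ratios against the matching effect × subject
error terms; partial η² = SS_effect / (SS_effect + SS_error)), and, for the
block analyses, Bonferroni-corrected pairwise paired t-tests over the block
marginal means.  No sphericity correction is applied by default;
Greenhouse–Geisser-corrected p-values can be requested.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "PairwiseResult",
    "AnalysisReport",
    "EmptyCellError",
    "IncompleteDesignError",
    "condition_means",
    "rm_anova_two_way",
    "bonferroni_pairwise",
    "run_analysis",
]

logger = logging.getLogger(__name__)

ANALYSIS_SPEC = {
    1: ("a1", "block"),
    2: ("a2", "block"),
    3: ("a3", "grammar"),
}


class EmptyCellError(ValueError):
    def __init__(self, cells: list[tuple]):
        self.cells = cells
        super().__init__(
            "no usable RT trials in cell(s) "
            + ", ".join(f"(subject={s}, {a}, {b})" for s, a, b in cells)
        )


class IncompleteDesignError(ValueError):
    pass


def condition_means(
    cohort: pd.DataFrame,
    target_flag: str,
    factor_b: str,
    deadline: float | None = None,
) -> pd.DataFrame:
    """Per-subject cell means for one analysis.

    Rows: subject × congruency × factor-b level, with ``mean_rt`` over
    correct non-timeout target trials, ``accuracy`` over all target trials
    (timeouts count as errors), and ``n_trials`` contributing to the mean.
    Raises :class:`EmptyCellError` when a subject has a cell without any
    correct RT.
    """
    if target_flag not in ("a1", "a2", "a3"):
        raise ValueError(f"unknown target flag {target_flag!r}")
    if factor_b not in ("block", "grammar"):
        raise ValueError(f"unknown factor {factor_b!r}")
    targets = cohort[cohort[target_flag].astype(bool)].copy()

    rows = []
    empty: list[tuple] = []
    levels_b = sorted(targets[factor_b].unique())
    for (subject, cong), sub in targets.groupby(["subject", "congruency"]):
        for lvl in levels_b:
            cell = sub[sub[factor_b] == lvl]
            usable = cell[cell["correct"].astype(bool) & ~cell["timeout"].astype(bool)]
            if len(usable) == 0:
                empty.append((subject, cong, lvl))
                continue
            mean_rt = float(usable["rt_ms"].mean())
            if deadline is not None and mean_rt > deadline:
                raise ValueError(
                    f"cell mean {mean_rt:.1f} exceeds the deadline {deadline}"
                )
            rows.append(
                {
                    "subject": subject,
                    "congruency": cong,
                    factor_b: lvl,
                    "mean_rt": mean_rt,
                    "accuracy": float(cell["correct"].astype(bool).mean()),
                    "n_trials": int(len(usable)),
                }
            )
    if empty:
        raise EmptyCellError(empty)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    df: int
    ms: float
    f: float | None = None
    p: float | None = None
    partial_eta_sq: float | None = None


@dataclass
class AnovaResult:
    """Full decomposition of a two-factor within-subject design."""

    factor_a: str
    factor_b: str
    n_subjects: int
    levels_a: list
    levels_b: list
    effects: dict[str, AnovaEffect]
    ss_total: float
    gg_epsilon: dict[str, float] = field(default_factory=dict)

    def effect(self, name: str) -> AnovaEffect:
        return self.effects[name]

    def to_dict(self) -> dict:
        return {
            "factor_a": self.factor_a,
            "factor_b": self.factor_b,
            "n_subjects": self.n_subjects,
            "levels_a": list(self.levels_a),
            "levels_b": list(self.levels_b),
            "ss_total": self.ss_total,
            "effects": {k: asdict(v) for k, v in self.effects.items()},
        }


def rm_anova_two_way(
    cells: pd.DataFrame,
    factor_a: str = "congruency",
    factor_b: str | None = None,
    value: str = "mean_rt",
    gg_correction: bool = False,
) -> AnovaResult:
    """Classical two-factor within-subject ANOVA on a cell-means table.

    ``cells`` must hold exactly one value per subject × A-level × B-level
    (a complete, balanced design).  F for each effect uses its own
    effect × subject interaction as the error term.
    """
    if factor_b is None:
        candidates = [c for c in ("block", "grammar") if c in cells.columns]
        if len(candidates) != 1:
            raise ValueError("factor_b is ambiguous; pass it explicitly")
        factor_b = candidates[0]

    subjects = sorted(cells["subject"].unique())
    levels_a = sorted(cells[factor_a].unique())
    levels_b = sorted(cells[factor_b].unique())
    s, a, b = len(subjects), len(levels_a), len(levels_b)
    if s < 2:
        raise IncompleteDesignError("need at least 2 subjects")
    if a < 2 or b < 2:
        raise IncompleteDesignError("each factor needs at least 2 levels")

    pivot = cells.pivot_table(
        index="subject", columns=[factor_a, factor_b], values=value, aggfunc="mean"
    )
    expected = list(itertools.product(levels_a, levels_b))
    missing = [
        (subj, la, lb)
        for subj in subjects
        for la, lb in expected
        if (la, lb) not in pivot.columns or pd.isna(pivot.loc[subj, (la, lb)])
    ]
    if missing:
        raise IncompleteDesignError(f"missing cells: {missing[:10]}")

    y = np.empty((s, a, b))
    for i, subj in enumerate(subjects):
        for j, la in enumerate(levels_a):
            for k, lb in enumerate(levels_b):
                y[i, j, k] = pivot.loc[subj, (la, lb)]

    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_total = float(((y - gm) ** 2).sum())
    ss_subj = float(a * b * ((m_s - gm) ** 2).sum())
    ss_a = float(s * b * ((m_a - gm) ** 2).sum())
    ss_b = float(s * a * ((m_b - gm) ** 2).sum())
    ss_ab = float(
        s * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    )
    ss_as = float(
        b * ((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    )
    ss_bs = float(
        a * ((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    )
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_as, df_bs = df_a * (s - 1), df_b * (s - 1)
    df_abs = df_ab * (s - 1)

    def _ms(ss, df):
        return ss / df if df else np.nan

    effects: dict[str, AnovaEffect] = {}
    effects["subjects"] = AnovaEffect("subjects", ss_subj, s - 1, _ms(ss_subj, s - 1))
    for name, ss_e, df_e, ss_err, df_err in [
        (factor_a, ss_a, df_a, ss_as, df_as),
        (factor_b, ss_b, df_b, ss_bs, df_bs),
        (f"{factor_a}*{factor_b}", ss_ab, df_ab, ss_abs, df_abs),
    ]:
        ms_e, ms_err = _ms(ss_e, df_e), _ms(ss_err, df_err)
        f_val = ms_e / ms_err if ms_err > 0 else (0.0 if ms_e == 0 else np.inf)
        p_val = float(sps.f.sf(f_val, df_e, df_err)) if np.isfinite(f_val) else 0.0
        denom = ss_e + ss_err
        eta = ss_e / denom if denom > 0 else 0.0
        effects[name] = AnovaEffect(name, ss_e, df_e, ms_e, f_val, p_val, eta)
    effects[f"{factor_a}*subjects"] = AnovaEffect(
        f"{factor_a}*subjects", ss_as, df_as, _ms(ss_as, df_as)
    )
    effects[f"{factor_b}*subjects"] = AnovaEffect(
        f"{factor_b}*subjects", ss_bs, df_bs, _ms(ss_bs, df_bs)
    )
    effects[f"{factor_a}*{factor_b}*subjects"] = AnovaEffect(
        f"{factor_a}*{factor_b}*subjects", ss_abs, df_abs, _ms(ss_abs, df_abs)
    )

    result = AnovaResult(
        factor_a=factor_a,
        factor_b=factor_b,
        n_subjects=s,
        levels_a=levels_a,
        levels_b=levels_b,
        effects=effects,
        ss_total=ss_total,
    )
    if gg_correction:
        result.gg_epsilon = {
            factor_a: _gg_epsilon(m_sa),
            factor_b: _gg_epsilon(m_sb),
        }
    return result


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon for one within factor (subjects × levels)."""
    k = data.shape[1]
    if k < 3:
        return 1.0
    cov = np.cov(data, rowvar=False)
    mean_var = np.trace(cov) / k
    mean_cov = cov.mean()
    row_means = cov.mean(axis=1)
    num = (k * (mean_var - mean_cov)) ** 2
    den = (k - 1) * (
        (cov ** 2).sum() - 2 * k * (row_means ** 2).sum() + k ** 2 * mean_cov ** 2
    )
    return float(num / den) if den > 0 else 1.0


@dataclass(frozen=True)
class PairwiseResult:
    level_1: object
    level_2: object
    mean_diff: float
    t: float
    df: int
    p_raw: float
    p_bonferroni: float


def bonferroni_pairwise(
    subject_means: pd.DataFrame,
    factor: str,
    value: str = "mean_rt",
) -> list[PairwiseResult]:
    """Paired t-tests over all level pairs of ``factor``, Bonferroni-adjusted.

    ``subject_means`` needs one value per subject per level.  With L levels
    the multiplier is m = L(L−1)/2.  A pair with zero within-pair variance
    reports its mean difference with an undefined t (NaN) unless the
    difference is exactly zero, in which case t = 0 and p = 1.
    """
    pivot = subject_means.pivot_table(
        index="subject", columns=factor, values=value, aggfunc="mean"
    )
    levels = sorted(pivot.columns)
    if len(levels) < 2:
        raise ValueError("need at least 2 levels for pairwise comparisons")
    m = len(levels) * (len(levels) - 1) // 2
    out: list[PairwiseResult] = []
    for l1, l2 in itertools.combinations(levels, 2):
        d = pivot[l1] - pivot[l2]
        diff = float(d.mean())
        if float(d.std(ddof=1)) == 0.0:
            if diff == 0.0:
                t_val, p_raw = 0.0, 1.0
            else:
                logger.warning(
                    "degenerate zero within-pair variance for (%s, %s)", l1, l2
                )
                t_val, p_raw = float("nan"), float("nan")
        else:
            t_val, p_raw = sps.ttest_rel(pivot[l1], pivot[l2])
            t_val, p_raw = float(t_val), float(p_raw)
        p_adj = min(1.0, m * p_raw) if np.isfinite(p_raw) else float("nan")
        out.append(
            PairwiseResult(
                level_1=l1,
                level_2=l2,
                mean_diff=diff,
                t=t_val,
                df=len(d) - 1,
                p_raw=p_raw,
                p_bonferroni=p_adj,
            )
        )
    return out


@dataclass
class AnalysisReport:
    """Bundle for one analysis: descriptives, ANOVA, and optional post-hocs."""

    analysis: int
    target_flag: str
    factor_b: str
    cell_means: pd.DataFrame          # per-subject table
    group_table: pd.DataFrame         # condition mean (SD) over subjects
    accuracy_table: pd.DataFrame
    anova: AnovaResult
    posthoc: list[PairwiseResult] | None
    dropped_subjects: list

    def to_dict(self) -> dict:
        def flat(df: pd.DataFrame) -> list[dict]:
            out = df.copy()
            out.columns = [
                "_".join(str(p) for p in c) if isinstance(c, tuple) else str(c)
                for c in out.columns
            ]
            return out.reset_index().to_dict(orient="records")

        return {
            "analysis": self.analysis,
            "target_flag": self.target_flag,
            "factor_b": self.factor_b,
            "group_table": flat(self.group_table),
            "accuracy_table": flat(self.accuracy_table),
            "anova": self.anova.to_dict(),
            "posthoc": [asdict(p) for p in self.posthoc] if self.posthoc else None,
            "dropped_subjects": list(self.dropped_subjects),
        }


def run_analysis(cohort: pd.DataFrame, which: int) -> AnalysisReport:
    """Run one of the three analyses on a cohort table.

    Subjects with an empty cell (no correct RT in some condition) are
    dropped listwise with a logged warning.  RT is the analysed variable;
    accuracy is reported descriptively only.
    """
    if which not in ANALYSIS_SPEC:
        raise ValueError(f"analysis must be 1, 2 or 3, got {which}")
    target_flag, factor_b = ANALYSIS_SPEC[which]

    dropped: list = []
    data = cohort
    while True:
        try:
            cells = condition_means(data, target_flag, factor_b)
            break
        except EmptyCellError as exc:
            bad = sorted({int(c[0]) for c in exc.cells})
            dropped.extend(bad)
            logger.warning(
                "analysis %d: dropping subject(s) %s with empty cells", which, bad
            )
            data = data[~data["subject"].isin(bad)]
            if data["subject"].nunique() < 2:
                raise IncompleteDesignError(
                    "fewer than 2 subjects left after dropping empty cells"
                ) from exc

    anova = rm_anova_two_way(cells, factor_a="congruency", factor_b=factor_b)
    group_table = cells.pivot_table(
        index="congruency", columns=factor_b, values="mean_rt",
        aggfunc=["mean", "std"],
    )
    accuracy_table = cells.pivot_table(
        index="congruency", columns=factor_b, values="accuracy",
        aggfunc=["mean", "std"],
    )
    posthoc = None
    if factor_b == "block":
        posthoc = bonferroni_pairwise(cells, factor="block")
    return AnalysisReport(
        analysis=which,
        target_flag=target_flag,
        factor_b=factor_b,
        cell_means=cells,
        group_table=group_table,
        accuracy_table=accuracy_table,
        anova=anova,
        posthoc=posthoc,
        dropped_subjects=dropped,
    )
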