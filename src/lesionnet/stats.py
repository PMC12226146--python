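"""Group-comparison and correlation statistics for metric and cognition
tables.

The battery mirrors a standard between-groups connectome analysis:
Mann-Whitney U tests for whole-brain metrics (Bonferroni family of 4),
chi-square tests for hub-frequency tables, mixed-design ANOVAs (group x
node) with Greenhouse-Geisser correction gated on Mauchly's test, Pearson
correlation grids between graph metrics and cognitive domain w-scores with
explicit Bonferroni families, McNemar's test for paired significance
patterns, and partial-eta-squared effect-size grading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "TestResult",
    "mann_whitney",
    "chi_square_2x2",
    "mixed_anova",
    "log_transform_if_nonnormal",
    "correlation_matrix",
    "mcnemar",
    "grade_effect_size",
]


@dataclass
class TestResult:
    """One statistical test with multiplicity-adjusted p and effect size."""

    __test__ = False  # not a pytest class

    name: str
    statistic: float
    p: float
    df: tuple | None = None
    family_size: int = 1
    effect_size: float | None = None
    effect_size_name: str | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def p_bonf(self) -> float:
        return min(1.0, self.family_size * self.p)

    @property
    def effect_grade(self) -> str | None:
        if self.effect_size is None or self.effect_size_name != "eta_p2":
            return None
        return grade_effect_size(self.effect_size)


def grade_effect_size(eta_p2: float) -> str:
    """Grade a partial eta squared: small < 0.060 <= moderate <= 0.140 < large."""
    if not 0 <= eta_p2 <= 1:
        raise ValueError(f"eta_p2 must lie in [0, 1], got {eta_p2}")
    if eta_p2 < 0.060:
        return "small"
    if eta_p2 <= 0.140:
        return "moderate"
    return "large"


def mann_whitney(group_a, group_b, family_size: int = 1) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration for small tie-free samples (both n <= 20) and
    the tie-corrected normal approximation otherwise.  If every value is
    tied across both groups the test is degenerate and p = 1 is returned
    with a diagnostic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    if np.unique(np.concatenate([a, b])).size == 1:
        return TestResult(
            name="mann-whitney",
            statistic=float(a.size * b.size / 2),
            p=1.0,
            family_size=family_size,
            diagnostics={"degenerate": "all values tied across both groups"},
        )
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = a.size <= 20 and b.size <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        name="mann-whitney",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        family_size=family_size,
        diagnostics={"method": method},
    )


def chi_square_2x2(table, family_size: int = 1, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 count table (no continuity correction by
    default).  A zero row or column margin makes the test undefined."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("table must be 2x2 non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return TestResult(
            name="chi-square",
            statistic=float("nan"),
            p=float("nan"),
            df=(1,),
            family_size=family_size,
            diagnostics={"degenerate": "zero margin"},
        )
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=correction)
    return TestResult(
        name="chi-square", statistic=float(chi2), p=float(p), df=(int(dof),),
        family_size=family_size,
    )


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "node",
    subject: str = "subject",
    between: str = "group",
    mauchly_alpha: float = 0.05,
    family_size: int = 1,
) -> dict[str, TestResult]:
    """Mixed-design (split-plot) ANOVA: one between factor, one within.

    Returns TestResults for the between-group effect, the within effect and
    the interaction.  When Mauchly's test rejects sphericity (p <
    ``mauchly_alpha``) and the within factor has more than two levels, the
    within and interaction p-values use Greenhouse-Geisser epsilon-adjusted
    degrees of freedom; the epsilon used is reported in the diagnostics.
    Requires complete data (every subject measured at every within level).
    """
    counts = data.groupby(subject, observed=True)[within].nunique()
    k = data[within].nunique()
    if (counts != k).any():
        missing = counts[counts != k].index.tolist()
        raise ValueError(f"incomplete within-factor data for subjects: {missing}")
    n_per_group = data.groupby(between, observed=True)[subject].nunique()
    if (n_per_group < 2).any():
        raise ValueError("need at least 2 subjects per group")

    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, subject=subject, between=between,
        correction=True,
    ).set_index("Source")

    eps = float(aov.loc[within, "eps"]) if k > 2 else 1.0
    p_spher_raw = aov.loc[within, "p_spher"] if "p_spher" in aov.columns else np.nan
    p_spher = float(p_spher_raw) if np.isfinite(p_spher_raw) else 1.0
    use_gg = k > 2 and p_spher < mauchly_alpha

    out: dict[str, TestResult] = {}
    between_row = aov.loc[between]
    out["between"] = TestResult(
        name="mixed-anova between",
        statistic=float(between_row["F"]),
        p=float(between_row["p_unc"]),
        df=(int(between_row["DF1"]), int(between_row["DF2"])),
        family_size=family_size,
        effect_size=float(between_row["np2"]),
        effect_size_name="eta_p2",
    )
    for label, src in (("within", within), ("interaction", "Interaction")):
        row = aov.loc[src]
        df1, df2, f = float(row["DF1"]), float(row["DF2"]), float(row["F"])
        if use_gg:
            p = float(sps.f.sf(f, eps * df1, eps * df2))
            df_rep = (eps * df1, eps * df2)
        else:
            p = float(row["p_unc"])
            df_rep = (df1, df2)
        out[label] = TestResult(
            name=f"mixed-anova {label}",
            statistic=f,
            p=p,
            df=df_rep,
            family_size=family_size,
            effect_size=float(row["np2"]),
            effect_size_name="eta_p2",
            diagnostics={"gg_epsilon": eps, "gg_applied": use_gg, "mauchly_p": p_spher},
        )
    return out


def log_transform_if_nonnormal(values, alpha: float = 0.05) -> tuple[np.ndarray, dict]:
    """Natural-log transform a variable if Shapiro-Wilk rejects normality.

    Zeros are handled with an offset of half the smallest positive value
    (recorded in the returned flags); negative values are an error since
    the normalized graph metrics this is applied to are non-negative.
    Constant vectors are returned unchanged with a diagnostic.
    """
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("negative values: log transform undefined")
    flags: dict = {"transformed": False, "offset": 0.0}
    if np.unique(x).size == 1:
        flags["degenerate"] = "constant vector; Shapiro-Wilk undefined"
        return x, flags
    stat, p = sps.shapiro(x)
    flags["shapiro_p"] = float(p)
    if p >= alpha:
        return x, flags
    offset = 0.0
    if (x == 0).any():
        offset = float(x[x > 0].min() / 2)
    flags.update(transformed=True, offset=offset)
    return np.log(x + offset), flags


def correlation_matrix(
    cognition: pd.DataFrame,
    metrics: pd.DataFrame,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Pearson correlation grid between metric columns and cognitive domain
    columns over the common subjects.

    Returns a long-format DataFrame with one row per (metric, domain) cell:
    r, df = n-2, two-sided p, and Bonferroni-adjusted p with the supplied
    family size (default: the number of cells in the grid).  Cells with a
    zero-variance column are flagged undefined (NaN).
    """
    common = cognition.index.intersection(metrics.index)
    if len(common) < 4:
        raise ValueError("need at least 4 complete subject pairs")
    cog = cognition.loc[common]
    met = metrics.loc[common]
    m = family_size if family_size is not None else len(cog.columns) * len(met.columns)

    rows = []
    for mc in met.columns:
        for cc in cog.columns:
            x = met[mc].to_numpy(dtype=float)
            y = cog[cc].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < 4 or x[ok].std() == 0 or y[ok].std() == 0:
                rows.append(
                    {"metric": mc, "domain": cc, "n": n, "df": max(n - 2, 0),
                     "r": np.nan, "p": np.nan, "p_bonf": np.nan,
                     "flag": "undefined (zero variance or too few pairs)"}
                )
                continue
            r, p = sps.pearsonr(x[ok], y[ok])
            rows.append(
                {"metric": mc, "domain": cc, "n": n, "df": n - 2,
                 "r": float(r), "p": float(p), "p_bonf": min(1.0, m * float(p)),
                 "flag": ""}
            )
    out = pd.DataFrame(rows)
    out.attrs["family_size"] = m
    return out


def mcnemar(paired_flags_a, paired_flags_b, exact_threshold: int = 25) -> TestResult:
    """McNemar's test on two paired boolean vectors.

    Uses the exact binomial test when the discordant count b + c is below
    ``exact_threshold`` and the chi-square statistic (b - c)^2 / (b + c)
    without continuity correction otherwise.  The chi-square statistic is
    reported in both cases; b + c = 0 gives p = 1 with a diagnostic.
    """
    a = np.asarray(paired_flags_a, dtype=bool)
    b = np.asarray(paired_flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired flag vectors must have equal length")
    n_b = int((a & ~b).sum())
    n_c = int((~a & b).sum())
    if n_b + n_c == 0:
        return TestResult(
            name="mcnemar", statistic=0.0, p=1.0, df=(1,),
            diagnostics={"b": n_b, "c": n_c, "degenerate": "no discordant pairs"},
        )
    chi2 = (n_b - n_c) ** 2 / (n_b + n_c)
    table = np.array([[int((a & b).sum()), n_b], [n_c, int((~a & ~b).sum())]])
    exact = (n_b + n_c) < exact_threshold
    res = _sm_mcnemar(table, exact=exact, correction=False)
    return TestResult(
        name="mcnemar",
        statistic=float(chi2),
        p=float(res.pvalue),
        df=(1,),
        diagnostics={"b": n_b, "c": n_c, "exact": exact},
    )
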