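"""Group-level statistics: within-subject SEM, rm-ANOVA, Dunn-Šidák contrasts.

Repeated-measures ANOVA (with Mauchly's sphericity test and Greenhouse-Geisser
correction) is delegated to pingouin; this module adds the conventions used
throughout the package: Cousineau-centered within-subject error bars, the
Dunn-Šidák family-wise correction, and paired post-hoc contrasts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps


def within_subject_sem(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    subject: str = "subject",
    morey: bool = False,
) -> pd.Series:
    """Per-condition SEM after removing overall between-subject variance.

    Each subject's mean across conditions is subtracted and the grand mean
    restored (Cousineau centering) before taking the per-condition SD/sqrt(N).
    ``morey=True`` applies the Morey bias correction factor sqrt(L/(L-1)).
    """
    wide = table.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("missing cells: the within-subject design must be complete")
    n_subjects, n_levels = wide.shape
    if n_subjects < 2:
        raise ValueError("within-subject SEM needs at least 2 subjects")
    centered = wide.sub(wide.mean(axis=1), axis=0) + wide.to_numpy().mean()
    sem = centered.std(ddof=1) / np.sqrt(n_subjects)
    if morey:
        sem = sem * np.sqrt(n_levels / (n_levels - 1))
    sem.name = "sem"
    return sem


def _mauchly_p(data: pd.DataFrame, dv: str, within: str, subject: str) -> float:
    """Mauchly test p-value; 1.0 when the factor has < 3 levels (trivially met)."""
    if data[within].nunique() < 3:
        return 1.0
    res = pg.sphericity(data, dv=dv, within=within, subject=subject)
    return float(res.pval)


def rm_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: str | Sequence[str] = "condition",
    subject: str = "subject",
    alpha_sphericity: float = 0.05,
) -> pd.DataFrame:
    """Repeated-measures ANOVA with sphericity handling.

    One or two within-subject factors.  The Greenhouse-Geisser epsilon is
    reported for every effect; degrees of freedom and the p-value are
    GG-corrected when Mauchly's test rejects sphericity (for the two-way
    interaction, where Mauchly is not available, whenever epsilon < 1).

    Returns columns: source, F, df1, df2, p_unc, p_gg, eps, mauchly_p,
    sphericity_met, df1_corr, df2_corr, p.
    """
    factors = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(factors) <= 2:
        raise ValueError("rm_anova supports 1 or 2 within-subject factors")
    cells = table.groupby([subject, *factors], observed=True)[dv].count()
    if (cells != 1).any():
        agg = table.groupby([subject, *factors], observed=True, as_index=False)[dv].mean()
    else:
        agg = table
    aov = pg.rm_anova(
        data=agg, dv=dv, within=factors if len(factors) > 1 else factors[0],
        subject=subject, correction=True, detailed=True,
    )
    if "ddof1" not in aov.columns:  # one-way detailed layout: DF + Error row
        err_df = float(aov.loc[aov["Source"] == "Error", "DF"].iloc[0])
        aov = aov[aov["Source"] != "Error"].reset_index(drop=True)
        aov = aov.rename(columns={"DF": "ddof1"})
        aov["ddof2"] = err_df
    else:
        aov = aov[aov["Source"] != "Error"].reset_index(drop=True)

    rows = []
    for _, eff in aov.iterrows():
        source = eff["Source"]
        f_val = float(eff["F"])
        df1, df2 = float(eff["ddof1"]), float(eff["ddof2"])
        eps = float(eff["eps"]) if "eps" in eff and np.isfinite(eff.get("eps", np.nan)) else 1.0
        if " * " in source:
            mauchly_p = np.nan  # not exposed for interactions
            correct = eps < 1.0 - 1e-12
        else:
            collapsed = agg.groupby([subject, source], observed=True, as_index=False)[dv].mean()
            mauchly_p = _mauchly_p(collapsed, dv, source, subject)
            if collapsed[source].nunique() < 3:
                eps = 1.0
            correct = mauchly_p < alpha_sphericity
        df1_c, df2_c = (df1 * eps, df2 * eps) if correct else (df1, df2)
        p_unc = float(eff["p_unc"])
        p_gg = float(sps.f.sf(f_val, df1 * eps, df2 * eps)) if np.isfinite(f_val) else np.nan
        rows.append(
            {
                "source": source,
                "F": f_val,
                "df1": df1,
                "df2": df2,
                "p_unc": p_unc,
                "p_gg": p_gg,
                "eps": eps,
                "mauchly_p": mauchly_p,
                "sphericity_met": not correct,
                "df1_corr": df1_c,
                "df2_corr": df2_c,
                "p": p_gg if correct else p_unc,
            }
        )
    return pd.DataFrame(rows)


def dunn_sidak(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Dunn-Šidák family-wise adjustment: p_adj = 1 − (1 − p)^m, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def paired_comparisons(
    table: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]],
    dv: str = "value",
    within: str = "condition",
    subject: str = "subject",
    m: int | None = None,
) -> pd.DataFrame:
    """Two-sided paired t-tests over a family of contrasts, Dunn-Šidák adjusted.

    Identical paired vectors yield t = 0, p = 1; a constant nonzero difference
    yields an infinite t statistic and p = 0.
    """
    wide = table.pivot(index=subject, columns=within, values=dv)
    if wide.shape[0] < 3:
        raise ValueError("paired comparisons need at least 3 subjects")
    rows = []
    for a, b in contrasts:
        for level in (a, b):
            if level not in wide.columns:
                raise ValueError(f"unknown level {level!r}")
        diff = wide[a] - wide[b]
        if np.allclose(diff, diff.iloc[0]):
            d0 = float(diff.iloc[0])
            t, p = (0.0, 1.0) if d0 == 0.0 else (np.inf * np.sign(d0), 0.0)
        else:
            t, p = sps.ttest_rel(wide[a], wide[b])
        rows.append({"contrast": f"{a} - {b}", "t": float(t),
                     "df": wide.shape[0] - 1, "p_unc": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = dunn_sidak(out["p_unc"].to_numpy(), m=m or len(contrasts))
    return out
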