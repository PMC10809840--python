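"""Group-level statistics: Box-Cox, repeated-measures ANOVA, Tukey HSD,
and relative topography tables.

The repeated-measures structure (subjects as a random factor) is realized as
an OLS model with subject entered as a blocking factor; for the balanced
designs produced by this pipeline its F tests coincide with the
random-intercept (compound-symmetry) mixed model.  Observations are
per-subject x channel x condition means of epoch features, aggregated before
testing so epoch counts do not inflate degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = ["AnovaResult", "boxcox_transform", "repeated_anova", "topography"]


def boxcox_transform(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform with maximum-likelihood lambda.

    Non-positive inputs are shifted to be strictly positive (shift
    ``-min + eps`` with eps a millionth of the range); the shift is returned
    so the transform is reproducible.  Constant input raises
    :class:`DataError`.

    Returns ``(transformed, lmbda, shift)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.ptp(values) == 0:
        raise DataError("Box-Cox requires non-constant input")
    shift = 0.0
    if values.min() <= 0:
        shift = -values.min() + 1e-6 * max(np.ptp(values), 1.0)
    transformed, lmbda = sps.boxcox(values + shift)
    return transformed, float(lmbda), shift


@dataclass
class AnovaResult:
    """Per-factor F table, post-hoc pairwise comparisons, and diagnostics."""

    table: pd.DataFrame                     # factor, F, df_num, df_den, p
    posthoc: pd.DataFrame | None = None     # Tukey HSD pairwise table
    flagged_terms: list[str] = field(default_factory=list)
    boxcox_lambda: float | None = None

    def p_value(self, factor: str) -> float:
        row = self.table[self.table["factor"] == factor]
        if row.empty:
            raise KeyError(f"no factor {factor!r} in ANOVA table")
        return float(row["p"].iloc[0])


def _aggregate(table: pd.DataFrame, value: str, subject: str,
               factors: list[str]) -> pd.DataFrame:
    agg = (table.dropna(subset=[value])
                .groupby([subject, *factors], observed=True)[value]
                .mean().reset_index())
    return agg


def repeated_anova(table: pd.DataFrame, value: str = "value",
                   subject: str = "subject",
                   factors: tuple[str, ...] = ("period", "channel"),
                   boxcox: bool = False,
                   posthoc_factor: str | None = None) -> AnovaResult:
    """Repeated-measures ANOVA with subject as a random (blocking) factor.

    ``table`` is a long-format frame with one value column plus subject and
    factor columns; values are first averaged per subject x factor cell.
    Main effects and all two-way interactions between the fixed factors are
    tested at alpha = 0.05, two-tailed.  Empty design cells flag the affected
    interaction terms rather than silently dropping them.  Tukey HSD is run
    on ``posthoc_factor`` (default: the first factor).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    factors = list(factors)
    if len(table[subject].unique()) < 2:
        raise DataError("repeated ANOVA needs at least two subjects")
    for f in factors:
        if table[f].nunique() < 2:
            raise DataError(f"factor {f!r} needs at least two levels")

    agg = _aggregate(table, value, subject, factors)
    lam = None
    if boxcox:
        transformed, lam, _ = boxcox_transform(agg[value].to_numpy())
        agg = agg.assign(**{value: transformed})

    flagged = []
    for i, fa in enumerate(factors):
        for fb in factors[i + 1:]:
            cells = pd.crosstab(agg[fa], agg[fb])
            if (cells == 0).any().any():
                flagged.append(f"{fa}:{fb}")
                warnings.warn(f"empty cells in {fa} x {fb}; interaction "
                              "estimate unreliable", stacklevel=2)

    # Classical univariate repeated-measures decomposition: each
    # within-subject main effect is tested against its own subject
    # interaction mean square (exact for two-level factors regardless of the
    # within-subject covariance); fixed-factor interactions are tested
    # against the remaining (highest-order) residual.
    main = " + ".join(f"C({f})" for f in factors)
    inter = [f"C({fa}):C({fb})" for i, fa in enumerate(factors)
             for fb in factors[i + 1:]]
    subj_inter = [f"C({f}):C({subject})" for f in factors]
    formula = f"{value} ~ {main}"
    if inter:
        formula += " + " + " + ".join(inter)
    formula += f" + C({subject}) + " + " + ".join(subj_inter)
    fit = smf.ols(formula, data=agg).fit()
    anova = sm.stats.anova_lm(fit, typ=2)

    def _ms(term: str) -> tuple[float, float]:
        row = anova.loc[term]
        return float(row["sum_sq"]), float(row["df"])

    res_ss, res_df = _ms("Residual")
    if res_df <= 0:
        raise DataError("design leaves no residual degrees of freedom")

    def _pretty(term: str) -> str:
        return term.replace("C(", "").replace(")", "").replace(":", " x ")

    rows = []
    for f in factors:
        ss, df = _ms(f"C({f})")
        ess, edf = _ms(f"C({f}):C({subject})")
        if edf <= 0 or ess <= 0:
            ess, edf = res_ss, res_df
        fstat = (ss / df) / (ess / edf)
        rows.append({"factor": f, "F": fstat, "df_num": df, "df_den": edf,
                     "p": float(sps.f.sf(fstat, df, edf))})
    for term in inter:
        ss, df = _ms(term)
        fstat = (ss / df) / (res_ss / res_df)
        rows.append({"factor": _pretty(term), "F": fstat, "df_num": df,
                     "df_den": res_df, "p": float(sps.f.sf(fstat, df, res_df))})
    ss, df = _ms(f"C({subject})")
    fstat = (ss / df) / (res_ss / res_df)
    rows.append({"factor": f"{subject} (random)", "F": fstat, "df_num": df,
                 "df_den": res_df, "p": float(sps.f.sf(fstat, df, res_df))})
    result = AnovaResult(table=pd.DataFrame(rows), flagged_terms=flagged,
                         boxcox_lambda=lam)

    ph_factor = posthoc_factor or factors[0]
    if agg[ph_factor].nunique() >= 2:
        hsd = pairwise_tukeyhsd(agg[value].to_numpy(),
                                agg[ph_factor].astype(str).to_numpy())
        frame = pd.DataFrame(hsd.summary().data[1:],
                             columns=hsd.summary().data[0])
        result.posthoc = frame
    return result


def topography(table: pd.DataFrame, feature: str,
               value: str = "value", channel: str = "channel",
               label: str = "label",
               stage: str | None = None) -> pd.DataFrame:
    """Relative per-contact change of a feature vs the nonseizure baseline.

    For each contact: 100 * (F_condition - F_nonseizure) / F_nonseizure,
    where the condition is the whole seizure period (``stage=None``) or one
    of S1/S2/S3.  Contacts with a non-positive baseline are flagged and get
    NaN.  Returns a frame with columns ``channel, percent, flagged``.
    """
    sub = table[table["feature"] == feature] if "feature" in table else table
    if sub.empty:
        raise DataError(f"feature {feature!r} absent from the table")
    is_seiz = sub[label] != "nonseizure"
    if stage is not None:
        is_seiz = sub[label] == stage
    base = (sub[sub[label] == "nonseizure"]
            .groupby(channel, observed=True)[value].mean())
    cond = sub[is_seiz].groupby(channel, observed=True)[value].mean()
    out = []
    for ch in base.index:
        b = base[ch]
        c = cond.get(ch, np.nan)
        if not np.isfinite(b) or b <= 0:
            out.append({"channel": ch, "percent": np.nan, "flagged": True})
        else:
            out.append({"channel": ch, "percent": 100.0 * (c - b) / b,
                        "flagged": False})
    return pd.DataFrame(out)
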