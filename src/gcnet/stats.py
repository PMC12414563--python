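"""Group-level inference: planned two-tailed contrasts with Bonferroni
correction, and an omnibus mixed model with subject as a random factor.

Planned contrasts are classical pooled-variance two-sample t-tests; subjects
whose value is missing (an undefined directional index) are dropped and
counted.  The omnibus model (value ~ group * band [* direction] with a
subject random intercept) is delegated to statsmodels MixedLM, fitted by
maximum likelihood, with likelihood-ratio chi-squares reported per term in a
sequential (type-I) decomposition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ContrastResult", "planned_contrast", "omnibus_model"]


@dataclass
class ContrastResult:
    measure: str
    band: str
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    mean_low: float
    mean_high: float
    sem_low: float
    sem_high: float
    n_low: int
    n_high: int
    n_dropped: int
    degenerate: bool = False


def planned_contrast(
    values_low,
    values_high,
    family_size: int = 1,
    *,
    measure: str = "",
    band: str = "",
    welch: bool = False,
) -> ContrastResult:
    """Two-tailed two-sample t contrast with Bonferroni correction.

    Pooled-variance (Student) by default; Welch optionally.  Missing values
    (NaN/None) are dropped per group and counted in ``n_dropped``.
    """
    lo = np.asarray([v for v in values_low if v is not None], dtype=float)
    hi = np.asarray([v for v in values_high if v is not None], dtype=float)
    lo = lo[np.isfinite(lo)]
    hi = hi[np.isfinite(hi)]
    n_dropped = (len(values_low) + len(values_high)) - (lo.size + hi.size)
    if lo.size < 2 or hi.size < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")

    df = lo.size + hi.size - 2
    pooled = (((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()) / df
    degenerate = pooled == 0
    if degenerate and lo.mean() == hi.mean():
        t, p = 0.0, 1.0
    elif degenerate:
        t, p = np.nan, np.nan
    else:
        res = sps.ttest_ind(lo, hi, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        if welch:
            df = int(np.floor(res.df))
    return ContrastResult(
        measure=measure, band=band, t=t, df=df, p_raw=p,
        p_bonferroni=min(1.0, p * family_size) if np.isfinite(p) else np.nan,
        mean_low=float(lo.mean()), mean_high=float(hi.mean()),
        sem_low=float(lo.std(ddof=1) / np.sqrt(lo.size)),
        sem_high=float(hi.std(ddof=1) / np.sqrt(hi.size)),
        n_low=int(lo.size), n_high=int(hi.size),
        n_dropped=int(n_dropped), degenerate=bool(degenerate),
    )


def _term_formulas(factors: list[str]) -> list[tuple[str, str]]:
    """Sequential model-building terms: main effects then interactions of
    increasing order, e.g. group, band, group:band."""
    terms = []
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            terms.append((":".join(combo),
                          ":".join(f"C({f})" for f in combo)))
    return terms


def omnibus_model(
    table: pd.DataFrame,
    value_col: str = "value",
    factors: tuple[str, ...] = ("group", "band"),
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Omnibus mixed model with a subject random intercept.

    Fits a sequence of nested MixedLM models adding one term at a time
    (main effects, then interactions) and reports the likelihood-ratio
    chi-square, df and p of each added term.  Rows with missing values are
    dropped.  If any fit fails to converge the function falls back to an
    empty table with a ``warning`` attribute set, leaving per-band planned
    contrasts as the inference route.
    """
    import statsmodels.formula.api as smf

    data = table.dropna(subset=[value_col]).copy()
    if data.empty:
        raise ValueError("no non-missing observations")
    terms = _term_formulas(list(factors))
    rows = []
    prev_llf = None
    prev_df = None
    rhs_parts: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = smf.mixedlm(f"{value_col} ~ 1", data,
                               groups=data[subject_col]).fit(reml=False)
        if not np.isfinite(null.llf):
            raise RuntimeError("degenerate null fit")
        prev_llf, prev_df = null.llf, null.df_modelwc
        for name, rhs in terms:
            rhs_parts.append(rhs)
            formula = f"{value_col} ~ " + " + ".join(rhs_parts)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(formula, data,
                                  groups=data[subject_col]).fit(reml=False)
            if not np.isfinite(fit.llf):
                raise RuntimeError(f"degenerate fit for term {name}")
            lr = 2 * (fit.llf - prev_llf)
            df_term = fit.df_modelwc - prev_df
            p = sps.chi2.sf(max(lr, 0.0), df_term) if df_term > 0 else np.nan
            rows.append({"term": name, "chi2": max(float(lr), 0.0),
                         "df": int(df_term), "p": float(p)})
            prev_llf, prev_df = fit.llf, fit.df_modelwc
    except Exception as exc:  # singular / non-converging fit
        out = pd.DataFrame(columns=["term", "chi2", "df", "p"])
        out.attrs["warning"] = (
            f"mixed model failed ({exc}); report per-band contrasts instead")
        return out
    return pd.DataFrame(rows)
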