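"""Individual-level interaction models: chemical PC scores vs. MHC diversity.

Each model regresses one chemical principal-component score on one MHC
functional-diversity measure, sex, breeding status (days relative to
hatch), and the diversity x sex and diversity x breeding-status
interactions:

    score ~ div + sex + status + div:sex + div:status

Term significance uses an ANOVA with Type III sums of squares, which
requires sum-to-zero contrasts for the categorical sex term; a
treatment-coded (reference F) coefficient table is reported alongside
because published coefficient tables rarely state their coding. Simple
slopes (per-sex slope of the score on diversity, and slopes at mean and
mean +/- 1 s.d. breeding status) are derived algebraically from the
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


@dataclass
class SimpleSlope:
    label: str
    slope: float
    se: float
    p_value: float


class MHCDiversityResults:
    """Fitted interaction model: coefficients, Type III tests, slopes."""

    def __init__(self, model: "MHCDiversityModel", fit_sum, fit_treat, anova3: pd.DataFrame):
        self.model = model
        self._fit = fit_sum
        self._fit_treatment = fit_treat
        self.anova_type3 = anova3
        self.params = fit_sum.params
        self.bse = fit_sum.bse
        self.conf_int = fit_sum.conf_int(alpha=0.05)
        self.rsquared_adj = float(fit_sum.rsquared_adj)
        self.fvalue = float(fit_sum.fvalue)
        self.df_model = int(fit_sum.df_model)
        self.df_resid = int(fit_sum.df_resid)
        self.f_pvalue = float(fit_sum.f_pvalue)
        self.fittedvalues = fit_sum.fittedvalues
        self.resid = fit_sum.resid
        self.simple_slopes = self._sex_slopes()
        self.status_slices = self._status_slices()

    # -- derived slopes ----------------------------------------------

    def _coef_names(self) -> dict[str, str]:
        div, sex, st = self.model.diversity, self.model.sex_col, self.model.status_col
        names = {n: n for n in self.params.index}
        out = {"div": div, "status": st}
        for n in names:
            if n.startswith(f"C({sex}, Sum)"):
                out["sex"] = n
            if ":" in n and n.startswith(div) and f"C({sex}, Sum)" in n:
                out["div_sex"] = n
            if ":" in n and n.startswith(div) and n.endswith(st):
                out["div_status"] = n
        return out

    def _lincom(self, weights: dict[str, float], label: str) -> SimpleSlope:
        vec = pd.Series(0.0, index=self.params.index)
        for name, w in weights.items():
            vec[name] = w
        tt = self._fit.t_test(vec.to_numpy())
        return SimpleSlope(label, float(np.squeeze(tt.effect)), float(np.squeeze(tt.sd)),
                           float(np.squeeze(tt.pvalue)))

    def _sex_slopes(self) -> dict[str, SimpleSlope]:
        c = self._coef_names()
        st_mean = float(self.model.data[self.model.status_col].mean())
        # Sum contrasts over levels (F, M): the kept column codes F=+1, M=-1
        out = {}
        for sex, code in (("F", 1.0), ("M", -1.0)):
            w = {c["div"]: 1.0, c["div_sex"]: code, c["div_status"]: st_mean}
            out[sex] = self._lincom(w, f"slope of {self.model.response} on "
                                       f"{self.model.diversity}, sex={sex}")
        return out

    def _status_slices(self) -> dict[str, SimpleSlope]:
        c = self._coef_names()
        st = self.model.data[self.model.status_col]
        mean, sd = float(st.mean()), float(st.std(ddof=1))
        out = {}
        for label, val in (("early", mean - sd), ("mid", mean), ("late", mean + sd)):
            # sex-averaged slope: Sum-coded sex contributes 0 at the average
            w = {c["div"]: 1.0, c["div_status"]: val}
            out[label] = self._lincom(w, f"slope at {label} incubation (status={val:.2f} d)")
        return out

    # -- reporting ----------------------------------------------------

    def term_table(self) -> pd.DataFrame:
        """Tidy per-term report: estimate, s.e., 95% CI, Type III p."""
        rows = []
        p3 = {self._strip(t): p for t, p in self.anova_type3["PR(>F)"].items()}
        for name in self.params.index:
            key = self._strip(name)
            rows.append({
                "term": name,
                "estimate": float(self.params[name]),
                "se": float(self.bse[name]),
                "ci_low": float(self.conf_int.loc[name, 0]),
                "ci_high": float(self.conf_int.loc[name, 1]),
                "p_type3": p3.get(key, np.nan),
            })
        return pd.DataFrame(rows)

    @staticmethod
    def _strip(term: str) -> str:
        return term.split("[")[0].replace("]", "")

    def summary(self) -> str:
        lines = [
            f"MHC diversity model: {self.model.response} ~ {self.model.diversity} * "
            f"({self.model.sex_col} + {self.model.status_col})",
            f"n = {len(self.model.data)}, adj. R^2 = {self.rsquared_adj:.3f}, "
            f"F({self.df_model}, {self.df_resid}) = {self.fvalue:.3f}, "
            f"p = {self.f_pvalue:.4g}",
            "",
            self.term_table().to_string(index=False, float_format=lambda v: f"{v: .4f}"),
            "",
            "simple slopes (response on diversity):",
        ]
        for s in list(self.simple_slopes.values()) + list(self.status_slices.values()):
            lines.append(f"  {s.label}: slope = {s.slope:.3f} (se {s.se:.3f}), p = {s.p_value:.4g}")
        return "\n".join(lines)


class MHCDiversityModel:
    """OLS interaction model of one chemical score on one diversity measure."""

    def __init__(self, data: pd.DataFrame, response: str, diversity: str,
                 sex_col: str = "sex", status_col: str = "breeding_status"):
        cols = [response, diversity, sex_col, status_col]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"data missing columns: {missing}")
        if data[cols].isna().to_numpy().any():
            raise ValueError("missing values in model columns")
        self.data = data.copy()
        self.response, self.diversity = response, diversity
        self.sex_col, self.status_col = sex_col, status_col
        # 6 parameters incl. intercept
        if len(data) < 8:
            raise ValueError("too few rows for the interaction model")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, diversity: str,
                       **kw) -> "MHCDiversityModel":
        return cls(data, response, diversity, **kw)

    def _formula(self, coding: str) -> str:
        sex = f"C({self.sex_col}, {coding})"
        d, st = self.diversity, self.status_col
        return f"Q('{self.response}') ~ {d} + {sex} + {st} + {d}:{sex} + {d}:{st}"

    def fit(self) -> MHCDiversityResults:
        fit_sum = smf.ols(self._formula("Sum"), data=self.data).fit()
        self._check_rank(fit_sum)
        fit_treat = smf.ols(self._formula("Treatment"), data=self.data).fit()
        anova3 = sm.stats.anova_lm(fit_sum, typ=3)
        anova3.index = [MHCDiversityResults._strip(t) for t in anova3.index]
        return MHCDiversityResults(self, fit_sum, fit_treat, anova3)

    @staticmethod
    def _check_rank(fit) -> None:
        x = fit.model.exog
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            _, r = np.linalg.qr(x)
            diag = np.abs(np.diag(r))
            aliased = [n for n, d in zip(fit.model.exog_names, diag)
                       if d <= 1e-8 * diag.max()]
            raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased}")


def fit_interaction_model(data: pd.DataFrame, response: str, diversity: str,
                          **kw) -> MHCDiversityResults:
    """Functional wrapper: build an :class:`MHCDiversityModel` and fit it."""
    return MHCDiversityModel.from_dataframe(data, response, diversity, **kw).fit()


@dataclass
class TTestResult:
    t: float
    df: int
    p_value: float


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample t-test, two-sided.

    df = n1 + n2 - 2 (two groups of 40 give the df = 78 reported in
    field comparisons of this design). Zero pooled variance makes the
    statistic undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("t statistic undefined: zero pooled variance")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), int(df), float(p))
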