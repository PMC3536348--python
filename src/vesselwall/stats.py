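"""Longitudinal statistics for the wall-morphometry study table.

The study design is repeated measures: each animal contributes both regions
(lesion and proximal control) at every examination, with 6 slices per
region as replicate observations.  The analysis is a linear mixed model

    response ~ region * timepoint  +  (1 | animal)

fitted by REML.  Fixed-effect terms (region, time, region x time) are tested
with Wald F statistics against a containment denominator df: all these terms
vary within animal, so their denominator stratum is the residual one,

    ddf = n_obs − rank(X) − (n_animals − 1).

Cell-mean contrasts (e.g. lesion − proximal at one timepoint) use the same
covariance and df.  The significance threshold throughout the package is
0.05.  Pearson correlation between a measured and a reference endpoint uses
the standard product-moment formula with the two-sided t approximation
``t = r sqrt((n−2)/(1−r²))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.regression.mixed_linear_model import MixedLM

ALPHA = 0.05


@dataclass
class Contrast:
    """A single linear contrast of fixed effects: estimate, se, t, p."""

    name: str
    estimate: float
    se: float
    t: float
    df: float
    p: float


@dataclass
class AnovaResults:
    """Mixed-model ANOVA table plus variance components and contrast support."""

    response: str
    effects: pd.DataFrame  # term, F, df_num, df_den, p
    var_animal: float
    var_residual: float
    n_obs: int
    n_animals: int
    _fe_params: np.ndarray = None
    _fe_cov: np.ndarray = None
    _design_info: object = None
    _ddf: float = 0.0

    def p_value(self, term: str) -> float:
        row = self.effects[self.effects["term"] == term]
        if row.empty:
            raise KeyError(f"no effect term {term!r}; have {list(self.effects['term'])}")
        return float(row["p"].iloc[0])

    def _design_row(self, region: str, timepoint: str) -> np.ndarray:
        from patsy import build_design_matrices

        (m,) = build_design_matrices(
            [self._design_info], pd.DataFrame({"region": [region], "timepoint": [timepoint]})
        )
        return np.asarray(m)[0]

    def contrast_cells(
        self, cell_a: tuple[str, str], cell_b: tuple[str, str], name: str | None = None
    ) -> Contrast:
        """Model-based difference of two cell means, cell = (region, timepoint)."""
        L = self._design_row(*cell_a) - self._design_row(*cell_b)
        est = float(L @ self._fe_params)
        se = float(np.sqrt(L @ self._fe_cov @ L))
        t = est / se if se > 0 else np.inf * np.sign(est)
        p = 2.0 * float(scipy.stats.t.sf(abs(t), self._ddf))
        return Contrast(name=name or f"{cell_a} - {cell_b}", estimate=est, se=se,
                        t=float(t), df=self._ddf, p=p)

    def summary(self) -> str:
        lines = [
            f"Repeated-measures mixed ANOVA on {self.response!r}",
            f"  {self.n_obs} observations, {self.n_animals} animals "
            f"(random intercept); REML",
            f"  variance components: animal {self.var_animal:.6g}, "
            f"residual {self.var_residual:.6g}",
            "",
            f"  {'term':<18} {'F':>10} {'df':>10} {'p':>12}",
        ]
        for _, r in self.effects.iterrows():
            lines.append(
                f"  {r['term']:<18} {r['F']:>10.3f} "
                f"{int(r['df_num'])},{int(r['df_den']):<7d} {r['p']:>12.4g}"
            )
        return "\n".join(lines)


class RepeatedMeasuresAnova:
    """Mixed-model repeated-measures ANOVA of one endpoint.

    Parameters
    ----------
    table : DataFrame
        Long-format study table with columns ``animal_id``, ``region``,
        ``timepoint`` and the response.
    response : str
        Column to analyse, e.g. ``wall_area_mm2`` or ``mean_thickness_mm``.
    """

    def __init__(self, table: pd.DataFrame, response: str):
        need = {"animal_id", "region", "timepoint", response}
        missing = need - set(table.columns)
        if missing:
            raise ValueError(f"study table lacks columns {sorted(missing)}")
        df = table[["animal_id", "region", "timepoint", response]].copy()
        if df["animal_id"].nunique() < 2:
            raise ValueError("need >= 2 animals (random intercept inestimable otherwise)")
        if df["region"].nunique() < 2:
            raise ValueError("need >= 2 region levels")
        if np.ptp(df[response].to_numpy(dtype=float)) == 0:
            raise ValueError("response is constant; nothing to analyse")
        self.table = df
        self.response = response

    @classmethod
    def from_table(cls, table: pd.DataFrame, response: str) -> "RepeatedMeasuresAnova":
        return cls(table, response)

    def fit(self) -> AnovaResults:
        # sum-to-zero coding so each term's Wald F tests the marginal (main)
        # effect, matching the classical two-way table on balanced data
        df = self.table
        terms = ["C(region, Sum)"]
        if df["timepoint"].nunique() > 1:
            terms += ["C(timepoint, Sum)", "C(region, Sum):C(timepoint, Sum)"]
        formula = f"{self.response} ~ " + " + ".join(terms)
        model = MixedLM.from_formula(formula, groups="animal_id", data=df)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                # gradient-based fits can hit singular score matrices when the
                # animal variance collapses; fall back to derivative-free
                result = None
                err = None
                for method in ("lbfgs", "powell", "nm"):
                    try:
                        result = model.fit(reml=True, method=method, maxiter=2000)
                        break
                    except (np.linalg.LinAlgError, ValueError) as exc:
                        err = exc
                if result is None:
                    raise RuntimeError(f"mixed-model fit failed: {err}")

        design_info = model.data.design_info
        fe_params = np.asarray(result.fe_params)
        k = fe_params.shape[0]
        fe_cov = np.asarray(result.cov_params())[:k, :k]
        n_obs = len(df)
        n_animals = df["animal_id"].nunique()
        ddf = n_obs - k - (n_animals - 1)

        rows = []
        pretty = {"C(region, Sum)": "region", "C(timepoint, Sum)": "time",
                  "C(region, Sum):C(timepoint, Sum)": "region:time"}
        for term_name, sl in design_info.term_name_slices.items():
            if term_name == "Intercept":
                continue
            idx = np.arange(k)[sl]
            L = np.zeros((len(idx), k))
            L[np.arange(len(idx)), idx] = 1.0
            v = L @ fe_params
            F = float(v @ np.linalg.solve(L @ fe_cov @ L.T, v)) / len(idx)
            p = float(scipy.stats.f.sf(F, len(idx), ddf))
            rows.append({"term": pretty.get(term_name, term_name), "F": F,
                         "df_num": len(idx), "df_den": ddf, "p": p})
        return AnovaResults(
            response=self.response,
            effects=pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p"]),
            var_animal=float(np.asarray(result.cov_re)[0, 0]),
            var_residual=float(result.scale),
            n_obs=n_obs,
            n_animals=n_animals,
            _fe_params=fe_params,
            _fe_cov=fe_cov,
            _design_info=design_info,
            _ddf=float(ddf),
        )


def repeated_measures_anova(table: pd.DataFrame, response: str) -> AnovaResults:
    """Functional form of :class:`RepeatedMeasuresAnova`."""
    return RepeatedMeasuresAnova(table, response).fit()


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-approximation p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(scipy.stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p=p)


def assess_study_pattern(
    table: pd.DataFrame,
    thickness_col: str = "mean_thickness_mm",
    area_col: str = "wall_area_mm2",
    alpha: float = ALPHA,
) -> dict:
    """Test the longitudinal lesion-vs-control pattern on one study table.

    Returns a dict of booleans (with the backing contrasts):

    * ``baseline_ns`` — no significant lesion-vs-proximal thickness difference
      at baseline;
    * ``week4_sig`` / ``week10_sig`` — lesion thickness significantly above
      proximal at 4 and 10 weeks;
    * ``regression_sig`` — lesion wall area significantly lower at 10 than at
      4 weeks.
    """
    res_t = repeated_measures_anova(table, thickness_col)
    c0 = res_t.contrast_cells(("lesion", "baseline"), ("proximal", "baseline"),
                              "lesion-proximal @ baseline")
    c4 = res_t.contrast_cells(("lesion", "week4"), ("proximal", "week4"),
                              "lesion-proximal @ week4")
    c10 = res_t.contrast_cells(("lesion", "week10"), ("proximal", "week10"),
                               "lesion-proximal @ week10")
    res_a = repeated_measures_anova(table, area_col)
    creg = res_a.contrast_cells(("lesion", "week4"), ("lesion", "week10"),
                                "lesion area week4-week10")
    return {
        "baseline_ns": c0.p >= alpha,
        "week4_sig": (c4.p < alpha) and (c4.estimate > 0),
        "week10_sig": (c10.p < alpha) and (c10.estimate > 0),
        "regression_sig": (creg.p < alpha) and (creg.estimate > 0),
        "contrasts": [c0, c4, c10, creg],
        "anova_thickness": res_t,
        "anova_area": res_a,
    }
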