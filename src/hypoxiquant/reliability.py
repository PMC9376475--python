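"""Variance decomposition and reliability (ICC) of hypoxic-percentage scores.

HP measured on several sections (and ROIs) per patient is modelled with
nested random effects:

    two-level   value_ps  = mu + b_p + e_ps
    three-level value_psr = mu + b_p + s_ps + e_psr

with independent Gaussian components.  The single-section intraclass
correlation ICC1 = sigma2_patient / total variance measures how much of the
observed spread is real between-patient signal; the reliability of the mean
of k sections follows the Spearman-Brown step-up

    ICC_k = k * ICC1 / (1 + (k - 1) * ICC1).

Estimation is REML (statsmodels MixedLM) by default, with closed-form
ANOVA method-of-moments estimators as the balanced-design cross-check.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import (
    InsufficientGroupingError,
    InvalidInputError,
    InvalidStructureError,
)

#: ICC at or above this value is conventionally read as high reliability.
HIGH_RELIABILITY_ICC = 0.85


@dataclasses.dataclass(frozen=True)
class VarianceComponents:
    """Estimated variance components of HP, in (HP %) squared units."""

    sigma2_patient: float
    sigma2_section: float
    sigma2_roi: float | None = None  # None for two-level fits
    grand_mean: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.sigma2_patient, self.sigma2_section, self.sigma2_roi):
            if v is not None and v < 0:
                raise InvalidInputError("variance components must be non-negative")

    @property
    def sigma2_within(self) -> float:
        """All variance below the patient level."""
        return self.sigma2_section + (self.sigma2_roi or 0.0)

    @property
    def total(self) -> float:
        return self.sigma2_patient + self.sigma2_within

    def fractions(self) -> dict[str, float]:
        """Each component as a percent of total variance."""
        if self.total <= 0:
            raise InvalidInputError("zero total variance: fractions undefined")
        out = {"patient": 100.0 * self.sigma2_patient / self.total,
               "section": 100.0 * self.sigma2_section / self.total}
        if self.sigma2_roi is not None:
            out["roi"] = 100.0 * self.sigma2_roi / self.total
        return out


def variance_fractions(vc: VarianceComponents) -> dict[str, float]:
    """Percent of total variance per component (sums to 100)."""
    return vc.fractions()


def icc_single(vc: VarianceComponents) -> float:
    """ICC1 = between-patient variance over total variance; NaN if total is 0."""
    if vc.total <= 0:
        return float("nan")
    return vc.sigma2_patient / vc.total


def icc_k_sections(icc1: float, k: int) -> float:
    """Reliability of the mean of k sections (Spearman-Brown step-up)."""
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if not 0 <= icc1 <= 1:
        raise InvalidInputError("icc1 must be in [0, 1]")
    return k * icc1 / (1.0 + (k - 1) * icc1)


def icc_table(icc1: float, max_k: int = 5, measure: str = "hp_wt", platform: str = "") -> pd.DataFrame:
    """ICC as a function of the number of sections analyzed (k = 1..max_k)."""
    rows = [{"k": k, "icc": icc_k_sections(icc1, k), "measure": measure, "platform": platform}
            for k in range(1, max_k + 1)]
    return pd.DataFrame(rows)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Requires at least 3 pairs; returns NaN for rank-degenerate (constant)
    input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D and paired")
    if len(x) < 3:
        raise InvalidInputError("spearman_rho requires at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = scipy.stats.spearmanr(x, y)
    return float(rho)


# --- estimation -----------------------------------------------------------

def _check_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"missing columns: {missing}")


def fit_two_level_mom(df: pd.DataFrame, value: str = "value",
                      patient: str = "patient_id") -> VarianceComponents:
    """ANOVA method-of-moments estimator for the two-level model.

    sigma2_within = MSW, sigma2_patient = (MSB - MSW) / k0 with the standard
    unbalanced-design k0 = (N - sum n_i^2 / N) / (a - 1); negative estimates
    are truncated at zero with a warning.
    """
    _check_columns(df, [value, patient])
    groups = df.groupby(patient)[value]
    a = groups.ngroups
    if a < 2:
        raise InsufficientGroupingError("need >= 2 patients")
    n_i = groups.size().to_numpy(dtype=float)
    N = n_i.sum()
    grand = df[value].mean()
    means = groups.mean().to_numpy()
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    ssw = float(((df[value] - groups.transform("mean")) ** 2).sum())
    msb = ssb / (a - 1)
    if N - a > 0:
        msw = ssw / (N - a)
    else:
        msw = 0.0
    k0 = (N - np.sum(n_i**2) / N) / (a - 1)
    s2p = (msb - msw) / k0
    if s2p < 0:
        warnings.warn("negative patient variance estimate truncated to 0")
        s2p = 0.0
    return VarianceComponents(sigma2_patient=s2p, sigma2_section=msw,
                              grand_mean=float(grand))


def fit_two_level(df: pd.DataFrame, value: str = "value", patient: str = "patient_id",
                  section: str = "section_id", method: str = "reml") -> VarianceComponents:
    """Fit value_ps = mu + b_p + e_ps and return the variance components.

    ``method`` is "reml" (statsmodels MixedLM) or "mom" (closed-form ANOVA).
    """
    _check_columns(df, [value, patient])
    if df.groupby(patient).ngroups < 2:
        raise InsufficientGroupingError("need >= 2 patients")
    if method == "mom":
        return fit_two_level_mom(df, value=value, patient=patient)
    if method != "reml":
        raise InvalidInputError("method must be 'reml' or 'mom'")
    import statsmodels.formula.api as smf

    data = df[[value, patient]].rename(columns={value: "y"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("y ~ 1", data, groups=data[patient])
        res = md.fit(reml=True, method="lbfgs", maxiter=200)
    s2p = max(float(res.cov_re.iloc[0, 0]), 0.0)
    s2e = max(float(res.scale), 0.0)
    return VarianceComponents(sigma2_patient=s2p, sigma2_section=s2e,
                              grand_mean=float(res.params["Intercept"]))


def fit_three_level(df: pd.DataFrame, value: str = "value", patient: str = "patient_id",
                    section: str = "section_id", roi: str = "roi_id",
                    method: str = "reml") -> VarianceComponents:
    """Fit the nested model value_psr = mu + b_p + s_ps + e_psr by REML.

    Sections must nest within patients (a section id may not recur under two
    patients once qualified); ``method`` "mom" uses the balanced nested-ANOVA
    closed form instead.
    """
    _check_columns(df, [value, patient, section, roi])
    if df.groupby(patient).ngroups < 2:
        raise InsufficientGroupingError("need >= 2 patients")
    if df.duplicated([patient, section, roi]).any():
        raise InvalidStructureError(
            "duplicate (patient, section, roi) rows: ids do not identify observations"
        )
    # qualify section ids by patient so reused plain ids stay nested
    data = df[[value, patient, section]].copy()
    data.columns = ["y", "p", "s"]
    data["s"] = data["p"].astype(str) + "/" + data["s"].astype(str)
    if method == "mom":
        return _fit_three_level_mom(data)
    if method != "reml":
        raise InvalidInputError("method must be 'reml' or 'mom'")
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("y ~ 1", data, groups=data["p"], re_formula="1",
                         vc_formula={"s": "0 + C(s)"})
        res = md.fit(reml=True, method="lbfgs", maxiter=200)
    s2p = max(float(res.cov_re.iloc[0, 0]), 0.0)
    s2s = max(float(np.asarray(res.vcomp).ravel()[0]), 0.0)
    s2r = max(float(res.scale), 0.0)
    return VarianceComponents(sigma2_patient=s2p, sigma2_section=s2s, sigma2_roi=s2r,
                              grand_mean=float(res.params["Intercept"]))


def _fit_three_level_mom(data: pd.DataFrame) -> VarianceComponents:
    """Balanced nested-ANOVA method of moments (columns y, p, s)."""
    n_per_section = data.groupby("s").size()
    sections_per_patient = data.groupby("p")["s"].nunique()
    if n_per_section.nunique() != 1 or sections_per_patient.nunique() != 1:
        raise InvalidInputError("method-of-moments path requires a balanced design")
    n = int(n_per_section.iloc[0])       # ROIs per section
    b = int(sections_per_patient.iloc[0])  # sections per patient
    a = data["p"].nunique()
    grand = data["y"].mean()
    p_mean_col = data.groupby("p")["y"].transform("mean")
    s_mean_col = data.groupby(["p", "s"])["y"].transform("mean")
    # row-wise sums already carry the replication factors (b*n, n, 1)
    ssa = float(((p_mean_col - grand) ** 2).sum())
    ssb = float(((s_mean_col - p_mean_col) ** 2).sum())
    ssw = float(((data["y"] - s_mean_col) ** 2).sum())
    msa = ssa / (a - 1)
    msb = ssb / (a * (b - 1)) if b > 1 else 0.0
    msw = ssw / (a * b * (n - 1)) if n > 1 else 0.0
    s2r = msw
    s2s = (msb - msw) / n if b > 1 else 0.0
    s2p = (msa - msb) / (b * n) if b > 1 else (msa - msw) / n
    out = []
    for v, name in ((s2p, "patient"), (s2s, "section")):
        if v < 0:
            warnings.warn(f"negative {name} variance estimate truncated to 0")
            v = 0.0
        out.append(v)
    return VarianceComponents(sigma2_patient=out[0], sigma2_section=out[1],
                              sigma2_roi=s2r, grand_mean=float(grand))


# --- statsmodels-style front end -----------------------------------------

class HPVarianceModel:
    """Nested random-effects model of HP heterogeneity.

    Construct from a long HP table (one row per section or per ROI), then
    :meth:`fit` to obtain an :class:`HPVarianceResults`.  With ``roi=None``
    the model is two-level (patient / section); with a ROI column it is
    three-level (patient / section / ROI).
    """

    def __init__(self, data: pd.DataFrame, value: str = "hp_wt",
                 patient: str = "patient_id", section: str = "section_id",
                 roi: str | None = None):
        _check_columns(data, [value, patient, section] + ([roi] if roi else []))
        self.data = data
        self.value = value
        self.patient = patient
        self.section = section
        self.roi = roi

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, value: str = "hp_wt",
                       roi: str | None = None, **kw) -> "HPVarianceModel":
        return cls(data, value=value, roi=roi, **kw)

    def fit(self, method: str = "reml") -> "HPVarianceResults":
        if self.roi is None:
            vc = fit_two_level(self.data, value=self.value, patient=self.patient,
                               section=self.section, method=method)
        else:
            vc = fit_three_level(self.data, value=self.value, patient=self.patient,
                                 section=self.section, roi=self.roi, method=method)
        return HPVarianceResults(self, vc, method)


class HPVarianceResults:
    """Fitted variance components with reliability diagnostics."""

    def __init__(self, model: HPVarianceModel, vc: VarianceComponents, method: str):
        self.model = model
        self.vc = vc
        self.method = method

    @property
    def icc1(self) -> float:
        return icc_single(self.vc)

    def icc_k(self, k: int) -> float:
        return icc_k_sections(self.icc1, k)

    def icc_table(self, max_k: int = 5, platform: str = "") -> pd.DataFrame:
        return icc_table(self.icc1, max_k=max_k, measure=self.model.value, platform=platform)

    def fractions(self) -> dict[str, float]:
        return self.vc.fractions()

    def sections_for_reliability(self, target: float = HIGH_RELIABILITY_ICC,
                                 max_k: int = 50) -> int | None:
        """Smallest k whose ICC_k reaches ``target``; None if unreachable."""
        for k in range(1, max_k + 1):
            if self.icc_k(k) >= target:
                return k
        return None

    def summary(self) -> str:
        vc = self.vc
        lines = [
            "HP variance components" + (" (three-level)" if vc.sigma2_roi is not None else " (two-level)"),
            "=" * 46,
            f"measure:            {self.model.value}",
            f"method:             {self.method}",
            f"grand mean (HP %):  {vc.grand_mean:8.3f}",
            f"sigma2 patient:     {vc.sigma2_patient:8.3f}",
            f"sigma2 section:     {vc.sigma2_section:8.3f}",
        ]
        if vc.sigma2_roi is not None:
            lines.append(f"sigma2 ROI:         {vc.sigma2_roi:8.3f}")
        fr = vc.fractions() if vc.total > 0 else {}
        for name, pct in fr.items():
            lines.append(f"fraction {name:<8}   {pct:7.1f} %")
        lines.append(f"ICC (1 section):    {self.icc1:8.3f}")
        for k in range(2, 6):
            lines.append(f"ICC ({k} sections):   {self.icc_k(k):8.3f}")
        n_req = self.sections_for_reliability()
        lines.append(
            f"sections for ICC >= {HIGH_RELIABILITY_ICC:.2f}: "
            + (str(n_req) if n_req is not None else f"> {50}")
        )
        return "\n".join(lines)

    def plot_icc(self, max_k: int = 5, ax=None):
        """Plot ICC against the number of sections analyzed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.icc_table(max_k=max_k)
        ax.plot(tab["k"], tab["icc"], marker="o")
        ax.axhline(HIGH_RELIABILITY_ICC, ls="--", color="grey")
        ax.set_xlabel("sections analyzed (k)")
        ax.set_ylabel("ICC")
        ax.set_ylim(0, 1)
        return ax
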