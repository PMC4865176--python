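"""Cohort characteristics by exposure group: the descriptive table with
per-row chi-square or t tests.

Categorical traits are compared between exposed and unexposed children
by the Pearson chi-square test on the 2x2 table (no continuity
correction); continuous traits by the pooled-variance two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SampleSheet


@dataclass
class TwoByTwo:
    """Counts with rows = exposure groups, columns = trait yes/no."""

    a: int  # unexposed, trait present
    b: int  # unexposed, trait absent
    c: int  # exposed, trait present
    d: int  # exposed, trait absent

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def chisq_2x2(t: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-square (1 df, no Yates correction) on a 2x2 table."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate table: zero margin")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def ttest_summary(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Pooled-variance two-sample t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=True)
    return float(res.statistic), float(res.pvalue)


def _fmt_p(p) -> str:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return "—"
    return f"{p:.3f}" if p >= 0.001 else "<0.001"


def _count_row(label, mask_u, mask_e, denom_u=None, denom_e=None):
    """Count (%) row with a chi-square p-value; denominators default to
    the non-missing group sizes."""
    nu = int(mask_u.sum())
    ne = int(mask_e.sum())
    du = len(mask_u) if denom_u is None else denom_u
    de = len(mask_e) if denom_e is None else denom_e
    try:
        _chi2, p = chisq_2x2(TwoByTwo(nu, du - nu, ne, de - ne))
    except ValueError:
        p = np.nan
    total = nu + ne
    dt = du + de
    return {
        "characteristic": label,
        "not_exposed": f"{nu} ({100 * nu / du:.1f})" if du else "0",
        "exposed": f"{ne} ({100 * ne / de:.1f})" if de else "0",
        "p_value": p, "p": _fmt_p(p),
        "total": f"{total} ({100 * total / dt:.1f})" if dt else "0",
    }


def _mean_row(label, x_u, x_e):
    x_u = np.asarray(x_u, dtype=float)
    x_e = np.asarray(x_e, dtype=float)
    x_u = x_u[~np.isnan(x_u)]
    x_e = x_e[~np.isnan(x_e)]
    if len(x_u) < 2 or len(x_e) < 2:
        p = np.nan
    else:
        _t, p = stats.ttest_ind(x_u, x_e, equal_var=True)
        p = float(p)
    both = np.concatenate([x_u, x_e])
    fmt = lambda x: f"{np.mean(x):.1f} ± {np.std(x, ddof=1):.1f}" \
        if len(x) > 1 else "—"
    return {
        "characteristic": label,
        "not_exposed": fmt(x_u), "exposed": fmt(x_e),
        "p_value": p, "p": _fmt_p(p),
        "total": fmt(both),
    }


def characteristics_table(sheet: SampleSheet) -> pd.DataFrame:
    """Descriptive table by exposure group with per-row tests.

    Rows mirror the usual cohort-characteristics layout: sex, age,
    birthweight by sex, feeding mode, gestation and maternal age when
    available, maternal education levels, study centres and postnatal
    smoke exposure.  Percentages use non-missing denominators.
    """
    f = sheet.frame
    u = f[f["exposure"] == 0]
    e = f[f["exposure"] == 1]
    rows = []
    rows.append(_count_row("Girls (n (%))", (u["sex"] == "girl"),
                           (e["sex"] == "girl")))
    rows.append(_mean_row("Child's age at blood draw (months)",
                          u["age_months"], e["age_months"]))
    rows.append(_mean_row("Girls birthweight (kg)",
                          u.loc[u["sex"] == "girl", "birthweight_kg"],
                          e.loc[e["sex"] == "girl", "birthweight_kg"]))
    rows.append(_mean_row("Boys birthweight (kg)",
                          u.loc[u["sex"] == "boy", "birthweight_kg"],
                          e.loc[e["sex"] == "boy", "birthweight_kg"]))
    rows.append(_count_row("Child formula vs. breastfed (%)",
                           ~u["breastfed"].astype(bool),
                           ~e["breastfed"].astype(bool)))
    if "gestation_weeks" in f:
        rows.append(_mean_row("Length of gestation (week)",
                              u["gestation_weeks"], e["gestation_weeks"]))
    if "maternal_age_years" in f:
        rows.append(_mean_row("Maternal age at delivery (years)",
                              u["maternal_age_years"],
                              e["maternal_age_years"]))
    edu_u = u["maternal_education"].dropna()
    edu_e = e["maternal_education"].dropna()
    for level, label in (("low", "Low"), ("middle", "Middle"),
                         ("high", "High")):
        rows.append(_count_row(f"Maternal education: {label} (n (%))",
                               (edu_u == level), (edu_e == level)))
    for centre, label in (("DE", "Germany"), ("BE", "Belgium"),
                          ("IT", "Italy"), ("ES", "Spain")):
        rows.append(_count_row(f"Centre: {label} (n (%))",
                               (u["centre"] == centre),
                               (e["centre"] == centre)))
    rows.append(_count_row("Smoke exposure age 4: mother (n (%))",
                           u["mother_smokes_age4"].astype(bool),
                           e["mother_smokes_age4"].astype(bool)))
    rows.append(_count_row("Smoke exposure age 4: father (n (%))",
                           u["father_smokes_age4"].astype(bool),
                           e["father_smokes_age4"].astype(bool)))
    out = pd.DataFrame(rows)
    out.attrs["n_not_exposed"] = len(u)
    out.attrs["n_exposed"] = len(e)
    out.attrs["n_total"] = len(u) + len(e)
    return out
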