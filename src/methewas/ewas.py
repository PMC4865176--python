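"""The EWAS engine: control-probe PCA, design construction, mass per-CpG
regression on M-values, FDR, genomic inflation and plot series.

Per CpG, methylation M-values are regressed by ordinary least squares on
an indicator-coded exposure plus covariates (sex, age, study centre,
maternal education, postnatal parental smoking, six estimated leukocyte
fractions, and up to 30 principal components of the array control
probes).  A companion OLS on beta-values with the identical design gives
the adjusted beta-scale difference reported in top tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CELL_TYPES, CellFractions, EwasResult, MethylationMatrix, ProbeManifest,
    SampleSheet,
)

log = logging.getLogger(__name__)

CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364


# ---------------------------------------------------------------------------
# control-probe PCA


def control_probe_pcs(controls: pd.DataFrame, k: int = 30) -> pd.DataFrame:
    """Principal components of log2 control-probe signals, per sample.

    Rows of ``controls`` are control probes, columns samples.  Signals are
    log2-transformed (floored at 1), each probe row is centred, and the
    sample scores of the first ``min(k, rank)`` components are returned in
    decreasing order of variance explained.
    """
    if controls.shape[1] < 2:
        raise ValueError("need at least 2 samples for control-probe PCA")
    if controls.shape[0] < 2:
        raise ValueError("need at least 2 control probes")
    x = np.log2(np.maximum(controls.values.astype(float), 1.0))
    x = x - x.mean(axis=1, keepdims=True)
    _u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = s.max() * max(x.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    ncomp = min(k, rank)
    if ncomp < k:
        warnings.warn(f"requested {k} control-probe PCs but rank is {rank}; "
                      f"returning {ncomp}", stacklevel=2)
    scores = vt[:ncomp].T * s[:ncomp]
    # deterministic sign: largest-magnitude sample score positive
    for c in range(ncomp):
        col = scores[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, c] = -col
    return pd.DataFrame(scores, index=controls.columns,
                        columns=[f"PC{i + 1}" for i in range(ncomp)])


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """Regression design: samples x regressors, exposure column flagged."""

    matrix: pd.DataFrame
    exposure_col: str = "exposure"
    log: dict = field(default_factory=dict)

    @property
    def samples(self) -> pd.Index:
        return self.matrix.index

    @property
    def exposure_index(self) -> int:
        return list(self.matrix.columns).index(self.exposure_col)


def build_design(sheet: SampleSheet, fractions: CellFractions,
                 pcs: pd.DataFrame | None = None) -> DesignMatrix:
    """Indicator-coded covariate design for the per-CpG regressions.

    Coding: exposure 0/1; sex as a girl indicator; age in months; centre
    as DE/IT/ES indicators against reference BE; maternal education as
    middle/high against low; postnatal maternal and paternal smoking as
    0/1; six cell-fraction columns; control-probe PCs as given.  Samples
    with any missing covariate are dropped (complete case) and degenerate
    (constant) columns pruned with a warning.
    """
    f = sheet.frame
    n_missing_exposure = int(f["exposure"].isna().sum())
    if n_missing_exposure:
        log.info("dropping %d samples with missing exposure",
                 n_missing_exposure)
        f = f[f["exposure"].notna()]
    complete = f["maternal_education"].notna() & f["sex"].notna() \
        & f["age_months"].notna()
    n_incomplete = int((~complete).sum())
    f = f[complete]
    cols = {
        "intercept": np.ones(len(f)),
        "exposure": f["exposure"].astype(float).values,
        "sex_girl": (f["sex"] == "girl").astype(float).values,
        "age_months": f["age_months"].astype(float).values,
        "centre_DE": (f["centre"] == "DE").astype(float).values,
        "centre_IT": (f["centre"] == "IT").astype(float).values,
        "centre_ES": (f["centre"] == "ES").astype(float).values,
        "edu_middle": (f["maternal_education"] == "middle").astype(float).values,
        "edu_high": (f["maternal_education"] == "high").astype(float).values,
        "mother_smokes_age4": f["mother_smokes_age4"].astype(float).values,
        "father_smokes_age4": f["father_smokes_age4"].astype(float).values,
    }
    design = pd.DataFrame(cols, index=f.index)
    frac = fractions.frame.reindex(f.index)
    if frac.isna().any().any():
        raise ValueError("cell fractions missing for some design samples")
    for ct in CELL_TYPES:
        design[f"cell_{ct}"] = frac[ct].values
    if pcs is not None:
        p = pcs.reindex(f.index)
        if p.isna().any().any():
            raise ValueError("control-probe PCs missing for some samples")
        for c in pcs.columns:
            design[c] = p[c].values

    exp_col = design["exposure"]
    if exp_col.nunique() < 2:
        raise ValueError("no contrast: exposure column is constant")

    pruned = []
    for c in list(design.columns):
        if c not in ("intercept", "exposure") and design[c].nunique() < 2:
            pruned.append(c)
            design = design.drop(columns=c)
    if pruned:
        warnings.warn(f"pruned degenerate design columns: {pruned}",
                      stacklevel=2)
    # rank check: greedily keep columns (protected ones first) that add rank
    if np.linalg.matrix_rank(design.values) < design.shape[1]:
        protected = [c for c in ("intercept", "exposure") if c in design]
        rest = [c for c in design.columns if c not in protected]
        kept = list(protected)
        rank = np.linalg.matrix_rank(design[kept].values)
        for c in rest:
            r_new = np.linalg.matrix_rank(design[kept + [c]].values)
            if r_new > rank:
                kept.append(c)
                rank = r_new
        drop = [c for c in design.columns if c not in kept]
        warnings.warn(f"pruned collinear design columns: {drop}",
                      stacklevel=2)
        design = design[[c for c in design.columns if c in kept]]
        pruned.extend(drop)
    return DesignMatrix(matrix=design, exposure_col="exposure",
                        log={"n_missing_exposure": n_missing_exposure,
                             "n_incomplete_covariates": n_incomplete,
                             "pruned_columns": pruned})


# ---------------------------------------------------------------------------
# mass regression


def _mass_ols(X: np.ndarray, Y: np.ndarray, obs: np.ndarray,
              e_idx: int, min_df: int):
    """Exposure coefficient, SE and df per outcome column of Y.

    Y is samples x probes with NaN at unobserved cells; per probe the OLS
    normal equations are downdated by the missing rows, which is fast when
    missingness is sparse.  Returns (coef, se, df, ok) arrays.
    """
    n, p = X.shape
    n_out = Y.shape[1]
    Y0 = np.where(obs, Y, 0.0)
    XtX = X.T @ X
    B = X.T @ Y0                       # p x probes
    y2 = (Y0 * Y0).sum(axis=0)
    n_obs = obs.sum(axis=0)
    e = np.zeros(p)
    e[e_idx] = 1.0

    coef = np.full(n_out, np.nan)
    se = np.full(n_out, np.nan)
    df = np.zeros(n_out, dtype=int)
    ok = np.zeros(n_out, dtype=bool)

    full_cols = np.flatnonzero(n_obs == n)
    if full_cols.size:
        try:
            cf = sla.cho_factor(XtX, check_finite=False)
            sol = sla.cho_solve(cf, np.column_stack([B[:, full_cols],
                                                     e[:, None]]),
                                check_finite=False)
            beta_full, z = sol[:, :-1], sol[:, -1]
            rss = y2[full_cols] - np.einsum("ij,ij->j", beta_full,
                                            B[:, full_cols])
            d = n - p
            if d >= min_df:
                sigma2 = np.maximum(rss, 0.0) / d
                coef[full_cols] = beta_full[e_idx]
                se[full_cols] = np.sqrt(np.maximum(sigma2 * z[e_idx], 1e-300))
                df[full_cols] = d
                ok[full_cols] = True
        except np.linalg.LinAlgError:
            pass  # fall through to per-probe path below

    rest = np.flatnonzero((n_obs < n) | ~ok)
    rhs = np.empty((p, 2))
    for j in rest:
        nj = int(n_obs[j])
        d = nj - p
        if d < min_df:
            continue
        miss = np.flatnonzero(~obs[:, j])
        Xm = X[miss]
        A = XtX - Xm.T @ Xm
        rhs[:, 0] = B[:, j]
        rhs[:, 1] = e
        try:
            cfj = sla.cho_factor(A, check_finite=False)
        except np.linalg.LinAlgError:
            continue
        sol = sla.cho_solve(cfj, rhs, check_finite=False)
        bj, zj = sol[:, 0], sol[:, 1]
        rss = y2[j] - bj @ B[:, j]
        sigma2 = max(rss, 0.0) / d
        coef[j] = bj[e_idx]
        se[j] = np.sqrt(max(sigma2 * zj[e_idx], 1e-300))
        df[j] = d
        ok[j] = True
    return coef, se, df, ok


def ewas_regression(mvals: MethylationMatrix,
                    betas: MethylationMatrix | None,
                    design: DesignMatrix,
                    manifest: ProbeManifest | None = None,
                    min_extra_df: int = 5) -> EwasResult:
    """Per-CpG OLS of M-values on the design, with beta-scale companion.

    The exposure coefficient, its t-based two-sided p-value (df = complete
    cases minus regressors) and the BH q-value are reported per probe; when
    ``betas`` is given, an OLS of beta-values on the identical design adds
    the adjusted beta-scale difference and its SE.  Probes with fewer than
    p + ``min_extra_df`` complete cases, or a rank-deficient design on
    their complete cases, are skipped and logged.
    """
    if mvals.scale != "mvalue":
        raise ValueError("ewas_regression expects M-values")
    if betas is not None and betas.scale != "beta":
        raise ValueError("companion matrix must be beta scale")
    X = design.matrix.values.astype(float)
    samples = design.samples
    Ym = mvals.values.loc[:, samples].values.T
    obs = mvals.mask.loc[:, samples].values.T
    n, p = X.shape
    e_idx = design.exposure_index
    min_df = min_extra_df

    m_coef, m_se, df, ok = _mass_ols(X, Ym, obs, e_idx, min_df)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = m_coef / m_se
    pvals = np.where(ok, 2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1)),
                     np.nan)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    if betas is not None:
        Yb = betas.values.loc[:, samples].values.T
        b_coef, b_se, _dfb, okb = _mass_ols(X, Yb, obs, e_idx, min_df)
        ok = ok & okb
    else:
        b_coef = np.full(len(mvals.probe_ids), np.nan)
        b_se = np.full(len(mvals.probe_ids), np.nan)

    probe_ids = mvals.probe_ids
    skipped = list(probe_ids[~ok])
    if skipped:
        log.info("skipped %d probes (insufficient complete cases or "
                 "rank-deficient design)", len(skipped))
    keep = ok
    q = bh_fdr(pvals[keep])
    lam = genomic_lambda(pvals[keep])

    if manifest is not None:
        ann = manifest.table.reindex(probe_ids[keep])
        chrom = ann["chromosome"].fillna("").values
        gene = ann["gene"].fillna("").values
        pos = ann["position"].fillna(0).astype(int).values
    else:
        chrom = np.full(int(keep.sum()), "", dtype=object)
        gene = np.full(int(keep.sum()), "", dtype=object)
        pos = np.zeros(int(keep.sum()), dtype=int)

    table = pd.DataFrame({
        "probe_id": probe_ids[keep],
        "chromosome": chrom,
        "gene": gene,
        "position": pos,
        "m_effect": m_coef[keep],
        "se_m": m_se[keep],
        "beta_diff": b_coef[keep] if betas is not None else np.nan,
        "se_beta": b_se[keep] if betas is not None else np.nan,
        "p_value": pvals[keep],
        "q_value": q,
    }).sort_values(["p_value", "probe_id"], kind="mergesort") \
      .reset_index(drop=True)
    if betas is None:
        table["beta_diff"] = 0.0
        table["se_beta"] = np.nan
    return EwasResult(table=table, lambda_=lam, n_samples=n,
                      n_probes=int(keep.sum()), skipped=skipped)


# ---------------------------------------------------------------------------
# FDR and inflation


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genomic_lambda(p) -> float:
    """Genomic-control inflation: median 1-df chi-square over its null median."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


# ---------------------------------------------------------------------------
# plot data


def plot_series(result: EwasResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Volcano and QQ tables for an EWAS result.

    Volcano: per-probe (m_effect, -log10 p).  QQ: sorted observed
    -log10 p against expected -log10((i - 0.5) / m).
    """
    t = result.table
    if not len(t):
        raise ValueError("empty result")
    volcano = pd.DataFrame({
        "probe_id": t["probe_id"],
        "m_effect": t["m_effect"],
        "neg_log10_p": -np.log10(t["p_value"]),
    })
    p_sorted = np.sort(t["p_value"].values)
    m = p_sorted.size
    qq = pd.DataFrame({
        "expected": -np.log10((np.arange(1, m + 1) - 0.5) / m),
        "observed": -np.log10(p_sorted),
    })
    return volcano, qq


def save_plots(result: EwasResult, volcano_path, qq_path) -> None:
    """Render the volcano and QQ figures to image files."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    volcano, qq = plot_series(result)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(volcano["m_effect"], volcano["neg_log10_p"], s=4, alpha=0.5)
    ax.set_xlabel("M-value exposure coefficient")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(volcano_path, dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(qq["expected"], qq["observed"], s=4, alpha=0.5)
    lim = max(qq["expected"].max(), qq["observed"].max())
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    fig.tight_layout()
    fig.savefig(qq_path, dpi=120)
    plt.close(fig)
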