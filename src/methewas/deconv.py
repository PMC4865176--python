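"""Reference-based leukocyte deconvolution by constrained projection.

Each sample's beta-values at cell-type-informative sites are projected
onto a purified-cell reference profile under a nonnegativity constraint
(nonnegative least squares); no sum-to-one constraint is imposed, so the
fitted fractions are free to total slightly off 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .datatypes import CELL_TYPES, CellFractions, CellReference, MethylationMatrix

#: nominal residual variance used to rank sites when the reference gives
#: only per-type means (no replicates)
NOMINAL_RESIDUAL_VARIANCE = 0.01


def select_reference_sites(reference: CellReference,
                           k: int = 500) -> CellReference:
    """Keep the k sites most discriminative of cell type.

    Discrimination is scored by a one-way ANOVA-style F statistic:
    between-type variance of the profile means over a nominal residual
    variance (the reference carries means only).  Ties break toward the
    lower probe id.
    """
    if k > len(reference):
        raise ValueError(f"k={k} exceeds available sites ({len(reference)})")
    profile = reference.profile
    score = profile.values.var(axis=1, ddof=1) / NOMINAL_RESIDUAL_VARIANCE
    order = sorted(range(len(profile)),
                   key=lambda i: (-score[i], profile.index[i]))
    keep = sorted(order[:k], key=lambda i: i)  # preserve original row order
    return CellReference(profile.iloc[keep])


def project_cell_fractions(betas: MethylationMatrix,
                           reference: CellReference) -> CellFractions:
    """Per-sample NNLS fit of beta-values onto the reference profile.

    For each sample with observed site vector y and reference matrix F,
    solves w = argmin ||y - F w||^2 subject to w >= 0.  Sites missing for
    a sample are dropped rowwise for that sample only.
    """
    if betas.scale != "beta":
        raise ValueError("project_cell_fractions expects beta scale")
    overlap = reference.site_ids.intersection(betas.probe_ids)
    if len(overlap) < 0.5 * len(reference):
        raise ValueError(
            f"only {len(overlap)} of {len(reference)} reference sites "
            "available (need >= 50%)")
    sites = [s for s in reference.site_ids if s in set(overlap)]
    F = reference.profile.loc[sites].values
    y_all = betas.values.loc[sites].values
    obs_all = betas.mask.loc[sites].values
    out = np.zeros((y_all.shape[1], 6))
    for j in range(y_all.shape[1]):
        obs = obs_all[:, j]
        w, _rnorm = nnls(F[obs], y_all[obs, j])
        out[j] = w
    return CellFractions(pd.DataFrame(out, index=betas.samples,
                                      columns=list(CELL_TYPES)))
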