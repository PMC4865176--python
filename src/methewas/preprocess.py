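"""Quality control and normalization for 450K-style intensity data.

The chain mirrors standard Infinium practice: bead-count and detection
p-value filtering with an 80% per-sample call-rate rule, smooth-quantile
colour-bias correction between the red and green channels, negative-control
background subtraction, the beta-value transform with a +100 offset,
beta-mixture quantile (BMIQ) normalization of type II probes onto the
type I scale, and cross-reactive probe removal.  M-values (logit2 of
beta) are used downstream for regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, digamma, logsumexp, polygamma
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .datatypes import MethylationMatrix, ProbeManifest, RawIntensitySet

log = logging.getLogger(__name__)

BETA_OFFSET = 100.0
M_EPS = 1e-6

# ---------------------------------------------------------------------------
# beta / M transforms


def compute_beta(meth, unmeth, offset: float = BETA_OFFSET):
    """beta = M / (U + M + offset), elementwise.

    The offset regularizes low-intensity probes: a probe with no signal in
    either channel maps to beta = 0 rather than 0/0.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if (meth < 0).any() or (unmeth < 0).any():
        raise ValueError("intensities must be nonnegative")
    out = meth / (unmeth + meth + offset)
    return out.item() if out.ndim == 0 else out


def beta_to_m(beta, eps: float = M_EPS):
    """M = log2(beta / (1 - beta)) after clipping beta to [eps, 1-eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    out = np.log2(b / (1.0 - b))
    return out.item() if out.ndim == 0 else out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# detection p-values and QC filters


@dataclass
class DetectionPMatrix:
    values: pd.DataFrame  # probes x samples, in [0, 1]


def detection_pvalues(raw: RawIntensitySet) -> DetectionPMatrix:
    """One-sided z-test of total signal against negative-control background.

    Per sample, the summed red+green negative-control signal defines a
    background distribution with mean mu and SD sigma; a probe's detection
    p is P(background >= meth + unmeth) = 1 - Phi((total - mu) / sigma).
    """
    neg_red, neg_green = raw.negative_controls()
    if len(neg_red) < 10:
        raise ValueError("need >= 10 negative controls per channel")
    neg_sum = neg_red.values + neg_green.values
    mu = neg_sum.mean(axis=0)
    sigma = neg_sum.std(axis=0, ddof=1)
    if (sigma == 0).any():
        raise ValueError("degenerate negative controls")
    total = raw.meth.values + raw.unmeth.values
    p = norm.sf((total - mu[None, :]) / sigma[None, :])
    return DetectionPMatrix(pd.DataFrame(p, index=raw.probe_ids,
                                         columns=raw.samples))


@dataclass
class QcResult:
    """Masks and retention lists produced by :func:`apply_qc_filters`."""

    mask: pd.DataFrame          # retained probes x retained samples, True = valid
    retained_samples: list
    retained_probes: list
    log: dict = field(default_factory=dict)


def apply_qc_filters(raw: RawIntensitySet, detp: DetectionPMatrix,
                     detection_p: float = 0.01, min_beads: int = 3,
                     sample_call_rate: float = 0.8,
                     max_probe_missing: float = 0.05) -> QcResult:
    """Mask unreliable cells, drop poor samples, then failing probes.

    A measurement cell is masked when it has fewer than ``min_beads``
    functional beads or detection p above ``detection_p``.  Samples with
    less than ``sample_call_rate`` unmasked cells are dropped; probes
    masked in more than ``max_probe_missing`` of retained samples are
    dropped entirely.
    """
    ok = (raw.beads.values >= min_beads) & (detp.values.values <= detection_p)
    call_rate = ok.mean(axis=0)
    keep_samples = call_rate >= sample_call_rate
    if not keep_samples.any():
        raise ValueError("all samples dropped by call-rate filter")
    ok_s = ok[:, keep_samples]
    probe_missing = 1.0 - ok_s.mean(axis=1)
    keep_probes = probe_missing <= max_probe_missing
    mask = pd.DataFrame(ok_s[keep_probes],
                        index=raw.probe_ids[keep_probes],
                        columns=raw.samples[keep_samples])
    info = {
        "n_cells_masked_beads": int((raw.beads.values < min_beads).sum()),
        "n_cells_masked_detection": int((detp.values.values > detection_p).sum()),
        "n_samples_dropped": int((~keep_samples).sum()),
        "samples_dropped": list(raw.samples[~keep_samples]),
        "n_probes_dropped": int((~keep_probes).sum()),
        "n_samples_retained": int(keep_samples.sum()),
        "n_probes_retained": int(keep_probes.sum()),
    }
    log.info("QC filters: %s", info)
    return QcResult(mask=mask,
                    retained_samples=list(raw.samples[keep_samples]),
                    retained_probes=list(raw.probe_ids[keep_probes]),
                    log=info)


# ---------------------------------------------------------------------------
# colour-bias correction and background subtraction


def probe_channels(manifest: ProbeManifest, probe_ids) -> tuple[np.ndarray, np.ndarray]:
    """Channel ('red'/'green') of the meth and unmeth signal per probe.

    Type I probes read both alleles in their design channel; type II
    probes read the methylated allele in green and the unmethylated in red.
    """
    sub = manifest.table.loc[probe_ids]
    is_two = (sub["design_type"] == "II").values
    chan = sub["channel"].values
    meth_ch = np.where(is_two, "green", chan)
    unmeth_ch = np.where(is_two, "red", chan)
    return meth_ch, unmeth_ch


def _quantile_map(values: np.ndarray, pool_sorted: np.ndarray,
                  target_sorted: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Map ``values`` through pool-ECDF -> target quantile function."""
    n = pool_sorted.size
    ranks = np.searchsorted(pool_sorted, values, side="right")
    p = (ranks - 0.5) / n
    p = np.clip(p, grid[0], grid[-1])
    return np.interp(p, grid, target_sorted)


def _quantile_curve(pool_sorted: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Quantile function of a sorted pool evaluated on ``grid``."""
    n = pool_sorted.size
    pp = (np.arange(n) + 0.5) / n
    return np.interp(grid, pp, pool_sorted)


def color_bias_correct(raw: RawIntensitySet,
                       manifest: ProbeManifest) -> RawIntensitySet:
    """Smooth-quantile normalization of the red and green channels.

    Per sample, the empirical quantile functions of all red-channel and all
    green-channel probe signals are each mapped onto their pointwise mean by
    monotone linear interpolation.  Type II probes contribute their component
    signals to each channel's pool but are left untouched by the cross-channel
    map; negative-control signals are passed through the same per-channel map
    so background subtraction stays consistent.
    """
    meth_ch, unmeth_ch = probe_channels(manifest, raw.probe_ids)
    is_one = (manifest.table.loc[raw.probe_ids, "design_type"] == "I").values
    m_red, m_green = meth_ch == "red", meth_ch == "green"
    u_red, u_green = unmeth_ch == "red", unmeth_ch == "green"
    if min(m_red.sum() + u_red.sum(), m_green.sum() + u_green.sum()) < 2:
        raise ValueError("each channel needs at least 2 probe signals")

    meth = raw.meth.values.copy()
    unmeth = raw.unmeth.values.copy()
    ctl_red = raw.controls_red.values.copy()
    ctl_green = raw.controls_green.values.copy()
    n_grid = 1000
    grid = (np.arange(n_grid) + 0.5) / n_grid

    for j in range(meth.shape[1]):
        red_pool = np.sort(np.concatenate([meth[m_red, j], unmeth[u_red, j]]))
        green_pool = np.sort(np.concatenate([meth[m_green, j],
                                             unmeth[u_green, j]]))
        target = 0.5 * (_quantile_curve(red_pool, grid)
                        + _quantile_curve(green_pool, grid))
        for sel_m, sel_u, pool in ((m_red & is_one, u_red & is_one, red_pool),
                                   (m_green & is_one, u_green & is_one,
                                    green_pool)):
            meth[sel_m, j] = _quantile_map(meth[sel_m, j], pool, target, grid)
            unmeth[sel_u, j] = _quantile_map(unmeth[sel_u, j], pool, target,
                                             grid)
        ctl_red[:, j] = _quantile_map(ctl_red[:, j], red_pool, target, grid)
        ctl_green[:, j] = _quantile_map(ctl_green[:, j], green_pool, target,
                                        grid)

    wrap = lambda a, tmpl: pd.DataFrame(a, index=tmpl.index,
                                        columns=tmpl.columns)
    return RawIntensitySet(meth=wrap(meth, raw.meth),
                           unmeth=wrap(unmeth, raw.unmeth),
                           beads=raw.beads,
                           controls_red=wrap(ctl_red, raw.controls_red),
                           controls_green=wrap(ctl_green, raw.controls_green),
                           control_type=raw.control_type)


def background_subtract(raw: RawIntensitySet, manifest: ProbeManifest,
                        floor: float = 1.0) -> RawIntensitySet:
    """Subtract the per-sample, per-channel median negative-control signal.

    The median is used rather than the mean for robustness; subtracted
    signals are floored at ``floor`` to keep later ratios positive.
    """
    neg_red, neg_green = raw.negative_controls()
    med = {"red": np.median(neg_red.values, axis=0),
           "green": np.median(neg_green.values, axis=0)}
    meth_ch, unmeth_ch = probe_channels(manifest, raw.probe_ids)

    def corrected(mat: np.ndarray, chans: np.ndarray) -> np.ndarray:
        out = mat.copy()
        for ch in ("red", "green"):
            sel = chans == ch
            out[sel] = np.maximum(mat[sel] - med[ch][None, :], floor)
        return out

    wrap = lambda a, tmpl: pd.DataFrame(a, index=tmpl.index,
                                        columns=tmpl.columns)
    return RawIntensitySet(
        meth=wrap(corrected(raw.meth.values, meth_ch), raw.meth),
        unmeth=wrap(corrected(raw.unmeth.values, unmeth_ch), raw.unmeth),
        beads=raw.beads, controls_red=raw.controls_red,
        controls_green=raw.controls_green, control_type=raw.control_type)


def betas_from_intensities(raw: RawIntensitySet, mask: pd.DataFrame,
                           stage: str = "corrected") -> MethylationMatrix:
    """Beta-value matrix over the QC-retained probes and samples."""
    meth = raw.meth.loc[mask.index, mask.columns].values
    unmeth = raw.unmeth.loc[mask.index, mask.columns].values
    vals = compute_beta(meth, unmeth)
    vals = np.where(mask.values, vals, np.nan)
    return MethylationMatrix(
        values=pd.DataFrame(vals, index=mask.index, columns=mask.columns),
        scale="beta", mask=mask, stage=stage)


# ---------------------------------------------------------------------------
# BMIQ


@dataclass
class BetaMixture:
    """Three-component beta mixture over [0, 1]: states U, H, M."""

    params: dict            # state -> (a, b)
    weights: dict           # state -> pi
    loglik_trace: list
    converged: bool

    STATES = ("U", "H", "M")

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """n x 3 array of log(pi_k) + log BetaPDF(x; a_k, b_k)."""
        logx, log1mx = np.log(x), np.log1p(-x)
        cols = []
        for k in self.STATES:
            a, b = self.params[k]
            cols.append(np.log(max(self.weights[k], 1e-300))
                        + (a - 1) * logx + (b - 1) * log1mx - betaln(a, b))
        return np.column_stack(cols)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        ld = self.log_density(x)
        ld -= logsumexp(ld, axis=1, keepdims=True)
        return np.exp(ld)

    def states(self, x: np.ndarray) -> np.ndarray:
        """Max-responsibility state index (0=U, 1=H, 2=M) per value."""
        return np.argmax(self.log_density(x), axis=1)


def _moment_match(m: float, v: float) -> tuple[float, float]:
    """Beta(a, b) parameters from mean and variance, guarded."""
    m = min(max(m, 1e-4), 1 - 1e-4)
    v = max(min(v, 0.99 * m * (1 - m)), 1e-7)
    common = m * (1 - m) / v - 1.0
    return max(m * common, 1e-2), max((1 - m) * common, 1e-2)


def _beta_wmle(s1: float, s2: float, a0: float, b0: float,
               n_newton: int = 8) -> tuple[float, float]:
    """Weighted-MLE Beta(a, b) via Newton on the digamma equations.

    ``s1``/``s2`` are the responsibility-weighted means of log x and
    log(1-x); ``(a0, b0)`` (typically moment-matched) seed the iteration.
    A truncated Newton suffices inside EM: any improvement of the
    component objective keeps the outer loop an ascent (generalized EM).
    """
    a, b = max(a0, 1e-2), max(b0, 1e-2)
    for _ in range(n_newton):
        common = digamma(a + b)
        g1 = common - digamma(a) + s1
        g2 = common - digamma(b) + s2
        tri_ab = polygamma(1, a + b)
        j11 = tri_ab - polygamma(1, a)
        j22 = tri_ab - polygamma(1, b)
        det = j11 * j22 - tri_ab * tri_ab
        if abs(det) < 1e-300:
            break
        da = -(j22 * g1 - tri_ab * g2) / det
        db = -(j11 * g2 - tri_ab * g1) / det
        step = 1.0
        while (a + step * da <= 0 or b + step * db <= 0) and step > 1e-4:
            step *= 0.5
        a, b = a + step * da, b + step * db
        if abs(da) + abs(db) < 1e-8 * (a + b):
            break
    return min(max(a, 1e-2), 1e6), min(max(b, 1e-2), 1e6)


def fit_beta_mixture(x: np.ndarray, max_iter: int = 100, tol: float = 1e-5,
                     fit_size: int = 2000) -> BetaMixture:
    """EM fit of the 3-state beta mixture.

    Initialization assigns beta < 0.25 to U, beta > 0.75 to M, the rest to
    H.  The M-step moment-matches each component and refines it by a
    truncated Newton weighted MLE (a generalized EM, so the likelihood
    ascends); as a numerical safety net the fit stops, keeping the
    previous parameters, if an update would ever decrease the
    log-likelihood — the recorded trace is therefore non-decreasing.
    For speed the mixture is fit on at most ``fit_size`` evenly spaced
    order statistics (a deterministic, distribution-preserving subsample);
    the fitted mixture is then applied to all probes.
    """
    x = np.clip(np.asarray(x, dtype=float), M_EPS, 1 - M_EPS)
    if x.size > fit_size:
        xs = np.sort(x)
        idx = np.linspace(0, x.size - 1, fit_size).round().astype(int)
        x = xs[idx]
    init = np.column_stack([x < 0.25, (x >= 0.25) & (x <= 0.75), x > 0.75]) \
        .astype(float)
    # guard against empty components
    init += 1e-3
    mix = _mixture_from_resp(x, init / init.sum(axis=1, keepdims=True))
    prev_mix = mix
    trace: list[float] = []
    converged = False
    logx, log1mx = np.log(x), np.log1p(-x)
    for _ in range(max_iter):
        ld = np.empty((x.size, 3))
        for i, k in enumerate(BetaMixture.STATES):
            a, b = mix.params[k]
            ld[:, i] = (np.log(max(mix.weights[k], 1e-300))
                        + (a - 1) * logx + (b - 1) * log1mx - betaln(a, b))
        top = ld.max(axis=1)
        se = np.exp(ld - top[:, None])
        norm_ = se.sum(axis=1)
        ll = float((top + np.log(norm_)).sum())
        if trace and ll < trace[-1] - 1e-10:
            mix = prev_mix       # MoM step overshot; keep previous params
            converged = True
            break
        if trace and abs(ll - trace[-1]) <= max(tol * (abs(trace[-1]) + 1.0),
                                                5e-5 * x.size):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        prev_mix = mix
        mix = _mixture_from_resp(x, se / norm_[:, None])
    mix.loglik_trace = trace
    mix.converged = converged
    return mix


def _mixture_from_resp(x: np.ndarray, r: np.ndarray,
                       mle: bool = True) -> BetaMixture:
    """M-step: moment-matched (a, b) refined by weighted MLE per state."""
    logx, log1mx = np.log(x), np.log1p(-x)
    params, weights = {}, {}
    for idx, k in enumerate(BetaMixture.STATES):
        w = r[:, idx]
        sw = w.sum()
        weights[k] = float(sw / len(x))
        m = float((w * x).sum() / sw)
        v = float((w * (x - m) ** 2).sum() / sw)
        a0, b0 = _moment_match(m, v)
        if mle:
            s1 = float((w * logx).sum() / sw)
            s2 = float((w * log1mx).sum() / sw)
            params[k] = _beta_wmle(s1, s2, a0, b0)
        else:
            params[k] = (a0, b0)
    total = sum(weights.values())
    weights = {k: v / total for k, v in weights.items()}
    return BetaMixture(params=params, weights=weights, loglik_trace=[],
                       converged=False)


@dataclass
class BmiqFit:
    """Per-sample BMIQ fit: the two design-class mixtures and assignments."""

    mix_type1: BetaMixture
    mix_type2: BetaMixture
    states_type2: np.ndarray
    fallback: bool = False


def _bmiq_transform_sample(b1: np.ndarray, b2: np.ndarray,
                           max_iter: int, tol: float):
    """Transform type II betas ``b2`` onto the type I scale of ``b1``."""
    mix1 = fit_beta_mixture(b1, max_iter=max_iter, tol=tol)
    mix2 = fit_beta_mixture(b2, max_iter=max_iter, tol=tol)
    fit = BmiqFit(mix_type1=mix1, mix_type2=mix2,
                  states_type2=np.empty(0, dtype=int))
    if not (mix1.converged and mix2.converged):
        fit.fallback = True
        return b2.copy(), fit

    x2 = np.clip(b2, M_EPS, 1 - M_EPS)
    states = mix2.states(x2)
    fit.states_type2 = states
    out = x2.copy()
    sel_u, sel_h, sel_m = states == 0, states == 1, states == 2
    if not (sel_u.any() and sel_m.any()):
        fit.fallback = True
        return b2.copy(), fit

    aU2, bU2 = mix2.params["U"]
    aU1, bU1 = mix1.params["U"]
    p = beta_dist.cdf(x2[sel_u], aU2, bU2)
    out[sel_u] = beta_dist.ppf(np.clip(p, 1e-12, 1 - 1e-12), aU1, bU1)
    aM2, bM2 = mix2.params["M"]
    aM1, bM1 = mix1.params["M"]
    p = beta_dist.cdf(x2[sel_m], aM2, bM2)
    out[sel_m] = beta_dist.ppf(np.clip(p, 1e-12, 1 - 1e-12), aM1, bM1)

    if sel_h.any():
        lo_src, hi_src = x2[sel_u].max(), x2[sel_m].min()
        lo_dst, hi_dst = out[sel_u].max(), out[sel_m].min()
        if hi_src - lo_src > 1e-9 and hi_dst > lo_dst:
            scale = (hi_dst - lo_dst) / (hi_src - lo_src)
            out[sel_h] = lo_dst + (x2[sel_h] - lo_src) * scale
        # else: H support degenerate, leave untouched
    return np.clip(out, 0.0, 1.0), fit


def bmiq_normalize(betas: MethylationMatrix, manifest: ProbeManifest,
                   max_iter: int = 100, tol: float = 1e-5
                   ) -> tuple[MethylationMatrix, dict]:
    """Beta-mixture quantile normalization of type II probes, per sample.

    Each sample's type I and type II beta distributions are fit with
    3-state (unmethylated / hemimethylated / methylated) beta mixtures;
    type II U- and M-state probes are mapped through the corresponding
    type II CDF and inverse type I CDF, and H-state probes by a linear
    dilation between the transformed state boundaries.  Samples whose
    mixtures fail to converge fall back to the identity transform (logged).
    """
    if betas.scale != "beta":
        raise ValueError("bmiq_normalize expects beta scale")
    design = manifest.table.loc[betas.probe_ids, "design_type"].values
    is_two = design == "II"
    if not is_two.any() or is_two.all():
        raise ValueError("both design types must be present")
    vals = betas.values.values.copy()
    mask = betas.mask.values
    fits: dict = {}
    for j, sample in enumerate(betas.samples):
        obs = mask[:, j]
        one = obs & ~is_two
        two = obs & is_two
        transformed, fit = _bmiq_transform_sample(
            vals[one, j], vals[two, j], max_iter=max_iter, tol=tol)
        if fit.fallback:
            log.warning("BMIQ fallback to identity for sample %s", sample)
        vals[two, j] = transformed
        fits[sample] = fit
    out = pd.DataFrame(vals, index=betas.probe_ids, columns=betas.samples)
    return betas.copy_with(values=out, stage="bmiq"), fits


# ---------------------------------------------------------------------------
# cross-reactive probe removal


def remove_crossreactive(betas: MethylationMatrix,
                         blacklist) -> MethylationMatrix:
    """Drop probes named in the cross-reactive blacklist (absent ids ignored)."""
    blk = set(blacklist)
    present = betas.probe_ids.isin(blk)
    absent = blk - set(betas.probe_ids)
    if absent:
        log.info("blacklist entries absent from matrix (ignored): %d",
                 len(absent))
    log.info("removing %d cross-reactive probes", int(present.sum()))
    keep = ~present
    return betas.copy_with(values=betas.values.loc[keep],
                           mask=betas.mask.loc[keep], stage="filtered")
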