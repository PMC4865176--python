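"""Synthetic cohort and array-intensity generator.

Emulates the structure of a multicentre childhood cohort assayed on a
450K-style array: 308 unexposed and 58 prenatally tobacco-exposed
children (plus 18 early-only exposures coded missing and excluded from
analysis), covariate marginals matching the published cohort table,
6-leukocyte-type cell mixtures, 33 slides x 12 arrays of batch structure,
and five planted exposure effects on the beta scale (+0.09, -0.02, +0.05,
+0.04, +0.04).  Raw methylated/unmethylated signals, bead counts and
negative-control probes are produced so that every QC and normalization
stage downstream has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    CELL_TYPES, CellReference, ProbeManifest, RawIntensitySet, SampleSheet,
)
from .preprocess import beta_to_m, m_to_beta

N_REFERENCE_SITES = 500

#: the five planted differential-methylation effects, in discovery-rank
#: order: three MYO1G probes, one CNTNAP2 (the hypomethylated one) and one
#: FRMD4A probe.  delta_beta is the exposed-vs-unexposed difference.
_PLANTED = [
    ("cg12803068", 0.09, "7", 45002919, "MYO1G", "s_shore"),
    ("cg25949550", -0.02, "7", 145814306, "CNTNAP2", "s_shore"),
    ("cg22132788", 0.05, "7", 45002486, "MYO1G", "island"),
    ("cg11813497", 0.04, "10", 14372879, "FRMD4A", "open_sea"),
    ("cg19089201", 0.04, "7", 45002287, "MYO1G", "island"),
]

#: unexposed baseline methylation at the planted probes; chosen so that
#: the smaller effects sit near the unmethylated boundary where residual
#: variance is low (as for the reported CNTNAP2 probe, whose printed SE
#: rounds to 0.00)
PLANTED_BASELINES = (0.35, 0.045, 0.13, 0.10, 0.10)


def default_effects() -> list[tuple[str, float]]:
    """The five planted (probe label, delta_beta) pairs, in rank order."""
    return [(name, d) for name, d, *_ in _PLANTED]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the emulated study: 308 unexposed + 58 exposed +
    18 early-only children on 33 slides of 12 arrays, with the five
    planted beta-scale effects.  ``n_probes`` defaults to 20000 rather
    than full array scale to keep desk runtime; all operators are
    dimension-agnostic.
    """

    n_unexposed: int = 308
    n_exposed: int = 58
    n_early_only: int = 18
    n_probes: int = 20000
    n_negative_controls: int = 600
    n_slides: int = 33
    arrays_per_slide: int = 12
    planted_effects: list = None          # [(probe index, delta_beta)]
    failed_probe_fraction: float = 0.005
    low_bead_fraction: float = 0.002
    intensity_log_mean: float = float(np.log(10000.0))
    intensity_log_sd: float = 0.3
    background_mean: float = 200.0
    background_sd: float = 40.0
    batch_shift_sd: float = 25.0          # per-slide background shift
    slide_effect_sd: float = 0.08         # per-slide M-scale probe effect
    channel_bias_sd: float = 0.05         # per-sample log colour bias
    m_noise_sd: float = 0.5               # residual M-scale noise
    type2_shrink: float = 0.12            # type II compression toward 0.5
    type1_fraction: float = 0.28
    cell_dirichlet_alpha: tuple = (6.0, 3.6, 2.4, 1.5, 2.1, 14.4)
    covariate_effect_table: dict = field(default_factory=lambda: {
        "sex": 0.08, "age_months": 0.01, "centre": 0.12,
        "maternal_education": 0.08, "mother_smokes_age4": 0.06,
        "father_smokes_age4": 0.06,
    })
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("n_unexposed", "n_exposed", "n_probes",
                     "n_negative_controls", "n_slides", "arrays_per_slide"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_early_only < 0:
            raise ValueError("n_early_only must be nonnegative")
        if self.planted_effects is None:
            start = N_REFERENCE_SITES
            if self.n_probes >= start + len(_PLANTED):
                self.planted_effects = [
                    (start + i, d) for i, (_, d, *_r) in enumerate(_PLANTED)]
            else:
                self.planted_effects = []
        for idx, delta in self.planted_effects:
            if not 0 <= idx < self.n_probes:
                raise ValueError(f"planted probe index {idx} out of range")
            if not -1 < delta < 1:
                raise ValueError("delta_beta must lie in (-1, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_unexposed + self.n_exposed + self.n_early_only

    def noise_free_variant(self) -> "SimulationConfig":
        """The deterministic-signal variant used by chain-identity checks.

        Keeps the background distribution on negative controls (so the
        detection machinery has a scale) but makes probe signals exact:
        no residual noise, batch, covariate or channel effects, no type II
        compression, fixed total intensity, and background entering probe
        signals as its constant mean.
        """
        return replace(self, noise_free=True, failed_probe_fraction=0.0,
                       low_bead_fraction=0.0, batch_shift_sd=0.0)


# ---------------------------------------------------------------------------
# sample sheet

# Cohort-table marginal counts per exposure group (category counts sum to
# the group size: 308 unexposed, 58 exposed, pooled 366 for early-only)
_MARGINALS = {
    "girl": {0: (163, 145), 1: (25, 33), "pooled": (188, 178)},
    "centre": {  # DE, BE, IT, ES
        0: (29, 58, 122, 99),
        1: (2, 10, 14, 32),
        "pooled": (31, 68, 136, 131),
    },
    "education": {  # low, middle, high, missing
        0: (38, 163, 105, 2),
        1: (24, 27, 7, 0),
        "pooled": (62, 190, 112, 2),
    },
    "mother_smokes_age4": {0: (31, 277), 1: (40, 18), "pooled": (71, 295)},
    "father_smokes_age4": {0: (75, 233), 1: (27, 31), "pooled": (102, 264)},
    "formula_fed": {0: (190, 118), 1: (52, 6), "pooled": (242, 124)},
}
_CENTRE_ORDER = ("DE", "BE", "IT", "ES")
_EDU_ORDER = ("low", "middle", "high", None)


def _allocate(n: int, weights) -> np.ndarray:
    """Integer allocation of n over categories by largest remainder."""
    w = np.asarray(weights, dtype=float)
    exact = n * w / w.sum()
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


def _categorical_column(rng, n, counts, categories):
    alloc = _allocate(n, counts)
    col = np.repeat(np.arange(len(categories)), alloc)
    rng.shuffle(col)
    return np.asarray([categories[i] for i in col], dtype=object)


def generate_sample_sheet(config: SimulationConfig) -> SampleSheet:
    """Draw a cohort sheet matching the emulated study's marginal tables.

    Categorical covariates are assigned by exact largest-remainder counts
    within each exposure group (so generated tables match the published
    marginals by construction); continuous covariates are Normal draws.
    Samples are shuffled across the slide x array grid at random.
    """
    capacity = config.n_slides * config.arrays_per_slide
    if config.n_samples > capacity:
        raise ValueError(
            f"{config.n_samples} samples exceed slide capacity {capacity}")
    rng = np.random.default_rng([config.seed, 101])

    groups = []
    for group, n in (("unexposed", config.n_unexposed),
                     ("exposed", config.n_exposed),
                     ("early_only", config.n_early_only)):
        if n == 0:
            continue
        key = {"unexposed": 0, "exposed": 1, "early_only": "pooled"}[group]
        sex = _categorical_column(rng, n, _MARGINALS["girl"][key],
                                  ("girl", "boy"))
        centre = _categorical_column(rng, n, _MARGINALS["centre"][key],
                                     _CENTRE_ORDER)
        edu = _categorical_column(rng, n, _MARGINALS["education"][key],
                                  _EDU_ORDER)
        mother = _categorical_column(rng, n,
                                     _MARGINALS["mother_smokes_age4"][key],
                                     (True, False))
        father = _categorical_column(rng, n,
                                     _MARGINALS["father_smokes_age4"][key],
                                     (True, False))
        formula = _categorical_column(rng, n, _MARGINALS["formula_fed"][key],
                                      (True, False))
        age_mu = {"unexposed": 66.4, "exposed": 66.6, "early_only": 66.4}[group]
        age = rng.normal(age_mu, 0.8, size=n)
        girls = sex == "girl"
        bw_mu = {"unexposed": (3.3, 3.3), "exposed": (3.0, 3.2),
                 "early_only": (3.2, 3.3)}[group]
        bw_sd = {"unexposed": (0.3, 0.3), "exposed": (0.3, 0.4),
                 "early_only": (0.3, 0.3)}[group]
        bw = np.where(girls, rng.normal(bw_mu[0], bw_sd[0], size=n),
                      rng.normal(bw_mu[1], bw_sd[1], size=n))
        smoked_late = group == "exposed"
        smoked_early = group in ("exposed", "early_only")
        groups.append(pd.DataFrame({
            "sex": sex, "age_months": age, "centre": centre,
            "maternal_education": edu,
            "smoked_early": smoked_early, "smoked_late": smoked_late,
            "mother_smokes_age4": mother, "father_smokes_age4": father,
            "birthweight_kg": bw, "breastfed": ~formula.astype(bool),
            "gestation_weeks": rng.normal(39.8, 1.2 if group != "exposed"
                                          else 1.4, size=n),
            "maternal_age_years": rng.normal(
                31.9 if group == "unexposed" else 32.6, 4.2, size=n),
        }))
    frame = pd.concat(groups, ignore_index=True)
    order = rng.permutation(len(frame))
    frame = frame.iloc[order].reset_index(drop=True)
    frame.index = pd.Index([f"S{i + 1:04d}" for i in range(len(frame))],
                           name="sample_id")
    exposure = pd.array(
        [1 if l else (None if e else 0)
         for e, l in zip(frame["smoked_early"], frame["smoked_late"])],
        dtype="Int64")
    frame["exposure"] = exposure
    positions = np.array([(s + 1, a + 1) for s in range(config.n_slides)
                          for a in range(config.arrays_per_slide)])
    chosen = positions[rng.permutation(capacity)[:len(frame)]]
    frame["slide"] = chosen[:, 0]
    frame["array_position"] = chosen[:, 1]
    return SampleSheet(frame)


# ---------------------------------------------------------------------------
# manifest and cell reference


def generate_manifest(config: SimulationConfig) -> ProbeManifest:
    """Simulated probe annotation: ids, random positions, design types.

    The first ``N_REFERENCE_SITES`` probes are the designated cell-type
    reference sites; the next five carry the planted effects and are laid
    out as type I probes (BMIQ maps type II onto the type I scale, so the
    planted beta-scale effects are interpretable as-is).  A sprinkling of
    probes land on X and Y — the pipeline must retain them.
    """
    rng = np.random.default_rng([config.seed, 202])
    n = config.n_probes
    ids = np.array([f"cg_s{i:07d}" for i in range(n)], dtype=object)
    n_ref = min(N_REFERENCE_SITES, n)
    ids[:n_ref] = [f"cgref{i:04d}" for i in range(n_ref)]
    chroms = np.asarray(
        [str(c) for c in rng.integers(1, 23, size=n)], dtype=object)
    # ~1% sex-chromosome probes
    sex_idx = rng.choice(n, size=max(2, n // 100), replace=False)
    chroms[sex_idx] = rng.choice(["X", "Y"], size=len(sex_idx))
    positions = rng.integers(10_000, 200_000_000, size=n)
    genes = np.asarray([""] * n, dtype=object)
    design = np.where(rng.random(n) < config.type1_fraction, "I", "II") \
        .astype(object)
    planted_rows = {idx for idx, _ in config.planted_effects}
    default_rows = dict(zip((N_REFERENCE_SITES + i for i in range(len(_PLANTED))),
                            _PLANTED))
    cgi = rng.choice(["island", "n_shore", "s_shore", "shelf", "open_sea"],
                     size=n, p=[0.3, 0.12, 0.12, 0.08, 0.38]).astype(object)
    for idx in sorted(planted_rows):
        design[idx] = "I"
        if idx in default_rows:
            name, _d, chrom, pos, gene, rel = default_rows[idx]
            ids[idx], chroms[idx], positions[idx] = name, chrom, pos
            genes[idx], cgi[idx] = gene, rel
    channel = np.asarray(["both"] * n, dtype=object)
    is_one = design == "I"
    ones = np.flatnonzero(is_one)
    half = rng.permutation(len(ones))
    channel[ones[half[: len(ones) // 2]]] = "red"
    channel[ones[half[len(ones) // 2:]]] = "green"
    table = pd.DataFrame({
        "chromosome": chroms, "position": positions, "gene": genes,
        "design_type": design, "channel": channel, "cgi_relation": cgi,
    }, index=pd.Index(ids, name="probe_id"))
    return ProbeManifest(table)


def generate_cell_reference(n_sites: int, seed: int,
                            site_ids=None) -> CellReference:
    """Reference mean-beta profiles that separate the 6 leukocyte types.

    Each site gets a baseline and 1-3 discriminating cell types shifted
    by at least 0.3 in beta, mimicking the strongly cell-type-informative
    sites used for constrained-projection deconvolution.
    """
    if n_sites < 6:
        raise ValueError("need at least 6 reference sites")
    rng = np.random.default_rng([int(seed), 303])
    base = rng.uniform(0.08, 0.35, size=n_sites)
    high = rng.random(n_sites) < 0.5
    base = np.where(high, 1.0 - base, base)
    profile = np.tile(base[:, None], (1, 6))
    for i in range(n_sites):
        k = rng.integers(1, 4)
        cols = rng.choice(6, size=k, replace=False)
        shift = rng.uniform(0.3, 0.6)
        direction = -1.0 if high[i] else 1.0
        profile[i, cols] = np.clip(base[i] + direction * shift, 0.02, 0.98)
    if site_ids is None:
        site_ids = [f"cgref{i:04d}" for i in range(n_sites)]
    return CellReference(pd.DataFrame(profile, index=pd.Index(site_ids,
                                                              name="probe_id"),
                                      columns=list(CELL_TYPES)))


# ---------------------------------------------------------------------------
# intensities


def _covariate_design(sheet: SampleSheet) -> tuple[np.ndarray, list[str]]:
    f = sheet.frame
    cols, names = [], []
    cols.append((f["sex"] == "girl").astype(float).values)
    names.append("sex")
    cols.append((f["age_months"].values - 66.4))
    names.append("age_months")
    for c in ("DE", "IT", "ES"):
        cols.append((f["centre"] == c).astype(float).values)
        names.append("centre")
    for e in ("middle", "high"):
        cols.append((f["maternal_education"] == e).astype(float).values)
        names.append("maternal_education")
    cols.append(f["mother_smokes_age4"].astype(float).values)
    names.append("mother_smokes_age4")
    cols.append(f["father_smokes_age4"].astype(float).values)
    names.append("father_smokes_age4")
    return np.column_stack(cols), names


def true_beta_matrix(config: SimulationConfig, sheet: SampleSheet,
                     reference: CellReference, rng) -> tuple[np.ndarray, np.ndarray]:
    """(samples x probes true beta, samples x 6 cell fractions)."""
    n_s, n_p = len(sheet), config.n_probes
    w = rng.dirichlet(config.cell_dirichlet_alpha, size=n_s)
    n_ref = min(len(reference), n_p)

    # symmetric low/mid/high mixture: the red and green signal pools then
    # share a distribution, so colour correction removes bias only
    baseline = np.empty(n_p)
    cls = rng.choice(3, size=n_p, p=[0.425, 0.15, 0.425])
    baseline[cls == 0] = rng.beta(2, 18, size=int((cls == 0).sum()))
    baseline[cls == 1] = rng.beta(5, 5, size=int((cls == 1).sum()))
    baseline[cls == 2] = rng.beta(18, 2, size=int((cls == 2).sum()))
    for i, (idx, _delta) in enumerate(config.planted_effects):
        baseline[idx] = PLANTED_BASELINES[i % len(PLANTED_BASELINES)]

    m = np.tile(beta_to_m(np.clip(baseline, 5e-3, 1 - 5e-3)), (n_s, 1))
    m[:, :n_ref] = beta_to_m(
        np.clip(w @ reference.profile.values[:n_ref].T, 5e-3, 1 - 5e-3))

    if not config.noise_free:
        design, names = _covariate_design(sheet)
        sds = np.array([config.covariate_effect_table.get(n, 0.0)
                        for n in names])
        gamma = rng.normal(size=(design.shape[1], n_p)) * sds[:, None]
        m += design @ gamma
        slide_codes = pd.factorize(sheet.frame["slide"])[0]
        u = rng.normal(size=slide_codes.max() + 1)
        v = rng.normal(size=n_p)
        m += config.slide_effect_sd * np.outer(u[slide_codes], v)
        m += rng.normal(0.0, config.m_noise_sd, size=(n_s, n_p))

    beta = m_to_beta(m)
    exposed = (sheet.frame["exposure"] == 1).fillna(False).to_numpy(dtype=bool)
    for idx, delta in config.planted_effects:
        beta[exposed, idx] = beta[exposed, idx] + delta
    np.clip(beta, 1e-3, 1 - 1e-3, out=beta)
    return beta, w


def generate_intensities(config: SimulationConfig, sheet: SampleSheet,
                         manifest: ProbeManifest,
                         reference: CellReference) -> RawIntensitySet:
    """Map true betas to raw two-channel signals with noise and QC failures.

    Total intensity is LogNormal; both channels receive additive Gaussian
    background whose mean shifts per slide (shared with the negative
    controls, so control-probe PCA can see the batch), and per-sample
    multiplicative colour bias.  A fraction of probe x sample cells fail
    (background-only signal) and another fraction get < 3 beads.
    """
    if len(manifest) != config.n_probes:
        raise ValueError("manifest size does not match config.n_probes")
    missing_ref = set(reference.site_ids) - set(manifest.probe_ids)
    if missing_ref:
        raise ValueError(f"reference sites absent from manifest: "
                         f"{sorted(missing_ref)[:3]}...")
    for idx, _ in config.planted_effects:
        if idx >= len(manifest):
            raise ValueError(f"planted probe index {idx} not in manifest")

    rng = np.random.default_rng([config.seed, 404])
    beta_true, _w = true_beta_matrix(config, sheet, reference, rng)
    n_s, n_p = beta_true.shape

    beta_meas = beta_true.copy()
    design = manifest.table["design_type"].values
    is_two = design == "II"
    if not config.noise_free and config.type2_shrink > 0:
        s = config.type2_shrink
        beta_meas[:, is_two] = 0.5 * s + (1 - s) * beta_meas[:, is_two]

    slide_codes = pd.factorize(sheet.frame["slide"])[0]
    n_slides = slide_codes.max() + 1
    u_bg = rng.normal(size=n_slides)
    bg_shift = config.batch_shift_sd * u_bg[slide_codes]

    if config.noise_free:
        T = np.full((n_s, n_p), np.exp(config.intensity_log_mean))
        bias_red = bias_green = np.ones(n_s)
    else:
        T = rng.lognormal(config.intensity_log_mean, config.intensity_log_sd,
                          size=(n_s, n_p))
        bias_red = rng.lognormal(0.0, config.channel_bias_sd, size=n_s)
        bias_green = rng.lognormal(0.0, config.channel_bias_sd, size=n_s)

    sig_m = T * beta_meas
    sig_u = T * (1.0 - beta_meas)

    n_failed = int(round(config.failed_probe_fraction * n_s * n_p))
    if n_failed:
        flat = rng.choice(n_s * n_p, size=n_failed, replace=False)
        fr, fc = np.unravel_index(flat, (n_s, n_p))
        sig_m[fr, fc] = 0.0
        sig_u[fr, fc] = 0.0

    if config.noise_free:
        bg_m = np.broadcast_to((config.background_mean + bg_shift)[:, None],
                               (n_s, n_p)).copy()
        bg_u = bg_m.copy()
    else:
        bg_m = rng.normal(config.background_mean + bg_shift[:, None],
                          config.background_sd, size=(n_s, n_p))
        bg_u = rng.normal(config.background_mean + bg_shift[:, None],
                          config.background_sd, size=(n_s, n_p))
    sig_m = np.clip(sig_m + bg_m, 0.0, None)
    sig_u = np.clip(sig_u + bg_u, 0.0, None)

    # channel bias: type I probes read both alleles in the design channel;
    # type II read meth in green, unmeth in red
    chan = manifest.table["channel"].values
    meth_ch_green = is_two | (chan == "green")
    unmeth_ch_green = (~is_two) & (chan == "green")
    bias_m = np.where(meth_ch_green[None, :], bias_green[:, None],
                      bias_red[:, None])
    bias_u = np.where(unmeth_ch_green[None, :], bias_green[:, None],
                      bias_red[:, None])
    sig_m *= bias_m
    sig_u *= bias_u

    beads = 3 + rng.poisson(12.0, size=(n_s, n_p))
    n_low = int(round(config.low_bead_fraction * n_s * n_p))
    if n_low:
        flat = rng.choice(n_s * n_p, size=n_low, replace=False)
        lr, lc = np.unravel_index(flat, (n_s, n_p))
        beads[lr, lc] = rng.integers(0, 3, size=n_low)

    n_ctl = config.n_negative_controls
    ctl_red = rng.normal(config.background_mean + bg_shift[:, None],
                         config.background_sd, size=(n_s, n_ctl))
    ctl_green = rng.normal(config.background_mean + bg_shift[:, None],
                           config.background_sd, size=(n_s, n_ctl))
    ctl_red = np.clip(ctl_red, 0.0, None) * bias_red[:, None]
    ctl_green = np.clip(ctl_green, 0.0, None) * bias_green[:, None]

    samples = sheet.samples
    probe_index = manifest.probe_ids
    ctl_index = pd.Index([f"neg{i:04d}" for i in range(n_ctl)],
                         name="control_id")
    return RawIntensitySet(
        meth=pd.DataFrame(sig_m.T, index=probe_index, columns=samples),
        unmeth=pd.DataFrame(sig_u.T, index=probe_index, columns=samples),
        beads=pd.DataFrame(beads.T, index=probe_index, columns=samples),
        controls_red=pd.DataFrame(ctl_red.T, index=ctl_index, columns=samples),
        controls_green=pd.DataFrame(ctl_green.T, index=ctl_index,
                                    columns=samples),
        control_type=pd.Series("negative", index=ctl_index,
                               name="control_type"),
    )


@dataclass
class SimulatedCohort:
    """Everything one synthetic run produces, plus the generating truth."""

    config: SimulationConfig
    sheet: SampleSheet
    manifest: ProbeManifest
    reference: CellReference
    raw: RawIntensitySet
    true_beta: np.ndarray = None       # samples x probes
    true_fractions: np.ndarray = None  # samples x 6


def simulate_cohort(config: SimulationConfig,
                    keep_truth: bool = True) -> SimulatedCohort:
    """Generate sheet, manifest, reference and raw intensities together."""
    sheet = generate_sample_sheet(config)
    manifest = generate_manifest(config)
    n_ref = min(N_REFERENCE_SITES, config.n_probes)
    reference = generate_cell_reference(n_ref, config.seed)
    # reuse one stream so intensities see the same truth recorded here
    rng = np.random.default_rng([config.seed, 404])
    truth = true_beta_matrix(config, sheet, reference, rng) if keep_truth \
        else (None, None)
    raw = generate_intensities(config, sheet, manifest, reference)
    return SimulatedCohort(config=config, sheet=sheet, manifest=manifest,
                           reference=reference, raw=raw,
                           true_beta=truth[0], true_fractions=truth[1])
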