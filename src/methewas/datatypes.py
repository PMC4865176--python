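"""Core containers for 450K-style methylation analysis.

All containers are thin, validated wrappers around pandas objects.  Probe
matrices are oriented probes x samples; sample sheets and cell-fraction
tables are indexed by sample id.  Beta-values live in [0, 1] and are
interpretable as percent methylation; M-values are their logit2 transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_TYPES = ("CD4T", "CD8T", "B", "NK", "monocyte", "granulocyte")
CENTRES = ("BE", "DE", "IT", "ES")
EDUCATION_LEVELS = ("low", "middle", "high")
SEXES = ("girl", "boy")
DESIGN_TYPES = ("I", "II")
CHANNELS = ("red", "green", "both")
CGI_RELATIONS = ("island", "n_shore", "s_shore", "shelf", "open_sea")

#: required sample-sheet columns (beyond the index of sample ids)
SHEET_COLUMNS = (
    "slide", "array_position", "sex", "age_months", "centre",
    "maternal_education", "smoked_early", "smoked_late", "exposure",
    "mother_smokes_age4", "father_smokes_age4", "birthweight_kg", "breastfed",
)


def code_exposure(smoked_early: bool, smoked_late: bool):
    """Code prenatal tobacco exposure from the two questionnaire items.

    Returns 1 if the mother smoked beyond gestational week 12, 0 if she
    never smoked, and ``None`` (missing) if she smoked only during the
    first 12 weeks — children with early-only exposure are excluded from
    analysis rather than counted in either group.
    """
    if smoked_late:
        return 1
    if smoked_early:
        return None
    return 0


@dataclass
class ProbeManifest:
    """Per-probe annotation: location, gene, Infinium design type, channel.

    ``table`` is indexed by probe id with columns chromosome, position
    (1-based, build-37 convention), gene, design_type (I/II), channel
    (red/green for type I, both for type II) and cgi_relation.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate probe_id: {dup!r}")
        bad = set(t["design_type"]) - set(DESIGN_TYPES)
        if bad:
            raise ValueError(f"unknown design_type: {sorted(bad)}")
        bad = set(t["channel"]) - set(CHANNELS)
        if bad:
            raise ValueError(f"unknown channel: {sorted(bad)}")
        is_one = t["design_type"] == "I"
        if (t.loc[is_one, "channel"] == "both").any():
            raise ValueError("type I probes must carry channel red or green")
        if (t.loc[~is_one, "channel"] != "both").any():
            raise ValueError("type II probes must carry channel 'both'")
        if (t["position"] < 1).any():
            raise ValueError("positions must be >= 1")
        bad = set(t["cgi_relation"]) - set(CGI_RELATIONS)
        if bad:
            raise ValueError(f"unknown cgi_relation: {sorted(bad)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RawIntensitySet:
    """Methylated/unmethylated signals, bead counts and control probes.

    ``meth``, ``unmeth`` and ``beads`` share a probe index and sample
    columns; ``controls_red``/``controls_green`` share a control-probe
    index (with per-control labels in ``control_type``) and the same
    sample columns.  At least 10 negative controls per channel are
    required: they define the background distribution used for detection
    p-values and background subtraction.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    beads: pd.DataFrame
    controls_red: pd.DataFrame
    controls_green: pd.DataFrame
    control_type: pd.Series

    def __post_init__(self):
        samples = self.meth.columns
        for name in ("unmeth", "beads", "controls_red", "controls_green"):
            other = getattr(self, name).columns
            if not samples.equals(other):
                missing = sorted(set(samples).symmetric_difference(other))
                raise ValueError(
                    f"sample axes differ between meth and {name}: {missing}")
        for name in ("unmeth", "beads"):
            if not self.meth.index.equals(getattr(self, name).index):
                raise ValueError(f"probe axes differ between meth and {name}")
        if not self.controls_red.index.equals(self.controls_green.index):
            raise ValueError("control probe axes differ between channels")
        if int((self.control_type == "negative").sum()) < 10:
            raise ValueError(
                "no negative controls (need >= 10 per channel)"
                if not (self.control_type == "negative").any()
                else "fewer than 10 negative controls per channel")
        if (self.meth.values < 0).any() or (self.unmeth.values < 0).any():
            raise ValueError("negative intensities")

    @property
    def samples(self) -> pd.Index:
        return self.meth.columns

    @property
    def probe_ids(self) -> pd.Index:
        return self.meth.index

    def negative_controls(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        neg = self.control_type == "negative"
        return self.controls_red.loc[neg], self.controls_green.loc[neg]


@dataclass
class MethylationMatrix:
    """A probes x samples methylation matrix with a validity mask.

    ``scale`` is "beta" (values in [0, 1]) or "mvalue"; ``mask`` is True
    where a measurement passed QC.  Masked cells hold NaN.  ``stage``
    records provenance (raw/corrected/bmiq/filtered).
    """

    values: pd.DataFrame
    scale: str
    mask: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self):
        if self.scale not in ("beta", "mvalue"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.shape != self.mask.shape:
            raise ValueError("mask dimensions must equal values dimensions")
        if self.scale == "beta":
            v = self.values.values[self.mask.values]
            if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
                raise ValueError("beta values outside [0, 1]")

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def copy_with(self, values=None, scale=None, mask=None, stage=None):
        return MethylationMatrix(
            values=self.values if values is None else values,
            scale=self.scale if scale is None else scale,
            mask=self.mask if mask is None else mask,
            stage=self.stage if stage is None else stage,
        )


@dataclass
class SampleSheet:
    """Cohort sheet: exposure coding, covariates and array assignment."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = set(SHEET_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        f = self.frame
        if f.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if f["centre"].isna().any():
            raise ValueError("centre must be non-missing")
        bad = set(f["centre"].dropna()) - set(CENTRES)
        if bad:
            raise ValueError(f"unknown centre: {sorted(bad)}")
        bad = set(f["sex"].dropna()) - set(SEXES)
        if bad:
            raise ValueError(f"unknown sex: {sorted(bad)}")
        if not ((f["array_position"] >= 1) & (f["array_position"] <= 12)).all():
            raise ValueError("array_position must lie in 1..12")
        # exposure must follow the questionnaire coding rule
        expected = pd.array(
            [code_exposure(e, l)
             for e, l in zip(f["smoked_early"], f["smoked_late"])],
            dtype="Int64")
        got = f["exposure"].astype("Int64").values
        same = (pd.isna(expected) & pd.isna(got)) | (expected == got)
        if not bool(np.all(same.to_numpy(dtype=bool, na_value=False))):
            raise ValueError("exposure inconsistent with smoking history")

    @property
    def samples(self) -> pd.Index:
        return self.frame.index

    def analysed(self) -> "SampleSheet":
        """Drop samples whose exposure is missing (early-only smokers)."""
        keep = self.frame["exposure"].notna()
        return SampleSheet(self.frame.loc[keep].copy())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CellReference:
    """Reference mean beta profile (sites x 6 leukocyte types)."""

    profile: pd.DataFrame  # index: site probe ids; columns: CELL_TYPES

    def __post_init__(self):
        if tuple(self.profile.columns) != CELL_TYPES:
            raise ValueError(f"reference columns must be {CELL_TYPES}")
        v = self.profile.values
        if (v < 0).any() or (v > 1).any():
            raise ValueError("reference profile entries must lie in [0, 1]")
        if self.profile.index.has_duplicates:
            raise ValueError("duplicate reference site ids")

    @property
    def site_ids(self) -> pd.Index:
        return self.profile.index

    def __len__(self) -> int:
        return len(self.profile)


@dataclass
class CellFractions:
    """Estimated leukocyte fractions, samples x 6, nonnegative.

    No sum-to-one constraint is imposed: the constrained projection
    leaves totals free (they are typically near 1).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        if tuple(self.frame.columns) != CELL_TYPES:
            raise ValueError(f"cell-fraction columns must be {CELL_TYPES}")
        if (self.frame.values < -1e-12).any():
            raise ValueError("cell fractions must be nonnegative")


@dataclass
class EwasResult:
    """Per-CpG association results plus global diagnostics.

    ``table`` rows (sorted ascending by p): probe_id, chromosome, gene,
    position, m_effect (M-scale exposure coefficient), se_m, beta_diff
    (adjusted beta-scale difference), se_beta, p_value, q_value.
    """

    table: pd.DataFrame
    lambda_: float
    n_samples: int
    n_probes: int
    skipped: list = field(default_factory=list)

    def __post_init__(self):
        t = self.table
        if len(t):
            if (t["q_value"].values + 1e-12 < t["p_value"].values).any():
                raise ValueError("q_value must be >= p_value")
            if not (t["beta_diff"].abs() < 1).all():
                raise ValueError("beta_diff must lie in (-1, 1)")
            if self.lambda_ <= 0:
                raise ValueError("lambda must be positive")

    def top(self, n: int = 25) -> pd.DataFrame:
        return self.table.nsmallest(n, "p_value")
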