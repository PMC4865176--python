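"""Tab-delimited interchange formats for every pipeline stage.

All readers accept plain or gzip-compressed TSV (pandas infers from the
``.gz`` suffix).  Matrices are written with the probe/control id in the
first column and one column per sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    CELL_TYPES, CellFractions, CellReference, EwasResult, MethylationMatrix,
    ProbeManifest, RawIntensitySet, SampleSheet,
)

MANIFEST_COLUMNS = ["probe_id", "chromosome", "position", "gene",
                    "design_type", "channel", "cgi_relation"]


def read_manifest(path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "gene": str},
                     keep_default_na=False, na_values=[])
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df["position"] = df["position"].astype(int)
    return ProbeManifest(df.set_index("probe_id"))


def write_manifest(manifest: ProbeManifest, path) -> None:
    manifest.table.reset_index().rename(columns={"index": "probe_id"}) \
        .to_csv(path, sep="\t", index=False)


def _read_matrix(path, id_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if id_col not in df.columns:
        raise ValueError(f"{path}: expected id column {id_col!r}")
    return df.set_index(id_col)


def read_intensities(meth_path, unmeth_path, beads_path,
                     controls_path) -> RawIntensitySet:
    """Read the four intensity tables into an aligned RawIntensitySet.

    The controls file is long on (control_id, channel): columns
    control_id, control_type, channel, then one column per sample.
    """
    meth = _read_matrix(meth_path, "probe_id")
    unmeth = _read_matrix(unmeth_path, "probe_id")
    beads = _read_matrix(beads_path, "probe_id")
    for name, df in (("unmeth", unmeth), ("beads", beads)):
        if not meth.columns.equals(df.columns):
            diff = sorted(set(meth.columns).symmetric_difference(df.columns))
            raise ValueError(f"sample axes differ between meth and {name}: {diff}")
    ctl = pd.read_csv(controls_path, sep="\t")
    for col in ("control_id", "control_type", "channel"):
        if col not in ctl.columns:
            raise ValueError(f"controls file missing column {col!r}")
    red = ctl[ctl["channel"] == "red"].set_index("control_id")
    green = ctl[ctl["channel"] == "green"].set_index("control_id")
    ctype = red["control_type"]
    red = red.drop(columns=["control_type", "channel"])
    green = green.drop(columns=["control_type", "channel"])
    green = green.reindex(red.index)
    if not (ctype == "negative").any():
        raise ValueError("no negative controls")
    sample_cols = meth.columns
    if not red.columns.equals(sample_cols):
        diff = sorted(set(sample_cols).symmetric_difference(red.columns))
        raise ValueError(f"sample axes differ between meth and controls: {diff}")
    return RawIntensitySet(meth=meth, unmeth=unmeth, beads=beads.astype(int),
                           controls_red=red, controls_green=green,
                           control_type=ctype)


def write_intensities(raw: RawIntensitySet, meth_path, unmeth_path,
                      beads_path, controls_path) -> None:
    raw.meth.rename_axis("probe_id").reset_index().to_csv(
        meth_path, sep="\t", index=False, float_format="%.4f")
    raw.unmeth.rename_axis("probe_id").reset_index().to_csv(
        unmeth_path, sep="\t", index=False, float_format="%.4f")
    raw.beads.rename_axis("probe_id").reset_index().to_csv(
        beads_path, sep="\t", index=False)
    rows = []
    for channel, mat in (("red", raw.controls_red), ("green", raw.controls_green)):
        block = mat.round(4).rename_axis("control_id").reset_index()
        block.insert(1, "control_type", raw.control_type.values)
        block.insert(2, "channel", channel)
        rows.append(block)
    pd.concat(rows, ignore_index=True).to_csv(controls_path, sep="\t",
                                              index=False)


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    df = df.set_index("sample_id")
    for col in ("smoked_early", "smoked_late", "mother_smokes_age4",
                "father_smokes_age4", "breastfed"):
        df[col] = df[col].astype(bool)
    df["exposure"] = df["exposure"].astype("Int64")
    if "maternal_education" in df:
        df["maternal_education"] = df["maternal_education"].where(
            df["maternal_education"].notna(), None)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.4f")


def read_cell_reference(path) -> CellReference:
    df = _read_matrix(path, "probe_id")
    return CellReference(df[list(CELL_TYPES)])


def write_cell_reference(reference: CellReference, path) -> None:
    reference.profile.rename_axis("probe_id").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.4f")


def read_methylation(path, scale: str, stage: str = "raw") -> MethylationMatrix:
    df = _read_matrix(path, "probe_id")
    mask = df.notna()
    return MethylationMatrix(values=df, scale=scale, mask=mask, stage=stage)


def write_methylation(matrix: MethylationMatrix, path) -> None:
    vals = matrix.values.where(matrix.mask)
    vals.rename_axis("probe_id").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def write_cell_fractions(fractions: CellFractions, path) -> None:
    fractions.frame.rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.4f")


def read_cell_fractions(path) -> CellFractions:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return CellFractions(df.set_index("sample_id")[list(CELL_TYPES)])


def read_blacklist(path) -> list[str]:
    """One probe id per line, '#' comments allowed."""
    out = []
    import gzip
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out


def write_ewas_results(result: EwasResult, path) -> None:
    """Write the top-table TSV, sorted ascending by p.

    Column styling follows the usual published top-table layout: the
    adjusted beta-scale difference and its SE with 2 decimals, p and FDR
    in scientific notation with 3 significant digits.
    """
    t = result.table.sort_values(
        ["p_value", "probe_id"], kind="mergesort").reset_index(drop=True)
    out = pd.DataFrame({
        "CpG ID": t["probe_id"],
        "CHR": t["chromosome"],
        "Gene": t["gene"],
        "Position (bp)": t["position"],
        "Beta difference": t["beta_diff"].map(lambda x: f"{x:.2f}"),
        "SE": t["se_beta"].map(lambda x: f"{x:.2f}"),
        "P-value": t["p_value"].map(lambda x: f"{x:.2E}"),
        "FDR": t["q_value"].map(lambda x: f"{x:.2E}"),
    })
    out.to_csv(path, sep="\t", index=False)
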