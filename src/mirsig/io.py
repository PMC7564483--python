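"""File formats of the pipeline.

Three plain-text inputs drive everything: a miRNA x sample raw-count TSV
(matrix convention of expression tools: miRNA rows, sample columns), a
long-form ddPCR CSV (one measurement per row, because each sample is
assayed for a sparse panel), and a sample-metadata CSV. Outputs carry a
``#``-prefixed header line with the tool version and a hash of the
producing configuration, and every reader skips such comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .ddpcr import DEFAULT_DROPLET_VOLUME_NL, quantify
from .errors import FormatError
from .screen import CASE, CONTROL, CountMatrix
from .simulate import MUT, NA, WT, Cohort

METADATA_COLUMNS = ("group", "kras_status")


def config_hash(config: Any) -> str:
    """Short stable hash of a configuration mapping/dataclass for provenance."""
    if hasattr(config, "__dataclass_fields__"):
        config = {k: getattr(config, k) for k in config.__dataclass_fields__}
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _header_line(extra: Mapping[str, Any] | None = None) -> str:
    parts = [f"# mirsig v{__version__}"]
    for key, value in (extra or {}).items():
        parts.append(f"{key}={value}")
    return " ".join(parts)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    sep: str = "\t",
    index: bool = True,
    header_info: Mapping[str, Any] | None = None,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_line(header_info) + "\n")
        df.to_csv(fh, sep=sep, index=index)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata: sample_id, group (CONTROL/CASE), kras_status (WT/MUT/NA)."""
    df = pd.read_csv(path, comment="#", dtype=str)
    for col in ("sample_id",) + METADATA_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"metadata is missing column '{col}'")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id in metadata: {dupes}")
    df = df.set_index("sample_id")
    df["kras_status"] = df["kras_status"].fillna(NA)
    bad_group = set(df["group"]) - {CONTROL, CASE}
    if bad_group:
        raise FormatError(f"unknown group labels: {sorted(bad_group)}")
    bad_kras = set(df["kras_status"]) - {WT, MUT, NA}
    if bad_kras:
        raise FormatError(f"unknown kras_status values: {sorted(bad_kras)}")
    controls_with_kras = df[(df["group"] == CONTROL) & (df["kras_status"] != NA)]
    if len(controls_with_kras):
        raise FormatError(
            "control samples must have kras_status NA: "
            f"{list(controls_with_kras.index)}"
        )
    if "has_effect" in df.columns:
        df["has_effect"] = df["has_effect"].map({"True": True, "False": False})
    return df


def read_counts(
    path: str | Path, meta: pd.DataFrame | None = None
) -> pd.DataFrame | CountMatrix:
    """Raw-count TSV: first column miRNA id, remaining columns samples.

    Cells must be non-negative integers; duplicate miRNA ids are rejected.
    With sample metadata the result is a labeled :class:`CountMatrix`,
    otherwise the bare DataFrame.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"duplicate miRNA id(s): {dupes}")
    for col in df.columns:
        values = df[col]
        numeric = pd.to_numeric(values, errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric)) | (numeric < 0)
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"non-(non-negative-integer) count at miRNA '{row}', sample '{col}': "
                f"{values[bad].iloc[0]!r}"
            )
        df[col] = numeric.astype(int)
    df.index.name = "mirna_id"
    if meta is None:
        return df
    missing = [s for s in df.columns if s not in meta.index]
    if missing:
        raise FormatError(f"count samples missing from metadata: {missing}")
    return CountMatrix(counts=df, group=meta.loc[df.columns, "group"])


def write_counts(
    counts: pd.DataFrame | CountMatrix,
    path: str | Path,
    header_info: Mapping[str, Any] | None = None,
) -> None:
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    write_table(df, path, sep="\t", header_info=header_info)


def read_ddpcr(
    path: str | Path,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> pd.DataFrame:
    """Long-form ddPCR CSV into a (sample_id, mirna_id, copies_per_ul) frame.

    Each row needs either ``copies_per_ul`` directly or raw droplet counts
    (``n_negative_droplets``, ``n_total_droplets``), which are quantified
    through the Poisson partition model; mixed files are allowed. An
    optional ``dilution_factor`` column scales droplet-derived rows.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("sample_id", "mirna_id"):
        if col not in df.columns:
            raise FormatError(f"ddPCR table is missing column '{col}'")
    has_conc = "copies_per_ul" in df.columns
    has_droplets = {"n_negative_droplets", "n_total_droplets"} <= set(df.columns)
    if not has_conc and not has_droplets:
        raise FormatError(
            "ddPCR table needs copies_per_ul or droplet-count columns "
            "(n_negative_droplets, n_total_droplets)"
        )
    dupes = df.duplicated(subset=["sample_id", "mirna_id"])
    if dupes.any():
        pairs = df.loc[dupes, ["sample_id", "mirna_id"]].to_records(index=False)
        raise FormatError(f"duplicate (sample, miRNA) pair(s): {list(pairs)[:5]}")
    conc = df["copies_per_ul"].astype(float) if has_conc else pd.Series(np.nan, index=df.index)
    if has_droplets:
        dilution = (
            df["dilution_factor"].fillna(1.0).astype(float)
            if "dilution_factor" in df.columns
            else pd.Series(1.0, index=df.index)
        )
        for i in df.index[conc.isna()]:
            n_neg, n_tot = df.loc[i, "n_negative_droplets"], df.loc[i, "n_total_droplets"]
            if pd.isna(n_neg) or pd.isna(n_tot):
                raise FormatError(
                    f"row {i}: neither copies_per_ul nor complete droplet counts"
                )
            conc.loc[i] = quantify(
                int(n_neg), int(n_tot), droplet_volume_nl, float(dilution.loc[i])
            )
    elif conc.isna().any():
        raise FormatError("rows with empty copies_per_ul and no droplet counts")
    out = df[["sample_id", "mirna_id"]].copy()
    out["copies_per_ul"] = conc
    return out


def write_ddpcr(
    ddpcr: pd.DataFrame,
    path: str | Path,
    header_info: Mapping[str, Any] | None = None,
) -> None:
    write_table(ddpcr, path, sep=",", index=False, header_info=header_info)


def write_metadata(
    meta: pd.DataFrame,
    path: str | Path,
    header_info: Mapping[str, Any] | None = None,
) -> None:
    write_table(meta, path, sep=",", header_info=header_info)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort as the pipeline's three inputs plus truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    info = {"config": config_hash(cohort.config), "seed": cohort.config.seed}
    paths = {
        "counts": outdir / "counts.tsv",
        "ddpcr": outdir / "ddpcr.csv",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth.csv",
    }
    write_counts(cohort.counts, paths["counts"], header_info=info)
    write_ddpcr(cohort.ddpcr, paths["ddpcr"], header_info=info)
    write_metadata(cohort.meta, paths["metadata"], header_info=info)
    write_table(cohort.truth, paths["truth"], sep=",", header_info=info)
    return paths


def read_truth(path: str | Path) -> pd.DataFrame:
    """Simulation ground truth, with NULL/NA kept as literal category labels."""
    df = pd.read_csv(path, comment="#", keep_default_na=False,
                     na_values=[""], dtype={"direction": str})
    if "mirna_id" not in df.columns:
        raise FormatError("truth table is missing column 'mirna_id'")
    for col in ("true_fc", "baseline_copies_per_ul"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    for col in ("kras_target", "low_abundance"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df.set_index("mirna_id")


def read_panel(spec: str) -> list[str]:
    """A panel given either as a comma-separated list or as ``@file`` (one id per line)."""
    if spec.startswith("@"):
        lines = Path(spec[1:]).read_text().splitlines()
        return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    return [part.strip() for part in spec.split(",") if part.strip()]
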