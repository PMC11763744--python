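"""File formats for pipeline inputs and outputs.

All tables are UTF-8 CSV/TSV with '.' decimal separators and empty
fields for missing values:

* dose-response CSV: cell_line, treatment, dose, unit, replicate,
  fluorescence (dose 0 = untreated control; one unit per treatment);
* expression TSV: first column ``gene_id``, remaining columns sample ids
  (log2 values);
* sample sheet CSV: sample_id, cell_line, replicate;
* annotation TSV: gene_id, symbol (empty symbol = uncharacterized);
* IC25 table TSV: cell_line, treatment, ic25, unit, ec50, hill, rmse,
  converged, extrapolated.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from rospanel.dose_response import IC25Estimate
from rospanel.errors import ValidationError

DOSE_RESPONSE_COLUMNS = ["cell_line", "treatment", "dose", "unit", "replicate", "fluorescence"]


def read_dose_response(path: str | Path) -> pd.DataFrame:
    """Read and validate a dose-response CSV.

    Rejects missing columns, negative doses or fluorescence, mixed units
    within a treatment (naming the offending rows), and (cell line,
    treatment) groups without a dose-0 control.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DOSE_RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col, dtype in [("dose", float), ("fluorescence", float), ("replicate", int)]:
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: column {col!r} not numeric: {exc}") from exc
    if (df["dose"] < 0).any():
        rows = (df.index[df["dose"] < 0] + 2).tolist()[:5]
        raise ValidationError(f"{path}: negative dose at rows {rows}")
    if (df["fluorescence"] < 0).any():
        rows = (df.index[df["fluorescence"] < 0] + 2).tolist()[:5]
        raise ValidationError(f"{path}: negative fluorescence at rows {rows}")
    for trt, grp in df.groupby("treatment"):
        units = grp["unit"].unique()
        if len(units) > 1:
            offending = grp.index[grp["unit"] != units[0]] + 2
            raise ValidationError(
                f"{path}: treatment {trt!r} mixes units {sorted(units)} "
                f"(rows {offending.tolist()[:5]})"
            )
    for (line, trt), grp in df.groupby(["cell_line", "treatment"]):
        if not (grp["dose"] == 0).any():
            raise ValidationError(f"{path}: no dose-0 control for ({line}, {trt})")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2 expression TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate gene identifiers")
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "cell_line": str})
    for col in ("sample_id", "cell_line"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_id", "symbol"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return df


def ic25_table(estimates: list[IC25Estimate], units: dict[str, str] | None = None) -> pd.DataFrame:
    """Assemble IC25 estimates into the exchange-table layout."""
    units = units or {}
    return pd.DataFrame(
        [
            {"cell_line": e.cell_line, "treatment": e.treatment, "ic25": e.ic25,
             "unit": units.get(e.treatment, ""), "ec50": e.ec50, "hill": e.hill,
             "rmse": e.rmse, "converged": e.converged, "extrapolated": e.extrapolated}
            for e in estimates
        ]
    )


def read_ic25_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("cell_line", "treatment", "ic25"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_gene_list(genes: list[str], path: str | Path) -> None:
    """One symbol per line, ready for external enrichment services."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
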