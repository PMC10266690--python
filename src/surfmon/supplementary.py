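"""Optional adapter for supplementary detection workbooks (XLSX).

Ingests a workbook holding one sheet per survey method, each a site-by-
species table of detections (counts or presence). Deposited supplementary
workbooks vary in layout, so the adapter targets a documented canonical
layout: sheet names are method labels (``seine``, ``bruv``, ``edna``),
first column the site name, remaining columns species. Anything else
should be reshaped to this layout first.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .io import FormatError, KNOWN_METHODS


def read_detection_workbook(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read per-method site x species detection tables from an XLSX workbook."""
    book = pd.read_excel(path, sheet_name=None, index_col=0, engine="openpyxl")
    out = {}
    for sheet, df in book.items():
        method = sheet.strip().lower()
        if method not in KNOWN_METHODS:
            raise FormatError(
                f"workbook sheet {sheet!r} is not a known method {list(KNOWN_METHODS)}"
            )
        numeric = df.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().any().any():
            raise FormatError(f"sheet {sheet!r} contains non-numeric cells")
        if (numeric < 0).any().any():
            raise FormatError(f"sheet {sheet!r} contains negative values")
        numeric.index = numeric.index.astype(str)
        numeric.index.name = "site"
        numeric.columns.name = "species"
        out[method] = numeric
    if not out:
        raise FormatError("workbook contains no method sheets")
    return out


def detection_tables_to_histories(
    tables: dict[str, pd.DataFrame], k_by_method: dict[str, int]
) -> pd.DataFrame:
    """Convert site x species detection-count tables to tidy (N, K) histories.

    Cell values are interpreted as N, the number of replicate surveys with
    a detection, capped at the method's K.
    """
    rows = []
    for method, table in tables.items():
        k = int(k_by_method[method])
        for site in table.index:
            for sp in table.columns:
                n = int(min(table.loc[site, sp], k))
                rows.append((str(sp), method, str(site), n, k))
    return pd.DataFrame(rows, columns=["species", "method", "site", "N", "K"])


def write_detection_workbook(tables: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Write per-method detection tables in the canonical workbook layout."""
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for method, table in tables.items():
            table.to_excel(writer, sheet_name=method)
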