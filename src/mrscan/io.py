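"""Delimited-text output for scan matrices, profiles and reports.

Matrices are written as TSV with site ids as row/column headers,
preceded by ``# key=value`` metadata lines carrying every parameter
needed to regenerate the file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _meta_lines(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_matrix_tsv(path, matrix: np.ndarray, site_ids, meta: dict) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(site_ids), columns=list(site_ids))
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", index_label="site_id")


def read_matrix_tsv(path):
    """Return ``(matrix_df, meta)`` from a TSV written by this module."""
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    return df, meta


def write_profiles_tsv(path, site_ids, profiles, meta: dict) -> None:
    """Two-profile TSV: per-column (influence / D_j) and per-row
    (sensitivity / D_i) marginals."""
    df = pd.DataFrame(
        {
            "site_id": list(site_ids),
            "col_profile": np.asarray(profiles.influence),
            "row_profile": np.asarray(profiles.sensitivity),
        }
    )
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", index=False)


def write_table_tsv(path, table: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        table.to_csv(fh, sep="\t", index=False)


def write_run_log(path, lines) -> None:
    Path(path).write_text("\n".join(str(x) for x in lines) + "\n")
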