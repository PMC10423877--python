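"""Delimited-table and JSON serialization for blocks, fits and reports.

CSV vs TSV is auto-detected from the file extension (`.tsv`/`.tab` use
tabs, everything else commas). Every JSON artifact written by the pipeline
embeds the run's config hash and seed under ``"provenance"``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import ConfoundTable, DataBlock
from .comparison import ComparisonReport
from .decomposition import CrossFit
from .errors import ValidationError
from .inference import PermutationReport

__all__ = [
    "read_block",
    "write_block",
    "read_confounds",
    "write_confounds",
    "fit_to_dict",
    "write_fit",
    "write_loadings_tsv",
    "write_permutation_report",
    "write_permutation_tsv",
    "write_comparison",
    "write_cosine_tsv",
]

ID_COL = "sample_id"


def _sep(path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def read_block(path, id_col: str = ID_COL) -> DataBlock:
    df = pd.read_csv(path, sep=_sep(path))
    return DataBlock.from_frame(df, id_col=id_col)


def write_block(block: DataBlock, path, id_col: str = ID_COL) -> None:
    block.to_frame(id_col).to_csv(path, sep=_sep(path), index=False)


def read_confounds(path, id_col: str = ID_COL, categorical=()) -> ConfoundTable:
    df = pd.read_csv(path, sep=_sep(path))
    if id_col not in df.columns:
        raise ValidationError(f"missing identifier column {id_col!r}")
    ids = tuple(str(s) for s in df[id_col])
    data = df.drop(columns=[id_col])
    return ConfoundTable(ids, data, tuple(categorical))


def write_confounds(confounds: ConfoundTable, path, id_col: str = ID_COL) -> None:
    confounds.to_frame(id_col).to_csv(path, sep=_sep(path), index=False)


def _diag_jsonable(diag: dict) -> dict:
    out = {}
    for key, val in diag.items():
        if isinstance(val, np.ndarray):
            out[key] = val.tolist()
        elif isinstance(val, (np.floating, np.integer)):
            out[key] = val.item()
        else:
            out[key] = val
    return out


def fit_to_dict(fit: CrossFit) -> dict:
    return {
        "method": fit.method,
        "k": fit.k,
        "x_names": list(fit.x_names),
        "y_names": list(fit.y_names),
        "U": fit.U.tolist(),
        "V": fit.V.tolist(),
        "assoc": fit.assoc.tolist(),
        "x_loadings": fit.x_loadings.tolist(),
        "y_loadings": fit.y_loadings.tolist(),
        "coef": None if fit.coef is None else fit.coef.tolist(),
        "diagnostics": _diag_jsonable(fit.diagnostics),
    }


def _dump(obj: dict, path, provenance: dict | None = None) -> None:
    if provenance:
        obj = {"provenance": provenance, **obj}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=False)
        fh.write("\n")


def write_fit(fit: CrossFit, path, provenance: dict | None = None) -> None:
    _dump(fit_to_dict(fit), path, provenance)


def _write_tsv(df: pd.DataFrame, path, provenance, **to_csv_kw) -> None:
    # provenance goes in a '#' comment line; read back with comment="#"
    with open(path, "w") as fh:
        if provenance:
            pairs = " ".join(f"{k}={v}" for k, v in provenance.items())
            fh.write(f"# {pairs}\n")
        df.to_csv(fh, sep="\t", **to_csv_kw)


def write_loadings_tsv(fit: CrossFit, path_x, path_y, provenance=None) -> None:
    """Structure-coefficient tables: variables as rows, components as columns."""
    comps = [f"component_{c + 1}" for c in range(fit.k)]
    _write_tsv(
        pd.DataFrame(fit.x_loadings, index=list(fit.x_names), columns=comps),
        path_x,
        provenance,
        index_label="variable",
    )
    _write_tsv(
        pd.DataFrame(fit.y_loadings, index=list(fit.y_names), columns=comps),
        path_y,
        provenance,
        index_label="variable",
    )


def write_permutation_report(
    report: PermutationReport, path, provenance: dict | None = None
) -> None:
    _dump(report.to_dict(), path, provenance)


def write_permutation_tsv(report: PermutationReport, path, provenance=None) -> None:
    _write_tsv(
        pd.DataFrame(
            {
                "component": np.arange(1, report.k + 1),
                "observed_rho": report.observed_rho,
                "p_value": report.p_values,
                "explained_variance_x": report.explained_variance_x,
                "explained_variance_y": report.explained_variance_y,
            }
        ),
        path,
        provenance,
        index=False,
    )


def write_vif_tsv(block, vif_values, path, provenance=None) -> None:
    _write_tsv(
        pd.DataFrame(
            {"variable": list(block.variable_names), "vif": vif_values}
        ),
        path,
        provenance,
        index=False,
    )


def write_comparison(
    report: ComparisonReport, path, provenance: dict | None = None
) -> None:
    _dump(report.to_dict(), path, provenance)


def write_cosine_tsv(report: ComparisonReport, path, provenance=None) -> None:
    """Human-readable pairwise matched-cosine table."""
    rows = []
    for (a, b), matches in report.alignments.items():
        for mt in matches:
            rows.append(
                {
                    "method_a": a,
                    "method_b": b,
                    "component_a": mt.index_a + 1,
                    "component_b": mt.index_b + 1,
                    "cosine": mt.cosine,
                    "brain_cosine": mt.brain_cosine,
                    "psych_cosine": mt.psych_cosine,
                }
            )
    _write_tsv(pd.DataFrame(rows), path, provenance, index=False)
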