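"""Readers and writers for abundance tables and analysis outputs.

Supported inputs: TSV/CSV OTU tables (samples as rows or columns, header +
label column) and BIOM 1.0 JSON.  BIOM 2.x (HDF5) files are not read; convert
them to BIOM 1.0 JSON or TSV first.  Counts must be integers because MaxRank
normalization draws individuals from the counted pool.

All writers embed the normalization provenance (R, repetitions, seed, tool
version) as comment headers so any output can be reproduced from its file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .normalize import NRAD
from .rad import RAD, build_rad

__all__ = [
    "AbundanceTable",
    "read_abundance_table",
    "read_biom_json",
    "write_biom_json",
    "write_nrads_long",
    "write_nrads_wide",
    "read_nrads_wide",
]

ORIENTATIONS = ("auto", "samples_as_rows", "samples_as_cols")


@dataclass(frozen=True)
class AbundanceTable:
    """Integer count matrix, oriented samples x features."""

    data: pd.DataFrame  # rows: samples, columns: features

    def to_rads(self, rename: dict | None = None) -> list[RAD]:
        """One RAD per sample; feature labels are discarded by design."""
        rads = []
        for label, row in self.data.iterrows():
            name = str(label)
            if rename:
                name = rename.get(name, name)
            rads.append(build_rad(row.to_numpy(), label=name))
        return rads

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


def _validate_counts(df: pd.DataFrame, path) -> pd.DataFrame:
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: table contains non-numeric entries")
    if np.any(~np.isfinite(values)) or np.any(values != np.floor(values)):
        raise ValueError(
            f"{path}: non-integer counts found. MaxRank normalization requires "
            "integer read counts; rescale relative abundances before import."
        )
    if np.any(values < 0):
        raise ValueError(f"{path}: negative counts are invalid")
    return df.astype(np.int64)


def read_abundance_table(path, orientation: str = "auto") -> AbundanceTable:
    """Read a TSV/CSV (or BIOM 1.0 JSON) OTU table.

    ``orientation`` controls which axis holds the samples.  ``auto`` assumes
    the longer axis holds features (OTU tables typically have far more OTUs
    than samples); pass an explicit orientation when that heuristic is wrong.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    path = Path(path)
    if path.suffix == ".biom":
        return read_biom_json(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    df = _validate_counts(df, path)
    if orientation == "samples_as_cols" or (orientation == "auto" and df.shape[0] > df.shape[1]):
        df = df.T
    return AbundanceTable(data=df)


def read_biom_json(path) -> AbundanceTable:
    """Read a BIOM format 1.0 (JSON) table; samples are columns in BIOM."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ValueError(
            f"{path}: not a BIOM 1.0 JSON file (BIOM 2.x HDF5 is not supported; "
            "export to BIOM 1.0 JSON or TSV first)"
        ) from exc
    shape = doc["shape"]
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    matrix = np.zeros(shape)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            matrix[i, j] = v
    else:
        matrix[:] = np.asarray(doc["data"])
    df = pd.DataFrame(matrix, index=rows, columns=cols)
    df = _validate_counts(df, path)
    return AbundanceTable(data=df.T)  # BIOM rows are observations


def write_biom_json(table: AbundanceTable, path, table_id: str = "radnorm table") -> None:
    """Write an AbundanceTable as minimal sparse BIOM 1.0 JSON."""
    df = table.data.T  # BIOM: rows = observations, columns = samples
    values = df.to_numpy()
    data = [
        [int(i), int(j), int(values[i, j])]
        for i, j in zip(*np.nonzero(values))
    ]
    doc = {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": f"radnorm {__version__}",
        "date": "",
        "rows": [{"id": str(r), "metadata": None} for r in df.index],
        "columns": [{"id": str(c), "metadata": None} for c in df.columns],
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(df.shape),
        "data": data,
    }
    Path(path).write_text(json.dumps(doc))


def _provenance_header(nrads) -> str:
    R = nrads[0].R
    reps = sorted({n.n_reps for n in nrads})
    seeds = sorted({str(n.seed) for n in nrads})
    return (
        f"# radnorm {__version__}\n"
        f"# R={R} n_reps={','.join(map(str, reps))} seed={','.join(seeds)}\n"
    )


def write_nrads_long(nrads, path) -> None:
    """Per-rank long table: sample, rank, mean, ci_low, ci_high."""
    nrads = list(nrads)
    frames = []
    for n in nrads:
        frames.append(pd.DataFrame({
            "sample": n.label, "rank": np.arange(1, n.R + 1),
            "mean": n.abundances, "ci_low": n.ci_low, "ci_high": n.ci_high,
        }))
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_provenance_header(nrads))
        out.to_csv(fh, sep="\t", index=False)


def write_nrads_wide(nrads, path) -> None:
    """Samples x ranks matrix of mean abundances (CIs omitted)."""
    nrads = list(nrads)
    mat = pd.DataFrame(
        np.vstack([n.abundances for n in nrads]),
        index=[n.label for n in nrads],
        columns=[f"rank{r}" for r in range(1, nrads[0].R + 1)],
    )
    with open(path, "w") as fh:
        fh.write(_provenance_header(nrads))
        mat.to_csv(fh, sep="\t")


def read_nrads_wide(path) -> list[NRAD]:
    """Read a wide NRAD matrix back; CI information is not recoverable."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    out = []
    for label, row in df.iterrows():
        a = row.to_numpy(dtype=float)
        out.append(NRAD(a, a.copy(), a.copy(), n_reps=1, seed=None, label=str(label)))
    return out
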