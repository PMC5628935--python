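"""Reading and writing NPX-style protein panel data and result tables.

The on-disk layout is a wide delimited table (TSV/CSV, or the first sheet of
an xlsx workbook): one header row naming the proteins, one row per sample
with the sample identifier in the first column, and log2 relative protein
quantities (NPX) in the body.  Per-protein limits of detection (LOD) may be
embedded as a row whose sample id is ``LOD`` (case-insensitive) or supplied
in a sidecar protein-metadata file; the embedded row wins if both are
present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NPXMatrix",
    "GROUPS",
    "COHORTS",
    "LOCATIONS",
    "ACTIVITIES",
    "read_npx",
    "read_protein_meta",
    "read_annotations",
    "write_results",
    "read_results",
    "write_cv_results",
]

GROUPS = ("CD", "UC", "HC")
COHORTS = ("discovery", "replication")
LOCATIONS = ("L1", "L2", "L3", "L4", "none")
ACTIVITIES = ("remission", "active", "unknown")

_LOD_SENTINELS = {"lod", "LOD", "Lod"}


@dataclass
class NPXMatrix:
    """Samples x proteins table of log2 protein quantities with an LOD mask.

    ``values`` holds the instrument value everywhere, including below-LOD
    cells, until :func:`splsero.preprocess.reset_below_lod` is applied.
    ``below_lod`` is a boolean frame of identical shape marking cells whose
    raw signal fell under the protein's limit of detection.
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.below_lod is None:
            self.below_lod = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        v, m = self.values, self.below_lod
        if v.shape != m.shape:
            raise ValueError(f"values {v.shape} and below_lod {m.shape} shapes differ")
        if not (v.index.equals(m.index) and v.columns.equals(m.columns)):
            raise ValueError("values and below_lod must share index and columns")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            bad = np.argwhere(~np.isfinite(v.to_numpy(dtype=float)))[0]
            raise ValueError(
                f"non-finite value at sample {v.index[bad[0]]!r}, "
                f"protein {v.columns[bad[1]]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "NPXMatrix":
        ids = list(sample_ids)
        return NPXMatrix(self.values.loc[ids].copy(), self.below_lod.loc[ids].copy())

    def drop_proteins(self, protein_ids) -> "NPXMatrix":
        drop = [p for p in protein_ids if p in self.values.columns]
        return NPXMatrix(
            self.values.drop(columns=drop), self.below_lod.drop(columns=drop)
        )

    def copy(self) -> "NPXMatrix":
        return NPXMatrix(self.values.copy(), self.below_lod.copy())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xlsx":
        raw = pd.read_excel(path, header=None, dtype=object)
    else:
        sep = "," if suffix == ".csv" else "\t"
        raw = pd.read_csv(path, sep=sep, header=None, dtype=object, comment="#")
    return raw


def read_npx(
    path: str | Path,
    lod_path: str | Path | None = None,
    transpose: bool = False,
) -> tuple[NPXMatrix, pd.DataFrame]:
    """Read a wide NPX table; return the matrix and a protein-metadata frame.

    Parameters
    ----------
    path:
        TSV/CSV/xlsx file; header row names proteins, first column holds
        sample ids.  A row whose id is ``LOD`` carries per-protein limits of
        detection.
    lod_path:
        Optional sidecar protein-metadata file (see
        :func:`read_protein_meta`).  Ignored for LOD purposes when the matrix
        file embeds an LOD row.
    transpose:
        Set when the file is exported proteins-as-rows.

    Returns
    -------
    (NPXMatrix, protein_meta)
        ``protein_meta`` has one row per protein with columns ``symbol``,
        ``uniprot`` and ``lod`` (NaN when no LOD is known).  ``below_lod``
        of the matrix is ``values < lod`` per protein; all-false (with a
        warning) for proteins without an LOD.
    """
    raw = _read_table(path)
    if transpose:
        raw = raw.T.reset_index(drop=True)
    header = [str(x) for x in raw.iloc[0, 1:]]
    if len(set(header)) != len(header):
        seen: set[str] = set()
        dups = []
        for h in header:
            if h in seen:
                dups.append(h)
            seen.add(h)
        raise ValueError(f"duplicate protein column name(s): {sorted(set(dups))}")
    body = raw.iloc[1:].copy()
    sample_col = body.iloc[:, 0].astype(str)

    lod_rows = sample_col.isin(_LOD_SENTINELS)
    embedded_lod = None
    if lod_rows.any():
        lod_values = body.loc[lod_rows].iloc[0, 1:]
        embedded_lod = pd.Series(
            [_to_float(v, "LOD", c) for v, c in zip(lod_values, header)],
            index=header,
            dtype=float,
        )
        body = body.loc[~lod_rows]
        sample_col = body.iloc[:, 0].astype(str)

    if sample_col.duplicated().any():
        raise ValueError(
            f"duplicate sample ids: {sample_col[sample_col.duplicated()].tolist()}"
        )

    values = pd.DataFrame(
        [
            [_to_float(v, s, c) for v, c in zip(row, header)]
            for s, row in zip(sample_col, body.iloc[:, 1:].to_numpy())
        ],
        index=pd.Index(sample_col.to_numpy(), name="sample_id"),
        columns=header,
        dtype=float,
    )

    meta = pd.DataFrame(
        {"symbol": header, "uniprot": "", "lod": np.nan},
        index=pd.Index(header, name="protein_id"),
    )
    if lod_path is not None:
        sidecar = read_protein_meta(lod_path)
        common = meta.index.intersection(sidecar.index)
        meta.loc[common, ["symbol", "uniprot", "lod"]] = sidecar.loc[
            common, ["symbol", "uniprot", "lod"]
        ]
    if embedded_lod is not None:
        meta["lod"] = embedded_lod  # embedded wins over sidecar

    below = pd.DataFrame(False, index=values.index, columns=values.columns)
    lod = meta["lod"]
    known = lod.notna()
    if known.any():
        below.loc[:, known[known].index] = values.loc[:, known[known].index].lt(
            lod[known], axis=1
        )
    missing = (~known).sum()
    if missing and known.any():
        warnings.warn(
            f"{missing} protein(s) have no LOD; their below-LOD mask is all-false"
        )
    return NPXMatrix(values, below), meta


def _to_float(value, sample, protein) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"non-numeric cell at sample {sample!r}, protein {protein!r}: {value!r}"
        ) from None


def read_protein_meta(path: str | Path) -> pd.DataFrame:
    """Read a sidecar protein-metadata table (protein_id, symbol, uniprot, lod)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if path.suffix.lower() == ".xlsx":
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=sep, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "protein_id" not in cols:
        raise ValueError("protein metadata needs a 'protein_id' column")
    out = pd.DataFrame(index=pd.Index(df[cols["protein_id"]].astype(str),
                                      name="protein_id"))
    out["symbol"] = df[cols["symbol"]].astype(str).to_numpy() if "symbol" in cols else out.index
    out["uniprot"] = df[cols["uniprot"]].astype(str).to_numpy() if "uniprot" in cols else ""
    out["lod"] = pd.to_numeric(df[cols["lod"]], errors="coerce").to_numpy() if "lod" in cols else np.nan
    if out.index.has_duplicates:
        raise ValueError("duplicate protein_id in protein metadata")
    return out


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample-annotation table.

    Requires columns ``sample_id``, ``cohort`` and ``group``; optional
    ``location`` (CD Montreal location, default ``none``), ``activity``
    (default ``unknown``) and ``prior_resection`` (yes/no/unknown).
    Enumerations are closed; unknown levels raise with the allowed values.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("sample_id", "cohort", "group"):
        if col not in df.columns:
            raise ValueError(f"annotation table lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in annotations")
    for col, allowed in (
        ("cohort", COHORTS),
        ("group", GROUPS),
    ):
        bad = sorted(set(df[col]) - set(allowed))
        if bad:
            raise ValueError(f"unknown {col} level(s) {bad}; allowed: {list(allowed)}")
    if "location" not in df.columns:
        df["location"] = "none"
    df["location"] = df["location"].fillna("none")
    bad = sorted(set(df["location"]) - set(LOCATIONS))
    if bad:
        raise ValueError(f"unknown location level(s) {bad}; allowed: {list(LOCATIONS)}")
    if "activity" not in df.columns:
        df["activity"] = "unknown"
    df["activity"] = df["activity"].fillna("unknown")
    bad = sorted(set(df["activity"]) - set(ACTIVITIES))
    if bad:
        raise ValueError(f"unknown activity level(s) {bad}; allowed: {list(ACTIVITIES)}")
    if "prior_resection" not in df.columns:
        df["prior_resection"] = "unknown"
    df["prior_resection"] = (
        df["prior_resection"].fillna("unknown").astype(str).str.lower()
        .replace({"true": "yes", "false": "no"})
    )
    bad = sorted(set(df["prior_resection"]) - {"yes", "no", "unknown"})
    if bad:
        raise ValueError(f"prior_resection must be yes/no/unknown, got {bad}")
    return df.set_index("sample_id", drop=False)


def align_annotations(matrix: NPXMatrix, annot: pd.DataFrame) -> pd.DataFrame:
    """Check every matrix sample is annotated; warn on extra annotations."""
    missing = [s for s in matrix.sample_ids if s not in annot.index]
    if missing:
        raise ValueError(f"samples without annotation: {missing}")
    extra = [s for s in annot.index if s not in set(matrix.sample_ids)]
    if extra:
        warnings.warn(f"{len(extra)} annotated sample(s) absent from the matrix")
    return annot.loc[matrix.sample_ids]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _format_q(q: float) -> str:
    return "<0.001" if q < 0.001 else f"{q:.3g}"


def write_results(results: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a univariate result table as TSV.

    Numeric columns are kept at full precision; an extra human-readable
    ``fold_change_ci`` column renders the linear fold change with its 95% CI
    (``0.42 (0.31–0.59)``) and ``q_printed`` renders the q-value the way a
    results table prints it.
    """
    path = Path(path)
    df = results.copy()
    if len(df) and {"fc", "fc_ci_low", "fc_ci_high"} <= set(df.columns):
        df["fold_change_ci"] = [
            f"{fc:.2f} ({lo:.2f}–{hi:.2f})"
            for fc, lo, hi in zip(df["fc"], df["fc_ci_low"], df["fc_ci_high"])
        ]
    if len(df) and "q_value" in df.columns:
        df["q_printed"] = [_format_q(q) for q in df["q_value"]]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_cv_results(rows: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a cross-validation / transfer summary table keyed by contrast."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        rows.to_csv(fh, sep="\t", index=False, float_format="%.6g")
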