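"""File readers and writers for the pipeline's plain-text formats.

Formats: peaks as BED6 plus a summit-offset column, gene tables as TSV,
cells / surfaces / matrices / Ct tables as CSV, reports and profiles as
JSON.  All files are UTF-8 with LF newlines.  Readers validate rather than
coerce: malformed lines raise with their line number, duplicate gene ids
are rejected.  Writers prepend ``# key=value`` header lines so every
output carries the seed and config hash that produced it; readers skip
``#`` comments.

Coordinate conventions: BED intervals are 0-based half-open with a summit
offset relative to ``start``; gene TSSs are 1-based.  Conversion to the
in-memory convention happens here, at the reader boundary, only.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from gzexit.migration import CellCohort, MigrationProfile


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# headers
# ---------------------------------------------------------------------------

def _meta_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path, meta: dict | None, sep: str,
                 index: bool = False) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_meta_lines(meta))
        # repr() gives shortest round-tripping float text
        df.to_csv(fh, sep=sep, index=index, lineterminator="\n",
                  float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# peaks (BED)
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED-like peak file into a 0-based half-open peak table.

    Columns beyond chrom/start/end are optional: name, score (parsed as
    the peak p-value), strand, summit offset relative to start.  A missing
    summit defaults to the interval midpoint.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer start/end"
                ) from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
            p_value = 1.0
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    p_value = float(fields[4])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric score"
                    ) from None
                if not 0 < p_value <= 1:
                    raise ParseError(
                        f"{path}:{lineno}: score column must be a p-value in (0, 1]"
                    )
            strand = fields[5] if len(fields) > 5 else "."
            if len(fields) > 6 and fields[6] not in (".", ""):
                try:
                    summit = start + int(fields[6])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer summit offset"
                    ) from None
                if not start <= summit < end:
                    raise ParseError(f"{path}:{lineno}: summit outside interval")
            else:
                summit = (start + end) // 2
            rows.append((chrom, start, end, name, p_value, strand, summit))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "p_value", "strand", "summit"],
    )


def write_bed(peaks: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a peak table as BED6 + summit-offset; round-trips bit-exactly."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_meta_lines(meta))
        for _, r in peaks.iterrows():
            strand = r.get("strand", ".")
            fh.write(
                f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t"
                f"{r.get('name', '.')}\t{r['p_value']!r}\t{strand}\t"
                f"{int(r['summit']) - int(r['start'])}\n"
            )


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

def read_gene_table(path) -> pd.DataFrame:
    """Read a TSV of gene records (gene_id, chrom, tss [1-based], strand)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: gene table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ParseError(f"{path}: duplicate gene_id {dups[:5]}")
    if not pd.api.types.is_integer_dtype(df["tss"]) or (df["tss"] < 1).any():
        raise ParseError(f"{path}: tss must be integers >= 1")
    if not df["strand"].isin(["+", "-"]).all():
        raise ParseError(f"{path}: strand must be + or -")
    return df


def write_gene_table(genes: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_table(genes, path, meta, sep="\t")


# ---------------------------------------------------------------------------
# cells and surfaces
# ---------------------------------------------------------------------------

def write_cells(cohorts, path, meta: dict | None = None) -> None:
    """Write one or more cohorts' cells as CSV (cell_id,x_um,y_um,condition)."""
    if isinstance(cohorts, CellCohort):
        cohorts = [cohorts]
    frames = []
    for cohort in cohorts:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{cohort.condition}:{i}"
                                for i in range(cohort.n_cells)],
                    "x_um": cohort.cells[:, 0],
                    "y_um": cohort.cells[:, 1],
                    "condition": cohort.condition,
                }
            )
        )
    _write_table(pd.concat(frames, ignore_index=True), path, meta, sep=",")


def write_surface(surface: np.ndarray, path, meta: dict | None = None) -> None:
    df = pd.DataFrame(np.asarray(surface), columns=["x_um", "y_um"])
    _write_table(df, path, meta, sep=",")


def read_cells(cells_path, surface_path) -> dict[str, CellCohort]:
    """Read cells + surface CSVs into per-condition cohorts."""
    cells = pd.read_csv(cells_path, comment="#", float_precision="round_trip")
    required = {"cell_id", "x_um", "y_um", "condition"}
    if not required.issubset(cells.columns):
        raise ParseError(f"{cells_path}: needs columns {sorted(required)}")
    for col in ("x_um", "y_um"):
        if not np.isfinite(cells[col].to_numpy(dtype=float)).all():
            raise ParseError(f"{cells_path}: non-finite values in {col}")
    surface_df = pd.read_csv(surface_path, comment="#", float_precision="round_trip")
    if not {"x_um", "y_um"}.issubset(surface_df.columns):
        raise ParseError(f"{surface_path}: needs columns x_um,y_um")
    surface = surface_df[["x_um", "y_um"]].to_numpy(dtype=float)
    return {
        cond: CellCohort(
            cells=grp[["x_um", "y_um"]].to_numpy(dtype=float),
            condition=str(cond),
            surface=surface,
        )
        for cond, grp in cells.groupby("condition", sort=False)
    }


# ---------------------------------------------------------------------------
# expression matrices and Ct tables
# ---------------------------------------------------------------------------

def write_matrix(matrix, path, meta: dict | None = None) -> None:
    """Write an expression matrix; sample columns are ``condition::replicate``."""
    _write_table(matrix.values, path, meta, sep=",", index=True)


def read_matrix(path):
    """Read an expression CSV; conditions are inferred from column names."""
    from gzexit.expression import ExpressionMatrix

    df = pd.read_csv(path, comment="#", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids")
    bad = [c for c in df.columns if "::" not in c]
    if bad:
        raise ParseError(
            f"{path}: sample columns must be 'condition::replicate', got {bad[:3]}"
        )
    design = pd.Series({c: c.split("::", 1)[0] for c in df.columns})
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ParseError(f"{path}: non-numeric expression values")
    return ExpressionMatrix(values=df, design=design)


def write_ct_table(ct: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_table(ct, path, meta, sep=",")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"gene", "condition", "replicate", "ct"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: Ct table needs columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# profiles and reports
# ---------------------------------------------------------------------------

def write_profile(profile: MigrationProfile, path, meta: dict | None = None) -> None:
    payload = dict(meta or {})
    payload.update(profile.to_dict())
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_profile(path) -> MigrationProfile:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    return MigrationProfile(
        distances=np.array([]),
        bin_edges=np.asarray(d["bin_edges"], dtype=float),
        counts=np.asarray(d["counts"], dtype=int),
        mean_um=float(d["mean_um"]),
        sd_um=float(d["sd_um"]),
        n=int(d["n"]),
        p99_um=float(d["p99_um"]),
        condition=d.get("condition", ""),
    )


def write_report(report: dict, path) -> None:
    Path(path).write_text(
        json.dumps(report, indent=1, sort_keys=True, default=float) + "\n",
        encoding="utf-8",
    )
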