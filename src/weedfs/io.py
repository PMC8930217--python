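"""Reading and writing expression matrices (TSV/CSV/GCT) and label files.

TSV/CSV layout: first column holds gene IDs (header cell ``gene_id``), one
column per sample; an optional second header row whose first cell is
``label`` carries per-sample class labels. GCT 1.2 follows the standard
two-line header (``#1.2`` then ``<n_genes>\t<n_samples>``) with Name and
Description columns; GCT carries no labels, so those come from a separate
two-column file. Missing cells are any of "", "NA", "NaN", "null" on input
and are written as "NA".

All writes are atomic (temp file + rename).
"""
from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np

from .matrix import ExpressionMatrix

MISSING_TOKENS = {"", "NA", "NaN", "nan", "null"}
FORMATS = ("tsv", "csv", "gct")


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in FORMATS:
        return suffix
    raise ValueError(f"cannot infer format from {path!r}; pass format explicitly")


def _parse_cell(token: str, line_no: int, gene: str, sample: str) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"line {line_no}: non-numeric cell {token!r} (gene {gene!r}, sample {sample!r})"
        ) from None


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column (sample_id, label) delimited text; tab or comma."""
    out: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.replace(",", "\t").split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {line_no}: expected two columns in label file")
        out[parts[0].strip()] = parts[1].strip()
    return out


def read_expression(
    path: str | Path,
    fmt: str | None = None,
    orientation: str = "genes_in_rows",
    label_source: str | Path | None = "header",
) -> ExpressionMatrix:
    """Parse a delimited expression matrix.

    ``label_source``: "header" looks for a ``label`` row under the header
    (TSV/CSV only); a path reads a two-column sample/label file; None
    attaches no labels.
    """
    fmt = _infer_format(path, fmt)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError("orientation must be 'genes_in_rows' or 'samples_in_rows'")
    lines = Path(path).read_text().splitlines()
    sep = "," if fmt == "csv" else "\t"

    if fmt == "gct":
        if len(lines) < 3 or not lines[0].startswith("#1.2"):
            raise ValueError("not a GCT 1.2 file (missing '#1.2' header)")
        try:
            n_genes, n_samples = (int(v) for v in lines[1].split("\t")[:2])
        except ValueError:
            raise ValueError("line 2: GCT counts line must hold two integers") from None
        header = lines[2].split("\t")
        if header[:2] != ["Name", "Description"]:
            raise ValueError("line 3: GCT header must start with Name\tDescription")
        sample_ids = header[2:]
        if len(sample_ids) != n_samples:
            raise ValueError(
                f"line 3: declared {n_samples} samples but header lists {len(sample_ids)}"
            )
        body = lines[3:]
        body = [l for l in body if l.strip()]
        if len(body) != n_genes:
            raise ValueError(f"declared {n_genes} genes but found {len(body)} data rows")
        gene_ids, rows = [], []
        for off, line in enumerate(body):
            parts = line.split("\t")
            if len(parts) != n_samples + 2:
                raise ValueError(f"line {off + 4}: ragged row ({len(parts)} fields)")
            gene_ids.append(parts[0])
            rows.append(
                [
                    _parse_cell(tok, off + 4, parts[0], sample_ids[j])
                    for j, tok in enumerate(parts[2:])
                ]
            )
        values = np.array(rows, dtype=float)
        label_row = None
    else:
        if not lines:
            raise ValueError("empty file")
        header = lines[0].split(sep)
        sample_ids = header[1:]
        label_row = None
        body_start = 1
        if len(lines) > 1 and lines[1].split(sep)[0].strip().lower() == "label":
            parts = lines[1].split(sep)
            if len(parts) != len(header):
                raise ValueError("line 2: label row width differs from header")
            label_row = parts[1:]
            body_start = 2
        gene_ids, rows = [], []
        for off, line in enumerate(lines[body_start:]):
            if not line.strip():
                continue
            line_no = body_start + off + 1
            parts = line.split(sep)
            if len(parts) != len(header):
                raise ValueError(
                    f"line {line_no}: ragged row ({len(parts)} fields, expected {len(header)})"
                )
            gene_ids.append(parts[0])
            rows.append(
                [
                    _parse_cell(tok, line_no, parts[0], sample_ids[j])
                    for j, tok in enumerate(parts[1:])
                ]
            )
        if not rows:
            raise ValueError("no data rows found")
        values = np.array(rows, dtype=float)

    if orientation == "samples_in_rows":
        values = values.T
        gene_ids, sample_ids = sample_ids, gene_ids

    labels = None
    if label_source == "header":
        if label_row is not None:
            labels = np.array([t.strip() for t in label_row])
    elif label_source is not None:
        mapping = read_labels(label_source)
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"label file has no entry for sample(s) {missing[:3]}")
        labels = np.array([mapping[s] for s in sample_ids])
    return ExpressionMatrix(
        values=values, gene_ids=list(gene_ids), sample_ids=list(sample_ids), labels=labels
    )


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _fmt_value(v: float, missing: bool) -> str:
    return "NA" if missing else format(v, ".17g")


def write_expression(m: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write a matrix losslessly (17 significant digits, missing as NA)."""
    fmt = _infer_format(path, fmt)
    lines: list[str] = []
    if fmt == "gct":
        lines.append("#1.2")
        lines.append(f"{m.n_genes}\t{m.n_samples}")
        lines.append("\t".join(["Name", "Description"] + m.sample_ids))
        for i, g in enumerate(m.gene_ids):
            cells = [
                _fmt_value(m.values[i, j], m.missing_mask[i, j])
                for j in range(m.n_samples)
            ]
            lines.append("\t".join([g, "na"] + cells))
    else:
        sep = "," if fmt == "csv" else "\t"
        lines.append(sep.join(["gene_id"] + m.sample_ids))
        if m.labels is not None:
            lines.append(sep.join(["label"] + [str(l) for l in m.labels]))
        for i, g in enumerate(m.gene_ids):
            cells = [
                _fmt_value(m.values[i, j], m.missing_mask[i, j])
                for j in range(m.n_samples)
            ]
            lines.append(sep.join([g] + cells))
    _atomic_write(path, "\n".join(lines) + "\n")


def write_labels(m: ExpressionMatrix, path: str | Path) -> None:
    if m.labels is None:
        raise ValueError("matrix carries no labels")
    _atomic_write(
        path, "".join(f"{s}\t{l}\n" for s, l in zip(m.sample_ids, m.labels))
    )
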