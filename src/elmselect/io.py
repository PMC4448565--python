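"""Readers and writers for expression-matrix and label file dialects.

Supported expression dialects: plain TSV/CSV (gene rows, first column =
gene id, header row = sample names), Broad GCT (``#1.2`` version line and
row/column count header) and Broad RES (per-value Absent/Present call
columns, which are skipped). Labels come from Broad CLS files or plain
one-label-per-line text. Values never coerce silently: any non-numeric or
missing cell is a parse error naming the offending line.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, ValidationError
from .fitness import FitnessResult

EXPRESSION_FORMATS = ("tsv", "csv", "gct", "res")
LABEL_FORMATS = ("cls", "plain")

_SUFFIX_TO_FORMAT = {
    ".tsv": "tsv", ".txt": "tsv", ".csv": "csv",
    ".gct": "gct", ".res": "res", ".cls": "cls",
}


class ParseError(ValidationError):
    """Malformed input file."""


def detect_format(path, default: str | None = None) -> str:
    fmt = _SUFFIX_TO_FORMAT.get(Path(path).suffix.lower(), default)
    if fmt is None:
        raise ParseError(f"cannot infer file format from suffix of {path!r}")
    return fmt


def _check_numeric(df: pd.DataFrame, path) -> np.ndarray:
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"{path}: non-numeric or missing value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} (data row {r + 1})"
        )
    return values


def _check_gene_ids(ids: Sequence[str], path) -> list[str]:
    ids = [str(g) for g in ids]
    seen: set[str] = set()
    for line_no, g in enumerate(ids):
        if g in seen:
            raise ParseError(f"{path}: duplicate gene id {g!r} (data row {line_no + 1})")
        seen.add(g)
    return ids


def read_expression(
    path, fmt: str | None = None, orientation: str = "genes_as_rows"
) -> pd.DataFrame:
    """Read an expression matrix into a genes x samples DataFrame.

    The index holds gene ids, the columns sample names. ``orientation``
    declares the layout of TSV/CSV files; GCT and RES are always gene-rows
    by definition.
    """
    path = Path(path)
    fmt = fmt or detect_format(path)
    if fmt not in EXPRESSION_FORMATS:
        raise ParseError(f"unsupported expression format {fmt!r}")
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")

    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        if orientation == "samples_as_rows":
            df = df.T
    elif fmt == "gct":
        df = _read_gct(path)
    else:
        df = _read_res(path)

    ids = _check_gene_ids(df.index, path)
    values = _check_numeric(df, path)
    return pd.DataFrame(values, index=ids, columns=[str(c) for c in df.columns])


def _read_gct(path: Path) -> pd.DataFrame:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#1.2"):
        raise ParseError(f"{path}: line 1: expected GCT version line '#1.2'")
    try:
        n_rows, n_cols = (int(t) for t in lines[1].split("\t")[:2])
    except (IndexError, ValueError):
        raise ParseError(f"{path}: line 2: expected '<rows>\\t<columns>'") from None
    header = lines[2].split("\t")
    if len(header) < 2 + n_cols:
        raise ParseError(
            f"{path}: line 3: header has {len(header)} fields, expected >= {2 + n_cols}"
        )
    sample_names = header[2 : 2 + n_cols]
    data_lines = [l for l in lines[3:] if l.strip()]
    if len(data_lines) != n_rows:
        raise ParseError(
            f"{path}: header declares {n_rows} rows but file has {len(data_lines)}"
        )
    ids, rows = [], []
    for i, line in enumerate(data_lines):
        fields = line.split("\t")
        if len(fields) != 2 + n_cols:
            raise ParseError(
                f"{path}: line {i + 4}: {len(fields)} fields, expected {2 + n_cols}"
            )
        ids.append(fields[0])
        rows.append(fields[2:])
    return pd.DataFrame(rows, index=ids, columns=sample_names)


def _read_res(path: Path) -> pd.DataFrame:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: RES file needs at least 3 header lines")
    header = lines[0].split("\t")
    # layout: Description, Accession, then sample names separated by empty call slots
    sample_names = [f for f in header[2:] if f.strip()]
    try:
        n_rows = int(lines[2].strip())
    except ValueError:
        raise ParseError(f"{path}: line 3: expected the gene count") from None
    data_lines = [l for l in lines[3:] if l.strip()]
    if len(data_lines) != n_rows:
        raise ParseError(
            f"{path}: header declares {n_rows} rows but file has {len(data_lines)}"
        )
    n_cols = len(sample_names)
    ids, rows = [], []
    for i, line in enumerate(data_lines):
        fields = line.split("\t")
        if len(fields) < 2 + 2 * n_cols:
            raise ParseError(
                f"{path}: line {i + 4}: {len(fields)} fields, "
                f"expected >= {2 + 2 * n_cols} (value + call per sample)"
            )
        ids.append(fields[1])  # accession column carries the gene id
        rows.append(fields[2 : 2 + 2 * n_cols : 2])  # every other field is a call
    return pd.DataFrame(rows, index=ids, columns=sample_names)


def write_expression(df: pd.DataFrame, path, fmt: str | None = None) -> None:
    """Write a genes x samples DataFrame in the named dialect."""
    path = Path(path)
    fmt = fmt or detect_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "csv":
        df.to_csv(path, index_label="gene_id")
    elif fmt == "gct":
        with path.open("w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
            for gene, row in zip(df.index, df.to_numpy()):
                fh.write(f"{gene}\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    elif fmt == "res":
        with path.open("w") as fh:
            fh.write(
                "Description\tAccession\t" + "\t\t".join(map(str, df.columns)) + "\n"
            )
            fh.write("\t" + "\t\t".join("" for _ in df.columns) + "\n")
            fh.write(f"{df.shape[0]}\n")
            for gene, row in zip(df.index, df.to_numpy()):
                cells = "\t".join(f"{float(v)!r}\tP" for v in row)
                fh.write(f"na\t{gene}\t{cells}\n")
    else:
        raise ParseError(f"unsupported expression format {fmt!r}")


def read_labels(path, fmt: str | None = None, n_samples: int | None = None) -> list[str]:
    """Read per-sample class labels from a CLS or plain text file."""
    path = Path(path)
    fmt = fmt or detect_format(path, default="plain")
    if fmt not in LABEL_FORMATS:
        raise ParseError(f"unsupported label format {fmt!r}")
    if fmt == "cls":
        labels = _read_cls(path)
    else:
        labels = [l.strip() for l in path.read_text().splitlines() if l.strip()]
    if n_samples is not None and len(labels) != n_samples:
        raise ValidationError(
            f"{path}: {len(labels)} labels for {n_samples} samples in the matrix"
        )
    return labels


def _read_cls(path: Path) -> list[str]:
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if len(lines) < 3:
        raise ParseError(f"{path}: CLS file needs 3 non-empty lines")
    head = lines[0].split()
    if len(head) < 2:
        raise ParseError(f"{path}: line 1: expected '<n_samples> <n_classes> 1'")
    n_samples, n_classes = int(head[0]), int(head[1])
    names_line = lines[1].split()
    names = names_line[1:] if names_line and names_line[0].startswith("#") else names_line
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise ParseError(
            f"{path}: line 3 has {len(tokens)} labels, header declares {n_samples}"
        )
    if all(t.lstrip("-").isdigit() for t in tokens) and len(names) == n_classes:
        # numeric tokens index class names in order of first appearance
        order = list(dict.fromkeys(tokens))
        mapping = {tok: names[i] for i, tok in enumerate(order)}
        return [mapping[t] for t in tokens]
    return tokens


def write_labels(labels: Sequence[str], path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or detect_format(path, default="plain")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "cls":
        classes = list(dict.fromkeys(labels))
        with path.open("w") as fh:
            fh.write(f"{len(labels)} {len(classes)} 1\n")
            fh.write("# " + " ".join(classes) + "\n")
            fh.write(" ".join(str(l) for l in labels) + "\n")
    elif fmt == "plain":
        Path(path).write_text("\n".join(str(l) for l in labels) + "\n")
    else:
        raise ParseError(f"unsupported label format {fmt!r}")


def build_dataset(df: pd.DataFrame, labels: Sequence[str]) -> ExpressionDataset:
    """Attach labels to a genes x samples DataFrame."""
    if len(labels) != df.shape[1]:
        raise ValidationError(
            f"{len(labels)} labels for {df.shape[1]} samples in the matrix"
        )
    return ExpressionDataset(
        matrix=df.to_numpy(dtype=float),
        gene_ids=list(df.index),
        labels=list(labels),
    )


def write_gene_list(
    gene_ids: Sequence[str],
    result: FitnessResult,
    out_dir,
    config: object | None = None,
    extra: dict | None = None,
) -> tuple[Path, Path]:
    """Write the selected genes as TSV plus a JSON run report.

    Returns the (tsv_path, json_path) pair. The JSON report echoes the
    configuration and seeds so a run can be replayed exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "selected_genes.tsv"
    with tsv_path.open("w") as fh:
        fh.write("rank\tgene_id\n")
        for rank, gene in enumerate(gene_ids, start=1):
            fh.write(f"{rank}\t{gene}\n")

    report: dict = {
        "selected_genes": list(gene_ids),
        "result": result.to_dict(),
    }
    if config is not None:
        report["config"] = asdict(config) if is_dataclass(config) else dict(config)
    if extra:
        report.update(extra)
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(report, indent=2, default=_jsonable))
    return tsv_path, json_path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
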