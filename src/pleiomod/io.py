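"""File-format helpers: edge-list TSV, expression TSV, labels, GMT, DE tables."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples expression matrix with a header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Read a two-column (sample, group) label file into a Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in label file: {dups}")
    return df.set_index("sample")["group"]


def write_labels_tsv(labels: pd.Series, path: str | Path) -> None:
    labels.rename("group").rename_axis("sample").reset_index().to_csv(
        path, sep="\t", header=False, index=False
    )


def read_de_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-gene differential-expression table (gene, t, p, df)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"t", "p"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table {path} lacks columns: {sorted(missing)}")
    return df


def write_de_tsv(de: pd.DataFrame, path: str | Path) -> None:
    de.rename_axis("gene").to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (set name, description, then member genes, tab-separated)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
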