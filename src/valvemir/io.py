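"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are tab-separated text. Writers may prepend ``#``-prefixed comment
header lines (tool version, seed, config hash); every reader skips them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

COMMENT_CHAR = "#"


class ValidationError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, features in rows, samples in columns.

    ``kind`` distinguishes the two feature spaces of the analysis
    (``"miRNA"`` or ``"mRNA"``); it is carried through so downstream stages
    can assert they were handed the matrix they expect.
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("miRNA", "mRNA"):
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            raise ValidationError("duplicate feature IDs in expression matrix")
        if cols.has_duplicates:
            raise ValidationError("duplicate sample IDs in expression matrix")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("non-finite values in expression matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.values.columns)
        if missing:
            raise ValidationError(f"unknown sample IDs: {sorted(missing)}")
        return ExpressionMatrix(self.values.loc[:, ids], self.kind)

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise ValidationError(f"unknown feature IDs: {sorted(missing)}")
        return ExpressionMatrix(self.values.loc[ids], self.kind)


def _header_lines(meta: Mapping[str, object] | None) -> str:
    if not meta:
        return ""
    return "".join(f"{COMMENT_CHAR} {k}={v}\n" for k, v in meta.items())


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    *,
    index: bool = False,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write a DataFrame as TSV with optional ``# key=value`` header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment=COMMENT_CHAR, **kwargs)


def write_expression(
    x: ExpressionMatrix, path: str | Path, *, meta: Mapping[str, object] | None = None
) -> None:
    df = x.values.copy()
    df.index.name = "feature_id"
    write_tsv(df, path, index=True, meta=meta)


def read_expression(path: str | Path, kind: str) -> ExpressionMatrix:
    # pandas mangles duplicate column names on read; check the raw header
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(COMMENT_CHAR):
                header = line.rstrip("\n").split("\t")[1:]
                if len(header) != len(set(header)):
                    raise ValidationError(f"duplicate sample column in {path}")
                break
    df = read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float), kind)


REQUIRED_META_COLS = ("sample_id", "group")
VALID_GROUPS = ("case", "control")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_META_COLS:
        if col not in meta.columns:
            raise ValidationError(f"metadata missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad = set(meta["group"]) - set(VALID_GROUPS)
    if bad:
        raise ValidationError(f"unknown group labels: {sorted(bad)}")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(read_tsv(path, dtype={"sample_id": str}))


def read_target_scores(path: str | Path) -> pd.DataFrame:
    """Read a (mirna_id, gene_id, score) table; duplicate pairs are averaged.

    Multiple rows per pair arise when scores are reported per transcript;
    the mean score per (miRNA, gene) pair is the working value.
    """
    df = read_tsv(path, dtype={"mirna_id": str, "gene_id": str})
    for col in ("mirna_id", "gene_id", "score"):
        if col not in df.columns:
            raise ValidationError(f"target-score table missing column {col!r}")
    df["score"] = df["score"].astype(float)
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValidationError("target scores must lie in [0, 1]")
    return (
        df.groupby(["mirna_id", "gene_id"], as_index=False)["score"]
        .mean()
        .sort_values(["mirna_id", "gene_id"], ignore_index=True)
    )


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Parse a GMT gene-set file: name, description, tab-separated members."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(COMMENT_CHAR):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {g for g in genes if g}
            if not members:
                raise ValidationError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return sets, descriptions


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(set(genes))]) + "\n")


def read_drug_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, dtype=str)
    for col in ("gene_id", "drug_name", "interaction_type"):
        if col not in df.columns:
            raise ValidationError(f"drug table missing column {col!r}")
    return df.drop_duplicates(ignore_index=True)


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, dtype={"sample_id": str, "group": str, "probe_id": str})
    for col in ("sample_id", "group", "probe_id", "ct"):
        if col not in df.columns:
            raise ValidationError(f"qPCR table missing column {col!r}")
    df["ct"] = df["ct"].astype(float)
    return df
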