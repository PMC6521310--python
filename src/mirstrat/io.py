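"""Readers and writers for the plain-text formats used throughout the pipeline.

All tables are tab-separated. An expression matrix is a pandas DataFrame with
genes as the row index and sample identifiers as columns; every reader
validates the invariants the downstream stages rely on (unique identifiers,
numeric non-negative values) and every writer round-trips through its reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violates the documented format contract."""


# ---------------------------------------------------------------------------
# expression matrices and per-sample vectors


def validate_expression(df: pd.DataFrame, *, allow_negative: bool = False) -> pd.DataFrame:
    """Validate an expression matrix (genes x samples).

    Raises :class:`FormatError` on duplicate gene/sample ids, non-numeric
    columns, or (unless ``allow_negative``) negative values.
    """
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id: {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id: {dup!r}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise FormatError(f"non-numeric expression column(s): {non_numeric}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"missing value in gene {gene!r}")
    if not allow_negative and (df.to_numpy() < 0).any():
        idx = np.argwhere(df.to_numpy() < 0)[0]
        raise FormatError(
            f"negative value at gene {df.index[idx[0]]!r}, sample {df.columns[idx[1]]!r}"
        )
    return df


def read_expression_tsv(path: str | Path, *, allow_negative: bool = False) -> pd.DataFrame:
    """Read a genes-as-rows expression TSV (first column gene id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_expression(df, allow_negative=allow_negative)


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_vector_tsv(path: str | Path) -> pd.Series:
    """Read a two-column (sample, value) TSV into a float Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise FormatError(f"expected exactly 2 columns in {path}, got {df.shape[1] + 1}")
    if df.index.duplicated().any():
        raise FormatError(f"duplicate sample id: {df.index[df.index.duplicated()][0]!r}")
    s = df.iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    return s


def write_vector_tsv(s: pd.Series, path: str | Path, *, value_name: str = "value") -> None:
    s.rename(value_name).to_csv(path, sep="\t", index_label="sample")


def read_stratification_tsv(path: str | Path) -> pd.Series:
    """Read a (sample, label) TSV; labels must be high/low/excluded."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    labels = df.iloc[:, 0]
    bad = set(labels.unique()) - {"high", "low", "excluded"}
    if bad:
        raise FormatError(f"unknown stratification label(s): {sorted(bad)}")
    labels.index = labels.index.astype(str)
    return labels


def write_stratification_tsv(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# gene lists and gene-set collections


def read_target_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored; duplicates removed (logged)."""
    genes: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    for line in Path(path).read_text().splitlines():
        g = line.strip()
        if not g:
            continue
        if g in seen:
            n_dup += 1
            continue
        seen.add(g)
        genes.append(g)
    if n_dup:
        log.info("dropped %d duplicate target gene(s) from %s", n_dup, path)
    return genes


def write_target_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional analysis universe."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={n: s & universe for n, s in self.sets.items()},
            descriptions=dict(self.descriptions),
            universe=universe,
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: tab-separated name, description, member genes."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        name, desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        uniq = set(members)
        if len(uniq) < len(members):
            log.info("gene set %r: %d duplicate member(s) removed", name, len(members) - len(uniq))
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = uniq
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# pathway graphs


@dataclass
class PathwayGraph:
    """Signed directed gene graph: nodes are genes, edges carry beta in {+1, -1}."""

    name: str
    genes: list[str]
    edges: list[tuple[str, str, int]]  # (source, target, sign)

    def __post_init__(self) -> None:
        node_set = set(self.genes)
        for src, tgt, sign in self.edges:
            if src not in node_set or tgt not in node_set:
                raise ValueError(f"pathway {self.name!r}: edge endpoint not in gene list")
            if sign not in (1, -1):
                raise ValueError(f"pathway {self.name!r}: edge sign must be +1 or -1, got {sign}")
            if src == tgt:
                log.info("pathway %r: self-loop on %r", self.name, src)


def read_pathways_tsv(path: str | Path) -> list[PathwayGraph]:
    """Edge-list TSV with columns pathway, source, target, sign."""
    df = pd.read_csv(path, sep="\t", dtype={"pathway": str, "source": str, "target": str})
    required = {"pathway", "source", "target", "sign"}
    if not required.issubset(df.columns):
        raise FormatError(f"pathway file {path} missing column(s): {sorted(required - set(df.columns))}")
    pathways = []
    for name, grp in df.groupby("pathway", sort=False):
        genes = sorted(set(grp["source"]) | set(grp["target"]))
        edges = [(r.source, r.target, int(r.sign)) for r in grp.itertuples()]
        pathways.append(PathwayGraph(name=name, genes=genes, edges=edges))
    return pathways


def write_pathways_tsv(pathways: Iterable[PathwayGraph], path: str | Path) -> None:
    rows = [
        {"pathway": p.name, "source": s, "target": t, "sign": sign}
        for p in pathways
        for s, t, sign in p.edges
    ]
    pd.DataFrame(rows, columns=["pathway", "source", "target", "sign"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# clinical and qPCR tables

CLINICAL_COLUMNS = [
    "gender",
    "age",
    "depth_of_invasion",
    "lymph_node_metastasis",
    "distant_metastasis",
    "stage",
    "vascular_invasion",
    "lymphatic_invasion",
    "perineural_invasion",
    "location",
]


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if "age" in df.columns and (df["age"].dropna() <= 0).any():
        raise FormatError("clinical table: age must be positive")
    return df


def write_clinical_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample")


QPCR_COLUMNS = ["target_tumor", "ref_tumor", "target_normal", "ref_normal"]


def read_qpcr_tsv(path: str | Path) -> pd.DataFrame:
    """Per-patient Ct quadruples: target/reference x tumor/normal."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"qPCR table missing column(s): {missing}")
    if (df[QPCR_COLUMNS] <= 0).any().any():
        raise FormatError("qPCR table: Ct values must be positive")
    df.index = df.index.astype(str)
    return df


def write_qpcr_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="patient")
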