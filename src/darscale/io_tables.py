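"""Abundance-table I/O and taxonomic collapsing.

The universal input is a samples x taxa matrix of read counts or relative
abundances, a per-taxon taxonomy lineage (phylum through genus), and a
per-sample metadata table mapping each sample to a subject and a body
site.  Tables arrive as TSV (either orientation) or BIOM (JSON or HDF5);
collapsed tables can be written back to TSV.

Lineage strings are semicolon-separated and may carry rank prefixes
("p__Firmicutes"); prefixes are stripped on parsing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Taxonomic ranks, coarsest to finest.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus")

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")

__all__ = [
    "RANKS",
    "AbundanceTable",
    "FormatError",
    "MetadataError",
    "collapse_to_level",
    "parse_lineage",
    "read_abundance_table",
    "write_abundance_table",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the named dialect."""


class MetadataError(ValueError):
    """Raised when samples in the table are missing from the metadata."""


def parse_lineage(lineage: str, depth: int = len(RANKS)) -> tuple[str, ...]:
    """Split a semicolon-separated lineage string into ``depth`` labels.

    Rank prefixes such as ``p__`` are stripped; missing trailing ranks
    are padded with empty strings.
    """
    parts = [] if lineage is None else [p.strip() for p in str(lineage).split(";")]
    parts = [_RANK_PREFIX.sub("", p) for p in parts]
    parts = parts[:depth] + [""] * (depth - len(parts))
    return tuple(parts)


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with taxonomy and sample metadata.

    Attributes
    ----------
    data
        DataFrame, rows indexed by sample id, columns by taxon id;
        non-negative counts or relative abundances.
    lineages
        DataFrame indexed by taxon id with one column per rank in
        :data:`RANKS`.
    metadata
        DataFrame indexed by sample id with columns ``subject_id`` and
        ``site``.
    """

    data: pd.DataFrame
    lineages: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------
    def validate(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("taxon ids must be unique")
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValueError("abundances must be non-negative")
        if values.shape[0] and np.any(values.sum(axis=1) <= 0):
            raise ValueError("every sample row must have a positive total")
        if list(self.lineages.columns) != list(RANKS):
            raise ValueError(f"lineages must have columns {RANKS}")
        missing_tax = self.data.columns.difference(self.lineages.index)
        if len(missing_tax):
            raise ValueError(f"taxa missing from lineages: {list(missing_tax)[:5]}")
        missing_meta = self.data.index.difference(self.metadata.index)
        if len(missing_meta):
            raise MetadataError(
                f"samples missing from metadata: {list(missing_meta)[:5]}"
            )
        for col in ("subject_id", "site"):
            if col not in self.metadata.columns:
                raise MetadataError(f"metadata lacks required column {col!r}")

    # -- conveniences -----------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sites(self) -> list[str]:
        return sorted(self.metadata.loc[self.data.index, "site"].unique())

    def samples_at_site(self, site: str, one_per_subject: bool = True) -> list[str]:
        """Sample ids at ``site``; optionally the first (by id) per subject."""
        meta = self.metadata.loc[self.data.index]
        ids = sorted(meta.index[meta["site"] == site])
        if not one_per_subject:
            return ids
        seen: dict[str, str] = {}
        for sid in ids:
            subj = meta.at[sid, "subject_id"]
            seen.setdefault(subj, sid)
        return sorted(seen.values())

    def subset(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(
            data=self.data.loc[list(sample_ids)].copy(),
            lineages=self.lineages.copy(),
            metadata=self.metadata.loc[list(sample_ids)].copy(),
        )


def _read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "subject_id", "site"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    return meta.set_index("sample_id")


def _lineage_frame(taxon_ids: Iterable[str], lineage_strings) -> pd.DataFrame:
    rows = [parse_lineage(s) for s in lineage_strings]
    return pd.DataFrame(rows, index=list(taxon_ids), columns=list(RANKS))


def _drop_empty_samples(data: pd.DataFrame) -> pd.DataFrame:
    totals = data.sum(axis=1)
    empty = totals[totals <= 0].index
    if len(empty):
        logger.warning(
            "dropping %d sample(s) with zero total abundance: %s",
            len(empty),
            list(empty)[:5],
        )
        data = data.drop(index=empty)
    return data


def read_abundance_table(
    path,
    metadata_path,
    format: str | None = None,
) -> AbundanceTable:
    """Read an abundance table plus sample metadata into an :class:`AbundanceTable`.

    Parameters
    ----------
    path
        TSV or BIOM abundance table.  TSV may have taxa in rows (with an
        optional trailing ``taxonomy`` column) or samples in rows; the
        orientation is resolved by matching ids against the metadata.
    metadata_path
        TSV with columns ``sample_id``, ``subject_id``, ``site``.
    format
        ``"tsv"`` or ``"biom"``; inferred from the file suffix if None.

    Rows with zero total abundance are dropped with a logged warning.
    """
    path = Path(path)
    if format is None:
        format = "biom" if path.suffix.lower() == ".biom" else "tsv"
    meta = _read_metadata(metadata_path)

    if format == "biom":
        data, lineages = _read_biom(path)
    elif format == "tsv":
        data, lineages = _read_tsv(path, meta)
    else:
        raise ValueError(f"unknown format {format!r}")

    data = _drop_empty_samples(data)
    missing = data.index.difference(meta.index)
    if len(missing):
        raise MetadataError(f"samples missing from metadata: {list(missing)[:5]}")
    return AbundanceTable(
        data=data, lineages=lineages, metadata=meta.loc[data.index].copy()
    )


def _read_tsv(path: Path, meta: pd.DataFrame):
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
    if raw.empty:
        raise FormatError(f"{path} contains no data")

    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    known = set(meta.index.astype(str))
    cols = [c for c in raw.columns if c != "taxonomy"]
    # orientation: the axis whose ids overlap the metadata more is the
    # sample axis; a full match on both axes is genuinely ambiguous
    col_hits = sum(c in known for c in cols)
    row_hits = sum(i in known for i in raw.index)
    if col_hits == len(cols) and row_hits == len(raw.index) and col_hits:
        raise FormatError(f"{path}: orientation ambiguous (ids match both ways)")
    if col_hits == 0 and row_hits == 0:
        raise FormatError(
            f"{path}: neither rows nor columns match metadata sample ids"
        )
    taxa_in_rows = col_hits / max(len(cols), 1) > row_hits / len(raw.index)

    if taxa_in_rows:
        lineage_strings = (
            raw["taxonomy"].astype(str)
            if "taxonomy" in raw.columns
            else pd.Series("", index=raw.index)
        )
        data = raw[cols].T.astype(float)
        lineages = _lineage_frame(raw.index, lineage_strings)
    else:
        data = raw.astype(float)
        lineages = _lineage_frame(data.columns, [""] * data.shape[1])
    data.index.name = None
    data.columns.name = None
    lineages.index.name = None
    return data, lineages


def _read_biom(path: Path):
    import biom

    try:
        tab = biom.load_table(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as BIOM: {exc}") from exc
    # BIOM is observations (taxa) x samples
    data = pd.DataFrame(
        tab.matrix_data.toarray().T,
        index=[str(s) for s in tab.ids("sample")],
        columns=[str(o) for o in tab.ids("observation")],
    )
    lineage_strings = []
    for obs in tab.ids("observation"):
        md = tab.metadata(obs, axis="observation")
        if md and "taxonomy" in md and md["taxonomy"] is not None:
            tax = md["taxonomy"]
            lineage_strings.append(
                ";".join(tax) if not isinstance(tax, str) else tax
            )
        else:
            lineage_strings.append("")
    lineages = _lineage_frame(data.columns, lineage_strings)
    return data, lineages


def write_abundance_table(
    table: AbundanceTable, path, metadata_path=None
) -> None:
    """Write a table as taxa-in-rows TSV with a ``taxonomy`` column.

    Optionally writes the sample metadata alongside; the output round-trips
    through :func:`read_abundance_table`.
    """
    out = table.data.T.copy()
    out.insert(
        out.shape[1],
        "taxonomy",
        [";".join(table.lineages.loc[t]) for t in out.index],
    )
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")
    if metadata_path is not None:
        meta = table.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")


def _collapse_labels(lineage: Sequence[str], level_idx: int) -> tuple[str, ...]:
    """Lineage prefix up to ``level_idx``, blanks filled as unclassified bins."""
    labels = list(lineage[: level_idx + 1])
    for j, lab in enumerate(labels):
        if lab == "" or pd.isna(lab):
            parent = labels[j - 1] if j > 0 else "root"
            labels[j] = f"unclassified-{parent}"
    return tuple(labels)


def collapse_to_level(table: AbundanceTable, level: str) -> AbundanceTable:
    """Sum taxa sharing the same lineage prefix up to ``level``.

    Per-sample totals are conserved exactly.  A blank lineage label at the
    requested level is assigned to an explicit ``unclassified-<parent>``
    bin rather than dropped.  Collapsing is idempotent and composes:
    genus->family then family->class equals genus->class.
    """
    if level not in RANKS:
        raise ValueError(f"level must be one of {RANKS}, got {level!r}")
    level_idx = RANKS.index(level)

    groups: dict[str, tuple[str, ...]] = {}
    for taxon in table.data.columns:
        prefix = _collapse_labels(table.lineages.loc[taxon], level_idx)
        groups[taxon] = prefix

    # name each group by its label at `level`; fall back to the full prefix
    # join only when the same label occurs under different parents
    label_prefixes: dict[str, set[tuple[str, ...]]] = {}
    for prefix in groups.values():
        label_prefixes.setdefault(prefix[-1], set()).add(prefix)
    new_ids = {
        taxon: (
            prefix[-1]
            if len(label_prefixes[prefix[-1]]) == 1
            else ";".join(prefix)
        )
        for taxon, prefix in groups.items()
    }
    collapsed = table.data.T.groupby(
        table.data.columns.map(new_ids), sort=True
    ).sum().T

    lineage_rows = {}
    for taxon, prefix in groups.items():
        nid = new_ids[taxon]
        if nid not in lineage_rows:
            lineage_rows[nid] = tuple(prefix) + ("",) * (len(RANKS) - len(prefix))
    lineages = pd.DataFrame(
        [lineage_rows[nid] for nid in collapsed.columns],
        index=collapsed.columns,
        columns=list(RANKS),
    )
    return AbundanceTable(
        data=collapsed, lineages=lineages, metadata=table.metadata.copy()
    )
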