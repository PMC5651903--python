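"""Readers, writers, and validated in-memory containers for the file formats
the pipeline consumes.

Expression matrices arrive as TSV (genes in rows, one header row of sample
ids) or GCT 1.2, always on linear scale; log transforms happen inside the
analysis functions, never at I/O time.  Gene sets are GMT, peaks are BED6 or
ENCODE narrowPeak (0-based half-open, preserved bit-exact on round trip),
clinical follow-up and gene loci are plain TSV.  Any path ending in ``.gz``
is transparently gzip-compressed.

All containers validate on construction so downstream code can assume unique
identifiers, finite non-negative expression, strictly positive follow-up
times, and well-formed intervals.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "GeneSetCollection",
    "SurvivalTable",
    "GenomicIntervalSet",
    "GeneLociTable",
    "read_expression",
    "write_expression",
    "read_sample_groups",
    "write_sample_groups",
    "read_gmt",
    "write_gmt",
    "read_intervals",
    "write_intervals",
    "read_survival",
    "write_survival",
    "read_loci",
    "write_loci",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = sorted(ids[ids.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what} ids: {dupes[:10]}")


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass
class ExpressionStudy:
    """Linear-scale gene x sample expression matrix with optional group labels.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``sample_group`` maps each sample id to a label such as ``tumor`` /
    ``normal`` or ``high`` / ``low``.
    """

    values: pd.DataFrame
    sample_group: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self._first_non_numeric()
            raise ValueError(f"non-numeric expression value at {bad}")
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.sample_group is not None:
            missing = self.values.columns.difference(self.sample_group.index)
            if len(missing):
                raise ValueError(f"samples without a group label: {sorted(missing)[:10]}")
            self.sample_group = self.sample_group.reindex(self.values.columns)

    def _first_non_numeric(self) -> str:
        for col in self.values.columns:
            coerced = pd.to_numeric(self.values[col], errors="coerce")
            bad = coerced.isna() & self.values[col].notna()
            if bad.any():
                return f"gene {bad.idxmax()!r}, sample {col!r}"
        return "unknown position"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, label: str) -> list[str]:
        if self.sample_group is None:
            raise ValueError("study has no sample group labels")
        return list(self.sample_group.index[self.sample_group == label])


def read_expression(path, dialect: str | None = None, groups=None) -> ExpressionStudy:
    """Read a TSV or GCT 1.2 expression matrix.

    ``dialect`` is ``"tsv"`` or ``"gct"``; when None it is inferred from the
    file extension.  ``groups`` optionally names a sidecar two-column TSV
    (sample_id, group) whose labels are attached to the study.
    """
    path = Path(path)
    if dialect is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        dialect = "gct" if stem.endswith(".gct") else "tsv"
    if dialect == "gct":
        values = _read_gct(path)
    elif dialect == "tsv":
        with _open_text(path) as fh:
            values = pd.read_csv(fh, sep="\t", index_col=0)
    else:
        raise ValueError(f"unknown expression dialect {dialect!r}")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    group_series = read_sample_groups(groups) if groups is not None else None
    return ExpressionStudy(values=values, sample_group=group_series)


def _read_gct(path) -> pd.DataFrame:
    with _open_text(path) as fh:
        magic = fh.readline().strip()
        if magic != "#1.2":
            raise ValueError(f"not a GCT 1.2 file (first line {magic!r})")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError("GCT dimension line malformed")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t", index_col=0)
    if "Description" in body.columns:
        body = body.drop(columns=["Description"])
    else:  # GCT 1.2 requires the Description column right after Name
        body = body.iloc[:, 1:]
    if body.shape != (n_rows, n_cols):
        raise ValueError(
            f"GCT declares {n_rows} x {n_cols} but body is "
            f"{body.shape[0]} x {body.shape[1]}"
        )
    return body


def write_expression(study: ExpressionStudy, path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        dialect = "gct" if stem.endswith(".gct") else "tsv"
    if dialect == "tsv":
        with _open_text(path, "wt") as fh:
            study.values.to_csv(fh, sep="\t", index_label="gene_id")
    elif dialect == "gct":
        with _open_text(path, "wt") as fh:
            fh.write("#1.2\n")
            fh.write(f"{study.n_genes}\t{study.n_samples}\n")
            out = study.values.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown expression dialect {dialect!r}")


def read_sample_groups(path) -> pd.Series:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample group file needs columns {sorted(required)}")
    extra = set(df.columns) - required
    if extra:
        log.warning("ignoring extra sample-group columns %s", sorted(extra))
    _check_unique(df["sample_id"], "sample")
    return pd.Series(df["group"].values, index=df["sample_id"].values, name="group")


def write_sample_groups(groups: pd.Series, path) -> None:
    with _open_text(path, "wt") as fh:
        pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
            fh, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Gene set collections (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. hallmark collections or a derived signature)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not name or not str(name).strip():
                raise ValueError("gene set with a blank name")
            if not members:
                raise ValueError(f"gene set {name!r} has no members")
            self.sets[name] = set(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if not name.strip():
                raise ValueError(f"GMT line {lineno}: blank set name")
            if not members:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no members")
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with _open_text(path, "wt") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Survival tables


@dataclass
class SurvivalTable:
    """Per-subject follow-up time (months, > 0) and binary event flag."""

    data: pd.DataFrame  # columns: sample_id, time, event

    def __post_init__(self) -> None:
        required = ["sample_id", "time", "event"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"survival table missing columns {missing}")
        self.data = self.data[required].copy()
        self.data["sample_id"] = self.data["sample_id"].astype(str)
        _check_unique(self.data["sample_id"], "sample")
        t = pd.to_numeric(self.data["time"], errors="coerce")
        if t.isna().any() or not np.isfinite(t).all() or (t <= 0).any():
            bad = self.data.loc[~(t > 0) | ~np.isfinite(t), "sample_id"].tolist()
            raise ValueError(f"non-positive or non-finite times for samples {bad[:10]}")
        e = pd.to_numeric(self.data["event"], errors="coerce")
        if not e.isin([0, 1]).all():
            bad = self.data.loc[~e.isin([0, 1]), "sample_id"].tolist()
            raise ValueError(f"event flag not in {{0,1}} for samples {bad[:10]}")
        self.data["time"] = t.astype(float)
        self.data["event"] = e.astype(int)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def subset(self, sample_ids) -> "SurvivalTable":
        keep = self.data["sample_id"].isin(set(sample_ids))
        return SurvivalTable(self.data.loc[keep].reset_index(drop=True))


def read_survival(path) -> SurvivalTable:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    if "sample" in df.columns and "sample_id" not in df.columns:
        df = df.rename(columns={"sample": "sample_id"})
    extra = set(df.columns) - {"sample_id", "time", "event"}
    if extra:
        log.warning("ignoring extra survival columns %s", sorted(extra))
    return SurvivalTable(df)


def write_survival(table: SurvivalTable, path) -> None:
    with _open_text(path, "wt") as fh:
        table.data.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genomic intervals (BED6 / narrowPeak)

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_COLS = BED6_COLS + ["signal_value", "p_value", "q_value", "summit"]


@dataclass
class GenomicIntervalSet:
    """Peak intervals in 0-based half-open coordinates.

    Ten columns are always carried internally (narrowPeak layout); for BED6
    input the four extras are filled with placeholders and ``summit`` with -1
    (absent).  Non-coordinate columns are stored as the strings read from
    disk so a write round-trips byte-identically.
    """

    records: pd.DataFrame
    source_format: str = "bed"

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in NARROWPEAK_COLS:
            if col not in df.columns:
                if col == "summit":
                    df[col] = -1
                elif col in ("signal_value", "p_value", "q_value"):
                    df[col] = "0"
                else:
                    raise ValueError(f"interval set missing column {col!r}")
        df = df[NARROWPEAK_COLS]
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["summit"] = df["summit"].astype(np.int64)
        for col in ("name", "score", "strand", "signal_value", "p_value", "q_value"):
            df[col] = df[col].astype(str)
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise ValueError(
                f"interval {row['name']!r}: start {row['start']} >= end {row['end']}"
            )
        lengths = df["end"] - df["start"]
        bad = (df["summit"] >= lengths) | ((df["summit"] < 0) & (df["summit"] != -1))
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise ValueError(f"interval {row['name']!r}: summit offset out of range")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def starts(self) -> np.ndarray:
        return self.records["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.records["end"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.records["chrom"].to_numpy()

    def anchors(self) -> np.ndarray:
        """Summit position when present, otherwise the interval midpoint."""
        s = self.records["summit"].to_numpy()
        centers = self.starts + (self.ends - self.starts) // 2
        return np.where(s >= 0, self.starts + s, centers)

    def subset(self, mask) -> "GenomicIntervalSet":
        return GenomicIntervalSet(
            self.records.loc[np.asarray(mask)].reset_index(drop=True),
            source_format=self.source_format,
        )


def read_intervals(path, format: str | None = None) -> GenomicIntervalSet:
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        format = "narrowpeak" if stem.lower().endswith(".narrowpeak") else "bed"
    format = format.lower()
    if format not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown interval format {format!r}")
    rows = []
    n_expected = 10 if format == "narrowpeak" else 6
    cols = NARROWPEAK_COLS if format == "narrowpeak" else BED6_COLS
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < n_expected:
                raise ValueError(
                    f"{path.name} line {lineno}: expected {n_expected} columns, "
                    f"got {len(fields)}"
                )
            rows.append(fields[:n_expected])
    df = pd.DataFrame(rows, columns=cols)
    if len(df) == 0:
        df = pd.DataFrame(columns=cols)
    return GenomicIntervalSet(df, source_format=format)


def write_intervals(intervals: GenomicIntervalSet, path, format: str | None = None) -> None:
    if format is None:
        format = intervals.source_format
    cols = NARROWPEAK_COLS if format.lower() == "narrowpeak" else BED6_COLS
    with _open_text(path, "wt") as fh:
        for _, row in intervals.records.iterrows():
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# Gene loci (TSS reference for peak annotation)


@dataclass
class GeneLociTable:
    """One TSS per gene: (gene, chrom, tss, strand)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "chrom", "tss", "strand"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"loci table missing columns {missing}")
        df = self.data[required].copy()
        df["gene"] = df["gene"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        _check_unique(df["gene"], "gene")
        tss = pd.to_numeric(df["tss"], errors="coerce")
        if tss.isna().any() or (tss < 0).any():
            bad = df.loc[~(tss >= 0), "gene"].tolist()
            raise ValueError(f"invalid tss for genes {bad[:10]}")
        df["tss"] = tss.astype(np.int64)
        if not df["strand"].isin(["+", "-"]).all():
            bad = df.loc[~df["strand"].isin(["+", "-"]), "gene"].tolist()
            raise ValueError(f"strand not +/- for genes {bad[:10]}")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data["gene"])


def read_loci(path) -> GeneLociTable:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    if "gene_id" in df.columns and "gene" not in df.columns:
        df = df.rename(columns={"gene_id": "gene"})
    extra = set(df.columns) - {"gene", "chrom", "tss", "strand"}
    if extra:
        log.warning("ignoring extra loci columns %s", sorted(extra))
    return GeneLociTable(df)


def write_loci(loci: GeneLociTable, path) -> None:
    with _open_text(path, "wt") as fh:
        loci.data.to_csv(fh, sep="\t", index=False)
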