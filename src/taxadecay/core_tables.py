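"""Data model, file I/O and cross-table validation for the biogeography pipeline.

Four containers flow through every stage of the analysis:

* :class:`OtuTable` — integer read counts per sample and OTU, with a taxonomy
  string per OTU from which the phylum is parseable.
* :class:`SampleFrame` — per-sample metadata: site grouping, GPS coordinates,
  elevation, soil chemistry, climate variables and plant diversity.
* :class:`SignalTable` — functional gene array intensities (probes annotated to
  gene categories), with undetected spots kept as an explicit missing marker
  rather than zero.
* :class:`DistanceMatrix` — labelled square symmetric matrix (geographic km,
  Bray-Curtis dissimilarity, or absolute scalar differences).

The internal orientation convention is samples-as-rows for every matrix; file
dialects that put OTUs or probes on rows are transposed on ingest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "OtuTable",
    "SampleFrame",
    "SignalTable",
    "DistanceMatrix",
    "read_otu_table",
    "write_otu_table",
    "read_sample_frame",
    "write_sample_frame",
    "read_signal_table",
    "write_signal_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "align_tables",
]

#: Tolerance for symmetry checks on distance matrices.
SYMMETRY_TOL = 1e-12

#: Columns a sample metadata sheet must provide.
REQUIRED_SAMPLE_COLUMNS = ("sample_id", "site_id", "latitude", "longitude")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A container invariant was violated; the message locates the cell."""


def _check_unique(labels: Sequence, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


# ---------------------------------------------------------------------------
# OtuTable
# ---------------------------------------------------------------------------

_RANK_PREFIXES = ("p__", "P__")


def parse_phylum(taxonomy: str) -> str:
    """Extract the phylum from a taxonomy string.

    Rank-prefixed dialects (``k__Bacteria; p__Acidobacteria; ...``) are
    preferred; plain semicolon-separated lineages fall back to position 1
    (domain; phylum; ...).  Returns ``"unclassified"`` when nothing parses.
    """
    if not taxonomy:
        return "unclassified"
    fields = [f.strip() for f in taxonomy.split(";")]
    for f in fields:
        for pref in _RANK_PREFIXES:
            if f.startswith(pref):
                name = f[len(pref):].strip()
                return name if name else "unclassified"
    if len(fields) >= 2 and fields[1] and not any(
        fields[1].startswith(p) for p in ("k__", "c__", "o__", "f__", "g__", "s__")
    ):
        return fields[1]
    return "unclassified"


@dataclass
class OtuTable:
    """Samples × OTUs count matrix with per-OTU taxonomy.

    Parameters
    ----------
    counts
        DataFrame with sample ids on the index and OTU ids on the columns;
        nonnegative integers.
    taxonomy
        Mapping of every OTU id to its taxonomy string (``"unclassified"``
        is acceptable).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        _check_unique(self.counts.index, "sample ids")
        _check_unique(self.counts.columns, "OTU ids")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            rounded = np.rint(values)
            if not np.allclose(values, rounded, atol=0, rtol=0):
                bad = np.argwhere(values != rounded)[0]
                raise ValidationError(
                    "non-integer count at sample "
                    f"{self.counts.index[bad[0]]!r}, OTU {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"OTU {self.counts.columns[j]!r}"
            )
        self.taxonomy = pd.Series(self.taxonomy, dtype=object)
        missing = self.counts.columns.difference(self.taxonomy.index)
        if len(missing):
            raise ValidationError(f"OTUs without taxonomy: {missing[:5].tolist()}")
        self.taxonomy = self.taxonomy.reindex(self.counts.columns)

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return self.counts.index.tolist()

    @property
    def otu_ids(self) -> list:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def phyla(self) -> pd.Series:
        """Per-OTU parsed phylum names."""
        return self.taxonomy.map(parse_phylum)

    def select_samples(self, sample_ids: Sequence) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)], self.taxonomy)

    def select_otus(self, otu_ids: Sequence) -> "OtuTable":
        cols = list(otu_ids)
        return OtuTable(self.counts[cols], self.taxonomy.loc[cols])


def read_otu_table(path, format_hint: str | None = None) -> OtuTable:
    """Read an OTU table from TSV (``#OTU ID`` dialect) or BIOM 1.0 JSON.

    The TSV dialect has OTUs as rows, samples as columns and taxonomy in a
    trailing ``taxonomy`` column; the table is transposed on ingest so samples
    index rows internally.
    """
    path = str(path)
    fmt = format_hint
    if fmt is None:
        fmt = "biom" if path.endswith(".biom") or path.endswith(".json") else "tsv"
    if fmt == "biom":
        return _read_otu_biom(path)
    return _read_otu_tsv(path)


def _read_otu_tsv(path: str) -> OtuTable:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.startswith("#OTU ID") or (line and not line.startswith("#")):
            header_idx = i
            break
    if header_idx is None or not lines[header_idx].strip():
        raise ParseError(f"{path}: no header line found")
    header = lines[header_idx].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: line {header_idx + 1}: malformed header {header!r}")
    has_tax = header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1:-1] if has_tax else header[1:]
    if not sample_ids:
        raise ParseError(f"{path}: line {header_idx + 1}: header names no samples")
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    taxonomies: list[str] = []
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        expected = len(sample_ids) + 1 + int(has_tax)
        if len(parts) != expected:
            raise ParseError(
                f"{path}: line {lineno}: expected {expected} fields, got {len(parts)}"
            )
        otu_ids.append(parts[0])
        cells = parts[1:len(sample_ids) + 1]
        row = []
        for sample, cell in zip(sample_ids, cells):
            try:
                value = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: line {lineno}: non-numeric count {cell!r} "
                    f"(OTU {parts[0]!r}, sample {sample!r})"
                ) from None
            if value < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: negative count {cell!r} "
                    f"(OTU {parts[0]!r}, sample {sample!r})"
                )
            row.append(int(round(value)))
        rows.append(row)
        taxonomies.append(parts[-1] if has_tax else "unclassified")
    counts = pd.DataFrame(rows, index=otu_ids, columns=sample_ids, dtype=np.int64).T
    taxonomy = pd.Series(taxonomies, index=otu_ids, dtype=object)
    return OtuTable(counts, taxonomy)


def _read_otu_biom(path: str) -> OtuTable:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid BIOM JSON at line {exc.lineno}") from exc
    try:
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        data = doc["data"]
        mtype = doc.get("matrix_type", "sparse")
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: missing BIOM field {exc}") from exc
    mat = np.zeros(shape, dtype=np.int64)
    if mtype == "dense":
        mat[:] = np.asarray(data)
    else:
        for i, j, v in data:
            mat[int(i), int(j)] = int(round(v))
    taxonomy = {}
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        tax = meta.get("taxonomy", "unclassified")
        if isinstance(tax, (list, tuple)):
            tax = "; ".join(tax)
        taxonomy[r["id"]] = tax
    counts = pd.DataFrame(mat, index=otu_ids, columns=sample_ids).T
    return OtuTable(counts, pd.Series(taxonomy, dtype=object))


def write_otu_table(otu: OtuTable, path, format: str = "tsv") -> None:
    """Write an OTU table in the ``#OTU ID`` TSV dialect or BIOM 1.0 JSON."""
    path = str(path)
    if format == "biom":
        mat = otu.counts.T  # rows = OTUs in BIOM
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "taxadecay",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [mat.shape[0], mat.shape[1]],
            "rows": [
                {"id": o, "metadata": {"taxonomy": otu.taxonomy[o]}}
                for o in mat.index
            ],
            "columns": [{"id": s, "metadata": None} for s in mat.columns],
            "data": [
                [int(i), int(j), int(v)]
                for (i, j), v in np.ndenumerate(mat.to_numpy())
                if v
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    out = otu.counts.T.copy()
    out["taxonomy"] = otu.taxonomy
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SampleFrame
# ---------------------------------------------------------------------------

@dataclass
class SampleFrame:
    """Per-sample metadata sheet, indexed by unique ``sample_id``.

    Required columns: ``site_id``, ``latitude``, ``longitude``.  Any further
    numeric columns (elevation, soil chemistry, climate, ``plant_shannon``)
    ride along and are retrievable by name; absent columns stay absent rather
    than being filled with zeros.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        _check_unique(df.index, "sample ids")
        for col in ("site_id", "latitude", "longitude"):
            if col not in df.columns:
                raise ValidationError(f"missing required column {col!r}")
        lat = pd.to_numeric(df["latitude"], errors="coerce")
        lon = pd.to_numeric(df["longitude"], errors="coerce")
        bad_lat = df.index[(lat.isna()) | (lat < -90) | (lat > 90)]
        if len(bad_lat):
            raise ValidationError(
                f"latitude out of [-90, 90] for sample {bad_lat[0]!r}"
            )
        bad_lon = df.index[(lon.isna()) | (lon < -180) | (lon > 180)]
        if len(bad_lon):
            raise ValidationError(
                f"longitude out of [-180, 180] for sample {bad_lon[0]!r}"
            )
        df = df.copy()
        df["latitude"] = lat
        df["longitude"] = lon
        for col in df.columns:
            if col == "site_id":
                continue
            converted = pd.to_numeric(df[col], errors="coerce")
            if not converted.isna().all():
                df[col] = converted
        self.data = df

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def site_ids(self) -> pd.Series:
        return self.data["site_id"]

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"sample frame has no column {name!r}")
        return self.data[name]

    def coordinates(self) -> pd.DataFrame:
        return self.data[["latitude", "longitude"]]

    def select_samples(self, sample_ids: Sequence) -> "SampleFrame":
        return SampleFrame(self.data.loc[list(sample_ids)])


def read_sample_frame(path) -> SampleFrame:
    """Read a CSV/TSV metadata sheet (delimiter sniffed from the header)."""
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "site_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: line 1: header lacks 'sample_id'")
    return SampleFrame(df)


def write_sample_frame(frame: SampleFrame, path, sep: str = "\t") -> None:
    out = frame.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# SignalTable
# ---------------------------------------------------------------------------

@dataclass
class SignalTable:
    """Functional gene array intensities, samples × probes internally.

    Undetected spots are NaN, *not* zero: the detection filter counts
    detections while the normaliser treats missing as zero contribution.

    Parameters
    ----------
    intensities
        DataFrame, sample ids on the index, probe ids on the columns; detected
        entries are nonnegative reals, undetected entries NaN.
    category
        Mapping probe id → gene-category name.
    site_of
        Optional mapping sample id → site id (required by the detection
        filter, usually supplied from a :class:`SampleFrame`).
    """

    intensities: pd.DataFrame
    category: pd.Series
    site_of: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.intensities.index, "sample ids")
        _check_unique(self.intensities.columns, "probe ids")
        values = self.intensities.to_numpy(dtype=float)
        if values.size and not np.isnan(values).all() and np.nanmin(values) < 0:
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative intensity at sample {self.intensities.index[i]!r}, "
                f"probe {self.intensities.columns[j]!r}"
            )
        self.intensities = self.intensities.astype(float)
        self.category = pd.Series(self.category, dtype=object)
        missing = self.intensities.columns.difference(self.category.index)
        if len(missing):
            raise ValidationError(f"probes without category: {missing[:5].tolist()}")
        self.category = self.category.reindex(self.intensities.columns)
        if self.site_of is not None:
            self.site_of = pd.Series(self.site_of).reindex(self.intensities.index)

    @property
    def sample_ids(self) -> list:
        return self.intensities.index.tolist()

    @property
    def probe_ids(self) -> list:
        return self.intensities.columns.tolist()

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (non-missing, positive) spots."""
        return self.intensities.notna() & (self.intensities > 0)

    def with_sites(self, frame: SampleFrame) -> "SignalTable":
        """Attach the sample → site mapping from a metadata sheet."""
        return SignalTable(
            self.intensities,
            self.category,
            frame.site_ids.reindex(self.intensities.index),
        )

    def select_samples(self, sample_ids: Sequence) -> "SignalTable":
        ids = list(sample_ids)
        site_of = None if self.site_of is None else self.site_of.loc[ids]
        return SignalTable(self.intensities.loc[ids], self.category, site_of)


def read_signal_table(path) -> SignalTable:
    """Read a probes × samples TSV with a trailing ``category`` column.

    Empty cells and ``NA`` mark undetected spots.
    """
    path = str(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA", "nan"])
    if "category" not in df.columns:
        raise ParseError(f"{path}: line 1: header lacks a 'category' column")
    category = df["category"].astype(object)
    inten = df.drop(columns=["category"]).astype(float).T
    return SignalTable(inten, category)


def write_signal_table(table: SignalTable, path) -> None:
    out = table.intensities.T.copy()
    out["category"] = table.category
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------

DISTANCE_KINDS = ("geographic-km", "bray-curtis", "scalar-difference")


@dataclass
class DistanceMatrix:
    """Labelled square symmetric nonnegative matrix with zero diagonal."""

    labels: list
    values: np.ndarray
    kind: str = "scalar-difference"

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        _check_unique(self.labels, "labels")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if self.kind not in DISTANCE_KINDS:
            raise ValidationError(f"unknown distance kind {self.kind!r}")
        if n and np.abs(self.values - self.values.T).max() > SYMMETRY_TOL:
            raise ValidationError("matrix is not symmetric to within 1e-12")
        # symmetrise exactly so downstream vectorisation is well defined
        self.values = (self.values + self.values.T) / 2.0
        if n and np.abs(np.diag(self.values)).max() > SYMMETRY_TOL:
            raise ValidationError("diagonal is not zero")
        np.fill_diagonal(self.values, 0.0)
        if n and self.values.min() < 0:
            raise ValidationError("negative distance entry")
        if self.kind == "bray-curtis" and n and self.values.max() > 1 + SYMMETRY_TOL:
            raise ValidationError("Bray-Curtis entry exceeds 1")

    @property
    def n(self) -> int:
        return len(self.labels)

    def select(self, labels: Sequence) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            [self.labels[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def read_distance_matrix(path, kind: str = "scalar-difference") -> DistanceMatrix:
    """Read a labelled square TSV; a lower-triangle dialect is mirrored up."""
    path = str(path)
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    labels = [h for h in header[1:] if h != ""]
    n = len(labels)
    mat = np.full((n, n), np.nan)
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        row_label = parts[0]
        if row_label not in labels:
            raise ParseError(f"{path}: line {lineno}: unknown row label {row_label!r}")
        i = labels.index(row_label)
        for j, cell in enumerate(parts[1:]):
            if j >= n or cell == "":
                continue
            try:
                mat[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric cell {cell!r}"
                ) from None
    # mirror the available triangle into missing cells
    missing = np.isnan(mat)
    mat[missing] = mat.T[missing]
    np.fill_diagonal(mat, np.where(np.isnan(np.diag(mat)), 0.0, np.diag(mat)))
    if np.isnan(mat).any():
        i, j = np.argwhere(np.isnan(mat))[0]
        raise ParseError(
            f"{path}: cell ({labels[i]}, {labels[j]}) missing from both triangles"
        )
    return DistanceMatrix(labels, mat, kind)


def write_distance_matrix(m: DistanceMatrix, path) -> None:
    df = m.to_frame()
    df.index.name = ""
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentReport:
    """Which sample ids were dropped from each table during alignment."""

    kept: list
    dropped_otu: list = field(default_factory=list)
    dropped_frame: list = field(default_factory=list)
    dropped_signals: list = field(default_factory=list)


def align_tables(
    otu: OtuTable,
    frame: SampleFrame,
    signals: SignalTable | None = None,
) -> tuple[OtuTable, SampleFrame, SignalTable | None, AlignmentReport]:
    """Restrict all tables to their common samples, in OTU-table order.

    Returns the aligned tables plus an :class:`AlignmentReport` listing the
    sample ids dropped from each input.  Raises :class:`ValidationError` when
    the intersection is empty.
    """
    common = [s for s in otu.sample_ids if s in set(frame.sample_ids)]
    if signals is not None:
        sig_ids = set(signals.sample_ids)
        common = [s for s in common if s in sig_ids]
    if not common:
        raise ValidationError("no samples shared between the input tables")
    report = AlignmentReport(
        kept=common,
        dropped_otu=[s for s in otu.sample_ids if s not in set(common)],
        dropped_frame=[s for s in frame.sample_ids if s not in set(common)],
        dropped_signals=(
            [] if signals is None
            else [s for s in signals.sample_ids if s not in set(common)]
        ),
    )
    otu_a = otu.select_samples(common)
    frame_a = frame.select_samples(common)
    signals_a = None if signals is None else signals.select_samples(common)
    return otu_a, frame_a, signals_a, report
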