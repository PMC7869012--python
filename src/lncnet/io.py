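"""Readers and writers for the external formats the pipeline touches.

Formats
-------
* GEO series-matrix text (expression values + sample metadata),
* feature annotation as a headered TSV or a GTF (coordinates kept 1-based
  inclusive, as in the GTF convention),
* GMT gene-set collections,
* Cytoscape-loadable tab-separated edge lists,
* plain headered TSV result tables.

Everything round-trips: ``read(write(x)) == x`` field-for-field, with
numbers written at full double precision.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("lncnet.io")

GROUPS = ("control", "treated")

ANNOTATION_COLUMNS = ["feature_id", "symbol", "biotype", "chrom", "strand", "start", "end"]

#: default mapping from GTF biotype attribute values to the two biotypes
#: the pipeline distinguishes
GTF_BIOTYPE_MAP = {
    "protein_coding": "mRNA",
    "mrna": "mRNA",
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "antisense": "lncRNA",
}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Normalized log2 intensities, features x samples, with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    groups
        Series mapping each sample id to ``"control"`` or ``"treated"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicated feature_id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicated sample_id {dup!r}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise FormatError(f"samples without group label: {missing}")
        self.groups = self.groups.reindex(self.values.columns)
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        for g in GROUPS:
            if not (self.groups == g).any():
                raise FormatError(f"group {g!r} has no samples")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix of the samples belonging to one group."""
        return self.values[self.samples_of(group)]

    def subset(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.groups)


def read_series_matrix(path, group_patterns: dict[str, str | list[str]]) -> ExpressionMatrix:
    """Read a GEO series-matrix text file.

    The expression block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` becomes the matrix (probe order and sample
    order preserved).  Group labels are derived from the per-sample metadata
    lines (``!Sample_title``, ``!Sample_characteristics_ch1``, ...):
    ``group_patterns`` maps ``"control"``/``"treated"`` to one or more
    substrings, and every sample must be matched by exactly one group.

    Raises
    ------
    FormatError
        If the table block is missing, a probe row is duplicated, or a
        sample matches zero or multiple groups.
    """
    sample_meta: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    saw_table = False
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                saw_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
            elif line.startswith("!Sample_"):
                fields = [f.strip().strip('"') for f in line.split("\t")]
                sample_meta.append(fields)
    if not saw_table or not table_lines:
        raise FormatError(f"{path}: no series_matrix_table block")

    header = [f.strip().strip('"') for f in table_lines[0].split("\t")]
    sample_ids = header[1:]
    rows = []
    index = []
    for line in table_lines[1:]:
        fields = line.split("\t")
        index.append(fields[0].strip().strip('"'))
        rows.append([float(v) if v.strip() not in ("", "null", "NULL") else math.nan
                     for v in fields[1:]])
    values = pd.DataFrame(rows, index=index, columns=sample_ids, dtype=float)

    # per-sample metadata string used for pattern matching
    meta_per_sample = ["" for _ in sample_ids]
    for fields in sample_meta:
        if len(fields) == len(sample_ids) + 1:
            for i, v in enumerate(fields[1:]):
                meta_per_sample[i] += v + " | "

    groups = {}
    for sid, meta in zip(sample_ids, meta_per_sample):
        hits = []
        for group, patterns in group_patterns.items():
            if isinstance(patterns, str):
                patterns = [patterns]
            if any(p.lower() in meta.lower() for p in patterns):
                hits.append(group)
        if len(hits) != 1:
            raise FormatError(
                f"sample {sid!r} matched {len(hits)} group patterns (metadata: {meta!r})"
            )
        groups[sid] = hits[0]
    return ExpressionMatrix(values, pd.Series(groups))


def write_series_matrix(matrix: ExpressionMatrix, path, title: str = "synthetic study") -> None:
    """Write an :class:`ExpressionMatrix` in series-matrix style.

    The group label is emitted as a ``!Sample_characteristics_ch1`` line
    (``group: control`` / ``group: treated``) so the file round-trips
    through :func:`read_series_matrix` with patterns
    ``{"control": "group: control", "treated": "group: treated"}``.
    """
    with open(path, "w") as fh:
        fh.write(f'!Series_title\t"{title}"\n')
        fh.write("!Sample_title\t" + "\t".join(f'"{s}"' for s in matrix.sample_ids) + "\n")
        fh.write(
            "!Sample_characteristics_ch1\t"
            + "\t".join(f'"group: {matrix.groups[s]}"' for s in matrix.sample_ids)
            + "\n"
        )
        fh.write("!series_matrix_table_begin\n")
        fh.write('"ID_REF"\t' + "\t".join(f'"{s}"' for s in matrix.sample_ids) + "\n")
        for fid, row in matrix.values.iterrows():
            fh.write(f'"{fid}"\t' + "\t".join(repr(float(v)) for v in row) + "\n")
        fh.write("!series_matrix_table_end\n")


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """Per-feature biotype, symbol and genomic coordinates.

    ``table`` holds one row per feature with columns
    ``feature_id, symbol, biotype, chrom, strand, start, end`` (1-based
    inclusive coordinates).  ``exons`` optionally maps a feature id to its
    sorted, non-overlapping exon intervals (also 1-based inclusive); when a
    feature has no exon records its whole span is treated as a single exon.
    """

    table: pd.DataFrame
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        missing = [c for c in ANNOTATION_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        if t["feature_id"].duplicated().any():
            dup = t.loc[t["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise FormatError(f"duplicated feature_id {dup!r}")
        bad_strand = set(t["strand"].unique()) - {"+", "-"}
        if bad_strand:
            raise FormatError(f"unknown strand symbol(s): {sorted(bad_strand)}")
        bad_bio = set(t["biotype"].unique()) - {"mRNA", "lncRNA"}
        if bad_bio:
            raise FormatError(f"unknown biotype(s): {sorted(bad_bio)}")
        t["start"] = t["start"].astype(int)
        t["end"] = t["end"].astype(int)
        rejected = t["start"] > t["end"]
        if rejected.any():
            for fid in t.loc[rejected, "feature_id"]:
                logger.warning("annotation record %s rejected: start > end", fid)
            t = t[~rejected].reset_index(drop=True)
        self.table = t[ANNOTATION_COLUMNS]
        self._row_of = {r.feature_id: r for r in self.table.itertuples(index=False)}
        cleaned = {}
        span = dict(zip(t["feature_id"], zip(t["start"], t["end"])))
        for fid, ivs in self.exons.items():
            if fid not in span:
                continue
            ivs = sorted((int(a), int(b)) for a, b in ivs)
            s0, e0 = span[fid]
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                if c <= b:
                    raise FormatError(f"{fid}: overlapping exons {(a, b)} and {(c, d)}")
            if ivs and (ivs[0][0] < s0 or ivs[-1][1] > e0):
                raise FormatError(f"{fid}: exon outside transcript span")
            cleaned[fid] = ivs
        self.exons = cleaned

    def __len__(self) -> int:
        return len(self.table)

    def of_biotype(self, biotype: str) -> "AnnotationTable":
        t = self.table[self.table["biotype"] == biotype]
        ex = {fid: iv for fid, iv in self.exons.items() if fid in set(t["feature_id"])}
        return AnnotationTable(t.reset_index(drop=True), ex)

    def exons_of(self, feature_id: str) -> list[tuple[int, int]]:
        """Exon intervals, falling back to the transcript span."""
        if feature_id in self.exons and self.exons[feature_id]:
            return self.exons[feature_id]
        rec = self.record(feature_id)
        return [(int(rec.start), int(rec.end))]

    def record(self, feature_id: str):
        """One annotation row as a lightweight namedtuple (attribute access)."""
        try:
            return self._row_of[feature_id]
        except KeyError:
            raise KeyError(feature_id) from None

    def row(self, feature_id: str) -> pd.Series:
        return pd.Series(self.record(feature_id)._asdict())

    @property
    def feature_ids(self) -> pd.Series:
        return self.table["feature_id"]


def _exons_to_str(ivs: list[tuple[int, int]]) -> str:
    return ";".join(f"{a}-{b}" for a, b in ivs)


def _exons_from_str(s: str) -> list[tuple[int, int]]:
    out = []
    for part in s.split(";"):
        if not part:
            continue
        a, b = part.split("-")
        out.append((int(a), int(b)))
    return out


def read_annotation(path, fmt: str | None = None,
                    column_map: dict[str, str] | None = None,
                    biotype_map: dict[str, str] | None = None) -> AnnotationTable:
    """Read a feature annotation from a headered TSV or a GTF.

    Parameters
    ----------
    fmt
        ``"tsv"`` or ``"gtf"``; sniffed from the file extension when omitted.
    column_map
        For TSV input, a mapping from the canonical column names
        (``feature_id``, ``biotype``, ...) to the file's column names, for
        platform tables with vendor-specific headers.
    biotype_map
        For GTF input, extra ``gene_biotype``/``transcript_biotype`` values
        mapped onto ``{"mRNA", "lncRNA"}`` (case-insensitive; merged over
        the defaults).
    """
    if fmt is None:
        fmt = "gtf" if str(path).lower().endswith((".gtf", ".gtf.gz")) else "tsv"
    if fmt == "tsv":
        return _read_annotation_tsv(path, column_map)
    if fmt == "gtf":
        return _read_annotation_gtf(path, biotype_map)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_annotation_tsv(path, column_map=None) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation TSV lacks column(s): {missing}")
    exons = {}
    if "exons" in df.columns:
        for fid, s in zip(df["feature_id"], df["exons"]):
            if isinstance(s, str) and s:
                exons[fid] = _exons_from_str(s)
    return AnnotationTable(df[ANNOTATION_COLUMNS].copy(), exons)


def _read_annotation_gtf(path, biotype_map=None) -> AnnotationTable:
    import pyranges

    bmap = dict(GTF_BIOTYPE_MAP)
    if biotype_map:
        bmap.update({k.lower(): v for k, v in biotype_map.items()})
    df = pyranges.read_gtf(path).df
    # pyranges exposes 0-based half-open Start; convert back to 1-based inclusive
    df["start1"] = df["Start"].astype(int) + 1
    df["end1"] = df["End"].astype(int)
    feats = df[df["Feature"] == "transcript"]
    rows = []
    for _, r in feats.iterrows():
        bio_raw = None
        for col in ("transcript_biotype", "gene_biotype"):
            if col in feats.columns and isinstance(r.get(col), str):
                bio_raw = r[col]
                break
        if bio_raw is None or bio_raw.lower() not in bmap:
            raise FormatError(
                f"transcript {r.get('transcript_id')!r}: missing or unknown biotype {bio_raw!r}"
            )
        symbol = r.get("gene_name")
        if not isinstance(symbol, str) or not symbol:
            symbol = r.get("gene_id", r["transcript_id"])
        rows.append(
            {
                "feature_id": r["transcript_id"],
                "symbol": symbol,
                "biotype": bmap[bio_raw.lower()],
                "chrom": str(r["Chromosome"]),
                "strand": str(r["Strand"]),
                "start": r["start1"],
                "end": r["end1"],
            }
        )
    exon_rows = df[df["Feature"] == "exon"]
    exons: dict[str, list[tuple[int, int]]] = {}
    for _, r in exon_rows.iterrows():
        exons.setdefault(r["transcript_id"], []).append((r["start1"], r["end1"]))
    return AnnotationTable(pd.DataFrame(rows), exons)


def write_annotation_tsv(annotation: AnnotationTable, path) -> None:
    df = annotation.table.copy()
    df["exons"] = [
        _exons_to_str(annotation.exons.get(fid, [])) for fid in df["feature_id"]
    ]
    df.to_csv(path, sep="\t", index=False)


def write_annotation_gtf(annotation: AnnotationTable, path, source: str = "lncnet") -> None:
    """Write transcripts (and their exon records) as GTF2.2, 1-based inclusive."""
    bio_back = {"mRNA": "protein_coding", "lncRNA": "lncRNA"}
    with open(path, "w") as fh:
        for _, r in annotation.table.iterrows():
            attrs = (
                f'gene_id "{r.symbol}"; transcript_id "{r.feature_id}"; '
                f'gene_name "{r.symbol}"; gene_biotype "{bio_back[r.biotype]}";'
            )
            fh.write(
                f"{r.chrom}\t{source}\ttranscript\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )
            for a, b in annotation.exons.get(r.feature_id, []):
                fh.write(
                    f"{r.chrom}\t{source}\texon\t{a}\t{b}\t.\t{r.strand}\t.\t"
                    f'gene_id "{r.symbol}"; transcript_id "{r.feature_id}";\n'
                )


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSets:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSets:
    """Read a GMT file: name, description, members, tab-separated.

    Lines with fewer than three fields are rejected with a warning; duplicate
    members within a set are dropped (first occurrence kept).
    """
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for n, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s line %d: fewer than 3 fields, skipped", path, n)
                continue
            name, description = fields[0], fields[1]
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = members
            desc[name] = description
    return GeneSets(sets, desc)


def write_gmt(gene_sets: GeneSets, path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.sets.items():
            description = gene_sets.descriptions.get(name, "")
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# edge lists and generic tables
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["lncRNA", "mRNA", "pcc", "p_value", "fdr", "sign"]


def write_edge_list(edges: pd.DataFrame, path) -> None:
    """Write a Cytoscape-loadable edge list.

    Columns: source lncRNA, target mRNA, pcc, p, fdr and a ``sign`` column
    (``positive`` for solid / ``negative`` for dotted rendering).  Numbers
    round-trip losslessly (shortest-repr doubles).
    """
    df = edges.copy()
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"edge table missing columns: {missing}")
    df[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"edge list missing columns: {missing}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as headered TSV, stable column order."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
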