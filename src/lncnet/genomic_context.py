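"""Genomic-context classification of lncRNAs and cis lncRNA-mRNA pairing.

A lncRNA is assigned exactly one of five classes by its relationship to
protein-coding genes, evaluated in a fixed (configurable) precedence order,
most specific overlap first:

1. ``exon_sense_overlapping`` - same strand, >= 1 bp overlap with a coding exon
2. ``natural_antisense``      - opposite strand, >= 1 bp overlap with a coding exon
3. ``intronic_antisense``     - opposite strand, wholly inside a coding gene
   span while overlapping no exon
4. ``bidirectional``          - no overlap with any coding gene, but a
   divergent (head-to-head) transcription start within a 1 kb window of an
   opposite-strand coding gene's start
5. ``intergenic``             - otherwise

Coordinates are 1-based inclusive throughout the public surface; the
interval arithmetic converts to 0-based half-open internally.
"""

from __future__ import annotations

import logging

import pandas as pd
from intervaltree import IntervalTree

from lncnet.io import AnnotationTable

logger = logging.getLogger("lncnet.genomic_context")

LNC_CLASSES = (
    "intergenic",
    "exon_sense_overlapping",
    "natural_antisense",
    "intronic_antisense",
    "bidirectional",
)

DEFAULT_PRECEDENCE = (
    "exon_sense_overlapping",
    "natural_antisense",
    "intronic_antisense",
    "bidirectional",
)


def genomic_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Base pairs strictly between two 1-based inclusive intervals.

    0 when the intervals overlap or abut; otherwise the number of bases
    separating the nearest ends.  Symmetric in its two intervals.
    """
    if start_a > end_a or start_b > end_b:
        raise ValueError("interval with start > end")
    return max(0, max(start_a, start_b) - min(end_a, end_b) - 1)


def _tss(strand: str, start: int, end: int) -> int:
    return start if strand == "+" else end


class CodingIndex:
    """Per-chromosome interval indexes over the coding annotation."""

    def __init__(self, coding: AnnotationTable):
        self.spans: dict[str, IntervalTree] = {}
        self.exons: dict[str, IntervalTree] = {}
        for row in coding.table.itertuples(index=False):
            # 0-based half-open for the tree
            self.spans.setdefault(row.chrom, IntervalTree()).addi(
                row.start - 1, row.end, (row.feature_id, row.strand, row.start, row.end)
            )
            tree = self.exons.setdefault(row.chrom, IntervalTree())
            for a, b in coding.exons_of(row.feature_id):
                tree.addi(a - 1, b, (row.feature_id, row.strand))

    def exon_overlaps(self, chrom: str, start: int, end: int):
        return self.exons.get(chrom, IntervalTree()).overlap(start - 1, end)

    def span_overlaps(self, chrom: str, start: int, end: int):
        return self.spans.get(chrom, IntervalTree()).overlap(start - 1, end)

    def genes_on(self, chrom: str):
        return [iv.data for iv in self.spans.get(chrom, IntervalTree())]


def classify_lncrna(
    lnc: pd.Series,
    index: CodingIndex,
    bidir_window: int = 1000,
    precedence=DEFAULT_PRECEDENCE,
) -> str:
    """Classify one lncRNA record against the coding index.

    ``lnc`` is a row of an :class:`AnnotationTable` (fields chrom, strand,
    start, end).  A lncRNA on a chromosome absent from the coding
    annotation is intergenic (warned).
    """
    chrom, strand = lnc["chrom"], lnc["strand"]
    start, end = int(lnc["start"]), int(lnc["end"])
    if chrom not in index.spans:
        logger.warning("lncRNA %s: chromosome %s has no coding genes; intergenic",
                       lnc.get("feature_id", "?"), chrom)
        return "intergenic"

    exon_hits = index.exon_overlaps(chrom, start, end)
    span_hits = index.span_overlaps(chrom, start, end)

    def rule(name: str) -> bool:
        if name == "exon_sense_overlapping":
            return any(d[1] == strand for iv in exon_hits for d in [iv.data])
        if name == "natural_antisense":
            return any(d[1] != strand for iv in exon_hits for d in [iv.data])
        if name == "intronic_antisense":
            return any(
                d[1] != strand and d[2] <= start and end <= d[3]
                for iv in span_hits
                for d in [iv.data]
            )
        if name == "bidirectional":
            if span_hits:  # any overlap with a coding gene body disqualifies
                return False
            lnc_tss = _tss(strand, start, end)
            for _, gstrand, gstart, gend in index.genes_on(chrom):
                if gstrand == strand:
                    continue
                gene_tss = _tss(gstrand, gstart, gend)
                if abs(lnc_tss - gene_tss) > bidir_window:
                    continue
                # divergent: the two bodies extend away from each other
                if gstrand == "+" and end < gstart:
                    return True
                if gstrand == "-" and start > gend:
                    return True
            return False
        raise ValueError(f"unknown rule {name!r}")

    for name in precedence:
        if rule(name):
            return name
    return "intergenic"


def classify_all(
    annotation: AnnotationTable,
    bidir_window: int = 1000,
    precedence=DEFAULT_PRECEDENCE,
    lnc_ids=None,
) -> pd.DataFrame:
    """Classify lncRNAs (all of them, or the subset ``lnc_ids``).

    Returns a DataFrame with columns ``feature_id, lnc_class``; the
    assignment is a total partition over the classified set.
    """
    coding = annotation.of_biotype("mRNA")
    lncs = annotation.of_biotype("lncRNA").table
    if lnc_ids is not None:
        lncs = lncs[lncs["feature_id"].isin(set(lnc_ids))]
    index = CodingIndex(coding)
    out = [
        {
            "feature_id": row["feature_id"],
            "lnc_class": classify_lncrna(row, index, bidir_window, precedence),
        }
        for _, row in lncs.iterrows()
    ]
    return pd.DataFrame(out, columns=["feature_id", "lnc_class"])


def class_composition(classes: pd.DataFrame) -> pd.DataFrame:
    """Per-class counts and percentages (the pie-chart table)."""
    counts = classes["lnc_class"].value_counts()
    total = int(counts.sum())
    rows = []
    for name in LNC_CLASSES:
        c = int(counts.get(name, 0))
        rows.append(
            {
                "lnc_class": name,
                "count": c,
                "percent": 100.0 * c / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _exon_overlap(annotation: AnnotationTable, fid_a: str, fid_b: str) -> bool:
    """Do two features share >= 1 bp of exonic sequence (span fallback)?"""
    if annotation.record(fid_a).chrom != annotation.record(fid_b).chrom:
        return False
    for a1, a2 in annotation.exons_of(fid_a):
        for b1, b2 in annotation.exons_of(fid_b):
            if max(a1, b1) <= min(a2, b2):
                return True
    return False


def _de_lookup(de_table: pd.DataFrame | None) -> dict[str, pd.Series]:
    if de_table is None:
        return {}
    return {r["feature_id"]: r for _, r in de_table.iterrows()}


_PAIR_STAT_COLS = ["p_value", "fold_change", "direction", "fdr"]


def _pair_record(lnc_id, mrna_id, distance, relation, lnc_de, mrna_de) -> dict:
    rec = {"lncRNA": lnc_id, "mRNA": mrna_id, "genomic_distance": distance,
           "relation": relation}
    for prefix, stats in (("lnc", lnc_de), ("mrna", mrna_de)):
        for col in _PAIR_STAT_COLS:
            rec[f"{prefix}_{col}"] = stats[col] if stats is not None and col in stats else None
    return rec


_PAIR_COLUMNS = (
    ["lncRNA", "mRNA", "genomic_distance", "relation"]
    + [f"lnc_{c}" for c in _PAIR_STAT_COLS]
    + [f"mrna_{c}" for c in _PAIR_STAT_COLS]
)


def antisense_dysregulated_pairs(
    de_lncs: pd.DataFrame,
    de_mrnas: pd.DataFrame,
    annotation: AnnotationTable,
) -> pd.DataFrame:
    """Dysregulated natural-antisense lncRNA-mRNA pairs.

    A pair qualifies when BOTH members are dysregulated and the lncRNA lies
    on the opposite strand of that specific mRNA with >= 1 bp exon overlap.
    """
    lnc_stats = _de_lookup(de_lncs)
    mrna_stats = _de_lookup(de_mrnas)
    known = set(annotation.feature_ids)
    by_chrom: dict[str, list] = {}
    for mrna_id in de_mrnas["feature_id"] if len(de_mrnas) else []:
        if mrna_id not in known:
            continue
        rec = annotation.record(mrna_id)
        by_chrom.setdefault(rec.chrom, []).append(rec)
    rows = []
    for lnc_id in de_lncs["feature_id"] if len(de_lncs) else []:
        if lnc_id not in known:
            logger.warning("antisense pairing: %s not in annotation, skipped", lnc_id)
            continue
        lnc = annotation.record(lnc_id)
        for mrna in by_chrom.get(lnc.chrom, []):
            if lnc.strand == mrna.strand:
                continue
            # cheap span check before the exon-level test
            if max(lnc.start, mrna.start) > min(lnc.end, mrna.end):
                continue
            if _exon_overlap(annotation, lnc_id, mrna.feature_id):
                rows.append(
                    _pair_record(lnc_id, mrna.feature_id, 0, "antisense_overlap",
                                 lnc_stats.get(lnc_id), mrna_stats.get(mrna.feature_id))
                )
    return pd.DataFrame(rows, columns=_PAIR_COLUMNS)


def nearby_dysregulated_pairs(
    de_lncs: pd.DataFrame,
    de_mrnas: pd.DataFrame,
    annotation: AnnotationTable,
    max_distance: int = 300_000,
) -> pd.DataFrame:
    """Dysregulated lncRNA-mRNA pairs within ``max_distance`` bp (inclusive).

    Pairs on one chromosome with genomic gap <= the threshold, each
    annotated with both members' DE statistics.  Many-to-one pairing is
    allowed (one mRNA may partner several lncRNAs and vice versa).
    Features lacking coordinates are skipped with a warning.
    """
    lnc_stats = _de_lookup(de_lncs)
    mrna_stats = _de_lookup(de_mrnas)
    known = set(annotation.feature_ids)
    by_chrom: dict[str, list] = {}
    for mrna_id in de_mrnas["feature_id"] if len(de_mrnas) else []:
        if mrna_id not in known:
            logger.warning("cis pairing: %s lacks coordinates, skipped", mrna_id)
            continue
        rec = annotation.record(mrna_id)
        by_chrom.setdefault(rec.chrom, []).append(rec)

    rows = []
    for lnc_id in de_lncs["feature_id"] if len(de_lncs) else []:
        if lnc_id not in known:
            logger.warning("cis pairing: %s lacks coordinates, skipped", lnc_id)
            continue
        lnc = annotation.record(lnc_id)
        for mrna in by_chrom.get(lnc.chrom, []):
            gap = genomic_gap(int(lnc.start), int(lnc.end),
                              int(mrna.start), int(mrna.end))
            if gap > max_distance:
                continue
            if lnc.strand != mrna.strand and _exon_overlap(
                annotation, lnc_id, mrna.feature_id
            ):
                relation = "antisense_overlap"
            else:
                relation = "neighbor"
            rows.append(
                _pair_record(lnc_id, mrna.feature_id, gap, relation,
                             lnc_stats.get(lnc_id), mrna_stats.get(mrna.feature_id))
            )
    return pd.DataFrame(rows, columns=_PAIR_COLUMNS)
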