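"""Gene models: GTF gene-feature I/O and positional classification of lncRNAs.

Coordinates are 1-based inclusive throughout (GTF dialect); all interval
arithmetic treats genes as closed intervals.  The gene-level model carries
no exon substructure: sense/antisense/intronic/lincRNA labels are decided
from gene-interval overlap, containment and strand alone.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GeneRecord",
    "read_gtf",
    "write_gtf",
    "classify_lncrna_position",
    "classify_positions",
    "write_position_classes",
]

BIOTYPES = ("coding", "lncRNA", "mito")

_BIOTYPE_ALIASES = {
    "coding": "coding",
    "protein_coding": "coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "lnc_RNA": "lncRNA",
    "mito": "mito",
    "mt": "mito",
}


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: closed interval on a chromosome, strand, biotype."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1 (1-based coordinates)")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: biotype must be one of {BIOTYPES}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GeneRecord") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end

    def contains(self, other: "GeneRecord") -> bool:
        """Containment of ``other`` within this gene's interval (spans may be equal)."""
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path) -> list[GeneRecord]:
    """Read gene features from a GTF file into :class:`GeneRecord` objects.

    Only ``gene`` features are parsed.  The biotype is taken from the first
    of the ``gene_biotype`` / ``gene_type`` / ``biotype`` attributes;
    unrecognised biotypes are mapped to ``coding`` with a warning.
    Malformed lines raise ``ValueError`` with the offending line number.
    """
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _parse_attributes(attrs_s)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise ValueError(f"{path}:{lineno}: gene feature without gene_id attribute")
            raw = attrs.get("gene_biotype") or attrs.get("gene_type") or attrs.get("biotype") or ""
            biotype = _BIOTYPE_ALIASES.get(raw)
            if biotype is None:
                warnings.warn(
                    f"{path}:{lineno}: unknown biotype {raw!r} for {gene_id}; treating as coding",
                    stacklevel=2,
                )
                biotype = "coding"
            try:
                records.append(
                    GeneRecord(gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand, biotype=biotype)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_gtf(records: Iterable[GeneRecord], path) -> None:
    """Write gene records as GTF gene features (round-trips with :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for rec in records:
            attrs = f'gene_id "{rec.gene_id}"; gene_biotype "{rec.biotype}";'
            fh.write(
                "\t".join(
                    [rec.chrom, "lncdosage", "gene", str(rec.start), str(rec.end), ".", rec.strand, ".", attrs]
                )
                + "\n"
            )


POSITION_CLASSES = ("sense", "antisense", "intronic", "lincRNA")


def classify_lncrna_position(lnc: GeneRecord, coding: Sequence[GeneRecord]) -> str:
    """Positional class of an lncRNA relative to protein-coding genes.

    Gene-level rule table, applied in precedence order:

    1. ``sense``     — overlaps a coding gene on the same strand;
    2. ``antisense`` — overlaps an opposite-strand coding gene without being
       contained in it (equal spans count as overlap, not containment);
    3. ``intronic``  — properly contained inside a coding gene (strictly
       smaller span, no strand requirement in the gene-level model);
    4. ``lincRNA``   — anything else (intergenic).

    The four labels are mutually exclusive and exhaustive.
    """
    if lnc.biotype != "lncRNA":
        raise ValueError(f"{lnc.gene_id} is not an lncRNA")
    contained = False
    opposite_overlap_not_contained = False
    for g in coding:
        if g.biotype != "coding" or not lnc.overlaps(g):
            continue
        if g.strand == lnc.strand:
            return "sense"
        proper = g.contains(lnc) and not (g.start == lnc.start and g.end == lnc.end)
        if proper:
            contained = True
        else:
            opposite_overlap_not_contained = True
    if opposite_overlap_not_contained:
        return "antisense"
    if contained:
        return "intronic"
    return "lincRNA"


def classify_positions(
    lncrnas: Sequence[GeneRecord], coding: Sequence[GeneRecord]
) -> dict[str, str]:
    """Classify every lncRNA; returns gene_id -> positional class."""
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in coding:
        if g.biotype == "coding":
            by_chrom.setdefault(g.chrom, []).append(g)
    return {
        lnc.gene_id: classify_lncrna_position(lnc, by_chrom.get(lnc.chrom, ()))
        for lnc in lncrnas
    }


def write_position_classes(classes: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\n")
        for gid, cls in classes.items():
            fh.write(f"{gid}\t{cls}\n")
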