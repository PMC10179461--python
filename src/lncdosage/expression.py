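"""Count-matrix container, CPM/FPKM normalisation and case/control ratio tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord

__all__ = ["CountMatrix", "cpm", "fpkm", "expression_ratio"]

logger = logging.getLogger(__name__)

GROUPS = ("control", "case")


@dataclass
class CountMatrix:
    """Integer RNA-seq counts, genes x samples, with a two-group design.

    ``counts`` is a pandas DataFrame indexed by gene id with one column per
    sample; ``groups`` maps every sample to ``control`` or ``case``.
    """

    counts: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        bad = {g for g in self.groups.values() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        for g in GROUPS:
            if not self.samples(g):
                raise ValueError(f"design has no {g} samples")
        arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, counts_path, design_path=None) -> None:
        df = self.counts.copy()
        df.index.name = "gene_id"
        df.to_csv(counts_path, sep="\t")
        if design_path is not None:
            pd.Series(self.groups, name="group").rename_axis("sample").to_csv(design_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, design_path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0)["group"]
        return cls(counts=df.astype(np.int64), groups=design.to_dict())


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalisation; every column of the result sums to 1e6."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    colsum = df.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"cannot CPM-normalise all-zero sample column(s): {list(zero.index)}")
    return df / colsum * 1e6


def fpkm(counts: CountMatrix | pd.DataFrame, gene_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Fragments per kilobase per million: counts / (length_kb * colsum/1e6)."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    missing = [g for g in df.index if g not in gene_lengths]
    if missing:
        raise KeyError(f"genes without a length: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    lengths = pd.Series({g: gene_lengths[g] for g in df.index}, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    per_million = df.sum(axis=0) / 1e6
    return df.div(per_million, axis=1).div(lengths / 1e3, axis=0)


def expression_ratio(
    counts: CountMatrix,
    annotation: Sequence[GeneRecord] | None = None,
    min_cpm: float = 1.0,
) -> pd.DataFrame:
    """Per-gene case/control expression ratio table on the CPM scale.

    Replicates are averaged on the CPM scale within each group, then the
    ratio of case to control means is taken.  Genes with mean control CPM
    below ``min_cpm`` or zero mean case CPM are dropped; the number dropped
    is stored in ``result.attrs["n_filtered"]`` and logged.

    Returns a DataFrame with columns ``gene_id, chrom, biotype,
    cpm_control, cpm_case, ratio``.
    """
    norm = cpm(counts)
    mean_control = norm[counts.samples("control")].mean(axis=1)
    mean_case = norm[counts.samples("case")].mean(axis=1)
    keep = (mean_control >= min_cpm) & (mean_case > 0)
    n_filtered = int((~keep).sum())
    if n_filtered:
        logger.info("expression_ratio: %d genes failed the expression filter", n_filtered)
    info: dict[str, GeneRecord] = {g.gene_id: g for g in annotation} if annotation else {}
    idx = counts.counts.index[keep]
    table = pd.DataFrame(
        {
            "gene_id": idx,
            "chrom": [info[g].chrom if g in info else "NA" for g in idx],
            "biotype": [info[g].biotype if g in info else "NA" for g in idx],
            "cpm_control": mean_control[keep].to_numpy(),
            "cpm_case": mean_case[keep].to_numpy(),
        }
    )
    table["ratio"] = table["cpm_case"] / table["cpm_control"]
    table.attrs["n_filtered"] = n_filtered
    return table
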