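"""Expression-ratio distribution analysis for aneuploid transcriptomes.

The central statistic of the package: per-gene case/control expression
ratios are binned into a fixed-width frequency distribution whose peaks
sit at canonical dosage-response values.  For a chromosome present in
three copies against a diploid control the canonical ratios are

* ``dosage_effect``  — 3/2, expression follows copy number,
* ``compensated``    — 1, expression is buffered back to diploid level,
* ``inverse``        — 2/3, genome-wide inverse response to the added dose,
* ``double_inverse`` — (2/3)**2 = 4/9, two multiplicative inverse responses.

Genes are assigned to the nearest canonical ratio within a tolerance;
histogram modes and per-chromosome medians summarise whole distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_RATIOS",
    "DosageClass",
    "DosageCall",
    "RatioHistogram",
    "histogram",
    "modal_bin",
    "classify_gene_response",
    "classify_ratio_table",
    "chromosome_medians",
]

#: Canonical case/control expression ratios for a trisomic-vs-diploid design.
CANONICAL_RATIOS: dict[str, float] = {
    "dosage_effect": 1.5,
    "compensated": 1.0,
    "inverse": 2.0 / 3.0,
    "double_inverse": 4.0 / 9.0,
}

#: Classification order: ascending ratio, so exact midpoints resolve to the
#: smaller canonical value.
_CANONICAL_ORDER = ("double_inverse", "inverse", "compensated", "dosage_effect")


@dataclass(frozen=True)
class DosageClass:
    """A dosage-response class: a label and its true case/control ratio.

    Canonical labels carry their fixed ratio; ``custom`` carries any
    positive ratio (used e.g. for knockdown shifts or closure genes).
    """

    label: str
    true_ratio: float

    def __post_init__(self) -> None:
        if self.label in CANONICAL_RATIOS:
            expected = CANONICAL_RATIOS[self.label]
            if not math.isclose(self.true_ratio, expected, rel_tol=1e-12):
                raise ValueError(
                    f"class {self.label!r} has fixed ratio {expected}, got {self.true_ratio}"
                )
        elif self.label != "custom":
            raise ValueError(f"unknown dosage class label {self.label!r}")
        if not self.true_ratio > 0:
            raise ValueError("true_ratio must be positive")

    @classmethod
    def dosage_effect(cls) -> "DosageClass":
        return cls("dosage_effect", CANONICAL_RATIOS["dosage_effect"])

    @classmethod
    def compensated(cls) -> "DosageClass":
        return cls("compensated", CANONICAL_RATIOS["compensated"])

    @classmethod
    def inverse(cls) -> "DosageClass":
        return cls("inverse", CANONICAL_RATIOS["inverse"])

    @classmethod
    def double_inverse(cls) -> "DosageClass":
        return cls("double_inverse", CANONICAL_RATIOS["double_inverse"])

    @classmethod
    def custom(cls, ratio: float) -> "DosageClass":
        return cls("custom", float(ratio))

    @classmethod
    def from_label(cls, label: str) -> "DosageClass":
        if label == "custom":
            raise ValueError("custom class needs an explicit ratio")
        return cls(label, CANONICAL_RATIOS[label])


@dataclass(frozen=True)
class DosageCall:
    """Nearest-canonical assignment for one gene's expression ratio."""

    gene_id: str
    assigned: str  # canonical label or "unclassified"
    ratio: float
    distance_to_canonical: float


@dataclass
class RatioHistogram:
    """Binned frequency distribution of expression ratios.

    Bins are half-open intervals ``[c - w/2, c + w/2)`` centred on integer
    multiples ``c = k*w`` of the bin width, so the canonical ratios 1.0 and
    1.5 (and a knockdown shift such as 1.3) are exact bin centres.
    Ratios at or above ``cap`` are counted in ``n_capped`` and excluded
    from the frequencies, which are normalised over included genes.
    """

    bin_width: float
    cap: float
    centers: np.ndarray
    counts: np.ndarray
    n_included: int
    n_capped: int
    frequencies: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = self.counts.sum()
        self.frequencies = (
            self.counts / total if total > 0 else np.zeros_like(self.counts, dtype=float)
        )

    @property
    def edges(self) -> np.ndarray:
        """Bin edges; edge ``i`` is the left edge of bin ``i`` (closed interval grid)."""
        return np.concatenate([self.centers - self.bin_width / 2, [self.centers[-1] + self.bin_width / 2]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.centers - self.bin_width / 2,
                "bin_hi": self.centers + self.bin_width / 2,
                "frequency": self.frequencies,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def histogram(ratios, bin_width: float = 0.05, cap: float = 3.0) -> RatioHistogram:
    """Bin positive expression ratios into a :class:`RatioHistogram`.

    Parameters
    ----------
    ratios : array-like of positive floats
    bin_width : bin width on the ratio scale (0.05 resolves the canonical peaks)
    cap : ratios >= cap are tallied in ``n_capped`` and left out of the frequencies
    """
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("cannot build a ratio histogram from an empty ratio list")
    if not np.all(r > 0):
        raise ValueError("ratios must all be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    capped = r >= cap
    kept = r[~capped]
    n_bins = int(math.floor(cap / bin_width + 0.5)) + 1
    centers = np.arange(n_bins) * bin_width
    counts = np.zeros(n_bins, dtype=np.int64)
    if kept.size:
        # snap quotients within 5e-10 of an edge upward so decimal edge
        # values (e.g. 1.025) obey the half-open convention despite binary
        # rounding
        idx = np.floor(np.round((kept + bin_width / 2) / bin_width, 9)).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(counts, idx, 1)
    return RatioHistogram(
        bin_width=bin_width,
        cap=cap,
        centers=centers,
        counts=counts,
        n_included=int(kept.size),
        n_capped=int(capped.sum()),
    )


def modal_bin(hist: RatioHistogram) -> float:
    """Centre of the maximum-frequency bin.

    Ties are broken toward the bin centre nearest 1.0 (the no-change ratio),
    then toward the smaller centre.
    """
    if hist.n_included == 0:
        raise ValueError("histogram is empty")
    best = hist.counts.max()
    candidates = hist.centers[hist.counts == best]
    order = np.lexsort((candidates, np.abs(candidates - 1.0)))
    return float(candidates[order[0]])


def classify_gene_response(
    ratio: float, tolerance: float = 0.1, gene_id: str = ""
) -> DosageCall:
    """Assign a ratio to the nearest canonical dosage class.

    A gene is called for the canonical ratio in {4/9, 2/3, 1, 3/2} that
    minimises the absolute distance, provided that distance does not exceed
    ``tolerance``; otherwise it is ``unclassified``.  Exact midpoints between
    two canonicals resolve to the smaller one.
    """
    if not ratio > 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    best_label = "unclassified"
    best_dist = math.inf
    for label in _CANONICAL_ORDER:
        d = abs(ratio - CANONICAL_RATIOS[label])
        if d < best_dist - 1e-12:  # exact midpoints keep the smaller canonical
            best_dist = d
            best_label = label
    if best_dist > tolerance + 1e-12:
        best_label = "unclassified"
    return DosageCall(gene_id=gene_id, assigned=best_label, ratio=float(ratio), distance_to_canonical=best_dist)


def classify_ratio_table(table: pd.DataFrame, tolerance: float = 0.1) -> pd.DataFrame:
    """Vectorised nearest-canonical classification of a ratio table.

    ``table`` needs columns ``gene_id`` and ``ratio``; returns a copy with
    ``assigned`` and ``distance_to_canonical`` columns appended.
    """
    ratios = table["ratio"].to_numpy(dtype=float)
    if not np.all(ratios > 0):
        raise ValueError("ratio table contains non-positive ratios")
    canon = np.array([CANONICAL_RATIOS[l] for l in _CANONICAL_ORDER])
    dist = np.abs(ratios[:, None] - canon[None, :])
    # round away float noise so exact midpoints resolve to the first
    # (smaller) canonical, matching classify_gene_response
    idx = np.argmin(np.round(dist, 12), axis=1)
    mind = dist[np.arange(len(ratios)), idx]
    labels = np.array(_CANONICAL_ORDER, dtype=object)[idx]
    labels[mind > tolerance + 1e-12] = "unclassified"
    out = table.copy()
    out["assigned"] = labels
    out["distance_to_canonical"] = mind
    return out


def chromosome_medians(table: pd.DataFrame) -> pd.DataFrame:
    """Median expression ratio per chromosome, split by biotype.

    Mirrors the per-chromosome boxplot summary: one median per
    (chromosome, biotype) group, with the group size alongside.
    """
    required = {"chrom", "biotype", "ratio"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ratio table lacks columns {sorted(missing)}")
    out = (
        table.groupby(["chrom", "biotype"], observed=True)["ratio"]
        .agg(median_ratio="median", n_genes="size")
        .reset_index()
    )
    return out
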