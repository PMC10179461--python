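"""cis (co-location) and trans (co-expression) lncRNA target prediction.

cis targets are coding genes whose gene-body interval lies within a 10 kb
window either side of an lncRNA on the same chromosome; trans targets are
coding genes whose CPM profile across all samples correlates with the
lncRNA at |r| > 0.95 with p < 0.01 (two-sided t test on n-2 df).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneRecord

__all__ = [
    "TargetPair",
    "gene_gap",
    "cis_targets",
    "pearson_with_p",
    "trans_targets",
    "validate_pairs",
    "write_pairs",
    "read_pairs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetPair:
    """One lncRNA -> gene link with its mode and evidence.

    ``distance`` (nt, 0 if overlapping) is set for cis pairs; ``r`` and
    ``p`` for trans pairs.
    """

    lncrna_id: str
    target_id: str
    mode: str  # "cis" | "trans"
    distance: int | None = None
    r: float | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValueError(f"mode must be cis or trans, got {self.mode!r}")
        if self.lncrna_id == self.target_id:
            raise ValueError(f"self-pair {self.lncrna_id!r}")


def gene_gap(a: GeneRecord, b: GeneRecord) -> int:
    """Gap in nucleotides between two closed gene intervals (0 if they overlap).

    Symmetric: gap(a, b) == gap(b, a).  Both genes must share a chromosome.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"{a.gene_id} and {b.gene_id} are on different chromosomes")
    return max(0, max(a.start, b.start) - min(a.end, b.end) - 1)


def cis_targets(
    lncrnas: Sequence[GeneRecord],
    coding_genes: Sequence[GeneRecord],
    window: int = 10_000,
) -> list[TargetPair]:
    """All (lncRNA, coding gene) pairs within ``window`` nt on the same chromosome.

    The gap is measured between gene bodies in both directions (upstream
    and downstream); overlapping genes pair at distance 0.  The window
    boundary is inclusive.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in coding_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs: list[TargetPair] = []
    for lnc in lncrnas:
        for g in by_chrom.get(lnc.chrom, ()):
            if g.gene_id == lnc.gene_id:
                continue
            gap = gene_gap(lnc, g)
            if gap <= window:
                pairs.append(
                    TargetPair(lncrna_id=lnc.gene_id, target_id=g.gene_id, mode="cis", distance=gap)
                )
    return pairs


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value.

    p comes from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom; |r|
    is capped at 1 numerically, with p = 0 at the cap.  Constant input
    vectors raise ``ValueError`` (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def trans_targets(
    expr_lnc: pd.DataFrame,
    expr_mrna: pd.DataFrame,
    r_min: float = 0.95,
    alpha: float = 0.01,
) -> list[TargetPair]:
    """Co-expression screen: all lncRNA x coding pairs across shared samples.

    Both matrices must be expression values (CPM) over the same sample
    columns, both groups pooled.  Pairs are retained when |r| strictly
    exceeds ``r_min`` and p is strictly below ``alpha``.  Constant rows
    are skipped with a log entry.
    """
    if list(expr_lnc.columns) != list(expr_mrna.columns):
        raise ValueError("expression matrices must share identical sample columns")
    n = expr_lnc.shape[1]
    if n < 3:
        raise ValueError("need at least 3 shared samples for a correlation screen")
    L = expr_lnc.to_numpy(dtype=float)
    M = expr_mrna.to_numpy(dtype=float)
    l_sd = L.std(axis=1)
    m_sd = M.std(axis=1)
    n_const = int((l_sd == 0).sum() + (m_sd == 0).sum())
    if n_const:
        logger.info("trans_targets: skipping %d constant expression rows", n_const)
    Lz = (L - L.mean(axis=1, keepdims=True)) / np.where(l_sd == 0, np.inf, l_sd)[:, None]
    Mz = (M - M.mean(axis=1, keepdims=True)) / np.where(m_sd == 0, np.inf, m_sd)[:, None]
    R = Lz @ Mz.T / n
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = np.abs(R) * np.sqrt((n - 2) / np.maximum(1.0 - R * R, 1e-300))
    P = 2.0 * stats.t.sf(t, df=n - 2)
    P[np.abs(R) >= 1.0] = 0.0
    # round away float noise so a pair at exactly |r| = r_min is rejected
    hits = np.argwhere((np.round(np.abs(R), 12) > r_min) & (P < alpha))
    lnc_ids = list(expr_lnc.index)
    mrna_ids = list(expr_mrna.index)
    pairs = []
    for i, j in hits:
        if lnc_ids[i] == mrna_ids[j]:
            continue
        pairs.append(
            TargetPair(
                lncrna_id=lnc_ids[i],
                target_id=mrna_ids[j],
                mode="trans",
                r=float(R[i, j]),
                p=float(P[i, j]),
            )
        )
    return pairs


def validate_pairs(pairs: Iterable[TargetPair], window: int = 10_000, r_min: float = 0.95, alpha: float = 0.01) -> None:
    """Re-check every emitted pair against its mode's invariant."""
    for p in pairs:
        if p.mode == "cis":
            if p.distance is None or p.distance > window:
                raise ValueError(f"cis pair {p.lncrna_id}-{p.target_id} violates the {window} nt window")
        else:
            if p.r is None or p.p is None or abs(p.r) <= r_min or p.p >= alpha:
                raise ValueError(f"trans pair {p.lncrna_id}-{p.target_id} violates |r|>{r_min}, p<{alpha}")


def write_pairs(pairs: Sequence[TargetPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("lncrna_id\ttarget_id\tmode\tdistance\tr\tp\n")
        for p in pairs:
            dist = "" if p.distance is None else str(p.distance)
            r = "" if p.r is None else f"{p.r:.6g}"
            pv = "" if p.p is None else f"{p.p:.6g}"
            fh.write(f"{p.lncrna_id}\t{p.target_id}\t{p.mode}\t{dist}\t{r}\t{pv}\n")


def read_pairs(path) -> list[TargetPair]:
    df = pd.read_csv(path, sep="\t", dtype={"lncrna_id": str, "target_id": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TargetPair(
                lncrna_id=row.lncrna_id,
                target_id=row.target_id,
                mode=row.mode,
                distance=None if pd.isna(row.distance) else int(row.distance),
                r=None if pd.isna(row.r) else float(row.r),
                p=None if pd.isna(row.p) else float(row.p),
            )
        )
    return out
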