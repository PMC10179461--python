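"""Over-representation analysis and simplified motif-enrichment screening.

ORA is an upper-tail hypergeometric test of a study gene set against
user-supplied term annotations (GO-style or pathway), BH-corrected within
each category.  The motif engine is a deliberately simplified
ranking-recovery screen: a motif's AUC is the area under the cumulative
recovery curve of its gene set within the top fraction of a ranked gene
list, and motifs are selected at a normalised enrichment score (z-score
across motifs) strictly above 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

__all__ = [
    "MotifResult",
    "hypergeom_ora",
    "motif_auc",
    "motif_nes",
    "filter_expressed_motifs",
    "read_term_map",
]

CATEGORIES = ("BP", "MF", "CC", "pathway")


@dataclass(frozen=True)
class MotifResult:
    motif_id: str
    auc: float
    nes: float
    selected: bool


def hypergeom_ora(
    study_genes: Sequence[str],
    term_map: Mapping[str, set],
    universe: Sequence[str],
    term_meta: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a study set against terms.

    ``term_map`` maps term id -> annotated gene set; ``term_meta``
    optionally maps term id -> (name, category).  p is the upper tail
    P(X >= k); BH correction is applied within each category.  Rows are
    sorted by adjusted p.
    """
    universe_set = set(universe)
    study = set(study_genes)
    stray = sorted(study - universe_set)
    if stray:
        raise ValueError(f"study genes absent from the universe: {stray[:10]}")
    N, n = len(universe_set), len(study)
    rows = []
    for term, genes in term_map.items():
        genes = set(genes) & universe_set
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        name, category = (term_meta or {}).get(term, (term, "BP"))
        rows.append(
            {"term_id": term, "term_name": name, "category": category, "k": k, "K": K, "n": n, "N": N, "p": p}
        )
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "category", "k", "K", "n", "N", "p"])
    if df.empty:
        df["padj"] = []
        return df
    df["padj"] = np.nan
    for _, idx in df.groupby("category").groups.items():
        df.loc[idx, "padj"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    return df.sort_values(["padj", "p", "term_id"], kind="mergesort").reset_index(drop=True)


def motif_auc(ranking: Sequence[str], gene_set: Sequence[str], top_fraction: float = 0.05) -> float:
    """Area under the recovery curve of ``gene_set`` in the top of ``ranking``.

    The curve tracks the fraction of the gene set recovered within the
    first i ranks, i = 1..ceil(top_fraction * len(ranking)); the AUC is its
    mean, which lies in [0, 1]: 0 when the set is entirely outside the top
    block, approaching 1 when the whole set leads the ranking.
    """
    genes = set(gene_set)
    if not genes:
        raise ValueError("gene_set is empty: AUC undefined")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    missing = genes - set(ranking)
    if missing:
        raise ValueError(f"gene_set members absent from the ranking: {sorted(missing)[:5]}")
    top_n = math.ceil(top_fraction * len(ranking))
    hits = np.fromiter((1 if g in genes else 0 for g in ranking[:top_n]), dtype=float, count=top_n)
    recovery = np.cumsum(hits) / len(genes)
    return float(recovery.mean())


def motif_nes(aucs: Mapping[str, float], nes_min: float = 3.0) -> list[MotifResult]:
    """z-standardise motif AUCs; a motif is selected when NES strictly exceeds 3.

    Needs at least 3 motifs for the standard deviation to be meaningful;
    with zero spread every NES is 0 and nothing is selected.
    """
    if len(aucs) < 3:
        raise ValueError("need at least 3 motifs to standardise enrichment scores")
    ids = sorted(aucs)
    values = np.array([aucs[m] for m in ids], dtype=float)
    sd = values.std(ddof=1)
    if sd <= 1e-12 * max(1.0, np.abs(values).max()):  # zero spread up to rounding
        nes = np.zeros_like(values)
    else:
        nes = (values - values.mean()) / sd
    return [
        MotifResult(motif_id=m, auc=float(v), nes=float(z), selected=bool(z > nes_min))
        for m, v, z in zip(ids, values, nes)
    ]


def filter_expressed_motifs(
    results: Sequence[MotifResult],
    motif_to_tf: Mapping[str, str],
    de_status: Mapping[str, str],
) -> list[MotifResult]:
    """Keep selected motifs whose annotated factor is itself differentially expressed."""
    return [
        r
        for r in results
        if r.selected and de_status.get(motif_to_tf.get(r.motif_id, ""), "ns") in ("up", "down")
    ]


def read_term_map(path):
    """Two-column TSV (term, gene) -> dict term -> set of genes."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], dtype=str)
    out: dict[str, set] = {}
    for term, gene in zip(df["term"], df["gene"]):
        out.setdefault(term, set()).add(gene)
    return out
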