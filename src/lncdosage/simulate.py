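"""Synthetic metafemale-vs-diploid RNA-seq datasets with planted ground truth.

The generator emulates the statistical structure of a trisomic-X
(metafemale) fly transcriptome measured against a diploid female control:

* a gene annotation over chromosome arms 2L/2R/3L/3R, chromosome 4, the X
  and the mitochondrial genome, with a minority of lncRNA genes;
* per-gene dosage-response classes with true case/control expression
  ratios 1.5 (dosage effect), 1.0 (compensated), 2/3 (inverse) and 4/9
  (double inverse), mixed per chromosome;
* negative-binomial counts (var = mu + alpha*mu^2) for two groups of
  replicates at a target library size;
* planted cis partners (an lncRNA placed within 10 kb of a coding gene)
  and planted trans partners (a shared per-sample latent factor that
  drives the pair's cross-sample correlation above 0.95);
* a knockdown scenario in which most genes shift by a global factor
  (e.g. 1.3), emulating the genome-wide upregulation seen when an
  inverse-dosage modulator is depleted.

Compositional closure.  CPM ratios only measure *relative* abundance, so
the abundance-weighted mean of measured ratios is identically 1 in any
matrix.  Real transcriptomes absorb this constraint in a handful of very
highly expressed genes; the generator reproduces that with a small
"closure block": ``n_closure_genes`` genes (on the reserved contig
``closure``) carrying ``closure_mass`` of the library at a solved ratio
such that the abundance-weighted mean ratio of the whole matrix is 1.
With the block in place, every planted class ratio equals its measured
CPM ratio in expectation — including scenarios, such as a uniform 1.3
shift or an all-dosage-effect mitochondrial set, that would otherwise be
cancelled by normalisation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneRecord, write_gtf
from .expression import CountMatrix
from .ratios import CANONICAL_RATIOS, DosageClass
from .targets import TargetPair

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "generate_annotation",
    "assign_dosage_classes",
    "simulate_counts",
    "plant_trans_structure",
    "simulate_dataset",
    "knockdown_config",
    "make_positional_lncrnas",
]

CLOSURE_CHROM = "closure"

#: Default chromosome sizes (gene counts) for a compact fly-like genome.
DEFAULT_GENES = {"2L": 260, "2R": 260, "3L": 260, "3R": 260, "4": 60, "X": 260, "mito": 40}

_AUTOSOME_MIX = {"inverse": 0.55, "compensated": 0.40, "double_inverse": 0.05}

#: Default per-chromosome dosage-class mixtures: X mostly compensated with a
#: mild positive shoulder, autosomes dominated by the inverse effect, the
#: mitochondrial genome showing a dosage effect with a double-inverse shoulder.
DEFAULT_MIXTURE = {
    "2L": _AUTOSOME_MIX,
    "2R": _AUTOSOME_MIX,
    "3L": _AUTOSOME_MIX,
    "3R": _AUTOSOME_MIX,
    "4": {"compensated": 0.55, "inverse": 0.35, "dosage_effect": 0.10},
    "X": {"compensated": 0.70, "dosage_effect": 0.15, "inverse": 0.15},
    "mito": {"dosage_effect": 0.70, "double_inverse": 0.30},
}


@dataclass
class SimulationConfig:
    genes_per_chromosome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENES))
    lncrna_fraction: float = 0.15
    class_mixture: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in DEFAULT_MIXTURE.items()}
    )
    replicates_per_group: int = 3
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.05
    library_size: int = 1_000_000
    n_cis_planted: int = 25
    n_trans_planted: int = 25
    trans_latent_sd: float = 2.0
    trans_mass_budget: float = 0.02
    global_shift: float = 1.0
    closure_mass: float = 0.30
    n_closure_genes: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.genes_per_chromosome.values()):
            raise ValueError("gene counts must be non-negative")
        if not 0 <= self.lncrna_fraction <= 1:
            raise ValueError("lncrna_fraction must be in [0, 1]")
        if self.replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.global_shift <= 0:
            raise ValueError("global_shift must be positive")
        if not 0 <= self.closure_mass < 1:
            raise ValueError("closure_mass must be in [0, 1)")
        for chrom, mix in self.class_mixture.items():
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"class mixture for {chrom} sums to {total}, expected 1")
            unknown = set(mix) - set(CANONICAL_RATIOS)
            if unknown:
                raise ValueError(f"unknown class labels in mixture for {chrom}: {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedDataset:
    """A simulated experiment: annotation, counts and the planted truth."""

    annotation: list[GeneRecord]
    counts: CountMatrix
    truth_class: dict[str, DosageClass]
    truth_targets: list[TargetPair]
    closure_gene_ids: list[str] = field(default_factory=list)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gtf(self.annotation, out / "annotation.gtf")
        self.counts.to_tsv(out / "counts.tsv", out / "design.tsv")
        with open(out / "truth_classes.tsv", "w") as fh:
            fh.write("gene_id\tclass\ttrue_ratio\n")
            for gid, cls in self.truth_class.items():
                fh.write(f"{gid}\t{cls.label}\t{cls.true_ratio:.6g}\n")
        with open(out / "truth_targets.tsv", "w") as fh:
            fh.write("lncrna_id\ttarget_id\tmode\n")
            for pair in self.truth_targets:
                fh.write(f"{pair.lncrna_id}\t{pair.target_id}\t{pair.mode}\n")


def _generate_annotation(config: SimulationConfig):
    """Lay out genes chromosome by chromosome; returns (records, planted cis pairs)."""
    total = sum(config.genes_per_chromosome.values())
    if total == 0:
        raise ValueError("configuration requests zero genes; cannot build an annotation")
    rng = np.random.default_rng([config.seed, 11])
    chroms = sorted(config.genes_per_chromosome)
    eligible = [c for c in chroms if c != "mito" and config.genes_per_chromosome[c] >= 2]
    # round-robin cis-pair quota over eligible chromosomes
    quota = {c: 0 for c in chroms}
    for i in range(config.n_cis_planted if eligible else 0):
        quota[eligible[i % len(eligible)]] += 1

    records: list[GeneRecord] = []
    cis_pairs: list[TargetPair] = []
    for chrom in chroms:
        n = config.genes_per_chromosome[chrom]
        if n == 0:
            continue
        if chrom == "mito":
            biotypes = np.array(["mito"] * n, dtype=object)
        else:
            is_lnc = rng.random(n) < config.lncrna_fraction
            biotypes = np.where(is_lnc, "lncRNA", "coding").astype(object)
        lengths = np.maximum(rng.lognormal(math.log(2000), 0.6, n).astype(int), 200)
        gaps = np.maximum(rng.lognormal(math.log(3000), 1.0, n).astype(int), 1)
        # planted cis pairs: force (coding, lncRNA) neighbours with a gap <= 8 kb
        planted_idx: list[int] = []
        candidates = list(range(1, n))
        rng.shuffle(candidates)
        for i in candidates:
            if len(planted_idx) >= quota[chrom]:
                break
            if i - 1 in planted_idx or i in planted_idx:
                continue
            planted_idx.append(i)
            biotypes[i] = "lncRNA"
            biotypes[i - 1] = "coding"
            gaps[i] = int(rng.integers(100, 8001))
        pos = 1
        chrom_records: list[GeneRecord] = []
        for i in range(n):
            start = pos + int(gaps[i])
            end = start + int(lengths[i]) - 1
            prefix = {"coding": "g", "lncRNA": "lnc", "mito": "mt"}[biotypes[i]]
            strand = "+" if rng.random() < 0.5 else "-"
            chrom_records.append(
                GeneRecord(
                    gene_id=f"{prefix}_{chrom}_{i:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype=str(biotypes[i]),
                )
            )
            pos = end + 1
        for i in sorted(planted_idx):
            lnc, coding = chrom_records[i], chrom_records[i - 1]
            gap = max(0, lnc.start - coding.end - 1)
            cis_pairs.append(
                TargetPair(lncrna_id=lnc.gene_id, target_id=coding.gene_id, mode="cis", distance=gap)
            )
        records.extend(chrom_records)
    return records, cis_pairs


def generate_annotation(config: SimulationConfig) -> list[GeneRecord]:
    """Generate a non-overlapping gene annotation per the configuration.

    Genes are laid out sequentially per chromosome with log-normal lengths
    and gaps; ``n_cis_planted`` lncRNAs are placed so that the gap to a
    coding neighbour is at most 8 kb (inside the 10 kb cis window).
    Deterministic given ``config.seed``.
    """
    return _generate_annotation(config)[0]


def assign_dosage_classes(
    annotation: Sequence[GeneRecord], config: SimulationConfig
) -> dict[str, DosageClass]:
    """Draw a dosage class for every gene from its chromosome's mixture."""
    rng = np.random.default_rng([config.seed, 12])
    out: dict[str, DosageClass] = {}
    for rec in annotation:
        mix = config.class_mixture.get(rec.chrom)
        if mix is None:
            raise ValueError(f"no class mixture configured for chromosome {rec.chrom!r}")
        labels = sorted(mix)
        probs = np.array([mix[l] for l in labels])
        label = labels[rng.choice(len(labels), p=probs / probs.sum())]
        out[rec.gene_id] = DosageClass.from_label(label)
    return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion) -> np.ndarray:
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = dispersion < 1e-8
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / dispersion[nb]
        out[nb] = rng.negative_binomial(size, size / (size + mu[nb]))
    return out


def simulate_counts(
    annotation: Sequence[GeneRecord],
    truth_class: Mapping[str, DosageClass],
    config: SimulationConfig,
    baseline: np.ndarray | None = None,
    dispersion: np.ndarray | None = None,
) -> CountMatrix:
    """Draw NB counts for two groups under the planted dosage classes.

    Control means are proportional to the (log-normal) baseline and scaled
    so each control column sums to ``library_size`` before noise; case
    means are control means times ``true_ratio * global_shift``.  The
    variance model is var = mu + dispersion * mu**2.
    """
    missing = [g.gene_id for g in annotation if g.gene_id not in truth_class]
    if missing:
        raise ValueError(f"genes without a truth class: {missing[:5]}")
    rng = np.random.default_rng([config.seed, 13])
    n = len(annotation)
    if baseline is None:
        baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    baseline = np.asarray(baseline, dtype=float)
    disp = config.nb_dispersion if dispersion is None else np.asarray(dispersion, dtype=float)
    ratios = np.array([truth_class[g.gene_id].true_ratio for g in annotation])
    mu_control = baseline / baseline.sum() * config.library_size
    mu_case = mu_control * ratios * config.global_shift
    reps = config.replicates_per_group
    cols, names, groups = [], [], {}
    for j in range(reps):
        cols.append(_nb_draw(rng, mu_control, disp))
        names.append(f"control_{j + 1}")
        groups[names[-1]] = "control"
    for j in range(reps):
        cols.append(_nb_draw(rng, mu_case, disp))
        names.append(f"case_{j + 1}")
        groups[names[-1]] = "case"
    counts = pd.DataFrame(
        np.column_stack(cols).astype(np.int64),
        index=pd.Index([g.gene_id for g in annotation], name="gene_id"),
        columns=names,
    )
    return CountMatrix(counts=counts, groups=groups)


def plant_trans_structure(
    counts: CountMatrix, truth_targets: Sequence[TargetPair], config: SimulationConfig
) -> CountMatrix:
    """Apply a shared per-sample latent multiplier to each planted trans pair.

    Both members of a pair are multiplied by the same exp(N(0, sd)) factor
    per sample, which drives their cross-sample Pearson correlation above
    0.95 once the latent spread dominates the counting noise.  With
    ``trans_latent_sd == 0`` the counts are returned unchanged.
    """
    if config.trans_latent_sd < 0:
        raise ValueError("trans_latent_sd must be non-negative")
    trans = [p for p in truth_targets if p.mode == "trans"]
    for pair in trans:
        for gid in (pair.lncrna_id, pair.target_id):
            if gid not in counts.counts.index:
                raise LookupError(f"planted trans pair references unknown gene {gid!r}")
    if config.trans_latent_sd == 0 or not trans:
        return counts
    rng = np.random.default_rng([config.seed, 14])
    df = counts.counts.copy()
    n_samples = df.shape[1]
    sd = config.trans_latent_sd
    for pair in trans:
        # mean-1 multiplier so planted pairs do not bias library sizes
        f = np.exp(rng.normal(-0.5 * sd * sd, sd, n_samples))
        for gid in (pair.lncrna_id, pair.target_id):
            df.loc[gid] = np.rint(df.loc[gid].to_numpy() * f).astype(np.int64)
    return CountMatrix(counts=df, groups=dict(counts.groups))


def _closure_block(
    baseline_model: np.ndarray,
    ratios_model: np.ndarray,
    config: SimulationConfig,
):
    """Closure genes: baselines and the solved ratio making the matrix balance."""
    m = config.closure_mass
    if m == 0 or config.n_closure_genes == 0:
        return [], np.array([]), None
    w = baseline_model / baseline_model.sum()
    W = float((w * ratios_model).sum()) * config.global_shift
    r_closure = (1.0 - (1.0 - m) * W) / (m * config.global_shift)
    if r_closure <= 0:
        raise ValueError(
            f"closure ratio is non-positive (weighted mean ratio {W:.3f}); "
            "increase closure_mass to absorb the compositional shift"
        )
    total = baseline_model.sum() * m / (1.0 - m)
    per_gene = np.full(config.n_closure_genes, total / config.n_closure_genes)
    records = []
    pos = 1
    for i in range(config.n_closure_genes):
        records.append(
            GeneRecord(
                gene_id=f"hk_{i:03d}",
                chrom=CLOSURE_CHROM,
                start=pos,
                end=pos + 1999,
                strand="+",
                biotype="coding",
            )
        )
        pos += 3000
    return records, per_gene, DosageClass.custom(r_closure)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: annotation, classes, counts, planted targets.

    Identical configurations (including the seed) produce identical
    datasets.
    """
    annotation, cis_pairs = _generate_annotation(config)
    truth_class = assign_dosage_classes(annotation, config)

    rng = np.random.default_rng([config.seed, 15])
    baseline_model = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, len(annotation))

    # planted trans pairs: disjoint lncRNA-coding pairs, cross-chromosome preferred
    lncs = [g for g in annotation if g.biotype == "lncRNA"]
    codings = [g for g in annotation if g.biotype == "coding"]
    rng.shuffle(lncs)
    rng.shuffle(codings)
    cis_lnc_ids = {p.lncrna_id for p in cis_pairs}
    trans_pairs: list[TargetPair] = []
    used: set[str] = set()
    lnc_iter = [g for g in lncs if g.gene_id not in cis_lnc_ids] + [
        g for g in lncs if g.gene_id in cis_lnc_ids
    ]
    for lnc in lnc_iter:
        if len(trans_pairs) >= config.n_trans_planted:
            break
        partner = next(
            (c for c in codings if c.gene_id not in used and c.chrom != lnc.chrom), None
        ) or next((c for c in codings if c.gene_id not in used), None)
        if partner is None:
            break
        used.add(partner.gene_id)
        used.add(lnc.gene_id)
        # a planted pair is co-regulated: the partner inherits the lncRNA's
        # dosage class so the group effect does not dilute their correlation
        truth_class[partner.gene_id] = truth_class[lnc.gene_id]
        trans_pairs.append(TargetPair(lncrna_id=lnc.gene_id, target_id=partner.gene_id, mode="trans"))

    # keep planted trans genes low-abundance so their latent multipliers
    # cannot move per-sample library sizes
    if trans_pairs and config.trans_mass_budget < 1:
        gene_index = {g.gene_id: i for i, g in enumerate(annotation)}
        member_idx = [gene_index[g] for p in trans_pairs for g in (p.lncrna_id, p.target_id)]
        budget = config.trans_mass_budget * baseline_model.sum()
        baseline_model[member_idx] = budget / len(member_idx)

    ratios_model = np.array([truth_class[g.gene_id].true_ratio for g in annotation])
    closure_records, closure_baseline, closure_class = _closure_block(
        baseline_model, ratios_model, config
    )
    full_annotation = list(annotation) + list(closure_records)
    for rec in closure_records:
        truth_class[rec.gene_id] = closure_class
    baseline = np.concatenate([baseline_model, closure_baseline])
    # each closure gene stands for the pooled mass of many real genes, so its
    # relative biological noise is far below a single gene's dispersion
    dispersion = np.concatenate(
        [
            np.full(len(annotation), config.nb_dispersion),
            np.full(len(closure_records), config.nb_dispersion / 100.0),
        ]
    )

    counts = simulate_counts(
        full_annotation, truth_class, config, baseline=baseline, dispersion=dispersion
    )
    counts = plant_trans_structure(counts, trans_pairs, config)
    return SimulatedDataset(
        annotation=full_annotation,
        counts=counts,
        truth_class=truth_class,
        truth_targets=cis_pairs + trans_pairs,
        closure_gene_ids=[r.gene_id for r in closure_records],
    )


def knockdown_config(
    n_genes: int = 2000,
    shift: float = 1.3,
    seed: int = 0,
    nb_dispersion: float = 0.05,
    closure_mass: float = 0.40,
    **overrides,
) -> SimulationConfig:
    """Configuration for a modulator-knockdown scenario.

    All genes are dosage-compensated relative to their own control but the
    case group carries a uniform global shift (default 1.3); the closure
    block absorbs the compositional displacement so the shift is visible
    in measured CPM ratios, as it is in real knockdown profiles.
    """
    half = n_genes // 2
    return SimulationConfig(
        genes_per_chromosome={"2L": half, "2R": n_genes - half},
        class_mixture={
            "2L": {"compensated": 1.0},
            "2R": {"compensated": 1.0},
        },
        lncrna_fraction=0.0,
        n_cis_planted=0,
        n_trans_planted=0,
        global_shift=shift,
        nb_dispersion=nb_dispersion,
        closure_mass=closure_mass,
        seed=seed,
        **overrides,
    )


def make_positional_lncrnas(
    coding: Sequence[GeneRecord], class_counts: Mapping[str, int], seed: int = 0
) -> list[GeneRecord]:
    """Construct lncRNAs with prescribed positional classes around coding genes.

    Useful for testing position classification round-trips: ``class_counts``
    maps each of lincRNA/intronic/antisense/sense to the number of lncRNAs
    to plant with that class.  Needs enough coding genes of length >= 400.
    """
    rng = np.random.default_rng(seed)
    hosts = [g for g in coding if g.biotype == "coding" and g.length >= 400]
    need = sum(class_counts.get(k, 0) for k in ("intronic", "antisense", "sense"))
    if len(hosts) < need:
        raise ValueError(f"need {need} coding hosts of length >= 400, have {len(hosts)}")
    rng.shuffle(hosts)
    out: list[GeneRecord] = []
    it = iter(hosts)
    other = {"+": "-", "-": "+"}
    k = 0
    for _ in range(class_counts.get("sense", 0)):
        h = next(it)
        out.append(GeneRecord(f"lnc_sense_{k}", h.chrom, h.start + 10, h.start + 209, h.strand, "lncRNA"))
        k += 1
    for _ in range(class_counts.get("antisense", 0)):
        h = next(it)
        # straddles the host start: overlap without containment
        start = max(1, h.start - 100)
        out.append(GeneRecord(f"lnc_anti_{k}", h.chrom, start, h.start + 99, other[h.strand], "lncRNA"))
        k += 1
    for _ in range(class_counts.get("intronic", 0)):
        h = next(it)
        out.append(
            GeneRecord(f"lnc_intr_{k}", h.chrom, h.start + 50, h.start + 249, other[h.strand], "lncRNA")
        )
        k += 1
    far = 10 ** 8
    chrom0 = coding[0].chrom if coding else "2L"
    for i in range(class_counts.get("lincRNA", 0)):
        out.append(GeneRecord(f"lnc_linc_{k}", chrom0, far + i * 5000, far + i * 5000 + 300, "+", "lncRNA"))
        k += 1
    return out
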