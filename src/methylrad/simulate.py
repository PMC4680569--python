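"""Synthetic genomes, methylomes and tag read sets with known truth.

The generative model inverts the M-index definition so that quantification
is consistent by construction: a site with symmetric methylation level
M* > 0 receives a read count drawn from Poisson(depth_max ** M*), so that
log(E depth) / log(depth_max) = M*.  Unmethylated sites (M* = 0), including
every site on control contigs, emit reads only through a small false-positive
background: with probability ``fp_site_rate`` a site emits
1 + Poisson(fp_mean_extra) reads.  The defaults reproduce the false-positive
magnitudes observed on an unmethylated chloroplast control (~3% of possible
sites touched by >= 1 read, ~0.1% by >= 5).

Reads are the site's tag sequence (uniform strand) with independent
substitution errors, filled to the 36-cycle read length with adaptor
sequence, at constant Q30.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enzyme import (FSPEI, EnzymeSpec, GenomeSequence, SiteCatalog,
                     enumerate_genome, reverse_complement, rtr_subset)
from .qc import RawRead

__all__ = ["SimConfig", "MethylomeTruth", "simulate_genome", "draw_mixture",
           "assign_methylation", "simulate_counts", "simulate_reads",
           "simulate_rtr", "DEFAULT_M_DISTRIBUTION"]

ADAPTOR = "AGATCGGAAGAGC"   # 3' adaptor filling the read to 36 nt
READ_LEN = 36

# Mixture over [0, 1] for per-site symmetric methylation levels:
# (weight, low, high); low == high is a point mass.  Shaped like a plant
# methylome: a fifth of sites essentially unmethylated, a broad methylated
# body, and a heavily methylated (repeat-like) tail.
DEFAULT_M_DISTRIBUTION: tuple[tuple[float, float, float], ...] = (
    (0.10, 0.00, 0.00),
    (0.10, 0.01, 0.20),
    (0.65, 0.20, 0.90),
    (0.15, 0.90, 1.00),
)


@dataclass
class SimConfig:
    genome_length: int = 100_000
    contig_count: int = 1
    control_length: int = 20_000
    gc: float = 0.36
    repeat_copies: int = 0
    repeat_unit: str | None = None
    m_distribution: tuple[tuple[float, float, float], ...] = DEFAULT_M_DISTRIBUTION
    depth_max: float = 256.0
    error_rate: float = 0.001
    fp_site_rate: float = 0.03       # probability an unmethylated site emits reads
    fp_mean_extra: float = 1.2       # emitted count = 1 + Poisson(fp_mean_extra)
    rtr_patterns: tuple[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc", "error_rate", "fp_site_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class MethylomeTruth:
    """Per-site symmetric methylation levels; control sites fixed at 0."""

    levels: pd.Series            # site_id -> M* in [0, 1]

    def __post_init__(self) -> None:
        if ((self.levels < 0) | (self.levels > 1)).any():
            raise ValueError("methylation levels must lie in [0, 1]")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def simulate_genome(config: SimConfig,
                    enzyme: EnzymeSpec = FSPEI) -> tuple[list[GenomeSequence], SiteCatalog]:
    """Random genome at the configured GC, optional planted repeats, plus an
    unmethylated control contig; catalog built by double-cut enumeration."""
    rng = np.random.default_rng(config.seed)
    contigs: list[GenomeSequence] = []
    per_len = config.genome_length // max(1, config.contig_count)
    for i in range(config.contig_count):
        seq = _random_seq(rng, per_len, config.gc)
        if i == 0 and config.repeat_copies > 0:
            # 44 nt with one CCGG centred so the full 32 nt tag span lies
            # inside the unit: every copy then shares an identical tag
            unit = config.repeat_unit or (
                "TACGATTACAGTCCATTGAA" + "CCGG" + "ATTGCATAACGTTAGATTGC")
            seq = list(seq)
            span = len(unit) + 40
            for c in range(config.repeat_copies):
                start = 40 + c * span
                if start + len(unit) + 40 > len(seq):
                    break
                seq[start : start + len(unit)] = unit
            seq = "".join(seq)
        contigs.append(GenomeSequence(f"chr{i + 1}", seq))
    if config.control_length > 0:
        contigs.append(GenomeSequence(
            "control", _random_seq(rng, config.control_length, config.gc),
            is_control=True))
    catalog = enumerate_genome(contigs, enzyme, genome_id="sim")
    return contigs, catalog


def draw_mixture(n: int, distribution, rng: np.random.Generator) -> np.ndarray:
    """Draw n methylation levels from a (weight, low, high) uniform mixture."""
    weights = np.array([w for w, _, _ in distribution], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("mixture weights must sum to a positive value")
    weights = weights / weights.sum()
    comps = rng.choice(len(distribution), size=n, p=weights)
    u = rng.random(n)
    levels = np.empty(n)
    for i, c in enumerate(comps):
        _, lo, hi = distribution[c]
        levels[i] = lo + u[i] * (hi - lo)
    return levels


def assign_methylation(catalog: SiteCatalog,
                       distribution=DEFAULT_M_DISTRIBUTION,
                       seed: int | np.random.Generator = 0) -> MethylomeTruth:
    """Independent mixture draws per non-control site; control sites 0."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    site_ids = [s.site_id for s in catalog]
    out = pd.Series(draw_mixture(len(site_ids), distribution, rng),
                    index=site_ids)
    for s in catalog:
        if s.is_control:
            out[s.site_id] = 0.0
    return MethylomeTruth(levels=out)


def simulate_counts(truth: MethylomeTruth, config: SimConfig,
                    seed: int | np.random.Generator | None = None) -> pd.Series:
    """Draw per-site read counts from the inverse M-index depth model."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed if seed is None else seed))
    m = truth.levels.to_numpy()
    counts = np.zeros(len(m), dtype=np.int64)
    meth = m > 0
    counts[meth] = rng.poisson(config.depth_max ** m[meth])
    unmeth = ~meth
    emits = rng.random(unmeth.sum()) < config.fp_site_rate
    fp = np.zeros(int(unmeth.sum()), dtype=np.int64)
    fp[emits] = 1 + rng.poisson(config.fp_mean_extra, size=int(emits.sum()))
    counts[unmeth] = fp
    return pd.Series(counts, index=truth.levels.index)


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.where(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        arr[i] = "ACGT"[(("ACGT".index(arr[i]) + int(rng.integers(1, 4))) % 4)]
    return "".join(arr)


def simulate_reads(truth: MethylomeTruth, catalog: SiteCatalog,
                   config: SimConfig,
                   seed: int | np.random.Generator | None = None
                   ) -> tuple[list[RawRead], pd.Series]:
    """Emit 36-nt reads per site and the exact truth count table.

    Emitted read counts per site equal the returned table exactly; reads are
    tag or reverse-complement tag (uniform), with substitution errors, the
    3' adaptor fill, and constant Q30 qualities.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed if seed is None else seed))
    counts = simulate_counts(truth, config, seed=rng)
    reads: list[RawRead] = []
    q30 = (30,) * READ_LEN
    for site_id, n in counts.items():
        if n == 0:
            continue
        tag = catalog[site_id].tag_seq
        for i in range(int(n)):
            seq = tag if rng.random() < 0.5 else reverse_complement(tag)
            seq = _mutate(rng, seq, config.error_rate)
            seq = (seq + ADAPTOR * 3)[:READ_LEN]
            reads.append(RawRead(f"{site_id}|{i}", seq, q30))
    return reads, counts


def simulate_rtr(reads: list[RawRead], catalog: SiteCatalog,
                 patterns: tuple[str, str],
                 seed: int | np.random.Generator = 0,
                 fixed_budget: bool = False) -> tuple[list[RawRead], SiteCatalog]:
    """Keep reads whose source site is ligatable by the selective adaptors.

    Reads carry their source site id (simulator bookkeeping).  With
    ``fixed_budget``, retained reads are resampled with replacement back to
    the original read total, emulating a fixed sequencing budget that
    concentrates depth on the retained sites.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    retained_catalog = rtr_subset(catalog, *patterns)
    kept = [r for r in reads if r.id.rsplit("|", 1)[0] in retained_catalog]
    if fixed_budget and kept:
        idx = rng.integers(0, len(kept), size=len(reads))
        kept = [RawRead(f"{kept[i].id}|b{j}", kept[i].seq, kept[i].quals)
                for j, i in enumerate(idx)]
    return kept, retained_catalog
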