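"""Mrr-like enzyme definitions and in-silico restriction-site enumeration.

Mrr-like methylation-dependent restriction endonucleases (FspEI, MspJI, ...)
cut double-stranded DNA at a fixed distance on the 3' side of a 5-methylated
(or 5-hydroxymethylated) cytosine.  When a recognition site is symmetrically
methylated — a methyl-C on each strand in a compatible geometry — the enzyme
cuts on both sides and excises a ~32 nt fragment with the methylated site near
the middle and 4 nt overhangs at both ends.  This module enumerates every
genomic locus that can yield such a double-cut fragment, classifies it by the
forward-strand motif (CCGG / CCWGG / other), and supports the selective
adaptor-overhang subsetting used to reduce tag representation (RTR).

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "IUPAC",
    "EnzymeSpec",
    "FSPEI",
    "GenomeSequence",
    "RestrictionSite",
    "SiteCatalog",
    "reverse_complement",
    "scan_contexts",
    "enumerate_sites",
    "count_by_class",
    "context_coverage",
    "rtr_subset",
    "write_catalog_tsv",
    "read_catalog_tsv",
    "write_catalog_bed",
]

# ---------------------------------------------------------------------------
# Alphabet helpers
# ---------------------------------------------------------------------------

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _matches(seq: str, motif: str) -> bool:
    """True iff ``seq`` (plain A/C/G/T/N) matches the IUPAC ``motif``.

    An N in the genomic sequence never matches: tags containing N are not
    sequenceable/matchable.
    """
    if len(seq) != len(motif):
        return False
    for base, code in zip(seq, motif):
        if base not in IUPAC[code]:
            return False
    return True


def iupac_match(seq: str, pattern: str) -> bool:
    """Public IUPAC pattern match (genomic N never matches)."""
    return _matches(seq, pattern)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnzymeSpec:
    """A methylation-dependent restriction enzyme.

    Parameters
    ----------
    name : str
    contexts : tuple of (motif, mC index)
        Single-strand recognition contexts on the strand carrying the
        methyl-C.  For FspEI these are ``("CC", 1)`` (C^mC) and ``("CDS", 0)``
        (^mCDS, D = A/G/T, S = C/G).
    cut_near, cut_far : int
        Cut distances, in nucleotides 3' of the methyl-C, for the strand
        carrying the methyl-C (near) and the opposite strand (far).
    overhang_len : int
        Length of the 5' overhang left at each cut (``cut_far - cut_near``).
    """

    name: str
    contexts: tuple[tuple[str, int], ...]
    cut_near: int = 12
    cut_far: int = 16
    overhang_len: int = 4

    def __post_init__(self) -> None:
        if self.cut_far - self.cut_near != self.overhang_len:
            raise ValueError("cut_far - cut_near must equal overhang_len")
        for motif, idx in self.contexts:
            if not motif or any(c not in IUPAC for c in motif):
                raise ValueError(f"motif {motif!r} is not IUPAC")
            if not (0 <= idx < len(motif)) or IUPAC[motif[idx]] != frozenset("C"):
                raise ValueError(f"methyl-C index {idx} of {motif!r} must point at a C")


FSPEI = EnzymeSpec("FspEI", contexts=(("CC", 1), ("CDS", 0)))


@dataclass(frozen=True)
class GenomeSequence:
    """One contig; ``is_control`` flags known-unmethylated internal controls
    (e.g. the chloroplast genome in plants)."""

    id: str
    seq: str
    is_control: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: sequence must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


SITE_CLASSES = ("CCGG", "CCWGG", "OTHER")


@dataclass(frozen=True)
class RestrictionSite:
    """A 32-bp-class double-cut locus, anchored on the forward strand.

    ``tag_span`` is the half-open forward-strand interval of the full
    double-cut fragment, outer cut to outer cut (31-33 nt, nominally 32).
    ``overhang_left``/``overhang_right`` are the two 4-nt overhang regions as
    forward-strand genomic sequence at ``tag_span`` start/end; the physical
    5' overhang at the right end reads as the reverse complement of
    ``overhang_right``.
    """

    contig: str
    pos: int                       # start of the forward-strand recognition context
    site_class: str
    top_mC: int
    bottom_mC: int
    tag_span: tuple[int, int]
    tag_seq: str
    overhang_left: str
    overhang_right: str
    is_control: bool = False

    @property
    def site_id(self) -> str:
        return f"{self.contig}:{self.pos}:{self.site_class}"

    @property
    def tag_len(self) -> int:
        return self.tag_span[1] - self.tag_span[0]


@dataclass
class SiteCatalog:
    """All enumerable double-cut sites of one genome for one enzyme."""

    genome_id: str
    enzyme: EnzymeSpec
    sites: dict[str, RestrictionSite] = field(default_factory=dict)
    genome_length: int = 0
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def add(self, site: RestrictionSite) -> None:
        if site.site_id in self.sites:
            raise ValueError(f"duplicate site_id {site.site_id}")
        self.sites[site.site_id] = site

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[RestrictionSite]:
        return iter(self.sites.values())

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.sites

    def __getitem__(self, site_id: str) -> RestrictionSite:
        return self.sites[site_id]

    def class_counts(self, contig: str | None = None) -> Counter:
        counts: Counter = Counter({c: 0 for c in SITE_CLASSES})
        for s in self:
            if contig is None or s.contig == contig:
                counts[s.site_class] += 1
        return counts

    def control_site_ids(self) -> list[str]:
        return [s.site_id for s in self if s.is_control]


# ---------------------------------------------------------------------------
# Context scanning
# ---------------------------------------------------------------------------


def _top_mc_positions(seq: str, enzyme: EnzymeSpec) -> dict[int, str]:
    """Forward-strand methyl-C positions -> name of a matching context.

    A position matching several contexts is recorded once (CC preferred, as
    the first context listed).
    """
    out: dict[int, str] = {}
    for motif, idx in enzyme.contexts:
        k = len(motif)
        for start in range(len(seq) - k + 1):
            if _matches(seq[start : start + k], motif):
                pos = start + idx
                out.setdefault(pos, motif)
    return out


def _bottom_mc_positions(seq: str, enzyme: EnzymeSpec) -> dict[int, str]:
    """Bottom-strand methyl-C positions, in forward coordinates.

    A bottom-strand context at forward position p corresponds to the enzyme
    motif appearing in the reverse complement; equivalently the forward strand
    shows the reverse complement of the motif, read right-to-left.
    """
    out: dict[int, str] = {}
    n = len(seq)
    for motif, idx in enzyme.contexts:
        rc = reverse_complement(motif)
        k = len(motif)
        for start in range(n - k + 1):
            if _matches(seq[start : start + k], rc):
                # bottom-strand motif occupies forward [start, start+k);
                # its position ``idx`` (5'->3' on the bottom strand) maps to
                # forward coordinate start + (k - 1 - idx).
                pos = start + (k - 1 - idx)
                out.setdefault(pos, motif)
    return out


def scan_contexts(genome: GenomeSequence, enzyme: EnzymeSpec = FSPEI) -> int:
    """Count single-strand recognition contexts on both strands.

    Each strand-specific methyl-C position counts once even if it matches
    more than one context (e.g. both CC and CDS).  N bases never match.
    """
    return len(_top_mc_positions(genome.seq, enzyme)) + len(
        _bottom_mc_positions(genome.seq, enzyme)
    )


# ---------------------------------------------------------------------------
# Double-cut site enumeration
# ---------------------------------------------------------------------------


def _classify(seq: str, t: int, b: int) -> tuple[str, int]:
    """Classify a (top_mC, bottom_mC) pair by forward-strand motif.

    Returns (site_class, pos) where pos is the start of the recognition
    context used for the site id.  CCGG requires offset b-t == 1 with the
    motif CCGG at t-1 (a CCGG inside CCCGG is still CCGG-class); CCWGG
    requires offset 2 with CCWGG at t-1.
    """
    off = b - t
    if off == 1 and t >= 1 and _matches(seq[t - 1 : t + 3], "CCGG"):
        return "CCGG", t - 1
    if off == 2 and t >= 1 and _matches(seq[t - 1 : t + 4], "CCWGG"):
        return "CCWGG", t - 1
    # OTHER: anchor on the top-strand context start (CC if present, else CDS)
    if t >= 1 and seq[t - 1 : t + 1] == "CC":
        return "OTHER", t - 1
    return "OTHER", t


_CLASS_RANK = {"CCGG": 0, "CCWGG": 1, "OTHER": 2}


def enumerate_sites(genome: GenomeSequence, enzyme: EnzymeSpec = FSPEI) -> SiteCatalog:
    """Enumerate all loci whose symmetric methylation yields a double-cut
    ~32 nt fragment.

    A locus is a (top_mC, bottom_mC) pair with a recognition context on each
    strand whose bidirectional near/far cuts excise one fragment of 31-33 nt
    containing both methyl-Cs.  With N12/N16 cuts the admissible offsets
    bottom_mC - top_mC are {1, 2} (fragment 32 and 31 nt respectively);
    canonical CCGG sites have offset 1 and CCWGG offset 2.

    Overlapping registers that share a methyl-C (e.g. the two indistinguishable
    methylation forms of CCCGG) are reported as a single site, preferring
    CCGG over CCWGG over OTHER, then the smaller offset.
    """
    catalog = SiteCatalog(genome_id=genome.id, enzyme=enzyme)
    catalog.genome_length = len(genome)
    catalog.contig_lengths[genome.id] = len(genome)
    for site in _enumerate_contig(genome, enzyme):
        catalog.add(site)
    return catalog


def enumerate_genome(contigs: Iterable[GenomeSequence], enzyme: EnzymeSpec = FSPEI,
                     genome_id: str = "genome") -> SiteCatalog:
    """Multi-contig enumeration; control contigs propagate their flag."""
    catalog = SiteCatalog(genome_id=genome_id, enzyme=enzyme)
    for contig in contigs:
        catalog.genome_length += len(contig)
        catalog.contig_lengths[contig.id] = len(contig)
        for site in _enumerate_contig(contig, enzyme):
            catalog.add(site)
    return catalog


def _enumerate_contig(genome: GenomeSequence, enzyme: EnzymeSpec) -> list[RestrictionSite]:
    seq = genome.seq
    n = len(seq)
    near, far, ov = enzyme.cut_near, enzyme.cut_far, enzyme.overhang_len
    top = _top_mc_positions(seq, enzyme)
    bottom = _bottom_mc_positions(seq, enzyme)
    # admissible offsets: fragment length = 33 - (b - t) must lie in [31, 33];
    # offset 0 would need one base to be both C and G, so {1, 2} in practice.
    candidates: list[tuple[int, int, int, str, int]] = []
    for t in top:
        for off in (1, 2):
            b = t + off
            if b not in bottom:
                continue
            start, end = b - far, t + far + 1
            if start < 0 or end > n:
                continue
            frag = seq[start:end]
            if "N" in frag:
                continue
            cls, pos = _classify(seq, t, b)
            candidates.append((_CLASS_RANK[cls], off, t, cls, pos))
    # resolve overlapping registers sharing a methyl-C: keep best first
    candidates.sort()
    used_t: set[int] = set()
    used_b: set[int] = set()
    sites: list[RestrictionSite] = []
    for _rank, off, t, cls, pos in candidates:
        b = t + off
        if t in used_t or b in used_b:
            continue
        used_t.add(t)
        used_b.add(b)
        start, end = b - far, t + far + 1
        sites.append(
            RestrictionSite(
                contig=genome.id,
                pos=pos,
                site_class=cls,
                top_mC=t,
                bottom_mC=b,
                tag_span=(start, end),
                tag_seq=seq[start:end],
                overhang_left=seq[start : start + ov],
                overhang_right=seq[end - ov : end],
                is_control=genome.is_control,
            )
        )
    sites.sort(key=lambda s: s.tag_span)
    return sites


# ---------------------------------------------------------------------------
# Catalog summaries
# ---------------------------------------------------------------------------


def count_by_class(catalog: SiteCatalog) -> dict[str, dict[str, float | int | None]]:
    """Per-class site counts and genome-wide densities (bp per site).

    Density is genome length divided by class count; absent (None) for a
    class with zero sites.
    """
    counts = catalog.class_counts()
    out: dict[str, dict[str, float | int | None]] = {}
    for cls in SITE_CLASSES:
        c = counts[cls]
        out[cls] = {
            "count": c,
            "density_bp": (catalog.genome_length / c) if c else None,
        }
    total = sum(counts.values())
    out["total"] = {
        "count": total,
        "density_bp": (catalog.genome_length / total) if total else None,
    }
    return out


def _cytosine_contexts(seq: str) -> dict[str, set[tuple[int, str]]]:
    """All genomic cytosines by CG/CHG/CHH context, both strands.

    Returns {context: {(forward position, strand)}}; the position is the
    forward coordinate of the cytosine (for '-' strand, of the G pairing with
    the bottom-strand C).  Trailing cytosines whose context runs off the
    contig end are unclassified, matching per-position downstream scans.
    """
    H = IUPAC["H"]
    out: dict[str, set[tuple[int, str]]] = {"CG": set(), "CHG": set(), "CHH": set()}
    n = len(seq)
    for i, base in enumerate(seq):
        if base == "C":
            if i + 1 < n and seq[i + 1] == "G":
                out["CG"].add((i, "+"))
            elif i + 2 < n and seq[i + 1] in H and seq[i + 2] == "G":
                out["CHG"].add((i, "+"))
            elif i + 2 < n and seq[i + 1] in H and seq[i + 2] in H:
                out["CHH"].add((i, "+"))
        if base == "G":
            # bottom-strand C at forward coord i; its 3' neighbours are at i-1, i-2
            if i - 1 >= 0 and seq[i - 1] == "C":
                out["CG"].add((i, "-"))
            elif i - 2 >= 0 and seq[i - 1].translate(_COMPLEMENT) in H and seq[i - 2] == "C":
                out["CHG"].add((i, "-"))
            elif i - 2 >= 0 and seq[i - 1].translate(_COMPLEMENT) in H \
                    and seq[i - 2].translate(_COMPLEMENT) in H:
                out["CHH"].add((i, "-"))
    return out


def context_coverage(catalog: SiteCatalog,
                     contigs: Iterable[GenomeSequence]) -> dict[str, float]:
    """Fraction of genomic CG / CHG / CHH cytosines (both strands) that
    coincide with a catalog methyl-C position on the same strand."""
    covered: dict[str, set[tuple[int, str]]] = {}
    for s in catalog:
        covered.setdefault(s.contig, set()).update(
            {(s.top_mC, "+"), (s.bottom_mC, "-")}
        )
    totals = {"CG": 0, "CHG": 0, "CHH": 0}
    hits = {"CG": 0, "CHG": 0, "CHH": 0}
    for contig in contigs:
        ctx = _cytosine_contexts(contig.seq)
        cov = covered.get(contig.id, set())
        for name, positions in ctx.items():
            totals[name] += len(positions)
            hits[name] += len(positions & cov)
    return {name: (hits[name] / totals[name]) if totals[name] else 0.0
            for name in totals}


# ---------------------------------------------------------------------------
# Reduced tag representation (selective adaptor overhangs)
# ---------------------------------------------------------------------------


def _ligatable(overhang_5p: str, adaptor_pattern: str) -> bool:
    """True iff a fragment 5' overhang can anneal to an adaptor overhang.

    Annealing is antiparallel complementarity: the fragment overhang must
    match the reverse complement of the adaptor's overhang pattern.
    """
    return _matches(overhang_5p, reverse_complement(adaptor_pattern))


def rtr_subset(catalog: SiteCatalog, pattern_a: str, pattern_b: str) -> SiteCatalog:
    """Subset a catalog to sites ligatable by two selective adaptor overhangs.

    A site is retained iff one adaptor can ligate its left end and the other
    its right end, testing both adaptor-to-end assignments (which also covers
    both fragment orientations).  The left-end fragment 5' overhang is
    ``overhang_left``; the right-end one is the reverse complement of
    ``overhang_right``.  Fully degenerate patterns (NNNN/NNNN) retain
    everything.
    """
    for p in (pattern_a, pattern_b):
        if len(p) != catalog.enzyme.overhang_len or any(c not in IUPAC for c in p):
            raise ValueError(f"invalid adaptor overhang pattern {p!r}")
    out = SiteCatalog(genome_id=catalog.genome_id, enzyme=catalog.enzyme,
                      genome_length=catalog.genome_length,
                      contig_lengths=dict(catalog.contig_lengths))
    for s in catalog:
        left = s.overhang_left
        right = reverse_complement(s.overhang_right)
        if (_ligatable(left, pattern_a) and _ligatable(right, pattern_b)) or (
            _ligatable(left, pattern_b) and _ligatable(right, pattern_a)
        ):
            out.add(s)
    return out


# ---------------------------------------------------------------------------
# Catalog I/O (TSV / BED6)
# ---------------------------------------------------------------------------

_TSV_HEADER = ["contig", "start", "end", "site_id", "class", "tag_seq",
               "overhang_left", "overhang_right", "top_mC", "bottom_mC",
               "is_control"]


def write_catalog_tsv(catalog: SiteCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("#genome_id=%s\tenzyme=%s\tgenome_length=%d\tcontigs=%s\n" % (
            catalog.genome_id, catalog.enzyme.name, catalog.genome_length,
            ",".join(f"{c}:{l}" for c, l in catalog.contig_lengths.items())))
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for s in catalog:
            fh.write("\t".join(map(str, [
                s.contig, s.tag_span[0], s.tag_span[1], s.site_id,
                s.site_class, s.tag_seq, s.overhang_left, s.overhang_right,
                s.top_mC, s.bottom_mC, int(s.is_control)])) + "\n")


def read_catalog_tsv(path, enzyme: EnzymeSpec = FSPEI) -> SiteCatalog:
    catalog = SiteCatalog(genome_id="catalog", enzyme=enzyme)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for kv in first[1:].strip().split("\t"):
                key, _, val = kv.partition("=")
                if key == "genome_id":
                    catalog.genome_id = val
                elif key == "genome_length":
                    catalog.genome_length = int(val)
                elif key == "contigs" and val:
                    for item in val.split(","):
                        c, _, l = item.rpartition(":")
                        catalog.contig_lengths[c] = int(l)
            header = fh.readline().rstrip("\n").split("\t")
        else:
            header = first.rstrip("\n").split("\t")
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected catalog header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            contig, start, end = f[0], int(f[1]), int(f[2])
            pos = int(f[3].rsplit(":", 2)[1])
            catalog.add(RestrictionSite(
                contig=contig, pos=pos, site_class=f[4],
                top_mC=int(f[8]), bottom_mC=int(f[9]),
                tag_span=(start, end), tag_seq=f[5],
                overhang_left=f[6], overhang_right=f[7],
                is_control=bool(int(f[10]))))
    return catalog


def write_catalog_bed(catalog: SiteCatalog, path) -> None:
    """BED6: score 0, strand '+' (sites are forward-anchored)."""
    with open(path, "w") as fh:
        for s in catalog:
            fh.write(f"{s.contig}\t{s.tag_span[0]}\t{s.tag_span[1]}"
                     f"\t{s.site_id}\t0\t+\n")
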