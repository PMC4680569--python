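"""Cluster-derived reference (CDR) construction for reference-free analysis.

HQ reads are first pooled into exactly matching clusters (discarding
sequences below a minimum depth), then merged by single linkage into 'locus'
clusters allowing a small number of mismatches so that tags from different
alleles of one site group together.  The depth-weighted per-position
consensus of each locus cluster is its representative; representatives form
the de novo reference, usable wherever a genome-derived site catalog would
be.  Unusually deep clusters (log-depth more than two standard deviations
above the mean) are flagged as likely repetitive loci.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .enzyme import EnzymeSpec, FSPEI, RestrictionSite, SiteCatalog, iupac_match
from .mapping import TagIndex, _hamming

__all__ = ["CDRCluster", "cluster_exact", "merge_clusters", "flag_repetitive",
           "match_cdr_to_reference", "cdr_catalog", "classify_cdr"]


@dataclass
class CDRCluster:
    representative: str
    depth: int
    members: dict[str, int]
    repetitive: bool = False

    def __post_init__(self) -> None:
        if self.depth != sum(self.members.values()):
            raise ValueError("depth must equal the sum of member counts")


def cluster_exact(reads: Iterable, min_depth: int = 2) -> dict[str, int]:
    """Pool reads into exact-sequence clusters; drop sequences seen fewer
    than ``min_depth`` times."""
    counts = Counter(r if isinstance(r, str) else r.seq for r in reads)
    return {seq: n for seq, n in sorted(counts.items()) if n >= min_depth}


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _consensus(members: dict[str, int]) -> str:
    """Depth-weighted per-position consensus.

    Position ties go to the base carried by the deepest member (then the
    lexicographically smallest member sequence) among the tied bases.
    """
    order = sorted(members, key=lambda s: (-members[s], s))
    length = len(order[0])
    out = []
    for i in range(length):
        votes: Counter = Counter()
        for seq in order:
            votes[seq[i]] += members[seq]
        top = max(votes.values())
        tied = {b for b, v in votes.items() if v == top}
        if len(tied) == 1:
            out.append(next(iter(tied)))
        else:
            out.append(next(seq[i] for seq in order if seq[i] in tied))
    return "".join(out)


def merge_clusters(exact: dict[str, int], max_mm: int = 2) -> list[CDRCluster]:
    """Single-linkage merge of exact clusters differing by <= ``max_mm``.

    Only equal-length sequences can be compared (Hamming distance); clusters
    of different lengths never merge.  Transitive chains may join alleles
    more than ``max_mm`` apart -- the documented single-linkage behaviour.
    Output order is deterministic: by descending depth then sequence.
    """
    strata: dict[int, list[str]] = {}
    for seq in exact:
        strata.setdefault(len(seq), []).append(seq)
    cdrs: list[CDRCluster] = []
    for length in sorted(strata):
        seqs = sorted(strata[length])
        uf = _UnionFind(len(seqs))
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                if _hamming(seqs[i], seqs[j]) <= max_mm:
                    uf.union(i, j)
        groups: dict[int, dict[str, int]] = {}
        for i, seq in enumerate(seqs):
            groups.setdefault(uf.find(i), {})[seq] = exact[seq]
        for members in groups.values():
            cdrs.append(CDRCluster(representative=_consensus(members),
                                   depth=sum(members.values()),
                                   members=members))
    cdrs.sort(key=lambda c: (-c.depth, c.representative))
    return cdrs


def flag_repetitive(cdrs: Sequence[CDRCluster]) -> list[CDRCluster]:
    """Flag CDRs whose log-depth exceeds mean + 2*sd of log-depths.

    Sample standard deviation (ddof=1); with fewer than two CDRs, or all
    depths equal, nothing is flagged.
    """
    if len(cdrs) < 2:
        raise ValueError("need at least two CDRs to estimate the depth spread")
    logs = [math.log(c.depth) for c in cdrs]
    mean = sum(logs) / len(logs)
    var = sum((x - mean) ** 2 for x in logs) / (len(logs) - 1)
    cutoff = mean + 2.0 * math.sqrt(var)
    for c, lg in zip(cdrs, logs):
        c.repetitive = lg > cutoff
    return list(cdrs)


def classify_cdr(seq: str) -> str:
    """Infer a site class from the CDR sequence alone.

    A full-length fragment places the recognition motif around the centre:
    for a fragment spanning [b-16, t+17) with offset b-t in {1,2}, CCGG
    starts 15 nt from the left end and CCWGG 14 nt.  Reported as inferred --
    end trimming shifts these by the trim width, so nearby offsets are also
    checked.
    """
    for off in range(max(0, len(seq) // 2 - 4), len(seq) // 2 + 1):
        if iupac_match(seq[off : off + 4], "CCGG"):
            return "CCGG"
        if iupac_match(seq[off : off + 5], "CCWGG"):
            return "CCWGG"
    return "OTHER"


def cdr_catalog(cdrs: Sequence[CDRCluster], enzyme: EnzymeSpec = FSPEI,
                include_repetitive: bool = True) -> SiteCatalog:
    """Expose CDRs as a SiteCatalog so tag_mapping can consume them.

    CDR coordinates are synthetic (each CDR is its own contig); classes are
    inferred from the sequence motif.
    """
    catalog = SiteCatalog(genome_id="cdr", enzyme=enzyme)
    for i, c in enumerate(cdrs):
        if c.repetitive and not include_repetitive:
            continue
        name = f"cdr_{i}"
        catalog.genome_length += len(c.representative)
        catalog.contig_lengths[name] = len(c.representative)
        catalog.add(RestrictionSite(
            contig=name, pos=0, site_class=classify_cdr(c.representative),
            top_mC=0, bottom_mC=1, tag_span=(0, len(c.representative)),
            tag_seq=c.representative,
            overhang_left=c.representative[: enzyme.overhang_len],
            overhang_right=c.representative[-enzyme.overhang_len:],
        ))
    return catalog


@dataclass
class CDRMatchReport:
    one_to_one: int = 0
    many_to_one: int = 0
    unmatched: int = 0
    assignments: dict[int, str | None] = field(default_factory=dict)

    @property
    def n_cdrs(self) -> int:
        return self.one_to_one + self.many_to_one + self.unmatched

    @property
    def one_to_one_fraction(self) -> float:
        return self.one_to_one / self.n_cdrs if self.n_cdrs else 0.0


def match_cdr_to_reference(cdrs: Sequence[CDRCluster], catalog: SiteCatalog,
                           max_mm: int = 2) -> CDRMatchReport:
    """Assign each CDR its best <=max_mm reference tag (evaluation mode).

    one-to-one: the CDR has a single best reference site and is that site's
    only best-matching CDR.  many-to-one: several reference sites tie, or
    several CDRs share one site.
    """
    index = TagIndex(catalog, max_mm=max_mm)
    report = CDRMatchReport()
    best_site: dict[int, str | None] = {}
    unique_best: dict[int, bool] = {}
    site_claims: Counter = Counter()
    for i, c in enumerate(cdrs):
        best, hits = index.query(c.representative)
        if best is None or not hits:
            best_site[i] = None
            continue
        unique_best[i] = len(hits) == 1
        best_site[i] = sorted(hits)[0]
        site_claims[best_site[i]] += 1
    for i in range(len(cdrs)):
        sid = best_site.get(i)
        report.assignments[i] = sid
        if sid is None:
            report.unmatched += 1
        elif unique_best[i] and site_claims[sid] == 1:
            report.one_to_one += 1
        else:
            report.many_to_one += 1
    return report


def write_cdr_fasta(cdrs: Sequence[CDRCluster], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(cdrs):
            fh.write(f">cdr_{i};depth={c.depth};repetitive={int(c.repetitive)}\n"
                     f"{c.representative}\n")
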