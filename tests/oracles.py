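"""Independent brute-force oracles the test suite checks the package against.

These deliberately avoid the package's scanning/indexing code paths: context
matching, cut geometry, Hamming search and single-linkage clustering are
re-derived here position by position.
"""

from __future__ import annotations

import itertools

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _is_top_mc(seq: str, t: int) -> bool:
    """Forward-strand methyl-C at t: C^mC (mC second) or ^mCDS (mC first)."""
    n = len(seq)
    if t >= 1 and seq[t - 1] == "C" and seq[t] == "C":
        return True
    return (seq[t] == "C" and t + 2 < n
            and seq[t + 1] in "AGT" and seq[t + 2] in "CG")


def oracle_sites(seq: str) -> list[tuple[int, int, str]]:
    """All double-cut loci of ``seq`` as (top_mC, bottom_mC, class).

    Tests every (top-context, bottom-context) position pair against the cut
    geometry: bidirectional N12/N16 cuts must excise one in-bounds, N-free
    fragment of 31-33 nt ([b-16, t+17)).  Overlapping registers sharing a
    methyl-C collapse to one site (CCGG preferred, then CCWGG, then OTHER,
    then the smaller offset).
    """
    n = len(seq)
    rc = revcomp(seq)
    tops = [t for t in range(n) if _is_top_mc(seq, t)]
    bottoms = [n - 1 - t for t in range(n) if _is_top_mc(rc, t)]
    candidates = []
    for t, b in itertools.product(tops, bottoms):
        length = (t + 17) - (b - 16)
        if not (31 <= length <= 33):
            continue
        if b - 16 < 0 or t + 17 > n:
            continue
        if "N" in seq[b - 16 : t + 17]:
            continue
        off = b - t
        if off == 1 and seq[t - 1 : t + 3] == "CCGG":
            cls = "CCGG"
        elif off == 2 and t >= 1 and seq[t - 1] == "C" and seq[t] == "C" \
                and seq[t + 1] in "AT" and seq[t + 2 : t + 4] == "GG":
            cls = "CCWGG"
        else:
            cls = "OTHER"
        candidates.append(({"CCGG": 0, "CCWGG": 1, "OTHER": 2}[cls], off, t, b, cls))
    candidates.sort()
    used_t, used_b, out = set(), set(), []
    for _rank, _off, t, b, cls in candidates:
        if t in used_t or b in used_b:
            continue
        used_t.add(t)
        used_b.add(b)
        out.append((t, b, cls))
    return sorted(out)


def oracle_map(read: str, tags: dict[str, str], max_mm: int = 2):
    """Brute-force best-hit search: slide the read over every tag and its
    reverse complement, count mismatches, return (best_mm, {site ids})."""
    best, hits = None, set()
    for site_id, tag in tags.items():
        for strand_seq in (tag, revcomp(tag)):
            for off in range(len(strand_seq) - len(read) + 1):
                mm = sum(1 for a, b in zip(read, strand_seq[off:]) if a != b)
                if mm > max_mm:
                    continue
                if best is None or mm < best:
                    best, hits = mm, {site_id}
                elif mm == best:
                    hits.add(site_id)
    return best, hits


def oracle_single_linkage(seqs: list[str], max_mm: int) -> list[frozenset]:
    """Partition equal-length sequences by single linkage at <= max_mm,
    via networkx connected components."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(seqs)
    for a, b in itertools.combinations(seqs, 2):
        if len(a) == len(b) and sum(x != y for x, y in zip(a, b)) <= max_mm:
            g.add_edge(a, b)
    return sorted((frozenset(c) for c in nx.connected_components(g)),
                  key=lambda c: sorted(c))
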