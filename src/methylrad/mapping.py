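"""Mismatch-tolerant mapping of QC'd tag reads onto a site catalog.

The reference is tiny (one ~31-32 nt tag per restriction site), so reads are
mapped by an exact <=2-mismatch search rather than a general-purpose aligner:
every alignment of the read within each tag window (both strands) is scored
by Hamming distance, the minimal mismatch count wins, and a read is `unique`
only when a single site attains that minimum.  A pigeonhole index (read split
into max_mm+1 parts; any <=max_mm hit matches one part exactly) makes lookups
fast without changing the brute-force contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .enzyme import SiteCatalog, reverse_complement
from .qc import RawRead

__all__ = ["TagAlignment", "DepthTable", "TagIndex", "build_index", "map_read",
           "map_reads", "tabulate_depth"]


@dataclass(frozen=True)
class TagAlignment:
    read_id: str
    site_id: str | None
    strand: str | None            # '+' read matches tag, '-' matches its rc
    mismatches: int | None
    mapping_class: str            # unique | multi | unmapped
    best_sites: tuple[str, ...] = ()   # all sites attaining the best score


@dataclass
class DepthTable:
    """Per-site read counts for one sample.

    ``library_size`` is the total number of mapped reads (unique + multi);
    ``counts`` holds unique-read counts by default (fractional multi counts
    if requested at tabulation).  RPM = count * 1e6 / library_size.
    """

    sample_id: str
    counts: pd.Series                 # index: site_id, values >= 0
    library_size: int
    site_class: pd.Series | None = None

    @property
    def rpm(self) -> pd.Series:
        if self.library_size == 0:
            return self.counts * 0.0
        return self.counts * 1e6 / self.library_size

    def detected(self, threshold: int = 1) -> pd.Index:
        return self.counts.index[self.counts >= threshold]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"count": self.counts, "RPM": self.rpm})
        if self.site_class is not None:
            df.insert(0, "class", self.site_class)
        df.index.name = "site_id"
        return df

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample_id={self.sample_id}\tlibrary_size={self.library_size}\n")
            self.to_frame().to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "DepthTable":
        with open(path) as fh:
            meta = fh.readline()
            sample_id, library_size = "sample", 0
            if meta.startswith("#"):
                for kv in meta[1:].strip().split("\t"):
                    k, _, v = kv.partition("=")
                    if k == "sample_id":
                        sample_id = v
                    elif k == "library_size":
                        library_size = int(v)
                df = pd.read_csv(fh, sep="\t", index_col="site_id")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", index_col="site_id")
        return cls(sample_id=sample_id, counts=df["count"],
                   library_size=library_size or int(df["count"].sum()),
                   site_class=df["class"] if "class" in df else None)


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _split_points(length: int, parts: int) -> list[tuple[int, int]]:
    step, rem = divmod(length, parts)
    out, start = [], 0
    for i in range(parts):
        end = start + step + (1 if i < rem else 0)
        out.append((start, end))
        start = end
    return out


class TagIndex:
    """Pigeonhole index over all read-length windows of every tag (both
    strands).  Duplicate tag sequences are allowed: reads hitting several
    sites equally well are classified `multi`."""

    def __init__(self, catalog: SiteCatalog, max_mm: int = 2):
        self.catalog = catalog
        self.max_mm = max_mm
        # windows are materialized lazily per query length
        self._tags: list[tuple[str, str, str]] = []   # (site_id, strand, seq)
        for s in catalog:
            self._tags.append((s.site_id, "+", s.tag_seq))
            self._tags.append((s.site_id, "-", reverse_complement(s.tag_seq)))
        self._max_tag_len = max((len(t[2]) for t in self._tags), default=0)
        self._by_length: dict[int, tuple[list[tuple[int, int]],
                                         dict[tuple[int, str], list[tuple[str, str, str]]]]] = {}

    @property
    def n_entries(self) -> int:
        return len(self._tags)

    def _windows_for(self, length: int):
        cached = self._by_length.get(length)
        if cached is not None:
            return cached
        parts = _split_points(length, self.max_mm + 1)
        buckets: dict[tuple[int, str], list[tuple[str, str, str]]] = {}
        for site_id, strand, seq in self._tags:
            for off in range(0, len(seq) - length + 1):
                window = seq[off : off + length]
                for pi, (a, b) in enumerate(parts):
                    buckets.setdefault((pi, window[a:b]), []).append(
                        (site_id, strand, window))
        self._by_length[length] = (parts, buckets)
        return parts, buckets

    def query(self, seq: str) -> tuple[int | None, dict[str, str]]:
        """Best mismatch count and {site_id: strand} of sites attaining it."""
        if not self._tags:
            return None, {}
        if len(seq) > self._max_tag_len or len(seq) <= self.max_mm:
            return None, {}
        parts, buckets = self._windows_for(len(seq))
        best: int | None = None
        hits: dict[str, str] = {}
        seen: set[tuple[str, str, str]] = set()
        for pi, (a, b) in enumerate(parts):
            for entry in buckets.get((pi, seq[a:b]), ()):
                if entry in seen:
                    continue
                seen.add(entry)
                site_id, strand, window = entry
                mm = _hamming(seq, window)
                if mm > self.max_mm:
                    continue
                if best is None or mm < best:
                    best, hits = mm, {site_id: strand}
                elif mm == best and site_id not in hits:
                    hits[site_id] = strand
        return best, hits


def build_index(catalog: SiteCatalog, max_mm: int = 2) -> TagIndex:
    if len(catalog) == 0:
        raise ValueError("cannot index an empty catalog")
    return TagIndex(catalog, max_mm=max_mm)


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------


def map_read(read: RawRead | str, index: TagIndex) -> TagAlignment:
    seq = read if isinstance(read, str) else read.seq
    rid = read if isinstance(read, str) else read.id
    best, hits = index.query(seq)
    if best is None or not hits:
        return TagAlignment(rid, None, None, None, "unmapped")
    if len(hits) == 1:
        (site_id, strand), = hits.items()
        return TagAlignment(rid, site_id, strand, best, "unique", (site_id,))
    site_id = sorted(hits)[0]
    return TagAlignment(rid, site_id, hits[site_id], best, "multi",
                        tuple(sorted(hits)))


def map_reads(reads: Iterable[RawRead | str], index: TagIndex) -> list[TagAlignment]:
    return [map_read(r, index) for r in reads]


def tabulate_depth(alignments: Iterable[TagAlignment], catalog: SiteCatalog,
                   sample_id: str = "sample",
                   count_multi: str = "exclude") -> DepthTable:
    """Build a per-site depth table from one sample's alignments.

    count_multi: 'exclude' (default; unique reads only, the conservative
    choice) or 'fractional' (a multi read adds 1/k to each of its k
    best-scoring sites).  Library size records all mapped reads
    (unique + multi) either way.
    """
    if count_multi not in ("exclude", "fractional"):
        raise ValueError("count_multi must be 'exclude' or 'fractional'")
    counts: dict[str, float] = {}
    library = 0
    for aln in alignments:
        if aln.mapping_class == "unmapped":
            continue
        library += 1
        if aln.site_id not in catalog:
            raise KeyError(f"alignment references unknown site {aln.site_id}")
        if aln.mapping_class == "unique":
            counts[aln.site_id] = counts.get(aln.site_id, 0) + 1
        elif count_multi == "fractional":
            w = 1.0 / len(aln.best_sites)
            for sid in aln.best_sites:
                counts[sid] = counts.get(sid, 0) + w
    series = pd.Series(counts, dtype=float).sort_index()
    classes = pd.Series({sid: catalog[sid].site_class for sid in series.index})
    return DepthTable(sample_id=sample_id, counts=series,
                      library_size=library, site_class=classes)


def mapping_summary(alignments: Iterable[TagAlignment]) -> dict[str, float]:
    counts = {"unique": 0, "multi": 0, "unmapped": 0}
    for aln in alignments:
        counts[aln.mapping_class] += 1
    total = sum(counts.values())
    out: dict[str, float] = dict(counts)
    out["total"] = total
    for k in ("unique", "multi", "unmapped"):
        out[f"{k}_pct"] = 100.0 * counts[k] / total if total else 0.0
    return out
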