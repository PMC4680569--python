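"""Relative methylation quantification and evaluation statistics.

The central quantity is the M-index: for a detected site,
``M = log(depth_site) / log(depth_max)``, where ``depth_max`` — the depth
representing ~100% methylation — is calibrated as the mean raw depth of the
top 2% most deeply covered sites.  M is capped into [0, 1]; a depth-1 site
gets M = 0 but still counts as detected.  The method is relative: M-index
supports comparisons across sites and libraries, not absolute
(bisulfite-style) methylation percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enzyme import SiteCatalog
from .mapping import DepthTable

__all__ = ["MIndexTable", "m_index", "trinary_call", "concordance", "fpr",
           "detection_rate", "window_profile", "rarefy", "WindowProfile"]


@dataclass
class MIndexTable:
    """Per-site M-index for one sample, with its calibration depth."""

    sample_id: str
    m: pd.Series                      # index: detected site_ids, values in [0,1]
    depth: pd.Series
    depth_max: float
    top_fraction: float = 0.02
    source: str = "reference"         # reference | denovo

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"depth": self.depth, "M": self.m})
        df.index.name = "site_id"
        return df

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample_id={self.sample_id}\tdepth_max={self.depth_max:g}"
                     f"\ttop_fraction={self.top_fraction}\tsource={self.source}\n")
            self.to_frame().to_csv(fh, sep="\t")


def m_index(depth_table: DepthTable, top_fraction: float = 0.02,
            repetitive_ids: set[str] | None = None,
            calibration: str = "mean", source: str = "reference") -> MIndexTable:
    """Compute per-site M-index from a depth table.

    depth_max is the ``calibration`` summary ('mean' | 'median' | 'max') of
    the top ``top_fraction`` of sites by raw depth; in de novo mode,
    repetitive-flagged sites are excluded from the calibration first.
    """
    counts = depth_table.counts[depth_table.counts >= 1]
    if len(counts) < 50:
        warnings.warn(f"only {len(counts)} detected sites: depth_max "
                      "calibration may be unreliable", stacklevel=2)
    calib = counts
    if repetitive_ids:
        calib = calib[~calib.index.isin(repetitive_ids)]
    if len(calib) == 0:
        raise ValueError("no sites available for depth_max calibration")
    k = max(1, math.ceil(top_fraction * len(calib)))
    top = calib.sort_values(ascending=False).iloc[:k]
    if calibration == "mean":
        depth_max = float(top.mean())
    elif calibration == "median":
        depth_max = float(top.median())
    elif calibration == "max":
        depth_max = float(top.max())
    else:
        raise ValueError(f"unknown calibration {calibration!r}")
    if depth_max <= 1:
        raise ValueError(f"depth_max = {depth_max:g} <= 1: cannot normalize")
    m = np.log(counts.to_numpy(dtype=float)) / math.log(depth_max)
    m = pd.Series(np.clip(m, 0.0, 1.0), index=counts.index)
    return MIndexTable(sample_id=depth_table.sample_id, m=m, depth=counts,
                       depth_max=depth_max, top_fraction=top_fraction,
                       source=source)


def trinary_call(m: float | pd.Series,
                 cutoffs: tuple[float, float] = (0.80, 0.20)):
    """high (M >= hi) / low (M <= lo) / medium."""
    hi, lo = cutoffs
    if isinstance(m, pd.Series):
        return pd.Series(np.where(m >= hi, "high",
                                  np.where(m <= lo, "low", "medium")),
                         index=m.index)
    return "high" if m >= hi else ("low" if m <= lo else "medium")


def concordance(a: MIndexTable, b: MIndexTable,
                cutoffs: tuple[float, float] = (0.80, 0.20),
                max_diff: float = 0.1) -> dict[str, float]:
    """Concordance of methylation calls over sites detected in both tables.

    A shared site is concordant iff the two trinary calls agree OR the
    M-index difference is below ``max_diff``; both components are reported
    so either reading of the rule is recoverable.  Symmetric in (a, b).
    """
    shared = a.m.index.intersection(b.m.index)
    if len(shared) == 0:
        raise ValueError("no shared detected sites")
    ma, mb = a.m.loc[shared], b.m.loc[shared]
    same_call = (trinary_call(ma, cutoffs) == trinary_call(mb, cutoffs)).to_numpy()
    small_diff = (np.abs(ma.to_numpy() - mb.to_numpy()) < max_diff)
    both = same_call | small_diff
    n = len(shared)
    return {
        "n_shared": n,
        "concordance_pct": 100.0 * both.sum() / n,
        "same_call_pct": 100.0 * same_call.sum() / n,
        "small_diff_pct": 100.0 * small_diff.sum() / n,
    }


def fpr(depth_table: DepthTable, catalog: SiteCatalog,
        min_reads: int = 1) -> dict[str, float]:
    """False-positive rate on known-unmethylated control contigs.

    FPR% = 100 * (control sites with depth >= min_reads) / (possible control
    sites in the catalog).  The denominator counts every enumerable 32-bp
    site on control contigs, detected or not.
    """
    control_ids = catalog.control_site_ids()
    possible = len(control_ids)
    if possible == 0:
        raise ValueError("catalog has no control-contig sites")
    counts = depth_table.counts.reindex(control_ids, fill_value=0)
    detected = int((counts >= min_reads).sum())
    return {"detected": detected, "possible": possible,
            "fpr_pct": 100.0 * detected / possible}


def detection_rate(reference: pd.Series, detected_ids,
                   bins=((0.0, 0.2), (0.2, 0.3), (0.3, 0.4), (0.4, 0.5),
                         (0.5, 0.6), (0.6, 0.7), (0.7, 0.8), (0.8, 0.9),
                         (0.9, 1.0))) -> pd.DataFrame:
    """Per-methylation-bin detection rates.

    ``reference`` maps site_id -> known methylation level in [0, 1];
    ``detected_ids`` is the set of site ids recovered by the query library.
    Bins are half-open [lo, hi) except the last, which includes hi.  A bin
    with no reference sites has an absent (NaN) rate.
    """
    detected = set(detected_ids)
    rows = []
    for i, (lo, hi) in enumerate(bins):
        last = i == len(bins) - 1
        mask = (reference >= lo) & ((reference <= hi) if last else (reference < hi))
        total = int(mask.sum())
        hit = sum(1 for sid in reference.index[mask] if sid in detected)
        rows.append({"bin_low": lo, "bin_high": hi, "total": total,
                     "detected": hit,
                     "rate_pct": 100.0 * hit / total if total else float("nan")})
    return pd.DataFrame(rows)


@dataclass
class WindowProfile:
    contig: str
    start: int
    end: int
    mean_m: float          # NaN when the window holds no detected site
    n_sites: int


def window_profile(mindex: MIndexTable, catalog: SiteCatalog,
                   window: int = 200_000,
                   zero_fill: bool = False) -> list[WindowProfile]:
    """Mean M-index in tiling windows along each contig (reference mode).

    With ``zero_fill``, catalog sites undetected in the sample contribute
    M = 0 to their window; otherwise only detected sites are averaged.
    """
    values: dict[str, tuple[int, float]] = {}
    for s in catalog:
        if s.site_id in mindex.m.index:
            values[s.site_id] = (s.tag_span[0], float(mindex.m[s.site_id]))
        elif zero_fill:
            values[s.site_id] = (s.tag_span[0], 0.0)
    per_window: dict[tuple[str, int], list[float]] = {}
    for s in catalog:
        if s.site_id in values:
            pos, m = values[s.site_id]
            per_window.setdefault((s.contig, pos // window), []).append(m)
    out = []
    for contig, length in catalog.contig_lengths.items():
        for w in range((length + window - 1) // window):
            ms = per_window.get((contig, w), [])
            out.append(WindowProfile(
                contig=contig, start=w * window,
                end=min((w + 1) * window, length),
                mean_m=float(np.mean(ms)) if ms else float("nan"),
                n_sites=len(ms)))
    return out


def rarefy(depth_table: DepthTable, fractions, seed: int | np.random.Generator,
           detect_threshold: int = 1, top_fraction: float = 0.02) -> pd.DataFrame:
    """Subsample mapped reads without replacement and re-quantify.

    For each fraction f, draws round(f * total) reads from the per-site count
    vector (multivariate hypergeometric — equivalent in distribution to
    rerunning mapping on a read subsample), then reports the number of sites
    at or above ``detect_threshold`` and the Pearson r between subsampled and
    full M-index over sites detected at both scales.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = depth_table.counts.astype(int)
    total = int(counts.sum())
    full = m_index(depth_table, top_fraction=top_fraction)
    rows = []
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fraction {f} outside (0, 1]")
        n_draw = int(round(f * total))
        if f == 1.0:
            sub = counts
        else:
            sub = pd.Series(
                rng.multivariate_hypergeometric(counts.to_numpy(), n_draw),
                index=counts.index)
        detected = int((sub >= detect_threshold).sum())
        sub_table = DepthTable(sample_id=depth_table.sample_id,
                               counts=sub[sub > 0].astype(float),
                               library_size=n_draw)
        if f == 1.0:
            r = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub_m = m_index(sub_table, top_fraction=top_fraction)
            shared = full.m.index.intersection(sub_m.m.index)
            shared = [s for s in shared
                      if full.depth[s] >= detect_threshold
                      and sub_m.depth[s] >= detect_threshold]
            if len(shared) >= 3:
                r = float(stats.pearsonr(full.m.loc[shared],
                                         sub_m.m.loc[shared]).statistic)
            else:
                r = float("nan")
        rows.append({"fraction": f, "reads_used": n_draw,
                     "sites_detected": detected, "pearson_r": r})
    return pd.DataFrame(rows)
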