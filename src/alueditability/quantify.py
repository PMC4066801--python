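"""Per-Alu editability from site-level A/G read counts.

Editability of an element is the percentage of sequenced adenosine read
bases observed as G (inosine is read as guanosine), pooled over every
adenosine position the element covers.  Coverage filters follow the
convention of requiring at least 30 covered adenosine positions and at
least 1000 sequenced adenosines/inosines in total per element.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotations import GenicAlu

SITE_COLUMNS = ["chrom", "pos", "strand", "a_reads", "g_reads"]


class StrandMismatchError(ValueError):
    """A site falls inside an Alu but its strand differs from the gene strand."""


@dataclass(frozen=True)
class SiteCount:
    chrom: str
    pos: int  # 0-based
    strand: str  # expressed strand
    a_reads: int
    g_reads: int

    def __post_init__(self):
        if self.a_reads < 0 or self.g_reads < 0 or self.a_reads + self.g_reads < 1:
            raise ValueError(f"invalid read counts at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class AluEditability:
    alu_id: str
    n_sites_covered: int
    total_a: int
    total_g: int

    @property
    def depth(self) -> int:
        return self.total_a + self.total_g

    @property
    def editability_pct(self) -> float:
        return 100.0 * self.total_g / self.depth


@dataclass(frozen=True)
class CoverageFilter:
    min_sites: int = 30
    min_depth: int = 1000

    def __post_init__(self):
        if self.min_sites < 0 or self.min_depth < 0:
            raise ValueError("coverage thresholds must be non-negative")


def sites_to_frame(sites) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        missing = set(SITE_COLUMNS) - set(sites.columns)
        if missing:
            raise ValueError(f"site table missing columns {sorted(missing)}")
        df = sites
    else:
        df = pd.DataFrame(
            [(s.chrom, s.pos, s.strand, s.a_reads, s.g_reads) for s in sites],
            columns=SITE_COLUMNS,
        )
    depth = df["a_reads"].to_numpy() + df["g_reads"].to_numpy()
    if len(df) and ((df["a_reads"].to_numpy() < 0).any()
                    or (df["g_reads"].to_numpy() < 0).any()
                    or (depth < 1).any()):
        raise ValueError("site counts must be non-negative with depth >= 1")
    return df


def read_site_counts(path) -> pd.DataFrame:
    """Read a site-count TSV (header required; gzip by extension)."""
    df = pd.read_csv(path, sep="\t")
    return sites_to_frame(df)


def write_site_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _assign_sites(site_df: pd.DataFrame, alus: Sequence[GenicAlu]):
    """Map each site row to the indices of the Alus containing it.

    Returns (site_index, alu_index) integer arrays.  Uses a sorted
    searchsorted fast path when the per-chromosome elements do not overlap,
    falling back to an interval tree otherwise (nested annotations).
    """
    site_idx_all = []
    alu_idx_all = []
    by_chrom: dict[str, list[int]] = {}
    for i, ga in enumerate(alus):
        by_chrom.setdefault(ga.element.chrom, []).append(i)

    for chrom, idxs in by_chrom.items():
        mask = site_df["chrom"].to_numpy() == chrom
        if not mask.any():
            continue
        spos = site_df["pos"].to_numpy()[mask]
        srow = np.flatnonzero(mask)
        order = sorted(idxs, key=lambda i: (alus[i].element.start, alus[i].element.end))
        starts = np.array([alus[i].element.start for i in order])
        ends = np.array([alus[i].element.end for i in order])
        order = np.array(order)
        if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
            tree = IntervalTree()
            for j, i in enumerate(order):
                tree.addi(starts[j], ends[j], int(i))
            for pos, row in zip(spos, srow):
                for iv in tree.at(int(pos)):
                    site_idx_all.append(row)
                    alu_idx_all.append(iv.data)
        else:
            k = np.searchsorted(starts, spos, side="right") - 1
            ok = (k >= 0) & (spos < ends[np.clip(k, 0, None)])
            site_idx_all.extend(srow[ok].tolist())
            alu_idx_all.extend(order[k[ok]].tolist())
    return np.asarray(site_idx_all, dtype=np.int64), np.asarray(alu_idx_all, dtype=np.int64)


def _aggregate(site_df: pd.DataFrame, alus: Sequence[GenicAlu],
               g_numerator: np.ndarray) -> list[AluEditability]:
    site_idx, alu_idx = _assign_sites(site_df, alus)
    if len(site_idx):
        strands = site_df["strand"].to_numpy()[site_idx]
        gene_strands = np.array([alus[i].gene_strand for i in alu_idx])
        bad = strands != gene_strands
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            row = site_df.iloc[site_idx[j]]
            raise StrandMismatchError(
                f"site {row['chrom']}:{row['pos']} strand {row['strand']} does not "
                f"match gene strand {gene_strands[j]} of {alus[alu_idx[j]].element.id}"
            )
    n = len(alus)
    a = site_df["a_reads"].to_numpy()[site_idx] + (
        site_df["g_reads"].to_numpy()[site_idx] - g_numerator[site_idx]
    )
    g = g_numerator[site_idx]
    total_a = np.bincount(alu_idx, weights=a, minlength=n)
    total_g = np.bincount(alu_idx, weights=g, minlength=n)
    # distinct covered positions per Alu
    if len(site_idx):
        pairs = pd.DataFrame({
            "alu": alu_idx,
            "pos": site_df["pos"].to_numpy()[site_idx],
        })
        nsites = pairs.drop_duplicates().groupby("alu").size()
    else:
        nsites = pd.Series(dtype=int)
    out = []
    for i in range(n):
        ns = int(nsites.get(i, 0))
        if ns == 0:
            continue
        out.append(AluEditability(alus[i].element.id, ns,
                                  int(total_a[i]), int(total_g[i])))
    return out


def aggregate_site_counts(sites, alus: Sequence[GenicAlu]) -> list[AluEditability]:
    """Pool site counts into per-Alu totals (unfiltered).

    Sites outside any Alu are ignored; an in-Alu site whose strand disagrees
    with the gene strand raises StrandMismatchError (inconsistent upstream
    strand handling).  Alus without any covered site are absent from the
    output.
    """
    df = sites_to_frame(sites)
    return _aggregate(df, alus, df["g_reads"].to_numpy().astype(float))


def strong_site_editability(sites, alus: Sequence[GenicAlu],
                            threshold_pct: float = 25.0) -> list[AluEditability]:
    """Editability counting only strong sites in the numerator.

    A site whose own editing level (100·g/(a+g)) is <= threshold contributes
    its full depth to the denominator but zero G to the numerator, so the
    statistic stays a per-adenosine fraction over the same read pool.
    """
    if not (0 < threshold_pct < 100):
        raise ValueError("threshold must be in (0, 100)")
    df = sites_to_frame(sites)
    a = df["a_reads"].to_numpy().astype(float)
    g = df["g_reads"].to_numpy().astype(float)
    level = 100.0 * g / (a + g)
    return _aggregate(df, alus, np.where(level > threshold_pct, g, 0.0))


def apply_coverage_filters(records: Iterable[AluEditability],
                           filt: CoverageFilter = CoverageFilter()
                           ) -> list[AluEditability]:
    """Keep records with n_sites >= min_sites and depth >= min_depth (inclusive)."""
    return [r for r in records
            if r.n_sites_covered >= filt.min_sites and r.depth >= filt.min_depth]


def editability_frame(records: Iterable[AluEditability],
                      alus: Sequence[GenicAlu] | None = None) -> pd.DataFrame:
    """Tabulate records; if genic alus are given, add coordinates and gene."""
    rows = [
        (r.alu_id, r.n_sites_covered, r.total_a, r.total_g, r.editability_pct)
        for r in records
    ]
    df = pd.DataFrame(
        rows, columns=["alu_id", "n_sites_covered", "total_a", "total_g",
                       "editability_pct"],
    )
    if alus is not None:
        meta = pd.DataFrame(
            [(ga.element.id, ga.element.chrom, ga.element.start, ga.element.end,
              ga.element.strand, ga.gene_id) for ga in alus],
            columns=["alu_id", "chrom", "start", "end", "strand", "gene_id"],
        )
        df = meta.merge(df, on="alu_id", how="inner")
    return df
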