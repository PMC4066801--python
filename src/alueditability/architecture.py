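"""Genomic-architecture covariates of Alu elements.

Per element: gap distance d to the nearest reversely oriented repeat,
same-/reverse-strand neighbor counts in symmetric windows (10 kb and 2 kb
each side by default), exon/intron co-residence with the nearest reverse
neighbor, percent identity to that neighbor, and subfamily relations.

Distances are edge-to-edge gaps: touching, overlapping, or nested elements
are at distance zero.  Window membership is measured by gap distance and is
inclusive at the boundary.  Neighbor pools contain *all* annotated repeats
on the chromosome, genic or not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import local_identity
from .annotations import GeneModel, GenicAlu, RepeatElement

WINDOW_WIDE = 10_000
WINDOW_NARROW = 2_000

SEGMENT_RELATIONS = (
    "same_exon", "same_intron", "different_segment",
    "neighbor_outside_gene", "unknown",
)


@dataclass(frozen=True)
class ArchitectureFeatures:
    alu_id: str
    d: int | None
    neighbor_id: str | None
    neighbor_length: int | None
    nss_10k: int
    nrs_10k: int
    nss_2k: int
    nrs_2k: int
    segment_relation: str
    pair_identity_pct: float | None
    same_family: bool | None
    same_subfamily: bool | None


def pair_gap_distance(a: RepeatElement, b: RepeatElement) -> int:
    """Edge gap in bp between two same-chromosome elements (0 if they touch,
    overlap or nest)."""
    if a.chrom != b.chrom:
        raise ValueError(f"elements on different chromosomes: {a.chrom} vs {b.chrom}")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def nearest_reverse_neighbor(target: RepeatElement,
                             all_repeats: Sequence[RepeatElement]):
    """Nearest opposite-strand repeat on the target's chromosome.

    Returns (neighbor, d) or None.  Ties by smaller gap, then smaller start,
    then id.  Simple linear scan; use batch_nearest_reverse for cohorts.
    """
    best = None
    for r in all_repeats:
        if r.chrom != target.chrom or r.strand == target.strand or r.id == target.id:
            continue
        key = (pair_gap_distance(target, r), r.start, r.id)
        if best is None or key < best[0]:
            best = (key, r)
    if best is None:
        return None
    return best[1], best[0][0]


def neighbor_counts(target: RepeatElement,
                    all_repeats: Sequence[RepeatElement],
                    window: int) -> tuple[int, int]:
    """(same-strand, reverse-strand) counts with gap <= window, excluding self."""
    if window <= 0:
        raise ValueError("window must be positive")
    nss = nrs = 0
    for r in all_repeats:
        if r.chrom != target.chrom or r.id == target.id:
            continue
        if pair_gap_distance(target, r) <= window:
            if r.strand == target.strand:
                nss += 1
            else:
                nrs += 1
    return nss, nrs


def _sorted_arrays(repeats: Sequence[RepeatElement]):
    """Per (chrom, strand): element arrays sorted by (start, id)."""
    groups: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(repeats):
        groups.setdefault((r.chrom, r.strand), []).append(i)
    out = {}
    for key, idxs in groups.items():
        idxs.sort(key=lambda i: (repeats[i].start, repeats[i].id))
        starts = np.array([repeats[i].start for i in idxs], dtype=np.int64)
        ends = np.array([repeats[i].end for i in idxs], dtype=np.int64)
        runmax = np.maximum.accumulate(ends)
        prev = np.concatenate(([np.iinfo(np.int64).min], runmax[:-1]))
        new = ends > prev
        achiever = np.maximum.accumulate(np.where(new, np.arange(len(ends)), 0))
        out[key] = dict(
            idx=np.array(idxs), starts=starts, ends=ends,
            ends_sorted=np.sort(ends), runmax=runmax, achiever=achiever,
        )
    return out


def batch_nearest_reverse(repeats: Sequence[RepeatElement]) -> dict[str, tuple[str, int]]:
    """Nearest reversely oriented neighbor for every element, vectorized.

    Returns alu_id -> (neighbor_id, d); elements with no opposite-strand
    repeat on their chromosome are absent from the mapping.
    """
    groups = _sorted_arrays(repeats)
    result: dict[str, tuple[str, int]] = {}
    for (chrom, strand), g in groups.items():
        opp = groups.get((chrom, "-" if strand == "+" else "+"))
        if opp is None:
            continue
        tstart = g["starts"]
        tend = g["ends"]
        ostart, orm, oach = opp["starts"], opp["runmax"], opp["achiever"]
        m = len(ostart)

        # smallest-start element whose end reaches the target => gap 0
        k = np.searchsorted(orm, tstart, side="left")
        k_ok = (k < m) & (ostart[np.clip(k, 0, m - 1)] <= tend)

        # no-overlap case: left = indices < r (max end), right = index r
        r = np.searchsorted(ostart, tend, side="right")
        has_left = r > 0
        left_idx = oach[np.clip(r - 1, 0, m - 1)]
        left_gap = np.where(has_left, tstart - orm[np.clip(r - 1, 0, m - 1)], np.iinfo(np.int64).max)
        has_right = r < m
        right_idx = np.clip(r, 0, m - 1)
        right_gap = np.where(has_right, ostart[right_idx] - tend, np.iinfo(np.int64).max)

        for j in range(len(tstart)):
            tid = repeats[g["idx"][j]].id
            if k_ok[j]:
                nb = repeats[opp["idx"][k[j]]]
                result[tid] = (nb.id, 0)
                continue
            cands = []
            if has_left[j]:
                nb = repeats[opp["idx"][left_idx[j]]]
                cands.append((int(left_gap[j]), nb.start, nb.id))
            if has_right[j]:
                nb = repeats[opp["idx"][right_idx[j]]]
                cands.append((int(right_gap[j]), nb.start, nb.id))
            if cands:
                gap, _, nid = min(cands)
                result[tid] = (nid, gap)
    return result


def batch_neighbor_counts(repeats: Sequence[RepeatElement],
                          window: int) -> dict[str, tuple[int, int]]:
    """(nss, nrs) for every element at the given window, vectorized."""
    if window <= 0:
        raise ValueError("window must be positive")
    groups = _sorted_arrays(repeats)
    result: dict[str, tuple[int, int]] = {}
    for (chrom, strand), g in groups.items():
        tstart, tend = g["starts"], g["ends"]
        counts = {}
        for pool_strand in "+-":
            pool = groups.get((chrom, pool_strand))
            if pool is None:
                counts[pool_strand] = np.zeros(len(tstart), dtype=np.int64)
                continue
            hi = np.searchsorted(pool["starts"], tend + window, side="right")
            lo = np.searchsorted(pool["ends_sorted"], tstart - window, side="left")
            counts[pool_strand] = hi - lo
        nss = counts[strand] - 1  # self always within its own window
        nrs = counts["-" if strand == "+" else "+"]
        for j, i in enumerate(g["idx"]):
            result[repeats[i].id] = (int(nss[j]), int(nrs[j]))
    return result


def _segment_index(gene: GeneModel, point: float):
    """('exon', i) / ('intron', i) for the segment containing the point."""
    for i, (s, e) in enumerate(gene.exons):
        if s <= point < e:
            return ("exon", i)
        if point < s:
            return ("intron", i - 1) if i > 0 else ("intron", -1)
    return ("intron", len(gene.exons) - 1)


def classify_segment_relation(alu: GenicAlu, neighbor: RepeatElement,
                              gene: GeneModel) -> str:
    """Exon/intron co-residence of an Alu and its neighbor, by midpoints."""
    nb_mid = neighbor.midpoint
    if not (gene.tx_start <= nb_mid < gene.tx_end):
        return "neighbor_outside_gene"
    a_seg = _segment_index(gene, alu.element.midpoint)
    n_seg = _segment_index(gene, nb_mid)
    if a_seg == n_seg:
        return "same_exon" if a_seg[0] == "exon" else "same_intron"
    return "different_segment"


def pair_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the best local alignment of seq_a against the
    reverse complement of seq_b (the opposite-strand pairing partner).

    BLASTN-like scoring: match +2, mismatch -3, gap of length k costs 5+2k.
    Identity = 100 * matched columns / alignment columns.
    """
    return local_identity(seq_a, _revcomp(seq_b))


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return seq.translate(_COMP)[::-1]


def build_feature_table(genic_alus: Sequence[GenicAlu],
                        all_repeats: Sequence[RepeatElement],
                        genes: Sequence[GeneModel],
                        sequences: Mapping[str, str] | None = None,
                        ) -> list[ArchitectureFeatures]:
    """One ArchitectureFeatures record per genic Alu.

    Identity fields are filled only when sequences (keyed by element id)
    are supplied.  Elements lacking any reverse-oriented repeat on their
    chromosome get d absent; downstream models exclude those records.
    """
    nearest = batch_nearest_reverse(all_repeats)
    wide = batch_neighbor_counts(all_repeats, WINDOW_WIDE)
    narrow = batch_neighbor_counts(all_repeats, WINDOW_NARROW)
    by_id = {r.id: r for r in all_repeats}
    genes_by_id = {g.gene_id: g for g in genes}

    out = []
    for ga in genic_alus:
        el = ga.element
        nb_info = nearest.get(el.id)
        nss10, nrs10 = wide.get(el.id, (0, 0))
        nss2, nrs2 = narrow.get(el.id, (0, 0))
        if nb_info is None:
            out.append(ArchitectureFeatures(
                el.id, None, None, None, nss10, nrs10, nss2, nrs2,
                "unknown", None, None, None))
            continue
        nb_id, d = nb_info
        nb = by_id[nb_id]
        relation = classify_segment_relation(ga, nb, genes_by_id[ga.gene_id])
        ident = None
        if sequences is not None and el.id in sequences and nb_id in sequences:
            ident = pair_identity(sequences[el.id], sequences[nb_id])
        out.append(ArchitectureFeatures(
            el.id, int(d), nb_id, nb.length, nss10, nrs10, nss2, nrs2,
            relation, ident,
            el.family == nb.family, el.name == nb.name,
        ))
    return out


def features_frame(features: Sequence[ArchitectureFeatures]) -> pd.DataFrame:
    rows = []
    for f in features:
        rows.append((
            f.alu_id,
            f.d if f.d is not None else np.nan,
            f.neighbor_id,
            f.neighbor_length if f.neighbor_length is not None else np.nan,
            f.nss_10k, f.nrs_10k, f.nss_2k, f.nrs_2k,
            f.segment_relation,
            f.pair_identity_pct if f.pair_identity_pct is not None else np.nan,
            f.same_family, f.same_subfamily,
        ))
    return pd.DataFrame(rows, columns=[
        "alu_id", "d", "neighbor_id", "neighbor_length",
        "nss_10k", "nrs_10k", "nss_2k", "nrs_2k",
        "segment_relation", "pair_identity_pct", "same_family", "same_subfamily",
    ])


def write_features(features: Sequence[ArchitectureFeatures], path) -> None:
    features_frame(features).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_fasta_sequences(path) -> dict[str, str]:
    """Sequences keyed by record id (ids must match element ids)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
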