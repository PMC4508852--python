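"""Gene-neighborhood functional consistency of annotated ORFans.

For each annotated ORFan, S counts GO terms shared between its assigned term
set and the union of terms of its qualifying neighbors: the nearest CDS on
either side on the same contig, kept only if on the same strand and within
1 kb (nearest boundary to nearest boundary, inclusive).  S_m sums S over all
ORFans of a metagenome.  Significance comes from a permutation null: ORFan
identities (term sets) are shuffled uniformly over the fixed set of original
ORFan positions while every other CDS stays put; S_m is recomputed for each
of n permutations and an add-one p-value and z-score are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import group_by_contig

NEIGHBOR_WINDOW_NT = 1000


@dataclass
class ContextResult:
    metagenome: str
    per_orfan_S: dict[str, int]
    S_m: int
    null_values: list[int]
    null_mean: float
    null_sd: float
    z: float
    p_value: float
    S_m_excluding_orfan_neighbors: int = 0


def find_neighbors(orfan_cds, contig_cds_list,
                   window: int = NEIGHBOR_WINDOW_NT) -> list:
    """Up to two qualifying neighbors of an ORFan CDS.

    The nearest CDS upstream and the nearest downstream on the contig are
    candidates; each is kept only if it lies on the same strand as the ORFan
    and the gap between nearest boundaries is <= ``window`` (inclusive).
    ``contig_cds_list`` must be position-sorted.
    """
    neighbors = []
    up = None
    down = None
    for cds in contig_cds_list:
        if cds.cds_id == orfan_cds.cds_id:
            continue
        if cds.start < orfan_cds.start or (cds.start == orfan_cds.start
                                           and cds.cds_id < orfan_cds.cds_id):
            up = cds  # list is sorted: the last such CDS is the nearest upstream
        elif down is None:
            down = cds
    for cand in (up, down):
        if cand is None:
            continue
        gap = max(cand.start - orfan_cds.end, orfan_cds.start - cand.end, 0)
        if cand.strand == orfan_cds.strand and gap <= window:
            neighbors.append(cand)
    return neighbors


def shared_terms(orfan_terms: set, neighbor_term_sets) -> int:
    """S = |orfan terms ∩ union of neighbor term sets|."""
    union: set = set()
    for t in neighbor_term_sets:
        union |= t
    return len(set(orfan_terms) & union)


def _neighbor_ids(orfan_ids, cds_records, window):
    """Map each ORFan cds_id to the ids of its qualifying neighbors."""
    contigs = group_by_contig(cds_records)
    by_id = {c.cds_id: c for c in cds_records}
    out = {}
    for oid in orfan_ids:
        cds = by_id[oid]
        out[oid] = [n.cds_id for n in find_neighbors(cds, contigs[cds.contig_id], window)]
    return out


def permutation_test(orfan_ids, cds_records, assignments: dict[str, set],
                     n: int = 1000, seed=0, metagenome: str = "",
                     window: int = NEIGHBOR_WINDOW_NT) -> ContextResult:
    """S_m with its 1000-shuffle permutation null.

    ``orfan_ids`` are the annotated ORFan CDS ids; ``assignments`` maps any
    cds_id to its GO term set (missing ids contribute no terms).  Each
    permutation reassigns the ORFan term sets uniformly at random over the
    original ORFan positions; neighbors that are themselves ORFans follow the
    permutation.  p is the add-one permutation p-value.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    orfan_ids = list(orfan_ids)
    if len(orfan_ids) < 2:
        raise ValueError("permutation test needs >= 2 ORFans")
    neigh = _neighbor_ids(orfan_ids, cds_records, window)
    orfan_set = set(orfan_ids)

    def terms_of(cds_id, perm_terms):
        if cds_id in perm_terms:
            return perm_terms[cds_id]
        return assignments.get(cds_id, set())

    def total_S(perm_terms, exclude_orfan_neighbors=False):
        per = {}
        for oid in orfan_ids:
            nbr_ids = neigh[oid]
            if exclude_orfan_neighbors:
                nbr_ids = [i for i in nbr_ids if i not in orfan_set]
            per[oid] = shared_terms(terms_of(oid, perm_terms),
                                    [terms_of(i, perm_terms) for i in nbr_ids])
        return per

    identity = {oid: assignments.get(oid, set()) for oid in orfan_ids}
    per_orfan = total_S(identity)
    S_m = sum(per_orfan.values())
    S_m_excl = sum(total_S(identity, exclude_orfan_neighbors=True).values())

    term_sets = [assignments.get(oid, set()) for oid in orfan_ids]
    null_values = []
    for _ in range(n):
        perm = rng.permutation(len(orfan_ids))
        perm_terms = {orfan_ids[i]: term_sets[perm[i]] for i in range(len(orfan_ids))}
        null_values.append(sum(total_S(perm_terms).values()))
    null = np.asarray(null_values, dtype=float)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    z = (S_m - null_mean) / null_sd if null_sd > 0 else 0.0
    p = (1 + int((null >= S_m).sum())) / (1 + n)
    return ContextResult(metagenome=metagenome, per_orfan_S=per_orfan, S_m=S_m,
                         null_values=[int(v) for v in null_values],
                         null_mean=null_mean, null_sd=null_sd, z=float(z),
                         p_value=p, S_m_excluding_orfan_neighbors=S_m_excl)
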