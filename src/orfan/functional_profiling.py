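"""GO-term functional profiles: enrichment, environment specificity, clustering.

Term frequencies are computed as the proportion of entities (ORFan clusters,
or reference CDSs) carrying a term, with zero counts replaced by a unit
pseudocount before proportioning.  Enrichment of a term among ORFans is the
fold change of proportions plus a one-sided (greater) exact binomial test
against the reference proportion, Benjamini-Hochberg adjusted across terms;
the same test is run against the template-library term frequencies.

Environment specificity tests, per key (top-hit template or GO term) and per
metagenome, whether the key's per-metagenome proportion exceeds the pooled
proportion of the other two metagenomes (binomial, Bonferroni-corrected).

Profile clustering uses 1 - Pearson correlation over the union term space
with average linkage, emitted as a newick string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    go_id: str
    metagenome: str
    orfan_cluster_count: int
    orfan_cds_count: int
    prop_orfan: float
    prop_ref: float
    fold: float
    p_vs_ref: float
    p_adj_vs_ref: float = float("nan")
    p_vs_library: float = float("nan")
    p_adj_vs_library: float = float("nan")


@dataclass
class SpecificityRow:
    key: str
    metagenomes: list[str]
    counts: list[int]
    prop: list[float]
    p_bonferroni: list[float]


def reference_subset(pfam_annotated_cds, n: int = 10000, seed=0) -> list:
    """Uniform sample without replacement of Pfam-annotated CDSs.

    If the population is smaller than ``n`` the whole population is returned
    (with a log message).
    """
    if n <= 0:
        raise ValueError("subset size must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = list(pfam_annotated_cds)
    if len(pop) <= n:
        if len(pop) < n:
            logger.info("population %d < requested %d; using all", len(pop), n)
        return pop
    idx = rng.choice(len(pop), size=n, replace=False)
    return [pop[i] for i in sorted(idx)]


def term_frequencies(entity_terms: dict[str, set], term_universe=None
                     ) -> dict[str, tuple[int, float]]:
    """term -> (count, proportion) over entities; zero counts pseudocounted to 1.

    ``entity_terms`` maps entity id -> its term set.  If ``term_universe`` is
    given, every universe term is reported (absent ones with the unit
    pseudocount); otherwise only observed terms are.
    """
    if not entity_terms:
        raise ValueError("empty entity set")
    total = len(entity_terms)
    counts: dict[str, int] = {}
    for terms in entity_terms.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    universe = set(counts) if term_universe is None else set(term_universe)
    out = {}
    for t in universe:
        c = counts.get(t, 0)
        c_eff = max(c, 1)
        out[t] = (c, c_eff / total)
    return out


def fold_change(prop_orfan: float, prop_ref: float) -> float:
    """Ratio of post-pseudocount proportions."""
    if prop_ref <= 0:
        raise ValueError("reference proportion must be positive (pseudocounted)")
    return prop_orfan / prop_ref


def enrichment_test(count: int, total: int, background_prop: float,
                    direction: str = "greater") -> float:
    """Exact one-sided binomial tail P(X >= count | n=total, p=background)."""
    if not (0 < background_prop < 1):
        raise ValueError("background proportion must be in (0,1)")
    if direction != "greater":
        raise ValueError("only the 'greater' direction is supported")
    if count <= 0:
        return 1.0
    return float(binom.sf(count - 1, total, background_prop))


def enrich(orfan_terms_by_cluster: dict[str, set],
           ref_terms_by_entity: dict[str, set],
           library_terms_by_entity: dict[str, set] | None = None,
           metagenome: str = "",
           orfan_cds_counts: dict[str, int] | None = None
           ) -> list[EnrichmentRow]:
    """Per-term enrichment of ORFan clusters against a reference subset.

    Tests every term observed among the ORFan clusters.  ``orfan_cds_counts``
    optionally maps cluster id -> member count to report CDS-level counts.
    """
    n_orfan = len(orfan_terms_by_cluster)
    orfan_freq = term_frequencies(orfan_terms_by_cluster)
    terms = sorted(orfan_freq)
    ref_freq = term_frequencies(ref_terms_by_entity, term_universe=terms)
    lib_freq = (term_frequencies(library_terms_by_entity, term_universe=terms)
                if library_terms_by_entity else None)
    rows = []
    for t in terms:
        c, prop_o = orfan_freq[t]
        _, prop_r = ref_freq[t]
        cds_count = 0
        if orfan_cds_counts:
            cds_count = sum(orfan_cds_counts.get(cid, 0)
                            for cid, ts in orfan_terms_by_cluster.items() if t in ts)
        row = EnrichmentRow(
            go_id=t, metagenome=metagenome, orfan_cluster_count=c,
            orfan_cds_count=cds_count, prop_orfan=prop_o, prop_ref=prop_r,
            fold=fold_change(prop_o, prop_r),
            p_vs_ref=enrichment_test(c, n_orfan, min(prop_r, 1 - 1e-12)))
        if lib_freq:
            _, prop_l = lib_freq[t]
            row.p_vs_library = enrichment_test(c, n_orfan, min(prop_l, 1 - 1e-12))
        rows.append(row)
    if rows:
        adj = multipletests([r.p_vs_ref for r in rows], method="fdr_bh")[1]
        for r, a in zip(rows, adj):
            r.p_adj_vs_ref = float(a)
        if lib_freq:
            adj = multipletests([r.p_vs_library for r in rows], method="fdr_bh")[1]
            for r, a in zip(rows, adj):
                r.p_adj_vs_library = float(a)
    return rows


def specificity_test(counts_by_key: dict[str, dict[str, int]],
                     totals: dict[str, int]) -> list[SpecificityRow]:
    """Three-way environment-specificity binomial tests with Bonferroni.

    For each key and metagenome, the key's count out of that metagenome's
    total is tested against a background probability pooled from the other
    metagenomes (unit pseudocount when the pooled count is zero).  Bonferroni
    correction spans every p-value computed.
    """
    mgs = sorted(totals)
    rows = []
    raw: list[float] = []
    for key in sorted(counts_by_key):
        counts = [counts_by_key[key].get(mg, 0) for mg in mgs]
        if sum(counts) == 0:
            continue
        props, ps = [], []
        for i, mg in enumerate(mgs):
            other_count = sum(c for j, c in enumerate(counts) if j != i)
            other_total = sum(totals[m] for j, m in enumerate(mgs) if j != i)
            p0 = max(other_count, 1) / other_total
            p0 = min(p0, 1 - 1e-12)
            props.append(counts[i] / totals[mg] if totals[mg] else 0.0)
            ps.append(enrichment_test(counts[i], totals[mg], p0))
        rows.append(SpecificityRow(key=key, metagenomes=mgs, counts=counts,
                                   prop=props, p_bonferroni=ps))
        raw.extend(ps)
    m = len(raw)
    for row in rows:
        row.p_bonferroni = [min(1.0, p * m) for p in row.p_bonferroni]
    return rows


def profile_clustering(profiles: dict[str, dict[str, float]]) -> str:
    """Average-linkage clustering of term-frequency profiles; newick output.

    Distance is 1 - Pearson correlation over the union term space.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    names = sorted(profiles)
    terms = sorted(set().union(*(profiles[n].keys() for n in names)))
    mat = np.array([[profiles[n].get(t, 0.0) for t in terms] for n in names])
    corr = np.corrcoef(mat)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 2.0)
    linkage = average(squareform(dist, checks=False))
    return _linkage_to_newick(linkage, names)


def _linkage_to_newick(linkage: np.ndarray, names: list[str]) -> str:
    n = len(names)
    heights = {i: 0.0 for i in range(n)}
    nodes: dict[int, str] = {i: names[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = max(h / 2 - heights[a], 0.0)
        lb = max(h / 2 - heights[b], 0.0)
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h / 2
    return nodes[n + len(linkage) - 1] + ";"
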