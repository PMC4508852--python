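"""The ORFan-calling funnel.

Predicted CDSs are reduced to ORFan families in four steps:

1. low-complexity filtering — CDSs whose protein is more than 40% repetitive
   (sliding-window Shannon entropy masking) are discarded;
2. domain screening — CDSs with a conserved-domain hit at E < 1e-3 are set
   aside as homology-annotatable;
3. greedy identity clustering at 60% (CD-HIT-style: longest sequence founds a
   cluster, later sequences join the first cluster whose representative they
   match) followed by removal of spurious clusters (singletons, short
   representatives, near-identical clusters);
4. nr screening of cluster representatives — clusters whose representative
   has a protein-database hit at E < 1e-3 are annotatable; the rest are the
   ORFans.

The per-metagenome funnel counts are conserved: every predicted CDS is
accounted for exactly once.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._align import global_align_stats

ENTROPY_WINDOW = 12
ENTROPY_THRESHOLD = 2.2  # bits; windows below this are masked


@dataclass
class SequenceCluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str
    spurious_reason: str | None = None  # singleton | short_representative | low_variation

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class FunnelCounts:
    """Per-metagenome CDS accounting at each funnel stage."""

    metagenome: str
    predicted: int = 0
    removed_domain_hits: int = 0
    removed_spurious: int = 0
    removed_repetitive: int = 0  # sub-count included in removed_spurious
    removed_nr_hits: int = 0
    candidate_orfans: int = 0
    orfan_clusters: int = 0

    def check(self) -> None:
        total = (self.removed_domain_hits + self.removed_spurious
                 + self.removed_nr_hits + self.candidate_orfans)
        if total != self.predicted:
            raise ValueError(
                f"{self.metagenome}: funnel counts {total} != predicted {self.predicted}")


# ---------------------------------------------------------------------------
# low-complexity filter

def _window_entropy(window: str) -> float:
    counts = Counter(window)
    n = len(window)
    return -sum(c / n * math.log2(c / n) for c in counts.values())


def low_complexity_fraction(aa_seq: str) -> float:
    """Fraction of residues inside low-entropy windows.

    Sliding window of 12 residues, stride 1; a window is masked when its
    Shannon entropy is below 2.2 bits; overlapping masked windows merge.
    Sequences shorter than the window are scored as one whole-sequence window.
    """
    if not aa_seq:
        raise ValueError("empty sequence")
    n = len(aa_seq)
    if n < ENTROPY_WINDOW:
        return 1.0 if _window_entropy(aa_seq) < ENTROPY_THRESHOLD else 0.0
    masked = np.zeros(n, dtype=bool)
    for i in range(n - ENTROPY_WINDOW + 1):
        if _window_entropy(aa_seq[i:i + ENTROPY_WINDOW]) < ENTROPY_THRESHOLD:
            masked[i:i + ENTROPY_WINDOW] = True
    return float(masked.sum()) / n


def filter_repetitive(cds_list, max_fraction: float = 0.40):
    """Split CDSs into (kept, discarded); discarded iff fraction > threshold."""
    kept, discarded = [], []
    for cds in cds_list:
        if low_complexity_fraction(cds.aa_seq) > max_fraction:
            discarded.append(cds)
        else:
            kept.append(cds)
    return kept, discarded


# ---------------------------------------------------------------------------
# identity + clustering

def pairwise_identity(a: str, b: str) -> float:
    """Percent identity over the shorter sequence (CD-HIT convention).

    Identities are counted in an optimal global alignment under unit scores
    (match +1, mismatch 0, gap -1); among co-optimal alignments the one with
    most identities defines the count.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    _, matches = global_align_stats(a, b)
    return 100.0 * matches / min(len(a), len(b))


def greedy_cluster(cds_list, threshold: float = 60.0) -> list[SequenceCluster]:
    """Deterministic greedy first-fit clustering by representative identity.

    Sequences are visited longest-first (ties by id); each joins the first
    existing cluster whose representative it matches at >= threshold percent
    identity, else founds a new cluster.
    """
    ordered = sorted(cds_list, key=lambda c: (-len(c.aa_seq), c.cds_id))
    clusters: list[SequenceCluster] = []
    reps: list[str] = []  # representative sequences, parallel to clusters
    for cds in ordered:
        for cl, rep_seq in zip(clusters, reps):
            if pairwise_identity(cds.aa_seq, rep_seq) >= threshold:
                cl.member_ids.append(cds.cds_id)
                break
        else:
            clusters.append(SequenceCluster(
                cluster_id=f"cl{len(clusters):05d}",
                member_ids=[cds.cds_id],
                representative_id=cds.cds_id))
            reps.append(cds.aa_seq)
    return clusters


def mark_spurious(clusters, sequences: dict[str, str],
                  min_rep_length: int = 100,
                  identity_threshold: float = 99.0) -> list[SequenceCluster]:
    """Flag spurious clusters in a fixed rule order.

    singleton -> representative shorter than ``min_rep_length`` aa ->
    all non-representative members at >= ``identity_threshold`` percent
    identity to the representative.  The first matching rule is recorded.
    """
    for cl in clusters:
        rep = sequences[cl.representative_id]
        if cl.size == 1:
            cl.spurious_reason = "singleton"
        elif len(rep) < min_rep_length:
            cl.spurious_reason = "short_representative"
        else:
            others = [m for m in cl.member_ids if m != cl.representative_id]
            if others and all(pairwise_identity(sequences[m], rep) >= identity_threshold
                              for m in others):
                cl.spurious_reason = "low_variation"
            else:
                cl.spurious_reason = None
    return clusters


# ---------------------------------------------------------------------------
# ORFan definition + funnel accounting

def call_orfans(clusters, domain_hits, nr_hits, evalue_cutoff: float = 1e-3,
                *, cds_by_id: dict | None = None,
                removed_domain_ids=(), removed_repetitive_ids=()):
    """Split non-spurious clusters into ORFans vs nr-annotated clusters.

    A cluster is an ORFan iff its representative has no nr hit with
    E < ``evalue_cutoff`` (a best hit at exactly the cutoff still *exceeds*
    it, so the comparison is strict).  ``domain_hits`` is keyed by cds_id and
    ``nr_hits`` by representative cds_id; hits naming unknown ids are an
    error.  Returns (orfan_clusters, annotated_clusters, funnel_counts) where
    funnel_counts maps metagenome -> :class:`FunnelCounts` (a single
    ``combined`` entry when ``cds_by_id`` is not given).
    """
    member_ids = {m for cl in clusters for m in cl.member_ids}
    rep_ids = {cl.representative_id for cl in clusters}
    known = member_ids | set(removed_domain_ids) | set(removed_repetitive_ids)
    for cds_id in domain_hits:
        if cds_id not in known:
            raise ValueError(f"domain hit references unknown cds_id {cds_id!r}")
    for cds_id in nr_hits:
        if cds_id not in rep_ids:
            raise ValueError(f"nr hit references unknown representative {cds_id!r}")

    def significant(hits):
        return any(h.evalue < evalue_cutoff for h in hits)

    orfans, annotated = [], []
    for cl in clusters:
        if cl.spurious_reason is not None:
            continue
        if significant(nr_hits.get(cl.representative_id, [])):
            annotated.append(cl)
        else:
            orfans.append(cl)

    def mg_of(cds_id: str) -> str:
        if cds_by_id is None:
            return "combined"
        return cds_by_id[cds_id].metagenome

    counts: dict[str, FunnelCounts] = defaultdict(lambda: FunnelCounts(""))

    def bump(cds_id, attr, n=1):
        mg = mg_of(cds_id)
        fc = counts[mg]
        fc.metagenome = mg
        setattr(fc, attr, getattr(fc, attr) + n)
        fc.predicted += n

    for cds_id in removed_repetitive_ids:
        bump(cds_id, "removed_spurious")
        counts[mg_of(cds_id)].removed_repetitive += 1
    for cds_id in removed_domain_ids:
        bump(cds_id, "removed_domain_hits")
    for cl in clusters:
        if cl.spurious_reason is not None:
            for m in cl.member_ids:
                bump(m, "removed_spurious")
    for cl in annotated:
        for m in cl.member_ids:
            bump(m, "removed_nr_hits")
    for cl in orfans:
        for m in cl.member_ids:
            bump(m, "candidate_orfans")
        counts[mg_of(cl.representative_id)].orfan_clusters += 1
    result = dict(counts)
    for fc in result.values():
        fc.check()
    return orfans, annotated, result


def domain_screen(cds_list, domain_hits, evalue_cutoff: float = 1e-3):
    """Split CDSs into (without, with) significant domain hits."""
    kept, removed = [], []
    for cds in cds_list:
        if any(h.evalue < evalue_cutoff for h in domain_hits.get(cds.cds_id, [])):
            removed.append(cds)
        else:
            kept.append(cds)
    return kept, removed


# ---------------------------------------------------------------------------
# composition statistics

def gc_content(nt_seq: str) -> float | None:
    """GC percentage over unambiguous bases; None if no A/C/G/T present."""
    counts = Counter(nt_seq.upper())
    acgt = sum(counts[b] for b in "ACGT")
    if acgt == 0:
        return None
    return 100.0 * (counts["G"] + counts["C"]) / acgt


def composition_stats(cds_sets: dict[str, list], min_length_nt: int = 300,
                      length_bins=(0, 300, 600, 900, 1200, 10**9)):
    """Mean GC% and mean nt length (excluding short CDSs) per labelled set.

    Returns (summary_rows, length_histograms, gc_values) where summary_rows
    is a list of dicts with ``set``, ``mean_gc``, ``mean_length_nt`` and
    ``n``; all-ambiguous sequences are excluded from GC with a warning count.
    """
    import logging
    logger = logging.getLogger(__name__)
    rows = []
    gc_values: dict[str, list[float]] = {}
    length_hist: dict[str, list[int]] = {}
    for label, cds_list in cds_sets.items():
        gcs = []
        for cds in cds_list:
            gc = gc_content(cds.nt_seq)
            if gc is None:
                logger.warning("%s: all-ambiguous sequence excluded from GC", cds.cds_id)
                continue
            gcs.append(gc)
        lengths = [c.nt_length for c in cds_list if c.nt_length >= min_length_nt]
        hist = [0] * (len(length_bins) - 1)
        for c in cds_list:
            for k in range(len(length_bins) - 1):
                if length_bins[k] <= c.nt_length < length_bins[k + 1]:
                    hist[k] += 1
                    break
        rows.append({"set": label,
                     "mean_gc": float(np.mean(gcs)) if gcs else float("nan"),
                     "mean_length_nt": float(np.mean(lengths)) if lengths else float("nan"),
                     "n": len(cds_list)})
        gc_values[label] = gcs
        length_hist[label] = hist
    return rows, length_hist, gc_values
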