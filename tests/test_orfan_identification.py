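"""The ORFan-calling funnel: masking, identity, clustering, spurious rules."""

import math
import random
from collections import Counter
from functools import lru_cache

import pytest

from orfan import orfan_identification as oi
from orfan.io_formats import CDSRecord, SearchHit

AA = "ACDEFGHIKLMNPQRSTVWY"


def cds(cds_id, aa_seq, mg="M1", nt_seq=""):
    return CDSRecord(cds_id=cds_id, contig_id="ctg", start=0,
                     end=3 * max(len(aa_seq), 1), strand="+",
                     aa_seq=aa_seq, nt_seq=nt_seq, metagenome=mg)


# ---------------------------------------------------------------------------
# low-complexity masking

def windows_oracle(seq, window=12, threshold=2.2):
    """Independent re-derivation of the masked fraction."""
    if len(seq) < window:
        counts = Counter(seq)
        h = -sum(c / len(seq) * math.log2(c / len(seq)) for c in counts.values())
        return 1.0 if h < threshold else 0.0
    masked = set()
    for i in range(len(seq) - window + 1):
        w = seq[i:i + window]
        counts = Counter(w)
        h = -sum(c / window * math.log2(c / window) for c in counts.values())
        if h < threshold:
            masked.update(range(i, i + window))
    return len(masked) / len(seq)


def test_zero_entropy_repeat_fully_masked():
    assert oi.low_complexity_fraction("A" * 120) == 1.0


def test_diverse_sequence_unmasked():
    seq = (AA * 6)[:120]
    assert oi.low_complexity_fraction(seq) == windows_oracle(seq) == 0.0


def test_half_repeat_half_diverse_matches_oracle():
    rng = random.Random(0)
    diverse = "".join(rng.choice(AA) for _ in range(60))
    seq = "A" * 60 + diverse
    frac = oi.low_complexity_fraction(seq)
    assert frac == pytest.approx(windows_oracle(seq))
    assert 0.4 < frac < 0.7


@pytest.mark.parametrize("n", range(10))
def test_masked_fraction_matches_oracle_random(n):
    rng = random.Random(100 + n)
    seq = "".join(rng.choice("AC" if rng.random() < 0.4 else AA)
                  for _ in range(rng.randint(5, 80)))
    assert oi.low_complexity_fraction(seq) == pytest.approx(windows_oracle(seq))


def test_filter_repetitive_threshold_is_strict():
    # masked fraction 1.0 for pure repeat, 0.0 for diverse
    repeat = cds("r", "AB" * 30)
    diverse = cds("d", (AA * 3)[:60])
    kept, discarded = oi.filter_repetitive([repeat, diverse])
    assert [c.cds_id for c in discarded] == ["r"]
    assert [c.cds_id for c in kept] == ["d"]
    assert oi.filter_repetitive([]) == ([], [])


def test_filter_repetitive_boundary():
    # fraction exactly at the threshold is kept ("over 40%" is strict)
    class Fake:
        aa_seq = "X"
        cds_id = "f"
    import orfan.orfan_identification as mod
    orig = mod.low_complexity_fraction
    try:
        mod.low_complexity_fraction = lambda s: 0.40
        kept, discarded = oi.filter_repetitive([Fake()])
        assert kept and not discarded
        mod.low_complexity_fraction = lambda s: 0.41
        kept, discarded = oi.filter_repetitive([Fake()])
        assert discarded and not kept
    finally:
        mod.low_complexity_fraction = orig


# ---------------------------------------------------------------------------
# pairwise identity vs exhaustive enumeration

def identity_oracle(a, b):
    """Enumerate every alignment; lexicographic (score, matches) objective."""

    @lru_cache(maxsize=None)
    def enum(i, j):
        if i == len(a) and j == len(b):
            return {(0, 0)}
        out = set()
        if i < len(a) and j < len(b):
            eq = 1 if a[i] == b[j] else 0
            out |= {(s + eq, m + eq) for s, m in enum(i + 1, j + 1)}
        if i < len(a):
            out |= {(s - 1, m) for s, m in enum(i + 1, j)}
        if j < len(b):
            out |= {(s - 1, m) for s, m in enum(i, j + 1)}
        return out
    best = max(enum(0, 0))
    return 100.0 * best[1] / min(len(a), len(b))


def test_pairwise_identity_examples():
    assert oi.pairwise_identity("MKVL", "MKVL") == 100.0
    assert oi.pairwise_identity("MKVL", "MKIL") == 75.0
    # shorter-sequence denominator
    assert oi.pairwise_identity("MKV", "MKVLLLL") == 100.0


def test_pairwise_identity_matches_enumeration_oracle():
    rng = random.Random(42)
    for _ in range(200):
        a = "".join(rng.choice("ACDE") for _ in range(rng.randint(2, 7)))
        b = "".join(rng.choice("ACDE") for _ in range(rng.randint(2, 7)))
        assert oi.pairwise_identity(a, b) == pytest.approx(identity_oracle(a, b))


# ---------------------------------------------------------------------------
# clustering

def test_greedy_cluster_identical_and_disjoint():
    a, b = cds("a", "MKVLMKVLMKVL"), cds("b", "MKVLMKVLMKVL")
    c = cds("c", "WWWWYYYYFFFF")
    clusters = oi.greedy_cluster([a, b, c])
    sizes = sorted(cl.size for cl in clusters)
    assert sizes == [1, 2]
    two = next(cl for cl in clusters if cl.size == 2)
    assert two.representative_id == "a"  # equal length: lexicographically first


def test_greedy_cluster_recovers_planted_families(small_sim):
    fam_of = small_sim.family_of()
    fams = list(small_sim.families.values())[:6]
    records = [cds(m, f.sequences[m]) for f in fams for m in f.member_ids]
    clusters = oi.greedy_cluster(records)
    got = {frozenset(cl.member_ids) for cl in clusters}
    want = {frozenset(f.member_ids) for f in fams}
    assert got == want
    # every member within threshold of its representative
    seqs = {c.cds_id: c.aa_seq for c in records}
    for cl in clusters:
        for m in cl.member_ids:
            assert oi.pairwise_identity(seqs[m], seqs[cl.representative_id]) >= 60.0


def test_greedy_cluster_deterministic(small_sim):
    f = list(small_sim.families.values())[0]
    records = [cds(m, f.sequences[m]) for m in f.member_ids]
    c1 = oi.greedy_cluster(records)
    c2 = oi.greedy_cluster(list(reversed(records)))
    assert [cl.member_ids for cl in c1] == [cl.member_ids for cl in c2]


# ---------------------------------------------------------------------------
# spurious rules

def test_mark_spurious_rule_order_and_boundaries():
    seqs = {
        "solo": "M" * 150,
        "short_rep": "M" * 99, "short_m2": "M" * 90, "short_m3": "M" * 80,
        "rep": "MKVL" * 50,  # 200 aa
    }
    # low-variation cluster: members >= 99% identical to rep
    seqs["near1"] = "A" + seqs["rep"][1:]         # 199/200 = 99.5%
    seqs["near2"] = seqs["rep"]                   # 100%
    seqs["far"] = "AAAA" + seqs["rep"][4:]        # 196/200 = 98%
    mk = lambda cid, members: oi.SequenceCluster(cid, members, members[0])

    clusters = oi.mark_spurious(
        [mk("c1", ["solo"]),
         mk("c2", ["short_rep", "short_m2", "short_m3"]),
         mk("c3", ["rep", "near1", "near2"]),
         mk("c4", ["rep", "near1", "far"])],
        seqs)
    reasons = {cl.cluster_id: cl.spurious_reason for cl in clusters}
    assert reasons == {"c1": "singleton", "c2": "short_representative",
                       "c3": "low_variation", "c4": None}


# ---------------------------------------------------------------------------
# ORFan definition + funnel conservation

def _cluster_fixture():
    seqs = {f"m{i}": "MKVL" * 30 for i in range(6)}
    cl1 = oi.SequenceCluster("cl1", ["m0", "m1"], "m0")
    cl2 = oi.SequenceCluster("cl2", ["m2", "m3"], "m2")
    cl3 = oi.SequenceCluster("cl3", ["m4"], "m4", spurious_reason="singleton")
    cds_by_id = {f"m{i}": cds(f"m{i}", seqs[f"m{i}"]) for i in range(5)}
    cds_by_id["dom"] = cds("dom", "MKVL" * 30)
    return [cl1, cl2, cl3], cds_by_id


def test_call_orfans_cutoff_is_strict():
    clusters, cds_by_id = _cluster_fixture()
    nr = {"m0": [SearchHit("m0", "nr1", evalue=1e-3)],   # exactly at cutoff
          "m2": [SearchHit("m2", "nr1", evalue=1e-4)]}   # below cutoff
    orfans, annotated, counts = oi.call_orfans(
        clusters, {}, nr, cds_by_id=cds_by_id)
    assert [cl.cluster_id for cl in orfans] == ["cl1"]
    assert [cl.cluster_id for cl in annotated] == ["cl2"]


def test_call_orfans_funnel_conservation():
    clusters, cds_by_id = _cluster_fixture()
    nr = {"m2": [SearchHit("m2", "nr1", evalue=1e-8)]}
    domain = {"dom": [SearchHit("dom", "PF1", evalue=1e-9)]}
    orfans, annotated, counts = oi.call_orfans(
        clusters, domain, nr, cds_by_id=cds_by_id,
        removed_domain_ids=["dom"], removed_repetitive_ids=[])
    fc = counts["M1"]
    fc.check()
    assert fc.predicted == 6
    assert fc.removed_domain_hits == 1
    assert fc.removed_spurious == 1
    assert fc.removed_nr_hits == 2
    assert fc.candidate_orfans == 2
    assert fc.orfan_clusters == 1


def test_call_orfans_unknown_id_is_error():
    clusters, cds_by_id = _cluster_fixture()
    with pytest.raises(ValueError, match="ghost"):
        oi.call_orfans(clusters, {"ghost": []}, {}, cds_by_id=cds_by_id)
    with pytest.raises(ValueError, match="m1"):
        # m1 is a member but not a representative
        oi.call_orfans(clusters, {}, {"m1": []}, cds_by_id=cds_by_id)


# ---------------------------------------------------------------------------
# composition

def test_composition_stats():
    sets = {"s": [cds("a", "MK", nt_seq="ATGTGC"),                 # 50% GC, 6 nt
                  cds("b", "M" * 100, nt_seq="GC" * 150),          # 100% GC, 300 nt
                  cds("c", "M" * 200, nt_seq="AT" * 300)]}         # 0% GC, 600 nt
    rows, hist, gc = oi.composition_stats(sets)
    (row,) = rows
    assert row["mean_gc"] == pytest.approx((50 + 100 + 0) / 3)
    # 6 nt sequence excluded from the length mean
    assert row["mean_length_nt"] == pytest.approx(450.0)


def test_gc_content_all_ambiguous():
    assert oi.gc_content("NNNN") is None
    assert oi.gc_content("ATGC") == 50.0
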