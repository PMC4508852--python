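"""Term frequencies, fold changes, binomial enrichment, specificity, clustering."""

import math

import numpy as np
import pytest

from orfan import functional_profiling as fp


# ---------------------------------------------------------------------------
# frequencies and folds

def test_term_frequencies_pseudocount():
    entities = {"e1": {"A"}, "e2": {"A", "B"}, "e3": set(), "e4": set()}
    freq = fp.term_frequencies(entities, term_universe={"A", "B", "C"})
    assert freq["A"] == (2, 0.5)
    assert freq["B"] == (1, 0.25)
    assert freq["C"] == (0, 0.25)  # zero count -> pseudocount 1
    with pytest.raises(ValueError):
        fp.term_frequencies({})


def test_fold_change_reproduces_reported_ratios():
    # printed proportion pairs and the folds they imply
    cases = [
        (7.8e-3, 2.0e-3, 3.9),    # ribonuclease activity, gut
        (1.8e-2, 6.7e-3, 2.7),    # endonuclease activity, ocean
        (3.0e-3, 1.1e-4, 27.3),   # PI alpha-mannosyltransferase, ocean
        (2.3e-3, 1.2e-4, 19.2),   # viral release from host cell, soil
        (5.9e-3, 4.9e-4, 12.0),   # dibenzothiophene catabolism, soil
        (2.1e-2, 4.6e-3, 4.6),    # polysaccharide catabolism, gut
    ]
    for p_orfan, p_ref, fold in cases:
        assert round(fp.fold_change(p_orfan, p_ref), 1) == fold
    assert fp.fold_change(0.5, 0.5) == 1.0


# ---------------------------------------------------------------------------
# binomial test vs direct summation

def binom_tail_oracle(count, n, p):
    return sum(math.comb(n, k) * p ** k * (1 - p) ** (n - k)
               for k in range(count, n + 1))


def test_enrichment_test_matches_direct_summation():
    rng = np.random.default_rng(4)
    assert fp.enrichment_test(8, 20, 0.1) == pytest.approx(
        binom_tail_oracle(8, 20, 0.1))
    for _ in range(50):
        n = int(rng.integers(1, 60))
        count = int(rng.integers(0, n + 1))
        p = float(rng.uniform(0.01, 0.9))
        assert fp.enrichment_test(count, n, p) == pytest.approx(
            binom_tail_oracle(count, n, p), rel=1e-9)


def test_enrichment_test_edges():
    assert fp.enrichment_test(0, 10, 0.2) == 1.0
    assert fp.enrichment_test(5, 5, 0.1) == pytest.approx(0.1 ** 5)
    with pytest.raises(ValueError):
        fp.enrichment_test(1, 10, 0.0)


def test_enrich_bh_adjustment_is_monotone():
    rng = np.random.default_rng(8)
    orfan = {f"c{i}": {f"T{rng.integers(6)}"} for i in range(60)}
    ref = {f"r{i}": {f"T{rng.integers(12)}"} for i in range(300)}
    rows = fp.enrich(orfan, ref)
    by_raw = sorted(rows, key=lambda r: r.p_vs_ref)
    adj = [r.p_adj_vs_ref for r in by_raw]
    assert adj == sorted(adj)
    for r in rows:
        assert r.fold == pytest.approx(r.prop_orfan / r.prop_ref)


def test_enrich_null_false_positive_rate_controlled():
    """With ORFan and reference terms from one distribution, few terms pass."""
    rng = np.random.default_rng(11)
    flagged, tested = 0, 0
    for _ in range(50):
        terms = [f"T{k}" for k in range(15)]
        orfan = {f"c{i}": {terms[rng.integers(15)]} for i in range(80)}
        ref = {f"r{i}": {terms[rng.integers(15)]} for i in range(400)}
        rows = fp.enrich(orfan, ref)
        tested += len(rows)
        flagged += sum(r.p_adj_vs_ref < 0.05 for r in rows)
    rate = flagged / tested
    se = math.sqrt(0.05 * 0.95 / tested)
    assert rate <= 0.05 + 2 * se


# ---------------------------------------------------------------------------
# reference subset

def test_reference_subset():
    pop = list(range(100))
    small = fp.reference_subset(pop, n=200, seed=1)
    assert small == pop  # population smaller than requested: take all
    sample = fp.reference_subset(pop, n=10, seed=1)
    assert len(sample) == 10 and len(set(sample)) == 10
    assert fp.reference_subset(pop, n=10, seed=1) == sample
    assert fp.reference_subset(pop, n=10, seed=2) != sample
    with pytest.raises(ValueError):
        fp.reference_subset(pop, n=0)


# ---------------------------------------------------------------------------
# environment specificity

def test_specificity_planted_key_detected():
    counts = {"spec": {"M1": 50, "M2": 0, "M3": 0},
              "flat": {"M1": 30, "M2": 30, "M3": 30}}
    totals = {"M1": 1000, "M2": 1000, "M3": 1000}
    rows = fp.specificity_test(counts, totals)
    by_key = {r.key: r for r in rows}
    spec = by_key["spec"]
    i = spec.metagenomes.index("M1")
    assert spec.p_bonferroni[i] < 0.05
    assert all(p > 0.05 for j, p in enumerate(spec.p_bonferroni) if j != i)
    flat = by_key["flat"]
    assert all(p > 0.5 for p in flat.p_bonferroni)
    assert spec.prop[i] == pytest.approx(0.05)


def test_specificity_absent_key_skipped():
    rows = fp.specificity_test({"gone": {"M1": 0, "M2": 0}},
                               {"M1": 10, "M2": 10})
    assert rows == []


# ---------------------------------------------------------------------------
# functional-profile clustering

def test_profile_clustering_recovers_block_structure():
    import dendropy
    rng = np.random.default_rng(3)
    orfan_block = {f"T{k}": 0.0 for k in range(10)}
    ref_block = dict(orfan_block)
    profiles = {}
    for i in range(3):
        o = dict(orfan_block)
        r = dict(ref_block)
        for k in range(5):
            o[f"T{k}"] = 0.2 + rng.normal(0, 0.01)
            r[f"T{k + 5}"] = 0.2 + rng.normal(0, 0.01)
        profiles[f"orfan{i}"] = o
        profiles[f"ref{i}"] = r
    newick = fp.profile_clustering(profiles)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    # the root bipartition splits ORFan profiles from reference profiles
    root_children = tree.seed_node.child_nodes()
    sides = [{leaf.taxon.label for leaf in ch.leaf_iter()}
             for ch in root_children]
    assert {"orfan0", "orfan1", "orfan2"} in sides
    assert {"ref0", "ref1", "ref2"} in sides


def test_profile_clustering_edges():
    with pytest.raises(ValueError):
        fp.profile_clustering({"a": {"T": 1.0}})
    # identical profiles join at distance ~0
    profiles = {"a": {"T1": 1.0, "T2": 0.0}, "b": {"T1": 1.0, "T2": 0.0},
                "c": {"T1": 0.0, "T2": 1.0}}
    newick = fp.profile_clustering(profiles)
    assert newick.endswith(";")
    import dendropy
    tree = dendropy.Tree.get(data=newick, schema="newick")
    clades = [{leaf.taxon.label for leaf in node.leaf_iter()}
              for node in tree.preorder_internal_node_iter()]
    assert {"a", "b"} in clades  # the zero-distance pair joins first
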