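"""Profile-profile remote homology search with decoy-calibrated significance.

The built-in scorer aligns two column-frequency profiles with local
(Smith-Waterman) dynamic programming; the column-pair score is the
log-average-odds sigma(i, j) = log2( sum_a p_i(a) q_j(a) / f(a) ) in bits,
with affine gaps (open 2.5 bits, extend 0.5 bits).

Significance is calibrated empirically on column-shuffled decoy families run
through the identical search path: an E-value from a Gumbel tail fitted to
decoy best scores (method of moments) and a probability score
100 * (1 - localFDR) where localFDR is the monotonized decoy/real score
density ratio.  A hit is significant when probability >= 80 and E-value <= 1
(both inclusive), and the empirical false discovery rate is the ratio of
decoy to real per-query pass rates at those thresholds.

Externally computed HHsearch results (.hhr) can be imported instead of the
built-in scorer; thresholds and downstream logic are identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._align import local_profile_score
from .io_formats import parse_search_hits
from .msa_profiles import ProfileMSA

logger = logging.getLogger(__name__)

EULER_GAMMA = 0.5772156649015329

PROBABILITY_THRESHOLD = 80.0  # inclusive
EVALUE_THRESHOLD = 1.0        # inclusive


@dataclass
class RemoteHit:
    cluster_id: str
    template_id: str
    raw_score: float
    evalue: float
    probability: float
    rank: int = 0
    template_description: str = ""

    @property
    def significant(self) -> bool:
        return is_significant(self.probability, self.evalue)


@dataclass
class FdrEstimate:
    threshold_probability: float
    threshold_evalue: float
    real_pass_rate: float
    decoy_pass_rate: float
    fdr: float | None  # None when real_pass_rate == 0


def is_significant(probability: float, evalue: float,
                   probability_threshold: float = PROBABILITY_THRESHOLD,
                   evalue_threshold: float = EVALUE_THRESHOLD) -> bool:
    return probability >= probability_threshold and evalue <= evalue_threshold


def sigma_matrix(query: ProfileMSA, template: ProfileMSA) -> np.ndarray:
    """log2 average-odds column-pair scores (bits)."""
    odds = query.columns / query.background  # (m, 20)
    dot = odds @ template.columns.T
    return np.log2(np.maximum(dot, 1e-12))


def profile_align(query: ProfileMSA, template: ProfileMSA,
                  gap_open: float = 2.5, gap_extend: float = 0.5) -> float:
    """Local profile-profile alignment score in bits (>= 0, symmetric)."""
    if query.n_columns == 0 or template.n_columns == 0:
        raise ValueError("empty profile")
    return local_profile_score(sigma_matrix(query, template), gap_open, gap_extend)


def _pava_decreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted isotonic regression, non-increasing (pool adjacent violators)."""
    y = list(map(float, y))
    w = list(map(float, w))
    vals, wts, sizes = [], [], []
    for yi, wi in zip(y, w):
        vals.append(yi)
        wts.append(wi)
        sizes.append(1)
        while len(vals) > 1 and vals[-2] < vals[-1]:  # violator: increase
            v = (vals[-1] * wts[-1] + vals[-2] * wts[-2]) / (wts[-1] + wts[-2])
            wt = wts[-1] + wts[-2]
            sz = sizes[-1] + sizes[-2]
            vals = vals[:-2] + [v]
            wts = wts[:-2] + [wt]
            sizes = sizes[:-2] + [sz]
    out = []
    for v, s in zip(vals, sizes):
        out.extend([v] * s)
    return np.array(out)


@dataclass
class Calibration:
    """Decoy-anchored score calibration.

    ``evalue`` follows a Gumbel tail fitted (method of moments) to decoy
    best scores; ``probability`` is 100*(1 - localFDR) with localFDR the
    monotonized decoy/real density ratio on a shared score grid.
    """

    lam: float
    mu: float
    n_templates: int
    grid: np.ndarray
    prob_values: np.ndarray

    def evalue(self, score: float) -> float:
        return float(self.n_templates * math.exp(-self.lam * (score - self.mu)))

    def probability(self, score: float) -> float:
        p = float(np.interp(score, self.grid, self.prob_values))
        return min(100.0, max(0.0, p))


MIN_DECOY_SCORES = 50


def calibrate(scores_real, scores_decoy, n_templates: int,
              n_bins: int = 24) -> Calibration:
    """Fit the decoy-anchored calibration model.

    ``scores_real``/``scores_decoy`` are per-query best scores from the
    identical search path.  Requires at least 50 decoy scores.
    """
    real = np.asarray(scores_real, dtype=float)
    decoy = np.asarray(scores_decoy, dtype=float)
    if decoy.size < MIN_DECOY_SCORES:
        raise ValueError(
            f"calibration needs >= {MIN_DECOY_SCORES} decoy scores, got {decoy.size}")
    sd = decoy.std(ddof=1)
    if sd <= 0:
        raise ValueError("decoy scores are degenerate (zero variance)")
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = decoy.mean() - EULER_GAMMA / lam

    combined = np.concatenate([real, decoy])
    # quantile grid over the combined scores: every bin is populated, so the
    # density ratio is defined everywhere data exist (a uniform grid leaves
    # empty bins in the gulf between decoy and strong-homolog scores)
    edges = np.unique(np.quantile(combined, np.linspace(0.0, 1.0, n_bins + 1)))
    if edges.size < 3:
        edges = np.array([combined.min() - 0.5, combined.mean(),
                          combined.max() + 0.5])
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    hr, _ = np.histogram(real, bins=edges)
    hd, _ = np.histogram(decoy, bins=edges)
    eps = 0.1  # light smoothing: heavy pseudocounts cap the density ratio
    dens_r = (hr + eps) / widths / real.size
    dens_d = (hd + eps) / widths / decoy.size
    lfdr = np.minimum(1.0, dens_d / dens_r)
    weights = hr + hd + 1e-6
    lfdr = np.clip(_pava_decreasing(lfdr, weights), 0.0, 1.0)
    prob = 100.0 * (1.0 - lfdr)
    return Calibration(lam=lam, mu=mu, n_templates=int(n_templates),
                       grid=centers, prob_values=prob)


def search_all(query_profiles: dict[str, ProfileMSA],
               template_library: dict[str, ProfileMSA],
               calibration: Calibration,
               descriptions: dict[str, str] | None = None,
               gap_open: float = 2.5, gap_extend: float = 0.5,
               scores: dict[str, dict[str, float]] | None = None
               ) -> dict[str, list[RemoteHit]]:
    """Score every query against every template; rank hits per query.

    Hits are ranked by probability descending, ties by E-value ascending
    then template id.  ``scores`` may supply precomputed raw scores.
    """
    descriptions = descriptions or {}
    results: dict[str, list[RemoteHit]] = {}
    for qid in sorted(query_profiles):
        q = query_profiles[qid]
        hits = []
        for tid in sorted(template_library):
            if scores is not None and tid in scores.get(qid, {}):
                s = scores[qid][tid]
            else:
                s = profile_align(q, template_library[tid], gap_open, gap_extend)
            hits.append(RemoteHit(
                cluster_id=qid, template_id=tid, raw_score=s,
                evalue=calibration.evalue(s),
                probability=calibration.probability(s),
                template_description=descriptions.get(tid, "")))
        hits.sort(key=lambda h: (-h.probability, h.evalue, h.template_id))
        for rank, h in enumerate(hits, start=1):
            h.rank = rank
        results[qid] = hits
    return results


def all_scores(query_profiles: dict[str, ProfileMSA],
               template_library: dict[str, ProfileMSA],
               gap_open: float = 2.5, gap_extend: float = 0.5
               ) -> dict[str, dict[str, float]]:
    """Raw profile-alignment scores for every query x template pair."""
    out: dict[str, dict[str, float]] = {}
    for qid, q in query_profiles.items():
        out[qid] = {tid: profile_align(q, t, gap_open, gap_extend)
                    for tid, t in template_library.items()}
    return out


def best_scores(score_table: dict[str, dict[str, float]]) -> list[float]:
    return [max(s.values()) for s in score_table.values() if s]


def estimate_fdr(real_results: dict[str, list[RemoteHit]],
                 decoy_results: dict[str, list[RemoteHit]],
                 probability_threshold: float = PROBABILITY_THRESHOLD,
                 evalue_threshold: float = EVALUE_THRESHOLD) -> FdrEstimate:
    """Empirical FDR: decoy per-query pass rate over real per-query pass rate."""

    def pass_rate(results):
        if not results:
            return 0.0
        passed = sum(
            1 for hits in results.values()
            if any(is_significant(h.probability, h.evalue,
                                  probability_threshold, evalue_threshold)
                   for h in hits))
        return passed / len(results)

    real_rate = pass_rate(real_results)
    decoy_rate = pass_rate(decoy_results)
    fdr = None if real_rate == 0 else min(1.0, decoy_rate / real_rate)
    if fdr is None:
        logger.warning("real pass rate is zero; FDR undefined")
    return FdrEstimate(threshold_probability=probability_threshold,
                       threshold_evalue=evalue_threshold,
                       real_pass_rate=real_rate, decoy_pass_rate=decoy_rate,
                       fdr=fdr)


def fdr_from_pass_rates(real_pass_rate: float, decoy_pass_rate: float) -> float | None:
    """The decoy/real pass-rate ratio on raw rates (e.g. from a report table)."""
    if real_pass_rate == 0:
        return None
    return decoy_pass_rate / real_pass_rate


def import_hhr_results(hhr_dir, cluster_ids=None) -> dict[str, list[RemoteHit]]:
    """Load per-cluster HHsearch .hhr files; probability/E-value verbatim.

    Clusters without a file are left unannotated with a warning.
    """
    hhr_dir = Path(hhr_dir)
    results: dict[str, list[RemoteHit]] = {}
    files = {p.stem: p for p in sorted(hhr_dir.glob("*.hhr"))}
    ids = list(cluster_ids) if cluster_ids is not None else sorted(files)
    for cid in ids:
        if cid not in files:
            logger.warning("no HHR file for cluster %s; left unannotated", cid)
            results[cid] = []
            continue
        hits = []
        for rank, h in enumerate(parse_search_hits(files[cid], "hhr"), start=1):
            hits.append(RemoteHit(cluster_id=cid, template_id=h.target_id,
                                  raw_score=h.bitscore, evalue=h.evalue,
                                  probability=h.probability or 0.0, rank=rank,
                                  template_description=h.target_description))
        results[cid] = hits
    return results
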