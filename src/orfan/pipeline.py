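"""End-to-end orchestration of the ORFan analysis.

Stages run in funnel order: repetitive filtering, domain screening, greedy
clustering, spurious-cluster removal, nr screening (ORFan definition),
cluster MSAs and profiles, decoy-calibrated remote homology search with an
empirical FDR, GO assignment, gene-neighborhood context statistics, level-6
enrichment, environment specificity, the HExxH metalloprotease screen and
composition statistics.  Every default threshold matches the analysis the
package reproduces; per-stage random seeds are derived from one master seed
by stage-name hashing so adding a stage never perturbs earlier randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (functional_profiling as fp, genomic_context as gc,
               motif_screen, msa_profiles, orfan_identification as oi,
               remote_homology as rh)
from .io_formats import (attach_sequences, parse_search_hits, read_cds_table,
                         read_fasta, read_go_map, read_obo)
from .ontology_annotation import (Ontology, assign_cluster_terms,
                                  assign_pfam_terms, filter_level)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    evalue_cutoff: float = 1e-3          # domain + nr screening
    cluster_identity: float = 60.0       # percent
    spurious_identity: float = 99.0      # percent
    min_rep_length: int = 100            # aa
    repetitive_fraction: float = 0.40
    probability_threshold: float = 80.0  # inclusive
    evalue_threshold: float = 1.0        # inclusive
    neighbor_window: int = 1000          # nt
    n_permutations: int = 1000
    reference_subset_size: int = 10000
    go_level: int = 6
    pseudocount: float = 1.0
    decoys_per_metagenome: int = 1000
    min_total_decoys: int = 60
    gap_open: float = 2.5
    gap_extend: float = 0.5
    enrichment_denominator: str = "annotated"  # or "all"
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineInputs:
    cds_records: list
    ontology: Ontology
    pfam_go_map: dict
    structure_go_map: dict
    template_msas: dict[str, list[str]]
    template_descriptions: dict[str, str]
    domain_hits: dict[str, list]
    nr_hits: dict[str, list]

    @classmethod
    def from_sim(cls, sim) -> "PipelineInputs":
        return cls(cds_records=sim.cds_records, ontology=sim.ontology,
                   pfam_go_map=sim.pfam_go_map,
                   structure_go_map=sim.structure_go_map,
                   template_msas=sim.template_msas,
                   template_descriptions=sim.template_descriptions,
                   domain_hits=sim.domain_hits, nr_hits=sim.nr_hits)

    @classmethod
    def from_dir(cls, path) -> "PipelineInputs":
        path = Path(path)
        records = read_cds_table(path / "cds_table.tsv")
        attach_sequences(records, aa=dict(read_fasta(path / "proteins.faa")),
                         nt=dict(read_fasta(path / "cds.fna")))
        domain_hits: dict[str, list] = {}
        for h in parse_search_hits(path / "domain_hits.tblout", "hmmer_tblout"):
            domain_hits.setdefault(h.query_id, []).append(h)
        nr_hits: dict[str, list] = {}
        for h in parse_search_hits(path / "nr_hits.blast6", "blast_tab6"):
            nr_hits.setdefault(h.query_id, []).append(h)
        template_msas = {p.stem: [s for _, s in read_fasta(p)]
                         for p in sorted((path / "templates").glob("*.afa"))}
        descriptions = {}
        for line in (path / "template_descriptions.tsv").read_text().splitlines():
            tid, _, desc = line.partition("\t")
            descriptions[tid] = desc
        return cls(cds_records=records, ontology=read_obo(path / "ontology.obo"),
                   pfam_go_map=read_go_map(path / "pfam_go.tsv"),
                   structure_go_map=read_go_map(path / "structure_go.tsv"),
                   template_msas=template_msas,
                   template_descriptions=descriptions,
                   domain_hits=domain_hits, nr_hits=nr_hits)


@dataclass
class PipelineReport:
    funnel: dict
    clusters: dict[str, list]
    orfan_clusters: dict[str, list]
    hits: dict[str, list]
    decoy_hits: dict[str, list]
    fdr: rh.FdrEstimate
    cluster_terms_top3: dict[str, set]
    cluster_terms_confident: dict[str, set]
    cds_terms: dict[str, set]
    context: dict[str, gc.ContextResult]
    enrichment: dict[str, list]
    specificity_templates: list
    specificity_terms: list
    metalloproteases: list
    composition: list
    profiles_newick: str
    annotated_orfan_clusters: dict[str, list]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs,
                 outdir=None) -> PipelineReport:
    """Run all stages and optionally write the report tables to ``outdir``."""
    cds_by_id = {c.cds_id: c for c in inputs.cds_records}
    seqs = {c.cds_id: c.aa_seq for c in inputs.cds_records}
    metagenomes = sorted({c.metagenome for c in inputs.cds_records})

    # ---- funnel per metagenome
    funnel: dict[str, oi.FunnelCounts] = {}
    clusters_by_mg: dict[str, list] = {}
    orfans_by_mg: dict[str, list] = {}
    for mg in metagenomes:
        recs = [c for c in inputs.cds_records if c.metagenome == mg]
        ids = {c.cds_id for c in recs}
        kept, repetitive = _filter_stage(recs, config)
        kept, domain_removed = _domain_stage(kept, inputs.domain_hits, config)
        clusters = _cluster_stage(kept, seqs, config, mg)
        rep_ids = {cl.representative_id for cl in clusters}
        orfans, _annot, counts = _orfan_stage(
            clusters,
            {cid: h for cid, h in inputs.domain_hits.items() if cid in ids},
            {cid: h for cid, h in inputs.nr_hits.items() if cid in rep_ids},
            config, cds_by_id,
            removed_domain_ids=[c.cds_id for c in domain_removed],
            removed_repetitive_ids=[c.cds_id for c in repetitive])
        funnel[mg] = counts[mg]
        clusters_by_mg[mg] = clusters
        orfans_by_mg[mg] = orfans

    # ---- profiles + remote homology with decoy calibration
    all_orfans = [cl for mg in metagenomes for cl in orfans_by_mg[mg]]
    msas = _msa_stage(all_orfans, seqs)
    profiles = _profile_stage(msas)
    templates = _profile_stage(inputs.template_msas)
    decoy_profiles = _decoy_stage(msas, orfans_by_mg, config)
    hits, decoy_hits, fdr = _search_stage(profiles, decoy_profiles, templates,
                                          inputs.template_descriptions, config)

    # ---- GO assignment
    cluster_terms_top3, cluster_terms_conf, cds_terms, annotated_by_mg = \
        _annotation_stage(orfans_by_mg, hits, inputs, cds_by_id)

    # ---- gene-neighborhood context
    context = _context_stage(annotated_by_mg, inputs.cds_records, cds_terms, config)

    # ---- enrichment, specificity, clustering of functional profiles
    enrichment, spec_templates, spec_terms, newick = _profiling_stage(
        metagenomes, orfans_by_mg, annotated_by_mg, hits, cluster_terms_conf,
        inputs, config, cds_by_id)

    # ---- metalloprotease screen
    metallo = _metallo_stage(all_orfans, hits, inputs, seqs, cds_by_id)

    # ---- composition statistics
    composition = _composition_stage(metagenomes, inputs, orfans_by_mg, cds_by_id)

    report = PipelineReport(
        funnel=funnel, clusters=clusters_by_mg, orfan_clusters=orfans_by_mg,
        hits=hits, decoy_hits=decoy_hits, fdr=fdr,
        cluster_terms_top3=cluster_terms_top3,
        cluster_terms_confident=cluster_terms_conf, cds_terms=cds_terms,
        context=context, enrichment=enrichment,
        specificity_templates=spec_templates, specificity_terms=spec_terms,
        metalloproteases=metallo, composition=composition,
        profiles_newick=newick, annotated_orfan_clusters=annotated_by_mg)
    if outdir is not None:
        write_report(report, outdir, config)
    return report


@_stage("repetitive_filter")
def _filter_stage(recs, config):
    return oi.filter_repetitive(recs, config.repetitive_fraction)


@_stage("domain_screen")
def _domain_stage(recs, domain_hits, config):
    return oi.domain_screen(recs, domain_hits, config.evalue_cutoff)


@_stage("clustering")
def _cluster_stage(recs, seqs, config, mg):
    clusters = oi.greedy_cluster(recs, config.cluster_identity)
    for cl in clusters:
        cl.cluster_id = f"{mg}_{cl.cluster_id}"
    oi.mark_spurious(clusters, seqs, config.min_rep_length,
                     config.spurious_identity)
    return clusters


@_stage("orfan_definition")
def _orfan_stage(clusters, domain_hits, nr_hits, config, cds_by_id, **kw):
    return oi.call_orfans(clusters, domain_hits, nr_hits,
                          config.evalue_cutoff, cds_by_id=cds_by_id, **kw)


@_stage("msa")
def _msa_stage(orfan_clusters, seqs):
    return {cl.cluster_id: msa_profiles.build_msa(cl, seqs)
            for cl in orfan_clusters}


@_stage("profiles")
def _profile_stage(msas):
    return {cid: msa_profiles.build_profile(rows, cluster_id=cid)
            for cid, rows in msas.items()}


@_stage("decoys")
def _decoy_stage(msas, orfans_by_mg, config):
    """Column-shuffled decoy profiles, selected per metagenome.

    Up to ``decoys_per_metagenome`` clusters are drawn per metagenome; when
    the population is small, extra independent shuffles of the same clusters
    are added until at least ``min_total_decoys`` decoys exist overall (the
    calibration needs a minimum decoy sample).
    """
    rng = np.random.default_rng(config.stage_seed("decoys"))
    decoys = {}
    pool = []
    for mg in sorted(orfans_by_mg):
        ids = sorted(cl.cluster_id for cl in orfans_by_mg[mg])
        take = min(config.decoys_per_metagenome, len(ids))
        chosen = [ids[i] for i in rng.permutation(len(ids))[:take]]
        pool.extend(chosen)
        for cid in chosen:
            rows = msa_profiles.shuffle_columns(msas[cid], rng)
            decoys[f"decoy_{cid}"] = msa_profiles.build_profile(
                rows, cluster_id=f"decoy_{cid}")
    k = 0
    while len(decoys) < config.min_total_decoys and pool:
        cid = pool[k % len(pool)]
        rows = msa_profiles.shuffle_columns(msas[cid], rng)
        decoys[f"decoy_{cid}_r{k}"] = msa_profiles.build_profile(
            rows, cluster_id=f"decoy_{cid}_r{k}")
        k += 1
    return decoys


@_stage("remote_homology")
def _search_stage(profiles, decoy_profiles, templates, descriptions, config):
    real_scores = rh.all_scores(profiles, templates, config.gap_open,
                                config.gap_extend)
    decoy_scores = rh.all_scores(decoy_profiles, templates, config.gap_open,
                                 config.gap_extend)
    calibration = rh.calibrate(rh.best_scores(real_scores),
                               rh.best_scores(decoy_scores), len(templates))
    hits = rh.search_all(profiles, templates, calibration, descriptions,
                         scores=real_scores)
    decoy_hits = rh.search_all(decoy_profiles, templates, calibration,
                               descriptions, scores=decoy_scores)
    fdr = rh.estimate_fdr(hits, decoy_hits, config.probability_threshold,
                          config.evalue_threshold)
    return hits, decoy_hits, fdr


@_stage("go_assignment")
def _annotation_stage(orfans_by_mg, hits, inputs, cds_by_id):
    if not inputs.structure_go_map:
        raise ValueError("structure GO map is empty")
    top3: dict[str, set] = {}
    confident: dict[str, set] = {}
    cds_terms: dict[str, set] = {}
    annotated_by_mg: dict[str, list] = {}
    for mg in sorted(orfans_by_mg):
        annotated = []
        for cl in orfans_by_mg[mg]:
            cluster_hits = [h for h in hits.get(cl.cluster_id, []) if h.significant]
            a3 = assign_cluster_terms(cluster_hits, inputs.structure_go_map,
                                      "top3_union")
            ac = assign_cluster_terms(cluster_hits, inputs.structure_go_map,
                                      "most_confident")
            top3[cl.cluster_id] = a3.terms
            confident[cl.cluster_id] = ac.terms
            if cluster_hits:
                annotated.append(cl)
            for m in cl.member_ids:
                cds_terms[m] = set(a3.terms)
        annotated_by_mg[mg] = annotated
    for cds_id, dhits in inputs.domain_hits.items():
        if cds_id in cds_by_id:
            cds_terms[cds_id] = assign_pfam_terms(dhits, inputs.pfam_go_map).terms
    return top3, confident, cds_terms, annotated_by_mg


@_stage("genomic_context")
def _context_stage(annotated_by_mg, cds_records, cds_terms, config):
    results = {}
    for mg in sorted(annotated_by_mg):
        orfan_ids = sorted(m for cl in annotated_by_mg[mg] for m in cl.member_ids)
        if len(orfan_ids) < 2:
            logger.warning("%s: <2 annotated ORFans; context test skipped", mg)
            continue
        mg_records = [c for c in cds_records if c.metagenome == mg]
        results[mg] = gc.permutation_test(
            orfan_ids, mg_records, cds_terms, n=config.n_permutations,
            seed=config.stage_seed(f"context:{mg}"), metagenome=mg,
            window=config.neighbor_window)
    return results


@_stage("functional_profiling")
def _profiling_stage(metagenomes, orfans_by_mg, annotated_by_mg, hits,
                     confident, inputs, config, cds_by_id):
    ontology = inputs.ontology
    lvl = config.go_level
    enrichment = {}
    profiles_for_clustering: dict[str, dict[str, float]] = {}
    spec_template_counts: dict[str, dict[str, int]] = {}
    spec_term_counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for mg in metagenomes:
        pool = (annotated_by_mg[mg] if config.enrichment_denominator == "annotated"
                else orfans_by_mg[mg])
        orfan_terms = {cl.cluster_id: filter_level(confident[cl.cluster_id],
                                                   ontology, lvl)
                       for cl in pool}
        pfam_cds = [c for c in inputs.cds_records
                    if c.metagenome == mg and c.cds_id in inputs.domain_hits]
        subset = fp.reference_subset(pfam_cds, config.reference_subset_size,
                                     config.stage_seed(f"refsubset:{mg}"))
        ref_terms = {}
        for c in subset:
            terms = assign_pfam_terms(inputs.domain_hits[c.cds_id],
                                      inputs.pfam_go_map,
                                      config.evalue_cutoff).terms
            ref_terms[c.cds_id] = filter_level(terms, ontology, lvl)
        lib_terms = {tid: filter_level(ts, ontology, lvl)
                     for tid, ts in inputs.structure_go_map.items()}
        cds_counts = {cl.cluster_id: cl.size for cl in pool}
        if orfan_terms and ref_terms:
            enrichment[mg] = fp.enrich(orfan_terms, ref_terms, lib_terms,
                                       metagenome=mg,
                                       orfan_cds_counts=cds_counts)
        else:
            enrichment[mg] = []
        freq_o = (fp.term_frequencies(orfan_terms) if orfan_terms else {})
        freq_r = (fp.term_frequencies(ref_terms) if ref_terms else {})
        profiles_for_clustering[f"{mg}_orfan"] = {t: p for t, (_, p) in freq_o.items()}
        profiles_for_clustering[f"{mg}_reference"] = {t: p for t, (_, p) in freq_r.items()}

        # environment-specificity counts
        totals[mg] = len(annotated_by_mg[mg])
        for cl in annotated_by_mg[mg]:
            sig = [h for h in hits[cl.cluster_id] if h.significant]
            top = sig[0].template_id
            spec_template_counts.setdefault(top, {}).setdefault(mg, 0)
            spec_template_counts[top][mg] += 1
            for t in filter_level(confident[cl.cluster_id], ontology, lvl):
                spec_term_counts.setdefault(t, {}).setdefault(mg, 0)
                spec_term_counts[t][mg] += 1
    spec_templates = (fp.specificity_test(spec_template_counts, totals)
                      if any(totals.values()) else [])
    spec_terms = (fp.specificity_test(spec_term_counts, totals)
                  if any(totals.values()) else [])
    newick = ""
    if len(profiles_for_clustering) >= 2 and any(profiles_for_clustering.values()):
        newick = fp.profile_clustering(profiles_for_clustering)
    return enrichment, spec_templates, spec_terms, newick


@_stage("motif_screen")
def _metallo_stage(all_orfans, hits, inputs, seqs, cds_by_id):
    return motif_screen.screen_metalloproteases(
        all_orfans, hits, inputs.template_descriptions, seqs,
        metagenome_of=lambda cl: cds_by_id[cl.representative_id].metagenome)


@_stage("composition")
def _composition_stage(metagenomes, inputs, orfans_by_mg, cds_by_id):
    sets = {}
    for mg in metagenomes:
        sets[f"{mg} domain-annotated"] = [
            c for c in inputs.cds_records
            if c.metagenome == mg and c.cds_id in inputs.domain_hits]
        sets[f"{mg} ORFans"] = [cds_by_id[m] for cl in orfans_by_mg[mg]
                                for m in cl.member_ids]
    rows, _, _ = oi.composition_stats(sets)
    return rows


# ---------------------------------------------------------------------------
# report serialization

def write_report(report: PipelineReport, outdir, config: PipelineConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([asdict(fc) for fc in report.funnel.values()]).to_csv(
        outdir / "funnel.tsv", sep="\t", index=False)
    rows = []
    for mg, clusters in report.clusters.items():
        for cl in clusters:
            rows.append({"metagenome": mg, "cluster_id": cl.cluster_id,
                         "representative": cl.representative_id,
                         "size": cl.size,
                         "spurious_reason": cl.spurious_reason or "",
                         "members": ",".join(cl.member_ids)})
    pd.DataFrame(rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    hit_rows = []
    for cid, hits in report.hits.items():
        for h in hits:
            if h.significant:
                hit_rows.append({"cluster_id": cid, "template_id": h.template_id,
                                 "rank": h.rank, "score_bits": round(h.raw_score, 3),
                                 "evalue": h.evalue, "probability": h.probability,
                                 "description": h.template_description})
    pd.DataFrame(hit_rows).to_csv(outdir / "remote_hits.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(report.fdr)]).to_csv(outdir / "fdr.tsv", sep="\t",
                                              index=False)
    ctx_rows = [{"metagenome": mg, "S_m": r.S_m, "null_mean": r.null_mean,
                 "null_sd": r.null_sd, "z": r.z, "p_value": r.p_value,
                 "S_m_excluding_orfan_neighbors": r.S_m_excluding_orfan_neighbors}
                for mg, r in report.context.items()]
    pd.DataFrame(ctx_rows).to_csv(outdir / "context.tsv", sep="\t", index=False)
    null_rows = [{"metagenome": mg, "null_S_m": v}
                 for mg, r in report.context.items() for v in r.null_values]
    pd.DataFrame(null_rows).to_csv(outdir / "null_distribution.tsv", sep="\t",
                                   index=False)
    enr_rows = [asdict(r) for mg in report.enrichment for r in report.enrichment[mg]]
    pd.DataFrame(enr_rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    for name, spec in (("specificity_templates", report.specificity_templates),
                       ("specificity_terms", report.specificity_terms)):
        srows = []
        for row in spec:
            for mg, c, p, pb in zip(row.metagenomes, row.counts, row.prop,
                                    row.p_bonferroni):
                srows.append({"key": row.key, "metagenome": mg, "count": c,
                              "proportion": p, "p_bonferroni": pb})
        pd.DataFrame(srows).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    met_rows = [{"metagenome": c.metagenome, "cluster_id": c.cluster_id,
                 "top_template_id": c.top_template_id,
                 "matched_descriptor": c.matched_descriptor,
                 "motif_positions": ",".join(map(str, c.motif_positions))}
                for c in report.metalloproteases]
    pd.DataFrame(met_rows).to_csv(outdir / "metalloproteases.tsv", sep="\t",
                                  index=False)
    pd.DataFrame(report.composition).to_csv(outdir / "composition.tsv", sep="\t",
                                            index=False)
    (outdir / "profiles.newick").write_text(report.profiles_newick + "\n")
    summary = {
        "config": asdict(config),
        "funnel": {mg: asdict(fc) for mg, fc in report.funnel.items()},
        "fdr": asdict(report.fdr),
        "n_metalloprotease_candidates": len(report.metalloproteases),
        "context_p_values": {mg: r.p_value for mg, r in report.context.items()},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True) + "\n")
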