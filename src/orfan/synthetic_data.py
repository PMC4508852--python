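"""Synthetic metagenomes with the statistical structure the pipeline assumes.

The generator emits, for each metagenome label: contigs tiled with
same-strand CDSs drawn from sequence families (an ancestor protein mutated
per site at a tunable divergence) plus low-complexity junk ORFs; fixture
domain/nr databases and matching search-hit tables; a structure template
library (aligned families with GO map and descriptions, some of them
protease/peptidase entries); and a layered two-namespace GO DAG with known
longest-path levels.

Families come in three kinds mirroring the funnel: *domain* families whose
members carry conserved-domain hits, *nr* families whose members have
protein-database hits, and *ORFan* families absent from both fixture
databases.  A configurable fraction of ORFan families is planted with a
remote structural homolog (a template derived from the same ancestor at
higher divergence); templates cycle through protease-description and
HExxH-motif combinations so the metalloprotease screen has true positives
and both kinds of negative, and the template plan includes
metagenome-specific and cross-metagenome-shared templates so environment
specificity is testable.  Gene-neighborhood GO correlation is planted by
placing, with probability ``neighbor_go_correlation``, a term-sharing
domain-family CDS directly next to each planted ORFan CDS.

Everything is keyed off a single seed: the same config yields byte-identical
outputs.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .io_formats import (CDSRecord, SearchHit, write_cds_table, write_fasta,
                         write_go_map, write_obo)
from .ontology_annotation import BP, MF, Ontology

AA = "ACDEFGHIKLMNPQRSTVWY"

_CODONS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()

_PROTEASE_RE = re.compile(r"protease|peptidase", re.IGNORECASE)


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    seed: int = 0
    metagenomes: tuple[str, ...] = ("GPC", "GOS", "HG")
    families_per_metagenome: int = 25
    family_size_range: tuple[int, int] = (3, 6)
    family_divergence: float = 0.15
    orfan_fraction: float = 0.4
    junk_fraction: float = 0.1
    neighbor_go_correlation: float = 0.8
    ontology_depth: int = 8
    terms_per_level: int = 8  # per namespace per level
    go_terms_per_family: int = 3
    planted_homolog_fraction: float = 0.6
    template_divergence: float = 0.35
    template_msa_size: int = 5
    n_distractor_templates: int = 4
    n_shared_templates: int = 2
    specific_template_clusters: int = 4
    length_range: tuple[int, int] = (110, 200)
    junk_length_range: tuple[int, int] = (60, 140)
    cds_per_contig: int = 6
    intercds_gap_nt: int = 100
    indel_rate: float = 0.0
    opposite_strand_fraction: float = 0.0

    def __post_init__(self):
        for name in ("family_divergence", "orfan_fraction", "junk_fraction",
                     "neighbor_go_correlation", "planted_homolog_fraction",
                     "template_divergence", "indel_rate", "opposite_strand_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.orfan_fraction + self.junk_fraction > 1.0:
            raise ConfigError("orfan_fraction + junk_fraction exceeds 1")
        if self.family_size_range[0] < 1:
            raise ConfigError("family_size_range minimum must be >= 1")
        if self.ontology_depth < 2:
            raise ConfigError("ontology_depth must be >= 2")


@dataclass
class FamilyTruth:
    family_id: str
    metagenome: str
    kind: str  # domain | nr | orfan
    member_ids: list[str]
    go_terms: set[str]
    template_id: str | None = None
    has_motif: bool = False
    sequences: dict[str, str] = field(default_factory=dict, repr=False)
    ancestor: str = field(default="", repr=False)

    @property
    def is_orfan(self) -> bool:
        return self.kind == "orfan"


@dataclass
class SimResult:
    config: SimConfig
    ontology: Ontology
    term_levels: dict[str, int]
    cds_records: list[CDSRecord]
    families: dict[str, FamilyTruth]
    junk_ids: list[str]
    domain_hits: dict[str, list[SearchHit]]
    nr_hits: dict[str, list[SearchHit]]
    pfam_go_map: dict[str, set[str]]
    structure_go_map: dict[str, set[str]]
    template_msas: dict[str, list[str]]
    template_descriptions: dict[str, str]
    env_specific_templates: dict[str, str]
    motif_truth: set[str] = field(default_factory=set)

    @property
    def orfan_families(self) -> dict[str, FamilyTruth]:
        return {fid: f for fid, f in self.families.items() if f.is_orfan}

    def family_of(self) -> dict[str, str]:
        return {m: fid for fid, f in self.families.items() for m in f.member_ids}

    def write(self, outdir) -> None:
        """Emit every fixture in the on-disk formats the readers accept."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cds_table(self.cds_records, outdir / "cds_table.tsv")
        write_fasta([(c.cds_id, c.aa_seq) for c in self.cds_records],
                    outdir / "proteins.faa")
        write_fasta([(c.cds_id, c.nt_seq) for c in self.cds_records],
                    outdir / "cds.fna")
        write_obo(self.ontology, outdir / "ontology.obo")
        write_go_map(self.pfam_go_map, outdir / "pfam_go.tsv")
        write_go_map(self.structure_go_map, outdir / "structure_go.tsv")
        with open(outdir / "domain_hits.tblout", "w") as fh:
            fh.write("# synthetic HMMER3 tblout fixture\n")
            for cds_id in sorted(self.domain_hits):
                for h in self.domain_hits[cds_id]:
                    fh.write(f"{h.query_id} - {h.target_id} - "
                             f"{h.evalue:.3g} {h.bitscore:.1f} 0.0\n")
        with open(outdir / "nr_hits.blast6", "w") as fh:
            for cds_id in sorted(self.nr_hits):
                for h in self.nr_hits[cds_id]:
                    fh.write("\t".join([h.query_id, h.target_id, "30.0", "100",
                                        "70", "0", "1", "100", "1", "100",
                                        f"{h.evalue:.3g}", f"{h.bitscore:.1f}"])
                             + "\n")
        tmpl_dir = outdir / "templates"
        tmpl_dir.mkdir(exist_ok=True)
        for tid in sorted(self.template_msas):
            rows = self.template_msas[tid]
            write_fasta([(f"{tid}_{i}", row) for i, row in enumerate(rows)],
                        tmpl_dir / f"{tid}.afa")
        with open(outdir / "template_descriptions.tsv", "w") as fh:
            for tid in sorted(self.template_descriptions):
                fh.write(f"{tid}\t{self.template_descriptions[tid]}\n")


# ---------------------------------------------------------------------------
# ontology

def make_ontology(config: SimConfig) -> tuple[Ontology, dict[str, int]]:
    """Layered two-root GO-like DAG with known longest-path levels.

    Each level L in 2..depth holds ``terms_per_level`` terms per namespace,
    each with one parent at level L-1 (fixing the longest-path level at L);
    half the terms at level >= 4 get an extra cross-level is_a parent two or
    more levels up, so shortest- and longest-path depths disagree for a
    sizeable fraction of terms.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    g = nx.DiGraph()
    names, namespaces, levels = {}, {}, {}
    counter = itertools.count(1)

    def new_term(ns, level):
        t = f"GO:{next(counter):07d}"
        g.add_node(t)
        names[t] = f"synthetic term {t[-4:]} ({ns} level {level})"
        namespaces[t] = ns
        levels[t] = level
        return t

    per_level: dict[tuple[str, int], list[str]] = {}
    for ns in (BP, MF):
        root = new_term(ns, 1)
        per_level[(ns, 1)] = [root]
    for level in range(2, config.ontology_depth + 1):
        for ns in (BP, MF):
            terms = []
            for _ in range(config.terms_per_level):
                t = new_term(ns, level)
                parent = per_level[(ns, level - 1)][
                    rng.integers(len(per_level[(ns, level - 1)]))]
                g.add_edge(t, parent)
                if level >= 4 and rng.random() < 0.5:
                    # cross-level shortcut: shortest path becomes < longest
                    up = int(rng.integers(1, level - 1))
                    cand = per_level[(ns, up)]
                    extra = cand[rng.integers(len(cand))]
                    if extra != parent:
                        g.add_edge(t, extra)
                terms.append(t)
            per_level[(ns, level)] = terms
    return Ontology(graph=g, names=names, namespaces=namespaces), levels


# ---------------------------------------------------------------------------
# sequences

def _random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def mutate(rng, seq: str, divergence: float, indel_rate: float = 0.0) -> str:
    """Per-site uniform substitution to one of the 19 other residues.

    An optional per-site indel rate (half insertions, half deletions) exists
    because clustering and alignment must tolerate gaps; it defaults to 0 so
    within-family identity stays analytically predictable.
    """
    out = []
    for ch in seq:
        if indel_rate and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(AA[rng.integers(20)])  # insertion before the site
        if rng.random() < divergence:
            choices = [a for a in AA if a != ch]
            out.append(choices[rng.integers(19)])
        else:
            out.append(ch)
    return "".join(out)


def _junk_protein(rng, length: int) -> str:
    unit_len = int(rng.integers(1, 4))
    unit = _random_protein(rng, unit_len)
    return (unit * (length // unit_len + 1))[:length]


def _back_translate(rng, aa_seq: str) -> str:
    return "".join(_CODONS[ch][rng.integers(len(_CODONS[ch]))] for ch in aa_seq)


def _plant_motif(rng, seq: str, pos: int) -> str:
    middle = "".join(rng.choice(list(AA), size=2))
    return seq[:pos] + "HE" + middle + "H" + seq[pos + 5:]


# ---------------------------------------------------------------------------
# template plan

_PROTEASE_DESCRIPTIONS = ["Peptidase M48", "Zinc metalloprotease domain",
                          "Peptidase M10, Matrixin", "DUF45 metallopeptidase"]
_NEUTRAL_DESCRIPTIONS = ["Putative lysozyme", "ABC transporter domain",
                         "Uncharacterized conserved protein",
                         "Ferredoxin-like fold protein",
                         "Response regulator receiver domain"]


@dataclass
class _TemplatePlan:
    template_id: str
    protease_desc: bool
    plant_motif: bool
    shared: bool
    specific_to: str | None = None


# ---------------------------------------------------------------------------
# main generator

def make_metagenomes(config: SimConfig) -> SimResult:
    """Generate the full synthetic study: see the module docstring."""
    if config.ontology_depth < 6:
        raise ConfigError("full simulation needs ontology_depth >= 6 "
                          "(level-6 analyses must be exercisable)")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 202]))
    ontology, term_levels = make_ontology(config)

    deep_terms = sorted(t for t, l in term_levels.items() if l >= 3)
    level6 = sorted(t for t, l in term_levels.items() if l == 6)

    def sample_terms(k: int) -> set[str]:
        # at least one level-6 term per set so level-restricted stages see data
        terms = {level6[rng.integers(len(level6))]}
        while len(terms) < k:
            terms.add(deep_terms[rng.integers(len(deep_terms))])
        return terms

    # ---- template plan (global across metagenomes)
    plans: list[_TemplatePlan] = []
    combo = itertools.cycle([(True, True), (False, True), (True, False),
                             (False, False)])

    def new_plan(shared=False, specific_to=None):
        prot, motif = next(combo)
        tid = f"t{len(plans) + 1:03d}x_A"
        plans.append(_TemplatePlan(template_id=tid, protease_desc=prot,
                                   plant_motif=motif, shared=shared,
                                   specific_to=specific_to))
        return plans[-1]

    shared_plans = [new_plan(shared=True) for _ in range(config.n_shared_templates)]
    specific_plans = {mg: new_plan(specific_to=mg) for mg in config.metagenomes}

    n_fam = config.families_per_metagenome
    n_orfan = int(round(config.orfan_fraction * n_fam))
    n_planted = int(round(config.planted_homolog_fraction * n_orfan))
    n_nonorfan = n_fam - n_orfan
    n_domain = max(1, (n_nonorfan + 1) // 2) if n_nonorfan else 0

    # per metagenome: assign planted families to templates — shared first,
    # then the metagenome-specific template, then unique singles
    assignment: dict[str, list[_TemplatePlan]] = {}
    for mg in config.metagenomes:
        plan_list: list[_TemplatePlan] = []
        for sp in shared_plans:
            if len(plan_list) < n_planted:
                plan_list.append(sp)
        spec = specific_plans[mg]
        while (len(plan_list) < n_planted
               and sum(1 for p in plan_list if p is spec) < config.specific_template_clusters):
            plan_list.append(spec)
        while len(plan_list) < n_planted:
            plan_list.append(new_plan())
        assignment[mg] = plan_list

    # ---- template ancestors, terms, descriptions, MSAs
    template_ancestor: dict[str, str] = {}
    template_terms: dict[str, set[str]] = {}
    template_descriptions: dict[str, str] = {}
    motif_pos: dict[str, int] = {}
    for plan in plans:
        length = int(rng.integers(*config.length_range))
        anc = _random_protein(rng, length)
        if plan.plant_motif:
            pos = int(rng.integers(10, length - 15))
            anc = _plant_motif(rng, anc, pos)
            motif_pos[plan.template_id] = pos
        template_ancestor[plan.template_id] = anc
        template_terms[plan.template_id] = sample_terms(config.go_terms_per_family)
        pool = _PROTEASE_DESCRIPTIONS if plan.protease_desc else _NEUTRAL_DESCRIPTIONS
        template_descriptions[plan.template_id] = pool[int(rng.integers(len(pool)))]
    for i in range(config.n_distractor_templates):
        tid = f"d{i + 1:03d}x_A"
        length = int(rng.integers(*config.length_range))
        template_ancestor[tid] = _random_protein(rng, length)
        template_terms[tid] = sample_terms(config.go_terms_per_family)
        # half the distractors read like proteases but match no family
        pool = _PROTEASE_DESCRIPTIONS if i % 2 == 0 else _NEUTRAL_DESCRIPTIONS
        template_descriptions[tid] = pool[int(rng.integers(len(pool)))]

    template_msas = {}
    for tid in sorted(template_ancestor):
        anc = template_ancestor[tid]
        template_msas[tid] = [anc] + [mutate(rng, anc, config.family_divergence)
                                      for _ in range(config.template_msa_size - 1)]

    # ---- families, members, layout
    families: dict[str, FamilyTruth] = {}
    cds_records: list[CDSRecord] = []
    junk_ids: list[str] = []
    domain_hits: dict[str, list[SearchHit]] = {}
    nr_hits: dict[str, list[SearchHit]] = {}
    pfam_go_map: dict[str, set[str]] = {}
    fam_counter = itertools.count(1)
    cds_counter = itertools.count(1)

    def fam_size() -> int:
        return int(rng.integers(config.family_size_range[0],
                                config.family_size_range[1] + 1))

    def new_family(mg, kind, anc, terms, template_id=None, has_motif=False,
                   motif_at=None) -> FamilyTruth:
        fid = f"F{next(fam_counter):04d}"
        members = {}
        for _ in range(fam_size()):
            seq = mutate(rng, anc, config.family_divergence, config.indel_rate)
            if has_motif and motif_at is not None and motif_at + 5 <= len(seq):
                seq = _plant_motif(rng, seq, motif_at)
            members[f"cds{next(cds_counter):06d}"] = seq
        fam = FamilyTruth(family_id=fid, metagenome=mg, kind=kind,
                          member_ids=list(members), go_terms=set(terms),
                          template_id=template_id, has_motif=has_motif,
                          sequences=members, ancestor=anc)
        families[fid] = fam
        return fam

    for mg in config.metagenomes:
        mg_families: list[FamilyTruth] = []
        plan_list = assignment[mg]
        for k in range(n_orfan):
            if k < len(plan_list):
                plan = plan_list[k]
                anc = mutate(rng, template_ancestor[plan.template_id],
                             config.template_divergence)
                fam = new_family(mg, "orfan", anc,
                                 template_terms[plan.template_id],
                                 template_id=plan.template_id,
                                 has_motif=plan.plant_motif,
                                 motif_at=motif_pos.get(plan.template_id))
            else:
                anc = _random_protein(rng, int(rng.integers(*config.length_range)))
                fam = new_family(mg, "orfan", anc,
                                 sample_terms(config.go_terms_per_family))
            mg_families.append(fam)
        for k in range(n_nonorfan):
            kind = "domain" if k < n_domain else "nr"
            anc = _random_protein(rng, int(rng.integers(*config.length_range)))
            mg_families.append(new_family(
                mg, kind, anc, sample_terms(config.go_terms_per_family)))

        domain_fams = [f for f in mg_families if f.kind == "domain"]
        planted_fams = [f for f in mg_families if f.kind == "orfan" and f.template_id]

        # ---- neighbor pairing plan: each planted ORFan family has one
        # dedicated buddy domain family that carries exactly one of its terms;
        # the buddy grows extra members on demand so pairing never starves
        avail: dict[str, list[str]] = {f.family_id: list(f.member_ids)
                                       for f in domain_fams}
        units: list[list[tuple[str, str]]] = []
        for i, of in enumerate(planted_fams):
            if not domain_fams:
                units.extend([(m, of.sequences[m])] for m in of.member_ids)
                continue
            buddy = domain_fams[i % len(domain_fams)]
            shared_term = sorted(of.go_terms)[int(rng.integers(len(of.go_terms)))]
            buddy.go_terms.add(shared_term)
            for m in of.member_ids:
                if rng.random() < config.neighbor_go_correlation:
                    if not avail[buddy.family_id]:
                        cid = f"cds{next(cds_counter):06d}"
                        buddy.sequences[cid] = mutate(rng, buddy.ancestor,
                                                      config.family_divergence)
                        buddy.member_ids.append(cid)
                        avail[buddy.family_id].append(cid)
                    bm = avail[buddy.family_id].pop(0)
                    units.append([(m, of.sequences[m]),
                                  (bm, buddy.sequences[bm])])
                else:
                    units.append([(m, of.sequences[m])])

        placed = {m for unit in units for m, _ in unit}
        for f in mg_families:
            for m in f.member_ids:
                if m not in placed:
                    units.append([(m, f.sequences[m])])

        # junk ORFs
        n_family_cds = sum(len(f.member_ids) for f in mg_families)
        for _ in range(int(round(config.junk_fraction * n_family_cds))):
            cid = f"cds{next(cds_counter):06d}"
            seq = _junk_protein(rng, int(rng.integers(*config.junk_length_range)))
            junk_ids.append(cid)
            units.append([(cid, seq)])

        # ---- contig layout: shuffle units, tile contigs, 100 nt gaps
        units = [units[i] for i in rng.permutation(len(units))]
        contig_idx = itertools.count(1)
        contig_id, slot, pos = None, 0, 0
        for unit in units:
            if contig_id is None or slot + len(unit) > config.cds_per_contig:
                contig_id = f"{mg}_ctg{next(contig_idx):05d}"
                slot, pos = 0, 0
            for cid, seq in unit:
                strand = "+"
                if (len(unit) == 1 and config.opposite_strand_fraction
                        and rng.random() < config.opposite_strand_fraction):
                    strand = "-"
                nt = _back_translate(rng, seq)
                cds_records.append(CDSRecord(
                    cds_id=cid, contig_id=contig_id, start=pos,
                    end=pos + len(nt), strand=strand, nt_seq=nt, aa_seq=seq,
                    metagenome=mg))
                pos += len(nt) + config.intercds_gap_nt
                slot += 1

        # ---- fixture search hits (after pairing may have touched GO sets)
        for f in mg_families:
            if f.kind == "domain":
                model = f"PF{int(f.family_id[1:]):05d}"
                pfam_go_map[model] = set(f.go_terms)
                for m in f.member_ids:
                    domain_hits[m] = [SearchHit(query_id=m, target_id=model,
                                                evalue=1e-10, bitscore=80.0)]
            elif f.kind == "nr":
                for m in f.member_ids:
                    nr_hits[m] = [SearchHit(query_id=m, target_id=f"nr|{f.family_id}",
                                            evalue=1e-8, bitscore=120.0)]
        # boundary exercise: a weak (above-cutoff) nr hit on one ORFan family
        orfan_fams = [f for f in mg_families if f.kind == "orfan"]
        if orfan_fams:
            for m in orfan_fams[0].member_ids:
                nr_hits[m] = [SearchHit(query_id=m, target_id="nr|weak",
                                        evalue=0.5, bitscore=22.0)]

    structure_go_map = {tid: set(terms) for tid, terms in template_terms.items()}
    env_specific = {mg: specific_plans[mg].template_id for mg in config.metagenomes}
    motif_truth = {fid for fid, f in families.items()
                   if f.has_motif and f.template_id
                   and _PROTEASE_RE.search(template_descriptions[f.template_id])}

    return SimResult(config=config, ontology=ontology, term_levels=term_levels,
                     cds_records=cds_records, families=families,
                     junk_ids=junk_ids, domain_hits=domain_hits,
                     nr_hits=nr_hits, pfam_go_map=pfam_go_map,
                     structure_go_map=structure_go_map,
                     template_msas=template_msas,
                     template_descriptions=template_descriptions,
                     env_specific_templates=env_specific,
                     motif_truth=motif_truth)


# ---------------------------------------------------------------------------
# focused benchmark for the remote-homology FDR property

def make_homology_benchmark(n_real: int, seed: int = 0, planted_fraction: float = 0.5,
                            n_templates: int = 10, family_size: int = 5,
                            length_range: tuple[int, int] = (120, 180),
                            family_divergence: float = 0.15,
                            template_divergence: float = 0.35):
    """Real query families with a known planted-homolog subset.

    Returns (real_msas, template_msas, truth) where ``truth`` maps query id
    to its planted template id (absent for unplanted queries).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    template_msas = {}
    template_anc = {}
    for i in range(n_templates):
        tid = f"T{i:03d}"
        anc = _random_protein(rng, int(rng.integers(*length_range)))
        template_anc[tid] = anc
        template_msas[tid] = [anc] + [mutate(rng, anc, family_divergence)
                                      for _ in range(family_size - 1)]
    real_msas = {}
    truth = {}
    tids = sorted(template_anc)
    for i in range(n_real):
        qid = f"Q{i:04d}"
        if rng.random() < planted_fraction:
            tid = tids[int(rng.integers(len(tids)))]
            anc = mutate(rng, template_anc[tid], template_divergence)
            truth[qid] = tid
        else:
            anc = _random_protein(rng, int(rng.integers(*length_range)))
        real_msas[qid] = [mutate(rng, anc, family_divergence)
                          for _ in range(family_size)]
    return real_msas, template_msas, truth
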