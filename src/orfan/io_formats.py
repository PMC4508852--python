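"""Readers/writers for every external format the pipeline touches.

FASTA (plain and aligned), a 1-based inclusive CDS coordinate table (GFF
habit on disk, 0-based half-open in memory), OBO 1.2 ontologies, two-column
GO mapping tables, and the three third-party search-result dialects the
pipeline can ingest: HMMER3 ``--tblout``, BLAST tabular ``-outfmt 6`` and
HHsearch ``.hhr`` summary hit lists.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO

from .ontology_annotation import Ontology, OntologyCycleError

logger = logging.getLogger(__name__)

CDS_COLUMNS = ["cds_id", "contig_id", "start", "end", "strand", "metagenome"]
GO_ID_RE = re.compile(r"^GO:\d{7}$")


class FormatError(ValueError):
    pass


@dataclass
class CDSRecord:
    """One predicted coding sequence on a contig.

    Coordinates are 0-based half-open nucleotide positions on the contig.
    """

    cds_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    nt_seq: str = ""
    aa_seq: str = ""
    metagenome: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.cds_id}: strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise FormatError(f"{self.cds_id}: end ({self.end}) must exceed start ({self.start})")
        if self.nt_seq and len(self.nt_seq) % 3 != 0:
            raise FormatError(f"{self.cds_id}: nucleotide length not divisible by 3")

    @property
    def nt_length(self) -> int:
        return self.end - self.start


@dataclass
class SearchHit:
    """A generic query -> target search result."""

    query_id: str
    target_id: str
    evalue: float
    bitscore: float = 0.0
    probability: float | None = None
    target_description: str = ""

    def __post_init__(self):
        if self.evalue < 0:
            raise FormatError(f"negative E-value for {self.query_id}->{self.target_id}")
        if self.probability is not None and not (0.0 <= self.probability <= 100.0):
            raise FormatError(f"probability out of [0,100] for {self.query_id}->{self.target_id}")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) pairs; sequences uppercased, gaps preserved.

    Duplicate ids and empty/malformed files raise :class:`FormatError`.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}:{lineno}: expected FASTA header, got {line[:30]!r}")
        break
    else:
        raise FormatError(f"{path}: empty FASTA file")
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(io.StringIO(text), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    seen: set[str] = set()
    for rid, _ in records:
        if rid in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rid!r}")
        seen.add(rid)
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# CDS coordinate table

def read_cds_table(path) -> list[CDSRecord]:
    """TSV with 1-based inclusive coordinates -> 0-based half-open records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CDS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        start = int(row.start) - 1
        end = int(row.end)
        if start < 0 or end <= start:
            raise FormatError(f"{row.cds_id}: bad coordinates {row.start}..{row.end}")
        records.append(CDSRecord(cds_id=row.cds_id, contig_id=row.contig_id,
                                 start=start, end=end, strand=row.strand,
                                 metagenome=row.metagenome))
    return records


def write_cds_table(records, path) -> None:
    """Inverse of :func:`read_cds_table` (emits 1-based inclusive coordinates)."""
    rows = [{"cds_id": r.cds_id, "contig_id": r.contig_id,
             "start": r.start + 1, "end": r.end, "strand": r.strand,
             "metagenome": r.metagenome} for r in records]
    pd.DataFrame(rows, columns=CDS_COLUMNS).to_csv(path, sep="\t", index=False)


def group_by_contig(records) -> dict[str, list[CDSRecord]]:
    """CDSs grouped by contig, each group sorted by start position."""
    groups: dict[str, list[CDSRecord]] = {}
    for r in records:
        groups.setdefault(r.contig_id, []).append(r)
    for g in groups.values():
        g.sort(key=lambda r: (r.start, r.cds_id))
    return groups


def attach_sequences(records, aa: dict[str, str] | None = None,
                     nt: dict[str, str] | None = None) -> None:
    for r in records:
        if aa is not None and r.cds_id in aa:
            r.aa_seq = aa[r.cds_id]
        if nt is not None and r.cds_id in nt:
            r.nt_seq = nt[r.cds_id]


# ---------------------------------------------------------------------------
# OBO ontology

def read_obo(path) -> Ontology:
    """OBO 1.2 -> is_a DAG. Obsolete terms are excluded; cycles are an error."""
    multigraph = obonet.read_obo(path)
    g = nx.DiGraph()
    names, namespaces = {}, {}
    for term, data in multigraph.nodes(data=True):
        g.add_node(term)
        names[term] = data.get("name", term)
        namespaces[term] = data.get("namespace", "")
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    ont = Ontology(graph=g, names=names, namespaces=namespaces)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyCycleError(f"is_a cycle through {cycle[0][0]}")
    return ont


def write_obo(ontology: Ontology, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go-synthetic\n\n")
        for term in sorted(ontology.graph.nodes):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {ontology.names.get(term, term)}\n")
            ns = ontology.namespaces.get(term)
            if ns:
                fh.write(f"namespace: {ns}\n")
            for parent in sorted(ontology.graph.successors(term)):
                fh.write(f"is_a: {parent} ! {ontology.names.get(parent, parent)}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# GO mapping tables

class GoMap(dict):
    """target_id -> set of GO ids; unlisted targets map to the empty set."""

    skipped: int = 0

    def __missing__(self, key):
        return set()


def read_go_map(path) -> GoMap:
    """TSV of (target_id, go_id) pairs; malformed GO ids are skipped+counted."""
    mapping = GoMap()
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not GO_ID_RE.match(parts[1].strip()):
                logger.warning("%s:%d: malformed GO mapping line skipped", path, lineno)
                skipped += 1
                continue
            mapping.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    mapping.skipped = skipped
    if skipped:
        logger.warning("%s: %d malformed lines skipped", path, skipped)
    return mapping


def write_go_map(mapping, path) -> None:
    with open(path, "w") as fh:
        for target in sorted(mapping):
            for go in sorted(mapping[target]):
                fh.write(f"{target}\t{go}\n")


# ---------------------------------------------------------------------------
# Third-party search results

DIALECTS = ("hmmer_tblout", "blast_tab6", "hhr")


def parse_search_hits(path, dialect: str) -> list[SearchHit]:
    """Adapt external search output into :class:`SearchHit` records.

    ``hmmer_tblout``: the scanned sequence (tblout column 1) becomes
    ``query_id`` and the profile (column 3) ``target_id``, so domain hits are
    keyed by CDS id as the pipeline expects.  ``blast_tab6`` keeps BLAST's
    query/subject orientation.  ``hhr`` parses the summary hit list only.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    parser = {"hmmer_tblout": _parse_tblout,
              "blast_tab6": _parse_blast6,
              "hhr": _parse_hhr}[dialect]
    return parser(Path(path))


def _parse_tblout(path: Path) -> list[SearchHit]:
    hits = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise FormatError(f"{path}:{lineno}: not HMMER tblout: {line[:40]!r}")
        try:
            evalue, score = float(parts[4]), float(parts[5])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: not HMMER tblout: {line[:40]!r}") from exc
        hits.append(SearchHit(query_id=parts[0], target_id=parts[2],
                              evalue=evalue, bitscore=score,
                              target_description=" ".join(parts[18:])))
    return hits


def _parse_blast6(path: Path) -> list[SearchHit]:
    hits = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 12:
            raise FormatError(f"{path}:{lineno}: not BLAST outfmt-6: {line[:40]!r}")
        try:
            evalue, bits = float(parts[10]), float(parts[11])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: not BLAST outfmt-6: {line[:40]!r}") from exc
        hits.append(SearchHit(query_id=parts[0], target_id=parts[1],
                              evalue=evalue, bitscore=bits))
    return hits


_HHR_HEADER_RE = re.compile(r"^\s*No\s+Hit\b")
_HHR_HIT_RE = re.compile(r"^\s*\d+\s+\S")


def _parse_hhr(path: Path) -> list[SearchHit]:
    lines = path.read_text().splitlines()
    hits: list[SearchHit] = []
    in_list = False
    for lineno, line in enumerate(lines, start=1):
        if _HHR_HEADER_RE.match(line):
            in_list = True
            continue
        if not in_list:
            continue
        if not line.strip():
            break  # end of the summary hit list
        if not _HHR_HIT_RE.match(line):
            raise FormatError(f"{path}:{lineno}: not an HHR hit line: {line[:40]!r}")
        # layout: rank, 30-char name+description field, then numeric columns
        # Prob E-value P-value Score SS Cols Query-HMM Template-HMM (Total)
        name_field = line[4:35].strip()
        numeric = line[35:].split()
        if len(numeric) < 4 or not name_field:
            raise FormatError(f"{path}:{lineno}: truncated HHR hit line")
        try:
            prob = float(numeric[0])
            evalue = float(numeric[1].replace("E", "e"))
            score = float(numeric[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad HHR numeric fields") from exc
        template_id = name_field.split()[0]
        description = name_field[len(template_id):].strip()
        if not math.isfinite(evalue) or evalue < 0:
            raise FormatError(f"{path}:{lineno}: bad HHR E-value")
        hits.append(SearchHit(query_id=path.stem, target_id=template_id,
                              evalue=evalue, bitscore=score, probability=prob,
                              target_description=description))
    return hits
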