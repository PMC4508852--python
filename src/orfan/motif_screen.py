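"""HExxH metalloprotease screen over annotated ORFan clusters.

A cluster is a metalloprotease candidate when both conditions hold:

1. its top significant remote-homology hit is to a structure whose
   description contains "protease" or "peptidase" (case-insensitive
   substring over the full description text), and
2. its representative sequence contains at least one HExxH motif
   (His-Glu-any-any-His; overlapping occurrences all count).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

HEXXH_RE = re.compile(r"(?=HE..H)", re.IGNORECASE)
PROTEASE_RE = re.compile(r"protease|peptidase", re.IGNORECASE)


@dataclass
class MotifCandidate:
    cluster_id: str
    motif_positions: list[int]
    top_template_id: str
    matched_descriptor: str  # protease | peptidase
    metagenome: str = ""


def find_hexxh(aa_seq: str) -> list[int]:
    """0-based start positions of all (possibly overlapping) HExxH matches."""
    return [m.start() for m in HEXXH_RE.finditer(aa_seq)]


def screen_metalloproteases(orfan_clusters, hits_by_cluster,
                            descriptions: dict[str, str],
                            sequences: dict[str, str],
                            metagenome_of=None) -> list[MotifCandidate]:
    """Apply the two-condition screen to ORFan clusters.

    ``hits_by_cluster`` maps cluster_id -> ranked RemoteHit list; only the
    rank-1 *significant* hit is consulted.  ``descriptions`` may override the
    hit's own description text by template id.
    """
    candidates = []
    for cl in orfan_clusters:
        hits = [h for h in hits_by_cluster.get(cl.cluster_id, []) if h.significant]
        if not hits:
            continue
        top = hits[0]
        text = descriptions.get(top.template_id, top.template_description)
        m = PROTEASE_RE.search(text)
        if not m:
            continue
        positions = find_hexxh(sequences[cl.representative_id])
        if not positions:
            continue
        candidates.append(MotifCandidate(
            cluster_id=cl.cluster_id, motif_positions=positions,
            top_template_id=top.template_id,
            matched_descriptor=m.group(0).lower(),
            metagenome=metagenome_of(cl) if metagenome_of else ""))
    return candidates


def tally(candidates) -> tuple[Counter, Counter]:
    """(per-metagenome counts, per-(metagenome, template) counts) — Table-4 shape."""
    per_mg = Counter(c.metagenome for c in candidates)
    per_template = Counter((c.metagenome, c.top_template_id) for c in candidates)
    return per_mg, per_template
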