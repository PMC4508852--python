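"""Cluster alignments, frequency profiles, and column-shuffled decoys.

Alignments are built center-star style around the cluster representative:
each member is globally aligned to the representative and the pairwise gap
patterns are merged, which is deterministic and adequate for the shallow,
high-identity clusters the funnel produces.  A profile is the per-column
amino-acid frequency vector with a background pseudocount.

Decoy families are made by permuting the *columns* of an alignment: this
preserves per-column conservation and overall composition while destroying
any resemblance to a real protein, which is exactly the property the decoy
false-discovery estimate needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import global_align

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20)


@dataclass
class ProfileMSA:
    cluster_id: str
    rows: list[str]
    columns: np.ndarray  # (n_columns, 20) frequency vectors
    background: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.columns.shape[0]

    def validate(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError(f"{self.cluster_id}: rows have unequal length")
        if not np.allclose(self.columns.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.cluster_id}: column frequencies do not sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{self.cluster_id}: background does not sum to 1")


def build_msa(cluster, sequences: dict[str, str]) -> list[str]:
    """Center-star multiple alignment around the cluster representative.

    Rows are returned in member order.  Each member is globally aligned to
    the representative; member-induced insertions relative to the
    representative are merged into a master gap pattern.
    """
    rep_id = cluster.representative_id
    rep = sequences[rep_id]
    members = list(cluster.member_ids)
    if len(members) == 1:
        return [sequences[members[0]]]

    # pairwise alignments vs the representative
    pair = {}
    for m in members:
        if m == rep_id:
            continue
        arep, amem, _, _ = global_align(rep, sequences[m])
        pair[m] = (arep, amem)

    # master insertion counts: extra columns after each representative position
    # index 0 = before first residue, i = after residue i
    ins = np.zeros(len(rep) + 1, dtype=int)
    for arep, _ in pair.values():
        pos, run = 0, 0
        for ch in arep:
            if ch == "-":
                run += 1
            else:
                ins[pos] = max(ins[pos], run)
                run = 0
                pos += 1
        ins[pos] = max(ins[pos], run)

    def expand(arep: str, other: str) -> str:
        """Pad `other` so its representative-gap pattern matches the master."""
        out = []
        pos, run, buf = 0, 0, []
        for ch_r, ch_o in zip(arep, other):
            if ch_r == "-":
                buf.append(ch_o)
                run += 1
            else:
                out.append("".join(buf) + "-" * (ins[pos] - run))
                out.append(ch_o)
                buf, run = [], 0
                pos += 1
        out.append("".join(buf) + "-" * (ins[pos] - run))
        return "".join(out)

    rows = []
    rep_self = rep  # representative aligned to itself: no internal gaps
    for m in members:
        if m == rep_id:
            # expand the ungapped representative against the master pattern
            arep = rep_self
            rows.append(expand(arep, arep))
        else:
            arep, amem = pair[m]
            rows.append(expand(arep, amem))
    width = {len(r) for r in rows}
    assert len(width) == 1, "center-star merge produced ragged rows"
    return rows


def build_profile(msa_rows, cluster_id: str = "", pseudocount_weight: float = 1.0,
                  background: np.ndarray | None = None) -> ProfileMSA:
    """Column frequency profile with background pseudocounts.

    For column i with residue counts c_i(a) over n_i non-gap residues,
    p_i(a) = (c_i(a) + w*f(a)) / (n_i + w).  Residues outside the 20-letter
    alphabet (B, Z, X, U, O, ...) are retained in rows but contribute their
    background distribution f fractionally.  All-gap columns are dropped.
    """
    if not msa_rows:
        raise ValueError("no rows")
    f = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    if not np.isclose(f.sum(), 1.0):
        raise ValueError("background must sum to 1")
    width = len(msa_rows[0])
    if any(len(r) != width for r in msa_rows):
        raise ValueError("rows have unequal length")
    w = float(pseudocount_weight)
    cols = []
    for j in range(width):
        counts = np.zeros(20)
        n = 0
        for row in msa_rows:
            ch = row[j]
            if ch == "-" or ch == ".":
                continue
            n += 1
            idx = AA_INDEX.get(ch.upper())
            if idx is None:
                counts += f  # ambiguous residue spread over the background
            else:
                counts[idx] += 1.0
        if n == 0:
            continue  # all-gap column
        denom = n + w
        if denom == 0:
            raise ValueError("zero pseudocount with empty column")
        cols.append((counts + w * f) / denom)
    if not cols:
        raise ValueError(f"{cluster_id}: no usable (non-gap) columns")
    profile = ProfileMSA(cluster_id=cluster_id, rows=list(msa_rows),
                         columns=np.array(cols), background=f)
    profile.validate()
    return profile


def shuffle_columns(msa_rows, seed) -> list[str]:
    """Apply one uniformly random column permutation identically to all rows.

    ``seed`` may be an int or a numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not msa_rows:
        return []
    width = len(msa_rows[0])
    perm = rng.permutation(width)
    return ["".join(row[j] for j in perm) for row in msa_rows]
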