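"""G-quadruplex motif scanning in 3'UTR sequences and set-enrichment
testing.

The motif is four [AU]GGA units separated by gaps of up to six
nucleotides; matching is leftmost non-overlapping with greedy gaps.
Experimentally determined G-quadruplex sequences can also be matched as
exact substrings. Enrichment between gene sets uses Fisher's exact test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

__all__ = [
    "G4_PATTERN",
    "MotifHit",
    "find_g4_motifs",
    "match_experimental_g4",
    "test_g4_enrichment",
]

G4_PATTERN = re.compile(r"[AU]GGA(.{0,6})[AU]GGA(.{0,6})[AU]GGA(.{0,6})[AU]GGA")
_VALID = set("ACGU")


@dataclass
class MotifHit:
    sequence_id: str
    start: int
    end: int
    match: str


def _to_rna(seq: str, sequence_id: str = "?") -> str:
    s = seq.upper().replace("T", "U")
    for i, ch in enumerate(s):
        if ch not in _VALID:
            raise ValueError(
                f"non-nucleotide character {ch!r} at position {i} of {sequence_id}")
    return s


def find_g4_motifs(seq: str, sequence_id: str = "seq",
                   overlapping: bool = False) -> list[MotifHit]:
    """Leftmost non-overlapping G-quadruplex motif matches in an RNA
    sequence (T is mapped to U on input).

    With ``overlapping`` every start position is probed instead.
    """
    s = _to_rna(seq, sequence_id)
    hits = []
    if not overlapping:
        for m in G4_PATTERN.finditer(s):
            hits.append(MotifHit(sequence_id, m.start(), m.end(), m.group(0)))
    else:
        i = 0
        while True:
            m = G4_PATTERN.search(s, i)
            if m is None:
                break
            hits.append(MotifHit(sequence_id, m.start(), m.end(), m.group(0)))
            i = m.start() + 1
    return hits


def match_experimental_g4(utr_seqs: dict[str, str],
                          g4_seqs: list[str] | dict[str, str]) -> pd.Series:
    """True iff any experimentally determined G4 sequence occurs verbatim
    (after T->U mapping) within the UTR sequence."""
    if not g4_seqs:
        raise ValueError("empty G4 sequence set")
    g4_list = list(g4_seqs.values()) if isinstance(g4_seqs, dict) else list(g4_seqs)
    g4_rna = [_to_rna(g, "g4") for g in g4_list]
    out = {}
    for gid, seq in utr_seqs.items():
        if not seq:
            out[gid] = False
            continue
        s = _to_rna(seq, gid)
        out[gid] = any(g in s for g in g4_rna)
    return pd.Series(out, name="has_experimental_g4")


def test_g4_enrichment(targets: set, nontargets: set,
                       has_motif: pd.Series) -> dict:
    """Fisher exact test of motif presence in targets vs nontargets.

    The sets must be disjoint and flagged for every gene. Returns the 2x2
    table, odds ratio and two-sided p; a degenerate margin yields NA with
    a warning field set.
    """
    if targets & nontargets:
        raise ValueError("target and nontarget sets overlap")
    missing = (targets | nontargets) - set(has_motif.index)
    if missing:
        raise ValueError(f"motif flags missing for {len(missing)} genes")
    t_pos = sum(bool(has_motif[g]) for g in targets)
    n_pos = sum(bool(has_motif[g]) for g in nontargets)
    table = [[t_pos, len(targets) - t_pos], [n_pos, len(nontargets) - n_pos]]
    flat = [v for row in table for v in row]
    cols = (table[0][0] + table[1][0], table[0][1] + table[1][1])
    if 0 in cols or len(targets) == 0 or len(nontargets) == 0:
        return {"table": table, "odds_ratio": float("nan"), "p": float("nan"),
                "warning": "degenerate margin"}
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(odds), "p": float(p)}
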