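"""Global pairwise alignment and cross-species PTM analog calls.

Cross-species analogs of a PTM site are determined by global (end-to-end)
pairwise alignment of the two protein sequences with affine gap penalties
(Needleman-Wunsch/Gotoh; BLOSUM62, gap open 10, extend 1 by default), then
projecting the site's residue position through the alignment.  A site whose
aligned target residue cannot chemically carry the modification (for example
a lysine-ubiquitylation site aligning onto an arginine) has no analog, as
does a site falling inside a deletion in the target.

A gap of length L costs ``gap_open + gap_extend * L``.  Traceback is
deterministic: at equal score, an aligned residue pair is preferred over a
gap in the query, which is preferred over a gap in the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .peptides import PTMSite

__all__ = ["ResidueMap", "AnalogCall", "global_align", "analog_for_site", "blosum62_score"]

NEG_INF = float("-inf")

_blosum62 = None


def blosum62_score(a: str, b: str) -> float:
    """BLOSUM62 substitution score; unknown letters score 0 (neutral)."""
    global _blosum62
    if _blosum62 is None:
        from Bio.Align import substitution_matrices

        _blosum62 = substitution_matrices.load("BLOSUM62")
    alphabet = _blosum62.alphabet
    if a not in alphabet or b not in alphabet or "X" in (a, b):
        return 0.0
    return float(_blosum62[a, b])


@dataclass(frozen=True)
class ResidueMap:
    """Column-wise residue correspondence from a global alignment.

    ``pairs`` lists aligned columns as (query_position, target_position),
    1-based, with ``None`` on the gapped side; positions are strictly
    increasing on both sides.
    """

    query_protein: str
    target_protein: str
    pairs: tuple
    alignment_score: float

    def target_position(self, query_position: int) -> int | None:
        for q, t in self.pairs:
            if q == query_position:
                return t
        raise ValueError(f"query position {query_position} not in alignment")


@dataclass(frozen=True)
class AnalogCall:
    """Verdict on the cross-species analog of one PTM site."""

    site: PTMSite
    target_position: int | None
    target_residue: str | None
    verdict: str  # analog | no_analog_incompatible_residue | no_analog_gap
    conserved: bool = False

    def __post_init__(self):
        if self.verdict == "analog" and not self.site.modification.allows(self.target_residue):
            raise ValueError("analog verdict with chemically incompatible target residue")


def global_align(
    seq_a: str,
    seq_b: str,
    score: Callable[[str, str], float] = blosum62_score,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    *,
    query_id: str = "query",
    target_id: str = "target",
) -> ResidueMap:
    """Optimal global alignment of ``seq_a`` (query) against ``seq_b`` (target).

    Gotoh three-state dynamic programming with affine gaps.  ``score`` maps a
    residue pair to a substitution score (default BLOSUM62 with neutral
    unknowns); ``gap_open``/``gap_extend`` are positive penalties.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(seq_a), len(seq_b)
    first = gap_open + gap_extend  # cost of the first residue of a gap

    # state M: a[i] aligned to b[j]; X: gap in query (consumes b); Y: gap in target
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        Y[i][0] = -(gap_open + gap_extend * i)

    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = score(ai, seq_b[j - 1])
            Mi[j] = s + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mi[j - 1] - first, Xi[j - 1] - gap_extend, Yi[j - 1] - first)
            Yi[j] = max(Mp[j] - first, Yp[j] - gap_extend, Xp[j] - first)

    # deterministic traceback: prefer M, then X (gap in query), then Y
    i, j = n, m
    finals = {"M": M[n][m], "X": X[n][m], "Y": Y[n][m]}
    best = max(finals.values())
    state = next(k for k in ("M", "X", "Y") if finals[k] == best)
    cols: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if state == "M":
            cur = M[i][j]
            s = score(seq_a[i - 1], seq_b[j - 1])
            cols.append((i, j))
            i, j = i - 1, j - 1
            cand = {"M": M[i][j] + s, "X": X[i][j] + s, "Y": Y[i][j] + s}
        elif state == "X":
            cur = X[i][j]
            cols.append((None, j))
            j -= 1
            cand = {"M": M[i][j] - first, "X": X[i][j] - gap_extend, "Y": Y[i][j] - first}
        else:
            cur = Y[i][j]
            cols.append((i, None))
            i -= 1
            cand = {"M": M[i][j] - first, "Y": Y[i][j] - gap_extend, "X": X[i][j] - first}
        if i == 0 and j == 0:
            break
        state = next(k for k in ("M", "X", "Y") if cand[k] >= cur - 1e-9)

    cols.reverse()
    return ResidueMap(query_id, target_id, tuple(cols), float(best))


def analog_for_site(
    site: PTMSite,
    query_sequence: str,
    target_sequence: str,
    *,
    target_id: str = "target",
    score: Callable[[str, str], float] = blosum62_score,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AnalogCall:
    """Project a PTM site onto a target protein and classify the analog.

    The modification's allowed-residue set is the sole arbiter of chemical
    compatibility; ``conserved`` additionally reports whether the aligned
    residue letter is identical.
    """
    pos = site.residue_position
    if not 1 <= pos <= len(query_sequence):
        raise ValueError(f"{site.abbreviated_name}: position {pos} outside the query sequence")
    if query_sequence[pos - 1] != site.residue:
        raise ValueError(
            f"{site.abbreviated_name}: query sequence has {query_sequence[pos - 1]} "
            f"at position {pos}, expected {site.residue}"
        )
    rmap = global_align(
        query_sequence, target_sequence, score, gap_open, gap_extend,
        query_id=site.protein_id, target_id=target_id,
    )
    tpos = rmap.target_position(pos)
    if tpos is None:
        return AnalogCall(site, None, None, "no_analog_gap")
    tres = target_sequence[tpos - 1]
    if not site.modification.allows(tres):
        return AnalogCall(site, tpos, tres, "no_analog_incompatible_residue")
    return AnalogCall(site, tpos, tres, "analog", conserved=(tres == site.residue))
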