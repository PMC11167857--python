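"""Modified-peptide sequence strings, PTM sites, and protein localization.

Peptide quantification exports annotate modifications inline with bracketed
nominal mass shifts, e.g. ``K[+112]STGGK[+42]APR``.  This module parses that
notation into a :class:`ModifiedPeptideForm`, localizes forms onto protein
sequences by exact substring search, and defines :class:`PTMSite` — a
biological modification at an absolute residue of a specific histone protein
(e.g. H3 K14 acetylation, "H3K14ac"), the unit of all downstream statistics.

Coordinates are 1-based and inclusive on both peptides and proteins, matching
the field's residue naming (K14 is the 14th residue of the mature protein).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping

from Bio import SeqIO

from .modifications import ModificationDef, MassTable, classify_annotations

DIGESTS = ("trypsin_propionyl", "v8_ambic", "v8_naphos")

__all__ = [
    "DIGESTS",
    "PeptideParseError",
    "ModifiedPeptideForm",
    "PTMSite",
    "parse_modified_sequence",
    "localize_peptide",
    "read_fasta",
]


class PeptideParseError(ValueError):
    """Malformed modified-sequence string; message names the offending offset."""


_BRACKET = re.compile(r"\[\s*([+-])\s*(\d+)\s*\]")


@dataclass(frozen=True)
class ModifiedPeptideForm:
    """One quantifiable peptide species.

    ``annotations`` holds 1-based peptide positions with the *total* integer
    mass shift observed at that residue (multiple bracket groups on one
    residue are summed at parse time and decomposed later by classification).
    ``nterm`` records that the first annotation was written before any
    residue, i.e. explicitly N-terminal.

    ``status`` after localization is one of ``"unlocalized"``, ``"localized"``
    or ``"ambiguous"``; ambiguity and absence are statuses, not errors.
    """

    stripped_sequence: str
    annotations: tuple = ()
    digest: str | None = None
    nterm: bool = False
    source_protein: str | None = None
    protein_start: int | None = None
    status: str = "unlocalized"
    all_hits: tuple = ()

    def __post_init__(self):
        n = len(self.stripped_sequence)
        for pos, _mass in self.annotations:
            if not 1 <= pos <= n:
                raise ValueError(f"annotation position {pos} outside 1..{n}")
        if self.protein_start is not None and self.status != "localized":
            raise ValueError("protein_start set on a non-localized form")

    # -- serialization -------------------------------------------------
    def serialize(self) -> str:
        """Canonical bracket notation (no spaces); parse∘serialize is identity."""
        ann = dict(self.annotations)
        out = []
        if self.nterm and 1 in ann:
            out.append(f"[{ann.pop(1):+d}]")
        for i, aa in enumerate(self.stripped_sequence, start=1):
            out.append(aa)
            if i in ann:
                out.append(f"[{ann[i]:+d}]")
        return "".join(out)

    def protein_position(self, peptide_position: int) -> int:
        if self.protein_start is None:
            raise ValueError("form is not localized")
        return self.protein_start + peptide_position - 1

    @property
    def protein_end(self) -> int:
        return self.protein_start + len(self.stripped_sequence) - 1

    def classify(self, table: MassTable, *, on_unresolved: str = "raise"):
        """Resolve this form's annotations against a mass table.

        Returns ``(assigned, unresolved)`` as in
        :func:`histodiff.modifications.classify_annotations`.
        """
        return classify_annotations(
            self.stripped_sequence, self.annotations, table, on_unresolved=on_unresolved
        )


@dataclass(frozen=True)
class PTMSite:
    """A biological modification at a specific residue of a specific protein."""

    protein_id: str
    protein_name: str
    residue_position: int
    residue: str
    modification: ModificationDef
    abbreviated_name: str

    def __post_init__(self):
        if self.modification.lab_introduced:
            raise ValueError(
                f"{self.abbreviated_name}: lab-introduced chemistry "
                f"({self.modification.name}) cannot define a biological PTM site"
            )
        if not self.modification.allows(self.residue):
            raise ValueError(
                f"{self.abbreviated_name}: {self.modification.name} is not chemically "
                f"allowed on residue {self.residue}"
            )


def parse_modified_sequence(raw: str, *, digest: str | None = None) -> ModifiedPeptideForm:
    """Parse a bracket-annotated peptide string.

    Whitespace inside brackets (``"[+ 42]"`` as printed in figure captions) is
    tolerated and ignored.  A bracket group before any residue is assigned to
    peptide position 1 with the N-terminal flag set.  Multiple groups on the
    same residue are summed into one nominal value.

    Raises :class:`PeptideParseError` on unbalanced brackets, non-integer
    shifts, or any character outside ``A-Z``/bracket groups, naming the
    0-based offset of the problem.
    """
    if not raw:
        raise PeptideParseError("empty sequence string")
    sequence: list[str] = []
    ann: dict[int, int] = {}
    nterm = False
    i = 0
    while i < len(raw):
        ch = raw[i]
        if ch == "[":
            m = _BRACKET.match(raw, i)
            if m is None:
                raise PeptideParseError(f"malformed bracket group at offset {i}: {raw[i:i+8]!r}")
            mass = int(m.group(2)) * (1 if m.group(1) == "+" else -1)
            if not sequence:
                # leading group: N-terminal, attaches to the first residue
                nterm = True
                ann[1] = ann.get(1, 0) + mass
            else:
                pos = len(sequence)
                ann[pos] = ann.get(pos, 0) + mass
            i = m.end()
        elif ch.isalpha() and ch.isupper():
            sequence.append(ch)
            i += 1
        elif ch == "]":
            raise PeptideParseError(f"unmatched ']' at offset {i}")
        else:
            raise PeptideParseError(f"unexpected character {ch!r} at offset {i}")
    if not sequence:
        raise PeptideParseError("no residues in sequence string")
    if nterm and 1 not in ann:  # pragma: no cover - cannot happen by construction
        raise PeptideParseError("internal: N-terminal flag without position-1 annotation")
    return ModifiedPeptideForm(
        stripped_sequence="".join(sequence),
        annotations=tuple(sorted(ann.items())),
        digest=digest,
        nterm=nterm,
    )


def localize_peptide(
    form: ModifiedPeptideForm, proteins: Mapping[str, str]
) -> ModifiedPeptideForm:
    """Exact substring search of the stripped sequence against each protein.

    A unique hit sets ``source_protein``/``protein_start`` and status
    ``"localized"``; multiple hits set status ``"ambiguous"`` with every hit
    recorded in ``all_hits``; zero hits set ``"unlocalized"``.  Repeated
    occurrences within one protein also count as distinct hits.
    """
    if not proteins:
        raise ValueError("protein collection is empty")
    hits: list[tuple[str, int]] = []
    needle = form.stripped_sequence
    for pid, seq in proteins.items():
        start = seq.find(needle)
        while start != -1:
            hits.append((pid, start + 1))
            start = seq.find(needle, start + 1)
    if len(hits) == 1:
        pid, start = hits[0]
        return replace(
            form, source_protein=pid, protein_start=start, status="localized",
            all_hits=tuple(hits),
        )
    status = "ambiguous" if hits else "unlocalized"
    return replace(
        form, source_protein=None, protein_start=None, status=status, all_hits=tuple(hits)
    )


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {protein_id: sequence}; id is the first header token."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records
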