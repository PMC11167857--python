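"""Nominal-mass modification definitions and mass-shift classification.

Bottom-up histone workflows annotate peptides with integer ("nominal") mass
shifts such as ``K[+42]`` rather than exact monoisotopic masses.  This module
holds the table that resolves a ``(nominal mass, residue)`` pair to a
modification identity (named after its Unimod entry), distinguishes biological
marks from lab-introduced derivatization chemistry (propionylation), and
decomposes composite N-terminal shifts such as ``+112`` on an N-terminal
lysine into an N-terminal plus a side-chain propionyl group.

The default table resolves ``+42`` to acetylation; at nominal resolution
``+42`` is ambiguous between acetyl and trimethyl, so the table is
configuration and can be overridden per residue (see :func:`load_mass_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

NTERM = "peptide-N-term"

__all__ = [
    "NTERM",
    "ModificationDef",
    "MassTable",
    "ClassificationError",
    "default_mass_table",
    "load_mass_table",
    "dump_mass_table",
    "classify_annotations",
]


@dataclass(frozen=True)
class ModificationDef:
    """One resolvable modification identity.

    Parameters
    ----------
    name : str
        Human-readable name, e.g. ``"acetyl"``.
    unimod_accession : int
        Unimod accession number; used downstream as the per-PTM covariate of
        the FDR regression.
    nominal_mass : int
        Nonzero integer mass shift in Da as printed in peptide annotations.
    allowed_residues : frozenset of str
        One-letter residue codes (plus ``"peptide-N-term"``) the modification
        can chemically occur on.  Sole arbiter of residue compatibility in
        homology analog calls.
    lab_introduced : bool
        True for derivatization chemistry (propionylation).  Lab-introduced
        definitions never define a biological PTM site.
    """

    name: str
    unimod_accession: int
    nominal_mass: int
    allowed_residues: frozenset = field(default_factory=frozenset)
    lab_introduced: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.nominal_mass, int) or self.nominal_mass == 0:
            raise ValueError(f"nominal_mass must be a nonzero integer, got {self.nominal_mass!r}")
        if not self.allowed_residues:
            raise ValueError(f"modification {self.name!r} has empty allowed_residues")
        object.__setattr__(self, "allowed_residues", frozenset(self.allowed_residues))

    def allows(self, residue: str) -> bool:
        return residue in self.allowed_residues


class ClassificationError(ValueError):
    """A mass shift could not be resolved to a unique modification."""


class MassTable:
    """Lookup from (nominal mass, residue) to a unique :class:`ModificationDef`.

    Ambiguity — two definitions claiming the same (mass, residue) pair — is a
    configuration error and raises at construction time.
    """

    def __init__(self, defs: Iterable[ModificationDef]):
        self.defs = list(defs)
        self._by_mass_residue: dict[tuple[int, str], ModificationDef] = {}
        for d in self.defs:
            for res in d.allowed_residues:
                key = (d.nominal_mass, res)
                if key in self._by_mass_residue:
                    raise ValueError(
                        f"ambiguous mass table: ({d.nominal_mass:+d}, {res}) claimed by both "
                        f"{self._by_mass_residue[key].name!r} and {d.name!r}"
                    )
                self._by_mass_residue[key] = d

    def lookup(self, mass: int, residue: str) -> ModificationDef | None:
        return self._by_mass_residue.get((mass, residue))

    def get(self, name: str) -> ModificationDef:
        for d in self.defs:
            if d.name == name:
                return d
        raise KeyError(f"no modification named {name!r} in mass table")

    def nterm_defs(self) -> list[ModificationDef]:
        return [d for d in self.defs if NTERM in d.allowed_residues]

    def __iter__(self):
        return iter(self.defs)

    def __len__(self) -> int:
        return len(self.defs)


def default_mass_table() -> MassTable:
    """The shipped nominal-mass table for propionylation-based histone work.

    +42 resolves to acetyl on K/S/T and the peptide N-terminus; +56 is the
    propionyl derivatization label (lab-introduced); +114 is the GG/ubiquityl
    tryptic remnant on K; +14/+28 are mono/di-methylation on K/R; +32 is
    dioxidation; +156 the 4-hydroxynonenal adduct.  Composite +112 is not a
    table entry — it decomposes into N-terminal + side-chain propionyl (see
    :func:`classify_annotations`).
    """
    return MassTable(
        [
            ModificationDef("acetyl", 1, 42, frozenset({"K", "S", "T", NTERM})),
            ModificationDef("propionyl", 58, 56, frozenset({"K", NTERM}), lab_introduced=True),
            ModificationDef("gg", 121, 114, frozenset({"K"})),
            ModificationDef("methyl", 34, 14, frozenset({"K", "R"})),
            ModificationDef("dimethyl", 36, 28, frozenset({"K", "R"})),
            ModificationDef("dioxidation", 425, 32, frozenset({"M", "W", "F", "Y"})),
            ModificationDef("hne", 53, 156, frozenset({"C", "H", "K"})),
        ]
    )


def load_mass_table(path) -> MassTable:
    """Read a mass table from YAML (the format :func:`dump_mass_table` writes)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defs = [
        ModificationDef(
            name=entry["name"],
            unimod_accession=int(entry["unimod_accession"]),
            nominal_mass=int(entry["nominal_mass"]),
            allowed_residues=frozenset(entry["allowed_residues"]),
            lab_introduced=bool(entry.get("lab_introduced", False)),
        )
        for entry in raw["modifications"]
    ]
    return MassTable(defs)


def dump_mass_table(table: MassTable, path) -> None:
    """Write a mass table as YAML; round-trips through :func:`load_mass_table`."""
    payload = {
        "modifications": [
            {
                "name": d.name,
                "unimod_accession": d.unimod_accession,
                "nominal_mass": d.nominal_mass,
                "allowed_residues": sorted(d.allowed_residues),
                "lab_introduced": d.lab_introduced,
            }
            for d in table.defs
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def classify_annotations(
    sequence: str,
    annotations: Sequence[tuple[int, int]],
    table: MassTable,
    *,
    on_unresolved: str = "raise",
) -> tuple[list[tuple[int, ModificationDef]], list[tuple[int, int, list[str]]]]:
    """Resolve (position, nominal mass) annotations to modification identities.

    Resolution per annotation:

    1. direct lookup of ``(mass, residue-at-position)``;
    2. if that fails at peptide position 1: decomposition of the shift into an
       N-terminus-allowed mass plus a residue-allowed mass (the exhaustive
       pair search over the table), e.g. ``+112`` on an N-terminal K becomes
       N-terminal propionyl (+56) plus side-chain propionyl (+56); a pure
       N-terminal match of the full mass is also accepted;
    3. otherwise unresolved.

    A decomposition or N-terminal resolution with more than one candidate is
    ambiguous and treated as unresolved (candidates listed).

    Parameters
    ----------
    on_unresolved : {"raise", "flag"}
        ``"raise"`` raises :class:`ClassificationError` naming the candidates
        considered; ``"flag"`` collects unresolved annotations in the second
        return value so callers can report them without dropping the peptide.

    Returns
    -------
    assigned : list of (position, ModificationDef)
        May contain two entries for one position when a composite N-terminal
        shift decomposes.
    unresolved : list of (position, mass, candidates-considered)
    """
    assigned: list[tuple[int, ModificationDef]] = []
    unresolved: list[tuple[int, int, list[str]]] = []
    for pos, mass in annotations:
        residue = sequence[pos - 1]
        direct = table.lookup(mass, residue)
        if direct is not None:
            assigned.append((pos, direct))
            continue
        candidates: list[tuple[ModificationDef, ...]] = []
        considered: list[str] = []
        if pos == 1:
            for nt in table.nterm_defs():
                considered.append(f"{nt.name}({nt.nominal_mass:+d} N-term)")
                if nt.nominal_mass == mass:
                    candidates.append((nt,))
                side = table.lookup(mass - nt.nominal_mass, residue)
                if side is not None:
                    candidates.append((nt, side))
        if len(candidates) == 1:
            assigned.extend((pos, d) for d in candidates[0])
        else:
            if len(candidates) > 1:
                considered = [" + ".join(d.name for d in combo) for combo in candidates]
            if on_unresolved == "raise":
                raise ClassificationError(
                    f"cannot resolve {mass:+d} on {residue}{pos}: "
                    + (f"ambiguous between {considered}" if len(candidates) > 1
                       else f"no match (considered: {considered or 'direct lookup only'})")
                )
            unresolved.append((pos, mass, considered))
    return assigned, unresolved
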