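"""Synthetic stand-in reference sequences for the worked histone examples.

These are NOT database sequences: they are synthetic histone-tail stand-ins
constructed so that the documented relationships hold offline —

* the tilapia-style H1 isoform X1 tail carries the worked K16 site and its
  K16 aligns onto an arginine (position 24) of the human-style H1 stand-in,
  the configuration under which a lysine-ubiquitylation site has no analog;
* the H1-like tail starts with the acetylatable serine 1 shared with the
  human-style H1 stand-in;
* the H3 tails are identical between the two species stand-ins, so K14/K18
  sites project onto conserved lysines.

Real accessions (e.g. XP_019210164.1, AAA63187.1) can be supplied as FASTA at
run time; nothing in the package requires them.
"""

from __future__ import annotations

from .modifications import MassTable, default_mass_table
from .peptides import PTMSite

__all__ = ["SEQUENCES", "QUERY_PROTEINS", "TARGET_PROTEINS", "TARGET_BY_QUERY",
           "write_reference_fasta", "worked_panel"]

_H1_TAIL = "LIVQAVSASKERSGVSLAALKKSLAAAGYDVEKNNSRIK"
_H3_TAIL = "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTE"

SEQUENCES: dict[str, str] = {
    # tilapia-style stand-ins
    "H1_isoX1_syn": "SEEAPAPAPAPAKAAKKKTTASKPKKVGPSVGE" + _H1_TAIL,
    "H1_like_syn": "SEEAPAPAPAPAKAAKKKKTTASKPKKVGPSVGE" + _H1_TAIL,
    "H3_syn": _H3_TAIL,
    # human-style stand-ins: H1 has an 8-residue insertion after S1 and an
    # arginine where the isoform-X1 K16 projects (position 24); H3 is
    # identical to the tilapia-style tail
    "human_H1_syn": "S" + "TTAPAAPA" + "EEAPAPAPAPAKAA" + "R" + "KKTTASKPKKVGPSVGE" + _H1_TAIL,
    "human_H3_syn": _H3_TAIL,
}


QUERY_PROTEINS = {k: SEQUENCES[k] for k in ("H1_isoX1_syn", "H1_like_syn", "H3_syn")}
TARGET_PROTEINS = {k: SEQUENCES[k] for k in ("human_H1_syn", "human_H3_syn")}
TARGET_BY_QUERY = {
    "H1_isoX1_syn": "human_H1_syn",
    "H1_like_syn": "human_H1_syn",
    "H3_syn": "human_H3_syn",
}


def write_reference_fasta(path, names=None) -> None:
    names = list(SEQUENCES) if names is None else list(names)
    with open(path, "w") as fh:
        for name in names:
            fh.write(f">{name} synthetic histone-tail stand-in\n{SEQUENCES[name]}\n")


def worked_panel(mass_table: MassTable | None = None) -> list[PTMSite]:
    """The four worked PTM sites: H1K16ub, H1S1ac, H3K14ac, H3K18ub."""
    t = mass_table or default_mass_table()
    return [
        PTMSite("H1_isoX1_syn", "H1 isoform X1", 16, "K", t.get("gg"), "H1K16ub"),
        PTMSite("H1_like_syn", "H1-like", 1, "S", t.get("acetyl"), "H1S1ac"),
        PTMSite("H3_syn", "H3", 14, "K", t.get("acetyl"), "H3K14ac"),
        PTMSite("H3_syn", "H3", 18, "K", t.get("gg"), "H3K18ub"),
    ]
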