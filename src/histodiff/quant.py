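"""Per-sample PTM site occupancy: relative abundance, beta- and M-values.

The relative abundance (occupancy) of a PTM site in a sample is, per digest,

    RA = 100 * sum(area of covering peptide forms carrying the mark at the
                   target residue) / sum(area of all covering forms)

computed separately within each of the three parallel digests and then
averaged, unweighted, over the digests that yielded signal.  "Covering" means
the localized peptide span includes the site's residue; "unmodified" means
lacking the mark of interest at the target residue — a form may well carry
other modifications elsewhere and still count as unmodified for this site.

beta = RA/100 clamped into [eps, 1-eps] so occupancies of exactly 0% or 100%
stay testable; M = log2(beta/(1-beta)), the logit used for group statistics
(the beta/M convention is borrowed from the DNA-methylation literature; the
log base is configurable and only rescales M by a constant).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .modifications import MassTable
from .peptides import DIGESTS, ModifiedPeptideForm, PTMSite, localize_peptide, parse_modified_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "QuantTable",
    "SampleDesign",
    "PTMQuantProfile",
    "PTMMatrix",
    "covering_forms",
    "relative_abundance_per_digest",
    "mean_relative_abundance",
    "build_ptm_matrix",
    "read_quant_table",
    "read_design_table",
]

REQUIRED_COLUMNS = ("modified_sequence", "digest", "sample_id", "normalized_area")

SHORT_TERM_GROUPS = ("FW", "SW", "SW_FW")
LONG_TERM_GROUPS = ("S0", "S1", "S3")
GROUPS_BY_EXPERIMENT = {"short_term": SHORT_TERM_GROUPS, "long_term": LONG_TERM_GROUPS}
TISSUES = ("gills", "kidney", "testes")


class QuantTable:
    """Long-format peptide quantification records.

    One row per (peptide form, sample, digest) with a nonnegative normalized
    area (arbitrary normalized-intensity units; inputs are already normalized
    upstream, no between-sample normalization happens here).
    """

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"quant table missing required columns: {missing}")
        records = records.copy()
        records["normalized_area"] = records["normalized_area"].astype(float)
        if (records["normalized_area"] < 0).any():
            raise ValueError("normalized_area must be nonnegative")
        bad = set(records["digest"]) - set(DIGESTS)
        if bad:
            raise ValueError(f"unknown digest condition(s): {sorted(bad)}; expected {DIGESTS}")
        dup = records.duplicated(subset=["modified_sequence", "sample_id", "digest"])
        if dup.any():
            key = records.loc[dup.idxmax(), ["modified_sequence", "sample_id", "digest"]]
            raise ValueError(
                "duplicate (peptide form, sample, digest) record: "
                f"{tuple(key)} (and possibly others)"
            )
        self.records = records

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def write(self, path, *, sep: str = ",") -> None:
        self.records.to_csv(path, sep=sep, index=False)


class SampleDesign:
    """Sample metadata: fish, tissue, experiment and treatment group.

    Groups must be consistent with the experiment: FW/SW/SW_FW belong to the
    short-term transfer experiment, S0/S1/S3 to the long-term salinity-pulse
    experiment.
    """

    def __init__(self, table: pd.DataFrame):
        required = ("sample_id", "fish_id", "tissue", "experiment", "group")
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        table = table.copy()
        if table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design table")
        bad_tissue = set(table["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValueError(f"unknown tissue(s): {sorted(bad_tissue)}")
        for _, row in table.iterrows():
            groups = GROUPS_BY_EXPERIMENT.get(row["experiment"])
            if groups is None:
                raise ValueError(f"unknown experiment {row['experiment']!r}")
            if row["group"] not in groups:
                raise ValueError(
                    f"group {row['group']!r} inconsistent with experiment "
                    f"{row['experiment']!r} (expected one of {groups})"
                )
        self.table = table.set_index("sample_id", drop=False)

    def samples(self, tissue=None, experiment=None, group=None) -> list[str]:
        t = self.table
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        if experiment is not None:
            t = t[t["experiment"] == experiment]
        if group is not None:
            t = t[t["group"] == group]
        return list(t["sample_id"])

    def write(self, path, *, sep: str = ",") -> None:
        self.table.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class PTMQuantProfile:
    """Occupancy of one PTM site in one sample (percent / beta / M)."""

    site: str
    sample_id: str
    per_digest_ra: Mapping[str, float]
    relative_abundance: float
    beta: float
    m_value: float


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_quant_table(path) -> QuantTable:
    """Read a delimited long-format quant table (comma or tab, auto-detected)."""
    return QuantTable(pd.read_csv(path, sep=_sniff_sep(path)))


def read_design_table(path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep=_sniff_sep(path)))


# ---------------------------------------------------------------------------
# form annotation
# ---------------------------------------------------------------------------

def annotate_forms(
    sequences_by_digest: Iterable[tuple[str, str]],
    proteins: Mapping[str, str],
    mass_table: MassTable,
    *,
    ambiguous_policy: str = "exclude",
) -> pd.DataFrame:
    """Parse, localize and classify each unique (sequence, digest) pair.

    Returns one row per usable localized form with its protein span and the
    set of resolved (absolute protein position, modification name) marks.
    Ambiguously localized forms are excluded by default (to avoid double
    counting across histone variants); with ``ambiguous_policy="all_hits"``
    they contribute one row per hit.  Unresolved mass shifts are logged and
    the form is kept — an unknown mark elsewhere on the peptide does not
    disqualify it from covering a site.
    """
    if ambiguous_policy not in ("exclude", "all_hits"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    rows = []
    n_ambiguous = n_unlocalized = n_unresolved = 0
    parse_cache: dict[str, ModifiedPeptideForm] = {}
    for seq, digest in sequences_by_digest:
        base = parse_cache.get(seq)
        if base is None:
            base = localize_peptide(parse_modified_sequence(seq), proteins)
            parse_cache[seq] = base
        if base.status == "unlocalized":
            n_unlocalized += 1
            continue
        hits = base.all_hits
        if base.status == "ambiguous":
            n_ambiguous += 1
            if ambiguous_policy == "exclude":
                continue
        assigned, unresolved = base.classify(mass_table, on_unresolved="flag")
        if unresolved:
            n_unresolved += 1
        for pid, start in hits:
            marks = frozenset(
                (start + pos - 1, mod.name) for pos, mod in assigned if not mod.lab_introduced
            )
            rows.append(
                {
                    "modified_sequence": seq,
                    "digest": digest,
                    "protein_id": pid,
                    "start": start,
                    "end": start + len(base.stripped_sequence) - 1,
                    "marks": marks,
                }
            )
    if n_unlocalized or n_ambiguous or n_unresolved:
        logger.info(
            "form annotation: %d unlocalized, %d ambiguous (%s), %d with unresolved masses",
            n_unlocalized, n_ambiguous, ambiguous_policy, n_unresolved,
        )
    return pd.DataFrame(
        rows, columns=["modified_sequence", "digest", "protein_id", "start", "end", "marks"]
    )


# ---------------------------------------------------------------------------
# spec-surface single-site operations
# ---------------------------------------------------------------------------

def covering_forms(
    site: PTMSite,
    forms: Iterable[ModifiedPeptideForm],
    mass_table: MassTable,
    digest: str | None = None,
) -> tuple[list[ModifiedPeptideForm], list[ModifiedPeptideForm]]:
    """Partition localized forms covering the site into (modified, unmodified).

    Modified means the form carries ``site.modification`` at exactly
    ``site.residue_position``; the same mark at a different residue, or any
    other mark, leaves the form in the unmodified partition.
    """
    modified, unmodified = [], []
    for form in forms:
        if form.status != "localized" or form.source_protein != site.protein_id:
            continue
        if digest is not None and form.digest != digest:
            continue
        if not (form.protein_start <= site.residue_position <= form.protein_end):
            continue
        assigned, _ = form.classify(mass_table, on_unresolved="flag")
        has_mark = any(
            form.protein_position(pos) == site.residue_position
            and mod.name == site.modification.name
            for pos, mod in assigned
        )
        (modified if has_mark else unmodified).append(form)
    return modified, unmodified


def relative_abundance_per_digest(
    site: PTMSite,
    table: QuantTable,
    sample_id: str,
    digest: str,
    proteins: Mapping[str, str],
    mass_table: MassTable,
) -> float | None:
    """RA (percent) for one (site, sample, digest); None when no covering signal."""
    recs = table.records
    recs = recs[(recs["sample_id"] == sample_id) & (recs["digest"] == digest)]
    forms = {
        seq: localize_peptide(parse_modified_sequence(seq, digest=digest), proteins)
        for seq in recs["modified_sequence"].unique()
    }
    modified, unmodified = covering_forms(site, forms.values(), mass_table, digest)
    mod_seqs = {f.serialize() for f in modified}
    cov_seqs = mod_seqs | {f.serialize() for f in unmodified}
    num = den = 0.0
    for seq, area in zip(recs["modified_sequence"], recs["normalized_area"]):
        canon = forms[seq].serialize()
        if canon in cov_seqs:
            den += area
            if canon in mod_seqs:
                num += area
    if den == 0:
        return None
    return 100.0 * num / den


def _beta_m(ra: float, eps: float, log_base: float) -> tuple[float, float]:
    beta = min(max(ra / 100.0, eps), 1.0 - eps)
    m = math.log(beta / (1.0 - beta), log_base)
    return beta, m


def mean_relative_abundance(
    site: PTMSite,
    table: QuantTable,
    sample_id: str,
    proteins: Mapping[str, str],
    mass_table: MassTable,
    *,
    eps: float = 1e-4,
    log_base: float = 2.0,
) -> PTMQuantProfile | None:
    """Average the per-digest RAs into one profile; None if all digests missing."""
    per_digest = {}
    for digest in DIGESTS:
        ra = relative_abundance_per_digest(site, table, sample_id, digest, proteins, mass_table)
        if ra is not None:
            per_digest[digest] = ra
    if not per_digest:
        logger.warning("site %s sample %s: no covering signal in any digest",
                       site.abbreviated_name, sample_id)
        return None
    ra = float(np.mean(list(per_digest.values())))
    beta, m = _beta_m(ra, eps, log_base)
    return PTMQuantProfile(site.abbreviated_name, sample_id, per_digest, ra, beta, m)


# ---------------------------------------------------------------------------
# bulk matrix construction
# ---------------------------------------------------------------------------

class PTMMatrix:
    """PTM x sample occupancy matrices (RA percent, beta, M) plus per-digest detail."""

    def __init__(self, ra: pd.DataFrame, beta: pd.DataFrame, m: pd.DataFrame,
                 per_digest: pd.DataFrame, missing: list, panel: Sequence[PTMSite]):
        self.ra = ra
        self.beta = beta
        self.m = m
        self.per_digest = per_digest
        self.missing = missing
        self.panel = list(panel)
        self.sites = {s.abbreviated_name: s for s in panel}

    @property
    def n_missing(self) -> int:
        return len(self.missing)

    def profile(self, site_name: str, sample_id: str) -> PTMQuantProfile | None:
        ra = self.ra.at[site_name, sample_id]
        if pd.isna(ra):
            return None
        pd_rows = self.per_digest
        sel = pd_rows[(pd_rows["site"] == site_name) & (pd_rows["sample_id"] == sample_id)]
        per_digest = dict(zip(sel["digest"], sel["ra"]))
        return PTMQuantProfile(
            site_name, sample_id, per_digest, float(ra),
            float(self.beta.at[site_name, sample_id]), float(self.m.at[site_name, sample_id]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (PTM, sample) with RA, beta and M."""
        long = self.ra.stack(future_stack=True).rename("relative_abundance").reset_index()
        long.columns = ["ptm", "sample_id", "relative_abundance"]
        long["beta"] = self.beta.stack(future_stack=True).values
        long["m_value"] = self.m.stack(future_stack=True).values
        return long

    def write(self, path, *, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def build_ptm_matrix(
    panel: Sequence[PTMSite],
    table: QuantTable,
    proteins: Mapping[str, str],
    mass_table: MassTable,
    *,
    eps: float = 1e-4,
    log_base: float = 2.0,
    ambiguous_policy: str = "exclude",
) -> PTMMatrix:
    """Quantify every panel site in every sample (vectorized over records).

    Profiles with no covering signal in any digest are left missing (NaN) and
    counted in the completeness report (``matrix.missing``), never imputed.
    """
    if not panel:
        raise ValueError("PTM panel is empty")
    names = [s.abbreviated_name for s in panel]
    if len(set(names)) != len(names):
        raise ValueError("abbreviated_name must be unique within the panel")

    recs = table.records
    uniq = recs[["modified_sequence", "digest"]].drop_duplicates()
    forms = annotate_forms(
        uniq.itertuples(index=False, name=None), proteins, mass_table,
        ambiguous_policy=ambiguous_policy,
    )

    # coverage: (site, form, digest) rows with a modified-indicator
    cov_rows = []
    for site in panel:
        sel = forms[
            (forms["protein_id"] == site.protein_id)
            & (forms["start"] <= site.residue_position)
            & (forms["end"] >= site.residue_position)
        ]
        if sel.empty:
            continue
        key = (site.residue_position, site.modification.name)
        is_mod = sel["marks"].map(lambda marks, k=key: k in marks)
        cov_rows.append(pd.DataFrame({
            "site": site.abbreviated_name,
            "modified_sequence": sel["modified_sequence"].values,
            "digest": sel["digest"].values,
            "is_modified": is_mod.values,
        }))
    sample_ids = table.sample_ids
    if cov_rows:
        coverage = pd.concat(cov_rows, ignore_index=True)
        merged = coverage.merge(recs, on=["modified_sequence", "digest"], how="inner")
        merged["mod_area"] = merged["normalized_area"].where(merged["is_modified"], 0.0)
        g = merged.groupby(["site", "sample_id", "digest"], sort=False)
        sums = g.agg(num=("mod_area", "sum"), den=("normalized_area", "sum")).reset_index()
        sums = sums[sums["den"] > 0]
        sums["ra"] = 100.0 * sums["num"] / sums["den"]
        per_digest = sums[["site", "sample_id", "digest", "ra"]].reset_index(drop=True)
        ra_mean = per_digest.groupby(["site", "sample_id"])["ra"].mean().unstack()
    else:
        per_digest = pd.DataFrame(columns=["site", "sample_id", "digest", "ra"])
        ra_mean = pd.DataFrame()

    ra = ra_mean.reindex(index=names, columns=sample_ids)
    beta = (ra / 100.0).clip(lower=eps, upper=1.0 - eps)
    m = np.log(beta / (1.0 - beta)) / np.log(log_base)

    missing = [(s, c) for s in names for c in sample_ids if pd.isna(ra.at[s, c])]
    if missing:
        logger.info("PTM matrix: %d of %d profiles missing (no covering signal)",
                    len(missing), len(names) * len(sample_ids))
    return PTMMatrix(ra, beta, m, per_digest, missing, panel)
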