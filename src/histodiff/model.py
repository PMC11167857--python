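"""Model/Results objects for per-tissue differential PTM-occupancy analysis.

:class:`GroupComparisonModel` is built from a quantified PTM x sample matrix
plus the sample design and compares two treatment groups within one tissue
and experiment; :meth:`~GroupComparisonModel.fit` runs the per-site group
tests on M-values, the covariate-conditioned FDR regression across the family
of hypotheses, and returns a :class:`ComparisonResults` carrying estimates,
q-values, responsiveness calls and volcano classes, with a ``summary()``
table.  :func:`run_comparisons` fits every standard group pair per tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import GROUPS_BY_EXPERIMENT, PTMMatrix, SampleDesign, TISSUES
from .stats import (
    DEFAULT_LAMBDA_GRID,
    conditioned_q_values,
    estimate_pi0_regression,
    fold_change,
    student_t_test,
    volcano_class,
    welch_t_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonSpec",
    "GroupComparisonModel",
    "ComparisonResults",
    "run_comparisons",
    "STANDARD_PAIRS",
]

# treatment (A) vs reference (B) pairs fitted per tissue in each experiment
STANDARD_PAIRS = {
    "short_term": (("SW", "FW"), ("SW_FW", "FW"), ("SW", "SW_FW")),
    "long_term": (("S1", "S0"), ("S3", "S0"), ("S3", "S1")),
}

RESULT_COLUMNS = [
    "ptm", "n_a", "n_b", "mean_ra_a", "mean_ra_b", "log2_fc",
    "t", "p", "pi0_hat", "q", "responsive", "volcano_class",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """One correction family: a (tissue, experiment, group pair) comparison."""

    tissue: str
    experiment: str
    group_a: str
    group_b: str

    def __post_init__(self):
        groups = GROUPS_BY_EXPERIMENT.get(self.experiment)
        if groups is None:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.group_a == self.group_b:
            raise ValueError("group_a and group_b must differ")
        for g in (self.group_a, self.group_b):
            if g not in groups:
                raise ValueError(f"group {g!r} not in experiment {self.experiment!r}")

    @property
    def label(self) -> str:
        return f"{self.tissue}:{self.experiment}:{self.group_a}_vs_{self.group_b}"


class GroupComparisonModel:
    """Differential occupancy between two treatment groups in one tissue.

    Parameters
    ----------
    matrix : PTMMatrix
        Quantified panel (M-values for testing, RA percent for fold changes).
    design : SampleDesign
        Sample metadata; selects the samples of each group within the tissue.
    spec : ComparisonSpec
        Which tissue/experiment/group pair this model compares.  Group A is
        the treatment, group B the reference; fold changes are A over B.
    covariates : mapping site name -> covariate label, optional
        Per-PTM categorical covariate of the FDR regression (by convention
        the Unimod accession of the modification).  Defaults to each site's
        ``modification.unimod_accession`` from the panel.
    """

    def __init__(
        self,
        matrix: PTMMatrix,
        design: SampleDesign,
        spec: ComparisonSpec,
        covariates: Mapping[str, object] | None = None,
    ):
        self.matrix = matrix
        self.design = design
        self.spec = spec
        if covariates is None:
            covariates = {s.abbreviated_name: s.modification.unimod_accession
                          for s in matrix.panel}
        self.covariates = dict(covariates)
        self.samples_a = [s for s in design.samples(spec.tissue, spec.experiment, spec.group_a)
                          if s in matrix.ra.columns]
        self.samples_b = [s for s in design.samples(spec.tissue, spec.experiment, spec.group_b)
                          if s in matrix.ra.columns]

    def fit(
        self,
        *,
        q_threshold: float = 0.1,
        fc_threshold: float = 1.0,
        lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
        link: str = "logistic",
        test: str = "welch",
        use_covariates: bool = True,
        min_n: int = 2,
    ) -> "ComparisonResults":
        """Run the family of per-site tests and the conditioned FDR correction.

        Sites with fewer than ``min_n`` non-missing M-values in either group
        are untestable: they are excluded from the family (reducing the
        realized number of hypotheses m) and listed in the results.
        """
        if len(self.samples_a) < min_n or len(self.samples_b) < min_n:
            raise ValueError(
                f"{self.spec.label}: fewer than {min_n} samples in a group "
                f"({len(self.samples_a)} vs {len(self.samples_b)})"
            )
        t_fun = {"welch": welch_t_test, "student": student_t_test}[test]
        rows, untestable = [], []
        for site in self.matrix.panel:
            name = site.abbreviated_name
            ma = self.matrix.m.loc[name, self.samples_a].dropna().to_numpy(float)
            mb = self.matrix.m.loc[name, self.samples_b].dropna().to_numpy(float)
            if ma.size < min_n or mb.size < min_n:
                untestable.append(name)
                continue
            ra_a = float(self.matrix.ra.loc[name, self.samples_a].mean())
            ra_b = float(self.matrix.ra.loc[name, self.samples_b].mean())
            t, p = t_fun(ma, mb)
            rows.append({
                "ptm": name, "n_a": ma.size, "n_b": mb.size,
                "mean_ra_a": ra_a, "mean_ra_b": ra_b,
                "log2_fc": fold_change(ra_a, ra_b), "t": t, "p": p,
            })
        if untestable:
            logger.info("%s: %d untestable site(s) excluded from the family",
                        self.spec.label, len(untestable))
        frame = pd.DataFrame(rows, columns=RESULT_COLUMNS[:8])
        if frame.empty:
            frame = frame.reindex(columns=RESULT_COLUMNS)
            return ComparisonResults(self, frame, untestable, q_threshold, fc_threshold)
        cov = [self.covariates.get(n) for n in frame["ptm"]] if use_covariates else None
        pi0 = estimate_pi0_regression(frame["p"].to_numpy(), cov, lambda_grid, link=link)
        q = conditioned_q_values(frame["p"].to_numpy(), pi0)
        frame["pi0_hat"] = pi0
        frame["q"] = q
        frame["responsive"] = frame["q"] < q_threshold
        frame["volcano_class"] = [
            volcano_class(qi, fc, q_threshold=q_threshold, fc_threshold=fc_threshold)
            for qi, fc in zip(frame["q"], frame["log2_fc"])
        ]
        frame = frame.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
        return ComparisonResults(self, frame, untestable, q_threshold, fc_threshold)


@dataclass
class ComparisonResults:
    """Fitted comparison: one row per tested PTM, sorted by q then p."""

    model: GroupComparisonModel
    frame: pd.DataFrame
    untestable: list = field(default_factory=list)
    q_threshold: float = 0.1
    fc_threshold: float = 1.0

    @property
    def spec(self) -> ComparisonSpec:
        return self.model.spec

    @property
    def m(self) -> int:
        """Realized family size (number of hypotheses actually tested)."""
        return len(self.frame)

    @property
    def responsive(self) -> list[str]:
        return list(self.frame.loc[self.frame["responsive"], "ptm"])

    def volcano_frame(self) -> pd.DataFrame:
        """Per-PTM table for volcano plotting (x = log2 FC, y = -log10 q)."""
        v = self.frame[["ptm", "log2_fc", "q", "volcano_class"]].copy()
        v["neg_log10_q"] = -np.log10(v["q"].clip(lower=1e-300))
        return v

    def plot_volcano(self, ax=None):
        """Convenience scatter of the volcano classes (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.volcano_frame()
        for cls in ("gray", "green", "blue", "red"):
            sel = v[v["volcano_class"] == cls]
            ax.scatter(sel["log2_fc"], sel["neg_log10_q"], s=12, c=cls, label=cls)
        ax.axhline(-np.log10(self.q_threshold), ls="--", lw=0.8, c="k")
        for x in (-self.fc_threshold, self.fc_threshold):
            ax.axvline(x, ls="--", lw=0.8, c="k")
        ax.set_xlabel("log2 fold change (RA %)")
        ax.set_ylabel("-log10 conditioned q")
        ax.set_title(self.spec.label)
        return ax

    def summary(self) -> str:
        s = self.spec
        lines = [
            f"Differential PTM occupancy: {s.tissue}, {s.experiment}, "
            f"{s.group_a} vs {s.group_b} (A vs B, fold change A/B on RA %)",
            f"  hypotheses tested (m): {self.m}; untestable: {len(self.untestable)}",
            f"  samples: n_a={len(self.model.samples_a)}, n_b={len(self.model.samples_b)}",
            f"  responsive (q < {self.q_threshold:g}): {len(self.responsive)}",
        ]
        top = self.frame.head(10)
        if not top.empty:
            lines.append("")
            lines.append(
                top[RESULT_COLUMNS].to_string(
                    index=False,
                    float_format=lambda x: f"{x:.4g}",
                )
            )
        return "\n".join(lines)

    def write(self, path, *, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index=False)


def run_comparisons(
    matrix: PTMMatrix,
    design: SampleDesign,
    *,
    covariates: Mapping[str, object] | None = None,
    tissues: Sequence[str] = TISSUES,
    pairs: Mapping[str, Sequence[tuple[str, str]]] = STANDARD_PAIRS,
    min_n: int = 2,
    **fit_kwargs,
) -> dict[str, ComparisonResults]:
    """Fit every (tissue, experiment, group pair) family present in the design.

    Families with too few samples in a group (for example testes missing for
    an experiment) are skipped with a logged reason, not an error.
    """
    results: dict[str, ComparisonResults] = {}
    for tissue in tissues:
        for experiment, exp_pairs in pairs.items():
            for group_a, group_b in exp_pairs:
                spec = ComparisonSpec(tissue, experiment, group_a, group_b)
                model = GroupComparisonModel(matrix, design, spec, covariates)
                if len(model.samples_a) < min_n or len(model.samples_b) < min_n:
                    logger.info("skipping %s: insufficient samples (%d vs %d)",
                                spec.label, len(model.samples_a), len(model.samples_b))
                    continue
                results[spec.label] = model.fit(min_n=min_n, **fit_kwargs)
    return results
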