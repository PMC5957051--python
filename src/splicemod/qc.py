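"""Candidate-modulator and gene quality filters.

The event-side cascade runs, in order: credible-interval width filter →
read-support filter → median imputation of missing PSI → interquartile-range
filter.  The gene side keeps genes measured in more than ``min_present_frac``
of samples whose expression coefficient of variation is at least ``min_cv``.

Comparison strictness mirrors the wording the thresholds come from: CI width
passes strictly below ``max_ci_width``; the passing fraction must strictly
exceed ``min_ci_frac``; read support is inclusive (``>=``); the PSI IQR must
strictly exceed ``min_iqr``; presence must strictly exceed
``min_present_frac``; CV is kept inclusively at ``>= min_cv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import ExpressionProfile, PsiProfile

__all__ = [
    "FilterConfig",
    "FilterReport",
    "filter_events_ci",
    "filter_events_reads",
    "impute_missing_psi",
    "filter_events_iqr",
    "filter_genes",
    "run_qc",
]

#: Quantile rule used for medians, quartiles and the IQR throughout.
QUANTILE_RULE = "linear"


@dataclass
class FilterConfig:
    """Thresholds of the QC cascade.

    Attributes
    ----------
    max_ci_width
        Events pass in a sample when ``ci_high - ci_low`` is strictly below
        this width.
    min_ci_frac
        Fraction of samples that must pass the CI-width check (strictly
        exceeded); samples with a missing interval count as failing.
    min_reads
        An event is kept when at least one sample has ``max(inc, exc)`` read
        support at or above this count.
    min_iqr
        Events are kept when their (post-imputation) PSI IQR strictly exceeds
        this value.
    min_cv
        Genes are kept when sd/mean of observed expression is at least this.
    min_present_frac
        Genes are kept when the observed fraction of samples strictly
        exceeds this.
    """

    max_ci_width: float = 0.25
    min_ci_frac: float = 0.95
    min_reads: int = 10
    min_iqr: float = 0.10
    min_cv: float = 0.50
    min_present_frac: float = 0.95

    def __post_init__(self) -> None:
        for name in ("min_ci_frac", "min_present_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_reads < 0:
            raise ValueError(f"min_reads must be >= 0, got {self.min_reads}")
        for name in ("max_ci_width", "min_iqr", "min_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_out: int


@dataclass
class FilterReport:
    """Per-stage survivor counts and the identifiers dropped at each stage."""

    stages: list[FilterStage] = field(default_factory=list)
    drops: list[tuple[str, str, str]] = field(default_factory=list)  # id, stage, reason
    metadata: dict = field(default_factory=lambda: {"quantile_rule": QUANTILE_RULE})

    def record(self, stage: str, ids_in: list[str], ids_out: list[str], reason: str) -> None:
        self.stages.append(FilterStage(stage, len(ids_in), len(ids_out)))
        survived = set(ids_out)
        for i in ids_in:
            if i not in survived:
                self.drops.append((i, stage, reason))

    def stage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_out) for s in self.stages],
            columns=["stage", "n_in", "n_out"],
        )

    def drop_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.drops, columns=["id", "stage", "reason"])

    def write(self, stage_path, drop_path) -> None:
        self.stage_frame().to_csv(stage_path, sep="\t", index=False)
        self.drop_frame().to_csv(drop_path, sep="\t", index=False)


def filter_events_ci(
    psi: PsiProfile, cfg: FilterConfig, report: FilterReport | None = None
) -> PsiProfile:
    """Keep events whose CI width passes in strictly more than ``min_ci_frac``
    of samples.  A sample passes when both bounds are present and
    ``ci_high - ci_low < max_ci_width``."""
    width = psi.ci_high.to_numpy(float) - psi.ci_low.to_numpy(float)
    passing = np.where(np.isnan(width), False, width < cfg.max_ci_width)
    n_samples = max(1, len(psi.samples))
    frac = passing.sum(axis=1) / n_samples
    keep = [i for i, f in zip(psi.event_ids, frac) if f > cfg.min_ci_frac]
    out = psi.select_events(keep)
    if report is not None:
        report.record(
            "ci_width",
            psi.event_ids,
            keep,
            f"CI width < {cfg.max_ci_width} in <= {cfg.min_ci_frac:.0%} of samples",
        )
    return out


def filter_events_reads(
    psi: PsiProfile, cfg: FilterConfig, report: FilterReport | None = None
) -> PsiProfile:
    """Keep events with at least ``min_reads`` reads supporting inclusion or
    exclusion in at least one sample."""
    inc = np.nan_to_num(psi.inc_reads.to_numpy(float), nan=0.0)
    exc = np.nan_to_num(psi.exc_reads.to_numpy(float), nan=0.0)
    best = np.maximum(inc, exc).max(axis=1) if inc.shape[1] else np.zeros(inc.shape[0])
    keep = [i for i, b in zip(psi.event_ids, best) if b >= cfg.min_reads]
    out = psi.select_events(keep)
    if report is not None:
        report.record(
            "read_support", psi.event_ids, keep, f"max read support < {cfg.min_reads}"
        )
    return out


def impute_missing_psi(psi: PsiProfile, report: FilterReport | None = None) -> PsiProfile:
    """Fill each missing PSI value with the median of that event's observed
    values.  Observed entries are untouched.  An event with no observed value
    raises ``ValueError`` naming it."""
    values = psi.psi.to_numpy(float).copy()
    for row, eid in enumerate(psi.event_ids):
        mask = np.isnan(values[row])
        if mask.all():
            raise ValueError(f"event {eid!r} has no observed PSI values to impute from")
        if mask.any():
            values[row, mask] = np.median(values[row, ~mask])
    out = PsiProfile(
        events=list(psi.events),
        psi=pd.DataFrame(values, index=psi.psi.index, columns=psi.psi.columns),
        ci_low=psi.ci_low.copy(),
        ci_high=psi.ci_high.copy(),
        inc_reads=psi.inc_reads.copy(),
        exc_reads=psi.exc_reads.copy(),
    )
    if report is not None:
        report.record("impute_missing", psi.event_ids, psi.event_ids, "")
    return out


def filter_events_iqr(
    psi: PsiProfile, cfg: FilterConfig, report: FilterReport | None = None
) -> PsiProfile:
    """Keep events whose PSI interquartile range strictly exceeds ``min_iqr``.

    Quartiles use linear interpolation between order statistics; missing
    values (normally already imputed) are ignored.
    """
    keep = []
    for eid in psi.event_ids:
        vals = psi.psi.loc[eid].to_numpy(float)
        obs = vals[~np.isnan(vals)]
        if obs.size == 0:
            continue
        q1, q3 = np.percentile(obs, [25, 75], method=QUANTILE_RULE)
        if q3 - q1 > cfg.min_iqr:
            keep.append(eid)
    out = psi.select_events(keep)
    if report is not None:
        report.record("psi_iqr", psi.event_ids, keep, f"PSI IQR <= {cfg.min_iqr}")
    return out


def filter_genes(
    expr: ExpressionProfile, cfg: FilterConfig, report: FilterReport | None = None
) -> ExpressionProfile:
    """Keep genes observed in strictly more than ``min_present_frac`` of
    samples whose coefficient of variation (sd/mean over observed values,
    sample sd) is at least ``min_cv``.  Genes with mean zero are dropped."""
    values = expr.values.to_numpy(float)
    n_samples = max(1, len(expr.samples))
    keep: list[str] = []
    present_ok: list[bool] = []
    for row, gene in enumerate(expr.genes):
        obs = values[row][~np.isnan(values[row])]
        present = obs.size / n_samples > cfg.min_present_frac
        present_ok.append(present)
        if not present:
            continue
        mean = obs.mean()
        if mean == 0:
            continue
        sd = obs.std(ddof=1) if obs.size > 1 else 0.0
        if sd / mean >= cfg.min_cv:
            keep.append(gene)
    out = expr.select_genes(keep)
    if report is not None:
        survivors_presence = [g for g, ok in zip(expr.genes, present_ok) if ok]
        report.record(
            "gene_presence",
            expr.genes,
            survivors_presence,
            f"observed fraction <= {cfg.min_present_frac:.0%}",
        )
        report.record(
            "gene_cv", survivors_presence, keep, f"expression CV < {cfg.min_cv:.0%}"
        )
    return out


def run_qc(
    expr: ExpressionProfile, psi: PsiProfile, cfg: FilterConfig
) -> tuple[ExpressionProfile, PsiProfile, FilterReport]:
    """Apply the full cascade and return filtered profiles plus the report.

    Event order: CI filter → read filter → median imputation → IQR filter.
    Gene order: presence → CV.  An empty PSI profile passes through with zero
    counts and no error.
    """
    report = FilterReport()
    out_psi = filter_events_ci(psi, cfg, report)
    out_psi = filter_events_reads(out_psi, cfg, report)
    if out_psi.n_events:
        out_psi = impute_missing_psi(out_psi, report)
    else:
        report.record("impute_missing", [], [], "")
    out_psi = filter_events_iqr(out_psi, cfg, report)
    out_expr = filter_genes(expr, cfg, report)
    return out_expr, out_psi, report
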