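"""Validation and summary layer: stratified correlations and per-TF landscapes.

``stratified_spearman`` recomputes the within-stratum TF-target Spearman
correlations for a triplet (the same quantities whose difference is gamma).
``summarize_tf`` aggregates called triplets into per-TF modulator summaries:
for each (TF, modulator event) the influenced-target fraction — called
targets over the TF's tested targets — and per-TF modulator counts above the
reporting thresholds (strictly over 10%, at least 20%, strictly over 30%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .model import StratumLabels, Triplet
from .profiles import TFTargetMap

logger = logging.getLogger(__name__)

__all__ = [
    "StratifiedCorrelation",
    "TFSummary",
    "stratified_spearman",
    "summarize_tf",
    "export_influence_matrix",
    "summaries_to_frame",
]

#: (threshold, inclusive?) bins in reporting order.
DEFAULT_THRESHOLDS: tuple[tuple[float, bool], ...] = (
    (0.10, False),  # strictly over 10%
    (0.20, True),   # at least 20%
    (0.30, False),  # strictly over 30%
)


@dataclass
class StratifiedCorrelation:
    """Spearman correlation of (TF, target) expression within each stratum."""

    rho_low: float
    p_low: float
    rho_high: float
    p_high: float
    n_low: int
    n_high: int
    degenerate: bool = False
    reason: str = ""


def stratified_spearman(
    f_expr: pd.Series, t_expr: pd.Series, strata: StratumLabels
) -> StratifiedCorrelation:
    """Within-stratum Spearman correlations with two-sided p-values.

    A constant vector within a stratum leaves that correlation undefined and
    flags the result instead of raising.
    """
    out = StratifiedCorrelation(
        rho_low=np.nan, p_low=np.nan, rho_high=np.nan, p_high=np.nan,
        n_low=strata.n_low, n_high=strata.n_high,
    )
    for name, samples in (("low", strata.low_samples), ("high", strata.high_samples)):
        f = f_expr[samples].to_numpy(float)
        t = t_expr[samples].to_numpy(float)
        if np.ptp(f) == 0 or np.ptp(t) == 0:
            out.degenerate = True
            out.reason = f"constant vector within {name} stratum"
            continue
        rho, p = stats.spearmanr(f, t)
        if name == "low":
            out.rho_low, out.p_low = float(rho), float(p)
        else:
            out.rho_high, out.p_high = float(rho), float(p)
    return out


@dataclass
class TFSummary:
    """Modulation landscape of one transcription factor.

    ``modulator_fractions`` maps each modulator event id to the fraction of
    the TF's tested targets it influences (has a called triplet for).
    ``counts`` holds event-level modulator counts per threshold bin;
    ``gene_counts`` the gene-level collapse (a gene influences when any of
    its events does), present only when an event→gene mapping was supplied.
    """

    tf: str
    n_targets: int
    modulator_fractions: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    gene_counts: dict[str, int] | None = None


def _bin_name(threshold: float, inclusive: bool) -> str:
    return f"{'ge' if inclusive else 'gt'}_{int(round(threshold * 100))}pct"


def summarize_tf(
    triplets: Iterable[Triplet],
    tf_targets: TFTargetMap,
    thresholds: tuple[tuple[float, bool], ...] = DEFAULT_THRESHOLDS,
    event_genes: Mapping[str, str] | None = None,
) -> list[TFSummary]:
    """Per-TF modulator summaries over a scored triplet batch.

    The denominator of each influenced-target fraction is the number of the
    TF's targets actually tested (appearing in the triplet batch); TFs with
    no tested targets are excluded with a warning.
    """
    triplets = list(triplets)
    tested_targets: dict[str, set[str]] = {}
    called: dict[tuple[str, str], set[str]] = {}  # (tf, event) -> called targets
    events_per_tf: dict[str, set[str]] = {}
    for t in triplets:
        tested_targets.setdefault(t.tf, set()).add(t.target)
        events_per_tf.setdefault(t.tf, set()).add(t.modulator.canonical)
        if t.called:
            called.setdefault((t.tf, t.modulator.canonical), set()).add(t.target)

    summaries: list[TFSummary] = []
    for tf in tf_targets.tfs:
        targets = tested_targets.get(tf, set())
        if not targets:
            logger.warning("TF %s has no tested targets; excluded from summary", tf)
            continue
        fractions = {
            eid: len(called.get((tf, eid), ())) / len(targets)
            for eid in sorted(events_per_tf[tf])
        }
        counts = {}
        gene_best: dict[str, float] = {}
        if event_genes is not None:
            for eid, frac in fractions.items():
                gene = event_genes.get(eid, eid)
                gene_best[gene] = max(gene_best.get(gene, 0.0), frac)
        for threshold, inclusive in thresholds:
            name = _bin_name(threshold, inclusive)
            counts[name] = sum(
                1 for f in fractions.values() if (f >= threshold if inclusive else f > threshold)
            )
        summary = TFSummary(
            tf=tf,
            n_targets=len(targets),
            modulator_fractions=fractions,
            counts=counts,
        )
        if event_genes is not None:
            summary.gene_counts = {
                _bin_name(th, inc): sum(
                    1
                    for f in gene_best.values()
                    if (f >= th if inc else f > th)
                )
                for th, inc in thresholds
            }
        summaries.append(summary)
    return summaries


def summaries_to_frame(summaries: Iterable[TFSummary]) -> pd.DataFrame:
    """Flat per-TF summary table (one row per TF)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "tf": s.tf,
            "n_targets": s.n_targets,
            "n_modulators": len(s.modulator_fractions),
        }
        row.update(s.counts)
        if s.gene_counts is not None:
            row.update({f"gene_{k}": v for k, v in s.gene_counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def export_influence_matrix(summaries: Iterable[TFSummary], path) -> pd.DataFrame:
    """Write the modulator x TF matrix of influenced-target fractions.

    Values are fixed at six decimals so the file round-trips bit-identically.
    Returns the matrix that was written.
    """
    summaries = list(summaries)
    tfs = [s.tf for s in summaries]
    modulators = sorted({eid for s in summaries for eid in s.modulator_fractions})
    mat = pd.DataFrame(0.0, index=modulators, columns=tfs)
    for s in summaries:
        for eid, frac in s.modulator_fractions.items():
            mat.at[eid, s.tf] = frac
    mat.index.name = "modulator_id"
    mat.to_csv(path, sep="\t", float_format="%.6f")
    return mat
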