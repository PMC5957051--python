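"""In-memory containers for expression, PSI and TF-target data.

All matrices are pandas DataFrames with identifier index (genes or canonical
event-id strings) and sample-name columns.  Missing measurements are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import SplicingEventID

__all__ = ["ExpressionProfile", "PsiProfile", "TFTargetMap", "align_profiles"]


@dataclass
class ExpressionProfile:
    """Genes x samples expression matrix (nonnegative reals, NaN = missing)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate gene identifiers: {dup}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def select_samples(self, samples: list[str]) -> "ExpressionProfile":
        return ExpressionProfile(self.values.loc[:, samples].copy())

    def select_genes(self, genes: list[str]) -> "ExpressionProfile":
        return ExpressionProfile(self.values.loc[genes].copy())


@dataclass
class PsiProfile:
    """Events x samples PSI matrix with credible intervals and read support.

    ``psi``, ``ci_low``, ``ci_high`` are in [0, 1] (NaN = missing);
    ``inc_reads`` / ``exc_reads`` count reads supporting inclusion/exclusion.
    All five frames share index (canonical event ids) and columns (samples);
    ``events`` carries the parsed identifiers in index order.
    """

    events: list[SplicingEventID]
    psi: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    inc_reads: pd.DataFrame
    exc_reads: pd.DataFrame

    def __post_init__(self) -> None:
        frames = [self.psi, self.ci_low, self.ci_high, self.inc_reads, self.exc_reads]
        shape = self.psi.shape
        for f in frames:
            if f.shape != shape:
                raise ValueError("PSI matrices do not share dimensions")
            if not f.index.equals(self.psi.index) or not f.columns.equals(self.psi.columns):
                raise ValueError("PSI matrices do not share index/columns")
        dup = self.psi.index[self.psi.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate event identifiers: {dup}")
        if len(self.events) != len(self.psi.index):
            raise ValueError("events list does not match matrix rows")
        for ev, idx in zip(self.events, self.psi.index):
            if ev.canonical != idx:
                raise ValueError(f"event order mismatch at {idx!r}")

    def validate_bounds(self) -> None:
        """Check 0 <= ci_low <= psi <= ci_high <= 1 wherever all are present."""
        psi, lo, hi = (f.to_numpy(float) for f in (self.psi, self.ci_low, self.ci_high))
        for name, arr in (("psi", psi), ("ci_low", lo), ("ci_high", hi)):
            obs = arr[~np.isnan(arr)]
            if obs.size and ((obs < 0).any() or (obs > 1).any()):
                raise ValueError(f"{name} values outside [0, 1]")
        full = ~(np.isnan(psi) | np.isnan(lo) | np.isnan(hi))
        if (lo[full] > psi[full] + 1e-12).any() or (psi[full] > hi[full] + 1e-12).any():
            raise ValueError("ci_low <= psi <= ci_high violated")

    @property
    def event_ids(self) -> list[str]:
        return list(self.psi.index)

    @property
    def samples(self) -> list[str]:
        return list(self.psi.columns)

    @property
    def n_events(self) -> int:
        return self.psi.shape[0]

    def select_samples(self, samples: list[str]) -> "PsiProfile":
        return PsiProfile(
            events=list(self.events),
            psi=self.psi.loc[:, samples].copy(),
            ci_low=self.ci_low.loc[:, samples].copy(),
            ci_high=self.ci_high.loc[:, samples].copy(),
            inc_reads=self.inc_reads.loc[:, samples].copy(),
            exc_reads=self.exc_reads.loc[:, samples].copy(),
        )

    def select_events(self, event_ids: list[str]) -> "PsiProfile":
        keep = set(event_ids)
        events = [ev for ev in self.events if ev.canonical in keep]
        ids = [ev.canonical for ev in events]
        return PsiProfile(
            events=events,
            psi=self.psi.loc[ids].copy(),
            ci_low=self.ci_low.loc[ids].copy(),
            ci_high=self.ci_high.loc[ids].copy(),
            inc_reads=self.inc_reads.loc[ids].copy(),
            exc_reads=self.exc_reads.loc[ids].copy(),
        )


@dataclass(frozen=True)
class TFTargetMap:
    """Set of directed (tf, target) regulatory relations."""

    pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @property
    def tfs(self) -> list[str]:
        return sorted({tf for tf, _ in self.pairs})

    def targets_of(self, tf: str) -> list[str]:
        return sorted({t for f, t in self.pairs if f == tf})

    def __len__(self) -> int:
        return len(self.pairs)


def align_profiles(
    expr: ExpressionProfile, psi: PsiProfile
) -> tuple[ExpressionProfile, PsiProfile]:
    """Restrict both profiles to their shared samples.

    Sample order follows the expression profile.  Raises ``ValueError`` when
    the intersection is empty.
    """
    psi_samples = set(psi.samples)
    shared = [s for s in expr.samples if s in psi_samples]
    if not shared:
        raise ValueError("no samples shared between expression and PSI profiles")
    return expr.select_samples(shared), psi.select_samples(shared)
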