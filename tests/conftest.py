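import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from splicemod.events import SplicingEventID
from splicemod.profiles import ExpressionProfile, PsiProfile

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_event(i: int, chrom: str = "chr1", strand: str = "+") -> SplicingEventID:
    s = 1000 * (i + 1)
    return SplicingEventID(
        chrom=chrom,
        blocks=((s, s + 100), (s + 200, s + 300), (s + 400, s + 500)),
        strand=strand,
    )


def make_psi_profile(
    psi: np.ndarray,
    ci_width: float | np.ndarray = 0.1,
    inc: np.ndarray | None = None,
    exc: np.ndarray | None = None,
    samples: list[str] | None = None,
) -> PsiProfile:
    """Build a PsiProfile from a raw PSI matrix with synthetic CI bounds."""
    psi = np.asarray(psi, dtype=float)
    n_events, n_samples = psi.shape
    events = [make_event(i) for i in range(n_events)]
    ids = [e.canonical for e in events]
    samples = samples or [f"s{j + 1}" for j in range(n_samples)]
    width = np.broadcast_to(np.asarray(ci_width, dtype=float), psi.shape)
    lo = np.clip(psi - width / 2, 0, 1)
    hi = np.clip(lo + width, 0, 1)
    lo = hi - width  # keep the requested width even at the upper boundary
    lo = np.clip(lo, 0, 1)
    lo[np.isnan(psi)] = np.nan
    hi[np.isnan(psi)] = np.nan
    if inc is None:
        inc = np.full(psi.shape, 50.0)
    if exc is None:
        exc = np.full(psi.shape, 50.0)
    frame = lambda a: pd.DataFrame(np.asarray(a, dtype=float), index=ids, columns=samples)
    return PsiProfile(
        events=events,
        psi=frame(psi),
        ci_low=frame(lo),
        ci_high=frame(hi),
        inc_reads=frame(inc),
        exc_reads=frame(exc),
    )


def make_expression(values: np.ndarray, genes=None, samples=None) -> ExpressionProfile:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionProfile(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
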