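"""Readers and writers for the pipeline's tab-separated formats.

Formats
-------
Expression
    TSV, first column the gene symbol (header ``gene``), remaining columns
    samples.
PSI (long dialect)
    TSV with exactly the columns ``event_id, sample, psi, ci_low, ci_high,
    inc_reads, exc_reads`` — one row per (event, sample).
PSI (MISO-summary dialect)
    One TSV per sample with header ``event_name, miso_posterior_mean, ci_low,
    ci_high, counts``; ``counts`` uses the ``(1,0):n,(0,1):m,...`` read-class
    notation, where class ``(1,0)`` supports inclusion and ``(0,1)`` exclusion.
TF-target map
    Two-column TSV ``tf<TAB>target``, no header.
Triplets
    TSV with fixed header ``modulator_id, tf, target, alpha0, alpha_f, beta_f,
    beta_m, gamma, p_gamma, q_gamma, n_low, n_high, category``.

Missing values are written as ``NA`` and read from ``NA`` or empty fields.
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import SplicingEventID, parse_event_id
from .profiles import ExpressionProfile, PsiProfile, TFTargetMap

if TYPE_CHECKING:  # pragma: no cover
    from .model import Triplet

__all__ = [
    "read_expression",
    "write_expression",
    "read_psi",
    "read_psi_long",
    "read_psi_miso",
    "write_psi",
    "read_tf_targets",
    "write_tf_targets",
    "TRIPLET_COLUMNS",
    "write_triplets",
    "read_triplets",
    "write_stratified_correlations",
    "write_cassette_bed",
]

_NA = "NA"


def _fmt_float(v) -> str:
    """Shortest round-trip decimal representation (repr of the float)."""
    return _NA if pd.isna(v) else repr(float(v))


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    # round_trip parsing: the default C float parser can be off by one ulp
    return pd.read_csv(
        path, sep="\t", na_values=[_NA], float_precision="round_trip", **kwargs
    )

PSI_LONG_COLUMNS = ["event_id", "sample", "psi", "ci_low", "ci_high", "inc_reads", "exc_reads"]
MISO_COLUMNS = ["event_name", "miso_posterior_mean", "ci_low", "ci_high", "counts"]
TRIPLET_COLUMNS = [
    "modulator_id",
    "tf",
    "target",
    "alpha0",
    "alpha_f",
    "beta_f",
    "beta_m",
    "gamma",
    "p_gamma",
    "q_gamma",
    "n_low",
    "n_high",
    "category",
]


# ---------------------------------------------------------------- expression

def read_expression(path: str | os.PathLike) -> ExpressionProfile:
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene rows in {path}: {dup}")
    return ExpressionProfile(df.astype(float))


def write_expression(path: str | os.PathLike, expr: ExpressionProfile) -> None:
    df = expr.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep=_NA, float_format=_fmt_float)


# ----------------------------------------------------------------------- PSI

def _pivot(long: pd.DataFrame, value: str, ids: list[str], samples: list[str]) -> pd.DataFrame:
    wide = long.pivot(index="event_id", columns="sample", values=value)
    return wide.reindex(index=ids, columns=samples)


def read_psi_long(path: str | os.PathLike) -> PsiProfile:
    long = _read_tsv(path, dtype={"event_id": str, "sample": str})
    if list(long.columns) != PSI_LONG_COLUMNS:
        raise ValueError(
            f"unknown PSI dialect in {path}: expected columns {PSI_LONG_COLUMNS}, "
            f"got {list(long.columns)}"
        )
    dup = long.duplicated(subset=["event_id", "sample"])
    if dup.any():
        dups = long.loc[dup, "event_id"].unique().tolist()
        raise ValueError(f"duplicate (event, sample) rows in {path}: {dups}")
    # preserve first-appearance order of events and samples
    ids_raw = list(dict.fromkeys(long["event_id"]))
    events = [parse_event_id(e) for e in ids_raw]
    canon = {raw: ev.canonical for raw, ev in zip(ids_raw, events)}
    long = long.assign(event_id=long["event_id"].map(canon))
    ids = [canon[r] for r in ids_raw]
    samples = list(dict.fromkeys(long["sample"]))
    return PsiProfile(
        events=events,
        psi=_pivot(long, "psi", ids, samples).astype(float),
        ci_low=_pivot(long, "ci_low", ids, samples).astype(float),
        ci_high=_pivot(long, "ci_high", ids, samples).astype(float),
        inc_reads=_pivot(long, "inc_reads", ids, samples).astype(float),
        exc_reads=_pivot(long, "exc_reads", ids, samples).astype(float),
    )


_COUNT_CLASS_RE = re.compile(r"\((?P<inc>\d+),(?P<exc>\d+)\):(?P<n>\d+)")


def _parse_miso_counts(text: str) -> tuple[float, float]:
    """Inclusion/exclusion read support from a MISO counts field.

    Class ``(1,0)`` supports inclusion, ``(0,1)`` exclusion; other classes
    (ambiguous or uninformative reads) are ignored.
    """
    if not isinstance(text, str) or not text.strip():
        return np.nan, np.nan
    inc = exc = 0
    matched = False
    for m in _COUNT_CLASS_RE.finditer(text.replace(" ", "")):
        matched = True
        cls = (m.group("inc"), m.group("exc"))
        if cls == ("1", "0"):
            inc += int(m.group("n"))
        elif cls == ("0", "1"):
            exc += int(m.group("n"))
    if not matched:
        raise ValueError(f"malformed MISO counts field: {text!r}")
    return float(inc), float(exc)


def read_psi_miso(
    paths: Mapping[str, str | os.PathLike] | Sequence[str | os.PathLike],
) -> PsiProfile:
    """Assemble a :class:`PsiProfile` from per-sample MISO summary files.

    ``paths`` maps sample name to file path; a plain sequence uses each file's
    stem as the sample name.  Events are the union across samples (entries
    missing for a sample are NaN), ordered by first appearance.
    """
    if not isinstance(paths, Mapping):
        paths = {Path(p).stem: p for p in paths}
    if not paths:
        raise ValueError("no MISO summary files given")
    per_sample: dict[str, pd.DataFrame] = {}
    events: dict[str, SplicingEventID] = {}
    for sample, path in paths.items():
        df = _read_tsv(path, dtype={"event_name": str})
        if list(df.columns) != MISO_COLUMNS:
            raise ValueError(
                f"unknown PSI dialect in {path}: expected columns {MISO_COLUMNS}, "
                f"got {list(df.columns)}"
            )
        parsed = [parse_event_id(e) for e in df["event_name"]]
        ids = [ev.canonical for ev in parsed]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate event rows in {path}: {dups}")
        for ev, i in zip(parsed, ids):
            events.setdefault(i, ev)
        counts = [_parse_miso_counts(c) for c in df["counts"]]
        per_sample[sample] = pd.DataFrame(
            {
                "psi": df["miso_posterior_mean"].to_numpy(float),
                "ci_low": df["ci_low"].to_numpy(float),
                "ci_high": df["ci_high"].to_numpy(float),
                "inc_reads": [c[0] for c in counts],
                "exc_reads": [c[1] for c in counts],
            },
            index=ids,
        )
    ids = list(events)
    samples = list(per_sample)
    mats = {
        name: pd.DataFrame(
            {s: per_sample[s][name].reindex(ids) for s in samples}, index=ids
        )
        for name in ("psi", "ci_low", "ci_high", "inc_reads", "exc_reads")
    }
    return PsiProfile(events=[events[i] for i in ids], **mats)


def read_psi(path: str | os.PathLike) -> PsiProfile:
    """Read a PSI file, auto-detecting the dialect from its header."""
    header = pd.read_csv(path, sep="\t", nrows=0).columns.tolist()
    if header == PSI_LONG_COLUMNS:
        return read_psi_long(path)
    if header == MISO_COLUMNS:
        return read_psi_miso([path])
    raise ValueError(f"unknown PSI dialect in {path}: header {header}")


def write_psi(path: str | os.PathLike, psi: PsiProfile) -> None:
    """Write a :class:`PsiProfile` in the long dialect."""
    rows = []
    for eid in psi.event_ids:
        for s in psi.samples:
            rows.append(
                (
                    eid,
                    s,
                    psi.psi.at[eid, s],
                    psi.ci_low.at[eid, s],
                    psi.ci_high.at[eid, s],
                    psi.inc_reads.at[eid, s],
                    psi.exc_reads.at[eid, s],
                )
            )
    pd.DataFrame(rows, columns=PSI_LONG_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep=_NA, float_format=_fmt_float
    )


# ----------------------------------------------------------------- TF-target

def read_tf_targets(path: str | os.PathLike) -> TFTargetMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["tf", "target"], dtype=str)
    pairs = list(zip(df["tf"], df["target"]))
    return TFTargetMap(pairs=frozenset(pairs))


def write_tf_targets(path: str | os.PathLike, tf_map: TFTargetMap) -> None:
    with open(path, "w") as fh:
        for tf, target in sorted(tf_map.pairs):
            fh.write(f"{tf}\t{target}\n")


# ------------------------------------------------------------------ triplets

def triplets_to_frame(triplets: Iterable["Triplet"]) -> pd.DataFrame:
    rows = []
    for t in triplets:
        f = t.fit
        rows.append(
            (
                t.modulator.canonical,
                t.tf,
                t.target,
                f.alpha0,
                f.alpha_f,
                f.beta_f,
                f.beta_m,
                f.gamma,
                f.p_gamma,
                f.q_gamma,
                f.n_low,
                f.n_high,
                t.category,
            )
        )
    return pd.DataFrame(rows, columns=TRIPLET_COLUMNS)


def write_triplets(path: str | os.PathLike, triplets: Iterable["Triplet"]) -> None:
    triplets_to_frame(triplets).to_csv(
        path, sep="\t", index=False, na_rep=_NA, float_format=_fmt_float
    )


def read_triplets(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"category": str})
    if list(df.columns) != TRIPLET_COLUMNS:
        raise ValueError(f"unexpected triplet table header in {path}: {list(df.columns)}")
    df["category"] = df["category"].fillna("")
    return df


STRATIFIED_CORR_COLUMNS = [
    "modulator_id",
    "tf",
    "target",
    "rho_low",
    "p_low",
    "rho_high",
    "p_high",
    "n_low",
    "n_high",
]


def write_stratified_correlations(path: str | os.PathLike, triplets: Iterable["Triplet"]) -> None:
    """Per-triplet within-stratum Spearman correlations (from the fits)."""
    rows = []
    for t in triplets:
        f = t.fit
        rows.append(
            (
                t.modulator.canonical,
                t.tf,
                t.target,
                f.rho_low,
                f.p_alpha_f,
                f.rho_high,
                f.p_mod_effect,
                f.n_low,
                f.n_high,
            )
        )
    pd.DataFrame(rows, columns=STRATIFIED_CORR_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep=_NA, float_format=_fmt_float
    )


# ----------------------------------------------------------------------- BED

def write_cassette_bed(path: str | os.PathLike, events: Iterable[SplicingEventID]) -> None:
    """Export cassette exons as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(ev.to_bed6() + "\n")
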