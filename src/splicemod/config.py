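"""Run configuration: a single TOML file drives every pipeline stage.

Layout: top-level ``seed`` (and optional ``out``), plus one table per stage::

    seed = 7

    [qc]
    max_ci_width = 0.25
    min_reads = 10

    [model]
    fdr = 0.05
    strat_frac = 0.3333333333333333
    n_perm = 999

    [simulate]
    n_samples = 300
    n_events = 10
    n_planted = 6          # cycles through the six categories, or:

    [[simulate.planted]]
    category = "inverts_inhibition"
    event = 0
    tf = "TF1"
    target = "TG003"

Unknown keys are rejected; CLI flags override file values.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, fields

from .model import MODULATION_CATEGORIES, ModelConfig
from .qc import FilterConfig
from .simulate import PlantedTriplet, SimConfig, default_effects

__all__ = ["ConfigError", "RunConfig", "load_run_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    seed: int
    qc: FilterConfig
    model: ModelConfig
    sim: SimConfig | None = None
    out: str | None = None


def _build(cls, table: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(table) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    try:
        return cls(**table)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{section}] configuration: {exc}") from exc


def _build_planted(entries: list[dict], n_planted: int | None, sim: SimConfig) -> tuple:
    planted = []
    if entries:
        for i, entry in enumerate(entries):
            entry = dict(entry)
            unknown = set(entry) - {
                "category", "event", "tf", "target",
                "alpha_f", "beta_f", "beta_m", "noise_sd",
            }
            if unknown:
                raise ConfigError(
                    f"unknown key(s) in [[simulate.planted]] #{i + 1}: {sorted(unknown)}"
                )
            try:
                category = entry["category"]
                defaults = default_effects(category)
                planted.append(
                    PlantedTriplet(
                        category=category,
                        event_index=int(entry["event"]),
                        tf=str(entry["tf"]),
                        target=str(entry["target"]),
                        alpha_f=float(entry.get("alpha_f", defaults[0])),
                        beta_f=float(entry.get("beta_f", defaults[1])),
                        beta_m=float(entry.get("beta_m", defaults[2])),
                        noise_sd=float(entry.get("noise_sd", 0.05)),
                    )
                )
            except KeyError as exc:
                raise ConfigError(
                    f"[[simulate.planted]] #{i + 1} is missing key {exc}"
                ) from exc
            except ValueError as exc:
                raise ConfigError(f"invalid [[simulate.planted]] #{i + 1}: {exc}") from exc
    elif n_planted:
        targets = sim.all_targets()
        if n_planted > len(targets):
            raise ConfigError(
                f"n_planted = {n_planted} exceeds the {len(targets)} configured targets"
            )
        for k in range(n_planted):
            target = targets[k]
            tf = sim.tf_name(k // sim.n_targets_per_tf)
            planted.append(
                PlantedTriplet.with_default_effects(
                    category=MODULATION_CATEGORIES[k % len(MODULATION_CATEGORIES)],
                    event_index=k % sim.n_events,
                    tf=tf,
                    target=target,
                )
            )
    return tuple(planted)


def load_run_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc

    unknown = set(data) - {"seed", "out", "qc", "model", "simulate"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if "seed" not in data:
        raise ConfigError("a top-level 'seed' is required")
    seed = data["seed"]
    if not isinstance(seed, int) or isinstance(seed, bool) or seed < 0:
        raise ConfigError(f"seed must be a nonnegative integer, got {seed!r}")

    qc = _build(FilterConfig, dict(data.get("qc", {})), "qc")

    model_table = dict(data.get("model", {}))
    model_table.setdefault("seed", seed)
    model = _build(ModelConfig, model_table, "model")

    sim = None
    if "simulate" in data:
        sim_table = dict(data["simulate"])
        planted_entries = sim_table.pop("planted", [])
        n_planted = sim_table.pop("n_planted", None)
        if n_planted is not None and (not isinstance(n_planted, int) or n_planted < 0):
            raise ConfigError(f"n_planted must be a nonnegative integer, got {n_planted!r}")
        sim_table.setdefault("seed", seed)
        sim = _build(SimConfig, sim_table, "simulate")
        planted = _build_planted(planted_entries, n_planted, sim)
        if planted:
            sim = _build(
                SimConfig,
                {**sim_table, "planted": planted},
                "simulate",
            )

    return RunConfig(seed=seed, qc=qc, model=model, sim=sim, out=data.get("out"))
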