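"""Modulation inference: stratified fits, permutation testing, classification.

For each candidate triplet (modulator splicing event M, transcription factor
F, target T) samples are split into low- and high-inclusion strata by M's PSI.
The modulation statistic is

    gamma = rho_high - rho_low,

the change in Spearman correlation of (F, T) expression between the strata.
Alongside, an ordinary least-squares fit of

    T ~ alpha0 + alpha_f * F + beta_f * m + beta_m * (F * m)

over the included samples (m the 0/1 stratum indicator; F, T standardized
log-scale expression) supplies the coefficients the six-category sign table
constrains.  ``alpha_f`` is the TF's unmodulated activity (its association
with the target at low modulator inclusion) and ``alpha_f + beta_m`` the
modulated activity.  gamma's significance comes from a stratum-label
permutation test; Benjamini-Hochberg adjustment across the candidate batch
calls triplets at a 5% false discovery rate by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .events import SplicingEventID
from .profiles import ExpressionProfile, PsiProfile, TFTargetMap

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "StratumLabels",
    "StratificationError",
    "ModulationFit",
    "Triplet",
    "MODULATION_CATEGORIES",
    "CATEGORY_CONSTRAINTS",
    "stratify_by_psi",
    "fit_triplet",
    "permutation_p_gamma",
    "bh_fdr",
    "sign_pattern",
    "classify_pattern",
    "classify",
    "unmodulated_activity",
    "infer_triplets",
]


# --------------------------------------------------------------- categories

#: The six modulation categories, in the canonical table order.
MODULATION_CATEGORIES: tuple[str, ...] = (
    "attenuates_inhibition",
    "enhances_inhibition",
    "inverts_inhibition",
    "inverts_activation",
    "enhances_activation",
    "attenuates_activation",
)

#: Sign constraints per category over (gamma, alpha_f, beta_f, beta_m,
#: mod_effect = alpha_f + beta_m).  Absent keys are unconstrained (the
#: table's blank cells).
CATEGORY_CONSTRAINTS: dict[str, dict[str, str]] = {
    "attenuates_inhibition": {"gamma": "+", "alpha_f": "-"},
    "enhances_inhibition": {"gamma": "-", "beta_f": "-", "beta_m": "-", "mod_effect": "-"},
    "inverts_inhibition": {
        "gamma": "+",
        "alpha_f": "-",
        "beta_f": "+",
        "beta_m": "+",
        "mod_effect": "+",
    },
    "inverts_activation": {
        "gamma": "-",
        "alpha_f": "+",
        "beta_f": "-",
        "beta_m": "-",
        "mod_effect": "-",
    },
    "enhances_activation": {"gamma": "+", "beta_f": "+", "beta_m": "+", "mod_effect": "+"},
    "attenuates_activation": {"gamma": "-", "alpha_f": "+"},
}

UNCLASSIFIED = "unclassified"

# tie-break when several categories match with equally many constraints
_MODE_PRIORITY = {"inverts": 3, "enhances": 2, "attenuates": 1}


# ------------------------------------------------------------------- config

@dataclass
class ModelConfig:
    """Tunable settings of the inference stage.

    ``strat_frac`` is the fraction of ranked samples in each stratum (1/3 for
    tertiles; 0.30 for top/bottom-30% splits).  ``n_perm`` is the number of
    label permutations behind gamma's p-value, ``alpha_sign`` the nominal
    level at which a coefficient counts as significantly signed, and ``fdr``
    the Benjamini-Hochberg threshold for calling triplets.  With
    ``strict_all_columns`` every non-blank column of the category table,
    including beta_f, must hold; switching it off relaxes the beta_f
    constraint.  ``seed`` is required for any stochastic step.
    """

    fdr: float = 0.05
    strat_frac: float = 1.0 / 3.0
    n_perm: int = 999
    alpha_sign: float = 0.05
    min_stratum_n: int = 8
    strict_all_columns: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fdr <= 1:
            raise ValueError(f"fdr must be in (0, 1], got {self.fdr}")
        if not 0 < self.strat_frac <= 0.5:
            raise ValueError(f"strat_frac must be in (0, 0.5], got {self.strat_frac}")
        if not 0 < self.alpha_sign <= 1:
            raise ValueError(f"alpha_sign must be in (0, 1], got {self.alpha_sign}")
        if self.min_stratum_n < 2:
            raise ValueError("min_stratum_n must be >= 2")
        if self.n_perm < 100:
            raise ValueError(f"n_perm must be >= 100, got {self.n_perm}")


# ------------------------------------------------------------ stratification

class StratificationError(ValueError):
    """Too few usable samples to form the requested strata."""

    def __init__(self, required: int, available: int):
        self.required = required
        self.available = available
        super().__init__(
            f"need at least {required} non-missing samples to stratify, "
            f"have {available}"
        )


@dataclass
class StratumLabels:
    """Per-sample assignment to the low/high modulator-inclusion strata."""

    labels: pd.Series  # values in {"low", "high", "excluded"}
    frac: float

    @property
    def low_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "low"])

    @property
    def high_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "high"])

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    def swapped(self) -> "StratumLabels":
        """Labels with low and high exchanged (gamma antisymmetry checks)."""
        swap = {"low": "high", "high": "low", "excluded": "excluded"}
        return StratumLabels(self.labels.map(swap), self.frac)


def stratify_by_psi(
    psi_values: pd.Series, frac: float = 1.0 / 3.0, min_stratum_n: int = 8
) -> StratumLabels:
    """Assign the bottom/top ``floor(frac * n)`` ranked samples to the low and
    high strata; the remainder (and samples with missing PSI) are excluded.

    Ranking ties are broken by stable input sample order.
    """
    if not 0 < frac <= 0.5:
        raise ValueError(f"frac must be in (0, 0.5], got {frac}")
    values = psi_values.to_numpy(float)
    observed = np.flatnonzero(~np.isnan(values))
    n = observed.size
    k = int(np.floor(frac * n))
    if k < min_stratum_n:
        raise StratificationError(required=int(np.ceil(min_stratum_n / frac)), available=n)
    order = observed[np.argsort(values[observed], kind="stable")]
    labels = pd.Series("excluded", index=psi_values.index, dtype=object)
    labels.iloc[order[:k]] = "low"
    labels.iloc[order[-k:]] = "high"
    return StratumLabels(labels=labels, frac=frac)


# --------------------------------------------------------------------- fits

@dataclass
class ModulationFit:
    """Coefficients and test results for one candidate triplet."""

    alpha0: float = np.nan
    alpha_f: float = np.nan
    beta_f: float = np.nan
    beta_m: float = np.nan
    gamma: float = np.nan
    rho_low: float = np.nan
    rho_high: float = np.nan
    p_alpha_f: float = np.nan
    p_mod_effect: float = np.nan
    p_beta_f: float = np.nan
    p_beta_m: float = np.nan
    p_gamma: float = np.nan
    q_gamma: float = np.nan
    n_low: int = 0
    n_high: int = 0
    degenerate: bool = False
    reason: str = ""

    @property
    def mod_effect(self) -> float:
        """Modulated TF activity: alpha_f + beta_m."""
        return self.alpha_f + self.beta_m


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd


def fit_triplet(
    f_expr: pd.Series, t_expr: pd.Series, strata: StratumLabels
) -> ModulationFit:
    """Fit one triplet on log-scale expression.

    Returns within-stratum Spearman correlations (and their two-sided
    p-values, reused as the sign tests of ``alpha_f`` and the modulated
    effect), ``gamma = rho_high - rho_low``, and the OLS coefficients of
    ``T ~ 1 + F + m + F*m`` with F and T z-scored over the included samples.
    A stratum in which F or T is constant yields a fit flagged ``degenerate``.
    """
    low, high = strata.low_samples, strata.high_samples
    fit = ModulationFit(n_low=len(low), n_high=len(high))
    f_low, t_low = f_expr[low].to_numpy(float), t_expr[low].to_numpy(float)
    f_high, t_high = f_expr[high].to_numpy(float), t_expr[high].to_numpy(float)
    if np.isnan(f_low).any() or np.isnan(t_low).any() or np.isnan(f_high).any() or np.isnan(t_high).any():
        fit.degenerate, fit.reason = True, "missing expression within a stratum"
        return fit
    for name, arr in (("F/low", f_low), ("T/low", t_low), ("F/high", f_high), ("T/high", t_high)):
        if np.ptp(arr) == 0:
            fit.degenerate, fit.reason = True, f"constant {name} within stratum"
            return fit
    rho_low, p_low = stats.spearmanr(f_low, t_low)
    rho_high, p_high = stats.spearmanr(f_high, t_high)
    fit.rho_low, fit.rho_high = float(rho_low), float(rho_high)
    fit.gamma = fit.rho_high - fit.rho_low
    fit.p_alpha_f = float(p_low)
    fit.p_mod_effect = float(p_high)

    f_inc = _zscore(np.concatenate([f_low, f_high]))
    t_inc = _zscore(np.concatenate([t_low, t_high]))
    m = np.concatenate([np.zeros(len(low)), np.ones(len(high))])
    X = np.column_stack([np.ones_like(m), f_inc, m, f_inc * m])
    res = sm.OLS(t_inc, X).fit()
    fit.alpha0, fit.alpha_f, fit.beta_f, fit.beta_m = (float(c) for c in res.params)
    fit.p_beta_f = float(res.pvalues[2])
    fit.p_beta_m = float(res.pvalues[3])
    return fit


# -------------------------------------------------------- permutation gamma

def _rank_rows(a: np.ndarray) -> np.ndarray:
    """Ordinal ranks along axis 1 (stable; ties broken by position).

    Exact Spearman ranks for tie-free rows, which is the case for continuous
    expression values.
    """
    order = np.argsort(a, axis=1, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(a.shape[1], dtype=float), a.shape), axis=1
    )
    return ranks


def _row_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equal-shape matrices."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _perm_stratum_indices(
    is_high: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Column indices of the low/high strata under ``n_perm`` label shuffles.

    Returns ``(low_idx, high_idx)`` of shapes (n_perm, n_low) and
    (n_perm, n_high): row b lists which included-sample positions land in
    each stratum under the b-th permutation.
    """
    n_low = int((~is_high).sum())
    perms = rng.permuted(np.tile(is_high, (n_perm, 1)), axis=1)
    order = np.argsort(perms, axis=1, kind="stable")  # False (low) sorts first
    return order[:, :n_low], order[:, n_low:]


def _perm_gammas(
    f_inc: np.ndarray,
    t_inc: np.ndarray,
    low_idx: np.ndarray,
    high_idx: np.ndarray,
) -> np.ndarray:
    """gamma* = rho_high* - rho_low* for every permuted label assignment."""
    rho_low = _row_corr(_rank_rows(f_inc[low_idx]), _rank_rows(t_inc[low_idx]))
    rho_high = _row_corr(_rank_rows(f_inc[high_idx]), _rank_rows(t_inc[high_idx]))
    return rho_high - rho_low


def _included_order(strata: StratumLabels) -> tuple[list[str], np.ndarray]:
    """Included samples in sorted-name order plus their high-stratum mask.

    Sorting by sample name makes the permutation stream, and hence p-values,
    independent of the column order of the input matrices.
    """
    included = sorted(strata.low_samples + strata.high_samples)
    is_high = np.array([strata.labels[s] == "high" for s in included])
    return included, is_high


def permutation_p_gamma(
    f_expr: pd.Series,
    t_expr: pd.Series,
    strata: StratumLabels,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value of gamma.

    Stratum labels are shuffled among the included samples ``n_perm`` times;
    ``p = (1 + #{b : |gamma*_b| >= |gamma_obs|}) / (n_perm + 1)``.
    Deterministic given ``seed`` (or an explicit ``rng``).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if rng is None:
        rng = np.random.default_rng(seed)
    fit = fit_triplet(f_expr, t_expr, strata)
    if fit.degenerate:
        raise ValueError(f"degenerate strata: {fit.reason}")
    included, is_high = _included_order(strata)
    f_inc = f_expr[included].to_numpy(float)
    t_inc = t_expr[included].to_numpy(float)
    low_idx, high_idx = _perm_stratum_indices(is_high, n_perm, rng)
    gammas = _perm_gammas(f_inc, t_inc, low_idx, high_idx)
    return _perm_pvalue(fit.gamma, gammas)


def _perm_pvalue(gamma_obs: float, perm_gammas: np.ndarray) -> float:
    # tiny tolerance so float noise between the observed (scipy) and the
    # vectorised permutation path cannot flip a >= comparison
    n_extreme = int((np.abs(perm_gammas) >= abs(gamma_obs) - 1e-12).sum())
    return (1 + n_extreme) / (perm_gammas.size + 1)


# ---------------------------------------------------------------------- FDR

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------ classification

_QUANTITIES = ("gamma", "alpha_f", "beta_f", "beta_m", "mod_effect")


def sign_pattern(fit: ModulationFit, alpha: float = 0.05) -> dict[str, str]:
    """Significant sign of each classified quantity: '+', '-' or '0'.

    A quantity is significantly signed when its sign p-value is at most
    ``alpha`` and the estimate is nonzero; gamma uses the permutation
    p-value, alpha_f and the modulated effect the within-stratum Spearman
    tests, beta_f and beta_m the regression coefficient tests.
    """
    values = {
        "gamma": (fit.gamma, fit.p_gamma),
        "alpha_f": (fit.alpha_f, fit.p_alpha_f),
        "beta_f": (fit.beta_f, fit.p_beta_f),
        "beta_m": (fit.beta_m, fit.p_beta_m),
        "mod_effect": (fit.mod_effect, fit.p_mod_effect),
    }
    pattern = {}
    for name, (value, p) in values.items():
        if np.isnan(value) or np.isnan(p) or p > alpha or value == 0:
            pattern[name] = "0"
        else:
            pattern[name] = "+" if value > 0 else "-"
    return pattern


def classify_pattern(pattern: dict[str, str], strict_all_columns: bool = True) -> str:
    """Map a sign pattern to a modulation category.

    A category matches when every one of its non-blank sign constraints
    holds.  Among multiple matches the one satisfying the most constraints
    wins; remaining ties resolve by specificity (inversion > enhancement >
    attenuation).  With ``strict_all_columns`` off, the beta_f column is
    treated as unconstrained.
    """
    best: tuple[int, int, str] | None = None
    for name in MODULATION_CATEGORIES:
        constraints = CATEGORY_CONSTRAINTS[name]
        if not strict_all_columns:
            constraints = {k: v for k, v in constraints.items() if k != "beta_f"}
        if all(pattern.get(k, "0") == v for k, v in constraints.items()):
            mode = name.split("_")[0]
            key = (len(constraints), _MODE_PRIORITY[mode], name)
            if best is None or key[:2] > best[:2]:
                best = key
    return best[2] if best else UNCLASSIFIED


def classify(
    fit: ModulationFit, alpha: float = 0.05, strict_all_columns: bool = True
) -> str:
    """Assign the category of one fitted triplet at sign level ``alpha``."""
    if fit.degenerate:
        return UNCLASSIFIED
    return classify_pattern(sign_pattern(fit, alpha), strict_all_columns)


def unmodulated_activity(fit: ModulationFit, alpha: float = 0.05) -> str:
    """The TF's activity on the target absent modulation: ``activation`` when
    alpha_f is significantly positive, ``inhibition`` when significantly
    negative, ``inactive`` otherwise."""
    s = sign_pattern(fit, alpha)["alpha_f"]
    return {"+": "activation", "-": "inhibition", "0": "inactive"}[s]


# ------------------------------------------------------------------ triplets

@dataclass
class Triplet:
    """One scored (modulator event, TF, target) hypothesis."""

    modulator: SplicingEventID
    tf: str
    target: str
    fit: ModulationFit
    category: str = ""
    called: bool = False


def infer_triplets(
    expr: ExpressionProfile,
    psi: PsiProfile,
    tf_targets: TFTargetMap,
    cfg: ModelConfig,
) -> list[Triplet]:
    """Score every (event, TF, target) candidate and call at the FDR threshold.

    Expression is log2(x+1)-transformed; per triplet the included samples are
    those in the modulator's low/high PSI strata.  Permutation p-values for
    gamma are computed for the whole batch, BH-adjusted globally, and called
    triplets (q <= fdr) are classified.  TFs or targets absent from the
    expression matrix, events with too few samples, and degenerate fits are
    skipped with a log entry.  Output is sorted by (tf, q_gamma).
    """
    if cfg.seed is None:
        raise ValueError("ModelConfig.seed is required for permutation testing")
    genes = set(expr.genes)
    pairs = []
    for tf, target in sorted(tf_targets.pairs):
        if tf not in genes or target not in genes or tf == target:
            logger.info("skipping pair (%s, %s): not measured", tf, target)
            continue
        pairs.append((tf, target))
    log_expr = np.log2(expr.values + 1.0)

    triplets: list[Triplet] = []
    seed_seq = np.random.SeedSequence(cfg.seed)
    children = seed_seq.spawn(psi.n_events)
    for event, child in zip(psi.events, children):
        eid = event.canonical
        try:
            strata = stratify_by_psi(psi.psi.loc[eid], cfg.strat_frac, cfg.min_stratum_n)
        except StratificationError as exc:
            logger.warning("skipping event %s: %s", eid, exc)
            continue
        included, is_high = _included_order(strata)
        rng = np.random.default_rng(child)
        low_idx, high_idx = _perm_stratum_indices(is_high, cfg.n_perm, rng)
        # cache permuted-and-ranked expression rows per gene within this event
        rank_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

        def ranked(gene: str) -> tuple[np.ndarray, np.ndarray]:
            if gene not in rank_cache:
                v = log_expr.loc[gene, included].to_numpy(float)
                rank_cache[gene] = (_rank_rows(v[low_idx]), _rank_rows(v[high_idx]))
            return rank_cache[gene]

        for tf, target in pairs:
            fit = fit_triplet(log_expr.loc[tf], log_expr.loc[target], strata)
            if fit.degenerate:
                logger.info("skipping (%s, %s, %s): %s", eid, tf, target, fit.reason)
                continue
            f_low, f_high = ranked(tf)
            t_low, t_high = ranked(target)
            gammas = _row_corr(f_high, t_high) - _row_corr(f_low, t_low)
            fit.p_gamma = _perm_pvalue(fit.gamma, gammas)
            triplets.append(Triplet(modulator=event, tf=tf, target=target, fit=fit))

    if not triplets:
        logger.warning("no valid candidate triplets")
        return []
    qvals = bh_fdr([t.fit.p_gamma for t in triplets])
    for t, q in zip(triplets, qvals):
        t.fit.q_gamma = float(q)
        t.called = bool(q <= cfg.fdr)
        if t.called:
            t.category = classify(t.fit, cfg.alpha_sign, cfg.strict_all_columns)
    triplets.sort(
        key=lambda t: (t.tf, t.fit.q_gamma, t.fit.p_gamma, t.target, t.modulator.canonical)
    )
    return triplets
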