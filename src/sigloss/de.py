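"""Integrated three-statistic permutation test for differential expression.

The discovery step compares anchor-low against anchor-high samples with
three statistics per gene — Welch *t*, a tie-corrected rank-sum *z*, and the
log2-median-ratio (LMR) — estimates their null distributions empirically by
permuting sample labels, converts each observed statistic to a two-tailed
empirical p-value, combines the three via Stouffer's method, and corrects
for multiple testing with Storey's q-value. Differentially expressed genes
(DEGs) are those with q below a threshold and |LMR| above a fold-change
threshold.

The three statistics are computed on the same samples and are strongly
positively correlated, so the closed-form normal p-value of the combined
Stouffer Z is anti-conservative. By default the pipeline therefore also
permutes the *combined* Z — the same permutation rounds already yield all
three statistics — and reports the overall p as the empirical two-tailed p
of Z against that null, which keeps the test calibrated. The closed-form
value is reported alongside as ``p_normal``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSignature, SiglossError

__all__ = [
    "SampleGroups", "PermutationConfig", "DegCriteria", "NullEnsembles",
    "assign_groups", "three_statistics", "permutation_null", "empirical_p",
    "stouffer_combine", "storey_q", "call_degs", "integrated_de",
]


@dataclass
class SampleGroups:
    """Anchor-defined sample dichotomy: ``low`` (loss) vs ``high`` (rest)."""

    low: list[str]
    high: list[str]
    anchor_gene: str | None = None
    rule: str = "explicit"

    def __post_init__(self) -> None:
        if set(self.low) & set(self.high):
            raise SiglossError("low and high groups overlap")
        if len(self.low) == 0 or len(self.high) == 0:
            raise SiglossError("degenerate grouping: one group is empty")
        # canonical order makes results invariant to input sample order
        self.low = sorted(self.low)
        self.high = sorted(self.high)


@dataclass
class PermutationConfig:
    B: int = 10_000
    seed: int = 0
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.B < 1:
            raise SiglossError("permutation count B must be >= 1")
        if self.B < 100:
            warnings.warn("B < 100 permutations: q-values will be unreliable", stacklevel=2)


@dataclass
class DegCriteria:
    q_max: float = 0.05
    lmr_min: float = 0.58  # log2(1.5) to two decimals

    def __post_init__(self) -> None:
        if not 0 < self.q_max < 1:
            raise SiglossError("q_max must lie in (0, 1)")
        if self.lmr_min < 0:
            raise SiglossError("lmr_min must be >= 0")


@dataclass
class NullEnsembles:
    """Permutation null statistics, genes x B per statistic."""

    t: np.ndarray = field(repr=False)
    w: np.ndarray = field(repr=False)
    lmr: np.ndarray = field(repr=False)
    exhaustive: bool = False

    @property
    def B(self) -> int:
        return self.t.shape[1]


def assign_groups(m: ExpressionMatrix, anchor: str,
                  rule: str = "quartile_low_vs_rest") -> SampleGroups:
    """Split samples by anchor-gene expression.

    ``quartile_low_vs_rest`` puts samples strictly below the lower quartile
    (linear-interpolation quantile) in ``low`` and the rest (ties included)
    in ``high``; ``below_median`` is analogous at the median.
    """
    if anchor not in m.values.index:
        raise SiglossError(f"anchor gene {anchor!r} not in matrix")
    vals = m.values.loc[anchor]
    if float(vals.max()) == float(vals.min()):
        raise SiglossError(f"degenerate grouping: anchor {anchor!r} is constant")
    if rule == "quartile_low_vs_rest":
        thr = float(np.quantile(vals, 0.25))
    elif rule == "below_median":
        thr = float(np.median(vals))
    else:
        raise SiglossError(f"unknown grouping rule {rule!r}")
    low = list(vals.index[vals < thr])
    high = list(vals.index[vals >= thr])
    if not low:
        raise SiglossError("degenerate grouping: no sample below threshold")
    return SampleGroups(low=low, high=high, anchor_gene=anchor, rule=rule)


# ---------------------------------------------------------------------------
# statistics


def _median_ratio(med_low: np.ndarray, med_high: np.ndarray, eps: float) -> np.ndarray:
    # pseudocount applied only where a median is zero
    lo = np.where(med_low == 0, eps, med_low)
    hi = np.where(med_high == 0, eps, med_high)
    return np.log2(lo / hi)


def _stats_for_assignments(x_log: np.ndarray, x_lin: np.ndarray,
                           low_idx: np.ndarray, eps: float
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch t, rank-sum z and LMR for each label assignment.

    ``low_idx`` is (B, n_low) column indices into the sample axis; returns
    three (genes, B) arrays. t and w run on the log2 matrix, LMR on linear.
    """
    n_genes, n = x_log.shape
    B, n1 = low_idx.shape
    n2 = n - n1

    L = np.zeros((n, B))
    L[low_idx.ravel(), np.repeat(np.arange(B), n1)] = 1.0

    s1 = x_log @ L
    q1 = (x_log ** 2) @ L
    tot = x_log.sum(axis=1, keepdims=True)
    tot2 = (x_log ** 2).sum(axis=1, keepdims=True)
    mean1, mean2 = s1 / n1, (tot - s1) / n2
    var1 = np.maximum(q1 - s1 ** 2 / n1, 0.0) / max(n1 - 1, 1)
    var2 = np.maximum((tot2 - q1) - (tot - s1) ** 2 / n2, 0.0) / max(n2 - 1, 1)
    # clamp cancellation residue for constant genes to an exact zero
    tol = 1e-12 * (tot2 / n + 1.0)
    var1 = np.where(var1 < tol, 0.0, var1)
    var2 = np.where(var2 < tol, 0.0, var2)
    denom = np.sqrt(var1 / n1 + var2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (mean1 - mean2) / denom, 0.0)

    ranks = rankdata(x_log, axis=1)
    w_sum = ranks @ L
    e_w = n1 * (n + 1) / 2.0
    # exact finite-population variance of the rank sum, tie-corrected
    var_w = n1 * n2 / (n * (n - 1)) * np.sum((ranks - (n + 1) / 2.0) ** 2, axis=1)
    sd_w = np.sqrt(var_w)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(sd_w > 0, (w_sum - e_w) / sd_w, 0.0)

    lmr = np.empty((n_genes, B))
    all_cols = np.arange(n)
    for b in range(B):
        lo_cols = low_idx[b]
        hi_cols = np.setdiff1d(all_cols, lo_cols, assume_unique=True)
        med_lo = np.median(x_lin[:, lo_cols], axis=1)
        med_hi = np.median(x_lin[:, hi_cols], axis=1)
        lmr[:, b] = _median_ratio(med_lo, med_hi, eps)
    return t, w, lmr


def _prep_matrices(m: ExpressionMatrix, groups: SampleGroups,
                   log_transform: bool = True) -> tuple[np.ndarray, np.ndarray, int, float]:
    samples = list(groups.low) + list(groups.high)
    missing = set(samples) - set(m.sample_ids)
    if missing:
        raise SiglossError(f"group samples absent from matrix: {sorted(missing)[:5]}")
    sub = m.values[samples]
    x_lin = sub.to_numpy(float)
    if m.scale == "log2":
        x_log = x_lin
        x_lin = 2.0 ** x_lin  # LMR is defined on the linear scale
    elif log_transform:
        x_log = np.log2(x_lin + 1.0)
    else:
        x_log = x_lin
    pos = x_lin[x_lin > 0]
    eps = 0.5 * float(pos.min()) if pos.size else 1.0
    return x_log, x_lin, len(groups.low), eps


def three_statistics(m: ExpressionMatrix, groups: SampleGroups,
                     log_transform: bool = True) -> pd.DataFrame:
    """Observed per-gene (t_stat, w_stat, lmr) for the given grouping."""
    if len(groups.low) < 2 or len(groups.high) < 2:
        raise SiglossError("each group needs at least 2 samples")
    x_log, x_lin, n1, eps = _prep_matrices(m, groups, log_transform)
    obs_idx = np.arange(n1)[None, :]
    t, w, lmr = _stats_for_assignments(x_log, x_lin, obs_idx, eps)
    return pd.DataFrame(
        {"t_stat": t[:, 0], "w_stat": w[:, 0], "lmr": lmr[:, 0]}, index=m.gene_ids
    )


def permutation_null(m: ExpressionMatrix, groups: SampleGroups,
                     config: PermutationConfig | None = None,
                     log_transform: bool = True) -> NullEnsembles:
    """Null ensembles of the three statistics under sample-label permutation.

    Each permutation draws a random subset of ``|low|`` samples as the
    pseudo-low group; the same assignment feeds all three statistics. With
    ``config.exhaustive`` every distinct assignment is enumerated once
    (requires C(n, |low|) <= B).
    """
    config = config or PermutationConfig()
    x_log, x_lin, n1, eps = _prep_matrices(m, groups, log_transform)
    n = x_log.shape[1]
    if config.exhaustive:
        total = comb(n, n1)
        if total > config.B:
            raise SiglossError(f"exhaustive mode needs B >= C({n},{n1}) = {total}")
        low_idx = np.array(list(itertools.combinations(range(n), n1)))
    else:
        rng = np.random.default_rng(config.seed)
        low_idx = np.argsort(rng.random((config.B, n)), axis=1)[:, :n1]
    t, w, lmr = _stats_for_assignments(x_log, x_lin, low_idx, eps)
    return NullEnsembles(t=t, w=w, lmr=lmr, exhaustive=config.exhaustive)


# ---------------------------------------------------------------------------
# empirical p-values and combination


def empirical_p(observed: float, null: np.ndarray) -> float:
    """Two-tailed empirical p with the +1/(B+1) pseudocount (never 0)."""
    null = np.asarray(null, float).ravel()
    if null.size == 0:
        raise SiglossError("empty null ensemble")
    ge = int(np.sum(null >= observed))
    le = int(np.sum(null <= observed))
    return min(1.0, 2.0 * (min(ge, le) + 1) / (null.size + 1))


def _empirical_p_sorted(values: np.ndarray, pool_sorted: np.ndarray) -> np.ndarray:
    n = pool_sorted.size
    le = np.searchsorted(pool_sorted, values, side="right")
    ge = n - np.searchsorted(pool_sorted, values, side="left")
    return np.minimum(1.0, 2.0 * (np.minimum(le, ge) + 1) / (n + 1))


def _empirical_p_rows(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
    le = (null <= obs[:, None]).sum(axis=1)
    ge = (null >= obs[:, None]).sum(axis=1)
    B = null.shape[1]
    return np.minimum(1.0, 2.0 * (np.minimum(le, ge) + 1) / (B + 1))


def _signed_z(p: np.ndarray, sign_source: np.ndarray) -> np.ndarray:
    return np.sign(sign_source) * ndtri(1.0 - np.asarray(p) / 2.0)


def stouffer_combine(p_t, p_w, p_lmr, signs) -> tuple[np.ndarray, np.ndarray]:
    """Stouffer combination of three two-tailed p-values with direction.

    Each p is converted to a signed z = sign * Phi^-1(1 - p/2); the combined
    Z is their equal-weight sum rescaled by sqrt(3), and the overall p is the
    two-tailed normal tail of Z.
    """
    ps = [np.atleast_1d(np.asarray(p, float)) for p in (p_t, p_w, p_lmr)]
    signs = [np.atleast_1d(np.asarray(s, float)) for s in signs]
    if len(signs) != 3 or any(s.shape != p.shape for s, p in zip(signs, ps)):
        raise SiglossError("signs must be three vectors matching the p-value vectors")
    for p in ps:
        if np.any((p <= 0) | (p > 1)):
            raise SiglossError("p-values must lie in (0, 1]")
    zs = [_signed_z(p, s) for p, s in zip(ps, signs)]
    z_comb = sum(zs) / np.sqrt(3.0)
    p_overall = 2.0 * (1.0 - ndtr(np.abs(z_comb)))
    return z_comb, np.maximum(p_overall, np.finfo(float).tiny)


def storey_q(p_values, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed-lambda pi0 estimate.

    pi0 = #{p > lambda} / (m (1 - lambda)), capped at 1; q_(i) is the running
    minimum of pi0 * m * p_(j) / j from the largest p downward, so q is
    monotone in p. With pi0 = 1 this reduces to Benjamini-Hochberg.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise SiglossError("no p-values given")
    if np.any((p <= 0) | (p > 1)):
        raise SiglossError("p-values must lie in (0, 1]")
    if not 0 <= lam < 1:
        raise SiglossError("lambda must lie in [0, 1)")
    m = p.size
    pi0 = min(1.0, float(np.sum(p > lam)) / (m * (1.0 - lam)))
    if pi0 <= 0:
        warnings.warn("pi0 estimate is 0; flooring at 1/m", stacklevel=2)
        pi0 = 1.0 / m
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_degs(stats: pd.DataFrame, criteria: DegCriteria | None = None,
              name: str = "signature") -> GeneSignature:
    """DEG calling: q < q_max and |LMR| beyond lmr_min, split by direction.

    ``up_genes`` are higher in the anchor-low group (positive LMR).
    """
    criteria = criteria or DegCriteria()
    if "q" not in stats.columns or "lmr" not in stats.columns:
        raise SiglossError("stats table needs 'q' and 'lmr' columns")
    sig_mask = stats["q"] < criteria.q_max
    up = set(stats.index[sig_mask & (stats["lmr"] > criteria.lmr_min)])
    down = set(stats.index[sig_mask & (stats["lmr"] < -criteria.lmr_min)])
    return GeneSignature(name, up_genes=up, down_genes=down)


# ---------------------------------------------------------------------------
# pipeline


def _pooled_p(obs: np.ndarray, null: np.ndarray, standardize: bool
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Empirical p of observed and null values against the gene-pooled null.

    Returns (p_obs, p_null, obs_std, null_std). With ``standardize`` each
    gene's values are centred/scaled by its own null moments before pooling.
    """
    if standardize:
        mu = null.mean(axis=1, keepdims=True)
        sd = null.std(axis=1, ddof=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        null_std = (null - mu) / sd
        obs_std = (obs[:, None] - mu) / sd
    else:
        null_std = null
        obs_std = obs[:, None]
    pool = np.sort(null_std, axis=None)
    p_obs = _empirical_p_sorted(obs_std.ravel(), pool)
    p_null = _empirical_p_sorted(null_std.ravel(), pool).reshape(null.shape)
    return p_obs, p_null, obs_std.ravel(), null_std


def integrated_de(m: ExpressionMatrix, groups: SampleGroups,
                  config: PermutationConfig | None = None, *,
                  null_mode: str = "pooled",
                  calibrate_overall: bool = True,
                  lam: float = 0.5,
                  log_transform: bool = True) -> pd.DataFrame:
    """Full integrated DE test; one row per gene.

    Columns: the three observed statistics; their empirical two-tailed
    p-values and signed z's; the Stouffer ``Z_comb``; ``p_normal`` (closed
    form); ``p_overall`` (permutation-calibrated by default, else equal to
    ``p_normal``); and the Storey ``q`` computed from ``p_overall``.

    ``null_mode='pooled'`` pools null values across genes per statistic
    (t and w standardized by their per-gene null moments first) to sharpen
    tail resolution; ``'per_gene'`` keeps each gene's own B-value null.
    """
    config = config or PermutationConfig()
    obs = three_statistics(m, groups, log_transform)
    nulls = permutation_null(m, groups, config, log_transform)

    stat_specs = [("t", obs["t_stat"].to_numpy(), nulls.t, True),
                  ("w", obs["w_stat"].to_numpy(), nulls.w, True),
                  ("lmr", obs["lmr"].to_numpy(), nulls.lmr, False)]
    p_cols: dict[str, np.ndarray] = {}
    z_null_sum = np.zeros_like(nulls.t)
    z_obs_sum = np.zeros(m.n_genes)
    for name, ov, nv, standardize in stat_specs:
        if null_mode == "pooled":
            p_obs, p_null, obs_std, null_std = _pooled_p(ov, nv, standardize)
        elif null_mode == "per_gene":
            p_obs = _empirical_p_rows(ov, nv)
            le = rankdata(nv, method="max", axis=1)
            ge = nv.shape[1] + 1 - rankdata(nv, method="min", axis=1)
            p_null = np.minimum(1.0, 2.0 * (np.minimum(le, ge) + 1) / (nv.shape[1] + 1))
            obs_std, null_std = ov, nv
        else:
            raise SiglossError(f"unknown null_mode {null_mode!r}")
        p_cols[f"p_{name}"] = p_obs
        z_obs = _signed_z(p_obs, obs_std)
        p_cols[f"z_{name}"] = z_obs
        z_obs_sum += z_obs
        if calibrate_overall:
            z_null_sum += _signed_z(p_null, null_std)

    z_comb = z_obs_sum / np.sqrt(3.0)
    p_normal = 2.0 * (1.0 - ndtr(np.abs(z_comb)))
    p_normal = np.maximum(p_normal, np.finfo(float).tiny)
    if calibrate_overall:
        z_comb_null = z_null_sum / np.sqrt(3.0)
        if null_mode == "pooled":
            pool = np.sort(z_comb_null, axis=None)
            p_overall = _empirical_p_sorted(z_comb, pool)
        else:
            p_overall = _empirical_p_rows(z_comb, z_comb_null)
    else:
        p_overall = p_normal

    out = obs.copy()
    for k, v in p_cols.items():
        out[k] = v
    out["Z_comb"] = z_comb
    out["p_normal"] = p_normal
    out["p_overall"] = p_overall
    out["q"] = storey_q(p_overall, lam=lam)
    return out
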