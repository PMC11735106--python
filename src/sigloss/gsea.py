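"""Gene-set enrichment by the weighted Kolmogorov-Smirnov running sum.

Genes are ordered by a ranking metric (the log2-median-ratio of the
differential analysis by default, descending). Walking down the list, set
members ("hits") increment a running sum by their normalized metric weight
and non-members decrement it by a constant; the enrichment score (ES) is
the signed maximum deviation. Significance comes from a permutation null —
either random gene sets of matched size drawn from the ranked universe, or
phenotype (sample-label) permutations that re-rank the list each round.
Normalized enrichment scores (NES) and the permutation FDR q follow the
standard convention of dividing by the mean |null ES| of matching sign and
comparing tail fractions of the normalized null and observed score
distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import SampleGroups, _prep_matrices, _stats_for_assignments
from .io import ExpressionMatrix, SiglossError


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    min_size: int = 15
    max_size: int = 500

    def restrict(self, universe: list[str]) -> dict[str, list[str]]:
        """Intersect each set with the universe and apply size bounds."""
        uni = set(universe)
        out = {}
        for name, genes in self.sets.items():
            inter = [g for g in dict.fromkeys(genes) if g in uni]
            if self.min_size <= len(inter) <= self.max_size:
                out[name] = inter
        return out


def rank_genes(metric: pd.Series) -> pd.Series:
    """Descending ranked list; metric ties broken by gene id (lexicographic)."""
    df = pd.DataFrame({"metric": metric.astype(float)})
    df["gene"] = df.index.astype(str)
    df = df.sort_values(["metric", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(df["metric"].to_numpy(), index=df["gene"].to_numpy(), name="metric")


def running_es(ranked: pd.Series, gene_set, weight_exp: float = 1.0
               ) -> tuple[float, np.ndarray, list[str]]:
    """Full running-sum walk: (ES, running sum, leading-edge genes).

    Hits advance by |metric|^weight_exp normalized over the set's hits,
    misses retreat by 1/(N - set size); ES is the running-sum value of
    maximum absolute deviation (ties broken toward the earlier position).
    The leading edge is the hit genes up to the extremum for positive ES,
    and from the extremum onward for negative ES.
    """
    genes = np.asarray(ranked.index)
    metric = ranked.to_numpy(float)
    n = genes.size
    hit = np.isin(genes, list(gene_set))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise SiglossError("gene set does not intersect the ranked universe")
    if n_hit == n:
        raise SiglossError("gene set equals the ranked universe")
    w = np.abs(metric) ** weight_exp
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit metrics zero: fall back to equal hit weights
        hit_w = hit.astype(float)
        total = hit_w.sum()
    step = hit_w / total - (~hit) / (n - n_hit)
    running = np.cumsum(step)
    dev = np.abs(running)
    # earliest position within floating tolerance of the max deviation
    i_star = int(np.argmax(dev >= dev.max() - 1e-12))
    es = float(running[i_star])
    if es >= 0:
        leading = genes[: i_star + 1][hit[: i_star + 1]]
    else:
        leading = genes[i_star:][hit[i_star:]]
    return es, running, list(leading)


def _es_from_positions(pos_sorted: np.ndarray, w_abs: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many hit-position sets (rows of ``pos_sorted``).

    Matches the full walk: between hits the running sum falls linearly, so
    the extremum lies at a hit (candidate max) or just before one (candidate
    min); the larger |value| wins, ties toward the earlier list position.
    """
    draws, s = pos_sorted.shape
    wv = w_abs[pos_sorted]
    tot = wv.sum(axis=1, keepdims=True)
    zero = tot[:, 0] == 0
    if zero.any():
        wv[zero] = 1.0
        tot = wv.sum(axis=1, keepdims=True)
    cum = np.cumsum(wv, axis=1) / tot
    d = 1.0 / (n - s)
    j = np.arange(1, s + 1)
    at_hit = cum - d * (pos_sorted + 1 - j)          # running sum at each hit
    before_hit = np.concatenate([np.zeros((draws, 1)), cum[:, :-1]], axis=1) \
        - d * (pos_sorted - (j - 1))                 # just before each hit
    tol = 1e-12
    jmax = np.argmax(at_hit >= at_hit.max(axis=1, keepdims=True) - tol, axis=1)
    jmin = np.argmax(before_hit <= before_hit.min(axis=1, keepdims=True) + tol, axis=1)
    rows = np.arange(draws)
    vmax = at_hit[rows, jmax]
    vmin = before_hit[rows, jmin]
    pos_max = pos_sorted[rows, jmax]
    pos_min = pos_sorted[rows, jmin] - 1
    use_max = (np.abs(vmax) > np.abs(vmin) + tol) | (
        (np.abs(vmax) >= np.abs(vmin) - tol) & (pos_max <= pos_min))
    return np.where(use_max, vmax, vmin)


def _nes_and_p(es: float, null_es: np.ndarray) -> tuple[float, float]:
    same = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    if same.size == 0:
        return np.nan, np.nan
    denom = np.abs(same).mean()
    nes = es / denom if denom > 0 else np.nan
    p = (np.sum(np.abs(same) >= abs(es)) + 1) / (same.size + 1)
    return float(nes), float(p)


def es_significance(ranked: pd.Series | None, sets: GeneSetCollection | dict,
                    mode: str = "gene_set_perm", n_perm: int = 1000,
                    seed: int = 0, weight_exp: float = 1.0,
                    expression: ExpressionMatrix | None = None,
                    groups: SampleGroups | None = None,
                    q_threshold: float = 0.25) -> pd.DataFrame:
    """Permutation significance of set enrichment; one row per evaluated set.

    ``gene_set_perm`` draws random sets of matched size from the ranked
    universe; ``phenotype_perm`` permutes sample labels (requires
    ``expression`` and ``groups``), re-computes the log2-median-ratio
    ranking each round and re-evaluates each set. Columns: size, ES, NES,
    p, q and a significance flag at ``q_threshold`` (default 0.25).
    """
    if n_perm < 10:
        raise SiglossError("n_perm must be at least 10")
    if isinstance(sets, dict):
        sets = GeneSetCollection(sets, min_size=1, max_size=10 ** 9)
    if mode == "phenotype_perm":
        if expression is None or groups is None:
            raise SiglossError("phenotype permutation needs expression and groups")
        x_log, x_lin, n1, eps = _prep_matrices(expression, groups)
        obs_idx = np.arange(n1)[None, :]
        _, _, lmr_obs = _stats_for_assignments(x_log, x_lin, obs_idx, eps)
        ranked = rank_genes(pd.Series(lmr_obs[:, 0], index=expression.gene_ids))
    elif mode != "gene_set_perm":
        raise SiglossError(f"unknown permutation mode {mode!r}")
    if ranked is None:
        raise SiglossError("gene_set_perm mode needs a ranked list")

    universe = list(ranked.index)
    use_sets = sets.restrict(universe)
    if not use_sets:
        raise SiglossError("no gene set passed the size filters")
    rng = np.random.default_rng(seed)
    n = len(universe)
    w_abs = np.abs(ranked.to_numpy(float)) ** weight_exp

    observed = {name: running_es(ranked, genes, weight_exp)
                for name, genes in use_sets.items()}

    null_by_set: dict[str, np.ndarray] = {}
    if mode == "gene_set_perm":
        size_cache: dict[int, np.ndarray] = {}
        for name, genes in use_sets.items():
            s = len(genes)
            if s not in size_cache:
                draws = np.argsort(rng.random((n_perm, n)), axis=1)[:, :s]
                size_cache[s] = _es_from_positions(np.sort(draws, axis=1), w_abs, n)
            null_by_set[name] = size_cache[s]
    else:
        perm_idx = np.argsort(rng.random((n_perm, x_log.shape[1])), axis=1)[:, :n1]
        _, _, lmr_null = _stats_for_assignments(x_log, x_lin, perm_idx, eps)
        nulls = {name: np.empty(n_perm) for name in use_sets}
        gene_arr = np.asarray(expression.gene_ids)
        for b in range(n_perm):
            rk = rank_genes(pd.Series(lmr_null[:, b], index=gene_arr))
            wv = np.abs(rk.to_numpy()) ** weight_exp
            order_genes = np.asarray(rk.index)
            for name, genes in use_sets.items():
                pos = np.sort(np.flatnonzero(np.isin(order_genes, genes)))
                nulls[name][b] = _es_from_positions(pos[None, :], wv, n)[0]
        null_by_set = nulls

    rows = []
    norm_null_all, norm_obs_all = [], []
    for name, (es, _, leading) in observed.items():
        null_es = null_by_set[name]
        nes, p = _nes_and_p(es, null_es)
        if np.isnan(nes):
            warnings.warn(f"set {name!r}: no sign-matched null ES; q undefined",
                          stacklevel=2)
        pos_mean = np.abs(null_es[null_es > 0]).mean() if (null_es > 0).any() else np.nan
        neg_mean = np.abs(null_es[null_es < 0]).mean() if (null_es < 0).any() else np.nan
        norm = np.where(null_es >= 0, null_es / pos_mean, null_es / neg_mean)
        norm_null_all.append(norm[np.isfinite(norm)])
        norm_obs_all.append(nes)
        rows.append({"set": name, "size": len(use_sets[name]), "ES": es,
                     "NES": nes, "p": p, "leading_edge": ",".join(leading)})
    norm_null = np.concatenate(norm_null_all) if norm_null_all else np.array([])
    norm_obs = np.asarray(norm_obs_all, float)

    for row in rows:
        nes = row["NES"]
        if not np.isfinite(nes):
            row["q"] = np.nan
            continue
        if nes >= 0:
            null_tail = np.mean(norm_null[norm_null >= 0] >= nes) if (norm_null >= 0).any() else 0.0
            obs_tail = np.mean(norm_obs[norm_obs >= 0] >= nes)
        else:
            null_tail = np.mean(norm_null[norm_null < 0] <= nes) if (norm_null < 0).any() else 0.0
            obs_tail = np.mean(norm_obs[norm_obs < 0] <= nes)
        row["q"] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else np.nan

    out = pd.DataFrame(rows).set_index("set")
    out["significant"] = out["q"] < q_threshold
    return out[["size", "ES", "NES", "p", "q", "significant", "leading_edge"]]
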