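"""Single-sample signature activation by the z-score method.

Each signature gene is standardized across the cohort (mean 0, sd 1); a
sample's activation score is the mean standardized expression over the
up-genes minus the mean over the down-genes. Prognostic groups come from
median dichotomization of the scores, or from quartile rules for single-
and co-loss grouping of individual genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSignature, SiglossError


def score_activation(m: ExpressionMatrix, sig: GeneSignature,
                     aggregate: str = "mean") -> pd.DataFrame:
    """Per-sample activation scores; columns ``score`` and ``coverage``.

    ``aggregate='mean'`` (default) averages per-gene z-scores, so the score
    is comparable across cohorts with different signature coverage;
    ``'sum_sqrt'`` uses sum/sqrt(k) instead. Zero-variance genes are dropped
    with a warning. Coverage is the fraction of signature genes found in the
    matrix (constant per cohort, repeated per sample for convenience).
    """
    if m.n_samples < 2:
        raise SiglossError("scoring needs at least 2 samples")
    if aggregate not in ("mean", "sum_sqrt"):
        raise SiglossError(f"unknown aggregate {aggregate!r}")
    expr = m.log2_values() if m.scale != "log2" else m.values

    parts = []
    n_found = 0
    for genes, direction in ((sig.up_genes, 1.0), (sig.down_genes, -1.0)):
        present = sorted(set(genes) & set(m.gene_ids))
        n_found += len(present)
        if not present:
            continue
        sub = expr.loc[present]
        sd = sub.std(axis=1, ddof=1)
        # rounding can leave ~1e-16 "variance" on constant rows
        dropped = sd.index[sd <= 1e-12 * (sub.abs().mean(axis=1) + 1.0)]
        if len(dropped):
            warnings.warn(f"dropping {len(dropped)} zero-variance signature gene(s)",
                          stacklevel=2)
            sub = sub.drop(index=dropped)
            sd = sd.drop(index=dropped)
        if sub.empty:
            continue
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        k = z.shape[0]
        agg = z.mean(axis=0) if aggregate == "mean" else z.sum(axis=0) / np.sqrt(k)
        parts.append(direction * agg)
    if n_found == 0:
        raise SiglossError("no signature gene present in the matrix")
    if not parts:
        raise SiglossError("all present signature genes had zero variance")
    score = sum(parts)
    coverage = n_found / max(len(sig), 1)
    return pd.DataFrame({"score": score, "coverage": coverage},
                        index=m.sample_ids)


def dichotomize(scores: pd.Series | pd.DataFrame, rule: str = "median") -> pd.Series:
    """Two-group labels from activation scores.

    ``median``: score strictly above the median -> ``high`` (activated,
    loss-like), ties and below -> ``low``. ``quartile``: strictly below the
    lower quartile -> ``low``, rest -> ``high`` (mirrors anchor grouping).
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["score"]
    if len(scores) < 2:
        raise SiglossError("dichotomization needs at least 2 samples")
    if float(scores.max()) == float(scores.min()):
        raise SiglossError("constant scores cannot be dichotomized")
    if rule == "median":
        thr = float(np.median(scores))
        labels = np.where(scores > thr, "high", "low")
    elif rule == "quartile":
        thr = float(np.quantile(scores, 0.25))
        labels = np.where(scores < thr, "low", "high")
    else:
        raise SiglossError(f"unknown dichotomization rule {rule!r}")
    return pd.Series(labels, index=scores.index, name="group")


def coloss_groups(gene_a: pd.Series, gene_b: pd.Series) -> pd.Series:
    """Quartile co-loss grouping of two genes over the same samples.

    Each gene is dichotomized at its own lower quartile; samples strictly
    below both cutoffs are ``both_low``, below exactly one ``single_low``,
    otherwise ``neither``.
    """
    if set(gene_a.index) != set(gene_b.index):
        raise SiglossError("co-loss grouping needs identical sample sets")
    gene_b = gene_b.reindex(gene_a.index)
    low_a = gene_a < np.quantile(gene_a, 0.25)
    low_b = gene_b < np.quantile(gene_b, 0.25)
    n_low = low_a.astype(int) + low_b.astype(int)
    labels = np.select([n_low == 2, n_low == 1], ["both_low", "single_low"], "neither")
    return pd.Series(labels, index=gene_a.index, name="coloss_group")
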