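"""Count filtering and TMM (trimmed mean of M-values) normalization.

Raw count libraries differ in sequencing depth and composition; TMM
estimates one positive scaling factor per sample from doubly trimmed,
precision-weighted log ratios (M-values) against a reference sample, and
downstream expression is taken as counts per million on the effective
(factor-corrected) library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, ScaleError, SiglossError


@dataclass
class TmmFactors:
    reference_sample: str
    factors: pd.Series = field(repr=False)
    trim_m: float = 0.30
    trim_a: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.trim_m < 0.5 and 0 <= self.trim_a < 0.5):
            raise SiglossError("trim fractions must lie in [0, 0.5)")


def filter_low_counts(m: ExpressionMatrix, min_total: int = 2,
                      mode: str = "total") -> ExpressionMatrix:
    """Drop genes with insufficient raw counts; gene order is preserved.

    ``mode='total'`` keeps genes whose summed count across all samples is at
    least ``min_total`` (default reading of an "at least 2 across all the
    libraries" rule); ``mode='each'`` requires every library to reach it.
    """
    if m.scale != "raw_counts":
        raise ScaleError(f"low-count filter needs raw counts, got scale {m.scale!r}")
    if mode == "total":
        keep = m.values.sum(axis=1) >= min_total
    elif mode == "each":
        keep = (m.values >= min_total).all(axis=1)
    else:
        raise SiglossError(f"unknown filter mode {mode!r}")
    return ExpressionMatrix(m.values.loc[keep], scale="raw_counts")


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
                     trim_m: float, trim_a: float, weighted: bool = True) -> float:
    """TMM factor of one library against the reference (log2 scale internals)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / n_obs) / (ref / n_ref))
        a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(m[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(m: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                weighted: bool = True) -> TmmFactors:
    """Per-sample TMM scaling factors, renormalized to unit geometric mean.

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean upper-quartile fraction across samples.
    """
    if m.scale != "raw_counts":
        raise ScaleError("TMM needs raw counts")
    if m.n_samples < 2:
        raise SiglossError("TMM needs at least 2 samples")
    counts = m.values.to_numpy(float)
    lib = counts.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise SiglossError(f"sample(s) with all-zero counts: {[m.sample_ids[i] for i in zero]}")
    f75 = np.quantile(counts / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = counts[:, ref_idx]
    facs = np.array([
        _tmm_pair_factor(counts[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a, weighted)
        for j in range(m.n_samples)
    ])
    facs /= np.exp(np.mean(np.log(facs)))
    return TmmFactors(
        reference_sample=m.sample_ids[ref_idx],
        factors=pd.Series(facs, index=m.sample_ids, name="tmm_factor"),
        trim_m=trim_m, trim_a=trim_a,
    )


def tmm_normalize(m: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                  weighted: bool = True) -> tuple[ExpressionMatrix, TmmFactors]:
    """TMM-normalize raw counts; returns CPM on effective library sizes."""
    tf = tmm_factors(m, trim_m=trim_m, trim_a=trim_a, weighted=weighted)
    lib = m.values.sum(axis=0)
    eff = lib * tf.factors
    cpm = m.values / eff.to_numpy() * 1e6
    return ExpressionMatrix(cpm, scale="normalized"), tf
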