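"""Between-sample normalization by trimmed mean of M-values (TMM).

Each sample receives a scaling factor computed from double-trimmed log2
expression ratios against a reference sample, weighted by inverse asymptotic
(delta-method binomial) variances, and the factors are rescaled so their
geometric mean is 1. The per-sample offset used by the count model is
log(library_size * tmm_factor).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import CountMatrix, ValidationError


class TMMNormalizer(BaseEstimator):
    """Trimmed-mean-of-M-values normalization factors.

    Parameters
    ----------
    logratio_trim : float
        Two-sided trim fraction applied to the M-values (log2 ratios).
    abs_trim : float
        Two-sided trim fraction applied to the A-values (average log2
        abundance).

    Attributes (after :meth:`fit`)
    ------------------------------
    factors_ : pandas Series, sample -> TMM factor (geometric mean 1).
    library_sizes_ : pandas Series of column sums.
    offsets_ : pandas Series, log(library_size * factor).
    reference_sample_ : the column used as the M-value reference — the sample
        whose 75th percentile of library-size-scaled counts is closest to the
        mean of those percentiles.
    """

    def __init__(self, logratio_trim: float = 0.30, abs_trim: float = 0.05):
        self.logratio_trim = logratio_trim
        self.abs_trim = abs_trim

    def fit(self, counts: CountMatrix) -> "TMMNormalizer":
        mat = counts.values().astype(float)
        lib = mat.sum(axis=0)
        if (lib <= 0).any():
            bad = [s for s, l in zip(counts.sample_ids, lib) if l <= 0]
            raise ValidationError(f"sample(s) with zero library size: {bad}")

        scaled = mat / lib
        f75 = np.quantile(scaled, 0.75, axis=0)
        ref = int(np.argmin(np.abs(f75 - f75.mean())))

        factors = np.ones(mat.shape[1])
        for j in range(mat.shape[1]):
            if j == ref:
                continue
            factors[j] = self._pairwise_factor(
                mat[:, j], lib[j], mat[:, ref], lib[ref], counts.sample_ids[j]
            )
        factors = factors / np.exp(np.mean(np.log(factors)))

        self.factors_ = pd.Series(factors, index=counts.sample_ids, name="tmm_factor")
        self.library_sizes_ = pd.Series(
            lib.astype(np.int64), index=counts.sample_ids, name="library_size"
        )
        self.offsets_ = pd.Series(
            np.log(lib * factors), index=counts.sample_ids, name="offset"
        )
        self.reference_sample_ = counts.sample_ids[ref]
        return self

    def _pairwise_factor(self, obs, n_obs, ref, n_ref, sample_id) -> float:
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            raise ValidationError(
                f"sample {sample_id!r} shares no nonzero genes with the "
                f"reference sample; cannot compute a TMM factor"
            )
        p_obs, p_ref = obs[keep] / n_obs, ref[keep] / n_ref
        M = np.log2(p_obs / p_ref)
        A = 0.5 * np.log2(p_obs * p_ref)
        # delta-method variance of M under binomial sampling
        w = 1.0 / ((n_obs - obs[keep]) / (n_obs * obs[keep])
                   + (n_ref - ref[keep]) / (n_ref * ref[keep]))
        if np.max(np.abs(M)) < 1e-6:  # identical relative compositions
            return 1.0
        keep2 = _double_trim_mask(M, A, self.logratio_trim, self.abs_trim)
        if not keep2.any():
            return 1.0
        f = np.sum(w[keep2] * M[keep2]) / np.sum(w[keep2])
        return float(2.0**f)

    def transform(self, counts: CountMatrix, log: bool = True, prior: float = 0.5) -> pd.DataFrame:
        """Counts per million on TMM-effective library sizes; log2(CPM+prior) if log."""
        eff = self.library_sizes_.loc[counts.sample_ids].to_numpy() * \
            self.factors_.loc[counts.sample_ids].to_numpy()
        cpm = counts.values() / eff * 1e6
        if log:
            cpm = np.log2(cpm + prior)
        return pd.DataFrame(cpm, index=counts.gene_ids, columns=counts.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.concat([self.library_sizes_, self.factors_, self.offsets_], axis=1)
        df.index.name = "sample_id"
        return df


def _double_trim_mask(M: np.ndarray, A: np.ndarray, m_trim: float, a_trim: float) -> np.ndarray:
    """Keep entries inside both the M-trimmed and A-trimmed central ranks."""
    n = M.size
    keep = np.ones(n, dtype=bool)
    for values, frac in ((M, m_trim), (A, a_trim)):
        lo = int(np.floor(n * frac) + 1)
        hi = n + 1 - lo
        ranks = values.argsort(kind="stable").argsort(kind="stable") + 1
        keep &= (ranks >= lo) & (ranks <= hi)
    return keep


def tmm_normalize(counts: CountMatrix, logratio_trim: float = 0.30,
                  abs_trim: float = 0.05) -> TMMNormalizer:
    """Fit TMM factors for a count matrix (thin wrapper over TMMNormalizer)."""
    return TMMNormalizer(logratio_trim=logratio_trim, abs_trim=abs_trim).fit(counts)
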