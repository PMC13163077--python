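"""Reference-based cell-type analysis of DEG lists.

Cell-type-specific genes are derived from a cluster-labeled reference by a
share-of-expression specificity score: with per-type mean depth-normalized
expression m_gc, s_g = max_c m_gc / sum_c m_gc, and a gene is a marker of
its argmax type iff s_g >= 0.6 (configurable). Because the threshold exceeds
0.5, a gene belongs to at most one type.

Cell-type over-representation tests up- and down-regulated DEGs separately
(upper-tail hypergeometric per type and direction) under Bonferroni control
across types: with 13 types the significance threshold is 0.05/13 ~ 0.00385,
i.e. -log10 ~ 2.41. The distribution-shift test collects the signed t-values
(sign(log2FC) * sqrt(F), 1-df Pain contrast) of all markers of a type and
compares their mean to zero with a one-sample t-test, Bonferroni-corrected
over the types tested; +/-2 is the conventional per-gene significance line
for the accompanying distribution curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import ReferenceMatrix, ValidationError
from .enrichment import OraResult, hypergeom_upper


@dataclass
class ShiftResult:
    """One cell type's signed-t distribution-shift test."""

    cell_type: str
    gene_count: int
    mean_t: float
    sd_t: float
    shift_stat: float
    df: int
    p: float
    bonferroni_p: float
    direction: str  # down / up / none


class MarkerSelector(BaseEstimator):
    """Derive cell-type marker sets from a labeled reference.

    Parameters
    ----------
    threshold : float
        Minimum specificity share (default 0.6).
    min_cells : int
        Minimum cells per type in the reference.
    min_mean : float
        Minimum depth-normalized mean expression in the assigned type.
    depth_scale : float
        Per-cell normalization target (counts per 10,000 by default).

    Attributes (after :meth:`fit`)
    ------------------------------
    markers_ : DataFrame (gene, cell_type, specificity, mean_in_type) for
        assigned genes only.
    marker_sets_ : dict cell type -> frozenset of marker genes.
    specificity_ : Series of specificity shares for all genes.
    cell_types_ : list of types present in the reference.
    """

    def __init__(self, threshold: float = 0.6, min_cells: int = 10,
                 min_mean: float = 0.0, depth_scale: float = 1e4):
        self.threshold = threshold
        self.min_cells = min_cells
        self.min_mean = min_mean
        self.depth_scale = depth_scale

    def fit(self, reference: ReferenceMatrix) -> "MarkerSelector":
        labels = reference.cell_labels
        sizes = labels.value_counts()
        small = sizes[sizes < self.min_cells]
        if not small.empty:
            raise ValidationError(
                f"cell type(s) below min_cells={self.min_cells}: "
                f"{small.index.tolist()}"
            )
        mat = reference.counts.to_numpy(dtype=float)
        depth = mat.sum(axis=0)
        if (depth <= 0).any():
            raise ValidationError("reference contains cells with zero total counts")
        norm = mat / depth * self.depth_scale
        types = reference.cell_types
        type_means = np.column_stack(
            [norm[:, (labels == ct).to_numpy()].mean(axis=1) for ct in types]
        )
        total = type_means.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(total[:, None] > 0, type_means / total[:, None], 0.0)
        best = share.argmax(axis=1)
        s = share[np.arange(share.shape[0]), best]
        # a tie in the argmax leaves the gene unassigned
        tie = (share == s[:, None]).sum(axis=1) > 1
        mean_in_type = type_means[np.arange(share.shape[0]), best]
        assigned = (s >= self.threshold) & (mean_in_type > self.min_mean) & ~tie
        genes = reference.counts.index
        self.specificity_ = pd.Series(s, index=genes, name="specificity")
        self.markers_ = pd.DataFrame({
            "cell_type": [types[b] for b in best[assigned]],
            "specificity": s[assigned],
            "mean_in_type": mean_in_type[assigned],
        }, index=genes[assigned])
        self.marker_sets_ = {
            ct: frozenset(self.markers_.index[self.markers_["cell_type"] == ct])
            for ct in types
        }
        self.cell_types_ = list(types)
        return self

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types_)


def derive_markers(reference: ReferenceMatrix, threshold: float = 0.6,
                   min_cells: int = 10, min_mean: float = 0.0) -> MarkerSelector:
    """Fit a MarkerSelector on a labeled reference (thin wrapper)."""
    return MarkerSelector(threshold=threshold, min_cells=min_cells,
                          min_mean=min_mean).fit(reference)


def celltype_ora(degs_up, degs_down, universe, reference: MarkerSelector,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Direction-split cell-type over-representation with Bonferroni control.

    For every cell type and each direction, an upper-tail hypergeometric test
    of the overlap between the direction's DEGs and the type's markers inside
    the universe. adjusted_p = min(1, p * n_types tested); the Bonferroni
    significance threshold alpha / n_types is reported alongside.
    """
    degs_up, degs_down, universe = set(degs_up), set(degs_down), set(universe)
    if degs_up & degs_down:
        raise ValidationError("up and down DEG lists overlap")
    for name, s in (("degs_up", degs_up), ("degs_down", degs_down)):
        stray = s - universe
        if stray:
            raise ValidationError(f"{name} gene(s) not in universe: {sorted(stray)[:5]}")
    N = len(universe)
    rows = []
    tested_types = []
    for ct in reference.cell_types_:
        markers = reference.marker_sets_[ct] & universe
        if not markers:
            warnings.warn(f"cell type {ct!r} has no markers in the universe; skipped")
            continue
        tested_types.append(ct)
        for direction, query in (("up", degs_up), ("down", degs_down)):
            k = len(markers & query)
            rows.append({
                "cell_type": ct, "direction": direction, "k": k,
                "K": len(markers), "n": len(query), "N": N,
                "p": hypergeom_upper(k, N, len(markers), len(query)),
            })
    df = pd.DataFrame(rows, columns=["cell_type", "direction", "k", "K", "n", "N", "p"])
    n_types = len(tested_types)
    if n_types:
        df["adjusted_p"] = np.minimum(1.0, df["p"] * n_types)
        df["bonferroni_threshold"] = alpha / n_types
        df["significant"] = df["p"] < alpha / n_types
    return df


def bonferroni_threshold(n_cell_types: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold under Bonferroni control."""
    return alpha / n_cell_types


def t_shift_test(reference: MarkerSelector, pain: pd.DataFrame,
                 types=None, min_markers: int = 3,
                 hist_bins: int = 20) -> list[ShiftResult]:
    """Test whether each cell type's signed-t distribution is shifted from 0.

    Collects t_signed of all the type's markers present in the Pain contrast
    and runs a two-sided one-sample t-test of the mean against zero, with
    Bonferroni correction over the types tested. Types with fewer than
    ``min_markers`` scored markers are skipped with a warning; a zero-variance
    marker set falls back to an exact sign test.
    """
    if types is None:
        types = reference.cell_types_
    collected = []
    for ct in types:
        t_vals = pain.loc[pain.index.intersection(reference.marker_sets_[ct]), "t_signed"]
        t_vals = t_vals.dropna()
        if len(t_vals) < min_markers:
            warnings.warn(f"cell type {ct!r}: fewer than {min_markers} markers "
                          "with contrast results; skipped")
            continue
        collected.append((ct, t_vals.to_numpy()))
    n_tested = len(collected)
    results = []
    for ct, t in collected:
        mean, sd = float(t.mean()), float(t.std(ddof=1))
        df = len(t) - 1
        if sd == 0.0:
            # all t identical: exact two-sided sign test on t != 0
            n_nonzero = int(np.sum(t != 0))
            p = float(min(1.0, 2.0 * 0.5**n_nonzero)) if n_nonzero else 1.0
            stat = np.inf * np.sign(mean) if mean != 0 else 0.0
        else:
            stat, p = stats.ttest_1samp(t, 0.0)
            stat, p = float(stat), float(p)
        bonf = min(1.0, p * n_tested)
        direction = "none"
        if bonf < 0.05 and mean != 0:
            direction = "down" if mean < 0 else "up"
        results.append(ShiftResult(ct, len(t), mean, sd, stat, df, p, bonf, direction))
    return results


def shift_to_frame(results: list[ShiftResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results],
                        columns=["cell_type", "gene_count", "mean_t", "sd_t",
                                 "shift_stat", "df", "p", "bonferroni_p", "direction"])


def t_histograms(reference: MarkerSelector, pain: pd.DataFrame, types,
                 bins: int = 20, t_range: tuple = (-6.0, 6.0)) -> pd.DataFrame:
    """Histogram bins of marker signed-t values per type, for plotting with
    reference lines at t = +/-2."""
    edges = np.linspace(*t_range, bins + 1)
    rows = []
    for ct in types:
        t = pain.loc[pain.index.intersection(reference.marker_sets_[ct]), "t_signed"]
        hist, _ = np.histogram(np.clip(t, *t_range), bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], hist):
            rows.append({"cell_type": ct, "bin_lo": lo, "bin_hi": hi, "count": int(c)})
    return pd.DataFrame(rows)


def common_deg_celltype_check(common_degs, universe, reference: MarkerSelector,
                              pain_a: pd.DataFrame, pain_b: pd.DataFrame):
    """Cell-type over-representation of an inter-region common DEG list,
    plus per-gene direction concordance between the two regions.

    Returns (ora DataFrame as in celltype_ora over the common list,
    concordance DataFrame: gene, cell_type, log2fc in each region, same_sign).
    """
    common = set(common_degs)
    if not common:
        return (pd.DataFrame(columns=["cell_type", "direction", "k", "K", "n",
                                      "N", "p", "adjusted_p",
                                      "bonferroni_threshold", "significant"]),
                pd.DataFrame(columns=["gene", "cell_type", "log2fc_a",
                                      "log2fc_b", "same_sign"]))
    stray = common - set(universe)
    if stray:
        raise ValidationError(f"common DEG(s) not in universe: {sorted(stray)[:5]}")
    for name, contrast in (("pain_a", pain_a), ("pain_b", pain_b)):
        missing = common - set(contrast.index)
        if missing:
            raise ValidationError(f"gene(s) missing from {name}: {sorted(missing)[:5]}")
    N = len(set(universe))
    rows = []
    tested = 0
    for ct in reference.cell_types_:
        markers = reference.marker_sets_[ct] & set(universe)
        if not markers:
            continue
        tested += 1
        k = len(markers & common)
        rows.append({"cell_type": ct, "direction": "any", "k": k, "K": len(markers),
                     "n": len(common), "N": N,
                     "p": hypergeom_upper(k, N, len(markers), len(common))})
    ora_df = pd.DataFrame(rows)
    if tested:
        ora_df["adjusted_p"] = np.minimum(1.0, ora_df["p"] * tested)
        ora_df["bonferroni_threshold"] = 0.05 / tested
        ora_df["significant"] = ora_df["p"] < 0.05 / tested
    marker_of = {}
    for ct, genes in reference.marker_sets_.items():
        for g in genes:
            marker_of[g] = ct
    conc_rows = []
    for g in sorted(common):
        a, b = float(pain_a.loc[g, "log2fc"]), float(pain_b.loc[g, "log2fc"])
        conc_rows.append({"gene": g, "cell_type": marker_of.get(g, ""),
                          "log2fc_a": a, "log2fc_b": b,
                          "same_sign": bool(np.sign(a) == np.sign(b) and a != 0)})
    return ora_df, pd.DataFrame(conc_rows)
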