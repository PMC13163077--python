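"""Two-factor negative-binomial differential expression.

The model per gene g and sample s is

    log mu_gs = offset_s + x_s' beta_g,     y_gs ~ NB(mu_gs, phi_g)

with var = mu + phi mu^2 and offsets from TMM-normalized library sizes. The
design spans the four condition x side group means (Sham.Right, Sham.Left,
SNL.Right, SNL.Left); every tested contrast is a 1-df linear combination of
those means:

    pain_main          0.5 (SNL.L + SNL.R) - 0.5 (Sham.L + Sham.R)
    side_main          0.5 (Sham.L + SNL.L) - 0.5 (Sham.R + SNL.R)
    interaction        (SNL.L - Sham.L) - (SNL.R - Sham.R)
    pain_within_left   SNL.L - Sham.L
    pain_within_right  SNL.R - Sham.R

Fitting is iteratively reweighted least squares, vectorized across genes.
Per-gene dispersion is estimated by maximizing the Cox-Reid adjusted profile
likelihood on a log grid with quadratic interpolation, then shrunk toward a
10-bin abundance trend with prior weight equivalent to 10 residual df. Each
contrast is tested with a quasi-likelihood F statistic: the 1-df deviance
(likelihood-ratio) statistic divided by a gene-wise quasi-dispersion
(residual deviance / residual df, shrunk toward its abundance trend with
prior df 10), referred to F(1, residual df + prior df). The signed t-value
is sign(log2FC) * sqrt(F). Genes with nominal p < 0.05 are flagged as DEGs;
Benjamini-Hochberg FDR is reported alongside but never used for gating.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, SampleDesign, ValidationError
from .normalization import TMMNormalizer

CONTRASTS = ("pain_main", "side_main", "interaction",
             "pain_within_left", "pain_within_right")

_LN2 = math.log(2.0)
_MU_FLOOR = 1e-8
_PRIOR_DF = 10.0
_N_TREND_BINS = 10


# ---------------------------------------------------------------------------
# expression filter

def filter_by_expression(counts: CountMatrix, min_count: int = 1,
                         min_fraction: float = 0.40) -> CountMatrix:
    """Drop genes expressed (count >= min_count) in fewer than
    ceil(min_fraction * n_samples) samples. Gene order is preserved."""
    n_req = math.ceil(min_fraction * counts.n_samples)
    n_ok = (counts.values() >= min_count).sum(axis=1)
    keep = n_ok >= n_req
    if not keep.any():
        raise ValidationError(
            "expression filter removed every gene; review min_count/min_fraction"
        )
    return CountMatrix(counts.counts.loc[keep])


# ---------------------------------------------------------------------------
# vectorized NB IRLS

def _nb_irls(Y, X, offsets, phi, beta0=None, tol=1e-8, max_iter=50):
    """Fit NB log-linear models for all genes at once.

    Y: (G, S) counts; X: (S, P); offsets: (S,); phi: scalar or (G,).
    Returns beta (G, P), mu (G, S), converged (G,) bool.
    """
    G, S = Y.shape
    P = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, float).reshape(-1, 1), (G, 1))
    if beta0 is None:
        # start from per-group log means via least squares on log(y + 0.5)
        z0 = np.log(Y + 0.5) - offsets[None, :]
        beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T
    else:
        beta = beta0.copy()
    converged = np.zeros(G, dtype=bool)
    dev = _nb_deviance(Y, _mu_of(beta, X, offsets), phi)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        b = beta[active]
        y = Y[active]
        ph = phi[active]
        eta = offsets[None, :] + b @ X.T
        mu = np.maximum(np.exp(eta), _MU_FLOOR)
        W = mu / (1.0 + ph * mu)                       # (g, S)
        z = (eta - offsets[None, :]) + (y - mu) / mu   # working response
        XtWX = np.einsum("sp,gs,sq->gpq", X, W, X)
        XtWz = np.einsum("sp,gs,gs->gp", X, W, z)
        XtWX += 1e-10 * np.eye(P)[None, :, :]          # guard vs empty groups
        b_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        b_new = np.clip(b_new, -40.0, 40.0)
        mu_new = _mu_of(b_new, X, offsets)
        dev_new = _nb_deviance(y, mu_new, ph)
        # step-halve where deviance increased
        worse = dev_new > dev[active] + 1e-9
        for _h in range(8):
            if not worse.any():
                break
            b_new[worse] = 0.5 * (b_new[worse] + b[worse])
            mu_w = _mu_of(b_new[worse], X, offsets)
            dev_new[worse] = _nb_deviance(y[worse], mu_w, ph[worse])
            worse = dev_new > dev[active] + 1e-9
        rel = np.abs(dev_new - dev[active]) / (np.abs(dev[active]) + 1.0)
        beta[active] = b_new
        newly = rel < tol
        idx = np.flatnonzero(active)
        converged[idx[newly]] = True
        dev[active] = dev_new
    mu = _mu_of(beta, X, offsets)
    return beta, mu, converged


def _mu_of(beta, X, offsets):
    return np.maximum(np.exp(offsets[None, :] + beta @ X.T), _MU_FLOOR)


def _nb_deviance(Y, mu, phi):
    """Unit NB deviance summed over samples; phi (G,1) broadcastable."""
    Y = np.asarray(Y, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(Y > 0, Y * np.log(Y / mu), 0.0)
        r = 1.0 / np.maximum(phi, 1e-12)
        term2 = (Y + r) * np.log((Y + r) / (mu + r))
    return 2.0 * np.sum(term1 - term2, axis=-1)


def _nb_loglik(Y, mu, phi):
    r = 1.0 / np.maximum(phi, 1e-12)
    return np.sum(
        gammaln(Y + r) - gammaln(r) - gammaln(Y + 1.0)
        + r * np.log(r / (r + mu)) + Y * np.log(mu / (r + mu)),
        axis=-1,
    )


def _cox_reid_adjustment(X, mu, phi):
    """0.5 * logdet(X'WX) per gene."""
    W = mu / (1.0 + phi * mu)
    XtWX = np.einsum("sp,gs,sq->gpq", X, W, X)
    XtWX += 1e-10 * np.eye(X.shape[1])[None, :, :]
    sign, logdet = np.linalg.slogdet(XtWX)
    return 0.5 * logdet


# ---------------------------------------------------------------------------
# trend helpers

def _abundance_trend(abundance, values, n_bins=_N_TREND_BINS):
    """Bin genes by abundance, average `values` per bin, linearly interpolate."""
    order = np.argsort(abundance, kind="stable")
    G = abundance.size
    n_bins = max(1, min(n_bins, G))
    splits = np.array_split(order, n_bins)
    centers = np.array([abundance[s].mean() for s in splits])
    means = np.array([values[s].mean() for s in splits])
    if n_bins == 1:
        return np.full(G, means[0])
    return np.interp(abundance, centers, means)


# ---------------------------------------------------------------------------
# the estimator

class NBTwoFactorDE(BaseEstimator):
    """Negative-binomial two-factor (condition x side) DE model for one region.

    Parameters
    ----------
    prior_df : float
        Prior weight (in residual df) for shrinking both the NB dispersion
        and the quasi-dispersion toward their abundance trends.
    dispersion_grid : tuple (lo, hi, n)
        Log-spaced grid on which the Cox-Reid adjusted profile likelihood is
        maximized per gene, refined by quadratic interpolation.
    deg_p : float
        Nominal p-value threshold defining a DEG.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : DataFrame (genes x 4) of fitted group-mean log expressions.
    dispersion_ : Series of shrunk per-gene NB dispersions.
    raw_dispersion_ : Series of unshrunk APL-maximizing dispersions.
    quasi_dispersion_ : Series of shrunk quasi-dispersions.
    deviance_ : Series of full-model residual deviances.
    converged_ : boolean Series per gene.
    residual_df_, denominator_df_ : scalars.
    """

    GROUPS = ("Sham.Right", "Sham.Left", "SNL.Right", "SNL.Left")

    def __init__(self, prior_df: float = _PRIOR_DF,
                 dispersion_grid: tuple = (1e-4, 5.0, 12),
                 deg_p: float = 0.05):
        self.prior_df = prior_df
        self.dispersion_grid = dispersion_grid
        self.deg_p = deg_p

    # -- design ------------------------------------------------------------
    def _design_matrix(self, design: SampleDesign, sample_ids):
        tab = design.table.set_index("sample_id").loc[list(sample_ids)]
        cond_ref = design.condition_reference
        side_ref = design.side_reference
        cond_alt = [l for l in tab["condition"].unique() if l != cond_ref][0]
        side_alt = [l for l in tab["side"].unique() if l != side_ref][0]
        # canonical group order: (ref cond, ref side), (ref, alt), (alt, ref), (alt, alt)
        groups = [(cond_ref, side_ref), (cond_ref, side_alt),
                  (cond_alt, side_ref), (cond_alt, side_alt)]
        X = np.zeros((len(tab), 4))
        for j, (c, s) in enumerate(groups):
            X[:, j] = ((tab["condition"] == c) & (tab["side"] == s)).to_numpy(float)
        if (X.sum(axis=0) == 0).any():
            raise ValidationError("a condition x side cell has no samples")
        names = [f"{c}.{s}" for c, s in groups]
        return X, names

    def _contrast_vector(self, contrast: str) -> np.ndarray:
        # columns: [ref.ref, ref.alt(Left), alt(SNL).ref(Right), alt.alt(Left)]
        vectors = {
            "pain_main": np.array([-0.5, -0.5, 0.5, 0.5]),
            "side_main": np.array([-0.5, 0.5, -0.5, 0.5]),
            "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
            "pain_within_left": np.array([0.0, -1.0, 0.0, 1.0]),
            "pain_within_right": np.array([-1.0, 0.0, 1.0, 0.0]),
        }
        if contrast not in vectors:
            raise ValueError(f"unknown contrast {contrast!r}; one of {CONTRASTS}")
        return vectors[contrast]

    # -- fitting -----------------------------------------------------------
    def fit(self, counts: CountMatrix, design: SampleDesign,
            norm: TMMNormalizer | None = None) -> "NBTwoFactorDE":
        design.match(counts)
        design.check_cells(min_per_cell=2)
        if norm is None:
            norm = TMMNormalizer().fit(counts)
        sample_ids = counts.sample_ids
        Y = counts.values().astype(float)
        offsets = norm.offsets_.loc[sample_ids].to_numpy()
        X, group_names = self._design_matrix(design, sample_ids)
        G, S = Y.shape
        resid_df = S - X.shape[1]
        if resid_df <= 0:
            raise ValidationError("no residual degrees of freedom")

        lo, hi, n_grid = self.dispersion_grid
        grid = np.exp(np.linspace(np.log(lo), np.log(hi), int(n_grid)))
        apl = np.empty((G, grid.size))
        beta_at = None
        for k, ph in enumerate(grid):
            beta_at, mu, _ = _nb_irls(Y, X, offsets, ph, beta0=beta_at)
            apl[:, k] = _nb_loglik(Y, mu, ph) - _cox_reid_adjustment(X, mu, ph)
        raw_disp = _interp_argmax(np.log(grid), apl)

        abundance = np.log2(Y.mean(axis=1) + 0.5)
        trend = np.maximum(_abundance_trend(abundance, raw_disp), 1e-6)
        disp = (resid_df * raw_disp + self.prior_df * trend) / (resid_df + self.prior_df)

        beta, mu, converged = _nb_irls(Y, X, offsets, disp)
        deviance = _nb_deviance(Y, mu, disp.reshape(-1, 1))

        s2 = deviance / resid_df
        s2_trend = np.maximum(_abundance_trend(abundance, s2), 1e-8)
        s2_shrunk = (resid_df * s2 + self.prior_df * s2_trend) / (resid_df + self.prior_df)

        self.coef_ = pd.DataFrame(beta, index=counts.gene_ids, columns=group_names)
        self.dispersion_ = pd.Series(disp, index=counts.gene_ids, name="dispersion")
        self.raw_dispersion_ = pd.Series(raw_disp, index=counts.gene_ids)
        self.deviance_ = pd.Series(deviance, index=counts.gene_ids, name="deviance")
        self.quasi_dispersion_ = pd.Series(s2_shrunk, index=counts.gene_ids)
        self.converged_ = pd.Series(converged, index=counts.gene_ids, name="converged")
        self.residual_df_ = resid_df
        self.denominator_df_ = resid_df + self.prior_df
        self._Y = Y
        self._X = X
        self._offsets = offsets
        self._gene_ids = counts.gene_ids
        self.group_names_ = group_names
        return self

    @property
    def factorial_coef_(self) -> pd.DataFrame:
        """Intercept / condition / side / interaction coding (natural log)."""
        b = self.coef_.to_numpy()
        out = np.column_stack([
            b[:, 0],                       # intercept: ref condition, ref side
            b[:, 2] - b[:, 0],             # condition effect at reference side
            b[:, 1] - b[:, 0],             # side effect under reference condition
            (b[:, 3] - b[:, 1]) - (b[:, 2] - b[:, 0]),
        ])
        return pd.DataFrame(
            out, index=self.coef_.index,
            columns=["intercept", "condition", "side", "condition_x_side"],
        )

    # -- testing -----------------------------------------------------------
    def contrast(self, contrast: str, genes=None) -> pd.DataFrame:
        """Test one 1-df contrast for all (or selected) genes.

        Returns a DataFrame indexed by gene with columns log2fc, F, p, fdr,
        t_signed, is_deg, df_num, df_den.
        """
        c = self._contrast_vector(contrast)
        if genes is None:
            genes = self._gene_ids
            idx = np.arange(len(self._gene_ids))
        else:
            pos = {g: i for i, g in enumerate(self._gene_ids)}
            missing = [g for g in genes if g not in pos]
            if missing:
                raise ValidationError(f"genes not in fit: {missing[:5]}")
            idx = np.array([pos[g] for g in genes])
        Y = self._Y[idx]
        disp = self.dispersion_.to_numpy()[idx]
        s2 = self.quasi_dispersion_.to_numpy()[idx]
        beta_full = self.coef_.to_numpy()[idx]
        dev_full = self.deviance_.to_numpy()[idx]

        # reduced design: restrict group means to the null space of c
        B = linalg.null_space(c[None, :])           # (4, 3)
        X_red = self._X @ B
        _, mu_red, _ = _nb_irls(Y, X_red, self._offsets, disp)
        dev_red = _nb_deviance(Y, mu_red, disp.reshape(-1, 1))

        lr = np.maximum(dev_red - dev_full, 0.0)
        F = lr / s2
        p = stats.f.sf(F, 1, self.denominator_df_)
        log2fc = (beta_full @ c) / _LN2
        t_signed = np.sign(log2fc) * np.sqrt(F)
        fdr = bh_adjust(p)
        return pd.DataFrame(
            {"log2fc": log2fc, "F": F, "p": p, "fdr": fdr,
             "t_signed": t_signed, "is_deg": p < self.deg_p,
             "df_num": 1, "df_den": self.denominator_df_},
            index=list(genes),
        )


def _interp_argmax(logx, scores):
    """Per-row argmax on a grid with quadratic refinement; returns exp scale."""
    G, K = scores.shape
    k = scores.argmax(axis=1)
    out = logx[k].astype(float)
    inner = (k > 0) & (k < K - 1)
    if inner.any():
        i = k[inner]
        rows = np.flatnonzero(inner)
        y0, y1, y2 = scores[rows, i - 1], scores[rows, i], scores[rows, i + 1]
        denom = y0 - 2 * y1 + y2
        step = logx[1] - logx[0]
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        out[inner] = logx[i] + np.clip(shift, -1.0, 1.0) * step
    return np.exp(out)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# spec-surface wrappers and downstream operations

def fit_two_factor_nb(counts: CountMatrix, design: SampleDesign,
                      norm: TMMNormalizer) -> NBTwoFactorDE:
    """Fit the per-gene two-factor NB model (wrapper over NBTwoFactorDE)."""
    return NBTwoFactorDE().fit(counts, design, norm)


def test_contrast(fit: NBTwoFactorDE, contrast: str) -> pd.DataFrame:
    return fit.contrast(contrast)


def interaction_followup(fit: NBTwoFactorDE, interaction: pd.DataFrame,
                         interaction_p: float = 0.05):
    """Within-hemisphere Pain contrasts for interaction DEGs only.

    BH is recomputed within each restricted gene list. Returns
    (left, right) DataFrames; empty frames (with a warning-level log) when no
    gene passes the interaction threshold.
    """
    degs = interaction.index[interaction["p"] < interaction_p].tolist()
    if not degs:
        cols = ["log2fc", "F", "p", "fdr", "t_signed", "is_deg", "df_num", "df_den"]
        empty = pd.DataFrame(columns=cols)
        return empty, empty.copy()
    left = fit.contrast("pain_within_left", genes=degs)
    right = fit.contrast("pain_within_right", genes=degs)
    return left, right


def classify_opposite_direction(left: pd.DataFrame, right: pd.DataFrame,
                                deg_p: float = 0.05) -> pd.DataFrame:
    """Classify interaction DEGs by within-hemisphere Pain behavior.

    opposite_significant: both sides p < deg_p with opposite log2FC signs;
    opposite_tendency: opposite signs, exactly one side significant;
    same_direction: otherwise.
    """
    if list(left.index) != list(right.index):
        raise ValidationError("left/right contrast gene lists differ")
    if left.empty:
        return pd.DataFrame(columns=["left_log2fc", "left_p", "right_log2fc",
                                     "right_p", "classification"])
    opposite = np.sign(left["log2fc"].to_numpy()) != np.sign(right["log2fc"].to_numpy())
    both_zero = (left["log2fc"].to_numpy() == 0) & (right["log2fc"].to_numpy() == 0)
    opposite &= ~both_zero
    sig_l = left["p"].to_numpy() < deg_p
    sig_r = right["p"].to_numpy() < deg_p
    cls = np.where(opposite & sig_l & sig_r, "opposite_significant",
                   np.where(opposite & (sig_l ^ sig_r), "opposite_tendency",
                            "same_direction"))
    return pd.DataFrame(
        {"left_log2fc": left["log2fc"], "left_p": left["p"],
         "right_log2fc": right["log2fc"], "right_p": right["p"],
         "classification": cls},
        index=left.index,
    )


def pca_qc(counts: CountMatrix, norm: TMMNormalizer, n_components: int = 2):
    """Sample PCA on gene-centered log2(CPM + 0.5) for outlier inspection.

    Returns (scores DataFrame samples x PCs, variance-fraction array).
    """
    if counts.n_samples < 3:
        raise ValidationError("PCA QC needs >= 3 samples")
    if n_components > counts.n_samples:
        raise ValidationError("more components requested than samples")
    logcpm = norm.transform(counts, log=True).to_numpy()
    centered = (logcpm - logcpm.mean(axis=1, keepdims=True)).T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(centered)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(scores, index=counts.sample_ids, columns=cols),
            pca.explained_variance_ratio_)


def overlap_test(degs_a, degs_b, background):
    """Upper-tail hypergeometric test of the overlap between two DEG lists.

    p = P(X >= |A & B|) with X ~ Hypergeometric(N=|background|, K=|A|, n=|B|).
    Direction is ignored. Both lists must lie inside the background.
    """
    A, B, bg = set(degs_a), set(degs_b), set(background)
    for name, s in (("degs_a", A), ("degs_b", B)):
        out = s - bg
        if out:
            raise ValidationError(f"{name} gene(s) not in background: {sorted(out)[:5]}")
    k = len(A & B)
    p = float(stats.hypergeom.sf(k - 1, len(bg), len(A), len(B)))
    return k, min(p, 1.0)
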