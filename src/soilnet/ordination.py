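"""Beta diversity, unconstrained and constrained ordination, PERMANOVA,
and taxa-environment correlation screens.

Bray-Curtis / PCoA go through scipy and scikit-bio. PERMANOVA is computed
here directly from the distance matrix so permutations are seeded and
vectorisable; redundancy analysis (RDA) is the classical least-squares
projection of the (optionally Hellinger-transformed) community matrix onto
standardised covariates followed by a PCA of the fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skb_pcoa
from statsmodels.stats.multitest import multipletests

from .containers import OtuTable, ValidationError


def bray_curtis(otu: OtuTable) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y).

    Pairs of all-zero samples have undefined distance and are returned as
    NaN with the offending samples listed in ``attrs['zero_samples']``.
    """
    if otu.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    x = otu.counts.to_numpy(dtype=float)
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, np.nan)
    np.fill_diagonal(d, 0.0)
    result = pd.DataFrame(d, index=otu.counts.index, columns=otu.counts.index)
    result.attrs["zero_samples"] = list(otu.depths.index[otu.depths == 0])
    return result


@dataclass
class OrdinationResult:
    """Axis coordinates plus eigenvalue bookkeeping.

    ``proportion_explained`` is per retained axis, relative to total
    variance. For RDA, ``constrained_proportion`` is the share of total
    community variance captured by the environmental fit, and
    ``biplot_scores`` are covariate loadings on the constrained axes.
    """

    coordinates: pd.DataFrame
    eigenvalues: pd.Series
    proportion_explained: pd.Series
    method: str
    constrained_proportion: float | None = None
    biplot_scores: pd.DataFrame | None = None
    negative_eigenvalue_mass: float = 0.0


def pcoa(dist: pd.DataFrame) -> OrdinationResult:
    """Principal coordinates analysis of a square symmetric distance matrix."""
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValidationError("distance matrix must be symmetric")
    if np.isnan(d).any():
        raise ValidationError("distance matrix contains NaN entries")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = skb_pcoa(DistanceMatrix(d, ids=list(dist.index)), method="eigh",
                       warn_neg_eigval=False)
    eig = res.eigvals
    neg_mass = float(-eig[eig < 0].sum() / np.abs(eig).sum()) if len(eig) else 0.0
    return OrdinationResult(
        coordinates=res.samples,
        eigenvalues=eig,
        proportion_explained=res.proportion_explained,
        method="pcoa",
        negative_eigenvalue_mass=neg_mass,
    )


def _permanova_ss(d2: np.ndarray, labels: np.ndarray,
                  group_codes: np.ndarray) -> float:
    """Within-group sum of squares from squared distances."""
    ssw = 0.0
    for g in group_codes:
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ssw += sub.sum() / (2.0 * len(idx))
    return ssw


def permanova(dist: pd.DataFrame, group: pd.Series, n_perm: int = 999,
              seed: int | np.random.Generator = 0) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)); the p-value is
    (#{F_perm >= F_obs} + 1) / (n_perm + 1) under free label permutation.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    group = group.loc[dist.index].astype(str)
    labels, codes = pd.factorize(group)
    n, g = len(labels), len(codes)
    if g < 2 or pd.Series(labels).value_counts().min() < 2:
        raise ValidationError("need >= 2 groups with >= 2 samples each")
    d2 = dist.to_numpy(dtype=float) ** 2
    sst = d2.sum() / (2.0 * n)
    code_ids = np.arange(g)

    def pseudo_f(lab: np.ndarray) -> float:
        ssw = _permanova_ss(d2, lab, code_ids)
        ssb = sst - ssw
        if ssw <= 0:
            return np.inf if ssb > 0 else 0.0
        return (ssb / (g - 1)) / (ssw / (n - g))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if pseudo_f(lab) >= f_obs:
            exceed += 1
    return {"pseudo_F": float(f_obs), "p": (exceed + 1) / (n_perm + 1),
            "n_permutations": n_perm, "n_groups": g, "n_samples": n}


def hellinger(counts: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: square root of relative abundance."""
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = counts.to_numpy(dtype=float) / totals[:, None]
    return pd.DataFrame(np.sqrt(rel), index=counts.index, columns=counts.columns)


def rda(community: pd.DataFrame, env: pd.DataFrame,
        transform: str = "hellinger", n_axes: int | None = None,
        collinearity_tol: float = 1e-8) -> OrdinationResult:
    """Redundancy analysis: community variance explained by covariates.

    The response is optionally Hellinger-transformed, then column-centred;
    covariates are standardised. Constrained axes are the principal axes of
    the fitted values of the multivariate regression; the proportion per
    axis is its eigenvalue over the total response variance.
    """
    env = env.loc[community.index]
    n, p = env.shape
    if n <= p:
        raise ValidationError(
            f"need more samples ({n}) than covariates ({p})")
    y = hellinger(community) if transform == "hellinger" else community.astype(float)
    yc = y - y.mean(axis=0)
    sd = env.std(ddof=1)
    if (sd == 0).any():
        raise ValidationError(
            f"constant covariate(s): {list(sd.index[sd == 0])}")
    x = ((env - env.mean()) / sd).to_numpy()
    # collinearity check via QR: tiny diagonal names the dependent column
    _, r_mat = np.linalg.qr(x)
    diag = np.abs(np.diag(r_mat))
    bad = diag < collinearity_tol * max(diag.max(), 1.0)
    if bad.any():
        raise ValidationError(
            f"collinear covariate(s): {list(env.columns[bad])}")
    beta, *_ = np.linalg.lstsq(x, yc.to_numpy(), rcond=None)
    fitted = x @ beta
    total_ss = float((yc.to_numpy() ** 2).sum())
    if total_ss == 0:
        raise ValidationError("response matrix has zero variance")
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    rank = int((s > 1e-12 * max(s[0], 1.0)).sum()) if len(s) else 0
    k = rank if n_axes is None else min(n_axes, rank)
    axes = [f"RDA{i + 1}" for i in range(k)]
    coords = pd.DataFrame(u[:, :k] * s[:k], index=community.index, columns=axes)
    eig = pd.Series(s[:k] ** 2, index=axes)
    prop = eig / total_ss
    # covariate loadings: correlation of each covariate with each axis
    biplot = pd.DataFrame(index=env.columns, columns=axes, dtype=float)
    for j, ax in enumerate(axes):
        denom = np.linalg.norm(coords[ax]) or 1.0
        biplot[ax] = (x.T @ (coords[ax] / denom)) / np.sqrt(n - 1)
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eig,
        proportion_explained=prop,
        method="rda",
        constrained_proportion=float((fitted ** 2).sum() / total_ss),
        biplot_scores=biplot,
    )


def taxa_env_correlation(taxa: pd.DataFrame, env: pd.DataFrame,
                         method: str = "spearman",
                         adjust: str = "none") -> pd.DataFrame:
    """Correlation screen between taxa abundances and covariates.

    Returns a long table (taxon, covariate, r, p, p_adj, method). Constant
    columns yield NaN r flagged via the ``constant`` column. BH adjustment,
    when requested, runs across the whole matrix of tests.
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown method {method!r}")
    if adjust not in ("none", "BH"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    env = env.loc[taxa.index]
    if len(taxa) < 4:
        raise ValidationError("need at least 4 samples for a correlation screen")
    rows = []
    for taxon in taxa.columns:
        tx = taxa[taxon].to_numpy(dtype=float)
        for cov in env.columns:
            ev = env[cov].to_numpy(dtype=float)
            ok = np.isfinite(tx) & np.isfinite(ev)
            constant = tx[ok].std() == 0 or ev[ok].std() == 0 or ok.sum() < 4
            if constant:
                r, p = np.nan, np.nan
            elif method == "spearman":
                r, p = stats.spearmanr(tx[ok], ev[ok])
            else:
                r, p = stats.pearsonr(tx[ok], ev[ok])
            rows.append({"taxon": taxon, "covariate": cov, "r": r, "p": p,
                         "constant": constant})
    result = pd.DataFrame(rows)
    result["p_adj"] = result["p"]
    valid = result["p"].notna()
    if adjust == "BH" and valid.any():
        result.loc[valid, "p_adj"] = multipletests(
            result.loc[valid, "p"], method="fdr_bh")[1]
    result["method"] = method
    return result
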