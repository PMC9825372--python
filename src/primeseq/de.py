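r"""Negative-binomial differential expression for gene-level count matrices.

The model is the standard NB log-link GLM: counts for gene g in sample j
are NB with mean :math:`s_j \mu_{gj}` and gene-wise dispersion
:math:`\alpha_g` (variance :math:`\mu + \alpha\mu^2`), where :math:`s_j`
are median-of-ratios size factors.  Per-gene fits use iteratively
reweighted least squares, vectorized across genes sharing a design matrix.

Three tests are provided: a Wald z-test on a two-level contrast, a
likelihood-ratio test between nested term sets (e.g. full
``hemisphere + exercise + hemisphere:exercise`` against reduced models to
attribute genes to individual terms), and a per-gene two-way ANOVA on
log2(normalized count + 1) with sequential (type-I) F tests.

Dispersions are gene-wise method-of-moments estimates with a small floor
and no shrinkage toward a fitted trend; this keeps the estimator simple
and fully testable, at the price of noisier per-gene dispersion at very
small n (a documented deviation from shrinkage-based packages).

A gene is declared differentially expressed when |log2 fold change|
exceeds log2(1.3) ~ 0.3785 (a >30% change) and the raw test p-value is
below 0.05, both strictly; the adjusted p is reported alongside and can be
used for gating instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._design import build_design_matrix, parse_terms
from .io import CountMatrix

__all__ = [
    "DEFAULT_LFC_CUT",
    "DEFAULT_P_CUT",
    "DEResult",
    "DEGSets",
    "median_ratio_size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "nb_lrt",
    "lrt_term_attribution",
    "per_gene_two_way_anova",
    "adjust_bh",
    "call_degs",
]

DEFAULT_LFC_CUT = float(np.log2(1.3))  # ~0.3785: a >30% expression change
DEFAULT_P_CUT = 0.05
ALPHA_FLOOR = 1e-8
_LN2 = float(np.log(2.0))


@dataclass
class DEResult:
    """Per-gene differential-expression statistics.

    ``table`` columns: base_mean, log2fc, se, stat, p, padj (log2fc and se
    in log2 units).  Non-converged or all-zero genes carry NaN statistics
    and are excluded from the BH batch.
    """

    table: pd.DataFrame
    test: str
    contrast: str = ""

    def __post_init__(self) -> None:
        if self.test not in ("wald", "lrt", "anova"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass
class DEGSets:
    up: set[str]
    down: set[str]
    contrast: str
    lfc_cut: float
    p_cut: float
    use: str = "p"

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down DEG sets must be disjoint")


# ---------------------------------------------------------------------------
# normalization and dispersion
# ---------------------------------------------------------------------------


def median_ratio_size_factors(
    counts: CountMatrix | np.ndarray, pseudo_reference: bool = False
) -> np.ndarray:
    """Median-of-ratios size factors.

    The per-gene reference is the geometric mean across samples; each
    sample's factor is the median of its counts over that reference, taken
    over genes with no zero anywhere.  With ``pseudo_reference=True`` the
    geometric mean is computed over positive entries only and genes
    positive in at least half the samples are used, for matrices with no
    all-positive gene.
    """
    K = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    K = K.astype(float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(K > 0, np.log(K), np.nan)
        log_ref = np.nanmean(logs, axis=1)
        use = (K > 0).sum(axis=1) >= (K.shape[1] + 1) // 2
        with np.errstate(invalid="ignore"):
            log_ratios = logs[use] - log_ref[use, None]
        sf = np.exp(np.nanmedian(log_ratios, axis=0))
        if not np.all(np.isfinite(sf)) or (sf <= 0).any():
            raise ValueError("size factor estimation failed (non-positive factor)")
        return sf
    else:
        all_pos = (K > 0).all(axis=1)
        if not all_pos.any():
            raise ValueError(
                "no gene has positive counts in every sample; re-run with "
                "pseudo_reference=True to use a positive-part reference"
            )
        log_ref = np.where(all_pos, np.log(np.where(K > 0, K, 1.0)).mean(axis=1), np.nan)
        use = all_pos
    with np.errstate(divide="ignore"):
        log_ratios = np.log(K[use]) - log_ref[use, None]
    sf = np.exp(np.nanmedian(log_ratios, axis=0))
    if not np.all(np.isfinite(sf)) or (sf <= 0).any():
        raise ValueError("size factor estimation failed (non-positive factor)")
    return sf


def estimate_dispersions(
    counts: CountMatrix | np.ndarray,
    groups: np.ndarray | list,
    size_factors: np.ndarray,
    alpha_floor: float = ALPHA_FLOOR,
) -> np.ndarray:
    """Gene-wise method-of-moments dispersion on normalized counts.

    Group means are removed (pooled within-group variance, unbiased
    denominator N - G over groups with >=2 samples), then
    ``alpha = max(floor, (var - mean) / mean^2)``.  Underdispersed or
    constant genes land on the floor.
    """
    K = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    q = K / np.asarray(size_factors)[None, :]
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    ss = np.zeros(K.shape[0])
    dof = 0
    used_cols = 0
    for lab in labels:
        cols = groups == lab
        n = int(cols.sum())
        if n < 2:
            continue
        sub = q[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += n - 1
        used_cols += n
    if dof < 1:
        raise ValueError("dispersion estimation needs a group with >=2 samples")
    var = ss / dof
    mean = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / mean**2
    alpha = np.where(np.isfinite(alpha), alpha, alpha_floor)
    return np.maximum(alpha, alpha_floor)


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized IRLS over genes sharing a design matrix)
# ---------------------------------------------------------------------------


def _irls_nb(
    Y: np.ndarray,
    X: np.ndarray,
    alpha: np.ndarray,
    offset: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
):
    """Fit NB log-link GLMs for all genes at once.

    Returns (beta [G x P], cov [G x P x P], converged [G]).  ``offset`` is
    log size factor per sample.
    """
    G, N = Y.shape
    P = X.shape[1]
    # initialize from intercept-only means
    mean0 = np.maximum(Y.mean(axis=1), 0.1)
    beta = np.zeros((G, P))
    beta[:, 0] = np.log(mean0)
    alpha = np.asarray(alpha, dtype=float)[:, None]
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    XT = X.T
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        b = beta[idx]
        eta = b @ XT + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[idx] * mu)  # IRLS weights for NB2 log link
        z = (eta - offset[None, :]) + (Y[idx] - mu) / mu
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X)
        XtWz = np.einsum("np,gn,gn->gp", X, W, z)
        XtWX += np.eye(P)[None, :, :] * 1e-10
        try:
            new_b = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_b = np.stack(
                [np.linalg.lstsq(a, v, rcond=None)[0] for a, v in zip(XtWX, XtWz)]
            )
        delta = np.abs(new_b - b).max(axis=1)
        beta[idx] = new_b
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    # covariance at the final fit
    eta = beta @ XT + offset[None, :]
    eta = np.clip(eta, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, W, X)
    XtWX += np.eye(P)[None, :, :] * 1e-10
    cov = np.linalg.inv(XtWX)
    return beta, cov, converged


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB2 log likelihood (summed over samples)."""
    from scipy.special import gammaln

    alpha = np.asarray(alpha, dtype=float)[:, None]
    inv = 1.0 / alpha
    mu = np.maximum(mu, 1e-300)
    ll = (
        gammaln(Y + inv)
        - gammaln(inv)
        - gammaln(Y + 1.0)
        + Y * np.log(alpha * mu / (1.0 + alpha * mu))
        - inv * np.log1p(alpha * mu)
    )
    return ll.sum(axis=1)


def _parse_contrast(contrast: str) -> tuple[str, str, str]:
    parts = contrast.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"contrast must be 'factor:test_level:ref_level', got {contrast!r}"
        )
    return parts[0], parts[1], parts[2]


def nb_wald_test(
    counts: CountMatrix,
    contrast: str,
    size_factors: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
) -> DEResult:
    """Wald test of a two-level contrast, e.g. ``"exercise:ELE:SED"``.

    Samples at other levels of the factor are ignored.  The factor may also
    be ``"group"`` (the exercise_learning composite).  The statistic is
    beta / SE(beta) from the NB GLM fit; p is the two-sided normal tail.
    All-zero and non-converged genes get NaN statistics and are excluded
    from the BH batch.
    """
    factor, test_lv, ref_lv = _parse_contrast(contrast)
    design = counts.design_frame().reset_index()
    if factor == "group":
        design["group"] = [s.group for s in counts.samples]
    if factor not in design.columns:
        raise ValueError(f"unknown contrast factor {factor!r}")
    mask = design[factor].isin([test_lv, ref_lv]).to_numpy()
    if design.loc[mask, factor].nunique() != 2:
        raise ValueError(f"contrast {contrast!r}: both levels must be present")
    sub_ids = design.loc[mask, "sample_id"].tolist()
    sub = counts.subset_samples(sub_ids)
    if size_factors is None:
        sf = median_ratio_size_factors(sub)
    else:
        sf = np.asarray(size_factors)[mask]
    in_test = (design.loc[mask, factor] == test_lv).to_numpy(dtype=float)
    groups = np.where(in_test > 0, test_lv, ref_lv)
    if dispersions is None:
        disp = estimate_dispersions(sub, groups, sf)
    else:
        disp = np.asarray(dispersions)
    for lv, n in zip(*np.unique(groups, return_counts=True)):
        if n < 1:
            raise ValueError(f"level {lv} has no samples")
    Y = sub.counts.astype(float)
    X = np.column_stack([np.ones(Y.shape[1]), in_test])
    offset = np.log(sf)
    usable = Y.sum(axis=1) > 0
    beta = np.full((Y.shape[0], 2), np.nan)
    se = np.full(Y.shape[0], np.nan)
    conv = np.zeros(Y.shape[0], dtype=bool)
    if usable.any():
        b, cov, cv = _irls_nb(Y[usable], X, disp[usable], offset)
        beta[usable] = b
        se[usable] = np.sqrt(np.maximum(cov[:, 1, 1], 0.0))
        conv[usable] = cv
    valid = usable & conv & (se > 0)
    stat = np.where(valid, beta[:, 1] / se, np.nan)
    p = np.where(valid, 2.0 * stats.norm.sf(np.abs(stat)), np.nan)
    q = Y / sf[None, :]
    table = pd.DataFrame(
        {
            "base_mean": q.mean(axis=1),
            "log2fc": beta[:, 1] / _LN2,
            "se": se / _LN2,
            "stat": stat,
            "p": p,
            "padj": adjust_bh(p),
        },
        index=counts.gene_ids,
    )
    return DEResult(table=table, test="wald", contrast=contrast)


def nb_lrt(
    counts: CountMatrix,
    full_terms: list[str] | str,
    reduced_terms: list[str] | str,
    size_factors: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
) -> DEResult:
    """Likelihood-ratio test between nested NB GLMs.

    ``full_terms``/``reduced_terms`` are term lists or formula strings such
    as ``"hemisphere + exercise + hemisphere:exercise"``.  The statistic is
    2(l_full - l_reduced) against chi-square with df equal to the
    difference in parameter counts.  The reported log2fc is the full
    model's last non-intercept coefficient (descriptive only).
    """
    if isinstance(full_terms, str):
        full_terms = parse_terms(full_terms)
    if isinstance(reduced_terms, str):
        reduced_terms = parse_terms(reduced_terms)
    full_main = {t for term in full_terms for t in ([term] if ":" not in term else [])}
    if not set(reduced_terms) <= set(full_terms):
        raise ValueError(
            f"reduced terms {reduced_terms} must be a subset of full terms {full_terms}"
        )
    design = counts.design_frame().reset_index()
    Xf, names_f = build_design_matrix(design, full_terms)
    Xr, _ = build_design_matrix(design, reduced_terms)
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts)
    sf = np.asarray(size_factors)
    if dispersions is None:
        # pool over the finest grouping implied by the full model
        grp = design[sorted(full_main)].astype(str).agg("|".join, axis=1).to_numpy() \
            if full_main else np.zeros(len(design))
        dispersions = estimate_dispersions(counts, grp, sf)
    disp = np.asarray(dispersions)
    Y = counts.counts.astype(float)
    offset = np.log(sf)
    usable = Y.sum(axis=1) > 0
    G = Y.shape[0]
    stat = np.full(G, np.nan)
    lfc = np.full(G, np.nan)
    conv = np.zeros(G, dtype=bool)
    df = Xf.shape[1] - Xr.shape[1]
    if usable.any():
        bf, _, cf = _irls_nb(Y[usable], Xf, disp[usable], offset)
        br, _, cr = _irls_nb(Y[usable], Xr, disp[usable], offset)
        mu_f = np.exp(np.clip(bf @ Xf.T + offset, -30, 30))
        mu_r = np.exp(np.clip(br @ Xr.T + offset, -30, 30))
        ll_f = _nb_loglik(Y[usable], mu_f, disp[usable])
        ll_r = _nb_loglik(Y[usable], mu_r, disp[usable])
        stat[usable] = np.maximum(2.0 * (ll_f - ll_r), 0.0)
        lfc[usable] = bf[:, -1] / _LN2 if Xf.shape[1] > 1 else 0.0
        conv[usable] = cf & cr
    valid = usable & conv
    if df == 0:
        p = np.where(valid, 1.0, np.nan)
        stat = np.where(valid, 0.0, np.nan)
    else:
        p = np.where(valid, stats.chi2.sf(stat, df), np.nan)
    q = Y / sf[None, :]
    table = pd.DataFrame(
        {
            "base_mean": q.mean(axis=1),
            "log2fc": lfc,
            "se": np.nan,
            "stat": np.where(valid, stat, np.nan),
            "p": p,
            "padj": adjust_bh(p),
        },
        index=counts.gene_ids,
    )
    label = f"{' + '.join(full_terms)} vs {' + '.join(reduced_terms) or '1'}"
    return DEResult(table=table, test="lrt", contrast=label)


#: Reduced models used to attribute genes to individual terms of the
#: ``hemisphere + exercise + hemisphere:exercise`` design.
LRT_ATTRIBUTION_REDUCED = {
    "exercise": ["hemisphere", "hemisphere:exercise"],
    "hemisphere": ["exercise", "hemisphere:exercise"],
    "interaction": ["hemisphere", "exercise"],
}


def lrt_term_attribution(
    counts: CountMatrix,
    p_cut: float = 0.05,
    size_factors: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
) -> dict[str, DEResult]:
    """Run the full-vs-reduced LRTs attributing genes to exercise,
    hemisphere, or their interaction."""
    full = ["hemisphere", "exercise", "hemisphere:exercise"]
    out = {}
    for term, reduced in LRT_ATTRIBUTION_REDUCED.items():
        out[term] = nb_lrt(counts, full, reduced, size_factors, dispersions)
    return out


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------


def per_gene_two_way_anova(
    counts: CountMatrix,
    factors: tuple[str, str] = ("hemisphere", "exercise"),
    size_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene 2-way ANOVA with interaction on log2(normalized count + 1).

    Classic sequential (type-I) F tests in the order ``factors[0]``,
    ``factors[1]``, interaction, mirroring a formula-order ANOVA fit run
    gene by gene.  Returns one row per gene with F and p per term.
    Constant-response genes get NaN (zero residual variance).
    """
    design = counts.design_frame().reset_index()
    a, b = factors
    cells = design.groupby([a, b]).size()
    la = design[a].nunique()
    lb = design[b].nunique()
    if len(cells) < la * lb:
        raise ValueError(f"every {a} x {b} combination needs at least one sample")
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts)
    Yv = np.log2(counts.counts / np.asarray(size_factors)[None, :] + 1.0)
    term_sets = [[], [a], [a, b], [a, b, f"{a}:{b}"]]
    rss, dfs = [], []
    n = Yv.shape[1]
    for terms in term_sets:
        X, _ = build_design_matrix(design, terms)
        Q, _ = np.linalg.qr(X)
        resid = Yv - (Yv @ Q) @ Q.T
        rss.append((resid**2).sum(axis=1))
        dfs.append(X.shape[1])
    df_resid = n - dfs[3]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom for the interaction model")
    mse = rss[3] / df_resid
    out = {}
    labels = [a, b, "interaction"]
    for i, lab in enumerate(labels):
        num_df = dfs[i + 1] - dfs[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (rss[i] - rss[i + 1]) / num_df / mse
        F = np.where(mse > 1e-12, F, np.nan)
        p = np.where(np.isfinite(F), stats.f.sf(F, num_df, df_resid), np.nan)
        out[f"F_{lab}"] = F
        out[f"p_{lab}"] = p
    return pd.DataFrame(out, index=counts.gene_ids)


# ---------------------------------------------------------------------------
# BH adjustment and DEG calling
# ---------------------------------------------------------------------------


def adjust_bh(p: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs are excluded then
    reinserted so they do not deflate the correction."""
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_degs(
    de: DEResult,
    lfc_cut: float = DEFAULT_LFC_CUT,
    p_cut: float = DEFAULT_P_CUT,
    use: str = "p",
) -> DEGSets:
    """Call up/down DEG sets with strict inequalities.

    ``use`` selects the gating column ("p" raw, or "padj").  Supplying
    0.3875 for ``lfc_cut`` triggers a warning: the >30% change criterion
    corresponds to log2(1.3) = 0.3785, and 0.3875 is almost surely a
    transposition of it.
    """
    if abs(lfc_cut - 0.3875) < 5e-5:
        warnings.warn(
            "lfc_cut 0.3875 looks like a transposition of log2(1.3)=0.3785 "
            "(the >30% change criterion); proceeding with the supplied value",
            stacklevel=2,
        )
    if use not in ("p", "padj"):
        raise ValueError("use must be 'p' or 'padj'")
    t = de.table
    gate = t[use] < p_cut
    up = set(t.index[(t["log2fc"] > lfc_cut) & gate])
    down = set(t.index[(t["log2fc"] < -lfc_cut) & gate])
    return DEGSets(up=up, down=down, contrast=de.contrast,
                   lfc_cut=lfc_cut, p_cut=p_cut, use=use)
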