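"""Window-wise correlation of sequence divergence with inheritance strength.

Because the plastome does not recombine, every window is in complete
linkage with every other; correlation mapping therefore ranks candidate
loci rather than proving causality.  Two mass-univariate passes are
provided:

* :class:`WindowCorrelationMapper` — Pearson and/or Spearman correlation
  of each window's change-count vector against the phenotype, with
  two-sided p-values and Benjamini–Hochberg adjustment across windows.
* :class:`PGLSMapper` — phylogenetic generalized least squares: the same
  per-window regression but with residual covariance proportional to
  shared branch length under Brownian motion on a supplied tree
  (optionally Pagel's-lambda scaled), which discounts correlations
  explained by phylogenetic relatedness alone.

Windows whose count vector has zero variance are flagged undefined and
excluded from the multiple-testing family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .alignment import DivergenceMatrix, PlastomeAlignment, count_changes

__all__ = [
    "PhenotypeTable",
    "bh_adjust",
    "WindowCorrelationMapper",
    "PGLSMapper",
    "correlate_windows",
    "pgls_windows",
    "region_correlation",
    "brownian_covariance",
]

EXACT_PERMUTATION_MAX_N = 8


@dataclass
class PhenotypeTable:
    """Per-sample inheritance strength with its direction convention.

    ``direction`` records what a large value means for the measuring
    cross series — e.g. in crosses where the tester plastome is paternal
    and white, a *low* percent-variegated means a *strong* maternal
    plastome.  The pipeline never flips signs; the label travels with the
    output so negative correlations stay interpretable.
    """

    values: dict[str, float]
    direction: str = "high_value_means_weak"
    series: str = ""

    def vector(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.values]
        if missing:
            raise KeyError(f"phenotype missing for samples: {missing}")
        return np.array([float(self.values[s]) for s in sample_ids])

    @classmethod
    def from_csv(cls, path, value_column: str = "value") -> "PhenotypeTable":
        df = pd.read_csv(path)
        direction = (
            str(df["direction"].iloc[0]) if "direction" in df else "high_value_means_weak"
        )
        series = str(df["series"].iloc[0]) if "series" in df else ""
        return cls(
            values=dict(zip(df["sample_id"].astype(str), df[value_column].astype(float))),
            direction=direction,
            series=series,
        )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved.

    All p-values must lie in (0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pearson_matrix(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of X (features x samples) against y, with
    two-sided t-approximation p-values.  Rows must have variance > 0."""
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    r = (Xc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = np.finfo(float).tiny  # |r| = 1 -> p -> 0
    return r, np.clip(p, np.finfo(float).tiny, 1.0)


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, X)


def _spearman_exact_p(R: np.ndarray, y_rank: np.ndarray, rho_obs: np.ndarray) -> np.ndarray:
    """Exact permutation p for Spearman's rho, enumerating all n!
    orderings of the phenotype ranks.  R is rank-transformed X rows."""
    n = len(y_rank)
    perms = np.array(list(itertools.permutations(y_rank)), dtype=float)  # (n!, n)
    Pc = perms - perms.mean(axis=1, keepdims=True)
    Pn = Pc / np.linalg.norm(Pc, axis=1, keepdims=True)
    Rc = R - R.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Rc, axis=1, keepdims=True)
    Rn = Rc / norms
    rho_all = Rn @ Pn.T  # (n_windows, n!)
    thresh = np.abs(rho_obs)[:, None] - 1e-12
    return (np.abs(rho_all) >= thresh).mean(axis=1)


class WindowCorrelationMapper(BaseEstimator):
    """Mass-univariate correlation of window divergence with phenotype.

    Each window's change-count vector across samples is one feature;
    ``fit`` computes, per feature, Pearson and/or Spearman correlation
    with the phenotype, a two-sided p-value (t-approximation for
    Pearson; exact permutation for Spearman when n <= 8, t-approximation
    otherwise) and BH-adjusted q-values over the defined windows.
    Pearson and Spearman families are adjusted separately.

    Parameters
    ----------
    method : {"pearson", "spearman", "both"}
        Which correlation track(s) to compute.

    Attributes
    ----------
    defined_ : bool array, shape (n_windows,)
        False where the count vector (or phenotype) has zero variance;
        such windows carry NaN statistics and are excluded from BH.
    r_pearson_, p_pearson_, q_pearson_ : arrays (when computed)
    r_spearman_, p_spearman_, q_spearman_ : arrays (when computed)
    """

    def __init__(self, method: str = "both"):
        self.method = method

    def fit(self, X, y):
        """X: (n_samples, n_windows) count matrix; y: phenotype values."""
        if self.method not in ("pearson", "spearman", "both"):
            raise ValueError(f"unknown method {self.method!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x windows)")
        n, n_windows = X.shape
        if n < 3:
            raise ValueError(f"need >= 3 samples, got {n}")
        if len(y) != n:
            raise ValueError("X and y have mismatched sample counts")
        W = X.T  # windows x samples
        var_ok = W.var(axis=1) > 0
        if y.var() == 0:
            var_ok = np.zeros(n_windows, dtype=bool)
        self.defined_ = var_ok
        self.n_samples_ = n

        def _with_nan(values: np.ndarray) -> np.ndarray:
            out = np.full(n_windows, np.nan)
            out[var_ok] = values
            return out

        if self.method in ("pearson", "both"):
            r, p = _pearson_matrix(W[var_ok], y)
            self.r_pearson_ = _with_nan(r)
            self.p_pearson_ = _with_nan(p)
            self.q_pearson_ = _with_nan(bh_adjust(p) if p.size else p)
        if self.method in ("spearman", "both"):
            R = _rank_rows(W[var_ok]) if var_ok.any() else W[var_ok]
            y_rank = stats.rankdata(y)
            rho, p_t = _pearson_matrix(R, y_rank) if var_ok.any() else (
                np.empty(0), np.empty(0))
            if n <= EXACT_PERMUTATION_MAX_N and var_ok.any():
                p_s = _spearman_exact_p(R, y_rank, rho)
            else:
                p_s = p_t
            self.r_spearman_ = _with_nan(rho)
            self.p_spearman_ = _with_nan(p_s)
            self.q_spearman_ = _with_nan(bh_adjust(p_s) if p_s.size else p_s)
        return self


def correlate_windows(
    matrix: DivergenceMatrix,
    phenotype: PhenotypeTable,
    method: str = "both",
    annotations: list[list[str]] | None = None,
) -> pd.DataFrame:
    """Correlation track over (collapsed) windows as a tidy DataFrame."""
    y = phenotype.vector(matrix.sample_ids)
    mapper = WindowCorrelationMapper(method=method).fit(matrix.counts.T, y)
    out = pd.DataFrame(
        {
            "window_id": matrix.window_ids,
            "start": matrix.starts,
            "end": matrix.ends,
            "defined": mapper.defined_,
        }
    )
    if method in ("pearson", "both"):
        out["r_pearson"] = mapper.r_pearson_
        out["p_pearson"] = mapper.p_pearson_
        out["q_pearson"] = mapper.q_pearson_
    if method in ("spearman", "both"):
        out["r_spearman"] = mapper.r_spearman_
        out["p_spearman"] = mapper.p_spearman_
        out["q_spearman"] = mapper.q_spearman_
    if annotations is not None:
        out["features"] = [";".join(a) for a in annotations]
    out.attrs["phenotype_direction"] = phenotype.direction
    out.attrs["n_samples"] = mapper.n_samples_
    return out


def brownian_covariance(
    tree: "dendropy.Tree | str", tip_order: list[str], lam: float = 1.0
) -> np.ndarray:
    """Brownian-motion tip covariance from a phylogeny.

    C[i, j] is the root-to-MRCA distance (shared path length) of tips i
    and j; diagonals are root-to-tip depths.  Off-diagonals are scaled by
    Pagel's lambda ``lam``.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in tip_order if s not in taxa]
    if missing:
        raise ValueError(f"tree lacks tips for samples: {missing}")
    extra = set(taxa) - set(tip_order)
    if extra:
        raise ValueError(f"tree has tips without phenotype/counts: {sorted(extra)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("tree has a negative branch length")
    depth = {}
    for node in tree.preorder_node_iter():
        d = 0.0 if node.parent_node is None else depth[node.parent_node] + (node.edge.length or 0.0)
        depth[node] = d
    pdm = tree.phylogenetic_distance_matrix()
    n = len(tip_order)
    C = np.empty((n, n))
    for i, a in enumerate(tip_order):
        C[i, i] = depth[tree.find_node_for_taxon(taxa[a])]
        for j in range(i + 1, n):
            b = tip_order[j]
            patristic = pdm.patristic_distance(taxa[a], taxa[b])
            shared = (C[i, i] + depth[tree.find_node_for_taxon(taxa[b])] - patristic) / 2.0
            C[i, j] = C[j, i] = lam * shared
    return C


class PGLSMapper(BaseEstimator):
    """Per-window generalized least squares under a phylogenetic covariance.

    For each window, regresses the phenotype on the window's change
    counts with GLS, residual covariance proportional to the
    Brownian-motion matrix of the supplied tree.  On a star phylogeny
    with equal tip depths the covariance is proportional to the
    identity, so estimates and p-values coincide with OLS.

    Attributes
    ----------
    slope_, se_, p_, q_ : arrays over windows (NaN where undefined).
    """

    def __init__(self, lam: float = 1.0):
        self.lam = lam

    def fit(self, X, y, covariance: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, n_windows = X.shape
        if n < 4:
            raise ValueError(f"PGLS needs >= 4 samples, got {n}")
        C = np.asarray(covariance, dtype=float)
        if C.shape != (n, n):
            raise ValueError("covariance shape mismatch")
        try:
            Lch = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            d = np.sqrt(np.diag(C))
            rho = C / np.outer(d, d)
            np.fill_diagonal(rho, 0.0)
            i, j = np.unravel_index(np.argmax(rho), rho.shape)
            raise ValueError(
                "singular phylogenetic covariance: tips "
                f"{i} and {j} are separated by (near-)zero branch length"
            ) from None
        # whiten: solve L z = v  ->  z has identity covariance
        from scipy.linalg import solve_triangular

        y_t = solve_triangular(Lch, y, lower=True)
        ones_t = solve_triangular(Lch, np.ones(n), lower=True)
        W = X.T
        var_ok = W.var(axis=1) > 0
        slope = np.full(n_windows, np.nan)
        se = np.full(n_windows, np.nan)
        p = np.full(n_windows, np.nan)
        df = n - 2
        for idx in np.nonzero(var_ok)[0]:
            x_t = solve_triangular(Lch, W[idx], lower=True)
            D = np.column_stack([ones_t, x_t])
            beta, res, rank, _ = np.linalg.lstsq(D, y_t, rcond=None)
            resid = y_t - D @ beta
            sigma2 = float(resid @ resid) / df
            XtX_inv = np.linalg.inv(D.T @ D)
            s = np.sqrt(sigma2 * XtX_inv[1, 1])
            slope[idx] = beta[1]
            se[idx] = s
            if s > 0:
                p[idx] = 2.0 * stats.t.sf(abs(beta[1]) / s, df)
            else:
                p[idx] = np.finfo(float).tiny
        self.defined_ = var_ok
        self.slope_ = slope
        self.se_ = se
        self.p_ = np.where(var_ok, np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
        q = np.full(n_windows, np.nan)
        if var_ok.any():
            q[var_ok] = bh_adjust(self.p_[var_ok])
        self.q_ = q
        return self


def pgls_windows(
    matrix: DivergenceMatrix,
    phenotype: PhenotypeTable,
    tree: "dendropy.Tree | str",
    lam: float = 1.0,
) -> pd.DataFrame:
    """PGLS track over (collapsed) windows as a tidy DataFrame."""
    y = phenotype.vector(matrix.sample_ids)
    C = brownian_covariance(tree, matrix.sample_ids, lam=lam)
    mapper = PGLSMapper(lam=lam).fit(matrix.counts.T, y, covariance=C)
    out = pd.DataFrame(
        {
            "window_id": matrix.window_ids,
            "start": matrix.starts,
            "end": matrix.ends,
            "defined": mapper.defined_,
            "pgls_slope": mapper.slope_,
            "pgls_se": mapper.se_,
            "pgls_p": mapper.p_,
            "pgls_q": mapper.q_,
        }
    )
    out.attrs["phenotype_direction"] = phenotype.direction
    return out


def region_correlation(
    alignment: PlastomeAlignment,
    phenotype: PhenotypeTable,
    interval: tuple[int, int],
    method: str = "both",
) -> dict:
    """Correlate divergence over one region of interest with phenotype.

    Counts changes of every sample over ``interval`` (a single window of
    bespoke size, e.g. a gene's 5' end or a promoter) and correlates the
    resulting vector with the phenotype.
    """
    samples = alignment.non_reference_ids
    counts = np.array([count_changes(alignment, s, interval) for s in samples], dtype=float)
    y = phenotype.vector(samples)
    record: dict = {
        "start": interval[0],
        "end": interval[1],
        "n_samples": len(samples),
        "counts": counts,
        "defined": bool(counts.var() > 0 and y.var() > 0),
        "direction": phenotype.direction,
    }
    if not record["defined"]:
        for key in ("r_pearson", "p_pearson", "r_spearman", "p_spearman"):
            record[key] = np.nan
        return record
    if method in ("pearson", "both"):
        r, p = stats.pearsonr(counts, y)
        record["r_pearson"], record["p_pearson"] = float(r), float(p)
    if method in ("spearman", "both"):
        rho, p = stats.spearmanr(counts, y)
        record["r_spearman"], record["p_spearman"] = float(rho), float(p)
    return record
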