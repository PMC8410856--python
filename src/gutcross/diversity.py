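"""Alpha/beta diversity: Shannon index, Bray-Curtis, PCoA, Kruskal-Wallis,
and permutation-based (optionally two-factor sequential) PERMANOVA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables import CountTable, RelAbundTable, TableError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "EllipseParams",
    "shannon",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "correlation_ellipse",
    "kruskal_wallis",
    "permanova",
]


def shannon(sample: np.ndarray) -> float:
    """Shannon diversity H = -sum p_i log2 p_i, in bits."""
    x = np.asarray(sample, dtype=float)
    if x.sum() <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return float(scipy.stats.entropy(x, base=2))


def alpha_diversity(table: CountTable | RelAbundTable) -> pd.Series:
    """Per-sample Shannon index (bits)."""
    return pd.Series(
        {s: shannon(table.data[s].to_numpy()) for s in table.sample_ids},
        name="shannon",
    )


def bray_curtis(table: CountTable | RelAbundTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(x, y) = sum|x - y| / sum(x + y), bounded in [0, 1].
    """
    mat = table.data.to_numpy(dtype=float).T  # samples x features
    if mat.shape[0] < 2:
        raise ValueError("need at least two samples")
    if (mat.sum(axis=1) == 0).any():
        bad = table.sample_ids[int(np.argmax(mat.sum(axis=1) == 0))]
        raise ValueError(f"sample {bad!r} is all zero")
    condensed = pdist(mat, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """PCoA embedding: axes ordered by decreasing eigenvalue.

    Coordinates keep only the axes with positive eigenvalues;
    ``proportion_explained`` is computed over the positive spectrum, and the
    negative eigenvalues are reported separately for diagnostics.
    """

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal-coordinates analysis of a distance matrix.

    Eigendecomposition of the Gower-centered matrix -1/2 J D^2 J; coordinates
    are eigenvectors scaled by the square roots of the positive eigenvalues.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-10, 1e-10 * abs(vals[0])) if n else 0.0
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=vals[pos],
        proportion_explained=vals[pos] / vals[pos].sum(),
        negative_eigenvalues=vals[vals < -tol],
    )


@dataclass
class EllipseParams:
    """2-sigma confidence ellipse of a group's first two ordination axes."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle_deg: float
    pearson_r: float
    degenerate: bool


def correlation_ellipse(coords: pd.DataFrame, labels) -> dict:
    """Per-group 2-sigma ellipses from the Pearson-correlation structure.

    ``coords`` must hold the first two ordination axes (samples x 2). The
    ellipse axes/angle come from the eigendecomposition of the group's 2x2
    sample covariance (equivalently, the correlation structure scaled by the
    per-axis SDs), radius two sigma.
    """
    labels = np.asarray(labels)
    xy = coords.to_numpy(dtype=float)[:, :2]
    out: dict = {}
    for g in pd.unique(labels):
        pts = xy[labels == g]
        if pts.shape[0] < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        sx, sy = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
        degenerate = sx < 1e-12 or sy < 1e-12
        r = 0.0 if degenerate else cov[0, 1] / (sx * sy)
        evals, evecs = np.linalg.eigh(cov)
        evals = np.clip(evals, 0.0, None)
        angle = math.degrees(math.atan2(evecs[1, 1], evecs[0, 1]))
        out[g] = EllipseParams(
            center=(float(center[0]), float(center[1])),
            semi_major=2.0 * math.sqrt(evals[1]),
            semi_minor=2.0 * math.sqrt(evals[0]),
            angle_deg=angle,
            pearson_r=float(r),
            degenerate=bool(degenerate or abs(r) > 1 - 1e-9),
        )
    return out


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    if np.ptp(values) == 0:  # scipy refuses all-identical data; H is 0 there
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*samples)
    return float(h), float(p)


@dataclass
class PermanovaResult:
    """Distance-based pseudo-F partition with permutation p-values."""

    terms: pd.DataFrame  # index term; columns F, R2, df, p
    residual_r2: float
    total_ss: float
    n_permutations: int

    def to_dict(self) -> dict:
        d = {
            term: {
                "F": float(row["F"]),
                "R2": float(row["R2"]),
                "p": float(row["p"]),
                "n_perm": self.n_permutations,
            }
            for term, row in self.terms.iterrows()
        }
        d["residual_R2"] = self.residual_r2
        return d


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def permanova(dm: DistanceMatrix, design, n_perm: int = 999,
              seed: int | None = None,
              permutations: str = "random") -> PermanovaResult:
    """Adonis-style PERMANOVA with sequential (Type I) sums of squares.

    Parameters
    ----------
    design : mapping or DataFrame
        One or two binary factors (term name -> 0/1 labels per sample, in
        ``dm`` sample order). With two factors the sums of squares are
        sequential in the order given, matching the adonis default.
    n_perm : int
        Number of free label permutations (ignored in exact mode).
    permutations : {"random", "exact"}
        "exact" enumerates all n! sample orderings (n <= 8 only) and returns
        the exact permutation p-value.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    design = pd.DataFrame(dict(design))
    if design.shape[0] != n:
        raise ValueError("design rows must match distance matrix samples")
    for term in design.columns:
        if design[term].nunique() < 2:
            raise ValueError(f"factor {term!r} is constant")
    if permutations == "random" and n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    a = -0.5 * d ** 2
    g = a - a.mean(axis=1, keepdims=True) - a.mean(axis=0, keepdims=True) + a.mean()
    ss_total = float(np.trace(g))

    # sequential hat matrices: intercept, then cumulative factor columns
    ones = np.ones((n, 1))
    hats = [_hat(ones)]
    dfs = []
    x = ones
    for term in design.columns:
        x = np.hstack([x, design[term].to_numpy(dtype=float)[:, None]])
        h = _hat(x)
        dfs.append(int(round(np.trace(h) - np.trace(hats[-1]))))
        hats.append(h)
    df_res = n - int(round(np.trace(hats[-1])))
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    res_tol = 1e-12 * max(abs(ss_total), 1.0)

    def _f(ss_terms: np.ndarray, ss_res) -> np.ndarray:
        # a vanishing residual means perfect separation: report F = +inf
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_terms / np.array(dfs)) / (np.maximum(ss_res, 0.0) / df_res)
        return np.where(np.asarray(ss_res) < res_tol,
                        np.where(ss_terms > res_tol, np.inf, 0.0), f)

    def f_stats(gmat: np.ndarray) -> np.ndarray:
        traces = np.array([float((h * gmat).sum()) for h in hats])
        ss_terms = np.diff(traces)
        return _f(ss_terms, ss_total - ss_terms.sum())

    # observed
    traces = np.array([float((h * g).sum()) for h in hats])
    ss_terms = np.diff(traces)
    ss_res = max(ss_total - ss_terms.sum(), 0.0)
    f_obs = _f(ss_terms, ss_res)
    r2 = ss_terms / ss_total

    if permutations == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        count = np.zeros(len(dfs))
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            f_p = f_stats(g[np.ix_(idx, idx)])
            count += f_p >= f_obs - 1e-12
            total += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(dfs))
        chunk = 256
        done = 0
        while done < n_perm:
            k = min(chunk, n_perm - done)
            idx = np.array([rng.permutation(n) for _ in range(k)])
            g_perms = g[idx[:, :, None], idx[:, None, :]]  # k x n x n
            tr = np.stack([np.einsum("ij,pij->p", h, g_perms) for h in hats])
            ss_t = np.diff(tr, axis=0)  # terms x k
            ss_r = ss_total - ss_t.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_p = (ss_t / np.array(dfs)[:, None]) / (
                    np.maximum(ss_r, 0.0) / df_res)
            f_p = np.where(ss_r[None, :] < res_tol,
                           np.where(ss_t > res_tol, np.inf, 0.0), f_p)
            count += (f_p >= (f_obs[:, None] - 1e-12)).sum(axis=1)
            done += k
        p = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm

    terms = pd.DataFrame(
        {"F": f_obs, "R2": r2, "df": dfs, "p": p},
        index=list(design.columns),
    )
    return PermanovaResult(
        terms=terms,
        residual_r2=float(ss_res / ss_total),
        total_ss=ss_total,
        n_permutations=n_used,
    )
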