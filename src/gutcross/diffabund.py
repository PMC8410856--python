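"""Compositional differential abundance.

Two complementary procedures, both operating on log-ratios so that results
are invariant to per-sample sequencing depth:

* an ANCOM-style test that, for every feature, tests the exposure effect on
  its log-ratio against each other feature and reports the proportion W of
  those tests that reject (significance declared at W >= 0.7);
* an ALDEx-style Monte-Carlo procedure that resamples per-sample
  compositions from a Dirichlet posterior, CLR-transforms, and averages
  BH-adjusted Welch p-values ("expected q") plus a signed standardized
  effect (positive = more abundant in the exposed class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .tables import CohortMetadata, CountTable, TableError

__all__ = [
    "AncomResult",
    "AldexResult",
    "ancom_w",
    "aldex_clr",
    "clr_transform",
    "clr_welch_test",
]


@dataclass
class AncomResult:
    """Per-feature W proportion (tests passed / (m-1)) and significance."""

    frame: pd.DataFrame  # index feature; columns w_proportion, significant
    threshold: float
    alpha: float

    def significant_features(self) -> list[str]:
        return list(self.frame.index[self.frame["significant"]])


def _bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask."""
    adj = scipy.stats.false_discovery_control(pvals, method="bh")
    return adj <= alpha


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values (a, b: features x samples)."""
    res = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
    return np.nan_to_num(res.pvalue, nan=1.0)


def ancom_w(table: CountTable, meta: CohortMetadata,
            covariate_adjust: bool = False, alpha: float = 0.05,
            threshold: float = 0.7) -> AncomResult:
    """ANCOM-style W proportion for a binary exposure.

    For each feature i and every other feature j, the per-sample log-ratio
    log((x_i + 1) / (x_j + 1)) is tested for an exposure effect — a Welch
    t-test, or the exposure coefficient of an additive linear model with the
    binary covariate when ``covariate_adjust``. The m-1 p-values of feature
    i's family are BH-corrected; W_i is the rejected fraction, and i is
    called significant when W_i >= ``threshold``.
    """
    counts = table.matrix
    m, n = counts.shape
    if m < 3:
        raise TableError("ANCOM needs at least 3 features")
    y = meta.exposure_for(table.sample_ids)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise TableError("each exposure class needs >= 2 samples")
    logx = np.log(counts + 1.0)

    if covariate_adjust:
        cov = meta.covariate_for(table.sample_ids)
        if cov is None:
            raise TableError("covariate_adjust requires a covariate column")
        z = np.column_stack([np.ones(n), y, cov])
        if np.linalg.matrix_rank(z) < 3:
            raise TableError("degenerate design: covariate confounded with exposure")
        pinv = np.linalg.pinv(z)
        xtx_inv = np.linalg.inv(z.T @ z)
        df = n - 3

        def exposure_p(ratios: np.ndarray) -> np.ndarray:
            beta = ratios @ pinv.T  # m-1 x 3
            resid = ratios - beta @ z.T
            sigma2 = (resid ** 2).sum(axis=1) / df
            se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
            t = beta[:, 1] / se
            return 2.0 * scipy.stats.t.sf(np.abs(t), df)
    else:
        g1, g0 = y == 1, y == 0

        def exposure_p(ratios: np.ndarray) -> np.ndarray:
            return _welch_p(ratios[:, g1], ratios[:, g0])

    w = np.zeros(m)
    for i in range(m):
        ratios = logx[i][None, :] - np.delete(logx, i, axis=0)
        pvals = exposure_p(ratios)
        w[i] = _bh_reject(pvals, alpha).sum() / (m - 1)

    frame = pd.DataFrame(
        {"w_proportion": w, "significant": w >= threshold},
        index=table.feature_ids,
    )
    return AncomResult(frame, threshold=threshold, alpha=alpha)


def clr_transform(proportions: np.ndarray) -> np.ndarray:
    """Centered log-ratio of strictly positive column compositions."""
    logp = np.log(proportions)
    return logp - logp.mean(axis=0, keepdims=True)


def clr_welch_test(proportions: np.ndarray, y: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One CLR + Welch + BH pass over strictly positive proportions.

    Returns (BH-adjusted p-values, signed effect) per feature; the effect is
    the between-class difference of median CLR values divided by the larger
    of the two within-class standard deviations (positive = higher in the
    exposed class, y == 1).
    """
    clr = clr_transform(proportions)
    g1, g0 = clr[:, y == 1], clr[:, y == 0]
    p = _welch_p(g1, g0)
    adj = scipy.stats.false_discovery_control(p, method="bh")
    diff = np.median(g1, axis=1) - np.median(g0, axis=1)
    disp = np.maximum(g1.std(axis=1, ddof=1), g0.std(axis=1, ddof=1))
    effect = diff / np.maximum(disp, 1e-8)
    return adj, effect


@dataclass
class AldexResult:
    """Expected BH-adjusted q and signed effect size per feature."""

    frame: pd.DataFrame  # index feature; columns expected_q, effect, significant
    n_mc: int
    q_threshold: float

    def significant_features(self) -> list[str]:
        return list(self.frame.index[self.frame["significant"]])


def aldex_clr(table: CountTable, meta: CohortMetadata, n_mc: int = 128,
              seed: int | None = None, q_threshold: float = 0.05) -> AldexResult:
    """ALDEx-style Dirichlet-CLR Welch test.

    Per Monte-Carlo instance, each sample's composition is drawn from
    Dirichlet(counts + 0.5), CLR-transformed and Welch-tested per feature
    with BH correction across features. ``expected_q`` averages the adjusted
    p over instances; the effect is the median over instances of the
    standardized CLR difference (see :func:`clr_welch_test`). Positive effect
    = more abundant in the exposed class.
    """
    if n_mc < 16:
        raise ValueError("n_mc must be >= 16")
    counts = table.matrix
    y = meta.exposure_for(table.sample_ids)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise TableError("each exposure class needs >= 2 samples")
    rng = np.random.default_rng(seed)
    alpha_post = counts + 0.5
    q_sum = np.zeros(counts.shape[0])
    effects = np.empty((n_mc, counts.shape[0]))
    for k in range(n_mc):
        gam = rng.standard_gamma(alpha_post)
        props = gam / gam.sum(axis=0, keepdims=True)
        adj, eff = clr_welch_test(props, y)
        q_sum += adj
        effects[k] = eff
    expected_q = q_sum / n_mc
    effect = np.median(effects, axis=0)
    frame = pd.DataFrame(
        {
            "expected_q": expected_q,
            "effect": effect,
            "significant": expected_q < q_threshold,
        },
        index=table.feature_ids,
    )
    return AldexResult(frame, n_mc=n_mc, q_threshold=q_threshold)
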