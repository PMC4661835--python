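"""Reliability-weighted animal model fitted by restricted maximum likelihood.

The model for a vector of estimated breeding values (EBVs) y is

    y = X b + Z a + e,    a ~ N(0, A sigma_a^2),    e ~ N(0, W sigma_e^2)

where X codes the mean plus a genotype (or diplotype) class factor, ``a`` is
the polygenic effect with pedigree covariance A, and W = diag(1/REL_i)
inflates the residual variance of animals whose EBV is less reliable.  With
one record per animal Z is the identity on phenotyped animals and

    V = sigma_a^2 A + sigma_e^2 W = sigma_e^2 (lambda A + W),
    lambda = sigma_a^2 / sigma_e^2.

REML therefore reduces to a one-dimensional problem: sigma_e^2 has a closed
form at any lambda, and the profiled restricted log-likelihood is maximised
over lambda by bounded scalar search (the lambda = 0 boundary is evaluated
explicitly).  Fixed effects are then the GLS solutions at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .pedigree import RelationshipMatrix


class ModelError(ValueError):
    pass


def build_design(classes: Sequence[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + class-indicator design with a deterministic reference.

    The lexicographically last class is the (dropped) reference level.
    Returns ``(X, column_names, levels)`` with levels sorted.
    """
    levels = sorted(set(classes))
    if len(levels) < 2:
        raise ModelError("no contrast: need at least two genotype classes")
    ref = levels[-1]
    coded = levels[:-1]
    X = np.ones((len(classes), 1 + len(coded)))
    for j, lvl in enumerate(coded, start=1):
        X[:, j] = [1.0 if c == lvl else 0.0 for c in classes]
    return X, ["intercept"] + [f"class[{l}]" for l in coded], levels


class MixedAnimalModel:
    """Animal model for one trait and one class factor.

    Parameters
    ----------
    y : EBV phenotypes, one record per animal.
    classes : genotype or diplotype class label per animal.
    A : numerator relationship (sub)matrix for exactly these animals, or the
        full :class:`RelationshipMatrix` (the submatrix is taken by id).
    reliabilities : EBV reliabilities in (0, 1]; residual weights are 1/REL.
    ids : animal identifiers aligned with ``y``.
    """

    def __init__(
        self,
        y: np.ndarray,
        classes: Sequence[str],
        A: np.ndarray | RelationshipMatrix,
        reliabilities: np.ndarray,
        ids: Sequence[str] | None = None,
    ):
        self.y = np.asarray(y, dtype=float)
        n = len(self.y)
        self.ids = list(ids) if ids is not None else [str(i) for i in range(n)]
        if isinstance(A, RelationshipMatrix):
            A = A.submatrix(self.ids)
        self.A = np.asarray(A, dtype=float)
        rel = np.asarray(reliabilities, dtype=float)
        if np.any(rel <= 0) or np.any(rel > 1):
            raise ModelError("reliabilities must lie in (0, 1]")
        if not (self.A.shape == (n, n) and len(rel) == n and len(classes) == n):
            raise ModelError("y, classes, A and reliabilities must align")
        if not np.all(np.isfinite(self.y)):
            raise ModelError("phenotypes must be finite")
        self.weights = 1.0 / rel
        self.classes = list(classes)
        self.exog, self.exog_names, self.levels = build_design(self.classes)
        self.nobs = n
        self.rank = np.linalg.matrix_rank(self.exog)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        A: RelationshipMatrix,
        y_col: str = "ebv",
        class_col: str = "class",
        rel_col: str = "rel",
        id_col: str = "animal",
    ) -> "MixedAnimalModel":
        """Build from a tidy per-animal frame, dropping incomplete rows listwise."""
        cols = [id_col, y_col, class_col, rel_col]
        df = data[cols].dropna()
        df = df[df[id_col].isin(A.ids)]
        if df.empty:
            raise ModelError("no animal has phenotype, class, reliability and pedigree")
        return cls(
            df[y_col].to_numpy(float),
            df[class_col].astype(str).tolist(),
            A,
            df[rel_col].to_numpy(float),
            ids=df[id_col].astype(str).tolist(),
        )

    # -- restricted likelihood machinery -------------------------------

    def _profile(self, lam: float) -> tuple[float, np.ndarray, np.ndarray, float]:
        """Profiled REML pieces at variance ratio ``lam``.

        Returns (restricted loglik, beta_hat, (X'H^-1 X)^-1, sigma_e^2_hat)
        with H = lam*A + W.
        """
        n, p = self.nobs, self.rank
        H = lam * self.A + np.diag(self.weights)
        try:
            c, low = linalg.cho_factor(H, lower=True)
        except linalg.LinAlgError:
            return -np.inf, np.zeros(self.exog.shape[1]), np.eye(self.exog.shape[1]), np.nan
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(c))))
        Hi_X = linalg.cho_solve((c, low), self.exog)
        Hi_y = linalg.cho_solve((c, low), self.y)
        XtHiX = self.exog.T @ Hi_X
        sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
        if sign <= 0:
            return -np.inf, np.zeros(self.exog.shape[1]), np.eye(self.exog.shape[1]), np.nan
        XtHiX_inv = np.linalg.inv(XtHiX)
        beta = XtHiX_inv @ (self.exog.T @ Hi_y)
        r = self.y - self.exog @ beta
        quad = float(r @ linalg.cho_solve((c, low), r))
        sigma2_e = quad / (n - p)
        if sigma2_e <= 0:
            sigma2_e = np.finfo(float).tiny
        ll = -0.5 * ((n - p) * np.log(sigma2_e) + logdet_H + logdet_XtHiX + (n - p))
        return ll, beta, XtHiX_inv, sigma2_e

    def fit(
        self,
        tol: float = 1e-8,
        lambda_bounds: tuple[float, float] = (1e-6, 1e4),
        fixed_lambda: float | None = None,
    ) -> "MixedAnimalModelResults":
        """Maximise the restricted likelihood over the variance ratio.

        ``fixed_lambda`` skips estimation and fits GLS at a known ratio
        (used to share variance components across markers for one trait).
        """
        if fixed_lambda is not None:
            lam = float(fixed_lambda)
        else:
            lo, hi = np.log(lambda_bounds[0]), np.log(lambda_bounds[1])
            res = optimize.minimize_scalar(
                lambda t: -self._profile(float(np.exp(t)))[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": tol},
            )
            lam = float(np.exp(res.x))
            # the boundary "no polygenic variance" is a legitimate optimum
            if self._profile(0.0)[0] >= self._profile(lam)[0]:
                lam = 0.0
        ll, beta, XtHiX_inv, sigma2_e = self._profile(lam)
        if not np.isfinite(ll):
            raise ModelError("restricted likelihood is degenerate at the optimum")
        return MixedAnimalModelResults(
            model=self,
            lam=lam,
            sigma2_a=lam * sigma2_e,
            sigma2_e=sigma2_e,
            loglik_reml=ll,
            params=beta,
            cov_params=sigma2_e * XtHiX_inv,
        )


@dataclass
class MixedAnimalModelResults:
    """REML/GLS solutions of a :class:`MixedAnimalModel`."""

    model: MixedAnimalModel
    lam: float
    sigma2_a: float
    sigma2_e: float
    loglik_reml: float
    params: np.ndarray
    cov_params: np.ndarray

    @property
    def df_resid(self) -> int:
        return self.model.nobs - self.model.rank

    @property
    def heritability_like_ratio(self) -> float:
        """sigma_a^2 / (sigma_a^2 + sigma_e^2); a summary, not an h2 estimate."""
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else np.nan

    # -- estimable functions --------------------------------------------

    def _lsm_rows(self) -> tuple[list[str], np.ndarray]:
        levels = self.model.levels
        p = len(self.params)
        L = np.zeros((len(levels), p))
        L[:, 0] = 1.0
        for i, lvl in enumerate(levels[:-1]):
            L[i, 1 + i] = 1.0
        return levels, L

    def lsmeans(self) -> pd.DataFrame:
        """Least-squares mean and standard error per class."""
        levels, L = self._lsm_rows()
        est = L @ self.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", L, self.cov_params, L))
        n_per = pd.Series(self.model.classes).value_counts()
        return pd.DataFrame(
            {"class": levels, "n": [int(n_per.get(l, 0)) for l in levels],
             "lsmean": est, "se": se}
        )

    def contrast(self, L: np.ndarray) -> tuple[float, float, float, float]:
        """Estimate, SE, t and two-sided p of a single linear contrast L'beta."""
        L = np.asarray(L, dtype=float)
        est = float(L @ self.params)
        var = float(L @ self.cov_params @ L)
        if var <= 0:
            raise ModelError("singular contrast")
        se = np.sqrt(var)
        t = est / se
        p = 2.0 * float(stats.t.sf(abs(t), self.df_resid))
        return est, se, t, p

    def anova(self) -> tuple[float, int, int, float]:
        """Wald F-test that all class effects are equal.

        Returns ``(F, num_df, den_df, p)`` with den_df = n - rank(X).
        """
        levels, L = self._lsm_rows()
        C = L[:-1] - L[-1]
        q = C.shape[0]
        cb = C @ self.params
        M = C @ self.cov_params @ C.T
        F = float(cb @ np.linalg.solve(M, cb)) / q
        p = float(stats.f.sf(F, q, self.df_resid))
        return F, q, self.df_resid, p

    def pairwise_pvalues(self) -> pd.DataFrame:
        """All pairwise t-tests on least-squares-mean differences."""
        levels, L = self._lsm_rows()
        rows = []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                est, se, t, p = self.contrast(L[i] - L[j])
                rows.append({"class_a": levels[i], "class_b": levels[j],
                             "diff": est, "se": se, "t": t, "p": p})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        f, q, dd, p = self.anova()
        lines = [
            "Reliability-weighted animal model (REML)",
            "=" * 56,
            f"No. animals:        {self.model.nobs}",
            f"Classes:            {', '.join(self.model.levels)}",
            f"sigma^2_a (polygenic): {self.sigma2_a:.6g}",
            f"sigma^2_e (residual):  {self.sigma2_e:.6g}",
            f"lambda = s2a/s2e:      {self.lam:.6g}",
            f"REML log-likelihood:   {self.loglik_reml:.6g}",
            "-" * 56,
            f"{'class':<12}{'n':>6}{'lsmean':>14}{'se':>12}",
        ]
        for _, r in self.lsmeans().iterrows():
            lines.append(f"{r['class']:<12}{r['n']:>6}{r['lsmean']:>14.4f}{r['se']:>12.4f}")
        lines += [
            "-" * 56,
            f"F({q}, {dd}) = {f:.4f},  p = {p:.4g}",
        ]
        return "\n".join(lines)
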