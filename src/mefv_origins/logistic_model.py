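"""Binary logistic regression fitted by Newton/IRLS, with optional ridge.

The association model regresses a binary genotype label (carries / does not
carry a given MEFV variant, or is / is not homozygous for it) on the
origin-score country fractions plus a sex indicator (female = 1, male = 0).
With 26 retained countries this is the 27-feature model.

The fit maximizes the (optionally ridge-penalized) Bernoulli log-likelihood

    L(b0, b) = sum_i [ y_i * eta_i - log(1 + exp(eta_i)) ] - (lam/2) * ||b||^2,
    eta_i = b0 + x_i . b,

by Newton's method with step halving (iteratively reweighted least squares).
The penalty applies to the coefficients only, never the intercept.  Features
are not standardized: country fractions already live in [0, 1] and sex is
binary, so coefficients stay interpretable as per-unit-ancestry log-odds;
note that the ridge penalty therefore acts on this natural scale.

Ridge with lam = 1.0 is the default.  The study's modeling era treated an
L2 penalty of this strength as the default configuration, and it also
stabilizes near-separated country indicators.  ``penalty="none"`` gives the
maximum-likelihood fit; under perfect separation that likelihood has no
finite maximizer and the fit is flagged ``converged=False`` rather than
failing silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["FeatureTable", "FitResult", "fit_logistic", "predict_proba", "make_feature_table"]

INTERCEPT = "(intercept)"
SEX_FEATURE = "sex"


@dataclass(frozen=True)
class FeatureTable:
    """Design matrix plus binary labels for one association model.

    ``features`` is a subjects x features DataFrame (no missing entries,
    unique column names); ``labels`` the 0/1 outcome vector.
    """

    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.labels)
        if y.shape != (len(self.features),):
            raise ValueError("labels must be one value per feature row")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing entries")
        if self.features.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        object.__setattr__(self, "labels", y.astype(float))

    @property
    def n(self) -> int:
        return len(self.features)

    def take(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.features.iloc[idx], self.labels[idx])


@dataclass(frozen=True)
class FitResult:
    """Coefficients of one logistic fit."""

    intercept: float
    coefficients: pd.Series  # feature name -> coefficient
    converged: bool
    iterations: int
    penalty: str  # "none" or "ridge"
    lam: float

    def as_series(self) -> pd.Series:
        """Intercept + coefficients as a single named Series."""
        return pd.concat([pd.Series({INTERCEPT: self.intercept}), self.coefficients])


def _penalized_loglik(X1: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float) -> float:
    eta = X1 @ beta
    # log(1 + e^eta) computed stably
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return ll - 0.5 * lam * float(beta[1:] @ beta[1:])


def fit_logistic(
    table: FeatureTable,
    penalty: str = "ridge",
    lam: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Fit by Newton/IRLS with step halving.

    The iteration stops when the max-norm of the penalized-likelihood
    gradient falls below ``tol``.  Non-convergence within ``max_iter``
    (e.g. perfect separation with no penalty) yields ``converged=False``.
    Constant feature columns are fitted rather than dropped, with a warning
    (under ridge their coefficients shrink toward zero).
    """
    if penalty not in ("none", "ridge"):
        raise ValueError(f"penalty must be 'none' or 'ridge', got {penalty!r}")
    lam_eff = float(lam) if penalty == "ridge" else 0.0
    if penalty == "ridge" and lam_eff <= 0:
        raise ValueError("ridge penalty requires lam > 0")
    y = table.labels
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels are single-class; a logistic model needs both outcomes")
    X = table.features.to_numpy(dtype=float)
    if X.shape[1] == 0:
        raise ValueError("at least one feature is required")
    const = X.std(axis=0) == 0
    if const.any():
        names = list(table.features.columns[const])
        warnings.warn(
            f"constant feature column(s) {names}; fitted anyway "
            "(coefficient is shrunk under ridge, unidentifiable without penalty)",
            stacklevel=2,
        )
    n, p = X.shape
    X1 = np.hstack([np.ones((n, 1)), X])
    mask = np.ones(p + 1)
    mask[0] = 0.0  # intercept is never penalized
    beta = np.zeros(p + 1)
    ll = _penalized_loglik(X1, y, beta, lam_eff)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X1 @ beta)
        grad = X1.T @ (y - mu) - lam_eff * mask * beta
        if np.max(np.abs(grad)) <= tol:
            converged = True
            it -= 1
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X1 * w[:, None]).T @ X1 + lam_eff * np.diag(mask)
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(H + 1e-8 * np.eye(p + 1), grad)
        # step halving keeps the penalized likelihood non-decreasing
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            ll_new = _penalized_loglik(X1, y, cand, lam_eff)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            break  # no ascent step found; report as non-converged below
        beta = beta + step * delta
        ll = ll_new
    else:
        it = max_iter
    if converged is False:
        mu = expit(X1 @ beta)
        grad = X1.T @ (y - mu) - lam_eff * mask * beta
        converged = bool(np.max(np.abs(grad)) <= tol)
    if lam_eff == 0.0:
        # the unpenalized likelihood has no finite maximizer under perfect
        # separation; saturated fitted probabilities betray the divergence
        mu = expit(X1 @ beta)
        if np.all(np.abs(mu - y) < 1e-6):
            warnings.warn(
                "perfect separation: unpenalized coefficients diverge; "
                "result flagged converged=False (consider a ridge penalty)",
                stacklevel=2,
            )
            converged = False
    return FitResult(
        intercept=float(beta[0]),
        coefficients=pd.Series(beta[1:], index=table.features.columns),
        converged=converged,
        iterations=it,
        penalty=penalty,
        lam=lam_eff if penalty == "ridge" else 0.0,
    )


def predict_proba(fit: FitResult, features: pd.DataFrame) -> np.ndarray:
    """Per-subject probability of the positive class, sigmoid(b0 + x.b).

    ``features`` must carry exactly the columns the fit was trained on
    (any order); a mismatch is an error, not a silent reindex.
    """
    if set(features.columns) != set(fit.coefficients.index) or len(
        features.columns
    ) != len(fit.coefficients):
        raise ValueError(
            "feature columns do not match the fitted model: "
            f"expected {sorted(fit.coefficients.index)}, got {sorted(features.columns)}"
        )
    X = features.loc[:, fit.coefficients.index].to_numpy(dtype=float)
    return expit(fit.intercept + X @ fit.coefficients.to_numpy())


def make_feature_table(
    cohort,
    matrix: pd.DataFrame,
    variant: str,
    outcome: str = "carrier",
) -> FeatureTable:
    """Assemble the country + sex design for one per-variant model.

    Rows are the referrals that appear in ``matrix`` (the filtered
    origin-score matrix) and have known sex, in matrix order.  Features are
    the matrix's country fractions plus a ``sex`` indicator (female = 1).
    The label is 1 when the referral carries ``variant`` (``outcome='carrier'``)
    or is homozygous for it (``outcome='homozygous'``).
    """
    from .genotype_summary import carries, classify_genotype

    if outcome not in ("carrier", "homozygous"):
        raise ValueError(f"outcome must be 'carrier' or 'homozygous', got {outcome!r}")
    by_id = {rec.subject_id: rec for rec in cohort}
    ids, sex, y = [], [], []
    for sid in matrix.index:
        rec = by_id.get(sid)
        if rec is None or rec.sex == "":
            continue
        ids.append(sid)
        sex.append(1.0 if rec.sex == "female" else 0.0)
        if outcome == "carrier":
            y.append(int(carries(rec, variant)))
        else:
            cls = classify_genotype(*rec.alleles)
            y.append(int(cls.kind == "HMZ" and cls.variants[0] == variant))
    features = matrix.loc[ids].copy()
    features[SEX_FEATURE] = sex
    return FeatureTable(features, np.asarray(y))
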