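"""Per-subject score statistics: GLM response residuals adjusting for covariates.

The score that GMDR classifies is the residual y - mu_hat from a generalized
linear model of the phenotype on the covariates (intercept always included):
ordinary least squares for quantitative traits, logistic regression for
binary traits, log-link Poisson regression for counts. With an intercept and
canonical link the maximum-likelihood score equations force these residuals
to sum to zero, which is what makes 0 the natural high/low-risk threshold in
the engine. Residuals are response residuals (not deviance or Pearson) in
every family, so that for a binary trait without covariates the scores are
exactly +/-(1 - prevalence)/prevalence-style constants and the engine
reduces to classical MDR balanced accuracy.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .data_model import CovariateMatrix, Phenotype, ScoreVector

__all__ = ["compute_scores", "load_scores", "write_scores"]

Family = Literal["normal", "bernoulli", "poisson", "auto"]

_AUTO_FAMILY = {"binary": "bernoulli", "quantitative": "normal", "count": "poisson"}


class ScoreComputationError(RuntimeError):
    """GLM fit failed (non-convergence or separation)."""


def compute_scores(
    phenotype: Phenotype,
    covariates: CovariateMatrix | None = None,
    family: Family = "auto",
) -> ScoreVector:
    """Fit phenotype ~ intercept + covariates and return response residuals.

    ``family='auto'`` maps binary -> bernoulli, quantitative -> normal,
    count -> poisson. Without covariates the fitted mean under all three
    families is the sample mean (closed form), so no iterative fit is run.
    """
    y = phenotype.values
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values; validate the dataset first")
    if family == "auto":
        family = _AUTO_FAMILY[phenotype.trait_kind]
    if family not in ("normal", "bernoulli", "poisson"):
        raise ValueError(f"unknown family {family!r}")
    if family == "bernoulli" and len(np.unique(y)) < 2:
        raise ScoreComputationError("binary phenotype is constant; scores undefined")

    if covariates is None or covariates.n_covariates == 0:
        # Intercept-only MLE: fitted mean equals the sample mean for the
        # normal, Bernoulli and Poisson families alike.
        resid = y - y.mean()
        return ScoreVector(values=resid, origin="computed")

    if covariates.n_subjects != len(y):
        raise ValueError("covariate rows must match phenotype length")
    X = sm.add_constant(covariates.values, has_constant="add")

    if family == "normal":
        fit = sm.OLS(y, X).fit()
        resid = y - fit.fittedvalues
    else:
        glm_family = (
            sm.families.Binomial() if family == "bernoulli" else sm.families.Poisson()
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                fit = sm.GLM(y, X, family=glm_family).fit(maxiter=200)
        except Exception as exc:  # separation, singular design, non-convergence
            raise ScoreComputationError(
                f"{family} GLM fit failed for covariates {covariates.names}: {exc}"
            ) from exc
        if not fit.converged:
            raise ScoreComputationError(
                f"{family} GLM did not converge for covariates {covariates.names}; "
                "check for separation or collinearity"
            )
        resid = y - fit.fittedvalues
    return ScoreVector(values=np.asarray(resid), origin="computed")


def load_scores(path: str | Path, expected_n: int | None = None) -> ScoreVector:
    """Read user-supplied scores: one value per line, or `subject<TAB>score`.

    Values are taken verbatim (no centering); lines starting with '#' are
    skipped. Order must match the dataset's subject order.
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            token = fields[-1]
            try:
                values.append(float(token))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric score {token!r}"
                ) from exc
    if expected_n is not None and len(values) != expected_n:
        raise ValueError(
            f"{path}: {len(values)} scores but {expected_n} subjects expected"
        )
    return ScoreVector(values=np.array(values), origin="user_supplied")


def write_scores(
    scores: ScoreVector, path: str | Path, subject_ids: list[str] | None = None
) -> None:
    """Write scores in the dialect `load_scores` reads (full repr precision)."""
    path = Path(path)
    with path.open("w") as fh:
        if subject_ids is not None:
            fh.write("#subject_id\tscore\n")
            for sid, v in zip(subject_ids, scores.values):
                fh.write(f"{sid}\t{float(v)!r}\n")
        else:
            for v in scores.values:
                fh.write(f"{float(v)!r}\n")
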