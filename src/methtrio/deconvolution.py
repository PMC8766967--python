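"""Per-subject mixture deconvolution of buffy-coat methylomes.

For each subject the buffy-coat beta profile is regressed on the profiles of
its two isolated fractions,

    buffy ~ w_P * PMN + w_L * lymphocyte + error,

by ordinary least squares *without* an intercept and without sum-to-one or
nonnegativity constraints.  When the buffy coat really is the mixture of its
fractions, the fitted coefficients recover the differential blood count and
their sum lands just below 1 (measurement noise in the regressors attenuates
both coefficients slightly).

The module follows the statsmodels idiom: :class:`MixtureModel` is built
from data, its :meth:`~MixtureModel.fit` returns :class:`MixtureResults`
carrying per-subject estimates, diagnostics and a ``summary()`` table, and
residual/discordance computations hang off the results object.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DesignError, SingularFitError
from .io import BetaMatrix, TrioDesign, align

logger = logging.getLogger(__name__)

#: Condition-number ceiling beyond which the two fraction profiles are
#: treated as collinear and the fit refused.
CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class MixtureFit:
    """Unconstrained two-component mixture fit for one subject."""

    subject_id: str
    w_pmn: float
    w_lymph: float
    residual_sd: float
    n_probes_used: int

    @property
    def coefficient_sum(self) -> float:
        return self.w_pmn + self.w_lymph


def fit_subject_mixture(
    buffy: np.ndarray,
    pmn: np.ndarray,
    lymph: np.ndarray,
    subject_id: str = "subject",
) -> MixtureFit:
    """OLS fit of one subject's buffy profile on its fraction profiles.

    Rows with a missing value in any of the three vectors are dropped
    (complete-case).  Raises :class:`SingularFitError` when the two fraction
    profiles are collinear beyond ``CONDITION_LIMIT`` and :class:`DataError`
    with fewer than two usable probes.
    """
    y = np.asarray(buffy, dtype=float)
    x1 = np.asarray(pmn, dtype=float)
    x2 = np.asarray(lymph, dtype=float)
    if not (y.shape == x1.shape == x2.shape):
        raise DataError("buffy, pmn and lymphocyte vectors must share length")
    keep = np.isfinite(y) & np.isfinite(x1) & np.isfinite(x2)
    y, x1, x2 = y[keep], x1[keep], x2[keep]
    n = y.size
    if n < 2:
        raise DataError(f"subject {subject_id!r}: fewer than 2 complete probes")
    X = np.column_stack([x1, x2])
    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise SingularFitError(
            f"subject {subject_id!r}: fraction profiles collinear "
            f"(condition number {cond:.3g})"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ddof = min(2, n - 1)
    residual_sd = float(np.sqrt((resid @ resid) / max(n - 2, 1))) if n > 2 else float(
        np.std(resid, ddof=ddof)
    )
    w_pmn, w_lymph = float(coef[0]), float(coef[1])
    if not (0.0 <= w_pmn <= 1.0 and 0.0 <= w_lymph <= 1.0):
        warnings.warn(
            f"subject {subject_id!r}: mixture coefficient outside [0, 1] "
            f"(w_pmn={w_pmn:.4f}, w_lymph={w_lymph:.4f}); reported unclipped",
            stacklevel=2,
        )
    return MixtureFit(subject_id, w_pmn, w_lymph, residual_sd, n)


class MixtureModel:
    """Cohort-level mixture deconvolution model.

    Parameters
    ----------
    beta
        Post-QC beta matrix containing every sample the design references.
    design
        Trio design mapping subjects to their three samples.
    """

    def __init__(self, beta: BetaMatrix, design: TrioDesign):
        beta, design, _ = align(beta, design)
        self.beta = beta
        self.design = design

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, design: TrioDesign) -> "MixtureModel":
        return cls(BetaMatrix(values), design)

    def fit(self) -> "MixtureResults":
        """Fit every subject; failures are recorded, not fatal."""
        fits: list[MixtureFit] = []
        failures: dict[str, str] = {}
        v = self.beta.values
        for s in self.design.subjects:
            try:
                fits.append(
                    fit_subject_mixture(
                        v[s.buffy].to_numpy(),
                        v[s.pmn].to_numpy(),
                        v[s.lymphocyte].to_numpy(),
                        subject_id=s.subject_id,
                    )
                )
            except (SingularFitError, DataError) as exc:
                logger.warning("mixture fit failed: %s", exc)
                failures[s.subject_id] = str(exc)
        return MixtureResults(self, fits, failures)


class MixtureResults:
    """Per-subject mixture estimates with diagnostics.

    ``weights`` tabulates the fitted coefficients — interpretable as each
    subject's differential blood count — together with their sum and the
    residual standard deviation of the fit.
    """

    def __init__(self, model: MixtureModel, fits: list[MixtureFit], failures: dict[str, str]):
        self.model = model
        self.fits = fits
        self.failures = failures

    @property
    def weights(self) -> pd.DataFrame:
        rows = {
            f.subject_id: {
                "w_pmn": f.w_pmn,
                "w_lymph": f.w_lymph,
                "coefficient_sum": f.coefficient_sum,
                "residual_sd": f.residual_sd,
                "n_probes_used": f.n_probes_used,
            }
            for f in self.fits
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "subject_id"
        return df

    def fit_for(self, subject_id: str) -> MixtureFit:
        for f in self.fits:
            if f.subject_id == subject_id:
                return f
        raise DesignError(f"no mixture fit for subject {subject_id!r}")

    def residuals(self):
        """Probe × subject residual matrix r = buffy − (w_P·pmn + w_L·lymph)."""
        from .discordance import compute_residuals

        return compute_residuals(self.model.beta, self.model.design, self)

    def summary(self) -> str:
        w = self.weights
        lines = [
            "Mixture deconvolution (OLS, no intercept, unconstrained)",
            f"subjects fitted: {len(self.fits)}   failed: {len(self.failures)}",
            f"probes per fit: {int(w['n_probes_used'].min())}"
            f"-{int(w['n_probes_used'].max())}" if len(self.fits) else "",
            "",
            w.to_string(float_format=lambda x: f"{x:.4f}"),
        ]
        if self.failures:
            lines += ["", "failures:"] + [f"  {k}: {v}" for k, v in self.failures.items()]
        return "\n".join(line for line in lines if line is not None)


def fit_cohort(matrix: BetaMatrix, design: TrioDesign) -> MixtureResults:
    """Functional entry point: one :class:`MixtureFit` per subject."""
    return MixtureModel(matrix, design).fit()
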