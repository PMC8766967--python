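"""Residual-based discordance detection.

For every probe and subject the model residual

    r = beta_buffy − (w_P · beta_pmn + w_L · beta_lymph)

measures how far the observed buffy-coat value departs from the fitted
mixture of its isolated fractions.  Residuals are pooled across all probes
and subjects, standardized, and trios whose |z| exceeds the two-sided
Bonferroni-corrected normal cutoff are flagged discordant.  Probes are then
partitioned into *discordant* (at least one flagged trio — each probe is
counted once regardless of how many trios flag it), *peak* (any residual in
the extreme-negative cluster below ``peak_threshold``) and *concordant*.

The Bonferroni denominator is the number of analyzed probes, not probes ×
subjects: with 412,481 probes at family level 0.05 the two-sided normal
critical value is 5.29, whereas the probes×subjects denominator would give
≈5.87.  The denominator is configurable via ``n_tests``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateDistributionError, DesignError
from .io import BetaMatrix, TrioDesign
from ._util import percent

logger = logging.getLogger(__name__)

DEFAULT_PEAK_THRESHOLD = -0.6


@dataclass
class ResidualMatrix:
    """Probe × subject mixture residuals with their standardization."""

    residuals: pd.DataFrame  # probes × subjects
    mu: float | None = None
    sigma: float | None = None
    zscores: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def probe_ids(self) -> pd.Index:
        return self.residuals.index

    @property
    def subject_ids(self) -> pd.Index:
        return self.residuals.columns

    def standardize(self, robust: bool = False) -> "ResidualMatrix":
        """Pool all finite residuals and attach z = (r − μ)/σ.

        ``robust=True`` swaps mean/sd for median/1.4826·MAD — a sensitivity
        knob, since gross outliers inflate the plain σ.
        """
        arr = self.residuals.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size < 2:
            raise DegenerateDistributionError("fewer than 2 finite residuals")
        if robust:
            mu = float(np.median(finite))
            sigma = float(1.4826 * np.median(np.abs(finite - mu)))
        else:
            mu = float(np.mean(finite))
            sigma = float(np.std(finite, ddof=1))
        if sigma == 0.0:
            raise DegenerateDistributionError("residual spread is zero")
        self.mu, self.sigma = mu, sigma
        self.zscores = (self.residuals - mu) / sigma
        return self


@dataclass
class DiscordancePartition:
    """Trio-level flags and the probe-level discordant/peak/concordant split.

    Trio- and probe-level counts are kept strictly separate: ``n_discordant_trios``
    counts flagged (probe, subject) pairs, while the probe sets count each
    probe once.
    """

    discordant_trios: set[tuple[str, str]]
    discordant_probes: pd.Index
    peak_probes: pd.Index
    concordant_probes: pd.Index
    z_cutoff: float
    n_tests: int
    n_probes: int
    n_subjects: int
    n_positive_flagged: int
    n_negative_flagged: int

    @property
    def n_discordant_trios(self) -> int:
        return len(self.discordant_trios)

    @property
    def pct_discordant_trios(self) -> float:
        """Flagged trios as a percentage of probes × subjects (2 dp)."""
        return percent(self.n_discordant_trios, self.n_probes * self.n_subjects)

    def counts(self) -> dict:
        return {
            "n_probes": self.n_probes,
            "n_subjects": self.n_subjects,
            "n_discordant_trios": self.n_discordant_trios,
            "pct_discordant_trios": self.pct_discordant_trios,
            "n_discordant_probes": int(len(self.discordant_probes)),
            "n_peak_probes": int(len(self.peak_probes)),
            "n_concordant_probes": int(len(self.concordant_probes)),
            "n_flagged_negative": self.n_negative_flagged,
            "n_flagged_positive": self.n_positive_flagged,
            "z_cutoff": self.z_cutoff,
            "n_tests": self.n_tests,
        }


def compute_residuals(matrix: BetaMatrix, design: TrioDesign, fits) -> ResidualMatrix:
    """Apply each subject's fitted weights to every probe trio.

    ``fits`` may be a :class:`~methtrio.deconvolution.MixtureResults` or a
    plain list of :class:`~methtrio.deconvolution.MixtureFit`.  Subjects in
    the design without a fit raise :class:`DesignError`; missing betas yield
    missing residuals.
    """
    fit_list = getattr(fits, "fits", fits)
    by_subject = {f.subject_id: f for f in fit_list}
    missing = [s.subject_id for s in design.subjects if s.subject_id not in by_subject]
    if missing:
        raise DesignError(f"no mixture fit for subject(s): {missing}")
    v = matrix.values
    cols = {}
    for s in design.subjects:
        f = by_subject[s.subject_id]
        cols[s.subject_id] = (
            v[s.buffy] - (f.w_pmn * v[s.pmn] + f.w_lymph * v[s.lymphocyte])
        )
    residuals = pd.DataFrame(cols, index=v.index)
    residuals.columns.name = "subject_id"
    return ResidualMatrix(residuals)


def bonferroni_z_cutoff(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Two-sided standard-normal critical value at family level ``alpha``
    over ``n_tests`` tests: the upper quantile at 1 − alpha/(2·n_tests)."""
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha={alpha} outside (0, 1)")
    if n_tests < 1:
        raise ConfigError("n_tests must be >= 1")
    return float(stats.norm.isf(alpha / (2.0 * n_tests)))


def classify_peak_probes(
    residuals: ResidualMatrix, peak_threshold: float = DEFAULT_PEAK_THRESHOLD
) -> pd.Index:
    """Probes whose minimum residual over subjects falls below the peak
    threshold; each probe appears once."""
    min_res = residuals.residuals.min(axis=1)
    return min_res.index[min_res < peak_threshold]


def standardize_and_flag(
    residuals: ResidualMatrix,
    alpha: float = 0.05,
    n_tests: int | None = None,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
    robust: bool = False,
) -> DiscordancePartition:
    """Standardize pooled residuals and flag trios beyond the Bonferroni cutoff.

    ``n_tests`` defaults to the number of analyzed probes (probes with at
    least one finite residual).
    """
    residuals.standardize(robust=robust)
    r = residuals.residuals
    z = residuals.zscores
    analyzed = r.index[r.notna().any(axis=1)]
    if n_tests is None:
        n_tests = len(analyzed)
    cutoff = bonferroni_z_cutoff(alpha, n_tests)

    flagged_mask = z.abs() > cutoff
    flagged = flagged_mask & z.notna()
    probe_any = flagged.any(axis=1)
    discordant_probes = analyzed.intersection(probe_any.index[probe_any], sort=False)

    flat_f = flagged.to_numpy()
    ii, jj = np.where(flat_f)
    trios = set(zip(r.index[ii], r.columns[jj]))

    flat_z = z.to_numpy()
    n_neg = int((flat_f & (flat_z < 0)).sum())
    n_pos = int((flat_f & (flat_z > 0)).sum())

    peak = classify_peak_probes(residuals, peak_threshold)
    concordant = analyzed.difference(discordant_probes, sort=False)
    part = DiscordancePartition(
        discordant_trios=trios,
        discordant_probes=discordant_probes,
        peak_probes=peak,
        concordant_probes=concordant,
        z_cutoff=cutoff,
        n_tests=n_tests,
        n_probes=len(analyzed),
        n_subjects=r.shape[1],
        n_positive_flagged=n_pos,
        n_negative_flagged=n_neg,
    )
    logger.info(
        "discordance: %d trios flagged (%s%%), %d discordant probes, "
        "%d peak probes, z cutoff %.2f",
        part.n_discordant_trios, part.pct_discordant_trios,
        len(discordant_probes), len(peak), cutoff,
    )
    return part


def remove_discordant(matrix: BetaMatrix, partition: DiscordancePartition) -> BetaMatrix:
    """Restrict the matrix to concordant probes; the count identity
    n_in = n_concordant + n_discordant is asserted and logged."""
    discordant = matrix.probe_ids.intersection(partition.discordant_probes, sort=False)
    keep = matrix.probe_ids.difference(discordant, sort=False)
    out = matrix.subset_probes(keep)
    assert matrix.n_probes == out.n_probes + len(discordant)
    logger.info(
        "remove_discordant: %d in, %d discordant, %d out",
        matrix.n_probes, len(discordant), out.n_probes,
    )
    return out


def residual_histogram(
    residuals: ResidualMatrix, bin_width: float = 0.001,
    lo: float = -1.2, hi: float = 1.2,
) -> dict:
    """Histogram of all finite residuals at fixed bin width (default 0.001)."""
    arr = residuals.residuals.to_numpy(dtype=float)
    finite = arr[np.isfinite(arr)]
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(finite, bins=edges)
    return {"bin_width": bin_width, "lo": lo, "hi": hi, "counts": counts.tolist()}
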