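"""Call-rate quality control and beta-distribution summaries.

A call is *unreliable* when its detection p-value exceeds ``p_threshold``.
A probe (and then, on the reduced matrix, a sample) is excluded when its
fraction of unreliable calls exceeds ``fail_fraction`` — the probe-first
order reflects that array QC is dominated by probe exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import BetaMatrix


@dataclass
class QcReport:
    n_probes_in: int
    n_probes_out: int
    n_samples_in: int
    n_samples_out: int
    p_threshold: float
    fail_fraction: float
    per_probe_call_rate: pd.Series = field(repr=False, default=None)
    per_sample_call_rate: pd.Series = field(repr=False, default=None)
    skipped: bool = False

    def __post_init__(self) -> None:
        assert self.n_probes_out <= self.n_probes_in
        assert self.n_samples_out <= self.n_samples_in

    def to_dict(self) -> dict:
        return {
            "skipped": self.skipped,
            "n_probes_in": self.n_probes_in,
            "n_probes_out": self.n_probes_out,
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "p_threshold": self.p_threshold,
            "fail_fraction": self.fail_fraction,
        }


def filter_by_call_rate(
    matrix: BetaMatrix, p_threshold: float = 0.01, fail_fraction: float = 0.05
) -> tuple[BetaMatrix, QcReport]:
    """Drop probes, then samples, whose unreliable-call fraction exceeds
    ``fail_fraction``.

    Without detection p-values the matrix passes through unchanged and the
    report is marked ``skipped`` — QC is never silently invented.
    """
    for name, v in (("p_threshold", p_threshold), ("fail_fraction", fail_fraction)):
        if not 0.0 < v < 1.0:
            raise ConfigError(f"{name}={v} outside (0, 1)")
    if matrix.detection_pvalues is None:
        report = QcReport(
            matrix.n_probes, matrix.n_probes, matrix.n_samples, matrix.n_samples,
            p_threshold, fail_fraction, skipped=True,
        )
        return matrix, report

    unreliable = matrix.detection_pvalues > p_threshold
    probe_fail = unreliable.mean(axis=1)
    keep_probes = probe_fail[probe_fail <= fail_fraction].index
    reduced = matrix.subset_probes(keep_probes)

    sample_fail = (reduced.detection_pvalues > p_threshold).mean(axis=0)
    keep_samples = sample_fail[sample_fail <= fail_fraction].index
    out = reduced.subset_samples(keep_samples)

    report = QcReport(
        n_probes_in=matrix.n_probes,
        n_probes_out=out.n_probes,
        n_samples_in=matrix.n_samples,
        n_samples_out=out.n_samples,
        p_threshold=p_threshold,
        fail_fraction=fail_fraction,
        per_probe_call_rate=1.0 - probe_fail,
        per_sample_call_rate=1.0 - sample_fail,
    )
    return out, report


def beta_density_summary(matrix: BetaMatrix, n_bins: int = 101) -> dict:
    """Binned per-sample beta densities plus a bimodality index.

    The bimodality index is the fraction of a sample's values lying in
    [0, 0.2] ∪ [0.8, 1]; strongly bimodal methylation data score >= 0.6.
    """
    if matrix.n_probes == 0 or matrix.n_samples == 0:
        raise ConfigError("beta_density_summary requires a non-empty matrix")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    densities = {}
    bimodality = {}
    for sample in matrix.sample_ids:
        col = matrix.values[sample].dropna().to_numpy()
        hist, _ = np.histogram(col, bins=edges, density=True)
        densities[sample] = hist
        extreme = ((col <= 0.2) | (col >= 0.8)).mean() if col.size else np.nan
        bimodality[sample] = float(extreme)
    return {
        "bin_edges": edges,
        "densities": pd.DataFrame(densities, index=pd.RangeIndex(n_bins, name="bin")),
        "bimodality": pd.Series(bimodality, name="bimodality_fraction"),
    }
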