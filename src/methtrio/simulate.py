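"""Synthetic trio cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* per-probe baseline methylation drawn from a bimodal mixture (most probes
  near 0 or near 1, a minority intermediate), identical for both isolated
  cell types;
* a configurable fraction of probes truly differentially methylated between
  PMN leukocytes and lymphocytes, with effect sizes |Δβ| in ``delta_range``;
* per-subject mixing weights w_L ~ Uniform(lymph_weight_range),
  w_P = 1 − w_L, so each buffy-coat profile is the weighted sum of its
  fractions plus additive truncated-Gaussian measurement noise;
* injected discordance: probes (biased toward open-sea, low-GC context and
  restricted to unmethylated baselines) at which the two *isolated* fractions
  gain methylation up to ``discordance_effect`` while the buffy coat keeps
  its pre-separation state — the signature that produces large negative
  mixture residuals.

Everything is driven by a single :class:`numpy.random.Generator` stream
seeded from ``SimulationConfig.seed``, so a cohort is reproducible as a unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import REGION_CLASSES, BetaMatrix, TrioDesign, TrioSubject

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_methylomes",
    "generate_cohort",
    "inject_discordance",
    "simulate_cohort",
]

#: Baseline probe-mean mixture: (weight, sampler) for the low / high /
#: intermediate components.  ~90% of probe means land near the extremes,
#: matching the bimodal beta-value densities seen on methylation arrays.
_MIX_WEIGHTS = (0.45, 0.45, 0.10)

#: Mean GC fraction by region class (islands are the most GC dense).
_GC_MEAN = {"island": 0.65, "shore": 0.55, "shelf": 0.47, "open_sea": 0.40}
_GC_SD = 0.06

#: Probes with baseline mean below this are treated as unmethylated and are
#: eligible for an unmethylated→methylated switch injection.
_UNMETHYLATED_CEILING = 0.30

#: Rate of multi-mapped 50-mers among simulated probes.
_MULTIMAP_RATE = 5e-4


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of a synthetic trio cohort.

    Defaults describe the study conditions the package is designed around:
    29 subjects, ~30% of probes truly different between PMN and lymphocytes,
    lymphocyte weights of 20–40%, and a small set of injected discordant
    probes with near-complete methylation gain in the isolated fractions.
    """

    n_subjects: int = 29
    n_probes: int = 20_000
    seed: int = 0
    frac_dmp_pl: float = 0.30
    delta_range: tuple[float, float] = (0.1, 0.5)
    lymph_weight_range: tuple[float, float] = (0.20, 0.40)
    noise_sd: float = 0.02
    n_discordant_probes: int = 200
    discordance_effect: float = 0.9
    region_weights: Mapping[str, float] = field(
        default_factory=lambda: {"open_sea": 3.0, "shelf": 2.0, "shore": 1.0, "island": 0.5}
    )
    region_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"island": 0.31, "shore": 0.23, "shelf": 0.10, "open_sea": 0.36}
    )
    #: Optional third, unmodeled cell component (its weight is taken out of
    #: w_P) for robustness experiments; 0 keeps w_P + w_L = 1 exactly.
    other_cell_fraction: float = 0.0
    #: "gain": isolated fractions gain methylation only (asymmetric negative
    #: residual peak).  "symmetric": half the injected probes instead raise
    #: the buffy coat, for null calibration.
    injection_mode: str = "gain"
    #: Fraction of subjects affected at each injected probe (1.0 = all).
    injection_subject_fraction: float = 1.0
    #: If > 0, simulate per-call detection p-values with this failure rate.
    detection_fail_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_probes < 2:
            raise ConfigError("need at least 1 subject and 2 probes")
        for name in ("frac_dmp_pl", "noise_sd", "other_cell_fraction",
                     "injection_subject_fraction", "detection_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.discordance_effect <= 1.0:
            raise ConfigError("discordance_effect outside [0, 1]")
        for name in ("delta_range", "lymph_weight_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(f"{name}=({lo}, {hi}) is not an ordered range in [0, 1]")
        if self.n_discordant_probes < 0:
            raise ConfigError("n_discordant_probes must be >= 0")
        if self.n_discordant_probes > self.n_probes:
            raise ConfigError("n_discordant_probes exceeds n_probes")
        if set(self.region_weights) != set(REGION_CLASSES):
            raise ConfigError("region_weights must cover exactly the 4 region classes")
        if any(w <= 0 for w in self.region_weights.values()):
            raise ConfigError("region_weights must be positive")
        if set(self.region_proportions) != set(REGION_CLASSES):
            raise ConfigError("region_proportions must cover exactly the 4 region classes")
        if abs(sum(self.region_proportions.values()) - 1.0) > 1e-9:
            raise ConfigError("region_proportions must sum to 1")
        if self.injection_mode not in ("gain", "symmetric"):
            raise ConfigError("injection_mode must be 'gain' or 'symmetric'")


@dataclass
class SyntheticTruth:
    """Generating parameters sufficient to score any downstream recovery.

    ``true_dmp`` marks, per comparison label, the probes whose *pre-injection*
    population means differ between the compared quantities (for BP and BL the
    buffy coat inherits any PMN/lymphocyte difference through the mixture, so
    the three columns coincide with the set of shifted probes).
    """

    true_pmn_beta: pd.Series
    true_lymph_beta: pd.Series
    weights: pd.DataFrame  # index subject_id, columns w_pmn, w_lymph
    true_dmp: pd.DataFrame  # index probe_id, bool columns BP, BL, PL
    injected: pd.DataFrame  # probe_id-indexed: affected, direction
    buffy_true: pd.DataFrame  # probe × subject pre-injection buffy means

    @property
    def injected_probe_ids(self) -> pd.Index:
        return self.injected.index


@dataclass
class SyntheticCohort:
    beta: BetaMatrix
    design: TrioDesign
    annotation: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig
    _rng: np.random.Generator | None = None


def _draw_annotation(config: SimulationConfig, rng: np.random.Generator,
                     probe_ids: pd.Index) -> pd.DataFrame:
    classes = list(REGION_CLASSES)
    probs = np.array([config.region_proportions[c] for c in classes])
    region = rng.choice(classes, size=config.n_probes, p=probs / probs.sum())
    gc = np.clip(
        rng.normal([_GC_MEAN[r] for r in region], _GC_SD), 0.05, 0.95
    )
    unique = rng.random(config.n_probes) >= _MULTIMAP_RATE
    chrom = rng.integers(1, 23, size=config.n_probes)
    position = rng.integers(1, 2**27, size=config.n_probes)
    return pd.DataFrame(
        {
            "chromosome": [f"chr{c}" for c in chrom],
            "position": position,
            "region_class": region,
            "gc_fraction": gc,
            "unique_mapping": unique,
        },
        index=probe_ids,
    )


def generate_methylomes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Draw the two cell-type methylomes and the probe annotation.

    Baselines come from a three-component mixture (low Beta(1,10), high
    Beta(10,1), intermediate Uniform(0.2, 0.8)); a ``frac_dmp_pl`` subset of
    probes has the lymphocyte mean shifted by ± a draw from ``delta_range``.
    The shift direction is drawn uniformly among directions that keep the
    mean inside [0, 1], so the realized effect never collapses by clipping.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_probes
    probe_ids = pd.Index([f"cg{i:07d}" for i in range(n)], name="probe_id")

    comp = rng.choice(3, size=n, p=_MIX_WEIGHTS)
    base = np.empty(n)
    base[comp == 0] = rng.beta(1.0, 10.0, size=int((comp == 0).sum()))
    base[comp == 1] = rng.beta(10.0, 1.0, size=int((comp == 1).sum()))
    base[comp == 2] = rng.uniform(0.2, 0.8, size=int((comp == 2).sum()))

    dmp = rng.random(n) < config.frac_dmp_pl
    delta = rng.uniform(*config.delta_range, size=n)
    coin = rng.random(n) < 0.5
    up_ok = base + delta <= 1.0
    down_ok = base - delta >= 0.0
    sign = np.where(up_ok & down_ok, np.where(coin, 1.0, -1.0),
                    np.where(up_ok, 1.0, -1.0))
    lymph = np.clip(base + np.where(dmp, sign * delta, 0.0), 0.0, 1.0)

    annotation = _draw_annotation(config, rng, probe_ids)
    pmn = pd.Series(base, index=probe_ids, name="pmn")
    lymph = pd.Series(lymph, index=probe_ids, name="lymphocyte")
    return pmn, lymph, annotation


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full measured cohort (no discordance injected yet).

    For each subject, w_L ~ Uniform(lymph_weight_range) and
    w_P = 1 − w_L − other_cell_fraction; the true buffy-coat profile is the
    weighted sum of the (true) fraction profiles, computed *before* any
    injection.  Measured betas add truncated Gaussian(0, noise_sd) noise,
    clipped to [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    pmn, lymph, annotation = generate_methylomes(config, rng)
    probe_ids = pmn.index

    subject_ids = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    w_l = rng.uniform(*config.lymph_weight_range, size=config.n_subjects)
    w_p = 1.0 - w_l - config.other_cell_fraction
    weights = pd.DataFrame({"w_pmn": w_p, "w_lymph": w_l}, index=pd.Index(subject_ids, name="subject_id"))

    buffy_true = np.outer(pmn.to_numpy(), w_p) + np.outer(lymph.to_numpy(), w_l)
    if config.other_cell_fraction > 0:
        other = np.where(rng.random(config.n_probes) < 0.5,
                         rng.beta(1.0, 10.0, config.n_probes),
                         rng.beta(10.0, 1.0, config.n_probes))
        buffy_true = buffy_true + np.outer(other, np.full(config.n_subjects, config.other_cell_fraction))

    def measure(true: np.ndarray) -> np.ndarray:
        return np.clip(true + rng.normal(0.0, config.noise_sd, size=true.shape), 0.0, 1.0)

    n_s = config.n_subjects
    meas_buffy = measure(buffy_true)
    meas_pmn = measure(np.tile(pmn.to_numpy()[:, None], (1, n_s)))
    meas_lymph = measure(np.tile(lymph.to_numpy()[:, None], (1, n_s)))
    if config.noise_sd == 0.0:
        meas_buffy, meas_pmn, meas_lymph = (
            buffy_true.copy(),
            np.tile(pmn.to_numpy()[:, None], (1, n_s)),
            np.tile(lymph.to_numpy()[:, None], (1, n_s)),
        )

    columns, data = [], []
    subjects = []
    for j, sid in enumerate(subject_ids):
        trio = {
            f"{sid}_buffy": meas_buffy[:, j],
            f"{sid}_pmn": meas_pmn[:, j],
            f"{sid}_lymphocyte": meas_lymph[:, j],
        }
        columns.extend(trio.keys())
        data.extend(trio.values())
        subjects.append(
            TrioSubject(sid, f"{sid}_buffy", f"{sid}_pmn", f"{sid}_lymphocyte")
        )
    values = pd.DataFrame(np.column_stack(data), index=probe_ids, columns=columns)

    detp = None
    if config.detection_fail_rate > 0:
        fails = rng.random(values.shape) < config.detection_fail_rate
        detp = pd.DataFrame(
            np.where(fails, rng.uniform(0.02, 0.5, size=values.shape), 0.0),
            index=values.index, columns=values.columns,
        )

    dmp = (pmn - lymph).abs() > 1e-12
    truth = SyntheticTruth(
        true_pmn_beta=pmn,
        true_lymph_beta=lymph,
        weights=weights,
        true_dmp=pd.DataFrame({lab: dmp for lab in ("BP", "BL", "PL")}),
        injected=pd.DataFrame(columns=["affected", "direction"]),
        buffy_true=pd.DataFrame(buffy_true, index=probe_ids, columns=subject_ids),
    )
    return SyntheticCohort(
        beta=BetaMatrix(values, detp),
        design=TrioDesign(tuple(subjects)),
        annotation=annotation,
        truth=truth,
        config=config,
        _rng=rng,
    )


def inject_discordance(cohort: SyntheticCohort,
                       config: SimulationConfig | None = None) -> SyntheticCohort:
    """Inject discordant probes into a measured cohort.

    Probes are sampled without replacement among unmethylated baselines
    (mean fraction beta < 0.3) with probability proportional to their
    region weight times an inverse-GC-rank factor, then the measured PMN and
    lymphocyte betas of the affected subjects are raised to
    ``discordance_effect`` (plus measurement noise) while the buffy coat is
    left untouched.
    """
    if config is None:
        config = cohort.config
    if config.n_discordant_probes == 0:
        return cohort
    if config.n_discordant_probes > config.n_probes:
        raise ConfigError("n_discordant_probes exceeds n_probes")
    rng = cohort._rng if cohort._rng is not None else np.random.default_rng(config.seed + 1)

    truth = cohort.truth
    base_mean = (truth.true_pmn_beta + truth.true_lymph_beta) / 2.0
    eligible = base_mean.index[base_mean < _UNMETHYLATED_CEILING]
    if config.n_discordant_probes > len(eligible):
        raise ConfigError(
            f"only {len(eligible)} unmethylated probes eligible for injection, "
            f"need {config.n_discordant_probes}"
        )
    ann = cohort.annotation.loc[eligible]
    region_w = ann["region_class"].map(config.region_weights).to_numpy(float)
    # inverse GC rank *within* each region, so the low-GC preference does not
    # double-count the region preference (GC correlates with region class)
    gc_rank = ann.groupby("region_class")["gc_fraction"].rank(method="first")
    n_in_region = ann.groupby("region_class")["gc_fraction"].transform("size")
    inv_gc = ((n_in_region - gc_rank + 1.0) / n_in_region).to_numpy()
    p = region_w * inv_gc
    chosen = rng.choice(eligible.to_numpy(), size=config.n_discordant_probes,
                        replace=False, p=p / p.sum())

    values = cohort.beta.values.copy()
    arr = values.to_numpy()
    row_of = {p: i for i, p in enumerate(values.index)}
    col_of = {c: i for i, c in enumerate(values.columns)}
    n_affected = max(1, round(config.injection_subject_fraction * cohort.design.n_subjects))
    records = []
    half = set()
    if config.injection_mode == "symmetric":
        half = set(rng.choice(chosen, size=len(chosen) // 2, replace=False))
    for probe in chosen:
        subjects = list(cohort.design.subjects)
        if n_affected < len(subjects):
            idx = rng.choice(len(subjects), size=n_affected, replace=False)
            subjects = [subjects[i] for i in idx]
        raise_buffy = probe in half
        cols = [
            col_of[c]
            for s in subjects
            for c in ((s.buffy,) if raise_buffy else (s.pmn, s.lymphocyte))
        ]
        noise = rng.normal(0.0, config.noise_sd, size=len(cols))
        arr[row_of[probe], cols] = np.clip(
            config.discordance_effect + noise, 0.0, 1.0
        )
        records.append(
            {
                "probe_id": probe,
                "affected": "buffy" if raise_buffy else "pmn+lymphocyte",
                "direction": "gain",
            }
        )
    values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    injected = pd.DataFrame(records).set_index("probe_id")
    new_truth = replace(truth, injected=injected)
    detp = cohort.beta.detection_pvalues
    return SyntheticCohort(
        beta=BetaMatrix(values, detp),
        design=cohort.design,
        annotation=cohort.annotation,
        truth=new_truth,
        config=config,
        _rng=rng,
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """generate_cohort followed by inject_discordance — the default recipe."""
    return inject_discordance(generate_cohort(config))
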