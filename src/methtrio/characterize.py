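"""Genomic characterization of discordant vs concordant probes.

Three questions, mirroring how array artifacts are usually triaged:
does discordance track multi-mapped 50-mers (uniqueness fractions)?  does it
track probe GC content (Welch comparison in percentage points)?  and is it
enriched in particular CpG-region classes (per-class 2×2 Pearson chi-squared
against a reference pool)?

Probe groups are deduplicated before counting — each probe counts once no
matter how many trios flagged it.  By default the reference is the pool of
*all* probes (the group is a subset of its own reference, matching how the
discordant-vs-all comparison is usually reported); ``disjoint_reference=True``
tests group vs complement instead, which is statistically cleaner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnnotationError, DataError
from .io import REGION_CLASSES
from ._util import round_sig


def percent_unique(n: int, n_multi: int) -> float:
    """Percentage of uniquely mapping probes, rounded to 4 significant digits."""
    if n <= 0:
        raise DataError("empty probe group")
    return round_sig(100.0 * (n - n_multi) / n, 4)


def _dedup(probes: Sequence) -> pd.Index:
    return pd.Index(probes).drop_duplicates()


def uniqueness_report(groups: dict[str, Sequence], annotation: pd.DataFrame) -> pd.DataFrame:
    """Per group: n, number multi-mapped, percent uniquely mapped (4 s.f.)."""
    if "unique_mapping" not in annotation.columns:
        raise AnnotationError("annotation lacks unique_mapping flags")
    rows = {}
    for name, probes in groups.items():
        idx = _dedup(probes)
        missing = idx.difference(annotation.index)
        if len(missing):
            raise AnnotationError(
                f"group {name!r}: probes without uniqueness flags: "
                f"{list(missing[:5])}"
            )
        flags = annotation.loc[idx, "unique_mapping"]
        n_multi = int((~flags).sum())
        rows[name] = {
            "n": len(idx),
            "n_multi_mapped": n_multi,
            "pct_unique": percent_unique(len(idx), n_multi),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def gc_comparison(group_a: Sequence, group_b: Sequence, annotation: pd.DataFrame) -> dict:
    """Mean GC per group, difference (a − b) in percentage points, Welch p."""
    if "gc_fraction" not in annotation.columns:
        raise AnnotationError("annotation lacks gc_fraction")
    a, b = _dedup(group_a), _dedup(group_b)
    if len(a) == 0 or len(b) == 0:
        raise DataError("gc_comparison requires two non-empty groups")
    gc_a = annotation.loc[a, "gc_fraction"].dropna()
    gc_b = annotation.loc[b, "gc_fraction"].dropna()
    if len(gc_a) < len(a) or len(gc_b) < len(b):
        raise AnnotationError("gc_fraction missing for some group probes")
    mean_a, mean_b = float(gc_a.mean()), float(gc_b.mean())
    if gc_a.var() == 0 and gc_b.var() == 0:
        p = 1.0 if mean_a == mean_b else 0.0
    else:
        p = float(stats.ttest_ind(gc_a, gc_b, equal_var=False).pvalue)
    return {
        "mean_gc_a": mean_a,
        "mean_gc_b": mean_b,
        "difference_pp": 100.0 * (mean_a - mean_b),
        "pvalue": p,
    }


@dataclass
class RegionEnrichment:
    """Per-region 2×2 chi-squared results for a probe group vs a reference."""

    table: pd.DataFrame  # index region class
    n_group: int
    n_reference: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["pvalue"] < alpha]


def region_proportion_tests(
    group_probes: Sequence,
    reference_probes: Sequence,
    annotation: pd.DataFrame,
    disjoint_reference: bool = False,
    yates: bool = False,
) -> RegionEnrichment:
    """Per-class Pearson chi-squared (1 df, no continuity correction unless
    ``yates``) of group vs reference region proportions.

    Expected cells below 5 attach a warning but the test is still computed.
    """
    group = _dedup(group_probes)
    reference = _dedup(reference_probes)
    if disjoint_reference:
        reference = reference.difference(group)
    for name, idx in (("group", group), ("reference", reference)):
        missing = idx.difference(annotation.index)
        if len(missing):
            raise AnnotationError(f"{name} probes lack annotation: {list(missing[:5])}")
    if len(group) == 0 or len(reference) == 0:
        raise DataError("region_proportion_tests requires non-empty groups")

    g_class = annotation.loc[group, "region_class"]
    r_class = annotation.loc[reference, "region_class"]
    rows = {}
    for cls in REGION_CLASSES:
        g_in = int((g_class == cls).sum())
        r_in = int((r_class == cls).sum())
        table = np.array(
            [[g_in, len(group) - g_in], [r_in, len(reference) - r_in]], dtype=float
        )
        low_expected = False
        if np.allclose(table[0] / table[0].sum(), table[1] / table[1].sum()):
            chi2, p = 0.0, 1.0
        elif (table.sum(0) > 0).all() and (table.sum(1) > 0).all():
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            low_expected = bool((expected < 5).any())
            chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
        else:
            chi2, p = np.nan, np.nan
        if low_expected:
            warnings.warn(
                f"region {cls}: expected cell below 5; chi-squared approximate",
                stacklevel=2,
            )
        prop_g = g_in / len(group)
        prop_r = r_in / len(reference)
        rows[cls] = {
            "count_group": g_in,
            "prop_group": prop_g,
            "count_reference": r_in,
            "prop_reference": prop_r,
            "chi2": float(chi2),
            "pvalue": float(p),
            "direction": "over" if prop_g > prop_r else ("under" if prop_g < prop_r else "equal"),
            "low_expected_cell": low_expected,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "region_class"
    assert int(table["count_group"].sum()) == len(group)
    return RegionEnrichment(table=table, n_group=len(group), n_reference=len(reference))
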