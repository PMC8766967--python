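"""Domain containers and text I/O.

The pipeline's universal currency is the :class:`BetaMatrix` — a probe ×
sample table of methylation fractions (beta values) in [0, 1], optionally
paired with a detection p-value matrix of identical shape.  Trios of samples
(buffy coat, PMN leukocytes, lymphocytes drawn from the same subject) are
described by a :class:`TrioDesign`; genomic probe context (CpG-island
relation, GC fraction, mappability-uniqueness) lives in a probe-annotation
``pandas.DataFrame`` validated by :func:`validate_annotation`.

All readers accept plain or gzip-compressed TSV/CSV; writers emit 6-decimal
text (the array's beta resolution is coarser).  Layout is fixed: probes as
rows, samples as columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    BetaValidationError,
    DesignError,
    FormatError,
    VocabularyError,
)

logger = logging.getLogger(__name__)

REGION_CLASSES = ("island", "shore", "shelf", "open_sea")

FRACTIONS = ("buffy", "pmn", "lymphocyte")
_FRACTION_ALIASES = {
    "buffy": "buffy",
    "buffy_coat": "buffy",
    "b": "buffy",
    "pmn": "pmn",
    "granulocyte": "pmn",
    "p": "pmn",
    "lymphocyte": "lymphocyte",
    "lymph": "lymphocyte",
    "l": "lymphocyte",
}

COMPARISON_LABELS = ("BP", "BL", "PL")
#: Closed vocabulary of pairwise comparisons: first fraction minus second.
COMPARISON_FRACTIONS = {
    "BP": ("buffy", "pmn"),
    "BL": ("buffy", "lymphocyte"),
    "PL": ("pmn", "lymphocyte"),
}

_MISSING_TOKENS = ["NA", ""]


def _region_vocab() -> dict[str, str]:
    with resources.files("methtrio.data").joinpath("region_vocab.json").open() as fh:
        return json.load(fh)


def normalize_region(token: object) -> str:
    """Map a manifest-style relation token (e.g. ``N_Shore``) to one of the
    four canonical region classes; empty/missing means open sea."""
    if token is None or (isinstance(token, float) and np.isnan(token)):
        token = ""
    token = str(token).strip()
    vocab = _region_vocab()
    if token not in vocab:
        raise VocabularyError(
            f"unknown CpG-region token {token!r}; expected one of {sorted(set(vocab))}"
        )
    return vocab[token]


# ---------------------------------------------------------------------------
# BetaMatrix


@dataclass
class BetaMatrix:
    """Probe × sample matrix of beta values in [0, 1].

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample-id columns.  NaN marks a
        missing call; every non-missing value must lie in [0, 1].
    detection_pvalues
        Optional per-call detection p-values with the exact same index and
        columns as ``values``.
    """

    values: pd.DataFrame
    detection_pvalues: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise BetaValidationError(f"duplicated probe id {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise BetaValidationError(f"duplicated sample id {dup!r}")
        arr = v.to_numpy(dtype=float)
        bad = np.isfinite(arr) & ((arr < 0.0) | (arr > 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BetaValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if np.isinf(arr).any():
            raise BetaValidationError("non-finite beta value present")
        if self.detection_pvalues is not None:
            d = self.detection_pvalues
            if not (d.index.equals(v.index) and d.columns.equals(v.columns)):
                raise BetaValidationError(
                    "detection p-value matrix does not share shape/ordering "
                    "with the beta matrix"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids: Sequence) -> "BetaMatrix":
        idx = self.values.index.intersection(pd.Index(probe_ids), sort=False)
        detp = None
        if self.detection_pvalues is not None:
            detp = self.detection_pvalues.loc[idx]
        return BetaMatrix(self.values.loc[idx], detp)

    def subset_samples(self, sample_ids: Sequence) -> "BetaMatrix":
        cols = self.values.columns.intersection(pd.Index(sample_ids), sort=False)
        detp = None
        if self.detection_pvalues is not None:
            detp = self.detection_pvalues[cols]
        return BetaMatrix(self.values[cols], detp)


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise FormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
        return "\t" if dialect == "tsv" else ","
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    return "," if name.endswith(".csv") else "\t"


def _read_matrix_table(path: str | Path, dialect: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path, dialect)
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0, na_values=_MISSING_TOKENS,
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed table: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: line 1: header has no sample columns")
    if any(str(c).startswith("Unnamed:") for c in df.columns):
        raise FormatError(f"{path}: line 1: empty sample id in header")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                probe = df.index[bad.to_numpy().argmax()]
                raise FormatError(
                    f"{path}: non-numeric cell {df.loc[probe, col]!r} at probe "
                    f"{probe!r}, sample {col!r}"
                )
            df[col] = coerced
    return df.astype(float)


def read_beta_matrix(
    path: str | Path,
    dialect: str | None = None,
    detection_path: str | Path | None = None,
) -> BetaMatrix:
    """Read a beta matrix (first column probe ids, header sample ids).

    A transposed table (samples as rows) is rejected rather than auto-fixed:
    the header heuristic fires when the row count is much smaller than the
    column count and row ids do not look like probe ids.
    """
    values = _read_matrix_table(path, dialect)
    if values.shape[0] < values.shape[1] and not any(
        str(i).lower().startswith(("cg", "ch.", "rs", "probe")) for i in values.index[:5]
    ):
        raise FormatError(
            f"{path}: table looks transposed (samples as rows); expected "
            "probes as rows, samples as columns"
        )
    detp = None
    if detection_path is not None:
        detp = _read_matrix_table(detection_path, dialect)
        detp = detp.loc[values.index, values.columns]
    return BetaMatrix(values, detp)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, dialect)
    matrix.values.to_csv(path, sep=sep, float_format="%.6f", index_label="probe_id")


# ---------------------------------------------------------------------------
# TrioDesign


@dataclass(frozen=True)
class TrioSubject:
    subject_id: str
    buffy: str
    pmn: str
    lymphocyte: str

    def sample_for(self, fraction: str) -> str:
        return getattr(self, fraction)


@dataclass
class TrioDesign:
    """Subject → (buffy, pmn, lymphocyte) sample mapping."""

    subjects: tuple[TrioSubject, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise DesignError("no subjects in trio design")
        seen_subjects: set[str] = set()
        seen_samples: set[str] = set()
        for s in self.subjects:
            if s.subject_id in seen_subjects:
                raise DesignError(f"duplicated subject id {s.subject_id!r}")
            seen_subjects.add(s.subject_id)
            for fraction in FRACTIONS:
                sid = s.sample_for(fraction)
                if sid in seen_samples:
                    raise DesignError(
                        f"sample {sid!r} appears in more than one subject/fraction"
                    )
                seen_samples.add(sid)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for s in self.subjects:
            out.extend([s.buffy, s.pmn, s.lymphocyte])
        return out

    def validate_against(self, matrix: BetaMatrix) -> None:
        missing = sorted(set(self.sample_ids) - set(matrix.sample_ids))
        if missing:
            raise DesignError(
                f"design samples absent from beta matrix: {missing[:5]}"
                + (" ..." if len(missing) > 5 else "")
            )


def read_trio_design(path: str | Path) -> TrioDesign:
    """Read a long-format CSV with columns subject_id, sample_id, fraction."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise DesignError(f"{path}: no subjects (empty file)") from exc
    required = {"subject_id", "sample_id", "fraction"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        raise DesignError(f"{path}: no subjects")
    subjects = []
    for subject_id, grp in df.groupby("subject_id", sort=False):
        fractions: dict[str, str] = {}
        for _, row in grp.iterrows():
            token = str(row["fraction"]).strip().lower()
            if token not in _FRACTION_ALIASES:
                raise VocabularyError(
                    f"{path}: unknown fraction {row['fraction']!r} for subject "
                    f"{subject_id!r}; expected one of {sorted(set(FRACTIONS))}"
                )
            fraction = _FRACTION_ALIASES[token]
            if fraction in fractions:
                raise DesignError(
                    f"{path}: subject {subject_id!r} has more than one "
                    f"{fraction!r} sample"
                )
            fractions[fraction] = str(row["sample_id"])
        missing = [f for f in FRACTIONS if f not in fractions]
        if missing:
            raise DesignError(
                f"{path}: subject {subject_id!r} is missing fraction(s) {missing}"
            )
        subjects.append(TrioSubject(subject_id=str(subject_id), **fractions))
    return TrioDesign(tuple(subjects))


def write_trio_design(design: TrioDesign, path: str | Path) -> None:
    rows = [
        {"subject_id": s.subject_id, "sample_id": s.sample_for(f), "fraction": f}
        for s in design.subjects
        for f in FRACTIONS
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Probe annotation


def gc_fraction(sequence: str) -> float:
    """GC fraction of an A/C/G/T probe sequence."""
    seq = sequence.upper()
    if not seq or set(seq) - set("ACGT"):
        raise AnnotationError(f"invalid probe sequence {sequence!r}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly normalize) a probe-annotation table.

    Index: probe_id.  Required column: ``region_class`` (canonical tokens).
    Optional: chromosome, position (1-based), probe_sequence, gc_fraction,
    unique_mapping.  gc_fraction is computed from probe_sequence when absent
    and checked for consistency when both are present.
    """
    df = df.copy()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise AnnotationError(f"duplicated probe id {dup!r} in annotation")
    if "region_class" not in df.columns:
        raise AnnotationError("annotation lacks a region_class column")
    bad = ~df["region_class"].isin(REGION_CLASSES)
    if bad.any():
        raise VocabularyError(
            f"unknown region_class {df.loc[bad, 'region_class'].iloc[0]!r}"
        )
    if "position" in df.columns:
        pos = pd.to_numeric(df["position"])
        if (pos < 1).any():
            raise AnnotationError("annotation position must be >= 1 (1-based)")
        df["position"] = pos.astype(int)
    if "probe_sequence" in df.columns:
        seqs = df["probe_sequence"].dropna()
        computed = seqs.map(gc_fraction)
        if "gc_fraction" not in df.columns:
            df["gc_fraction"] = np.nan
        have_both = df["gc_fraction"].notna() & df.index.isin(seqs.index)
        if have_both.any():
            diff = (df.loc[have_both, "gc_fraction"] - computed[have_both]).abs()
            if (diff > 1e-4).any():
                probe = diff.idxmax()
                raise AnnotationError(
                    f"gc_fraction inconsistent with probe_sequence at {probe!r}"
                )
        df.loc[df["gc_fraction"].isna() & df.index.isin(seqs.index), "gc_fraction"] = (
            computed
        )
    if "gc_fraction" in df.columns:
        gc = df["gc_fraction"].dropna()
        if ((gc < 0) | (gc > 1)).any():
            raise AnnotationError("gc_fraction outside [0, 1]")
    if "unique_mapping" in df.columns:
        df["unique_mapping"] = df["unique_mapping"].astype(bool)
    return df


def read_probe_annotation(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a manifest-style annotation TSV into a validated DataFrame.

    The ``region_class`` column may carry either canonical tokens or manifest
    spellings (``Island``, ``N_Shore`` ...); a ``relation_to_island`` column
    is accepted as an alias.  Empty relation means open sea.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype={0: str}, keep_default_na=False,
                     na_values=["NA"])
    if "probe_id" not in df.columns:
        raise FormatError(f"{path}: annotation lacks a probe_id column")
    df = df.set_index("probe_id")
    if "region_class" not in df.columns and "relation_to_island" in df.columns:
        df = df.rename(columns={"relation_to_island": "region_class"})
    if "region_class" not in df.columns:
        raise FormatError(f"{path}: annotation lacks a region_class column")
    df["region_class"] = df["region_class"].map(normalize_region)
    if "probe_sequence" in df.columns:
        df["probe_sequence"] = df["probe_sequence"].replace("", np.nan)
    if "unique_mapping" in df.columns:
        df["unique_mapping"] = (
            df["unique_mapping"].astype(str).str.strip().str.lower()
            .map({"true": True, "false": False, "1": True, "0": False})
        )
    return validate_annotation(df)


def write_probe_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", float_format="%.6f", index_label="probe_id")


# ---------------------------------------------------------------------------
# Alignment


def align(
    matrix: BetaMatrix,
    design: TrioDesign | None = None,
    annotation: pd.DataFrame | None = None,
) -> tuple[BetaMatrix, TrioDesign | None, pd.DataFrame | None]:
    """Intersect probe/sample universes before any combined computation.

    Order is stable: the beta matrix's probe and sample order wins.  Dropped
    counts are logged, never silent.
    """
    out = matrix
    if design is not None:
        design.validate_against(out)
        out = out.subset_samples(design.sample_ids)
    if annotation is not None:
        common = out.probe_ids.intersection(annotation.index, sort=False)
        n_dropped = out.n_probes - len(common)
        if n_dropped:
            logger.info("align: dropping %d probes without annotation", n_dropped)
        out = out.subset_probes(common)
        annotation = annotation.loc[common]
    return out, design, annotation
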