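"""Reading, writing and preprocessing of methylation beta matrices.

The on-disk dialects follow GEO series-matrix conventions: beta matrices are
TSV with probes in rows (first column the cg-prefixed probe ID) and samples
in columns; sample metadata is a TSV with one row per sample; linear-clock
coefficients are CSV with one ``(Intercept)`` row.  All readers accept
plain or gzip-compressed files (by extension, as pandas does).

Preprocessing implements the rules used when pooling 450K/27K blood
studies: dropping sex-chromosome and multi-locus probes, harmonizing to a
shared probe panel, and the +0.5-year correction that undoes the right
censoring introduced by integer-valued recorded ages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, HarmonizationError, ValidationError

__all__ = [
    "BetaMatrix",
    "ProbeAnnotation",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_meta",
    "write_sample_meta",
    "read_probe_annotation",
    "exclude_probes",
    "harmonize_to_panel",
    "apply_age_censoring_correction",
    "read_clock_coefficients",
    "write_clock_coefficients",
]

#: Canonical metadata columns, in file order.
META_COLUMNS = ["sample_id", "age", "age_is_integer", "sex", "cohort", "study_id", "bmi"]

SEX_VALUES = {"male", "female", "unknown"}
COHORT_VALUES = {"control", "case"}


@dataclass
class BetaMatrix:
    """Probe-by-sample grid of methylation beta fractions.

    ``values`` is a DataFrame indexed by probe ID with sample IDs as
    columns; entries are fractions in [0, 1], NaN marking missing calls.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe IDs: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups[:5]}")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {vals[i, j]!r} outside [0, 1] at probe "
                f"{idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_feature_array(self) -> np.ndarray:
        """Samples-by-probes float array (the model-input orientation)."""
        return self.values.to_numpy(dtype=float).T


@dataclass(frozen=True)
class ProbeAnnotation:
    """Chromosome placement for one probe."""

    probe_id: str
    chromosome: str
    multi_locus: bool = False


def read_beta_matrix(path) -> BetaMatrix:
    """Read a series-matrix-style TSV into a validated :class:`BetaMatrix`.

    Row and column order are preserved; ``NA``/empty cells become missing.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=["NA"], float_precision="round_trip"
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse beta matrix {path}: {exc}") from exc
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise FormatError(f"non-numeric cells in sample column(s) {non_numeric[:5]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df.astype(float))


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    # %.17g preserves float64 exactly, so read(write(m)) round-trips
    matrix.values.to_csv(
        path, sep="\t", index_label="ID_REF", na_rep="NA", float_format="%.17g"
    )


def _flag_integer_ages(age_strings: pd.Series) -> pd.Series:
    # An age recorded without a decimal point is integer-valued metadata.
    return ~age_strings.astype(str).str.contains(r"\.", regex=True)


def read_sample_meta(path) -> pd.DataFrame:
    """Read the per-sample metadata TSV.

    Columns: sample_id, age, sex, cohort, study_id, optional bmi, optional
    age_is_integer.  When ``age_is_integer`` is absent it is inferred from
    the textual form of the age (no decimal point -> integer-valued).
    """
    raw = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "study_id": str})
    required = {"sample_id", "age"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"metadata missing required column(s): {sorted(missing)}")
    if raw["sample_id"].duplicated().any():
        dups = raw.loc[raw["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample IDs in metadata: {dups[:5]}")
    if "age_is_integer" not in raw.columns:
        age_text = pd.read_csv(path, sep="\t", dtype=str)["age"]
        raw["age_is_integer"] = _flag_integer_ages(age_text)
    else:
        raw["age_is_integer"] = raw["age_is_integer"].astype(bool)
    meta = raw.copy()
    meta["age"] = meta["age"].astype(float)
    validate_sample_meta(meta)
    return meta[[c for c in META_COLUMNS if c in meta.columns]]


def validate_sample_meta(meta: pd.DataFrame) -> None:
    if (meta["age"] < 0).any():
        bad = meta.loc[meta["age"] < 0, "sample_id"].tolist()
        raise ValidationError(f"negative age for sample(s) {bad[:5]}")
    if "sex" in meta.columns:
        bad_sex = set(meta["sex"].dropna()) - SEX_VALUES
        if bad_sex:
            raise ValidationError(f"unrecognized sex value(s): {sorted(bad_sex)}")
    if "cohort" in meta.columns:
        bad_cohort = set(meta["cohort"].dropna()) - COHORT_VALUES
        if bad_cohort:
            raise ValidationError(f"unrecognized cohort value(s): {sorted(bad_cohort)}")
    if "bmi" in meta.columns:
        bmi = meta["bmi"].dropna()
        if (bmi <= 0).any():
            raise ValidationError("bmi must be positive when present")


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta[[c for c in META_COLUMNS if c in meta.columns]].to_csv(path, sep="\t", index=False)


def read_probe_annotation(path) -> dict[str, ProbeAnnotation]:
    """Read a probe annotation TSV (probe_id, chromosome, multi_locus)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    if df["probe_id"].duplicated().any():
        raise FormatError("duplicate probe IDs in annotation")
    return {
        row.probe_id: ProbeAnnotation(row.probe_id, row.chromosome, bool(row.multi_locus))
        for row in df.itertuples()
    }


def exclude_probes(
    matrix: BetaMatrix,
    annot: Mapping[str, ProbeAnnotation] | Iterable[ProbeAnnotation],
    policy: Literal["strict", "lenient"] = "strict",
) -> BetaMatrix:
    """Drop sex-chromosome (X/Y) and multi-locus probes.

    Under ``strict`` policy a probe missing from the annotation is an
    error; under ``lenient`` it is kept (it cannot be shown to be
    excludable).
    """
    if not isinstance(annot, Mapping):
        annot = {a.probe_id: a for a in annot}
    keep: list[str] = []
    unannotated: list[str] = []
    for pid in matrix.probe_ids:
        ann = annot.get(pid)
        if ann is None:
            unannotated.append(pid)
            keep.append(pid)
            continue
        chrom = ann.chromosome.removeprefix("chr").upper()
        if chrom in {"X", "Y"} or ann.multi_locus:
            continue
        keep.append(pid)
    if unannotated and policy == "strict":
        raise ValidationError(
            f"probe(s) missing from annotation under strict policy: {unannotated[:5]}"
        )
    if not keep:
        raise ValidationError("probe exclusion removed every probe; downstream needs >= 1")
    return BetaMatrix(matrix.values.loc[keep])


def harmonize_to_panel(
    matrix: BetaMatrix,
    panel: Sequence[str],
    impute: Literal["error", "constant"] | Mapping[str, float] = "error",
) -> BetaMatrix:
    """Reindex a matrix onto a fixed probe panel, in panel order.

    Probes absent from the matrix — and missing entries within present
    probes — are filled according to ``impute``: ``"error"`` refuses,
    ``"constant"`` fills 0.5, a mapping supplies per-probe reference
    medians (missing keys fall back to 0.5).
    """
    panel = list(panel)
    if not panel:
        raise HarmonizationError("panel is empty")
    if len(set(panel)) != len(panel):
        raise HarmonizationError("panel contains duplicate probe IDs")
    absent = [p for p in panel if p not in matrix.values.index]
    out = matrix.values.reindex(panel)
    if out.isna().to_numpy().any():
        if impute == "error":
            if absent:
                raise HarmonizationError(f"probe(s) absent from matrix: {absent}")
            raise HarmonizationError("matrix has missing entries and impute policy is 'error'")
        if impute == "constant":
            out = out.fillna(0.5)
        else:
            fills = pd.Series({p: float(impute.get(p, 0.5)) for p in panel})
            out = out.apply(lambda row: row.fillna(fills[row.name]), axis=1)
    return BetaMatrix(out)


def apply_age_censoring_correction(meta: pd.DataFrame) -> pd.DataFrame:
    """Undo integer-age right censoring: add 0.5 years to flagged samples.

    A recorded whole-year age understates the true age by up to one year,
    so flagged ages get +0.5; float-valued ages are untouched.  Flags are
    cleared afterwards so the correction cannot be applied twice.
    """
    if (meta["age"] < 0).any():
        raise ValidationError("negative age encountered before censoring correction")
    out = meta.copy()
    flagged = out["age_is_integer"].astype(bool)
    out.loc[flagged, "age"] = out.loc[flagged, "age"] + 0.5
    out["age_is_integer"] = False
    return out


INTERCEPT_KEY = "(Intercept)"


def read_clock_coefficients(path):
    """Read a linear-clock coefficient CSV into a :class:`LinearClock`.

    Expected columns: ``probe_id``, ``weight``; exactly one row with
    probe_id ``(Intercept)``.  An optional comment header line
    ``# uses_transform: true|false`` records whether predictions live in
    transformed-age space (default true, the Horvath convention).
    """
    from .linear_clock import LinearClock  # local import to avoid cycle

    uses_transform = True
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "uses_transform" in first:
                uses_transform = first.split(":", 1)[1].strip().lower() in {"true", "1", "yes"}
            df = pd.read_csv(fh)
        else:
            import io

            df = pd.read_csv(io.StringIO(first + fh.read()))
    if not {"probe_id", "weight"} <= set(df.columns):
        raise FormatError("coefficient file needs 'probe_id' and 'weight' columns")
    is_intercept = df["probe_id"] == INTERCEPT_KEY
    n_int = int(is_intercept.sum())
    if n_int != 1:
        raise FormatError(f"expected exactly one intercept row, found {n_int}")
    probes = df.loc[~is_intercept, "probe_id"]
    if probes.duplicated().any():
        raise FormatError("duplicate probe IDs in coefficient file")
    weights = dict(zip(probes, df.loc[~is_intercept, "weight"].astype(float)))
    intercept = float(df.loc[is_intercept, "weight"].iloc[0])
    return LinearClock(weights=weights, intercept=intercept, uses_transform=uses_transform)


def write_clock_coefficients(clock, path) -> None:
    """Serialize a LinearClock to the coefficient CSV dialect (round-trips)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write(f"# uses_transform: {str(clock.uses_transform).lower()}\n")
        fh.write("probe_id,weight\n")
        fh.write(f"{INTERCEPT_KEY},{clock.intercept!r}\n")
        for pid, w in clock.weights.items():
            fh.write(f"{pid},{w!r}\n")
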