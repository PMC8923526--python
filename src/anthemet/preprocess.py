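"""Peak-table preprocessing for widely targeted metabolomics.

Turns a raw peak-area table (samples x compounds, with extraction-blank
replicates and designated internal-standard columns) into the relative
metabolite-content matrix used by all downstream analyses:

1. blank-based signal-to-noise ratios per compound,
2. detection filtering (S/N above a threshold in more than a given
   fraction of samples),
3. normalization by the internal standard,
4. column standardization (z-scores) and 0-1 scaling.

Values below the instrument detection limit are expected to be zero
already in the input; they propagate as S/N = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ["sample_id", "experiment", "cultivar", "plant", "datetime", "replicate"]

#: allowed states of a MetaboliteMatrix
_STATES = ("raw-relative", "standardized", "scaled01")


class PreprocessingError(ValueError):
    """Raised when a peak table violates a preprocessing contract."""


@dataclass
class PeakTable:
    """Raw peak areas with blank controls and internal-standard designations.

    Parameters
    ----------
    areas
        samples x compounds nonnegative peak areas; index = sample ids.
    blank_areas
        compounds x blank-replicates nonnegative areas (index = compound ids,
        one column per extraction-blank replicate).
    internal_standard_ids
        compound labels spiked as internal standards; must be columns of
        ``areas``. They are never candidate metabolites.
    sample_meta
        per-sample metadata (experiment, cultivar, plant, datetime, replicate),
        indexed like ``areas``.
    """

    areas: pd.DataFrame
    blank_areas: pd.DataFrame
    internal_standard_ids: tuple[str, ...]
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.areas.to_numpy() < 0).any():
            raise PreprocessingError("peak areas must be nonnegative")
        missing = [c for c in self.internal_standard_ids if c not in self.areas.columns]
        if missing:
            raise PreprocessingError(f"internal standards not in area columns: {missing}")
        if self.blank_areas.shape[1] < 1:
            raise PreprocessingError("at least one blank replicate is required")
        self.internal_standard_ids = tuple(self.internal_standard_ids)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.areas.columns)

    @classmethod
    def from_csv(
        cls,
        peaks_path,
        blanks_path,
        internal_standard_ids: Sequence[str] | None = None,
    ) -> "PeakTable":
        """Read the peak CSV (metadata columns + compound columns, plus an
        ``is_internal_standard`` header row convention via column prefix) and
        the companion blank CSV keyed by compound."""
        peaks = pd.read_csv(peaks_path)
        meta = peaks[META_COLUMNS].copy()
        meta.index = peaks["sample_id"]
        areas = peaks.drop(columns=META_COLUMNS)
        areas.index = peaks["sample_id"]
        blanks = pd.read_csv(blanks_path, index_col=0)
        if internal_standard_ids is None:
            internal_standard_ids = [c for c in areas.columns if c.startswith("IS_")]
        return cls(areas, blanks, tuple(internal_standard_ids), meta)


@dataclass
class MetaboliteMatrix:
    """Relative metabolite contents with per-sample metadata.

    ``values`` holds X_ij (n samples x m metabolites).  ``state`` tracks the
    transformation applied: raw relative contents, column z-scores
    (population SD), or 0-1 range-scaled values.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    state: str = "raw-relative"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise PreprocessingError(f"unknown state {self.state!r}; expected one of {_STATES}")
        if self.values.isna().to_numpy().any():
            raise PreprocessingError("metabolite matrix must not contain missing values")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, metabolite_ids: Sequence[str]) -> "MetaboliteMatrix":
        missing = [m for m in metabolite_ids if m not in self.values.columns]
        if missing:
            raise KeyError(f"metabolites not in matrix: {missing}")
        return replace(self, values=self.values[list(metabolite_ids)].copy())

    def select_samples(self, mask) -> "MetaboliteMatrix":
        return replace(
            self,
            values=self.values.loc[mask].copy(),
            sample_meta=self.sample_meta.loc[mask].copy(),
        )

    def to_csv(self, path) -> None:
        out = pd.concat([self.sample_meta.reset_index(drop=True),
                         self.values.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, state: str = "raw-relative") -> "MetaboliteMatrix":
        df = pd.read_csv(path)
        meta = df[META_COLUMNS].copy()
        meta.index = df["sample_id"]
        values = df.drop(columns=META_COLUMNS)
        values.index = df["sample_id"]
        return cls(values, meta, state)


def compute_snr(
    areas: pd.DataFrame,
    blank_areas: pd.DataFrame,
    *,
    substitute_zero_blanks: bool = False,
) -> pd.DataFrame:
    """Signal-to-noise ratio: each area divided by the mean blank area of the
    same compound.

    Zeros in ``areas`` (below-detection values) propagate to S/N = 0.  A
    compound whose blank replicates average to zero is an error by default;
    with ``substitute_zero_blanks`` the smallest positive mean blank is
    substituted and the substitution is logged.
    """
    mean_blank = blank_areas.mean(axis=1)
    mean_blank = mean_blank.reindex(areas.columns)
    if mean_blank.isna().any():
        missing = list(mean_blank.index[mean_blank.isna()])
        raise PreprocessingError(f"compounds without blank measurements: {missing}")
    zero = mean_blank <= 0
    if zero.any():
        if not substitute_zero_blanks:
            raise PreprocessingError(
                f"zero mean blank area for compounds: {list(mean_blank.index[zero])}"
            )
        smallest_positive = mean_blank[~zero].min()
        logger.warning(
            "substituting smallest positive mean blank %g for %d compounds: %s",
            smallest_positive, int(zero.sum()), list(mean_blank.index[zero]),
        )
        mean_blank = mean_blank.mask(zero, smallest_positive)
    return areas.div(mean_blank, axis=1)


def detection_filter(
    snr: pd.DataFrame,
    threshold: float = 2.0,
    min_fraction: float = 0.5,
    internal_standard_ids: Iterable[str] = (),
) -> list[str]:
    """Keep metabolite j iff S/N > ``threshold`` in strictly more than
    ``min_fraction`` of the samples (both inequalities strict).

    Internal standards are excluded from both the candidate list and the
    output.  Raises if nothing survives.
    """
    if not 0 < min_fraction < 1:
        raise PreprocessingError("min_fraction must lie strictly between 0 and 1")
    is_ids = set(internal_standard_ids)
    candidates = [c for c in snr.columns if c not in is_ids]
    n = snr.shape[0]
    counts = (snr[candidates] > threshold).sum(axis=0)
    kept = [c for c in candidates if counts[c] > min_fraction * n]
    if not kept:
        raise PreprocessingError(
            "detection filter removed every metabolite; review the S/N threshold "
            f"(threshold={threshold}, min_fraction={min_fraction})"
        )
    return kept


def normalize_by_internal_standard(
    areas: pd.DataFrame,
    internal_standard: str | Mapping[str, str],
    sample_meta: pd.DataFrame,
    metabolite_ids: Sequence[str] | None = None,
) -> MetaboliteMatrix:
    """Relative metabolite content: peak area divided by the internal-standard
    area of the same sample.

    ``internal_standard`` is either one global standard column label or a
    mapping metabolite -> its standard (e.g. by ionization mode).
    """
    if metabolite_ids is None:
        is_cols = {internal_standard} if isinstance(internal_standard, str) else set(internal_standard.values())
        metabolite_ids = [c for c in areas.columns if c not in is_cols]
    if isinstance(internal_standard, str):
        is_map = {m: internal_standard for m in metabolite_ids}
    else:
        is_map = dict(internal_standard)
        missing = [m for m in metabolite_ids if m not in is_map]
        if missing:
            raise PreprocessingError(f"metabolites without internal-standard assignment: {missing}")
    used_standards = sorted(set(is_map.values()))
    for s in used_standards:
        bad = areas.index[areas[s] <= 0]
        if len(bad):
            raise PreprocessingError(
                f"internal standard {s!r} has non-positive area in samples: {list(bad)}"
            )
    values = pd.DataFrame(
        {m: areas[m] / areas[is_map[m]] for m in metabolite_ids}, index=areas.index
    )
    return MetaboliteMatrix(values, sample_meta.loc[areas.index].copy(), "raw-relative")


def _constant_columns(values: pd.DataFrame) -> list[str]:
    sd = values.std(axis=0, ddof=0)
    return list(sd.index[sd <= 0])


def standardize(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Column-wise z-scores using the population SD (divisor n)."""
    constant = _constant_columns(matrix.values)
    if constant:
        raise PreprocessingError(f"constant columns cannot be standardized: {constant}")
    v = matrix.values
    z = (v - v.mean(axis=0)) / v.std(axis=0, ddof=0)
    return replace(matrix, values=z, state="standardized")


def scale01(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Scale every column to the range [0, 1] by (x - min)/(max - min)."""
    v = matrix.values
    span = v.max(axis=0) - v.min(axis=0)
    constant = list(span.index[span <= 0])
    if constant:
        raise PreprocessingError(f"constant columns cannot be 0-1 scaled: {constant}")
    scaled = (v - v.min(axis=0)) / span
    return replace(matrix, values=scaled, state="scaled01")


def preprocess_peak_table(
    table: PeakTable,
    snr_threshold: float = 2.0,
    min_fraction: float = 0.5,
    internal_standard: str | Mapping[str, str] | None = None,
    substitute_zero_blanks: bool = False,
) -> MetaboliteMatrix:
    """Full pipeline on a raw PeakTable: S/N, detection filter, internal
    standard normalization.  Returns the raw-relative matrix restricted to
    detected metabolites."""
    snr = compute_snr(table.areas, table.blank_areas,
                      substitute_zero_blanks=substitute_zero_blanks)
    kept = detection_filter(snr, snr_threshold, min_fraction, table.internal_standard_ids)
    if internal_standard is None:
        internal_standard = table.internal_standard_ids[0]
    return normalize_by_internal_standard(
        table.areas, internal_standard, table.sample_meta, metabolite_ids=kept
    )
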