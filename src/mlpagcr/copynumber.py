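"""Peak-area normalization and integer copy-number calling.

Raw capillary peak areas are converted to copy numbers in three steps:

1. within-sample normalization, either by the sample's total probe area
   (``GLOBAL_SUM``, used for the genome-wide telomeric/centromeric panels)
   or by the most centromeric probe's area (``ANCHOR``, used for
   arm-specific panels on the assumption that the probe nearest the
   centromere is never part of the duplicated segment);
2. per-probe division by the mean of the control samples' normalized
   values, giving a dimensionless ratio that is ~1 for two normal copies...
   or rather ~1 per normal copy (haploid assay: 1 = normal, 0 = deleted,
   2 = duplicated);
3. rounding the ratio to the nearest integer, flagging calls whose ratio
   falls too far from every integer as AMBIGUOUS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .probes import ProbeSet

__all__ = [
    "NormalizationMode",
    "QCFlag",
    "PeakTable",
    "CopyNumberMatrix",
    "CallingError",
    "match_peaks",
    "normalize_within_sample",
    "call_copy_numbers",
]

logger = logging.getLogger(__name__)


class CallingError(ValueError):
    pass


class NormalizationMode(str, Enum):
    GLOBAL_SUM = "GLOBAL_SUM"
    ANCHOR = "ANCHOR"


class QCFlag(str, Enum):
    OK = "OK"
    AMBIGUOUS = "AMBIGUOUS"
    MISSING = "MISSING"


@dataclass
class PeakTable:
    """Peak areas for one sample: (fragment size bp, area) pairs."""

    sample_id: str
    peaks: list[tuple[float, float]]
    is_control: bool = False

    def __post_init__(self):
        for size, area in self.peaks:
            if area < 0:
                raise CallingError(f"sample {self.sample_id}: negative peak area at {size} bp")


def match_peaks(
    table: PeakTable, probeset: ProbeSet, tolerance: float = 1.0
) -> pd.Series:
    """Match peaks to panel probes by product length (± ``tolerance`` bp).

    Returns areas indexed by probe id; probes without a matching peak are
    NaN.  Unmatched peaks are ignored with a warning, and a probe matched
    by two peaks is an error.
    """
    areas = pd.Series(np.nan, index=probeset.ids, dtype=float)
    for size, area in table.peaks:
        probe = probeset.by_length(size, tolerance)
        if probe is None:
            logger.warning(
                "sample %s: peak at %.1f bp matches no probe; ignored",
                table.sample_id, size,
            )
            continue
        if not np.isnan(areas[probe.id]):
            raise CallingError(
                f"sample {table.sample_id}: probe {probe.id} matched by more than one peak"
            )
        areas[probe.id] = area
    return areas


def normalize_within_sample(
    areas: pd.Series,
    mode: NormalizationMode | str = NormalizationMode.GLOBAL_SUM,
    anchor: str | None = None,
) -> pd.Series:
    """Within-sample normalization of probe areas.

    GLOBAL_SUM: v_j = area_j / sum_k area_k  (scale invariant).
    ANCHOR:     v_j = area_j / area_anchor   (anchor assumed copy number 1).
    """
    mode = NormalizationMode(mode)
    present = areas.dropna()
    if len(present) < 2:
        raise CallingError("need at least two measured probes to normalize")
    if mode is NormalizationMode.GLOBAL_SUM:
        total = present.sum()
        if total <= 0:
            raise CallingError("total probe area is zero")
        return areas / total
    if anchor is None:
        raise CallingError("ANCHOR mode requires an anchor probe id")
    anchor_area = areas.get(anchor, np.nan)
    if np.isnan(anchor_area) or anchor_area <= 0:
        raise CallingError(f"anchor probe {anchor} has no positive area")
    return areas / anchor_area


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class CopyNumberMatrix:
    """Per-isolate, per-probe normalized ratios, integer calls and QC flags."""

    ratios: pd.DataFrame  # isolates x probes, float
    calls: pd.DataFrame  # isolates x probes, int (0 where MISSING)
    flags: pd.DataFrame  # isolates x probes, QCFlag values (str)
    probeset: ProbeSet | None = None

    @property
    def isolates(self) -> list[str]:
        return list(self.ratios.index)

    def row(self, isolate: str) -> tuple[pd.Series, pd.Series, pd.Series]:
        return (
            self.ratios.loc[isolate],
            self.calls.loc[isolate],
            self.flags.loc[isolate],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (isolate, probe, ratio, call, flag)."""
        out = (
            self.ratios.stack().rename("ratio").to_frame()
            .join(self.calls.stack().rename("call"))
            .join(self.flags.stack().rename("flag"))
            .reset_index()
        )
        out.columns = ["isolate", "probe", "ratio", "call", "flag"]
        return out


def call_copy_numbers(
    samples: Sequence[PeakTable],
    probeset: ProbeSet,
    mode: NormalizationMode | str = NormalizationMode.GLOBAL_SUM,
    anchor: str | None = None,
    tolerance: float = 0.3,
    match_tolerance_bp: float = 1.0,
) -> CopyNumberMatrix:
    """Call integer copy numbers for every non-control sample.

    Control samples (``is_control``) define, probe by probe, the mean
    normalized value corresponding to copy number 1; each test sample's
    normalized value is divided by that mean and rounded (half away from
    zero).  A cell is AMBIGUOUS when its ratio is more than ``tolerance``
    from the nearest integer, MISSING when the sample had no peak for the
    probe.
    """
    mode = NormalizationMode(mode)
    if mode is NormalizationMode.ANCHOR and anchor is None:
        anchor = probeset.most_centromeric_id
    controls = [s for s in samples if s.is_control]
    tests = [s for s in samples if not s.is_control]
    if not controls:
        raise CallingError("at least one control sample is required")
    ids = {s.sample_id for s in samples}
    if len(ids) != len(samples):
        raise CallingError("duplicate sample ids")

    def _norm(table: PeakTable) -> pd.Series:
        return normalize_within_sample(
            match_peaks(table, probeset, match_tolerance_bp), mode, anchor
        )

    control_mat = pd.DataFrame({s.sample_id: _norm(s) for s in controls}).T
    control_mean = control_mat.mean(axis=0, skipna=True)
    bad = control_mean.index[(control_mean.isna()) | (control_mean <= 0)]
    if len(bad):
        raise CallingError(f"control mean is zero or undefined for probes: {list(bad)}")

    ratio_rows, call_rows, flag_rows = {}, {}, {}
    for s in tests:
        v = _norm(s)
        ratio = v / control_mean
        call = _round_half_away(ratio.to_numpy(dtype=float))
        dev = np.abs(ratio.to_numpy(dtype=float) - call)
        flags = np.where(dev > tolerance, QCFlag.AMBIGUOUS.value, QCFlag.OK.value)
        missing = ratio.isna().to_numpy()
        flags = np.where(missing, QCFlag.MISSING.value, flags)
        call = np.where(missing, 0, call)
        ratio_rows[s.sample_id] = ratio
        call_rows[s.sample_id] = pd.Series(call.astype(int), index=ratio.index)
        flag_rows[s.sample_id] = pd.Series(flags, index=ratio.index)

    index = [s.sample_id for s in tests]
    return CopyNumberMatrix(
        ratios=pd.DataFrame(ratio_rows).T.reindex(index),
        calls=pd.DataFrame(call_rows).T.reindex(index).astype(int),
        flags=pd.DataFrame(flag_rows).T.reindex(index),
        probeset=probeset,
    )
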