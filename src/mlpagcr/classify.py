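"""Classification of copy-number calls into rearrangement events.

The assay selects for loss of the terminal left-arm segment of chromosome V
(telomeric probe call 0 on chrV-L).  Each surviving isolate is then
classified by what healed the broken chromosome:

* an **arm duplication** — telomeric probe call >= 2 on another arm, the
  signature of a nonreciprocal translocation that copied that arm's
  terminal segment onto the broken chromosome;
* a **whole-chromosome duplication** — call >= 2 at *every* probed locus of
  a chromosome (telomeric and, when probed, centromeric probes on both
  arms), the operational definition of aneuploidy;
* **no duplication** — the deletion alone, consistent with healing by
  de novo telomere addition;
* **ambiguous** — any contributing call flagged AMBIGUOUS.

Arm-specific probe ladders refine an arm duplication to a breakpoint: the
most centromeric duplicated probe and its single-copy centromeric neighbour
bracket the candidate target element(s).
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .copynumber import CopyNumberMatrix, QCFlag
from .genome import Arm, GenomeAnnotation, Orientation, split_arm_key
from .probes import PlacementFlag, Probe, ProbeRole, ProbeSet

__all__ = [
    "IsolateStatus",
    "Geometry",
    "Validity",
    "IsolateClassification",
    "BreakpointCall",
    "CohortSummary",
    "ClassificationError",
    "classify_isolate",
    "classify_matrix",
    "localize_breakpoint",
    "summarize_cohort",
]

UNKNOWN_TARGET = "UNKNOWN"


class ClassificationError(ValueError):
    pass


class IsolateStatus(str, Enum):
    CLASSIFIED = "CLASSIFIED"
    NO_DUPLICATION = "NO_DUPLICATION"
    AMBIGUOUS = "AMBIGUOUS"


class Geometry(str, Enum):
    """Predicted product geometry from the orientation of candidate targets."""

    MONOCENTRIC = "MONOCENTRIC"
    DICENTRIC_INTERMEDIATE = "DICENTRIC_INTERMEDIATE"
    MIXED = "MIXED"
    UNKNOWN = "UNKNOWN"


class Validity(str, Enum):
    SIMPLE = "SIMPLE"  # single 1 -> >=2 step along the ladder
    COMPLEX = "COMPLEX"  # non-monotone calls, e.g. a rearranged dicentric


@dataclass
class IsolateClassification:
    isolate: str
    has_assay_deletion: bool
    arm_duplications: list[str] = field(default_factory=list)  # arm keys
    whole_chromosome_duplications: list[str] = field(default_factory=list)
    status: IsolateStatus = IsolateStatus.CLASSIFIED
    #: arm duplications reported by a fallback telomeric probe, where the
    #: skipped terminal element(s) are unprobed
    caveat_arms: list[str] = field(default_factory=list)

    @property
    def has_arm_duplication(self) -> bool:
        return bool(self.arm_duplications)

    def event_notation(self, assay_arm: str = "chrV-L") -> str:
        """Compact event string, e.g. '-chrV-L +chrXIII-L'."""
        parts = []
        if self.has_assay_deletion:
            parts.append(f"-{assay_arm}")
        parts.extend(f"+{a}" for a in self.arm_duplications)
        parts.extend(f"+{c}" for c in self.whole_chromosome_duplications)
        return " ".join(parts) if parts else "."


@dataclass
class BreakpointCall:
    arm: str
    most_centromeric_duplicated_probe: str | None
    flanking_centromeric_probe: str | None
    target_element_ids: list[str]
    geometry: Geometry
    validity: Validity

    @property
    def has_duplication(self) -> bool:
        return self.most_centromeric_duplicated_probe is not None

    @property
    def target_label(self) -> str:
        return "/".join(self.target_element_ids) if self.target_element_ids else UNKNOWN_TARGET


def classify_isolate(
    calls: pd.Series,
    flags: pd.Series,
    telomeric: ProbeSet,
    annotation: GenomeAnnotation,
    centromeric: ProbeSet | None = None,
    assay_arm: str = "chrV-L",
) -> IsolateClassification:
    """Classify one isolate from its telomeric (and optional centromeric) calls."""
    isolate = str(calls.name) if calls.name is not None else "?"
    probes: list[Probe] = list(telomeric)
    if centromeric is not None:
        probes += list(centromeric)
    probe_by_id = {p.id: p for p in probes}
    assay_probe = telomeric.arm_probe(assay_arm)
    if assay_probe.id not in calls.index or flags.get(assay_probe.id) == QCFlag.MISSING.value:
        raise ClassificationError(
            f"isolate {isolate}: no call for the assay arm probe {assay_probe.id}"
        )

    contributing = [pid for pid in calls.index if pid in probe_by_id]
    ambiguous = any(flags.get(pid) == QCFlag.AMBIGUOUS.value for pid in contributing)

    # whole-chromosome duplication: every probed OK locus >= 2, requiring
    # at least two probed loci on the chromosome; ambiguous cells carry no
    # trustworthy call and are excluded from event evidence
    by_chrom: dict[str, list[str]] = defaultdict(list)
    for pid in contributing:
        if flags.get(pid) == QCFlag.OK.value:
            by_chrom[probe_by_id[pid].chromosome].append(pid)
    whole_dups = [
        chrom
        for chrom, pids in by_chrom.items()
        if len(pids) >= 2 and all(calls[pid] >= 2 for pid in pids)
    ]
    whole_set = set(whole_dups)

    arm_dups: list[str] = []
    caveats: list[str] = []
    for p in telomeric:
        if p.id not in calls.index or flags.get(p.id) != QCFlag.OK.value:
            continue
        if p.arm_key == assay_arm or p.chromosome in whole_set:
            continue
        if calls[p.id] >= 2:
            arm_dups.append(p.arm_key)
            if p.placement is PlacementFlag.FALLBACK_CENTROMERIC:
                caveats.append(p.arm_key)

    has_deletion = calls[assay_probe.id] == 0
    if ambiguous:
        status = IsolateStatus.AMBIGUOUS
    elif has_deletion and not arm_dups and not whole_dups:
        status = IsolateStatus.NO_DUPLICATION
    else:
        status = IsolateStatus.CLASSIFIED
    chrom_order = {n: i for i, n in enumerate(annotation.chromosome_names)}
    return IsolateClassification(
        isolate=isolate,
        has_assay_deletion=bool(has_deletion),
        arm_duplications=sorted(arm_dups, key=lambda k: (chrom_order[split_arm_key(k)[0]], k)),
        whole_chromosome_duplications=sorted(whole_dups, key=lambda c: chrom_order[c]),
        status=status,
        caveat_arms=caveats,
    )


def classify_matrix(
    matrix: CopyNumberMatrix,
    telomeric: ProbeSet,
    annotation: GenomeAnnotation,
    centromeric: ProbeSet | None = None,
    assay_arm: str = "chrV-L",
) -> list[IsolateClassification]:
    """Classify every isolate of a copy-number matrix (pure; no state)."""
    out = []
    for isolate in matrix.isolates:
        _, calls, flags = matrix.row(isolate)
        out.append(
            classify_isolate(calls, flags, telomeric, annotation, centromeric, assay_arm)
        )
    return out


def localize_breakpoint(
    calls: pd.Series,
    arm_probeset: ProbeSet,
    annotation: GenomeAnnotation,
) -> BreakpointCall:
    """Localize an arm duplication breakpoint along an arm-specific ladder.

    ``calls`` are indexed by probe id.  The ladder is scanned centromere to
    telomere for the first probe with call >= 2; the candidate targets are
    the annotated elements lying strictly between that probe and its
    centromeric single-copy neighbour.  A ladder whose calls step more than
    once (e.g. 1,2,1,2) is flagged COMPLEX — the signature of a dicentric
    intermediate that underwent secondary rearrangements — but is still
    summarized under its most centromeric step.
    """
    ordered = arm_probeset.ordered_centromere_to_telomere()
    arm_key = ordered[0].arm_key
    seq = [int(calls[p.id]) for p in ordered]
    dup_idx = [i for i, c in enumerate(seq) if c >= 2]
    if not dup_idx:
        return BreakpointCall(arm_key, None, None, [], Geometry.UNKNOWN, Validity.SIMPLE)
    first = dup_idx[0]
    flank = ordered[first - 1] if first > 0 else None
    dup_probe = ordered[first]
    # simple pattern: calls are 1 up to the step, then >= 2 to the telomere
    simple = all(c >= 2 for c in seq[first:]) and all(c == 1 for c in seq[:first])
    validity = Validity.SIMPLE if simple else Validity.COMPLEX

    chrom, arm = split_arm_key(arm_key)
    lo = min(dup_probe.anchor, flank.anchor) if flank else None
    hi = max(dup_probe.anchor, flank.anchor) if flank else None
    targets = []
    for el in annotation.elements_on_arm(chrom, arm):
        if flank is None:
            # duplicated from the first ladder probe: anything centromeric of it
            if (arm is Arm.L and el.start > dup_probe.anchor) or (
                arm is Arm.R and el.end < dup_probe.anchor
            ):
                targets.append(el)
        elif lo < el.start and el.end < hi:
            targets.append(el)
    orientations = {el.orientation for el in targets}
    if not targets:
        geometry = Geometry.UNKNOWN
    elif orientations == {Orientation.TELOMERE}:
        geometry = Geometry.MONOCENTRIC
    elif orientations == {Orientation.CENTROMERE}:
        geometry = Geometry.DICENTRIC_INTERMEDIATE
    else:
        geometry = Geometry.MIXED
    return BreakpointCall(
        arm=arm_key,
        most_centromeric_duplicated_probe=dup_probe.id,
        flanking_centromeric_probe=flank.id if flank else None,
        target_element_ids=[el.id for el in targets],
        geometry=geometry,
        validity=validity,
    )


@dataclass
class CohortSummary:
    n: int
    n_assay_deletions: int
    n_arm_duplication_isolates: int
    n_no_duplication: int
    n_ambiguous: int
    arm_duplication_counts: dict[str, int]
    whole_chromosome_duplication_counts: dict[str, int]
    n_whole_chromosome_duplication_isolates: int
    #: per arm: target label -> (count, percent of that arm's duplications)
    breakpoint_targets: dict[str, dict[str, tuple[int, float]]] = field(default_factory=dict)

    @property
    def duplication_fraction(self) -> float:
        return self.n_arm_duplication_isolates / self.n if self.n else 0.0

    def arm_fraction(self, arm_keys: Iterable[str]) -> float:
        """Fraction of arm-duplication events falling on the given arms."""
        total = sum(self.arm_duplication_counts.values())
        if not total:
            return 0.0
        return sum(self.arm_duplication_counts.get(a, 0) for a in arm_keys) / total

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "assay_deletions": self.n_assay_deletions,
            "arm_duplication_isolates": self.n_arm_duplication_isolates,
            "no_duplication": self.n_no_duplication,
            "ambiguous": self.n_ambiguous,
            "arm_duplication_counts": dict(self.arm_duplication_counts),
            "whole_chromosome_duplication_counts": dict(
                self.whole_chromosome_duplication_counts
            ),
            "whole_chromosome_duplication_isolates": self.n_whole_chromosome_duplication_isolates,
            "breakpoint_targets": {
                arm: {t: {"n": n, "percent": pct} for t, (n, pct) in targets.items()}
                for arm, targets in self.breakpoint_targets.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def summarize_cohort(
    classifications: Sequence[IsolateClassification],
    breakpoints: Mapping[str, Sequence[BreakpointCall]] | Sequence[BreakpointCall] | None = None,
) -> CohortSummary:
    """Aggregate per-isolate classifications (and optional breakpoint calls).

    Breakpoint target percentages are per arm, as a share of that arm's
    duplication-bearing isolates localized on the ladder, rounded to 0
    decimals.
    """
    if not classifications:
        return CohortSummary(0, 0, 0, 0, 0, {}, {}, 0, {})
    n = len(classifications)
    n_del = sum(c.has_assay_deletion for c in classifications)
    n_amb = sum(c.status is IsolateStatus.AMBIGUOUS for c in classifications)
    n_nodup = sum(c.status is IsolateStatus.NO_DUPLICATION for c in classifications)
    counted = [c for c in classifications if c.status is not IsolateStatus.AMBIGUOUS]
    arm_counts: Counter[str] = Counter()
    whole_counts: Counter[str] = Counter()
    n_arm_dup = 0
    n_whole = 0
    for c in counted:
        if c.arm_duplications:
            n_arm_dup += 1
            arm_counts.update(c.arm_duplications)
        if c.whole_chromosome_duplications:
            n_whole += 1
            whole_counts.update(c.whole_chromosome_duplications)

    bp_summary: dict[str, dict[str, tuple[int, float]]] = {}
    if breakpoints:
        if not isinstance(breakpoints, Mapping):
            grouped: dict[str, list[BreakpointCall]] = defaultdict(list)
            for bp in breakpoints:
                grouped[bp.arm].append(bp)
            breakpoints = grouped
        for arm, calls in breakpoints.items():
            located = [bp for bp in calls if bp.has_duplication]
            total = len(located)
            target_counts = Counter(bp.target_label for bp in located)
            bp_summary[arm] = {
                t: (cnt, round(100.0 * cnt / total)) for t, cnt in target_counts.most_common()
            }
    return CohortSummary(
        n=n,
        n_assay_deletions=n_del,
        n_arm_duplication_isolates=n_arm_dup,
        n_no_duplication=n_nodup,
        n_ambiguous=n_amb,
        arm_duplication_counts=dict(arm_counts),
        whole_chromosome_duplication_counts=dict(whole_counts),
        n_whole_chromosome_duplication_isolates=n_whole,
        breakpoint_targets=bp_summary,
    )
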