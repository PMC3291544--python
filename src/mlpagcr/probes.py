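"""Design of multiplex probe panels and their theoretical target coverage.

Three panel roles are supported, mirroring how the assay interrogates the
genome:

* ``TELOMERIC`` — one probe per chromosome arm placed between the arm's
  telomere and its most distal Ty1/Ty2/solo-delta element, so that any
  translocation-associated terminal duplication raises the probe's copy
  number.  Arms whose terminal element leaves no usable unique window get a
  fallback probe immediately centromeric to the terminal element.
* ``CENTROMERIC`` — one probe per arm centromeric to the arm's innermost
  element; paired with the telomeric panel it distinguishes whole-chromosome
  duplications from terminal arm duplications.
* ``ARM_SPECIFIC`` — a ladder of probes, one in every inter-element gap of a
  single arm (including the telomere-side and centromere-side gaps), used to
  localize the duplication breakpoint to the Ty element(s) between the last
  single-copy probe and the first duplicated probe.

Because this package carries no nucleotide sequence, "unique hybridizable
sequence" is abstracted to a minimum window size (default 300 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import csv

from .genome import (
    Arm,
    GenomeAnnotation,
    RepeatElement,
    TargetCatalog,
    split_arm_key,
)

__all__ = [
    "ProbeRole",
    "PlacementFlag",
    "Probe",
    "ProbeSet",
    "DesignError",
    "DesignConstraints",
    "design_probe_set",
    "assign_product_lengths",
    "theoretical_coverage",
    "CoverageStat",
    "write_probeset_tsv",
    "read_probeset_tsv",
]


class DesignError(ValueError):
    pass


class ProbeRole(str, Enum):
    TELOMERIC = "TELOMERIC"
    CENTROMERIC = "CENTROMERIC"
    ARM_SPECIFIC = "ARM_SPECIFIC"


class PlacementFlag(str, Enum):
    PREFERRED = "PREFERRED"
    #: the preferred telomeric window was too small; the probe sits just
    #: centromeric to the arm's terminal element and cannot report
    #: duplications mediated by the element(s) it skipped.
    FALLBACK_CENTROMERIC = "FALLBACK_CENTROMERIC"


@dataclass(frozen=True)
class Probe:
    id: str
    chromosome: str
    arm: Arm
    anchor: int  # bp position the probe hybridizes at
    role: ProbeRole
    product_length: int = 0  # assigned later; unique within a ProbeSet
    placement: PlacementFlag = PlacementFlag.PREFERRED

    @property
    def arm_key(self) -> str:
        return f"{self.chromosome}-{self.arm.value}"


@dataclass
class ProbeSet:
    role: ProbeRole
    probes: list[Probe]
    min_gap: int = 2

    def __post_init__(self):
        lengths = [p.product_length for p in self.probes if p.product_length]
        if len(set(lengths)) != len(lengths):
            raise DesignError("product lengths not unique within probe set")

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.probes]

    def by_id(self, probe_id: str) -> Probe:
        for p in self.probes:
            if p.id == probe_id:
                return p
        raise KeyError(probe_id)

    def by_length(self, length: float, tolerance: float = 1.0) -> Probe | None:
        """The unique probe whose product length is within ``tolerance`` bp."""
        best, best_d = None, tolerance
        for p in self.probes:
            d = abs(p.product_length - length)
            if d <= best_d:
                best, best_d = p, d
        return best

    def for_arm(self, chromosome: str, arm: Arm | str) -> list[Probe]:
        arm = Arm(arm)
        return [p for p in self.probes if p.chromosome == chromosome and p.arm is arm]

    def arm_probe(self, arm_key: str) -> Probe:
        """The single probe of a genome-wide (telomeric/centromeric) panel on an arm."""
        chrom, arm = split_arm_key(arm_key)
        probes = self.for_arm(chrom, arm)
        if len(probes) != 1:
            raise DesignError(f"expected exactly one {self.role.value} probe on {arm_key}")
        return probes[0]

    def ordered_centromere_to_telomere(self) -> list[Probe]:
        """Arm-specific probes in the order breakpoint scanning expects."""
        if self.role is not ProbeRole.ARM_SPECIFIC:
            raise DesignError("ordering defined for ARM_SPECIFIC sets only")
        arm = self.probes[0].arm
        return sorted(self.probes, key=lambda p: p.anchor, reverse=(arm is Arm.L))

    @property
    def most_centromeric_id(self) -> str:
        return self.ordered_centromere_to_telomere()[0].id


@dataclass(frozen=True)
class DesignConstraints:
    min_unique_window: int = 300  # bp of element-free sequence a probe needs
    collocated_gap: int = 1000  # inter-element gaps below this share one probe
    start_length: int = 100  # bp, shortest amplification product
    min_length_gap: int = 2  # bp between adjacent product lengths
    #: arm-specific gaps wider than this get a second probe, so a
    #: breakpoint falling between them localizes to an element-free
    #: interval (an unannotated target) instead of the nearest element
    long_gap: int = 120_000


def _sorted_by_distal(elements: list[RepeatElement], arm: Arm) -> list[RepeatElement]:
    """Elements sorted centromere -> telomere."""
    return sorted(elements, key=lambda e: e.start, reverse=(arm is Arm.L))


def _telomeric_probe(
    chrom, arm: Arm, elements: list[RepeatElement], constraints: DesignConstraints
) -> Probe:
    name = f"{chrom.name}-{arm.value}-tel"
    lo, hi = chrom.arm_interval(arm)
    tel_edge = chrom.telomere_inner_edge(arm)
    if not elements:
        return Probe(name, chrom.name, arm, (lo + hi) // 2, ProbeRole.TELOMERIC)
    terminal = _sorted_by_distal(elements, arm)[-1]
    if arm is Arm.L:
        window = (tel_edge, terminal.start - 1)
    else:
        window = (terminal.end + 1, tel_edge)
    width = window[1] - window[0] + 1
    if width >= constraints.min_unique_window:
        return Probe(name, chrom.name, arm, (window[0] + window[1]) // 2, ProbeRole.TELOMERIC)
    # no usable unique window telomeric to the terminal element: fall back
    # to immediately centromeric of it
    offset = constraints.min_unique_window // 2
    anchor = terminal.end + offset if arm is Arm.L else terminal.start - offset
    if not (lo <= anchor <= hi):
        raise DesignError(f"no placeable telomeric probe window on {chrom.name}-{arm.value}")
    return Probe(
        name, chrom.name, arm, anchor, ProbeRole.TELOMERIC,
        placement=PlacementFlag.FALLBACK_CENTROMERIC,
    )


def _centromeric_probe(chrom, arm: Arm, elements: list[RepeatElement]) -> Probe:
    name = f"{chrom.name}-{arm.value}-cen"
    lo, hi = chrom.arm_interval(arm)
    if not elements:
        return Probe(name, chrom.name, arm, (lo + hi) // 2, ProbeRole.CENTROMERIC)
    innermost = _sorted_by_distal(elements, arm)[0]
    if arm is Arm.L:
        window = (innermost.end + 1, hi)
    else:
        window = (lo, innermost.start - 1)
    if window[1] < window[0]:
        raise DesignError(f"no placeable centromeric probe window on {chrom.name}-{arm.value}")
    return Probe(name, chrom.name, arm, (window[0] + window[1]) // 2, ProbeRole.CENTROMERIC)


def _arm_specific_probes(
    chrom, arm: Arm, elements: list[RepeatElement], constraints: DesignConstraints
) -> list[Probe]:
    ordered = _sorted_by_distal(elements, arm)  # centromere -> telomere
    # cluster closely collocated elements: gaps below the threshold get no probe
    blocks: list[list[RepeatElement]] = []
    for el in ordered:
        if blocks:
            prev = blocks[-1][-1]
            gap = (prev.start - el.end if arm is Arm.L else el.start - prev.end) - 1
            if gap < constraints.collocated_gap:
                blocks[-1].append(el)
                continue
        blocks.append([el])
    lo, hi = chrom.arm_interval(arm)
    cen_edge = hi if arm is Arm.L else lo
    tel_edge = chrom.telomere_inner_edge(arm)
    # boundaries walked centromere -> telomere
    bounds: list[int] = [cen_edge]
    for block in blocks:
        if arm is Arm.L:
            bounds.extend([max(e.end for e in block), min(e.start for e in block)])
        else:
            bounds.extend([min(e.start for e in block), max(e.end for e in block)])
    bounds.append(tel_edge)
    probes = []
    k = 0
    for i in range(0, len(bounds), 2):
        a, b = bounds[i], bounds[i + 1]
        if abs(b - a) > constraints.long_gap:
            anchors = [a + (b - a) // 3, a + 2 * (b - a) // 3]
        else:
            anchors = [(a + b) // 2]
        for anchor in anchors:
            probes.append(
                Probe(
                    f"{chrom.name}-{arm.value}-g{k:02d}",
                    chrom.name, arm, anchor, ProbeRole.ARM_SPECIFIC,
                )
            )
            k += 1
    return probes


def design_probe_set(
    annotation: GenomeAnnotation,
    role: ProbeRole | str,
    arm: str | None = None,
    constraints: DesignConstraints = DesignConstraints(),
) -> ProbeSet:
    """Design a probe panel and assign its unique product lengths.

    ``arm`` (an arm key like ``"chrIII-R"``) is required for, and only
    valid with, the ARM_SPECIFIC role.  The design is deterministic: probes
    are ordered by chromosome, then arm (L before R), then position, and
    product lengths form an arithmetic ladder from
    ``constraints.start_length`` with step ``constraints.min_length_gap``.
    """
    role = ProbeRole(role)
    if (arm is None) == (role is ProbeRole.ARM_SPECIFIC):
        raise DesignError("arm must be given exactly when role is ARM_SPECIFIC")
    probes: list[Probe] = []
    if role is ProbeRole.ARM_SPECIFIC:
        chrom_name, arm_enum = split_arm_key(arm)
        chrom = annotation.chromosome(chrom_name)
        elements = annotation.elements_on_arm(chrom_name, arm_enum)
        probes = _arm_specific_probes(chrom, arm_enum, elements, constraints)
    else:
        for chrom in annotation.chromosomes:
            for arm_enum in (Arm.L, Arm.R):
                elements = annotation.elements_on_arm(chrom.name, arm_enum)
                if role is ProbeRole.TELOMERIC:
                    probes.append(_telomeric_probe(chrom, arm_enum, elements, constraints))
                else:
                    probes.append(_centromeric_probe(chrom, arm_enum, elements))
    return assign_product_lengths(
        probes, annotation, constraints.start_length, constraints.min_length_gap, role
    )


def assign_product_lengths(
    probes: Sequence[Probe],
    annotation: GenomeAnnotation,
    start_length: int = 100,
    min_gap: int = 2,
    role: ProbeRole | None = None,
) -> ProbeSet:
    """Assign strictly increasing product lengths, ``min_gap`` bp apart.

    Probe order is deterministic: chromosome order of the annotation, arm L
    before R, then anchor position.
    """
    if start_length <= 0:
        raise DesignError("start_length must be positive")
    if min_gap < 1:
        raise DesignError("min_gap must be >= 1")
    chrom_order = {name: i for i, name in enumerate(annotation.chromosome_names)}
    ordered = sorted(
        probes, key=lambda p: (chrom_order[p.chromosome], p.arm.value, p.anchor)
    )
    assigned = [
        replace(p, product_length=start_length + i * min_gap)
        for i, p in enumerate(ordered)
    ]
    if role is None:
        roles = {p.role for p in assigned}
        if len(roles) != 1:
            raise DesignError("mixed probe roles; pass role explicitly")
        role = roles.pop()
    return ProbeSet(role=role, probes=assigned, min_gap=min_gap)


@dataclass(frozen=True)
class CoverageStat:
    covered: int
    total: int

    @property
    def percent(self) -> float:
        return round(100.0 * self.covered / self.total, 1) if self.total else 0.0


def probe_is_telomeric_to(probe: Probe, start: int, end: int) -> bool:
    """True if the probe anchor lies strictly telomeric to interval [start, end]."""
    if probe.arm is Arm.L:
        return probe.anchor < start
    return probe.anchor > end


def theoretical_coverage(catalog: TargetCatalog, probeset: ProbeSet) -> CoverageStat:
    """Fraction of catalog targets whose duplication the telomeric panel detects.

    A target is covered iff its arm's telomeric probe lies telomeric to it:
    the duplication (target element -> telomere) then spans the probe.
    Fallback probes sit centromeric to the arm's terminal element(s) and do
    not cover them.
    """
    if probeset.role is not ProbeRole.TELOMERIC:
        raise DesignError("coverage is defined for the telomeric panel")
    arm_probes = {}
    for p in probeset:
        if p.arm_key in arm_probes:
            raise DesignError(f"multiple telomeric probes on {p.arm_key}")
        arm_probes[p.arm_key] = p
    covered = 0
    for t in catalog.targets:
        probe = arm_probes.get(f"{t.chromosome}-{t.arm.value}")
        if probe is None:
            raise DesignError(f"panel has no probe for arm {t.chromosome}-{t.arm.value}")
        if probe_is_telomeric_to(probe, t.start, t.end):
            covered += 1
    return CoverageStat(covered=covered, total=catalog.total)


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

_PROBESET_COLS = [
    "probe_id", "chrom", "arm", "anchor_bp", "role", "product_length_bp", "placement_flag",
]


def write_probeset_tsv(probeset: ProbeSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PROBESET_COLS)
        for p in probeset:
            w.writerow(
                [p.id, p.chromosome, p.arm.value, p.anchor, p.role.value,
                 p.product_length, p.placement.value]
            )


def read_probeset_tsv(path: str | Path) -> ProbeSet:
    probes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _PROBESET_COLS if c not in (reader.fieldnames or [])]
        if missing:
            raise DesignError(f"{path}: missing columns {missing}")
        for row in reader:
            probes.append(
                Probe(
                    id=row["probe_id"],
                    chromosome=row["chrom"],
                    arm=Arm(row["arm"]),
                    anchor=int(row["anchor_bp"]),
                    role=ProbeRole(row["role"]),
                    product_length=int(row["product_length_bp"]),
                    placement=PlacementFlag(row["placement_flag"]),
                )
            )
    roles = {p.role for p in probes}
    if len(roles) != 1:
        raise DesignError(f"{path}: expected a single probe role, found {roles}")
    lengths = sorted(p.product_length for p in probes)
    gaps = [b - a for a, b in zip(lengths, lengths[1:])]
    return ProbeSet(role=roles.pop(), probes=probes, min_gap=min(gaps) if gaps else 2)
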