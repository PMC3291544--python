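"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study conditions of a budding-yeast GCR assay:

* an S288C-like repeat landscape — 16 chromosomes, 13 Ty2 elements, and a
  Ty1/solo-delta complement tuned so the genome carries exactly 254
  potential Ty-related translocation targets (Ty2 counted as two deltas),
  with named hotspot clusters on chrIII-R (FS1: a tandem delta triplet;
  FS2: a single delta), chrV-R, chrXIV-L and chrX-R, and four arms whose
  terminal element abuts the telomere (forcing fallback telomeric probes);
* hotspot-biased translocation cohorts in which every isolate carries the
  assay's chrV-L deletion and duplications are drawn from a per-target
  probability model;
* multiplicative peak noise (per-probe efficiency, per-sample scale,
  lognormal measurement error) on top of true copy numbers;
* jackpot-skewed fluctuation-test culture counts from a
  Luria-Delbruck-style generative scheme;
* paired aneuploidy indicators for selective/nonselective matched isolates.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .classify import (
    BreakpointCall,
    Geometry,
    IsolateClassification,
    IsolateStatus,
    Validity,
)
from .copynumber import PeakTable
from .genome import (
    Arm,
    Chromosome,
    ElementClass,
    GenomeAnnotation,
    Orientation,
    RepeatElement,
    TargetCatalog,
    TargetSite,
    build_target_catalog,
    split_arm_key,
)
from .probes import PlacementFlag, Probe, ProbeRole, ProbeSet, probe_is_telomeric_to

__all__ = [
    "EventModel",
    "NoiseModel",
    "SimulatedIsolate",
    "make_fixture_annotation",
    "default_wildtype_event_model",
    "reference_wildtype_events",
    "reference_rad52_events",
    "simulate_cohort",
    "true_copy_numbers",
    "simulate_peaks",
    "simulate_fluctuation",
    "simulate_paired_aneuploidy",
    "lea_coulson_rate",
    "ASSAY_ARM",
]

#: the chromosome arm whose terminal loss the assay selects for
ASSAY_ARM = "chrV-L"

# ---------------------------------------------------------------------------
# fixture annotation
# ---------------------------------------------------------------------------

# Chromosome sizes (bp) and centromere midpoints loosely following the
# S288C karyotype; exact values are not load-bearing, only the arm
# structure and element counts are.
_CHROM_SPECS: list[tuple[str, int, int]] = [
    ("chrI", 230_000, 151_000),
    ("chrII", 813_000, 238_000),
    ("chrIII", 317_000, 114_000),
    ("chrIV", 1_532_000, 450_000),
    ("chrV", 577_000, 152_000),
    ("chrVI", 270_000, 148_000),
    ("chrVII", 1_091_000, 497_000),
    ("chrVIII", 563_000, 106_000),
    ("chrIX", 440_000, 356_000),
    ("chrX", 746_000, 436_000),
    ("chrXI", 667_000, 440_000),
    ("chrXII", 1_078_000, 151_000),
    ("chrXIII", 924_000, 268_000),
    ("chrXIV", 784_000, 628_000),
    ("chrXV", 1_091_000, 327_000),
    ("chrXVI", 948_000, 556_000),
]

_TEL_LEN = 500  # bp of terminal telomeric repeat on each arm
_CEN_LEN = 120

_TY1_LEN = 5900
_TY2_LEN = 5950
_DELTA_LEN = 334

# Named elements on the four hotspot arms.  Orientations follow the
# Watson/Crick naming convention of the locus ids (W = + strand, C = -);
# a + strand element on a right arm is telomere-oriented.
# (id, chrom, start, class, strand)
_NAMED_ELEMENTS: list[tuple[str, str, int, ElementClass, str]] = [
    # chrIII-R: FS1 = tandem delta triplet, FS2 = single delta
    ("YCRWdelta8", "chrIII", 227_000, ElementClass.SOLO_DELTA, "+"),
    ("YCRWdelta9", "chrIII", 227_600, ElementClass.SOLO_DELTA, "+"),
    ("YCRWdelta10", "chrIII", 228_200, ElementClass.SOLO_DELTA, "+"),
    ("YCRWdelta11", "chrIII", 250_000, ElementClass.SOLO_DELTA, "+"),
    # chrIII-L carries a pair of deltas (duplications here occur without
    # any full-length Ty1 on the arm)
    ("YCLWdelta1", "chrIII", 60_000, ElementClass.SOLO_DELTA, "+"),
    ("YCLWdelta2", "chrIII", 82_000, ElementClass.SOLO_DELTA, "+"),
    # chrV-R, centromere -> telomere
    ("YERCdelta14", "chrV", 350_000, ElementClass.SOLO_DELTA, "-"),
    ("YERCdelta15", "chrV", 350_600, ElementClass.SOLO_DELTA, "-"),
    ("YERCdelta16", "chrV", 351_200, ElementClass.SOLO_DELTA, "-"),
    ("YERWdelta17", "chrV", 385_000, ElementClass.SOLO_DELTA, "+"),
    ("YERWdelta21", "chrV", 385_700, ElementClass.SOLO_DELTA, "+"),
    ("YERCTy1-1", "chrV", 386_400, ElementClass.TY1, "-"),
    ("YERWdelta22", "chrV", 480_000, ElementClass.SOLO_DELTA, "+"),
    ("YERCTy1-2", "chrV", 520_000, ElementClass.TY1, "-"),
    # chrX-R: tandem Ty1 pair
    ("YJRWTy1-1", "chrX", 590_000, ElementClass.TY1, "+"),
    ("YJRWTy1-2", "chrX", 596_200, ElementClass.TY1, "+"),
    # chrXIV-L, centromere -> telomere (left arm: decreasing coordinate)
    ("YNLCTy1-1", "chrXIV", 560_000, ElementClass.TY1, "-"),
    ("YNLWTy1-2", "chrXIV", 430_000, ElementClass.TY1, "+"),
    ("YNLCTy2-1", "chrXIV", 300_000, ElementClass.TY2, "-"),
]

#: arms whose terminal element abuts the telomere, forcing the telomeric
#: probe to fall back centromeric of it
FALLBACK_ARMS = ("chrII-L", "chrIV-R", "chrIX-R", "chrXV-L")

#: hotspot arms whose element layout is fixed by the named fixtures above;
#: the random placer never adds elements here, keeping their probe ladders
#: and breakpoint targets exactly as designed
_RESERVED_ARMS = frozenset({"chrIII-R", "chrV-R", "chrX-R", "chrXIV-L"})


def _strand_orientation(strand: str, arm: Arm) -> Orientation:
    from .genome import strand_to_orientation

    return strand_to_orientation(strand, arm)


@dataclass(frozen=True)
class FixtureParams:
    n_chromosomes: int = 16
    ty2_count: int = 13
    target_total: int = 254
    ty1_count: int = 32
    #: fraction of randomly placed elements oriented toward the telomere
    telomere_oriented_fraction: float = 0.5
    min_separation: int = 2_000  # bp between placed elements
    edge_margin: int = 3_000  # keep random elements clear of telomeres/centromere


def make_fixture_annotation(
    params: FixtureParams = FixtureParams(), seed: int = 0
) -> GenomeAnnotation:
    """Build the S288C-like fixture annotation.

    Element totals satisfy ``ty1 + delta + 2 * ty2 == target_total`` with
    the requested Ty1/Ty2 counts; hotspot-arm elements are at fixed named
    positions, the remainder are placed by a seeded RNG (length-weighted
    arm choice, uniform position, minimum separation).  Deterministic for
    a given (params, seed).
    """
    if params.n_chromosomes != len(_CHROM_SPECS):
        raise ValueError(
            f"fixture supports exactly {len(_CHROM_SPECS)} chromosomes"
        )
    delta_count = params.target_total - params.ty1_count - 2 * params.ty2_count
    if delta_count < 0:
        raise ValueError("infeasible constraints: negative solo-delta count")

    chroms = [
        Chromosome(
            name=name,
            length=length,
            cen_start=cen_mid - _CEN_LEN // 2,
            cen_end=cen_mid + _CEN_LEN // 2,
            tel_left_end=_TEL_LEN,
            tel_right_start=length - _TEL_LEN + 1,
        )
        for name, length, cen_mid in _CHROM_SPECS
    ]
    chrom_by_name = {c.name: c for c in chroms}

    elements: list[RepeatElement] = []
    lengths = {
        ElementClass.TY1: _TY1_LEN,
        ElementClass.TY2: _TY2_LEN,
        ElementClass.SOLO_DELTA: _DELTA_LEN,
    }
    for eid, chrom, start, cls, strand in _NAMED_ELEMENTS:
        end = start + lengths[cls] - 1
        c = chrom_by_name[chrom]
        arm = Arm.L if end < c.cen_start else Arm.R
        elements.append(
            RepeatElement(eid, chrom, start, end, cls, _strand_orientation(strand, arm))
        )

    # terminal deltas abutting the telomere on the four fallback arms
    for arm_key in FALLBACK_ARMS:
        chrom_name, arm = split_arm_key(arm_key)
        c = chrom_by_name[chrom_name]
        if arm is Arm.L:
            start = c.tel_left_end + 100  # only 99 bp of unique window left
        else:
            start = c.tel_right_start - 100 - _DELTA_LEN
        end = start + _DELTA_LEN - 1
        elements.append(
            RepeatElement(
                f"{chrom_name}-{arm.value}-terminal-delta", chrom_name, start, end,
                ElementClass.SOLO_DELTA, _strand_orientation("+", arm),
            )
        )

    named_ty1 = sum(1 for e in elements if e.cls is ElementClass.TY1)
    named_ty2 = sum(1 for e in elements if e.cls is ElementClass.TY2)
    named_delta = sum(1 for e in elements if e.cls is ElementClass.SOLO_DELTA)
    remaining = (
        [ElementClass.TY1] * (params.ty1_count - named_ty1)
        + [ElementClass.TY2] * (params.ty2_count - named_ty2)
        + [ElementClass.SOLO_DELTA] * (delta_count - named_delta)
    )
    if (params.ty1_count < named_ty1 or params.ty2_count < named_ty2
            or delta_count < named_delta):
        raise ValueError("infeasible constraints: fewer elements than named fixtures")

    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for e in elements:
        occupied.setdefault(e.chromosome, []).append((e.start, e.end))
    arm_intervals = []
    for c in chroms:
        for arm in (Arm.L, Arm.R):
            if f"{c.name}-{arm.value}" in _RESERVED_ARMS:
                continue
            lo, hi = c.arm_interval(arm)
            lo = max(lo, (c.tel_left_end if arm is Arm.L else c.cen_end) + params.edge_margin)
            hi = min(hi, (c.cen_start if arm is Arm.L else c.tel_right_start) - params.edge_margin)
            if hi - lo > 20_000:
                arm_intervals.append((c.name, arm, lo, hi))
    weights = np.array([hi - lo for _, _, lo, hi in arm_intervals], dtype=float)
    weights /= weights.sum()

    counter = 0
    for cls in remaining:
        el_len = lengths[cls]
        placed = False
        for _ in range(400):
            i = rng.choice(len(arm_intervals), p=weights)
            chrom_name, arm, lo, hi = arm_intervals[i]
            start = int(rng.integers(lo, hi - el_len))
            end = start + el_len - 1
            clash = any(
                start - params.min_separation <= e1 and end + params.min_separation >= s0
                for s0, e1 in occupied.get(chrom_name, [])
            )
            if clash:
                continue
            orient = (
                Orientation.TELOMERE
                if rng.random() < params.telomere_oriented_fraction
                else Orientation.CENTROMERE
            )
            tag = {ElementClass.TY1: "Ty1", ElementClass.TY2: "Ty2",
                   ElementClass.SOLO_DELTA: "delta"}[cls]
            counter += 1
            elements.append(
                RepeatElement(
                    f"syn{tag}-{counter:03d}", chrom_name, start, end, cls, orient
                )
            )
            occupied.setdefault(chrom_name, []).append((start, end))
            placed = True
            break
        if not placed:
            raise ValueError("infeasible constraints: could not place all elements")
    return GenomeAnnotation(chroms, elements)


# ---------------------------------------------------------------------------
# event model
# ---------------------------------------------------------------------------

@dataclass
class EventModel:
    """Per-isolate event probabilities for a simulated GCR cohort.

    ``target_probs`` maps catalog target ids to the probability that an
    isolate's duplication was mediated by that target; the map sums to the
    duplication-bearing fraction.  The remaining mass splits between
    deletion-only isolates and ambiguous isolates.  Whole-chromosome
    duplications occur independently per isolate at
    ``whole_chromosome_dup_rate`` unless ``gcr_aneuploidy_coupling`` ties
    them to duplication-bearing GCRs.
    """

    target_probs: dict[str, float]
    no_duplication_fraction: float = 0.0
    ambiguous_fraction: float = 0.0
    whole_chromosome_dup_rate: float = 0.0
    #: 0 = independent; 1 = whole-chromosome duplications occur only in
    #: GCR-bearing isolates (probability mass concentrated there)
    gcr_aneuploidy_coupling: float = 0.0

    def __post_init__(self):
        total = sum(self.target_probs.values())
        budget = total + self.no_duplication_fraction + self.ambiguous_fraction
        if budget > 1.0 + 1e-9:
            raise ValueError(f"event probabilities sum to {budget} > 1")
        for name in ("no_duplication_fraction", "ambiguous_fraction",
                     "whole_chromosome_dup_rate", "gcr_aneuploidy_coupling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


# Hotspot target usage of the wild-type cohort: (target element ids, count).
# Six recurrent target regions account for 67 of the 106 arm duplications;
# the chrV-R list also includes its four singleton targets.
_WT_HOTSPOT_COUNTS: list[tuple[str, tuple[str, ...], int]] = [
    ("chrIII-R", ("YCRWdelta8", "YCRWdelta9", "YCRWdelta10"), 17),  # FS1
    ("chrIII-R", ("YCRWdelta11",), 11),  # FS2
    ("chrV-R", ("YERWdelta17", "YERWdelta21", "YERCTy1-1"), 18),
    ("chrV-R", ("YERCdelta14", "YERCdelta15", "YERCdelta16"), 5),
    ("chrV-R", (), 1),  # no annotated element in the breakpoint interval
    ("chrV-R", (), 1),  # (a second unannotated-target event)
    ("chrV-R", ("YERWdelta22",), 1),
    ("chrV-R", ("YERCTy1-2",), 1),
    ("chrXIV-L", ("YNLCTy2-1",), 6),
    ("chrXIV-L", ("YNLCTy1-1",), 1),
    ("chrXIV-L", ("YNLWTy1-2",), 1),
    ("chrX-R", ("YJRWTy1-1", "YJRWTy1-2"), 10),
]

_WT_N = 112
_WT_N_DUP = 106
_WT_N_NODUP = 5
_WT_N_AMBIG = 1

#: breakpoint positions of the two chrV-R events whose target interval
#: carries no annotated element: inside the long element-free stretch
#: between the centromere and the YERCdelta14-16 cluster, bracketed by the
#: ladder's paired long-gap probes
_VR_UNKNOWN_POSITIONS = (250_000, 255_000)


def default_wildtype_event_model(
    annotation: GenomeAnnotation,
    catalog: TargetCatalog | None = None,
) -> EventModel:
    """The wild-type study regime as a generative model.

    Hotspot regions carry their observed maximum-likelihood fractions of
    the 106 duplication-bearing isolates out of 112 (with 5 deletion-only
    and 1 ambiguous); the non-hotspot remainder is spread uniformly over
    all other catalog targets.
    """
    if catalog is None:
        catalog = build_target_catalog(annotation)
    probs: dict[str, float] = {}
    hotspot_elements: set[str] = set()
    by_element: dict[str, str] = {}
    for t in catalog.targets:
        by_element.setdefault(t.element_id, t.id)
    n_hot = 0
    for arm, element_ids, count in _WT_HOTSPOT_COUNTS:
        if not element_ids:
            continue
        n_hot += count
        # mass of a multi-element cluster is carried by its first target
        per = count / _WT_N
        lead = by_element[element_ids[0]]
        probs[lead] = probs.get(lead, 0.0) + per
        hotspot_elements.update(element_ids)
    n_unlocalized = sum(c for _, ids, c in _WT_HOTSPOT_COUNTS if not ids)
    n_other = _WT_N_DUP - n_hot - n_unlocalized
    others = [
        t for t in catalog.targets
        if t.element_id not in hotspot_elements
        and f"{t.chromosome}-{t.arm.value}" != ASSAY_ARM
    ]
    # fold the unlocalized events into the diffuse remainder
    rest_mass = (n_other + n_unlocalized) / _WT_N
    for t in others:
        probs[t.id] = probs.get(t.id, 0.0) + rest_mass / len(others)
    return EventModel(
        target_probs=probs,
        no_duplication_fraction=_WT_N_NODUP / _WT_N,
        ambiguous_fraction=_WT_N_AMBIG / _WT_N,
    )


# ---------------------------------------------------------------------------
# simulated isolates
# ---------------------------------------------------------------------------

@dataclass
class SimulatedIsolate:
    """Ground truth for one simulated isolate."""

    isolate: str
    dup_arm: str | None = None  # arm key of the duplicated arm, if any
    dup_target_ids: tuple[str, ...] = ()  # element id(s) at the breakpoint
    dup_position: int | None = None  # telomeric edge of the target region
    ambiguous: bool = False
    whole_chromosome_dups: tuple[str, ...] = ()

    @property
    def has_duplication(self) -> bool:
        return self.dup_arm is not None and not self.ambiguous

    def expected_classification(self) -> IsolateClassification:
        if self.ambiguous:
            status = IsolateStatus.AMBIGUOUS
        elif self.dup_arm is None and not self.whole_chromosome_dups:
            status = IsolateStatus.NO_DUPLICATION
        else:
            status = IsolateStatus.CLASSIFIED
        return IsolateClassification(
            isolate=self.isolate,
            has_assay_deletion=True,
            arm_duplications=[self.dup_arm] if (self.dup_arm and not self.ambiguous) else [],
            whole_chromosome_duplications=list(self.whole_chromosome_dups),
            status=status,
        )


def _element_by_id(annotation: GenomeAnnotation) -> dict[str, RepeatElement]:
    return {e.id: e for e in annotation.elements}


def _target_telomeric_edge(annotation: GenomeAnnotation, arm_key: str,
                           element_ids: tuple[str, ...]) -> int:
    """The telomeric edge of a target region: the duplication spans from
    here to the telomere."""
    chrom, arm = split_arm_key(arm_key)
    els = [_element_by_id(annotation)[i] for i in element_ids]
    if arm is Arm.L:
        return min(e.start for e in els)
    return max(e.end for e in els)


def simulate_cohort(
    annotation: GenomeAnnotation,
    event_model: EventModel,
    n: int,
    seed: int = 0,
    catalog: TargetCatalog | None = None,
) -> list[SimulatedIsolate]:
    """Draw a cohort of GCR-bearing isolates from an event model.

    Every isolate carries the assay's chrV-L deletion (the selection);
    duplication targets, deletion-only status, ambiguity and independent
    whole-chromosome duplications are drawn per the model.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if catalog is None:
        catalog = build_target_catalog(annotation)
    target_by_id = {t.id: t for t in catalog.targets}
    rng = np.random.default_rng(seed)
    ids = list(event_model.target_probs)
    probs = np.array([event_model.target_probs[i] for i in ids])
    p_nodup = event_model.no_duplication_fraction
    p_ambig = event_model.ambiguous_fraction
    outcomes = ["nodup", "ambiguous"] + ids
    weights = np.concatenate([[p_nodup, p_ambig], probs])
    slack = 1.0 - weights.sum()
    if slack > 1e-9:  # any unassigned mass counts as deletion-only
        weights[0] += slack
    weights = weights / weights.sum()
    chrom_names = annotation.chromosome_names

    isolates = []
    for i in range(n):
        choice = outcomes[rng.choice(len(outcomes), p=weights)]
        dup_arm = None
        dup_ids: tuple[str, ...] = ()
        dup_pos = None
        ambiguous = False
        if choice == "ambiguous":
            ambiguous = True
            # an ambiguous isolate carries a half-strength duplication signal
            t = target_by_id[ids[rng.choice(len(ids), p=probs / probs.sum())]]
            dup_arm = f"{t.chromosome}-{t.arm.value}"
            dup_ids = (t.element_id,)
            dup_pos = t.start if t.arm is Arm.L else t.end
        elif choice != "nodup":
            t = target_by_id[choice]
            dup_arm = f"{t.chromosome}-{t.arm.value}"
            dup_ids = (t.element_id,)
            dup_pos = t.start if t.arm is Arm.L else t.end
        whole: tuple[str, ...] = ()
        p_whole = event_model.whole_chromosome_dup_rate
        if event_model.gcr_aneuploidy_coupling > 0:
            # concentrate aneuploidy on duplication-bearing GCR isolates
            bearing = dup_arm is not None
            c = event_model.gcr_aneuploidy_coupling
            p_whole = p_whole * (1 + c) if bearing else p_whole * (1 - c)
        if p_whole > 0 and rng.random() < min(1.0, p_whole):
            whole = (chrom_names[rng.integers(len(chrom_names))],)
        isolates.append(
            SimulatedIsolate(
                isolate=f"iso{i + 1:04d}",
                dup_arm=dup_arm,
                dup_target_ids=dup_ids,
                dup_position=dup_pos,
                ambiguous=ambiguous,
                whole_chromosome_dups=whole,
            )
        )
    return isolates


def reference_wildtype_events(
    annotation: GenomeAnnotation | None = None,
) -> list[SimulatedIsolate]:
    """The wild-type cohort with the exact published event counts.

    112 isolates: 17 FS1 + 11 FS2 on chrIII-R, 27 chrV-R (18 + 5 + 4
    singletons), 8 chrXIV-L, 10 chrX-R, 33 duplications spread over other
    arms, 5 deletion-only, 1 ambiguous.  Deterministic; feed through the
    peak simulator and the calling/classification pipeline to reproduce
    the cohort summary numbers.
    """
    if annotation is None:
        annotation = make_fixture_annotation()
    isolates: list[SimulatedIsolate] = []
    k = 0
    unknown_pos = list(_VR_UNKNOWN_POSITIONS)

    def add(arm: str | None, ids: tuple[str, ...], count: int, ambiguous: bool = False):
        nonlocal k
        for _ in range(count):
            k += 1
            pos = (
                _target_telomeric_edge(annotation, arm, ids) if (arm and ids) else None
            )
            if arm and not ids:  # unannotated target in an element-free gap
                pos = unknown_pos.pop(0)
            isolates.append(
                SimulatedIsolate(
                    isolate=f"wt{k:03d}",
                    dup_arm=arm,
                    dup_target_ids=ids,
                    dup_position=pos,
                    ambiguous=ambiguous,
                )
            )

    for arm, ids, count in _WT_HOTSPOT_COUNTS:
        add(arm, ids, count)
    # the 33 non-hotspot duplications, spread deterministically over arms
    # observed at low frequency (including delta-only arms)
    other_arms = [
        "chrIII-L", "chrIX-L", "chrXIII-L", "chrXIV-R", "chrXV-L", "chrXVI-L",
        "chrII-R", "chrIV-R", "chrVII-R", "chrXII-R", "chrVI-R",
    ]
    annotation_catalog = build_target_catalog(annotation)
    for j in range(33):
        arm = other_arms[j % len(other_arms)]
        on_arm = annotation_catalog.on_arm(*split_arm_key(arm))
        chrom, a = split_arm_key(arm)
        # pick the most centromeric target so the telomeric probe covers it
        targets = sorted(on_arm, key=lambda t: t.start, reverse=(a is Arm.L))
        t = targets[0]
        add(arm, (t.element_id,), 1)
    add(None, (), _WT_N_NODUP)
    add("chrXIII-L", tuple(
        t.element_id for t in annotation_catalog.on_arm("chrXIII", Arm.L)[:1]
    ), _WT_N_AMBIG, ambiguous=True)
    assert len(isolates) == _WT_N
    return isolates


def reference_rad52_events(
    annotation: GenomeAnnotation | None = None,
) -> list[SimulatedIsolate]:
    """The recombination-deficient (rad52-type) regime: 50 isolates, 34
    deletion-only (68%), 16 with a single arm duplication."""
    if annotation is None:
        annotation = make_fixture_annotation()
    catalog = build_target_catalog(annotation)
    isolates = []
    dup_arms = ["chrIII-R", "chrIV-R", "chrX-R", "chrX-R", "chrV-R"]
    arms_cycle = dup_arms + ["chrXIII-L", "chrII-R", "chrXIV-L", "chrXII-R",
                             "chrIX-L", "chrXV-R"]
    for i in range(16):
        arm = arms_cycle[i % len(arms_cycle)]
        chrom, a = split_arm_key(arm)
        targets = sorted(catalog.on_arm(chrom, a), key=lambda t: t.start,
                         reverse=(a is Arm.L))
        t = targets[0]
        pos = t.start if a is Arm.L else t.end
        isolates.append(
            SimulatedIsolate(f"r52-{i + 1:03d}", arm, (t.element_id,), pos)
        )
    for i in range(34):
        isolates.append(SimulatedIsolate(f"r52-{i + 17:03d}"))
    return isolates


# ---------------------------------------------------------------------------
# true copy numbers and noisy peaks
# ---------------------------------------------------------------------------

def true_copy_numbers(
    isolates: Sequence[SimulatedIsolate],
    probeset: ProbeSet,
    annotation: GenomeAnnotation,
    assay_arm: str = ASSAY_ARM,
) -> pd.DataFrame:
    """True per-probe copy number of each isolate for a probe panel.

    Baseline 1 everywhere; 0 at the assay arm's telomeric probe (the
    selected deletion); +1 at every probe telomeric of a duplication
    breakpoint on the duplicated arm; +1 at every probe of a
    whole-chromosome-duplicated chromosome.  Ambiguous isolates carry 1.5
    at the affected probe (a mixed-population signal that no integer call
    fits).
    """
    mat = pd.DataFrame(
        1.0, index=[s.isolate for s in isolates], columns=probeset.ids
    )
    for s in isolates:
        for p in probeset:
            if p.arm_key == assay_arm and p.role is ProbeRole.TELOMERIC:
                mat.loc[s.isolate, p.id] = 0.0
        if s.dup_arm is not None and s.dup_position is not None:
            for p in probeset:
                if p.arm_key != s.dup_arm:
                    continue
                dup_covers = probe_is_telomeric_to(p, s.dup_position, s.dup_position)
                if dup_covers:
                    mat.loc[s.isolate, p.id] += 0.5 if s.ambiguous else 1.0
        for chrom in s.whole_chromosome_dups:
            for p in probeset:
                if p.chromosome == chrom:
                    mat.loc[s.isolate, p.id] += 1.0
    return mat


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative noise on peak areas.

    area = sample_scale * probe_efficiency * CN * exp(eps),
    eps ~ Normal(0, cv); zero copies emit a small background area.
    """

    sigma_efficiency: float = 0.2  # lognormal sd of per-probe efficiency
    sigma_scale: float = 0.3  # lognormal sd of per-sample loading scale
    cv: float = 0.05  # measurement coefficient of variation
    background: float = 10.0  # area emitted at copy number 0
    base_area: float = 10_000.0  # fluorescence units per copy, pre-noise

    def __post_init__(self):
        if min(self.sigma_efficiency, self.sigma_scale, self.cv) < 0:
            raise ValueError("noise sigmas must be nonnegative")
        if self.background < 0:
            raise ValueError("background must be nonnegative")


def simulate_peaks(
    true_cn: pd.DataFrame,
    probeset: ProbeSet,
    noise: NoiseModel = NoiseModel(),
    n_controls: int = 3,
    seed: int = 0,
) -> list[PeakTable]:
    """Noisy peak tables for a cohort plus ``n_controls`` control samples.

    Controls are all-ones copy number.  Probe efficiencies are drawn once
    and shared by every sample in the run, mirroring a real multiplex
    panel's probe-to-probe amplification differences.
    """
    if n_controls < 1:
        raise ValueError("need at least one control sample")
    rng = np.random.default_rng(seed)
    probes = list(probeset)
    efficiency = np.exp(rng.normal(0.0, noise.sigma_efficiency, size=len(probes)))

    def one_sample(sample_id: str, cn: np.ndarray, is_control: bool) -> PeakTable:
        scale = math.exp(rng.normal(0.0, noise.sigma_scale))
        eps = np.exp(rng.normal(0.0, noise.cv, size=len(probes)))
        areas = noise.base_area * scale * efficiency * cn * eps
        areas = np.where(cn > 0, areas, noise.background * scale)
        peaks = [
            (float(p.product_length), float(a)) for p, a in zip(probes, areas)
        ]
        return PeakTable(sample_id, peaks, is_control=is_control)

    tables = [
        one_sample(f"control{i + 1}", np.ones(len(probes)), True)
        for i in range(n_controls)
    ]
    for isolate in true_cn.index:
        cn = true_cn.loc[isolate, [p.id for p in probes]].to_numpy(dtype=float)
        tables.append(one_sample(str(isolate), cn, False))
    return tables


# ---------------------------------------------------------------------------
# fluctuation assay
# ---------------------------------------------------------------------------

def lea_coulson_rate(count: int, final_population: float) -> float:
    """Per-culture rate via the method-of-the-median transform.

    Solves r / m - ln(m) = 1.24 for the expected mutation number m given a
    culture's mutant count r, and returns m / N.  Monotone in r, so the
    cohort median of transformed values estimates the rate without the
    upward jackpot bias of raw mutant frequencies.  r = 0 maps to rate 0.
    """
    if count <= 0:
        return 0.0

    def f(log_m: float) -> float:
        m = math.exp(log_m)
        return count / m - log_m - 1.24

    lo, hi = -30.0, math.log(max(count, 2.0) * 10)
    while f(hi) > 0:
        hi += 5.0
    m = math.exp(optimize.brentq(f, lo, hi, xtol=1e-12))
    return m / final_population


def simulate_fluctuation(
    mutation_rate: float,
    final_population: float,
    n_cultures: int,
    seed: int = 0,
    transform: str = "frequency",
) -> tuple[np.ndarray, np.ndarray]:
    """Mutant counts and per-culture rate values for a fluctuation test.

    The generative scheme grows each culture by deterministic doubling
    from a single founder to ``final_population``; each generation g
    acquires Poisson(rate * population_g) new, heritable mutations whose
    descendants all survive to plating.  This produces the characteristic
    heavy-tailed ("jackpot") count distribution.

    ``transform``: ``"frequency"`` (default; count / population, whose
    cohort median is robust to jackpots) or ``"lea_coulson"``
    (method-of-the-median per-culture values).
    """
    if mutation_rate == 0.0:
        counts = np.zeros(n_cultures, dtype=np.int64)
        return counts, np.zeros(n_cultures)
    if not (0.0 < mutation_rate < 1.0):
        raise ValueError("mutation rate must lie in [0, 1)")
    if final_population < 1e3:
        raise ValueError("final population must be at least 1e3")
    generations = int(math.ceil(math.log2(final_population)))
    n0 = final_population / 2.0 ** generations
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_cultures, dtype=np.int64)
    for g in range(1, generations + 1):
        # mutations arise in the cells newly born this generation
        new_cells = n0 * 2.0 ** (g - 1)
        new_mutants = rng.poisson(mutation_rate * new_cells, size=n_cultures)
        counts += new_mutants * 2 ** (generations - g)
    if transform == "frequency":
        rates = counts / final_population
    elif transform == "lea_coulson":
        rates = np.array([lea_coulson_rate(int(c), final_population) for c in counts])
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return counts, rates


# ---------------------------------------------------------------------------
# paired aneuploidy
# ---------------------------------------------------------------------------

def simulate_paired_aneuploidy(
    n: int,
    p_selective: float,
    p_nonselective: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired aneuploidy indicators for matched selective/nonselective isolates.

    One matched pair per independent culture: the GCR-selected colony is
    aneuploid with probability ``p_selective``, its nonselectively grown
    sibling with probability ``p_nonselective``, independently.  The
    discordant-pair counts feed the paired exact test.
    """
    for p in (p_selective, p_nonselective):
        if not (0.0 <= p <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sel = rng.random(n) < p_selective
    nonsel = rng.random(n) < p_nonselective
    return pd.DataFrame(
        {"culture": [f"c{i + 1:03d}" for i in range(n)],
         "selective_aneuploid": sel, "nonselective_aneuploid": nonsel}
    ).set_index("culture")


def discordant_counts(pairs: pd.DataFrame) -> tuple[int, int]:
    """(b, c): selective-only and nonselective-only aneuploid pair counts."""
    b = int((pairs["selective_aneuploid"] & ~pairs["nonselective_aneuploid"]).sum())
    c = int((~pairs["selective_aneuploid"] & pairs["nonselective_aneuploid"]).sum())
    return b, c
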