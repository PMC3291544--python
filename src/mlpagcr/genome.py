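"""Genome annotation model and the catalog of Ty-mediated translocation targets.

The assay this package analyzes selects for loss of a nonessential terminal
segment of chromosome V-L seeded by a full-length Ty1 element; the broken
chromosome is healed by nonreciprocal recombination with an ectopic Ty1, Ty2
or solo-delta element elsewhere in the genome, duplicating everything from
that target element to the telomere of the target arm.  This module models
the annotation (chromosomes, centromeres, telomeres, repeat elements) and
derives the catalog of *potential* translocation targets against which the
observed duplication distribution is compared.

Coordinates are 1-based inclusive throughout (SGD convention).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Arm",
    "ElementClass",
    "Orientation",
    "RepeatElement",
    "Chromosome",
    "GenomeAnnotation",
    "TargetSite",
    "TargetCatalog",
    "AnnotationError",
    "load_annotation",
    "write_annotation",
    "build_target_catalog",
    "arm_target_probabilities",
    "TY2_LTR_LENGTH",
]

#: Length in bp of the terminal long-terminal-repeats carved out of a Ty2
#: element when it is counted as two independent delta targets.
TY2_LTR_LENGTH = 334


class AnnotationError(ValueError):
    """Raised when an annotation record violates a structural invariant."""


class Arm(str, Enum):
    L = "L"
    R = "R"


class ElementClass(str, Enum):
    TY1 = "TY1"
    TY2 = "TY2"
    SOLO_DELTA = "SOLO_DELTA"


class Orientation(str, Enum):
    """Transcriptional direction of an element relative to its arm's telomere.

    A translocation targeting a TELOMERE-oriented element yields a stable
    monocentric product; a CENTROMERE-oriented target yields a dicentric
    intermediate that must undergo secondary rearrangements.
    """

    TELOMERE = "TELOMERE"
    CENTROMERE = "CENTROMERE"


class CatalogMode(str, Enum):
    TY1_ONLY = "TY1_ONLY"
    TY1_PLUS_DELTA = "TY1_PLUS_DELTA"


class OrientationFilter(str, Enum):
    ALL = "ALL"
    TELOMERE_ORIENTED = "TELOMERE_ORIENTED"


def strand_to_orientation(strand: str, arm: Arm) -> Orientation:
    """Resolve a GFF strand symbol to a telomere/centromere orientation.

    Convention: on a right arm "+" transcribes toward the right telomere
    (TELOMERE-oriented); on a left arm "-" transcribes toward the left
    telomere.
    """
    if strand not in {"+", "-"}:
        raise AnnotationError(f"invalid strand {strand!r}")
    if arm is Arm.R:
        return Orientation.TELOMERE if strand == "+" else Orientation.CENTROMERE
    return Orientation.TELOMERE if strand == "-" else Orientation.CENTROMERE


def orientation_to_strand(orientation: Orientation, arm: Arm) -> str:
    if arm is Arm.R:
        return "+" if orientation is Orientation.TELOMERE else "-"
    return "-" if orientation is Orientation.TELOMERE else "+"


@dataclass(frozen=True)
class RepeatElement:
    id: str
    chromosome: str
    start: int
    end: int
    cls: ElementClass
    orientation: Orientation
    arm: Arm | None = None  # resolved during annotation validation

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"element {self.id}: invalid interval [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    cen_start: int
    cen_end: int
    tel_left_end: int = 0
    tel_right_start: int = 0

    def __post_init__(self):
        if self.length < 3:
            raise AnnotationError(f"{self.name}: length {self.length} too small")
        if not (1 < self.cen_start <= self.cen_end < self.length):
            raise AnnotationError(
                f"{self.name}: centromere [{self.cen_start}, {self.cen_end}] "
                f"not strictly inside chromosome of length {self.length}"
            )
        tl = self.tel_left_end
        tr = self.tel_right_start
        if tl >= self.cen_start:
            raise AnnotationError(f"{self.name}: left telomere overlaps centromere")
        if tr and tr <= self.cen_end:
            raise AnnotationError(f"{self.name}: right telomere overlaps centromere")

    def arm_interval(self, arm: Arm) -> tuple[int, int]:
        """The interval of an arm, exclusive of the centromere."""
        if arm is Arm.L:
            return (1, self.cen_start - 1)
        return (self.cen_end + 1, self.length)

    def telomere_inner_edge(self, arm: Arm) -> int:
        """The arm-interior boundary of the arm's telomeric repeat region."""
        if arm is Arm.L:
            return self.tel_left_end + 1
        tr = self.tel_right_start if self.tel_right_start else self.length + 1
        return tr - 1


@dataclass
class GenomeAnnotation:
    """A validated genome annotation.

    ``elements`` are stored sorted by (chromosome order, coordinate); each
    element carries its resolved arm.
    """

    chromosomes: list[Chromosome]
    elements: list[RepeatElement] = field(default_factory=list)

    def __post_init__(self):
        self._chrom_by_name = {c.name: c for c in self.chromosomes}
        if len(self._chrom_by_name) != len(self.chromosomes):
            raise AnnotationError("duplicate chromosome names")
        seen_ids: set[str] = set()
        resolved: list[RepeatElement] = []
        for el in self.elements:
            if el.id in seen_ids:
                raise AnnotationError(f"duplicate element id {el.id}")
            seen_ids.add(el.id)
            chrom = self._chrom_by_name.get(el.chromosome)
            if chrom is None:
                raise AnnotationError(f"element {el.id}: unknown chromosome {el.chromosome}")
            if el.end > chrom.length:
                raise AnnotationError(
                    f"element {el.id}: extends past end of {chrom.name} "
                    f"({el.end} > {chrom.length})"
                )
            if el.start <= chrom.cen_end and el.end >= chrom.cen_start:
                raise AnnotationError(f"element {el.id}: overlaps centromere of {chrom.name}")
            arm = Arm.L if el.end < chrom.cen_start else Arm.R
            resolved.append(
                RepeatElement(el.id, el.chromosome, el.start, el.end, el.cls, el.orientation, arm)
            )
        order = {c.name: i for i, c in enumerate(self.chromosomes)}
        resolved.sort(key=lambda e: (order[e.chromosome], e.start))
        self.elements = resolved

    def chromosome(self, name: str) -> Chromosome:
        try:
            return self._chrom_by_name[name]
        except KeyError:
            raise AnnotationError(f"unknown chromosome {name}") from None

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def arm_keys(self) -> list[str]:
        """All arm identifiers, chromosome order, L before R (e.g. 'chrI-L')."""
        return [f"{c.name}-{a.value}" for c in self.chromosomes for a in (Arm.L, Arm.R)]

    def elements_on_arm(self, chromosome: str, arm: Arm | str) -> list[RepeatElement]:
        arm = Arm(arm)
        return [e for e in self.elements if e.chromosome == chromosome and e.arm is arm]


def split_arm_key(key: str) -> tuple[str, Arm]:
    chrom, _, arm = key.rpartition("-")
    return chrom, Arm(arm)


# ---------------------------------------------------------------------------
# target catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetSite:
    """One potential translocation target.

    A Ty1 or solo delta contributes a single site; a Ty2 contributes two
    sites, one per terminal LTR, since the LTRs carry the bulk of the
    Ty1/Ty2 homology.
    """

    id: str
    element_id: str
    chromosome: str
    arm: Arm
    start: int
    end: int
    orientation: Orientation


@dataclass
class TargetCatalog:
    mode: CatalogMode
    orientation_filter: OrientationFilter
    targets: list[TargetSite]

    @property
    def total(self) -> int:
        return len(self.targets)

    def per_arm_counts(self, arm_keys: Sequence[str] | None = None) -> dict[str, int]:
        counts = Counter(f"{t.chromosome}-{t.arm.value}" for t in self.targets)
        if arm_keys is None:
            return dict(counts)
        return {k: counts.get(k, 0) for k in arm_keys}

    def on_arm(self, chromosome: str, arm: Arm | str) -> list[TargetSite]:
        arm = Arm(arm)
        return [t for t in self.targets if t.chromosome == chromosome and t.arm is arm]


def build_target_catalog(
    annotation: GenomeAnnotation,
    mode: CatalogMode | str = CatalogMode.TY1_PLUS_DELTA,
    orientation_filter: OrientationFilter | str = OrientationFilter.ALL,
) -> TargetCatalog:
    """Enumerate the potential translocation targets of an annotation.

    ``TY1_ONLY`` counts full-length Ty1 elements; ``TY1_PLUS_DELTA``
    additionally counts solo delta elements and counts each Ty2 element as
    two separate delta targets (its two LTR ends).
    """
    mode = CatalogMode(mode)
    orientation_filter = OrientationFilter(orientation_filter)
    targets: list[TargetSite] = []
    for el in annotation.elements:
        assert el.arm is not None
        if el.cls is ElementClass.TY1:
            targets.append(
                TargetSite(el.id, el.id, el.chromosome, el.arm, el.start, el.end, el.orientation)
            )
        elif mode is not CatalogMode.TY1_PLUS_DELTA:
            continue
        elif el.cls is ElementClass.SOLO_DELTA:
            targets.append(
                TargetSite(el.id, el.id, el.chromosome, el.arm, el.start, el.end, el.orientation)
            )
        else:  # TY2 -> two LTR delta targets
            ltr = min(TY2_LTR_LENGTH, max(1, el.length // 2))
            targets.append(
                TargetSite(
                    f"{el.id}:ltr5", el.id, el.chromosome, el.arm,
                    el.start, el.start + ltr - 1, el.orientation,
                )
            )
            targets.append(
                TargetSite(
                    f"{el.id}:ltr3", el.id, el.chromosome, el.arm,
                    el.end - ltr + 1, el.end, el.orientation,
                )
            )
    if orientation_filter is OrientationFilter.TELOMERE_ORIENTED:
        targets = [t for t in targets if t.orientation is Orientation.TELOMERE]
    return TargetCatalog(mode, orientation_filter, targets)


def arm_target_probabilities(
    catalog: TargetCatalog, arm_keys: Sequence[str] | None = None
) -> dict[str, float]:
    """Per-arm probabilities under the equal-target-usage null model.

    p(arm) = (# targets on arm) / (total targets); this is the expected
    distribution of arm duplications if every catalog target recombined
    with the assay's seed Ty1 at equal frequency.
    """
    if catalog.total == 0:
        raise ValueError("cannot compute probabilities of an empty target catalog")
    counts = catalog.per_arm_counts(arm_keys)
    total = catalog.total
    return {k: v / total for k, v in counts.items()}


# ---------------------------------------------------------------------------
# I/O: simplified TSV dialect and GFF3
# ---------------------------------------------------------------------------

_TSV_ELEMENT_COLS = ["chrom", "start", "end", "class", "orientation", "id"]
_TSV_CHROM_COLS = ["chrom", "length", "cen_start", "cen_end", "tel_left_end", "tel_right_start"]


def _read_tsv_rows(path: Path, required: list[str]) -> list[dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise AnnotationError(f"{path}: missing columns {missing}")
        return list(reader)


def _chromosomes_from_tsv(path: Path) -> list[Chromosome]:
    rows = _read_tsv_rows(path, _TSV_CHROM_COLS[:4])
    chroms = []
    for row in rows:
        chroms.append(
            Chromosome(
                name=row["chrom"],
                length=int(row["length"]),
                cen_start=int(row["cen_start"]),
                cen_end=int(row["cen_end"]),
                tel_left_end=int(row.get("tel_left_end") or 0),
                tel_right_start=int(row.get("tel_right_start") or 0),
            )
        )
    return chroms


def load_annotation(
    path: str | Path,
    dialect: str = "tsv",
    chromosomes_path: str | Path | None = None,
) -> GenomeAnnotation:
    """Load and validate a genome annotation.

    ``tsv``: a simplified element table (chrom, start, end, class,
    orientation, id) plus a companion chromosome table (chrom, length,
    cen_start, cen_end[, tel_left_end, tel_right_start]) given as
    ``chromosomes_path``.

    ``gff3``: one file holding chromosome lengths (##sequence-region
    pragmas), ``centromere``/``telomere`` features, ``LTR_retrotransposon``
    features with a ``class=Ty1|Ty2`` attribute and
    ``long_terminal_repeat`` features for solo deltas; the strand column
    carries the orientation (resolved via :func:`strand_to_orientation`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        if chromosomes_path is None:
            raise AnnotationError("tsv dialect requires a companion chromosomes table")
        chroms = _chromosomes_from_tsv(Path(chromosomes_path))
        elements = []
        for row in _read_tsv_rows(path, _TSV_ELEMENT_COLS):
            try:
                elements.append(
                    RepeatElement(
                        id=row["id"],
                        chromosome=row["chrom"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        cls=ElementClass(row["class"]),
                        orientation=Orientation(row["orientation"]),
                    )
                )
            except ValueError as exc:
                raise AnnotationError(f"record {row.get('id', row)}: {exc}") from exc
        return GenomeAnnotation(chroms, elements)
    if dialect == "gff3":
        return _load_gff3(path)
    raise AnnotationError(f"unknown dialect {dialect!r}")


def _load_gff3(path: Path) -> GenomeAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    lengths: dict[str, int] = {}
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            _, chrom, _start, end = directive.split()[:4]
            lengths[chrom] = int(end)
    cen: dict[str, tuple[int, int]] = {}
    tel: dict[str, list[tuple[int, int]]] = {}
    raw_elements: list[tuple[str, int, int, str, str, str]] = []
    for feat in db.all_features():
        chrom, ftype = feat.seqid, feat.featuretype
        if ftype == "centromere":
            cen[chrom] = (feat.start, feat.end)
        elif ftype == "telomere":
            tel.setdefault(chrom, []).append((feat.start, feat.end))
        elif ftype in {"LTR_retrotransposon", "long_terminal_repeat"}:
            if ftype == "long_terminal_repeat":
                cls = "SOLO_DELTA"
            else:
                raw = feat.attributes.get("class", [""])[0]
                cls = {"Ty1": "TY1", "Ty2": "TY2"}.get(raw)
                if cls is None:
                    raise AnnotationError(
                        f"{path}: element {feat.id}: unknown class {raw!r}"
                    )
            raw_elements.append(
                (chrom, feat.start, feat.end, cls, feat.strand, feat.id)
            )
    chroms = []
    for chrom, length in lengths.items():
        if chrom not in cen:
            raise AnnotationError(f"{path}: chromosome {chrom} has no centromere feature")
        cs, ce = cen[chrom]
        tl_end, tr_start = 0, 0
        for ts, te in tel.get(chrom, []):
            if ts == 1:
                tl_end = te
            else:
                tr_start = ts
        chroms.append(Chromosome(chrom, length, cs, ce, tl_end, tr_start))
    chrom_by_name = {c.name: c for c in chroms}
    elements = []
    for chrom, start, end, cls, strand, eid in raw_elements:
        c = chrom_by_name.get(chrom)
        if c is None:
            raise AnnotationError(f"element {eid}: unknown chromosome {chrom}")
        arm = Arm.L if end < c.cen_start else Arm.R
        elements.append(
            RepeatElement(
                id=eid, chromosome=chrom, start=start, end=end,
                cls=ElementClass(cls),
                orientation=strand_to_orientation(strand, arm),
            )
        )
    return GenomeAnnotation(chroms, elements)


def write_annotation(
    annotation: GenomeAnnotation,
    path: str | Path,
    dialect: str = "tsv",
    chromosomes_path: str | Path | None = None,
) -> None:
    """Write an annotation in either supported dialect (round-trip safe)."""
    path = Path(path)
    if dialect == "tsv":
        if chromosomes_path is None:
            raise AnnotationError("tsv dialect requires a chromosomes output path")
        with open(chromosomes_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(_TSV_CHROM_COLS)
            for c in annotation.chromosomes:
                w.writerow(
                    [c.name, c.length, c.cen_start, c.cen_end, c.tel_left_end, c.tel_right_start]
                )
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(_TSV_ELEMENT_COLS)
            for e in annotation.elements:
                w.writerow(
                    [e.chromosome, e.start, e.end, e.cls.value, e.orientation.value, e.id]
                )
        return
    if dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c in annotation.chromosomes:
                fh.write(f"##sequence-region {c.name} 1 {c.length}\n")
            for c in annotation.chromosomes:
                fh.write(
                    f"{c.name}\tmlpagcr\tcentromere\t{c.cen_start}\t{c.cen_end}\t.\t.\t.\t"
                    f"ID=CEN_{c.name}\n"
                )
                if c.tel_left_end:
                    fh.write(
                        f"{c.name}\tmlpagcr\ttelomere\t1\t{c.tel_left_end}\t.\t.\t.\t"
                        f"ID=TEL_{c.name}_L\n"
                    )
                if c.tel_right_start:
                    fh.write(
                        f"{c.name}\tmlpagcr\ttelomere\t{c.tel_right_start}\t{c.length}\t.\t.\t.\t"
                        f"ID=TEL_{c.name}_R\n"
                    )
            for e in annotation.elements:
                assert e.arm is not None
                strand = orientation_to_strand(e.orientation, e.arm)
                if e.cls is ElementClass.SOLO_DELTA:
                    ftype, attrs = "long_terminal_repeat", f"ID={e.id}"
                else:
                    cls = "Ty1" if e.cls is ElementClass.TY1 else "Ty2"
                    ftype, attrs = "LTR_retrotransposon", f"ID={e.id};class={cls}"
                fh.write(
                    f"{e.chromosome}\tmlpagcr\t{ftype}\t{e.start}\t{e.end}\t.\t{strand}\t.\t{attrs}\n"
                )
        return
    raise AnnotationError(f"unknown dialect {dialect!r}")
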