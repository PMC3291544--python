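import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlpagcr.genome import (
    AnnotationError,
    Arm,
    Chromosome,
    ElementClass,
    GenomeAnnotation,
    Orientation,
    RepeatElement,
    arm_target_probabilities,
    build_target_catalog,
    load_annotation,
    strand_to_orientation,
    write_annotation,
)


def toy_chromosome(name="chrT", length=200_000, cen=100_000):
    return Chromosome(name, length, cen - 60, cen + 60, 500, length - 499)


def el(eid, start, end, cls, orient=Orientation.TELOMERE, chrom="chrT"):
    return RepeatElement(eid, chrom, start, end, cls, orient)


class TestAnnotationModel:
    def test_empty_annotation_has_two_arms_no_elements(self):
        ann = GenomeAnnotation([toy_chromosome()], [])
        assert ann.arm_keys() == ["chrT-L", "chrT-R"]
        assert ann.elements == []

    def test_arm_assignment_from_coordinates(self, tmp_path):
        # one Ty1 at 50-55 kb on a chromosome with the centromere at 40 kb
        chrom_tsv = tmp_path / "chroms.tsv"
        el_tsv = tmp_path / "elements.tsv"
        chrom_tsv.write_text(
            "chrom\tlength\tcen_start\tcen_end\nchrI\t100000\t39940\t40060\n"
        )
        el_tsv.write_text(
            "chrom\tstart\tend\tclass\torientation\tid\n"
            "chrI\t50000\t55000\tTY1\tTELOMERE\tTy1-a\n"
        )
        ann = load_annotation(el_tsv, "tsv", chrom_tsv)
        assert ann.elements[0].arm is Arm.R

    @pytest.mark.parametrize(
        "arm,strand,expected",
        [
            (Arm.R, "+", Orientation.TELOMERE),
            (Arm.R, "-", Orientation.CENTROMERE),
            (Arm.L, "-", Orientation.TELOMERE),
            (Arm.L, "+", Orientation.CENTROMERE),
        ],
    )
    def test_strand_orientation_convention(self, arm, strand, expected):
        assert strand_to_orientation(strand, arm) is expected

    @pytest.mark.parametrize(
        "bad_element,match",
        [
            (el("outside", 250_000, 251_000, ElementClass.TY1), "outside"),
            (el("on-cen", 99_000, 101_000, ElementClass.TY1), "on-cen"),
        ],
    )
    def test_invalid_elements_rejected_by_name(self, bad_element, match):
        with pytest.raises(AnnotationError, match=match):
            GenomeAnnotation([toy_chromosome()], [bad_element])

    def test_duplicate_ids_rejected(self):
        dup = [
            el("same", 10_000, 10_300, ElementClass.SOLO_DELTA),
            el("same", 20_000, 20_300, ElementClass.SOLO_DELTA),
        ]
        with pytest.raises(AnnotationError, match="duplicate"):
            GenomeAnnotation([toy_chromosome()], dup)


class TestTargetCatalog:
    def toy_annotation(self):
        elements = [
            el("ty1-a", 110_000, 115_900, ElementClass.TY1),
            el("ty1-b", 130_000, 135_900, ElementClass.TY1, Orientation.CENTROMERE),
            el("d1", 140_000, 140_333, ElementClass.SOLO_DELTA),
            el("d2", 150_000, 150_333, ElementClass.SOLO_DELTA),
            el("d3", 160_000, 160_333, ElementClass.SOLO_DELTA, Orientation.CENTROMERE),
            el("ty2-a", 170_000, 175_950, ElementClass.TY2),
        ]
        return GenomeAnnotation([toy_chromosome()], elements)

    def test_empty_catalog(self):
        ann = GenomeAnnotation([toy_chromosome()], [])
        assert build_target_catalog(ann).total == 0

    def test_ty2_counts_as_two_delta_targets(self):
        ann = self.toy_annotation()
        assert build_target_catalog(ann, "TY1_ONLY").total == 2
        assert build_target_catalog(ann, "TY1_PLUS_DELTA").total == 7

    def test_orientation_filter_is_a_subset(self):
        ann = self.toy_annotation()
        full = build_target_catalog(ann)
        tel = build_target_catalog(ann, orientation_filter="TELOMERE_ORIENTED")
        assert tel.total < full.total
        assert {t.id for t in tel.targets} <= {t.id for t in full.targets}
        for arm, n in tel.per_arm_counts().items():
            assert n <= full.per_arm_counts().get(arm, 0)

    def test_probabilities_normalize(self):
        ann = self.toy_annotation()
        # counts (2, 5) across the L/R arms of the toy chromosome would be
        # a two-arm example; here all targets sit on one arm
        probs = arm_target_probabilities(build_target_catalog(ann))
        assert probs == {"chrT-R": 1.0}

    def test_two_arm_probabilities(self):
        elements = [
            el("l1", 20_000, 20_333, ElementClass.SOLO_DELTA),
            el("l2", 30_000, 30_333, ElementClass.SOLO_DELTA),
            el("r1", 120_000, 120_333, ElementClass.SOLO_DELTA),
            el("r2", 130_000, 130_333, ElementClass.SOLO_DELTA),
            el("r3", 140_000, 140_333, ElementClass.SOLO_DELTA),
        ]
        ann = GenomeAnnotation([toy_chromosome()], elements)
        probs = arm_target_probabilities(build_target_catalog(ann))
        assert probs == {"chrT-L": pytest.approx(0.4), "chrT-R": pytest.approx(0.6)}

    def test_empty_catalog_probabilities_error(self):
        ann = GenomeAnnotation([toy_chromosome()], [])
        with pytest.raises(ValueError):
            arm_target_probabilities(build_target_catalog(ann))

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(list(ElementClass)),
                st.integers(min_value=0, max_value=30),
            ),
            min_size=1,
            max_size=12,
            unique_by=lambda t: t[1],
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_total_additive_and_order_invariant(self, spec):
        elements = []
        for i, (cls, slot) in enumerate(spec):
            start = 110_000 + slot * 2_000
            length = 5_900 if cls is not ElementClass.SOLO_DELTA else 334
            elements.append(el(f"e{i}", start, start + length, cls))
        ann_fwd = GenomeAnnotation([toy_chromosome()], elements)
        ann_rev = GenomeAnnotation([toy_chromosome()], elements[::-1])
        cat_fwd = build_target_catalog(ann_fwd)
        cat_rev = build_target_catalog(ann_rev)
        assert cat_fwd.total == cat_rev.total
        assert cat_fwd.total == sum(cat_fwd.per_arm_counts().values())
        n_ty2 = sum(1 for c, _ in spec if c is ElementClass.TY2)
        assert cat_fwd.total == len(spec) + n_ty2


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["tsv", "gff3"])
    def test_write_load_identity(self, tmp_path, dialect, annotation):
        main = tmp_path / f"ann.{dialect}"
        chroms = tmp_path / "chroms.tsv" if dialect == "tsv" else None
        write_annotation(annotation, main, dialect, chroms)
        again = load_annotation(main, dialect, chroms)
        assert [c for c in again.chromosomes] == [c for c in annotation.chromosomes]
        assert again.elements == annotation.elements
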