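import pytest

from mlpagcr.copynumber import NormalizationMode, call_copy_numbers
from mlpagcr.classify import classify_matrix, localize_breakpoint, summarize_cohort
from mlpagcr.genome import build_target_catalog
from mlpagcr.probes import ProbeRole, design_probe_set
from mlpagcr.simulate import (
    NoiseModel,
    make_fixture_annotation,
    reference_wildtype_events,
    simulate_peaks,
    true_copy_numbers,
)

HOTSPOT_ARMS = ("chrIII-R", "chrV-R", "chrX-R", "chrXIV-L")


@pytest.fixture(scope="session")
def annotation():
    return make_fixture_annotation(seed=0)


@pytest.fixture(scope="session")
def catalog(annotation):
    return build_target_catalog(annotation)


@pytest.fixture(scope="session")
def telomeric_panel(annotation):
    return design_probe_set(annotation, ProbeRole.TELOMERIC)


@pytest.fixture(scope="session")
def centromeric_panel(annotation):
    return design_probe_set(annotation, ProbeRole.CENTROMERIC)


@pytest.fixture(scope="session")
def wildtype_events(annotation):
    return reference_wildtype_events(annotation)


@pytest.fixture(scope="session")
def wildtype_pipeline(annotation, telomeric_panel, wildtype_events):
    """The reference wild-type cohort pushed through peak simulation,
    calling, classification and per-arm breakpoint localization."""
    cn = true_copy_numbers(wildtype_events, telomeric_panel, annotation)
    peaks = simulate_peaks(
        cn, telomeric_panel, NoiseModel(cv=0.02), n_controls=3, seed=5
    )
    matrix = call_copy_numbers(peaks, telomeric_panel)
    classifications = classify_matrix(matrix, telomeric_panel, annotation)
    breakpoints = []
    for arm_key in HOTSPOT_ARMS:
        ladder = design_probe_set(annotation, ProbeRole.ARM_SPECIFIC, arm_key)
        subset = [
            e for e in wildtype_events if e.dup_arm == arm_key and not e.ambiguous
        ]
        arm_cn = true_copy_numbers(subset, ladder, annotation)
        arm_peaks = simulate_peaks(
            arm_cn, ladder, NoiseModel(cv=0.02), n_controls=3, seed=7
        )
        arm_matrix = call_copy_numbers(
            arm_peaks, ladder, NormalizationMode.ANCHOR
        )
        breakpoints.extend(
            localize_breakpoint(arm_matrix.calls.loc[i], ladder, annotation)
            for i in arm_matrix.isolates
        )
    summary = summarize_cohort(classifications, breakpoints)
    return {
        "matrix": matrix,
        "classifications": classifications,
        "breakpoints": breakpoints,
        "summary": summary,
    }
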