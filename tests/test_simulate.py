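import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mlpagcr.classify import IsolateStatus, classify_matrix, summarize_cohort
from mlpagcr.copynumber import call_copy_numbers
from mlpagcr.genome import ElementClass, build_target_catalog
from mlpagcr.probes import ProbeRole, design_probe_set
from mlpagcr.simulate import (
    EventModel,
    FixtureParams,
    NoiseModel,
    default_wildtype_event_model,
    discordant_counts,
    lea_coulson_rate,
    make_fixture_annotation,
    reference_rad52_events,
    simulate_cohort,
    simulate_fluctuation,
    simulate_paired_aneuploidy,
    simulate_peaks,
    true_copy_numbers,
)


class TestFixtureAnnotation:
    def test_published_aggregate_constraints(self, annotation, catalog):
        assert catalog.total == 254
        ty2 = [e for e in annotation.elements if e.cls is ElementClass.TY2]
        assert len(ty2) == 13

    def test_deterministic_for_seed(self):
        a = make_fixture_annotation(seed=7)
        b = make_fixture_annotation(seed=7)
        assert a.elements == b.elements
        c = make_fixture_annotation(seed=8)
        assert c.elements != a.elements

    def test_infeasible_constraints_error(self):
        with pytest.raises(ValueError):
            make_fixture_annotation(FixtureParams(target_total=10))


class TestCohortSimulation:
    def test_single_target_model(self, annotation, catalog):
        target = next(t for t in catalog.targets if t.chromosome == "chrX")
        model = EventModel(target_probs={target.id: 1.0})
        cohort = simulate_cohort(annotation, model, 20, seed=1, catalog=catalog)
        assert all(s.dup_arm == f"chrX-{target.arm.value}" for s in cohort)

    def test_hotspot_proportions_within_binomial_error(self, annotation, catalog):
        model = default_wildtype_event_model(annotation, catalog)
        cohort = simulate_cohort(annotation, model, 112, seed=2, catalog=catalog)
        counts = pd.Series([s.dup_arm for s in cohort if s.has_duplication]).value_counts()
        # binomial 99% CI oracle for each hotspot arm's expected share
        for arm, p in [("chrIII-R", 28 / 112), ("chrV-R", 27 / 112), ("chrX-R", 10 / 112)]:
            lo, hi = sps.binom.interval(0.99, 112, p)
            assert lo <= counts.get(arm, 0) <= hi

    def test_no_duplication_fraction(self, annotation, catalog):
        target = catalog.targets[0]
        model = EventModel(
            target_probs={target.id: 0.32}, no_duplication_fraction=0.68
        )
        cohort = simulate_cohort(annotation, model, 400, seed=3, catalog=catalog)
        frac = np.mean([s.dup_arm is None for s in cohort])
        assert abs(frac - 0.68) < 3 * np.sqrt(0.68 * 0.32 / 400)

    def test_rad52_regime_deletion_only_share(self, annotation):
        events = reference_rad52_events(annotation)
        assert len(events) == 50
        assert sum(1 for e in events if e.dup_arm is None) == 34


class TestNoiseAndRecovery:
    def test_zero_noise_areas_proportional_to_cn(self, annotation, telomeric_panel):
        events = reference_rad52_events(annotation)[:5]
        cn = true_copy_numbers(events, telomeric_panel, annotation)
        noise = NoiseModel(sigma_efficiency=0, sigma_scale=0, cv=0, background=0)
        peaks = simulate_peaks(cn, telomeric_panel, noise, n_controls=1, seed=0)
        sample = next(p for p in peaks if p.sample_id == events[0].isolate)
        areas = np.array([a for _, a in sample.peaks])
        expected = cn.loc[events[0].isolate].to_numpy() * noise.base_area
        assert np.allclose(areas, expected)

    def test_same_seed_identical_tables(self, annotation, telomeric_panel):
        events = reference_rad52_events(annotation)[:3]
        cn = true_copy_numbers(events, telomeric_panel, annotation)
        a = simulate_peaks(cn, telomeric_panel, seed=9)
        b = simulate_peaks(cn, telomeric_panel, seed=9)
        assert [t.peaks for t in a] == [t.peaks for t in b]

    def test_noise_free_classification_recovers_truth(
        self, annotation, telomeric_panel, wildtype_events
    ):
        cn = true_copy_numbers(wildtype_events, telomeric_panel, annotation)
        noise = NoiseModel(sigma_efficiency=0.1, sigma_scale=0.2, cv=0.0)
        peaks = simulate_peaks(cn, telomeric_panel, noise, n_controls=2, seed=4)
        matrix = call_copy_numbers(peaks, telomeric_panel)
        classifications = classify_matrix(matrix, telomeric_panel, annotation)
        by_id = {c.isolate: c for c in classifications}
        for truth in wildtype_events:
            got = by_id[truth.isolate]
            expected = truth.expected_classification()
            assert got.status is expected.status
            assert got.arm_duplications == expected.arm_duplications

    def test_accuracy_monotone_in_noise(self, annotation, telomeric_panel):
        events = reference_rad52_events(annotation)
        cn = true_copy_numbers(events, telomeric_panel, annotation)
        truth = cn.round().astype(int)
        accs = []
        for cv in (0.02, 0.30):
            peaks = simulate_peaks(
                cn, telomeric_panel, NoiseModel(cv=cv), n_controls=3, seed=6
            )
            m = call_copy_numbers(peaks, telomeric_panel)
            accs.append(
                (m.calls.values == truth.loc[m.isolates].values).mean()
            )
        assert accs[0] > accs[1]


class TestFluctuation:
    def test_zero_rate_zero_counts(self):
        counts, rates = simulate_fluctuation(0.0, 1e6, 10, seed=0)
        assert not counts.any() and not rates.any()

    def test_jackpot_skew(self):
        counts, _ = simulate_fluctuation(1e-7, 1e7, 5000, seed=1)
        assert counts.mean() > np.median(counts)

    def test_deterministic(self):
        a, _ = simulate_fluctuation(1e-7, 1e6, 50, seed=5)
        b, _ = simulate_fluctuation(1e-7, 1e6, 50, seed=5)
        assert (a == b).all()

    def test_expected_mutation_number(self):
        # mean mutant count per culture under this scheme is
        # m * (generations/2 + 1) with m = rate * N; check the total
        # mutation count m against its Poisson expectation instead
        rate, n = 2e-6, 1e6
        counts, _ = simulate_fluctuation(rate, n, 4000, seed=6)
        # fraction of cultures with zero mutants estimates exp(-m)
        p0 = (counts == 0).mean()
        m = rate * n
        assert abs(p0 - np.exp(-m)) < 0.03

    def test_lea_coulson_transform_monotone(self):
        rates = [lea_coulson_rate(c, 1e7) for c in (0, 1, 2, 5, 50)]
        assert rates == sorted(rates)
        assert rates[0] == 0.0


class TestPairedAneuploidy:
    def test_all_negative(self):
        pairs = simulate_paired_aneuploidy(20, 0.0, 0.0, seed=0)
        assert discordant_counts(pairs) == (0, 0)

    def test_discordance_tracks_probabilities(self):
        pairs = simulate_paired_aneuploidy(4000, 0.3, 0.05, seed=1)
        b, c = discordant_counts(pairs)
        # b ~ n * p_sel * (1 - p_non), c ~ n * p_non * (1 - p_sel)
        assert abs(b - 4000 * 0.3 * 0.95) < 4 * np.sqrt(4000 * 0.285)
        assert abs(c - 4000 * 0.05 * 0.7) < 4 * np.sqrt(4000 * 0.035)
        assert b > c
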