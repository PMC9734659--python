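"""Marker calls, pair informativity, and covering-marker selection."""

import itertools
import math

import numpy as np
import pytest

from chimertrack import (
    MarkerAssay,
    MixtureSpec,
    TypingCall,
    call_typing,
    classify_informativity,
    recipient_specific_pair,
    screen_pair,
    select_covering_markers,
    simulate_mixture_plate,
    simulate_pair,
)
from chimertrack.errors import QCError, ValidationError
from chimertrack.panel import PairGenotypes, MarkerGenotype, WellMeasurement
from chimertrack.typing_engine import (
    ATYPICAL,
    DONOR_SPECIFIC,
    INDETERMINATE,
    NEGATIVE,
    NON_INFORMATIVE,
    POSITIVE,
    RECIPIENT_SPECIFIC,
    PairScreenResult,
    brute_force_cover,
)
from test_simulate import panel_with_q

ASSAY = MarkerAssay(id="KMR019", allele_freq=0.25, cq_window=(15.0, 38.0))


def wells(sample, assay, *cqs):
    return [WellMeasurement(sample, assay, i + 1, cq) for i, cq in enumerate(cqs)]


class TestCallTyping:
    def test_small_dcq_is_positive(self):
        call = call_typing(wells("S", "KMR019", 26.0), wells("S", "REF901", 25.0), ASSAY)
        assert call == TypingCall(POSITIVE, pytest.approx(1.0))

    def test_no_amplification_is_negative(self):
        call = call_typing(wells("S", "KMR019", None, None), wells("S", "REF901", 25.0), ASSAY)
        assert call.status == NEGATIVE and call.dcq is None

    def test_cq_above_window_is_atypical(self):
        call = call_typing(wells("S", "KMR019", 41.0), wells("S", "REF901", 25.0), ASSAY)
        assert call.status == ATYPICAL

    def test_cq_below_window_is_atypical(self):
        call = call_typing(wells("S", "KMR019", 12.0), wells("S", "REF901", 25.0), ASSAY)
        assert call.status == ATYPICAL

    def test_large_dcq_is_negative(self):
        call = call_typing(wells("S", "KMR019", 32.0), wells("S", "REF901", 25.0), ASSAY)
        assert call == TypingCall(NEGATIVE, pytest.approx(7.0))

    def test_ambiguous_band_is_atypical(self):
        call = call_typing(wells("S", "KMR019", 29.5), wells("S", "REF901", 25.0), ASSAY)
        assert call.status == ATYPICAL

    def test_mean_over_amplified_replicates(self):
        call = call_typing(
            wells("S", "KMR019", 26.0, 27.0, None), wells("S", "REF901", 25.0), ASSAY
        )
        assert call.dcq == pytest.approx(1.5)

    def test_missing_reference_is_qc_error_not_negative(self):
        with pytest.raises(QCError):
            call_typing(wells("S", "KMR019", 26.0), wells("S", "REF901", None), ASSAY)


class TestClassifyInformativity:
    GRID = {
        (POSITIVE, POSITIVE): NON_INFORMATIVE,
        (POSITIVE, NEGATIVE): RECIPIENT_SPECIFIC,
        (POSITIVE, ATYPICAL): INDETERMINATE,
        (NEGATIVE, POSITIVE): DONOR_SPECIFIC,
        (NEGATIVE, NEGATIVE): NON_INFORMATIVE,
        (NEGATIVE, ATYPICAL): INDETERMINATE,
        (ATYPICAL, POSITIVE): INDETERMINATE,
        (ATYPICAL, NEGATIVE): INDETERMINATE,
        (ATYPICAL, ATYPICAL): INDETERMINATE,
    }

    @pytest.mark.parametrize("recipient,donor", list(GRID))
    def test_total_over_status_grid(self, recipient, donor):
        category = classify_informativity(TypingCall(recipient), TypingCall(donor))
        assert category == self.GRID[(recipient, donor)]


def typing_plate(panel, pair, params, rng=None):
    """Pure-subject typing wells for both members of a pair."""
    plate = []
    for sample, genotypes in (("recipient", pair.recipient), ("donor", pair.donor)):
        subject = PairGenotypes(genotypes, genotypes, "unrelated")
        plate += simulate_mixture_plate(
            subject, MixtureSpec(true_fraction=1.0), params, panel,
            rng or np.random.default_rng(0), sample_id=sample,
        )
    return plate


class TestScreenPair:
    def test_identical_genotypes_not_informative(self, small_panel, noise_free_params):
        genotypes = {m: MarkerGenotype(1) for m in small_panel.marker_ids}
        pair = PairGenotypes(genotypes, genotypes, "sibling")
        plate = typing_plate(small_panel, pair, noise_free_params)
        screen = screen_pair(plate, small_panel, "recipient", "donor")
        assert screen.n_informative == 0

    def test_fully_recipient_specific_pair(self, panel, noise_free_params):
        pair = recipient_specific_pair(panel)
        plate = typing_plate(panel, pair, noise_free_params)
        screen = screen_pair(plate, panel, "recipient", "donor")
        assert screen.n_recipient_specific == 39
        assert screen.n_informative == screen.n_recipient_specific + screen.n_donor_specific

    def test_missing_subject_rejected(self, small_panel, noise_free_params):
        pair = recipient_specific_pair(small_panel)
        plate = typing_plate(small_panel, pair, noise_free_params)
        with pytest.raises(ValidationError):
            screen_pair(plate, small_panel, "recipient", "nobody")

    def test_screen_matches_carrier_status_noise_free(self, small_panel, noise_free_params):
        # with exact copies, a marker is positive iff the subject carries it
        rng = np.random.default_rng(11)
        for _ in range(25):
            pair = simulate_pair(panel_with_q(0.4, n=4), "unrelated", rng)
            panel4 = panel_with_q(0.4, n=4)
            plate = typing_plate(panel4, pair, noise_free_params)
            screen = screen_pair(plate, panel4, "recipient", "donor")
            for m in panel4.marker_ids:
                expected = (
                    RECIPIENT_SPECIFIC
                    if pair.recipient[m].carrier and not pair.donor[m].carrier
                    else DONOR_SPECIFIC
                    if pair.donor[m].carrier and not pair.recipient[m].carrier
                    else NON_INFORMATIVE
                )
                assert screen.calls[m] == expected

    def test_recipient_specific_rate_matches_closed_form(self):
        # P(recipient carrier, donor non-carrier) = (1-(1-q)^2) (1-q)^2
        q, n_pairs = 0.25, 5000
        panel39 = panel_with_q(q, n=39)
        rng = np.random.default_rng(12)
        hits = trials = 0
        for _ in range(n_pairs):
            pair = simulate_pair(panel39, "unrelated", rng)
            for m in panel39.marker_ids:
                trials += 1
                hits += pair.recipient[m].carrier and not pair.donor[m].carrier
        expected = (1 - (1 - q) ** 2) * (1 - q) ** 2
        se = math.sqrt(expected * (1 - expected) / trials)
        assert abs(hits / trials - expected) < 3 * se


def screens_from_sets(marker_sets):
    """Build PairScreenResults where pair i is covered by marker_sets[i]."""
    markers = sorted(set().union(*marker_sets)) if marker_sets else []
    out = []
    for i, covered_by in enumerate(marker_sets):
        calls = {
            m: (RECIPIENT_SPECIFIC if m in covered_by else NON_INFORMATIVE)
            for m in markers
        }
        out.append(PairScreenResult(f"P{i}", calls))
    return out


class TestSelectCoveringMarkers:
    def test_toy_instance_matches_brute_force(self):
        screens = screens_from_sets([{"A"}, {"A", "B"}, {"B", "C"}])
        subset, coverage = select_covering_markers(screens, 2)
        assert subset == ["A", "B"]
        assert coverage == 1.0
        assert brute_force_cover(screens, 2)[1] == coverage

    def test_k_zero_empty(self):
        screens = screens_from_sets([{"A"}])
        assert select_covering_markers(screens, 0) == ([], 0.0)

    def test_greedy_stops_early(self):
        screens = screens_from_sets([{"A"}, {"A"}, {"A"}])
        subset, coverage = select_covering_markers(screens, 3)
        assert subset == ["A"] and coverage == 1.0

    def test_coverage_non_decreasing_in_k(self):
        rng = np.random.default_rng(13)
        markers = [f"M{i}" for i in range(8)]
        sets = [
            {m for m in markers if rng.random() < 0.25} for _ in range(10)
        ]
        screens = screens_from_sets([s for s in sets if s] or [{"M0"}])
        coverages = [select_covering_markers(screens, k)[1] for k in range(6)]
        assert coverages == sorted(coverages)

    def test_greedy_against_exhaustive_on_random_instances(self):
        # k = 1 greedy is exactly optimal; for k > 1 greedy is bounded by
        # the optimum and guarantees the (1 - 1/e) approximation factor
        rng = np.random.default_rng(14)
        for _ in range(40):
            n_markers = int(rng.integers(2, 13))
            n_pairs = int(rng.integers(1, 11))
            markers = [f"M{i}" for i in range(n_markers)]
            sets = [
                {m for m in markers if rng.random() < 0.3} for _ in range(n_pairs)
            ]
            screens = screens_from_sets(sets)
            _, greedy_1 = select_covering_markers(screens, 1)
            _, best_1 = brute_force_cover(screens, 1)
            assert greedy_1 == pytest.approx(best_1)
            for k in (2, 3):
                _, greedy_cov = select_covering_markers(screens, k)
                _, best_cov = brute_force_cover(screens, k)
                assert greedy_cov <= best_cov + 1e-12
                assert greedy_cov >= (1 - 1 / math.e) * best_cov - 1e-12

    def test_simulated_cohort_nearly_always_covered(self, noise_free_params):
        # 39 markers at q=0.25: P(no recipient-specific marker) ~ 1.6e-5
        panel39 = panel_with_q(0.25, n=39)
        rng = np.random.default_rng(15)
        covered = 0
        n_pairs = 200
        for _ in range(n_pairs):
            pair = simulate_pair(panel39, "unrelated", rng)
            covered += any(
                pair.recipient[m].carrier and not pair.donor[m].carrier
                for m in panel39.marker_ids
            )
        assert covered == n_pairs
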