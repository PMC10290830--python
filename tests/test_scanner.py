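"""Scanner: exact p-values, PPV, true hit ratios, leave-parts-out trials."""

import itertools
import math

import numpy as np
import pytest

from marz import (
    Background,
    Catalog,
    PromoterRecord,
    ScanHit,
    SiteAlignment,
    build_count_matrix,
    evaluate_model,
    exact_score_distribution,
    gapped_pwm,
    get_model,
    is_true_positive,
    leave_parts_out,
    model_from_pattern,
    ppv,
    recovery_ppm,
    sample_promoters,
    scan_promoter,
    select_p_threshold,
    to_probability,
    trial_set_correlations,
    true_hit_ratio,
)
from marz.matrices import WeightMatrix
from marz.scanner import trials_table


def brute_force_distribution(pwm_values, bg_probs):
    """Independent enumeration oracle: pure-python walk over all 4**6
    windows in lexicographic order, grouping tail mass per score."""
    sums = {}
    order = []
    for window in itertools.product(range(4), repeat=6):
        s = 0.0
        p = 1.0
        for j, letter in enumerate(window):
            s += pwm_values[letter][j]
            p *= bg_probs[letter]
        if s not in sums:
            sums[s] = 0.0
            order.append(s)
        sums[s] += p
    scores = sorted(sums)
    tail = {}
    running = 0.0
    for s in reversed(scores):
        running += sums[s]
        tail[s] = running
    return scores, tail


def random_pwm(rng, background=None):
    background = background or Background()
    values = rng.normal(0, 1.5, size=(4, 6))
    return WeightMatrix(values=values, background=background)


class TestExactDistribution:
    def test_matches_enumeration_oracle_bit_exactly(self, rng):
        bg = Background()
        for _ in range(5):
            pwm = random_pwm(rng, bg)
            dist = exact_score_distribution(pwm, bg)
            scores, tail = brute_force_distribution(
                pwm.values.tolist(), bg.probs.tolist()
            )
            assert dist.scores.tolist() == scores
            assert dist.tail.tolist() == [tail[s] for s in scores]

    def test_tail_non_increasing_and_total_one(self, rng):
        pwm = random_pwm(rng)
        dist = exact_score_distribution(pwm)
        assert np.all(np.diff(dist.tail) <= 0)
        assert dist.tail[0] == pytest.approx(1.0, abs=1e-9)

    def test_flat_pwm_single_score(self):
        bg = Background(np.array([0.25, 0.25, 0.25, 0.25]))
        pwm = WeightMatrix(values=np.zeros((4, 6)), background=bg)
        dist = exact_score_distribution(pwm, bg)
        assert dist.scores.tolist() == [0.0]
        assert dist.tail.tolist() == [1.0]  # powers of two sum exactly

    def test_unique_top_window_tail(self):
        bg = Background()
        values = np.zeros((4, 6))
        values[0, :] = 5.0  # poly-A is the unique top scorer
        pwm = WeightMatrix(values=values, background=bg)
        dist = exact_score_distribution(pwm, bg)
        assert dist.min_p_value == pytest.approx(0.3**6)


class TestScanning:
    @pytest.fixture
    def informative_pwm(self, rng):
        al = SiteAlignment(["TCAGTT"] * 40 + ["TCAGTC"] * 10)
        prob = to_probability(build_count_matrix(al))
        return gapped_pwm(prob, get_model(63, Catalog.FULL64))

    def test_pmax_one_hits_every_window(self, informative_pwm):
        rec = PromoterRecord("p1", "ACGT" * 25)
        hits = scan_promoter(rec, informative_pwm, p_max=1.0)
        assert len(hits) == 100 - 6 + 1

    def test_planted_site_found_at_offset(self, rng, informative_pwm):
        proms = sample_promoters(5, rng, planting="TCAGTT", offset=47)
        for rec in proms.records:
            hits = scan_promoter(rec, informative_pwm, p_max=0.001)
            assert 47 in [h.start for h in hits]

    def test_unreachable_pmax_gives_no_hits(self, informative_pwm):
        dist = exact_score_distribution(informative_pwm)
        rec = PromoterRecord("p1", "ACGT" * 25)
        hits = scan_promoter(rec, informative_pwm, p_max=dist.min_p_value / 2)
        assert hits == []

    def test_short_sequence_rejected(self, informative_pwm):
        with pytest.raises(ValueError, match="shorter"):
            scan_promoter(PromoterRecord("p", "ACGTA"), informative_pwm)


class TestAccuracyFormulas:
    def test_ppv(self):
        assert ppv(8, 2) == pytest.approx(0.8)
        assert ppv(0, 5) == 0.0
        assert ppv(5, 0) == 1.0
        with pytest.raises(ValueError):
            ppv(0, 0)

    @pytest.mark.parametrize(
        "start,truth,expected",
        [(10, (15, 21), True), (10, (16, 22), False), (10, (10, 16), True)],
    )
    def test_true_positive_overlap_rule(self, start, truth, expected):
        hit = ScanHit("p", start, 0.0, 0.5)
        assert is_true_positive(hit, truth) is expected

    def test_true_hit_ratio(self):
        assert true_hit_ratio(3, 5, 1.0) == pytest.approx(0.75)
        assert true_hit_ratio(4, 4, 0.0) == 1.0
        assert math.isnan(true_hit_ratio(2, 3, 3.0))
        with pytest.raises(ValueError):
            true_hit_ratio(5, 3, 0.0)


class TestThresholdSelection:
    def test_isolating_threshold_reaches_ppv_one(self, rng):
        al = SiteAlignment(["TCAGTT"] * 30)
        prob = to_probability(build_count_matrix(al))
        pwm = gapped_pwm(prob, get_model(63, Catalog.FULL64))
        proms = sample_promoters(8, rng, planting="TCAGTT", offset=47)
        p = select_p_threshold(pwm, proms.records)
        dist = exact_score_distribution(pwm)
        assert p >= dist.min_p_value
        # the selected threshold must yield perfect PPV on this fixture
        for rec in proms.records:
            hits = scan_promoter(rec, pwm, p_max=p, distribution=dist)
            assert all(is_true_positive(h, rec.truth_interval) for h in hits)

    def test_flat_pwm_geometry_ppv(self):
        bg = Background(np.array([0.25, 0.25, 0.25, 0.25]))
        pwm = WeightMatrix(values=np.zeros((4, 6)), background=bg)
        rec = PromoterRecord("p", "A" * 100, truth_interval=(47, 53))
        p = select_p_threshold(pwm, [rec], bg)
        assert p == 1.0  # only achievable candidate
        hits = scan_promoter(rec, pwm, bg, p_max=p)
        tp = sum(is_true_positive(h, rec.truth_interval) for h in hits)
        assert tp == 11  # windows starting 42..52 overlap [47, 53)
        assert len(hits) == 95

    def test_no_truth_interval_rejected(self, rng):
        bg = Background()
        pwm = WeightMatrix(values=np.zeros((4, 6)), background=bg)
        with pytest.raises(ValueError, match="truth"):
            select_p_threshold(pwm, [PromoterRecord("p", "A" * 50)], bg)


class TestEvaluateModel:
    def test_planted_recovery_near_one(self, rng):
        proms = sample_promoters(30, rng, planting=recovery_ppm())
        sites = [r.sequence[47:53] for r in proms.records]
        prob = to_probability(build_count_matrix(SiteAlignment(sites)))
        pwm = gapped_pwm(prob, get_model(63, Catalog.FULL64))
        result = evaluate_model(
            pwm, proms.records, p_value=0.006, n_scrambles=20, rng=rng
        )
        assert result.mean_true_hit_ratio == pytest.approx(1.0, abs=0.25)
        assert result.ppv > 0.3

    def test_deterministic_given_seed(self, rng):
        proms = sample_promoters(10, rng, planting=recovery_ppm())
        prob = to_probability(
            build_count_matrix(SiteAlignment([r.sequence[47:53] for r in proms.records]))
        )
        pwm = gapped_pwm(prob, get_model(58, Catalog.FULL64))
        a = evaluate_model(pwm, proms.records, p_value=0.006, n_scrambles=5,
                           rng=np.random.default_rng(7))
        b = evaluate_model(pwm, proms.records, p_value=0.006, n_scrambles=5,
                           rng=np.random.default_rng(7))
        assert a.per_record.equals(b.per_record)


@pytest.fixture(scope="module")
def planted_records():
    rng = np.random.default_rng(99)
    return sample_promoters(45, rng, planting=recovery_ppm()).records


class TestLeavePartsOut:

    def test_shape_and_partition(self, planted_records):
        results = leave_parts_out(
            planted_records, n_trials=2, train_size=22, n_scrambles=5,
            rng=np.random.default_rng(0),
        )
        assert len(results) == 2
        for res in results:
            assert len(res.mean_ratios) == 64
            assert sorted(res.train_ids + res.test_ids) == sorted(
                r.id for r in planted_records
            )
            assert math.isnan(res.mean_ratios[0])  # all-ignored model

    def test_seed_reproducibility(self, planted_records):
        runs = [
            leave_parts_out(
                planted_records, n_trials=2, train_size=22, n_scrambles=5,
                rng=np.random.default_rng(11),
            )
            for _ in range(2)
        ]
        for a, b in zip(*runs):
            assert a.train_ids == b.train_ids
            np.testing.assert_array_equal(a.mean_ratios, b.mean_ratios)

    def test_trials_table_tidy(self, planted_records):
        results = leave_parts_out(
            planted_records, n_trials=2, train_size=22, n_scrambles=5,
            rng=np.random.default_rng(1),
        )
        table = trials_table(results)
        assert len(table) == 2 * 64
        assert set(table.columns) == {
            "trial", "model_id", "pattern", "mean_true_hit_ratio"
        }


class TestCorrelations:
    def test_self_and_negation(self, rng):
        x = rng.normal(size=64)
        corr = trial_set_correlations(np.vstack([x, x, -x]))
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_sets_near_zero(self, rng):
        sets = rng.normal(size=(40, 64))
        corr = trial_set_correlations(sets)
        off = corr[np.triu_indices(40, k=1)]
        assert abs(off.mean()) < 0.05

    def test_zero_variance_flagged(self):
        corr = trial_set_correlations(np.vstack([np.ones(64), np.arange(64.0)]))
        assert math.isnan(corr[0, 1])

    def test_nan_models_dropped(self, rng):
        x = rng.normal(size=64)
        y = x + rng.normal(0, 0.1, 64)
        x[0] = np.nan
        corr = trial_set_correlations(np.vstack([x, y]))
        assert corr[0, 1] > 0.9
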