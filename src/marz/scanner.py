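"""PWM scanning with exact p-values, PPV threshold selection, true-hit-ratio
evaluation and leave-parts-out trials.

The scanning contract mirrors the common motif-search tools: a window is a
hit when the probability, under the background model, of a window scoring at
least as high is no larger than the p-value threshold.  At width 6 the score
distribution is computed exactly by enumerating all 4096 windows, so
p-values carry no approximation.  Scanning is forward-strand only by
default: core promoter elements are orientation-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import (
    Background,
    SiteAlignment,
    WeightMatrix,
    build_count_matrix,
    encode_sequence,
    gapped_pwm,
    to_probability,
)
from .models import Catalog, GappedModel, enumerate_models, get_model

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


@dataclass
class PromoterRecord:
    """A promoter search sequence with an optional annotated element."""

    id: str
    sequence: str
    truth_interval: tuple[int, int] | None = None  # 0-based half-open
    tss_offset: int | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.truth_interval is not None:
            start, end = self.truth_interval
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"truth interval {self.truth_interval} out of bounds for "
                    f"record {self.id!r} of length {len(self.sequence)}"
                )


@dataclass
class ScanHit:
    promoter_id: str
    start: int  # 0-based window start
    score: float
    p_value: float


@dataclass
class ScoreDistribution:
    """Exact background distribution of window scores for one PWM.

    ``scores`` is ascending and ``tail[i]`` = P(score >= scores[i]); the
    tail at the minimum score is 1.
    """

    scores: np.ndarray
    tail: np.ndarray

    def p_value(self, score: float) -> float:
        """Exact P(window score >= ``score``) under the background."""
        idx = int(np.searchsorted(self.scores, score, side="left"))
        if idx >= self.scores.size:
            return 0.0
        return float(self.tail[idx])

    def score_cutoff(self, p_max: float) -> float | None:
        """Smallest achievable score whose tail probability is <= p_max.

        Returns None when even the top score's tail exceeds p_max (no window
        can ever be a hit at this threshold).
        """
        passing = np.nonzero(self.tail <= p_max)[0]
        if passing.size == 0:
            return None
        return float(self.scores[passing[0]])

    @property
    def min_p_value(self) -> float:
        return float(self.tail[-1])


def window_scores(windows: np.ndarray, pwm: WeightMatrix) -> np.ndarray:
    """Score encoded windows (rows) against a PWM, summing columns in order.

    Column contributions are accumulated sequentially left to right so that
    identical windows produce bit-identical floats wherever they are scored.
    """
    scores = np.zeros(windows.shape[:-1])
    for j in range(pwm.width):
        scores += pwm.values[windows[..., j], j]
    return scores


def exact_score_distribution(
    pwm: WeightMatrix, background: Background | None = None
) -> ScoreDistribution:
    """Enumerate all 4**w windows and their exact background probabilities."""
    background = background or pwm.background
    w = pwm.width
    n = 4**w
    codes = np.arange(n)
    letters = np.empty((n, w), dtype=np.int64)
    for j in range(w):
        letters[:, j] = (codes // 4 ** (w - 1 - j)) % 4
    scores = window_scores(letters, pwm)
    probs = np.ones(n)
    for j in range(w):
        probs *= background.probs[letters[:, j]]
    uniq, inverse = np.unique(scores, return_inverse=True)
    sums = np.zeros(uniq.size)
    np.add.at(sums, inverse, probs)  # accumulates in window-enumeration order
    tail = np.cumsum(sums[::-1])[::-1].copy()
    return ScoreDistribution(scores=uniq, tail=tail)


def sequence_windows(seq: str, width: int = 6) -> np.ndarray:
    arr = encode_sequence(seq)
    if arr.size < width:
        raise ValueError(
            f"sequence of length {arr.size} is shorter than the scan width {width}"
        )
    return np.lib.stride_tricks.sliding_window_view(arr, width)


def scan_promoter(
    record: PromoterRecord,
    pwm: WeightMatrix,
    background: Background | None = None,
    p_max: float = 1.0,
    distribution: ScoreDistribution | None = None,
    both_strands: bool = False,
) -> list[ScanHit]:
    """All windows of the record whose exact tail p-value is <= ``p_max``.

    With ``both_strands`` the reverse complement is scanned too and hits are
    reported in forward coordinates.
    """
    if not 0.0 < p_max <= 1.0:
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    background = background or pwm.background
    dist = distribution or exact_score_distribution(pwm, background)
    windows = sequence_windows(record.sequence, pwm.width)
    scores = window_scores(windows, pwm)
    hits = [
        ScanHit(record.id, int(i), float(s), dist.p_value(float(s)))
        for i, s in enumerate(scores)
        if dist.p_value(float(s)) <= p_max
    ]
    if both_strands:
        rc = _COMPLEMENT[encode_sequence(record.sequence)][::-1]
        rc_windows = np.lib.stride_tricks.sliding_window_view(rc, pwm.width)
        rc_scores = window_scores(rc_windows, pwm)
        n = len(record.sequence)
        for i, s in enumerate(rc_scores):
            p = dist.p_value(float(s))
            if p <= p_max:
                hits.append(ScanHit(record.id, n - pwm.width - int(i), float(s), p))
        hits.sort(key=lambda h: h.start)
    return hits


def ppv(true_positives: int, false_positives: int) -> float:
    """Positive predictive value TP/(TP+FP)."""
    if true_positives < 0 or false_positives < 0:
        raise ValueError("counts must be non-negative")
    total = true_positives + false_positives
    if total == 0:
        raise ValueError("PPV is undefined when there are no hits at all")
    return true_positives / total


def is_true_positive(
    hit: ScanHit, truth_interval: tuple[int, int], width: int = 6
) -> bool:
    """A hit is true when its window overlaps the annotated element by >= 1 nt."""
    start, end = truth_interval
    return hit.start < end and start < hit.start + width


def select_p_threshold(
    pwm: WeightMatrix,
    records: list[PromoterRecord],
    background: Background | None = None,
    candidate_p_values=None,
) -> float:
    """The p-value threshold maximizing PPV over the records' pooled hits.

    Candidates default to the PWM's achievable tail probabilities plus 1.0
    (PPV is piecewise constant between them); ties break toward the smallest
    (most selective) p.
    """
    background = background or pwm.background
    dist = exact_score_distribution(pwm, background)
    if candidate_p_values is None:
        candidates = sorted(set(dist.tail.tolist()) | {1.0})
    else:
        candidates = sorted(set(float(p) for p in candidate_p_values))
    per_record = []
    for rec in records:
        if rec.truth_interval is None:
            raise ValueError(
                f"record {rec.id!r} has no truth interval; PPV needs "
                "annotated elements"
            )
        hits = scan_promoter(rec, pwm, background, 1.0, distribution=dist)
        per_record.append(
            [(h.p_value, is_true_positive(h, rec.truth_interval, pwm.width)) for h in hits]
        )
    best_p, best_ppv = None, -1.0
    for p in candidates:
        tp = fp = 0
        for hits in per_record:
            for pv, is_tp in hits:
                if pv <= p:
                    tp += is_tp
                    fp += not is_tp
        if tp + fp == 0:
            continue
        value = ppv(tp, fp)
        if value > best_ppv or (value == best_ppv and p < best_p):
            best_p, best_ppv = p, value
    if best_p is None:
        raise ValueError("no candidate p-value yields any hit")
    return float(best_p)


def true_hit_ratio(tp: int, all_hits: int, avg_scrambled: float) -> float:
    """tp / (all_hits - avg_scrambled); NaN when the denominator is <= 0."""
    if tp > all_hits:
        raise ValueError("true positives cannot exceed total hits")
    if avg_scrambled < 0:
        raise ValueError("average scrambled hit count must be non-negative")
    denom = all_hits - avg_scrambled
    if denom <= 0:
        return float("nan")
    return tp / denom


@dataclass
class ScanEvaluation:
    """Per-promoter and aggregate accuracy of one model's PWM."""

    per_record: pd.DataFrame
    mean_true_hit_ratio: float
    n_undefined: int
    ppv: float


def _scramble_rows(rows: np.ndarray, n_scrambles: int, rng: np.random.Generator) -> np.ndarray:
    """(n*k, L) array of independent letter permutations of each row."""
    rep = np.repeat(rows, n_scrambles, axis=0)
    return rng.permuted(rep, axis=1)


def evaluate_model(
    pwm: WeightMatrix,
    records: list[PromoterRecord],
    background: Background | None = None,
    p_value: float = 0.006,
    n_scrambles: int = 100,
    rng: np.random.Generator | None = None,
) -> ScanEvaluation:
    """Hit counts, true positives and true hit ratios over a promoter set.

    For every record the real sequence and ``n_scrambles`` composition
    preserving scrambles are scanned at the fixed p-value threshold; the per
    record true hit ratio is tp / (all_real_hits - mean_scrambled_hits) and
    records with a non-positive denominator are excluded from the mean (and
    counted in ``n_undefined``).
    """
    if n_scrambles < 1:
        raise ValueError("need at least one scramble")
    rng = rng if rng is not None else np.random.default_rng()
    background = background or pwm.background
    dist = exact_score_distribution(pwm, background)
    cutoff = dist.score_cutoff(p_value)
    rows = []
    total_tp = total_fp = 0
    for rec in records:
        if rec.truth_interval is None:
            raise ValueError(
                f"record {rec.id!r} has no truth interval; evaluation needs "
                "annotated elements"
            )
        arr = encode_sequence(rec.sequence)
        windows = np.lib.stride_tricks.sliding_window_view(arr, pwm.width)
        scrambles = _scramble_rows(arr[None, :], n_scrambles, rng)
        scr_windows = np.lib.stride_tricks.sliding_window_view(
            scrambles, pwm.width, axis=1
        )
        if cutoff is None:
            all_hits, tp, avg_scr = 0, 0, 0.0
        else:
            scores = window_scores(windows, pwm)
            hit_mask = scores >= cutoff
            all_hits = int(hit_mask.sum())
            starts = np.arange(windows.shape[0])
            t0, t1 = rec.truth_interval
            overlap = (starts < t1) & (starts + pwm.width > t0)
            tp = int((hit_mask & overlap).sum())
            scr_scores = window_scores(scr_windows, pwm)
            avg_scr = float((scr_scores >= cutoff).sum() / n_scrambles)
        ratio = true_hit_ratio(tp, all_hits, avg_scr)
        total_tp += tp
        total_fp += all_hits - tp
        rows.append(
            dict(
                id=rec.id,
                all_hits=all_hits,
                true_positive_hits=tp,
                avg_scrambled_hits=avg_scr,
                true_hit_ratio=ratio,
            )
        )
    frame = pd.DataFrame(rows)
    defined = frame["true_hit_ratio"].dropna()
    mean_ratio = float(defined.mean()) if len(defined) else float("nan")
    overall_ppv = (
        ppv(total_tp, total_fp) if (total_tp + total_fp) > 0 else float("nan")
    )
    return ScanEvaluation(
        per_record=frame,
        mean_true_hit_ratio=mean_ratio,
        n_undefined=int(frame["true_hit_ratio"].isna().sum()),
        ppv=overall_ppv,
    )


@dataclass
class TrialResult:
    """One leave-parts-out trial: a random train/test split of the records."""

    trial_index: int
    train_ids: list[str]
    test_ids: list[str]
    mean_ratios: np.ndarray  # one entry per catalog model, NaN when undefined
    top_ids: list[int] = field(default_factory=list)
    bottom_ids: list[int] = field(default_factory=list)


def _extreme_sets(ratios: np.ndarray, k: int) -> tuple[list[int], list[int]]:
    """Model ids of the k highest / k lowest defined ratios, ties included."""
    defined = np.nonzero(np.isfinite(ratios))[0]
    if defined.size <= 2 * k:
        return defined.tolist(), defined.tolist()
    vals = ratios[defined]
    order = np.sort(vals)
    top_cut, bottom_cut = order[-k], order[k - 1]
    top = defined[vals >= top_cut]
    bottom = defined[vals <= bottom_cut]
    return sorted(int(i) for i in top), sorted(int(i) for i in bottom)


def leave_parts_out(
    records: list[PromoterRecord],
    catalog: Catalog = Catalog.FULL64,
    n_trials: int = 50,
    train_size: int = 102,
    p_value: float = 0.006,
    n_scrambles: int = 100,
    rng: np.random.Generator | None = None,
    pseudocount: float = 1.0,
    background: Background | None = None,
    extreme_fraction: float = 0.05,
) -> list[TrialResult]:
    """Repeated random-split evaluation of every catalog model.

    Each trial draws ``train_size`` records whose annotated 6-mers build the
    per-model gapped PWMs, scans the remaining records (and their
    scrambles) at the fixed p-value, and records each model's mean true hit
    ratio together with the top/bottom ``extreme_fraction`` model sets.
    All records must share one sequence length.
    """
    if len(records) < train_size + 1:
        raise ValueError(
            f"need more than train_size={train_size} records, got {len(records)}"
        )
    rng = rng if rng is not None else np.random.default_rng()
    background = background or Background()
    models = enumerate_models(6, catalog)
    k = max(1, round(extreme_fraction * len(models)))
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("leave-parts-out requires equal-length promoter records")
    seqs = np.vstack([encode_sequence(r.sequence) for r in records])
    truths = []
    for r in records:
        if r.truth_interval is None:
            raise ValueError(f"record {r.id!r} has no truth interval")
        truths.append(r.truth_interval)
    width = 6
    n_windows = seqs.shape[1] - width + 1
    starts = np.arange(n_windows)

    results = []
    for t in range(n_trials):
        perm = rng.permutation(len(records))
        train_idx, test_idx = perm[:train_size], perm[train_size:]
        train_sites = [
            records[i].sequence[slice(*records[i].truth_interval)] for i in train_idx
        ]
        alignment = SiteAlignment(train_sites)
        if alignment.site_length != width:
            raise ValueError("annotated truth intervals must span 6 bp")
        prob = to_probability(build_count_matrix(alignment, pseudocount))

        test_seqs = seqs[test_idx]
        test_windows = np.lib.stride_tricks.sliding_window_view(
            test_seqs, width, axis=1
        )
        scrambles = _scramble_rows(test_seqs, n_scrambles, rng)
        scr_windows = np.lib.stride_tricks.sliding_window_view(
            scrambles, width, axis=1
        )
        overlap = np.vstack(
            [
                (starts < truths[i][1]) & (starts + width > truths[i][0])
                for i in test_idx
            ]
        )

        ratios = np.full(len(models), np.nan)
        for m, model in enumerate(models):
            if model.considered_count == 0:
                continue  # no scoring matrix exists for the all-ignored model
            pwm = gapped_pwm(prob, model, background)
            cutoff = exact_score_distribution(pwm, background).score_cutoff(p_value)
            if cutoff is None:
                continue  # threshold unreachable: zero hits, ratio undefined
            scores = window_scores(test_windows, pwm)
            hit_mask = scores >= cutoff
            all_hits = hit_mask.sum(axis=1)
            tp = (hit_mask & overlap).sum(axis=1)
            scr_hits = (
                (window_scores(scr_windows, pwm) >= cutoff)
                .sum(axis=1)
                .reshape(len(test_idx), n_scrambles)
                .mean(axis=1)
            )
            denom = all_hits - scr_hits
            defined = denom > 0
            if defined.any():
                ratios[m] = float((tp[defined] / denom[defined]).mean())
        top, bottom = _extreme_sets(ratios, k)
        results.append(
            TrialResult(
                trial_index=t,
                train_ids=[records[i].id for i in train_idx],
                test_ids=[records[i].id for i in test_idx],
                mean_ratios=ratios,
                top_ids=top,
                bottom_ids=bottom,
            )
        )
    return results


def trials_table(results: list[TrialResult], catalog: Catalog = Catalog.FULL64) -> pd.DataFrame:
    """Tidy (trial, model_id, pattern, mean_true_hit_ratio) table."""
    models = enumerate_models(6, catalog)
    rows = []
    for res in results:
        for model, ratio in zip(models, res.mean_ratios):
            rows.append(
                dict(
                    trial=res.trial_index,
                    model_id=model.model_id,
                    pattern=model.pattern,
                    mean_true_hit_ratio=float(ratio),
                )
            )
    return pd.DataFrame(rows)


def trial_set_correlations(trial_sets: np.ndarray) -> np.ndarray:
    """Pearson correlations between per-model mean-ratio vectors.

    ``trial_sets`` has one row per set of trials and one column per model;
    models with an undefined ratio in any set are dropped before the
    correlation.  Zero-variance sets yield NaN entries.
    """
    sets = np.asarray(trial_sets, dtype=float)
    if sets.ndim != 2 or sets.shape[0] < 2:
        raise ValueError("need at least two trial sets")
    keep = np.isfinite(sets).all(axis=0)
    sets = sets[:, keep]
    n = sets.shape[0]
    out = np.full((n, n), np.nan)
    stds = sets.std(axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sets)
    for i in range(n):
        for j in range(n):
            if stds[i] > 0 and stds[j] > 0:
                out[i, j] = corr[i, j]
    np.fill_diagonal(out, np.where(stds > 0, 1.0, np.nan))
    return out
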