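"""RZ screening: real-vs-scrambled discrimination of gapped models.

Each model scores a 6 bp window as the sum, over the sliding frames of the
model inside the window, of the log-odds of the observed considered-letter
tuple frequency against the background product for that tuple.  Thresholds
are resolved per model from the empirical percentiles of the training-site
scores; windows scoring at or above the threshold are designated binding
sites.  The RZ score real/(real+scrambled) compares hit counts on real
promoters against composition-preserving scrambles: 1 means hits only in
real sequences, 0 only in scrambles, 0.5 a balanced count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import (
    Background,
    GappedTupleTable,
    SiteAlignment,
    encode_sequence,
    gapped_tuple_table,
    tuple_indices,
)
from .models import Catalog, GappedModel, enumerate_models, frame_count

DEFAULT_THRESHOLD_POSITIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


def scramble_sequence(seq: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the letters of ``seq``.

    Preserves the per-letter multiset exactly, so scrambles share the
    original's nucleotide composition.
    """
    letters = list(seq)
    return "".join(rng.permutation(letters))


def _tuple_background_logs(model: GappedModel, background: Background) -> np.ndarray:
    """log2 background probability of every considered-letter tuple."""
    c = model.considered_count
    logs = np.log2(background.probs)
    out = np.zeros(4**c)
    for pos in range(c):
        digit = (np.arange(4**c) // 4 ** (c - 1 - pos)) % 4
        out += logs[digit]
    return out


def score_windows(
    windows: np.ndarray,
    model: GappedModel,
    table: GappedTupleTable,
    background: Background | None = None,
) -> np.ndarray:
    """Tuple-log-odds score of each encoded window (rows of length 6)."""
    background = background or Background()
    bg_logs = _tuple_background_logs(model, background)
    window_length = windows.shape[1]
    scores = np.zeros(windows.shape[0])
    for f in range(frame_count(model, window_length)):
        idx = tuple_indices(windows, model, f)
        freq = table.frame_table(f if not table.pooled else 0)
        scores += np.log2(freq[idx]) - bg_logs[idx]
    return scores


def score_training_sites(
    alignment: SiteAlignment,
    model: GappedModel,
    table: GappedTupleTable,
    background: Background | None = None,
) -> np.ndarray:
    """One score per training site, summed over the model's frames."""
    return score_windows(alignment.to_array(), model, table, background)


def resolve_threshold(training_scores, position: float) -> float:
    """Empirical percentile cutoff so the top (1-position) sites are detected.

    Position 0 returns the minimum training score (every training site is
    designated a binding site under the rule score >= threshold); position 1
    returns the maximum (only the top-scoring site is designated).
    """
    scores = np.sort(np.asarray(training_scores, dtype=float))
    if scores.size == 0:
        raise ValueError("cannot resolve a threshold from an empty score list")
    if not 0.0 <= position <= 1.0:
        raise ValueError(f"threshold position must be in [0, 1], got {position}")
    idx = math.ceil(position * (scores.size - 1))
    return float(scores[idx])


def rz_score(real_hits: float, scrambled_hits: float) -> float:
    """real/(real+scrambled); NaN when both counts are zero."""
    if real_hits < 0 or scrambled_hits < 0:
        raise ValueError("hit counts must be non-negative")
    total = real_hits + scrambled_hits
    if total == 0:
        return float("nan")
    return real_hits / total


def _promoter_windows(seq: str, window_length: int) -> np.ndarray:
    arr = encode_sequence(seq)
    if arr.size < window_length:
        raise ValueError(
            f"promoter of length {arr.size} is shorter than the "
            f"{window_length} bp scoring window"
        )
    return np.lib.stride_tricks.sliding_window_view(arr, window_length)


def run_rz_screen(
    alignment: SiteAlignment,
    promoters: list[str],
    catalog: Catalog = Catalog.ANCHORED32,
    threshold_positions=DEFAULT_THRESHOLD_POSITIONS,
    scrambles_per_promoter: int = 1,
    rng: np.random.Generator | None = None,
    pseudocount: float = 1.0,
    background: Background | None = None,
) -> pd.DataFrame:
    """Score every catalog model at every threshold against real promoters
    and their scrambles.

    Promoter windows are the site-length windows of each promoter, scored
    exactly as the training sites are.  Scrambled hit counts are averaged
    over ``scrambles_per_promoter`` composition-preserving scrambles of each
    promoter.  Returns one row per model x threshold.
    """
    if not promoters:
        raise ValueError("at least one promoter sequence is required")
    rng = rng if rng is not None else np.random.default_rng()
    background = background or Background()
    site_length = alignment.site_length
    scrambled = [
        scramble_sequence(p, rng)
        for p in promoters
        for _ in range(scrambles_per_promoter)
    ]
    real_windows = [_promoter_windows(p, site_length) for p in promoters]
    scram_windows = [_promoter_windows(p, site_length) for p in scrambled]

    rows = []
    for model in enumerate_models(site_length, catalog):
        if model.considered_count == 0:
            for pos in threshold_positions:
                rows.append(
                    dict(
                        model_id=model.model_id,
                        pattern=model.pattern,
                        threshold_position=pos,
                        threshold_value=float("nan"),
                        real_hits=float("nan"),
                        scrambled_hits=float("nan"),
                        rz_score=float("nan"),
                    )
                )
            continue
        table = gapped_tuple_table(alignment, model, pseudocount=pseudocount)
        training = score_training_sites(alignment, model, table, background)
        real_scores = np.concatenate(
            [score_windows(w, model, table, background) for w in real_windows]
        )
        scram_scores = np.concatenate(
            [score_windows(w, model, table, background) for w in scram_windows]
        )
        for pos in threshold_positions:
            thr = resolve_threshold(training, pos)
            real_hits = int((real_scores >= thr).sum())
            scram_hits = float((scram_scores >= thr).sum()) / scrambles_per_promoter
            rows.append(
                dict(
                    model_id=model.model_id,
                    pattern=model.pattern,
                    threshold_position=pos,
                    threshold_value=thr,
                    real_hits=real_hits,
                    scrambled_hits=scram_hits,
                    rz_score=rz_score(real_hits, scram_hits),
                )
            )
    return pd.DataFrame(rows)


@dataclass
class PerformanceClassification:
    """Good/poor model sets at one threshold position."""

    threshold_position: float
    good_model_ids: list[int]
    poor_model_ids: list[int]
    good_cutoff: float
    poor_cutoff: float


def classify_models(
    rz_table: pd.DataFrame, target_count: int = 3
) -> list[PerformanceClassification]:
    """Pick the ~``target_count`` highest- and lowest-RZ models per threshold.

    Ties at the cutoff value are included, so the sets may exceed the target
    count, mirroring a median-of-three selection rule.
    """
    out = []
    for pos, group in rz_table.groupby("threshold_position", sort=True):
        defined = group.dropna(subset=["rz_score"])
        if target_count > len(defined):
            raise ValueError(
                f"target_count {target_count} exceeds the {len(defined)} "
                "models with defined RZ scores"
            )
        scores = defined["rz_score"].to_numpy()
        if np.all(scores == scores[0]):
            warnings.warn(
                f"all RZ scores equal at threshold {pos}; no good/poor split",
                stacklevel=2,
            )
            out.append(
                PerformanceClassification(float(pos), [], [], float("nan"), float("nan"))
            )
            continue
        order = np.sort(scores)
        good_cut = order[-target_count]
        poor_cut = order[target_count - 1]
        good = defined.loc[defined["rz_score"] >= good_cut, "model_id"]
        poor = defined.loc[defined["rz_score"] <= poor_cut, "model_id"]
        good_ids = sorted(int(i) for i in good)
        poor_ids = sorted(int(i) for i in poor)
        overlap = set(good_ids) & set(poor_ids)
        if overlap:
            good_ids = [i for i in good_ids if i not in overlap]
            poor_ids = [i for i in poor_ids if i not in overlap]
            warnings.warn(
                f"good/poor cutoffs overlap at threshold {pos}; dropped "
                f"{sorted(overlap)} from both sets",
                stacklevel=2,
            )
        out.append(
            PerformanceClassification(
                threshold_position=float(pos),
                good_model_ids=good_ids,
                poor_model_ids=poor_ids,
                good_cutoff=float(good_cut),
                poor_cutoff=float(poor_cut),
            )
        )
    return out


def rz_heatmap_table(rz_table: pd.DataFrame) -> pd.DataFrame:
    """Models x thresholds matrix of RZ scores on the 0-100 integer scale."""
    wide = rz_table.pivot(
        index="model_id", columns="threshold_position", values="rz_score"
    )
    return (wide * 100).round(0)
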