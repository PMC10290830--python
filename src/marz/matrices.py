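"""Count, probability, log-odds and gapped-model matrices from aligned sites.

Two representations of a gapped model's statistics are built on purpose:

* a background-filled position weight matrix (:func:`gapped_pwm`), in which
  ignored columns contribute zero log-odds to every window score -- the
  position-independent form used by the scanner; and
* a joint tuple table (:func:`gapped_tuple_table`) over the 4**c
  combinations of the model's c considered positions, which captures
  within-frame dependence and drives the RZ screening engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import CONSIDERED, GappedModel, frame_count

ALPHABET = "ACGT"
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET.encode()):
    _ENCODE[_b] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map an ACGT string to int codes 0..3 (A,C,G,T)."""
    arr = _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


@dataclass
class SiteAlignment:
    """Aligned equal-length binding-site sequences (no indels)."""

    sites: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("alignment must contain at least one site")
        self.sites = [s.upper() for s in self.sites]
        length = len(self.sites[0])
        for i, s in enumerate(self.sites):
            if len(s) != length:
                raise ValueError(
                    f"site {i} has length {len(s)}, expected {length}"
                )
            if set(s) - set(ALPHABET):
                raise ValueError(f"site {i} contains non-ACGT characters: {s!r}")

    @property
    def site_length(self) -> int:
        return len(self.sites[0])

    def __len__(self) -> int:
        return len(self.sites)

    def to_array(self) -> np.ndarray:
        """(n_sites, site_length) int codes."""
        return np.vstack([encode_sequence(s) for s in self.sites])


@dataclass
class Background:
    """Genome-wide single-nucleotide frequencies (order A,C,G,T)."""

    probs: np.ndarray = field(
        default_factory=lambda: np.array([0.3, 0.2, 0.2, 0.3])
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (4,):
            raise ValueError("background needs exactly 4 probabilities (A,C,G,T)")
        if (self.probs <= 0).any():
            raise ValueError("background probabilities must be strictly positive")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")

    @classmethod
    def from_at_gc(cls, at: float = 0.6, gc: float = 0.4) -> "Background":
        """Split an A+T / G+C content evenly within each pair.

        The fly-genome default (A/T 0.6, G/C 0.4) gives A=T=0.3, C=G=0.2.
        """
        return cls(np.array([at / 2, gc / 2, gc / 2, at / 2]))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(ALPHABET, self.probs.tolist()))


def _values_frame(values: np.ndarray) -> pd.DataFrame:
    width = values.shape[1]
    return pd.DataFrame(
        values, index=list(ALPHABET), columns=range(1, width + 1)
    )


@dataclass
class CountMatrix:
    values: np.ndarray  # (4, L), pseudocount already included
    pseudocount: float = 1.0

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return _values_frame(self.values)


@dataclass
class ProbabilityMatrix:
    values: np.ndarray  # (4, L), columns sum to 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("probability matrix columns must sum to 1")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return _values_frame(self.values)


@dataclass
class WeightMatrix:
    """Log-odds matrix: entry = log(prob/background) in ``log_base``."""

    values: np.ndarray  # (4, L)
    background: Background
    log_base: float = 2.0
    model: GappedModel | None = None

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return _values_frame(self.values)


def build_count_matrix(alignment: SiteAlignment, pseudocount: float = 1.0) -> CountMatrix:
    """Per-position nucleotide counts with a uniform pseudocount added."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    arr = alignment.to_array()
    counts = np.zeros((4, alignment.site_length), dtype=float)
    for j in range(alignment.site_length):
        counts[:, j] = np.bincount(arr[:, j], minlength=4)
    return CountMatrix(values=counts + pseudocount, pseudocount=pseudocount)


def to_probability(counts: CountMatrix) -> ProbabilityMatrix:
    sums = counts.values.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("cannot normalize a column with zero total count")
    return ProbabilityMatrix(values=counts.values / sums)


def to_log_odds(
    prob: ProbabilityMatrix,
    background: Background | None = None,
    log_base: float = 2.0,
) -> WeightMatrix:
    background = background or Background()
    if (prob.values == 0).any():
        raise ValueError(
            "probability matrix contains zeros; rebuild counts with a "
            "positive pseudocount before taking log-odds"
        )
    values = np.log(prob.values / background.probs[:, None]) / np.log(log_base)
    return WeightMatrix(values=values, background=background, log_base=log_base)


def gapped_pwm(
    prob: ProbabilityMatrix,
    model: GappedModel,
    background: Background | None = None,
    log_base: float = 2.0,
) -> WeightMatrix:
    """Background-fill the ignored columns of a log-odds matrix.

    Considered columns carry the log-odds of ``prob``; ignored columns carry
    the background itself and therefore contribute exactly zero to every
    window score.
    """
    background = background or Background()
    if model.considered_count == 0:
        raise ValueError(
            f"model {model.pattern!r} considers no positions; a scoring "
            "matrix requires at least one considered position"
        )
    if model.length != prob.width:
        raise ValueError(
            f"model length {model.length} does not match matrix width {prob.width}"
        )
    full = to_log_odds(prob, background, log_base)
    values = np.zeros_like(full.values)
    for j, sym in enumerate(model.pattern):
        if sym == CONSIDERED:
            values[:, j] = full.values[:, j]
    return WeightMatrix(
        values=values, background=background, log_base=log_base, model=model
    )


@dataclass
class GappedTupleTable:
    """Joint frequencies of the considered-position tuples of a model.

    ``tables`` has one row per frame offset (or a single pooled row) and
    4**c columns indexed base-4 by the considered letters read left to
    right; each row sums to 1.
    """

    model: GappedModel
    tables: np.ndarray  # (n_frames or 1, 4**c)
    pooled: bool
    pseudocount: float

    @property
    def tuple_arity(self) -> int:
        return self.model.considered_count

    def frame_table(self, frame_offset: int) -> np.ndarray:
        return self.tables[0] if self.pooled else self.tables[frame_offset]


def tuple_indices(arr: np.ndarray, model: GappedModel, frame_offset: int) -> np.ndarray:
    """Base-4 index of each row's considered-letter tuple at a frame."""
    idx = np.zeros(arr.shape[0], dtype=np.int64)
    for pos in model.considered_positions:
        idx = idx * 4 + arr[:, frame_offset + pos]
    return idx


def gapped_tuple_table(
    alignment: SiteAlignment,
    model: GappedModel,
    pseudocount: float = 1.0,
    pooled: bool = False,
) -> GappedTupleTable:
    if model.considered_count == 0:
        raise ValueError(
            f"model {model.pattern!r} considers no positions; cannot build "
            "a tuple table"
        )
    arr = alignment.to_array()
    n_frames = frame_count(model, alignment.site_length)
    size = 4**model.considered_count
    tables = np.zeros((n_frames, size), dtype=float)
    for f in range(n_frames):
        counts = np.bincount(tuple_indices(arr, model, f), minlength=size)
        tables[f] = counts + pseudocount
    tables /= tables.sum(axis=1, keepdims=True)
    if pooled:
        tables = tables.mean(axis=0, keepdims=True)
    return GappedTupleTable(
        model=model, tables=tables, pooled=pooled, pseudocount=pseudocount
    )
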