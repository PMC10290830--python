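"""Gapped n-mer model catalogs.

A gapped n-mer model is an ordered pattern of considered (``m``) and ignored
(``k``) positions.  When a model is laid over a nucleotide window, only the
``m`` positions contribute to scoring; ``k`` positions are skipped.  Two
catalogs are supported:

* ``ANCHORED32`` -- the original set of 32 models of length 1..6 whose first
  and last symbols are always considered.  Within each length block (block
  starts 0, 1, 2, 4, 8, 16 for lengths 1..6) models are numbered by the
  binary value of the interior symbols, ``m`` = 1.
* ``FULL64`` -- all 64 length-6 patterns, numbered by reading the pattern as
  a binary number with ``m`` = 1 and ``k`` = 0, most significant symbol
  first (so ``kkkkkk`` = 0 and ``mmmmmm`` = 63).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

CONSIDERED = "m"
IGNORED = "k"

#: 1-based site position -> position relative to the transcription start
#: site (there is no position 0; the +1 base is the TSS itself).
TSS_POSITION_LABELS = ("-2", "-1", "+1", "+2", "+3", "+4")


class Catalog(str, enum.Enum):
    """Which model catalog a pattern is numbered under."""

    ANCHORED32 = "anchored32"
    FULL64 = "full64"


class TallyMode(str, enum.Enum):
    """How position-inclusion tallies count coverage.

    PER_FRAME adds one for every (model, frame) pair that covers a site
    position with a considered symbol; PER_MODEL_UNION adds at most one per
    model, if any of its frames covers the position.
    """

    PER_FRAME = "per_frame"
    PER_MODEL_UNION = "per_model_union"


# Start of each length block in the anchored catalog (index = length).
_ANCHORED_BLOCK_STARTS = {1: 0, 2: 1, 3: 2, 4: 4, 5: 8, 6: 16}


def _validate_pattern(pattern: str) -> None:
    if not (1 <= len(pattern) <= 6):
        raise ValueError(f"pattern length must be 1..6, got {len(pattern)}")
    bad = set(pattern) - {CONSIDERED, IGNORED}
    if bad:
        raise ValueError(f"pattern may only contain 'm'/'k', got {sorted(bad)}")


@dataclass(frozen=True)
class GappedModel:
    """A gapped n-mer pattern with its catalog identity."""

    pattern: str
    catalog: Catalog
    model_id: int

    def __post_init__(self) -> None:
        _validate_pattern(self.pattern)
        expected = model_id(self.pattern, self.catalog)
        if expected != self.model_id:
            raise ValueError(
                f"model_id {self.model_id} inconsistent with pattern "
                f"{self.pattern!r} under {self.catalog.value} "
                f"(expected {expected})"
            )

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def considered_positions(self) -> tuple[int, ...]:
        """0-based offsets of considered symbols within the pattern."""
        return tuple(i for i, s in enumerate(self.pattern) if s == CONSIDERED)

    @property
    def considered_count(self) -> int:
        return self.pattern.count(CONSIDERED)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.catalog.value}:{self.model_id}:{self.pattern}"


def model_id(pattern: str, catalog: Catalog) -> int:
    """Catalog number of ``pattern``.

    FULL64 reads the pattern as a 6-bit binary number (m=1).  ANCHORED32
    adds the binary value of the interior symbols to the length-block start.
    """
    _validate_pattern(pattern)
    catalog = Catalog(catalog)
    if catalog is Catalog.FULL64:
        if len(pattern) != 6:
            raise ValueError("FULL64 patterns must have length 6")
        return int("".join("1" if s == CONSIDERED else "0" for s in pattern), 2)
    if pattern[0] != CONSIDERED or pattern[-1] != CONSIDERED:
        raise ValueError(
            f"anchored patterns must start and end with 'm', got {pattern!r}"
        )
    interior = pattern[1:-1]
    offset = 0
    for s in interior:
        offset = (offset << 1) | (s == CONSIDERED)
    return _ANCHORED_BLOCK_STARTS[len(pattern)] + offset


def pattern_from_id(model_number: int, catalog: Catalog) -> str:
    """Inverse of :func:`model_id` over the given catalog."""
    catalog = Catalog(catalog)
    if catalog is Catalog.FULL64:
        if not 0 <= model_number <= 63:
            raise ValueError(f"FULL64 ids are 0..63, got {model_number}")
        bits = format(model_number, "06b")
        return "".join(CONSIDERED if b == "1" else IGNORED for b in bits)
    if not 0 <= model_number <= 31:
        raise ValueError(f"ANCHORED32 ids are 0..31, got {model_number}")
    length = next(
        L
        for L in range(6, 0, -1)
        if model_number >= _ANCHORED_BLOCK_STARTS[L]
    )
    offset = model_number - _ANCHORED_BLOCK_STARTS[length]
    if length <= 2:
        interior = ""
    else:
        interior = "".join(
            CONSIDERED if b == "1" else IGNORED
            for b in format(offset, f"0{length - 2}b")
        )
    return CONSIDERED + interior + (CONSIDERED if length >= 2 else "")


def get_model(model_number: int, catalog: Catalog = Catalog.FULL64) -> GappedModel:
    """Convenience constructor from a catalog number."""
    catalog = Catalog(catalog)
    return GappedModel(pattern_from_id(model_number, catalog), catalog, model_number)


def model_from_pattern(pattern: str, catalog: Catalog = Catalog.FULL64) -> GappedModel:
    catalog = Catalog(catalog)
    return GappedModel(pattern, catalog, model_id(pattern, catalog))


def enumerate_models(site_length: int = 6, catalog: Catalog = Catalog.ANCHORED32) -> list[GappedModel]:
    """All models of the catalog, in catalog-number order.

    For ANCHORED32 this is every pattern of length 1..site_length anchored by
    considered symbols at both ends (32 models at site_length 6, in blocks of
    1, 1, 2, 4, 8, 16 by length); for FULL64 it is all 2**site_length
    patterns of length ``site_length``.
    """
    try:
        catalog = Catalog(catalog)
    except ValueError as exc:
        raise ValueError(f"unknown catalog {catalog!r}") from exc
    if site_length != 6:
        raise ValueError(
            "catalog numbering is defined for 6 bp sites; got "
            f"site_length={site_length}"
        )
    if catalog is Catalog.FULL64:
        n = 2**site_length
        return [get_model(i, catalog) for i in range(n)]
    return [get_model(i, catalog) for i in range(32)]


def frame_count(model: GappedModel, site_length: int) -> int:
    """Number of offsets at which the model fits inside a site."""
    if model.length > site_length:
        raise ValueError(
            f"model length {model.length} exceeds site length {site_length}"
        )
    return site_length - model.length + 1


def mask_site(site: str, model: GappedModel, frame_offset: int = 0) -> str:
    """Replace every position the model does not consider with ``N``.

    Positions outside the frame and positions under an ignored symbol are
    masked; e.g. ``TCAGTG`` under ``mmkkmm`` at offset 0 becomes ``TCNNTG``.
    """
    site = site.upper()
    if set(site) - set("ACGT"):
        raise ValueError(f"site contains non-ACGT characters: {site!r}")
    if not 0 <= frame_offset <= len(site) - model.length:
        raise ValueError(
            f"frame_offset {frame_offset} out of range for site length "
            f"{len(site)} and model length {model.length}"
        )
    out = ["N"] * len(site)
    for pos in model.considered_positions:
        out[frame_offset + pos] = site[frame_offset + pos]
    return "".join(out)


@dataclass
class PositionTally:
    """Considered-position coverage counts over a set of models."""

    counts: np.ndarray
    mode: TallyMode
    performance_class: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("tally counts must be non-negative")


def position_inclusion_tally(
    models: list[GappedModel],
    site_length: int = 6,
    mode: TallyMode = TallyMode.PER_FRAME,
) -> PositionTally:
    """Tally how often each site position is considered, over sliding frames.

    In PER_FRAME mode every frame of every model contributes; in
    PER_MODEL_UNION mode each model contributes at most once per position.
    """
    mode = TallyMode(mode)
    counts = np.zeros(site_length, dtype=int)
    for model in models:
        covered = np.zeros(site_length, dtype=int)
        for offset in range(frame_count(model, site_length)):
            for pos in model.considered_positions:
                covered[offset + pos] += 1
        if mode is TallyMode.PER_MODEL_UNION:
            covered = (covered > 0).astype(int)
        counts += covered
    return PositionTally(counts=counts, mode=mode)


def catalog_table(catalog: Catalog, site_length: int = 6):
    """The catalog as a tidy table (catalog, model_id, pattern)."""
    import pandas as pd

    models = enumerate_models(site_length, catalog)
    return pd.DataFrame(
        {
            "catalog": [m.catalog.value for m in models],
            "model_id": [m.model_id for m in models],
            "pattern": [m.pattern for m in models],
        }
    )
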