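"""Synthetic sites and promoters with known ground truth.

Every pipeline stage is testable without external databases: sites are
drawn column-independently from a position probability matrix, optionally
with a planted pairwise coupling, and promoters are background-i.i.d.
sequences of configurable length with a site written at a known offset.

The coupling mechanism is mixture forcing: with probability c a site's two
coupled positions are overwritten with the chosen letter pair, otherwise
the site is left as drawn.  Its joint and marginal frequencies have closed
forms -- the joint probability of the pair is c + (1-c) * p_i(a) * p_j(b) --
which makes exact power calculations possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrices import (
    ALPHABET,
    Background,
    ProbabilityMatrix,
    SiteAlignment,
    decode_sequence,
)
from .scanner import PromoterRecord

#: Default promoter geometry: 100 bp spanning -49..+50 around the TSS, with
#: the 6 bp element at 0-based offset 47 so that its third base sits on the
#: +1 start site (site positions 1..6 = -2,-1,+1,+2,+3,+4).
DEFAULT_PROMOTER_LENGTH = 100
DEFAULT_SITE_OFFSET = 47


def _consensus_ppm(columns: list[dict[str, float]]) -> ProbabilityMatrix:
    values = np.zeros((4, len(columns)))
    for j, col in enumerate(columns):
        for letter, p in col.items():
            values[ALPHABET.index(letter), j] = p
    return ProbabilityMatrix(values=values)


def inr_like_ppm() -> ProbabilityMatrix:
    """An initiator-like matrix with consensus TCAGTY.

    Each of the first five columns puts 0.7 on the consensus letter and 0.1
    on the rest; the final pyrimidine column splits 0.35/0.35 between T and
    C.  A deliberately simple stand-in for an experimentally derived
    initiator profile.
    """
    cols = [
        {"T": 0.7, "A": 0.1, "C": 0.1, "G": 0.1},
        {"C": 0.7, "A": 0.1, "G": 0.1, "T": 0.1},
        {"A": 0.7, "C": 0.1, "G": 0.1, "T": 0.1},
        {"G": 0.7, "A": 0.1, "C": 0.1, "T": 0.1},
        {"T": 0.7, "A": 0.1, "C": 0.1, "G": 0.1},
        {"T": 0.35, "C": 0.35, "A": 0.15, "G": 0.15},
    ]
    return _consensus_ppm(cols)


def tata_like_ppm() -> ProbabilityMatrix:
    """A TATA-box-like matrix with a strong TATAAA consensus (0.8 per column)."""
    cols = []
    for letter in "TATAAA":
        col = {b: 0.2 / 3 for b in ALPHABET if b != letter}
        col[letter] = 0.8
        cols.append(col)
    return _consensus_ppm(cols)


def recovery_ppm(
    strong_positions: tuple[int, ...] = (2, 5),
    strong_prob: float = 0.9,
    weak_prob: float = 0.5,
) -> ProbabilityMatrix:
    """A TCAGTT-consensus matrix with extra information planted at chosen
    1-based positions.

    Used as the ground truth of recovery benchmarks: models that consider
    the strong positions should outrank models that ignore them.
    """
    cols = []
    for j, letter in enumerate("TCAGTT", start=1):
        p = strong_prob if j in strong_positions else weak_prob
        col = {b: (1 - p) / 3 for b in ALPHABET if b != letter}
        col[letter] = p
        cols.append(col)
    return _consensus_ppm(cols)


@dataclass(frozen=True)
class CouplingSpec:
    """Planted pairwise dependence: force (a at i, b at j) with probability c."""

    position_pair: tuple[int, int]  # 1-based, i < j
    nucleotide_pair: tuple[str, str]
    strength: float

    def __post_init__(self) -> None:
        i, j = self.position_pair
        if not i < j:
            raise ValueError("position pair must satisfy i < j")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must be in [0, 1]")
        for letter in self.nucleotide_pair:
            if letter not in ALPHABET:
                raise ValueError(f"unknown nucleotide {letter!r}")


def _draw_letters(ppm: ProbabilityMatrix, n: int, rng: np.random.Generator) -> np.ndarray:
    length = ppm.width
    out = np.empty((n, length), dtype=np.int8)
    for j in range(length):
        cum = np.cumsum(ppm.values[:, j])[:-1]
        out[:, j] = np.searchsorted(cum, rng.random(n), side="right")
    return out


def sample_sites(
    ppm: ProbabilityMatrix, n: int, rng: np.random.Generator, label: str = "synthetic"
) -> SiteAlignment:
    """n sites with independent positions drawn from the ppm columns."""
    arr = _draw_letters(ppm, n, rng)
    return SiteAlignment([decode_sequence(row) for row in arr], label=label)


def sample_sites_coupled(
    ppm: ProbabilityMatrix,
    spec: CouplingSpec,
    n: int,
    rng: np.random.Generator,
    label: str = "synthetic-coupled",
) -> SiteAlignment:
    """Sites from the ppm with a planted coupling.

    With strength 0 the output is bitwise identical to :func:`sample_sites`
    at the same generator state (the coupling draw happens after the site
    draw); with strength 1 every site carries the forced letter pair.
    """
    arr = _draw_letters(ppm, n, rng)
    force = rng.random(n) < spec.strength
    i, j = spec.position_pair
    a, b = spec.nucleotide_pair
    arr[force, i - 1] = ALPHABET.index(a)
    arr[force, j - 1] = ALPHABET.index(b)
    return SiteAlignment([decode_sequence(row) for row in arr], label=label)


@dataclass
class PlantedPromoterSet:
    """Synthetic promoters with recorded truth intervals and parameters."""

    records: list[PromoterRecord]
    background: Background
    offset: int
    length: int
    seed_note: str = ""
    planted_sites: list[str] = field(default_factory=list)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


def sample_promoters(
    n: int,
    rng: np.random.Generator,
    background: Background | None = None,
    length: int = DEFAULT_PROMOTER_LENGTH,
    planting: ProbabilityMatrix | str | None = None,
    offset: int = DEFAULT_SITE_OFFSET,
    id_prefix: str = "syn",
) -> PlantedPromoterSet:
    """Background-i.i.d. promoters with an optional planted 6 bp element.

    ``planting`` may be a fixed site string, a probability matrix to draw
    one site per record from, or None for site-free sequences (the truth
    interval is still recorded at the offset so geometry-only evaluations
    are possible).
    """
    background = background or Background()
    site_width = 6 if not isinstance(planting, str) else len(planting)
    if isinstance(planting, ProbabilityMatrix):
        site_width = planting.width
    if not 0 <= offset <= length - site_width:
        raise ValueError(
            f"offset {offset} out of range for length {length} and a "
            f"{site_width} bp site"
        )
    cum = np.cumsum(background.probs)[:-1]
    base = np.searchsorted(cum, rng.random((n, length)), side="right").astype(np.int8)
    planted: list[str] = []
    if isinstance(planting, ProbabilityMatrix):
        sites_arr = _draw_letters(planting, n, rng)
        planted = [decode_sequence(row) for row in sites_arr]
        base[:, offset : offset + site_width] = sites_arr
    elif isinstance(planting, str):
        site = np.array(
            [ALPHABET.index(ch) for ch in planting.upper()], dtype=np.int8
        )
        planted = [planting.upper()] * n
        base[:, offset : offset + site_width] = site
    records = [
        PromoterRecord(
            id=f"{id_prefix}{i:04d}",
            sequence=decode_sequence(base[i]),
            truth_interval=(offset, offset + site_width),
        )
        for i in range(n)
    ]
    return PlantedPromoterSet(
        records=records,
        background=background,
        offset=offset,
        length=length,
        planted_sites=planted,
    )
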