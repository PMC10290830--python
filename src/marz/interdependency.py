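"""Monte Carlo test of pairwise positional nucleotide interdependency.

The null hypothesis for each (position pair, nucleotide pair) is that the
two positions are independent: the joint frequency of letter ``a`` at
position i and letter ``b`` at position j equals the product of the
marginals.  Null sets of sites are simulated from the alignment's own
position probability matrix with independent columns, and the observed
joint count is compared against the simulated counts.  Monte Carlo
p-values use the add-one convention (1 + #as-extreme)/(n_sets + 1), so they
are never exactly zero; the upper and lower one-tailed p-values (over- and
under-enrichment) and the doubled-minimum two-tailed p-value are all
reported.  No multiple-testing correction is applied across the 240
hypotheses of a 6 bp site.
"""

from __future__ import annotations

import warnings
from itertools import combinations, product

import numpy as np
import pandas as pd

from .matrices import ALPHABET, ProbabilityMatrix, SiteAlignment

DEFAULT_ALPHAS = (0.05, 0.01, 0.001)


def position_probability_matrix(alignment: SiteAlignment) -> ProbabilityMatrix:
    """Raw per-position letter frequencies (no pseudocount)."""
    arr = alignment.to_array()
    n, length = arr.shape
    values = np.zeros((4, length))
    for j in range(length):
        values[:, j] = np.bincount(arr[:, j], minlength=4) / n
    return ProbabilityMatrix(values=values)


def enumerate_pair_hypotheses(site_length: int = 6) -> list[tuple[tuple[int, int], tuple[str, str]]]:
    """All (1-based position pair, ordered nucleotide pair) hypotheses.

    C(L, 2) position pairs x 16 nucleotide pairs; 240 for a 6 bp site.
    """
    if site_length < 2:
        raise ValueError("need at least two positions")
    positions = combinations(range(1, site_length + 1), 2)
    return [
        ((i, j), (a, b))
        for (i, j) in positions
        for a, b in product(ALPHABET, repeat=2)
    ]


def expected_pair_count(n_sites: int, p_i: float, p_j: float) -> float:
    """Expected joint count under independence: n * p_i(a) * p_j(b)."""
    return n_sites * p_i * p_j


def observed_pair_counts(alignment: SiteAlignment) -> np.ndarray:
    """(n_pairs, 16) joint counts of each letter pair in the alignment."""
    arr = alignment.to_array()
    length = alignment.site_length
    pairs = list(combinations(range(length), 2))
    counts = np.zeros((len(pairs), 16), dtype=np.int64)
    for p, (i, j) in enumerate(pairs):
        counts[p] = np.bincount(arr[:, i] * 4 + arr[:, j], minlength=16)
    return counts


def simulate_null_counts(
    ppm: ProbabilityMatrix,
    n_sets: int,
    set_size: int,
    rng: np.random.Generator,
    chunk_size: int = 20000,
) -> np.ndarray:
    """(n_pairs, 16, n_sets) joint counts over independent-column null sets.

    Each null set is ``set_size`` sites whose positions are drawn
    independently from the ppm columns, so the null joint count of any
    letter pair is Binomial(set_size, p_i(a) * p_j(b)).
    """
    if n_sets < 1 or set_size < 1:
        raise ValueError("n_sets and set_size must be positive")
    length = ppm.width
    pairs = list(combinations(range(length), 2))
    cums = [np.cumsum(ppm.values[:, j])[:-1] for j in range(length)]
    out = np.empty((len(pairs), 16, n_sets), dtype=np.int32)
    done = 0
    while done < n_sets:
        m = min(chunk_size, n_sets - done)
        letters = [
            np.searchsorted(cums[j], rng.random((m, set_size)), side="right")
            for j in range(length)
        ]
        offsets = (np.arange(m) * 16)[:, None]
        for p, (i, j) in enumerate(pairs):
            idx = offsets + letters[i] * 4 + letters[j]
            out[p, :, done : done + m] = (
                np.bincount(idx.ravel(), minlength=m * 16).reshape(m, 16).T
            )
        done += m
    return out


def pair_dependence_test(
    alignment: SiteAlignment,
    n_sets: int = 100_000,
    rng: np.random.Generator | None = None,
    alphas=DEFAULT_ALPHAS,
) -> pd.DataFrame:
    """Monte Carlo interdependency test over all position and letter pairs.

    Returns one row per hypothesis (240 for 6 bp sites) with observed and
    expected joint counts, the add-one Monte Carlo p-values and significance
    flags (on the two-tailed p) at each alpha level.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if n_sets < 1000:
        warnings.warn(
            f"n_sets={n_sets} cannot resolve p-values below {1 / (n_sets + 1):.2g}; "
            "the 0.001 level may be unreachable",
            stacklevel=2,
        )
    n = len(alignment)
    length = alignment.site_length
    ppm = position_probability_matrix(alignment)
    observed = observed_pair_counts(alignment)  # (n_pairs, 16)
    null_counts = simulate_null_counts(ppm, n_sets, n, rng)

    obs = observed[:, :, None]
    p_upper = (1 + (null_counts >= obs).sum(axis=2)) / (n_sets + 1)
    p_lower = (1 + (null_counts <= obs).sum(axis=2)) / (n_sets + 1)
    p_two = np.minimum(1.0, 2 * np.minimum(p_upper, p_lower))

    pairs = list(combinations(range(length), 2))
    rows = []
    for p, (i, j) in enumerate(pairs):
        for ai in range(4):
            for bj in range(4):
                cell = ai * 4 + bj
                expected = expected_pair_count(n, ppm.values[ai, i], ppm.values[bj, j])
                row = dict(
                    position_i=i + 1,
                    position_j=j + 1,
                    nt_i=ALPHABET[ai],
                    nt_j=ALPHABET[bj],
                    observed=int(observed[p, cell]),
                    expected=float(expected),
                    p_upper=float(p_upper[p, cell]),
                    p_lower=float(p_lower[p, cell]),
                    p_two_tailed=float(p_two[p, cell]),
                )
                for alpha in alphas:
                    row[f"sig_{alpha:g}"] = bool(p_two[p, cell] <= alpha)
                rows.append(row)
    return pd.DataFrame(rows)
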