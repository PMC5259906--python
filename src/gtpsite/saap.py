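"""Significant amino-acid pairs (SAAPs).

An ordered adjacent residue pair (dipeptide) is *significant* when its
presence in classification windows is enriched in the positive
(binding) class under a one-sided hypergeometric test.  For a pair seen
in ``n`` of ``N`` window fragments, ``x`` of them among the ``M``
positive fragments, the p-value is the upper tail

    P(X >= x),   X ~ Hypergeometric(N, M, n),

i.e. the probability of drawing at least ``x`` positives when ``n``
fragments are sampled without replacement from ``N`` of which ``M`` are
positive.  Pairs with p-value below ``alpha`` (default 0.030212) are
kept, most significant first, capped at ``max_k`` (default 160), and
appended to the window feature vector as binary presence features.

Selection is fully deterministic and must be fitted on training folds
only; it is part of the model, not of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from scipy.stats import hypergeom

from .io_formats import PSSM_COLUMNS, ParameterError
from .encoding import WindowFragment

_STANDARD = set(PSSM_COLUMNS)

#: Significance threshold for pair selection.
DEFAULT_ALPHA = 0.030212
#: Cap on the number of selected pairs.
DEFAULT_MAX_K = 160


@dataclass
class PairStatistic:
    """Contingency counts and p-value for one ordered residue pair."""

    pair: str
    N: int
    M: int
    n: int
    x: int
    pvalue: float | None = None

    def validate(self) -> None:
        ok = (
            0 <= self.x <= min(self.n, self.M)
            and self.n <= self.N
            and self.M <= self.N
        )
        if not ok:
            raise ParameterError(
                f"inconsistent contingency counts for {self.pair}: "
                f"N={self.N} M={self.M} n={self.n} x={self.x}"
            )


@dataclass
class SAAPSelection:
    """An ordered list of selected pairs with its selection settings."""

    pairs: List[str] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA
    max_k: int = DEFAULT_MAX_K

    def __len__(self) -> int:
        return len(self.pairs)


def enumerate_pairs(fragment: WindowFragment) -> Set[str]:
    """Set of adjacent ordered pairs in a fragment (presence, not count).

    Pairs touching the padding symbol or an ambiguity code are excluded.
    """
    res = fragment.residues
    return {
        res[i : i + 2]
        for i in range(len(res) - 1)
        if res[i] in _STANDARD and res[i + 1] in _STANDARD
    }


def pair_contingency(fragments: Sequence[WindowFragment]) -> List[PairStatistic]:
    """Presence counts for every pair occurring in at least one fragment.

    Requires both classes to be present (the statistic is undefined
    otherwise).  p-values are left unset.
    """
    N = len(fragments)
    M = sum(f.label for f in fragments)
    if M == 0 or M == N:
        raise ParameterError(
            "pair statistics need both positive and negative fragments"
        )
    n_count: Dict[str, int] = {}
    x_count: Dict[str, int] = {}
    for frag in fragments:
        for pair in enumerate_pairs(frag):
            n_count[pair] = n_count.get(pair, 0) + 1
            if frag.label:
                x_count[pair] = x_count.get(pair, 0) + 1
    return [
        PairStatistic(pair=p, N=N, M=M, n=n_count[p], x=x_count.get(p, 0))
        for p in sorted(n_count)
    ]


def hypergeom_pvalue(N: int, M: int, n: int, x: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= x)``.

    ``X`` counts positives among ``n`` fragments drawn without
    replacement from ``N`` fragments of which ``M`` are positive.
    Returns exactly 1.0 when ``x == 0`` (the whole support).
    """
    PairStatistic("", N, M, n, x).validate()
    if x == 0:
        return 1.0
    # survival function at x-1 == P(X >= x); scipy evaluates the tail
    # stably in log space internally.
    return float(hypergeom.sf(x - 1, N, M, n))


def compute_pvalues(stats: Iterable[PairStatistic]) -> List[PairStatistic]:
    """Fill the p-value of every statistic in place; returns the list."""
    stats = list(stats)
    for s in stats:
        s.pvalue = hypergeom_pvalue(s.N, s.M, s.n, s.x)
    return stats


def select_saaps(
    stats: Sequence[PairStatistic],
    alpha: float = DEFAULT_ALPHA,
    max_k: int = DEFAULT_MAX_K,
) -> SAAPSelection:
    """Pairs with p-value below ``alpha``, most significant first.

    Ties are broken lexicographically; the list is truncated to
    ``max_k``.  An empty selection is valid.
    """
    scored: List[Tuple[float, str]] = []
    for s in stats:
        if s.pvalue is None:
            raise ParameterError(f"p-value not computed for pair {s.pair}")
        if s.pvalue < alpha:
            scored.append((s.pvalue, s.pair))
    scored.sort()
    return SAAPSelection(
        pairs=[pair for _, pair in scored[:max_k]], alpha=alpha, max_k=max_k
    )


def fit_selection(
    fragments: Sequence[WindowFragment],
    alpha: float = DEFAULT_ALPHA,
    max_k: int = DEFAULT_MAX_K,
) -> Tuple[SAAPSelection, List[PairStatistic]]:
    """Count, test and select in one step; returns (selection, all stats)."""
    stats = compute_pvalues(pair_contingency(fragments))
    return select_saaps(stats, alpha=alpha, max_k=max_k), stats


def augment(
    vector: np.ndarray, fragment: WindowFragment, selection: SAAPSelection
) -> np.ndarray:
    """Append binary presence features for the selected pairs.

    New length = old + ``len(selection)``; an empty selection returns the
    vector unchanged.
    """
    if not selection.pairs:
        return vector
    present = enumerate_pairs(fragment)
    extra = np.array(
        [1.0 if p in present else 0.0 for p in selection.pairs], dtype=float
    )
    return np.concatenate([vector, extra])
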