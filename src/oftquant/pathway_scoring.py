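"""Directional pathway-activation scoring over differential-abundance results.

Given user-supplied pathway definitions (member proteins annotated with a
literature regulation direction: +1 if increased abundance is consistent
with pathway activation, -1 if with inhibition, 0 unknown), each pathway is
scored by

* an overlap p-value — one-sided Fisher's exact (hypergeometric tail)
  probability of observing at least the seen number of dysregulated
  members, given the dysregulated set size and the detected-protein
  universe; regulation direction plays no role here;
* an activation z-score — z = (N+ - N-) / sqrt(N), where N+ counts
  dysregulated members whose fold-change sign matches their activation
  direction, N- those that oppose it, and N = N+ + N-.  Members with
  unknown direction are excluded from N (configurable).

A pathway is called *activated* when z >= +2 and p < 0.05, *inhibited*
when z <= -2 and p < 0.05, else *indeterminate*.  No multiple-testing
correction is applied across pathways; the p < 0.05 screen is used as-is.

Candidate proteins are pre-filtered for measurement quality: proteins with
two or more channels below an intensity floor (default 4,000), proteins
quantified by a single peptide, and proteins without a nominally
significant abundance change (p >= 0.1) are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .proteomics_quant import CHANNELS

INTENSITY_FLOOR = 4000.0
MIN_PEPTIDES = 2
INPUT_P_MAX = 0.1
Z_CALL_THRESHOLD = 2.0
PATHWAY_P_MAX = 0.05


@dataclass(frozen=True)
class PathwayDefinition:
    """A pathway: member proteins with literature activation direction."""

    pathway_id: str
    members: dict[str, int]  # protein_id -> direction in {-1, 0, +1}

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id}: no members")
        bad = {d for d in self.members.values() if d not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"pathway {self.pathway_id}: directions {bad} invalid")


@dataclass(frozen=True)
class DirectionCounts:
    """Concordance tally of dysregulated pathway members.

    ``n_unknown`` members lack a literature direction; they are excluded
    from N by default and only enter the z denominator when
    ``count_unknown_in_n`` is set (an alternative reading of "detected
    dysregulated proteins in the pathway").
    """

    n_plus: int
    n_minus: int
    n_unknown: int = 0
    count_unknown_in_n: bool = False

    @property
    def n(self) -> int:
        base = self.n_plus + self.n_minus
        return base + self.n_unknown if self.count_unknown_in_n else base


@dataclass(frozen=True)
class PathwayResult:
    pathway_id: str
    p: float
    z: float | None  # None when no direction-annotated member is dysregulated
    ratio: float  # dysregulated members / pathway size
    n_plus: int
    n_minus: int
    call: str  # activated | inhibited | indeterminate


def analysis_input_filter(
    table: pd.DataFrame,
    results: pd.DataFrame,
    intensity_floor: float = INTENSITY_FLOOR,
    min_peptides: int = MIN_PEPTIDES,
    p_max: float = INPUT_P_MAX,
) -> pd.DataFrame:
    """Select well-measured, nominally changed proteins for pathway input.

    Keeps proteins with fewer than two channels below ``intensity_floor``,
    at least ``min_peptides`` distinct peptides, and differential p below
    ``p_max``.  Returns the joined rows (channel sums, peptide_count, fold,
    p, q) for the retained proteins.
    """
    joined = table.join(results, how="inner")
    low = (joined[CHANNELS] < intensity_floor).sum(axis=1)
    keep = (low < 2) & (joined["peptide_count"] >= min_peptides) & (joined["p"] < p_max)
    return joined.loc[keep]


def fisher_overlap(k: int, K: int, n: int, M: int) -> float:
    """One-sided enrichment p-value P(X >= k), X ~ Hypergeom(M, K, n).

    ``k`` dysregulated members seen in a pathway of detected size ``K``,
    with ``n`` dysregulated proteins in a universe of ``M`` detected.
    """
    if not (0 <= k <= min(K, n) <= M and K <= M):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, M={M}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def pathway_z(counts: DirectionCounts) -> float | None:
    """Activation z-score (N+ - N-)/sqrt(N); None when N = 0."""
    if counts.n == 0:
        return None
    return (counts.n_plus - counts.n_minus) / math.sqrt(counts.n)


def direction_counts(
    fold_signs: dict[str, int],
    definition: PathwayDefinition,
    include_unknown: bool = False,
) -> DirectionCounts:
    """Concordance counts between observed fold signs and member directions.

    ``fold_signs`` maps dysregulated protein -> sign of its fold change.
    A member is activation-consistent (N+) when sign x direction = +1 and
    inhibition-consistent (N-) when it is -1.  Direction-0 members are
    excluded from N unless ``include_unknown``, in which case they inflate
    the z denominator without contributing to the numerator.
    """
    n_plus = n_minus = n_unknown = 0
    for prot, direction in definition.members.items():
        s = fold_signs.get(prot)
        if s is None:
            continue
        prod = s * direction
        if prod > 0:
            n_plus += 1
        elif prod < 0:
            n_minus += 1
        else:
            n_unknown += 1
    return DirectionCounts(
        n_plus=n_plus,
        n_minus=n_minus,
        n_unknown=n_unknown,
        count_unknown_in_n=include_unknown,
    )


def score_pathways(
    fold_signs: dict[str, int],
    definitions: list[PathwayDefinition],
    universe: set[str],
    z_threshold: float = Z_CALL_THRESHOLD,
    p_threshold: float = PATHWAY_P_MAX,
) -> list[PathwayResult]:
    """Score every pathway and call activation/inhibition.

    ``fold_signs``: dysregulated protein -> +1/-1 fold-change sign (the
    pathway-input filtered set); ``universe``: all detected proteins the
    dysregulated set was drawn from.
    """
    dysreg = {p: s for p, s in fold_signs.items() if p in universe}
    n = len(dysreg)
    M = len(universe)
    out: list[PathwayResult] = []
    for d in definitions:
        detected_members = set(d.members) & universe
        K = len(detected_members)
        k = len(set(dysreg) & set(d.members))
        p = fisher_overlap(k, K, n, M) if K > 0 else 1.0
        counts = direction_counts(dysreg, d)
        z = pathway_z(counts)
        ratio = k / len(d.members)
        if z is not None and z >= z_threshold and p < p_threshold:
            call = "activated"
        elif z is not None and z <= -z_threshold and p < p_threshold:
            call = "inhibited"
        else:
            call = "indeterminate"
        out.append(
            PathwayResult(
                pathway_id=d.pathway_id,
                p=p,
                z=z,
                ratio=ratio,
                n_plus=counts.n_plus,
                n_minus=counts.n_minus,
                call=call,
            )
        )
    return out
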