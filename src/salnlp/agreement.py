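"""Inter-annotator agreement for set-valued sentence labels.

Krippendorff's alpha is computed in the coincidence-matrix formulation,
which accommodates any number of annotators and missing annotations, with
a pluggable distance between values.  For set-valued limitation labels the
distance is MASI (Measuring Agreement on Set-valued Items): one minus the
product of the Jaccard overlap J and a monotonicity weight M that grades
how one set relates to the other (identical 1, strict sub/superset 2/3,
crossing overlap 1/3, disjoint 0).

Pairwise token-level agreement uses Cohen's kappa over categorical labels
including an outside label "O".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "masi_distance",
    "nominal_distance",
    "UnitLabelMatrix",
    "krippendorff_alpha",
    "cohens_kappa",
    "pairwise_kappa_matrix",
    "AgreementError",
]


class AgreementError(ValueError):
    pass


def masi_distance(a: frozenset | set, b: frozenset | set) -> float:
    """MASI distance between two label sets, in [0, 1].

    Two empty sets are identical (distance 0); an empty set is disjoint
    from any non-empty set (distance 1).
    """
    a, b = frozenset(a), frozenset(b)
    if not a and not b:
        return 0.0
    inter = a & b
    union = a | b
    if not inter:
        return 1.0
    jaccard = len(inter) / len(union)
    if a == b:
        mono = 1.0
    elif a <= b or b <= a:
        mono = 2.0 / 3.0
    else:
        mono = 1.0 / 3.0
    return 1.0 - jaccard * mono


def nominal_distance(a: Hashable, b: Hashable) -> float:
    return 0.0 if a == b else 1.0


@dataclass
class UnitLabelMatrix:
    """Units x annotators matrix of label values, with missing cells.

    ``cells`` maps ``(unit_id, annotator_id)`` to a value (typically a
    frozenset of category names).  Units with fewer than two non-missing
    cells carry no coincidence information and are skipped.
    """

    units: list[Hashable]
    annotators: list[str]
    cells: dict[tuple[Hashable, str], Hashable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.annotators) < 2:
            raise AgreementError("need at least 2 annotators")

    def values_for_unit(self, unit: Hashable) -> list:
        return [
            self.cells[(unit, a)] for a in self.annotators if (unit, a) in self.cells
        ]


def krippendorff_alpha(
    matrix: UnitLabelMatrix,
    distance: Callable = masi_distance,
    *,
    square_distance: bool = False,
) -> float:
    """Krippendorff's alpha with an arbitrary distance.

    alpha = 1 - Do/De with observed disagreement pooled over pairable
    values within units and expected disagreement from the pooled value
    marginals.  The supplied distance is used directly as the delta^2 term
    (set ``square_distance=True`` to square it instead).
    """

    def delta(x, y) -> float:
        d = distance(x, y)
        return d * d if square_distance else d

    pairable: list[list] = []
    for unit in matrix.units:
        vals = matrix.values_for_unit(unit)
        if len(vals) >= 2:
            pairable.append(vals)
    if not pairable:
        raise AgreementError("no unit has two or more annotations; alpha undefined")

    n_total = sum(len(vals) for vals in pairable)
    # observed disagreement: ordered within-unit pairs, weighted 1/(m_u - 1)
    d_obs = 0.0
    for vals in pairable:
        m = len(vals)
        unit_sum = sum(2.0 * delta(x, y) for x, y in combinations(vals, 2))
        d_obs += unit_sum / (m - 1)
    d_obs /= n_total

    # expected disagreement from pooled marginals (ordered pairs)
    marginal = Counter(v for vals in pairable for v in vals)
    values = list(marginal)
    d_exp = 0.0
    for i, x in enumerate(values):
        for y in values[i + 1:]:
            d_exp += 2.0 * marginal[x] * marginal[y] * delta(x, y)
    d_exp /= n_total * (n_total - 1)

    if d_exp == 0.0:
        if d_obs == 0.0:
            return 1.0
        raise AgreementError(
            "expected disagreement is zero but observed disagreement is not"
        )
    return 1.0 - d_obs / d_exp


def cohens_kappa(a: Sequence[Hashable], b: Sequence[Hashable]) -> float:
    """Cohen's kappa between two aligned categorical labelings.

    kappa = (po - pe) / (1 - pe) with pe from the marginal products.  When
    both annotators produce a single identical label everywhere (pe = 1),
    agreement is perfect by convention and 1.0 is returned.
    """
    if len(a) != len(b):
        raise AgreementError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise AgreementError("empty sequences")
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    ca, cb = Counter(a), Counter(b)
    pe = sum(ca[k] * cb.get(k, 0) for k in ca) / (n * n)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def pairwise_kappa_matrix(
    labelings: Mapping[str, Sequence[Hashable]]
) -> pd.DataFrame:
    """Full pairwise Cohen's kappa matrix over named annotators."""
    names = list(labelings)
    mat = np.full((len(names), len(names)), np.nan)
    for i, ni in enumerate(names):
        mat[i, i] = 1.0
        for j in range(i + 1, len(names)):
            k = cohens_kappa(labelings[ni], labelings[names[j]])
            mat[i, j] = mat[j, i] = k
    return pd.DataFrame(mat, index=names, columns=names)
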