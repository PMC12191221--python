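"""Inter-rater reliability of LN-RADS categories.

Two readers' category vectors are compared with unweighted Cohen's
kappa over the 6-category contingency table: kappa = (p_o - p_e)/(1 - p_e)
with observed agreement p_o and chance agreement p_e from the marginal
products. The standard error is the large-sample (Fleiss-Cohen-Everitt)
expression, giving a Wald 95% interval clipped to [-1, 1]. Kappa values
are mapped onto the conventional interpretation bands (slight, fair,
moderate, substantial, almost perfect).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "AgreementResult",
    "cohens_kappa",
    "interpret_kappa",
    "pairwise_agreement",
]


@dataclass(frozen=True)
class AgreementResult:
    kappa: Optional[float]
    se: Optional[float]
    ci: Optional[tuple[float, float]]
    percent_agreement: float
    band: Optional[str]
    n: int
    #: set when kappa is undefined (degenerate marginals, p_e = 1)
    undefined_reason: Optional[str] = None


def _contingency(a: Sequence, b: Sequence) -> tuple[np.ndarray, list]:
    labels = sorted(set(a) | set(b), key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)), dtype=float)
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    return table, labels


def cohens_kappa(a: Sequence, b: Sequence, level: float = 0.95) -> AgreementResult:
    """Unweighted Cohen's kappa between two rating vectors.

    Works for any hashable labels (kappa is invariant under relabelling);
    in this package the labels are LN-RADS categories.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)} ratings")
    n = len(a)
    if n < 2:
        raise ValueError("kappa requires at least two rated items")
    table, _ = _contingency(a, b)
    p = table / n
    p_row = p.sum(axis=1)
    p_col = p.sum(axis=0)
    # form the agreement terms from counts so that e.g. perfect agreement
    # gives p_o = 1.0 exactly
    p_o = float(np.trace(table)) / n
    p_e = float(table.sum(axis=1) @ table.sum(axis=0)) / (n * n)
    if 1.0 - p_e < 1e-12:
        return AgreementResult(
            kappa=None,
            se=None,
            ci=None,
            percent_agreement=p_o,
            band=None,
            n=n,
            undefined_reason="degenerate marginals: chance agreement equals 1",
        )
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Large-sample variance (Fleiss, Cohen & Everitt 1969).
    diag = np.diag(p)
    term1 = float(
        np.sum(diag * ((1.0 - p_e) - (p_row + p_col) * (1.0 - p_o)) ** 2)
    )
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    # (p_.i + p_j.)^2 for cell (i, j): column marginal of i plus row marginal of j
    grid = (p_col[:, np.newaxis] + p_row[np.newaxis, :]) ** 2
    term2 = float((1.0 - p_o) ** 2 * np.sum(off * grid))
    term3 = (p_o * p_e - 2.0 * p_e + p_o) ** 2
    var = (term1 + term2 - term3) / (n * (1.0 - p_e) ** 4)
    se = math.sqrt(max(var, 0.0))
    z = norm.ppf(0.5 + level / 2.0)
    ci = (max(kappa - z * se, -1.0), min(kappa + z * se, 1.0))
    return AgreementResult(
        kappa=kappa,
        se=se,
        ci=ci,
        percent_agreement=p_o,
        band=interpret_kappa(kappa),
        n=n,
    )


def interpret_kappa(kappa: float) -> str:
    """Map kappa onto the conventional agreement bands.

    The printed band edges (0.01-0.20, 0.21-0.40, 0.41-0.60, 0.61-0.80,
    0.81-1.00) are treated as inclusive at both ends; continuous values
    falling between printed edges take the band below the next edge, and
    kappa <= 0 means no agreement beyond chance.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa <= 0.0:
        return "none"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost_perfect"


def pairwise_agreement(
    ratings_by_reader: Mapping[str, Sequence], level: float = 0.95
) -> dict[tuple[str, str], AgreementResult]:
    """Cohen's kappa for every unordered reader pair."""
    readers = list(ratings_by_reader)
    if len(readers) < 2:
        raise ValueError("pairwise agreement requires at least two readers")
    lengths = {len(v) for v in ratings_by_reader.values()}
    if len(lengths) != 1:
        raise ValueError("all rating vectors must have equal length")
    return {
        (r1, r2): cohens_kappa(ratings_by_reader[r1], ratings_by_reader[r2], level=level)
        for r1, r2 in itertools.combinations(readers, 2)
    }
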