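"""Inter-rater agreement: Cohen's kappa.

kappa = (po - pe) / (1 - pe), where po is the observed fraction of
items the two coders label identically and pe the agreement expected by
chance from the coders' label marginals.  Binary and multi-class labels
are supported, unweighted.  ``expected_agreement_from`` inverts the
formula: given a published (po, kappa) pair it recovers the implied pe,
so reported agreement figures can be checked for internal consistency
even when the underlying confusion table is unpublished.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

__all__ = [
    "AgreementResult",
    "cohen_kappa",
    "kappa_from_confusion",
    "expected_agreement_from",
]


@dataclass(frozen=True)
class AgreementResult:
    """Observed/chance agreement, kappa, and the label confusion table.

    ``confusion[i][j]`` counts items coder A labeled ``labels[i]`` and
    coder B labeled ``labels[j]``.
    """

    n: int
    po: float
    pe: float
    kappa: float
    labels: tuple[Hashable, ...]
    confusion: tuple[tuple[int, ...], ...]


def _from_confusion(table: np.ndarray, labels: tuple[Hashable, ...]) -> AgreementResult:
    n = int(table.sum())
    if n < 1:
        raise ValueError("need at least one item")
    po = float(np.trace(table)) / n
    marg_a = table.sum(axis=1) / n
    marg_b = table.sum(axis=0) / n
    pe = float(marg_a @ marg_b)
    if pe < 1.0:
        kappa = (po - pe) / (1.0 - pe)
    else:  # degenerate: both coders constant -> po == pe == 1
        kappa = 1.0
    return AgreementResult(
        n=n,
        po=po,
        pe=pe,
        kappa=float(kappa),
        labels=labels,
        confusion=tuple(tuple(int(x) for x in row) for row in table),
    )


def cohen_kappa(labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]) -> AgreementResult:
    """Cohen's kappa for two equal-length label sequences."""
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label sequences differ in length ({len(labels_a)} vs {len(labels_b)})"
        )
    if not labels_a:
        raise ValueError("need at least one item")
    labels = tuple(sorted(set(labels_a) | set(labels_b), key=repr))
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        table[index[a], index[b]] += 1
    return _from_confusion(table, labels)


def kappa_from_confusion(table, labels: Sequence[Hashable] | None = None) -> AgreementResult:
    """Cohen's kappa straight from a square confusion table."""
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("confusion table must be square")
    if labels is None:
        labels = tuple(range(arr.shape[0]))
    return _from_confusion(arr, tuple(labels))


def expected_agreement_from(po: float, kappa: float) -> float:
    """Chance agreement pe implied by a (po, kappa) pair.

    Inverts kappa = (po - pe)/(1 - pe):  pe = (po - kappa)/(1 - kappa).
    Round-trips through the forward formula exactly (up to float
    arithmetic) whenever kappa < 1.
    """
    if kappa >= 1.0:
        raise ValueError("pe is undefined for kappa >= 1")
    return (po - kappa) / (1.0 - kappa)
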