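"""Alignment-quality metrics against a reference alignment.

Sensitivity is the number of correctly aligned site pairs divided by the
number of aligned pairs in the reference; precision divides by the aligned
pairs in the test alignment.  Zero denominators yield an undefined metric
(None), never a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Set, Tuple

from .profiles import PairwiseAlignment


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class QualityScores:
    sensitivity: Optional[float]
    precision: Optional[float]
    n_correct: int
    n_ref_pairs: int
    n_test_pairs: int


def aligned_site_pairs(alignment: PairwiseAlignment) -> Set[Tuple[int, int]]:
    """Columns where both sequences have residues."""
    return {(i, j) for i, j in alignment.columns if i is not None and j is not None}


def alignment_quality(
    test: PairwiseAlignment, ref: PairwiseAlignment
) -> QualityScores:
    if (test.length_a, test.length_b) != (ref.length_a, ref.length_b):
        raise MetricsError(
            f"alignments relate different profiles: "
            f"({test.length_a}, {test.length_b}) vs ({ref.length_a}, {ref.length_b})"
        )
    test_pairs = aligned_site_pairs(test)
    ref_pairs = aligned_site_pairs(ref)
    n_correct = len(test_pairs & ref_pairs)
    sens = n_correct / len(ref_pairs) if ref_pairs else None
    prec = n_correct / len(test_pairs) if test_pairs else None
    return QualityScores(
        sensitivity=sens,
        precision=prec,
        n_correct=n_correct,
        n_ref_pairs=len(ref_pairs),
        n_test_pairs=len(test_pairs),
    )


@dataclass(frozen=True)
class DatasetQuality:
    mean_sensitivity: Optional[float]
    mean_precision: Optional[float]
    n_pairs: int
    n_undefined_sensitivity: int
    n_undefined_precision: int


def dataset_quality(
    pairs: Iterable[Tuple[PairwiseAlignment, PairwiseAlignment]],
    micro: bool = False,
) -> DatasetQuality:
    """Aggregate quality over (test, reference) pairs.

    Macro-average by default (mean of per-pair scores, undefined excluded);
    ``micro=True`` pools correct/total counts over all pairs instead.
    """
    scores: List[QualityScores] = [alignment_quality(t, r) for t, r in pairs]
    if not scores:
        raise MetricsError("empty dataset")
    if micro:
        n_corr = sum(s.n_correct for s in scores)
        n_ref = sum(s.n_ref_pairs for s in scores)
        n_test = sum(s.n_test_pairs for s in scores)
        return DatasetQuality(
            mean_sensitivity=n_corr / n_ref if n_ref else None,
            mean_precision=n_corr / n_test if n_test else None,
            n_pairs=len(scores),
            n_undefined_sensitivity=sum(1 for s in scores if s.sensitivity is None),
            n_undefined_precision=sum(1 for s in scores if s.precision is None),
        )
    sens = [s.sensitivity for s in scores if s.sensitivity is not None]
    prec = [s.precision for s in scores if s.precision is not None]
    return DatasetQuality(
        mean_sensitivity=sum(sens) / len(sens) if sens else None,
        mean_precision=sum(prec) / len(prec) if prec else None,
        n_pairs=len(scores),
        n_undefined_sensitivity=len(scores) - len(sens),
        n_undefined_precision=len(scores) - len(prec),
    )
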