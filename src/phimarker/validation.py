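"""Held-out validation of discovered markers on newer panel releases.

For every drug shared between a training release and a test release, the
test set is the cell lines screened against the drug only in the newer
release.  A per-drug sensitivity threshold — the median of *all* training
logIC50 values for the drug — splits test cells into sensitive
(logIC50 < threshold) and resistant (logIC50 >= threshold).  Each
significant marker then predicts test-set sensitivity (or resistance,
per its training direction, which is frozen) from mutation status alone,
and the prediction is scored with the Matthews correlation coefficient.
MCC > 0 is the better-than-random criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import (
    SENSITIVITY,
    AssociationResult,
    ContingencyTable,
    phi_coefficient,
)
from .discovery import DiscoveryReport
from .exceptions import NoPredictionError, UndefinedStatisticError
from .io import MutationPanel, ResponsePanel

logger = logging.getLogger(__name__)


@dataclass
class ValidationResult:
    """Test-set performance of one marker."""

    drug: str
    feature: str
    drug_threshold: float  # median of all training logIC50 for the drug
    n_test: int
    table: ContingencyTable
    mcc_test: float
    degenerate: bool = False  # a zero marginal forced MCC := 0

    def to_row(self) -> dict:
        t = self.table
        return {
            "drug": self.drug,
            "feature": self.feature,
            "drug_threshold": self.drug_threshold,
            "nTest": self.n_test,
            "TP": t.tp, "FN": t.fn, "FP": t.fp, "TN": t.tn,
            "MCC_tst": self.mcc_test,
            "degenerate": self.degenerate,
        }


def split_by_release(
    train: ResponsePanel, test: ResponsePanel
) -> dict[str, list[str]]:
    """Per-drug held-out cell sets.

    For each drug present in both panels: the cells with a response in the
    test panel and none in the training panel.  Drugs absent from either
    panel are dropped (logged).  Raises if no drug is shared.
    """
    common = [d for d in train.drugs if d in set(test.drugs)]
    if not common:
        raise ValueError("no drugs in common between training and test panels")
    for d in train.drugs:
        if d not in set(test.drugs):
            logger.info("drug %r absent from the test release; dropped", d)
    out: dict[str, list[str]] = {}
    for drug in common:
        trained = set(train.responses(drug).index)
        out[drug] = [c for c in test.responses(drug).index if c not in trained]
    return out


def drug_sensitivity_threshold(train_responses: pd.Series) -> float:
    """Median of all training logIC50 values for one drug."""
    values = np.asarray(train_responses, dtype=float)
    if values.size == 0:
        raise ValueError("drug has no training responses")
    return float(np.median(values))


def validate_marker(
    assoc: AssociationResult,
    train_responses: pd.Series,
    test_responses: np.ndarray,
    test_flags: np.ndarray,
) -> ValidationResult:
    """Score one marker on held-out cells.

    The drug threshold comes exclusively from training responses; the
    direction is frozen from training.  Observed positives are the
    sensitive test cells for sensitivity markers and the resistant ones for
    resistance markers (ties at the threshold count as resistant).  The
    prediction is the mutation flag.  A zero marginal (no prediction
    possible in one direction) scores as MCC = 0 with a degenerate flag;
    a test set without any mutated cell yields no prediction at all and
    raises :class:`NoPredictionError`.
    """
    y = np.asarray(test_responses, dtype=float)
    mt = np.asarray(test_flags, dtype=bool)
    if y.shape != mt.shape or y.ndim != 1:
        raise ValueError("test responses and flags must be parallel 1-d vectors")
    if y.size == 0:
        raise NoPredictionError(
            f"{assoc.drug}/{assoc.feature}: empty test set"
        )
    if not mt.any():
        raise NoPredictionError(
            f"{assoc.drug}/{assoc.feature}: no mutated cell lines in the test set"
        )
    threshold = drug_sensitivity_threshold(train_responses)
    sensitive = y < threshold
    if assoc.threshold.direction == SENSITIVITY:
        positive = sensitive
    else:
        positive = ~sensitive
    table = ContingencyTable(
        tp=int(np.sum(mt & positive)),
        fn=int(np.sum(~mt & positive)),
        fp=int(np.sum(mt & ~positive)),
        tn=int(np.sum(~mt & ~positive)),
    )
    try:
        mcc = phi_coefficient(table)
        degenerate = False
    except UndefinedStatisticError:
        mcc = 0.0  # no prediction in one margin scores as random
        degenerate = True
    return ValidationResult(
        drug=assoc.drug,
        feature=assoc.feature,
        drug_threshold=threshold,
        n_test=int(y.size),
        table=table,
        mcc_test=mcc,
        degenerate=degenerate,
    )


@dataclass
class ValidationReport:
    """Validation outcomes for a set of markers plus the non-evaluable ones."""

    results: list[ValidationResult]
    non_evaluable: list[tuple[str, str, str]]  # (drug, feature, reason)

    def mcc_values(self) -> np.ndarray:
        return np.array([r.mcc_test for r in self.results], dtype=float)

    def fraction_positive(self) -> float:
        """count(MCC > 0) / count(evaluable) — the better-than-random rate."""
        mcc = self.mcc_values()
        if mcc.size == 0:
            return float("nan")
        return float(np.mean(mcc > 0.0))

    def summary(self) -> str:
        mcc = self.mcc_values()
        lines = [
            "Held-out marker validation",
            "=" * 40,
            f"Evaluable markers:     {len(self.results)}",
            f"Non-evaluable markers: {len(self.non_evaluable)}",
        ]
        if mcc.size:
            lines += [
                f"Median test MCC:       {np.median(mcc):.3f}",
                f"Fraction MCC > 0:      {self.fraction_positive():.3f}",
            ]
        return "\n".join(lines)


def validate_report(
    report: DiscoveryReport,
    train_responses: ResponsePanel,
    test_responses: ResponsePanel,
    mutations: MutationPanel,
    pairs: set[tuple[str, str]] | None = None,
) -> ValidationReport:
    """Validate markers from a discovery report on a newer release.

    By default every chi2-significant association is validated; *pairs*
    restricts to an explicit call set (e.g. the consensus set).  Train/test
    disjointness per drug is asserted on every run.
    """
    test_sets = split_by_release(train_responses, test_responses)
    chosen = (
        report.significant() if pairs is None
        else [r for r in report.results if (r.drug, r.feature) in pairs]
    )
    results: list[ValidationResult] = []
    non_evaluable: list[tuple[str, str, str]] = []
    mut_frame = mutations.frame
    for assoc in chosen:
        if assoc.drug not in test_sets:
            non_evaluable.append(
                (assoc.drug, assoc.feature, "drug absent from test release")
            )
            continue
        cells = test_sets[assoc.drug]
        trained = set(train_responses.responses(assoc.drug).index)
        assert not trained.intersection(cells), "train/test leak"
        cells = [c for c in cells if c in mut_frame.index]
        calls = mut_frame.loc[cells, assoc.feature] if cells else pd.Series(dtype=float)
        known = calls.notna()
        y = test_responses.responses(assoc.drug).loc[calls.index[known]].to_numpy()
        flags = (calls[known] == 1.0).to_numpy()
        try:
            results.append(
                validate_marker(
                    assoc,
                    train_responses.responses(assoc.drug),
                    y,
                    flags,
                )
            )
        except NoPredictionError as err:
            non_evaluable.append((assoc.drug, assoc.feature, str(err)))
    return ValidationReport(results=results, non_evaluable=non_evaluable)


def benchmark_methods(
    call_sets: dict[str, set[tuple[str, str]]],
    report: DiscoveryReport,
    train_responses: ResponsePanel,
    test_responses: ResponsePanel,
    mutations: MutationPanel,
) -> pd.DataFrame:
    """Validate several call sets on identical splits and summarise each.

    Returns one row per method: number of markers, evaluable count, median
    test MCC and the fraction with MCC > 0.  Empty call sets produce an
    all-NaN row with a logged warning.  Per-marker rows are preserved on the
    returned frame's ``attrs["per_marker"]``.
    """
    rows = []
    per_marker: dict[str, ValidationReport] = {}
    for method, pairs in call_sets.items():
        if not pairs:
            logger.warning("call set %r is empty; nothing to validate", method)
            rows.append({"method": method, "n_markers": 0, "n_evaluable": 0,
                         "median_mcc": float("nan"),
                         "fraction_mcc_positive": float("nan")})
            continue
        vrep = validate_report(report, train_responses, test_responses,
                               mutations, pairs=pairs)
        per_marker[method] = vrep
        mcc = vrep.mcc_values()
        rows.append({
            "method": method,
            "n_markers": len(pairs),
            "n_evaluable": len(vrep.results),
            "median_mcc": float(np.median(mcc)) if mcc.size else float("nan"),
            "fraction_mcc_positive": vrep.fraction_positive(),
        })
    frame = pd.DataFrame(rows)
    frame.attrs["per_marker"] = per_marker
    return frame
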