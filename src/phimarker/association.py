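"""Mutation-dependent thresholding, the phi coefficient, the 2x2
chi-squared test and Benjamini-Hochberg FDR control.

One drug-gene association is scored in four steps:

1. split the drug's logIC50 values into mutant (MT) and wild-type (WT)
   groups and set the threshold at the midpoint of the two group medians,
   ``thres = (medMT + medWT) / 2``;
2. call the direction: mutants more sensitive (``medMT < medWT``) or more
   resistant (``medMT >= medWT``); observed positives are the cells on the
   mutant side of the threshold (strictly below it for sensitivity markers,
   at or above it for resistance markers);
3. cross-classify cells by mutation status (the prediction) and threshold
   side (the observation) into a TP/FN/FP/TN contingency table and
   summarise discrimination with the phi coefficient (identical to the
   Matthews correlation coefficient);
4. test the table with Pearson's chi-squared statistic (one degree of
   freedom, no continuity correction, so the exact identity
   ``chi2 = n * phi**2`` holds) and control the panel-wide false discovery
   rate with Benjamini-Hochberg step-up.

Because the threshold always lies between the two group medians, at least
half of each group falls on its own side, so phi >= 0 whenever
``medMT != medWT`` and every marginal of the table is positive — phi is
always defined at this intra-association level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import UndefinedStatisticError

SENSITIVITY = "sensitivity"
RESISTANCE = "resistance"


@dataclass(frozen=True)
class AssociationData:
    """Paired responses and mutation flags for one drug-gene association."""

    responses: np.ndarray  # logIC50, log10 uM
    flags: np.ndarray      # 1 = mutated, 0 = wild-type

    def __post_init__(self):
        responses = np.asarray(self.responses, dtype=float)
        flags = np.asarray(self.flags, dtype=bool)
        object.__setattr__(self, "responses", responses)
        object.__setattr__(self, "flags", flags)
        if responses.shape != flags.shape or responses.ndim != 1:
            raise ValueError("responses and flags must be parallel 1-d vectors")
        if responses.size < 2:
            raise ValueError("an association needs at least two cell lines")
        if not np.all(np.isfinite(responses)):
            raise ValueError("responses must be finite")
        if flags.all() or not flags.any():
            raise ValueError(
                "association needs at least one mutated and one wild-type cell"
            )

    @property
    def n(self) -> int:
        return int(self.responses.size)

    @property
    def n_mutated(self) -> int:
        return int(self.flags.sum())


@dataclass(frozen=True)
class ThresholdResult:
    """Mutation-dependent logIC50 threshold and marker direction."""

    med_mt: float
    med_wt: float
    threshold: float
    direction: str  # SENSITIVITY or RESISTANCE

    @property
    def degenerate(self) -> bool:
        """Group medians tie exactly; the resistance branch was taken and
        phi >= 0 is no longer guaranteed."""
        return self.med_mt == self.med_wt


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-classification of cells: mutation status (prediction)
    against threshold side (observation)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def pp(self) -> int:
        """Predicted positives = mutated cells."""
        return self.tp + self.fp

    @property
    def pn(self) -> int:
        return self.fn + self.tn

    @property
    def op(self) -> int:
        """Observed positives (cells on the marker side of the threshold)."""
        return self.tp + self.fn

    @property
    def on(self) -> int:
        return self.fp + self.tn


def compute_threshold(data: AssociationData) -> ThresholdResult:
    """Midpoint-of-medians threshold and direction call.

    Even-sized groups use the midpoint-of-central-order-statistics median.
    A tie ``medMT == medWT`` falls to the resistance branch.
    """
    med_mt = float(np.median(data.responses[data.flags]))
    med_wt = float(np.median(data.responses[~data.flags]))
    threshold = (med_mt + med_wt) / 2.0
    direction = SENSITIVITY if med_mt < med_wt else RESISTANCE
    return ThresholdResult(med_mt, med_wt, threshold, direction)


def build_contingency(data: AssociationData, t: ThresholdResult) -> ContingencyTable:
    """Cross-classify cells against the threshold.

    Sensitivity markers: observed positive iff logIC50 < threshold.
    Resistance markers: observed positive iff logIC50 >= threshold.
    The prediction is the mutation flag.
    """
    if t.direction == SENSITIVITY:
        positive = data.responses < t.threshold
    else:
        positive = data.responses >= t.threshold
    mt = data.flags
    return ContingencyTable(
        tp=int(np.sum(mt & positive)),
        fn=int(np.sum(~mt & positive)),
        fp=int(np.sum(mt & ~positive)),
        tn=int(np.sum(~mt & ~positive)),
    )


def phi_coefficient(t: ContingencyTable) -> float:
    """phi / Matthews correlation coefficient of a 2x2 table.

    ``(TP*TN - FP*FN) / sqrt((TP+FN)(FN+TN)(TN+FP)(FP+TP))``; raises
    :class:`UndefinedStatisticError` if any marginal is zero.
    """
    op, pn, on, pp = t.op, t.pn, t.on, t.pp
    if min(op, pn, on, pp) == 0:
        raise UndefinedStatisticError(
            f"phi undefined: zero marginal in table "
            f"(TP={t.tp}, FN={t.fn}, FP={t.fp}, TN={t.tn})"
        )
    num = t.tp * t.tn - t.fp * t.fn
    den = math.sqrt(float(op) * float(pn) * float(on) * float(pp))
    return num / den


def chi2_statistic(t: ContingencyTable) -> float:
    """Pearson chi-squared statistic of a 2x2 table, no continuity
    correction, computed from the observed-vs-expected sum.

    Expected counts come from the margins, e.g. ``E(TP) = PP * OP / n``.
    Equals ``n * phi**2`` exactly (up to floating point).
    """
    n = t.n
    expected = {
        "tp": t.pp * t.op / n if n else 0.0,
        "fn": t.pn * t.op / n if n else 0.0,
        "fp": t.pp * t.on / n if n else 0.0,
        "tn": t.pn * t.on / n if n else 0.0,
    }
    if min(expected.values()) <= 0.0:
        raise UndefinedStatisticError(
            f"chi-squared undefined: zero expected count in table "
            f"(TP={t.tp}, FN={t.fn}, FP={t.fp}, TN={t.tn})"
        )
    observed = {"tp": t.tp, "fn": t.fn, "fp": t.fp, "tn": t.tn}
    return float(
        sum((observed[k] - expected[k]) ** 2 / expected[k] for k in observed)
    )


def chi2_pvalue(chi2: float) -> float:
    """Upper-tail p-value of the chi-squared distribution with df = 1.

    Uses the survival function, which stays accurate down to the smallest
    representable doubles (~1e-308), far beyond where ``1 - cdf`` underflows.
    """
    if not math.isfinite(chi2) or chi2 < 0.0:
        raise ValueError(f"chi-squared statistic must be finite and >= 0, got {chi2}")
    return float(stats.chi2.sf(chi2, df=1))


def bh_fdr(pvalues, q: float) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at FDR level *q*.

    Returns ``(mask, critical_p)`` where ``mask[i]`` is True iff
    ``pvalues[i]`` is declared significant and ``critical_p`` is the largest
    p-value passing the step-up bound (NaN when nothing is significant).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr needs at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError(f"FDR level q must lie in (0, 1), got {q}")
    m = p.size
    order = np.sort(p)
    bounds = q * np.arange(1, m + 1) / m
    passing = np.nonzero(order <= bounds)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool), float("nan")
    critical = float(order[passing[-1]])
    return p <= critical, critical


def phi_significance_cutoff(n: int, critical_p: float) -> float:
    """Smallest phi that is significant at *critical_p* given *n* cells.

    From the duality ``chi2 = n * phi**2``: any association on n cells with
    ``phi >= sqrt(chi2_crit / n)`` has ``p <= critical_p``, where
    ``chi2_crit`` is the df = 1 upper-tail quantile.  Scales as 1/sqrt(n).
    """
    if n < 2:
        raise ValueError("need at least two cells")
    if not (0.0 < critical_p < 1.0):
        raise ValueError("critical_p must lie in (0, 1)")
    chi2_crit = float(stats.chi2.isf(critical_p, df=1))
    return math.sqrt(chi2_crit / n)


@dataclass
class AssociationResult:
    """Everything measured for one drug-gene association on training data."""

    drug: str
    feature: str
    n: int
    n_mutated: int
    threshold: ThresholdResult
    table: ContingencyTable
    phi: float
    chi2: float
    p: float
    significant: bool = False
    p_external: float | None = None
    significant_external: bool | None = None
    consensus: bool | None = None

    @property
    def prevalence(self) -> float:
        """Mutant fraction among the drug's tested cells."""
        return self.n_mutated / self.n

    def to_row(self) -> dict:
        t, thr = self.table, self.threshold
        return {
            "drug": self.drug,
            "feature": self.feature,
            "nTrain": self.n,
            "prevalence": self.prevalence,
            "medMT": thr.med_mt,
            "medWT": thr.med_wt,
            "threshold": thr.threshold,
            "direction": thr.direction,
            "degenerate": thr.degenerate,
            "TP": t.tp, "FN": t.fn, "FP": t.fp, "TN": t.tn,
            "phi": self.phi,
            "chi2": self.chi2,
            "p_chi2": self.p,
            "significant_chi2": self.significant,
            "p_external": np.nan if self.p_external is None else self.p_external,
            "significant_external": self.significant_external,
            "consensus": self.consensus,
        }


def score_association(data: AssociationData, drug: str = "", feature: str = "") -> AssociationResult:
    """Run the full intra-association pipeline on one data set."""
    thr = compute_threshold(data)
    table = build_contingency(data, thr)
    phi = phi_coefficient(table)
    chi2 = chi2_statistic(table)
    return AssociationResult(
        drug=drug,
        feature=feature,
        n=data.n,
        n_mutated=data.n_mutated,
        threshold=thr,
        table=table,
        phi=phi,
        chi2=chi2,
        p=chi2_pvalue(chi2),
    )
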