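"""Panel-wide marker discovery.

:class:`MarkerDiscovery` is the model object: it is built from a response
panel and a mutation panel (or straight from a panel CSV) and its
:meth:`~MarkerDiscovery.fit` runs the intra-association pipeline over every
testable drug-feature pair, applies Benjamini-Hochberg FDR control once
over all scored associations, and returns a :class:`DiscoveryResults`
carrying the per-association estimates, the significance calls and a
summary table.  Consensus calls against an external p-value table and
held-out validation hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as gio
from .association import (
    AssociationData,
    AssociationResult,
    bh_fdr,
    score_association,
)
from .exceptions import EmptyReportError, UndefinedStatisticError
from .io import ExternalPValueTable, MutationPanel, PanelDialect, ResponsePanel


@dataclass(frozen=True)
class ScanSkip:
    """A drug-feature pair that could not be scored, with the reason."""

    drug: str
    feature: str
    reason: str


@dataclass
class DiscoveryReport:
    """Raw output of a panel scan: scored associations plus bookkeeping."""

    results: list[AssociationResult]
    skipped: list[ScanSkip]
    q: float
    critical_p_chi2: float
    critical_p_external: float = float("nan")

    def pairs(self) -> set[tuple[str, str]]:
        return {(r.drug, r.feature) for r in self.results}

    def significant(self) -> list[AssociationResult]:
        return [r for r in self.results if r.significant]


def scan_panel(
    responses: ResponsePanel,
    mutations: MutationPanel,
    q: float = 0.20,
) -> DiscoveryReport:
    """Score every testable (drug, feature) pair and apply BH-FDR jointly.

    A pair is testable when, among the drug's tested cells with a
    non-missing mutation call, both the mutant and the wild-type group are
    non-empty.  Untestable pairs are skipped with a reason, never scored.
    BH runs once over all scored associations (a single fixed denominator),
    and a result is flagged significant when its p-value is at or below the
    step-up critical value.
    """
    common = [c for c in responses.cells if c in set(mutations.cells)]
    if not common:
        raise EmptyReportError("panels share no cell-line identifiers")
    mut_frame = mutations.frame.loc[common]

    results: list[AssociationResult] = []
    skipped: list[ScanSkip] = []
    features = mutations.features
    mut_values = mut_frame.to_numpy(dtype=float)  # cells x features
    cell_pos = {c: i for i, c in enumerate(common)}

    for drug in responses.drugs:
        resp = responses.responses(drug)
        resp = resp[resp.index.isin(cell_pos)]
        if resp.empty:
            for feature in features:
                skipped.append(ScanSkip(drug, feature, "no tested cells"))
            continue
        rows = np.fromiter((cell_pos[c] for c in resp.index), dtype=int)
        y = resp.to_numpy(dtype=float)
        for j, feature in enumerate(features):
            calls = mut_values[rows, j]
            known = ~np.isnan(calls)
            if not known.any():
                skipped.append(ScanSkip(drug, feature, "no mutation calls"))
                continue
            flags = calls[known] == 1.0
            yk = y[known]
            if yk.size < 2 or not flags.any() or flags.all():
                reason = (
                    "all cells mutated" if flags.all() else
                    "no mutated cells" if not flags.any() else
                    "fewer than two cells"
                )
                skipped.append(ScanSkip(drug, feature, reason))
                continue
            data = AssociationData(yk, flags)
            try:
                results.append(score_association(data, drug=drug, feature=feature))
            except UndefinedStatisticError:
                skipped.append(ScanSkip(drug, feature, "degenerate table"))

    if not results:
        raise EmptyReportError("no testable drug-feature pair in the panels")

    mask, critical = bh_fdr([r.p for r in results], q)
    for r, sig in zip(results, mask):
        r.significant = bool(sig)
    return DiscoveryReport(results=results, skipped=skipped, q=q,
                           critical_p_chi2=critical)


def consensus_calls(
    report: DiscoveryReport,
    external: ExternalPValueTable,
    q: float | None = None,
) -> DiscoveryReport:
    """Attach external significance and consensus flags to a report.

    BH is applied to the external p-values over the scanned pairs covered by
    the table; pairs the table does not cover count as externally
    non-significant.  ``consensus`` is significant-under-both.  The three
    disjoint call sets (consensus, chi2-only, external-only) can then be
    read off the flags.
    """
    q = report.q if q is None else q
    covered = [r for r in report.results if external.get(r.drug, r.feature) is not None]
    if covered:
        pvals = [external.get(r.drug, r.feature) for r in covered]
        mask, critical = bh_fdr(pvals, q)
    else:
        mask, critical = np.zeros(0, dtype=bool), float("nan")
    ext_sig = {
        (r.drug, r.feature): bool(s) for r, s in zip(covered, mask)
    }
    for r in report.results:
        r.p_external = external.get(r.drug, r.feature)
        r.significant_external = ext_sig.get((r.drug, r.feature), False)
        r.consensus = bool(r.significant and r.significant_external)
    report.critical_p_external = critical
    return report


def call_sets(report: DiscoveryReport) -> dict[str, set[tuple[str, str]]]:
    """The three disjoint call sets after :func:`consensus_calls`."""
    consensus, chi2_only, external_only = set(), set(), set()
    for r in report.results:
        key = (r.drug, r.feature)
        if r.consensus:
            consensus.add(key)
        elif r.significant:
            chi2_only.add(key)
        elif r.significant_external:
            external_only.add(key)
    return {
        "consensus": consensus,
        "chi2_only": chi2_only,
        "external_only": external_only,
    }


class MarkerDiscovery:
    """Model object for panel-wide drug-gene marker discovery.

    Parameters
    ----------
    responses
        Drug-response panel (logIC50 in log10 uM).
    mutations
        Binary mutation panel sharing the cell-identifier scheme.

    Examples
    --------
    >>> model = MarkerDiscovery(responses, mutations)   # doctest: +SKIP
    >>> res = model.fit(q=0.20)                         # doctest: +SKIP
    >>> print(res.summary())                            # doctest: +SKIP
    """

    def __init__(self, responses: ResponsePanel, mutations: MutationPanel):
        self.responses = responses
        self.mutations = mutations

    @classmethod
    def from_csv(cls, path, dialect: PanelDialect = PanelDialect()) -> "MarkerDiscovery":
        """Build the model straight from a panel CSV in the documented dialect."""
        rp, mp = gio.read_panel(path, dialect)
        return cls(rp, mp)

    @classmethod
    def from_dataframes(cls, responses: pd.DataFrame, mutations: pd.DataFrame) -> "MarkerDiscovery":
        """Build from cells-by-drugs and cells-by-features DataFrames
        (NaN = untested response / missing call)."""
        return cls(ResponsePanel(responses), MutationPanel(mutations))

    def fit(self, q: float = 0.20) -> "DiscoveryResults":
        """Scan the panel and control the FDR at level *q* (default 20%)."""
        report = scan_panel(self.responses, self.mutations, q=q)
        return DiscoveryResults(self, report)


class DiscoveryResults:
    """Fitted results of a :class:`MarkerDiscovery` scan."""

    def __init__(self, model: MarkerDiscovery, report: DiscoveryReport):
        self.model = model
        self.report = report

    # -- accessors ---------------------------------------------------------
    @property
    def results(self) -> list[AssociationResult]:
        return self.report.results

    @property
    def critical_p(self) -> float:
        return self.report.critical_p_chi2

    @property
    def n_significant(self) -> int:
        return len(self.report.significant())

    def to_frame(self) -> pd.DataFrame:
        return gio.results_to_frame(self.report.results)

    # -- downstream steps --------------------------------------------------
    def add_external(self, external: ExternalPValueTable, q: float | None = None) -> "DiscoveryResults":
        """Attach external significance and consensus flags (in place)."""
        consensus_calls(self.report, external, q)
        return self

    def call_sets(self) -> dict[str, set[tuple[str, str]]]:
        return call_sets(self.report)

    def validate(self, test_responses: ResponsePanel, test_mutations: MutationPanel | None = None):
        """Validate significant markers on held-out cell lines; see
        :func:`phimarker.validation.validate_report`."""
        from .validation import validate_report

        return validate_report(
            self.report,
            self.model.responses,
            test_responses,
            test_mutations if test_mutations is not None else self.model.mutations,
        )

    # -- presentation ------------------------------------------------------
    def summary(self, max_rows: int = 10) -> str:
        """Plain-text summary: scan size, FDR control and top markers."""
        rep = self.report
        lines = [
            "Marker discovery (mutation-dependent threshold, chi-squared test)",
            "=" * 66,
            f"Scored associations:      {len(rep.results)}",
            f"Skipped pairs:            {len(rep.skipped)}",
            f"FDR level q:              {rep.q:.3g}",
            f"BH critical p-value:      {rep.critical_p_chi2:.6g}",
            f"Significant associations: {self.n_significant}",
        ]
        if any(r.p_external is not None for r in rep.results):
            sets = self.call_sets()
            lines += [
                f"External critical p:      {rep.critical_p_external:.6g}",
                f"Consensus / chi2-only / external-only: "
                f"{len(sets['consensus'])} / {len(sets['chi2_only'])} / "
                f"{len(sets['external_only'])}",
            ]
        top = sorted(rep.results, key=lambda r: r.p)[:max_rows]
        if top:
            lines.append("")
            lines.append(f"{'drug':<16}{'feature':<16}{'n':>5}{'phi':>8}"
                         f"{'chi2':>10}{'p':>12}  direction")
            for r in top:
                lines.append(
                    f"{r.drug:<16}{r.feature:<16}{r.n:>5}{r.phi:>8.3f}"
                    f"{r.chi2:>10.2f}{r.p:>12.3g}  {r.threshold.direction}"
                )
        return "\n".join(lines)

    def plot_association(self, drug: str, feature: str, ax=None):
        """Scatter + boxplot of one association's logIC50 by mutation
        status, with the mutation-dependent threshold drawn."""
        import matplotlib.pyplot as plt

        match = [r for r in self.results if r.drug == drug and r.feature == feature]
        if not match:
            raise KeyError(f"association {drug}/{feature} was not scored")
        r = match[0]
        resp = self.model.responses.responses(drug)
        calls = self.model.mutations.calls(feature).reindex(resp.index)
        known = calls.notna()
        y = resp[known]
        mt = calls[known] == 1.0
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        groups = [y[mt].to_numpy(), y[~mt].to_numpy()]
        ax.boxplot(groups, positions=[1, 2], widths=0.5, showfliers=False)
        rng = np.random.default_rng(0)  # jitter only, cosmetic
        for pos, g in zip((1, 2), groups):
            ax.plot(pos + rng.uniform(-0.12, 0.12, g.size), g, ".", alpha=0.5)
        ax.axhline(r.threshold.threshold, color="red", linestyle=":",
                   label=f"threshold = {r.threshold.threshold:.2f}")
        ax.set_xticks([1, 2], ["mutated", "wild-type"])
        ax.set_ylabel("logIC50 (log10 uM)")
        ax.set_title(f"{drug} vs {feature} (phi = {r.phi:.2f}, p = {r.p:.2g})")
        ax.legend(loc="best", fontsize=8)
        return ax

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"<DiscoveryResults {len(self.results)} associations, "
                f"{self.n_significant} significant at q={self.report.q}>")
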