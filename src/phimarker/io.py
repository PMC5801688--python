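"""Reading and writing drug-response / mutation panels in the GDSC-style
CSV dialect.

The canonical dialect is one row per cell line with three kinds of columns:

* ``cell_line`` — the cell-line identifier (must be unique);
* ``IC50_<drug>`` — drug-response columns; a blank field means the
  (drug, cell) pair was not screened.  Values may be shipped either as the
  natural logarithm of IC50 in uM (the GDSC convention) or already in
  log10 uM; the :class:`PanelDialect` ``scale`` flag says which, and values
  are converted to log10 uM exactly once, at ingest;
* ``MUT_<feature>`` — genomic-feature columns holding either an ``x::y``
  mutation descriptor (coding-variant token ``::`` copy-number token) or a
  plain binary token (used for translocation and MSI columns).

Columns matching none of these raise :class:`~phimarker.exceptions.PanelFormatError`.
A drug listed twice keeps the more broadly tested instance (ties: first
occurrence), mirroring how the duplicated camptothecin screen is resolved
in the public release.
"""

from __future__ import annotations

import csv
import enum
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import PanelFormatError

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


class CallState(enum.Enum):
    """Mutation call for one (feature, cell line) pair."""

    MUTATED = "mutated"
    WILD_TYPE = "wild-type"
    MISSING = "missing"


#: copy-number token for the wild-type range, open on both sides
_CN_WT_TOKEN = "0<cn<8"
_CN_EQ_RE = re.compile(r"^cn=(\d+)$")

#: canonical descriptor emitted for each call state (round-trips via
#: :func:`parse_mutation_descriptor`)
CANONICAL_DESCRIPTOR = {
    CallState.MUTATED: "mut::" + _CN_WT_TOKEN,
    CallState.WILD_TYPE: "wt::" + _CN_WT_TOKEN,
    CallState.MISSING: "na::na",
}


def parse_mutation_descriptor(descriptor: str, *, context: str = "") -> CallState:
    """Resolve a GDSC-style ``x::y`` descriptor to a mutation call.

    The variant token ``x`` annotates a coding mutation unless it is ``wt``
    or ``na``.  The copy-number token ``y`` annotates a deletion (cn = 0) or
    amplification (cn >= 8); ``0<cn<8`` is the wild-type range, open on both
    sides.  A gene with no detected mutation is wild-type, so an unknown
    copy number (``na``) with a non-variant ``x`` still yields a wild-type
    call.  Token shapes outside the dialect degrade to a MISSING call with a
    logged warning; a malformed separator is a hard format error.

    Parameters
    ----------
    descriptor
        The ``x::y`` string.
    context
        Optional "drug/gene/cell" label used in error and log messages.
    """
    if not isinstance(descriptor, str) or "::" not in descriptor:
        where = f" at {context}" if context else ""
        raise PanelFormatError(
            f"malformed mutation descriptor {descriptor!r}{where}: "
            "expected 'x::y' with a '::' separator"
        )
    x, _, y = descriptor.partition("::")
    x = x.strip()
    y = y.strip()

    # 'wt' asserts the variant scan found nothing; 'na' (or a blank token)
    # means no variant information at all
    x_known = bool(x) and x != "na"
    is_variant = x_known and x != "wt"

    cn: int | None = None  # None = unknown copy number
    y_known = True
    if y == _CN_WT_TOKEN:
        cn = 1  # any value in the open wild-type range
    elif y in ("na", ""):
        cn = None
    else:
        m = _CN_EQ_RE.match(y)
        if m:
            cn = int(m.group(1))
        else:
            y_known = False

    if not x_known and not y_known:
        return CallState.MISSING
    if not y_known:
        logger.warning(
            "unrecognised copy-number token %r%s; treating as unknown",
            y, f" at {context}" if context else "",
        )
        cn = None
    if is_variant:
        return CallState.MUTATED
    if cn is not None and (cn == 0 or cn >= 8):
        return CallState.MUTATED
    if not x_known and cn is None:
        # neither a variant scan result nor copy-number evidence
        return CallState.MISSING
    # variant scan negative, or copy number confirmed in the wt range
    return CallState.WILD_TYPE


def format_call_state(state: CallState) -> str:
    """Canonical ``x::y`` descriptor for *state* (parse/format round-trip)."""
    return CANONICAL_DESCRIPTOR[state]


def to_log10(ln_ic50):
    """Convert natural-log IC50 (uM) to log10 IC50 (uM).

    Strictly increasing and invertible; raises ``ValueError`` on non-finite
    input so sentinel values can never masquerade as responses.
    """
    arr = np.asarray(ln_ic50, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite IC50 value cannot be converted")
    out = arr / LN10
    return float(out) if np.isscalar(ln_ic50) or arr.ndim == 0 else out


@dataclass(frozen=True)
class PanelDialect:
    """Column conventions and value scale of a panel CSV file."""

    cell_column: str = "cell_line"
    response_prefix: str = "IC50_"
    feature_prefix: str = "MUT_"
    #: scale of the stored response values: "ln" (natural log uM, the GDSC
    #: convention, converted at ingest) or "log10" (stored as-is)
    scale: str = "log10"
    #: token map for plain binary feature columns (translocations, MSI);
    #: keys are lower-cased file tokens
    binary_tokens: Mapping[str, CallState] = field(
        default_factory=lambda: {
            "0": CallState.WILD_TYPE,
            "wt": CallState.WILD_TYPE,
            "not-detected": CallState.WILD_TYPE,
            "mss": CallState.WILD_TYPE,
            "1": CallState.MUTATED,
            "msi": CallState.MUTATED,
            "na": CallState.MISSING,
            "": CallState.MISSING,
        }
    )

    def __post_init__(self):
        if self.scale not in ("ln", "log10"):
            raise ValueError(f"scale must be 'ln' or 'log10', got {self.scale!r}")


class ResponsePanel:
    """Sparse matrix of logIC50 (log10 uM) values, drugs x cell lines.

    Internally a cells-by-drugs ``DataFrame`` with ``NaN`` marking untested
    pairs; every stored value is finite and identifiers are unique.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise PanelFormatError("duplicate cell-line identifiers in response panel")
        if frame.columns.has_duplicates:
            raise PanelFormatError("duplicate drug identifiers in response panel")
        values = frame.to_numpy(dtype=float)
        if np.any(np.isinf(values)):
            raise PanelFormatError("non-finite response values in panel")
        self.frame = frame.astype(float)

    @property
    def drugs(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def cells(self) -> list[str]:
        return list(self.frame.index)

    @property
    def n_values(self) -> int:
        """Number of stored (drug, cell) responses."""
        return int(self.frame.notna().to_numpy().sum())

    def responses(self, drug: str) -> pd.Series:
        """logIC50 values for *drug*, indexed by cell line (tested cells only)."""
        return self.frame[drug].dropna()

    def n_tested(self, drug: str) -> int:
        return int(self.frame[drug].notna().sum())

    def value(self, drug: str, cell: str) -> float:
        v = self.frame.at[cell, drug]
        if pd.isna(v):
            raise KeyError((drug, cell))
        return float(v)

    def __contains__(self, key) -> bool:
        drug, cell = key
        return (
            drug in self.frame.columns
            and cell in self.frame.index
            and pd.notna(self.frame.at[cell, drug])
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<ResponsePanel {len(self.drugs)} drugs x {len(self.cells)} cells, "
            f"{self.n_values} values>"
        )


class MutationPanel:
    """Binary mutation calls, features x cell lines.

    Internally a cells-by-features ``DataFrame`` holding 1.0 (mutated),
    0.0 (wild-type) or ``NaN`` (missing call).
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise PanelFormatError("duplicate cell-line identifiers in mutation panel")
        if frame.columns.has_duplicates:
            raise PanelFormatError("duplicate feature identifiers in mutation panel")
        values = frame.to_numpy(dtype=float)
        bad = np.isfinite(values) & (values != 0.0) & (values != 1.0)
        if bad.any():
            raise PanelFormatError("mutation calls must be 0, 1 or missing")
        self.frame = frame.astype(float)

    @property
    def features(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def cells(self) -> list[str]:
        return list(self.frame.index)

    def calls(self, feature: str) -> pd.Series:
        """Calls for *feature* indexed by cell (NaN = missing)."""
        return self.frame[feature]

    def state(self, feature: str, cell: str) -> CallState:
        v = self.frame.at[cell, feature]
        if pd.isna(v):
            return CallState.MISSING
        return CallState.MUTATED if v == 1.0 else CallState.WILD_TYPE

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<MutationPanel {len(self.features)} features x {len(self.cells)} cells>"


@dataclass
class ExternalPValueTable:
    """Per-association p-values produced by an external test (e.g. the
    MANOVA screen shipped with the GDSC release)."""

    entries: dict[tuple[str, str], float]

    def __post_init__(self):
        for (drug, feature), p in self.entries.items():
            if not (0.0 <= p <= 1.0) or not math.isfinite(p):
                raise PanelFormatError(
                    f"external p-value out of [0, 1] for {drug}/{feature}: {p}"
                )

    def get(self, drug: str, feature: str) -> float | None:
        return self.entries.get((drug, feature))

    def __len__(self) -> int:
        return len(self.entries)


def _resolve_duplicate_drugs(
    names: Sequence[str], data: pd.DataFrame
) -> list[int]:
    """Column indices to keep: for duplicated drug names keep the most
    broadly tested instance, ties broken by first occurrence."""
    keep: dict[str, int] = {}
    for idx, name in enumerate(names):
        if name not in keep:
            keep[name] = idx
        else:
            prev = keep[name]
            n_prev = int(data.iloc[:, prev].notna().sum())
            n_new = int(data.iloc[:, idx].notna().sum())
            if n_new > n_prev:
                keep[name] = idx
            logger.warning(
                "drug %r listed twice (%d vs %d tested cells); keeping the "
                "more broadly tested instance", name, n_prev, n_new,
            )
    return [keep[n] for n in dict.fromkeys(names)]


def read_panel(
    path: Union[str, Path], dialect: PanelDialect = PanelDialect()
) -> tuple[ResponsePanel, MutationPanel]:
    """Read a panel CSV into a (ResponsePanel, MutationPanel) pair.

    Blank response fields become absent values (never sentinels); mutation
    descriptors are resolved via :func:`parse_mutation_descriptor`; responses
    are converted to log10 uM if the dialect declares them natural-log.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        header = next(csv.reader(fh))
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw.columns = pd.Index(range(len(header)))  # positional; header may repeat

    if dialect.cell_column not in header:
        raise PanelFormatError(
            f"missing cell identifier column {dialect.cell_column!r} in {path}"
        )
    cell_idx = header.index(dialect.cell_column)
    cells = pd.Index(raw.iloc[:, cell_idx].to_numpy(), name=None)
    if cells.duplicated().any():
        dupes = sorted(cells[cells.duplicated()].unique())
        raise PanelFormatError(f"duplicate cell-line identifiers: {dupes}")

    resp_cols: list[tuple[str, int]] = []
    feat_cols: list[tuple[str, int]] = []
    for idx, name in enumerate(header):
        if idx == cell_idx:
            continue
        if name.startswith(dialect.response_prefix):
            resp_cols.append((name[len(dialect.response_prefix):], idx))
        elif name.startswith(dialect.feature_prefix):
            feat_cols.append((name[len(dialect.feature_prefix):], idx))
        else:
            raise PanelFormatError(
                f"unknown column {name!r} in {path}: expected "
                f"{dialect.cell_column!r}, {dialect.response_prefix}* or "
                f"{dialect.feature_prefix}*"
            )

    # responses: blank -> NaN, then duplicate-drug resolution, then scale
    resp_data = pd.DataFrame(index=cells)
    if resp_cols:
        block = raw.iloc[:, [i for _, i in resp_cols]].replace("", np.nan)
        block = block.apply(pd.to_numeric)
        block.index = cells
        names = [n for n, _ in resp_cols]
        keep = _resolve_duplicate_drugs(names, block)
        resp_data = block.iloc[:, keep]
        resp_data.columns = [names[i] for i in keep]
        if dialect.scale == "ln":
            resp_data = resp_data / LN10

    feat_data = pd.DataFrame(index=cells)
    call_value = {CallState.MUTATED: 1.0, CallState.WILD_TYPE: 0.0,
                  CallState.MISSING: np.nan}
    seen_features: set[str] = set()
    for feature, idx in feat_cols:
        if feature in seen_features:
            raise PanelFormatError(f"feature {feature!r} listed twice")
        seen_features.add(feature)
        col = raw.iloc[:, idx]
        states = []
        for cell, token in zip(cells, col):
            token = token.strip()
            if "::" in token:
                state = parse_mutation_descriptor(
                    token, context=f"{feature}/{cell}"
                )
            else:
                state = dialect.binary_tokens.get(token.lower())
                if state is None:
                    # any other non-blank token names the detected variant
                    # (e.g. the fusion identifier in translocation columns)
                    state = CallState.MUTATED
            states.append(call_value[state])
        feat_data[feature] = states

    return ResponsePanel(resp_data), MutationPanel(feat_data)


def write_panel(
    responses: ResponsePanel,
    mutations: MutationPanel,
    path: Union[str, Path],
    dialect: PanelDialect = PanelDialect(),
) -> None:
    """Write panels as one CSV in the canonical dialect (log10 scale).

    Mutation calls are emitted as canonical ``x::y`` descriptors so the file
    round-trips exactly through :func:`read_panel`.
    """
    if dialect.scale != "log10":
        raise ValueError("panels are stored in log10 scale; write with a log10 dialect")
    cells = responses.cells
    if mutations.cells != cells:
        raise ValueError("response and mutation panels must share cell-line order")
    out = pd.DataFrame({dialect.cell_column: cells})
    for drug in responses.drugs:
        out[dialect.response_prefix + drug] = responses.frame[drug].to_numpy()
    state_of = {1.0: CallState.MUTATED, 0.0: CallState.WILD_TYPE}
    for feature in mutations.features:
        col = mutations.frame[feature]
        out[dialect.feature_prefix + feature] = [
            format_call_state(state_of.get(v, CallState.MISSING) if pd.notna(v)
                              else CallState.MISSING)
            for v in col
        ]
    out.to_csv(path, index=False, float_format="%.17g")


def read_external_pvalues(
    path: Union[str, Path],
    columns: tuple[str, str, str] = ("drug", "feature", "p"),
) -> ExternalPValueTable:
    """Read a (drug, feature, p-value) CSV into an ExternalPValueTable."""
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise PanelFormatError(f"external p-value table misses columns {missing}")
    d, f, p = columns
    entries: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        key = (str(getattr(row, d)), str(getattr(row, f)))
        if key in entries:
            raise PanelFormatError(f"duplicate external p-value entry for {key}")
        entries[key] = float(getattr(row, p))
    return ExternalPValueTable(entries)


def write_external_pvalues(
    table: ExternalPValueTable,
    path: Union[str, Path],
    columns: tuple[str, str, str] = ("drug", "feature", "p"),
) -> None:
    rows = [
        {columns[0]: d, columns[1]: f, columns[2]: p}
        for (d, f), p in table.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def results_to_frame(results: Iterable) -> pd.DataFrame:
    """Tabulate AssociationResult / ValidationResult objects.

    Columns mirror the supplementary-table layout of the original screen
    (drug, feature, nTrain, prevalence, p-values, significance flags, nTest,
    MCC on the test set) plus the threshold and contingency details needed
    for exact round-trips.
    """
    rows = [r.to_row() for r in results]
    if not rows:
        raise ValueError("cannot tabulate an empty result collection")
    return pd.DataFrame(rows)


def write_results(results, path: Union[str, Path]) -> None:
    """Write results as CSV; numeric fields round-trip at full precision."""
    frame = results_to_frame(results)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    return pd.read_csv(path, float_precision="round_trip")
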