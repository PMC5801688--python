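"""GDSC-shaped synthetic panels with planted drug-gene effects.

The generator emulates the salient pathologies of public drug-response
panels: a sparse logIC50 matrix (roughly 55-80% filled), binary mutation
features spanning rare to common prevalences, per-drug baselines spread
over several orders of magnitude of potency, and response noise that can
be Gaussian, right-skewed (mean-centred log-normal) or contaminated with
a heavy-tailed outlier component.  Planted effects shift the mutant group
additively on the log10-molar scale — the same scale on which thresholds
and medians operate — with a sign encoding sensitivity (mutants more
potent, negative shift) or resistance (positive shift).

Defaults mirror the release-1.0-like screen the package targets: 638 cell
lines, 130 drugs, 71 genomic features, 57.6% of drug-cell pairs measured,
per-feature prevalence log-uniform on [0.02, 0.3], per-drug baseline
location uniform on [-1, 2] log10 uM and noise sd 0.5 log10 units.

Everything is driven by one integer seed through numpy's default
(PCG64) generator, so a fixed spec reproduces bit-identical panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .discovery import scan_panel
from .io import MutationPanel, PanelDialect, ResponsePanel, write_panel

SENSITIVITY = "sensitivity"
RESISTANCE = "resistance"


@dataclass(frozen=True)
class PlantedEffect:
    """One planted drug-gene association.

    ``delta`` is the magnitude of the mutant-group shift in log10 molar
    units; ``sign`` is ``"sensitivity"`` (shift down) or ``"resistance"``
    (shift up).
    """

    drug: str
    feature: str
    delta: float
    sign: str = SENSITIVITY

    def __post_init__(self):
        if self.sign not in (SENSITIVITY, RESISTANCE):
            raise ValueError(f"sign must be sensitivity/resistance, got {self.sign!r}")
        if not math.isfinite(self.delta) or self.delta < 0:
            raise ValueError("delta must be a finite non-negative magnitude")

    @property
    def shift(self) -> float:
        """Signed additive shift applied to mutant responses."""
        return -self.delta if self.sign == SENSITIVITY else self.delta


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one synthetic panel."""

    n_cells: int = 638
    n_drugs: int = 130
    n_features: int = 71
    missing_fraction: float = 0.424
    #: scalar prevalence for every feature, or a (lo, hi) log-uniform range
    prevalence: float | tuple[float, float] = (0.02, 0.30)
    #: per-drug baseline location (log10 uM): scalar or uniform range
    baseline_loc: float | tuple[float, float] = (-1.0, 2.0)
    noise_sd: float = 0.5
    noise_family: str = "gaussian"  # gaussian | skewed | contaminated
    skew: float = 0.8               # log-normal sigma of the skewed family
    outlier_fraction: float = 0.05  # contaminated family mixture weight
    outlier_scale: float = 5.0      # sd multiplier of the outlier component
    planted: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must lie in [0, 1)")
        prev = self.prevalence
        lo, hi = (prev, prev) if np.isscalar(prev) else prev
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.noise_family not in ("gaussian", "skewed", "contaminated"):
            raise ValueError(f"unknown noise family {self.noise_family!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        object.__setattr__(self, "planted", tuple(self.planted))

    def drug_names(self) -> list[str]:
        return [f"drug{i:03d}" for i in range(self.n_drugs)]

    def feature_names(self) -> list[str]:
        return [f"gene{j:03d}" for j in range(self.n_features)]

    def cell_names(self) -> list[str]:
        return [f"cell{k:04d}" for k in range(self.n_cells)]


@dataclass
class SyntheticPanel:
    """A generated panel with its ground truth."""

    responses: ResponsePanel
    mutations: MutationPanel
    truth: pd.DataFrame  # columns: drug, feature, delta, sign
    spec: SyntheticSpec

    def write(self, panel_path, truth_path, dialect: PanelDialect = PanelDialect()):
        write_panel(self.responses, self.mutations, panel_path, dialect)
        self.truth.to_csv(truth_path, index=False, float_format="%.17g")


def _noise(rng: np.random.Generator, spec: SyntheticSpec, size) -> np.ndarray:
    """Zero-centred noise with standard-deviation parameter ``noise_sd``."""
    sd = spec.noise_sd
    if spec.noise_family == "gaussian":
        return rng.normal(0.0, sd, size)
    if spec.noise_family == "skewed":
        # mean-centred log-normal, rescaled to sd = noise_sd
        s = spec.skew
        raw = rng.lognormal(mean=0.0, sigma=s, size=size)
        mean = math.exp(s * s / 2.0)
        std = math.sqrt((math.exp(s * s) - 1.0) * math.exp(s * s))
        return (raw - mean) * (sd / std)
    # contaminated: two-component scale mixture
    out = rng.normal(0.0, sd, size)
    mask = rng.random(size) < spec.outlier_fraction
    out[mask] = rng.normal(0.0, sd * spec.outlier_scale, int(mask.sum()))
    return out


def generate(spec: SyntheticSpec) -> SyntheticPanel:
    """Draw one panel from *spec* (bit-reproducible for a fixed seed).

    Mutation flags are Bernoulli per (feature, cell) at the feature's
    prevalence; responses are a per-drug baseline plus noise plus the
    planted shift for mutants of planted pairs; missing entries are removed
    per ``missing_fraction``.  A feature drawn all-mutant or all-wild-type
    is allowed (it exercises the scan's skip path) but recorded in
    ``truth.attrs["monomorphic_features"]``.
    """
    rng = np.random.default_rng(spec.seed)
    drugs = spec.drug_names()
    features = spec.feature_names()
    cells = spec.cell_names()
    for eff in spec.planted:
        if eff.drug not in drugs or eff.feature not in features:
            raise ValueError(f"planted pair {eff.drug}/{eff.feature} outside the panel")

    prev = spec.prevalence
    if np.isscalar(prev):
        prevalences = np.full(spec.n_features, float(prev))
    else:
        lo, hi = prev
        prevalences = np.exp(
            rng.uniform(math.log(lo), math.log(hi), spec.n_features)
        )
    flags = rng.random((spec.n_cells, spec.n_features)) < prevalences[None, :]

    loc = spec.baseline_loc
    if np.isscalar(loc):
        baselines = np.full(spec.n_drugs, float(loc))
    else:
        baselines = rng.uniform(loc[0], loc[1], spec.n_drugs)

    resp = baselines[None, :] + _noise(rng, spec, (spec.n_cells, spec.n_drugs))
    fidx = {f: j for j, f in enumerate(features)}
    didx = {d: i for i, d in enumerate(drugs)}
    for eff in spec.planted:
        j, i = fidx[eff.feature], didx[eff.drug]
        resp[flags[:, j], i] += eff.shift
    if spec.missing_fraction > 0.0:
        missing = rng.random((spec.n_cells, spec.n_drugs)) < spec.missing_fraction
        resp[missing] = np.nan

    responses = ResponsePanel(pd.DataFrame(resp, index=cells, columns=drugs))
    mutations = MutationPanel(
        pd.DataFrame(flags.astype(float), index=cells, columns=features)
    )
    truth = pd.DataFrame(
        [{"drug": e.drug, "feature": e.feature, "delta": e.delta, "sign": e.sign}
         for e in spec.planted],
        columns=["drug", "feature", "delta", "sign"],
    )
    mono = [features[j] for j in range(spec.n_features)
            if flags[:, j].all() or not flags[:, j].any()]
    truth.attrs["monomorphic_features"] = mono
    return SyntheticPanel(responses, mutations, truth, spec)


def noisy_external_table(
    report,
    truth_pairs: set[tuple[str, str]],
    rng: np.random.Generator,
    miss_rate: float = 0.3,
    strength: tuple[float, float] = (3.0, 10.0),
    n_false: int = 0,
):
    """An "external test" p-value table as a noisy, distorted view of the
    ground truth.

    Emulates a second, imperfect statistical test whose errors are
    independent of the scan's: a truly associated pair gets a small
    p-value (``10**-U(strength)``) unless it is among the fraction
    ``miss_rate`` the external test misses (external false negatives,
    scrambled to a non-small uniform p); every null pair draws a uniform
    p-value, so the external test also produces its own false positives
    under multiple testing; ``n_false`` null pairs can additionally be
    forced to tiny p-values.  Used by the method-comparison study of
    consensus vs single-test call sets.
    """
    from .io import ExternalPValueTable

    entries: dict[tuple[str, str], float] = {}
    null_pairs = []
    for r in report.results:
        key = (r.drug, r.feature)
        if key in truth_pairs:
            if rng.random() < miss_rate:
                entries[key] = float(rng.uniform(0.05, 1.0))
            else:
                entries[key] = float(10.0 ** -rng.uniform(*strength))
        else:
            entries[key] = float(rng.uniform(0.0, 1.0))
            null_pairs.append(key)
    if null_pairs and n_false > 0:
        chosen = rng.choice(len(null_pairs), size=min(n_false, len(null_pairs)),
                            replace=False)
        for idx in chosen:
            entries[null_pairs[int(idx)]] = float(rng.uniform(1e-8, 1e-6))
    return ExternalPValueTable(entries)


def power_study(
    deltas: Sequence[float],
    prevalences: Sequence[float],
    ns: Sequence[int],
    q: float = 0.20,
    replicates: int = 20,
    n_null_features: int = 20,
    noise_sd: float = 0.5,
    noise_family: str = "gaussian",
    seed: int = 0,
) -> pd.DataFrame:
    """Detection rate and false-discovery proportion over a parameter grid.

    Each replicate plants one effect of magnitude ``delta`` in a one-drug
    panel alongside ``n_null_features`` null features, scans it at FDR
    level *q*, and records whether the planted pair was called significant
    and the proportion of calls that were null pairs.  Returns one row per
    (delta, prevalence, n) with the rates averaged over replicates.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rows = []
    counter = 0
    for delta in deltas:
        for prevalence in prevalences:
            for n in ns:
                detected = 0
                fdp = []
                for _ in range(replicates):
                    counter += 1
                    planted = (
                        (PlantedEffect("drug000", "gene000", delta),)
                        if delta > 0 else ()
                    )
                    spec = SyntheticSpec(
                        n_cells=n, n_drugs=1,
                        n_features=1 + n_null_features,
                        missing_fraction=0.0,
                        prevalence=prevalence,
                        baseline_loc=0.0,
                        noise_sd=noise_sd,
                        noise_family=noise_family,
                        planted=planted,
                        seed=seed * 1_000_003 + counter,
                    )
                    panel = generate(spec)
                    report = scan_panel(panel.responses, panel.mutations, q=q)
                    called = {(r.drug, r.feature) for r in report.significant()}
                    truth_pairs = {("drug000", "gene000")} if delta > 0 else set()
                    if truth_pairs and truth_pairs <= called:
                        detected += 1
                    false = len(called - truth_pairs)
                    fdp.append(false / len(called) if called else 0.0)
                rows.append({
                    "delta": delta, "prevalence": prevalence, "n": n,
                    "detection_rate": detected / replicates if delta > 0 else float("nan"),
                    "any_call_rate": float(np.mean([f > 0 for f in fdp])) if delta == 0
                    else float("nan"),
                    "fdp": float(np.mean(fdp)),
                })
    return pd.DataFrame(rows)
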