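"""Composite antidiabetic scoring indices.

Implements the two composite scores used to rank samples across a panel of
bioactivity endpoints, and their average:

* **AHCI** (antihyperglycemic composite index) — built from lower-is-better
  endpoints (enzyme-inhibition IC50 values).  Each parameter contributes an
  individual index ``(100 - value) / (100 - least) * 100`` where ``least``
  is the smallest value over the configured reference set (samples plus,
  by default, the positive controls).
* **OGRCI** (oxidation-glycation reduction composite index) — built from
  higher-is-better endpoints (radical scavenging, reducing power, glycation
  inhibition).  Each parameter contributes ``value / highest * 100``.
* **OADP** (overall antidiabetic potential) — the average of AHCI and OGRCI.

Per-sample scores are the (weighted) mean of individual indices, rounded to
integers per configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import AssayPanel
from .errors import DegenerateReferenceError, UnscorableSampleError

LOWER_BETTER = "lower_better"
HIGHER_BETTER = "higher_better"

#: Default AHCI parameters: the four enzyme-inhibition IC50 endpoints.
AHCI_PARAMETERS = (
    ("amylase_ic50", LOWER_BETTER),
    ("glucosidase_ic50", LOWER_BETTER),
    ("dppiv_ic50", LOWER_BETTER),
    ("ptp1b_ic50", LOWER_BETTER),
)

#: Default OGRCI parameters: three antioxidant endpoints plus AGEs inhibition.
OGRCI_PARAMETERS = (
    ("dpph_pct", HIGHER_BETTER),
    ("frap", HIGHER_BETTER),
    ("teac", HIGHER_BETTER),
    ("ages_pct", HIGHER_BETTER),
)


@dataclass
class IndexConfig:
    """Configuration of a composite index.

    ``nd_policy`` controls missing cells: ``"exclude"`` re-averages over the
    available parameters, ``"zero"`` scores the missing parameter 0.
    ``rounding`` is ``"nearest"`` (half away from zero) or ``"floor"``.
    ``weights`` must be a simplex over the parameters (default: equal).
    """

    parameters: tuple = AHCI_PARAMETERS
    include_positive_controls: bool = True
    nd_policy: str = "exclude"
    rounding: str = "nearest"
    weights: tuple | None = None

    def __post_init__(self):
        if len(self.parameters) < 1:
            raise ValueError("at least one parameter is required")
        for _, direction in self.parameters:
            if direction not in {LOWER_BETTER, HIGHER_BETTER}:
                raise ValueError(f"unknown direction {direction!r}")
        if self.nd_policy not in {"exclude", "zero"}:
            raise ValueError("nd_policy must be 'exclude' or 'zero'")
        if self.rounding not in {"nearest", "floor"}:
            raise ValueError("rounding must be 'nearest' or 'floor'")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != len(self.parameters):
                raise ValueError("weights length must match parameters")
            if (w < 0).any() or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("weights must be nonnegative and sum to 1")

    def weight_vector(self) -> np.ndarray:
        if self.weights is None:
            return np.full(len(self.parameters), 1.0 / len(self.parameters))
        return np.asarray(self.weights, dtype=float)


@dataclass
class CompositeScoreSet:
    """Per-sample individual indices, composite scores and reference provenance."""

    indices: pd.DataFrame  # samples x endpoints, individual indices (unrounded)
    ahci: pd.Series
    ogrci: pd.Series
    overall: pd.Series
    ahci_raw: pd.Series
    ogrci_raw: pd.Series
    reference_values: dict  # endpoint_id -> (reference value, holder sample_id)


def _round(value: float, mode: str) -> int:
    if mode == "floor":
        return int(math.floor(value))
    # nearest, half away from zero
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


def inhibition_index(value: float, reference_least: float) -> float:
    """Individual index for a lower-is-better (IC50-like) parameter.

    ``(100 - value) / (100 - reference_least) * 100``.  A value below the
    reference yields an index above 100 (allowed); a value above 100 would
    go negative and is clamped to 0 with a warning — on a 0-100 potency
    index a sample cannot be worse than "no activity".
    """
    if reference_least >= 100:
        raise DegenerateReferenceError(
            f"reference least value {reference_least} >= 100 makes the index undefined"
        )
    index = (100.0 - value) / (100.0 - reference_least) * 100.0
    if index < 0:
        warnings.warn(
            f"value {value} exceeds 100: inhibition index clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return index


def benefit_index(value: float, reference_highest: float) -> float:
    """Individual index for a higher-is-better parameter: value/highest*100."""
    if reference_highest <= 0:
        raise DegenerateReferenceError(
            f"reference highest value {reference_highest} must be positive"
        )
    if value < 0:
        raise ValueError("benefit parameter values must be nonnegative")
    return value / reference_highest * 100.0


def reference_value(
    panel: AssayPanel,
    endpoint_id: str,
    direction: str,
    include_positive_controls: bool = True,
) -> tuple[float, str]:
    """Reference (least or highest) value for an endpoint, with its holder."""
    df = panel.data
    rows = df[(df["endpoint_id"] == endpoint_id) & (~df["nd_flag"])]
    if not include_positive_controls and "role" in rows.columns:
        rows = rows[rows["role"] != "positive_control"]
    if rows.empty:
        raise DegenerateReferenceError(f"no usable values for endpoint {endpoint_id!r}")
    idx = rows["mean"].idxmin() if direction == LOWER_BETTER else rows["mean"].idxmax()
    return float(rows.loc[idx, "mean"]), str(rows.loc[idx, "sample_id"])


def _individual_index(value: float, direction: str, ref: float) -> float:
    if direction == LOWER_BETTER:
        return inhibition_index(value, ref)
    return benefit_index(value, ref)


def composite_index(panel: AssayPanel, config: IndexConfig) -> tuple[pd.Series, pd.Series, pd.DataFrame, dict]:
    """Weighted composite index over the configured parameters.

    Returns ``(rounded scores, raw scores, individual indices, references)``
    for every non-control sample in the panel.
    """
    refs = {
        ep: reference_value(panel, ep, direction, config.include_positive_controls)
        for ep, direction in config.parameters
    }
    samples = panel.samples(role="sample") if "role" in panel.data.columns else panel.samples()
    weights = config.weight_vector()
    index_rows, raw_scores = {}, {}
    for sample in samples:
        indices, row = [], {}
        available = np.zeros(len(config.parameters), dtype=bool)
        for k, (ep, direction) in enumerate(config.parameters):
            value = panel.value(sample, ep)
            if value is None:
                row[ep] = np.nan
                indices.append(np.nan)
                continue
            idx = _individual_index(value, direction, refs[ep][0])
            row[ep] = idx
            indices.append(idx)
            available[k] = True
        index_rows[sample] = row
        if not available.any():
            raise UnscorableSampleError(f"sample {sample!r}: all parameters ND")
        idx_arr = np.asarray(indices, dtype=float)
        if config.nd_policy == "zero":
            idx_arr = np.where(available, idx_arr, 0.0)
            raw_scores[sample] = float(idx_arr @ weights / weights.sum())
        else:  # exclude: re-average over available parameters
            w = weights[available]
            raw_scores[sample] = float(idx_arr[available] @ w / w.sum())
    raw = pd.Series(raw_scores, name="score")
    rounded = raw.map(lambda v: _round(v, config.rounding)).astype(int)
    return rounded, raw, pd.DataFrame.from_dict(index_rows, orient="index"), refs


def ahci(panel: AssayPanel, config: IndexConfig | None = None) -> pd.Series:
    """Antihyperglycemic composite index per sample (rounded integers)."""
    config = config or IndexConfig(parameters=AHCI_PARAMETERS)
    return composite_index(panel, config)[0]


def ogrci(panel: AssayPanel, config: IndexConfig | None = None) -> pd.Series:
    """Oxidation-glycation reduction composite index per sample."""
    config = config or IndexConfig(parameters=OGRCI_PARAMETERS)
    return composite_index(panel, config)[0]


def overall_score(ahci_score: float, ogrci_score: float, rounding: str = "nearest") -> int:
    """Overall antidiabetic potential: the mean of AHCI and OGRCI."""
    if ahci_score is None or ogrci_score is None:
        raise UnscorableSampleError("both AHCI and OGRCI are required")
    return _round((ahci_score + ogrci_score) / 2.0, rounding)


def score_panel(
    panel: AssayPanel,
    ahci_config: IndexConfig | None = None,
    ogrci_config: IndexConfig | None = None,
) -> CompositeScoreSet:
    """Compute AHCI, OGRCI and the overall score for every sample."""
    ahci_config = ahci_config or IndexConfig(parameters=AHCI_PARAMETERS)
    ogrci_config = ogrci_config or IndexConfig(parameters=OGRCI_PARAMETERS)
    a_round, a_raw, a_idx, a_refs = composite_index(panel, ahci_config)
    o_round, o_raw, o_idx, o_refs = composite_index(panel, ogrci_config)
    samples = a_round.index.intersection(o_round.index)
    overall = pd.Series(
        {
            s: overall_score(int(a_round[s]), int(o_round[s]), ahci_config.rounding)
            for s in samples
        },
        name="overall",
    ).astype(int)
    return CompositeScoreSet(
        indices=pd.concat([a_idx, o_idx], axis=1),
        ahci=a_round,
        ogrci=o_round,
        overall=overall,
        ahci_raw=a_raw,
        ogrci_raw=o_raw,
        reference_values={**a_refs, **o_refs},
    )


def rank_samples(scores: CompositeScoreSet) -> pd.DataFrame:
    """Rank samples by overall score, descending; ties keep input order.

    Returns a DataFrame with columns ``sample_id, ahci, ogrci, overall,
    rank, tied`` where ``tied`` flags samples sharing their overall score
    with another sample.
    """
    if len(scores.overall) < 1:
        raise ValueError("at least one sample is required")
    df = pd.DataFrame(
        {
            "sample_id": scores.overall.index,
            "ahci": scores.ahci.reindex(scores.overall.index).values,
            "ogrci": scores.ogrci.reindex(scores.overall.index).values,
            "overall": scores.overall.values,
        }
    )
    # stable sort keeps input order within ties
    df = df.sort_values("overall", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = df["overall"].rank(method="min", ascending=False).astype(int)
    df["tied"] = df.duplicated("overall", keep=False)
    return df
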