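"""Seeded synthetic-data generators for every pipeline input.

Emulates the study designs the pipeline consumes at desk scale:
triplicate endpoint measurements with Gaussian noise around target
mean/SD cells, sigmoidal dose-response series with known IC50 and Hill
slope, and genotype-structured log-normal metabolite abundance matrices
with planted marker compounds.  Every generator is bit-reproducible for a
fixed seed, and ground-truth labels are always returned alongside the
data so recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import ND_TOKEN, RESPONSE_BAND, DoseResponseSeries
from .errors import ParameterError
from .profiling import AbundanceMatrix


@dataclass
class GeneratorSpec:
    """Common knobs of a synthetic-data generator.

    ``noise_sd`` is the Gaussian noise standard deviation; with
    ``noise_relative`` it is interpreted as a fraction of the clean signal
    instead of an absolute value in response units.
    """

    seed: int = 0
    noise_sd: float = 2.0
    noise_relative: bool = False
    n_replicates: int = 3
    design: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")


def fourpl_response(concentration, ic50: float, hill: float) -> np.ndarray:
    """Clean percent-inhibition response 100 * c^h / (IC50^h + c^h)."""
    c = np.asarray(concentration, dtype=float)
    return 100.0 * c**hill / (ic50**hill + c**hill)


def gen_dose_response(
    ic50: float,
    hill: float,
    concentrations,
    spec: GeneratorSpec | None = None,
    analyte_id: str = "synthetic",
    assay_id: str = "amylase",
) -> DoseResponseSeries:
    """Noisy sigmoidal dose-response series with known IC50.

    Each reported response is the mean of ``n_replicates`` Gaussian draws
    around the four-parameter-logistic curve, truncated to the plate
    tolerance band [-20, 120].
    """
    spec = spec or GeneratorSpec()
    if ic50 <= 0 or hill <= 0:
        raise ParameterError("ic50 and hill must be positive")
    c = np.asarray(concentrations, dtype=float)
    if c.size == 0:
        raise ParameterError("concentration grid must be nonempty")
    rng = np.random.default_rng(spec.seed)
    clean = fourpl_response(c, ic50, hill)
    sd = spec.noise_sd * (np.abs(clean) / 100.0 if spec.noise_relative else 1.0)
    draws = rng.normal(clean[None, :], np.broadcast_to(sd, (1, c.size)), size=(spec.n_replicates, c.size))
    responses = np.clip(draws.mean(axis=0), *RESPONSE_BAND)
    return DoseResponseSeries(
        analyte_id=analyte_id,
        assay_id=assay_id,
        concentrations=c,
        responses=responses,
        n_replicates=spec.n_replicates,
    )


def gen_assay_panel(targets: pd.DataFrame, spec: GeneratorSpec | None = None) -> pd.DataFrame:
    """Replicate tables drawn from target mean/SD cells.

    ``targets`` has columns ``sample_id, endpoint_id, mean, sd`` plus
    optional ``unit`` and ``role``; a cell whose mean is the literal token
    ``"ND"`` (or NaN) propagates as ND replicates.  Returns a long table
    with one row per replicate, ready for
    :func:`nutrascreen.assay.summarize_replicates`.
    """
    spec = spec or GeneratorSpec()
    required = {"sample_id", "endpoint_id", "mean", "sd"}
    if not required.issubset(targets.columns):
        raise ParameterError(f"targets must have columns {sorted(required)}")
    sd_numeric = pd.to_numeric(targets["sd"], errors="coerce")
    if (sd_numeric.dropna() < 0).any():
        raise ParameterError("target SD must be nonnegative")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for _, row in targets.iterrows():
        unit = row.get("unit", "% inhibition")
        role = row.get("role", "sample")
        mean = row["mean"]
        is_nd = (isinstance(mean, str) and mean.strip() == ND_TOKEN) or pd.isna(mean)
        for rep in range(1, spec.n_replicates + 1):
            if is_nd:
                value: object = ND_TOKEN
            else:
                value = rng.normal(float(mean), float(row["sd"]))
            rows.append(
                {
                    "sample_id": row["sample_id"],
                    "endpoint_id": row["endpoint_id"],
                    "replicate": rep,
                    "value": value,
                    "unit": unit,
                    "role": role,
                }
            )
    return pd.DataFrame(rows)


def gen_metabolite_matrix(
    n_compounds: int,
    groups: dict,
    n_markers: int = 10,
    fold_change: float = 8.0,
    spec: GeneratorSpec | None = None,
    base_log_mean: float = 10.0,
    base_log_sd: float = 1.0,
    noise_log_sd: float = 0.25,
) -> tuple[AbundanceMatrix, dict]:
    """Genotype-structured log-normal abundance matrix with planted markers.

    ``groups`` maps group name -> number of samples.  Each group receives
    ``n_markers`` dedicated marker compounds whose abundance is multiplied
    by ``fold_change`` in that group only; all compounds carry log-normal
    biological noise.  Returns the matrix plus ground truth:
    ``{"sample_groups": {sample: group}, "markers": {group: [compound]}}``.
    """
    spec = spec or GeneratorSpec()
    if len(groups) < 2:
        raise ParameterError("need >= 2 groups")
    if fold_change <= 0:
        raise ParameterError("fold_change must be positive")
    if n_markers * len(groups) > n_compounds:
        raise ParameterError(
            f"{n_markers} markers x {len(groups)} groups exceed {n_compounds} compounds"
        )
    rng = np.random.default_rng(spec.seed)
    compounds = [f"compound_{i:03d}" for i in range(n_compounds)]
    samples, sample_groups = [], {}
    for gname, count in groups.items():
        for j in range(1, count + 1):
            sid = f"{gname}_{j}"
            samples.append(sid)
            sample_groups[sid] = gname
    base = rng.normal(base_log_mean, base_log_sd, size=n_compounds)
    log_abund = base[:, None] + rng.normal(0.0, noise_log_sd, size=(n_compounds, len(samples)))
    markers: dict = {}
    next_row = 0
    for gname in groups:
        rows = list(range(next_row, next_row + n_markers))
        next_row += n_markers
        markers[gname] = [compounds[i] for i in rows]
        cols = [k for k, s in enumerate(samples) if sample_groups[s] == gname]
        log_abund[np.ix_(rows, cols)] += np.log(fold_change)
    data = pd.DataFrame(np.exp(log_abund), index=compounds, columns=samples)
    truth = {"sample_groups": sample_groups, "markers": markers}
    return AbundanceMatrix(data, normalization="raw"), truth
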