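"""Quantification of plate-reader assay signals.

Turns raw microplate readouts into the endpoint quantities a bioactivity
panel reports: percent inhibition, IC50 from dose-response series,
calibrated equivalents (gallic-acid, quercetin, Fe²⁺, Trolox) and
replicate summaries (mean ± SD).  Concentrations are µg/mL throughout;
unit conversion is the loader's job.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DegenerateCurveError,
    InsufficientStandardsError,
    InvalidControlError,
    MissingDataError,
    NotEstimableError,
)

#: Closed vocabulary of panel unit tags.
UNIT_TAGS = frozenset(
    {
        "IC50 µg/mL",
        "% inhibition",
        "µmol Fe2+/g",
        "µmol TE/g",
        "mg GAE/100 g",
        "mg QE/100 g",
    }
)

#: Assays for which dose-response series are collected.
ASSAY_IDS = frozenset({"amylase", "glucosidase", "dppiv", "ptp1b", "dpph"})

#: Token used for missing values in every CSV the pipeline reads or writes.
ND_TOKEN = "ND"

#: Tolerance band for noisy plate responses, in percent inhibition.
RESPONSE_BAND = (-20.0, 120.0)


@dataclass
class DoseResponseSeries:
    """Concentration/response pairs behind a single IC50 estimate.

    ``concentrations`` must be strictly positive and strictly increasing;
    ``responses`` are percent-inhibition values within the plate tolerance
    band [-20, 120].
    """

    analyte_id: str
    assay_id: str
    concentrations: np.ndarray
    responses: np.ndarray
    n_replicates: int = 3

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.assay_id not in ASSAY_IDS:
            raise ValueError(f"unknown assay_id {self.assay_id!r}; expected one of {sorted(ASSAY_IDS)}")
        if self.concentrations.ndim != 1 or len(self.concentrations) == 0:
            raise ValueError("concentrations must be a nonempty 1-D sequence")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if len(self.responses) != len(self.concentrations):
            raise ValueError("responses and concentrations must have equal length")
        lo, hi = RESPONSE_BAND
        if np.any(self.responses < lo) or np.any(self.responses > hi):
            raise ValueError(f"responses must lie within [{lo}, {hi}]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")


@dataclass
class CalibrationCurve:
    """Ordinary-least-squares standard curve (response vs concentration)."""

    standard_name: str
    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.valid_range
        if not (0 <= lo < hi):
            raise ValueError("valid_range must satisfy 0 <= low < high")
        if not (0 <= self.r_squared <= 1):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class IC50Fit:
    """Result of an IC50 estimation, with fit diagnostics."""

    ic50: float
    method: str  # "fourpl" | "loglinear"
    hill: float | None = None
    top: float | None = None
    bottom: float | None = None
    residual_sd: float | None = None
    converged: bool = True


class AssayPanel:
    """Per-sample, per-endpoint summary values (mean, SD, n, unit, ND flag).

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``sample_id, endpoint_id, mean, sd, n, unit, nd_flag`` (plus an optional
    ``role`` column separating samples from positive controls).  Missing
    cells carry ``nd_flag == True`` and a NaN mean.
    """

    COLUMNS = ["sample_id", "endpoint_id", "mean", "sd", "n", "unit", "nd_flag"]

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"panel is missing columns {missing}")
        df = data.copy().reset_index(drop=True)
        df["nd_flag"] = df["nd_flag"].astype(bool)
        numeric = ~df["nd_flag"]
        if df.loc[numeric, "sd"].lt(0).any():
            raise ValueError("SD must be nonnegative")
        if df.loc[numeric, "n"].lt(1).any():
            raise ValueError("n must be >= 1")
        if df.loc[numeric, "mean"].isna().any():
            raise ValueError("non-ND rows must carry a numeric mean")
        bad_units = set(df["unit"]) - UNIT_TAGS
        if bad_units:
            raise ValueError(f"unknown unit tags {sorted(bad_units)}")
        per_endpoint = df.groupby("endpoint_id")["unit"].nunique()
        if (per_endpoint > 1).any():
            raise ValueError("unit tag must be consistent within an endpoint")
        if df.duplicated(["sample_id", "endpoint_id"]).any():
            raise ValueError("duplicate (sample_id, endpoint_id) rows")
        self.data = df

    # -- access -------------------------------------------------------------
    def samples(self, role: str | None = None) -> list[str]:
        df = self.data
        if role is not None and "role" in df.columns:
            df = df[df["role"] == role]
        return list(dict.fromkeys(df["sample_id"]))

    def endpoints(self) -> list[str]:
        return list(dict.fromkeys(self.data["endpoint_id"]))

    def value(self, sample_id: str, endpoint_id: str) -> float | None:
        """Mean value of a cell, or None when the cell is ND or absent."""
        rows = self.data[
            (self.data["sample_id"] == sample_id)
            & (self.data["endpoint_id"] == endpoint_id)
        ]
        if rows.empty or bool(rows.iloc[0]["nd_flag"]):
            return None
        return float(rows.iloc[0]["mean"])

    def subset(self, endpoint_ids) -> "AssayPanel":
        return AssayPanel(self.data[self.data["endpoint_id"].isin(endpoint_ids)])

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "AssayPanel":
        df = pd.read_csv(path, dtype={"sample_id": str, "endpoint_id": str})
        if "nd_flag" not in df.columns:
            df["nd_flag"] = False
        df["mean"] = pd.to_numeric(df["mean"].replace(ND_TOKEN, np.nan), errors="coerce")
        df["nd_flag"] = df["nd_flag"].fillna(False).astype(bool) | df["mean"].isna()
        df["sd"] = pd.to_numeric(df.get("sd"), errors="coerce").fillna(0.0)
        df["n"] = pd.to_numeric(df.get("n"), errors="coerce").fillna(1).astype(int)
        return cls(df)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["mean"] = out["mean"].astype(object)
        out.loc[out["nd_flag"], "mean"] = ND_TOKEN
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def percent_inhibition(sample_signal: float, control_signal: float) -> float:
    """Percent inhibition of a signal relative to an uninhibited control.

    Computes ``(1 - sample/control) * 100``.  Negative values (sample signal
    above the control) are returned as-is so QC can flag them; they are never
    clamped here.
    """
    if control_signal <= 0:
        raise InvalidControlError(
            f"control signal must be positive, got {control_signal}"
        )
    if sample_signal < 0:
        raise ValueError(f"sample signal must be nonnegative, got {sample_signal}")
    value = (1.0 - sample_signal / control_signal) * 100.0
    if value < 0:
        warnings.warn(
            f"negative inhibition ({value:.2f} %): sample signal exceeds control",
            stacklevel=2,
        )
    return value


def fit_standard_curve(concentrations, responses, standard_name: str = "standard") -> CalibrationCurve:
    """Fit an OLS line response = slope * concentration + intercept."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(x) < 3:
        raise InsufficientStandardsError(
            f"need >= 3 standards, got {len(x)}"
        )
    if len(np.unique(x)) != len(x):
        raise ValueError("standard concentrations must be distinct")
    if np.allclose(y, y[0]):
        raise DegenerateCurveError("constant responses: slope 0, R² undefined")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        standard_name=standard_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        valid_range=(float(x.min()), float(x.max())),
    )


def quantify_equivalents(
    curve: CalibrationCurve,
    response: float,
    dilution_factor: float = 1.0,
    sample_mass_g: float = 1.0,
    basis: str = "per-g",
) -> float:
    """Convert a calibrated response into standard equivalents.

    The back-calculated concentration ``(response - intercept)/slope`` is
    scaled by the dilution factor and divided by the sample mass; ``basis``
    selects the reporting denominator (``per-g`` or ``per-100g``).
    """
    if curve.slope == 0:
        raise DegenerateCurveError("slope 0: cannot invert calibration curve")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    if sample_mass_g <= 0:
        raise ValueError("sample_mass_g must be positive")
    if basis not in {"per-g", "per-100g"}:
        raise ValueError("basis must be 'per-g' or 'per-100g'")
    conc = (response - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    span = hi - lo
    if conc < lo - 0.05 * span or conc > hi + 0.05 * span:
        warnings.warn(
            f"back-calculated concentration {conc:.3g} outside calibration "
            f"range [{lo}, {hi}]",
            stacklevel=2,
        )
    value = conc * dilution_factor / sample_mass_g
    if basis == "per-100g":
        value *= 100.0
    return value


def _fourpl(x, bottom, top, log_ic50, hill):
    # increasing logistic: response rises from `bottom` to `top` with x
    return bottom + (top - bottom) / (1.0 + (10.0**log_ic50 / x) ** hill)


def _loglinear_ic50(series: DoseResponseSeries) -> IC50Fit:
    c = series.concentrations
    r = series.responses
    above = r >= 50.0
    if above.all():
        raise NotEstimableError("all responses above 50 %: IC50 < min concentration", "<min")
    if not above.any():
        raise NotEstimableError("no response reaches 50 %: IC50 > max concentration", ">max")
    # first index where the series crosses 50 from below
    idx = int(np.argmax(above)) if not above[0] else int(np.argmax(~above))
    lo, hi = idx - 1, idx
    if above[0]:  # series starts above 50 (decreasing tail); find downward crossing
        lo, hi = idx - 1, idx
    r0, r1 = r[lo], r[hi]
    if r1 == r0:
        log_ic50 = (math.log10(c[lo]) + math.log10(c[hi])) / 2.0
    else:
        frac = (50.0 - r0) / (r1 - r0)
        log_ic50 = math.log10(c[lo]) + frac * (math.log10(c[hi]) - math.log10(c[lo]))
    return IC50Fit(ic50=float(10**log_ic50), method="loglinear")


def estimate_ic50(series: DoseResponseSeries, method: str = "fourpl") -> IC50Fit:
    """Estimate the concentration producing 50 % inhibition.

    ``fourpl`` fits the four-parameter logistic
    ``bottom + (top - bottom)/(1 + (IC50/x)^h)`` by nonlinear least squares
    and falls back to log-linear interpolation when the fit fails;
    ``loglinear`` interpolates log-concentration between the two points
    bracketing 50 %.  Raises :class:`NotEstimableError` (with a ``">max"`` /
    ``"<min"`` bound) when 50 % is never bracketed.
    """
    if method not in {"fourpl", "loglinear"}:
        raise ValueError("method must be 'fourpl' or 'loglinear'")
    if method == "loglinear":
        return _loglinear_ic50(series)

    c = series.concentrations
    r = series.responses
    if len(c) < 4:
        return _loglinear_ic50(series)
    if r.max() < 50.0:
        raise NotEstimableError("no response reaches 50 %: IC50 > max concentration", ">max")
    if r.min() > 50.0:
        raise NotEstimableError("all responses above 50 %: IC50 < min concentration", "<min")

    logc = np.log10(c)
    # initial guess: midpoint crossing, unit Hill slope
    guess_mid = float(np.interp(50.0, np.sort(r), logc[np.argsort(r)]))
    # an asymptote is identifiable only when its plateau was sampled;
    # otherwise it is pinned to the theoretical 0 / 100 of a
    # control-normalized inhibition curve (standard dose-response practice)
    fit_bottom = bool(r.min() <= 20.0)
    fit_top = bool(r.max() >= 80.0)

    def model(x, *params):
        i = 0
        bottom = 0.0
        top = 100.0
        if fit_bottom:
            bottom = params[i]
            i += 1
        if fit_top:
            top = params[i]
            i += 1
        return _fourpl(x, bottom, top, params[i], params[i + 1])

    p0: list = []
    lower: list = []
    upper: list = []
    if fit_bottom:
        p0 += [0.0]; lower += [-5.0]; upper += [30.0]
    if fit_top:
        p0 += [100.0]; lower += [70.0]; upper += [120.0]
    p0 += [guess_mid, 1.0]
    lower += [logc.min() - 3.0, 0.05]
    upper += [logc.max() + 3.0, 10.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, c, r, p0=p0, bounds=(lower, upper), maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        bottom = float(popt[0]) if fit_bottom else 0.0
        top = float(popt[1] if fit_bottom else popt[0]) if fit_top else 100.0
        log_ic50, hill = popt[-2], popt[-1]
        resid = r - model(c, *popt)
        dof = max(len(c) - len(popt), 1)
        fit = IC50Fit(
            ic50=float(10**log_ic50),
            method="fourpl",
            hill=float(hill),
            top=float(top),
            bottom=float(bottom),
            residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        )
        # reject fits that run away from the sampled range
        if not (c.min() / 1e3 <= fit.ic50 <= c.max() * 1e3):
            raise RuntimeError("fourpl fit outside plausible range")
        return fit
    except (RuntimeError, ValueError):
        fit = _loglinear_ic50(series)
        fit.converged = False
        return fit


def summarize_replicates(raw: pd.DataFrame) -> AssayPanel:
    """Aggregate replicate endpoint measurements into an AssayPanel.

    ``raw`` is a long table with columns ``sample_id, endpoint_id, value``
    and optionally ``unit`` and ``role``.  Values equal to the literal token
    ``"ND"`` mark non-detectable cells: a group whose replicates are all ND
    becomes an ND panel row.  SD uses the n-1 (sample) denominator; a single
    replicate yields SD 0 with a warning.
    """
    required = {"sample_id", "endpoint_id", "value"}
    if not required.issubset(raw.columns):
        raise ValueError(f"raw table must have columns {sorted(required)}")
    if raw.empty:
        raise MissingDataError("empty replicate table")
    rows = []
    keys = ["sample_id", "endpoint_id"]
    for (sample, endpoint), grp in raw.groupby(keys, sort=False):
        unit = grp["unit"].iloc[0] if "unit" in grp.columns else "% inhibition"
        role = grp["role"].iloc[0] if "role" in grp.columns else "sample"
        values = grp["value"]
        nd_mask = values.astype(str).str.strip().eq(ND_TOKEN)
        numeric = pd.to_numeric(values[~nd_mask], errors="raise").astype(float)
        if nd_mask.all():
            rows.append((sample, endpoint, np.nan, 0.0, int(nd_mask.sum()), unit, True, role))
            continue
        if numeric.empty:
            raise MissingDataError(f"({sample}, {endpoint}): no replicate values")
        n = len(numeric)
        if n == 1:
            warnings.warn(
                f"({sample}, {endpoint}): single replicate, SD set to 0",
                stacklevel=2,
            )
            sd = 0.0
        else:
            sd = float(numeric.std(ddof=1))
        rows.append((sample, endpoint, float(numeric.mean()), sd, n, unit, False, role))
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "endpoint_id", "mean", "sd", "n", "unit", "nd_flag", "role"],
    )
    return AssayPanel(df)
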