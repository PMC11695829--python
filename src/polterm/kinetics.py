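"""In vitro kinetics: anisotropy decay fits, binding isotherms, reporters.

Fluorescence-anisotropy degradation traces are rescaled to the unit
interval and fitted with a single-exponential decay carrying a free plateau,

    y(t) = (1 - c) * exp(-k t) + c,        k > 0,  c < 1,

with the substrate half-life defined parametrically as ln 2 / k.  The
plateau c may fit below zero: a trace truncated before reaching its plateau
and then rescaled to [0, 1] is exactly such a curve.  RNA
binding titrations are fitted with the probe-depletion (quadratic) 1:1
isotherm

    f = ((P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)) / (2 L),
    anisotropy = a_free + (a_bound - a_free) * f,

where P is total protein, L total labelled probe; with L << Kd this reduces
to the hyperbola f = P / (P + Kd).  Both fits are exposed statsmodels-style:
a model object built from data whose ``fit()`` returns a results object
with estimates, standard errors from the residual covariance, diagnostics
and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class DecayTrace:
    """An anisotropy degradation time course."""

    time: np.ndarray
    anisotropy: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.anisotropy, dtype=float)
        if t.size < 5:
            raise ValueError("decay trace needs at least 5 points")
        if t.size != y.size:
            raise ValueError("time and anisotropy lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "anisotropy", y)

    @classmethod
    def from_tsv(cls, path: str, time_col: str = "time",
                 value_col: str = "anisotropy", label: str = "") -> "DecayTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(df[time_col].to_numpy(), df[value_col].to_numpy(),
                   label=label or path)


@dataclass(frozen=True)
class Titration:
    """A protein-concentration series at fixed labelled-probe concentration."""

    protein_conc: np.ndarray
    anisotropy: np.ndarray
    probe_conc: float = 50e-9

    def __post_init__(self):
        p = np.asarray(self.protein_conc, dtype=float)
        y = np.asarray(self.anisotropy, dtype=float)
        if p.size < 5:
            raise ValueError("titration needs at least 5 points")
        if p.size != y.size:
            raise ValueError("concentration and anisotropy lengths differ")
        if np.any(p < 0) or np.any(np.diff(p) <= 0):
            raise ValueError("protein concentrations must be >= 0 and strictly increasing")
        if self.probe_conc <= 0:
            raise ValueError("probe concentration must be > 0")
        object.__setattr__(self, "protein_conc", p)
        object.__setattr__(self, "anisotropy", y)

    @classmethod
    def from_tsv(cls, path: str, conc_col: str = "protein_conc",
                 value_col: str = "anisotropy", probe_conc: float = 50e-9) -> "Titration":
        df = pd.read_csv(path, sep="\t")
        return cls(df[conc_col].to_numpy(), df[value_col].to_numpy(),
                   probe_conc=probe_conc)


@dataclass(frozen=True)
class ReporterReading:
    """One phosphatase-reporter measurement."""

    a400: float
    od: float
    blank: float
    condition: str

    def __post_init__(self):
        if self.od <= 0:
            raise ValueError("culture OD must be > 0")


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

def rescale_unit_interval(trace: DecayTrace) -> DecayTrace:
    """Affine-map a trace's anisotropy onto [0, 1] (idempotent)."""
    y = trace.anisotropy
    ymin, ymax = float(y.min()), float(y.max())
    if ymax <= ymin:
        raise ValueError("constant trace cannot be rescaled to [0, 1]")
    return replace(trace, anisotropy=(y - ymin) / (ymax - ymin))


# ---------------------------------------------------------------------------
# exponential decay
# ---------------------------------------------------------------------------

def _exp_model(t, k, c):
    return (1.0 - c) * np.exp(-k * t) + c


@dataclass
class DecayFitResults:
    """Results of an exponential decay fit.

    ``half_life`` is ln 2 / k (parametric, not the time to cross 0.5).
    ``bse`` are standard errors from the covariance of the least-squares
    estimate; NaN when the covariance is singular.
    """

    k: float
    plateau: float
    half_life: float
    residual_norm: float
    success: bool
    message: str = ""
    cov: np.ndarray | None = None
    nobs: int = 0
    label: str = ""

    @property
    def params(self) -> pd.Series:
        return pd.Series({"k": self.k, "plateau": self.plateau})

    @property
    def bse(self) -> pd.Series:
        if self.cov is None:
            return pd.Series({"k": np.nan, "plateau": np.nan})
        se = np.sqrt(np.diag(self.cov))
        return pd.Series({"k": se[0], "plateau": se[1]})

    def predict(self, t) -> np.ndarray:
        return _exp_model(np.asarray(t, dtype=float), self.k, self.plateau)

    def summary(self) -> str:
        lines = [
            f"Exponential decay fit{': ' + self.label if self.label else ''}",
            "=" * 46,
            f"model: y(t) = (1 - c) exp(-k t) + c   n = {self.nobs}",
            f"converged: {self.success}  {self.message}",
        ]
        se = self.bse
        lines += [
            f"k         {self.k: .6g}  (se {se['k']:.3g})  1/s",
            f"plateau c {self.plateau: .6g}  (se {se['plateau']:.3g})",
            f"half-life {self.half_life: .6g}  s  (ln 2 / k)",
            f"residual norm {self.residual_norm: .4g}",
        ]
        return "\n".join(lines)


class ExponentialDecay:
    """Single-exponential decay model for a rescaled anisotropy trace.

    Parameters
    ----------
    trace : DecayTrace
        The time course; rescaled to [0, 1] on construction unless already
        within the unit interval.
    """

    def __init__(self, trace: DecayTrace, rescale: bool = True):
        if rescale:
            trace = rescale_unit_interval(trace)
        self.trace = trace

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time",
                       value_col: str = "anisotropy", label: str = "") -> "ExponentialDecay":
        return cls(DecayTrace(df[time_col].to_numpy(),
                              df[value_col].to_numpy(), label=label))

    def _initial_rate(self) -> float:
        """Log-linear regression on the upper half of the decay (the points
        with signal above the mid-level), where the plateau matters least."""
        t, y = self.trace.time, self.trace.anisotropy
        mid = 0.5 * (y.max() + y.min())
        mask = y > mid
        if mask.sum() < 2:
            mask = np.ones_like(y, dtype=bool)
        yy = np.clip(y[mask], 1e-9, None)
        slope = np.polyfit(t[mask], np.log(yy), 1)[0]
        return max(-slope, 1e-12)

    def fit(self, xtol: float = 1e-8, max_nfev: int = 10_000) -> DecayFitResults:
        t, y = self.trace.time, self.trace.anisotropy
        failure = DecayFitResults(
            k=np.nan, plateau=np.nan, half_life=np.nan,
            residual_norm=np.nan, success=False, nobs=t.size,
            label=self.trace.label,
        )
        # non-decaying data: overall trend must be downward
        if np.polyfit(t, y, 1)[0] >= 0:
            failure.message = "no decay detected (signal does not decrease)"
            return failure
        k0 = self._initial_rate()
        c0 = float(np.clip(y[-1], -0.9, 0.99))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                # the plateau may fit below 0: a trace truncated before its
                # plateau, rescaled to [0, 1], has effective c = -m/(1-m) < 0
                popt, pcov = curve_fit(
                    _exp_model, t, y, p0=(k0, c0),
                    bounds=([0.0, -10.0], [np.inf, 1.0 - 1e-12]),
                    xtol=xtol, max_nfev=max_nfev,
                )
        except (RuntimeError, ValueError) as exc:
            failure.message = f"optimizer failed: {exc}"
            return failure
        k, c = float(popt[0]), float(popt[1])
        resid = y - _exp_model(t, k, c)
        if k <= 0 or not np.isfinite(k):
            failure.message = "no decay detected (k <= 0)"
            return failure
        return DecayFitResults(
            k=k, plateau=c, half_life=float(np.log(2) / k),
            residual_norm=float(np.linalg.norm(resid)),
            success=True, message="converged", cov=pcov, nobs=t.size,
            label=self.trace.label,
        )


def fit_exponential(trace: DecayTrace) -> DecayFitResults:
    """Rescale a trace to [0, 1] and fit the plateau-exponential model."""
    return ExponentialDecay(trace).fit()


def halflife_fold(res_a: DecayFitResults, res_b: DecayFitResults) -> float:
    """Half-life ratio a/b of two successful fits."""
    if not (res_a.success and res_b.success):
        raise ValueError("both decay fits must have succeeded")
    return res_a.half_life / res_b.half_life


def refit_decay_table(path: str, time_col: str = "time") -> pd.DataFrame:
    """Refit every trace column of a TSV time-course table.

    The file must carry a time column; every other numeric column is taken
    as one anisotropy trace.  Returns one row per trace with the rate,
    plateau and half-life.
    """
    df = pd.read_csv(path, sep="\t")
    rows = []
    for col in df.columns:
        if col == time_col:
            continue
        sub = df[[time_col, col]].dropna()
        res = fit_exponential(
            DecayTrace(sub[time_col].to_numpy(), sub[col].to_numpy(), label=col)
        )
        rows.append({
            "trace": col, "k": res.k, "plateau": res.plateau,
            "half_life": res.half_life, "success": res.success,
        })
    return pd.DataFrame(rows).set_index("trace")


# ---------------------------------------------------------------------------
# binding isotherm
# ---------------------------------------------------------------------------

def fraction_bound(P, L: float, Kd: float):
    """Probe fraction bound under the depletion-aware 1:1 isotherm."""
    P = np.asarray(P, dtype=float)
    s = P + L + Kd
    return (s - np.sqrt(s * s - 4.0 * P * L)) / (2.0 * L)


@dataclass
class BindingFitResults:
    """Results of a 1:1 binding-isotherm fit."""

    Kd: float
    anisotropy_free: float
    anisotropy_bound: float
    residual_norm: float
    success: bool
    message: str = ""
    cov: np.ndarray | None = None
    probe_conc: float = np.nan
    nobs: int = 0

    @property
    def params(self) -> pd.Series:
        return pd.Series({
            "Kd": self.Kd,
            "anisotropy_free": self.anisotropy_free,
            "anisotropy_bound": self.anisotropy_bound,
        })

    @property
    def bse(self) -> pd.Series:
        if self.cov is None:
            return pd.Series(
                dict.fromkeys(("Kd", "anisotropy_free", "anisotropy_bound"), np.nan)
            )
        se = np.sqrt(np.diag(self.cov))
        return pd.Series({
            "Kd": se[0], "anisotropy_free": se[1], "anisotropy_bound": se[2],
        })

    def predict(self, P) -> np.ndarray:
        f = fraction_bound(P, self.probe_conc, self.Kd)
        return self.anisotropy_free + (self.anisotropy_bound - self.anisotropy_free) * f

    def summary(self) -> str:
        se = self.bse
        return "\n".join([
            "1:1 binding isotherm fit (probe depletion)",
            "=" * 46,
            f"probe L = {self.probe_conc:.3g} M   n = {self.nobs}",
            f"converged: {self.success}  {self.message}",
            f"Kd        {self.Kd: .6g}  (se {se['Kd']:.3g})  M",
            f"a_free    {self.anisotropy_free: .6g}  (se {se['anisotropy_free']:.3g})",
            f"a_bound   {self.anisotropy_bound: .6g}  (se {se['anisotropy_bound']:.3g})",
            f"residual norm {self.residual_norm: .4g}",
        ])


class BindingIsotherm:
    """Depletion-aware 1:1 binding model for an anisotropy titration."""

    def __init__(self, titration: Titration):
        conc = titration.protein_conc
        if conc[conc > 0].size and conc.max() / max(conc[conc > 0].min(), 1e-30) < 10:
            warnings.warn("titration spans < 10-fold concentration range")
        self.titration = titration

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, conc_col: str = "protein_conc",
                       value_col: str = "anisotropy",
                       probe_conc: float = 50e-9) -> "BindingIsotherm":
        return cls(Titration(df[conc_col].to_numpy(), df[value_col].to_numpy(),
                             probe_conc=probe_conc))

    def fit(self, xtol: float = 1e-8, max_nfev: int = 10_000) -> BindingFitResults:
        t = self.titration
        P, y, L = t.protein_conc, t.anisotropy, t.probe_conc

        def model(P, Kd, a_free, a_bound):
            return a_free + (a_bound - a_free) * fraction_bound(P, L, Kd)

        a0, a1 = float(y[0]), float(y[-1])
        # initial Kd: concentration at the half-rise of the curve
        half = 0.5 * (a0 + a1)
        idx = int(np.argmin(np.abs(y - half)))
        kd0 = max(float(P[idx]), L / 10.0, 1e-12)
        failure = BindingFitResults(
            Kd=np.nan, anisotropy_free=np.nan, anisotropy_bound=np.nan,
            residual_norm=np.nan, success=False, probe_conc=L, nobs=P.size,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model, P, y, p0=(kd0, a0, a1),
                    bounds=([1e-15, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                    xtol=xtol, max_nfev=max_nfev,
                )
        except (RuntimeError, ValueError) as exc:
            failure.message = f"optimizer failed: {exc}"
            return failure
        Kd, a_free, a_bound = map(float, popt)
        resid = y - model(P, *popt)
        if not np.isfinite(Kd) or a_bound == a_free:
            failure.message = "degenerate fit (no binding signal)"
            return failure
        return BindingFitResults(
            Kd=Kd, anisotropy_free=a_free, anisotropy_bound=a_bound,
            residual_norm=float(np.linalg.norm(resid)),
            success=True, message="converged", cov=pcov, probe_conc=L,
            nobs=P.size,
        )


def fit_binding(titration: Titration) -> BindingFitResults:
    return BindingIsotherm(titration).fit()


# ---------------------------------------------------------------------------
# reporter assay
# ---------------------------------------------------------------------------

def reporter_activity(readings, scale_to_control: bool = True,
                      control_condition: str = "control") -> pd.DataFrame:
    """Blank-corrected, OD-normalised phosphatase activity per reading.

    activity = (A400 - blank) / OD; negative blank-corrected absorbances are
    clipped to zero with a warning.  With ``scale_to_control`` every value is
    divided by the mean activity of the control condition (control mean
    becomes exactly 1).
    """
    readings = list(readings)
    if not readings:
        raise ValueError("no readings")
    rows = []
    clipped = 0
    for r in readings:
        net = r.a400 - r.blank
        if net < 0:
            clipped += 1
            net = 0.0
        rows.append({"condition": r.condition, "activity": net / r.od})
    if clipped:
        warnings.warn(f"{clipped} reading(s) below blank; clipped to 0")
    df = pd.DataFrame(rows)
    if scale_to_control:
        ctrl = df.loc[df["condition"] == control_condition, "activity"]
        if ctrl.empty:
            raise ValueError(f"no readings in condition {control_condition!r}")
        mean_ctrl = ctrl.mean()
        if mean_ctrl <= 0:
            raise ValueError("control activity is zero; cannot scale")
        df["scaled_activity"] = df["activity"] / mean_ctrl
    return df
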