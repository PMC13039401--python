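"""Degradation-kinetics model fitting.

Translation-shutoff and pulse-chase experiments yield fraction-remaining
time courses.  Two kinetic models cover the observed behaviors:

* ``single_plateau`` — Y(t) = A·exp(−k·t) + C, a single-exponential
  decay in which a fraction C of the protein remains stable over time
  (e.g. the ~40% of ASBT-L73Q that escapes degradation);
* ``double_exp`` — Y(t) = A1·exp(−k1·t) + A2·exp(−k2·t), biphasic decay
  with fast and slow pools (k1 ≥ k2 by convention);
* ``linear`` — Y(t) = a + b·t, for slow near-linear early-phase decays.

The API follows the Model/Results convention: build a
:class:`DecayModel` from arrays or a DataFrame, call :meth:`~DecayModel.fit`,
and read estimates, uncertainties and derived quantities (half-life,
fraction remaining at 90 min) off the returned :class:`DecayResults`.
Replicates are fitted jointly by pooling residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["DecayCurve", "DecayModel", "DecayResults",
           "fit_single_plateau", "fit_double_exp", "half_life",
    "remaining_at"]

MODELS = ("single_plateau", "double_exp", "linear")
K_MAX = 10.0          # min^-1; generous upper bound for rate constants
K_MIN = 1e-8
MULTISTART_SEEDS = (11, 23, 37, 51, 73)  # fixed for reproducibility


@dataclass
class DecayCurve:
    """A normalized fraction-remaining time course.

    Times are minutes, strictly increasing, starting at 0; values are
    normalized so that the t = 0 point equals 1 (the constructor divides
    by the t = 0 value, so raw densitometry on any scale is accepted).
    """

    times: np.ndarray
    values: np.ndarray
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) < 2:
            raise ValueError("need at least two time points")
        if self.times[0] != 0:
            raise ValueError("first time point must be 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("fraction remaining cannot be negative")
        y0 = self.values[0]
        if y0 <= 0:
            raise ValueError("value at t=0 must be positive")
        self.values = self.values / y0


def _eval_model(model: str, params: dict[str, float],
                t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if model == "single_plateau":
        return params["A"] * np.exp(-params["k"] * t) + params["C"]
    if model == "double_exp":
        return (params["A1"] * np.exp(-params["k1"] * t)
                + params["A2"] * np.exp(-params["k2"] * t))
    if model == "linear":
        return params["a"] + params["b"] * t
    raise ValueError(f"unknown model {model!r}")


class DecayModel:
    """Kinetic decay model over one or more replicate curves."""

    def __init__(self, curves: list[DecayCurve] | DecayCurve,
                 model: str = "single_plateau"):
        if isinstance(curves, DecayCurve):
            curves = [curves]
        if not curves:
            raise ValueError("no curves supplied")
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        min_points = {"single_plateau": 4, "double_exp": 5, "linear": 2}
        n_t = len(curves[0].times)
        if n_t < min_points[model]:
            raise ValueError(
                f"{model} requires >= {min_points[model]} time points, "
                f"got {n_t}")
        self.curves = curves
        self.model = model
        # pooled residual vectors
        self.t = np.concatenate([c.times for c in curves])
        self.y = np.concatenate([c.values for c in curves])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: str = "single_plateau",
                       time_col: str = "time_min", value_col: str = "value",
                       replicate_col: str = "replicate") -> "DecayModel":
        """Build from a long table (time_min, value, replicate).

        Each replicate is normalized to its own t = 0 value.
        """
        if replicate_col not in df.columns:
            df = df.assign(**{replicate_col: "rep1"})
        curves = []
        for rep, grp in df.groupby(replicate_col, sort=True):
            grp = grp.sort_values(time_col)
            curves.append(DecayCurve(grp[time_col].to_numpy(),
                                     grp[value_col].to_numpy(),
                                     replicate_id=str(rep)))
        return cls(curves, model=model)

    # -- fitting -----------------------------------------------------------

    def _bounds(self):
        if self.model == "single_plateau":
            return (np.array([0.0, K_MIN, 0.0]),
                    np.array([1.0, K_MAX, 1.0]))
        if self.model == "double_exp":
            return (np.array([0.0, K_MIN, 0.0, K_MIN]),
                    np.array([1.0, K_MAX, 1.0, K_MAX]))
        raise AssertionError

    def _starts(self) -> list[np.ndarray]:
        t, y = self.t, self.y
        t_span = max(t.max(), 1.0)
        starts: list[np.ndarray] = []
        if self.model == "single_plateau":
            c0 = float(np.clip(y.min(), 0.0, 1.0))
            # log-linear regression of (Y - min Y) for A and k
            resid = np.clip(y - c0, 1e-6, None)
            slope, intercept = np.polyfit(t, np.log(resid), 1)
            k0 = float(np.clip(-slope, K_MIN, K_MAX))
            a0 = float(np.clip(math.exp(intercept), 0.0, 1.0))
            starts.append(np.array([a0, k0, c0]))
            for seed in MULTISTART_SEEDS:
                rng = np.random.default_rng(seed)
                starts.append(np.array([
                    rng.uniform(0.1, 1.0),
                    10 ** rng.uniform(-3, 0) / t_span * 10,
                    rng.uniform(0.0, 0.9),
                ]))
        else:  # double_exp
            starts.append(np.array([0.5, 5 * math.log(2) / t_span,
                                    0.5, 0.5 * math.log(2) / t_span]))
            for seed in MULTISTART_SEEDS:
                rng = np.random.default_rng(seed)
                a1 = rng.uniform(0.1, 0.9)
                starts.append(np.array([
                    a1, 10 ** rng.uniform(-2.5, 0.5) / t_span * 10,
                    1 - a1, 10 ** rng.uniform(-4, -1) / t_span * 10,
                ]))
        lo, hi = self._bounds()
        return [np.clip(s, lo, hi) for s in starts]

    def fit(self) -> "DecayResults":
        if self.model == "linear":
            b, a = np.polyfit(self.t, self.y, 1)
            params = {"a": float(a), "b": float(b)}
            resid = self.y - _eval_model("linear", params, self.t)
            return DecayResults(self, params, float(resid @ resid),
                                converged=True)

        names = (["A", "k", "C"] if self.model == "single_plateau"
                 else ["A1", "k1", "A2", "k2"])
        lo, hi = self._bounds()

        def residuals(p):
            params = dict(zip(names, p))
            return _eval_model(self.model, params, self.t) - self.y

        best = None
        for x0 in self._starts():
            try:
                sol = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                             xtol=1e-14, ftol=1e-14,
                                             gtol=1e-14)
            except Exception:
                continue
            rss = float(sol.fun @ sol.fun)
            if best is None or rss < best[0] - 1e-12:
                best = (rss, sol)
        if best is None:
            raise RuntimeError("all optimization starts failed")
        rss, sol = best
        params = dict(zip(names, sol.x))
        converged = bool(sol.success)

        if self.model == "double_exp" and params["k1"] < params["k2"]:
            params = {"A1": params["A2"], "k1": params["k2"],
                      "A2": params["A1"], "k2": params["k1"]}

        res = DecayResults(self, params, rss, converged=converged,
                           jac=sol.jac, param_names=names)
        if self.model == "single_plateau" and params["A"] < 0.01:
            res.notes.append("degradation fraction ~0; k unidentifiable")
        if self.model == "double_exp":
            ratio = params["k1"] / max(params["k2"], K_MIN)
            if ratio < 1.5:
                res.biphasic_supported = False
                res.notes.append(
                    "k1/k2 < 1.5: biphasic model unsupported; see "
                    "alternative_fit")
                res.alternative_fit = DecayModel(
                    self.curves, "single_plateau").fit()
            else:
                res.biphasic_supported = True
        return res


@dataclass
class DecayResults:
    """Fit results: parameter estimates, uncertainties and diagnostics."""

    model_obj: DecayModel
    params: dict[str, float]
    rss: float
    converged: bool = True
    jac: np.ndarray | None = None
    param_names: list[str] | None = None
    notes: list[str] = field(default_factory=list)
    biphasic_supported: bool | None = None
    alternative_fit: "DecayResults | None" = None

    @property
    def model(self) -> str:
        return self.model_obj.model

    @property
    def nobs(self) -> int:
        return len(self.model_obj.t)

    def predict(self, t) -> np.ndarray:
        return _eval_model(self.model, self.params, np.asarray(t, float))

    @property
    def bse(self) -> dict[str, float]:
        """Asymptotic standard errors from the Gauss-Newton approximation."""
        names = self.param_names or list(self.params)
        if self.jac is None:
            return {n: math.nan for n in names}
        dof = max(self.nobs - len(names), 1)
        try:
            cov = np.linalg.pinv(self.jac.T @ self.jac) * self.rss / dof
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(names), np.nan)
        return dict(zip(names, se.tolist()))

    # -- derived quantities ------------------------------------------------

    @property
    def degradable_fraction(self) -> float:
        if self.model == "single_plateau":
            return self.params["A"]
        if self.model == "double_exp":
            return self.params["A1"] + self.params["A2"]
        return math.nan

    def half_life(self) -> float:
        """Half-life in minutes.

        For the plateau model this is ln2/k, the half-life of the
        *degradable* fraction (the total signal never halves when
        C >= 0.5).  For the biphasic model, the time at which Y(t) drops
        to half its t = 0 value, found by bracketed root solving.
        """
        if not self.converged:
            raise ValueError("half-life undefined: fit did not converge")
        if self.model == "linear":
            b, a = self.params["b"], self.params["a"]
            if b >= 0:
                raise ValueError("non-decaying linear fit has no half-life")
            return (a / 2 - a) / b
        if self.degradable_fraction < 0.01:
            raise ValueError("degradable fraction < 0.01: half-life "
                             "undefined")
        if self.model == "single_plateau":
            return math.log(2) / self.params["k"]
        # double_exp: solve Y(t) = Y(0)/2 on [0, 10/k2]
        y0 = float(self.predict(0.0))
        t_hi = 10.0 / max(self.params["k2"], K_MIN)
        f = lambda t: float(self.predict(t)) - y0 / 2
        if f(t_hi) > 0:
            raise ValueError("curve never reaches half of initial value")
        return float(optimize.brentq(f, 0.0, t_hi, xtol=1e-6))

    def time_to_total_half(self) -> float | None:
        """Plateau model: time at which *total* signal reaches 0.5,
        or None when the plateau C >= 0.5 makes it unreachable."""
        if self.model != "single_plateau":
            return None
        A, k, C = (self.params[n] for n in ("A", "k", "C"))
        if C >= 0.5 or A <= 0:
            return None
        arg = (0.5 - C) / A
        if arg >= 1:
            return 0.0
        return -math.log(arg) / k

    def remaining_at(self, t: float = 90.0) -> float:
        """Model-predicted fraction remaining at time t minutes."""
        if t < 0:
            raise ValueError("t must be non-negative")
        if not self.converged:
            raise ValueError("remaining_at undefined: fit did not converge")
        return float(self.predict(float(t)))

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": self.bse,
            "rss": self.rss,
            "converged": self.converged,
            "nobs": self.nobs,
            "remaining_at_90": self.remaining_at(90.0),
            "notes": list(self.notes),
        }
        try:
            out["half_life_degradable"] = self.half_life()
        except ValueError:
            out["half_life_degradable"] = None
        if self.model == "single_plateau":
            out["time_to_total_half"] = self.time_to_total_half()
        if self.biphasic_supported is not None:
            out["biphasic_supported"] = self.biphasic_supported
        return out

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Degradation kinetics fit",
            "=" * 46,
            f"model:            {self.model}",
            f"n obs:            {self.nobs} "
            f"({len(self.model_obj.curves)} replicate(s), pooled)",
            f"converged:        {self.converged}",
            f"RSS:              {self.rss:.6g}",
            "-" * 46,
            f"{'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        for name, val in self.params.items():
            lines.append(f"{name:<8}{val:>12.5g}{se.get(name, math.nan):>12.3g}")
        lines.append("-" * 46)
        try:
            lines.append(f"half-life (degradable): {self.half_life():.4g} min")
        except ValueError as exc:
            lines.append(f"half-life: undefined ({exc})")
        lines.append(f"remaining at 90 min:    {self.remaining_at(90.0):.4g}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


# -- functional wrappers ----------------------------------------------------

def fit_single_plateau(curve: DecayCurve | list[DecayCurve]) -> DecayResults:
    """Fit Y(t) = A·exp(−k·t) + C (stable-fraction exponential decay)."""
    return DecayModel(curve, "single_plateau").fit()


def fit_double_exp(curve: DecayCurve | list[DecayCurve]) -> DecayResults:
    """Fit Y(t) = A1·exp(−k1·t) + A2·exp(−k2·t) (biphasic decay)."""
    return DecayModel(curve, "double_exp").fit()


def half_life(fit: DecayResults) -> float:
    return fit.half_life()


def remaining_at(fit: DecayResults, t: float = 90.0) -> float:
    return fit.remaining_at(t)
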