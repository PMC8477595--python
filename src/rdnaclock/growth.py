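"""Von Bertalanffy growth models: standard and Francis parameterisations.

Standard form: L(t) = Linf * (1 - exp(-K (t - t0))).
Francis form re-expresses the same curve as mean lengths (L1, L2, L3) at
reference ages tau1 < tau3 with tau2 = (tau1 + tau3) / 2:

    L(t) = L1 + (L3 - L1) * (1 - r^(2 (t - tau1) / (tau3 - tau1))) / (1 - r^2)

with r = (L3 - L2) / (L2 - L1) = exp(-K (tau3 - tau1) / 2). Ages are in
months throughout (multiply by 12 to convert year-based parameters).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

MONTHS_PER_YEAR = 12.0
_R_ONE_TOL = 1e-9


class InvalidParameterisationError(ValueError):
    pass


@dataclass
class VBGMFit:
    parameterisation: str  # "standard" | "francis"
    params: dict[str, float]  # Linf/K/t0 or L1/L2/L3 (+ tau1, tau3)
    residual_sd: float = math.nan
    sse: float = math.nan
    n: int = 0
    converged: bool = False
    message: str = ""
    bootstrap_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot_failed: int = 0

    def predict(self, age) -> np.ndarray:
        return vbgm_predict(self, age)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "parameterisation": self.parameterisation,
                    "params": self.params,
                    "residual_sd": self.residual_sd,
                    "sse": self.sse,
                    "n": self.n,
                    "converged": self.converged,
                    "message": self.message,
                    "bootstrap_ci": {k: list(v) for k, v in self.bootstrap_ci.items()},
                    "n_boot_failed": self.n_boot_failed,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def _standard_curve(age: np.ndarray, linf: float, k: float, t0: float) -> np.ndarray:
    return linf * (1.0 - np.exp(-k * (age - t0)))


def _francis_curve(
    age: np.ndarray, l1: float, l2: float, l3: float, tau1: float, tau3: float
) -> np.ndarray:
    if not (l1 < l2 < l3):
        raise InvalidParameterisationError(
            f"Francis parameters need L1 < L2 < L3, got ({l1}, {l2}, {l3})"
        )
    r = (l3 - l2) / (l2 - l1)
    frac = (age - tau1) / (tau3 - tau1)
    if abs(r - 1.0) < _R_ONE_TOL:
        # r -> 1 is the K -> 0 linear limit of the curve
        return l1 + (l3 - l1) * frac
    return l1 + (l3 - l1) * (1.0 - r ** (2.0 * frac)) / (1.0 - r**2)


def vbgm_predict(fit_or_params, age) -> np.ndarray:
    """Evaluate a growth curve at the given ages (months)."""
    age = np.asarray(age, dtype=float)
    if isinstance(fit_or_params, VBGMFit):
        parameterisation, params = fit_or_params.parameterisation, fit_or_params.params
    else:
        parameterisation, params = fit_or_params
    if parameterisation == "standard":
        return _standard_curve(age, params["Linf"], params["K"], params["t0"])
    if parameterisation == "francis":
        return _francis_curve(
            age, params["L1"], params["L2"], params["L3"], params["tau1"], params["tau3"]
        )
    raise ValueError(f"unknown parameterisation {parameterisation!r}")


def convert_parameterisation(
    fit: VBGMFit, target: str, tau1: float | None = None, tau3: float | None = None
) -> VBGMFit:
    """Exact algebraic conversion between the two forms (same curve)."""
    if target == fit.parameterisation:
        return fit
    if target == "francis":
        if tau1 is None or tau3 is None or not tau1 < tau3:
            raise ValueError("francis target needs reference ages tau1 < tau3")
        tau2 = 0.5 * (tau1 + tau3)
        l1, l2, l3 = (
            float(vbgm_predict(fit, np.array([t]))[0]) for t in (tau1, tau2, tau3)
        )
        if not l1 < l2 < l3:
            raise InvalidParameterisationError(
                "curve is not increasing over the reference ages; pick tau1 < tau3 inside the growth range"
            )
        params = {"L1": l1, "L2": l2, "L3": l3, "tau1": tau1, "tau3": tau3}
    elif target == "standard":
        p = fit.params
        l1, l2, l3, t1, t3 = p["L1"], p["L2"], p["L3"], p["tau1"], p["tau3"]
        if l1 >= l3 or not (l1 < l2 < l3):
            raise InvalidParameterisationError("need L1 < L2 < L3")
        r = (l3 - l2) / (l2 - l1)
        if abs(r - 1.0) < _R_ONE_TOL:
            raise InvalidParameterisationError(
                "L2 at the midpoint (r = 1) is the K -> 0 linear limit; no finite standard form exists"
            )
        k = -2.0 * math.log(r) / (t3 - t1)
        linf = l1 + (l3 - l1) / (1.0 - r**2)
        t0 = t1 + math.log(1.0 - l1 / linf) / k
        params = {"Linf": linf, "K": k, "t0": t0}
    else:
        raise ValueError(f"unknown parameterisation {target!r}")
    return VBGMFit(
        parameterisation=target,
        params=params,
        residual_sd=fit.residual_sd,
        sse=fit.sse,
        n=fit.n,
        converged=fit.converged,
        message=f"converted from {fit.parameterisation}",
    )


def _start_standard(ages: np.ndarray, lengths: np.ndarray) -> tuple[float, float, float]:
    linf0 = 1.1 * float(lengths.max())
    # log-linearised step: log(1 - L/Linf0) ~ -K * age
    frac = np.clip(lengths / linf0, None, 0.999)
    z = np.log(1.0 - frac)
    slope = stats.linregress(ages, z).slope
    k0 = max(-float(slope), 1e-4)
    return linf0, k0, 0.0


def _start_francis(
    ages: np.ndarray, lengths: np.ndarray, tau1: float, tau3: float
) -> tuple[float, float, float]:
    tau2 = 0.5 * (tau1 + tau3)
    starts = []
    for tau in (tau1, tau2, tau3):
        w = np.argsort(np.abs(ages - tau))[: max(3, len(ages) // 5)]
        starts.append(float(lengths[w].mean()))
    l1, l2, l3 = starts
    span = max(lengths.max() - lengths.min(), 1.0)
    # nudge into a strictly increasing, non-degenerate configuration
    l3 = max(l3, l1 + 0.1 * span)
    mid = 0.5 * (l1 + l3)
    if not l1 < l2 < l3 or abs((l3 - l2) / max(l2 - l1, 1e-9) - 1.0) < 1e-3:
        l2 = mid + 0.1 * (l3 - l1)
    return l1, l2, l3


def fit_vbgm(
    ages,
    lengths,
    parameterisation: str = "standard",
    start: tuple | None = None,
    tau1: float | None = None,
    tau3: float | None = None,
) -> VBGMFit:
    """Nonlinear least squares on length residuals.

    Francis reference ages default to the min and max observed ages.
    Non-convergence (including degenerate all-equal lengths) is flagged on
    the returned fit, never raised silently.
    """
    ages = np.asarray(ages, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if ages.shape != lengths.shape or ages.ndim != 1:
        raise ValueError("ages and lengths must be 1-D vectors of equal length")
    if len(ages) < 4 or len(np.unique(ages)) < 3:
        raise ValueError("need >= 4 pairs spanning >= 3 distinct ages")
    n = len(ages)

    if np.ptp(lengths) == 0:
        return VBGMFit(
            parameterisation=parameterisation,
            params={},
            n=n,
            converged=False,
            message="degenerate data: lengths are constant",
        )

    if parameterisation == "standard":
        x0 = np.array(start if start is not None else _start_standard(ages, lengths))

        def resid(theta):
            return _standard_curve(ages, *theta) - lengths

        bounds = ([1e-6, 1e-9, -np.inf], [np.inf, np.inf, np.inf])
        names = ("Linf", "K", "t0")
        extra: dict[str, float] = {}
    elif parameterisation == "francis":
        if tau1 is None:
            tau1 = float(ages.min())
        if tau3 is None:
            tau3 = float(ages.max())
        if not tau1 < tau3:
            raise ValueError("tau1 must be < tau3")
        x0 = np.array(start if start is not None else _start_francis(ages, lengths, tau1, tau3))

        def resid(theta):
            l1, l2, l3 = theta
            if not l1 < l2 < l3:
                return np.full_like(lengths, 1e6)
            return _francis_curve(ages, l1, l2, l3, tau1, tau3) - lengths

        bounds = ([-np.inf] * 3, [np.inf] * 3)
        names = ("L1", "L2", "L3")
        extra = {"tau1": tau1, "tau3": tau3}
    else:
        raise ValueError(f"unknown parameterisation {parameterisation!r}")

    sol = optimize.least_squares(resid, x0, bounds=bounds, xtol=1e-12, ftol=1e-12, gtol=1e-12)
    sse = float(np.sum(sol.fun**2))
    dof = max(n - len(x0), 1)
    converged = bool(sol.success)
    params = {name: float(v) for name, v in zip(names, sol.x)}
    params.update(extra)
    if parameterisation == "francis" and converged and not (
        params["L1"] < params["L2"] < params["L3"]
    ):
        converged = False
    return VBGMFit(
        parameterisation=parameterisation,
        params=params,
        residual_sd=math.sqrt(sse / dof),
        sse=sse,
        n=n,
        converged=converged,
        message=sol.message,
    )


def bootstrap_ci(
    ages,
    lengths,
    parameterisation: str = "standard",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    tau1: float | None = None,
    tau3: float | None = None,
) -> VBGMFit:
    """Nonparametric case-resampling bootstrap percentile intervals.

    Replicates that fail to converge are dropped and counted; losing more
    than 20% of them escalates a warning on the report.
    """
    ages = np.asarray(ages, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    base = fit_vbgm(ages, lengths, parameterisation, tau1=tau1, tau3=tau3)
    if not base.converged:
        raise RuntimeError(f"base fit did not converge: {base.message}")
    rng = np.random.default_rng(seed)
    names = [k for k in base.params if k not in ("tau1", "tau3")]
    draws: dict[str, list[float]] = {k: [] for k in names}
    failed = 0
    n = len(ages)
    start = tuple(base.params[k] for k in names)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        a, l = ages[idx], lengths[idx]
        if len(np.unique(a)) < 3 or np.ptp(l) == 0:
            failed += 1
            continue
        try:
            rep = fit_vbgm(a, l, parameterisation, start=start, tau1=tau1, tau3=tau3)
        except Exception:
            failed += 1
            continue
        if not rep.converged:
            failed += 1
            continue
        for k in names:
            draws[k].append(rep.params[k])
    if n_boot > 0 and failed > 0.2 * n_boot:
        warnings.warn(
            f"{failed}/{n_boot} bootstrap replicates failed to converge", stacklevel=2
        )
    lo_q, hi_q = 100.0 * (1.0 - level) / 2.0, 100.0 * (1.0 + level) / 2.0
    for k in names:
        vals = np.asarray(draws[k])
        if vals.size == 0:
            base.bootstrap_ci[k] = (math.nan, math.nan)
        else:
            base.bootstrap_ci[k] = (
                float(np.percentile(vals, lo_q)),
                float(np.percentile(vals, hi_q)),
            )
    base.n_boot_failed = failed
    return base
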