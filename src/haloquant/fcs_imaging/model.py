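"""Two-component 3D free-diffusion autocorrelation model and fitting.

The model for the normalized fluorescence autocorrelation at lag tau is

    G(tau) = offset + (1/N) * [f1*g(tau; tau1) + (1-f1)*g(tau; tau2)]
    g(tau; taud) = 1/(1 + tau/taud) * 1/sqrt(1 + tau/(kappa^2 * taud))

with N the mean number of molecules in the effective confocal volume,
f1 the fast-component fraction, tau1 < tau2 the component diffusion
times and kappa the axial/lateral structure parameter. No triplet term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ..constants import NA_NM_UM3
from ..errors import FitFailureError, InvalidParameterError

__all__ = [
    "AutocorrCurve",
    "FCSFit",
    "EffectiveVolume",
    "two_component_model",
    "fit_autocorrelation",
    "effective_volume_from_dye",
    "curve_from_csv",
    "curve_to_frame",
]

DEFAULT_KAPPA = 5.0


@dataclass(frozen=True)
class AutocorrCurve:
    """An autocorrelation curve: strictly increasing positive lags and G."""

    lags: np.ndarray  # seconds
    g: np.ndarray  # dimensionless
    mean_count_rate: float | None = None  # photons/s, optional

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if lags.shape != g.shape or lags.ndim != 1:
            raise InvalidParameterError("lags and G must be equal-length 1-D arrays")
        if lags.size and (np.any(lags <= 0) or np.any(np.diff(lags) <= 0)):
            raise InvalidParameterError("lags must be strictly increasing and > 0")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g", g)


@dataclass(frozen=True)
class FCSFit:
    """Fitted two-component diffusion parameters, ordered tau1 < tau2."""

    n_mean: float
    f1: float
    tau1: float
    tau2: float
    kappa: float
    offset: float
    residual_rms: float
    concentration_nm: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_mean <= 0:
            raise InvalidParameterError("N_mean must be > 0")
        if self.tau1 > self.tau2:
            raise InvalidParameterError("components must be ordered tau1 <= tau2")


@dataclass(frozen=True)
class EffectiveVolume:
    """Calibrated effective confocal volume in µm^3 (= fL)."""

    v_eff_um3: float

    def __post_init__(self) -> None:
        if self.v_eff_um3 <= 0:
            raise InvalidParameterError("V_eff must be > 0")


def two_component_model(
    lag,
    n_mean: float,
    f1: float,
    tau1: float,
    tau2: float,
    kappa: float = DEFAULT_KAPPA,
    offset: float = 0.0,
):
    """Evaluate G(lag) for the two-component 3D diffusion model.

    Accepts scalar or array lag (seconds, > 0); pure function.
    """
    lag = np.asarray(lag, dtype=float)

    def g_single(taud):
        return 1.0 / (1.0 + lag / taud) / np.sqrt(1.0 + lag / (kappa**2 * taud))

    out = offset + (f1 * g_single(tau1) + (1.0 - f1) * g_single(tau2)) / n_mean
    return float(out) if out.ndim == 0 else out


def fit_autocorrelation(
    curve: AutocorrCurve,
    *,
    kappa: float = DEFAULT_KAPPA,
    init: dict | None = None,
    bounds: dict | None = None,
    sigma: np.ndarray | None = None,
    v_eff: EffectiveVolume | None = None,
) -> FCSFit:
    """Weighted nonlinear least-squares fit of the two-component model.

    ``kappa`` is fixed (calibrated on dye data and reused for cell fits).
    Components are reordered so tau1 < tau2. When ``v_eff`` is supplied the
    concentration N/(V_eff * NA) in nM is filled in. Parameters pinned at
    their bounds are flagged.
    """
    lags, g = curve.lags, curve.g
    if lags.size < 8:
        raise InvalidParameterError("need >= 8 lag points spanning both decays")
    if kappa <= 0:
        raise InvalidParameterError("kappa must be > 0")

    offset0 = float(g[-1])
    amp0 = max(float(g[0]) - offset0, 1e-6)
    n0 = 1.0 / amp0
    # crude half-decay lag for diffusion-time seeding
    half = offset0 + amp0 / 2.0
    below = np.nonzero(g <= half)[0]
    tau_half = float(lags[below[0]]) if below.size else float(np.sqrt(lags[0] * lags[-1]))
    defaults = {
        "n_mean": n0,
        "f1": 0.5,
        "tau1": tau_half / 10.0,
        "tau2": tau_half * 10.0,
        "offset": offset0,
    }
    if init:
        defaults.update(init)
    lo = {
        "n_mean": 1e-8,
        "f1": 0.0,
        "tau1": lags[0] / 100.0,
        "tau2": lags[0] / 100.0,
        "offset": -1.0,
    }
    hi = {
        "n_mean": 1e8,
        "f1": 1.0,
        "tau1": lags[-1] * 100.0,
        "tau2": lags[-1] * 100.0,
        "offset": 1.0,
    }
    if bounds:
        for k, (a, b) in bounds.items():
            lo[k], hi[k] = a, b
    names = ["n_mean", "f1", "tau1", "tau2", "offset"]
    p0 = np.clip(
        [defaults[k] for k in names], [lo[k] for k in names], [hi[k] for k in names]
    )

    def model(lag, n_mean, f1, tau1, tau2, offset):
        return two_component_model(lag, n_mean, f1, tau1, tau2, kappa, offset)

    try:
        popt, _ = curve_fit(
            model,
            lags,
            g,
            p0=p0,
            sigma=sigma,
            bounds=([lo[k] for k in names], [hi[k] for k in names]),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            "autocorrelation fit did not converge",
            diagnostics={"p0": dict(zip(names, p0))},
        ) from exc

    n_mean, f1, tau1, tau2, offset = (float(v) for v in popt)
    if tau1 > tau2:
        tau1, tau2 = tau2, tau1
        f1 = 1.0 - f1
    resid = g - model(lags, n_mean, f1, tau1, tau2, offset)

    flags = []
    for name, val in zip(names, (n_mean, f1, tau1, tau2, offset)):
        span = hi[name] - lo[name]
        if min(val - lo[name], hi[name] - val) < 1e-9 * max(span, 1.0):
            flags.append(f"{name}-at-bound")

    conc = None
    if v_eff is not None:
        conc = n_mean / (v_eff.v_eff_um3 * NA_NM_UM3)
    return FCSFit(
        n_mean=n_mean,
        f1=f1,
        tau1=tau1,
        tau2=tau2,
        kappa=kappa,
        offset=offset,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        concentration_nm=conc,
        flags=tuple(flags),
    )


def effective_volume_from_dye(
    dye_fit: FCSFit, known_concentration_nm: float
) -> EffectiveVolume:
    """Effective confocal volume from a dye measurement of known concentration.

    V_eff = N / (C * NA), with C in nM and V_eff in µm^3.
    """
    if known_concentration_nm <= 0:
        raise InvalidParameterError("known concentration must be > 0")
    if dye_fit.n_mean <= 0:
        raise InvalidParameterError("N_mean must be > 0")
    return EffectiveVolume(dye_fit.n_mean / (known_concentration_nm * NA_NM_UM3))


def curve_from_csv(path) -> AutocorrCurve:
    """Read an autocorrelation curve from CSV columns (lag_s, g)."""
    df = pd.read_csv(path)
    missing = {"lag_s", "g"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"curve CSV missing columns: {sorted(missing)}")
    return AutocorrCurve(
        lags=df["lag_s"].to_numpy(dtype=float), g=df["g"].to_numpy(dtype=float)
    )


def curve_to_frame(curve: AutocorrCurve) -> pd.DataFrame:
    return pd.DataFrame({"lag_s": curve.lags, "g": curve.g})
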