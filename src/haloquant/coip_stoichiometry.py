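"""Cohesin dimer fraction from reciprocal-tag IP/CoIP band intensities.

One allele carries a V5 tag, the other a FLAG tag; pulling down one tag and
blotting for the other probes self-association. Loading-corrected IP and
CoIP efficiencies invert, under the equal-likelihood tag-pairing assumption
(as many V5:V5 dimers as V5:FLAG dimers), to the fraction of molecules in
dimers:

    %IP    = input_frac * I_IP   / (ip_load * I_IN)
    %CoIP  = input_frac * I_CoIP / (coip_load * I_IN)
    M      = %IP - 3 * %CoIP          (monomer share of the pull-down)
    dimer  = 1 - M/%IP = 3 * %CoIP / %IP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "CoIPExperiment",
    "DimerEstimate",
    "efficiencies",
    "dimer_fraction",
    "analyze_experiment",
    "aggregate",
    "experiments_from_csv",
    "DEFAULT_INPUT_FRACTION",
    "DEFAULT_IP_LOAD",
    "DEFAULT_COIP_LOAD",
]

DEFAULT_INPUT_FRACTION = 0.015
DEFAULT_IP_LOAD = 0.1
DEFAULT_COIP_LOAD = 0.9


@dataclass(frozen=True)
class CoIPExperiment:
    """Band intensities and loading fractions for one pull-down."""

    antibody: Literal["V5", "FLAG"]
    benzonase: bool
    i_in: float
    i_ip: float
    i_coip: float
    input_fraction: float = DEFAULT_INPUT_FRACTION
    ip_load_fraction: float = DEFAULT_IP_LOAD
    coip_load_fraction: float = DEFAULT_COIP_LOAD

    def __post_init__(self) -> None:
        for name in ("input_fraction", "ip_load_fraction", "coip_load_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidParameterError(f"{name} must be in (0, 1], got {v}")
        if self.i_in <= 0:
            raise InvalidParameterError(f"I_IN must be > 0, got {self.i_in}")
        if self.i_ip < 0 or self.i_coip < 0:
            raise InvalidParameterError("band intensities must be >= 0")


@dataclass(frozen=True)
class DimerEstimate:
    """Per-experiment dimer/monomer split with out-of-model flagging."""

    pct_ip: float
    pct_coip: float
    monomer_fraction: float
    dimer_fraction: float
    out_of_model: bool = False

    def __post_init__(self) -> None:
        s = self.monomer_fraction + self.dimer_fraction
        if abs(s - 1.0) > 1e-9:
            raise InvalidParameterError("monomer + dimer fractions must sum to 1")


def efficiencies(exp: CoIPExperiment) -> tuple[float, float]:
    """Loading-corrected (%IP, %CoIP) as fractions of input."""
    pct_ip = exp.input_fraction * exp.i_ip / (exp.ip_load_fraction * exp.i_in)
    pct_coip = exp.input_fraction * exp.i_coip / (exp.coip_load_fraction * exp.i_in)
    return pct_ip, pct_coip


def dimer_fraction(pct_ip: float, pct_coip: float) -> DimerEstimate:
    """Invert IP/CoIP efficiencies to the dimer fraction.

    ``pct_coip > pct_ip/3`` exits the model's range; the result is clamped
    to [0, 1] and flagged ``out_of_model`` rather than silently accepted.
    """
    if pct_ip <= 0:
        raise InvalidParameterError(f"pct_ip must be > 0, got {pct_ip}")
    if pct_coip < 0:
        raise InvalidParameterError(f"pct_coip must be >= 0, got {pct_coip}")
    monomer = (pct_ip - 3.0 * pct_coip) / pct_ip
    dimer = 3.0 * pct_coip / pct_ip
    # tolerance so that exact full-dimer inputs are not flagged on rounding
    out_of_model = dimer > 1.0 + 1e-9
    if dimer > 1.0:
        dimer, monomer = 1.0, 0.0
    return DimerEstimate(
        pct_ip=pct_ip,
        pct_coip=pct_coip,
        monomer_fraction=monomer,
        dimer_fraction=dimer,
        out_of_model=out_of_model,
    )


def analyze_experiment(exp: CoIPExperiment) -> DimerEstimate:
    """Full per-experiment analysis: efficiencies then inversion."""
    pct_ip, pct_coip = efficiencies(exp)
    return dimer_fraction(pct_ip, pct_coip)


def aggregate(estimates: Sequence[DimerEstimate] | Iterable[float]) -> tuple[float, float]:
    """Mean and sample (n-1) std of dimer fractions (or raw values).

    Accepts either :class:`DimerEstimate` objects or bare numbers (e.g.
    percentages); a single value yields std 0.0.
    """
    vals = [
        e.dimer_fraction if isinstance(e, DimerEstimate) else float(e)
        for e in estimates
    ]
    if not vals:
        raise InvalidParameterError("need >= 1 estimate")
    mean = float(np.mean(vals))
    std = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, std


def random_pairing_dimer_fraction(pct_ip: float, pct_coip: float) -> DimerEstimate:
    """Model variant: random tag pairing (V5:V5 : V5:FLAG : FLAG:FLAG = 1:2:1).

    Not the default model — provided for sensitivity analysis only.
    Under random pairing half the V5-containing dimers are cross-tagged, so
    the V5 molecules in dimers are 2*%CoIP of the pull-down and the dimer
    fraction is 2*%CoIP/%IP.
    """
    if pct_ip <= 0:
        raise InvalidParameterError(f"pct_ip must be > 0, got {pct_ip}")
    dimer = 2.0 * pct_coip / pct_ip
    out_of_model = dimer > 1.0
    if out_of_model:
        dimer = 1.0
    return DimerEstimate(
        pct_ip=pct_ip,
        pct_coip=pct_coip,
        monomer_fraction=1.0 - dimer,
        dimer_fraction=dimer,
        out_of_model=out_of_model,
    )


def experiments_from_csv(path) -> list[CoIPExperiment]:
    """Read CoIP experiments from CSV.

    Required columns: antibody, benzonase, I_IN, I_IP, I_CoIP. Optional:
    input_fraction, ip_load_fraction, coip_load_fraction.
    """
    df = pd.read_csv(path)
    missing = {"antibody", "benzonase", "I_IN", "I_IP", "I_CoIP"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"CoIP CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for col in ("input_fraction", "ip_load_fraction", "coip_load_fraction"):
            if col in df.columns and not pd.isna(getattr(row, col)):
                kwargs[col] = float(getattr(row, col))
        out.append(
            CoIPExperiment(
                antibody=str(row.antibody),
                benzonase=bool(row.benzonase),
                i_in=float(row.I_IN),
                i_ip=float(row.I_IP),
                i_coip=float(row.I_CoIP),
                **kwargs,
            )
        )
    return out
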