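"""Synthetic data generators with recorded ground truth.

Every pipeline input can be generated here with known true parameters so
that each estimator has a matching recovery test. All generators take an
explicit seed and draw from a single local ``numpy`` Generator; identical
seed and parameters give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constants import NA_NM_UM3
from .coip_stoichiometry import CoIPExperiment
from .errors import GeometryError, InvalidParameterError
from .fcm_quant import FCMSample
from .fcs_imaging.model import AutocorrCurve, two_component_model
from .fcs_imaging.stack import ImageStack
from .gel_quant import GelLane

__all__ = [
    "GroundTruth",
    "Ellipsoid",
    "gen_gel_lanes",
    "gen_fcm_events",
    "gen_fcs_curve",
    "gen_image_stack",
    "gen_coip",
    "gen_cell_cycle",
    "autocorrelate_trace",
]


@dataclass(frozen=True)
class GroundTruth:
    """True parameter values a generated dataset was produced from."""

    generator: str
    params: dict

    def __getitem__(self, key):
        return self.params[key]


# ------------------------------------------------------------------ gel

def gen_gel_lanes(
    true_abundance: float,
    fpm: float,
    standard_amounts: Sequence[float],
    cells_per_lane: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    cell_line: str = "sim",
) -> tuple[list[GelLane], GroundTruth]:
    """Simulate standard titration lanes and lysate lanes.

    Standard lane intensity is fpm*amount*(1+eps) and lysate lane intensity
    fpm*true_abundance*n_cells*(1+eps) with eps ~ N(0, noise_cv).
    """
    if fpm <= 0 or true_abundance <= 0:
        raise InvalidParameterError("fpm and true_abundance must be > 0")
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")
    if any(a <= 0 for a in standard_amounts) or any(c <= 0 for c in cells_per_lane):
        raise InvalidParameterError("amounts and cell counts must be > 0")
    rng = np.random.default_rng(seed)
    lanes: list[GelLane] = []
    for i, amount in enumerate(standard_amounts):
        eps = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
        lanes.append(
            GelLane(
                lane_id=f"std{i}",
                kind="standard",
                band_intensity=max(fpm * amount * (1.0 + eps), 0.0),
                amount=float(amount),
                cell_line=cell_line,
            )
        )
    for i, n_cells in enumerate(cells_per_lane):
        eps = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
        lanes.append(
            GelLane(
                lane_id=f"lys{i}",
                kind="lysate",
                band_intensity=max(fpm * true_abundance * n_cells * (1.0 + eps), 0.0),
                n_cells=float(n_cells),
                replicate_id=f"rep{i}",
                cell_line=cell_line,
            )
        )
    truth = GroundTruth(
        "gen_gel_lanes",
        {
            "true_abundance": true_abundance,
            "fpm": fpm,
            "noise_cv": noise_cv,
            "seed": seed,
        },
    )
    return lanes, truth


# ------------------------------------------------------------------ FCM

def gen_fcm_events(
    lines: Sequence[tuple[float, float]],
    background_mu_sigma: tuple[float, float],
    n_events: int,
    seed: int = 0,
    signal_sigma: float = 0.4,
    line_names: Sequence[str] | None = None,
) -> tuple[list[FCMSample], GroundTruth]:
    """Simulate per-cell fluorescence events for several cell lines.

    ``lines`` is a list of (true_abundance, au_per_molecule). Labeled-event
    signal is lognormal with arithmetic mean abundance*au_per_molecule and
    log-space sd ``signal_sigma``; an additive background draw (lognormal
    with log-space mu/sigma ``background_mu_sigma``) is shared by labeled
    and unlabeled samples. Each line yields a labeled and an unlabeled
    sample.
    """
    if not lines:
        raise InvalidParameterError("need >= 1 cell line")
    if n_events < 1:
        raise InvalidParameterError("n_events must be >= 1")
    if signal_sigma < 0:
        raise InvalidParameterError("signal_sigma must be >= 0")
    bg_mu, bg_sigma = background_mu_sigma
    rng = np.random.default_rng(seed)
    names = list(line_names) if line_names else [f"line{i}" for i in range(len(lines))]
    if len(names) != len(lines):
        raise InvalidParameterError("line_names length must match lines")

    samples: list[FCMSample] = []
    for name, (abundance, au_per_mol) in zip(names, lines):
        if abundance < 0 or au_per_mol <= 0:
            raise InvalidParameterError("abundance >= 0 and au_per_molecule > 0")
        mean_signal = abundance * au_per_mol
        if mean_signal > 0 and signal_sigma > 0:
            mu = np.log(mean_signal) - signal_sigma**2 / 2.0
            signal = rng.lognormal(mu, signal_sigma, n_events)
        else:
            signal = np.full(n_events, mean_signal)
        bg_labeled = _background_draw(rng, bg_mu, bg_sigma, n_events)
        bg_unlabeled = _background_draw(rng, bg_mu, bg_sigma, n_events)
        samples.append(FCMSample(name, True, signal + bg_labeled))
        samples.append(FCMSample(name, False, bg_unlabeled))

    truth = GroundTruth(
        "gen_fcm_events",
        {
            "lines": {
                n: {"true_abundance": a, "au_per_molecule": u}
                for n, (a, u) in zip(names, lines)
            },
            "background_mu_sigma": (bg_mu, bg_sigma),
            "signal_sigma": signal_sigma,
            "n_events": n_events,
            "seed": seed,
        },
    )
    return samples, truth


def _background_draw(rng, mu, sigma, n):
    if sigma > 0:
        return rng.lognormal(mu, sigma, n)
    return np.full(n, np.exp(mu) if mu != -np.inf else 0.0)


# ------------------------------------------------------------------ FCS

def gen_fcs_curve(
    n_mean: float,
    f1: float,
    tau1_s: float,
    tau2_s: float,
    kappa: float,
    offset: float,
    lags_s: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[AutocorrCurve, GroundTruth]:
    """Simulate a two-component autocorrelation curve.

    Noise is heteroscedastic: per-lag sd is ``noise_sd`` scaled by
    sqrt(0.1 + normalized model decay), so short lags are noisier, as in
    measured curves.
    """
    lags = np.asarray(lags_s, dtype=float)
    if lags.size and (np.any(lags <= 0) or np.any(np.diff(lags) <= 0)):
        raise InvalidParameterError("lags must be strictly increasing and > 0")
    if not 0 <= f1 <= 1:
        raise InvalidParameterError("f1 must be in [0, 1]")
    if kappa <= 0:
        raise InvalidParameterError("kappa must be > 0")
    if n_mean <= 0 or tau1_s <= 0 or tau2_s <= 0:
        raise InvalidParameterError("N_mean and diffusion times must be > 0")
    g = two_component_model(lags, n_mean, f1, tau1_s, tau2_s, kappa, offset)
    g = np.atleast_1d(np.asarray(g, dtype=float))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        decay = (g - offset) * n_mean  # in [0, 1]
        sd = noise_sd * np.sqrt(0.1 + decay)
        g = g + rng.normal(0.0, 1.0, g.size) * sd
    truth = GroundTruth(
        "gen_fcs_curve",
        {
            "n_mean": n_mean,
            "f1": f1,
            "tau1_s": tau1_s,
            "tau2_s": tau2_s,
            "kappa": kappa,
            "offset": offset,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
    return AutocorrCurve(lags=lags, g=g), truth


def autocorrelate_trace(trace: np.ndarray, dt_s: float, max_lag_s: float) -> AutocorrCurve:
    """Naive normalized autocorrelation of a binned intensity trace.

    Simulation helper only: G(tau) = <dI(t) dI(t+tau)> / <I>^2 for lags up
    to ``max_lag_s``. Not a hardware multi-tau correlator.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 2:
        raise InvalidParameterError("trace must be a 1-D array with >= 2 bins")
    if dt_s <= 0 or max_lag_s <= dt_s:
        raise InvalidParameterError("need dt_s > 0 and max_lag_s > dt_s")
    mean = trace.mean()
    if mean == 0:
        raise InvalidParameterError("trace mean is zero")
    d = trace - mean
    n_lags = min(int(max_lag_s / dt_s), trace.size - 1)
    lags = np.arange(1, n_lags + 1) * dt_s
    g = np.array(
        [np.mean(d[:-k] * d[k:]) for k in range(1, n_lags + 1)]
    ) / mean**2
    return AutocorrCurve(lags=lags, g=g)


# ------------------------------------------------------------------ imaging

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in µm, (z, y, x)."""

    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_um):
            raise InvalidParameterError("semi-axes must be > 0")

    def mask(self, shape, voxel_size_um) -> np.ndarray:
        """Boolean voxel mask (voxel centers inside the ellipsoid)."""
        coords = np.meshgrid(
            *[
                (np.arange(n) + 0.5) * v
                for n, v in zip(shape, voxel_size_um)
            ],
            indexing="ij",
        )
        q = sum(
            ((c - c0) / a) ** 2
            for c, c0, a in zip(coords, self.center_um, self.semi_axes_um)
        )
        return q <= 1.0

    @property
    def volume_um3(self) -> float:
        a, b, c = self.semi_axes_um
        return 4.0 / 3.0 * np.pi * a * b * c


def gen_image_stack(
    nucleus: Ellipsoid,
    cell: Ellipsoid | np.ndarray,
    conc_nuc_nm: float,
    conc_cyt_nm: float,
    k_nm_per_au: float,
    background_au: float,
    voxel_size_um: tuple[float, float, float],
    shape: tuple[int, int, int],
    seed: int = 0,
    poisson_scale: float = 0.0,
    read_noise_sd: float = 0.0,
    dna_level_au: float = 1000.0,
    boundary_level_au: float = 1000.0,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate a 3-channel confocal stack of one cell.

    Protein-channel voxels are background + concentration/k (+ optional
    Poisson photon noise at ``poisson_scale`` counts/AU and Gaussian read
    noise). The DNA channel marks the nucleus, the boundary channel the
    cell extent. Ground truth records voxelized compartment volumes and the
    implied molecule counts (conc * volume * 0.602214086).
    """
    if conc_nuc_nm < 0 or conc_cyt_nm < 0:
        raise InvalidParameterError("concentrations must be >= 0")
    if k_nm_per_au <= 0:
        raise InvalidParameterError("k_nM must be > 0")
    if background_au < 0:
        raise InvalidParameterError("background must be >= 0")
    nuc_mask = nucleus.mask(shape, voxel_size_um)
    if isinstance(cell, Ellipsoid):
        cell_mask = cell.mask(shape, voxel_size_um)
    else:
        cell_mask = np.asarray(cell, dtype=bool)
        if cell_mask.shape != tuple(shape):
            raise InvalidParameterError("cell mask shape must match stack shape")
    if np.any(nuc_mask & ~cell_mask):
        raise GeometryError("nucleus must be strictly inside the cell")
    if not nuc_mask.any():
        raise GeometryError("nucleus does not intersect the voxel grid")

    cyt_mask = cell_mask & ~nuc_mask
    conc = np.zeros(shape, dtype=float)
    conc[nuc_mask] = conc_nuc_nm
    conc[cyt_mask] = conc_cyt_nm
    protein = background_au + conc / k_nm_per_au
    dna = np.where(nuc_mask, dna_level_au, 0.0)
    boundary = np.where(cell_mask, boundary_level_au, 0.0)

    rng = np.random.default_rng(seed)
    if poisson_scale > 0:
        protein = rng.poisson(protein * poisson_scale).astype(float) / poisson_scale
        dna = rng.poisson(dna * poisson_scale).astype(float) / poisson_scale
        boundary = rng.poisson(boundary * poisson_scale).astype(float) / poisson_scale
    if read_noise_sd > 0:
        protein = protein + rng.normal(0.0, read_noise_sd, shape)
        dna = dna + rng.normal(0.0, read_noise_sd, shape)
        boundary = boundary + rng.normal(0.0, read_noise_sd, shape)

    voxel_vol = float(np.prod(voxel_size_um))
    vols = {
        "nucleus": float(nuc_mask.sum()) * voxel_vol,
        "cytoplasm": float(cyt_mask.sum()) * voxel_vol,
        "cell": float(cell_mask.sum()) * voxel_vol,
    }
    counts = {
        "nucleus": conc_nuc_nm * vols["nucleus"] * NA_NM_UM3,
        "cytoplasm": conc_cyt_nm * vols["cytoplasm"] * NA_NM_UM3,
    }
    counts["cell"] = counts["nucleus"] + counts["cytoplasm"]
    truth = GroundTruth(
        "gen_image_stack",
        {
            "conc_nuc_nm": conc_nuc_nm,
            "conc_cyt_nm": conc_cyt_nm,
            "k_nm_per_au": k_nm_per_au,
            "background_au": background_au,
            "volumes_um3": vols,
            "counts": counts,
            "nucleus_analytic_volume_um3": nucleus.volume_um3,
            "nuclear_mask": nuc_mask,
            "cell_mask": cell_mask,
            "seed": seed,
        },
    )
    stack = ImageStack(
        dna=dna, boundary=boundary, protein=protein,
        voxel_size_um=tuple(float(v) for v in voxel_size_um),
    )
    return stack, truth


# ------------------------------------------------------------------ CoIP

def gen_coip(
    true_dimer_fraction: float,
    ip_efficiency: float,
    input_total_au: float = 1e5,
    loading: tuple[float, float, float] = (0.015, 0.1, 0.9),
    noise_cv: float = 0.0,
    seed: int = 0,
    antibody: str = "V5",
    benzonase: bool = False,
) -> tuple[CoIPExperiment, GroundTruth]:
    """Forward-simulate CoIP band intensities from a known dimer fraction.

    Under the equal-likelihood tag-pairing assumption (as many same-tag as
    cross-tag dimers), a dimer fraction d and pull-down efficiency e give
    %IP = e and %CoIP = e*d/3; band intensities are back-computed so the
    standard inversion recovers d exactly in the noiseless case.
    """
    if not 0 <= true_dimer_fraction <= 1:
        raise InvalidParameterError("dimer fraction must be in [0, 1]")
    if not 0 < ip_efficiency <= 1:
        raise InvalidParameterError("ip_efficiency must be in (0, 1]")
    input_frac, ip_load, coip_load = loading
    for frac in loading:
        if not 0 < frac <= 1:
            raise InvalidParameterError("loading fractions must be in (0, 1]")
    if input_total_au <= 0:
        raise InvalidParameterError("input_total_au must be > 0")
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")

    pct_ip = ip_efficiency
    pct_coip = ip_efficiency * true_dimer_fraction / 3.0
    i_in = input_total_au
    i_ip = pct_ip * ip_load * i_in / input_frac
    i_coip = pct_coip * coip_load * i_in / input_frac
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        i_ip = max(i_ip * (1.0 + rng.normal(0.0, noise_cv)), 0.0)
        i_coip = max(i_coip * (1.0 + rng.normal(0.0, noise_cv)), 0.0)
    exp = CoIPExperiment(
        antibody=antibody,
        benzonase=benzonase,
        i_in=i_in,
        i_ip=i_ip,
        i_coip=i_coip,
        input_fraction=input_frac,
        ip_load_fraction=ip_load,
        coip_load_fraction=coip_load,
    )
    truth = GroundTruth(
        "gen_coip",
        {
            "true_dimer_fraction": true_dimer_fraction,
            "ip_efficiency": ip_efficiency,
            "pct_ip": pct_ip,
            "pct_coip": pct_coip,
            "noise_cv": noise_cv,
            "seed": seed,
        },
    )
    return exp, truth


# ------------------------------------------------------------------ cell cycle

def gen_cell_cycle(
    fractions: tuple[float, float, float],
    dapi_means: tuple[float, float] = (100.0, 200.0),
    dapi_cv: float = 0.05,
    edu_pos_shift: float = 1000.0,
    n_events: int = 10000,
    seed: int = 0,
    edu_bg_mu_sigma: tuple[float, float] = (3.0, 0.3),
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate DAPI/EdU bivariate events plus an EdU-negative control.

    G1 events sit at the 2C DAPI mean, G2 at 4C, both EdU-negative; S
    events have DAPI uniform between 2C and 4C (times multiplicative noise)
    and EdU shifted up by ``edu_pos_shift``. Returns (events, control,
    truth); n_events = 0 yields empty tables.
    """
    f_g1, f_s, f_g2 = fractions
    if abs(f_g1 + f_s + f_g2 - 1.0) > 1e-9 or min(fractions) < 0:
        raise InvalidParameterError("fractions must be >= 0 and sum to 1")
    d2c, d4c = dapi_means
    if d4c <= d2c:
        raise InvalidParameterError("4C DAPI mean must exceed 2C mean")
    if n_events < 0:
        raise InvalidParameterError("n_events must be >= 0")
    bg_mu, bg_sigma = edu_bg_mu_sigma

    rng = np.random.default_rng(seed)
    cols = ["dapi_au", "edu_au", "phase"]
    if n_events == 0:
        empty = pd.DataFrame(columns=cols)
        ctrl = pd.DataFrame(columns=["dapi_au", "edu_au"])
        return empty, ctrl, GroundTruth("gen_cell_cycle", {"fractions": fractions})

    phases = rng.choice(3, size=n_events, p=[f_g1, f_s, f_g2])
    dapi = np.empty(n_events)
    edu = rng.lognormal(bg_mu, bg_sigma, n_events)
    for ph, mean in ((0, d2c), (2, d4c)):
        idx = phases == ph
        dapi[idx] = rng.normal(mean, dapi_cv * mean, idx.sum())
    idx_s = phases == 1
    base = rng.uniform(d2c, d4c, idx_s.sum())
    dapi[idx_s] = base * (1.0 + rng.normal(0.0, dapi_cv, idx_s.sum()))
    edu[idx_s] += edu_pos_shift

    events = pd.DataFrame(
        {"dapi_au": dapi, "edu_au": edu,
         "phase": np.array(["G1", "S", "G2"])[phases]}
    )
    # control: same cell-cycle DAPI distribution, background-only EdU
    ctrl_phases = rng.choice(3, size=n_events, p=[f_g1, f_s, f_g2])
    ctrl_dapi = np.empty(n_events)
    for ph, mean in ((0, d2c), (2, d4c)):
        idx = ctrl_phases == ph
        ctrl_dapi[idx] = rng.normal(mean, dapi_cv * mean, idx.sum())
    idx_s = ctrl_phases == 1
    ctrl_dapi[idx_s] = rng.uniform(d2c, d4c, idx_s.sum()) * (
        1.0 + rng.normal(0.0, dapi_cv, idx_s.sum())
    )
    control = pd.DataFrame(
        {"dapi_au": ctrl_dapi, "edu_au": rng.lognormal(bg_mu, bg_sigma, n_events)}
    )
    truth = GroundTruth(
        "gen_cell_cycle",
        {
            "fractions": fractions,
            "dapi_means": dapi_means,
            "dapi_cv": dapi_cv,
            "edu_pos_shift": edu_pos_shift,
            "n_events": n_events,
            "seed": seed,
            "realized_fractions": tuple(
                float((phases == p).mean()) for p in (0, 1, 2)
            ),
        },
    )
    return events, control, truth
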