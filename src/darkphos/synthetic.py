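"""Synthetic study generator with known ground truth.

Emulates the full measurement campaign on a hot phosphate solution:

* CPMG/inversion-recovery relaxation series (R1, R2 vs temperature,
  293-343 K in 10 K steps);
* CEST Z-spectra, -4000..+4000 Hz in 200 Hz steps, 5 s continuous-wave
  saturation: a temperature series at 150 Hz nutation (298-353 K) and a
  power series (20-150 Hz) at 298 K;
* DOSY gradient series at 293 and 343 K, 16 linearly spaced gradients with
  the last point attenuated below 5%.

Noiseless observables are computed by the forward simulators
(:mod:`darkphos.bloch`, :mod:`darkphos.dosy`); independent multiplicative
Gaussian noise of fractional size ``noise_sigma`` is then applied per data
point from a seeded generator, so a study is bit-for-bit reproducible from
its seed and the stored truth suffices to recompute every noiseless value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import bloch, dosy
from .thermo import ThermoKineticParams, exchange_state

__all__ = [
    "StudyDesign",
    "StudyTruth",
    "SyntheticStudy",
    "default_truth",
    "spin_system_at",
    "generate_relaxation_observables",
    "generate_study",
]


def _default_offsets() -> np.ndarray:
    return np.arange(-4000.0, 4001.0, 200.0)


@dataclass(frozen=True)
class StudyDesign:
    """Acquisition design of one synthetic campaign."""

    temperatures_relax: tuple = (293.0, 303.0, 313.0, 323.0, 333.0, 343.0)
    temperatures_cest: tuple = (298.0, 313.0, 323.0, 333.0, 343.0, 353.0)
    offsets: np.ndarray = field(default_factory=_default_offsets)
    nutations: tuple = (20.0, 30.0, 50.0, 100.0, 150.0)
    sat_duration: float = 5.0
    temperatures_dosy: tuple = (293.0, 343.0)
    n_gradients: int = 16
    dosy_delta_small: float = 2e-3
    dosy_delta_big: float = 50e-3
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("temperatures_relax", "temperatures_cest", "nutations",
                     "temperatures_dosy"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))


def _linear(T: float, anchors: tuple[tuple[float, float], tuple[float, float]]) -> float:
    (t0, v0), (t1, v1) = anchors
    return v0 + (v1 - v0) * (T - t0) / (t1 - t0)


@dataclass(frozen=True)
class StudyTruth:
    """Ground-truth parameters sufficient to recompute every noiseless observable."""

    thermo: ThermoKineticParams
    #: dark-pool R2 (s^-1) anchors: linear in T between these two points
    r2b_anchors: tuple = ((293.0, 450.0), (353.0, 1000.0))
    #: monomer R1 (s^-1) anchors: gently declining, 1-2 orders below R2obs
    r1a_anchors: tuple = ((293.0, 0.06), (353.0, 0.04))
    #: true diffusion coefficients (m^2/s) by DOSY temperature
    dosy_D: tuple = ((293.0, 7.5e-10), (343.0, 3.2e-9))
    exchange_on: bool = True

    def r2b_at(self, T: float) -> float:
        return _linear(T, self.r2b_anchors)

    def r1a_at(self, T: float) -> float:
        return _linear(T, self.r1a_anchors)

    def diffusion_at(self, T: float) -> float:
        table = dict(self.dosy_D)
        if T not in table:
            raise KeyError(f"no true diffusion coefficient stored for T={T} K")
        return table[T]


def default_truth() -> StudyTruth:
    """The fitted exchange model used as the default simulation truth.

    Thermodynamics dH = 25 kJ/mol, dS = 30 J/(mol K) (dark fraction 0.0013
    at 293 K rising to 0.0073 at 353 K); Arrhenius kinetics k0 = 2e4 s^-1,
    Ea = 10 kJ/mol (forward rate 350 -> 660 s^-1); dark-pool R2 rising
    linearly from 450 s^-1 at 293 K to 1000 s^-1 at 353 K.
    """
    return StudyTruth(thermo=ThermoKineticParams(dH=25e3, dS=30.0, k0=20e3, Ea=10e3))


def spin_system_at(truth: StudyTruth, T: float) -> bloch.SpinSystemParams:
    """Two-pool spin system implied by the truth at temperature ``T``.

    The monomer pool is in the fast-motion regime so R2A = R1A; the dark
    pool shares the monomer chemical shift and R1B = R1A (the fit is
    insensitive to R1B over two orders of magnitude).
    """
    r1a = truth.r1a_at(T)
    if truth.exchange_on:
        state = exchange_state(truth.thermo, T)
        pB, kf, kb = state.pB, state.kf, state.kb
    else:
        pB, kf, kb = 0.0, 0.0, 0.0
    return bloch.SpinSystemParams(
        R1A=r1a, R2A=r1a, R1B=r1a, R2B=truth.r2b_at(T),
        pB=pB, kf=kf, kb=kb, offsetA=0.0, offsetB=0.0,
    )


def generate_relaxation_observables(truth: StudyTruth, T: float) -> tuple[float, float]:
    """Noiseless (R1obs, R2obs) of the detected line at temperature ``T``."""
    return bloch.observed_rates(spin_system_at(truth, T))


@dataclass(frozen=True)
class SyntheticStudy:
    """Complete simulated campaign: data, truth, design and seed."""

    truth: StudyTruth
    design: StudyDesign
    relaxation: np.ndarray  # structured columns (T, R1obs, R2obs)
    zspectra: list  # list[bloch.ZSpectrum]
    dosy_datasets: list  # list[dosy.DosyDataset]
    seed: int

    @property
    def relaxation_series(self) -> list[tuple[float, float]]:
        """(T, R2obs) pairs, the input of the transverse-rate fit stage."""
        return [(float(t), float(r2)) for t, _, r2 in self.relaxation]


def _apply_noise(values: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return values
    return values * (1.0 + sigma * rng.standard_normal(values.shape))


def generate_study(truth: StudyTruth | None = None,
                   design: StudyDesign | None = None) -> SyntheticStudy:
    """Simulate the full campaign described by ``design`` under ``truth``."""
    if truth is None:
        truth = default_truth()
    if design is None:
        design = StudyDesign()
    rng = np.random.default_rng(design.seed)
    sigma = design.noise_sigma

    relax = np.empty((len(design.temperatures_relax), 3))
    for i, T in enumerate(design.temperatures_relax):
        r1, r2 = generate_relaxation_observables(truth, T)
        relax[i] = (T, r1, r2)
    relax[:, 1] = _apply_noise(relax[:, 1], sigma, rng)
    relax[:, 2] = _apply_noise(relax[:, 2], sigma, rng)

    zspectra = []
    nu_max = max(design.nutations)
    # temperature series at the strongest rf field
    for T in design.temperatures_cest:
        scheme = bloch.SaturationScheme(nutation=nu_max, duration=design.sat_duration,
                                        offsets=design.offsets)
        zs = bloch.simulate_z_spectrum(spin_system_at(truth, T), scheme)
        zspectra.append(replace(zs, temperature=T, z=_apply_noise(zs.z, sigma, rng)))
    # rf-power series at the lowest CEST temperature
    T_pow = min(design.temperatures_cest)
    for nu in design.nutations:
        if nu == nu_max:
            continue
        scheme = bloch.SaturationScheme(nutation=nu, duration=design.sat_duration,
                                        offsets=design.offsets)
        zs = bloch.simulate_z_spectrum(spin_system_at(truth, T_pow), scheme)
        zspectra.append(replace(zs, temperature=T_pow, z=_apply_noise(zs.z, sigma, rng)))

    dosy_datasets = []
    for T in design.temperatures_dosy:
        D = truth.diffusion_at(T)
        g = dosy.design_gradients(D, n=design.n_gradients,
                                  delta_small=design.dosy_delta_small,
                                  delta_big=design.dosy_delta_big)
        psi = dosy.attenuation(g, D, delta_small=design.dosy_delta_small,
                               delta_big=design.dosy_delta_big)
        dosy_datasets.append(dosy.DosyDataset(
            gradients=g, intensities=_apply_noise(psi, sigma, rng),
            delta_small=design.dosy_delta_small, delta_big=design.dosy_delta_big, T=T,
        ))

    return SyntheticStudy(truth=truth, design=design, relaxation=relax,
                          zspectra=zspectra, dosy_datasets=dosy_datasets,
                          seed=design.seed)
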