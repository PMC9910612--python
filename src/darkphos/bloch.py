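"""Two-pool Bloch-McConnell simulator for CEST Z-spectra.

Magnetization of a visible pool A (phosphate monomers) and a dark pool B
(assemblies) evolves under rotating-frame precession, a continuous-wave rf
field applied at the saturation offset, longitudinal/transverse relaxation,
and first-order A <-> B exchange.  The state vector is augmented with a
constant to carry the R1*Meq recovery terms,

    m = (MxA, MyA, MzA, MxB, MyB, MzB, 1),

so the equations of motion are dm/dt = L m with a constant 7x7 generator L
and the evolution over a saturation period is a single matrix exponential.

All interfaces use Hz for offsets and nutation frequencies; angular
frequencies (rad/s) appear only inside the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "SpinSystemParams",
    "SaturationScheme",
    "ZSpectrum",
    "build_generator",
    "equilibrium_state",
    "propagate",
    "steady_state_z_single_pool",
    "simulate_z_spectrum",
    "dip_width",
    "observed_rates",
]


@dataclass(frozen=True)
class SpinSystemParams:
    """Relaxation, offsets, population and exchange rates of the two pools.

    ``offsetA``/``offsetB`` are chemical-shift offsets from the carrier in
    Hz.  Equilibrium longitudinal magnetizations are (1-pB, pB) in
    normalized units.  Detailed balance ``kf*(1-pB) == kb*pB`` is enforced
    to 1e-9 relative.
    """

    R1A: float
    R2A: float
    R1B: float
    R2B: float
    pB: float
    kf: float
    kb: float
    offsetA: float = 0.0
    offsetB: float = 0.0

    def __post_init__(self) -> None:
        for name in ("R1A", "R2A", "R1B", "R2B", "kf", "kb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.pB <= 1.0:
            raise ValueError(f"pB must lie in [0, 1], got {self.pB}")
        flux_a = self.kf * (1.0 - self.pB)
        flux_b = self.kb * self.pB
        scale = max(flux_a, flux_b)
        if scale > 0 and abs(flux_a - flux_b) > 1e-9 * scale:
            raise ValueError(
                f"detailed balance violated: kf*(1-pB)={flux_a!r} vs kb*pB={flux_b!r}"
            )


@dataclass(frozen=True)
class SaturationScheme:
    """Continuous-wave saturation block: rf strength, duration, offset grid."""

    nutation: float  # Hz
    duration: float  # s
    offsets: np.ndarray = field(default_factory=lambda: np.arange(-4000.0, 4001.0, 200.0))

    def __post_init__(self) -> None:
        if self.nutation < 0:
            raise ValueError("nutation frequency must be >= 0")
        if not self.duration > 0:
            raise ValueError("saturation duration must be positive")
        offsets = np.asarray(self.offsets, dtype=float)
        if offsets.ndim != 1 or len(offsets) < 2 or np.any(np.diff(offsets) <= 0):
            raise ValueError("offsets must be a strictly increasing 1-D sequence")
        object.__setattr__(self, "offsets", offsets)


@dataclass(frozen=True)
class ZSpectrum:
    """Detected pool-A longitudinal magnetization vs saturation offset."""

    offsets: np.ndarray  # Hz
    z: np.ndarray  # normalized, dimensionless
    temperature: float | None = None  # K
    nutation: float | None = None  # Hz
    duration: float | None = None  # s

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if offsets.shape != z.shape:
            raise ValueError("offsets and z must have matching shapes")
        if not np.all(np.isfinite(z)):
            raise ValueError("z values must be finite")
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "z", z)


def build_generator(sys: SpinSystemParams, sat_offset: float, nutation: float) -> np.ndarray:
    """Constant coefficient operator of the augmented 7-state system.

    The rf field lies along x in the frame rotating at the saturation
    frequency, so each pool precesses at 2*pi*(offset_pool - sat_offset)
    and the rf couples My and Mz at omega1 = 2*pi*nutation.  Exchange
    couples corresponding components of A and B with rates -kf/+kb (A rows)
    and +kf/-kb (B rows); recovery toward (1-pB, pB) enters through the
    constant-augmentation column.
    """
    dA = 2.0 * np.pi * (sys.offsetA - sat_offset)
    dB = 2.0 * np.pi * (sys.offsetB - sat_offset)
    w1 = 2.0 * np.pi * nutation
    meqA = 1.0 - sys.pB
    meqB = sys.pB

    L = np.zeros((7, 7))
    for base, (r1, r2, d) in zip((0, 3), ((sys.R1A, sys.R2A, dA), (sys.R1B, sys.R2B, dB))):
        x, y, z = base, base + 1, base + 2
        L[x, x] = -r2
        L[x, y] = d
        L[y, x] = -d
        L[y, y] = -r2
        L[y, z] = w1
        L[z, y] = -w1
        L[z, z] = -r1
    L[2, 6] = sys.R1A * meqA
    L[5, 6] = sys.R1B * meqB
    # first-order exchange on every magnetization component
    for i in range(3):
        L[i, i] += -sys.kf
        L[i, i + 3] += sys.kb
        L[i + 3, i] += sys.kf
        L[i + 3, i + 3] += -sys.kb
    return L


def equilibrium_state(sys: SpinSystemParams) -> np.ndarray:
    """Thermal-equilibrium augmented state (0, 0, 1-pB, 0, 0, pB, 1)."""
    return np.array([0.0, 0.0, 1.0 - sys.pB, 0.0, 0.0, sys.pB, 1.0])


def propagate(
    sys: SpinSystemParams,
    sat_offset: float,
    nutation: float,
    t: float,
    M0: np.ndarray,
) -> np.ndarray:
    """Evolve the augmented state for time ``t`` via a matrix exponential."""
    if t < 0:
        raise ValueError("evolution time must be >= 0")
    M0 = np.asarray(M0, dtype=float)
    if M0.shape != (7,):
        raise ValueError("M0 must be an augmented 7-state vector")
    if t == 0:
        return M0.copy()
    L = build_generator(sys, sat_offset, nutation)
    return expm(L * t) @ M0


def steady_state_z_single_pool(R1: float, R2: float, nutation: float, delta: float) -> float:
    """Closed-form saturated steady state of an isolated pool.

    For a single pool irradiated at offset ``delta`` (Hz) with nutation
    frequency ``nutation`` (Hz), the stationary longitudinal magnetization
    relative to equilibrium is

        z = R1 (R2^2 + D^2) / (R1 (R2^2 + D^2) + w1^2 R2),

    with D = 2*pi*delta and w1 = 2*pi*nutation.  Serves as the no-exchange
    oracle for the full simulator.
    """
    if not (R1 > 0 and R2 > 0):
        raise ValueError("R1 and R2 must be positive")
    D = 2.0 * np.pi * delta
    w1 = 2.0 * np.pi * nutation
    num = R1 * (R2 * R2 + D * D)
    return num / (num + w1 * w1 * R2)


def simulate_z_spectrum(sys: SpinSystemParams, scheme: SaturationScheme) -> ZSpectrum:
    """Z-spectrum: normalized pool-A Mz after the saturation period.

    Starts each offset from thermal equilibrium and reports
    MzA(duration)/MzA_eq; pool B is spectroscopically silent and does not
    contribute to the detected signal.
    """
    m0 = equilibrium_state(sys)
    meqA = 1.0 - sys.pB
    if meqA <= 0:
        raise ValueError("pool A population must be positive to detect a signal")
    # one stacked matrix exponential over the offset grid
    L = np.stack([build_generator(sys, off, scheme.nutation) for off in scheme.offsets])
    z = (expm(L * scheme.duration) @ m0)[:, 2] / meqA
    return ZSpectrum(
        offsets=scheme.offsets.copy(),
        z=z,
        nutation=scheme.nutation,
        duration=scheme.duration,
    )


def _interp_crossing(x0: float, x1: float, z0: float, z1: float, level: float) -> float:
    if z1 == z0:
        return x0
    return x0 + (level - z0) * (x1 - x0) / (z1 - z0)


def dip_width(zs: ZSpectrum) -> float:
    """Full width (Hz) of the saturation dip at half its depth.

    The baseline is the mean z of the two extreme offsets and the
    half-height level is (baseline + min)/2; crossings are located by
    linear interpolation between grid points.  Raises if the minimum sits
    on a boundary offset (dip not resolved within the scan window).
    """
    z = zs.z
    offsets = zs.offsets
    if len(z) < 3:
        raise ValueError("need at least 3 points to measure a dip width")
    imin = int(np.argmin(z))
    if imin == 0 or imin == len(z) - 1:
        raise ValueError("dip not resolved within scan window")
    baseline = 0.5 * (z[0] + z[-1])
    level = 0.5 * (baseline + z[imin])

    left = None
    for i in range(imin - 1, -1, -1):
        if z[i] >= level:
            left = _interp_crossing(offsets[i], offsets[i + 1], z[i], z[i + 1], level)
            break
    right = None
    for i in range(imin + 1, len(z)):
        if z[i] >= level:
            right = _interp_crossing(offsets[i - 1], offsets[i], z[i - 1], z[i], level)
            break
    if left is None or right is None:
        raise ValueError("dip not resolved within scan window")
    return float(right - left)


def _slowest_mode_rate(r_a: float, r_b: float, sys: SpinSystemParams) -> float:
    """Decay rate of the dominant eigenmode of a 2x2 relaxation-exchange block."""
    K = np.array([[-r_a - sys.kf, sys.kb], [sys.kf, -r_b - sys.kb]])
    w, V = np.linalg.eig(K)
    start = np.array([1.0 - sys.pB, sys.pB])
    coeff = np.linalg.solve(V, start)
    mode = int(np.argmax(np.abs(coeff)))
    return float(-np.real(w[mode]))


def observed_rates(sys: SpinSystemParams) -> tuple[float, float]:
    """Apparent (R1obs, R2obs) of the detected line under exchange.

    Valid for the shared-chemical-shift case (offsetA == offsetB), where
    transverse and longitudinal blocks decouple into real 2x2 operators.
    Each observed rate is the decay rate of the eigenmode carrying the
    largest share of the equilibrium-weighted start vector; in the
    kf -> infinity limit R2obs tends to the population-weighted mean
    (1-pB)*R2A + pB*R2B.
    """
    if sys.offsetA != sys.offsetB:
        raise ValueError("observed_rates requires offsetA == offsetB")
    r1 = _slowest_mode_rate(sys.R1A, sys.R1B, sys)
    r2 = _slowest_mode_rate(sys.R2A, sys.R2B, sys)
    return r1, r2
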