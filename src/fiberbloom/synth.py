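"""Seeded generators emulating the statistical structure of the measurements.

Three kinds of inputs are emulated so that every analysis stage is
testable end to end without external data:

* release time series — the cylinder-diffusion forward model plus
  i.i.d. Gaussian noise on the released fraction,
* crystal observations — nitrile-stretch positions jittered around
  polymorph reference values, with color/habit copied from the library
  (each attribute independently recorded with a completeness
  probability), and full synthetic Raman spectra (Lorentzian lines on a
  linear baseline with Gaussian noise),
* measured unit cells — reference cells perturbed by relative length
  and absolute angle noise at the scale of typical 3D ED esds.

Every generator is a pure function of (config, seed): identical inputs
give identical outputs, and truth labels always accompany the generated
observations so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cells import CellReferenceEntry, UnitCell
from .diffusion import FiberGeometry, TransportParameters, dimensionless_state, release_fraction
from .raman import RamanReferenceEntry, default_library

__all__ = [
    "GeneratorConfig",
    "PopulationSpec",
    "generate_release_observations",
    "generate_crystal_population",
    "generate_raman_spectrum",
    "generate_perturbed_cell",
]

#: the composition observed on 0.1 wt% fibers after 6 days of aging
FIBER_SURFACE_COMPOSITION = {"Y": 2, "R": 2, "ON": 29}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the generators.

    Defaults mirror the characterized system: D = 3.5e-11 cm^2/s for
    the additive in polyethylene, fiber radius 0.03 cm (0.6 mm
    diameter), 1 wt% loading, diffusion-limited surface transfer.
    Noise scales are stand-ins for unreported instrument variability.
    """

    seed: int
    transport: TransportParameters = field(
        default_factory=lambda: TransportParameters(
            diffusion_coeff_cm2_s=3.5e-11, initial_conc_frac=0.01
        )
    )
    geometry: FiberGeometry = field(default_factory=lambda: FiberGeometry(radius_cm=0.03))
    noise_w: float = 0.02
    raman_sigma_shift_cm1: float = 0.5
    raman_fwhm_cm1: float = 6.0
    raman_noise: float = 0.01
    raman_baseline: float = 0.05
    raman_baseline_slope: float = 1e-4
    cell_sigma_len_rel: float = 0.005
    cell_sigma_ang_deg: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "noise_w", "raman_sigma_shift_cm1", "raman_fwhm_cm1", "raman_noise",
            "cell_sigma_len_rel", "cell_sigma_ang_deg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PopulationSpec:
    """How many crystals of which polymorphs, and how complete the attributes are."""

    composition: dict[str, float]
    n_crystals: int | None = None
    attribute_completeness: float = 1.0

    def counts(self) -> dict[str, int]:
        """Resolve the composition to integer counts."""
        vals = list(self.composition.values())
        if all(float(v).is_integer() for v in vals):
            counts = {k: int(v) for k, v in self.composition.items()}
            n = sum(counts.values())
            if self.n_crystals is not None and self.n_crystals != n:
                raise ValueError(
                    f"composition counts sum to {n}, but n_crystals = {self.n_crystals}"
                )
            return counts
        if self.n_crystals is None:
            raise ValueError("probabilistic composition requires n_crystals")
        total = sum(vals)
        probs = {k: v / total for k, v in self.composition.items()}
        # largest-remainder rounding keeps the total exact
        raw = {k: p * self.n_crystals for k, p in probs.items()}
        counts = {k: int(math.floor(v)) for k, v in raw.items()}
        short = self.n_crystals - sum(counts.values())
        for k, _ in sorted(raw.items(), key=lambda kv: kv[1] - math.floor(kv[1]), reverse=True)[:short]:
            counts[k] += 1
        return counts


def generate_release_observations(
    config: GeneratorConfig, times_s: np.ndarray
) -> pd.DataFrame:
    """Noisy released-fraction observations from the forward model.

    Noise is applied only for t > 0 (a blank wash at t = 0 reads zero by
    convention); observations are clipped to [0, 1.05], the plausible
    measurement range including overshoot.
    """
    times_s = np.asarray(times_s, dtype=float)
    if times_s.size > 1 and np.any(np.diff(times_s) <= 0):
        raise ValueError("times_s must be strictly increasing")
    rng = config.rng()
    taus = config.transport.diffusion_coeff_cm2_s * times_s / config.geometry.radius_cm**2
    eta = dimensionless_state(config.transport, config.geometry, 0.0).eta
    w_true = np.atleast_1d(release_fraction(taus, eta=eta))
    noise = rng.normal(0.0, config.noise_w, size=times_s.shape) if config.noise_w > 0 else 0.0
    w_obs = np.clip(w_true + noise, 0.0, 1.05)
    w_obs = np.where(times_s == 0, 0.0, w_obs)
    return pd.DataFrame(
        {"time_s": times_s, "fraction_w": w_obs, "w_true": w_true, "seed": config.seed}
    )


def generate_crystal_population(
    spec: PopulationSpec,
    config: GeneratorConfig,
    library: tuple[RamanReferenceEntry, ...] | None = None,
) -> pd.DataFrame:
    """Per-crystal observations for a population of known composition.

    Each crystal draws its measured nu_CN from one of its polymorph's
    reference positions plus Gaussian jitter; color and habit are copied
    from the reference entry, each present with probability
    ``attribute_completeness``.  The ``true_polymorph`` column retains
    the ground truth.
    """
    entries = {e.polymorph_id: e for e in (library or default_library())}
    counts = spec.counts()
    unknown = set(counts) - set(entries)
    if unknown:
        raise ValueError(f"unknown polymorph ids in composition: {sorted(unknown)}")
    rng = config.rng()
    rows = []
    i = 0
    for pid, n in counts.items():
        e = entries[pid]
        for _ in range(n):
            pos = e.nu_cn_cm1[rng.integers(len(e.nu_cn_cm1))]
            nu = pos + rng.normal(0.0, config.raman_sigma_shift_cm1)
            color = e.color if rng.random() < spec.attribute_completeness else None
            habit = (
                (e.habit if e.habit != "any" else None)
                if rng.random() < spec.attribute_completeness
                else None
            )
            rows.append(
                {
                    "source_id": f"xtal-{i:04d}",
                    "true_polymorph": pid,
                    "nu_cn_cm1": nu,
                    "color": color,
                    "habit": habit,
                    "seed": config.seed,
                }
            )
            i += 1
    return pd.DataFrame(rows)


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    g = fwhm / 2.0
    return g**2 / ((x - center) ** 2 + g**2)


def generate_raman_spectrum(
    polymorph_id: str,
    config: GeneratorConfig,
    library: tuple[RamanReferenceEntry, ...] | None = None,
    grid_cm1: np.ndarray | None = None,
) -> pd.DataFrame:
    """Synthetic two-column Raman spectrum of the nitrile region.

    Unit-amplitude Lorentzians at each reference position (the RPL
    doublet emits both components), a gently sloping linear baseline,
    and Gaussian noise.  With noise and baseline set to zero the values
    are the analytic Lorentzian sum.
    """
    entries = {e.polymorph_id: e for e in (library or default_library())}
    if polymorph_id not in entries:
        raise ValueError(f"unknown polymorph {polymorph_id!r}")
    e = entries[polymorph_id]
    x = grid_cm1 if grid_cm1 is not None else np.arange(2150.0, 2290.0 + 1e-9, 0.5)
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x)
    for pos in e.nu_cn_cm1:
        y += _lorentzian(x, pos, config.raman_fwhm_cm1)
    y += config.raman_baseline + config.raman_baseline_slope * (x - x[0])
    if config.raman_noise > 0:
        y += config.rng().normal(0.0, config.raman_noise, size=x.shape)
    return pd.DataFrame({"wavenumber_cm1": x, "intensity": y})


def generate_perturbed_cell(
    ref: CellReferenceEntry,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    max_retries: int = 100,
) -> UnitCell:
    """Reference cell with measurement-scale perturbations.

    Lengths are scaled by (1 + N(0, sigma_len_rel)) and angles shifted
    by N(0, sigma_ang_deg); draws producing a degenerate metric are
    resampled (bounded retries).
    """
    rng = rng if rng is not None else config.rng()
    base = ref.cell
    for _ in range(max_retries):
        a, b, c = (
            L * (1.0 + rng.normal(0.0, config.cell_sigma_len_rel))
            for L in base.lengths()
        )
        al, be, ga = (
            A + rng.normal(0.0, config.cell_sigma_ang_deg) for A in base.angles()
        )
        try:
            return UnitCell(a, b, c, al, be, ga)
        except ValueError:
            continue
    raise ValueError(f"could not draw a valid perturbed cell for {ref.polymorph_id}")
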