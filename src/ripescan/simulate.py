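"""Synthetic ripening-cohort generator: traits, spectra and fruit color.

The generator emulates a fruit-ripening study cohort — 68 samples per
species split across ripening stages (three for mandarin, four for tomato)
— with the statistical structure the downstream analysis assumes:

* per-stage trait distributions whose means follow the published stage
  summaries (chlorophylls, acidity and firmness fall with ripening; sugars,
  the maturity index, carotenoids and lycopene rise),
* a near-perfect chlorophyll a / chlorophyll b linkage (the two pigments
  co-degrade, so their correlation across a ripening cohort is ~1),
* reflectance spectra generated by a Beer–Lambert-style forward model in
  which the pigment traits drive Gaussian/logistic absorption features, so
  the ratio-index-to-trait coupling exists *by construction*,
* mean fruit color obtained by band-averaging each spectrum.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StageProfile",
    "SimConfig",
    "MANDARIN_TRAITS",
    "TOMATO_TRAITS",
    "WAVELENGTH_GRID",
    "SPECTRAL_SHAPE",
    "default_profiles",
    "default_allocation",
    "simulate_traits",
    "simulate_spectrum",
    "simulate_rgb",
    "simulate_cohort",
]

MANDARIN_TRAITS = ("Chl a", "Chl b", "TSS", "TA", "TSS/TA", "Car")
TOMATO_TRAITS = MANDARIN_TRAITS + ("Lycopene", "Firmness")

#: Acquisition grid: 302-1148 nm at a 2 nm step (424 points).
WAVELENGTH_GRID = np.arange(302.0, 1150.0, 2.0)

# Per-stage (min, max, mean) envelopes for each trait, as published for a
# Balady mandarin / Alissa F1 tomato ripening series.  Stage order is
# unripe -> overripe.  Units: Chl a/b mg/g tissue; TSS Brix %; TA %;
# TSS/TA dimensionless; Car mg/g fw; Lycopene ug/g; Firmness Kgf/cm2.
_MANDARIN_STAGES = ("unripe", "ripe", "overripe")
_MANDARIN_TABLE = {
    "Chl a":  [(3.56, 4.24, 3.92), (0.22, 0.54, 0.39), (0.03, 0.16, 0.08)],
    "Chl b":  [(4.97, 6.23, 5.57), (0.36, 0.84, 0.62), (0.06, 0.19, 0.11)],
    "TSS":    [(8.80, 10.20, 9.56), (10.00, 12.00, 10.85), (10.90, 12.00, 11.70)],
    "TA":     [(1.15, 1.42, 1.31), (0.68, 0.77, 0.72), (0.60, 0.67, 0.64)],
    "TSS/TA": [(6.82, 8.56, 7.33), (13.08, 17.41, 15.07), (16.81, 19.61, 18.35)],
    "Car":    [(0.07, 0.09, 0.08), (0.14, 0.21, 0.17), (0.21, 0.23, 0.22)],
}
_TOMATO_STAGES = ("green_dark", "yellow_green", "red_light", "red_dark")
_TOMATO_TABLE = {
    "Chl a":    [(0.90, 1.57, 1.30), (0.81, 0.98, 0.92), (0.61, 0.88, 0.79), (0.56, 0.80, 0.70)],
    "Chl b":    [(0.88, 1.51, 1.26), (0.79, 1.20, 0.98), (0.56, 1.02, 0.82), (0.47, 0.97, 0.70)],
    "TSS":      [(4.00, 5.20, 4.58), (4.70, 5.60, 5.15), (5.30, 6.00, 5.60), (5.70, 6.80, 6.00)],
    "TA":       [(0.62, 0.71, 0.68), (0.74, 0.76, 0.75), (0.77, 0.80, 0.79), (0.82, 0.83, 0.82)],
    "TSS/TA":   [(6.13, 7.28, 6.69), (6.30, 7.39, 6.87), (6.73, 7.53, 7.11), (6.89, 8.27, 7.28)],
    "Car":      [(0.10, 0.13, 0.12), (0.11, 0.15, 0.14), (0.14, 0.19, 0.16), (0.21, 0.29, 0.22)],
    "Lycopene": [(4.53, 12.48, 9.39), (14.04, 42.76, 22.75), (34.17, 50.09, 42.98), (50.87, 65.70, 60.28)],
    "Firmness": [(610.0, 690.0, 647.50), (510.0, 610.0, 548.24), (410.0, 510.0, 476.47), (350.0, 420.0, 383.44)],
}

#: Structural constants of the forward spectral model (all config-exposed).
#: Absorption features: a red/green chlorophyll plateau bounded by logistic
#: shoulders (the right shoulder *is* the red edge), a blue chlorophyll
#: (Soret) Gaussian, and carotenoid/lycopene Gaussians in the 450-505 nm
#: window.  Baseline is a gentle visible-to-NIR ramp; noise is
#: multiplicative lognormal.
SPECTRAL_SHAPE = {
    "baseline_low": 0.72,        # visible baseline reflectance
    "baseline_rise": 0.10,       # extra NIR reflectance
    "baseline_center": 760.0,    # nm, midpoint of the baseline ramp
    "baseline_width": 120.0,     # nm
    "chl_amp": 0.33,             # optical depth per unit chlorophyll load
    "chl_left_nm": 500.0,        # green shoulder of the chlorophyll plateau
    "chl_left_width": 15.0,
    "chl_edge_nm": 695.0,        # red-edge midpoint
    "chl_edge_width": 8.0,
    "soret_amp": 0.06,           # blue chlorophyll (Soret) band — in fruit
    "soret_nm": 430.0,           # skin the blue window is carotenoid-dominated
    "soret_width": 34.0,
    "car_amp": 4.0,              # optical depth per unit carotenoid (mg/g)
    "car_bands": ((450.0, 22.0, 1.0), (480.0, 22.0, 0.9)),
    "lyc_amp": 0.018,            # optical depth per unit lycopene (ug/g)
    "lyc_nm": 505.0,
    "lyc_width": 18.0,
    "chlb_weight": 0.5,          # chlorophyll load = Chl a + w * Chl b
    "noise_sigma": 0.01,         # lognormal sigma at noise_scale = 1
    # per-sample biological nuisances (trait-independent)
    "edge_jitter_nm": 2.5,       # sd of the random shift of the pigment band edges
    "edge_width_logsd": 0.3,     # lognormal spread of the band-shoulder widths
    "flav_amp": 2.0,             # skin flavonoid/phenolic blue absorber, scaled by Car
    "flav_nm": 410.0,
    "flav_width": 80.0,
    "flav_logsd": 1.0,           # lognormal spread of the flavonoid factor
    "nir_scatter_sd": 0.05,      # sd of the per-sample NIR albedo factor (log scale)
    "nir_scatter_nm": 755.0,     # onset midpoint of the scattering term
    "nir_scatter_width": 20.0,
    "uv_scatter_sd": 0.08,       # sd of the per-sample UV cuticle factor (log scale)
    "uv_scatter_nm": 430.0,      # offset midpoint of the UV screening term
    "uv_scatter_width": 40.0,
}


@dataclass(frozen=True)
class StageProfile:
    """Trait distribution for one ripening stage of one species."""

    species: str
    stage: str
    trait_means: dict[str, float]
    trait_sds: dict[str, float]

    def __post_init__(self) -> None:
        traits = MANDARIN_TRAITS if self.species == "mandarin" else TOMATO_TRAITS
        missing = [t for t in traits if t not in self.trait_means]
        if missing:
            raise ValueError(f"profile for {self.species}/{self.stage} missing traits {missing}")
        bad = [t for t, s in self.trait_sds.items() if s < 0]
        if bad:
            raise ValueError(f"negative standard deviation for traits {bad}")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    ``stage_allocation`` is the per-stage sample count (defaults to the
    closest-to-equal split of ``n_total``); ``noise_scale`` multiplies the
    spectral/RGB measurement-noise sigma.
    """

    species: str
    n_total: int = 68
    stage_allocation: tuple[int, ...] | None = None
    seed: int = 0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.species not in ("mandarin", "tomato"):
            raise ValueError(f"unknown species {self.species!r}")
        n_stages = 3 if self.species == "mandarin" else 4
        if self.n_total < n_stages:
            raise ValueError("n_total must be at least the number of stages")
        alloc = self.stage_allocation
        if alloc is None:
            alloc = default_allocation(self.species, self.n_total)
            object.__setattr__(self, "stage_allocation", tuple(alloc))
        else:
            object.__setattr__(self, "stage_allocation", tuple(int(a) for a in alloc))
        if len(self.stage_allocation) != n_stages:
            raise ValueError(f"expected {n_stages} stage counts, got {len(self.stage_allocation)}")
        if sum(self.stage_allocation) != self.n_total:
            raise ValueError("stage_allocation must sum to n_total")


def default_allocation(species: str, n_total: int = 68) -> tuple[int, ...]:
    """Closest-to-equal split of the cohort across ripening stages."""
    n_stages = 3 if species == "mandarin" else 4
    base, extra = divmod(n_total, n_stages)
    return tuple(base + (1 if i < extra else 0) for i in range(n_stages))


def default_profiles(species: str) -> list[StageProfile]:
    """Bundled stage profiles for a species.

    Means are the published per-stage means; standard deviations use the
    normal-range heuristic sd = (max - min) / 4.
    """
    if species == "mandarin":
        stages, table = _MANDARIN_STAGES, _MANDARIN_TABLE
    elif species == "tomato":
        stages, table = _TOMATO_STAGES, _TOMATO_TABLE
    else:
        raise ValueError(f"unknown species {species!r}; expected 'mandarin' or 'tomato'")
    profiles = []
    for k, stage in enumerate(stages):
        means = {t: table[t][k][2] for t in table}
        sds = {t: (table[t][k][1] - table[t][k][0]) / 4.0 for t in table}
        profiles.append(StageProfile(species, stage, means, sds))
    return profiles


def _truncnorm_positive(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated to (0, inf) via rejection sampling."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    # pathological profile (mean far below 0): clamp the stragglers
    return np.clip(out, 1e-9, None)


def simulate_traits(config: SimConfig, profiles: list[StageProfile] | None = None) -> pd.DataFrame:
    """Draw one trait table for a ripening cohort.

    Each trait is drawn per stage from a positive-truncated normal, except:

    * ``Chl b`` is an affine function of the drawn ``Chl a`` (fit through
      the stage means) plus 2% relative noise — the two chlorophylls
      co-degrade, so their cohort correlation is ~1;
    * ``TSS/TA`` is recomputed as TSS / TA after both are drawn (never drawn
      independently); a zero TA draw is re-drawn.

    Returns a DataFrame with ``sample_id``, ``species``, ``stage`` and one
    column per trait; deterministic for a fixed config.
    """
    if profiles is None:
        profiles = default_profiles(config.species)
    traits = MANDARIN_TRAITS if config.species == "mandarin" else TOMATO_TRAITS
    rng = np.random.default_rng(config.seed)

    # chlorophyll a -> b affine link through the stage means
    a_means = np.array([p.trait_means["Chl a"] for p in profiles])
    b_means = np.array([p.trait_means["Chl b"] for p in profiles])
    slope, intercept = np.polyfit(a_means, b_means, 1)

    frames = []
    offset = 0
    for prof, n in zip(profiles, config.stage_allocation):
        block: dict[str, np.ndarray] = {}
        chla = _truncnorm_positive(rng, prof.trait_means["Chl a"], prof.trait_sds["Chl a"], n)
        block["Chl a"] = chla
        chlb = intercept + slope * chla
        chlb = chlb + rng.normal(0.0, 0.02 * prof.trait_means["Chl b"], n)
        block["Chl b"] = np.clip(chlb, 1e-6, None)
        for t in traits:
            if t in ("Chl a", "Chl b", "TSS/TA"):
                continue
            block[t] = _truncnorm_positive(rng, prof.trait_means[t], prof.trait_sds[t], n)
        ta = block["TA"]
        for _ in range(100):  # division guard: re-draw exact zeros
            zero = ta == 0
            if not zero.any():
                break
            ta[zero] = rng.normal(prof.trait_means["TA"], prof.trait_sds["TA"], int(zero.sum()))
            ta = np.abs(ta)
        block["TA"] = ta
        block["TSS/TA"] = block["TSS"] / block["TA"]
        df = pd.DataFrame({t: block[t] for t in traits})
        df.insert(0, "stage", prof.stage)
        df.insert(0, "species", config.species)
        df.insert(0, "sample_id", [f"{config.species[:3]}-{i:03d}" for i in range(offset, offset + n)])
        frames.append(df)
        offset += n
    return pd.concat(frames, ignore_index=True)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((wl - center) / width) ** 2))


def _logistic(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wl - center) / width))


def absorption_profile(
    trait_row,
    wl: np.ndarray | None = None,
    shape: dict | None = None,
    edge_shift: float = 0.0,
    flav_factor: float = 0.0,
    width_factor: float = 1.0,
) -> np.ndarray:
    """Total optical depth at each wavelength for one sample's pigment traits.

    ``edge_shift`` (nm) displaces the chlorophyll band shoulders and
    ``width_factor`` rescales their steepness, emulating per-sample
    red-edge position/shape variability; ``flav_factor`` scales a skin
    flavonoid blue absorber (itself proportional to the carotenoid level,
    so a pigment-free sample stays absorption-free).
    """
    p = SPECTRAL_SHAPE if shape is None else shape
    if wl is None:
        wl = WAVELENGTH_GRID
    chla = float(trait_row["Chl a"])
    chlb = float(trait_row["Chl b"])
    car = float(trait_row["Car"])
    lyc = float(trait_row["Lycopene"]) if "Lycopene" in trait_row else 0.0
    for name, v in (("Chl a", chla), ("Chl b", chlb), ("Car", car), ("Lycopene", lyc)):
        if v < 0:
            raise ValueError(f"negative pigment value for {name}: {v}")

    chl_load = chla + p["chlb_weight"] * chlb
    plateau = _logistic(wl, p["chl_left_nm"] + edge_shift, p["chl_left_width"] * width_factor) * (
        1.0 - _logistic(wl, p["chl_edge_nm"] + edge_shift, p["chl_edge_width"] * width_factor)
    )
    absorb = p["chl_amp"] * chl_load * plateau
    absorb = absorb + p["soret_amp"] * chl_load * _gauss(wl, p["soret_nm"], p["soret_width"])
    car_profile = sum(w * _gauss(wl, c, s) for c, s, w in p["car_bands"])
    absorb = absorb + p["car_amp"] * car * car_profile
    absorb = absorb + p["lyc_amp"] * lyc * (
        car_profile + _gauss(wl, p["lyc_nm"], p["lyc_width"])
    )
    absorb = absorb + flav_factor * car * _gauss(wl, p["flav_nm"], p["flav_width"])
    return absorb


def simulate_spectrum(trait_row, seed: int, noise_scale: float = 1.0, shape: dict | None = None):
    """Forward-model one reflectance spectrum from a sample's pigment traits.

    ``reflectance = baseline(l) * exp(-absorption(l)) * nuisances * noise``
    on the 302-1148 nm / 2 nm grid.  Baseline is a gentle logistic ramp from
    ~0.72 (visible) to ~0.82 (NIR plateau); absorption features are as in
    :data:`SPECTRAL_SHAPE`.

    Three trait-independent per-sample nuisances emulate biological
    variability that real ratio-index screens have to contend with: a small
    random shift of the pigment band edges (red-edge position jitter), a
    lognormally spread skin flavonoid absorber in the UV/blue tail, and a
    smooth per-sample NIR albedo factor (internal scattering differences).
    Per-wavelength noise is multiplicative lognormal.  Deterministic for a
    fixed seed.
    """
    from .spectral import Spectrum

    p = SPECTRAL_SHAPE if shape is None else shape
    wl = WAVELENGTH_GRID
    rng = np.random.default_rng(seed)
    edge_shift = rng.normal(0.0, p["edge_jitter_nm"])
    width_factor = rng.lognormal(0.0, p["edge_width_logsd"])
    flav_factor = p["flav_amp"] * rng.lognormal(0.0, p["flav_logsd"])
    nir_factor = rng.normal(0.0, p["nir_scatter_sd"])
    uv_factor = rng.normal(0.0, p["uv_scatter_sd"])

    baseline = p["baseline_low"] + p["baseline_rise"] * _logistic(
        wl, p["baseline_center"], p["baseline_width"]
    )
    refl = baseline * np.exp(
        -absorption_profile(trait_row, wl, shape=p, edge_shift=edge_shift,
                            flav_factor=flav_factor, width_factor=width_factor)
    )
    refl = refl * np.exp(nir_factor * _logistic(wl, p["nir_scatter_nm"], p["nir_scatter_width"]))
    refl = refl * np.exp(uv_factor * (1.0 - _logistic(wl, p["uv_scatter_nm"], p["uv_scatter_width"])))
    noise = rng.lognormal(0.0, p["noise_sigma"] * noise_scale, wl.size)
    refl = refl * noise
    return Spectrum(wl.copy(), np.clip(refl, 1e-6, 1.2 - 1e-9))


def simulate_rgb(spectrum) -> tuple[float, float, float]:
    """Band-averaged fruit color from a reflectance spectrum.

    R, G, B are mean reflectance over 600-700, 500-600 and 400-500 nm,
    scaled to the 0-255 8-bit range and rounded to 2 decimals.
    """
    wl = spectrum.wavelengths
    if wl[0] > 400 or wl[-1] < 700:
        raise ValueError("spectrum must cover 400-700 nm for RGB band averaging")
    refl = spectrum.reflectance
    bands = {"R": (600.0, 700.0), "G": (500.0, 600.0), "B": (400.0, 500.0)}
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (wl >= lo) & (wl <= hi)
        out[name] = round(float(np.clip(refl[sel].mean(), 0.0, 1.0)) * 255.0, 2)
    return out["R"], out["G"], out["B"]


def simulate_cohort(config: SimConfig, profiles: list[StageProfile] | None = None):
    """Generate a full cohort: traits, wide spectra table, and RGB triplets.

    Returns ``(traits_df, spectra_df, rgb_df)`` with aligned row order;
    spectra columns are integer wavelengths in nm.  Per-sample spectrum
    seeds are spawned from the config seed, so the whole bundle is
    deterministic.
    """
    traits = simulate_traits(config, profiles)
    seed_rng = np.random.default_rng(config.seed + 1_000_003)
    spec_seeds = seed_rng.integers(0, 2**31 - 1, size=len(traits))
    spectra_rows = []
    rgb_rows = []
    for i, row in traits.iterrows():
        spec = simulate_spectrum(row, int(spec_seeds[i]), noise_scale=config.noise_scale)
        spectra_rows.append(spec.reflectance)
        r, g, b = simulate_rgb(spec)
        rgb_rows.append({"R": r, "G": g, "B": b})
    spectra_df = pd.DataFrame(
        np.vstack(spectra_rows), columns=[int(w) for w in WAVELENGTH_GRID], index=traits.index
    )
    rgb_df = pd.DataFrame(rgb_rows, index=traits.index)
    return traits, spectra_df, rgb_df
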