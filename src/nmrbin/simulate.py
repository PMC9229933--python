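"""Synthetic ¹H-NMR cohort generator.

Emulates the statistical structure the analysis assumes: a 2 (sanitary
condition: HSC vs LSC) × 2 (age: week 14 vs 22) design with n animals per
cell (default 6, one pig per pen), metabolite signals as Lorentzian
(Cauchy) mixtures at the metabolite table's bin positions, planted
HSC/LSC abundance ratios, a multiplicative log-normal animal effect per
metabolite, additive Gaussian point noise, a smooth baseline, and a large
interference hump confined to the suppressed-water region [4.70, 4.90)
(20 bins at 0.01 ppm) so the exclusion stage is exercised.

Generation is a pure function of (design, library): the master seed
spawns one child stream per sample in a fixed order, so cohorts are
bit-for-bit reproducible and independent of generation order.

Intensity scale: with the default 400 intensity·ppm abundance per
metabolite and 64 grid points per 0.01-ppm bin, metabolite peak bins
integrate well above the 100,000 intensity-threshold default while
signal-free bins stay far below it, and the interference bins dominate
every metabolite bin — all three filter behaviours are realisable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binning import BinSpec, make_bins
from .types import ConfigurationError, SampleMetadata, Spectrum, ValidationError

#: published per-metabolite HSC/LSC ratios used as default planting targets
DEFAULT_PLANTED_RATIOS: dict[tuple[str, int], float] = {
    ("Xanthine", 14): 1.53,
    ("Xanthine", 22): 1.41,
    ("Butyrate", 14): 0.74,
    ("Butyrate", 22): 0.79,
    ("Propionate", 14): 0.73,
    ("Propionate", 22): 0.73,
    ("UDP-glucose", 14): 1.15,
    ("UDP-glucose", 22): 4.76,
    ("Valerate", 14): 0.84,
    ("Valerate", 22): 1.37,
    ("Uridine derivates", 14): 2.27,
    ("Uridine derivates", 22): 1.36,
    ("Bile acids", 14): 0.64,
    ("Bile acids", 22): 1.54,
    ("Kynurenic acid", 14): 0.80,
    ("Kynurenic acid", 22): 0.62,
}

DEFAULT_BASE_ABUNDANCE = 400.0  # intensity·ppm per metabolite


@dataclass(frozen=True)
class MetaboliteSignature:
    """A metabolite's spectral fingerprint: Lorentzian peaks with relative areas.

    ``peaks`` is a list of (center_ppm, relative_area, linewidth_ppm);
    relative areas are normalised to sum to 1 so ``base_abundance`` is
    the metabolite's total spectral area.
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]
    origin: str

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValidationError(f"{self.name}: needs at least one peak")
        areas = np.array([a for _, a, _ in self.peaks], dtype=float)
        if np.any(areas <= 0):
            raise ValidationError(f"{self.name}: relative areas must be positive")
        if np.any(np.array([w for _, _, w in self.peaks]) <= 0):
            raise ValidationError(f"{self.name}: linewidths must be positive")
        if abs(areas.sum() - 1.0) > 1e-9:
            norm = tuple((c, a / areas.sum(), w) for c, a, w in self.peaks)
            object.__setattr__(self, "peaks", norm)


def _sig(name, origin, centers_areas, linewidth=0.005):
    peaks = tuple((c, a, linewidth) for c, a in centers_areas)
    return MetaboliteSignature(name=name, peaks=peaks, origin=origin)


def default_signature_library() -> list[MetaboliteSignature]:
    """The 8 metabolites of the study's result table, peaks centred inside
    their listed 0.01-ppm bins (bin centre = left edge + 0.005)."""
    return [
        _sig("Xanthine", "diet", [(7.935, 1.0)]),
        _sig("Butyrate", "microbiome", [(1.525, 0.45), (0.885, 0.35), (2.185, 0.20)]),
        _sig("Propionate", "microbiome", [(1.065, 0.70), (2.185, 0.30)]),
        _sig("UDP-glucose", "microbiome", [(5.645, 1 / 3), (5.635, 1 / 3), (5.625, 1 / 3)]),
        _sig("Valerate", "microbiome", [(0.845, 1.0)]),
        _sig(
            "Uridine derivates",
            "microbiome",
            [(5.945, 1 / 6), (6.135, 1 / 6), (6.125, 1 / 6), (6.115, 1 / 6), (7.895, 1 / 6), (7.865, 1 / 6)],
        ),
        _sig(
            "Bile acids",
            "endogenous",
            [(0.775, 0.2), (0.765, 0.2), (0.755, 0.2), (0.745, 0.2), (0.735, 0.2)],
        ),
        _sig(
            "Kynurenic acid",
            "endogenous",
            [(6.655, 0.40), (7.825, 0.20), (7.685, 0.20), (7.495, 0.20)],
        ),
    ]


@dataclass(frozen=True)
class CohortDesign:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the study conditions: 6 animals per treatment per
    age, planted HSC/LSC ratios at the metabolite table's values, and an
    interference region spanning exactly 20 bins at 0.01-ppm width.
    """

    n_per_cell: int = 6
    planted_ratio: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED_RATIOS))
    base_abundance: dict = field(default_factory=dict)  # metabolite -> intensity·ppm
    animal_cv: float = 0.12
    noise_sd: float = 500.0
    baseline_amplitude: float = 50.0
    interference_region: tuple[float, float] = (4.70, 4.90)
    interference_amplitude: float = 3.0e5
    window: tuple[float, float] = (0.0, 10.0)
    points_per_bin: int = 64
    bin_width: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ConfigurationError("n_per_cell must be >= 2 (the model needs >=2 per cell)")
        if any(r <= 0 for r in self.planted_ratio.values()):
            raise ConfigurationError("planted ratios must be positive")
        if self.animal_cv < 0 or self.noise_sd < 0:
            raise ConfigurationError("animal_cv and noise_sd must be non-negative")
        if self.points_per_bin < 1:
            raise ConfigurationError("points_per_bin must be >= 1")
        lo, hi = self.interference_region
        n = (hi - lo) / self.bin_width
        if abs(n - 20) > 1e-8:
            raise ConfigurationError(
                f"interference_region must span exactly 20 bins of width "
                f"{self.bin_width}; got {n:.3f}"
            )

    def bin_spec(self) -> BinSpec:
        return BinSpec(window_lo=self.window[0], window_hi=self.window[1], width=self.bin_width)

    def abundance_of(self, metabolite: str) -> float:
        return float(self.base_abundance.get(metabolite, DEFAULT_BASE_ABUNDANCE))


def truth_frame(design: CohortDesign, library: Sequence[MetaboliteSignature]) -> pd.DataFrame:
    """Ground-truth table: one row per planted (metabolite, week) with the
    true ratio and the bin labels the metabolite's peaks fall into."""
    bins = make_bins(design.bin_spec())
    edges = np.array([b[1] for b in bins] + [bins[-1][2]])
    labels = [b[0] for b in bins]
    by_name = {s.name: s for s in library}
    rows = []
    for (met, week), ratio in sorted(design.planted_ratio.items()):
        if met not in by_name:
            continue
        affected = []
        for c, _, _ in by_name[met].peaks:
            j = int(np.searchsorted(edges, c, side="right") - 1)
            if 0 <= j < len(labels) and labels[j] not in affected:
                affected.append(labels[j])
        rows.append(
            {
                "metabolite": met,
                "week": week,
                "true_ratio": float(ratio),
                "affected_bins": ";".join(affected),
            }
        )
    return pd.DataFrame(rows, columns=["metabolite", "week", "true_ratio", "affected_bins"])


def _ppm_grid(design: CohortDesign) -> np.ndarray:
    """Uniform grid with points_per_bin samples per bin, offset half a step
    from the edges (no point sits exactly on a bin boundary)."""
    lo, hi = design.window
    n_bins = design.bin_spec().n_bins
    n_pts = n_bins * design.points_per_bin
    dx = (hi - lo) / n_pts
    return lo + (np.arange(n_pts) + 0.5) * dx


def _lorentzian(x: np.ndarray, center: float, gamma: float) -> np.ndarray:
    return (gamma / np.pi) / ((x - center) ** 2 + gamma ** 2)


def _peak_basis(
    x: np.ndarray, library: Sequence[MetaboliteSignature], window: tuple[float, float]
) -> np.ndarray:
    """n_metabolites × n_points matrix of unit-area metabolite profiles."""
    lo, hi = window
    basis = np.empty((len(library), x.size))
    for i, sig in enumerate(library):
        prof = np.zeros_like(x)
        for c, a, w in sig.peaks:
            if not (lo <= c < hi):
                raise ConfigurationError(
                    f"{sig.name}: peak centre {c} outside window [{lo}, {hi})"
                )
            prof += a * _lorentzian(x, c, w)
        basis[i] = prof
    return basis


def _deterministic_background(x: np.ndarray, design: CohortDesign) -> np.ndarray:
    """Smooth baseline plus the interference hump (noise-free, sample-invariant)."""
    lo, hi = design.window
    bg = design.baseline_amplitude * (1.0 + 0.3 * np.sin(2 * np.pi * (x - lo) / (hi - lo)))
    if design.baseline_amplitude == 0:
        bg = np.zeros_like(x)
    ilo, ihi = design.interference_region
    centre = 0.5 * (ilo + ihi)
    mask = (x >= ilo) & (x < ihi)
    hump = np.zeros_like(x)
    hump[mask] = design.interference_amplitude * np.exp(
        -0.5 * ((x[mask] - centre) / 0.12) ** 2
    )
    return bg + hump


def _cohort_layout(design: CohortDesign) -> list[SampleMetadata]:
    """Fixed sample order: week 14 then 22; HSC then LSC; animal index.

    Animals are sampled at both ages (12 animals -> 24 samples at the
    default n=6/cell); one pig per pen, so pen_id tracks animal_id.
    """
    meta = []
    for week in (14, 22):
        for treatment in ("HSC", "LSC"):
            for i in range(design.n_per_cell):
                animal = f"{treatment}{i + 1:02d}"
                meta.append(
                    SampleMetadata(
                        sample_id=f"{animal}_wk{week}",
                        animal_id=animal,
                        pen_id=f"pen_{animal}",
                        treatment=treatment,
                        week=week,
                    )
                )
    return meta


def simulate_cohort(
    design: CohortDesign,
    library: Optional[Sequence[MetaboliteSignature]] = None,
) -> tuple[list[Spectrum], list[SampleMetadata], pd.DataFrame]:
    """Generate a full 2 × 2 × n_per_cell cohort of synthetic spectra.

    Each spectrum is Σ_m abundance_m × (Lorentzian mixture of metabolite m)
    + baseline + interference hump + i.i.d. Gaussian point noise, with
    abundance_m = base_abundance × log-normal animal effect × planted
    ratio (HSC samples at weeks where a ratio is planted). Returns
    (spectra, metadata, truth table).
    """
    if library is None:
        library = default_signature_library()
    meta = _cohort_layout(design)
    x = _ppm_grid(design)
    basis = _peak_basis(x, library, design.window)
    background = _deterministic_background(x, design)
    base = np.array([design.abundance_of(s.name) for s in library])
    sigma = float(np.sqrt(np.log1p(design.animal_cv ** 2)))

    children = np.random.SeedSequence(design.seed).spawn(len(meta))
    spectra: list[Spectrum] = []
    for m, child in zip(meta, children):
        rng = np.random.default_rng(child)
        if sigma > 0:
            effects = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=len(library))
        else:
            effects = np.ones(len(library))
            rng.lognormal(mean=0.0, sigma=1.0, size=len(library))  # keep stream aligned
        ratios = np.array(
            [
                design.planted_ratio.get((s.name, m.week), 1.0)
                if m.treatment == "HSC"
                else 1.0
                for s in library
            ]
        )
        abundance = base * effects * ratios
        y = abundance @ basis + background
        if design.noise_sd > 0:
            y = y + rng.normal(0.0, design.noise_sd, size=x.size)
        spectra.append(Spectrum(sample_id=m.sample_id, ppm=x.copy(), intensity=y))
    return spectra, meta, truth_frame(design, library)


def null_cohort(
    design: CohortDesign,
    library: Optional[Sequence[MetaboliteSignature]] = None,
) -> tuple[list[Spectrum], list[SampleMetadata], pd.DataFrame]:
    """A cohort with every planted ratio forced to 1.0 (no treatment effect);
    the truth table records true_ratio = 1 for all planted keys."""
    null_design = dataclasses.replace(
        design, planted_ratio={k: 1.0 for k in design.planted_ratio}
    )
    return simulate_cohort(null_design, library)
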