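"""Synthetic canopy data generator.

Emulates the statistical structure of jujube-canopy hyperspectral samples
under four ordinal levels of leaf-mite infestation: per-sample reflectance
spectra on a shared wavelength grid, SPAD (relative chlorophyll) readings
that decrease with infestation severity, raw digital-number (DN) scenes
with embedded calibration plates, and collinear regression designs used to
exercise variable selection.

The spectral forward model is a parametric construction, not a
radiative-transfer simulation.  Reflectance is a red-edge-blended mixture of
a visible compartment and a NIR plateau:

* a broad "yellowing" hump centred near 560 nm whose amplitude grows as
  chlorophyll falls (chlorosis of mite-damaged canopies),
* a narrow green peak at 550 nm,
* a 531 nm absorption dip that deepens with chlorophyll,
* a red absorption valley at 670 nm that deepens with chlorophyll,
* a blue-edge chlorophyll absorption shoulder reaching 500 nm,
* a logistic red edge (inflection 715 nm) rising to a NIR plateau whose
  height increases with chlorophyll.

Amplitudes were chosen once so that the canonical qualitative findings hold
on generated data: NDVI/RVI/PhRI/MCARI correlate positively with SPAD,
TCARI/GI negatively, and per-band correlations are negative through the red
valley and positive on the NIR plateau.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "WavelengthGrid",
    "Severity",
    "GeneratorConfig",
    "SpectralShape",
    "DEFAULT_SHAPE",
    "SampleSet",
    "DNCube",
    "generate_spectrum",
    "generate_sample_set",
    "generate_dn_scene",
    "generate_collinear_design",
    "generate_scene",
]

SPAD_MIN = 15.0
SPAD_MAX = 75.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-centre wavelengths (nm) shared by all spectra in a run."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 bands")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """45 evenly spaced bands spanning 500-900 nm."""
        return cls(np.linspace(500.0, 900.0, 45))

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size

    def nearest(self, wavelength_nm: float, tolerance_nm: float = 5.0) -> int:
        """Index of the band centre nearest ``wavelength_nm``.

        Exact distance ties are broken toward the shorter wavelength.  A
        request with no band within ``tolerance_nm`` raises ``ValueError``.
        """
        d = np.abs(self.wavelengths_nm - wavelength_nm)
        idx = int(np.argmin(d))  # argmin returns the lowest index on ties
        if idx > 0 and np.isclose(d[idx - 1], d[idx]):
            idx -= 1
        if d[idx] > tolerance_nm:
            raise ValueError(
                f"no band within {tolerance_nm} nm of {wavelength_nm} nm "
                f"(nearest centre: {self.wavelengths_nm[idx]:.1f} nm)"
            )
        return idx


class Severity(enum.IntEnum):
    """Ordinal mite-infestation grade: healthy through severe damage."""

    I = 1
    II = 2
    III = 3
    IV = 4

    @classmethod
    def from_label(cls, label: str) -> "Severity":
        return cls[label.strip()]


@dataclass(frozen=True)
class SpectralShape:
    """Parameters of the parametric canopy reflectance model (see module docs).

    Amplitudes are unitless reflectance, positions/widths in nm.
    """

    base: float = 0.14              # visible background floor
    y_amp0: float = 0.03            # yellowing hump, chlorophyll-independent part
    y_amp1: float = 0.24            # yellowing growth as chlorophyll falls
    y_center: float = 560.0
    y_width: float = 65.0
    green_amp: float = 0.05         # narrow green peak
    green_center: float = 550.0
    green_width: float = 16.0
    dip531_amp: float = 0.05        # 531 nm dip deepening with chlorophyll
    dip531_width: float = 8.0
    red_amp0: float = 0.02          # red valley at 670 nm
    red_amp1: float = 0.04
    red_center: float = 670.0
    red_width: float = 26.0
    blue_amp: float = 0.18          # blue-edge absorption shoulder
    blue_center: float = 480.0
    blue_width: float = 32.0
    nir0: float = 0.42              # NIR plateau and its rise with chlorophyll
    nir1: float = 0.12
    edge_center: float = 715.0      # red-edge logistic inflection
    edge_scale: float = 12.0


DEFAULT_SHAPE = SpectralShape()


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for sample-set generation.

    Defaults reproduce four balanced severity classes with class-mean SPAD
    falling from 57 (healthy) to 34 (severe) and a within-class spread of 4
    SPAD units, yielding an overall coefficient of variation near 21%.
    """

    n_samples: int = 400
    severity_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    spad_mean_by_class: tuple[float, float, float, float] = (57.0, 51.0, 43.0, 34.0)
    spad_sd: float = 4.0
    noise_sd: float = 0.01
    n_groups: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.severity_mix) != 4 or len(self.spad_mean_by_class) != 4:
            raise ValueError("severity_mix and spad_mean_by_class need exactly 4 entries")
        if not np.isclose(sum(self.severity_mix), 1.0):
            raise ValueError("severity_mix must sum to 1")
        if any(p < 0 for p in self.severity_mix):
            raise ValueError("severity_mix proportions must be non-negative")
        if not all(a > b for a, b in zip(self.spad_mean_by_class, self.spad_mean_by_class[1:])):
            raise ValueError("spad_mean_by_class must be strictly decreasing with severity")
        if self.spad_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_groups < 1:
            raise ValueError("n_groups must be positive")


@dataclass
class SampleSet:
    """Spectra + SPAD + severity, the in-memory container of the pipeline."""

    grid: WavelengthGrid
    reflectance: np.ndarray          # (n_samples, n_bands)
    spad: np.ndarray                 # (n_samples,)
    severity: np.ndarray             # (n_samples,) ints 1..4
    group: np.ndarray | None = None  # (n_samples,) sampling-site ids
    lat: np.ndarray | None = None
    lon: np.ndarray | None = None
    sample_id: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.spad = np.asarray(self.spad, dtype=float)
        self.severity = np.asarray(self.severity, dtype=int)
        if self.reflectance.shape != (self.spad.size, self.grid.n_bands):
            raise ValueError("reflectance shape must be (n_samples, n_bands)")
        if self.sample_id is None:
            self.sample_id = np.arange(self.spad.size)

    def __len__(self) -> int:
        return self.spad.size

    @property
    def n_samples(self) -> int:
        return self.spad.size

    def subset(self, idx: np.ndarray) -> "SampleSet":
        take = lambda a: None if a is None else np.asarray(a)[idx]
        return SampleSet(
            grid=self.grid,
            reflectance=self.reflectance[idx],
            spad=self.spad[idx],
            severity=self.severity[idx],
            group=take(self.group),
            lat=take(self.lat),
            lon=take(self.lon),
            sample_id=take(self.sample_id),
            seed=self.seed,
        )

    def split(
        self,
        validation_fraction: float = 1.0 / 3.0,
        method: str = "sample",
        seed: int = 0,
    ) -> tuple["SampleSet", "SampleSet"]:
        """Split into (modeling, validation) sets.

        ``method='sample'`` draws individual samples; ``method='group'``
        holds out whole sampling sites, mimicking a field design in which
        entire survey plots are reserved for validation.
        """
        if not 0 < validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        rng = np.random.default_rng(seed)
        n = self.n_samples
        if method == "sample":
            perm = rng.permutation(n)
            n_val = max(1, int(round(validation_fraction * n)))
            val_idx = np.sort(perm[:n_val])
            mod_idx = np.sort(perm[n_val:])
        elif method == "group":
            if self.group is None:
                raise ValueError("group-wise split requested but samples carry no group ids")
            groups = np.unique(self.group)
            perm = rng.permutation(groups.size)
            n_val = max(1, int(round(validation_fraction * groups.size)))
            val_groups = set(groups[perm[:n_val]].tolist())
            mask = np.array([g in val_groups for g in self.group])
            val_idx = np.flatnonzero(mask)
            mod_idx = np.flatnonzero(~mask)
        else:
            raise ValueError(f"unknown split method {method!r}")
        if mod_idx.size == 0 or val_idx.size == 0:
            raise ValueError("split produced an empty set")
        return self.subset(mod_idx), self.subset(val_idx)

    # -- CSV round trip ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "sample_id": self.sample_id,
            "severity": [Severity(s).name for s in self.severity],
            "spad": self.spad,
            "lat": self.lat if self.lat is not None else np.full(len(self), np.nan),
            "lon": self.lon if self.lon is not None else np.full(len(self), np.nan),
        }
        if self.group is not None:
            cols["group"] = self.group
        df = pd.DataFrame(cols)
        for j, wl in enumerate(self.grid.wavelengths_nm):
            df[f"r{wl:.1f}"] = self.reflectance[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleSet":
        df = pd.read_csv(path)
        rcols = [c for c in df.columns if c.startswith("r") and c[1:].replace(".", "", 1).isdigit()]
        wl = np.array([float(c[1:]) for c in rcols])
        order = np.argsort(wl)
        rcols = [rcols[i] for i in order]
        return cls(
            grid=WavelengthGrid(wl[order]),
            reflectance=df[rcols].to_numpy(float),
            spad=df["spad"].to_numpy(float),
            severity=np.array([Severity.from_label(s) for s in df["severity"]]),
            group=df["group"].to_numpy() if "group" in df else None,
            lat=df["lat"].to_numpy(float) if "lat" in df else None,
            lon=df["lon"].to_numpy(float) if "lon" in df else None,
            sample_id=df["sample_id"].to_numpy(),
        )


@dataclass
class DNCube:
    """Raw digital-number scene with embedded calibration-plate regions."""

    dn: np.ndarray                       # (rows, cols, bands)
    plate_regions: dict[float, np.ndarray]  # nominal reflectance -> pixel mask
    gain: np.ndarray                     # per-band
    offset: np.ndarray                   # per-band

    def plate_mean_dn(self, rho: float) -> np.ndarray:
        """Per-band mean DN over the plate of nominal reflectance ``rho``."""
        mask = self.plate_regions[rho]
        return self.dn[mask].mean(axis=0)


# ---------------------------------------------------------------------------
# spectrum forward model
# ---------------------------------------------------------------------------

def _gauss(lam: np.ndarray, mu: float, sig: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - mu) / sig) ** 2)


def _spectrum_clean(
    spad: np.ndarray, grid: WavelengthGrid, shape: SpectralShape
) -> np.ndarray:
    """Noise-free reflectance for an array of SPAD values -> (n, bands)."""
    lam = grid.wavelengths_nm
    c = (np.atleast_1d(np.asarray(spad, float))[:, None] - SPAD_MIN) / (SPAD_MAX - SPAD_MIN)
    p = shape
    vis = (
        p.base
        + (p.y_amp0 + p.y_amp1 * (1.0 - c)) * _gauss(lam, p.y_center, p.y_width)
        + p.green_amp * _gauss(lam, p.green_center, p.green_width)
        - p.dip531_amp * c * _gauss(lam, 531.0, p.dip531_width)
        - (p.red_amp0 + p.red_amp1 * c) * _gauss(lam, p.red_center, p.red_width)
        - p.blue_amp * c * _gauss(lam, p.blue_center, p.blue_width)
    )
    nir = p.nir0 + p.nir1 * c
    s = 1.0 / (1.0 + np.exp(-(lam - p.edge_center) / p.edge_scale))
    return (1.0 - s) * vis + s * nir


def generate_spectrum(
    spad: float,
    grid: WavelengthGrid | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    shape: SpectralShape = DEFAULT_SHAPE,
) -> np.ndarray:
    """One canopy reflectance spectrum for a given SPAD reading.

    With ``noise_sd=0`` the output is a deterministic function of ``spad``;
    otherwise i.i.d. Gaussian noise is added per band and the result clipped
    to the open unit interval.
    """
    if not SPAD_MIN <= spad <= SPAD_MAX:
        raise ValueError(f"spad={spad} outside [{SPAD_MIN}, {SPAD_MAX}]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = grid or WavelengthGrid.default()
    r = _spectrum_clean(spad, grid, shape)[0]
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
        r = np.clip(r, 1e-4, 1.0 - 1e-4)
    return r


def generate_sample_set(
    cfg: GeneratorConfig | None = None,
    grid: WavelengthGrid | None = None,
    shape: SpectralShape = DEFAULT_SHAPE,
) -> SampleSet:
    """Draw a SampleSet under the configured study conditions.

    Severity classes are i.i.d. multinomial draws from ``severity_mix``;
    SPAD is Normal(class mean, spad_sd) clipped to [15, 75]; spectra come
    from the forward model plus per-band Gaussian noise.  Samples are
    assigned round-robin to ``n_groups`` sampling sites with jittered
    synthetic coordinates so group-wise splitting is exercisable.
    """
    cfg = cfg or GeneratorConfig()
    if cfg.n_samples < 8:
        raise ValueError("n_samples must be >= 8 to represent all four severity classes")
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(cfg.seed)

    severity = rng.choice(4, size=cfg.n_samples, p=list(cfg.severity_mix)) + 1
    means = np.asarray(cfg.spad_mean_by_class)[severity - 1]
    spad = np.clip(rng.normal(means, cfg.spad_sd), SPAD_MIN, SPAD_MAX)

    refl = _spectrum_clean(spad, grid, shape)
    if cfg.noise_sd > 0:
        refl = refl + rng.normal(0.0, cfg.noise_sd, size=refl.shape)
        refl = np.clip(refl, 1e-4, 1.0 - 1e-4)

    group = np.arange(cfg.n_samples) % cfg.n_groups
    site_lat = 37.0 + 0.01 * rng.random(cfg.n_groups)
    site_lon = 79.0 + 0.01 * rng.random(cfg.n_groups)
    lat = site_lat[group] + 1e-4 * rng.standard_normal(cfg.n_samples)
    lon = site_lon[group] + 1e-4 * rng.standard_normal(cfg.n_samples)

    return SampleSet(
        grid=grid, reflectance=refl, spad=spad, severity=severity,
        group=group, lat=lat, lon=lon, seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# DN scenes and collinear designs
# ---------------------------------------------------------------------------

def generate_dn_scene(
    reflectance: np.ndarray,
    plate_reflectances: tuple[float, ...] = (0.03, 0.22, 0.48, 0.64),
    gain: float | np.ndarray = 4000.0,
    offset: float | np.ndarray = 100.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    quantize: bool = False,
    plate_size: int = 2,
) -> DNCube:
    """Forward-model a DN cube: DN = offset + gain * reflectance + noise.

    Calibration plates of the given nominal reflectances are painted into
    the bottom rows of the scene and their pixel masks recorded.  ``quantize``
    rounds DN to integer counts (a real sensor does; the default keeps floats
    so the empirical-line round trip is exact).
    """
    refl = np.asarray(reflectance, dtype=float)
    if refl.ndim != 3:
        raise ValueError("reflectance cube must be 3-D (rows, cols, bands)")
    rows, cols, bands = refl.shape
    gain = np.broadcast_to(np.asarray(gain, float), (bands,)).copy()
    offset = np.broadcast_to(np.asarray(offset, float), (bands,)).copy()
    if np.any(gain <= 0):
        raise ValueError("gain must be positive in every band")
    for rho in plate_reflectances:
        if not 0.0 < rho < 1.0:
            raise ValueError(f"plate reflectance {rho} outside (0, 1)")
    if plate_size * len(plate_reflectances) > cols or plate_size > rows:
        raise ValueError("scene too small to embed the calibration plates")

    scene = refl.copy()
    plate_regions: dict[float, np.ndarray] = {}
    for i, rho in enumerate(plate_reflectances):
        mask = np.zeros((rows, cols), dtype=bool)
        mask[rows - plate_size:, i * plate_size:(i + 1) * plate_size] = True
        scene[mask] = rho
        plate_regions[rho] = mask

    dn = offset + gain * scene
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dn = dn + rng.normal(0.0, noise_sd, size=dn.shape)
    dn = np.maximum(dn, 0.0)
    if quantize:
        dn = np.rint(dn)
    return DNCube(dn=dn, plate_regions=plate_regions, gain=gain, offset=offset)


def generate_collinear_design(
    n_obs: int,
    n_bands: int,
    informative_bands: tuple[int, ...],
    duplicate_map: dict[int, int] | None = None,
    noise_sd: float = 0.1,
    response_noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted-truth regression design for band-selection tests.

    Informative columns are mutually orthogonal unit-variance signals; the
    response is an exact linear function of them (plus optional noise).
    ``duplicate_map`` maps column -> source column copied exactly, emulating
    the extreme inter-band collinearity of hyperspectral data; all remaining
    columns are low-amplitude pure noise with standard deviation ``noise_sd``.

    Returns ``(X, y, coef)`` where ``coef`` is the full-length coefficient
    vector (zero outside the informative bands).
    """
    duplicate_map = duplicate_map or {}
    informative_bands = tuple(informative_bands)
    k = len(informative_bands)
    if k == 0 or k > min(n_obs, n_bands):
        raise ValueError("need 1 <= len(informative_bands) <= min(n_obs, n_bands)")
    for j in (*informative_bands, *duplicate_map, *duplicate_map.values()):
        if not 0 <= j < n_bands:
            raise ValueError(f"column index {j} out of range for n_bands={n_bands}")
    if set(duplicate_map) & set(informative_bands):
        raise ValueError("a duplicate column cannot also be informative")

    rng = np.random.default_rng(seed)
    X = noise_sd * rng.standard_normal((n_obs, n_bands))
    q, _ = np.linalg.qr(rng.standard_normal((n_obs, k)))
    X[:, list(informative_bands)] = q * np.sqrt(n_obs)  # ~unit-variance columns
    for dst, src in duplicate_map.items():
        X[:, dst] = X[:, src]

    coef = np.zeros(n_bands)
    signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    coef[list(informative_bands)] = signs * (1.0 + 0.5 * np.arange(k))
    y = X @ coef
    if response_noise_sd > 0:
        y = y + rng.normal(0.0, response_noise_sd, size=n_obs)
    return X, y, coef


def generate_scene(
    cfg: GeneratorConfig | None = None,
    grid: WavelengthGrid | None = None,
    shape_px: tuple[int, int] = (40, 40),
    patch_scale: float = 6.0,
    pixel_spad_sd: float = 1.5,
    seed: int | None = None,
    spectral_shape: SpectralShape = DEFAULT_SHAPE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reflectance scene with smooth planted severity patches.

    A Gaussian-filtered random field is quantized by the severity mix into
    contiguous class patches; per-pixel SPAD is the class mean plus a small
    jitter.  Returns ``(cube, spad_truth, severity_truth)`` with cube shaped
    (rows, cols, bands).
    """
    cfg = cfg or GeneratorConfig()
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows, cols = shape_px

    field_ = gaussian_filter(rng.standard_normal((rows, cols)), patch_scale)
    qs = np.cumsum(cfg.severity_mix)[:-1]
    cuts = np.quantile(field_, qs)
    severity = 1 + np.searchsorted(cuts, field_.ravel()).reshape(rows, cols)

    means = np.asarray(cfg.spad_mean_by_class)[severity - 1]
    spad = np.clip(means + rng.normal(0.0, pixel_spad_sd, size=means.shape), SPAD_MIN, SPAD_MAX)

    cube = _spectrum_clean(spad.ravel(), grid, spectral_shape).reshape(rows, cols, grid.n_bands)
    if cfg.noise_sd > 0:
        cube = cube + rng.normal(0.0, cfg.noise_sd, size=cube.shape)
        cube = np.clip(cube, 1e-4, 1.0 - 1e-4)
    return cube, spad, severity
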