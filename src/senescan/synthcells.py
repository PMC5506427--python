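"""Seeded synthetic per-cell image populations with ground truth.

The generator emulates the per-cell image data an imaging flow cytometer
produces for senescence assays: bright-field images where X-gal-stained
(SA-β-gal-positive) cells appear dark, DAPI nuclei, γH2AX focus channels,
nuclear senescence markers (HMGB1, Ki67, BrdU), cell-type channels (CD45,
pCK, GFP) and a viability-dye channel.  Every cell carries its ground-truth
phenotype labels, so masking, feature extraction and gating can be scored
against the truth.

Population structure: each sample is a mixture over cell types; each cell
draws a latent senescent state, conditionally an X-gal staining state
(sensitivity / false-positive rate), marker positivity conditional on
senescence, a focus count, a target area, and nuisance states (doublet,
defocus, dead).  (config, seed) fully determines every pixel: phenotypes and
each cell's render use independent counter-derived RNG streams.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .imgio import CellRecord, write_dataset

__all__ = [
    "MarkerConfig",
    "FociConfig",
    "CellTypeConfig",
    "PopulationConfig",
    "SynthConfig",
    "sample_phenotypes",
    "render_cell",
    "generate_cells",
    "generate_population",
]

#: channels expressed without antibody staining (kept in unstained controls)
INTRINSIC_CHANNELS = ("BF", "DAPI", "GFP")


class ConfigError(ValueError):
    pass


def _check_prob(p: float, what: str) -> float:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{what} must be in [0, 1], got {p}")
    return float(p)


@dataclass
class MarkerConfig:
    """A fluorescence marker whose positivity depends on senescence.

    level_pos / level_neg are mean pixel amplitudes of the stained
    compartment when the cell is marker-positive / -negative (level_neg
    doubles as the autofluorescence floor); cv is the lognormal coefficient
    of variation of the per-cell level.
    """

    p_pos_given_sen: float
    p_pos_given_nonsen: float
    level_pos: float = 80.0
    level_neg: float = 4.0
    cv: float = 0.3
    compartment: str = "nucleus"  # "nucleus" or "cell"


@dataclass
class FociConfig:
    """γH2AX focus-count model: a positive cell has ``min_pos`` plus a
    Poisson(``mean_extra``) extra foci; a negative cell has
    Poisson(``mean_neg``)."""

    pos_fraction: float = 0.0
    min_pos: int = 3
    mean_extra: float = 3.0
    mean_neg: float = 0.3


@dataclass
class CellTypeConfig:
    """A cell-type subpopulation: mixture weight, identity-channel
    amplitudes, and optional overrides of the sample-level senescent
    fraction and mean area."""

    prob: float
    channel_levels: dict[str, float] = field(default_factory=dict)
    senescent_fraction: float | None = None
    area_um2_mean: float | None = None


@dataclass
class PopulationConfig:
    """One sample (population) of cells."""

    name: str
    n_cells: int
    senescent_fraction: float = 0.0
    stain_sensitivity: float = 1.0       # P(X-gal dark | senescent)
    stain_false_rate: float = 0.0        # P(X-gal dark | not senescent)
    area_um2_mean: float = 400.0
    area_cv: float = 0.25
    area_um2_mean_senescent: float | None = None  # optional size shift of SA+ cells
    darkness_mean: float = 180.0         # extra BF darkening of stained cells
    darkness_sigma: float = 15.0
    foci: FociConfig | None = None
    markers: dict[str, MarkerConfig] = field(default_factory=dict)
    cell_types: dict[str, CellTypeConfig] = field(default_factory=dict)
    viable_fraction: float = 1.0
    unstained: bool = False              # unstained control: no X-gal, no antibodies

    def __post_init__(self) -> None:
        for p, what in [
            (self.senescent_fraction, "senescent_fraction"),
            (self.stain_sensitivity, "stain_sensitivity"),
            (self.stain_false_rate, "stain_false_rate"),
            (self.viable_fraction, "viable_fraction"),
        ]:
            _check_prob(p, f"{self.name}.{what}")
        if self.cell_types:
            total = sum(t.prob for t in self.cell_types.values())
            if not np.isclose(total, 1.0):
                raise ConfigError(
                    f"{self.name}: cell type probabilities sum to {total}, not 1"
                )
        if self.area_um2_mean <= 0 or self.area_cv <= 0:
            raise ConfigError(f"{self.name}: area parameters must be positive")


@dataclass
class SynthConfig:
    """Full generative description of a synthetic dataset."""

    populations: list[PopulationConfig]
    channels: list[str] = field(default_factory=lambda: ["BF", "DAPI"])
    seed: int = 0
    pixel_size_um: float = 0.5
    image_size_px: int = 128
    background: float = 600.0            # BF background grey level
    bf_baseline: float = 30.0            # attenuation of any cell in BF
    bf_baseline_sigma: float = 5.0
    noise_sigma: float = 2.0             # additive Gaussian read noise
    dapi_total_intensity: float = 50000.0  # summed DAPI signal per nucleus (DNA content)
    dapi_cv: float = 0.1                 # per-cell DNA-content variation
    nucleus_area_fraction: float = 0.22
    spot_amplitude: float = 40.0
    spot_sigma_px: float = 1.5
    spot_min_sep_px: float = 6.0
    foci_haze_amplitude: float = 6.0
    dead_dye_level: float = 150.0        # viability-dye amplitude in dead cells
    live_dye_level: float = 4.0
    viability_channel: str = "LiveDead"
    aspect_range: tuple[float, float] = (0.8, 1.0)
    edge_softness: float = 0.15          # soft-edge ramp width, fraction of radius
    defocus_fraction: float = 0.0
    defocus_sigma_px: float = 6.0
    doublet_fraction: float = 0.0

    def __post_init__(self) -> None:
        if "BF" not in self.channels:
            raise ConfigError("channel list must include 'BF'")
        for p, what in [
            (self.defocus_fraction, "defocus_fraction"),
            (self.doublet_fraction, "doublet_fraction"),
        ]:
            _check_prob(p, what)
        if self.pixel_size_um <= 0 or self.image_size_px < 16:
            raise ConfigError("invalid pixel_size_um / image_size_px")

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = copy.deepcopy(dict(d))
        pops = []
        for p in d.pop("populations"):
            p = dict(p)
            if p.get("foci") is not None:
                p["foci"] = FociConfig(**p["foci"])
            p["markers"] = {
                k: MarkerConfig(**v) for k, v in (p.get("markers") or {}).items()
            }
            p["cell_types"] = {
                k: CellTypeConfig(**v) for k, v in (p.get("cell_types") or {}).items()
            }
            pops.append(PopulationConfig(**p))
        if "aspect_range" in d:
            d["aspect_range"] = tuple(d["aspect_range"])
        return cls(populations=pops, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aspect_range"] = list(self.aspect_range)
        return d


# ---------------------------------------------------------------------------
# phenotype sampling


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def sample_phenotypes(config: SynthConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the ground-truth label table for every cell of every population.

    Reproducible: the table is a pure function of (config, seed).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 0])
    rows = []
    idx = 0
    for pop in config.populations:
        for _ in range(pop.n_cells):
            row: dict = {
                "cell_id": f"{pop.name}_{idx:06d}",
                "sample_id": pop.name,
                "cell_index": idx,
            }
            # cell type
            ctype, tcfg = "default", None
            if pop.cell_types:
                names = list(pop.cell_types)
                probs = [pop.cell_types[n].prob for n in names]
                ctype = names[rng.choice(len(names), p=probs)]
                tcfg = pop.cell_types[ctype]
            row["cell_type"] = ctype
            sen_frac = pop.senescent_fraction
            area_mean = pop.area_um2_mean
            if tcfg is not None:
                if tcfg.senescent_fraction is not None:
                    sen_frac = tcfg.senescent_fraction
                if tcfg.area_um2_mean is not None:
                    area_mean = tcfg.area_um2_mean
            senescent = bool(rng.random() < sen_frac)
            p_stain = pop.stain_sensitivity if senescent else pop.stain_false_rate
            stained = bool(rng.random() < p_stain) and not pop.unstained
            if senescent and pop.area_um2_mean_senescent is not None:
                area_mean = pop.area_um2_mean_senescent
            darkness = max(0.0, rng.normal(config.bf_baseline, config.bf_baseline_sigma))
            if stained:
                darkness += max(0.0, rng.normal(pop.darkness_mean, pop.darkness_sigma))
            row.update(
                senescent=senescent,
                stained=stained,
                darkness=darkness,
                area_um2=float(_lognormal(rng, area_mean, pop.area_cv)),
                aspect=float(rng.uniform(*config.aspect_range)),
                dna_content=float(_lognormal(rng, 1.0, config.dapi_cv)),
                viable=bool(rng.random() < pop.viable_fraction),
                doublet=bool(rng.random() < config.doublet_fraction),
                defocused=bool(rng.random() < config.defocus_fraction),
            )
            # γH2AX foci
            if pop.foci is not None and "gH2AX" in config.channels:
                pos = rng.random() < pop.foci.pos_fraction
                count = (
                    pop.foci.min_pos + rng.poisson(pop.foci.mean_extra)
                    if pos
                    else rng.poisson(pop.foci.mean_neg)
                )
                row["foci_positive"] = bool(pos)
                row["foci_count"] = int(count)
            # markers
            for mname, m in pop.markers.items():
                if mname not in config.channels:
                    continue
                p = m.p_pos_given_sen if senescent else m.p_pos_given_nonsen
                pos = bool(rng.random() < p) and not pop.unstained
                level = float(
                    _lognormal(rng, m.level_pos if pos else m.level_neg, m.cv)
                )
                row[f"marker_pos_{mname}"] = pos
                row[f"marker_level_{mname}"] = level
            # cell-type channel amplitudes
            if tcfg is not None:
                for ch, lvl in tcfg.channel_levels.items():
                    if ch in config.channels:
                        row[f"type_level_{ch}"] = float(
                            _lognormal(rng, max(lvl, 1e-9), 0.2)
                        )
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering


def _finite_int(val) -> int:
    if val is None or (isinstance(val, float) and not np.isfinite(val)):
        return 0
    return int(val)


_GRID_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    if shape not in _GRID_CACHE:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        _GRID_CACHE[shape] = (yy, xx)
    return _GRID_CACHE[shape]


def _soft_ellipse(
    shape: tuple[int, int],
    center: tuple[float, float],
    a_px: float,
    b_px: float,
    angle: float,
    softness: float,
) -> np.ndarray:
    """Soft-edged filled ellipse: 1 inside, 0 outside, linear ramp of relative
    width ``softness`` across the boundary."""
    yy, xx = _grid(shape)
    y = yy - center[0]
    x = xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (x * ca + y * sa) / a_px
    v = (-x * sa + y * ca) / b_px
    r = np.hypot(u, v)
    return np.clip((1.0 - r) / max(softness, 1e-6) + 0.5, 0.0, 1.0)


def _spot_positions(
    rng: np.random.Generator, k: int, r_max: float, min_sep: float
) -> np.ndarray:
    """Dart-throwing placement of k foci within radius r_max, best-effort
    pairwise separation ``min_sep``."""
    pts: list[np.ndarray] = []
    for _ in range(k):
        best, best_d = None, -1.0
        for _try in range(200):
            rr = r_max * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            p = np.array([rr * np.sin(th), rr * np.cos(th)])
            d = min((np.linalg.norm(p - q) for q in pts), default=np.inf)
            if d >= min_sep:
                best = p
                break
            if d > best_d:
                best, best_d = p, d
        pts.append(best)
    return np.array(pts) if pts else np.empty((0, 2))


def _render_single(
    labels: Mapping,
    config: SynthConfig,
    rng: np.random.Generator,
    center: tuple[float, float],
    images: dict[str, np.ndarray],
    area_um2: float,
) -> None:
    """Draw one cell body (all channels, additively) into ``images``."""
    shape = images["BF"].shape
    area_px = area_um2 / config.pixel_size_um**2
    q = labels["aspect"]
    a = np.sqrt(area_px / (np.pi * q))
    b = q * a
    angle = rng.uniform(0, np.pi)
    extent = a * (1 + config.edge_softness)
    if (
        center[0] - extent < 1
        or center[1] - extent < 1
        or center[0] + extent > shape[0] - 2
        or center[1] + extent > shape[1] - 2
    ):
        raise ConfigError(
            f"cell (area {area_um2:.0f} um^2) does not fit the frame: "
            "increase image_size_px"
        )
    w_cell = _soft_ellipse(shape, center, a, b, angle, config.edge_softness)
    images["BF"] -= labels["darkness"] * w_cell

    # nucleus strictly inside the cell
    r_n = np.sqrt(config.nucleus_area_fraction * area_px / np.pi)
    jitter_max = max(0.0, b - r_n * (1 + config.edge_softness) - 2.0)
    jr = min(jitter_max, 0.15 * b) * np.sqrt(rng.random())
    jth = rng.uniform(0, 2 * np.pi)
    n_center = (center[0] + jr * np.sin(jth), center[1] + jr * np.cos(jth))
    w_nuc = _soft_ellipse(shape, n_center, r_n, r_n, 0.0, config.edge_softness)

    if "DAPI" in images:
        # DAPI total intensity reflects DNA content, not nuclear size: a large
        # senescent nucleus is dimmer per pixel, a doublet doubles the total
        amp = (
            config.dapi_total_intensity
            * labels.get("dna_content", 1.0)
            / (np.pi * r_n**2)
        )
        images["DAPI"] += amp * w_nuc
    if "gH2AX" in images:
        images["gH2AX"] += config.foci_haze_amplitude * w_nuc
        k = _finite_int(labels.get("foci_count"))
        if k > 0:
            yy, xx = _grid(shape)
            r_place = max(r_n - 2.0 * config.spot_sigma_px - 1.0, 1.0)
            for dy, dx in _spot_positions(rng, k, r_place, config.spot_min_sep_px):
                amp = config.spot_amplitude * rng.uniform(0.85, 1.15)
                d2 = (yy - n_center[0] - dy) ** 2 + (xx - n_center[1] - dx) ** 2
                images["gH2AX"] += amp * np.exp(-d2 / (2 * config.spot_sigma_px**2))
    for key, val in labels.items():
        # NaN level = this population does not carry that stain
        if key.startswith("marker_level_"):
            ch, weight = key[len("marker_level_"):], w_nuc
        elif key.startswith("type_level_"):
            ch, weight = key[len("type_level_"):], w_cell
        else:
            continue
        if ch in images and val is not None and np.isfinite(val):
            images[ch] += float(val) * weight
    vch = config.viability_channel
    if vch in images:
        lvl = config.live_dye_level if labels["viable"] else config.dead_dye_level
        images[vch] += lvl * w_cell


def render_cell(
    labels: Mapping, config: SynthConfig, rng: np.random.Generator
) -> CellRecord:
    """Render one cell record (all configured channels) from its labels."""
    n = config.image_size_px
    shape = (n, n)
    images = {ch: np.zeros(shape) for ch in config.channels}
    images["BF"] += config.background
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    if labels.get("doublet", False):
        area_px = labels["area_um2"] / config.pixel_size_um**2
        a1 = np.sqrt(area_px / (np.pi * labels["aspect"]))
        area2 = labels["area_um2"] * rng.uniform(0.8, 1.2)
        a2 = np.sqrt(area2 / config.pixel_size_um**2 / (np.pi * labels["aspect"]))
        th = rng.uniform(0, 2 * np.pi)
        d = 0.95 * (a1 + a2)
        u = np.array([np.sin(th), np.cos(th)])
        c1 = (center[0] - d / 2 * u[0], center[1] - d / 2 * u[1])
        c2 = (center[0] + d / 2 * u[0], center[1] + d / 2 * u[1])
        _render_single(labels, config, rng, c1, images, labels["area_um2"])
        _render_single(labels, config, rng, c2, images, area2)
    else:
        _render_single(labels, config, rng, center, images, labels["area_um2"])
    if labels.get("defocused", False):
        for ch in images:
            base = config.background if ch == "BF" else 0.0
            images[ch] = base + ndimage.gaussian_filter(
                images[ch] - base, config.defocus_sigma_px
            )
    for ch in images:
        if config.noise_sigma > 0:
            images[ch] = images[ch] + rng.normal(0, config.noise_sigma, shape)
        images[ch] = np.round(np.clip(images[ch], 0, 65535))
    truth = {
        k: v
        for k, v in labels.items()
        if k not in ("cell_id", "sample_id", "cell_index")
    }
    return CellRecord(
        cell_id=str(labels["cell_id"]),
        sample_id=str(labels["sample_id"]),
        channels=images,
        pixel_size_um=config.pixel_size_um,
        ground_truth=truth,
    )


def generate_cells(
    config: SynthConfig,
    seed: int | None = None,
    phenotypes: pd.DataFrame | None = None,
    failures: list | None = None,
) -> Iterator[CellRecord]:
    """Yield rendered cells for the whole configured dataset.

    Each cell's render uses its own counter-derived RNG stream, so the output
    is identical whether cells are consumed lazily, partially, or in
    parallel.  If ``failures`` is given, cells that do not fit the frame are
    skipped and recorded there as (cell_id, message) instead of raising.
    """
    seed = config.seed if seed is None else seed
    if phenotypes is None:
        phenotypes = sample_phenotypes(config, seed)
    for row in phenotypes.to_dict("records"):
        rng = np.random.default_rng([seed, 1, int(row["cell_index"])])
        try:
            yield render_cell(row, config, rng)
        except ConfigError as err:
            if failures is None:
                raise
            failures.append((str(row["cell_id"]), str(err)))


def generate_population(
    config: SynthConfig, out_dir: str | Path, seed: int | None = None
) -> tuple[Path, Path]:
    """Write the full synthetic dataset (TIFFs + manifest.csv) and its
    ground_truth.csv; returns (manifest_path, truth_path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    phen = sample_phenotypes(config, seed)
    manifest = write_dataset(generate_cells(config, seed, phen), out_dir)
    truth_path = out_dir / "ground_truth.csv"
    phen.drop(columns=["cell_index"]).to_csv(truth_path, index=False)
    return manifest, truth_path
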