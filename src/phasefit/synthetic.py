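"""Seeded generators for competition assays, cell populations and images.

Every downstream stage of the analysis (selection-coefficient fitting,
cost/benefit decomposition, foci segmentation, noise statistics) can be
exercised on output from this module, with known ground truth.

Three generators are provided:

* :func:`simulate_competition_series` — two-strain exponential growth
  with multiplicative qPCR-style measurement noise (lognormal in copy
  space, i.e. Gaussian in log2 space).
* :func:`simulate_cell_population` — per-cell total fluorescence drawn
  from a lognormal, partitioned between foci and cytosol by a
  zero-inflated Beta fraction.
* :func:`render_synthetic_image` — 8-bit grayscale frames of disk-like
  cells with bright intracellular foci, plus exact ground-truth label
  masks and a per-cell truth table.

All randomness flows from one explicit integer seed per call; there is
no hidden global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk

from .core import CELL_COLUMNS, EnvironmentCondition, Strain, validate_cells

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "GeneratorParams",
    "CompetitionSeries",
    "simulate_competition_series",
    "CellPopulationParams",
    "simulate_cell_population",
    "SyntheticImage",
    "render_synthetic_image",
]

#: default sampling grid of the competition assay, hours
DEFAULT_TIMEPOINTS = (0.0, 17.0, 34.0, 51.0, 58.0, 75.0, 82.0)


@dataclass
class GeneratorParams:
    """Parameters of the two-strain competition generator.

    Growth rates are in doublings per hour (omega = 1/tau).  Measurement
    noise is multiplicative in copy space with standard deviation
    ``noise_sd_log2`` in log2 units, independent per strain and
    timepoint.
    """

    omega_agg: float
    omega_sol: float
    init_agg: float = 1.0
    init_sol: float = 1.0
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    noise_sd_log2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size == 0 or not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be non-empty and strictly increasing")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if self.init_agg < 1 or self.init_sol < 1:
            raise ValueError("initial cell counts must be >= 1")


@dataclass
class CompetitionSeries:
    """One replicate of a two-strain competition time series.

    ``copies_agg``/``copies_sol`` are gene-copy numbers (or any quantity
    proportional to cell counts; dilutions cancel in the ratio).
    """

    env: EnvironmentCondition
    replicate: int
    times: np.ndarray
    copies_agg: np.ndarray
    copies_sol: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.copies_agg = np.asarray(self.copies_agg, dtype=float)
        self.copies_sol = np.asarray(self.copies_sol, dtype=float)
        if not (len(self.times) == len(self.copies_agg) == len(self.copies_sol)):
            raise ValueError("times and copy arrays must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.copies_agg <= 0) or np.any(self.copies_sol <= 0):
            raise ValueError("copy numbers must be strictly positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "copies_agg": self.copies_agg,
                "copies_sol": self.copies_sol,
                "replicate": self.replicate,
                "env": self.env.label,
                "medium": self.env.medium.name,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, env: EnvironmentCondition) -> "CompetitionSeries":
        df = df.sort_values("time_h")
        rep = int(df["replicate"].iloc[0]) if "replicate" in df else 0
        return cls(
            env=env,
            replicate=rep,
            times=df["time_h"].to_numpy(),
            copies_agg=df["copies_agg"].to_numpy(),
            copies_sol=df["copies_sol"].to_numpy(),
        )


def simulate_competition_series(
    params: GeneratorParams,
    env: EnvironmentCondition,
    replicate: int = 0,
) -> CompetitionSeries:
    """Simulate one competition replicate under exponential growth.

    Noiseless copy numbers follow ``init * 2**(t * omega)`` per strain;
    the returned values multiply each by ``2**eps`` with
    ``eps ~ Normal(0, noise_sd_log2)`` drawn independently per strain
    and timepoint.  Identical seeds give identical output.
    """
    t = np.asarray(params.timepoints, dtype=float)
    clean_agg = params.init_agg * np.exp2(t * params.omega_agg)
    clean_sol = params.init_sol * np.exp2(t * params.omega_sol)
    if params.noise_sd_log2 > 0:
        rng = np.random.default_rng(params.seed)
        eps = rng.normal(0.0, params.noise_sd_log2, size=(2, t.size))
        clean_agg = clean_agg * np.exp2(eps[0])
        clean_sol = clean_sol * np.exp2(eps[1])
    return CompetitionSeries(env=env, replicate=replicate, times=t,
                             copies_agg=clean_agg, copies_sol=clean_sol)


@dataclass
class CellPopulationParams:
    """Parameters of the single-cell fluorescence generator.

    Total fluorescence per cell is ``total_scale * LogNormal(total_mean_log,
    total_sd_log)`` (a.u.); with probability ``p_no_foci`` a cell carries no
    foci, otherwise the fraction of total fluorescence in foci is drawn from
    ``Beta(foci_frac_a, foci_frac_b)``.  The soluble strain never forms foci
    (``p_no_foci`` is forced to 1).  Cell area is a positive truncated
    normal in square micrometres.
    """

    n_cells: int
    strain: Strain = Strain.AGG
    total_mean_log: float = math.log(1000.0)
    total_sd_log: float = 0.5
    p_no_foci: float = 0.1
    foci_frac_a: float = 23.5
    foci_frac_b: float = 1.5
    total_scale: float = 1.0
    area_mean: float = 20.0
    area_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.strain = Strain.parse(self.strain)
        if self.strain is Strain.SOL:
            self.p_no_foci = 1.0
        if not 0.0 <= self.p_no_foci <= 1.0:
            raise ValueError("p_no_foci must lie in [0, 1]")
        if not 0.0 < self.total_scale <= 1.0:
            raise ValueError("total_scale must lie in (0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.total_sd_log < 0 or self.area_sd < 0:
            raise ValueError("spreads must be >= 0")
        if self.foci_frac_a <= 0 or self.foci_frac_b <= 0:
            raise ValueError("Beta shape parameters must be > 0")


def default_population_params(strain: Strain | str, n_cells: int = 200,
                              seed: int = 0) -> CellPopulationParams:
    """Study-condition defaults per strain.

    The aggregating strain partitions ~94% of its protein into foci on
    average, shows a modestly reduced total abundance (scale 0.8) and a
    broader cell-to-cell distribution than the soluble strain.
    """
    strain = Strain.parse(strain)
    if strain is Strain.SOL:
        return CellPopulationParams(n_cells=n_cells, strain=strain,
                                    total_sd_log=0.35, p_no_foci=1.0, seed=seed)
    return CellPopulationParams(n_cells=n_cells, strain=strain,
                                total_sd_log=0.5, p_no_foci=0.1,
                                total_scale=0.8, seed=seed)


def simulate_cell_population(params: CellPopulationParams) -> pd.DataFrame:
    """Draw a per-cell fluorescence table (canonical cell schema).

    Guarantees ``f_cyto + f_foci == f_total`` to full precision for every
    record and a foci fraction of exactly zero for the soluble strain.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    total = params.total_scale * rng.lognormal(params.total_mean_log,
                                               params.total_sd_log, size=n)
    frac = np.zeros(n)
    if params.p_no_foci < 1.0:
        has_foci = rng.random(n) >= params.p_no_foci
        k = int(has_foci.sum())
        draws = rng.beta(params.foci_frac_a, params.foci_frac_b, size=k)
        frac[has_foci] = np.minimum(draws, np.nextafter(1.0, 0.0))
    f_foci = frac * total
    area = rng.normal(params.area_mean, params.area_sd, size=n)
    # redraw the rare non-positive areas (truncation at 0)
    while np.any(area <= 0):
        bad = area <= 0
        area[bad] = rng.normal(params.area_mean, params.area_sd, size=int(bad.sum()))
    cells = pd.DataFrame(
        {
            "cell_id": [f"{params.strain.name}-{i}" for i in range(n)],
            "strain": params.strain.name,
            "area_um2": area,
            "f_total": total,
            "f_foci": f_foci,
            "f_cyto": total - f_foci,
            "n_foci": (frac > 0).astype(int),
        }
    )
    return validate_cells(cells)


@dataclass
class SyntheticImage:
    """A rendered frame plus the exact ground truth that was drawn.

    ``truth_cells``/``truth_foci`` are integer label masks (0 =
    background); every focus lies inside exactly one cell.  The truth
    table records the areas and integrated intensities of what was
    actually rasterised (before background noise), one row per cell.
    """

    pixels: np.ndarray
    pixel_scale: float
    truth_cells: np.ndarray
    truth_foci: np.ndarray
    truth_table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit")
        cells_of_foci = self.truth_cells[self.truth_foci > 0]
        if cells_of_foci.size and (cells_of_foci == 0).any():
            raise ValueError("every truth focus must lie inside a truth cell")
        if len(self.truth_table) != int(self.truth_cells.max()):
            raise ValueError("truth_table rows must equal number of labeled cells")

    def save(self, pixels_path, cells_path=None, foci_path=None, table_path=None) -> None:
        import tifffile

        tifffile.imwrite(pixels_path, self.pixels)
        if cells_path is not None:
            tifffile.imwrite(cells_path, self.truth_cells.astype(np.uint16))
        if foci_path is not None:
            tifffile.imwrite(foci_path, self.truth_foci.astype(np.uint16))
        if table_path is not None:
            self.truth_table.to_csv(table_path, index=False)


def render_synthetic_image(
    cells: pd.DataFrame,
    pixel_scale: float = 0.2,
    background_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
    cell_intensity: int = 30,
    focus_intensity: int = 200,
) -> SyntheticImage:
    """Rasterise a cell table into an 8-bit frame with ground truth.

    Cells are drawn as non-overlapping discs on a jittered grid with
    interior intensity ``cell_intensity`` (default 30: inside the 20-255
    cell-detection band but below the 40 a.u. foci threshold, like a dim
    cytosol); a cell with ``f_foci > 0`` receives one bright focus disc
    (intensity ``focus_intensity``, default 200) at its centre, sized
    from its foci fraction and clipped to the detectable 0.2-10 um^2
    window.  Additive Gaussian background noise (sd in intensity units)
    is applied last and clipped to [0, 255].
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be > 0")
    rng = np.random.default_rng(seed)
    n = len(cells)
    if n:
        radii_px = np.sqrt(cells["area_um2"].to_numpy() / math.pi) / pixel_scale
    else:
        radii_px = np.zeros(0)
    margin = 4
    slot = int(2 * (radii_px.max() if n else 8)) + 2 * margin
    ncols = max(1, math.ceil(math.sqrt(n))) if n else 1
    nrows = max(1, math.ceil(n / ncols)) if n else 1
    auto_shape = (nrows * slot + 2 * margin, ncols * slot + 2 * margin)
    if shape is None:
        shape = auto_shape
    elif n and (shape[0] < auto_shape[0] or shape[1] < auto_shape[1]):
        raise ValueError(
            f"frame {shape} too small for {n} cells; needs at least {auto_shape}"
        )

    img = np.zeros(shape, dtype=float)
    truth_cells = np.zeros(shape, dtype=np.int32)
    truth_foci = np.zeros(shape, dtype=np.int32)
    rows = []
    focus_label = 0
    for i in range(n):
        r, c = divmod(i, ncols)
        rad = radii_px[i]
        jitter_span = max(0.0, slot / 2 - rad - 2)
        cy = margin + r * slot + slot / 2 + rng.uniform(-1, 1) * min(1.5, jitter_span)
        cx = margin + c * slot + slot / 2 + rng.uniform(-1, 1) * min(1.5, jitter_span)
        rr, cc = _draw_disk((cy, cx), rad, shape=shape)
        img[rr, cc] = cell_intensity
        truth_cells[rr, cc] = i + 1

        rec = cells.iloc[i]
        f_frac = rec["f_foci"] / rec["f_total"] if rec["f_total"] > 0 else 0.0
        n_foci_drawn = 0
        f_foci_drawn = 0.0
        if f_frac > 0:
            # dense deposit: drawn area is a quarter of the fraction-weighted
            # cell area, kept inside the detectable 0.2-10 um^2 window
            area_um2 = float(np.clip(f_frac * rec["area_um2"] / 4.0, 0.4,
                                     min(10.0, 0.4 * rec["area_um2"])))
            frad = math.sqrt(area_um2 / math.pi) / pixel_scale
            frr, fcc = _draw_disk((cy, cx), min(frad, max(rad - 1.5, 1.0)), shape=shape)
            img[frr, fcc] = focus_intensity
            focus_label += 1
            truth_foci[frr, fcc] = focus_label
            n_foci_drawn = 1
            f_foci_drawn = float(focus_intensity) * len(frr)
        cell_px = int(len(rr))
        f_total_drawn = float(img[rr, cc].sum())
        rows.append(
            {
                "cell_id": int(i + 1),
                "strain": rec.get("strain", Strain.AGG.name),
                "area_um2": cell_px * pixel_scale**2,
                "f_total": f_total_drawn,
                "f_foci": f_foci_drawn,
                "f_cyto": f_total_drawn - f_foci_drawn,
                "n_foci": n_foci_drawn,
            }
        )

    if background_sd > 0:
        img = img + rng.normal(0.0, background_sd, size=shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(rows, columns=["cell_id", *CELL_COLUMNS[1:], "n_foci"])
    if n == 0:
        truth = pd.DataFrame(columns=["cell_id", *CELL_COLUMNS[1:], "n_foci"])
    return SyntheticImage(pixels=pixels, pixel_scale=pixel_scale,
                          truth_cells=truth_cells, truth_foci=truth_foci,
                          truth_table=truth)
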