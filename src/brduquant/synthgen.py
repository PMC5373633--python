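"""Synthetic cell populations for replication-labelling experiments.

This module generates ground-truth populations of cultured cells after a
thymidine-analogue (BrdU/EdU) labelling pulse, renders them as two-channel
fluorescence microscopy images (DAPI + replication signal), emits flow-style
event tables, and applies an antibody-dissociation wash model to the truth
table.  Every downstream stage of the pipeline (segmentation, per-nucleus
measurement, the R/non-R statistic, cell-cycle gating) can therefore be
exercised against known ground truth.

The population model is a two-component mixture: a replicating (S-phase)
fraction ``F`` whose nuclear replication signal is drawn from a log-normal
"R" component, and a non-replicating fraction (G1 + G2/M) drawn from a much
dimmer "non-R" background component.  DNA content spans 2N (G1) to 4N (G2/M),
with S-phase cells uniformly in between — the classic bivariate arc of a
cycling culture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk

__all__ = [
    "PopulationParams",
    "CellCycleParams",
    "ImagingParams",
    "TRUTH_COLUMNS",
    "generate_population",
    "place_nuclei",
    "render_images",
    "generate_flow_events",
    "apply_wash_dissociation",
]

#: Column order of a population-truth table.
TRUTH_COLUMNS = [
    "cell_id",
    "phase",
    "dna_content",
    "true_signal",
    "center_row",
    "center_col",
    "radius",
]

PHASES = ("G1", "S", "G2M")


@dataclass
class PopulationParams:
    """Two-component mixture of replicating (R) and non-replicating cells.

    Parameters
    ----------
    n_cells:
        Population size.
    frac_replicating:
        Fraction F of cells exhibiting replication signal after the pulse.
        Default 0.44 (a 30-minute pulse in a cycling human line).
    mu_signal_R, mu_signal_nonR:
        Mean nuclear replication-channel signal of the R and non-R
        components, arbitrary fluorescence units.  The default component
        ratio of 6 sits at the upper end of what a good anti-BrdU antibody
        achieves and is well above the 3-4 separation guideline.
    cv_R, cv_nonR:
        Coefficients of variation of the log-normal components.
    seed:
        RNG seed; identical parameters and seed give identical output.
    """

    n_cells: int = 10_000
    frac_replicating: float = 0.44
    mu_signal_R: float = 300.0
    mu_signal_nonR: float = 50.0
    cv_R: float = 0.25
    cv_nonR: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError(f"n_cells must be >= 0, got {self.n_cells}")
        if not (0.0 <= self.frac_replicating < 1.0):
            raise ValueError(
                f"frac_replicating must be in [0, 1), got {self.frac_replicating}"
            )
        if not (self.mu_signal_R >= self.mu_signal_nonR > 0):
            raise ValueError(
                "require mu_signal_R >= mu_signal_nonR > 0, got "
                f"{self.mu_signal_R} and {self.mu_signal_nonR}"
            )
        if self.cv_R < 0 or self.cv_nonR < 0:
            raise ValueError("coefficients of variation must be >= 0")


@dataclass
class CellCycleParams:
    """Cell-cycle phase structure and DNA-content scale.

    ``frac_s`` must equal ``frac_replicating`` of the paired
    :class:`PopulationParams`: only S-phase cells incorporate the analogue.
    G2/M DNA content is fixed at twice the G1 (2N) value.
    """

    frac_g1: float = 0.45
    frac_s: float = 0.44
    frac_g2m: float = 0.11
    dna_g1: float = 100.0
    dna_cv: float = 0.05

    @property
    def dna_g2m(self) -> float:
        return 2.0 * self.dna_g1

    def validate(self) -> None:
        total = self.frac_g1 + self.frac_s + self.frac_g2m
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phase fractions must sum to 1, got {total!r}")
        if min(self.frac_g1, self.frac_s, self.frac_g2m) < 0:
            raise ValueError("phase fractions must be >= 0")
        if self.dna_g1 <= 0:
            raise ValueError("dna_g1 must be > 0")
        if self.dna_cv < 0:
            raise ValueError("dna_cv must be >= 0")


@dataclass
class ImagingParams:
    """Rendering geometry and acquisition noise for the synthetic microscope.

    Nuclei are rendered as non-overlapping disks; ``dapi_gain`` converts DNA
    content into per-pixel DAPI intensity (pixel value = gain * dna / area, so
    integrated DAPI is proportional to DNA content regardless of radius).
    """

    image_width: int = 1024
    image_height: int = 1024
    nucleus_radius_range: tuple[float, float] = (8.0, 14.0)
    min_center_spacing: float = 0.0
    gaussian_noise_sd: float = 4.0
    poisson_noise: bool = True
    bit_depth: int = 16
    dapi_gain: float = 2000.0
    max_render_cells: int = 400
    seed: int = 0

    def validate(self) -> None:
        rmin, rmax = self.nucleus_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError(f"invalid nucleus_radius_range {self.nucleus_radius_range}")
        if self.min_center_spacing < 0:
            raise ValueError("min_center_spacing must be >= 0")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.gaussian_noise_sd < 0:
            raise ValueError("gaussian_noise_sd must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Log-normal sample with the given arithmetic mean and CV (cv=0 -> constant)."""
    if cv == 0.0:
        return np.full(size, float(mean))
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def generate_population(pop: PopulationParams, cyc: CellCycleParams) -> pd.DataFrame:
    """Draw a ground-truth population table.

    Each cell is assigned a phase (G1/S/G2M) by the stated fractions; S cells
    draw their replication signal from the R component, the others from the
    non-R background component.  DNA content is 2N for G1, 4N for G2/M and
    uniform in between for S, each perturbed multiplicatively by ``dna_cv``.

    Returns a DataFrame with columns :data:`TRUTH_COLUMNS`; nucleus centres
    and radii are left NaN until :func:`place_nuclei` lays the cells out on an
    image canvas.
    """
    pop.validate()
    cyc.validate()
    if abs(cyc.frac_s - pop.frac_replicating) > 1e-9:
        raise ValueError(
            "frac_s of CellCycleParams must equal frac_replicating of "
            f"PopulationParams (replication signal is S-phase only): "
            f"frac_s={cyc.frac_s} vs frac_replicating={pop.frac_replicating}"
        )

    rng = np.random.default_rng(pop.seed)
    n = pop.n_cells
    probs = np.array([cyc.frac_g1, cyc.frac_s, cyc.frac_g2m], dtype=float)
    probs = probs / probs.sum()
    phase_idx = rng.choice(3, size=n, p=probs)
    phase = np.array(PHASES)[phase_idx]
    is_s = phase_idx == 1

    signal = np.empty(n)
    signal[is_s] = _lognormal(rng, pop.mu_signal_R, pop.cv_R, int(is_s.sum()))
    signal[~is_s] = _lognormal(rng, pop.mu_signal_nonR, pop.cv_nonR, int((~is_s).sum()))

    dna = np.empty(n)
    dna[phase_idx == 0] = cyc.dna_g1
    dna[phase_idx == 2] = cyc.dna_g2m
    dna[is_s] = rng.uniform(cyc.dna_g1, cyc.dna_g2m, int(is_s.sum()))
    dna *= _lognormal(rng, 1.0, cyc.dna_cv, n)

    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1, dtype=np.int64),
            "phase": phase,
            "dna_content": dna,
            "true_signal": signal,
            "center_row": np.full(n, np.nan),
            "center_col": np.full(n, np.nan),
            "radius": np.full(n, np.nan),
        }
    )


def place_nuclei(truth: pd.DataFrame, img: ImagingParams) -> pd.DataFrame:
    """Assign non-overlapping disk centres and radii to every cell.

    Rejection sampling under the RNG seeded by ``img.seed``: centres must be
    at least ``max(min_center_spacing, r_i + r_j + 2)`` apart (the +2 pixel
    margin keeps rendered disks from touching, so the ground-truth label mask
    has one connected component per cell) and disks must lie fully inside the
    canvas.  Raises if the constraint cannot be satisfied after a bounded
    number of attempts, reporting how many cells were placed.
    """
    img.validate()
    rng = np.random.default_rng(img.seed)
    n = len(truth)
    out = truth.copy()
    if n == 0:
        return out

    rmin, rmax = img.nucleus_radius_range
    radii = rng.uniform(rmin, rmax, n)
    rows = np.empty(n)
    cols = np.empty(n)
    max_attempts = 2000
    for i in range(n):
        r = radii[i]
        placed = False
        for _ in range(max_attempts):
            cr = rng.uniform(r + 1, img.image_height - r - 2)
            cc = rng.uniform(r + 1, img.image_width - r - 2)
            if i:
                d = np.hypot(rows[:i] - cr, cols[:i] - cc)
                sep = np.maximum(img.min_center_spacing, radii[:i] + r + 2.0)
                if np.any(d < sep):
                    continue
            rows[i], cols[i] = cr, cc
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place {n} nuclei without overlap; placed {i} "
                f"(canvas {img.image_width}x{img.image_height}, "
                f"radii {img.nucleus_radius_range})"
            )
    out["center_row"] = rows
    out["center_col"] = cols
    out["radius"] = radii
    return out


def render_images(
    truth: pd.DataFrame, img: ImagingParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a placed truth table into (dapi, signal, label_mask).

    DAPI per-pixel intensity is ``dapi_gain * dna_content / area`` so the
    integrated nuclear DAPI is proportional to DNA content; the signal channel
    carries ``true_signal`` per pixel inside the nucleus footprint.  Optional
    Poisson shot noise and additive Gaussian read noise are applied, and the
    channels are clipped to the unsigned ``bit_depth`` range.
    """
    img.validate()
    shape = (img.image_height, img.image_width)
    dapi = np.zeros(shape, dtype=float)
    signal = np.zeros(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)

    if len(truth):
        if truth[["center_row", "center_col", "radius"]].isna().any().any():
            raise ValueError(
                "truth table has unplaced cells; call place_nuclei() first"
            )
        for row in truth.itertuples(index=False):
            rr, cc = _draw_disk((row.center_row, row.center_col), row.radius, shape=shape)
            area = rr.size
            dapi[rr, cc] = img.dapi_gain * row.dna_content / area
            signal[rr, cc] = row.true_signal
            labels[rr, cc] = row.cell_id

    rng = np.random.default_rng(img.seed + 1)
    if img.poisson_noise:
        dapi = rng.poisson(dapi).astype(float)
        signal = rng.poisson(signal).astype(float)
    if img.gaussian_noise_sd > 0:
        dapi += rng.normal(0.0, img.gaussian_noise_sd, shape)
        signal += rng.normal(0.0, img.gaussian_noise_sd, shape)

    vmax = 2**img.bit_depth - 1
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    dapi = np.clip(np.rint(dapi), 0, vmax).astype(dtype)
    signal = np.clip(np.rint(signal), 0, vmax).astype(dtype)
    return dapi, signal, labels


def generate_flow_events(
    truth: pd.DataFrame, noise_cv: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Flow-cytometry-style event table: one event per cell.

    The replication signal and DNA content of each cell are multiplied by
    independent log-normal measurement noise of the given CV (default 5%, a
    typical DNA-content CV on a well-aligned cytometer) and the event order is
    randomised, as acquisition order carries no information.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(truth)
    events = pd.DataFrame(
        {
            "signal": truth["true_signal"].to_numpy()
            * _lognormal(rng, 1.0, noise_cv, n),
            "dna_content": truth["dna_content"].to_numpy()
            * _lognormal(rng, 1.0, noise_cv, n),
        }
    )
    order = rng.permutation(n)
    return events.iloc[order].reset_index(drop=True)


def apply_wash_dissociation(
    truth: pd.DataFrame,
    kin,
    t_wash: float,
    stabilised: bool = False,
    formaldehyde_conc: float = 0.0,
    background: float | None = None,
) -> pd.DataFrame:
    """Apply the antibody wash model to the specific signal of S-phase cells.

    The measured nuclear signal of an S cell decomposes into a non-specific
    background (the non-R component mean) plus a specifically bound part.
    Unstabilised washing multiplies the specific part by
    ``exp(-k_off * t_wash)``; formaldehyde post-fixation instead multiplies it
    once by the concentration-dependent stabilisation efficiency and freezes
    it against further decay.  Non-replicating cells carry no specific signal
    and are untouched.

    ``background`` defaults to the mean true signal of the non-S cells in the
    table itself.
    """
    from .kinetics import retained_fraction, stabilisation_factor

    if t_wash < 0:
        raise ValueError(f"t_wash must be >= 0, got {t_wash}")
    if formaldehyde_conc < 0:
        raise ValueError(f"formaldehyde_conc must be >= 0, got {formaldehyde_conc}")

    out = truth.copy()
    is_s = out["phase"].to_numpy() == "S"
    if not is_s.any():
        return out
    if background is None:
        non_s = out.loc[~is_s, "true_signal"]
        background = float(non_s.mean()) if len(non_s) else 0.0

    if stabilised:
        factor = stabilisation_factor(formaldehyde_conc, kin)
    else:
        factor = retained_fraction(kin.k_off, t_wash)

    sig = out.loc[is_s, "true_signal"].to_numpy()
    specific = np.clip(sig - background, 0.0, None)
    out.loc[is_s, "true_signal"] = background + specific * factor
    return out
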