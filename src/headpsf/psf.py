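"""Point-spread-function resolution analysis of lead fields.

The PSF of a seed source is the map of Pearson correlation coefficients
between the seed's lead-field column and every other source's column: it
measures how strongly activity at the seed is confounded with activity
elsewhere, i.e. the spatial blurring an estimator based on these lead fields
cannot avoid.  The three orientation maps of one seed are combined by
pointwise RMS; a map's spatial extent is quantified by fitting the
smoothed PSF-versus-distance profile with a two-component Gaussian and
reading off the full width at half maximum (FWHM = 2*sqrt(2 ln 2) sigma for
a single Gaussian).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .leadfield import Leadfield

__all__ = [
    "PSFMap",
    "FWHMResult",
    "psf_map",
    "rms_superposition",
    "psf_stats",
    "smooth_on_mesh",
    "fit_psf_profile",
    "fwhm_sigma_factor",
    "fwhm_map",
]


def fwhm_sigma_factor() -> float:
    """FWHM of a unit-sigma Gaussian: 2 sqrt(2 ln 2) = 2.35482..."""
    return 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PSFMap:
    """Per-source PSF values of one seed (correlations, or their RMS)."""

    seed: int
    values: np.ndarray  # NaN marks undefined (zero-variance column)
    orientation: str  # x | y | z | RMS

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass(frozen=True)
class FWHMResult:
    """Two-component Gaussian profile fit and its half-maximum width."""

    params: tuple  # (a1, s1, a2, s2)
    fwhm: float  # mm, numeric half-maximum crossing of the fitted curve
    sigma_equivalent: float  # fwhm / (2 sqrt(2 ln 2))
    residual: float  # RMS fit residual
    fallback_single: bool = False  # two-component fit failed; single used


def psf_map(lf: Leadfield, seed: int) -> PSFMap:
    """Correlation of the seed's lead-field column with every column."""
    m = lf.matrix
    if not 0 <= seed < m.shape[1]:
        raise IndexError(f"seed {seed} out of range for {m.shape[1]} sources")
    centered = m - m.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    seed_col = centered[:, seed]
    seed_norm = norms[seed]
    if seed_norm == 0:
        raise ValueError("seed column has zero variance; PSF undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (seed_col @ centered) / (seed_norm * norms)
    vals[norms == 0] = np.nan  # undefined, reported missing (never 0)
    vals = np.clip(vals, -1.0, 1.0)
    vals[seed] = 1.0
    return PSFMap(seed, vals, lf.orientation)


def rms_superposition(maps: list[PSFMap]) -> PSFMap:
    """Pointwise sqrt(mean of squares) of the x, y, z maps of one seed."""
    if len(maps) != 3:
        raise ValueError("RMS superposition needs the three orientation maps")
    seeds = {m.seed for m in maps}
    if len(seeds) != 1:
        raise ValueError(f"maps have mismatched seeds: {sorted(seeds)}")
    stack = np.stack([m.values for m in maps])
    vals = np.sqrt(np.mean(stack**2, axis=0))
    return PSFMap(maps[0].seed, vals, "RMS")


def psf_stats(pm: PSFMap) -> tuple[float, float]:
    """(mean, min) over defined values (missing excluded)."""
    v = pm.values[~np.isnan(pm.values)]
    if v.size == 0:
        raise ValueError("PSF map has no defined values")
    return float(v.mean()), float(v.min())


def smoothing_operator(positions: np.ndarray, kernel_fwhm: float):
    """Row-normalised sparse Gaussian smoothing matrix (3-sigma cutoff).

    Build once per source space and reuse across maps.
    """
    from scipy import sparse

    positions = np.asarray(positions, dtype=float)
    sigma = kernel_fwhm / fwhm_sigma_factor()
    tree = cKDTree(positions)
    pairs = tree.sparse_distance_matrix(tree, 3.0 * sigma, output_type="coo_matrix")
    w = np.exp(-0.5 * (pairs.data / sigma) ** 2)
    W = sparse.coo_matrix((w, (pairs.row, pairs.col)), shape=pairs.shape).tocsr()
    norm = np.asarray(W.sum(axis=1)).ravel()
    return sparse.diags(1.0 / norm) @ W


def smooth_on_mesh(
    pm: PSFMap, positions: np.ndarray, kernel_fwhm: float = 10.0, operator=None
) -> PSFMap:
    """Gaussian-weighted neighbourhood average in Euclidean distance.

    ``kernel_fwhm = 0`` returns the map unchanged.  Missing values do not
    contribute and stay missing.  Pass a precomputed ``operator`` (from
    :func:`smoothing_operator`) when smoothing many maps of one space.
    """
    if kernel_fwhm == 0 and operator is None:
        return pm
    if operator is None:
        operator = smoothing_operator(positions, kernel_fwhm)
    vals = pm.values
    missing = np.isnan(vals)
    if missing.any():
        filled = np.where(missing, 0.0, vals)
        num = operator @ filled
        den = operator @ (~missing).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / den, np.nan)
        out[missing] = np.nan
    else:
        out = operator @ vals
    return PSFMap(pm.seed, out, pm.orientation)


def _two_gauss(d, a1, s1, a2, s2):
    return a1 * np.exp(-(d**2) / (2 * s1**2)) + a2 * np.exp(-(d**2) / (2 * s2**2))


def _numeric_half_max(f, params, d_max: float) -> float:
    """Half-maximum crossing of the fitted profile by bisection.

    The fitted curve decays to zero, so a crossing always exists; the search
    range is widened as needed (the FWHM may legitimately exceed the source
    space for very broad point spreads).
    """
    peak = f(0.0, *params)
    half = peak / 2.0
    reach = d_max
    for _ in range(12):
        d = np.linspace(0, reach, 4097)
        y = f(d, *params)
        below = np.nonzero(y <= half)[0]
        if len(below):
            break
        reach *= 4.0
    else:
        raise ValueError("fitted profile never falls to half maximum")
    hi = below[0]
    lo, hi_d = d[hi - 1], d[hi]
    for _ in range(60):
        mid = 0.5 * (lo + hi_d)
        if f(mid, *params) > half:
            lo = mid
        else:
            hi_d = mid
    return float(lo + hi_d)  # full width = 2 * crossing distance


def fit_psf_profile(
    pm: PSFMap, seed_position: np.ndarray, positions: np.ndarray
) -> FWHMResult:
    """Fit PSF-vs-distance with a1 exp(-d^2/2 s1^2) + a2 exp(-d^2/2 s2^2).

    FWHM is always read numerically from the fitted curve (robust to which
    component dominates); sigma_equivalent = FWHM / 2.35482.  If the
    two-component fit does not converge, a single Gaussian is fitted and
    flagged.
    """
    positions = np.asarray(positions, dtype=float)
    d = np.linalg.norm(positions - np.asarray(seed_position), axis=1)
    v = pm.values
    ok = ~np.isnan(v)
    d, v = d[ok], v[ok]
    if len(d) < 20:
        raise ValueError("need at least 20 defined points to fit a profile")
    if np.ptp(v) == 0:
        raise ValueError("constant profile has no half-maximum crossing")
    d_max = d.max()
    scale = d_max / 3.0
    fallback = False
    try:
        params, _ = curve_fit(
            _two_gauss,
            d,
            v,
            p0=(0.6 * v.max(), 0.5 * scale, 0.4 * v.max(), 1.5 * scale),
            bounds=([0, 1e-3, 0, 1e-3], [2, 10 * d_max, 2, 10 * d_max]),
            maxfev=20000,
        )
    except RuntimeError:
        fallback = True
        single = lambda dd, a, s: a * np.exp(-(dd**2) / (2 * s**2))  # noqa: E731
        p, _ = curve_fit(
            single, d, v, p0=(v.max(), scale), bounds=([0, 1e-3], [2, 10 * d_max]),
            maxfev=20000,
        )
        params = (p[0], p[1], 0.0, p[1])
    fwhm = _numeric_half_max(_two_gauss, tuple(params), 2.0 * d_max)
    resid = float(np.sqrt(np.mean((_two_gauss(d, *params) - v) ** 2)))
    return FWHMResult(
        tuple(float(x) for x in params),
        fwhm,
        fwhm / fwhm_sigma_factor(),
        resid,
        fallback,
    )


def fwhm_map(
    leadfields: dict[str, Leadfield],
    seeds: np.ndarray,
    positions: np.ndarray,
    kernel_fwhm: float = 10.0,
    include_orientations: bool = True,
) -> dict[str, np.ndarray]:
    """Batch FWHM per seed: psf_map -> (RMS) -> smooth -> fit.

    ``leadfields`` maps orientation tags to the model's three lead fields.
    Returns {"x": ..., "y": ..., "z": ..., "RMS": ...} arrays of FWHM (mm),
    one value per seed.
    """
    seeds = np.asarray(seeds, dtype=int)
    keys = (["x", "y", "z"] if include_orientations else []) + ["RMS"]
    out = {k: np.empty(len(seeds)) for k in keys}
    op = smoothing_operator(positions, kernel_fwhm) if kernel_fwhm else None
    for i, seed in enumerate(seeds):
        maps = {o: psf_map(leadfields[o], int(seed)) for o in ("x", "y", "z")}
        maps["RMS"] = rms_superposition([maps["x"], maps["y"], maps["z"]])
        for k in keys:
            sm = smooth_on_mesh(maps[k], positions, kernel_fwhm, operator=op)
            res = fit_psf_profile(sm, positions[seed], positions)
            out[k][i] = res.fwhm
    return out
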