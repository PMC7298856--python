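"""Synthetic landscapes for offline testing of the niche-modelling pipeline.

Real inputs for this kind of analysis — gridded bioclimate baselines,
future climate-model output, livestock censuses, species occurrence
records — are large external downloads.  This module generates stand-ins
with the statistical structure the downstream analysis assumes:

* spatially autocorrelated environmental layers (Gaussian random fields
  built from kernel-smoothed white noise) with a *prescribed* pairwise
  correlation matrix across layers;
* future layer stacks equal to the baseline plus a per-scenario additive
  trend plus per-climate-model noise;
* a known "truth" suitability surface lying inside the fitted model
  family (complementary log-log of a linear + quadratic combination of a
  subset of layers), so parameter-recovery tests are meaningful;
* occurrence records sampled multinomially in proportion to truth
  suitability, placed at cell centers;
* a right-skewed (lognormal) cattle-abundance field and a contiguous
  partition of the grid into labelled zoogeographic-style regions.

All generators are deterministic functions of their spec and seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Grid, GridMismatchError, LayerStack

__all__ = [
    "SyntheticSpec",
    "TruthSurface",
    "gen_env_stack",
    "gen_future_stacks",
    "sample_occurrences",
    "gen_cattle_and_regions",
]

#: layer names used when n_layers == 7, mirroring the candidate variables of
#: a typical bioclim + relative-humidity niche analysis
DEFAULT_SEVEN = ["bio1", "bio4", "bio6", "bio12", "bio14", "bio15", "rh"]


class InvalidSpecError(ValueError):
    """The synthetic spec violates one of its invariants."""


class DegenerateTruthError(ValueError):
    """Occurrences requested from an all-zero suitability surface."""


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of the synthetic world.

    Parameters
    ----------
    grid : Grid
        Working grid (0.2 degree cells by default elsewhere).
    n_layers : int
        Number of environmental variables (>= 2).
    correlation : float | array
        Target pairwise Pearson correlation between layers: a scalar
        applied to every off-diagonal pair, or a full PSD matrix.
    truth_coefficients : mapping
        ``{layer_name: (linear, quadratic)}`` weights of the truth
        suitability model; layers absent from the mapping are inactive.
    truth_intercept : float
        Intercept of the truth linear predictor.
    n_gcm : int
        Number of pseudo general-circulation models (>= 1).
    scenario_shifts : mapping
        ``{(rcp, period): shift}`` with ``shift`` a scalar or per-layer
        vector added to the baseline for that scenario.
    gcm_noise_sd : float
        Standard deviation of the per-(GCM, layer) additive offset.
    smooth_sigma : float
        Gaussian kernel width (cells) of the spatial autocorrelation.
    seed : int
    """

    grid: Grid
    n_layers: int = 7
    correlation: float | np.ndarray = 0.3
    truth_coefficients: Mapping[str, tuple[float, float]] | None = None
    truth_intercept: float = 0.0
    n_gcm: int = 20
    scenario_shifts: Mapping[tuple[str, str], float | Sequence[float]] = dataclasses.field(
        default_factory=lambda: {
            ("rcp45", "2050"): 0.5,
            ("rcp45", "2070"): 0.8,
            ("rcp85", "2050"): 1.0,
            ("rcp85", "2070"): 1.6,
        }
    )
    gcm_noise_sd: float = 0.3
    smooth_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise InvalidSpecError("n_layers must be >= 2")
        if self.n_gcm < 1:
            raise InvalidSpecError("n_gcm must be >= 1")
        self.correlation_matrix()  # validates PSD

    def layer_names(self) -> list[str]:
        if self.n_layers == len(DEFAULT_SEVEN):
            return list(DEFAULT_SEVEN)
        return [f"env{i + 1:02d}" for i in range(self.n_layers)]

    def correlation_matrix(self) -> np.ndarray:
        k = self.n_layers
        if np.isscalar(self.correlation):
            r = float(self.correlation)
            C = np.full((k, k), r)
            np.fill_diagonal(C, 1.0)
        else:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (k, k):
                raise InvalidSpecError(f"correlation matrix must be {k}x{k}")
            if not np.allclose(C, C.T):
                raise InvalidSpecError("correlation matrix must be symmetric")
        if np.min(np.linalg.eigvalsh(C)) < -1e-10:
            raise InvalidSpecError("correlation matrix is not positive semi-definite")
        return C

    def shift_vector(self, rcp: str, period: str) -> np.ndarray:
        s = self.scenario_shifts[(rcp, period)]
        if np.isscalar(s):
            return np.full(self.n_layers, float(s))
        s = np.asarray(s, dtype=float)
        if s.shape != (self.n_layers,):
            raise InvalidSpecError("per-layer shift length must equal n_layers")
        return s


@dataclasses.dataclass
class TruthSurface:
    """Known suitability surface in [0, 1] with its generating weights."""

    suitability: np.ndarray
    grid: Grid
    mask: np.ndarray
    coefficients: dict[str, tuple[float, float]]
    intercept: float

    def __post_init__(self) -> None:
        vals = self.suitability[self.mask]
        if not np.all(np.isfinite(vals)):
            raise ValueError("truth suitability has non-finite valid cells")
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("truth suitability must lie in [0, 1]")

    @property
    def active_layers(self) -> list[str]:
        return [n for n, (a, b) in self.coefficients.items() if a != 0 or b != 0]


def _smooth_fields(rng: np.random.Generator, shape: tuple[int, int], k: int, sigma: float) -> np.ndarray:
    """k spatially smooth standardized fields, shape (cells, k)."""
    out = np.empty((shape[0] * shape[1], k))
    for j in range(k):
        f = rng.standard_normal(shape)
        if sigma > 0:
            f = ndimage.gaussian_filter(f, sigma, mode="wrap")
        out[:, j] = f.ravel()
    return out


def gen_env_stack(spec: SyntheticSpec) -> LayerStack:
    """Generate co-registered environmental layers with the target correlation.

    The smoothed noise fields are orthonormalized (QR) before mixing with
    the Cholesky factor of the correlation matrix, so the empirical
    pairwise Pearson r over cells reproduces the target almost exactly
    while keeping the fields spatially smooth.
    """
    rng = np.random.default_rng(spec.seed)
    C = spec.correlation_matrix()
    k = spec.n_layers
    Z = _smooth_fields(rng, spec.grid.shape, k, spec.smooth_sigma)
    Z -= Z.mean(axis=0)
    # Orthonormal basis spanning the smooth fields -> exact sample correlation
    Q, _ = np.linalg.qr(Z)
    Q *= np.sqrt(Z.shape[0])
    # eigen-factorization tolerates PSD-but-singular targets
    w, V = np.linalg.eigh(C)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    X = Q @ L.T
    names = spec.layer_names()
    layers = {n: X[:, j].reshape(spec.grid.shape) for j, n in enumerate(names)}
    return LayerStack(spec.grid, layers)


def gen_future_stacks(
    baseline: LayerStack, spec: SyntheticSpec
) -> dict[tuple[str, str, str], LayerStack]:
    """Pseudo-GCM future stacks: baseline + scenario shift + per-GCM offset.

    Returns a dict keyed by ``(gcm, rcp, period)`` with gcm labels
    ``"gcm01"`` ... .  The per-(GCM, layer, scenario) offset is a single
    number (spatially constant), drawn with sd ``spec.gcm_noise_sd``.
    """
    if baseline.grid != spec.grid:
        raise GridMismatchError("baseline grid does not match spec grid")
    if list(baseline.names) != spec.layer_names():
        raise GridMismatchError("baseline layer names do not match spec")
    rng = np.random.default_rng(spec.seed + 1)
    out: dict[tuple[str, str, str], LayerStack] = {}
    scen_keys = sorted(spec.scenario_shifts)
    for rcp, period in scen_keys:
        shift = spec.shift_vector(rcp, period)
        for g in range(spec.n_gcm):
            noise = rng.normal(0.0, spec.gcm_noise_sd, size=spec.n_layers) if spec.gcm_noise_sd > 0 else np.zeros(spec.n_layers)
            layers = {
                name: baseline[name] + shift[j] + noise[j]
                for j, name in enumerate(baseline.names)
            }
            out[(f"gcm{g + 1:02d}", rcp, period)] = LayerStack(
                baseline.grid, layers, baseline.mask
            )
    return out


def make_truth(stack: LayerStack, spec: SyntheticSpec) -> TruthSurface:
    """Truth suitability: cloglog link over a linear+quadratic predictor.

    ``s(x) = 1 - exp(-exp(eta))`` with
    ``eta = intercept + sum_i a_i x_i + b_i x_i^2``; the generating
    process therefore lies inside the linear+quadratic feature family of
    the fitted model.
    """
    coefs = spec.truth_coefficients
    if coefs is None:
        # default: first five layers active, hump-shaped responses
        names = stack.names[:5]
        coefs = {n: (0.8, -0.5) for n in names}
    eta = np.full(stack.grid.shape, float(spec.truth_intercept))
    for name, (a, b) in coefs.items():
        x = stack[name]
        eta = eta + a * x + b * x**2
    suit = 1.0 - np.exp(-np.exp(np.clip(eta, -700, 50)))
    suit = np.where(stack.mask, suit, np.nan)
    return TruthSurface(suit, stack.grid, stack.mask, dict(coefs), float(spec.truth_intercept))


def sample_occurrences(truth: TruthSurface, n: int, seed: int = 0) -> pd.DataFrame:
    """Sample n occurrence points, cell chosen ~ multinomial(truth suitability).

    Points are placed at cell centers (no sub-cell jitter), removing any
    raster-lookup ambiguity.  Returns a table with columns
    ``species, longitude, latitude``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rows, cols = np.where(truth.mask)
    weights = truth.suitability[rows, cols]
    weights = np.where(np.isfinite(weights), weights, 0.0)
    total = weights.sum()
    if n > 0 and total <= 0:
        raise DegenerateTruthError("truth suitability is zero everywhere")
    if n == 0:
        return pd.DataFrame(columns=["species", "longitude", "latitude"])
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, p=weights / total)
    lon, lat = zip(*(truth.grid.center_of(rows[i], cols[i]) for i in idx))
    return pd.DataFrame(
        {"species": "synthetic_vector", "longitude": lon, "latitude": lat}
    )


def gen_cattle_and_regions(
    spec: SyntheticSpec,
    n_regions: int = 2,
    log_mean: float = 1.0,
    log_sd: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Lognormal cattle-abundance field and a contiguous region partition.

    Cattle density (head per 10 km^2) is ``exp(mu + sd * G)`` with G a
    smooth standard Gaussian field, giving the right-skewed distribution
    livestock censuses show.  Regions are ``n_regions`` contiguous
    vertical bands labelled 1..n_regions.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    rng = np.random.default_rng(spec.seed + 2)
    g = _smooth_fields(rng, spec.grid.shape, 1, spec.smooth_sigma)[:, 0]
    g = (g - g.mean()) / (g.std() or 1.0)
    cattle = np.exp(log_mean + log_sd * g).reshape(spec.grid.shape)
    cols = np.arange(spec.grid.ncols)
    band = np.minimum(cols * n_regions // spec.grid.ncols, n_regions - 1) + 1
    regions = np.broadcast_to(band, spec.grid.shape).copy()
    return cattle, regions
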