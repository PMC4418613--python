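"""Digital phantoms and simulated cohorts.

The study's CT segmentations are not public, so testing runs on two kinds
of synthetic input with the same statistical structure:

* **phantoms** — rasterized spheres/ellipsoids with controllable surface
  lobulation (Gaussian radial bumps), standing in for manually segmented
  tumors: low-lobulation phantoms play the encapsulated class (smooth,
  compact capsule), high-lobulation ones the invasive class;
* **cohorts** — 53-subject two-class tables whose default per-class
  categorical prevalences and continuous means/SDs equal the published
  clinical/CT and shape-feature summaries (23 encapsulated vs 30
  invasive; cystic change 3/23 vs 16/30; discrete compactness
  0.825±0.106 vs 0.691±0.160; ...).

All generators are pure functions of (spec, seed).  Sub-seeds derive from
the master seed by a counter-based spawn-key scheme, so generating one
more phantom never changes the previous ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm, truncnorm

from .io import VoxelMask

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "ClassParams",
    "make_phantom",
    "make_phantom_pair",
    "simulate_cohort",
    "simulate_phantom_cohort",
    "dice",
    "DEFAULT_COHORT_SPEC",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key)))


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one digital tumor phantom.

    ``kind`` is sphere, ellipsoid or lobulated; sizes are in voxels.  A
    lobulated phantom is its base shape with ``n_lobes`` Gaussian radial
    bumps at seeded random directions; each bump raises the local radius
    by up to ``amplitude`` x the base radius, so amplitude 0 reduces to
    the base shape exactly.
    """

    kind: str = "sphere"
    radius: float = 15.0
    semi_axes: tuple[float, float, float] | None = None
    n_lobes: int = 0
    amplitude: float = 0.0
    lobe_width: float = 0.35  # angular sigma of a bump, radians
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def axes(self) -> tuple[float, float, float]:
        if self.kind == "sphere" or self.semi_axes is None:
            return (self.radius,) * 3
        return self.semi_axes


def make_phantom(spec: PhantomSpec) -> VoxelMask:
    """Rasterize a phantom: voxel centers inside the surface are foreground.

    The grid is auto-sized with a >= 2-voxel background margin; the result
    is a single 26-connected component.
    """
    if spec.kind not in ("sphere", "ellipsoid", "lobulated"):
        raise ValueError(f"unknown phantom kind {spec.kind!r}")
    ax, ay, az = spec.axes()
    if min(ax, ay, az) < 2:
        raise ValueError("phantom radius/semi-axes must be >= 2 voxels")
    if not (0.0 <= spec.amplitude <= 1.0):
        raise ValueError("lobulation amplitude must be in [0, 1]")

    reach = 1.0 + min(spec.amplitude * max(spec.n_lobes, 1), 1.0)
    half = np.ceil(np.array([ax, ay, az]) * reach).astype(int) + 3
    shape = 2 * half + 1
    center = half.astype(float)
    idx = np.indices(shape).astype(float)
    rel = [idx[i] - center[i] for i in range(3)]
    # normalized ellipsoidal radius of every voxel center
    rho = np.sqrt((rel[0] / ax) ** 2 + (rel[1] / ay) ** 2
                  + (rel[2] / az) ** 2)

    threshold = np.ones_like(rho)
    if spec.kind == "lobulated" and spec.n_lobes > 0 and spec.amplitude > 0:
        rng = _rng(spec.seed, 0)
        dirs = rng.normal(size=(spec.n_lobes, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        r = np.sqrt(rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.stack([np.where(r > 0, rel[i] / r, 0.0)
                          for i in range(3)], axis=-1)
        bump = np.zeros_like(rho)
        for d in dirs:
            cosang = np.clip(u @ d, -1.0, 1.0)
            ang = np.arccos(cosang)
            bump += np.exp(-0.5 * (ang / spec.lobe_width) ** 2)
        bump = np.minimum(bump, 1.0)
        # modulate around the base surface: lobes rise to (1 + 0.6 a) R
        # and the valleys between them sink to (1 - 0.4 a) R, so higher
        # amplitude means a wavier, less compact surface, not just a
        # larger object; amplitude 0 is exactly the base shape
        threshold = 1.0 + spec.amplitude * (0.6 * bump - 0.4)

    grid = (rho <= threshold).astype(np.uint8)
    labeled, ncomp = ndimage.label(grid, structure=_STRUCT26)
    if ncomp > 1:  # radial bumps keep the shape star-shaped; belt & braces
        sizes = ndimage.sum_labels(grid, labeled, np.arange(1, ncomp + 1))
        grid = (labeled == int(np.argmax(sizes)) + 1).astype(np.uint8)
    return VoxelMask(grid, spacing=spec.spacing,
                     meta={"phantom": spec.kind, "seed": spec.seed})


def dice(a: VoxelMask, b: VoxelMask) -> float:
    """Dice overlap of two masks on identical grids."""
    ga, gb = a.grid.astype(bool), b.grid.astype(bool)
    if ga.shape != gb.shape:
        raise ValueError("Dice requires identical grid shapes")
    inter = np.count_nonzero(ga & gb)
    return 2.0 * inter / (np.count_nonzero(ga) + np.count_nonzero(gb))


def make_phantom_pair(spec: PhantomSpec, rater_noise: float = 1.0
                      ) -> tuple[VoxelMask, VoxelMask]:
    """One phantom plus a second-reader rendition of it.

    The second mask perturbs the boundary of the first: surface voxels
    are eroded and boundary-adjacent background voxels dilated, each with
    per-voxel probability rater_noise / (rater_noise + 4) — zero noise
    gives an identical mask, large noise reshapes the whole boundary.
    The dilate/erode decisions are driven by a smoothed (spatially
    correlated) random field, so disagreement forms coherent patches the
    way human readers over- or under-include a region, rather than
    salt-and-pepper voxel flips that would shred the contact surface.  A
    perturbation that disconnects the object is retried with a fresh
    sub-seed (up to 10 times).
    """
    if rater_noise < 0:
        raise ValueError("rater_noise must be >= 0")
    first = make_phantom(spec)
    if rater_noise == 0:
        return first, VoxelMask(first.grid.copy(), first.spacing,
                                first.origin, dict(first.meta))
    p = rater_noise / (rater_noise + 4.0)
    z_cut = norm.ppf(1.0 - p)  # marginal flip probability stays p
    g = first.grid.astype(bool)
    eroded = ndimage.binary_erosion(g)
    surface = g & ~eroded
    dilated = ndimage.binary_dilation(g)
    halo = dilated & ~g
    for attempt in range(10):
        rng = _rng(spec.seed, 1, attempt)
        field = ndimage.gaussian_filter(rng.normal(size=g.shape), 5.0)
        field /= field.std() or 1.0
        out = g.copy()
        out[surface & (field < -z_cut)] = False
        out[halo & (field > z_cut)] = True
        _, ncomp = ndimage.label(out, structure=_STRUCT26)
        if ncomp == 1 and out.any():
            return first, VoxelMask(out.astype(np.uint8), first.spacing,
                                    first.origin, {"rater": 2})
    labeled, ncomp = ndimage.label(out, structure=_STRUCT26)
    sizes = ndimage.sum_labels(out, labeled, np.arange(1, ncomp + 1))
    out = labeled == int(np.argmax(sizes)) + 1
    return first, VoxelMask(out.astype(np.uint8), first.spacing,
                            first.origin, {"rater": 2})


# ---------------------------------------------------------------------------
# Cohort simulation

@dataclass(frozen=True)
class ClassParams:
    """Per-class population parameters of the simulated cohort."""

    n: int
    age: tuple[float, float]
    diameter: tuple[float, float]
    p_symptoms: float
    p_myasthenia: float
    p_cystic: float
    p_calcification: float
    log_volume: tuple[float, float]
    surface_area_cm2: tuple[float, float]
    sphericity: tuple[float, float]
    discrete_compactness: tuple[float, float]
    roundness: tuple[float, float]


@dataclass(frozen=True)
class CohortSpec:
    """Two-class cohort recipe; defaults are the published summaries."""

    encapsulated: ClassParams
    invasive: ClassParams
    seed: int = 0
    #: optional correlation matrix over the 5 continuous shape features
    #: (applied within class via a Gaussian copula); None = independent.
    feature_correlation: np.ndarray | None = None


DEFAULT_COHORT_SPEC = CohortSpec(
    encapsulated=ClassParams(
        n=23, age=(52.0, 12.7), diameter=(4.9, 1.7),
        p_symptoms=2 / 23, p_myasthenia=4 / 23, p_cystic=3 / 23,
        p_calcification=4 / 23,
        log_volume=(1.631, 0.529), surface_area_cm2=(89.989, 59.312),
        sphericity=(0.677, 0.106), discrete_compactness=(0.825, 0.106),
        roundness=(0.699, 0.068)),
    invasive=ClassParams(
        n=30, age=(55.3, 13.6), diameter=(4.2, 1.8),
        p_symptoms=9 / 30, p_myasthenia=7 / 30, p_cystic=16 / 30,
        p_calcification=7 / 30,
        log_volume=(1.335, 0.604), surface_area_cm2=(83.552, 86.609),
        sphericity=(0.604, 0.104), discrete_compactness=(0.691, 0.160),
        roundness=(0.685, 0.074)),
)

_UNIT_FEATURES = ("sphericity", "discrete_compactness", "roundness")
_POSITIVE = ("age", "diameter", "surface_area_cm2")
_SHAPE_FEATURES = ("log_volume", "surface_area_cm2", "sphericity",
                   "discrete_compactness", "roundness")


def _truncated_normal(rng, mean, sd, size, low=-np.inf, high=np.inf,
                      max_tries=1000):
    """Normal draws truncated to (low, high] by resampling (no clipping)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    for _ in range(max_tries):
        bad = (out <= low) | (out > high)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    raise RuntimeError("truncated sampling failed to converge")


def _simulate_class(params: ClassParams, label: int, prefix: str,
                    rng: np.random.Generator,
                    correlation: np.ndarray | None) -> pd.DataFrame:
    n = params.n
    if n <= 0:
        raise ValueError("class sizes must be positive")
    df = pd.DataFrame({
        "subject_id": [f"{prefix}{i + 1:03d}" for i in range(n)],
        "label": label,
    })
    df["age"] = _truncated_normal(rng, *params.age, n, low=0.0)
    df["symptoms"] = (rng.random(n) < params.p_symptoms).astype(int)
    df["myasthenia"] = (rng.random(n) < params.p_myasthenia).astype(int)
    df["cystic_change"] = (rng.random(n) < params.p_cystic).astype(int)
    df["calcification"] = (rng.random(n) < params.p_calcification).astype(int)
    df["diameter"] = _truncated_normal(rng, *params.diameter, n, low=0.0)

    if correlation is not None:
        corr = np.asarray(correlation, dtype=float)
        if corr.shape != (5, 5):
            raise ValueError("feature_correlation must be 5x5")
        z = rng.multivariate_normal(np.zeros(5), corr, size=n)
        u = norm.cdf(z)
        for j, feat in enumerate(_SHAPE_FEATURES):
            m, s = getattr(params, feat)
            lo = 0.0 if feat in _POSITIVE or feat in _UNIT_FEATURES \
                else -np.inf
            hi = 1.0 if feat in _UNIT_FEATURES else np.inf
            df[feat] = _inverse_truncnorm(u[:, j], m, s, lo, hi)
    else:
        for feat in _SHAPE_FEATURES:
            m, s = getattr(params, feat)
            lo = 0.0 if feat in _POSITIVE or feat in _UNIT_FEATURES \
                else -np.inf
            hi = 1.0 if feat in _UNIT_FEATURES else np.inf
            df[feat] = _truncated_normal(rng, m, s, n, low=lo, high=hi)
    return df


def _inverse_truncnorm(u, mean, sd, low, high):
    """Quantile transform of uniforms to a truncated normal margin."""
    if sd == 0:
        return np.full(len(u), mean)
    a = (low - mean) / sd if np.isfinite(low) else -np.inf
    b = (high - mean) / sd if np.isfinite(high) else np.inf
    return truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b,
                         loc=mean, scale=sd)


def simulate_cohort(spec: CohortSpec = DEFAULT_COHORT_SPEC) -> pd.DataFrame:
    """Draw a two-class cohort table from the spec's population parameters.

    Continuous features are normal within class (unit-interval features
    truncated to (0, 1] by resampling); binary covariates are Bernoulli at
    the class rates.  Deterministic per seed.
    """
    rng_enc = _rng(spec.seed, 10)
    rng_inv = _rng(spec.seed, 11)
    enc = _simulate_class(spec.encapsulated, 0, "E", rng_enc,
                          spec.feature_correlation)
    inv = _simulate_class(spec.invasive, 1, "I", rng_inv,
                          spec.feature_correlation)
    df = pd.concat([enc, inv], ignore_index=True)
    df.attrs["seed"] = spec.seed
    return df


def simulate_phantom_cohort(n_enc: int = 20, n_inv: int = 20,
                            lobulation_gap: float = 0.5, seed: int = 0,
                            base_radius: tuple[float, float] = (8.0, 12.0),
                            n_lobes: tuple[int, int] = (4, 8),
                            amplitude_sd: float = 0.05
                            ) -> tuple[list[VoxelMask], np.ndarray]:
    """Two classes of phantoms separated only by lobulation amplitude.

    Class amplitudes sit at 0.5 -/+ lobulation_gap/2 (clipped to [0, 1])
    with per-subject jitter; radii, axis ratios and lobe counts vary
    randomly in both classes alike.  With a large gap the invasive class
    is visibly lobulated and its discrete compactness drops.
    """
    if not (0.0 <= lobulation_gap <= 1.0):
        raise ValueError("lobulation_gap must be in [0, 1]")
    amps = {0: max(0.0, 0.5 - lobulation_gap / 2),
            1: min(1.0, 0.5 + lobulation_gap / 2)}
    masks, labels = [], []
    counter = 0
    for label, count in ((0, n_enc), (1, n_inv)):
        for _ in range(count):
            rng = _rng(seed, 20, counter)
            r = rng.uniform(*base_radius)
            stretch = rng.uniform(1.0, 1.4)
            axes = (r, r, r * stretch)
            amp = float(np.clip(rng.normal(amps[label], amplitude_sd),
                                0.0, 1.0))
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            spec = PhantomSpec(kind="lobulated", semi_axes=axes,
                               n_lobes=int(rng.integers(*n_lobes)),
                               amplitude=amp, seed=sub_seed)
            masks.append(make_phantom(spec))
            labels.append(label)
            counter += 1
    return masks, np.asarray(labels, dtype=int)
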