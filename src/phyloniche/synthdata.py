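"""Synthetic study systems with known ground truth.

Generates every input the pipeline consumes: a time-calibrated pure-birth
tree, continuous climatic traits evolved under any of the four trait models,
smooth spatial climate layers (planar gradient plus a smoothed Gaussian
random field), per-species Gaussian-niche suitability surfaces, and
suitability-proportional occurrence samples.  The default scenario mirrors
the scale of a ~20-species montane lizard radiation: 20 species on a tree of
depth 10 MY, three climate variables on a 100 x 100 grid, 200 occurrence
records per species.

Everything is reproducible end to end from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import GridLayer, OccurrenceSet
from .trees import Phylo, read_newick, simulate_bm_tips, transform_vcv, vcv

__all__ = ["SyntheticScenario", "ScenarioData", "simulate_yule_tree", "simulate_trait",
           "make_landscape", "make_correlated_landscape", "make_suitability",
           "sample_occurrences", "generate_scenario"]


def simulate_yule_tree(n_tips: int, T: float = 1.0, seed=None) -> Phylo:
    """Pure-birth tree with ``n_tips`` tips rescaled to depth ``T``.

    Ultrametric by construction; tip labels are ``sp01, sp02, ...``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)

    class _N:
        __slots__ = ("time", "kids", "label")

        def __init__(self, time):
            self.time = time
            self.kids = []
            self.label = None

    # crown-conditioned pure birth: the root splits at time 0 into 2 lineages;
    # with k extant lineages the next split waits Exp(rate k) (unit birth rate)
    root = _N(0.0)
    root.kids = [_N(0.0), _N(0.0)]
    extant = list(root.kids)
    t = 0.0
    for k in range(2, n_tips):
        t += rng.exponential(1.0 / k)
        parent = extant.pop(rng.integers(len(extant)))
        parent.time = t
        parent.kids = [_N(t), _N(t)]
        extant.extend(parent.kids)
    present = t + rng.exponential(1.0 / n_tips)  # extend past the last split
    for i, leaf in enumerate(extant):
        leaf.time = present
        leaf.label = f"sp{i + 1:02d}"
    scale = T / present

    def newick(node: _N, parent_time: float) -> str:
        bl = (node.time - parent_time) * scale
        if not node.kids:
            return f"{node.label}:{bl:.10g}"
        inner = ",".join(newick(k, node.time) for k in node.kids)
        return f"({inner}):{bl:.10g}"

    s = "(" + ",".join(newick(k, 0.0) for k in root.kids) + ");"
    return read_newick(s)


def simulate_trait(tree: Phylo, model: str = "bm", sigma2: float = 1.0,
                   z0: float = 0.0, seed=None, size: int = 1, **shape) -> np.ndarray:
    """Draw tip traits from MVN(z0*1, sigma2 * transformed C).

    ``shape`` carries the model's shape parameter (``lam``, ``delta``, ``r``
    or ``alpha``); OU uses the same conditional-on-root covariance as the
    fitting code.  Returns (n_tips,) or (size, n_tips).
    """
    rng = np.random.default_rng(seed)
    C = vcv(tree)
    Ct = C.C if model == "bm" else transform_vcv(C, model, shape).C
    n = tree.n_tips
    if sigma2 == 0:
        out = np.full((size, n), z0)
    else:
        L = np.linalg.cholesky(sigma2 * Ct + 1e-12 * np.eye(n))
        out = z0 + rng.standard_normal((size, n)) @ L.T
    return out[0] if size == 1 else out


def make_landscape(shape: tuple[int, int] = (100, 100), gradient: float = 1.0,
                   noise: float = 0.2, seed=None, smooth_sigma: float = 5.0,
                   west: float = -105.0, south: float = 15.0,
                   cellsize: float = 0.05) -> GridLayer:
    """Smooth synthetic climate layer: planar gradient + smoothed Gaussian field.

    Values span roughly [0, gradient] plus noise of amplitude ``noise``
    (standard deviation of the smoothed field).
    """
    nr, nc = shape
    if nr < 10 or nc < 10:
        raise ValueError("landscape must be at least 10 x 10")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:nr, 0:nc]
    plane = (xx / (nc - 1)) * np.cos(theta) + (yy / (nr - 1)) * np.sin(theta)
    plane = (plane - plane.min()) / max(plane.max() - plane.min(), 1e-12) * gradient
    values = plane
    if noise > 0:
        f = gaussian_filter(rng.standard_normal((nr, nc)), smooth_sigma)
        f = f / max(f.std(), 1e-12) * noise
        values = values + f
    return GridLayer(nrows=nr, ncols=nc, west=west, south=south,
                     cellsize=cellsize, nodata=-9999.0, values=values)


def make_correlated_landscape(base: GridLayer, target_r: float, seed=None,
                              smooth_sigma: float = 5.0) -> GridLayer:
    """Sibling layer with Pearson correlation ~ ``target_r`` to ``base``."""
    if not -1 <= target_r <= 1:
        raise ValueError("target_r must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    b = base.values
    z = (b - b.mean()) / max(b.std(), 1e-12)
    f = gaussian_filter(rng.standard_normal(b.shape), smooth_sigma)
    f = (f - f.mean()) / max(f.std(), 1e-12)
    # project out the base so the mix hits target_r exactly in expectation
    f = f - z * (z * f).mean() / max((z * z).mean(), 1e-12)
    f = f / max(f.std(), 1e-12)
    mix = target_r * z + np.sqrt(max(1 - target_r ** 2, 0.0)) * f
    vals = mix * b.std() + b.mean()
    return GridLayer(nrows=base.nrows, ncols=base.ncols, west=base.west,
                     south=base.south, cellsize=base.cellsize,
                     nodata=base.nodata, values=vals)


def make_suitability(climate: GridLayer, mu: float, tau: float) -> GridLayer:
    """Gaussian niche response: S = exp(-(B - mu)^2 / (2 tau^2)) in (0, 1]."""
    if tau <= 0:
        raise ValueError("niche breadth tau must be > 0")
    m = climate.valid_mask()
    vals = np.full_like(climate.values, climate.nodata, dtype=float)
    vals[m] = np.exp(-((climate.values[m] - mu) ** 2) / (2.0 * tau ** 2))
    return GridLayer(nrows=climate.nrows, ncols=climate.ncols, west=climate.west,
                     south=climate.south, cellsize=climate.cellsize,
                     nodata=climate.nodata, values=vals)


def sample_occurrences(suitability: GridLayer, n: int, species: str = "sp",
                       seed=None) -> OccurrenceSet:
    """Draw ``n`` occurrence points with cell probability proportional to suitability.

    Coordinates are jittered uniformly within the chosen cell.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    m = suitability.valid_mask()
    w = np.where(m, suitability.values, 0.0).ravel()
    tot = w.sum()
    if tot <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample")
    idx = rng.choice(len(w), size=n, p=w / tot)
    row, col = np.unravel_index(idx, suitability.values.shape)
    lon_c, lat_c = suitability.cell_center(row, col)
    jitter = suitability.cellsize
    lon = lon_c + rng.uniform(-0.5, 0.5, n) * jitter
    lat = lat_c + rng.uniform(-0.5, 0.5, n) * jitter
    return OccurrenceSet(species, lon, lat)


@dataclass
class SyntheticScenario:
    """Parameters of a full synthetic study system."""

    n_species: int = 20
    tree_depth: float = 10.0            # MY
    grid_shape: tuple[int, int] = (100, 100)
    n_variables: int = 3
    trait_models: list[dict] = field(default_factory=list)  # per-variable model spec
    niche_breadth_frac: float = 0.15    # tau as fraction of each layer's range
    occurrences_per_species: int = 200
    landscape_gradient: float = 1.0
    landscape_noise: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.trait_models:
            self.trait_models = [{"model": "bm", "sigma2": 1.0, "z0": 0.0}
                                 for _ in range(self.n_variables)]
        if len(self.trait_models) != self.n_variables:
            raise ValueError("need one trait model spec per variable")


@dataclass
class ScenarioData:
    tree: Phylo
    climate: dict[str, GridLayer]
    suitability: dict[str, dict[str, GridLayer]]   # variable -> species -> layer
    combined_suitability: dict[str, GridLayer]     # species -> product over variables
    occurrences: dict[str, OccurrenceSet]
    true_optima: "object"                          # DataFrame species x variable
    scenario: SyntheticScenario


def generate_scenario(scenario: SyntheticScenario | None = None, seed=None) -> ScenarioData:
    """Generate a complete synthetic study system.

    Per variable, species niche optima evolve by the variable's trait model on
    the tree and are mapped linearly into the central 60% of the layer's
    range (an affine map, so the optima remain draws from the same model
    class); suitability is the Gaussian response around each optimum, and the
    species' overall surface is the product across variables.
    """
    import pandas as pd

    sc = scenario or SyntheticScenario()
    if seed is not None:
        sc.seed = seed
    ss = np.random.SeedSequence(sc.seed)
    s_tree, s_land, s_trait, s_occ = ss.spawn(4)

    tree = simulate_yule_tree(sc.n_species, sc.tree_depth, seed=s_tree)
    species = tree.tip_labels

    land_seeds = s_land.spawn(sc.n_variables)
    trait_seeds = s_trait.spawn(sc.n_variables)
    climate: dict[str, GridLayer] = {}
    optima = {}
    suitability: dict[str, dict[str, GridLayer]] = {}
    for v in range(sc.n_variables):
        name = f"var{v + 1}"
        layer = make_landscape(sc.grid_shape, gradient=sc.landscape_gradient,
                               noise=sc.landscape_noise, seed=land_seeds[v])
        climate[name] = layer
        spec = dict(sc.trait_models[v])
        model = spec.pop("model", "bm")
        raw = simulate_trait(tree, model=model, seed=trait_seeds[v], **spec)
        vals = layer.valid_values()
        lo, hi = np.quantile(vals, [0.2, 0.8])
        rng_raw = max(raw.max() - raw.min(), 1e-12)
        mu = lo + (raw - raw.min()) / rng_raw * (hi - lo)
        optima[name] = mu
        tau = sc.niche_breadth_frac * (vals.max() - vals.min())
        suitability[name] = {sp: make_suitability(layer, mu[i], tau)
                             for i, sp in enumerate(species)}

    combined = {}
    for i, sp in enumerate(species):
        prod = None
        for name in climate:
            s = suitability[name][sp].values
            prod = s.copy() if prod is None else prod * s
        ref = climate[next(iter(climate))]
        combined[sp] = GridLayer(nrows=ref.nrows, ncols=ref.ncols, west=ref.west,
                                 south=ref.south, cellsize=ref.cellsize,
                                 nodata=ref.nodata, values=prod)

    occ_seeds = s_occ.spawn(len(species))
    occurrences = {sp: sample_occurrences(combined[sp], sc.occurrences_per_species,
                                          species=sp, seed=occ_seeds[i])
                   for i, sp in enumerate(species)}
    true_optima = pd.DataFrame(optima, index=species)
    return ScenarioData(tree=tree, climate=climate, suitability=suitability,
                        combined_suitability=combined, occurrences=occurrences,
                        true_optima=true_optima, scenario=sc)
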