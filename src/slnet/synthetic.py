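"""Synthetic cohorts of regional BOLD-like time-series, plus graph and
dynamical-system fixtures.

The cohort generator uses a latent-factor Gaussian model: one latent
signal per lobe block plus one global signal shared by all regions.
The loading of a region in block ``b`` onto the latent of block ``b'``
is the symmetric per-block-pair coupling ``base_coupling[b, b']`` (for
patients, ``base_coupling + ad_effect``), which gives direct monotone
control of block-pairwise synchrony.  Slow BOLD-like temporal
autocorrelation is emulated by a short moving-average smoother; no
hemodynamic model, head motion or scanner drift is simulated.

Default coupling values emulate the qualitative regime reported for
resting-state AAL parcellations in early Alzheimer's disease: controls
show a strong parieto-occipital synchronization cluster and moderate
frontal coupling; the patient effect raises frontal-frontal and right
temporal-frontal coupling and lowers fronto-posterior, left
temporal-posterior and within-posterior coupling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.ndimage import uniform_filter1d

from .graphs import BinaryGraph

__all__ = [
    "ConfigurationError",
    "CohortConfig",
    "RegionalTimeSeries",
    "BLOCKS",
    "default_block_map",
    "default_base_coupling",
    "default_ad_effect",
    "simulate_cohort",
    "coupled_map_pair",
    "ring_lattice",
    "random_graph",
]


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


#: Lobe block labels used by the default cohort model.
BLOCKS = (
    "frontal",
    "temporal-L",
    "temporal-R",
    "parieto-occipital",
    "subcortical",
    "cerebellar",
)


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def default_block_map(n_regions: int = 116) -> tuple[str, ...]:
    """Assign ``n_regions`` regions to the six lobe blocks.

    For 116 regions the assignment matches the bundled AAL registry's
    block sizes (32 frontal, 10+10 temporal, 28 parieto-occipital,
    10 subcortical, 26 cerebellar); other sizes allocate proportionally
    (at least one region per block).
    """
    proportions = {"frontal": 32, "temporal-L": 10, "temporal-R": 10,
                   "parieto-occipital": 28, "subcortical": 10, "cerebellar": 26}
    total = sum(proportions.values())
    counts = {b: max(1, int(round(n_regions * c / total)))
              for b, c in proportions.items()}
    # fix rounding drift on the largest block
    drift = n_regions - sum(counts.values())
    counts["frontal"] += drift
    if counts["frontal"] < 1:
        raise ConfigurationError(f"n_regions={n_regions} too small for 6 blocks")
    out: list[str] = []
    for b in BLOCKS:
        out.extend([b] * counts[b])
    return tuple(out)


def default_base_coupling() -> dict[tuple[str, str], float]:
    """Healthy-control block-pair latent loadings.

    Within-block loadings are strongest for the parieto-occipital
    cluster and moderate for frontal cortex; all cross-block loadings
    sit at a common low baseline.
    """
    within = {"frontal": 0.60, "temporal-L": 0.85, "temporal-R": 0.85,
              "parieto-occipital": 0.90, "subcortical": 0.80, "cerebellar": 0.85}
    coupling: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations_with_replacement(BLOCKS, 2):
        coupling[_canon(a, b)] = within[a] if a == b else 0.25
    return coupling


def default_ad_effect() -> dict[tuple[str, str], float]:
    """Additive patient-group coupling deltas (the "AD" effect):
    frontal hypersynchronization, fronto-posterior and within-posterior
    decoupling, right-lateralized temporal-frontal increase."""
    eff = {_canon(a, b): 0.0
           for a, b in itertools.combinations_with_replacement(BLOCKS, 2)}
    eff[_canon("frontal", "frontal")] = +0.15
    eff[_canon("frontal", "parieto-occipital")] = -0.20
    eff[_canon("temporal-L", "parieto-occipital")] = -0.15
    eff[_canon("temporal-R", "frontal")] = +0.10
    eff[_canon("parieto-occipital", "parieto-occipital")] = -0.15
    return eff


@dataclass(frozen=True)
class RegionalTimeSeries:
    """One subject's R x Tn matrix of regional time-series."""

    subject_id: str
    group: str
    values: np.ndarray
    tr_seconds: float = 2.85
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D (regions x timepoints) array")
        if np.isnan(v).any():
            raise ValueError("values contain NaN")
        if np.any(v.std(axis=1) == 0):
            raise ValueError("every region's series must have nonzero variance")
        if self.group not in ("control", "patient"):
            raise ValueError(f"group must be 'control' or 'patient', got {self.group!r}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "values", v)
        if self.region_labels is not None:
            if len(self.region_labels) != v.shape[0]:
                raise ValueError("region_labels length must match row count")
            object.__setattr__(self, "region_labels", tuple(self.region_labels))

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a simulated two-group cohort.

    Defaults mirror the study design the package emulates: 21 controls
    and 18 patients, 116 regions x 200 timepoints at TR 2.85 s.
    """

    n_control: int = 21
    n_patient: int = 18
    n_regions: int = 116
    n_timepoints: int = 200
    seed: int = 0
    block_map: tuple[str, ...] = field(default_factory=default_block_map)
    base_coupling: dict = field(default_factory=default_base_coupling)
    ad_effect: dict = field(default_factory=default_ad_effect)
    noise_sd: float = 0.35
    smooth_window: int = 3
    global_weight: float = 0.65
    tr_seconds: float = 2.85
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_patient < 1:
            raise ConfigurationError("need at least one subject per group")
        if len(self.block_map) != self.n_regions:
            raise ConfigurationError(
                f"block_map covers {len(self.block_map)} regions, "
                f"expected n_regions={self.n_regions}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.smooth_window < 1:
            raise ConfigurationError("smooth_window must be >= 1")
        blocks = sorted(set(self.block_map))
        base = _canonical_coupling(self.base_coupling, blocks, "base_coupling")
        eff = _canonical_coupling(self.ad_effect, blocks, "ad_effect",
                                  lo=-1.0, hi=1.0, default=0.0)
        for key, v in base.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(
                    f"base_coupling[{key}]={v} outside [0, 1]")
            tot = v + eff[key]
            if not 0.0 <= tot <= 1.0:
                raise ConfigurationError(
                    f"base_coupling + ad_effect = {tot} outside [0, 1] for {key}")
        object.__setattr__(self, "base_coupling", base)
        object.__setattr__(self, "ad_effect", eff)
        object.__setattr__(self, "block_map", tuple(self.block_map))

    @property
    def blocks(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.block_map)))


def _canonical_coupling(coupling: dict, blocks, name: str,
                        lo: float = 0.0, hi: float = 1.0,
                        default: float | None = None) -> dict:
    """Normalize a per-block-pair map to canonical (sorted) keys and
    verify symmetry, range and coverage."""
    canon: dict[tuple[str, str], float] = {}
    for (a, b), v in coupling.items():
        key = _canon(a, b)
        if key in canon and canon[key] != v:
            raise ConfigurationError(
                f"{name} is asymmetric for block pair {key}: "
                f"{canon[key]} vs {v}")
        canon[key] = float(v)
        if not lo <= v <= hi:
            raise ConfigurationError(f"{name}[{key}]={v} outside [{lo}, {hi}]")
    for a, b in itertools.combinations_with_replacement(blocks, 2):
        key = _canon(a, b)
        if key not in canon:
            if default is None:
                raise ConfigurationError(f"{name} missing block pair {key}")
            canon[key] = default
    return canon


def _loading_matrix(config: CohortConfig, group: str) -> np.ndarray:
    blocks = config.blocks
    n = len(blocks)
    load = np.zeros((n, n))
    for i, a in enumerate(blocks):
        for j, b in enumerate(blocks):
            key = _canon(a, b)
            v = config.base_coupling[key]
            if group == "patient":
                v += config.ad_effect[key]
            load[i, j] = v
    return load


def _simulate_subject(config: CohortConfig, group: str, rng) -> np.ndarray:
    blocks = config.blocks
    block_idx = np.array([blocks.index(b) for b in config.block_map])
    load = _loading_matrix(config, group)            # blocks x blocks
    tn = config.n_timepoints
    latents = rng.standard_normal((len(blocks), tn))
    global_latent = rng.standard_normal(tn)
    noise = rng.standard_normal((config.n_regions, tn))
    series = (load[block_idx] @ latents
              + config.global_weight * global_latent[None, :]
              + config.noise_sd * noise)
    if config.smooth_window > 1:
        series = uniform_filter1d(series, size=config.smooth_window,
                                  axis=1, mode="nearest")
    return series


def simulate_cohort(config: CohortConfig) -> list[RegionalTimeSeries]:
    """Simulate a full two-group cohort.

    Per-subject random streams are spawned from the master seed with the
    counter scheme ``default_rng([config.seed, subject_index])``, so the
    same seed reproduces the cohort bit-exactly and each subject's data
    is independent of cohort ordering.
    """
    subjects: list[RegionalTimeSeries] = []
    labels = config.region_labels
    if labels is None:
        labels = tuple(f"{b}_{k:03d}" for k, b in enumerate(config.block_map))
    idx = 0
    for group, count, prefix in (("control", config.n_control, "ctrl"),
                                 ("patient", config.n_patient, "pat")):
        for k in range(count):
            rng = np.random.default_rng([config.seed, idx])
            values = _simulate_subject(config, group, rng)
            subjects.append(RegionalTimeSeries(
                subject_id=f"{prefix}-{k + 1:02d}", group=group,
                values=values, tr_seconds=config.tr_seconds,
                region_labels=labels))
            idx += 1
    return subjects


def coupled_map_pair(coupling: float, n: int, seed,
                     transient: int = 5000,
                     noise_sd: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Driver-response pair of unidirectionally coupled Henon maps.

    The driver is the classic Henon map (a=1.4, b=0.3); the response is
    an identical Henon system whose quadratic term mixes its own state
    with the driver's with weight ``coupling``::

        x[t+1] = 1.4 - x[t]^2 + 0.3 x[t-1]
        y[t+1] = 1.4 - (c x[t] + (1 - c) y[t]) y[t] + 0.3 y[t-1]

    At ``coupling = 1`` the response synchronizes identically to the
    driver after the transient; at 0 the two series are independent.
    Optional observational noise can be added to both outputs.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError(f"coupling must lie in [0, 1], got {coupling}")
    if n < 50:
        raise ValueError(f"need n >= 50, got {n}")
    rng = np.random.default_rng(seed)
    total = transient + n
    x = np.empty(total)
    y = np.empty(total)
    x[0], x[1] = rng.uniform(-0.1, 0.1, size=2)
    y[0], y[1] = rng.uniform(-0.1, 0.1, size=2)
    b = 0.3
    for t in range(1, total - 1):
        x[t + 1] = 1.4 - x[t] ** 2 + b * x[t - 1]
        drive = coupling * x[t] + (1.0 - coupling) * y[t]
        y[t + 1] = 1.4 - drive * y[t] + b * y[t - 1]
    xs, ys = x[transient:].copy(), y[transient:].copy()
    if noise_sd > 0:
        xs = xs + noise_sd * rng.standard_normal(n)
        ys = ys + noise_sd * rng.standard_normal(n)
    return xs, ys


def ring_lattice(n_vertices: int, k: int) -> BinaryGraph:
    """Regular ring lattice: each vertex linked to its k/2 nearest
    neighbors on each side (k even, k < n)."""
    if k % 2 != 0:
        raise ValueError(f"k must be even, got {k}")
    if not 0 < k < n_vertices:
        raise ValueError(f"need 0 < k < n_vertices, got k={k}, n={n_vertices}")
    edges = set()
    for i in range(n_vertices):
        for step in range(1, k // 2 + 1):
            edges.add((i, (i + step) % n_vertices))
    return BinaryGraph(n_vertices=n_vertices, edges=frozenset(edges))


def random_graph(n_vertices: int, n_edges: int, seed) -> BinaryGraph:
    """Uniform simple graph with exactly ``n_edges`` edges (G(n, m))."""
    max_edges = n_vertices * (n_vertices - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"n_edges={n_edges} exceeds maximum {max_edges} for n={n_vertices}")
    rng = np.random.default_rng(seed)
    g = nx.gnm_random_graph(n_vertices, n_edges,
                            seed=int(rng.integers(0, 2**31 - 1)))
    return BinaryGraph.from_networkx(g)
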