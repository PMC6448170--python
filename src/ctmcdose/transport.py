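"""Voxel Monte Carlo photon transport with Woodcock delta tracking.

Physics scope (collision-kerma approximation, valid at CT energies where
secondary-electron ranges are sub-voxel):

* photoelectric -- full local energy deposit, history ends;
* incoherent -- free-electron Klein-Nishina angle/energy, the electron's
  share is deposited at the interaction site;
* coherent -- Thomson angular shape, no deposit;
* photons below the cutoff deposit their remaining energy locally.

Flight sampling uses a global-majorant (Woodcock) scheme, so no voxel
boundary ray tracing is needed; straight flight segments also feed the
track-length energy-fluence estimator.  Histories are split into batches
with independent seeded streams; batch spread gives the statistical error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .acquisition import SourcePhotonBatch, batch_rng, emit_photons
from .phantom import ELEMENTS, CompositionTable, VoxelPhantom
from .spectrum import AttenuationTable, ConfigurationError

__all__ = [
    "MaterialXS",
    "TallySpec",
    "TallyResult",
    "RunConfig",
    "SimulationResult",
    "mixture_mu",
    "sample_compton",
    "sample_thomson",
    "track_photon",
    "run_simulation",
    "fluence_to_kerma",
    "batch_statistics",
    "TransportEngine",
]

ELECTRON_REST_KEV = 510.998950
KEV_TO_JOULE = 1.602176634e-16
# photons/mm^2 * keV * cm^2/g -> Gy
_FLUENCE_KERMA_GY = 100.0 * KEV_TO_JOULE * 1000.0

_CHANNELS = ("pe", "incoh", "coh")


def mixture_mu(
    fractions,
    density: float,
    energy_kev,
    xs: AttenuationTable,
) -> dict:
    """Linear attenuation per channel (1/cm) for an elemental mixture.

    ``fractions`` is a mapping element name -> weight fraction (or a sequence
    ordered like :data:`ctmcdose.phantom.ELEMENTS`).
    """
    if not isinstance(fractions, dict):
        fractions = dict(zip(ELEMENTS, fractions))
    total = sum(fractions.values())
    if not 0.9 < total < 1.1:
        raise ConfigurationError(f"weight fractions sum to {total:.3f}, expected ~1")
    out = {}
    for channel in _CHANNELS + ("total", "en"):
        acc = 0.0
        for element, w in fractions.items():
            if w <= 0:
                continue
            acc = acc + w * xs.mass_coefficient(element, energy_kev, channel)
        out[channel] = density * acc
    return out


class MaterialXS:
    """Per-composition-row mass coefficients on a uniform fine energy grid."""

    def __init__(
        self,
        composition: CompositionTable,
        xs: AttenuationTable,
        max_energy_kev: float,
        min_energy_kev: float = 1.0,
        grid_step_kev: float = 0.5,
    ):
        self.energy_grid = np.arange(
            min_energy_kev, max_energy_kev + grid_step_kev, grid_step_kev
        )
        self._e0 = self.energy_grid[0]
        self._de = grid_step_kev
        n_rows = composition.n_rows
        n_e = self.energy_grid.size
        self.mass = {ch: np.zeros((n_rows, n_e)) for ch in _CHANNELS + ("en",)}
        for row in range(n_rows):
            for element, w in zip(ELEMENTS, composition.fractions[row]):
                if w <= 0:
                    continue
                for ch in _CHANNELS + ("en",):
                    self.mass[ch][row] += w * xs.mass_coefficient(
                        element, self.energy_grid, ch
                    )
        self.mass["total"] = sum(self.mass[ch] for ch in _CHANNELS)

    def energy_index(self, energy_kev) -> np.ndarray:
        idx = np.rint((np.asarray(energy_kev) - self._e0) / self._de).astype(np.intp)
        return np.clip(idx, 0, self.energy_grid.size - 1)


@dataclass
class TallySpec:
    """Scoring region + score kind.

    ``kind`` is ``cylinder`` (center, axis, radius, length), ``voxel_mask``
    (boolean grid) or ``region`` (composition-row index).  ``score`` is
    ``energy_deposition`` (Gy) or ``energy_fluence`` (track-length estimate
    in ``n_energy_bins`` bins; cylinder regions only).
    """

    name: str
    kind: str = "cylinder"
    score: str = "energy_deposition"
    center_mm: Sequence[float] = (0.0, 0.0, 0.0)
    axis: Sequence[float] = (0.0, 0.0, 1.0)
    radius_mm: float = 2.0
    length_mm: float = 10.0
    mask: Optional[np.ndarray] = None
    region_row: Optional[int] = None
    n_energy_bins: int = 30

    def __post_init__(self):
        if self.kind not in ("cylinder", "voxel_mask", "region"):
            raise ConfigurationError(f"unknown tally kind {self.kind!r}")
        if self.score not in ("energy_deposition", "energy_fluence"):
            raise ConfigurationError(f"unknown score {self.score!r}")
        if self.kind == "cylinder":
            if self.radius_mm <= 0 or self.length_mm <= 0:
                raise ConfigurationError("cylinder dimensions must be positive")
            axis = np.asarray(self.axis, dtype=float)
            self.axis = axis / np.linalg.norm(axis)
            self.center_mm = np.asarray(self.center_mm, dtype=float)
        if self.score == "energy_fluence" and self.kind != "cylinder":
            raise ConfigurationError("energy-fluence scoring requires a cylinder tally")
        if self.kind == "voxel_mask" and self.mask is None:
            raise ConfigurationError("voxel_mask tally needs a mask")
        if self.kind == "region" and self.region_row is None:
            raise ConfigurationError("region tally needs a composition-row index")

    def volume_mm3(self) -> float:
        if self.kind != "cylinder":
            raise ConfigurationError("analytic volume only defined for cylinders")
        return float(np.pi * self.radius_mm**2 * self.length_mm)

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Point-inclusion test for cylinder tallies; (n, 3) -> (n,) bool."""
        q = points_mm - self.center_mm
        along = q @ self.axis
        radial2 = np.einsum("ij,ij->i", q, q) - along**2
        return (np.abs(along) <= self.length_mm / 2) & (radial2 <= self.radius_mm**2)


def batch_statistics(batch_means) -> tuple:
    """(mean, sigma_MC, relative sigma) from per-batch means.

    ``sigma_MC`` is the standard error of the grand mean: sample SD of the
    batch means over sqrt(n_batches).
    """
    arr = np.asarray(batch_means, dtype=float)
    if arr.shape[0] < 2:
        raise ConfigurationError("need at least 2 batches for statistics")
    mean = arr.mean(axis=0)
    sigma = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean != 0, sigma / np.abs(mean), 0.0)
    return mean, sigma, rel


@dataclass
class TallyResult:
    """Batched scores for one tally, normalized per source photon."""

    name: str
    score: str
    batch_values: np.ndarray  # (n_batches,) or (n_batches, n_energy_bins)
    n_histories: int
    seed: int
    energy_bin_edges: Optional[np.ndarray] = None

    @property
    def n_batches(self) -> int:
        return self.batch_values.shape[0]

    @property
    def mean(self):
        return batch_statistics(self.batch_values)[0]

    @property
    def sigma(self):
        return batch_statistics(self.batch_values)[1]

    @property
    def relative_sigma(self):
        return batch_statistics(self.batch_values)[2]


@dataclass
class RunConfig:
    n_histories: int = 100_000
    n_batches: int = 10
    master_seed: int = 0
    cutoff_kev: float = 1.0

    def __post_init__(self):
        if not self.n_histories >= self.n_batches >= 2:
            raise ConfigurationError("need n_histories >= n_batches >= 2")


@dataclass
class SimulationResult:
    tallies: dict
    emitted_kev: float
    deposited_kev: float
    escaped_kev: float
    config: RunConfig = None

    @property
    def conservation_residual(self) -> float:
        return abs(self.emitted_kev - self.deposited_kev - self.escaped_kev) / self.emitted_kev


def sample_compton(energy_kev, rng: np.random.Generator):
    """Klein-Nishina (free electron) scatter: returns (E', cos theta).

    Rejection sampling of cos theta against the exact KN differential cross
    section (its forward maximum bounds the envelope), then the Compton
    relation for the scattered energy.
    """
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    alpha = e / ELECTRON_REST_KEV
    cos_t = np.empty_like(e)
    todo = np.arange(e.size)
    while todo.size:
        mu = 2.0 * rng.random(todo.size) - 1.0
        a = alpha[todo]
        x = 1.0 / (1.0 + a * (1.0 - mu))
        g = x * x * (x + 1.0 / x - 1.0 + mu * mu)
        accept = rng.random(todo.size) * 2.0 < g
        cos_t[todo[accept]] = mu[accept]
        todo = todo[~accept]
    e_out = e / (1.0 + alpha * (1.0 - cos_t))
    if np.ndim(energy_kev) == 0:
        return float(e_out[0]), float(cos_t[0])
    return e_out, cos_t


def sample_thomson(n: int, rng: np.random.Generator) -> np.ndarray:
    """Thomson angular shape (1 + cos^2)/2 via rejection; returns cos theta."""
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        mu = 2.0 * rng.random(todo.size) - 1.0
        accept = rng.random(todo.size) * 2.0 < (1.0 + mu * mu)
        out[todo[accept]] = mu[accept]
        todo = todo[~accept]
    return out


def _rotate_directions(d: np.ndarray, cos_t: np.ndarray, rng: np.random.Generator):
    """Rotate unit vectors by polar angle acos(cos_t) and a uniform azimuth."""
    n = d.shape[0]
    phi = rng.random(n) * 2.0 * np.pi
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    # orthonormal frame around each direction
    helper = np.zeros_like(d)
    use_x = np.abs(d[:, 0]) < 0.9
    helper[use_x, 0] = 1.0
    helper[~use_x, 1] = 1.0
    u = np.cross(d, helper)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    out = (
        cos_t[:, None] * d
        + sin_t[:, None] * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _segment_cylinder_length(p, d, seg_len, tally: TallySpec):
    """Length of each segment [p, p + seg_len*d] inside a finite cylinder."""
    q = p - tally.center_mm
    a = tally.axis
    qa = q @ a
    da = d @ a
    q_perp = q - qa[:, None] * a
    d_perp = d - da[:, None] * a
    A = np.einsum("ij,ij->i", d_perp, d_perp)
    B = 2.0 * np.einsum("ij,ij->i", q_perp, d_perp)
    C = np.einsum("ij,ij->i", q_perp, q_perp) - tally.radius_mm**2

    t0 = np.full(p.shape[0], np.inf)
    t1 = np.full(p.shape[0], -np.inf)
    quad = A > 1e-30
    disc = B[quad] ** 2 - 4.0 * A[quad] * C[quad]
    ok = disc > 0
    sq = np.sqrt(np.clip(disc, 0.0, None))
    qidx = np.where(quad)[0][ok]
    t0[qidx] = ((-B[quad][ok] - sq[ok]) / (2.0 * A[quad][ok]))
    t1[qidx] = ((-B[quad][ok] + sq[ok]) / (2.0 * A[quad][ok]))
    par = ~quad & (C <= 0)  # parallel to axis, inside radius
    t0[par], t1[par] = -np.inf, np.inf

    # axial clipping
    half = tally.length_mm / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (-half - qa) / da
        tb = (half - qa) / da
    ax_lo = np.minimum(ta, tb)
    ax_hi = np.maximum(ta, tb)
    perp = np.abs(da) < 1e-12
    inside_ax = np.abs(qa) <= half
    ax_lo[perp] = np.where(inside_ax[perp], -np.inf, np.inf)
    ax_hi[perp] = np.where(inside_ax[perp], np.inf, -np.inf)

    lo = np.maximum.reduce([t0, ax_lo, np.zeros_like(t0)])
    hi = np.minimum.reduce([t1, ax_hi, seg_len])
    return np.clip(hi - lo, 0.0, None)


class _BatchScores:
    def __init__(self, tallies, cutoff, kv):
        self.dep_kev = {t.name: 0.0 for t in tallies if t.score == "energy_deposition"}
        self.flu = {}
        self.flu_edges = {}
        for t in tallies:
            if t.score == "energy_fluence":
                self.flu[t.name] = np.zeros(t.n_energy_bins)
                self.flu_edges[t.name] = np.linspace(cutoff, kv, t.n_energy_bins + 1)
        self.total_dep_kev = 0.0
        self.escaped_kev = 0.0
        self.emitted_kev = 0.0


class TransportEngine:
    """Reusable Woodcock transport state for one phantom + cross-section set."""

    def __init__(self, phantom: VoxelPhantom, mxs: MaterialXS):
        self.phantom = phantom
        self.mxs = mxs
        self.grid_min = phantom.grid_min_mm
        self.grid_max = phantom.grid_max_mm
        self.spacing = phantom.spacing_mm
        self.dims = np.array(phantom.dims)
        self.density = np.ascontiguousarray(phantom.density, dtype=np.float64)
        self.material = np.ascontiguousarray(phantom.material_index, dtype=np.intp)
        # global majorant per energy grid point (1/mm): for every material row
        # present, its maximum density anywhere in the grid bounds mu there
        rows = np.unique(self.material)
        max_density = np.zeros(self.mxs.mass["total"].shape[0])
        for row in rows:
            max_density[row] = self.density[self.material == row].max()
        self.majorant_mm = (
            np.max(self.mxs.mass["total"] * max_density[:, None], axis=0) / 10.0
        )
        if np.any(self.majorant_mm <= 0):
            raise ConfigurationError("majorant must be positive above the cutoff")

    # -- geometry helpers ------------------------------------------------
    def _ray_box(self, pos, d):
        """(t_entry, t_exit) of rays with the grid box; t_entry < 0 -> inside."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (self.grid_min - pos) / d
            t_hi = (self.grid_max - pos) / d
        swap_lo = np.minimum(t_lo, t_hi)
        swap_hi = np.maximum(t_lo, t_hi)
        # rays parallel to an axis: outside slab -> miss
        par = np.abs(d) < 1e-15
        inside_slab = (pos >= self.grid_min) & (pos <= self.grid_max)
        swap_lo[par] = np.where(inside_slab[par], -np.inf, np.inf)
        swap_hi[par] = np.where(inside_slab[par], np.inf, -np.inf)
        return swap_lo.max(axis=1), swap_hi.min(axis=1)

    def _voxel_lookup(self, pos):
        idx = ((pos - self.grid_min) / self.spacing).astype(np.intp)
        idx = np.clip(idx, 0, self.dims - 1)
        flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), tuple(self.dims))
        return self.material.ravel()[flat], self.density.ravel()[flat]

    # -- main transport loop ---------------------------------------------
    def run(
        self,
        photons: SourcePhotonBatch,
        tallies: Sequence[TallySpec],
        rng: np.random.Generator,
        cutoff_kev: float = 1.0,
        kv: float = 120.0,
    ) -> _BatchScores:
        scores = _BatchScores(tallies, cutoff_kev, kv)
        dep_tallies = [t for t in tallies if t.score == "energy_deposition"]
        flu_tallies = [t for t in tallies if t.score == "energy_fluence"]

        pos = photons.position_mm.astype(np.float64).copy()
        d = photons.direction.astype(np.float64).copy()
        e = photons.energy_kev.astype(np.float64).copy()
        w = photons.weight.astype(np.float64).copy()
        scores.emitted_kev = float(np.sum(e * w))

        # fly in from outside the grid (vacuum outside)
        t_in, t_out = self._ray_box(pos, d)
        hit = (t_out > np.maximum(t_in, 0.0)) & (t_out > 0)
        scores.escaped_kev += float(np.sum(e[~hit] * w[~hit]))
        pos, d, e, w, t_in = pos[hit], d[hit], e[hit], w[hit], t_in[hit]
        eps = 1e-6 * self.spacing.min()
        outside = t_in > 0
        pos[outside] += (t_in[outside, None] + eps) * d[outside]

        def deposit(points, energies):
            scores.total_dep_kev += float(energies.sum())
            for t in dep_tallies:
                inside = self._tally_mask(t, points)
                scores.dep_kev[t.name] += float(energies[inside].sum())

        while e.size:
            e_idx = self.mxs.energy_index(e)
            mu_maj = self.majorant_mm[e_idx]
            s = -np.log(rng.random(e.size)) / mu_maj
            _, t_exit = self._ray_box(pos, d)
            seg = np.minimum(s, t_exit + eps)
            for t in flu_tallies:
                lengths = _segment_cylinder_length(pos, d, seg, t)
                scored = lengths > 0
                if scored.any():
                    edges = scores.flu_edges[t.name]
                    bins = np.clip(
                        np.searchsorted(edges, e[scored], side="right") - 1,
                        0,
                        edges.size - 2,
                    )
                    np.add.at(
                        scores.flu[t.name], bins, lengths[scored] * w[scored]
                    )
            exited = s >= t_exit
            scores.escaped_kev += float(np.sum(e[exited] * w[exited]))
            keep = ~exited
            pos, d, e, w, s = pos[keep], d[keep], e[keep], w[keep], s[keep]
            if not e.size:
                break
            pos += s[:, None] * d

            mat, rho = self._voxel_lookup(pos)
            e_idx = self.mxs.energy_index(e)
            mu_pe = self.mxs.mass["pe"][mat, e_idx] * rho / 10.0
            mu_in = self.mxs.mass["incoh"][mat, e_idx] * rho / 10.0
            mu_co = self.mxs.mass["coh"][mat, e_idx] * rho / 10.0
            mu_tot = mu_pe + mu_in + mu_co
            mu_maj = self.majorant_mm[self.mxs.energy_index(e)]
            real = rng.random(e.size) * mu_maj < mu_tot
            if real.any():
                r_pos, r_e, r_w = pos[real], e[real], w[real]
                u = rng.random(int(real.sum())) * mu_tot[real]
                is_pe = u < mu_pe[real]
                is_compt = ~is_pe & (u < mu_pe[real] + mu_in[real])
                is_rayl = ~is_pe & ~is_compt

                if is_pe.any():
                    deposit(r_pos[is_pe], r_e[is_pe] * r_w[is_pe])

                survivors_dir = d[real].copy()
                alive_real = ~is_pe
                if is_compt.any():
                    e_new, cos_t = sample_compton(r_e[is_compt], rng)
                    e_new = np.atleast_1d(e_new)
                    cos_t = np.atleast_1d(cos_t)
                    deposit(r_pos[is_compt], (r_e[is_compt] - e_new) * r_w[is_compt])
                    below = e_new <= cutoff_kev
                    if below.any():
                        deposit(
                            r_pos[is_compt][below], e_new[below] * r_w[is_compt][below]
                        )
                    r_e[is_compt] = np.where(below, 0.0, e_new)
                    survivors_dir[is_compt] = _rotate_directions(
                        survivors_dir[is_compt], cos_t, rng
                    )
                    alive_real[is_compt] = ~below
                if is_rayl.any():
                    cos_t = sample_thomson(int(is_rayl.sum()), rng)
                    survivors_dir[is_rayl] = _rotate_directions(
                        survivors_dir[is_rayl], cos_t, rng
                    )

                # merge: virtual collisions continue unchanged; real survivors
                # carry updated energy/direction
                new_e = e.copy()
                new_d = d.copy()
                new_e[real] = r_e
                new_d[real] = survivors_dir
                alive = np.ones(e.size, dtype=bool)
                alive[np.where(real)[0][~alive_real]] = False
                pos, d, e, w = pos[alive], new_d[alive], new_e[alive], w[alive]
        return scores

    def _tally_mask(self, tally: TallySpec, points):
        if tally.kind == "cylinder":
            return tally.contains(points)
        idx = ((points - self.grid_min) / self.spacing).astype(np.intp)
        idx = np.clip(idx, 0, self.dims - 1)
        if tally.kind == "voxel_mask":
            return tally.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        mat = self.material[idx[:, 0], idx[:, 1], idx[:, 2]]
        return mat == tally.region_row

    def tally_mass_kg(self, tally: TallySpec) -> float:
        """Mass of the scoring region (voxel densities; analytic cylinder volume)."""
        if tally.kind == "cylinder":
            idx = np.clip(
                ((np.asarray(tally.center_mm) - self.grid_min) / self.spacing).astype(int),
                0,
                self.dims - 1,
            )
            rho = self.density[idx[0], idx[1], idx[2]]  # g/cm^3
            return float(rho * tally.volume_mm3() / 1000.0 / 1000.0)  # kg
        if tally.kind == "voxel_mask":
            mask = tally.mask
        else:
            mask = self.material == tally.region_row
        grams = float(self.density[mask].sum() * self.phantom.voxel_volume_cm3())
        return grams / 1000.0

    def free_path_lengths(
        self, pos, direction, energy_kev, n, rng: np.random.Generator
    ) -> np.ndarray:
        """Distance (mm) to the first real collision for n identical photons
        launched from ``pos`` along ``direction``; escapes give +inf."""
        p = np.tile(np.asarray(pos, dtype=float), (n, 1))
        d = np.tile(np.asarray(direction, dtype=float), (n, 1))
        e = np.full(n, float(energy_kev))
        out = np.full(n, np.inf)
        travelled = np.zeros(n)
        active = np.arange(n)
        while active.size:
            e_idx = self.mxs.energy_index(e[active])
            mu_maj = self.majorant_mm[e_idx]
            s = -np.log(rng.random(active.size)) / mu_maj
            _, t_exit = self._ray_box(p[active], d[active])
            exited = s >= t_exit
            travelled[active] += s
            p[active] += s[:, None] * d[active]
            inside = active[~exited]
            if inside.size:
                mat, rho = self._voxel_lookup(p[inside])
                mu_tot = (
                    self.mxs.mass["total"][mat, self.mxs.energy_index(e[inside])]
                    * rho
                    / 10.0
                )
                mu_maj_i = self.majorant_mm[self.mxs.energy_index(e[inside])]
                real = rng.random(inside.size) * mu_maj_i < mu_tot
                out[inside[real]] = travelled[inside[real]]
                active = inside[~real]
            else:
                active = inside
        return out


def track_photon(
    photon: SourcePhotonBatch,
    phantom: VoxelPhantom,
    mxs: MaterialXS,
    tallies: Sequence[TallySpec],
    rng: np.random.Generator,
    cutoff_kev: float = 1.0,
    kv: float = 120.0,
):
    """Transport a (batch of) photon(s); returns (scores, all_escaped flag)."""
    engine = TransportEngine(phantom, mxs)
    scores = engine.run(photon, tallies, rng, cutoff_kev=cutoff_kev, kv=kv)
    escaped = scores.escaped_kev >= scores.emitted_kev * (1 - 1e-12)
    return scores, escaped


def run_simulation(
    config: RunConfig,
    protocol,
    model,
    phantom: VoxelPhantom,
    tallies: Sequence[TallySpec],
    xs: Optional[AttenuationTable] = None,
    composition: Optional[CompositionTable] = None,
    batch_order: Optional[Sequence[int]] = None,
) -> SimulationResult:
    """Run batched histories and reduce tallies with batch statistics.

    Results are normalized per source photon.  Batches use independent
    streams seeded from (master seed, batch index), and the reduction is
    performed in batch-index order, so results do not depend on the order in
    which batches execute (``batch_order`` exists to exercise exactly that).
    """
    xs = xs or AttenuationTable.load_default()
    composition = composition or CompositionTable.load_default()
    mxs = MaterialXS(composition, xs, max_energy_kev=protocol.kv)
    engine = TransportEngine(phantom, mxs)

    order = list(batch_order) if batch_order is not None else list(range(config.n_batches))
    if sorted(order) != list(range(config.n_batches)):
        raise ConfigurationError("batch_order must be a permutation of the batch indices")
    base = config.n_histories // config.n_batches
    extra = config.n_histories % config.n_batches
    sizes = [base + (1 if i < extra else 0) for i in range(config.n_batches)]

    per_batch = {}
    totals = np.zeros(3)
    for b in order:
        rng = batch_rng(config.master_seed, b)
        photons = emit_photons(protocol, model, rng, sizes[b])
        scores = engine.run(
            photons, tallies, rng, cutoff_kev=config.cutoff_kev, kv=protocol.kv
        )
        per_batch[b] = scores
        totals += (scores.emitted_kev, scores.total_dep_kev, scores.escaped_kev)

    results = {}
    for t in tallies:
        rows = []
        for b in range(config.n_batches):
            scores = per_batch[b]
            if t.score == "energy_deposition":
                mass = engine.tally_mass_kg(t)
                dose_gy = scores.dep_kev[t.name] * KEV_TO_JOULE / mass
                rows.append(dose_gy / sizes[b])
                edges = None
            else:
                flu = scores.flu[t.name] / t.volume_mm3() / sizes[b]
                rows.append(flu)
                edges = scores.flu_edges[t.name]
        results[t.name] = TallyResult(
            name=t.name,
            score=t.score,
            batch_values=np.asarray(rows),
            n_histories=config.n_histories,
            seed=config.master_seed,
            energy_bin_edges=edges,
        )
    return SimulationResult(
        tallies=results,
        emitted_kev=float(totals[0]),
        deposited_kev=float(totals[1]),
        escaped_kev=float(totals[2]),
        config=config,
    )


def fluence_to_kerma(
    result: TallyResult, xs: AttenuationTable, material: str = "air"
) -> TallyResult:
    """Convert a 30-bin energy-fluence tally to air kerma (Gy per photon).

    Bin-center energies feed the mass energy-absorption lookup; the batch
    dimension is carried through so sigma propagates via batch statistics.
    """
    if result.score != "energy_fluence" or result.energy_bin_edges is None:
        raise ConfigurationError("kerma conversion needs an energy-fluence tally")
    edges = result.energy_bin_edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu_en = xs.mass_coefficient(material, centers, channel="en")
    factors = centers * mu_en * _FLUENCE_KERMA_GY
    kerma_batches = result.batch_values @ factors
    return TallyResult(
        name=f"{result.name}_kerma",
        score="air_kerma",
        batch_values=kerma_batches,
        n_histories=result.n_histories,
        seed=result.seed,
    )
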