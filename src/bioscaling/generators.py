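"""Seeded generators for the chain classes the scaling theory describes.

Four static ensembles — stretched rod, freely jointed chain (FJC),
self-avoiding walk (SAW, pivot-sampled on the cubic lattice) and compact
globule — plus a folding-trajectory synthesizer whose per-frame radius of
gyration follows a prescribed alpha(t) schedule.  Together they span the
scaling exponents alpha = 1, 1/2, ~0.588 and ~1/3, so every estimator in
the package can be exercised without external data.

Reproducibility: every generator draws from numpy Generator streams
seeded as SeedSequence((seed, stream_id, index)), so the same
(config, seed) is bit-identical and growing ``n_samples`` never
reshuffles earlier samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .geometry import Conformation, StructureEnsemble
from .scaling import globule_radius, rg_from_alpha

__all__ = [
    "GeneratorConfig",
    "AlphaSchedule",
    "make_stretched",
    "make_fjc",
    "make_saw",
    "make_globule",
    "make_folding_trajectory",
]

# Stream ids keeping the generators' random streams disjoint.
_STREAM_FJC = 0
_STREAM_SAW = 1
_STREAM_GLOBULE = 2
_STREAM_TRAJECTORY = 3


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator settings.

    ``burn_in`` and ``stride`` apply to the Markov-chain (pivot) sampler:
    defaults 10*N and N attempted pivots respectively.
    """

    n_segments: int
    segment_length: float = 1.0
    seed: int = 0
    n_samples: int = 1
    burn_in: int | None = None
    stride: int | None = None

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if (self.burn_in is not None and self.burn_in < 0) or (
            self.stride is not None and self.stride < 0
        ):
            raise ValueError("burn_in and stride must be >= 0")

    @property
    def effective_burn_in(self) -> int:
        return 10 * self.n_segments if self.burn_in is None else self.burn_in

    @property
    def effective_stride(self) -> int:
        stride = self.n_segments if self.stride is None else self.stride
        return max(stride, 1)


@dataclass(frozen=True)
class AlphaSchedule:
    """Prescribed scaling exponent per trajectory frame."""

    frame_times: tuple[float, ...]
    alpha_values: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.frame_times)
        alphas = tuple(float(a) for a in self.alpha_values)
        if len(times) != len(alphas):
            raise ValueError("frame_times and alpha_values must have equal length")
        if not times:
            raise ValueError("schedule must be non-empty")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("frame_times must be non-decreasing")
        if any(a <= 0 or a > 1.25 for a in alphas):
            raise ValueError("alpha values must lie in (0, 1.25]")
        object.__setattr__(self, "frame_times", times)
        object.__setattr__(self, "alpha_values", alphas)

    @classmethod
    def linear(
        cls, alpha_start: float, alpha_end: float, n_frames: int, dt: float = 1.0
    ) -> "AlphaSchedule":
        """Linear alpha ramp over ``n_frames`` frames spaced ``dt`` ps."""
        alphas = np.linspace(alpha_start, alpha_end, n_frames)
        times = np.arange(n_frames) * dt
        return cls(tuple(times), tuple(alphas))

    def __len__(self) -> int:
        return len(self.frame_times)


def _stream(seed: int, stream_id: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream_id, index)))


def make_stretched(n_segments: int, segment_length: float) -> Conformation:
    """Fully stretched chain: N+1 collinear beads spaced a along +x."""
    if n_segments < 1 or segment_length <= 0:
        raise ValueError("require n_segments >= 1 and segment_length > 0")
    coords = np.zeros((n_segments + 1, 3))
    coords[:, 0] = segment_length * np.arange(n_segments + 1)
    return Conformation(coords)


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random directions on the unit sphere."""
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def make_fjc(config: GeneratorConfig) -> StructureEnsemble:
    """Freely jointed chains: N bonds of exact length a, iid directions."""
    n, a = config.n_segments, config.segment_length
    members = []
    for i in range(config.n_samples):
        rng = _stream(config.seed, _STREAM_FJC, i)
        bonds = a * _unit_vectors(rng, n)
        coords = np.vstack([np.zeros(3), np.cumsum(bonds, axis=0)])
        members.append(Conformation(coords))
    return StructureEnsemble(tuple(members), kind="sample_set")


def _octahedral_matrices() -> np.ndarray:
    """The 47 non-identity symmetries of the cubic lattice (signed permutations)."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=np.int64)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if not np.array_equal(m, np.eye(3, dtype=np.int64)):
                mats.append(m)
    return np.stack(mats)


_PIVOT_MATRICES = _octahedral_matrices()


def _lattice_keys(coords: np.ndarray, span: int) -> np.ndarray:
    """Pack integer lattice sites into scalar keys for fast overlap tests."""
    base = 2 * span + 1
    shifted = coords + span
    return (shifted[:, 0] * base + shifted[:, 1]) * base + shifted[:, 2]


def make_saw(config: GeneratorConfig) -> StructureEnsemble:
    """Self-avoiding walks sampled with the pivot algorithm.

    Walks live on the simple cubic lattice with lattice constant equal to
    ``segment_length``; the Markov chain starts from a straight rod,
    proposes a random non-identity octahedral symmetry applied to the
    suffix past a random pivot site, and rejects self-intersecting
    proposals.  States are retained every ``stride`` attempted pivots
    after ``burn_in`` attempts, then scaled to physical units.
    """
    n, a = config.n_segments, config.segment_length
    if n < 2:
        raise ValueError("SAW sampling requires n_segments >= 2")
    rng = _stream(config.seed, _STREAM_SAW)
    walk = np.zeros((n + 1, 3), dtype=np.int64)
    walk[:, 0] = np.arange(n + 1)
    span = n  # coordinates can never leave [-N, N]^3

    burn_in = config.effective_burn_in
    stride = config.effective_stride
    total = burn_in + config.n_samples * stride
    members = []
    n_draws = 0
    while n_draws < total:
        # draw pivot sites and symmetries in blocks to cut Generator overhead
        block = min(4096, total - n_draws)
        sites = rng.integers(1, n, size=block)
        which = rng.integers(0, len(_PIVOT_MATRICES), size=block)
        for site, mi in zip(sites, which):
            pivot = walk[site]
            suffix = (walk[site + 1 :] - pivot) @ _PIVOT_MATRICES[mi].T + pivot
            prefix_keys = _lattice_keys(walk[: site + 1], span)
            suffix_keys = _lattice_keys(suffix, span)
            # a rigid symmetry keeps the suffix internally self-avoiding,
            # so only prefix/suffix overlap must be checked
            if not np.any(np.isin(suffix_keys, prefix_keys, assume_unique=True)):
                walk = np.concatenate([walk[: site + 1], suffix])
            n_draws += 1
            if n_draws > burn_in and (n_draws - burn_in) % stride == 0:
                members.append(Conformation(a * walk.astype(float)))
            if n_draws >= total:
                break
    return StructureEnsemble(tuple(members[: config.n_samples]), kind="sample_set")


# Globule placement limits: per-bead direction retries and total backtracks.
_GLOBULE_TRIES = 80
_GLOBULE_BACKTRACKS = 2000
_GLOBULE_MIN_SEP_FACTOR = 0.8
_GLOBULE_CONFINEMENT_FACTOR = 1.1


def _spiral_globule(n_segments: int, a: float, r_conf: float) -> np.ndarray:
    """Deterministic fallback: beads chained along a space-filling
    spherical spiral, bond length a exact, confined to radius r_conf."""
    def curve(t: float) -> np.ndarray:
        rho = min(r_conf, 0.35 * r_conf * t ** (1.0 / 3.0))
        theta = math.pi / 2.0 * (1.0 + math.sin(0.61 * t))
        phi = t
        return rho * np.array(
            [math.sin(theta) * math.cos(phi),
             math.sin(theta) * math.sin(phi),
             math.cos(theta)]
        )

    coords = [curve(0.0)]
    t = 0.0
    for _ in range(n_segments):
        # march until the chord from the last bead reaches a, then bisect
        prev = coords[-1]
        t_hi = t
        step = 0.05
        while np.linalg.norm(curve(t_hi) - prev) < a:
            t_hi += step
        t_lo = max(t, t_hi - step)
        for _ in range(80):
            mid = 0.5 * (t_lo + t_hi)
            if np.linalg.norm(curve(mid) - prev) < a:
                t_lo = mid
            else:
                t_hi = mid
        t = 0.5 * (t_lo + t_hi)
        coords.append(prev + a * _normalized(curve(t) - prev))
    return np.asarray(coords)


def _normalized(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else np.array([1.0, 0.0, 0.0])


def make_globule(config: GeneratorConfig) -> StructureEnsemble:
    """Compact globules: confined random chains with excluded volume.

    Beads are placed sequentially with exact bond length a, a minimum
    non-bonded separation of 0.8 a, inside a sphere of radius
    1.1 * globule_radius(N, a^3) about the origin.  Placement backtracks
    on dead ends and falls back to a deterministic space-filling spiral
    after a bounded number of restarts; ensemble-mean Rg then scales with
    N to an exponent near 1/3.
    """
    n, a = config.n_segments, config.segment_length
    if n < 2:
        raise ValueError("globule generation requires n_segments >= 2")
    r_conf = _GLOBULE_CONFINEMENT_FACTOR * globule_radius(n, a**3)
    min_sep = _GLOBULE_MIN_SEP_FACTOR * a
    members = []
    for i in range(config.n_samples):
        rng = _stream(config.seed, _STREAM_GLOBULE, i)
        coords = _place_globule(rng, n, a, r_conf, min_sep)
        if coords is None:
            coords = _spiral_globule(n, a, r_conf)
        members.append(Conformation(coords))
    return StructureEnsemble(tuple(members), kind="sample_set")


def _place_globule(
    rng: np.random.Generator, n: int, a: float, r_conf: float, min_sep: float
) -> np.ndarray | None:
    start = rng.uniform(-1.0, 1.0, 3)
    start *= 0.3 * r_conf / max(np.linalg.norm(start), 1e-12)
    coords = [start]
    backtracks = 0
    while len(coords) < n + 1:
        placed = False
        for _ in range(_GLOBULE_TRIES):
            cand = coords[-1] + a * _unit_vectors(rng, 1)[0]
            if np.linalg.norm(cand) > r_conf:
                continue
            if len(coords) > 1:
                d2 = ((np.asarray(coords[:-1]) - cand) ** 2).sum(axis=1)
                if d2.min() < min_sep * min_sep:
                    continue
            coords.append(cand)
            placed = True
            break
        if not placed:
            backtracks += 1
            if backtracks > _GLOBULE_BACKTRACKS:
                return None
            del coords[-1 if len(coords) > 1 else 0 :]
            if not coords:
                coords = [start]
    return np.asarray(coords)


# Folding-trajectory perturbation settings.
_CRANKSHAFT_ANGLE_STD = 0.5  # rad
_DEGENERATE_DISPLACEMENT = 1e-9


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    ux, uy, uz = axis
    c, s = math.cos(angle), math.sin(angle)
    cc = 1.0 - c
    return np.array(
        [
            [c + ux * ux * cc, ux * uy * cc - uz * s, ux * uz * cc + uy * s],
            [uy * ux * cc + uz * s, c + uy * uy * cc, uy * uz * cc - ux * s],
            [uz * ux * cc - uy * s, uz * uy * cc + ux * s, c + uz * uz * cc],
        ]
    )


def _perturb(coords: np.ndarray, rng: np.random.Generator, n_moves: int) -> np.ndarray:
    """Crankshaft moves; degenerate (collinear) picks fall back to a
    small pivot rotation of the chain suffix so stretched chains still
    acquire three-dimensional structure."""
    coords = coords.copy()
    n = len(coords)
    for _ in range(n_moves):
        i = int(rng.integers(0, n - 2))
        k = int(rng.integers(i + 2, n))
        angle = rng.normal(0.0, _CRANKSHAFT_ANGLE_STD)
        axis = coords[k] - coords[i]
        norm = np.linalg.norm(axis)
        moved = False
        if norm > _DEGENERATE_DISPLACEMENT:
            rot = _rotation_about_axis(axis / norm, angle)
            interior = coords[i + 1 : k]
            new_interior = (interior - coords[i]) @ rot.T + coords[i]
            if np.abs(new_interior - interior).max() > _DEGENERATE_DISPLACEMENT:
                coords[i + 1 : k] = new_interior
                moved = True
        if not moved:  # collinear section: pivot the suffix instead
            axis = _unit_vectors(rng, 1)[0]
            rot = _rotation_about_axis(axis, angle)
            coords[i + 1 :] = (coords[i + 1 :] - coords[i]) @ rot.T + coords[i]
    return coords


def make_folding_trajectory(
    config: GeneratorConfig, schedule: AlphaSchedule
) -> StructureEnsemble:
    """Synthesize a folding trajectory following an alpha(t) schedule.

    Starting from the stretched rod, each frame applies seeded crankshaft
    perturbations to the previous frame and then rescales radially about
    the centroid so the frame's radius of gyration matches the scaling
    model's prediction for the scheduled alpha.  Bond lengths are not
    preserved by the rescaling; only Rg enters the exponent estimator.
    """
    n, a = config.n_segments, config.segment_length
    if n < 2:
        raise ValueError("trajectory synthesis requires n_segments >= 2")
    coords = make_stretched(n, a).coordinates
    members = []
    for j, (t, alpha) in enumerate(zip(schedule.frame_times, schedule.alpha_values)):
        rng = _stream(config.seed, _STREAM_TRAJECTORY, j)
        coords = _perturb(coords, rng, n_moves=max(2, n // 2))
        target = rg_from_alpha(alpha, n, a)
        centroid = coords.mean(axis=0)
        current = float(np.sqrt(((coords - centroid) ** 2).sum(axis=1).mean()))
        coords = centroid + (coords - centroid) * (target / current)
        members.append(Conformation(coords, frame_time=float(t)))
    return StructureEnsemble(tuple(members), kind="trajectory")
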