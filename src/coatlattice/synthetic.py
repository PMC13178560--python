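"""Ground-truthed synthetic tubular coat lattices.

Emulates the AP3:ARF1 membrane coat: a one-start pseudo-helical lattice of
arch-shaped adaptor complexes wrapped on a ~40-nm-diameter coat cylinder
around a ~20-nm membrane tube, with ~6.05 complexes per turn and a 7.5-nm
pitch.  Because units-per-turn is non-integer the six stripes (rows of
arches stacked along the tube axis, lattice step n -> n+6) spiral slowly
around the tube.  Each stripe carries a direction bit; antiparallel stripes
(bit = 1) have all members rotated 180 degrees in-plane about the outward
normal.  Every complex carries two ARF1 sites (one on the beta3 end, one on
the delta end of the arch); sites of circumferentially adjacent complexes
meet between stripes as C2 ARF1 dimers, giving the 1:2 AP3:ARF1
stoichiometry and the three linkage classes:

* parallel neighbor stripes (equal bits)    -> heterotypic beta3-delta,
* antiparallel, bits (0, 1) across +theta   -> homotypic beta3-beta3,
* antiparallel, bits (1, 0) across +theta   -> homotypic delta-delta.

Ground truth (noise-free poses, stripe ids, direction bits, linkage classes
and dimer midpoints) is recorded before noise is applied, so every
downstream stage can be scored against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError
from .geometry import eulers_to_matrices, make_table, matrix_to_euler

N_STRIPES = 6

#: Body-frame offsets (A) of the two ARF1 sites from the complex origin.
#: +x is the delta -> beta3 arch axis, -z points toward the membrane.
ARF1_BODY_OFFSETS = {
    "b3": np.array([100.0, 0.0, -80.0]),
    "d": np.array([-100.0, 0.0, -80.0]),
}

#: Max site-site distance for geometric dimer pairing (A).  At the preset
#: geometry adjacent-stripe partner sites sit ~56 A apart and the next
#: nearest inter-stripe candidate is ~105 A, so pairing is unambiguous.
DIMER_PAIR_RADIUS_A = 80.0


@dataclass(frozen=True)
class LatticeConfig:
    """Generator parameters for one synthetic coat tube."""

    preset: str = "ap3_arf1"
    coat_radius_A: float = 200.0
    membrane_radius_A: float = 100.0
    twist_deg: float = 360.0 / 6.05  # 59.5041 deg/subunit, right-handed
    rise_A: float = 75.0 / 6.05  # 12.3967 A/subunit -> 7.5 nm pitch
    n_turns: float = 10.0
    stripe_direction_bits: tuple | None = None
    flip_probability: float = 0.5
    pos_noise_sigma_A: float = 0.0
    ang_noise_sigma_deg: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_turns < 2:
            raise ConfigError("n_turns must be >= 2")
        if not (self.coat_radius_A > self.membrane_radius_A > 0):
            raise ConfigError("need coat_radius > membrane_radius > 0")
        if not (0.0 <= self.flip_probability <= 1.0):
            raise ConfigError("flip_probability must be in [0, 1]")
        if self.pos_noise_sigma_A < 0 or self.ang_noise_sigma_deg < 0:
            raise ConfigError("noise sigmas must be non-negative")
        if self.rise_A <= 0 or self.twist_deg == 0:
            raise ConfigError("rise must be positive and twist nonzero")
        if self.stripe_direction_bits is not None and (
            len(self.stripe_direction_bits) != N_STRIPES
            or any(b not in (0, 1) for b in self.stripe_direction_bits)
        ):
            raise ConfigError("stripe_direction_bits must be 6 values in {0, 1}")

    @property
    def units_per_turn(self) -> float:
        return 360.0 / abs(self.twist_deg)

    @property
    def n_particles(self) -> int:
        return int(np.floor(self.n_turns * self.units_per_turn)) + 1


_PRESETS = {"ap3_arf1": LatticeConfig()}


def preset(name: str = "ap3_arf1", **overrides) -> LatticeConfig:
    """Return a named preset configuration, optionally overridden."""
    if name not in _PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return replace(_PRESETS[name], preset=name, **overrides)


@dataclass
class GroundTruth:
    """Per-particle, per-site and per-linkage truth for one generated tube."""

    config: LatticeConfig
    particles: pd.DataFrame  # particle_id, stripe_id, direction_bit, true pose
    arf1_sites: pd.DataFrame  # site_id, particle_id, site_type, x/y/z (A)
    linkages: pd.DataFrame  # id_a, id_b, boundary, link_class, parallel, midpoint
    boundary_classes: list = field(default_factory=list)  # class per cyclic boundary


def _linkage_class(bit_lower: int, bit_upper: int) -> tuple:
    """Truth rule for the boundary between stripe s (lower theta) and s+1.

    Returns (class, parallel, side_lower, side_upper).  With bit 0 the body
    +x (delta -> beta3) axis points toward +theta, so the site a complex
    presents to its +theta neighbor is beta3 when its bit is 0, delta when
    flipped; the -theta-facing site is the opposite.
    """
    side_lower = "b3" if bit_lower == 0 else "d"
    side_upper = "d" if bit_upper == 0 else "b3"
    parallel = bit_lower == bit_upper
    if side_lower == side_upper:
        cls = "bb" if side_lower == "b3" else "dd"
    else:
        cls = "bd"
    return cls, parallel, side_lower, side_upper


def simulate_lattice(config: LatticeConfig) -> tuple:
    """Generate one synthetic coat tube.

    Returns ``(table, truth)``: a canonical particle table (noise applied)
    and the :class:`GroundTruth` recorded before noise.  Particle k sits at
    azimuth ``k * twist`` and height ``k * rise`` on the coat cylinder with
    stripe id ``k mod 6``; members of flipped stripes are rotated 180
    degrees about the body z (outward normal).  Deterministic for a fixed
    ``rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_particles
    k = np.arange(n)
    theta = np.deg2rad(config.twist_deg) * k
    r = config.coat_radius_A
    pos = np.stack([r * np.cos(theta), r * np.sin(theta), config.rise_A * k], axis=1)

    stripe_id = k % N_STRIPES
    if config.stripe_direction_bits is not None:
        bits = np.asarray(config.stripe_direction_bits, dtype=int)
    else:
        bits = (rng.random(N_STRIPES) < config.flip_probability).astype(int)
    flipped = bits[stripe_id].astype(bool)

    # body axes in the lab frame: x = +theta tangent, y = tube axis, z = outward
    ct, st = np.cos(theta), np.sin(theta)
    zero = np.zeros(n)
    bx = np.stack([-st, ct, zero], axis=1)
    by = np.stack([zero, zero, np.ones(n)], axis=1)
    bz = np.stack([ct, st, zero], axis=1)
    bx[flipped] *= -1.0  # 180 deg about body z
    by[flipped] *= -1.0
    rots = np.stack([bx, by, bz], axis=2)  # columns are body axes
    eulers = np.array([matrix_to_euler(m) for m in rots])

    truth_particles = pd.DataFrame(
        {
            "particle_id": k,
            "stripe_id": stripe_id,
            "direction_bit": bits[stripe_id],
            "x_A": pos[:, 0],
            "y_A": pos[:, 1],
            "z_A": pos[:, 2],
            "rot_deg": eulers[:, 0],
            "tilt_deg": eulers[:, 1],
            "psi_deg": eulers[:, 2],
        }
    )
    sites = _true_arf1_sites(truth_particles, rots)
    linkages, boundary_classes = _true_linkages(bits, n, sites)
    truth = GroundTruth(
        config=config,
        particles=truth_particles,
        arf1_sites=sites,
        linkages=linkages,
        boundary_classes=boundary_classes,
    )

    # noise, applied after truth is recorded (draw order is fixed so the same
    # seed yields the same lattice at any sigma)
    dpos = rng.normal(0.0, 1.0, size=(n, 3))
    axes = rng.normal(0.0, 1.0, size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = np.abs(rng.normal(0.0, 1.0, size=n))

    noisy_pos = pos + config.pos_noise_sigma_A * dpos
    if config.ang_noise_sigma_deg > 0:
        ang = np.deg2rad(config.ang_noise_sigma_deg) * angles
        noisy_rots = np.array(
            [rots[i] @ _axis_angle(axes[i], ang[i]) for i in range(n)]
        )
        noisy_eulers = np.array([matrix_to_euler(m) for m in noisy_rots])
    else:
        noisy_eulers = eulers

    if config.pos_noise_sigma_A > 0:
        mag = np.linalg.norm(config.pos_noise_sigma_A * dpos, axis=1)
        scores = 1.0 - mag / (mag.max() + 1e-12)
    else:
        scores = np.ones(n)

    table = make_table(
        noisy_pos,
        noisy_eulers,
        particle_ids=k,
        tomo_id="synthetic",
        tube_id=f"{config.preset}_seed{config.rng_seed}",
        scores=scores,
    )
    return table, truth


def _axis_angle(axis, angle):
    axis = np.asarray(axis, float)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _true_arf1_sites(truth_particles: pd.DataFrame, rots: np.ndarray) -> pd.DataFrame:
    pos = truth_particles[["x_A", "y_A", "z_A"]].to_numpy()
    rows = []
    sid = 0
    for i in range(len(truth_particles)):
        for site_type, off in ARF1_BODY_OFFSETS.items():
            p = pos[i] + rots[i] @ off
            rows.append(
                (
                    sid,
                    int(truth_particles["particle_id"].iloc[i]),
                    int(truth_particles["stripe_id"].iloc[i]),
                    site_type,
                    p[0],
                    p[1],
                    p[2],
                )
            )
            sid += 1
    return pd.DataFrame(
        rows,
        columns=["site_id", "particle_id", "stripe_id", "site_type", "x_A", "y_A", "z_A"],
    )


def _true_linkages(bits, n, sites: pd.DataFrame):
    """One linkage per one-start step k -> k+1, classed by the bit rule."""
    site_lookup = {
        (int(r.particle_id), r.site_type): np.array([r.x_A, r.y_A, r.z_A])
        for r in sites.itertuples()
    }
    rows = []
    for k in range(n - 1):
        s = k % N_STRIPES
        cls, parallel, side_lo, side_up = _linkage_class(bits[s], bits[(s + 1) % N_STRIPES])
        p_lo = site_lookup[(k, side_lo)]
        p_up = site_lookup[(k + 1, side_up)]
        mid = 0.5 * (p_lo + p_up)
        rows.append((k, k + 1, s, cls, parallel, side_lo, side_up, *mid))
    linkages = pd.DataFrame(
        rows,
        columns=[
            "id_a",
            "id_b",
            "boundary",
            "link_class",
            "parallel",
            "side_a",
            "side_b",
            "mid_x_A",
            "mid_y_A",
            "mid_z_A",
        ],
    )
    boundary_classes = [
        _linkage_class(bits[s], bits[(s + 1) % N_STRIPES])[0] for s in range(N_STRIPES)
    ]
    return linkages, boundary_classes


# --------------------------------------------------------------------------
# ARF1 site emission with geometric dimer pairing
# --------------------------------------------------------------------------


def emit_arf1_sites(
    truth: GroundTruth, *, pair_radius_A: float = DIMER_PAIR_RADIUS_A
) -> pd.DataFrame:
    """Labeled ARF1 site table with geometric dimer pairing.

    Pairs inter-stripe site pairs closer than ``pair_radius_A`` greedily by
    ascending distance (each site joins at most one dimer) and assigns a
    ``dimer_id`` (-1 = unpaired).  This pairing is purely geometric and is
    independent of the generator's rule-based linkage truth, so the two can
    cross-check each other.  Warns if more than 5% of interior sites stay
    unpaired.
    """
    sites = truth.arf1_sites.copy()
    xyz = sites[["x_A", "y_A", "z_A"]].to_numpy()
    stripe = sites["stripe_id"].to_numpy()
    tree = cKDTree(xyz)
    cand = []
    for i, j in tree.query_pairs(pair_radius_A):
        if stripe[i] == stripe[j]:
            continue
        cand.append((float(np.linalg.norm(xyz[i] - xyz[j])), i, j))
    cand.sort()
    dimer = np.full(len(sites), -1, dtype=int)
    next_id = 0
    for _, i, j in cand:
        if dimer[i] == -1 and dimer[j] == -1:
            dimer[i] = dimer[j] = next_id
            next_id += 1
    sites["dimer_id"] = dimer

    n = truth.config.n_particles
    interior = (sites["particle_id"] >= N_STRIPES) & (
        sites["particle_id"] < n - N_STRIPES
    )
    n_int = int(interior.sum())
    if n_int and (dimer[interior.to_numpy()] == -1).sum() / n_int > 0.05:
        warnings.warn(
            "more than 5% of interior ARF1 sites are unpaired; "
            "lattice geometry and pairing radius may be inconsistent",
            stacklevel=2,
        )
    return sites


# --------------------------------------------------------------------------
# membrane points and oversampled seeds
# --------------------------------------------------------------------------


def emit_membrane_points(
    config: LatticeConfig,
    *,
    density_per_nm2: float | None = None,
    n_points: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Uniform random points on the membrane cylinder under the lattice.

    Give either a surface density (points / nm^2) or an exact count.  The
    axial span matches the lattice extent.  Seeded (default: derived from
    the config seed).
    """
    config.validate()
    length = (config.n_particles - 1) * config.rise_A
    r = config.membrane_radius_A
    if n_points is None:
        if density_per_nm2 is None or density_per_nm2 <= 0:
            raise ConfigError("need density_per_nm2 > 0 or an explicit n_points")
        area_nm2 = (2 * np.pi * r / 10.0) * (length / 10.0)
        n_points = int(round(density_per_nm2 * area_nm2))
    rng = np.random.default_rng(config.rng_seed + 7919 if seed is None else seed)
    theta = rng.uniform(-np.pi, np.pi, n_points)
    z = rng.uniform(0.0, length, n_points)
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def simulate_oversampled_seeds(config: LatticeConfig, spacing_A: float):
    """Ring-seeded oversampled table plus nearest-true-particle assignment.

    Builds a straight tube annotation matching the lattice extent at the
    coat radius, seeds it with :func:`coatlattice.seeding.seed_surface`, and
    maps every seed to its nearest true lattice position (index into the
    truth table).  Used to exercise duplicate-removal cleaning.
    """
    from .seeding import build_annotation, seed_surface  # deferred: avoid cycle

    config.validate()
    table, truth = simulate_lattice(replace(config, pos_noise_sigma_A=0.0,
                                            ang_noise_sigma_deg=0.0))
    length = (config.n_particles - 1) * config.rise_A
    ann = build_annotation(
        [[0.0, 0.0, 0.0], [0.0, 0.0, max(length, 1.0)]],
        radius_A=config.coat_radius_A,
        tube_id=f"{config.preset}_seeds",
    )
    seeds = seed_surface(ann, spacing_A=spacing_A)
    true_pos = truth.particles[["x_A", "y_A", "z_A"]].to_numpy()
    tree = cKDTree(true_pos)
    _, nearest = tree.query(seeds[["x_A", "y_A", "z_A"]].to_numpy())
    return seeds, nearest
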