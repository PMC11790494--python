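"""Hard-rectangle Monte Carlo on a periodic plane with local order metrics.

Membrane-bound DNA rafts are modelled as hard rectangles (no overlap,
separating-axis test) on a flat periodic square box — the vesicle radius is
orders of magnitude above the raft scale, so curvature is negligible over an
ordering domain.  Metropolis single-particle translation/rotation moves
stand in for Brownian dynamics: the steady-state ordering, not kinetics, is
the quantity of interest.

The in-place shape transformation interpolates every particle's half-length
and half-width from the near-square (70.8 x 55 nm, aspect ratio ~1.3) to
the elongated (190 x 20 nm, aspect ratio ~9.5) conformation in small
substeps, relaxing with MC sweeps between substeps and retrying particles
whose shape update would create an overlap — the hard-particle analogue of
strand-displacement reconfiguration at fixed surface coverage.

Order is quantified over neighbour pairs (centre distance below a radius):
nematic S2 = <cos 2 dtheta>, tetratic S4 = <cos 4 dtheta>, the fraction of
particles whose local S4 exceeds a cutoff (0.7), and connected-cluster sizes
among those ordered particles.  The default neighbour radius is half the
mean centre-to-centre spacing (0.5 box/sqrt(n)), i.e. the near-contact
shell: hard-core alignment of elongated particles lives at contact, and a
radius of the order of the particle long axis averages it away against the
many uncorrelated mid-range pairs at the coverages studied here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "RaftConfig",
    "MoveSettings",
    "OrderMetrics",
    "MCResult",
    "TransformReport",
    "OrderingError",
    "SDR_DIMS_NM",
    "EDR_DIMS_NM",
    "init_config",
    "run_mc",
    "transform_shapes",
    "order_metrics",
]

#: Raft dimensions (length, width) in nm for the two conformations.
SDR_DIMS_NM = (70.8, 55.0)
EDR_DIMS_NM = (190.0, 20.0)


class OrderingError(RuntimeError):
    """Raised when insertion or shape transformation cannot proceed."""


@dataclass
class RaftConfig:
    """Positions/orientations/half-dimensions of hard rectangles in a periodic box."""

    box_nm: float
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    half_length: np.ndarray
    half_width: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "theta", "half_length", "half_width"):
            if len(getattr(self, name)) != n:
                raise ValueError("all particle arrays must have equal length")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def coverage(self) -> float:
        """phi = sum of particle areas / box area."""
        return float(np.sum(4.0 * self.half_length * self.half_width) / self.box_nm**2)

    def copy(self) -> "RaftConfig":
        return RaftConfig(
            box_nm=self.box_nm,
            x=self.x.copy(),
            y=self.y.copy(),
            theta=self.theta.copy(),
            half_length=self.half_length.copy(),
            half_width=self.half_width.copy(),
        )

    def is_overlap_free(self) -> bool:
        return not _has_any_overlap(self.x, self.y, self.theta, self.half_length, self.half_width, self.box_nm)


@dataclass(frozen=True)
class MoveSettings:
    """Metropolis move amplitudes and budget; identical seed => identical trajectory."""

    translation_step_nm: float = 5.0
    rotation_step_rad: float = 0.2
    sweeps: int = 1000
    seed: int = 0
    sample_every: int = 0  # 0: keep only the final frame

    def __post_init__(self) -> None:
        if self.translation_step_nm <= 0 or self.rotation_step_rad <= 0:
            raise ValueError("move steps must be positive")
        if self.sweeps < 0:
            raise ValueError("sweeps must be >= 0")


@dataclass(frozen=True)
class OrderMetrics:
    """Pair-orientation order over neighbour pairs plus cluster statistics."""

    neighbor_radius_nm: float
    s2: float
    s4: float
    local_s4: np.ndarray  # per particle; NaN when fewer than min_neighbors
    ordered_fraction: float
    mean_cluster_size: float
    n_pairs: int


@dataclass
class MCResult:
    """Trajectory (sampled configurations) and the overall acceptance rate."""

    trajectory: list[RaftConfig]
    acceptance_rate: float

    @property
    def final(self) -> RaftConfig:
        return self.trajectory[-1]


@dataclass
class TransformReport:
    """Outcome of an in-place shape transformation."""

    config: RaftConfig
    n_substeps: int
    total_retries: int


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _rects_overlap(dx, dy, th1, hl1, hw1, th2, hl2, hw2):  # pragma: no cover - jit
    """Separating-axis test for two oriented rectangles at offset (dx, dy)."""
    c1, s1 = np.cos(th1), np.sin(th1)
    c2, s2 = np.cos(th2), np.sin(th2)
    # axes: (c1,s1),(−s1,c1),(c2,s2),(−s2,c2)
    for k in range(4):
        if k == 0:
            ax, ay = c1, s1
        elif k == 1:
            ax, ay = -s1, c1
        elif k == 2:
            ax, ay = c2, s2
        else:
            ax, ay = -s2, c2
        r1 = hl1 * abs(ax * c1 + ay * s1) + hw1 * abs(-ax * s1 + ay * c1)
        r2 = hl2 * abs(ax * c2 + ay * s2) + hw2 * abs(-ax * s2 + ay * c2)
        dist = abs(dx * ax + dy * ay)
        if dist > r1 + r2:
            return False
    return True


@njit(cache=True)
def _overlaps_any(i, xi, yi, thi, hli, hwi, x, y, theta, hl, hw, box):  # pragma: no cover - jit
    """True when particle state (xi, yi, thi, hli, hwi) overlaps any j != i."""
    n = x.shape[0]
    ri = np.sqrt(hli * hli + hwi * hwi)
    for j in range(n):
        if j == i:
            continue
        dx = x[j] - xi
        dy = y[j] - yi
        dx -= box * np.rint(dx / box)
        dy -= box * np.rint(dy / box)
        rj = np.sqrt(hl[j] * hl[j] + hw[j] * hw[j])
        if dx * dx + dy * dy > (ri + rj) * (ri + rj):
            continue
        if _rects_overlap(dx, dy, thi, hli, hwi, theta[j], hl[j], hw[j]):
            return True
    return False


@njit(cache=True)
def _has_any_overlap(x, y, theta, hl, hw, box):  # pragma: no cover - jit
    n = x.shape[0]
    for i in range(n - 1):
        ri = np.sqrt(hl[i] ** 2 + hw[i] ** 2)
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            rj = np.sqrt(hl[j] ** 2 + hw[j] ** 2)
            if dx * dx + dy * dy > (ri + rj) * (ri + rj):
                continue
            if _rects_overlap(dx, dy, theta[i], hl[i], hw[i], theta[j], hl[j], hw[j]):
                return True
    return False


@njit(cache=True)
def _mc_sweeps(x, y, theta, hl, hw, box, n_sweeps, tstep, rstep, seed):  # pragma: no cover - jit
    """In-place Metropolis sweeps; returns (accepted, attempted)."""
    np.random.seed(seed)
    n = x.shape[0]
    accepted = 0
    attempted = 0
    for _ in range(n_sweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            xi = x[i] + (np.random.random() * 2.0 - 1.0) * tstep
            yi = y[i] + (np.random.random() * 2.0 - 1.0) * tstep
            thi = theta[i] + (np.random.random() * 2.0 - 1.0) * rstep
            xi -= box * np.floor(xi / box)
            yi -= box * np.floor(yi / box)
            attempted += 1
            if not _overlaps_any(i, xi, yi, thi, hl[i], hw[i], x, y, theta, hl, hw, box):
                x[i] = xi
                y[i] = yi
                theta[i] = thi
                accepted += 1
    return accepted, attempted


@njit(cache=True)
def _rsa_fill(n, hl, hw, box, seed, max_attempts):  # pragma: no cover - jit
    """Random sequential insertion of n identical rectangles; -1 on failure."""
    np.random.seed(seed)
    x = np.empty(n)
    y = np.empty(n)
    theta = np.empty(n)
    hls = np.full(n, hl)
    hws = np.full(n, hw)
    placed = 0
    attempts = 0
    while placed < n:
        if attempts >= max_attempts:
            return x, y, theta, -1
        xi = np.random.random() * box
        yi = np.random.random() * box
        thi = np.random.random() * np.pi
        attempts += 1
        if placed == 0 or not _overlaps_any(
            placed, xi, yi, thi, hl, hw, x[:placed + 1], y[:placed + 1], theta[:placed + 1], hls[:placed + 1], hws[:placed + 1], box
        ):
            x[placed] = xi
            y[placed] = yi
            theta[placed] = thi
            placed += 1
    return x, y, theta, placed


# ---------------------------------------------------------------------------
# public operations


def init_config(
    n: int,
    dims_nm: tuple[float, float] = SDR_DIMS_NM,
    box_nm: float | None = None,
    coverage: float | None = None,
    seed: int = 0,
    max_attempts_per_particle: int = 20000,
) -> RaftConfig:
    """Overlap-free random configuration by random sequential insertion.

    Give either ``box_nm`` or a target ``coverage`` (the box is then sized
    so n particles reach it).  Requested coverages beyond the insertion
    regime (phi <= 0.3 for these shapes) fail with a suggestion to lower phi.
    """
    length, width = dims_nm
    if length <= 0 or width <= 0 or n < 1:
        raise ValueError("need positive dimensions and n >= 1")
    area = length * width
    if box_nm is None:
        if coverage is None:
            raise ValueError("give either box_nm or coverage")
        if coverage <= 0:
            raise ValueError("coverage must be positive")
        box_nm = float(np.sqrt(n * area / coverage))
    phi = n * area / box_nm**2
    if phi > 0.55:
        raise OrderingError(
            f"requested coverage {phi:.2f} is beyond random insertion; lower phi"
        )
    x, y, theta, status = _rsa_fill(
        n, length / 2.0, width / 2.0, float(box_nm), int(seed), int(max_attempts_per_particle) * n
    )
    if status < 0:
        raise OrderingError(
            f"random sequential insertion failed at coverage {phi:.2f}; lower phi or enlarge the box"
        )
    return RaftConfig(
        box_nm=float(box_nm),
        x=x,
        y=y,
        theta=theta,
        half_length=np.full(n, length / 2.0),
        half_width=np.full(n, width / 2.0),
    )


def run_mc(config: RaftConfig, moves: MoveSettings) -> MCResult:
    """Metropolis hard-core dynamics; every emitted frame is overlap-free.

    With ``sample_every > 0`` intermediate configurations are recorded every
    that many sweeps; the initial configuration is always frame 0.
    """
    cfg = config.copy()
    trajectory = [config.copy()]
    accepted = attempted = 0
    if moves.sweeps > 0:
        chunk = moves.sample_every if moves.sample_every > 0 else moves.sweeps
        done = 0
        k = 0
        while done < moves.sweeps:
            todo = min(chunk, moves.sweeps - done)
            a, t = _mc_sweeps(
                cfg.x, cfg.y, cfg.theta, cfg.half_length, cfg.half_width,
                cfg.box_nm, todo, moves.translation_step_nm, moves.rotation_step_rad,
                (moves.seed + 977 * k) % 2**31,
            )
            accepted += a
            attempted += t
            done += todo
            k += 1
            if moves.sample_every > 0 or done == moves.sweeps:
                trajectory.append(cfg.copy())
    rate = accepted / attempted if attempted else 0.0
    return MCResult(trajectory=trajectory, acceptance_rate=float(rate))


def transform_shapes(
    config: RaftConfig,
    new_dims_nm: tuple[float, float],
    n_substeps: int = 20,
    relax: MoveSettings | None = None,
    max_retries: int = 50,
) -> TransformReport:
    """Interpolate all particles from their current dims to ``new_dims_nm``.

    The half-length is interpolated linearly and the half-width follows a
    linearly interpolated particle area, keeping the per-substep area change
    well under the 10% precondition.  At each substep every particle's shape
    update is attempted; particles whose new shape would overlap keep the
    old shape, the configuration is relaxed with MC sweeps, and the update
    is retried (up to ``max_retries`` relaxation rounds per substep).

    Raises
    ------
    OrderingError
        When particles remain stuck after the retry budget (naming them) or
        a substep would change the area by more than 10%.
    """
    relax = relax or MoveSettings(sweeps=50, seed=12345)
    cfg = config.copy()
    hl0, hw0 = float(cfg.half_length[0]), float(cfg.half_width[0])
    if not (np.allclose(cfg.half_length, hl0) and np.allclose(cfg.half_width, hw0)):
        raise ValueError("transform_shapes expects identical particle dimensions")
    hl1, hw1 = new_dims_nm[0] / 2.0, new_dims_nm[1] / 2.0
    a0, a1 = hl0 * hw0, hl1 * hw1

    fracs = np.linspace(0.0, 1.0, n_substeps + 1)[1:]
    areas = a0 + fracs * (a1 - a0)
    area_prev = a0
    for a in areas:
        if abs(a - area_prev) / area_prev > 0.10:
            raise OrderingError("per-substep area change exceeds 10%; increase n_substeps")
        area_prev = a

    total_retries = 0
    for step, f in enumerate(fracs):
        hl_t = hl0 + f * (hl1 - hl0)
        hw_t = (a0 + f * (a1 - a0)) / hl_t
        pending = np.arange(cfg.n)
        for attempt in range(max_retries + 1):
            still = []
            for i in pending:
                old_hl, old_hw = cfg.half_length[i], cfg.half_width[i]
                if _overlaps_any(
                    i, cfg.x[i], cfg.y[i], cfg.theta[i], hl_t, hw_t,
                    cfg.x, cfg.y, cfg.theta, cfg.half_length, cfg.half_width, cfg.box_nm,
                ):
                    still.append(i)
                else:
                    cfg.half_length[i] = hl_t
                    cfg.half_width[i] = hw_t
            pending = np.array(still, dtype=int)
            if pending.size == 0:
                break
            total_retries += 1
            _mc_sweeps(
                cfg.x, cfg.y, cfg.theta, cfg.half_length, cfg.half_width, cfg.box_nm,
                relax.sweeps, relax.translation_step_nm, relax.rotation_step_rad,
                (relax.seed + 1009 * (step * (max_retries + 1) + attempt)) % 2**31,
            )
        if pending.size > 0:
            raise OrderingError(
                f"substep {step}: particles {pending.tolist()} stuck after {max_retries} retries"
            )
        if relax.sweeps > 0:
            _mc_sweeps(
                cfg.x, cfg.y, cfg.theta, cfg.half_length, cfg.half_width, cfg.box_nm,
                relax.sweeps, relax.translation_step_nm, relax.rotation_step_rad,
                (relax.seed + 7919 * step) % 2**31,
            )
    return TransformReport(config=cfg, n_substeps=n_substeps, total_retries=total_retries)


def order_metrics(
    config: RaftConfig,
    neighbor_radius_nm: float | None = None,
    s4_cutoff: float = 0.7,
    min_neighbors: int = 1,
) -> OrderMetrics:
    """Local nematic/tetratic order over near-contact neighbour pairs.

    ``neighbor_radius_nm`` defaults to half the mean centre-to-centre
    spacing, ``0.5 * box / sqrt(n)``: only pairs in the contact shell count
    as neighbours, which is where hard-core alignment is expressed.  The
    local S4 of a particle is the mean cos(4 dtheta) over its neighbours and
    is scored against ``s4_cutoff`` when the particle has at least
    ``min_neighbors`` neighbours; particles with none are unordered.
    Cluster sizes are connected components of the neighbour graph restricted
    to ordered particles.
    """
    if config.n < 2:
        raise ValueError("order metrics need at least 2 particles")
    if neighbor_radius_nm is None:
        neighbor_radius_nm = 0.5 * config.box_nm / np.sqrt(config.n)
    min_width = float(2.0 * config.half_width.min())
    if neighbor_radius_nm < min_width:
        warnings.warn(
            "neighbor radius is below the side-by-side contact distance; pair statistics may be empty",
            stacklevel=2,
        )

    dx = config.x[:, None] - config.x[None, :]
    dy = config.y[:, None] - config.y[None, :]
    dx -= config.box_nm * np.rint(dx / config.box_nm)
    dy -= config.box_nm * np.rint(dy / config.box_nm)
    dist = np.hypot(dx, dy)
    iu = np.triu_indices(config.n, k=1)
    pair_mask = dist[iu] < neighbor_radius_nm
    i_idx, j_idx = iu[0][pair_mask], iu[1][pair_mask]
    n_pairs = int(i_idx.size)

    if n_pairs == 0:
        local = np.full(config.n, np.nan)
        return OrderMetrics(
            neighbor_radius_nm=float(neighbor_radius_nm), s2=0.0, s4=0.0,
            local_s4=local, ordered_fraction=0.0, mean_cluster_size=0.0, n_pairs=0,
        )

    dtheta = config.theta[i_idx] - config.theta[j_idx]
    c2, c4 = np.cos(2.0 * dtheta), np.cos(4.0 * dtheta)
    s2, s4 = float(c2.mean()), float(c4.mean())

    sums = np.zeros(config.n)
    counts = np.zeros(config.n, dtype=int)
    np.add.at(sums, i_idx, c4)
    np.add.at(sums, j_idx, c4)
    np.add.at(counts, i_idx, 1)
    np.add.at(counts, j_idx, 1)
    with np.errstate(invalid="ignore"):
        local = np.where(counts >= min_neighbors, sums / np.maximum(counts, 1), np.nan)
    ordered = np.nan_to_num(local, nan=-np.inf) > s4_cutoff
    ordered_fraction = float(ordered.mean())

    mean_cluster = 0.0
    if ordered.any():
        keep = ordered[i_idx] & ordered[j_idx]
        adj = coo_matrix(
            (np.ones(keep.sum()), (i_idx[keep], j_idx[keep])), shape=(config.n, config.n)
        )
        n_comp, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels[ordered], minlength=n_comp)
        sizes = sizes[sizes > 0]
        mean_cluster = float(sizes.mean()) if sizes.size else 0.0

    return OrderMetrics(
        neighbor_radius_nm=float(neighbor_radius_nm),
        s2=s2,
        s4=s4,
        local_s4=local,
        ordered_fraction=ordered_fraction,
        mean_cluster_size=mean_cluster,
        n_pairs=n_pairs,
    )
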