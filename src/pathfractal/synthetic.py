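"""Synthetic trajectories and a simulated thermal-stress experiment.

Two families of generators live here:

* **Canonical curves** with known dimension (line, circle, Koch curve,
  Hilbert curve) used to validate the estimators against analytic anchors:
  a straight line has D = 1, the Koch curve D = log 4 / log 3 ≈ 1.2619 and
  a high-order Hilbert curve approaches the space-filling limit D = 2.
* **Stochastic walks** — a correlated random walk (CRW) whose turning
  angles are wrapped-normal with concentration ``kappa`` (large kappa →
  straight, directional paths; kappa = 0 → uniform turning, maximally
  tortuous) and a truncated-power-law Lévy walk — plus
  :func:`simulate_experiment`, which builds a full two-family ×
  three-treatment design with site-level random intercepts, a warming
  effect that straightens paths, and microhabitat-dependent buffering of
  that effect in structurally complex habitats.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .metrics import FAMILIES, MICROHABITATS, TREATMENTS
from .trajectory import Trajectory

#: microhabitats treated as structurally complex (buffering thermal effects)
COMPLEX_MICROHABITATS = frozenset({"boulders", "macrophytes"})

#: observed sampling proportions of specimens across microhabitats
DEFAULT_MICROHABITAT_PROBS = {
    "boulders": 0.5076,
    "gravels": 0.0344,
    "macrophytes": 0.1374,
    "detritus": 0.0229,
    "pebbles": 0.1374,
    "sand": 0.1603,
}


def _traj(specimen_id, x, y, fps=25.0, px_per_cm=None) -> Trajectory:
    n = len(x)
    return Trajectory(
        specimen_id=specimen_id,
        frames=np.arange(n, dtype=np.int64),
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        fps=fps,
        px_per_cm=px_per_cm,
    )


# --------------------------------------------------------- canonical curves

def gen_line(n: int = 1000, step_px: float = 1.0, angle: float = 0.3) -> Trajectory:
    """Straight path of n points; D = 1 for every estimator."""
    if n < 2:
        raise ParameterError("line needs n >= 2")
    t = np.arange(n) * step_px
    return _traj("line", t * math.cos(angle), t * math.sin(angle))


def gen_circle(n: int = 1000, radius_px: float = 200.0) -> Trajectory:
    """Closed circle of n vertices; a smooth curve, D = 1."""
    if n < 3:
        raise ParameterError("circle needs n >= 3")
    th = np.linspace(0.0, 2 * math.pi, n)
    return _traj("circle", radius_px * np.cos(th), radius_px * np.sin(th))


def gen_koch(order: int = 5, span_px: float = 729.0) -> Trajectory:
    """Koch-curve vertex sequence of 4^order segments; D = log4/log3."""
    if not 1 <= order <= 8:
        raise ParameterError(f"koch order must be in [1, 8], got {order}")
    pts = np.array([0.0 + 0.0j, 1.0 + 0.0j])
    rot = np.exp(1j * math.pi / 3)
    for _ in range(order):
        a, b = pts[:-1], pts[1:]
        d = (b - a) / 3.0
        pts = np.column_stack(
            [a, a + d, a + d + d * rot, a + 2 * d, b]
        ).ravel()
        # consecutive duplicates (segment end == next start) collapse:
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = pts[1:] != pts[:-1]
        pts = pts[keep]
    pts = pts * span_px
    return _traj(f"koch{order}", pts.real, -pts.imag)


def _hilbert_xy(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Cell coordinates of the order-k Hilbert curve on a 2^k grid."""
    n = 1 << order
    d = np.arange(n * n, dtype=np.int64)
    x = np.zeros_like(d)
    y = np.zeros_like(d)
    t = d.copy()
    s = 1
    while s < n:
        rx = (t // 2) & 1
        ry = (t ^ rx) & 1
        # rotate quadrant
        flip = ry == 0
        swap_mask = flip & (rx == 1)
        x_f = np.where(swap_mask, s - 1 - x, x)
        y_f = np.where(swap_mask, s - 1 - y, y)
        x, y = np.where(flip, y_f, x), np.where(flip, x_f, y)
        x = x + s * rx
        y = y + s * ry
        t //= 4
        s *= 2
    return x, y


def gen_hilbert(order: int = 7, cell_px: float = 1.0) -> Trajectory:
    """Hilbert space-filling curve: visits each of 4^order grid cells once.

    As the order grows the rendered curve fills the unit square, so box
    counting approaches D = 2 — the isotropic two-dimensional reference.
    """
    if not 1 <= order <= 8:
        raise ParameterError(f"hilbert order must be in [1, 8], got {order}")
    x, y = _hilbert_xy(order)
    return _traj(f"hilbert{order}", x * cell_px, y * cell_px)


# --------------------------------------------------------- stochastic walks

def _reflect_step(px, py, nx, ny, cx, cy, radius):
    """Fold a proposed position back inside the circular arena."""
    dx, dy = nx - cx, ny - cy
    d = math.hypot(dx, dy)
    if d <= radius:
        return nx, ny, False
    # radial fold: distance beyond the wall is reflected inward
    scale = (2 * radius - d) / d
    return cx + dx * scale, cy + dy * scale, True


def gen_crw(
    n: int,
    step_px: float = 2.0,
    kappa: float = 1.0,
    seed: int | None = None,
    arena_diameter_px: float = 600.0,
    fps: float = 25.0,
    specimen_id: str = "crw",
) -> Trajectory:
    """Correlated random walk with wrapped-normal turning angles.

    Successive headings differ by an angle drawn from a normal distribution
    of concentration ``kappa`` (variance 1/kappa, wrapped on the circle);
    ``kappa = 0`` gives uniform turning. The walk starts at the arena
    center and reflects off the circular wall.
    """
    if n < 10:
        raise ParameterError(f"crw needs n >= 10, got {n}")
    if kappa < 0:
        raise ParameterError(f"kappa must be >= 0, got {kappa}")
    if step_px <= 0 or arena_diameter_px <= 0:
        raise ParameterError("step_px and arena_diameter_px must be positive")
    rng = np.random.default_rng(seed)
    radius = arena_diameter_px / 2.0
    cx = cy = radius
    if kappa > 0:
        turns = rng.normal(0.0, kappa**-0.5, size=n - 1)
    else:
        turns = rng.uniform(-math.pi, math.pi, size=n - 1)
    theta = rng.uniform(-math.pi, math.pi)
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = cx, cy
    for i in range(1, n):
        theta += turns[i - 1]
        nx = x[i - 1] + step_px * math.cos(theta)
        ny = y[i - 1] + step_px * math.sin(theta)
        nx, ny, hit = _reflect_step(x[i - 1], y[i - 1], nx, ny, cx, cy, radius)
        if hit:
            theta = math.atan2(ny - y[i - 1], nx - x[i - 1])
        x[i], y[i] = nx, ny
    return _traj(specimen_id, x, y, fps=fps)


def gen_levy(
    n: int,
    mu: float = 2.0,
    seed: int | None = None,
    l_min_px: float = 1.0,
    l_max_px: float = 300.0,
    arena_diameter_px: float = 600.0,
    fps: float = 25.0,
    specimen_id: str = "levy",
) -> Trajectory:
    """Lévy walk: uniform headings, truncated power-law step lengths.

    Step lengths follow p(l) ∝ l^(-mu) on [l_min, l_max]; mu near 1 is
    dominated by rare ballistic moves, mu near 3 is diffusive.
    """
    if n < 10:
        raise ParameterError(f"levy needs n >= 10, got {n}")
    if not 1.0 < mu <= 3.0:
        raise ParameterError(f"mu must be in (1, 3], got {mu}")
    rng = np.random.default_rng(seed)
    radius = arena_diameter_px / 2.0
    cx = cy = radius
    u = rng.uniform(size=n - 1)
    a, b = l_min_px ** (1.0 - mu), l_max_px ** (1.0 - mu)
    steps = (a + u * (b - a)) ** (1.0 / (1.0 - mu))
    headings = rng.uniform(-math.pi, math.pi, size=n - 1)
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = cx, cy
    for i in range(1, n):
        nx = x[i - 1] + steps[i - 1] * math.cos(headings[i - 1])
        ny = y[i - 1] + steps[i - 1] * math.sin(headings[i - 1])
        nx, ny, _ = _reflect_step(x[i - 1], y[i - 1], nx, ny, cx, cy, radius)
        # long Lévy steps can overshoot even after one fold; clamp radially
        dx, dy = nx - cx, ny - cy
        d = math.hypot(dx, dy)
        if d > radius:
            nx, ny = cx + dx * radius / d * 0.999, cy + dy * radius / d * 0.999
        x[i], y[i] = nx, ny
    return _traj(specimen_id, x, y, fps=fps)


# ---------------------------------------------------- simulated experiment

@dataclass
class SimConfig:
    """Design and effect sizes of the simulated thermal-stress experiment.

    The thermal effect acts on the log turning-angle concentration: warming
    adds ``beta_treatment`` to log kappa, straightening paths and lowering
    every fractal index. In structurally complex microhabitats the effect
    is attenuated by ``buffer_complex`` (1 = fully buffered). Specimens are
    nested in sites through a Gaussian random intercept on the same scale.
    """

    n_per_cell: int = 15  # specimens per family × treatment cell (15 → 90/family)
    n_frames: int = 15000  # 600 s at 25 fps
    fps: float = 25.0
    arena_diameter_cm: float = 20.0
    px_per_cm: float = 30.0
    microhabitat_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_MICROHABITAT_PROBS)
    )
    n_sites: int = 6
    sigma_site: float = 0.15
    baseline_log_kappa: float = math.log(0.5)
    beta_treatment: dict = field(default_factory=lambda: {"+5C": 0.6, "+10C": 1.2})
    buffer_complex: float = 0.8
    family_kappa_offset: dict = field(
        default_factory=lambda: {"Baetidae": 0.0, "Leptophlebiidae": 0.1}
    )
    base_step_px: dict = field(
        default_factory=lambda: {"Baetidae": 2.5, "Leptophlebiidae": 1.8}
    )
    length_speed_link: float = 0.2  # log-step increase per SD of body length
    speed_noise_sd: float = 0.2
    body_length_mean: dict = field(
        default_factory=lambda: {"Baetidae": 0.55, "Leptophlebiidae": 0.85}
    )
    body_length_sd: dict = field(
        default_factory=lambda: {"Baetidae": 0.08, "Leptophlebiidae": 0.12}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.microhabitat_probs.values())
        if abs(total - 1.0) > 1e-6:
            raise ParameterError(f"microhabitat probabilities sum to {total}, not 1")
        if self.n_per_cell < 2:
            raise ParameterError("n_per_cell must be >= 2")
        if self.n_sites < 1:
            raise ParameterError("n_sites must be >= 1")


def is_complex_microhabitat(name: str) -> bool:
    return name in COMPLEX_MICROHABITATS


def simulate_experiment(
    cfg: SimConfig,
) -> tuple[list[Trajectory], pd.DataFrame, pd.DataFrame]:
    """Simulate the full experiment: trajectories, metadata and ground truth.

    For each specimen the turning concentration is

        log kappa = baseline + beta[treatment] * (1 - buffer * complex)
                    + family offset + u_site,    u_site ~ N(0, sigma_site²)

    and the trajectory is a CRW of ``n_frames`` steps in the arena.
    Morphology is family-specific (body length truncated above 0.2 cm) and
    the per-specimen step length is tied to body length, inducing the
    morphology–speed correlations seen in real nymphs.

    Returns (trajectories, metadata table, per-specimen truth table); the
    truth table carries kappa, the site intercept and the step length for
    parameter-recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    u_site = rng.normal(0.0, cfg.sigma_site, size=cfg.n_sites)
    habitats = list(cfg.microhabitat_probs)
    probs = np.array([cfg.microhabitat_probs[h] for h in habitats])

    trajectories: list[Trajectory] = []
    meta_rows = []
    truth_rows = []
    arena_px = cfg.arena_diameter_cm * cfg.px_per_cm
    for family in FAMILIES:
        for treatment in TREATMENTS:
            for i in range(cfg.n_per_cell):
                sid = f"{family[:4].lower()}_{treatment.replace('+', 'p')}_{i:03d}"
                site = int(rng.integers(cfg.n_sites))
                habitat = habitats[int(rng.choice(len(habitats), p=probs))]
                beta = cfg.beta_treatment.get(treatment, 0.0)
                buffered = beta * (
                    1.0 - cfg.buffer_complex * is_complex_microhabitat(habitat)
                )
                log_kappa = (
                    cfg.baseline_log_kappa
                    + buffered
                    + cfg.family_kappa_offset[family]
                    + u_site[site]
                )
                kappa = math.exp(log_kappa)

                length = -1.0
                while length <= 0.2:  # inclusion rule: body length > 0.2 cm
                    length = rng.normal(
                        cfg.body_length_mean[family], cfg.body_length_sd[family]
                    )
                z_len = (length - cfg.body_length_mean[family]) / cfg.body_length_sd[family]
                lyo_weight = 4.0 * length**3 * math.exp(rng.normal(0.0, 0.15))
                step = cfg.base_step_px[family] * math.exp(
                    cfg.length_speed_link * z_len
                    + rng.normal(0.0, cfg.speed_noise_sd)
                )

                traj_seed = int(rng.integers(2**31))
                traj = gen_crw(
                    cfg.n_frames,
                    step_px=step,
                    kappa=kappa,
                    seed=traj_seed,
                    arena_diameter_px=arena_px,
                    fps=cfg.fps,
                    specimen_id=sid,
                ).replace(px_per_cm=cfg.px_per_cm)
                trajectories.append(traj)
                meta_rows.append(
                    {
                        "specimen_id": sid,
                        "family": family,
                        "microhabitat": habitat,
                        "treatment": treatment,
                        "site": f"site{site}",
                        "body_length_cm": round(length, 4),
                        "lyo_weight_mg": round(lyo_weight, 4),
                    }
                )
                truth_rows.append(
                    {
                        "specimen_id": sid,
                        "kappa": kappa,
                        "log_kappa": log_kappa,
                        "u_site": u_site[site],
                        "step_px": step,
                        "traj_seed": traj_seed,
                    }
                )
    return trajectories, pd.DataFrame(meta_rows), pd.DataFrame(truth_rows)
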