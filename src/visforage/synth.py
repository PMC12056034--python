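"""Synthetic visual-foraging data: patches of conjunction objects and virtual foragers.

A patch holds 42 targets and 42 distractors placed on a jittered 12 x 7 grid.
A virtual forager collects all targets by tapping them in nearest-neighbour
order; which object *part* (half-disc vs. rectangle) it aims at follows a
two-state Markov chain (the attention template), and the tap lands at a noisy
anchor pulled partway toward the object's center of mass.  Inter-target times
are log-normal with an inflated final interval (the "end peak").
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import geometry

PARTS = ("disc", "rect")


# ---------------------------------------------------------------------------
# configuration / domain types
# ---------------------------------------------------------------------------


@dataclass
class PatchConfig:
    """Layout of one foraging patch (trial display)."""

    grid_cols: int = 12
    grid_rows: int = 7
    grid_extent_px: tuple[float, float] = (1430.0, 780.0)
    screen_px: tuple[float, float] = (1920.0, 1080.0)
    jitter_px: float = 20.0
    n_targets: int = 42
    n_distractors: int = 42
    half_disc_radius_px: float = 23.0
    rect_w_px: float = 46.0
    rect_h_px: float = 23.0
    acceptance_radius_px: float = 40.0
    #: color of the *target's* rectangle; the disc gets the other color and
    #: distractors invert the assignment.
    target_rect_color: str = "green"

    def __post_init__(self) -> None:
        if self.n_targets + self.n_distractors > self.grid_cols * self.grid_rows:
            raise ValueError(
                f"{self.n_targets + self.n_distractors} objects do not fit a "
                f"{self.grid_cols} x {self.grid_rows} grid"
            )
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        for name in ("half_disc_radius_px", "rect_w_px", "rect_h_px", "acceptance_radius_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.target_rect_color not in ("green", "red"):
            raise ValueError("target_rect_color must be 'green' or 'red'")


@dataclass
class ConjunctionObject:
    """One two-part item: a half-disc flush on a rectangle."""

    object_id: int
    center_px: tuple[float, float]
    orientation_deg: int
    role: str  # 'target' | 'distractor'
    disc_color: str
    rect_color: str

    def __post_init__(self) -> None:
        if self.orientation_deg not in geometry.CARDINAL_ORIENTATIONS:
            raise ValueError("orientation must be one of 0/90/180/270")
        if {self.disc_color, self.rect_color} != {"red", "green"}:
            raise ValueError("exactly one part must be red and one green")

    def part_color(self, part: str) -> str:
        return self.disc_color if part == "disc" else self.rect_color


@dataclass
class Patch:
    """All objects of one trial, plus their grid-cell assignment."""

    trial_id: int
    objects: list[ConjunctionObject]
    grid_cells: list[tuple[int, int]]
    config: PatchConfig = field(default_factory=PatchConfig)

    @property
    def centers(self) -> np.ndarray:
        return np.array([o.center_px for o in self.objects])

    @property
    def roles(self) -> np.ndarray:
        return np.array([o.role for o in self.objects])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for obj, cell in zip(self.objects, self.grid_cells):
            rows.append(
                dict(
                    trial_id=self.trial_id,
                    object_id=obj.object_id,
                    cx=obj.center_px[0],
                    cy=obj.center_px[1],
                    orientation_deg=obj.orientation_deg,
                    role=obj.role,
                    disc_color=obj.disc_color,
                    rect_color=obj.rect_color,
                    grid_col=cell[0],
                    grid_row=cell[1],
                )
            )
        return pd.DataFrame(rows)


@dataclass
class ForagerParams:
    """Generative parameters of one virtual participant.

    p_switch_att
        Probability the attended part changes between successive collections.
        0.5 is memoryless ("random") switching; below 0.5 produces runs.
    p_pref
        Probability that the first attended part of a trial is ``preferred_part``.
    motor_sigma_px
        Isotropic Gaussian scatter of the tap around its anchor.
    com_weight
        Pull (lambda in [0, 1]) of the tap anchor from the attended part's
        centroid toward the whole object's center of mass.
    itt_logmean, itt_logsd
        Log-normal parameters of cruise-phase inter-target times (ms).
    endpeak_mult
        Multiplier (>= 1) applied to the trial's final inter-target time.
    error_rate
        Probability that a collection event also produces a distractor tap.
    """

    p_switch_att: float = 0.41
    preferred_part: str = "disc"
    p_pref: float = 0.8
    motor_sigma_px: float = 8.0
    com_weight: float = 0.3
    itt_logmean: float = float(np.log(700.0))
    itt_logsd: float = 0.35
    endpeak_mult: float = 10.0
    error_rate: float = 0.0125

    def __post_init__(self) -> None:
        for name in ("p_switch_att", "p_pref", "com_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.motor_sigma_px < 0:
            raise ValueError("motor_sigma_px must be >= 0")
        if self.endpeak_mult < 1:
            raise ValueError("endpeak_mult must be >= 1")
        if self.preferred_part not in PARTS:
            raise ValueError("preferred_part must be 'disc' or 'rect'")


@dataclass
class TapEvent:
    """One observed tap (canonical fields are filled by preprocessing)."""

    participant_id: int
    trial_id: int
    tap_index: int
    time_ms: float
    screen_xy_px: tuple[float, float]
    object_id: Optional[int] = None
    canonical_xy_px: Optional[tuple[float, float]] = None
    part_label: Optional[str] = None
    is_error: bool = False


TAPLOG_COLUMNS = [
    "participant_id",
    "trial_id",
    "tap_index",
    "time_ms",
    "x_px",
    "y_px",
    "object_id",
    "is_error",
]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_patch(config: PatchConfig, seed, trial_id: int = 0) -> Patch:
    """Place targets and distractors in distinct cells of the jittered grid."""
    rng = np.random.default_rng(seed)
    n_obj = config.n_targets + config.n_distractors
    n_cells = config.grid_cols * config.grid_rows
    cells = rng.choice(n_cells, size=n_obj, replace=False)
    cols, rows = cells % config.grid_cols, cells // config.grid_cols

    ew, eh = config.grid_extent_px
    sw, sh = config.screen_px
    cell_w, cell_h = ew / config.grid_cols, eh / config.grid_rows
    x0, y0 = (sw - ew) / 2.0, (sh - eh) / 2.0
    cx = x0 + (cols + 0.5) * cell_w + rng.uniform(-config.jitter_px, config.jitter_px, n_obj)
    cy = y0 + (rows + 0.5) * cell_h + rng.uniform(-config.jitter_px, config.jitter_px, n_obj)
    orientations = rng.choice(geometry.CARDINAL_ORIENTATIONS, size=n_obj)

    t_rect = config.target_rect_color
    t_disc = "red" if t_rect == "green" else "green"
    objects, grid_cells = [], []
    for i in range(n_obj):
        is_target = i < config.n_targets
        objects.append(
            ConjunctionObject(
                object_id=i,
                center_px=(float(cx[i]), float(cy[i])),
                orientation_deg=int(orientations[i]),
                role="target" if is_target else "distractor",
                disc_color=t_disc if is_target else t_rect,
                rect_color=t_rect if is_target else t_disc,
            )
        )
        grid_cells.append((int(cols[i]), int(rows[i])))
    return Patch(trial_id=trial_id, objects=objects, grid_cells=grid_cells, config=config)


def simulate_attention_sequence(params: ForagerParams, n_collections: int, seed_or_rng) -> np.ndarray:
    """Part labels of a trial's collections under the two-state Markov chain."""
    if n_collections < 1:
        raise ValueError("n_collections must be >= 1")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    other = PARTS[1 - PARTS.index(params.preferred_part)]
    first = params.preferred_part if rng.random() < params.p_pref else other
    # state as 0/1; cumulative XOR of switch indicators gives the chain
    switches = rng.random(n_collections - 1) < params.p_switch_att
    states = np.empty(n_collections, dtype=np.int8)
    states[0] = PARTS.index(first)
    if n_collections > 1:
        states[1:] = (states[0] + np.cumsum(switches)) % 2
    return np.array(PARTS, dtype=object)[states]


def tap_anchor(attended_part: str, params: ForagerParams, r: float = geometry.DEFAULT_RADIUS) -> np.ndarray:
    """Canonical tap mean: part centroid pulled toward the center of mass."""
    lam = params.com_weight
    return (1.0 - lam) * geometry.part_centroid(attended_part, r) + lam * geometry.center_of_mass(r)


def simulate_tap(
    obj: ConjunctionObject,
    attended_part: str,
    params: ForagerParams,
    rng: np.random.Generator,
    r: float = geometry.DEFAULT_RADIUS,
) -> np.ndarray:
    """Screen position of one tap on ``obj`` while attending ``attended_part``."""
    if attended_part not in PARTS:
        raise ValueError("attended_part must be 'disc' or 'rect'")
    canonical = tap_anchor(attended_part, params, r) + rng.normal(0.0, params.motor_sigma_px, 2)
    return geometry.canonical_to_screen(canonical, obj.center_px, obj.orientation_deg)


def simulate_taps_vectorized(
    centers: np.ndarray,
    orientations: np.ndarray,
    parts: np.ndarray,
    params: ForagerParams,
    rng: np.random.Generator,
    r: float = geometry.DEFAULT_RADIUS,
) -> np.ndarray:
    """Vectorized :func:`simulate_tap` over aligned arrays of objects/parts."""
    n = len(parts)
    anchors = np.where(
        (parts == "disc")[:, None],
        tap_anchor("disc", params, r),
        tap_anchor("rect", params, r),
    )
    canonical = anchors + rng.normal(0.0, params.motor_sigma_px, (n, 2))
    rots = np.stack([geometry.rotation_matrix(o) for o in geometry.CARDINAL_ORIENTATIONS])
    idx = (np.asarray(orientations) // 90).astype(int)
    rotated = np.einsum("nij,nj->ni", rots[idx], canonical)
    return rotated + np.asarray(centers, dtype=float)


def simulate_itts(n_collections: int, params: ForagerParams, rng: np.random.Generator) -> np.ndarray:
    """Inter-target times (ms): log-normal cruise, final value end-peaked."""
    if n_collections < 2:
        raise ValueError("n_collections must be >= 2")
    itts = rng.lognormal(params.itt_logmean, params.itt_logsd, n_collections)
    itts[-1] *= params.endpeak_mult
    return itts


def _nearest_unvisited(pos: np.ndarray, centers: np.ndarray, available: np.ndarray) -> int:
    idx = np.flatnonzero(available)
    d2 = ((centers[idx] - pos) ** 2).sum(axis=1)
    return int(idx[np.argmin(d2)])


def simulate_experiment(
    n_participants: int,
    n_trials: int,
    patch_config: PatchConfig,
    params_per_participant: list[ForagerParams],
    seed,
) -> tuple[pd.DataFrame, dict]:
    """Full experiment: tap log (DataFrame) plus ground truth for recovery tests.

    Each participant gets an independent RNG stream spawned from the master
    seed so runs replay deterministically.  Collection order is greedy: the
    nearest unvisited target from the previous tap (start: screen center).
    Returns ``(taplog, ground_truth)`` where ``ground_truth`` holds the
    per-participant params, every patch, and every realized attention sequence.
    """
    if len(params_per_participant) != n_participants:
        raise ValueError("need one ForagerParams per participant")
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = master.spawn(n_participants)

    records: list[dict] = []
    truth: dict = {"params": {}, "patches": {}, "attention": {}}
    screen_center = np.array(patch_config.screen_px) / 2.0

    for pid, (params, stream) in enumerate(zip(params_per_participant, streams)):
        rng = np.random.default_rng(stream)
        truth["params"][pid] = params
        for trial in range(n_trials):
            patch = generate_patch(patch_config, rng, trial_id=trial)
            centers = patch.centers
            is_target = patch.roles == "target"
            n_t = int(is_target.sum())

            attention = simulate_attention_sequence(params, n_t, rng)
            itts = simulate_itts(n_t, params, rng)
            times = np.cumsum(itts)
            truth["patches"][(pid, trial)] = patch
            truth["attention"][(pid, trial)] = attention

            available = np.ones(len(patch.objects), dtype=bool)
            pos = screen_center.copy()
            tap_index = 0
            prev_time = 0.0
            for j in range(n_t):
                part = attention[j]
                if params.error_rate > 0 and rng.random() < params.error_rate:
                    cand = available & ~is_target
                    if cand.any():
                        k = _nearest_unvisited(pos, centers, cand)
                        obj = patch.objects[k]
                        xy = simulate_tap(obj, part, params, rng, patch_config.half_disc_radius_px)
                        t_err = prev_time + rng.uniform(0.2, 0.8) * (times[j] - prev_time)
                        records.append(
                            dict(
                                participant_id=pid, trial_id=trial, tap_index=tap_index,
                                time_ms=float(t_err), x_px=float(xy[0]), y_px=float(xy[1]),
                                object_id=obj.object_id, is_error=True,
                            )
                        )
                        available[k] = False
                        pos = xy
                        tap_index += 1
                k = _nearest_unvisited(pos, centers, available & is_target)
                obj = patch.objects[k]
                xy = simulate_tap(obj, part, params, rng, patch_config.half_disc_radius_px)
                records.append(
                    dict(
                        participant_id=pid, trial_id=trial, tap_index=tap_index,
                        time_ms=float(times[j]), x_px=float(xy[0]), y_px=float(xy[1]),
                        object_id=obj.object_id, is_error=False,
                    )
                )
                available[k] = False
                pos = xy
                prev_time = times[j]
                tap_index += 1

    taplog = pd.DataFrame.from_records(records, columns=TAPLOG_COLUMNS)
    return taplog, truth


def params_to_dict(params: ForagerParams) -> dict:
    return asdict(params)
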