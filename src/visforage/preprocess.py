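"""From raw taps to count data.

Assigns taps to objects (nearest center within the acceptance radius),
rotates them into the canonical object frame, labels the tapped part
(half-disc vs. rectangle), and aggregates per-participant/trial counts:
part switches out of switching opportunities, red-part taps out of collected
targets (per trial, experiment half, block, or overall), inter-target-time
series and end-peak factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .synth import Patch, ConjunctionObject, PatchConfig

log = logging.getLogger(__name__)

SCOPES = ("trial", "half", "block", "all")


@dataclass
class SwitchCounts:
    participant_id: int
    trial_id: int
    k_switch: int
    m_opportunities: int

    def __post_init__(self) -> None:
        if not 0 <= self.k_switch <= self.m_opportunities:
            raise ValueError("k_switch must lie in [0, m_opportunities]")


@dataclass
class ITTSeries:
    participant_id: int
    trial_id: int
    itts_ms: np.ndarray

    @property
    def trial_duration_s(self) -> float:
        return float(np.sum(self.itts_ms)) / 1000.0


# ---------------------------------------------------------------------------
# per-tap operations
# ---------------------------------------------------------------------------


def assign_tap(tap_xy, patch: Patch, acceptance_radius_px: float | None = None):
    """Nearest object center within the acceptance radius, else None.

    Ties (equal distance) break toward the lowest object_id, which is the
    order objects are stored in.
    """
    if not patch.objects:
        raise ValueError("patch contains no objects")
    if acceptance_radius_px is None:
        acceptance_radius_px = patch.config.acceptance_radius_px
    d2 = ((patch.centers - np.asarray(tap_xy, dtype=float)) ** 2).sum(axis=1)
    best = int(np.argmin(d2))  # argmin returns the first (lowest id) on ties
    if d2[best] <= acceptance_radius_px**2:
        return patch.objects[best].object_id
    return None


def to_canonical(tap_screen_xy, obj: ConjunctionObject) -> np.ndarray:
    """Undo the object's translation and rotation (inverse of the simulator)."""
    return geometry.screen_to_canonical(tap_screen_xy, obj.center_px, obj.orientation_deg)


def classify_part(canonical_xy) -> str:
    """'disc' for canonical y > 0, 'rect' otherwise (boundary y=0 -> rect)."""
    y = np.asarray(canonical_xy, dtype=float)[..., 1]
    if y.ndim == 0:
        return "disc" if y > 0 else "rect"
    return np.where(y > 0, "disc", "rect")


# ---------------------------------------------------------------------------
# per-trial aggregation
# ---------------------------------------------------------------------------


def count_switches(part_labels, participant_id: int = 0, trial_id: int = 0) -> SwitchCounts:
    """Part changes between successive collected targets within one trial."""
    labels = np.asarray(part_labels)
    if labels.size == 0:
        raise ValueError("empty trial: no part labels to count")
    k = int(np.sum(labels[1:] != labels[:-1]))
    return SwitchCounts(participant_id, trial_id, k, labels.size - 1)


def end_peak_factor(itts, include_last_in_median: bool = True) -> float:
    """Last inter-target time divided by the trial's median inter-target time."""
    itts = np.asarray(itts, dtype=float)
    if itts.size < 2:
        raise ValueError("need at least 2 inter-target times")
    med = np.median(itts) if include_last_in_median else np.median(itts[:-1])
    return float(itts[-1] / med)


def participant_mean(factors) -> float:
    """Participant-level end-peak value: mean of the per-trial factors."""
    return float(np.mean(np.asarray(factors, dtype=float)))


# ---------------------------------------------------------------------------
# tap-log pipeline
# ---------------------------------------------------------------------------


def label_taps(taplog: pd.DataFrame, patches: dict, config: PatchConfig | None = None) -> pd.DataFrame:
    """Assign, canonicalize and part-label every tap of a tap log.

    ``patches`` maps (participant_id, trial_id) -> Patch.  Taps that land
    outside every acceptance radius are dropped with a warning.  Returns the
    log with columns ``object_id`` (re-derived), ``canon_x``, ``canon_y``,
    ``part_label``, ``part_color`` and ``role`` added.
    """
    out_rows = []
    n_dropped = 0
    for (pid, trial), group in taplog.groupby(["participant_id", "trial_id"], sort=True):
        patch = patches[(pid, trial)]
        by_id = {o.object_id: o for o in patch.objects}
        for row in group.itertuples(index=False):
            oid = assign_tap((row.x_px, row.y_px), patch)
            if oid is None:
                n_dropped += 1
                continue
            obj = by_id[oid]
            canon = to_canonical((row.x_px, row.y_px), obj)
            part = classify_part(canon)
            out_rows.append(
                dict(
                    participant_id=pid, trial_id=trial, tap_index=row.tap_index,
                    time_ms=row.time_ms, x_px=row.x_px, y_px=row.y_px,
                    object_id=oid, is_error=bool(row.is_error) or obj.role != "target",
                    canon_x=float(canon[0]), canon_y=float(canon[1]),
                    part_label=part, part_color=obj.part_color(part), role=obj.role,
                )
            )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} taps outside every acceptance radius")
        log.warning("dropped %d unassigned taps", n_dropped)
    return pd.DataFrame(out_rows)


def _collected(labeled: pd.DataFrame) -> pd.DataFrame:
    """Non-error taps (collected targets), in tap order."""
    return labeled.loc[~labeled["is_error"]].sort_values(
        ["participant_id", "trial_id", "tap_index"]
    )


def switch_counts_table(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per participant x trial: k_switch out of m_opportunities."""
    rows = []
    for (pid, trial), grp in _collected(labeled).groupby(["participant_id", "trial_id"]):
        sc = count_switches(grp["part_label"].to_numpy(), pid, trial)
        rows.append(vars(sc))
    return pd.DataFrame(rows)


def aggregate_switch_counts(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Sum trial-level switch counts per participant (the main model's data)."""
    agg = per_trial.groupby("participant_id")[["k_switch", "m_opportunities"]].sum()
    return agg.reset_index()


def preference_counts_table(
    labeled: pd.DataFrame, scope: str = "all", n_trials: int | None = None
) -> pd.DataFrame:
    """Red-part taps out of collected targets, aggregated per scope.

    Scopes: 'trial' (per trial), 'half' (trials split in two), 'block'
    (successive pairs of trials -> 10 blocks at 20 trials), 'all'.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    coll = _collected(labeled).copy()
    coll["is_red"] = coll["part_color"] == "red"
    if n_trials is None:
        n_trials = int(coll["trial_id"].max()) + 1

    if scope == "trial":
        keys = ["participant_id", "trial_id"]
    elif scope == "half":
        coll["half"] = np.where(coll["trial_id"] < n_trials // 2, 1, 2)
        keys = ["participant_id", "half"]
    elif scope == "block":
        coll["block"] = coll["trial_id"] // 2 + 1
        keys = ["participant_id", "block"]
    else:
        keys = ["participant_id"]

    out = coll.groupby(keys).agg(k_red=("is_red", "sum"), n=("is_red", "size")).reset_index()
    out["k_red"] = out["k_red"].astype(int)
    return out


def itt_table(taplog_or_labeled: pd.DataFrame, first_tap_as_itt: bool = True) -> pd.DataFrame:
    """Per-trial inter-target times of collected targets, long format.

    The first tap's latency from trial start counts as the first ITT by
    default (switchable).
    """
    df = taplog_or_labeled
    coll = df.loc[~df["is_error"]].sort_values(["participant_id", "trial_id", "tap_index"])
    rows = []
    for (pid, trial), grp in coll.groupby(["participant_id", "trial_id"]):
        t = grp["time_ms"].to_numpy(dtype=float)
        itts = np.diff(t, prepend=0.0) if first_tap_as_itt else np.diff(t)
        for j, v in enumerate(itts):
            rows.append(dict(participant_id=pid, trial_id=trial, itt_index=j, itt_ms=float(v)))
    return pd.DataFrame(rows)


def end_peak_table(itt_df: pd.DataFrame, include_last_in_median: bool = True) -> pd.DataFrame:
    """Per-trial end-peak factors and the per-participant mean."""
    rows = []
    for (pid, trial), grp in itt_df.groupby(["participant_id", "trial_id"]):
        itts = grp.sort_values("itt_index")["itt_ms"].to_numpy()
        rows.append(
            dict(participant_id=pid, trial_id=trial,
                 end_peak_factor=end_peak_factor(itts, include_last_in_median),
                 trial_duration_s=float(itts.sum() / 1000.0))
        )
    per_trial = pd.DataFrame(rows)
    per_participant = (
        per_trial.groupby("participant_id")["end_peak_factor"].mean().reset_index()
    )
    return per_trial.merge(per_participant, on="participant_id", suffixes=("", "_participant"))
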