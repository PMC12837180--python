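"""Spatiotemporal gait parameters and pre/post session comparison.

All "forward" quantities are projections onto the walking direction,
estimated as the principal axis of pelvis displacement.  Step-length
symmetry uses the bounded ratio 100 * min(L, R) / max(L, R), where 100%
is perfect symmetry.
"""
from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .containers import GaitEvents, MarkerTrajectorySet
from .cycles import _walking_direction

#: Parameters where a larger value counts as improvement; double support
#: improves when it decreases; step width has no universal direction.
IMPROVEMENT_DIRECTION = {
    "speed": "up",
    "stride_length": "up",
    "step_length_left": "up",
    "step_length_right": "up",
    "cadence": "up",
    "step_length_symmetry": "up",
    "double_support_s": "down",
    "double_support_pct": "down",
    "step_width": "context-dependent",
}


@dataclass
class SpatiotemporalSummary:
    """Mean spatiotemporal parameters of one walking trial."""

    speed: float                 # m/s
    stride_length: float         # m
    step_length_left: float      # m
    step_length_right: float     # m
    step_width: float            # m
    cadence: float               # steps/min
    double_support_s: float      # s per gait cycle
    double_support_pct: float    # % of gait cycle
    step_length_symmetry: float  # %, 100 = symmetric

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if np.isfinite(v) and f.name != "step_length_symmetry" and v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
        if np.isfinite(self.step_length_symmetry) and not (
                0.0 <= self.step_length_symmetry <= 100.0):
            raise ValueError("step-length symmetry must lie in [0, 100] %")

    def as_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


def symmetry_index(left_step: float, right_step: float) -> float:
    """Bounded step-length symmetry: 100 * min(L, R) / max(L, R)."""
    if left_step <= 0 or right_step <= 0:
        raise ValueError(
            f"step lengths must be > 0, got left={left_step}, right={right_step}"
        )
    return 100.0 * min(left_step, right_step) / max(left_step, right_step)


def percent_change(pre: float, post: float) -> float:
    """Signed relative change 100 * (post - pre) / pre."""
    if pre == 0:
        raise ValueError("percent change undefined for pre = 0")
    return 100.0 * (post - pre) / pre


def _interp_pos(t_query, t, pos):
    return np.stack([np.interp(t_query, t, pos[:, k]) for k in range(3)], axis=-1)


def compute_spatiotemporal(markers: MarkerTrajectorySet,
                           events: GaitEvents) -> SpatiotemporalSummary:
    """Spatiotemporal parameters from heel/pelvis markers and events.

    stride length: forward heel displacement between consecutive
    same-side heel-strikes (mean over strides and sides); step length:
    forward distance between the two heels at each heel-strike of the
    leading side; step width: mediolateral heel separation at
    heel-strikes; cadence: steps per minute over the first-to-last
    heel-strike window; speed: pelvis forward displacement over the same
    window; double support: summed both-feet-in-stance duration per
    cycle from the event sequence.
    """
    for side in ("right", "left"):
        if len(events.heel_strikes.get(side, ())) < 2:
            raise ValueError(
                f"need >= 2 heel-strikes per side, missing on {side!r}"
            )
    pelvis = markers.marker("pelvis")
    t = markers.time
    fwd = _walking_direction(pelvis)
    up = np.array([0.0, 1.0, 0.0])
    lat = np.cross(fwd, up)
    lat /= np.linalg.norm(lat)

    heel = {s: markers.marker(f"heel_{s[0]}") for s in ("right", "left")}
    other = {"right": "left", "left": "right"}

    stride_lengths, step_lengths, widths = [], {}, []
    for side in ("right", "left"):
        hs = events.heel_strikes[side]
        own = _interp_pos(hs, t, heel[side])
        opp = _interp_pos(hs, t, heel[other[side]])
        stride_lengths.extend(np.diff(own @ fwd))
        step_lengths[side] = float(np.mean((own - opp) @ fwd))
        widths.extend(np.abs((own - opp) @ lat))

    all_hs = np.sort(np.concatenate([events.heel_strikes[s] for s in ("right", "left")]))
    duration = all_hs[-1] - all_hs[0]
    if duration <= 0:
        raise ValueError("degenerate event sequence: zero walking duration")
    cadence = 60.0 * (len(all_hs) - 1) / duration
    pelvis_fwd = pelvis @ fwd
    speed = float(np.interp(all_hs[-1], t, pelvis_fwd)
                  - np.interp(all_hs[0], t, pelvis_fwd)) / duration

    ds_s, ds_pct = _double_support(events)
    return SpatiotemporalSummary(
        speed=speed,
        stride_length=float(np.mean(stride_lengths)),
        step_length_left=step_lengths["left"],
        step_length_right=step_lengths["right"],
        step_width=float(np.mean(widths)),
        cadence=cadence,
        double_support_s=ds_s,
        double_support_pct=ds_pct,
        step_length_symmetry=symmetry_index(step_lengths["left"], step_lengths["right"]),
    )


def _double_support(events: GaitEvents):
    """Double-support time per right-side gait cycle from the four-event
    sequence HS_R, TO_L, HS_L, TO_R: both feet are in stance from each
    heel-strike until the contralateral toe-off."""
    hs_r = events.heel_strikes["right"]
    per_cycle_s, per_cycle_pct = [], []
    for a, b in zip(hs_r[:-1], hs_r[1:]):
        to_l = events.toe_offs["left"]
        to_r = events.toe_offs["right"]
        hs_l = events.heel_strikes["left"]
        tol = to_l[(to_l > a) & (to_l < b)]
        tor = to_r[(to_r > a) & (to_r < b)]
        hsl = hs_l[(hs_l > a) & (hs_l < b)]
        if len(tol) != 1 or len(tor) != 1 or len(hsl) != 1:
            continue  # incomplete cycle at a recording edge
        ds = (tol[0] - a) + (tor[0] - hsl[0])
        if ds < 0:
            continue
        per_cycle_s.append(ds)
        per_cycle_pct.append(100.0 * ds / (b - a))
    if not per_cycle_s:
        return float("nan"), float("nan")
    return float(np.mean(per_cycle_s)), float(np.mean(per_cycle_pct))


@dataclass
class SessionComparison:
    """Paired pre/post summaries with signed percent changes and
    improvement-direction annotations per parameter."""

    pre: SpatiotemporalSummary
    post: SpatiotemporalSummary
    percent_changes: dict
    directions: dict

    def improved(self, parameter: str) -> bool | None:
        """Whether the change is in the improving direction (None when
        direction is context-dependent or the change is zero)."""
        d = self.directions[parameter]
        c = self.percent_changes[parameter]
        if d == "context-dependent" or c == 0:
            return None
        return c > 0 if d == "up" else c < 0


def compare_sessions(pre: SpatiotemporalSummary,
                     post: SpatiotemporalSummary) -> SessionComparison:
    """Signed percent change per parameter between two sessions."""
    pre_d, post_d = pre.as_dict(), post.as_dict()
    if set(pre_d) != set(post_d):
        raise ValueError("pre and post summaries have mismatched parameter sets")
    changes = {}
    for k in pre_d:
        if not np.isfinite(pre_d[k]) or not np.isfinite(post_d[k]):
            changes[k] = float("nan")
        else:
            changes[k] = percent_change(pre_d[k], post_d[k])
    return SessionComparison(pre=pre, post=post, percent_changes=changes,
                             directions=dict(IMPROVEMENT_DIRECTION))
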