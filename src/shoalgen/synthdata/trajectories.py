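"""Agent-based zonal schooling simulator.

A standard repulsion / orientation / attraction model in a circular
arena stands in for filmed fish: each agent moves at constant speed and
re-aims each frame at a weighted combination of (i) moving away from
neighbours inside the repulsion zone, (ii) the mean heading of
neighbours in the orientation zone and (iii) the direction towards
neighbours in the attraction zone, plus wrapped-normal angular noise.
The boundary reflects. The focal individual carries its own orientation
and attraction weights, which are monotone links from a sociability
parameter to the alignment / attraction phenotypes measured downstream —
behavioural realism beyond that monotone link is not a goal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from shoalgen.shoalmetrics import Trajectory


@dataclass
class AgentParams:
    """Zonal-model weights for one class of agents.

    Radii in cm; weights unitless; noise_sd is the angular noise standard
    deviation in radians per frame; speed in cm/s.
    """

    w_orientation: float = 2.0
    w_attraction: float = 1.0
    w_repulsion: float = 5.0
    r_repulsion: float = 2.0
    r_orientation: float = 10.0
    r_attraction: float = 30.0
    noise_sd: float = 0.4
    speed: float = 6.0


def simulate_trajectories(
    focal_params: AgentParams,
    group_params: AgentParams,
    n_frames: int,
    seed: int,
    n_individuals: int = 8,
    frame_rate: float = 25.0,
    arena_diameter: float = 55.0,
    dropout: float = 0.0,
    dropout_individuals: Optional[list[int]] = None,
) -> Trajectory:
    """Simulate one open-field trial; individual 0 is the focal fish.

    ``dropout`` masks each frame of the listed individuals (default all)
    independently with the given probability, emulating tracking loss.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames to define headings")
    rng = np.random.default_rng(seed)
    radius = arena_diameter / 2.0
    dt = 1.0 / frame_rate

    pos = np.empty((n_frames, n_individuals, 2))
    # start clustered near the centre (acclimation cylinder), random headings
    pos[0] = rng.uniform(-0.15 * radius, 0.15 * radius, (n_individuals, 2))
    angle = rng.uniform(0, 2 * np.pi, n_individuals)
    heading = np.column_stack([np.cos(angle), np.sin(angle)])

    w_ori = np.full(n_individuals, group_params.w_orientation)
    w_att = np.full(n_individuals, group_params.w_attraction)
    w_rep = np.full(n_individuals, group_params.w_repulsion)
    noise = np.full(n_individuals, group_params.noise_sd)
    speed = np.full(n_individuals, group_params.speed)
    for arr, val in (
        (w_ori, focal_params.w_orientation),
        (w_att, focal_params.w_attraction),
        (w_rep, focal_params.w_repulsion),
        (noise, focal_params.noise_sd),
        (speed, focal_params.speed),
    ):
        arr[0] = val
    r_rep = np.full(n_individuals, group_params.r_repulsion)
    r_ori = np.full(n_individuals, group_params.r_orientation)
    r_att = np.full(n_individuals, group_params.r_attraction)
    r_rep[0], r_ori[0], r_att[0] = (
        focal_params.r_repulsion,
        focal_params.r_orientation,
        focal_params.r_attraction,
    )

    for t in range(1, n_frames):
        p = pos[t - 1]
        diff = p[None, :, :] - p[:, None, :]  # diff[i, j] = p_j - p_i
        dist = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(dist, np.inf)
        desired = np.zeros((n_individuals, 2))
        for i in range(n_individuals):
            rep = dist[i] < r_rep[i]
            if rep.any():
                away = -diff[i][rep] / dist[i][rep][:, None]
                desired[i] = w_rep[i] * away.mean(axis=0)
            else:
                ori_zone = (dist[i] >= r_rep[i]) & (dist[i] < r_ori[i])
                att_zone = (dist[i] >= r_ori[i]) & (dist[i] < r_att[i])
                d = heading[i].copy()
                if ori_zone.any():
                    d = d + w_ori[i] * _normalize(heading[ori_zone].mean(axis=0))
                if att_zone.any():
                    towards = diff[i][att_zone] / dist[i][att_zone][:, None]
                    d = d + w_att[i] * _normalize(towards.mean(axis=0))
                desired[i] = d
        for i in range(n_individuals):
            d = desired[i]
            n = np.linalg.norm(d)
            base = d / n if n > 0 else heading[i]
            theta = np.arctan2(base[1], base[0]) + rng.normal(0.0, noise[i])
            heading[i] = (np.cos(theta), np.sin(theta))
        step = heading * (speed * dt)[:, None]
        new = p + step
        # reflective circular boundary
        r_new = np.linalg.norm(new, axis=1)
        outside = r_new > radius
        if outside.any():
            for i in np.where(outside)[0]:
                normal = new[i] / r_new[i]
                heading[i] = heading[i] - 2 * np.dot(heading[i], normal) * normal
                new[i] = normal * (2 * radius - r_new[i])
        pos[t] = new

    mask = np.ones((n_frames, n_individuals), bool)
    if dropout > 0:
        targets = (
            np.arange(n_individuals) if dropout_individuals is None else np.array(dropout_individuals)
        )
        drop = rng.uniform(size=(n_frames, len(targets))) < dropout
        mask[:, targets] = ~drop
    positions = pos.copy()
    positions[~mask] = np.nan
    return Trajectory(
        positions=positions,
        valid_mask=mask,
        frame_rate=frame_rate,
        arena_diameter=arena_diameter,
        focal_index=0,
    )


def focal_params_from_sociability(sociability: float, base: Optional[AgentParams] = None) -> AgentParams:
    """Monotone link from a sociability score to focal agent weights.

    Higher sociability raises the orientation and attraction weights
    (softplus link, so weights stay positive); zero gives the group
    baseline.
    """
    base = base or AgentParams()
    gain = np.logaddexp(0.0, sociability) / np.logaddexp(0.0, 0.0)
    return AgentParams(
        w_orientation=base.w_orientation * gain,
        w_attraction=base.w_attraction * gain,
        w_repulsion=base.w_repulsion,
        r_repulsion=base.r_repulsion,
        r_orientation=base.r_orientation,
        r_attraction=base.r_attraction,
        noise_sd=base.noise_sd,
        speed=base.speed,
    )


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v
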