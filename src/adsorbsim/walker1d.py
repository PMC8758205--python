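"""Vectorized single-molecule 1D random walks in a bounded column.

Two experiments:

* :func:`run_reflective` — molecules bounce at both ends; per observation
  frame the simulator counts distinct molecules that hit a wall and distinct
  molecules that cross a marked interior plane (directionally or in either
  direction).  With one sub-step per frame the endpoint counts reproduce the
  single-PDF discrete law; binning many sub-steps per frame recovers the
  mirror-doubled continuum law.
* :func:`run_absorbing` — the floor captures any molecule whose step
  endpoint crosses it; the ceiling reflects.  The cumulative capture curve
  reproduces the Langmuir–Schaefer law and the solution develops the
  erf-shaped depletion gradient.

Hit detection is deliberately by step endpoint, not by within-step
first-passage bridges: the gap between the endpoint count and the continuum
law, and its closure by sub-step binning, is the physics under study.

Column densities use a reference area A = 1 m^2, so a bulk number density
of c_b corresponds to a line density n/L = c_b (molecules per metre).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "WalkerEnsemble",
    "BinningScheme",
    "EventLog",
    "step_gaussian",
    "reflect",
    "run_reflective",
    "run_absorbing",
    "crossing_probability_single_step",
]


@dataclass
class WalkerEnsemble:
    """Positions and active flags of N point molecules in a column [0, L]."""

    pos: np.ndarray
    alive: np.ndarray
    L: float
    rng: np.random.Generator

    @classmethod
    def uniform(cls, n: int, L: float, seed) -> "WalkerEnsemble":
        rng = np.random.default_rng(seed)
        return cls(
            pos=rng.uniform(0.0, L, size=n),
            alive=np.ones(n, dtype=bool),
            L=L,
            rng=rng,
        )

    @property
    def n(self) -> int:
        return self.pos.size


@dataclass
class BinningScheme:
    """Observation frame ``dt_obs`` subdivided into ``n_sub`` simulation steps."""

    dt_obs: float
    n_sub: int = 1

    def __post_init__(self) -> None:
        if self.dt_obs <= 0:
            raise ValueError(f"dt_obs must be positive, got {self.dt_obs!r}")
        if int(self.n_sub) != self.n_sub or self.n_sub < 1:
            raise ValueError(f"n_sub must be an integer >= 1, got {self.n_sub!r}")
        self.n_sub = int(self.n_sub)

    @property
    def dt_sub(self) -> float:
        return self.dt_obs / self.n_sub


@dataclass
class EventLog:
    """Per-frame event counts from a walker run.

    Each counter counts *distinct* molecules per frame: a molecule
    triggering the same counter several times within one frame contributes
    one.  ``wall_hits`` sums the floor and ceiling distinct counts, so the
    per-wall mean is ``wall_hits / (2 * frames)``.
    """

    times: np.ndarray
    floor_hits: np.ndarray
    ceiling_hits: np.ndarray
    cross_directional: np.ndarray
    cross_either: np.ndarray
    adsorbed_cum: np.ndarray

    @property
    def wall_hits(self) -> np.ndarray:
        return self.floor_hits + self.ceiling_hits

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "wall_hits": self.wall_hits,
                "floor_hits": self.floor_hits,
                "ceiling_hits": self.ceiling_hits,
                "cross_d": self.cross_directional,
                "cross_nd": self.cross_either,
                "adsorbed_cum": self.adsorbed_cum,
            }
        )


def step_gaussian(ens: WalkerEnsemble, D: float, dt: float) -> WalkerEnsemble:
    """Displace every alive molecule by an independent N(0, 2*D*dt) step.

    Boundary handling is the caller's job (see :func:`reflect`).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    sigma = np.sqrt(2.0 * D * dt)
    if sigma > 0:
        ens.pos[ens.alive] += ens.rng.normal(0.0, sigma, size=int(ens.alive.sum()))
    return ens


def reflect(pos: np.ndarray, L: float):
    """Fold positions back into [0, L], flagging which wall(s) were touched.

    Applies x < 0 -> -x and x > L -> 2L - x repeatedly until inside.

    Returns
    -------
    (pos, hit_floor, hit_ceiling):
        Folded positions and boolean flags marking molecules that folded at
        the floor / ceiling at least once.
    """
    pos = np.asarray(pos, dtype=float).copy()
    hit_floor = np.zeros(pos.shape, dtype=bool)
    hit_ceiling = np.zeros(pos.shape, dtype=bool)
    while True:
        below = pos < 0.0
        above = pos > L
        if not (below.any() or above.any()):
            break
        hit_floor |= below
        hit_ceiling |= above
        pos[below] = -pos[below]
        pos[above] = 2.0 * L - pos[above]
    return pos, hit_floor, hit_ceiling


def run_reflective(
    n: int,
    L: float,
    D: float,
    scheme: BinningScheme,
    plane_x: float,
    frames: int,
    seed,
) -> EventLog:
    """Reflective-box run counting wall hits and interior-plane crossings.

    Molecules start uniformly distributed in [0, L].  Each observation frame
    consists of ``scheme.n_sub`` Gaussian sub-steps; after each sub-step
    positions are folded back into the box.  Per frame, the log records the
    number of distinct molecules that touched the floor, touched the
    ceiling, crossed ``plane_x`` downward (+ side to - side), and crossed it
    in either direction — each molecule at most once per frame per counter.
    """
    if not (0.0 < plane_x < L):
        raise ValueError(f"plane_x must lie strictly inside (0, {L}), got {plane_x!r}")
    ens = WalkerEnsemble.uniform(n, L, seed)
    dt_sub = scheme.dt_sub

    floor_c = np.zeros(frames, dtype=np.int64)
    ceil_c = np.zeros(frames, dtype=np.int64)
    cr_d = np.zeros(frames, dtype=np.int64)
    cr_nd = np.zeros(frames, dtype=np.int64)

    side = ens.pos > plane_x
    for f in range(frames):
        hit_fl = np.zeros(n, dtype=bool)
        hit_ce = np.zeros(n, dtype=bool)
        crossed_down = np.zeros(n, dtype=bool)
        crossed_any = np.zeros(n, dtype=bool)
        for _ in range(scheme.n_sub):
            step_gaussian(ens, D, dt_sub)
            ens.pos, fl, ce = reflect(ens.pos, L)
            hit_fl |= fl
            hit_ce |= ce
            new_side = ens.pos > plane_x
            changed = new_side != side
            crossed_any |= changed
            crossed_down |= changed & ~new_side  # was +, now -
            side = new_side
        floor_c[f] = hit_fl.sum()
        ceil_c[f] = hit_ce.sum()
        cr_d[f] = crossed_down.sum()
        cr_nd[f] = crossed_any.sum()

    times = (np.arange(frames) + 1) * scheme.dt_obs
    return EventLog(
        times=times,
        floor_hits=floor_c,
        ceiling_hits=ceil_c,
        cross_directional=cr_d,
        cross_either=cr_nd,
        adsorbed_cum=np.zeros(frames, dtype=np.int64),
    )


def run_absorbing(
    n: int,
    L: float,
    D: float,
    dt: float,
    frames: int,
    seed,
    hist_bins: int = 0,
    hist_every: int = 0,
):
    """Absorbing-floor run: capture on endpoint crossing, reflective ceiling.

    Per step (one step per frame), a molecule whose Gaussian endpoint lands
    below the floor is permanently removed and counted into the cumulative
    capture curve; a molecule crossing the ceiling is folded back.

    Parameters
    ----------
    hist_bins, hist_every:
        If both positive, record a concentration histogram with
        ``hist_bins`` uniform bins over [0, L] every ``hist_every`` frames.

    Returns
    -------
    (EventLog, histograms):
        ``histograms`` is a list of (t, counts) pairs; counts are raw
        molecules per bin (divide by bin width for a line density).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    ens = WalkerEnsemble.uniform(n, L, seed)
    sigma = np.sqrt(2.0 * D * dt)
    pos = ens.pos
    adsorbed = 0
    floor_c = np.zeros(frames, dtype=np.int64)
    cum = np.zeros(frames, dtype=np.int64)
    histograms: list[tuple[float, np.ndarray]] = []
    edges = np.linspace(0.0, L, hist_bins + 1) if hist_bins > 0 else None

    for f in range(frames):
        pos = pos + ens.rng.normal(0.0, sigma, size=pos.size)
        gone = pos < 0.0
        n_gone = int(gone.sum())
        if n_gone:
            adsorbed += n_gone
            pos = pos[~gone]
        # ceiling (and any rare multi-fold) reflection; floor already drained
        pos, _, _ = reflect(pos, L)
        floor_c[f] = n_gone
        cum[f] = adsorbed
        if edges is not None and hist_every > 0 and (f + 1) % hist_every == 0:
            counts, _ = np.histogram(pos, bins=edges)
            histograms.append(((f + 1) * dt, counts))

    times = (np.arange(frames) + 1) * dt
    log = EventLog(
        times=times,
        floor_hits=floor_c,
        ceiling_hits=np.zeros(frames, dtype=np.int64),
        cross_directional=np.zeros(frames, dtype=np.int64),
        cross_either=np.zeros(frames, dtype=np.int64),
        adsorbed_cum=cum,
    )
    return log, histograms


def crossing_probability_single_step(x0, D: float, dt: float):
    """Probability one Gaussian step from x0 >= 0 ends past the wall at 0.

    Phi(-x0 / sqrt(2*D*dt)) with Phi the standard normal CDF; the unit-test
    oracle for endpoint-based capture detection.
    """
    if np.any(np.asarray(x0) < 0):
        raise ValueError("x0 must be nonnegative")
    sigma = np.sqrt(2.0 * D * dt)
    return norm.cdf(-np.asarray(x0, dtype=float) / sigma)
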