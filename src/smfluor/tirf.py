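"""Donor-bleaching FRET from two-channel TIRF intensity trajectories.

Immobilized dual-labelled complexes are imaged until both dyes photobleach.
A trajectory is *usable* when the acceptor bleaches first in a single step
and the donor later bleaches in a single step to background — the "useful
bleaching sequence".  For such traces the FRET efficiency is obtained
γ-free from the donor channel alone:

    E = (I_d − I_da) / I_d

where I_da is the mean donor intensity while the acceptor is still active
and I_d the mean donor intensity after acceptor bleaching (both background
subtracted).  Averaging over seconds of frames essentially eliminates shot
noise from the estimate.

Bleach steps are located by binary segmentation: each channel is recursively
split at the change point that most reduces the within-segment squared
error, accepting a split only when the reduction exceeds a BIC-style
penalty scaled by the channel's estimated noise variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MIN_SEGMENT_FRAMES = 5


@dataclass
class Trajectory:
    """Frame-indexed donor/acceptor intensities for one molecule."""

    I_d: np.ndarray
    I_a: np.ndarray
    frame_period_ms: float = 100.0
    molecule_id: str = ""

    def __post_init__(self) -> None:
        self.I_d = np.asarray(self.I_d, dtype=float)
        self.I_a = np.asarray(self.I_a, dtype=float)
        if self.I_d.shape != self.I_a.shape:
            raise ValueError("donor and acceptor channels must have equal length")
        if self.frame_period_ms <= 0:
            raise ValueError("frame period must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.I_d.size)


@dataclass
class BleachAnalysis:
    B_d: float
    B_a: float
    acceptor_bleach_frame: int
    donor_bleach_frame: int
    usable: bool
    I_da: float = float("nan")
    I_d_alone: float = float("nan")
    E: float = float("nan")
    donor_steps: list[int] = field(default_factory=list)
    acceptor_steps: list[int] = field(default_factory=list)


def subtract_background(traj: Trajectory, tail_frames: int = 30):
    """Background from the post-bleach tail of each channel.

    B_d and B_a are the means of the last ``tail_frames`` frames (several
    seconds at the 100 ms frame period); both channels are shifted down by
    their background.  Returns (corrected trajectory, B_d, B_a).
    """
    if traj.n_frames <= tail_frames:
        raise ValueError(
            f"trajectory of {traj.n_frames} frames shorter than tail ({tail_frames})"
        )
    B_d = float(np.mean(traj.I_d[-tail_frames:]))
    B_a = float(np.mean(traj.I_a[-tail_frames:]))
    corrected = Trajectory(
        I_d=traj.I_d - B_d, I_a=traj.I_a - B_a,
        frame_period_ms=traj.frame_period_ms, molecule_id=traj.molecule_id,
    )
    return corrected, B_d, B_a


def _segment_cost(prefix: np.ndarray, prefix2: np.ndarray, lo: int, hi: int) -> float:
    """Within-segment squared error of x[lo:hi] about its mean (O(1) via prefix sums)."""
    n = hi - lo
    s = prefix[hi] - prefix[lo]
    s2 = prefix2[hi] - prefix2[lo]
    return s2 - s * s / n


def _best_split(prefix, prefix2, lo: int, hi: int):
    """Best single change point in x[lo:hi]; returns (index, cost reduction)."""
    if hi - lo < 2 * MIN_SEGMENT_FRAMES:
        return -1, 0.0
    base = _segment_cost(prefix, prefix2, lo, hi)
    cuts = np.arange(lo + MIN_SEGMENT_FRAMES, hi - MIN_SEGMENT_FRAMES + 1)
    nl = cuts - lo
    nr = hi - cuts
    sl = prefix[cuts] - prefix[lo]
    sr = prefix[hi] - prefix[cuts]
    s2l = prefix2[cuts] - prefix2[lo]
    s2r = prefix2[hi] - prefix2[cuts]
    cost = (s2l - sl * sl / nl) + (s2r - sr * sr / nr)
    k = int(np.argmin(cost))
    return int(cuts[k]), float(base - cost[k])


def find_change_points(x: np.ndarray) -> list[int]:
    """Step locations in a piecewise-constant-plus-noise signal.

    Binary segmentation with a BIC-style acceptance threshold
    2·σ²·ln(n) per split, σ estimated robustly from first differences
    (median absolute deviation), so noiseless staircases are segmented
    exactly and pure noise yields no splits.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * MIN_SEGMENT_FRAMES:
        return []
    prefix = np.concatenate(([0.0], np.cumsum(x)))
    prefix2 = np.concatenate(([0.0], np.cumsum(x * x)))
    diffs = np.diff(x)
    sigma = np.median(np.abs(diffs - np.median(diffs))) / 0.6745 / np.sqrt(2.0)
    scale = float(np.mean(np.abs(x))) + 1.0
    penalty = max(2.0 * sigma * sigma * np.log(n), 1e-9 * scale)

    cps: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        cut, gain = _best_split(prefix, prefix2, lo, hi)
        if cut < 0 or gain <= penalty:
            continue
        cps.append(cut)
        stack.append((lo, cut))
        stack.append((cut, hi))
    return sorted(cps)


def _classify_steps(x: np.ndarray, cps: list[int]):
    """Split change points into upward and downward steps by segment means."""
    bounds = [0, *cps, x.size]
    means = [float(np.mean(x[bounds[i]:bounds[i + 1]])) for i in range(len(bounds) - 1)]
    down = [cp for i, cp in enumerate(cps) if means[i + 1] < means[i]]
    up = [cp for i, cp in enumerate(cps) if means[i + 1] >= means[i]]
    return down, up, means


def detect_bleach_steps(traj: Trajectory) -> BleachAnalysis:
    """Locate bleach steps in a background-corrected trajectory.

    usable is True iff the acceptor channel shows exactly one downward step,
    the donor channel exactly one downward step that lands at background
    (zero after correction, within noise), and the acceptor step precedes
    the donor step.  Non-conforming traces (blinking, multi-step, wrong
    order) come back with usable=False rather than raising.
    """
    a_cps = find_change_points(traj.I_a)
    d_cps = find_change_points(traj.I_d)
    a_down, _, _ = _classify_steps(traj.I_a, a_cps)
    d_down, _, d_means = _classify_steps(traj.I_d, d_cps)

    usable = len(a_down) == 1 and len(d_down) == 1 and a_down[0] < d_down[0]
    acc_frame = a_down[0] if a_down else -1
    don_frame = d_down[0] if d_down else -1
    if usable:
        # donor must bleach *to background*: final-segment mean consistent with 0
        tail = traj.I_d[don_frame:]
        tol = 5.0 * np.std(tail) / np.sqrt(max(tail.size, 1)) + 0.05 * max(d_means) + 1e-9
        if abs(float(np.mean(tail))) > tol:
            usable = False
    return BleachAnalysis(
        B_d=0.0, B_a=0.0,
        acceptor_bleach_frame=acc_frame, donor_bleach_frame=don_frame,
        usable=usable, donor_steps=d_cps, acceptor_steps=a_cps,
    )


def donor_bleach_fret(
    traj: Trajectory,
    steps: BleachAnalysis,
    laser_on_frame: int = 0,
    min_region_frames: int = 5,
) -> BleachAnalysis:
    """FRET efficiency by the donor-bleaching method on a usable trace.

    I_da averages the donor channel from laser-on to the acceptor bleach,
    I_d_alone from the acceptor bleach to the donor bleach, and
    E = (I_d_alone − I_da)/I_d_alone.
    """
    if not steps.usable:
        raise ValueError("trajectory is not usable for donor-bleaching FRET")
    a, d = steps.acceptor_bleach_frame, steps.donor_bleach_frame
    if a - laser_on_frame < min_region_frames or d - a < min_region_frames:
        raise ValueError("averaging regions too short")
    I_da = float(np.mean(traj.I_d[laser_on_frame:a]))
    I_d_alone = float(np.mean(traj.I_d[a:d]))
    if I_d_alone == 0:
        raise ValueError("zero donor intensity after acceptor bleach; E undefined")
    steps.I_da = I_da
    steps.I_d_alone = I_d_alone
    steps.E = (I_d_alone - I_da) / I_d_alone
    return steps


def analyze_trajectory(traj: Trajectory, tail_frames: int = 30) -> BleachAnalysis:
    """Full per-molecule chain: background → step detection → efficiency."""
    corrected, B_d, B_a = subtract_background(traj, tail_frames)
    steps = detect_bleach_steps(corrected)
    steps.B_d, steps.B_a = B_d, B_a
    if steps.usable:
        try:
            steps = donor_bleach_fret(corrected, steps)
        except ValueError:
            steps.usable = False
    return steps
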