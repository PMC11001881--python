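"""Langevin dynamics of a dual-basin topology in reduced units.

BAOAB splitting (one force evaluation per step): with friction gamma and
temperature T (k_B = 1, masses 1),

    B: v += dt/2 f      A: x += dt/2 v
    O: v = c1 v + c2 xi,  c1 = exp(-gamma dt), c2 = sqrt(T (1 - c1^2))
    A: x += dt/2 v      B: v += dt/2 f

At gamma = 0, T = 0 the O step is the identity and the scheme reduces to
velocity Verlet (conservative NVE dynamics).  Defaults follow the refolding
protocol: dt = 0.002 tau, T = 0.67, snapshots every 1000 steps, run until
the monitored selection's best-fit RMSD to the target conformation drops
below 0.5 nm (5 A) or the step budget is exhausted.  Trajectories are
bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import kabsch
from .topology import DualBasinTopology


@dataclass
class SimulationParams:
    temperature: float = 0.67       # reduced
    dt: float = 0.002               # tau
    friction: float = 1.0           # 1/tau (not stated upstream; see docs)
    sample_stride: int = 1000       # steps between snapshots
    max_steps: int = 5_800_000      # 11600 tau at dt = 0.002
    stop_rmsd: float | None = 0.5   # nm; None disables the stop criterion
    seed: int = 0
    energy_bound: float = 1e8       # abort when |E_pot| exceeds this

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")


@dataclass
class Trajectory:
    frames: np.ndarray              # (n_frames, n_atoms, 3), nm
    times: np.ndarray               # tau
    potential_energy: np.ndarray
    kinetic_energy: np.ndarray
    termination: str                # "stop_rmsd" | "max_steps"
    monitored_rmsd: np.ndarray | None = None
    params: SimulationParams | None = None

    def __len__(self) -> int:
        return len(self.frames)


class RmsdMonitor:
    """Best-fit RMSD of a frame subset against reference coordinates (nm)."""

    def __init__(self, reference: np.ndarray,
                 selection: np.ndarray | None = None):
        reference = np.asarray(reference, dtype=float)
        if selection is None:
            selection = np.arange(len(reference))
        self.selection = np.asarray(selection, dtype=np.int64)
        if self.selection.size == 0:
            raise ValueError("empty RMSD selection")
        if len(reference) == len(self.selection):
            self.ref = reference
        else:
            self.ref = reference[self.selection]

    def __call__(self, frame: np.ndarray) -> float:
        frame = np.asarray(frame, dtype=float)
        if self.selection.max() >= len(frame):
            raise ValueError(
                f"selection indices up to {int(self.selection.max())} do "
                f"not fit a {len(frame)}-atom frame")
        sub = frame[self.selection]
        if sub.shape != self.ref.shape:
            raise ValueError(
                f"selection shape {sub.shape} does not match reference "
                f"{self.ref.shape}")
        _, _, rmsd = kabsch(sub, self.ref)
        return rmsd


def rmsd_to(reference: np.ndarray, selection: np.ndarray | None = None):
    """Callable computing best-fit (superposed) RMSD of a frame's selection
    against the reference, in the coordinate units supplied."""
    return RmsdMonitor(reference, selection)


def run_langevin(
    topology: DualBasinTopology,
    start: np.ndarray,
    params: SimulationParams,
    monitor: RmsdMonitor | None = None,
) -> Trajectory:
    """Integrate Langevin dynamics from ``start`` (nm).

    The monitor (if given) is evaluated at every snapshot; the run stops
    once it drops below ``params.stop_rmsd``.  Energy divergence beyond
    ``params.energy_bound`` aborts with the offending frame index.
    """
    from ._kernels import HAVE_NUMBA, baoab_chunk

    coords = np.array(start, dtype=float).reshape(topology.n_atoms, 3)
    rng = np.random.default_rng(params.seed)
    n = topology.n_atoms
    dt = params.dt
    c1 = float(np.exp(-params.friction * dt))
    c2 = float(np.sqrt(params.temperature * (1.0 - c1 * c1)))
    noisy = params.friction > 0 and params.temperature > 0

    vel = (np.sqrt(params.temperature) * rng.standard_normal((n, 3))
           if params.temperature > 0 else np.zeros((n, 3)))
    _, forces = topology.energy_forces(coords)
    use_kernel = HAVE_NUMBA and n <= 2000
    kargs = topology.kernel_args()

    frames, times, e_pot, e_kin, rmsds = [], [], [], [], []
    termination = "max_steps"

    def snapshot(step):
        frames.append(coords.copy())
        times.append(step * dt)
        pe = topology.energy(coords).total
        ke = 0.5 * float(np.sum(vel**2))
        e_pot.append(pe)
        e_kin.append(ke)
        if abs(pe) > params.energy_bound:
            raise RuntimeError(
                f"energy divergence at frame {len(frames) - 1} "
                f"(step {step}): E_pot = {pe:.3e}")
        if monitor is not None:
            rmsds.append(monitor(coords))
            if (params.stop_rmsd is not None
                    and rmsds[-1] < params.stop_rmsd):
                return True
        return False

    step = 0
    if snapshot(0):
        termination = "stop_rmsd"
        step = params.max_steps  # already at the target: no integration
    while step < params.max_steps:
        stride = min(params.sample_stride, params.max_steps - step)
        noise = (rng.standard_normal((stride, n, 3)) if noisy
                 else np.zeros((stride, n, 3)))
        if use_kernel:
            baoab_chunk(coords, vel, forces, noise, dt,
                        c1 if params.friction > 0 else 1.0,
                        c2 if noisy else 0.0, *kargs)
        else:
            for k in range(stride):
                vel += 0.5 * dt * forces
                coords += 0.5 * dt * vel
                if params.friction > 0:
                    vel *= c1
                    if noisy:
                        vel += c2 * noise[k]
                coords += 0.5 * dt * vel
                _, forces = topology.energy_forces(coords)
                vel += 0.5 * dt * forces
        step += stride
        if snapshot(step):
            termination = "stop_rmsd"
            break

    return Trajectory(
        frames=np.array(frames),
        times=np.array(times),
        potential_energy=np.array(e_pot),
        kinetic_energy=np.array(e_kin),
        termination=termination,
        monitored_rmsd=np.array(rmsds) if monitor is not None else None,
        params=params,
    )


def steepest_descent(topology: DualBasinTopology, coords: np.ndarray,
                     step: float = 1e-4, n_steps: int = 500) -> np.ndarray:
    """Crude energy minimisation (used to verify basin structure)."""
    x = np.array(coords, dtype=float)
    e_prev, f = topology.energy_forces(x)
    e_prev = e_prev.total
    gamma = step
    for _ in range(n_steps):
        fmax = np.abs(f).max()
        if fmax < 1e-6:
            break
        x_new = x + gamma * f
        e_new, f_new = topology.energy_forces(x_new)
        if e_new.total <= e_prev:
            x, f, e_prev = x_new, f_new, e_new.total
            gamma *= 1.2
        else:
            gamma *= 0.5
    return x
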