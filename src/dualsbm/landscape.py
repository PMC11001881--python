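"""Refolding-landscape analysis over native-contact order parameters.

Per frame:

* ``Q_X`` — fraction of a native-contact subset with current distance below
  ``lambda * r0`` (lambda defaults to 1.2; dual-basin contacts use the
  basin-specific r0 of the state whose Q is being computed);
* ``Q_ID`` — Q over the interdomain (NGN-KOW) contact subset;
* ``Q_diff = Q_KOWbeta - Q_KOWalpha`` — which fold the switch domain
  currently resembles;
* ``delta_d`` — NGN-KOW centre-of-geometry distance minus its value in the
  active-state reference (nm).

Landscapes are 2-D occupancy histograms over pairs of these parameters,
pooled across trajectories; per-state contact-probability maps and
first-passage event detection complete the analysis layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .langevin import Trajectory
from .shadow import ContactMap

FORMED_FACTOR = 1.2


def q_fraction(frame: np.ndarray, contacts, r0: np.ndarray | None = None,
               formed_factor: float = FORMED_FACTOR) -> float:
    """Fraction of the given native contacts formed in a frame (nm).

    ``contacts`` is a ContactMap, a list of Contact, or an (n, 2) index
    array with ``r0`` supplied separately.
    """
    idx, r0 = _contact_arrays(contacts, r0)
    if len(idx) == 0:
        raise ValueError("empty contact set: Q is undefined")
    frame = np.asarray(frame, dtype=float)
    d = np.linalg.norm(frame[idx[:, 1]] - frame[idx[:, 0]], axis=1)
    return float(np.mean(d < formed_factor * r0))


def contact_formed_matrix(frames: np.ndarray, contacts, r0=None,
                          formed_factor: float = FORMED_FACTOR) -> np.ndarray:
    """(n_frames, n_contacts) boolean formation matrix."""
    idx, r0 = _contact_arrays(contacts, r0)
    frames = np.asarray(frames, dtype=float)
    d = np.linalg.norm(frames[:, idx[:, 1]] - frames[:, idx[:, 0]], axis=2)
    return d < formed_factor * r0


def _contact_arrays(contacts, r0=None):
    if isinstance(contacts, ContactMap):
        contacts = contacts.contacts
    if r0 is not None:
        idx = np.asarray(contacts, dtype=np.int64).reshape(-1, 2)
        return idx, np.asarray(r0, dtype=float)
    idx = np.array([[c.i, c.j] for c in contacts], np.int64).reshape(-1, 2)
    r0 = np.array([c.r0 for c in contacts], dtype=float)
    return idx, r0


@dataclass
class OrderParameterDefs:
    """Contact subsets and selections defining the order parameters.

    Contact subsets are (index array, r0 array) pairs in the simulated
    topology's atom numbering; r0 values are basin-specific (alpha-state
    native distances for Q_KOWalpha, beta-state for Q_KOWbeta).
    """

    id_contacts: tuple[np.ndarray, np.ndarray]
    kow_alpha_contacts: tuple[np.ndarray, np.ndarray]
    kow_beta_contacts: tuple[np.ndarray, np.ndarray]
    ngn_atoms: np.ndarray
    kow_atoms: np.ndarray
    active_ref_distance: float           # nm, NGN-KOW cog distance in state B
    formed_factor: float = FORMED_FACTOR
    extra_groups: dict = field(default_factory=dict)  # name -> atom indices


@dataclass
class OrderParameterSeries:
    times: np.ndarray
    q_id: np.ndarray
    q_kow_alpha: np.ndarray
    q_kow_beta: np.ndarray
    delta_d: np.ndarray
    group_distances: dict = field(default_factory=dict)

    @property
    def q_diff(self) -> np.ndarray:
        return self.q_kow_beta - self.q_kow_alpha

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time": self.times,
            "q_id": self.q_id,
            "q_kow_alpha": self.q_kow_alpha,
            "q_kow_beta": self.q_kow_beta,
            "q_diff": self.q_diff,
            "delta_d": self.delta_d,
        }
        for name, dist in self.group_distances.items():
            data[f"d_{name}"] = dist
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6f")


def order_parameters(traj: Trajectory,
                     defs: OrderParameterDefs) -> OrderParameterSeries:
    """Per-frame order parameters of a trajectory (nm coordinates)."""
    frames = np.asarray(traj.frames, dtype=float)
    n_atoms = frames.shape[1]
    for idx, _ in (defs.id_contacts, defs.kow_alpha_contacts,
                   defs.kow_beta_contacts):
        if len(idx) and int(np.max(idx)) >= n_atoms:
            raise ValueError("order-parameter contacts do not match the "
                             "trajectory's topology")
    lam = defs.formed_factor
    q_id = contact_formed_matrix(frames, *defs.id_contacts,
                                 formed_factor=lam).mean(axis=1)
    q_a = contact_formed_matrix(frames, *defs.kow_alpha_contacts,
                                formed_factor=lam).mean(axis=1)
    q_b = contact_formed_matrix(frames, *defs.kow_beta_contacts,
                                formed_factor=lam).mean(axis=1)
    cog_ngn = frames[:, defs.ngn_atoms].mean(axis=1)
    cog_kow = frames[:, defs.kow_atoms].mean(axis=1)
    d = np.linalg.norm(cog_kow - cog_ngn, axis=1)
    group_distances = {}
    for name, atoms in defs.extra_groups.items():
        cog = frames[:, np.asarray(atoms, dtype=np.int64)].mean(axis=1)
        group_distances[name] = np.linalg.norm(cog - cog_kow, axis=1)
    return OrderParameterSeries(
        times=np.asarray(traj.times),
        q_id=q_id,
        q_kow_alpha=q_a,
        q_kow_beta=q_b,
        delta_d=d - defs.active_ref_distance,
        group_distances=group_distances,
    )


def make_order_parameter_defs(
    cmap_a: ContactMap,
    cmap_b: ContactMap,
    model_b,
    groups,
    model_a=None,
    ngn_group: str = "NGN",
    kow_group: str = "KOW",
    exclusive: bool = True,
    formed_factor: float = FORMED_FACTOR,
) -> OrderParameterDefs:
    """Order-parameter definitions from two classified contact maps.

    Q_KOWalpha/Q_KOWbeta use each state's intra-KOW native contacts; with
    ``exclusive=True`` (default) only fold-discriminating pairs are kept:
    a pair is dropped if it is a native contact of the other state, or (when
    ``model_a`` is given) if its distance in the other state's native
    structure already satisfies the formed criterion — such pairs read as
    "formed" in either fold and carry no fold information.
    Q_ID uses the state-A interdomain set.  The reference NGN-KOW distance
    comes from the state-B (active) model.
    """
    from .shadow import ANGSTROM_PER_NM, interdomain_subset

    def kow_pairs(cmap):
        return {(c.i, c.j): c.r0 for c in cmap.contacts
                if c.groups == (kow_group, kow_group)}

    pa, pb = kow_pairs(cmap_a), kow_pairs(cmap_b)
    if exclusive:
        keep_a = sorted(set(pa) - set(pb))
        keep_b = sorted(set(pb) - set(pa))
        if model_a is not None:
            coords_a = model_a.coords / ANGSTROM_PER_NM
            coords_b_nm = model_b.coords / ANGSTROM_PER_NM

            def unformed_in(coords, pairs, source):
                out = []
                for i, j in pairs:
                    d = float(np.linalg.norm(coords[j] - coords[i]))
                    if d >= formed_factor * source[(i, j)]:
                        out.append((i, j))
                return out

            # alpha pairs must be unformed in the beta-native structure
            keep_a = unformed_in(coords_b_nm, keep_a, pa)
            # beta pairs must be unformed in the alpha-native structure
            keep_b = unformed_in(coords_a, keep_b, pb)
    else:
        keep_a, keep_b = sorted(pa), sorted(pb)
    if not keep_a or not keep_b:
        raise ValueError("state-exclusive KOW contact subsets are empty")
    idc = interdomain_subset(cmap_a, ngn_group, kow_group)
    if not len(idc):
        raise ValueError("no interdomain contacts in the state-A map")

    def arrays(pairs, source):
        idx = np.array(pairs, dtype=np.int64).reshape(-1, 2)
        return idx, np.array([source[p] for p in pairs], dtype=float)

    ngn_atoms = np.flatnonzero(groups.mask(model_b, ngn_group))
    kow_atoms = np.flatnonzero(groups.mask(model_b, kow_group))
    coords_b = model_b.coords / ANGSTROM_PER_NM
    ref = float(np.linalg.norm(coords_b[kow_atoms].mean(axis=0)
                               - coords_b[ngn_atoms].mean(axis=0)))
    id_idx, id_r0 = _contact_arrays(idc.contacts)
    return OrderParameterDefs(
        id_contacts=(id_idx, id_r0),
        kow_alpha_contacts=arrays(keep_a, pa),
        kow_beta_contacts=arrays(keep_b, pb),
        ngn_atoms=ngn_atoms,
        kow_atoms=kow_atoms,
        active_ref_distance=ref,
        formed_factor=formed_factor,
    )


_PARAM_RANGES = {
    "q_id": (0.0, 1.0),
    "q_kow_alpha": (0.0, 1.0),
    "q_kow_beta": (0.0, 1.0),
    "q_diff": (-1.0, 1.0),
}


def landscape_histogram(series_list, x: str, y: str, bins: int = 40,
                        x_range=None, y_range=None):
    """Pooled 2-D occupancy histogram over two order parameters.

    Counts every frame of every series once (the grid sum equals the total
    number of frames).  When projecting against ``q_id``, frames with
    Q_ID = 0 carry no interdomain information; the caller may instead use
    ``delta_d`` on that axis (the convention used for fully dissociated
    frames).
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("no order-parameter series given")
    frames = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    for name in (x, y):
        if name not in frames.columns:
            raise KeyError(f"unknown order parameter {name!r}")
    xv = frames[x].to_numpy()
    yv = frames[y].to_numpy()

    def _range(name, values, given):
        if given is not None:
            return given
        if name in _PARAM_RANGES:
            return _PARAM_RANGES[name]
        lo, hi = float(values.min()), float(values.max())
        pad = 1e-9 + 0.05 * (hi - lo)
        return (lo - pad, hi + pad)

    xr = _range(x, xv, x_range)
    yr = _range(y, yv, y_range)
    # clip into range so every frame lands in a bin (conservation)
    xv = np.clip(xv, xr[0], np.nextafter(xr[1], -np.inf))
    yv = np.clip(yv, yr[0], np.nextafter(yr[1], -np.inf))
    counts, xe, ye = np.histogram2d(xv, yv, bins=bins, range=[xr, yr])
    return counts, xe, ye


@dataclass
class StateWindow:
    """Rectangular state definition in a 2-D order-parameter plane."""

    name: str
    x: str
    y: str
    x_bounds: tuple[float, float]
    y_bounds: tuple[float, float]

    def mask(self, series: OrderParameterSeries) -> np.ndarray:
        frame = series.to_frame()
        xv = frame[self.x].to_numpy()
        yv = frame[self.y].to_numpy()
        return ((xv >= self.x_bounds[0]) & (xv <= self.x_bounds[1])
                & (yv >= self.y_bounds[0]) & (yv <= self.y_bounds[1]))


def contact_probability_map(trajectories, series_list, window: StateWindow,
                            layers: dict, residue_of_atom: np.ndarray,
                            formed_factor: float = FORMED_FACTOR):
    """Per-residue-pair contact-formation probabilities within a state.

    ``layers`` maps layer name (e.g. KOWalpha / KOWbeta / ID) to an
    (index array, r0 array) contact subset; ``residue_of_atom`` maps atom
    index to a residue label.  Returns {layer: DataFrame(res_i, res_j, p)}.
    """
    pooled_frames = []
    for traj, series in zip(trajectories, series_list):
        m = window.mask(series)
        if m.any():
            pooled_frames.append(np.asarray(traj.frames)[m])
    if not pooled_frames:
        raise ValueError(f"state window {window.name!r} contains no frames")
    frames = np.concatenate(pooled_frames, axis=0)
    out = {}
    for layer, (idx, r0) in layers.items():
        formed = contact_formed_matrix(frames, idx, r0,
                                       formed_factor=formed_factor)
        res_i = residue_of_atom[idx[:, 0]]
        res_j = residue_of_atom[idx[:, 1]]
        df = pd.DataFrame({
            "res_i": np.minimum(res_i, res_j),
            "res_j": np.maximum(res_i, res_j),
            "formed": formed.mean(axis=0),
        })
        # a residue pair is formed when ANY of its atom contacts is formed
        any_formed = []
        for (ri, rj), grp in df.groupby(["res_i", "res_j"]).groups.items():
            cols = formed[:, np.asarray(grp)]
            any_formed.append((ri, rj, float(cols.any(axis=1).mean())))
        out[layer] = pd.DataFrame(any_formed,
                                  columns=["res_i", "res_j", "p"])
    return out


@dataclass
class Event:
    kind: str
    time: float
    frame: int


def detect_events(series: OrderParameterSeries,
                  strand_contacts: dict | None = None,
                  frames: np.ndarray | None = None,
                  formation_threshold: float = 0.5,
                  dissociation_threshold: float = 0.30,
                  association_series: np.ndarray | None = None,
                  association_threshold: float = 0.75,
                  formed_factor: float = FORMED_FACTOR) -> list[Event]:
    """First-passage events of one trajectory.

    * strand-pair formation: first frame where a strand-pair contact
      fraction reaches ``formation_threshold`` (one event kind per entry of
      ``strand_contacts``, which maps name -> (index array, r0 array) and
      requires ``frames``);
    * domain dissociation: first frame with Q_ID <= dissociation threshold
      (default 0.30, i.e. 70% of interdomain contacts broken);
    * association/locking: first frame where ``association_series`` (e.g.
      the alpha3-RNAP contact fraction) reaches ``association_threshold``.

    A threshold never crossed yields no event for that kind.
    """
    for name, value in (("formation", formation_threshold),
                        ("dissociation", dissociation_threshold),
                        ("association", association_threshold)):
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name} threshold must be in (0, 1)")
    events: list[Event] = []

    def first_crossing(values, cond) -> int | None:
        hits = np.flatnonzero(cond(np.asarray(values)))
        return int(hits[0]) if hits.size else None

    k = first_crossing(series.q_id, lambda v: v <= dissociation_threshold)
    if k is not None:
        events.append(Event("dissociation", float(series.times[k]), k))
    if strand_contacts:
        if frames is None:
            raise ValueError("strand-pair events require trajectory frames")
        for name, (idx, r0) in strand_contacts.items():
            frac = contact_formed_matrix(frames, idx, r0,
                                         formed_factor=formed_factor
                                         ).mean(axis=1)
            k = first_crossing(frac, lambda v: v >= formation_threshold)
            if k is not None:
                events.append(Event(f"formation:{name}",
                                    float(series.times[k]), k))
    if association_series is not None:
        k = first_crossing(association_series,
                           lambda v: v >= association_threshold)
        if k is not None:
            events.append(Event("association", float(series.times[k]), k))
    return sorted(events, key=lambda e: e.time)


def first_passage_histogram(events, bins) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of event times; counts conserve the number of events."""
    times = np.array([e.time for e in events], dtype=float)
    if times.size == 0:
        if np.ndim(bins) == 0:
            raise ValueError("empty event list needs explicit bin edges")
        return np.zeros(len(bins) - 1, dtype=int), np.asarray(bins, float)
    counts, edges = np.histogram(times, bins=bins)
    # events at/beyond the last edge still count (conservation)
    over = times > edges[-1]
    under = times < edges[0]
    counts[-1] += int(over.sum())
    counts[0] += int(under.sum())
    return counts, edges
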