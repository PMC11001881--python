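"""Shared fixtures: toy systems, merged topologies, and a session-scoped
batch of refolding trajectories reused by landscape/event/acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from dualsbm import (build_single_basin, classify_contacts, make_two_state_toy,
                     merge_dual_basin, shadow_contact_map)
from dualsbm.fixtures import (TOY_SWITCHING_TEMPERATURE, ToySwitcherSpec,
                              make_symmetric_toy)
from dualsbm.landscape import make_order_parameter_defs, order_parameters
from dualsbm.langevin import SimulationParams, run_langevin


class ToyBundle:
    """Two-state switcher toy with its maps, topologies and parameter defs."""

    def __init__(self, spec: ToySwitcherSpec | None = None):
        self.model_a, self.model_b, self.groups = make_two_state_toy(spec)
        self.cmap_a = classify_contacts(
            shadow_contact_map(self.model_a), self.model_a, self.groups)
        self.cmap_b = classify_contacts(
            shadow_contact_map(self.model_b), self.model_b, self.groups)
        self.topo_a = build_single_basin(self.model_a, self.cmap_a)
        self.topo_b = build_single_basin(self.model_b, self.cmap_b)
        self.merged, self.report = merge_dual_basin(self.topo_a, self.topo_b)
        self.defs = make_order_parameter_defs(
            self.cmap_a, self.cmap_b, self.model_b, self.groups,
            model_a=self.model_a)
        self.start = self.model_a.coords / 10.0   # nm, alpha-docked state
        self.target = self.model_b.coords / 10.0


@pytest.fixture(scope="session")
def toy():
    return ToyBundle()


@pytest.fixture(scope="session")
def sym_toy():
    model_a, model_b, groups = make_symmetric_toy()
    cmap_a = classify_contacts(shadow_contact_map(model_a), model_a, groups)
    cmap_b = classify_contacts(shadow_contact_map(model_b), model_b, groups)
    # dihedral_thresh=0 keeps the merged Hamiltonian exactly mirror
    # symmetric (every mirror-odd dihedral becomes an even two-well term)
    merged, _ = merge_dual_basin(
        build_single_basin(model_a, cmap_a),
        build_single_basin(model_b, cmap_b),
        dihedral_thresh=0.0,
    )

    def dock(cmap):
        rows = np.array(
            [[c.i, c.j, c.r0] for c in cmap.contacts
             if set(c.groups) == {"NGN", "KOW"}])
        return rows[:, :2].astype(np.int64), rows[:, 2]

    return {
        "model_a": model_a, "model_b": model_b, "merged": merged,
        "dock_a": dock(cmap_a), "dock_b": dock(cmap_b),
    }


N_REPLICAS = 20
REPLICA_TEMPERATURE = TOY_SWITCHING_TEMPERATURE
REPLICA_MAX_STEPS = 250_000   # 500 tau: scaled-down refolding campaign
                              # (all toy switching events finish < 200 tau)


@pytest.fixture(scope="session")
def refolding_batch(toy):
    """20 seeded refolding replicas of the toy at its switching temperature
    (the desk-scale stand-in for the 500-run campaign)."""
    trajectories = []
    series = []
    for seed in range(N_REPLICAS):
        params = SimulationParams(
            temperature=REPLICA_TEMPERATURE,
            max_steps=REPLICA_MAX_STEPS,
            sample_stride=1000,
            stop_rmsd=None,
            seed=seed,
        )
        traj = run_langevin(toy.merged, toy.start, params)
        trajectories.append(traj)
        series.append(order_parameters(traj, toy.defs))
    return {"trajectories": trajectories, "series": series}
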