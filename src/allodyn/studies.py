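"""Frozen synthetic study conditions used by the demo, tests and reports.

Three standard scenarios exercise the analysis stages on the synthetic
dimer, each sized to run on a single CPU in seconds to a few minutes:

* **landscape study** — single-block chains with a soft double well
  (1.0 kcal/mol barrier, slight tilt toward the near well so both wells
  are comparably populated once the radial Jacobian is accounted for) and
  low friction, so a 10^5-step run crosses the barrier dozens of times
  and the stationary populations equilibrate.  Used for free-energy
  recovery against the analytic marginal and for correlation-sign
  recovery (the breathing mode dominates the motion of these short
  chains).

* **crossing study** — the same geometry with a 3 kcal/mol (~5 kBT)
  barrier, the rare-transition regime accelerated sampling exists for.
  The boost threshold sits at the barrier top with a small acceleration
  parameter, nearly flattening the well-to-well profile.

* **network study** — the full 40-beads-per-chain dimer with four
  10-bead blocks per chain, whose contact graph (intra-block cliques plus
  single inter-block bridges) carries the planted community structure.
"""

from __future__ import annotations

from .core import Trajectory
from .synthetic import DimerModel, SimulationParams, build_dimer_model, simulate

LANDSCAPE_LAYOUT = [5]
LANDSCAPE_DOUBLEWELL = {"d1": 20.0, "d2": 28.0, "barrier": 1.0, "tilt": -0.02}
LANDSCAPE_PARAMS = dict(n_steps=100_000, dt=0.01, friction=0.25, stride=5)

CROSSING_LAYOUT = [5]
CROSSING_DOUBLEWELL = {"d1": 20.0, "d2": 28.0, "barrier": 3.0, "tilt": 0.0}
CROSSING_PARAMS = dict(n_steps=75_000, dt=0.01, friction=0.5, stride=10)
#: boost threshold at the barrier top; aggressive acceleration parameter
CROSSING_BOOST = (3.0, 0.15)

NETWORK_LAYOUT = [10, 10, 10, 10]
NETWORK_PARAMS = dict(n_steps=20_000, dt=0.005, friction=1.0, stride=10)


def landscape_model() -> DimerModel:
    return build_dimer_model(
        n_beads_per_chain=sum(LANDSCAPE_LAYOUT),
        community_layout=LANDSCAPE_LAYOUT,
        doublewell_spec=LANDSCAPE_DOUBLEWELL,
    )


def landscape_run(seed: int) -> tuple[DimerModel, Trajectory]:
    model = landscape_model()
    traj = simulate(model, SimulationParams(seed=seed, **LANDSCAPE_PARAMS))
    return model, traj


def crossing_model() -> DimerModel:
    return build_dimer_model(
        n_beads_per_chain=sum(CROSSING_LAYOUT),
        community_layout=CROSSING_LAYOUT,
        doublewell_spec=CROSSING_DOUBLEWELL,
    )


def crossing_pair(seed: int) -> tuple[DimerModel, Trajectory, Trajectory]:
    """Unboosted and boosted runs of equal length and seed."""
    model = crossing_model()
    unboosted = simulate(
        model, SimulationParams(seed=seed, boost=None, **CROSSING_PARAMS)
    )
    boosted = simulate(
        model, SimulationParams(seed=seed, boost=CROSSING_BOOST, **CROSSING_PARAMS)
    )
    return model, unboosted, boosted


def network_model() -> DimerModel:
    return build_dimer_model(
        n_beads_per_chain=sum(NETWORK_LAYOUT), community_layout=NETWORK_LAYOUT
    )


def network_run(seed: int) -> tuple[DimerModel, Trajectory]:
    model = network_model()
    traj = simulate(model, SimulationParams(seed=seed, **NETWORK_PARAMS))
    return model, traj
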