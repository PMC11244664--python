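"""Independent straight-line event-walk oracle for the delivery-time model.

Deliberately naive: a single cursor loop with inline physics (momentum
scaling, per-axis travel, spill bookkeeping), structured nothing like the
package's simulator, so agreement is meaningful.
"""

import math

import numpy as np

PROTON_M0 = 938.272


def pc(energy):
    return math.sqrt(energy * energy + 2.0 * energy * PROTON_M0)


def naive_walk(plan, p):
    """Return (events, gaps): events are (layer, t_start, t_end, mu, spill),
    gaps are (kind, t_start, t_end)."""
    events = []
    gaps = []
    t = 0.0
    spill = 0
    budget = p.max_mu_per_spill
    layers_in_spill = 1
    unlimited = p.max_mee_layers_per_spill is None
    eps = 1e-9 * p.max_mu_per_spill
    delivered_any = False
    for j, layer in enumerate(plan.layers):
        ratio = pc(p.max_energy) / pc(layer.energy)
        vx = p.scan_speed_x_max_energy * ratio * 1000.0  # mm/s
        vy = p.scan_speed_y_max_energy * ratio * 1000.0
        if j > 0:
            first_mu = layer.spots[0].mu
            can_continue = unlimited or layers_in_spill < p.max_mee_layers_per_spill
            if can_continue and p.recapture_efficiency * budget + eps >= first_mu:
                gaps.append(("layer_switch", t, t + p.mee_layer_switch_time))
                t += p.mee_layer_switch_time
                budget = p.recapture_efficiency * budget
                layers_in_spill += 1
            else:
                gaps.append(("spill_change", t, t + p.spill_change_time))
                t += p.spill_change_time
                spill += 1
                budget = p.max_mu_per_spill
                layers_in_spill = 1
        prev = None
        for spot in layer.spots:
            if prev is None:
                if delivered_any:
                    gaps.append(("spot_switch", t, t + p.magnet_prep_time))
                    t += p.magnet_prep_time
            else:
                dt = p.magnet_prep_time + max(
                    abs(spot.x - prev.x) / vx, abs(spot.y - prev.y) / vy
                )
                gaps.append(("spot_switch", t, t + dt))
                t += dt
            if budget + eps < spot.mu:
                gaps.append(("spill_change", t, t + p.spill_change_time))
                t += p.spill_change_time
                spill += 1
                budget = p.max_mu_per_spill
                layers_in_spill = 1
            dur = spot.mu / p.beam_current
            events.append((j, t, t + dur, spot.mu, spill))
            t += dur
            budget -= spot.mu
            prev = spot
            delivered_any = True
    return events, gaps


def random_toy_plan(rng, max_mu=18.0):
    """Random small plan: <=4 layers, <=20 spots each, energies descending."""
    from pbs4d.plan import EnergyLayer, Spot, TreatmentPlan

    n_layers = int(rng.integers(1, 5))
    energies = np.sort(rng.uniform(75.0, 228.0, size=n_layers))[::-1]
    layers = []
    for e in energies:
        n_spots = int(rng.integers(1, 21))
        spots = tuple(
            Spot(float(rng.uniform(-50, 50)), float(rng.uniform(-50, 50)),
                 float(rng.uniform(0.01, max_mu)))
            for _ in range(n_spots)
        )
        layers.append(EnergyLayer(float(e), spots))
    return TreatmentPlan(layers=tuple(layers))


def random_machine(rng):
    from pbs4d.machine import MachineParameters

    kmax = rng.choice([1, 2, 4, 16, None])
    return MachineParameters(
        name="random",
        scan_speed_x_max_energy=float(rng.uniform(3, 50)),
        scan_speed_y_max_energy=float(rng.uniform(3, 120)),
        magnet_prep_time=float(rng.uniform(0.0005, 0.003)),
        spill_change_time=float(rng.uniform(0.5, 3.0)),
        max_mu_per_spill=float(rng.uniform(18, 70)),
        max_mee_layers_per_spill=None if kmax is None else int(kmax),
        recapture_efficiency=float(rng.uniform(0.0, 1.0)),
        mee_layer_switch_time=float(rng.uniform(0.05, 0.5)),
        beam_current=float(rng.uniform(5, 50)),
    )
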