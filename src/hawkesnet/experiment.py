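"""Seed-swept experiment orchestration: generate -> analyse -> (simulate).

A run config is a plain dict (usually loaded from YAML):

    seed: 1                 # master seed
    n_seeds: 3              # replicates (child networks)
    network:
      model: random         # random | ring | hub | patchy
      params: {n: 500, frac_inhib: 0.2, p: 0.1, w_exc: 0.02, w_inh: -0.1}
    theory: {y0: 1.0, max_order: 10}
    ring: {max_order: 20}        # optional distance analytics (ring/patchy nets)
    simulate: {duration: 60.0, warmup: 5.0, y0_rate: 10.0}   # optional
    estimate: {bin: 0.5}                                     # optional

Child seeds follow a documented counter scheme so every stage is
reproducible from the master seed alone:
``child = master * 10_000 + stage_index * 100 + replicate`` with stage
indices 0 (network) and 1 (simulation).
"""

from __future__ import annotations

import numpy as np

from . import netgen, ring, theory
from .simulate import SimConfig, estimate as estimate_counts, simulate as run_simulation
from .errors import ParameterError
from .network import Network, RingProfile

__all__ = ["build_network", "child_seed", "run_experiment"]

_STAGE_NETWORK = 0
_STAGE_SIMULATE = 1


def child_seed(master: int, stage: int, replicate: int = 0) -> int:
    """Per-stage, per-replicate seed derived from the master seed."""
    return (int(master) * 10_000 + stage * 100 + replicate) % (2**31 - 1)


def build_network(model: str, params: dict, seed: int) -> Network:
    """Dispatch to the named generator."""
    params = dict(params)
    if model == "random":
        return netgen.make_random(seed=seed, **params)
    if model == "ring":
        for key in ("profile_exc", "profile_inh"):
            if isinstance(params.get(key), dict):
                params[key] = RingProfile(**params[key])
        return netgen.make_ring(seed=seed, **params)
    if model == "hub":
        return netgen.make_hub_network(seed=seed, **params)
    if model == "patchy":
        return netgen.make_patchy(seed=seed, **params)
    raise ParameterError(f"unknown network model: {model!r}")


def _theory_block(net: Network, y0: float, max_order: int) -> dict:
    res = theory.analyse_network(net, y0)
    terms = theory.series_terms(net, res.rates, max_order, with_matrices=False)
    contrib = theory.average_contributions(terms)
    spec = theory.spectrum_report(net)
    return {
        "mean_rate": float(res.rates.mean()),
        "avg_correlation": res.avg_correlation,
        "population_variance": res.population_variance,
        "order_contributions": contrib.total,
        "order_chain": contrib.chain,
        "order_common_input": contrib.common_input,
        "spectral_radius": spec.spectral_radius,
        "max_real_part": spec.max_real_part,
        "predicted_bulk_radius": spec.predicted_bulk_radius,
        "predicted_mean_outlier": spec.predicted_mean_outlier,
        "_result": res,
    }


def run_experiment(config: dict) -> dict:
    """Execute the configured pipeline over seeds; aggregate means and SEs."""
    master = int(config.get("seed", 0))
    n_seeds = int(config.get("n_seeds", 1))
    net_cfg = config["network"]
    th_cfg = dict(config.get("theory", {}))
    y0 = float(th_cfg.get("y0", 1.0))
    max_order = int(th_cfg.get("max_order", 10))

    replicates = []
    for r in range(n_seeds):
        stage = "generate"
        try:
            net = build_network(net_cfg["model"], net_cfg.get("params", {}), child_seed(master, _STAGE_NETWORK, r))
            stage = "theory"
            block = _theory_block(net, y0, max_order)
            res = block.pop("_result")
            if "ring" in config:
                stage = "ring"
                if net.positions is None:
                    raise ParameterError("ring analytics need a network with ring positions")
                block["distance_correlation"] = ring.distance_correlation_numeric(
                    res.covariance, net.positions
                )
            if "simulate" in config:
                stage = "simulate"
                sim_cfg = SimConfig(seed=child_seed(master, _STAGE_SIMULATE, r), **config["simulate"])
                spikes = run_simulation(net, sim_cfg)
                stage = "estimate"
                stats = estimate_counts(spikes, float(config.get("estimate", {}).get("bin", 0.5)))
                block["sim_mean_rate"] = float(stats.rates_hat.mean())
                block["sim_mean_cv"] = float(np.nanmean(stats.cv))
                block["sim_pop_var"] = stats.pop_var_hat
                block["predicted_rates"] = res.rates * (sim_cfg.y0_rate / y0)
                block["estimated_rates"] = stats.rates_hat
            replicates.append(block)
        except Exception as err:
            raise RuntimeError(
                f"experiment stage '{stage}' failed for replicate {r} "
                f"(model={net_cfg['model']}): {err}"
            ) from err

    def agg(key: str) -> dict:
        vals = np.array([rep[key] for rep in replicates])
        se = vals.std(axis=0, ddof=1) / np.sqrt(n_seeds) if n_seeds > 1 else np.zeros_like(
            np.asarray(vals[0], dtype=float)
        )
        return {"mean": vals.mean(axis=0), "se": se}

    scalar_keys = [k for k in replicates[0] if k not in ("predicted_rates", "estimated_rates")]
    report = {
        "config": config,
        "seed": master,
        "n_seeds": n_seeds,
        "aggregate": {k: agg(k) for k in scalar_keys},
        "replicates": replicates,
    }
    return report
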