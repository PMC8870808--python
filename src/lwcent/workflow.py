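"""End-to-end evaluation workflow.

Runs the SIR ground truth once, ranks the network with each requested
method, and collects monotonicity, Kendall tau, imprecision and Jaccard
curves plus the score CCDF into a single serializable report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .evaluation import ccdf_curve, imprecision, jaccard_topk, kendall_tau, monotonicity
from .methods import method_ranking
from .ranking import Ranking
from .sir import InfluenceTable, SIRConfig, default_beta, influence_table

__all__ = ["EvalReport", "evaluate_network", "DEFAULT_P_GRID", "DEFAULT_T_LIST"]

DEFAULT_P_GRID = tuple(round(0.01 * i, 2) for i in range(1, 11))
DEFAULT_T_LIST = (10,)


@dataclass
class EvalReport:
    """Evaluation results for one network."""

    config: SIRConfig
    influence: InfluenceTable
    rankings: dict[str, Ranking]
    monotonicity: dict[str, float]
    kendall_tau: dict[str, float]
    imprecision: dict[str, dict[float, float]]
    jaccard: dict[str, dict[int, float]]
    ccdf: dict[str, pd.Series]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.rankings:
            rows.append(
                {
                    "method": name,
                    "monotonicity": self.monotonicity[name],
                    "kendall_tau": self.kendall_tau[name],
                }
            )
        return pd.DataFrame(rows)

    def curves_frame(self) -> pd.DataFrame:
        """Long-format imprecision / Jaccard / CCDF curves."""
        rows = []
        for name in self.rankings:
            for p, v in self.imprecision[name].items():
                rows.append({"method": name, "curve": "imprecision", "x": p, "value": v})
            for t, v in self.jaccard[name].items():
                rows.append({"method": name, "curve": "jaccard", "x": t, "value": v})
            for s, v in self.ccdf[name].items():
                rows.append({"method": name, "curve": "ccdf", "x": float(s), "value": v})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "sir": {
                "beta": self.config.beta,
                "gamma": self.config.gamma,
                "runs": self.config.runs,
                "rng_seed": self.config.rng_seed,
            },
            "monotonicity": self.monotonicity,
            "kendall_tau": self.kendall_tau,
            "imprecision": {
                m: {str(p): v for p, v in c.items()} for m, c in self.imprecision.items()
            },
            "jaccard": {
                m: {str(t): v for t, v in c.items()} for m, c in self.jaccard.items()
            },
        }


def evaluate_network(
    net: nx.Graph,
    methods: tuple[str, ...] = ("degree", "bc", "cc", "localc", "cld", "lwc"),
    beta: float | str = "auto",
    gamma: float = 1.0,
    runs: int = 100,
    rng_seed: int = 0,
    p_grid: tuple[float, ...] = DEFAULT_P_GRID,
    t_list: tuple[int, ...] = DEFAULT_T_LIST,
) -> EvalReport:
    """Run the full ranking-evaluation protocol on one network."""
    if beta == "auto":
        beta = default_beta(net)
    config = SIRConfig(beta=float(beta), gamma=gamma, runs=runs, rng_seed=rng_seed)
    influence = influence_table(net, config)
    truth = influence.ranking()

    rankings: dict[str, Ranking] = {m: method_ranking(net, m) for m in methods}
    report = EvalReport(
        config=config,
        influence=influence,
        rankings=rankings,
        monotonicity={},
        kendall_tau={},
        imprecision={},
        jaccard={},
        ccdf={},
    )
    n = net.number_of_nodes()
    for name, ranking in rankings.items():
        report.monotonicity[name] = monotonicity(ranking)
        report.kendall_tau[name] = kendall_tau(truth, ranking)
        report.imprecision[name] = {p: imprecision(influence, ranking, p) for p in p_grid}
        report.jaccard[name] = {
            t: jaccard_topk(truth, ranking, t) for t in t_list if 1 <= t <= n
        }
        report.ccdf[name] = ccdf_curve(ranking)
    return report
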