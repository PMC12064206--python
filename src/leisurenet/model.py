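"""Model/Results interface over the full diary-to-network pipeline.

:class:`LeisureNetworkModel` is built from a long-format diary table (or
a simulation config, or a CSV path) and holds the analysis settings —
similarity threshold, weighting, participation floor, cohesion method,
QAP permutation count. ``fit()`` runs ingestion filters, SWB grouping,
the 2-mode -> 1-mode projection for every (group x day type) cell,
the distribution indices, degree-centrality tables, cohesive-subgroup
decomposition, and the pairwise QAP correlation table, returning a
:class:`LeisureNetworkResults` with a ``summary()`` suitable for a
terminal and a ``save()`` that writes every artefact with a manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diary_io, metrics as metrics_mod
from .cohesion import CohesionResult, detect_cohesive_groups
from .diary_io import FilterReport, IncidenceMatrix
from .network import ActivityNetwork, project_to_network, prune_inactive_nodes
from .qap import qap_table
from .simulate import DAY_TYPES, SimulationConfig, generate_diaries

__all__ = ["LeisureNetworkModel", "LeisureNetworkResults"]

GROUPS = (diary_io.HIGH, diary_io.LOW)
CELLS = tuple((g, d) for d in DAY_TYPES for g in GROUPS)


def _cell_name(group: str, day_type: str) -> str:
    return f"{group}_{day_type}"


class LeisureNetworkModel:
    """Leisure-activity co-participation network analysis of a diary table.

    Parameters
    ----------
    diaries : DataFrame
        Long-format diary records in the canonical schema.
    tau : float
        Cosine-similarity threshold for edge retention (default 0.3).
    weighting : {"binary", "minutes"}
        Whether participation vectors are 0/1 or minute-weighted.
    min_participants : int
        Activities with fewer distinct participants are dropped before
        projection (default 2).
    prune : bool, min_degree, min_centrality
        Optional inactive-node pruning after projection; off by default
        because the distribution indices report isolates.
    cohesion_method : {"modularity_greedy", "louvain", "component"}
    qap_permutations : int
        Permutations per QAP pair (default 1000).
    """

    def __init__(self, diaries: pd.DataFrame, tau: float = 0.3,
                 weighting: str = "binary", min_participants: int = 2,
                 prune: bool = False, min_degree: int = 0,
                 min_centrality: float = float("inf"),
                 cohesion_method: str = "modularity_greedy",
                 qap_permutations: int = 1000):
        self.diaries = diaries
        self.tau = tau
        self.weighting = weighting
        self.min_participants = min_participants
        self.prune = prune
        self.min_degree = min_degree
        self.min_centrality = min_centrality
        self.cohesion_method = cohesion_method
        self.qap_permutations = qap_permutations

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "LeisureNetworkModel":
        """Build a model from a canonical diary CSV; rejects are kept on
        the model as ``.rejects``."""
        result = diary_io.read_diary(path)
        model = cls(result.records, **kwargs)
        model.rejects = result.rejects
        return model

    @classmethod
    def from_simulation(cls, config: SimulationConfig | None = None,
                        seed: int | None = None, **kwargs) -> "LeisureNetworkModel":
        """Build a model from the synthetic diary generator."""
        from .simulate import default_config

        if config is None:
            config = default_config(seed=seed if seed is not None else 0)
        elif seed is not None:
            config.seed = seed
        return cls(generate_diaries(config), **kwargs)

    def config_dict(self) -> dict:
        return {
            "tau": self.tau,
            "weighting": self.weighting,
            "min_participants": self.min_participants,
            "prune": self.prune,
            "min_degree": self.min_degree,
            "min_centrality": (None if self.min_centrality == float("inf")
                               else self.min_centrality),
            "cohesion_method": self.cohesion_method,
            "qap_permutations": self.qap_permutations,
        }

    def fit(self, seed: int = 0) -> "LeisureNetworkResults":
        """Run the full pipeline deterministically under ``seed``."""
        t0 = time.perf_counter()
        log: list[dict] = []

        filtered, report = diary_io.apply_inclusion_filters(self.diaries)
        filtered = filtered.assign(swb_group=diary_io.assign_swb_group(filtered))
        log.append({"stage": "filter", "n_input": report.n_input,
                    "n_output": report.n_output, "removed": report.n_removed})

        incidences: dict[str, IncidenceMatrix] = {}
        networks: dict[str, ActivityNetwork] = {}
        summaries: dict[str, metrics_mod.NetworkSummary] = {}
        centrality: dict[str, pd.DataFrame] = {}
        cohesion: dict[str, CohesionResult] = {}

        for group, day_type in CELLS:
            name = _cell_name(group, day_type)
            inc = diary_io.build_incidence(filtered, group, day_type)
            incidences[name] = inc
            net = project_to_network(inc, tau=self.tau, weighting=self.weighting,
                                     min_participants=self.min_participants)
            if self.prune:
                net, removed = prune_inactive_nodes(net, self.min_degree,
                                                    self.min_centrality)
                log.append({"stage": f"prune[{name}]", "removed": len(removed)})
            networks[name] = net
            summaries[name] = metrics_mod.summarize(net)
            if net.n_nodes >= 2:
                centrality[name] = metrics_mod.degree_centrality(net)
            else:
                centrality[name] = pd.DataFrame(
                    columns=["activity", "degree", "centrality", "index", "rank"])
            cohesion[name] = detect_cohesive_groups(net, method=self.cohesion_method,
                                                    seed=seed)
            log.append({"stage": f"network[{name}]", "n_persons": len(inc.persons),
                        "n_nodes": net.n_nodes, "n_edges": net.n_edges})

        qap = qap_table(networks, n_permutations=self.qap_permutations, seed=seed)
        log.append({"stage": "qap", "n_pairs": len(qap)})

        return LeisureNetworkResults(
            model=self,
            seed=seed,
            filter_report=report,
            incidences=incidences,
            networks=networks,
            summaries=summaries,
            centrality=centrality,
            cohesion=cohesion,
            qap=qap,
            log=log,
            elapsed=time.perf_counter() - t0,
        )


@dataclass
class LeisureNetworkResults:
    """Fitted artefacts for all four (group x day type) networks."""

    model: LeisureNetworkModel
    seed: int
    filter_report: FilterReport
    incidences: dict[str, IncidenceMatrix]
    networks: dict[str, ActivityNetwork]
    summaries: dict[str, metrics_mod.NetworkSummary]
    centrality: dict[str, pd.DataFrame]
    cohesion: dict[str, CohesionResult]
    qap: pd.DataFrame
    log: list[dict] = field(default_factory=list)
    elapsed: float = 0.0

    def summary_frame(self) -> pd.DataFrame:
        """Distribution indices, one row per network."""
        rows = []
        for name, s in self.summaries.items():
            rows.append({
                "network": name, "n_nodes": s.n_nodes, "n_edges": s.n_edges,
                "density": s.density, "inclusiveness": s.inclusiveness,
                "mean_distance": s.mean_distance,
                "isolated_nodes": s.isolated_count,
                "n_subgroups": self.cohesion[name].n_groups,
            })
        return pd.DataFrame(rows)

    def top_activities(self, network: str, k: int = 10) -> pd.DataFrame:
        return metrics_mod.top_k(self.centrality[network], k=k)

    def summary(self) -> str:
        """Printable report: distribution indices, top-5 activities per
        network, subgroup counts and the QAP correlation table."""
        lines = ["Leisure-activity network analysis", "=" * 60]
        lines.append(f"seed={self.seed}  tau={self.model.tau}  "
                     f"weighting={self.model.weighting}")
        fr = self.filter_report
        lines.append(f"records: {fr.n_input} in, {fr.n_output} kept "
                     f"(age {fr.removed_age}, duplicate {fr.removed_duplicate}, "
                     f"missing {fr.removed_missing})")
        lines.append("")
        lines.append("Network distribution indices")
        lines.append(self.summary_frame().round(3).to_string(index=False))
        lines.append("")
        for name in self.networks:
            top = self.top_activities(name, k=5)
            if len(top) == 0:
                continue
            lines.append(f"Top activities by degree centrality - {name}")
            lines.append(top[["rank", "activity", "index"]]
                         .head(8).to_string(index=False))
            lines.append("")
        lines.append("QAP correlations (pairwise, permutation p-values)")
        lines.append(self.qap.round(3).to_string(index=False))
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict:
        """Write every artefact under ``outdir`` plus a manifest with
        SHA-256 checksums; returns the manifest dict."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def emit(name: str, writer) -> None:
            path = outdir / name
            writer(path)
            written.append(path)

        emit("run_config.json", lambda p: p.write_text(json.dumps(
            {"seed": self.seed, **self.model.config_dict()}, indent=2)))
        emit("filter_report.json", lambda p: self.filter_report.to_json(p))
        emit("network_summaries.csv",
             lambda p: self.summary_frame().to_csv(p, index=False))
        emit("qap_correlations.csv", lambda p: self.qap.to_csv(p, index=False))
        for name, net in self.networks.items():
            emit(f"network_{name}.graphml", net.to_graphml)
            emit(f"network_{name}.edgelist.tsv", net.to_edgelist)
            emit(f"centrality_{name}.csv",
                 lambda p, n=name: self.centrality[n].to_csv(p, index=False))
            emit(f"cohesion_{name}.csv",
                 lambda p, n=name: self.cohesion[n].to_csv(p))
        manifest = {
            "seed": self.seed,
            "elapsed_seconds": round(self.elapsed, 3),
            "stages": self.log,
            "files": {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in written
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
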