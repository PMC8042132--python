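"""End-to-end pipeline wiring with deterministic run manifests.

Stages communicate only through documented file formats — no hidden state —
so any stage can be validated in isolation. One global integer seed expands
to per-stage seeds by a fixed schedule (expression: seed, corpus: seed+1,
traits: seed+2, gene sets: seed+3), and the manifest records input/output
checksums, parameters, seeds and the package version, enough to reproduce
every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

import guiltnet
from guiltnet import (
    build_network,
    correlation_matrix,
    demo_scenario,
    gamma_profile,
    knn_neighbors,
    ora,
    profile as profile_genes,
    quantile_normalize,
    read_corpus,
    read_expression,
    read_gmt,
    read_thesaurus,
    read_traits,
    screen_associations,
    write_corpus,
    write_expression,
    write_gmt,
    write_thesaurus,
    write_traits,
)
from guiltnet.commonality import results_frame

ALL_STAGES = ("simulate", "coexpress", "litnet", "gamma", "assoc", "enrich",
              "profile")


@dataclass
class RunConfig:
    """Pipeline parameters; defaults follow the analysis conventions
    (K=40 neighbors, min_shared=2, min_overlap=5, alpha=0.05,
    adjusted alpha=0.05)."""

    outdir: str = "runs/demo"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    k: int = 40
    min_shared: int = 2
    min_overlap: int = 5
    alpha: float = 0.05
    alpha_adj: float = 0.05
    z_cutoff: float = 3.5
    concept_types: tuple[str, ...] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        if cfg.concept_types is not None:
            cfg.concept_types = tuple(cfg.concept_types)
        return cfg

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if self.min_shared < 1:
            raise ValueError("min_shared must be >= 1")
        if self.min_overlap < 0:
            raise ValueError("min_overlap must be >= 0")
        for name, a in (("alpha", self.alpha), ("alpha_adj", self.alpha_adj)):
            if not (0 < a < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {', '.join(sorted(bad))}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    ran: list[str] = []

    def emit(name: str, path: Path) -> None:
        outputs[name] = _sha256(path)

    def path_of(name: str) -> Path:
        return out / name

    stages = set(config.stages)
    current = "setup"
    try:
        if "simulate" in stages:
            current = "simulate"
            scen = demo_scenario(config.seed)
            write_expression(scen["expression"], path_of("expression.tsv"))
            write_thesaurus(scen["thesaurus"], path_of("thesaurus.tsv"))
            write_corpus(scen["corpus"], path_of("corpus.jsonl"))
            write_traits(scen["traits"], path_of("traits.tsv"))
            write_gmt(scen["genesets"], path_of("genesets.gmt"))
            path_of("universe.txt").write_text(
                "\n".join(scen["universe"]) + "\n")
            truth = scen["truth"]
            path_of("truth.json").write_text(json.dumps({
                "modules": [
                    {"module_id": m.module_id, "gene_ids": list(m.gene_ids),
                     "rho": m.rho, "linked_concepts": list(m.linked_concepts)}
                    for m in truth.modules
                ],
                "trait_effects": [asdict(e) for e in truth.trait_effects],
                "enriched_sets": [list(p) for p in truth.enriched_sets],
            }, indent=1) + "\n")
            for f in ("expression.tsv", "thesaurus.tsv", "corpus.jsonl",
                      "traits.tsv", "genesets.gmt", "universe.txt",
                      "truth.json"):
                emit(f, path_of(f))
            ran.append("simulate")

        if "coexpress" in stages:
            current = "coexpress"
            expr = read_expression(path_of("expression.tsv"))
            nn = knn_neighbors(correlation_matrix(quantile_normalize(expr)),
                               config.k)
            nn.to_frame().to_csv(path_of("neighbors.tsv"), sep="\t",
                                 index=False, lineterminator="\n")
            emit("neighbors.tsv", path_of("neighbors.tsv"))
            ran.append("coexpress")

        if "litnet" in stages:
            current = "litnet"
            corpus = read_corpus(path_of("corpus.jsonl"))
            thes = read_thesaurus(path_of("thesaurus.tsv"))
            net = build_network(corpus, thes)
            net.edges_frame().to_csv(path_of("network_edges.tsv"), sep="\t",
                                     index=False, lineterminator="\n")
            net.nodes_frame().to_csv(path_of("network_nodes.tsv"), sep="\t",
                                     index=False, lineterminator="\n")
            emit("network_edges.tsv", path_of("network_edges.tsv"))
            emit("network_nodes.tsv", path_of("network_nodes.tsv"))
            ran.append("litnet")

        if "gamma" in stages:
            current = "gamma"
            import pandas as pd
            from guiltnet.coexpression import NeighborList
            from guiltnet.litnet import CooccurrenceNetwork
            nb = pd.read_csv(path_of("neighbors.tsv"), sep="\t")
            neighbors: dict[str, list[tuple[str, float]]] = {}
            for row in nb.itertuples(index=False):
                neighbors.setdefault(row.gene_id, []).append(
                    (row.neighbor_id, row.r))
            nn = NeighborList(config.k, neighbors)
            net = CooccurrenceNetwork.from_frames(
                pd.read_csv(path_of("network_nodes.tsv"), sep="\t"),
                pd.read_csv(path_of("network_edges.tsv"), sep="\t"),
            )
            universe = path_of("universe.txt").read_text().split()
            ctypes = set(config.concept_types) if config.concept_types else None
            per_gene = {
                g: gamma_profile(g, nn, net, universe, config.min_shared,
                                 concept_types=ctypes)
                for g in sorted(neighbors)
            }
            results_frame(per_gene).to_csv(
                path_of("commonalities.tsv"), sep="\t", index=False,
                lineterminator="\n")
            emit("commonalities.tsv", path_of("commonalities.tsv"))
            ran.append("gamma")

        if "assoc" in stages:
            current = "assoc"
            expr = read_expression(path_of("expression.tsv"))
            traits = read_traits(path_of("traits.tsv"))
            table, skipped = screen_associations(expr, traits, config.alpha)
            table.to_csv(path_of("assoc.tsv"), sep="\t", index=False,
                         lineterminator="\n")
            path_of("assoc_skipped.txt").write_text(
                "".join(s + "\n" for s in skipped))
            emit("assoc.tsv", path_of("assoc.tsv"))
            ran.append("assoc")

        if "enrich" in stages:
            current = "enrich"
            sets = read_gmt(path_of("genesets.gmt"))
            universe = path_of("universe.txt").read_text().split()
            truth = json.loads(path_of("truth.json").read_text())
            query = truth["modules"][0]["gene_ids"]
            table = ora(query, sets, universe, config.min_overlap,
                        config.alpha_adj)
            table.to_csv(path_of("enrichment.tsv"), sep="\t", index=False,
                         lineterminator="\n")
            emit("enrichment.tsv", path_of("enrichment.tsv"))
            ran.append("enrich")

        if "profile" in stages:
            current = "profile"
            expr = read_expression(path_of("expression.tsv"))
            profile_genes(expr, config.z_cutoff).to_csv(
                path_of("profile.tsv"), sep="\t", index=False,
                lineterminator="\n")
            emit("profile.tsv", path_of("profile.tsv"))
            ran.append("profile")
    except (ValueError, OSError, KeyError) as exc:
        raise StageError(current, str(exc)) from exc

    manifest = {
        "version": guiltnet.__version__,
        "seed": config.seed,
        "seed_schedule": {"expression": config.seed, "corpus": config.seed + 1,
                          "traits": config.seed + 2, "genesets": config.seed + 3},
        "parameters": {
            "k": config.k, "min_shared": config.min_shared,
            "min_overlap": config.min_overlap, "alpha": config.alpha,
            "alpha_adj": config.alpha_adj, "z_cutoff": config.z_cutoff,
            "concept_types": list(config.concept_types)
            if config.concept_types else None,
        },
        "stages_run": ran,
        "stages_skipped": [s for s in ALL_STAGES if s not in stages],
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
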