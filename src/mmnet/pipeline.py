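"""End-to-end orchestration: synth -> stats -> ordination -> correlations -> networks.

One :class:`RunConfig` drives the whole analysis for all experimental
groups. Correlations are computed within each group's samples only, so
each group gets its own heterogeneous network (the unit of output).
Every source of randomness is derived from the config seed, making a
rerun byte-identical; the run manifest records the config hash and
library versions.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, network, stats
from .correlate import CorrelationSet, cross_modal_spearman, metabolite_spearman, sparcc
from .synth import SyntheticConfig, generate_dataset
from .tables import (
    FeatureTable,
    GroupDesign,
    TableValidationError,
    export_graphml,
    read_feature_table,
    read_group_design,
    write_feature_table,
    write_group_design,
    write_manifest,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths or synthetic config plus thresholds and seeds for one run.

    Either ``synthetic`` is set (data are generated) or the three input
    paths are. ``contrasts`` lists (group A, group B) pairs for the
    differential stage; by default each exposure arm is compared with
    its diet-matched control and each diet pair is compared.
    """

    synthetic: SyntheticConfig | None = None
    microbes_path: str | None = None
    metabolites_path: str | None = None
    metadata_path: str | None = None
    kegg_mapping_path: str | None = None
    contrasts: list = field(default_factory=list)
    p_threshold: float = 0.05
    use_bh: bool = False
    sparcc_resamples: int = 20
    sparcc_permutations: int = 100
    layout_iterations: int = 50
    seed: int = 0
    outdir: str = "mmnet_run"

    def validate(self) -> None:
        if self.synthetic is None:
            missing = [
                name
                for name, p in [
                    ("microbes_path", self.microbes_path),
                    ("metabolites_path", self.metabolites_path),
                    ("metadata_path", self.metadata_path),
                ]
                if p is None or not Path(p).exists()
            ]
            if missing:
                raise PipelineError(
                    f"config: no synthetic config and missing input(s): {missing}"
                )
        if not (0 < self.p_threshold <= 1):
            raise PipelineError("config: p_threshold must be in (0, 1]")

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k != "synthetic"
        }
        d["synthetic"] = None if self.synthetic is None else self.synthetic.to_dict()
        d["contrasts"] = [list(c) for c in self.contrasts]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        d["contrasts"] = [tuple(c) for c in d.get("contrasts", [])]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _default_contrasts(groups) -> list:
    pairs = [
        ("Chow+GWI", "Chow"),
        ("WD", "Chow"),
        ("WD+GWI", "Chow+GWI"),
        ("WD+GWI", "WD"),
    ]
    usable = [(a, b) for a, b in pairs if a in groups and b in groups]
    if usable:
        return usable
    return [(groups[i], groups[0]) for i in range(1, len(groups))]


def _write_tsv(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, lineterminator="\n")


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        microbes, metabolites, design, truth = generate_dataset(config.synthetic)
        return microbes, metabolites, design, truth
    microbes = read_feature_table(config.microbes_path, "microbe", compositional=False)
    metabolites = read_feature_table(config.metabolites_path, "metabolite")
    design = read_group_design(config.metadata_path)
    return microbes, metabolites, design, None


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Per-group directories hold correlation sets, the GraphML network,
    the ATria ranking and layout coordinates; the top level holds the
    input tables, differential tables, ordination outputs, the
    network-specific metabolite lists and the run manifest. Any stage
    failure aborts with the stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    t0 = time.perf_counter()
    try:
        stage = "inputs"
        microbes, metabolites, design, truth = _load_inputs(config)
        design.check_covers(microbes.sample_ids)
        design.check_covers(metabolites.sample_ids)
        for g in design.groups:
            if len(design.samples(g)) == 0:
                raise TableValidationError(f"group {g!r} has no samples")
        write_feature_table(
            microbes, outdir / "microbes.tsv", outdir / "microbes.annotations.tsv"
        )
        write_feature_table(
            metabolites, outdir / "metabolites.tsv", outdir / "metabolites.annotations.tsv"
        )
        write_group_design(design, outdir / "metadata.tsv")
        if truth is not None:
            truth.to_json(outdir / "ground_truth.json")
        logger.info("inputs ready (%.1fs)", time.perf_counter() - t0)

        stage = "differential"
        contrasts = config.contrasts or _default_contrasts(design.groups)
        for table, label in ((microbes, "microbes"), (metabolites, "metabolites")):
            frames = [
                stats.differential_abundance(table, design, c, bh_correct=config.use_bh)
                for c in contrasts
            ]
            _write_tsv(pd.concat(frames), outdir / f"differential_{label}.tsv")
        volcano = pd.concat(
            {
                f"{a} vs {b}": stats.volcano_stats(metabolites, design, (a, b))
                for a, b in contrasts
            },
            names=["contrast", "feature_id"],
        )
        _write_tsv(volcano, outdir / "volcano_metabolites.tsv")

        stage = "ordination"
        alpha = diversity.alpha_diversity(microbes).to_frame()
        alpha["group"] = design.assignments.reindex(alpha.index)
        _write_tsv(alpha, outdir / "alpha_diversity.tsv")
        _write_tsv(diversity.bray_curtis_matrix(microbes), outdir / "bray_curtis.tsv")
        ordination = diversity.pca_metabolites(metabolites, design)
        _write_tsv(ordination.scores, outdir / "pca_scores.tsv")
        _write_tsv(
            pd.DataFrame(
                {"explained_variance_ratio": ordination.explained_variance_ratio},
                index=[f"PC{i+1}" for i in range(len(ordination.explained_variance_ratio))],
            ),
            outdir / "pca_explained_variance.tsv",
        )

        kegg_mapping = None
        if config.kegg_mapping_path:
            kegg_mapping = network.read_kegg_mapping(config.kegg_mapping_path)

        networks: dict = {}
        seeds = {"config": config.seed}
        group_seeds = np.random.SeedSequence(config.seed).generate_state(
            len(design.groups)
        ) % (2**31)
        for gi, group in enumerate(design.groups):
            stage = f"correlations[{group}]"
            gdir = outdir / f"group_{group.replace('+', 'p').replace(' ', '_')}"
            gdir.mkdir(exist_ok=True)
            samples = design.samples(group)
            sub_mic = microbes.subset_samples(samples)
            sub_met = metabolites.subset_samples(samples)
            seeds[group] = int(group_seeds[gi])
            mm, _state = sparcc(
                sub_mic,
                n_resamples=config.sparcc_resamples,
                n_permutations=config.sparcc_permutations,
                seed=int(group_seeds[gi]),
            )
            tt = metabolite_spearman(sub_met)
            mt = cross_modal_spearman(sub_mic, sub_met)
            corr = CorrelationSet.concat([mm, tt, mt])
            _write_tsv(corr.records, gdir / "correlations.tsv", index=False)

            stage = f"network[{group}]"
            net = network.build_heteronet(
                corr,
                group=group,
                microbe_table=microbes,
                metabolite_table=metabolites,
                design=design,
                p_threshold=config.p_threshold,
                use_bh=config.use_bh,
            )
            if kegg_mapping is not None:
                network.kegg_support(net, kegg_mapping)
            ranking = network.atria_rank(net)
            network.annotate_ranks(net, ranking)
            _write_tsv(ranking.to_frame(), gdir / "atria_ranking.tsv", index=False)
            coords = network.fruchterman_reingold(
                net, seed=int(group_seeds[gi]), iterations=config.layout_iterations
            )
            _write_tsv(
                pd.DataFrame(
                    [(n, xy[0], xy[1]) for n, xy in sorted(coords.items())],
                    columns=["node", "x", "y"],
                ),
                gdir / "layout.tsv",
                index=False,
            )
            export_graphml(net, gdir / "network.graphml")
            networks[group] = net
            logger.info("group %s done (%.1fs)", group, time.perf_counter() - t0)

        stage = "network_specific_metabolites"
        if len(networks) >= 2:
            specific = network.network_specific_metabolites(
                networks, metabolites, design
            )
            rows = []
            for grp in design.groups:
                frame = specific[grp]
                for met in frame.index:
                    rows.append({"group": grp, "metabolite": met,
                                 **frame.loc[met].to_dict()})
            _write_tsv(
                pd.DataFrame(rows, columns=["group", "metabolite", *design.groups]),
                outdir / "network_specific_metabolites.tsv",
                index=False,
            )

        stage = "manifest"
        write_manifest(outdir / "manifest.json", config.to_dict(), seeds)
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    logger.info("run complete in %.1fs -> %s", time.perf_counter() - t0, outdir)
    return outdir
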