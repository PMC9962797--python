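"""Synthetic four-arm microbiome/metabolome data with planted structure.

The generator emulates the statistical shape of a mouse fecal
shotgun-metagenomics + global-metabolomics study: a four-arm design
(chow or Western diet, crossed with Gulf War chemical exposure, six
animals per arm by default), sparse compositional species abundances
drawn from a multivariate log-normal basis and closed to fractions, and
log-normal ion-count-like metabolite intensities. Differential features
(group fold changes), microbe-microbe basis correlations and cross-modal
microbe-metabolite correlations can all be planted, and the planted
truth is returned alongside the tables so every downstream stage is
testable without any external data.

Species basis abundances follow SparCC's own generative assumption
(log-normal basis, closure afterward), so basis-correlation recovery can
be scored against known truth. Structural zeros are Bernoulli-masked
before closure with abundance-dependent probabilities: rare species are
the most zero-inflated, matching real metagenomes where absence
concentrates in the tail of the abundance distribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (
    DEFAULT_GROUP_ORDER,
    METABOLITE,
    MICROBE,
    FeatureTable,
    GroupDesign,
)

LN2 = math.log(2.0)

#: Fixed synthetic taxonomy used to label species with a phylum.
SYNTHETIC_PHYLA = (
    "Firmicutes",
    "Bacteroidetes",
    "Actinobacteria",
    "Proteobacteria",
    "Verrucomicrobia",
)

#: Fixed synthetic pathway classes used to label metabolites.
SYNTHETIC_PATHWAYS = (
    "lipid",
    "amino acid",
    "nucleotide",
    "carbohydrate",
    "vitamins and cofactors",
    "xenobiotics",
)


class InvalidConfigError(ValueError):
    """Raised when a synthetic configuration cannot produce valid data."""


def species_id(i: int) -> str:
    return f"sp{i + 1:03d}"


def metabolite_id(i: int) -> str:
    return f"met{i + 1:03d}"


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    ``group_effects`` plant log2 fold changes of a feature in one group,
    ``cross_links`` plant microbe->metabolite correlations against the
    (pre-closure) species basis, and ``basis_correlations`` plant
    microbe-microbe correlations into the log-normal basis.
    """

    n_groups: int = 4
    n_per_group: int = 6
    n_species: int = 40
    n_metabolites: int = 120
    sparsity: float = 0.3
    group_effects: list = field(default_factory=list)  # (feature_id, group, log2fc)
    #: (species_id, metabolite_id, rho) or (species_id, metabolite_id, rho, group)
    #: — with a group, the correlation exists only in that arm's samples
    cross_links: list = field(default_factory=list)
    basis_correlations: list = field(default_factory=list)  # (sp_a, sp_b, rho)
    noise_sd: float = 0.5
    seed: int = 0

    @property
    def group_names(self) -> tuple[str, ...]:
        if self.n_groups <= len(DEFAULT_GROUP_ORDER):
            return DEFAULT_GROUP_ORDER[: self.n_groups]
        extra = tuple(f"G{i + 1}" for i in range(len(DEFAULT_GROUP_ORDER), self.n_groups))
        return DEFAULT_GROUP_ORDER + extra

    @property
    def species_ids(self) -> list[str]:
        return [species_id(i) for i in range(self.n_species)]

    @property
    def metabolite_ids(self) -> list[str]:
        return [metabolite_id(i) for i in range(self.n_metabolites)]

    def sample_ids(self) -> list[str]:
        return [
            f"{g}-{i + 1}" for g in self.group_names for i in range(self.n_per_group)
        ]

    def validate(self) -> None:
        if self.n_groups < 1:
            raise InvalidConfigError("need at least one group")
        if self.n_per_group < 3:
            raise InvalidConfigError("group sizes must be >= 3")
        if not (0.0 <= self.sparsity <= 0.8):
            raise InvalidConfigError("sparsity must be in [0, 0.8]")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        known_features = set(self.species_ids) | set(self.metabolite_ids)
        groups = set(self.group_names)
        for fid, grp, _ in self.group_effects:
            if fid not in known_features:
                raise InvalidConfigError(f"planted effect on unknown feature {fid!r}")
            if grp not in groups:
                raise InvalidConfigError(f"planted effect in unknown group {grp!r}")
        for link in self.cross_links:
            sid, mid, rho = link[0], link[1], link[2]
            if sid not in set(self.species_ids):
                raise InvalidConfigError(f"cross_link references unknown species {sid!r}")
            if mid not in set(self.metabolite_ids):
                raise InvalidConfigError(f"cross_link references unknown metabolite {mid!r}")
            if abs(rho) > 1:
                raise InvalidConfigError(f"|target correlation| must be <= 1, got {rho}")
            if len(link) > 3 and link[3] is not None and link[3] not in groups:
                raise InvalidConfigError(f"cross_link restricted to unknown group {link[3]!r}")
        for a, b, rho in self.basis_correlations:
            if a not in set(self.species_ids) or b not in set(self.species_ids):
                raise InvalidConfigError(f"basis correlation on unknown species ({a!r}, {b!r})")
            if abs(rho) > 1:
                raise InvalidConfigError(f"|basis correlation| must be <= 1, got {rho}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("group_effects", "cross_links", "basis_correlations"):
            if key in d:
                d[key] = [tuple(item) for item in d[key]]
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure of one synthetic dataset.

    ``basis`` holds the latent pre-closure, pre-masking species
    abundances (features x samples) that cross-modal links were planted
    against.
    """

    differential: list  # (feature_id, group, log2fc)
    cross_links: list  # (species_id, metabolite_id, rho)
    basis_correlations: list  # (species_a, species_b, rho)
    basis: pd.DataFrame

    def to_json(self, path=None) -> str:
        payload = {
            "differential": [list(t) for t in self.differential],
            "cross_links": [list(t) for t in self.cross_links],
            "basis_correlations": [list(t) for t in self.basis_correlations],
            "basis": {
                "index": list(self.basis.index),
                "columns": list(self.basis.columns),
                "data": self.basis.to_numpy().tolist(),
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "GroundTruth":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        payload = json.loads(text)
        basis = pd.DataFrame(
            payload["basis"]["data"],
            index=payload["basis"]["index"],
            columns=payload["basis"]["columns"],
        )
        return cls(
            differential=[tuple(t) for t in payload["differential"]],
            cross_links=[tuple(t) for t in payload["cross_links"]],
            basis_correlations=[tuple(t) for t in payload["basis_correlations"]],
            basis=basis,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return (
            self.differential == other.differential
            and self.cross_links == other.cross_links
            and self.basis_correlations == other.basis_correlations
            and self.basis.equals(other.basis)
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _group_of_sample(config: SyntheticConfig) -> pd.Series:
    samples = config.sample_ids()
    groups = np.repeat(list(config.group_names), config.n_per_group)
    return pd.Series(groups, index=samples, name="group")


def make_design(config: SyntheticConfig) -> GroupDesign:
    return GroupDesign(_group_of_sample(config), config.group_names)


def _basis_correlation_cholesky(config: SyntheticConfig) -> np.ndarray:
    d = config.n_species
    corr = np.eye(d)
    sid_index = {s: i for i, s in enumerate(config.species_ids)}
    for a, b, rho in config.basis_correlations:
        i, j = sid_index[a], sid_index[b]
        corr[i, j] = corr[j, i] = rho
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise InvalidConfigError(
            "planted basis correlations do not form a positive-definite matrix"
        ) from exc


def generate_microbiome(config: SyntheticConfig):
    """Generate a closed species relative-abundance table plus ground truth.

    Returns ``(FeatureTable(kind="microbe"), GroundTruth)``. The ground
    truth's ``basis`` is the latent log-normal abundance matrix before
    zero-masking and closure.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    d, samples = config.n_species, config.sample_ids()
    n = len(samples)
    groups = _group_of_sample(config)

    # species log-means span ~a 20-fold abundance range (index 1 most
    # abundant); mild dominance keeps closure noise from swamping the
    # per-species signal, so planted basis structure stays recoverable
    mu = np.linspace(1.5, -1.5, d)

    chol = _basis_correlation_cholesky(config)
    z = chol @ rng.standard_normal((d, n))
    log_basis = mu[:, None] + config.noise_sd * z

    sid_index = {s: i for i, s in enumerate(config.species_ids)}
    for fid, grp, log2fc in config.group_effects:
        if fid in sid_index:
            mask = (groups == grp).to_numpy()
            log_basis[sid_index[fid], mask] += log2fc * LN2

    basis = np.exp(log_basis)

    # abundance-dependent structural zeros: absence concentrates steeply in
    # the rare tail (cubic in rarity rank), so masked mass — and hence the
    # noise masking injects into the closure denominator — stays small.
    # Average zero probability equals `sparsity`.
    if config.sparsity > 0:
        rarity = (np.arange(d) + 0.5) / d
        base_p = rarity**3
        scale = config.sparsity / base_p.mean()
        p_zero = np.clip(scale * base_p, 0.0, 0.95)
        for _ in range(30):  # rescale under the cap until the mean matches
            if p_zero.mean() >= config.sparsity - 1e-6 or scale > 1e6:
                break
            scale *= config.sparsity / p_zero.mean()
            p_zero = np.clip(scale * base_p, 0.0, 0.95)
        mask = rng.random((d, n)) < p_zero[:, None]
        masked = np.where(mask, 0.0, basis)
    else:
        masked = basis

    colsums = masked.sum(axis=0)
    dead = np.where(colsums <= 0)[0]
    if dead.size:
        raise InvalidConfigError(
            f"sparsity={config.sparsity} produced all-zero sample(s): "
            f"{[samples[j] for j in dead]}"
        )
    fractions = masked / colsums

    phyla = pd.Series(
        [SYNTHETIC_PHYLA[i % len(SYNTHETIC_PHYLA)] for i in range(d)],
        index=config.species_ids,
        name="annotation",
    )
    table = FeatureTable(
        pd.DataFrame(fractions, index=config.species_ids, columns=samples),
        MICROBE,
        phyla,
        compositional=True,
    )
    truth = GroundTruth(
        differential=[tuple(t) for t in config.group_effects],
        cross_links=[tuple(t) for t in config.cross_links],
        basis_correlations=[tuple(t) for t in config.basis_correlations],
        basis=pd.DataFrame(basis, index=config.species_ids, columns=samples),
    )
    return table, truth


def generate_metabolome(config: SyntheticConfig, microbiome_truth: GroundTruth | None = None) -> FeatureTable:
    """Generate log-normal ion-count intensities, honoring planted links.

    Each cross-link ``(s, m, rho)`` builds the log-intensity of ``m`` as
    ``rho * z_s + sqrt(1 - rho^2) * eps`` where ``z_s`` is the
    standardized log basis abundance of species ``s`` (so the target
    rank correlation survives the exponential, which is monotone).
    """
    config.validate()
    if config.cross_links and microbiome_truth is None:
        raise InvalidConfigError("cross_links planted but no microbiome basis given")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    m, samples = config.n_metabolites, config.sample_ids()
    n = len(samples)
    groups = _group_of_sample(config)

    # ion-count scale: intensities around 1e6 with ~1 decade of spread
    mu = np.log(1e6) + rng.normal(0.0, 1.0, size=m)
    log_int = mu[:, None] + config.noise_sd * rng.standard_normal((m, n))

    mid_index = {s: i for i, s in enumerate(config.metabolite_ids)}
    if config.cross_links:
        basis = microbiome_truth.basis
        for link in config.cross_links:
            sid, mid, rho = link[0], link[1], link[2]
            only_group = link[3] if len(link) > 3 else None
            if sid not in basis.index:
                raise InvalidConfigError(f"cross_link species {sid!r} absent from basis")
            in_scope = (
                np.ones(n, dtype=bool)
                if only_group is None
                else (groups == only_group).to_numpy()
            )
            log_s = np.log(basis.loc[sid].to_numpy())[in_scope]
            sd = log_s.std()
            if sd <= 0:
                raise InvalidConfigError(
                    f"cross_link species {sid!r} has zero variance; "
                    "cannot plant a correlation"
                )
            z_s = (log_s - log_s.mean()) / sd
            eps = rng.standard_normal(n)
            # unit-variance construct so the target correlation is exact;
            # out-of-scope samples keep independent unit-variance noise
            row = mu[mid_index[mid]] + eps.copy()
            row[in_scope] = mu[mid_index[mid]] + rho * z_s + math.sqrt(
                1.0 - rho * rho
            ) * eps[in_scope]
            log_int[mid_index[mid]] = row

    for fid, grp, log2fc in config.group_effects:
        if fid in mid_index:
            mask = (groups == grp).to_numpy()
            log_int[mid_index[fid], mask] += log2fc * LN2

    pathways = pd.Series(
        [SYNTHETIC_PATHWAYS[i % len(SYNTHETIC_PATHWAYS)] for i in range(m)],
        index=config.metabolite_ids,
        name="annotation",
    )
    return FeatureTable(
        pd.DataFrame(np.exp(log_int), index=config.metabolite_ids, columns=samples),
        METABOLITE,
        pathways,
        compositional=False,
    )


def generate_dataset(config: SyntheticConfig):
    """Full synthetic study: (microbes, metabolites, design, ground truth)."""
    microbes, truth = generate_microbiome(config)
    metabolites = generate_metabolome(config, truth)
    return microbes, metabolites, make_design(config), truth


def write_dataset(config: SyntheticConfig, outdir) -> dict:
    """Generate and write tables, metadata and ground truth to ``outdir``."""
    from .tables import write_feature_table, write_group_design

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    microbes, metabolites, design, truth = generate_dataset(config)
    paths = {
        "microbes": outdir / "microbes.tsv",
        "microbe_annotations": outdir / "microbes.annotations.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "metabolite_annotations": outdir / "metabolites.annotations.tsv",
        "metadata": outdir / "metadata.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_feature_table(microbes, paths["microbes"], paths["microbe_annotations"])
    write_feature_table(metabolites, paths["metabolites"], paths["metabolite_annotations"])
    write_group_design(design, paths["metadata"])
    truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
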