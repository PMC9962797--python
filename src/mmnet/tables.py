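"""Tabular and graph containers plus strict TSV/GraphML I/O.

Two in-memory containers anchor the pipeline: :class:`FeatureTable`
(a features x samples matrix of relative abundances or ion-count
intensities with per-feature annotations) and :class:`GroupDesign`
(the sample -> experimental-group map for the four-arm design).
All tabular I/O is tab-delimited UTF-8 with '.' decimals; networks are
exchanged as GraphML so typed node/edge attributes survive round-trips.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

MICROBE = "microbe"
METABOLITE = "metabolite"
KINDS = (MICROBE, METABOLITE)

#: Canonical order of the four experimental arms: chow or Western diet,
#: crossed with vehicle or Gulf War chemical (PB + permethrin) exposure.
DEFAULT_GROUP_ORDER = ("Chow", "Chow+GWI", "WD", "WD+GWI")

COMPOSITIONAL_TOL = 1e-6


class TableValidationError(ValueError):
    """Raised when a table violates its structural contract."""


@dataclass
class FeatureTable:
    """Features x samples numeric matrix with feature-level annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features, columns are samples. Non-negative.
    kind : str
        ``"microbe"`` (relative abundances) or ``"metabolite"``
        (ion-count-like intensities).
    annotations : pandas.Series, optional
        Feature id -> phylum (microbes) or biochemical-pathway label
        (metabolites).
    compositional : bool
        If True, every sample column must sum to 1 (within tolerance).
    """

    values: pd.DataFrame
    kind: str
    annotations: pd.Series | None = None
    compositional: bool = False

    def __post_init__(self) -> None:
        # normalize axis metadata so write->read round-trips compare equal
        self.values = self.values.rename_axis(index=None, columns=None)
        if self.annotations is not None:
            self.annotations = self.annotations.rename("annotation").rename_axis(None)
        self.validate()

    # -- contract ----------------------------------------------------------
    def validate(self) -> None:
        if self.kind not in KINDS:
            raise TableValidationError(f"unknown table kind {self.kind!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate feature id(s): {dup}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample id(s): {dup}")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise TableValidationError("non-numeric values in table body")
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise TableValidationError(
                f"non-numeric cell at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise TableValidationError(
                f"negative value at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        if self.compositional:
            sums = vals.sum(axis=0)
            bad = np.where(np.abs(sums - 1.0) > COMPOSITIONAL_TOL)[0]
            if bad.size:
                j = bad[0]
                raise TableValidationError(
                    f"sample {cols[j]!r} declared compositional but sums to "
                    f"{sums[j]:.6g}, not 1"
                )
        if self.annotations is not None:
            missing = self.annotations.index.difference(idx)
            if len(missing):
                raise TableValidationError(
                    f"annotations reference unknown feature(s): {list(missing)[:5]}"
                )

    # -- convenience -------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        sub = self.values.loc[:, list(sample_ids)].copy()
        if self.compositional:
            # subsetting samples keeps columns closed; features untouched
            pass
        return FeatureTable(sub, self.kind, self.annotations, self.compositional)

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, FeatureTable):
            return NotImplemented
        def _norm(s):
            return s.rename(None).rename_axis(None)

        ann_eq = (
            (self.annotations is None and other.annotations is None)
            or (
                self.annotations is not None
                and other.annotations is not None
                and _norm(self.annotations).equals(_norm(other.annotations))
            )
        )
        return (
            self.kind == other.kind
            and self.compositional == other.compositional
            and self.values.equals(other.values)
            and ann_eq
        )


@dataclass
class GroupDesign:
    """Sample -> group assignment with a canonical group order."""

    assignments: pd.Series  # index: sample id, value: group label
    group_order: tuple[str, ...] = DEFAULT_GROUP_ORDER

    def __post_init__(self) -> None:
        self.assignments = pd.Series(self.assignments)
        if self.assignments.index.duplicated().any():
            dup = self.assignments.index[self.assignments.index.duplicated()]
            raise TableValidationError(
                f"sample(s) assigned more than once: {dup.unique().tolist()}"
            )
        groups_seen = set(self.assignments.unique())
        order = [g for g in self.group_order if g in groups_seen]
        order += sorted(groups_seen - set(self.group_order))
        self.group_order = tuple(order)
        for g in self.group_order:
            if not (self.assignments == g).any():
                raise TableValidationError(f"group {g!r} has no samples")

    @property
    def groups(self) -> tuple[str, ...]:
        return self.group_order

    def samples(self, group: str) -> list[str]:
        if group not in self.group_order:
            raise KeyError(f"unknown group {group!r}")
        return list(self.assignments.index[self.assignments == group])

    def check_covers(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.assignments.index]
        if missing:
            raise TableValidationError(
                f"sample(s) missing from design: {missing[:10]}"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GroupDesign):
            return NotImplemented
        return (
            self.group_order == other.group_order
            and self.assignments.equals(other.assignments)
        )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_feature_table(
    path,
    kind: str,
    annotations_path=None,
    compositional: bool | None = None,
) -> FeatureTable:
    """Read a features x samples TSV (first column = feature id).

    ``compositional`` defaults to True for microbe tables; pass False to
    skip the closure check on non-closed microbial data.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise TableValidationError(
                f"{path.name}: non-numeric cell(s) in sample column {col!r}"
                f" at feature(s) {bad.tolist()[:5]}"
            )
    ann = None
    if annotations_path is not None:
        ann = read_annotations(annotations_path)
        ann = ann.reindex(df.index).dropna()
    if compositional is None:
        compositional = kind == MICROBE
    df = df.astype(float)
    return FeatureTable(df, kind, ann, compositional)


def write_feature_table(table: FeatureTable, path, annotations_path=None) -> None:
    path = Path(path)
    out = table.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", lineterminator="\n")
    if annotations_path is not None and table.annotations is not None:
        ann = table.annotations.rename("annotation")
        ann.index.name = "feature_id"
        ann.to_csv(annotations_path, sep="\t", lineterminator="\n")


def read_annotations(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(str)
    s.index = s.index.astype(str)
    return s


def read_group_design(path, group_order=DEFAULT_GROUP_ORDER) -> GroupDesign:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise TableValidationError(f"{Path(path).name}: need sample and group columns")
    s = pd.Series(
        df.iloc[:, 1].astype(str).to_numpy(),
        index=df.iloc[:, 0].astype(str),
        name="group",
    )
    s.index.name = "sample"
    return GroupDesign(s, tuple(group_order))


def write_group_design(design: GroupDesign, path) -> None:
    s = design.assignments.rename("group")
    s.index.name = "sample"
    s.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# GraphML I/O
# ---------------------------------------------------------------------------

NODE_ATTRS = ("node_type", "phylum_or_pathway", "mean_abundance", "rank")
EDGE_ATTRS = ("weight", "layer", "p_value", "kegg_supported")

_NODE_DEFAULTS = {"node_type": "", "phylum_or_pathway": "", "mean_abundance": 0.0, "rank": 0}
_EDGE_DEFAULTS = {"weight": 0.0, "layer": "", "p_value": 1.0, "kegg_supported": False}


def export_graphml(network: nx.Graph, path) -> None:
    """Write a heterogeneous network as GraphML plus a flat edge TSV.

    Edge signs are preserved verbatim (negative weights mark negative
    correlations). A ``<path>.edges.tsv`` sidecar is emitted for
    grep-ability.
    """
    g = network.copy()
    for _, data in g.nodes(data=True):
        for k, default in _NODE_DEFAULTS.items():
            data.setdefault(k, default)
    for _, _, data in g.edges(data=True):
        for k, default in _EDGE_DEFAULTS.items():
            data.setdefault(k, default)
    nx.write_graphml(g, str(path), infer_numeric_types=False)
    rows = [
        {"source": u, "target": v, **{k: d.get(k) for k in EDGE_ATTRS}}
        for u, v, d in sorted(g.edges(data=True))
    ]
    edge_df = pd.DataFrame(rows, columns=["source", "target", *EDGE_ATTRS])
    edge_df.to_csv(str(path) + ".edges.tsv", sep="\t", index=False, lineterminator="\n")


def import_graphml(path) -> nx.Graph:
    return nx.read_graphml(str(path))


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def write_manifest(path, config_dict: dict, seeds: dict) -> dict:
    """Record config hash, seeds and software versions for reproducibility.

    Deliberately contains no timestamps so that reruns are byte-identical.
    """
    import networkx
    import scipy
    import sklearn

    from . import __version__

    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seeds": seeds,
        "versions": {
            "mmnet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
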