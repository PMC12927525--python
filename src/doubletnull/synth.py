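"""Synthetic droplet scRNA-seq count data with known cluster structure.

The generator emulates the situation the doublet-null procedure is built
for: a UMI count matrix containing two transcriptionally distinct "parent"
clusters, optionally an injected dissociation-doublet cluster whose
expression mixes the two parents, optionally a genuine intermediate
("decoy") population that mixes the parents *and* carries its own unique
marker genes, and several unrelated background clusters.  Mitochondrial
genes are tagged by the ``mt-`` name prefix and per-cell sequencing depth
varies, so the standard QC filters have something to act on.

Counts follow a negative-binomial (gamma-Poisson) model: each cluster has
a relative expression profile (a shared baseline times cluster-specific
fold changes on its marker genes), each cell a log-normal library-size
multiplier, and counts are drawn NB with a single global size/dispersion
parameter.  Everything is deterministic given ``SynthConfig.seed``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ClusterSpec",
    "DoubletSpec",
    "DecoySpec",
    "SynthConfig",
    "GroundTruth",
    "generate_dataset",
    "write_10x",
    "benchmark_config",
]


@dataclass
class ClusterSpec:
    """One singlet cluster: a label, a size, and its marker genes.

    ``de_genes`` maps gene index -> multiplicative fold change applied to
    the shared baseline expression profile.
    """

    label: str
    n_cells: int
    de_genes: dict[int, float] = field(default_factory=dict)

    def validate(self, n_genes: int) -> None:
        if self.n_cells < 2:
            raise ValueError(
                f"cluster {self.label!r}: every cluster needs >= 2 cells, got {self.n_cells}"
            )
        for g, fc in self.de_genes.items():
            if not (0 <= g < n_genes):
                raise ValueError(f"cluster {self.label!r}: de_gene index {g} out of range")
            if fc <= 0:
                raise ValueError(
                    f"cluster {self.label!r}: effect size for gene {g} must be > 0, got {fc}"
                )


@dataclass
class DoubletSpec:
    """An injected artifact cluster mixing two parent clusters.

    ``mixing='count_sum'`` adds the expected molecule counts of two sampled
    parent cells (what a physical droplet doublet does) and then thins to a
    freshly sampled singlet-like library size; ``'count_mean'`` averages
    them instead, matching the in-silico mixing used by the null itself.
    """

    parent_a: str
    parent_b: str
    n_cells: int
    mixing: str = "count_sum"

    def validate(self, labels: set[str]) -> None:
        if self.parent_a not in labels or self.parent_b not in labels:
            raise ValueError(
                f"doublet parents ({self.parent_a!r}, {self.parent_b!r}) must be existing cluster labels"
            )
        if self.n_cells < 2:
            raise ValueError("doublet cluster needs >= 2 cells")
        if self.mixing not in ("count_sum", "count_mean"):
            raise ValueError(f"mixing must be 'count_sum' or 'count_mean', got {self.mixing!r}")


@dataclass
class DecoySpec:
    """A genuine intermediate population: parent mixture plus its own markers.

    Unlike a doublet, the decoy carries ``n_unique_markers`` genes at
    ``unique_effect_size``-fold that neither parent uses — the signature a
    real transitional cell type would show.
    """

    parent_a: str
    parent_b: str
    n_cells: int
    n_unique_markers: int = 50
    unique_effect_size: float = 8.0

    def validate(self, labels: set[str]) -> None:
        if self.parent_a not in labels or self.parent_b not in labels:
            raise ValueError(
                f"decoy parents ({self.parent_a!r}, {self.parent_b!r}) must be existing cluster labels"
            )
        if self.n_cells < 2:
            raise ValueError("decoy cluster needs >= 2 cells")
        if self.n_unique_markers < 1:
            raise ValueError("decoy needs >= 1 unique marker gene")
        if self.unique_effect_size <= 0:
            raise ValueError("unique_effect_size must be > 0")


@dataclass
class SynthConfig:
    n_genes: int
    clusters: list[ClusterSpec]
    n_mito_genes: int = 13
    doublet_spec: DoubletSpec | None = None
    decoy_spec: DecoySpec | None = None
    depth_lognormal_mu: float = np.log(2000.0)
    depth_lognormal_sigma: float = 0.45
    nb_dispersion: float = 2.0  # NB size; var = mu + mu^2/size
    mito_baseline_share: float = 0.03
    mito_cell_sigma: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.n_mito_genes <= self.n_genes):
            raise ValueError(
                f"n_mito_genes must satisfy 0 <= n_mito_genes <= n_genes "
                f"({self.n_mito_genes} vs {self.n_genes})"
            )
        if not self.clusters:
            raise ValueError("at least one cluster is required")
        labels = [c.label for c in self.clusters]
        if len(set(labels)) != len(labels):
            raise ValueError("cluster labels must be unique")
        for c in self.clusters:
            c.validate(self.n_genes)
        if self.doublet_spec is not None:
            self.doublet_spec.validate(set(labels))
        if self.decoy_spec is not None:
            self.decoy_spec.validate(set(labels))
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass
class GroundTruth:
    """What the generator knows and downstream stages must recover."""

    artifact_clusters: list[str]
    decoy_clusters: list[str]
    doublet_parents: dict[str, tuple[str, str]]
    cluster_markers: dict[str, list[str]]
    decoy_unique_markers: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "artifact_clusters": self.artifact_clusters,
            "decoy_clusters": self.decoy_clusters,
            "doublet_parents": {k: list(v) for k, v in self.doublet_parents.items()},
            "cluster_markers": self.cluster_markers,
            "decoy_unique_markers": self.decoy_unique_markers,
        }


def _gene_names(n_genes: int, n_mito: int) -> list[str]:
    names = [f"mt-gene{i}" for i in range(n_mito)]
    names += [f"gene{i}" for i in range(n_mito, n_genes)]
    return names


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, size: float) -> np.ndarray:
    """NB draws with mean mu and variance mu + mu^2/size (gamma-Poisson)."""
    out = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    p = size / (size + mu[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def generate_dataset(config: SynthConfig) -> tuple[ad.AnnData, pd.Series, GroundTruth]:
    """Generate (counts, cluster labels, ground truth) from a config.

    Returns an AnnData (cells x genes, sparse integer ``X``, ``var['mito']``
    flags, ``obs['cluster']``), a barcode-indexed label Series, and the
    :class:`GroundTruth` record.  Identical config + seed gives bitwise
    identical counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    n_mito = config.n_mito_genes
    gene_names = _gene_names(n_genes, n_mito)
    mito_mask = np.zeros(n_genes, dtype=bool)
    mito_mask[:n_mito] = True

    # Shared baseline relative-expression profile.  Non-mito weights are
    # log-normal (heavy-tailed, like real transcriptomes); mito genes share
    # a fixed fraction of the library.
    base = np.zeros(n_genes)
    nm = n_genes - n_mito
    w = rng.lognormal(0.0, 1.5, nm)
    base[n_mito:] = w / w.sum() * (1.0 - (config.mito_baseline_share if n_mito else 0.0))
    if n_mito:
        wm = rng.lognormal(0.0, 0.5, n_mito)
        base[:n_mito] = wm / wm.sum() * config.mito_baseline_share

    # Cluster-level relative profiles: baseline times marker fold changes.
    profiles: dict[str, np.ndarray] = {}
    markers: dict[str, list[str]] = {}
    for c in config.clusters:
        r = base.copy()
        for g, fc in c.de_genes.items():
            r[g] *= fc
        profiles[c.label] = r
        markers[c.label] = [gene_names[g] for g, fc in sorted(c.de_genes.items()) if fc > 1]

    blocks: list[np.ndarray] = []
    labels: list[str] = []
    # Per-cell expected-count vectors are kept for the parents so doublet
    # cells can mix actual sampled parent cells, not just cluster means.
    cell_mu: dict[str, np.ndarray] = {}
    cell_depth: dict[str, np.ndarray] = {}

    def _draw_cluster(label: str, n_cells: int, rel: np.ndarray) -> None:
        depth = rng.lognormal(config.depth_lognormal_mu, config.depth_lognormal_sigma, n_cells)
        mu = depth[:, None] * rel[None, :]
        if n_mito:
            mito_mult = rng.lognormal(0.0, config.mito_cell_sigma, n_cells)
            mu[:, :n_mito] *= mito_mult[:, None]
        cell_mu[label] = mu
        cell_depth[label] = mu.sum(axis=1)
        blocks.append(_nb_sample(rng, mu, config.nb_dispersion))
        labels.extend([label] * n_cells)

    for c in config.clusters:
        _draw_cluster(c.label, c.n_cells, profiles[c.label])

    artifact_clusters: list[str] = []
    doublet_parents: dict[str, tuple[str, str]] = {}
    if config.doublet_spec is not None:
        d = config.doublet_spec
        label = "doublet"
        ia = rng.integers(0, cell_mu[d.parent_a].shape[0], d.n_cells)
        ib = rng.integers(0, cell_mu[d.parent_b].shape[0], d.n_cells)
        mu = cell_mu[d.parent_a][ia] + cell_mu[d.parent_b][ib]
        if d.mixing == "count_sum":
            # physical doublet: summed molecules, thinned back to a
            # freshly sampled singlet-like library size
            new_depth = rng.lognormal(
                config.depth_lognormal_mu, config.depth_lognormal_sigma, d.n_cells
            )
            mu *= (new_depth / mu.sum(axis=1))[:, None]
        else:  # count_mean
            mu *= 0.5
        blocks.append(_nb_sample(rng, mu, config.nb_dispersion))
        labels.extend([label] * d.n_cells)
        artifact_clusters.append(label)
        doublet_parents[label] = (d.parent_a, d.parent_b)

    decoy_clusters: list[str] = []
    decoy_unique: dict[str, list[str]] = {}
    if config.decoy_spec is not None:
        d = config.decoy_spec
        label = "decoy"
        rel = 0.5 * (profiles[d.parent_a] + profiles[d.parent_b])
        parent_de = set()
        for c in config.clusters:
            if c.label in (d.parent_a, d.parent_b):
                parent_de |= set(c.de_genes)
        candidates = np.array(
            [g for g in range(n_mito, n_genes) if g not in parent_de], dtype=int
        )
        if candidates.size < d.n_unique_markers:
            raise ValueError(
                "not enough genes free of both parents' de_genes for decoy unique markers"
            )
        uniq = np.sort(rng.choice(candidates, d.n_unique_markers, replace=False))
        rel = rel.copy()
        rel[uniq] *= d.unique_effect_size
        _draw_cluster(label, d.n_cells, rel)
        decoy_clusters.append(label)
        decoy_unique[label] = [gene_names[g] for g in uniq]

    counts = np.vstack(blocks)
    barcodes = [f"cell{i:06d}" for i in range(counts.shape[0])]
    obs = pd.DataFrame({"cluster": pd.Categorical(labels)}, index=barcodes)
    var = pd.DataFrame({"mito": mito_mask}, index=gene_names)
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    truth = GroundTruth(
        artifact_clusters=artifact_clusters,
        decoy_clusters=decoy_clusters,
        doublet_parents=doublet_parents,
        cluster_markers=markers,
        decoy_unique_markers=decoy_unique,
    )
    return adata, pd.Series(labels, index=barcodes, name="cluster"), truth


def write_10x(
    adata: ad.AnnData,
    dir_path: str | os.PathLike,
    labels: pd.Series | None = None,
    truth: GroundTruth | None = None,
) -> None:
    """Write the 10x-convention triplet plus clusters.tsv / ground_truth.json.

    ``matrix.mtx`` is stored genes x cells (10x orientation); in-memory
    AnnData is cells x genes.  Round-trips losslessly through
    :func:`doubletnull.io.read_10x`.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("refusing to write an empty matrix")
    if labels is not None and len(labels) == 0:
        raise ValueError("label table is empty")
    os.makedirs(dir_path, exist_ok=True)
    X = sp.coo_matrix(adata.X.T)
    X = X.astype(np.int64)
    scipy.io.mmwrite(os.path.join(dir_path, "matrix.mtx"), X, field="integer")
    feat = pd.DataFrame(
        {
            "id": adata.var_names,
            "name": adata.var_names,
            "type": "Gene Expression",
        }
    )
    feat.to_csv(os.path.join(dir_path, "features.tsv"), sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        os.path.join(dir_path, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    if labels is not None:
        labels.to_csv(os.path.join(dir_path, "clusters.tsv"), sep="\t", header=False)
    if truth is not None:
        with open(os.path.join(dir_path, "ground_truth.json"), "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1)


def benchmark_config(
    seed: int,
    scenario: str = "doublet",
    n_clusters: int = 5,
    cells_per_cluster: int = 800,
    n_genes: int = 2000,
    hybrid_cells: int = 200,
    markers_per_cluster: int = 80,
    n_unique_markers: int = 50,
    unique_effect_size: float = 8.0,
) -> SynthConfig:
    """The standard test-bed: 5 background clusters plus one hybrid cluster.

    ``scenario='doublet'`` injects a count-sum doublet cluster between the
    first two clusters (the artifact case); ``scenario='decoy'`` injects a
    genuine intermediate with its own unique markers instead (the
    negative-control case).  Marker fold changes are drawn log-normally
    around 4-fold, the scale typical of markers separating distinct cell
    types.  Gene/marker assignment depends only on ``seed``.
    """
    if scenario not in ("doublet", "decoy"):
        raise ValueError(f"scenario must be 'doublet' or 'decoy', got {scenario!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    n_mito = 13
    usable = np.arange(n_mito, n_genes)
    perm = rng.permutation(usable)
    clusters = []
    for i in range(n_clusters):
        genes = perm[i * markers_per_cluster : (i + 1) * markers_per_cluster]
        folds = np.exp(rng.normal(np.log(4.0), 0.4, markers_per_cluster)).clip(2.0, None)
        clusters.append(
            ClusterSpec(
                label=f"c{i + 1}",
                n_cells=cells_per_cluster,
                de_genes={int(g): float(f) for g, f in zip(genes, folds)},
            )
        )
    doublet = decoy = None
    if scenario == "doublet":
        doublet = DoubletSpec("c1", "c2", hybrid_cells, mixing="count_sum")
    else:
        decoy = DecoySpec(
            "c1",
            "c2",
            hybrid_cells,
            n_unique_markers=n_unique_markers,
            unique_effect_size=unique_effect_size,
        )
    return SynthConfig(
        n_genes=n_genes,
        n_mito_genes=n_mito,
        clusters=clusters,
        doublet_spec=doublet,
        decoy_spec=decoy,
        seed=seed,
    )
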