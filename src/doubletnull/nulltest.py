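"""The simulated-doublet null test for a hybrid scRNA-seq cluster.

A cluster that co-expresses the signatures of two "parent" clusters can be
a genuine cell population or a dissociation artifact (droplet doublets /
incompletely dissociated cell pairs).  The test builds an explicit null:
artificial doublet profiles are made by pairing random cells from the two
parents, un-logging their normalized expression, averaging, and re-logging
(restricted to the highly variable genes); a negative-control pool is
sampled from all remaining clusters.  Euclidean distances in HVG space
then say whether the query cluster sits closer to the artificial doublets
than to either parent or to unrelated cells — the artifact signature.

``HybridDoubletTest`` is the model object (data + configuration); its
:meth:`~HybridDoubletTest.fit` returns :class:`HybridDoubletResults` with
the distance summaries, the verdict and margins, and a ``summary()``
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist, pdist

from .features import HVGResult, select_hvg
from .preprocess import QCThresholds, normalize_log10k, qc_filter

__all__ = [
    "DoubletSimConfig",
    "SimulatedDoubletSet",
    "mix_profiles",
    "simulate_doublets",
    "sample_negative_control",
    "distance_report",
    "verdict",
    "DoubletVerdict",
    "HybridDoubletTest",
    "HybridDoubletResults",
]

COMPARISONS = (
    "query_vs_query",
    "query_vs_parent_a",
    "query_vs_parent_b",
    "query_vs_simulated_doublets",
    "query_vs_negative_control",
)
_ALTERNATIVES = ("query_vs_parent_a", "query_vs_parent_b", "query_vs_negative_control")


@dataclass
class DoubletSimConfig:
    parent_a: str
    parent_b: str
    query: str
    n_pairs: int = 5000
    n_negative: int = 5000
    seed: int = 0

    def validate(self) -> None:
        if len({self.parent_a, self.parent_b, self.query}) != 3:
            raise ValueError("parent_a, parent_b and query must be three distinct clusters")
        if self.n_pairs <= 0 or self.n_negative <= 0:
            raise ValueError("n_pairs and n_negative must be positive")


@dataclass
class SimulatedDoubletSet:
    profiles: np.ndarray  # n_pairs x n_hvg
    pair_indices: list[tuple[str, str]]  # (cell from parent_a, cell from parent_b)
    seed: int


@dataclass
class DoubletVerdict:
    is_doublet_like: bool
    margins: dict[str, float]  # alternative mean minus simulated-doublet mean
    rule_trace: str

    def to_dict(self) -> dict:
        return {
            "is_doublet_like": bool(self.is_doublet_like),
            "margins": {k: float(v) for k, v in self.margins.items()},
            "rule_trace": self.rule_trace,
        }


def mix_profiles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """In-silico doublet profile: unlog, average, relog.

    Element-wise ln(1 + ((e^a - 1) + (e^b - 1)) / 2).  Exactly inverts the
    log1p normalization convention, is commutative, and is the identity
    when ``a == b``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"profile shapes differ: {a.shape} vs {b.shape}")
    return np.log1p(0.5 * (np.expm1(a) + np.expm1(b)))


def _hvg_matrix(norm: ad.AnnData, hvg: HVGResult | list[str]) -> np.ndarray:
    genes = hvg.genes if isinstance(hvg, HVGResult) else list(hvg)
    idx = norm.var_names.get_indexer(genes)
    if (idx < 0).any():
        missing = [g for g, i in zip(genes, idx) if i < 0]
        raise KeyError(f"HVG genes missing from matrix: {missing[:5]}...")
    X = sp.csr_matrix(norm.X)[:, idx]
    return np.asarray(X.todense(), dtype=np.float64)


def simulate_doublets(
    norm: ad.AnnData,
    labels: pd.Series,
    hvg: HVGResult | list[str],
    cfg: DoubletSimConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDoubletSet:
    """Draw ``cfg.n_pairs`` artificial doublets from the two parent pools.

    One cell is sampled uniformly with replacement from each parent;
    :func:`mix_profiles` is applied to their HVG-restricted log-normalized
    vectors.  Seeded and reproducible.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = labels.reindex(norm.obs_names)
    for parent in (cfg.parent_a, cfg.parent_b):
        if (labels == parent).sum() == 0:
            raise ValueError(f"parent cluster {parent!r} is empty")
    a_cells = norm.obs_names[(labels == cfg.parent_a).to_numpy()]
    b_cells = norm.obs_names[(labels == cfg.parent_b).to_numpy()]
    ia = rng.integers(0, len(a_cells), cfg.n_pairs)
    ib = rng.integers(0, len(b_cells), cfg.n_pairs)
    Xa = _hvg_matrix(norm[a_cells], hvg)
    Xb = _hvg_matrix(norm[b_cells], hvg)
    profiles = mix_profiles(Xa[ia], Xb[ib])
    pairs = [(a_cells[i], b_cells[j]) for i, j in zip(ia, ib)]
    return SimulatedDoubletSet(profiles=profiles, pair_indices=pairs, seed=cfg.seed)


def sample_negative_control(
    labels: pd.Series,
    cfg: DoubletSimConfig,
    rng: np.random.Generator | None = None,
) -> pd.Index:
    """Sample ``cfg.n_negative`` cells from every cluster except the parents
    and the query.

    Without replacement when the pool is large enough; otherwise with
    replacement, with a warning.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    pool = labels.index[~labels.isin([cfg.parent_a, cfg.parent_b, cfg.query])]
    if len(pool) == 0:
        raise ValueError("negative-control pool is empty: no cluster besides parents and query")
    replace = len(pool) < cfg.n_negative
    if replace:
        warnings.warn(
            f"negative-control pool has {len(pool)} cells < n_negative={cfg.n_negative}; "
            "sampling with replacement"
        )
    chosen = rng.choice(len(pool), size=cfg.n_negative, replace=replace)
    return pool[chosen]


def _summarize(d: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(d)),
        "median": float(np.median(d)),
        "p5": float(np.percentile(d, 5)),
        "p95": float(np.percentile(d, 95)),
        "n_pairs_evaluated": int(d.size),
    }


def distance_report(
    norm: ad.AnnData,
    labels: pd.Series,
    hvg: HVGResult | list[str],
    sim: SimulatedDoubletSet,
    neg: pd.Index,
    cfg: DoubletSimConfig,
    return_distances: bool = False,
):
    """All-pairs Euclidean distance summaries in HVG space.

    Compares the query cluster with itself (self-pairs excluded), each
    parent, the simulated doublets, and the negative-control cells.
    Returns a DataFrame indexed by comparison name with mean / median /
    5th / 95th percentile and the number of pairs; optionally also the raw
    distance vectors.
    """
    labels = labels.reindex(norm.obs_names)
    q_mask = (labels == cfg.query).to_numpy()
    if q_mask.sum() == 0:
        raise ValueError(f"query cluster {cfg.query!r} is empty")
    Q = _hvg_matrix(norm[q_mask], hvg)

    dists: dict[str, np.ndarray] = {}
    if Q.shape[0] >= 2:
        dists["query_vs_query"] = pdist(Q)
    else:
        warnings.warn("fewer than 2 query cells; query_vs_query comparison omitted")
    for name, lab in (("query_vs_parent_a", cfg.parent_a), ("query_vs_parent_b", cfg.parent_b)):
        mask = (labels == lab).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"parent cluster {lab!r} is empty")
        dists[name] = cdist(Q, _hvg_matrix(norm[mask], hvg)).ravel()
    dists["query_vs_simulated_doublets"] = cdist(Q, sim.profiles).ravel()
    # neg may contain repeats (with-replacement sampling): index positionally
    neg_pos = norm.obs_names.get_indexer(np.asarray(neg))
    dists["query_vs_negative_control"] = cdist(Q, _hvg_matrix(norm[neg_pos], hvg)).ravel()

    table = pd.DataFrame({k: _summarize(v) for k, v in dists.items()}).T
    table.index.name = "comparison"
    table["n_pairs_evaluated"] = table["n_pairs_evaluated"].astype(int)
    if return_distances:
        return table, dists
    return table


def verdict(report: pd.DataFrame) -> DoubletVerdict:
    """Artifact call: the query is doublet-like iff its mean distance to the
    simulated doublets is strictly smaller than to each parent and to the
    negative control.

    Margins (alternative mean minus simulated mean) are positive exactly
    when the simulated-doublet comparison wins; the query-to-itself mean is
    reported as context but does not enter the rule.
    """
    needed = ("query_vs_simulated_doublets",) + _ALTERNATIVES
    missing = [c for c in needed if c not in report.index]
    if missing:
        raise ValueError(f"distance report is missing comparisons: {missing}")
    sim_mean = float(report.loc["query_vs_simulated_doublets", "mean"])
    margins = {alt: float(report.loc[alt, "mean"]) - sim_mean for alt in _ALTERNATIVES}
    is_doublet_like = all(m > 0 for m in margins.values())
    lines = [f"mean d(query, simulated doublets) = {sim_mean:.4f}"]
    for alt, m in margins.items():
        lines.append(
            f"mean d({alt.replace('query_vs_', 'query, ')}) - sim = {m:+.4f} "
            f"({'sim closer' if m > 0 else 'alternative closer'})"
        )
    if "query_vs_query" in report.index:
        lines.append(
            f"context: mean d(query, query) = {report.loc['query_vs_query', 'mean']:.4f}"
        )
    lines.append(
        "verdict: doublet-like artifact" if is_doublet_like else "verdict: not doublet-like"
    )
    return DoubletVerdict(is_doublet_like=is_doublet_like, margins=margins, rule_trace="\n".join(lines))


class HybridDoubletTest:
    """Model object for the cluster-level doublet-artifact test.

    Parameters
    ----------
    norm
        Log-normalized cells x genes AnnData (see
        :func:`doubletnull.preprocess.normalize_log10k`).
    labels
        Cell -> cluster mapping.  Defaults to ``norm.obs['cluster']``.
    parent_a, parent_b, query
        Cluster labels: the two parents whose signatures the query
        co-expresses, and the hybrid cluster under test.
    hvg
        Variable-gene set defining the expression space; computed from
        ``counts`` in :meth:`from_counts`, or pass an
        :class:`~doubletnull.features.HVGResult` / gene list.
    n_pairs, n_negative
        Sizes of the simulated-doublet set and negative-control pool
        (default 5000 each).
    """

    def __init__(
        self,
        norm: ad.AnnData,
        parent_a: str,
        parent_b: str,
        query: str,
        labels: pd.Series | None = None,
        hvg: HVGResult | list[str] | None = None,
        n_pairs: int = 5000,
        n_negative: int = 5000,
    ):
        self.norm = norm
        self.labels = labels if labels is not None else norm.obs["cluster"].astype(str)
        self.labels = pd.Series(self.labels, index=norm.obs_names).astype(str)
        if hvg is None:
            raise ValueError("an HVG set is required; use from_counts() to compute one")
        self.hvg = hvg
        self.cfg = DoubletSimConfig(parent_a, parent_b, query, n_pairs, n_negative)
        self.cfg.validate()
        present = set(self.labels.unique())
        for lab in (parent_a, parent_b, query):
            if lab not in present:
                raise ValueError(f"cluster {lab!r} not present in the label table")

    @classmethod
    def from_counts(
        cls,
        counts: ad.AnnData,
        parent_a: str,
        parent_b: str,
        query: str,
        labels: pd.Series | None = None,
        qc: QCThresholds | None = None,
        n_hvg: int = 2000,
        n_pairs: int = 5000,
        n_negative: int = 5000,
    ) -> "HybridDoubletTest":
        """Build the test from raw counts: QC -> normalize -> HVG -> model."""
        if labels is not None:
            counts = counts.copy()
            counts.obs["cluster"] = pd.Series(labels, index=counts.obs_names).astype(str)
        filtered, _ = qc_filter(counts, qc)
        norm = normalize_log10k(filtered)
        hvg = select_hvg(filtered, n_hvg=n_hvg)
        return cls(norm, parent_a, parent_b, query, hvg=hvg, n_pairs=n_pairs, n_negative=n_negative)

    def fit(self, seed: int = 0) -> "HybridDoubletResults":
        """Run the null construction and distance comparisons."""
        cfg = DoubletSimConfig(
            self.cfg.parent_a,
            self.cfg.parent_b,
            self.cfg.query,
            self.cfg.n_pairs,
            self.cfg.n_negative,
            seed=seed,
        )
        rng = np.random.default_rng(seed)
        sim = simulate_doublets(self.norm, self.labels, self.hvg, cfg, rng=rng)
        neg = sample_negative_control(self.labels, cfg, rng=rng)
        table, dists = distance_report(
            self.norm, self.labels, self.hvg, sim, neg, cfg, return_distances=True
        )
        v = verdict(table)
        return HybridDoubletResults(
            model=self, config=cfg, distance_report=table, verdict_=v, simulated=sim,
            negative_control=neg, distances_=dists,
        )


@dataclass
class HybridDoubletResults:
    """Fitted doublet-null test: distance summaries, margins and verdict."""

    model: HybridDoubletTest
    config: DoubletSimConfig
    distance_report: pd.DataFrame
    verdict_: DoubletVerdict
    simulated: SimulatedDoubletSet
    negative_control: pd.Index
    distances_: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def is_doublet_like(self) -> bool:
        return self.verdict_.is_doublet_like

    @property
    def margins(self) -> dict[str, float]:
        return self.verdict_.margins

    def summary(self) -> str:
        cfg = self.config
        head = (
            f"Hybrid-cluster doublet test\n"
            f"  query={cfg.query}  parents=({cfg.parent_a}, {cfg.parent_b})  "
            f"n_pairs={cfg.n_pairs}  n_negative={cfg.n_negative}  seed={cfg.seed}\n"
        )
        tbl = self.distance_report.round(4).to_string()
        return head + "\n" + tbl + "\n\n" + self.verdict_.rule_trace

    def plot_distances(self, ax=None, bins: int = 60):
        """Overlaid histograms of the per-comparison distance distributions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for name, d in self.distances_.items():
            ax.hist(d, bins=bins, density=True, histtype="step", label=name)
        ax.set_xlabel("Euclidean distance (HVG space)")
        ax.set_ylabel("density")
        ax.legend(fontsize=7)
        return ax
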