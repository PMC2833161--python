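"""Benchmarks for the coherence statistic and the clustering stages.

Covers: random protein clusters and dilution series for characterizing
functional coherence; partition-agreement metrics (purity, inverse
purity, adjusted Rand index); cosine silhouette widths; and a (k, n_pc)
parameter sweep reporting best-cluster enrichment, silhouette, and
purity against reference labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from . import coarse as coarse_mod
from . import reduce as reduce_mod
from .annotate import hypergeom_pvalue
from .coherence import DocumentIndex, KnowledgeCorpus, functional_coherence
from .microenv import MicroenvironmentSet, standardize

DEFAULT_FRACTIONS = (1.0, 0.8, 0.6, 0.4, 0.2)
DEFAULT_REPLICATES = 50


def make_random_clusters(pool, sizes, n_per_size: int, seed: int = 0) -> list[list[str]]:
    """Uniformly sampled (without replacement) protein clusters of the
    requested sizes, ``n_per_size`` replicates each; seeded."""
    pool = list(pool)
    rng = np.random.default_rng(seed)
    clusters = []
    for size in sizes:
        if size > len(pool):
            raise ValueError(f"requested size {size} exceeds pool of {len(pool)}")
        for _ in range(n_per_size):
            idx = rng.choice(len(pool), size=size, replace=False)
            clusters.append([pool[i] for i in idx])
    return clusters


@dataclass
class DilutionSeries:
    """Clusters with progressively reduced biological signal.

    ``fixed`` mode replaces members with pool proteins at constant size;
    ``additive`` mode keeps the base and adds pool proteins until the
    base is the requested fraction of the cluster.
    """

    base: list[str]
    mode: str
    fractions: list[float]
    pool_tag: str
    clusters: dict[float, list[list[str]]] = field(default_factory=dict)  # fraction → replicates
    percent_signal: dict[float, float] = field(default_factory=dict)


def make_dilution_series(base, pool, mode: str, fractions=DEFAULT_FRACTIONS,
                         n_replicates: int = DEFAULT_REPLICATES, seed: int = 0,
                         pool_tag: str = "random") -> DilutionSeries:
    """Build a dilution series from a base cluster and a disjoint pool."""
    base = list(base)
    pool = list(pool)
    if set(base) & set(pool):
        raise ValueError("replacement pool must be disjoint from the base cluster")
    if mode not in ("fixed", "additive"):
        raise ValueError(f"unknown dilution mode {mode!r}")
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    series = DilutionSeries(base=base, mode=mode, fractions=list(fractions), pool_tag=pool_tag)
    for frac in fractions:
        reps = []
        for _ in range(n_replicates):
            if frac == 1.0:
                cluster = list(base)
            elif mode == "fixed":
                n_keep = int(round(frac * len(base)))
                n_replace = len(base) - n_keep
                if n_replace > len(pool):
                    raise ValueError("replacement count exceeds pool size")
                keep_idx = rng.choice(len(base), size=n_keep, replace=False)
                pool_idx = rng.choice(len(pool), size=n_replace, replace=False)
                cluster = [base[i] for i in sorted(keep_idx)] + [pool[i] for i in pool_idx]
            else:  # additive: size = base_size / fraction (rounded up)
                size = int(np.ceil(len(base) / frac))
                n_add = size - len(base)
                if n_add > len(pool):
                    raise ValueError("additive count exceeds pool size")
                pool_idx = rng.choice(len(pool), size=n_add, replace=False)
                cluster = list(base) + [pool[i] for i in pool_idx]
            reps.append(cluster)
        series.clusters[frac] = reps
        kept = len(base) if mode == "additive" or frac == 1.0 else int(round(frac * len(base)))
        series.percent_signal[frac] = kept / len(reps[0])
    return series


def coherence_curve(series: DilutionSeries, index: DocumentIndex,
                    corpus: KnowledgeCorpus) -> list[tuple[float, float]]:
    """(fraction, median F) per dilution fraction; unscorable replicate
    clusters are recorded as missing, not fatal."""
    curve = []
    for frac in series.fractions:
        values = []
        for cluster in series.clusters[frac]:
            try:
                values.append(functional_coherence(cluster, index, corpus).F)
            except ValueError:
                continue
        curve.append((frac, float(np.median(values)) if values else float("nan")))
    return curve


def partition_metrics(predicted, truth) -> dict[str, float]:
    """Purity (precision-like), inverse purity (recall-like), and ARI."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("label vectors differ in length")
    n = len(truth)

    def _purity(a, b):
        total = 0
        for c in np.unique(a):
            mask = a == c
            _, counts = np.unique(b[mask], return_counts=True)
            total += counts.max()
        return total / n

    return {
        "purity": _purity(predicted, truth),
        "inverse_purity": _purity(truth, predicted),
        "ari": float(adjusted_rand_score(truth, predicted)),
    }


def silhouette_cosine(ms: MicroenvironmentSet, labels) -> tuple[np.ndarray, float]:
    """Per-point and mean silhouette widths under cosine distance;
    singleton clusters get width 0 (sklearn's convention)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    widths = silhouette_samples(ms.features, labels, metric="cosine")
    return widths, float(widths.mean())


def parameter_sweep(ms: MicroenvironmentSet, k_values, pc_values, truth_labels,
                    seed: int = 0, n_restarts: int = 3) -> list[dict]:
    """Sweep (k, n_pc): run reduce→coarse and report, per combination,
    the mean best-cluster hypergeometric enrichment over truth classes,
    mean cosine silhouette, and purity.  Returns one dict per row
    (write with pandas if a TSV is wanted)."""
    truth_labels = np.asarray(truth_labels)
    std = standardize(ms) if ms.space_tag == "raw" else ms
    rows = []
    for n_pc in pc_values:
        model = reduce_mod.fit_pca(std, n_components=n_pc)
        red = reduce_mod.transform(model, std)
        for k in k_values:
            result = coarse_mod.restarts(red, k, n_restarts=n_restarts, base_seed=seed)
            labels = result.assignments
            enrich = _mean_best_enrichment(labels, truth_labels)
            if k >= 2:
                _, sil = silhouette_cosine(red, labels)
            else:
                sil = float("nan")
            purity = partition_metrics(labels, truth_labels)["purity"]
            rows.append(
                {"k": k, "n_pc": n_pc, "mean_best_log10_p": enrich,
                 "mean_silhouette": sil, "purity": purity}
            )
    return rows


def _mean_best_enrichment(labels: np.ndarray, truth: np.ndarray) -> float:
    """For each truth class, the best (smallest) hypergeometric p of any
    predicted cluster for containing that class; mean of log10 p."""
    n = len(labels)
    logs = []
    for t in np.unique(truth):
        if t < 0:
            continue
        t_mask = truth == t
        best = 1.0
        for c in np.unique(labels):
            c_mask = labels == c
            k = int(np.sum(t_mask & c_mask))
            p = hypergeom_pvalue(k, int(c_mask.sum()), int(t_mask.sum()), n)
            best = min(best, p)
        logs.append(np.log10(max(best, 1e-300)))
    return float(np.mean(logs))


def labels_from_records(records, ms: MicroenvironmentSet) -> np.ndarray:
    """Partition labels induced by selected cluster records: sites in the
    same record share a label, every unassigned site becomes a singleton.
    Useful for comparing a selection against planted labels."""
    key = lambda s: (s.structure_id, s.chain, s.residue_number)
    assign = {}
    for j, r in enumerate(records):
        for s in r.member_sites:
            assign[key(s)] = j
    labels = np.empty(ms.n_sites, dtype=int)
    next_singleton = len(records)
    for i, s in enumerate(ms.sites):
        if key(s) in assign:
            labels[i] = assign[key(s)]
        else:
            labels[i] = next_singleton
            next_singleton += 1
    return labels


def sweep_to_tsv(rows: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plot_coherence_curves(curves: dict[str, list[tuple[float, float]]], path) -> None:
    """Optional PNG plot of dilution curves (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        xs, ys = zip(*sorted(curve))
        ax.plot(xs, ys, marker="o", label=label)
    ax.set_xlabel("fraction of original members (signal)")
    ax.set_ylabel("median functional coherence")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
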